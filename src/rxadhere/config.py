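"""Study configuration: simulation settings plus analysis parameters."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .definitions import DEFAULT_HBA1C_DIABETES_THRESHOLD
from .errors import ConfigurationError
from .synthetic_data import SimConfig

__all__ = ["StudyConfig", "load_study_config"]


@dataclass
class StudyConfig:
    """Everything a full study run needs besides the seed.

    ``age_knot`` and ``tablets_knot`` are the linear-spline knots for
    age (association with non-adherence flattens around 70) and
    second-line pill burden (flattens around 10 tablets/day); both are
    overridable. ``category_map`` and ``charlson_weights`` default to
    the package's built-in maps when ``None``.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    age_knot: float = 70.0
    tablets_knot: float = 10.0
    hba1c_diabetes_threshold: float = DEFAULT_HBA1C_DIABETES_THRESHOLD
    mpr_bin_edges: list[float] = field(
        default_factory=lambda: [20, 50, 60, 70, 80, 85, 90, 95, 100, 105, 110, 120]
    )
    category_map: dict | None = None
    charlson_weights: dict | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def load_study_config(path) -> StudyConfig:
    """Load a study.yaml; unknown keys raise a configuration error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("simulate", {}) or {}
    try:
        sim = SimConfig(**sim_raw)
    except TypeError as exc:
        raise ConfigurationError(f"bad simulate section: {exc}") from exc
    try:
        cfg = StudyConfig(sim=sim, **raw)
    except TypeError as exc:
        raise ConfigurationError(f"bad study config: {exc}") from exc
    sim.validate()
    return cfg
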