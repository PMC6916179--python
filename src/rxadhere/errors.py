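"""Exception hierarchy for rxadhere."""


class RxAdhereError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RxAdhereError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(RxAdhereError):
    """An input table is missing a required column or has a bad value."""


class UndeterminedDiagnosisError(RxAdhereError):
    """No qualifying record from which to compute a diagnosis date."""


class UndefinedOutcomeError(RxAdhereError):
    """An outcome/metric was requested for an undefined (invalid) input."""


class IncomparableModelsError(RxAdhereError):
    """A nested-model test was requested between fits on different rows."""


class ReferentialIntegrityError(RxAdhereError):
    """A join between pipeline tables produced orphan identifiers."""
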