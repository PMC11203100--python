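"""Exception hierarchy shared across the package.

Each class maps to a distinct CLI exit code so that shell pipelines can
distinguish configuration mistakes from data problems.
"""


class MRError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(MRError):
    """Missing/invalid configuration: absent columns, bad YAML keys, unknown methods."""

    exit_code = 2


class ValidationError(MRError):
    """Input data violates a contract (bad numeric field, se <= 0, unknown SNP...)."""

    exit_code = 3


class EmptyInstrumentsError(MRError):
    """No instruments survive a selection/harmonization stage."""

    exit_code = 4


class InsufficientInstrumentsError(MRError):
    """An estimator requires more instruments than are available."""

    exit_code = 4
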