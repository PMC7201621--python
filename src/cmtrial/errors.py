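"""Exception taxonomy shared across the pipeline stages."""


class CMTrialError(Exception):
    """Base class for all cmtrial errors."""


class InvalidInputError(CMTrialError, ValueError):
    """An argument violates a precondition (non-positive weight, unknown protocol...)."""


class ImplausibleInputError(CMTrialError, ValueError):
    """Inputs are formally valid but yield a physiologically impossible result."""


class ContractError(CMTrialError, TypeError):
    """Caller passed an argument combination that violates an interface contract."""


class ConfigError(CMTrialError, ValueError):
    """A configuration object is internally inconsistent or infeasible."""


class CalibrationError(CMTrialError, RuntimeError):
    """The response-model calibration loop failed to reach its targets."""


class StateError(CMTrialError, RuntimeError):
    """An operation was invoked on an object in the wrong state."""


class DegenerateInputError(CMTrialError, ValueError):
    """A statistical routine received data it cannot form a test from."""


class DataIntegrityError(CMTrialError, ValueError):
    """Tables that should join cleanly do not (orphan ids, duplicates...)."""


class AmbiguityError(CMTrialError, ValueError):
    """A reconstruction admits more than one equally good answer."""
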