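"""Exception taxonomy shared across the package."""


class BoneCnnError(Exception):
    """Base class for package errors."""


class ConfigurationError(BoneCnnError, ValueError):
    """A configuration object violates one of its invariants."""


class InputError(BoneCnnError, ValueError):
    """Runtime input (image, batch, labels) violates a precondition."""


class FormatError(BoneCnnError, ValueError):
    """A serialised artifact (manifest CSV, config file) is malformed."""


class ContractViolationError(BoneCnnError, RuntimeError):
    """An operation was asked to break a pipeline contract (e.g. augmenting val/test)."""
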