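"""Exception hierarchy shared across the package."""


class FedSimHashError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FedSimHashError, ValueError):
    """An invalid parameter value (fractions, bit widths, key sizes, ...)."""


class FormatError(FedSimHashError, ValueError):
    """Malformed input data: unknown code prefix, non-binary code entry, ..."""


class DimensionError(FedSimHashError, ValueError):
    """Shape mismatch between matrices that must conform."""


class PartitionError(FedSimHashError, ValueError):
    """A site-partition plan that cannot be satisfied by the cohort."""


class AssemblyError(FedSimHashError, ValueError):
    """A site dataset that would be empty or unusable after filtering."""


class NumericError(FedSimHashError, ArithmeticError):
    """Non-finite values or unsolvable linear systems during optimization."""


class ProtocolError(FedSimHashError, RuntimeError):
    """Federation or encryption message-protocol violation."""


class IntegrityError(FedSimHashError, RuntimeError):
    """A decrypted value inconsistent with the protocol's invariants."""
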