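"""Exception hierarchy shared across the package."""


class MetalScreenError(Exception):
    """Base class for all package-specific errors."""


class FormulaError(MetalScreenError, ValueError):
    """Malformed or unrepresentable elemental composition."""


class FormulaUnderflowError(FormulaError):
    """A composition delta would drive an element count below zero."""


class UnknownElementError(FormulaError, KeyError):
    """Element symbol not present in the isotope table."""


class InvalidPairingError(MetalScreenError, ValueError):
    """Building-block roles do not form a legal coupling."""


class DuplicateIdError(MetalScreenError, ValueError):
    """A registry or enumeration contains a repeated identifier."""


class PlateOverflowError(MetalScreenError, ValueError):
    """More compounds than wells."""


class InputError(MetalScreenError, ValueError):
    """Generic invalid-input error for analytic routines."""


class DegenerateControlError(InputError):
    """Growth control does not exceed the blank; normalization undefined."""


class UndefinedConversionError(InputError):
    """Total UV peak area is zero; conversion percent undefined."""


class UnsupportedKernelError(MetalScreenError, ValueError):
    """Feature importance requires a linear-kernel model."""
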