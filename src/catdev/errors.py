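"""Exception types shared across the package."""


class CatDevError(Exception):
    """Base class for all package-specific errors."""


class InvalidItemError(CatDevError):
    """Item parameters violate their model's constraints."""


class InvalidResponseError(CatDevError):
    """A response code is outside the item's category range."""


class MissingItemError(CatDevError):
    """An item id was requested that the bank does not contain."""


class CalibrationError(CatDevError):
    """Item calibration cannot proceed (e.g. a degenerate item)."""


class ScreeningError(CatDevError):
    """A pool-screening step cannot be computed on the given data."""
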