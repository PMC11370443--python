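"""Exception hierarchy for scarquant."""


class ScarQuantError(Exception):
    """Base class for all scarquant errors."""


class ValidationError(ScarQuantError, ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(ScarQuantError, ValueError):
    """A run configuration is inconsistent or names an unknown option."""


class ImageIOError(ScarQuantError, OSError):
    """An image file could not be read or written."""


class EmptyTissueError(ScarQuantError, ValueError):
    """No tissue was found in an image; the background threshold may need adjustment."""
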