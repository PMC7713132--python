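"""Exception types shared across the package."""


class MirsortError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MirsortError):
    """Malformed input (bad manifest, bad sequence alphabet, bad config)."""


class ConstructionError(MirsortError):
    """A synthetic hairpin could not be built as requested."""


class NoDuplexError(MirsortError):
    """A guide span pairs nowhere in the fold; no guide/star duplex exists."""
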