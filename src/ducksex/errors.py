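"""Exception hierarchy shared across the package."""


class DucksexError(Exception):
    """Base class for all package-specific errors."""


class AudioFormatError(DucksexError):
    """Unsupported or malformed audio input (wrong channel count, encoding, rate)."""


class ManifestError(DucksexError):
    """Invalid dataset manifest (missing columns, duplicate ids, bad labels)."""


class ParameterError(DucksexError):
    """Out-of-range or inconsistent algorithm parameter."""


class ShapeError(DucksexError):
    """Array shape mismatch between pipeline stages."""


class StateError(DucksexError):
    """Operation applied in the wrong pipeline state (e.g. double windowing)."""
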