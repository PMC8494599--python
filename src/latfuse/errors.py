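"""Exception types shared across the package."""


class LatfuseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LatfuseError, ValueError):
    """Unsupported or malformed image file (channel count, bit depth, codec)."""


class DimensionError(LatfuseError, ValueError):
    """Shapes of paired inputs disagree or are inconsistent with an operation."""


class ContractError(LatfuseError, ValueError):
    """A documented numeric contract is violated (range, convexity, extractor shape)."""


class ConvergenceWarning(UserWarning):
    """The iterative solver stopped at max_iter with a residual above tolerance."""
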