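"""Exception hierarchy for refstab."""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class FormatError(RefstabError, ValueError):
    """Malformed input file: missing columns, bad dialect, duplicate wells."""


class CqValueError(RefstabError, ValueError):
    """Non-numeric, non-finite or non-positive Cq value; names the offending row."""


class InsufficientDataError(RefstabError):
    """Too few samples/genes for the requested statistic."""


class EstimationError(RefstabError):
    """Amplification-efficiency estimation failed (no usable window)."""


class GeneSetMismatchError(RefstabError, ValueError):
    """Per-method rank lists do not cover the identical gene set."""
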