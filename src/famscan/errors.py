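"""Exception hierarchy shared across stages."""


class FamscanError(Exception):
    """Base class for all famscan errors."""


class FormatError(FamscanError, ValueError):
    """Malformed input data (ragged alignments, bad GFF3 lines, ...)."""


class InputError(FamscanError, ValueError):
    """Semantically invalid input (empty sequence, too few taxa, ...)."""


class ConfigurationError(FamscanError, ValueError):
    """Invalid configuration, preset or catalog entry."""


class AnnotationError(FamscanError, KeyError):
    """Cross-reference failure between stages (e.g. member without gene model)."""


class DataError(FamscanError, ValueError):
    """Inconsistent tabular data (e.g. missing reference-gene rows)."""
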