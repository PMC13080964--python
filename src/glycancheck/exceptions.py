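"""Exception hierarchy for glycancheck."""


class GlycanCheckError(Exception):
    """Base class for all package errors."""


class ParseError(GlycanCheckError):
    """A structure file could not be read."""


class FormatError(GlycanCheckError):
    """Unknown or unsupported structure format, or a format capacity limit."""


class GeometryError(GlycanCheckError):
    """Degenerate geometric input (collinear, duplicate, mismatched points)."""


class DictionaryError(GlycanCheckError):
    """Malformed or missing reference-dictionary entry."""


class BuildError(GlycanCheckError):
    """Synthetic glycan construction failed (bad spec, unresolvable clash)."""


class LinkageError(GlycanCheckError):
    """Ambiguous or invalid glycosidic connectivity."""
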