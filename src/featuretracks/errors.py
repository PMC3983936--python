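"""Exception hierarchy.

Every error raised by this package derives from :class:`FeatureTracksError`
so callers can catch one base class at the CLI boundary.
"""


class FeatureTracksError(Exception):
    """Base class for all featuretracks errors."""


class CoordinateError(FeatureTracksError):
    """Invalid residue coordinates (start > end, non-positive, ...)."""


class VocabularyError(FeatureTracksError):
    """A string is not in a closed vocabulary (glyph kinds, styles)."""


class ConfigError(FeatureTracksError):
    """A LayoutConfig invariant is violated."""


class WindowError(FeatureTracksError):
    """A requested residue window is inverted or out of range."""


class ParseError(FeatureTracksError):
    """An input document could not be parsed; message carries location."""


class MultiSegmentError(ParseError):
    """A GFF3 document annotates more than one seqid (one segment per view)."""


class SchemaError(FeatureTracksError):
    """A layout-JSON document is missing required keys."""

    def __init__(self, missing_keys):
        self.missing_keys = list(missing_keys)
        super().__init__(
            "layout document missing required keys: " + ", ".join(self.missing_keys)
        )


class GeometryError(FeatureTracksError):
    """Glyph kind and supplied geometry fields do not match."""


class CapabilityError(FeatureTracksError):
    """An optional capability (raster export) is unavailable at runtime."""


class FeasibilityError(FeatureTracksError):
    """Requested synthetic fixture cannot satisfy its depth/length bounds."""
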