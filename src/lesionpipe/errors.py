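"""Exception hierarchy shared across the pipeline stages."""


class LesionPipeError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(LesionPipeError, ValueError):
    """A parameter object or configuration violates its contract."""


class MissingTissueError(LesionPipeError, ValueError):
    """A required tissue mask is empty."""


class DegenerateDesignError(LesionPipeError, ValueError):
    """A regression design matrix cannot support the requested model."""


class CollinearityError(DegenerateDesignError):
    """Design matrix is rank deficient."""

    def __init__(self, terms):
        self.terms = list(terms)
        super().__init__(f"collinear design columns: {', '.join(self.terms)}")


class AlignmentError(LesionPipeError, ValueError):
    """Two gridded inputs do not share a grid/affine."""


class FormatError(LesionPipeError, ValueError):
    """A file does not conform to its declared on-disk format."""


class TrackingError(LesionPipeError, RuntimeError):
    """Tractogram generation failed (e.g. degenerate FOD field)."""


class EmptyROIError(LesionPipeError, ValueError):
    """A lesionometry ROI is empty; statistics are undefined."""
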