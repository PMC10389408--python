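"""Exception hierarchy shared across the pipeline stages."""


class TammorphError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(TammorphError):
    """A polygon is degenerate, self-intersecting or otherwise unusable."""


class UndersampledZoneError(TammorphError):
    """A zone holds fewer cells than the sampling protocol requires."""

    def __init__(self, slide_id, zone_id, available, required):
        self.slide_id = slide_id
        self.zone_id = zone_id
        self.available = available
        self.required = required
        super().__init__(
            f"slide {slide_id!r} zone {zone_id!r} has {available} cells, "
            f"{required} required"
        )


class DegenerateLabelsError(TammorphError):
    """All-event or all-non-event outcome vector; ROC/survival undefined."""


class DegenerateCovariateError(TammorphError):
    """A covariate is constant (or separates the outcome) and cannot be fit."""


class ConvergenceError(TammorphError):
    """The partial-likelihood optimiser failed to converge."""


class AnnotationError(TammorphError):
    """A slide annotation file is missing required structure."""


class StageError(TammorphError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")
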