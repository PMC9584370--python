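"""Exception types shared across the blebquant pipeline."""


class BlebQuantError(Exception):
    """Base class for all blebquant errors."""


class ParameterError(BlebQuantError, ValueError):
    """An argument is out of its documented domain."""


class SizingError(ParameterError):
    """A phantom grid is too small to contain the requested geometry."""


class MissingComponentError(BlebQuantError, KeyError):
    """A required anatomical component is absent from a label volume."""


class TopologyError(BlebQuantError):
    """A surface is not closed/manifold, or a mask yields no valid surface."""


class DegenerateFitError(BlebQuantError):
    """Too few or too ill-conditioned points to fit the plate plane."""


class AmbiguityError(DegenerateFitError):
    """The plate point cloud has no unique minor principal axis."""


class GeometryError(BlebQuantError):
    """Components are not arranged as the measurement requires."""


class IncompleteDataError(BlebQuantError):
    """A clinical record lacks a required field."""


class SchemaError(BlebQuantError):
    """A cohort file does not provide the mandatory columns."""


class StageError(BlebQuantError):
    """A pipeline stage failed; carries the stage name for attribution."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
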