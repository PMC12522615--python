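"""Exception hierarchy shared across the package."""


class PerioPanoError(Exception):
    """Base class for all domain errors raised by periopano."""


class AnnotationParseError(PerioPanoError):
    """A LabelMe document is malformed (missing or ill-typed field)."""


class UnsupportedShapeError(AnnotationParseError):
    """A shape has a shape_type other than 'polygon'."""


class DuplicateAnnotationError(AnnotationParseError):
    """The same tooth / bone / CEJ role is annotated more than once."""


class SchemaError(PerioPanoError):
    """A label or FDI code is missing from, or invalid under, a schema/class map."""


class SceneValidationError(PerioPanoError):
    """A contour or scene violates its structural invariants."""


class SplitError(PerioPanoError):
    """Dataset split requested on an empty or inconsistent input."""


class AmbiguousAxisError(PerioPanoError):
    """A tooth polygon is too isotropic to define a principal axis."""


class MeasurementError(PerioPanoError):
    """Scene-level measurement cannot proceed (e.g. no bone contour)."""


class NoAssessableTeethError(PerioPanoError):
    """Staging requested on a scene with no measurable tooth."""


class GenerationError(PerioPanoError):
    """The synthetic scene configuration cannot be placed without overlap."""
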