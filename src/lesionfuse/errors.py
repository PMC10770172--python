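"""Exception hierarchy for lesionfuse.

Every stage raises a subclass of :class:`LesionFuseError`, so callers (and the
pipeline driver) can catch domain failures without masking programming errors.
"""


class LesionFuseError(Exception):
    """Base class for all lesionfuse domain errors."""


class InvalidSpecError(LesionFuseError):
    """A synthetic lesion specification is inconsistent (e.g. lesion out of bounds)."""


class EmptyDatasetError(LesionFuseError):
    """A dataset request for zero samples."""


class InvalidInputError(LesionFuseError):
    """An operation received an image/mask/sequence that violates its preconditions."""


class UnfillableMaskError(LesionFuseError):
    """Inpainting found a masked pixel with no unmasked neighbours even after
    escalating the neighbourhood radius."""


class InvalidArchitectureError(LesionFuseError):
    """A CNN stack cannot be built for the requested input size."""


class InvalidModelError(LesionFuseError):
    """A model handle lacks a required structural property (e.g. 64-unit dense layer)."""


class DegenerateTrainingError(LesionFuseError):
    """Training data covers a single class only."""


class UnbalanceableError(LesionFuseError):
    """Class balancing is impossible because one class is empty."""


class EmptyPartitionError(LesionFuseError):
    """BSC segregation called on an empty record sequence."""


class UndefinedRatioError(LesionFuseError):
    """An error ratio was requested over an empty confidence band."""


class UndefinedScoreError(LesionFuseError):
    """A clinical score has a zero denominator (empty mask, zero perimeter...)."""


class NoLesionError(LesionFuseError):
    """Segmentation found no lesion (constant image or empty post-morphology mask)."""


class UnsupportedClassifierError(LesionFuseError):
    """An unknown classifier name was requested."""


class UndefinedAucError(LesionFuseError):
    """ROC/AUC requested with a single-class truth vector."""
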