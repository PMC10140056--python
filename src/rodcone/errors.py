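"""Exception hierarchy for rodcone.

All errors derive from :class:`RodconeError`; argument-validation failures
additionally derive from :class:`ValueError` so that generic callers can
catch them idiomatically.
"""


class RodconeError(Exception):
    """Base class for all rodcone errors."""


class InvalidArgumentError(RodconeError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateLandmarkError(RodconeError, ValueError):
    """Fovea and optic-nerve landmarks coincide (or one is missing),
    so the two-landmark similarity transform is undefined."""


class InsufficientSupportError(RodconeError, ValueError):
    """Fewer than three non-collinear scattered samples: no triangulation,
    hence no interpolant."""


class EmptyRegionError(RodconeError, ValueError):
    """A regional statistic was requested over a mask with no valid pixels."""


class NonIdentifiableError(RodconeError):
    """The two ETDRS regions have effectively identical rod/cone
    composition, so the two-region linear system has no unique solution."""


class NoCompensationLayerError(RodconeError, ValueError):
    """Voxel removal requested but the vitreous (compensation layer)
    is empty, so column length cannot be conserved."""
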