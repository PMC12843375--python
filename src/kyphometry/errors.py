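"""Exception hierarchy for kyphometry.

All exceptions derive from :class:`KyphometryError` so callers can catch
package failures with a single except clause.
"""


class KyphometryError(Exception):
    """Base class for all kyphometry errors."""


class InsufficientPointsError(KyphometryError):
    """Fewer than three points were supplied to a circle fit."""


class CollinearPointsError(KyphometryError):
    """Points are collinear within tolerance; the fitted circle degenerates
    (radius tends to infinity)."""


class DegenerateAngleError(KyphometryError):
    """An angle endpoint coincides with the circle center (or with the other
    endpoint), so the subtended angle is undefined."""


class SpecError(KyphometryError):
    """A phantom specification is geometrically invalid (arc out of image
    bounds, vertebral bodies overlapping, non-positive sizes, ...)."""


class ZeroVarianceError(KyphometryError):
    """A correlation-type statistic was requested on a constant column."""


class TooFewPairsError(KyphometryError):
    """Not enough paired measurements for the requested statistic."""


class EmptyDatasetError(KyphometryError):
    """A detection evaluation was requested on an empty dataset."""


class UndefinedMetricError(KyphometryError):
    """A diagnostic proportion has a zero denominator.

    Report builders normally record such metrics as absent (``None``) rather
    than raising; this exception exists for strict call sites.
    """
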