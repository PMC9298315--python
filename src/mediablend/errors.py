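"""Exception hierarchy for mediablend.

Every error raised by the library derives from :class:`MediablendError`,
so callers (and the CLI) can distinguish validation problems from bugs.
"""


class MediablendError(Exception):
    """Base class for all mediablend errors."""


# --- registry -----------------------------------------------------------


class DuplicateName(MediablendError):
    """A stock or component name is already registered (case-insensitive)."""


class UnknownComponent(MediablendError):
    """A stock references a component absent from the registry."""


class NonPositiveConcentration(MediablendError):
    """A concentration that must be > 0 is zero or negative."""


class MissingSolubility(MediablendError):
    """Stockability asked for a component without a solubility limit."""


class UnitMismatch(MediablendError):
    """Two quantities with different unit families were combined."""


# --- blending -----------------------------------------------------------


class OverfullWell(MediablendError):
    """Summed stock volumes exceed the well fill volume."""


class SubMinimumTransfer(MediablendError):
    """A required transfer is below the pipettable minimum.

    Attributes
    ----------
    item : str
        Offending target item.
    required_ul : float
        The ideal transfer volume that is too small.
    min_dilution : float
        Smallest fold-dilution of the stock that would lift the transfer
        to the minimum (e.g. 10.0 means "use a 10x more dilute stock").
    """

    def __init__(self, item, required_ul, min_transfer):
        self.item = item
        self.required_ul = required_ul
        self.min_dilution = min_transfer / required_ul if required_ul > 0 else float("inf")
        super().__init__(
            f"transfer for {item!r} is {required_ul:.4g} ul, below the "
            f"{min_transfer:g} ul minimum; dilute the stock >= "
            f"{self.min_dilution:.3g}x to make it pipettable"
        )


class AmbiguousItem(MediablendError):
    """A component target is supplied by more than one registered stock."""


class UnresolvedItem(MediablendError):
    """A target item matches no registered stock or component."""


class WaterOnlyMedium(MediablendError):
    """Fold-concentration is undefined for a pure-water plan."""


# --- plates -------------------------------------------------------------


class CapacityExceeded(MediablendError):
    """More wells requested than the plate budget provides."""


class MissingPlan(MediablendError):
    """A well assignment references a medium without a transfer plan."""


# --- statistics ---------------------------------------------------------


class EmptyFactor(MediablendError):
    """A factorial factor has no (or a single) level."""


class RankDeficient(MediablendError):
    """The design matrix does not have full column rank."""


class TooFewRuns(MediablendError):
    """Not enough runs to estimate the requested model terms."""


class MissingControl(MediablendError):
    """Screen data lack the named control condition."""


class TooFewReplicates(MediablendError):
    """A statistical comparison needs at least two replicates per group."""


# --- simulator / optimizer ---------------------------------------------


class InvalidShapeParameters(MediablendError):
    """Effect-shape parameters violate their constraints."""


class InfeasibleCandidate(MediablendError):
    """A screening candidate cannot be blended under the constraints."""
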