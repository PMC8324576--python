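"""Semi-quantitative afforestation / deforestation / fire-regime classification.

Each record is assessed over event windows anchored on the year of Iberian
contact (or documented population decline): the 100 years following contact,
a baseline of the 100 years immediately before it, and a pre-contact window
(1000-1400 CE for the Neotropics, 1000 CE to contact for the East Indies).
Three lines of evidence are combined: the direction of the openness proxy
itself (window-mean change), the trend's first-derivative sign detections
inside the window, and — for the Neotropics — whether the zonation places a
significant compositional break with a clear arboreal-share change inside
the window.  Full classes require proxy and trend agreement (plus the
compositional break in the Neotropics); one line of evidence missing demotes
the class to minor/unclear; a pre-contact signal is assigned only when no
post-contact class fires; records meeting nothing are classified as limited
forest response.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .composition import CharcoalSeries, OpennessSeries, PFGTable
from .records import Region, ValidationError
from .smoothing import DerivativeEstimate, DerivativeSign, GamFit
from .zonation import ZonationResult

__all__ = [
    "Direction",
    "VegetationClass",
    "FireClass",
    "Thresholds",
    "EventWindows",
    "EvidenceBundle",
    "SignalClassification",
    "assess_window",
    "classify_vegetation",
    "classify_fire",
]


class Direction(enum.Enum):
    CLOSING = "CLOSING"  # forest cover increasing (openness falling)
    OPENING = "OPENING"
    FLAT = "FLAT"
    NONE = "NONE"  # no detected trend (GAM evidence only)


class VegetationClass(enum.Enum):
    POST_AFFORESTATION = "POST_AFFORESTATION"
    POST_AFFORESTATION_MINOR = "POST_AFFORESTATION_MINOR"
    POST_DEFORESTATION = "POST_DEFORESTATION"
    POST_DEFORESTATION_MINOR = "POST_DEFORESTATION_MINOR"
    PRE_AFFORESTATION = "PRE_AFFORESTATION"
    LIMITED = "LIMITED"


class FireClass(enum.Enum):
    FIRE_DECREASE = "FIRE_DECREASE"
    FIRE_DECREASE_MINOR = "FIRE_DECREASE_MINOR"
    FIRE_INCREASE = "FIRE_INCREASE"
    FIRE_INCREASE_MINOR = "FIRE_INCREASE_MINOR"
    FIRE_LIMITED = "FIRE_LIMITED"
    NOT_APPLICABLE = "NOT_APPLICABLE"


@dataclass(frozen=True)
class Thresholds:
    """Magnitude thresholds behind the directional rules.

    The classification criteria state directions, not magnitudes; these
    defaults make the rules explicit and are the knobs the sensitivity sweep
    varies.  ``theta`` is on the openness-proportion scale, ``delta_pp`` in
    percentage points of arboreal share, ``theta_fire`` a relative change in
    window-mean charcoal influx.
    """

    theta: float = 0.02
    delta_pp: float = 5.0
    theta_fire: float = 0.20
    #: A derivative sign detection counts toward a window only where the
    #: fitted slope reaches this fraction of the record's peak slope of the
    #: same sign; this keeps the broad tail of an old transition, smeared
    #: out by a low-rank smooth, from registering as change in a later
    #: window.
    gam_localization: float = 0.5
    #: Trend-centre and zone-boundary windows are padded by these many years
    #: before and after: smoothing and finite sampling blur the apparent
    #: timing of an event by roughly the sampling interval, and the blur is
    #: asymmetric — a transition is expressed in the fit and the zonation
    #: only once enough younger samples record the new state, so apparent
    #: timings lag more often than they lead.
    window_pad_before_yr: float = 75.0
    window_pad_after_yr: float = 250.0

    def __post_init__(self) -> None:
        if self.theta <= 0 or self.delta_pp <= 0 or self.theta_fire <= 0:
            raise ValidationError("all thresholds must be > 0")
        if not 0.0 <= self.gam_localization <= 1.0:
            raise ValidationError("gam_localization must be in [0, 1]")


@dataclass(frozen=True)
class EventWindows:
    """Assessment windows (year CE intervals) anchored on the contact year.

    The post-contact assessment compares the century after contact with the
    century before it.  The pre-contact assessment asks whether forest cover
    increased *within* the pre-contact period (1000-1400 CE in the
    Neotropics, 1000 CE to contact in the East Indies): its proxy comparison
    is the period's final century against its first century, while trend
    detections and compositional breaks count anywhere inside the period.
    """

    contact_year: float
    region: Region
    post_window: tuple[float, float] = field(init=False)
    baseline_window: tuple[float, float] = field(init=False)
    pre_window: tuple[float, float] = field(init=False)  # the whole pre period
    pre_assess_window: tuple[float, float] = field(init=False)  # final century
    pre_baseline_window: tuple[float, float] = field(init=False)  # first century
    industrial_window: tuple[float, float] = (1850.0, 1950.0)

    def __post_init__(self) -> None:
        c = self.contact_year
        object.__setattr__(self, "post_window", (c, c + 100.0))
        object.__setattr__(self, "baseline_window", (c - 100.0, c))
        pre_hi = 1400.0 if self.region is Region.NEOTROPICS else c
        if pre_hi <= 1100.0:
            raise ValidationError("pre period too short; contact year too early")
        object.__setattr__(self, "pre_window", (1000.0, pre_hi))
        object.__setattr__(self, "pre_assess_window", (pre_hi - 100.0, pre_hi))
        object.__setattr__(self, "pre_baseline_window", (1000.0, 1100.0))


@dataclass(frozen=True)
class EvidenceBundle:
    """One window's evidence: proxy direction, trend direction, PFG break."""

    proxy_direction: Direction
    proxy_magnitude: float  # window mean - baseline mean (openness proportion)
    gam_direction: Direction
    pfg_clear_change: bool
    pfg_delta_pp: float  # arboreal-share change across the in-window break
    samples_in_window: int
    insufficient: bool = False


@dataclass(frozen=True)
class SignalClassification:
    record_id: str
    vegetation_class: VegetationClass
    fire_class: FireClass
    post_evidence: EvidenceBundle | None = None
    pre_evidence: EvidenceBundle | None = None
    flags: tuple[str, ...] = ()


_INSUFFICIENT = EvidenceBundle(
    proxy_direction=Direction.FLAT, proxy_magnitude=0.0,
    gam_direction=Direction.NONE, pfg_clear_change=False, pfg_delta_pp=0.0,
    samples_in_window=0, insufficient=True,
)


def _window_mean(ages: np.ndarray, values: np.ndarray, window: tuple[float, float]) -> tuple[float, int]:
    mask = (ages >= window[0]) & (ages <= window[1])
    if not mask.any():
        return float("nan"), 0
    return float(np.mean(values[mask])), int(mask.sum())


def _gam_direction(
    deriv: DerivativeEstimate,
    window: tuple[float, float],
    localization: float = 0.0,
) -> Direction:
    """Dominant trend sign that the fitted curve attributes to a window.

    Each contiguous run of grid points whose derivative interval excludes
    zero is one detected transition; it is attributed to its slope-weighted
    centre (the run's centre of mass under the |slope| profile, which sits
    at the steep part of a fitted sigmoid even when its shallow tail drags
    the run far beyond the transition).  A sign counts for the window when
    such a centre falls inside it and (with ``localization`` > 0) the run's
    peak slope reaches that fraction of the record-wide maximum slope of
    the same sign.  This keeps the tail of a transition centred centuries
    away — or a featureless millennial drift fitted as a straight line —
    from registering as change inside a later event window.
    """
    hits = {}
    for which, s in ((DerivativeSign.NEG, -1.0), (DerivativeSign.POS, 1.0)):
        profile = s * deriv.dmu
        peak_floor = localization * profile.max() if profile.max() > 0 else 0.0
        mask = deriv.sign == which
        n_hits = 0
        i = 0
        while i < mask.size:
            if not mask[i]:
                i += 1
                continue
            j = i
            while j + 1 < mask.size and mask[j + 1]:
                j += 1
            w = profile[i : j + 1]
            centre = float(np.sum(deriv.grid[i : j + 1] * w) / np.sum(w))
            if window[0] <= centre <= window[1] and w.max() >= peak_floor:
                n_hits += 1
            i = j + 1
        hits[which] = n_hits
    neg, pos = hits[DerivativeSign.NEG], hits[DerivativeSign.POS]
    if neg > pos:
        return Direction.CLOSING  # openness falling = forest closing
    if pos > neg:
        return Direction.OPENING
    return Direction.NONE


def _zone_arboreal_deltas(
    zonation: ZonationResult, pfg: PFGTable, min_clusters: int = 2
) -> list[tuple[float, float]]:
    """(boundary age, younger-zone arboreal share minus older-zone, in pp).

    Boundaries come from cutting the merge tree at the larger of the
    broken-stick zone count and ``min_clusters``: the dendrogram's top
    splits are examined even when the broken-stick rule is conservative,
    and the arboreal-share magnitude threshold downstream decides whether a
    split marks a clear forest-cover change.
    """
    share = pfg.arboreal_share() * 100.0
    k = min(max(zonation.n_zones, min_clusters), zonation.n_samples)
    positions = zonation.breaks_at(k)
    out = []
    cuts = [-1, *positions, len(share) - 1]
    zone_means = [
        float(np.nanmean(share[cuts[i] + 1 : cuts[i + 1] + 1]))
        for i in range(len(cuts) - 1)
    ]
    for j, pos in enumerate(positions):
        # samples are ordered by depth: zone j is the younger side of cut j
        age = (zonation.ages[pos] + zonation.ages[pos + 1]) / 2.0
        out.append((age, zone_means[j] - zone_means[j + 1]))
    return out


def assess_window(
    openness: OpennessSeries,
    fit: GamFit,
    deriv: DerivativeEstimate,
    zonation: ZonationResult | None,
    pfg: PFGTable | None,
    window: tuple[float, float],
    baseline: tuple[float, float],
    thresholds: Thresholds = Thresholds(),
    gam_window: tuple[float, float] | None = None,
    pfg_window: tuple[float, float] | None = None,
) -> EvidenceBundle:
    """Evidence for forest change in one window relative to its baseline.

    The proxy direction compares window-mean openness with the baseline mean
    at threshold ``theta``; the trend direction summarizes localized
    derivative sign detections inside ``gam_window`` (default: the proxy
    window); the PFG break requires a significant zone boundary inside
    ``pfg_window`` (same default) whose arboreal-share change reaches
    ``delta_pp`` percentage points.  A window with no samples (or no
    baseline samples) yields an insufficient-data bundle.
    """
    ages, vals = openness.valid()
    w_mean, n_in = _window_mean(ages, vals, window)
    b_mean, n_base = _window_mean(ages, vals, baseline)
    if n_in == 0 or n_base == 0:
        return _INSUFFICIENT

    diff = w_mean - b_mean
    if diff <= -thresholds.theta:
        proxy = Direction.CLOSING
    elif diff >= thresholds.theta:
        proxy = Direction.OPENING
    else:
        proxy = Direction.FLAT

    pb, pa = thresholds.window_pad_before_yr, thresholds.window_pad_after_yr
    gw = gam_window or window
    gam = _gam_direction(deriv, (gw[0] - pb, gw[1] + pa), thresholds.gam_localization)

    pw = pfg_window or window
    pfg_window = (pw[0] - pb, pw[1] + pa)
    clear, delta_pp = False, 0.0
    if zonation is not None and pfg is not None:
        in_window = [
            (age, d)
            for age, d in _zone_arboreal_deltas(zonation, pfg)
            if pfg_window[0] <= age <= pfg_window[1]
        ]
        if in_window:
            age, delta_pp = max(in_window, key=lambda t: abs(t[1]))
            clear = abs(delta_pp) >= thresholds.delta_pp

    return EvidenceBundle(
        proxy_direction=proxy,
        proxy_magnitude=diff,
        gam_direction=gam,
        pfg_clear_change=clear,
        pfg_delta_pp=delta_pp,
        samples_in_window=n_in,
    )


def _full_or_minor(bundle: EvidenceBundle, closing: bool, region: Region) -> VegetationClass | None:
    """Match one direction's full/minor pattern against a bundle."""
    want_proxy = Direction.CLOSING if closing else Direction.OPENING
    clear_signed = bundle.pfg_clear_change and (
        (bundle.pfg_delta_pp > 0) == closing
    )
    proxy_ok = bundle.proxy_direction is want_proxy
    gam_ok = bundle.gam_direction is want_proxy
    if proxy_ok and gam_ok and (region is not Region.NEOTROPICS or clear_signed):
        return (
            VegetationClass.POST_AFFORESTATION if closing
            else VegetationClass.POST_DEFORESTATION
        )
    minor = (proxy_ok and gam_ok and not clear_signed) or (
        proxy_ok and clear_signed and not gam_ok
    )
    if minor:
        return (
            VegetationClass.POST_AFFORESTATION_MINOR if closing
            else VegetationClass.POST_DEFORESTATION_MINOR
        )
    return None


def classify_vegetation(
    post: EvidenceBundle, pre: EvidenceBundle, region: Region
) -> VegetationClass:
    """Combine post- and pre-contact evidence into one vegetation class.

    Post-contact classes (full, then minor; afforestation checked before
    deforestation) pre-empt the pre-contact class; a pre-contact
    afforestation (full or minor pattern) is assigned only when the post
    window shows nothing; otherwise the response is limited.
    """
    if not post.insufficient:
        for closing in (True, False):
            cls = _full_or_minor(post, closing, region)
            if cls is not None:
                return cls
    if not pre.insufficient:
        pre_cls = _full_or_minor(pre, closing=True, region=region)
        if pre_cls is not None:
            return VegetationClass.PRE_AFFORESTATION
    return VegetationClass.LIMITED


def classify_fire(
    influx: CharcoalSeries,
    deriv: DerivativeEstimate,
    windows: EventWindows,
    thresholds: Thresholds = Thresholds(),
) -> FireClass:
    """Fire-regime change after contact from charcoal influx.

    A full increase/decrease requires both a relative window-mean change of
    at least ``theta_fire`` and a matching derivative sign detection inside
    the post window; one line of evidence without the other is classified
    minor/uncertain; neither is limited.
    """
    ages, vals = influx.valid()
    w_mean, n_in = _window_mean(ages, vals, windows.post_window)
    b_mean, n_base = _window_mean(ages, vals, windows.baseline_window)
    if n_in == 0 or n_base == 0:
        return FireClass.NOT_APPLICABLE

    if b_mean > 0:
        rel = (w_mean - b_mean) / b_mean
    else:
        rel = float("inf") if w_mean > 0 else 0.0
    # influx series are log-standardized upstream, so NEG = influx falling
    gam = _gam_direction(deriv, windows.post_window, thresholds.gam_localization)

    drop = rel <= -thresholds.theta_fire
    rise = rel >= thresholds.theta_fire
    if drop and gam is Direction.CLOSING:
        return FireClass.FIRE_DECREASE
    if rise and gam is Direction.OPENING:
        return FireClass.FIRE_INCREASE
    if drop or (gam is Direction.CLOSING and not rise):
        return FireClass.FIRE_DECREASE_MINOR
    if rise or (gam is Direction.OPENING and not drop):
        return FireClass.FIRE_INCREASE_MINOR
    return FireClass.FIRE_LIMITED
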