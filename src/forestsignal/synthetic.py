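"""Synthetic pollen and charcoal records with the structure the pipeline assumes.

The generator emulates the data shapes of late-Holocene tropical records:
irregularly spaced samples over the past ~2,000 years, overdispersed
compositional pollen counts whose arboreal fraction follows a piecewise
trajectory with optional step/ramp events at specified calendar years, and
gamma-noise charcoal concentrations coupled to a linear age-depth model.
Counts are Dirichlet-multinomial: the expected composition is derived from
the arboreal-fraction path, perturbed with Dirichlet precision phi, then
drawn as a multinomial of the per-sample counting sum.  Everything is
deterministic given the scenario seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .composition import PFGMap, PFG_GROUPS, GroupRole
from .records import (
    CharcoalRecord,
    CharcoalSample,
    PollenRecord,
    Region,
    RecordType,
    Sample,
    SiteMetadata,
    ValidationError,
)

__all__ = [
    "Sampling",
    "CharcoalBlock",
    "ScenarioSpec",
    "simulate_pollen_record",
    "simulate_charcoal_record",
    "scenario_library",
    "synthetic_pfg_map",
]


class Sampling(enum.Enum):
    EVEN = "EVEN"
    JITTERED = "JITTERED"
    CLUSTERED = "CLUSTERED"


#: How the arboreal / non-arboreal / excluded mass is split across groups.
_ARBOREAL_WEIGHTS = {
    "TROPICAL_TREES": 0.50,
    "MONTANE_TREES": 0.15,
    "CONIFERS": 0.10,
    "SHRUBS": 0.15,
    "PALMS": 0.10,
}
_NONARBOREAL_WEIGHTS = {"GRASSES": 0.70, "DRY_HERBS": 0.30}
_EXCLUDED_WEIGHTS = {"AQUATIC_WETLAND": 0.60, "FERNS": 0.40}

#: Core accumulation rate used to lay samples out in depth (cm / yr).
_ACCUMULATION_CM_PER_YR = 0.05


@dataclass(frozen=True)
class CharcoalBlock:
    """Charcoal scenario parameters: gamma-noise concentrations with a step."""

    baseline: float = 100.0  # fragments cm^-3 before the event
    event_multiplier: float = 1.0  # concentration mean multiplier after the event
    dispersion: float = 0.1  # gamma squared coefficient of variation

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValidationError("charcoal baseline must be > 0")
        if self.event_multiplier < 0:
            raise ValidationError("event multiplier must be >= 0")
        if self.dispersion <= 0:
            raise ValidationError("charcoal dispersion must be > 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterization of one synthetic record.

    ``ap_trajectory`` gives breakpoints (year CE, arboreal fraction of the
    dryland pollen sum); the optional ``event`` adds ``delta_ap`` on top,
    ramped linearly over ``ramp_years`` from ``year``.  Openness is therefore
    1 - AP fraction by construction.
    """

    name: str
    span: tuple[float, float] = (0.0, 1950.0)
    n_samples: int = 40
    sampling: Sampling = Sampling.JITTERED
    ap_trajectory: tuple[tuple[float, float], ...] = ((0.0, 0.70), (1950.0, 0.70))
    event: tuple[float, float, float] | None = None  # (year, delta_ap, ramp_years)
    count_depth: float = 300.0
    overdispersion: float = 50.0  # Dirichlet precision phi
    taxa_per_group: int = 3
    excluded_fraction: float = 0.15
    charcoal: CharcoalBlock | None = None
    age_error_sd: float = 0.0
    contact_year: float = 1520.0
    region: Region = Region.NEOTROPICS
    seed: int = 0
    intent: str = ""  # documented expected outcome, for humans

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("need at least 2 samples")
        if self.count_depth < 50:
            raise ValidationError("count_depth must be >= 50")
        if self.overdispersion <= 0:
            raise ValidationError("Dirichlet precision must be > 0")
        if not 0.0 <= self.excluded_fraction < 1.0:
            raise ValidationError("excluded_fraction must be in [0, 1)")
        if self.taxa_per_group < 1:
            raise ValidationError("taxa_per_group must be >= 1")
        if self.event is not None and self.event[2] < 0:
            raise ValidationError("ramp_years must be >= 0")
        grid = np.linspace(self.span[0], self.span[1], 512)
        ap = self.ap_fraction(grid)
        if ap.min() < 0.01 or ap.max() > 0.99:
            raise ValidationError(
                "AP trajectory (with event) leaves [0.01, 0.99]; infeasible"
            )

    def ap_fraction(self, ages) -> np.ndarray:
        """Arboreal fraction of dryland pollen at the given ages."""
        ages = np.asarray(ages, dtype=float)
        xs = [b[0] for b in self.ap_trajectory]
        ys = [b[1] for b in self.ap_trajectory]
        base = np.interp(ages, xs, ys)
        if self.event is not None:
            year, delta, ramp = self.event
            if ramp > 0:
                progress = np.clip((ages - year) / ramp, 0.0, 1.0)
            else:
                progress = (ages >= year).astype(float)
            base = base + delta * progress
        return base


def _sample_ages(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.span
    n = spec.n_samples
    if spec.sampling is Sampling.EVEN:
        ages = np.linspace(lo, hi, n)
    elif spec.sampling is Sampling.JITTERED:
        step = (hi - lo) / (n - 1)
        ages = np.linspace(lo, hi, n) + rng.uniform(-0.3, 0.3, n) * step
        ages = np.clip(np.sort(ages), lo, hi)
    else:  # CLUSTERED: sorted uniform draws give naturally clumpy spacing
        ages = np.sort(rng.uniform(lo, hi, n))
    if spec.age_error_sd > 0:
        for _ in range(1000):
            jittered = ages + rng.normal(0.0, spec.age_error_sd, n)
            if np.all(np.diff(jittered) > 0):
                ages = jittered
                break
    # enforce strict increase (ties break depth ordering downstream)
    for i in range(1, n):
        if ages[i] <= ages[i - 1]:
            ages[i] = ages[i - 1] + 1e-6
    return ages


def _taxon_names(taxa_per_group: int) -> dict[str, list[str]]:
    return {
        g: [f"{g}_taxon{i + 1}" for i in range(taxa_per_group)] for g in PFG_GROUPS
    }


def synthetic_pfg_map(taxa_per_group: int = 3) -> PFGMap:
    """The functional-group map matching the synthesized taxon names."""
    mapping = {
        name: g for g, names in _taxon_names(taxa_per_group).items() for name in names
    }
    return PFGMap(mapping=mapping)


def _metadata(spec: ScenarioSpec, record_type: RecordType) -> SiteMetadata:
    suffix = "_charcoal" if record_type is RecordType.CHARCOAL else ""
    return SiteMetadata(
        site_id=f"SYN_{spec.name}_{spec.seed}{suffix}",
        site_name=f"Synthetic {spec.name.replace('_', ' ')}",
        region=spec.region,
        zone="Synthetic",
        latitude=0.0,
        longitude=-60.0 if spec.region is Region.NEOTROPICS else 120.0,
        elevation=100.0,
        biome="tropical moist forest",
        contact_year=spec.contact_year,
        record_type=record_type,
    )


def simulate_pollen_record(spec: ScenarioSpec) -> PollenRecord:
    """Draw one Dirichlet-multinomial pollen record from a scenario.

    Sample ages follow the sampling mode; expected composition at each age
    splits (1 - excluded_fraction) of the pollen sum between arboreal and
    non-arboreal dryland groups according to the AP trajectory, and the rest
    across aquatic/wetland and fern taxa; within-group mass is spread evenly
    over the synthesized taxa.  Identical spec and seed give an identical
    record.
    """
    rng = np.random.default_rng(spec.seed)
    ages = _sample_ages(spec, rng)
    ap = spec.ap_fraction(ages)
    names = _taxon_names(spec.taxa_per_group)

    taxa: list[str] = []
    mass_weights: list[np.ndarray] = []  # per-sample expected proportion per taxon
    dry = 1.0 - spec.excluded_fraction
    group_mass = {}
    for g, w in _ARBOREAL_WEIGHTS.items():
        group_mass[g] = dry * w * ap
    for g, w in _NONARBOREAL_WEIGHTS.items():
        group_mass[g] = dry * w * (1.0 - ap)
    for g, w in _EXCLUDED_WEIGHTS.items():
        group_mass[g] = spec.excluded_fraction * w * np.ones_like(ap)
    for g in PFG_GROUPS:
        per_taxon = group_mass[g] / spec.taxa_per_group
        for name in names[g]:
            taxa.append(name)
            mass_weights.append(per_taxon)
    pi = np.column_stack(mass_weights)  # (n_samples, n_taxa)

    samples = []
    top_age = spec.span[1]
    for i in range(spec.n_samples):
        alpha = spec.overdispersion * pi[i]
        p = rng.dirichlet(alpha)
        total = max(int(rng.poisson(spec.count_depth)), 1)
        counts = rng.multinomial(total, p)
        depth = (top_age - ages[i]) * _ACCUMULATION_CM_PER_YR
        samples.append(
            Sample(
                depth=float(depth),
                age=float(ages[i]),
                counts={t: int(c) for t, c in zip(taxa, counts)},
            )
        )
    samples.sort(key=lambda s: s.depth)
    return PollenRecord(
        metadata=_metadata(spec, RecordType.POLLEN), samples=tuple(samples)
    )


def simulate_charcoal_record(spec: ScenarioSpec) -> CharcoalRecord:
    """Draw a gamma-noise charcoal record paired with linear deposition.

    Mean concentration is the baseline, multiplied by the event multiplier
    after the event year (the pollen event year, or the contact year when no
    pollen event is specified).
    """
    if spec.charcoal is None:
        raise ValidationError("scenario has no charcoal block")
    blk = spec.charcoal
    rng = np.random.default_rng(spec.seed + 1_000_003)
    ages = _sample_ages(spec, rng)
    event_year = spec.event[0] if spec.event is not None else spec.contact_year
    mean = np.where(ages >= event_year, blk.baseline * blk.event_multiplier, blk.baseline)
    shape = 1.0 / blk.dispersion
    conc = rng.gamma(shape, np.maximum(mean, 1e-12) / shape)
    top_age = spec.span[1]
    samples = [
        CharcoalSample(
            depth=float((top_age - a) * _ACCUMULATION_CM_PER_YR),
            age=float(a),
            concentration=float(c),
        )
        for a, c in zip(ages, conc)
    ]
    samples.sort(key=lambda s: s.depth)
    return CharcoalRecord(
        metadata=_metadata(spec, RecordType.CHARCOAL), samples=tuple(samples)
    )


def scenario_library() -> dict[str, ScenarioSpec]:
    """Named scenarios mirroring the qualitative patterns seen in real records.

    Each is fully parameterized; vary ``seed`` (e.g. ``dataclasses.replace``)
    for replicate draws.
    """
    base_open = ((0.0, 0.55), (1950.0, 0.55))
    base_closed = ((0.0, 0.70), (1950.0, 0.70))
    lib = {
        "post_contact_afforestation": ScenarioSpec(
            name="post_contact_afforestation",
            ap_trajectory=base_open,
            event=(1520.0, +0.15, 50.0),
            charcoal=CharcoalBlock(baseline=100.0, event_multiplier=0.5),
            intent="forest closes in the century after contact (full or minor class)",
        ),
        "pre_iberian_afforestation": ScenarioSpec(
            name="pre_iberian_afforestation",
            ap_trajectory=base_open,
            event=(1250.0, +0.15, 50.0),
            intent="forest closes 1000-1400 CE; nothing at contact (pre-contact class)",
        ),
        "post_contact_deforestation": ScenarioSpec(
            name="post_contact_deforestation",
            ap_trajectory=base_closed,
            event=(1520.0, -0.15, 50.0),
            charcoal=CharcoalBlock(baseline=100.0, event_multiplier=2.0),
            intent="forest opens in the century after contact (full or minor class)",
        ),
        "industrial_deforestation": ScenarioSpec(
            name="industrial_deforestation",
            ap_trajectory=base_closed,
            event=(1870.0, -0.20, 40.0),
            intent="opening confined to the industrial era; headline class limited",
        ),
        "null_stable": ScenarioSpec(
            name="null_stable",
            ap_trajectory=base_closed,
            intent="stationary composition; limited forest response",
        ),
    }
    return lib
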