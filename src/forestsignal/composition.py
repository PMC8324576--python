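"""Plant-functional-group reclassification, openness ratios and charcoal influx.

Pollen taxa are collapsed into nine plant functional groups (PFGs) that track
major vegetation state shifts: five arboreal groups (tropical trees, montane
trees, conifers, shrubs, palms), two non-arboreal dryland groups (grasses,
dry herbs) and two groups excluded from the openness sum (aquatic/wetland
taxa and ferns, whose fluctuations are commonly driven by local hydrology
rather than regional forest cover).  Landscape openness is the bounded
proportion NAP/(NAP+AP) over dryland taxa only; charcoal concentrations are
converted to influx (fragments cm^-2 yr^-1) with the age-depth model's
deposition time.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .chronology import AgeDepthModel, deposition_time
from .records import CharcoalRecord, PollenRecord, ValidationError

__all__ = [
    "GroupRole",
    "PFG_GROUPS",
    "PFGMap",
    "PFGTable",
    "OpennessVariant",
    "OpennessSeries",
    "CharcoalSeries",
    "UnmappedPolicy",
    "map_to_pfg",
    "openness_ratio",
    "charcoal_influx",
    "default_pfg_map",
    "read_pfg_map",
]


class GroupRole(enum.Enum):
    ARBOREAL = "arboreal"
    NON_ARBOREAL_DRYLAND = "non_arboreal_dryland"
    EXCLUDED = "excluded"


#: The nine plant functional groups and their role in the openness proxy.
PFG_GROUPS: dict[str, GroupRole] = {
    "TROPICAL_TREES": GroupRole.ARBOREAL,
    "MONTANE_TREES": GroupRole.ARBOREAL,
    "CONIFERS": GroupRole.ARBOREAL,
    "SHRUBS": GroupRole.ARBOREAL,
    "PALMS": GroupRole.ARBOREAL,
    "GRASSES": GroupRole.NON_ARBOREAL_DRYLAND,
    "DRY_HERBS": GroupRole.NON_ARBOREAL_DRYLAND,
    "AQUATIC_WETLAND": GroupRole.EXCLUDED,
    "FERNS": GroupRole.EXCLUDED,
}

#: Catch-all bin for unrecognized taxa; excluded so unknown taxa cannot move
#: the openness proxy.
OTHER_BIN = "OTHER"


class UnmappedPolicy(enum.Enum):
    ERROR = "ERROR"
    OTHER_BIN = "OTHER_BIN"


class OpennessVariant(enum.Enum):
    NAP_AP = "NAP_AP"  # all non-arboreal dryland taxa in the numerator
    GRASS_AP = "GRASS_AP"  # grasses only (forest-openness variant)


@dataclass(frozen=True)
class PFGMap:
    """Taxon -> functional-group assignment with per-group roles.

    The default assignment (see :func:`default_pfg_map`) is an editable
    seed drawn from the Latin American surface-pollen biomization
    literature; site-specific maps should be supplied as YAML configs and
    override it without code changes.
    """

    mapping: Mapping[str, str]
    roles: Mapping[str, GroupRole] = field(default_factory=lambda: dict(PFG_GROUPS))

    def __post_init__(self) -> None:
        roles = dict(self.roles)
        if OTHER_BIN not in roles:
            roles[OTHER_BIN] = GroupRole.EXCLUDED
            object.__setattr__(self, "roles", roles)
        core = {g for g in roles if g != OTHER_BIN}
        if core != set(PFG_GROUPS):
            raise ValidationError(
                f"a PFG map must define exactly the nine groups {sorted(PFG_GROUPS)}"
            )
        for g in ("GRASSES", "DRY_HERBS"):
            if roles[g] is not GroupRole.NON_ARBOREAL_DRYLAND:
                raise ValidationError(f"{g} must be non_arboreal_dryland")
        for g in ("AQUATIC_WETLAND", "FERNS"):
            if roles[g] is not GroupRole.EXCLUDED:
                raise ValidationError(f"{g} must be excluded")
        for g in ("TROPICAL_TREES", "MONTANE_TREES", "CONIFERS", "SHRUBS", "PALMS"):
            if roles[g] is not GroupRole.ARBOREAL:
                raise ValidationError(f"{g} must be arboreal")
        for taxon, group in self.mapping.items():
            if group not in roles:
                raise ValidationError(f"taxon {taxon!r} mapped to unknown group {group!r}")

    def groups_with_role(self, role: GroupRole) -> list[str]:
        return [g for g, r in self.roles.items() if r is role]


#: A deliberately small seed assignment of common Neotropical / Asia-Pacific
#: pollen types; real analyses override it per record.
_DEFAULT_TAXON_GROUPS: dict[str, str] = {
    "Moraceae": "TROPICAL_TREES",
    "Urticaceae": "TROPICAL_TREES",
    "Cecropia": "TROPICAL_TREES",
    "Melastomataceae": "TROPICAL_TREES",
    "Fabaceae": "TROPICAL_TREES",
    "Anacardiaceae": "TROPICAL_TREES",
    "Euphorbiaceae": "TROPICAL_TREES",
    "Combretaceae": "TROPICAL_TREES",
    "Alnus": "MONTANE_TREES",
    "Quercus": "MONTANE_TREES",
    "Weinmannia": "MONTANE_TREES",
    "Polylepis": "MONTANE_TREES",
    "Hedyosmum": "MONTANE_TREES",
    "Podocarpus": "CONIFERS",
    "Pinus": "CONIFERS",
    "Abies": "CONIFERS",
    "Asteraceae": "SHRUBS",
    "Ericaceae": "SHRUBS",
    "Melastomataceae/Combretaceae": "SHRUBS",
    "Arecaceae": "PALMS",
    "Mauritia": "PALMS",
    "Poaceae": "GRASSES",
    "Amaranthaceae": "DRY_HERBS",
    "Chenopodiaceae": "DRY_HERBS",
    "Apiaceae": "DRY_HERBS",
    "Plantago": "DRY_HERBS",
    "Cyperaceae": "AQUATIC_WETLAND",
    "Typha": "AQUATIC_WETLAND",
    "Isoetes": "AQUATIC_WETLAND",
    "Monolete fern spores": "FERNS",
    "Trilete fern spores": "FERNS",
    "Cyathea": "FERNS",
}


def default_pfg_map() -> PFGMap:
    """The packaged seed taxon assignment (editable; see :class:`PFGMap`)."""
    return PFGMap(mapping=dict(_DEFAULT_TAXON_GROUPS))


def read_pfg_map(path: str | Path) -> PFGMap:
    """Load a PFG map config: ``{taxa: {taxon: group}, roles: {group: role}}``.

    ``roles`` is optional and defaults to the standard nine-group roles.
    """
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not doc or "taxa" not in doc:
        raise ValidationError(f"{path}: PFG map config needs a 'taxa' section")
    roles = dict(PFG_GROUPS)
    for g, r in (doc.get("roles") or {}).items():
        roles[g] = GroupRole(r)
    return PFGMap(mapping=dict(doc["taxa"]), roles=roles)


@dataclass(frozen=True)
class PFGTable:
    """Per-sample group counts and relative abundances (ordered by depth).

    ``proportions`` are computed over the non-excluded (terrestrial dryland)
    sum; samples whose dryland sum is zero are flagged and carry NaN
    proportions so downstream stages can drop them explicitly.
    """

    ages: tuple[float, ...]
    depths: tuple[float, ...]
    counts: pd.DataFrame  # index aligned with ages; columns = groups
    proportions: pd.DataFrame
    flagged: tuple[bool, ...]  # True where the dryland sum is zero
    roles: Mapping[str, GroupRole]

    def arboreal_share(self) -> np.ndarray:
        """Arboreal proportion of the dryland sum, per sample (NaN if flagged)."""
        arb = [g for g, r in self.roles.items() if r is GroupRole.ARBOREAL]
        return self.proportions[arb].sum(axis=1).to_numpy()

    def drop_flagged(self) -> "PFGTable":
        """A copy with zero-dryland-sum samples removed (alignment preserved)."""
        keep = [i for i, f in enumerate(self.flagged) if not f]
        return PFGTable(
            ages=tuple(self.ages[i] for i in keep),
            depths=tuple(self.depths[i] for i in keep),
            counts=self.counts.iloc[keep].reset_index(drop=True),
            proportions=self.proportions.iloc[keep].reset_index(drop=True),
            flagged=tuple(False for _ in keep),
            roles=self.roles,
        )


def map_to_pfg(
    record: PollenRecord,
    pfg_map: PFGMap | None = None,
    unmapped_policy: UnmappedPolicy = UnmappedPolicy.OTHER_BIN,
) -> PFGTable:
    """Collapse taxon counts into the nine functional groups.

    Group counts are the sums of member-taxon counts (count conservation);
    proportions are taken over the non-excluded groups only.
    """
    pfg_map = pfg_map or default_pfg_map()
    unmapped = [t for t in record.taxa if t not in pfg_map.mapping]
    if unmapped and unmapped_policy is UnmappedPolicy.ERROR:
        raise ValidationError(f"unmapped taxa: {unmapped}")
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} unmapped taxa routed to {OTHER_BIN} (excluded): "
            f"{unmapped[:5]}{'...' if len(unmapped) > 5 else ''}",
            stacklevel=2,
        )

    groups = list(pfg_map.roles)
    rows = []
    for s in record.samples:
        acc = dict.fromkeys(groups, 0)
        for taxon, n in s.counts.items():
            acc[pfg_map.mapping.get(taxon, OTHER_BIN)] += int(n)
        rows.append(acc)
    counts = pd.DataFrame(rows, columns=groups)

    included = [g for g in groups if pfg_map.roles[g] is not GroupRole.EXCLUDED]
    dryland_sum = counts[included].sum(axis=1)
    flagged = (dryland_sum == 0).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        proportions = counts[included].div(dryland_sum.replace(0, np.nan), axis=0)
    return PFGTable(
        ages=tuple(record.ages),
        depths=tuple(record.depths),
        counts=counts,
        proportions=proportions,
        flagged=tuple(bool(f) for f in flagged),
        roles=dict(pfg_map.roles),
    )


@dataclass(frozen=True)
class OpennessSeries:
    """Landscape-openness proxy per sample: NAP/(NAP+AP) over dryland taxa.

    Bounded in [0, 1]; higher = more open.  Flagged samples (zero dryland
    sum) carry NaN and are skipped by consumers.
    """

    ages: tuple[float, ...]
    openness: tuple[float, ...]
    nap: tuple[int, ...]
    ap: tuple[int, ...]
    variant: OpennessVariant
    flagged: tuple[bool, ...]

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        """(ages, openness) with flagged samples removed."""
        keep = ~np.asarray(self.flagged)
        return np.asarray(self.ages)[keep], np.asarray(self.openness)[keep]

    def max_count(self) -> int:
        sums = np.asarray(self.nap) + np.asarray(self.ap)
        return int(sums.max()) if sums.size else 0


def openness_ratio(
    pfg: PFGTable, variant: OpennessVariant = OpennessVariant.NAP_AP
) -> OpennessSeries:
    """Openness proxy from a PFG table.

    NAP_AP uses all non-arboreal dryland groups in the numerator; GRASS_AP
    restricts it to grasses (the denominator stays grasses + arboreal), the
    variant used where only grass curves are available.
    """
    arb = [g for g, r in pfg.roles.items() if r is GroupRole.ARBOREAL]
    if variant is OpennessVariant.NAP_AP:
        nap_groups = [g for g, r in pfg.roles.items() if r is GroupRole.NON_ARBOREAL_DRYLAND]
    else:
        nap_groups = ["GRASSES"]
    nap = pfg.counts[nap_groups].sum(axis=1).to_numpy()
    ap = pfg.counts[arb].sum(axis=1).to_numpy()
    total = nap + ap
    flagged = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        openness = np.where(flagged, np.nan, nap / np.where(flagged, 1, total))
    return OpennessSeries(
        ages=pfg.ages,
        openness=tuple(float(x) for x in openness),
        nap=tuple(int(x) for x in nap),
        ap=tuple(int(x) for x in ap),
        variant=variant,
        flagged=tuple(bool(f) for f in flagged),
    )


@dataclass(frozen=True)
class CharcoalSeries:
    """Charcoal influx per sample: concentration / deposition time."""

    ages: tuple[float, ...]
    influx: tuple[float, ...]  # fragments cm^-2 yr^-1
    concentration: tuple[float, ...]  # fragments cm^-3
    deposition_times: tuple[float, ...]  # yr cm^-1
    flagged: tuple[bool, ...]  # degenerate sedimentation

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~np.asarray(self.flagged)
        return np.asarray(self.ages)[keep], np.asarray(self.influx)[keep]


def charcoal_influx(record: CharcoalRecord, model: AgeDepthModel) -> CharcoalSeries:
    """Convert charcoal concentrations into influx rates.

    influx_i = concentration_i / deposition_time(depth_i); a depth with
    degenerate (zero-slope) sedimentation is flagged rather than fatal.
    """
    ages, influx, conc, dts, flags = [], [], [], [], []
    for s in record.samples:
        ages.append(s.age)
        conc.append(s.concentration)
        try:
            dt = deposition_time(model, s.depth)
        except ValidationError:
            dts.append(float("nan"))
            influx.append(float("nan"))
            flags.append(True)
            continue
        dts.append(dt)
        influx.append(s.concentration / dt)
        flags.append(False)
    return CharcoalSeries(
        ages=tuple(ages),
        influx=tuple(influx),
        concentration=tuple(conc),
        deposition_times=tuple(dts),
        flagged=tuple(flags),
    )
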