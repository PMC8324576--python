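"""Domain types, readers/writers and screening rules for stratigraphic records.

A record is an ordered sequence of samples down a sediment core: depth below
surface (cm), calibrated calendar age (years CE, increasing toward present)
and either pollen taxon counts or charcoal concentrations.  The screening
rules encode the study-selection criteria used to decide which records can
support an assessment of forest change around the time of Iberian contact:
geographic/dating/span assertions (C1-C3, carried as metadata), a tropical or
subtropical biome (C4), at least one sample dated 1500-1600 CE (C5), and a
temporal resolution finer than 200 years per sample over the most recent two
millennia (C6).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Region",
    "RecordType",
    "AgeBasis",
    "SiteMetadata",
    "Sample",
    "PollenRecord",
    "CharcoalSample",
    "CharcoalRecord",
    "InclusionDecision",
    "ScreeningPolicy",
    "ValidationError",
    "ce_to_bp",
    "bp_to_ce",
    "read_record",
    "write_record",
    "read_manifest",
    "compute_resolution",
    "screen_record",
]

#: "Present" in the cal-yr-BP convention.
_BP_PRESENT_CE = 1950.0


def ce_to_bp(age_ce: float) -> float:
    """Convert a calendar age in years CE to calibrated years before present."""
    return _BP_PRESENT_CE - age_ce


def bp_to_ce(age_bp: float) -> float:
    """Convert calibrated years BP to calendar years CE."""
    return _BP_PRESENT_CE - age_bp


class ValidationError(ValueError):
    """A record or table violates a structural invariant."""


class Region(enum.Enum):
    NEOTROPICS = "NEOTROPICS"
    EAST_INDIES = "EAST_INDIES"


class RecordType(enum.Enum):
    POLLEN = "POLLEN"
    CHARCOAL = "CHARCOAL"
    PHYTOLITH = "PHYTOLITH"


class AgeBasis(enum.Enum):
    PUBLISHED_MODEL = "PUBLISHED_MODEL"
    INTERPOLATED = "INTERPOLATED"


class ScreeningPolicy(enum.Enum):
    NEOTROPICS_STRICT = "NEOTROPICS_STRICT"
    EAST_INDIES_LIBERAL = "EAST_INDIES_LIBERAL"


@dataclass(frozen=True)
class SiteMetadata:
    """Site-level metadata accompanying a stratigraphic record.

    ``contact_year`` is the calendar year CE of Iberian contact or of the
    documented population decline used to anchor the post-contact assessment
    window.  ``colonial_territory``, ``directly_dated`` and ``spans_600_1900``
    carry the geography / direct-dating / temporal-span assertions that cannot
    be recomputed from the count table itself.
    """

    site_id: str
    site_name: str
    region: Region
    zone: str
    latitude: float
    longitude: float
    elevation: float
    biome: str
    contact_year: float
    record_type: RecordType = RecordType.POLLEN
    tropical_biome: bool = True
    colonial_territory: bool = True
    directly_dated: bool = True
    spans_600_1900: bool = True

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude {self.longitude} outside [-180, 180]")
        if not 1492.0 <= self.contact_year <= 1900.0:
            raise ValidationError(
                f"contact_year {self.contact_year} outside [1492, 1900]"
            )


@dataclass(frozen=True)
class Sample:
    depth: float  # cm below surface
    age: float  # calendar years CE
    counts: Mapping[str, int]  # taxon name -> count


@dataclass(frozen=True)
class CharcoalSample:
    depth: float
    age: float
    concentration: float  # fragments cm^-3

    @classmethod
    def from_count_volume(cls, depth: float, age: float, count: float, volume: float):
        if volume <= 0:
            raise ValidationError(f"volume must be > 0 at depth {depth}, got {volume}")
        return cls(depth=depth, age=age, concentration=count / volume)


def _check_strata(depths: Sequence[float], ages: Sequence[float]) -> None:
    for i in range(1, len(depths)):
        if depths[i] <= depths[i - 1]:
            raise ValidationError(
                f"depths not strictly increasing at {depths[i - 1]} -> {depths[i]} cm"
            )
        if ages[i] >= ages[i - 1]:
            raise ValidationError(
                "age reversal: depth "
                f"{depths[i - 1]} cm has age {ages[i - 1]} CE but deeper "
                f"{depths[i]} cm has age {ages[i]} CE"
            )


@dataclass(frozen=True)
class PollenRecord:
    """Per-sample taxon counts ordered by depth, with site metadata."""

    metadata: SiteMetadata
    samples: tuple[Sample, ...]
    age_basis: AgeBasis = AgeBasis.PUBLISHED_MODEL

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValidationError("a pollen record needs at least 2 samples")
        _check_strata([s.depth for s in self.samples], [s.age for s in self.samples])
        for s in self.samples:
            for taxon, n in s.counts.items():
                if n < 0:
                    raise ValidationError(
                        f"negative count {n} for taxon {taxon!r} at depth {s.depth}"
                    )

    @property
    def ages(self) -> list[float]:
        return [s.age for s in self.samples]

    @property
    def depths(self) -> list[float]:
        return [s.depth for s in self.samples]

    @property
    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            for t in s.counts:
                seen.setdefault(t, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per sample, columns depth, age, then taxa."""
        taxa = self.taxa
        rows = []
        for s in self.samples:
            row = {"depth": s.depth, "age": s.age}
            for t in taxa:
                row[t] = int(s.counts.get(t, 0))
            rows.append(row)
        return pd.DataFrame(rows, columns=["depth", "age", *taxa])


@dataclass(frozen=True)
class CharcoalRecord:
    metadata: SiteMetadata
    samples: tuple[CharcoalSample, ...]

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValidationError("a charcoal record needs at least 2 samples")
        _check_strata([s.depth for s in self.samples], [s.age for s in self.samples])
        for s in self.samples:
            if s.concentration < 0:
                raise ValidationError(
                    f"negative concentration {s.concentration} at depth {s.depth}"
                )

    @property
    def ages(self) -> list[float]:
        return [s.age for s in self.samples]

    @property
    def depths(self) -> list[float]:
        return [s.depth for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.depths,
                "age": self.ages,
                "concentration": [s.concentration for s in self.samples],
            }
        )


@dataclass(frozen=True)
class InclusionDecision:
    included: bool
    failed_criteria: tuple[str, ...] = ()
    resolution_years_per_sample: float | None = None
    override: bool = False

    def __post_init__(self) -> None:
        expected = (len(self.failed_criteria) == 0) or self.override
        if self.included != expected:
            raise ValidationError("included must equal (no failures) OR override")


# ---------------------------------------------------------------------------
# File I/O
#
# Dialect: UTF-8 CSV/TSV, one row per sample; first column depth (cm), second
# age (years CE); remaining columns are taxon counts (pollen) or a single
# `concentration` column (alternatively `count` + `volume`) for charcoal.
# Site metadata lives in a YAML sidecar `<table>.meta.yaml`.
# ---------------------------------------------------------------------------

_META_SUFFIX = ".meta.yaml"


def _metadata_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + _META_SUFFIX)


def _metadata_to_dict(meta: SiteMetadata) -> dict:
    d = {
        "site_id": meta.site_id,
        "site_name": meta.site_name,
        "region": meta.region.value,
        "zone": meta.zone,
        "latitude": meta.latitude,
        "longitude": meta.longitude,
        "elevation": meta.elevation,
        "biome": meta.biome,
        "contact_year": meta.contact_year,
        "record_type": meta.record_type.value,
        "tropical_biome": meta.tropical_biome,
        "colonial_territory": meta.colonial_territory,
        "directly_dated": meta.directly_dated,
        "spans_600_1900": meta.spans_600_1900,
    }
    return d


def _metadata_from_dict(d: Mapping) -> SiteMetadata:
    required = {
        "site_id",
        "site_name",
        "region",
        "zone",
        "latitude",
        "longitude",
        "elevation",
        "biome",
        "contact_year",
    }
    missing = required - set(d)
    if missing:
        raise ValidationError(f"metadata sidecar missing fields: {sorted(missing)}")
    return SiteMetadata(
        site_id=str(d["site_id"]),
        site_name=str(d["site_name"]),
        region=Region(d["region"]),
        zone=str(d["zone"]),
        latitude=float(d["latitude"]),
        longitude=float(d["longitude"]),
        elevation=float(d["elevation"]),
        biome=str(d["biome"]),
        contact_year=float(d["contact_year"]),
        record_type=RecordType(d.get("record_type", "POLLEN")),
        tropical_biome=bool(d.get("tropical_biome", True)),
        colonial_territory=bool(d.get("colonial_territory", True)),
        directly_dated=bool(d.get("directly_dated", True)),
        spans_600_1900=bool(d.get("spans_600_1900", True)),
    )


def read_record(path: str | Path, fmt: str | None = None) -> PollenRecord | CharcoalRecord:
    """Read a pollen or charcoal record from a CSV/TSV table plus its sidecar.

    ``fmt`` is ``"COUNT_CSV"`` or ``"WIDE_TSV"``; when omitted it is inferred
    from the file extension.  The record kind (pollen vs charcoal) follows the
    sidecar's ``record_type``.  Rows are sorted by depth before validation, so
    age reversals are reported against the stratigraphic order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "WIDE_TSV" if path.suffix.lower() in {".tsv", ".txt"} else "COUNT_CSV"
    sep = "\t" if fmt == "WIDE_TSV" else ","
    try:
        frame = pd.read_csv(path, sep=sep, encoding="utf-8",
                            float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise ValidationError(f"malformed table {path}: {exc}") from exc
    if frame.shape[1] < 3 or list(frame.columns[:2]) != ["depth", "age"]:
        raise ValidationError(
            f"{path}: header must start with 'depth', 'age' followed by data columns"
        )
    meta_path = _metadata_path(path)
    if not meta_path.exists():
        raise ValidationError(f"metadata sidecar not found: {meta_path}")
    meta = _metadata_from_dict(yaml.safe_load(meta_path.read_text(encoding="utf-8")))

    frame = frame.sort_values("depth", kind="stable").reset_index(drop=True)
    if meta.record_type is RecordType.CHARCOAL:
        if "concentration" in frame.columns:
            conc = frame["concentration"].astype(float)
        elif {"count", "volume"} <= set(frame.columns):
            vols = frame["volume"].astype(float)
            if (vols <= 0).any():
                raise ValidationError(f"{path}: charcoal volume must be > 0")
            conc = frame["count"].astype(float) / vols
        else:
            raise ValidationError(
                f"{path}: charcoal table needs 'concentration' or 'count'+'volume'"
            )
        samples = tuple(
            CharcoalSample(depth=float(d), age=float(a), concentration=float(c))
            for d, a, c in zip(frame["depth"], frame["age"], conc)
        )
        return CharcoalRecord(metadata=meta, samples=samples)

    taxa = [c for c in frame.columns if c not in ("depth", "age")]
    counts = frame[taxa]
    if (counts.to_numpy() < 0).any():
        bad = [t for t in taxa if (counts[t] < 0).any()]
        raise ValidationError(f"{path}: negative counts in columns {bad}")
    samples = tuple(
        Sample(
            depth=float(row["depth"]),
            age=float(row["age"]),
            counts={t: int(row[t]) for t in taxa},
        )
        for _, row in frame.iterrows()
    )
    return PollenRecord(metadata=meta, samples=samples)


def write_record(
    record: PollenRecord | CharcoalRecord, path: str | Path, fmt: str | None = None
) -> Path:
    """Write a record table and its metadata sidecar; returns the table path."""
    path = Path(path)
    if fmt is None:
        fmt = "WIDE_TSV" if path.suffix.lower() in {".tsv", ".txt"} else "COUNT_CSV"
    sep = "\t" if fmt == "WIDE_TSV" else ","
    path.parent.mkdir(parents=True, exist_ok=True)
    record.to_frame().to_csv(
        path, sep=sep, index=False, encoding="utf-8", float_format="%.17g"
    )
    _metadata_path(path).write_text(
        yaml.safe_dump(_metadata_to_dict(record.metadata), sort_keys=False),
        encoding="utf-8",
    )
    return path


def read_manifest(path: str | Path) -> list[Path]:
    """Read a YAML manifest listing record table paths (relative to the manifest)."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not doc or "records" not in doc or not doc["records"]:
        raise ValidationError(f"manifest {path} lists no records")
    return [(path.parent / p).resolve() for p in doc["records"]]


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

#: Default assessment window for temporal resolution: the most recent two
#: millennia, [-50 CE, record top].
RESOLUTION_WINDOW_START_CE = -50.0
RESOLUTION_THRESHOLD_YR = 200.0
CONTACT_SAMPLE_WINDOW = (1500.0, 1600.0)


def compute_resolution(
    record: PollenRecord | CharcoalRecord,
    window_start: float = RESOLUTION_WINDOW_START_CE,
    window_end: float | None = None,
) -> float:
    """Mean years per sample over an age window (default: upper 2,000 years).

    The span is clipped to the record: (min(window_end, youngest age) -
    max(window_start, oldest age)) / n_in_window.  A single in-window sample
    returns span / 1 (zero when the clipped span is empty).
    """
    ages = record.ages
    if window_end is None:
        window_end = max(ages)
    in_window = [a for a in ages if window_start <= a <= window_end]
    if not in_window:
        raise ValidationError(
            f"no samples in window [{window_start}, {window_end}] CE"
        )
    span = min(window_end, max(ages)) - max(window_start, min(ages))
    return span / len(in_window)


def screen_record(
    record: PollenRecord | CharcoalRecord,
    region_policy: ScreeningPolicy,
    overrides: Iterable[str] = (),
) -> InclusionDecision:
    """Apply the record-selection criteria and return an inclusion decision.

    NEOTROPICS_STRICT checks the metadata assertions C1-C3, the biome flag
    (C4), the presence of a sample dated 1500-1600 CE (C5) and sub-200-year
    resolution over the upper two millennia (C6).  EAST_INDIES_LIBERAL only
    requires coverage of the 200 years before contact plus at least one
    post-contact sample.  A site_id in ``overrides`` is retained regardless
    of failures (the decision records both).
    """
    meta = record.metadata
    ages = record.ages
    failed: list[str] = []
    resolution: float | None = None

    if region_policy is ScreeningPolicy.NEOTROPICS_STRICT:
        if not meta.colonial_territory:
            failed.append("C1")
        if not meta.directly_dated:
            failed.append("C2")
        if not meta.spans_600_1900:
            failed.append("C3")
        if not meta.tropical_biome:
            failed.append("C4")
        lo, hi = CONTACT_SAMPLE_WINDOW
        if not any(lo <= a <= hi for a in ages):
            failed.append("C5")
        try:
            resolution = compute_resolution(record)
        except ValidationError:
            failed.append("C6")
        else:
            if resolution >= RESOLUTION_THRESHOLD_YR:
                failed.append("C6")
    else:
        contact = meta.contact_year
        pre_ok = any(contact - 200.0 <= a <= contact for a in ages)
        post_ok = any(a > contact for a in ages)
        if not pre_ok:
            failed.append("C5")
        if not post_ok:
            failed.append("C5")
        failed = sorted(set(failed))
        try:
            resolution = compute_resolution(record)
        except ValidationError:
            resolution = None

    override = meta.site_id in set(overrides) and bool(failed)
    return InclusionDecision(
        included=(not failed) or override,
        failed_criteria=tuple(failed),
        resolution_years_per_sample=resolution,
        override=override,
    )
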