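"""Batch orchestration: screen, compose, smooth, zone, classify, summarize.

The per-record computation is split into a "prepare" step (functional-group
mapping, openness, spline fit, derivative, zonation — everything that does
not depend on the classification thresholds) and a cheap "classify" step, so
the sensitivity sweep can re-classify prepared records across a threshold
grid without refitting anything.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chronology import AgeDepthModel, AgeModelMethod, ChronologyTable, build_age_model
from .classify import (
    EventWindows,
    FireClass,
    SignalClassification,
    Thresholds,
    VegetationClass,
    assess_window,
    classify_fire,
    classify_vegetation,
)
from .composition import (
    CharcoalSeries,
    OpennessVariant,
    PFGMap,
    PFGTable,
    charcoal_influx,
    default_pfg_map,
    map_to_pfg,
    openness_ratio,
    read_pfg_map,
)
from .records import (
    CharcoalRecord,
    PollenRecord,
    Region,
    ScreeningPolicy,
    ValidationError,
    read_manifest,
    read_record,
    screen_record,
)
from .smoothing import (
    DEFAULT_DRAW_SEED,
    N_POSTERIOR_DRAWS,
    SourceKind,
    basis_rank,
    derivative,
    fit_gam,
    standardize,
)
from .zonation import ZonationResult, coniss

__all__ = [
    "RunConfig",
    "PollenStages",
    "CharcoalStages",
    "SummaryTable",
    "prepare_pollen",
    "prepare_charcoal",
    "classify_pollen_record",
    "classify_charcoal_record",
    "run_pipeline",
    "sensitivity_sweep",
]

log = logging.getLogger("forestsignal")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one batch run (thresholds, smoothing, outputs)."""

    manifest: Path
    pfg_map: Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    gam_criterion: str = "reml"
    draw_seed: int = DEFAULT_DRAW_SEED
    n_draws: int = N_POSTERIOR_DRAWS
    sqrt_transform: bool = False
    openness_variant: OpennessVariant = OpennessVariant.NAP_AP
    screening_overrides: tuple[str, ...] = ()
    out_dir: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        if "manifest" not in doc:
            raise ValidationError(f"{path}: run config needs a 'manifest' key")
        thr = doc.get("thresholds", {})
        return cls(
            manifest=(path.parent / doc["manifest"]).resolve(),
            pfg_map=(path.parent / doc["pfg_map"]).resolve() if doc.get("pfg_map") else None,
            thresholds=Thresholds(
                theta=float(thr.get("theta", 0.02)),
                delta_pp=float(thr.get("delta_pp", 5.0)),
                theta_fire=float(thr.get("theta_fire", 0.20)),
            ),
            gam_criterion=doc.get("gam_criterion", "reml"),
            draw_seed=int(doc.get("draw_seed", DEFAULT_DRAW_SEED)),
            n_draws=int(doc.get("n_draws", N_POSTERIOR_DRAWS)),
            sqrt_transform=bool(doc.get("sqrt_transform", False)),
            screening_overrides=tuple(doc.get("screening_overrides", ())),
            out_dir=(path.parent / doc["out_dir"]).resolve() if doc.get("out_dir") else None,
        )


@dataclass(frozen=True)
class PollenStages:
    """Threshold-independent per-record computations for a pollen record."""

    record: PollenRecord
    pfg: PFGTable
    openness: object  # OpennessSeries
    fit: object  # GamFit
    deriv: object  # DerivativeEstimate
    zonation: ZonationResult
    windows: EventWindows


@dataclass(frozen=True)
class CharcoalStages:
    record: CharcoalRecord
    influx: CharcoalSeries
    fit: object
    deriv: object
    windows: EventWindows


def prepare_pollen(
    record: PollenRecord,
    pfg_map: PFGMap | None = None,
    *,
    openness_variant: OpennessVariant = OpennessVariant.NAP_AP,
    gam_criterion: str = "reml",
    sqrt_transform: bool = False,
    draw_seed: int = DEFAULT_DRAW_SEED,
    n_draws: int = N_POSTERIOR_DRAWS,
) -> PollenStages:
    """Run every threshold-independent stage for one pollen record."""
    pfg = map_to_pfg(record, pfg_map).drop_flagged()
    if len(pfg.ages) < 5:
        raise ValidationError(
            f"{record.metadata.site_id}: fewer than 5 usable samples"
        )
    openness = openness_ratio(pfg, openness_variant)
    ages, vals = openness.valid()
    std = standardize(vals, ages, SourceKind.PERCENTAGE, max_count=openness.max_count())
    fit = fit_gam(std, k=basis_rank(len(vals)), criterion=gam_criterion)
    deriv = derivative(fit, seed=draw_seed, n_draws=n_draws)
    comp = pfg.proportions.to_numpy()
    if sqrt_transform:
        comp = np.sqrt(comp)
    zon = coniss(comp, pfg.ages)
    windows = EventWindows(record.metadata.contact_year, record.metadata.region)
    return PollenStages(
        record=record, pfg=pfg, openness=openness, fit=fit, deriv=deriv,
        zonation=zon, windows=windows,
    )


def classify_stages(
    stages: PollenStages, thresholds: Thresholds = Thresholds()
) -> SignalClassification:
    """Apply the window rules to prepared stages at the given thresholds."""
    w = stages.windows
    post = assess_window(
        stages.openness, stages.fit, stages.deriv, stages.zonation, stages.pfg,
        w.post_window, w.baseline_window, thresholds,
    )
    pre = assess_window(
        stages.openness, stages.fit, stages.deriv, stages.zonation, stages.pfg,
        w.pre_assess_window, w.pre_baseline_window, thresholds,
        gam_window=w.pre_window, pfg_window=w.pre_window,
    )
    veg = classify_vegetation(post, pre, stages.record.metadata.region)
    flags = tuple(
        f for f, bad in (
            ("post_window_insufficient", post.insufficient),
            ("pre_window_insufficient", pre.insufficient),
        ) if bad
    )
    return SignalClassification(
        record_id=stages.record.metadata.site_id,
        vegetation_class=veg,
        fire_class=FireClass.NOT_APPLICABLE,
        post_evidence=post,
        pre_evidence=pre,
        flags=flags,
    )


def classify_pollen_record(
    record: PollenRecord,
    pfg_map: PFGMap | None = None,
    thresholds: Thresholds = Thresholds(),
    **prepare_kwargs,
) -> SignalClassification:
    """End-to-end vegetation classification of one pollen record."""
    return classify_stages(prepare_pollen(record, pfg_map, **prepare_kwargs), thresholds)


def prepare_charcoal(
    record: CharcoalRecord,
    model: AgeDepthModel | None = None,
    *,
    gam_criterion: str = "reml",
    draw_seed: int = DEFAULT_DRAW_SEED,
    n_draws: int = N_POSTERIOR_DRAWS,
) -> CharcoalStages:
    """Influx conversion plus trend fitting for a charcoal record.

    Without an explicit age-depth model, a linear model through the record's
    own (depth, age) pairs is used.
    """
    if model is None:
        table = ChronologyTable(
            depths=tuple(record.depths),
            ages=tuple(record.ages),
            age_sds=tuple(0.0 for _ in record.ages),
        )
        model = build_age_model(table, AgeModelMethod.LINEAR)
    influx = charcoal_influx(record, model)
    ages, vals = influx.valid()
    std = standardize(vals, ages, SourceKind.COUNT_OR_FREQUENCY)
    fit = fit_gam(std, k=basis_rank(len(vals)), criterion=gam_criterion)
    deriv = derivative(fit, seed=draw_seed, n_draws=n_draws)
    windows = EventWindows(record.metadata.contact_year, record.metadata.region)
    return CharcoalStages(record=record, influx=influx, fit=fit, deriv=deriv, windows=windows)


def classify_charcoal_record(
    record: CharcoalRecord,
    model: AgeDepthModel | None = None,
    thresholds: Thresholds = Thresholds(),
    **prepare_kwargs,
) -> FireClass:
    stages = prepare_charcoal(record, model, **prepare_kwargs)
    return classify_fire(stages.influx, stages.deriv, stages.windows, thresholds)


@dataclass(frozen=True)
class SummaryTable:
    """One row per manifest record plus class tallies (the machine twin of
    the per-region colour tallies of the study design)."""

    frame: pd.DataFrame

    def tallies(self) -> pd.DataFrame:
        return (
            self.frame.groupby(["region", "vegetation_class"]).size()
            .rename("count").reset_index()
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, encoding="utf-8")


def run_pipeline(config: RunConfig) -> SummaryTable:
    """Screen and classify every record in the manifest.

    Records failing validation or screening are never silently dropped: they
    appear in the summary with class EXCLUDED and the reason in ``flags``.
    Deterministic given the config (all randomness is seeded from it).
    """
    paths = read_manifest(config.manifest)
    pfg_map = read_pfg_map(config.pfg_map) if config.pfg_map else None
    rows = []
    artifacts: dict[str, dict] = {}
    for path in paths:
        meta_region = None
        try:
            record = read_record(path)
            meta = record.metadata
            meta_region = meta.region
            policy = (
                ScreeningPolicy.NEOTROPICS_STRICT
                if meta.region is Region.NEOTROPICS
                else ScreeningPolicy.EAST_INDIES_LIBERAL
            )
            decision = screen_record(record, policy, config.screening_overrides)
            if not decision.included:
                log.info("%s excluded by screening: %s", meta.site_id, decision.failed_criteria)
                rows.append(_row(meta, "EXCLUDED", "NOT_APPLICABLE",
                                 decision.resolution_years_per_sample,
                                 len(record.samples),
                                 ";".join(decision.failed_criteria)))
                continue
            if isinstance(record, CharcoalRecord):
                stages = prepare_charcoal(
                    record, gam_criterion=config.gam_criterion,
                    draw_seed=config.draw_seed, n_draws=config.n_draws,
                )
                fire = classify_fire(stages.influx, stages.deriv, stages.windows,
                                     config.thresholds)
                rows.append(_row(meta, "NOT_APPLICABLE", fire.value,
                                 decision.resolution_years_per_sample,
                                 len(record.samples), ""))
                continue
            stages = prepare_pollen(
                record, pfg_map,
                openness_variant=config.openness_variant,
                gam_criterion=config.gam_criterion,
                sqrt_transform=config.sqrt_transform,
                draw_seed=config.draw_seed, n_draws=config.n_draws,
            )
            result = classify_stages(stages, config.thresholds)
            log.info("%s -> %s (post: %s/%s, pre: %s/%s)",
                     meta.site_id, result.vegetation_class.value,
                     result.post_evidence.proxy_direction.value,
                     result.post_evidence.gam_direction.value,
                     result.pre_evidence.proxy_direction.value,
                     result.pre_evidence.gam_direction.value)
            rows.append(_row(meta, result.vegetation_class.value, result.fire_class.value,
                             decision.resolution_years_per_sample,
                             len(record.samples), ";".join(result.flags)))
            artifacts[meta.site_id] = _artifact(stages, result)
        except (ValidationError, FileNotFoundError) as exc:
            log.warning("%s failed validation: %s", path, exc)
            rows.append({
                "record_id": str(path.name), "region": meta_region.value if meta_region else "",
                "zone": "", "biome": "", "vegetation_class": "EXCLUDED",
                "fire_class": "NOT_APPLICABLE", "resolution": np.nan,
                "n_samples": 0, "flags": f"validation:{exc}",
            })
    summary = SummaryTable(frame=pd.DataFrame(rows))
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv")
        for rid, art in artifacts.items():
            (out / f"{rid}.json").write_text(json.dumps(art, indent=1), encoding="utf-8")
    return summary


def _row(meta, veg, fire, resolution, n_samples, flags):
    return {
        "record_id": meta.site_id, "region": meta.region.value, "zone": meta.zone,
        "biome": meta.biome, "vegetation_class": veg, "fire_class": fire,
        "resolution": resolution if resolution is not None else np.nan,
        "n_samples": n_samples, "flags": flags,
    }


def _artifact(stages: PollenStages, result: SignalClassification) -> dict:
    grid = stages.deriv.grid
    lo, hi = stages.fit.band(grid)
    return {
        "record_id": result.record_id,
        "vegetation_class": result.vegetation_class.value,
        "gam": {
            "k": stages.fit.k, "lambda": stages.fit.lam, "edf": stages.fit.edf,
            "criterion": stages.fit.criterion,
        },
        "zonation": {
            "n_zones": stages.zonation.n_zones,
            "boundaries_ce": list(stages.zonation.zone_boundaries),
        },
        "post_evidence": _bundle_dict(result.post_evidence),
        "pre_evidence": _bundle_dict(result.pre_evidence),
        "trend": {
            "grid_ce": [float(g) for g in grid],
            "mu": [float(m) for m in stages.fit.predict(grid)],
            "lower": [float(x) for x in lo],
            "upper": [float(x) for x in hi],
        },
    }


def _bundle_dict(b) -> dict:
    return {
        "proxy_direction": b.proxy_direction.value,
        "proxy_magnitude": b.proxy_magnitude,
        "gam_direction": b.gam_direction.value,
        "pfg_clear_change": b.pfg_clear_change,
        "pfg_delta_pp": b.pfg_delta_pp,
        "samples_in_window": b.samples_in_window,
        "insufficient": b.insufficient,
    }


def sensitivity_sweep(
    stages_list: list[PollenStages],
    thetas: list[float],
    deltas: list[float],
    theta_fire: float = 0.20,
) -> pd.DataFrame:
    """Re-classify prepared records across a threshold grid.

    Returns one row per record and grid point plus, via the ``stability``
    column of the aggregate, the fraction of grid points agreeing with the
    record's modal class — the reproducible counterpart of "classified with
    a degree of uncertainty".
    """
    if not thetas or not deltas:
        raise ValidationError("sweep grid must be non-empty")
    rows = []
    for stages in stages_list:
        rid = stages.record.metadata.site_id
        for th in thetas:
            for de in deltas:
                thr = Thresholds(theta=th, delta_pp=de, theta_fire=theta_fire)
                res = classify_stages(stages, thr)
                rows.append({
                    "record_id": rid, "theta": th, "delta_pp": de,
                    "vegetation_class": res.vegetation_class.value,
                })
    frame = pd.DataFrame(rows)
    modal = (
        frame.groupby("record_id")["vegetation_class"]
        .agg(lambda s: s.value_counts(sort=True).iloc[0] / len(s))
        .rename("stability")
    )
    return frame.merge(modal, on="record_id")
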