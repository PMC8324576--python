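import numpy as np
import pytest

from forestsignal import (
    AgeModelMethod,
    CharcoalRecord,
    CharcoalSample,
    ChronologyTable,
    OpennessVariant,
    PollenRecord,
    Sample,
    UnmappedPolicy,
    ValidationError,
    build_age_model,
    charcoal_influx,
    default_pfg_map,
    map_to_pfg,
    openness_ratio,
)
from forestsignal.composition import PFGMap, read_pfg_map

from conftest import random_record


def record_from_counts(meta, counts_per_sample):
    return PollenRecord(
        metadata=meta,
        samples=tuple(
            Sample(depth=float(10 * i + 1), age=float(1900 - 100 * i), counts=c)
            for i, c in enumerate(counts_per_sample)
        ),
    )


class TestPFGMapping:
    def test_simple_proportions(self, site_meta):
        rec = record_from_counts(
            site_meta,
            [{"Moraceae": 40, "Poaceae": 10}, {"Moraceae": 10, "Poaceae": 40}],
        )
        pfg = map_to_pfg(rec, default_pfg_map())
        assert pfg.proportions.loc[0, "TROPICAL_TREES"] == pytest.approx(0.8)
        assert pfg.proportions.loc[0, "GRASSES"] == pytest.approx(0.2)

    def test_count_conservation_and_normalization(self, pfg_map):
        rng = np.random.default_rng(11)
        from conftest import make_record

        rec = make_record("null_stable", seed=3)
        pfg = map_to_pfg(rec, pfg_map)
        for i, s in enumerate(rec.samples):
            assert pfg.counts.iloc[i].sum() == sum(s.counts.values())
            if not pfg.flagged[i]:
                assert pfg.proportions.iloc[i].sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_sample_flagged(self, site_meta):
        rec = record_from_counts(
            site_meta, [{"Moraceae": 10, "Poaceae": 10}, {"Moraceae": 0, "Poaceae": 0}]
        )
        pfg = map_to_pfg(rec, default_pfg_map())
        assert pfg.flagged == (False, True)
        assert np.isnan(pfg.proportions.iloc[1]).all()
        assert map_to_pfg(rec, default_pfg_map()).drop_flagged().flagged == (False,)

    def test_taxon_order_irrelevant(self, site_meta):
        a = record_from_counts(site_meta, [{"Moraceae": 7, "Poaceae": 3, "Pinus": 5}] * 2)
        b = record_from_counts(site_meta, [{"Pinus": 5, "Poaceae": 3, "Moraceae": 7}] * 2)
        pa, pb = map_to_pfg(a), map_to_pfg(b)
        assert pa.counts.equals(pb.counts)

    def test_unmapped_error_policy_lists_taxa(self, site_meta):
        rec = record_from_counts(site_meta, [{"Mysterium": 5, "Poaceae": 5}] * 2)
        with pytest.raises(ValidationError, match="Mysterium"):
            map_to_pfg(rec, default_pfg_map(), UnmappedPolicy.ERROR)

    def test_unmapped_other_bin_excluded_from_openness(self, site_meta):
        rec = record_from_counts(site_meta, [{"Mysterium": 50, "Poaceae": 5,
                                              "Moraceae": 5}] * 2)
        with pytest.warns(UserWarning, match="unmapped"):
            pfg = map_to_pfg(rec, default_pfg_map(), UnmappedPolicy.OTHER_BIN)
        op = openness_ratio(pfg)
        assert op.openness[0] == pytest.approx(0.5)

    def test_map_config_round_trip(self, tmp_path):
        cfg = tmp_path / "map.yaml"
        cfg.write_text("taxa:\n  Moraceae: TROPICAL_TREES\n  Poaceae: GRASSES\n")
        m = read_pfg_map(cfg)
        assert m.mapping["Poaceae"] == "GRASSES"

    def test_role_invariants_enforced(self):
        from forestsignal.composition import PFG_GROUPS, GroupRole

        roles = dict(PFG_GROUPS)
        roles["GRASSES"] = GroupRole.ARBOREAL
        with pytest.raises(ValidationError):
            PFGMap(mapping={}, roles=roles)


class TestOpenness:
    def test_ferns_ignored(self, site_meta):
        rec = record_from_counts(
            site_meta,
            [{"Moraceae": 80, "Poaceae": 20, "Cyathea": 50}] * 2,
        )
        op = openness_ratio(map_to_pfg(rec))
        assert op.openness[0] == pytest.approx(0.20)

    def test_closed_forest_bound(self, site_meta):
        rec = record_from_counts(site_meta, [{"Moraceae": 100, "Poaceae": 0}] * 2)
        op = openness_ratio(map_to_pfg(rec))
        assert op.openness[0] == 0.0

    def test_grass_ap_variant(self, site_meta):
        rec = record_from_counts(
            site_meta,
            [{"Poaceae": 30, "Plantago": 20, "Moraceae": 50}] * 2,
        )
        op = openness_ratio(map_to_pfg(rec), OpennessVariant.GRASS_AP)
        assert op.openness[0] == pytest.approx(30 / 80)

    def test_scale_invariance(self, site_meta):
        base = {"Moraceae": 12, "Poaceae": 7, "Pinus": 4}
        scaled = {t: 13 * c for t, c in base.items()}
        a = openness_ratio(map_to_pfg(record_from_counts(site_meta, [base] * 2)))
        b = openness_ratio(map_to_pfg(record_from_counts(site_meta, [scaled] * 2)))
        assert a.openness[0] == pytest.approx(b.openness[0], abs=1e-12)

    def test_monotone_in_nap(self, site_meta):
        vals = []
        for nap in (0, 10, 20, 40):
            rec = record_from_counts(
                site_meta, [{"Moraceae": 50, "Poaceae": nap}] * 2
            )
            vals.append(openness_ratio(map_to_pfg(rec)).openness[0])
        assert vals == sorted(vals)


class TestCharcoalInflux:
    def _record(self, site_meta, concentrations):
        return CharcoalRecord(
            metadata=site_meta,
            samples=tuple(
                CharcoalSample(depth=float(10 * i + 5), age=float(1800 - 200 * i),
                               concentration=float(c))
                for i, c in enumerate(concentrations)
            ),
        )

    def test_arithmetic(self, site_meta):
        model = build_age_model(
            ChronologyTable((0.0, 100.0), (2000.0, 0.0), (0.0, 0.0)),
            AgeModelMethod.LINEAR,
        )  # 20 yr/cm everywhere
        series = charcoal_influx(self._record(site_meta, [200.0, 60.0, 0.0]), model)
        assert series.influx[0] == pytest.approx(10.0, rel=1e-9)
        assert series.influx[1] == pytest.approx(3.0, rel=1e-9)
        assert series.influx[2] == 0.0
        for f, c, dt in zip(series.influx, series.concentration,
                            series.deposition_times):
            assert f == pytest.approx(c / dt, rel=1e-9)

    def test_halving_sedimentation_halves_influx(self, site_meta):
        fast = build_age_model(
            ChronologyTable((0.0, 100.0), (2000.0, 0.0), (0.0, 0.0))
        )
        slow = build_age_model(
            ChronologyTable((0.0, 50.0), (2000.0, 0.0), (0.0, 0.0))
        )  # half the accumulation rate
        rec = self._record(site_meta, [100.0, 100.0])
        f_fast = charcoal_influx(rec, fast).influx[0]
        f_slow = charcoal_influx(rec, slow).influx[0]
        assert f_slow == pytest.approx(f_fast / 2.0, rel=1e-9)

    def test_count_volume_input(self, site_meta, tmp_path):
        import dataclasses

        from forestsignal import RecordType, read_record, write_record

        meta = dataclasses.replace(site_meta, record_type=RecordType.CHARCOAL)
        rec = self._record(meta, [50.0, 25.0])
        path = write_record(rec, tmp_path / "char.csv")
        back = read_record(path)
        assert isinstance(back, CharcoalRecord)
        assert back.samples[0].concentration == pytest.approx(50.0)
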