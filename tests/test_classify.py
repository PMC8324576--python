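import dataclasses

import numpy as np
import pytest

from forestsignal import (
    Direction,
    EventWindows,
    EvidenceBundle,
    FireClass,
    Region,
    Thresholds,
    ValidationError,
    VegetationClass,
    classify_fire,
    classify_vegetation,
)
from forestsignal.classify import _INSUFFICIENT


def bundle(proxy, gam, clear=False, delta_pp=0.0, magnitude=0.0):
    return EvidenceBundle(
        proxy_direction=proxy,
        proxy_magnitude=magnitude,
        gam_direction=gam,
        pfg_clear_change=clear,
        pfg_delta_pp=delta_pp,
        samples_in_window=3,
    )


FLAT = bundle(Direction.FLAT, Direction.NONE)


class TestWindows:
    def test_post_window_anchored_on_contact(self):
        w = EventWindows(1520.0, Region.NEOTROPICS)
        assert w.post_window == (1520.0, 1620.0)
        assert w.baseline_window == (1420.0, 1520.0)
        assert w.pre_window == (1000.0, 1400.0)

    def test_east_indies_pre_window_runs_to_contact(self):
        w = EventWindows(1570.0, Region.EAST_INDIES)
        assert w.pre_window == (1000.0, 1570.0)
        assert w.pre_assess_window == (1470.0, 1570.0)

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValidationError):
            Thresholds(theta=0.0)


class TestVegetationRules:
    def test_full_afforestation_neotropics(self):
        post = bundle(Direction.CLOSING, Direction.CLOSING, clear=True, delta_pp=12.0)
        assert (
            classify_vegetation(post, FLAT, Region.NEOTROPICS)
            is VegetationClass.POST_AFFORESTATION
        )

    def test_minor_when_pfg_stable(self):
        post = bundle(Direction.CLOSING, Direction.CLOSING, clear=False)
        assert (
            classify_vegetation(post, FLAT, Region.NEOTROPICS)
            is VegetationClass.POST_AFFORESTATION_MINOR
        )

    def test_minor_when_gam_silent_but_pfg_clear(self):
        post = bundle(Direction.CLOSING, Direction.NONE, clear=True, delta_pp=8.0)
        assert (
            classify_vegetation(post, FLAT, Region.NEOTROPICS)
            is VegetationClass.POST_AFFORESTATION_MINOR
        )

    def test_east_indies_full_without_pfg(self):
        post = bundle(Direction.CLOSING, Direction.CLOSING, clear=False)
        assert (
            classify_vegetation(post, FLAT, Region.EAST_INDIES)
            is VegetationClass.POST_AFFORESTATION
        )

    def test_pre_iberian_when_post_silent(self):
        pre = bundle(Direction.CLOSING, Direction.CLOSING, clear=True, delta_pp=10.0)
        assert (
            classify_vegetation(FLAT, pre, Region.NEOTROPICS)
            is VegetationClass.PRE_AFFORESTATION
        )

    def test_post_preempts_pre(self):
        post = bundle(Direction.CLOSING, Direction.CLOSING, clear=True, delta_pp=9.0)
        pre = bundle(Direction.CLOSING, Direction.CLOSING, clear=True, delta_pp=9.0)
        assert (
            classify_vegetation(post, pre, Region.NEOTROPICS)
            is VegetationClass.POST_AFFORESTATION
        )

    def test_all_flat_is_limited(self):
        assert (
            classify_vegetation(FLAT, FLAT, Region.NEOTROPICS)
            is VegetationClass.LIMITED
        )

    def test_insufficient_bundles_are_limited(self):
        assert (
            classify_vegetation(_INSUFFICIENT, _INSUFFICIENT, Region.NEOTROPICS)
            is VegetationClass.LIMITED
        )

    def test_wrong_sign_pfg_does_not_support_full(self):
        # an arboreal DROP across the boundary cannot support afforestation
        post = bundle(Direction.CLOSING, Direction.CLOSING, clear=True, delta_pp=-9.0)
        assert (
            classify_vegetation(post, FLAT, Region.NEOTROPICS)
            is VegetationClass.POST_AFFORESTATION_MINOR
        )

    @pytest.mark.parametrize(
        "closing_cls,opening_cls",
        [
            (VegetationClass.POST_AFFORESTATION, VegetationClass.POST_DEFORESTATION),
            (
                VegetationClass.POST_AFFORESTATION_MINOR,
                VegetationClass.POST_DEFORESTATION_MINOR,
            ),
        ],
    )
    def test_mirror_symmetry_of_rules(self, closing_cls, opening_cls):
        """Swapping CLOSING and OPENING evidence (and the sign of the
        arboreal-share change) swaps afforestation and deforestation."""
        full = closing_cls is VegetationClass.POST_AFFORESTATION
        post_c = bundle(Direction.CLOSING, Direction.CLOSING, clear=full,
                        delta_pp=8.0 if full else 0.0)
        post_o = bundle(Direction.OPENING, Direction.OPENING, clear=full,
                        delta_pp=-8.0 if full else 0.0)
        assert classify_vegetation(post_c, FLAT, Region.NEOTROPICS) is closing_cls
        assert classify_vegetation(post_o, FLAT, Region.NEOTROPICS) is opening_cls


class TestFireRules:
    def _series(self, ages, influx):
        from forestsignal.composition import CharcoalSeries

        return CharcoalSeries(
            ages=tuple(ages),
            influx=tuple(influx),
            concentration=tuple(influx),
            deposition_times=tuple(1.0 for _ in ages),
            flagged=tuple(False for _ in ages),
        )

    def _deriv(self, grid, sign):
        from forestsignal.smoothing import DerivativeEstimate, DerivativeSign

        g = np.asarray(grid, dtype=float)
        signs = np.full(g.size, DerivativeSign.NONE, dtype=object)
        dmu = np.zeros(g.size)
        if sign is not None:
            lo, hi, which = sign
            mask = (g >= lo) & (g <= hi)
            signs[mask] = which
            dmu[mask] = -1.0 if which is DerivativeSign.NEG else 1.0
        return DerivativeEstimate(grid=g, dmu=dmu, lower=dmu - 0.1, upper=dmu + 0.1,
                                  sign=signs)

    def test_halved_influx_with_detection(self):
        from forestsignal.smoothing import DerivativeSign

        w = EventWindows(1520.0, Region.NEOTROPICS)
        ages = np.arange(1400.0, 1640.0, 20.0)
        influx = np.where(ages >= 1520.0, 5.0, 10.0)
        deriv = self._deriv(np.arange(1400, 1641, 10.0),
                            (1500.0, 1560.0, DerivativeSign.NEG))
        assert (
            classify_fire(self._series(ages, influx), deriv, w)
            is FireClass.FIRE_DECREASE
        )

    def test_drop_without_detection_is_minor(self):
        w = EventWindows(1520.0, Region.NEOTROPICS)
        ages = np.arange(1400.0, 1640.0, 20.0)
        influx = np.where(ages >= 1520.0, 7.0, 10.0)  # 30% drop
        deriv = self._deriv(np.arange(1400, 1641, 10.0), None)
        assert (
            classify_fire(self._series(ages, influx), deriv, w)
            is FireClass.FIRE_DECREASE_MINOR
        )

    def test_stationary_is_limited(self):
        w = EventWindows(1520.0, Region.NEOTROPICS)
        ages = np.arange(1400.0, 1640.0, 20.0)
        influx = np.full(ages.size, 10.0)
        deriv = self._deriv(np.arange(1400, 1641, 10.0), None)
        assert (
            classify_fire(self._series(ages, influx), deriv, w)
            is FireClass.FIRE_LIMITED
        )

    def test_increase_mirror(self):
        from forestsignal.smoothing import DerivativeSign

        w = EventWindows(1520.0, Region.NEOTROPICS)
        ages = np.arange(1400.0, 1640.0, 20.0)
        influx = np.where(ages >= 1520.0, 20.0, 10.0)
        deriv = self._deriv(np.arange(1400, 1641, 10.0),
                            (1500.0, 1560.0, DerivativeSign.POS))
        assert (
            classify_fire(self._series(ages, influx), deriv, w)
            is FireClass.FIRE_INCREASE
        )

    def test_no_window_data_not_applicable(self):
        w = EventWindows(1520.0, Region.NEOTROPICS)
        ages = np.arange(0.0, 900.0, 100.0)
        deriv = self._deriv(np.arange(0, 901, 10.0), None)
        assert (
            classify_fire(self._series(ages, np.full(ages.size, 1.0)), deriv, w)
            is FireClass.NOT_APPLICABLE
        )
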