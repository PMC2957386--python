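import numpy as np
import pytest

from checklist_irr.io import ItemDefinition
from checklist_irr.reliability import (
    FLAG_TRUNCATED,
    FLAG_UNDEFINED,
    KappaBands,
    classify_kappa,
    intraclass_kappa,
    kappa_for_item,
    one_way_components,
    si_kappa,
    weighted_kappa_quadratic,
)

from _oracle import oracle_components, oracle_icc, oracle_si
from conftest import random_units


class TestOneWayComponents:
    def test_perfect_within_agreement(self):
        vc = one_way_components([[0, 0], [1, 1]])
        assert vc.sigma2_error == 0.0
        assert vc.sigma2_article > 0

    def test_no_variance_anywhere(self):
        vc = one_way_components([[1, 1], [1, 1]])
        assert vc.sigma2_article == vc.sigma2_error == 0.0

    def test_frozen_oracle_example(self):
        # explicit-enumeration oracle values for {1,1,0},{0,0},{1,0}
        vc = one_way_components([[1, 1, 0], [0, 0], [1, 0]])
        assert vc.sigma2_error == pytest.approx(7 / 24, abs=1e-12)
        assert vc.ms_between == pytest.approx(0.2738095238095238, abs=1e-12)
        assert vc.n0 == pytest.approx(16 / 7, abs=1e-12)
        assert vc.truncated and vc.sigma2_article == 0.0

    def test_balanced_design_n0_is_group_size(self, rng):
        units = [list(rng.integers(0, 2, size=4)) for _ in range(6)]
        assert one_way_components(units).n0 == pytest.approx(4.0)

    @pytest.mark.parametrize("units", [[[1, 2, 3]], [[1], [2]]])
    def test_preconditions(self, units):
        with pytest.raises(ValueError):
            one_way_components(units)

    def test_matches_enumeration_oracle_on_random_instances(self, rng):
        for _ in range(250):
            units = random_units(rng, values=(0.0, 1.0, 2.0))
            vc = one_way_components(units)
            ref = oracle_components(units)
            assert vc.sigma2_article == pytest.approx(
                ref["sigma2_article"], abs=1e-10)
            assert vc.sigma2_error == pytest.approx(
                ref["sigma2_error"], abs=1e-10)
            assert vc.truncated == ref["truncated"]


class TestIntraclassKappa:
    def test_perfect_agreement_distinct_articles_is_one(self):
        r = intraclass_kappa([[1, 1, 1], [0, 0], [1, 1]])
        assert r.kappa == pytest.approx(1.0)

    def test_truncation_to_zero(self):
        r = intraclass_kappa([[0, 1], [1, 0]])
        assert r.kappa == 0.0
        assert FLAG_TRUNCATED in r.flags

    def test_frozen_oracle_example(self):
        r = intraclass_kappa([[1, 1, 0], [0, 0], [1, 0]])
        assert r.kappa == 0.0 and FLAG_TRUNCATED in r.flags

    def test_undefined_when_no_variance(self):
        r = intraclass_kappa([[1, 1], [1, 1]])
        assert r.kappa is None and FLAG_UNDEFINED in r.flags

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="binary"):
            intraclass_kappa([[1, 2], [0, 1]])


class TestWeightedKappaQuadratic:
    def test_frozen_oracle_example(self):
        r = weighted_kappa_quadratic([[1, 2, 2], [3, 3], [1, 3]])
        assert r.kappa == pytest.approx(0.2195121951219512, abs=1e-12)

    def test_unanimous_within_differing_between_is_one(self):
        r = weighted_kappa_quadratic([[1, 1], [3, 3, 3], [2, 2]])
        assert r.kappa == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        for _ in range(50):
            units = random_units(rng, values=(1.0, 2.0, 3.0))
            base = weighted_kappa_quadratic(units)
            shifted = [[5.0 * x - 2.0 for x in u] for u in units]
            other = weighted_kappa_quadratic(shifted)
            if base.kappa is None:
                assert other.kappa is None
            else:
                assert other.kappa == pytest.approx(base.kappa, abs=1e-10)

    def test_yes_no_only_equals_intraclass_on_recoding(self):
        units13 = [[1, 1, 3], [3, 3], [1, 3]]
        units01 = [[1, 1, 0], [0, 0], [1, 0]]
        a = weighted_kappa_quadratic(units13)
        b = intraclass_kappa(units01)
        assert a.kappa == pytest.approx(b.kappa, abs=1e-12)


class TestSiKappa:
    def test_frozen_oracle_example(self):
        r = si_kappa([["yes", "yes", "na"], ["no", "no"], ["yes", "na"]],
                     ("yes", "no", "na"))
        assert r.kappa == pytest.approx(0.34883720930232553, abs=1e-12)
        assert FLAG_TRUNCATED in r.flags  # two dummies clip negative

    def test_two_category_si_equals_intraclass(self, rng):
        for _ in range(100):
            units = random_units(rng, values=(0.0, 1.0))
            tokens = [["yes" if x else "no" for x in u] for u in units]
            si = si_kappa(tokens, ("yes", "no"))
            ic = intraclass_kappa(units)
            if ic.kappa is None:
                assert si.kappa is None
            else:
                assert si.kappa == pytest.approx(ic.kappa, abs=1e-12)

    def test_unanimous_within_is_one(self):
        r = si_kappa([["yes"] * 3, ["na"] * 2, ["no"] * 2], ("yes", "no", "na"))
        assert r.kappa == pytest.approx(1.0)

    def test_matches_per_dummy_oracle(self, rng):
        cats = ("yes", "no", "na")
        for _ in range(100):
            units = random_units(rng, values=cats)
            tokens = [[str(x) for x in u] for u in units]
            got = si_kappa(tokens, cats).kappa
            ref = oracle_si(tokens, cats)
            if ref is None:
                assert got is None
            else:
                assert got == pytest.approx(ref, abs=1e-10)


class TestClassifyKappa:
    @pytest.mark.parametrize("kappa,label", [
        (0.77, "excellent"), (0.66, "moderate_good"), (0.40, "moderate_good"),
        (0.75, "moderate_good"), (0.39, "poor"), (0.81, "excellent"),
        (0.0, "poor"), (1.0, "excellent"),
    ])
    def test_bands(self, kappa, label):
        assert classify_kappa(kappa) == label

    def test_band_validation(self):
        with pytest.raises(ValueError):
            KappaBands(poor_below=0.8, excellent_above=0.5)


class TestKappaForItem:
    @pytest.mark.parametrize("item,units,method", [
        (ItemDefinition("A1", "A", "ordinal_yes_q_no"),
         [["yes", "?"], ["no", "no"]], "weighted_quadratic"),
        (ItemDefinition("STEP1.reliability", "STEP1", "binary_yes_no"),
         [["yes", "yes"], ["no", "no"]], "intraclass"),
        (ItemDefinition("A9", "A", "nominal_with_na_3"),
         [["yes", "na"], ["no", "no"]], "si"),
    ])
    def test_dispatch(self, item, units, method):
        assert kappa_for_item(item, units).method == method

    def test_scale_mismatch(self):
        item = ItemDefinition("B11", "B", "binary_yes_no")
        with pytest.raises(ValueError, match="outside scale"):
            kappa_for_item(item, [["yes", "na"], ["no", "no"]])


def test_kappa_always_in_unit_interval(rng):
    """Post-truncation kappa is in [0,1]; 1 exactly when error variance is 0
    and article variance positive."""
    for _ in range(200):
        units = random_units(rng, values=(0.0, 1.0))
        r = intraclass_kappa(units)
        if r.kappa is None:
            continue
        assert 0.0 <= r.kappa <= 1.0
        vc = r.components
        assert (r.kappa == 1.0) == (
            vc.sigma2_error == 0.0 and vc.sigma2_article > 0)
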