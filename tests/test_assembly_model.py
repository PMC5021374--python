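"""Closed-form activity curves against enumeration oracles and invariants."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringstoich import (
    DimerRule,
    NoDimerError,
    RingModel,
    activity_curve,
    dimer_type_distribution,
    relative_activity,
    relative_activity_dimer_seeded,
    relative_activity_random,
)


def enumerate_activity_random(p: float, z: int, k: int) -> float:
    """Brute-force oracle: sum over all 2^z wild/mutant strings."""
    total = 0.0
    for comp in itertools.product([0, 1], repeat=z):
        m = sum(comp)
        if m < k:
            total += p**m * (1 - p) ** (z - m)
    return total


def enumerate_activity_dimer_seeded(
    p: float, z: int, k: int, requires_donor: bool = True
) -> float:
    """Oracle: enumerate dimer classes x all 2^(z-2) monomer strings."""
    weights = {0: (1 - p) ** 2, 1: 2 * p * (1 - p)}
    if not requires_donor:
        weights[2] = p**2
    norm = sum(weights.values())
    total = 0.0
    for d, w in weights.items():
        for comp in itertools.product([0, 1], repeat=z - 2):
            m = sum(comp)
            if d + m < k:
                total += (w / norm) * p**m * (1 - p) ** (z - 2 - m)
    return total


class TestRandomAssembly:
    @pytest.mark.parametrize(
        "p, z, k, expected",
        [
            (0.0, 6, 1, 1.0),
            (1.0, 6, 1, 0.0),
            (0.5, 6, 1, 0.015625),  # 1/64: only the all-wild-type string
            (0.2, 6, 2, 0.65536),  # mutant counts 0 and 1, enumerated by hand
            (0.3, 1, 1, 0.7),  # single-subunit ring: A = 1 - p
        ],
    )
    def test_known_values(self, p, z, k, expected):
        assert relative_activity_random(p, RingModel(z, k)) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize("z", range(1, 11))
    @pytest.mark.parametrize("p", [0.2, 0.5, 0.8])
    def test_matches_exhaustive_enumeration(self, z, p):
        for k in {1, (z + 1) // 2, z}:
            assert relative_activity_random(p, RingModel(z, k)) == pytest.approx(
                enumerate_activity_random(p, z, k), abs=1e-12
            )

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            relative_activity_random(1.5, RingModel(6, 1))
        with pytest.raises(ValueError):
            relative_activity_random(-0.1, RingModel(6, 1))

    def test_saturated_blocking_number_gives_unit_activity(self):
        model = RingModel(6, 7)  # k > z: no ring can ever be poisoned
        for p in [0.0, 0.3, 1.0]:
            assert relative_activity_random(p, model) == 1.0


class TestDimerTypeDistribution:
    def test_pure_wild_type_pool(self):
        assert dimer_type_distribution(0.0, DimerRule()) == {"WW": 1.0, "WM": 0.0}

    def test_equal_mix_renormalizes_without_mm(self):
        dist = dimer_type_distribution(0.5, DimerRule())
        assert dist["WW"] == pytest.approx(1 / 3)
        assert dist["WM"] == pytest.approx(2 / 3)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_all_mutant_pool_cannot_seed(self):
        with pytest.raises(NoDimerError):
            dimer_type_distribution(1.0, DimerRule(requires_donor=True))

    def test_unconstrained_rule_keeps_mm_class(self):
        dist = dimer_type_distribution(0.5, DimerRule(requires_donor=False))
        assert dist["MM"] == pytest.approx(0.25)
        assert sum(dist.values()) == pytest.approx(1.0)


class TestDimerSeededAssembly:
    @pytest.mark.parametrize(
        "p, z, k, expected",
        [
            (0.0, 6, 1, 1.0),
            (0.5, 6, 1, (1 / 3) * 0.5**4),  # WW dimer and 4 wild-type monomers
            (0.5, 6, 7, 1.0),  # k > z unreachable
        ],
    )
    def test_known_values(self, p, z, k, expected):
        model = RingModel(z, k, "dimer_seeded")
        assert relative_activity_dimer_seeded(p, model) == pytest.approx(
            expected, abs=1e-12
        )

    def test_all_mutant_pool_warns_and_returns_zero(self):
        model = RingModel(6, 1, "dimer_seeded")
        with pytest.warns(UserWarning, match="no dimers"):
            assert relative_activity_dimer_seeded(1.0, model) == 0.0

    @pytest.mark.parametrize("z", range(2, 11))
    @pytest.mark.parametrize("p", [0.2, 0.5, 0.8])
    @pytest.mark.parametrize("requires_donor", [True, False])
    def test_matches_exhaustive_enumeration(self, z, p, requires_donor):
        rule = DimerRule(requires_donor)
        for k in {1, (z + 1) // 2, z}:
            model = RingModel(z, k, "dimer_seeded")
            assert relative_activity_dimer_seeded(p, model, rule) == pytest.approx(
                enumerate_activity_dimer_seeded(p, z, k, requires_donor), abs=1e-12
            )

    def test_monomer_ring_forbidden(self):
        with pytest.raises(ValueError):
            RingModel(1, 1, "dimer_seeded")


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    p=st.floats(0.0, 1.0),
    z=st.integers(1, 12),
    mode=st.sampled_from(["random", "dimer_seeded"]),
    data=st.data(),
)
def test_activity_is_a_probability_with_fixed_endpoints(p, z, mode, data):
    if mode == "dimer_seeded" and z < 2:
        z = 2
    import warnings

    k = data.draw(st.integers(1, z))
    model = RingModel(z, k, mode)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # p = 1 no-dimer convention warns
        a = relative_activity(p, model)
        assert 0.0 <= a <= 1.0
        assert relative_activity(0.0, model) == pytest.approx(1.0)
        assert relative_activity(1.0, model) == pytest.approx(0.0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    z=st.integers(1, 12),
    mode=st.sampled_from(["random", "dimer_seeded"]),
    data=st.data(),
)
def test_activity_nonincreasing_in_mutant_fraction(z, mode, data):
    import warnings

    if mode == "dimer_seeded" and z < 2:
        z = 2
    k = data.draw(st.integers(1, z))
    model = RingModel(z, k, mode)
    grid = [i / 50 for i in range(51)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = [relative_activity(p, model) for p in grid]
    assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


@settings(deadline=None, max_examples=40, derandomize=True)
@given(p=st.floats(0.0, 0.999), z=st.integers(2, 12))
def test_unconstrained_single_poison_dimer_mode_reduces_to_random(p, z):
    """Without the donor rule and with K = 1, both modes equal (1-p)^z."""
    rule = DimerRule(requires_donor=False)
    a_dimer = relative_activity_dimer_seeded(p, RingModel(z, 1, "dimer_seeded"), rule)
    a_random = relative_activity_random(p, RingModel(z, 1))
    assert a_dimer == pytest.approx(a_random, abs=1e-12)
    assert a_random == pytest.approx((1 - p) ** z, abs=1e-9)


class TestActivityCurve:
    def test_preserves_order_and_values(self, hexamer):
        curve = activity_curve(hexamer, [0.0, 1.0, 0.5])
        assert list(curve["p"]) == [0.0, 1.0, 0.5]
        assert list(curve["activity"]) == pytest.approx([1.0, 0.0, 0.015625])

    def test_empty_grid_gives_empty_curve(self, hexamer):
        assert activity_curve(hexamer, []).empty

    def test_csv_round_trip(self, hexamer, tmp_path):
        import pandas as pd

        curve = activity_curve(hexamer, [0.0, 0.25, 0.5])
        path = tmp_path / "curve.csv"
        curve.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert back["activity"].tolist() == pytest.approx(curve["activity"].tolist())
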