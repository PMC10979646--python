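"""The sequential updating mechanism and its middle-ordinal grid."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qbe.core import (
    A_VALUE_SCALE,
    R_VALUE_SCALE,
    EvidenceItem,
    OrdinalScale,
    TheoryDataset,
    count_matrix,
)
from qbe.quantify import (
    BoundError,
    QuantConfig,
    check_bounds,
    enumerate_middle_assignments,
    quantify_theory,
    resolve_values,
    update_step,
)


def closed_form_posteriors(dataset, config=None):
    """Independent oracle: prior times the per-cell product of update factors.

    The multiplicative fold is a commutative product, so each grid posterior
    equals ``prior * prod_cells ((1 + a/100) / (1 - r/100)) ** count``.
    """
    config = config or QuantConfig()
    mat = count_matrix(dataset)
    out = {}
    for a_mid in enumerate_middle_assignments(config.a_scale):
        a_vals = resolve_values(config.a_scale, a_mid)
        for r_mid in enumerate_middle_assignments(config.r_scale):
            r_vals = resolve_values(config.r_scale, r_mid)
            p = config.resolved_prior
            for r, r_lab in enumerate(("high", "medium", "low")):
                for c, a_lab in enumerate(
                    ("accepted", "coherent_testable", "coherent_untestable")
                ):
                    factor = (1 + a_vals[a_lab] / 100) / (1 - r_vals[r_lab] / 100)
                    p *= factor ** mat[r, c]
            out[(a_mid, r_mid)] = p
    return out


class TestMiddleEnumeration:
    def test_three_label_scale_has_eight_singletons(self):
        assignments = enumerate_middle_assignments(A_VALUE_SCALE)
        assert assignments == [(v,) for v in range(2, 10)]

    def test_two_label_scale_has_one_empty_assignment(self):
        scale = OrdinalScale(("lo", "hi"), 1, 10)
        assert enumerate_middle_assignments(scale) == [()]

    def test_four_label_scale_matches_brute_force(self):
        scale = OrdinalScale(("a", "b", "c", "d"), 1, 10)
        got = enumerate_middle_assignments(scale)
        brute = [
            (i, j) for i in range(2, 10) for j in range(2, 10) if i < j
        ]
        assert got == sorted(brute)
        assert len(got) == math.comb(8, 2) == 28

    def test_resolve_values_pins_anchors(self):
        assert resolve_values(A_VALUE_SCALE, (5,)) == {
            "coherent_untestable": 1,
            "coherent_testable": 5,
            "accepted": 10,
        }
        assert resolve_values(R_VALUE_SCALE, (7,)) == {
            "low": 1,
            "medium": 7,
            "high": 10,
        }
        two = OrdinalScale(("lo", "hi"), 3, 7)
        assert resolve_values(two, ()) == {"lo": 3, "hi": 7}

    @pytest.mark.parametrize("bad", [(1,), (10,), (5, 5), (7, 3)])
    def test_resolve_values_rejects_inadmissible_assignments(self, bad):
        scale = OrdinalScale(("a", "b", "c", "d"), 1, 10) if len(bad) == 2 else A_VALUE_SCALE
        with pytest.raises(ValueError):
            resolve_values(scale, bad)


class TestUpdateStep:
    @pytest.mark.parametrize(
        "p,a,r,mech,expected",
        [
            (0.04, 10, 10, "multiplicative", 0.04 * 1.1 / 0.9),
            (0.5, 1, 1, "multiplicative", 0.5 * 1.01 / 0.99),
            (0.04, 10, 10, "additive", 0.14 / 0.9),
        ],
    )
    def test_closed_forms(self, p, a, r, mech, expected):
        assert update_step(p, a, r, mech) == pytest.approx(expected, rel=1e-12)

    def test_marginal_must_stay_positive(self):
        with pytest.raises(ValueError, match="below 100"):
            update_step(0.04, 10, 100)


class TestQuantifyTheory:
    def test_demo_theory_grid_mean(self, demo):
        ps = quantify_theory(demo["A"])
        assert len(ps) == 64
        assert ps.posteriors.mean() == pytest.approx(0.4409, abs=5e-5)

    def test_empty_dataset_keeps_the_prior(self):
        ps = quantify_theory(TheoryDataset("T", []))
        assert np.allclose(ps.posteriors, 0.04)

    def test_single_anchor_item_is_middle_independent(self):
        ds = TheoryDataset("T", [EvidenceItem("m", "accepted", "high")])
        ps = quantify_theory(ds)
        assert np.allclose(ps.posteriors, 0.04 * 1.1 / 0.9, rtol=1e-12)

    def test_rejected_items_are_skipped_not_fatal(self):
        ds = TheoryDataset(
            "T",
            [
                EvidenceItem("m1", "accepted", "high"),
                EvidenceItem("m2", "rejected", "high"),
            ],
        )
        ps = quantify_theory(ds)
        assert ps.n_rejected == 1
        assert np.allclose(ps.posteriors, 0.04 * 1.1 / 0.9, rtol=1e-12)

    def test_grid_cardinality_formula(self):
        # |grid| = C(span-1, mA) * C(span-1, mR)
        cfg = QuantConfig(
            a_scale=OrdinalScale(("a", "b", "c", "d"), 1, 10),
            r_scale=R_VALUE_SCALE,
        )
        ps = quantify_theory(TheoryDataset("T", []), cfg)
        assert len(ps) == math.comb(9 - 1, 2) * math.comb(9 - 1, 1) == 28 * 8

    def test_closed_form_oracle_agreement(self, random_dataset):
        for seed in range(3):
            ds = random_dataset(seed)
            ps = quantify_theory(ds)
            oracle = closed_form_posteriors(ds)
            for key, p in ps.entries.items():
                assert p == pytest.approx(oracle[key], rel=1e-12)

    def test_order_invariance_multiplicative(self, random_dataset):
        ds = random_dataset(3)
        rev = TheoryDataset(ds.name, list(reversed(ds.items)))
        a = quantify_theory(ds).posteriors
        b = quantify_theory(rev).posteriors
        assert np.allclose(a, b, rtol=1e-12)

    def test_additive_mechanism_is_order_dependent_but_defined(self):
        cfg = QuantConfig(mechanism="additive")
        ds = TheoryDataset(
            "T",
            [
                EvidenceItem("m1", "accepted", "high"),
                EvidenceItem("m2", "coherent_untestable", "low"),
            ],
        )
        ps = quantify_theory(ds, cfg)
        # fold by hand: ((0.04 + 0.10)/0.9 + 0.01)/0.99
        expected = ((0.04 + 0.10) / 0.9 + 0.01) / 0.99
        assert np.allclose(ps.posteriors, expected, rtol=1e-12)

    @given(st.floats(min_value=0.001, max_value=0.2))
    def test_prior_linearity(self, prior):
        ds = TheoryDataset(
            "T",
            [
                EvidenceItem("m1", "coherent_testable", "medium"),
                EvidenceItem("m2", "accepted", "low"),
            ],
        )
        base = quantify_theory(ds, QuantConfig(prior=0.04)).posteriors
        scaled = quantify_theory(ds, QuantConfig(prior=prior)).posteriors
        assert np.allclose(scaled, base * (prior / 0.04), rtol=1e-12)

    def test_appending_evidence_strictly_increases_posteriors(self, random_dataset):
        ds = random_dataset(7)
        base = quantify_theory(ds).posteriors
        for a_score, r_score in [
            ("coherent_untestable", "low"),
            ("coherent_testable", "medium"),
            ("accepted", "high"),
        ]:
            bigger = TheoryDataset(
                ds.name, ds.items + [EvidenceItem("extra", a_score, r_score)]
            )
            assert (quantify_theory(bigger).posteriors > base).all()

    def test_raising_either_score_never_decreases_posteriors(self):
        base_items = [EvidenceItem("m1", "coherent_untestable", "low")]
        base = quantify_theory(TheoryDataset("T", base_items)).posteriors
        for a_score, r_score in [
            ("coherent_testable", "low"),
            ("accepted", "low"),
            ("coherent_untestable", "medium"),
            ("coherent_untestable", "high"),
        ]:
            up = quantify_theory(
                TheoryDataset("T", [EvidenceItem("m1", a_score, r_score)])
            ).posteriors
            assert (up >= base).all()


class TestBounds:
    def test_demo_theories_stay_within_bounds(self, demo):
        for ds in demo.values():
            ps = quantify_theory(ds)
            assert check_bounds(ps) == []
            assert (ps.posteriors > 0).all() and (ps.posteriors < 1).all()
            assert (ps.posteriors >= ps.config.resolved_prior).all()

    def test_runaway_dataset_violates_upper_bound(self):
        # 0.04 * (1.1/0.9)^n crosses 1 after 17 steps
        items = [EvidenceItem(f"m{i}", "accepted", "high") for i in range(60)]
        ps = quantify_theory(TheoryDataset("T", items))
        violations = check_bounds(ps)
        assert violations
        assert min(v.step_index for v in violations) == 16  # 17th item, 0-based

    def test_bound_policy_error_aborts_with_diagnostic(self):
        items = [EvidenceItem(f"m{i}", "accepted", "high") for i in range(60)]
        with pytest.raises(BoundError, match="step 16"):
            quantify_theory(TheoryDataset("T", items), QuantConfig(bound_policy="error"))

    def test_bound_policy_ignore_records_nothing(self):
        items = [EvidenceItem(f"m{i}", "accepted", "high") for i in range(60)]
        ps = quantify_theory(TheoryDataset("T", items), QuantConfig(bound_policy="ignore"))
        assert check_bounds(ps) == []


class TestConfig:
    def test_default_prior_is_uniform_over_field(self):
        assert QuantConfig().resolved_prior == pytest.approx(1 / 25)
        assert QuantConfig(theory_count=10).resolved_prior == pytest.approx(0.1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"theory_count": 0},
            {"prior": 0.0},
            {"prior": 1.5},
            {"mechanism": "divide"},
            {"bound_policy": "explode"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            QuantConfig(**kwargs)

    def test_config_hash_distinguishes_mechanisms(self):
        assert QuantConfig().config_hash() != QuantConfig(mechanism="additive").config_hash()
        assert QuantConfig().config_hash() == QuantConfig(prior=0.04).config_hash()

    def test_posterior_set_json_round_trip(self, demo):
        from qbe.quantify import PosteriorSet

        ps = quantify_theory(demo["B"])
        clone = PosteriorSet.from_dict(ps.to_dict())
        assert clone.theory_name == ps.theory_name
        assert clone.entries == ps.entries
        assert clone.config.config_hash() == ps.config.config_hash()
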