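"""Chemotaxis index, inclusion rules, ANOVA and Dunnett comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asetrace import (
    PlateRecord,
    apply_inclusion,
    chemotaxis_index,
    simulate_chemotaxis_plate,
    summarize_conditions,
    two_way_anova_dunnett,
)


def _plate(pid, A, C, genotype="wildtype", salt="NH4Cl"):
    return PlateRecord(plate_id=pid, genotype=genotype, salt=salt, A=A, C=C, n_loaded=200)


class TestIndex:
    @pytest.mark.parametrize("A,C,expected", [(30, 10, 0.5), (7, 7, 0.0), (0, 10, -1.0)])
    def test_formula(self, A, C, expected):
        assert chemotaxis_index(A, C) == pytest.approx(expected)

    def test_undefined_for_empty_plate(self):
        with pytest.raises(ValueError, match="undefined"):
            chemotaxis_index(0, 0)

    @given(A=st.integers(0, 200), C=st.integers(0, 200))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry_and_bounds(self, A, C):
        if A + C == 0:
            return
        idx = chemotaxis_index(A, C)
        assert -1.0 <= idx <= 1.0
        assert idx == pytest.approx(-chemotaxis_index(C, A))


class TestInclusion:
    def test_boundary_at_ten_scored_worms(self):
        plates = [_plate("p9", 5, 4), _plate("p10", 5, 5), _plate("p11", 11, 0)]
        included, excluded = apply_inclusion(plates)
        assert [p.plate_id for p in included] == ["p10", "p11"]
        assert excluded[0][0].plate_id == "p9" and excluded[0][1] == "participation"

    def test_manual_exclusion_logged(self):
        plates = [_plate("good", 30, 10), _plate("scoring-error", 5, 30)]
        included, excluded = apply_inclusion(plates, manual_exclusions=["scoring-error"])
        assert [p.plate_id for p in included] == ["good"]
        assert excluded == [(plates[1], "manual")]

    def test_constructed_twenty_plate_fixture(self):
        # exactly the plates with fewer than 10 scored worms drop out
        plates = [_plate(f"p{i}", A=i, C=4) for i in range(20)]  # scored = i + 4
        included, excluded = apply_inclusion(plates)
        assert {p.plate_id for p in excluded[0:0]} == set()
        assert [p.plate_id for p in included] == [f"p{i}" for i in range(6, 20)]
        assert all(reason == "participation" for _, reason in excluded)
        assert len(excluded) == 6


class TestSummaries:
    def test_hand_computed_mean_and_sem(self):
        plates = [_plate("a", 30, 20), _plate("b", 35, 15)]  # indices 0.2, 0.4
        out = summarize_conditions(plates)
        assert out.loc[0, "mean"] == pytest.approx(0.3)
        assert out.loc[0, "sem"] == pytest.approx(0.1)
        assert out.loc[0, "n"] == 2

    def test_single_plate_sem_flagged_nan(self):
        out = summarize_conditions([_plate("a", 30, 20)])
        assert np.isnan(out.loc[0, "sem"])

    def test_order_invariant(self):
        plates = [_plate(f"p{i}", 20 + i, 20) for i in range(6)]
        a = summarize_conditions(plates)
        b = summarize_conditions(plates[::-1])
        assert a.equals(b)


def _balanced_design(seed, shift_cell=None, n_per_cell=8):
    rng = np.random.default_rng(seed)
    plates = []
    for g in ("wildtype", "mutA", "mutB"):
        for s in ("NH4Cl", "NaCl"):
            p_att = 0.65
            if shift_cell == (g, s):
                p_att = 0.35
            for i in range(n_per_cell):
                plates.append(
                    simulate_chemotaxis_plate(
                        200, 0.4, p_att, seed=int(rng.integers(2**31)),
                        plate_id=f"{g}-{s}-{i}", condition=g, salt=s,
                    )
                )
    return plates


class TestAnovaDunnett:
    def test_all_equal_indices_give_zero_f_and_unit_p(self):
        plates = [
            _plate(f"{g}-{s}-{i}", 30, 10, genotype=g, salt=s)
            for g in ("wildtype", "mut")
            for s in ("NH4Cl", "NaCl")
            for i in range(4)
        ]
        res = two_way_anova_dunnett(plates, seed=0)
        f_vals = res.anova["F"].dropna()
        np.testing.assert_allclose(f_vals, 0.0, atol=1e-10)
        assert (res.comparisons["p_adj"] == 1.0).all()

    def test_shifted_cell_detected_others_not(self):
        plates = _balanced_design(3, shift_cell=("mutB", "NH4Cl"), n_per_cell=12)
        res = two_way_anova_dunnett(plates, reference_level="wildtype", seed=1)
        c = res.comparisons.set_index(["salt", "genotype"])
        assert c.loc[("NH4Cl", "mutB"), "significant"]
        assert not c.loc[("NaCl", "mutB"), "significant"]

    def test_adjusted_pvalues_match_scipy_dunnett_oracle(self):
        """Within one salt the adjustment agrees with an independent
        implementation pooling over the same groups."""
        from scipy.stats import dunnett as scipy_dunnett

        from asetrace.chemo import _dunnett_corr, dunnett_adjusted_pvalues

        rng = np.random.default_rng(42)
        control = rng.normal(0.3, 0.1, 12)
        arm1 = rng.normal(0.34, 0.1, 12)
        arm2 = rng.normal(0.2, 0.1, 12)
        ref = scipy_dunnett(arm1, arm2, control=control)
        # rebuild the same t statistics and adjust with our MC routine
        pooled = np.concatenate([control, arm1, arm2])
        groups = [control, arm1, arm2]
        df_resid = sum(len(g) - 1 for g in groups)
        mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_resid
        t = np.array(
            [
                (g.mean() - control.mean()) / np.sqrt(mse * (1 / len(g) + 1 / 12))
                for g in (arm1, arm2)
            ]
        )
        corr = _dunnett_corr(np.array([12.0, 12.0]), 12.0)
        ours = dunnett_adjusted_pvalues(t, corr, df_resid, n_sim=200_000, seed=9)
        np.testing.assert_allclose(ours, ref.pvalue, atol=0.01)

    def test_empty_cell_named_in_error(self):
        plates = _balanced_design(5)
        plates = [p for p in plates if not (p.genotype == "mutA" and p.salt == "NaCl")]
        with pytest.raises(ValueError, match="mutA.*NaCl"):
            two_way_anova_dunnett(plates, seed=0)

    def test_missing_reference_level_rejected(self):
        plates = _balanced_design(6)
        with pytest.raises(ValueError, match="reference level"):
            two_way_anova_dunnett(plates, reference_level="PS312", seed=0)

    def test_inclusion_filter_applied_before_analysis(self):
        plates = _balanced_design(7)
        plates.append(_plate("tiny", 3, 2, genotype="mutA", salt="NH4Cl"))
        res = two_way_anova_dunnett(plates, seed=0)
        assert any(p.plate_id == "tiny" and r == "participation" for p, r in res.excluded)


class TestEstimatorConsistency:
    def test_mean_index_tracks_analytic_expectation(self):
        from asetrace.calibration import chemotaxis_estimator

        out = chemotaxis_estimator(0.75, n_plates=2000, seed=11)
        assert abs(out["mean_index"] - out["expected"]) < 3 * out["mc_se"]
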