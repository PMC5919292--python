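"""Profile fitting, ROC calibration, sequential gating and HLI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import hlikit
from hlikit.classifier import (
    ReferenceProfile,
    apply_gates,
    calibrate_albumin_cutoff,
    compute_hli,
    exclude_gfp,
    fit_reference_profile,
    rank_feature_importance,
)
from hlikit.morphometry import MORPHOLOGY_FEATURES, CellTable
from tests.conftest import table


def simple_profile(cutoff=500.0):
    gates = {
        "nuclear_area": (50.0, 300.0),
        "nuclear_width": (4.0, 20.0),
        "cell_area": (700.0, 2600.0),
        "cell_width": (25.0, 60.0),
        "symmetry": (0.6, 1.0),
    }
    return ReferenceProfile(morphology_gates=gates, albumin_cutoff=cutoff)


def cell_row(**kw):
    base = dict(cell_id=1, nuclear_area=110.0, nuclear_width=11.0, cell_area=1600.0,
                cell_width=42.0, symmetry=0.85, mfi_albumin=2000.0)
    base.update(kw)
    return base


class TestROC:
    def test_perfect_separation(self):
        roc = calibrate_albumin_cutoff([2000.0] * 5, [100.0] * 5)
        assert roc.auc == 1.0
        assert 100.0 < roc.optimal_cutoff <= 2000.0

    def test_identical_distributions_auc_half(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        assert calibrate_albumin_cutoff(vals, vals).auc == pytest.approx(0.5)

    def test_binormal_closed_form(self):
        # AUC of two Gaussians is Phi(dmu / sqrt(s1^2 + s2^2))
        rng = np.random.default_rng(0)
        for (m1, s1), (m2, s2), tol in [
            ((2000, 300), (120, 60), 0.005),   # near-total separation
            ((1.0, 1.0), (0.0, 1.0), 0.04),    # heavy overlap, 3 SE of AUC
        ]:
            pos, neg = rng.normal(m1, s1, 500), rng.normal(m2, s2, 500)
            expected = stats.norm.cdf((m1 - m2) / np.hypot(s1, s2))
            assert calibrate_albumin_cutoff(pos, neg).auc == pytest.approx(expected, abs=tol)

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_auc_equals_scaled_mann_whitney(self, data):
        # brute-force U over all (pos, neg) pairs, ties counted half
        pos = data.draw(st.lists(st.integers(0, 10), min_size=1, max_size=30))
        neg = data.draw(st.lists(st.integers(0, 10), min_size=1, max_size=30))
        u = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
        roc = calibrate_albumin_cutoff(np.array(pos, float), np.array(neg, float))
        assert roc.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        pos, neg = rng.normal(2, 1, 200), rng.normal(0, 1, 300)
        expected = roc_auc_score(np.r_[np.ones(200), np.zeros(300)], np.r_[pos, neg])
        assert calibrate_albumin_cutoff(pos, neg).auc == pytest.approx(expected, abs=1e-12)

    def test_ties_break_to_higher_threshold(self):
        roc = calibrate_albumin_cutoff([10.0, 12.0], [1.0, 2.0])
        assert roc.optimal_cutoff == 10.0  # smallest positive, not 3..9

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            calibrate_albumin_cutoff([], [1.0])


class TestProfileFitting:
    def test_gates_cover_independent_adult_draw(self, reference_profile):
        ind = table("adult_hep", 2000, np.random.default_rng(777))
        ok = np.ones(len(ind), bool)
        for feat in MORPHOLOGY_FEATURES:
            lo, hi = reference_profile.morphology_gates[feat]
            v = ind.df[feat].to_numpy()
            assert ((v >= lo) & (v <= hi)).mean() > 0.98, feat
            ok &= (v >= lo) & (v <= hi)
        assert ok.mean() >= 0.95  # joint coverage incl. polyploid nuclei

    def test_polyploid_nuclei_pass_the_nuclear_gate(self, reference_profile):
        ind = table("adult_hep", 2000, np.random.default_rng(5))
        poly = ind.df.loc[ind.df.is_polyploid_true]
        lo, hi = reference_profile.morphology_gates["nuclear_area"]
        assert ((poly.nuclear_area >= lo) & (poly.nuclear_area <= hi)).mean() > 0.98

    def test_too_few_cells_errors(self):
        rng = np.random.default_rng(0)
        small = table("adult_hep", 20, rng)
        with pytest.raises(ValueError, match="50"):
            fit_reference_profile(small, table("fibroblast", 500, rng))

    def test_zero_variance_feature_degenerate_gate(self):
        rng = np.random.default_rng(2)
        ref = table("adult_hep", 200, rng)
        ref.df["symmetry"] = 0.85
        prof = fit_reference_profile(ref, table("fibroblast", 200, rng))
        assert prof.morphology_gates["symmetry"] == (0.85, 0.85)
        assert "symmetry" in prof.calibration_meta["degenerate_features"]

    def test_identical_negatives_warns_auc_half(self):
        rng = np.random.default_rng(3)
        ref = table("adult_hep", 200, rng)
        with pytest.warns(UserWarning, match="AUC"):
            prof = fit_reference_profile(ref, ref)
        assert prof.calibration_meta["albumin_auc"] == pytest.approx(0.5, abs=0.01)
        assert "warning" in prof.calibration_meta


class TestGating:
    def test_boundary_values_pass(self):
        prof = simple_profile()
        df = pd.DataFrame([cell_row(nuclear_area=50.0, cell_area=2600.0, mfi_albumin=500.0)])
        gated = apply_gates(CellTable(df), prof)
        assert gated.df.assigned_class.iloc[0] == "hepatocyte_positive"

    def test_fibroblast_fails_at_cell_stage_albumin_unevaluated(self):
        # elongated cell with adult-level albumin: attrition at stage 2,
        # albumin gate never evaluated
        prof = simple_profile()
        df = pd.DataFrame([cell_row(symmetry=0.25, cell_width=15.0)])
        gated = apply_gates(CellTable(df), prof)
        assert bool(gated.df.gate_nuclear.iloc[0]) is True
        assert bool(gated.df.gate_cell.iloc[0]) is False
        assert gated.df.gate_albumin.isna().iloc[0]
        res = compute_hli(gated)
        assert res.per_gate_attrition == {"nuclear": 0, "cell": 1, "albumin": 0}

    def test_adult_preset_means_pass_all_gates(self, reference_profile):
        df = pd.DataFrame([cell_row(mfi_albumin=2000.0)])
        gated = apply_gates(CellTable(df), reference_profile)
        assert gated.df.assigned_class.iloc[0] == "hepatocyte_positive"

    def test_missing_feature_named_in_error(self):
        df = pd.DataFrame([cell_row()]).drop(columns=["symmetry"])
        with pytest.raises(KeyError, match="symmetry"):
            apply_gates(CellTable(df), simple_profile())

    def test_all_stages_mode_records_every_gate(self):
        prof = simple_profile()
        df = pd.DataFrame([cell_row(nuclear_area=400.0)])  # fails stage 1
        gated = apply_gates(CellTable(df), prof, short_circuit=False)
        assert bool(gated.df.gate_albumin.iloc[0]) is True  # still evaluated


class TestHLI:
    @pytest.mark.parametrize("n_pos,expected", [(100, 1.0), (0, 0.0), (92, 0.23)])
    def test_hli_is_positive_fraction(self, n_pos, expected):
        n = 100 if n_pos != 92 else 400
        rows = [cell_row(cell_id=i + 1, mfi_albumin=2000.0 if i < n_pos else 100.0)
                for i in range(n)]
        gated = apply_gates(CellTable(pd.DataFrame(rows)), simple_profile())
        res = compute_hli(gated)
        assert res.hli == pytest.approx(expected)
        assert sum(res.per_gate_attrition.values()) == res.n_total - res.n_positive

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compute_hli(CellTable(pd.DataFrame(columns=["assigned_class"])))

    def test_order_invariance(self, reference_profile):
        tab = table("ihep", 300, np.random.default_rng(9))
        gated = apply_gates(tab, reference_profile)
        shuffled = CellTable(gated.df.sample(frac=1, random_state=0).reset_index(drop=True))
        assert compute_hli(gated).hli == compute_hli(shuffled).hli

    def test_self_consistency_same_preset_scores_high(self, reference_profile):
        ind = table("adult_hep", 500, np.random.default_rng(55))
        assert compute_hli(apply_gates(ind, reference_profile)).hli >= 0.9

    def test_albumin_below_cutoff_drives_hli_to_zero(self, reference_profile):
        ind = table("adult_hep", 300, np.random.default_rng(56))
        ind.df["mfi_albumin"] = reference_profile.albumin_cutoff - 1.0
        assert compute_hli(apply_gates(ind, reference_profile)).hli == 0.0


class TestGFPExclusion:
    def mixture(self, n, rng):
        adult = hlikit.make_population_spec("adult_hep")
        huvec = hlikit.make_population_spec("huvec_gfp")
        spec = hlikit.make_population_spec(
            "mixture",
            {"mixture_components": [(adult, 0.5), (huvec, 0.5)], "n_cells": n},
        )
        return hlikit.sample_feature_table(spec, rng=rng)

    def test_cocultured_huvecs_removed_at_mixing_fraction(self):
        tab = self.mixture(400, np.random.default_rng(4))
        out = exclude_gfp(tab, gfp_channel_cutoff=500.0)
        removed = out.provenance["n_gfp_excluded"]
        lo, hi = stats.binom.ppf([0.005, 0.995], 400, 0.5)
        assert lo <= removed <= hi
        assert set(out.df.true_class) == {"adult_hep"}

    def test_cutoff_above_max_keeps_everything(self):
        tab = self.mixture(100, np.random.default_rng(5))
        out = exclude_gfp(tab, gfp_channel_cutoff=1e9)
        assert len(out) == 100 and out.provenance["n_gfp_excluded"] == 0

    def test_all_positive_empties_table_and_hli_errors(self):
        tab = table("huvec_gfp", 60, np.random.default_rng(6))
        out = exclude_gfp(tab, gfp_channel_cutoff=1.0)
        assert len(out) == 0
        with pytest.raises(ValueError):
            compute_hli(out)

    def test_missing_gfp_column_errors(self):
        df = pd.DataFrame([cell_row()])
        with pytest.raises(KeyError, match="mfi_gfp"):
            exclude_gfp(CellTable(df), 500.0)


@pytest.fixture(scope="module")
def adult_vs_fibroblast():
    rng = np.random.default_rng(12)
    a = table("adult_hep", 300, rng).df
    f = table("fibroblast", 300, rng).df
    return CellTable(pd.concat([a, f], ignore_index=True).assign(
        cell_id=lambda d: np.arange(len(d)) + 1))


class TestFeatureImportance:
    def test_symmetry_outranks_uninformative_features(self, adult_vs_fibroblast):
        # generator separates these classes only on symmetry (among the
        # morphology features), so symmetry must rank first
        ranking = rank_feature_importance(adult_vs_fibroblast)
        names = [f for f, _ in ranking]
        assert names[0] == "symmetry"
        assert names.index("symmetry") < names.index("nuclear_area")

    def test_shuffled_labels_kill_importance(self, adult_vs_fibroblast):
        tab = adult_vs_fibroblast.copy()
        rng = np.random.default_rng(0)
        tab.df["true_class"] = rng.permutation(tab.df["true_class"].to_numpy())
        ranking = rank_feature_importance(tab)
        # held-out accuracy SE at n=300 is sqrt(0.25/300) ~ 0.029; 3 SE bound
        assert all(abs(v) < 3 * np.sqrt(0.25 / 300) for _, v in ranking)

    def test_duplicate_column_splits_importance_preserving_rest(self, adult_vs_fibroblast):
        tab = adult_vs_fibroblast.copy()
        tab.df["symmetry_dup"] = tab.df["symmetry"]
        ranking = rank_feature_importance(
            tab, features=MORPHOLOGY_FEATURES + ["symmetry_dup"]
        )
        scores = dict(ranking)
        top2 = [f for f, _ in ranking[:2]]
        assert set(top2) == {"symmetry", "symmetry_dup"}
        assert scores["cell_area"] < min(scores["symmetry"], scores["symmetry_dup"])

    def test_single_class_errors(self):
        tab = table("adult_hep", 120, np.random.default_rng(7))
        with pytest.raises(ValueError, match="two classes"):
            rank_feature_importance(tab)
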