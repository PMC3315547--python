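"""Per-platform differential-calling rules and their invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from omicord import differential as dd
from omicord.design import DEFAULT_DESIGN
from omicord.io import sample_column, time_column


def grubbs_critical_oracle(n, alpha=0.05):
    """Independent re-derivation of the two-sided Grubbs critical value."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


class TestQuantileNormalize:
    def test_rank_mean_by_hand(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = dd.quantile_normalize(m)
        expected = [2.5, 3.5, 4.5]
        assert list(out["a"]) == expected
        assert list(out["b"]) == expected

    def test_identical_columns_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(dd.quantile_normalize(m), m)

    def test_single_row_becomes_row_mean(self):
        m = pd.DataFrame({"a": [2.0], "b": [6.0]})
        out = dd.quantile_normalize(m)
        assert (out.to_numpy() == 4.0).all()

    def test_nan_names_offending_cell(self):
        m = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="g2.*'a'"):
            dd.quantile_normalize(m)


def _matrix_from_logratios(logratios: dict, design, rng, noise=1e-6):
    """Intensity matrix with given per-entity, per-time log10 ratios."""
    cols = {}
    for t in design.rna_time_points:
        for r in range(1, design.replicates + 1):
            cols[sample_column(t, r)] = None
    rows = {}
    for sym, prof in logratios.items():
        row = {}
        for t in design.rna_time_points:
            lr = prof.get(t, 0.0)
            for r in range(1, design.replicates + 1):
                row[sample_column(t, r)] = 10 ** (3.0 + lr + rng.normal(0, noise))
        rows[sym] = row
    return pd.DataFrame.from_dict(rows, orient="index")


class TestRnaCalling:
    def test_constructed_twofold_induction_called(self, design):
        rng = np.random.default_rng(0)
        logr = {"hit": {4.0: np.log10(2.0)}}
        logr.update({f"flat{i}": {} for i in range(20)})
        m = _matrix_from_logratios(logr, design, rng)
        res = dd.call_differential_rna(m, design, normalize=False)
        assert bool(res.loc["hit", "significant"])
        assert res.loc["hit", time_column("ratio", 4.0)] == pytest.approx(
            np.log10(2.0), abs=1e-3
        )
        assert not res.loc[[f"flat{i}" for i in range(20)], "significant"].any()

    def test_missing_control_rejected(self, design):
        rng = np.random.default_rng(1)
        m = _matrix_from_logratios({"g": {}}, design, rng)
        m = m.drop(columns=[sample_column(0.0, r) for r in range(1, 4)])
        with pytest.raises(ValueError, match="control"):
            dd.call_differential_rna(m, design)

    def test_significant_implies_fold_change(self, design):
        rng = np.random.default_rng(2)
        logr = {f"g{i}": {4.0: rng.normal(0, 0.25)} for i in range(60)}
        m = _matrix_from_logratios(logr, design, rng, noise=0.05)
        res = dd.call_differential_rna(m, design)
        ratio_cols = [c for c in res.columns if c.startswith("ratio_")]
        called = res[res["significant"]]
        assert (called[ratio_cols].abs().max(axis=1) >= np.log10(1.5) - 1e-12).all()


class TestGrubbsAggregation:
    def test_worked_example_removes_outlier(self):
        logs = np.array([0.10, 0.12, 0.09, 0.11, 0.50])
        g = np.abs(logs - logs.mean()).max() / logs.std(ddof=1)
        assert g == pytest.approx(1.79, abs=0.01)
        assert g > grubbs_critical_oracle(5)
        keep = dd.grubbs_filter(logs)
        assert list(keep) == [True, True, True, True, False]
        pep = pd.DataFrame({
            "peptide_id": [f"p{i}" for i in range(5)],
            "protein_symbol": "P",
            "time_hr": 4.0,
            "ratio": 10 ** logs,
        })
        agg = dd.aggregate_protein_ratios(pep)
        assert agg.loc["P", time_column("ratio", 4.0)] == pytest.approx(0.105)
        assert agg.loc["P", time_column("npep", 4.0)] == 4

    def test_two_peptides_skip_test(self):
        pep = pd.DataFrame({
            "peptide_id": ["p1", "p2"], "protein_symbol": "P",
            "time_hr": 1.0, "ratio": [1.6, 1.7],
        })
        agg = dd.aggregate_protein_ratios(pep)
        assert agg.loc["P", time_column("npep", 1.0)] == 2
        assert agg.loc["P", time_column("ratio", 1.0)] == pytest.approx(
            np.log10([1.6, 1.7]).mean()
        )

    def test_identical_ratios_zero_sd_no_removal(self):
        pep = pd.DataFrame({
            "peptide_id": [f"p{i}" for i in range(4)], "protein_symbol": "P",
            "time_hr": 8.0, "ratio": [2.0] * 4,
        })
        agg = dd.aggregate_protein_ratios(pep)
        assert agg.loc["P", time_column("npep", 8.0)] == 4
        assert agg.loc["P", time_column("ratio", 8.0)] == pytest.approx(np.log10(2.0))

    def test_nonpositive_ratio_rejected(self):
        pep = pd.DataFrame({
            "peptide_id": ["p1"], "protein_symbol": "P", "time_hr": 1.0,
            "ratio": [-0.5],
        })
        with pytest.raises(ValueError, match="non-positive"):
            dd.aggregate_protein_ratios(pep)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_aggregation_invariant_to_peptide_order(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 10))
        ratios = 10 ** rng.normal(0, 0.2, n)
        pep = pd.DataFrame({
            "peptide_id": [f"p{i}" for i in range(n)], "protein_symbol": "P",
            "time_hr": 4.0, "ratio": ratios,
        })
        shuffled = pep.sample(frac=1.0, random_state=seed).reset_index(drop=True)
        a = dd.aggregate_protein_ratios(pep)
        b = dd.aggregate_protein_ratios(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_large_outlier_removed_at_moderate_peptide_count(self):
        # power statement: with >= 8 peptides a 10-SD outlier is nearly
        # always removed (small n saturates the Grubbs statistic)
        rng = np.random.default_rng(3)
        hits = 0
        trials = 300
        for _ in range(trials):
            v = rng.normal(0, 0.1, 8)
            j = int(rng.integers(8))
            v[j] += np.sign(rng.random() - 0.5) * 1.0
            hits += not dd.grubbs_filter(v)[j]
        assert hits / trials >= 0.95


class TestMsCalling:
    def _agg(self, ratio, npep):
        return pd.DataFrame(
            {time_column("ratio", 4.0): [np.log10(ratio)],
             time_column("npep", 4.0): [npep]},
            index=pd.Index(["P"], name="symbol"),
        )

    def test_fold_with_two_peptides_is_significant(self):
        res = dd.call_differential_ms(self._agg(1.65, 2))
        assert bool(res.loc["P", "significant"])

    def test_single_peptide_gated_out(self):
        res = dd.call_differential_ms(self._agg(3.0, 1))
        assert not bool(res.loc["P", "significant"])

    def test_subthreshold_ratio_not_significant(self):
        res = dd.call_differential_ms(self._agg(1.4, 5))
        assert not bool(res.loc["P", "significant"])

    @settings(max_examples=30, deadline=None)
    @given(st.floats(1.05, 10.0), st.integers(2, 6))
    def test_fold_threshold_symmetry(self, r, npep):
        up = dd.call_differential_ms(self._agg(r, npep))
        down = dd.call_differential_ms(self._agg(1.0 / r, npep))
        assert bool(up.loc["P", "significant"]) == bool(down.loc["P", "significant"])


def _western_frame(sym, treated, control):
    rows = [{"symbol": sym, "time_hr": 0.0, "channel": "control", "rep": i + 1,
             "intensity": c} for i, c in enumerate(control)]
    rows += [{"symbol": sym, "time_hr": 4.0, "channel": "treated", "rep": i + 1,
              "intensity": t} for i, t in enumerate(treated)]
    return pd.DataFrame(rows)


class TestWesternCalling:
    def test_uniform_ratio_called(self):
        res = dd.call_differential_western(_western_frame("W", [3, 3, 3], [2, 2, 2]))
        assert res.loc["W", time_column("ratio", 4.0)] == pytest.approx(np.log10(1.5))
        assert bool(res.loc["W", "significant"])

    def test_identity_not_called(self):
        res = dd.call_differential_western(_western_frame("W", [2, 2, 2], [2, 2, 2]))
        assert res.loc["W", time_column("ratio", 4.0)] == pytest.approx(0.0)
        assert not bool(res.loc["W", "significant"])

    def test_median_of_nine_pairwise_ratios(self):
        # treated {4,2,2} vs control {2,2,2}: ratios {2,2,2,1,1,1,1,1,1},
        # median 1 -> not significant despite one doubled replicate
        res = dd.call_differential_western(_western_frame("W", [4, 2, 2], [2, 2, 2]))
        assert res.loc["W", time_column("ratio", 4.0)] == pytest.approx(0.0)
        assert not bool(res.loc["W", "significant"])

    def test_fewer_than_three_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            dd.call_differential_western(_western_frame("W", [3, 3], [2, 2, 2]))
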