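from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from sinetrace.enrichment import (
    assign_windows,
    bonferroni,
    count_motif,
    enrichment_table,
    permutation_test,
)
from sinetrace.stats import mann_whitney_u


def toy_windows(n, chrom="c1", size=1000):
    return pd.DataFrame(
        {
            "window_id": [f"w{i}" for i in range(n)],
            "chrom": chrom,
            "start": [i * size for i in range(n)],
            "end": [(i + 1) * size for i in range(n)],
        }
    )


class TestAssignWindows:
    def test_containing_window_arithmetic(self):
        """217 assigned positions with 14 double-occupancy windows give 203
        containing windows; positions in gaps stay unassigned."""
        win = toy_windows(300)
        rng = np.random.default_rng(0)
        singles = rng.choice(300, size=203, replace=False)
        positions = [int(w) * 1000 + 5 for w in singles]
        positions += [int(w) * 1000 + 600 for w in singles[:14]]  # doubles
        pos = pd.DataFrame({"chrom": "c1", "position": positions})
        pos = pd.concat(
            [pos, pd.DataFrame({"chrom": ["c9"] * 9, "position": [5] * 9})],
            ignore_index=True,
        )
        assigned, info = assign_windows(pos, win)
        assert info["n_positions"] == 226
        assert info["n_unassigned"] == 9
        assert info["n_containing"] == 203
        assert info["n_multi"] == 14
        assert assigned["insert_count"].sum() == 217

    def test_no_positions(self):
        assigned, info = assign_windows(pd.DataFrame(columns=["chrom", "position"]), toy_windows(5))
        assert info["n_containing"] == 0 and (assigned["insert_count"] == 0).all()


class TestPermutationTest:
    def test_extreme_observation_gets_smoothed_minimum(self):
        values = np.concatenate([np.zeros(20), np.ones(5) * 100])
        labels = np.array([False] * 20 + [True] * 5)
        res = permutation_test(values, labels, n_perm=999, rng=0, alternative="greater")
        assert res["p"] == pytest.approx(1 / 1000)

    def test_matches_exhaustive_enumeration_on_toy_table(self):
        values = np.array([1.0, 5.0, 2.0, 8.0, 3.0, 9.0, 4.0, 7.0])
        labels = np.zeros(8, bool)
        labels[[1, 3]] = True
        res = permutation_test(values, labels, n_perm=60_000, rng=1)
        ranks = rankdata(values)
        mu = 2 * 6 / 2
        u_obs = ranks[labels].sum() - 3
        null = [
            abs(sum(ranks[list(c)]) - 3 - mu) for c in combinations(range(8), 2)
        ]
        exact = np.mean([u >= abs(u_obs - mu) - 1e-9 for u in null])
        assert res["p"] == pytest.approx(exact, abs=0.01)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(10)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            vals = rng.normal(size=150)
            labels = np.zeros(150, bool)
            labels[rng.choice(150, 30, replace=False)] = True
            p = permutation_test(vals, labels, n_perm=499, rng=rng)["p"]
            rejections += p <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        vals = rng.random(60) + 0.5
        labels = np.zeros(60, bool)
        labels[:12] = True
        p1 = permutation_test(vals, labels, n_perm=999, rng=5)["p"]
        p2 = permutation_test(np.log(vals), labels, n_perm=999, rng=5)["p"]
        assert p1 == p2

    def test_converges_to_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.2, size=200)
        y = rng.normal(size=200)
        vals = np.concatenate([x, y])
        labels = np.array([True] * 200 + [False] * 200)
        res = permutation_test(vals, labels, n_perm=20_000, rng=4)
        asym = mann_whitney_u(x, y)
        assert res["p"] == pytest.approx(asym.p, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([1.0, 2.0], [True, True])


class TestBonferroni:
    def test_adjustment_and_cap(self):
        assert bonferroni([0.004], m=9) == [pytest.approx(0.036)]
        assert bonferroni([0.5], m=9) == [1.0]
        assert bonferroni([0.2, 0.01]) == [pytest.approx(0.4), pytest.approx(0.02)]

    def test_never_decreases(self):
        ps = [0.001, 0.2, 0.9]
        adj = bonferroni(ps, m=5)
        assert all(a >= p for a, p in zip(adj, ps))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5], m=2)


class TestMotif:
    def test_hand_matched_occurrence(self):
        assert count_motif("CCACCATAACCAC", both_strands=False) == 1

    def test_poly_a_has_none(self):
        assert count_motif("A" * 100) == 0

    def test_tandem_overlapping_scan(self):
        assert count_motif("CCACCATAACCACCCACCATAACCAC", both_strands=False) == 2

    def test_both_strand_counting(self):
        fwd = "CCACCATAACCAC"
        comp = str.maketrans("ACGT", "TGCA")
        rc = fwd.translate(comp)[::-1]
        assert count_motif(rc, both_strands=False) == 0
        assert count_motif(rc, both_strands=True) == 1


class TestEnrichmentTable:
    def _table(self, rng, planted=False):
        win = toy_windows(120)
        win["sine"] = rng.poisson(20, 120).astype(float)
        win["gc"] = rng.normal(0.41, 0.02, 120)
        labels = np.zeros(120, bool)
        labels[rng.choice(120, 25, replace=False)] = True
        if planted:
            win.loc[labels, "sine"] *= 2
        win["insert_count"] = labels.astype(int)
        return win

    def test_null_features_survive_bonferroni(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            win = self._table(rng)
            out = enrichment_table(win, ["sine", "gc"], n_perm=499, rng=rng)
            hits += (out["p_bonferroni"] < 0.05).any()
        assert hits <= 3

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(1)
        win = self._table(rng, planted=True)
        out = enrichment_table(win, ["sine", "gc"], n_perm=999, rng=rng)
        row = out.set_index("feature").loc["sine"]
        assert row["p_bonferroni"] < 0.05
        assert row["abs_median_diff"] == pytest.approx(
            abs(row["median_containing"] - row["median_free"])
        )

    def test_same_seed_same_pvalues(self):
        rng = np.random.default_rng(2)
        win = self._table(rng)
        out1 = enrichment_table(win, ["sine"], n_perm=500, rng=7)
        out2 = enrichment_table(win, ["sine"], n_perm=500, rng=7)
        assert out1.equals(out2)
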