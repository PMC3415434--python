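"""Genomic-window enrichment testing for insertion sites.

Inserts are assigned to non-overlapping genome-tiling windows; for each
genomic feature the insert-containing and insert-free windows are compared
with the Mann-Whitney-Wilcoxon U statistic, the p-value is calibrated by
label permutation (class sizes preserved, add-one smoothing), and a
Bonferroni correction accounts for the number of features tested.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .stats import mann_whitney_u

__all__ = [
    "INSTABILITY_13MER",
    "assign_windows",
    "permutation_test",
    "bonferroni",
    "count_motif",
    "enrichment_table",
]

# degenerate 13-mer associated with crossover events at recombination hotspots
INSTABILITY_13MER = "CCNCCNTNNCCNC"


def assign_windows(
    positions: pd.DataFrame, windows: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Count inserts per window.

    ``positions``: columns chrom, position.  ``windows``: columns window_id,
    chrom, start, end (non-overlapping).  Returns the windows table with an
    ``insert_count`` column plus counts of containing windows and positions
    left unassigned (falling in no window).
    """
    counts = np.zeros(len(windows), dtype=int)
    unassigned = 0
    by_chrom: dict[str, pd.DataFrame] = {
        c: sub.sort_values("start") for c, sub in windows.groupby("chrom")
    }
    index_of = {wid: i for i, wid in enumerate(windows["window_id"])}
    for row in positions.itertuples():
        sub = by_chrom.get(row.chrom)
        if sub is None:
            unassigned += 1
            continue
        starts = sub["start"].to_numpy()
        i = np.searchsorted(starts, row.position, side="right") - 1
        if i < 0 or row.position >= sub["end"].iloc[i]:
            unassigned += 1
            continue
        counts[index_of[sub["window_id"].iloc[i]]] += 1
    out = windows.copy()
    out["insert_count"] = counts
    info = {
        "n_positions": len(positions),
        "n_unassigned": unassigned,
        "n_containing": int((counts > 0).sum()),
        "n_free": int((counts == 0).sum()),
        "n_multi": int((counts > 1).sum()),
    }
    return out, info


def _u_from_ranks(ranks: np.ndarray, labels: np.ndarray) -> float:
    n1 = int(labels.sum())
    return float(ranks[labels].sum() - n1 * (n1 + 1) / 2)


def permutation_test(
    values: Sequence[float],
    labels: Sequence[bool],
    n_perm: int = 10000,
    alternative: str = "two-sided",
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Permutation-calibrated Mann-Whitney-Wilcoxon test.

    ``labels`` marks the insert-containing class.  Labels are reshuffled
    ``n_perm`` times preserving class sizes; the empirical p-value is
    (1 + #{permuted U as or more extreme}) / (1 + n_perm), with "as or more
    extreme" defined on U centered at its null mean (ties count as extreme).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both label classes must be non-empty")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives coarse empirical p-values")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(values)
    n1 = int(labels.sum())
    ranks = rankdata(values)
    mu = n1 * (n - n1) / 2.0
    u_obs = _u_from_ranks(ranks, labels)

    # vectorized label permutations: each row is a random subset of size n1
    perm_u = np.empty(n_perm)
    offset = n1 * (n1 + 1) / 2
    block = 2000
    for b0 in range(0, n_perm, block):
        b = min(block, n_perm - b0)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        perm_u[b0 : b0 + b] = ranks[idx].sum(axis=1) - offset

    eps = 1e-9
    if alternative in ("greater", "right"):
        more = np.sum(perm_u >= u_obs - eps)
    elif alternative in ("less", "left"):
        more = np.sum(perm_u <= u_obs + eps)
    elif alternative in ("two-sided", "two"):
        more = np.sum(np.abs(perm_u - mu) >= abs(u_obs - mu) - eps)
    else:
        raise ValueError(f"unknown alternative: {alternative}")
    p = (1 + int(more)) / (1 + n_perm)

    asym = mann_whitney_u(values[labels], values[~labels], alternative="two-sided")
    return {"u": u_obs, "z": asym.z, "p": p, "n_perm": n_perm, "alternative": alternative}


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """min(1, m*p) for each p; m defaults to the number of p-values."""
    p_values = list(p_values)
    m = m if m is not None else len(p_values)
    if m < 1:
        raise ValueError("m must be >= 1")
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
        out.append(min(1.0, m * p))
    return out


_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "[ACGT]"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def count_motif(sequence: str, motif: str = INSTABILITY_13MER, both_strands: bool = True) -> int:
    """Overlapping occurrences of a degenerate motif (N = any base); by
    default counted on both strands (the hotspot biology is strand-
    symmetric)."""
    seq = sequence.upper()
    pattern = "".join(_IUPAC[b] for b in motif.upper())
    n = len(re.findall(f"(?=({pattern}))", seq))
    if both_strands:
        rc = seq.translate(_COMP)[::-1]
        n += len(re.findall(f"(?=({pattern}))", rc))
    return n


def enrichment_table(
    windows: pd.DataFrame,
    features: Sequence[str],
    n_perm: int = 10000,
    alternative: str = "two-sided",
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-feature enrichment of insert-containing vs insert-free windows:
    medians, absolute median difference, U, Z, empirical p and
    Bonferroni-adjusted p (m = number of features)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = windows["insert_count"].to_numpy() > 0
    rows = []
    for feat in features:
        vals = windows[feat].to_numpy(dtype=float)
        res = permutation_test(vals, labels, n_perm=n_perm, alternative=alternative, rng=rng)
        med_in = float(np.median(vals[labels]))
        med_out = float(np.median(vals[~labels]))
        rows.append(
            {
                "feature": feat,
                "median_containing": med_in,
                "median_free": med_out,
                "abs_median_diff": abs(med_in - med_out),
                "U": res["u"],
                "Z": res["z"],
                "p_empirical": res["p"],
            }
        )
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = bonferroni(df["p_empirical"], m=len(features))
    return df
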