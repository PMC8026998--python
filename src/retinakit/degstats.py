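"""Expression statistics: CPM filtering, permutation-FDR t test, ΔΔCT.

The differential-expression test is a per-gene equal-variance Student's t on
log expression whose significance cutoff is calibrated by label permutations:
the threshold c is the smallest |t| such that

    FDR(c) = mean over permutations of #{null |t| >= c} / max(1, #{observed |t| >= c})

does not exceed the target (default 0.05, 250 randomizations).  When the
space of distinct balanced label assignments is no larger than the requested
number of permutations, all assignments except the identity are enumerated
instead of sampled.

qPCR relative expression uses the ΔΔCT method against a housekeeping
reference gene: fold change = 2^(−ΔΔCT).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from ._ranksum import rank_sum_test

__all__ = [
    "DEResult",
    "cpm",
    "filter_genes",
    "perm_fdr_ttest",
    "delta_delta_ct",
    "mann_whitney",
]


@dataclass(frozen=True)
class DEResult:
    """Permutation-FDR t-test outcome."""

    table: pd.DataFrame  # per gene: t, mean_log2_diff, significant
    threshold: float  # |t| cutoff actually applied (inf when nothing passes)
    fdr_target: float
    n_perm: int

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene ids")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalisation: count / library size × 1e6."""
    _validate_counts(counts)
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size in samples {bad}")
    return counts / lib * 1e6


def filter_genes(
    counts: pd.DataFrame,
    labels,
    min_cpm: float = 1.0,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Keep genes with cpm strictly > ``min_cpm`` in >= ``min_samples``
    samples of at least one group; gene order is preserved.

    ``labels`` assigns each sample column to one of two groups.  Returns the
    subset of the *count* matrix (not the CPM matrix).
    """
    labels = np.asarray(labels)
    if len(labels) != counts.shape[1]:
        raise ValueError("labels length must match the number of samples")
    groups = pd.unique(labels)
    for g in groups:
        if np.sum(labels == g) < min_samples:
            raise ValueError(f"group {g!r} has fewer than {min_samples} samples")
    cpm_mat = cpm(counts)
    keep = np.zeros(counts.shape[0], dtype=bool)
    for g in groups:
        sub = cpm_mat.loc[:, labels == g]
        keep |= ((sub > min_cpm).sum(axis=1) >= min_samples).to_numpy()
    return counts.loc[keep]


def _t_rows(mat: np.ndarray, mask1: np.ndarray, mask2: np.ndarray) -> np.ndarray:
    """Equal-variance two-sample t per row (gene); constant rows get t = 0."""
    a, b = mat[:, mask1], mat[:, mask2]
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    sp2 = ((na - 1) * np.var(a, axis=1, ddof=1) + (nb - 1) * np.var(b, axis=1, ddof=1)) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t[denom == 0] = 0.0
    return t


def _label_assignments(n: int, n1: int, n_perm: int, rng: np.random.Generator):
    """Distinct label assignments (as group-1 index sets), excluding identity.

    When the design is balanced (n1 = n − n1) an assignment and its
    complement give the same |t|, so assignments are canonicalised to the
    subset containing sample 0 and counted once.  The space is enumerated
    exhaustively when it has no more than ``n_perm`` members, else sampled
    without replacement.
    """
    identity = tuple(range(n1))
    balanced = 2 * n1 == n

    def canon(c: tuple) -> tuple:
        if balanced and 0 not in c:
            return tuple(sorted(set(range(n)) - set(c)))
        return c

    total = comb(n - 1, n1 - 1) if balanced else comb(n, n1)
    if total - 1 <= n_perm:
        if balanced:
            space = ((0,) + c for c in combinations(range(1, n), n1 - 1))
        else:
            space = combinations(range(n), n1)
        return [c for c in space if c != identity]
    seen = {identity}
    out = []
    while len(out) < n_perm:
        c = canon(tuple(sorted(rng.choice(n, size=n1, replace=False).tolist())))
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def perm_fdr_ttest(
    matrix: pd.DataFrame,
    labels,
    n_perm: int = 250,
    fdr: float = 0.05,
    seed: int = 0,
) -> DEResult:
    """Two-tailed permutation-FDR Student's t test on a log2-expression matrix.

    ``matrix`` is genes × samples, already on a log scale (use
    ``np.log2(cpm(counts) + 1)`` for raw counts); ``labels`` assigns the two
    groups.  The significant set is exactly the genes whose |t| reaches the
    permutation-calibrated cutoff.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    mask1 = labels == groups[0]
    mask2 = labels == groups[1]
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError("need >= 2 samples per group")

    mat = matrix.to_numpy(dtype=float)
    n = mat.shape[1]
    n1 = int(mask1.sum())
    # reorder columns so group 1 comes first: permutation space is index sets
    order = np.concatenate([np.flatnonzero(mask1), np.flatnonzero(mask2)])
    mat = mat[:, order]
    base1 = np.arange(n, dtype=int) < n1

    t_obs = _t_rows(mat, base1, ~base1)
    abs_obs = np.abs(t_obs)

    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    assignments = _label_assignments(n, n1, n_perm, rng)
    null_abs = np.empty((len(assignments), mat.shape[0]))
    for k, idx in enumerate(assignments):
        m1 = np.zeros(n, dtype=bool)
        m1[list(idx)] = True
        null_abs[k] = np.abs(_t_rows(mat, m1, ~m1))

    # candidate cutoffs: the observed |t| values (a cutoff between two
    # observed values selects the same gene set as the larger of the two)
    candidates = np.unique(abs_obs)
    sorted_obs = np.sort(abs_obs)
    sorted_null = np.sort(null_abs.reshape(-1))
    n_obs_ge = len(sorted_obs) - np.searchsorted(sorted_obs, candidates, "left")
    n_null_ge = (len(sorted_null) - np.searchsorted(sorted_null, candidates, "left")) / len(assignments)
    est_fdr = n_null_ge / np.maximum(1, n_obs_ge)
    ok = est_fdr <= fdr
    threshold = float(candidates[ok][0]) if ok.any() else float("inf")

    significant = abs_obs >= threshold
    mean_diff = mat[:, ~base1].mean(axis=1) - mat[:, base1].mean(axis=1)
    table = pd.DataFrame(
        {"t": t_obs, "mean_log2_diff": mean_diff, "significant": significant},
        index=matrix.index,
    )
    return DEResult(table=table, threshold=threshold, fdr_target=fdr, n_perm=len(assignments))


def delta_delta_ct(records: pd.DataFrame, control_group: str = "control") -> pd.DataFrame:
    """ΔΔCT relative expression: fold change = 2^(−ΔΔCT) per group.

    ``records`` holds one row per sample with columns sample_id, group,
    ct_target, ct_reference (the housekeeping gene).  ΔCT = ct_target −
    ct_reference per sample; ΔΔCT = mean ΔCT(group) − mean ΔCT(control).
    Returns per-group fold changes plus per-sample folds (relative to the
    control-group mean ΔCT) for nonparametric testing.
    """
    req = {"sample_id", "group", "ct_target", "ct_reference"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing CT values")
    if control_group not in set(records["group"]):
        raise ValueError(f"control group {control_group!r} not present")

    rec = records.copy()
    rec["delta_ct"] = rec["ct_target"] - rec["ct_reference"]
    ctrl_mean = rec.loc[rec["group"] == control_group, "delta_ct"].mean()
    rec["fold"] = 2.0 ** (-(rec["delta_ct"] - ctrl_mean))

    rows = []
    for grp, sub in rec.groupby("group", sort=True):
        ddct = float(sub["delta_ct"].mean() - ctrl_mean)
        rows.append((grp, ddct, 2.0**-ddct, len(sub)))
    summary = pd.DataFrame(rows, columns=["group", "delta_delta_ct", "fold_change", "n"])
    summary.attrs["per_sample"] = rec[["sample_id", "group", "delta_ct", "fold"]]
    return summary


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney / Wilcoxon rank-sum test (shared engine).

    Exact for small samples, tie-corrected normal approximation otherwise;
    returns (rank-sum statistic of x, p value).
    """
    return rank_sum_test(x, y)
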