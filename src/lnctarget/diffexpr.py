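"""Count normalization and negative-binomial differential testing.

The differential engine is a transparent method-of-moments NB Wald test:
median-of-ratios size factors, per-gene moment dispersion pooled across the
two conditions, a delta-method standard error for the log2 fold change, and
a Student t reference with the pooled within-group degrees of freedom.  The
t reference (rather than a normal) accounts for the handful of degrees of
freedom available at typical 3 vs 3 designs and keeps the test calibrated
near its nominal level; see docs/methods.md.  Significance is called at a
BH-adjusted FDR (default 0.1).

Also provides the NanoString-style two-step normalization (technical
positive controls, then minimum-CV housekeeping genes) and the DM/CTRL
group fold-change test used for patient panel data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MIN_DISPERSION = 1e-8
LOG2FC_PSEUDOCOUNT = 0.5

__all__ = [
    "CountMatrix",
    "size_factors",
    "filter_low_counts",
    "de_test",
    "bh_adjust",
    "nanostring_normalize",
    "group_fold_change",
]


@dataclass
class CountMatrix:
    """Genes x samples raw counts with a per-sample condition label."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids
    condition: pd.Series  # sample id -> condition label

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        missing = [s for s in self.counts.columns if s not in self.condition.index]
        if missing:
            raise ValueError(f"sample(s) without condition label: {missing}")
        self.condition = self.condition.loc[self.counts.columns]
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_tsv(
        cls, path: str | Path, condition_map: Optional[dict[str, str]] = None
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if condition_map is None:
            # sample naming convention: <condition>_<replicate>
            condition_map = {c: c.rsplit("_", 1)[0] for c in df.columns}
        cond = pd.Series({c: condition_map[c] for c in df.columns})
        return cls(df, cond)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    def samples_of(self, label: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition[s] == label]


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_s = median over all-positive genes of count_gs / geomean_g.
    When no gene is positive in every sample, falls back to total-count
    ratios with a warning.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = df.to_numpy(dtype=float)
    positive = (vals > 0).all(axis=1)
    if positive.any():
        sub = vals[positive]
        geomean = np.exp(np.log(sub).mean(axis=1, keepdims=True))
        f = np.median(sub / geomean, axis=0)
    else:
        warnings.warn(
            "no gene with all-positive counts; falling back to total-count ratios"
        )
        totals = vals.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total count")
        f = totals / totals.mean()
    f = f / np.exp(np.mean(np.log(f)))  # geometric-mean centering
    return pd.Series(f, index=df.columns)


def filter_low_counts(cm: CountMatrix, min_total: int) -> CountMatrix:
    """Drop genes whose total raw count across samples is below min_total."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = cm.counts.sum(axis=1) >= min_total
    return CountMatrix(cm.counts.loc[keep].copy(), cm.condition.copy())


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _group_moments(norm: np.ndarray, cols: np.ndarray):
    sub = norm[:, cols]
    return sub.mean(axis=1), sub.var(axis=1, ddof=1), sub.shape[1]


def de_test(
    cm: CountMatrix,
    de_fdr: float = 0.1,
    control_label: str = "control",
    knockdown_label: str = "knockdown",
    factors: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """NB Wald test of knockdown vs control on size-factored counts.

    Per gene: log2fc = log2((mu_kd + 0.5) / (mu_ctrl + 0.5)) on normalized
    group means; the squared SE is the delta-method NB variance
    (1/mu + alpha)/n per group, summed and divided by ln(2)^2, with the
    moment dispersion alpha pooled across conditions; the statistic is
    referred to a t distribution with n1 + n2 - 2 df, and p-values are
    BH-adjusted.
    """
    ctrl = cm.samples_of(control_label)
    kd = cm.samples_of(knockdown_label)
    if len(ctrl) < 2 or len(kd) < 2:
        raise ValueError(
            f"each condition needs >= 2 replicates "
            f"(control={len(ctrl)}, knockdown={len(kd)})"
        )
    if factors is None:
        factors = size_factors(cm)
    norm = cm.counts.to_numpy(dtype=float) / factors.loc[cm.counts.columns].to_numpy()
    cols = {s: i for i, s in enumerate(cm.counts.columns)}
    ci = np.array([cols[s] for s in ctrl])
    ki = np.array([cols[s] for s in kd])

    m_c, v_c, n_c = _group_moments(norm, ci)
    m_k, v_k, n_k = _group_moments(norm, ki)

    with np.errstate(divide="ignore", invalid="ignore"):
        a_c = (v_c - m_c) / np.maximum(m_c, 1e-12) ** 2
        a_k = (v_k - m_k) / np.maximum(m_k, 1e-12) ** 2
    alpha = ((n_c - 1) * a_c + (n_k - 1) * a_k) / (n_c + n_k - 2)
    alpha = np.maximum(np.nan_to_num(alpha), MIN_DISPERSION)

    log2fc = np.log2((m_k + LOG2FC_PSEUDOCOUNT) / (m_c + LOG2FC_PSEUDOCOUNT))
    se2 = (
        (1.0 / np.maximum(m_c, LOG2FC_PSEUDOCOUNT) + alpha) / n_c
        + (1.0 / np.maximum(m_k, LOG2FC_PSEUDOCOUNT) + alpha) / n_k
    ) / np.log(2.0) ** 2
    se = np.sqrt(se2)
    stat = log2fc / se
    df = n_c + n_k - 2
    p = 2.0 * stats.t.sf(np.abs(stat), df)
    padj = bh_adjust(p)
    direction = np.where(
        (padj < de_fdr) & (log2fc > 0),
        "up",
        np.where((padj < de_fdr) & (log2fc < 0), "down", "ns"),
    )
    out = pd.DataFrame(
        {
            "gene_id": cm.counts.index,
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "p": p,
            "padj": padj,
            "direction": direction,
        }
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# NanoString-style panel normalization and DM/CTRL fold change
# ---------------------------------------------------------------------------


def _geomean(a: np.ndarray, axis=None) -> np.ndarray:
    return np.exp(np.log(a).mean(axis=axis))


def nanostring_normalize(
    raw: pd.DataFrame,
    positive_control_ids: Sequence[str],
    housekeeping_candidate_ids: Sequence[str],
    k: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Two-step panel normalization.

    Step 1 scales each sample by (grand geometric mean of positive
    controls) / (sample geometric mean of positive controls).  Step 2
    selects the k housekeeping candidates with the lowest coefficient of
    variation on step-1 counts and applies the analogous geometric-mean
    factor.  Returns the normalized matrix and the chosen housekeeping set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    missing = [g for g in positive_control_ids if g not in raw.index]
    if missing:
        raise ValueError(f"positive control(s) absent from matrix: {missing}")
    missing = [g for g in housekeeping_candidate_ids if g not in raw.index]
    if missing:
        raise ValueError(f"housekeeping candidate(s) absent from matrix: {missing}")
    if k > len(housekeeping_candidate_ids):
        raise ValueError("k exceeds the number of housekeeping candidates")

    pos = raw.loc[list(positive_control_ids)].to_numpy(dtype=float)
    if (pos <= 0).any():
        raise ValueError("zero or negative positive-control count")
    sample_gm = _geomean(pos, axis=0)
    grand_gm = _geomean(pos)
    step1 = raw * (grand_gm / sample_gm)

    hk = step1.loc[list(housekeeping_candidate_ids)]
    cv = hk.std(axis=1, ddof=1) / hk.mean(axis=1)
    chosen = list(cv.sort_values(kind="mergesort").index[:k])

    hk_vals = step1.loc[chosen].to_numpy(dtype=float)
    if (hk_vals <= 0).any():
        raise ValueError("zero housekeeping count after step 1")
    hk_gm = _geomean(hk_vals, axis=0)
    norm = step1 * (_geomean(hk_vals) / hk_gm)
    return norm, chosen


def group_fold_change(
    norm: pd.DataFrame, groups: pd.Series, test_label: str = "DM",
    reference_label: str = "CTRL",
) -> pd.DataFrame:
    """Per-gene DM/CTRL mean fold change with a two-tailed unpaired t test.

    Genes with zero reference mean get an undefined fold change (NaN) and
    are flagged.
    """
    test_cols = [s for s in norm.columns if groups.get(s) == test_label]
    ref_cols = [s for s in norm.columns if groups.get(s) == reference_label]
    if len(test_cols) < 2 or len(ref_cols) < 2:
        raise ValueError("each group needs >= 2 samples")
    t_vals = norm[test_cols].to_numpy(dtype=float)
    r_vals = norm[ref_cols].to_numpy(dtype=float)
    ref_mean = r_vals.mean(axis=1)
    test_mean = t_vals.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(ref_mean > 0, test_mean / ref_mean, np.nan)
    tt = stats.ttest_ind(t_vals, r_vals, axis=1, equal_var=True)
    p = np.asarray(tt.pvalue, dtype=float)
    # degenerate case: both groups constant and equal -> no evidence
    degen = ~np.isfinite(p)
    p[degen & (test_mean == ref_mean)] = 1.0
    p[~np.isfinite(p)] = 1.0
    padj = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": norm.index,
            "fold_change": fc,
            "t": np.asarray(tt.statistic, dtype=float),
            "p": p,
            "padj": padj,
            "fc_undefined": ref_mean <= 0,
        }
    ).reset_index(drop=True)
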