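"""Tile-wise ROC-AUC comparison of two segmentation models.

Each validation tile contributes one AUC per model; the paired differences
``d = auc_b - auc_a`` are tested with a paired t-test and a Wilcoxon
signed-rank test (both two-sided).

Wilcoxon conventions: zero differences are discarded (Wilcoxon's original
rule); absolute differences are ranked with mid-ranks for ties; the
reported statistic is ``W = min(sum of positive ranks, sum of negative
ranks)``. The two-sided p-value comes from exact enumeration of the sign
distribution for n <= 25 (a dynamic-programming convolution over the
doubled ranks, so mid-ranks are exact too) and from the normal
approximation with continuity and tie corrections for larger n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import roc_auc


class DegenerateDifferences(ValueError):
    """All differences zero / zero variance: the test statistic is undefined."""


@dataclass
class ComparisonResult:
    n: int
    mean_auc_a: float
    mean_auc_b: float
    t_statistic: float
    t_pvalue: float
    wilcoxon_W: float
    wilcoxon_pvalue: float
    median_d: float
    q1_d: float
    q3_d: float
    n_outliers: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def tilewise_auc(probs_per_tile, masks_per_tile) -> tuple[np.ndarray, np.ndarray]:
    """One ROC-AUC per tile from burnt-probability maps and binary masks.

    Tiles whose reference mask contains a single class cannot be scored;
    they are excluded. Returns (aucs over retained tiles, boolean retained
    flags aligned with the input order).
    """
    aucs, retained = [], []
    for probs, mask in zip(probs_per_tile, masks_per_tile):
        mask = np.asarray(mask).ravel()
        if mask.min() == mask.max():
            retained.append(False)
            continue
        aucs.append(roc_auc(np.asarray(probs).ravel(), mask))
        retained.append(True)
    if not aucs:
        raise ValueError("no tile contains both classes; tile-wise AUC undefined")
    return np.array(aucs), np.array(retained)


def paired_t(d: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on differences: t = mean(d) / (sd(d)/sqrt(n)),
    sample sd (n-1 denominator), df = n-1."""
    d = np.asarray(d, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired t needs at least two differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDifferences("zero variance of differences; t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(min(p, 1.0))


def _signed_ranks(d: np.ndarray) -> np.ndarray:
    """Mid-ranks of |d| after dropping zeros, signed by d."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateDifferences("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    return np.sign(d) * ranks


def _exact_two_sided_p(ranks_abs: np.ndarray, w_min: float) -> float:
    """Exact P(W+ <= w_min) * 2 by DP over the 2n-scaled rank distribution.

    Mid-ranks are half-integers at worst, so doubling them gives integers;
    the distribution of W+ under random signs is the convolution of
    independent {0, 2r} contributions and is symmetric about its midpoint.
    """
    doubled = np.round(2 * ranks_abs).astype(np.int64)
    total = int(doubled.sum())
    dist = np.zeros(total + 1, dtype=np.float64)
    dist[0] = 1.0
    for r in doubled:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= 2.0 ** len(doubled)
    w2 = int(round(2 * w_min))
    p = 2.0 * dist[: w2 + 1].sum()
    return float(min(p, 1.0))


def _normal_two_sided_p(ranks_abs: np.ndarray, w_min: float) -> float:
    """Normal approximation with continuity correction and tie correction."""
    n = ranks_abs.size
    mu = n * (n + 1) / 4.0
    tie_term = 0.0
    _, counts = np.unique(ranks_abs, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        raise DegenerateDifferences("degenerate rank variance")
    z = (w_min - mu + 0.5) / np.sqrt(sigma2)
    return float(min(2.0 * stats.norm.cdf(z), 1.0))


def wilcoxon_signed_rank(d: np.ndarray, exact_threshold: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test; returns (W, p).

    W is the smaller of the positive- and negative-rank sums.
    """
    signed = _signed_ranks(d)
    w_pos = signed[signed > 0].sum()
    w_neg = -signed[signed < 0].sum()
    w = float(min(w_pos, w_neg)) + 0.0  # normalize -0.0
    ranks_abs = np.abs(signed)
    if ranks_abs.size <= exact_threshold:
        p = _exact_two_sided_p(ranks_abs, w)
    else:
        p = _normal_two_sided_p(ranks_abs, w)
    return w, p


def compare_models(table: pd.DataFrame, col_a: str = "auc_model_a",
                   col_b: str = "auc_model_b") -> ComparisonResult:
    """Full paired comparison of two models' tile-wise AUC columns.

    The difference summary (median, quartiles, Tukey 1.5*IQR outlier
    count) describes ``d = auc_b - auc_a``.
    """
    a = table[col_a].to_numpy(dtype=float)
    b = table[col_b].to_numpy(dtype=float)
    if a.size < 2:
        raise ValueError("need at least two tiles to compare models")
    for name, v in ((col_a, a), (col_b, b)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} contains AUCs outside [0, 1]")
    d = b - a
    t_stat, t_p = paired_t(d)
    w, w_p = wilcoxon_signed_rank(d)
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    iqr = q3 - q1
    outliers = int(np.sum((d < q1 - 1.5 * iqr) | (d > q3 + 1.5 * iqr)))
    return ComparisonResult(
        n=int(a.size), mean_auc_a=float(a.mean()), mean_auc_b=float(b.mean()),
        t_statistic=t_stat, t_pvalue=t_p, wilcoxon_W=w, wilcoxon_pvalue=w_p,
        median_d=float(med), q1_d=float(q1), q3_d=float(q3), n_outliers=outliers)


def plot_comparison(table: pd.DataFrame, out_path=None, col_a: str = "auc_model_a",
                    col_b: str = "auc_model_b"):
    """Histogram of AUC differences plus per-model boxplots (optional render)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = table[col_b].to_numpy(float) - table[col_a].to_numpy(float)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].hist(d, bins=15, color="tab:orange", edgecolor="k")
    axes[0].axvline(0.0, color="red", linestyle="--")
    axes[0].set_xlabel("AUC difference (model B - model A)")
    axes[0].set_ylabel("tiles")
    axes[1].boxplot([table[col_a], table[col_b]], tick_labels=["model A", "model B"])
    axes[1].set_ylabel("tile ROC-AUC")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
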