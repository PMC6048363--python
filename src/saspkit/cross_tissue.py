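"""Cross-tissue expression/splicing dichotomization and t-statistic ranking.

Mirrors a GTEx-style analysis: filter weakly expressed genes by total CPM,
quantile-normalize expression across samples, split samples either by the
mean expression of a regulator or at the local density minimum of a bimodal
exon-inclusion (PSI) distribution, and rank all genes by an ordinary
two-sample pooled-variance t-statistic (high vs low group) to feed preranked
gene-set enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    BimodalityError,
    DegenerateInputError,
    SampleSizeError,
)


def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: count * 1e6 / library size (column sums unless
    supplied)."""
    lib = counts.sum(axis=0) if library_sizes is None else library_sizes
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise DegenerateInputError(f"sample {bad}: non-positive library size")
    return counts * 1e6 / lib


def cpm_filter(
    counts: pd.DataFrame,
    threshold: float = 10.0,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Keep genes whose CPM summed across all samples is strictly above the
    threshold."""
    if counts.shape[1] < 1:
        raise SampleSizeError("count matrix needs at least one sample")
    total = cpm(counts, library_sizes).sum(axis=1)
    return counts.loc[total > threshold]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rank-based quantile normalization across columns.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; tied values within a column receive the mean of the
    reference values their ranks span.  A single-row matrix is returned
    unchanged (documented identity).
    """
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise DegenerateInputError("quantile normalization requires no missing values")
    n, m = x.shape
    if n <= 1:
        return matrix.copy()
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(m):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty(n)
        ranked[order] = ref
        # ties: average the reference values spanned by each tied run
        sorted_col = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                ranked[order[i:k + 1]] = ref[i:k + 1].mean()
            i = k + 1
        out[:, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class SampleDichotomy:
    labels: pd.Series  # 'high' / 'low' per sample
    cutoff: float
    cutoff_method: str

    @property
    def high(self) -> pd.Index:
        return self.labels.index[self.labels == "high"]

    @property
    def low(self) -> pd.Index:
        return self.labels.index[self.labels == "low"]

    def inverted(self) -> "SampleDichotomy":
        """Swap the group labels (e.g. to orient a PSI split by exon
        *skipping* rather than inclusion)."""
        return SampleDichotomy(
            labels=self.labels.map({"high": "low", "low": "high"}),
            cutoff=self.cutoff,
            cutoff_method=self.cutoff_method,
        )


def dichotomize_by_mean(values: pd.Series) -> SampleDichotomy:
    """Split samples at the arithmetic mean; a sample exactly at the cutoff
    is labelled high."""
    v = values.astype(float)
    if len(v) < 2:
        raise SampleSizeError("need >=2 samples to dichotomize")
    cutoff = float(v.mean())
    labels = pd.Series(np.where(v >= cutoff, "high", "low"), index=v.index)
    if (labels == "high").all() or (labels == "low").all():
        raise DegenerateInputError("dichotomy is degenerate: one group is empty")
    return SampleDichotomy(labels=labels, cutoff=cutoff, cutoff_method="mean_expression")


def dichotomize_fixed(values: pd.Series, cutoff: float) -> SampleDichotomy:
    v = values.astype(float)
    labels = pd.Series(np.where(v >= cutoff, "high", "low"), index=v.index)
    if (labels == "high").all() or (labels == "low").all():
        raise DegenerateInputError("dichotomy is degenerate: one group is empty")
    return SampleDichotomy(labels=labels, cutoff=float(cutoff), cutoff_method="fixed")


def density_minimum_cutoff(
    values,
    grid_points: int = 512,
    bandwidth: str | float = "silverman",
    min_peak_fraction: float = 0.05,
) -> float:
    """Valley threshold of a bimodal distribution on [0, 1].

    A Gaussian kernel density estimate (Silverman bandwidth by default) is
    evaluated on a uniform grid over [0, 1]; the cutoff is the grid location
    of the minimum density strictly between the two highest local maxima.
    Local maxima below ``min_peak_fraction`` of the top peak are treated as
    tail ripples of the estimate, not modes.

    Raises :class:`BimodalityError` when the estimate has fewer than two
    local maxima.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise SampleSizeError("need >=3 values for a density estimate")
    if x.min() < 0 or x.max() > 1:
        raise DegenerateInputError("PSI values must lie in [0, 1]")
    kde = stats.gaussian_kde(x, bw_method="silverman" if bandwidth == "silverman" else bandwidth)
    grid = np.linspace(0.0, 1.0, grid_points)
    dens = kde(grid)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:])
    peaks = np.where(interior)[0] + 1
    # boundary maxima count too (mode clipped at 0 or 1)
    if dens[0] > dens[1]:
        peaks = np.concatenate([[0], peaks])
    if dens[-1] > dens[-2]:
        peaks = np.concatenate([peaks, [grid_points - 1]])
    peaks = peaks[dens[peaks] >= min_peak_fraction * dens.max()]
    if len(peaks) < 2:
        raise BimodalityError("density estimate is not bimodal")
    top2 = peaks[np.argsort(dens[peaks])][-2:]
    lo, hi = int(top2.min()), int(top2.max())
    if hi - lo < 2:
        raise BimodalityError("the two main modes are not separated")
    between = slice(lo + 1, hi)
    cut_idx = lo + 1 + int(np.argmin(dens[between]))
    return float(grid[cut_idx])


def dichotomize_by_density_minimum(
    values: pd.Series, grid_points: int = 512
) -> SampleDichotomy:
    cutoff = density_minimum_cutoff(values.to_numpy(), grid_points=grid_points)
    d = dichotomize_fixed(values, cutoff)
    return SampleDichotomy(labels=d.labels, cutoff=cutoff, cutoff_method="density_minimum")


def rank_genes_by_t(
    matrix: pd.DataFrame,
    dichotomy: SampleDichotomy,
) -> pd.DataFrame:
    """Per-gene pooled-variance t-statistics (high minus low), sorted
    descending with a gene-id tiebreak.

    Genes with zero pooled variance get t = 0 and a flag.  No empirical-Bayes
    variance moderation is applied (ordinary t-statistics).
    """
    hi = matrix[dichotomy.high].to_numpy(dtype=float)
    lo = matrix[dichotomy.low].to_numpy(dtype=float)
    n1, n2 = hi.shape[1], lo.shape[1]
    if n1 < 2 or n2 < 2:
        raise SampleSizeError("both groups need >=2 samples for a t-statistic")
    m1, m2 = hi.mean(axis=1), lo.mean(axis=1)
    v1, v2 = hi.var(axis=1, ddof=1), lo.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    # relative tolerance: quantile-normalized ties can leave a variance that
    # is float noise rather than exactly zero
    zero = se <= 1e-9 * (np.abs(m1) + np.abs(m2) + 1.0)
    t = np.zeros(len(matrix))
    np.divide(m1 - m2, se, out=t, where=~zero)
    out = pd.DataFrame(
        {"gene": matrix.index.astype(str), "t": t, "zero_variance": zero}
    )
    out = out.sort_values(["t", "gene"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)
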