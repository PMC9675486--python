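"""Step-function binarization of gene expression (StepMiner).

Each gene's expression values (log2 scale) are sorted and fitted with a
one-step function: a constant low segment followed by a constant high
segment.  The split minimizing the residual sum of squares defines a
per-gene threshold t = (low_mean + high_mean) / 2.  Samples are then
ternarized: LOW if the value is at or below t - margin, HIGH if at or
above t + margin, INTERMEDIATE in between.  Intermediate samples are
excluded from downstream pairwise implication counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LOW",
    "HIGH",
    "INTERMEDIATE",
    "MISSING",
    "StepFit",
    "TernaryMatrix",
    "fit_step",
    "ternarize",
]

# Ternary codes.  LOW/HIGH are 0/1 so that quadrant (i, j) indexes read
# directly as (A-code, B-code); INTERMEDIATE and MISSING never enter counts.
LOW: int = 0
HIGH: int = 1
INTERMEDIATE: int = 2
MISSING: int = -1

CODE_LABELS = {LOW: "low", HIGH: "high", INTERMEDIATE: "intermediate", MISSING: "missing"}


@dataclass(frozen=True)
class StepFit:
    """One-step fit to a gene's sorted expression values.

    Attributes
    ----------
    threshold : float
        Binarization threshold, midway between the two segment means.
    split_index : int
        Number of values in the low segment (1 <= k <= n-1).
    low_mean, high_mean : float
        Means of the low and high segments (low_mean <= high_mean).
    sse : float
        Residual sum of squares of the two-segment fit.
    f_statistic : float
        ((SST - SSE) / 1) / (SSE / (n - 2)) with SST the single-mean
        (null) sum of squares; infinite for a perfect step.
    n : int
        Number of non-missing values used.
    """

    threshold: float
    split_index: int
    low_mean: float
    high_mean: float
    sse: float
    f_statistic: float
    n: int

    @property
    def is_degenerate(self) -> bool:
        """True when the fitted step has no height (constant gene)."""
        return self.high_mean - self.low_mean == 0.0


def fit_step(values) -> StepFit:
    """Fit a one-step function to a vector of expression values.

    Missing (NaN) values are dropped; at least 4 finite values are
    required.  Values are sorted ascending and every split k in
    [1, n-1] is scored by the SSE of the two-segment constant fit; the
    smallest k attaining the minimal SSE wins (deterministic tie-break).

    Returns
    -------
    StepFit

    Raises
    ------
    ValueError
        If fewer than 4 finite values are supplied.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 4:
        raise ValueError(f"fit_step requires >= 4 non-missing values, got {n}")
    x = np.sort(x)

    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    total, total_sq = csum[-1], csq[-1]
    k = np.arange(1, n)
    m1 = csum[:-1] / k
    m2 = (total - csum[:-1]) / (n - k)
    # SSE(k) = sum(x^2) - k*m1^2 - (n-k)*m2^2, clipped against round-off
    sse_all = total_sq - k * m1 * m1 - (n - k) * m2 * m2
    np.clip(sse_all, 0.0, None, out=sse_all)
    i = int(np.argmin(sse_all))  # argmin returns the first (smallest k) minimum
    sse = float(sse_all[i])

    mean = total / n
    sst = float(total_sq - n * mean * mean)
    if sse <= 0.0:
        f = np.inf if sst > 0.0 else 0.0
        sse = 0.0
    else:
        f = ((sst - sse) / 1.0) / (sse / (n - 2))

    lo, hi = float(m1[i]), float(m2[i])
    return StepFit(
        threshold=(lo + hi) / 2.0,
        split_index=i + 1,
        low_mean=lo,
        high_mean=hi,
        sse=sse,
        f_statistic=float(f),
        n=n,
    )


@dataclass
class TernaryMatrix:
    """Genes x samples ternary codes with per-gene step fits.

    Attributes
    ----------
    codes : pandas.DataFrame (int8)
        Codes in {LOW, HIGH, INTERMEDIATE, MISSING}, genes in rows.
    fits : pandas.DataFrame
        Per-gene fit table (threshold, split_index, low_mean, high_mean,
        sse, f_statistic, n_used), indexed by gene; NaN rows for genes
        that could not be fitted.
    informative : pandas.Series (bool)
        Genes eligible for pairwise implication analysis.
    margin : float
        Half-width (log2 units) of the intermediate zone around the
        threshold.
    """

    codes: pd.DataFrame
    fits: pd.DataFrame
    informative: pd.Series
    margin: float = 0.5

    @property
    def gene_ids(self) -> list:
        return list(self.codes.index)

    @property
    def sample_ids(self) -> list:
        return list(self.codes.columns)

    def informative_codes(self) -> pd.DataFrame:
        """Code rows restricted to informative genes."""
        return self.codes.loc[self.informative[self.informative].index]

    def __eq__(self, other) -> bool:  # used by round-trip tests
        if not isinstance(other, TernaryMatrix):
            return NotImplemented
        return (
            self.codes.equals(other.codes)
            and np.isclose(self.margin, other.margin)
            and self.informative.equals(other.informative)
            and _frames_close(self.fits, other.fits)
        )


def _frames_close(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        return False
    av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    both_nan = np.isnan(av) & np.isnan(bv)
    return bool(np.all(both_nan | np.isclose(av, bv, equal_nan=True)))


def _code_row(values: np.ndarray, threshold: float, margin: float) -> np.ndarray:
    codes = np.full(values.shape, INTERMEDIATE, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        codes[values <= threshold - margin] = LOW
        codes[values >= threshold + margin] = HIGH  # boundary inclusive
    codes[~np.isfinite(values)] = MISSING
    return codes


def ternarize(
    matrix: pd.DataFrame,
    margin: float = 0.5,
    min_range: float = 1.0,
    min_per_side: int = 3,
) -> TernaryMatrix:
    """Ternarize an expression matrix gene by gene.

    Parameters
    ----------
    matrix : DataFrame
        Genes x samples, log2 scale, NaN allowed.
    margin : float
        Intermediate half-width around each gene threshold (> 0).
    min_range : float
        Genes whose observed max-min dynamic range (log2) is below this
        are flagged uninformative and excluded from pairwise analysis.
    min_per_side : int
        Minimum number of LOW and of HIGH samples for a gene to count
        as informative.

    Degenerate (constant) genes and genes with fewer than 4 values are
    coded all-INTERMEDIATE (missing stays MISSING) and flagged
    uninformative.
    """
    if margin <= 0:
        raise ValueError("margin must be > 0")
    values = matrix.to_numpy(dtype=float)
    n_genes = values.shape[0]
    codes = np.full(values.shape, INTERMEDIATE, dtype=np.int8)
    fit_rows = np.full((n_genes, 7), np.nan)
    informative = np.zeros(n_genes, dtype=bool)

    for gi in range(n_genes):
        row = values[gi]
        finite = row[np.isfinite(row)]
        codes[gi, ~np.isfinite(row)] = MISSING
        if finite.size < 4:
            continue
        fit = fit_step(finite)
        fit_rows[gi] = (
            fit.threshold,
            fit.split_index,
            fit.low_mean,
            fit.high_mean,
            fit.sse,
            fit.f_statistic,
            fit.n,
        )
        if fit.is_degenerate:
            continue  # all INTERMEDIATE, uninformative
        codes[gi] = _code_row(row, fit.threshold, margin)
        dynamic_range = float(finite.max() - finite.min())
        n_low = int(np.sum(codes[gi] == LOW))
        n_high = int(np.sum(codes[gi] == HIGH))
        informative[gi] = (
            dynamic_range >= min_range and n_low >= min_per_side and n_high >= min_per_side
        )

    fits = pd.DataFrame(
        fit_rows,
        index=matrix.index,
        columns=["threshold", "split_index", "low_mean", "high_mean", "sse", "f_statistic", "n_used"],
    )
    return TernaryMatrix(
        codes=pd.DataFrame(codes, index=matrix.index, columns=matrix.columns),
        fits=fits,
        informative=pd.Series(informative, index=matrix.index, name="informative"),
        margin=margin,
    )
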