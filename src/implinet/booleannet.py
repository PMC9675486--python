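"""Boolean implication relationships between ternarized gene pairs.

For two ternarized genes A and B, samples where both codes are LOW or
HIGH populate a 2x2 quadrant table.  A quadrant (i, j) is *sparse* when
its observed count O falls well below the count E = row_i * col_j / n
expected under independence:

    S = (E - O) / sqrt(E)          (sparseness statistic)
    p_err = (O/row_i + O/col_j)/2  (predicted error rate)

A quadrant with S > s_min and p_err < p_max supports a Boolean
implication.  One sparse quadrant gives one of the four asymmetric
relations (e.g. sparse (low, high) means "A low => B low"); the two
sparse off-diagonal quadrants together give "equivalent"; the two
sparse diagonal quadrants give "opposite".  A global permutation FDR is
estimated by shuffling every gene's codes across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stepminer import HIGH, LOW, TernaryMatrix

__all__ = [
    "RELATIONS",
    "ASYMMETRIC_RELATIONS",
    "SYMMETRIC_RELATIONS",
    "CONVERSE",
    "QuadrantCounts",
    "ImplicationResult",
    "quadrant_counts",
    "sparseness",
    "classify_pair",
    "all_pairs",
    "count_implications",
    "permutation_fdr",
]

ASYMMETRIC_RELATIONS = ("low=>low", "low=>high", "high=>low", "high=>high")
SYMMETRIC_RELATIONS = ("equivalent", "opposite")
RELATIONS = ASYMMETRIC_RELATIONS + SYMMETRIC_RELATIONS + ("none",)

# Sparse quadrant (A-code, B-code) -> implication stated from A's side.
_QUADRANT_RELATION = {
    (0, 0): "low=>high",   # A low forbids B low
    (0, 1): "low=>low",    # A low forbids B high
    (1, 0): "high=>high",  # A high forbids B low
    (1, 1): "high=>low",   # A high forbids B high
}

# Relation of pair (A, B) as seen from (B, A); the asymmetric relations map
# to their contrapositive restated with B as antecedent.
CONVERSE = {
    "low=>low": "high=>high",
    "high=>high": "low=>low",
    "low=>high": "low=>high",
    "high=>low": "high=>low",
    "equivalent": "equivalent",
    "opposite": "opposite",
    "none": "none",
}


@dataclass(frozen=True)
class QuadrantCounts:
    """2x2 counts of (A-code, B-code) over samples binarized in both genes."""

    n00: int
    n01: int
    n10: int
    n11: int

    @property
    def n(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    @property
    def a_low(self) -> int:
        return self.n00 + self.n01

    @property
    def a_high(self) -> int:
        return self.n10 + self.n11

    @property
    def b_low(self) -> int:
        return self.n00 + self.n10

    @property
    def b_high(self) -> int:
        return self.n01 + self.n11

    def observed(self, quadrant: tuple[int, int]) -> int:
        return {(0, 0): self.n00, (0, 1): self.n01, (1, 0): self.n10, (1, 1): self.n11}[quadrant]

    def row_total(self, i: int) -> int:
        return self.a_low if i == LOW else self.a_high

    def col_total(self, j: int) -> int:
        return self.b_low if j == LOW else self.b_high


@dataclass(frozen=True)
class ImplicationResult:
    """Classification of one gene pair.

    ``relation`` is stated from gene_a's side ("low=>low" reads "gene_a
    low implies gene_b low").  S1/p1 refer to the first tested sparse
    quadrant, S2/p2 to the second for symmetric relations (NaN
    otherwise).  ``passes`` is False for pairs skipped or classified
    "none".
    """

    gene_a: str
    gene_b: str
    relation: str
    s1: float
    p1: float
    s2: float
    p2: float
    n_usable: int
    passes: bool


def quadrant_counts(a, b) -> QuadrantCounts:
    """Count LOW/HIGH co-occurrence of two equal-length ternary vectors.

    Samples where either code is INTERMEDIATE or MISSING are dropped.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("ternary vectors must have equal length")
    usable = np.isin(a, (LOW, HIGH)) & np.isin(b, (LOW, HIGH))
    a, b = a[usable], b[usable]
    return QuadrantCounts(
        n00=int(np.sum((a == LOW) & (b == LOW))),
        n01=int(np.sum((a == LOW) & (b == HIGH))),
        n10=int(np.sum((a == HIGH) & (b == LOW))),
        n11=int(np.sum((a == HIGH) & (b == HIGH))),
    )


def sparseness(counts: QuadrantCounts, quadrant: tuple[int, int]) -> tuple[float, float]:
    """Sparseness statistic S and predicted error rate for one quadrant.

    Returns (nan, nan) when the quadrant is untestable (zero expected
    count, i.e. an empty row or column).
    """
    row = counts.row_total(quadrant[0])
    col = counts.col_total(quadrant[1])
    n = counts.n
    if n == 0 or row == 0 or col == 0:
        return (float("nan"), float("nan"))
    expected = row * col / n
    observed = counts.observed(quadrant)
    s = (expected - observed) / np.sqrt(expected)
    p_err = 0.5 * (observed / row + observed / col)
    return (float(s), float(p_err))


def _classify_counts(
    counts: QuadrantCounts, s_min: float, p_max: float
) -> tuple[str, float, float, float, float]:
    quadrants = [(0, 0), (0, 1), (1, 0), (1, 1)]
    stats = {q: sparseness(counts, q) for q in quadrants}
    sparse = [
        q
        for q in quadrants
        if np.isfinite(stats[q][0]) and stats[q][0] > s_min and stats[q][1] < p_max
    ]
    nan = float("nan")
    if len(sparse) == 1:
        q = sparse[0]
        return (_QUADRANT_RELATION[q], *stats[q], nan, nan)
    if len(sparse) == 2:
        qset = set(sparse)
        if qset == {(0, 1), (1, 0)}:
            return ("equivalent", *stats[(0, 1)], *stats[(1, 0)])
        if qset == {(0, 0), (1, 1)}:
            return ("opposite", *stats[(0, 0)], *stats[(1, 1)])
    return ("none", nan, nan, nan, nan)


def classify_pair(
    a,
    b,
    s_min: float = 3.0,
    p_max: float = 0.1,
    min_samples: int = 20,
    gene_a: str = "A",
    gene_b: str = "B",
) -> ImplicationResult:
    """Classify one ternary gene pair into one of the six relations.

    Pairs with fewer than ``min_samples`` usable samples are returned
    with relation "none" and ``passes`` False.
    """
    counts = quadrant_counts(a, b)
    if counts.n < min_samples:
        nan = float("nan")
        return ImplicationResult(gene_a, gene_b, "none", nan, nan, nan, nan, counts.n, False)
    relation, s1, p1, s2, p2 = _classify_counts(counts, s_min, p_max)
    return ImplicationResult(
        gene_a, gene_b, relation, s1, p1, s2, p2, counts.n, relation != "none"
    )


# ---------------------------------------------------------------------------
# Vectorized all-pairs machinery


def _pairwise_cells(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs quadrant counts via indicator matrix products.

    codes: int8 array genes x samples.  Returns four G x G float arrays
    n00, n01, n10, n11 where entry (a, b) counts samples with
    A-code = i, B-code = j over samples binarized in both genes.
    """
    low = (codes == LOW).astype(np.float64)
    high = (codes == HIGH).astype(np.float64)
    return low @ low.T, low @ high.T, high @ low.T, high @ high.T


def _classify_matrix(
    codes: np.ndarray, s_min: float, p_max: float, min_samples: int
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Vectorized pair classification.

    Returns (relation_code GxG int8, per-quadrant stat arrays).
    Relation codes index into RELATIONS.
    """
    n00, n01, n10, n11 = _pairwise_cells(codes)
    cells = {(0, 0): n00, (0, 1): n01, (1, 0): n10, (1, 1): n11}
    n = n00 + n01 + n10 + n11
    row = {0: n00 + n01, 1: n10 + n11}
    col = {0: n00 + n10, 1: n01 + n11}

    sparse = {}
    stats = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for q, obs in cells.items():
            expected = row[q[0]] * col[q[1]] / np.where(n > 0, n, 1)
            s = (expected - obs) / np.sqrt(np.where(expected > 0, expected, np.nan))
            p_err = 0.5 * (
                obs / np.where(row[q[0]] > 0, row[q[0]], np.nan)
                + obs / np.where(col[q[1]] > 0, col[q[1]], np.nan)
            )
            testable = (expected > 0) & (n >= min_samples)
            sparse[q] = testable & (s > s_min) & (p_err < p_max)
            stats[f"S{q[0]}{q[1]}"] = s
            stats[f"p{q[0]}{q[1]}"] = p_err

    n_sparse = sum(m.astype(np.int8) for m in sparse.values())
    rel = np.full(n.shape, RELATIONS.index("none"), dtype=np.int8)
    for q, name in _QUADRANT_RELATION.items():
        rel[(n_sparse == 1) & sparse[q]] = RELATIONS.index(name)
    rel[(n_sparse == 2) & sparse[(0, 1)] & sparse[(1, 0)]] = RELATIONS.index("equivalent")
    rel[(n_sparse == 2) & sparse[(0, 0)] & sparse[(1, 1)]] = RELATIONS.index("opposite")
    stats["n_usable"] = n
    return rel, stats


_REL_QUADRANTS = {
    "low=>high": [(0, 0)],
    "low=>low": [(0, 1)],
    "high=>high": [(1, 0)],
    "high=>low": [(1, 1)],
    "equivalent": [(0, 1), (1, 0)],
    "opposite": [(0, 0), (1, 1)],
}


def all_pairs(
    ternary: TernaryMatrix,
    s_min: float = 3.0,
    p_max: float = 0.1,
    min_samples: int = 20,
    include_none: bool = True,
) -> pd.DataFrame:
    """Classify every unordered pair of informative genes.

    Returns a DataFrame with one row per unordered pair in matrix order
    (gene_a precedes gene_b), columns gene_a, gene_b, relation, S1, p1,
    S2, p2, n_usable, passes.  Asymmetric relations are stored once,
    directed from gene_a; symmetric relations once per pair.
    """
    inf = ternary.informative_codes()
    genes = np.asarray(inf.index)
    codes = inf.to_numpy(dtype=np.int8)
    n_genes = len(genes)
    if n_genes < 2:
        return _empty_pair_table()

    rel, stats = _classify_matrix(codes, s_min, p_max, min_samples)
    ia, ib = np.triu_indices(n_genes, k=1)
    rel_ab = rel[ia, ib]
    if not include_none:
        keep = rel_ab != RELATIONS.index("none")
        ia, ib, rel_ab = ia[keep], ib[keep], rel_ab[keep]

    nan = np.nan
    s1 = np.full(ia.shape, nan)
    p1 = np.full(ia.shape, nan)
    s2 = np.full(ia.shape, nan)
    p2 = np.full(ia.shape, nan)
    for ri, name in enumerate(RELATIONS[:-1]):
        mask = rel_ab == ri
        if not mask.any():
            continue
        quads = _REL_QUADRANTS[name]
        q = quads[0]
        s1[mask] = stats[f"S{q[0]}{q[1]}"][ia[mask], ib[mask]]
        p1[mask] = stats[f"p{q[0]}{q[1]}"][ia[mask], ib[mask]]
        if len(quads) == 2:
            q = quads[1]
            s2[mask] = stats[f"S{q[0]}{q[1]}"][ia[mask], ib[mask]]
            p2[mask] = stats[f"p{q[0]}{q[1]}"][ia[mask], ib[mask]]

    table = pd.DataFrame(
        {
            "gene_a": genes[ia],
            "gene_b": genes[ib],
            "relation": np.asarray(RELATIONS)[rel_ab],
            "S1": s1,
            "p1": p1,
            "S2": s2,
            "p2": p2,
            "n_usable": stats["n_usable"][ia, ib].astype(int),
        }
    )
    table["passes"] = table["relation"] != "none"
    return table


def _empty_pair_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": pd.Series(dtype=object),
            "gene_b": pd.Series(dtype=object),
            "relation": pd.Series(dtype=object),
            "S1": pd.Series(dtype=float),
            "p1": pd.Series(dtype=float),
            "S2": pd.Series(dtype=float),
            "p2": pd.Series(dtype=float),
            "n_usable": pd.Series(dtype=int),
            "passes": pd.Series(dtype=bool),
        }
    )


def count_implications(
    codes: np.ndarray, s_min: float, p_max: float, min_samples: int
) -> dict[str, int]:
    """Significant-implication counts by relation over all unordered pairs."""
    rel, _ = _classify_matrix(codes, s_min, p_max, min_samples)
    iu = np.triu_indices(rel.shape[0], k=1)
    vals = rel[iu]
    return {
        name: int(np.sum(vals == RELATIONS.index(name))) for name in RELATIONS[:-1]
    }


def permutation_fdr(
    ternary: TernaryMatrix,
    s_min: float = 3.0,
    p_max: float = 0.1,
    min_samples: int = 20,
    n_perm: int = 100,
    seed: int | None = None,
    by_relation: bool = False,
):
    """Network-level permutation FDR for the implication discovery.

    Each permutation independently shuffles every gene's codes across
    samples (preserving per-gene marginals) and the full pair
    classification is rerun.  FDR = mean permuted significant-pair
    count / observed count, 0 when the observed count is 0.

    With ``by_relation=True`` returns a dict mapping each relation type
    to its own FDR; otherwise a single float.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    codes = ternary.informative_codes().to_numpy(dtype=np.int8)
    rng = np.random.default_rng(seed)

    observed = count_implications(codes, s_min, p_max, min_samples)
    null_totals = {name: 0.0 for name in observed}
    for _ in range(n_perm):
        permuted = rng.permuted(codes, axis=1)
        null = count_implications(permuted, s_min, p_max, min_samples)
        for name, c in null.items():
            null_totals[name] += c

    if by_relation:
        return {
            name: (null_totals[name] / n_perm / observed[name]) if observed[name] else 0.0
            for name in observed
        }
    obs_total = sum(observed.values())
    null_mean = sum(null_totals.values()) / n_perm
    return (null_mean / obs_total) if obs_total else 0.0
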