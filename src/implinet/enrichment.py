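"""Gene-set overlap and SNP allele enrichment statistics.

Overlaps between two gene lists drawn from a common universe are scored
with the upper-tail hypergeometric test.  Case/control allele carrier
tables are scored with the two-sided Fisher exact test and an exact
binomial test of each group against an expected population frequency
(two-sided by doubling the smaller tail, capped at 1).  The contrast
between protective and risk allele groups compares their signed log
odds ratios (progressor vs nonprogressor, Haldane-Anscombe 0.5
correction) with the two-tailed Welch's t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import welch_t

__all__ = [
    "OverlapTest",
    "AlleleEnrichment",
    "hypergeom_overlap",
    "binom_two_sided",
    "allele_tests",
    "allele_table_tests",
    "log_odds_ratio",
    "enrichment_contrast",
]


@dataclass(frozen=True)
class OverlapTest:
    """Upper-tail hypergeometric test of the overlap of two gene lists."""

    universe: int
    size_a: int
    size_b: int
    overlap: int
    p_value: float


@dataclass(frozen=True)
class AlleleEnrichment:
    """Enrichment of one allele's carriers among progressors vs nonprogressors."""

    allele_id: str
    carriers_prog: int
    n_prog: int
    carriers_nonprog: int
    n_nonprog: int
    expected_freq: float
    p_fisher: float
    p_binomial_prog: float
    p_binomial_nonprog: float
    log_odds: float
    direction: str  # "risk" (carriers enriched in progressors) or "protective"


def hypergeom_overlap(universe: int, size_a: int, size_b: int, overlap: int) -> OverlapTest:
    """P(X >= overlap) for the intersection of two lists from one universe.

    Example: 274 methylation-stable genes against a cluster list from a
    universe of 22,178 tested genes.
    """
    if not (0 <= overlap <= min(size_a, size_b) and max(size_a, size_b) <= universe):
        raise ValueError(
            f"inconsistent counts: universe={universe}, sizes=({size_a}, {size_b}), "
            f"overlap={overlap}"
        )
    p = float(sps.hypergeom.sf(overlap - 1, universe, size_a, size_b))
    return OverlapTest(universe, size_a, size_b, overlap, p)


def binom_two_sided(k: int, n: int, p: float) -> float:
    """Exact binomial two-sided p by doubling the smaller tail, capped at 1."""
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    lower = float(sps.binom.cdf(k, n, p))
    upper = float(sps.binom.sf(k - 1, n, p))
    return min(1.0, 2.0 * min(lower, upper))


def log_odds_ratio(
    carriers_prog: int, n_prog: int, carriers_nonprog: int, n_nonprog: int
) -> float:
    """Signed log odds ratio progressor vs nonprogressor (+0.5 correction)."""
    a = carriers_prog + 0.5
    b = n_prog - carriers_prog + 0.5
    c = carriers_nonprog + 0.5
    d = n_nonprog - carriers_nonprog + 0.5
    return float(np.log((a / b) / (c / d)))


def allele_tests(
    allele_id: str,
    carriers_prog: int,
    n_prog: int,
    carriers_nonprog: int,
    n_nonprog: int,
    expected_freq: float,
) -> AlleleEnrichment:
    """Fisher and binomial tests for one allele's carrier counts.

    Fisher: two-sided on the 2x2 carriers/non-carriers table.
    Binomial: each group's carrier count against the expected
    population frequency.  Direction is "risk" when the carrier
    frequency is higher among progressors.
    """
    if n_prog <= 0 or n_nonprog <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= carriers_prog <= n_prog and 0 <= carriers_nonprog <= n_nonprog):
        raise ValueError("carrier counts exceed group sizes")
    table = [
        [carriers_prog, n_prog - carriers_prog],
        [carriers_nonprog, n_nonprog - carriers_nonprog],
    ]
    p_fisher = float(sps.fisher_exact(table, alternative="two-sided")[1])
    lo = log_odds_ratio(carriers_prog, n_prog, carriers_nonprog, n_nonprog)
    return AlleleEnrichment(
        allele_id=allele_id,
        carriers_prog=carriers_prog,
        n_prog=n_prog,
        carriers_nonprog=carriers_nonprog,
        n_nonprog=n_nonprog,
        expected_freq=expected_freq,
        p_fisher=p_fisher,
        p_binomial_prog=binom_two_sided(carriers_prog, n_prog, expected_freq),
        p_binomial_nonprog=binom_two_sided(carriers_nonprog, n_nonprog, expected_freq),
        log_odds=lo,
        direction="risk" if lo >= 0 else "protective",
    )


def allele_table_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Run :func:`allele_tests` over a SNP table.

    Expected columns: allele_id, carriers_prog, n_prog,
    carriers_nonprog, n_nonprog, expected_freq.
    """
    results = [
        allele_tests(
            str(r.allele_id),
            int(r.carriers_prog),
            int(r.n_prog),
            int(r.carriers_nonprog),
            int(r.n_nonprog),
            float(r.expected_freq),
        )
        for r in table.itertuples(index=False)
    ]
    return pd.DataFrame([vars(r) for r in results])


def enrichment_contrast(protective_scores, risk_scores) -> tuple[float, float]:
    """Welch's t contrast of protective vs risk allele enrichment scores.

    Scores are signed log odds ratios (progressor vs nonprogressor) of
    the two allele groups; opposing enrichment shows up as a
    significant two-tailed Welch's t.
    """
    protective = np.asarray(protective_scores, dtype=float)
    risk = np.asarray(risk_scores, dtype=float)
    if protective.size < 2 or risk.size < 2:
        raise ValueError("each allele group needs >= 2 scores")
    return welch_t(protective, risk)
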