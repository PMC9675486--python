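"""Synthetic cohorts and SNP tables with planted, known structure.

The generator emulates what the network analysis assumes about real
expression data: bimodal per-gene distributions with a clear low and
high mode (default means 4 and 8 on the log2 scale), sample states
ordered along a progression path (NE -> BE -> EAC by default), gene
clusters co-up/co-down per state (planting equivalent / opposite /
asymmetric implications between clusters), uninformative background
genes, Gaussian noise, a configurable rate of near-threshold
"intermediate" measurements, and an optional additive batch shift.
Ground truth (gene -> cluster, sample -> state, the implied relation
between every planted cluster pair) is returned alongside the matrix
so every pipeline stage can be checked without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClusterSpec",
    "SyntheticSpec",
    "GroundTruth",
    "default_spec",
    "implied_relation",
    "generate_cohort",
    "generate_snp_table",
]


@dataclass(frozen=True)
class ClusterSpec:
    """One planted cluster: its size and per-state low/high level."""

    name: str
    size: int
    levels: dict  # state -> "low" | "high"


@dataclass
class SyntheticSpec:
    """Full description of a synthetic cohort.

    Attributes
    ----------
    states : list of (name, n_samples)
        Progression states in order, with per-state sample counts.
    clusters : list of ClusterSpec
    n_background : int
        State-independent genes; half flat (unimodal noise), half
        bimodal with a random, state-unrelated sample split.
    low_mean, high_mean : float
        The two modes, log2 units.
    sigma : float
        Gaussian noise s.d. (log2 units).
    intermediate_rate : float
        Per-entry probability that a cluster-gene measurement lands at
        the threshold midpoint (exercises the INTERMEDIATE code path).
    batch_shift : float
        Additive shift between consecutive batches (0 disables).
    n_batches : int
    background_split : (float, float)
        Range of per-gene LOW fractions for bimodal background genes.
    seed : int
        Fixes the entire output.
    """

    states: list = field(default_factory=lambda: [("NE", 50), ("BE", 50), ("EAC", 50)])
    clusters: list = field(default_factory=list)
    n_background: int = 500
    low_mean: float = 4.0
    high_mean: float = 8.0
    sigma: float = 0.3
    intermediate_rate: float = 0.01
    batch_shift: float = 0.0
    n_batches: int = 1
    background_split: tuple = (0.3, 0.7)
    seed: int = 7

    def __post_init__(self):
        if any(n <= 0 for _, n in self.states):
            raise ValueError("state sample counts must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.intermediate_rate < 1:
            raise ValueError("intermediate_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort or SNP table."""

    gene_to_cluster: dict
    sample_to_state: dict
    implied_relations: list  # (cluster_a, cluster_b, relation from a's side)
    snp_freqs: dict = field(default_factory=dict)


def default_spec(seed: int = 7) -> SyntheticSpec:
    """The default three-state cohort.

    Three 20-gene clusters mirror the seed-gene logic of the
    esophageal continuum: a squamous cluster high only in NE
    (SPINK7-like), a metaplasia cluster high in BE and EAC
    (SLC44A4-like), and a transformation cluster high only in EAC
    (CXCL8-like).  The nested state design automatically plants the
    "CXCL8 high => SLC44A4 high" style asymmetric implication.
    """
    return SyntheticSpec(
        states=[("NE", 50), ("BE", 50), ("EAC", 50)],
        clusters=[
            ClusterSpec("SPINK7", 20, {"NE": "high", "BE": "low", "EAC": "low"}),
            ClusterSpec("SLC44A4", 20, {"NE": "low", "BE": "high", "EAC": "high"}),
            ClusterSpec("CXCL8", 20, {"NE": "low", "BE": "low", "EAC": "high"}),
        ],
        n_background=500,
        sigma=0.3,
        seed=seed,
    )


def implied_relation(levels_a: dict, levels_b: dict, states: list) -> str:
    """Boolean relation implied by two clusters' per-state level designs.

    A quadrant (i, j) is structurally empty when no state puts cluster
    A at level i and cluster B at level j; the empty-quadrant set maps
    to the relation exactly as in the pairwise classifier.
    """
    occupied = {
        (1 if levels_a[s] == "high" else 0, 1 if levels_b[s] == "high" else 0)
        for s in states
    }
    empty = {(0, 0), (0, 1), (1, 0), (1, 1)} - occupied
    if empty == {(0, 1), (1, 0)}:
        return "equivalent"
    if empty == {(0, 0), (1, 1)}:
        return "opposite"
    mapping = {(0, 0): "low=>high", (0, 1): "low=>low", (1, 0): "high=>high", (1, 1): "high=>low"}
    if len(empty) == 1:
        return mapping[next(iter(empty))]
    return "none"


def generate_cohort(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw an expression matrix, sample annotations, and ground truth.

    Cluster genes are Normal(state level mean, sigma); flat background
    genes are Normal(midpoint, sigma); bimodal background genes split
    samples at random, independent of state.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    state_names = [s for s, _ in spec.states]
    sample_ids = []
    sample_states = []
    for state, count in spec.states:
        for i in range(count):
            sample_ids.append(f"{state}_{i + 1:03d}")
            sample_states.append(state)
    n_samples = len(sample_ids)
    state_arr = np.asarray(sample_states)
    midpoint = (spec.low_mean + spec.high_mean) / 2.0

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    gene_to_cluster: dict[str, str] = {}

    for cluster in spec.clusters:
        means = np.where(
            np.isin(state_arr, [s for s in state_names if cluster.levels[s] == "high"]),
            spec.high_mean,
            spec.low_mean,
        ).astype(float)
        for gi in range(cluster.size):
            gene = cluster.name if gi == 0 else f"{cluster.name}_{gi + 1:02d}"
            values = rng.normal(means, spec.sigma)
            if spec.intermediate_rate > 0:
                mid = rng.random(n_samples) < spec.intermediate_rate
                values[mid] = midpoint + rng.uniform(-0.1, 0.1, int(mid.sum()))
            gene_ids.append(gene)
            rows.append(values)
            gene_to_cluster[gene] = cluster.name

    n_flat = spec.n_background // 2
    for bi in range(spec.n_background):
        gene = f"BG{bi + 1:04d}"
        if bi < n_flat:
            values = rng.normal(midpoint, spec.sigma, n_samples)
        else:
            frac_low = rng.uniform(*spec.background_split)
            is_low = rng.random(n_samples) < frac_low
            values = rng.normal(np.where(is_low, spec.low_mean, spec.high_mean), spec.sigma)
        gene_ids.append(gene)
        rows.append(values)
        gene_to_cluster[gene] = "background"

    matrix = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=sample_ids)

    batches = np.arange(n_samples) % spec.n_batches
    if spec.n_batches > 1 and spec.batch_shift != 0.0:
        matrix = matrix.add(pd.Series(batches * spec.batch_shift, index=sample_ids), axis=1)

    annotations = pd.DataFrame(
        {"sample_id": sample_ids, "class_label": sample_states, "batch": batches}
    ).set_index("sample_id")

    implied = []
    for i, ca in enumerate(spec.clusters):
        for cb in spec.clusters[i + 1 :]:
            rel = implied_relation(ca.levels, cb.levels, state_names)
            if rel != "none":
                implied.append((ca.name, cb.name, rel))
    truth = GroundTruth(
        gene_to_cluster=gene_to_cluster,
        sample_to_state=dict(zip(sample_ids, sample_states)),
        implied_relations=implied,
    )
    return matrix, annotations, truth


def generate_snp_table(
    n_prog: int,
    n_nonprog: int,
    alleles: list[dict],
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw binomial carrier counts for a case/control SNP table.

    ``alleles`` is a list of dicts with keys allele_id, freq_prog,
    freq_nonprog and optionally expected_freq (defaults to the mean of
    the two) and group ("risk"/"protective", recorded in the table).
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    for allele in alleles:
        fp, fn = float(allele["freq_prog"]), float(allele["freq_nonprog"])
        if not (0 <= fp <= 1 and 0 <= fn <= 1):
            raise ValueError("carrier frequencies must lie in [0, 1]")
        rows.append(
            {
                "allele_id": allele["allele_id"],
                "carriers_prog": int(rng.binomial(n_prog, fp)),
                "n_prog": n_prog,
                "carriers_nonprog": int(rng.binomial(n_nonprog, fn)),
                "n_nonprog": n_nonprog,
                "expected_freq": float(allele.get("expected_freq", (fp + fn) / 2.0)),
                "group": allele.get("group", ""),
            }
        )
        truth[allele["allele_id"]] = (fp, fn)
    table = pd.DataFrame(rows)
    return table, GroundTruth(
        gene_to_cluster={}, sample_to_state={}, implied_relations=[], snp_freqs=truth
    )
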