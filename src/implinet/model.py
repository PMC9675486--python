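"""Model/Results facade over the Boolean implication network pipeline.

`BooleanImplicationNetwork` holds an expression matrix plus the
pipeline's tuning parameters; `fit()` binarizes every gene, classifies
every informative pair into a Boolean implication relation, groups
equivalent genes into clusters and assembles the directed cluster
graph, optionally estimating a permutation FDR.  The returned
`BooleanNetworkResults` carries the intermediate artifacts and exposes
signature selection, composite scoring, classification reports,
progression-state assignment and invariance checks, and basic plots.
"""

from __future__ import annotations

import pandas as pd

from . import booleannet, network, progression, scoring, stepminer

__all__ = ["BooleanImplicationNetwork", "BooleanNetworkResults"]


class BooleanImplicationNetwork:
    """Boolean implication network model of an expression cohort.

    Parameters
    ----------
    data : DataFrame
        Genes x samples expression, log2 scale, NaN for missing.
    annotations : DataFrame, optional
        Sample annotations indexed by sample id with a ``class_label``
        column (used for signature selection and reports).
    margin : float
        Intermediate half-width around each gene's step threshold
        (log2 units).
    min_range, min_per_side : float, int
        Informativeness filter: minimum dynamic range and minimum
        samples coded LOW and HIGH.
    s_min, p_max : float
        Sparse-quadrant cutoffs (S > s_min and p_err < p_max).
    min_samples : int
        Minimum usable samples for a pair to be classified.
    min_share : float
        Minimum shared-equivalence fraction for cluster membership.
    min_edge_support : float
        Minimum cross-pair support for a cluster-graph edge.
    normalize_scale : float
        Divisor of threshold-centered expression in composite scores.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        annotations: pd.DataFrame | None = None,
        *,
        margin: float = 0.5,
        min_range: float = 1.0,
        min_per_side: int = 3,
        s_min: float = 3.0,
        p_max: float = 0.1,
        min_samples: int = 20,
        min_share: float = 0.5,
        min_edge_support: float = 0.5,
        normalize_scale: float = 3.0,
    ):
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique()
            raise ValueError(f"duplicate gene id(s): {', '.join(map(str, dups[:10]))}")
        if data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if annotations is not None:
            unknown = [s for s in annotations.index if s not in data.columns]
            if unknown:
                raise ValueError(
                    f"annotated sample(s) absent from matrix: {', '.join(map(str, unknown[:10]))}"
                )
        self.data = data
        self.annotations = annotations
        self.margin = margin
        self.min_range = min_range
        self.min_per_side = min_per_side
        self.s_min = s_min
        self.p_max = p_max
        self.min_samples = min_samples
        self.min_share = min_share
        self.min_edge_support = min_edge_support
        self.normalize_scale = normalize_scale

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, annotations: pd.DataFrame | None = None, **params
    ) -> "BooleanImplicationNetwork":
        return cls(data, annotations, **params)

    def fit(
        self, n_permutations: int = 0, seed: int | None = None
    ) -> "BooleanNetworkResults":
        """Run binarization, pair classification, clustering and graph assembly.

        ``n_permutations`` > 0 additionally estimates the network-level
        permutation FDR with the given seed.
        """
        ternary = stepminer.ternarize(
            self.data,
            margin=self.margin,
            min_range=self.min_range,
            min_per_side=self.min_per_side,
        )
        implications = booleannet.all_pairs(
            ternary, s_min=self.s_min, p_max=self.p_max, min_samples=self.min_samples
        )
        clusters = network.build_clusters(
            implications, min_share=self.min_share, genes=list(ternary.informative_codes().index)
        )
        graph = network.build_cluster_graph(
            clusters, implications, min_edge_support=self.min_edge_support
        )
        fdr = None
        if n_permutations > 0:
            fdr = booleannet.permutation_fdr(
                ternary,
                s_min=self.s_min,
                p_max=self.p_max,
                min_samples=self.min_samples,
                n_perm=n_permutations,
                seed=seed,
            )
        return BooleanNetworkResults(self, ternary, implications, clusters, graph, fdr)


class BooleanNetworkResults:
    """Fitted Boolean implication network.

    Attributes
    ----------
    model : BooleanImplicationNetwork
    ternary : TernaryMatrix
    implications : DataFrame
        One row per unordered informative gene pair.
    clusters : list of GeneCluster
    cluster_graph : ClusterGraph
    fdr : float or None
        Network-level permutation FDR when requested at fit time.
    """

    def __init__(self, model, ternary, implications, clusters, cluster_graph, fdr=None):
        self.model = model
        self.ternary = ternary
        self.implications = implications
        self.clusters = clusters
        self.cluster_graph = cluster_graph
        self.fdr = fdr

    # -- summaries ---------------------------------------------------------

    def relation_counts(self) -> pd.Series:
        sig = self.implications[self.implications["passes"]]
        return sig["relation"].value_counts()

    def summary(self) -> str:
        """Plain-text overview of the fitted network."""
        n_genes, n_samples = self.model.data.shape
        n_inf = int(self.ternary.informative.sum())
        counts = self.relation_counts()
        lines = [
            "Boolean Implication Network Results",
            "=" * 37,
            f"Samples:                {n_samples}",
            f"Genes:                  {n_genes} ({n_inf} informative)",
            f"Pairs classified:       {len(self.implications)}",
            f"Significant relations:  {int(counts.sum())}",
        ]
        for name in booleannet.RELATIONS[:-1]:
            if counts.get(name, 0):
                lines.append(f"  {name:<12} {int(counts[name])}")
        lines.append(f"Clusters:               {len(self.clusters)}")
        multi = [c for c in self.clusters if len(c) > 1]
        if multi:
            lines.append("  " + ", ".join(f"{c.cluster_id}[{c.seed_gene}] n={len(c)}" for c in multi[:8]))
        lines.append(f"Cluster-graph edges:    {self.cluster_graph.graph.number_of_edges()}")
        if self.fdr is not None:
            lines.append(f"Permutation FDR:        {self.fdr:.4g}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<BooleanNetworkResults: {len(self.clusters)} clusters, "
            f"{int(self.implications['passes'].sum())} significant relations>"
        )

    # -- signatures and scores --------------------------------------------

    def _labels(self, labels: pd.Series | None) -> pd.Series:
        if labels is not None:
            return labels
        if self.model.annotations is None or "class_label" not in self.model.annotations:
            raise ValueError("no labels supplied and model has no class_label annotations")
        return self.model.annotations["class_label"]

    def select_signature(
        self,
        case_label: str,
        control_label: str | None = None,
        labels: pd.Series | None = None,
        max_len: int = 3,
    ) -> list[network.SignaturePath]:
        """Rank candidate signature paths by training ROC-AUC."""
        return network.select_signature(
            self.cluster_graph,
            self.model.data,
            self.ternary.fits,
            self._labels(labels),
            case_label,
            control_label,
            max_len=max_len,
            scale=self.model.normalize_scale,
        )

    def composite_scores(self, path: network.SignaturePath, ternary_codes: bool = False) -> pd.Series:
        """Per-sample composite score of a signature path."""
        members = self.cluster_graph.members_by_id
        if ternary_codes:
            return scoring.ternary_composite_score(path, self.ternary, members)
        return scoring.composite_score(
            path, self.model.data, self.ternary.fits, members, scale=self.model.normalize_scale
        )

    def classification_report(
        self,
        path: network.SignaturePath,
        case_label: str,
        control_label: str | None = None,
        labels: pd.Series | None = None,
    ) -> scoring.ClassificationReport:
        scores = self.composite_scores(path)
        return scoring.classification_report(scores, self._labels(labels), case_label, control_label)

    # -- progression -------------------------------------------------------

    def assign_states(self, model: progression.ProgressionModel) -> pd.DataFrame:
        return progression.assign_states(model, self.ternary)

    def check_invariance(self, model: progression.ProgressionModel) -> pd.DataFrame:
        return progression.check_invariance(
            model, self.ternary, s_min=self.model.s_min, p_max=self.model.p_max
        )

    # -- plots -------------------------------------------------------------

    def plot_scores(self, path, case_label=None, labels=None, ax=None):
        """Strip/violin-style plot of composite scores by class label."""
        import matplotlib.pyplot as plt

        scores = self.composite_scores(path)
        labels = self._labels(labels).reindex(scores.index)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        classes = [c for c in pd.unique(labels.dropna())]
        data = [scores[labels == c].dropna() for c in classes]
        ax.violinplot(data, showmeans=True)
        ax.set_xticks(range(1, len(classes) + 1), classes)
        ax.set_ylabel("composite score")
        ax.set_title(str(path))
        return ax

    def plot_roc(self, path, case_label, control_label=None, labels=None, ax=None):
        """ROC curve of a signature path's composite score."""
        import matplotlib.pyplot as plt
        from sklearn.metrics import roc_curve

        scores = self.composite_scores(path)
        labels = self._labels(labels).reindex(scores.index)
        if control_label is None:
            mask = labels.notna() & scores.notna()
        else:
            mask = labels.isin([case_label, control_label]) & scores.notna()
        y = (labels[mask] == case_label).astype(int)
        fpr, tpr, _ = roc_curve(y, scores[mask])
        auc = scoring.roc_auc(scores[mask].to_numpy(), y.to_numpy())
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(fpr, tpr, label=f"AUC = {auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax
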