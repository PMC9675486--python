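"""Seed-gene Boolean progression models.

Ordered disease states are defined as quadrant constraints on a few
seed genes (for the esophageal continuum: NE = SPINK7 high & SLC44A4
low & CXCL8 low, BE = SLC44A4 high & CXCL8 low, EAC = SLC44A4 high &
CXCL8 high).  A sample is assigned to a state only when exactly one
state's constraints are fully satisfied by its ternary codes; the
model's implied implications (e.g. CXCL8 high => SLC44A4 high) are
checked for invariance with the same sparse-quadrant statistic used
pair-wise, so a forbidden quadrant (CXCL8 high & SLC44A4 low) that is
not sparse falsifies the ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .booleannet import quadrant_counts, sparseness
from .stepminer import HIGH, LOW, TernaryMatrix

__all__ = [
    "ProgressionModel",
    "StateAssignment",
    "assign_states",
    "confusion_table",
    "check_invariance",
    "default_esophagus_model",
    "read_model",
    "write_model",
]

UNASSIGNED = "UNASSIGNED"

_CODE_OF = {"low": LOW, "high": HIGH}


@dataclass
class ProgressionModel:
    """Ordered states defined by required LOW/HIGH codes of seed genes.

    Attributes
    ----------
    states : list of str
        Disease states in progression order.
    constraints : dict
        state -> {gene: "low" | "high"}.
    implications : list of tuples
        Model-implied invariants as (gene_a, state_a, gene_b, state_b),
        read "gene_a at state_a implies gene_b at state_b".
    """

    states: list[str]
    constraints: dict[str, dict[str, str]]
    implications: list[tuple[str, str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        for s in self.states:
            self.constraints.setdefault(s, {})
        for s, cons in self.constraints.items():
            if s not in self.states:
                raise ValueError(f"constraints refer to unknown state {s!r}")
            for g, code in cons.items():
                if code not in _CODE_OF:
                    raise ValueError(f"constraint {s}/{g}: code must be 'low' or 'high'")
        for prev, nxt in zip(self.states, self.states[1:]):
            a, b = self.constraints[prev], self.constraints[nxt]
            if a and b and a == b:
                raise ValueError(f"consecutive states {prev!r} and {nxt!r} are identical")

    @property
    def seed_genes(self) -> list[str]:
        genes: list[str] = []
        for s in self.states:
            for g in self.constraints[s]:
                if g not in genes:
                    genes.append(g)
        return genes


@dataclass(frozen=True)
class StateAssignment:
    sample_id: str
    state: str  # a model state or UNASSIGNED
    matched_constraints: int


def default_esophagus_model() -> ProgressionModel:
    """The three-seed-gene NE -> BE -> EAC model.

    BE (SLC44A4 high, CXCL8 low) precedes EAC (SLC44A4 high, CXCL8
    high); the quadrant CXCL8 high & SLC44A4 low is forbidden, which is
    exactly the invariant "CXCL8 high => SLC44A4 high".  SPINK7 marks
    the normal squamous epithelium.
    """
    return ProgressionModel(
        states=["NE", "BE", "EAC"],
        constraints={
            "NE": {"SPINK7": "high", "SLC44A4": "low", "CXCL8": "low"},
            "BE": {"SPINK7": "low", "SLC44A4": "high", "CXCL8": "low"},
            "EAC": {"SPINK7": "low", "SLC44A4": "high", "CXCL8": "high"},
        },
        implications=[
            ("SPINK7", "high", "SLC44A4", "low"),
            ("CXCL8", "high", "SLC44A4", "high"),
        ],
    )


def assign_states(model: ProgressionModel, ternary: TernaryMatrix) -> pd.DataFrame:
    """Assign each sample to the unique state whose constraints it meets.

    A sample is UNASSIGNED when any constraint gene is INTERMEDIATE or
    MISSING, or when zero or more than one state matches fully.

    Returns a DataFrame indexed by sample with columns ``state`` and
    ``matched_constraints`` (constraint count of the matched state, 0
    when unassigned).

    Raises
    ------
    KeyError
        If a constraint gene is absent from the ternary matrix.
    """
    genes = model.seed_genes
    missing = [g for g in genes if g not in ternary.codes.index]
    if missing:
        raise KeyError(f"constraint gene(s) absent from matrix: {', '.join(missing)}")
    codes = ternary.codes.loc[genes]

    binarized = codes.isin([LOW, HIGH]).all(axis=0)
    states = []
    matched = []
    for sample in codes.columns:
        col = codes[sample]
        if not binarized[sample]:
            states.append(UNASSIGNED)
            matched.append(0)
            continue
        hits = [
            s
            for s in model.states
            if model.constraints[s]
            and all(col[g] == _CODE_OF[c] for g, c in model.constraints[s].items())
        ]
        if len(hits) == 1:
            states.append(hits[0])
            matched.append(len(model.constraints[hits[0]]))
        else:
            states.append(UNASSIGNED)
            matched.append(0)
    return pd.DataFrame(
        {"state": states, "matched_constraints": matched}, index=codes.columns
    )


def confusion_table(assignments: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Cross-tabulate assigned states against annotated class labels."""
    labels = labels.reindex(assignments.index)
    return pd.crosstab(labels, assignments["state"], dropna=False)


def check_invariance(
    model: ProgressionModel,
    ternary: TernaryMatrix,
    s_min: float = 3.0,
    p_max: float = 0.1,
) -> pd.DataFrame:
    """Test each model-implied implication with the sparse-quadrant statistic.

    For "gene_a at state_a => gene_b at state_b" the forbidden quadrant
    is (gene_a = state_a, gene_b = NOT state_b); the implication passes
    when that quadrant is sparse (S > s_min, p_err < p_max).  The
    report also gives the fraction of binarized samples falling in the
    forbidden quadrant.  Untestable pairs (empty row/column) fail with
    a reason.  An empty implication list returns an empty, vacuously
    passing report (warned).
    """
    if not model.implications:
        import warnings

        warnings.warn("model declares no implications; invariance check is vacuous", stacklevel=2)
    rows = []
    for gene_a, state_a, gene_b, state_b in model.implications:
        for g in (gene_a, gene_b):
            if g not in ternary.codes.index:
                raise KeyError(f"implication gene absent from matrix: {g}")
        a = ternary.codes.loc[gene_a].to_numpy()
        b = ternary.codes.loc[gene_b].to_numpy()
        counts = quadrant_counts(a, b)
        quadrant = (_CODE_OF[state_a], 1 - _CODE_OF[state_b])
        s, p_err = sparseness(counts, quadrant)
        forbidden = counts.observed(quadrant)
        frac = forbidden / counts.n if counts.n else np.nan
        if not np.isfinite(s):
            passes, reason = False, "untestable quadrant (empty row or column)"
        else:
            passes = bool(s > s_min and p_err < p_max)
            reason = "" if passes else "quadrant not sparse"
        rows.append(
            {
                "implication": f"{gene_a} {state_a} => {gene_b} {state_b}",
                "S": s,
                "p_err": p_err,
                "forbidden_fraction": frac,
                "n_usable": counts.n,
                "passes": passes,
                "reason": reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["implication", "S", "p_err", "forbidden_fraction", "n_usable", "passes", "reason"],
    )


# ---------------------------------------------------------------------------
# Declarative model files: lines are
#   state <name> <gene>=<high|low> [<gene>=<high|low> ...]
#   implication <gene_a> <high|low> => <gene_b> <high|low>
# '#' starts a comment; state order is file order.


def read_model(path) -> ProgressionModel:
    states: list[str] = []
    constraints: dict[str, dict[str, str]] = {}
    implications: list[tuple[str, str, str, str]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if tokens[0] == "state":
            if len(tokens) < 3:
                raise ValueError(f"{path}:{lineno}: state line needs a name and constraints")
            name = tokens[1]
            if name not in states:
                states.append(name)
            cons = constraints.setdefault(name, {})
            for tok in tokens[2:]:
                gene, _, code = tok.partition("=")
                if code.lower() not in _CODE_OF:
                    raise ValueError(f"{path}:{lineno}: bad constraint {tok!r}")
                cons[gene] = code.lower()
        elif tokens[0] == "implication":
            if len(tokens) != 6 or tokens[3] != "=>":
                raise ValueError(
                    f"{path}:{lineno}: expected 'implication GENE high|low => GENE high|low'"
                )
            implications.append((tokens[1], tokens[2].lower(), tokens[4], tokens[5].lower()))
        else:
            raise ValueError(f"{path}:{lineno}: unknown directive {tokens[0]!r}")
    return ProgressionModel(states=states, constraints=constraints, implications=implications)


def write_model(model: ProgressionModel, path) -> None:
    lines = []
    for s in model.states:
        cons = " ".join(f"{g}={c}" for g, c in model.constraints[s].items())
        lines.append(f"state {s} {cons}".rstrip())
    for ga, sa, gb, sb in model.implications:
        lines.append(f"implication {ga} {sa} => {gb} {sb}")
    Path(path).write_text("\n".join(lines) + "\n")
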