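"""Set logic for factor-regulated genes and per-mutant dysregulation calls.

A gene is *differentially expressed* in a contrast if its BH-adjusted p is
below alpha AND it reaches the INT or HE expression class in at least one
replicate of at least one of the two conditions (genes that stay NE/LE on
both sides are ignored).  A gene is *factor-regulated and lineage-relevant*
if it is differential both in the ex vivo lineage contrast (naive helper
vs regulatory T cells) and in the transduction contrast (control vs
factor-transduced helper cells); its direction is the sign of the fold
change induced by the factor.

Per deletion mutant, a regulated gene is *dysregulated* if it differs
significantly from the full-length factor condition AND the change points
back toward the control baseline; any other outcome — no significant
change, or a significant change that exaggerates the factor's effect —
counts as *retained* control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from foxdissect.de import DEResult
from foxdissect.io import CountMatrix


@dataclass
class RegulationTable:
    """Per-gene regulation call.

    ``table`` columns: ``regulated`` (bool), ``direction`` ('up'/'down',
    NaN when not regulated) and one ``status_<mutant>`` column per mutant
    with values retained/dysregulated/untested.
    """

    table: pd.DataFrame
    mutants: list[str] = field(default_factory=list)

    @property
    def regulated_genes(self) -> pd.Index:
        return self.table.index[self.table["regulated"]]

    def dysregulated(self, mutant: str) -> pd.Index:
        col = f"status_{mutant}"
        return self.table.index[self.table[col] == "dysregulated"]

    def retained(self, mutant: str) -> pd.Index:
        col = f"status_{mutant}"
        return self.table.index[self.table[col] == "retained"]


def _expressed_filter(classes: pd.DataFrame, cm: CountMatrix,
                      condition_a: str, condition_b: str) -> pd.Series:
    """True where the gene is INT or HE in >=1 replicate of either condition."""
    samples = cm.samples_of(condition_a) + cm.samples_of(condition_b)
    missing = [s for s in samples if s not in classes.columns]
    if missing:
        raise ValueError(f"missing class labels for samples: {missing}")
    sub = classes[samples]
    return sub.isin(["INT", "HE"]).any(axis=1)


def call_differential(de: DEResult, classes: pd.DataFrame, cm: CountMatrix,
                      alpha: float = 0.05) -> pd.Series:
    """Differential-expression call for one contrast (boolean per gene)."""
    padj_ok = de.table["padj"] < alpha
    expr_ok = _expressed_filter(classes, cm, de.contrast.condition_A,
                                de.contrast.condition_B)
    return (padj_ok & expr_ok).rename("differential")


def call_regulated(de_lineage: DEResult, de_factor: DEResult,
                   classes: pd.DataFrame, cm: CountMatrix,
                   alpha: float = 0.05) -> RegulationTable:
    """Intersect the lineage and transduction contrasts into a regulated set.

    ``de_factor`` must be oriented with the factor condition as B so that
    a positive fold change means upregulation by the factor.
    """
    if not de_lineage.table.index.equals(de_factor.table.index):
        raise ValueError("mismatched gene universes between the two DE results")
    d1 = call_differential(de_lineage, classes, cm, alpha)
    d2 = call_differential(de_factor, classes, cm, alpha)
    regulated = d1 & d2
    direction = pd.Series(pd.NA, index=regulated.index, dtype=object)
    up = de_factor.table["log2fc"] > 0
    direction[regulated & up] = "up"
    direction[regulated & ~up] = "down"
    table = pd.DataFrame({"regulated": regulated, "direction": direction})
    return RegulationTable(table=table)


def call_mutant_status(regulation: RegulationTable, mutant: str,
                       de_factor_vs_mutant: DEResult,
                       alpha: float = 0.05) -> RegulationTable:
    """Classify each regulated gene as retained or dysregulated in a mutant.

    ``de_factor_vs_mutant`` must be oriented A = full-length factor,
    B = mutant, so its fold change is the mutant's expression relative to
    the factor condition.  Dysregulated requires significance AND movement
    toward the control baseline: down for factor-upregulated genes, up for
    factor-downregulated genes.  Adds a ``status_<mutant>`` column in place
    and returns the table.
    """
    t = regulation.table
    de = de_factor_vs_mutant.table
    if not t.index.equals(de.index):
        raise ValueError("mismatched gene universes")
    sig = de["padj"] < alpha
    toward_control = pd.Series(False, index=t.index)
    toward_control[(t["direction"] == "up") & (de["log2fc"] < 0)] = True
    toward_control[(t["direction"] == "down") & (de["log2fc"] > 0)] = True
    status = pd.Series("untested", index=t.index, dtype=object)
    reg = t["regulated"].astype(bool)
    status[reg] = "retained"
    status[reg & sig & toward_control] = "dysregulated"
    t[f"status_{mutant}"] = status
    if mutant not in regulation.mutants:
        regulation.mutants.append(mutant)
    # hard invariant: dysregulated implies regulated
    assert (t.loc[status == "dysregulated", "regulated"]).all()
    return regulation


def summarize_sets(regulation: RegulationTable) -> dict:
    """Per-mutant dysregulated/retained counts by direction plus Venn sizes."""
    t = regulation.table
    out = {
        "n_regulated": int(t["regulated"].sum()),
        "n_up": int((t["direction"] == "up").sum()),
        "n_down": int((t["direction"] == "down").sum()),
        "mutants": {},
        "pairwise_dysregulated_overlap": {},
    }
    for m in regulation.mutants:
        s = t[f"status_{m}"]
        dys = s == "dysregulated"
        out["mutants"][m] = {
            "dysregulated": int(dys.sum()),
            "dysregulated_up": int((dys & (t["direction"] == "up")).sum()),
            "dysregulated_down": int((dys & (t["direction"] == "down")).sum()),
            "retained": int((s == "retained").sum()),
        }
    for m1, m2 in combinations(regulation.mutants, 2):
        inter = set(regulation.dysregulated(m1)) & set(regulation.dysregulated(m2))
        out["pairwise_dysregulated_overlap"][f"{m1}&{m2}"] = len(inter)
    return out
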