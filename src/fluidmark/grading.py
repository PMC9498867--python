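"""Hierarchical specificity/expression grading of ASMs and cluster-based
validation.

Specificity of one comparison is graded on its log2 fold change:
level I (1, 2], II (2, 3], III (3, 4], IV (> 4).  Expression is graded on
the marker's target-group mean EXP: level I (1, 10], II (10, 100],
III (100, 1000], IV (> 1000), with linear-tercile sublevels "+", "++",
"+++" inside levels I-III (left-closed, right-open; the last tercile
absorbs the interval's upper bound).  A mean EXP of 376.19 therefore
grades to level III "+" (tercile boundaries 400 and 700).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix, SampleSheet

SPECIFICITY_LEVELS = ("I", "II", "III", "IV")
_SPECIFICITY_EDGES = (1.0, 2.0, 3.0, 4.0)  # (edge_k, edge_{k+1}] per level
_EXPRESSION_INTERVALS = {
    "I": (1.0, 10.0),
    "II": (10.0, 100.0),
    "III": (100.0, 1000.0),
}


@dataclass
class GradeRecord:
    rna_id: str
    group: str
    specificity_counts: dict[str, int] = field(default_factory=dict)
    expression_level: str | None = None
    expression_sub: str | None = None  # "+", "++", "+++" or None for level IV
    mean_exp: float = float("nan")


def grade_specificity(log2fc: float) -> str | None:
    """Specificity level of one comparison; None when log2FC <= 1."""
    if log2fc <= 1.0:
        return None
    if log2fc <= 2.0:
        return "I"
    if log2fc <= 3.0:
        return "II"
    if log2fc <= 4.0:
        return "III"
    return "IV"


def grade_expression(mean_exp: float) -> tuple[str, str | None] | None:
    """Expression level and tercile sublevel; None when mean EXP <= 1."""
    if mean_exp < 0:
        raise ValueError("mean EXP must be nonnegative")
    if mean_exp <= 1.0:
        return None
    if mean_exp > 1000.0:
        return "IV", None
    for level, (lo, hi) in _EXPRESSION_INTERVALS.items():
        if lo < mean_exp <= hi:
            width = hi - lo
            if mean_exp < lo + width / 3.0:
                return level, "+"
            if mean_exp < lo + 2.0 * width / 3.0:
                return level, "++"
            return level, "+++"
    raise AssertionError("unreachable")


def build_grade_table(
    asm: pd.DataFrame,
    exp: ExpressionMatrix,
) -> tuple[list[GradeRecord], pd.DataFrame]:
    """Grade every ASM: bin its five comparisons by specificity level and
    grade the target-group mean expression.

    ``asm`` is the long-format ASM frame (five rows per marker).  Rows of
    the rendered table are sorted by group, then descending mean EXP.
    """
    records: list[GradeRecord] = []
    if not asm.empty:
        for (rna_id, group), sub in asm.groupby(["rna_id", "target_group"]):
            counts = {lvl: 0 for lvl in SPECIFICITY_LEVELS}
            for lfc in sub["log2fc"]:
                lvl = grade_specificity(float(lfc))
                if lvl is not None:
                    counts[lvl] += 1
            mean_exp = float(exp.group_means.loc[rna_id, group])
            graded = grade_expression(mean_exp)
            level, sublevel = graded if graded is not None else (None, None)
            records.append(
                GradeRecord(
                    rna_id=str(rna_id),
                    group=str(group),
                    specificity_counts=counts,
                    expression_level=level,
                    expression_sub=sublevel,
                    mean_exp=mean_exp,
                )
            )
    records.sort(key=lambda r: (r.group, -r.mean_exp, r.rna_id))
    rows = [
        {
            "group": r.group,
            "rna_id": r.rna_id,
            **{f"spec_{lvl}": r.specificity_counts.get(lvl, 0)
               for lvl in SPECIFICITY_LEVELS},
            "expression_level": r.expression_level or "",
            "expression_sub": r.expression_sub or "",
            "mean_exp": r.mean_exp,
        }
        for r in records
    ]
    cols = ["group", "rna_id", "spec_I", "spec_II", "spec_III", "spec_IV",
            "expression_level", "expression_sub", "mean_exp"]
    return records, pd.DataFrame(rows, columns=cols)


def cluster_validate(
    exp: ExpressionMatrix,
    sample_sheet: SampleSheet,
    marker_ids: Sequence[str],
    n_clusters: int = 6,
    method: str = "average",
) -> tuple[list[str], float]:
    """Agglomerative clustering of samples on Euclidean distance over the
    marker expression rows; returns (dendrogram leaf order, purity).

    Purity is the fraction of samples whose cluster's majority group
    matches their own group after cutting the tree into ``n_clusters``.
    """
    ids = [r for r in marker_ids if r in exp.exp.index]
    if not ids:
        raise ValueError("no marker rows present in the expression matrix")
    mat = exp.exp.loc[ids].to_numpy().T  # samples x markers
    samples = list(exp.exp.columns)
    if len(samples) == 1:
        return samples, 1.0
    link = linkage(pdist(mat, metric="euclidean"), method=method)
    order = [samples[i] for i in leaves_list(link)]
    labels = fcluster(link, t=min(n_clusters, len(samples)), criterion="maxclust")
    groups = np.array([sample_sheet.group_of(s) for s in samples])
    correct = 0
    for cl in np.unique(labels):
        members = groups[labels == cl]
        correct += int(pd.Series(members).value_counts().max())
    purity = correct / len(samples)
    return order, purity
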