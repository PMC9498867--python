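"""Screening of relative (RSM) and absolute (ASM) specific markers and
candidate reference genes.

An RSM distinguishes the two members of one group pair: log2FC above 1
toward its target group with q below 0.05.  An ASM is over-expressed in
its group against *every* one of the other five groups under the same
thresholds, so it can identify one fluid/tissue out of all six.  Reference
genes are expressed in every sample and ranked by the stability of their
log-expression across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

Q_THRESHOLD = 0.05
LFC_THRESHOLD = 1.0


@dataclass
class MarkerCall:
    """One marker with its per-comparison evidence.

    ``per_comparison`` maps (group_a, group_b) of the underlying DE pair to
    (log2fc oriented target-over-other, q_value).  RSM calls carry exactly
    one comparison; ASM calls exactly five.
    """

    rna_id: str
    marker_type: str  # "RSM" | "ASM" | "reference"
    target_group: str | None
    per_comparison: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    mean_exp_target: float = float("nan")


def call_rsm(
    de: Mapping[tuple[str, str], pd.DataFrame],
    q_threshold: float = Q_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
) -> pd.DataFrame:
    """RSMs for every pair: strict log2FC > threshold toward the target.

    Returns a frame with one row per (pair, RNA, target group); ``log2fc``
    is oriented target-over-other.
    """
    rows = []
    for (a, b), frame in sorted(de.items()):
        sig = frame[frame["q_value"] < q_threshold]
        for row in sig.itertuples():
            if row.log2fc > lfc_threshold:
                target, other, lfc = a, b, row.log2fc
            elif row.log2fc < -lfc_threshold:
                target, other, lfc = b, a, -row.log2fc
            else:
                continue
            rows.append(
                {
                    "rna_id": row.rna_id,
                    "target_group": target,
                    "other_group": other,
                    "group_a": a,
                    "group_b": b,
                    "log2fc": lfc,
                    "q_value": row.q_value,
                }
            )
    cols = ["rna_id", "target_group", "other_group", "group_a", "group_b",
            "log2fc", "q_value"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["group_a", "group_b", "target_group", "rna_id"],
                           kind="mergesort").reset_index(drop=True)


def call_asm(
    de: Mapping[tuple[str, str], pd.DataFrame],
    groups: list[str] | None = None,
    q_threshold: float = Q_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
) -> pd.DataFrame:
    """ASMs: over-expressed against all five other groups.

    Returns a long frame with five rows per ASM (one per comparison),
    ``log2fc`` oriented target-over-other.  Only over-expression counts:
    an RNA consistently *under*-expressed in a group is not an ASM.
    """
    if groups is None:
        groups = sorted({g for pair in de for g in pair})
    rows = []
    for g in groups:
        others = [h for h in groups if h != g]
        # oriented evidence per RNA: rna_id -> {other: (lfc, q)}
        evidence: dict[str, dict[str, tuple[float, float]]] = {}
        for h in others:
            pair = (g, h) if (g, h) in de else (h, g)
            frame = de.get(pair)
            if frame is None:
                continue  # untested pair: cannot supply ASM evidence
            sign = 1.0 if pair == (g, h) else -1.0
            for row in frame.itertuples():
                lfc = sign * row.log2fc
                if lfc > lfc_threshold and row.q_value < q_threshold:
                    evidence.setdefault(row.rna_id, {})[h] = (lfc, row.q_value)
        for rna_id in sorted(evidence):
            if len(evidence[rna_id]) == len(others):
                for h in others:
                    lfc, q = evidence[rna_id][h]
                    rows.append(
                        {
                            "rna_id": rna_id,
                            "target_group": g,
                            "other_group": h,
                            "log2fc": lfc,
                            "q_value": q,
                        }
                    )
    cols = ["rna_id", "target_group", "other_group", "log2fc", "q_value"]
    return pd.DataFrame(rows, columns=cols)


def asm_groups(asm: pd.DataFrame) -> dict[str, list[str]]:
    """Map group -> sorted ASM rna_ids from a long-format ASM frame."""
    out: dict[str, list[str]] = {}
    if asm.empty:
        return out
    for g, sub in asm.groupby("target_group"):
        out[str(g)] = sorted(sub["rna_id"].unique())
    return out


def screen_reference_genes(
    exp: ExpressionMatrix,
    k: int = 10,
    min_exp: float = 1.0,
) -> tuple[pd.DataFrame, bool]:
    """Rank candidate reference genes by log-expression stability.

    Candidates must have EXP > ``min_exp`` in every sample.  The stability
    score is the coefficient of variation of log2(EXP + 1) across all
    samples; the ``k`` lowest-CV candidates are returned (ties broken by
    higher mean EXP, then rna_id).  The boolean flag warns when fewer than
    ``k`` candidates exist.
    """
    mat = exp.exp
    candidates = mat[(mat > min_exp).all(axis=1)]
    log_mat = np.log2(candidates + 1.0)
    mean_log = log_mat.mean(axis=1)
    sd_log = log_mat.std(axis=1, ddof=1)
    cv = sd_log / mean_log
    table = pd.DataFrame(
        {
            "rna_id": candidates.index,
            "cv_log2": cv.to_numpy(),
            "mean_exp": candidates.mean(axis=1).to_numpy(),
        }
    )
    table = table.sort_values(
        ["cv_log2", "mean_exp", "rna_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    short = len(table) < k
    return table.head(k).copy(), short
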