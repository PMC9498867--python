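"""Annotation cascade, UMI collapse and EXP normalisation.

Clean inserts are annotated against the class references in the fixed
priority order miRNA > piRNA > snoRNA > snRNA > tRNA > rRNA: equal-length
matching with a bounded number of substitutions, first class with a hit
wins, and within a class exact hits outrank mismatched ones before the
lexicographically smallest id breaks remaining ties.  tRNA/rRNA hits count
toward the mapping rate but are deleted from the count matrix.  Molecule
counts are distinct UMIs per (RNA, sample), optionally merged with the
directional rule; EXP is counts per ``scale_constant`` total assigned
molecules per sample.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    CLASS_RANK,
    DELETED_CLASSES,
    DNA_ALPHABET,
    CountMatrix,
    ExpressionMatrix,
    ReferenceSet,
    SampleSheet,
)
from .preprocess import CleanRead

EXPRESSION_TIERS = ("undetected", "low", "moderate", "high")


class ReferenceIndex:
    """Hash index over reference sequences for the annotation cascade."""

    def __init__(self, ref: ReferenceSet):
        self.exact: dict[str, tuple[int, str, str]] = {}
        self.by_length: dict[int, list[tuple[int, str, str, str]]] = defaultdict(list)
        for rec in ref:
            key = (CLASS_RANK[rec.rna_class], rec.rna_id, rec.rna_class)
            self.exact[rec.sequence] = key
            self.by_length[len(rec.sequence)].append((*key, rec.sequence))
        for bucket in self.by_length.values():
            bucket.sort()
        # reference sequences whose 1-substitution neighbourhood contains a
        # reference of a strictly higher-priority class: only these exact
        # hits can be overruled by a mismatched hit at max_mismatch=1
        self.shadowed: set[str] = set()
        for seq, (rank, _, _) in self.exact.items():
            if rank == 0:
                continue
            if any(hit[0] < rank for hit in _neighbour_hits(self, seq)):
                self.shadowed.add(seq)


def _neighbour_hits(index: ReferenceIndex, insert: str):
    """(class_rank, rna_id, rna_class) for every 1-substitution neighbour."""
    hits = []
    for i, base in enumerate(insert):
        prefix, suffix = insert[:i], insert[i + 1:]
        for alt in DNA_ALPHABET:
            if alt == base:
                continue
            hit = index.exact.get(prefix + alt + suffix)
            if hit is not None:
                hits.append(hit)
    return hits


def assign_class(
    insert: str,
    ref: ReferenceSet | ReferenceIndex,
    max_mismatch: int = 1,
) -> tuple[str, str] | None:
    """Assign an insert to (rna_id, rna_class), or None if unassigned.

    Equal-length matching with at most ``max_mismatch`` substitutions.
    Priority: class rank, then mismatch count, then lexicographic rna_id.
    """
    index = ref if isinstance(ref, ReferenceIndex) else ReferenceIndex(ref)
    best: tuple[int, int, str, str] | None = None  # (rank, mm, id, class)
    exact = index.exact.get(insert)
    if exact is not None:
        best = (exact[0], 0, exact[1], exact[2])
        # an exact hit can only be overruled by a mismatched hit in a
        # higher-priority class; skip the neighbourhood search when none
        # can exist
        if exact[0] == 0 or (max_mismatch == 1 and insert not in index.shadowed):
            return exact[1], exact[2]
    if max_mismatch == 1:
        for rank, rid, cls in _neighbour_hits(index, insert):
            cand = (rank, 1, rid, cls)
            if best is None or cand < best:
                best = cand
    elif max_mismatch > 1:
        for rank, rid, cls, seq in index.by_length.get(len(insert), []):
            mm = sum(1 for a, b in zip(insert, seq) if a != b)
            if mm <= max_mismatch:
                cand = (rank, mm, rid, cls)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    return best[2], best[3]


def _hamming1(a: str, b: str) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > 1:
                return False
    return mm == 1


def directional_molecule_count(umi_counts: Mapping[str, int]) -> int:
    """Number of molecules under the directional UMI-merging rule.

    UMIs are visited in descending read count; a UMI joins an existing
    cluster through an edge parent->child when they are at Hamming distance
    one and ``count(parent) >= 2 * count(child) - 1``.  The number of
    clusters is the molecule count.
    """
    umis = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    assigned: set[str] = set()
    n_clusters = 0
    for seed in umis:
        if seed in assigned:
            continue
        n_clusters += 1
        stack = [seed]
        assigned.add(seed)
        while stack:
            parent = stack.pop()
            pc = umi_counts[parent]
            for child in umis:
                if child in assigned:
                    continue
                if pc >= 2 * umi_counts[child] - 1 and _hamming1(parent, child):
                    assigned.add(child)
                    stack.append(child)
    return n_clusters


def collapse_umi(
    assigned_reads: Mapping[str, Sequence[tuple[tuple[str, str] | None, str]]],
    merge_mode: str = "exact",
) -> CountMatrix:
    """Collapse per-sample (assignment, UMI) pairs into molecule counts.

    ``assigned_reads`` maps sample_id to a sequence of
    ``((rna_id, rna_class) | None, umi)``.  tRNA/rRNA assignments count
    toward the mapping rate but are excluded from the matrix.
    """
    if merge_mode not in ("exact", "directional"):
        raise ValueError(f"unknown merge_mode {merge_mode!r}")
    mapping_rate: dict[str, float] = {}
    per_cell: dict[str, dict[str, dict[str, int]]] = {}
    for sample in sorted(assigned_reads):
        reads = assigned_reads[sample]
        n_assigned = 0
        cell: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
        for assignment, umi in reads:
            if assignment is None:
                continue
            rna_id, rna_class = assignment
            n_assigned += 1
            if rna_class in DELETED_CLASSES:
                continue
            cell[rna_id][umi] += 1
        mapping_rate[sample] = n_assigned / len(reads) if reads else 0.0
        per_cell[sample] = cell

    rna_ids = sorted({r for cell in per_cell.values() for r in cell})
    data = {}
    for sample, cell in per_cell.items():
        col = np.zeros(len(rna_ids), dtype=int)
        for i, rid in enumerate(rna_ids):
            if rid in cell:
                umis = cell[rid]
                col[i] = (
                    len(umis) if merge_mode == "exact"
                    else directional_molecule_count(umis)
                )
        data[sample] = col
    counts = pd.DataFrame(data, index=pd.Index(rna_ids, name="rna_id"))
    return CountMatrix(counts, mapping_rate)


def quantify_samples(
    clean_reads: Mapping[str, Sequence[CleanRead]],
    ref: ReferenceSet,
    max_mismatch: int = 1,
    merge_mode: str = "exact",
) -> CountMatrix:
    """Assign every clean read and collapse UMIs, sample by sample."""
    index = ReferenceIndex(ref)
    assigned = {
        sample: [(assign_class(r.insert, index, max_mismatch), r.umi) for r in reads]
        for sample, reads in clean_reads.items()
    }
    return collapse_umi(assigned, merge_mode)


class NormalizationError(ValueError):
    pass


def normalize_exp(
    counts: CountMatrix,
    sample_sheet: SampleSheet,
    scale_constant: float = 1e5,
) -> ExpressionMatrix:
    """EXP values: molecule counts scaled to ``scale_constant`` per sample.

    Group means exclude technical replicates (internal quality control
    only, not part of group-level analysis).
    """
    mat = counts.counts
    totals = mat.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise NormalizationError(
            f"sample(s) with zero assigned molecules: {list(zero.index)}"
        )
    exp = mat / totals * scale_constant
    group_means = {}
    for group in sample_sheet.groups:
        members = [s for s in sample_sheet.samples_for_group(group)
                   if s in exp.columns]
        if members:
            group_means[group] = exp[members].mean(axis=1)
    gm = pd.DataFrame(group_means)
    return ExpressionMatrix(exp=exp, scale_constant=scale_constant, group_means=gm)


def tier_expression(exp_value: float) -> str:
    """Expression tier: 0 undetected, (0,1] low, (1,10) moderate, >=10 high."""
    if exp_value < 0:
        raise ValueError("EXP value must be nonnegative")
    if exp_value == 0:
        return "undetected"
    if exp_value <= 1:
        return "low"
    if exp_value < 10:
        return "moderate"
    return "high"


def class_composition(
    counts: CountMatrix,
    ref: ReferenceSet,
    sample_sheet: SampleSheet,
) -> dict[str, dict[str, float]]:
    """Per-group proportion of molecules per RNA class (replicates excluded)."""
    class_of = {r.rna_id: r.rna_class for r in ref}
    mat = counts.counts
    out: dict[str, dict[str, float]] = {}
    for group in sample_sheet.groups:
        members = [s for s in sample_sheet.samples_for_group(group)
                   if s in mat.columns]
        if not members:
            raise ValueError(f"group {group} has no samples in the count matrix")
        sub = mat[members]
        total = float(sub.values.sum())
        if total == 0:
            raise ValueError(f"group {group} has no molecules")
        per_class: dict[str, float] = defaultdict(float)
        sums = sub.sum(axis=1)
        for rid, n in sums.items():
            per_class[class_of[rid]] += float(n)
        out[group] = {c: v / total for c, v in sorted(per_class.items())}
    return out


def group_intersections(exp: ExpressionMatrix) -> dict[frozenset, int]:
    """Counts of RNAs per detection pattern across groups.

    An RNA is detected in a group when its group-mean EXP is > 0; the keys
    are the nonempty sets of groups in which each RNA is detected.
    """
    gm = exp.group_means
    out: dict[frozenset, int] = defaultdict(int)
    detected = gm > 0
    for _, row in detected.iterrows():
        pattern = frozenset(g for g in gm.columns if row[g])
        if pattern:
            out[pattern] += 1
    return dict(out)


def replicate_correlation(exp: ExpressionMatrix, sample_a: str, sample_b: str) -> float:
    """Pearson r over RNAs detected (EXP > 0) in either sample."""
    a = exp.exp[sample_a]
    b = exp.exp[sample_b]
    mask = (a > 0) | (b > 0)
    if mask.sum() < 2:
        raise ValueError("fewer than two detected RNAs in the pair")
    r, _ = sps.pearsonr(a[mask], b[mask])
    return float(r)
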