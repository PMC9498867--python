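"""Shared domain containers for the small-RNA forensic profiling pipeline.

The pipeline works on six forensically relevant sample groups — menstrual
blood (MB), saliva (SA), semen (SE), skin (SK), venous blood (VB) and
vaginal secretion (VS) — and six small-RNA classes annotated in a fixed
priority order (miRNA first, rRNA last).  Counts are absolute molecule
counts obtained by UMI deduplication; expression (EXP) is molecules per
``scale_constant`` total assigned molecules per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Forensic sample groups, canonical order.
GROUPS: tuple[str, ...] = ("MB", "SA", "SE", "SK", "VB", "VS")

#: RNA classes in annotation-priority order (first hit wins downstream).
RNA_CLASSES: tuple[str, ...] = ("miRNA", "piRNA", "snoRNA", "snRNA", "tRNA", "rRNA")

#: Classes dropped from the count matrix after annotation.
DELETED_CLASSES: frozenset[str] = frozenset({"tRNA", "rRNA"})

CLASS_RANK: dict[str, int] = {c: i for i, c in enumerate(RNA_CLASSES)}

DNA_ALPHABET = "ACGT"


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference small RNA."""

    rna_id: str
    rna_class: str
    sequence: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {self.rna_class!r}")
        if set(self.sequence) - set(DNA_ALPHABET):
            raise ValueError(f"{self.rna_id}: sequence has non-ACGT characters")


@dataclass
class ReferenceSet:
    """Reference small RNAs grouped by class.

    Invariants: unique ids, unique sequences, lengths within the 18–30 nt
    size-selection window (miRNA 20–24, piRNA 26–30).
    """

    records: list[ReferenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.rna_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate rna_id in reference set")
        seqs = [r.sequence for r in self.records]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate sequence in reference set")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def by_id(self) -> dict[str, ReferenceRecord]:
        return {r.rna_id: r for r in self.records}

    def ids(self, classes: Iterable[str] | None = None) -> list[str]:
        keep = set(classes) if classes is not None else None
        return [r.rna_id for r in self.records if keep is None or r.rna_class in keep]

    def to_fasta(self, path) -> None:
        recs = [
            SeqRecord(Seq(r.sequence), id=r.rna_id, description=r.rna_class)
            for r in self.records
        ]
        with open(path, "w") as fh:
            SeqIO.write(recs, fh, "fasta")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSet":
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.description.split()
            rna_class = parts[1] if len(parts) > 1 else "miRNA"
            records.append(ReferenceRecord(rec.id, rna_class, str(rec.seq).upper()))
        return cls(records)


@dataclass
class SampleSheet:
    """Sample ids, group labels and technical-replicate links.

    ``replicate_of`` is the empty string for ordinary samples; a technical
    replicate names its parent sample and is excluded from group-level
    statistics (it exists for repeatability QC only).
    """

    frame: pd.DataFrame  # columns: sample_id, group, replicate_of

    def __post_init__(self) -> None:
        need = {"sample_id", "group", "replicate_of"}
        if not need <= set(self.frame.columns):
            raise ValueError(f"sample sheet must have columns {sorted(need)}")
        bad = set(self.frame["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups in sample sheet: {sorted(bad)}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.frame["group"]))

    def group_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["group"].iloc[0]

    def samples_for_group(self, group: str, include_replicates: bool = False) -> list[str]:
        f = self.frame
        mask = f["group"] == group
        if not include_replicates:
            mask &= f["replicate_of"] == ""
        return list(f.loc[mask, "sample_id"])

    def replicate_pairs(self) -> list[tuple[str, str]]:
        """(parent, replicate) pairs declared in the sheet."""
        f = self.frame
        return [
            (row.replicate_of, row.sample_id)
            for row in f.itertuples()
            if row.replicate_of
        ]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls(frame)


@dataclass
class CountMatrix:
    """UMI-collapsed absolute molecule counts, RNA × sample.

    ``mapping_rate`` is the per-sample fraction of clean reads assigned to
    any reference class (including the tRNA/rRNA hits that are subsequently
    deleted from the matrix itself).
    """

    counts: pd.DataFrame
    mapping_rate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        for s, r in self.mapping_rate.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"mapping rate for {s} outside [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "rna_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, mapping_rate: Mapping[str, float] | None = None) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="rna_id")
        return cls(counts, dict(mapping_rate or {}))


@dataclass
class ExpressionMatrix:
    """EXP-normalised expression, RNA × sample, with per-group means.

    Each sample column sums to ``scale_constant``; ``group_means`` are
    arithmetic means over each group's samples with technical replicates
    excluded.
    """

    exp: pd.DataFrame
    scale_constant: float
    group_means: pd.DataFrame

    def to_tsv(self, path) -> None:
        out = self.exp.copy()
        out.index.name = "rna_id"
        out.to_csv(path, sep="\t")

    def group_means_to_tsv(self, path) -> None:
        out = self.group_means.copy()
        out.index.name = "rna_id"
        out.to_csv(path, sep="\t")
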