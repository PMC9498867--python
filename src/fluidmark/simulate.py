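"""Ground-truthed synthetic data generator.

Emulates the study design the downstream analysis assumes: six sample
groups (five body fluids plus skin) with five biological samples each and
one technical replicate, a six-class small-RNA reference restricted to the
18–30 nt size-selection window, group-specific class composition (semen
piRNA-dominant), planted absolute and relative specific markers with known
log2 effects, planted stable reference genes, negative-binomial biological
noise, PCR duplication and sequencing substitution errors.  Reads follow
the library layout insert | UMI | 3'-adapter.

Every operation takes an explicit seed; there is no global random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    DELETED_CLASSES,
    DNA_ALPHABET,
    GROUPS,
    RNA_CLASSES,
    ReferenceRecord,
    ReferenceSet,
    SampleSheet,
)

# Insert length windows per class, constrained to the 18-30 nt gel window.
# Mature miRNAs are 20-24 nt; piRNAs 26-31 nt, truncated at the 30 nt upper
# gel bound; the remaining classes contribute 18-30 nt fragments.
CLASS_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "miRNA": (20, 24),
    "piRNA": (26, 30),
    "snoRNA": (18, 30),
    "snRNA": (18, 30),
    "tRNA": (18, 30),
    "rRNA": (18, 30),
}

_ID_PREFIX = {
    "miRNA": "miR-sim-",
    "piRNA": "piR-sim-",
    "snoRNA": "snoR-sim-",
    "snRNA": "snR-sim-",
    "tRNA": "tRNA-sim-",
    "rRNA": "rRNA-sim-",
}

# Default per-group class mixtures (fractions of total molecules).  Semen is
# piRNA-dominant with a reduced sno/snRNA share; every other group is
# miRNA-dominant with roughly 30% sno/snRNA; venous blood carries the least
# piRNA.  Values are qualitative, not reproductions of any measured table.
DEFAULT_CLASS_MIX: dict[str, dict[str, float]] = {
    "MB": {"miRNA": 0.50, "piRNA": 0.12, "snoRNA": 0.25, "snRNA": 0.05, "tRNA": 0.04, "rRNA": 0.04},
    "SA": {"miRNA": 0.50, "piRNA": 0.12, "snoRNA": 0.25, "snRNA": 0.05, "tRNA": 0.04, "rRNA": 0.04},
    "SE": {"miRNA": 0.22, "piRNA": 0.60, "snoRNA": 0.10, "snRNA": 0.023, "tRNA": 0.030, "rRNA": 0.027},
    "SK": {"miRNA": 0.50, "piRNA": 0.12, "snoRNA": 0.25, "snRNA": 0.05, "tRNA": 0.04, "rRNA": 0.04},
    "VB": {"miRNA": 0.57, "piRNA": 0.05, "snoRNA": 0.25, "snRNA": 0.05, "tRNA": 0.04, "rRNA": 0.04},
    "VS": {"miRNA": 0.50, "piRNA": 0.12, "snoRNA": 0.25, "snRNA": 0.05, "tRNA": 0.04, "rRNA": 0.04},
}

DEFAULT_N_PER_CLASS: dict[str, int] = {
    "miRNA": 550,
    "piRNA": 1200,
    "snoRNA": 250,
    "snRNA": 20,
    "tRNA": 30,
    "rRNA": 30,
}

#: EXP budget a group profile distributes over its RNAs.
PROFILE_TOTAL_EXP = 1e5


class GenerationError(RuntimeError):
    pass


class CapacityError(ValueError):
    pass


@dataclass
class GroupProfile:
    """Expected EXP-scale mean per RNA for one group, plus its class mix."""

    group: str
    mean_exp: dict[str, float]
    class_mix: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix for {self.group} sums to {total}, not 1")
        if any(v < 0 for v in self.mean_exp.values()):
            raise ValueError("negative mean_exp")


@dataclass
class PlantedTruth:
    """Ground truth of the planted effects, for recovery evaluation."""

    asm: dict[str, dict[str, float]]  # group -> {rna_id: log2 effect}
    rsm: dict[tuple[str, str], list[tuple[str, str, float]]]  # pair -> [(rna_id, up_group, effect)]
    reference_genes: set[str]
    null_rnas: set[str]

    def to_json(self, path) -> None:
        payload = {
            "asm": self.asm,
            "rsm": {f"{a}_{b}": v for (a, b), v in self.rsm.items()},
            "reference_genes": sorted(self.reference_genes),
            "null_rnas": sorted(self.null_rnas),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        rsm = {}
        for key, v in payload["rsm"].items():
            a, b = key.split("_")
            rsm[(a, b)] = [tuple(x) for x in v]
        return cls(
            asm=payload["asm"],
            rsm=rsm,
            reference_genes=set(payload["reference_genes"]),
            null_rnas=set(payload["null_rnas"]),
        )


@dataclass
class TruthSpec:
    """What to plant: marker counts per group/pair and their effects."""

    n_asm_per_group: int = 6
    n_rsm_per_pair: int = 2
    n_reference_genes: int = 10
    asm_effect: float = 3.0  # log2 units
    rsm_effect: float = 3.0
    marker_mean_range: tuple[float, float] = (100.0, 400.0)  # baseline EXP
    reference_mean_range: tuple[float, float] = (200.0, 800.0)
    lognormal_sigma: float = 1.2  # spread of baseline expression weights


@dataclass
class ReadSimConfig:
    """Read-level simulation parameters.

    ``library_depth`` is the expected number of sequenced reads per sample;
    the expected molecule count is ``library_depth / pcr_dup_mean``.  Each
    molecule is emitted ``1 + Poisson(pcr_dup_mean - 1)`` times.  Planted
    reference genes use ``reference_dispersion`` instead of the shared
    ``nb_dispersion``: the generator plants stability, not just equal means.
    """

    umi_length: int = 10
    adapter: str = "AGATCGGAAGAGCACACGTCT"
    pcr_dup_mean: float = 2.0
    error_rate: float = 0.001
    library_depth: int = 30000
    nb_dispersion: float = 0.2
    reference_dispersion: float = 0.02
    read_length: int = 60
    base_quality: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        if self.umi_length < 8:
            raise ValueError("umi_length must be >= 8 (UMI collision control)")
        if len(self.adapter) < 10:
            raise ValueError("adapter must be >= 10 nt")
        if self.pcr_dup_mean < 1:
            raise ValueError("pcr_dup_mean must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if self.nb_dispersion <= 0 or self.reference_dispersion <= 0:
            raise ValueError("dispersions must be > 0")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "ReadSimConfig":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=length))


#: References ending in a run of A this long are never generated: their
#: reads would be indistinguishable from poly-A artifacts and removed by
#: the cleaning rules, making the RNA unquantifiable by construction.
_MAX_TRAILING_A = 7


def build_reference(n_per_class: Mapping[str, int], seed: int,
                    max_retries: int = 100) -> ReferenceSet:
    """Generate a reference set with unique ids and unique sequences."""
    bad = set(n_per_class) - set(RNA_CLASSES)
    if bad:
        raise ValueError(f"unknown RNA classes requested: {sorted(bad)}")
    if any(n < 0 for n in n_per_class.values()):
        raise ValueError("negative class counts")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    records: list[ReferenceRecord] = []
    for rna_class in RNA_CLASSES:
        n = int(n_per_class.get(rna_class, 0))
        lo, hi = CLASS_LENGTH_RANGES[rna_class]
        prefix = _ID_PREFIX[rna_class]
        for i in range(n):
            for _ in range(max_retries):
                length = int(rng.integers(lo, hi + 1))
                seq = _random_sequence(rng, length)
                if seq not in seen and not seq.endswith("A" * (_MAX_TRAILING_A + 1)):
                    break
            else:
                raise GenerationError(
                    f"could not draw a unique {rna_class} sequence "
                    f"after {max_retries} retries"
                )
            seen.add(seq)
            records.append(ReferenceRecord(f"{prefix}{i:05d}", rna_class, seq))
    return ReferenceSet(records)


# ---------------------------------------------------------------------------
# expression profiles and planted truth
# ---------------------------------------------------------------------------

def build_profiles(
    ref: ReferenceSet,
    truth_spec: TruthSpec | None = None,
    seed: int = 0,
    class_mix: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[list[GroupProfile], PlantedTruth]:
    """Build per-group mean-EXP profiles with planted markers.

    Baseline expression weights are shared across groups within each class
    and scaled by the group's class-mix proportion, so class composition
    differs between groups the way body fluids differ, while within-class
    relative abundances are common.  On top of that baseline:

    * ASMs of group g: equal baseline mean in all groups, multiplied by
      ``2**asm_effect`` in g only.
    * RSMs of pair (A, B): equal baseline mean everywhere except group B,
      where it is divided by ``2**rsm_effect`` ("down in B").  This makes
      the RNA differential in pair (A, B) (attributed to A) without ever
      satisfying the ASM definition for any group.
    * Reference genes: one mean, identical in all six groups.
    """
    spec = truth_spec or TruthSpec()
    mixes = {g: dict((class_mix or DEFAULT_CLASS_MIX)[g]) for g in GROUPS}
    rng = np.random.default_rng(seed)

    ids_by_class: dict[str, list[str]] = {c: [] for c in RNA_CLASSES}
    for rec in ref:
        ids_by_class[rec.rna_class].append(rec.rna_id)
    all_ids = [rec.rna_id for rec in ref]

    # baseline weights, shared across groups
    weights = {rid: float(w) for rid, w in
               zip(all_ids, rng.lognormal(0.0, spec.lognormal_sigma, size=len(all_ids)))}
    class_weight_sum = {
        c: sum(weights[r] for r in ids_by_class[c]) for c in RNA_CLASSES
    }

    base_mean = {
        g: {
            rid: (
                mixes[g][rec_class] * PROFILE_TOTAL_EXP * weights[rid]
                / class_weight_sum[rec_class]
                if class_weight_sum[rec_class] > 0
                else 0.0
            )
            for rec_class in RNA_CLASSES
            for rid in ids_by_class[rec_class]
        }
        for g in GROUPS
    }

    # choose planted ids from retained (non-tRNA/rRNA) classes
    plantable = [r for c in RNA_CLASSES if c not in DELETED_CLASSES
                 for r in ids_by_class[c]]
    pairs = list(combinations(GROUPS, 2))
    n_needed = (
        spec.n_asm_per_group * len(GROUPS)
        + spec.n_rsm_per_pair * len(pairs)
        + spec.n_reference_genes
    )
    if n_needed > len(plantable):
        raise CapacityError(
            f"truth spec needs {n_needed} plantable RNAs, reference has "
            f"{len(plantable)} outside the deleted classes"
        )
    chosen = list(rng.choice(plantable, size=n_needed, replace=False))

    def take(n: int) -> list[str]:
        out, chosen[:n] = chosen[:n], []
        return out

    asm: dict[str, dict[str, float]] = {}
    for g in GROUPS:
        asm[g] = {rid: spec.asm_effect for rid in take(spec.n_asm_per_group)}
    rsm: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
    for i, (a, b) in enumerate(pairs):
        members = []
        for j, rid in enumerate(take(spec.n_rsm_per_pair)):
            # alternate which side of the pair the marker favours
            up, down = (a, b) if (i + j) % 2 == 0 else (b, a)
            members.append((rid, up, spec.rsm_effect))
        rsm[(a, b)] = members
    reference_genes = set(take(spec.n_reference_genes))

    lo, hi = spec.marker_mean_range
    for g, members in asm.items():
        for rid, effect in members.items():
            b = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            for h in GROUPS:
                base_mean[h][rid] = b * (2.0 ** effect if h == g else 1.0)
    for (a, bgrp), members in rsm.items():
        for rid, up, effect in members:
            down = bgrp if up == a else a
            b = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            for h in GROUPS:
                base_mean[h][rid] = b / (2.0 ** effect) if h == down else b
    rlo, rhi = spec.reference_mean_range
    for rid in sorted(reference_genes):
        b = float(np.exp(rng.uniform(np.log(rlo), np.log(rhi))))
        for h in GROUPS:
            base_mean[h][rid] = b

    planted = set(reference_genes)
    for members in asm.values():
        planted |= set(members)
    for members in rsm.values():
        planted |= {rid for rid, _, _ in members}
    null_rnas = set(all_ids) - planted

    profiles = [GroupProfile(g, base_mean[g], mixes[g]) for g in GROUPS]
    truth = PlantedTruth(asm=asm, rsm=rsm, reference_genes=reference_genes,
                         null_rnas=null_rnas)
    return profiles, truth


def true_differential_pairs(profiles: list[GroupProfile],
                            min_ratio: float = 1.0 + 1e-9) -> dict[tuple[str, str], set[str]]:
    """RNAs whose true profile means differ between each group pair.

    Used as the ground truth when scoring marker-call false discoveries: a
    call is false only if the two groups' true means are equal (ratio below
    ``min_ratio``).
    """
    by_group = {p.group: p.mean_exp for p in profiles}
    out: dict[tuple[str, str], set[str]] = {}
    for a, b in combinations(sorted(by_group), 2):
        diff = set()
        for rid, ma in by_group[a].items():
            mb = by_group[b][rid]
            if ma == mb == 0:
                continue
            if mb == 0 or ma == 0 or max(ma / mb, mb / ma) >= min_ratio:
                diff.add(rid)
        out[(a, b)] = diff
    return out


# ---------------------------------------------------------------------------
# molecule counts
# ---------------------------------------------------------------------------

def make_sample_sheet(n_per_group: int, tech_rep_group: str = "VB",
                      tech_rep_index: int = 2) -> SampleSheet:
    """Sample sheet for ``n_per_group`` samples per group plus one technical
    replicate of ``tech_rep_group`` sample ``tech_rep_index``."""
    rows = []
    for g in GROUPS:
        for i in range(1, n_per_group + 1):
            rows.append({"sample_id": f"{g}{i:03d}", "group": g, "replicate_of": ""})
    parent = f"{tech_rep_group}{tech_rep_index:03d}"
    rows.append({
        "sample_id": f"{tech_rep_group}{n_per_group + 1:03d}",
        "group": tech_rep_group,
        "replicate_of": parent,
    })
    return SampleSheet(pd.DataFrame(rows))


def simulate_counts(
    profiles: list[GroupProfile],
    n_per_group: int,
    cfg: ReadSimConfig,
    truth: PlantedTruth | None = None,
    sample_sheet: SampleSheet | None = None,
) -> tuple[pd.DataFrame, SampleSheet]:
    """Draw true molecule counts per RNA and sample.

    Counts are negative binomial with mean proportional to the group's
    mean-EXP profile (expected total molecules per sample =
    ``library_depth / pcr_dup_mean``) and gamma-Poisson dispersion
    ``nb_dispersion`` (``reference_dispersion`` for planted reference
    genes).  The technical replicate declared in the sample sheet copies
    its parent's molecule column: same extract, no new biological draw.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    sheet = sample_sheet or make_sample_sheet(n_per_group)
    by_group = {p.group: p for p in profiles}
    rna_ids = list(profiles[0].mean_exp)
    rng = np.random.default_rng(cfg.seed)

    disp = np.full(len(rna_ids), cfg.nb_dispersion)
    if truth is not None:
        ref_mask = np.array([rid in truth.reference_genes for rid in rna_ids])
        disp[ref_mask] = cfg.reference_dispersion

    total_molecules = cfg.library_depth / cfg.pcr_dup_mean
    data: dict[str, np.ndarray] = {}
    for row in sheet.frame.itertuples():
        if row.replicate_of:
            continue  # filled after its parent below
        prof = by_group[row.group]
        mean_exp = np.array([prof.mean_exp[r] for r in rna_ids])
        total = mean_exp.sum()
        mu = mean_exp / total * total_molecules if total > 0 else mean_exp
        lam = np.zeros_like(mu)
        pos = mu > 0
        shape = 1.0 / disp[pos]
        lam[pos] = rng.gamma(shape, mu[pos] * disp[pos])
        data[row.sample_id] = rng.poisson(lam)
    for parent, rep in sheet.replicate_pairs():
        data[rep] = data[parent].copy()

    counts = pd.DataFrame(data, index=pd.Index(rna_ids, name="rna_id"))
    counts = counts[[s for s in sheet.sample_ids]]
    return counts, sheet


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _apply_errors(read: str, rng: np.random.Generator, n_err: int) -> str:
    chars = list(read)
    positions = rng.choice(len(chars), size=n_err, replace=False)
    for pos in positions:
        alternatives = [b for b in DNA_ALPHABET if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_reads(
    counts: pd.DataFrame,
    ref: ReferenceSet,
    cfg: ReadSimConfig,
    out_dir,
) -> pd.DataFrame:
    """Emit per-sample FASTQ files and return the truth manifest.

    Every true molecule receives a random UMI (collisions possible, and
    recorded); each molecule is sequenced ``1 + Poisson(pcr_dup_mean - 1)``
    times; each read is insert + UMI + adapter prefix padded with A to
    ``read_length``, with per-base substitution errors at ``error_rate``.
    The manifest has one row per (sample, rna_id) with the molecule count
    and the comma-joined UMIs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq_of = {r.rna_id: r.sequence for r in ref}
    missing = set(counts.index) - set(seq_of)
    if missing:
        raise KeyError(f"rna_ids absent from reference: {sorted(missing)[:5]}")

    qual_char = chr(33 + cfg.base_quality)
    manifest_rows = []
    for s_idx, sample in enumerate(counts.columns):
        rng = np.random.default_rng([cfg.seed, 104729, s_idx])
        lines: list[str] = []
        serial = 0
        col = counts[sample]
        for rna_id in counts.index:
            k = int(col[rna_id])
            if k == 0:
                continue
            insert = seq_of[rna_id]
            umi_codes = rng.integers(0, 4, size=(k, cfg.umi_length))
            umis = ["".join(DNA_ALPHABET[c] for c in row) for row in umi_codes]
            dups = 1 + rng.poisson(cfg.pcr_dup_mean - 1.0, size=k)
            n_reads = int(dups.sum())
            base_len = min(cfg.read_length,
                           len(insert) + cfg.umi_length + len(cfg.adapter))
            n_err = (
                rng.binomial(cfg.read_length, cfg.error_rate, size=n_reads)
                if cfg.error_rate > 0 else np.zeros(n_reads, dtype=int)
            )
            qual = qual_char * cfg.read_length
            r = 0
            for umi, d in zip(umis, dups):
                template = (insert + umi + cfg.adapter)[: cfg.read_length]
                template = template + "A" * (cfg.read_length - len(template))
                for _ in range(int(d)):
                    read = template
                    if n_err[r]:
                        read = _apply_errors(read, rng, int(n_err[r]))
                    lines.append(f"@{sample}_r{serial}\n{read}\n+\n{qual}\n")
                    serial += 1
                    r += 1
            manifest_rows.append({
                "sample_id": sample,
                "rna_id": rna_id,
                "molecules": k,
                "umis": ",".join(umis),
            })
        (out_dir / f"{sample}.fastq").write_text("".join(lines))

    manifest = pd.DataFrame(
        manifest_rows, columns=["sample_id", "rna_id", "molecules", "umis"]
    )
    return manifest
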