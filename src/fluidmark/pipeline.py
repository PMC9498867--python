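"""Pipeline orchestration: staged runs with on-disk artifacts and a run
manifest.

Each stage reads the previous stage's TSV/JSON artifacts from the run
directory and writes its own, so stages can be re-run individually from
the CLI.  ``run_all`` on a fixed-seed synthetic configuration is
end-to-end deterministic: identical configs produce byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import CountMatrix, ExpressionMatrix, ReferenceSet, SampleSheet
from .diffexp import run_all_pairs
from .grading import build_grade_table, cluster_validate
from .markers import asm_groups, call_asm, call_rsm, screen_reference_genes
from .preprocess import PreprocessConfig, clean_sample
from .quantify import (
    class_composition,
    group_intersections,
    normalize_exp,
    quantify_samples,
    replicate_correlation,
)
from .simulate import (
    DEFAULT_N_PER_CLASS,
    ReadSimConfig,
    TruthSpec,
    build_profiles,
    build_reference,
    simulate_counts,
    simulate_reads,
)

logger = logging.getLogger("fluidmark")


class MissingInputError(FileNotFoundError):
    pass


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Every tunable parameter of the pipeline, serialised into the run
    manifest.  Marker thresholds default to q < 0.05 and |log2FC| > 1."""

    out_dir: str = "fluidmark_run"
    seed: int = 17
    # simulation
    n_per_class: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_CLASS))
    n_per_group: int = 5
    umi_length: int = 10
    adapter: str = "AGATCGGAAGAGCACACGTCT"
    pcr_dup_mean: float = 2.0
    error_rate: float = 0.001
    library_depth: int = 30000
    nb_dispersion: float = 0.2
    reference_dispersion: float = 0.02
    read_length: int = 60
    base_quality: int = 36
    n_asm_per_group: int = 6
    n_rsm_per_pair: int = 2
    n_reference_genes_planted: int = 10
    asm_effect: float = 3.0
    rsm_effect: float = 3.0
    # preprocessing / quantification
    max_mismatch: int = 1
    min_overlap: int = 8
    merge_mode: str = "exact"
    scale_constant: float = 1e5
    # differential expression / markers
    pseudocount: float = 0.5
    q_threshold: float = 0.05
    lfc_threshold: float = 1.0
    k_reference_genes: int = 10

    def validate(self) -> None:
        if self.q_threshold <= 0 or self.q_threshold >= 1:
            raise ConfigError("q_threshold must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ConfigError("lfc_threshold must be nonnegative")
        if self.merge_mode not in ("exact", "directional"):
            raise ConfigError(f"unknown merge_mode {self.merge_mode!r}")
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        # construction of the component configs re-checks their invariants
        self.read_sim_config()
        self.preprocess_config()

    def read_sim_config(self) -> ReadSimConfig:
        return ReadSimConfig(
            umi_length=self.umi_length,
            adapter=self.adapter,
            pcr_dup_mean=self.pcr_dup_mean,
            error_rate=self.error_rate,
            library_depth=self.library_depth,
            nb_dispersion=self.nb_dispersion,
            reference_dispersion=self.reference_dispersion,
            read_length=self.read_length,
            base_quality=self.base_quality,
            seed=self.seed,
        )

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            adapter=self.adapter,
            umi_length=self.umi_length,
            max_mismatch=self.max_mismatch,
            min_overlap=self.min_overlap,
        )

    def truth_spec(self) -> TruthSpec:
        return TruthSpec(
            n_asm_per_group=self.n_asm_per_group,
            n_rsm_per_pair=self.n_rsm_per_pair,
            n_reference_genes=self.n_reference_genes_planted,
            asm_effect=self.asm_effect,
            rsm_effect=self.rsm_effect,
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        cfg = cls(**json.loads(Path(path).read_text()))
        cfg.validate()
        return cfg


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingInputError(
            f"{stage}: required input {path} is missing; run the upstream "
            f"stage first"
        )
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _out(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(cfg: PipelineConfig) -> None:
    cfg.validate()
    out = _out(cfg)
    sim = cfg.read_sim_config()
    logger.info("simulate: building reference (%d RNAs)", sum(cfg.n_per_class.values()))
    ref = build_reference(cfg.n_per_class, seed=cfg.seed)
    profiles, truth = build_profiles(ref, cfg.truth_spec(), seed=cfg.seed + 1)
    counts, sheet = simulate_counts(profiles, cfg.n_per_group, sim, truth=truth)
    fastq_dir = out / "fastq"
    logger.info("simulate: writing reads for %d samples", len(sheet.sample_ids))
    manifest = simulate_reads(counts, ref, sim, fastq_dir)

    ref.to_fasta(out / "reference.fasta")
    sheet.to_tsv(out / "sample_sheet.tsv")
    truth.to_json(out / "planted_truth.json")
    counts.index.name = "rna_id"
    counts.to_csv(out / "true_counts.tsv", sep="\t")
    manifest.to_csv(out / "truth_manifest.tsv", sep="\t", index=False)
    mean_frame = pd.DataFrame({p.group: p.mean_exp for p in profiles})
    mean_frame.index.name = "rna_id"
    mean_frame.to_csv(out / "true_mean_exp.tsv", sep="\t")


def run_preprocess(cfg: PipelineConfig) -> None:
    cfg.validate()
    out = _out(cfg)
    sheet = SampleSheet.from_tsv(_require(out / "sample_sheet.tsv", "preprocess"))
    fastq_dir = _require(out / "fastq", "preprocess")
    pp = cfg.preprocess_config()
    clean_dir = out / "clean"
    clean_dir.mkdir(exist_ok=True)
    qc_rows = []
    for sample in sheet.sample_ids:
        fq = _require(fastq_dir / f"{sample}.fastq", "preprocess")
        reads, stats = clean_sample(fq, pp, sample_id=sample)
        frame = pd.DataFrame(
            {"insert": [r.insert for r in reads], "umi": [r.umi for r in reads]}
        )
        frame.to_csv(clean_dir / f"{sample}.tsv", sep="\t", index=False)
        row = {
            "sample_id": sample,
            "raw_reads": stats.raw_reads,
            "clean_reads": stats.clean_reads,
            "q20_fraction": stats.q20_fraction,
        }
        for reason, n in sorted(stats.discard_reasons.items()):
            row[f"discard_{reason}"] = n
        qc_rows.append(row)
    qc = pd.DataFrame(qc_rows).fillna(0)
    qc.to_csv(out / "qc_stats.tsv", sep="\t", index=False)
    logger.info("preprocess: %d samples cleaned", len(qc_rows))


def _load_clean(out: Path, sheet: SampleSheet):
    clean = {}
    for sample in sheet.sample_ids:
        path = _require(out / "clean" / f"{sample}.tsv", "quantify")
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        from .preprocess import CleanRead

        clean[sample] = [
            CleanRead(sample, ins, umi)
            for ins, umi in zip(frame["insert"], frame["umi"])
        ]
    return clean


def run_quantify(cfg: PipelineConfig) -> None:
    cfg.validate()
    out = _out(cfg)
    ref = ReferenceSet.from_fasta(_require(out / "reference.fasta", "quantify"))
    sheet = SampleSheet.from_tsv(_require(out / "sample_sheet.tsv", "quantify"))
    clean = _load_clean(out, sheet)
    counts = quantify_samples(clean, ref, cfg.max_mismatch, cfg.merge_mode)
    exp = normalize_exp(counts, sheet, cfg.scale_constant)

    counts.to_tsv(out / "counts.tsv")
    pd.Series(counts.mapping_rate, name="mapping_rate").rename_axis(
        "sample_id"
    ).to_csv(out / "mapping_rates.tsv", sep="\t")
    exp.to_tsv(out / "exp.tsv")
    exp.group_means_to_tsv(out / "group_means.tsv")

    comp = class_composition(counts, ref, sheet)
    comp_frame = pd.DataFrame(comp).T
    comp_frame.index.name = "group"
    comp_frame.fillna(0.0).to_csv(out / "class_composition.tsv", sep="\t")

    inter = group_intersections(exp)
    inter_frame = pd.DataFrame(
        sorted(
            (("+".join(sorted(k)), v) for k, v in inter.items()),
            key=lambda kv: (-kv[1], kv[0]),
        ),
        columns=["groups", "n_rnas"],
    )
    inter_frame.to_csv(out / "intersections.tsv", sep="\t", index=False)

    summary = {"n_detected_rnas": int((exp.group_means > 0).any(axis=1).sum())}
    pairs = sheet.replicate_pairs()
    if pairs:
        parent, rep = pairs[0]
        summary["replicate_pair"] = [parent, rep]
        summary["replicate_pearson_r"] = replicate_correlation(exp, parent, rep)
    (out / "quantify_summary.json").write_text(json.dumps(summary, indent=1,
                                                          sort_keys=True))
    logger.info("quantify: %d RNAs x %d samples", *counts.counts.shape)


def run_de(cfg: PipelineConfig) -> None:
    cfg.validate()
    out = _out(cfg)
    counts = CountMatrix.from_tsv(_require(out / "counts.tsv", "de"))
    sheet = SampleSheet.from_tsv(_require(out / "sample_sheet.tsv", "de"))
    de = run_all_pairs(counts, sheet, cfg.pseudocount)
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    for (a, b), frame in sorted(de.items()):
        frame.to_csv(de_dir / f"{a}_{b}.tsv", sep="\t", index=False)
    logger.info("de: %d pairs tested", len(de))


def _load_de(out: Path, stage: str) -> dict[tuple[str, str], pd.DataFrame]:
    de_dir = _require(out / "de", stage)
    de = {}
    for path in sorted(de_dir.glob("*_*.tsv")):
        a, b = path.stem.split("_")
        de[(a, b)] = pd.read_csv(path, sep="\t")
    if not de:
        raise MissingInputError(f"{stage}: no DE tables found in {de_dir}")
    return de


def _load_exp(out: Path, cfg: PipelineConfig, stage: str) -> ExpressionMatrix:
    exp = pd.read_csv(_require(out / "exp.tsv", stage), sep="\t", index_col="rna_id")
    gm = pd.read_csv(_require(out / "group_means.tsv", stage), sep="\t",
                     index_col="rna_id")
    return ExpressionMatrix(exp=exp, scale_constant=cfg.scale_constant,
                            group_means=gm)


def run_markers(cfg: PipelineConfig) -> None:
    cfg.validate()
    out = _out(cfg)
    de = _load_de(out, "markers")
    exp = _load_exp(out, cfg, "markers")
    rsm = call_rsm(de, cfg.q_threshold, cfg.lfc_threshold)
    asm = call_asm(de, q_threshold=cfg.q_threshold, lfc_threshold=cfg.lfc_threshold)
    refs, short = screen_reference_genes(exp, cfg.k_reference_genes)
    rsm.to_csv(out / "rsm.tsv", sep="\t", index=False)
    asm.to_csv(out / "asm.tsv", sep="\t", index=False)
    refs.to_csv(out / "reference_genes.tsv", sep="\t", index=False)
    if short:
        logger.warning("markers: fewer reference-gene candidates than requested")
    logger.info("markers: %d RSM rows, %d ASMs",
                len(rsm), asm["rna_id"].nunique() if not asm.empty else 0)


def run_grade(cfg: PipelineConfig) -> None:
    cfg.validate()
    out = _out(cfg)
    asm = pd.read_csv(_require(out / "asm.tsv", "grade"), sep="\t")
    sheet = SampleSheet.from_tsv(_require(out / "sample_sheet.tsv", "grade"))
    exp = _load_exp(out, cfg, "grade")
    _, table = build_grade_table(asm, exp)
    table.to_csv(out / "grades.tsv", sep="\t", index=False)
    validation = {"n_asm": int(asm["rna_id"].nunique()) if not asm.empty else 0}
    if not asm.empty:
        ids = sorted(asm["rna_id"].unique())
        order, purity = cluster_validate(exp, sheet, ids)
        validation["cluster_purity"] = purity
        validation["dendrogram_order"] = order
    (out / "validation.json").write_text(json.dumps(validation, indent=1,
                                                    sort_keys=True))
    logger.info("grade: %d graded ASMs", len(table))


def write_manifest(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    inputs = {}
    for name in ("reference.fasta", "sample_sheet.tsv", "counts.tsv"):
        path = out / name
        if path.exists():
            inputs[name] = _sha256(path)
    manifest = {
        "version": __version__,
        "parameters": dataclasses.asdict(cfg),
        "input_checksums": inputs,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))


def run_all(cfg: PipelineConfig) -> None:
    """End-to-end: simulate, preprocess, quantify, DE, markers, grading."""
    cfg.validate()
    run_simulate(cfg)
    run_preprocess(cfg)
    run_quantify(cfg)
    run_de(cfg)
    run_markers(cfg)
    run_grade(cfg)
    write_manifest(cfg)
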