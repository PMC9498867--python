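"""Shared fixtures: small synthetic references for unit tests and two
session-scoped pipeline runs (a count-level run at the standard study
design and an error-free read-level run) reused across test modules."""

from __future__ import annotations

import pandas as pd
import pytest

import fluidmark as fm
from fluidmark.containers import DELETED_CLASSES, CountMatrix


SMALL_N_PER_CLASS = {"miRNA": 50, "piRNA": 80, "snoRNA": 20, "snRNA": 5,
                     "tRNA": 5, "rRNA": 5}


def retained_counts(counts: pd.DataFrame, ref) -> CountMatrix:
    """True molecule counts restricted to non-tRNA/rRNA classes, as the
    quantification stage would report them."""
    drop = [r.rna_id for r in ref if r.rna_class in DELETED_CLASSES]
    return CountMatrix(counts.drop(index=drop))


@pytest.fixture(scope="session")
def small_ref():
    return fm.build_reference(SMALL_N_PER_CLASS, seed=1)


@pytest.fixture(scope="session")
def small_truth_setup(small_ref):
    spec = fm.TruthSpec(n_asm_per_group=2, n_rsm_per_pair=1, n_reference_genes=3)
    profiles, truth = fm.build_profiles(small_ref, spec, seed=2)
    return profiles, truth


@pytest.fixture(scope="session")
def default_cfg():
    return fm.PipelineConfig(seed=11)


@pytest.fixture(scope="session")
def count_run(default_cfg):
    """Count-level pipeline at the standard study design (6 groups x 5
    samples + 1 technical replicate, ~2000 retained RNAs, planted markers):
    expression, DE, marker calls and reference-gene screen."""
    cfg = default_cfg
    ref = fm.build_reference(cfg.n_per_class, seed=cfg.seed)
    profiles, truth = fm.build_profiles(ref, cfg.truth_spec(), seed=cfg.seed + 1)
    counts, sheet = fm.simulate_counts(
        profiles, cfg.n_per_group, cfg.read_sim_config(), truth=truth
    )
    cm = retained_counts(counts, ref)
    exp = fm.normalize_exp(cm, sheet, cfg.scale_constant)
    de = fm.run_all_pairs(cm, sheet, cfg.pseudocount)
    asm = fm.call_asm(de)
    rsm = fm.call_rsm(de)
    refs, short = fm.screen_reference_genes(exp, cfg.k_reference_genes)
    return {
        "cfg": cfg,
        "ref": ref,
        "profiles": profiles,
        "truth": truth,
        "counts": cm,
        "sheet": sheet,
        "exp": exp,
        "de": de,
        "asm": asm,
        "rsm": rsm,
        "reference_genes": refs,
    }


@pytest.fixture(scope="session")
def errorfree_run(tmp_path_factory, default_cfg):
    """Read-level run with no sequencing errors and 12-nt UMIs: FASTQ
    simulation, cleaning and UMI quantification, plus the truth manifest."""
    out = tmp_path_factory.mktemp("errorfree")
    cfg = fm.PipelineConfig(seed=29, error_rate=0.0, umi_length=12)
    ref = fm.build_reference(cfg.n_per_class, seed=cfg.seed)
    profiles, truth = fm.build_profiles(ref, cfg.truth_spec(), seed=cfg.seed + 1)
    sim = cfg.read_sim_config()
    counts, sheet = fm.simulate_counts(profiles, cfg.n_per_group, sim, truth=truth)
    manifest = fm.simulate_reads(counts, ref, sim, out)
    pp = cfg.preprocess_config()
    clean = {}
    stats = {}
    for sample in sheet.sample_ids:
        reads, st = fm.clean_sample(out / f"{sample}.fastq", pp, sample_id=sample)
        clean[sample] = reads
        stats[sample] = st
    cm = fm.quantify_samples(clean, ref, cfg.max_mismatch, cfg.merge_mode)
    exp = fm.normalize_exp(cm, sheet, cfg.scale_constant)
    return {
        "cfg": cfg,
        "ref": ref,
        "truth": truth,
        "true_counts": counts,
        "sheet": sheet,
        "manifest": manifest,
        "clean": clean,
        "qc": stats,
        "counts": cm,
        "exp": exp,
    }
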