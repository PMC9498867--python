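"""Generator tests: reference construction, planted effects, count noise
model and read emission."""

import numpy as np
import pandas as pd
import pytest

import fluidmark as fm
from fluidmark.containers import GROUPS
from fluidmark.simulate import CLASS_LENGTH_RANGES, CapacityError


class TestBuildReference:
    def test_empty_request_gives_empty_reference(self):
        ref = fm.build_reference({c: 0 for c in CLASS_LENGTH_RANGES}, seed=1)
        assert len(ref) == 0

    def test_deterministic_for_fixed_seed(self):
        a = fm.build_reference({"miRNA": 50}, seed=1)
        b = fm.build_reference({"miRNA": 50}, seed=1)
        assert a.records == b.records

    def test_sizes_classes_and_length_windows(self):
        n = {"miRNA": 200, "piRNA": 400, "snoRNA": 100, "snRNA": 10,
             "tRNA": 20, "rRNA": 20}
        ref = fm.build_reference(n, seed=7)
        assert len(ref) == 750
        for rec in ref:
            lo, hi = CLASS_LENGTH_RANGES[rec.rna_class]
            assert lo <= len(rec.sequence) <= hi
            assert 18 <= len(rec.sequence) <= 30
        by_class = {}
        for rec in ref:
            by_class[rec.rna_class] = by_class.get(rec.rna_class, 0) + 1
        assert by_class == {k: v for k, v in n.items()}

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            fm.build_reference({"mRNA": 5}, seed=0)


class TestBuildProfiles:
    def test_planted_asm_fold_arithmetic(self, small_ref):
        profiles, truth = fm.build_profiles(
            small_ref, fm.TruthSpec(n_asm_per_group=2, n_rsm_per_pair=0,
                                    n_reference_genes=0, asm_effect=3.0),
            seed=5,
        )
        means = {p.group: p.mean_exp for p in profiles}
        for g, members in truth.asm.items():
            for rid in members:
                others = [means[h][rid] for h in GROUPS if h != g]
                assert np.allclose(others, others[0])
                assert means[g][rid] == pytest.approx(8.0 * others[0])

    def test_zero_effect_marker_is_null(self, small_ref):
        profiles, truth = fm.build_profiles(
            small_ref, fm.TruthSpec(n_asm_per_group=1, n_rsm_per_pair=0,
                                    n_reference_genes=0, asm_effect=0.0),
            seed=5,
        )
        means = {p.group: p.mean_exp for p in profiles}
        for g, members in truth.asm.items():
            for rid in members:
                vals = [means[h][rid] for h in GROUPS]
                assert np.allclose(vals, vals[0])

    def test_asm_sets_disjoint_and_union_36(self, small_ref):
        profiles, truth = fm.build_profiles(
            small_ref, fm.TruthSpec(n_asm_per_group=6), seed=3
        )
        all_asm = [r for members in truth.asm.values() for r in members]
        assert len(all_asm) == 36
        assert len(set(all_asm)) == 36

    def test_reference_genes_identical_across_groups(self, small_truth_setup):
        profiles, truth = small_truth_setup
        means = {p.group: p.mean_exp for p in profiles}
        for rid in truth.reference_genes:
            vals = [means[g][rid] for g in GROUPS]
            assert np.allclose(vals, vals[0])

    def test_semen_class_mix_is_pirna_dominant(self, small_truth_setup):
        profiles, _ = small_truth_setup
        se = next(p for p in profiles if p.group == "SE")
        assert se.class_mix["piRNA"] == max(se.class_mix.values())

    def test_capacity_error_when_overplanted(self, small_ref):
        with pytest.raises(CapacityError):
            fm.build_profiles(small_ref, fm.TruthSpec(n_asm_per_group=50), seed=1)


class TestSimulateCounts:
    def test_deterministic_and_zero_mean_rows(self, small_truth_setup):
        profiles, truth = small_truth_setup
        profiles = [fm.GroupProfile(p.group, dict(p.mean_exp), p.class_mix)
                    for p in profiles]
        dead = next(iter(truth.null_rnas))
        for p in profiles:
            p.mean_exp[dead] = 0.0
        cfg = fm.ReadSimConfig(library_depth=5000, seed=9)
        a, _ = fm.simulate_counts(profiles, 3, cfg, truth=truth)
        b, _ = fm.simulate_counts(profiles, 3, cfg, truth=truth)
        pd.testing.assert_frame_equal(a, b)
        assert (a.loc[dead] == 0).all()

    def test_replicate_column_copies_parent(self, small_truth_setup):
        profiles, truth = small_truth_setup
        cfg = fm.ReadSimConfig(library_depth=5000, seed=9)
        counts, sheet = fm.simulate_counts(profiles, 3, cfg, truth=truth)
        (parent, rep), = sheet.replicate_pairs()
        assert (counts[parent] == counts[rep]).all()

    def test_poisson_limit_of_dispersion(self, small_truth_setup):
        """As the NB dispersion goes to zero the variance/mean ratio of the
        counts approaches 1 (Poisson)."""
        profiles, truth = small_truth_setup
        cfg = fm.ReadSimConfig(library_depth=20000, nb_dispersion=1e-8,
                               reference_dispersion=1e-8, seed=13)
        counts, sheet = fm.simulate_counts(profiles, 30, cfg,
                                           sample_sheet=fm.make_sample_sheet(30))
        mb = counts[[s for s in counts.columns if s.startswith("MB")]]
        m = mb.mean(axis=1)
        v = mb.var(axis=1, ddof=1)
        big = m > 20
        ratio = (v[big] / m[big]).mean()
        assert ratio == pytest.approx(1.0, rel=0.1)

    def test_planted_effect_recovered_at_large_n(self, small_ref):
        """Empirical group-mean ratio of a planted marker converges to 2^e
        (within 10% relative error at n=200)."""
        profiles, truth = fm.build_profiles(
            small_ref, fm.TruthSpec(n_asm_per_group=1, n_rsm_per_pair=0,
                                    n_reference_genes=0, asm_effect=3.0),
            seed=21,
        )
        cfg = fm.ReadSimConfig(library_depth=30000, seed=23)
        counts, sheet = fm.simulate_counts(
            profiles, 200, cfg, truth=truth, sample_sheet=fm.make_sample_sheet(200)
        )
        g = "MB"
        rid = next(iter(truth.asm[g]))
        mb_cols = sheet.samples_for_group("MB")
        sa_cols = sheet.samples_for_group("SA")
        ratio = counts.loc[rid, mb_cols].mean() / counts.loc[rid, sa_cols].mean()
        assert ratio == pytest.approx(8.0, rel=0.10)


class TestSimulateReads:
    def test_conservation_and_exact_read_counts(self, small_ref,
                                                small_truth_setup, tmp_path):
        """With no errors and no PCR duplication, reads per sample equal
        the molecule count, every insert matches a reference sequence
        exactly, and manifest molecule totals match the count matrix."""
        profiles, truth = small_truth_setup
        cfg = fm.ReadSimConfig(library_depth=4000, pcr_dup_mean=1.0,
                               error_rate=0.0, seed=31)
        counts, sheet = fm.simulate_counts(profiles, 2, cfg, truth=truth)
        manifest = fm.simulate_reads(counts, small_ref, cfg, tmp_path)
        seqs = {r.sequence for r in small_ref}
        umi_len = cfg.umi_length
        for sample in counts.columns:
            lines = (tmp_path / f"{sample}.fastq").read_text().splitlines()
            n_reads = len(lines) // 4
            assert n_reads == counts[sample].sum()
            for seq_line in lines[1::4]:
                matched = any(
                    seq_line.startswith(s) for s in seqs
                    if len(s) + umi_len <= len(seq_line)
                )
                assert matched
            msum = manifest.loc[manifest.sample_id == sample, "molecules"].sum()
            assert msum == counts[sample].sum()

    def test_pcr_duplication_mean(self, small_ref, small_truth_setup, tmp_path):
        profiles, truth = small_truth_setup
        cfg = fm.ReadSimConfig(library_depth=30000, pcr_dup_mean=3.0,
                               error_rate=0.0, seed=37)
        counts, sheet = fm.simulate_counts(profiles, 2, cfg, truth=truth)
        sub = counts[["MB001"]]
        fm.simulate_reads(sub, small_ref, cfg, tmp_path)
        n_reads = (tmp_path / "MB001.fastq").read_text().count("\n") // 4
        n_molecules = sub["MB001"].sum()
        assert n_molecules > 5000
        # CLT bound: mean duplicates per molecule ~ N(3, sqrt(2/n))
        assert n_reads / n_molecules == pytest.approx(3.0, abs=0.1)

    def test_byte_identical_fastq_for_fixed_seed(self, small_ref,
                                                 small_truth_setup,
                                                 tmp_path_factory):
        profiles, truth = small_truth_setup
        cfg = fm.ReadSimConfig(library_depth=3000, seed=41)
        counts, _ = fm.simulate_counts(profiles, 2, cfg, truth=truth)
        d1 = tmp_path_factory.mktemp("rep1")
        d2 = tmp_path_factory.mktemp("rep2")
        fm.simulate_reads(counts, small_ref, cfg, d1)
        fm.simulate_reads(counts, small_ref, cfg, d2)
        for fq in sorted(d1.glob("*.fastq")):
            assert fq.read_bytes() == (d2 / fq.name).read_bytes()
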