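"""Annotation-cascade, UMI-collapse and EXP-normalisation tests, including
the manifest-derived oracle for absolute molecule counts."""

import numpy as np
import pandas as pd
import pytest

import fluidmark as fm
from fluidmark.containers import CLASS_RANK, ReferenceRecord, ReferenceSet
from fluidmark.preprocess import CleanRead
from fluidmark.quantify import (
    NormalizationError,
    ReferenceIndex,
    directional_molecule_count,
)


@pytest.fixture(scope="module")
def toy_ref():
    return ReferenceSet(
        [
            ReferenceRecord("miR-a", "miRNA", "ACGTACGTACGTACGTACGTAC"),
            ReferenceRecord("miR-b", "miRNA", "TTTTACGTACGTACGTACGTAC"),
            ReferenceRecord("piR-a", "piRNA", "GGGGACGTACGTACGTACGTACGTACGG"),
            ReferenceRecord("tRNA-a", "tRNA", "CCCCACGTACGTACGTACGTAC"),
        ]
    )


def brute_force_assign(insert, ref, max_mismatch):
    """Oracle: exhaustive scan honouring class priority, then mismatch
    count, then lexicographic id."""
    best = None
    for rec in ref:
        if len(rec.sequence) != len(insert):
            continue
        mm = sum(1 for a, b in zip(rec.sequence, insert) if a != b)
        if mm <= max_mismatch:
            cand = (CLASS_RANK[rec.rna_class], mm, rec.rna_id, rec.rna_class)
            if best is None or cand < best:
                best = cand
    return None if best is None else (best[2], best[3])


class TestAssignClass:
    def test_exact_hit(self, toy_ref):
        assert fm.assign_class("ACGTACGTACGTACGTACGTAC", toy_ref) == ("miR-a", "miRNA")

    def test_class_priority_cascade(self):
        seq = "ACGTACGTACGTACGTACGTAC"
        ref = ReferenceSet(
            [
                ReferenceRecord("piR-x", "piRNA", seq),
                ReferenceRecord("miR-x", "miRNA", seq[:-1] + ("G" if seq[-1] != "G" else "T")),
            ]
        )
        # exact piRNA hit loses to a 1-mismatch miRNA hit: class outranks
        got = fm.assign_class(seq, ref, max_mismatch=1)
        assert got == ("miR-x", "miRNA")
        assert got == brute_force_assign(seq, ref, 1)

    def test_one_mismatch_assignment(self, toy_ref):
        query = "GGGGACGTACGTACGTACGTACGTACGT"[:27] + "T"
        assert fm.assign_class(query, toy_ref, 1) == ("piR-a", "piRNA")

    def test_unassigned_when_no_match(self, toy_ref):
        assert fm.assign_class("G" * 22, toy_ref, 1) is None

    def test_matches_exhaustive_oracle_on_random_queries(self, small_ref):
        rng = np.random.default_rng(55)
        index = ReferenceIndex(small_ref)
        seqs = [r.sequence for r in small_ref]
        queries = []
        for i in range(300):
            base = seqs[int(rng.integers(0, len(seqs)))]
            chars = list(base)
            for _ in range(int(rng.integers(0, 3))):  # 0-2 substitutions
                pos = int(rng.integers(0, len(chars)))
                chars[pos] = "ACGT"[int(rng.integers(0, 4))]
            queries.append("".join(chars))
        for q in queries:
            for mm in (0, 1):
                assert fm.assign_class(q, index, mm) == \
                    brute_force_assign(q, small_ref, mm)


class TestCollapseUmi:
    def test_distinct_umis_counted(self, toy_ref):
        reads = [(("miR-a", "miRNA"), u) for u in
                 ["AAAAAAAAAA", "AAAAAAAAAA", "CCCCCCCCCC", "GGGGGGGGGG"] * 2
                 + ["AAAAAAAAAA", "CCCCCCCCCC"]]
        cm = fm.collapse_umi({"s1": reads})
        assert cm.counts.loc["miR-a", "s1"] == 3

    def test_directional_rule_merges_error_umi(self):
        umis = {"AAAAAAAAAA": 9, "AAAAAAAAAT": 1}
        assert directional_molecule_count(umis) == 1
        # parent too weak to absorb the child: two molecules
        assert directional_molecule_count({"AAAAAAAAAA": 2, "AAAAAAAAAT": 2}) == 2

    def test_trna_excluded_but_counts_toward_mapping_rate(self):
        reads = [
            (("tRNA-a", "tRNA"), "AAAAAAAAAA"),
            (("miR-a", "miRNA"), "CCCCCCCCCC"),
            (None, "GGGGGGGGGG"),
        ]
        cm = fm.collapse_umi({"s1": reads})
        assert list(cm.counts.index) == ["miR-a"]
        assert cm.mapping_rate["s1"] == pytest.approx(2 / 3)

    def test_read_order_invariance(self, errorfree_run):
        sample = "SE001"
        reads = errorfree_run["clean"][sample]
        index = ReferenceIndex(errorfree_run["ref"])
        assigned = [(fm.assign_class(r.insert, index, 1), r.umi) for r in reads]
        fwd = fm.collapse_umi({sample: assigned})
        rev = fm.collapse_umi({sample: assigned[::-1]})
        pd.testing.assert_frame_equal(fwd.counts, rev.counts)

    def test_errorfree_counts_match_manifest_oracle(self, errorfree_run):
        """With no sequencing errors, the UMI-collapsed count matrix equals
        distinct-UMI counts recomputed directly from the truth manifest
        (which absorbs any UMI collisions)."""
        ref = errorfree_run["ref"]
        class_of = {r.rna_id: r.rna_class for r in ref}
        manifest = errorfree_run["manifest"]
        got = errorfree_run["counts"].counts
        mismatches = 0
        cells = 0
        expected = {}
        for row in manifest.itertuples():
            if class_of[row.rna_id] in ("tRNA", "rRNA"):
                continue
            expected[(row.rna_id, row.sample_id)] = len(set(row.umis.split(",")))
        for (rid, sample), exp_n in expected.items():
            cells += 1
            if int(got.at[rid, sample]) != exp_n:
                mismatches += 1
        # and no counts where the manifest has none
        total = int(got.values.sum())
        assert total == sum(expected.values())
        assert cells > 1000
        assert mismatches == 0


class TestNormalizeExp:
    def test_column_sums_and_arithmetic(self, errorfree_run):
        exp = errorfree_run["exp"]
        sums = exp.exp.sum(axis=0)
        assert np.allclose(sums, exp.scale_constant, atol=1e-6)

    def test_simple_proportions(self, small_ref):
        counts = pd.DataFrame({"s1": [10, 90]}, index=["a", "b"])
        sheet = fm.SampleSheet(pd.DataFrame(
            [{"sample_id": "s1", "group": "MB", "replicate_of": ""},
             {"sample_id": "s2", "group": "MB", "replicate_of": ""}]))
        cm = fm.CountMatrix(counts)
        exp = fm.normalize_exp(cm, sheet, 1e5)
        assert exp.exp.loc["a", "s1"] == pytest.approx(10000)
        assert exp.exp.loc["b", "s1"] == pytest.approx(90000)
        doubled = fm.normalize_exp(fm.CountMatrix(counts * 2), sheet, 1e5)
        pd.testing.assert_frame_equal(exp.exp, doubled.exp)

    def test_zero_sample_raises_with_name(self):
        counts = pd.DataFrame({"s1": [1], "s2": [0]}, index=["a"])
        sheet = fm.SampleSheet(pd.DataFrame(
            [{"sample_id": "s1", "group": "MB", "replicate_of": ""},
             {"sample_id": "s2", "group": "MB", "replicate_of": ""}]))
        with pytest.raises(NormalizationError, match="s2"):
            fm.normalize_exp(fm.CountMatrix(counts), sheet)

    def test_group_means_exclude_technical_replicate(self, errorfree_run):
        exp = errorfree_run["exp"]
        sheet = errorfree_run["sheet"]
        (parent, rep), = sheet.replicate_pairs()
        members = sheet.samples_for_group("VB")
        assert rep not in members
        manual = exp.exp[members].mean(axis=1)
        pd.testing.assert_series_equal(
            exp.group_means["VB"], manual, check_names=False
        )


class TestTierExpression:
    @pytest.mark.parametrize(
        "value,tier",
        [
            (0.0, "undetected"),
            (0.5, "low"),
            (1.0, "low"),
            (1.0001, "moderate"),
            (5.3, "moderate"),
            (9.999, "moderate"),
            (10.0, "high"),
            (376.19, "high"),
        ],
    )
    def test_tier_boundaries(self, value, tier):
        assert fm.tier_expression(value) == tier

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fm.tier_expression(-0.1)


class TestProfileSummaries:
    def test_single_class_composition_is_one(self):
        ref = ReferenceSet([ReferenceRecord("miR-a", "miRNA", "A" * 22)])
        counts = pd.DataFrame({"s1": [5], "s2": [3]}, index=["miR-a"])
        sheet = fm.SampleSheet(pd.DataFrame(
            [{"sample_id": "s1", "group": "MB", "replicate_of": ""},
             {"sample_id": "s2", "group": "MB", "replicate_of": ""}]))
        comp = fm.class_composition(fm.CountMatrix(counts), ref, sheet)
        assert comp["MB"] == {"miRNA": pytest.approx(1.0)}

    def test_semen_group_is_pirna_dominant(self, errorfree_run):
        comp = fm.class_composition(
            errorfree_run["counts"], errorfree_run["ref"], errorfree_run["sheet"]
        )
        se = comp["SE"]
        assert se["piRNA"] == max(se.values())
        assert comp["MB"]["miRNA"] == max(comp["MB"].values())

    def test_intersections_sum_to_detected(self, errorfree_run):
        inter = fm.group_intersections(errorfree_run["exp"])
        gm = errorfree_run["exp"].group_means
        detected_anywhere = int((gm > 0).any(axis=1).sum())
        assert sum(inter.values()) == detected_anywhere
        assert all(pattern for pattern in inter)

    def test_replicate_correlation_trivial_cases(self, errorfree_run):
        exp = errorfree_run["exp"]
        s = exp.exp.columns[0]
        assert fm.replicate_correlation(exp, s, s) == pytest.approx(1.0)

    def test_replicate_pair_highly_correlated(self, errorfree_run):
        """Technical replicates share the molecule pool; only UMI draws and
        PCR resampling differ, so EXP correlation should be near one."""
        (parent, rep), = errorfree_run["sheet"].replicate_pairs()
        r = fm.replicate_correlation(errorfree_run["exp"], parent, rep)
        assert r > 0.95

    def test_anticorrelated_toy_vectors(self):
        counts = pd.DataFrame({"s1": [1, 2, 3], "s2": [3, 2, 1]},
                              index=["a", "b", "c"])
        sheet = fm.SampleSheet(pd.DataFrame(
            [{"sample_id": "s1", "group": "MB", "replicate_of": ""},
             {"sample_id": "s2", "group": "MB", "replicate_of": ""}]))
        exp = fm.normalize_exp(fm.CountMatrix(counts), sheet)
        # equal column sums, so EXP preserves the anti-proportional pattern
        r = fm.replicate_correlation(exp, "s1", "s2")
        assert r == pytest.approx(-1.0)
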