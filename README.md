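# fluidmark

UMI-based small-RNA profiling and specific-marker screening for forensic
body-fluid / tissue identification (BFID).

Forensic stains — menstrual blood (MB), saliva (SA), semen (SE), skin
(SK), venous blood (VB), vaginal secretion (VS) — can be told apart by
their small non-coding RNA profiles (miRNA, piRNA, snoRNA, snRNA), which
are abundant and degradation-resistant.  `fluidmark` implements the full
computational workflow for this kind of study:

1. **Read cleaning** — 3'-adapter location with bounded mismatches, UMI
   extraction, 18–30 nt insert window, poly-A and quality filters, with
   exact per-sample QC accounting (raw = clean + discards).
2. **Absolute quantification** — class-priority annotation
   (miRNA → piRNA → snoRNA → snRNA → tRNA → rRNA, equal-length matching
   with ≤1 substitution), UMI collapse to molecule counts (`exact` or
   `directional` merging), tRNA/rRNA deletion, and EXP normalisation
   (molecules per 10⁵ assigned molecules per sample).
3. **Differential expression** — for each of the C(6,2) = 15 group
   pairs, a negative-binomial Wald test on
   log2FC = log2((m̄_A + c)/(m̄_B + c)) with method-of-moments dispersion
   (Var = m + αm²), median-of-ratios size factors and Benjamini–Hochberg
   adjustment within the pair.
4. **Marker screening** — *relative specific markers* (RSM: log2FC > 1
   toward one member of a pair, q < 0.05), *absolute specific markers*
   (ASM: the same condition against all five other groups), and
   reference genes (EXP > 1 everywhere, lowest CV of log2(EXP+1)).
5. **Grading and validation** — per-comparison specificity levels
   I (1,2] / II (2,3] / III (3,4] / IV (>4) on log2FC; expression levels
   I (1,10] / II (10,100] / III (100,1000] / IV (>1000) on group-mean
   EXP with linear-tercile sublevels + / ++ / +++; hierarchical
   clustering of samples on Euclidean distance over ASM expression with
   a 6-cluster purity score.

Because real casework libraries are not distributable, the package
includes a first-class synthetic generator (`fluidmark.simulate`) that
produces ground-truthed references, group profiles with planted
ASMs/RSMs/reference genes, negative-binomial counts, and UMI-tagged
FASTQ reads with PCR duplication and sequencing errors — the whole
pipeline is exercised and validated against that planted truth.  See
`docs/methods.md` for the model and its assumptions.

## Worked example

Run the full synthetic study end to end (simulate → preprocess →
quantify → DE → markers → grade):

```sh
fluidmark -v all --out-dir run --seed 17
```

```
INFO fluidmark: preprocess: 31 samples cleaned
INFO fluidmark: quantify: 2012 RNAs x 31 samples
INFO fluidmark: de: 15 pairs tested
INFO fluidmark: markers: 6002 RSM rows, 594 ASMs
INFO fluidmark: grade: 594 graded ASMs
```

`run/` now contains the reference FASTA, per-sample FASTQ, the truth
manifest, QC statistics, count/EXP matrices, 15 DE tables, the marker
tables and the grade table.  The top of `run/grades.tsv`:

```
group  rna_id         spec_I  spec_II  spec_III  spec_IV  expression_level  expression_sub  mean_exp
MB     miR-sim-00501  0       4        1         0        IV                                2094.03245270747
MB     piR-sim-00044  0       3        2         0        IV                                1354.91691658766
```

Each row is one ASM: the `spec_*` columns count in how many of its five
pairwise comparisons the log2 fold change fell in that specificity
level (miR-sim-00501 beats the other groups by 4–16-fold in four
comparisons and 8–16-fold in one), and the expression grade places its
target-group mean EXP of 2094 in level IV (> 1000), where no sublevel
applies.  A marker graded, say, III "+" — mean EXP just above 100 —
would be specific but harder to detect; the two axes are
detection-oriented and efficiency-oriented respectively.

QC and validation summaries from the same run:

```
$ head -2 run/qc_stats.tsv
sample_id  raw_reads  clean_reads  q20_fraction  discard_no_adapter
MB001      30839      30832        1.0           7

$ python -c "import json; d=json.load(open('run/validation.json')); print(d['n_asm'], d['cluster_purity'])"
594 0.8709677419354839
```

594 ASMs are recovered (the 36 planted ones plus the class-composition
differences the generator builds in, e.g. semen's piRNA dominance), and
clustering all 31 samples on those markers groups 87% of them with
their own fluid.  The technical-replicate pair VB002/VB006 reports a
Pearson correlation of 0.9997 in `run/quantify_summary.json`.

Every stage can also be run individually (`fluidmark simulate`,
`fluidmark de`, ...) against an existing run directory, and
`fluidmark show-config` prints the effective parameters.  The same
functionality is available as a library:

```python
import fluidmark as fm

ref = fm.build_reference({"miRNA": 550, "piRNA": 1200, "snoRNA": 250,
                          "snRNA": 20, "tRNA": 30, "rRNA": 30}, seed=17)
profiles, truth = fm.build_profiles(ref, fm.TruthSpec(), seed=18)
counts, sheet = fm.simulate_counts(profiles, 5, fm.ReadSimConfig(seed=19),
                                   truth=truth)
```

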