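# aiedit

Exome-wide A-to-I RNA-editing analysis from paired tumor/normal DNA and
RNA base counts.

## The problem

Adenosine deaminases acting on RNA (ADAR1-p110, ADAR1-p150, ADAR2)
deaminate adenosine to inosine in double-stranded RNA; sequencers and
ribosomes read inosine as guanosine, so editing appears in RNA-seq as an
A>G mismatch against the DNA (or T>C on the reference-forward strand of a
minus-strand gene). Distinguishing genuine editing from germline SNPs,
somatic mutations and sequencing artifacts in a tumor/normal cohort
requires a disciplined filter cascade; quantifying *how much* a tumor
over-edits relative to its matched normal tissue, and whether that burden
tracks ADAR expression, requires paired editing-level statistics. `aiedit`
implements this entire workflow for anyone analyzing exome-scale editing
in paired cohorts, starting from per-site base counts (post-alignment) and
ending at cohort statistics.

## What it does

- **`synthdata`** — simulates a complete, self-consistent cohort (reference
  genome, gene models, Alu/simple-repeat annotation, SNP catalogue with
  minor allele frequencies, conservation scores, paired DNA/RNA base
  counts for tumor and normal of every patient, ADAR expression coupled to
  editing, Sanger-style chromatogram traces) with full ground truth, so
  every downstream stage is testable without controlled-access data.
- **`varcall`** — a transparent threshold caller: a candidate variant needs
  depth ≥ 8×, variation frequency (VAF = alt/(ref+alt)) ≥ 5 %, mean
  alternate base quality ≥ 20, and no read-strand bias (two-sided Fisher
  exact test on the {ref,alt}×{fwd,rev} table, α = 0.05).
- **`edcall`** — the editing filter cascade: subtract any variant with DNA
  support in the same patient; remove catalogued SNPs with MAF > 0.001;
  discard simple-repeat calls; partition into Alu (kept as-is) and non-Alu
  (further required to have VAF ≥ 10 % and a flanking 50-mer unique in the
  genome); then strand-aware mismatch classification (12 classes after
  strand collapse), recoding annotation (codon ⌊(cds_pos−1)/3⌋+1, standard
  genetic code), and assembly into cohort-level editing sites with
  recurrence, database and conservation annotation.
- **`edprofile`** — editing-level matrices, singleton/recurrence and
  mismatch-spectrum summaries, per-patient over-/under-editing (a site is
  over-edited when VAF_tumor − VAF_normal > 0.10), and the ±10 nt
  neighbor-preference base-frequency matrix.
- **`edassoc`** — Spearman correlation of editing burden (or per-site
  levels) with ADAR expression (exact permutation p for n ≤ 9), paired
  t tests of tumor vs normal levels, expression fold changes.
- **`sangerq`** — editing percentage from chromatogram peak heights,
  100·G/(A+G) after baseline subtraction, with reverse-strand channel
  swapping and batch quantification.

## Worked example

```python
import pandas as pd
from aiedit import (CohortConfig, simulate_cohort, discover_editing_sites,
                    benchmark_against_truth, edprofile, edassoc)

cohort = simulate_cohort(CohortConfig(seed=1))     # 15 patients, 200 edits
result = discover_editing_sites(cohort)
print(result.stage_counts)
bench = benchmark_against_truth(result, cohort)
print(f"sensitivity={bench.sensitivity:.3f} precision={bench.precision:.3f}")

matrix = edprofile.level_matrix(cohort.counts, result.sites)
summaries, stats = edprofile.patient_overediting(matrix)
print(stats)
burden = pd.Series({s.patient: s.over_fraction for s in summaries}).dropna()
res = edassoc.burden_expression_correlation(burden, cohort.expression)
print(f"rho={res.estimate:.2f} p={res.p_value:.4f}")
```

prints

```
{'input': 1783, 'dna_subtracted': 463, 'snp_filtered': 463,
 'repeat_filtered': 463, 'alu_group': 104, 'non_alu_group': 359,
 'non_alu_refined': 346, 'surviving': 450, 'sites': 200}
sensitivity=0.995 precision=0.995
{'n_patients_evaluated': 15, 'n_over_dominant': 14, 'over_dominant_pct': 93.3}
rho=0.73 p=0.0018
```

Reading this: 1783 raw RNA calls collapse to 463 once anything with DNA
support (germline SNPs, somatic SNVs) is subtracted; the non-Alu group
loses 13 more calls to the stringent 10 %/uniqueness refinement; the 450
surviving per-sample calls collapse to 200 cohort sites, recovering 199 of
the 200 planted edits with one false positive. Because the generator
couples tumor editing to ADAR1-p110 expression, 14 of 15 patients are
over-editing-dominant and the burden-expression Spearman correlation is
strongly positive.

The same stages are available from a shell:

```bash
aiedit simulate --out cohort/ --seed 1
aiedit call --counts cohort/base_counts.tsv --genes cohort/genes.bed \
            --material RNA --out rna_calls.tsv
aiedit profile cascade --cohort-dir cohort/ --rna-calls rna_calls.tsv \
            --out sites.tsv
aiedit profile summarize --sites sites.tsv --out summary.json
```

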