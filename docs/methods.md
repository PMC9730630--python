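# Methods

## Model and procedure

A-to-I editing converts adenosine to inosine in double-stranded RNA;
inosine base-pairs like guanosine, so an edited position appears in
RNA-seq reads as an A>G mismatch on the transcribed strand while the
underlying DNA remains homozygous reference. The package treats editing
discovery as a constrained variant-calling problem on paired DNA/RNA
base-count tables followed by set subtraction:

1. **Candidate calling.** Within annotated gene territory, a non-reference
   allele is a candidate when site depth ≥ 8×, VAF = alt/(ref+alt) ≥ 0.05,
   the mean Phred quality of alternate-supporting bases ≥ 20, and the
   two-sided Fisher exact p on the {ref,alt}×{fwd,rev} read-strand table is
   ≥ α (default 0.05). All comparisons are inclusive (depth 8 and VAF 0.05
   pass). The strand test is skipped below 2 alternate reads, where it has
   no power and would only add noise. "Base quality ≥ 20" is applied to
   the per-allele mean carried by the base-count format; a read-level mask
   is not expressible at this abstraction and the choice is recorded here.
2. **DNA subtraction.** An RNA call is removed when the same patient's
   exome shows the same allele at the same site in either tissue with ≥ 2
   alternate reads or ≥ 2 % allele fraction (both configurable). This is
   deliberately far laxer than DNA variant *calling*: any DNA trace of the
   allele disqualifies it as editing. A patient with RNA calls but no DNA
   data at all is an error unless explicitly allowed.
3. **Known-SNP removal.** Calls at catalogue positions with matching
   alternate allele and minor allele frequency strictly above 0.001 are
   removed; rarer catalogue entries do not remove calls (they are
   indistinguishable from private variation, which the DNA subtraction
   handles).
4. **Simple-repeat removal**, then **Alu partition**. Calls in Alu
   elements receive no further filtering — the A-to-G dominance there is
   credible a priori because inverted Alu pairs form the dsRNA substrate
   ADARs require. Non-Alu calls must additionally reach VAF ≥ 0.10 and
   have a flanking k-mer (k = 50, centered) that occurs exactly once in
   the reference counting both strands. The k-mer test is an exact,
   deterministic surrogate for a genome-wide similarity search (BLAT-style
   tools are neither deterministic nor self-contained at this scale); a
   precomputed low-mappability BED can be supplied instead for real
   genomes, where 50-mer exactness is too blunt an instrument.
5. **Assembly.** Surviving per-sample calls are collapsed by (site, alt).
   Mismatch classes are strand-collapsed (both alleles complemented for
   minus-strand genes, so a reference-forward T>C is A-to-G), giving 12
   ordered classes. Recurrence counts distinct patients by default — a
   patient's tumor and normal samples count once — with a per-sample mode
   available, since published singleton counts can be read either way.
   Codon consequences use cds_pos on the transcribed strand,
   codon_index = ⌊(cds_pos−1)/3⌋+1, and the standard genetic code (e.g.
   A>G at CDS position 22 of a transcript whose eighth codon is ATG gives
   p.M8V).

The subtraction stages (2–4a) commute as set operations; the Alu partition
must precede the stringent non-Alu refinement, and the pipeline enforces
this ordering.

### Downstream statistics

- **Editing level** is the VAF at a site in one RNA sample; a level exists
  only where ref+alt reads ≥ a minimum depth (default 8), otherwise the
  site/sample cell is missing.
- **Over-/under-editing**: per patient, a site with both tissues observed
  is over-edited when level_tumor − level_normal > 0.10 (strict) and
  under-edited when the reverse difference exceeds 0.10; pairs missing a
  tissue are excluded, patients with no evaluable pair leave the
  denominator. The cohort statistic is the fraction of evaluable patients
  with more over- than under-edited sites.
- **Neighbor preference**: base frequencies at offsets −10…+10 around the
  edited adenosine on the transcribed strand (minus-strand contexts
  reverse-complemented). Every row sums to 1 and the center row is
  degenerate at A by construction.
- **Association**: Spearman rho with mid-ranked ties; the two-sided p is
  an exact permutation enumeration for n ≤ 9 (9! tables) and the usual t
  approximation above. Paired tumor/normal comparisons use the paired
  Student t (optionally on log-transformed values); degenerate inputs are
  guarded (identical vectors → t=0, p=1; a zero-variance non-zero shift →
  p=0). Printed-style percentages round half away from zero to one
  decimal, matching how such tables are typeset. No multiple-testing
  correction is applied by default, mirroring nominal-p reporting.
- **Trace quantification**: editing % = 100·G/(A+G) from
  baseline-subtracted peak heights at the basecall position (window ±4
  scan points; baseline = channel median over the trace; a peak-area mode
  exists behind a flag since peak-height vs area is an open choice among
  trace-quantification tools). Reverse-strand reads complement-swap the
  channels. The estimate is scale-invariant and withheld with a
  "no-signal" flag when A+G falls below a configurable floor.

## Synthetic cohort generator

The generator emulates the *structure* of a 15-patient paired tumor/normal
discovery cohort, not any real dataset's content. Defaults: 200 planted
A-to-I sites (recurrence profile ≈ 91 % singletons), 500 germline SNPs
with log-uniform MAF in [1e-4, 0.5] (straddling the 0.001 catalogue
threshold), 50 somatic SNVs (one patient each, tumor VAF ~ U(0.1, 0.5)),
250 error-only background sites, 50× mean Poisson depth in both materials,
1e-3 uniform per-base error, base qualities ~ N(35, 3) truncated to
[2, 41] (headroom around the Q20 threshold), Alu covering 30 % of gene
territory, simple repeats 2 %. True editing levels are Beta(6, 14) in
normal and Beta(8, 12) in tumor tissue — means 0.30 and 0.40, the range
where validated recoding sites typically sit — and the tumor level of each
patient is shifted by `adar_coupling` × (standardized log2 tumor
ADAR1-p110), linking expression to burden. Expression is FPKM-like:
ADAR1-p110 ≈ 22 in normal liver with an average 1.8-fold tumor increase
(≈ 40 in tumor, ~20-fold above ADAR2 at ≈ 2); only ranks matter
downstream. Edits sit on adenosines of the transcribed strand (T>C on the
forward reference for minus-strand genes, so strand collapse is genuinely
exercised), avoid simple repeats, and with probability 0.7 have C or T
planted immediately 5' (the ADAR neighbor preference; CAG/TAG contexts
dominate real data). SNP carriers are heterozygous (allele fraction 0.5)
in both materials and tissues; DNA is homozygous reference at edit sites.
Chromatograms are sums of per-base Gaussian peaks (12 scan points per
base, σ = 2.5, amplitude ≈ 1000 with ±15 % jitter) with the center A/G
amplitudes split (1−level)/level, plus additive Gaussian noise clipped at
zero.

What the generator does *not* emulate: alignment artifacts other than a
requestable strand-bias artifact, overdispersed or GC-biased coverage,
allele-specific expression, hyper-editing read clusters, degraded-RNA
biases, and real Alu sequence content (intervals are labels, not SINE
sequence). Passing tests therefore demonstrate correctness of the
decision rules and statistics under a clean generative model, not
robustness to every real-data pathology.

## Numerical and convention choices

- Interval files are 0-based half-open; site records are 1-based. A site
  with 1-based coordinate p is tested against an annotation interval
  [start, end) as start ≤ p < end, so an interval's exclusive end never
  captures the site printed at that coordinate; readers/writers are the
  only place conventions convert.
- Depth for the ≥ 8× filter is the sum of all eight stranded counts; the
  VAF denominator is ref+alt only, and a site with two alternate alleles
  above threshold yields one call per allele.
- Determinism: every stochastic component flows from one integer seed via
  `numpy.random.default_rng`; identical configurations produce
  bit-identical output files. The reference/annotation skeleton and the
  count simulation draw from independent seed streams so a fixed panel
  can be re-sequenced across replicates.
- The flanking-uniqueness index treats a palindromic k-mer's two strands
  as one occurrence; windows that would run off a contig leave the site
  retained with a warning rather than silently dropped.

## Benchmarks and problem sizes

`aiedit.benchmarks` (driven by `scripts/acceptance.py` and the acceptance
tests) uses: the default 200-edit cohort for recovery (sensitivity ≥ 0.90,
precision ≥ 0.95 against planted truth; heterozygous SNPs cannot evade DNA
subtraction, while a low-VAF somatic SNV occasionally can when the exome
samples zero alternate reads — that failure mode is a property of the
published subtraction logic and is charged to precision); 200 replicate
25-site panels at `adar_coupling = 0` for null calibration of the
burden-expression Spearman test (fixed panel, redrawn expression, levels
and reads); 60 simulated traces for the Sanger round-trip; and a ~450-call
cohort for the brute-force cascade cross-check. These sizes give stable
statistics at interactive runtimes on a single core.

## Known limitations

- The caller has no genotype-likelihood model and no indel support; it is
  a faithful implementation of a threshold rule, not a general-purpose
  variant caller.
- Hyper-editing clusters and intronic/intergenic discovery are out of
  scope (exome territory only).
- The k-mer uniqueness surrogate under-removes paralogy that diverges
  within 50 bp and over-removes recent exact duplications; supply a
  mappability BED for real genomes.
- Conservation scores are consumed as a precomputed input column; the
  package does not compute them.
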