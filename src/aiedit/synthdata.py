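"""Synthetic paired DNA/RNA editing cohort generator.

Emulates the structure of a tumor/normal exome + transcriptome study of
A-to-I RNA editing: a small reference genome with annotated protein-coding
genes, Alu and simple-repeat intervals, a germline SNP catalogue, planted
A-to-I editing sites (with per-patient, per-tissue true editing levels),
germline heterozygous SNPs, somatic SNVs, per-site base-count tables with
Poisson depth and uniform sequencing error, an ADAR expression table whose
tumor ADAR1-p110 level is coupled to each patient's editing shift, and
4-channel Sanger-style chromatogram traces.

Every downstream stage of the pipeline (variant calling, the editing filter
cascade, profiling, association statistics, trace quantification) is
testable against the ground truth returned alongside the simulated data.
All randomness flows from a single integer seed; identical configurations
produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._util import BASES, complement

MIN_CDS_LEN = 90        # bases; shortest CDS the gene layout will draw
UTR_LEN = 60            # bases of UTR on each side of the CDS
ALU_LEN = 300           # typical SINE element length
REPEAT_LEN = 40         # simple-repeat interval length
GENE_GAP = 50           # minimum intergenic spacing


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass
class CohortConfig:
    """Parameters of a simulated paired tumor/normal editing cohort.

    Defaults describe a 15-patient discovery-style cohort: 200 planted
    A-to-I sites (about 91% singletons), 500 germline SNPs with minor
    allele frequencies straddling the 0.001 catalogue threshold, 50
    somatic SNVs, 50x mean depth in both materials and a 1e-3 per-base
    error rate.
    """

    n_patients: int = 15
    genome_length: int = 200_000
    n_genes: int = 60
    alu_fraction: float = 0.30
    n_edit_sites: int = 200
    n_snps: int = 500
    n_somatic: int = 50
    n_background: int = 250
    n_strand_artifacts: int = 0
    depth_mean_dna: float = 50.0
    depth_mean_rna: float = 50.0
    seq_error_rate: float = 1e-3
    # Beta(a, b) parameters of true editing levels per tissue
    edit_level_normal: tuple[float, float] = (6.0, 14.0)
    edit_level_tumor: tuple[float, float] = (8.0, 12.0)
    # slope linking standardized log2 tumor ADAR1-p110 to the tumor editing shift
    adar_coupling: float = 0.15
    # probability that the base 5' of a planted edit is C or T (ADAR motif)
    motif_ct_bias: float = 0.7
    # distribution over how many patients share each planted site
    recurrence_profile: dict[int, float] = field(
        default_factory=lambda: {1: 0.91, 2: 0.05, 3: 0.03, 5: 0.01}
    )
    simple_repeat_fraction: float = 0.02
    n_duplicated_segments: int = 0
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError(
                "a seed is required: simulated cohorts must be reproducible"
            )
        counts = (
            self.n_patients, self.genome_length, self.n_genes,
            self.n_edit_sites, self.n_snps, self.n_somatic,
            self.n_background, self.n_strand_artifacts,
            self.n_duplicated_segments,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be >= 0")
        if self.n_patients < 1 or self.n_genes < 1:
            raise ConfigurationError("need at least one patient and one gene")
        for p in (self.alu_fraction, self.seq_error_rate,
                  self.motif_ct_bias, self.simple_repeat_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.genome_length < 3 * self.n_genes * MIN_CDS_LEN:
            raise ConfigurationError("genome too short for the requested gene count")
        # worst-case gene footprint must fit with spacing to spare
        worst = self.n_genes * (2 * UTR_LEN + 2 * MIN_CDS_LEN + GENE_GAP)
        if worst > self.genome_length:
            raise ConfigurationError(
                "impossible geometry: more interval mass than genome"
            )
        if self.alu_fraction + self.simple_repeat_fraction > 0.9:
            raise ConfigurationError("repeat annotation would saturate gene territory")
        if not self.recurrence_profile:
            raise ConfigurationError("recurrence profile is empty")
        if any(k < 1 or v < 0 for k, v in self.recurrence_profile.items()):
            raise ConfigurationError("recurrence profile keys >= 1, weights >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "recurrence_profile" in d:
            d["recurrence_profile"] = {int(k): float(v)
                                       for k, v in d["recurrence_profile"].items()}
        for key in ("edit_level_normal", "edit_level_tumor"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GeneModel:
    """One single-exon protein-coding gene; 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str
    cds_start: int
    cds_end: int

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def in_cds(self, pos0: int) -> bool:
        return self.cds_start <= pos0 < self.cds_end


@dataclass
class ReferenceBundle:
    """Reference sequence plus every static annotation the pipeline consumes.

    Planted-site positions are fixed here (before count simulation) because
    the conservation table must cover them and the motif bias rewrites the
    base 5' of each edit on the transcribed strand.
    """

    sequences: dict[str, str]
    genes: list[GeneModel]
    alu: pd.DataFrame            # chrom, start, end, name
    simple_repeats: pd.DataFrame
    snps: pd.DataFrame           # chrom, pos (1-based), id, ref, alt, maf
    conservation: pd.DataFrame   # chrom, pos, score
    planted: pd.DataFrame        # chrom, pos, ref, alt, kind, gene, strand, flags

    def gene_intervals(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.chrom, g.start, g.end, g.name, g.strand, g.cds_start, g.cds_end)
             for g in self.genes],
            columns=["chrom", "start", "end", "name", "strand",
                     "cds_start", "cds_end"],
        )


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    edits: pd.DataFrame          # chrom,pos,ref,alt,gene,strand,in_alu,in_duplication
    edit_levels: pd.DataFrame    # chrom,pos,patient,level_normal,level_tumor
    snps: pd.DataFrame           # chrom,pos,ref,alt,maf
    snp_genotypes: pd.DataFrame  # chrom,pos,patient (heterozygous carriers)
    somatic: pd.DataFrame        # chrom,pos,ref,alt,patient,vaf_tumor
    expression: pd.DataFrame     # gene,patient,tissue,fpkm


@dataclass
class SyntheticCohort:
    config: CohortConfig
    reference: ReferenceBundle
    counts: pd.DataFrame
    truth: SyntheticTruth
    expression: pd.DataFrame


@dataclass
class ChromatogramTrace:
    """4-channel Sanger trace with per-base scan-point indices."""

    intensities: np.ndarray      # (n_scan, 4) in channel order A,C,G,T
    basecalls: str
    base_positions: np.ndarray   # scan index of each basecall, strictly increasing

    def __post_init__(self) -> None:
        if np.any(self.intensities < 0):
            raise ValueError("trace intensities must be non-negative")
        pos = np.asarray(self.base_positions)
        if len(pos) != len(self.basecalls):
            raise ValueError("one scan position per basecall required")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("basecall positions must be strictly increasing")
        if np.any(pos < 0) or np.any(pos >= len(self.intensities)):
            raise ValueError("basecall positions outside scan range")


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def _layout_genes(cfg: CohortConfig, rng: np.random.Generator,
                  chrom: str) -> list[GeneModel]:
    lengths = []
    for _ in range(cfg.n_genes):
        cds_len = MIN_CDS_LEN + 3 * int(rng.integers(0, 171))  # 90..600, codon-exact
        lengths.append(cds_len)
    total = sum(2 * UTR_LEN + l for l in lengths) + cfg.n_genes * GENE_GAP
    if total > cfg.genome_length:
        raise ConfigurationError("impossible geometry: more interval mass than genome")
    slack = cfg.genome_length - total
    gaps = rng.multinomial(slack, np.ones(cfg.n_genes) / cfg.n_genes)
    genes = []
    cursor = 0
    for i, cds_len in enumerate(lengths):
        cursor += GENE_GAP + int(gaps[i])
        start = cursor
        cds_start = start + UTR_LEN
        cds_end = cds_start + cds_len
        end = cds_end + UTR_LEN
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(chrom, start, end, f"GENE{i + 1:03d}",
                               strand, cds_start, cds_end))
        cursor = end
    return genes


def _place_intervals(rng: np.random.Generator, genes: list[GeneModel],
                     target_fraction: float, elem_len: int,
                     name_prefix: str) -> pd.DataFrame:
    """Tile fixed-length elements inside gene bodies until the requested
    fraction of total gene territory is covered. Elements never overlap."""
    territory = sum(g.end - g.start for g in genes)
    target = int(round(target_fraction * territory))
    rows: list[tuple] = []
    covered = 0
    order = rng.permutation(len(genes))
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(genes))}
    attempts = 0
    while covered < target and attempts < 50 * len(genes):
        attempts += 1
        gi = int(order[attempts % len(genes)])
        g = genes[gi]
        span = min(elem_len, g.end - g.start)
        if span <= 0 or g.end - g.start - span <= 0:
            continue
        s = g.start + int(rng.integers(0, g.end - g.start - span))
        e = s + span
        if any(s < oe and os_ < e for os_, oe in occupied[gi]):
            continue
        occupied[gi].append((s, e))
        rows.append((g.chrom, s, e, f"{name_prefix}{len(rows) + 1}"))
        covered += span
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _in_any(pos1: int, intervals: pd.DataFrame) -> bool:
    """Same point-in-interval rule as the filter stages: 1-based site pos1
    is inside [start, end) when start <= pos1 < end."""
    if intervals.empty:
        return False
    m = (intervals["start"] <= pos1) & (pos1 < intervals["end"])
    return bool(m.any())


def generate_reference(config: CohortConfig) -> ReferenceBundle:
    """Build the reference genome, annotations and planted-site skeleton.

    Planted categories (edits, SNPs, somatic SNVs, error-only background
    sites, optional strand-artifact sites) occupy pairwise disjoint
    positions inside gene territory. Edits sit on adenosines of the
    transcribed strand (T on the forward reference for minus-strand genes)
    and avoid simple repeats, so the repeat filter cannot eat true sites.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])
    chrom = "chr1"

    seq = rng.choice(list("ACGT"), size=config.genome_length,
                     p=[0.29, 0.21, 0.21, 0.29])
    genes = _layout_genes(config, rng, chrom)
    # start codon on the transcribed strand, for annotation realism
    for g in genes:
        if g.strand == "+":
            seq[g.cds_start:g.cds_start + 3] = list("ATG")
        else:
            seq[g.cds_end - 3:g.cds_end] = list("CAT")

    alu = _place_intervals(rng, genes, config.alu_fraction, ALU_LEN, "ALU")
    repeats = _place_intervals(rng, genes, config.simple_repeat_fraction,
                               REPEAT_LEN, "SR")

    # ---- choose planted positions (0-based), pairwise disjoint -----------
    genic: list[tuple[int, GeneModel]] = []
    for g in genes:
        for p in range(g.start, g.end):
            genic.append((p, g))
    taken: set[int] = set()

    def sample_positions(n: int, predicate) -> list[tuple[int, GeneModel]]:
        cand = [pg for pg in genic if pg[0] not in taken and predicate(*pg)]
        if len(cand) < n:
            raise ConfigurationError(
                f"cannot place {n} sites: only {len(cand)} candidate positions"
            )
        idx = rng.choice(len(cand), size=n, replace=False)
        chosen = [cand[int(i)] for i in sorted(idx)]
        taken.update(p for p, _ in chosen)
        return chosen

    def is_edit_candidate(p: int, g: GeneModel) -> bool:
        want = "A" if g.strand == "+" else "T"
        if seq[p] != want:
            return False
        return not _in_any(p + 1, repeats)

    edit_sites = sample_positions(config.n_edit_sites, is_edit_candidate)
    snp_sites = sample_positions(config.n_snps, lambda p, g: True)
    som_sites = sample_positions(config.n_somatic, lambda p, g: True)
    bg_sites = sample_positions(config.n_background, lambda p, g: True)
    art_sites = sample_positions(config.n_strand_artifacts, lambda p, g: True)

    # ---- 5' neighbor preference of ADAR (C/T depletion of G upstream) ----
    for p, g in edit_sites:
        if rng.random() >= config.motif_ct_bias:
            continue
        nb = p - 1 if g.strand == "+" else p + 1     # transcript 5' neighbor
        if nb in taken or nb < 0 or nb >= len(seq):
            continue
        base_tx = "C" if rng.random() < 0.5 else "T"
        seq[nb] = base_tx if g.strand == "+" else complement(base_tx)

    # ---- optional duplicated segments (exercise uniqueness filtering) ----
    sequences = {chrom: "".join(seq)}
    dup_edit_pos: set[int] = set()
    if config.n_duplicated_segments > 0:
        s = sequences[chrom]
        extra = []
        pool = [p for p, _ in edit_sites]
        pick = rng.choice(len(pool), size=min(config.n_duplicated_segments,
                                              len(pool)), replace=False)
        for i in pick:
            p = pool[int(i)]
            lo, hi = max(0, p - 100), min(len(s), p + 100)
            extra.append(s[lo:hi])
            dup_edit_pos.add(p)
        sequences[chrom] = s + "".join(extra)

    # ---- catalogue tables -------------------------------------------------
    def alt_for(ref: str) -> str:
        others = [b for b in BASES if b != ref]
        return others[int(rng.integers(0, 3))]

    s = sequences[chrom]
    planted_rows = []
    for p, g in edit_sites:
        ref = s[p]
        alt = "G" if g.strand == "+" else "C"
        planted_rows.append((chrom, p + 1, ref, alt, "edit", g.name, g.strand,
                             _in_any(p + 1, alu), p in dup_edit_pos))
    for p, g in snp_sites:
        planted_rows.append((chrom, p + 1, s[p], alt_for(s[p]), "snp",
                             g.name, g.strand, _in_any(p + 1, alu), False))
    for p, g in som_sites:
        planted_rows.append((chrom, p + 1, s[p], alt_for(s[p]), "somatic",
                             g.name, g.strand, _in_any(p + 1, alu), False))
    for p, g in bg_sites:
        planted_rows.append((chrom, p + 1, s[p], alt_for(s[p]), "background",
                             g.name, g.strand, _in_any(p + 1, alu), False))
    for p, g in art_sites:
        planted_rows.append((chrom, p + 1, s[p], alt_for(s[p]), "artifact",
                             g.name, g.strand, _in_any(p + 1, alu), False))
    planted = pd.DataFrame(
        planted_rows,
        columns=["chrom", "pos", "ref", "alt", "kind", "gene", "strand",
                 "in_alu", "in_duplication"],
    )

    snp_mask = planted["kind"] == "snp"
    mafs = np.exp(rng.uniform(np.log(1e-4), np.log(0.5), int(snp_mask.sum())))
    snps = planted.loc[snp_mask, ["chrom", "pos", "ref", "alt"]].copy()
    snps.insert(2, "id", [f"rs{900000 + i}" for i in range(len(snps))])
    snps["maf"] = np.round(mafs, 6)
    snps = snps.reset_index(drop=True)

    edit_mask = planted["kind"] == "edit"
    cons = planted.loc[edit_mask, ["chrom", "pos"]].copy()
    cons["score"] = np.round(rng.normal(1.0, 0.8, int(edit_mask.sum())), 3)
    cons = cons.reset_index(drop=True)

    return ReferenceBundle(sequences=sequences, genes=genes, alu=alu,
                           simple_repeats=repeats, snps=snps,
                           conservation=cons, planted=planted)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _patient_ids(n: int) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(n)]


def _simulate_expression(cfg: CohortConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """FPKM-like expression. ADAR1-p110 averages ~22 in normal liver and is
    on average 1.8-fold higher in tumors (~40); ADAR2 sits near 2 FPKM in
    both tissues (~20-fold below tumor ADAR1-p110)."""
    patients = _patient_ids(cfg.n_patients)
    rows = []
    for p in patients:
        p110_n = 22.0 * float(rng.lognormal(0.0, 0.15))
        fold = 1.8 * float(rng.lognormal(0.0, 0.20))
        p110_t = p110_n * fold
        for gene, n_val, t_val in [
            ("ADAR1-p110", p110_n, p110_t),
            ("ADAR1-p150", 5.0 * float(rng.lognormal(0, 0.2)),
             5.0 * float(rng.lognormal(0, 0.2))),
            ("ADAR2", 2.0 * float(rng.lognormal(0, 0.15)),
             2.0 * float(rng.lognormal(0, 0.15))),
        ]:
            rows.append((gene, p, "normal", round(n_val, 3)))
            rows.append((gene, p, "tumor", round(t_val, 3)))
        for j in range(5):
            rows.append((f"FILLER{j + 1}", p, "normal",
                         round(10 * float(rng.lognormal(0, 0.4)), 3)))
            rows.append((f"FILLER{j + 1}", p, "tumor",
                         round(10 * float(rng.lognormal(0, 0.4)), 3)))
    return pd.DataFrame(rows, columns=["gene", "patient", "tissue", "fpkm"])


def _mean_quals(rng: np.random.Generator, counts: np.ndarray) -> np.ndarray:
    q = np.clip(rng.normal(35.0, 3.0, counts.shape), 2.0, 41.0)
    return np.where(counts > 0, np.round(q, 1), 0.0)


def simulate_cohort(config: CohortConfig,
                    reference: ReferenceBundle | None = None) -> SyntheticCohort:
    """Simulate per-site base counts for DNA and RNA, tumor and normal.

    Noise model: per-site depth ~ Poisson(mean); alt reads ~ Binomial(depth,
    true allele fraction); every read miscalled with probability
    ``seq_error_rate`` uniformly to one of the other three bases; read
    strand 50/50 except at requested strand-artifact sites, where all alt
    reads land on the forward strand. True allele fractions: RNA edits at
    their per-patient/tissue level with homozygous-reference DNA; germline
    SNPs heterozygous (0.5) in both materials and tissues of carriers;
    somatic SNVs at their clonal fraction in tumor DNA and RNA only.
    """
    config.validate()
    if reference is None:
        reference = generate_reference(config)
    rng = np.random.default_rng([int(config.seed), 1])
    patients = _patient_ids(config.n_patients)
    n_p = config.n_patients

    expression = _simulate_expression(config, rng)
    p110_t = (expression.query("gene == 'ADAR1-p110' and tissue == 'tumor'")
              .set_index("patient")["fpkm"])
    log_expr = np.log2(p110_t.loc[patients].to_numpy())
    shift = config.adar_coupling * (log_expr - log_expr.mean())

    planted = reference.planted
    a_n, b_n = config.edit_level_normal
    a_t, b_t = config.edit_level_tumor
    rec_keys = np.array(sorted(config.recurrence_profile))
    rec_w = np.array([config.recurrence_profile[k] for k in rec_keys], float)
    rec_w = rec_w / rec_w.sum()

    # ---- per-category truth: allele fraction per patient x tissue x material
    edit_rows = planted[planted["kind"] == "edit"].reset_index(drop=True)
    snp_rows = planted[planted["kind"] == "snp"].reset_index(drop=True)
    som_rows = planted[planted["kind"] == "somatic"].reset_index(drop=True)

    lvl_records = []
    edit_truth = edit_rows.copy()
    vaf = {}  # (pos, material, tissue) -> np.ndarray over patients
    for _, row in edit_rows.iterrows():
        r = int(rng.choice(rec_keys, p=rec_w))
        r = min(r, n_p)
        carriers = rng.choice(n_p, size=r, replace=False)
        ln = np.zeros(n_p)
        lt = np.zeros(n_p)
        for c in carriers:
            ln[c] = float(rng.beta(a_n, b_n))
            lt[c] = float(np.clip(rng.beta(a_t, b_t) + shift[c], 0.0, 1.0))
            lvl_records.append((row["chrom"], row["pos"], patients[int(c)],
                               ln[c], lt[c]))
        pos = int(row["pos"])
        vaf[(pos, "RNA", "normal")] = ln
        vaf[(pos, "RNA", "tumor")] = lt

    maf_by_pos = reference.snps.set_index("pos")["maf"]
    geno_records = []
    for _, row in snp_rows.iterrows():
        pos = int(row["pos"])
        maf = float(maf_by_pos.loc[pos])
        p_het = 2.0 * maf * (1.0 - maf)
        het = rng.random(n_p) < p_het
        frac = np.where(het, 0.5, 0.0)
        for mat in ("DNA", "RNA"):
            for tis in ("normal", "tumor"):
                vaf[(pos, mat, tis)] = frac
        for c in np.nonzero(het)[0]:
            geno_records.append((row["chrom"], pos, patients[int(c)]))

    som_records = []
    som_truth = som_rows.copy()
    som_patients = []
    som_vafs = []
    for _, row in som_rows.iterrows():
        pos = int(row["pos"])
        c = int(rng.integers(0, n_p))
        v = float(rng.uniform(0.1, 0.5))
        frac = np.zeros(n_p)
        frac[c] = v
        vaf[(pos, "DNA", "tumor")] = frac
        vaf[(pos, "RNA", "tumor")] = frac
        som_patients.append(patients[c])
        som_vafs.append(round(v, 4))
    som_truth["patient"] = som_patients
    som_truth["vaf_tumor"] = som_vafs
    som_truth = som_truth[["chrom", "pos", "ref", "alt", "patient", "vaf_tumor"]]

    art_pos = set(planted.loc[planted["kind"] == "artifact", "pos"].astype(int))
    for pos in art_pos:
        for tis in ("normal", "tumor"):
            vaf[(pos, "RNA", tis)] = np.full(n_p, 0.15)

    # ---- base-count simulation -------------------------------------------
    base_idx = {b: i for i, b in enumerate(BASES)}
    err = config.seq_error_rate
    zero = np.zeros(n_p)
    out: list[tuple] = []
    for _, row in planted.iterrows():
        chrom, pos, ref, alt = row["chrom"], int(row["pos"]), row["ref"], row["alt"]
        ri, ai = base_idx[ref], base_idx[alt]
        one_sided = pos in art_pos
        for material, mean_depth in (("DNA", config.depth_mean_dna),
                                     ("RNA", config.depth_mean_rna)):
            for tissue in ("normal", "tumor"):
                frac = vaf.get((pos, material, tissue), zero)
                depth = rng.poisson(mean_depth, n_p)
                alt_n = rng.binomial(depth, frac)
                ref_n = depth - alt_n
                counts = np.zeros((n_p, 4), dtype=np.int64)
                counts[:, ri] = ref_n
                counts[:, ai] += alt_n
                if err > 0:
                    for bi in (ri, ai):
                        n_err = rng.binomial(counts[:, bi], err)
                        counts[:, bi] -= n_err
                        others = [k for k in range(4) if k != bi]
                        spread = rng.multinomial(n_err, [1 / 3] * 3)
                        for j, k in enumerate(others):
                            counts[:, k] += spread[:, j]
                        if bi == ai and ai == ri:
                            break
                fwd = rng.binomial(counts, 0.5)
                if one_sided and material == "RNA":
                    fwd[:, ai] = counts[:, ai]   # planted strand artifact
                rev = counts - fwd
                mq = _mean_quals(rng, counts)
                for k in range(n_p):
                    out.append((chrom, pos, ref, patients[k], material, tissue,
                                *fwd[k], *rev[k], *mq[k]))
    columns = ["chrom", "pos", "ref", "sample", "material", "tissue",
               "A_fwd", "C_fwd", "G_fwd", "T_fwd",
               "A_rev", "C_rev", "G_rev", "T_rev",
               "meanQ_A", "meanQ_C", "meanQ_G", "meanQ_T"]
    counts_df = pd.DataFrame(out, columns=columns)
    counts_df = counts_df.sort_values(
        ["chrom", "pos", "sample", "material", "tissue"]).reset_index(drop=True)

    truth = SyntheticTruth(
        edits=edit_truth[["chrom", "pos", "ref", "alt", "gene", "strand",
                          "in_alu", "in_duplication"]].reset_index(drop=True),
        edit_levels=pd.DataFrame(
            lvl_records,
            columns=["chrom", "pos", "patient", "level_normal", "level_tumor"]),
        snps=reference.snps[["chrom", "pos", "ref", "alt", "maf"]].copy(),
        snp_genotypes=pd.DataFrame(geno_records,
                                   columns=["chrom", "pos", "patient"]),
        somatic=som_truth,
        expression=expression.copy(),
    )
    return SyntheticCohort(config=config, reference=reference,
                           counts=counts_df, truth=truth,
                           expression=expression)


# ---------------------------------------------------------------------------
# chromatogram simulation
# ---------------------------------------------------------------------------

def simulate_chromatogram(true_level: float, context: str,
                          peak_width: float = 2.5, noise_sd: float = 5.0,
                          seed: int = 0, spacing: int = 12,
                          amplitude: float = 1000.0) -> ChromatogramTrace:
    """Simulate a 4-channel trace over an A-centered sequence context.

    Each base produces a Gaussian peak of width ``peak_width`` scan points
    in its own channel. At the central base the A-channel amplitude is
    proportional to (1 - true_level) and the G channel to true_level, which
    is how a partially edited adenosine appears in a cDNA trace. Gaussian
    noise of standard deviation ``noise_sd`` is added and intensities are
    clipped at zero.
    """
    if not 0.0 <= true_level <= 1.0:
        raise ValueError("true_level must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if len(context) % 2 != 1:
        raise ValueError("context must have odd length")
    center = len(context) // 2
    if context[center] != "A":
        raise ValueError("context must be centered on an adenosine")
    rng = np.random.default_rng(seed)
    n_scan = len(context) * spacing
    x = np.arange(n_scan)
    intensities = np.zeros((n_scan, 4))
    base_idx = {b: i for i, b in enumerate(BASES)}
    positions = np.array([i * spacing + spacing // 2
                          for i in range(len(context))])
    for i, b in enumerate(context):
        c = positions[i]
        shape = np.exp(-0.5 * ((x - c) / peak_width) ** 2)
        jitter = float(rng.uniform(0.85, 1.15))
        if i == center:
            intensities[:, base_idx["A"]] += (1.0 - true_level) * amplitude * shape
            intensities[:, base_idx["G"]] += true_level * amplitude * shape
        else:
            intensities[:, base_idx[b]] += amplitude * jitter * shape
    if noise_sd > 0:
        intensities += rng.normal(0.0, noise_sd, intensities.shape)
    intensities = np.clip(intensities, 0.0, None)
    return ChromatogramTrace(intensities=intensities, basecalls=context,
                             base_positions=positions)
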