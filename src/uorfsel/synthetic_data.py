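"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates, at desk scale, the data the analyses were designed
for: a transcriptome of 5'UTRs carrying translated uORFs with configurable
start/stop codon usage on both strands; a population variant table whose
per-variant singleton status follows the generative model MAPS assumes
(per-context baseline proportion from a mutation-rate table, plus a
class-specific excess delta for selected consequence classes); a per-base
conservation track where designated position classes are conserved with a
target probability; a codon-stability table; and a biobank of genotypes,
covariates and dated phenotype events driven by a logistic disease model
with configurable carrier odds ratios.

Every generator is a pure function of (config, seed): a fixed seed yields
bit-identical outputs.  Ground-truth class labels are written to sidecar
tables so each downstream stage has a parameter-recovery test.

Singleton status is simulated directly rather than through a population
model: MAPS consumes only the (context, singleton) pair, so the Bernoulli
scheme is the minimal sufficient generative model (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

from .genomic_model import (
    NUG_STARTS,
    RNA_STOPS,
    SENSE_CODONS,
    BiobankTable,
    ConservationTrack,
    CscTable,
    OrfAnnotation,
    UtrAnnotation,
    VariantRecord,
    context_from_genome,
    revcomp,
    rna_to_dna,
    translate_codon,
)
from .maps import MutationRateTable

DNA = "ACGT"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """All knobs of the synthetic world, with study-condition defaults."""

    seed: int = 0
    # transcriptome
    n_genes: int = 60
    utr_length_range: tuple[int, int] = (150, 300)
    uorf_rate: float = 0.85  # probability a gene's UTR carries a translated uORF
    uorf_codon_range: tuple[int, int] = (6, 40)  # codons incl. start & stop
    start_codon_weights: dict = field(
        default_factory=lambda: {"AUG": 0.35, "CUG": 0.30, "GUG": 0.20, "UUG": 0.15}
    )
    stop_codon_weights: dict = field(
        default_factory=lambda: {"UGA": 0.45, "UAG": 0.36, "UAA": 0.19}
    )
    minus_strand_prob: float = 0.5
    cds_length: int = 90  # nt of coding sequence modelled after each UTR
    intergenic_pad: int = 30
    # mutation-rate table and singleton model
    rate_range: tuple[float, float] = (0.01, 0.09)  # arbitrary units
    baseline_intercept: float = 0.05
    baseline_slope: float = 5.0  # baseline p(singleton) = a + b * mu
    deltas: dict = field(
        default_factory=lambda: {
            "stop_gain": 0.05,
            "stop_strengthen": 0.04,
            "start_disrupt": 0.04,
        }
    )
    # variant emission
    emit_prob_orf: float = 0.6  # fraction of possible uORF SNVs observed
    emit_prob_utr: float = 0.25
    n_calibration: int = 20000  # synthetic synonymous coding variants
    max_an: int = 150000
    frac_fail_filter: float = 0.02
    frac_lcr: float = 0.02
    frac_low_an: float = 0.02
    # conservation
    conserved_prob: dict = field(
        default_factory=lambda: {"stop_creating": 0.6, "start_disrupt": 0.6}
    )
    background_score_sd: float = 1.0  # background scores ~ Normal(0, sd)
    # biobank
    n_individuals: int = 5000
    n_test_variants: int = 2
    carrier_freq: float = 0.01
    true_or: float = 3.0
    baseline_prevalence: float = 0.05
    n_null_phenotypes: int = 8
    single_date_frac: float = 0.05
    missing_genotype_frac: float = 0.01
    afr_fraction: float = 0.2  # two ancestry strata, EUR and AFR

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("utr_length_range", "uorf_codon_range", "rate_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for w in (self.start_codon_weights, self.stop_codon_weights):
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError("codon weights must sum to 1")
        lo, hi = self.uorf_codon_range
        if 3 * hi > self.utr_length_range[0]:
            raise ValueError(
                "longest uORF does not fit the shortest UTR; adjust ranges"
            )
        for cat, d in self.deltas.items():
            hi_p = self.baseline_intercept + self.baseline_slope * self.rate_range[1]
            if not 0 <= hi_p + d <= 1:
                raise ValueError(f"baseline + delta for {cat} outside [0, 1]")


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA), size=n))


def _weighted_choice(rng: np.random.Generator, weights: dict) -> str:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def make_transcriptome(
    config: SimulationConfig, seed: int | None = None
) -> tuple[dict[str, str], list[UtrAnnotation], list[OrfAnnotation]]:
    """Generate a genome, 5'UTR annotations and planted translated uORFs.

    Genes are laid end to end on one chromosome with random intergenic
    padding; roughly half sit on the minus strand (genomic sequence is then
    the reverse complement of the transcript).  Each uORF is a valid ORF --
    NUG start, sense-codon body, single terminal stop -- drawn from the
    configured start/stop codon weights, placed wholly inside its UTR, with
    its distance to the downstream CDS start recorded.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chrom = "chr1"
    pieces: list[str] = []
    cursor = 0
    utrs: list[UtrAnnotation] = []
    orfs: list[OrfAnnotation] = []
    for g in range(config.n_genes):
        pad = _random_dna(rng, config.intergenic_pad)
        pieces.append(pad)
        cursor += len(pad)
        utr_len = int(rng.integers(*config.utr_length_range, endpoint=True))
        strand = "-" if rng.random() < config.minus_strand_prob else "+"
        tx_seq = list(_random_dna(rng, utr_len))  # transcript orientation, DNA
        gene_orfs: list[tuple[str, int, int]] = []  # (orf_id, offset, length_nt)
        if rng.random() < config.uorf_rate:
            n_codons = int(rng.integers(*config.uorf_codon_range, endpoint=True))
            length = 3 * n_codons
            offset = int(rng.integers(0, utr_len - length + 1))
            start = rna_to_dna(_weighted_choice(rng, config.start_codon_weights))
            stop = rna_to_dna(_weighted_choice(rng, config.stop_codon_weights))
            body = [
                rna_to_dna(SENSE_CODONS[i])
                for i in rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)
            ]
            orf_seq = start + "".join(body) + stop
            tx_seq[offset : offset + length] = list(orf_seq)
            gene_orfs.append((f"uorf_{g}", offset, length))
        tx_str = "".join(tx_seq)
        # genomic layout: UTR block, then (plus) or preceded by (minus) the CDS
        if strand == "+":
            utr_start = cursor
            genomic_utr = tx_str
            cds_seq = _random_dna(rng, config.cds_length)
            pieces.append(genomic_utr + cds_seq)
            cursor += utr_len + config.cds_length
            cds_start = utr_start + utr_len
        else:
            cds_seq = _random_dna(rng, config.cds_length)
            utr_start = cursor + config.cds_length
            pieces.append(cds_seq + revcomp(tx_str))
            cursor += utr_len + config.cds_length
            cds_start = utr_start - 1
        utr = UtrAnnotation(
            transcript_id=f"tx_{g}",
            chrom=chrom,
            strand=strand,
            blocks=[(utr_start, utr_start + utr_len)],
            sequence=tx_str,
            contained_orf_ids=[oid for oid, _o, _l in gene_orfs],
            cds_start=cds_start,
        )
        utrs.append(utr)
        for oid, offset, length in gene_orfs:
            if strand == "+":
                blocks = [(utr_start + offset, utr_start + offset + length)]
            else:
                # transcript offset o maps to genomic end - o
                hi = utr_start + utr_len - offset
                blocks = [(hi - length, hi)]
            orf = OrfAnnotation(
                orf_id=oid,
                transcript_id=f"tx_{g}",
                chrom=chrom,
                strand=strand,
                blocks=blocks,
                orf_class="uORF",
                spliced_sequence=tx_str[offset : offset + length],
                cds_start_distance=utr_len - (offset + length),
            )
            orf.validate()
            orfs.append(orf)
    genome = {chrom: "".join(pieces)}
    return genome, utrs, orfs


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_RNA_COMP = str.maketrans("ACGU", "UGCA")


def make_rate_table(config: SimulationConfig, seed: int | None = None) -> MutationRateTable:
    """Rates for all 96 collapsed (triplet, alt) mutation classes."""
    rng = np.random.default_rng((config.seed if seed is None else seed) + 101)
    rates = {}
    for a in DNA:
        for c in "AC":  # collapsed central base
            for b in DNA:
                for alt in DNA:
                    if alt == c:
                        continue
                    rates[f"{a}{c}{b}>{alt}"] = float(
                        rng.uniform(*config.rate_range)
                    )
    return MutationRateTable(rates)


def make_csc_table(config: SimulationConfig, seed: int | None = None) -> CscTable:
    """Codon stability coefficients ~ Normal(0, 0.1) for the 61 sense codons."""
    rng = np.random.default_rng((config.seed if seed is None else seed) + 202)
    return CscTable({c: float(rng.normal(0, 0.1)) for c in SENSE_CODONS})


def baseline_proportion(config: SimulationConfig, rates: MutationRateTable, context: str) -> float:
    return config.baseline_intercept + config.baseline_slope * rates.get(context)


def _truth_category(orf_seq_rna: str, tidx: int, alt_tx_base_rna: str) -> str:
    """Generator-side consequence rule, in pure transcript space.

    Deliberately written without the genomic classifier so the sidecar truth
    labels exercise the coordinate/strand machinery independently.
    """
    codon_index, offset = divmod(tidx, 3)
    ref_codon = orf_seq_rna[3 * codon_index : 3 * codon_index + 3]
    alt_codon = ref_codon[:offset] + alt_tx_base_rna + ref_codon[offset + 1 :]
    if codon_index == 0:
        return "start_maintain" if alt_codon in NUG_STARTS else "start_disrupt"
    strength = {"UGA": 1, "UAG": 2, "UAA": 3}
    if ref_codon in RNA_STOPS and alt_codon in RNA_STOPS:
        return (
            "stop_strengthen"
            if strength[alt_codon] > strength[ref_codon]
            else "stop_weaken"
        )
    if ref_codon in RNA_STOPS:
        return "stop_loss"
    if alt_codon in RNA_STOPS:
        return "stop_gain"
    if translate_codon(ref_codon) == translate_codon(alt_codon):
        return "synonymous"
    return "missense"


def simulate_variants(
    config: SimulationConfig,
    orfs: list[OrfAnnotation],
    utrs: list[UtrAnnotation],
    rates: MutationRateTable,
    genome: dict[str, str],
    seed: int | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Emit SNVs whose singleton status realises the MAPS generative model.

    Three sources: (1) a calibration class of synthetic synonymous coding
    variants on a dedicated coding chromosome, singletons at the per-context
    baseline; (2) all possible SNVs inside uORFs, each observed with
    probability ``emit_prob_orf``, singletons at baseline + delta(category);
    (3) UTR background SNVs outside uORFs at baseline.  AC/AN, FILTER and
    low-complexity flags include configurable contamination so the QC filter
    has work to do.  Returns the records (sorted) and the ground-truth
    sidecar table.

    The genome dict is extended in place with the calibration chromosome.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 303)
    variants: list[VariantRecord] = []
    truth_rows: list[dict] = []

    def an_filter_lcr() -> tuple[int, str, bool]:
        if rng.random() < config.frac_low_an:
            an = int(config.max_an * rng.uniform(0.5, 0.75))
        else:
            an = int(config.max_an * rng.uniform(0.9, 1.0))
        filt = "AC0" if rng.random() < config.frac_fail_filter else "PASS"
        lcr = bool(rng.random() < config.frac_lcr)
        return an, filt, lcr

    def make_record(chrom, pos0, ref, alt, p_singleton) -> VariantRecord:
        singleton = bool(rng.random() < p_singleton)
        ac = 1 if singleton else int(2 + rng.poisson(5))
        an, filt, lcr = an_filter_lcr()
        return VariantRecord(
            chrom=chrom,
            pos=pos0 + 1,
            ref=ref,
            alt=alt,
            allele_count=ac,
            allele_number=max(an, ac),
            filter_status=filt,
            lcr_flag=lcr,
        )

    # (1) calibration chromosome: synonymous coding stand-ins
    cal_chrom = "chr_cds"
    cal_len = 3 * config.n_calibration + 2
    cal_seq = _random_dna(rng, cal_len)
    genome[cal_chrom] = cal_seq
    for i in range(config.n_calibration):
        pos0 = 1 + 3 * i  # spaced so contexts never overlap a variant base
        ref = cal_seq[pos0]
        alt = DNA[int(rng.integers(0, 3))]
        alt = alt if alt != ref else "T" if ref != "T" else "G"
        v = make_record(cal_chrom, pos0, ref, alt, 0.0)
        v.context = context_from_genome(genome, v)
        p = config.baseline_intercept + config.baseline_slope * rates.get(v.context)
        singleton = bool(rng.random() < p)
        v.allele_count = 1 if singleton else int(2 + rng.poisson(5))
        variants.append(v)
        truth_rows.append(
            {
                "chrom": cal_chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "true_class": "coding_synonymous",
                "orf_id": "",
                "singleton": v.is_singleton,
            }
        )

    # (2) uORF SNVs -- enumerate in transcript space, map to the genome
    orf_positions = {
        (o.chrom, int(p)) for o in orfs for p in o.genomic_positions()
    }
    for orf in orfs:
        gpos = orf.genomic_positions()  # translation order
        seq = orf.spliced_sequence
        for tidx in range(orf.length):
            for alt_rna in "ACGU":
                if alt_rna == seq[tidx]:
                    continue
                if rng.random() >= config.emit_prob_orf:
                    continue
                category = _truth_category(seq, tidx, alt_rna)
                pos0 = int(gpos[tidx])
                if orf.strand == "+":
                    ref_g = rna_to_dna(seq[tidx])
                    alt_g = rna_to_dna(alt_rna)
                else:
                    ref_g = rna_to_dna(seq[tidx].translate(_RNA_COMP))
                    alt_g = rna_to_dna(alt_rna.translate(_RNA_COMP))
                v = make_record(orf.chrom, pos0, ref_g, alt_g, 0.0)
                v.context = context_from_genome(genome, v)
                p = config.baseline_intercept + config.baseline_slope * rates.get(
                    v.context
                ) + config.deltas.get(category, 0.0)
                if not 0 <= p <= 1:
                    raise ValueError(f"baseline + delta = {p} outside [0, 1]")
                singleton = bool(rng.random() < p)
                v.allele_count = 1 if singleton else int(2 + rng.poisson(5))
                variants.append(v)
                truth_rows.append(
                    {
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "ref": v.ref,
                        "alt": v.alt,
                        "true_class": category,
                        "orf_id": orf.orf_id,
                        "singleton": v.is_singleton,
                    }
                )

    # (3) UTR background outside uORFs
    for u in utrs:
        for pos0 in (int(p) for p in u.genomic_positions()):
            if (u.chrom, pos0) in orf_positions:
                continue
            if rng.random() >= config.emit_prob_utr:
                continue
            ref = genome[u.chrom][pos0]
            alt = DNA[int(rng.integers(0, 3))]
            alt = alt if alt != ref else "T" if ref != "T" else "G"
            v = make_record(u.chrom, pos0, ref, alt, 0.0)
            v.context = context_from_genome(genome, v)
            if v.context is None:
                continue
            p = config.baseline_intercept + config.baseline_slope * rates.get(v.context)
            singleton = bool(rng.random() < p)
            v.allele_count = 1 if singleton else int(2 + rng.poisson(5))
            variants.append(v)
            truth_rows.append(
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "true_class": "utr_background",
                    "orf_id": "",
                    "singleton": v.is_singleton,
                }
            )

    variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    truth = pd.DataFrame(truth_rows).sort_values(
        ["chrom", "pos", "ref", "alt"], kind="stable"
    )
    truth = truth.reset_index(drop=True)
    return variants, truth


def write_vcf(path, variants: list[VariantRecord], contigs: dict[str, int]) -> None:
    """Write SNVs as uncompressed VCF v4.2 with AC/AN/lcr INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n')
        fh.write(
            '##INFO=<ID=lcr,Number=0,Type=Flag,Description="Low complexity region">\n'
        )
        fh.write('##FILTER=<ID=AC0,Description="No high-quality genotype">\n')
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = f"AC={v.allele_count};AN={v.allele_number}"
            if v.lcr_flag:
                info += ";lcr"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{v.filter_status}\t{info}\n"
            )


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------


def simulate_conservation(
    config: SimulationConfig,
    positions_by_class: dict[str, list[tuple[str, int]]],
    background_positions: list[tuple[str, int]],
    seed: int | None = None,
) -> ConservationTrack:
    """Per-base scores: designated classes conserved (score > 2) with prob q.

    Conserved bases draw scores from Uniform(2.5, 8); non-conserved bases
    and the background draw from Normal(0, sd) truncated at 2 (background's
    analytic conserved fraction is the configured normal tail beyond 2).
    Positions listed in several classes keep their first assignment.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 404)
    track = ConservationTrack()
    sd = config.background_score_sd

    def background_score() -> float:
        return float(rng.normal(0, sd))

    def nonconserved_score() -> float:
        while True:
            s = rng.normal(0, sd)
            if s <= 2.0:
                return float(s)

    assigned: set[tuple[str, int]] = set()
    for cls, positions in positions_by_class.items():
        q = config.conserved_prob.get(cls, 0.0)
        for chrom, pos in positions:
            if (chrom, pos) in assigned:
                continue
            assigned.add((chrom, pos))
            if rng.random() < q:
                track.set(chrom, pos, float(rng.uniform(2.5, 8.0)))
            else:
                track.set(chrom, pos, nonconserved_score())
    for chrom, pos in background_positions:
        if (chrom, pos) not in assigned:
            assigned.add((chrom, pos))
            track.set(chrom, pos, background_score())
    return track


# ---------------------------------------------------------------------------
# Biobank
# ---------------------------------------------------------------------------


def _solve_intercept(eta_wo_b0: np.ndarray, prevalence: float) -> float:
    """beta0 such that mean sigmoid(beta0 + eta) equals the target prevalence."""

    def f(b0):
        return np.mean(1.0 / (1.0 + np.exp(-(b0 + eta_wo_b0)))) - prevalence

    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target prevalence infeasible for the linear predictor")
    return float(optimize.brentq(f, lo, hi))


def simulate_biobank(
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[BiobankTable, pd.DataFrame]:
    """Genotypes, covariates and dated phenotype events under a logistic model.

    Each test variant targets its own phenotype code with the configured
    true odds ratio; ``n_null_phenotypes`` additional codes depend only on
    covariates.  Cases receive two or three distinct event dates; a
    configurable fraction of non-cases receive exactly one date so the
    single-date exclusion rule is exercised.  Burden-qualifying coding
    variants (pLOF / high-REVEL missense, rare) are attached per gene.

    Returns the table and a ground-truth sheet (variant, gene, phenotype,
    true OR, carrier frequency).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 505)
    n = config.n_individuals
    individuals = pd.Index([f"ind_{i}" for i in range(n)], name="individual")

    age = rng.uniform(25, 80, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.normal(0, 1, size=(n, 10))
    covariates = pd.DataFrame(
        {"age": age, "age2": age**2, "sex": sex},
        index=individuals,
    )
    for i in range(10):
        covariates[f"PC{i + 1}"] = pcs[:, i]
    strata = pd.Series(
        np.where(rng.random(n) < config.afr_fraction, "AFR", "EUR"),
        index=individuals,
        name="ancestry",
    )

    # covariate effects on disease risk (standardised age)
    age_z = (age - age.mean()) / age.std()
    cov_eta = 0.2 * age_z + 0.1 * sex

    dosage_cols: dict[str, np.ndarray] = {}
    ann_rows: list[dict] = []
    truth_rows: list[dict] = []
    events_rows: list[dict] = []

    def random_dates(k: int) -> list[str]:
        base = np.datetime64("2010-01-01")
        days: set[int] = set()
        while len(days) < k:
            days.update(int(d) for d in rng.integers(0, 3650, size=k - len(days)))
        return [str(base + d) for d in sorted(days)]

    log_or = float(np.log(config.true_or))
    af = 1.0 - np.sqrt(1.0 - config.carrier_freq)  # HWE allele freq for carrier freq

    for j in range(config.n_test_variants):
        vid = f"var_{j}"
        gene = f"GENE{j}"
        code = f"P{100 + j}"
        dos = rng.binomial(2, af, size=n).astype(float)
        miss = rng.random(n) < config.missing_genotype_frac
        dos_obs = dos.copy()
        dos_obs[miss] = np.nan
        dosage_cols[vid] = dos_obs
        eta = cov_eta + log_or * dos
        b0 = _solve_intercept(eta, config.baseline_prevalence)
        case = rng.random(n) < 1.0 / (1.0 + np.exp(-(b0 + eta)))
        for i in np.nonzero(case)[0]:
            for date in random_dates(int(rng.integers(2, 4))):
                events_rows.append(
                    {"individual": individuals[i], "code": code, "date": date}
                )
        noncase = np.nonzero(~case)[0]
        single = noncase[rng.random(len(noncase)) < config.single_date_frac]
        for i in single:
            events_rows.append(
                {"individual": individuals[i], "code": code, "date": random_dates(1)[0]}
            )
        ann_rows.append(
            {
                "variant": vid,
                "gene": gene,
                "cds_labels": "",
                "revel": np.nan,
                "maf": af,
            }
        )
        truth_rows.append(
            {
                "variant": vid,
                "gene": gene,
                "phenotype": code,
                "true_or": config.true_or,
                "carrier_freq": config.carrier_freq,
            }
        )
        # burden-qualifying coding variants in the same gene
        for k in range(3):
            bvid = f"{vid}_cds{k}"
            bmaf = float(rng.uniform(1e-5, 5e-4))
            baf = bmaf
            bdos = rng.binomial(2, baf, size=n).astype(float)
            dosage_cols[bvid] = bdos
            label, revel = ("pLOF", np.nan) if k == 0 else (
                "missense",
                float(rng.uniform(0, 1)),
            )
            ann_rows.append(
                {
                    "variant": bvid,
                    "gene": gene,
                    "cds_labels": label,
                    "revel": revel,
                    "maf": bmaf,
                }
            )

    # null phenotypes: covariates only
    for j in range(config.n_null_phenotypes):
        code = f"N{200 + j}"
        b0 = _solve_intercept(cov_eta, config.baseline_prevalence)
        case = rng.random(n) < 1.0 / (1.0 + np.exp(-(b0 + cov_eta)))
        for i in np.nonzero(case)[0]:
            for date in random_dates(int(rng.integers(2, 4))):
                events_rows.append(
                    {"individual": individuals[i], "code": code, "date": date}
                )

    dosages = pd.DataFrame(dosage_cols, index=individuals)
    events = pd.DataFrame(events_rows, columns=["individual", "code", "date"])
    annotations = pd.DataFrame(ann_rows).set_index("variant")
    table = BiobankTable(dosages, covariates, events, annotations)
    table.validate()
    truth = pd.DataFrame(truth_rows)
    truth["ancestry_strata"] = ",".join(sorted(strata.unique()))
    table.strata = strata  # carried alongside; not part of the core contract
    return table, truth


def write_biobank(outdir, table: BiobankTable) -> None:
    """Write the four biobank TSVs (plus ancestry strata when present)."""
    import os

    table.dosages.to_csv(os.path.join(outdir, "dosages.tsv"), sep="\t")
    table.covariates.to_csv(os.path.join(outdir, "covariates.tsv"), sep="\t")
    table.events.to_csv(os.path.join(outdir, "events.tsv"), sep="\t", index=False)
    table.variant_annotations.to_csv(
        os.path.join(outdir, "variant_annotations.tsv"), sep="\t"
    )
    strata = getattr(table, "strata", None)
    if strata is not None:
        strata.to_csv(os.path.join(outdir, "strata.tsv"), sep="\t")
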