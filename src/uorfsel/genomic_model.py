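"""Domain types and I/O for the uORF selection analyses.

Coordinate conventions used throughout the package:

* internal coordinates are 0-based, half-open genomic intervals;
* VCF positions are converted from 1-based on read;
* BED input/output is 0-based half-open (the native BED convention);
* ORF ``spliced_sequence`` is stored in *translation orientation* as RNA
  (minus-strand ORFs are reverse-complemented on read).

Trinucleotide mutation contexts are reference-strand DNA triplets collapsed
so that the central (reference) base is A or C; when the central base is G or
T the triplet is reverse-complemented and the alternate allele complemented.
This gives one canonical representative per strand-symmetric mutation class
(32 triplets x 3 alternates = 96 classes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DNA_BASES = "ACGT"
RNA_STOPS = ("UGA", "UAG", "UAA")
NUG_STARTS = ("AUG", "CUG", "GUG", "UUG")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def translate_codon(codon_rna: str) -> str:
    """One-letter amino acid (or '*') for an RNA codon, standard code."""
    return str(Seq(codon_rna).translate())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class OrfAnnotation:
    """A translated ORF as strand-aware genomic blocks plus its codon sequence.

    ``blocks`` are 0-based half-open genomic intervals in ascending genomic
    order.  ``spliced_sequence`` is RNA in translation orientation: for a
    minus-strand ORF it is the reverse complement of the concatenated genomic
    block sequence.  ``cds_start_distance`` is the distance in nucleotides
    from the ORF 3' end to the downstream CDS start (uORFs only).
    """

    orf_id: str
    transcript_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    orf_class: str  # uORF | dORF | lncRNA | pseudogene
    spliced_sequence: str
    cds_start_distance: int | None = None

    def __post_init__(self) -> None:
        self.spliced_sequence = dna_to_rna(self.spliced_sequence.upper())

    @property
    def length(self) -> int:
        return len(self.spliced_sequence)

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, index: int) -> str:
        return self.spliced_sequence[3 * index : 3 * index + 3]

    @property
    def start_codon(self) -> str:
        return self.codon(0)

    @property
    def stop_codon(self) -> str:
        return self.codon(self.n_codons - 1)

    def genomic_positions(self) -> np.ndarray:
        """Genomic positions (0-based) of each base, in translation order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.blocks])
        return pos[::-1] if self.strand == "-" else pos

    def transcript_index(self, genomic_pos: int) -> int:
        """Translation-orientation index of a genomic position.

        Raises ValueError if the position is outside the ORF blocks.
        """
        offset = 0
        total = sum(e - s for s, e in self.blocks)
        for s, e in self.blocks:
            if s <= genomic_pos < e:
                plus_index = offset + (genomic_pos - s)
                if self.strand == "+":
                    return plus_index
                return total - 1 - plus_index
            offset += e - s
        raise ValueError(
            f"position {self.chrom}:{genomic_pos} outside ORF {self.orf_id}"
        )

    def contains(self, genomic_pos: int) -> bool:
        return any(s <= genomic_pos < e for s, e in self.blocks)

    def validate(self) -> None:
        block_len = sum(e - s for s, e in self.blocks)
        if block_len != self.length:
            raise ValueError(
                f"{self.orf_id}: block length {block_len} != sequence length "
                f"{self.length}"
            )
        if self.length % 3 != 0:
            raise ValueError(f"{self.orf_id}: length {self.length} not divisible by 3")
        if self.stop_codon not in RNA_STOPS:
            raise ValueError(f"{self.orf_id}: last codon {self.stop_codon} not a stop")
        if self.orf_class == "uORF" and self.start_codon not in NUG_STARTS:
            raise ValueError(
                f"{self.orf_id}: uORF start codon {self.start_codon} not NUG"
            )


@dataclass
class UtrAnnotation:
    """A 5'UTR (or other UTR) as genomic blocks plus transcript-orientation sequence."""

    transcript_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    sequence: str
    contained_orf_ids: list[str] = field(default_factory=list)
    cds_start: int | None = None  # genomic position of downstream CDS first base

    def __post_init__(self) -> None:
        self.sequence = dna_to_rna(self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    def genomic_positions(self) -> np.ndarray:
        pos = np.concatenate([np.arange(s, e) for s, e in self.blocks])
        return pos[::-1] if self.strand == "-" else pos

    def contains(self, genomic_pos: int) -> bool:
        return any(s <= genomic_pos < e for s, e in self.blocks)


@dataclass
class VariantRecord:
    """One SNV with allele counts, QC flags and its mutation context."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    allele_count: int
    allele_number: int
    filter_status: str = "PASS"
    lcr_flag: bool = False
    context: str | None = None  # collapsed "XYZ>A" (DNA), central base = ref
    methylation_level: int | None = None
    cds_labels: frozenset[str] = frozenset()
    revel: float | None = None

    @property
    def is_singleton(self) -> bool:
        return self.allele_count == 1

    @property
    def maf(self) -> float:
        return self.allele_count / self.allele_number

    @property
    def pos0(self) -> int:
        """0-based genomic position."""
        return self.pos - 1


class ConservationTrack:
    """Per-base conservation scores (phyloP-like), keyed by (chrom, 0-based pos).

    Lookups of absent positions return None -- never a default of 0, because a
    missing alignment column is not evidence of neutrality.
    """

    def __init__(self, scores: dict[tuple[str, int], float] | None = None):
        self._scores: dict[tuple[str, int], float] = dict(scores or {})

    def __len__(self) -> int:
        return len(self._scores)

    def set(self, chrom: str, pos: int, score: float) -> None:
        self._scores[(chrom, pos)] = float(score)

    def get(self, chrom: str, pos: int) -> float | None:
        return self._scores.get((chrom, pos))

    def items(self):
        return self._scores.items()


ALL_CODONS = [a + b + c for a in "UCAG" for b in "UCAG" for c in "UCAG"]
SENSE_CODONS = [c for c in ALL_CODONS if c not in RNA_STOPS]


class CscTable:
    """Codon stability coefficients for the 61 sense codons (RNA keys)."""

    def __init__(self, csc: dict[str, float]):
        csc = {dna_to_rna(k.upper()): float(v) for k, v in csc.items()}
        missing = set(SENSE_CODONS) - set(csc)
        if missing:
            raise ValueError(f"CSC table missing sense codons: {sorted(missing)}")
        stops = set(csc) & set(RNA_STOPS)
        if stops:
            raise ValueError(f"CSC table contains stop codons: {sorted(stops)}")
        self._csc = {k: csc[k] for k in SENSE_CODONS}

    def __getitem__(self, codon: str) -> float:
        codon = dna_to_rna(codon.upper())
        if codon not in self._csc:
            raise KeyError(f"codon {codon} absent from CSC table")
        return self._csc[codon]

    def __contains__(self, codon: str) -> bool:
        return dna_to_rna(codon.upper()) in self._csc

    def items(self):
        return self._csc.items()


@dataclass
class BiobankTable:
    """Per-individual genotypes, covariates and dated phenotype events.

    ``dosages``: DataFrame individuals x variants, values {0,1,2} or NaN.
    ``covariates``: DataFrame individuals x {age, age2, sex, PC1..PC10}.
    ``events``: DataFrame with columns individual, code, date.
    ``variant_annotations``: DataFrame indexed by variant id with columns
    gene, cds_labels (comma-joined), revel, maf -- used for burden building.
    """

    dosages: pd.DataFrame
    covariates: pd.DataFrame
    events: pd.DataFrame
    variant_annotations: pd.DataFrame

    def validate(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2} or missing")
        if not self.dosages.index.equals(self.covariates.index):
            raise ValueError("dosage and covariate individuals differ")
        if self.covariates.isna().any().any():
            raise ValueError("covariate vectors must be complete")


# ---------------------------------------------------------------------------
# Mutation-context normalisation
# ---------------------------------------------------------------------------


def normalize_context(
    ref_triplet: str, ref: str, alt: str, strand_of_record: str = "+"
) -> str | None:
    """Collapse a mutation context so the central reference base is A or C.

    ``ref_triplet`` is the DNA triplet centred on ``ref``.  If the record is
    given in transcript orientation on the minus strand, pass
    ``strand_of_record='-'`` and the triplet/alleles are first mapped back to
    the reference strand; collapsing then makes the result strand-free.

    Returns a context key ``"XYZ>A"`` (central base of XYZ mutating to A), or
    None for triplets containing N (such records are excluded from MAPS).
    """
    ref_triplet = rna_to_dna(ref_triplet.upper())
    ref = rna_to_dna(ref.upper())
    alt = rna_to_dna(alt.upper())
    if strand_of_record == "-":
        ref_triplet = revcomp(ref_triplet)
        ref = revcomp(ref)
        alt = revcomp(alt)
    if len(ref_triplet) != 3 or "N" in ref_triplet or "N" in alt:
        return None
    if ref_triplet[1] != ref:
        raise ValueError(f"central base of {ref_triplet} is not ref {ref}")
    if ref_triplet[1] in "GT":
        ref_triplet = revcomp(ref_triplet)
        alt = revcomp(alt)
    return f"{ref_triplet}>{alt}"


def context_from_genome(genome: dict[str, str], v: VariantRecord) -> str | None:
    """Collapsed context for a variant from a chrom->sequence mapping."""
    seq = genome[v.chrom]
    if v.pos0 < 1 or v.pos0 + 2 > len(seq):
        return None
    triplet = seq[v.pos0 - 1 : v.pos0 + 2].upper()
    if triplet[1] != v.ref.upper():
        raise ValueError(
            f"genome base {triplet[1]} at {v.chrom}:{v.pos} != ref {v.ref}"
        )
    return normalize_context(triplet, v.ref, v.alt)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _spliced_dna(genome_seq: str, blocks: list[tuple[int, int]], strand: str) -> str:
    concat = "".join(genome_seq[s:e] for s, e in blocks)
    return revcomp(concat) if strand == "-" else concat


def read_orf_bed(path, genome: dict[str, str]) -> list[OrfAnnotation]:
    """Read ORFs from a BED12 file, extracting sequences from ``genome``.

    The BED name column carries ``orf_id|orf_class|transcript_id[|cds_dist]``.
    Records whose spliced length is not divisible by 3 are rejected with a
    logged warning and parsing continues.
    """
    orfs: list[OrfAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            parts = name.split("|")
            orf_id, orf_class = parts[0], parts[1]
            transcript_id = parts[2] if len(parts) > 2 else ""
            cds_dist = int(parts[3]) if len(parts) > 3 and parts[3] != "" else None
            seq = _spliced_dna(genome[chrom], blocks, strand)
            if len(seq) % 3 != 0:
                logger.warning(
                    "rejecting ORF %s: length %d not divisible by 3", orf_id, len(seq)
                )
                continue
            orfs.append(
                OrfAnnotation(
                    orf_id=orf_id,
                    transcript_id=transcript_id,
                    chrom=chrom,
                    strand=strand,
                    blocks=blocks,
                    orf_class=orf_class,
                    spliced_sequence=seq,
                    cds_start_distance=cds_dist,
                )
            )
    return orfs


def write_orf_bed(path, orfs: list[OrfAnnotation]) -> None:
    """Write ORFs as BED12 (inverse of :func:`read_orf_bed`)."""
    with open(path, "w") as fh:
        for o in orfs:
            start = o.blocks[0][0]
            end = o.blocks[-1][1]
            name = f"{o.orf_id}|{o.orf_class}|{o.transcript_id}"
            if o.cds_start_distance is not None:
                name += f"|{o.cds_start_distance}"
            sizes = ",".join(str(e - s) for s, e in o.blocks)
            offs = ",".join(str(s - start) for s, e in o.blocks)
            fh.write(
                "\t".join(
                    [
                        o.chrom,
                        str(start),
                        str(end),
                        name,
                        "0",
                        o.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(o.blocks)),
                        sizes,
                        offs,
                    ]
                )
                + "\n"
            )


def read_utr_bed(path, genome: dict[str, str]) -> list[UtrAnnotation]:
    """Read UTRs from BED12; name column carries ``transcript_id[|orf_ids|cds_start]``.

    ``orf_ids`` is a comma-joined list (may be empty), ``cds_start`` a 0-based
    genomic position.
    """
    utrs: list[UtrAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            parts = name.split("|")
            tid = parts[0]
            orf_ids = [x for x in parts[1].split(",") if x] if len(parts) > 1 else []
            cds_start = int(parts[2]) if len(parts) > 2 and parts[2] != "" else None
            seq = _spliced_dna(genome[chrom], blocks, strand)
            utrs.append(
                UtrAnnotation(
                    transcript_id=tid,
                    chrom=chrom,
                    strand=strand,
                    blocks=blocks,
                    sequence=seq,
                    contained_orf_ids=orf_ids,
                    cds_start=cds_start,
                )
            )
    return utrs


def write_utr_bed(path, utrs: list[UtrAnnotation]) -> None:
    with open(path, "w") as fh:
        for u in utrs:
            start = u.blocks[0][0]
            end = u.blocks[-1][1]
            name = f"{u.transcript_id}|{','.join(u.contained_orf_ids)}"
            if u.cds_start is not None:
                name += f"|{u.cds_start}"
            sizes = ",".join(str(e - s) for s, e in u.blocks)
            offs = ",".join(str(s - start) for s, e in u.blocks)
            fh.write(
                "\t".join(
                    [
                        u.chrom,
                        str(start),
                        str(end),
                        name,
                        "0",
                        u.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(u.blocks)),
                        sizes,
                        offs,
                    ]
                )
                + "\n"
            )


def read_variants_vcf(path) -> tuple[list[VariantRecord], int]:
    """Read SNVs from a VCF, splitting multiallelic sites into biallelic records.

    No filtering is applied here (see :func:`qc_filter`).  Returns the records
    and the count of skipped non-SNV alleles.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    n_skipped = 0
    vcf = VCF(str(path))
    for var in vcf:
        ac = var.INFO.get("AC")
        an = var.INFO.get("AN")
        acs = ac if isinstance(ac, tuple) else (ac,)
        lcr = bool(var.INFO.get("lcr", 0))
        filt = var.FILTER or "PASS"  # cyvcf2 reports PASS as None
        for alt, ac_i in zip(var.ALT, acs):
            if len(var.REF) != 1 or len(alt) != 1 or alt not in DNA_BASES:
                n_skipped += 1
                continue
            records.append(
                VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    allele_count=int(ac_i),
                    allele_number=int(an),
                    filter_status=filt,
                    lcr_flag=lcr,
                )
            )
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-SNV alleles", n_skipped)
    return records, n_skipped


def qc_filter(
    variants: list[VariantRecord], an_fraction: float = 0.8
) -> list[VariantRecord]:
    """High-confidence variant filter.

    Keeps records with FILTER == PASS, outside low-complexity regions, and
    with allele number at least ``an_fraction`` of the maximum allele number
    observed in the input set (controls for uneven sequencing depth).
    """
    if not variants:
        return []
    if not 0 < an_fraction <= 1:
        raise ValueError("an_fraction must be in (0, 1]")
    max_an = max(v.allele_number for v in variants)
    cutoff = an_fraction * max_an
    return [
        v
        for v in variants
        if v.filter_status == "PASS" and not v.lcr_flag and v.allele_number >= cutoff
    ]


def read_conservation_bedgraph(path) -> ConservationTrack:
    """Read a per-base bedGraph (chrom, start, end, score) into a track."""
    track = ConservationTrack()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, score = line.split("\t")
            for p in range(int(start), int(end)):
                track.set(chrom, p, float(score))
    return track


def write_conservation_bedgraph(path, track: ConservationTrack) -> None:
    with open(path, "w") as fh:
        for (chrom, pos), score in sorted(track.items()):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{score:g}\n")


def read_csc_table(path) -> CscTable:
    df = pd.read_csv(path, sep="\t")
    return CscTable(dict(zip(df["codon"], df["csc"])))


def write_csc_table(path, table: CscTable) -> None:
    pd.DataFrame(table.items(), columns=["codon", "csc"]).to_csv(
        path, sep="\t", index=False
    )


def read_fasta(path) -> dict[str, str]:
    """Chrom -> uppercase DNA sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, genome: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_biobank(
    dosage_path, covariate_path, event_path, annotation_path
) -> BiobankTable:
    """Assemble a biobank table from its four TSV components."""
    dosages = pd.read_csv(dosage_path, sep="\t", index_col=0)
    covariates = pd.read_csv(covariate_path, sep="\t", index_col=0)
    events = pd.read_csv(event_path, sep="\t", dtype={"code": str})
    annotations = pd.read_csv(annotation_path, sep="\t", index_col=0)
    return BiobankTable(dosages, covariates, events, annotations)
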