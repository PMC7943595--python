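"""Shared fixtures: handcrafted genomes/ORFs and a small simulated world."""

from __future__ import annotations

import numpy as np
import pytest

from uorfsel.genomic_model import OrfAnnotation, VariantRecord, revcomp, rna_to_dna
from uorfsel.maps import MutationRateTable
from uorfsel.synthetic_data import (
    SimulationConfig,
    make_rate_table,
    make_transcriptome,
    simulate_variants,
)


def make_orf(
    seq_rna: str,
    strand: str = "+",
    chrom: str = "chr1",
    start: int = 100,
    orf_id: str = "orf1",
    orf_class: str = "uORF",
    blocks: list[tuple[int, int]] | None = None,
    cds_start_distance: int | None = None,
) -> OrfAnnotation:
    """Single-block ORF (unless blocks given) with the given RNA sequence."""
    if blocks is None:
        blocks = [(start, start + len(seq_rna))]
    return OrfAnnotation(
        orf_id=orf_id,
        transcript_id="tx1",
        chrom=chrom,
        strand=strand,
        blocks=blocks,
        orf_class=orf_class,
        spliced_sequence=seq_rna,
        cds_start_distance=cds_start_distance,
    )


def genome_for(orf: OrfAnnotation, pad: int = 10) -> dict[str, str]:
    """A genome dict whose sequence is consistent with the ORF's blocks."""
    end = orf.blocks[-1][1] + pad
    seq = list("A" * end)
    dna = rna_to_dna(orf.spliced_sequence)
    if orf.strand == "-":
        dna = revcomp(dna)
    offset = 0
    for s, e in orf.blocks:
        seq[s:e] = list(dna[offset : offset + e - s])
        offset += e - s
    return {orf.chrom: "".join(seq)}


def variant_for(
    orf: OrfAnnotation,
    transcript_idx: int,
    alt_rna: str,
    ac: int = 1,
    an: int = 1000,
) -> VariantRecord:
    """SNV at a translation-orientation index of the ORF, in genomic alleles."""
    comp = str.maketrans("ACGU", "UGCA")
    gpos = int(orf.genomic_positions()[transcript_idx])
    ref_rna = orf.spliced_sequence[transcript_idx]
    if orf.strand == "-":
        ref_rna = ref_rna.translate(comp)
        alt_rna = alt_rna.translate(comp)
    return VariantRecord(
        chrom=orf.chrom,
        pos=gpos + 1,
        ref=rna_to_dna(ref_rna),
        alt=rna_to_dna(alt_rna),
        allele_count=ac,
        allele_number=an,
    )


def synth_variants(
    rates: MutationRateTable,
    n: int,
    delta: float = 0.0,
    seed: int = 0,
    intercept: float = 0.05,
    slope: float = 5.0,
) -> list[VariantRecord]:
    """Variants with random contexts whose singleton law is a + b*mu + delta."""
    rng = np.random.default_rng(seed)
    contexts = rates.contexts()
    picks = rng.integers(0, len(contexts), size=n)
    out = []
    for i, k in enumerate(picks):
        ctx = contexts[k]
        p = intercept + slope * rates.get(ctx) + delta
        singleton = rng.random() < p
        out.append(
            VariantRecord(
                chrom="chrX",
                pos=i + 1,
                ref="A",
                alt="G",
                allele_count=1 if singleton else 5,
                allele_number=1000,
                context=ctx,
            )
        )
    return out


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_genes=30, n_calibration=3000)


@pytest.fixture(scope="session")
def sim_world(sim_config):
    """(genome, utrs, orfs, rates, variants, truth) from one generator run."""
    genome, utrs, orfs = make_transcriptome(sim_config)
    rates = make_rate_table(sim_config)
    variants, truth = simulate_variants(sim_config, orfs, utrs, rates, genome)
    return genome, utrs, orfs, rates, variants, truth
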