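"""Reading-frame-aware classification of SNVs within translated ORFs.

An SNV landing inside a translated ORF is interpreted through the ORF's
mapped reading frame: the affected codon is substituted in translation
orientation (minus-strand alleles complemented) and categorised as

* ``stop_gain`` -- a sense codon becomes UAA/UAG/UGA (an upstream
  termination codon, UTC, when the ORF is a uORF);
* ``stop_strengthen`` / ``stop_weaken`` -- an existing stop codon moves up
  or down the termination-efficiency hierarchy UAA > UAG > UGA;
* ``stop_loss`` -- a stop codon becomes a sense codon;
* ``start_maintain`` / ``start_disrupt`` -- first-codon variants that keep
  or break the NUG start context (position 1 vs positions 2-3);
* ``missense`` / ``synonymous`` -- everything else, by the standard genetic
  code.

The module also enumerates potential stop-creating and start-disrupting
genomic positions for the conservation analyses, and annotates each call's
direction of codon-optimality change from a codon-stability-coefficient
(CSC) table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .genomic_model import (
    NUG_STARTS,
    RNA_STOPS,
    CscTable,
    OrfAnnotation,
    UtrAnnotation,
    VariantRecord,
    dna_to_rna,
    translate_codon,
)

logger = logging.getLogger(__name__)

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: Termination-efficiency ranks: UAA is the strongest stop, UGA the weakest
#: and most read-through prone.
STOP_STRENGTH = {"UGA": 1, "UAG": 2, "UAA": 3}

#: Severity order used to deduplicate variants hitting multiple ORFs.
SEVERITY_ORDER = (
    "stop_gain",
    "stop_strengthen",
    "start_disrupt",
    "stop_loss",
    "stop_weaken",
    "missense",
    "synonymous",
    "start_maintain",
)
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}


def stop_strength(codon: str) -> int:
    """Rank of a stop codon in the UAA > UAG > UGA hierarchy (UAA -> 3)."""
    codon = dna_to_rna(codon.upper())
    if codon not in STOP_STRENGTH:
        raise ValueError(f"{codon} is not a stop codon")
    return STOP_STRENGTH[codon]


@dataclass
class ConsequenceCall:
    """The uORF-frame classification of one SNV against one ORF."""

    variant: VariantRecord
    orf_id: str
    codon_index: int
    codon_offset: int
    ref_codon: str
    alt_codon: str
    category: str
    new_stop: str | None = None  # set for stop_gain / stop_strengthen
    csc_delta: float | None = None
    optimality: str = "n/a"  # increasing | decreasing | neutral | n/a

    @property
    def severity_rank(self) -> int:
        return _SEVERITY_RANK[self.category]


@dataclass
class PotentialStopPosition:
    """A genomic position where a single substitution creates an in-frame stop."""

    chrom: str
    pos: int  # 0-based genomic
    orf_id: str | None
    achievable_stops: frozenset[str]
    distance_to_cds: int | None = None

    @property
    def is_multi(self) -> bool:
        return len(self.achievable_stops) > 1

    @property
    def distance_window(self) -> int | None:
        """10-bp CDS-distance bin id: [0,10) -> 0, [10,20) -> 1, ..."""
        if self.distance_to_cds is None:
            return None
        return self.distance_to_cds // 10


def _categorise(ref_codon: str, alt_codon: str, codon_index: int) -> tuple[str, str | None]:
    """Category and (for stop gain/strengthen) the resulting stop codon."""
    if codon_index == 0:
        if alt_codon in NUG_STARTS:
            return "start_maintain", None
        return "start_disrupt", None
    ref_stop = ref_codon in RNA_STOPS
    alt_stop = alt_codon in RNA_STOPS
    if ref_stop and alt_stop:
        if STOP_STRENGTH[alt_codon] > STOP_STRENGTH[ref_codon]:
            return "stop_strengthen", alt_codon
        return "stop_weaken", None
    if ref_stop:
        return "stop_loss", None
    if alt_stop:
        return "stop_gain", alt_codon
    if translate_codon(ref_codon) == translate_codon(alt_codon):
        return "synonymous", None
    return "missense", None


def classify_orf_snv(
    orf: OrfAnnotation,
    variant: VariantRecord,
    csc: CscTable | None = None,
) -> ConsequenceCall:
    """Classify an SNV lying within ``orf`` by its effect on the mapped codon.

    The variant's reference-strand alleles are mapped into translation
    orientation (complemented for minus-strand ORFs), substituted into the
    codon containing the position, and categorised.  First-codon variants
    follow the NUG start rules; elsewhere the stop table and the standard
    genetic code decide.
    """
    if len(variant.ref) != 1 or len(variant.alt) != 1:
        raise ValueError("SNV only: indels cannot be classified against a frame")
    idx = orf.transcript_index(variant.pos0)  # raises if outside the ORF
    codon_index, offset = divmod(idx, 3)
    ref_base = dna_to_rna(variant.ref.upper())
    alt_base = dna_to_rna(variant.alt.upper())
    if orf.strand == "-":
        ref_base = ref_base.translate(_RNA_COMPLEMENT)
        alt_base = alt_base.translate(_RNA_COMPLEMENT)
    ref_codon = orf.codon(codon_index)
    if ref_codon[offset] != ref_base:
        raise ValueError(
            f"ref allele {variant.ref} does not match ORF {orf.orf_id} codon "
            f"{ref_codon} at offset {offset}"
        )
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    category, new_stop = _categorise(ref_codon, alt_codon, codon_index)
    call = ConsequenceCall(
        variant=variant,
        orf_id=orf.orf_id,
        codon_index=codon_index,
        codon_offset=offset,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        category=category,
        new_stop=new_stop,
    )
    if csc is not None:
        call.optimality = csc_direction(ref_codon, alt_codon, csc)
        if call.optimality != "n/a":
            call.csc_delta = csc[alt_codon] - csc[ref_codon]
    return call


def classify_start_snv(orf: OrfAnnotation, variant: VariantRecord) -> str:
    """Start-codon rule for a first-codon SNV: maintain vs disrupt.

    Mutations of the first position that keep the codon in the NUG set
    maintain the start context; mutations of the second or third position
    disrupt translation initiation.
    """
    call = classify_orf_snv(orf, variant)
    if call.codon_index != 0:
        raise ValueError("variant is not in the first codon")
    return call.category


def csc_direction(ref_codon: str, alt_codon: str, table: CscTable) -> str:
    """Direction of the codon-optimality change, by sign of CSC(alt) - CSC(ref)."""
    ref_codon = dna_to_rna(ref_codon.upper())
    alt_codon = dna_to_rna(alt_codon.upper())
    if ref_codon in RNA_STOPS or alt_codon in RNA_STOPS:
        return "n/a"
    delta = table[alt_codon] - table[ref_codon]
    if delta > 0:
        return "increasing"
    if delta < 0:
        return "decreasing"
    return "neutral"


def classify_variants(
    orfs: list[OrfAnnotation],
    variants: list[VariantRecord],
    csc: CscTable | None = None,
    dedup: bool = True,
) -> list[ConsequenceCall]:
    """Classify each variant against every ORF containing it.

    With ``dedup`` a variant hitting several ORFs is reduced to its single
    most severe call (severity order ``SEVERITY_ORDER``), so class-level
    tallies count each variant once.
    """
    by_chrom: dict[str, list[OrfAnnotation]] = {}
    for o in orfs:
        by_chrom.setdefault(o.chrom, []).append(o)
    calls: list[ConsequenceCall] = []
    for v in variants:
        hits = [
            classify_orf_snv(o, v, csc)
            for o in by_chrom.get(v.chrom, [])
            if o.contains(v.pos0)
        ]
        if not hits:
            continue
        if dedup:
            calls.append(min(hits, key=lambda c: c.severity_rank))
        else:
            calls.extend(hits)
    return calls


def find_potential_stop_positions(orf: OrfAnnotation) -> list[PotentialStopPosition]:
    """Positions in sense codons where one substitution yields an in-frame stop.

    The ORF's terminal annotated stop codon is excluded -- substitutions there
    are stop-weakening/strengthening, not stop-creating.  Positions where more
    than one stop codon is achievable carry the full achievable set.
    """
    positions = orf.genomic_positions()  # translation order
    out: list[PotentialStopPosition] = []
    for codon_index in range(orf.n_codons - 1):  # skip terminal stop
        ref_codon = orf.codon(codon_index)
        if ref_codon in RNA_STOPS:
            continue
        for offset in range(3):
            achievable = {
                alt_codon
                for b in "ACGU"
                if b != ref_codon[offset]
                and (alt_codon := ref_codon[:offset] + b + ref_codon[offset + 1 :])
                in RNA_STOPS
            }
            if achievable:
                gpos = int(positions[3 * codon_index + offset])
                dist = orf.cds_start_distance
                out.append(
                    PotentialStopPosition(
                        chrom=orf.chrom,
                        pos=gpos,
                        orf_id=orf.orf_id,
                        achievable_stops=frozenset(achievable),
                        distance_to_cds=_position_cds_distance(orf, 3 * codon_index + offset)
                        if dist is not None
                        else None,
                    )
                )
    return out


def _position_cds_distance(orf: OrfAnnotation, transcript_idx: int) -> int:
    """Distance from a base (by translation-orientation index) to the CDS start.

    ``cds_start_distance`` is anchored at the ORF 3' end; a base ``k`` bases
    upstream of the 3' end is that much further from the CDS.
    """
    return orf.cds_start_distance + (orf.length - 1 - transcript_idx)


def find_start_disrupting_positions(
    orf: OrfAnnotation, in_frame: bool = True
) -> list[PotentialStopPosition]:
    """Start-disrupting genomic positions for an ORF.

    ``in_frame=True``: the two positions at offsets 1 and 2 of the first
    codon (mutating them breaks the NUG start).  ``in_frame=False``: the
    control enumeration -- U/G positions of every NUG triplet occurring
    inside the ORF *out of frame* (not aligned to codon boundaries, and not
    the annotated start itself).
    """
    positions = orf.genomic_positions()
    seq = orf.spliced_sequence
    out: list[PotentialStopPosition] = []
    dist_known = orf.cds_start_distance is not None

    def make(tidx: int) -> PotentialStopPosition:
        return PotentialStopPosition(
            chrom=orf.chrom,
            pos=int(positions[tidx]),
            orf_id=orf.orf_id,
            achievable_stops=frozenset(),
            distance_to_cds=_position_cds_distance(orf, tidx) if dist_known else None,
        )

    if in_frame:
        return [make(1), make(2)]
    for i in range(len(seq) - 2):
        if i % 3 == 0:
            continue  # in-frame triplets are not controls
        if seq[i : i + 3] in NUG_STARTS:
            out.extend([make(i + 1), make(i + 2)])
    return out


def exclude_cds_overlap(
    calls: list[ConsequenceCall],
    cds_intervals: list[tuple[str, int, int]],
) -> list[ConsequenceCall]:
    """Drop calls whose variant falls inside any annotated CDS interval.

    Guards against 5'UTR/CDS overlap between mRNA isoforms driving apparent
    constraint.  Intervals are (chrom, start, end), 0-based half-open.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in cds_intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    kept = [
        c
        for c in calls
        if not any(
            s <= c.variant.pos0 < e for s, e in by_chrom.get(c.variant.chrom, [])
        )
    ]
    removed = len(calls) - len(kept)
    if removed:
        logger.info("excluded %d calls overlapping CDS intervals", removed)
    return kept


def find_utr_stop_creating_positions(
    utr: UtrAnnotation,
    exclude_orf_positions: set[int] | None = None,
    frame: str = "any",
) -> list[PotentialStopPosition]:
    """Control enumeration: UTR positions one substitution from a stop triplet.

    Outside a translated ORF no reading frame is defined, so a position
    qualifies if some substitution creates UGA/UAG/UAA in any of the three
    local frames (``frame='any'``, default) or only in the frame anchored at
    the UTR 5' end (``frame='fixed'``).  Distances to the CDS start are
    transcript-coordinate, for 10-bp window matching.
    """
    if frame not in ("any", "fixed"):
        raise ValueError("frame must be 'any' or 'fixed'")
    seq = utr.sequence
    positions = utr.genomic_positions()
    exclude = exclude_orf_positions or set()
    achievable_at: dict[int, set[str]] = {}
    for i in range(len(seq) - 2):
        if frame == "fixed" and i % 3 != 0:
            continue
        triplet = seq[i : i + 3]
        for off in range(3):
            for b in "ACGU":
                if b == triplet[off]:
                    continue
                alt = triplet[:off] + b + triplet[off + 1 :]
                if alt in RNA_STOPS:
                    achievable_at.setdefault(i + off, set()).add(alt)
    out = []
    for tidx in sorted(achievable_at):
        gpos = int(positions[tidx])
        if gpos in exclude:
            continue
        out.append(
            PotentialStopPosition(
                chrom=utr.chrom,
                pos=gpos,
                orf_id=None,
                achievable_stops=frozenset(achievable_at[tidx]),
                distance_to_cds=utr.length - tidx,
            )
        )
    return out
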