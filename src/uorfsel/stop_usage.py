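"""Stop-codon usage of translated uORFs versus 5'UTR background.

Translated uORFs preferentially end in the weak, read-through-prone stop
codons (UGA, UAG) and are depleted of the strong UAA stop relative to the
general trinucleotide content of 5'UTRs.  This module quantifies that:

* the observed stop-codon proportions of a uORF set, with a bootstrap CI
  from resampling ORFs with replacement;
* a background distribution built by repeatedly drawing one stop-matching
  trinucleotide (UGA/UAG/UAA, transcript orientation, overlapping
  occurrences counted at every offset) from each 5'UTR;
* one-sided permutation p-values for depletion or enrichment of a given
  codon, comparing the paired iteration streams.
"""

from __future__ import annotations

import numpy as np

from .genomic_model import OrfAnnotation, UtrAnnotation
from .resampling import paired_exceedance_pvalue

#: Fixed codon order for all proportion triplets.
STOP_ORDER = ("UGA", "UAG", "UAA")
_STOP_INDEX = {c: i for i, c in enumerate(STOP_ORDER)}


def uorf_stop_frequencies(
    orfs: list[OrfAnnotation],
    n_iter: int = 0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Observed stop-codon proportions (UGA, UAG, UAA) of a uORF set.

    With ``n_iter > 0`` also returns the (n_iter, 3) matrix of proportions
    from resampling the ORFs with replacement -- the per-iteration stream
    used for CIs and paired permutation p-values.
    """
    if not orfs:
        raise ValueError("no ORFs supplied")
    codes = np.array([_STOP_INDEX[o.stop_codon] for o in orfs])
    props = np.bincount(codes, minlength=3) / len(codes)
    draws = None
    if n_iter > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(codes), size=(n_iter, len(codes)))
        resampled = codes[idx]
        draws = np.stack(
            [(resampled == k).mean(axis=1) for k in range(3)], axis=1
        )
    return props, draws


def stop_occurrences(sequence: str, mask: np.ndarray | None = None) -> np.ndarray:
    """Counts of UGA/UAG/UAA occurrences in a transcript-orientation sequence.

    Overlapping occurrences are counted at every offset.  ``mask`` is a
    per-base boolean array; occurrences touching any masked base are
    dropped.
    """
    counts = np.zeros(3, dtype=int)
    for i in range(len(sequence) - 2):
        tri = sequence[i : i + 3]
        if tri in _STOP_INDEX:
            if mask is not None and mask[i : i + 3].any():
                continue
            counts[_STOP_INDEX[tri]] += 1
    return counts


def background_stop_distribution(
    utrs: list[UtrAnnotation],
    n_iter: int = 10000,
    exclude_orf_overlap: bool = False,
    orfs: list[OrfAnnotation] | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Per-iteration stop-trinucleotide proportions from 5'UTR background.

    Each iteration draws one stop-matching trinucleotide uniformly from each
    eligible UTR and reports the proportions of UGA/UAG/UAA among the draws.
    UTRs with no occurrence are skipped.  With ``exclude_orf_overlap``,
    trinucleotides overlapping translated-uORF intervals (looked up from
    ``orfs`` by the UTR's ``contained_orf_ids``) are masked before scanning.

    Returns an (n_iter, 3) array; each row sums to 1.
    """
    orf_by_id = {o.orf_id: o for o in (orfs or [])}
    per_utr_probs: list[np.ndarray] = []
    for u in utrs:
        mask = None
        if exclude_orf_overlap and u.contained_orf_ids:
            gpos = u.genomic_positions()
            masked_g: set[int] = set()
            for oid in u.contained_orf_ids:
                o = orf_by_id.get(oid)
                if o is not None:
                    masked_g.update(int(p) for p in o.genomic_positions())
            mask = np.fromiter(
                (int(p) in masked_g for p in gpos), dtype=bool, count=len(gpos)
            )
        counts = stop_occurrences(u.sequence, mask)
        total = counts.sum()
        if total > 0:
            per_utr_probs.append(counts / total)
    if not per_utr_probs:
        raise ValueError("no UTR contains a stop-matching trinucleotide")
    probs = np.stack(per_utr_probs)  # (n_utr, 3)
    rng = np.random.default_rng(seed)
    n_utr = probs.shape[0]
    cum = probs.cumsum(axis=1)
    choice = np.empty((n_iter, n_utr), dtype=np.int8)
    for j in range(n_utr):
        choice[:, j] = np.searchsorted(cum[j], rng.random(n_iter), side="right")
    draws = np.stack([(choice == k).mean(axis=1) for k in range(3)], axis=1)
    return draws


def background_mean_proportions(
    utrs: list[UtrAnnotation],
    exclude_orf_overlap: bool = False,
    orfs: list[OrfAnnotation] | None = None,
) -> np.ndarray:
    """Analytic expectation of :func:`background_stop_distribution`.

    One uniform draw per eligible UTR makes the expected proportion of codon
    k the average over eligible UTRs of that UTR's occurrence fraction.
    """
    orf_by_id = {o.orf_id: o for o in (orfs or [])}
    per_utr = []
    for u in utrs:
        mask = None
        if exclude_orf_overlap and u.contained_orf_ids:
            gpos = u.genomic_positions()
            masked_g: set[int] = set()
            for oid in u.contained_orf_ids:
                o = orf_by_id.get(oid)
                if o is not None:
                    masked_g.update(int(p) for p in o.genomic_positions())
            mask = np.fromiter(
                (int(p) in masked_g for p in gpos), dtype=bool, count=len(gpos)
            )
        counts = stop_occurrences(u.sequence, mask)
        if counts.sum() > 0:
            per_utr.append(counts / counts.sum())
    if not per_utr:
        raise ValueError("no UTR contains a stop-matching trinucleotide")
    return np.stack(per_utr).mean(axis=0)


def usage_pvalue(
    orf_draws: np.ndarray,
    background_draws: np.ndarray,
    codon: str,
    direction: str,
) -> float:
    """One-sided permutation p-value for codon usage difference.

    ``depletion``: uORFs use the codon less than background; unfavorable
    iterations are those where the uORF frequency fails to fall below the
    background frequency, exact ties counting half (mid-p).  ``enrichment``
    counts the reverse.
    """
    if direction not in ("depletion", "enrichment"):
        raise ValueError("direction must be 'depletion' or 'enrichment'")
    k = _STOP_INDEX[codon.upper().replace("T", "U")]
    a = np.asarray(orf_draws)[:, k]
    b = np.asarray(background_draws)[:, k]
    if direction == "depletion":
        return paired_exceedance_pvalue(b, a)  # background exceeds uORF usage
    return paired_exceedance_pvalue(a, b)
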