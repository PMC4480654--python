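"""SNP classification and the neutrality index.

The neutrality index compares non-synonymous/synonymous ratios between
divergence (D) and within-species polymorphism (P):

    NI = log[ (2*Ds + 1)(2*Pn + 1) / ((2*Dn + 1)(2*Ps + 1)) ]

with +1 pseudo-counts keeping it finite for any non-negative counts.
NI > 0 is consistent with purifying selection, NI < 0 with positive
selection.  The log base (default e) only rescales; signs and ranks are
base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np

from .alignment import ConsistencyError, GeneAlignment, SnpRecord
from .genetic_code import STOP_CODONS, translate_codon
from .pairwise import DivergenceEstimate

SYNONYMOUS = "synonymous"
NON_SYNONYMOUS = "non-synonymous"
UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class PolymorphismCounts:
    Ps: int
    Pn: int


@dataclass
class NeutralityResult:
    gene_id: str
    Ds: float
    Dn: float
    Ps: int
    Pn: int
    NI: float
    log_base: float


def classify_snp(g: GeneAlignment, snp: SnpRecord) -> str:
    """Classify one SNP against the ungapped reference CDS.

    Multiple SNPs in a codon are classified independently against the
    reference codon (phase is unavailable at SNP-table granularity).
    Edits creating or destroying a stop, or codons containing ambiguity,
    are unclassifiable.
    """
    cds = g.ungapped(g.reference_species)
    pos = snp.cds_position
    if not 0 <= pos < len(cds):
        raise ConsistencyError(
            f"{g.gene_id}: SNP position {pos} outside CDS of {len(cds)} bases"
        )
    if cds[pos] != snp.ref_base:
        raise ConsistencyError(
            f"{g.gene_id}@{pos}: ref base {snp.ref_base!r} != CDS base {cds[pos]!r}"
        )
    ci = pos // 3
    ref_codon = cds[3 * ci : 3 * ci + 3]
    off = pos % 3
    alt_codon = ref_codon[:off] + snp.alt_base + ref_codon[off + 1 :]
    if any(b not in "ACGT" for b in ref_codon):
        return UNCLASSIFIABLE
    if ref_codon in STOP_CODONS or alt_codon in STOP_CODONS:
        return UNCLASSIFIABLE
    return SYNONYMOUS if translate_codon(ref_codon) == translate_codon(alt_codon) else NON_SYNONYMOUS


def count_polymorphisms(
    g: GeneAlignment,
    snps: list[SnpRecord],
    codon_subset: set[int] | None = None,
) -> PolymorphismCounts:
    """Ps/Pn over this gene's SNPs, optionally restricted to a codon subset.

    ``codon_subset`` is expressed in original reference codon indices so
    the same SNP table serves trimmed alignments (each record counted
    once, no frequency weighting).
    """
    ps = pn = 0
    for snp in snps:
        if snp.gene_id != g.gene_id:
            continue
        if codon_subset is not None and snp.cds_position // 3 not in codon_subset:
            continue
        cls = classify_snp(g, snp)
        if cls == SYNONYMOUS:
            ps += 1
        elif cls == NON_SYNONYMOUS:
            pn += 1
    return PolymorphismCounts(Ps=ps, Pn=pn)


def neutrality_index(
    Ds: float, Dn: float, Ps: float, Pn: float, log_base: float = math.e
) -> float:
    """Pseudo-count neutrality index; defined for all non-negative reals.

    Fractional divergence counts from pathway averaging are accepted
    as-is (the formula needs no integrality).
    """
    for name, v in (("Ds", Ds), ("Dn", Dn), ("Ps", Ps), ("Pn", Pn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if log_base <= 0 or log_base == 1:
        raise ValueError(f"invalid log base {log_base}")
    val = math.log((2 * Ds + 1) * (2 * Pn + 1) / ((2 * Dn + 1) * (2 * Ps + 1)))
    return val / math.log(log_base)


def divergence_counts_for_ni(est: DivergenceEstimate) -> tuple[float, float]:
    """(Ds, Dn) for the NI formula: raw averaged difference counts, not JC rates."""
    if not est.valid:
        raise ValueError(f"{est.gene_id}: invalid divergence estimate ({est.reason})")
    return est.Sd, est.Nd


def neutrality_result(
    g: GeneAlignment,
    est: DivergenceEstimate,
    snps: list[SnpRecord],
    log_base: float = math.e,
) -> NeutralityResult:
    ds, dn = divergence_counts_for_ni(est)
    pc = count_polymorphisms(g, snps)
    return NeutralityResult(
        gene_id=g.gene_id,
        Ds=ds,
        Dn=dn,
        Ps=pc.Ps,
        Pn=pc.Pn,
        NI=neutrality_index(ds, dn, pc.Ps, pc.Pn, log_base),
        log_base=log_base,
    )
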