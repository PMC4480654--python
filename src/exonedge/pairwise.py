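"""Counting-based pairwise dN/dS (NG86 with pathway averaging + JC69).

The estimator sums expected synonymous/non-synonymous site counts
(averaged between the two sequences) and pathway-averaged difference
counts over every codon column that is gap-free and unambiguous in both
species, then applies the Jukes–Cantor correction to the proportions.
Genes failing the minimum-aligned-bases rule, the JC domain (p >= 3/4),
or with dS = 0 are flagged invalid rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import GeneAlignment, aligned_bases
from .genetic_code import (
    CodonError,
    N_SITES,
    ND_TABLE,
    S_SITES,
    SD_TABLE,
    encode_codon,
    is_sense,
    jukes_cantor,
)

MIN_ALIGNED_BASES = 150


@dataclass(frozen=True)
class SiteCounts:
    """Expected synonymous (S) and non-synonymous (N) sites; S + N = 3 per codon."""

    S: float
    N: float


@dataclass(frozen=True)
class SubstCounts:
    """Pathway-averaged synonymous (Sd) and non-synonymous (Nd) differences."""

    Sd: float
    Nd: float


@dataclass
class DivergenceEstimate:
    gene_id: str
    Sd: float
    Nd: float
    S: float
    N: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float
    n_codons_used: int
    aligned_bases: int
    valid: bool
    reason: str  # ok | internal_stop | min_aligned | jc_domain | ds_zero


def count_sites(codon: str) -> SiteCounts:
    """NG86 expected site counts for one sense codon."""
    i = encode_codon(codon)
    if i < 0 or not is_sense(codon):
        raise CodonError(f"count_sites requires a sense codon, got {codon!r}")
    return SiteCounts(S=float(S_SITES[i]), N=float(N_SITES[i]))


def count_differences(a: str, b: str) -> SubstCounts:
    """Pathway-averaged difference counts between two sense codons."""
    ia, ib = encode_codon(a), encode_codon(b)
    if ia < 0 or ib < 0 or not (is_sense(a) and is_sense(b)):
        raise CodonError(f"count_differences requires sense codons, got {a!r}, {b!r}")
    return SubstCounts(Sd=float(SD_TABLE[ia, ib]), Nd=float(ND_TABLE[ia, ib]))


@dataclass
class CodonProfile:
    """Per-codon count arrays for one gene and species pair.

    Precomputing these once makes trimming/randomization replicates a
    matter of fancy-indexed sums.  Arrays are aligned to the gene's codon
    index; ``usable`` marks columns that are sense codons in both species.
    """

    gene_id: str
    usable: np.ndarray  # bool, per codon
    sd: np.ndarray
    nd: np.ndarray
    s_sites: np.ndarray
    n_sites: np.ndarray
    aligned_bases_per_codon: np.ndarray

    def estimate(self, idx: np.ndarray | None = None) -> dict[str, float]:
        """Summed estimate over the codon subset ``idx`` (default: all)."""
        if idx is None:
            idx = np.arange(self.usable.size)
        use = idx[self.usable[idx]]
        Sd = float(self.sd[use].sum())
        Nd = float(self.nd[use].sum())
        S = float(self.s_sites[use].sum())
        N = float(self.n_sites[use].sum())
        ab = int(self.aligned_bases_per_codon[idx].sum())
        pS = Sd / S if S > 0 else float("nan")
        pN = Nd / N if N > 0 else float("nan")
        dS = jukes_cantor(pS) if np.isfinite(pS) else float("nan")
        dN = jukes_cantor(pN) if np.isfinite(pN) else float("nan")
        omega = dN / dS if np.isfinite(dS) and np.isfinite(dN) and dS > 0 else float("nan")
        return {
            "Sd": Sd, "Nd": Nd, "S": S, "N": N, "pS": pS, "pN": pN,
            "dS": dS, "dN": dN, "omega": omega,
            "n_codons_used": int(use.size), "aligned_bases": ab,
        }


def codon_profile(g: GeneAlignment, pair: tuple[str, str]) -> CodonProfile:
    a = g.species_codons(pair[0])
    b = g.species_codons(pair[1])
    usable = (a >= 0) & (b >= 0) & np.isfinite(SD_TABLE[a, b])
    sd = np.where(usable, SD_TABLE[a, b], 0.0)
    nd = np.where(usable, ND_TABLE[a, b], 0.0)
    s_sites = np.where(usable, 0.5 * (S_SITES[a] + S_SITES[b]), 0.0)
    n_sites = np.where(usable, 0.5 * (N_SITES[a] + N_SITES[b]), 0.0)
    # aligned bases per codon column (gap-free in both, base-wise)
    cols = g.codon_columns()
    sa, sb = g.sequences[pair[0]], g.sequences[pair[1]]
    ab = np.array(
        [sum(sa[c] != "-" and sb[c] != "-" for c in row) for row in cols],
        dtype=np.int64,
    )
    return CodonProfile(g.gene_id, usable, sd, nd, s_sites, n_sites, ab)


def _finish(gene_id: str, vals: dict[str, float], ab: int,
            min_aligned: int, internal_stop: bool) -> DivergenceEstimate:
    valid, reason = True, "ok"
    if internal_stop:
        valid, reason = False, "internal_stop"
    elif ab < min_aligned:
        valid, reason = False, "min_aligned"
    elif not (np.isfinite(vals["dS"]) and np.isfinite(vals["dN"])):
        valid, reason = False, "jc_domain"
    elif vals["dS"] == 0.0:
        valid, reason = False, "ds_zero"
    return DivergenceEstimate(
        gene_id=gene_id,
        Sd=vals["Sd"], Nd=vals["Nd"], S=vals["S"], N=vals["N"],
        pS=vals["pS"], pN=vals["pN"], dS=vals["dS"], dN=vals["dN"],
        omega=vals["omega"],
        n_codons_used=vals["n_codons_used"],
        aligned_bases=ab,
        valid=valid,
        reason=reason,
    )


def estimate_pairwise(
    g: GeneAlignment,
    pair: tuple[str, str],
    min_aligned: int = MIN_ALIGNED_BASES,
) -> DivergenceEstimate:
    """Pairwise NG86/JC divergence for one gene and species pair.

    Codon columns containing any gap or ambiguity in either species are
    skipped entirely.  ``aligned_bases`` follows the column definition
    (neither species gapped), which is what the inclusion threshold tests.
    """
    ab = aligned_bases(g, pair)
    prof = codon_profile(g, pair)
    vals = prof.estimate()
    return _finish(g.gene_id, vals, ab, min_aligned, g.internal_stop)
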