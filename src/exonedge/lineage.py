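"""Lineage-specific per-branch dN/dS on a 3-taxon trio.

The single internal node of the unrooted tree ((ingroup1, ingroup2),
outgroup) is inferred per codon column by parsimony over the 61 sense
codons (branch cost = nucleotide Hamming distance).  Branch difference
counts average uniformly over tied most-parsimonious ancestors; per-branch
site counts come from the tip sequence's codons.  The branch filters
follow the dS < 0.02, dS > 2, dN > 2 rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import TrioAlignment
from .genetic_code import (
    HAMMING,
    N_SITES,
    ND_TABLE,
    S_SITES,
    SD_TABLE,
    SENSE_CODONS,
    SENSE_INDICES,
    jukes_cantor,
)
from .pairwise import MIN_ALIGNED_BASES

DS_MIN = 0.02
DS_MAX = 2.0
DN_MAX = 2.0

_HAM_SENSE = HAMMING[SENSE_INDICES, :]  # (61, 64)
_SD_SENSE = SD_TABLE[SENSE_INDICES, :]
_ND_SENSE = ND_TABLE[SENSE_INDICES, :]


@dataclass
class BranchEstimate:
    gene_id: str
    branch: str
    Sd: float
    Nd: float
    S: float
    N: float
    dS: float
    dN: float
    omega: float
    valid: bool
    reason: str  # ok | dS_low | dS_high | dN_high | too_short | undefined


def _usable_columns(t: TrioAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Encoded tip codons (3, L) and the mask of gap-free sense columns."""
    tips = np.stack([t.species_codons(sp) for sp in TrioAlignment.BRANCHES])
    ok = (tips >= 0).all(axis=0)
    ok &= np.isfinite(S_SITES[np.where(tips >= 0, tips, 0)]).all(axis=0)
    return tips, ok


def infer_ancestral_codons(t: TrioAlignment) -> list[frozenset[str] | None]:
    """Per codon column, the set of most-parsimonious internal-node codons.

    Columns with a gap or ambiguity in any species yield ``None``
    (skipped).  Ancestor candidates are restricted to sense codons.
    """
    tips, ok = _usable_columns(t)
    out: list[frozenset[str] | None] = []
    for j in range(tips.shape[1]):
        if not ok[j]:
            out.append(None)
            continue
        cost = (
            _HAM_SENSE[:, tips[0, j]]
            + _HAM_SENSE[:, tips[1, j]]
            + _HAM_SENSE[:, tips[2, j]]
        )
        m = cost.min()
        out.append(frozenset(SENSE_CODONS[i] for i in np.flatnonzero(cost == m)))
    return out


def branch_counts(t: TrioAlignment) -> dict[str, dict[str, float]]:
    """Per-branch summed Sd/Nd (tie-averaged) and S/N site counts."""
    tips, ok = _usable_columns(t)
    idx = np.flatnonzero(ok)
    result = {
        br: {"Sd": 0.0, "Nd": 0.0, "S": 0.0, "N": 0.0}
        for br in TrioAlignment.BRANCHES
    }
    if idx.size == 0:
        return result
    a, b, c = (tips[k][idx] for k in range(3))
    cost = _HAM_SENSE[:, a] + _HAM_SENSE[:, b] + _HAM_SENSE[:, c]  # (61, L)
    is_min = cost == cost.min(axis=0, keepdims=True)
    weights = is_min / is_min.sum(axis=0, keepdims=True)
    for br, tip in zip(TrioAlignment.BRANCHES, (a, b, c)):
        result[br]["Sd"] = float((weights * _SD_SENSE[:, tip]).sum())
        result[br]["Nd"] = float((weights * _ND_SENSE[:, tip]).sum())
        result[br]["S"] = float(S_SITES[tip].sum())
        result[br]["N"] = float(N_SITES[tip].sum())
    return result


def classify_branch(
    dS: float,
    dN: float,
    ds_min: float = DS_MIN,
    ds_max: float = DS_MAX,
    dn_max: float = DN_MAX,
) -> str:
    """Filter verdict for one branch's corrected rates."""
    if not (np.isfinite(dS) and np.isfinite(dN)):
        return "undefined"
    if dS < ds_min:
        return "dS_low"
    if dS > ds_max:
        return "dS_high"
    if dN > dn_max:
        return "dN_high"
    return "ok"


def estimate_lineage(
    t: TrioAlignment,
    min_aligned: int = MIN_ALIGNED_BASES,
    ds_min: float = DS_MIN,
    ds_max: float = DS_MAX,
    dn_max: float = DN_MAX,
) -> dict[str, BranchEstimate]:
    """Per-branch JC-corrected rates with the branch filters applied.

    The sequence-length rule is assessed on the columns actually used
    (gap-free, unambiguous in all three species; 3 bases per codon).
    """
    counts = branch_counts(t)
    tips, ok = _usable_columns(t)
    used_bases = 3 * int(ok.sum())
    out: dict[str, BranchEstimate] = {}
    for br in TrioAlignment.BRANCHES:
        cc = counts[br]
        pS = cc["Sd"] / cc["S"] if cc["S"] > 0 else float("nan")
        pN = cc["Nd"] / cc["N"] if cc["N"] > 0 else float("nan")
        dS = jukes_cantor(pS) if np.isfinite(pS) else float("nan")
        dN = jukes_cantor(pN) if np.isfinite(pN) else float("nan")
        omega = dN / dS if np.isfinite(dN) and np.isfinite(dS) and dS > 0 else float("nan")
        if t.internal_stop or used_bases < min_aligned:
            valid, reason = False, "too_short"
        else:
            reason = classify_branch(dS, dN, ds_min, ds_max, dn_max)
            valid = reason == "ok"
        out[br] = BranchEstimate(
            gene_id=t.gene_id, branch=br,
            Sd=cc["Sd"], Nd=cc["Nd"], S=cc["S"], N=cc["N"],
            dS=dS, dN=dN, omega=omega, valid=valid, reason=reason,
        )
    return out
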