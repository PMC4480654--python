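"""Standard genetic code and Nei–Gojobori-style counting tables.

Codons are encoded as integers ``16*i(b1) + 4*i(b2) + i(b3)`` with base order
``TCAG``; ``-1`` marks any triplet containing a gap or ambiguity character.
Lookup tables covering all 64 codons are built once at import time:

``S_SITES``/``N_SITES``
    Expected synonymous / non-synonymous site counts per codon (NaN for
    stop codons).  Mutations creating stop codons count as non-synonymous.
``SD_TABLE``/``ND_TABLE``
    Synonymous / non-synonymous difference counts between codon pairs,
    averaged over all orderings of single-nucleotide mutational pathways.
    Pathways passing through a stop codon are excluded; if every pathway
    does, the average falls back to all pathways with each step classified
    by the code (a step to or from a stop is a protein-altering change).
``HAMMING``
    Nucleotide Hamming distance between codons (0–3).
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

BASES = "TCAG"
GAP = "-"

# Standard code in TCAG nested order (TTT, TTC, TTA, TTG, TCT, ...).
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

CODONS: list[str] = [a + b + c for a in BASES for b in BASES for c in BASES]
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
AMINO_ACID: dict[str, str] = dict(zip(CODONS, _AA))
STOP_CODONS = frozenset(c for c in CODONS if AMINO_ACID[c] == "*")
SENSE_CODONS: list[str] = [c for c in CODONS if c not in STOP_CODONS]
SENSE_INDICES = np.array([CODON_INDEX[c] for c in SENSE_CODONS], dtype=np.intp)


class CodonError(ValueError):
    """A codon outside the operation's domain (stop, gap, or ambiguity)."""


def is_sense(codon: str) -> bool:
    return AMINO_ACID.get(codon, "*") != "*"


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; ``*`` for stops."""
    try:
        return AMINO_ACID[codon]
    except KeyError:
        raise CodonError(f"not an unambiguous codon: {codon!r}") from None


def encode_codon(codon: str) -> int:
    """Integer encoding in [0, 64), or -1 for gapped/ambiguous triplets."""
    return CODON_INDEX.get(codon, -1)


def encode_codons(seq: str) -> np.ndarray:
    """Encode a (gap-free or gapped) nucleotide string codon-wise.

    The string is chunked into consecutive triplets; any triplet that is
    not one of the 64 unambiguous codons (gaps, IUPAC ambiguity codes,
    lowercase leftovers) encodes as -1.
    """
    n = len(seq) // 3
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        out[i] = CODON_INDEX.get(seq[3 * i : 3 * i + 3], -1)
    return out


def _site_counts(codon: str) -> float:
    """Synonymous site count: per position, syn neighbours / 3, summed."""
    aa = AMINO_ACID[codon]
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if AMINO_ACID[nb] == aa:  # stop neighbours translate to '*'
                s += 1.0
    return s / 3.0


def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, pathway-averaged."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    clean: list[tuple[float, float]] = []
    everything: list[tuple[float, float]] = []
    for order in permutations(diff):
        cur = a
        sd = nd = 0.0
        through_stop = False
        for step, pos in enumerate(order):
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if AMINO_ACID[cur] == AMINO_ACID[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            if step < len(order) - 1 and nxt in STOP_CODONS:
                through_stop = True
            cur = nxt
        everything.append((sd, nd))
        if not through_stop:
            clean.append((sd, nd))
    paths = clean if clean else everything
    return (
        float(np.mean([p[0] for p in paths])),
        float(np.mean([p[1] for p in paths])),
    )


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    s_sites = np.full(64, np.nan)
    n_sites = np.full(64, np.nan)
    for c in SENSE_CODONS:
        i = CODON_INDEX[c]
        s_sites[i] = _site_counts(c)
        n_sites[i] = 3.0 - s_sites[i]
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    ham = np.zeros((64, 64), dtype=np.int64)
    for ca in CODONS:
        ia = CODON_INDEX[ca]
        for cb in CODONS:
            ib = CODON_INDEX[cb]
            ham[ia, ib] = sum(x != y for x, y in zip(ca, cb))
            if ca in STOP_CODONS or cb in STOP_CODONS:
                continue
            sd[ia, ib], nd[ia, ib] = _pathway_counts(ca, cb)
    return s_sites, n_sites, sd, nd, ham


S_SITES, N_SITES, SD_TABLE, ND_TABLE, HAMMING = _build_tables()


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); NaN outside [0, 3/4)."""
    if p < 0.0 or p >= 0.75:
        return float("nan")
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))
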