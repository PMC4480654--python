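"""Transcript-number-normalized alternative-splicing index.

EST intron chains (sorted intron intervals in gene-local coordinates,
with the EST's mapped extent) are compared pairwise over their shared
extent.  Two chains provide evidence of alternative splicing when an
intron of one overlaps but mismatches an intron of the other (alternative
boundaries), or when one chain is exonic across an interval the other
splices out (retention-type), judged only within both mapped extents.

To remove transcript-coverage bias the per-gene index is the mean event
count over repeated uniform subsamples of the mapped ESTs (by default
100 samples of 10), so genes with many ESTs are not credited with more
events merely for being better sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

EST_COLUMNS = [
    "gene_id", "est_id", "intron_start", "intron_end",
    "est_extent_start", "est_extent_end",
]


@dataclass(frozen=True)
class EstChain:
    """One EST's intron chain; intervals half-open, sorted, non-overlapping."""

    gene_id: str
    est_id: str
    introns: tuple[tuple[int, int], ...]
    extent: tuple[int, int]

    def __post_init__(self) -> None:
        prev = -1
        for s, e in self.introns:
            if s >= e:
                raise ValueError(f"{self.est_id}: empty intron ({s}, {e})")
            if s < prev:
                raise ValueError(f"{self.est_id}: introns unsorted/overlapping")
            prev = e


@dataclass
class SplicingIndex:
    gene_id: str
    n_ests: int
    index: float
    n_resamples: int
    sample_size: int
    seed: int | None = None
    excluded: bool = False


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def count_as_events(chains: list[EstChain]) -> int:
    """Distinct alternative-splicing event signatures among a set of chains.

    A boundary-mismatch between two overlapping introns counts once as
    the unordered interval pair; an intron spliced by one chain but
    covered exonically by another (within the other's extent) counts once
    per intron interval.  Absence of evidence outside an EST's mapped
    extent is not evidence of constitutive splicing.
    """
    if len(chains) < 2:
        raise ValueError("count_as_events requires >= 2 chains")
    signatures: set[tuple] = set()
    for ca, cb in combinations(chains, 2):
        if not _overlap(ca.extent, cb.extent):
            continue
        lo = max(ca.extent[0], cb.extent[0])
        hi = min(ca.extent[1], cb.extent[1])
        for one, other in ((ca, cb), (cb, ca)):
            for intron in one.introns:
                if not (lo <= intron[0] and intron[1] <= hi):
                    continue  # not fully inside the shared extent
                partners = [j for j in other.introns if _overlap(intron, j)]
                if partners:
                    for j in partners:
                        if j != intron:
                            signatures.add(("boundary", *sorted((intron, j))))
                else:
                    signatures.add(("retention", intron))
    return len(signatures)


def splicing_index(
    chains: list[EstChain],
    sample_size: int = 10,
    n_resamples: int = 100,
    rng: np.random.Generator | None = None,
) -> SplicingIndex:
    """Mean event count over uniform without-replacement EST subsamples.

    Genes with fewer mapped ESTs than ``sample_size`` are excluded
    (flagged) rather than scored on a biased sample.
    """
    gene_id = chains[0].gene_id if chains else ""
    n = len(chains)
    if n < sample_size:
        return SplicingIndex(gene_id, n, float("nan"), n_resamples, sample_size,
                             excluded=True)
    rng = rng if rng is not None else np.random.default_rng()
    total = 0.0
    for _ in range(n_resamples):
        pick = rng.choice(n, size=sample_size, replace=False)
        total += count_as_events([chains[i] for i in pick])
    return SplicingIndex(gene_id, n, total / n_resamples, n_resamples, sample_size)


def read_est_chains(path: str | Path) -> dict[str, list[EstChain]]:
    """EST table TSV -> per-gene chain lists.

    One row per intron; ESTs with no intron carry a single row with empty
    intron fields (NaN).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in EST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"EST table {path}: missing columns {missing}")
    out: dict[str, list[EstChain]] = {}
    for (gene, est), rows in df.groupby(["gene_id", "est_id"], sort=True):
        introns = tuple(
            (int(s), int(e))
            for s, e in zip(rows["intron_start"], rows["intron_end"])
            if pd.notna(s) and pd.notna(e)
        )
        extent = (int(rows["est_extent_start"].iloc[0]), int(rows["est_extent_end"].iloc[0]))
        out.setdefault(str(gene), []).append(
            EstChain(str(gene), str(est), tuple(sorted(introns)), extent)
        )
    return out


def est_chain_frame(chains: list[EstChain]) -> pd.DataFrame:
    rows = []
    for c in chains:
        if c.introns:
            for s, e in c.introns:
                rows.append((c.gene_id, c.est_id, s, e, *c.extent))
        else:
            rows.append((c.gene_id, c.est_id, np.nan, np.nan, *c.extent))
    return pd.DataFrame(rows, columns=EST_COLUMNS)
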