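"""Exon-edge codon removal and the matched-randomization test.

For each gene, codons are removed sequentially from the edges of every
eligible exon (fully aligned, in frame, a multiple of three in length),
and in parallel the *same number* of codons is removed uniformly at
random from the concatenated eligible-exon alignment.  Per-gene
statistics (dN, dS, dN/dS, NI) or cross-gene correlation strengths are
recomputed under both treatments; the empirical p-value

    p = (s - q + 1) / (s + 1)

counts the ``s`` random replicates against the sequential estimate
(q = replicates where sequential > random for dN/dS/omega, < for NI;
ties never increment q).  One shared random-removal stream per gene is
reused across statistics within a replicate so their nulls are paired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import ExonBlock, GeneAlignment, SnpRecord, concatenate_blocks, select_codons
from .pairwise import MIN_ALIGNED_BASES, CodonProfile, codon_profile
from .polymorphism import NON_SYNONYMOUS, SYNONYMOUS, classify_snp, neutrality_index

BOTH_EDGES = "both_edges"
INTERNAL_EDGES_ONLY = "internal_edges_only"

HIGHER_IS_EXTREME = frozenset({"dN", "dS", "omega"})
LOWER_IS_EXTREME = frozenset({"NI"})


@dataclass(frozen=True)
class TrimSpec:
    """Edge-removal settings: k codons per trimmed edge of each eligible exon."""

    k: int
    mode: str = BOTH_EDGES
    min_post_trim_bases: int = MIN_ALIGNED_BASES

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.mode not in (BOTH_EDGES, INTERNAL_EDGES_ONLY):
            raise ValueError(f"unknown trim mode {self.mode!r}")


@dataclass
class RandomizationResult:
    unit: str
    statistic: str
    observed_sequential: float
    null_values: np.ndarray
    q: int
    p: float
    s: int
    seed: int | None = None
    unreliable: bool = False


def eligible_exons(g: GeneAlignment, spec: TrimSpec | None = None) -> list[ExonBlock]:
    """Blocks that are fully aligned, in frame, and a multiple of three."""
    return [
        b
        for b in g.exon_blocks
        if b.fully_aligned and b.in_frame and b.multiple_of_three
    ]


def _sequential_keep(blocks: list[ExonBlock], spec: TrimSpec) -> np.ndarray:
    """Concatenated-coordinate codon indices kept after edge removal."""
    keep: list[np.ndarray] = []
    last = len(blocks) - 1
    for i, b in enumerate(blocks):
        lo, hi = b.codon_start, b.codon_end
        if spec.mode == BOTH_EDGES:
            trim5 = trim3 = spec.k
        else:  # terminal gene edges exempt: splice enhancers flank introns
            trim5 = 0 if i == 0 else spec.k
            trim3 = 0 if i == last else spec.k
        lo2, hi2 = lo + trim5, hi - trim3
        if lo2 < hi2:
            keep.append(np.arange(lo2, hi2))
    if not keep:
        return np.empty(0, dtype=np.intp)
    return np.concatenate(keep).astype(np.intp)


def concat_eligible(g: GeneAlignment) -> GeneAlignment | None:
    """Concatenation of the gene's eligible exons (None if there are none).

    All trimmed/untrimmed/random estimates for a gene are made on this
    same exon set so treatments stay comparable.
    """
    blocks = eligible_exons(g)
    if not blocks:
        return None
    return concatenate_blocks(g, blocks)


def trim_edges(g: GeneAlignment, spec: TrimSpec) -> GeneAlignment | None:
    """Sequential edge removal over the eligible-exon concatenation.

    Returns None when no eligible exon remains or no codon survives;
    callers must additionally check the post-trim minimum-length rule
    against ``spec.min_post_trim_bases``.
    """
    base = concat_eligible(g)
    if base is None:
        return None
    keep = _sequential_keep(base.exon_blocks, spec)
    if keep.size == 0:
        return None
    return select_codons(base, keep)


def random_trim(
    g: GeneAlignment, n_remove: int, rng: np.random.Generator
) -> GeneAlignment:
    """Remove ``n_remove`` codon columns uniformly without replacement."""
    n = g.n_codons
    if n_remove > n:
        raise ValueError(f"{g.gene_id}: cannot remove {n_remove} of {n} codons")
    if n_remove == 0:
        return g
    drop = rng.choice(n, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(n), drop)
    return select_codons(g, keep)


@dataclass
class GeneTrimProfile:
    """Everything needed to re-estimate one gene under any codon subset.

    Built once per gene: NG86 per-codon count arrays on the eligible-exon
    concatenation, per-codon polymorphism counts (classified against the
    original reference), and the sequential-removal keep set.
    """

    gene_id: str
    profile: CodonProfile
    seq_keep: np.ndarray
    n_codons: int
    min_post_trim_bases: int
    ps_codon: np.ndarray | None = None
    pn_codon: np.ndarray | None = None
    log_base: float = math.e

    @property
    def n_remove(self) -> int:
        return self.n_codons - self.seq_keep.size

    @property
    def eligible(self) -> bool:
        return 3 * self.seq_keep.size >= self.min_post_trim_bases

    def statistics(self, idx: np.ndarray, which: tuple[str, ...]) -> dict[str, float]:
        vals = self.profile.estimate(idx)
        out: dict[str, float] = {}
        for stat in which:
            if stat in ("dN", "dS", "omega"):
                out[stat] = vals[stat]
            elif stat == "NI":
                if self.ps_codon is None:
                    out[stat] = float("nan")
                else:
                    out[stat] = neutrality_index(
                        vals["Sd"], vals["Nd"],
                        float(self.ps_codon[idx].sum()),
                        float(self.pn_codon[idx].sum()),
                        self.log_base,
                    )
            else:
                raise ValueError(f"unknown statistic {stat!r}")
        return out


def build_trim_profile(
    g: GeneAlignment,
    spec: TrimSpec,
    pair: tuple[str, str],
    snps: list[SnpRecord] | None = None,
    log_base: float = math.e,
) -> GeneTrimProfile | None:
    base = concat_eligible(g)
    if base is None:
        return None
    prof = codon_profile(base, pair)
    seq_keep = _sequential_keep(base.exon_blocks, spec)
    ps = pn = None
    if snps is not None:
        ps = np.zeros(base.n_codons)
        pn = np.zeros(base.n_codons)
        pos_of = {int(c): i for i, c in enumerate(base.source_codons)}
        for snp in snps:
            if snp.gene_id != g.gene_id:
                continue
            j = pos_of.get(snp.cds_position // 3)
            if j is None:
                continue
            cls = classify_snp(g, snp)
            if cls == SYNONYMOUS:
                ps[j] += 1
            elif cls == NON_SYNONYMOUS:
                pn[j] += 1
    return GeneTrimProfile(
        gene_id=g.gene_id,
        profile=prof,
        seq_keep=seq_keep,
        n_codons=base.n_codons,
        min_post_trim_bases=spec.min_post_trim_bases,
        ps_codon=ps,
        pn_codon=pn,
        log_base=log_base,
    )


def _empirical_p(obs: float, nulls: np.ndarray, statistic: str) -> tuple[int, float, bool]:
    finite = nulls[np.isfinite(nulls)]
    s_valid = finite.size
    unreliable = s_valid < 0.9 * nulls.size or not np.isfinite(obs)
    if s_valid == 0 or not np.isfinite(obs):
        return 0, float("nan"), True
    if statistic in LOWER_IS_EXTREME:
        q = int((obs < finite).sum())
    else:
        q = int((obs > finite).sum())
    return q, (s_valid - q + 1) / (s_valid + 1), unreliable


def randomization_test(
    g: GeneAlignment,
    spec: TrimSpec,
    statistics: tuple[str, ...] = ("dN", "dS", "omega"),
    s: int = 1000,
    rng: np.random.Generator | None = None,
    pair: tuple[str, str] | None = None,
    snps: list[SnpRecord] | None = None,
    log_base: float = math.e,
) -> dict[str, RandomizationResult] | None:
    """Per-gene sequential-vs-random removal test for each statistic.

    Returns None when the gene has no eligible exon or fails the
    post-trim minimum-length rule.  All statistics share the same random
    removal sets replicate by replicate.
    """
    if pair is None:
        pair = tuple(g.species)[:2]  # type: ignore[assignment]
    rng = rng if rng is not None else np.random.default_rng()
    tp = build_trim_profile(g, spec, pair, snps=snps, log_base=log_base)
    if tp is None or not tp.eligible:
        return None
    m = tp.seq_keep.size
    observed = tp.statistics(tp.seq_keep, statistics)
    nulls = {stat: np.empty(s) for stat in statistics}
    all_idx = np.arange(tp.n_codons)
    for r in range(s):
        keep = rng.choice(tp.n_codons, size=m, replace=False) if m < tp.n_codons else all_idx
        vals = tp.statistics(keep, statistics)
        for stat in statistics:
            nulls[stat][r] = vals[stat]
    out = {}
    for stat in statistics:
        q, p, bad = _empirical_p(observed[stat], nulls[stat], stat)
        out[stat] = RandomizationResult(
            unit=g.gene_id, statistic=stat,
            observed_sequential=observed[stat],
            null_values=nulls[stat], q=q, p=p, s=s, unreliable=bad,
        )
    return out


def rho_randomization(
    profiles: list[GeneTrimProfile],
    covariate: np.ndarray,
    statistic: str = "omega",
    s: int = 1000,
    rng: np.random.Generator | None = None,
) -> RandomizationResult:
    """Randomization test on a cross-gene Spearman correlation strength.

    ``covariate`` is aligned with ``profiles``.  The observed value is
    Spearman's rho between the covariate and the sequentially trimmed
    statistic; each null replicate randomly trims every gene once and
    recomputes rho.  q counts replicates where |rho_sequential| <
    |rho_random| (correlation attenuation), so small p flags attenuation
    beyond what matched random removal produces.
    """
    from scipy import stats as sps

    rng = rng if rng is not None else np.random.default_rng()
    cov = np.asarray(covariate, dtype=float)
    usable = [
        (tp, c)
        for tp, c in zip(profiles, cov)
        if tp is not None and tp.eligible and np.isfinite(c)
    ]
    if len(usable) < 30:
        raise ValueError(f"need >= 30 eligible genes, got {len(usable)}")
    kept_profiles = [tp for tp, _ in usable]
    kept_cov = np.array([c for _, c in usable])
    if np.unique(kept_cov).size < 2:
        raise ValueError("degenerate (constant) covariate")

    def rho_of(stat_values: np.ndarray) -> float:
        mask = np.isfinite(stat_values)
        if mask.sum() < 3 or np.unique(stat_values[mask]).size < 2:
            return float("nan")
        return float(sps.spearmanr(kept_cov[mask], stat_values[mask]).statistic)

    seq_vals = np.array(
        [tp.statistics(tp.seq_keep, (statistic,))[statistic] for tp in kept_profiles]
    )
    observed = rho_of(seq_vals)
    nulls = np.empty(s)
    for r in range(s):
        rv = np.empty(len(kept_profiles))
        for i, tp in enumerate(kept_profiles):
            m = tp.seq_keep.size
            keep = (
                rng.choice(tp.n_codons, size=m, replace=False)
                if m < tp.n_codons
                else np.arange(tp.n_codons)
            )
            rv[i] = tp.statistics(keep, (statistic,))[statistic]
        nulls[r] = rho_of(rv)
    finite = nulls[np.isfinite(nulls)]
    s_valid = finite.size
    q = int((abs(observed) < np.abs(finite)).sum())
    p = (s_valid - q + 1) / (s_valid + 1) if s_valid else float("nan")
    return RandomizationResult(
        unit=f"rho:{statistic}", statistic="rho",
        observed_sequential=observed, null_values=nulls,
        q=q, p=p, s=s,
        unreliable=s_valid < 0.9 * s or not np.isfinite(observed),
    )
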