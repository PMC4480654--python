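"""Ground-truth generator for orthologue trios with exon-edge constraint.

The generative model, per gene:

* exon structure — exon count ~ geometric (mean 5), exon lengths
  lognormal with median 53 codons, echoing a compact intron-rich plant
  genome; exons tile the CDS, no indels are simulated (alignment
  construction is upstream), so every block is fully aligned unless gap
  injection is switched on.
* root CDS — codons drawn uniformly from the 61 sense codons.
* divergence — along each of the three branches from the single internal
  node of ((ingroup1, ingroup2), outgroup), substitution *attempts* arrive
  as Poisson(rate x 3L); each attempt picks a uniform site and a uniform
  alternative base, attempts creating stops are rejected, synonymous
  attempts are accepted with probability phi(site) and non-synonymous
  attempts with probability omega_g x psi(site), where phi/psi drop from
  1 to the edge multipliers within ``edge_depth`` codons of an exon edge.
* expression — a Gaussian copula couples the per-gene latent expression
  level to omega_g at a configured Spearman correlation; tissue values
  are latent x tissue profile x lognormal noise.  In the default edge
  scenario the *extra* non-synonymous edge constraint scales with the
  gene's expression percentile (psi_g = psi_edge x (1 - coupling x u)),
  so edges of highly expressed genes are disproportionately conserved at
  protein-changing sites — the structure the edge-removal analysis is
  designed to detect.
* polymorphism — Ps ~ Poisson(theta_s x L) and Pn ~ Poisson(theta_n x L
  x omega_g) SNPs placed uniformly among single-base edits of the
  ingroup1 sequence with the required class (stop-touching edits
  excluded), so every record classifies consistently downstream.
* ESTs — a fraction of multi-exon genes carries a second isoform
  (alternative donor or intron retention); ESTs sample the isoform
  mixture with full-extent mapping.

All randomness flows from one master seed through per-gene derived
streams, so any gene's outputs are reproducible independently of
iteration order.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import (
    ExonBlock,
    SnpRecord,
    TrioAlignment,
    compute_block_flags,
    exon_map_frame,
    snp_frame,
    write_gene_alignment,
)
from .genetic_code import (
    AMINO_ACID,
    BASES,
    CODONS,
    ND_TABLE,
    SD_TABLE,
    SENSE_CODONS,
    STOP_CODONS,
    encode_codons,
)
from .splicing import EstChain, est_chain_frame


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic orthologue-trio dataset."""

    n_genes: int = 300
    # gene structure
    exon_count_mean: float = 5.0
    exon_length_median: float = 53.0  # codons
    exon_length_sigma: float = 0.6    # lognormal sigma (log scale)
    min_exon_codons: int = 2
    # branch expected substitution attempts per nucleotide site
    # (ingroup1, ingroup2, outgroup incl. stem)
    branch_rates: tuple[float, float, float] = (0.12, 0.12, 0.36)
    # gene-level non-synonymous acceptance omega_g ~ lognormal
    omega_median: float = 0.2
    omega_sigma: float = 0.6
    omega_fixed: float | None = None
    branch_omega_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # exon-edge constraint
    edge_depth: int = 10              # codons from each exon edge
    phi_edge: float = 0.3             # synonymous acceptance multiplier at edges
    psi_edge: float = 0.3             # non-synonymous acceptance multiplier at edges
    expression_edge_coupling: float = 1.0  # scales psi down with expression percentile
    # expression model
    n_tissues: int = 8
    expression_mu: float = 2.0        # log-abundance location
    expression_sigma: float = 1.0
    tissue_noise_sigma: float = 0.3
    expression_omega_rho: float = -0.4  # target Spearman(expression, omega_g)
    # polymorphism (expected SNPs per codon)
    theta_s: float = 0.03
    theta_n: float = 0.084            # theta_s x neutral nonsyn/syn edit ratio
    # ESTs / alternative splicing
    as_gene_fraction: float = 0.3
    est_mean: float = 15.0
    # alignment-artifact injection (exercises eligibility flags)
    gap_block_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for m in (self.phi_edge, self.psi_edge):
            if not 0 < m <= 1:
                raise ValueError("edge multipliers must lie in (0, 1]")
        if any(r < 0 for r in self.branch_rates):
            raise ValueError("branch rates must be non-negative")
        if abs(self.expression_omega_rho) > 0.95:
            raise ValueError("unreachable expression-omega correlation target")

    @staticmethod
    def neutral(n_genes: int = 300, **kw) -> "SimulationConfig":
        """No edge constraint, omega_g = 1, expression decoupled from rate."""
        return SimulationConfig(
            n_genes=n_genes,
            omega_fixed=1.0,
            edge_depth=0,
            expression_omega_rho=0.0,
            expression_edge_coupling=0.0,
            **kw,
        )


@dataclass
class GeneTruth:
    """Generator-side ground truth sufficient to recheck every estimator."""

    gene_id: str
    n_codons: int
    n_exons: int
    omega_g: float
    phi_edge_g: float
    psi_edge_g: float
    edge_flags: np.ndarray          # per-codon bool
    root_codons: list[str]
    branch_sd: dict[str, float]     # pathway recount root vs tip
    branch_nd: dict[str, float]
    branch_events_syn: dict[str, int]   # accepted substitution events
    branch_events_nonsyn: dict[str, int]
    expression_latent: float
    expression_percentile: float
    ps_true: int = 0
    pn_true: int = 0
    n_isoforms: int = 1


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    seed: int
    alignments: list[TrioAlignment]
    truth: list[GeneTruth]
    snps: list[SnpRecord]
    expression: pd.DataFrame
    est_chains: dict[str, list[EstChain]]


# per sense codon: qualifying single-base edits by class (stop edits excluded)
def _edit_tables() -> tuple[dict[str, list], dict[str, list]]:
    syn: dict[str, list] = {}
    non: dict[str, list] = {}
    for c in SENSE_CODONS:
        syn[c], non[c] = [], []
        for pos in range(3):
            for b in BASES:
                if b == c[pos]:
                    continue
                alt = c[:pos] + b + c[pos + 1 :]
                if alt in STOP_CODONS:
                    continue
                (syn[c] if AMINO_ACID[alt] == AMINO_ACID[c] else non[c]).append((pos, b))
    return syn, non


_SYN_EDITS, _NONSYN_EDITS = _edit_tables()


def _gene_rng(seed: int, stream: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, gene_index])


def _draw_structure(cfg: SimulationConfig, rng: np.random.Generator) -> list[int]:
    n_exons = int(rng.geometric(1.0 / cfg.exon_count_mean))
    lengths = np.exp(
        math.log(cfg.exon_length_median)
        + cfg.exon_length_sigma * rng.standard_normal(n_exons)
    )
    return [max(cfg.min_exon_codons, int(round(x))) for x in lengths]


def _edge_flags(exon_lengths: list[int], depth: int) -> np.ndarray:
    flags = []
    for L in exon_lengths:
        f = np.zeros(L, dtype=bool)
        if depth > 0:
            f[:depth] = True
            f[max(0, L - depth):] = True
        flags.append(f)
    return np.concatenate(flags)


def _evolve_branch(
    root: list[str],
    rate: float,
    omega_branch: float,
    phi_site: np.ndarray,
    psi_site: np.ndarray,
    rng: np.random.Generator,
) -> tuple[list[str], int, int]:
    """Attempt-and-accept substitution process along one branch."""
    seq = list(root)
    L = len(seq)
    n_att = int(rng.poisson(rate * 3 * L))
    syn_events = nonsyn_events = 0
    for _ in range(n_att):
        site = int(rng.integers(3 * L))
        ci, off = divmod(site, 3)
        codon = seq[ci]
        cur = codon[off]
        alt = BASES[int(rng.integers(4))]
        while alt == cur:
            alt = BASES[int(rng.integers(4))]
        cand = codon[:off] + alt + codon[off + 1 :]
        if cand in STOP_CODONS:
            continue
        if AMINO_ACID[cand] == AMINO_ACID[codon]:
            if rng.random() < phi_site[ci]:
                seq[ci] = cand
                syn_events += 1
        else:
            if rng.random() < min(1.0, omega_branch * psi_site[ci]):
                seq[ci] = cand
                nonsyn_events += 1
    return seq, syn_events, nonsyn_events


def _recount(root: list[str], tip: list[str]) -> tuple[float, float]:
    a = encode_codons("".join(root))
    b = encode_codons("".join(tip))
    return float(SD_TABLE[a, b].sum()), float(ND_TABLE[a, b].sum())


def simulate_gene(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    gene_id: str = "g0",
    omega_g: float | None = None,
    expression_percentile: float = 0.5,
    expression_latent: float = 1.0,
) -> tuple[TrioAlignment, GeneTruth]:
    """One trio alignment plus its truth record.

    ``omega_g`` defaults to a draw from the configured lognormal;
    expression inputs come from the dataset-level copula when called via
    :func:`simulate_dataset`.
    """
    if omega_g is None:
        omega_g = (
            cfg.omega_fixed
            if cfg.omega_fixed is not None
            else float(
                np.exp(math.log(cfg.omega_median) + cfg.omega_sigma * rng.standard_normal())
            )
        )
    exon_lengths = _draw_structure(cfg, rng)
    L = int(sum(exon_lengths))
    edge = _edge_flags(exon_lengths, cfg.edge_depth)

    phi_g = cfg.phi_edge
    psi_g = cfg.psi_edge * max(
        0.02, 1.0 - cfg.expression_edge_coupling * expression_percentile
    )
    phi_site = np.where(edge, phi_g, 1.0)
    psi_site = np.where(edge, psi_g, 1.0)

    root = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=L)]
    tips: dict[str, list[str]] = {}
    ev_s: dict[str, int] = {}
    ev_n: dict[str, int] = {}
    b_sd: dict[str, float] = {}
    b_nd: dict[str, float] = {}
    for br, rate, scale in zip(
        TrioAlignment.BRANCHES, cfg.branch_rates, cfg.branch_omega_scale
    ):
        tip, s_ev, n_ev = _evolve_branch(
            root, rate, omega_g * scale, phi_site, psi_site, rng
        )
        tips[br] = tip
        ev_s[br], ev_n[br] = s_ev, n_ev
        b_sd[br], b_nd[br] = _recount(root, tip)

    blocks, pos = [], 0
    for i, ln in enumerate(exon_lengths):
        blocks.append(ExonBlock(exon_index=i, codon_start=pos, codon_end=pos + ln))
        pos += ln
    sequences = {br: "".join(tips[br]) for br in TrioAlignment.BRANCHES}
    if cfg.gap_block_fraction > 0:
        for i, b in enumerate(blocks):
            if rng.random() < cfg.gap_block_fraction:
                ci = int(rng.integers(b.codon_start, b.codon_end))
                s = sequences[TrioAlignment.INGROUP2]
                sequences[TrioAlignment.INGROUP2] = (
                    s[: 3 * ci] + "---" + s[3 * ci + 3 :]
                )
    trio = TrioAlignment(
        gene_id=gene_id,
        reference_species=TrioAlignment.INGROUP1,
        sequences=sequences,
        exon_blocks=blocks,
    )
    trio.exon_blocks = compute_block_flags(trio)
    truth = GeneTruth(
        gene_id=gene_id,
        n_codons=L,
        n_exons=len(exon_lengths),
        omega_g=float(omega_g),
        phi_edge_g=phi_g,
        psi_edge_g=psi_g,
        edge_flags=edge,
        root_codons=root,
        branch_sd=b_sd,
        branch_nd=b_nd,
        branch_events_syn=ev_s,
        branch_events_nonsyn=ev_n,
        expression_latent=float(expression_latent),
        expression_percentile=float(expression_percentile),
    )
    return trio, truth


def simulate_polymorphism(
    cfg: SimulationConfig,
    trio: TrioAlignment,
    truth: GeneTruth,
    rng: np.random.Generator,
) -> list[SnpRecord]:
    """SNPs on the ingroup1 (reference) CDS, consistent with classify_snp."""
    cds = trio.ungapped(TrioAlignment.INGROUP1)
    L = len(cds) // 3
    syn_edits: list[tuple[int, str, str]] = []
    non_edits: list[tuple[int, str, str]] = []
    for ci in range(L):
        codon = cds[3 * ci : 3 * ci + 3]
        for pos, alt in _SYN_EDITS.get(codon, ()):
            syn_edits.append((3 * ci + pos, codon[pos], alt))
        for pos, alt in _NONSYN_EDITS.get(codon, ()):
            non_edits.append((3 * ci + pos, codon[pos], alt))
    n_s = min(int(rng.poisson(cfg.theta_s * L)), len(syn_edits))
    n_n = min(int(rng.poisson(cfg.theta_n * L * truth.omega_g)), len(non_edits))
    records = []
    for pool, k in ((syn_edits, n_s), (non_edits, n_n)):
        if k > 0:
            for i in rng.choice(len(pool), size=k, replace=False):
                pos, ref, alt = pool[int(i)]
                records.append(SnpRecord(trio.gene_id, pos, ref, alt))
    truth.ps_true, truth.pn_true = n_s, n_n
    return records


def _copula_draws(
    cfg: SimulationConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(omega_g, expression latent, expression percentile) for n genes.

    A bivariate Gaussian copula with r = 2 sin(pi rho_s / 6) hits the
    requested Spearman correlation exactly in expectation; both margins
    are lognormal via their own quantile transforms.
    """
    r = 2.0 * math.sin(math.pi * cfg.expression_omega_rho / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    z_omega, z_expr = z[:, 0], z[:, 1]
    if cfg.omega_fixed is not None:
        omega = np.full(n, cfg.omega_fixed)
    else:
        omega = np.exp(math.log(cfg.omega_median) + cfg.omega_sigma * z_omega)
    latent = np.exp(cfg.expression_mu + cfg.expression_sigma * z_expr)
    percentile = stats.norm.cdf(z_expr)
    return omega, latent, percentile


def simulate_expression(
    cfg: SimulationConfig,
    gene_ids: list[str],
    latent: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Tissue matrix: latent x per-gene tissue profile x lognormal noise."""
    n, t = len(gene_ids), cfg.n_tissues
    if t == 1 and cfg.tissue_noise_sigma == 0:
        vals = latent[:, None].copy()
    else:
        kappa = rng.uniform(0.0, 2.0, size=n)  # per-gene tissue specificity
        profile = np.exp(kappa[:, None] * rng.standard_normal((n, t)))
        profile /= profile.mean(axis=1, keepdims=True)
        noise = np.exp(cfg.tissue_noise_sigma * rng.standard_normal((n, t)))
        vals = latent[:, None] * profile * noise
    return pd.DataFrame(vals, index=pd.Index(gene_ids, name="gene_id"),
                        columns=[f"tissue_{i}" for i in range(t)])


def simulate_est_chains(
    cfg: SimulationConfig,
    trio: TrioAlignment,
    truth: GeneTruth,
    rng: np.random.Generator,
) -> list[EstChain]:
    """EST intron chains from a 1- or 2-isoform mixture, full-extent mapped."""
    # gene-local nucleotide layout: exon blocks with simulated intron lengths
    introns: list[tuple[int, int]] = []
    pos = 0
    for b in trio.exon_blocks:
        pos += 3 * b.n_codons
        if b is not trio.exon_blocks[-1]:
            ilen = int(rng.integers(80, 500))
            introns.append((pos, pos + ilen))
            pos += ilen
    extent = (0, pos)
    isoforms: list[tuple[tuple[int, int], ...]] = [tuple(introns)]
    if introns and rng.random() < cfg.as_gene_fraction:
        j = int(rng.integers(len(introns)))
        alt = list(introns)
        if rng.random() < 0.5:
            s, e = alt[j]
            alt[j] = (s + 9, e)  # alternative donor site 9 nt into the exon
        else:
            del alt[j]           # intron retention
        isoforms.append(tuple(alt))
    truth.n_isoforms = len(isoforms)
    n_ests = int(rng.poisson(cfg.est_mean))
    chains = []
    for k in range(n_ests):
        iso = isoforms[int(rng.integers(len(isoforms)))]
        chains.append(EstChain(trio.gene_id, f"{trio.gene_id}_est{k}", iso, extent))
    return chains


def simulate_dataset(cfg: SimulationConfig, seed: int) -> SimulatedDataset:
    """The full synthetic dataset: trios, truth, SNPs, expression, ESTs."""
    omega, latent, pct = _copula_draws(cfg, cfg.n_genes, _gene_rng(seed, 4, 0))
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    alignments, truths, snps = [], [], []
    est_chains: dict[str, list[EstChain]] = {}
    for i, gid in enumerate(gene_ids):
        trio, truth = simulate_gene(
            cfg,
            _gene_rng(seed, 1, i),
            gene_id=gid,
            omega_g=float(omega[i]),
            expression_percentile=float(pct[i]),
            expression_latent=float(latent[i]),
        )
        snps.extend(simulate_polymorphism(cfg, trio, truth, _gene_rng(seed, 2, i)))
        chains = simulate_est_chains(cfg, trio, truth, _gene_rng(seed, 3, i))
        if chains:
            est_chains[gid] = chains
        alignments.append(trio)
        truths.append(truth)
    expression = simulate_expression(cfg, gene_ids, latent, _gene_rng(seed, 5, 0))
    return SimulatedDataset(cfg, seed, alignments, truths, snps, expression, est_chains)


def _truth_frame(truths: list[GeneTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        row = {
            "gene_id": t.gene_id,
            "n_codons": t.n_codons,
            "n_exons": t.n_exons,
            "omega_g": t.omega_g,
            "phi_edge_g": t.phi_edge_g,
            "psi_edge_g": t.psi_edge_g,
            "edge_codons": int(t.edge_flags.sum()),
            "expression_latent": t.expression_latent,
            "expression_percentile": t.expression_percentile,
            "ps_true": t.ps_true,
            "pn_true": t.pn_true,
            "n_isoforms": t.n_isoforms,
        }
        for br in ("ingroup1", "ingroup2", "outgroup"):
            row[f"sd_{br}"] = t.branch_sd[br]
            row[f"nd_{br}"] = t.branch_nd[br]
        rows.append(row)
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6f")


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> None:
    """Emit the dataset in the pipeline's on-disk dialect.

    alignments/<gene>.fasta, exon_map.tsv, snps.tsv, expression.tsv,
    est_chains.tsv, truth.tsv, config.json — every table header records
    the master seed.
    """
    out = Path(out_dir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    for g in ds.alignments:
        write_gene_alignment(g, out / "alignments" / f"{g.gene_id}.fasta")
    _write_tsv(exon_map_frame(ds.alignments), out / "exon_map.tsv", ds.seed)
    _write_tsv(snp_frame(ds.snps), out / "snps.tsv", ds.seed)
    _write_tsv(ds.expression, out / "expression.tsv", ds.seed, index=True)
    all_chains = [c for chains in ds.est_chains.values() for c in chains]
    _write_tsv(est_chain_frame(all_chains), out / "est_chains.tsv", ds.seed)
    _write_tsv(_truth_frame(ds.truth), out / "truth.tsv", ds.seed)
    with open(out / "config.json", "w") as fh:
        json.dump({"seed": ds.seed, **asdict(ds.config)}, fh, indent=2)
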