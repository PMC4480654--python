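"""Generator contracts: truth bookkeeping, copula targets, edge localization."""

import numpy as np
import pytest
from scipy import stats

from exonedge.alignment import TrioAlignment
from exonedge.genetic_code import ND_TABLE, SD_TABLE, encode_codons
from exonedge.pipeline import load_data
from exonedge.polymorphism import NON_SYNONYMOUS, SYNONYMOUS, classify_snp
from exonedge.simulate import (
    SimulationConfig,
    simulate_dataset,
    simulate_gene,
    write_dataset,
)


def test_zero_rates_give_identical_tips(rng):
    cfg = SimulationConfig(n_genes=1, branch_rates=(0.0, 0.0, 0.0))
    trio, _ = simulate_gene(cfg, rng)
    seqs = list(trio.sequences.values())
    assert seqs[0] == seqs[1] == seqs[2]


def test_zero_omega_blocks_protein_changes(rng):
    cfg = SimulationConfig(n_genes=1, omega_fixed=0.0, edge_depth=0)
    trio, truth = simulate_gene(cfg, rng, omega_g=0.0)
    assert all(v == 0.0 for v in truth.branch_nd.values())
    assert sum(truth.branch_sd.values()) > 0  # synonymous change still flows


def test_truth_recount_matches_emitted_sequences(rng):
    """Branch Sd/Nd in the truth record equal an independent recount."""
    cfg = SimulationConfig(n_genes=1)
    trio, truth = simulate_gene(cfg, rng, omega_g=0.3, expression_percentile=0.5)
    root = encode_codons("".join(truth.root_codons))
    for br in TrioAlignment.BRANCHES:
        tip = encode_codons(trio.sequences[br])
        assert SD_TABLE[root, tip].sum() == pytest.approx(truth.branch_sd[br])
        assert ND_TABLE[root, tip].sum() == pytest.approx(truth.branch_nd[br])


def test_snp_records_classify_as_generated():
    ds = simulate_dataset(SimulationConfig(n_genes=15), 11)
    by_gene = {g.gene_id: g for g in ds.alignments}
    truth = {t.gene_id: t for t in ds.truth}
    counts = {g: [0, 0] for g in by_gene}
    for snp in ds.snps:
        cls = classify_snp(by_gene[snp.gene_id], snp)
        assert cls in (SYNONYMOUS, NON_SYNONYMOUS)
        counts[snp.gene_id][cls == NON_SYNONYMOUS] += 1
    for gid, (ps, pn) in counts.items():
        assert (ps, pn) == (truth[gid].ps_true, truth[gid].pn_true)


class TestExpressionCopula:
    def test_target_rho_recovered(self):
        cfg = SimulationConfig(n_genes=500, expression_omega_rho=-0.4)
        ds = simulate_dataset(cfg, 21)
        omega = np.array([t.omega_g for t in ds.truth])
        latent = np.array([t.expression_latent for t in ds.truth])
        rho = stats.spearmanr(latent, omega).statistic
        assert abs(rho - (-0.4)) < 0.07

    def test_zero_target_uncorrelated(self):
        cfg = SimulationConfig(n_genes=500, expression_omega_rho=0.0)
        ds = simulate_dataset(cfg, 22)
        omega = np.array([t.omega_g for t in ds.truth])
        latent = np.array([t.expression_latent for t in ds.truth])
        assert abs(stats.spearmanr(latent, omega).statistic) < 0.1

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(expression_omega_rho=-0.99)


def test_edge_effect_is_localized():
    """Substitution density at edge codons is depressed when constrained."""
    cfg = SimulationConfig(
        n_genes=150, edge_depth=10, phi_edge=0.3, psi_edge=0.3,
        expression_edge_coupling=0.0,
    )
    ds = simulate_dataset(cfg, 31)
    edge_diffs = edge_codons = int_diffs = int_codons = 0
    for g, t in zip(ds.alignments, ds.truth):
        a = encode_codons(g.sequences["ingroup1"])
        b = encode_codons(g.sequences["ingroup2"])
        diffs = SD_TABLE[a, b] + ND_TABLE[a, b]
        e = t.edge_flags
        edge_diffs += diffs[e].sum()
        int_diffs += diffs[~e].sum()
        edge_codons += int(e.sum())
        int_codons += int((~e).sum())
    rate_edge = edge_diffs / edge_codons
    rate_int = int_diffs / int_codons
    # Poisson one-sided z-test on the density contrast
    z = (rate_int - rate_edge) / np.sqrt(
        int_diffs / int_codons**2 + edge_diffs / edge_codons**2
    )
    assert rate_edge < rate_int
    assert stats.norm.sf(z) < 0.01


def test_emitted_files_parse_cleanly(tmp_path):
    cfg = SimulationConfig(n_genes=8, gap_block_fraction=0.3)
    ds = simulate_dataset(cfg, 41)
    write_dataset(ds, tmp_path)
    data = load_data(tmp_path)
    assert len(data.alignments) == 8
    assert data.expression.shape == (8, cfg.n_tissues)
    assert data.snps is not None
    # gap injection must leave some blocks not fully aligned
    flags = [b.fully_aligned for g in data.alignments for b in g.exon_blocks]
    assert not all(flags)
    # round trip preserves sequences bit-for-bit
    orig = {g.gene_id: g.sequences for g in ds.alignments}
    for g in data.alignments:
        assert g.sequences == orig[g.gene_id]


def test_per_gene_streams_independent_of_order():
    """Gene i's alignment is identical whether or not other genes exist."""
    cfg_small = SimulationConfig(n_genes=3)
    cfg_big = SimulationConfig(n_genes=6)
    d1 = simulate_dataset(cfg_small, 5)
    d2 = simulate_dataset(cfg_big, 5)
    for a, b in zip(d1.alignments, d2.alignments):
        assert a.sequences == b.sequences
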