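"""Edge trimming, matched random removal, and the randomization test."""

import numpy as np
import pytest

from exonedge.genetic_code import SENSE_CODONS
from exonedge.trimming import (
    INTERNAL_EDGES_ONLY,
    TrimSpec,
    _empirical_p,
    _sequential_keep,
    build_trim_profile,
    concat_eligible,
    eligible_exons,
    random_trim,
    randomization_test,
    rho_randomization,
    trim_edges,
)

from conftest import make_gene


def sense_seq(rng, n):
    return "".join(SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n))


def gene_with_exons(rng, exon_codons, mutations=0):
    n = sum(exon_codons)
    a = sense_seq(rng, n)
    b = list(a)
    for _ in range(mutations):
        while True:
            pos = int(rng.integers(len(b)))
            alt = "ACGT"[int(rng.integers(4))]
            ci = pos // 3
            codon = "".join(b[3 * ci : 3 * ci + 3])
            cand = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
            if alt != b[pos] and cand in SENSE_CODONS:
                b[pos] = alt
                break
    blocks, pos = [], 0
    for ln in exon_codons:
        blocks.append((pos, pos + ln))
        pos += ln
    return make_gene({"a": a, "b": "".join(b)}, blocks=blocks)


class TestEligibility:
    def test_gapped_blocks_excluded(self, rng):
        g = gene_with_exons(rng, [30, 30])
        s = g.sequences["b"]
        g.sequences["b"] = "---" + s[3:]  # corrupt first codon
        from exonedge.alignment import compute_block_flags

        g.exon_blocks = compute_block_flags(g)
        elig = eligible_exons(g)
        assert [b.exon_index for b in elig] == [1]

    def test_clean_blocks_kept(self, rng):
        g = gene_with_exons(rng, [60, 60])
        assert len(eligible_exons(g)) == 2

    def test_flagged_block_excluded(self, rng):
        from dataclasses import replace

        g = gene_with_exons(rng, [60, 60])
        g.exon_blocks[0] = replace(g.exon_blocks[0], multiple_of_three=False)
        assert [b.exon_index for b in eligible_exons(g)] == [1]


class TestTrimArithmetic:
    def test_both_edges_removal(self, rng):
        g = gene_with_exons(rng, [100])
        out = trim_edges(g, TrimSpec(k=10))
        assert out.n_codons == 80
        assert list(out.source_codons) == list(range(10, 90))

    def test_exons_fully_consumed(self, rng):
        g = gene_with_exons(rng, [60, 60])
        assert trim_edges(g, TrimSpec(k=30)) is None

    def test_threshold_boundary(self, rng):
        g = gene_with_exons(rng, [110, 110])
        out = trim_edges(g, TrimSpec(k=30))
        assert out.n_codons == 100  # 300 bases, still eligible

    def test_internal_edges_only_exempts_gene_termini(self, rng):
        g = gene_with_exons(rng, [50, 50])
        base = concat_eligible(g)
        keep = _sequential_keep(base.exon_blocks, TrimSpec(k=10, mode=INTERNAL_EDGES_ONLY))
        # first exon keeps its 5' edge, last exon its 3' edge
        assert keep.min() == 0 and keep.max() == 99
        assert keep.size == 100 - 20  # one internal edge per exon


class TestRandomTrim:
    def test_zero_removal_is_identity(self, rng):
        g = gene_with_exons(rng, [60])
        out = random_trim(g, 0, rng)
        assert out.sequences == g.sequences

    def test_seed_determinism(self, rng):
        g = gene_with_exons(rng, [60])
        o1 = random_trim(g, 20, np.random.default_rng(7))
        o2 = random_trim(g, 20, np.random.default_rng(7))
        assert o1.sequences == o2.sequences

    def test_too_many_rejected(self, rng):
        g = gene_with_exons(rng, [60])
        with pytest.raises(ValueError):
            random_trim(g, 61, rng)

    def test_retained_codons_are_subset(self, rng):
        g = gene_with_exons(rng, [60])
        out = random_trim(g, 15, rng)
        assert set(out.source_codons) <= set(range(60))
        assert out.n_codons == 45


@pytest.mark.parametrize(
    "s,q,expected",
    [(1000, 1000, 1 / 1001), (1000, 0, 1.0), (4, 2, 0.6)],
)
def test_empirical_p_formula(s, q, expected):
    nulls = np.concatenate([np.zeros(q), np.full(s - q, 2.0)])
    got_q, p, _ = _empirical_p(1.0, nulls, "omega")
    assert got_q == q
    assert p == pytest.approx(expected)


def test_empirical_p_direction_for_ni():
    nulls = np.array([1.0, 2.0, 3.0, 4.0])
    q, p, _ = _empirical_p(2.5, nulls, "NI")  # lower is extreme: q = #(obs < null)
    assert q == 2 and p == pytest.approx(0.6)


def test_ties_do_not_increment_q():
    nulls = np.full(4, 1.0)
    q, p, _ = _empirical_p(1.0, nulls, "omega")
    assert q == 0 and p == 1.0


def test_paired_design_removal_counts(rng):
    """Sequential and random treatments remove identical codon numbers."""
    g = gene_with_exons(rng, [80, 80], mutations=40)
    spec = TrimSpec(k=10)
    tp = build_trim_profile(g, spec, ("a", "b"))
    assert tp.n_remove == 40
    trimmed = trim_edges(g, spec)
    randomized = random_trim(concat_eligible(g), tp.n_remove, rng)
    assert trimmed.n_codons == randomized.n_codons


def test_randomization_test_structure(rng):
    g = gene_with_exons(rng, [120, 120], mutations=120)
    res = randomization_test(
        g, TrimSpec(k=10), ("dS", "omega"), s=50,
        rng=np.random.default_rng(3), pair=("a", "b"),
    )
    assert set(res) == {"dS", "omega"}
    r = res["dS"]
    assert r.null_values.size == 50
    assert 1 / 51 <= r.p <= 1.0
    assert r.p == pytest.approx((50 - r.q + 1) / 51)


def test_randomization_ineligible_gene_returns_none(rng):
    g = gene_with_exons(rng, [30])  # 30-codon exon, k=20 leaves nothing
    assert randomization_test(g, TrimSpec(k=20), ("dS",), s=5, rng=rng, pair=("a", "b")) is None


def test_rho_randomization_self_covariate(rng):
    """Covariate equal to the sequential statistic gives observed rho = 1."""
    genes = [gene_with_exons(rng, [100, 100], mutations=80) for _ in range(32)]
    spec = TrimSpec(k=10)
    profiles = [build_trim_profile(g, spec, ("a", "b")) for g in genes]
    seq_omega = np.array(
        [tp.statistics(tp.seq_keep, ("omega",))["omega"] for tp in profiles]
    )
    res = rho_randomization(profiles, seq_omega, "omega", s=10, rng=np.random.default_rng(5))
    assert res.observed_sequential == pytest.approx(1.0)
    assert res.null_values.size == 10


def test_rho_randomization_constant_covariate_rejected(rng):
    genes = [gene_with_exons(rng, [100, 100], mutations=80) for _ in range(32)]
    profiles = [build_trim_profile(g, TrimSpec(k=10), ("a", "b")) for g in genes]
    with pytest.raises(ValueError):
        rho_randomization(profiles, np.ones(32), "omega", s=5, rng=rng)


def test_trim_spec_validation():
    with pytest.raises(ValueError):
        TrimSpec(k=0)
    with pytest.raises(ValueError):
        TrimSpec(k=5, mode="sideways")
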