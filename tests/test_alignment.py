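"""Alignment data model, I/O round trips, and column bookkeeping."""

import numpy as np
import pytest

from exonedge.alignment import (
    ConsistencyError,
    ExonBlock,
    FormatError,
    GeneAlignment,
    SnpRecord,
    aligned_bases,
    concatenate_blocks,
    exon_map_frame,
    read_gene_alignment,
    write_gene_alignment,
)

from conftest import make_gene


def test_well_formed_input_round_trips(tmp_path):
    g = make_gene(
        {"sp1": "ATGAAATTTGGGCCCAAA", "sp2": "ATGAAA---GGGCCCAAA"},
        blocks=[(0, 3), (3, 6)],
        gene_id="g1",
    )
    write_gene_alignment(g, tmp_path / "g1.fasta")
    exon_map_frame([g]).to_csv(tmp_path / "map.tsv", sep="\t", index=False)
    back = read_gene_alignment(tmp_path / "g1.fasta", tmp_path / "map.tsv")
    assert back.sequences == g.sequences
    assert back.exon_blocks == g.exon_blocks
    assert back.reference_species == "sp1"
    assert back.n_codons == 6


def test_exon_map_must_tile_cds(tmp_path):
    g = make_gene({"a": "ATG" * 20, "b": "ATG" * 20}, blocks=[(0, 10), (10, 20)])
    write_gene_alignment(g, tmp_path / "toy.fasta")
    bad = exon_map_frame([g])
    bad.loc[1, "codon_start"] = 12  # leaves [10, 12) uncovered
    bad.to_csv(tmp_path / "map.tsv", sep="\t", index=False)
    with pytest.raises(ConsistencyError):
        read_gene_alignment(tmp_path / "toy.fasta", tmp_path / "map.tsv")


def test_unequal_lengths_is_format_error():
    with pytest.raises(FormatError):
        GeneAlignment("g", "a", {"a": "ATGATG", "b": "ATG"}, [ExonBlock(0, 0, 2)])


def test_gap_in_block_clears_fully_aligned():
    g = make_gene(
        {"a": "ATGAAATTTGGG", "b": "ATG---TTTGGG"}, blocks=[(0, 2), (2, 4)]
    )
    assert not g.exon_blocks[0].fully_aligned
    assert g.exon_blocks[1].fully_aligned


def test_internal_stop_flagged(tmp_path):
    g = make_gene({"a": "ATGTAAGGGAAA", "b": "ATGTACGGGAAA"})
    write_gene_alignment(g, tmp_path / "s.fasta")
    exon_map_frame([g]).to_csv(tmp_path / "map.tsv", sep="\t", index=False)
    back = read_gene_alignment(tmp_path / "s.fasta", tmp_path / "map.tsv", gene_id="toy")
    assert back.internal_stop


class TestAlignedBases:
    def test_gapless(self):
        g = make_gene({"a": "ATG" * 20, "b": "ATG" * 20})
        assert aligned_bases(g, ("a", "b")) == 60

    def test_all_gaps(self):
        g = make_gene({"a": "ATGATG", "b": "------"}, reference="a")
        assert aligned_bases(g, ("a", "b")) == 0

    def test_matches_column_scan_and_symmetry(self, rng):
        cols = []
        for _ in range(90):
            a = rng.choice(list("ACGT-"))
            b = rng.choice(list("ACGT-"))
            cols.append((a, b))
        sa = "".join(c[0] for c in cols)
        sb = "".join(c[1] for c in cols)
        # reference must be frame-clean for construction: use a third row
        g = GeneAlignment(
            "toy", "ref",
            {"ref": "A" * 90, "a": sa, "b": sb},
            [ExonBlock(0, 0, 30)],
        )
        brute = sum(x != "-" and y != "-" for x, y in cols)
        assert aligned_bases(g, ("a", "b")) == brute
        assert aligned_bases(g, ("b", "a")) == brute
        assert brute <= g.alignment_length

    def test_unknown_species(self):
        g = make_gene({"a": "ATGATG", "b": "ATGATG"})
        with pytest.raises(ConsistencyError):
            aligned_bases(g, ("a", "zzz"))


class TestConcatenateBlocks:
    def test_identity_on_full_set(self):
        g = make_gene(
            {"a": "ATGAAATTTGGGCCCAAA", "b": "ATGAAACTTGGGCCCAAA"},
            blocks=[(0, 3), (3, 6)],
        )
        out = concatenate_blocks(g, g.exon_blocks)
        assert out.sequences == g.sequences
        assert [(b.codon_start, b.codon_end) for b in out.exon_blocks] == [(0, 3), (3, 6)]

    def test_subset_arithmetic(self):
        g = make_gene({"a": "ATG" * 20, "b": "ATG" * 20}, blocks=[(0, 10), (10, 20)])
        out = concatenate_blocks(g, [g.exon_blocks[0]])
        assert out.n_codons == 10
        assert list(out.source_codons) == list(range(10))

    def test_aligned_bases_additive_over_kept_blocks(self):
        g = make_gene(
            {"a": "ATGAAATTTGGGCCCAAA", "b": "ATG---TTTGGGCCCAAA"},
            blocks=[(0, 2), (2, 4), (4, 6)],
        )
        total = 0
        for b in g.exon_blocks:
            piece = concatenate_blocks(g, [b])
            total += aligned_bases(piece, ("a", "b"))
        assert total == aligned_bases(g, ("a", "b"))

    def test_empty_keep_rejected(self):
        g = make_gene({"a": "ATGATG", "b": "ATGATG"})
        with pytest.raises(ConsistencyError):
            concatenate_blocks(g, [])

    def test_foreign_block_rejected(self):
        g = make_gene({"a": "ATGATG", "b": "ATGATG"})
        with pytest.raises(ConsistencyError):
            concatenate_blocks(g, [ExonBlock(0, 0, 99)])


def test_snp_record_validation():
    with pytest.raises(ConsistencyError):
        SnpRecord("g", 0, "A", "A")
    with pytest.raises(ConsistencyError):
        SnpRecord("g", 0, "A", "X")
    r = SnpRecord("g", 5, "A", "G")
    assert r.cds_position == 5
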