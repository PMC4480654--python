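"""Data model and I/O for per-gene codon alignments and their sidecars.

Coordinates are 0-based, half-open, and expressed in codon units over the
ungapped *reference* CDS; genomic coordinates never enter the pipeline.
A gene is represented by a gapped multi-FASTA alignment (record id =
species label) plus an exon-map TSV giving the exon tiling of the
reference CDS in codon space.  SNP tables, expression matrices, and EST
intron-chain tables are plain TSVs read into pandas frames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import GAP, STOP_CODONS, encode_codons

EXON_MAP_COLUMNS = ["gene_id", "exon_index", "codon_start", "codon_end"]
SNP_COLUMNS = ["gene_id", "cds_position", "ref_base", "alt_base"]


class FormatError(ValueError):
    """Malformed input file (lengths, frame, alphabet)."""


class ConsistencyError(ValueError):
    """Inputs that parse individually but contradict each other."""


@dataclass(frozen=True)
class ExonBlock:
    """One exon's span on the ungapped reference CDS, in codon units.

    ``in_frame`` and ``multiple_of_three`` record upstream alignment-
    construction verdicts (in codon coordinates both hold trivially, so
    they can only be supplied, not derived); ``fully_aligned`` is computed
    from the alignment: no species has a gap within the block's columns.
    """

    exon_index: int
    codon_start: int
    codon_end: int
    fully_aligned: bool = True
    in_frame: bool = True
    multiple_of_three: bool = True

    def __post_init__(self) -> None:
        if self.codon_start >= self.codon_end:
            raise ConsistencyError(
                f"exon {self.exon_index}: empty span "
                f"[{self.codon_start}, {self.codon_end})"
            )

    @property
    def n_codons(self) -> int:
        return self.codon_end - self.codon_start


@dataclass
class GeneAlignment:
    """Gapped per-species CDS alignment with an exon tiling.

    ``source_codons``, when present, maps each current codon back to its
    codon index in the original (pre-trim) reference CDS so that SNP
    records keep meaning after column removal.
    """

    gene_id: str
    reference_species: str
    sequences: dict[str, str]
    exon_blocks: list[ExonBlock]
    internal_stop: bool = False
    source_codons: np.ndarray | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise FormatError(f"{self.gene_id}: unequal alignment lengths {lengths}")
        if self.reference_species not in self.sequences:
            raise ConsistencyError(
                f"{self.gene_id}: reference {self.reference_species!r} missing"
            )

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def ungapped(self, species: str) -> str:
        try:
            return self.sequences[species].replace(GAP, "")
        except KeyError:
            raise ConsistencyError(f"{self.gene_id}: unknown species {species!r}") from None

    @property
    def n_codons(self) -> int:
        return len(self.ungapped(self.reference_species)) // 3

    def reference_columns(self) -> np.ndarray:
        """Alignment column index of each ungapped reference base."""
        ref = self.sequences[self.reference_species]
        return np.flatnonzero(np.frombuffer(ref.encode(), dtype=np.uint8) != ord(GAP))

    def codon_columns(self) -> np.ndarray:
        """(n_codons, 3) alignment columns holding each reference codon."""
        cols = self.reference_columns()
        return cols[: 3 * self.n_codons].reshape(-1, 3)

    def species_codons(self, species: str) -> np.ndarray:
        """Encoded codons of ``species`` at the reference codon columns.

        Triplets containing a gap or ambiguity encode as -1.
        """
        seq = self.sequences[species]
        cols = self.codon_columns()
        return encode_codons("".join(seq[a] + seq[b] + seq[c] for a, b, c in cols))


@dataclass
class TrioAlignment(GeneAlignment):
    """Three-species alignment on the fixed topology ((ingroup1, ingroup2), outgroup)."""

    INGROUP1 = "ingroup1"
    INGROUP2 = "ingroup2"
    OUTGROUP = "outgroup"
    BRANCHES = (INGROUP1, INGROUP2, OUTGROUP)

    def __post_init__(self) -> None:
        super().__post_init__()
        if set(self.sequences) != set(self.BRANCHES):
            raise ConsistencyError(
                f"{self.gene_id}: trio must have species {self.BRANCHES}, "
                f"got {sorted(self.sequences)}"
            )


@dataclass(frozen=True)
class SnpRecord:
    """A within-species biallelic SNP on the ungapped reference CDS."""

    gene_id: str
    cds_position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ConsistencyError(f"{self.gene_id}@{self.cds_position}: ref == alt")
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT":
                raise ConsistencyError(f"{self.gene_id}@{self.cds_position}: base {b!r}")


def _has_internal_stop(cds: str) -> bool:
    n = len(cds) // 3
    for i in range(n - 1):  # a terminal stop is legitimate
        if cds[3 * i : 3 * i + 3] in STOP_CODONS:
            return True
    return False


def compute_block_flags(g: GeneAlignment) -> list[ExonBlock]:
    """Recompute ``fully_aligned`` for every block from the alignment.

    A block is fully aligned iff its reference codons occupy contiguous
    alignment columns (no insertions inside) and no species has a gap
    character in any of those columns.
    """
    cols = g.reference_columns()
    rows = list(g.sequences.values())
    out = []
    for b in g.exon_blocks:
        span = cols[3 * b.codon_start : 3 * b.codon_end]
        contiguous = bool(span[-1] - span[0] + 1 == len(span))
        clean = contiguous and not any(
            GAP in row[span[0] : span[-1] + 1] for row in rows
        )
        out.append(replace(b, fully_aligned=clean))
    return out


def _check_tiling(blocks: list[ExonBlock], n_codons: int, gene_id: str) -> None:
    ordered = sorted(blocks, key=lambda b: b.codon_start)
    if [b.codon_start for b in ordered] != [b.codon_start for b in blocks]:
        raise ConsistencyError(f"{gene_id}: exon blocks not sorted")
    pos = 0
    for b in ordered:
        if b.codon_start != pos:
            raise ConsistencyError(
                f"{gene_id}: exon tiling gap/overlap at codon {pos} "
                f"(next block starts at {b.codon_start})"
            )
        pos = b.codon_end
    if pos != n_codons:
        raise ConsistencyError(
            f"{gene_id}: exon blocks tile [0, {pos}) but CDS has {n_codons} codons"
        )


def read_exon_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in EXON_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"exon map {path}: missing columns {missing}")
    return df


def _blocks_from_frame(rows: pd.DataFrame) -> list[ExonBlock]:
    blocks = []
    for r in rows.itertuples(index=False):
        blocks.append(
            ExonBlock(
                exon_index=int(r.exon_index),
                codon_start=int(r.codon_start),
                codon_end=int(r.codon_end),
                in_frame=bool(getattr(r, "in_frame", True)),
                multiple_of_three=bool(getattr(r, "multiple_of_three", True)),
            )
        )
    return blocks


def read_gene_alignment(
    fasta_path: str | Path,
    exon_map_path: str | Path,
    gene_id: str | None = None,
    reference_species: str | None = None,
) -> GeneAlignment:
    """Read one gene's gapped multi-FASTA plus its exon-map rows.

    The reference species defaults to the first FASTA record; the gene id
    defaults to the FASTA file stem.  Exon rows must tile the reference
    CDS exactly; per-block ``fully_aligned`` flags are computed from the
    alignment.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"{fasta_path}: no FASTA records")
    gene_id = gene_id or Path(fasta_path).stem
    sequences = {r.id: str(r.seq).upper() for r in records}
    reference_species = reference_species or records[0].id

    exon_map = read_exon_map(exon_map_path)
    rows = exon_map[exon_map["gene_id"] == gene_id].sort_values("exon_index")
    if rows.empty:
        raise ConsistencyError(f"{exon_map_path}: no exon rows for {gene_id}")
    blocks = _blocks_from_frame(rows)

    g = GeneAlignment(
        gene_id=gene_id,
        reference_species=reference_species,
        sequences=sequences,
        exon_blocks=blocks,
    )
    ref_cds = g.ungapped(reference_species)
    if len(ref_cds) % 3:
        raise FormatError(f"{gene_id}: reference CDS length {len(ref_cds)} not a multiple of 3")
    _check_tiling(blocks, len(ref_cds) // 3, gene_id)
    g.exon_blocks = compute_block_flags(g)
    g.internal_stop = _has_internal_stop(ref_cds)
    return g


def write_gene_alignment(g: GeneAlignment, fasta_path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sp, description="") for sp, seq in g.sequences.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def exon_map_frame(genes: list[GeneAlignment]) -> pd.DataFrame:
    rows = []
    for g in genes:
        for b in g.exon_blocks:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "exon_index": b.exon_index,
                    "codon_start": b.codon_start,
                    "codon_end": b.codon_end,
                    "in_frame": b.in_frame,
                    "multiple_of_three": b.multiple_of_three,
                }
            )
    return pd.DataFrame(rows, columns=EXON_MAP_COLUMNS + ["in_frame", "multiple_of_three"])


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"SNP table {path}: missing columns {missing}")
    return [
        SnpRecord(str(r.gene_id), int(r.cds_position), str(r.ref_base), str(r.alt_base))
        for r in df.itertuples(index=False)
    ]


def snp_frame(snps: list[SnpRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.gene_id, s.cds_position, s.ref_base, s.alt_base) for s in snps],
        columns=SNP_COLUMNS,
    )


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """genes x tissues abundance table; index gene_id, one column per tissue."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id", comment="#")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate tissue labels")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative abundance values")
    return df


def aligned_bases(g: GeneAlignment, pair: tuple[str, str]) -> int:
    """Number of alignment columns where neither species of ``pair`` has a gap."""
    a, b = (g.sequences.get(sp) for sp in pair)
    for sp, row in zip(pair, (a, b)):
        if row is None:
            raise ConsistencyError(f"{g.gene_id}: unknown species {sp!r}")
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    return int(np.sum((arr_a != ord(GAP)) & (arr_b != ord(GAP))))


def concatenate_blocks(g: GeneAlignment, keep: list[ExonBlock]) -> GeneAlignment:
    """New alignment holding only the columns of ``keep``, coordinates remapped.

    Block order follows reference position regardless of the order given.
    ``source_codons`` tracks original reference codon indices (composed
    with any existing mapping on ``g``).
    """
    own = {(b.codon_start, b.codon_end) for b in g.exon_blocks}
    for b in keep:
        if (b.codon_start, b.codon_end) not in own:
            raise ConsistencyError(f"{g.gene_id}: block {b} is not part of this gene")
    if not keep:
        raise ConsistencyError(f"{g.gene_id}: empty block selection")
    keep = sorted(keep, key=lambda b: b.codon_start)

    cols = g.reference_columns()
    pieces: dict[str, list[str]] = {sp: [] for sp in g.sequences}
    new_blocks: list[ExonBlock] = []
    kept_codons: list[np.ndarray] = []
    pos = 0
    for b in keep:
        span = cols[3 * b.codon_start : 3 * b.codon_end]
        lo, hi = int(span[0]), int(span[-1]) + 1
        for sp, seq in g.sequences.items():
            pieces[sp].append(seq[lo:hi])
        new_blocks.append(
            replace(b, codon_start=pos, codon_end=pos + b.n_codons)
        )
        kept_codons.append(np.arange(b.codon_start, b.codon_end))
        pos += b.n_codons
    src = np.concatenate(kept_codons)
    if g.source_codons is not None:
        src = g.source_codons[src]
    cls = type(g)
    return cls(
        gene_id=g.gene_id,
        reference_species=g.reference_species,
        sequences={sp: "".join(parts) for sp, parts in pieces.items()},
        exon_blocks=new_blocks,
        internal_stop=g.internal_stop,
        source_codons=src,
    )


def select_codons(g: GeneAlignment, keep_idx: np.ndarray) -> GeneAlignment:
    """Subset a *gap-free, single-block-compatible* alignment by codon index.

    Intended for trimmed/randomized column removal where every retained
    reference codon occupies exactly its own three contiguous columns.
    The result is a single-block alignment; ``source_codons`` is updated.
    """
    keep_idx = np.sort(np.asarray(keep_idx, dtype=np.intp))
    if keep_idx.size == 0:
        raise ConsistencyError(f"{g.gene_id}: empty codon selection")
    cols = g.codon_columns()[keep_idx].ravel()
    sequences = {
        sp: "".join(seq[c] for c in cols) for sp, seq in g.sequences.items()
    }
    src = keep_idx if g.source_codons is None else g.source_codons[keep_idx]
    return GeneAlignment(
        gene_id=g.gene_id,
        reference_species=g.reference_species,
        sequences=sequences,
        exon_blocks=[ExonBlock(0, 0, len(keep_idx))],
        internal_stop=g.internal_stop,
        source_codons=src,
    )
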