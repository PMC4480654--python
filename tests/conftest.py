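import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from exonedge.alignment import ExonBlock, GeneAlignment, TrioAlignment, compute_block_flags

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_gene(
    sequences: dict[str, str],
    blocks: list[tuple[int, int]] | None = None,
    gene_id: str = "toy",
    reference: str | None = None,
) -> GeneAlignment:
    """Build a GeneAlignment from raw strings; blocks default to one exon."""
    reference = reference or next(iter(sequences))
    n_codons = len(sequences[reference].replace("-", "")) // 3
    if blocks is None:
        blocks = [(0, n_codons)]
    g = GeneAlignment(
        gene_id=gene_id,
        reference_species=reference,
        sequences={k: v.upper() for k, v in sequences.items()},
        exon_blocks=[ExonBlock(i, s, e) for i, (s, e) in enumerate(blocks)],
    )
    g.exon_blocks = compute_block_flags(g)
    return g


def make_trio(seq1: str, seq2: str, seq3: str, blocks=None, gene_id="toy") -> TrioAlignment:
    t = TrioAlignment(
        gene_id=gene_id,
        reference_species="ingroup1",
        sequences={"ingroup1": seq1, "ingroup2": seq2, "outgroup": seq3},
        exon_blocks=[ExonBlock(i, s, e) for i, (s, e) in enumerate(blocks or [(0, len(seq1.replace('-', '')) // 3)])],
    )
    t.exon_blocks = compute_block_flags(t)
    return t


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
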