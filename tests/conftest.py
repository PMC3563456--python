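import pytest

from mirscreen import read_mapper, smallrna_prep
from mirscreen.synthetic_data import SimConfig, generate_genome, simulate_reads


@pytest.fixture(scope="session")
def small_bundle():
    """One small simulated experiment shared by read-level tests.

    5 planted mirtrons, 300 decoy introns, 6 canonical + 6 scatter loci;
    reads prepped, collapsed and mapped once per session.
    """
    cfg = SimConfig(
        seed=42,
        n_planted_mirtrons=5,
        n_decoy_introns=300,
        n_planted_canonical=6,
        n_scatter_decoys=6,
    )
    genome, exons, truth = generate_genome(cfg)
    raw = simulate_reads(truth, genome, "sample1")
    prep = smallrna_prep.prepare_reads(
        raw, smallrna_prep.TrimParams(), [truth.rrna_sequence]
    )
    index = read_mapper.build_index(genome, 6)
    alignments = read_mapper.map_collapsed_reads(prep["collapsed"], index, 2)
    return {
        "config": cfg,
        "genome": genome,
        "exons": exons,
        "truth": truth,
        "raw": raw,
        "prep": prep,
        "index": index,
        "alignments": alignments,
    }
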