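import numpy as np
import pytest

from circm6a import (
    ReferenceBundle,
    SimConfig,
    build_sim_transcriptome,
    make_toy_reference,
    simulate_merip,
    sort_and_index,
)


@pytest.fixture(scope="session")
def toy_ref(tmp_path_factory):
    """Small deterministic reference: 12 genes x 5 exons of 400 bp."""
    d = tmp_path_factory.mktemp("ref")
    fasta, gtf = make_toy_reference(
        d, n_genes=12, exons_per_gene=5, exon_len=400, intron_len=200,
        spacing=600, seed=11,
    )
    return ReferenceBundle.load(fasta, gtf)


@pytest.fixture(scope="session")
def small_sim(toy_ref, tmp_path_factory):
    """A small fragmentation-after MeRIP simulation with sorted BAMs."""
    d = tmp_path_factory.mktemp("sim")
    cfg = SimConfig(depth=20.0, strategy="frag_after")
    tset = build_sim_transcriptome(
        toy_ref, n_circ=10, n_linear=12, frac_m6a=0.5, frac_m6a_linear=0.2,
        proximal_frac=0.5, max_frag_len=cfg.max_fragment,
        seed=np.random.default_rng(5),
    )
    sim = simulate_merip(tset, toy_ref, cfg, d, seed=17, truth_reads="all")
    input_bam = sort_and_index(sim.input_sam, d / "input.bam")
    ip_bam = sort_and_index(sim.ip_sam, d / "ip.bam")
    return {"ref": toy_ref, "tset": tset, "sim": sim,
            "input_bam": input_bam, "ip_bam": ip_bam}
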