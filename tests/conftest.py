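import random

import pytest

from kresolve.assembly_graph import SequenceGraph
from kresolve.repeat_finder import AlgorithmParams, RepeatSite
from kresolve.seq_io import ReadLibrary
from kresolve.simulate import (
    ReadSimSpec,
    SyntheticGenomeSpec,
    build_unitig_graph,
    make_repeat_genome,
    simulate_reads,
)


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_junction_graph(
    ka=5, repeat_len=30, flank_len=60, n_in=2, n_out=2, seed=0, cov=1000.0
):
    """A structurally valid star: n_in flank nodes -> repeat -> n_out flanks.

    Overlaps are consistent by construction (flanks borrow the repeat's
    terminal k-1 bases).  Returns (graph, site).
    """
    rng = random.Random(seed)
    ov = ka - 1
    g = SequenceGraph(ka)
    rep = rand_seq(rng, repeat_len)
    g.add_node("R", rep, cov)
    ins, outs = [], []
    for i in range(n_in):
        g.add_node(f"A{i}", rand_seq(rng, flank_len - ov) + rep[:ov], cov)
        g.add_edge((f"A{i}", "+"), ("R", "+"))
        ins.append((f"A{i}", "+"))
    for j in range(n_out):
        g.add_node(f"X{j}", rep[-ov:] + rand_seq(rng, flank_len - ov), cov)
        g.add_edge(("R", "+"), (f"X{j}", "+"))
        outs.append((f"X{j}", "+"))
    site = RepeatSite(("R", "+"), tuple(sorted(ins)), tuple(sorted(outs)))
    return g, site


SMALL_SIM = dict(
    unique_segment_length=800,
    repeat_length=60,
    kmer_disjoint_k=31,
)
SMALL_KA = 31
SMALL_READ_LEN = 100
SMALL_K_RR = 91


def small_sim_instance(seed, coverage=40.0):
    """Fast end-to-end instance: 800 bp flanks, 60 bp repeat x2, k=31."""
    genome, truth = make_repeat_genome(SyntheticGenomeSpec(seed=seed, **SMALL_SIM))
    library = simulate_reads(
        genome, ReadSimSpec(read_length=SMALL_READ_LEN, fold_coverage=coverage, seed=seed)
    )
    graph = build_unitig_graph(library, SMALL_KA)
    return genome, truth, library, graph


@pytest.fixture
def small_params():
    return AlgorithmParams(k_rresolver=SMALL_K_RR, bloom_bits=1 << 24, seed=0)


@pytest.fixture
def junction():
    return make_junction_graph()


@pytest.fixture
def small_instance():
    return small_sim_instance(seed=1)
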