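import random

import pytest

from kresolve.assembly_graph import revcomp, validate_graph
from kresolve.errors import ConfigurationError
from kresolve.kmer_bloom import canonical
from kresolve.path_support import PathEvaluation, SupportMatrix
from kresolve.repeat_finder import AlgorithmParams, RepeatSite, Verdict, find_repeat_sites
from kresolve.resolver import (
    apply_edits,
    choose_k_rresolver,
    plan_resolution,
    resolve_graph,
)
from kresolve.seq_io import ReadLibrary
from kresolve.simulate import score_resolution, simulate_reads, ReadSimSpec

from .conftest import make_junction_graph, small_sim_instance

PARAMS = AlgorithmParams()


def matrix_from(site, support):
    """SupportMatrix with given supported pairs; everything else unsupported."""
    entries = {}
    for inn in site.ins:
        for out in site.outs:
            sup = (inn, out) in support
            entries[(inn, out)] = PathEvaluation(
                (inn, site.repeat, out), 18, 18 if sup else 0, sup, Verdict.PROCEED
            )
    return SupportMatrix(site, entries)


def skipped_matrix(site):
    entries = {}
    for inn in site.ins:
        for out in site.outs:
            entries[(inn, out)] = PathEvaluation(
                (inn, site.repeat, out), 0, 0, None, Verdict.SKIP_LOW_COVERAGE
            )
    return SupportMatrix(site, entries)


class TestPlanResolution:
    def test_diagonal_two_copies(self, junction):
        _, site = junction
        a0, a1 = site.ins
        x0, x1 = site.outs
        edit = plan_resolution(site, matrix_from(site, {(a0, x0), (a1, x1)}), PARAMS)
        assert edit is not None and edit.is_full_resolution
        assert len(edit.copies) == 2
        assert edit.removed_in == [] and edit.removed_out == []

    def test_three_by_three_two_components(self):
        _, site = make_junction_graph(n_in=3, n_out=3)
        a, b, c = site.ins
        x, y, z = site.outs
        support = {(a, x), (a, y), (b, x), (b, y), (c, z)}
        edit = plan_resolution(site, matrix_from(site, support), PARAMS)
        assert edit is not None and len(edit.copies) == 2
        sizes = sorted((len(i), len(o)) for _, i, o in edit.copies)
        assert sizes == [(1, 1), (2, 2)]
        assert not edit.is_full_resolution  # partial simplification

    def test_all_supported_noop(self, junction):
        _, site = junction
        all_pairs = {(i, o) for i in site.ins for o in site.outs}
        assert plan_resolution(site, matrix_from(site, all_pairs), PARAMS) is None

    def test_skipped_site_noop(self, junction):
        _, site = junction
        assert plan_resolution(site, skipped_matrix(site), PARAMS) is None

    def test_nothing_supported_noop(self, junction):
        _, site = junction
        assert plan_resolution(site, matrix_from(site, set()), PARAMS) is None

    def test_dead_in_edge_removed_when_other_side_supported(self):
        _, site = make_junction_graph(n_in=3, n_out=2)
        a, b, c = site.ins
        x, y = site.outs
        edit = plan_resolution(site, matrix_from(site, {(a, x), (b, y)}), PARAMS)
        assert edit is not None
        assert edit.removed_in == [c]
        assert len(edit.copies) == 2


class TestApplyEdits:
    def test_full_resolution_yields_two_linear_contigs(self, junction):
        g, site = junction
        a0, a1 = site.ins
        x0, x1 = site.outs
        seq_a0rx0 = (
            g.oriented_sequence(a0)
            + g.oriented_sequence(site.repeat)[4:]
            + g.oriented_sequence(x0)[4:]
        )
        seq_a1rx1 = (
            g.oriented_sequence(a1)
            + g.oriented_sequence(site.repeat)[4:]
            + g.oriented_sequence(x1)[4:]
        )
        edit = plan_resolution(site, matrix_from(site, {(a0, x0), (a1, x1)}), PARAMS)
        g2, applied, deferred, removed = apply_edits(g, [edit])
        assert len(applied) == 1 and deferred == 0
        from kresolve.assembly_graph import merge_unambiguous_paths

        g2, merges = merge_unambiguous_paths(g2)
        assert len(g2.nodes) == 2
        spelled = sorted(n.sequence for n in g2.nodes.values())
        want = sorted(
            min(s, revcomp(s)) for s in (seq_a0rx0, seq_a1rx1)
        )
        assert sorted(min(s, revcomp(s)) for s in spelled) == want
        assert validate_graph(g2) == []

    def test_noop_edit_list(self, junction):
        g, _ = junction
        before = g.copy()
        g2, applied, deferred, removed = apply_edits(g, [])
        assert g2 == before and applied == [] and removed == 0

    def test_cov_split_conserved(self, junction):
        g, site = junction
        total_before = g.total_cov_sum()
        a0, a1 = site.ins
        x0, x1 = site.outs
        edit = plan_resolution(site, matrix_from(site, {(a0, x0), (a1, x1)}), PARAMS)
        g2, *_ = apply_edits(g, [edit])
        assert g2.total_cov_sum() == pytest.approx(total_before)


class TestChooseK:
    def test_plus_sixty(self):
        assert choose_k_rresolver(100, 250, AlgorithmParams()) == 160

    def test_capped_by_read_length(self):
        assert choose_k_rresolver(100, 151, AlgorithmParams()) == 148

    def test_override(self):
        assert choose_k_rresolver(100, 250, AlgorithmParams(k_rresolver=120)) == 120

    def test_too_small_rejected(self):
        with pytest.raises(ConfigurationError):
            choose_k_rresolver(100, 100, AlgorithmParams())
        with pytest.raises(ConfigurationError):
            choose_k_rresolver(100, 250, AlgorithmParams(k_rresolver=90))


class TestResolveGraph:
    def test_end_to_end_recovery(self):
        genome, truth, library, graph = small_sim_instance(seed=7)
        params = AlgorithmParams(k_rresolver=91, bloom_bits=1 << 24, seed=7)
        kmers_before = {
            canonical(n.sequence[i : i + 31])
            for n in graph.nodes.values()
            for i in range(len(n.sequence) - 30)
        }
        resolved, report = resolve_graph(graph, [library], params)
        score = score_resolution(resolved, truth, 31)
        assert score.chimeric_junctions == 0
        assert score.resolved_repeats == score.total_repeats == 2
        assert score.contig_count == 1
        assert validate_graph(resolved) == []
        # sequence conservation: no k_assembly-mer content destroyed
        kmers_after = {
            canonical(n.sequence[i : i + 31])
            for n in resolved.nodes.values()
            for i in range(len(n.sequence) - 30)
        }
        assert kmers_before <= kmers_after

    def test_two_passes_per_library(self):
        _, _, library, graph = small_sim_instance(seed=7)
        params = AlgorithmParams(k_rresolver=91, bloom_bits=1 << 24, seed=7)
        _, report = resolve_graph(graph, [library], params)
        assert [r.iteration for r in report.rows] == [1, 2]

    def test_shortest_library_first(self):
        genome, truth, lib_long, graph = small_sim_instance(seed=9)
        lib_short = simulate_reads(
            genome, ReadSimSpec(read_length=80, fold_coverage=5.0, seed=9)
        )
        params = AlgorithmParams(bloom_bits=1 << 24, seed=9)
        _, report = resolve_graph(graph, [lib_long, lib_short], params)
        lengths = [r.read_length for r in report.rows]
        assert lengths == sorted(lengths)
        assert lengths[0] == 80

    def test_counter_consistency(self):
        _, _, library, graph = small_sim_instance(seed=8)
        params = AlgorithmParams(k_rresolver=91, bloom_bits=1 << 24, seed=8)
        _, report = resolve_graph(graph, [library], params)
        for r in report.rows:
            assert (
                r.sites_resolved + r.sites_simplified + r.sites_skipped + r.sites_unchanged
                == r.sites_found
            )

    def test_skip_safety_low_coverage(self):
        _, _, lib40, graph = small_sim_instance(seed=11)
        for n in graph.nodes.values():
            n.cov_sum *= 2.0 / 40.0
        rng = random.Random(11)
        sub = ReadLibrary(
            lib40.read_length, rng.sample(lib40.reads, len(lib40.reads) // 20)
        )
        params = AlgorithmParams(k_rresolver=91, bloom_bits=1 << 24, seed=11)
        before = graph.copy()
        resolved, report = resolve_graph(graph, [sub], params)
        assert report.total_edits() == 0
        assert all(r.sites_skipped == r.sites_found for r in report.rows)
        assert resolved == before

    def test_deterministic_given_seed(self):
        outs = []
        for _ in range(2):
            _, _, library, graph = small_sim_instance(seed=13)
            params = AlgorithmParams(k_rresolver=91, bloom_bits=1 << 24, seed=13)
            resolved, _ = resolve_graph(graph, [library], params)
            outs.append(
                sorted((i, n.sequence, n.cov_sum) for i, n in resolved.nodes.items())
            )
        assert outs[0] == outs[1]

    def test_requires_library(self):
        _, _, _, graph = small_sim_instance(seed=7)
        with pytest.raises(ConfigurationError):
            resolve_graph(graph, [], AlgorithmParams())
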