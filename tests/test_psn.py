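"""Persistence networks: contact, salt bridge, hydrogen bond, cutoff scan."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mutassess import synthetic as syn
from mutassess.ensemble_io import sidechain_center_of_mass
from mutassess.psn import (
    build_contact_psn,
    build_hbond_network,
    build_salt_bridge_network,
    connected_components,
    cutoff_scan,
    edge_table,
    hubs,
)

from conftest import graph_from_edges, residue


def brute_force_contact_adjacency(ensemble, cutoff, persistence_cutoff, seq_excl=1):
    """Independent oracle: per-atom COM summation, double loop over frames/pairs."""
    res = ensemble.residues
    edges = {}
    for i, j in itertools.combinations(range(len(res)), 2):
        if res[i].chain == res[j].chain and abs(res[i].position - res[j].position) <= seq_excl:
            continue
        hits = 0
        for f in range(ensemble.n_frames):
            a = sidechain_center_of_mass(ensemble, res[i], f)
            b = sidechain_center_of_mass(ensemble, res[j], f)
            if float(np.sqrt(((a - b) ** 2).sum())) < cutoff:
                hits += 1
        p = 100.0 * hits / ensemble.n_frames
        if p >= persistence_cutoff:
            edges[(res[i], res[j])] = p
    return edges


class TestContactPSN:
    def test_always_in_contact_pair_weight_100(self):
        ens = syn.make_toy_ensemble(6, {(2, 5): 100.0}, n_frames=10, seed=0)
        g = build_contact_psn(ens)
        (a, b, d), = list(g.edges(data=True))
        assert {a.position, b.position} == {2, 5}
        assert d["persistence"] == pytest.approx(100.0)

    def test_sub_threshold_persistence_drops_edge(self):
        ens = syn.make_toy_ensemble(6, {(2, 5): 15.0}, n_frames=20, seed=0)
        assert build_contact_psn(ens, persistence_cutoff=20.0).number_of_edges() == 0

    def test_inclusive_threshold_keeps_exact_20_percent(self):
        ens = syn.make_toy_ensemble(6, {(2, 5): 20.0}, n_frames=20, seed=0)
        g = build_contact_psn(ens, persistence_cutoff=20.0)
        assert g.number_of_edges() == 1

    def test_matches_exhaustive_oracle_on_planted_schedule(self, toy_ensemble):
        g = build_contact_psn(toy_ensemble, 5.0, 20.0)
        oracle = brute_force_contact_adjacency(toy_ensemble, 5.0, 20.0)
        got = {tuple(sorted((a, b))): d["persistence"] for a, b, d in g.edges(data=True)}
        assert set(got) == {tuple(sorted(k)) for k in oracle}
        for pair, p in oracle.items():
            assert got[tuple(sorted(pair))] == pytest.approx(p)

    @pytest.mark.parametrize("noise", [0.0, 0.1])
    def test_oracle_equivalence_with_jitter(self, noise):
        ens = syn.make_toy_ensemble(
            10, {(2, 7): 60.0, (3, 9): 35.0}, n_frames=30, seed=4, noise=noise
        )
        g = build_contact_psn(ens, 5.0, 20.0)
        oracle = brute_force_contact_adjacency(ens, 5.0, 20.0)
        got = {tuple(sorted((a, b))): d["persistence"] for a, b, d in g.edges(data=True)}
        assert got == {tuple(sorted(k)): pytest.approx(v) for k, v in oracle.items()}

    def test_single_residue_gives_empty_graph(self):
        ens = syn.make_toy_ensemble(2, None, n_frames=2, seed=0)
        sub = type(ens)(
            [a for a in ens.atoms if a.residue.position == 1],
            ens.coords[:, [i for i, a in enumerate(ens.atoms) if a.residue.position == 1], :],
        )
        assert build_contact_psn(sub).number_of_edges() == 0

    def test_bad_cutoff_raises(self, toy_ensemble):
        with pytest.raises(ValueError):
            build_contact_psn(toy_ensemble, distance_cutoff=-1.0)

    def test_frame_permutation_invariance(self, toy_ensemble):
        perm = np.random.default_rng(0).permutation(toy_ensemble.n_frames)
        permuted = toy_ensemble.subset_frames(perm)
        g1 = build_contact_psn(toy_ensemble)
        g2 = build_contact_psn(permuted)
        assert edge_table(g1).equals(edge_table(g2))

    def test_smaller_cutoff_graph_is_subgraph_of_larger(self, toy_ensemble):
        g_small = build_contact_psn(toy_ensemble, 4.5, 20.0)
        g_large = build_contact_psn(toy_ensemble, 5.5, 20.0)
        assert set(g_small.edges) <= set(g_large.edges)

    def test_raising_persistence_cutoff_never_adds_edges(self, toy_ensemble):
        lo = build_contact_psn(toy_ensemble, 5.0, 20.0)
        hi = build_contact_psn(toy_ensemble, 5.0, 60.0)
        assert set(hi.edges) <= set(lo.edges)


class TestHubsAndComponents:
    def test_star_graph_threshold_boundary(self):
        g = graph_from_edges([(1, 2), (1, 3), (1, 4)])
        h = hubs(g, min_degree=3)
        assert set(h) == {residue(1)} and h[residue(1)] == 3

    def test_empty_graph(self):
        g = graph_from_edges([])
        assert hubs(g) == {}
        assert connected_components(g) == ([], [])

    def test_hub_set_equals_degree_count_oracle(self, rng):
        base = nx.gnp_random_graph(30, 0.12, seed=42)
        g = graph_from_edges([(u + 1, v + 1) for u, v in base.edges()])
        adjacency = {}
        for a, b in g.edges:
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
        expected = {n for n, nb in adjacency.items() if len(nb) >= 3}
        assert set(hubs(g, 3)) == expected

    def test_two_triangles(self):
        g = graph_from_edges([(1, 2), (2, 3), (1, 3), (10, 11), (11, 12), (10, 12)])
        comps, singles = connected_components(g)
        assert sorted(len(c) for c in comps) == [3, 3] and singles == []

    def test_complete_graph_single_component(self):
        g = graph_from_edges(list(itertools.combinations(range(1, 6), 2)))
        comps, _ = connected_components(g)
        assert len(comps) == 1 and len(comps[0]) == 5

    def test_components_match_flood_fill_oracle(self):
        base = nx.gnp_random_graph(25, 0.08, seed=7)
        g = graph_from_edges([(u + 1, v + 1) for u, v in base.edges()])

        def flood(start, seen):
            stack, comp = [start], set()
            while stack:
                n = stack.pop()
                if n in comp:
                    continue
                comp.add(n)
                seen.add(n)
                stack.extend(g[n])
            return comp

        seen, expected = set(), []
        for n in g.nodes:
            if n not in seen:
                expected.append(flood(n, seen))
        exp_multi = sorted((frozenset(c) for c in expected if len(c) > 1), key=len)
        got_multi = sorted((frozenset(c) for c in connected_components(g)[0]), key=len)
        assert got_multi == exp_multi


class TestSaltBridges:
    def test_full_persistence_bridge(self):
        ens = syn.make_charged_pair_ensemble(100.0, 10)
        g, recs = build_salt_bridge_network(ens)
        assert len(recs) == 1 and recs[0].persistence == pytest.approx(100.0)
        assert g.number_of_edges() == 1

    def test_beyond_cutoff_never_recorded(self):
        ens = syn.make_charged_pair_ensemble(0.0, 10)
        g, recs = build_salt_bridge_network(ens, distance_cutoff=4.5)
        assert recs == [] and g.number_of_edges() == 0

    def test_high_persistence_value_recovered(self, charged_pair_998):
        _, recs = build_salt_bridge_network(charged_pair_998)
        assert len(recs) == 1
        assert recs[0].persistence == pytest.approx(99.8, abs=100.0 / charged_pair_998.n_frames)

    def test_boundary_20_percent_kept(self):
        ens = syn.make_charged_pair_ensemble(20.0, 20)
        g, recs = build_salt_bridge_network(ens, persistence_cutoff=20.0)
        assert g.number_of_edges() == 1 and recs[0].persistence == pytest.approx(20.0)

    def test_edge_types_are_acidic_basic_pairs(self, toy_ensemble):
        _, recs = build_salt_bridge_network(toy_ensemble)
        for r in recs:
            types = {r.residue_a.name, r.residue_b.name}
            assert types & {"ASP", "GLU"} and types & {"LYS", "ARG"}

    def test_no_charged_residues_empty_network(self):
        ens = syn.make_toy_ensemble(4, None, n_frames=2, seed=0, residue_names=["ALA"] * 4)
        g, recs = build_salt_bridge_network(ens)
        assert recs == [] and g.number_of_edges() == 0


class TestHBonds:
    def test_close_donor_acceptor_full_weight(self):
        # two serines with OG at 2.9 A (no hydrogens -> distance criterion)
        ens = syn.make_toy_ensemble(6, None, n_frames=4, seed=0, residue_names=["SER"] * 6)
        coords = ens.coords.copy()
        iog = [i for i, a in enumerate(ens.atoms) if a.atom_name == "OG"]
        r1, r4 = iog[0], iog[3]
        coords[:, r4, :] = coords[:, r1, :] + np.array([2.9, 0.0, 0.0])
        ens2 = type(ens)(ens.atoms, coords)
        g, recs = build_hbond_network(ens2)
        pairs = {frozenset((r.residue_a.position, r.residue_b.position)) for r in recs}
        assert frozenset((1, 4)) in pairs
        rec = next(r for r in recs if frozenset((r.residue_a.position, r.residue_b.position)) == frozenset((1, 4)))
        assert rec.persistence == pytest.approx(100.0)

    def test_distant_pair_no_edge(self):
        ens = syn.make_toy_ensemble(6, None, n_frames=4, seed=0, residue_names=["SER"] * 6)
        g, recs = build_hbond_network(ens)  # ring OGs are ~12 A apart
        assert g.number_of_edges() == 0

    def test_matches_brute_force_distance_criterion(self, toy_ensemble):
        g, recs = build_hbond_network(toy_ensemble, persistence_cutoff=20.0)
        from mutassess.psn import HBOND_ACCEPTORS, HBOND_DONORS

        def atoms_of(res, table):
            return [
                i
                for i in toy_ensemble.atom_indices(res)
                if toy_ensemble.atoms[i].atom_name in table.get(res.name.upper(), ())
            ]

        expected = set()
        res = toy_ensemble.residues
        for rd in res:
            for ra in res:
                if rd == ra or abs(rd.position - ra.position) <= 1:
                    continue
                di, ai = atoms_of(rd, HBOND_DONORS), atoms_of(ra, HBOND_ACCEPTORS)
                if not di or not ai:
                    continue
                hits = 0
                for f in range(toy_ensemble.n_frames):
                    dmin = min(
                        np.linalg.norm(toy_ensemble.coords[f, i] - toy_ensemble.coords[f, j])
                        for i in di
                        for j in ai
                    )
                    hits += dmin < 3.5
                if 100.0 * hits / toy_ensemble.n_frames >= 20.0:
                    expected.add(frozenset((rd, ra)))
        got = {frozenset((a, b)) for a, b in g.edges}
        assert got == expected


class TestCutoffScan:
    def test_no_resampling_identity(self, toy_ensemble):
        table = cutoff_scan(toy_ensemble, [4.5, 5.5], resample_fraction=1.0, repetitions=1)
        for cutoff, row in zip([4.5, 5.5], table.itertuples()):
            g = build_contact_psn(toy_ensemble, cutoff, 20.0)
            assert row.edges_mean == g.number_of_edges() and row.edges_sd == 0.0
            assert row.hubs_mean == len(hubs(g))

    def test_edge_count_monotone_in_cutoff(self, toy_ensemble):
        table = cutoff_scan(toy_ensemble, [4.5, 5.5], resample_fraction=1.0, repetitions=1)
        assert table.edges_mean.iloc[1] >= table.edges_mean.iloc[0]

    def test_seeded_reproducibility(self, toy_ensemble):
        t1 = cutoff_scan(toy_ensemble, [4.0, 5.0], 0.8, 5, seed=99)
        t2 = cutoff_scan(toy_ensemble, [4.0, 5.0], 0.8, 5, seed=99)
        assert t1.equals(t2)

    def test_bad_fraction_raises(self, toy_ensemble):
        with pytest.raises(ValueError):
            cutoff_scan(toy_ensemble, [4.0, 5.0], resample_fraction=1.5)
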