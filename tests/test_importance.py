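"""Importance statistic D, ranking, gate/hub labels, pathways, fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gnmgates import (
    ValidationError,
    build_kirchhoff,
    classify_gates_hubs,
    eigendecompose,
    extract_paths,
    generate_synthetic_structure,
    mode_correlation,
    rank_residues,
    residue_importance,
    spring_energy_fractions,
    spring_fluctuation,
)
from gnmgates.importance import ImportanceProfile

from conftest import (
    connected_cluster,
    make_records,
    network_from_adjacency,
    random_connected_network,
)


def brute_force_contact_sum(net, spec):
    """Independent oracle: double loop over the contact pattern applying
    C_ii + C_jj - 2 C_ij with the max-mode correlation."""
    C = mode_correlation(spec, "max")
    n = net.n
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and net.matrix[i, j] != 0:
                out[i] += spring_fluctuation(C, i, j)
    return out


class TestResidueImportance:
    def test_ring_symmetry_gives_equal_values(self):
        structure = generate_synthetic_structure("ring", 12)
        net = build_kirchhoff(structure)
        prof = residue_importance(net, eigendecompose(net))
        np.testing.assert_allclose(prof.values, prof.values[0], rtol=1e-9)

    def test_contact_sum_matches_double_loop_oracle(self):
        net = random_connected_network(10, seed=4)
        spec = eigendecompose(net)
        prof = residue_importance(net, spec, variant="contact_sum")
        np.testing.assert_allclose(prof.values,
                                   brute_force_contact_sum(net, spec),
                                   atol=1e-10)

    def test_all_pairs_closed_form_identity(self):
        # sum over all j != i equals (n u_i^2 + 1)/lambda_max by
        # orthonormality of the top eigenvector
        net = random_connected_network(14, seed=9)
        spec = eigendecompose(net)
        prof = residue_importance(net, spec, variant="all_pairs")
        u = spec.eigenvectors[:, -1]
        expected = (net.n * u**2 + 1.0) / spec.lambda_max
        np.testing.assert_allclose(prof.values, expected, atol=1e-10)

    def test_values_invariant_under_eigenvector_sign_flip(self, cluster30,
                                                          cluster30_spectrum):
        _, net = cluster30
        spec = cluster30_spectrum
        flipped = type(spec)(
            eigenvalues=spec.eigenvalues.copy(),
            eigenvectors=-spec.eigenvectors,
            zero_mode_count=spec.zero_mode_count,
            kT=spec.kT,
            gamma=spec.gamma,
        )
        a = residue_importance(net, spec).values
        b = residue_importance(net, flipped).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_isolated_residue_gets_zero_with_warning(self, caplog):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = adj[0, 2] = adj[2, 0] = True
        net = network_from_adjacency(adj)  # node 3 isolated
        prof = residue_importance(net, eigendecompose(net))
        assert prof.values[3] == 0.0

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_leaves_profile_unchanged(self, seed):
        structure, net = connected_cluster(15, seed=seed % 50)
        rng = np.random.default_rng(seed)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = structure.transformed(Q, rng.standard_normal(3) * 30.0)
        net2 = build_kirchhoff(moved)
        a = residue_importance(net, eigendecompose(net)).values
        b = residue_importance(net2, eigendecompose(net2)).values
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestRanking:
    def test_sorting_with_explicit_values(self):
        records = make_records(3)  # author numbers 1, 2, 3
        prof = ImportanceProfile(values=np.array([0.1, 0.9, 0.4]),
                                 records=records)
        top2 = rank_residues(prof, 2)
        assert [r.author_seq_number for r in top2] == [2, 3]

    def test_ties_broken_by_ascending_author_number(self):
        structure = generate_synthetic_structure("ring", 12)
        net = build_kirchhoff(structure)
        prof = residue_importance(net, eigendecompose(net))
        top3 = rank_residues(prof, 3)
        assert [r.author_seq_number for r in top3] == [1, 2, 3]

    def test_top_k_bounds(self):
        records = make_records(3)
        prof = ImportanceProfile(values=np.zeros(3), records=records)
        with pytest.raises(ValidationError):
            rank_residues(prof, 0)
        with pytest.raises(ValidationError):
            rank_residues(prof, 4)


class TestGateHubClassification:
    def test_degree_extremes_get_expected_labels(self):
        # two triangles sharing node 2, pendant node 5 on node 0:
        # degrees [3, 2, 4, 2, 2, 1], median 2 -> node 2 buried (hub),
        # node 5 loosely packed (gate)
        edges = [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (2, 4), (0, 5)]
        adj = np.zeros((6, 6), dtype=bool)
        for a, b in edges:
            adj[a, b] = adj[b, a] = True
        net = network_from_adjacency(adj)
        prof = residue_importance(net, eigendecompose(net))
        labels = classify_gates_hubs(net, prof, top_k=6)
        assert labels[2] == "hub"
        assert labels[5] == "gate"

    def test_only_top_k_residues_are_labeled(self, cluster30, cluster30_spectrum):
        _, net = cluster30
        prof = residue_importance(net, cluster30_spectrum)
        labels = classify_gates_hubs(net, prof, top_k=5)
        labeled = [l for l in labels if l != "unlabeled"]
        assert len(labeled) == 5
        assert set(labeled) <= {"gate", "hub"}

    def test_quantile_bounds_checked(self, cluster30, cluster30_spectrum):
        _, net = cluster30
        prof = residue_importance(net, cluster30_spectrum)
        with pytest.raises(ValidationError):
            classify_gates_hubs(net, prof, top_k=5, surface_degree_quantile=1.0)


class TestExtractPaths:
    def _profile_with_top(self, net, top_indices):
        """Profile whose ranking puts the given internal indices first."""
        values = np.zeros(net.n)
        for r, idx in enumerate(top_indices):
            values[idx] = 100.0 - r
        return ImportanceProfile(values=values, records=list(net.index_map))

    def test_mutually_noncontacting_top_residues_give_no_paths(self):
        structure = generate_synthetic_structure("chain", 9, spacing=3.8)
        net = build_kirchhoff(structure)  # consecutive contacts only
        prof = self._profile_with_top(net, [0, 4, 8])
        assert extract_paths(net, prof, top_k=3) == []

    def test_simple_chain_of_four(self):
        structure = generate_synthetic_structure("chain", 8, spacing=3.8)
        net = build_kirchhoff(structure)
        prof = self._profile_with_top(net, [2, 3, 4, 5])
        paths = extract_paths(net, prof, top_k=4)
        assert len(paths) == 1
        p = paths[0]
        assert [net.index_map[i].author_seq_number for i in p.members] == [3, 4, 5, 6]
        assert sorted(net.index_map[e].author_seq_number for e in p.endpoints) \
            == [3, 6]

    def test_components_match_union_find_oracle(self):
        structure, net = connected_cluster(20, seed=13)
        prof = residue_importance(net, eigendecompose(net))
        top = prof.ranking[:10]
        paths = extract_paths(net, prof, top_k=10)

        # independent union-find over the induced subgraph
        parent = {i: i for i in top}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for ai, a in enumerate(top):
            for b in top[ai + 1:]:
                if net.matrix[a, b] != 0:
                    parent[find(a)] = find(b)
        from collections import defaultdict

        comps = defaultdict(set)
        for i in top:
            comps[find(i)].add(i)
        expected = sorted(
            frozenset(c) for c in comps.values() if len(c) >= 2
        )
        got = sorted(frozenset(p.members) for p in paths)
        assert got == expected

    def test_consecutive_members_are_in_contact(self, cluster30,
                                                cluster30_spectrum):
        _, net = cluster30
        prof = residue_importance(net, cluster30_spectrum)
        for p in extract_paths(net, prof, top_k=10):
            for a, b in zip(p.members, p.members[1:]):
                # BFS order: each member is adjacent to some earlier member
                assert any(net.matrix[b, c] != 0
                           for c in p.members[:p.members.index(b)])
            assert net.matrix[p.members[0], p.members[1]] != 0


class TestSpringEnergyFractions:
    def test_single_spring_fraction_is_one(self):
        adj = np.array([[False, True], [True, False]])
        net = network_from_adjacency(adj)
        fr = spring_energy_fractions(net, eigendecompose(net))
        assert fr == {(0, 1): pytest.approx(1.0, abs=1e-15)}

    def test_ring_fractions_all_equal(self):
        structure = generate_synthetic_structure("ring", 12)
        net = build_kirchhoff(structure)
        fr = spring_energy_fractions(net, eigendecompose(net))
        assert len(fr) == 12
        np.testing.assert_allclose(list(fr.values()), 1.0 / 12.0, rtol=1e-9)

    def test_fractions_normalized_and_nonnegative(self):
        net = random_connected_network(10, seed=21)
        fr = spring_energy_fractions(net, eigendecompose(net))
        total = sum(fr.values())
        assert total == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0.0 for v in fr.values())
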