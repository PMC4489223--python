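import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgdock.postprocess import (
    ClusteringConfig,
    FilteredSet,
    consensus_cluster,
    filter_trajectory,
    kmedoids_once,
    pose_distance,
    pose_distance_matrix,
)
from cgdock.sampler import Trajectory

from conftest import make_snapshot


def synthetic_trajectory(helix20_cg, n, bound_mask=None, energies=None,
                         rng=None):
    rng = rng or np.random.default_rng(0)
    snaps = []
    for i in range(n):
        e = energies[i] if energies is not None else float(rng.normal())
        bound = bound_mask[i] if bound_mask is not None else True
        base = np.array([12.0, 0.0, i * 0.01])
        pep = base + np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        snaps.append(make_snapshot(helix20_cg, pep, e_binding=e, index=i,
                                   bound=bound))
    return Trajectory(replica_index=0, snapshots=snaps)


class TestFilterTrajectory:
    def test_all_bound_keeps_100_lowest(self, helix20_cg, rng):
        energies = list(rng.normal(size=1000))
        t = synthetic_trajectory(helix20_cg, 1000, energies=energies)
        fs = filter_trajectory(t)
        assert len(fs) == 100
        kept = sorted(m.energy_binding for m in fs.models)
        dropped = sorted(energies)[100:]
        assert kept[-1] <= min(dropped)

    def test_fewer_bound_keeps_all(self, helix20_cg):
        mask = [i < 40 for i in range(200)]
        t = synthetic_trajectory(helix20_cg, 200, bound_mask=mask)
        assert len(filter_trajectory(t)) == 40

    def test_no_bound_states_warns_empty(self, helix20_cg):
        t = synthetic_trajectory(helix20_cg, 50, bound_mask=[False] * 50)
        with pytest.warns(UserWarning, match="no bound states"):
            fs = filter_trajectory(t)
        assert len(fs) == 0

    def test_sorted_by_binding_energy(self, helix20_cg):
        t = synthetic_trajectory(helix20_cg, 300)
        fs = filter_trajectory(t)
        e = [m.energy_binding for m in fs.models]
        assert e == sorted(e)

    def test_stable_tie_break_by_snapshot_index(self, helix20_cg):
        t = synthetic_trajectory(helix20_cg, 10, energies=[0.0] * 10)
        fs = filter_trajectory(t, max_models=5)
        assert [m.snapshot_index for m in fs.models] == [0, 1, 2, 3, 4]

    def test_idempotent_count_formula(self, helix20_cg, rng):
        trajs = []
        bound_counts = []
        for k, n_bound in enumerate((150, 40, 0)):
            mask = [i < n_bound for i in range(200)]
            trajs.append(synthetic_trajectory(helix20_cg, 200,
                                              bound_mask=mask))
            bound_counts.append(n_bound)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            total = sum(len(filter_trajectory(t)) for t in trajs)
        assert total == sum(min(100, b) for b in bound_counts)


class TestPoseDistance:
    def test_identity(self, snapshot_factory):
        a = snapshot_factory([[12, 0, 0], [15.8, 0, 0], [19.6, 0, 0]])
        assert pose_distance(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_global_rigid_motion_removed(self, snapshot_factory, rng):
        pep = np.array([[12.0, 0, 0], [15.8, 0, 0], [19.6, 0, 0]])
        a = snapshot_factory(pep)
        b = snapshot_factory(pep)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(scale=20, size=3)
        for chain in (b.complex.receptor, b.complex.peptide):
            chain.ca = chain.ca @ rot.T + shift
            chain.sc = chain.sc @ rot.T + shift
        assert pose_distance(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry(self, snapshot_factory, rng):
        a = snapshot_factory(rng.normal(scale=10, size=(4, 3)))
        b = snapshot_factory(rng.normal(scale=10, size=(4, 3)))
        assert pose_distance(a, b) == pytest.approx(pose_distance(b, a),
                                                    abs=1e-6)

    def test_matches_two_stage_oracle(self, snapshot_factory, rng):
        # oracle: scipy align_vectors for the receptor fit, explicit sum
        for _ in range(5):
            a = snapshot_factory(rng.normal(scale=8, size=(4, 3)))
            b = snapshot_factory(rng.normal(scale=8, size=(4, 3)))
            # perturb receptor b slightly so the fit is nontrivial
            b.complex.receptor.ca = (b.complex.receptor.ca
                                     + rng.normal(scale=0.3, size=(20, 3)))
            ra = a.complex.receptor.ca
            rb = b.complex.receptor.ca
            rot, _ = Rotation.align_vectors(ra - ra.mean(0), rb - rb.mean(0))
            pep_b = rot.apply(b.complex.peptide.ca - rb.mean(0)) + ra.mean(0)
            expected = np.sqrt(
                ((pep_b - a.complex.peptide.ca) ** 2).sum() / 4)
            assert pose_distance(a, b) == pytest.approx(expected, abs=1e-6)

    def test_matrix_matches_pairwise(self, snapshot_factory, rng):
        models = [
            snapshot_factory(rng.normal(scale=8, size=(4, 3)))
            for _ in range(9)
        ]
        for m in models:
            m.complex.receptor.ca = (m.complex.receptor.ca
                                     + rng.normal(scale=0.2, size=(20, 3)))
        dm = pose_distance_matrix(models)
        for i in range(9):
            for j in range(9):
                expected = 0.0 if i == j else pose_distance(models[i],
                                                            models[j])
                assert dm[i, j] == pytest.approx(expected, abs=1e-9)


class TestKMedoids:
    def test_two_triads_match_exhaustive(self):
        pts = np.array([
            [0.0, 0], [0.2, 0.1], [0.1, -0.1],
            [10.0, 0], [10.2, 0.1], [10.1, -0.1],
        ])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        best_cost = np.inf
        best = None
        for pair in itertools.combinations(range(6), 2):
            cost = d[:, pair].min(axis=1).sum()
            if cost < best_cost - 1e-12:
                best_cost, best = cost, set(pair)
        medoids, _, cost = kmedoids_once(d, 2, np.random.default_rng(0))
        assert set(medoids) == best
        assert cost == pytest.approx(best_cost)

    def test_k_equals_n(self, rng):
        pts = rng.normal(size=(5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        medoids, assign, cost = kmedoids_once(d, 5, rng)
        assert cost == 0.0
        assert sorted(medoids) == list(range(5))

    def test_duplicates_tie_break_lowest_index(self):
        d = np.zeros((4, 4))
        medoids, _, cost = kmedoids_once(d, 1, np.random.default_rng(3))
        assert cost == 0.0
        assert medoids[0] == 0

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            kmedoids_once(np.zeros((3, 3)), 4, np.random.default_rng(0))


def blob_filtered_set(snapshot_factory, rng, n_blobs=10, per_blob=12):
    models, prov = [], []
    centers = rng.normal(scale=60, size=(n_blobs, 3))
    idx = 0
    for b in range(n_blobs):
        for _ in range(per_blob):
            base = centers[b] + rng.normal(scale=0.2, size=3)
            pep = base + np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
            models.append(snapshot_factory(pep, e_binding=rng.normal(),
                                           index=idx))
            prov.append((0, idx))
            idx += 1
    return FilteredSet(models, prov), centers


class TestConsensus:
    def test_k10_returns_10_models(self, snapshot_factory, rng):
        fs, _ = blob_filtered_set(snapshot_factory, rng)
        final = consensus_cluster(fs, ClusteringConfig(seed=0))
        assert len(final) == 10
        assert final.restarts_performed == 100

    def test_blobs_all_hit(self, snapshot_factory, rng):
        fs, centers = blob_filtered_set(snapshot_factory, rng)
        final = consensus_cluster(fs, ClusteringConfig(seed=1))
        hit = set()
        for m in final.medoids:
            c = m.complex.peptide.ca[0]
            hit.add(int(np.argmin(np.linalg.norm(centers - c, axis=1))))
        assert hit == set(range(10))

    def test_medoids_are_members_and_partition(self, snapshot_factory, rng):
        fs, _ = blob_filtered_set(snapshot_factory, rng)
        final = consensus_cluster(fs, ClusteringConfig(seed=2))
        assert all(0 <= i < len(fs) for i in final.medoid_indices)
        all_members = sorted(sum(final.cluster_members, []))
        assert all_members == list(range(len(fs)))

    def test_order_invariance(self, snapshot_factory, rng):
        fs, _ = blob_filtered_set(snapshot_factory, rng)
        perm = np.random.default_rng(9).permutation(len(fs))
        fs2 = FilteredSet([fs.models[i] for i in perm],
                          [fs.provenance[i] for i in perm])
        f1 = consensus_cluster(fs, ClusteringConfig(seed=3))
        f2 = consensus_cluster(fs2, ClusteringConfig(seed=3))
        pos1 = sorted(tuple(m.complex.peptide.ca[0].round(6))
                      for m in f1.medoids)
        pos2 = sorted(tuple(m.complex.peptide.ca[0].round(6))
                      for m in f2.medoids)
        assert pos1 == pos2

    def test_small_set_reduces_k(self, snapshot_factory, rng):
        fs, _ = blob_filtered_set(snapshot_factory, rng, n_blobs=2,
                                  per_blob=3)
        with pytest.warns(UserWarning, match="reducing k"):
            final = consensus_cluster(fs, ClusteringConfig(k=10, seed=0))
        assert len(final) == 6

    def test_cluster_statistics(self, snapshot_factory, rng):
        fs, _ = blob_filtered_set(snapshot_factory, rng)
        final = consensus_cluster(fs, ClusteringConfig(seed=4))
        dm = pose_distance_matrix(fs.models)
        for c, med in enumerate(final.medoid_indices):
            members = final.cluster_members[c]
            dists = dm[members, med]
            assert final.density[c] == pytest.approx(dists.mean(), abs=1e-9)
            assert final.diversity[c] == pytest.approx(dists.max(), abs=1e-9)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            consensus_cluster(FilteredSet(), ClusteringConfig())
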