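"""Model selection: per-trajectory filtering and consensus k-medoids.

From each trajectory, unbound snapshots are excluded and the 100 lowest
binding-energy models are kept (fewer when a trajectory has fewer bound
states). The pooled filtered set is clustered 100 times with different
initial medoids and k = 10; the 10 consensus medoids are the final models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cg_model import CGSnapshot, kabsch_rotation
from .energy import BOUND_CUTOFF
from .sampler import Trajectory

__all__ = [
    "FilteredSet",
    "ClusteringConfig",
    "FinalModelSet",
    "filter_trajectory",
    "pose_distance",
    "pose_distance_matrix",
    "kmedoids_once",
    "consensus_cluster",
    "MODELS_PER_TRAJECTORY",
]

MODELS_PER_TRAJECTORY = 100
DEFAULT_K = 10
DEFAULT_RESTARTS = 100


@dataclass
class FilteredSet:
    models: list[CGSnapshot] = field(default_factory=list)
    provenance: list[tuple[int, int]] = field(default_factory=list)  # (replica, snap idx)

    def __len__(self) -> int:
        return len(self.models)

    def extend(self, other: "FilteredSet") -> None:
        self.models.extend(other.models)
        self.provenance.extend(other.provenance)


@dataclass
class ClusteringConfig:
    k: int = DEFAULT_K
    n_restarts: int = DEFAULT_RESTARTS
    metric: str = "receptor_superposed_peptide_rmsd"
    consensus: str = "frequency"  # or "best_cost"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.n_restarts < 1:
            raise ValueError("k and n_restarts must be positive")


@dataclass
class FinalModelSet:
    medoids: list[CGSnapshot]
    medoid_indices: list[int]           # indices into the filtered set
    assignment: np.ndarray              # filtered-set index -> cluster id
    cluster_members: list[list[int]]
    density: list[float]                # mean member-to-medoid distance
    diversity: list[float]              # max member-to-medoid distance
    provenance: list[tuple[int, int]]
    restarts_performed: int = 0

    def __len__(self) -> int:
        return len(self.medoids)


def filter_trajectory(t: Trajectory, cutoff: float = BOUND_CUTOFF,
                      max_models: int = MODELS_PER_TRAJECTORY) -> FilteredSet:
    """Bound snapshots of one trajectory, sorted by binding energy, capped
    at ``max_models`` (stable tie-break by snapshot index)."""
    bound = [s for s in t.snapshots if s.bound]
    if not bound:
        warnings.warn(
            f"trajectory {t.replica_index}: no bound states", stacklevel=2
        )
        return FilteredSet()
    order = sorted(range(len(bound)),
                   key=lambda i: (bound[i].energy_binding, i))
    kept = [bound[i] for i in order[:max_models]]
    return FilteredSet(
        models=kept,
        provenance=[(s.replica_index, s.snapshot_index) for s in kept],
    )


def filter_trajectories(trajectories, cutoff: float = BOUND_CUTOFF,
                        max_models: int = MODELS_PER_TRAJECTORY) -> FilteredSet:
    fs = FilteredSet()
    for t in trajectories:
        fs.extend(filter_trajectory(t, cutoff=cutoff, max_models=max_models))
    return fs


def pose_distance(a: CGSnapshot, b: CGSnapshot) -> float:
    """Receptor-superposed peptide C-alpha RMSD between two poses.

    b's receptor is Kabsch-fitted onto a's receptor; the peptide RMSD is
    then taken without further fitting. Symmetric to numerical precision.
    """
    ca, cb = a.complex, b.complex
    r, t = kabsch_rotation(cb.receptor.ca, ca.receptor.ca)
    pep_b = cb.peptide.ca @ r.T + t
    diff = pep_b - ca.peptide.ca
    return float(np.sqrt((diff * diff).sum() / len(pep_b)))


def pose_distance_matrix(models, chunk: int = 64) -> np.ndarray:
    """Full symmetric pose-distance matrix, batched over pairs.

    Equivalent to calling :func:`pose_distance` on every pair, but uses
    stacked covariance/SVD computations to stay fast for ~1000 models.
    """
    models = list(models)
    n = len(models)
    rec = np.stack([m.complex.receptor.ca for m in models])
    pep = np.stack([m.complex.peptide.ca for m in models])
    rec_cent = rec.mean(axis=1, keepdims=True)
    rec_c = rec - rec_cent
    n_pep = pep.shape[1]

    dmat = np.zeros((n, n))
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        # Fit every model j in [s, e) onto every reference i.
        for i in range(n):
            js = np.arange(s, e)
            js = js[js > i]
            if not len(js):
                continue
            h = np.einsum("bki,kj->bij", rec_c[js], rec_c[i])
            u, _, vt = np.linalg.svd(h)
            det = np.linalg.det(np.einsum("bij,bjk->bik",
                                          np.transpose(vt, (0, 2, 1)),
                                          np.transpose(u, (0, 2, 1))))
            corr = np.repeat(np.eye(3)[None], len(js), axis=0)
            corr[:, 2, 2] = np.sign(det)
            rot = np.einsum("bij,bjk,bkl->bil",
                            np.transpose(vt, (0, 2, 1)), corr,
                            np.transpose(u, (0, 2, 1)))
            pep_fit = np.einsum(
                "bij,bkj->bki", rot, pep[js] - rec_cent[js]
            ) + rec_cent[i]
            diff = pep_fit - pep[i]
            rmsd = np.sqrt((diff * diff).sum(axis=(1, 2)) / n_pep)
            dmat[i, js] = rmsd
            dmat[js, i] = rmsd
    return dmat


def _seed_medoids(distances: np.ndarray, k: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Random initial medoids with D^2 weighting (k-means++ style), so
    independent restarts start from well-spread configurations."""
    n = len(distances)
    first = int(rng.integers(n))
    medoids = [first]
    d2 = distances[first] ** 2
    for _ in range(k - 1):
        total = d2.sum()
        if total <= 0:
            remaining = np.setdiff1d(np.arange(n), medoids)
            medoids.append(int(rng.choice(remaining)))
            continue
        nxt = int(rng.choice(n, p=d2 / total))
        medoids.append(nxt)
        d2 = np.minimum(d2, distances[nxt] ** 2)
    return np.sort(np.asarray(medoids))


def kmedoids_once(distances: np.ndarray, k: int, rng: np.random.Generator):
    """One PAM-style k-medoids run from random initial medoids.

    Alternates assignment and medoid update (member minimizing the
    within-cluster distance sum, ties to the lowest index) until the cost
    stops decreasing. Returns (medoid indices, assignment, cost).
    """
    n = len(distances)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} models")
    medoids = _seed_medoids(distances, k, rng)
    prev_cost = np.inf
    while True:
        assign = np.argmin(distances[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if not len(members):
                continue
            sub = distances[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[int(np.argmin(sub))]
        medoids = np.sort(new_medoids)
        assign = np.argmin(distances[:, medoids], axis=1)
        cost = float(distances[np.arange(n), medoids[assign]].sum())
        if cost >= prev_cost - 1e-12:
            return medoids, assign, cost
        prev_cost = cost


def consensus_cluster(fs: FilteredSet, cfg: ClusteringConfig,
                      distances: np.ndarray | None = None) -> FinalModelSet:
    """Consensus k-medoids over ``cfg.n_restarts`` independent restarts.

    Frequency consensus (default): each model is scored by how often it was
    selected as a medoid; the k most frequent win (ties broken by lower
    binding energy, then lower index). ``consensus="best_cost"`` instead
    returns the single lowest-cost run's medoids.
    """
    n = len(fs)
    k = cfg.k
    if n == 0:
        raise ValueError("cannot cluster an empty filtered set")
    if n < k:
        warnings.warn(f"only {n} models; reducing k from {k}", stacklevel=2)
        k = n
    if distances is None:
        distances = pose_distance_matrix(fs.models)

    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(cfg.seed).spawn(cfg.n_restarts)]
    freq = np.zeros(n, dtype=int)
    best_cost = np.inf
    best_medoids = None
    restarts = 0
    for rng in rngs:
        medoids, _, cost = kmedoids_once(distances, k, rng)
        freq[medoids] += 1
        if cost < best_cost:
            best_cost, best_medoids = cost, medoids
        restarts += 1

    if cfg.consensus == "best_cost":
        chosen = np.sort(best_medoids)
    else:
        e_bind = np.array([m.energy_binding for m in fs.models])
        order = np.lexsort((np.arange(n), e_bind, -freq))
        chosen = np.sort(order[:k])

    assign = np.argmin(distances[:, chosen], axis=1)
    members = [list(np.flatnonzero(assign == c)) for c in range(k)]
    density, diversity = [], []
    for c, med in enumerate(chosen):
        dists = distances[members[c], med] if members[c] else np.zeros(1)
        density.append(float(dists.mean()))
        diversity.append(float(dists.max()))
    return FinalModelSet(
        medoids=[fs.models[int(i)] for i in chosen],
        medoid_indices=[int(i) for i in chosen],
        assignment=assign,
        cluster_members=members,
        density=density,
        diversity=diversity,
        provenance=[fs.provenance[int(i)] for i in chosen],
        restarts_performed=restarts,
    )


def cluster_report_tsv(final: FinalModelSet, dest=None) -> str:
    lines = [
        "cluster\tsize\tdensity\tdiversity\tmedoid_replica"
        "\tmedoid_snapshot\te_binding"
    ]
    for c in range(len(final)):
        rep, snap = final.provenance[c]
        lines.append(
            f"{c}\t{len(final.cluster_members[c])}\t{final.density[c]:.3f}"
            f"\t{final.diversity[c]:.3f}\t{rep}\t{snap}"
            f"\t{final.medoids[c].energy_binding:.4f}"
        )
    text = "\n".join(lines) + "\n"
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)
    return text
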