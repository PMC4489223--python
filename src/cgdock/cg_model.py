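"""Coarse-grained representation and geometry.

Each residue carries two interaction centers: its C-alpha and a pseudo
side-chain centroid (coincident with the C-alpha for glycine). Peptide
conformers are self-avoiding off-lattice C-alpha walks with a fixed
3.8 A virtual bond.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .structures_io import PeptideSpec, ReceptorStructure, STANDARD_RESIDUES

__all__ = [
    "CGChain",
    "CGComplex",
    "CGSnapshot",
    "BOND_LENGTH",
    "BOND_TOLERANCE",
    "SC_DISTANCE",
    "build_cg",
    "peptide_chain",
    "longest_dimension",
    "random_peptide_conformation",
    "place_on_sphere",
    "place_sc_from_trace",
    "kabsch_rotation",
]

BOND_LENGTH = 3.8
BOND_TOLERANCE = 0.4
MIN_NONBONDED = 4.0
ANGLE_MIN_DEG = 75.0
ANGLE_MAX_DEG = 150.0

# Canonical |sc - ca| distance (A) used when side-chain atoms are absent.
SC_DISTANCE = {
    "A": 1.53, "R": 4.12, "N": 2.47, "D": 2.44, "C": 2.05,
    "Q": 3.07, "E": 3.11, "G": 0.00, "H": 3.14, "I": 2.31,
    "L": 2.60, "K": 3.52, "M": 2.95, "F": 3.41, "P": 1.87,
    "S": 1.90, "T": 1.93, "V": 1.97, "W": 3.86, "Y": 3.84,
}


@dataclass
class CGChain:
    """One chain (or concatenated multi-chain receptor) at CG resolution."""

    ca: np.ndarray                   # (n, 3)
    sc: np.ndarray                   # (n, 3)
    sequence: str
    ss: str
    chain_index: np.ndarray          # (n,) int, for sequence-gap rules
    chain_ids: list[str] | None = None        # per-residue author chain id
    author_ids: list[tuple[int, str]] | None = None  # (seq id, icode)

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.sc = np.asarray(self.sc, dtype=float)
        n = len(self.sequence)
        if not (self.ca.shape == self.sc.shape == (n, 3)):
            raise ValueError("ca/sc/sequence lengths disagree")
        if len(self.ss) != n:
            raise ValueError("ss length disagrees with sequence")

    @property
    def n(self) -> int:
        return len(self.sequence)

    def copy(self) -> "CGChain":
        return replace(self, ca=self.ca.copy(), sc=self.sc.copy())

    def bond_lengths(self) -> np.ndarray:
        """Consecutive C-alpha distances within each chain segment."""
        d = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
        same = self.chain_index[1:] == self.chain_index[:-1]
        return d[same]

    def centroid(self) -> np.ndarray:
        return self.ca.mean(axis=0)


@dataclass
class CGComplex:
    receptor: CGChain
    peptide: CGChain

    def copy(self) -> "CGComplex":
        return CGComplex(self.receptor.copy(), self.peptide.copy())


@dataclass
class CGSnapshot:
    """One recorded pose with replica/time metadata and energy terms."""

    complex: CGComplex
    replica_index: int
    macrocycle_index: int
    snapshot_index: int
    temperature: float
    energy_total: float
    energy_binding: float
    energy_restraint: float
    bound: bool = True


def build_cg(receptor: ReceptorStructure, ss: str | None = None) -> CGChain:
    """Project a validated all-atom receptor onto the CG representation.

    Side-chain centroid = mean of heavy side-chain atoms when present;
    otherwise placed along the C-alpha minus (N,C midpoint) direction at a
    per-residue-type canonical distance. Glycine: sc == ca.
    """
    n = receptor.n_residues
    ca = np.empty((n, 3))
    sc = np.empty((n, 3))
    seq = []
    chain_ids = []
    author_ids = []
    for g, chain_id, res in receptor.residues():
        one = STANDARD_RESIDUES.get(res.name, "X")
        seq.append(one)
        chain_ids.append(chain_id)
        author_ids.append(res.author_id)
        ca[g] = res.atoms["CA"]
        if one == "G":
            sc[g] = ca[g]
            continue
        side = res.side_chain_positions()
        if len(side):
            sc[g] = side.mean(axis=0)
        elif "N" in res.atoms and "C" in res.atoms:
            mid = 0.5 * (res.atoms["N"] + res.atoms["C"])
            direction = ca[g] - mid
            norm = np.linalg.norm(direction)
            if norm < 1e-9:
                direction, norm = np.array([0.0, 0.0, 1.0]), 1.0
            sc[g] = ca[g] + SC_DISTANCE.get(one, 2.5) * direction / norm
        else:
            sc[g] = np.nan  # C-alpha-only input: fill from the trace below
    sequence = "".join(seq)
    missing = np.isnan(sc).any(axis=1)
    if missing.any():
        sc[missing] = place_sc_from_trace(ca, sequence)[missing]
    return CGChain(
        ca=ca,
        sc=sc,
        sequence=sequence,
        ss=ss if ss is not None else "C" * n,
        chain_index=receptor.chain_index,
        chain_ids=chain_ids,
        author_ids=author_ids,
    )


def place_sc_from_trace(ca: np.ndarray, sequence: str) -> np.ndarray:
    """Pseudo side-chain centroids from a bare C-alpha trace.

    sc_i points away from the midpoint of the flanking C-alphas (the single
    neighbour for termini) at the canonical per-type distance.
    """
    n = len(sequence)
    ca = np.asarray(ca, dtype=float)
    sc = ca.copy()
    if n == 1:
        return sc
    mids = np.empty_like(ca)
    mids[1:-1] = 0.5 * (ca[:-2] + ca[2:])
    mids[0] = ca[1]
    mids[-1] = ca[-2]
    direction = ca - mids
    norms = np.linalg.norm(direction, axis=1)
    norms[norms < 1e-9] = 1.0
    unit = direction / norms[:, None]
    dist = np.array([SC_DISTANCE.get(a, 2.5) for a in sequence])
    return ca + unit * dist[:, None]


def peptide_chain(spec: PeptideSpec, ca: np.ndarray) -> CGChain:
    """Wrap a peptide C-alpha trace into a CGChain with derived sc centers."""
    return CGChain(
        ca=np.asarray(ca, dtype=float),
        sc=place_sc_from_trace(ca, spec.sequence),
        sequence=spec.sequence,
        ss=spec.ss_states,
        chain_index=np.zeros(len(spec), dtype=int),
    )


def longest_dimension(receptor: CGChain) -> float:
    """Maximum pairwise C-alpha distance (the receptor's longest dimension)."""
    if receptor.n < 2:
        raise ValueError("longest_dimension requires at least 2 residues")
    return float(pdist(receptor.ca).max())


def random_peptide_conformation(
    spec: PeptideSpec, rng: np.random.Generator, max_attempts: int = 1000
) -> CGChain:
    """Self-avoiding random C-alpha walk for the peptide.

    Bond length 3.8 A, pseudo-bond angle in [75, 150] deg, no nonconsecutive
    pair closer than 4.0 A. Deterministic given the generator state.
    """
    n = len(spec)
    for _ in range(max_attempts):
        ca = _attempt_walk(n, rng)
        if ca is not None:
            return peptide_chain(spec, ca)
    raise RuntimeError(
        f"failed to generate a self-avoiding {n}-mer in {max_attempts} attempts"
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _attempt_walk(n: int, rng: np.random.Generator,
                  per_step_tries: int = 50) -> np.ndarray | None:
    ca = np.zeros((n, 3))
    if n == 1:
        return ca
    ca[1] = ca[0] + BOND_LENGTH * _random_unit(rng)
    for i in range(2, n):
        prev_bond = ca[i - 1] - ca[i - 2]
        prev_unit = prev_bond / np.linalg.norm(prev_bond)
        placed = False
        for _ in range(per_step_tries):
            theta = np.deg2rad(rng.uniform(ANGLE_MIN_DEG, ANGLE_MAX_DEG))
            phi = rng.uniform(0.0, 2.0 * np.pi)
            # Local frame around the previous bond direction.
            arbitrary = np.array([1.0, 0.0, 0.0])
            if abs(prev_unit[0]) > 0.9:
                arbitrary = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(prev_unit, arbitrary)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(prev_unit, e1)
            # Bond angle theta between incoming and outgoing bonds.
            direction = (
                -np.cos(theta) * prev_unit
                + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
            )
            cand = ca[i - 1] + BOND_LENGTH * direction
            d = np.linalg.norm(ca[: i - 1] - cand, axis=1)
            if np.all(d >= MIN_NONBONDED):
                ca[i] = cand
                placed = True
                break
        if not placed:
            return None
    return ca


def place_on_sphere(
    peptide: CGChain, receptor: CGChain, rng: np.random.Generator,
    margin: float = 20.0,
) -> CGComplex:
    """Rigidly place the peptide on the initialization sphere.

    Sphere radius = receptor longest dimension + ``margin``, centered at the
    receptor C-alpha centroid; peptide centroid lands uniformly on the
    sphere after a uniform random rotation of the conformer.
    """
    radius = longest_dimension(receptor) + margin
    center = receptor.centroid()
    rot = Rotation.random(rng=rng).as_matrix()
    direction = _random_unit(rng)
    target = center + radius * direction

    pep = peptide.copy()
    pivot = pep.centroid()
    pep.ca = (pep.ca - pivot) @ rot.T + target
    pep.sc = (pep.sc - pivot) @ rot.T + target
    return CGComplex(receptor.copy(), pep)


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation + translation superimposing ``mobile`` onto ``target``.

    Returns (R, t) with ``mobile @ R.T + t`` least-squares fitted to target.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = tc - r @ mc
    return r, t
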