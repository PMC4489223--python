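"""Pluggable coarse-grained energy.

The receptor restraint network follows the protocol rules exactly
(5-15 A reference band, minimum intra-chain sequence gap of 5, 1 A
flat-bottom tolerance, linear penalty with per-restraint slope modifiers
for flexible residues). The inter/intra-chain terms are a documented
stand-in for the original statistical force field: a symmetric 20x20
contact matrix on pseudo side-chain centers, linear clash penalties, a
soft pseudo-bond-angle band, an optional secondary-structure bias, and a
soft spherical wall that keeps the peptide inside the sampling volume.
All energies are in reduced units.

Inter-chain interactions act only between residue pairs whose C-alpha
distance is within ``interaction_cap`` (equal to the bound-state cutoff),
which makes the binding energy identically zero for unbound poses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from .cg_model import CGChain, CGComplex

__all__ = [
    "AA_ORDER",
    "Restraint",
    "RestraintSet",
    "EnergyModel",
    "default_contact_matrix",
    "default_energy_model",
    "generate_restraints",
    "restraint_energy",
    "total_energy",
    "is_bound",
    "EnergyEvaluator",
    "restraints_to_tsv",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

RESTRAINT_MIN_D = 5.0
RESTRAINT_MAX_D = 15.0
RESTRAINT_MIN_GAP = 5
RESTRAINT_TOLERANCE = 1.0

FLEX_SLOPE_FACTOR = {"rigid": 1.0, "moderate": 0.5, "full": 0.0}

BOUND_CUTOFF = 8.0


@dataclass(frozen=True)
class Restraint:
    """Flat-bottom C-alpha distance restraint between receptor residues."""

    i: int
    j: int
    d_ref: float
    tolerance: float = RESTRAINT_TOLERANCE
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("restraint slope must be non-negative")


@dataclass
class RestraintSet:
    restraints: list[Restraint]
    flexibility_marks: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = {frozenset((r.i, r.j)) for r in self.restraints}
        if len(pairs) != len(self.restraints):
            raise ValueError("duplicate restraint pairs")
        n = len(self.restraints)
        self.idx_i = np.array([r.i for r in self.restraints], dtype=int)
        self.idx_j = np.array([r.j for r in self.restraints], dtype=int)
        self.d_ref = np.array([r.d_ref for r in self.restraints])
        self.tol = np.array([r.tolerance for r in self.restraints])
        self.slope = np.array([r.slope for r in self.restraints])
        if n == 0:
            for a in ("idx_i", "idx_j"):
                setattr(self, a, np.empty(0, dtype=int))

    def __len__(self) -> int:
        return len(self.restraints)


def _load_matrix_tsv(text: str) -> np.ndarray:
    rows = {}
    header = None
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts[1:]
            continue
        rows[parts[0]] = [float(x) for x in parts[1:]]
    m = np.zeros((20, 20))
    for a, vals in rows.items():
        for b, v in zip(header, vals):
            m[_AA_INDEX[a], _AA_INDEX[b]] = v
    return m


def default_contact_matrix() -> np.ndarray:
    """The shipped hydrophobicity-based contact matrix (symmetric 20x20)."""
    data = resources.files("cgdock.data").joinpath("contact_matrix.tsv")
    return _load_matrix_tsv(data.read_text())


@dataclass
class EnergyModel:
    """Parameter set for the stand-in CG energy; any symmetric 20x20
    contact matrix may be plugged in."""

    contact_matrix: np.ndarray = None
    contact_min: float = 4.5
    contact_max: float = 7.0
    clash_distance: float = 4.0
    clash_weight: float = 5.0
    interaction_cap: float = BOUND_CUTOFF
    angle_weight: float = 3.0
    angle_min_deg: float = 75.0
    angle_max_deg: float = 150.0
    wall_weight: float = 3.0     # soft spherical confinement (per A)
    wall_margin: float = 25.0    # wall radius = receptor longest dim + this
    ss_bias_strength: float = 1.0
    exclusion_penalty: float = 5.0
    k_r: float = 1.0
    restraint_tolerance: float = RESTRAINT_TOLERANCE
    bound_cutoff: float = BOUND_CUTOFF
    excluded_residues: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.contact_matrix is None:
            self.contact_matrix = default_contact_matrix()
        self.contact_matrix = np.asarray(self.contact_matrix, dtype=float)
        if self.contact_matrix.shape != (20, 20):
            raise ValueError("contact matrix must be 20x20")
        if not np.allclose(self.contact_matrix, self.contact_matrix.T):
            raise ValueError("contact matrix must be symmetric")
        for name in ("contact_min", "contact_max", "clash_distance",
                     "interaction_cap", "bound_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def default_energy_model(**overrides) -> EnergyModel:
    return EnergyModel(**overrides)


def generate_restraints(
    receptor: CGChain,
    marks: Mapping[int, str] | None = None,
    k_r: float = 1.0,
    tolerance: float = RESTRAINT_TOLERANCE,
) -> RestraintSet:
    """Build the receptor restraint network from the input distance map.

    Pairs with 5 <= d <= 15 A and intra-chain sequence separation >= 5 are
    restrained at their input distance (pairs from different chains are
    always sequence-eligible). Slopes: k_r, halved when either endpoint is
    marked moderately flexible, zero when either is fully flexible; when
    the endpoints disagree the more flexible mark wins.
    """
    marks = dict(marks or {})
    ca = receptor.ca
    chain = receptor.chain_index
    n = receptor.n
    diff = ca[:, None, :] - ca[None, :, :]
    d = np.sqrt((diff * diff).sum(axis=2))
    ii, jj = np.triu_indices(n, k=1)
    same_chain = chain[ii] == chain[jj]
    gap_ok = ~same_chain | (jj - ii >= RESTRAINT_MIN_GAP)
    dist = d[ii, jj]
    keep = gap_ok & (dist >= RESTRAINT_MIN_D) & (dist <= RESTRAINT_MAX_D)

    restraints = []
    for i, j, dref in zip(ii[keep], jj[keep], dist[keep]):
        fi = FLEX_SLOPE_FACTOR[marks.get(int(i), "rigid")]
        fj = FLEX_SLOPE_FACTOR[marks.get(int(j), "rigid")]
        restraints.append(
            Restraint(int(i), int(j), float(dref), tolerance,
                      k_r * min(fi, fj))
        )
    return RestraintSet(restraints, flexibility_marks=marks)


def restraint_energy(r: Restraint, d: float) -> float:
    """Flat-bottom piecewise-linear penalty: zero within the tolerance band,
    then linear with the restraint's slope."""
    return r.slope * max(0.0, abs(d - r.d_ref) - r.tolerance)


def restraints_to_tsv(rs: RestraintSet, dest=None) -> str:
    lines = ["i\tj\td_ref\ttolerance\tslope"]
    for r in rs.restraints:
        lines.append(f"{r.i}\t{r.j}\t{r.d_ref:.3f}\t{r.tolerance:.3f}\t{r.slope:.3f}")
    text = "\n".join(lines) + "\n"
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)
    return text


def is_bound(c: CGComplex, cutoff: float = BOUND_CUTOFF) -> bool:
    """Bound state: minimum peptide-receptor C-alpha distance <= cutoff
    (closed boundary)."""
    diff = c.receptor.ca[:, None, :] - c.peptide.ca[None, :, :]
    dmin = np.sqrt((diff * diff).sum(axis=2)).min()
    return bool(dmin <= cutoff)


class EnergyEvaluator:
    """Precompiled evaluator bound to one topology, used by the sampler.

    Recomputes the full energy from coordinates on every call, so stored
    snapshot energies can never drift from their coordinates.
    """

    def __init__(self, model: EnergyModel, restraints: RestraintSet,
                 receptor: CGChain, peptide: CGChain):
        self.model = model
        self.rs = restraints
        self.rec_aa = np.array([_AA_INDEX[a] for a in receptor.sequence])
        self.pep_aa = np.array([_AA_INDEX[a] for a in peptide.sequence])
        self.pep_ss = peptide.ss
        self.n_rec = receptor.n
        self.n_pep = peptide.n
        self.pair_energy = model.contact_matrix[
            self.rec_aa[:, None], self.pep_aa[None, :]
        ]
        self.excluded = np.zeros(self.n_rec, dtype=bool)
        for idx in model.excluded_residues:
            self.excluded[idx] = True
        # Peptide nonconsecutive pair indices for self-avoidance.
        pi, pj = np.triu_indices(self.n_pep, k=2)
        self._pep_pairs = (pi, pj)
        # Helical i,i+3 targets where both ends are 'H'.
        h = np.array([s == "H" for s in self.pep_ss])
        hi = np.arange(self.n_pep - 3) if self.n_pep > 3 else np.empty(0, int)
        self._helix_i = hi[[h[i] and h[i + 3] for i in hi]] if len(hi) else hi
        e = np.array([s == "E" for s in self.pep_ss])
        mid = np.arange(1, self.n_pep - 1)
        self._strand_mid = mid[e[mid]] if len(mid) else mid
        # Soft confinement keeps the peptide inside the sampling sphere;
        # centred on the (moving) receptor so the term is rigid-motion
        # invariant.
        diff = receptor.ca[:, None, :] - receptor.ca[None, :, :]
        longest = float(np.sqrt((diff * diff).sum(axis=2)).max())
        self.wall_radius = longest + model.wall_margin

    # -- components -------------------------------------------------------

    def intra_peptide(self, pep_ca: np.ndarray) -> float:
        m = self.model
        e = 0.0
        # Self-avoidance on nonconsecutive pairs.
        pi, pj = self._pep_pairs
        if len(pi):
            d = np.linalg.norm(pep_ca[pi] - pep_ca[pj], axis=1)
            viol = np.maximum(0.0, 4.0 - d)
            e += m.clash_weight * viol.sum()
        # Pseudo-bond-angle band.
        if self.n_pep >= 3:
            b1 = pep_ca[:-2] - pep_ca[1:-1]
            b2 = pep_ca[2:] - pep_ca[1:-1]
            cosang = (b1 * b2).sum(axis=1) / (
                np.linalg.norm(b1, axis=1) * np.linalg.norm(b2, axis=1)
            )
            theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            out = np.maximum(0.0, m.angle_min_deg - theta) + np.maximum(
                0.0, theta - m.angle_max_deg
            )
            e += m.angle_weight * np.deg2rad(out).sum()
            # Extended-state bias: keep strand angles open (>= 145 deg).
            if len(self._strand_mid):
                t = theta[self._strand_mid - 1]
                e += m.ss_bias_strength * np.deg2rad(
                    np.maximum(0.0, 145.0 - t)
                ).sum()
        # Helical bias: i,i+3 distance near 5.1 A.
        if len(self._helix_i):
            d3 = np.linalg.norm(
                pep_ca[self._helix_i + 3] - pep_ca[self._helix_i], axis=1
            )
            e += m.ss_bias_strength * ((d3 - 5.1) ** 2).sum()
        return float(e)

    def binding(self, rec_ca, rec_sc, pep_ca, pep_sc) -> float:
        m = self.model
        diff = rec_ca[:, None, :] - pep_ca[None, :, :]
        d_ca = np.sqrt((diff * diff).sum(axis=2))
        cap = d_ca <= m.interaction_cap
        if not cap.any():
            return 0.0
        e = 0.0
        clash = cap & (d_ca < m.clash_distance)
        if clash.any():
            e += m.clash_weight * (m.clash_distance - d_ca[clash]).sum()
        diff_sc = rec_sc[:, None, :] - pep_sc[None, :, :]
        d_sc = np.sqrt((diff_sc * diff_sc).sum(axis=2))
        contact = cap & (d_sc >= m.contact_min) & (d_sc <= m.contact_max)
        if contact.any():
            e += self.pair_energy[contact].sum()
            if self.excluded.any():
                e += m.exclusion_penalty * (
                    contact & self.excluded[:, None]
                ).sum()
        return float(e)

    def restraint(self, rec_ca: np.ndarray) -> float:
        rs = self.rs
        if len(rs) == 0:
            return 0.0
        d = np.linalg.norm(rec_ca[rs.idx_i] - rec_ca[rs.idx_j], axis=1)
        viol = np.maximum(0.0, np.abs(d - rs.d_ref) - rs.tol)
        return float((rs.slope * viol).sum())

    def wall(self, rec_ca: np.ndarray, pep_ca: np.ndarray) -> float:
        sep = float(np.linalg.norm(pep_ca.mean(axis=0) - rec_ca.mean(axis=0)))
        return self.model.wall_weight * max(0.0, sep - self.wall_radius)

    def evaluate(self, rec_ca, rec_sc, pep_ca, pep_sc):
        """Return (E_total, E_binding, E_restraint)."""
        e_bind = self.binding(rec_ca, rec_sc, pep_ca, pep_sc)
        e_restr = self.restraint(rec_ca)
        e_intra = self.intra_peptide(pep_ca) + self.wall(rec_ca, pep_ca)
        return e_intra + e_bind + e_restr, e_bind, e_restr

    def min_inter_ca(self, rec_ca, pep_ca) -> float:
        diff = rec_ca[:, None, :] - pep_ca[None, :, :]
        return float(np.sqrt((diff * diff).sum(axis=2)).min())


def total_energy(c: CGComplex, m: EnergyModel, rs: RestraintSet):
    """(E_total, E_binding, E_restraint) for one pose.

    E_total = intra-peptide (angle band + SS bias + self-avoidance)
            + inter-chain (contacts + clashes + exclusion penalties)
            + receptor restraint energy.
    """
    if rs.idx_i.size and rs.idx_i.max() >= c.receptor.n:
        raise ValueError("restraint indices exceed receptor size")
    ev = EnergyEvaluator(m, rs, c.receptor, c.peptide)
    return ev.evaluate(c.receptor.ca, c.receptor.sc, c.peptide.ca, c.peptide.sc)
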