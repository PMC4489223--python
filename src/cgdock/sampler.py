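"""Replica-exchange Monte Carlo simulated annealing.

Ten replicas (by default) run uniformly spaced temperatures that shrink
proportionally every macrocycle; adjacent replicas attempt configuration
swaps once per snapshot interval, alternating even/odd pairs. Each replica
emits one trajectory of time-stamped snapshots: at defaults 50 macrocycles
x 20 snapshots = 1000 snapshots per trajectory, 10 000 models in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cg_model import (
    BOND_LENGTH,
    BOND_TOLERANCE,
    CGChain,
    CGComplex,
    CGSnapshot,
    place_on_sphere,
    place_sc_from_trace,
    random_peptide_conformation,
)
from .energy import EnergyEvaluator, EnergyModel, RestraintSet
from .structures_io import PeptideSpec

__all__ = [
    "SimulationConfig",
    "ReplicaLadder",
    "Trajectory",
    "metropolis_accept",
    "exchange_probability",
    "attempt_exchange",
    "mc_move",
    "run_docking",
    "MAX_MACROCYCLES",
    "DEFAULT_MACROCYCLES",
]

DEFAULT_MACROCYCLES = 50
MAX_MACROCYCLES = 200

_BOND_LO = BOND_LENGTH - BOND_TOLERANCE
_BOND_HI = BOND_LENGTH + BOND_TOLERANCE


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_replicas: int = 10
    n_macrocycles: int = DEFAULT_MACROCYCLES
    snapshots_per_macrocycle: int = 20
    moves_per_snapshot: int = 60
    t_max_start: float = 3.5
    t_min_start: float = 1.0
    annealing_factor: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_macrocycles <= MAX_MACROCYCLES:
            raise ConfigError(
                f"n_macrocycles must be in 1-{MAX_MACROCYCLES}, "
                f"got {self.n_macrocycles}"
            )
        if self.n_replicas < 1 or self.snapshots_per_macrocycle < 1:
            raise ConfigError("replica and snapshot counts must be positive")
        if not 0 < self.annealing_factor <= 1:
            raise ConfigError("annealing_factor must be in (0, 1]")
        if self.t_min_start <= 0 or self.t_max_start < self.t_min_start:
            raise ConfigError("need 0 < t_min_start <= t_max_start")

    @property
    def total_snapshots(self) -> int:
        return (self.n_replicas * self.n_macrocycles
                * self.snapshots_per_macrocycle)


@dataclass
class ReplicaLadder:
    """Per-replica temperatures, hottest first, strictly decreasing."""

    temperatures: np.ndarray

    @classmethod
    def build(cls, cfg: SimulationConfig) -> "ReplicaLadder":
        if cfg.n_replicas == 1:
            temps = np.array([cfg.t_max_start])
        else:
            temps = np.linspace(cfg.t_max_start, cfg.t_min_start,
                                cfg.n_replicas)
        return cls(temperatures=temps)

    def scaled(self, factor: float) -> np.ndarray:
        return self.temperatures * factor


def build_ladder(cfg: SimulationConfig) -> ReplicaLadder:
    return ReplicaLadder.build(cfg)


def annealing_scale(cfg: SimulationConfig, macrocycle: int) -> float:
    """Proportional ladder shrinkage: 1.0 at the first macrocycle,
    annealing_factor at the last."""
    if cfg.n_macrocycles == 1:
        return 1.0
    frac = macrocycle / (cfg.n_macrocycles - 1)
    return float(cfg.annealing_factor ** frac)


@dataclass
class Trajectory:
    replica_index: int
    snapshots: list[CGSnapshot] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snapshots)


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / temperature)


def exchange_probability(e_a: float, e_b: float,
                         t_a: float, t_b: float) -> float:
    arg = (1.0 / t_a - 1.0 / t_b) * (e_a - e_b)
    return min(1.0, math.exp(min(arg, 0.0)) if arg < 0 else 1.0)


def attempt_exchange(e_a, e_b, t_a, t_b, rng: np.random.Generator) -> bool:
    """Metropolis-type swap decision for adjacent replicas."""
    return rng.random() < exchange_probability(e_a, e_b, t_a, t_b)


class _ReplicaState:
    """Mutable coordinates + cached energies of one replica."""

    __slots__ = ("rec_ca", "rec_sc", "pep_ca", "pep_sc", "energy")

    def __init__(self, cplx: CGComplex, evaluator: EnergyEvaluator):
        self.rec_ca = cplx.receptor.ca.copy()
        self.rec_sc = cplx.receptor.sc.copy()
        self.pep_ca = cplx.peptide.ca.copy()
        self.pep_sc = cplx.peptide.sc.copy()
        self.energy = evaluator.evaluate(
            self.rec_ca, self.rec_sc, self.pep_ca, self.pep_sc
        )


def _bond_ok(ca: np.ndarray, i: int, ref: np.ndarray | None = None) -> bool:
    """Check the bonds touching residue i stay inside the tolerance band.

    With ``ref`` (native bond lengths) the band is relative to the input
    structure, which also covers e.g. cis-proline geometry.
    """
    n = len(ca)
    for k in (i - 1, i):
        if 0 <= k < n - 1:
            d = float(np.linalg.norm(ca[k + 1] - ca[k]))
            lo, hi = (_BOND_LO, _BOND_HI) if ref is None else (
                ref[k] - BOND_TOLERANCE, ref[k] + BOND_TOLERANCE)
            if not lo <= d <= hi:
                return False
    return True


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _propose(state: _ReplicaState, rng: np.random.Generator,
             rec_bond_ref: np.ndarray):
    """Propose a move; returns (new_rec_ca, new_rec_sc, new_pep_ca) or None
    when the proposal violates the hard bond-length wall."""
    n_pep = len(state.pep_ca)
    u = rng.random()
    if u < 0.30:  # peptide single-residue displacement
        i = int(rng.integers(n_pep))
        pep = state.pep_ca.copy()
        pep[i] += rng.normal(0.0, 0.3, 3)
        if not _bond_ok(pep, i):
            return None
        return state.rec_ca, state.rec_sc, pep
    if u < 0.55:  # 2-4 residue fragment rotation (crankshaft / pivot)
        if n_pep < 3:
            return None
        length = int(rng.integers(2, min(4, n_pep - 1) + 1))
        s = int(rng.integers(0, n_pep - length + 1))
        e = s + length - 1
        angle = rng.normal(0.0, 0.6)
        pep = state.pep_ca.copy()
        if s > 0 and e < n_pep - 1:
            axis = pep[e + 1] - pep[s - 1]
            if np.linalg.norm(axis) < 1e-6:
                return None
            rot = _rotation_about_axis(axis, angle)
            pivot = pep[s - 1]
        else:
            anchor = s - 1 if s > 0 else e + 1
            if anchor < 0 or anchor >= n_pep:
                return None
            rot = _rotation_about_axis(rng.normal(size=3), angle)
            pivot = pep[anchor]
        seg = slice(s, e + 1)
        pep[seg] = (pep[seg] - pivot) @ rot.T + pivot
        return state.rec_ca, state.rec_sc, pep
    if u < 0.80:  # rigid-body peptide translation + rotation
        pep = state.pep_ca.copy()
        rot = _rotation_about_axis(rng.normal(size=3), rng.normal(0.0, 0.35))
        pivot = pep.mean(axis=0)
        pep = (pep - pivot) @ rot.T + pivot + rng.normal(0.0, 2.0, 3)
        return state.rec_ca, state.rec_sc, pep
    # receptor single-C-alpha displacement (<= 0.5 A)
    i = int(rng.integers(len(state.rec_ca)))
    delta = rng.normal(0.0, 0.2, 3)
    norm = np.linalg.norm(delta)
    if norm > 0.5:
        delta *= 0.5 / norm
    rec = state.rec_ca.copy()
    rec[i] += delta
    if not _bond_ok(rec, i, ref=rec_bond_ref):
        return None
    rec_sc = state.rec_sc.copy()
    rec_sc[i] += delta
    return rec, rec_sc, state.pep_ca


def mc_move(state: _ReplicaState, temperature: float,
            rng: np.random.Generator, evaluator: EnergyEvaluator,
            sequence: str, rec_bond_ref: np.ndarray) -> bool:
    """One Metropolis move; mutates ``state`` in place when accepted."""
    prop = _propose(state, rng, rec_bond_ref)
    if prop is None:
        return False
    rec_ca, rec_sc, pep_ca = prop
    pep_sc = (state.pep_sc if pep_ca is state.pep_ca
              else place_sc_from_trace(pep_ca, sequence))
    new_energy = evaluator.evaluate(rec_ca, rec_sc, pep_ca, pep_sc)
    if not metropolis_accept(new_energy[0] - state.energy[0],
                             temperature, rng):
        return False
    state.rec_ca, state.rec_sc = rec_ca, rec_sc
    state.pep_ca, state.pep_sc = pep_ca, pep_sc
    state.energy = new_energy
    return True


def run_docking(
    receptor: CGChain,
    peptide: PeptideSpec,
    restraints: RestraintSet,
    model: EnergyModel,
    cfg: SimulationConfig,
) -> list[Trajectory]:
    """Full REMC annealing run; returns one trajectory per replica."""
    ladder = ReplicaLadder.build(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    init_seeds, move_seeds, exch_seed = np.split(
        np.array(ss.spawn(2 * cfg.n_replicas + 1)), [cfg.n_replicas,
                                                     2 * cfg.n_replicas]
    )
    init_rngs = [np.random.default_rng(s) for s in init_seeds]
    move_rngs = [np.random.default_rng(s) for s in move_seeds]
    exch_rng = np.random.default_rng(exch_seed[0])

    # Template complex (fixes topology/metadata for snapshots).
    template = None
    states: list[_ReplicaState] = []
    evaluator = None
    for r in range(cfg.n_replicas):
        conf = random_peptide_conformation(peptide, init_rngs[r])
        cplx = place_on_sphere(conf, receptor, init_rngs[r])
        if template is None:
            template = cplx
            evaluator = EnergyEvaluator(model, restraints,
                                        cplx.receptor, cplx.peptide)
        states.append(_ReplicaState(cplx, evaluator))

    rec_bond_ref = np.linalg.norm(np.diff(receptor.ca, axis=0), axis=1)

    trajectories = [Trajectory(replica_index=r) for r in range(cfg.n_replicas)]
    global_step = 0
    for mc in range(cfg.n_macrocycles):
        temps = ladder.scaled(annealing_scale(cfg, mc))
        for snap in range(cfg.snapshots_per_macrocycle):
            for r in range(cfg.n_replicas):
                for _ in range(cfg.moves_per_snapshot):
                    mc_move(states[r], float(temps[r]), move_rngs[r],
                            evaluator, peptide.sequence, rec_bond_ref)
            # Exchange sweep: alternate even/odd adjacent pairs.
            start = global_step % 2
            for a in range(start, cfg.n_replicas - 1, 2):
                b = a + 1
                if attempt_exchange(states[a].energy[0], states[b].energy[0],
                                    float(temps[a]), float(temps[b]),
                                    exch_rng):
                    states[a], states[b] = states[b], states[a]
            global_step += 1
            for r in range(cfg.n_replicas):
                st = states[r]
                bound = (evaluator.min_inter_ca(st.rec_ca, st.pep_ca)
                         <= model.bound_cutoff)
                rec = CGChain(
                    ca=st.rec_ca.copy(), sc=st.rec_sc.copy(),
                    sequence=receptor.sequence, ss=receptor.ss,
                    chain_index=receptor.chain_index,
                    chain_ids=receptor.chain_ids,
                    author_ids=receptor.author_ids,
                )
                pep = CGChain(
                    ca=st.pep_ca.copy(), sc=st.pep_sc.copy(),
                    sequence=peptide.sequence, ss=peptide.ss_states,
                    chain_index=np.zeros(len(peptide), dtype=int),
                )
                trajectories[r].snapshots.append(CGSnapshot(
                    complex=CGComplex(rec, pep),
                    replica_index=r,
                    macrocycle_index=mc,
                    snapshot_index=len(trajectories[r].snapshots),
                    temperature=float(temps[r]),
                    energy_total=st.energy[0],
                    energy_binding=st.energy[1],
                    energy_restraint=st.energy[2],
                    bound=bound,
                ))
    return trajectories
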