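"""Programmatic synthetic structures: every pipeline stage is testable
with no downloads.

Receptor kinds: ideal alpha-helix, two-helix groove bundle with a designed
attractive site (the docking-funnel case), and a compact random-coil
globule. All geometry is deterministic given the seed; PDB files are
emitted as text on demand, never checked in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cg_model import CGComplex, build_cg, peptide_chain
from .energy import AA_ORDER, EnergyModel
from .structures_io import (
    Chain,
    ReceptorStructure,
    Residue,
    THREE_LETTER,
    validate_peptide,
)

__all__ = [
    "ToyComplexSpec",
    "ideal_helix",
    "groove_receptor",
    "groove_case",
    "random_coil_globule",
    "funnel_energy_model",
    "make_test_suite",
    "receptor_to_pdb",
]

HELIX_RISE = 1.5          # A per residue
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.3        # C-alpha radius, A
GROOVE_SEPARATION = 13.0  # helix axis-to-axis distance, A


@dataclass
class ToyComplexSpec:
    receptor_kind: str = "two_helix_groove"  # single_helix | two_helix_groove | random_coil_globule
    receptor_length: int = 36                # total residues (split over helices)
    peptide_sequence: str = "FFFFF"
    designed_site: list[int] = field(default_factory=list)
    seed: int = 0


def _helix_trace(n: int, atom_radius: float, angle_offset: float,
                 z_offset: float) -> np.ndarray:
    i = np.arange(n)
    ang = np.deg2rad(HELIX_TWIST * i + angle_offset)
    return np.stack([
        atom_radius * np.cos(ang),
        atom_radius * np.sin(ang),
        HELIX_RISE * i + z_offset,
    ], axis=1)


def _helix_residues(n: int, names: list[str], start_id: int = 1,
                    transform=None) -> list[Residue]:
    """Full-backbone helix residues from ideal internal coordinates."""
    ca = _helix_trace(n, HELIX_RADIUS, 0.0, 0.0)
    nn = _helix_trace(n, 1.60, -26.0, -0.90)
    cc = _helix_trace(n, 1.70, 26.0, 0.65)
    oo = cc + np.array([0.0, 0.0, 1.23])
    if transform is not None:
        ca, nn, cc, oo = (transform(x) for x in (ca, nn, cc, oo))
    out = []
    for i in range(n):
        out.append(Residue(names[i], start_id + i, "", {
            "N": nn[i], "CA": ca[i], "C": cc[i], "O": oo[i],
        }))
    return out


def ideal_helix(n: int, chain_id: str = "A",
                sequence: str | None = None) -> ReceptorStructure:
    """Ideal alpha-helix receptor: 1.5 A rise, 100 deg twist, 2.3 A C-alpha
    radius, full backbone so validation passes."""
    if n < 2:
        raise ValueError("helix needs at least 2 residues")
    seq = sequence or "A" * n
    if len(seq) != n:
        raise ValueError("sequence length mismatch")
    names = [THREE_LETTER[a] for a in seq]
    return ReceptorStructure([Chain(chain_id, _helix_residues(n, names))])


def groove_receptor(spec: ToyComplexSpec):
    """Two antiparallel helices forming a groove with a designed binding
    site; returns (receptor, reference bound peptide pose).

    Inward-facing residues in the middle of both helices become tryptophan
    (the designed site, recorded in ``spec.designed_site``); everything
    else is alanine. The reference pose lies in the groove centre against
    the site. Site affinity comes from the pluggable contact matrix (see
    :func:`funnel_energy_model`), not from the sampler.
    """
    n_per = spec.receptor_length // 2
    if n_per < 8:
        raise ValueError("groove receptor needs >= 16 residues")
    half = GROOVE_SEPARATION / 2.0
    span = HELIX_RISE * (n_per - 1)

    def move_a(x):
        return x + np.array([-half, 0.0, 0.0])

    def move_b(x):
        # antiparallel: flip about the x axis, then shift to +x
        y = x * np.array([1.0, -1.0, -1.0])
        return y + np.array([half, 0.0, span])

    # Determine inward-facing residues (sc radial direction toward x=0).
    i = np.arange(n_per)
    radial_x = np.cos(np.deg2rad(HELIX_TWIST * i))
    mid = (i >= n_per // 4) & (i < n_per - n_per // 4)
    # Chain A sits at -x: inward means radial +x. Chain B's flip leaves x
    # unchanged, so its inward residues have radial -x.
    inward_a = np.flatnonzero((radial_x > 0.5) & mid)
    inward_b = np.flatnonzero((radial_x < -0.5) & mid)

    names_a = ["TRP" if k in inward_a else "ALA" for k in range(n_per)]
    names_b = ["TRP" if k in inward_b else "ALA" for k in range(n_per)]
    chain_a = Chain("A", _helix_residues(n_per, names_a, transform=move_a))
    chain_b = Chain("B", _helix_residues(n_per, names_b, transform=move_b))
    receptor = ReceptorStructure([chain_a, chain_b])

    spec.designed_site = sorted(
        [int(k) for k in inward_a] + [int(k) + n_per for k in inward_b]
    )

    # Reference pose: gentle zigzag along the groove axis at x = 0,
    # centred on the designed site's z range.
    pep = validate_peptide(spec.peptide_sequence)
    m = len(pep)
    site_z = np.array(
        [receptor.residue_at(g).atoms["CA"][2] for g in spec.designed_site]
    )
    z0 = float(site_z.mean()) - 0.5 * 3.446 * (m - 1)
    ys = 0.8 * np.where(np.arange(m) % 2 == 0, 1.0, -1.0)
    dz = np.sqrt(3.8 ** 2 - (2 * 0.8) ** 2)
    ca = np.stack([np.zeros(m), ys, z0 + dz * np.arange(m)], axis=1)
    reference = peptide_chain(pep, ca)
    return receptor, reference


def funnel_energy_model(site_energy: float = -4.0,
                        background: float = 0.3) -> EnergyModel:
    """Contact matrix making TRP-PHE contacts strongly favourable and
    ALA-PHE contacts mildly repulsive — the groove fixture's funnel."""
    m = np.zeros((20, 20))
    w, f, a = AA_ORDER.index("W"), AA_ORDER.index("F"), AA_ORDER.index("A")
    m[w, f] = m[f, w] = site_energy
    m[a, f] = m[f, a] = background
    return EnergyModel(contact_matrix=m)


def groove_case(receptor_length: int = 36, peptide_sequence: str = "FFFFF"):
    """Ready-to-dock funnel fixture.

    Returns a dict with the receptor structure, its CG chain, the peptide
    spec, the designed-site indices, the reference bound CG complex, and
    the funnel energy model.
    """
    spec = ToyComplexSpec(receptor_length=receptor_length,
                          peptide_sequence=peptide_sequence)
    receptor, reference = groove_receptor(spec)
    rec_cg = build_cg(receptor)
    return {
        "spec": spec,
        "receptor": receptor,
        "receptor_cg": rec_cg,
        "peptide": validate_peptide(peptide_sequence),
        "designed_site": spec.designed_site,
        "reference": CGComplex(rec_cg, reference),
        "model": funnel_energy_model(),
    }


def _globule_walk(n: int, radius: float,
                  rng: np.random.Generator) -> np.ndarray | None:
    ca = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(200):
            step = rng.normal(size=3)
            # pull back toward the origin near the confinement wall
            pull = -ca[i - 1] / radius
            direction = step + 1.5 * pull
            direction /= np.linalg.norm(direction)
            cand = ca[i - 1] + 3.8 * direction
            if np.linalg.norm(cand) > radius:
                continue
            if i > 1 and np.linalg.norm(ca[: i - 1] - cand,
                                        axis=1).min() < 4.0:
                continue
            ca[i] = cand
            break
        else:
            return None
    return ca


def random_coil_globule(n: int = 60, seed: int = 0,
                        radius: float | None = None) -> ReceptorStructure:
    """Compact self-avoiding random C-alpha walk with fabricated backbone.

    Confined to a sphere so restraint-band (5-15 A) pairs are dense.
    """
    rng = np.random.default_rng(seed)
    if radius is None:
        radius = 3.2 * n ** (1 / 3)
    for _ in range(200):
        ca = _globule_walk(n, radius, rng)
        if ca is not None:
            break
    else:
        raise RuntimeError("globule walk failed; adjust radius")

    residues = []
    for i in range(n):
        prev_dir = ca[i - 1] - ca[i] if i > 0 else ca[1] - ca[0]
        next_dir = ca[i + 1] - ca[i] if i < n - 1 else ca[n - 2] - ca[n - 1]
        u = prev_dir / np.linalg.norm(prev_dir)
        v = next_dir / np.linalg.norm(next_dir)
        w = np.cross(u, v)
        if np.linalg.norm(w) < 1e-6:
            w = np.array([0.0, 0.0, 1.0])
        w /= np.linalg.norm(w)
        residues.append(Residue("ALA", i + 1, "", {
            "N": ca[i] + 1.46 * u,
            "CA": ca[i].copy(),
            "C": ca[i] + 1.52 * v,
            "O": ca[i] + 1.52 * v + 1.23 * w,
        }))
    return ReceptorStructure([Chain("A", residues)])


def receptor_to_pdb(receptor: ReceptorStructure, dest=None) -> str:
    """Full-backbone fixed-column PDB text for a synthetic receptor."""
    lines = []
    serial = 1
    for chain in receptor.chains:
        for res in chain.residues:
            for name in ("N", "CA", "C", "O"):
                xyz = res.atoms[name]
                element = name[0]
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} {res.name:>3s} "
                    f"{chain.chain_id}{res.seq_id:4d}"
                    f"{res.insertion_code or ' ':1s}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if dest is not None:
        with open(dest, "w") as fh:
            fh.write(text)
    return text


def make_test_suite(seed: int, outdir) -> dict:
    """Write the full fixture catalog (PDB + config + manifest) to a
    directory; byte-identical for a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    helix = ideal_helix(20)
    receptor_to_pdb(helix, outdir / "helix20.pdb")

    case = groove_case()
    receptor_to_pdb(case["receptor"], outdir / "groove.pdb")

    globule = random_coil_globule(60, seed=seed)
    receptor_to_pdb(globule, outdir / "globule60.pdb")

    (outdir / "groove.cfg").write_text(
        "receptor=groove.pdb\n"
        f"peptide={case['peptide'].sequence}\n"
        f"seed={seed}\n"
    )

    manifest = {
        "seed": seed,
        "cases": {
            "helix20": {
                "file": "helix20.pdb",
                "kind": "single_helix",
                "n_residues": 20,
                "ca_bond_band": [3.7, 3.9],
                "i_i5_band": [5.0, 15.0],
            },
            "groove": {
                "file": "groove.pdb",
                "kind": "two_helix_groove",
                "n_residues": case["spec"].receptor_length,
                "peptide": case["peptide"].sequence,
                "designed_site": case["designed_site"],
            },
            "globule60": {
                "file": "globule60.pdb",
                "kind": "random_coil_globule",
                "n_residues": 60,
            },
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
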