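"""Docking quality assessment and peptide-receptor contact maps.

Quality classes use ligand RMSD — peptide-only C-alpha RMSD after
superimposing the receptor structures:
high < 3 A, 3 A <= medium <= 5.5 A, low > 5.5 A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cg_model import CGComplex, kabsch_rotation

__all__ = [
    "QualityClass",
    "ContactMap",
    "ligand_rmsd",
    "classify_quality",
    "best_of_set",
    "contact_map",
    "HIGH_RMSD_MAX",
    "MEDIUM_RMSD_MAX",
    "DEFAULT_CONTACT_CUTOFF",
]

HIGH_RMSD_MAX = 3.0      # high-quality: rmsd strictly below this
MEDIUM_RMSD_MAX = 5.5    # medium-quality: up to and including this
DEFAULT_CONTACT_CUTOFF = 6.5


@dataclass(frozen=True)
class QualityClass:
    label: str  # "high" | "medium" | "low"
    rmsd: float


@dataclass
class ContactMap:
    matrix: np.ndarray          # (n_peptide, n_receptor) bool
    cutoff: float
    contacts: list[tuple[int, int, float]]  # (pep res, rec res, distance)


def _check_topology(model: CGComplex, reference: CGComplex) -> None:
    if (model.receptor.n != reference.receptor.n
            or model.peptide.n != reference.peptide.n):
        raise ValueError("model and reference topology mismatch")


def ligand_rmsd(model: CGComplex, reference: CGComplex) -> float:
    """Peptide C-alpha RMSD after Kabsch superposition of the receptors.

    The fitted transform comes from the receptor C-alphas only; the peptide
    is carried along without refitting.
    """
    _check_topology(model, reference)
    r, t = kabsch_rotation(model.receptor.ca, reference.receptor.ca)
    pep = model.peptide.ca @ r.T + t
    diff = pep - reference.peptide.ca
    return float(np.sqrt((diff * diff).sum() / len(pep)))


def classify_quality(rmsd: float) -> QualityClass:
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    if rmsd < HIGH_RMSD_MAX:
        label = "high"
    elif rmsd <= MEDIUM_RMSD_MAX:
        label = "medium"
    else:
        label = "low"
    return QualityClass(label=label, rmsd=float(rmsd))


def best_of_set(models, reference: CGComplex):
    """Minimum ligand RMSD over a model set.

    Returns (best rmsd, index of best model, QualityClass).
    """
    models = list(models)
    if not models:
        raise ValueError("empty model set")
    rmsds = [
        ligand_rmsd(m.complex if hasattr(m, "complex") else m, reference)
        for m in models
    ]
    best = int(np.argmin(rmsds))
    return rmsds[best], best, classify_quality(rmsds[best])


def contact_map(model: CGComplex, cutoff: float = DEFAULT_CONTACT_CUTOFF,
                use_sc: bool = True) -> ContactMap:
    """Boolean peptide x receptor contact matrix at a user-defined cutoff.

    Distances are pseudo side-chain center distances; set ``use_sc=False``
    (or strip sc positions) to fall back to C-alpha distances.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pep = model.peptide.sc if use_sc else model.peptide.ca
    rec = model.receptor.sc if use_sc else model.receptor.ca
    diff = pep[:, None, :] - rec[None, :, :]
    d = np.sqrt((diff * diff).sum(axis=2))
    matrix = d <= cutoff
    contacts = [
        (int(i), int(j), float(d[i, j]))
        for i, j in np.argwhere(matrix)
    ]
    contacts.sort(key=lambda c: c[2])
    return ContactMap(matrix=matrix, cutoff=float(cutoff), contacts=contacts)


def contact_map_to_tsv(cm: ContactMap, model: CGComplex, dest=None) -> str:
    rec = model.receptor
    lines = ["peptide_res\treceptor_chain\treceptor_res\tdistance"]
    for i, j, d in cm.contacts:
        cid = rec.chain_ids[j] if rec.chain_ids is not None else "A"
        rid = rec.author_ids[j][0] if rec.author_ids is not None else j + 1
        lines.append(f"{i}\t{cid}\t{rid}\t{d:.3f}")
    text = "\n".join(lines) + "\n"
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)
    return text
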