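"""PDB-format structure I/O, validation and normalization.

Reading is backed by :mod:`biotite`; writing uses a fixed-column wwPDB v3.3
compliant writer for C-alpha records (multi-MODEL trajectories and final
models are emitted in C-alpha representation only).
"""

from __future__ import annotations

import io
import string
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "ReceptorStructure",
    "PeptideSpec",
    "PDBFormatError",
    "EmptyInputError",
    "ReceptorValidationError",
    "UnmappableResidueError",
    "PeptideError",
    "read_pdb",
    "validate_receptor",
    "normalize_nonstandard",
    "validate_peptide",
    "write_models_pdb",
    "load_nonstandard_table",
    "STANDARD_RESIDUES",
    "ONE_LETTER",
    "THREE_LETTER",
]

STANDARD_RESIDUES = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_LETTER = STANDARD_RESIDUES  # 3-letter -> 1-letter
THREE_LETTER = {v: k for k, v in STANDARD_RESIDUES.items()}

AMINO_ALPHABET = frozenset(STANDARD_RESIDUES)  # three-letter names

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
_BACKBONE = ("N", "CA", "C", "O")

MAX_CHAIN_LENGTH = 500
MAX_PEPTIDE_LENGTH = 30
SS_ALPHABET = frozenset("HEC")


class PDBFormatError(ValueError):
    """Raised when a PDB record cannot be parsed; names the offending line."""


class EmptyInputError(ValueError):
    """Raised when the input stream contains no protein residues."""


class UnmappableResidueError(ValueError):
    """Raised when a residue name has no entry in the normalization table."""


class PeptideError(ValueError):
    """Raised for invalid peptide sequence or secondary-structure input."""


@dataclass(frozen=True)
class AtomRecord:
    """A single coordinate record as read from the file."""

    atom_name: str
    residue_name: str
    chain_id: str
    residue_seq_id: int
    insertion_code: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")


@dataclass
class Residue:
    name: str
    seq_id: int
    insertion_code: str
    atoms: dict[str, np.ndarray]

    @property
    def author_id(self) -> tuple[int, str]:
        return (self.seq_id, self.insertion_code)

    def has_complete_backbone(self) -> bool:
        return all(a in self.atoms for a in _BACKBONE)

    def missing_backbone(self) -> list[str]:
        return [a for a in _BACKBONE if a not in self.atoms]

    def side_chain_positions(self) -> np.ndarray:
        """Heavy side-chain atom coordinates (may be empty)."""
        skip = {"N", "CA", "C", "O", "OXT"}
        coords = [
            xyz for name, xyz in self.atoms.items()
            if name not in skip and not name.startswith("H")
        ]
        if not coords:
            return np.empty((0, 3))
        return np.asarray(coords)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ReceptorStructure:
    """Validated multi-chain receptor with a dense global residue index.

    The global index runs over chains in file order; the mapping
    ``global index <-> (chain_id, author seq id, insertion code)`` is
    bijective and preserved for round-tripping.
    """

    chains: list[Chain]
    source_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: list[tuple[str, int, str]] = []
        self._reverse: dict[tuple[str, int, str], int] = {}
        g = 0
        for chain in self.chains:
            for res in chain.residues:
                key = (chain.chain_id, res.seq_id, res.insertion_code)
                if key in self._reverse:
                    raise ValueError(f"duplicate residue key {key}")
                self._index.append(key)
                self._reverse[key] = g
                g += 1

    @property
    def n_residues(self) -> int:
        return len(self._index)

    def residues(self) -> Iterable[tuple[int, str, Residue]]:
        """Yield (global index, chain id, residue) in global order."""
        g = 0
        for chain in self.chains:
            for res in chain.residues:
                yield g, chain.chain_id, res
                g += 1

    def residue_at(self, gidx: int) -> Residue:
        chain_id, seq_id, icode = self._index[gidx]
        for chain in self.chains:
            if chain.chain_id == chain_id:
                for res in chain.residues:
                    if res.seq_id == seq_id and res.insertion_code == icode:
                        return res
        raise KeyError(gidx)

    def global_index(self, chain_id: str, seq_id: int, icode: str = "") -> int:
        return self._reverse[(chain_id, seq_id, icode)]

    def author_key(self, gidx: int) -> tuple[str, int, str]:
        return self._index[gidx]

    @property
    def ca_trace(self) -> np.ndarray:
        """(n_residues, 3) array of C-alpha coordinates in global order."""
        return np.array(
            [res.atoms["CA"] for _, _, res in self.residues()], dtype=float
        )

    @property
    def sequence(self) -> str:
        return "".join(
            STANDARD_RESIDUES.get(res.name, "X") for _, _, res in self.residues()
        )

    @property
    def chain_index(self) -> np.ndarray:
        """Per-residue integer chain index (0-based, file order)."""
        out = []
        for ci, chain in enumerate(self.chains):
            out.extend([ci] * len(chain.residues))
        return np.asarray(out, dtype=int)


@dataclass(frozen=True)
class PeptideSpec:
    """Peptide sequence plus per-residue secondary-structure states."""

    sequence: str
    ss_states: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.sequence) <= MAX_PEPTIDE_LENGTH:
            raise PeptideError(
                f"peptide length must be 1-{MAX_PEPTIDE_LENGTH}, "
                f"got {len(self.sequence)}"
            )
        if len(self.ss_states) != len(self.sequence):
            raise PeptideError(
                "secondary-structure string length "
                f"({len(self.ss_states)}) does not match sequence length "
                f"({len(self.sequence)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class ReceptorValidationError(ValueError):
    """Carries the full violation report of a failed receptor validation."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            "receptor validation failed:\n" + "\n".join(violations)
        )


def _prescan(text: str) -> None:
    """Cheap per-line sanity scan so format errors can name a line number."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBFormatError(
                f"line {lineno}: coordinate record too short"
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBFormatError(
                    f"line {lineno}: cannot parse {what} coordinate "
                    f"field {line[lo:hi]!r}"
                ) from None


def read_pdb(source) -> ReceptorStructure:
    """Parse PDB text into a :class:`ReceptorStructure`.

    Keeps the first altloc of each atom, retains HETATM amino acids for
    later normalization, and drops waters and non-peptidic ligands.
    ``source`` may be a path, a file object, or a string of PDB text.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        text = s if "\n" in s or s.startswith(("ATOM", "HETATM")) else open(s).read()

    _prescan(text)
    if not any(l.startswith(("ATOM", "HETATM")) for l in text.splitlines()):
        raise EmptyInputError("no ATOM/HETATM records in input")

    try:
        pdb = PDBFile.read(io.StringIO(text))
        atoms = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:  # biotite raises plain ValueError/InvalidFileError
        raise PDBFormatError(f"could not parse PDB input: {exc}") from exc

    known = AMINO_ALPHABET | set(load_nonstandard_table())
    chains: list[Chain] = []
    order: list[str] = []
    by_chain: dict[str, dict[tuple[int, str], Residue]] = {}
    for i in range(atoms.array_length()):
        res_name = atoms.res_name[i].strip()
        if res_name in _WATER_NAMES:
            continue
        chain_id = atoms.chain_id[i].strip() or "A"
        key = (int(atoms.res_id[i]), atoms.ins_code[i].strip())
        if chain_id not in by_chain:
            by_chain[chain_id] = {}
            order.append(chain_id)
        cdict = by_chain[chain_id]
        if key not in cdict:
            cdict[key] = Residue(res_name, key[0], key[1], {})
        name = atoms.atom_name[i].strip()
        if name and name not in cdict[key].atoms:
            cdict[key].atoms[name] = np.array(atoms.coord[i], dtype=float)

    for chain_id in order:
        residues = [
            r for r in by_chain[chain_id].values()
            if r.name in known or "CA" in r.atoms
        ]
        if residues:
            chains.append(Chain(chain_id, residues))

    if not chains:
        raise EmptyInputError("input contains no protein residues")

    meta = {
        "chain_ids": [c.chain_id for c in chains],
        "numbering": {
            c.chain_id: [r.author_id for r in c.residues] for c in chains
        },
    }
    return ReceptorStructure(chains, source_metadata=meta)


def validate_receptor(s: ReceptorStructure) -> ReceptorStructure:
    """Enforce the input contract: complete N/CA/C/O backbone on every
    residue and at most 500 residues per chain.

    Returns the structure unchanged when valid; raises
    :class:`ReceptorValidationError` listing every violation otherwise.
    """
    violations: list[str] = []
    for chain in s.chains:
        if len(chain) > MAX_CHAIN_LENGTH:
            violations.append(
                f"chain {chain.chain_id}: {len(chain)} residues exceeds the "
                f"{MAX_CHAIN_LENGTH}-residue limit"
            )
        for res in chain.residues:
            missing = res.missing_backbone()
            if missing:
                violations.append(
                    f"chain {chain.chain_id} residue {res.seq_id}"
                    f"{res.insertion_code}: missing backbone atom(s) "
                    + ",".join(missing)
                )
    if violations:
        raise ReceptorValidationError(violations)
    return s


def load_nonstandard_table() -> dict[str, str]:
    """Default non-standard -> standard residue-name mapping (shipped as data)."""
    table: dict[str, str] = {}
    data = resources.files("cgdock.data").joinpath("nonstandard_residues.tsv")
    for line in data.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        src, dst = line.split("\t")
        table[src] = dst
    return table


def normalize_nonstandard(
    s: ReceptorStructure, mapping: Mapping[str, str] | None = None
) -> ReceptorStructure:
    """Rename non-standard residues to their standard counterparts.

    Identity on all-standard input; unmappable names are a hard error.
    """
    if mapping is None:
        mapping = load_nonstandard_table()
    changed = False
    new_chains = []
    for chain in s.chains:
        new_res = []
        for res in chain.residues:
            name = res.name
            if name not in AMINO_ALPHABET:
                if name not in mapping:
                    raise UnmappableResidueError(
                        f"residue {name} (chain {chain.chain_id} "
                        f"{res.seq_id}{res.insertion_code}) has no entry in "
                        "the normalization table"
                    )
                name = mapping[name]
                changed = True
            new_res.append(Residue(name, res.seq_id, res.insertion_code,
                                   dict(res.atoms)))
        new_chains.append(Chain(chain.chain_id, new_res))
    if not changed:
        return s
    return ReceptorStructure(new_chains, source_metadata=dict(s.source_metadata))


def validate_peptide(sequence: str, ss: str | None = None) -> PeptideSpec:
    """Validate and normalize peptide input; all-coil SS when omitted."""
    seq = sequence.strip().upper()
    if not seq:
        raise PeptideError("peptide sequence is empty")
    if len(seq) > MAX_PEPTIDE_LENGTH:
        raise PeptideError(
            f"peptide has {len(seq)} residues; maximum is {MAX_PEPTIDE_LENGTH}"
        )
    bad = sorted(set(seq) - set(THREE_LETTER))
    if bad:
        raise PeptideError(
            f"non-standard amino-acid letter(s) in sequence: {','.join(bad)}"
        )
    if ss is None:
        ss_states = "C" * len(seq)
    else:
        ss_states = ss.strip().upper()
        if len(ss_states) != len(seq):
            raise PeptideError(
                f"secondary-structure length {len(ss_states)} does not match "
                f"sequence length {len(seq)}"
            )
        bad_ss = sorted(set(ss_states) - SS_ALPHABET)
        if bad_ss:
            raise PeptideError(
                f"secondary-structure letters must be H/E/C, got: "
                + ",".join(bad_ss)
            )
    return PeptideSpec(seq, ss_states)


def _free_chain_id(used: set[str]) -> str:
    for cid in "PQRSTUVWXYZABCDEFGHIJKLMNO" + string.digits:
        if cid not in used:
            return cid
    raise ValueError("no free chain identifier for the peptide chain")


def _ca_line(serial: int, res_name: str, chain_id: str, seq_id: int,
             icode: str, xyz: np.ndarray) -> str:
    return (
        f"ATOM  {serial % 100000:5d}  CA  {res_name:>3s} {chain_id}"
        f"{seq_id % 10000:4d}{icode or ' ':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {' C':>2s}"
    )


def write_models_pdb(models, dest=None) -> str:
    """Write snapshots as a multi-MODEL C-alpha-only PDB file.

    Receptor chains keep their author numbering; the peptide is written as
    a chain ID not used by the receptor. Returns the PDB text; also writes
    it to ``dest`` (path or file object) when given.
    """
    models = list(models)
    if not models:
        raise ValueError("empty model list")

    first = models[0].complex
    rec = first.receptor
    used = set(rec.chain_ids) if rec.chain_ids is not None else {"A"}
    pep_chain = _free_chain_id(used)

    lines: list[str] = []
    for m, snap in enumerate(models, start=1):
        cplx = snap.complex
        if cplx.receptor.n != rec.n or cplx.peptide.n != first.peptide.n:
            raise ValueError("models do not share residue topology")
        lines.append(f"MODEL     {m:4d}")
        serial = 1
        r = cplx.receptor
        prev_chain = None
        for i in range(r.n):
            cid = r.chain_ids[i] if r.chain_ids is not None else "A"
            if prev_chain is not None and cid != prev_chain:
                lines.append("TER")
            prev_chain = cid
            seq_id, icode = (
                r.author_ids[i] if r.author_ids is not None else (i + 1, "")
            )
            res3 = THREE_LETTER.get(r.sequence[i], "UNK")
            lines.append(_ca_line(serial, res3, cid, seq_id, icode, r.ca[i]))
            serial += 1
        lines.append("TER")
        p = cplx.peptide
        for i in range(p.n):
            res3 = THREE_LETTER.get(p.sequence[i], "UNK")
            lines.append(_ca_line(serial, res3, pep_chain, i + 1, "", p.ca[i]))
            serial += 1
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"

    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)
    return text
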