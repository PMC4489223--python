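import numpy as np
import pytest

from cgdock.cg_model import CGChain, CGComplex, CGSnapshot, build_cg, peptide_chain
from cgdock.fixtures import groove_case, ideal_helix, random_coil_globule
from cgdock.structures_io import validate_peptide


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def helix20():
    return ideal_helix(20)


@pytest.fixture(scope="session")
def helix20_cg(helix20):
    return build_cg(helix20)


@pytest.fixture(scope="session")
def groove():
    return groove_case()


@pytest.fixture(scope="session")
def globule60():
    return random_coil_globule(60, seed=11)


@pytest.fixture
def two_atom_receptor():
    ca = np.array([[0.0, 0.0, 0.0], [30.0, 0.0, 0.0]])
    return CGChain(ca=ca, sc=ca.copy(), sequence="GG", ss="CC",
                   chain_index=np.zeros(2, dtype=int))


def make_snapshot(receptor_cg, pep_ca, e_binding=0.0, replica=0, index=0,
                  bound=True, sequence=None):
    """Synthetic snapshot with a given peptide trace / binding energy."""
    pep_ca = np.asarray(pep_ca, dtype=float)
    seq = sequence or "A" * len(pep_ca)
    pep = peptide_chain(validate_peptide(seq), pep_ca)
    return CGSnapshot(
        complex=CGComplex(receptor_cg.copy(), pep),
        replica_index=replica,
        macrocycle_index=0,
        snapshot_index=index,
        temperature=1.0,
        energy_total=e_binding,
        energy_binding=e_binding,
        energy_restraint=0.0,
        bound=bound,
    )


@pytest.fixture
def snapshot_factory(helix20_cg):
    def factory(pep_ca, **kw):
        return make_snapshot(helix20_cg, pep_ca, **kw)
    return factory


def build_pdb_text(residues):
    """Minimal PDB text from [(resname, chain, seqid, {atom: xyz}), ...]."""
    lines = []
    serial = 1
    for resname, chain, seqid, atoms in residues:
        for name, xyz in atoms.items():
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} {chain}"
                f"{seqid:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def backbone(x=0.0, y=0.0, z=0.0):
    return {
        "N": (x - 1.4, y, z),
        "CA": (x, y, z),
        "C": (x + 1.5, y, z),
        "O": (x + 1.5, y + 1.2, z),
    }
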