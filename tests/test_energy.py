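import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from cgdock.cg_model import CGChain, CGComplex, place_sc_from_trace
from cgdock.energy import (
    AA_ORDER,
    EnergyModel,
    Restraint,
    RestraintSet,
    default_energy_model,
    generate_restraints,
    is_bound,
    restraint_energy,
    restraints_to_tsv,
    total_energy,
)
from cgdock.structures_io import validate_peptide
from cgdock.cg_model import peptide_chain, random_peptide_conformation, place_on_sphere


def chain_from_ca(ca, sequence=None, chain_index=None):
    ca = np.asarray(ca, dtype=float)
    seq = sequence or "A" * len(ca)
    ci = (np.asarray(chain_index) if chain_index is not None
          else np.zeros(len(ca), dtype=int))
    return CGChain(ca=ca, sc=place_sc_from_trace(ca, seq), sequence=seq,
                   ss="C" * len(ca), chain_index=ci)


# ---------------------------------------------------------------- oracle --

def reference_energy(cplx, model, rs):
    """Slow, explicit reimplementation of the documented energy terms."""
    rec, pep = cplx.receptor, cplx.peptide
    e_restr = 0.0
    for r in rs.restraints:
        d = np.linalg.norm(rec.ca[r.i] - rec.ca[r.j])
        e_restr += r.slope * max(0.0, abs(d - r.d_ref) - r.tolerance)

    e_bind = 0.0
    excluded = set(model.excluded_residues)
    for i in range(rec.n):
        for j in range(pep.n):
            d_ca = np.linalg.norm(rec.ca[i] - pep.ca[j])
            if d_ca > model.interaction_cap:
                continue
            if d_ca < model.clash_distance:
                e_bind += model.clash_weight * (model.clash_distance - d_ca)
            d_sc = np.linalg.norm(rec.sc[i] - pep.sc[j])
            if model.contact_min <= d_sc <= model.contact_max:
                ai = AA_ORDER.index(rec.sequence[i])
                aj = AA_ORDER.index(pep.sequence[j])
                e_bind += model.contact_matrix[ai, aj]
                if i in excluded:
                    e_bind += model.exclusion_penalty

    e_intra = 0.0
    for i in range(pep.n):
        for j in range(i + 2, pep.n):
            d = np.linalg.norm(pep.ca[i] - pep.ca[j])
            e_intra += model.clash_weight * max(0.0, 4.0 - d)
    for i in range(1, pep.n - 1):
        b1 = pep.ca[i - 1] - pep.ca[i]
        b2 = pep.ca[i + 1] - pep.ca[i]
        cosang = b1 @ b2 / (np.linalg.norm(b1) * np.linalg.norm(b2))
        theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        out = max(0.0, model.angle_min_deg - theta) + max(
            0.0, theta - model.angle_max_deg)
        e_intra += model.angle_weight * np.deg2rad(out)
        if pep.ss[i] == "E":
            e_intra += model.ss_bias_strength * np.deg2rad(
                max(0.0, 145.0 - theta))
    for i in range(pep.n - 3):
        if pep.ss[i] == "H" and pep.ss[i + 3] == "H":
            d3 = np.linalg.norm(pep.ca[i + 3] - pep.ca[i])
            e_intra += model.ss_bias_strength * (d3 - 5.1) ** 2
    longest = max(
        np.linalg.norm(rec.ca[i] - rec.ca[j])
        for i in range(rec.n) for j in range(i + 1, rec.n)
    )
    sep = np.linalg.norm(pep.ca.mean(axis=0) - rec.ca.mean(axis=0))
    e_intra += model.wall_weight * max(
        0.0, sep - (longest + model.wall_margin))
    return e_intra + e_bind + e_restr, e_bind, e_restr


# ---------------------------------------------------------- restraints ----

class TestGenerateRestraints:
    def test_distance_band_excludes_close_pair(self):
        # residues 0 and 6: gap 6 but 4.9 A apart -> no restraint
        ca = np.zeros((7, 3))
        ca[:, 0] = [0, 20, 40, 60, 80, 100, 4.9]
        rs = generate_restraints(chain_from_ca(ca))
        assert not any({r.i, r.j} == {0, 6} for r in rs.restraints)

    def test_gap_rule_excludes_close_sequence_pair(self):
        # residues 0 and 4: 10 A apart but gap 4 -> no restraint
        ca = np.zeros((5, 3))
        ca[:, 0] = [0, 100, 200, 300, 10.0]
        rs = generate_restraints(chain_from_ca(ca))
        assert len(rs) == 0

    def test_interchain_pairs_always_sequence_eligible(self):
        ca = np.zeros((2, 3))
        ca[1, 0] = 10.0
        c = chain_from_ca(ca, chain_index=[0, 1])
        rs = generate_restraints(c)
        assert len(rs) == 1 and rs.restraints[0].d_ref == pytest.approx(10.0)

    def test_helix_matches_bruteforce_enumeration(self, helix20_cg):
        rs = generate_restraints(helix20_cg)
        got = {(r.i, r.j): r.d_ref for r in rs.restraints}
        expected = {}
        ca = helix20_cg.ca
        for i in range(20):
            for j in range(i + 1, 20):
                d = np.linalg.norm(ca[i] - ca[j])
                if j - i >= 5 and 5.0 <= d <= 15.0:
                    expected[(i, j)] = d
        assert set(got) == set(expected)
        for key in got:
            assert got[key] == pytest.approx(expected[key], abs=1e-9)

    def test_flexibility_marks_modify_slopes(self, helix20_cg):
        rs = generate_restraints(helix20_cg, marks={0: "moderate", 7: "full"})
        for r in rs.restraints:
            if 7 in (r.i, r.j):
                assert r.slope == 0.0
            elif 0 in (r.i, r.j):
                assert r.slope == pytest.approx(0.5)
            else:
                assert r.slope == pytest.approx(1.0)

    def test_more_flexible_mark_wins(self):
        ca = np.zeros((7, 3))
        ca[6, 0] = 10.0
        rs = generate_restraints(chain_from_ca(ca[[0, 1, 2, 3, 4, 5, 6]]),
                                 marks={0: "moderate", 6: "full"})
        r = next(r for r in rs.restraints if {r.i, r.j} == {0, 6})
        assert r.slope == 0.0

    def test_invariant_under_rigid_motion(self, helix20_cg, rng):
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(scale=30, size=3)
        moved = helix20_cg.copy()
        moved.ca = moved.ca @ rot.T + shift
        moved.sc = moved.sc @ rot.T + shift
        a = generate_restraints(helix20_cg)
        b = generate_restraints(moved)
        assert [(r.i, r.j) for r in a.restraints] == \
            [(r.i, r.j) for r in b.restraints]
        np.testing.assert_allclose(a.d_ref, b.d_ref, atol=1e-9)

    def test_tsv_export(self, helix20_cg, tmp_path):
        rs = generate_restraints(helix20_cg)
        text = restraints_to_tsv(rs, tmp_path / "r.tsv")
        assert text.splitlines()[0] == "i\tj\td_ref\ttolerance\tslope"
        assert len(text.splitlines()) == len(rs) + 1


class TestRestraintEnergy:
    def test_within_tolerance_free(self):
        r = Restraint(0, 5, 10.0)
        assert restraint_energy(r, 10.5) == 0.0

    def test_linear_beyond_tolerance(self):
        r = Restraint(0, 5, 10.0, slope=2.5)
        assert restraint_energy(r, 12.0) == pytest.approx(2.5 * 1.0)

    def test_fully_flexible_always_zero(self):
        r = Restraint(0, 5, 10.0, slope=0.0)
        for d in (2.0, 10.0, 40.0):
            assert restraint_energy(r, d) == 0.0

    @given(st.floats(min_value=0.1, max_value=30.0))
    @settings(max_examples=60, deadline=None)
    def test_flat_bottom_shape(self, d):
        r = Restraint(0, 5, 12.0, slope=1.7)
        e = restraint_energy(r, d)
        viol = abs(d - 12.0)
        if viol <= 1.0:
            assert e == 0.0
        else:
            assert e == pytest.approx(1.7 * (viol - 1.0))

    def test_slope_by_finite_difference(self):
        r = Restraint(0, 5, 10.0, slope=3.0)
        h = 1e-6
        for d in (13.0, 6.5):
            grad = (restraint_energy(r, d + h) - restraint_energy(r, d - h)) / (2 * h)
            assert abs(grad) == pytest.approx(3.0, rel=1e-4)

    def test_symmetric_about_reference(self):
        r = Restraint(0, 5, 10.0, slope=1.0)
        assert restraint_energy(r, 13.0) == pytest.approx(restraint_energy(r, 7.0))


class TestRestraintSet:
    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError):
            RestraintSet([Restraint(0, 5, 8.0), Restraint(5, 0, 9.0)])

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            Restraint(0, 5, 8.0, slope=-1.0)


# -------------------------------------------------------- total energy ----

def random_complex(seed, n_rec=12, pep="FWKLA"):
    rng = np.random.default_rng(seed)
    rec_ca = np.cumsum(
        3.8 * _unit_steps(rng, n_rec), axis=0)
    rec = chain_from_ca(rec_ca, sequence="".join(
        rng.choice(list(AA_ORDER), n_rec)))
    spec = validate_peptide(pep)
    conf = random_peptide_conformation(spec, rng)
    offset = rng.normal(scale=6.0, size=3)
    conf.ca = conf.ca + rec_ca.mean(axis=0) + offset
    conf.sc = place_sc_from_trace(conf.ca, spec.sequence)
    return CGComplex(rec, conf)


def _unit_steps(rng, n):
    steps = rng.normal(size=(n, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    steps[0] = 0
    return steps


class TestTotalEnergy:
    def test_far_peptide_zero_binding(self, helix20_cg):
        pep = peptide_chain(
            validate_peptide("AAAAA"),
            np.array([[100.0 + 3.8 * i, 0, 0] for i in range(5)]))
        cplx = CGComplex(helix20_cg.copy(), pep)
        rs = generate_restraints(helix20_cg)
        _, e_bind, e_restr = total_energy(cplx, default_energy_model(), rs)
        assert e_bind == 0.0
        assert e_restr == 0.0

    def test_single_contact_equals_matrix_entry(self):
        # one receptor residue (W), one peptide residue (F), sc-sc inside
        # the shell, ca-ca inside the cap, no clash
        rec = CGChain(ca=np.array([[0.0, 0, 0]]), sc=np.array([[1.0, 0, 0]]),
                      sequence="W", ss="C", chain_index=np.zeros(1, int))
        pep = CGChain(ca=np.array([[6.0, 0, 0]]), sc=np.array([[6.5, 0, 0]]),
                      sequence="F", ss="C", chain_index=np.zeros(1, int))
        model = default_energy_model()
        _, e_bind, _ = total_energy(
            CGComplex(rec, pep), model, RestraintSet([]))
        w, f = AA_ORDER.index("W"), AA_ORDER.index("F")
        assert e_bind == pytest.approx(model.contact_matrix[w, f])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        cplx = random_complex(seed)
        model = default_energy_model(excluded_residues=frozenset({0, 3}))
        rs = generate_restraints(cplx.receptor)
        got = total_energy(cplx, model, rs)
        want = reference_energy(cplx, model, rs)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_invariant_under_global_rigid_motion(self, rng):
        cplx = random_complex(3)
        model = default_energy_model()
        rs = generate_restraints(cplx.receptor)
        before = total_energy(cplx, model, rs)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(scale=50, size=3)
        moved = cplx.copy()
        for chain in (moved.receptor, moved.peptide):
            chain.ca = chain.ca @ rot.T + shift
            chain.sc = chain.sc @ rot.T + shift
        after = total_energy(moved, model, rs)
        np.testing.assert_allclose(after, before, atol=1e-9)

    def test_binding_zero_whenever_unbound(self):
        model = default_energy_model()
        rs = RestraintSet([])
        for seed in range(30):
            cplx = random_complex(seed + 100)
            _, e_bind, _ = total_energy(cplx, model, rs)
            if not is_bound(cplx, model.bound_cutoff):
                assert e_bind == 0.0


class TestIsBound:
    def test_initial_placement_unbound(self, helix20_cg, rng):
        pep = random_peptide_conformation(validate_peptide("ACDEF"), rng)
        cplx = place_on_sphere(pep, helix20_cg, rng)
        assert not is_bound(cplx)

    def test_exact_cutoff_is_bound(self):
        rec = chain_from_ca([[0, 0, 0], [3.8, 0, 0]])
        pep = chain_from_ca([[0, 8.0, 0]], sequence="A")
        assert is_bound(CGComplex(rec, pep), cutoff=8.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_minimum_scan(self, seed):
        cplx = random_complex(seed + 50)
        dmin = min(
            np.linalg.norm(cplx.receptor.ca[i] - cplx.peptide.ca[j])
            for i in range(cplx.receptor.n) for j in range(cplx.peptide.n)
        )
        assert is_bound(cplx) == (dmin <= 8.0)


class TestEnergyModel:
    def test_contact_matrix_symmetric(self):
        m = default_energy_model()
        np.testing.assert_allclose(m.contact_matrix, m.contact_matrix.T)

    def test_asymmetric_matrix_rejected(self):
        bad = np.zeros((20, 20))
        bad[0, 1] = 1.0
        with pytest.raises(ValueError):
            EnergyModel(contact_matrix=bad)
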