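"""Closed-form physics limits, brute-force oracles and exact bookkeeping."""

import math

import numpy as np
import pandas as pd
import pytest

from allopath.energetics import (
    COULOMB_CONSTANT,
    EnergyParams,
    binding_energy,
    effective_born_radii,
    gb_energy,
    pair_energy_mm,
    per_residue_decomposition,
    polar_solvation,
    sasa_nonpolar,
    verify_table2_consistency,
)

from conftest import make_ensemble, make_topology


# --- gas-phase pair energies -------------------------------------------------

def test_unit_charges_at_one_angstrom_give_coulomb_constant():
    top = make_topology(2, charges=[1.0, 1.0], epsilons=[0.0, 0.0])
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    _, e_ele = pair_energy_mm(coords, top, [0], [1], interior_dielectric=1.0)
    assert e_ele == pytest.approx(332.0637, abs=1e-10)


def test_lj_minimum_is_minus_epsilon():
    top = make_topology(2, charges=[0.0, 0.0], epsilons=[0.25, 0.25], rmin_halves=[1.7, 1.7])
    coords = np.array([[0.0, 0, 0], [3.4, 0, 0]])  # r = r_min
    e_vdw, _ = pair_energy_mm(coords, top, [0], [1])
    assert e_vdw == pytest.approx(-0.25, abs=1e-12)


def test_electrostatics_scale_inversely_with_dielectric():
    rng = np.random.default_rng(0)
    top = make_topology(6, charges=rng.uniform(-1, 1, 6))
    coords = rng.uniform(0, 10, size=(6, 3))
    _, e2 = pair_energy_mm(coords, top, [0, 1, 2], [3, 4, 5], interior_dielectric=2.0)
    _, e4 = pair_energy_mm(coords, top, [0, 1, 2], [3, 4, 5], interior_dielectric=4.0)
    assert e2 == pytest.approx(2.0 * e4, rel=1e-12)


def test_pair_energies_equal_brute_force_double_loop():
    rng = np.random.default_rng(5)
    n = 10
    top = make_topology(
        n,
        charges=rng.uniform(-1, 1, n),
        epsilons=rng.uniform(0.05, 0.3, n),
        rmin_halves=rng.uniform(1.5, 2.5, n),
    )
    coords = rng.uniform(0, 12, size=(n, 3))
    ga, gb = [0, 1, 2, 3, 4], [5, 6, 7, 8, 9]
    e_vdw, e_ele = pair_energy_mm(coords, top, ga, gb, interior_dielectric=4.0)
    brute_vdw = brute_ele = 0.0
    for i in ga:
        for j in gb:
            r = np.linalg.norm(coords[i] - coords[j])
            brute_ele += COULOMB_CONSTANT * top.charges[i] * top.charges[j] / (4.0 * r)
            eps = math.sqrt(top.epsilons[i] * top.epsilons[j])
            rmin = top.rmin_halves[i] + top.rmin_halves[j]
            brute_vdw += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
    assert e_ele == pytest.approx(brute_ele, rel=1e-12)
    assert e_vdw == pytest.approx(brute_vdw, rel=1e-12)


def test_overlapping_atoms_rejected():
    top = make_topology(2, charges=[1.0, -1.0])
    coords = np.zeros((2, 3))
    with pytest.raises(ValueError, match="overlap"):
        pair_energy_mm(coords, top, [0], [1])


# --- polar solvation ---------------------------------------------------------

def test_single_ion_recovers_born_formula():
    q, radius = 1.0, 2.0
    e = gb_energy(np.zeros((1, 3)), [q], [radius], interior_dielectric=1.0, exterior_dielectric=80.0)
    born = -COULOMB_CONSTANT / 2.0 * (1.0 - 1.0 / 80.0) * q**2 / radius
    assert e == pytest.approx(born, rel=1e-12)


def test_polar_energy_vanishes_when_dielectrics_match():
    rng = np.random.default_rng(2)
    coords = rng.uniform(0, 8, (5, 3))
    e = gb_energy(coords, rng.uniform(-1, 1, 5), np.full(5, 1.8),
                  interior_dielectric=4.0, exterior_dielectric=4.0)
    assert e == 0.0


def test_two_atom_energy_matches_hand_evaluated_expression():
    coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
    q = np.array([0.5, -0.5])
    rho = np.array([1.6, 2.0])
    e = gb_energy(coords, q, rho, interior_dielectric=4.0, exterior_dielectric=80.0)

    # independent transcription of the descreening + Born-pair expressions
    def inv_reff(i, j):
        r = 3.0
        u = r + rho[j]
        l = max(rho[i], abs(r - rho[j]))
        integral = (
            1 / l - 1 / u + r / 4 * (1 / u**2 - 1 / l**2)
            + 1 / (2 * r) * math.log(l / u)
            + rho[j] ** 2 / (4 * r) * (1 / l**2 - 1 / u**2)
        )
        return 1 / rho[i] - 0.5 * integral

    reff = np.array([1 / inv_reff(0, 1), 1 / inv_reff(1, 0)])
    tau = 1 / 4.0 - 1 / 80.0
    expected = 0.0
    for i in range(2):
        for j in range(2):
            r2 = 9.0 if i != j else 0.0
            f = math.sqrt(r2 + reff[i] * reff[j] * math.exp(-r2 / (4 * reff[i] * reff[j])))
            expected += -0.5 * COULOMB_CONSTANT * tau * q[i] * q[j] / f
    assert e == pytest.approx(expected, abs=1e-6)


def test_isolated_atom_effective_radius_is_intrinsic():
    coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
    reff = effective_born_radii(coords, np.array([1.5, 2.5]))
    np.testing.assert_allclose(reff, [1.5, 2.5], rtol=1e-3)


def test_non_positive_radius_rejected():
    with pytest.raises(ValueError, match="radius"):
        effective_born_radii(np.zeros((1, 3)), np.array([0.0]))


def test_polar_solvation_uses_topology_parameters():
    top = make_topology(2, charges=[1.0, 0.0], rmin_halves=[2.0, 2.0])
    coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
    e = polar_solvation(coords, top, [0], interior_dielectric=1.0, exterior_dielectric=80.0)
    born = -COULOMB_CONSTANT / 2.0 * (1.0 - 1.0 / 80.0) / 2.0
    assert e == pytest.approx(born, rel=1e-12)


# --- nonpolar / SASA ---------------------------------------------------------

def test_isolated_sphere_area_within_one_percent():
    sasa, _ = sasa_nonpolar(np.zeros((1, 3)), [2.0], probe_radius=1.4, point_number=960)
    assert sasa == pytest.approx(4 * math.pi * 3.4**2, rel=0.01)


def test_nonpolar_intercept_is_recovered_at_zero_area():
    sasa, e = sasa_nonpolar(np.zeros((1, 3)), [1.9], gamma=0.00542, b=0.92)
    assert e - 0.00542 * sasa == pytest.approx(0.92, abs=1e-9)


def test_fully_buried_atom_contributes_no_area():
    # a small sphere strictly inside a large one
    coords = np.array([[0.0, 0, 0], [0.1, 0, 0]])
    radii = np.array([2.5, 0.5])
    per_atom, _ = sasa_nonpolar(coords, radii, per_atom=True)
    alone, _ = sasa_nonpolar(coords[:1], radii[:1])
    assert per_atom[1] == pytest.approx(0.0, abs=1e-9)
    assert per_atom[0] == pytest.approx(alone, rel=1e-6)


# --- binding energy and decomposition ---------------------------------------

def binding_toy(n_frames=4, seed=0):
    rng = np.random.default_rng(seed)
    base = np.array(
        [[0.0, 0, 0], [4.0, 0, 0], [0.0, 4, 0], [9.0, 0, 0], [13.0, 0, 0], [9.0, 4, 0]]
    )
    frames = base[None] + rng.normal(scale=0.05, size=(n_frames, 6, 3))
    top = make_topology(
        6, segments=["R"] * 3 + ["L"] * 3, charges=[0.5, -0.5, 0.5, -0.5, 0.5, -0.5]
    )
    return make_ensemble(frames, topology=top)


def test_bookkeeping_identities_hold_exactly():
    bd = binding_energy(binding_toy(), "R", "L")
    df = bd.per_frame
    assert np.abs(df.dE_MM - (df.dE_vdW + df.dE_ele + df.dE_int)).max() < 1e-10
    assert np.abs(df.dG_solv - (df.dE_polar_GB + df.dE_nonpolar)).max() < 1e-10
    assert np.abs(df.dG_binding - (df.dE_MM + df.dG_solv)).max() < 1e-10
    assert bd.e_mm[0] == pytest.approx(bd.e_vdw[0] + bd.e_ele[0] + bd.e_int[0], abs=1e-6)
    assert bd.g_binding[0] == pytest.approx(bd.e_mm[0] + bd.g_solv[0], abs=1e-6)
    assert bd.e_int == (0.0, 0.0)  # single-trajectory mode
    assert bd.entropy_term == "omitted"


def test_two_bead_complex_matches_closed_form_electrostatics():
    top = make_topology(2, segments=["R", "L"], charges=[1.0, -1.0], epsilons=[0.0, 0.0])
    r = 6.0
    ens = make_ensemble(np.array([[[0.0, 0, 0], [r, 0, 0]]]), topology=top)
    bd = binding_energy(ens, "R", "L")
    assert bd.e_ele[0] == pytest.approx(-COULOMB_CONSTANT / (4.0 * r), rel=1e-12)
    assert bd.g_binding[0] == pytest.approx(bd.e_mm[0] + bd.g_solv[0], abs=1e-12)


def test_separation_limit():
    """Far apart: gas-phase and polar terms vanish; only the SASA intercept
    survives the complex - receptor - ligand difference (exactly -b)."""
    top = make_topology(4, segments=["R", "R", "L", "L"], charges=[0.0] * 4)
    base = np.array([[0.0, 0, 0], [4.0, 0, 0], [500.0, 0, 0], [504.0, 0, 0]])
    ens = make_ensemble(base[None], topology=top)
    bd = binding_energy(ens, "R", "L")
    assert abs(bd.e_vdw[0]) < 1e-10
    assert abs(bd.e_ele[0]) < 1e-10
    assert abs(bd.e_polar[0]) < 1e-9
    assert bd.e_nonpolar[0] == pytest.approx(-0.92, abs=1e-6)


def test_decomposition_sums_to_totals():
    params = EnergyParams()
    ens = binding_toy()
    bd = binding_energy(ens, "R", "L", params)
    table = per_residue_decomposition(ens, "R", "L", params)
    assert table["dE_vdW"].sum() == pytest.approx(bd.e_vdw[0], abs=1e-3)
    assert table["dE_ele"].sum() == pytest.approx(bd.e_ele[0], abs=1e-3)
    assert table["dE_polar_GB"].sum() == pytest.approx(bd.e_polar[0], abs=1e-3)
    assert table["dE_nonpolar"].sum() == pytest.approx(bd.e_nonpolar[0], abs=1e-3)
    assert table["dG_total"].sum() == pytest.approx(bd.g_binding[0], abs=1e-3)


def test_single_interacting_pair_carries_all_gas_phase_energy():
    top = make_topology(2, segments=["R", "L"], charges=[1.0, -1.0])
    ens = make_ensemble(np.array([[[0.0, 0, 0], [5.0, 0, 0]]]), topology=top)
    bd = binding_energy(ens, "R", "L")
    table = per_residue_decomposition(ens, "R", "L")
    by_res = table.set_index("residue")
    pair_sum = by_res.loc[["1", "2"], ["dE_vdW", "dE_ele"]].to_numpy().sum()
    assert pair_sum == pytest.approx(bd.e_vdw[0] + bd.e_ele[0], abs=1e-9)


def test_decomposition_matches_brute_force_pair_ledger():
    rng = np.random.default_rng(8)
    n = 10
    top = make_topology(
        n,
        segments=["R"] * 5 + ["L"] * 5,
        charges=rng.uniform(-0.8, 0.8, n),
        epsilons=rng.uniform(0.05, 0.2, n),
        rmin_halves=rng.uniform(1.6, 2.2, n),
    )
    coords = rng.uniform(0, 10, size=(n, 3))
    while np.min(np.linalg.norm(coords[:5][:, None] - coords[5:][None], axis=-1)) < 2.0:
        coords = rng.uniform(0, 10, size=(n, 3))
    ens = make_ensemble(coords[None], topology=top)
    table = per_residue_decomposition(ens, "R", "L").set_index("residue")

    ledger = {str(i + 1): np.zeros(2) for i in range(n)}
    for i in range(5):
        for j in range(5, n):
            r = np.linalg.norm(coords[i] - coords[j])
            ele = COULOMB_CONSTANT * top.charges[i] * top.charges[j] / (4.0 * r)
            eps = math.sqrt(top.epsilons[i] * top.epsilons[j])
            rmin = top.rmin_halves[i] + top.rmin_halves[j]
            vdw = eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
            for k in (i, j):
                ledger[str(k + 1)] += 0.5 * np.array([vdw, ele])
    for res, (vdw, ele) in ledger.items():
        assert table.loc[res, "dE_vdW"] == pytest.approx(vdw, abs=1e-9)
        assert table.loc[res, "dE_ele"] == pytest.approx(ele, abs=1e-9)


def test_overlapping_receptor_ligand_rejected():
    ens = binding_toy()
    with pytest.raises(ValueError, match="overlap"):
        binding_energy(ens, "R", "R")


# --- published-table consistency --------------------------------------------

TERNARY = {"dE_vdW": -159.66, "dE_ele": -106.65, "dE_polar": 128.48, "dE_nonpolar": -18.39,
           "dE_MM": -266.31, "dG_solv": 110.09, "dG_binding": -156.22}
BINARY = {"dE_vdW": -138.73, "dE_ele": -154.08, "dE_polar": -163.28, "dE_nonpolar": -17.00,
          "dE_MM": -292.82, "dG_solv": -146.29, "dG_binding": -146.53}


def test_ternary_column_is_internally_consistent():
    report = verify_table2_consistency({"ternary": TERNARY}).iloc[0]
    assert report["dE_MM_recomputed"] == pytest.approx(-266.31, abs=1e-9)
    assert report["dG_solv_recomputed"] == pytest.approx(110.09, abs=1e-9)
    assert report["dG_binding_recomputed"] == pytest.approx(-156.22, abs=1e-9)
    assert bool(report["consistent"])
    assert not report["polar_sign_inconsistency"]


def test_binary_column_flags_polar_sign():
    report = verify_table2_consistency({"binary": BINARY}).iloc[0]
    assert report["dE_MM_recomputed"] == pytest.approx(-292.81, abs=1e-9)
    assert not report["consistent"]
    assert bool(report["polar_sign_inconsistency"])


def test_missing_component_rejected():
    with pytest.raises(ValueError, match="dE_polar"):
        verify_table2_consistency({"x": {"dE_vdW": 1.0, "dE_ele": 2.0, "dE_nonpolar": 3.0}})
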