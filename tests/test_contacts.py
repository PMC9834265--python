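"""Contact tables: metrics, oracle equivalence, invariances, key-residue rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from nanodoe import (
    make_toy_complex,
    parse_structure,
    residue_contact_table,
    select_key_residues,
)
from nanodoe.contacts import vdw_radius
from nanodoe.structures import AtomRecord, Structure


def _two_atom_structure(separation: float) -> Structure:
    return Structure([
        AtomRecord("A", "ALA", 1, "", "CA", "C", 0.0, 0.0, 0.0),
        AtomRecord("B", "GLY", 2, "", "CA", "C", separation, 0.0, 0.0),
    ])


def _random_structure(rng, n_a=6, n_b=7, atoms_per_res=3, spread=6.0) -> Structure:
    atoms = []
    for chain, n_res, base in (("A", n_a, 0.0), ("B", n_b, 3.0)):
        for r in range(n_res):
            center = rng.uniform(-spread, spread, 3) + base
            for k in range(atoms_per_res):
                x, y, z = center + rng.normal(0, 1.0, 3)
                atoms.append(AtomRecord(chain, "ALA", r + 1, "", f"C{k}", "C", x, y, z))
    return Structure(atoms)


def _brute_force_minima(structure, group_a, group_b, metric):
    """Independent oracle: all-atom-pairs double loop."""
    minima = {}
    for a in structure:
        if a.chain_id not in group_a:
            continue
        for b in structure:
            if b.chain_id not in group_b:
                continue
            d = np.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2)
            if metric == "vdw-gap":
                d -= vdw_radius(a.element) + vdw_radius(b.element)
            key = (a.residue_id, b.residue_id)
            if key not in minima or d < minima[key]:
                minima[key] = d
    return minima


def test_single_pair_distance_reported():
    table = residue_contact_table(_two_atom_structure(1.0), {"A"}, {"B"})
    assert len(table) == 1
    assert table.records[0].distance == pytest.approx(1.0, abs=1e-9)


def test_pair_beyond_reporting_radius_is_empty():
    table = residue_contact_table(_two_atom_structure(10.0), {"A"}, {"B"})
    assert len(table) == 0


def test_vdw_gap_metric_can_be_negative():
    table = residue_contact_table(_two_atom_structure(3.0), {"A"}, {"B"}, metric="vdw-gap")
    assert table.records[0].distance == pytest.approx(3.0 - 2 * 1.70)
    overlapping = residue_contact_table(_two_atom_structure(1.0), {"A"}, {"B"}, metric="vdw-gap")
    assert overlapping.records[0].distance < 0


@pytest.mark.parametrize("metric", ["min-atom", "vdw-gap"])
def test_matches_brute_force_all_pairs_oracle(metric):
    rng = np.random.default_rng(11)
    structure = _random_structure(rng)
    table = residue_contact_table(structure, {"A"}, {"B"}, metric=metric, radius=4.0)
    oracle = _brute_force_minima(structure, {"A"}, {"B"}, metric)
    expected = {k: v for k, v in oracle.items() if v <= 4.0}
    got = {(r.nb_residue, r.antigen_residue): r.distance for r in table.records}
    assert set(got) == set(expected)
    for key in expected:
        assert got[key] == pytest.approx(expected[key], abs=1e-9)


def test_planted_toy_complex_distances_recovered_to_1e6():
    planted = [1.1, 0.7, 2.19, 3.5]
    text = make_toy_complex(planted, seed=5)
    table = residue_contact_table(parse_structure(text), {"A"}, {"B"})
    minima = {rid.residue_number: d for rid, d in table.minima().items()}
    for k, d in enumerate(planted):
        assert minima[k + 1] == pytest.approx(d, abs=1e-6)
    # decoys (resnum >= 50) never appear
    assert all(n < 50 for n in minima)


def test_group_swap_transposes_table_with_identical_distances():
    rng = np.random.default_rng(3)
    structure = _random_structure(rng)
    fwd = residue_contact_table(structure, {"A"}, {"B"})
    rev = residue_contact_table(structure, {"B"}, {"A"})
    fwd_set = {(r.nb_residue, r.antigen_residue, round(r.distance, 9)) for r in fwd.records}
    rev_set = {(r.antigen_residue, r.nb_residue, round(r.distance, 9)) for r in rev.records}
    assert fwd_set == rev_set


@settings(deadline=None, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_min_atom_distances_invariant_under_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    structure = _random_structure(rng, n_a=3, n_b=3, atoms_per_res=2)
    rot = Rotation.random(random_state=seed + 1).as_matrix()
    shift = rng.uniform(-20, 20, 3)
    moved = Structure([
        AtomRecord(a.chain_id, a.residue_name, a.residue_number, a.insertion_code,
                   a.atom_name, a.element, *(rot @ np.array([a.x, a.y, a.z]) + shift))
        for a in structure
    ])
    t0 = residue_contact_table(structure, {"A"}, {"B"})
    t1 = residue_contact_table(moved, {"A"}, {"B"})
    d0 = {(r.nb_residue, r.antigen_residue): r.distance for r in t0.records}
    d1 = {(r.nb_residue, r.antigen_residue): r.distance for r in t1.records}
    assert set(d0) == set(d1)
    for key, d in d0.items():
        assert d >= 0
        assert d1[key] == pytest.approx(d, abs=1e-6)


def test_selection_errors():
    structure = _two_atom_structure(1.0)
    with pytest.raises(ValueError, match="overlap"):
        residue_contact_table(structure, {"A"}, {"A", "B"})
    with pytest.raises(ValueError, match="non-empty"):
        residue_contact_table(structure, set(), {"B"})


def test_key_residue_cutoff_is_strict_and_monotone():
    planted = [2.19, 2.2, 1.0, 3.0]
    table = residue_contact_table(parse_structure(make_toy_complex(planted, seed=1)), {"A"}, {"B"})
    selected = select_key_residues(table, 2.2)
    assert [r.residue_number for r in selected] == [1, 3]  # 2.19 in, 2.20 out
    # monotone non-decreasing as a set in the cutoff
    prev: set = set()
    for cutoff in (0.5, 1.5, 2.2, 2.5, 5.0):
        cur = set(select_key_residues(table, cutoff))
        assert prev <= cur
        prev = cur
    assert select_key_residues(table, 0.2) == []
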