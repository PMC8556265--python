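"""Water-network tests: H-bond detection vs brute force, regions, exclusivity,
single-file segmentation, and orientation inference."""

import numpy as np
import pytest

from chw import pore, waters
from chw._geom import random_rotation
from chw.pore import ChannelAxis
from chw.structure import Atom, Residue, StructureModel
from chw.synth import PoreSpec, make_toy_pore

from conftest import make_model, make_water

Z_AXIS = ChannelAxis(np.zeros(3), (0, 0, 1), (-20, 20))


def water_model(*positions):
    m = StructureModel("wm")
    m.waters = [make_water(*p, number=i + 1) for i, p in enumerate(positions)]
    return m


# ------------------------------------------------------------------ H-bonds

@pytest.mark.parametrize(
    "d,expected_klass",
    [(2.80, "typical"), (3.10, "standard"), (3.40, "standard"), (3.50, None)],
)
def test_hbond_distance_classes(d, expected_klass):
    """Boundary-inclusive classes: ≤2.8 typical, ≤3.4 standard, beyond none."""
    m = water_model((0, 0, 0), (0, 0, d))
    bonds = waters.detect_hbonds(m)
    if expected_klass is None:
        assert bonds == []
    else:
        assert len(bonds) == 1
        assert bonds[0].klass == expected_klass
        assert bonds[0].distance == pytest.approx(d)


def test_hbonds_match_bruteforce_and_monotonic():
    """Count equals an all-pairs scan; raising d_max never loses bonds."""
    rng = np.random.default_rng(12)
    pts = rng.uniform(0, 12, size=(40, 3))
    m = water_model(*pts)
    for d_max in (2.8, 3.0, 3.4, 4.0):
        got = waters.detect_hbonds(m, d_max=d_max)
        brute = sum(
            1
            for i in range(len(pts))
            for j in range(i + 1, len(pts))
            if np.linalg.norm(pts[i] - pts[j]) <= d_max
        )
        assert len(got) == brute
    counts = [len(waters.detect_hbonds(m, d_max=d)) for d in (2.6, 3.0, 3.4, 3.8)]
    assert counts == sorted(counts)


def test_hbonds_exclude_same_residue_pairs():
    res = Residue("GLN", 5, "", "A", [
        Atom("O", "OE1", "", np.zeros(3), 20.0, 1.0, "GLN", 5, "", "A", False, False),
        Atom("N", "NE2", "", np.array([0.0, 0.0, 2.3]), 20.0, 1.0, "GLN", 5, "", "A", False, False),
    ])
    m = StructureModel("x")
    m.chains["A"] = [res]
    assert waters.detect_hbonds(m) == []


def test_hbond_donor_assignment_to_backbone_carbonyl():
    m = water_model((0, 0, 0))
    m.chains["A"] = [Residue("GLY", 1, "", "A", [
        Atom("O", "O", "", np.array([2.7, 0, 0]), 20.0, 1.0, "GLY", 1, "", "A", False, False)
    ])]
    (bond,) = waters.detect_hbonds(m)
    water_is_a = bond.atom_a.is_water
    assert bond.donor_assignment == ("a_donates" if water_is_a else "b_donates")


# ------------------------------------------------------------------ regions

@pytest.fixture(scope="module")
def pore_with_profile():
    model = make_toy_pore(PoreSpec(radius_profile=lambda z: 5.0, z_range=(-22, 22)))
    axis = ChannelAxis(np.zeros(3), (0, 0, 1), (-21, 21))
    profile = pore.compute_profile(model, axis, step=1.0)
    return model, axis, profile


def test_classify_waters_census(pore_with_profile):
    model, axis, profile = pore_with_profile
    model = StructureModel("t", chains=model.chains)
    model.waters = (
        [make_water(0, 0, z, 100 + i) for i, z in enumerate(np.linspace(-14, 14, 5))]
        + [make_water(0, 0, -17.0, 200), make_water(0, 0, 17.0, 201)]
        + [make_water(0, 20.0, 0.0, 300)]  # far off-axis at channel z → bulk
    )
    spec = waters.RegionSpec(channel_z=(-15, 15), vestibule_z=((-21, -15), (15, 21)))
    graph = waters.classify_waters(model, axis, profile, spec)
    assert graph.census == {
        "channel": 5,
        "extracellular_vestibule": 1,
        "intracellular_vestibule": 1,
        "bulk": 1,
    }
    assert sum(graph.census.values()) == len(model.waters)
    # partition: every water got exactly one region label
    assert all(w.region in graph.census for w in graph.nodes)


def test_region_spec_rejects_overlap():
    with pytest.raises(ValueError):
        waters.RegionSpec(channel_z=(-15, 15), vestibule_z=((-20, -10), (15, 20)))


def test_label_channel_waters_by_z_order(pore_with_profile):
    model, axis, profile = pore_with_profile
    model = StructureModel("t", chains=model.chains)
    zs = [3.0, -5.0, 11.0, 0.0]
    model.waters = [make_water(0, 0, z, 50 + i) for i, z in enumerate(zs)]
    spec = waters.RegionSpec(channel_z=(-15, 15), vestibule_z=((-21, -15), (15, 21)))
    graph = waters.classify_waters(model, axis, profile, spec)
    waters.label_channel_waters(graph, axis)
    ordered = sorted(graph.nodes, key=lambda w: float(axis.z_of(w.coords)))
    assert [w.label for w in ordered] == ["Wat1", "Wat2", "Wat3", "Wat4"]


# ------------------------------------------------------------------ exclusivity

def test_exclusive_pairs_exemplar_and_cutoff():
    close = water_model((0, 0, 0), (0, 0, 2.3))
    pairs, groups = waters.exclusive_pairs(close.waters)
    assert len(pairs) == 1 and pairs[0][2] == pytest.approx(2.3)
    apart = water_model((0, 0, 0), (0, 0, 2.6))
    assert waters.exclusive_pairs(apart.waters)[0] == []


def test_exclusive_pairs_transitive_group():
    """Pairwise 2.3/2.4/2.4 Å → one exclusion group of three."""
    a, b = np.array([0, 0, 0]), np.array([0, 0, 2.3])
    # place c at 2.4 from both
    c = np.array([np.sqrt(2.4**2 - 1.15**2), 0, 1.15])
    m = water_model(a, b, c)
    pairs, groups = waters.exclusive_pairs(m.waters)
    assert len(pairs) == 3
    assert len(groups) == 1 and len(groups[0]) == 3


def test_exclusive_pairs_match_bruteforce():
    rng = np.random.default_rng(8)
    pts = rng.uniform(0, 8, (30, 3))
    m = water_model(*pts)
    pairs, _ = waters.exclusive_pairs(m.waters, cutoff=2.5)
    brute = {
        (i, j)
        for i in range(30)
        for j in range(i + 1, 30)
        if np.linalg.norm(pts[i] - pts[j]) < 2.5
    }
    got = {
        tuple(sorted((a.oxygen.residue_number - 1, b.oxygen.residue_number - 1)))
        for a, b, _ in pairs
    }
    assert got == brute


# ------------------------------------------------------------------ single file

def _graph_of(zs_or_points):
    nodes = []
    for i, p in enumerate(zs_or_points):
        p = (0.0, 0.0, p) if np.isscalar(p) else p
        w = make_water(*p, number=i + 1)
        w.region = "channel"
        nodes.append(w)
    return waters.WaterGraph(nodes=nodes, edges=[])


def test_single_file_uniform_chain():
    g = _graph_of([0.0, 2.8, 5.6, 8.4, 11.2])
    segs = waters.single_file_segments(g, Z_AXIS)
    assert [s.kind for s in segs] == ["single_file"]
    assert len(segs[0].waters) == 5


def test_single_file_lateral_pair_is_multifile():
    g = _graph_of([(0, 0, 0), (0, 0, 2.8), (3.0, 0, 2.8), (0, 0, 5.6)])
    segs = waters.single_file_segments(g, Z_AXIS)
    assert any(s.kind == "multi_file" for s in segs)


def test_single_file_gap_splits_segments():
    g = _graph_of([0.0, 2.8, 5.6, 9.6, 12.4])  # 4.0 Å gap after the third
    segs = waters.single_file_segments(g, Z_AXIS)
    assert len(segs) == 2
    assert [len(s.waters) for s in segs] == [3, 2]
    assert all(s.kind == "single_file" for s in segs)


def test_single_file_trivial_cases():
    assert waters.single_file_segments(_graph_of([]), Z_AXIS) == []
    segs = waters.single_file_segments(_graph_of([1.0]), Z_AXIS)
    assert len(segs) == 1 and len(segs[0].waters) == 1


# ------------------------------------------------------------------ orientation

def _bonded_model(partners):
    """One water at (2,0,0), 2 Å lateral of the axis, plus named partner atoms."""
    m = StructureModel("o")
    w = make_water(2.0, 0.0, 0.0, 1)
    m.waters = [w]
    residues = []
    for i, (resname, atname, element, pos) in enumerate(partners):
        residues.append(Residue(resname, 10 + i, "", "A", [
            Atom(element, atname, "", np.array(pos, dtype=float), 20.0, 1.0,
                 resname, 10 + i, "", "A", False, False)
        ]))
    m.chains["A"] = residues
    return m, w


def test_orientation_two_wall_side_carbonyls():
    """Donating to two wall-side carbonyls points the oxygen to the lumen."""
    m, w = _bonded_model([
        ("GLY", "O", "O", (4.5, 0.8, 0.0)),
        ("SER", "O", "O", (4.4, -0.9, 0.3)),
    ])
    bonds = waters.detect_hbonds(m)
    verdict, why = waters.infer_orientation(w, bonds, Z_AXIS)
    assert verdict == "oxygen_toward_channel"
    assert "GLY10:O" in why


def test_orientation_water_only_partner_ambiguous():
    m = water_model((2, 0, 0), (2, 0, 2.8))
    bonds = waters.detect_hbonds(m)
    verdict, _ = waters.infer_orientation(m.waters[0], bonds, Z_AXIS)
    assert verdict == "ambiguous"


def test_orientation_single_donated_bond_ambiguous():
    """One carbonyl acceptor plus one amide on the far side: below the
    two-acceptor rule."""
    m, w = _bonded_model([
        ("GLY", "O", "O", (4.5, 0.8, 0.0)),
        ("GLN", "NE2", "N", (-0.5, -0.8, 0.0)),
    ])
    bonds = waters.detect_hbonds(m)
    verdict, _ = waters.infer_orientation(w, bonds, Z_AXIS)
    assert verdict == "ambiguous"


def test_orientation_no_bonds():
    m = water_model((2, 0, 0))
    verdict, why = waters.infer_orientation(m.waters[0], [], Z_AXIS)
    assert verdict == "ambiguous" and why == ""


# ------------------------------------------------------------------ invariance

def test_network_invariant_under_rigid_transform():
    """Bond count, classes, and exclusion groups survive a rigid transform."""
    rng = np.random.default_rng(21)
    pts = rng.uniform(0, 9, (25, 3))
    m1 = water_model(*pts)
    R = random_rotation(np.random.default_rng(22))
    t = np.array([5.0, -1.0, 3.0])
    m2 = water_model(*(pts @ R.T + t))
    b1 = waters.detect_hbonds(m1)
    b2 = waters.detect_hbonds(m2)
    assert len(b1) == len(b2)
    assert sorted(b.klass for b in b1) == sorted(b.klass for b in b2)
    p1, g1 = waters.exclusive_pairs(m1.waters)
    p2, g2 = waters.exclusive_pairs(m2.waters)
    assert len(p1) == len(p2) and [len(g) for g in g1] == [len(g) for g in g2]
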