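"""Geometric contact typing, pose selection, and population maps."""

import numpy as np
import pytest

from bitterqsar.chem import ComplexPose
from bitterqsar.interactions import (
    InteractionRecord,
    Residue,
    Thresholds,
    arene_vs_polar_summary,
    detect_interactions,
    lowest_energy_selection,
    population_map,
    read_records_csv,
    write_records_csv,
)
from bitterqsar.synth import gen_toy_complex


KIND_CUTOFF = {
    "H-Donor": "hbond_dist",
    "H-Acceptor": "hbond_dist",
    "Ionic": "ionic_dist",
    "pi-pi": "pipi_dist",
    "H-pi": "chpi_dist",
    "pi-H": "chpi_dist",
}


@pytest.mark.parametrize(
    "kind,expected",
    [
        ("salt_bridge", {"H-Donor": 1, "Ionic": 1}),
        ("hbond", {"H-Donor": 1}),
        ("pi_stack", {"pi-pi": 1}),
        ("ch_pi", {"H-pi": 1}),
        ("none", {}),
    ],
)
def test_toy_complexes_yield_designed_record_sets(kind, expected):
    records = detect_interactions(gen_toy_complex(kind))
    counted = {}
    for r in records:
        counted[r.kind] = counted.get(r.kind, 0) + 1
    assert counted == expected


def test_salt_bridge_distances_match_design():
    records = detect_interactions(gen_toy_complex("salt_bridge"))
    by_kind = {r.kind: r for r in records}
    assert by_kind["H-Donor"].distance == pytest.approx(3.24, abs=0.01)
    assert by_kind["Ionic"].distance <= 4.0
    assert all(r.residue.label == "GLU265" for r in records)


def test_every_record_within_its_cutoff_under_jitter():
    th = Thresholds()
    for kind in ("salt_bridge", "hbond", "pi_stack", "ch_pi"):
        for seed in range(10):
            pose = gen_toy_complex(kind, jitter=0.15, seed=seed)
            for r in detect_interactions(pose, th):
                assert 0 < r.distance <= getattr(th, KIND_CUTOFF[r.kind])


def test_shrinking_cutoffs_never_adds_records():
    for kind in ("salt_bridge", "hbond", "pi_stack", "ch_pi", "none"):
        for seed in range(5):
            pose = gen_toy_complex(kind, jitter=0.2, seed=seed)
            base = Thresholds()
            n_base = len(detect_interactions(pose, base))
            for factor in (0.9, 0.7, 0.5):
                n_small = len(detect_interactions(pose, base.scaled(factor)))
                assert n_small <= n_base
                n_base = n_small
                base = base.scaled(factor)


def test_detection_invariant_under_rigid_motion():
    pose = gen_toy_complex("salt_bridge")
    before = detect_interactions(pose)
    rng = np.random.default_rng(11)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    t = np.array([5.0, -3.0, 8.0])
    from bitterqsar.chem import ReceptorAtom, ReceptorStructure

    moved_receptor = ReceptorStructure(
        atoms=[
            ReceptorAtom(
                a.serial, a.name, a.resname, a.chain, a.resnum, a.element,
                tuple(np.asarray(a.pos) @ q.T + t),
            )
            for a in pose.receptor.atoms
        ]
    )
    moved = ComplexPose(moved_receptor, pose.ligand.with_coords(pose.ligand.coords @ q.T + t))
    after = detect_interactions(moved)
    assert sorted((r.kind, round(r.distance, 6)) for r in after) == sorted(
        (r.kind, round(r.distance, 6)) for r in before
    )


def test_missing_group_atoms_skips_residue_gracefully():
    pose = gen_toy_complex("salt_bridge")
    from bitterqsar.chem import ReceptorStructure

    pruned = ReceptorStructure(
        atoms=[a for a in pose.receptor.atoms if a.name != "OE2"]
    )
    records = detect_interactions(ComplexPose(pruned, pose.ligand))
    assert all(r.kind != "Ionic" for r in records)  # charge group skipped
    assert any(r.kind == "H-Donor" for r in records)  # H-bond still typed


def test_lowest_energy_selection_tie_keeps_earlier_pose():
    poses = [
        gen_toy_complex("salt_bridge", score=s) for s in (-6.0, -7.5, -7.5)
    ]
    chosen = lowest_energy_selection({"cmpd": poses})["cmpd"]
    assert chosen is poses[1]


def test_lowest_energy_selection_single_and_unscored():
    single = gen_toy_complex("hbond", score=-3.0)
    unscored = gen_toy_complex("hbond", score=None)
    out = lowest_energy_selection({"a": [single], "b": [unscored]})
    assert out["a"] is single
    assert "b" not in out


@pytest.mark.parametrize(
    "counts,total,expected",
    [
        ({"GLU265": 250}, 453, {"GLU265": 55.2}),
        ({"TRP88": 12}, 45, {"TRP88": 26.7}),
        ({"GLU265": 11}, 45, {"GLU265": 24.4}),
    ],
)
def test_population_percentages_match_printed_pairs(counts, total, expected):
    records = []
    for label, n in counts.items():
        res = Residue("A", int(label[3:]), label[:3])
        records += [InteractionRecord(res, "H-Donor", 3.0, ("x", "y"))] * n
    # pad with records on other residues up to the printed total
    filler = Residue("A", 999, "ALA")
    records += [InteractionRecord(filler, "H-pi", 4.0, ("x", "y"))] * (
        total - len(records)
    )
    pm = population_map(records)
    assert pm.total == total
    for label, pct in expected.items():
        assert pm.percentages[label.replace("GLU", "GLU").replace("TRP", "TRP")] == pct


def test_population_map_single_record_and_empty():
    res = Residue("A", 88, "TRP")
    pm = population_map([InteractionRecord(res, "H-pi", 3.9, ("a", "b"))])
    assert pm.percentages == {"TRP88": 100.0}
    empty = population_map([])
    assert empty.total == 0 and empty.counts == {} and empty.percentages == {}


def test_population_percentage_identity():
    rng = np.random.default_rng(2)
    residues = [Residue("A", int(n), "ALA") for n in rng.integers(1, 9, size=50)]
    records = [
        InteractionRecord(r, "H-Donor", float(rng.uniform(2, 3.4)), ("a", "b"))
        for r in residues
    ]
    pm = population_map(records)
    assert sum(pm.counts.values()) == pm.total
    for label, count in pm.counts.items():
        assert pm.percentages[label] == round(100.0 * count / pm.total, 1)


def test_arene_vs_polar_summary_flags():
    w88 = Residue("A", 88, "TRP")
    e265 = Residue("A", 265, "GLU")
    recs = {
        "methoxyflavone": [InteractionRecord(w88, "pi-pi", 3.6, ("a", "b"))],
        "flavonol": [
            InteractionRecord(w88, "H-pi", 4.0, ("a", "b")),
            InteractionRecord(e265, "H-Donor", 3.2, ("a", "b")),
            InteractionRecord(e265, "Ionic", 3.6, ("a", "b")),
        ],
        "inert": [],
    }
    table = arene_vs_polar_summary(recs, ["TRP88", "GLU265"])
    assert table.loc["methoxyflavone", "TRP88"] == "R"
    assert table.loc["methoxyflavone", "GLU265"] == "-"
    assert table.loc["flavonol", "TRP88"] == "R"
    assert table.loc["flavonol", "GLU265_polar"] == "H-Donor,Ionic"
    assert table.loc["inert", "TRP88"] == "-" and table.loc["inert", "GLU265"] == "-"


def test_records_csv_round_trip(tmp_path):
    recs = {
        "a": detect_interactions(gen_toy_complex("salt_bridge")),
        "b": detect_interactions(gen_toy_complex("pi_stack")),
    }
    path = tmp_path / "records.csv"
    write_records_csv(recs, path)
    back = read_records_csv(path)
    assert set(back) == {"a", "b"}
    for cid in recs:
        assert [(r.kind, round(r.distance, 6)) for r in back[cid]] == [
            (r.kind, round(r.distance, 6)) for r in recs[cid]
        ]


def test_record_vocabulary_enforced():
    res = Residue("A", 1, "ALA")
    with pytest.raises(ValueError, match="kind"):
        InteractionRecord(res, "halogen", 3.0, ("a", "b"))
    with pytest.raises(ValueError):
        InteractionRecord(res, "Ionic", -1.0, ("a", "b"))
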