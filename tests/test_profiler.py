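"""Geometric interaction detection and dynophore occurrence statistics."""

import numpy as np
import pandas as pd
import pytest

from maolie.errors import ConfigurationError, InvalidInputError
from maolie.profiler import (
    AROMATIC_RING_ATOMS,
    CARBOXYLATE_O,
    HYDROPHOBIC_ATOMS,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    FeatureAnnotation,
    GeometricCriteria,
    detect_frame,
    presence_timeline,
    profile,
    read_annotations,
)
from maolie.synthetic import ContactSchedule, PocketSpec, PoseShift, gen_pocket_trajectory
from maolie.trajectory import Structure, Trajectory


def pocket_frame(n9_od1_distance=2.8, with_h=True, h_angle_deg=180.0):
    """Minimal pocket: ligand N9(-H9) donor opposite an Asn OD1 acceptor."""
    rows = [
        ("N9", "N", "HRM", 1, "ligand"),
        ("C2", "C", "HRM", 1, "ligand"),
        ("OD1", "O", "ASN", 181, "protein"),
        ("CB", "C", "LEU", 337, "protein"),
    ]
    coords = [
        [0.0, 0.0, 0.0],
        [-1.4, 0.0, 0.0],
        [n9_od1_distance, 0.0, 0.0],
        [0.0, 8.0, 0.0],
    ]
    if with_h:
        theta = np.radians(180.0 - h_angle_deg)
        rows.append(("H9", "H", "HRM", 1, "ligand"))
        coords.append([np.cos(theta), np.sin(theta), 0.0])
    atoms = pd.DataFrame(rows, columns=["name", "element", "resname", "resnum", "role"])
    atoms["chain"] = "A"
    return Structure(atoms, np.array(coords))


DONOR = [FeatureAnnotation("pyrrole_nh", "hbond_donor", ("N9",))]


class TestDetectFrame:
    def test_hbond_detected_at_short_distance_with_collinear_h(self):
        events = detect_frame(pocket_frame(2.8), DONOR)
        assert [(e.feature_id, e.partner) for e in events] == [("pyrrole_nh", "ASN181")]

    def test_no_event_beyond_distance_cutoff(self):
        assert detect_frame(pocket_frame(3.5), DONOR) == []

    def test_bent_hydrogen_fails_angle_criterion(self):
        assert detect_frame(pocket_frame(2.8, h_angle_deg=90.0), DONOR) == []
        # distance-only fallback when no explicit hydrogen is present
        assert detect_frame(pocket_frame(2.8, with_h=False), DONOR) != []

    def test_unresolvable_annotation_atom_is_configuration_error(self):
        bad = [FeatureAnnotation("x", "hbond_donor", ("N77",))]
        with pytest.raises(ConfigurationError, match="N77"):
            detect_frame(pocket_frame(), bad)

    def test_matches_brute_force_all_pairs_oracle(self):
        """Random 50-atom frame: detection equals a plain nested-loop scan."""
        rng = np.random.default_rng(21)
        lig_names = ["N9", "N1", "C2", "C3", "C5", "CM1"]
        rows = [(nm, nm[0], "HRM", 1, "ligand") for nm in lig_names]
        env_pool = [
            ("OD1", "O", "ASN", 181), ("ND2", "N", "ASN", 181),
            ("CB", "C", "LEU", 337), ("CD1", "C", "LEU", 337),
            ("CZ", "C", "TYR", 407), ("CE1", "C", "TYR", 407),
            ("OH", "O", "TYR", 407), ("SD", "S", "MET", 350),
            ("OD1", "O", "ASP", 132), ("O", "O", "HOH", 700),
            ("N5", "N", "FAD", 600), ("O", "O", "GLY", 20),
            ("N", "N", "GLY", 21), ("CB", "C", "ALA", 30),
        ]
        for k in range(44 - len(lig_names)):
            nm, el, rn, num = env_pool[k % len(env_pool)]
            role = "water" if rn == "HOH" else ("cofactor" if rn == "FAD" else "protein")
            rows.append((nm, el, rn, num + (k // len(env_pool)) * 1000, role))
        atoms = pd.DataFrame(rows, columns=["name", "element", "resname", "resnum", "role"])
        atoms["chain"] = "A"

        annotations = [
            FeatureAnnotation("donor", "hbond_donor", ("N9",)),
            FeatureAnnotation("acceptor", "hbond_acceptor", ("N1",)),
            FeatureAnnotation("rings", "hydrophobic", ("C2", "C3", "C5")),
            FeatureAnnotation("cation", "positive_ionizable", ("N1",)),
            FeatureAnnotation("arom", "aromatic", ("C2", "C5")),
        ]
        criteria = GeometricCriteria()

        for trial in range(5):
            coords = rng.uniform(-4, 4, (len(rows), 3))
            frame = Structure(atoms, coords)
            got = {(e.feature_id, e.partner) for e in detect_frame(frame, annotations, criteria)}
            assert got == brute_force_events(frame, annotations, criteria)


def brute_force_events(frame, annotations, criteria):
    """Independent nested-loop reimplementation of the detection rules."""
    a = frame.atoms
    xyz = frame.coords
    lig_idx = {a["name"].iloc[i]: i for i in range(len(a)) if a["role"].iloc[i] == "ligand"}
    events = set()

    def label(i):
        return (
            "water"
            if a["role"].iloc[i] == "water"
            else f"{a['resname'].iloc[i]}{a['resnum'].iloc[i]}"
        )

    def env_atoms():
        for i in range(len(a)):
            if a["role"].iloc[i] in ("protein", "water", "cofactor"):
                yield i, a["resname"].iloc[i], a["name"].iloc[i], a["role"].iloc[i]

    for ann in annotations:
        ftype = "hydrophobic" if ann.type == "aromatic" else ann.type
        for nm in ann.ligand_atom_names:
            li = lig_idx[nm]
            for i, rn, anm, role in env_atoms():
                d = float(np.linalg.norm(xyz[li] - xyz[i]))
                hit = False
                if ftype == "hydrophobic":
                    hit = (
                        rn in HYDROPHOBIC_ATOMS
                        and anm in HYDROPHOBIC_ATOMS[rn]
                        and d <= criteria.hydrophobic_max_distance
                    )
                elif ftype == "hbond_donor":
                    is_acc = (
                        (rn in SIDECHAIN_ACCEPTORS and anm in SIDECHAIN_ACCEPTORS[rn])
                        or (role == "water" and a["element"].iloc[i].upper() == "O")
                        or (role == "protein" and anm == "O")
                    )
                    if is_acc and d <= criteria.hbond_max_heavy_distance:
                        hs = [
                            h
                            for h in range(len(a))
                            if a["role"].iloc[h] == "ligand"
                            and a["element"].iloc[h].upper() == "H"
                            and np.linalg.norm(xyz[h] - xyz[li]) <= 1.25
                            and li == min(
                                (j for j in lig_idx.values()
                                 if a["element"].iloc[j].upper() != "H"),
                                key=lambda j: np.linalg.norm(xyz[h] - xyz[j]),
                            )
                        ]
                        if not hs:
                            hit = True
                        else:
                            for h in hs:
                                u = xyz[li] - xyz[h]
                                v = xyz[i] - xyz[h]
                                ang = np.degrees(
                                    np.arccos(
                                        np.clip(
                                            u @ v / np.linalg.norm(u) / np.linalg.norm(v),
                                            -1, 1,
                                        )
                                    )
                                )
                                if ang >= criteria.hbond_min_angle:
                                    hit = True
                elif ftype == "hbond_acceptor":
                    is_don = (
                        (rn in SIDECHAIN_DONORS and anm in SIDECHAIN_DONORS[rn])
                        or (role == "water" and a["element"].iloc[i].upper() == "O")
                        or (role == "protein" and anm == "N")
                    )
                    hit = is_don and d <= criteria.hbond_max_heavy_distance
                elif ftype == "positive_ionizable":
                    is_pi = (
                        rn in AROMATIC_RING_ATOMS and anm in AROMATIC_RING_ATOMS[rn]
                    ) or (rn in CARBOXYLATE_O and anm in CARBOXYLATE_O[rn])
                    hit = is_pi and d <= criteria.ionic_max_distance
                if hit:
                    events.add((ann.feature_id, label(i)))
    return events


@pytest.fixture(scope="module")
def scheduled():
    contacts = (
        ContactSchedule("N9", "ASN", 181, "OD1", ((0, 300),), 2.8),
        ContactSchedule("C8", "TYR", 407, "CZ", ((0, 300),), 3.8),
        ContactSchedule("C5", "LEU", 337, "CD1", ((300, 1000),), 3.8),
    )
    spec = PocketSpec(n_frames=1000, contacts=contacts, seed=4)
    traj, truth = gen_pocket_trajectory(spec)
    from maolie.datasets import load_harmine_features

    return profile(traj, load_harmine_features()), truth


class TestProfile:
    def test_scheduled_occupancies_recovered_exactly(self, scheduled):
        prof, truth = scheduled
        assert prof.occurrence_percent[("pyrrole_nh", "ASN181")] == 30.0
        assert prof.occurrence_percent[("benzene_ring", "TYR407")] == 30.0
        assert prof.occurrence_percent[("benzene_ring", "LEU337")] == 70.0
        assert truth.pair_occupancy_percent["N9-ASN181"] == 30.0

    def test_occurrence_is_exactly_consistent_with_barcode(self, scheduled):
        prof, _ = scheduled
        for pair in prof.pairs:
            assert prof.occurrence_percent[pair] == pytest.approx(
                100.0 * prof.barcode[pair].sum() / prof.n_frames, abs=0
            )

    def test_pose_shift_swaps_partners(self):
        contacts = (
            ContactSchedule("C8", "TYR", 407, "CZ", ((0, 300),), 3.8),
            ContactSchedule("C5", "MET", 350, "SD", ((300, 1000),), 3.8),
        )
        spec = PocketSpec(
            n_frames=1000, contacts=contacts, pose_shift=PoseShift(300, (0, 0, 3.0)), seed=5
        )
        traj, _ = gen_pocket_trajectory(spec)
        from maolie.datasets import load_harmine_features

        prof = profile(traj, load_harmine_features())
        assert prof.occurrence_percent[("benzene_ring", "TYR407")] == 30.0
        assert prof.occurrence_percent[("benzene_ring", "MET350")] == 70.0

    def test_shrinking_cutoffs_is_monotone(self, scheduled):
        prof, _ = scheduled
        contacts = (
            ContactSchedule("N9", "ASN", 181, "OD1", ((0, 300),), 2.8),
            ContactSchedule("C8", "TYR", 407, "CZ", ((0, 300),), 3.8),
            ContactSchedule("C5", "LEU", 337, "CD1", ((300, 1000),), 3.8),
        )
        spec = PocketSpec(n_frames=200, contacts=tuple(
            ContactSchedule(c.ligand_atom, c.partner_resname, c.partner_resnum,
                            c.partner_atom,
                            tuple((s // 5, e // 5) for s, e in c.frame_ranges),
                            c.target_distance)
            for c in contacts
        ), seed=6)
        traj, _ = gen_pocket_trajectory(spec)
        from maolie.datasets import load_harmine_features

        anns = load_harmine_features()
        loose = profile(traj, anns, GeometricCriteria(3.0, 130.0, 4.5, 5.0))
        tight = profile(traj, anns, GeometricCriteria(2.5, 130.0, 3.5, 4.0))
        for pair, pct in tight.occurrence_percent.items():
            assert pct <= loose.occurrence_percent.get(pair, 0.0) + 1e-12

    def test_aggregate_invariant_to_frame_reordering(self, scheduled):
        prof, _ = scheduled
        contacts = (ContactSchedule("N9", "ASN", 181, "OD1", ((0, 30),), 2.8),)
        spec = PocketSpec(n_frames=100, contacts=contacts, seed=7)
        traj, _ = gen_pocket_trajectory(spec)
        from maolie.datasets import load_harmine_features

        anns = load_harmine_features()
        p1 = profile(traj, anns)
        perm = np.random.default_rng(0).permutation(traj.n_frames)
        shuffled = Trajectory(traj.topology, traj.frames[perm], traj.frame_interval_ps)
        p2 = profile(shuffled, anns)
        key = ("pyrrole_nh", "ASN181")
        assert p1.occurrence_percent[key] == p2.occurrence_percent[key]
        # barcodes are equivariant under the same permutation
        np.testing.assert_array_equal(p1.barcode[key][perm], p2.barcode[key])


class TestPresenceTimeline:
    def make_profile(self, track):
        from maolie.profiler import DynophoreProfile

        track = np.asarray(track, dtype=bool)
        return DynophoreProfile(
            pairs=[("f", "ASN181")],
            occurrence_percent={("f", "ASN181"): 100.0 * track.mean()},
            barcode={("f", "ASN181"): track},
            n_frames=len(track),
        )

    def test_all_present_single_run(self):
        tl = presence_timeline(self.make_profile([True] * 10))
        assert tl[("f", "ASN181")]["runs"] == [(True, 10)]
        assert tl[("f", "ASN181")]["longest_present"] == 10

    def test_alternating_runs(self):
        tl = presence_timeline(self.make_profile([True, False] * 5))
        assert len(tl[("f", "ASN181")]["runs"]) == 10
        assert tl[("f", "ASN181")]["longest_present"] == 1

    def test_scheduled_absent_then_present(self):
        track = [False] * 300 + [True] * 700
        tl = presence_timeline(self.make_profile(track))
        assert tl[("f", "ASN181")]["runs"] == [(False, 300), (True, 700)]

    def test_unknown_pair_rejected(self):
        with pytest.raises(InvalidInputError):
            presence_timeline(self.make_profile([True]), [("nope", "X")])


class TestAnnotations:
    def test_packaged_annotation_file_parses(self):
        from maolie.datasets import load_harmine_features

        anns = load_harmine_features()
        ids = {a.feature_id for a in anns}
        assert {"pyrrole_nh", "pyridine_n", "benzene_ring"} <= ids

    def test_unknown_feature_type_rejected(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("f1\tmagnetic\tN9\n")
        with pytest.raises(ConfigurationError):
            read_annotations(p)
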