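"""Simplified dynamic pharmacophore (dynophore) profiling.

A dynophore summarises a protein--ligand MD trajectory as, for each
(ligand pharmacophore feature, environment partner) pair, the percentage of
frames in which a geometric interaction criterion is satisfied, plus the
frame-by-frame presence "barcode".  Ligand features are declared in a text
annotation table (no cheminformatic perception); environment donor,
acceptor and hydrophobe atoms come from built-in residue tables covering
the 20 standard amino acids, the FAD cofactor and water.

Detection rules (all cutoffs configurable):

* hydrophobic -- any annotated ligand carbon within ``hydrophobic_max_distance``
  of an apolar (C/S side-chain) atom of a hydrophobic residue.  Aromatic
  stacking is folded into this rule: ring--ring contacts are reported as
  hydrophobic, without a ring-plane angle test.
* hbond_donor -- ligand donor heavy atom within ``hbond_max_heavy_distance``
  of an environment acceptor; if an explicit hydrogen is bonded to the
  donor, the D-H...A angle must also reach ``hbond_min_angle``.
* hbond_acceptor -- symmetric, against the environment donor table.
* positive_ionizable -- annotated charged nitrogen within
  ``ionic_max_distance`` of aromatic ring carbons (cation-pi) or
  carboxylate oxygens (salt bridge).

All water molecules are aggregated under the single partner label
``"water"``; other partners are labelled ``RESNAME+RESNUM`` (e.g. ASN181).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import ConfigurationError, FormatError, InvalidInputError
from .trajectory import Structure, Trajectory

FEATURE_TYPES = (
    "hydrophobic",
    "hbond_donor",
    "hbond_acceptor",
    "positive_ionizable",
    "aromatic",
)

# Apolar side-chain atoms (carbon/sulfur) of hydrophobic residues.
HYDROPHOBIC_ATOMS: dict[str, set[str]] = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1", "CD"},
    "MET": {"CB", "CG", "SD", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "PRO": {"CB", "CG", "CD"},
    "CYS": {"CB", "SG"},
}

# Environment hydrogen-bond acceptor atoms.  Backbone carbonyl O is an
# acceptor in every residue; water O accepts and donates.
SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1"},
    "FAD": {"N5", "N1", "O2", "O4"},
}

# Environment hydrogen-bond donor heavy atoms (backbone N for every residue).
SIDECHAIN_DONORS: dict[str, set[str]] = {
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "TRP": {"NE1"},
    "HIS": {"NE2"},
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
}

AROMATIC_RING_ATOMS: dict[str, set[str]] = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
}

CARBOXYLATE_O: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

#: Maximum covalent D-H bond length used to find explicit hydrogens.
_H_BOND_SEARCH = 1.25


@dataclass(frozen=True)
class FeatureAnnotation:
    """One declared ligand pharmacophore feature."""

    feature_id: str
    type: str
    ligand_atom_names: tuple[str, ...]

    def __post_init__(self):
        if self.type not in FEATURE_TYPES:
            raise ConfigurationError(
                f"feature {self.feature_id!r}: unknown type {self.type!r}"
            )
        if not self.ligand_atom_names:
            raise ConfigurationError(f"feature {self.feature_id!r} names no atoms")


@dataclass(frozen=True)
class GeometricCriteria:
    """Distance/angle cutoffs for interaction detection.

    Defaults: 3.0 A heavy-atom H-bond distance (anchored to the ~2.9 A
    donor-acceptor switching distance seen for the pyrrole N--Asn181
    contact), 130 deg minimum D-H...A angle, 4.5 A hydrophobic contact,
    5.0 A ionic/cation-pi contact.
    """

    hbond_max_heavy_distance: float = 3.0
    hbond_min_angle: float = 130.0
    hydrophobic_max_distance: float = 4.5
    ionic_max_distance: float = 5.0

    def __post_init__(self):
        if min(self.hbond_max_heavy_distance, self.hydrophobic_max_distance,
               self.ionic_max_distance) <= 0:
            raise InvalidInputError("distance cutoffs must be positive")
        if not 0 < self.hbond_min_angle <= 180:
            raise InvalidInputError("hbond_min_angle must be in (0, 180]")


class InteractionEvent(NamedTuple):
    feature_id: str
    feature_type: str
    partner: str  # "ASN181", "FAD600", or "water"


@dataclass
class DynophoreProfile:
    """Occurrence statistics of feature--partner interactions over frames."""

    pairs: list[tuple[str, str]]  # (feature_id, partner), sorted by occurrence desc
    occurrence_percent: dict[tuple[str, str], float]
    barcode: dict[tuple[str, str], np.ndarray]  # boolean, per frame
    n_frames: int


def read_annotations(path: str | Path) -> list[FeatureAnnotation]:
    """Read a feature annotation TSV: feature_id, type, comma-joined atoms."""
    out = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "feature_id":
                continue
            if len(parts) != 3:
                raise FormatError(f"line {lineno}: expected 3 tab-separated fields")
            out.append(
                FeatureAnnotation(parts[0], parts[1], tuple(parts[2].split(",")))
            )
    if not out:
        raise FormatError(f"{path}: no feature annotations found")
    return out


def _partner_label(resname: str, resnum: int, role: str) -> str:
    return "water" if role == "water" else f"{resname}{resnum}"


class _EnvTables:
    """Precomputed environment atom index lists for one topology."""

    def __init__(self, structure: Structure):
        a = structure.atoms
        env = a["role"].isin(["protein", "water", "cofactor"]).to_numpy()
        labels = [
            _partner_label(rn, num, role)
            for rn, num, role in zip(a["resname"], a["resnum"], a["role"])
        ]
        self.labels = np.array(labels)

        def pick(table: dict[str, set[str]], extra=None) -> np.ndarray:
            keep = np.zeros(len(a), dtype=bool)
            for i, (rn, nm) in enumerate(zip(a["resname"], a["name"])):
                if not env[i]:
                    continue
                if rn in table and nm in table[rn]:
                    keep[i] = True
                elif extra is not None and extra(i, rn, nm):
                    keep[i] = True
            return np.flatnonzero(keep)

        roles = a["role"].to_numpy()
        names = a["name"].to_numpy()
        is_water_o = lambda i, rn, nm: roles[i] == "water" and a["element"].iloc[i].upper() == "O"  # noqa: E731
        backbone_o = lambda i, rn, nm: roles[i] == "protein" and nm == "O"  # noqa: E731
        backbone_n = lambda i, rn, nm: roles[i] == "protein" and nm == "N"  # noqa: E731

        self.hydrophobes = pick(HYDROPHOBIC_ATOMS)
        self.acceptors = pick(
            SIDECHAIN_ACCEPTORS, lambda i, rn, nm: is_water_o(i, rn, nm) or backbone_o(i, rn, nm)
        )
        self.donors = pick(
            SIDECHAIN_DONORS, lambda i, rn, nm: is_water_o(i, rn, nm) or backbone_n(i, rn, nm)
        )
        self.ionic = pick(AROMATIC_RING_ATOMS | CARBOXYLATE_O)
        # hydrogens attached to environment donors, for the angle test
        self.names = names


def _resolve_feature_atoms(
    structure: Structure, annotations: Sequence[FeatureAnnotation]
) -> dict[str, np.ndarray]:
    a = structure.atoms
    lig = (a["role"] == "ligand").to_numpy()
    by_name: dict[str, int] = {}
    for i in np.flatnonzero(lig):
        by_name.setdefault(a["name"].iloc[i], i)
    resolved = {}
    for ann in annotations:
        idx = []
        for nm in ann.ligand_atom_names:
            if nm not in by_name:
                raise ConfigurationError(
                    f"feature {ann.feature_id!r}: ligand atom {nm!r} not found in topology"
                )
            idx.append(by_name[nm])
        resolved[ann.feature_id] = np.array(idx, dtype=int)
    return resolved


def _ligand_hydrogens(structure: Structure, coords: np.ndarray) -> dict[int, np.ndarray]:
    """Map ligand heavy-atom index -> indices of covalently attached hydrogens."""
    a = structure.atoms
    lig = np.flatnonzero((a["role"] == "ligand").to_numpy())
    h_idx = [i for i in lig if a["element"].iloc[i].upper() == "H"]
    heavy = [i for i in lig if a["element"].iloc[i].upper() != "H"]
    attached: dict[int, list[int]] = {i: [] for i in heavy}
    for h in h_idx:
        d = np.linalg.norm(coords[heavy] - coords[h], axis=1)
        j = int(np.argmin(d))
        if d[j] <= _H_BOND_SEARCH:
            attached[heavy[j]].append(h)
    return {k: np.array(v, dtype=int) for k, v in attached.items()}


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _detect(
    coords: np.ndarray,
    env: _EnvTables,
    feature_atoms: dict[str, np.ndarray],
    annotations: Sequence[FeatureAnnotation],
    criteria: GeometricCriteria,
    lig_h: dict[int, np.ndarray],
) -> set[InteractionEvent]:
    events: set[InteractionEvent] = set()
    for ann in annotations:
        lig_idx = feature_atoms[ann.feature_id]
        ftype = "hydrophobic" if ann.type == "aromatic" else ann.type
        if ftype == "hydrophobic":
            cand, cutoff = env.hydrophobes, criteria.hydrophobic_max_distance
        elif ftype == "hbond_donor":
            cand, cutoff = env.acceptors, criteria.hbond_max_heavy_distance
        elif ftype == "hbond_acceptor":
            cand, cutoff = env.donors, criteria.hbond_max_heavy_distance
        elif ftype == "positive_ionizable":
            cand, cutoff = env.ionic, criteria.ionic_max_distance
        else:  # pragma: no cover - guarded by FeatureAnnotation
            continue
        if cand.size == 0:
            continue
        d = np.linalg.norm(
            coords[lig_idx][:, None, :] - coords[cand][None, :, :], axis=-1
        )
        hits = np.argwhere(d <= cutoff)
        for li, ci in hits:
            lig_atom = int(lig_idx[li])
            env_atom = int(cand[ci])
            if ftype == "hbond_donor":
                hs = lig_h.get(lig_atom, np.array([], dtype=int))
                if hs.size:
                    best = max(
                        _angle_deg(coords[lig_atom], coords[h], coords[env_atom])
                        for h in hs
                    )
                    if best < criteria.hbond_min_angle:
                        continue
            events.add(
                InteractionEvent(ann.feature_id, ann.type, str(env.labels[env_atom]))
            )
    return events


def detect_frame(
    frame: Structure,
    annotations: Sequence[FeatureAnnotation],
    criteria: GeometricCriteria = GeometricCriteria(),
) -> list[InteractionEvent]:
    """Detect all feature--partner interactions in a single frame."""
    env = _EnvTables(frame)
    feature_atoms = _resolve_feature_atoms(frame, annotations)
    lig_h = _ligand_hydrogens(frame, frame.coords)
    events = _detect(frame.coords, env, feature_atoms, annotations, criteria, lig_h)
    return sorted(events)


def profile(
    traj: Trajectory,
    annotations: Sequence[FeatureAnnotation],
    criteria: GeometricCriteria = GeometricCriteria(),
) -> DynophoreProfile:
    """Aggregate per-frame detections into occurrence percentages and barcodes.

    Occurrence is exactly ``100 * presence_count / n_frames``; pairs are
    reported sorted by descending occurrence.
    """
    if traj.n_frames == 0:
        raise InvalidInputError("trajectory has no frames")
    top = traj.topology
    env = _EnvTables(top)
    feature_atoms = _resolve_feature_atoms(top, annotations)

    presence: dict[tuple[str, str], np.ndarray] = {}
    for f in range(traj.n_frames):
        coords = traj.frames[f]
        lig_h = _ligand_hydrogens(top, coords)
        for ev in _detect(coords, env, feature_atoms, annotations, criteria, lig_h):
            key = (ev.feature_id, ev.partner)
            if key not in presence:
                presence[key] = np.zeros(traj.n_frames, dtype=bool)
            presence[key][f] = True

    occurrence = {
        k: 100.0 * int(v.sum()) / traj.n_frames for k, v in presence.items()
    }
    pairs = sorted(occurrence, key=lambda k: (-occurrence[k], k))
    return DynophoreProfile(
        pairs=pairs,
        occurrence_percent=occurrence,
        barcode=presence,
        n_frames=traj.n_frames,
    )


def _run_lengths(track: np.ndarray) -> list[tuple[bool, int]]:
    runs = []
    start = 0
    for i in range(1, len(track) + 1):
        if i == len(track) or track[i] != track[start]:
            runs.append((bool(track[start]), i - start))
            start = i
    return runs


def presence_timeline(
    prof: DynophoreProfile, pair_selection: Iterable[tuple[str, str]] | None = None
) -> dict[tuple[str, str], dict]:
    """Frame-indexed presence tracks with run-length summaries.

    For each selected pair returns the boolean track, the run-length
    encoding as (value, length) tuples, and the longest contiguous presence
    and absence.
    """
    if pair_selection is None:
        pair_selection = prof.pairs
    out = {}
    for pair in pair_selection:
        pair = tuple(pair)
        if pair not in prof.barcode:
            raise InvalidInputError(f"unknown pair {pair!r}")
        track = prof.barcode[pair]
        runs = _run_lengths(track)
        out[pair] = {
            "track": track,
            "runs": runs,
            "longest_present": max((n for v, n in runs if v), default=0),
            "longest_absent": max((n for v, n in runs if not v), default=0),
        }
    return out


def write_occurrence_tsv(path: str | Path, prof: DynophoreProfile) -> None:
    """Write pair occurrences: feature, partner, percent, count, n_frames."""
    with Path(path).open("w") as fh:
        fh.write("# feature\tpartner\toccurrence_percent\tcount\tn_frames\n")
        for feat, partner in prof.pairs:
            count = int(prof.barcode[(feat, partner)].sum())
            fh.write(
                f"{feat}\t{partner}\t{prof.occurrence_percent[(feat, partner)]:.1f}"
                f"\t{count}\t{prof.n_frames}\n"
            )


def write_barcode_tsv(path: str | Path, prof: DynophoreProfile) -> None:
    """Write the frames x pairs 0/1 presence matrix."""
    with Path(path).open("w") as fh:
        header = "\t".join(f"{f}|{p}" for f, p in prof.pairs)
        fh.write(f"frame\t{header}\n")
        for i in range(prof.n_frames):
            row = "\t".join(str(int(prof.barcode[pair][i])) for pair in prof.pairs)
            fh.write(f"{i}\t{row}\n")
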