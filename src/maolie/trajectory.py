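"""Trajectory containers, I/O and geometric analysis.

Handles the structural side of the pipeline: reading a topology PDB plus a
multi-model PDB or XYZ trajectory, assigning coarse roles (protein, ligand,
water, cofactor, ion) from residue names, Kabsch superposition, per-frame
ligand RMSD against the initial structure, atom-pair distance series with
block averaging, and binding-cavity water counting.

Coordinates are in Angstrom throughout.  The simulated systems this targets
are spherical water droplets, so no periodic-boundary imaging is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import FormatError, InvalidInputError

logger = logging.getLogger(__name__)

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SPC", "SOL"}
COFACTOR_RESNAMES = {"FAD"}
ION_RESNAMES = {"CL", "NA", "CLA", "SOD", "K", "MG", "CA"}

DEFAULT_LIGAND_RESNAME = "HRM"


@dataclass
class Structure:
    """Labelled atoms with one coordinate set.

    ``atoms`` columns: name, element, resname, resnum, chain, role.
    ``coords`` is an (n_atoms, 3) array in Angstrom.
    """

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise InvalidInputError(
                f"coords shape {self.coords.shape} does not match {len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise InvalidInputError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(self.atoms, coords)


@dataclass
class Trajectory:
    """A topology plus an ordered stack of coordinate frames."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval_ps: float = 100.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise InvalidInputError(
                f"frames shape {self.frames.shape} does not match topology with "
                f"{self.topology.n_atoms} atoms"
            )
        if not self.frame_interval_ps > 0:
            raise InvalidInputError("frame_interval_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass
class DistanceSeries:
    """Per-frame distance between two atom selections, with block averages."""

    label_a: str
    label_b: str
    distances: np.ndarray  # Angstrom, one per frame
    block_averages: np.ndarray
    block_length_ns: float


def assign_role(resname: str, ligand_resname: str = DEFAULT_LIGAND_RESNAME) -> str:
    resname = resname.strip().upper()
    if resname in STANDARD_AMINO_ACIDS:
        return "protein"
    if resname in WATER_RESNAMES:
        return "water"
    if resname in COFACTOR_RESNAMES:
        return "cofactor"
    if resname in ION_RESNAMES:
        return "ion"
    if resname == ligand_resname.upper():
        return "ligand"
    raise FormatError(
        f"unknown residue name {resname!r}: not a standard residue and not the "
        f"configured ligand residue {ligand_resname!r}"
    )


def _check_frame_atom_counts(path: Path) -> None:
    """Validate per-frame atom counts of a trajectory file before parsing."""
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        counts, current, in_model = [], 0, False
        with path.open() as fh:
            for line in fh:
                rec = line[:6].strip()
                if rec == "MODEL":
                    in_model, current = True, 0
                elif rec == "ENDMDL":
                    counts.append(current)
                    in_model = False
                elif rec in ("ATOM", "HETATM"):
                    current += 1
        if in_model:
            counts.append(current)
        if not counts:  # single-model PDB: nothing to cross-check
            return
    elif suffix == ".xyz":
        counts = []
        with path.open() as fh:
            lines = fh.readlines()
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            try:
                n = int(lines[i].split()[0])
            except ValueError:
                raise FormatError(f"{path}: expected atom count at line {i + 1}")
            counts.append(n)
            i += n + 2
    else:
        return
    for idx, c in enumerate(counts):
        if c != counts[0]:
            raise FormatError(
                f"{path}: frame {idx} has {c} atoms, expected {counts[0]}"
            )


def read_trajectory(
    topology_path: str | Path,
    coordinate_path: str | Path | None = None,
    ligand_resname: str = DEFAULT_LIGAND_RESNAME,
    frame_interval_ps: float = 100.0,
) -> Trajectory:
    """Read a topology PDB and an optional multi-model PDB / XYZ trajectory.

    Roles are assigned from residue names (standard amino acids -> protein,
    HOH/WAT/TIP3/SPC -> water, FAD -> cofactor, common monatomic ions -> ion,
    the configured ligand residue name -> ligand); any other residue name is
    an error.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    files = [topology_path]
    if coordinate_path is not None:
        coordinate_path = Path(coordinate_path)
        _check_frame_atom_counts(coordinate_path)
        files.append(coordinate_path)
    _check_frame_atom_counts(topology_path)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guessing chatter
        u = mda.Universe(*[str(f) for f in files])

    n_atoms = len(u.atoms)
    names = [a.name for a in u.atoms]
    resnames = [a.resname for a in u.atoms]
    resnums = [int(a.resid) for a in u.atoms]
    try:
        chains = [str(c) for c in u.atoms.chainIDs]
    except (AttributeError, mda.exceptions.NoDataError):
        chains = [""] * n_atoms
    try:
        elements = [str(e) for e in u.atoms.elements]
    except (AttributeError, mda.exceptions.NoDataError):
        elements = [_element_from_name(n) for n in names]
    elements = [e if e else _element_from_name(n) for e, n in zip(elements, names)]
    roles = [assign_role(rn, ligand_resname) for rn in resnames]

    atoms = pd.DataFrame(
        {
            "name": names,
            "element": elements,
            "resname": [r.strip().upper() for r in resnames],
            "resnum": resnums,
            "chain": chains,
            "role": roles,
        }
    )

    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    topology = Structure(atoms, frames[0])
    return Trajectory(topology, frames, frame_interval_ps=frame_interval_ps)


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "NA", "MG", "FE", "BR"):
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "X"


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------


def select(
    structure: Structure,
    role: str | None = None,
    name: str | Sequence[str] | None = None,
    resname: str | None = None,
    resnum: int | None = None,
    element: str | None = None,
    heavy: bool = False,
) -> np.ndarray:
    """Return indices of atoms matching all given criteria."""
    mask = np.ones(structure.n_atoms, dtype=bool)
    a = structure.atoms
    if role is not None:
        mask &= (a["role"] == role).to_numpy()
    if name is not None:
        names = [name] if isinstance(name, str) else list(name)
        mask &= a["name"].isin(names).to_numpy()
    if resname is not None:
        mask &= (a["resname"] == resname.upper()).to_numpy()
    if resnum is not None:
        mask &= (a["resnum"] == resnum).to_numpy()
    if element is not None:
        mask &= (a["element"].str.upper() == element.upper()).to_numpy()
    if heavy:
        mask &= (a["element"].str.upper() != "H").to_numpy()
    return np.flatnonzero(mask)


def find_atoms(structure: Structure, spec: str) -> np.ndarray:
    """Resolve an atom spec like ``"ASN:181:OD1"``, ``"ASN:181"`` or ``"HRM:N9"``.

    ``RES:NUM:NAME`` selects one named atom; ``RES:NUM`` selects all heavy
    atoms of that residue; ``RES:NAME`` (non-numeric second field) selects the
    named atom in every residue with that residue name.
    """
    parts = spec.split(":")
    if len(parts) == 3:
        idx = select(structure, resname=parts[0], resnum=int(parts[1]), name=parts[2])
    elif len(parts) == 2:
        if parts[1].isdigit():
            idx = select(structure, resname=parts[0], resnum=int(parts[1]), heavy=True)
        else:
            idx = select(structure, resname=parts[0], name=parts[1])
    else:
        raise InvalidInputError(f"cannot parse atom spec {spec!r}")
    if idx.size == 0:
        raise InvalidInputError(f"atom spec {spec!r} matches no atoms")
    return idx


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body (Kabsch) superposition.

    Fits the selected atoms of ``mobile`` onto the same selection of
    ``reference`` and applies the resulting rotation + translation to all
    atoms.  Returns ``(rotation_matrix, translation, aligned_coords, rmsd)``
    where the RMSD is over the selection after superposition.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        selection = np.arange(len(mobile))
    if len(selection) < 3:
        raise InvalidInputError(f"need >= 3 atoms to superpose, got {len(selection)}")
    m_sel, r_sel = mobile[selection], reference[selection]
    m_cen, r_cen = m_sel.mean(axis=0), r_sel.mean(axis=0)
    rot, _ = Rotation.align_vectors(r_sel - r_cen, m_sel - m_cen)
    R = rot.as_matrix()
    aligned = (mobile - m_cen) @ R.T + r_cen
    fit_rmsd = float(np.sqrt(np.mean(np.sum((aligned[selection] - r_sel) ** 2, axis=1))))
    translation = r_cen - m_cen @ R.T
    return R, translation, aligned, fit_rmsd


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    traj: Trajectory,
    align_selection: np.ndarray | None = None,
    measure_selection: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Per-frame RMSD of a selection against frame 0, after superposition.

    Default convention: align each frame onto frame 0 using protein C-alpha
    atoms, then measure the heavy-atom RMSD of the ligand -- the standard
    pose-stability metric whose trajectory average is reported per compound.
    Falls back to all heavy atoms for alignment if no protein C-alphas exist.

    Returns ``(per_frame_rmsd, time_average)``.
    """
    top = traj.topology
    if align_selection is None:
        align_selection = select(top, role="protein", name="CA")
        if align_selection.size < 3:
            align_selection = select(top, heavy=True)
    if measure_selection is None:
        measure_selection = select(top, role="ligand", heavy=True)
    align_selection = np.asarray(align_selection)
    measure_selection = np.asarray(measure_selection)
    if align_selection.size == 0 or measure_selection.size == 0:
        raise InvalidInputError("empty alignment or measurement selection")

    ref = traj.frames[0]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, _, aligned, _ = superpose(traj.frames[i], ref, align_selection)
        out[i] = _rmsd(aligned[measure_selection], ref[measure_selection])
    return out, float(out.mean())


# ---------------------------------------------------------------------------
# Distances and water counts
# ---------------------------------------------------------------------------


def distance_series(
    traj: Trajectory,
    atoms_a: np.ndarray | str,
    atoms_b: np.ndarray | str,
    block_length_ns: float = 0.1,
) -> DistanceSeries:
    """Per-frame minimum distance between two selections, block-averaged.

    Selections may be index arrays or atom specs (see :func:`find_atoms`).
    Multi-atom selections use the nearest pair per frame, which covers the
    "nearest side-chain heavy atom" convention for residue partners.  Block
    averages are over contiguous windows of ``block_length_ns`` (default
    0.1 ns: 1000 blocks cover a 100 ns run sampled every 0.1 ns).
    """
    top = traj.topology
    if isinstance(atoms_a, str):
        label_a, atoms_a = atoms_a, find_atoms(top, atoms_a)
    else:
        label_a = ",".join(top.atoms["name"].iloc[atoms_a])
    if isinstance(atoms_b, str):
        label_b, atoms_b = atoms_b, find_atoms(top, atoms_b)
    else:
        label_b = ",".join(top.atoms["name"].iloc[atoms_b])
    if not block_length_ns > 0:
        raise InvalidInputError("block_length_ns must be positive")

    a = traj.frames[:, np.asarray(atoms_a), :]
    b = traj.frames[:, np.asarray(atoms_b), :]
    diff = a[:, :, None, :] - b[:, None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1)).min(axis=(1, 2))

    frames_per_block = int(round(block_length_ns * 1000.0 / traj.frame_interval_ps))
    frames_per_block = max(frames_per_block, 1)
    if frames_per_block > traj.n_frames:
        raise InvalidInputError(
            f"block of {frames_per_block} frames exceeds trajectory length {traj.n_frames}"
        )
    n_blocks = traj.n_frames // frames_per_block
    blocks = dist[: n_blocks * frames_per_block].reshape(n_blocks, frames_per_block)
    return DistanceSeries(
        label_a=label_a,
        label_b=label_b,
        distances=dist,
        block_averages=blocks.mean(axis=1),
        block_length_ns=block_length_ns,
    )


def count_waters(
    traj: Trajectory,
    center_selection: np.ndarray | str | None = None,
    radius: float = 5.0,
) -> tuple[np.ndarray, float]:
    """Count water oxygens within ``radius`` of a center, per frame.

    The default center is the FAD N5 atom, the conventional origin of the
    MAO-A binding cavity; the centroid is used for multi-atom centers.
    Returns ``(per_frame_counts, mean_count)``.  A topology without waters
    yields zeros with a warning.
    """
    top = traj.topology
    if not radius > 0:
        raise InvalidInputError("radius must be positive")
    if center_selection is None:
        center_selection = select(top, resname="FAD", name="N5")
        if center_selection.size == 0:
            raise InvalidInputError("no FAD N5 atom found; give center_selection explicitly")
    elif isinstance(center_selection, str):
        center_selection = find_atoms(top, center_selection)
    center_selection = np.asarray(center_selection)
    if center_selection.size == 0:
        raise InvalidInputError("empty center selection")

    water_o = select(top, role="water", element="O")
    if water_o.size == 0:
        logger.warning("topology contains no water oxygens; returning zero counts")
        return np.zeros(traj.n_frames, dtype=int), 0.0
    centers = traj.frames[:, center_selection, :].mean(axis=1)
    w = traj.frames[:, water_o, :]
    d = np.linalg.norm(w - centers[:, None, :], axis=-1)
    counts = (d <= radius).sum(axis=1)
    return counts, float(counts.mean())


# ---------------------------------------------------------------------------
# Writers (fixed-column PDB 3.3 and plain XYZ)
# ---------------------------------------------------------------------------


def _pdb_atom_line(i: int, name: str, resname: str, chain: str, resnum: int,
                   xyz: np.ndarray, element: str) -> str:
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {i:>5d} {nm:<4.4s} {resname:<3.3s} {(chain or 'A'):1.1s}{resnum:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{element:>2.2s}\n"
    )


def write_pdb(path: str | Path, structure: Structure) -> None:
    """Write a single-model PDB (fixed-column, PDB 3.3 ATOM records)."""
    with Path(path).open("w") as fh:
        _write_model(fh, structure.atoms, structure.coords)
        fh.write("END\n")


def _write_model(fh, atoms: pd.DataFrame, coords: np.ndarray) -> None:
    for i, (row, xyz) in enumerate(zip(atoms.itertuples(), coords), start=1):
        fh.write(
            _pdb_atom_line(i, row.name, row.resname, row.chain, row.resnum, xyz, row.element)
        )


def write_trajectory_pdb(path: str | Path, traj: Trajectory) -> None:
    """Write a multi-model PDB trajectory."""
    with Path(path).open("w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"MODEL     {m + 1:>4d}\n")
            _write_model(fh, traj.topology.atoms, traj.frames[m])
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_trajectory_xyz(path: str | Path, traj: Trajectory) -> None:
    """Write an XYZ trajectory (element x y z; count + comment per frame)."""
    atoms = traj.topology.atoms
    with Path(path).open("w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"{traj.topology.n_atoms}\n")
            fh.write(f"frame {m}\n")
            for el, xyz in zip(atoms["element"], traj.frames[m]):
                fh.write(f"{el:<2s} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n")
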