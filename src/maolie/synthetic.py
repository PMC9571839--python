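"""Synthetic MD data with known ground truth.

No trajectories or energy logs are deposited for the beta-carboline/MAO-A
simulations, so every downstream operation is exercised against generated
inputs whose true statistics are known by construction:

* interaction-energy time series -- an AR(1) Gaussian process (slow-wander
  autocorrelation mimicking MD energy traces) affinely rescaled after
  generation so that the sample mean and block-mean SD match the requested
  targets exactly;
* LIE calibration datasets with known coefficients and controllable noise;
* toy binding-pocket trajectories with scheduled contacts, hydrogen-bond
  geometries, rigid pose shifts and fixed or Poisson water occupancy,
  emitted together with a machine-readable ground-truth report.

All generators are deterministic given their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .energy_stats import (
    DEFAULT_N_BLOCKS,
    EnergyTimeSeries,
    InteractionEnergySummary,
    block_statistics,
)
from .errors import GenerationError, InvalidInputError
from .lie_engine import BindingFreeEnergy, LIECoefficients
from .trajectory import Structure, Trajectory

# ---------------------------------------------------------------------------
# Energy series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergySeriesSpec:
    """Target statistics for one synthetic interaction-energy series.

    ``target_block_sd`` is the sample SD of the ``n_blocks`` block means that
    :func:`~maolie.energy_stats.block_statistics` will recover -- by
    construction, exactly.
    """

    compound_id: int
    state: str
    component: str
    target_mean: float
    target_block_sd: float
    n_steps: int = 5000
    ar1_phi: float = 0.95
    n_blocks: int = DEFAULT_N_BLOCKS
    sampling_interval_ps: float = 20.0

    def __post_init__(self):
        if not 0 <= self.ar1_phi < 1:
            raise InvalidInputError(f"ar1_phi must be in [0, 1), got {self.ar1_phi}")
        if self.target_block_sd < 0:
            raise InvalidInputError("target_block_sd must be >= 0")
        if self.n_steps < self.n_blocks:
            raise InvalidInputError(
                f"n_steps ({self.n_steps}) must be >= n_blocks ({self.n_blocks})"
            )


def gen_energy_series(spec: EnergySeriesSpec, seed: int) -> EnergyTimeSeries:
    """Generate an AR(1) series whose block statistics hit the spec exactly.

    The raw process x_t = phi * x_{t-1} + eps_t is rescaled affinely so the
    mean of the block means equals ``target_mean`` and their sample SD equals
    ``target_block_sd`` (post-hoc rescaling keeps fixture-based tests exact
    rather than relying on asymptotic variance formulas).
    """
    rng = np.random.default_rng(seed)
    n = spec.n_steps
    if spec.target_block_sd == 0.0:
        values = np.full(n, spec.target_mean)
    else:
        x = np.empty(n)
        x[0] = rng.standard_normal() / np.sqrt(1 - spec.ar1_phi**2)
        eps = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = spec.ar1_phi * x[t - 1] + eps[t]
        block_len = n // spec.n_blocks
        used = block_len * spec.n_blocks
        bm = x[:used].reshape(spec.n_blocks, block_len).mean(axis=1)
        sd = bm.std(ddof=1)
        if sd == 0.0:  # pragma: no cover - essentially impossible for Gaussian noise
            raise GenerationError("degenerate raw series; change the seed")
        scale = spec.target_block_sd / sd
        values = spec.target_mean + scale * (x - bm.mean())
    return EnergyTimeSeries(
        compound_id=spec.compound_id,
        state=spec.state,
        component=spec.component,
        values=values,
        sampling_interval_ps=spec.sampling_interval_ps,
    )


def gen_compound_series(
    summary: InteractionEnergySummary,
    seed: int,
    n_steps: int = 5000,
    ar1_phi: float = 0.95,
) -> list[EnergyTimeSeries]:
    """Generate the four (state, component) series matching a summary's
    bound/free means and SDs."""
    targets = {
        ("bound", "vdw"): summary.vdw_bound,
        ("free", "vdw"): summary.vdw_free,
        ("bound", "el"): summary.el_bound,
        ("free", "el"): summary.el_free,
    }
    out = []
    for k, ((state, comp), ms) in enumerate(targets.items()):
        spec = EnergySeriesSpec(
            compound_id=summary.compound_id,
            state=state,
            component=comp,
            target_mean=ms.mean,
            target_block_sd=ms.sd,
            n_steps=n_steps,
            ar1_phi=ar1_phi,
        )
        out.append(gen_energy_series(spec, seed=seed * 8 + k))
    return out


def gen_lie_dataset(
    summaries: Sequence[InteractionEnergySummary],
    true_coeffs: LIECoefficients,
    noise_sd: float,
    seed: int,
) -> list[BindingFreeEnergy]:
    """Synthetic 'experimental' binding free energies from known coefficients.

    dG_i = alpha*dVdW_i + beta*dEl_i + gamma + N(0, noise_sd^2), for
    parameter-recovery testing of the calibration.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for s in summaries:
        value = (
            true_coeffs.alpha * s.delta_vdw.mean
            + true_coeffs.beta * s.delta_el.mean
            + true_coeffs.gamma
        )
        if noise_sd > 0:
            value += rng.normal(0.0, noise_sd)
        out.append(
            BindingFreeEnergy(
                compound_id=s.compound_id,
                value=float(value),
                uncertainty=noise_sd,
                source="experimental",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Toy pocket trajectories
# ---------------------------------------------------------------------------

# Minimal beta-carboline-like ligand template (HRM): tricyclic heavy-atom
# skeleton with pyridine N1, pyrrole N9 (+H9), C1-methyl and a methoxy O.
# Coordinates are relative to the ligand origin, roughly planar.
LIGAND_TEMPLATE: list[tuple[str, str, np.ndarray]] = [
    ("N1", "N", np.array([2.1, 0.7, 0.0])),
    ("C2", "C", np.array([2.1, -0.7, 0.0])),
    ("C3", "C", np.array([0.9, -1.4, 0.0])),
    ("C4", "C", np.array([-0.3, -0.7, 0.0])),
    ("C4A", "C", np.array([-0.3, 0.7, 0.0])),
    ("C9A", "C", np.array([0.9, 1.4, 0.0])),
    ("N9", "N", np.array([-1.6, 1.1, 0.0])),
    ("H9", "H", np.array([-1.9, 2.05, 0.0])),
    ("C4B", "C", np.array([-1.6, -1.1, 0.0])),
    ("C5", "C", np.array([-2.9, -1.4, 0.0])),
    ("C6", "C", np.array([-3.9, -0.5, 0.0])),
    ("C7", "C", np.array([-3.9, 0.9, 0.0])),
    ("C8", "C", np.array([-2.9, 1.8, 0.0])),
    ("CM1", "C", np.array([3.4, 1.4, 0.0])),
    ("OM", "O", np.array([-5.1, 1.5, 0.0])),
]

# Pseudo-residues of the toy pocket: (resname, resnum, {atom: coords}).
# Each residue carries a CA (for alignment) plus only the side-chain atoms
# the detection tables need.  Anchors are >= ~8 A from the ligand rest
# position so that only scheduled contacts fire.
def _ring(center: np.ndarray, radius: float = 1.4) -> dict[str, np.ndarray]:
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    ang = np.linspace(0, 2 * np.pi, 7)[:6]
    return {
        nm: center + radius * np.array([np.cos(a), np.sin(a), 0.0])
        for nm, a in zip(names, ang)
    }


def default_pocket_residues() -> list[tuple[str, int, dict[str, np.ndarray]]]:
    res = []
    asn = {
        "CA": np.array([-11.0, 7.5, 0.0]),
        "CB": np.array([-10.2, 6.9, 0.0]),
        "CG": np.array([-9.4, 6.3, 0.0]),
        "OD1": np.array([-8.6, 5.7, 0.0]),
        "ND2": np.array([-9.6, 5.2, 1.0]),
    }
    res.append(("ASN", 181, asn))
    tyr407 = {"CA": np.array([12.0, 7.0, 2.0]), "OH": np.array([9.0, 8.6, 2.0])}
    tyr407.update(_ring(np.array([9.5, 6.0, 2.0])))
    res.append(("TYR", 407, tyr407))
    tyr444 = {"CA": np.array([12.0, -1.0, -2.0]), "OH": np.array([9.0, 1.6, -2.0])}
    tyr444.update(_ring(np.array([9.5, -1.0, -2.0])))
    res.append(("TYR", 444, tyr444))
    leu = {
        "CA": np.array([-10.0, -3.0, 3.0]),
        "CB": np.array([-9.2, -2.5, 3.2]),
        "CG": np.array([-8.4, -2.0, 3.4]),
        "CD1": np.array([-7.6, -1.4, 3.6]),
        "CD2": np.array([-8.8, -1.0, 4.2]),
    }
    res.append(("LEU", 337, leu))
    met = {
        "CA": np.array([2.0, 13.0, -3.0]),
        "CB": np.array([2.2, 12.0, -3.2]),
        "CG": np.array([2.4, 11.0, -3.4]),
        "SD": np.array([2.6, 10.0, -3.6]),
        "CE": np.array([3.4, 9.4, -3.0]),
    }
    res.append(("MET", 350, met))
    phe = {"CA": np.array([-10.5, 2.0, -5.0]), "CB": np.array([-9.7, 2.2, -5.0])}
    phe.update(_ring(np.array([-8.3, 2.5, -5.0])))
    res.append(("PHE", 352, phe))
    fad = {
        "N5": np.array([0.0, -8.0, 0.0]),
        "N1": np.array([1.3, -8.6, 0.0]),
        "O2": np.array([2.2, -7.7, 0.3]),
        "O4": np.array([-1.2, -8.9, -0.3]),
    }
    res.append(("FAD", 600, fad))
    return res


@dataclass(frozen=True)
class ContactSchedule:
    """One scheduled ligand--residue contact.

    ``ligand_atom`` is placed at ``target_distance`` from ``partner_atom`` of
    the partner residue during the given frame ranges (inclusive start,
    exclusive stop) and at ``off_distance`` elsewhere.
    """

    ligand_atom: str
    partner_resname: str
    partner_resnum: int
    partner_atom: str
    frame_ranges: tuple[tuple[int, int], ...]
    target_distance: float = 2.8
    off_distance: float = 8.0

    @property
    def partner_label(self) -> str:
        return f"{self.partner_resname}{self.partner_resnum}"

    def active(self, frame: int) -> bool:
        return any(start <= frame < stop for start, stop in self.frame_ranges)


@dataclass(frozen=True)
class PoseShift:
    """Rigid ligand displacement applied from ``frame`` onward."""

    frame: int
    displacement: tuple[float, float, float]


@dataclass(frozen=True)
class PocketSpec:
    """Full specification of a toy pocket trajectory."""

    n_frames: int = 1000
    frame_interval_ps: float = 100.0
    contacts: tuple[ContactSchedule, ...] = ()
    pose_shift: PoseShift | None = None
    n_waters: int = 7
    water_radius: float = 4.0
    water_poisson_lambda: float | None = None
    jitter_sd: float = 0.05
    ligand_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise InvalidInputError("n_frames must be >= 1")
        for c in self.contacts:
            for start, stop in c.frame_ranges:
                if not (0 <= start < stop <= self.n_frames):
                    raise InvalidInputError(
                        f"contact {c.ligand_atom}-{c.partner_label}: frame range "
                        f"({start}, {stop}) outside [0, {self.n_frames})"
                    )


@dataclass
class PocketGroundTruth:
    """What the generator actually built, for test assertions and reports."""

    pair_occupancy_percent: dict[str, float]  # "N9-ASN181" -> 30.0
    rmsd_planned: np.ndarray  # noiseless ligand heavy-atom RMSD vs frame 0
    water_counts: np.ndarray
    n_frames: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": f"occupancy:{k}", "value": v}
            for k, v in sorted(self.pair_occupancy_percent.items())
        ]
        rows.append({"quantity": "mean_water_count", "value": float(self.water_counts.mean())})
        rows.append({"quantity": "mean_rmsd_planned", "value": float(self.rmsd_planned.mean())})
        return pd.DataFrame(rows)


def _check_conflicts(spec: PocketSpec) -> None:
    by_atom: dict[str, list[ContactSchedule]] = {}
    for c in spec.contacts:
        by_atom.setdefault(c.ligand_atom, []).append(c)
    conflicts = []
    for atom, entries in by_atom.items():
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                a, b = entries[i], entries[j]
                overlap = [
                    f
                    for f in range(spec.n_frames)
                    if a.active(f) and b.active(f)
                ]
                if overlap:
                    conflicts.append(
                        f"{atom}: {a.partner_label} and {b.partner_label} both "
                        f"active in frames {overlap[0]}..{overlap[-1]}"
                    )
    if conflicts:
        raise GenerationError(
            "mutually unsatisfiable contact schedule entries: " + "; ".join(conflicts)
        )


def gen_pocket_trajectory(spec: PocketSpec) -> tuple[Trajectory, PocketGroundTruth]:
    """Build a toy pocket trajectory realising the scheduled geometry.

    The pocket residues are static; the ligand sits at its rest position
    (displaced rigidly from the pose-shift frame onward), with each
    scheduled contact's ligand atom overridden to lie on the line from the
    partner atom towards the ligand rest position, at the on/off distance.
    A hydrogen attached to a scheduled donor follows collinearly, so the
    D-H...A angle is 180 degrees while the contact is active.  Thermal
    jitter is added to non-scheduled ligand atoms and waters only, keeping
    scheduled distances exact.
    """
    _check_conflicts(spec)
    rng = np.random.default_rng(spec.seed)
    residues = default_pocket_residues()

    names, elements, resnames, resnums, roles = [], [], [], [], []
    base_coords = []

    for resname, resnum, atom_map in residues:
        role = "cofactor" if resname == "FAD" else "protein"
        for nm, xyz in atom_map.items():
            names.append(nm)
            elements.append("S" if nm.startswith("S") else nm[0])
            resnames.append(resname)
            resnums.append(resnum)
            roles.append(role)
            base_coords.append(xyz)

    lig_pos = np.asarray(spec.ligand_position, dtype=float)
    lig_start = len(names)
    lig_index: dict[str, int] = {}
    for nm, el, xyz in LIGAND_TEMPLATE:
        lig_index[nm] = len(names)
        names.append(nm)
        elements.append(el)
        resnames.append("HRM")
        resnums.append(1)
        roles.append("ligand")
        base_coords.append(lig_pos + xyz)

    # Water slots.  Fixed occupancy: n_waters oxygens inside water_radius of
    # the FAD N5 center in every frame.  Poisson occupancy: per-frame counts
    # drawn once, inactive slots parked far outside the cavity.
    fad_n5 = dict(residues[-1][2])["N5"]
    if spec.water_poisson_lambda is not None:
        water_counts = rng.poisson(spec.water_poisson_lambda, size=spec.n_frames)
        n_slots = int(water_counts.max(initial=0))
    else:
        water_counts = np.full(spec.n_frames, spec.n_waters, dtype=int)
        n_slots = spec.n_waters
    water_start = len(names)
    water_base = []
    for w in range(n_slots):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        r = spec.water_radius * (0.4 + 0.55 * rng.random())
        water_base.append(fad_n5 + r * direction)
        names.append("O")
        elements.append("O")
        resnames.append("HOH")
        resnums.append(700 + w)
        roles.append("water")
    base_coords.extend(water_base)

    atoms = pd.DataFrame(
        {
            "name": names,
            "element": elements,
            "resname": resnames,
            "resnum": resnums,
            "chain": ["A"] * len(names),
            "role": roles,
        }
    )
    base_coords = np.array(base_coords)

    # Resolve partner anchor coordinates
    partner_xyz: dict[tuple[str, int, str], np.ndarray] = {}
    for resname, resnum, atom_map in residues:
        for nm, xyz in atom_map.items():
            partner_xyz[(resname, resnum, nm)] = xyz
    for c in spec.contacts:
        key = (c.partner_resname, c.partner_resnum, c.partner_atom)
        if key not in partner_xyz:
            raise GenerationError(
                f"contact partner atom {c.partner_resname}{c.partner_resnum}:"
                f"{c.partner_atom} not in the pocket"
            )
        if c.ligand_atom not in lig_index:
            raise GenerationError(f"contact ligand atom {c.ligand_atom!r} not in template")

    shift_vec = (
        np.asarray(spec.pose_shift.displacement, dtype=float)
        if spec.pose_shift is not None
        else np.zeros(3)
    )
    shift_frame = spec.pose_shift.frame if spec.pose_shift is not None else spec.n_frames

    scheduled_atoms = {lig_index[c.ligand_atom] for c in spec.contacts}
    # hydrogens riding on scheduled donors
    h_partner = {lig_index["N9"]: lig_index.get("H9")}

    n_atoms = len(names)
    frames = np.empty((spec.n_frames, n_atoms, 3))
    planned_lig = np.empty((spec.n_frames, len(LIGAND_TEMPLATE), 3))

    lig_slice = slice(lig_start, lig_start + len(LIGAND_TEMPLATE))
    for f in range(spec.n_frames):
        coords = base_coords.copy()
        if f >= shift_frame:
            coords[lig_slice] += shift_vec
        for c in spec.contacts:
            li = lig_index[c.ligand_atom]
            anchor = partner_xyz[(c.partner_resname, c.partner_resnum, c.partner_atom)]
            direction = coords[li] - anchor
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
            dist = c.target_distance if c.active(f) else c.off_distance
            coords[li] = anchor + dist * direction
            h = h_partner.get(li)
            if h is not None:
                # H on the segment donor -> acceptor, collinear
                coords[h] = coords[li] - 1.0 * direction
        planned_lig[f] = coords[lig_slice]
        # jitter: non-scheduled ligand atoms + active waters
        if spec.jitter_sd > 0:
            for i in range(lig_start, lig_start + len(LIGAND_TEMPLATE)):
                if i in scheduled_atoms or i in h_partner.values():
                    continue
                coords[i] += rng.normal(0.0, spec.jitter_sd, 3)
        # water occupancy
        active = int(water_counts[f])
        for w in range(n_slots):
            wi = water_start + w
            if w < active:
                coords[wi] = water_base[w] + (
                    rng.normal(0.0, spec.jitter_sd, 3) if spec.jitter_sd > 0 else 0.0
                )
            else:
                coords[wi] = np.array([60.0 + 3.0 * w, 60.0, 60.0])
        frames[f] = coords

    # Ground truth
    occupancy = {
        f"{c.ligand_atom}-{c.partner_label}": 100.0
        * sum(c.active(f) for f in range(spec.n_frames))
        / spec.n_frames
        for c in spec.contacts
    }
    heavy = [i for i, (nm, el, _) in enumerate(LIGAND_TEMPLATE) if el != "H"]
    ref = planned_lig[0][heavy]
    rmsd_planned = np.sqrt(
        ((planned_lig[:, heavy, :] - ref) ** 2).sum(axis=-1).mean(axis=-1)
    )

    topology = Structure(atoms, frames[0])
    traj = Trajectory(topology, frames, frame_interval_ps=spec.frame_interval_ps)
    truth = PocketGroundTruth(
        pair_occupancy_percent=occupancy,
        rmsd_planned=rmsd_planned,
        water_counts=water_counts,
        n_frames=spec.n_frames,
    )
    return traj, truth


def write_ground_truth_tsv(path: str | Path, truth: PocketGroundTruth) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)
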