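"""Trajectory containers, readers/writers and outcome classification.

An ensemble is a set of trajectories sharing atom count and three bond
definitions: bond 1 is the first-formed bond shared by both products;
bonds 2 and 3 are the bifurcating forming bonds whose first crossing of
the bond-formation criterion (1.700 A) labels a trajectory as the
[4+2]-like (``adduct_42``) or [6+4]-like (``adduct_64``) product.  A
trajectory that re-extends bond 1 past its transition-state value by a
configurable margin without forming either bond is a recrossing.

On disk an ensemble is a directory of multi-frame XYZ files with a
tab-separated sidecar per trajectory (frame index, potential energy in
kcal/mol, per-atom velocities in A/fs) plus a JSON manifest, or a single
HDF5 container with one group per trajectory.  The XYZ/sidecar writers
emit full ``repr`` precision so a write/read cycle is bit-identical.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np

__all__ = [
    "BOND_FORMATION_CRITERION",
    "Outcome",
    "Trajectory",
    "TrajectoryEnsemble",
    "classify_outcome",
    "select_subsets",
    "bond_length_series",
    "write_ensemble",
    "read_ensemble",
    "write_ensemble_hdf5",
    "read_ensemble_hdf5",
    "read_xyz_frames",
]

BOND_FORMATION_CRITERION = 1.700  # A


class Outcome(enum.Enum):
    ADDUCT_42 = "adduct_42"   # channel A: bond 2 forms first
    ADDUCT_64 = "adduct_64"   # channel B: bond 3 forms first
    RECROSS = "recross"
    UNRESOLVED = "unresolved"


@dataclass
class Trajectory:
    coordinates: np.ndarray          # (F, N, 3) A
    velocities: np.ndarray | None    # (F, N, 3) A/fs, optional
    energies: np.ndarray             # (F,) kcal/mol
    times: np.ndarray                # (F,) fs, strictly increasing, uniform
    atom_labels: list[str]
    outcome: Outcome | None = None
    ts_frame_index: int = 0
    energy_drift_exceeded: bool = False
    max_energy_drift: float = 0.0

    def __post_init__(self) -> None:
        f = self.coordinates.shape[0]
        if self.energies.shape != (f,) or self.times.shape != (f,):
            raise ValueError("frame count mismatch between arrays")
        if self.velocities is not None and self.velocities.shape != self.coordinates.shape:
            raise ValueError("velocity array incongruent with coordinates")
        if f > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("frame times must increase by a constant step")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class TrajectoryEnsemble:
    trajectories: list[Trajectory]
    bond_definitions: Mapping[int, tuple[int, int]]
    tss_bond_lengths: Mapping[int, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = {t.n_atoms for t in self.trajectories}
        if len(counts) > 1:
            raise ValueError(f"inconsistent atom counts across trajectories: {counts}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def outcome_counts(self) -> dict[str, int]:
        out = {o.value: 0 for o in Outcome}
        for t in self.trajectories:
            key = t.outcome.value if t.outcome is not None else Outcome.UNRESOLVED.value
            out[key] += 1
        return out


def bond_length_series(traj: Trajectory, pair: Sequence[int]) -> np.ndarray:
    i, j = pair
    return np.linalg.norm(traj.coordinates[:, i] - traj.coordinates[:, j], axis=-1)


def classify_outcome(traj: Trajectory,
                     bond_definitions: Mapping[int, tuple[int, int]],
                     tss_bond_lengths: Mapping[int, float],
                     criterion: float = BOND_FORMATION_CRITERION,
                     reactant_delta: float = 0.5) -> Outcome:
    """Label a trajectory by its first decisive event.

    ``adduct_42`` if bond 2 first crosses below ``criterion``,
    ``adduct_64`` if bond 3 does, ``recross`` if bond 1 re-lengthens past
    its transition-state value + ``reactant_delta`` while bonds 2 and 3
    are still unformed, ``unresolved`` otherwise.  Appending frames after
    the first decisive event cannot change the label.
    """
    d1 = bond_length_series(traj, bond_definitions[1])
    d2 = bond_length_series(traj, bond_definitions[2])
    d3 = bond_length_series(traj, bond_definitions[3])

    nf = traj.n_frames
    sentinel = nf + 1

    def first_true(mask: np.ndarray) -> int:
        idx = np.flatnonzero(mask)
        return int(idx[0]) if idx.size else sentinel

    t2 = first_true(d2 < criterion)
    t3 = first_true(d3 < criterion)
    t_back = first_true(
        (d1 > tss_bond_lengths[1] + reactant_delta) & (d2 > criterion) & (d3 > criterion)
    )
    best = min(t2, t3, t_back)
    if best == sentinel:
        return Outcome.UNRESOLVED
    if best == t2 and t2 <= t3:
        return Outcome.ADDUCT_42
    if best == t3:
        return Outcome.ADDUCT_64
    return Outcome.RECROSS


def select_subsets(ensemble: TrajectoryEnsemble, n_per_outcome: int = 102,
                   seed: int = 0,
                   outcomes: tuple[Outcome, Outcome] = (Outcome.ADDUCT_42,
                                                        Outcome.ADDUCT_64),
                   ) -> dict[Outcome, list[Trajectory]]:
    """Uniform random subsets without replacement, one per adduct class.

    Subsets are drawn strictly within each outcome class (no label
    leakage) and are deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    subsets: dict[Outcome, list[Trajectory]] = {}
    for outcome in outcomes:
        members = [t for t in ensemble.trajectories if t.outcome == outcome]
        if len(members) < n_per_outcome:
            raise ValueError(
                f"outcome {outcome.value} has only {len(members)} trajectories, "
                f"need {n_per_outcome}"
            )
        idx = rng.choice(len(members), size=n_per_outcome, replace=False)
        subsets[outcome] = [members[i] for i in sorted(idx)]
    return subsets


# ---------------------------------------------------------------------------
# multi-frame XYZ + sidecar
# ---------------------------------------------------------------------------


def _write_xyz(path: Path, traj: Trajectory) -> None:
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame={f} time_fs={float(traj.times[f])!r}\n")
            for a in range(traj.n_atoms):
                x, y, z = (float(v) for v in traj.coordinates[f, a])
                fh.write(f"{traj.atom_labels[a]} {x!r} {y!r} {z!r}\n")


def _write_sidecar(path: Path, traj: Trajectory) -> None:
    with path.open("w") as fh:
        fh.write("# frame\tenergy_kcal_mol\tatom\tvx_A_fs\tvy_A_fs\tvz_A_fs\n")
        for f in range(traj.n_frames):
            e = float(traj.energies[f])
            if traj.velocities is None:
                fh.write(f"{f}\t{e!r}\t-\t-\t-\t-\n")
            else:
                for a in range(traj.n_atoms):
                    vx, vy, vz = (float(v) for v in traj.velocities[f, a])
                    fh.write(f"{f}\t{e!r}\t{a}\t{vx!r}\t{vy!r}\t{vz!r}\n")


def read_xyz_frames(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Parse a multi-frame XYZ file.

    Returns (coordinates (F, N, 3), atom labels, comment lines); raises a
    ``ValueError`` naming the offending frame on malformed input.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    coords = []
    labels: list[str] = []
    comments = []
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            nat = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: frame {frame}: bad atom-count line "
                             f"{pos + 1}: {lines[pos]!r}") from exc
        if pos + 1 + nat >= len(lines) + 1:
            raise ValueError(f"{path}: frame {frame} truncated (expected "
                             f"{nat} atoms)")
        comments.append(lines[pos + 1])
        block = lines[pos + 2: pos + 2 + nat]
        if len(block) < nat:
            raise ValueError(f"{path}: frame {frame} is missing atoms "
                             f"(expected {nat}, got {len(block)})")
        frame_coords = []
        frame_labels = []
        for k, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: frame {frame}, line {pos + 3 + k}: "
                                 f"malformed atom record {ln!r}")
            frame_labels.append(parts[0])
            frame_coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if not labels:
            labels = frame_labels
        elif frame_labels != labels:
            raise ValueError(f"{path}: frame {frame}: atom labels differ from "
                             f"frame 0")
        coords.append(frame_coords)
        pos += 2 + nat
        frame += 1
    if not coords:
        raise ValueError(f"{path}: no frames found")
    arr = np.array(coords, dtype=float)
    return arr, labels, comments


def _read_sidecar(path: Path, n_frames: int, n_atoms: int):
    energies = np.full(n_frames, np.nan)
    velocities = np.zeros((n_frames, n_atoms, 3))
    has_vel = True
    with path.open() as fh:
        for ln in fh:
            if ln.startswith("#") or not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            f = int(parts[0])
            energies[f] = float(parts[1])
            if parts[2] == "-":
                has_vel = False
            else:
                a = int(parts[2])
                velocities[f, a] = [float(parts[3]), float(parts[4]), float(parts[5])]
    if np.any(np.isnan(energies)):
        missing = int(np.flatnonzero(np.isnan(energies))[0])
        raise ValueError(
            f"{path}: missing energy for frame {missing}; energy profiles "
            f"require per-frame potential energies"
        )
    return energies, (velocities if has_vel else None)


def write_ensemble(ensemble: TrajectoryEnsemble, out_dir: Path) -> None:
    """Write one XYZ + sidecar pair per trajectory plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, traj in enumerate(ensemble.trajectories):
        stem = f"traj_{i:05d}"
        _write_xyz(out_dir / f"{stem}.xyz", traj)
        _write_sidecar(out_dir / f"{stem}.tsv", traj)
    manifest = {
        "n_trajectories": len(ensemble),
        "bond_definitions": {str(k): list(v) for k, v in ensemble.bond_definitions.items()},
        "tss_bond_lengths": {str(k): v for k, v in ensemble.tss_bond_lengths.items()},
        "outcomes": [
            (t.outcome.value if t.outcome else None) for t in ensemble.trajectories
        ],
        "ts_frame_indices": [t.ts_frame_index for t in ensemble.trajectories],
        "outcome_counts": ensemble.outcome_counts(),
        "meta": _jsonable(ensemble.meta),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_ensemble(path: Path,
                  bond_definitions: Mapping[int, tuple[int, int]] | None = None,
                  ) -> TrajectoryEnsemble:
    """Read an ensemble directory written by :func:`write_ensemble`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if bond_definitions is None:
        bond_definitions = {int(k): tuple(v) for k, v in manifest["bond_definitions"].items()}
    tss = {int(k): v for k, v in manifest["tss_bond_lengths"].items()}
    trajectories = []
    for i in range(manifest["n_trajectories"]):
        stem = f"traj_{i:05d}"
        coords, labels, comments = read_xyz_frames(path / f"{stem}.xyz")
        times = np.array([
            float(c.split("time_fs=")[1].split()[0]) for c in comments
        ])
        energies, velocities = _read_sidecar(path / f"{stem}.tsv",
                                             coords.shape[0], coords.shape[1])
        outcome = manifest["outcomes"][i]
        traj = Trajectory(
            coordinates=coords,
            velocities=velocities,
            energies=energies,
            times=times,
            atom_labels=labels,
            outcome=Outcome(outcome) if outcome else None,
            ts_frame_index=int(manifest["ts_frame_indices"][i]),
        )
        trajectories.append(traj)
    return TrajectoryEnsemble(trajectories, bond_definitions, tss,
                              meta=manifest.get("meta", {}))


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def write_ensemble_hdf5(ensemble: TrajectoryEnsemble, path: Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["bond_definitions"] = json.dumps(
            {str(k): list(v) for k, v in ensemble.bond_definitions.items()}
        )
        h5.attrs["tss_bond_lengths"] = json.dumps(
            {str(k): v for k, v in ensemble.tss_bond_lengths.items()}
        )
        h5.attrs["meta"] = json.dumps(_jsonable(ensemble.meta))
        for i, traj in enumerate(ensemble.trajectories):
            grp = h5.create_group(f"traj_{i:05d}")
            grp.create_dataset("coordinates", data=traj.coordinates)
            if traj.velocities is not None:
                grp.create_dataset("velocities", data=traj.velocities)
            grp.create_dataset("energies", data=traj.energies)
            grp.create_dataset("times", data=traj.times)
            grp.attrs["atom_labels"] = json.dumps(traj.atom_labels)
            grp.attrs["outcome"] = traj.outcome.value if traj.outcome else ""
            grp.attrs["ts_frame_index"] = traj.ts_frame_index


def read_ensemble_hdf5(path: Path) -> TrajectoryEnsemble:
    trajectories = []
    with h5py.File(path, "r") as h5:
        bond_definitions = {
            int(k): tuple(v) for k, v in json.loads(h5.attrs["bond_definitions"]).items()
        }
        tss = {int(k): v for k, v in json.loads(h5.attrs["tss_bond_lengths"]).items()}
        meta = json.loads(h5.attrs.get("meta", "{}"))
        for name in sorted(h5.keys()):
            grp = h5[name]
            outcome = grp.attrs["outcome"]
            trajectories.append(Trajectory(
                coordinates=grp["coordinates"][()],
                velocities=grp["velocities"][()] if "velocities" in grp else None,
                energies=grp["energies"][()],
                times=grp["times"][()],
                atom_labels=json.loads(grp.attrs["atom_labels"]),
                outcome=Outcome(outcome) if outcome else None,
                ts_frame_index=int(grp.attrs["ts_frame_index"]),
            ))
    return TrajectoryEnsemble(trajectories, bond_definitions, tss, meta=meta)
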