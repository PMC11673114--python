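"""Trajectory-averaged energy profiles and roaming-species statistics.

Energy profiles average per-frame electronic (here: potential) energies
over the same structural windows as the entropy profiles, using equal
numbers of trajectories per adduct (set by the minor product), excluding
the first three time steps of each trajectory (which carry the sampled
zero-point energy artifact near the transition state), and reporting the
mean relative to the first surviving window with a bootstrap standard
error over trajectories.

Roaming species are frames whose outcome-defining forming bond changes
at a near-zero rate, |d(bond)/dt| <= 0.01 A/fs; the roaming fraction is
reported per window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .trajectory_io import Trajectory, bond_length_series

__all__ = [
    "EnergyProfile",
    "RoamingSeries",
    "energy_profile",
    "bond_velocity",
    "roaming_fraction",
    "ROAMING_THRESHOLD",
]

ROAMING_THRESHOLD = 0.01  # A/fs


@dataclass
class EnergyProfile:
    centers: np.ndarray           # A
    mean_energy: np.ndarray       # kcal/mol, relative to first window
    standard_errors: np.ndarray   # kcal/mol, bootstrap over trajectories
    counts: np.ndarray            # frames per window


@dataclass
class RoamingSeries:
    centers: np.ndarray
    fraction: np.ndarray          # in [0, 1]
    counts: np.ndarray
    threshold: float = ROAMING_THRESHOLD


def _frame_arrays(trajectories: Sequence[Trajectory], bond: tuple[int, int],
                  tss_length: float, skip_first: int):
    """Per-frame (delta_r, energy, trajectory index) with the first
    ``skip_first`` frames of each trajectory excluded."""
    drs, energies, ids = [], [], []
    for k, traj in enumerate(trajectories):
        d = bond_length_series(traj, bond)
        sl = slice(skip_first, None)
        drs.append(d[sl] - tss_length)
        energies.append(traj.energies[sl])
        ids.append(np.full(d[sl].size, k))
    return (np.concatenate(drs), np.concatenate(energies),
            np.concatenate(ids))


def _trim_equal(subsets: Mapping, seed: int):
    """Trim every subset to the minor-product count, drawn with a seed."""
    n_min = min(len(v) for v in subsets.values())
    rng = np.random.default_rng(seed)
    out = {}
    for key, trajs in subsets.items():
        if len(trajs) > n_min:
            idx = np.sort(rng.choice(len(trajs), n_min, replace=False))
            out[key] = [trajs[i] for i in idx]
        else:
            out[key] = list(trajs)
    return out


def energy_profile(trajectories: Sequence[Trajectory], windows,
                   bond: tuple[int, int], tss_length: float,
                   skip_first: int = 3, n_bootstrap: int = 1000,
                   seed: int = 0) -> EnergyProfile:
    """Mean frame energy per structural window, relative to the first
    window's mean; SE over trajectories (nonparametric bootstrap).

    ``windows`` is the (truncated) window list from the entropy stage so
    both profiles share one grid.  Frames missing energies raise.
    """
    for traj in trajectories:
        if traj.energies is None or np.any(~np.isfinite(traj.energies)):
            raise ValueError("energy profile requires finite per-frame "
                             "energies for every trajectory")
    dr, energy, ids = _frame_arrays(trajectories, bond, tss_length, skip_first)

    n_traj = len(trajectories)
    centers, means, ses, counts = [], [], [], []
    sums = np.zeros((len(windows), n_traj))
    nums = np.zeros((len(windows), n_traj), dtype=int)
    for k, w in enumerate(windows):
        mask = (dr >= w.lo) & (dr < w.hi)
        centers.append(w.center)
        counts.append(int(mask.sum()))
        np.add.at(sums[k], ids[mask], energy[mask])
        np.add.at(nums[k], ids[mask], 1)
        means.append(energy[mask].mean() if mask.any() else np.nan)
    means = np.asarray(means)
    ref = means[0]

    rng = np.random.default_rng(seed)
    boot = np.full((n_bootstrap, len(windows)), np.nan)
    for b in range(n_bootstrap):
        take = rng.integers(0, n_traj, n_traj)
        s = sums[:, take].sum(axis=1)
        m = nums[:, take].sum(axis=1)
        with np.errstate(invalid="ignore"):
            prof = s / m
        boot[b] = prof - prof[0]
    se = np.nanstd(boot, axis=0, ddof=1) if n_bootstrap else np.zeros(len(windows))

    return EnergyProfile(
        centers=np.asarray(centers),
        mean_energy=means - ref,
        standard_errors=se,
        counts=np.asarray(counts),
    )


def energy_profile_balanced(subsets: Mapping, windows_by_key: Mapping,
                            bonds_by_key: Mapping, tss_by_key: Mapping,
                            skip_first: int = 3, seed: int = 0,
                            n_bootstrap: int = 1000) -> dict:
    """Energy profile per adduct with subsets trimmed to equal size
    (the minor-product count), as used for cross-channel comparison."""
    trimmed = _trim_equal(subsets, seed)
    return {
        key: energy_profile(trajs, windows_by_key[key], bonds_by_key[key],
                            tss_by_key[key], skip_first=skip_first,
                            n_bootstrap=n_bootstrap, seed=seed)
        for key, trajs in trimmed.items()
    }


def bond_velocity(traj: Trajectory, bond: tuple[int, int]) -> np.ndarray:
    """Rate of change of a bond length, A/fs, per frame.

    With velocities present: the relative velocity projected on the bond
    unit vector (exact, insensitive to rigid rotation).  Without: central
    finite differences of the length series (O(dt^2) consistent).
    """
    if traj.n_frames < 2 and traj.velocities is None:
        raise ValueError("cannot differentiate a single-frame trajectory")
    i, j = bond
    if traj.velocities is not None:
        rij = traj.coordinates[:, i] - traj.coordinates[:, j]
        vij = traj.velocities[:, i] - traj.velocities[:, j]
        d = np.linalg.norm(rij, axis=-1)
        return np.sum(rij * vij, axis=-1) / d
    d = bond_length_series(traj, bond)
    return np.gradient(d, traj.times)


def roaming_fraction(trajectories: Sequence[Trajectory], windows,
                     bond: tuple[int, int], tss_length: float,
                     threshold: float = ROAMING_THRESHOLD,
                     per_trajectory: bool = False) -> RoamingSeries:
    """Fraction of member frames with |bond velocity| <= threshold per
    window (default), or the fraction of member trajectories having at
    least one such frame in the window (``per_trajectory=True``).

    Empty windows yield NaN (omitted points).
    """
    drs, vels, ids = [], [], []
    for k, traj in enumerate(trajectories):
        d = bond_length_series(traj, bond)
        drs.append(d - tss_length)
        vels.append(bond_velocity(traj, bond))
        ids.append(np.full(d.size, k))
    dr = np.concatenate(drs)
    v = np.concatenate(vels)
    ids = np.concatenate(ids)
    slow = np.abs(v) <= threshold

    centers, fracs, counts = [], [], []
    for w in windows:
        mask = (dr >= w.lo) & (dr < w.hi)
        centers.append(w.center)
        counts.append(int(mask.sum()))
        if not mask.any():
            fracs.append(np.nan)
        elif per_trajectory:
            present = np.unique(ids[mask])
            roamers = np.unique(ids[mask & slow])
            fracs.append(roamers.size / present.size)
        else:
            fracs.append(float(slow[mask].mean()))
    return RoamingSeries(np.asarray(centers), np.asarray(fracs),
                         np.asarray(counts), threshold)
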