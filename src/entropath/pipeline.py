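"""End-to-end orchestration: simulate/ingest -> featurize -> densify ->
profile -> report, as one configured, seeded run.

For each adduct channel the pipeline selects a balanced random subset of
trajectories, converts their post-TS frames to internal coordinates,
trains a bidirectional GAN on the normalized table, pools real and
generated configurations into structural windows along that adduct's
forming bond, and emits configurational-entropy profiles (real-only and
GAN-augmented), trajectory-averaged energy profiles, roaming-fraction
series and optional moiety decompositions, plus a JSON report with a
trap/barrier summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bgan import BGANConfig, generate, train
from .energy import energy_profile, roaming_fraction
from .entropy import (EstimatorConfig, MoietyDefinition, entropy_profile,
                      moiety_profiles, segment_windows, truncate_sparse)
from .internal_coordinates import build_scheme, evaluate, fit_normalizer
from .constants import ROOM_T
from .toy_system import ModelSurfaceSpec, generate_ensemble, build_topology
from .trajectory_io import (Outcome, TrajectoryEnsemble, read_ensemble,
                            read_ensemble_hdf5, select_subsets)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

ADDUCT_BOND = {Outcome.ADDUCT_42: 2, Outcome.ADDUCT_64: 3}


@dataclass
class RunConfig:
    surface: ModelSurfaceSpec | None = None      # synthetic source ...
    input_path: str | None = None                # ... or an ensemble on disk
    n_trajectories: int = 2000
    temperature: float = ROOM_T
    subset_size: int = 102
    window_width: float = 0.05
    dr_range: tuple[float, float] = (-0.6, 0.6)
    truncation_fraction: float = 0.25
    pseudo_per_real: float = 3.0                 # generated rows per real row
    bgan: BGANConfig = field(default_factory=lambda: BGANConfig(
        hidden=(64, 64, 64), epochs=300))
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    moieties: dict[str, list[int]] = field(default_factory=dict)
    seed: int = 0
    max_training_rows: int = 4096
    skip_bgan: bool = False                      # real-only ablation mode
    out_dir: str | None = None

    def config_hash(self) -> str:
        """Hash of everything that determines the numbers (the output
        location does not)."""
        payload = _jsonable(asdict(self))
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


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


def _load_ensemble(config: RunConfig) -> TrajectoryEnsemble:
    if config.surface is not None:
        return generate_ensemble(config.surface, config.n_trajectories,
                                 temperature=config.temperature,
                                 seed=config.seed)
    if config.input_path is None:
        raise ValueError("config needs either a surface or an input path")
    path = Path(config.input_path)
    if path.is_dir():
        return read_ensemble(path)
    return read_ensemble_hdf5(path)


def _profile_frame(profile) -> pd.DataFrame:
    df = pd.DataFrame({
        "center_A": profile.centers,
        "entropy_kB": profile.entropy,
        "minus_T_dS_kcal_mol": profile.minus_t_delta_s,
        "se_kcal_mol": profile.standard_errors,
        "population": profile.populations,
    })
    if profile.pseudo_populations is not None:
        df["pseudo_population"] = profile.pseudo_populations
    return df


def _classify_extremum(profile, dr_limit: float = 0.6):
    inside = np.abs(profile.centers) <= dr_limit
    if not inside.any():
        return {"kind": "none", "reason": "no window within display range"}
    vals = profile.minus_t_delta_s[inside]
    ses = profile.standard_errors[inside]
    centers = profile.centers[inside]
    k = int(np.argmax(np.abs(vals)))
    value, se, center = float(vals[k]), float(ses[k]), float(centers[k])
    significant = abs(value) > 2.0 * se if se > 0 else abs(value) > 0
    kind = "trap" if value < 0 else "barrier"
    return {
        "kind": kind if significant else "none",
        "minus_T_dS_kcal_mol": value,
        "center_A": center,
        "se_kcal_mol": se,
        "significant": bool(significant),
    }


def analyse_channel(trajectories, bond: tuple[int, int], tss_length: float,
                    scheme, config: RunConfig, seed: int,
                    temperature: float):
    """Full per-adduct analysis; returns (profiles dict, windows)."""
    frames = []
    traj_ids = []
    for k, traj in enumerate(trajectories):
        sl = slice(traj.ts_frame_index, None)
        frames.append(traj.coordinates[sl])
        traj_ids.append(np.full(traj.coordinates[sl].shape[0], k))
    coords = np.concatenate(frames, axis=0)
    traj_ids = np.concatenate(traj_ids)

    table = evaluate(coords, scheme, redundant=True)
    n_tree = scheme.n_coordinates
    bond_col = scheme.bond_column(bond)
    dr_real = table[:, bond_col] - tss_length

    if config.skip_bgan:
        pooled = table[:, :n_tree]
        dr = dr_real
        pseudo_mask = np.zeros(pooled.shape[0], dtype=bool)
        ids = traj_ids
    else:
        rng = np.random.default_rng(seed)
        rows = table.shape[0]
        if rows > config.max_training_rows:
            pick = np.sort(rng.choice(rows, config.max_training_rows,
                                      replace=False))
            training = table[pick]
        else:
            training = table
        normalizer = fit_normalizer(training)
        bundle = train(normalizer.apply(training),
                       dataclasses.replace(config.bgan, seed=seed),
                       normalizer=normalizer)
        n_pseudo = int(config.pseudo_per_real * rows)
        pseudo = generate(bundle, n_pseudo, seed=seed + 1)
        pooled = np.concatenate([table, pseudo.values], axis=0)[:, list(range(n_tree))]
        dr = np.concatenate([dr_real,
                             pseudo.values[:, bond_col] - tss_length])
        pseudo_mask = np.concatenate([
            np.zeros(rows, dtype=bool), np.ones(n_pseudo, dtype=bool)])
        ids = np.concatenate([traj_ids, np.full(n_pseudo, -1)])

    lo, hi = config.dr_range
    windows = truncate_sparse(
        segment_windows(dr, config.window_width, lo=lo, hi=hi),
        config.truncation_fraction)

    est = dataclasses.replace(config.estimator, bootstrap_seed=seed)
    tmask = scheme.torsion_columns()
    profile = entropy_profile(windows, pooled, temperature=temperature,
                              config=est, traj_ids=ids,
                              pseudo_mask=pseudo_mask, torsion_mask=tmask)

    # real-only ablation on the same grid conventions
    real_windows = truncate_sparse(
        segment_windows(dr_real, config.window_width, lo=lo, hi=hi),
        config.truncation_fraction)
    real_profile = entropy_profile(real_windows, table[:, :n_tree],
                                   temperature=temperature, config=est,
                                   traj_ids=traj_ids, torsion_mask=tmask)

    moieties = [MoietyDefinition.of(name, atoms)
                for name, atoms in config.moieties.items()]
    moiety = {}
    if moieties:
        moiety = moiety_profiles(real_windows, table[:, :n_tree], scheme,
                                 moieties, temperature=temperature,
                                 config=est, traj_ids=traj_ids,
                                 torsion_mask=tmask)
    return {
        "augmented": profile,
        "real_only": real_profile,
        "moieties": moiety,
    }, windows


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the run report (also written to
    ``config.out_dir`` with tidy per-stage tables when set)."""
    ensemble = _load_ensemble(config)
    counts = ensemble.outcome_counts()
    log.info("outcome counts: %s", counts)

    n_sub = min(config.subset_size,
                counts[Outcome.ADDUCT_42.value],
                counts[Outcome.ADDUCT_64.value])
    if n_sub < 1:
        raise RuntimeError(f"no balanced subsets possible: counts {counts}")
    subsets = select_subsets(ensemble, n_per_outcome=n_sub,
                             seed=config.seed + 1)

    if config.surface is not None:
        topo = build_topology(config.surface)
        connectivity = topo.connectivity
    else:
        connectivity = ensemble.meta.get("connectivity")
        if connectivity is None:
            raise ValueError("loaded ensembles must carry a 'connectivity' "
                             "edge list in their manifest meta")
        connectivity = [tuple(e) for e in connectivity]
    scheme = build_scheme(connectivity,
                          root=ensemble.bond_definitions[1][0])

    report = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outcome_counts": counts,
        "subset_size": n_sub,
        "channels": {},
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    trimmed = {o: subsets[o] for o in (Outcome.ADDUCT_42, Outcome.ADDUCT_64)}
    for outcome, trajs in trimmed.items():
        bond_id = ADDUCT_BOND[outcome]
        bond = ensemble.bond_definitions[bond_id]
        tss = ensemble.tss_bond_lengths[bond_id]
        seed = config.seed + 100 + bond_id
        profiles, windows = analyse_channel(
            trajs, bond, tss, scheme, config, seed, config.temperature)
        eprof = energy_profile(trajs, windows, bond, tss,
                               seed=seed, n_bootstrap=1000)
        roam = roaming_fraction(trajs, windows, bond, tss)

        label = outcome.value
        summary = {
            "extremum": _classify_extremum(profiles["augmented"]),
            "extremum_real_only": _classify_extremum(profiles["real_only"]),
            "trap_depth_kcal_mol": profiles["augmented"].trap_depth(),
            "barrier_height_kcal_mol": profiles["augmented"].barrier_height(),
            "trap_depth_real_only_kcal_mol":
                profiles["real_only"].trap_depth(),
            "n_trajectories": len(trajs),
        }
        report["channels"][label] = summary
        if out_dir:
            prov = (f"# entropath {__version__} config={config.config_hash()} "
                    f"seed={config.seed}\n")
            for name, prof in (("entropy", profiles["augmented"]),
                               ("entropy_real_only", profiles["real_only"])):
                path = out_dir / f"{name}_{label}.tsv"
                with path.open("w") as fh:
                    fh.write(prov)
                    _profile_frame(prof).to_csv(fh, sep="\t", index=False)
            for mname, mprof in profiles["moieties"].items():
                path = out_dir / f"entropy_moiety_{mname}_{label}.tsv"
                with path.open("w") as fh:
                    fh.write(prov)
                    _profile_frame(mprof).to_csv(fh, sep="\t", index=False)
            with (out_dir / f"energy_{label}.tsv").open("w") as fh:
                fh.write(prov)
                pd.DataFrame({
                    "center_A": eprof.centers,
                    "mean_energy_kcal_mol": eprof.mean_energy,
                    "se_kcal_mol": eprof.standard_errors,
                    "frames": eprof.counts,
                }).to_csv(fh, sep="\t", index=False)
            with (out_dir / f"roaming_{label}.tsv").open("w") as fh:
                fh.write(prov)
                pd.DataFrame({
                    "center_A": roam.centers,
                    "roaming_fraction": roam.fraction,
                    "frames": roam.counts,
                }).to_csv(fh, sep="\t", index=False)

    a = report["channels"][Outcome.ADDUCT_42.value]["extremum"]
    b = report["channels"][Outcome.ADDUCT_64.value]["extremum"]
    if (a.get("kind") == b.get("kind") and a.get("kind") != "none"
            and "minus_T_dS_kcal_mol" in a and "minus_T_dS_kcal_mol" in b):
        diff = abs(a["minus_T_dS_kcal_mol"] - b["minus_T_dS_kcal_mol"])
        comb = np.hypot(a["se_kcal_mol"], b["se_kcal_mol"])
        report["asymmetry"] = {
            "difference_kcal_mol": diff,
            "combined_se": float(comb),
            "significant": bool(diff > 2.0 * comb),
        }
        if not report["asymmetry"]["significant"]:
            report["asymmetry"]["note"] = "no significant asymmetry"
    if out_dir:
        (out_dir / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2))
    return report
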