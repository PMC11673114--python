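# entropath

Entropic path sampling for post-transition-state bifurcations (PTSB):
configurational-entropy and energy profiles along bifurcating reaction
pathways, computed from quasiclassical trajectory (QCT) ensembles.

## The problem

An ambimodal transition state is a single saddle point whose downhill
dynamics lead to two different products; selectivity is then decided not
by a second barrier but by the dynamics after the saddle.  Two factors
compete along each post-TS pathway: the energy gradient, and the
*configurational entropy* of the evolving structural ensemble.  A window
along the pathway where entropy rises (−TΔS dips) is an **entropic
trap** — a reservoir of long-lived, conformationally flexible
intermediates that roam and can reroute to the other product.  A window
where entropy falls (−TΔS climbs) is an **entropic barrier**, a
dynamical bottleneck.  Quantifying these features from trajectory
ensembles is what this package does.

## The method

Given an ensemble of QCTs launched from the ambimodal saddle:

1. **Trajectory stage** — trajectories are classified by which forming
   bond (bond 2 → "[4+2]-like" adduct, bond 3 → "[6+4]-like") first
   crosses the 1.700 Å bond-formation criterion; balanced random subsets
   (default 102 per adduct) are drawn for profiling.
2. **Featurization** — Cartesian frames are converted to the 3N−6
   connectivity-derived internal coordinates (N−1 bonds, N−2 angles,
   N−3 torsions), which removes external rototranslation, and normalized
   to [−1, 1].
3. **Densification** — a bidirectional GAN (paired generators
   G_X: Z→X, G_Z: X→Z with discriminators in both spaces and cyclic
   reconstruction losses α·MSE(x, G_X(G_Z(x))) + β·MSE(z, G_Z(G_X(z))),
   α = β = 10) learns the configuration distribution and emits
   statistically indistinguishable pseudo-configurations.
4. **Entropy profiling** — configurations are segmented into structural
   windows along Δr = r(forming bond) − r(TSS); windows below 25% of the
   largest population are discarded; per window the entropy over the
   3N−6 coordinates is estimated as

       S = Σᵢ S₁(i) − Σ_{(i,j)∈T*} I(i, j),

   the marginal histogram entropies minus the pairwise mutual
   information summed over the **maximum information spanning tree**
   (MIST), and reported as −TΔS (kcal/mol) relative to the first
   surviving window near the TS.
5. **Energy and roaming** — window-averaged potential energies (equal
   trajectory counts per adduct, first three time steps excluded) and
   the fraction of *roaming* frames (|d r/dt| ≤ 0.01 Å/fs) per window.
6. **Quasiharmonic comparator** — −TΔS profiles from projected
   vibrational wavenumbers with the quasiharmonic floor (modes below
   100 cm⁻¹ raised to 100 cm⁻¹), for contrast with the histogram method.

A fully tested synthetic stage (`entropath.toy_system`) provides the
ground truth: an analytic two-channel surface with a reactant minimum,
an ambimodal saddle, two product wells, a tunable low-gradient shelf
(an engineered entropic trap) and quasiclassical normal-mode sampling
with velocity-Verlet propagation at 1 fs.

## Worked example

```python
from entropath import RunConfig, run_pipeline, trap_study_spec

config = RunConfig(surface=trap_study_spec(0.45), n_trajectories=2000,
                   subset_size=150, seed=7, skip_bgan=True,
                   dr_range=(-0.6, 0.05), out_dir="runs/trap")
report = run_pipeline(config)
for channel, summary in report["channels"].items():
    print(channel, "trap depth:",
          round(summary["trap_depth_real_only_kcal_mol"], 2), "kcal/mol;",
          "strongest excursion:", summary["extremum_real_only"]["kind"],
          round(summary["extremum_real_only"]["minus_T_dS_kcal_mol"], 2),
          "kcal/mol at", round(summary["extremum_real_only"]["center_A"], 3), "A")
```

prints (seed 7):

```
adduct_42 trap depth: -1.18 kcal/mol; strongest excursion: trap -1.18 kcal/mol at -0.125 A
adduct_64 trap depth: -0.0 kcal/mol; strongest excursion: barrier 2.79 kcal/mol at -0.325 A
```

The channel carrying the engineered shelf (adduct_42) shows an entropic
trap of ≈ −1.2 kcal/mol just past the transition state, while the
unmodified channel (adduct_64) shows no trap at all — its profile only
climbs toward formation as the closing ring narrows the conformational
distribution (an entropic barrier).  Per-window tables
(`entropy_*.tsv`, `energy_*.tsv`, `roaming_*.tsv`) and a JSON report
with the trap/barrier summary are written to `runs/trap/`.

The same stages are available as a CLI:

```bash
entropath simulate --n 2000 --seed 7 --out runs/sim
entropath entropy-profile runs/sim --subset 102 --out runs/profiles
entropath vtst freqs.tsv --out vtst_profile.tsv
```

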