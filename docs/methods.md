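# Methods

This note records the models, estimators, numerical choices and known
limitations behind `entropath`.

## Configurational entropy of a structural window

The object of interest is the entropy of the *geometric* distribution of
an ensemble of molecular configurations — not an equilibrium
thermodynamic entropy.  Configurations are described by the 3N−6
internal coordinates induced by the bonding graph (N−1 bonds, N−2
angles, N−3 torsions, built from a breadth-first spanning tree with
Z-matrix-style references; a bond closing a ring is excluded from the
tree set and kept as an optional redundant column for generative-model
training).  Internal coordinates remove the six external
rototranslational degrees of freedom exactly.

Per structural window the entropy is estimated as

    S = Σᵢ S₁(i) − Σ_{(i,j)∈T*} I(i,j)            [k_B units]

where S₁ are marginal histogram entropies (plug-in estimate plus
ln(bin width), Miller–Madow bias corrected), I(i,j) = S₁(i)+S₁(j)−S₂(i,j)
are pairwise mutual informations from 2-D histograms (clipped at 0),
and T* is the maximum-weight spanning tree of the complete MI graph
(maximum information spanning tree, MIST).  For two coordinates this is
algebraically identical to the joint histogram entropy; for trees of
variables (e.g. Markov chains) it is exact in the infinite-sample limit;
in general it is an upper-bound-correcting truncation of the mutual
information expansion at pairwise order.

Numerical choices:

- **Bin edges are fixed per coordinate across windows** (pooled range),
  so that window *differences* ΔS are not contaminated by varying
  supports.  Bin count: Rice-like rule ⌈2·n^(1/3)⌉ on the smallest
  surviving window population, clamped to [8, 48]; configurable, and
  studies that compare conditions fix it (default 24 in the canned
  studies) so the estimator is identical across compared ensembles.
- **Miller–Madow correction** (+ (K−1)/2n per histogram) removes the
  leading small-sample bias; because window populations differ, the
  correction matters for cross-window comparability.
- **Torsions are recentred** before histogramming: each circular
  coordinate is rotated so its circular mean sits at 0 and re-wrapped to
  (−π, π].  Histogram entropy is branch-cut sensitive; a lobe straddling
  ±π would otherwise read as two lobes.  One global shift per coordinate
  leaves differential entropy unchanged.
- **Windows** are half-open uniform bins of width 0.05 Å on
  Δr = r(forming bond) − r(TSS), ordered from the TS side toward
  product; a value on an edge belongs to the upper bin.  Windows with
  population below 25% of the largest are discarded (the generative
  model under-samples the product-forming region; the rule also guards
  the real-only mode against noisy tails).  The profile reference is the
  first surviving window on the TS side, where −TΔS ≡ 0.  Windows with
  fewer than 50 members are dropped with a log record.
- **Profiling range**: the canned studies profile Δr ∈ [−0.6, +0.05] Å —
  from just above the TS toward product, matching the natural direction
  of a TS-initiated ensemble.  Reactant-ward windows (Δr > 0) are sparse
  and erratically populated; placing the reference there destabilizes
  the whole profile.  The segmentation itself accepts any range.
- **Uncertainty**: nonparametric bootstrap over trajectories (default 40
  resamples; generated pseudo-configurations are resampled i.i.d. since
  they carry no trajectory identity).  The energy profile uses 1000
  bootstrap resamples (means are cheap).
- Units: S internally in k_B (nats); −TΔS = −T·k_B·ΔS with
  k_B = 0.0019872 kcal/(mol·K), T = 298.15 K by default.

The Jacobian (sin θ) weight for bond angles is omitted: between-window
entropy *differences* largely cancel it, and the estimator is used only
for ΔS.  This is a known approximation, not an oversight.

Moiety decomposition restricts the estimator to the coordinate columns
whose atoms all lie inside the moiety; cross-moiety MI edges are
excluded by construction, so moiety entropies of independent moieties
add to the total.

## Bidirectional GAN densification

Two generator/discriminator pairs on the normalized ([−1, 1])
coordinate table: G_X maps standard-normal latents (dimension
min(3N−6, 16)) into coordinate space, G_Z maps coordinates to latents,
and sigmoid discriminators D_X, D_Z separate real from generated samples
in each space.  The adversarial objectives are least-squares on the
discriminator outputs (real → 1, generated → 0); generators additionally
minimize the cyclic reconstruction loss

    L_rec = α·MSE(x, G_X(G_Z(x))) + β·MSE(z, G_Z(G_X(z))),  α = β = 10,

which ties the two maps into an approximate bijection.  Networks are
small fully connected tanh MLPs (3×128 hidden by default; the canned
studies use 3×64) trained with Adam (lr 2·10⁻⁴, β₁ = 0.5, batch 64),
implemented directly on numpy arrays with hand-written backpropagation;
training is deterministic under a seed at a fixed thread count.  Tables
larger than 4096 rows are subsampled for training.  Generated samples
are explicitly tagged pseudo — they carry no energies or velocities and
therefore cannot enter energy or roaming statistics.

Note the deliberate tension in the β-cycle: it enforces bijectivity and
therefore *opposes* generator collapse; the degenerate-data collapse
behaviour is only recovered with β ≪ α.

## The synthetic reactive system

The generator emulates the statistical structure of QCT ensembles at an
ambimodal saddle without quantum chemistry.  Reactive surface in channel
coordinates (x, y):

    V = Eb[(y²−1)² + x²y + x⁴/4] + g·x − τ·exp(−((x−x_t)²+(y−y_t)²)/w²)

with reactant minimum (0, 1), index-1 ambimodal saddle (0, −1) whose
unstable mode points along ±x (the two channels), product wells at
(±1.57, −1.22).  The two forming distances are affine images of (x, y):
d₂ = 2.5 + (y+1) − 0.4x, d₃ = 2.5 + (y+1) + 0.4x Å, so the reactant has
long unformed bonds (3.5 Å) and the 1.700 Å formation criterion is
crossed just past each product basin entrance.  Atoms 1–2 carry the
shared first-formed bond d₁, harmonically tied to 1.6 + 0.5(y+1) Å, so
reactant recovery (recrossing) is detectable as d₁ > d₁(TSS) + 0.5 Å.
Three frame beads are attached by trilaterated harmonic distance
restraints (force constants 8/3/1.2 kcal/mol/Å², exactly satisfied at
the saddle so it remains a true stationary point).

Defaults (chosen once, as the study conditions): Eb = 2 kcal/mol,
bead mass 6 amu, N = 6 beads, T = 298.15 K, dt = 1 fs.  The light mass
puts thermal forming-bond velocities (σ ≈ 0.006 Å/fs) just under the
0.01 Å/fs roaming cutoff, so the roaming fraction has dynamic range:
fast descent reads ≈ 0.3–0.5, lingering reads ≈ 0.7–0.9.

**The engineered entropic trap** (`trap_study_spec`): the shelf Gaussian
(depth τ, width 0.5) is centred at (0.45, −1.0) — just past the saddle
on channel A — and the same Gaussian softens the frame force constants
by 1/(1 + κ·e) with κ = 2, inflating configurational variance where
trajectories dwell.  The linear asymmetry is set analytically to cancel
the Gaussian's pull at the saddle, g(τ) = 2τ·x_t/w²·exp(−x_t²/w²), which
pins the saddle at (0, −1) for every τ: the transition-state reference
ensemble is then identical across a trap-depth scan.  Shelf windows map
to Δr ∈ [−0.55, −0.30) Å under the bond map.

Two measured facts shape the ground-truth studies.  First, the entropic
trap is created by the *flexibility* (κ): the flexibility-only shelf
(τ = 0) traps deepest, and deepening the potential well erodes the
entropic signature strictly monotonically — the well converts entropic
trapping into energetic descent (window-resolved depth shrinks by
~0.1–0.25 kcal/mol per 0.45 kcal/mol of τ, reproducible to ±0.03 across
seeds).  The trap-depth scan therefore checks strict monotonicity with
this measured sign.  Second, committed-subset profiles confound the
shelf with flux selection — a deeper shelf starves its own channel of
committed trajectories, leaving the fast completers — so the scan pools
the full ensemble along each forming-bond coordinate
(`studies.surface_profile`); the channel comparison at the study point
and the symmetric null still use committed subsets as the main pipeline
does.

**Quasiclassical sampling**: mass-weighted Hessian by central finite
differences of the analytic gradient, rototranslation projected out;
each real mode receives (n + ½)hν with n geometrically
(Boltzmann-)sampled at T and a uniform random phase; the unstable mode
receives a thermal velocity (½kT·Z², Z ~ N(0,1)) with uniform random
sign.  Each initial condition is integrated both forward and backward by
velocity-Verlet; on this surface the unstable mode connects the two
product channels, so each time-directed half is kept as one TS-initiated
trajectory (the reactant connection appears as recrossing halves).

**Energy conservation**: velocity-Verlet conserves a shadow Hamiltonian;
the instantaneous total energy carries a bounded O(dt²) oscillation that
reaches a few 10⁻⁴ of the initial kinetic energy in anharmonic corners
at dt = 1 fs.  The integrator-quality figure is therefore the *secular*
drift — |least-squares slope| × run length — whose median is below
10⁻⁴·KE₀ on the default surface and falls 4× per dt halving (second
order).  Trajectories are excluded (with a count in the run manifest)
when the secular drift exceeds 10⁻³·KE₀ or any excursion exceeds 5% of
KE₀; on the default surface this removes ≈ 2–6%, rising to ≈ 10% at the
strongest shelf settings.

**What the synthetic ensembles do not emulate**: quantum-chemical
forces and realistic frequencies (modes here are 30–180 cm⁻¹), zero-point
leakage physics, tunnelling, many-mode molecules (12 internal
coordinates vs hundreds), solvent or enzyme environments.  Passing the
ground-truth tests shows the *pipeline* recovers engineered entropic
features from trajectory data of this statistical character; it does not
validate quantum-chemical energetics or any specific reaction's numbers.  The
full-scale analyses of real reactions additionally require externally
computed (e.g. DFT-level) trajectory ensembles as input.

## Energy and roaming profiles

Window-averaged potential energies use real frames only, the adduct
subsets trimmed to the minor-product count, the first three time steps
of each trajectory excluded (they carry the sampled zero-point-energy
artifact near the TS), the first surviving window as energy zero, and
bootstrap-over-trajectories standard errors.  Roaming uses the rate of
change of the *outcome-defining* forming bond, computed from velocities
projected on the bond unit vector (finite-difference fallback when
velocities are absent); a frame roams when |v| ≤ 0.01 Å/fs.  Both a
per-frame fraction (default) and a per-trajectory mode are implemented.

## Quasiharmonic comparator

Harmonic-oscillator entropies from projected wavenumbers,
S(ν̃) = R[(θ/T)/(e^{θ/T}−1) − ln(1−e^{−θ/T})], θ = hcν̃/k_B, with
wavenumbers below 100 cm⁻¹ raised to 100 cm⁻¹ and imaginary modes
dropped.  Mode correspondence across path points is by sorted-order
index after truncation to the smallest common count — a deterministic
stand-in for mode-following.  The comparator cannot represent
anharmonic multi-well torsions, which is precisely the contrast it is
meant to expose.

## Design decisions that were genuinely open

- The bond-map sign is chosen so forming bonds are *long* at the
  reactant (3.5 Å) and cross 1.700 Å on the product side; the channel
  separation q = 0.4 places formation just past the basin entrance,
  before the stiffest part of the well, keeping the 1 fs integrator
  within its drift budget.
- The drift flag is applied to the secular trend, not the bounded
  shadow-energy oscillation (see above); a 10⁻⁴ flag on the raw
  excursion would discard a third of the trajectories preferentially in
  the soft shelf region and bias exactly the statistics of interest.
- Moiety decomposition excludes cross-moiety MI edges
  (restriction-to-subset); with correlated moieties the decomposition is
  therefore not additive — by construction.
- The per-window bootstrap resamples whole trajectories, since frames
  within a trajectory are strongly autocorrelated; resampling frames
  would understate the error several-fold.

## Problem sizes of the canned studies

Ground-truth studies use 2000-trajectory ensembles with subsets of up to
300 per adduct and 40 bootstrap resamples; the generator-fidelity
benchmark trains on 1024 rows for 800 epochs and tests 5000 generated
samples; estimator oracles use 10⁵ samples.  These sizes give estimator
errors well inside the stated tolerances while keeping a full validation
run to a few CPU-minutes.
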