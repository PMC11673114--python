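"""Analytic bead model of an ambimodal reaction with two product channels.

The model emulates the statistical structure of quasiclassical trajectory
(QCT) ensembles launched from an ambimodal saddle point, without any
quantum chemistry.  A two-dimensional "reactive surface" in channel
coordinates (x, y),

    V(x, y) = Eb * [(y^2 - 1)^2 + x^2 y + x^4 / 4] + g * x
              - tau * exp(-((x - x_t)^2 + (y - y_t)^2) / w^2)

has a reactant minimum at (0, 1), an index-1 ambimodal saddle at (0, -1)
and two product wells at x != 0.  The channel coordinates are embedded in
a small bead "molecule": the two forming distances d2 = |r0 - r1| and
d3 = |r0 - r2| are affine images of (x, y),

    d2 = d_ts + p (y - y_ts) - q x,      d3 = d_ts + p (y - y_ts) + q x,

so positive x shortens d2 (channel A, the [4+2]-like adduct) and negative
x shortens d3 (channel B, the [6+4]-like adduct).  The remaining "frame"
beads are tied to the reactive triad by harmonic distance restraints whose
force constants are softened by 1/(1 + kappa * exp(-dist^2/w^2)) near the
shelf centre, providing a tunable ground-truth entropic trap: when
kappa > 0 the frame becomes floppier inside the shelf region, inflating
the configurational variance sampled there.

Initial conditions are drawn by quantum harmonic normal-mode sampling
(zero-point plus Boltzmann thermal energy per mode) and propagated with a
velocity-Verlet integrator at a 1 fs step, both forward and backward in
time, until a forming bond drops below the bond-formation criterion
(1.700 A) or the reactant basin is recovered.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .constants import (
    KB_KCAL,
    KCAL_MOL_TO_INTERNAL,
    KCAL_PER_WAVENUMBER,
    ROOM_T,
    wavenumber_from_eigenvalue,
)
from .trajectory_io import (
    BOND_FORMATION_CRITERION,
    Outcome,
    Trajectory,
    TrajectoryEnsemble,
    classify_outcome,
)

__all__ = [
    "ModelSurfaceSpec",
    "InitialCondition",
    "reactive_potential",
    "saddle_geometry",
    "saddle_normal_modes",
    "normal_mode_sample",
    "trap_study_spec",
    "propagate",
    "generate_ensemble",
]

_ACC = KCAL_MOL_TO_INTERNAL


@dataclass(frozen=True)
class ModelSurfaceSpec:
    """Parameters of the model surface and its bead embedding.

    Energies in kcal/mol, lengths in A, force constants in kcal/mol/A^2.
    """

    barrier_scale: float = 2.0             # Eb, kcal/mol
    asymmetry: float = 0.0                 # g, kcal/mol per unit x
    shelf_depth: float = 0.0               # tau
    shelf_center: tuple[float, float] = (0.45, -1.0)  # (x_t, y_t)
    shelf_width: float = 0.5               # w (dimensionless channel units)
    frame_mode_constants: tuple[float, ...] = (8.0, 3.0, 1.2)
    softening: float = 0.0                 # kappa
    bead_count: int = 6
    # affine bond map d2/d3(x, y); y_ts = -1 (the saddle)
    d_ts: float = 2.5
    p: float = 1.0
    q: float = 0.4
    y_ts: float = -1.0
    # shared first-formed bond d1 = |r1 - r2|, harmonically tied to y
    d1_ts: float = 1.6
    p1: float = 0.5
    k1: float = 8.0
    mass: float = 6.0                      # amu, light beads

    def __post_init__(self) -> None:
        if not (self.barrier_scale > 0):
            raise ValueError("barrier_scale must be > 0")
        if not (self.shelf_width > 0):
            raise ValueError("shelf_width must be > 0")
        if self.bead_count < 4:
            raise ValueError("bead_count must be >= 4 (3N-6 >= 6)")
        if self.p == 0 or self.q == 0:
            raise ValueError("bond map must be invertible (p, q != 0)")

    # -- bond map ---------------------------------------------------------
    def bonds_from_channel(self, x, y):
        """(x, y) -> (d2, d3)."""
        d2 = self.d_ts + self.p * (y - self.y_ts) - self.q * x
        d3 = self.d_ts + self.p * (y - self.y_ts) + self.q * x
        return d2, d3

    def channel_from_bonds(self, d2, d3):
        """(d2, d3) -> (x, y); inverse of :meth:`bonds_from_channel`."""
        x = (d3 - d2) / (2.0 * self.q)
        y = self.y_ts + (d2 + d3 - 2.0 * self.d_ts) / (2.0 * self.p)
        return x, y

    def d1_eq(self, y):
        return self.d1_ts + self.p1 * (y - self.y_ts)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSurfaceSpec":
        d = json.loads(text)
        for key in ("shelf_center", "frame_mode_constants"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def trap_study_spec(shelf_depth: float = 0.45) -> "ModelSurfaceSpec":
    """Study conditions with an entropic trap on channel A.

    The shelf Gaussian is centred just past the saddle so trajectories
    must climb out of it slowly (a low-gradient shelf rather than an
    accelerating well), and the frame softening (kappa = 2) peaks in the
    same region.  The linear asymmetry is set to cancel the Gaussian's
    pull at the saddle exactly, g = 2 tau x_t / w^2 * exp(-x_t^2 / w^2),
    which pins the saddle at (0, -1) for every ``shelf_depth`` (tau,
    kcal/mol): the transition-state reference ensemble is then identical
    across a trap-depth scan.
    """
    x_t, y_t = 0.45, -1.0
    w = 0.5
    g = 2.0 * shelf_depth * x_t / w**2 * math.exp(-(x_t**2) / w**2)
    return ModelSurfaceSpec(
        shelf_depth=shelf_depth,
        shelf_center=(x_t, y_t),
        shelf_width=w,
        softening=2.0,
        asymmetry=g,
    )


@dataclass
class InitialCondition:
    coordinates: np.ndarray   # (N, 3) A
    velocities: np.ndarray    # (N, 3) A/fs
    mode_energies: np.ndarray  # per sampled mode, kcal/mol
    seed: int


def reactive_potential(x, y, spec: ModelSurfaceSpec):
    """Reactive-surface energy V(x, y) in kcal/mol (array-friendly)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite channel coordinates")
    eb = spec.barrier_scale
    v = eb * ((y**2 - 1.0) ** 2 + x**2 * y + x**4 / 4.0) + spec.asymmetry * x
    if spec.shelf_depth != 0.0:
        xt, yt = spec.shelf_center
        w2 = spec.shelf_width**2
        v = v - spec.shelf_depth * np.exp(-(((x - xt) ** 2 + (y - yt) ** 2) / w2))
    return v if v.ndim else float(v)


def _reactive_gradient(x, y, spec: ModelSurfaceSpec):
    """(dV/dx, dV/dy) of the reactive surface."""
    eb = spec.barrier_scale
    gx = eb * (2.0 * x * y + x**3) + spec.asymmetry
    gy = eb * (4.0 * y * (y**2 - 1.0) + x**2)
    if spec.shelf_depth != 0.0:
        xt, yt = spec.shelf_center
        w2 = spec.shelf_width**2
        e = np.exp(-(((x - xt) ** 2 + (y - yt) ** 2) / w2))
        gx = gx + 2.0 * spec.shelf_depth * (x - xt) * e / w2
        gy = gy + 2.0 * spec.shelf_depth * (y - yt) * e / w2
    return gx, gy


def _softening_factor(x, y, spec: ModelSurfaceSpec):
    """s(x, y) scaling the frame force constants, and ds/dx, ds/dy."""
    if spec.softening == 0.0:
        one = np.ones_like(np.asarray(x, dtype=float))
        zero = np.zeros_like(one)
        return one, zero, zero
    xt, yt = spec.shelf_center
    w2 = spec.shelf_width**2
    e = np.exp(-(((x - xt) ** 2 + (y - yt) ** 2) / w2))
    denom = 1.0 + spec.softening * e
    s = 1.0 / denom
    ds_de = -spec.softening / denom**2
    dsx = ds_de * e * (-2.0 * (x - xt) / w2)
    dsy = ds_de * e * (-2.0 * (y - yt) / w2)
    return s, dsx, dsy


# ---------------------------------------------------------------------------
# topology: frame restraints
# ---------------------------------------------------------------------------


def _frame_anchor_plan(n: int) -> list[tuple[int, int, int, int]]:
    """For each frame bead i >= 3 return (i, anchor, ref_b, ref_c).

    The first three frame beads attach to reactive atoms 1, 2, 0 in turn
    (secondary references are the other two reactive atoms); further beads
    chain onto bead i-3.
    """
    plan: list[tuple[int, int, int, int]] = []
    cycle = (1, 2, 0)
    for i in range(3, n):
        if i < 6:
            a = cycle[i - 3]
            others = [j for j in (0, 1, 2) if j != a]
            plan.append((i, a, others[0], others[1]))
        else:
            a = i - 3
            prev = plan[i - 6]  # entry for bead a
            plan.append((i, a, prev[1], prev[2]))
    return plan


@dataclass(frozen=True)
class _Topology:
    """Derived, spec-dependent geometry data: restraint list and TS frame."""

    restraints: tuple[tuple[int, int, float, float], ...]  # (i, j, r0, k)
    saddle_coordinates: np.ndarray                         # (N, 3)
    saddle_channel: tuple[float, float]                    # (x*, y*)
    tss_bond_lengths: dict[int, float]                     # bond id -> A

    @property
    def connectivity(self) -> list[tuple[int, int]]:
        """Bonding graph: reactive triangle plus each bead's primary bond
        (restraints are stored in groups of three per frame bead, primary
        first)."""
        edges = [(0, 1), (0, 2), (1, 2)]
        for k in range(0, len(self.restraints), 3):
            i, j, _r0, _k = self.restraints[k]
            edges.append((min(i, j), max(i, j)))
        return edges


def _reactive_hessian_xy(x: float, y: float, spec: ModelSurfaceSpec):
    eb = spec.barrier_scale
    hxx = eb * (2.0 * y + 3.0 * x**2)
    hxy = eb * 2.0 * x
    hyy = eb * (12.0 * y**2 - 4.0)
    if spec.shelf_depth != 0.0:
        xt, yt = spec.shelf_center
        w2 = spec.shelf_width**2
        dx, dy = x - xt, y - yt
        e = math.exp(-((dx**2 + dy**2) / w2))
        c = 2.0 * spec.shelf_depth / w2
        hxx += c * e * (1.0 - 2.0 * dx**2 / w2)
        hyy += c * e * (1.0 - 2.0 * dy**2 / w2)
        hxy += -c * e * 2.0 * dx * dy / w2
    return np.array([[hxx, hxy], [hxy, hyy]])


def _locate_saddle_channel(spec: ModelSurfaceSpec) -> tuple[float, float]:
    """Index-1 stationary point of the reactive surface near (0, -1),
    polished to machine precision by Newton iteration."""
    z = np.array([0.0, -1.0])
    for _ in range(60):
        g = np.array(_reactive_gradient(z[0], z[1], spec), dtype=float)
        if np.max(np.abs(g)) < 1e-13:
            break
        z = z - np.linalg.solve(_reactive_hessian_xy(z[0], z[1], spec), g)
    else:
        raise RuntimeError("saddle search did not converge")
    return float(z[0]), float(z[1])


def build_topology(spec: ModelSurfaceSpec) -> _Topology:
    """Construct the saddle-point geometry and the frame restraint list.

    Frame beads are trilaterated from their anchor/reference atoms so every
    restraint is exactly satisfied at the saddle; the tertiary restraint
    target is set to the realized distance, which keeps the saddle an exact
    stationary point of the full potential.
    """
    n = spec.bead_count
    xs, ys = _locate_saddle_channel(spec)
    d2, d3 = spec.bonds_from_channel(xs, ys)
    d1 = spec.d1_eq(ys)

    coords = np.zeros((n, 3))
    coords[1] = (-d1 / 2.0, 0.0, 0.0)
    coords[2] = (+d1 / 2.0, 0.0, 0.0)
    # atom 0 at distance d2 from atom 1 and d3 from atom 2, in the xy-plane
    x0 = (d2**2 - d3**2) / (2.0 * d1)  # offset from midpoint along x
    h2 = d2**2 - (x0 + d1 / 2.0) ** 2
    if h2 <= 0:
        raise ValueError("degenerate reactive triangle at the saddle")
    coords[0] = (x0, math.sqrt(h2), 0.0)

    k_primary, k_secondary, k_tertiary = (tuple(spec.frame_mode_constants) + (
        spec.frame_mode_constants[-1],
    ) * 3)[:3]
    r_primary, r_secondary = 1.5, 2.4

    # Placement must commute with the channel mirror (x -> -x, atoms 1<->2)
    # so the symmetric surface has an exactly 1:1 product ratio: beads use
    # the global z axis (mirror-invariant) for their out-of-plane offset,
    # and a bead anchored on the mirror plane gets equal reference
    # distances and equal reference force constants to atoms 1 and 2.
    zhat = np.array([0.0, 0.0, 1.0])
    restraints: list[tuple[int, int, float, float]] = []
    for i, a, b, c in _frame_anchor_plan(n):
        pa, pb, pc = coords[a], coords[b], coords[c]
        on_mirror_plane = {b, c} == {1, 2}
        if on_mirror_plane:
            mid = 0.5 * (pb + pc)
            u = pa - mid
            u = u / np.linalg.norm(u)
            w = zhat - (zhat @ u) * u
            w = w / np.linalg.norm(w)
            pos = pa + r_primary * (0.5 * u + math.sqrt(0.75) * w)
            coords[i] = pos
            # realized targets (equal whenever the surface is symmetric)
            # with equal constants keep the restraint form mirror-covariant
            k_ref = 0.5 * (k_secondary + k_tertiary)
            restraints.append((i, a, r_primary, k_primary))
            restraints.append((i, b, float(np.linalg.norm(pos - pb)), k_ref))
            restraints.append((i, c, float(np.linalg.norm(pos - pc)), k_ref))
            continue
        u = pb - pa
        dab = np.linalg.norm(u)
        u = u / dab
        cosang = (r_primary**2 + dab**2 - r_secondary**2) / (2 * r_primary * dab)
        cosang = min(1.0, max(-1.0, cosang))
        sinang = math.sqrt(max(0.0, 1.0 - cosang**2))
        w = zhat - (zhat @ u) * u
        w = w / np.linalg.norm(w)
        pos = pa + r_primary * (cosang * u + sinang * w)
        coords[i] = pos
        restraints.append((i, a, float(np.linalg.norm(pos - pa)), k_primary))
        restraints.append((i, b, float(np.linalg.norm(pos - pb)), k_secondary))
        restraints.append((i, c, float(np.linalg.norm(pos - pc)), k_tertiary))

    tss = {1: float(d1), 2: float(d2), 3: float(d3)}
    return _Topology(tuple(restraints), coords, (xs, ys), tss)


# ---------------------------------------------------------------------------
# energies and forces
# ---------------------------------------------------------------------------


def _channel_of(coords: np.ndarray, spec: ModelSurfaceSpec):
    """Channel coordinates and forming distances for (..., N, 3) input."""
    r01 = coords[..., 0, :] - coords[..., 1, :]
    r02 = coords[..., 0, :] - coords[..., 2, :]
    d2 = np.linalg.norm(r01, axis=-1)
    d3 = np.linalg.norm(r02, axis=-1)
    x, y = spec.channel_from_bonds(d2, d3)
    return x, y, d2, d3, r01, r02


def potential_energy(coords: np.ndarray, spec: ModelSurfaceSpec,
                     topo: _Topology) -> np.ndarray:
    """Total potential (kcal/mol) for coordinates of shape (..., N, 3)."""
    v, _ = _potential_and_forces(coords, spec, topo, need_forces=False)
    return v


def _potential_and_forces(coords: np.ndarray, spec: ModelSurfaceSpec,
                          topo: _Topology, need_forces: bool = True):
    _prepare_topo_arrays(topo)
    coords = np.asarray(coords, dtype=float)
    x, y, d2, d3, r01, r02 = _channel_of(coords, spec)
    batch = x.shape

    v = np.asarray(reactive_potential(x, y, spec), dtype=float)

    # d1 bond restrained toward its y-dependent equilibrium
    r12 = coords[..., 1, :] - coords[..., 2, :]
    d1 = np.linalg.norm(r12, axis=-1)
    dev1 = d1 - spec.d1_eq(y)
    v = v + 0.5 * spec.k1 * dev1**2

    # frame restraints, softened near the shelf
    s, dsx, dsy = _softening_factor(x, y, spec)
    idx_i = topo._idx_i
    idx_j = topo._idx_j
    r0s = topo._r0
    ks = topo._k
    rij = coords[..., idx_i, :] - coords[..., idx_j, :]          # (..., M, 3)
    dij = np.linalg.norm(rij, axis=-1)                           # (..., M)
    dev = dij - r0s
    vframe_raw = 0.5 * np.sum(ks * dev**2, axis=-1)              # (...,)
    v = v + s * vframe_raw

    if not need_forces:
        return v, None

    grads = np.zeros_like(coords)

    # chain rule pieces for x, y as functions of d2, d3
    u01 = r01 / d2[..., None]
    u02 = r02 / d3[..., None]
    inv2q = 1.0 / (2.0 * spec.q)
    inv2p = 1.0 / (2.0 * spec.p)
    # dx/dr0 = -u01*inv2q + u02*inv2q ; dy/dr0 = (u01+u02)*inv2p ; etc.
    gx, gy = _reactive_gradient(x, y, spec)
    # add softening and d1-equilibrium couplings into gx, gy
    gx = gx + dsx * vframe_raw
    gy = gy + dsy * vframe_raw - spec.k1 * dev1 * spec.p1

    cx = gx[..., None] * inv2q
    cy = gy[..., None] * inv2p
    g0 = (-cx + cy) * u01 + (cx + cy) * u02
    g1 = (cx - cy) * u01
    g2 = (-cx - cy) * u02
    grads[..., 0, :] += g0
    grads[..., 1, :] += g1
    grads[..., 2, :] += g2

    # d1 restraint direct term
    u12 = r12 / d1[..., None]
    f1 = (spec.k1 * dev1)[..., None] * u12
    grads[..., 1, :] += f1
    grads[..., 2, :] -= f1

    # frame restraints (M is small: loop, avoiding duplicate-index pitfalls)
    uij = rij / dij[..., None]
    coef = (s[..., None] * ks * dev)[..., None] * uij            # (..., M, 3)
    for m in range(idx_i.size):
        grads[..., idx_i[m], :] += coef[..., m, :]
        grads[..., idx_j[m], :] -= coef[..., m, :]

    return v, grads


def _prepare_topo_arrays(topo: _Topology) -> None:
    if not hasattr(topo, "_idx_i"):
        arr = np.array([(i, j, r0, k) for i, j, r0, k in topo.restraints])
        object.__setattr__(topo, "_idx_i", arr[:, 0].astype(int))
        object.__setattr__(topo, "_idx_j", arr[:, 1].astype(int))
        object.__setattr__(topo, "_r0", arr[:, 2])
        object.__setattr__(topo, "_k", arr[:, 3])


def gradient(coords: np.ndarray, spec: ModelSurfaceSpec,
             topo: _Topology) -> np.ndarray:
    _prepare_topo_arrays(topo)
    _, g = _potential_and_forces(coords, spec, topo)
    return g


# ---------------------------------------------------------------------------
# normal-mode analysis and quasiclassical sampling
# ---------------------------------------------------------------------------


def saddle_geometry(spec: ModelSurfaceSpec) -> tuple[np.ndarray, _Topology]:
    """Saddle-point Cartesian geometry and the derived topology."""
    topo = build_topology(spec)
    _prepare_topo_arrays(topo)
    return topo.saddle_coordinates.copy(), topo


def _mass_weighted_hessian(coords: np.ndarray, spec: ModelSurfaceSpec,
                           topo: _Topology, h: float = 1e-5) -> np.ndarray:
    n3 = coords.size
    flat = coords.reshape(-1)
    hess = np.zeros((n3, n3))
    for k in range(n3):
        fp = flat.copy(); fp[k] += h
        fm = flat.copy(); fm[k] -= h
        gp = gradient(fp.reshape(coords.shape), spec, topo).reshape(-1)
        gm = gradient(fm.reshape(coords.shape), spec, topo).reshape(-1)
        hess[k] = (gp - gm) / (2.0 * h)
    hess = 0.5 * (hess + hess.T)
    return hess / spec.mass  # equal masses: mass-weighting is a scale


def _rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rototranslational directions (3N vectors)."""
    n = coords.shape[0]
    com = coords.mean(axis=0)
    rel = coords - com
    vecs = []
    for axis in range(3):
        t = np.zeros((n, 3)); t[:, axis] = 1.0
        vecs.append(t.reshape(-1))
    for axis in range(3):
        e = np.zeros(3); e[axis] = 1.0
        vecs.append(np.cross(rel, e).reshape(-1))
    basis = np.array(vecs).T
    qmat, _ = np.linalg.qr(basis)
    return qmat[:, :6]


def saddle_normal_modes(spec: ModelSurfaceSpec, topo: _Topology | None = None):
    """Vibrational analysis at the saddle.

    Returns (coords, eigenvalues, eigenvectors) with rototranslation
    projected out; eigenvalues in kcal/mol/A^2/amu, exactly one negative.
    """
    if topo is None:
        coords, topo = saddle_geometry(spec)
    else:
        coords = topo.saddle_coordinates.copy()
        _prepare_topo_arrays(topo)
    hess = _mass_weighted_hessian(coords, spec, topo)
    proj = _rigid_body_basis(coords)
    pmat = np.eye(hess.shape[0]) - proj @ proj.T
    hp = pmat @ hess @ pmat
    lam, vec = np.linalg.eigh(hp)
    # drop the 6 projected (near-zero) directions
    order = np.argsort(np.abs(lam))
    keep = np.sort(order[6:])
    lam, vec = lam[keep], vec[:, keep]
    n_neg = int(np.sum(lam < 0))
    if n_neg != 1:
        raise ValueError(
            f"saddle must have exactly 1 negative-curvature mode, found {n_neg}"
        )
    return coords, lam, vec


def normal_mode_sample(spec: ModelSurfaceSpec, temperature: float = ROOM_T,
                       seed: int = 0, modes=None) -> InitialCondition:
    """Quasiclassical initial condition at the ambimodal saddle.

    Every real mode i receives (n_i + 1/2) h nu_i with the quantum number
    n_i Boltzmann-sampled at ``temperature`` and a uniformly random phase
    splitting the energy between displacement and velocity.  The unstable
    mode receives a thermally sampled velocity with uniform random sign.
    """
    if modes is None:
        modes = saddle_normal_modes(spec)
    coords, lam, vec = modes
    rng = np.random.default_rng(seed)

    neg = int(np.argmin(lam))
    kt = KB_KCAL * temperature

    q_mw = np.zeros(lam.size)
    qdot_mw = np.zeros(lam.size)
    energies = np.zeros(lam.size)
    for i in range(lam.size):
        if i == neg:
            z = rng.standard_normal()
            e_trans = 0.5 * kt * z * z
            sign = 1.0 if rng.random() < 0.5 else -1.0
            qdot_mw[i] = sign * math.sqrt(2.0 * e_trans * _ACC)
            energies[i] = e_trans
            continue
        nu = wavenumber_from_eigenvalue(lam[i])          # cm^-1
        hnu = nu * KCAL_PER_WAVENUMBER                   # kcal/mol
        if temperature <= 0:
            n_i = 0
        else:
            ratio = math.exp(-hnu / kt)
            # geometric quantum-number sampling: P(n) = (1-r) r^n
            n_i = int(rng.geometric(1.0 - ratio) - 1)
        e_i = (n_i + 0.5) * hnu
        energies[i] = e_i
        amp = math.sqrt(2.0 * e_i / lam[i])              # A sqrt(amu)
        omega = math.sqrt(lam[i] * _ACC)                 # rad/fs
        phase = rng.uniform(0.0, 2.0 * math.pi)
        q_mw[i] = amp * math.cos(phase)
        qdot_mw[i] = -amp * omega * math.sin(phase)

    inv_sqrt_m = 1.0 / math.sqrt(spec.mass)
    dr = (vec @ q_mw).reshape(coords.shape) * inv_sqrt_m
    vel = (vec @ qdot_mw).reshape(coords.shape) * inv_sqrt_m
    return InitialCondition(coords + dr, vel, energies, seed)


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

DRIFT_TOLERANCE = 1e-3       # secular drift flag, relative to initial KE
BLOWUP_TOLERANCE = 0.05      # instantaneous shadow-energy excursion


def _kinetic_energy(vel: np.ndarray, mass: float) -> np.ndarray:
    return 0.5 * mass * np.sum(vel**2, axis=(-2, -1)) / _ACC


def secular_drift(total_energy: np.ndarray) -> float:
    """Secular (trend) component of the total-energy series, kcal/mol.

    A velocity-Verlet integrator conserves a shadow Hamiltonian, so the
    instantaneous total energy carries a bounded O(dt^2) oscillation; the
    integrator-quality figure is the linear trend accumulated over the
    run (|least-squares slope| x run length), the usual MD drift number.
    """
    e = np.asarray(total_energy, dtype=float)
    if e.size < 2:
        return 0.0
    t = np.arange(e.size, dtype=float)
    slope = np.polyfit(t, e, 1)[0]
    return float(abs(slope) * e.size)


def _propagate_batch(r0: np.ndarray, v0: np.ndarray, spec: ModelSurfaceSpec,
                     topo: _Topology, dt: float, max_steps: int,
                     criterion: float, reactant_delta: float):
    """Velocity-Verlet for a batch (B, N, 3); returns frame stacks and the
    per-trajectory termination index (inclusive)."""
    _prepare_topo_arrays(topo)
    r = r0.copy()
    v = v0.copy()
    vpot, g = _potential_and_forces(r, spec, topo)
    acc = -g / spec.mass * _ACC

    frames_r = [r.copy()]
    frames_v = [v.copy()]
    frames_e = [vpot.copy()]

    b = r.shape[0]
    end = np.full(b, max_steps, dtype=int)
    done = np.zeros(b, dtype=bool)
    d1_limit = topo.tss_bond_lengths[1] + reactant_delta

    for step in range(1, max_steps + 1):
        r = r + dt * v + 0.5 * dt * dt * acc
        vpot, g = _potential_and_forces(r, spec, topo)
        new_acc = -g / spec.mass * _ACC
        v = v + 0.5 * dt * (acc + new_acc)
        acc = new_acc
        frames_r.append(r.copy())
        frames_v.append(v.copy())
        frames_e.append(vpot.copy())

        d2 = np.linalg.norm(r[:, 0] - r[:, 1], axis=-1)
        d3 = np.linalg.norm(r[:, 0] - r[:, 2], axis=-1)
        d1 = np.linalg.norm(r[:, 1] - r[:, 2], axis=-1)
        formed = (d2 < criterion) | (d3 < criterion)
        reacted_back = (d1 > d1_limit) & (d2 > criterion) & (d3 > criterion)
        newly = (~done) & (formed | reacted_back)
        end[newly] = step
        done |= newly
        if done.all():
            break

    rr = np.stack(frames_r)   # (F, B, N, 3)
    vv = np.stack(frames_v)
    ee = np.stack(frames_e)
    end = np.minimum(end, rr.shape[0] - 1)
    return rr, vv, ee, end


def propagate(ic: InitialCondition, spec: ModelSurfaceSpec,
              topo: _Topology | None = None, dt: float = 1.0,
              max_steps: int = 3000, criterion: float = BOND_FORMATION_CRITERION,
              reactant_delta: float = 0.5) -> Trajectory:
    """Integrate one initial condition forward and backward in time.

    The returned trajectory runs from the backward terminus through the
    initial (saddle-region) frame to the forward terminus;
    ``ts_frame_index`` marks the initial frame.  Per-frame potential
    energies are relative to the saddle.  The trajectory is flagged
    (``energy_drift_exceeded``) when |E(t) - E(0)| exceeds
    ``DRIFT_TOLERANCE`` x the initial kinetic energy.
    """
    if topo is None:
        _, topo = saddle_geometry(spec)
    r0 = ic.coordinates[None]
    halves = []
    for sign in (-1.0, +1.0):
        v0 = sign * ic.velocities[None]
        rr, vv, ee, end = _propagate_batch(
            r0, v0, spec, topo, dt, max_steps, criterion, reactant_delta
        )
        k = int(end[0])
        halves.append((rr[: k + 1, 0], vv[: k + 1, 0], ee[: k + 1, 0]))

    (rb, vb, eb), (rf, vf, ef) = halves
    # backward half reversed in time; its velocities flip sign so that the
    # joined series is a single forward-in-time path
    coords = np.concatenate([rb[::-1], rf[1:]], axis=0)
    vels = np.concatenate([-vb[::-1], vf[1:]], axis=0)
    ener = np.concatenate([eb[::-1], ef[1:]], axis=0)
    times = np.arange(coords.shape[0], dtype=float) * dt

    e_tot = ener + _kinetic_energy(vels, spec.mass)
    ts_idx = rb.shape[0] - 1
    ke0 = float(_kinetic_energy(ic.velocities, spec.mass))
    drift = secular_drift(e_tot)
    excursion = float(np.max(np.abs(e_tot - e_tot[ts_idx])))
    flagged = bool(drift > DRIFT_TOLERANCE * max(ke0, 1e-12)
                   or excursion > BLOWUP_TOLERANCE * max(ke0, 1e-12))

    traj = Trajectory(
        coordinates=coords,
        velocities=vels,
        energies=ener,
        times=times,
        atom_labels=["C"] * spec.bead_count,
        ts_frame_index=ts_idx,
    )
    traj.energy_drift_exceeded = flagged
    traj.max_energy_drift = drift
    return traj


def generate_ensemble(spec: ModelSurfaceSpec, n_traj: int,
                      temperature: float = ROOM_T, seed: int = 0,
                      dt: float = 1.0, max_steps: int = 3000,
                      criterion: float = BOND_FORMATION_CRITERION,
                      reactant_delta: float = 0.5) -> TrajectoryEnsemble:
    """Ensemble of ``n_traj`` saddle-initiated trajectories.

    Each sampled initial condition is propagated in both time directions;
    on this surface the unstable mode connects the two product channels,
    so each time-directed half is kept as one TS-initiated trajectory.
    Trajectories whose energy drift exceeds the tolerance are excluded
    (recorded in ``ensemble.meta``).
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    coords0, topo = saddle_geometry(spec)
    modes = saddle_normal_modes(spec, topo)

    n_ic = (n_traj + 1) // 2
    rng = np.random.default_rng(seed)
    ic_seeds = rng.integers(0, 2**31 - 1, size=n_ic)
    r0 = np.empty((n_ic, spec.bead_count, 3))
    v0 = np.empty_like(r0)
    for i, s in enumerate(ic_seeds):
        ic = normal_mode_sample(spec, temperature, int(s), modes=modes)
        r0[i] = ic.coordinates
        v0[i] = ic.velocities

    bond_definitions = {1: (1, 2), 2: (0, 1), 3: (0, 2)}
    trajectories = []
    n_flagged = 0
    for sign in (+1.0, -1.0):
        rr, vv, ee, end = _propagate_batch(
            r0, sign * v0, spec, topo, dt, max_steps, criterion, reactant_delta
        )
        ke0 = _kinetic_energy(v0, spec.mass)
        for i in range(n_ic):
            k = int(end[i])
            c = rr[: k + 1, i]
            vel = vv[: k + 1, i]
            en = ee[: k + 1, i]
            e_tot = en + _kinetic_energy(vel, spec.mass)
            drift = secular_drift(e_tot)
            excursion = float(np.max(np.abs(e_tot - e_tot[0])))
            if (drift > DRIFT_TOLERANCE * max(ke0[i], 1e-12)
                    or excursion > BLOWUP_TOLERANCE * max(ke0[i], 1e-12)):
                n_flagged += 1
                continue
            traj = Trajectory(
                coordinates=c,
                velocities=vel,
                energies=en,
                times=np.arange(k + 1, dtype=float) * dt,
                atom_labels=["C"] * spec.bead_count,
                ts_frame_index=0,
            )
            trajectories.append(traj)
    trajectories = trajectories[:n_traj]

    ens = TrajectoryEnsemble(
        trajectories=trajectories,
        bond_definitions=bond_definitions,
        tss_bond_lengths=dict(topo.tss_bond_lengths),
    )
    for traj in ens.trajectories:
        traj.outcome = classify_outcome(
            traj, bond_definitions, ens.tss_bond_lengths,
            criterion=criterion, reactant_delta=reactant_delta,
        )
    ens.meta = {
        "connectivity": [list(e) for e in topo.connectivity],
        "seed": int(seed),
        "temperature": float(temperature),
        "n_requested": int(n_traj),
        "n_flagged_energy_drift": int(n_flagged),
        "outcome_counts": {
            o.value: sum(1 for t in ens.trajectories if t.outcome == o)
            for o in Outcome
        },
        "spec": asdict(spec),
    }
    return ens
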