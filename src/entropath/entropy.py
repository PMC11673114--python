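"""Configurational-entropy profiles along the forming-bond coordinate.

Configurations (real trajectory frames, optionally densified with
generated pseudo-configurations) are segmented into structural windows
along Delta r = r_bond - r_bond(TSS).  Sparse windows are removed by the
25%-of-largest-population rule.  Per window, the configurational entropy
over the 3N-6 internal coordinates is estimated as the sum of marginal
histogram entropies minus the pairwise mutual information summed over
the maximum information spanning tree (MIST):

    S  =  sum_i S1(i)  -  sum_{(i,j) in T*} I(i, j)

with fixed per-coordinate bin edges shared across windows so that window
differences are comparable, and Miller-Madow bias correction on every
plug-in entropy.  Profiles are reported as -T*dS in kcal/mol relative to
the first surviving window on the transition-state side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .constants import KB_KCAL, ROOM_T

__all__ = [
    "StructuralWindow",
    "EntropyProfile",
    "MoietyDefinition",
    "EstimatorConfig",
    "segment_windows",
    "truncate_sparse",
    "marginal_entropies",
    "pairwise_mutual_information",
    "mist_entropy",
    "entropy_profile",
    "moiety_profiles",
    "induced_columns",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StructuralWindow:
    """Half-open interval [lo, hi) on Delta r with its member configurations."""

    lo: float
    hi: float
    members: np.ndarray      # indices into the configuration table
    def __post_init__(self):
        if not self.hi > self.lo:
            raise ValueError("window interval must have hi > lo")

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def population(self) -> int:
        return int(self.members.size)


@dataclass
class EntropyProfile:
    centers: np.ndarray            # A
    entropy: np.ndarray            # k_B units
    minus_t_delta_s: np.ndarray    # kcal/mol
    standard_errors: np.ndarray    # kcal/mol, bootstrap
    reference_index: int
    temperature: float
    populations: np.ndarray
    pseudo_populations: np.ndarray | None = None

    def __post_init__(self):
        if abs(self.minus_t_delta_s[self.reference_index]) > 1e-12:
            raise ValueError("-T dS must vanish at the reference window")

    def trap_depth(self) -> float:
        """Most negative -T dS (kcal/mol); < 0 indicates an entropic trap."""
        return float(np.min(self.minus_t_delta_s))

    def barrier_height(self) -> float:
        """Most positive -T dS (kcal/mol); > 0 indicates an entropic barrier."""
        return float(np.max(self.minus_t_delta_s))

    def extremum(self) -> tuple[float, float, float]:
        """(center, -T dS, SE) of the largest-magnitude excursion."""
        k = int(np.argmax(np.abs(self.minus_t_delta_s)))
        return (float(self.centers[k]), float(self.minus_t_delta_s[k]),
                float(self.standard_errors[k]))


@dataclass(frozen=True)
class MoietyDefinition:
    name: str
    atoms: frozenset[int]

    @classmethod
    def of(cls, name: str, atoms: Sequence[int]) -> "MoietyDefinition":
        return cls(name, frozenset(int(a) for a in atoms))


@dataclass(frozen=True)
class EstimatorConfig:
    """Histogram-estimator knobs.

    ``bins`` None selects a Rice-like rule ceil(2 n^(1/3)) clamped to
    [8, 48] from the smallest surviving window population, shared by all
    windows for comparability.
    """

    bins: int | None = None
    min_population: int = 50
    n_bootstrap: int = 40
    bootstrap_seed: int = 0
    miller_madow: bool = True


def rice_bins(n: int, floor: int = 8, cap: int = 48) -> int:
    return int(min(max(math.ceil(2.0 * n ** (1.0 / 3.0)), floor), cap))


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def segment_windows(delta_r: np.ndarray, window_width: float = 0.05,
                    lo: float | None = None, hi: float | None = None,
                    ) -> list[StructuralWindow]:
    """Uniform half-open bins along Delta r, ordered from the TS side
    (largest Delta r) toward product formation (most negative).

    A value exactly on a bin edge belongs to the upper bin.  Windows
    outside [lo, hi) (when given) and empty windows are dropped.
    """
    delta_r = np.asarray(delta_r, dtype=float)
    if delta_r.size == 0:
        raise ValueError("no configurations to segment")
    if window_width <= 0:
        raise ValueError("window_width must be > 0")
    data_max = hi is None
    lo = float(np.min(delta_r)) if lo is None else lo
    hi = float(np.max(delta_r)) if hi is None else hi
    n_bins = max(int(np.ceil((hi - lo) / window_width)), 1)
    idx = np.floor((delta_r - lo) / window_width).astype(int)
    if data_max:
        # the observed maximum belongs to the top bin
        idx = np.where(delta_r == hi, np.minimum(idx, n_bins - 1), idx)
        in_range = (delta_r >= lo) & (delta_r <= hi)
    else:
        in_range = (delta_r >= lo) & (delta_r < hi)
    windows = []
    for b in range(n_bins - 1, -1, -1):   # TS side (high dr) first
        members = np.flatnonzero((idx == b) & in_range)
        if members.size:
            windows.append(StructuralWindow(lo + b * window_width,
                                            lo + (b + 1) * window_width,
                                            members))
    return windows


def truncate_sparse(windows: Sequence[StructuralWindow],
                    fraction: float = 0.25) -> list[StructuralWindow]:
    """Drop windows with population strictly below ``fraction`` x the
    largest window population (mitigates generative under-sampling near
    product formation); survivors keep their order."""
    if not windows:
        raise ValueError("no windows to truncate")
    largest = max(w.population for w in windows)
    cut = fraction * largest
    survivors = [w for w in windows if not w.population < cut]
    if not survivors:
        raise ValueError("truncation removed every window")
    return survivors


# ---------------------------------------------------------------------------
# histogram entropies
# ---------------------------------------------------------------------------


def _plugin_entropy(counts: np.ndarray, n: int, miller_madow: bool) -> float:
    """Discrete plug-in entropy (nats) with optional Miller-Madow bias
    correction; ``counts`` may be any shape."""
    p = counts[counts > 0] / n
    s = float(-np.sum(p * np.log(p)))
    if miller_madow:
        s += (p.size - 1) / (2.0 * n)
    return s


def fixed_edges(table: np.ndarray, bins: int) -> list[np.ndarray]:
    """Per-coordinate histogram edges spanning the pooled data range."""
    edges = []
    for c in range(table.shape[1]):
        lo = float(np.min(table[:, c]))
        hi = float(np.max(table[:, c]))
        if hi == lo:
            hi = lo + 1e-12
        edges.append(np.linspace(lo, hi, bins + 1))
    return edges


def _digitize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin indices in [0, B-1] for fixed edges (right-open bins; the last
    edge is inclusive so the maximum lands in the top bin)."""
    b = edges.size - 1
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, b - 1)


def marginal_entropies(table: np.ndarray, edges: Sequence[np.ndarray],
                       miller_madow: bool = True) -> np.ndarray:
    """Differential entropy per coordinate (k_B units = nats):
    S1 = -sum p ln p + ln(bin width), from fixed-edge histograms."""
    table = np.asarray(table, dtype=float)
    n, d = table.shape
    out = np.empty(d)
    for c in range(d):
        e = edges[c]
        counts = np.bincount(_digitize(table[:, c], e), minlength=e.size - 1)
        width = e[1] - e[0]
        out[c] = _plugin_entropy(counts, n, miller_madow) + np.log(width)
    return out


def pairwise_mutual_information(table: np.ndarray, edges: Sequence[np.ndarray],
                                pair: tuple[int, int],
                                miller_madow: bool = True) -> float:
    """I(a, b) = S1(a) + S1(b) - S2(a, b) >= 0 from 2-D fixed-edge
    histograms (the ln-width terms cancel)."""
    a, b = pair
    n = table.shape[0]
    ia = _digitize(table[:, a], edges[a])
    ib = _digitize(table[:, b], edges[b])
    ba = edges[a].size - 1
    bb = edges[b].size - 1
    s1a = _plugin_entropy(np.bincount(ia, minlength=ba), n, miller_madow)
    s1b = _plugin_entropy(np.bincount(ib, minlength=bb), n, miller_madow)
    s2 = _plugin_entropy(np.bincount(ia * bb + ib, minlength=ba * bb), n,
                         miller_madow)
    return max(s1a + s1b - s2, 0.0)


def _mist_from_digitized(dig: np.ndarray, n_bins: Sequence[int],
                         widths: Sequence[float], miller_madow: bool,
                         return_tree: bool = False):
    """MIST entropy from pre-digitized columns (rows x columns)."""
    n, d = dig.shape
    s1_disc = np.empty(d)
    for c in range(d):
        s1_disc[c] = _plugin_entropy(np.bincount(dig[:, c], minlength=n_bins[c]),
                                     n, miller_madow)
    s1 = s1_disc + np.log(widths)
    if d == 1:
        return (float(s1[0]), []) if return_tree else float(s1[0])

    graph = nx.Graph()
    graph.add_nodes_from(range(d))
    for a in range(d):
        for b in range(a + 1, d):
            s2 = _plugin_entropy(
                np.bincount(dig[:, a] * n_bins[b] + dig[:, b],
                            minlength=n_bins[a] * n_bins[b]),
                n, miller_madow)
            mi = max(s1_disc[a] + s1_disc[b] - s2, 0.0)
            graph.add_edge(a, b, weight=mi)
    tree = nx.maximum_spanning_tree(graph)
    mi_sum = sum(data["weight"] for _u, _v, data in tree.edges(data=True))
    s = float(np.sum(s1) - mi_sum)
    if return_tree:
        return s, sorted((min(u, v), max(u, v)) for u, v in tree.edges)
    return s


def mist_entropy(table: np.ndarray, edges: Sequence[np.ndarray],
                 miller_madow: bool = True) -> float:
    """Configurational entropy (k_B units) of one window table by the
    maximum-information-spanning-tree approximation."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 1:
        raise ValueError("need a (rows, >=1 columns) table")
    dig = np.column_stack([_digitize(table[:, c], edges[c])
                           for c in range(table.shape[1])])
    n_bins = [e.size - 1 for e in edges]
    widths = [e[1] - e[0] for e in edges]
    return _mist_from_digitized(dig, n_bins, widths, miller_madow)


# ---------------------------------------------------------------------------
# torsion recentring
# ---------------------------------------------------------------------------


def recenter_torsions(table: np.ndarray, torsion_mask: np.ndarray) -> np.ndarray:
    """Rotate each circular coordinate so its circular mean sits at 0 and
    re-wrap to (-pi, pi].

    Histogram entropy is branch-cut sensitive: a distribution straddling
    +/-pi would be split into two artificial lobes.  Rotating by the
    circular mean (one global shift per coordinate, applied before edges
    are fixed) removes the cut from the populated region without changing
    the underlying differential entropy.
    """
    table = np.array(table, dtype=float)
    for c in np.flatnonzero(torsion_mask):
        ang = table[:, c]
        mean = math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
        shifted = np.mod(ang - mean + np.pi, 2.0 * np.pi) - np.pi
        table[:, c] = np.where(shifted == -np.pi, np.pi, shifted)
    return table


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def _window_tables(windows, table):
    return [table[w.members] for w in windows]


def entropy_profile(windows: Sequence[StructuralWindow], table: np.ndarray,
                    temperature: float = ROOM_T,
                    config: EstimatorConfig = EstimatorConfig(),
                    traj_ids: np.ndarray | None = None,
                    pseudo_mask: np.ndarray | None = None,
                    columns: Sequence[int] | None = None,
                    torsion_mask: np.ndarray | None = None,
                    ) -> EntropyProfile:
    """-T dS profile over (already truncated) structural windows.

    ``table`` holds one row per configuration (real frames and pseudo
    configurations pooled); ``windows`` index into it.  The reference is
    the first window (TS side).  Bootstrap standard errors resample whole
    trajectories when ``traj_ids`` is given (pseudo rows, identified by
    ``pseudo_mask``, are then resampled independently), otherwise rows.

    Windows whose population is below ``config.min_population`` are
    dropped with a log record.
    """
    table = np.asarray(table, dtype=float)
    if columns is not None:
        col_idx = np.asarray(columns, dtype=int)
    else:
        col_idx = np.arange(table.shape[1])
    sub = table[:, col_idx]
    if torsion_mask is not None:
        sub = recenter_torsions(sub, np.asarray(torsion_mask)[col_idx])

    kept = [w for w in windows if w.population >= config.min_population]
    for w in windows:
        if w.population < config.min_population:
            log.info("window [%.3f, %.3f) dropped: population %d < %d",
                     w.lo, w.hi, w.population, config.min_population)
    if not kept:
        raise ValueError("no window meets the minimum population")

    bins = config.bins or rice_bins(min(w.population for w in kept))
    pooled = np.concatenate([sub[w.members] for w in kept], axis=0)
    edges = fixed_edges(pooled, bins)
    n_bins = [e.size - 1 for e in edges]
    widths = [e[1] - e[0] for e in edges]

    dig_all = np.column_stack([_digitize(sub[:, c], edges[c])
                               for c in range(sub.shape[1])])

    s = np.array([
        _mist_from_digitized(dig_all[w.members], n_bins, widths,
                             config.miller_madow)
        for w in kept
    ])
    ref = 0
    factor = temperature * KB_KCAL
    minus_tds = -factor * (s - s[ref])

    # bootstrap over trajectories (real rows) + iid pseudo rows
    rng = np.random.default_rng(config.bootstrap_seed)
    boot = np.zeros((config.n_bootstrap, len(kept)))
    if config.n_bootstrap:
        if traj_ids is not None:
            ids = np.asarray(traj_ids)
            pseudo = (np.asarray(pseudo_mask) if pseudo_mask is not None
                      else np.zeros(table.shape[0], dtype=bool))
            unique_ids = np.unique(ids[~pseudo])
        for b in range(config.n_bootstrap):
            if traj_ids is None:
                for k, w in enumerate(kept):
                    take = rng.integers(0, w.members.size, w.members.size)
                    boot[b, k] = _mist_from_digitized(
                        dig_all[w.members[take]], n_bins, widths,
                        config.miller_madow)
            else:
                chosen = rng.choice(unique_ids, unique_ids.size, replace=True)
                counts = {}
                for t in chosen:
                    counts[t] = counts.get(t, 0) + 1
                weight = np.array([counts.get(t, 0) for t in ids], dtype=int)
                for k, w in enumerate(kept):
                    m = w.members
                    wm = weight[m].copy()
                    if pseudo.any():
                        mp = pseudo[m]
                        n_pseudo = int(mp.sum())
                        if n_pseudo:
                            resampled = np.bincount(
                                rng.integers(0, n_pseudo, n_pseudo),
                                minlength=n_pseudo)
                            wm[mp] = resampled
                    rows = np.repeat(m, wm)
                    if rows.size < 2:
                        boot[b, k] = s[k]
                        continue
                    boot[b, k] = _mist_from_digitized(
                        dig_all[rows], n_bins, widths, config.miller_madow)
        delta = -factor * (boot - boot[:, [ref]])
        se = delta.std(axis=0, ddof=1)
    else:
        se = np.zeros(len(kept))

    pops = np.array([w.population for w in kept])
    pseudo_pops = None
    if pseudo_mask is not None:
        pm = np.asarray(pseudo_mask)
        pseudo_pops = np.array([int(pm[w.members].sum()) for w in kept])
    return EntropyProfile(
        centers=np.array([w.center for w in kept]),
        entropy=s,
        minus_t_delta_s=minus_tds,
        standard_errors=se,
        reference_index=ref,
        temperature=temperature,
        populations=pops,
        pseudo_populations=pseudo_pops,
    )


def induced_columns(scheme, moiety: MoietyDefinition,
                    redundant: bool = False) -> list[int]:
    """Scheme columns whose atoms all belong to the moiety."""
    cols = []
    groups = [scheme.bonds, scheme.angles, scheme.torsions]
    if redundant:
        groups.append(scheme.ring_closures)
    offset = 0
    for group in groups:
        for k, tup in enumerate(group):
            if all(a in moiety.atoms for a in tup):
                cols.append(offset + k)
        offset += len(group)
    return cols


def moiety_profiles(windows: Sequence[StructuralWindow], table: np.ndarray,
                    scheme, moieties: Sequence[MoietyDefinition],
                    temperature: float = ROOM_T,
                    config: EstimatorConfig = EstimatorConfig(),
                    torsion_mask: np.ndarray | None = None,
                    **kwargs) -> dict[str, EntropyProfile]:
    """Entropy profile restricted to each moiety's induced coordinate
    subset (cross-moiety correlations excluded)."""
    out = {}
    for moiety in moieties:
        cols = induced_columns(scheme, moiety)
        if not cols:
            raise ValueError(f"moiety {moiety.name!r} induces no coordinates")
        out[moiety.name] = entropy_profile(
            windows, table, temperature=temperature, config=config,
            columns=cols, torsion_mask=torsion_mask, **kwargs)
    return out
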