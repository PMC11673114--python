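"""Quasiharmonic vibrational-entropy comparator along a reaction path.

Given projected vibrational wavenumbers at points along a reaction path,
computes harmonic-oscillator entropies with the quasiharmonic correction
that raises wavenumbers below 100 cm^-1 to that floor (damping the
unbounded low-frequency limit of the harmonic entropy), and reports the
-T*dS profile relative to the first path point.  Imaginary (negative)
modes are dropped.  This is the harmonic counterpart against which the
histogram-based configurational-entropy profiles are compared; it cannot
represent anharmonic, multi-well torsional motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import KCAL_PER_WAVENUMBER, KB_KCAL, R_CAL, ROOM_T

__all__ = [
    "FrequencySeries",
    "raise_frequencies",
    "harmonic_entropy",
    "vtst_profile",
    "QH_FLOOR",
]

QH_FLOOR = 100.0  # cm^-1


@dataclass
class FrequencySeries:
    """Wavenumber lists (cm^-1) at points along a reaction path."""

    path: np.ndarray                     # path parameter values
    wavenumbers: list[np.ndarray]        # one array per point
    temperature: float = ROOM_T

    def __post_init__(self):
        if len(self.wavenumbers) != self.path.size:
            raise ValueError("one wavenumber list per path point required")

    @classmethod
    def from_table(cls, path: Path, temperature: float = ROOM_T
                   ) -> "FrequencySeries":
        """Read a tab-separated table: first column path parameter, the
        remaining columns wavenumbers (ragged rows allowed)."""
        params, freqs = [], []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            vals = [float(x) for x in line.split()]
            params.append(vals[0])
            freqs.append(np.array(vals[1:]))
        return cls(np.array(params), freqs, temperature)


def raise_frequencies(wavenumbers: Sequence[float], floor: float = QH_FLOOR
                      ) -> tuple[np.ndarray, int]:
    """Quasiharmonic floor: wavenumbers below ``floor`` are raised to it;
    imaginary modes (negative wavenumbers) are dropped.

    Returns (adjusted wavenumbers, number of dropped imaginary modes).
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    nu = np.asarray(wavenumbers, dtype=float)
    real = nu[nu >= 0]
    n_dropped = int(nu.size - real.size)
    return np.maximum(real, floor), n_dropped


def harmonic_entropy(wavenumber: float, temperature: float = ROOM_T) -> float:
    """Harmonic-oscillator vibrational entropy, cal/(mol K):

        S = R [ (theta/T) / (e^(theta/T) - 1) - ln(1 - e^(-theta/T)) ],
        theta = h c nu / k_B.
    """
    nu = np.asarray(wavenumber, dtype=float)
    if np.any(nu <= 0) or temperature <= 0:
        raise ValueError("wavenumber and temperature must be > 0")
    theta_over_t = nu * KCAL_PER_WAVENUMBER / (KB_KCAL * temperature)
    with np.errstate(over="ignore"):
        s = R_CAL * (theta_over_t / np.expm1(theta_over_t)
                     - np.log(-np.expm1(-theta_over_t)))
    return float(s) if s.ndim == 0 else s


def vtst_profile(series: FrequencySeries, temperature: float | None = None,
                 floor: float = QH_FLOOR):
    """-T dS (kcal/mol) along the path from quasiharmonic mode entropies.

    A uniform mode set is enforced across path points: after dropping
    imaginary modes, each point's wavenumbers are sorted and truncated to
    the smallest common mode count (sorted-order index matching).
    Returns (path, minus_t_delta_s, entropies in cal/(mol K)).
    """
    t = series.temperature if temperature is None else temperature
    cleaned = []
    for nu in series.wavenumbers:
        adj, _ = raise_frequencies(nu, floor)
        cleaned.append(np.sort(adj))
    n_modes = min(len(c) for c in cleaned)
    if n_modes == 0:
        raise ValueError("no real modes remain after dropping imaginaries")
    s = np.array([harmonic_entropy(c[:n_modes], t).sum() for c in cleaned])
    minus_tds = -t * (s - s[0]) / 1000.0   # cal -> kcal
    return series.path, minus_tds, s
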