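"""Bidirectional GAN for densifying internal-coordinate tables.

Two generator/discriminator pairs are trained jointly on normalized
internal coordinates: G_X maps latent vectors z ~ p(z) (standard normal)
to coordinate space X, G_Z maps coordinates back to latent space Z, and
the discriminators D_X / D_Z separate real from generated samples in
each space.  A cyclic reconstruction loss

    L_rec = alpha * MSE(x, G_X(G_Z(x))) + beta * MSE(z, G_Z(G_X(z)))

with alpha = beta = 10.0 ties the two maps into an approximate bijection,
so draws from the latent prior pushed through G_X are statistically
indistinguishable from the training configurations.

The adversarial objectives use the least-squares form on sigmoid
discriminator outputs (targets 1 for real, 0 for generated):

    L_DX = 1/2 E[(D_X(x) - 1)^2] + 1/2 E[D_X(G_X(z))^2]
    L_GX = 1/2 E[(D_X(G_X(z)) - 1)^2]            (and symmetrically in Z)

All networks are small fully connected tanh nets trained with Adam,
implemented directly on numpy arrays; training is deterministic under a
seed at fixed thread count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .internal_coordinates import Normalizer

__all__ = [
    "BGANConfig",
    "BGANModelBundle",
    "PseudoConfigurations",
    "adversarial_losses",
    "reconstruction_loss",
    "train",
    "generate",
    "indistinguishability_report",
    "save_bundle",
    "load_bundle",
]


@dataclass(frozen=True)
class BGANConfig:
    latent_dim: int | None = None        # None -> min(data_dim, 16)
    hidden: tuple[int, ...] = (128, 128, 128)
    learning_rate: float = 2e-4
    batch_size: int = 64
    epochs: int = 3000
    alpha: float = 10.0                  # x-cycle reconstruction weight
    beta: float = 10.0                   # z-cycle reconstruction weight
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.latent_dim is not None and self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "BGANConfig":
        d = json.loads(text)
        d["hidden"] = tuple(d["hidden"])
        return cls(**d)


# ---------------------------------------------------------------------------
# minimal fully connected network with manual backprop
# ---------------------------------------------------------------------------


class _MLP:
    """Tanh MLP; output linear (generators) or sigmoid (discriminators)."""

    def __init__(self, rng: np.random.Generator, sizes: Sequence[int],
                 sigmoid_out: bool = False):
        self.sigmoid_out = sigmoid_out
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = math.sqrt(2.0 / (fan_in + fan_out))
            self.weights.append(rng.normal(0.0, scale, (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._zero_grad()
        # Adam state
        self._m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._t = 0

    def _zero_grad(self):
        self.g_weights = [np.zeros_like(w) for w in self.weights]
        self.g_biases = [np.zeros_like(b) for b in self.biases]

    def forward(self, x: np.ndarray):
        acts = [x]
        h = x
        last = len(self.weights) - 1
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            if k < last:
                h = np.tanh(z)
            elif self.sigmoid_out:
                h = 1.0 / (1.0 + np.exp(-z))
            else:
                h = z
            acts.append(h)
        return h, acts

    def backward(self, acts, grad_out: np.ndarray, accumulate: bool = True):
        """Backpropagate d(loss)/d(output); returns d(loss)/d(input)."""
        last = len(self.weights) - 1
        grad = grad_out
        for k in range(last, -1, -1):
            h_out = acts[k + 1]
            if k < last:
                grad = grad * (1.0 - h_out**2)
            elif self.sigmoid_out:
                grad = grad * h_out * (1.0 - h_out)
            if accumulate:
                self.g_weights[k] += acts[k].T @ grad
                self.g_biases[k] += grad.sum(axis=0)
            grad = grad @ self.weights[k].T
        return grad

    def adam_step(self, lr: float, beta1: float = 0.5, beta2: float = 0.999,
                  eps: float = 1e-8):
        self._t += 1
        params = self.weights + self.biases
        grads = self.g_weights + self.g_biases
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**self._t)
            vhat = v / (1 - beta2**self._t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        self._zero_grad()

    def state(self):
        return {"weights": [w.copy() for w in self.weights],
                "biases": [b.copy() for b in self.biases],
                "sigmoid_out": self.sigmoid_out}


@dataclass
class BGANModelBundle:
    g_x: _MLP                      # latent -> coordinates (decoder)
    g_z: _MLP                      # coordinates -> latent (encoder)
    d_x: _MLP                      # discriminator on X
    d_z: _MLP                      # discriminator on Z
    config: BGANConfig
    normalizer: Normalizer | None
    loss_history: pd.DataFrame
    data_dim: int
    latent_dim: int


@dataclass
class PseudoConfigurations:
    """Generated configurations; tagged so they are never silently mixed
    with real frames (they carry no energies or velocities)."""

    normalized: np.ndarray
    values: np.ndarray | None      # de-normalized, if a normalizer exists
    pseudo: bool = True


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _ls(real_out, fake_out):
    """Least-squares discriminator loss: real -> 1, fake -> 0."""
    return 0.5 * float(np.mean((real_out - 1.0) ** 2)) \
        + 0.5 * float(np.mean(fake_out**2))


def adversarial_losses(batch_x: np.ndarray, batch_z: np.ndarray,
                       bundle: BGANModelBundle) -> dict[str, float]:
    """The four adversarial objective values at the current parameters."""
    fake_x, _ = bundle.g_x.forward(batch_z)
    fake_z, _ = bundle.g_z.forward(batch_x)
    dx_real, _ = bundle.d_x.forward(batch_x)
    dx_fake, _ = bundle.d_x.forward(fake_x)
    dz_real, _ = bundle.d_z.forward(batch_z)
    dz_fake, _ = bundle.d_z.forward(fake_z)
    losses = {
        "d_x": _ls(dx_real, dx_fake),
        "d_z": _ls(dz_real, dz_fake),
        "g_x": 0.5 * float(np.mean((dx_fake - 1.0) ** 2)),
        "g_z": 0.5 * float(np.mean((dz_fake - 1.0) ** 2)),
    }
    if not all(np.isfinite(v) for v in losses.values()):
        raise FloatingPointError(f"non-finite adversarial loss: {losses}")
    return losses


def reconstruction_loss(batch_x: np.ndarray, batch_z: np.ndarray,
                        bundle: BGANModelBundle, alpha: float = 10.0,
                        beta: float = 10.0) -> float:
    """alpha * MSE(x, G_X(G_Z(x))) + beta * MSE(z, G_Z(G_X(z)))."""
    zx, _ = bundle.g_z.forward(batch_x)
    xzx, _ = bundle.g_x.forward(zx)
    xz, _ = bundle.g_x.forward(batch_z)
    zxz, _ = bundle.g_z.forward(xz)
    return alpha * float(np.mean((batch_x - xzx) ** 2)) \
        + beta * float(np.mean((batch_z - zxz) ** 2))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

DIVERGENCE_LIMIT = 1e6


def train(table: np.ndarray, config: BGANConfig = BGANConfig(),
          normalizer: Normalizer | None = None) -> BGANModelBundle:
    """Train the four networks on a normalized (rows x columns) table.

    Each epoch alternates a discriminator update and a generator update
    (adversarial + cyclic reconstruction losses) per minibatch; the
    returned bundle records per-epoch mean losses.  Deterministic under
    ``config.seed`` at a fixed thread count.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("need a 2-D training table with >= 2 rows")
    n, d = table.shape
    latent = config.latent_dim or min(d, 16)
    rng = np.random.default_rng(config.seed)

    hid = list(config.hidden)
    bundle = BGANModelBundle(
        g_x=_MLP(rng, [latent] + hid + [d]),
        g_z=_MLP(rng, [d] + hid + [latent]),
        d_x=_MLP(rng, [d] + hid + [1], sigmoid_out=True),
        d_z=_MLP(rng, [latent] + hid + [1], sigmoid_out=True),
        config=config,
        normalizer=normalizer,
        loss_history=pd.DataFrame(),
        data_dim=d,
        latent_dim=latent,
    )
    lr = config.learning_rate
    bs = min(config.batch_size, n)
    history = {k: [] for k in ("d_x", "d_z", "g_x", "g_z", "reconstruction")}

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep = {k: 0.0 for k in history}
        n_batches = 0
        for start in range(0, n, bs):
            xb = table[order[start:start + bs]]
            b = xb.shape[0]
            zb = rng.standard_normal((b, latent))

            # --- discriminator update (generators fixed) ---------------
            fake_x, _ = bundle.g_x.forward(zb)
            fake_z, _ = bundle.g_z.forward(xb)
            dxr, c_dxr = bundle.d_x.forward(xb)
            dxf, c_dxf = bundle.d_x.forward(fake_x)
            dzr, c_dzr = bundle.d_z.forward(zb)
            dzf, c_dzf = bundle.d_z.forward(fake_z)
            bundle.d_x.backward(c_dxr, (dxr - 1.0) / b)
            bundle.d_x.backward(c_dxf, dxf / b)
            bundle.d_z.backward(c_dzr, (dzr - 1.0) / b)
            bundle.d_z.backward(c_dzf, dzf / b)
            loss_dx = _ls(dxr, dxf)
            loss_dz = _ls(dzr, dzf)
            bundle.d_x.adam_step(lr)
            bundle.d_z.adam_step(lr)

            # --- generator update (discriminators fixed) ---------------
            fake_x, c_gx = bundle.g_x.forward(zb)
            fake_z, c_gz = bundle.g_z.forward(xb)
            dxf, c_dxf = bundle.d_x.forward(fake_x)
            dzf, c_dzf = bundle.d_z.forward(fake_z)
            # adversarial terms
            g_fake_x = bundle.d_x.backward(c_dxf, (dxf - 1.0) / b,
                                           accumulate=False)
            g_fake_z = bundle.d_z.backward(c_dzf, (dzf - 1.0) / b,
                                           accumulate=False)
            # cycles: x -> z -> x and z -> x -> z (reuse forward caches)
            zx, c_zx = bundle.g_z.forward(xb)
            xzx, c_xzx = bundle.g_x.forward(zx)
            zxz, c_zxz = bundle.g_z.forward(fake_x)
            g_xzx = 2.0 * config.alpha * (xzx - xb) / xzx.size
            g_zxz = 2.0 * config.beta * (zxz - zb) / zxz.size
            # backprop generator graphs
            bundle.g_x.backward(c_gx, g_fake_x)              # adversarial G_X
            bundle.g_z.backward(c_gz, g_fake_z)              # adversarial G_Z
            grad_zx = bundle.g_x.backward(c_xzx, g_xzx)      # alpha cycle
            bundle.g_z.backward(c_zx, grad_zx)
            grad_fx = bundle.g_z.backward(c_zxz, g_zxz)      # beta cycle
            bundle.g_x.backward(c_gx, grad_fx)
            loss_gx = 0.5 * float(np.mean((dxf - 1.0) ** 2))
            loss_gz = 0.5 * float(np.mean((dzf - 1.0) ** 2))
            loss_rec = config.alpha * float(np.mean((xb - xzx) ** 2)) \
                + config.beta * float(np.mean((zb - zxz) ** 2))
            bundle.g_x.adam_step(lr)
            bundle.g_z.adam_step(lr)

            for key, val in (("d_x", loss_dx), ("d_z", loss_dz),
                             ("g_x", loss_gx), ("g_z", loss_gz),
                             ("reconstruction", loss_rec)):
                if not np.isfinite(val) or val > DIVERGENCE_LIMIT:
                    bundle.loss_history = pd.DataFrame(history)
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}: {key}={val}")
                ep[key] += val
            n_batches += 1
        for key in history:
            history[key].append(ep[key] / n_batches)

    bundle.loss_history = pd.DataFrame(history)
    return bundle


def generate(bundle: BGANModelBundle, n: int, seed: int = 0,
             denormalize: bool = True) -> PseudoConfigurations:
    """Draw n pseudo-configurations from the latent prior through G_X."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((max(n, 0), bundle.latent_dim))
    x, _ = bundle.g_x.forward(z)
    values = None
    if denormalize and bundle.normalizer is not None:
        values = bundle.normalizer.invert(x)
    return PseudoConfigurations(normalized=x, values=values)


def indistinguishability_report(real: np.ndarray, generated: np.ndarray,
                                alpha_level: float = 0.01,
                                column_labels: Sequence[str] | None = None,
                                ) -> pd.DataFrame:
    """Per-coordinate two-sample comparison of real vs generated tables.

    Columns: KS statistic and p-value, mean and variance ratios, and a
    pass flag (KS statistic below its large-sample critical value at
    ``alpha_level``)."""
    real = np.asarray(real, dtype=float)
    generated = np.asarray(generated, dtype=float)
    if real.shape[1] != generated.shape[1]:
        raise ValueError("tables must share the column schema")
    n1, n2 = real.shape[0], generated.shape[0]
    c_alpha = math.sqrt(-0.5 * math.log(alpha_level / 2.0))
    critical = c_alpha * math.sqrt((n1 + n2) / (n1 * n2))
    rows = []
    for c in range(real.shape[1]):
        ks = stats.ks_2samp(real[:, c], generated[:, c])
        r_var = np.var(real[:, c])
        g_var = np.var(generated[:, c])
        rows.append({
            "coordinate": (column_labels[c] if column_labels is not None
                           else f"col_{c}"),
            "ks_statistic": ks.statistic,
            "ks_pvalue": ks.pvalue,
            "mean_ratio": (np.mean(generated[:, c]) /
                           np.mean(real[:, c])) if np.mean(real[:, c]) != 0 else np.nan,
            "variance_ratio": g_var / r_var if r_var > 0 else np.nan,
            "passes": bool(ks.statistic < critical),
        })
    df = pd.DataFrame(rows)
    df.attrs["critical_value"] = critical
    df.attrs["pass_rate"] = float(df["passes"].mean())
    return df


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_bundle(bundle: BGANModelBundle, path: Path) -> None:
    """Single-archive serialization: weights + config + normalization."""
    arrays = {}
    for name, net in (("g_x", bundle.g_x), ("g_z", bundle.g_z),
                      ("d_x", bundle.d_x), ("d_z", bundle.d_z)):
        for k, w in enumerate(net.weights):
            arrays[f"{name}_w{k}"] = w
        for k, b in enumerate(net.biases):
            arrays[f"{name}_b{k}"] = b
    meta = {
        "config": bundle.config.to_json(),
        "normalizer": (bundle.normalizer.to_json()
                       if bundle.normalizer is not None else None),
        "data_dim": bundle.data_dim,
        "latent_dim": bundle.latent_dim,
        "n_layers": len(bundle.g_x.weights),
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    arrays["loss_history"] = bundle.loss_history.to_numpy()
    arrays["loss_columns"] = np.array(list(bundle.loss_history.columns),
                                      dtype="U32")
    np.savez(path, **arrays)


def load_bundle(path: Path) -> BGANModelBundle:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        config = BGANConfig.from_json(meta["config"])
        normalizer = (Normalizer.from_json(meta["normalizer"])
                      if meta["normalizer"] else None)
        rng = np.random.default_rng(0)
        d, latent = meta["data_dim"], meta["latent_dim"]
        hid = list(config.hidden)
        nets = {
            "g_x": _MLP(rng, [latent] + hid + [d]),
            "g_z": _MLP(rng, [d] + hid + [latent]),
            "d_x": _MLP(rng, [d] + hid + [1], sigmoid_out=True),
            "d_z": _MLP(rng, [latent] + hid + [1], sigmoid_out=True),
        }
        for name, net in nets.items():
            net.weights = [npz[f"{name}_w{k}"] for k in range(len(net.weights))]
            net.biases = [npz[f"{name}_b{k}"] for k in range(len(net.biases))]
        history = pd.DataFrame(npz["loss_history"],
                               columns=list(npz["loss_columns"]))
    return BGANModelBundle(nets["g_x"], nets["g_z"], nets["d_x"], nets["d_z"],
                           config, normalizer, history, d, latent)
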