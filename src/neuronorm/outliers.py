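"""Normative outlier model: adversarial autoencoder, reconstruction errors,
and Outlier Index Scores.

The normative model is an adversarial autoencoder (AAE): an autoencoder whose
latent code is pushed, by a discriminator playing a minimax game against the
encoder, toward a standard Gaussian prior. Trained on healthy-control
morphometry only, it reconstructs in-norm profiles accurately and out-of-norm
profiles poorly, so the squared reconstruction error acts as a deviation
score.

Errors are summarized per region and overall (mean over regions), then
robust-scaled against the training distribution: subtract the training
median, divide by the training interquartile range. The result — the Outlier
Index Score (OIS) — reads as "number of training IQRs away from the training
median" and is banded into Within the norm (< 0.26), Low (>= 0.26),
Medium (>= 1.1) and High (>= 2.3).

The networks are small fully-connected stacks implemented directly in numpy
(manual gradients, Adam), which keeps training deterministic, single-threaded
and fast at this feature count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

CATEGORY_NAMES = ("Within the norm", "Low", "Medium", "High")
DEFAULT_CUTOFFS = (0.26, 1.1, 2.3)


# ---------------------------------------------------------------------------
# minimal MLP machinery

def _leaky(x, a=0.2):
    return np.where(x > 0, x, a * x)


def _leaky_grad(x, a=0.2):
    return np.where(x > 0, 1.0, a)


class _MLP:
    """Fully-connected stack, leaky-ReLU hidden units, linear output."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def params(self):
        return self.W + self.b

    def forward(self, x):
        acts, pres = [x], []
        h = x
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            pre = h @ w + b
            pres.append(pre)
            h = pre if i == len(self.W) - 1 else _leaky(pre)
            acts.append(h)
        return h, (acts, pres)

    def backward(self, grad_out, cache):
        """Return (param grads aligned with params(), grad wrt input)."""
        acts, pres = cache
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        g = grad_out
        for i in reversed(range(len(self.W))):
            dpre = g if i == len(self.W) - 1 else g * _leaky_grad(pres[i])
            gW[i] = acts[i].T @ dpre
            gb[i] = dpre.sum(axis=0)
            g = dpre @ self.W[i].T
        return gW + gb, g


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


# ---------------------------------------------------------------------------
# configuration and model containers

@dataclass
class AAEConfig:
    """Training configuration for the adversarial autoencoder."""

    latent_dim: int = 20
    encoder_hidden: tuple[int, ...] = (100, 50)
    discriminator_hidden: tuple[int, ...] = (50, 25)
    epochs: int = 200
    batch_size: int = 64
    lr_reconstruction: float = 1e-3
    lr_adversarial: float = 1e-3     # discriminator
    lr_generator: float = 5e-4       # encoder's adversarial update
    disc_steps: int = 5              # discriminator updates per minibatch
    val_fraction: float = 0.1
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class RobustScaler:
    """Per-feature (x - median) / IQR scaling, quantiles by linear interpolation."""

    center: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "RobustScaler":
        x = np.asarray(x, dtype=float)
        center = np.median(x, axis=0)
        q1, q3 = np.percentile(x, [25, 75], axis=0)
        scale = q3 - q1
        if (scale <= 0).any():
            j = int(np.argmax(scale <= 0))
            raise ValueError(f"feature {j} has zero IQR; cannot robust-scale")
        return cls(center, scale)

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.center) / self.scale


@dataclass
class AAEModel:
    """Fitted normative network plus the input scaler it was trained with."""

    scaler: RobustScaler
    encoder: _MLP
    decoder: _MLP
    discriminator: _MLP
    config: AAEConfig
    loss_history: dict = field(default_factory=dict)

    def encode(self, features: np.ndarray) -> np.ndarray:
        z, _ = self.encoder.forward(self.scaler.transform(features))
        return z

    def reconstruct_scaled(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (scaled input, reconstruction in scaled space)."""
        xs = self.scaler.transform(features)
        z, _ = self.encoder.forward(xs)
        xhat, _ = self.decoder.forward(z)
        return xs, xhat


def train_aae(train_features: np.ndarray, config: AAEConfig | None = None) -> AAEModel:
    """Train the adversarial autoencoder on healthy-control features.

    Each minibatch runs three updates: (1) encoder+decoder on the mean squared
    reconstruction error; (2) discriminator on a cross-entropy distinguishing
    Gaussian prior draws from encoded batches; (3) encoder on the generator
    objective of fooling the discriminator. Training stops early when the
    validation reconstruction error stops improving (patience in epochs); the
    best-epoch parameters are kept. Fully seeded: same data and config give
    identical models.
    """
    config = config or AAEConfig()
    x = np.asarray(train_features, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("training features must be finite")
    if len(x) < config.batch_size:
        raise ValueError(f"need at least batch_size={config.batch_size} rows, got {len(x)}")
    rng = np.random.default_rng(config.seed)
    scaler = RobustScaler.fit(x)
    xs = scaler.transform(x)
    n, k = xs.shape

    n_val = max(1, int(round(config.val_fraction * n))) if config.val_fraction > 0 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    x_tr, x_val = xs[tr_idx], xs[val_idx]

    lat = config.latent_dim
    enc = _MLP([k, *config.encoder_hidden, lat], rng)
    dec = _MLP([lat, *reversed(config.encoder_hidden), k], rng)
    disc = _MLP([lat, *config.discriminator_hidden, 1], rng)
    opt_ae = _Adam(enc.params() + dec.params(), config.lr_reconstruction)
    opt_disc = _Adam(disc.params(), config.lr_adversarial)
    opt_gen = _Adam(enc.params(), config.lr_generator)

    history = {"reconstruction": [], "discriminator": [], "generator": [],
               "validation": []}
    best_val, best_state, stale = np.inf, None, 0

    def snapshot():
        return [p.copy() for p in enc.params() + dec.params() + disc.params()]

    def restore(state):
        for p, s in zip(enc.params() + dec.params() + disc.params(), state):
            p[...] = s

    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        ep_rec, ep_disc, ep_gen, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, len(x_tr) - config.batch_size + 1, config.batch_size):
            xb = x_tr[order[start:start + config.batch_size]]
            bsz = len(xb)

            # --- reconstruction: update encoder + decoder
            z, enc_cache = enc.forward(xb)
            xhat, dec_cache = dec.forward(z)
            rec_loss = ((xhat - xb) ** 2).mean()
            g_xhat = 2.0 * (xhat - xb) / xhat.size
            dec_grads, g_z = dec.backward(g_xhat, dec_cache)
            enc_grads, _ = enc.backward(g_z, enc_cache)
            opt_ae.step(enc_grads + dec_grads)

            # --- discriminator: prior draws vs (detached) encodings.
            # Several updates per minibatch keep it tracking the moving
            # encoder; a lagging discriminator lets the latent drift.
            z_fake, _ = enc.forward(xb)
            for _ in range(config.disc_steps):
                z_real = rng.standard_normal((bsz, lat))
                logits_r, cache_r = disc.forward(z_real)
                logits_f, cache_f = disc.forward(z_fake)
                d_loss = (np.logaddexp(0, -logits_r).mean()
                          + np.logaddexp(0, logits_f).mean())
                g_r = (_sigmoid(logits_r) - 1.0) / bsz
                g_f = _sigmoid(logits_f) / bsz
                grads_r, _ = disc.backward(g_r, cache_r)
                grads_f, _ = disc.backward(g_f, cache_f)
                opt_disc.step([a + b for a, b in zip(grads_r, grads_f)])

            # --- generator: encoder fools the (frozen) discriminator
            z, enc_cache = enc.forward(xb)
            logits, cache = disc.forward(z)
            g_loss = np.logaddexp(0, -logits).mean()
            g_logits = (_sigmoid(logits) - 1.0) / bsz
            _, g_z = disc.backward(g_logits, cache)
            enc_grads, _ = enc.backward(g_z, enc_cache)
            opt_gen.step(enc_grads)

            if not (np.isfinite(rec_loss) and np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (rec={rec_loss}, "
                    f"disc={d_loss}, gen={g_loss}); lower the learning rates")
            ep_rec += rec_loss
            ep_disc += d_loss
            ep_gen += g_loss
            n_batches += 1

        history["reconstruction"].append(ep_rec / max(n_batches, 1))
        history["discriminator"].append(ep_disc / max(n_batches, 1))
        history["generator"].append(ep_gen / max(n_batches, 1))

        if n_val:
            zv, _ = enc.forward(x_val)
            xv_hat, _ = dec.forward(zv)
            val = float(((xv_hat - x_val) ** 2).mean())
            history["validation"].append(val)
            if val < best_val - 1e-9:
                best_val, best_state, stale = val, snapshot(), 0
            else:
                stale += 1
                if stale >= config.patience:
                    break

    if best_state is not None:
        restore(best_state)
    return AAEModel(scaler, enc, dec, disc, config, history)


def reconstruction_errors(model: AAEModel, features: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-region squared errors and their per-participant mean.

    Errors are computed in the robust-scaled feature space the network was
    trained in, so regions contribute on a common footing regardless of their
    absolute volume.
    """
    xs, xhat = model.reconstruct_scaled(features)
    per_roi = (xs - xhat) ** 2
    return per_roi, per_roi.mean(axis=1)


# ---------------------------------------------------------------------------
# Outlier Index Score

@dataclass
class OisScaling:
    """Training medians/IQRs for error scaling, plus category cut-offs."""

    roi_median: np.ndarray
    roi_iqr: np.ndarray
    overall_median: float
    overall_iqr: float
    cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS

    def __post_init__(self) -> None:
        c1, c2, c3 = self.cutoffs
        if not c1 < c2 < c3:
            raise ValueError("cutoffs must be strictly increasing")


def fit_ois_scaling(train_roi_errors: np.ndarray, train_overall_errors: np.ndarray,
                    cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS) -> OisScaling:
    """Fit the robust error scaling on training reconstruction errors.

    After scaling, the training errors have median exactly 0 and IQR exactly
    1, region-wise and overall; the reconstruction-error distributions are
    positively skewed, which is why median/IQR rather than mean/SD are used.
    """
    e = np.asarray(train_roi_errors, dtype=float)
    o = np.asarray(train_overall_errors, dtype=float)
    if len(o) < 10:
        raise ValueError("need at least 10 training rows to fit the scaling")
    med = np.median(e, axis=0)
    q1, q3 = np.percentile(e, [25, 75], axis=0)
    iqr = q3 - q1
    if (iqr <= 0).any():
        j = int(np.argmax(iqr <= 0))
        raise ValueError(f"zero IQR of reconstruction error on ROI index {j}")
    oq1, oq3 = np.percentile(o, [25, 75])
    o_iqr = oq3 - oq1
    if o_iqr <= 0:
        raise ValueError("zero IQR of the overall reconstruction error")
    return OisScaling(med, iqr, float(np.median(o)), float(o_iqr), cutoffs)


def compute_ois(roi_errors: np.ndarray, overall_errors: np.ndarray,
                scaling: OisScaling) -> tuple[np.ndarray, np.ndarray]:
    """Scale errors into Outlier Index Scores.

    ``OIS = (error - train median) / train IQR``: the number of training
    interquartile ranges away from the training median. Negative values
    (errors below the training median) are legitimate and not clamped.
    """
    roi = (np.asarray(roi_errors, dtype=float) - scaling.roi_median) / scaling.roi_iqr
    overall = (np.asarray(overall_errors, dtype=float) - scaling.overall_median) / scaling.overall_iqr
    return roi, overall


def categorize_ois(overall_ois, cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS):
    """Band overall OIS values into the four deviation categories.

    ``< c1`` Within the norm, ``[c1, c2)`` Low, ``[c2, c3)`` Medium,
    ``>= c3`` High, with default cut-offs (0.26, 1.1, 2.3).
    """
    c1, c2, c3 = cutoffs
    if not c1 < c2 < c3:
        raise ValueError("cutoffs must be strictly increasing")
    values = np.atleast_1d(np.asarray(overall_ois, dtype=float))
    idx = np.searchsorted([c1, c2, c3], values, side="right")
    cats = np.array(CATEGORY_NAMES, dtype=object)[idx]
    return cats if np.ndim(overall_ois) else cats[0]


def derive_cutoffs(train_overall_ois: np.ndarray,
                   percentiles: tuple[float, float, float] = (25.0, 50.0, 75.0)
                   ) -> tuple[float, float, float]:
    """Data-driven category cut-offs from the positive tail of training OIS.

    Takes the configured percentiles (quartiles by default) of the strictly
    positive training OIS values. This is an opt-in alternative: the
    published cut-offs (0.26, 1.1, 2.3) remain the defaults everywhere unless
    the caller passes the derived values explicitly.
    """
    ois = np.asarray(train_overall_ois, dtype=float)
    if len(ois) < 100:
        raise ValueError("need at least 100 training OIS values to derive cutoffs")
    tail = ois[ois > 0]
    if len(tail) < 10:
        raise ValueError("positive tail too small to derive cutoffs")
    c1, c2, c3 = np.percentile(tail, list(percentiles))
    if not c1 < c2 < c3:
        raise ValueError("derived cutoffs are not strictly increasing")
    return float(c1), float(c2), float(c3)
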