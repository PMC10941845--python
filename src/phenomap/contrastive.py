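"""Small self-supervised contrastive patch encoder (optional featurizer).

A two-layer NumPy MLP trained with an InfoNCE (NT-Xent) objective on two
stochastic augmentations of each patch (axis flips, random crop-resize,
HU jitter).  Desk-scale stand-in for large pretrained 3D contrastive
encoders: it demonstrates the training dynamics (loss decrease, attraction
of augmented views) on synthetic patches, not transfer to real CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import zoom


@dataclass
class AugmentConfig:
    flip_prob: float = 0.5
    hu_jitter_sd: float = 30.0
    crop_scale_range: tuple[float, float] = (0.75, 1.0)


def _pool_to(vol: np.ndarray, side: int) -> np.ndarray:
    factors = [side / s for s in vol.shape]
    return zoom(vol, factors, order=1, mode="nearest")


def augment_patch(
    insp: np.ndarray, exp: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig
) -> tuple[np.ndarray, np.ndarray]:
    """One stochastic view of a paired patch (same geometry for both phases)."""
    vi, ve = insp.astype(float), exp.astype(float)
    for ax in range(3):
        if rng.random() < cfg.flip_prob:
            vi, ve = np.flip(vi, ax), np.flip(ve, ax)
    s = rng.uniform(*cfg.crop_scale_range)
    if s < 1.0:
        size = [max(2, int(round(s * d))) for d in vi.shape]
        starts = [rng.integers(0, d - sz + 1) for d, sz in zip(vi.shape, size)]
        sl = tuple(slice(a, a + sz) for a, sz in zip(starts, size))
        shape = vi.shape
        vi = zoom(vi[sl], [d / sz for d, sz in zip(shape, size)], order=1, mode="nearest")
        ve = zoom(ve[sl], [d / sz for d, sz in zip(shape, size)], order=1, mode="nearest")
    vi = vi + rng.normal(0.0, cfg.hu_jitter_sd, vi.shape)
    ve = ve + rng.normal(0.0, cfg.hu_jitter_sd, ve.shape)
    return vi, ve


class ContrastiveEncoder:
    """MLP encoder on pooled paired patches with NT-Xent training.

    Input: each phase pooled to ``pool_side``^3 and HU-normalized, the two
    phases concatenated.  ``encode`` is deterministic; training is
    deterministic given its seed.
    """

    def __init__(self, pool_side: int = 8, hidden: int = 128, dim: int = 64, seed: int = 0):
        self.pool_side = pool_side
        self.dim = dim
        n_in = 2 * pool_side**3
        rng = np.random.default_rng(seed)
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / hidden), (hidden, dim))
        self.b2 = np.zeros(dim)
        self.loss_history: list[float] = []

    # -- forward ------------------------------------------------------------
    def _prep(self, insp: np.ndarray, exp: np.ndarray) -> np.ndarray:
        pi = _pool_to(np.asarray(insp, float), self.pool_side)
        pe = _pool_to(np.asarray(exp, float), self.pool_side)
        x = np.concatenate([pi.ravel(), pe.ravel()])
        return (x + 1000.0) / 500.0

    def _forward(self, X: np.ndarray):
        H = X @ self.W1 + self.b1
        R = np.maximum(H, 0.0)
        F = R @ self.W2 + self.b2
        norms = np.linalg.norm(F, axis=1, keepdims=True) + 1e-12
        Z = F / norms
        return H, R, F, norms, Z

    def encode(self, insp: np.ndarray, exp: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        """Feature vector (length ``dim``) for one paired patch."""
        X = self._prep(insp, exp)[None, :]
        return self._forward(X)[4][0]

    def featurizer(self):
        return lambda pi, pe, pm: self.encode(pi, pe, pm)

    # -- training -----------------------------------------------------------
    def _ntxent_grad(self, Z: np.ndarray, tau: float):
        """NT-Xent loss and dL/dZ for 2B row-normalized embeddings where
        rows (2i, 2i+1) are positive pairs."""
        n = Z.shape[0]
        S = (Z @ Z.T) / tau
        np.fill_diagonal(S, -np.inf)
        Smax = S.max(axis=1, keepdims=True)
        E = np.exp(S - Smax)
        P = E / E.sum(axis=1, keepdims=True)
        pos = np.arange(n) ^ 1  # partner index
        loss = float(np.mean(-np.log(P[np.arange(n), pos] + 1e-12)))
        Y = np.zeros_like(P)
        Y[np.arange(n), pos] = 1.0
        G = (P - Y) / n
        np.fill_diagonal(G, 0.0)
        dZ = (G + G.T) @ Z / tau
        return loss, dZ

    def train(
        self,
        patches: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
        epochs: int = 10,
        batch_size: int = 32,
        lr: float = 1e-2,
        tau: float = 0.5,
        seed: int = 0,
        augment: AugmentConfig | None = None,
    ) -> list[float]:
        """Train on (insp, exp, mask) patch triples; returns per-epoch mean
        loss (with the pre-update loss of epoch 0 first)."""
        if epochs < 0:
            raise ValueError("epochs must be >= 0")
        if len(patches) < 2:
            raise ValueError("need at least 2 patches")
        cfg = augment or AugmentConfig()
        rng = np.random.default_rng(seed)
        params = [self.W1, self.b1, self.W2, self.b2]
        m_adam = [np.zeros_like(p) for p in params]
        v_adam = [np.zeros_like(p) for p in params]
        t = 0
        for _ in range(epochs):
            order = rng.permutation(len(patches))
            losses = []
            for start in range(0, len(order), batch_size):
                idx = order[start : start + batch_size]
                if len(idx) < 2:
                    continue
                # two different stochastic views per patch -> rows (2j, 2j+1)
                X = np.vstack(
                    [
                        self._prep(*augment_patch(patches[i][0], patches[i][1], rng, cfg))
                        for i in idx
                        for _ in (0, 1)
                    ]
                )
                H, R, F, norms, Z = self._forward(X)
                loss, dZ = self._ntxent_grad(Z, tau)
                losses.append(loss)
                # backprop through row normalization
                dF = dZ / norms - Z * np.sum(dZ * Z, axis=1, keepdims=True) / norms
                dW2 = R.T @ dF
                db2 = dF.sum(axis=0)
                dR = dF @ self.W2.T
                dH = dR * (H > 0)
                dW1 = X.T @ dH
                db1 = dH.sum(axis=0)
                grads = [dW1, db1, dW2, db2]
                t += 1
                for p, g, m, v in zip(params, grads, m_adam, v_adam):
                    m *= 0.9
                    m += 0.1 * g
                    v *= 0.999
                    v += 0.001 * g * g
                    mh = m / (1 - 0.9**t)
                    vh = v / (1 - 0.999**t)
                    p -= lr * mh / (np.sqrt(vh) + 1e-8)
            if losses:
                self.loss_history.append(float(np.mean(losses)))
        return self.loss_history
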