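"""Minimal 1-D conv net with manual backprop, in numpy.

Just enough machinery for the codon-context shape model: one-hot codon
encoding (pad tokens are zero rows), stacked same-padding 1-D convolutions
with ReLU, learned position-weighted pooling over the context window, a
small dense head predicting the log-shape, and Adam. Float32 throughout;
fully deterministic given the generator passed in.

Two equivalent evaluation modes are provided. *Window mode* treats each
121-codon window as an independent input — the natural fit for the
(window, target) training-pair contract. *Dense mode* runs the conv stack
once over a whole padded transcript and slides the pooling window, which
makes per-codon prediction across a transcriptome (and in-loop retraining
on sampled positions) two orders of magnitude cheaper than cutting out
overlapping windows. The two modes share all parameters; they differ only
in whether convolutions at a window's rim see zeros or the true
neighbouring codons, which pooling initialised uniform keeps negligible —
the pipeline uses dense mode for both fitting and prediction, so training
and inference are always mutually consistent.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

LOG_CLIP = float(np.log(1e-8))


def one_hot(X: np.ndarray, n_channels: int = 64) -> np.ndarray:
    """(..., L) integer codons -> (..., L, 64) float32; tokens >= 64 are zero rows."""
    H = np.zeros(X.shape + (n_channels,), dtype=np.float32)
    idx = np.nonzero(X < n_channels)
    H[idx + (X[idx],)] = 1.0
    return H


def _im2col(H: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B, L, k*C) sliding windows with zero padding."""
    pad = k // 2
    Hp = np.pad(H, ((0, 0), (pad, pad), (0, 0)))
    L = H.shape[1]
    return np.concatenate([Hp[:, d : d + L, :] for d in range(k)], axis=2)


def _col2im(dcol: np.ndarray, k: int, C: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    B, L, _ = dcol.shape
    pad = k // 2
    dHp = np.zeros((B, L + 2 * pad, C), dtype=dcol.dtype)
    for d in range(k):
        dHp[:, d : d + L, :] += dcol[:, :, d * C : (d + 1) * C]
    return dHp[:, pad : pad + L, :]


class ConvNet:
    """Conv stack -> position-weighted pooling -> dense -> scalar log-shape.

    The pooling weights (one per window position and channel, initialised
    to the uniform average) are trained with everything else, so the model
    can interpolate between pure context averaging and focusing on the
    codon at the window centre.
    """

    def __init__(
        self,
        n_filters: int,
        kernel_size: int,
        n_conv: int,
        hidden_units: int,
        window: int,
        rng: np.random.Generator,
        in_channels: int = 64,
    ):
        self.k = kernel_size
        self.n_conv = n_conv
        self.window = window
        self.params: Dict[str, np.ndarray] = {}
        c_in = in_channels
        for i in range(n_conv):
            fan_in = self.k * c_in
            self.params[f"Wc{i}"] = (
                rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, n_filters))
            ).astype(np.float32)
            self.params[f"bc{i}"] = np.zeros(n_filters, dtype=np.float32)
            c_in = n_filters
        # pooling weights: half the mass on the window centre, half spread
        # uniformly — ribosome dwell is dominated by the codon in the
        # P-site, with context modulating it
        alpha = np.full((window, n_filters), 0.5 / window, dtype=np.float32)
        alpha[window // 2] += 0.5
        self.params["alpha"] = alpha
        self.params["W1"] = (
            rng.normal(0.0, np.sqrt(2.0 / n_filters), size=(n_filters, hidden_units))
        ).astype(np.float32)
        self.params["b1"] = np.zeros(hidden_units, dtype=np.float32)
        self.params["W2"] = (
            rng.normal(0.0, np.sqrt(1.0 / hidden_units), size=(hidden_units, 1))
        ).astype(np.float32)
        self.params["b2"] = np.zeros(1, dtype=np.float32)
        self._init_adam()

    def _init_adam(self) -> None:
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------
    # shared pieces

    def _conv_stack(
        self, H: np.ndarray, keep_cache: bool
    ) -> Tuple[np.ndarray, Optional[dict]]:
        cache: Optional[dict] = {"acts": [], "cols": []} if keep_cache else None
        for i in range(self.n_conv):
            col = _im2col(H, self.k)
            B, L, kc = col.shape
            z = col.reshape(B * L, kc) @ self.params[f"Wc{i}"] + self.params[f"bc{i}"]
            H = np.maximum(z.reshape(B, L, -1), 0.0)
            if keep_cache:
                cache["cols"].append(col)
                cache["acts"].append(H)
        return H, cache

    def _conv_stack_backward(self, dH: np.ndarray, cache: dict) -> Dict[str, np.ndarray]:
        grads: Dict[str, np.ndarray] = {}
        for i in range(self.n_conv - 1, -1, -1):
            act = cache["acts"][i]
            dzc = dH * (act > 0)
            col = cache["cols"][i]
            B, L, kc = col.shape
            dzc2 = dzc.reshape(B * L, -1)
            grads[f"Wc{i}"] = col.reshape(B * L, kc).T @ dzc2
            grads[f"bc{i}"] = dzc2.sum(axis=0)
            dcol = (dzc2 @ self.params[f"Wc{i}"].T).reshape(B, L, kc)
            dH = _col2im(dcol, self.k, kc // self.k)
        return grads

    def _head(
        self, pooled: np.ndarray, keep_cache: bool
    ) -> Tuple[np.ndarray, Optional[dict]]:
        h1 = np.maximum(pooled @ self.params["W1"] + self.params["b1"], 0.0)
        z = (h1 @ self.params["W2"] + self.params["b2"]).ravel()
        cache = {"pooled": pooled, "h1": h1} if keep_cache else None
        return z, cache

    def _head_backward(
        self, dz: np.ndarray, cache: dict
    ) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
        h1, pooled = cache["h1"], cache["pooled"]
        dz = dz.astype(np.float32).reshape(-1, 1)
        grads = {
            "W2": h1.T @ dz,
            "b2": dz.sum(axis=0),
        }
        dh1 = (dz @ self.params["W2"].T) * (h1 > 0)
        grads["W1"] = pooled.T @ dh1
        grads["b1"] = dh1.sum(axis=0)
        dpooled = dh1 @ self.params["W1"].T
        return dpooled, grads

    # ------------------------------------------------------------------
    # window mode: X is (B, window) integer codons

    def forward(
        self, X: np.ndarray, keep_cache: bool = False
    ) -> Tuple[np.ndarray, Optional[dict]]:
        if X.shape[1] != self.window:
            raise ValueError(f"window mode expects width {self.window}")
        H, conv_cache = self._conv_stack(one_hot(X), keep_cache)
        pooled = np.einsum("bpf,pf->bf", H, self.params["alpha"])
        z, head_cache = self._head(pooled, keep_cache)
        if keep_cache:
            cache = dict(conv_cache)
            cache.update(head_cache)
            cache["H_top"] = H
            return z, cache
        return z, None

    def backward(self, dz: np.ndarray, cache: dict) -> Dict[str, np.ndarray]:
        dpooled, grads = self._head_backward(dz, cache)
        H = cache["H_top"]
        grads["alpha"] = np.einsum("bpf,bf->pf", H, dpooled)
        dH = dpooled[:, None, :] * self.params["alpha"][None, :, :]
        grads.update(self._conv_stack_backward(dH, cache))
        return grads

    # ------------------------------------------------------------------
    # dense mode: one padded transcript at a time

    def forward_dense(
        self, padded_codons: np.ndarray, keep_cache: bool = False
    ) -> Tuple[np.ndarray, Optional[dict]]:
        """Per-codon log-shape for a transcript padded with window//2 tokens.

        ``padded_codons`` has length n + window - 1; returns n values, one
        per real codon.
        """
        M = len(padded_codons)
        n = M - self.window + 1
        if n < 1:
            raise ValueError("sequence shorter than the context window")
        H, conv_cache = self._conv_stack(one_hot(padded_codons[None, :]), keep_cache)
        H = H[0]  # (M, F)
        strided = np.lib.stride_tricks.sliding_window_view(H, self.window, axis=0)
        # strided: (n, F, window) read-only view
        pooled = np.einsum("nfp,pf->nf", strided, self.params["alpha"])
        z, head_cache = self._head(pooled, keep_cache)
        if keep_cache:
            cache = dict(conv_cache)
            cache.update(head_cache)
            cache["H_top_dense"] = H
            cache["n"] = n
            return z, cache
        return z, None

    def backward_dense(self, dz: np.ndarray, cache: dict) -> Dict[str, np.ndarray]:
        dpooled, grads = self._head_backward(dz, cache)
        H = cache["H_top_dense"]
        n = cache["n"]
        strided = np.lib.stride_tricks.sliding_window_view(H, self.window, axis=0)
        grads["alpha"] = np.einsum("nfp,nf->pf", strided, dpooled)
        dH = np.zeros_like(H)
        alpha = self.params["alpha"]
        for d in range(self.window):
            dH[d : d + n] += dpooled * alpha[d]
        grads.update(self._conv_stack_backward(dH[None, :, :], cache))
        return grads

    # ------------------------------------------------------------------

    def adam_step(
        self,
        grads: Dict[str, np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self._adam_t += 1
        t = self._adam_t
        for key, p in self.params.items():
            g = grads.get(key)
            if g is None:
                continue
            m = self._adam_m[key]
            v = self._adam_v[key]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)

    def get_weights(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: Dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = weights[k].copy()
        self._init_adam()

    def predict_log(self, X: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """Window-mode prediction in batches."""
        out = np.empty(len(X), dtype=np.float64)
        for s in range(0, len(X), batch_size):
            z, _ = self.forward(X[s : s + batch_size], keep_cache=False)
            out[s : s + len(z)] = z
        return out
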