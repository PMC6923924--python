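"""The codon-context shape model.

A small CNN regressor maps the 121-codon window around a position (60
codons upstream, the codon itself, 60 downstream; positions beyond the CDS
carry a pad token) to the normalized ribosome density x at that position.
Training pairs come from the current read allocation: per-transcript
profiles are normalized to mean 1 (x_ij = c_ij / sum_j c_ij * l_i, l_i in
codons), zeros and log-scale outliers beyond 3 sigma are discarded, and the
surviving log-range is split into 10 equal bins that are each resampled to
the same size so rare high/low densities are not drowned out. The loss is
the mean squared difference of (clipped) natural logs.

Because every CDS codon of every transcript needs a prediction on every
refit, the model is evaluated in "dense" mode wherever the pipeline calls
it: the conv stack runs once over a whole padded transcript and the pooling
window slides, rather than cutting out one 121-codon window per position.
Fitting inside the allocation loop uses the same dense code path, so
training and inference always see identical context semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._nn import LOG_CLIP, ConvNet
from .prime import AllocatedProfile, profile_offsets
from .transcriptome import PAD_INDEX, Transcriptome

logger = logging.getLogger(__name__)

#: codons of context on each side of the position of interest
CONTEXT = 60
WINDOW = 2 * CONTEXT + 1


def normalize_profile(profile: np.ndarray) -> Optional[np.ndarray]:
    """Normalize a per-codon count/mass vector to mean 1.

    x_j = c_j / sum(c) * l with l the codon count, so sum(x) == l and the
    values are comparable across transcripts of different depth and length.
    Returns None for an all-zero profile (excluded from training).
    """
    profile = np.asarray(profile, dtype=np.float64)
    total = profile.sum()
    if total <= 0:
        return None
    return profile / total * len(profile)


def normalized_profiles(
    allocated: AllocatedProfile, transcriptome: Transcriptome
) -> Tuple[np.ndarray, np.ndarray]:
    """Flat mean-1 normalized profiles for all transcripts with any mass.

    Returns ``(x_flat, covered)`` where ``x_flat`` aligns with the profile
    offsets (zeros for uncovered transcripts) and ``covered`` flags the
    transcripts that had mass.
    """
    offsets = allocated.offsets
    x_flat = np.zeros_like(allocated.mass)
    covered = np.zeros(len(transcriptome), dtype=bool)
    totals = allocated.transcript_mass()
    for i in range(len(transcriptome)):
        if totals[i] > 0:
            sl = slice(offsets[i], offsets[i + 1])
            x_flat[sl] = allocated.mass[sl] / totals[i] * (offsets[i + 1] - offsets[i])
            covered[i] = True
    return x_flat, covered


class _PaddedCodons:
    """Concatenated per-transcript codon arrays with CONTEXT pads each side."""

    def __init__(self, transcriptome: Transcriptome):
        parts = []
        offsets = [0]
        n_codons = []
        for t in transcriptome:
            codons = transcriptome.codons(t.transcript_id)
            parts.append(np.full(CONTEXT, PAD_INDEX, dtype=np.int16))
            parts.append(codons.astype(np.int16))
            parts.append(np.full(CONTEXT, PAD_INDEX, dtype=np.int16))
            offsets.append(offsets[-1] + len(codons) + 2 * CONTEXT)
            n_codons.append(len(codons))
        self.flat = np.concatenate(parts) if parts else np.empty(0, dtype=np.int16)
        self.offsets = np.asarray(offsets)
        self.n_codons = np.asarray(n_codons)

    def windows(self, tx_idx: np.ndarray, codon_idx: np.ndarray) -> np.ndarray:
        """(n, 121) codon-index windows centred on the given positions."""
        starts = self.offsets[tx_idx] + codon_idx
        return self.flat[starts[:, None] + np.arange(WINDOW)[None, :]]

    def transcript(self, i: int) -> np.ndarray:
        """Padded codon array of one transcript (length n_codons + 120)."""
        return self.flat[self.offsets[i] : self.offsets[i + 1]]


@dataclass
class TrainingSet:
    """Sampled (window, target) pairs and the statistics behind them.

    ``X`` holds the 121-codon windows row-wise; ``tx_idx``/``codon_idx``
    record where each sample sits on the transcriptome, which lets the
    trainer evaluate samples in dense mode instead of window-by-window.
    """

    X: np.ndarray
    y: np.ndarray
    mu: float
    sigma: float
    bin_edges: Optional[np.ndarray]
    per_bin: Optional[np.ndarray]
    tx_idx: Optional[np.ndarray] = None
    codon_idx: Optional[np.ndarray] = None


def build_training_set(
    x_flat: np.ndarray,
    transcriptome: Transcriptome,
    samples_per_bin: int = 2000,
    n_bins: int = 10,
    rng: Optional[np.random.Generator] = None,
    padded: Optional[_PaddedCodons] = None,
) -> TrainingSet:
    """Assemble (window, target) pairs with outlier filtering and bin balance.

    Zero targets are discarded; mu/sigma are the mean/sd of the natural logs
    of the rest; targets outside [mu-3sigma, mu+3sigma] (log scale) are
    discarded; the remaining log-range is split into ``n_bins`` equal bins
    and each is resampled to ``samples_per_bin`` points (with replacement
    when the bin holds fewer). When sigma is 0 (degenerate data) filtering
    and binning are skipped and ``n_bins * samples_per_bin`` points are
    drawn uniformly.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    offsets = profile_offsets(transcriptome)
    pos_tx = np.searchsorted(offsets, np.arange(len(x_flat)), side="right") - 1
    pos_codon = np.arange(len(x_flat)) - offsets[pos_tx]
    keep = x_flat > 0
    tx, codon, vals = pos_tx[keep], pos_codon[keep], x_flat[keep]
    if len(vals) == 0:
        raise ValueError("no nonzero targets to train on")
    logv = np.log(vals)
    mu = float(logv.mean())
    sigma = float(logv.std())
    padded = _PaddedCodons(transcriptome) if padded is None else padded
    if sigma == 0.0:
        pick = rng.integers(0, len(vals), size=n_bins * samples_per_bin)
        edges = None
        per_bin = None
    else:
        lo, hi = mu - 3 * sigma, mu + 3 * sigma
        inside = (logv >= lo) & (logv <= hi)
        tx, codon, vals, logv = tx[inside], codon[inside], vals[inside], logv[inside]
        edges = np.linspace(lo, hi, n_bins + 1)
        which = np.clip(np.digitize(logv, edges) - 1, 0, n_bins - 1)
        picks: List[np.ndarray] = []
        per_bin = np.zeros(n_bins, dtype=np.int64)
        for b in range(n_bins):
            members = np.nonzero(which == b)[0]
            if len(members) == 0:
                logger.warning("training bin %d empty; skipped", b)
                continue
            replace = len(members) < samples_per_bin
            picks.append(rng.choice(members, size=samples_per_bin, replace=replace))
            per_bin[b] = samples_per_bin
        pick = np.concatenate(picks)
    return TrainingSet(
        X=padded.windows(tx[pick], codon[pick]),
        y=vals[pick],
        mu=mu,
        sigma=sigma,
        bin_edges=edges,
        per_bin=per_bin,
        tx_idx=tx[pick],
        codon_idx=codon[pick],
    )


def shape_loss(y_predict: Sequence[float], y_ground_truth: Sequence[float]) -> float:
    """Mean squared difference of natural logs, clipped at 1e-8."""
    yp = np.maximum(1e-8, np.asarray(y_predict, dtype=np.float64))
    yt = np.maximum(1e-8, np.asarray(y_ground_truth, dtype=np.float64))
    if yp.shape != yt.shape or yp.size == 0:
        raise ValueError("prediction/truth lists must be equal-length and non-empty")
    return float(np.mean((np.log(yp) - np.log(yt)) ** 2))


def _sum_grads(acc: Optional[Dict], grads: Dict) -> Dict:
    if acc is None:
        return {k: v.astype(np.float64) for k, v in grads.items()}
    for k, v in grads.items():
        acc[k] += v
    return acc


class ShapeModel(BaseEstimator, RegressorMixin):
    """CNN regressor from 121-codon windows to ribosome density.

    The network one-hot encodes the 64 codons (pad positions are zero
    vectors), applies ``n_conv`` same-padding 1-D convolutions with ReLU,
    pools the window with learned per-position weights (initialised to the
    uniform average, so the model can weight the window centre as strongly
    as the data warrants), and maps through one hidden dense layer to a
    scalar log-density that is exponentiated — predictions are always
    positive. Trained with Adam on the squared-log loss; an epoch whose
    validation loss exceeds the previous epoch's stops training and the
    previous weights are kept.

    Sized (32 filters, kernel 5) so that a refit on a few tens of
    thousands of samples takes seconds on one CPU core, which is what the
    iterative allocation loop needs; width, depth and kernel are all
    parameters.
    """

    def __init__(
        self,
        n_filters: int = 32,
        kernel_size: int = 5,
        n_conv: int = 3,
        hidden_units: int = 64,
        learning_rate: float = 1e-3,
        batch_size: int = 512,
        max_epochs: int = 50,
        validation_fraction: float = 0.1,
        early_stopping_tolerance: float = 0.05,
        random_state: int = 0,
    ):
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.n_conv = n_conv
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.early_stopping_tolerance = early_stopping_tolerance
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _new_net(self, window: int, rng: np.random.Generator) -> ConvNet:
        return ConvNet(
            self.n_filters,
            self.kernel_size,
            self.n_conv,
            self.hidden_units,
            window,
            rng,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShapeModel":
        """Window-mode training on an explicit (n_samples, 121) matrix."""
        X = np.asarray(X)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or len(X) != len(y) or len(y) == 0:
            raise ValueError("X must be (n_samples, window) matching y")
        rng = np.random.default_rng(self.random_state)
        net = self._new_net(X.shape[1], rng)
        t = np.maximum(LOG_CLIP, np.log(np.maximum(1e-300, y)))
        n_val = max(1, int(round(self.validation_fraction * len(y))))
        order = rng.permutation(len(y))
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(train_idx) == 0:
            train_idx = val_idx
        history: List[Tuple[float, float]] = []
        prev_val = np.inf
        best_weights = net.get_weights()
        for _epoch in range(self.max_epochs):
            perm = rng.permutation(len(train_idx))
            train_losses = []
            for s in range(0, len(perm), self.batch_size):
                idx = train_idx[perm[s : s + self.batch_size]]
                z, cache = net.forward(X[idx], keep_cache=True)
                zc = np.maximum(z, LOG_CLIP)
                diff = zc - t[idx]
                loss = float(np.mean(diff**2))
                if not np.isfinite(loss):
                    raise RuntimeError("shape-model training diverged (non-finite loss)")
                dz = 2.0 * diff * (z > LOG_CLIP) / len(idx)
                net.adam_step(net.backward(dz, cache), self.learning_rate)
                train_losses.append(loss)
            zv = net.predict_log(X[val_idx])
            val_loss = float(np.mean((np.maximum(zv, LOG_CLIP) - t[val_idx]) ** 2))
            history.append((float(np.mean(train_losses)), val_loss))
            if val_loss > prev_val * (1.0 + self.early_stopping_tolerance):
                net.set_weights(best_weights)
                break
            if val_loss < prev_val:
                prev_val = val_loss
                best_weights = net.get_weights()
        self.net_ = net
        self.loss_history_ = history
        self.n_epochs_ = len(history)
        return self

    def fit_indexed(
        self,
        padded: _PaddedCodons,
        tx_idx: np.ndarray,
        codon_idx: np.ndarray,
        y: np.ndarray,
    ) -> "ShapeModel":
        """Dense-mode training on transcript positions.

        Equivalent objective to :meth:`fit`, but samples are grouped by
        transcript and evaluated through one conv pass per transcript per
        epoch, so duplicated positions (bin resampling) and overlapping
        windows cost nothing extra. Batches are groups of transcripts
        holding roughly ``batch_size`` samples.
        """
        y = np.asarray(y, dtype=np.float64)
        rng = np.random.default_rng(self.random_state)
        net = self._new_net(WINDOW, rng)
        t = np.maximum(LOG_CLIP, np.log(np.maximum(1e-300, y)))
        n = len(y)
        n_val = max(1, int(round(self.validation_fraction * n)))
        order = rng.permutation(n)
        val_s, train_s = order[:n_val], order[n_val:]
        if len(train_s) == 0:
            train_s = val_s

        def aggregate(samples: np.ndarray):
            """Group samples per transcript: position, target, weight arrays."""
            per_tx: Dict[int, Dict[Tuple[int, float], float]] = {}
            for s in samples:
                key = (int(codon_idx[s]), float(t[s]))
                d = per_tx.setdefault(int(tx_idx[s]), {})
                d[key] = d.get(key, 0.0) + 1.0
            out = {}
            for i, d in per_tx.items():
                pos = np.array([k[0] for k in d], dtype=np.int64)
                tt = np.array([k[1] for k in d])
                ww = np.array(list(d.values()))
                out[i] = (pos, tt, ww)
            return out

        train_by_tx = aggregate(train_s)
        val_by_tx = aggregate(val_s)
        tx_list = np.array(sorted(train_by_tx))
        tx_weight = np.array([train_by_tx[i][2].sum() for i in tx_list])

        def val_loss_now() -> float:
            num = den = 0.0
            for i, (pos, tt, ww) in val_by_tx.items():
                z, _ = net.forward_dense(padded.transcript(i))
                num += float(np.sum(ww * (np.maximum(z[pos], LOG_CLIP) - tt) ** 2))
                den += float(ww.sum())
            return num / den

        history: List[Tuple[float, float]] = []
        prev_val = np.inf
        best_weights = net.get_weights()
        for _epoch in range(self.max_epochs):
            perm = rng.permutation(len(tx_list))
            train_losses: List[float] = []
            batch: List[int] = []
            batch_w = 0.0
            for j, k in enumerate(perm):
                batch.append(int(tx_list[k]))
                batch_w += float(tx_weight[k])
                if batch_w < self.batch_size and j < len(perm) - 1:
                    continue
                acc = None
                num = 0.0
                for i in batch:
                    pos, tt, ww = train_by_tx[i]
                    z, cache = net.forward_dense(padded.transcript(i), keep_cache=True)
                    zc = np.maximum(z[pos], LOG_CLIP)
                    diff = zc - tt
                    num += float(np.sum(ww * diff**2))
                    dz_full = np.zeros(len(z))
                    dz_full[pos] = 2.0 * ww * diff * (z[pos] > LOG_CLIP) / batch_w
                    acc = _sum_grads(acc, net.backward_dense(dz_full, cache))
                loss = num / batch_w
                if not np.isfinite(loss):
                    raise RuntimeError("shape-model training diverged (non-finite loss)")
                net.adam_step(acc, self.learning_rate)
                train_losses.append(loss)
                batch = []
                batch_w = 0.0
            vl = val_loss_now()
            history.append((float(np.mean(train_losses)), vl))
            if vl > prev_val * (1.0 + self.early_stopping_tolerance):
                net.set_weights(best_weights)
                break
            if vl < prev_val:
                prev_val = vl
                best_weights = net.get_weights()
        self.net_ = net
        self.loss_history_ = history
        self.n_epochs_ = len(history)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Positive shape value for each window row of integer matrix X."""
        return np.exp(self.net_.predict_log(np.asarray(X)))


def train_shape_model(
    training_set: TrainingSet,
    validation_fraction: float = 0.1,
    seed: int = 0,
    transcriptome: Optional[Transcriptome] = None,
    padded: Optional[_PaddedCodons] = None,
    **params,
) -> ShapeModel:
    """Fit a :class:`ShapeModel` on a prepared training set.

    Uses the dense code path when the training set carries transcript
    positions and a transcriptome (or padded codon cache) is supplied;
    falls back to window-mode fitting otherwise.
    """
    model = ShapeModel(
        validation_fraction=validation_fraction, random_state=seed, **params
    )
    if training_set.tx_idx is not None and (transcriptome is not None or padded is not None):
        padded = _PaddedCodons(transcriptome) if padded is None else padded
        return model.fit_indexed(
            padded, training_set.tx_idx, training_set.codon_idx, training_set.y
        )
    return model.fit(training_set.X, training_set.y)


def predict_instructive_shape(
    model: ShapeModel,
    transcriptome: Transcriptome,
    padded: Optional[_PaddedCodons] = None,
) -> np.ndarray:
    """Per-codon instructive shape values for every transcript, flattened.

    One value per CDS codon (aligned with :func:`profile_offsets`), each
    transcript renormalized to mean 1 so shape carries only within-
    transcript structure and abundance stays a separate factor in the
    allocation weight.
    """
    padded = _PaddedCodons(transcriptome) if padded is None else padded
    offsets = profile_offsets(transcriptome)
    s = np.empty(int(offsets[-1]), dtype=np.float64)
    for i in range(len(transcriptome)):
        z, _ = model.net_.forward_dense(padded.transcript(i))
        sl = slice(offsets[i], offsets[i + 1])
        s[sl] = np.exp(z)
        mean = s[sl].mean()
        s[sl] = s[sl] / mean if mean > 0 else 1.0
    return s
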