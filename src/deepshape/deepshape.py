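"""The full allocation loop: abundance x instructive shape.

Each iteration (1) splits every read over its candidates with weight
proportional to the candidate transcript's normalized abundance times the
predicted shape value at the candidate codon, (2) refits the shape model on
the freshly allocated, normalized profiles and refreshes the instructive
shape values of every transcript, and (3) re-estimates abundances from the
allocated mass. With all shape values fixed at 1 the loop reduces exactly
to the abundance-only allocator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .mapping import ReadAlignments
from .prime import (
    MILLION,
    AbundanceState,
    AllocatedProfile,
    allocate_reads,
    initialize_uniform,
    update_abundance,
)
from .shape import (
    ShapeModel,
    _PaddedCodons,
    build_training_set,
    normalized_profiles,
    predict_instructive_shape,
    profile_offsets,
)
from .transcriptome import Transcriptome

logger = logging.getLogger(__name__)


def allocate_reads_with_shape(
    alignments: ReadAlignments,
    state: AbundanceState,
    shapes: np.ndarray,
    transcriptome: Transcriptome,
) -> AllocatedProfile:
    """Proportional allocation with weight r_i * s_i(candidate codon).

    ``shapes`` is a flat per-codon array aligned with the profile offsets;
    the product rule reduces to plain abundance allocation when all shape
    values are 1.
    """
    return allocate_reads(alignments, state, transcriptome, site_weights=shapes)


@dataclass
class DeepShapeConfig:
    """Loop controls.

    ``n_iter`` allocation/update iterations; the shape model is refit every
    ``shape_retrain_interval`` iterations (from scratch, on the current
    allocation). ``warm_start`` may carry abundances from a previous run
    (e.g. the abundance-only allocator); otherwise initialization is
    uniform. ``shape_max_epochs`` caps each refit. With
    ``shape_averaging`` (default) the instructive shapes used for
    allocation are the running average of all refit predictions so far,
    renormalized per transcript; successive refits are trained on slightly
    different resamples and seeds, and averaging damps that refit-to-refit
    variance so the loop improves monotonically instead of drifting.
    ``shape_params`` passes any further :class:`ShapeModel`
    hyperparameters through.
    """

    n_iter: int = 200
    shape_retrain_interval: int = 1
    warm_start: Optional[np.ndarray] = None
    seed: int = 0
    samples_per_bin: int = 2000
    shape_max_epochs: int = 25
    shape_averaging: bool = True
    shape_params: Dict = field(default_factory=dict)
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.shape_retrain_interval < 1:
            raise ValueError("n_iter and shape_retrain_interval must be >= 1")


def run_deepshape(
    alignments: ReadAlignments,
    transcriptome: Transcriptome,
    config: Optional[DeepShapeConfig] = None,
) -> Tuple[
    AbundanceState, AllocatedProfile, Optional[ShapeModel], np.ndarray, List[float]
]:
    """Run the three-step loop; returns state, profile, model, shapes, history."""
    config = DeepShapeConfig() if config is None else config
    offsets = profile_offsets(transcriptome)
    shapes = np.ones(int(offsets[-1]))
    shape_sum = np.zeros_like(shapes)
    n_refits = 0
    padded: Optional[_PaddedCodons] = None
    if config.warm_start is not None:
        warm = np.asarray(config.warm_start, dtype=np.float64)
        if warm.shape != (len(transcriptome),):
            raise ValueError("warm_start must hold one abundance per transcript")
        state = AbundanceState(abundance=warm.copy(), read_counts=np.zeros(len(warm)))
    else:
        state = initialize_uniform(transcriptome)
    model: Optional[ShapeModel] = None
    history: List[float] = []
    for it in range(1, config.n_iter + 1):
        profile = allocate_reads_with_shape(alignments, state, shapes, transcriptome)
        if it % config.shape_retrain_interval == 0:
            if padded is None:
                padded = _PaddedCodons(transcriptome)
            try:
                x_flat, _ = normalized_profiles(profile, transcriptome)
                rng = np.random.default_rng([int(config.seed), it])
                ts = build_training_set(
                    x_flat,
                    transcriptome,
                    samples_per_bin=config.samples_per_bin,
                    rng=rng,
                    padded=padded,
                )
                params = dict(config.shape_params)
                params.setdefault("max_epochs", config.shape_max_epochs)
                candidate = ShapeModel(
                    random_state=int(config.seed) + it, **params
                ).fit_indexed(padded, ts.tx_idx, ts.codon_idx, ts.y)
                model = candidate
                s_new = predict_instructive_shape(model, transcriptome, padded=padded)
                if config.shape_averaging:
                    shape_sum += s_new
                    n_refits += 1
                    shapes = shape_sum / n_refits
                    for i in range(len(transcriptome)):
                        sl = slice(offsets[i], offsets[i + 1])
                        shapes[sl] /= shapes[sl].mean()
                else:
                    shapes = s_new
            except Exception as exc:  # keep iterating with the last valid shapes
                logger.warning("shape refit failed at iteration %d: %s", it, exc)
        new_state = update_abundance(profile, transcriptome)
        delta = float(np.max(np.abs(new_state.abundance - state.abundance)) / MILLION)
        history.append(delta)
        new_state.iteration = it
        state = new_state
        if delta < config.tol:
            break
    profile = allocate_reads_with_shape(alignments, state, shapes, transcriptome)
    return state, profile, model, shapes, history


class DeepShapeAllocator(BaseEstimator):
    """Joint abundance/shape allocator (estimator interface).

    Parameters mirror :class:`DeepShapeConfig`; ``warm_start`` accepts a
    per-transcript abundance vector, typically ``PrimeAllocator.r_``.

    Attributes
    ----------
    r_, read_counts_, profile_, abundance_ : as in PrimeAllocator.
    shape_model_ : the last fitted :class:`ShapeModel` (None if never fit).
    shapes_ : flat per-codon instructive shape values used last.
    history_ : max abundance change per iteration.
    """

    def __init__(
        self,
        n_iter: int = 200,
        shape_retrain_interval: int = 1,
        warm_start: Optional[np.ndarray] = None,
        seed: int = 0,
        samples_per_bin: int = 2000,
        shape_max_epochs: int = 25,
        shape_averaging: bool = True,
        shape_params: Optional[Dict] = None,
        tol: float = 1e-8,
    ):
        self.n_iter = n_iter
        self.shape_retrain_interval = shape_retrain_interval
        self.warm_start = warm_start
        self.seed = seed
        self.samples_per_bin = samples_per_bin
        self.shape_max_epochs = shape_max_epochs
        self.shape_averaging = shape_averaging
        self.shape_params = shape_params
        self.tol = tol

    def fit(self, alignments: ReadAlignments, transcriptome: Transcriptome):
        config = DeepShapeConfig(
            n_iter=self.n_iter,
            shape_retrain_interval=self.shape_retrain_interval,
            warm_start=self.warm_start,
            seed=self.seed,
            samples_per_bin=self.samples_per_bin,
            shape_max_epochs=self.shape_max_epochs,
            shape_averaging=self.shape_averaging,
            shape_params=self.shape_params or {},
            tol=self.tol,
        )
        state, profile, model, shapes, history = run_deepshape(
            alignments, transcriptome, config
        )
        self.transcriptome_ = transcriptome
        self.r_ = state.abundance
        self.read_counts_ = state.read_counts
        self.profile_ = profile
        self.shape_model_ = model
        self.shapes_ = shapes
        self.history_ = history
        self.abundance_ = pd.DataFrame(
            {
                "transcript_id": transcriptome.transcript_ids,
                "read_count": self.read_counts_,
                "abundance": self.r_,
            }
        )
        return self
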