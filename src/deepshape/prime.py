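"""Iterative proportional allocation of multi-mapped footprints.

Starting from a uniform CDS-length-normalized ribosome abundance, each
iteration (i) splits every read over its candidate transcripts in
proportion to the current abundances and (ii) re-estimates abundances from
the allocated mass. Unique reads anchor the abundances; shared reads are
pulled toward the transcripts the unique evidence supports, and the scheme
converges to a fixed point of the allocate/update map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .mapping import ReadAlignments
from .transcriptome import Transcriptome

MILLION = 1_000_000.0


@dataclass
class AbundanceState:
    """Per-transcript allocated mass and normalized abundance.

    ``read_counts`` is the (fractional) read mass c_ri on each CDS;
    ``abundance`` is the CDS-length-normalized per-million abundance
    r_i = (c_ri / l_ri) / sum_k (c_rk / l_rk) * 10^6.
    """

    abundance: np.ndarray
    read_counts: np.ndarray
    iteration: int = 0


@dataclass
class AllocatedProfile:
    """Per-codon fractional read mass, flattened across transcripts.

    ``mass[offsets[i]:offsets[i+1]]`` is transcript ``i``'s per-codon mass.
    """

    mass: np.ndarray
    offsets: np.ndarray

    def profile(self, i: int) -> np.ndarray:
        return self.mass[self.offsets[i] : self.offsets[i + 1]]

    def transcript_mass(self) -> np.ndarray:
        """Total allocated mass per transcript (c_ri)."""
        return np.add.reduceat(self.mass, self.offsets[:-1])

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())


def profile_offsets(transcriptome: Transcriptome) -> np.ndarray:
    """Flat-array offsets of each transcript's codon block."""
    return np.concatenate(([0], np.cumsum(transcriptome.codon_counts())))


def global_codon_index(
    alignments: ReadAlignments, transcriptome: Transcriptome
) -> np.ndarray:
    """Flat codon position of every candidate entry."""
    offsets = profile_offsets(transcriptome)
    return offsets[alignments.cand_tx] + alignments.cand_codon


def initialize_uniform(transcriptome: Transcriptome) -> AbundanceState:
    """Uniform starting abundance: r_i = 10^6 / #transcripts."""
    n = len(transcriptome)
    if n == 0:
        raise ValueError("empty transcriptome")
    return AbundanceState(
        abundance=np.full(n, MILLION / n), read_counts=np.zeros(n), iteration=0
    )


def allocate_reads(
    alignments: ReadAlignments,
    state: AbundanceState,
    transcriptome: Transcriptome,
    site_weights: Optional[np.ndarray] = None,
) -> AllocatedProfile:
    """Split every read over its candidates proportionally.

    A read with candidate set M puts weight ``w_i / sum_{k in M} w_k`` on
    candidate i, where ``w_i = r_i`` (times the per-codon site weight when
    ``site_weights`` — a flat array over all codon positions — is given).
    Candidate sets with zero total weight fall back to a uniform split, so
    read mass is always conserved.
    """
    offsets = profile_offsets(transcriptome)
    g_idx = offsets[alignments.cand_tx] + alignments.cand_codon
    w = state.abundance[alignments.cand_tx].astype(np.float64)
    if site_weights is not None:
        w = w * site_weights[g_idx]
    denom = np.bincount(alignments.cand_class, weights=w, minlength=alignments.n_classes)
    zero_entries = denom[alignments.cand_class] <= 0.0
    if zero_entries.any():
        w = np.where(zero_entries, 1.0, w)
        denom = np.bincount(
            alignments.cand_class, weights=w, minlength=alignments.n_classes
        )
    frac = (
        w
        / denom[alignments.cand_class]
        * alignments.class_multiplicity[alignments.cand_class]
    )
    mass = np.bincount(g_idx, weights=frac, minlength=int(offsets[-1]))
    return AllocatedProfile(mass=mass, offsets=offsets)


def update_abundance(
    profile: AllocatedProfile, transcriptome: Transcriptome
) -> AbundanceState:
    """Re-estimate CDS-length-normalized abundances from allocated mass."""
    c = profile.transcript_mass()
    if not np.any(c > 0):
        raise ValueError("all-zero allocated profile; cannot normalize abundances")
    lengths = transcriptome.cds_lengths_nt()
    density = c / lengths
    r = density / density.sum() * MILLION
    return AbundanceState(abundance=r, read_counts=c)


def run_prime(
    alignments: ReadAlignments,
    transcriptome: Transcriptome,
    n_iter: int = 200,
    tol: float = 1e-8,
) -> Tuple[AbundanceState, AllocatedProfile, List[float]]:
    """Alternate allocation and abundance update.

    Stops after ``n_iter`` iterations or when the largest per-transcript
    abundance change, as a fraction of 10^6, drops below ``tol``. Returns
    the final state, the profile allocated under the final abundances, and
    the per-iteration max-change history.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    state = initialize_uniform(transcriptome)
    history: List[float] = []
    profile = None
    for it in range(1, n_iter + 1):
        profile = allocate_reads(alignments, state, transcriptome)
        new_state = update_abundance(profile, transcriptome)
        delta = float(np.max(np.abs(new_state.abundance - state.abundance)) / MILLION)
        history.append(delta)
        new_state.iteration = it
        state = new_state
        if delta < tol:
            break
    # the reported profile reflects the final abundances
    profile = allocate_reads(alignments, state, transcriptome)
    return state, profile, history


class PrimeAllocator(BaseEstimator):
    """Abundance-guided multi-mapped read allocator (estimator interface).

    Parameters
    ----------
    n_iter : int
        Maximum allocate/update iterations (default 200).
    tol : float
        Convergence tolerance on the max per-transcript abundance change
        as a fraction of 10^6.

    Attributes
    ----------
    abundance_ : pandas.DataFrame
        Columns transcript_id, read_count (c_ri), abundance (r_i).
    r_ : ndarray — per-million CDS-length-normalized abundances.
    read_counts_ : ndarray — allocated read mass per transcript.
    profile_ : AllocatedProfile — per-codon allocated mass.
    n_iter_ : int — iterations actually run.
    history_ : list of float — max abundance change per iteration.
    """

    def __init__(self, n_iter: int = 200, tol: float = 1e-8):
        self.n_iter = n_iter
        self.tol = tol

    def fit(self, alignments: ReadAlignments, transcriptome: Transcriptome):
        state, profile, history = run_prime(
            alignments, transcriptome, n_iter=self.n_iter, tol=self.tol
        )
        self.transcriptome_ = transcriptome
        self.r_ = state.abundance
        self.read_counts_ = state.read_counts
        self.profile_ = profile
        self.n_iter_ = state.iteration
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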