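"""Downstream translation statistics and evaluation against ground truth.

Covers the length-normalized abundance scale shared by mRNA (TPM) and
ribosome (r_i) measurements, translation efficiency r_i/t_i, per-transcript
ribosome stalling calls (positions whose normalized density strictly
exceeds mu + 2 sigma), the Codon Residence Index (relative dwell of a codon
versus its synonymous codons on the same transcript), condition comparison
by paired Wilcoxon tests, and the accuracy metrics used on simulated data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from Bio.Data.CodonTable import standard_dna_table

from .mapping import ReadAlignments
from .prime import AbundanceState, AllocatedProfile, allocate_reads
from .shape import normalize_profile
from .transcriptome import CODONS, PAD_INDEX, Transcriptome

logger = logging.getLogger(__name__)

MILLION = 1_000_000.0


def _synonymous_families() -> List[List[int]]:
    """Codon-index families by encoded amino acid; stop codons form one family."""
    by_aa: Dict[str, List[int]] = {}
    for i, codon in enumerate(CODONS):
        aa = standard_dna_table.forward_table.get(codon, "*")
        by_aa.setdefault(aa, []).append(i)
    return list(by_aa.values())


SYNONYMOUS_FAMILIES = _synonymous_families()
_FAMILY_OF = np.empty(64, dtype=np.int64)
for _f, _members in enumerate(SYNONYMOUS_FAMILIES):
    for _m in _members:
        _FAMILY_OF[_m] = _f


def length_normalized_abundance(
    counts: np.ndarray, lengths: np.ndarray
) -> np.ndarray:
    """Per-million length-normalized abundance: (c_i/l_i)/sum_k(c_k/l_k)*1e6."""
    counts = np.asarray(counts, dtype=np.float64)
    lengths = np.asarray(lengths, dtype=np.float64)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    if not np.any(counts > 0):
        raise ValueError("all counts are zero")
    density = counts / lengths
    return density / density.sum() * MILLION


def translation_efficiency(
    ribo: pd.DataFrame, rna: pd.DataFrame
) -> pd.DataFrame:
    """TE = r_i / t_i on matched transcripts.

    ``ribo`` needs columns (transcript_id, abundance); ``rna`` columns
    (transcript_id, tpm). Transcripts with t_i = 0 are flagged undefined
    and carry NaN TE.
    """
    merged = ribo[["transcript_id", "abundance"]].merge(
        rna[["transcript_id", "tpm"]], on="transcript_id", how="inner"
    )
    t = merged["tpm"].to_numpy(dtype=np.float64)
    r = merged["abundance"].to_numpy(dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(t > 0, r / t, np.nan)
    merged["te"] = te
    merged["te_defined"] = t > 0
    return merged


@dataclass
class StallingCalls:
    """Positions called as stalling on one normalized profile."""

    positions: np.ndarray
    mu: float
    sigma: float


def detect_stalling(x: np.ndarray) -> StallingCalls:
    """Codon positions whose value strictly exceeds mu + 2 sigma.

    mu and sigma (population standard deviation) are taken over the
    transcript's own normalized profile, so calls are invariant to
    rescaling the whole profile. A uniform (sigma = 0) profile yields no
    calls because the inequality is strict.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("profile must have at least 2 positions")
    mu = float(x.mean())
    sigma = float(x.std())
    return StallingCalls(
        positions=np.nonzero(x > mu + 2.0 * sigma)[0], mu=mu, sigma=sigma
    )


def compute_cri(x: np.ndarray, codons: np.ndarray) -> np.ndarray:
    """Codon Residence Index of each codon on one transcript.

    For codon j with occurrences on the transcript, CRI_j is the mean
    normalized density over its occurrences divided by the average of the
    same means over j's synonymous codons present on the transcript
    (including j itself), minus 1. Codons absent from the transcript, and
    families whose occurrences carry zero density, are NaN. Positive CRI:
    the ribosome dwells longer on this codon than on its synonyms.
    """
    x = np.asarray(x, dtype=np.float64)
    codons = np.asarray(codons)
    if len(x) != len(codons):
        raise ValueError("profile and codon sequence lengths differ")
    out = np.full(64, np.nan)
    valid = codons < PAD_INDEX
    mean_x = np.full(64, np.nan)
    for j in np.unique(codons[valid]):
        mean_x[j] = x[codons == j].mean()
    for family in SYNONYMOUS_FAMILIES:
        present = [j for j in family if not np.isnan(mean_x[j])]
        if not present:
            continue
        denom = float(np.mean([mean_x[j] for j in present]))
        if denom <= 0:
            continue
        for j in present:
            out[j] = mean_x[j] / denom - 1.0
    return out


@dataclass
class CRITable:
    """Per-transcript CRI values plus the filtered per-codon summary."""

    per_transcript: pd.DataFrame  # index transcript_id, one column per codon
    summary: pd.DataFrame  # codon, mean_cri, n_transcripts
    condition: str = ""


def aggregate_cri(
    profiles: Sequence[Optional[np.ndarray]],
    transcriptome: Transcriptome,
    ribo_abundance: np.ndarray,
    rna_abundance: np.ndarray,
    min_abundance: float = 10.0,
    condition: str = "",
    weights: Optional[np.ndarray] = None,
) -> CRITable:
    """Mean CRI per codon over well-measured transcripts.

    ``profiles[i]`` is transcript i's normalized per-codon profile (None to
    skip). Transcripts must clear ``min_abundance`` on *both* the
    ribosome and mRNA length-normalized scales (strict inequality). The
    summary mean is unweighted unless per-transcript ``weights`` are given.
    """
    rows = []
    ids = []
    w = []
    for i, t in enumerate(transcriptome):
        x = profiles[i]
        if x is None:
            continue
        if not (ribo_abundance[i] > min_abundance and rna_abundance[i] > min_abundance):
            continue
        rows.append(compute_cri(x, transcriptome.codons(t.transcript_id)))
        ids.append(t.transcript_id)
        w.append(1.0 if weights is None else float(weights[i]))
    per_transcript = pd.DataFrame(rows, index=ids, columns=CODONS)
    if per_transcript.empty:
        logger.warning("no transcripts pass the abundance filter; empty CRI table")
        summary = pd.DataFrame({"codon": CODONS, "mean_cri": np.nan, "n_transcripts": 0})
        return CRITable(per_transcript, summary, condition)
    values = per_transcript.to_numpy()
    w = np.asarray(w)
    mask = ~np.isnan(values)
    wsum = (mask * w[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_cri = np.where(
            wsum > 0,
            np.nansum(values * w[:, None], axis=0) / np.where(wsum > 0, wsum, 1.0),
            np.nan,
        )
    summary = pd.DataFrame(
        {"codon": CODONS, "mean_cri": mean_cri, "n_transcripts": mask.sum(axis=0)}
    )
    return CRITable(per_transcript, summary, condition)


def compare_cri_conditions(
    table_a: CRITable, table_b: CRITable, min_pairs: int = 5
) -> pd.DataFrame:
    """Paired two-sided Wilcoxon signed-rank test per codon, A vs B.

    Transcripts present in both conditions with a defined CRI for the codon
    form the pairs. Codons with fewer than ``min_pairs`` pairs are flagged
    and skipped; all-zero difference vectors (e.g. identical conditions)
    are degenerate and reported with NaN p. Benjamini-Hochberg q-values are
    added across the tested codons; raw p-values are kept.
    """
    a = table_a.per_transcript
    b = table_b.per_transcript
    shared = a.index.intersection(b.index)
    records = []
    for codon in CODONS:
        va = a.loc[shared, codon].to_numpy()
        vb = b.loc[shared, codon].to_numpy()
        ok = ~(np.isnan(va) | np.isnan(vb))
        n = int(ok.sum())
        if n < min_pairs:
            records.append((codon, n, np.nan, np.nan, "too_few_pairs"))
            continue
        diff = va[ok] - vb[ok]
        if np.all(diff == 0):
            records.append((codon, n, 0.0, np.nan, "degenerate"))
            continue
        stat, p = stats.wilcoxon(va[ok], vb[ok], alternative="two-sided")
        records.append((codon, n, float(stat), float(p), "ok"))
    df = pd.DataFrame(
        records, columns=["codon", "n_pairs", "statistic", "p_value", "status"]
    )
    tested = df["p_value"].notna()
    q = np.full(len(df), np.nan)
    if tested.any():
        q[tested.to_numpy()] = multipletests(
            df.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    df["q_value"] = q
    return df


def uniform_baseline_profile(
    alignments: ReadAlignments, transcriptome: Transcriptome
) -> AllocatedProfile:
    """One-pass allocation splitting every read 1/|M| over its candidates."""
    n = len(transcriptome)
    state = AbundanceState(abundance=np.ones(n), read_counts=np.zeros(n))
    return allocate_reads(alignments, state, transcriptome)


def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def profile_pccs(
    estimated: AllocatedProfile, true_profiles: Sequence[np.ndarray]
) -> np.ndarray:
    """Per-transcript PCC between allocated and true per-codon mass.

    NaN where the true profile has no reads or either vector is constant.
    """
    out = np.full(len(true_profiles), np.nan)
    for i, truth in enumerate(true_profiles):
        if truth is None or truth.sum() <= 0:
            continue
        out[i] = _pcc(estimated.profile(i), truth)
    return out


def stalling_overlap(
    estimated: AllocatedProfile, true_profiles: Sequence[np.ndarray]
) -> Tuple[float, float, int, int, int]:
    """Sensitivity/precision of stalling calls on reconstructed profiles.

    Both truth and estimate are normalized per transcript and annotated
    with the strict mu + 2 sigma rule; counts are pooled over transcripts
    with any true reads. Returns (sensitivity, precision, n_true, n_called,
    n_overlap).
    """
    n_true = n_called = n_overlap = 0
    for i, truth in enumerate(true_profiles):
        if truth is None or truth.sum() <= 0:
            continue
        true_x = normalize_profile(truth)
        true_calls = set(detect_stalling(true_x).positions.tolist())
        est = estimated.profile(i)
        est_x = normalize_profile(est)
        est_calls = (
            set() if est_x is None else set(detect_stalling(est_x).positions.tolist())
        )
        n_true += len(true_calls)
        n_called += len(est_calls)
        n_overlap += len(true_calls & est_calls)
    sensitivity = n_overlap / n_true if n_true else float("nan")
    precision = n_overlap / n_called if n_called else float("nan")
    return sensitivity, precision, n_true, n_called, n_overlap


def evaluate(
    estimated_counts: np.ndarray,
    true_counts: np.ndarray,
    estimated_profile: AllocatedProfile,
    true_profiles: Sequence[np.ndarray],
    cds_lengths_nt: np.ndarray,
) -> Dict[str, float]:
    """Accuracy report against simulation ground truth.

    Abundance agreement on the raw count scale and the CDS-length-
    normalized per-million scale (PCC and MSE); the distribution of
    per-transcript profile PCCs (mean, and the fraction above 0.9 over all
    transcripts with true reads — undefined PCCs count against the
    fraction); and pooled stalling sensitivity/precision.
    """
    est_norm = length_normalized_abundance(estimated_counts, cds_lengths_nt)
    true_norm = length_normalized_abundance(true_counts, cds_lengths_nt)
    pccs = profile_pccs(estimated_profile, true_profiles)
    covered = np.array(
        [t is not None and t.sum() > 0 for t in true_profiles], dtype=bool
    )
    defined = covered & ~np.isnan(pccs)
    sens, prec, n_true, n_called, n_overlap = stalling_overlap(
        estimated_profile, true_profiles
    )
    return {
        "count_pcc": _pcc(estimated_counts, true_counts),
        "count_mse": float(np.mean((estimated_counts - true_counts) ** 2)),
        "normalized_pcc": _pcc(est_norm, true_norm),
        "normalized_mse": float(np.mean((est_norm - true_norm) ** 2)),
        "mean_profile_pcc": float(np.nanmean(pccs[covered])) if covered.any() else float("nan"),
        "fraction_profile_pcc_gt_0.9": (
            float((pccs[covered] > 0.9).sum() / covered.sum()) if covered.any() else float("nan")
        ),
        "n_profiles_evaluated": int(covered.sum()),
        "stalling_sensitivity": sens,
        "stalling_precision": prec,
        "stalling_true_events": n_true,
        "stalling_called_events": n_called,
        "stalling_overlap_events": n_overlap,
    }
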