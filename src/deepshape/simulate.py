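"""Synthetic Ribo-seq data with full ground truth.

The generator emulates the study conditions end to end: a multi-isoform
transcriptome whose isoforms share exons verbatim (so that short footprints
multi-map), log-normal transcript abundances and translation efficiencies,
per-transcript codon occupancy profiles from a ribosome flow model (RFM)
whose elongation rates depend on codon identity, and error-free 30-nt
footprint reads whose P-sites are drawn from those profiles.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded
from scipy.optimize import root as scipy_root

from .transcriptome import PAD_INDEX, Transcript, Transcriptome

logger = logging.getLogger(__name__)

MILLION = 1_000_000.0


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults are the desk-scale conditions used throughout the test-suite:
    300 genes with 1-3 exon-sharing isoforms each, CDS spanning the whole
    transcript, 2x10^5 error-free 30-nt footprints with a 12-nt P-site
    offset. TPM and TE are log-normal on the natural-log scale; RFM
    elongation rates are log-normal per codon identity so codon usage has a
    transcriptome-wide, recoverable effect on occupancy.
    """

    n_genes: int = 300
    isoforms_per_gene: Tuple[int, int] = (1, 3)
    exons_per_gene: Tuple[int, int] = (4, 8)
    exon_length_range: Tuple[int, int] = (90, 300)
    shared_exon_probability: float = 1.0
    frame_preserving_probability: float = 0.8
    tpm_lognormal_mu_sigma: Tuple[float, float] = (0.0, 2.0)
    isoform_dirichlet_alpha: float = 0.15
    te_lognormal_mu_sigma: Tuple[float, float] = (0.0, 1.0)
    n_ribo_reads: int = 200_000
    read_length: int = 30
    rfm_initiation_rate: float = 0.005
    rfm_codon_rate_sigma: float = 1.0
    psite_offset: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_ribo_reads <= 0:
            raise ValueError("counts must be positive")
        if self.read_length < 3:
            raise ValueError("read_length must be >= 3")
        if not 0.0 <= self.shared_exon_probability <= 1.0:
            raise ValueError("shared_exon_probability must be in [0, 1]")
        if self.rfm_initiation_rate <= 0:
            raise ValueError("rfm_initiation_rate must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream ``stream`` of this config's seed."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Per-transcript truth emitted by the simulator.

    ``table`` columns: transcript_id, tpm (t_i, sums to 10^6), te (r_i/t_i),
    te_target (the raw log-normal draw before renormalisation),
    ribo_abundance (r_i, CDS-length-normalized, sums to 10^6),
    ribo_read_count (c_ri). ``profiles`` are the RFM per-codon occupancy
    densities (each sums to 1). ``read_profiles`` — filled once footprints
    are generated — are the realised per-codon counts of emitted reads,
    the placement truth an allocator is asked to reconstruct.
    """

    table: pd.DataFrame
    profiles: List[np.ndarray] = field(default_factory=list)
    read_profiles: List[np.ndarray] = field(default_factory=list)

    @property
    def transcript_ids(self) -> List[str]:
        return list(self.table["transcript_id"])


@dataclass
class SyntheticReads:
    """Emitted footprints and their placement truth.

    ``sequences[k]`` is the read string of read ``read_ids[k]``;
    ``true_transcript_index[k]`` / ``true_codon[k]`` its source transcript
    (index in transcriptome order) and true P-site codon.
    """

    read_ids: List[str]
    sequences: List[str]
    true_transcript_index: np.ndarray
    true_codon: np.ndarray
    n_window_skipped: int = 0

    def __len__(self) -> int:
        return len(self.sequences)

    def write_fastq(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for rid, seq in zip(self.read_ids, self.sequences):
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_truth_tsv(self, path: Union[str, Path], transcript_ids: Sequence[str]) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\ttranscript_id\tpsite_codon\n")
            for rid, ti, cj in zip(self.read_ids, self.true_transcript_index, self.true_codon):
                fh.write(f"{rid}\t{transcript_ids[ti]}\t{cj}\n")


# ---------------------------------------------------------------------------
# transcriptome construction


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def generate_transcriptome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Transcriptome:
    """Build a multi-isoform transcriptome with verbatim-shared exons.

    Each gene gets a set of exon blocks; its first isoform concatenates all
    of them and further isoforms drop a random non-empty subset of internal
    exons (first and last exon always retained), so isoforms of a gene share
    exons verbatim. Exon lengths are drawn uniformly, so most are not a
    multiple of 3 and dropped exons shift the reading frame of everything
    downstream. The CDS spans the whole transcript, trimmed to a whole
    number of codons.
    """
    rng = config.rng(1) if rng is None else rng
    lo_iso, hi_iso = config.isoforms_per_gene
    lo_ex, hi_ex = config.exons_per_gene
    lo_len, hi_len = config.exon_length_range
    transcripts: List[Transcript] = []
    for g in range(config.n_genes):
        gene_id = f"G{g:04d}"
        n_exons = int(rng.integers(lo_ex, hi_ex + 1))
        exon_lengths = []
        for _ in range(n_exons):
            length = int(rng.integers(lo_len, hi_len + 1))
            if rng.random() < config.frame_preserving_probability:
                length -= length % 3  # dropping this exon keeps downstream frame
            elif length % 3 == 0:
                length += 1  # force a frame-shifting junction
            exon_lengths.append(length)
        exons = [_random_sequence(rng, length) for length in exon_lengths]
        n_iso = int(rng.integers(lo_iso, hi_iso + 1))
        used_drop_sets = {frozenset()}
        structures: List[Optional[List[str]]] = [exons]
        for _ in range(n_iso - 1):
            if rng.random() >= config.shared_exon_probability or n_exons < 3:
                structures.append(None)  # independent isoform, fresh sequence
                continue
            internal = list(range(1, n_exons - 1))
            for _attempt in range(20):
                drop = frozenset(i for i in internal if rng.random() < 0.4)
                if not drop:
                    drop = frozenset({internal[int(rng.integers(len(internal)))]})
                if drop not in used_drop_sets:
                    used_drop_sets.add(drop)
                    structures.append([e for i, e in enumerate(exons) if i not in drop])
                    break
        for k, structure in enumerate(structures):
            if structure is None:
                seq = _random_sequence(rng, sum(len(e) for e in exons))
            else:
                seq = "".join(structure)
            cds_end = 3 * (len(seq) // 3)
            transcripts.append(Transcript(f"{gene_id}.I{k + 1}", gene_id, seq, 0, cds_end))
    return Transcriptome(transcripts)


# ---------------------------------------------------------------------------
# abundances


def sample_ground_truth(
    transcriptome: Transcriptome,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> GroundTruth:
    """Draw transcript abundances, TEs, ribosome abundances and read counts.

    Gene expression is log-normal; within a gene, isoform usage follows a
    sparse symmetric Dirichlet (``isoform_dirichlet_alpha``), reproducing
    the strong single-isoform dominance of real transcriptomes — most
    genes express one major isoform and minor isoforms at a small
    fraction. t_i is the product, normalized per million; te a log-normal
    draw; r_i proportional to t_i * te_i, normalized per million. The
    expected read count of a transcript is proportional to r_i * l_ri
    (reads cover the CDS, so longer CDS at equal density catch more
    reads): c_ri = round(n_ribo_reads * r_i * l_ri / sum_k r_k * l_rk).
    """
    rng = config.rng(2) if rng is None else rng
    n = len(transcriptome)
    if n == 0:
        raise ValueError("empty transcriptome")
    mu_t, sigma_t = config.tpm_lognormal_mu_sigma
    mu_e, sigma_e = config.te_lognormal_mu_sigma
    tpm = np.empty(n)
    for gene_id, tids in transcriptome.genes.items():
        gene_expr = float(np.exp(rng.normal(mu_t, sigma_t)))
        fractions = rng.dirichlet(np.full(len(tids), config.isoform_dirichlet_alpha))
        for tid, frac in zip(tids, fractions):
            tpm[transcriptome.index_of(tid)] = gene_expr * frac
    tpm = tpm / tpm.sum() * MILLION
    te_target = np.exp(rng.normal(mu_e, sigma_e, size=n))
    r = tpm * te_target
    r = r / r.sum() * MILLION
    lengths = transcriptome.cds_lengths_nt()
    mass = r * lengths
    counts = np.rint(config.n_ribo_reads * mass / mass.sum()).astype(np.int64)
    table = pd.DataFrame(
        {
            "transcript_id": transcriptome.transcript_ids,
            "tpm": tpm,
            "te": r / tpm,
            "te_target": te_target,
            "ribo_abundance": r,
            "ribo_read_count": counts,
        }
    )
    return GroundTruth(table=table)


# ---------------------------------------------------------------------------
# ribosome flow model


def _rfm_solve_batch(
    site_rates: List[np.ndarray], initiation_rate: float, n_bisect: int = 100
) -> List[np.ndarray]:
    """Steady-state densities for many RFMs at once.

    The steady state carries a constant flux J: initiation
    J = lam_0 (1 - x_1), interior J = lam_j x_j (1 - x_{j+1}), exit
    J = lam_n x_n. Given J the profile satisfies two equivalent
    recursions, of which the forward one (from initiation,
    x_{j+1} = 1 - J/(lam_j x_j)) is numerically stable on the
    high-density branch and the backward one (from the exit,
    x_j = J/(lam_j (1 - x_{j+1}))) on the low-density branch. The true
    profile follows the forward branch upstream of the shock and the
    backward branch downstream; the two branches cross if and only if J
    does not exceed the steady-state flux, so J is found by bisection on
    the crossing predicate and the profile assembled piecewise, then
    polished to machine precision by damped Newton on the full dynamics.
    Transcripts are right-padded with infinite rates so everything
    vectorises across transcripts of unequal length.
    """
    n_tx = len(site_rates)
    lengths = np.array([len(r) for r in site_rates], dtype=np.int64)
    if np.any(lengths < 1):
        raise ValueError("RFM needs at least one site")
    l_max = int(lengths.max())
    rates = np.full((n_tx, l_max), np.inf)
    for i, r in enumerate(site_rates):
        if np.any(np.asarray(r) <= 0):
            raise ValueError("RFM rates must be positive")
        rates[i, : len(r)] = r
    cols = np.arange(l_max)[None, :]
    real = cols < lengths[:, None]
    lam0 = float(initiation_rate)

    def branches(J: np.ndarray):
        """Forward/backward branches plus cumulative numerical-stability flags.

        The forward map x -> 1 - J/(lam x) contracts while lam x^2 >= J
        (high density), the backward map x -> J/(lam (1 - x)) while
        lam (1 - x)^2 >= J (low density); the flags mark the prefix/suffix
        on which each branch can be trusted.
        """
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            f = np.empty((n_tx, l_max))
            f_ok = np.zeros((n_tx, l_max), dtype=bool)
            fc = np.broadcast_to(1.0 - J / lam0, (n_tx,)).copy()
            vf = (fc > 0.0) & (fc < 1.0)
            for c in range(l_max):
                if c > 0:
                    fc = 1.0 - J / (rates[:, c - 1] * fc)
                    fc = np.where(np.isfinite(fc), fc, 1.0)
                    vf = vf & (fc > 0.0) & (fc < 1.0)
                f[:, c] = fc
                vf = vf & (rates[:, c] * fc**2 >= J * (1.0 - 1e-9))
                f_ok[:, c] = vf
            b = np.empty((n_tx, l_max))
            b_ok = np.zeros((n_tx, l_max), dtype=bool)
            bc = np.zeros(n_tx)
            vb = np.ones(n_tx, dtype=bool)
            for c in range(l_max - 1, -1, -1):
                vb = vb & (rates[:, c] * (1.0 - bc) ** 2 >= J * (1.0 - 1e-9))
                bc = J / (rates[:, c] * (1.0 - bc))
                bc = np.where(np.isfinite(bc), bc, 0.0)
                vb = vb & (bc >= 0.0) & (bc < 1.0)
                b[:, c], b_ok[:, c] = bc, vb
        return f, f_ok, b, b_ok

    def handoffs(J: np.ndarray):
        """Per-transcript feasibility: some shock position m admits flux J.

        Position m means sites 1..m follow the forward branch and sites
        m+1..n the backward branch; the link constraint is
        lam_m f_m (1 - b_{m+1}) >= J (with the initiation/exit forms at
        m = 0 and m = n).
        """
        f, f_ok, b, b_ok = branches(J)
        # link[m] for m = 0..n stored in columns 0..n of an (n+1)-wide array
        link = np.full((n_tx, l_max + 1), -np.inf)
        ok = np.zeros((n_tx, l_max + 1), dtype=bool)
        b_pad = np.concatenate([b, np.zeros((n_tx, 1))], axis=1)
        b_ok_pad = np.concatenate([b_ok, np.ones((n_tx, 1), dtype=bool)], axis=1)
        # m = 0: initiation supplies the flux into the backward branch
        link[:, 0] = lam0 * (1.0 - b[:, 0])
        ok[:, 0] = b_ok[:, 0]
        # m >= 1: site m is column m-1
        with np.errstate(invalid="ignore"):
            link[:, 1:] = np.where(
                real, rates * f * (1.0 - b_pad[:, 1:]), -np.inf
            )
        ok[:, 1:] = real & f_ok & b_ok_pad[:, 1:]
        # at m = n the backward part is empty: b_ok beyond the last real
        # column is vacuously true via the padding above
        feasible = ok & (link >= J[:, None] * (1.0 - 1e-12))
        return feasible, link, f, b

    lo = np.zeros(n_tx)
    hi = np.full(n_tx, lam0)
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        ok = handoffs(mid)[0].any(axis=1)
        lo = np.where(ok, mid, lo)
        hi = np.where(ok, hi, mid)
    feasible, link, f, b = handoffs(lo)
    out = []
    for i in range(n_tx):
        n = int(lengths[i])
        cand = np.nonzero(feasible[i, : n + 1])[0]
        if len(cand) == 0:
            cand = np.array([0])
        m = int(cand[np.argmin(np.abs(link[i, cand] - lo[i]))])
        x = np.concatenate((f[i, :m], b[i, m:n]))
        x = np.clip(x, 1e-12, 1.0 - 1e-12)
        out.append(_rfm_polish(x, np.asarray(site_rates[i], dtype=np.float64), lam0))
    return out


def _rfm_residual(x: np.ndarray, s: np.ndarray, lam0: float) -> np.ndarray:
    """dx/dt of every site at state ``x`` (s = per-site rates)."""
    xp = np.concatenate((x, [0.0]))
    inflow = np.empty_like(x)
    inflow[0] = lam0 * (1.0 - x[0])
    inflow[1:] = s[:-1] * x[:-1] * (1.0 - x[1:])
    outflow = s * x * (1.0 - xp[1:])
    return inflow - outflow

def _rfm_polish(
    x: np.ndarray, s: np.ndarray, lam0: float, tol: float = 1e-12, max_iter: int = 50
) -> np.ndarray:
    """Newton refinement of an approximate RFM fixed point.

    The flux-bisection solution is exact in the flux but, for long chains
    near jamming, the back-substitution amplifies the last bits of flux
    error into the upstream densities; a few Newton steps on the full
    dynamics (tridiagonal Jacobian) restore the residual to machine
    precision.
    """
    n = len(x)
    x = x.copy()
    fnorm = np.max(np.abs(_rfm_residual(x, s, lam0)))
    mu = 0.0  # Levenberg-Marquardt shift; 0 is a pure Newton step
    for _ in range(max_iter):
        if fnorm < tol:
            return x
        F = _rfm_residual(x, s, lam0)
        xp = np.concatenate((x, [0.0]))
        # tridiagonal Jacobian in solve_banded (1,1) layout
        # dF_j/dx_j = -s_{j-1} x_{j-1} - s_j (1 - x_{j+1}); j=0 term uses lam0
        main = -(s * (1.0 - xp[1:]))
        main[0] -= lam0
        main[1:] -= s[:-1] * x[:-1]
        upper = np.zeros(n)
        upper[1:] = (s * x)[: n - 1]  # dF_j/dx_{j+1} = s_j x_j
        lower = np.zeros(n)
        lower[:-1] = s[:-1] * (1.0 - x[1:])  # dF_{j+1}/dx_j
        improved = False
        for _try in range(30):
            ab = np.vstack([upper, main - mu, lower])
            try:
                step = solve_banded((1, 1), ab, -F)
            except np.linalg.LinAlgError:
                mu = max(10.0 * mu, 1e-6)
                continue
            x_new = np.clip(x + step, 1e-14, 1.0 - 1e-14)
            fnorm_new = np.max(np.abs(_rfm_residual(x_new, s, lam0)))
            if np.isfinite(fnorm_new) and fnorm_new < fnorm:
                x, fnorm = x_new, fnorm_new
                mu *= 0.3  # ease back toward Newton
                improved = True
                break
            mu = max(10.0 * mu, 1e-6)  # regularize harder, step shrinks
        if not improved:
            break
    if fnorm > 1e-8:
        return _rfm_refine_hard(x, s, lam0)
    return x


def _rfm_refine_hard(x: np.ndarray, s: np.ndarray, lam0: float) -> np.ndarray:
    """Fallback for chains the banded Newton cannot finish.

    Multi-bottleneck chains can have shock structures the piecewise
    two-branch start misplaces; a trust-region root solve and, if needed,
    stiff integration of the dynamics over increasing horizons carry the
    state across the valley, after which Newton converges.
    """

    def fun(y):
        return _rfm_residual(y, s, lam0)

    def jac(y):
        n = len(y)
        yp = np.concatenate((y, [0.0]))
        J = np.zeros((n, n))
        main = -(s * (1.0 - yp[1:]))
        main[0] -= lam0
        main[1:] -= s[:-1] * y[:-1]
        np.fill_diagonal(J, main)
        for j in range(n - 1):
            J[j, j + 1] = s[j] * y[j]
            J[j + 1, j] = s[j] * (1.0 - y[j + 1])
        return J

    sol = scipy_root(fun, x, jac=jac, method="hybr", tol=1e-12)
    x = np.clip(sol.x, 1e-14, 1.0 - 1e-14)
    if np.max(np.abs(fun(x))) < 1e-9:
        return x
    for horizon in (1e4, 1e5, 1e6, 1e7):
        ivp = solve_ivp(
            lambda _, y: fun(y), (0.0, horizon), x,
            method="LSODA", lband=1, uband=1, rtol=1e-12, atol=1e-14,
        )
        x = np.clip(ivp.y[:, -1], 1e-14, 1.0 - 1e-14)
        if np.max(np.abs(fun(x))) < 1e-9:
            return x
    raise RuntimeError("RFM steady state failed to converge")


def rfm_steady_state(rates: Sequence[float], tol: float = 1e-8) -> np.ndarray:
    """Steady-state site densities of a ribosome flow model.

    ``rates`` is ``[lam_0, lam_1, ..., lam_n]``: initiation rate followed by
    the per-site elongation rates (the last of which doubles as the exit
    rate). Returns densities ``x_1..x_n`` in (0, 1). The dynamics are
    dx_j/dt = lam_{j-1} x_{j-1} (1 - x_j) - lam_j x_j (1 - x_{j+1}) with
    x_0 = 1 and free exit; the returned fixed point has residual below
    ``tol``.
    """
    rates = np.asarray(rates, dtype=np.float64)
    if rates.ndim != 1 or len(rates) < 2:
        raise ValueError("need initiation rate plus at least one site rate")
    x = _rfm_solve_batch([rates[1:]], float(rates[0]))[0]
    # constant-flux check: initiation, every interior bond, and exit
    x_next = np.concatenate((x[1:], [0.0]))
    flux = rates[1:] * x * (1.0 - x_next)
    flux0 = rates[0] * (1.0 - x[0])
    if np.max(np.abs(flux - flux0)) > tol:
        raise RuntimeError("RFM fixed point residual above tolerance")
    return x


def codon_rate_table(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Per-codon-identity elongation rates, log-normal around unit median.

    One draw per run: codon identity has a transcriptome-wide effect, which
    is what makes codon dwell-time statistics (CRI) recoverable downstream.
    """
    rng = config.rng(3) if rng is None else rng
    rates = np.exp(rng.normal(0.0, config.rfm_codon_rate_sigma, size=64))
    return rates


def make_profiles(
    transcriptome: Transcriptome,
    ground_truth: GroundTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Fill per-transcript codon occupancy profiles from RFM steady states.

    Elongation rate at a codon position is the transcriptome-wide rate of
    that codon identity; each profile is the steady-state density vector
    normalized to sum 1. Returns the codon rate table used.
    """
    rates64 = codon_rate_table(config, rng)
    site_rate_vectors = []
    for t in transcriptome:
        codons = transcriptome.codons(t.transcript_id)
        site_rates = np.where(codons == PAD_INDEX, 1.0, rates64[np.minimum(codons, 63)])
        site_rate_vectors.append(site_rates)
    densities = _rfm_solve_batch(site_rate_vectors, config.rfm_initiation_rate)
    ground_truth.profiles = [x / x.sum() for x in densities]
    return rates64


# ---------------------------------------------------------------------------
# reads


def generate_footprints(
    transcriptome: Transcriptome,
    ground_truth: GroundTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> "SyntheticReads":
    """Emit error-free footprint reads according to counts and profiles.

    For transcript i, ``ribo_read_count`` P-site codons are drawn from its
    occupancy profile; each read is the exact ``read_length`` substring
    whose 5' end sits ``psite_offset`` nt upstream of the P-site
    nucleotide. Draws whose read window would leave the transcript are
    skipped and counted (`n_window_skipped`), mirroring the edge losses of
    a real library. ``ground_truth.read_profiles`` is filled with the
    per-codon counts of the reads actually emitted.
    """
    if not ground_truth.profiles:
        raise ValueError("profiles must be generated before footprints")
    rng = config.rng(4) if rng is None else rng
    read_ids: List[str] = []
    sequences: List[str] = []
    true_tx: List[int] = []
    true_codon: List[int] = []
    read_profiles: List[np.ndarray] = []
    n_skipped = 0
    serial = 0
    counts_col = ground_truth.table["ribo_read_count"].to_numpy()
    for i, t in enumerate(transcriptome):
        profile = ground_truth.profiles[i]
        emitted = np.zeros(len(profile), dtype=np.float64)
        read_profiles.append(emitted)
        c = int(counts_col[i])
        if c == 0:
            continue
        if t.length < config.read_length:
            logger.warning(
                "transcript %s shorter than read length; skipped", t.transcript_id
            )
            n_skipped += c
            continue
        codon_counts = rng.multinomial(c, profile)
        for j in np.nonzero(codon_counts)[0]:
            start = t.cds_start + 3 * int(j) - config.psite_offset
            if start < 0 or start + config.read_length > t.length:
                n_skipped += int(codon_counts[j])
                continue
            seq = t.sequence[start : start + config.read_length]
            for _ in range(int(codon_counts[j])):
                read_ids.append(f"r{serial:08d}")
                sequences.append(seq)
                true_tx.append(i)
                true_codon.append(int(j))
                serial += 1
            emitted[j] += int(codon_counts[j])
    ground_truth.read_profiles = read_profiles
    return SyntheticReads(
        read_ids=read_ids,
        sequences=sequences,
        true_transcript_index=np.asarray(true_tx, dtype=np.int64),
        true_codon=np.asarray(true_codon, dtype=np.int64),
        n_window_skipped=n_skipped,
    )


def generate_rnaseq_abundance(
    ground_truth: GroundTruth, path: Optional[Union[str, Path]] = None
) -> pd.DataFrame:
    """Export the true transcript abundances as a (transcript_id, tpm) table.

    Stands in for read-level RNA-seq simulation: the downstream TE analysis
    only consumes TPM values.
    """
    df = ground_truth.table[["transcript_id", "tpm"]].copy()
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def simulate_dataset(
    config: SimulationConfig,
) -> Tuple[Transcriptome, GroundTruth, SyntheticReads]:
    """Run the full synthetic pipeline: transcriptome, truth, profiles, reads."""
    transcriptome = generate_transcriptome(config)
    truth = sample_ground_truth(transcriptome, config)
    make_profiles(transcriptome, truth, config)
    reads = generate_footprints(transcriptome, truth, config)
    return transcriptome, truth, reads
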