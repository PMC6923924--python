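"""Per-read candidate P-site assignments on transcripts.

A footprint's P-site is attributed to the nucleotide ``psite_offset``
downstream of its 5' end; reads whose P-site falls outside the CDS carry no
signal about coding-region occupancy and are excluded. Reads with identical
candidate sets are compressed into equivalence classes with a multiplicity,
which is what the iterative allocators operate on (mathematically identical
to per-read allocation, much cheaper).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .simulate import SyntheticReads
from .transcriptome import Transcript, Transcriptome

logger = logging.getLogger(__name__)


def psite_codon(transcript: Transcript, five_prime_pos: int, offset: int) -> Optional[int]:
    """Codon index of the P-site of a read starting at ``five_prime_pos``.

    The P-site nucleotide is ``five_prime_pos + offset``; returns its codon
    index within the CDS, or ``None`` when it lies outside ``[cds_start,
    cds_end)``.
    """
    n = five_prime_pos + offset
    if transcript.cds_start <= n < transcript.cds_end:
        return (n - transcript.cds_start) // 3
    return None


@dataclass
class ReadAlignments:
    """Candidate (transcript, P-site codon) sets for a read population.

    Candidates are stored flattened: entry ``k`` belongs to equivalence
    class ``cand_class[k]`` and points at codon ``cand_codon[k]`` of
    transcript ``cand_tx[k]`` (index in transcriptome order);
    ``class_multiplicity[c]`` reads share class ``c``'s candidate set.
    """

    cand_class: np.ndarray
    cand_tx: np.ndarray
    cand_codon: np.ndarray
    class_multiplicity: np.ndarray
    n_reads: int
    n_dropped: int
    read_class: Optional[Dict[str, int]] = None

    @property
    def n_classes(self) -> int:
        return len(self.class_multiplicity)

    @property
    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.cand_class, minlength=self.n_classes)

    @property
    def unique_mapping_fraction(self) -> float:
        """Fraction of retained reads with exactly one candidate."""
        if self.n_reads == 0:
            return float("nan")
        sizes = self.class_sizes
        return float(self.class_multiplicity[sizes == 1].sum() / self.n_reads)

    def candidates_of(self, read_id: str) -> List[Tuple[int, int]]:
        """Candidate (transcript index, codon) list of one read, if retained."""
        if self.read_class is None:
            raise ValueError("read ids were not retained")
        c = self.read_class[read_id]
        mask = self.cand_class == c
        return list(zip(self.cand_tx[mask].tolist(), self.cand_codon[mask].tolist()))


def build_alignments(
    per_read: Iterable[Tuple[str, Sequence[Tuple[int, int]]]],
    keep_read_ids: bool = True,
) -> ReadAlignments:
    """Compress per-read candidate lists into equivalence classes."""
    class_of: Dict[Tuple[Tuple[int, int], ...], int] = {}
    mult: List[int] = []
    flat_class: List[int] = []
    flat_tx: List[int] = []
    flat_codon: List[int] = []
    read_class: Optional[Dict[str, int]] = {} if keep_read_ids else None
    n_reads = 0
    n_dropped = 0
    for read_id, candidates in per_read:
        key = tuple(sorted(set(candidates)))
        if not key:
            n_dropped += 1
            continue
        n_reads += 1
        c = class_of.get(key)
        if c is None:
            c = len(mult)
            class_of[key] = c
            mult.append(0)
            for tx, codon in key:
                flat_class.append(c)
                flat_tx.append(tx)
                flat_codon.append(codon)
        mult[c] += 1
        if read_class is not None:
            read_class[read_id] = c
    return ReadAlignments(
        cand_class=np.asarray(flat_class, dtype=np.int64),
        cand_tx=np.asarray(flat_tx, dtype=np.int64),
        cand_codon=np.asarray(flat_codon, dtype=np.int64),
        class_multiplicity=np.asarray(mult, dtype=np.float64),
        n_reads=n_reads,
        n_dropped=n_dropped,
        read_class=read_class,
    )


def _iter_fastq(path: Union[str, Path]) -> Iterator[Tuple[str, str]]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header[1:].strip().split()[0], seq


def _occurrence_index(
    transcriptome: Transcriptome, lengths: Sequence[int]
) -> Dict[str, List[Tuple[int, int]]]:
    """Exact substring index: sequence -> [(transcript index, position)]."""
    index: Dict[str, List[Tuple[int, int]]] = {}
    for i, t in enumerate(transcriptome):
        seq = t.sequence
        has_n = "N" in seq
        for L in lengths:
            for p in range(len(seq) - L + 1):
                window = seq[p : p + L]
                if has_n and "N" in window:
                    continue
                index.setdefault(window, []).append((i, p))
    return index


def map_reads_exact(
    reads: Union[str, Path, SyntheticReads, Iterable[Tuple[str, str]]],
    transcriptome: Transcriptome,
    psite_offset: int = 12,
    min_read_length: Optional[int] = None,
    max_read_length: Optional[int] = None,
    keep_read_ids: bool = False,
) -> ReadAlignments:
    """Map reads by exact substring occurrence over all transcripts.

    Every exact occurrence of a read in any transcript becomes a candidate,
    converted to a P-site codon via ``psite_offset``; occurrences whose
    P-site leaves the CDS are discarded, and reads left with no candidate
    are dropped and counted. Reads containing ``N`` never match.
    """
    if isinstance(reads, SyntheticReads):
        pairs: Iterable[Tuple[str, str]] = zip(reads.read_ids, reads.sequences)
    elif isinstance(reads, (str, Path)):
        pairs = _iter_fastq(reads)
    else:
        pairs = reads
    pairs = [
        (rid, seq.upper())
        for rid, seq in pairs
        if (min_read_length is None or len(seq) >= min_read_length)
        and (max_read_length is None or len(seq) <= max_read_length)
    ]
    lengths = sorted({len(seq) for _, seq in pairs})
    index = _occurrence_index(transcriptome, lengths)

    def candidates() -> Iterator[Tuple[str, List[Tuple[int, int]]]]:
        for rid, seq in pairs:
            cands = []
            for tx, pos in index.get(seq, ()):  # N-containing reads miss the index
                codon = psite_codon(transcriptome.transcripts[tx], pos, psite_offset)
                if codon is not None:
                    cands.append((tx, codon))
            yield rid, cands

    return build_alignments(candidates(), keep_read_ids=keep_read_ids)


def load_alignments(
    sam_or_bam: Union[str, Path],
    transcriptome: Transcriptome,
    psite_offset: int = 12,
    min_read_length: Optional[int] = None,
    max_read_length: Optional[int] = None,
    keep_read_ids: bool = False,
) -> ReadAlignments:
    """Build candidate sets from transcriptome-space SAM/BAM alignments.

    Primary and secondary records of a read each contribute one candidate;
    leading soft-clips shift the 5' end upstream before the P-site offset
    is applied. Reverse-strand records are discarded (Ribo-seq
    transcriptome alignments are sense), as are records on references
    absent from the transcriptome (with a warning).
    """
    per_read: Dict[str, List[Tuple[int, int]]] = {}
    mode = "rb" if str(sam_or_bam).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(sam_or_bam), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_reverse:
                continue
            qlen = rec.query_length or (rec.infer_read_length() or 0)
            if min_read_length is not None and qlen < min_read_length:
                continue
            if max_read_length is not None and qlen > max_read_length:
                continue
            ref = rec.reference_name
            per_read.setdefault(rec.query_name, [])
            if ref not in transcriptome:
                logger.warning("reference %s absent from transcriptome; record skipped", ref)
                continue
            left_clip = 0
            if rec.cigartuples and rec.cigartuples[0][0] == 4:  # leading soft clip
                left_clip = rec.cigartuples[0][1]
            five_prime = rec.reference_start - left_clip
            tx = transcriptome.index_of(ref)
            codon = psite_codon(transcriptome.transcripts[tx], five_prime, psite_offset)
            if codon is not None:
                per_read[rec.query_name].append((tx, codon))
    return build_alignments(per_read.items(), keep_read_ids=keep_read_ids)
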