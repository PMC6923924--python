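"""Transcript sequences, CDS annotation and codon-level views.

Everything downstream (read allocation, shape modelling, codon statistics)
operates in transcript coordinates on whole codons of the coding region.
Coordinates are 0-based half-open internally; codon index for a CDS
nucleotide ``n`` is ``(n - cds_start) // 3``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple, Union

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Lexicographic codon alphabet order.
NUCLEOTIDES = "ACGT"

#: Embedding index used both for codons containing N and for positions
#: outside the CDS when building context windows.
PAD_INDEX = 64

_NT_TO_IDX = {c: i for i, c in enumerate(NUCLEOTIDES)}

#: All 64 codons in lexicographic order (AAA, AAC, ..., TTT).
CODONS = [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]
_CODON_TO_IDX = {codon: i for i, codon in enumerate(CODONS)}


def encode_codon(codon: str) -> int:
    """Map a codon string to its lexicographic index in ``0..63``.

    Codons containing any character outside ``ACGT`` (e.g. ``N``) map to
    :data:`PAD_INDEX`.
    """
    return _CODON_TO_IDX.get(codon.upper(), PAD_INDEX)


def decode_codon(index: int) -> str:
    """Inverse of :func:`encode_codon` for indices in ``0..63``."""
    return CODONS[index]


@dataclass
class Transcript:
    """A transcript sequence with its CDS interval.

    ``cds_start``/``cds_end`` are 0-based half-open nucleotide coordinates on
    the transcript. ``length`` is the transcript length in nucleotides and
    ``cds_length`` the CDS length in nucleotides (a multiple of 3).
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    def validate(self) -> Optional[str]:
        """Return a reason string if the transcript violates an invariant."""
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            return "CDS interval outside transcript bounds"
        if self.cds_length % 3 != 0:
            return "CDS length not a multiple of 3"
        if self.n_codons < 3:
            return "CDS shorter than 3 codons"
        if set(self.sequence) - set("ACGTN"):
            return "sequence contains characters outside ACGTN"
        return None


def cds_codons(transcript: Transcript) -> np.ndarray:
    """Encode the CDS of ``transcript`` as an array of codon indices.

    Returns an ``int16`` array of length ``cds_length // 3``; codons
    containing ``N`` carry the sentinel :data:`PAD_INDEX`.
    """
    cds = transcript.cds_sequence
    n = len(cds) // 3
    out = np.empty(n, dtype=np.int16)
    for j in range(n):
        out[j] = encode_codon(cds[3 * j : 3 * j + 3])
    return out


def decode_codons(indices: Iterable[int]) -> str:
    """Decode codon indices back to a nucleotide string (N-free codons only)."""
    return "".join(decode_codon(int(i)) for i in indices)


class Transcriptome:
    """An ordered collection of validated transcripts grouped by gene."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts: List[Transcript] = list(transcripts)
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript ids")
        self._index: Dict[str, int] = {tid: i for i, tid in enumerate(ids)}
        self.genes: Dict[str, List[str]] = {}
        for t in self.transcripts:
            self.genes.setdefault(t.gene_id, []).append(t.transcript_id)
        self._codon_cache: Dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._index

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self.transcripts[self._index[transcript_id]]

    def index_of(self, transcript_id: str) -> int:
        return self._index[transcript_id]

    @property
    def transcript_ids(self) -> List[str]:
        return [t.transcript_id for t in self.transcripts]

    def codons(self, transcript_id: str) -> np.ndarray:
        """Cached codon-index array for a transcript's CDS."""
        if transcript_id not in self._codon_cache:
            self._codon_cache[transcript_id] = cds_codons(self[transcript_id])
        return self._codon_cache[transcript_id]

    def cds_lengths_nt(self) -> np.ndarray:
        """CDS lengths in nucleotides, in transcript order."""
        return np.array([t.cds_length for t in self.transcripts], dtype=np.float64)

    def codon_counts(self) -> np.ndarray:
        """CDS lengths in codons, in transcript order."""
        return np.array([t.n_codons for t in self.transcripts], dtype=np.int64)


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_annotation_tsv(path: Union[str, Path]) -> Dict[str, Tuple[str, int, int]]:
    """Read the simple TSV dialect: transcript_id, gene_id, cds_start, cds_end.

    A header line starting with ``transcript_id`` is permitted and skipped.
    """
    out: Dict[str, Tuple[str, int, int]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "transcript_id":
                continue
            tid, gid, start, end = parts[0], parts[1], int(parts[2]), int(parts[3])
            out[tid] = (gid, start, end)
    return out


def _read_annotation_gtf(path: Union[str, Path]) -> Dict[str, Tuple[str, int, int]]:
    """Read CDS features from a GTF whose coordinates are in transcript space.

    The CDS interval of a transcript is the union (min start, max end) of its
    CDS features, converted from GTF's 1-based inclusive convention.
    """
    cds: Dict[str, List[Tuple[int, int]]] = {}
    gene_of: Dict[str, str] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "CDS":
                continue
            attrs = {}
            for item in fields[8].strip().split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, value = item.partition(" ")
                attrs[key] = value.strip().strip('"')
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            gene_of[tid] = attrs.get("gene_id", tid)
            cds.setdefault(tid, []).append((int(fields[3]) - 1, int(fields[4])))
    return {
        tid: (gene_of[tid], min(s for s, _ in ivs), max(e for _, e in ivs))
        for tid, ivs in cds.items()
    }


def load_transcriptome(
    fasta_path: Union[str, Path],
    annotation_path: Union[str, Path],
) -> Transcriptome:
    """Load transcript sequences (FASTA) and CDS annotation (GTF or TSV).

    Transcripts present in the annotation but absent from the FASTA are
    skipped with a warning, as are transcripts violating CDS invariants
    (interval out of bounds, CDS not a whole number of codons, CDS shorter
    than 3 codons).
    """
    fasta_path = Path(fasta_path)
    annotation_path = Path(annotation_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    if not annotation_path.exists():
        raise FileNotFoundError(annotation_path)

    with _open_text(fasta_path) as fh:
        sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}

    name = annotation_path.name.lower()
    if name.endswith((".gtf", ".gtf.gz", ".gff", ".gff.gz")):
        annotation = _read_annotation_gtf(annotation_path)
    else:
        annotation = _read_annotation_tsv(annotation_path)

    transcripts = []
    for tid, (gid, start, end) in annotation.items():
        if tid not in sequences:
            logger.warning("transcript %s in annotation but not in FASTA; skipped", tid)
            continue
        t = Transcript(tid, gid, sequences[tid], start, end)
        reason = t.validate()
        if reason is not None:
            logger.warning("transcript %s dropped: %s", tid, reason)
            continue
        transcripts.append(t)
    return Transcriptome(transcripts)
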