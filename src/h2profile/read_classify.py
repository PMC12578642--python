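"""Translated homology classification of short reads against the reference DB.

Reads are translated in all six frames (bacterial/archaeal code, table 11),
each frame is aligned to candidate reference proteins with affine-gap local
Smith–Waterman (BLOSUM62, gap open 11 / extend 1, BLAST cost convention), and
the single best-scoring hit is kept if it survives two filters: a minimum
aligned length (default 28 aa; 26 aa under the health-status profile) and the
best-hit family's minimum percent identity (the 50/60/70 scheme).  Filters
apply to the best hit only — a read whose best hit fails is unclassified, with
no fallback to lower-scoring references.

Candidate references are found with an exact amino-acid k-mer seed index
(default k=5), the same seed-and-extend shape as a translated BLAST search;
``seed_len=0`` disables seeding and scores every (frame, reference) pair.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

from .reference_db import ReferenceDB, threshold_for

__all__ = [
    "Read",
    "Alignment",
    "Hit",
    "HitSet",
    "ClassifyParams",
    "ReferenceIndex",
    "six_frame_translate",
    "local_align",
    "classify_read",
    "classify_reads",
    "read_sequences",
    "write_hits_tsv",
]

logger = logging.getLogger(__name__)

FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _codon_map(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


_CODON_CACHE: dict[int, dict[str, str]] = {}


@dataclass(frozen=True)
class Read:
    read_id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.read_id}: quality/sequence length mismatch")

    def reverse_complement(self) -> "Read":
        rc = self.seq.translate(_COMPLEMENT)[::-1]
        qual = self.qual[::-1] if self.qual is not None else None
        return Read(self.read_id, rc, qual)


@dataclass(frozen=True)
class Alignment:
    """Statistics of one local protein alignment.

    ``identity_pct`` is identities divided by alignment columns *including*
    gap columns; ``aligned_len_aa`` counts query residues inside the aligned
    region.  Ranges are 0-based half-open residue intervals.
    """

    score: float
    n_columns: int
    n_identities: int
    aligned_len_aa: int
    q_range: tuple[int, int]
    t_range: tuple[int, int]

    @property
    def identity_pct(self) -> float:
        if self.n_columns == 0:
            return 0.0
        return 100.0 * self.n_identities / self.n_columns


@dataclass(frozen=True)
class Hit:
    read_id: str
    seq_id: str
    family_id: str
    frame: int
    alignment: Alignment


@dataclass
class ClassifyParams:
    """Tunable knobs of the classification stage.

    ``min_len_aa``: minimum aligned query length in residues (28 default,
    26 in the health-status profile).  ``min_score``: optional raw-score
    floor, off by default.  ``seed_len``: exact k-mer seed length for
    candidate selection; 0 = exhaustive search.
    """

    min_len_aa: int = 28
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    genetic_code: int = 11
    min_score: float | None = None
    seed_len: int = 5

    def __post_init__(self) -> None:
        if self.min_len_aa < 1:
            raise ValueError("min_len_aa must be >= 1")
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")


@dataclass
class HitSet:
    """Outcome of screening a read stream: retained hits plus tallies."""

    hits: list[Hit]
    total_reads: int

    @property
    def family_counts(self) -> Counter:
        return Counter(h.family_id for h in self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def six_frame_translate(seq: str, genetic_code: int = 11) -> dict[int, str]:
    """Translate ``seq`` in frames +1, +2, +3, -1, -2, -3.

    Trailing partial codons are dropped; codons containing N (or any
    non-ACGT letter) yield X; stop codons appear as ``*`` and never align as
    matches.
    """
    if not seq:
        raise ValueError("cannot translate an empty sequence")
    codons = _CODON_CACHE.get(genetic_code)
    if codons is None:
        codons = _CODON_CACHE[genetic_code] = _codon_map(genetic_code)
    seq = seq.upper()
    rc = seq.translate(_COMPLEMENT)[::-1]
    out: dict[int, str] = {}
    for frame in FRAMES:
        template = seq if frame > 0 else rc
        off = abs(frame) - 1
        n = (len(template) - off) // 3
        out[frame] = "".join(
            codons.get(template[off + 3 * i : off + 3 * i + 3], "X") for i in range(n)
        )
    return out


def _make_aligner(params: ClassifyParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # BLAST cost convention: a gap of length k costs open + k*extend, so the
    # first gap column scores -(open + extend).
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


_ALIGNER_CACHE: dict[tuple, PairwiseAligner] = {}


def _aligner_for(params: ClassifyParams) -> PairwiseAligner:
    key = (params.matrix, params.gap_open, params.gap_extend)
    aligner = _ALIGNER_CACHE.get(key)
    if aligner is None:
        aligner = _ALIGNER_CACHE[key] = _make_aligner(params)
    return aligner


def _alignment_stats(aln) -> Alignment:
    counts = aln.counts()
    coords = aln.coordinates
    t_start, t_end = int(coords[0, 0]), int(coords[0, -1])
    q_start, q_end = int(coords[1, 0]), int(coords[1, -1])
    n_columns = counts.identities + counts.mismatches + counts.gaps
    return Alignment(
        score=float(aln.score),
        n_columns=int(n_columns),
        n_identities=int(counts.identities),
        aligned_len_aa=q_end - q_start,
        q_range=(q_start, q_end),
        t_range=(t_start, t_end),
    )


def local_align(query: str, target: str, params: ClassifyParams | None = None) -> Alignment:
    """Optimal affine-gap local alignment of two peptides.

    Deterministic: among co-optimal tracebacks the aligner's canonical first
    path is reported; the score is the exact Smith–Waterman optimum.
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty peptides")
    params = params or ClassifyParams()
    aligner = _aligner_for(params)
    # target is the first PairwiseAligner argument so coordinates rows are
    # (target, query); keep this consistent with _alignment_stats.
    alignments = aligner.align(target, query)
    if len(alignments) == 0 or alignments.score <= 0:
        return Alignment(0.0, 0, 0, 0, (0, 0), (0, 0))
    return _alignment_stats(alignments[0])


class ReferenceIndex:
    """Exact amino-acid k-mer index over reference proteins.

    Maps each k-mer to the set of reference seq_ids containing it; a frame
    peptide's candidate references are the union over its k-mers.  With
    ``seed_len=0`` every reference is a candidate (exhaustive mode).
    """

    def __init__(self, db: ReferenceDB, seed_len: int = 5):
        self.db = db
        self.seed_len = seed_len
        self._kmers: dict[str, set[str]] = {}
        if seed_len > 0:
            for seq in db.sequences.values():
                prot = seq.protein
                for i in range(len(prot) - seed_len + 1):
                    self._kmers.setdefault(prot[i : i + seed_len], set()).add(seq.seq_id)

    def candidates(self, peptide: str) -> set[str]:
        if self.seed_len == 0:
            return set(self.db.sequences)
        k = self.seed_len
        found: set[str] = set()
        for i in range(len(peptide) - k + 1):
            ids = self._kmers.get(peptide[i : i + k])
            if ids:
                found |= ids
        return found


def classify_read(
    read: Read,
    db: ReferenceDB,
    params: ClassifyParams | None = None,
    index: ReferenceIndex | None = None,
) -> Hit | None:
    """Best translated hit for one read, or None if it fails the filters.

    The best hit maximizes alignment score over frames x candidate
    references; score ties break toward higher identity, then lexicographically
    smallest seq_id.  The aligned-length and per-family identity filters are
    applied to the best hit only.
    """
    params = params or ClassifyParams()
    if index is None:
        index = ReferenceIndex(db, params.seed_len)
    aligner = _aligner_for(params)
    frames = six_frame_translate(read.seq, params.genetic_code)

    best_score = 0.0
    best_pairs: list[tuple[int, str]] = []  # (frame, seq_id) at best_score
    for frame, peptide in frames.items():
        if len(peptide) < 1:
            continue
        for seq_id in index.candidates(peptide):
            score = aligner.score(db.sequences[seq_id].protein, peptide)
            if score > best_score:
                best_score = score
                best_pairs = [(frame, seq_id)]
            elif score == best_score and score > 0:
                best_pairs.append((frame, seq_id))
    if not best_pairs:
        return None
    if params.min_score is not None and best_score < params.min_score:
        return None

    # Resolve ties with full alignments: higher identity, then smallest seq_id.
    resolved: list[tuple[float, str, int, Alignment]] = []
    for frame, seq_id in best_pairs:
        aln = local_align(frames[frame], db.sequences[seq_id].protein, params)
        resolved.append((-aln.identity_pct, seq_id, frame, aln))
    resolved.sort(key=lambda item: (item[0], item[1]))
    _, seq_id, frame, aln = resolved[0]

    if aln.aligned_len_aa < params.min_len_aa:
        return None
    family_id = db.sequences[seq_id].family_id
    if aln.identity_pct < threshold_for(db, family_id):
        return None
    return Hit(read.read_id, seq_id, family_id, frame, aln)


def classify_reads(
    reads: Iterable[Read],
    db: ReferenceDB,
    params: ClassifyParams | None = None,
) -> HitSet:
    """Screen a read stream; order-independent counts, bounded memory."""
    params = params or ClassifyParams()
    index = ReferenceIndex(db, params.seed_len)
    hits: list[Hit] = []
    total = 0
    for read in reads:
        total += 1
        hit = classify_read(read, db, params, index)
        if hit is not None:
            hits.append(hit)
        if total % 20000 == 0:
            logger.info("screened %d reads, %d classified", total, len(hits))
    return HitSet(hits=hits, total_reads=total)


def read_sequences(path: str | Path) -> Iterator[Read]:
    """Stream reads from FASTQ or FASTA, gzip-compressed or plain.

    Format is inferred from the filename (.fastq/.fq vs .fasta/.fa/.fna).
    A malformed record raises with the index of the offending record.
    """
    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        parser = SeqIO.parse(fh, fmt)
        i = 0
        while True:
            try:
                record = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed {fmt} record #{i} in {path}: {exc}") from exc
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in record.letter_annotations["phred_quality"]
                )
            yield Read(record.id, str(record.seq).upper(), qual)
            i += 1


def write_hits_tsv(hitset: HitSet, path: str | Path) -> None:
    """Write retained hits as TSV (0-based half-open coordinates)."""
    with open(path, "w") as fh:
        fh.write(
            "read_id\tseq_id\tfamily_id\tframe\tscore\tidentity_pct\t"
            "aligned_len_aa\tq_start\tq_end\tt_start\tt_end\n"
        )
        for h in hitset.hits:
            a = h.alignment
            fh.write(
                f"{h.read_id}\t{h.seq_id}\t{h.family_id}\t{h.frame:+d}\t"
                f"{a.score:g}\t{a.identity_pct:.4f}\t{a.aligned_len_aa}\t"
                f"{a.q_range[0]}\t{a.q_range[1]}\t{a.t_range[0]}\t{a.t_range[1]}\n"
            )
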