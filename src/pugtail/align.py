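"""Ends-free read mapping with explicit soft clips, plus SAM interchange.

Reads are placed on a multi-reference set (viral segments plus the spike-in)
with a local affine-gap alignment (Gotoh recurrences, vectorized per row).
Read ends that do not align — where a non-templated tail and any adapter
remnant live — are reported as terminal soft clips, which is the contract the
downstream tail caller consumes.  SAM text is read and written through pysam
so external aligners are interchangeable with the built-in one.

Coordinates are 0-based half-open internally; SAM I/O converts to/from the
1-based convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from ._util import revcomp
from .prep import ReadRecord

logger = logging.getLogger(__name__)

NEG = np.int32(-(10**6))

Cigar = List[Tuple[str, int]]

_QUERY_OPS = {"M", "=", "X", "I", "S"}
_REF_OPS = {"M", "=", "X", "D"}
_PYSAM_OP = {0: "M", 1: "I", 2: "D", 4: "S", 7: "=", 8: "X"}
_OP_PYSAM = {v: k for k, v in _PYSAM_OP.items()}


@dataclass(frozen=True)
class ScoringParams:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -4  # score of the first base of a gap
    gap_extend: int = -2
    band: Optional[int] = 100  # None => exhaustive DP over the whole reference
    seed_k: int = 12
    min_score: int = 40  # below this the read is reported unmapped

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


@dataclass
class AlignmentRecord:
    """Placement of a read on a reference.

    ``cigar`` is in SAM orientation: for strand "-" it describes the reverse
    complement of the read, exactly as the sequence would be stored in SAM.
    Soft clips occur only at the two ends.
    """

    read_id: str
    ref_id: str
    strand: str  # "+" or "-"
    ref_start: int  # 0-based
    cigar: Cigar = field(default_factory=list)
    score: int = 0
    ambiguous: bool = False

    @property
    def is_unmapped(self) -> bool:
        return self.ref_id == "*"

    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_OPS)

    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    def validate(self, read_len: Optional[int] = None, ref_len: Optional[int] = None) -> None:
        interior = self.cigar[1:-1] if len(self.cigar) > 2 else []
        if any(op == "S" for op, _ in interior):
            raise ValueError("soft clips allowed only at alignment ends")
        if read_len is not None and self.query_length() != read_len:
            raise ValueError("CIGAR query length != read length")
        if ref_len is not None and self.ref_start + self.ref_span() > ref_len:
            raise ValueError("alignment overruns the reference")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _sw_matrices(read: str, ref: str, p: ScoringParams):
    """Fill local affine-gap DP matrices (Gotoh), vectorized along the reference.

    H is the running best; E is the gap-in-read state (consumes reference, D);
    F is the gap-in-reference state (consumes read, I); G = max(0, diagonal, F)
    is the best non-E score, from which E opens (re-opening from an E-valued H
    is dominated because gap_open <= gap_extend).
    """
    m, n = len(read), len(ref)
    match, mismatch = np.int32(p.match), np.int32(p.mismatch)
    go, ge = np.int32(p.gap_open), np.int32(p.gap_extend)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    G = np.zeros((m + 1, n + 1), dtype=np.int32)
    refv = _encode(ref)
    readv = _encode(read)
    j_idx = np.arange(1, n + 1, dtype=np.int32)
    k_term = go - ge * np.arange(1, n + 1, dtype=np.int32)  # go - ge*(k+1) for k=0..n-1
    for i in range(1, m + 1):
        s = np.where(refv == readv[i - 1], match, mismatch)
        diag = H[i - 1, :-1] + s
        F[i, 1:] = np.maximum(H[i - 1, 1:] + go, F[i - 1, 1:] + ge)
        Grow = np.maximum(np.maximum(diag, F[i, 1:]), 0)
        G[i, 1:] = Grow
        u = G[i, :-1] + k_term
        E[i, 1:] = ge * j_idx + np.maximum.accumulate(u)
        H[i, 1:] = np.maximum(Grow, E[i, 1:])
    return H, E, F, G


def _traceback(read: str, ref: str, p: ScoringParams, H, E, F, G, end: Tuple[int, int]):
    """Recover one optimal path ending at ``end``; returns (qstart, qend, rstart, ops)."""
    go, ge = p.gap_open, p.gap_extend
    i, j = end
    ops: List[str] = []
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            state = "E" if H[i, j] == E[i, j] else "G"
            continue
        if state == "G":
            v = G[i, j]
            if v == 0:
                break
            s = p.match if read[i - 1] == ref[j - 1] else p.mismatch
            if v == H[i - 1, j - 1] + s:
                ops.append("M")
                i -= 1
                j -= 1
                state = "H"
            elif v == F[i, j]:
                state = "F"
            else:  # pragma: no cover - matrix inconsistency
                raise AssertionError("traceback failed in state G")
            continue
        if state == "E":
            ops.append("D")
            if G[i, j - 1] + go == E[i, j]:
                j -= 1
                state = "G"
            else:
                j -= 1
                state = "E"
            continue
        # state == "F"
        ops.append("I")
        if H[i - 1, j] + go == F[i, j]:
            i -= 1
            state = "H"
        else:
            i -= 1
            state = "F"
    return i, end[0], j, ops[::-1]


def _compress(ops: Sequence[str]) -> Cigar:
    out: Cigar = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


def sw_score(read: str, ref: str, p: ScoringParams = ScoringParams()) -> int:
    """Best local affine-gap score (no traceback)."""
    H, _, _, _ = _sw_matrices(read, ref, p)
    return int(H.max())


def align_endsfree(
    read: str,
    ref: str,
    p: ScoringParams = ScoringParams(),
    read_id: str = "read",
    ref_id: str = "ref",
    ref_offset: int = 0,
    strand: str = "+",
) -> AlignmentRecord:
    """Maximal-scoring local alignment of ``read`` against ``ref`` with soft-clipped ends.

    Tie-break is junction-conservative and deterministic: among equal-scoring
    end cells the one consuming the fewest read bases, then the fewest
    reference bases, is chosen, so score-neutral extensions past a tail
    junction are not absorbed into the aligned region.  Reads whose best score
    falls below ``p.min_score`` are reported unmapped (the raw score is kept).
    """
    if len(read) < 1:
        raise ValueError("empty read")
    H, E, F, G = _sw_matrices(read, ref, p)
    best = int(H.max())
    if best < p.min_score:
        return AlignmentRecord(read_id, "*", strand, 0, [("S", len(read))], best)
    ii, jj = np.nonzero(H == best)
    k = np.lexsort((jj, ii))[0]  # smallest read extent, then smallest ref extent
    qstart, qend, rstart, ops = _traceback(read, ref, p, H, E, F, G, (int(ii[k]), int(jj[k])))
    cigar: Cigar = []
    if qstart:
        cigar.append(("S", qstart))
    cigar.extend(_compress(ops))
    if len(read) - qend:
        cigar.append(("S", len(read) - qend))
    rec = AlignmentRecord(read_id, ref_id, strand, ref_offset + rstart, cigar, best)
    rec.validate(read_len=len(read))
    return rec


class KmerIndex:
    """Exact k-mer index over a reference set, used to select alignment windows."""

    def __init__(self, refs: Dict[str, str], k: int = 12):
        self.k = k
        self.refs = refs
        self.index: Dict[str, List[Tuple[str, int]]] = {}
        for ref_id, seq in refs.items():
            for pos in range(len(seq) - k + 1):
                self.index.setdefault(seq[pos : pos + k], []).append((ref_id, pos))

    def hits(self, read: str) -> Dict[str, List[Tuple[int, int]]]:
        """Per-reference list of (read_pos, ref_pos) exact k-mer matches."""
        out: Dict[str, List[Tuple[int, int]]] = {}
        k = self.k
        for qpos in range(0, len(read) - k + 1, 4):  # stride 4: plenty for error rates here
            for ref_id, rpos in self.index.get(read[qpos : qpos + k], ()):
                out.setdefault(ref_id, []).append((qpos, rpos))
        return out


def map_to_refset(
    read: ReadRecord,
    refs: Dict[str, str],
    p: ScoringParams = ScoringParams(),
    index: Optional[KmerIndex] = None,
) -> AlignmentRecord:
    """Best placement of a read across all references and both strands.

    Strand "-" aligns the reverse complement of the read and reports forward
    reference coordinates.  Score ties across distinct references pick the
    lexicographically smallest ref_id and set ``ambiguous`` (such records are
    excluded from quantification by default).  With ``p.band`` set, alignment
    runs only in seed-supported windows; with ``band=None`` it is exhaustive.
    """
    if not refs:
        raise ValueError("empty reference set")
    if index is None and p.band is not None:
        index = KmerIndex(refs, p.seed_k)
    candidates: List[AlignmentRecord] = []
    for strand in ("+", "-"):
        q = read.seq if strand == "+" else revcomp(read.seq)
        if p.band is not None:
            for ref_id, hitlist in index.hits(q).items():
                ref = refs[ref_id]
                lo = min(rpos - qpos for qpos, rpos in hitlist)
                hi = max(rpos + (len(q) - qpos) for qpos, rpos in hitlist)
                pad = p.band // 2 + 25
                lo, hi = max(0, lo - pad), min(len(ref), hi + pad)
                rec = align_endsfree(q, ref[lo:hi], p, read.read_id, ref_id, lo, strand)
                if not rec.is_unmapped:
                    candidates.append(rec)
        else:
            for ref_id in sorted(refs):
                rec = align_endsfree(q, refs[ref_id], p, read.read_id, ref_id, 0, strand)
                if not rec.is_unmapped:
                    candidates.append(rec)
    if not candidates:
        return AlignmentRecord(read.read_id, "*", "+", 0, [("S", len(read.seq))], 0)
    best_score = max(c.score for c in candidates)
    tied = sorted(
        (c for c in candidates if c.score == best_score), key=lambda c: (c.ref_id, c.strand, c.ref_start)
    )
    best = tied[0]
    if len({c.ref_id for c in tied}) > 1:
        best.ambiguous = True
    return best


def map_reads(
    reads: Sequence[ReadRecord], refs: Dict[str, str], p: ScoringParams = ScoringParams()
) -> List[AlignmentRecord]:
    index = KmerIndex(refs, p.seed_k) if p.band is not None else None
    return [map_to_refset(r, refs, p, index) for r in reads]


# ---------------------------------------------------------------------------
# SAM interchange (via pysam)
# ---------------------------------------------------------------------------


def _sam_header(refs: Dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": name, "LN": len(seq)} for name, seq in refs.items()],
        }
    )


def write_sam(
    records: Sequence[AlignmentRecord],
    reads: Dict[str, ReadRecord],
    refs: Dict[str, str],
    path,
) -> None:
    """Write records as SAM text (1-based POS, FLAG bit 16 for strand "-")."""
    header = _sam_header(refs)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            read = reads[rec.read_id]
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.read_id
            if rec.strand == "-":
                seg.query_sequence = revcomp(read.seq)
                seg.query_qualities = list(read.quals)[::-1]
            else:
                seg.query_sequence = read.seq
                seg.query_qualities = list(read.quals)
            if rec.is_unmapped:
                seg.is_unmapped = True
                seg.cigartuples = None
            else:
                seg.reference_id = header.get_tid(rec.ref_id)
                seg.reference_start = rec.ref_start
                seg.cigartuples = [(_OP_PYSAM[op], n) for op, n in rec.cigar]
                seg.mapping_quality = 60
            seg.is_reverse = rec.strand == "-"
            seg.set_tag("AS", int(rec.score))
            seg.set_tag("XB", 1 if rec.ambiguous else 0)
            out.write(seg)


def read_sam(path) -> Tuple[List[AlignmentRecord], Dict[str, ReadRecord]]:
    """Read SAM text back into alignment records plus sense-oriented reads.

    Records with unsupported CIGAR operations (e.g. hard clips) are rejected
    with a logged message naming the op and the line; remaining records are
    returned.  Sequences stored reverse-complemented (FLAG 16) are restored to
    read orientation.
    """
    records: List[AlignmentRecord] = []
    reads: Dict[str, ReadRecord] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for lineno, seg in enumerate(fh, start=1):
            if seg.is_unmapped:
                rec = AlignmentRecord(
                    seg.query_name, "*", "+", 0, [("S", seg.query_length or len(seg.query_sequence or ""))], 0
                )
            else:
                try:
                    cigar = [(_PYSAM_OP[op], n) for op, n in seg.cigartuples]
                except KeyError as exc:
                    bad = "H" if exc.args[0] == 5 else str(exc.args[0])
                    logger.warning(
                        "rejecting SAM record %s (line %d): unsupported CIGAR op %r",
                        seg.query_name,
                        lineno,
                        bad,
                    )
                    continue
                rec = AlignmentRecord(
                    seg.query_name,
                    seg.reference_name,
                    "-" if seg.is_reverse else "+",
                    seg.reference_start,
                    cigar,
                    int(seg.get_tag("AS")) if seg.has_tag("AS") else 0,
                    bool(seg.get_tag("XB")) if seg.has_tag("XB") else False,
                )
            records.append(rec)
            seq = seg.query_sequence or ""
            quals = list(seg.query_qualities) if seg.query_qualities is not None else [0] * len(seq)
            if seg.is_reverse:
                seq, quals = revcomp(seq), quals[::-1]
            if seq:
                reads[seg.query_name] = ReadRecord(seg.query_name, seq, quals)
    return records, reads
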