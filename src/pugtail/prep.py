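"""Read preparation: orientation to cDNA sense, primer trimming, quality and TG-repeat filters.

Long-read cDNA libraries built with a strand-switch protocol carry the strand-switch
primer (SSP) at the 5' end of the sense strand and the reverse-transcription primer
(VNP) at the 3' end; sequencing reports either strand of the cDNA at random.  This
module restores the sense orientation from the primer layout, trims the primers and
the RT-adapter remnant while preserving any non-templated alternating-TG tail, applies
a mean-error-probability quality filter, and flags reads containing a 10-nt TG-repeat
seed motif.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import edlib
import numpy as np

from ._util import revcomp

logger = logging.getLogger(__name__)

# Primer sequences of the PCS111-style strand-switch chemistry.
SSP = "TCTGTTGGTGCTGATATTGCTTT"
VNP = "TTGCCTGTCGCTCTATCTTC"
ADAPTER1 = "GCTATGGCTGTTCTCATGGC"
ADAPTER2 = "ACTTGCCTGTCGCTCTATCTTC"

#: reverse complement of adapter2+adapter1, the sequence trailing the tail in sense reads
RC_TAIL_ADAPTER = revcomp(ADAPTER2) + revcomp(ADAPTER1)

#: the 10-nt TG-repeat motif used by the prefilter
TG_MOTIF = "GTGTGTGTGT"


@dataclass
class ReadRecord:
    """A raw or processed read with per-base Phred qualities and stage flags."""

    read_id: str
    seq: str
    quals: List[int]
    oriented: bool = False
    full_length: bool = False
    passed_q: bool = False
    passed_tg: bool = False

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.seq)} != quality length {len(self.quals)}"
            )


@dataclass(frozen=True)
class PrimerSet:
    ssp: str = SSP
    vnp: str = VNP
    adapter1: str = ADAPTER1
    adapter2: str = ADAPTER2
    max_edits: int = 3

    def __post_init__(self) -> None:
        for name in ("ssp", "vnp", "adapter1", "adapter2"):
            p = getattr(self, name)
            if len(p) < 10:
                raise ValueError(f"primer {name} shorter than 10 nt")
        shortest = min(len(self.ssp), len(self.vnp))
        if self.max_edits >= shortest / 2:
            raise ValueError("max_edits must be < half the shortest primer length")


@dataclass(frozen=True)
class OrientationResult:
    orientation: str  # "+", "-", or "ambiguous"
    full_length: bool
    ssp_end: Optional[int]  # end (exclusive) of the SSP match on the sense read
    vnp_start: Optional[int]  # start of the rc(VNP) match on the sense read


def _best_hit(query: str, target: str, max_edits: int) -> Optional[Tuple[int, int, int]]:
    """Best infix match of query in target: (edit distance, start, end-exclusive)."""
    if not target:
        return None
    res = edlib.align(query, target, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return res["editDistance"], start, end + 1


def _scan_orientation(sense: str, primers: PrimerSet, window: int):
    """Locate SSP near the 5' end and rc(VNP) near the 3' end of a candidate sense read."""
    head = sense[:window]
    tail_off = max(0, len(sense) - window)
    tail = sense[tail_off:]
    ssp_hit = _best_hit(primers.ssp, head, primers.max_edits)
    vnp_hit = _best_hit(revcomp(primers.vnp), tail, primers.max_edits)
    n_found = (ssp_hit is not None) + (vnp_hit is not None)
    dist = (ssp_hit[0] if ssp_hit else 0) + (vnp_hit[0] if vnp_hit else 0)
    ssp_end = ssp_hit[2] if ssp_hit else None
    vnp_start = vnp_hit[1] + tail_off if vnp_hit else None
    return n_found, dist, ssp_end, vnp_start


def detect_orientation(read: ReadRecord, primers: PrimerSet = PrimerSet(), window: int = 120) -> OrientationResult:
    """Decide the cDNA-sense orientation of a read from its terminal primers.

    Both the read and its reverse complement are scanned in the first/last
    ``window`` nt for the SSP and the reverse complement of the VNP under edit
    distance <= ``primers.max_edits``.  "+" means the read as given is already
    in sense orientation.  Reads where both orientations score equally (most
    commonly: no primer found at all) are reported ambiguous.
    """
    fwd = _scan_orientation(read.seq, primers, window)
    rev = _scan_orientation(revcomp(read.seq), primers, window)
    # more primers found wins; among equals, lower total edit distance wins
    fwd_key = (fwd[0], -fwd[1])
    rev_key = (rev[0], -rev[1])
    if fwd[0] == 0 and rev[0] == 0:
        return OrientationResult("ambiguous", False, None, None)
    if fwd_key > rev_key:
        n, _, ssp_end, vnp_start = fwd
        return OrientationResult("+", n == 2, ssp_end, vnp_start)
    if rev_key > fwd_key:
        n, _, ssp_end, vnp_start = rev
        return OrientationResult("-", n == 2, ssp_end, vnp_start)
    return OrientationResult("ambiguous", False, None, None)


def orient_and_trim(
    read: ReadRecord, primers: PrimerSet = PrimerSet(), window: int = 120
) -> Tuple[ReadRecord, str]:
    """Return the sense-oriented read with terminal primers/adapters trimmed.

    The SSP (and anything 5' of it) is removed; the suffix from the rc(VNP)
    match onward — which covers the rc(adapter2)+rc(adapter1) remnant of the RT
    primer — is removed.  The alternating-TG tail region, which lies between
    the fragment and the adapter remnant, is preserved.  Qualities follow the
    sequence through reverse-complementing and slicing.

    Returns ``(read, status)`` where status is "ok" or "ambiguous".  Ambiguous
    reads are returned unchanged (and should be excluded by the caller); this
    also makes the operation idempotent, since a trimmed read no longer
    carries primers.
    """
    det = detect_orientation(read, primers, window)
    if det.orientation == "ambiguous":
        return read, "ambiguous"
    if det.orientation == "+":
        seq, quals = read.seq, list(read.quals)
    else:
        seq, quals = revcomp(read.seq), list(read.quals)[::-1]
    start = det.ssp_end if det.ssp_end is not None else 0
    end = det.vnp_start if det.vnp_start is not None else len(seq)
    if end < start:  # overlapping matches on a degenerate read
        end = start
    trimmed = replace(
        read,
        seq=seq[start:end],
        quals=quals[start:end],
        oriented=True,
        full_length=det.full_length,
    )
    return trimmed, "ok"


def quality_filter(read: ReadRecord, min_q: float = 9.0) -> bool:
    """Pass iff the read-level quality -10*log10(mean per-base error prob) >= min_q."""
    if not read.quals:
        raise ValueError("empty quality vector")
    p = np.power(10.0, -np.asarray(read.quals, dtype=float) / 10.0)
    read_q = -10.0 * math.log10(float(p.mean()))
    return read_q >= min_q - 1e-9


def tg_prefilter(read: ReadRecord) -> bool:
    """Pass iff the sequence contains GTGTGTGTGT flanked by >=1 character on each side.

    This is the sequence-line dialect of the classic flanked grep motif used to
    prescreen candidate pUG reads; the tail caller, not this filter, decides
    the final call.
    """
    seq = read.seq
    i = seq.find(TG_MOTIF)
    while i != -1:
        if i > 0 and i + len(TG_MOTIF) < len(seq):
            return True
        i = seq.find(TG_MOTIF, i + 1)
    return False


@dataclass
class PrepResult:
    reads: List[ReadRecord]
    audit: List[Tuple[str, str, str, str]] = field(default_factory=list)  # id, stage, decision, reason


def run_prep(
    reads: Sequence[ReadRecord],
    primers: PrimerSet = PrimerSet(),
    min_q: float = 9.0,
    require_full_length: bool = True,
    drop_tg: bool = False,
    window: int = 120,
) -> PrepResult:
    """Quality filter, then orientation/trimming, then the TG-repeat prefilter.

    The TG prefilter is advisory by default: reads are flagged via
    ``passed_tg`` so that short terminal tails (which lack a 3' flanking base
    for the motif) are not lost before the tail caller sees them.  ``drop_tg``
    restores the strict grep-style behaviour.
    """
    kept: List[ReadRecord] = []
    audit: List[Tuple[str, str, str, str]] = []
    for read in reads:
        if not quality_filter(read, min_q):
            audit.append((read.read_id, "quality", "drop", f"read quality < {min_q}"))
            continue
        read = replace(read, passed_q=True)
        trimmed, status = orient_and_trim(read, primers, window)
        if status == "ambiguous":
            audit.append((read.read_id, "orient", "drop", "ambiguous orientation"))
            continue
        if require_full_length and not trimmed.full_length:
            audit.append((read.read_id, "orient", "drop", "not full length"))
            continue
        trimmed = replace(trimmed, passed_tg=tg_prefilter(trimmed))
        if drop_tg and not trimmed.passed_tg:
            audit.append((read.read_id, "tg_filter", "drop", "no flanked TG motif"))
            continue
        audit.append((read.read_id, "prep", "keep", ""))
        kept.append(trimmed)
    return PrepResult(kept, audit)
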