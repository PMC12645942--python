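"""Calling non-templated alternating-UG (pUG) tails from 3' soft clips.

In sense-oriented cDNA, a pUG tail appears as an alternating T/G stretch
between the genome-templated fragment and the reverse-complemented RT-primer
adapter.  For a "+"-strand alignment the tail sits in the terminal soft clip;
for a "-"-strand alignment (an antisense fragment) the RNA 3' end maps to the
reference left end, so the tail is the leading soft clip in SAM orientation.

The caller proceeds per read: extract the 3' clip, strip any adapter remnant,
retract repeat-continuing bases the aligner may have absorbed into the
aligned region, score the clip against the infinite UG repeat in both phases
under an edit budget, and canonicalize the templated/non-templated junction
(templated-maximal: junction bases matching both genome and tail are assigned
to the genome).  The retract/extend pair makes the reported attachment site
invariant to how the aligner distributed repeat-matching bases between M and
S operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import pandas as pd

from ._util import comp_base
from .align import AlignmentRecord
from .prep import RC_TAIL_ADAPTER, PrimerSet, ReadRecord
from ._util import revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TailParams:
    min_tail_len: int = 10  # matches the 10-nt prefilter motif
    purity_min: float = 0.9
    max_edit_rate: float = 0.1
    adapter_max_edit_rate: float = 0.2
    max_residual: int = 30  # advisory; not a hard filter by default
    repeat_unit: str = "TG"

    def __post_init__(self) -> None:
        if not (0 < self.purity_min <= 1):
            raise ValueError("purity_min must be in (0, 1]")
        if self.min_tail_len < 2:
            raise ValueError("min_tail_len must be >= 2")


@dataclass
class PugTailCall:
    read_id: str
    ref_id: str
    strand: str
    attachment_pos: int  # 0-based reference coordinate of the last templated base
    tail_len: int
    purity: float
    residual_len: int
    passed: bool = True
    adapter_found: bool = False
    junction_shifted: bool = False


def extract_3prime_clip(aln: AlignmentRecord, read: ReadRecord) -> Optional[Tuple[str, int]]:
    """Return (clip, junction_ref_pos) for the RNA-3'-end soft clip, or None.

    ``clip`` is reported in read (RNA-sense) orientation, so a pUG tail reads
    as alternating T/G in both strands.  The junction is the reference
    coordinate of the last aligned (templated) base adjacent to the clip:
    for strand "+" the rightmost aligned base, for strand "-" ``ref_start``.
    """
    if aln.is_unmapped:
        logger.debug("read %s unmapped; no clip", aln.read_id)
        return None
    if aln.strand == "+":
        op, n = aln.cigar[-1]
        clip_len = n if op == "S" else 0
        junction = aln.ref_start + aln.ref_span() - 1
    else:
        op, n = aln.cigar[0]
        clip_len = n if op == "S" else 0
        junction = aln.ref_start
    clip = read.seq[len(read.seq) - clip_len :] if clip_len else ""
    return clip, junction


def trim_adapter_from_clip(
    clip: str, primers: PrimerSet = PrimerSet(), rate: float = 0.2
) -> Tuple[str, bool]:
    """Strip the rc(adapter2)+rc(adapter1) remnant from a clip, if present.

    The best infix match of the 42-nt remnant at edit rate <= ``rate`` marks
    the adapter start; the clip is truncated there.  No match leaves the clip
    unchanged.
    """
    adapter = revcomp(primers.adapter2) + revcomp(primers.adapter1)
    if not clip:
        return clip, False
    k = int(rate * len(adapter))
    res = edlib.align(adapter, clip, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return clip, False
    start = res["locations"][0][0]
    return clip[:start], True


def _phase_repeat(unit: str, start_offset: int, length: int) -> str:
    doubled = unit * (length // len(unit) + 2)
    return doubled[start_offset : start_offset + length]


def call_pug_tail(
    clip_core: str, p: TailParams = TailParams(), hamming: bool = False
) -> Optional[Tuple[int, int, float]]:
    """Longest clip prefix consistent with the alternating repeat, or None.

    For each repeat phase (TGTG... and GTGT...) the longest prefix length L
    with edit distance <= floor(max_edit_rate * L) to a prefix of the infinite
    repeat is found; the larger L across phases wins (ties broken by fewer
    edits).  Returns ``(tail_len, edits, purity)`` with purity = 1 - edits/L,
    or None when no prefix of length >= min_tail_len qualifies.  ``hamming``
    disables indels (substitution-only scoring) for oracle cross-checks.
    """
    best: Optional[Tuple[int, int]] = None  # (L, edits)
    n = len(clip_core)
    for offset in range(len(p.repeat_unit)):
        for L in range(n, p.min_tail_len - 1, -1):
            budget = int(p.max_edit_rate * L)
            if hamming:
                ref = _phase_repeat(p.repeat_unit, offset, L)
                d = sum(a != b for a, b in zip(clip_core[:L], ref))
                if d > budget:
                    continue
            else:
                target = _phase_repeat(p.repeat_unit, offset, L + budget + 2)
                res = edlib.align(clip_core[:L], target, mode="SHW", task="distance", k=budget)
                d = res["editDistance"]
                if d < 0:
                    continue
            if best is None or L > best[0] or (L == best[0] and d < best[1]):
                best = (L, d)
            break  # longest qualifying prefix for this phase found
    if best is None:
        return None
    L, d = best
    purity = 1.0 - d / L
    if purity < p.purity_min:
        return None
    return L, d, purity


def tail_edit_distance(tail: str, unit: str = "TG") -> int:
    """Edit distance of ``tail`` to the best-phase prefix of the infinite repeat."""
    if not tail:
        return 0
    best = len(tail)
    for offset in range(len(unit)):
        target = _phase_repeat(unit, offset, 2 * len(tail) + 4)
        d = edlib.align(tail, target, mode="SHW", task="distance")["editDistance"]
        best = min(best, d)
    return best


def _genome_next(ref_seq: str, strand: str, pos: int, step: int) -> Optional[str]:
    """Reference base ``step`` positions beyond the junction, in read sense."""
    if strand == "+":
        idx = pos + 1 + step
        return ref_seq[idx] if idx < len(ref_seq) else None
    idx = pos - 1 - step
    return comp_base(ref_seq[idx]) if idx >= 0 else None


def reconcile_templated(
    call: PugTailCall,
    ref_seq: str,
    clip_core: str,
    p: TailParams = TailParams(),
) -> Optional[PugTailCall]:
    """Canonicalize the junction: genome wins bases matching both genome and tail.

    While the next reference base beyond the junction (read-sense for strand
    "-") equals the next clip base, that base is moved from the tail to the
    templated region — the attachment coordinate advances and tail_len
    shrinks.  Shifting stops at the reference boundary.  If the tail drops
    below ``min_tail_len`` the call is demoted to a no-call (None).  Purity is
    recomputed on the final tail extent.
    """
    pos = call.attachment_pos
    idx = 0
    while idx < call.tail_len:
        nxt = _genome_next(ref_seq, call.strand, pos, 0)
        if nxt is None or nxt != clip_core[idx]:
            break
        pos = pos + 1 if call.strand == "+" else pos - 1
        idx += 1
    tail_len = call.tail_len - idx
    if tail_len < p.min_tail_len:
        logger.debug("read %s: junction shift left tail below min length; demoted", call.read_id)
        return None
    tail_seq = clip_core[idx : idx + tail_len]
    edits = tail_edit_distance(tail_seq, p.repeat_unit)
    purity = 1.0 - edits / tail_len
    passed = purity >= p.purity_min and tail_len >= p.min_tail_len
    return PugTailCall(
        call.read_id,
        call.ref_id,
        call.strand,
        pos,
        tail_len,
        purity,
        call.residual_len,
        passed,
        call.adapter_found,
        call.junction_shifted or idx > 0,
    )


def _retract_repeat_bases(
    aln: AlignmentRecord,
    read: ReadRecord,
    clip: str,
    junction: int,
    clip_len_orig: int,
    unit: str = "TG",
    cap: int = 80,
    gap_lookahead: int = 4,
) -> Tuple[str, int]:
    """Pull aligner-absorbed repeat bases back out of the alignment into the clip.

    A maximal-scoring local aligner may assign the first bases of a tail to
    the reference whenever the genome continuation resembles the repeat (e.g.
    a gap plus a few matching bases scores positively).  Walking the CIGAR
    inward from the clip, aligned read bases that continue the alternating
    pattern anchored at the clip's first base are prepended to the clip and
    the junction moves inward; inserted (I) repeat-unit bases are pulled in
    without moving the junction; deleted (D) reference bases move the
    junction only mid-retraction.  Bases that also match the genome are
    re-absorbed afterwards by the templated-maximal shift, so the pair is a
    no-op except where the aligner mis-assigned tail bases.
    """
    if not clip or clip[0] not in unit:
        return clip, junction
    step = -1 if aln.strand == "+" else 1
    cigar = aln.cigar[::-1] if aln.strand == "+" else aln.cigar
    qi = len(read.seq) - clip_len_orig - 1  # read-orientation base adjacent to the alignment
    ref_left = aln.ref_span() - 1  # keep at least one aligned reference base

    # flatten the junction-proximal cigar into per-base columns with read-sense bases
    cols: List[Tuple[str, Optional[str]]] = []
    for op, n in cigar:
        if op == "S":
            continue
        for _ in range(n):
            if op == "D":
                cols.append(("D", None))
            else:
                if qi < 0:
                    break
                cols.append((op, read.seq[qi]))
                qi -= 1
        if len(cols) >= cap + gap_lookahead + 1:
            break

    def take(i: int) -> bool:
        """Retract column i into the clip; False when the budget is exhausted."""
        nonlocal clip, junction, ref_left
        op, b = cols[i]
        if op == "I":
            clip = b + clip
            return True
        if ref_left <= 0:
            return False
        if op != "D":
            clip = b + clip
        junction += step
        ref_left -= 1
        return True

    i = 0
    retracted = 0
    while i < len(cols) and retracted < cap:
        op, b = cols[i]
        alternating = b is not None and b in unit and b != clip[0]
        if (op in ("M", "=", "X") and alternating) or (op == "I" and b in unit):
            if not take(i):
                break
            i += 1
            retracted += 1
            continue
        if op == "D" and retracted > 0:
            if not take(i):
                break
            i += 1
            retracted += 1
            continue
        # alternation stopped: a spurious gap placed just inside the alignment can
        # hide absorbed tail bases behind a shifted frame; cross it if it is close
        gap_at = next(
            (j for j in range(i, min(i + gap_lookahead + 1, len(cols))) if cols[j][0] in ("I", "D")),
            None,
        )
        if gap_at is None:
            break
        ok = True
        for j in range(i, gap_at + 1):
            if retracted >= cap or not take(j):
                ok = False
                break
            retracted += 1
        i = gap_at + 1
        if not ok:
            break
    return clip, junction


def call_read(
    aln: AlignmentRecord,
    read: ReadRecord,
    ref_seq: str,
    p: TailParams = TailParams(),
    primers: PrimerSet = PrimerSet(),
    retract: bool = True,
) -> Optional[PugTailCall]:
    """Run the full per-read calling chain; returns a passing call or None."""
    extracted = extract_3prime_clip(aln, read)
    if extracted is None:
        return None
    clip, junction = extracted
    if not clip:
        return None
    clip_core, adapter_found = trim_adapter_from_clip(clip, primers, p.adapter_max_edit_rate)
    if retract:
        clip_core, junction = _retract_repeat_bases(
            aln, read, clip_core, junction, len(clip), p.repeat_unit
        )
    if not clip_core:
        return None
    called = call_pug_tail(clip_core, p)
    if called is None:
        return None
    tail_len, _, purity = called
    raw = PugTailCall(
        read_id=aln.read_id,
        ref_id=aln.ref_id,
        strand=aln.strand,
        attachment_pos=junction,
        tail_len=tail_len,
        purity=purity,
        residual_len=len(clip_core) - tail_len,
        adapter_found=adapter_found,
    )
    return reconcile_templated(raw, ref_seq, clip_core, p)


def call_all(
    alignments: Sequence[AlignmentRecord],
    reads: Dict[str, ReadRecord],
    refs: Dict[str, str],
    p: TailParams = TailParams(),
    primers: PrimerSet = PrimerSet(),
    include_ambiguous: bool = False,
    retract: bool = True,
) -> List[PugTailCall]:
    """Tail calls for a whole dataset; deterministic given inputs.

    Ambiguously mapped reads are excluded unless ``include_ambiguous``.  Calls
    on the spike-in reference are emitted like any other and separated at
    quantification time.
    """
    calls: List[PugTailCall] = []
    for aln in alignments:
        if aln.is_unmapped or (aln.ambiguous and not include_ambiguous):
            continue
        call = call_read(aln, reads[aln.read_id], refs[aln.ref_id], p, primers, retract)
        if call is not None and call.passed:
            calls.append(call)
    return calls


_CALL_COLUMNS = [
    "read_id",
    "ref_id",
    "strand",
    "attachment_pos",
    "tail_len",
    "purity",
    "residual_len",
    "passed",
    "adapter_found",
    "junction_shifted",
]


def calls_to_frame(calls: Sequence[PugTailCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls], columns=_CALL_COLUMNS)


def write_calls_tsv(calls: Sequence[PugTailCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> List[PugTailCall]:
    df = pd.read_csv(path, sep="\t")
    return [PugTailCall(**row) for row in df.to_dict("records")]


def write_sites_bed(calls: Sequence[PugTailCall], path) -> None:
    """BED6 of attachment sites (0-based half-open; score = tail length)."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.ref_id, c.attachment_pos, c.read_id)):
            fh.write(
                f"{c.ref_id}\t{c.attachment_pos}\t{c.attachment_pos + 1}\t{c.read_id}\t{c.tail_len}\t{c.strand}\n"
            )
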