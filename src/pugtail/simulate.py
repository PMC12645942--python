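"""Synthetic pUG-seq data: references, library-structured reads with ground truth, evaluation.

The generator emulates the read structure of a strand-switch long-read cDNA
library built on pUG-tailed RNA fragments.  Each sense-oriented read is

    [SSP] [fragment, sense] [(TG)-alternating tail] [rc(adapter2)] [rc(adapter1)]

where the trailing adapters are the reverse complement of the poly(AC) RT
primer body.  Antisense fragments carry the reverse complement of the
reference interval; spike-in reads are fragments of the "spike" reference
with a fixed 36-nt (18-unit) tail emulating an in-vitro gfp(UG)18 control.
Reads are reverse-complemented at random (both cDNA strands are sequenced),
and substitution/insertion/deletion errors are applied per base.

Truth bookkeeping: the attachment coordinate (last templated base) is only
well-defined up to the templated-maximal convention — a junction base that
matches both the genome continuation and the tail is indistinguishable from
a templated base.  The generator therefore constrains the tail phase so that
the genome base just past the fragment never equals the first tail base,
making every truth attachment coordinate canonical by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import comp_base, revcomp
from .prep import ADAPTER1, ADAPTER2, SSP, ReadRecord
from .tails import PugTailCall

_BASES = "ACGT"

TRUTH_COLUMNS = [
    "read_id",
    "ref_id",
    "frag_start",
    "frag_end",
    "strand",
    "true_tail_len",
    "observed_tail_len",
    "attachment_pos",
    "is_spike",
    "is_pug",
]


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    ref_lengths: Sequence[int] = (3000, 2500)
    n_reads: int = 500
    pug_rate: float = 0.5
    tail_len_min: int = 10
    tail_len_max: int = 60
    frag_len_min: int = 100
    frag_len_max: int = 800
    antisense_rate: float = 0.2
    spike_rate: float = 0.05
    sub_rate: float = 0.03
    ins_rate: float = 0.01
    del_rate: float = 0.01
    anneal_policy: str = "end"  # "end": observed tail = true tail; "uniform": >=18 nt copied
    flip_rate: float = 0.5  # probability the sequencer reports the antisense cDNA strand

    def __post_init__(self) -> None:
        for name in ("pug_rate", "antisense_rate", "spike_rate", "sub_rate", "ins_rate", "del_rate", "flip_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1:
            raise ValueError("sub+ins+del must be < 1")
        if self.tail_len_min < 2:
            raise ValueError("tail_len_min must be >= 2")
        if self.frag_len_min < 30:
            raise ValueError("frag_len_min must be >= 30")
        if self.anneal_policy not in ("end", "uniform"):
            raise ValueError("anneal_policy must be 'end' or 'uniform'")


@dataclass
class EvalReport:
    sensitivity: float
    precision: float
    site_exact_rate: float
    site_within_k: float
    tail_len_mae: float
    n_truth_pug: int = 0
    n_calls: int = 0
    n_recovered: int = 0


def make_references(seed: int, ref_lengths: Sequence[int], spike_len: int = 720) -> Dict[str, str]:
    """Uniform-random reference set plus an always-appended "spike" reference.

    Deterministic given the seed; lengths below 100 nt are rejected.
    """
    for L in ref_lengths:
        if L < 100:
            raise ValueError(f"reference length {L} too short (must be >= 100)")
    rng = np.random.default_rng(seed)
    refs: Dict[str, str] = {}
    for i, L in enumerate(ref_lengths, start=1):
        refs[f"ORV{i}-like"] = "".join(_BASES[b] for b in rng.integers(0, 4, size=L))
    refs["spike"] = "".join(_BASES[b] for b in rng.integers(0, 4, size=spike_len))
    return refs


def _alternating_tail(phase: str, length: int) -> str:
    unit = "TG" if phase == "T" else "GT"
    return (unit * (length // 2 + 1))[:length]


def _continuation_base(ref: str, strand: str, frag_start: int, frag_end: int) -> Optional[str]:
    """Genome base just past the fragment's RNA 3' end, in read sense."""
    if strand == "+":
        return ref[frag_end] if frag_end < len(ref) else None
    return comp_base(ref[frag_start - 1]) if frag_start > 0 else None


def _draw_fragment(rng: np.random.Generator, ref_len: int, fmin: int, fmax: int) -> Tuple[int, int]:
    flen = min(int(rng.integers(fmin, fmax + 1)), ref_len)
    start = int(rng.integers(0, ref_len - flen + 1))
    return start, start + flen


def _apply_errors(seq: str, rng: np.random.Generator, sub: float, ins: float, dele: float) -> str:
    if sub == ins == dele == 0:
        return seq
    n = len(seq)
    u = rng.random(n)
    sub_choice = rng.integers(0, 3, size=n)
    ins_choice = rng.integers(0, 4, size=n)
    out: List[str] = []
    for i, b in enumerate(seq):
        x = u[i]
        if x < sub:
            others = [c for c in _BASES if c != b] if b in _BASES else list(_BASES[:3])
            out.append(others[sub_choice[i]])
        elif x < sub + ins:
            out.append(_BASES[ins_choice[i]])
            out.append(b)
        elif x < sub + ins + dele:
            continue
        else:
            out.append(b)
    return "".join(out)


def simulate_reads(
    cfg: SimConfig, refs: Dict[str, str]
) -> Tuple[List[Tuple[str, str, List[int]]], pd.DataFrame]:
    """Simulate a library of reads plus a truth table, deterministically.

    Returns ``(reads, truth)`` where reads are (read_id, sequence, qualities)
    tuples and truth is a DataFrame with one row per read (TRUTH_COLUMNS).
    """
    if cfg.spike_rate > 0 and "spike" not in refs:
        raise ValueError("spike_rate > 0 requires a reference named 'spike'")
    nonspike = [r for r in refs if r != "spike"]
    if not nonspike:
        raise ValueError("need at least one non-spike reference")
    rng = np.random.default_rng(cfg.seed)
    reads: List[Tuple[str, str, List[int]]] = []
    rows: List[dict] = []
    for i in range(cfg.n_reads):
        read_id = f"read{i:05d}"
        is_spike = bool(rng.random() < cfg.spike_rate) if "spike" in refs else False
        if is_spike:
            ref_id, strand, is_pug = "spike", "+", True
            true_tail = 36
            ref = refs[ref_id]
            phase = "T"  # gfp(UG)18: tail starts with U
            for _ in range(200):
                frag_start, frag_end = _draw_fragment(rng, len(ref), cfg.frag_len_min, cfg.frag_len_max)
                if _continuation_base(ref, strand, frag_start, frag_end) != phase:
                    break
        else:
            ref_id = nonspike[int(rng.integers(0, len(nonspike)))]
            ref = refs[ref_id]
            strand = "-" if rng.random() < cfg.antisense_rate else "+"
            is_pug = bool(rng.random() < cfg.pug_rate)
            frag_start, frag_end = _draw_fragment(rng, len(ref), cfg.frag_len_min, cfg.frag_len_max)
            if is_pug:
                raw = int(rng.integers(cfg.tail_len_min, cfg.tail_len_max + 1))
                true_tail = max(cfg.tail_len_min, raw - raw % 2)  # even lengths (whole UG units)
                cont = _continuation_base(ref, strand, frag_start, frag_end)
                if cont == "T":
                    phase = "G"
                elif cont == "G":
                    phase = "T"
                else:
                    phase = "T" if rng.random() < 0.5 else "G"
            else:
                true_tail, phase = 0, "T"
        if is_pug:
            if cfg.anneal_policy == "end" or true_tail <= 18:
                observed = true_tail
            else:
                observed = int(rng.integers(18, true_tail + 1))
        else:
            observed = 0
        frag = ref[frag_start:frag_end]
        if strand == "-":
            frag = revcomp(frag)
        sense = SSP + frag + _alternating_tail(phase, observed) + revcomp(ADAPTER2) + revcomp(ADAPTER1)
        seq = _apply_errors(sense, rng, cfg.sub_rate, cfg.ins_rate, cfg.del_rate)
        if rng.random() < cfg.flip_rate:
            seq = revcomp(seq)
        quals = np.clip(np.rint(rng.normal(12.0, 3.0, size=len(seq))), 2, 40).astype(int).tolist()
        reads.append((read_id, seq, quals))
        rows.append(
            {
                "read_id": read_id,
                "ref_id": ref_id,
                "frag_start": frag_start,
                "frag_end": frag_end,
                "strand": strand,
                "true_tail_len": true_tail,
                "observed_tail_len": observed,
                "attachment_pos": frag_end - 1 if strand == "+" else frag_start,
                "is_spike": is_spike,
                "is_pug": is_pug,
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return reads, truth


def reads_to_records(reads: Sequence[Tuple[str, str, List[int]]]) -> List[ReadRecord]:
    return [ReadRecord(rid, seq, quals) for rid, seq, quals in reads]


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def evaluate_calls(
    calls: Sequence[PugTailCall], truth: pd.DataFrame, k: int = 5
) -> EvalReport:
    """Score tail calls against simulator ground truth.

    sensitivity = pUG reads recovered / pUG reads simulated; precision =
    calls on pUG reads / all calls (1.0 by convention when there are no
    calls); site metrics and tail-length MAE are computed over recovered
    reads.  Deterministic.
    """
    if truth.empty:
        raise ValueError("empty truth table")
    truth_by_id = truth.set_index("read_id")
    unknown = {c.read_id for c in calls} - set(truth_by_id.index)
    if unknown:
        raise ValueError(f"calls reference unknown read ids: {sorted(unknown)[:5]}")
    pug_ids = set(truth_by_id.index[truth_by_id["is_pug"]])
    calls_by_read: Dict[str, PugTailCall] = {}
    for c in calls:
        calls_by_read.setdefault(c.read_id, c)
    n_calls = len(calls)
    true_calls = sum(1 for c in calls if c.read_id in pug_ids)
    recovered = [rid for rid in calls_by_read if rid in pug_ids]
    exact = within = 0
    abs_err_sum = 0.0
    for rid in recovered:
        c = calls_by_read[rid]
        t = truth_by_id.loc[rid]
        if c.ref_id == t["ref_id"]:
            err = abs(int(c.attachment_pos) - int(t["attachment_pos"]))
            exact += err == 0
            within += err <= k
        abs_err_sum += abs(int(c.tail_len) - int(t["observed_tail_len"]))
    n_rec = len(recovered)
    return EvalReport(
        sensitivity=n_rec / len(pug_ids) if pug_ids else (1.0 if not calls else 0.0),
        precision=true_calls / n_calls if n_calls else 1.0,
        site_exact_rate=exact / n_rec if n_rec else 0.0,
        site_within_k=within / n_rec if n_rec else 0.0,
        tail_len_mae=abs_err_sum / n_rec if n_rec else math.nan,
        n_truth_pug=len(pug_ids),
        n_calls=n_calls,
        n_recovered=n_rec,
    )
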