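"""End-to-end orchestration: prep -> align -> call -> quantify, plus simulation harness."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .align import AlignmentRecord, ScoringParams, map_reads
from .prep import PrepResult, PrimerSet, ReadRecord, run_prep
from .quantify import DEFAULT_BINWIDTH, DEFAULT_SCALE, SiteTable, build_site_table
from .simulate import EvalReport, SimConfig, evaluate_calls, make_references, reads_to_records, simulate_reads
from .tails import PugTailCall, TailParams, call_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    prep: PrepResult
    alignments: List[AlignmentRecord]
    calls: List[PugTailCall]
    table: SiteTable
    normalization_error: Optional[str] = None


def run_pipeline(
    reads: Sequence[ReadRecord],
    refs: Dict[str, str],
    primers: PrimerSet = PrimerSet(),
    min_q: float = 9.0,
    require_full_length: bool = True,
    drop_tg: bool = False,
    sparams: ScoringParams = ScoringParams(),
    tparams: TailParams = TailParams(),
    spike_ref_id: str = "spike",
    binwidth: int = DEFAULT_BINWIDTH,
    scale: float = DEFAULT_SCALE,
) -> PipelineResult:
    """Run the full tail-detection pipeline on raw reads.

    Normalization is attempted but a zero spike count is not fatal: raw
    counts are always produced and the refusal is recorded.
    """
    prep = run_prep(reads, primers, min_q, require_full_length, drop_tg)
    alignments = map_reads(prep.reads, refs, sparams)
    reads_by_id = {r.read_id: r for r in prep.reads}
    calls = call_all(alignments, reads_by_id, refs, tparams, primers)
    norm_error = None
    try:
        table = build_site_table(calls, refs, spike_ref_id, binwidth, scale, normalize=True)
    except ValueError as exc:
        logger.warning("normalization refused: %s", exc)
        norm_error = str(exc)
        table = build_site_table(calls, refs, spike_ref_id, binwidth, scale, normalize=False)
    return PipelineResult(prep, alignments, calls, table, norm_error)


def simulate_and_run(
    cfg: SimConfig,
    k: int = 5,
    ref_seed: Optional[int] = None,
    **pipeline_kwargs,
) -> Tuple[PipelineResult, EvalReport, pd.DataFrame, Dict[str, str]]:
    """Simulate a dataset, run the pipeline on it, and score against truth."""
    refs = make_references(cfg.seed if ref_seed is None else ref_seed, cfg.ref_lengths)
    raw_reads, truth = simulate_reads(cfg, refs)
    result = run_pipeline(reads_to_records(raw_reads), refs, **pipeline_kwargs)
    report = evaluate_calls(result.calls, truth, k=k)
    return result, report, truth, refs
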