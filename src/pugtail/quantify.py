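"""Aggregation of tail calls: per-reference counts, spike-in normalization, binned site histograms.

Raw per-reference tail counts are normalized by the number of spike-in tail
reads: norm = raw * S / spike_count, with S a fixed, documented scale constant
(default 100, i.e. counts per 100 sequenced spike tails).  Attachment sites
are binned into fixed-width windows (default 50 nt) covering each reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .tails import PugTailCall

DEFAULT_SCALE = 100.0
DEFAULT_BINWIDTH = 50

Bin = Tuple[int, int, int]  # start (0-based), end (half-open), count


@dataclass
class SpikeStats:
    spike_ref_id: str
    spike_count: int
    scale: Optional[float]  # S / spike_count, None when spike_count == 0


@dataclass
class SiteTable:
    binwidth: int
    spike: SpikeStats
    raw: Dict[str, int] = field(default_factory=dict)
    norm: Dict[str, float] = field(default_factory=dict)
    bins: Dict[str, List[Bin]] = field(default_factory=dict)


def count_calls(
    calls: Sequence[PugTailCall], spike_ref_id: str = "spike", by_strand: bool = False
) -> Tuple[Dict, SpikeStats]:
    """Per-reference counts of passing calls; spike calls are counted separately.

    With ``by_strand`` the keys are (ref_id, strand) tuples; by default
    strands are merged.
    """
    raw: Dict = {}
    spike_count = 0
    for c in calls:
        if not c.passed:
            continue
        if c.ref_id == spike_ref_id:
            spike_count += 1
            continue
        key = (c.ref_id, c.strand) if by_strand else c.ref_id
        raw[key] = raw.get(key, 0) + 1
    return raw, SpikeStats(spike_ref_id, spike_count, None)


def spike_normalize(
    raw: Dict[str, int], spike: SpikeStats, S: float = DEFAULT_SCALE
) -> Dict[str, float]:
    """norm(ref) = raw(ref) * S / spike_count; refuses to normalize without spike reads."""
    if spike.spike_count < 1:
        raise ValueError(
            "spike-in count is zero: normalization refused (raw counts remain available)"
        )
    spike.scale = S / spike.spike_count
    return {ref: n * spike.scale for ref, n in raw.items()}


def bin_sites(
    positions: Sequence[int], ref_length: int, binwidth: int = DEFAULT_BINWIDTH
) -> List[Bin]:
    """Fixed-width histogram of attachment positions over [0, ref_length).

    Bin index is floor(pos / binwidth); the last bin may be short; empty bins
    are reported with count 0.  Out-of-range positions indicate an upstream
    bug and raise.
    """
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    n_bins = math.ceil(ref_length / binwidth)
    counts = [0] * n_bins
    for pos in positions:
        if not (0 <= pos < ref_length):
            raise ValueError(f"attachment position {pos} outside [0, {ref_length})")
        counts[pos // binwidth] += 1
    return [
        (i * binwidth, min((i + 1) * binwidth, ref_length), counts[i]) for i in range(n_bins)
    ]


def build_site_table(
    calls: Sequence[PugTailCall],
    refs: Dict[str, str],
    spike_ref_id: str = "spike",
    binwidth: int = DEFAULT_BINWIDTH,
    S: float = DEFAULT_SCALE,
    normalize: bool = True,
) -> SiteTable:
    raw, spike = count_calls(calls, spike_ref_id)
    table = SiteTable(binwidth=binwidth, spike=spike)
    for ref_id in refs:
        if ref_id == spike_ref_id:
            continue
        table.raw[ref_id] = raw.get(ref_id, 0)
        positions = [
            c.attachment_pos for c in calls if c.passed and c.ref_id == ref_id
        ]
        table.bins[ref_id] = bin_sites(positions, len(refs[ref_id]), binwidth)
    if normalize:
        table.norm = spike_normalize(table.raw, spike, S)
    return table


def write_outputs(table: SiteTable, calls: Sequence[PugTailCall], outdir, S: float = DEFAULT_SCALE):
    """Write the summary TSV, a bedGraph of binned counts, and BED6 sites.

    Output is byte-stable for identical input (fixed ordering, fixed float
    formatting).  Returns the three paths.
    """
    from pathlib import Path

    from .tails import write_sites_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = outdir / "summary.tsv"
    bedgraph = outdir / "sites.bedGraph"
    bed = outdir / "sites.bed"
    with open(summary, "w") as fh:
        fh.write(
            f"# norm_count = raw_count * S / spike_count; S={S:g}; "
            f"spike_ref={table.spike.spike_ref_id}; spike_count={table.spike.spike_count}\n"
        )
        fh.write("ref_id\traw_count\tnorm_count\n")
        for ref_id in sorted(table.raw):
            norm = table.norm.get(ref_id)
            norm_s = f"{norm:.6g}" if norm is not None else "NA"
            fh.write(f"{ref_id}\t{table.raw[ref_id]}\t{norm_s}\n")
    with open(bedgraph, "w") as fh:
        fh.write('track type=bedGraph name="pug_tail_sites_binned"\n')
        for ref_id in sorted(table.bins):
            for start, end, count in table.bins[ref_id]:
                if count:
                    fh.write(f"{ref_id}\t{start}\t{end}\t{count}\n")
    write_sites_bed([c for c in calls if c.passed and c.ref_id != table.spike.spike_ref_id], bed)
    return summary, bedgraph, bed


def read_summary_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_bedgraph(path) -> List[Tuple[str, int, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("track"):
                continue
            ref_id, start, end, count = line.rstrip("\n").split("\t")
            out.append((ref_id, int(start), int(end), int(count)))
    return out
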