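"""Tail caller: clip extraction, adapter trimming, repeat scoring, junction canonicalization."""

from __future__ import annotations

import random

import pytest

from pugtail._util import revcomp
from pugtail.align import AlignmentRecord
from pugtail.prep import ADAPTER1, ADAPTER2, PrimerSet, ReadRecord
from pugtail.simulate import SimConfig
from pugtail.pipeline import simulate_and_run
from pugtail.tails import (
    PugTailCall,
    TailParams,
    call_all,
    call_pug_tail,
    call_read,
    extract_3prime_clip,
    reconcile_templated,
    tail_edit_distance,
    trim_adapter_from_clip,
)

PRIMERS = PrimerSet()
PARAMS = TailParams()
RC_ADAPTER = revcomp(ADAPTER2) + revcomp(ADAPTER1)


def _read(seq, rid="r"):
    return ReadRecord(rid, seq, [20] * len(seq))


# ---------------------------------------------------------------------------
# independent brute-force oracle for tail scoring
# ---------------------------------------------------------------------------


def _edit_dp_all_prefixes(query: str, target: str):
    """bestD[i] = min edit distance of query[:i] to any prefix of target."""
    m, n = len(query), len(target)
    prev = list(range(n + 1))
    best = [0] * (m + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (query[i - 1] != target[j - 1]))
        best[i] = min(cur)
        prev = cur
    return best


def oracle_call(clip: str, p: TailParams = PARAMS):
    """Brute-force search over all prefixes, phases, and edit scripts."""
    best = None  # (L, edits)
    for phase in ("TG", "GT"):
        target = (phase * (len(clip) + 10))[: 2 * len(clip) + 8]
        bestD = _edit_dp_all_prefixes(clip, target)
        for L in range(len(clip), p.min_tail_len - 1, -1):
            if bestD[L] <= int(p.max_edit_rate * L):
                if best is None or L > best[0] or (L == best[0] and bestD[L] < best[1]):
                    best = (L, bestD[L])
                break
    if best is None:
        return None
    L, d = best
    purity = 1.0 - d / L
    return None if purity < p.purity_min else (L, d, purity)


class TestExtract3PrimeClip:
    def test_plus_strand_cigar_arithmetic(self):
        aln = AlignmentRecord("r", "REF", "+", 100, [("M", 200), ("S", 20)])
        read = _read("A" * 200 + "TG" * 10)
        clip, junction = extract_3prime_clip(aln, read)
        assert junction == 299
        assert clip == "TG" * 10

    def test_no_terminal_clip_gives_empty(self):
        aln = AlignmentRecord("r", "REF", "+", 100, [("M", 200)])
        clip, _ = extract_3prime_clip(aln, _read("A" * 200))
        assert clip == ""

    def test_minus_strand_junction_is_ref_start(self, small_clean_run):
        result, _, truth, _ = small_clean_run
        byid = truth.set_index("read_id")
        reads = {r.read_id: r for r in result.prep.reads}
        seen = 0
        for aln in result.alignments:
            t = byid.loc[aln.read_id]
            if aln.strand != "-" or not t.is_pug:
                continue
            clip, junction = extract_3prime_clip(aln, reads[aln.read_id])
            assert abs(junction - t.attachment_pos) <= 4
            assert clip  # the tail must sit in the clip
            seen += 1
        assert seen > 0

    def test_unmapped_record_gives_none(self):
        aln = AlignmentRecord("r", "*", "+", 0, [("S", 10)])
        assert extract_3prime_clip(aln, _read("A" * 10)) is None


class TestTrimAdapterFromClip:
    def test_tail_plus_adapter(self):
        clip = "TG" * 10 + RC_ADAPTER
        core, found = trim_adapter_from_clip(clip, PRIMERS)
        assert (core, found) == ("TG" * 10, True)
        # the expected adapter block, from an independent reverse complement
        from Bio.Seq import Seq

        assert RC_ADAPTER == str(Seq(ADAPTER1 + ADAPTER2).reverse_complement())

    def test_no_adapter_unchanged(self):
        core, found = trim_adapter_from_clip("TG" * 10, PRIMERS)
        assert (core, found) == ("TG" * 10, False)

    def test_adapter_only_clip_empties(self):
        core, found = trim_adapter_from_clip(RC_ADAPTER, PRIMERS)
        assert (core, found) == ("", True)


class TestCallPugTail:
    def test_perfect_repeat(self):
        assert call_pug_tail("TG" * 10, PARAMS)[0] == 20
        assert call_pug_tail("TG" * 10, PARAMS)[2] == 1.0

    def test_empty_no_call(self):
        assert call_pug_tail("", PARAMS) is None

    def test_single_substitution_tolerated(self):
        res = call_pug_tail("TGTGAGTGTGTG", PARAMS)
        assert res is not None
        L, d, purity = res
        assert (L, purity) == (12, 11 / 12)
        assert oracle_call("TGTGAGTGTGTG", PARAMS)[:2] == (L, d)

    def test_homopolymer_rejected(self):
        assert call_pug_tail("T" * 10, PARAMS) is None
        assert oracle_call("T" * 10, PARAMS) is None

    def test_matches_bruteforce_oracle_on_random_clips(self):
        rng = random.Random(77)
        for _ in range(150):
            n = rng.randint(0, 40)
            style = rng.random()
            if style < 0.4:  # mutated tails
                s = ("TG" * 25)[:n]
                s = "".join(c if rng.random() > 0.12 else rng.choice("ACGT") for c in s)
            elif style < 0.7:
                s = "".join(rng.choice("TG") for _ in range(n))
            else:
                s = "".join(rng.choice("ACGT") for _ in range(n))
            mine, ora = call_pug_tail(s, PARAMS), oracle_call(s, PARAMS)
            assert (mine is None) == (ora is None), s
            if mine:
                assert mine[0] == ora[0] and mine[2] == ora[2], s

    def test_purity_consistent_with_edit_distance(self, clean_run):
        result, _, _, _ = clean_run
        for c in result.calls[:100]:
            d_implied = round((1 - c.purity) * c.tail_len)
            assert abs(c.purity * c.tail_len - (c.tail_len - d_implied)) <= 1

    def test_min_tail_monotonicity(self, small_clean_run):
        result, _, _, refs = small_clean_run
        reads = {r.read_id: r for r in result.prep.reads}
        counts = []
        for mtl in (10, 20, 40):
            p = TailParams(min_tail_len=mtl)
            counts.append(len(call_all(result.alignments, reads, refs, p)))
        assert counts == sorted(counts, reverse=True)


class TestReconcileTemplated:
    def test_worked_example(self):
        """Genome TG beyond the junction absorbs the clip's first repeat unit."""
        call = PugTailCall("r", "REF", "+", 7, 12, 1.0, 0)
        out = reconcile_templated(call, "ACGTACGTTG", "TGTGTGTGTGTG", PARAMS)
        assert (out.attachment_pos, out.tail_len) == (9, 10)
        assert out.junction_shifted

    def test_no_shift_when_genome_differs(self):
        call = PugTailCall("r", "REF", "+", 7, 12, 1.0, 0)
        out = reconcile_templated(call, "ACGTACGTAA", "TGTGTGTGTGTG", PARAMS)
        assert (out.attachment_pos, out.tail_len) == (7, 12)
        assert not out.junction_shifted

    def test_demotion_below_min_tail_len(self):
        call = PugTailCall("r", "REF", "+", 7, 11, 1.0, 0)
        # genome continues TG: shifting twice leaves 9 < 10
        out = reconcile_templated(call, "ACGTACGTTGAA", "TGTGTGTGTGT", PARAMS)
        assert out is None


def _build_perturbation_case(rng):
    """A clean read whose genome continues with j repeat bases beyond the fragment."""
    j = rng.randint(0, 4)
    tail_len = rng.choice([14, 20, 30, 40])
    phase = rng.choice("TG")
    tail = (("TG" if phase == "T" else "GT") * 40)[:tail_len]
    flen = rng.randint(60, 120)
    frag = "".join(rng.choice("ACGT") for _ in range(flen))
    stop = rng.choice("AC")  # never matches the next tail base, ending the templated run
    left = "".join(rng.choice("ACGT") for _ in range(30))
    right = "".join(rng.choice("ACGT") for _ in range(30))
    ref = left + frag + tail[:j] + stop + right
    frag_start = len(left)
    canonical = frag_start + flen + j - 1  # templated-maximal attachment
    read = frag + tail
    return ref, read, frag_start, flen, j, tail_len, canonical


class TestJunctionPerturbationInvariance:
    def test_calls_invariant_to_repeat_base_placement(self):
        """Moving up to 4 repeat-matching bases between M and S leaves calls unchanged."""
        rng = random.Random(2024)
        cases = checked = 0
        while cases < 30:
            ref, read, frag_start, flen, j, tail_len, canonical = _build_perturbation_case(rng)
            cases += 1
            results = set()
            for delta in range(0, j + 1):
                aligned = flen + j - delta
                aln = AlignmentRecord(
                    "r", "REF", "+", frag_start, [("M", aligned), ("S", len(read) - aligned)]
                )
                call = call_read(aln, _read(read), ref, PARAMS, PRIMERS)
                assert call is not None
                results.add((call.attachment_pos, call.tail_len))
                checked += 1
            assert results == {(canonical, tail_len - j)}
        assert checked >= 30


class TestCallAll:
    def test_error_free_dataset_recovers_exact_truth(self, small_clean_run):
        result, report, truth, _ = small_clean_run
        called = {c.read_id for c in result.calls}
        expected = set(truth[truth.is_pug].read_id)
        assert called == expected

    def test_no_tails_no_calls(self):
        cfg = SimConfig(seed=23, n_reads=60, pug_rate=0.0, spike_rate=0.0,
                        sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
        result, _, _, _ = simulate_and_run(cfg)
        assert result.calls == []

    def test_spike_calls_carry_spike_ref(self, clean_run):
        result, _, truth, _ = clean_run
        spike_ids = set(truth[truth.is_spike].read_id)
        spike_calls = [c for c in result.calls if c.ref_id == "spike"]
        assert spike_calls
        assert {c.read_id for c in spike_calls} == spike_ids
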