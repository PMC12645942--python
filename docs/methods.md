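# Methods

## The problem

A pUG tail is a post-transcriptionally added stretch of alternating
uridine/guanosine at an RNA 3′ end. In sense-oriented cDNA reads it is a
non-templated alternating `TG` run between the genome-templated fragment and
the reverse complement of the poly(AC) RT primer. Three quantities are of
interest per read: whether a tail is present, where on the reference it
attaches (the last templated base), and how long the sequenced copy of the
tail is. Per library, the interesting outputs are spike-normalized tail
counts per reference and the spatial distribution of attachment sites.

## Read model and library chemistry

Reads are assumed to follow the strand-switch protocol layout

    [SSP] [fragment, sense] [(TG)k] [rc(adapter2)] [rc(adapter1)]

with SSP `TCTGTTGGTGCTGATATTGCTTT`, VNP `TTGCCTGTCGCTCTATCTTC`, adapter1
`GCTATGGCTGTTCTCATGGC`, adapter2 `ACTTGCCTGTCGCTCTATCTTC` (adapter2 is
`AC`+VNP; the RT primer is adapter1+adapter2+(AC)₉). Either cDNA strand may
be reported by the sequencer, so orientation must be inferred from the
primers. Antisense fragments (the RNA was transcribed from the opposite
strand of the reference) are supported throughout and map as strand "−";
their tails sit at the reference *left* end of the alignment.

## Pipeline stages and parameters

**Quality filter.** Pass iff −10·log₁₀(mean per-base error probability) ≥
`min_q` (default 9). The mean is taken over error probabilities, not Phred
scores, so the filter is dominated by the worst bases and is monotone in
every individual base quality.

**Orientation and trimming.** Both the read and its reverse complement are
scanned in their first/last 120 nt (window `W`; primers are terminal by
construction, so a generous window only costs time) for SSP and rc(VNP)
under edit distance ≤ `max_edits` (default 3, ≈15% of a 20–23 nt primer,
matching long-read error rates). More primer hits wins; equal evidence →
ambiguous, and ambiguous reads are excluded. `full_length` means both
primers were found; by default non-full-length reads are dropped
(`--no-require-full-length` keeps them). Trimming removes the SSP and
everything 5′ of it, and everything from the rc(VNP) match onward — which is
exactly the rc(adapter2)+rc(adapter1) remnant — while the tail, which lies
5′ of the remnant, is preserved.

**TG prescreen.** The classic prefilter greps for `GTGTGTGTGT` flanked by at
least one character on each side. Two deliberate choices: (i) the pattern is
applied to the sequence only, not to FASTQ header/quality lines, which the
raw line-based grep could spuriously match; (ii) in the packaged pipeline
the result is recorded as a per-read flag rather than used as a hard drop
(`--drop-tg` restores hard filtering). The reason for (ii): after adapter
trimming, a terminal tail of exactly 10 nt has no 3′ flanking character and
a flanked-motif grep necessarily discards it, even error-free; the tail
caller — which implements the actual definition of a tail — makes the
decision instead, and the flag remains available for triage. Specificity
does not suffer: the caller requires ≥10 nt of ≥90%-pure repeat, which
random genomic 3′ ends essentially never satisfy (zero false calls on
tail-free datasets, see tests).

**Alignment.** Local affine-gap alignment (Gotoh recurrences, vectorized
along the reference with NumPy; integer scores): match +2, mismatch −4, gap
open −4 (first gap base), extend −2. Exact 12-mer seeds select candidate
reference windows (band padding 100 nt); `band=None` disables seeding and is
bit-identical to an exhaustive DP, which the test suite checks against an
independent brute-force implementation. Unaligned read ends become soft
clips. Reads are aligned to every reference on both strands; the best score
wins, score ties across distinct references are flagged ambiguous and
excluded from quantification. A read is unmapped when no seed exists or the
best score falls below `min_score` (default 40 ≡ 20 matched bases); a pure
"score ≤ 0" rule never fires for local alignment, since any shared base
scores positively. Tie-breaks among equal-scoring alignments are
junction-conservative: the end cell consuming the fewest read bases (then
fewest reference bases) is chosen, so a score-neutral extension past a tail
junction — one mismatch plus two repeat bases that happen to match the
genome is exactly score-neutral under this scoring — is never absorbed into
the aligned region.

**Tail calling.** For a strand "+" alignment the 3′ clip is the terminal
soft clip and the junction is the rightmost aligned reference base; for
strand "−" the clip is the read's 3′ suffix (leading soft clip in SAM
orientation) and the junction is `ref_start`. The rc(adapter2)+rc(adapter1)
remnant (42 nt) is located in the clip by edit-distance search (rate ≤ 0.2)
and removed. The tail is the longest clip prefix *L* whose unit-cost edit
distance to a prefix of the infinite repeat (both phases, `TGTG…` and
`GTGT…`, tried; the larger *L* wins, ties by fewer edits) is ≤
⌊`max_edit_rate`·L⌋; a call requires *L* ≥ `min_tail_len` (default 10,
matching the 10-nt prescreen motif) and purity 1 − edits/L ≥ `purity_min`
(default 0.9). Indels inside tails are allowed via the edit distance; a
substitution-only (Hamming) mode exists for cross-checks. `max_edit_rate`
0.1 tolerates roughly one error per 10 nt of tail, in line with modern
long-read error rates.

**Junction canonicalization.** When the genome continues with bases equal to
the start of the tail, the junction is ambiguous; the templated-maximal
convention is used (genome wins), which makes attachment coordinates a
function of the read and reference only, not of aligner internals. This is
implemented as a retract-then-extend pair around the caller:

* *Retraction*: walking inward from the clip through the CIGAR, aligned read
  bases that continue the clip's alternating T/G pattern are pulled back
  into the clip (junction moves inward); inserted repeat bases are pulled in
  without moving the junction; a gap op within 4 columns of where the
  alternation stops is crossed together with the intervening bases. The gap
  lookahead matters because a maximal-scoring aligner can hide absorbed tail
  bases behind a spurious 1-base gap (a gap plus ≥3 repeat bases matching
  the genome scores positively); crossing it restores a synchronized frame.
* *Forward shift*: while the next reference base beyond the junction
  (complemented for strand "−") equals the next clip base, that base is
  reassigned to the templated region — the attachment coordinate advances
  and the tail shortens. Shifting stops at the reference boundary; if the
  tail drops below `min_tail_len` the call is demoted and logged. Purity is
  recomputed on the final tail extent.

Because every base the retraction removes that also matches the genome is
re-absorbed by the forward shift, the pair is a no-op except where the
aligner mis-assigned tail bases, and calls are invariant to the aligner
moving up to four repeat-matching bases between M and S (property-tested on
randomized constructions). In noisy data a genuine indel adjacent to the
junction can displace the reported site by up to the lookahead plus one
(≤ 5 nt), which is the dominant contribution to site error under noise.

**Quantification.** Passing calls are counted per reference; calls on the
spike-in reference are counted separately and never included in viral
counts. Normalization is `norm = raw × S / spike_count` with S = 100
(counts per 100 sequenced spike tails), recorded in the output header — a
single explicit scale constant; only relative comparisons between libraries
are meaningful, so S is configurable. Zero spike tails refuses normalization
with an explicit error while raw counts are still emitted. Attachment
positions (the last templated base — not the clip start or the tail
midpoint) are binned at ⌊pos/binwidth⌋ with binwidth 50 nt over
[0, reference length); the last bin may be short; empty bins are reported as
zeros. Histograms merge strands by default (per-strand counting is available
via a flag). Outputs are a summary TSV, a bedGraph of non-zero bins
(0-based half-open) and BED6 of individual sites; all byte-stable.

## The synthetic-data generator

The generator emulates: the exact five-part read layout above with the real
primer/adapter sequences; tails of even length, uniform 10–60 nt (a range
chosen to straddle the 10-nt calling threshold and so exercise boundary
behaviour — fragment and tail length distributions are otherwise unknown,
defaults are uniform 100–800 nt fragments); tail phase (starts with T or G)
randomized, so the caller must accept both; spike-in reads as fragments of a
dedicated 720-nt "spike" reference carrying a fixed 36-nt (18-unit) tail;
antisense fragments (default 20%); a 0.5-probability strand flip; per-base
substitution/insertion/deletion errors (defaults 3%/1%/1%, Nanopore-like);
and per-base qualities from a normal(12, 3) clipped to [2, 40] — a crude
quality model, sufficient because only the mean-error filter consumes
qualities.

Two generator design points deserve emphasis:

* **Canonical truth junctions.** The attachment coordinate is only
  well-defined up to the templated-maximal convention: a junction base
  matching both genome continuation and tail is indistinguishable from a
  templated base, in the real chemistry as in simulation. The generator
  therefore constrains the tail phase so the genome base just past the
  fragment never equals the first tail base (when that base is T or G the
  phase is forced to the other letter; spike fragments are redrawn
  instead, keeping their fixed UG phase). This makes every truth coordinate
  exactly recoverable in error-free data, which is what gives the clean
  end-to-end check its sharp expectation (sensitivity, precision, site
  exactness all 1.0, tail-length MAE 0).
* **Observed vs true tail length.** The (AC)₉ primer anneals *within* the
  tail, so the cDNA copy can be shorter than the biological tail. The
  default `anneal_policy="end"` copies the full tail (observed = true),
  keeping truth unambiguous for recovery tests; `"uniform"` draws the copied
  length uniformly from {18, …, true} (18 nt = the primer's anneal span),
  reflecting an unknown real anneal distribution. The uniform mode is a
  guess and is excluded from the headline checks.

What the generator does **not** model: basecaller-specific error profiles
(errors are i.i.d. per base, no homopolymer bias — real Nanopore data is
harsher in exactly the regions a TG repeat occupies), PCR duplicates,
barcodes, rRNA carryover, or host-transcriptome decoys. Passing the
simulation checks therefore demonstrates the algorithm's correctness under
the stated read model, not end-to-end performance on real flow-cell data.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally, SAM is 1-based, BED/bedGraph
0-based half-open. Alignment scores are int32. The aligner rejects interior
soft clips and hard clips (records skipped with a logged line number).
Empty clips, adapter-only clips, unmapped and ambiguous reads produce no
call and are logged rather than raised. `bin_sites` treats an out-of-range
position as a hard error, since it indicates an upstream bug rather than bad
data. The flanked-motif search and the tail scorer are deterministic;
phase ties in the tail scorer resolve to fewer edits.

## Problem sizes

The bundled checks simulate 500-read libraries on two references of
3000/2500 nt plus the spike-in — ample to estimate binomial recovery rates
with ~±2% standard error while keeping the whole suite and the
reproduction script each under a minute of compute on one core. Sensitivity
under the noisy condition is seed-dependent (≈0.85–0.92 over seeds);
losses split between reads failing the two-primer full-length requirement
(~5%) and tails whose junction-proximal errors exceed the edit budget of the
prefix-anchored tail definition (~5–9%).

## Known limitations

* The tail definition is prefix-anchored in the clip: sequencing errors
  immediately at the junction consume edit budget first and are the main
  sensitivity cost under noise. A gap-tolerant anchor was deliberately not
  adopted — it would blur the attachment-site definition.
* Site accuracy under noise is bounded by the gap-crossing lookahead (±5 nt
  worst case near a junction-adjacent indel).
* The built-in aligner targets small reference sets (viral segments plus
  controls); it is quadratic per window and unsuitable for
  transcriptome-scale decoy mapping. External aligners can be substituted
  via SAM, subject to the soft-clip (no hard-clip) contract.
* Only alternating two-letter repeats are called (the unit is configurable,
  but poly(A) and homopolymer calling are out of scope).
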