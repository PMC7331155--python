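# Methods

This note documents the models implemented in `trudrop`, their assumptions,
the defaults that matter, and what the synthetic testbed does and does not
establish about real sequencing runs.

## Library structures and primer derivation

The three presets (`TRUSEQ`, `INDROP_V2`, `TRUDROP`) store each strand of
the final library as an ordered list of segments (flow-cell adapter, sample
index, priming site, cell barcodes, W1 spacer, UMI, poly-T, insert), written
5′→3′. Fixed segments hold literal bases; variable segments hold a
placeholder with a length range (sample index 6–10 nt, cell barcode 1
8–11 nt, cell barcode 2 8 nt, UMI 6 nt). Rendering a side with the default
placeholder dialect reproduces the published template strings character for
character, which the template-conformance tests pin down; the transcript
insert renders as the `NNNNNN` random-hexamer prefix actually printed in
the templates, with an unbounded length range behind it.

Index-read primers are not part of the library molecule and are never
printed in template form, so they are *derived*: a read primer equals its
priming site; an index primer is the reverse complement of the priming site
flanking the index, per standard Illumina sequencing chemistry. This
derivation is what exposes the compatibility hazard: the V2 i7 index primer
(revcomp of the truncated site `CTCTTTCCCTACACGACGCTCTTCCGATCT`) and the
TruSeq index primer (revcomp of `GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT`) share
the 13 nt prefix `AGATCGGAAGAGC`.

`mispriming_report` compares primers of the **same read role** across two
structures, not the full cross product. Only primers pooled for the same
read of a shared run compete for annealing, and every Illumina-style index
primer necessarily begins with revcomp(`GCTCTTCCGATCT`) = `AGATCGGAAGAGC`,
so a cross-role comparison would flag a constitutive 13-mer shared even
between two fully standard structures — a false alarm, not a hazard.
Scoring is exact 5′ prefix identity only (threshold 13 nt by default);
thermodynamic annealing models are out of scope.

## Index sets and read assignment

Index sets are validated per side: every i7 pair and every i5 pair must be
at least 2 edits apart (Levenshtein distance, via edlib), so a single base
error cannot convert one sample's index into another's. Sides are never
compared against each other. Sheets mixing index lengths within a side are
rejected rather than padded. Scheme classification: `single` (no i5),
`unique_dual` (no index reused on either side), otherwise
`combinatorial_dual`.

Read assignment matches each observed index to the unique sheet index
within a Hamming-distance tolerance (default 1 mismatch, the common
demultiplexer default; the distance-2 validation guarantees a unique
1-mismatch neighbourhood only for substitution errors, so ambiguous best
matches return `undetermined`). For dual sheets, a read whose two sides
match sheet indexes but form a combination no sample was assigned is
classified `filtered_hopped` — the unique-dual countermeasure. Single-index
sheets use i7 only and can never filter.

## Collision model

For a pool of `S` single-indexed samples of `c` cells each (`k = S·c`), all
cells are treated as one pooled sample because a hop can move a read
between any two samples. Cell barcodes are uniform independent draws from a
space of size `N`; the probability that a focal cell shares its barcode is
`P_c = 1 − (1 − 1/N)^(k−1)` (exact for a focal cell; the exponent excludes
the cell itself — using `k` instead changes results by < 10⁻⁴ at default
scales). Index hopping is a per-cell Bernoulli event with probability `h`,
independent of collision, so the discarded fraction is
`P_c + h − P_c·h`.

Defaults: `c = 3000` cells per sample, `h = 0.0485` (the documented NovaSeq
hop rate), `N = 147,456 = 384 × 384`. `N` is nowhere a published constant;
384 × 384 is the inDrop V2 bead-barcode combination count and reproduces
the published 8.67 % discard figure for a pool of 2 to within 0.03
percentage points. Pools beyond size 2 are covered by the monotonicity
properties rather than by value assertions, because the published list of
five pool sizes carries only four percentages and the mapping is ambiguous.
The model assumes uniform barcode usage; real bead lots have skewed
whitelist frequencies, which would increase collisions.

`mc_discard` is the Monte-Carlo counterpart (uniform draws, duplicate
detection, independent hop flags) and agrees with the analytic value within
3 standard errors across the tested grid; it is the stochastic route used
by the acceptance script (200 pools × 6,000 cells = 1.2 × 10⁶ simulated
cells, a few seconds on one CPU).

## Hop simulator

`simulate_pool` emulates only what demultiplexing can see. Per read: the
sample is fixed by the read budget; bc1 (length uniform on 8–11), bc2
(8 nt) and UMI (6 nt) are uniform random, or drawn from per-sample cell
pools over a 384 × 384 whitelist space when `cells_per_sample` is set
(cells sampled per read with replacement, or round-robin for exact
per-cell read counts); the barcode read is `bc1 + W1 + bc2 + UMI + poly-T
fill` and the transcript read is uniform random sequence.

Hopping swaps one side's index for a uniformly chosen *other* sample's
index on that side. Dual sheets hop each side independently at `h/2`, so
the per-read probability of at least one hopped side is
`1 − (1 − h/2)² ≈ h` and single-side hops dominate; double-side hops are
rare (`h²/4`) and, when both sides land on the same foreign sample, form an
anticipated pair that no scheme can detect — the simulator keeps them and
the scorer counts them as mis-assigned. Single-index sheets hop i7 at the
full rate `h`, making the mis-assignment rate of a single-indexed pool
directly comparable to `h`. Whether i7 and i5 hop at equal rates on real
flow cells is not documented; the split is a modelling choice.

Qualities follow a configurable per-cycle model (constant Q37 by default,
optionally a profile with Gaussian spread, rounded and clipped to [2, 40]).
Base-calling errors are **not** injected — observed indexes differ from
truth only by hopping, so simulated "percent perfect index reads" is 100 %.
Real runs add index-read sequencing errors, primer cross-talk, and
cluster-density effects the simulator does not model; passing tests
establish the correctness of the filtering logic and the internal
consistency of the rates, not sequencer behaviour.

FASTQ output is standard 4-line Phred+33 via Biopython, with I1/I2 index
files and a bcl2fastq-style `i7+i5` header comment (either source is
accepted on input); identical seeds give byte-identical files.

### The single-index countermeasure

`single_index_collision_loss` implements the truth-free discard rule: any
(bc1, bc2) barcode observed in the retained reads of ≥ 2 samples is
discarded everywhere. Its expected yield depends on read depth per cell in
a way the per-cell analytic model deliberately ignores: with `r` reads per
cell, the probability that a cell is flagged through its own hopped reads
is `1 − (1−h)^r − h^r`, which is ≈ 0 at `r = 1` (a whole-cell hop moves
*all* evidence to the wrong sample and is invisible) and → 1 for large
`r`. The cross-module test therefore checks the rule against a closed form
derived for the simulator's actual mechanics (one read per cell, two equal
samples: discard probability `1 − (1 − 1/(2N))^(k−1)`), not against the
analytic `p_discard`, which answers a different question (what fraction of
cells is *unusable*, counting every hopped cell as lost).

## Barcode-read parser and region maps

The parser anchors on the fixed 22 nt W1 spacer at offsets 8–11, taking the
offset with the fewest Hamming mismatches (ties break to the shortest bc1;
indels in W1 are not modelled). The default tolerance of 2 mismatches stays
far below the spacer length, making mis-anchoring on random sequence
vanishingly unlikely. Failures return an invalid record with a diagnostic
rather than raising, since malformed reads are data, not bugs. Optional
bc1/bc2 whitelists gate validity (exact by default, 1-mismatch rescue
configurable).

Region maps translate the published run layouts into 0-based half-open
per-read intervals: V2 NextSeq (100 transcript / 6 index / 50 barcode+UMI
cycles, the last 6 running into poly-A) and TruDrop PE150 (barcode read QC
regions cycles [0, 11) and [30, 50); transcript QC emphasis on the first
100 cycles). The published barcode QC intervals treat W1 as 19 cycles
although the spacer is 22 nt; the region maps follow the published
intervals while the parser uses the true 22 nt spacer.

## Quality statistics

Per-cycle summaries accumulate mean Phred score and fraction ≥ threshold
(default Q30) per cycle; ragged reads contribute only to cycles they cover.
Region means weight per-cycle means by per-cycle base counts — for
uniform-length reads this is a plain mean. Error probabilities use
`p = 10^(−Q/10)`. The published error probabilities are not exactly
`10^(−Q̄/10)` of the published mean qualities (averaging error rates and
averaging qualities do not commute); both orders are available to callers,
and only published probabilities are used in the fold-change checks.

The exact Mann-Whitney test computes the tie-free null distribution of U by
integer partition counting: the number of label arrangements with `U = u`
is the number of partitions of `u` into at most `min(n1, n2)` parts each at
most `max(n1, n2)` — accumulated as Gaussian-binomial coefficients in exact
integer arithmetic, with floating point entering only at the final
division, so 10⁻⁹-scale p-values are exact. The two-sided p doubles the
smaller tail and clamps at 1 (no mid-p correction); this convention
reproduces the published values `2.339 × 10⁻⁹` (U=0, 26 vs 11),
`3.023 × 10⁻⁶` (U=11, 21 vs 11) and `1.243 × 10⁻⁴` (U=25, 21 vs 11)
to four significant figures. The fourth published value (`7.143 × 10⁻³` at
U=49, 21 vs 11) is **not** the exact tie-free p for those arguments: the
partition-count distribution, an independent brute-force enumeration, and
scipy's exact method all give `7.299 × 10⁻³`, and the normal approximation
gives ≈ 8.8 × 10⁻³ — the corresponding test asserts the published value
and is expected to fail, documenting the discrepancy rather than hiding
it. Ties raise an explicit error in raw-sample mode; a normal approximation
with continuity correction is available for large groups and converges to
the exact p (checked at n1 = n2 = 20, mid-range U, < 5 % relative error).

Yield percentages are `observed / target × 100`, rounded half-up to one
decimal to match the published formatting.

## Problem sizes and determinism

The test suite and acceptance script are sized for a single CPU: pooled
simulations of 10⁵ reads (2- and 24-sample sheets), Monte-Carlo collision
runs of ~10⁶ cells, brute-force Mann-Whitney enumeration up to
`n1 + n2 = 14`, and property tests with derandomised generators. Every
stochastic path takes an explicit seed; stochastic assertions use
3-standard-error tolerances fixed in advance.

## Known limitations

* No modelling of index-read base-calling errors, so observed
  "percent perfect index reads" cannot degrade as it does on real runs.
* Uniform barcode-usage and hop-destination distributions; real bead lots
  and flow cells are skewed.
* Prefix-identity mispriming only; no annealing thermodynamics.
* Barcode-error correction graphs, alignment, and UMI counting are out of
  scope — the parser stops at (bc1, bc2, UMI) recovery.
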