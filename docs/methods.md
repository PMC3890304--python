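# Methods

This note documents the models, conventions and numerical choices
behind preyprimer, and what its synthetic fixtures do and do not
establish about real data.

## The assay model

The toolkit implements the computational side of a species-specific
PCR prey-detection assay. The biological design it encodes:

- a fast-evolving marker (typified by the mitochondrial control
  region / D-loop) is aligned for the target species and a panel of
  *confounder* taxa — species whose DNA could plausibly be present in a
  predator's gut and cross-amplify;
- primer footprints are placed where the target's sequence is separated
  from every confounder, with a stricter separation demanded from
  confounders whose geographic range overlaps the target's (those are
  the realistic false-positive sources);
- a specific (inner) pair is nested inside a general (outer) pair that
  amplifies the whole taxon group, supporting confirmation and
  re-amplification;
- in the field survey, a universal primer pair acts as a positive
  control for each gut-content extract, gating which specimens can be
  said to have testable DNA at all.

## Difference counting

All specificity arithmetic rests on one primitive,
`count_differences`: two aligned strings of equal length are compared
column by column; a column counts as a difference when the IUPAC
expansion sets of its two symbols are disjoint, a base-vs-gap column
counts one, and a gap-vs-gap column counts zero. Consequences:

- a degenerate primer position (e.g. R) matches either of its
  expansions at zero cost;
- an ambiguous confounder residue whose set contains the target base
  counts as *no* difference — the conservative reading, refusing to
  claim specificity that an unresolved confounder base might defeat;
- a multi-column gap counts one difference per column (a literal
  "mismatches plus insertions/deletions" tally). A run-length mode
  (one difference per maximal gap run) is available via
  `gap_mode="run"` for users who prefer event counting; the per-column
  mode is the default and the one used everywhere in validation.

## Diagnostic-window search

Candidate windows begin and end on alignment columns where the target
has a residue, and are constrained by the target's *ungapped* length
(default 18–26 nt, the realistic primer range; the length band is a
parameter). A window passes when its minimum difference count over all
confounders is ≥ `t_all` (default 1) and over range-overlapping
confounders is ≥ `t_overlap` (default 2); with no overlap-flagged
confounders the second tier is vacuous and recorded as such. Passing is
monotone under window extension, so the default report lists *maximal*
passing windows (no passing window strictly contains them);
`include_subwindows=True` enumerates all. Ordering is deterministic:
reference start ascending, then longest first.

The default implementation uses per-confounder column-difference
prefix sums (O(1) per window/confounder after an O(columns) setup); the
test suite and the acceptance script compare it against an independent
brute-force rescan of every window.

## Thermodynamics

Melting temperatures use the SantaLucia 1998 unified nearest-neighbor
parameter set with the entropy salt correction
0.368·(N−1)·ln[Na⁺] and

Tm = 1000·ΔH° / (ΔS°(salt-corrected) + R·ln C_eff) − 273.15 (°C),

with ΔH° in kcal/mol, ΔS° in cal/(mol·K), R = 1.987 cal/(mol·K).
Defaults: 50 mM monovalent salt, 0 mM divalent (divalent, when given,
is folded in as [Na⁺] + 120·√[Mg²⁺]), total oligo concentration
0.25 µM with effective duplex concentration C_eff = half of it — the
one-strand-in-modest-excess convention, chosen because it reproduces
the values printed by the oligo-analysis calculator this assay family
was designed with to within 0.5 °C; the published values themselves are
only held to a ±2 °C band since that calculator's exact model is
proprietary. Degenerate oligos are handled by averaging Tm over all
expansions when there are ≤ 64, otherwise by collapsing each ambiguous
position to its most stable member (G > C > A > T). Oligos shorter than
8 nt are rejected rather than extrapolated. Secondary-structure folding
and RNA parameters are out of scope.

GC% is ambiguity-weighted: each symbol contributes the G/C fraction of
its expansion set (S=1, R=Y=K=M=N=0.5, W=0, B=V=2/3, D=H=1/3), reported
rounded half-up to one decimal. Two cells of the original published
primer sheet (31.5 and 27.7) appear to have been truncated rather than
rounded (6/19 = 31.58, 5/18 = 27.78); this package rounds, so it prints
31.6 and 27.8 for those two primers, and the discrepancy is noted
rather than imitated.

## Coordinates and product length

All user-facing coordinates are 1-based inclusive on the plus strand of
the ungapped target reference; alignment columns map to reference
positions by counting non-gap target characters (gap columns map to the
preceding residue and are flagged). Footprints that begin upstream of
the reference's first position are stored with start ≤ 0.

Published amplicon sizes in this assay family equal
`rev_end − fwd_start` — one less than the inclusive footprint-to-
footprint span. Both conventions are computed on every pair
(`product_length_reported`, `product_length_inclusive`); the former is the
reported default so that the published sheet is reproduced verbatim,
and the off-by-one is documented here rather than silently "fixed".

## In-silico PCR

Binding sites are ungapped, ambiguity-aware matches of the primer (or
its reverse complement, for reverse primers) at every template offset,
under a mismatch budget. Defaults are deliberately conservative:
`max_mismatch=0`, and any mismatch in the primer's 3'-terminal 3 nt
disqualifies a site even when the budget would allow it, because
3'-end mismatches are the ones that most reliably abort extension —
in the motivating assay, natural template variation under two of the
specific reverse primers is the accepted explanation for those pairs
failing in practice. Templates are scanned in both orientations and
hits reported in plus-strand coordinates, so FASTA orientation is
irrelevant. Indels inside a binding site are not modelled (no gapped
primer alignment), and no attempt is made to predict *unreliable*
amplification — the observed behaviour of universal primers on
mismatched templates has no clean threshold semantics.

## Survey scoring

Five categories: Empty (empty gut; PCR calls ignored), then the 2×2 of
(universal-control call × prey-specific call). Two prevalence
denominators:

- **all**: prey-positives / n;
- **amplifiable**: prey-positives / (Uni+WF− + Uni+WF+ + Uni−WF+).
  A control-negative but prey-positive specimen remains in the
  denominator: its extract demonstrably contained amplifiable DNA. This
  is the rule under which the reconstructed historical survey gives
  12/42 = 28.6%.

Percentages are rounded half-up to one decimal. A zero amplifiable
denominator is reported as undefined (None), never as 0%. The
percentile bootstrap resamples specimens with replacement; resamples
with a zero denominator are dropped and counted, with a warning flag
when they exceed half of the resamples. Prevalence is a detection
proportion only — the toolkit deliberately does not convert it into a
predation or consumption rate (gut passage time bounds what a positive
means, and scavenging/secondary predation cannot be excluded).

## Synthetic fixtures

`generate_panel` draws a uniform-random background sequence, then:

- mutates the target at chosen positions inside each planted window —
  `diffs_vs_overlapping` positions per window, with one difference
  pinned at each window end;
- non-overlapping confounders copy the target's variant base at all but
  `diffs_vs_all` of those positions, so their in-window count is exact;
- the first overlap-flagged confounder (the "twin") receives no
  background mutations at all, making it identical to the target
  outside the planted windows;
- remaining confounders take i.i.d. substitutions (default rate 0.05)
  and single-column deletions (default 0.01) outside the planted
  windows and outside two reserved conserved footprints (the
  general-pair primer sites).

The twin forces `min_diff_all = 0` for every window not overlapping a
planted interval, so no spurious diagnostic window can pass; endpoint
pinning means that at thresholds equal to the planted counts and a
window cap equal to the planted length, each planted interval is the
*unique* maximal diagnostic window (`exact_recovery_params` returns
those settings). Every generated panel is re-verified by direct
recount before being returned. Default study conditions: 482 alignment
columns, four 18-nt planted windows at the footprints of the motivating
assay, 7 confounders (3 range-overlapping), 2 differences vs all / 4 vs
overlapping — comfortably above the 1/2 design minimums, as the
empirical regions typically were.

What passing on these fixtures does *not* show: robustness to
phylogenetically correlated variation, shared indels, alignment error,
or intraspecific variation in the target (the motivating assay's own
failure mode — primers designed from a single reference haplotype can
miss natural variants). The generator is i.i.d. by construction.

`generate_survey` has two modes: exact counts (largest-remainder
rounding of n·p, deterministic — used wherever a known tally must be
reproduced) and multinomial sampling (for parameter-recovery checks).
Both shuffle record order and are deterministic per seed
(numpy PCG64 `default_rng`).

## Problem sizes in validation

The test suite and acceptance script validate window search against the
brute-force oracle on 100 random panels of up to 8 sequences × 300
columns, planted-window recovery and in-silico PCR specificity on 100
default-condition panels each, and survey parameter recovery at
n = 10,000 records within 3 binomial standard errors — sizes at which
the brute-force oracles remain exact and fast.

## Known limitations

- Tm is duplex-formation thermodynamics only; no hairpin/self-dimer
  free energies (the dimer screen is a complementarity-run heuristic,
  not a ΔG model).
- Binding-site search is ungapped; a primer spanning a template indel
  is reported as a non-match.
- The amplifiable-denominator rule assumes the universal control and
  specific pair have comparable sensitivity on degraded extracts.
- Per-site prevalence machinery is provided (`group_by`), but fixtures
  assign sites uniformly at random; no spatial structure is simulated.
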