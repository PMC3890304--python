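# preyprimer

Toolkit for designing and scoring species-specific PCR assays that
detect prey DNA in predator gut contents ("molecular gut-content
analysis"). It was built around the classic assay architecture used to
detect winter flounder (*Pseudopleuronectes americanus*) mitochondrial
control-region DNA in blue crab (*Callinectes sapidus*) foreguts, but
every stage is generic: any target species, marker, confounder set and
predator survey can be plugged in.

It is aimed at molecular ecologists who have a marker alignment of
their prey species against potential cross-amplifying taxa and want to
(1) find primer sites that are diagnostic for the prey, (2) check
specificity computationally before ordering oligos, and (3) turn a
stack of per-specimen PCR calls into defensible prevalence numbers.

## What it computes

**Diagnostic windows.** Given an aligned panel with one *target* record
and labelled *confounder* records (each flagged for geographic range
overlap with the target), a window of alignment columns is diagnostic
when

> min over all confounders of d(target, confounder) ≥ t_all (default 1), and
> min over range-overlapping confounders ≥ t_overlap (default 2),

where d counts mismatches plus indel columns, ambiguity-code aware
(R matches A or G, etc.). The stricter tier for sympatric taxa reflects
that those are the species the assay could actually mis-call in the
field. `find_diagnostic_windows` returns every maximal passing window
with per-confounder counts; primers are then cut from windows with
`make_primer` / `pair_up`, which also computes GC% (ambiguity-weighted)
and nearest-neighbor melting temperature

> Tm = ΔH° / (ΔS° + 0.368·(N−1)·ln[Na⁺] + R·ln C) − 273.15

with SantaLucia-98 unified stack parameters. `check_nested` verifies
that a specific (inner) pair sits inside a general (outer) pair's
amplicon, and `dimer_score` screens primer pairs for complementary runs.

**In-silico PCR.** `predict_amplicons` scans templates (both
orientations) for ambiguity-aware primer binding sites under a mismatch
budget (default 0, with 3'-terminal mismatches forbidden over a 3-nt
window) and pairs compatible forward/reverse sites into predicted
products, reproducing the amplification matrix a wet-lab specificity
test would give.

**Survey scoring.** `summarize` classifies per-specimen records into
the five detection categories — Empty, Uni−WF−, Uni−WF+, Uni+WF−,
Uni+WF+ (universal control call × prey-specific call) — and reports
prevalence as prey-positive/all specimens and prey-positive/specimens
with amplifiable DNA, plus per-site/date breakdowns and a bootstrap CI.

**Synthetic panels.** `generate_panel` builds alignments with planted
diagnostic windows whose per-confounder difference counts are exact (a
built-in recount gate), and `generate_survey` builds assay tables with
known category proportions — every stage of the toolkit is testable
against a known ground truth without downloading anything.

## Worked example

`examples/score_gut_content_survey.py` reconstructs the original
55-crab wild survey from its published tallies and prints:

```
category  count
   Empty      5
 Uni-WF-      8
 Uni-WF+      1
 Uni+WF-     30
 Uni+WF+     11
   total     55

prey-positive specimens: 12
prevalence, all specimens:        21.8%  (12/55)
prevalence, amplifiable extracts: 28.6%  (12/42)
bootstrap 95% CI (amplifiable):   [15.4%, 42.9%]
```

21.8% of all surveyed crabs carried detectable winter flounder DNA;
restricting the denominator to the 42 specimens whose extracts
demonstrably supported PCR (nonempty gut, positive with either primer
pair — including the one control-negative but prey-positive crab)
raises the estimate to 28.6%. The wide bootstrap interval is what a
55-specimen survey buys.

The other examples cover the design stages:
`design_diagnostic_primers.py` (recovering planted diagnostic windows
and cutting a primer pair from them), `published_primer_sheet.py`
(recomputing GC%, Tm, amplicon lengths and nesting for the published
primer catalogue), and `insilico_pcr_specificity.py` (the predicted
amplification matrix on a synthetic panel).

A thin CLI wraps the same calls:

```sh
preyprimer design --alignment aln.fasta --labels labels.tsv --t-all 1 --t-overlap 2
preyprimer ispcr  --primers pairs.tsv --templates templates.fasta --max-mismatch 0
preyprimer survey --records crabs.tsv --group-by site --bootstrap 1000 --seed 7
```

## Layout

- `src/preyprimer/sequtils.py` — IUPAC alphabet, reverse complement,
  GC%, nearest-neighbor Tm, aligned mismatch counting, FASTA I/O
- `src/preyprimer/alignment_panel.py` — labelled alignment loading and
  gapped↔reference coordinate mapping
- `src/preyprimer/diagnostics.py` — diagnostic-window search
- `src/preyprimer/pairdesign.py` — primers, pairs, nesting, dimers
- `src/preyprimer/primers.py` — the published primer catalogue
- `src/preyprimer/ispcr.py` — binding-site search and amplicon prediction
- `src/preyprimer/survey.py` — assay classification and prevalence
- `src/preyprimer/fixtures.py` — synthetic panel/survey generators
- `docs/methods.md` — models, conventions, and design decisions
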