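"""Find diagnostic primer windows in a labelled marker alignment.

Generates a synthetic control-region panel (one target species, seven
confounder taxa, four planted target-unique regions), scans it under
the two-tier rule — at least 1 difference vs every confounder, at least
2 vs confounders whose range overlaps the target's — and cuts a primer
pair from the recovered regions.
"""

from preyprimer import (
    PanelSpec,
    find_diagnostic_windows,
    generate_panel,
    make_primer,
    pair_up,
)
from preyprimer.fixtures import exact_recovery_params

panel, truth = generate_panel(PanelSpec(seed=11))
print(f"panel: 1 target + {len(panel.confounders)} confounders, "
      f"{panel.alignment_length} columns")

windows = find_diagnostic_windows(panel, **exact_recovery_params(truth))
print(f"\n{len(windows)} diagnostic windows (maximal, two-tier thresholds):")
for w in windows:
    print(f"  ref {w.reference_span[0]:>3}-{w.reference_span[1]:<3}  "
          f"len {w.length}  min diffs: all={w.min_diff_all} "
          f"overlap={w.min_diff_overlap}")

# A species-specific pair: forward primer in the first window, reverse
# primer in the last, exactly how a nested inner pair is laid out.
fwd = make_primer(panel, windows[0].reference_span, "forward", name="spec_f")
rev = make_primer(panel, windows[-1].reference_span, "reverse", name="spec_r")
pair = pair_up(fwd, rev, "specific")
print(f"\npair '{pair.pair_name}': product {pair.product_length_reported} bp "
      f"(footprint span {pair.product_length_inclusive} nt)")
for p in (fwd, rev):
    print(f"  {p.name}: {p.sequence}  {p.orientation[:3]} "
          f"{p.start}-{p.end}  Tm {p.tm_celsius:.1f} C  GC {p.gc_percent}%")

# Each printed window is an interval where the target is separable from
# every confounder; primers cut from two such windows can only amplify
# the target, which the in-silico PCR example verifies.
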