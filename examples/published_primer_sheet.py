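"""Recompute the published winter-flounder assay primer sheet.

The catalogue holds the primers of the original assay (WF =
winter-flounder-specific, FF = general flatfish, plus the 18S and COI
mini-barcode universal controls). GC%, nearest-neighbor Tm and
amplicon lengths are recomputed from the sequences and footprint
coordinates alone.
"""

from preyprimer import check_nested, dimer_score
from preyprimer.primers import PUBLISHED_PRIMERS, published_pair

print(f"{'name':<14}{'dir':<5}{'footprint':<12}{'Tm':>6}{'GC%':>7}  sequence")
for name, p in PUBLISHED_PRIMERS.items():
    span = f"{p.start}-{p.end}"
    print(f"{name:<14}{p.orientation[:3]:<5}{span:<12}"
          f"{p.tm_celsius:>6.1f}{p.gc_percent:>7}  {p.sequence}")

print("\namplicon lengths (reported convention, rev_end - fwd_start):")
for pair_name in ("WF92", "WF127", "WF208", "FF450", "FF530", "Unibar"):
    pair = published_pair(pair_name)
    print(f"  {pair_name:<7} {pair.product_length_reported} bp")

# The species-specific pairs are nested inside the outer flatfish pair,
# so a positive can be re-amplified/confirmed with the outer primers.
outer = published_pair("FF530")
for name in ("WF92", "WF127", "WF208"):
    rep = check_nested(published_pair(name), outer)
    print(f"  {name} nested in FF530: {rep.nested} "
          f"(margins 5'={rep.margin_5p} nt, 3'={rep.margin_3p} nt)")

# Primer-dimer screen: longest perfect complementary run between the
# two primers of the main detection pair.
wf208 = published_pair("WF208")
rep = dimer_score(wf208.forward, wf208.reverse)
print(f"\nWF208 dimer screen: max complementary run {rep.max_run} nt "
      f"(3'-anchored {rep.three_prime_run} nt)")
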