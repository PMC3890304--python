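"""In-silico PCR: predict amplification of templates by a primer pair.

A binding site is an ungapped, ambiguity-aware match of a primer (or of
its reverse complement, for reverse primers) on the template plus
strand, allowing up to ``max_mismatch`` differences; sites carrying a
mismatch inside the primer's 3'-terminal window can be excluded, since
3'-end mismatches are the ones that most reliably abort extension.
Amplicons pair a forward site with a downstream reverse site within a
product-size cap. Templates are scanned in both orientations (hits from
the reverse-complement scan are mapped back to plus-strand coordinates),
so template orientation in user FASTA does not matter.

Defaults are conservative: ``max_mismatch=0`` and no 3'-window mismatch
over 3 nt — any primer-site variation is treated as potential
amplification failure. Indels inside binding sites are not modelled
(matching is ungapped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import InvalidSequenceError
from .pairdesign import FORWARD, REVERSE, Primer, PrimerPair
from .sequtils import NucSequence, SeqLike, as_sequence, bases_compatible, reverse_complement

DEFAULT_MAX_PRODUCT = 2000
DEFAULT_3P_WINDOW = 3


@dataclass(frozen=True)
class BindingSite:
    """One primer match on the template plus strand (1-based inclusive)."""

    start: int
    end: int
    mismatches: int
    three_prime_mismatch: bool


@dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product on one template."""

    template_id: str
    fwd_site: tuple[int, int]
    rev_site: tuple[int, int]
    product_length_reported: int
    product_length_inclusive: int
    fwd_mismatches: int
    rev_mismatches: int
    three_prime_mismatch_fwd: bool
    three_prime_mismatch_rev: bool
    strand: str = "+"


def _require_ungapped(seq: NucSequence, what: str) -> NucSequence:
    if seq.is_gapped:
        raise InvalidSequenceError(f"{what} {seq.id!r} must be ungapped")
    return seq


def find_binding_sites(
    primer: Primer,
    template: SeqLike,
    *,
    max_mismatch: int = 0,
    forbid_3prime_mismatch: bool = True,
    three_prime_window: int = DEFAULT_3P_WINDOW,
) -> list[BindingSite]:
    """Every plus-strand binding site of a primer on a template.

    Forward primers are matched as-is; reverse primers are matched as
    their reverse complement (the plus-strand footprint they anneal to).
    Every offset is tested (exhaustive scan). Ambiguity codes match any
    member of their expansion set on either side.
    """
    tpl = _require_ungapped(as_sequence(template), "template")
    probe = _require_ungapped(primer.sequence, "primer")
    if primer.orientation == REVERSE:
        probe = reverse_complement(probe)
    p, t = probe.residues, tpl.residues
    L = len(p)
    # Probe indices lying in the primer's 3'-terminal window. For a
    # forward primer the 3' end is the probe's right end; a reverse
    # primer's 3' end maps to the left end of its plus-strand footprint.
    if primer.orientation == FORWARD:
        three_p = set(range(max(0, L - three_prime_window), L))
    else:
        three_p = set(range(min(three_prime_window, L)))
    sites = []
    for off in range(len(t) - L + 1):
        mism = 0
        three_hit = False
        for j in range(L):
            if not bases_compatible(p[j], t[off + j]):
                mism += 1
                if j in three_p:
                    three_hit = True
                if mism > max_mismatch:
                    break
        else:
            if forbid_3prime_mismatch and three_hit:
                continue
            sites.append(
                BindingSite(
                    start=off + 1, end=off + L,
                    mismatches=mism, three_prime_mismatch=three_hit,
                )
            )
    return sites


def _scan_one_orientation(
    pair: PrimerPair,
    tpl: NucSequence,
    strand: str,
    plus_length: int,
    **kw,
) -> list[AmpliconHit]:
    max_product = kw.pop("max_product")
    fwd_sites = find_binding_sites(pair.forward, tpl, **kw)
    rev_sites = find_binding_sites(pair.reverse, tpl, **kw)
    hits = []
    for f in fwd_sites:
        for r in rev_sites:
            if r.start <= f.end:
                continue
            product = r.end - f.start
            if product > max_product:
                continue
            fs, rs = (f.start, f.end), (r.start, r.end)
            if strand == "-":
                # Map spans from the reverse-complement scan back to the
                # template's plus strand.
                fs, rs = (
                    (plus_length - rs[1] + 1, plus_length - rs[0] + 1),
                    (plus_length - fs[1] + 1, plus_length - fs[0] + 1),
                )
            hits.append(
                AmpliconHit(
                    template_id=tpl.id,
                    fwd_site=fs,
                    rev_site=rs,
                    product_length_reported=product,
                    product_length_inclusive=product + 1,
                    fwd_mismatches=f.mismatches,
                    rev_mismatches=r.mismatches,
                    three_prime_mismatch_fwd=f.three_prime_mismatch,
                    three_prime_mismatch_rev=r.three_prime_mismatch,
                    strand=strand,
                )
            )
    return hits


def predict_amplicons(
    pair: PrimerPair,
    templates: Sequence[SeqLike],
    *,
    max_mismatch: int = 0,
    max_product: int = DEFAULT_MAX_PRODUCT,
    forbid_3prime_mismatch: bool = True,
    three_prime_window: int = DEFAULT_3P_WINDOW,
    scan_both_strands: bool = True,
) -> list[AmpliconHit]:
    """All predicted products of a pair on a set of templates.

    Every compatible forward/reverse site combination with a product
    length (reported convention, rev_end − fwd_start) at most
    ``max_product`` is returned, sorted by template then position. An
    empty list predicts no amplification.
    """
    kw = dict(
        max_mismatch=max_mismatch,
        forbid_3prime_mismatch=forbid_3prime_mismatch,
        three_prime_window=three_prime_window,
        max_product=max_product,
    )
    hits: list[AmpliconHit] = []
    for template in templates:
        tpl = _require_ungapped(as_sequence(template), "template")
        hits.extend(_scan_one_orientation(pair, tpl, "+", len(tpl), **kw))
        if scan_both_strands:
            hits.extend(
                _scan_one_orientation(
                    pair, reverse_complement(tpl), "-", len(tpl), **kw
                )
            )
    hits.sort(key=lambda h: (h.template_id, h.fwd_site, h.rev_site, h.strand))
    return hits


def hits_to_table(hits: list[AmpliconHit]):
    """Tabulate amplicon hits (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "template": h.template_id,
                "strand": h.strand,
                "fwd_start": h.fwd_site[0],
                "fwd_end": h.fwd_site[1],
                "rev_start": h.rev_site[0],
                "rev_end": h.rev_site[1],
                "product_length": h.product_length_reported,
                "fwd_mismatches": h.fwd_mismatches,
                "rev_mismatches": h.rev_mismatches,
            }
            for h in hits
        ]
    )


def hits_to_bed(hits: list[AmpliconHit]) -> str:
    """Amplicons as BED (0-based half-open, template plus strand)."""
    lines = [
        f"{h.template_id}\t{h.fwd_site[0] - 1}\t{h.rev_site[1]}"
        f"\tamplicon_{i + 1}\t{h.product_length_reported}\t{h.strand}"
        for i, h in enumerate(hits)
    ]
    return "\n".join(lines) + ("\n" if lines else "")
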