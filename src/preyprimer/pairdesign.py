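"""Primer and primer-pair construction from reference coordinates.

Primers are recorded as synthesized (5'->3'): a forward primer equals
the plus-strand reference subsequence over its footprint, a reverse
primer is the reverse complement. Footprints are 1-based inclusive on
the ungapped target reference; footprints reaching upstream of the
reference's first position are stored with start < 1.

Two product-length conventions coexist in the literature this toolkit
serves. The *reported* convention here is ``rev_end - fwd_start``
(one less than the inclusive footprint-to-footprint span), because that
is the convention under which published amplicon sizes for this assay
family are internally consistent; the inclusive count is always carried
alongside as ``product_length_inclusive``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import pandas as pd

from .alignment_panel import AlignedPanel
from .errors import GapInPrimerError, GeometryError, SpanError
from .sequtils import (
    COMPLEMENT,
    GAP,
    DEFAULT_THERMO,
    NucSequence,
    SeqLike,
    ThermoParams,
    as_sequence,
    bases_compatible,
    gc_content,
    melting_temp,
    reverse_complement,
)

FORWARD = "forward"
REVERSE = "reverse"

_MIN_PRIMER_LEN = 8


@dataclass(frozen=True)
class Primer:
    """An oligo with reference coordinates and thermodynamic properties."""

    name: str
    sequence: NucSequence
    orientation: str
    reference_span: tuple[int, int]
    gc_percent: float
    tm_celsius: Optional[float]
    reference_id: str = ""

    @property
    def start(self) -> int:
        return self.reference_span[0]

    @property
    def end(self) -> int:
        return self.reference_span[1]

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_sequence(
        cls,
        name: str,
        sequence: SeqLike,
        orientation: str,
        reference_span: tuple[int, int],
        *,
        reference_id: str = "",
        thermo: ThermoParams = DEFAULT_THERMO,
    ) -> "Primer":
        """Build a primer from its synthesized sequence and a known
        footprint (used for catalogued primers whose reference is not at
        hand, including footprints starting before position 1)."""
        seq = as_sequence(sequence, name)
        if orientation not in (FORWARD, REVERSE):
            raise SpanError(f"orientation must be forward/reverse, got {orientation!r}")
        if len(seq) < _MIN_PRIMER_LEN:
            raise SpanError(f"{name}: primer length {len(seq)} < {_MIN_PRIMER_LEN}")
        return cls(
            name=name,
            sequence=seq,
            orientation=orientation,
            reference_span=reference_span,
            gc_percent=gc_content(seq),
            tm_celsius=melting_temp(seq, thermo),
            reference_id=reference_id,
        )


def make_primer(
    reference: Union[AlignedPanel, SeqLike],
    span: tuple[int, int],
    orientation: str,
    *,
    name: str = "",
    thermo: ThermoParams = DEFAULT_THERMO,
) -> Primer:
    """Cut a primer from a reference at a 1-based inclusive footprint.

    ``reference`` may be an :class:`AlignedPanel` (the ungapped target is
    used) or a sequence; for an aligned sequence, a footprint crossing a
    gap is an error. Forward primers are the subsequence as-is, reverse
    primers its reverse complement.
    """
    if isinstance(reference, AlignedPanel):
        ref_seq = reference.ungapped_target()
        ref_id = reference.reference_id
    else:
        ref_seq = as_sequence(reference)
        ref_id = ref_seq.id
    start, end = span
    if start < 1 or end > len(ref_seq) or start > end:
        raise SpanError(
            f"footprint {span} outside reference 1..{len(ref_seq)}"
        )
    sub = ref_seq.residues[start - 1 : end]
    if GAP in sub:
        raise GapInPrimerError(
            f"footprint {span} crosses a gap in reference {ref_id or 'sequence'}"
        )
    if sum(c != GAP for c in sub) < _MIN_PRIMER_LEN:
        raise SpanError(
            f"footprint {span} yields a {len(sub)}-nt oligo (< {_MIN_PRIMER_LEN})"
        )
    seq = NucSequence(sub, name or f"{ref_id}:{start}-{end}")
    if orientation == REVERSE:
        seq = reverse_complement(seq)
    elif orientation != FORWARD:
        raise SpanError(f"orientation must be forward/reverse, got {orientation!r}")
    return Primer(
        name=name or seq.id,
        sequence=seq,
        orientation=orientation,
        reference_span=(start, end),
        gc_percent=gc_content(seq),
        tm_celsius=melting_temp(seq, thermo),
        reference_id=ref_id,
    )


@dataclass(frozen=True)
class PrimerPair:
    pair_name: str
    forward: Primer
    reverse: Primer

    @property
    def product_length_reported(self) -> int:
        """rev_end - fwd_start: the reported amplicon-size convention."""
        return self.reverse.end - self.forward.start

    @property
    def product_length_inclusive(self) -> int:
        return self.product_length_reported + 1


def pair_up(forward: Primer, reverse: Primer, name: str = "") -> PrimerPair:
    """Combine a forward and a reverse primer into a pair.

    The footprints must sit on the same reference, forward entirely
    before reverse (nearly abutting is fine; overlapping is not).
    """
    if forward.orientation != FORWARD or reverse.orientation != REVERSE:
        raise GeometryError(
            f"pair needs a forward and a reverse primer, got "
            f"{forward.orientation}/{reverse.orientation}"
        )
    if (
        forward.reference_id
        and reverse.reference_id
        and forward.reference_id != reverse.reference_id
    ):
        raise GeometryError(
            f"primers sit on different references "
            f"({forward.reference_id!r} vs {reverse.reference_id!r})"
        )
    if forward.start >= reverse.start or forward.end >= reverse.start:
        raise GeometryError(
            f"footprints inverted or overlapping: forward {forward.reference_span} "
            f"vs reverse {reverse.reference_span}"
        )
    return PrimerPair(
        pair_name=name or f"{forward.name}+{reverse.name}",
        forward=forward,
        reverse=reverse,
    )


@dataclass(frozen=True)
class NestingReport:
    nested: bool
    margin_5p: int
    margin_3p: int


def check_nested(inner: PrimerPair, outer: PrimerPair) -> NestingReport:
    """Is the inner pair's amplicon contained in the outer pair's?

    Containment is non-strict (a pair nests within itself with zero
    margins). Margins are in nt: inner-forward start minus outer-forward
    start, and outer-reverse end minus inner-reverse end.
    """
    m5 = inner.forward.start - outer.forward.start
    m3 = outer.reverse.end - inner.reverse.end
    return NestingReport(nested=(m5 >= 0 and m3 >= 0), margin_5p=m5, margin_3p=m3)


@dataclass(frozen=True)
class DimerReport:
    max_run: int
    three_prime_run: int


def dimer_score(a: Primer | SeqLike, b: Primer | SeqLike) -> DimerReport:
    """Primer-dimer heuristic: longest perfect Watson-Crick complementary
    run between two primers in annealing orientation (a 5'->3' against b
    3'->5'), over every relative offset.

    ``three_prime_run`` is the longest such run that involves the
    3'-terminal base of either primer (3'-anchored runs are the ones
    that prime extension). Symmetric in its arguments.
    """
    sa = (a.sequence if isinstance(a, Primer) else as_sequence(a)).residues
    sb = (b.sequence if isinstance(b, Primer) else as_sequence(b)).residues
    rb = sb[::-1]  # b read 3'->5'
    best = best_3p = 0
    for offset in range(-(len(rb) - 1), len(sa)):
        run = 0
        for j in range(len(rb)):
            i = offset + j
            if 0 <= i < len(sa) and bases_compatible(sa[i], COMPLEMENT[rb[j]]):
                run += 1
                best = max(best, run)
                # a's 3' end is index len(sa)-1; b's 3' end is rb index 0.
                if i == len(sa) - 1 or j == 0:
                    best_3p = max(best_3p, run)
            else:
                run = 0
    return DimerReport(max_run=best, three_prime_run=best_3p)


def pairs_to_table(pairs: list[PrimerPair]) -> pd.DataFrame:
    """Serialize primer pairs to a table mirroring a published primer
    sheet: name, direction/position, sequence, Tm, GC%, product length,
    pair name."""
    rows = []
    for p in pairs:
        for primer, role in ((p.forward, "For"), (p.reverse, "Rev")):
            rows.append(
                {
                    "name": primer.name,
                    "direction_position": f"{role}, {primer.start}-{primer.end}",
                    "sequence_5to3": primer.sequence.residues,
                    "tm_celsius": (
                        None
                        if primer.tm_celsius is None
                        else round(primer.tm_celsius, 1)
                    ),
                    "gc_percent": primer.gc_percent,
                    "product_length": (
                        "" if role == "For" else p.product_length_reported
                    ),
                    "pair_name": p.pair_name,
                }
            )
    return pd.DataFrame(rows)


def primers_to_fasta(primers: list[Primer]) -> list[NucSequence]:
    return [NucSequence(p.sequence.residues, p.name) for p in primers]
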