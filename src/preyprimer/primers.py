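"""Catalogue of the published winter-flounder detection primers.

The species-specific (WF) and general-flatfish (FF) primers target the
winter flounder (*Pseudopleuronectes americanus*) mitochondrial control
region, with footprints on GenBank reference U12068; the 18S and
Uni-Minibar (COI mini-barcode) primers are the universal
amplifiability controls (footprints on EU637075 and HM180652
respectively). Footprints are 1-based inclusive; a start of 0 marks a
footprint beginning upstream of the reference's first position.
"""

from __future__ import annotations

from .pairdesign import FORWARD, REVERSE, Primer, PrimerPair, pair_up

_CATALOG = [
    # name, orientation, (start, end), sequence 5'->3', reference
    ("WF200f", FORWARD, (75, 93), "ATAATGAACTAGGACATCT", "U12068"),
    ("WF270r", REVERSE, (150, 167), "AATAGGTTTCAGTAAATC", "U12068"),
    ("WF310r", REVERSE, (185, 202), "GTCCTGGACTTTCAGATG", "U12068"),
    ("WF400r", REVERSE, (266, 283), "ATACGAATTTGAGTTGGA", "U12068"),
    ("FF_A", FORWARD, (0, 18), "CCCTAACTCCCAAAGCTAG", "U12068"),
    ("FF_2", REVERSE, (382, 401), "CCTGAAGTAGGAACCAAATG", "U12068"),
    ("FF_3", REVERSE, (465, 482), "TGGGTAACGAGTCGTATG", "U12068"),
    ("18S-A", FORWARD, (-1, 19), "AACCTGGTTGATCCTGCCAGT", "EU637075"),
    ("18S-570R", REVERSE, (597, 616), "GCTATTGGAGCTGGAATTAC", "EU637075"),
    ("Uni-MinibarF1", FORWARD, (3, 28), "TCCACTAATCACAARGATATTGGTAC", "HM180652"),
    ("Uni-MinibarR1", REVERSE, (156, 179), "GAAAATCATAATGAAGGCATGAGC", "HM180652"),
]

PUBLISHED_PRIMERS: dict[str, Primer] = {
    name: Primer.from_sequence(
        name, seq, orientation, span, reference_id=ref
    )
    for name, orientation, span, seq, ref in _CATALOG
}


def published_pair(name: str) -> PrimerPair:
    """The published primer pairs by name: WF92, WF127, WF208 (species-
    specific, nested in the FF amplicons), FF450, FF530 (general
    flatfish), 18S and Unibar (universal controls)."""
    f = PUBLISHED_PRIMERS
    pairs = {
        "WF92": (f["WF200f"], f["WF270r"]),
        "WF127": (f["WF200f"], f["WF310r"]),
        "WF208": (f["WF200f"], f["WF400r"]),
        "FF450": (f["FF_A"], f["FF_2"]),
        "FF530": (f["FF_A"], f["FF_3"]),
        "18S": (f["18S-A"], f["18S-570R"]),
        "Unibar": (f["Uni-MinibarF1"], f["Uni-MinibarR1"]),
    }
    fwd, rev = pairs[name]
    return pair_up(fwd, rev, name)
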