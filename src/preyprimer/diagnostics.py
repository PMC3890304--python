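"""Diagnostic-window search over a labelled marker alignment.

A window of the alignment is *diagnostic* when the target's sequence
differs from every confounder by at least ``t_all`` sites and from every
range-overlapping confounder by at least ``t_overlap`` sites (defaults 1
and 2 — the two-tier rule under which a primer placed in the window is
expected to amplify the target species only).

Differences are counted per aligned column ("mismatches plus
insertions/deletions"): a multi-column gap contributes one difference
per column. A run-length alternative (one difference per maximal gap
run) is available via ``gap_mode="run"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .alignment_panel import AlignedPanel
from .errors import SpanError
from .sequtils import GAP, bases_compatible

DEFAULT_T_ALL = 1
DEFAULT_T_OVERLAP = 2
DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 26


@dataclass(frozen=True)
class DiagnosticWindow:
    """An alignment interval scored against every confounder.

    ``column_span`` and ``reference_span`` are 1-based inclusive;
    ``length`` is the target's ungapped length within the span.
    ``min_diff_overlap`` is None when the panel has no range-overlapping
    confounders, in which case the overlap tier is vacuously satisfied.
    """

    column_span: tuple[int, int]
    reference_span: tuple[int, int]
    length: int
    diff_counts: dict[str, int]
    min_diff_all: int
    min_diff_overlap: Optional[int]
    passes: bool

    @property
    def overlap_tier_vacuous(self) -> bool:
        return self.min_diff_overlap is None


def _window_diffs(
    target: str, other: str, start: int, end: int, gap_mode: str
) -> int:
    """Differences between two aligned rows over columns start..end
    (0-based inclusive)."""
    diffs = 0
    in_gap_run = False
    for i in range(start, end + 1):
        a, b = target[i], other[i]
        gap_col = (a == GAP) != (b == GAP)
        if gap_mode == "run" and gap_col:
            if not in_gap_run:
                diffs += 1
            in_gap_run = True
            continue
        in_gap_run = False
        if not bases_compatible(a, b):
            diffs += 1
    return diffs


def score_window(
    panel: AlignedPanel,
    column_span: tuple[int, int],
    *,
    t_all: int = DEFAULT_T_ALL,
    t_overlap: int = DEFAULT_T_OVERLAP,
    min_primer_len: int = 8,
    gap_mode: str = "per-column",
) -> DiagnosticWindow:
    """Score one alignment interval against every confounder.

    The confounder side is scored conservatively: a column where the
    confounder's ambiguity set contains the target base counts as zero
    differences (no specificity is claimed that an ambiguous confounder
    residue could defeat).
    """
    start, end = column_span
    if not (1 <= start <= end <= panel.alignment_length):
        raise SpanError(
            f"span {column_span} outside alignment 1..{panel.alignment_length}"
        )
    if gap_mode not in ("per-column", "run"):
        raise SpanError(f"unknown gap_mode {gap_mode!r}")
    tgt = panel.target.seq.residues
    length = sum(c != GAP for c in tgt[start - 1 : end])
    if length < min_primer_len:
        raise SpanError(
            f"span {column_span} holds only {length} target residues "
            f"(< min primer length {min_primer_len})"
        )
    diff_counts = {
        c.id: _window_diffs(tgt, c.seq.residues, start - 1, end - 1, gap_mode)
        for c in panel.confounders
    }
    overlap_ids = [c.id for c in panel.overlapping_confounders]
    min_all = min(diff_counts.values())
    min_overlap = min((diff_counts[i] for i in overlap_ids), default=None)
    passes = min_all >= t_all and (min_overlap is None or min_overlap >= t_overlap)
    ref_start, _ = panel.column_to_reference(start)
    ref_end, _ = panel.column_to_reference(end)
    return DiagnosticWindow(
        column_span=(start, end),
        reference_span=(ref_start, ref_end),
        length=length,
        diff_counts=diff_counts,
        min_diff_all=min_all,
        min_diff_overlap=min_overlap,
        passes=passes,
    )


def find_diagnostic_windows(
    panel: AlignedPanel,
    *,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    t_all: int = DEFAULT_T_ALL,
    t_overlap: int = DEFAULT_T_OVERLAP,
    include_subwindows: bool = False,
    gap_mode: str = "per-column",
) -> list[DiagnosticWindow]:
    """All diagnostic windows whose target-ungapped length lies in
    ``[min_len, max_len]``.

    Candidate spans begin and end on columns where the target has a
    residue. By default only maximal passing windows (those not
    contained in a larger passing window) are returned; with
    ``include_subwindows=True`` every passing window is returned.
    Output is ordered by reference start, then longest first.
    """
    if min_len > max_len:
        raise SpanError(f"min_len {min_len} > max_len {max_len}")
    if t_all < 0 or t_overlap < 0:
        raise SpanError("thresholds must be >= 0")
    tgt = panel.target.seq.residues
    nongap_cols = [i for i, c in enumerate(tgt) if c != GAP]  # 0-based
    n = len(nongap_cols)
    if n < min_len:
        return []

    passing: list[DiagnosticWindow] = []
    if gap_mode == "per-column":
        # Per-confounder column difference indicators -> prefix sums, so a
        # window's count is a two-term difference instead of a rescan.
        names = [c.id for c in panel.confounders]
        ind = np.array(
            [
                [not bases_compatible(a, b) for a, b in zip(tgt, c.seq.residues)]
                for c in panel.confounders
            ],
            dtype=np.int32,
        )
        csum = np.zeros((len(names), panel.alignment_length + 1), dtype=np.int32)
        np.cumsum(ind, axis=1, out=csum[:, 1:])
        overlap_idx = [
            i for i, c in enumerate(panel.confounders) if c.overlaps_target_range
        ]
        for a in range(n):
            for length in range(min_len, min(max_len, n - a) + 1):
                start_col = nongap_cols[a]
                end_col = nongap_cols[a + length - 1]
                counts = csum[:, end_col + 1] - csum[:, start_col]
                min_all = int(counts.min())
                if min_all < t_all:
                    continue
                min_overlap = (
                    int(counts[overlap_idx].min()) if overlap_idx else None
                )
                if min_overlap is not None and min_overlap < t_overlap:
                    continue
                ref_start, _ = panel.column_to_reference(start_col + 1)
                ref_end, _ = panel.column_to_reference(end_col + 1)
                passing.append(
                    DiagnosticWindow(
                        column_span=(start_col + 1, end_col + 1),
                        reference_span=(ref_start, ref_end),
                        length=length,
                        diff_counts=dict(zip(names, (int(x) for x in counts))),
                        min_diff_all=min_all,
                        min_diff_overlap=min_overlap,
                        passes=True,
                    )
                )
    else:
        for a in range(n):
            for length in range(min_len, min(max_len, n - a) + 1):
                span = (nongap_cols[a] + 1, nongap_cols[a + length - 1] + 1)
                w = score_window(
                    panel, span, t_all=t_all, t_overlap=t_overlap,
                    min_primer_len=min_len, gap_mode=gap_mode,
                )
                if w.passes:
                    passing.append(w)

    if not include_subwindows:
        passing = _maximal_only(passing)
    passing.sort(key=lambda w: (w.reference_span[0], -w.length, w.reference_span[1]))
    return passing


def _maximal_only(windows: list[DiagnosticWindow]) -> list[DiagnosticWindow]:
    spans = [w.column_span for w in windows]
    out = []
    for w in windows:
        s, e = w.column_span
        contained = any(
            (s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in spans
        )
        if not contained:
            out.append(w)
    return out


def windows_to_table(windows: list[DiagnosticWindow]):
    """Tabulate windows (TSV-ready): coordinates, per-confounder counts."""
    import pandas as pd

    rows = []
    for w in windows:
        row = {
            "col_start": w.column_span[0],
            "col_end": w.column_span[1],
            "ref_start": w.reference_span[0],
            "ref_end": w.reference_span[1],
            "length": w.length,
            "min_diff_all": w.min_diff_all,
            "min_diff_overlap": (
                "" if w.min_diff_overlap is None else w.min_diff_overlap
            ),
            "passes": w.passes,
        }
        for cid, d in sorted(w.diff_counts.items()):
            row[f"diff_{cid}"] = d
        rows.append(row)
    return pd.DataFrame(rows)


def windows_to_bed(windows: list[DiagnosticWindow], reference_id: str) -> str:
    """BED (0-based half-open, reference coordinates) for browser use."""
    lines = [
        f"{reference_id}\t{w.reference_span[0] - 1}\t{w.reference_span[1]}"
        f"\tdiag_{i + 1}\t{w.min_diff_all}\t+"
        for i, w in enumerate(windows)
    ]
    return "\n".join(lines) + ("\n" if lines else "")
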