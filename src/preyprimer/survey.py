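"""Scoring of per-specimen gut-content PCR assays.

Each predator specimen carries a gut status (empty / nonempty) and, for
nonempty guts, two PCR calls: a universal control pair (does the extract
support PCR at all?) and the prey-specific pair. Specimens fall into
five categories — Empty, Uni-WF-, Uni-WF+, Uni+WF-, Uni+WF+ — and
detection prevalence is computed under two denominator rules:

``prevalence_all``
    prey-positive specimens / all specimens.
``prevalence_amplifiable``
    prey-positive specimens / specimens with demonstrably amplifiable
    DNA, i.e. nonempty and positive with *either* pair (a
    control-negative but prey-positive extract evidently contained
    amplifiable DNA and stays in the denominator).

Percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import EmptySurveyError, IncompleteRecordError, PreyPrimerError
from .sequtils import round_half_up

GUT_EMPTY = "empty"
GUT_NONEMPTY = "nonempty"
POSITIVE = "positive"
NEGATIVE = "negative"

CAT_EMPTY = "Empty"
CAT_UNEG_WNEG = "Uni-WF-"
CAT_UNEG_WPOS = "Uni-WF+"
CAT_UPOS_WNEG = "Uni+WF-"
CAT_UPOS_WPOS = "Uni+WF+"
CATEGORIES = (CAT_EMPTY, CAT_UNEG_WNEG, CAT_UNEG_WPOS, CAT_UPOS_WNEG, CAT_UPOS_WPOS)

_TARGET_POSITIVE = {CAT_UNEG_WPOS, CAT_UPOS_WPOS}
_AMPLIFIABLE = {CAT_UNEG_WPOS, CAT_UPOS_WNEG, CAT_UPOS_WPOS}


@dataclass(frozen=True)
class AssayRecord:
    specimen_id: str
    gut_status: str
    control_call: Optional[str] = None
    target_call: Optional[str] = None
    site: Optional[str] = None
    date: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gut_status not in (GUT_EMPTY, GUT_NONEMPTY):
            raise PreyPrimerError(
                f"{self.specimen_id}: gut_status must be "
                f"'{GUT_EMPTY}'/'{GUT_NONEMPTY}', got {self.gut_status!r}"
            )
        for call, label in ((self.control_call, "control"), (self.target_call, "target")):
            if call is not None and call not in (POSITIVE, NEGATIVE):
                raise PreyPrimerError(
                    f"{self.specimen_id}: {label} call must be "
                    f"'{POSITIVE}'/'{NEGATIVE}', got {call!r}"
                )


def classify_record(rec: AssayRecord) -> str:
    """The five-way category of one specimen.

    Empty guts are Empty regardless of any calls; nonempty guts need
    both calls.
    """
    if rec.gut_status == GUT_EMPTY:
        return CAT_EMPTY
    if rec.control_call is None or rec.target_call is None:
        raise IncompleteRecordError(
            f"{rec.specimen_id}: nonempty gut record is missing a PCR call"
        )
    table = {
        (NEGATIVE, NEGATIVE): CAT_UNEG_WNEG,
        (NEGATIVE, POSITIVE): CAT_UNEG_WPOS,
        (POSITIVE, NEGATIVE): CAT_UPOS_WNEG,
        (POSITIVE, POSITIVE): CAT_UPOS_WPOS,
    }
    return table[(rec.control_call, rec.target_call)]


@dataclass(frozen=True)
class SurveySummary:
    """Category tally plus both prevalence estimates (percent, one
    decimal; ``prevalence_amplifiable`` is None when its denominator is
    zero)."""

    n_total: int
    counts: dict[str, int]
    prevalence_all: float
    prevalence_amplifiable: Optional[float]

    @property
    def n_target_positive(self) -> int:
        return self.counts[CAT_UNEG_WPOS] + self.counts[CAT_UPOS_WPOS]

    @property
    def n_amplifiable(self) -> int:
        return sum(self.counts[c] for c in _AMPLIFIABLE)


def _summarize_categories(cats: Sequence[str]) -> SurveySummary:
    counts = {c: 0 for c in CATEGORIES}
    for c in cats:
        counts[c] += 1
    n = len(cats)
    positive = counts[CAT_UNEG_WPOS] + counts[CAT_UPOS_WPOS]
    amplifiable = sum(counts[c] for c in _AMPLIFIABLE)
    return SurveySummary(
        n_total=n,
        counts=counts,
        prevalence_all=round_half_up(100.0 * positive / n),
        prevalence_amplifiable=(
            None if amplifiable == 0 else round_half_up(100.0 * positive / amplifiable)
        ),
    )


def summarize(
    records: Iterable[AssayRecord],
    group_by: Optional[Sequence[str]] = None,
) -> Union[SurveySummary, tuple[SurveySummary, dict[tuple, SurveySummary]]]:
    """Overall summary, optionally also per group.

    ``group_by`` names record fields ("site", "date"); when given, the
    return value is ``(overall, {group_key: summary, ...})``.
    """
    records = list(records)
    if not records:
        raise EmptySurveyError("no assay records to summarize")
    cats = [classify_record(r) for r in records]
    overall = _summarize_categories(cats)
    if not group_by:
        return overall
    groups: dict[tuple, list[str]] = {}
    for rec, cat in zip(records, cats):
        key = tuple(getattr(rec, f) for f in group_by)
        groups.setdefault(key, []).append(cat)
    return overall, {k: _summarize_categories(v) for k, v in sorted(groups.items())}


@dataclass(frozen=True)
class BootstrapInterval:
    low: float
    high: float
    n_boot: int
    n_degenerate: int
    degenerate_warning: bool


def bootstrap_ci(
    records: Sequence[AssayRecord],
    *,
    denominator_rule: str = "amplifiable",
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 95.0,
) -> BootstrapInterval:
    """Percentile bootstrap CI for a prevalence.

    Specimens are resampled with replacement; resamples with a zero
    denominator are dropped from the percentile (and flagged as a
    warning when they exceed half of all resamples).
    """
    records = list(records)
    if not records:
        raise EmptySurveyError("no assay records to bootstrap")
    if n_boot < 100:
        raise PreyPrimerError(f"n_boot must be >= 100, got {n_boot}")
    if denominator_rule not in ("all", "amplifiable"):
        raise PreyPrimerError(f"unknown denominator rule {denominator_rule!r}")
    cats = np.array([classify_record(r) for r in records])
    positive = np.isin(cats, list(_TARGET_POSITIVE))
    in_denom = (
        np.ones(len(cats), dtype=bool)
        if denominator_rule == "all"
        else np.isin(cats, list(_AMPLIFIABLE))
    )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(cats), size=(n_boot, len(cats)))
    num = positive[idx].sum(axis=1)
    den = in_denom[idx].sum(axis=1)
    ok = den > 0
    n_degenerate = int((~ok).sum())
    if not ok.any():
        raise PreyPrimerError("every bootstrap resample had a zero denominator")
    prev = 100.0 * num[ok] / den[ok]
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(prev, [alpha, 100.0 - alpha])
    return BootstrapInterval(
        low=round_half_up(float(lo)),
        high=round_half_up(float(hi)),
        n_boot=n_boot,
        n_degenerate=n_degenerate,
        degenerate_warning=n_degenerate > n_boot / 2,
    )


# ---------------------------------------------------------------------------
# Tidy-table I/O

_REQUIRED_COLS = ("specimen_id", "gut_status", "control_call", "target_call")


def read_records(path: Union[str, Path]) -> list[AssayRecord]:
    """Read assay records from a tidy CSV/TSV (header required; one
    specimen per row; empty-gut rows may leave the call columns blank).
    Unknown status or call strings are rejected, not coerced."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise PreyPrimerError(f"{path}: missing columns {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def _opt(key):
            v = d.get(key)
            return None if v is None or pd.isna(v) or v == "" else str(v)

        records.append(
            AssayRecord(
                specimen_id=str(d["specimen_id"]),
                gut_status=str(d["gut_status"]),
                control_call=_opt("control_call"),
                target_call=_opt("target_call"),
                site=_opt("site"),
                date=_opt("date"),
            )
        )
    return records


def records_to_frame(records: Sequence[AssayRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def summary_to_table(summary: SurveySummary) -> pd.DataFrame:
    """Category table in the style of a detection-survey figure legend."""
    rows = [{"category": c, "count": summary.counts[c]} for c in CATEGORIES]
    rows.append({"category": "total", "count": summary.n_total})
    return pd.DataFrame(rows)
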