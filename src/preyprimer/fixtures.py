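"""Synthetic data generators: marker panels with planted diagnostic
windows, template sets for in-silico PCR specificity checks, and assay
surveys with known category proportions.

The panel generator emulates the empirical structure behind a
species-specific assay design: a marker region largely conserved across
the target and its confounder taxa, with a small number of intervals
where the target is unique. Differences are planted so that every
confounder of each class carries *exactly* the specified count inside
each window, one planted difference pins each end of the window, and the
first overlap-flagged confounder (the "twin") is identical to the target
everywhere outside the planted windows. The twin guarantees that no
window outside the planted intervals can pass any positive threshold,
and the endpoint pinning makes each planted interval the unique maximal
diagnostic window when the search thresholds equal the planted counts
and the window cap equals the planted length. Both facts are verified by
direct recount before a panel is emitted.

This is an i.i.d. planting model, not sequence evolution: real marker
alignments have phylogenetically correlated substitutions, rate
heterogeneity and shared indels that these fixtures do not attempt to
reproduce.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .alignment_panel import (
    ROLE_CONFOUNDER,
    ROLE_TARGET,
    AlignedPanel,
    build_panel,
)
from .errors import FixtureSpecError
from .pairdesign import FORWARD, REVERSE, PrimerPair, make_primer, pair_up
from .sequtils import GAP, NucSequence, count_differences, write_fasta
from .survey import (
    CAT_EMPTY,
    CAT_UNEG_WNEG,
    CAT_UNEG_WPOS,
    CAT_UPOS_WNEG,
    CAT_UPOS_WPOS,
    CATEGORIES,
    GUT_EMPTY,
    GUT_NONEMPTY,
    NEGATIVE,
    POSITIVE,
    AssayRecord,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedWindow:
    """One interval to make diagnostic: ``start`` is a 1-based target
    reference position, counts are exact per confounder class."""

    start: int
    length: int
    diffs_vs_all: int
    diffs_vs_overlapping: int

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# Default study conditions: a control-region-sized marker (482 columns,
# the span covered by the outer general-flatfish amplicon) carrying four
# unique regions at the published primer footprints, against seven
# confounder taxa of which three share the target's range. Planted
# difference counts sit above the two-tier minimums (>=1 vs all, >=2 vs
# range-overlapping), as the empirical regions "typically" did.
DEFAULT_WINDOWS = (
    PlantedWindow(75, 18, 2, 4),
    PlantedWindow(150, 18, 2, 4),
    PlantedWindow(185, 18, 2, 4),
    PlantedWindow(266, 18, 2, 4),
)


@dataclass(frozen=True)
class PanelSpec:
    n_confounders: int = 7
    n_overlapping: int = 3
    alignment_length: int = 482
    background_sub_rate: float = 0.05
    indel_rate: float = 0.01
    planted_windows: tuple[PlantedWindow, ...] = DEFAULT_WINDOWS
    conserved_footprints: Optional[tuple[tuple[int, int], ...]] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_confounders < 1 or not 0 <= self.n_overlapping <= self.n_confounders:
            raise FixtureSpecError("need >=1 confounder, 0 <= n_overlapping <= n_confounders")
        for rate in (self.background_sub_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise FixtureSpecError(f"rate {rate} outside [0, 1]")
        wins = sorted(self.planted_windows, key=lambda w: w.start)
        prev_end = 0
        for w in wins:
            if w.start < 1 or w.end > self.alignment_length:
                raise FixtureSpecError(f"window {w.span} outside alignment")
            if w.start <= prev_end:
                raise FixtureSpecError("planted windows overlap")
            prev_end = w.end
            if not 0 <= w.diffs_vs_all <= w.diffs_vs_overlapping <= w.length:
                raise FixtureSpecError(
                    f"window {w.span}: need 0 <= diffs_vs_all <= "
                    f"diffs_vs_overlapping <= length"
                )
        for start, length in self.resolved_footprints():
            if start < 1 or start + length - 1 > self.alignment_length:
                raise FixtureSpecError("conserved footprint outside alignment")
            for w in wins:
                if start <= w.end and w.start <= start + length - 1:
                    raise FixtureSpecError(
                        "conserved footprint overlaps a planted window"
                    )

    def resolved_footprints(self) -> tuple[tuple[int, int], ...]:
        """Conserved primer footprints (start, length); when unset, two
        20-nt footprints flanking the planted windows."""
        if self.conserved_footprints is not None:
            return self.conserved_footprints
        wins = sorted(self.planted_windows, key=lambda w: w.start)
        if not wins:
            return ((1, 20), (self.alignment_length - 19, 20))
        left = max(1, wins[0].start - 30)
        right = min(self.alignment_length - 19, wins[-1].end + 11)
        return ((left, 20), (right, 20))


@dataclass(frozen=True)
class PanelTruth:
    """Ground truth emitted with every synthetic panel."""

    windows: tuple[PlantedWindow, ...]
    diff_positions: tuple[tuple[int, ...], ...]  # per window, 1-based reference
    conserved_footprints: tuple[tuple[int, int], ...]
    seed: int


def _plant_positions(
    rng: np.random.Generator, w: PlantedWindow
) -> tuple[list[int], list[int]]:
    """Choose planted positions P (|P| = diffs_vs_overlapping) and the
    subset Q (|Q| = diffs_vs_all) seen by non-overlapping confounders.
    Window endpoints are pinned first so a passing window at matched
    thresholds must cover the whole planted span."""
    d_over, d_all = w.diffs_vs_overlapping, w.diffs_vs_all
    def _pick(pool: list[int], k: int) -> list[int]:
        if k <= 0:
            return []
        return [int(x) for x in rng.choice(pool, size=k, replace=False)]

    pinned = [w.start, w.end][: min(2, d_over)]
    interior = [p for p in range(w.start + 1, w.end) if p not in pinned]
    positions = sorted(pinned + _pick(interior, d_over - len(pinned)))
    q_pinned = [p for p in ([w.start, w.end][: min(2, d_all)]) if p in positions]
    q_pool = [p for p in positions if p not in q_pinned]
    q = sorted(q_pinned + _pick(q_pool, d_all - len(q_pinned)))
    return positions, q


def generate_panel(spec: PanelSpec) -> tuple[AlignedPanel, PanelTruth]:
    """Deterministically (per seed) generate a labelled panel with
    planted diagnostic windows, plus its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.alignment_length
    background = rng.choice(_BASES, size=L)

    wins = tuple(sorted(spec.planted_windows, key=lambda w: w.start))
    footprints = spec.resolved_footprints()
    protected = np.zeros(L, dtype=bool)  # no background mutation here
    for w in wins:
        protected[w.start - 1 : w.end] = True
    for start, length in footprints:
        protected[start - 1 : start + length - 1] = True

    target = background.copy()
    all_positions: list[tuple[int, ...]] = []
    q_sets: list[set[int]] = []
    for w in wins:
        positions, q = _plant_positions(rng, w)
        for p in positions:
            alt = [b for b in "ACGT" if b != background[p - 1]]
            target[p - 1] = rng.choice(alt)
        all_positions.append(tuple(positions))
        q_sets.append(set(q))

    records = [NucSequence("".join(target), "target")]
    labels: dict[str, dict[str, object]] = {
        "target": {"role": ROLE_TARGET}
    }
    for k in range(spec.n_confounders):
        overlapping = k < spec.n_overlapping
        cid = f"conf_{'ov' if overlapping else 'non'}_{k + 1}"
        row = background.copy()
        if not overlapping:
            # Match the target at the planted positions outside Q, so the
            # in-window difference count is exactly diffs_vs_all.
            for positions, q in zip(all_positions, q_sets):
                for p in positions:
                    if p not in q:
                        row[p - 1] = target[p - 1]
        is_twin = overlapping and k == 0
        if not is_twin:
            mutable = ~protected
            subs = mutable & (rng.random(L) < spec.background_sub_rate)
            for i in np.flatnonzero(subs):
                alt = [b for b in "ACGT" if b != row[i]]
                row[i] = rng.choice(alt)
            dels = mutable & ~subs & (rng.random(L) < spec.indel_rate)
            row[dels] = GAP
        records.append(NucSequence("".join(row), cid))
        labels[cid] = {
            "role": ROLE_CONFOUNDER,
            "overlaps_target_range": overlapping,
        }

    panel = build_panel(records, labels)
    truth = PanelTruth(
        windows=wins,
        diff_positions=tuple(all_positions),
        conserved_footprints=footprints,
        seed=spec.seed,
    )
    _verify_panel(panel, truth)
    return panel, truth


def _verify_panel(panel: AlignedPanel, truth: PanelTruth) -> None:
    """Recount every planted window against every confounder and check
    the twin's identity outside the windows before emitting a panel."""
    tgt = panel.target.seq.residues
    in_window = np.zeros(len(tgt), dtype=bool)
    for w in truth.windows:
        in_window[w.start - 1 : w.end] = True
    for conf in panel.confounders:
        for w in truth.windows:
            expected = (
                w.diffs_vs_overlapping if conf.overlaps_target_range else w.diffs_vs_all
            )
            got = count_differences(
                tgt[w.start - 1 : w.end], conf.seq.residues[w.start - 1 : w.end]
            )
            if got != expected:
                raise FixtureSpecError(
                    f"internal check failed: {conf.id} carries {got} differences "
                    f"in window {w.span}, expected {expected}"
                )
    twin = panel.overlapping_confounders[0] if panel.overlapping_confounders else None
    if twin is not None:
        outside = [
            i for i in range(len(tgt)) if not in_window[i]
        ]
        if any(tgt[i] != twin.seq.residues[i] for i in outside):
            raise FixtureSpecError(
                "internal check failed: twin confounder differs from the "
                "target outside the planted windows"
            )


def exact_recovery_params(truth: PanelTruth) -> dict[str, int]:
    """Search parameters under which the planted windows are the exact
    maximal diagnostic windows: thresholds matched to the planted counts
    and the window cap equal to the planted length. Requires windows of
    one common length and common difference counts."""
    lengths = {w.length for w in truth.windows}
    d_all = {w.diffs_vs_all for w in truth.windows}
    d_over = {w.diffs_vs_overlapping for w in truth.windows}
    if len(lengths) != 1 or len(d_all) != 1 or len(d_over) != 1:
        raise FixtureSpecError(
            "exact recovery is defined for homogeneous planted windows"
        )
    (length,), (t_all,), (t_overlap,) = lengths, d_all, d_over
    return {
        "min_len": min(8, length),
        "max_len": length,
        "t_all": t_all,
        "t_overlap": t_overlap,
    }


def write_panel_fixture(
    panel: AlignedPanel, truth: PanelTruth, directory: Union[str, Path]
) -> dict[str, Path]:
    """Write aligned FASTA + labels TSV + ground-truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "panel.fasta"
    labels = directory / "labels.tsv"
    truth_json = directory / "truth.json"
    write_fasta([r.seq for r in panel.records], fasta)
    with open(labels, "w") as fh:
        for r in panel.records:
            flag = int(bool(r.overlaps_target_range))
            fh.write(f"{r.id}\t{r.role}\t{flag}\n")
    with open(truth_json, "w") as fh:
        json.dump(
            {
                "seed": truth.seed,
                "windows": [asdict(w) for w in truth.windows],
                "diff_positions": [list(p) for p in truth.diff_positions],
                "conserved_footprints": [list(f) for f in truth.conserved_footprints],
            },
            fh,
            indent=2,
        )
    return {"alignment": fasta, "labels": labels, "truth": truth_json}


# ---------------------------------------------------------------------------
# In-silico PCR specificity fixtures


@dataclass(frozen=True)
class SpecificityFixture:
    """Templates plus one target-specific and one conserved primer pair,
    mirroring a published specificity matrix: the specific pair should
    amplify the target template only, the conserved pair every marker
    template, and neither the unrelated predator-like template."""

    specific_pair: PrimerPair
    conserved_pair: PrimerPair
    target_template: NucSequence
    confounder_templates: tuple[NucSequence, ...]
    predator_template: NucSequence

    @property
    def marker_templates(self) -> tuple[NucSequence, ...]:
        return (self.target_template, *self.confounder_templates)

    @property
    def all_templates(self) -> tuple[NucSequence, ...]:
        return (*self.marker_templates, self.predator_template)


def specificity_fixture(spec: PanelSpec) -> SpecificityFixture:
    """Build templates and pairs for a specificity check from a planted
    panel: the specific pair's primers sit in the first and last planted
    windows (so every confounder carries >=1 difference per footprint),
    the conserved pair's in the reserved conserved footprints."""
    panel, truth = generate_panel(spec)
    if len(truth.windows) < 2:
        raise FixtureSpecError("specificity fixture needs >= 2 planted windows")
    w_fwd, w_rev = truth.windows[0], truth.windows[-1]
    specific = pair_up(
        make_primer(panel, w_fwd.span, FORWARD, name="specific_f"),
        make_primer(panel, w_rev.span, REVERSE, name="specific_r"),
        "specific",
    )
    (c1s, c1l), (c2s, c2l) = truth.conserved_footprints[0], truth.conserved_footprints[-1]
    conserved = pair_up(
        make_primer(panel, (c1s, c1s + c1l - 1), FORWARD, name="conserved_f"),
        make_primer(panel, (c2s, c2s + c2l - 1), REVERSE, name="conserved_r"),
        "conserved",
    )
    rng = np.random.default_rng(spec.seed + 1)
    predator = NucSequence(
        "".join(rng.choice(_BASES, size=spec.alignment_length)), "predator"
    )
    return SpecificityFixture(
        specific_pair=specific,
        conserved_pair=conserved,
        target_template=panel.ungapped_target(),
        confounder_templates=tuple(c.seq.ungapped() for c in panel.confounders),
        predator_template=predator,
    )


# ---------------------------------------------------------------------------
# Survey fixtures


def _exact_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder rounding of n * p to integer counts summing to n."""
    raw = [n * p for p in proportions]
    counts = [int(x) for x in raw]
    remainders = [(x - int(x), i) for i, x in enumerate(raw)]
    short = n - sum(counts)
    for _, i in sorted(remainders, key=lambda t: (-t[0], t[1]))[:short]:
        counts[i] += 1
    return counts


_CATEGORY_FIELDS = {
    CAT_EMPTY: (GUT_EMPTY, None, None),
    CAT_UNEG_WNEG: (GUT_NONEMPTY, NEGATIVE, NEGATIVE),
    CAT_UNEG_WPOS: (GUT_NONEMPTY, NEGATIVE, POSITIVE),
    CAT_UPOS_WNEG: (GUT_NONEMPTY, POSITIVE, NEGATIVE),
    CAT_UPOS_WPOS: (GUT_NONEMPTY, POSITIVE, POSITIVE),
}


def generate_survey(
    n: int,
    proportions: Union[dict[str, float], Sequence[float]],
    seed: int = 0,
    *,
    exact_counts: bool = True,
    sites: Optional[Sequence[str]] = None,
    dates: Optional[Sequence[str]] = None,
) -> list[AssayRecord]:
    """Synthetic assay records with known category proportions.

    ``proportions`` follows the category order Empty, Uni-WF-, Uni-WF+,
    Uni+WF-, Uni+WF+ (or is a mapping keyed by those names). With
    ``exact_counts`` the counts are the largest-remainder rounding of
    n*p (deterministic); otherwise a single multinomial draw. Record
    order is shuffled; sites/dates, when given, are assigned uniformly
    at random. Deterministic for a fixed seed.
    """
    if isinstance(proportions, dict):
        unknown = set(proportions) - set(CATEGORIES)
        if unknown:
            raise FixtureSpecError(f"unknown categories: {sorted(unknown)}")
        props = [float(proportions.get(c, 0.0)) for c in CATEGORIES]
    else:
        props = [float(p) for p in proportions]
    if len(props) != len(CATEGORIES):
        raise FixtureSpecError(f"need {len(CATEGORIES)} proportions, got {len(props)}")
    if any(p < 0 for p in props):
        raise FixtureSpecError("proportions must be >= 0")
    if abs(sum(props) - 1.0) > 1e-6:
        raise FixtureSpecError(f"proportions sum to {sum(props)}, not 1")
    if n < 1:
        raise FixtureSpecError("n must be >= 1")

    rng = np.random.default_rng(seed)
    if exact_counts:
        counts = _exact_counts(n, props)
    else:
        counts = rng.multinomial(n, props).tolist()
    cats = [c for c, k in zip(CATEGORIES, counts) for _ in range(k)]
    order = rng.permutation(len(cats))
    width = len(str(n))
    records = []
    for rank, idx in enumerate(order, start=1):
        gut, control, target = _CATEGORY_FIELDS[cats[idx]]
        records.append(
            AssayRecord(
                specimen_id=f"S{rank:0{width}d}",
                gut_status=gut,
                control_call=control,
                target_call=target,
                site=None if sites is None else str(rng.choice(list(sites))),
                date=None if dates is None else str(rng.choice(list(dates))),
            )
        )
    return records


def published_survey_records() -> list[AssayRecord]:
    """Reconstruction of the published 55-specimen wild survey from its
    printed tallies: 5 empty guts; of the 50 nonempty, 41 control-
    positive of which 11 prey-positive; 1 control-negative but
    prey-positive specimen; the remaining 8 negative with both pairs."""
    counts = {
        CAT_EMPTY: 5,
        CAT_UNEG_WNEG: 8,
        CAT_UNEG_WPOS: 1,
        CAT_UPOS_WNEG: 30,
        CAT_UPOS_WPOS: 11,
    }
    records = []
    i = 0
    for cat, k in counts.items():
        gut, control, target = _CATEGORY_FIELDS[cat]
        for _ in range(k):
            i += 1
            records.append(
                AssayRecord(
                    specimen_id=f"WC{i:02d}",
                    gut_status=gut,
                    control_call=control,
                    target_call=target,
                )
            )
    return records
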