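"""Diagnostic-window scoring and search, checked against a brute-force
all-windows oracle."""

import numpy as np
import pytest

from preyprimer import (
    NucSequence,
    PanelSpec,
    build_panel,
    count_differences,
    find_diagnostic_windows,
    generate_panel,
    score_window,
)
from preyprimer.errors import SpanError
from preyprimer.fixtures import PlantedWindow, exact_recovery_params
from preyprimer.sequtils import GAP


def brute_force_windows(panel, min_len, max_len, t_all, t_overlap):
    """Independent oracle: score every candidate span directly with
    count_differences, then keep maximal passing spans."""
    tgt = panel.target.seq.residues
    nongap = [i for i, c in enumerate(tgt) if c != GAP]
    passing = []
    for a in range(len(nongap)):
        for L in range(min_len, max_len + 1):
            if a + L > len(nongap):
                break
            s, e = nongap[a], nongap[a + L - 1]
            counts = {
                c.id: count_differences(tgt[s : e + 1], c.seq.residues[s : e + 1])
                for c in panel.confounders
            }
            ov = [counts[c.id] for c in panel.overlapping_confounders]
            if min(counts.values()) >= t_all and (not ov or min(ov) >= t_overlap):
                passing.append((s + 1, e + 1))
    maximal = [
        w
        for w in passing
        if not any(
            w2 != w and w2[0] <= w[0] and w[1] <= w2[1] for w2 in passing
        )
    ]
    return sorted(maximal)


def _random_panel(rng):
    n_conf = int(rng.integers(2, 7))
    n_ov = int(rng.integers(0, n_conf + 1))
    cols = int(rng.integers(80, 301))
    spec = PanelSpec(
        n_confounders=n_conf,
        n_overlapping=n_ov,
        alignment_length=cols,
        background_sub_rate=float(rng.uniform(0.0, 0.15)),
        indel_rate=float(rng.uniform(0.0, 0.03)),
        planted_windows=(
            PlantedWindow(int(rng.integers(10, 30)), 14, 2, 3),
            PlantedWindow(int(rng.integers(50, cols - 20)), 14, 2, 3),
        ),
        conserved_footprints=((1, 8),),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return generate_panel(spec)[0]


class TestScoreWindow:
    def _uniform_panel(self):
        row = "ACGTACGTACGTACGTACGT"
        seqs = [NucSequence(row, i) for i in ("t", "c1", "c2")]
        labels = {
            "t": {"role": "target"},
            "c1": {"role": "confounder", "overlaps_target_range": True},
            "c2": {"role": "confounder", "overlaps_target_range": False},
        }
        return build_panel(seqs, labels)

    def test_conserved_region_fails(self):
        w = score_window(self._uniform_panel(), (1, 20))
        assert w.diff_counts == {"c1": 0, "c2": 0}
        assert w.min_diff_all == 0 and not w.passes

    def test_planted_differences_counted(self, small_panel):
        panel, truth = small_panel
        w0 = truth.windows[0]
        w = score_window(panel, w0.span, t_all=2, t_overlap=3, min_primer_len=8)
        assert w.min_diff_all == w0.diffs_vs_all
        assert w.min_diff_overlap == w0.diffs_vs_overlapping
        assert w.passes

    def test_minimum_dominates(self):
        # one confounder identical to the target over the span
        seqs = [
            NucSequence("ACGTACGTACGT", "t"),
            NucSequence("ACGTACGTACGT", "twin"),
            NucSequence("TTTTACGTACGT", "far"),
        ]
        labels = {
            "t": {"role": "target"},
            "twin": {"role": "confounder", "overlaps_target_range": False},
            "far": {"role": "confounder", "overlaps_target_range": False},
        }
        w = score_window(build_panel(seqs, labels), (1, 12))
        assert w.min_diff_all == 0 and not w.passes

    def test_no_overlap_confounders_vacuous_tier(self):
        seqs = [NucSequence("ACGTACGTACGT", "t"), NucSequence("AAATACGTACGT", "c")]
        labels = {
            "t": {"role": "target"},
            "c": {"role": "confounder", "overlaps_target_range": False},
        }
        w = score_window(build_panel(seqs, labels), (1, 12), t_all=1, t_overlap=5)
        assert w.min_diff_overlap is None
        assert w.overlap_tier_vacuous and w.passes

    def test_span_too_short(self, small_panel):
        panel, _ = small_panel
        with pytest.raises(SpanError):
            score_window(panel, (1, 4), min_primer_len=8)

    def test_gap_run_mode_counts_runs_once(self):
        seqs = [NucSequence("ACGTACGTACGT", "t"), NucSequence("ACG---GTACGT", "c")]
        labels = {
            "t": {"role": "target"},
            "c": {"role": "confounder", "overlaps_target_range": False},
        }
        panel = build_panel(seqs, labels)
        per_col = score_window(panel, (1, 12), min_primer_len=8)
        run = score_window(panel, (1, 12), min_primer_len=8, gap_mode="run")
        # per-column counts 3 gap columns + 1 mismatch (T vs G at col 4?) -- compute:
        # t ACGTACGTACGT vs c ACG---GTACGT: cols 4-6 gaps, col 7 G vs G, col 8 T vs T ...
        assert per_col.diff_counts["c"] == 3 + run.diff_counts["c"] - 1
        assert run.diff_counts["c"] == 1


class TestFindDiagnosticWindows:
    def test_uniform_panel_empty(self):
        row = "ACGT" * 10
        seqs = [NucSequence(row, "t"), NucSequence(row, "c")]
        labels = {
            "t": {"role": "target"},
            "c": {"role": "confounder", "overlaps_target_range": True},
        }
        panel = build_panel(seqs, labels)
        assert find_diagnostic_windows(panel, min_len=8, max_len=12) == []

    def test_matches_brute_force_oracle_on_random_panels(self):
        rng = np.random.default_rng(2024)
        for _ in range(12):
            panel = _random_panel(rng)
            for t_all, t_overlap in ((1, 2), (2, 3)):
                got = find_diagnostic_windows(
                    panel, min_len=10, max_len=16, t_all=t_all, t_overlap=t_overlap
                )
                want = brute_force_windows(panel, 10, 16, t_all, t_overlap)
                assert sorted(w.column_span for w in got) == want

    def test_threshold_monotonicity(self, default_panel):
        panel, _ = default_panel
        loose = {
            w.column_span
            for w in find_diagnostic_windows(
                panel, min_len=10, max_len=18, t_all=1, t_overlap=1,
                include_subwindows=True,
            )
        }
        tight = {
            w.column_span
            for w in find_diagnostic_windows(
                panel, min_len=10, max_len=18, t_all=2, t_overlap=2,
                include_subwindows=True,
            )
        }
        assert tight <= loose

    def test_subwindows_superset_of_maximal(self, default_panel):
        panel, _ = default_panel
        kw = dict(min_len=10, max_len=18, t_all=1, t_overlap=2)
        maximal = find_diagnostic_windows(panel, **kw)
        every = find_diagnostic_windows(panel, include_subwindows=True, **kw)
        assert {w.column_span for w in maximal} <= {w.column_span for w in every}
        assert all(w.passes for w in every)

    def test_deterministic_ordering(self, default_panel):
        panel, _ = default_panel
        kw = dict(min_len=10, max_len=18, t_all=1, t_overlap=2)
        a = [w.column_span for w in find_diagnostic_windows(panel, **kw)]
        b = [w.column_span for w in find_diagnostic_windows(panel, **kw)]
        assert a == b
        starts = [s for s, _ in a]
        assert starts == sorted(starts)

    def test_planted_recovery_and_degradation(self, default_panel):
        panel, truth = default_panel
        params = exact_recovery_params(truth)
        got = [w.reference_span for w in find_diagnostic_windows(panel, **params)]
        assert got == [w.span for w in truth.windows]
        params["t_all"] = truth.windows[0].diffs_vs_all + 1
        assert find_diagnostic_windows(panel, **params) == []
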