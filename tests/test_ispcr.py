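"""In-silico PCR: binding-site search and amplicon prediction."""

import numpy as np
import pytest

from preyprimer import (
    NucSequence,
    PanelSpec,
    find_binding_sites,
    predict_amplicons,
    reverse_complement,
    specificity_fixture,
)
from preyprimer.pairdesign import FORWARD, REVERSE, Primer, pair_up
from preyprimer.sequtils import bases_compatible


def _primer(seq, orientation=FORWARD, name="p"):
    return Primer.from_sequence(name, seq, orientation, (1, len(seq)))


def naive_sites(probe, template, max_mismatch):
    """All-offsets oracle for plus-strand matching."""
    out = []
    for off in range(len(template) - len(probe) + 1):
        m = sum(
            not bases_compatible(a, b)
            for a, b in zip(probe, template[off : off + len(probe)])
        )
        if m <= max_mismatch:
            out.append((off + 1, off + len(probe), m))
    return out


class TestFindBindingSites:
    def test_exact_single_site(self):
        tpl = "A" * 30 + "ACGTACGTCC" + "A" * 30
        sites = find_binding_sites(_primer("ACGTACGTCC"), tpl)
        assert [(s.start, s.end) for s in sites] == [(31, 40)]
        assert sites[0].mismatches == 0

    def test_mismatch_tolerance_steps(self):
        site = "ACGTACGTCCGGTTAA"
        mutated = site[:5] + "T" + site[6:]  # one internal substitution
        tpl = "G" * 20 + mutated + "G" * 20
        p = _primer(site)
        assert find_binding_sites(p, tpl, max_mismatch=0) == []
        hits = find_binding_sites(p, tpl, max_mismatch=1)
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_reverse_primer_matches_reverse_complement_footprint(self):
        tpl = "T" * 25 + str(reverse_complement("GTCCTGGACTTTCAGATG")) + "T" * 25
        sites = find_binding_sites(_primer("GTCCTGGACTTTCAGATG", REVERSE), tpl)
        assert [(s.start, s.end) for s in sites] == [(26, 43)]

    def test_ambiguity_matches_both_expansions(self):
        p = _primer("ACGTACGRCC")
        for base in "AG":
            tpl = "T" * 10 + "ACGTACG" + base + "CC" + "T" * 10
            assert len(find_binding_sites(p, tpl)) == 1

    def test_three_prime_mismatch_filtered(self):
        site = "ACGTACGTCCGGTTAA"
        mutated = site[:-1] + "C"  # 3'-terminal mismatch for a forward primer
        tpl = "G" * 10 + mutated + "G" * 10
        p = _primer(site)
        assert find_binding_sites(p, tpl, max_mismatch=1) == []
        kept = find_binding_sites(
            p, tpl, max_mismatch=1, forbid_3prime_mismatch=False
        )
        assert len(kept) == 1 and kept[0].three_prime_mismatch

    def test_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(5)
        tpl = "".join(rng.choice(list("ACGT"), size=400))
        probe = tpl[100:118]
        p = _primer(probe)
        for mm in (0, 1, 2):
            got = [
                (s.start, s.end, s.mismatches)
                for s in find_binding_sites(
                    p, tpl, max_mismatch=mm, forbid_3prime_mismatch=False
                )
            ]
            assert got == naive_sites(probe, tpl, mm)

    def test_monotone_in_mismatch_budget(self):
        rng = np.random.default_rng(6)
        tpl = "".join(rng.choice(list("ACGT"), size=300))
        p = _primer(tpl[50:62])
        prev = set()
        for mm in range(3):
            cur = {
                (s.start, s.end)
                for s in find_binding_sites(
                    p, tpl, max_mismatch=mm, forbid_3prime_mismatch=False
                )
            }
            assert prev <= cur
            prev = cur


class TestPredictAmplicons:
    def _pair_on(self, tpl, fspan, rspan):
        fwd = Primer.from_sequence(
            "f", tpl[fspan[0] - 1 : fspan[1]], FORWARD, fspan
        )
        rev = Primer.from_sequence(
            "r",
            str(reverse_complement(tpl[rspan[0] - 1 : rspan[1]])),
            REVERSE,
            rspan,
        )
        return pair_up(fwd, rev)

    def test_product_geometry_and_length(self):
        rng = np.random.default_rng(7)
        tpl = "".join(rng.choice(list("ACGT"), size=500))
        pair = self._pair_on(tpl, (101, 118), (301, 318))
        hits = predict_amplicons(pair, [NucSequence(tpl, "t")])
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        h = plus[0]
        assert h.fwd_site == (101, 118) and h.rev_site == (301, 318)
        assert h.product_length_reported == 318 - 101
        assert h.product_length_inclusive == 318 - 101 + 1

    def test_reverse_complemented_template_found_in_plus_coords(self):
        rng = np.random.default_rng(8)
        tpl = "".join(rng.choice(list("ACGT"), size=400))
        pair = self._pair_on(tpl, (51, 68), (201, 218))
        flipped = NucSequence(str(reverse_complement(tpl)), "flip")
        hits = predict_amplicons(pair, [flipped])
        assert len(hits) == 1
        h = hits[0]
        # plus-strand coordinates on the flipped template
        assert h.strand == "-"
        assert h.rev_site[1] - h.fwd_site[0] == h.product_length_reported
        assert h.product_length_reported == 218 - 51

    def test_empty_template_list(self):
        pair = self._pair_on("ACGTACGTACGTACGTACGTACGTACGT", (1, 8), (21, 28))
        assert predict_amplicons(pair, []) == []

    def test_max_product_cap(self):
        rng = np.random.default_rng(9)
        tpl = "".join(rng.choice(list("ACGT"), size=600))
        pair = self._pair_on(tpl, (1, 18), (501, 518))
        assert predict_amplicons(pair, [NucSequence(tpl, "t")], max_product=400) == []
        assert (
            len(predict_amplicons(pair, [NucSequence(tpl, "t")], max_product=600)) >= 1
        )


class TestSpecificityMatrix:
    def test_specific_pair_hits_target_only_conserved_hits_all(self):
        """The planted-panel analogue of the published amplification
        matrix: the species-specific pair amplifies the target template
        only, the general (conserved-site) pair every marker template,
        and neither the unrelated predator template."""
        for seed in (0, 1, 2, 3, 4):
            fx = specificity_fixture(PanelSpec(seed=seed))
            specific_hits = {
                h.template_id
                for h in predict_amplicons(fx.specific_pair, fx.all_templates)
            }
            assert specific_hits == {fx.target_template.id}
            conserved_hits = {
                h.template_id
                for h in predict_amplicons(fx.conserved_pair, fx.all_templates)
            }
            assert conserved_hits == {t.id for t in fx.marker_templates}

    def test_monotone_in_mismatch_budget(self):
        fx = specificity_fixture(PanelSpec(seed=12))
        prev: set = set()
        for mm in (0, 1, 2):
            cur = {
                (h.template_id, h.fwd_site, h.rev_site)
                for h in predict_amplicons(
                    fx.specific_pair,
                    fx.all_templates,
                    max_mismatch=mm,
                    forbid_3prime_mismatch=False,
                )
            }
            assert prev <= cur
            prev = cur
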