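import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit.harmonize import (
    DIRECT,
    DROPPED_DUPLICATE,
    DROPPED_INCOMPATIBLE,
    DROPPED_MISSING_OUTCOME,
    DROPPED_PALINDROMIC,
    STRAND_FLIPPED,
    STRAND_FLIPPED_SWAPPED,
    SWAPPED,
    classify_snp,
    harmonize_datasets,
    harmonize_pair,
)
from mrkit.io import SummaryDataset

from .conftest import make_record


class TestClassify:
    @pytest.mark.parametrize("ea,oa,expected", [
        ("A", "T", "palindromic"), ("T", "A", "palindromic"),
        ("C", "G", "palindromic"), ("G", "C", "palindromic"),
        ("A", "G", "non_palindromic"), ("C", "T", "non_palindromic"),
        ("A", "C", "non_palindromic"),
    ])
    def test_definition(self, ea, oa, expected):
        assert classify_snp(ea, oa) == expected


class TestHarmonizePair:
    def test_direct_match_unchanged(self):
        x = make_record("rs1", "A", "G", beta=0.10, eaf=0.30)
        y = make_record("rs1", "A", "G", beta=-0.05, eaf=0.28)
        p = harmonize_pair(x, y)
        assert p.status == DIRECT and p.beta_y == -0.05 and p.eaf_y == 0.28

    def test_swapped_negates_beta_and_flips_eaf(self):
        x = make_record("rs1", "A", "G", beta=0.10, eaf=0.30)
        y = make_record("rs1", "G", "A", beta=-0.05, eaf=0.72)
        p = harmonize_pair(x, y)
        assert p.status == SWAPPED
        assert p.beta_y == pytest.approx(0.05)
        assert p.eaf_y == pytest.approx(0.28)

    def test_strand_flip_direct(self):
        x = make_record("rs1", "A", "G", beta=0.10, eaf=0.30)
        y = make_record("rs1", "T", "C", beta=0.07, eaf=0.30)
        p = harmonize_pair(x, y)
        assert p.status == STRAND_FLIPPED and p.beta_y == 0.07

    def test_strand_flip_swapped(self):
        x = make_record("rs1", "A", "G", beta=0.10, eaf=0.30)
        y = make_record("rs1", "C", "T", beta=0.07, eaf=0.70)
        p = harmonize_pair(x, y)
        assert p.status == STRAND_FLIPPED_SWAPPED
        assert p.beta_y == pytest.approx(-0.07)
        assert p.eaf_y == pytest.approx(0.30)

    def test_palindromic_intermediate_freq_dropped(self):
        x = make_record("rs1", "A", "T", eaf=0.50)
        y = make_record("rs1", "A", "T", eaf=0.30)
        assert harmonize_pair(x, y).status == DROPPED_PALINDROMIC

    def test_palindromic_window_edges(self):
        # eaf exactly at 0.42 is inside the default +-0.08 window -> dropped
        x = make_record("rs1", "A", "T", eaf=0.42)
        y = make_record("rs1", "A", "T", eaf=0.30)
        assert harmonize_pair(x, y).status == DROPPED_PALINDROMIC
        x2 = make_record("rs1", "A", "T", eaf=0.41)
        assert harmonize_pair(x2, y).status == DIRECT

    def test_palindromic_frequency_orientation(self):
        x = make_record("rs1", "C", "G", beta=0.1, eaf=0.20)
        concordant = make_record("rs1", "C", "G", beta=0.05, eaf=0.25)
        assert harmonize_pair(x, concordant).status == DIRECT
        discordant = make_record("rs1", "G", "C", beta=0.05, eaf=0.80)
        p = harmonize_pair(x, discordant)
        assert p.status == SWAPPED and p.beta_y == pytest.approx(-0.05)
        assert p.eaf_y == pytest.approx(0.20)

    def test_palindromic_missing_eaf_dropped(self):
        x = make_record("rs1", "A", "T", eaf=None)
        y = make_record("rs1", "A", "T", eaf=0.2)
        assert harmonize_pair(x, y).status == DROPPED_PALINDROMIC

    def test_incompatible_alleles_dropped(self):
        x = make_record("rs1", "A", "G")
        y = make_record("rs1", "A", "C")
        assert harmonize_pair(x, y).status == DROPPED_INCOMPATIBLE

    def test_id_mismatch_is_usage_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            harmonize_pair(make_record("rs1"), make_record("rs2"))

    def test_idempotent_on_direct_pair(self):
        x = make_record("rs1", "A", "G", beta=0.10, eaf=0.30)
        y = make_record("rs1", "A", "G", beta=0.05, eaf=0.28)
        p1 = harmonize_pair(x, y)
        y2 = make_record("rs1", "A", "G", beta=p1.beta_y, eaf=p1.eaf_y)
        p2 = harmonize_pair(x, y2)
        assert (p2.status, p2.beta_y, p2.eaf_y) == (p1.status, p1.beta_y, p1.eaf_y)

    def test_double_swap_restores_original(self):
        x = make_record("rs1", "A", "G", beta=0.10, eaf=0.30)
        y = make_record("rs1", "G", "A", beta=-0.05, eaf=0.72)
        p1 = harmonize_pair(x, y)
        # re-encode the harmonized pair in the swapped orientation again
        y2 = make_record("rs1", "G", "A", beta=-p1.beta_y, eaf=1 - p1.eaf_y)
        p2 = harmonize_pair(x, y2)
        assert p2.beta_y == pytest.approx(p1.beta_y)
        assert p2.eaf_y == pytest.approx(p1.eaf_y)


class TestHarmonizeDatasets:
    def test_missing_outcome_dropped(self):
        exp = SummaryDataset("e", "continuous",
                             [make_record("rs1"), make_record("rs2")])
        out = SummaryDataset("o", "binary", [make_record("rs1")])
        pairs, rep = harmonize_datasets(exp, out)
        statuses = {p.snp_id: p.status for p in pairs}
        assert statuses["rs2"] == DROPPED_MISSING_OUTCOME
        assert rep.conserved()

    def test_duplicate_in_exposure_dropped(self):
        exp = SummaryDataset("e", "continuous",
                             [make_record("rs1"), make_record("rs1"),
                              make_record("rs2")])
        out = SummaryDataset("o", "binary",
                             [make_record("rs1"), make_record("rs2")])
        pairs, rep = harmonize_datasets(exp, out)
        assert [p.status for p in pairs if p.snp_id == "rs1"] == \
            [DROPPED_DUPLICATE, DROPPED_DUPLICATE]
        assert rep.counts[DROPPED_DUPLICATE] == 2
        assert rep.conserved()

    def test_all_matching_no_drops(self):
        recs = [make_record(f"rs{i}", "A", "G", eaf=0.3) for i in range(5)]
        exp = SummaryDataset("e", "continuous", recs)
        out = SummaryDataset("o", "binary", [make_record(f"rs{i}", "A", "G",
                                                         eaf=0.3)
                                             for i in range(5)])
        pairs, rep = harmonize_datasets(exp, out)
        assert rep.kept == 5 and rep.conserved()

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_count_conservation_on_fuzzed_datasets(self, data):
        alleles = ["A", "C", "G", "T"]
        n = data.draw(st.integers(1, 12))
        exp_recs, out_recs = [], []
        for i in range(n):
            sid = f"rs{data.draw(st.integers(0, 7))}"
            ea = data.draw(st.sampled_from(alleles))
            oa = data.draw(st.sampled_from([a for a in alleles if a != ea]))
            eaf = data.draw(st.sampled_from([0.1, 0.45, 0.5, 0.9, None]))
            exp_recs.append(make_record(sid, ea, oa, eaf=eaf))
            if data.draw(st.booleans()):
                ea2 = data.draw(st.sampled_from(alleles))
                oa2 = data.draw(st.sampled_from([a for a in alleles if a != ea2]))
                out_recs.append(make_record(sid, ea2, oa2, eaf=eaf))
        exp = SummaryDataset("e", "continuous", exp_recs)
        out = SummaryDataset("o", "binary", out_recs)
        pairs, rep = harmonize_datasets(exp, out)
        assert rep.conserved()
        assert sum(rep.counts.values()) == len(exp_recs)
        for p in pairs:
            if p.kept:
                assert p.se_x > 0 and p.se_y > 0
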