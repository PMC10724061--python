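import numpy as np
import pandas as pd
import pytest

from luxomics.io import GeneModel, PeakTable, SampleDesign
from luxomics.m6a import (
    annotate_region,
    assign_peaks,
    enrichment_profile,
    m6a_density,
    metagene_profile,
)

IP = [SampleDesign("ip1", "WT", "blue", 1, "merip_ip")]
INPUT = [SampleDesign("in1", "WT", "blue", 1, "merip_input")]


def make_peaks(rows):
    frame = pd.DataFrame(rows, columns=["peak_id", "gene_id", "start", "end", "ip:ip1", "input:in1"])
    return PeakTable(frame=frame, ip_samples=IP, input_samples=INPUT)


MODEL = GeneModel("g1", 100, 900, 500)  # 1500 nt, CDS/3'UTR junction at 1000


class TestAssign:
    def test_inside_single_model(self):
        peaks = make_peaks([["p1", "", 10, 60, 5.0, 1.0]])
        out = assign_peaks(peaks, [MODEL])
        assert out.frame["gene_id"].tolist() == ["g1"]

    def test_tie_goes_to_lexicographically_smaller(self):
        models = [GeneModel("gB", 10, 30, 10), GeneModel("gA", 10, 30, 10)]
        peaks = make_peaks([["p1", "", 0, 30, 5.0, 1.0]])
        out = assign_peaks(peaks, models)
        assert out.frame["gene_id"].tolist() == ["gA"]

    def test_largest_overlap_wins(self):
        models = [GeneModel("gA", 10, 30, 10), GeneModel("gB", 100, 900, 500)]
        peaks = make_peaks([["p1", "", 40, 120, 5.0, 1.0]])  # 10 nt in gA, 80 in gB
        out = assign_peaks(peaks, models)
        assert out.frame["gene_id"].tolist() == ["gB"]

    def test_no_overlap_left_unassigned(self):
        peaks = make_peaks([["p1", "", 2000, 2100, 5.0, 1.0]])
        out = assign_peaks(peaks, [MODEL])
        assert out.frame["gene_id"].tolist() == [""]


class TestDensity:
    def test_signal_per_kb(self):
        model = GeneModel("g1", 100, 600, 300)  # 1 kb
        peaks = make_peaks([["p1", "g1", 10, 60, 5.0, 1.0]])
        d = m6a_density(peaks, [model], "ip1")
        assert d["g1"] == pytest.approx(5.0)

    def test_two_peaks_summed(self):
        model = GeneModel("g1", 200, 1500, 300)  # 2 kb
        peaks = make_peaks([["p1", "g1", 0, 50, 2.0, 1.0], ["p2", "g1", 100, 150, 3.0, 1.0]])
        d = m6a_density(peaks, [model], "ip1")
        assert d["g1"] == pytest.approx(2.5)

    def test_no_peaks_zero(self):
        d = m6a_density(make_peaks([]), [MODEL], "ip1")
        assert d["g1"] == 0.0

    def test_invariant_under_peak_splitting(self):
        model = GeneModel("g1", 100, 600, 300)
        whole = make_peaks([["p1", "g1", 10, 110, 6.0, 1.0]])
        split = make_peaks([["p1", "g1", 10, 60, 2.0, 1.0], ["p2", "g1", 60, 110, 4.0, 1.0]])
        d1 = m6a_density(whole, [model], "ip1")
        d2 = m6a_density(split, [model], "ip1")
        assert d1["g1"] == pytest.approx(d2["g1"])


class TestEnrichment:
    @pytest.mark.parametrize(
        "ip,inp,p,expected",
        [(4.0, 1.0, 0.0, 2.0), (3.0, 3.0, 0.0, 0.0), (0.0, 0.0, 0.5, 0.0)],
    )
    def test_log2_ratio(self, ip, inp, p, expected):
        assert enrichment_profile(ip, inp, (1.0, 1.0), p) == pytest.approx(expected)

    def test_nonpositive_size_factor_rejected(self):
        with pytest.raises(ValueError):
            enrichment_profile(1.0, 1.0, (0.0, 1.0))


class TestAnnotateRegion:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (25, 75, "utr5"),          # midpoint 50
            (940, 1040, "stop_proximal"),  # midpoint 990, junction 1000
            (1350, 1450, "utr3"),      # midpoint 1400
            (400, 500, "cds"),
        ],
    )
    def test_midpoint_rule(self, start, end, expected):
        assert annotate_region(start, end, MODEL, stop_window=100) == expected

    def test_midpoint_outside_transcript_rejected(self):
        with pytest.raises(ValueError):
            annotate_region(1600, 1700, MODEL)


class TestMetagene:
    def test_peak_spanning_utr3_fills_last_bins_uniformly(self):
        peaks = make_peaks([["p1", "g1", 1000, 1500, 10.0, 1.0]])
        prof = metagene_profile(peaks, [MODEL], ("WT", "blue"))
        np.testing.assert_allclose(prof.bin_means[75:], 10.0 / 25.0)
        np.testing.assert_allclose(prof.bin_means[:75], 0.0)

    def test_conservation(self):
        peaks = make_peaks(
            [["p1", "g1", 50, 450, 7.5, 1.0], ["p2", "g1", 900, 1200, 2.25, 1.0]]
        )
        prof = metagene_profile(peaks, [MODEL], ("WT", "blue"))
        assert prof.total_signal() == pytest.approx(9.75, rel=1e-9)

    def test_mean_identity_for_identical_genes(self):
        m2 = GeneModel("g2", 100, 900, 500)
        single = metagene_profile(
            make_peaks([["p1", "g1", 900, 1200, 4.0, 1.0]]), [MODEL], ("WT", "blue")
        )
        double = metagene_profile(
            make_peaks(
                [["p1", "g1", 900, 1200, 4.0, 1.0], ["p2", "g2", 900, 1200, 4.0, 1.0]]
            ),
            [MODEL, m2],
            ("WT", "blue"),
        )
        np.testing.assert_allclose(double.bin_means, single.bin_means)

    def test_planted_cohort_signal_concentrates_near_stop(self, default_cohort):
        """The generator plants peaks in the last 150 nt of CDS / 3'UTR, so the
        WT blue-dark metagene difference must peak in those bins."""
        c = default_cohort
        blue = metagene_profile(c.peaks, c.models, ("WT", "blue"))
        dark = metagene_profile(c.peaks, c.models, ("WT", "dark"))
        diff = blue.bin_means - dark.bin_means
        assert np.argmax(diff) >= 65  # late-CDS / 3'UTR bins (junction at 75)

    def test_conservation_on_cohort(self, default_cohort):
        c = default_cohort
        prof = metagene_profile(c.peaks, c.models, ("WT", "dark"))
        cols = [f"ip:{s.sample_id}" for s in c.peaks.ip_samples if s.genotype == "WT" and s.condition == "dark"]
        total = c.peaks.frame[cols].mean(axis=1).sum()
        assert prof.total_signal() == pytest.approx(total, rel=1e-9)
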