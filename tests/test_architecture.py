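"""Peak architecture classification, spacing statistics, bridged-gene range."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from napregulon import architecture as arch
from napregulon.architecture import (
    ClassificationError,
    bridged_gene_range,
    classify_peak,
    classify_peaks,
    nearest_peak_distances,
    quartiles,
    spacing_summary,
)
from napregulon.io import Gene, Peak


def make_peak(mid, peak_id="p", contig="c1", width=10):
    return Peak(contig=contig, start=mid - width // 2, end=mid + width - width // 2,
                peak_id=peak_id)


def brute_force_classify(peak, genes):
    """Independent reference classifier scanning every gene linearly."""
    m = peak.midpoint
    containing = [g for g in genes if g.contig == peak.contig and g.start <= m < g.end]
    if containing:
        return "intragenic"
    lefts = [g for g in genes if g.contig == peak.contig and g.end <= m]
    rights = [g for g in genes if g.contig == peak.contig and g.start > m]
    if not lefts or not rights:
        return "terminal"
    left = max(lefts, key=lambda g: g.end)
    right = min(rights, key=lambda g: g.start)
    return {
        ("+", "+"): "intergenic_tandem",
        ("-", "-"): "intergenic_tandem",
        ("+", "-"): "intergenic_convergent",
        ("-", "+"): "intergenic_divergent",
    }[(left.strand, right.strand)]


class TestClassifyPeak:
    @pytest.mark.parametrize(
        "strands,expected",
        [
            (("+", "+"), "intergenic_tandem"),
            (("-", "-"), "intergenic_tandem"),
            (("+", "-"), "intergenic_convergent"),
            (("-", "+"), "intergenic_divergent"),
        ],
    )
    def test_flank_strand_truth_table(self, strands, expected):
        genes = [
            Gene(contig="c1", start=0, end=100, gene_id="L", strand=strands[0]),
            Gene(contig="c1", start=300, end=400, gene_id="R", strand=strands[1]),
        ]
        ctx = classify_peak(make_peak(200), genes)
        assert ctx.category == expected
        assert (ctx.left_gene_id, ctx.right_gene_id) == ("L", "R")

    def test_midpoint_inside_gene_body_is_intragenic(self, toy_genes):
        ctx = classify_peak(make_peak(150), toy_genes)
        assert ctx.category == "intragenic"
        assert ctx.containing_gene_id == "gA"

    def test_terminal_when_one_flank_missing(self, toy_genes):
        assert classify_peak(make_peak(50), toy_genes).category == "terminal"
        assert classify_peak(make_peak(950), toy_genes).category == "terminal"

    def test_overlap_mode_differs_for_straddling_peak(self, toy_genes):
        # peak covers gene gA's 3' edge but its midpoint is intergenic
        peak = Peak(contig="c1", start=290, end=400, peak_id="p")
        assert classify_peak(peak, toy_genes).category.startswith("intergenic")
        assert classify_peak(peak, toy_genes, containment="overlap").category == "intragenic"

    def test_containing_tie_broken_by_smallest_start(self):
        genes = [
            Gene(contig="c1", start=50, end=300, gene_id="g2", strand="+"),
            Gene(contig="c1", start=20, end=400, gene_id="g1", strand="-"),
        ]
        ctx = classify_peak(make_peak(100), genes)
        assert ctx.containing_gene_id == "g1"

    def test_contig_without_annotation_raises(self, toy_genes):
        with pytest.raises(ClassificationError):
            classify_peak(make_peak(100, contig="cX"), toy_genes)

    def test_random_peaks_match_brute_force_oracle(self, annotation, genome):
        rng = np.random.default_rng(0)
        clen = genome.length("contig_1")
        peaks = [
            make_peak(int(m), peak_id=f"p{i}", contig="contig_1")
            for i, m in enumerate(rng.integers(10, clen - 10, size=200))
        ]
        contexts = classify_peaks(peaks, annotation)
        for peak, ctx in zip(peaks, contexts):
            assert ctx.category == brute_force_classify(peak, annotation)

    def test_categories_exhaustive_and_exclusive(self, annotation):
        rng = np.random.default_rng(1)
        peaks = [
            make_peak(int(m), peak_id=f"p{i}", contig="contig_1")
            for i, m in enumerate(rng.integers(10, 199_000, size=100))
        ]
        for ctx in classify_peaks(peaks, annotation):
            assert ctx.category in arch.CATEGORIES


class TestArchitectureFractions:
    def test_all_intragenic(self):
        contexts = [arch.PeakContext(f"p{i}", "intragenic") for i in range(5)]
        table = arch.architecture_fractions(contexts).set_index("category")
        assert table.loc["intragenic", "percent"] == 100

    def test_43_of_50_intergenic_rounds_to_86(self):
        contexts = [
            arch.PeakContext(f"p{i}", "intergenic_tandem") for i in range(43)
        ] + [arch.PeakContext(f"q{i}", "intragenic") for i in range(7)]
        table = arch.architecture_fractions(contexts).set_index("category")
        assert table.loc["intergenic_tandem", "percent"] == 86
        assert table["count"].sum() == 50

    def test_planted_80_20_split_recovered(self, annotation, genome):
        # place 400 midpoints in intergenic gaps and 100 inside gene bodies
        rng = np.random.default_rng(2)
        genes = sorted(g for g in annotation)
        gaps = []
        prev = 0
        for g in genes:
            if g.start - prev >= 3:
                gaps.append((prev, g.start))
            prev = g.end
        peaks = []
        for i in range(400):
            gs, ge = gaps[int(rng.integers(len(gaps)))]
            peaks.append(make_peak(int(rng.integers(gs + 1, ge)), f"ig{i}", "contig_1", 2))
        for i in range(100):
            g = genes[int(rng.integers(len(genes)))]
            peaks.append(make_peak(int(rng.integers(g.start + 1, g.end)), f"in{i}", "contig_1", 2))
        table = arch.architecture_fractions(classify_peaks(peaks, annotation))
        table = table.set_index("category")
        intergenic = table.loc[
            ["intergenic_tandem", "intergenic_convergent", "intergenic_divergent"],
            "percent",
        ].sum()
        assert abs(intergenic - 80) <= 4
        assert abs(table.loc["intragenic", "percent"] - 20) <= 4


class TestNearestDistances:
    def test_hand_checked_triple(self):
        peaks = [make_peak(m, f"p{m}", width=2) for m in (0, 100, 300)]
        peaks[0] = Peak(contig="c1", start=0, end=1, peak_id="p0")  # midpoint 0
        assert sorted(nearest_peak_distances(peaks)) == [100, 100, 200]

    def test_two_peaks_symmetric(self):
        peaks = [make_peak(10, "a", width=2), make_peak(75, "b", width=2)]
        assert nearest_peak_distances(peaks) == [65, 65]

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(3)
        mids = sorted(set(rng.integers(100, 1_000_000, size=100).tolist()))
        peaks = [make_peak(int(m), f"p{i}", width=2) for i, m in enumerate(mids)]
        got = sorted(nearest_peak_distances(peaks))
        expected = sorted(
            min(abs(a - b) for b in mids if b != a) for a in mids
        )
        assert got == expected

    def test_invariant_under_relabeling_and_translation(self):
        mids = [10, 500, 780, 2100]
        base = sorted(nearest_peak_distances(
            [make_peak(m, f"p{i}", width=2) for i, m in enumerate(mids)]
        ))
        shuffled = sorted(nearest_peak_distances(
            [make_peak(m, f"z{9 - i}", width=2) for i, m in enumerate(mids)]
        ))
        translated = sorted(nearest_peak_distances(
            [make_peak(m + 1000, f"p{i}", width=2) for i, m in enumerate(mids)]
        ))
        assert base == shuffled == translated

    def test_single_peak_everywhere_raises(self):
        with pytest.raises(ValueError):
            nearest_peak_distances([make_peak(10, "a", width=2)])

    def test_circular_mode_adds_wraparound_neighbor(self):
        peaks = [make_peak(10, "a", width=2), make_peak(900, "b", width=2)]
        linear = nearest_peak_distances(peaks)
        circular = nearest_peak_distances(
            peaks, circular=True, contig_lengths={"c1": 1000}
        )
        assert linear == [890, 890]
        assert circular == [110, 110]


class TestQuartiles:
    def test_five_values_per_method(self):
        # hinges: halves include the median for odd n -> (2, 3, 4);
        # linear interpolation on [1..5] also lands on (2, 3, 4)
        assert quartiles([1, 2, 3, 4, 5], "hinges") == (2, 3, 4)
        assert quartiles([1, 2, 3, 4, 5], "linear") == (2, 3, 4)
        # even n separates the two estimators
        assert quartiles([1, 2, 3, 4], "hinges") == (1.5, 2.5, 3.5)
        assert quartiles([1, 2, 3, 4], "linear") == (1.75, 2.5, 3.25)

    def test_constant_data(self):
        assert quartiles([7.0] * 9) == (7, 7, 7)

    @pytest.mark.parametrize("method", ["hinges", "linear"])
    def test_against_sorting_oracle(self, method):
        import statistics

        rng = np.random.default_rng(4)
        data = rng.normal(size=1000).tolist()
        q1, med, q3 = quartiles(data, method)
        s = sorted(data)
        assert med == pytest.approx(statistics.median(s))
        if method == "hinges":
            half = len(s) // 2 + len(s) % 2
            assert q1 == pytest.approx(statistics.median(s[:half]))
            assert q3 == pytest.approx(statistics.median(s[len(s) // 2 :]))
        else:
            def interp(p):
                h = (len(s) - 1) * p
                lo, hi = int(np.floor(h)), int(np.ceil(h))
                return s[lo] + (h - lo) * (s[hi] - s[lo])

            assert q1 == pytest.approx(interp(0.25))
            assert q3 == pytest.approx(interp(0.75))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            quartiles([])


class TestBridgedGeneRange:
    def test_interquartile_spacing_to_gene_count(self):
        assert bridged_gene_range(1933, 15390, 946) == (2, 16)

    def test_sub_gene_distances_give_zero(self):
        assert bridged_gene_range(500, 945, 946) == (0, 0)

    def test_matches_integer_division_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            q1 = float(rng.uniform(1, 10_000))
            q3 = q1 + float(rng.uniform(0, 40_000))
            assert bridged_gene_range(q1, q3) == (int(q1 // 946), int(q3 // 946))

    @given(
        q1=st.floats(1, 1e5),
        dq=st.floats(0, 1e5),
        extra=st.floats(1, 500),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_spacing_antitone_in_gene_length(self, q1, dq, extra):
        lo, hi = bridged_gene_range(q1, q1 + dq, 946)
        lo2, hi2 = bridged_gene_range(q1 + extra, q1 + dq + 2 * extra, 946)
        assert lo2 >= lo and hi2 >= hi
        lo3, hi3 = bridged_gene_range(q1, q1 + dq, 946 + extra)
        assert lo3 <= lo and hi3 <= hi

    @pytest.mark.parametrize("bad", [(0, 10, 946), (10, 5, 946), (10, 20, 0)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            bridged_gene_range(*bad)


def test_spacing_summary_is_consistent(peaks_de_truth):
    peaks = peaks_de_truth[0]
    s = spacing_summary(peaks)
    assert s.q1 <= s.median <= s.q3
    assert s.min_genes <= s.max_genes
    assert all(d >= 0 for d in s.distances)
    assert sorted(s.distances) == sorted(nearest_peak_distances(peaks))
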