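"""Regulon calling, promoter windows, direct-target assignment, summaries."""

import numpy as np
import pytest

from napregulon import regulon as reg
from napregulon.io import DERecord, Gene, Peak
from napregulon.regulon import (
    ACTIVATED,
    REPRESSED,
    Regulon,
    RegulonEntry,
    assign_direct_targets,
    call_regulon,
    compare_regulons,
    lfc_threshold_for_fold,
    promoter_window,
    regulon_summary,
)


def de(gene_id, log2fc, adj_p=0.001, condition="aerobic"):
    return DERecord(gene_id=gene_id, log2fc=log2fc, adj_p=adj_p, condition=condition)


class TestCallRegulon:
    def test_threshold_is_strict(self):
        records = [de("g1", 1.585), de("g2", 1.586), de("g3", -1.585)]
        r = call_regulon(records, "aerobic")
        assert r.gene_ids == {"g2"}

    def test_sign_determines_direction(self):
        r = call_regulon([de("up", 2.0), de("down", -2.0, adj_p=0.01)], "aerobic")
        by_id = {e.gene_id: e for e in r.entries}
        assert by_id["up"].direction == REPRESSED
        assert by_id["down"].direction == ACTIVATED

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(0)
        records = [
            de(f"g{i}", float(rng.normal(0, 2)), float(rng.uniform(0, 0.2)))
            for i in range(10)
        ]
        r = call_regulon(records, "aerobic", 1.585, 0.05)
        expected = {
            x.gene_id for x in records if abs(x.log2fc) > 1.585 and x.adj_p <= 0.05
        }
        assert r.gene_ids == expected

    def test_p_filter_can_be_disabled(self):
        records = [de("g1", 3.0, adj_p=0.9)]
        assert len(call_regulon(records, "aerobic")) == 0
        assert call_regulon(records, "aerobic", p_threshold=None).gene_ids == {"g1"}

    def test_no_records_for_condition(self):
        with pytest.raises(ValueError, match="condition"):
            call_regulon([de("g1", 2.0)], "hypoxia")

    def test_raising_threshold_never_adds_genes(self):
        rng = np.random.default_rng(1)
        records = [
            de(f"g{i}", float(rng.normal(0, 3)), float(rng.uniform(0, 0.1)))
            for i in range(100)
        ]
        prev = None
        for thr in (0.5, 1.0, 1.585, 2.5, 4.0):
            ids = call_regulon(records, "aerobic", thr).gene_ids
            if prev is not None:
                assert ids <= prev
            prev = ids


class TestThresholdForFold:
    def test_threefold_gives_1585(self):
        assert lfc_threshold_for_fold(3) == 1.585

    def test_identity_and_powers_of_two(self):
        assert lfc_threshold_for_fold(1) == 0.0
        for k in (1, 2, 5, 10):
            assert lfc_threshold_for_fold(2**k) == k

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            lfc_threshold_for_fold(0)


class TestPromoterWindow:
    def test_plus_strand_window(self):
        g = Gene(contig="c", start=1000, end=2000, gene_id="g", strand="+")
        assert promoter_window(g) == (850, 1000)

    def test_minus_strand_window_is_mirrored(self):
        g = Gene(contig="c", start=0, end=1000, gene_id="g", strand="-")
        assert promoter_window(g) == (1000, 1150)

    def test_clipping_at_contig_edges(self):
        left = Gene(contig="c", start=40, end=500, gene_id="l", strand="+")
        right = Gene(contig="c", start=0, end=950, gene_id="r", strand="-")
        assert promoter_window(left) == (0, 40)
        assert promoter_window(right, contig_length=1000) == (950, 1000)

    def test_batch_matches_strand_aware_oracle(self, annotation, genome):
        clen = genome.length("contig_1")
        for g in annotation:
            w = promoter_window(g, 150, clen)
            if g.strand == "+":
                assert w == (max(0, g.start - 150), g.start)
            else:
                assert w == (g.end, min(clen, g.end + 150))


class TestAssignDirectTargets:
    @pytest.fixture
    def simple(self):
        gene = Gene(contig="c", start=1000, end=2000, gene_id="g", strand="+")
        regulon = Regulon(
            condition="aerobic",
            entries=(RegulonEntry(gene_id="g", log2fc=2.0, direction=REPRESSED),),
        )
        return gene, regulon

    def test_peak_ending_at_window_start_is_no_overlap(self, simple):
        gene, regulon = simple  # window is [850, 1000)
        peak = Peak(contig="c", start=800, end=850, peak_id="p")
        out = assign_direct_targets(regulon, [peak], [gene])
        assert out.entries[0].mode == "indirect"
        assert out.entries[0].supporting_peaks == ()

    def test_single_bp_overlap_is_direct(self, simple):
        gene, regulon = simple
        peak = Peak(contig="c", start=800, end=851, peak_id="p")
        out = assign_direct_targets(regulon, [peak], [gene])
        assert out.entries[0].mode == "direct"
        assert out.entries[0].supporting_peaks == ("p",)

    def test_missing_gene_is_named(self, simple):
        _, regulon = simple
        with pytest.raises(KeyError, match="'g'"):
            assign_direct_targets(regulon, [], [])

    def test_membership_never_changes(self, peaks_de_truth, annotation, genome):
        peaks, records, _ = peaks_de_truth
        r = call_regulon(records, "aerobic")
        out = assign_direct_targets(r, peaks, annotation, contig_lengths=genome.lengths())
        assert out.gene_ids == r.gene_ids

    def test_planted_direct_targets_recovered_exactly(
        self, peaks_de_truth, annotation, genome
    ):
        peaks, records, truth = peaks_de_truth
        r = call_regulon(records, "aerobic")
        out = assign_direct_targets(r, peaks, annotation, contig_lengths=genome.lengths())
        direct = {e.gene_id for e in out.direct_entries()}
        assert direct == set(truth.direct_targets)  # precision = recall = 1.0
        indirect = {e.gene_id for e in out.entries if e.mode == "indirect"}
        assert indirect == set(truth.indirect_targets)


def build_regulon(n_repressed, n_activated, n_direct_rep=0, n_direct_act=0,
                  condition="aerobic", prefix="g"):
    entries = []
    for i in range(n_repressed):
        mode = "direct" if i < n_direct_rep else "indirect"
        entries.append(
            RegulonEntry(
                gene_id=f"{prefix}r{i}", log2fc=2.0, direction=REPRESSED,
                mode=mode, supporting_peaks=("p",) if mode == "direct" else (),
            )
        )
    for i in range(n_activated):
        mode = "direct" if i < n_direct_act else "indirect"
        entries.append(
            RegulonEntry(
                gene_id=f"{prefix}a{i}", log2fc=-2.0, direction=ACTIVATED,
                mode=mode, supporting_peaks=("p",) if mode == "direct" else (),
            )
        )
    return Regulon(condition=condition, entries=tuple(entries))


class TestRegulonSummary:
    def test_71_genes_59_repressed_gives_17_pct_decreased(self):
        summary = regulon_summary(build_regulon(59, 12))
        assert summary["n_total"] == 71
        assert summary["pct_with_decreased_transcription_in_mutant"] == 17

    def test_124_genes_57_activated_gives_46_pct(self):
        summary = regulon_summary(build_regulon(67, 57))
        assert summary["n_total"] == 124
        assert summary["pct_activated"] == 46

    def test_empty_regulon_is_all_zeros(self):
        summary = regulon_summary(Regulon(condition="x", entries=()))
        assert all(v == 0 for v in summary.values())

    def test_count_identities(self, peaks_de_truth, annotation, genome):
        peaks, records, _ = peaks_de_truth
        r = assign_direct_targets(
            call_regulon(records, "aerobic"), peaks, annotation,
            contig_lengths=genome.lengths(),
        )
        s = regulon_summary(r)
        assert s["n_repressed"] + s["n_activated"] == s["n_total"]
        assert s["n_direct"] <= s["n_total"]
        assert s["n_direct_repressed"] + s["n_direct_activated"] == s["n_direct"]


class TestCompareRegulons:
    def test_identical_regulons(self):
        a = build_regulon(3, 2)
        cmp_res = compare_regulons(a, a)
        assert cmp_res.shared == a.gene_ids
        assert not cmp_res.unique_a and not cmp_res.unique_b

    def test_disjoint_regulons(self):
        a = build_regulon(2, 1, prefix="x")
        b = build_regulon(2, 1, prefix="y")
        cmp_res = compare_regulons(a, b)
        assert not cmp_res.shared
        assert cmp_res.n_unique_a == 3 and cmp_res.n_unique_b == 3

    def test_71_vs_124_with_36_shared(self):
        shared = [f"s{i}" for i in range(36)]
        a_ids = shared + [f"a{i}" for i in range(35)]
        b_ids = shared + [f"b{i}" for i in range(88)]
        a = Regulon("aerobic", tuple(
            RegulonEntry(g, 2.0, REPRESSED) for g in a_ids
        ))
        b = Regulon("hypoxia", tuple(
            RegulonEntry(g, 2.0, REPRESSED) for g in b_ids
        ))
        cmp_res = compare_regulons(a, b)
        assert (cmp_res.n_shared, cmp_res.n_unique_a, cmp_res.n_unique_b) == (36, 35, 88)
        # set identities
        assert cmp_res.n_shared + cmp_res.n_unique_a == len(a)
        assert cmp_res.n_shared + cmp_res.n_unique_b == len(b)
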