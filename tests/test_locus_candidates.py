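"""LD statistics, penetrance estimators, and candidate selection."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mechsnp import locus_candidates as lc
from mechsnp import synthetic_data as synth


def brute_force_ld(col_a, col_b):
    """Independent oracle: exhaustive counting over the four haplotype classes."""
    n = len(col_a)
    n11 = sum(1 for a, b in zip(col_a, col_b) if a == 1 and b == 1)
    f_a = sum(col_a) / n
    f_b = sum(col_b) / n
    h_ab = n11 / n
    d = h_ab - f_a * f_b
    var = f_a * (1 - f_a) * f_b * (1 - f_b)
    return d, d * d / var if var > 0 else math.nan


class TestLDStats:
    def test_worked_two_by_two_table(self, two_site_panel):
        stats = lc.ld_stats(two_site_panel, "a", "b")
        assert stats.d == pytest.approx(0.14, abs=1e-12)
        assert stats.r2 == pytest.approx(0.340277777, abs=1e-8)
        assert stats.d_prime == pytest.approx(0.583333333, abs=1e-8)
        assert stats.h_ab == pytest.approx(0.5)

    def test_identical_columns_give_perfect_ld(self):
        col = np.array([0, 1, 1, 0, 1, 0], dtype=np.uint8)
        panel = lc.HaplotypePanel(np.column_stack([col, col]), ["a", "b"], [1, 2])
        stats = lc.ld_stats(panel, "a", "b")
        assert stats.r2 == pytest.approx(1.0)
        assert stats.d_prime == pytest.approx(1.0)

    def test_equilibrium_gives_zero(self):
        # h_ab = f_a*f_b exactly: product panel over {0,1}x{0,1}
        rows = [[a, b] for a in (0, 1) for b in (0, 1)]
        panel = lc.HaplotypePanel(np.array(rows, dtype=np.uint8), ["a", "b"], [1, 2])
        stats = lc.ld_stats(panel, "a", "b")
        assert stats.d == 0.0
        assert stats.r2 == 0.0

    def test_monomorphic_snp_is_flagged_not_zero(self):
        panel = lc.HaplotypePanel(np.array([[0, 1], [0, 0]], dtype=np.uint8),
                                  ["a", "b"], [1, 2])
        stats = lc.ld_stats(panel, "a", "b")
        assert not stats.defined
        assert math.isnan(stats.r2)

    def test_matches_brute_force_oracle_exactly(self, demo_panel):
        small = lc.HaplotypePanel(demo_panel.alleles[:200], demo_panel.snp_ids,
                                  demo_panel.positions)
        for a in small.snp_ids:
            for b in small.snp_ids:
                if a >= b:
                    continue
                stats = lc.ld_stats(small, a, b)
                d_ref, r2_ref = brute_force_ld(small.column(a).tolist(),
                                               small.column(b).tolist())
                assert stats.d == pytest.approx(d_ref, abs=1e-14)
                if not math.isnan(r2_ref):
                    assert stats.r2 == pytest.approx(r2_ref, abs=1e-12)


class TestMarkerPenetrance:
    def test_bayes_worked_example(self):
        est = lc.marker_penetrance(lc.MarkerAssociation("m", 0.5, 0.4), 0.01)
        assert est.allele_freq == pytest.approx(0.401)
        assert est.p_d_given_allele == pytest.approx(0.0124688279, abs=1e-9)

    def test_null_association_returns_prevalence(self):
        est = lc.marker_penetrance(lc.MarkerAssociation("m", 0.35, 0.35), 0.01)
        assert est.p_d_given_allele == pytest.approx(0.01)
        assert est.p_d_given_not == pytest.approx(0.01)

    @given(f_case=st.floats(0.01, 0.99), f_control=st.floats(0.01, 0.99),
           k=st.floats(0.001, 0.2))
    def test_prevalence_conservation(self, f_case, f_control, k):
        est = lc.marker_penetrance(lc.MarkerAssociation("m", f_case, f_control), k)
        recombined = (est.p_d_given_allele * est.allele_freq
                      + est.p_d_given_not * (1 - est.allele_freq))
        assert recombined == pytest.approx(k, abs=1e-12)

    def test_fixed_marker_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            lc.marker_penetrance(lc.MarkerAssociation("m", 1.0, 1.0), 0.01)


class TestImpliedPenetrance:
    MARKER = lc.PenetranceEstimate(0.012, 0.0095, 0.3)

    def test_two_equation_worked_example(self):
        est = lc.implied_candidate_penetrance(self.MARKER, 0.01, f_c=0.2, p_cm=0.6)
        assert est.p_d_given_allele == pytest.approx(0.014, abs=1e-12)
        assert est.p_d_given_not == pytest.approx(0.009, abs=1e-12)
        assert est.feasible

    def test_complete_ld_returns_marker_penetrance(self):
        for f_c in (0.1, 0.3, 0.6):
            est = lc.implied_candidate_penetrance(self.MARKER, 0.01, f_c=f_c, p_cm=1.0)
            assert est.p_d_given_allele == pytest.approx(0.012, abs=1e-12)

    def test_rare_candidate_under_strong_marker_is_infeasible(self):
        strong = lc.PenetranceEstimate(0.5, 0.005, 0.3)
        est = lc.implied_candidate_penetrance(strong, 0.01, f_c=1e-4, p_cm=0.01)
        assert not est.feasible

    def test_independence_is_infeasible_not_an_exception(self):
        est = lc.implied_candidate_penetrance(self.MARKER, 0.01, f_c=0.4, p_cm=0.4)
        assert not est.feasible
        assert math.isnan(est.p_d_given_allele)

    def test_monotone_in_p_cm_toward_marker_penetrance(self):
        xs = [lc.implied_candidate_penetrance(self.MARKER, 0.01, 0.2, p).p_d_given_allele
              for p in (0.4, 0.6, 0.8, 1.0)]
        assert all(a >= b for a, b in zip(xs, xs[1:]))
        assert xs[-1] == pytest.approx(0.012, abs=1e-12)


@pytest.fixture(scope="module")
def selection(demo_panel, demo_locus):
    spec, model, marker = demo_locus
    cohort = synth.gen_case_control(demo_panel, model, 2000, 2000, seed=13)
    k = model.prevalence(spec.allele_freq("causal"))
    assoc = cohort.marker_association(demo_panel, marker)
    return lc.select_candidates(demo_panel, [assoc], prevalence=k), assoc, k


class TestSelection:
    def test_marker_always_selected_with_reason_both(self, selection):
        cs, _, _ = selection
        assert cs.record("marker").reason == "both"

    def test_causal_in_near_complete_ld_selected(self, selection):
        cs, _, _ = selection
        rec = cs.record("causal")
        assert rec.selected
        assert rec.best_r2 > 0.8

    def test_equilibrium_snps_not_selected(self, selection):
        cs, _, _ = selection
        for snp in ("null1", "null2", "null3"):
            assert cs.record(snp).reason == "none"

    def test_selection_invariant_to_column_order_and_polarity(
            self, demo_panel, selection):
        _, assoc, k = selection
        baseline = lc.select_candidates(demo_panel, [assoc], prevalence=k)
        order = np.array([3, 0, 6, 1, 2, 5, 4])
        alleles = demo_panel.alleles[:, order].copy()
        snp_ids = [demo_panel.snp_ids[i] for i in order]
        flip = snp_ids.index("causal")
        alleles[:, flip] = 1 - alleles[:, flip]   # swap 0/1 labelling
        shuffled = lc.HaplotypePanel(alleles, snp_ids,
                                     demo_panel.positions[order])
        result = lc.select_candidates(shuffled, [assoc], prevalence=k)
        assert set(result.selected_ids()) == set(baseline.selected_ids())

    def test_monomorphic_candidate_reported_not_dropped(self, demo_locus):
        spec, model, marker = demo_locus
        panel = synth.gen_haplotype_panel(spec, 400, seed=1)
        alleles = panel.alleles.copy()
        alleles[:, panel.snp_ids.index("null3")] = 0
        mono = lc.HaplotypePanel(alleles, panel.snp_ids, panel.positions)
        cs = lc.select_candidates(
            mono, [lc.MarkerAssociation("marker", 0.33, 0.30)], prevalence=0.01)
        rec = cs.record("null3")
        assert rec.reason == "none" and rec.monomorphic

    def test_monomorphic_marker_is_an_error(self, demo_panel):
        alleles = demo_panel.alleles.copy()
        alleles[:, demo_panel.snp_ids.index("marker")] = 1
        panel = lc.HaplotypePanel(alleles, demo_panel.snp_ids, demo_panel.positions)
        with pytest.raises(ValueError, match="monomorphic"):
            lc.select_candidates(panel, [lc.MarkerAssociation("marker", 0.3, 0.3)],
                                 prevalence=0.01)


class TestIO:
    def test_vcf_round_trip(self, demo_panel, tmp_path):
        path = tmp_path / "panel.vcf"
        small = lc.HaplotypePanel(demo_panel.alleles[:100], demo_panel.snp_ids,
                                  demo_panel.positions)
        small.to_vcf(path, chrom="3")
        back = lc.HaplotypePanel.from_vcf(path)
        assert np.array_equal(back.alleles, small.alleles)
        assert back.snp_ids == small.snp_ids
        assert np.array_equal(back.positions, small.positions)

    def test_unphased_vcf_rejected(self, tmp_path):
        path = tmp_path / "unphased.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(ValueError, match="unphased"):
            lc.HaplotypePanel.from_vcf(path)

    def test_text_matrix_round_trip(self, demo_panel, tmp_path):
        path = tmp_path / "panel.txt"
        small = lc.HaplotypePanel(demo_panel.alleles[:50], demo_panel.snp_ids,
                                  demo_panel.positions)
        small.to_text(path)
        back = lc.HaplotypePanel.from_text(path)
        assert np.array_equal(back.alleles, small.alleles)

    def test_marker_csv_round_trip(self, tmp_path):
        markers = [lc.MarkerAssociation("rs1", 0.33, 0.30)]
        path = tmp_path / "markers.csv"
        lc.write_marker_csv(markers, path)
        assert lc.read_marker_csv(path) == markers
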