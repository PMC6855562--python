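"""The synthetic ground-truth generator and its statistical guarantees."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radnet.annotation import GeneAnnotation
from radnet.synthetic import (
    GroundTruthNetwork,
    SyntheticTruthRecord,
    generate_ground_truth_network,
    make_truth_record,
    simulate_cellline_pair,
    simulate_patient_cohort,
    simulate_relapse_times,
)


class TestGenerateGroundTruthNetwork:
    def test_requested_density_and_sign_mix(self):
        truth = generate_ground_truth_network(
            100, density=0.02, frac_inhibitor=0.03, seed=1
        )
        n_edges = (truth.edge_weights != 0).sum()
        assert n_edges == round(0.02 * 100 * 99)  # 198
        assert abs(truth.density - 0.02) / 0.02 <= 0.1
        n_neg = (truth.edge_weights < 0).sum()
        assert 0 <= n_neg <= 0.1 * n_edges

    def test_zero_inhibitor_fraction_gives_all_positive_weights(self):
        truth = generate_ground_truth_network(50, frac_inhibitor=0.0, seed=2)
        assert (truth.edge_weights >= 0).all()

    def test_same_seed_reproduces_identical_network(self):
        a = generate_ground_truth_network(60, seed=3)
        b = generate_ground_truth_network(60, seed=3)
        np.testing.assert_array_equal(a.edge_weights, b.edge_weights)
        pd.testing.assert_frame_equal(a.annotation.table, b.annotation.table)

    def test_spectral_radius_below_one(self):
        truth = generate_ground_truth_network(80, seed=4, spectral_radius=0.8)
        assert truth.spectral_radius < 1
        assert truth.spectral_radius == pytest.approx(0.8, abs=1e-6)

    def test_coordinates_strictly_increasing_per_chromosome(self):
        truth = generate_ground_truth_network(95, n_chromosomes=7, seed=5)
        for _, g in truth.annotation.table.groupby("chrom"):
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            assert (np.diff(starts) > 0).all()
            assert (starts < ends).all()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_ground_truth_network(5)
        with pytest.raises(ValueError):
            generate_ground_truth_network(20, density=0.5)
        with pytest.raises(ValueError):
            generate_ground_truth_network(20, density=1e-6)


class TestTruthRecord:
    def test_drivers_and_markers_disjoint_and_downstream(self, truth100):
        rec = make_truth_record(truth100, n_drivers=4, n_markers=4, seed=1)
        assert not set(rec.drivers) & rec.markers
        # every marker is a direct target of some driver
        w = truth100.edge_weights
        idx = {g: i for i, g in enumerate(truth100.genes)}
        for m in rec.markers:
            assert any(w[idx[d], idx[m]] != 0 for d in rec.drivers)

    def test_hazard_sign_matches_direction(self, truth100):
        rec = make_truth_record(truth100, hazard_scale=2.0, seed=2)
        for g, d in rec.drivers.items():
            assert rec.hazard_coefficients[g] == (2.0 if d == "up" else -2.0)

    def test_overlapping_driver_marker_sets_rejected(self):
        with pytest.raises(ValueError):
            SyntheticTruthRecord(
                drivers={"a": "up"},
                markers={"a"},
                hazard_coefficients={"a": 1.0},
                seed=0,
            )


def small_linear_truth(w_ab=0.6, beta_a=1.0, beta_b=1.0, noise=1e-12):
    """Two connected genes plus spacers (generator requires >= 10 genes)."""
    n = 10
    ann = GeneAnnotation.from_frame(
        pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "chrom": "chr1",
                "start": np.arange(n) * 1000 + 100,
                "end": np.arange(n) * 1000 + 600,
            }
        )
    )
    w = np.zeros((n, n))
    w[0, 1] = w_ab  # g0 -> g1
    beta = np.ones(n)
    beta[0], beta[1] = beta_a, beta_b
    return GroundTruthNetwork(
        annotation=ann,
        edge_weights=w,
        cn_coefficients=beta,
        noise_sd=np.full(n, noise),
    )


class TestSimulatePatientCohort:
    def test_no_network_no_noise_expression_is_affine_in_copy_number(self):
        truth = small_linear_truth(w_ab=0.0)
        expr, cn, _ = simulate_patient_cohort(truth, n_patients=30, seed=6)
        expected = 8.0 + truth.cn_coefficients[:, None] * cn.to_numpy()
        np.testing.assert_allclose(expr.to_numpy(), expected, atol=1e-9)

    def test_chain_propagation_matches_analytic_two_gene_solution(self):
        # x_b = w * x_a + beta_b c_b; a copy-number shift delta on gene a
        # moves E[x_b] by w * beta_a * delta
        w_ab, beta_a, delta = 0.6, 1.1, 0.8
        truth = small_linear_truth(w_ab=w_ab, beta_a=beta_a, noise=1e-12)
        expr0, cn0, _ = simulate_patient_cohort(
            truth, n_patients=5, segment_prob=0.0, seed=7
        )
        from radnet.synthetic import _solve_expression

        n = truth.n_genes
        c = np.zeros((n, 1))
        c[0, 0] = delta
        x = _solve_expression(truth, c, np.zeros((n, 1)))
        assert x[1, 0] == pytest.approx(w_ab * beta_a * delta, rel=1e-9)
        assert x[0, 0] == pytest.approx(beta_a * delta, rel=1e-9)

    def test_seeded_cohort_is_reproducible(self, truth100):
        e1, c1, k1 = simulate_patient_cohort(truth100, n_patients=40, seed=8)
        e2, c2, k2 = simulate_patient_cohort(truth100, n_patients=40, seed=8)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(k1, k2)

    def test_unstable_network_refused(self):
        truth = small_linear_truth()
        truth.edge_weights[0, 1] = 0.9
        truth.edge_weights[1, 0] = 2.0  # spectral radius > 1
        with pytest.raises(ValueError, match="spectral"):
            simulate_patient_cohort(truth, n_patients=10, seed=9)


class TestSimulateCelllinePair:
    def test_no_alterations_yield_all_zero_segments(self, truth100):
        rec = make_truth_record(truth100, n_drivers=0, n_markers=0, seed=3)
        pair = simulate_cellline_pair(
            truth100, rec, broad_frac=0.0, focal_count=0, seed=10
        )
        assert (pair["segments"]["log2_ratio"] == 0).all()
        assert pair["altered_genes"] == set()

    def test_planted_gene_ratios_exceed_cutoff_exactly_on_altered_genes(
        self, truth100, record100, cellline100
    ):
        from radnet.cna import map_segments_to_genes

        vals = map_segments_to_genes(cellline100["segments"], truth100.annotation)
        altered = cellline100["altered_genes"]
        assert (vals[sorted(altered)].abs() > 0.1).all()
        unaltered = set(truth100.genes) - altered
        assert (vals[sorted(unaltered)].abs() <= 0.1).all()

    def test_driver_focal_alterations_signed_by_direction(
        self, record100, cellline100
    ):
        cn = cellline100["gene_cn"]
        for g, d in record100.drivers.items():
            assert (cn[g] > 0.1) if d == "up" else (cn[g] < -0.1)

    def test_seeded_seg_output_byte_identical(self, truth100, record100, tmp_path):
        from radnet.io import write_seg

        p1, p2 = tmp_path / "a.seg", tmp_path / "b.seg"
        write_seg(simulate_cellline_pair(truth100, record100, seed=11)["segments"], p1)
        write_seg(simulate_cellline_pair(truth100, record100, seed=11)["segments"], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_focal_count_beyond_gene_count_rejected(self, truth100, record100):
        with pytest.raises(ValueError):
            simulate_cellline_pair(truth100, record100, focal_count=101)


class TestSimulateRelapseTimes:
    def test_zero_hazard_coefficients_give_null_association(self, truth100):
        rec = make_truth_record(truth100, hazard_scale=0.0, seed=4)
        expr, _, skel = simulate_patient_cohort(truth100, n_patients=200, seed=12)
        clinical = simulate_relapse_times(expr, rec, skel, seed=13)
        g = next(iter(rec.drivers))
        tau = stats.kendalltau(
            expr.loc[g], clinical["months"]
        ).statistic
        assert abs(tau) < 0.15

    def test_positive_hazard_shortens_relapse_of_high_expressors(self, truth100):
        rec = make_truth_record(truth100, hazard_scale=2.0, seed=5)
        expr, _, skel = simulate_patient_cohort(truth100, n_patients=400, seed=14)
        clinical = simulate_relapse_times(
            expr, rec, skel, censor_frac=0.0, seed=15
        )
        up = [g for g, d in rec.drivers.items() if d == "up"]
        g = up[0]
        high = expr.loc[g] > expr.loc[g].median()
        assert (
            clinical.loc[high.values, "months"].median()
            < clinical.loc[~high.values, "months"].median()
        )

    def test_zero_censoring_marks_every_record_as_event(self, truth100, record100):
        expr, _, skel = simulate_patient_cohort(truth100, n_patients=50, seed=16)
        clinical = simulate_relapse_times(
            expr, record100, skel, censor_frac=0.0, seed=17
        )
        assert clinical["event"].all()

    def test_censor_fraction_respected(self, truth100, record100):
        expr, _, skel = simulate_patient_cohort(truth100, n_patients=200, seed=18)
        clinical = simulate_relapse_times(
            expr, record100, skel, censor_frac=0.4, seed=19
        )
        assert (~clinical["event"]).mean() == pytest.approx(0.4, abs=0.02)

    def test_invalid_censor_fraction_rejected(self, truth100, record100):
        expr, _, skel = simulate_patient_cohort(truth100, n_patients=40, seed=20)
        with pytest.raises(ValueError):
            simulate_relapse_times(expr, record100, skel, censor_frac=1.0)

    def test_clinical_table_carries_all_covariates(self, truth100, record100):
        expr, _, skel = simulate_patient_cohort(truth100, n_patients=40, seed=21)
        clinical = simulate_relapse_times(expr, record100, skel, seed=22)
        for col in ("months", "event", "irradiated", "age", "t_stage", "gleason", "psa"):
            assert col in clinical.columns
        assert (clinical["months"] >= 0).all()
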