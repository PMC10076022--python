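import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metacrit.dnb import (
    CriteriaConfig,
    cluster_candidates,
    fisher_z,
    module_indices,
    scan_stages,
    sd_filter,
    stage_standardize,
)
from metacrit.io import StageDesign
from metacrit.synth import SimulationConfig, simulate_staged_expression

from conftest import expr_from
from oracles import module_indices_oracle


def design_for(n_ref, n_stage, stage="Stage I"):
    mapping = {f"s{j}": ("Normal" if j < n_ref else stage)
               for j in range(n_ref + n_stage)}
    return StageDesign(mapping, ("Normal", stage), "Normal")


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form_at_half(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-12)

    @given(st.floats(min_value=-0.999, max_value=0.999))
    def test_odd_symmetry(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestSdFilter:
    def test_boundary_is_inclusive(self, rng):
        ref = rng.normal(0, 1.0, size=(1, 6))
        ref = (ref - ref.mean()) / ref.std(ddof=1)          # SD exactly 1
        stage = 2.0 * ref                                    # SD exactly 2
        m = expr_from(np.hstack([ref, stage]))
        design = design_for(6, 6)
        assert sd_filter(m, design, "Stage I", fold=2.0) == ["g0"]

    def test_equal_sds_yield_empty(self, rng):
        base = rng.normal(size=(4, 6))
        m = expr_from(np.hstack([base, base]))
        assert sd_filter(m, design_for(6, 6), "Stage I", fold=2.0) == []

    def test_small_stage_errors(self, rng):
        m = expr_from(rng.normal(size=(3, 7)))
        design = design_for(5, 2)
        with pytest.raises(ValueError, match="at least 3"):
            sd_filter(m, design, "Stage I")

    def test_recovers_planted_module(self):
        hits_crit, hits_other = [], []
        for seed in range(5):
            sim = simulate_staged_expression(SimulationConfig(seed=seed))
            truth = set(sim.truth.dnb_members)
            passed = set(sd_filter(sim.expression, sim.design, "Stage II"))
            hits_crit.append(len(truth & passed) / len(truth))
            other = set(sd_filter(sim.expression, sim.design, "Stage I"))
            hits_other.append(len(truth & other) / len(truth))
        assert min(hits_crit) >= 0.8
        assert max(hits_other) <= 0.1


class TestClusterCandidates:
    def test_two_planted_blocks_appear(self, rng):
        n = 40
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        rows = []
        for z in (z1, z2):
            for _ in range(5):
                rows.append(np.sqrt(0.9) * z + np.sqrt(0.1) * rng.normal(size=n))
        m = expr_from(np.array(rows))
        design = StageDesign({f"s{j}": "T" for j in range(n)}, ("T",), "T")
        cands = cluster_candidates(m, design, "T", m.gene_ids, min_size=5)
        blocks = [set(c) for c in cands]
        assert {f"g{i}" for i in range(5)} in blocks
        assert {f"g{i}" for i in range(5, 10)} in blocks

    def test_too_few_genes_warns_and_returns_empty(self, rng):
        m = expr_from(rng.normal(size=(4, 10)))
        design = StageDesign({f"s{j}": "T" for j in range(10)}, ("T",), "T")
        with pytest.warns(UserWarning, match="min_size"):
            assert cluster_candidates(m, design, "T", m.gene_ids, 5) == []

    def test_uncorrelated_genes_only_coarse_candidates(self, rng):
        m = expr_from(rng.normal(size=(12, 30)))
        design = StageDesign({f"s{j}": "T" for j in range(30)}, ("T",), "T")
        cands = cluster_candidates(m, design, "T", m.gene_ids, min_size=5)
        # no tight candidate: every candidate's mean |r| stays near background
        X = m.values
        for c in cands:
            idx = [m.gene_ids.index(g) for g in c]
            C = np.abs(np.corrcoef(X[idx]))
            iu = np.triu_indices_from(C, k=1)
            assert C[iu].mean() < 0.35


class TestModuleIndices:
    def test_formula_arithmetic(self):
        # sd_avg=2, pcc_in=0.6, pcc_out=0.3 -> ci = 2*0.6/0.3 = 4
        assert 2.0 * 0.6 / 0.3 == pytest.approx(4.0)

    def test_matches_bruteforce_oracle(self, rng):
        for trial in range(12):
            n_genes = int(rng.integers(6, 13))
            n = int(rng.integers(5, 9))
            vals = rng.normal(size=(n_genes, 2 * n)) * rng.uniform(
                0.5, 2.0, size=(n_genes, 1)
            )
            m = expr_from(vals)
            design = design_for(n, n)
            members = [f"g{i}" for i in range(3)]
            cand = module_indices(m, design, "Stage I", members)
            ref_samples = [f"s{j}" for j in range(n)]
            stage_samples = [f"s{j}" for j in range(n, 2 * n)]
            exp = module_indices_oracle(m.data, stage_samples, ref_samples, members)
            assert cand.sd_avg == pytest.approx(exp[0], abs=1e-12)
            assert cand.pcc_in == pytest.approx(exp[1], abs=1e-12)
            assert cand.pcc_out == pytest.approx(exp[2], abs=1e-12)
            assert cand.ci == pytest.approx(exp[3], abs=1e-10)

    def test_ratio_cancels_when_in_equals_out(self, rng):
        # pcc_in == pcc_out and unit gauged SD => ci == 1 by construction
        cand = None
        m = expr_from(rng.normal(size=(6, 16)))
        design = design_for(8, 8)
        cand = module_indices(m, design, "Stage I", ["g0", "g1"])
        assert cand.ci == pytest.approx(
            cand.sd_avg * cand.pcc_in / cand.pcc_out, rel=1e-12
        )

    def test_scale_covariance_in_member_expression(self, rng):
        m = expr_from(rng.normal(size=(8, 20)))
        design = design_for(10, 10)
        members = ["g0", "g1", "g2"]
        base = module_indices(m, design, "Stage I", members)
        scaled = m.data.copy()
        stage_cols = [f"s{j}" for j in range(10, 20)]
        scaled.loc[members, stage_cols] *= 2.0
        doubled = module_indices(expr_from(scaled.to_numpy()), design,
                                 "Stage I", members)
        assert doubled.sd_avg == pytest.approx(2 * base.sd_avg, abs=1e-9)
        assert doubled.ci == pytest.approx(2 * base.ci, abs=1e-9)
        assert doubled.pcc_in == pytest.approx(base.pcc_in, abs=1e-12)
        assert doubled.pcc_out == pytest.approx(base.pcc_out, abs=1e-12)

    def test_permuting_samples_within_stage_changes_nothing(self, rng):
        m = expr_from(rng.normal(size=(6, 14)))
        design = design_for(7, 7)
        base = module_indices(m, design, "Stage I", ["g0", "g1"])
        perm_cols = (
            [f"s{j}" for j in np.array(range(7))[rng.permutation(7)]]
            + [f"s{j}" for j in (7 + rng.permutation(7))]
        )
        permuted = expr_from(
            m.data[perm_cols].to_numpy(), samples=[f"s{j}" for j in range(14)]
        )
        again = module_indices(permuted, design, "Stage I", ["g0", "g1"])
        assert again.ci == pytest.approx(base.ci, abs=1e-12)


class TestScanStages:
    def test_single_satisfying_candidate_selected(self, rng):
        """A planted module at one stage is found at that stage."""
        sim = simulate_staged_expression(SimulationConfig(
            n_genes=400, dnb_size=12,
            stage_sizes={"Normal": 30, "Stage I": 30, "Stage II": 30},
            critical_stage="Stage I", seed=11,
        ))
        report = scan_stages(sim.expression, sim.design)
        assert report.selected_stage == "Stage I"
        assert report.ci_curve["Stage I"] is not None

    def test_no_candidates_yields_none(self):
        sim = simulate_staged_expression(SimulationConfig(
            n_genes=300, dnb_size=10, sd_inflation=1.0, rho_in=0.2,
            stage_sizes={"Normal": 20, "Stage I": 20}, critical_stage="Stage I",
            seed=0,
        ))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = scan_stages(sim.expression, sim.design)
        assert report.selected_stage is None
        assert report.dnb_members == []

    def test_report_roundtrip(self, tmp_path):
        from metacrit.dnb import DNBReport
        from metacrit.io import read_report, write_report

        sim = simulate_staged_expression(SimulationConfig(
            n_genes=300, dnb_size=10,
            stage_sizes={"Normal": 20, "Stage I": 20}, critical_stage="Stage I",
            seed=1,
        ))
        report = scan_stages(sim.expression, sim.design)
        path = tmp_path / "r.json"
        write_report(report, path)
        back = read_report(path, DNBReport)
        assert back.selected_stage == report.selected_stage
        assert back.dnb_members == report.dnb_members
        assert back.ci_curve == report.ci_curve

    def test_bootstrap_criteria_accept_planted_module(self):
        sim = simulate_staged_expression(SimulationConfig(
            n_genes=300, dnb_size=12,
            stage_sizes={"Normal": 30, "Stage I": 30}, critical_stage="Stage I",
            seed=2,
        ))
        report = scan_stages(
            sim.expression, sim.design,
            criteria=CriteriaConfig(mode="bootstrap", bootstrap_b=100, seed=0),
        )
        assert report.selected_stage == "Stage I"


def test_stage_standardize_zero_mean_unit_sd(rng):
    m = expr_from(rng.normal(size=(5, 12)))
    design = design_for(6, 6)
    z = stage_standardize(m, design)
    for stage in ("Normal", "Stage I"):
        block = z.data[design.samples_for(stage)]
        assert np.allclose(block.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(block.std(axis=1, ddof=1), 1, atol=1e-12)
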