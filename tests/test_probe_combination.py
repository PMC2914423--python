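"""Quartet combination: size normalization, allele parameters, weights, QC."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnarray.probe_combination import (
    PanelFit,
    ReferencePanel,
    SnpProbeSet,
    allele_params_closed_form,
    combine_to_snp_signal,
    estimate_allele_params,
    fit_quartet_weights,
    fit_reference_panel,
    merge_amplicon_groups,
    qc_filter,
    size_normalize,
)
from cnarray.simulate import NoiseSpec, simulate_reference_panel


def _probe_rows(rows):
    return pd.DataFrame(
        rows,
        columns=["snp_id", "sample_id", "chrom", "pos", "quartet", "allele",
                 "pm", "mm", "amplicon_size", "subarray"],
    )


class TestSizeNormalize:
    def test_single_group_self_normalizes(self):
        rows = [(f"s{i}", "a", "1", i + 1, 1, al, 600.0, 100.0, 400, "Nsp")
                for i in range(10) for al in "AB"]
        out = size_normalize(_probe_rows(rows), min_group_obs=1)
        assert np.allclose(out["inorm"], 1.0)

    def test_two_groups_normalized_by_own_group_mean(self):
        rows = []
        # group 200: two records with dI 200 and 600 -> mean 400
        rows.append(("s1", "a", "1", 1, 1, "A", 300.0, 100.0, 200, "Nsp"))
        rows.append(("s1", "a", "1", 1, 1, "B", 700.0, 100.0, 200, "Nsp"))
        # group 500: constant dI 100
        rows += [(f"t{i}", "a", "1", 10 + i, 1, "A", 200.0, 100.0, 500, "Nsp")
                 for i in range(4)]
        out = size_normalize(_probe_rows(rows), min_group_obs=1)
        g200 = out[out["amplicon_size"] == 200].sort_values("allele")
        assert list(g200["inorm"]) == pytest.approx([0.5, 1.5])
        assert np.allclose(out[out["amplicon_size"] == 500]["inorm"], 1.0)

    def test_negative_di_propagates(self):
        rows = [("s1", "a", "1", 1, 1, "A", 100.0, 300.0, 200, "Nsp")]
        rows += [(f"t{i}", "a", "1", 5 + i, 1, "A", 600.0, 100.0, 200, "Nsp")
                 for i in range(4)]
        out = size_normalize(_probe_rows(rows), min_group_obs=1)
        assert out["inorm"].iloc[0] < 0

    def test_nonpositive_group_mean_drops_probes(self):
        rows = [("s1", "a", "1", 1, 1, "A", 100.0, 300.0, 200, "Nsp"),
                ("s2", "a", "1", 2, 1, "A", 100.0, 300.0, 200, "Nsp"),
                ("t1", "a", "1", 9, 1, "A", 500.0, 100.0, 700, "Nsp")]
        with pytest.warns(UserWarning, match="non-positive"):
            out = size_normalize(_probe_rows(rows), min_group_obs=1)
        assert set(out["snp_id"]) == {"t1"}

    def test_sparse_size_pools_with_nearest(self):
        # size 210 has one observation -> pooled with well-populated 200
        rows = [(f"s{i}", "a", "1", i + 1, 1, "A", 500.0, 100.0, 200, "Nsp")
                for i in range(30)]
        rows.append(("lone", "a", "1", 99, 1, "A", 900.0, 100.0, 210, "Nsp"))
        out = size_normalize(_probe_rows(rows), min_group_obs=20)
        lone = out[out["snp_id"] == "lone"]["inorm"].iloc[0]
        # pooled mean = (30*400 + 800)/31
        assert lone == pytest.approx(800.0 / ((30 * 400 + 800) / 31))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            size_normalize(_probe_rows([]))


class TestAlleleParams:
    def test_symmetric_unit_design(self):
        n = {"AA": 24, "BB": 24}
        k_a, k_b = allele_params_closed_form(n, {"AA": 2, "BB": 0}, {"AA": 0, "BB": 2})
        assert (k_a, k_b) == pytest.approx((1.0, 1.0))

    def test_doubling_signal_halves_parameters(self):
        n = {"AA": 24, "BB": 24}
        k_a, k_b = allele_params_closed_form(n, {"AA": 4, "BB": 0}, {"AA": 0, "BB": 4})
        assert (k_a, k_b) == pytest.approx((0.5, 0.5))

    def test_three_genotype_design_matches_hand_computation(self):
        n = {"AA": 10, "AB": 20, "BB": 10}
        x = {"AA": 2.2, "AB": 1.0, "BB": 0.1}
        y = {"AA": 0.1, "AB": 1.2, "BB": 2.4}
        k_a, k_b = allele_params_closed_form(n, x, y)
        assert k_a == pytest.approx(0.9078, abs=1e-4)
        assert k_b == pytest.approx(0.8328, abs=1e-4)

    def test_degenerate_design_raises(self):
        # collinear rows: x = y for every class
        n = {"AA": 10, "AB": 10}
        with pytest.raises(ZeroDivisionError):
            allele_params_closed_form(n, {"AA": 1, "AB": 2}, {"AA": 1, "AB": 2})

    def test_closed_form_matches_weighted_least_squares_oracle(self, rng):
        """The closed form must agree with an independent lstsq solution of
        the weighted design on random polymorphic panels."""
        for _ in range(100):
            n = {g: int(rng.integers(1, 30)) for g in ("AA", "AB", "BB")}
            x = {g: float(rng.uniform(0.05, 3.0)) for g in n}
            y = {g: float(rng.uniform(0.05, 3.0)) for g in n}
            try:
                k_a, k_b = allele_params_closed_form(n, x, y)
            except ZeroDivisionError:
                continue
            w = np.sqrt([n[g] for g in ("AA", "AB", "BB")])
            a = np.column_stack([
                w * np.array([x[g] for g in ("AA", "AB", "BB")]),
                w * np.array([y[g] for g in ("AA", "AB", "BB")]),
            ])
            sol, *_ = np.linalg.lstsq(a, 2.0 * w, rcond=None)
            assert (k_a, k_b) == pytest.approx(tuple(sol), abs=1e-3)

    def test_closed_form_dominates_grid(self, rng):
        """E at the closed-form optimum is <= E everywhere on a 200x200 grid."""
        def e_val(ka, kb, n, x, y):
            return sum(
                n[g] * (ka * x[g] + kb * y[g] - 2.0) ** 2 for g in n
            )

        for _ in range(5):
            n = {g: int(rng.integers(5, 25)) for g in ("AA", "AB", "BB")}
            x = {g: float(rng.uniform(0.1, 3.0)) for g in n}
            y = {g: float(rng.uniform(0.1, 3.0)) for g in n}
            k_a, k_b = allele_params_closed_form(n, x, y)
            ks = np.linspace(0.1, 5, 200)
            ka_g, kb_g = np.meshgrid(ks, ks)
            e_grid = sum(
                n[g] * (ka_g * x[g] + kb_g * y[g] - 2.0) ** 2 for g in n
            )
            assert e_val(k_a, k_b, n, x, y) <= e_grid.min() + 1e-9


class TestQuartetWeights:
    @pytest.mark.parametrize(
        "variances,w_expected,combined,equal",
        [
            ({1: 1.0, 2: 1.0}, {1: 0.5, 2: 0.5}, 0.5, 1.0),
            ({1: 1.0, 2: 3.0}, {1: 0.75, 2: 0.25}, 0.75, 2.0),
            ({1: 0.2}, {1: 1.0}, 0.2, 0.2),
        ],
    )
    def test_inverse_variance_weighting(self, variances, w_expected, combined, equal):
        w, v, comb, eq = fit_quartet_weights(variances)
        assert w == pytest.approx(w_expected)
        assert comb == pytest.approx(combined)
        assert eq == pytest.approx(equal)

    def test_weights_from_sample_vectors(self, rng):
        data = {q: rng.normal(2.0, 0.3, size=48) for q in range(1, 7)}
        w, v, comb, eq = fit_quartet_weights(data)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-9)
        for q in v:
            assert v[q] == pytest.approx(np.var(data[q], ddof=1))

    def test_zero_variance_floored(self):
        with pytest.warns(UserWarning, match="floored"):
            w, v, comb, eq = fit_quartet_weights({1: 0.0, 2: 1.0})
        assert v[1] == pytest.approx(1e-6)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(1e-4, 10.0), min_size=1, max_size=10))
    def test_combined_variance_bounds(self, variances):
        """sigma_i^2 <= min(sigma_q^2) and <= the equal-weight benchmark."""
        v_in = {q + 1: v for q, v in enumerate(variances)}
        w, v, comb, eq = fit_quartet_weights(v_in)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-9)
        assert comb <= min(variances) + 1e-12
        assert comb <= eq + 1e-12


class TestCombineAndQc:
    def _ps(self, **kw):
        base = dict(snp_id="s", chromosome="1", position_bp=1, k_a=1.0, k_b=1.0,
                    quartet_weights={1: 0.5, 2: 0.5}, quartet_variances={1: 1.0, 2: 1.0})
        base.update(kw)
        return SnpProbeSet(**base)

    def test_diploid_heterozygote_design_point(self):
        ps = self._ps()
        ints = {(1, "A"): 1.0, (1, "B"): 1.0, (2, "A"): 1.0, (2, "B"): 1.0}
        assert combine_to_snp_signal(ints, ps) == pytest.approx(2.0)

    def test_weighted_sum(self):
        ps = self._ps(quartet_weights={1: 0.75, 2: 0.25})
        ints = {(1, "A"): 1.0, (1, "B"): 1.0, (2, "A"): 2.0, (2, "B"): 2.0}
        # S_q = 2.0 and 4.0
        assert combine_to_snp_signal(ints, ps) == pytest.approx(2.5)

    def test_missing_quartet_renormalizes(self):
        ps = self._ps(quartet_weights={1: 0.75, 2: 0.25})
        with pytest.warns(UserWarning, match="renormalized"):
            s = combine_to_snp_signal({(2, "A"): 2.0, (2, "B"): 2.0}, ps)
        assert s == pytest.approx(4.0)

    def test_amplicon_group_averaging(self):
        df = pd.DataFrame({
            "snp_id": ["a", "b", "c"],
            "chrom": ["1", "1", "1"],
            "pos": [100, 200, 300],
            "signal": [1.8, 2.2, 3.0],
        })
        out = merge_amplicon_groups(df, {"a": "amp1", "b": "amp1"})
        assert len(out) == 2
        merged = out[out["snp_id"] == "a"]
        assert merged["signal"].iloc[0] == pytest.approx(2.0)
        assert "b" not in set(out["snp_id"])

    def test_qc_variance_cutoff(self):
        sets = {"keep": self._ps(snp_id="keep"), "drop": self._ps(snp_id="drop")}
        sig = pd.DataFrame({
            "snp_id": ["keep"] * 4 + ["drop"] * 4,
            "sample_id": list("wxyz") * 2,
            # mean (S-2)^2 = 0.0376 vs 0.30
            "signal": [2 + 0.194, 2 - 0.194, 2 + 0.194, 2 - 0.194,
                       2 + 0.5477, 2 - 0.5477, 2 + 0.5477, 2 - 0.5477],
        })
        out = qc_filter(sets, sig, cutoff=0.25)
        assert not out["keep"].excluded
        assert out["drop"].excluded and out["drop"].exclusion_reason == "high_variance"


@pytest.fixture(scope="module")
def fitted_panel():
    probe_df, gt_df, truth = simulate_reference_panel(
        n_samples=48, n_snps=150, rng=np.random.default_rng(42)
    )
    panel = ReferencePanel(
        samples={s: "F" for s in truth["sample_ids"]},
        genotypes=gt_df,
        intensities=probe_df,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_reference_panel(panel)
    return fit, truth


class TestPanelFit:
    def test_diploid_panel_mean_signal_near_two(self, fitted_panel):
        fit, _ = fitted_panel
        sig = fit.panel_signals
        retained = sig[sig["snp_id"].isin(fit.retained())]
        assert 1.95 <= retained["signal"].mean() <= 2.05

    def test_allelic_bias_recovered(self, fitted_panel):
        """The uneven-amplification statistic — the median over SNPs of
        max(kA/kB, kB/kA) — is recovered within 5% of the generating value;
        per-SNP ratios track truth to within the panel-size noise floor."""
        fit, truth = fitted_panel
        idx = {s: i for i, s in enumerate(truth["snp_ids"])}
        true_ratios, fit_ratios, errs = [], [], []
        for s in fit.retained():
            i = idx[s]
            rt = max(truth["k_a"][i] / truth["k_b"][i], truth["k_b"][i] / truth["k_a"][i])
            ps = fit.probe_sets[s]
            rf = max(ps.k_a / ps.k_b, ps.k_b / ps.k_a)
            true_ratios.append(rt)
            fit_ratios.append(rf)
            errs.append(abs(rf / rt - 1))
        assert np.median(fit_ratios) == pytest.approx(np.median(true_ratios), rel=0.05)
        # per-SNP: median estimation error limited by 48-sample medians
        assert np.median(errs) <= 0.10

    def test_weighted_variance_never_exceeds_equal_weight(self, fitted_panel):
        fit, _ = fitted_panel
        for s in fit.retained():
            ps = fit.probe_sets[s]
            assert ps.combined_variance <= ps.equal_weight_variance + 1e-12

    def test_monomorphic_snp_excluded(self):
        probe_df, gt_df, truth = simulate_reference_panel(
            n_samples=8, n_snps=5, rng=np.random.default_rng(1)
        )
        gt_df.loc[gt_df["snp_id"] == "snp000000", "genotype"] = "AA"
        panel = ReferencePanel(
            samples={s: "F" for s in truth["sample_ids"]},
            genotypes=gt_df, intensities=probe_df,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_reference_panel(panel)
        ps = fit.probe_sets["snp000000"]
        assert ps.excluded and ps.exclusion_reason == "monomorphic"

    def test_estimate_allele_params_single_snp_api(self, fitted_panel, rng):
        fit, truth = fitted_panel
        probe_df, gt_df, t2 = simulate_reference_panel(
            n_samples=24, n_snps=3, rng=rng
        )
        panel = ReferencePanel(
            samples={s: "F" for s in t2["sample_ids"]},
            genotypes=gt_df, intensities=probe_df,
        )
        k_a, k_b = estimate_allele_params(panel, "snp000001")
        assert k_a > 0 and k_b > 0

    def test_panel_fit_json_round_trip(self, fitted_panel, tmp_path):
        import json
        fit, _ = fitted_panel
        path = tmp_path / "fit.json"
        path.write_text(json.dumps(fit.to_dict()))
        back = PanelFit.from_dict(json.loads(path.read_text()))
        snp = fit.retained()[0]
        assert back.probe_sets[snp].k_a == pytest.approx(fit.probe_sets[snp].k_a)
        assert back.probe_sets[snp].quartet_weights == pytest.approx(
            fit.probe_sets[snp].quartet_weights
        )
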