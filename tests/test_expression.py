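"""TMM normalization, rhythm screen, classification, phase shifts, amplitudes."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from zeitconflict import expression, synthetic
from zeitconflict.expression import (
    classify_genes,
    compare_amplitudes,
    filter_low_counts,
    mean_expression_test,
    normalize_counts,
    phase_distribution_tests,
    phase_shift_analysis,
    screen_rhythmicity,
    tmm_factors,
)


@pytest.fixture(scope="module")
def sim():
    cfg = synthetic.ExpressionSimConfig(
        seed=13, n_genes=200, rhythmic_fraction=0.5,
        specific_fraction_a=0.2, specific_fraction_b=0.2,
        amplitude_range=(0.5, 1.0), shift_fraction=0.5, dispersion=0.1,
    )
    counts, design, truth = synthetic.generate_expression(cfg)
    return counts, design, truth


@pytest.fixture(scope="module")
def norm(sim):
    counts, design, _ = sim
    return normalize_counts(counts, design)


class TestTmm:
    def test_identical_libraries_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(50, 500)
        counts = pd.DataFrame({"s1": col, "s2": col})
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(50, 500) + 1
        counts = pd.DataFrame({"s1": col, "s2": 2 * col})
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0, atol=1e-9)

    def test_inflated_subset_shifts_factor(self):
        rng = np.random.default_rng(2)
        mu = np.full(1000, 100.0)
        base = rng.poisson(mu) + 1
        mu2 = mu.copy()
        mu2[:50] *= 10  # 5% of genes 10x up in library 2
        inflated = rng.poisson(mu2) + 1
        counts = pd.DataFrame({"s1": base, "s2": inflated})
        f = tmm_factors(counts)
        # library 2 spends sequencing depth on the inflated genes, so its
        # trimmed mean of M is negative: factor < 1, boosting the rest back
        assert f["s2"] / f["s1"] < 0.95
        # brute-force check: trimmed median M of the unaffected majority
        lib = counts.sum()
        M = np.log2((counts["s2"][50:] / lib["s2"]) / (counts["s1"][50:] / lib["s1"]))
        assert f["s2"] / f["s1"] == pytest.approx(2 ** np.median(M), abs=0.05)

    def test_matches_edger_reference(self, tmp_path):
        # independent oracle: edgeR::calcNormFactors on the same matrix
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        rng = np.random.default_rng(3)
        mat = rng.negative_binomial(5, 0.05, size=(400, 4)) + rng.poisson(2, (400, 4))
        counts = pd.DataFrame(mat, columns=[f"s{i}" for i in range(4)])
        csv = tmp_path / "counts.csv"
        counts.to_csv(csv, index=False)
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f"x <- as.matrix(read.csv('{csv}'))\n"
            "cat(calcNormFactors(x, method='TMM'), sep='\\n')\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        ref = np.array([float(v) for v in out.stdout.split()])
        got = tmm_factors(counts).to_numpy()
        assert np.allclose(got, ref, atol=0.02)

    def test_cpm_sums_and_effective_scaling(self, sim):
        counts, design, _ = sim
        mat = normalize_counts(counts, design)
        cpm = 2 ** mat.values - 0.5
        sums = cpm.sum(axis=0).to_numpy()
        expected = 1e6 / mat.norm_factors.to_numpy()
        assert np.allclose(sums, expected, rtol=1e-9)
        # factor-1 case: columns sum to exactly 1e6
        col = counts.iloc[:, 0]
        dup = pd.DataFrame({"a": col, "b": col})
        dd = pd.DataFrame({"sample_id": ["a", "b"], "condition": "X",
                           "zt_h": [0.0, 4.0], "replicate": [1, 1]})
        m2 = normalize_counts(dup, dd)
        assert np.allclose((2 ** m2.values - 0.5).sum(axis=0), 1e6, rtol=1e-12)

    def test_zero_library_errors(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(ValueError, match="zero-count"):
            tmm_factors(counts)

    def test_low_count_filter(self):
        design = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(6)],
            "condition": ["A"] * 3 + ["B"] * 3,
            "zt_h": [0.0, 4.0, 8.0] * 2, "replicate": [1, 2, 3] * 2,
        })
        counts = pd.DataFrame(
            np.vstack([np.full(6, 1000), np.zeros(6)]).astype(int),
            index=["expressed", "silent"], columns=design["sample_id"],
        )
        kept = filter_low_counts(counts, design)
        assert list(kept.index) == ["expressed"]


class TestScreenAndClassify:
    def test_sensitivity_and_phase_on_strong_genes(self, sim, norm):
        counts, design, truth = sim
        res = screen_rhythmicity(norm, "Aligned")
        rhythmic_a = truth.genes["class"].isin(["shared", "a_specific"])
        sens = (res["rhythmic"] & rhythmic_a).sum() / rhythmic_a.sum()
        assert sens >= 0.9
        # peak-phase estimate lands within one sampling step of the truth
        sel = rhythmic_a & res["rhythmic"]
        dphi = np.abs(
            (res.loc[sel, "phase_h"] - truth.genes.loc[sel, "phase_Aligned"] + 12) % 24 - 12
        )
        assert np.median(dphi) <= 4.0

    def test_null_matrix_flags_almost_nothing(self):
        cfg = synthetic.ExpressionSimConfig(seed=5, n_genes=400, rhythmic_fraction=0.0)
        counts, design, _ = synthetic.generate_expression(cfg)
        res = screen_rhythmicity(normalize_counts(counts, design), "Aligned")
        assert res["rhythmic"].mean() <= 0.01

    def test_classification_rules(self):
        idx = ["g1", "g2", "g3", "g4"]
        ra = pd.DataFrame({"p_adj": [0.005, 0.005, 0.005, 0.5]}, index=idx)
        rb = pd.DataFrame({"p_adj": [0.5, 0.05, 0.005, 0.5]}, index=idx)
        out = classify_genes(ra, rb)
        assert out.tolist() == ["a_specific", "indeterminate", "shared", "arrhythmic"]

    def test_classification_is_partition(self, sim, norm):
        _, _, truth = sim
        ra = screen_rhythmicity(norm, "Aligned")
        rb = screen_rhythmicity(norm, "SC")
        out = classify_genes(ra, rb)
        assert len(out) == len(ra)
        assert out.isin(["shared", "a_specific", "b_specific",
                         "arrhythmic", "indeterminate"]).all()


class TestPhaseShift:
    def test_planted_shift_flags_temperature_tracking(self, sim, norm):
        counts, design, truth = sim
        ra = screen_rhythmicity(norm, "Aligned")
        rb = screen_rhythmicity(norm, "SC")
        shared = classify_genes(ra, rb)
        genes = shared.index[shared == "shared"]
        res = phase_shift_analysis(norm, genes, "Aligned", "SC")
        joined = res.join(truth.genes)
        flagged = joined["temperature_tracking"]
        # flagged genes are overwhelmingly the planted 12-h shifters and vice versa
        assert (joined.loc[flagged, "is_shifted"]).mean() >= 0.9
        shifted = joined["is_shifted"]
        assert joined.loc[shifted, "temperature_tracking"].mean() >= 0.85
        med = joined.loc[flagged, "d_phase_light"].abs().median()
        assert abs(med - 12) < 0.5

    def test_unshifted_gene_near_zero(self, sim, norm):
        counts, design, truth = sim
        stay = truth.genes.index[
            (truth.genes["class"] == "shared") & ~truth.genes["is_shifted"]
        ][:5]
        res = phase_shift_analysis(norm, stay, "Aligned", "SC")
        assert np.abs(res["d_phase_light"]).max() < 3.0
        assert not res["temperature_tracking"].any()


class TestAmplitudeAndPhases:
    def test_planted_reduction_recovered(self):
        rng = np.random.default_rng(11)
        t = np.tile(np.arange(13) * 4.0, 3)
        genes = {}
        for g in range(120):
            ph = rng.uniform(0, 24)
            a = 1.0
            y1 = 5 + a * np.cos(2 * np.pi * (t - ph) / 24) + rng.normal(0, 0.2, len(t))
            y2 = 5 + 0.9 * a * np.cos(2 * np.pi * (t - ph) / 24) + rng.normal(0, 0.2, len(t))
            genes[f"g{g}"] = (y1, y2)
        # wrap into an ExpressionMatrix-like frame
        ids_a = [f"A{i}" for i in range(len(t))]
        ids_b = [f"B{i}" for i in range(len(t))]
        values = pd.DataFrame(
            {**{ids_a[i]: [genes[g][0][i] for g in genes] for i in range(len(t))},
             **{ids_b[i]: [genes[g][1][i] for g in genes] for i in range(len(t))}},
            index=list(genes),
        )
        design = pd.DataFrame({
            "sample_id": ids_a + ids_b,
            "condition": ["A"] * len(t) + ["B"] * len(t),
            "zt_h": np.concatenate([t, t]),
            "replicate": 1,
        })
        mat = expression.ExpressionMatrix(values=values, design=design)
        out = compare_amplitudes(mat, list(genes), "A", "B")
        assert out["p"] < 0.01
        assert -13 <= out["median_pct_change"] <= -7

    def test_single_gene_refused(self, norm):
        with pytest.raises(ValueError):
            compare_amplitudes(norm, ["gene00000"], "Aligned", "SC")

    def test_bimodal_detected_by_axial_rayleigh(self):
        a = np.concatenate([
            synthetic.generate_phase_sample(100, 4.0, 5.0, seed=0),
            synthetic.generate_phase_sample(100, 16.0, 5.0, seed=1),
        ])
        b = synthetic.generate_phase_sample(120, 4.0, 1.0, seed=2)
        out = phase_distribution_tests(a, b, n_mc=500, seed=0)
        assert out["p_rayleigh_axial_a"] < 0.01
        assert out["p_rayleigh_axial_a"] < out["p_rayleigh_a"]

    def test_mean_expression_comparison(self, sim, norm):
        _, _, truth = sim
        ga = truth.genes.index[truth.genes["class"] == "a_specific"]
        gb = truth.genes.index[truth.genes["class"] == "b_specific"]
        out = mean_expression_test(norm, ga, gb, "Aligned", "SC")
        assert 0 <= out["p"] <= 1
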