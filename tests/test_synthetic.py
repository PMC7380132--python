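import json

import numpy as np
import pytest
from scipy import stats

from mesoscore import (
    CohortDesign,
    GroupDesign,
    classify_cohort,
    default_design,
    default_gene_universe,
    default_signatures,
    fisher_exact_2x2,
    generate_archetypes,
    generate_cohort,
    mes15_zscore,
    read_expression,
    simulate_default_cohort,
    write_fixture_bundle,
    ztransform,
)


class TestGenerateArchetypes:
    def test_same_seed_is_bit_identical(self):
        a = generate_archetypes(seed=5)
        b = generate_archetypes(seed=5)
        assert a.means.equals(b.means)

    def test_different_seed_differs(self):
        a = generate_archetypes(seed=5)
        b = generate_archetypes(seed=6)
        assert not a.means.equals(b.means)

    def test_null_effects_make_classes_exchangeable(self):
        a = generate_archetypes(seed=0, mes15_fold=1.0, omental_fold=1.0,
                                primary_fold=1.0)
        for cls in a.means.columns[1:]:
            np.testing.assert_array_equal(a.means[cls], a.means.iloc[:, 0])

    def test_mes_fold_ratio_holds_for_every_gene(self):
        a = generate_archetypes(seed=0, mes15_fold=8.0)
        sigs = default_signatures()
        ratio = (a.means.loc[list(sigs["mes15"].genes), "metastatic_stroma"]
                 / a.means.loc[list(sigs["mes15"].genes), "cancer_epithelium"])
        assert (ratio >= 8.0 - 1e-12).all()

    def test_signature_gene_missing_from_universe_errors(self):
        with pytest.raises(ValueError, match="absent"):
            generate_archetypes(gene_universe=("POSTN", "BG0001"), seed=0)


class TestGenerateCohort:
    def test_noise_free_expression_is_exact_mixture(self):
        archetypes = generate_archetypes(seed=2)
        design = CohortDesign(
            groups=(GroupDesign("ov-per", "III-IV", 5, "metastatic"),),
            noise_sigma=0.0, seed=3,
        )
        cohort = generate_cohort(archetypes, design)
        means = archetypes.means
        for sid in cohort.matrix.sample_ids:
            t = cohort.truth.loc[sid]
            expected = (
                t.fibroblast_fraction * means[t.stroma_identity]
                + t.cancer_fraction * means["cancer_epithelium"]
                + t.immune_fraction * means["immune"]
            )
            np.testing.assert_allclose(
                cohort.matrix.data[sid].to_numpy(), expected.to_numpy(), rtol=1e-12
            )

    def test_pure_cancer_sample_equals_archetype(self):
        archetypes = generate_archetypes(seed=2)
        # extreme concentrations pin the Dirichlet draw at the cancer vertex
        design = CohortDesign(
            groups=(GroupDesign("ov-ov", "I-II", 1, "primary",
                                (1e-9, 1e9, 1e-9)),),
            noise_sigma=0.0, seed=1,
        )
        cohort = generate_cohort(archetypes, design)
        np.testing.assert_allclose(
            cohort.matrix.values[:, 0],
            archetypes.means["cancer_epithelium"].to_numpy(),
            rtol=1e-6,
        )

    def test_same_seed_is_bit_identical(self):
        a = simulate_default_cohort(seed=4)
        b = simulate_default_cohort(seed=4)
        assert a.matrix.data.equals(b.matrix.data)
        assert a.truth.equals(b.truth)
        assert a.annotations.equals(b.annotations)

    def test_truth_fractions_sum_to_one(self, default_cohort):
        totals = default_cohort.truth[
            ["fibroblast_fraction", "cancer_fraction", "immune_fraction"]
        ].sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-12)

    def test_intended_mes_definition(self, default_cohort):
        t = default_cohort.truth
        expected = (t.stroma_identity == "metastatic_stroma") & (
            t.fibroblast_fraction >= default_cohort.design.mes_fibroblast_floor
        )
        assert (t.intended_mes == expected).all()

    def test_empty_design_errors(self):
        archetypes = generate_archetypes(seed=0)
        with pytest.raises(ValueError, match="zero samples"):
            generate_cohort(
                archetypes,
                CohortDesign(groups=(GroupDesign("ov-ov", "I-II", 0),), seed=0),
            )

    def test_classifier_recovers_intended_labels(self, default_cohort):
        c = default_cohort
        calls, _ = classify_cohort(c.matrix, c.signatures["mes15"])
        recovery = (calls["is_mes"] == c.truth["intended_mes"]).mean()
        assert recovery >= 0.90


class TestFixtureBundle:
    def test_roundtrip_and_determinism(self, tmp_path):
        cohort = simulate_default_cohort(seed=7)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        paths1 = write_fixture_bundle(cohort, d1)
        write_fixture_bundle(simulate_default_cohort(seed=7), d2)
        back = read_expression(paths1["matrix.tsv"])
        np.testing.assert_array_equal(back.values, cohort.matrix.values)
        assert back.gene_ids == cohort.matrix.gene_ids
        for name in ("matrix.tsv", "annotations.tsv", "content.tsv",
                     "truth.tsv", "signatures.gmt", "manifest.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_manifest_hash_tracks_config(self, tmp_path):
        c1 = simulate_default_cohort(seed=7)
        design2 = default_design(seed=7)
        design2 = CohortDesign(groups=design2.groups, noise_sigma=0.3, seed=7)
        c2 = generate_cohort(generate_archetypes(seed=7), design2)
        p1 = write_fixture_bundle(c1, tmp_path / "a")
        p2 = write_fixture_bundle(c2, tmp_path / "b")
        h1 = json.loads(p1["manifest.json"].read_text())["config_hash"]
        h2 = json.loads(p2["manifest.json"].read_text())["config_hash"]
        assert h1 != h2
        assert h1 == c1.design.config_hash()

    def test_refuses_nonempty_directory(self, tmp_path):
        cohort = simulate_default_cohort(seed=7)
        write_fixture_bundle(cohort, tmp_path / "a")
        with pytest.raises(FileExistsError):
            write_fixture_bundle(cohort, tmp_path / "a")
        write_fixture_bundle(cohort, tmp_path / "a", force=True)


def _small_universe():
    sigs = default_signatures()
    return default_gene_universe(n_background=10), sigs


class TestGeneratorStatistics:
    def test_parameter_recovery_positive_slope(self):
        """Regressing log expression of a Mes gene on fibroblast fraction
        within metastatic-stroma samples recovers a positive slope in >= 95%
        of replicates at default effect sizes (n=100 per replicate)."""
        universe, sigs = _small_universe()
        archetypes = generate_archetypes(universe, sigs, seed=0)
        gene = sigs["mes15"].genes[0]
        positive = 0
        n_reps = 50
        for rep in range(n_reps):
            design = CohortDesign(
                groups=(GroupDesign("ov-per", "III-IV", 100, "metastatic",
                                    (5.0, 4.0, 1.0)),),
                noise_sigma=0.15, seed=1000 + rep,
            )
            cohort = generate_cohort(archetypes, design, sigs)
            y = np.log(cohort.matrix.data.loc[gene].to_numpy())
            x = cohort.truth["fibroblast_fraction"].to_numpy()
            slope = stats.linregress(x, y).slope
            positive += slope > 0
        assert positive / n_reps >= 0.95

    def test_null_calibration(self):
        """With all fold effects at 1 the cohort carries no Mes structure:
        the all-genes-above-median call rate stays at its exchangeability
        level and the stage-group Fisher test rejects at <= nominal 5%."""
        universe, sigs = _small_universe()
        null_arch = generate_archetypes(universe, sigs, seed=0,
                                        mes15_fold=1.0, omental_fold=1.0,
                                        primary_fold=1.0)
        n_cohorts = 200
        total_calls = 0
        total_samples = 0
        rejections = 0
        for rep in range(n_cohorts):
            design = default_design(seed=2000 + rep, scale=0.25)
            cohort = generate_cohort(null_arch, design, sigs)
            calls, _ = classify_cohort(cohort.matrix, sigs["mes15"])
            total_calls += int(calls["is_mes"].sum())
            total_samples += len(calls)
            ann = cohort.annotations
            merged = calls.join(ann["stage_group"])
            tab = merged.groupby("stage_group")["is_mes"].agg(["sum", "size"])
            table = np.array([
                [tab.loc["I-II", "sum"], tab.loc["I-II", "size"] - tab.loc["I-II", "sum"]],
                [tab.loc["III-IV", "sum"], tab.loc["III-IV", "size"] - tab.loc["III-IV", "sum"]],
            ])
            rejections += fisher_exact_2x2(table) <= 0.05
        # exchangeability: P(all 15 genes above their cohort medians) <= 2^-15
        # per sample; allow generous Monte Carlo slack on the expected <1 call
        expected_rate = 0.5**15
        assert total_calls <= max(5, 10 * expected_rate * total_samples)
        assert rejections / n_cohorts <= 0.05 + 0.03

    def test_mes_zscore_monotone_in_fold(self):
        universe, sigs = _small_universe()
        means = []
        for fold in (2.0, 4.0, 8.0):
            archetypes = generate_archetypes(universe, sigs, seed=0,
                                             mes15_fold=fold)
            design = default_design(seed=11)
            cohort = generate_cohort(archetypes, design, sigs)
            z = ztransform(cohort.matrix)
            score = mes15_zscore(z, sigs["mes15"])
            met = cohort.truth.index[
                cohort.truth.stroma_identity == "metastatic_stroma"
            ]
            means.append(score[met].mean())
        assert means[0] < means[1] < means[2]
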