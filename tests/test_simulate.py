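"""Synthetic cohort generator: determinism, calibration, filter accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pwascan as pw
from pwascan.simulate import ConfigError


class TestConfigValidation:
    def test_zero_individuals_rejected(self):
        with pytest.raises(ConfigError, match="n_individuals"):
            pw.SimulationConfig(n_individuals=0)

    def test_bad_distribution_kind_named(self):
        cfg = pw.SimulationConfig(allele_freq_spec={"kind": "nope"})
        with pytest.raises(ConfigError, match="allele_freq_spec"):
            pw.generate_cohort(cfg)

    def test_bad_prevalence_rejected(self):
        with pytest.raises(ConfigError, match="baseline_prevalence"):
            pw.PhenotypeSpec(name="x", baseline_prevalence=1.5)

    def test_null_mode_forces_unit_odds_ratio(self):
        eff = pw.GeneEffectSpec(gene_id="g", mode="null", odds_ratio=7.0)
        assert eff.odds_ratio == 1.0


class TestGenerateCohort:
    def test_identical_seeds_identical_output(self):
        cfg = dict(n_individuals=300, n_genes=5, seed=42)
        a = pw.generate_cohort(pw.SimulationConfig(**cfg))
        b = pw.generate_cohort(pw.SimulationConfig(**cfg))
        pd.testing.assert_frame_equal(a.individuals, b.individuals)
        pd.testing.assert_frame_equal(a.variants, b.variants)
        pd.testing.assert_frame_equal(a.dosages, b.dosages)

    def test_different_seeds_differ(self):
        a = pw.generate_cohort(pw.SimulationConfig(n_individuals=300, n_genes=5, seed=1))
        b = pw.generate_cohort(pw.SimulationConfig(n_individuals=300, n_genes=5, seed=2))
        assert not a.dosages.equals(b.dosages)

    def test_dosages_binomial_moments(self):
        # one common variant: mean dosage within 3 SE of 2 * freq
        cfg = pw.SimulationConfig(
            n_individuals=10_000,
            n_genes=1,
            variants_per_gene=1,
            allele_freq_spec={"kind": "fixed", "value": 0.3},
            seed=3,
        )
        cohort = pw.generate_cohort(cfg)
        mean = cohort.dosages.iloc[:, 0].mean()
        se = np.sqrt(2 * 0.3 * 0.7 / 10_000)
        assert abs(mean - 0.6) < 3 * se

    def test_layout_on_chromosomes(self):
        cohort = pw.generate_cohort(
            pw.SimulationConfig(n_individuals=10, n_genes=4, n_chromosomes=2, seed=0)
        )
        assert set(cohort.gene_coords.chrom) == {"chr1", "chr2"}
        merged = cohort.variants.merge(cohort.gene_coords, on="gene_id")
        assert ((merged.pos >= merged.cds_start) & (merged.pos <= merged.cds_end)).all()


class TestImplantPhenotypes:
    def test_prevalence_calibrated_under_null(self):
        cfg = pw.SimulationConfig(
            n_individuals=50_000,
            n_genes=2,
            seed=9,
            phenotypes=[dict(name="c", baseline_prevalence=0.05)],
        )
        cohort = pw.generate_cohort(cfg)
        labels, _ = pw.implant_phenotypes(cohort)
        se = np.sqrt(0.05 * 0.95 / 50_000)
        assert abs(labels["c"].mean() - 0.05) < 3 * se

    def test_null_labels_independent_of_genotype(self):
        # with all-null genetics, a common variant should associate with
        # the label only at the chi-square type-I rate
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = pw.SimulationConfig(
                n_individuals=1500,
                n_genes=1,
                variants_per_gene=1,
                allele_freq_spec={"kind": "fixed", "value": 0.3},
                seed=seed,
                phenotypes=[
                    dict(
                        name="c",
                        baseline_prevalence=0.2,
                        causal_effects=[
                            dict(gene_id="GENE0001", mode="null", odds_ratio=1.0)
                        ],
                    )
                ],
            )
            cohort = pw.generate_cohort(cfg)
            labels, _ = pw.implant_phenotypes(cohort)
            table = pd.crosstab(cohort.dosages.iloc[:, 0], labels["c"])
            if table.shape[0] > 1:
                p = stats.chi2_contingency(table)[1]
                hits += p < 0.001
        assert hits <= 1  # expected 0.04 false positives over 40 seeds

    def test_sex_restricted_assigns_missing(self):
        cfg = pw.SimulationConfig(
            n_individuals=2000,
            n_genes=2,
            seed=5,
            phenotypes=[
                dict(name="prostate", baseline_prevalence=0.06, sex_restricted="male")
            ],
        )
        cohort = pw.generate_cohort(cfg)
        labels, _ = pw.implant_phenotypes(cohort)
        male = cohort.individuals["sex"] == 1
        assert labels.loc[~male, "prostate"].isna().all()
        assert labels.loc[male, "prostate"].notna().all()

    def test_unresolvable_gene_listed(self):
        cohort = pw.generate_cohort(pw.SimulationConfig(n_individuals=50, n_genes=2, seed=0))
        with pytest.raises(ConfigError, match="NOSUCH"):
            pw.implant_phenotypes(
                cohort,
                [
                    pw.PhenotypeSpec(
                        name="c",
                        baseline_prevalence=0.1,
                        causal_effects=[
                            dict(gene_id="NOSUCH", mode="dominant", odds_ratio=2)
                        ],
                    )
                ],
            )

    def test_recessive_needs_two_hits(self):
        # one ultra-rare fully damaging variant, no homozygotes in sample:
        # a recessive effect cannot express, so carrier case rate stays at
        # baseline; the truth log verifies nobody reached two events
        cfg = pw.SimulationConfig(
            n_individuals=20_000,
            n_genes=1,
            variants_per_gene=1,
            allele_freq_spec={"kind": "fixed", "value": 0.002},
            damage_prob_spec={"kind": "fixed", "value": 1.0},
            seed=17,
            phenotypes=[
                dict(
                    name="c",
                    baseline_prevalence=0.1,
                    causal_effects=[
                        dict(gene_id="GENE0001", mode="recessive", odds_ratio=20)
                    ],
                )
            ],
        )
        cohort = pw.generate_cohort(cfg)
        assert (cohort.dosages.iloc[:, 0] < 2).all()  # no homozygotes drawn
        labels, truth = pw.implant_phenotypes(cohort)
        assert (truth.n_damaging_events < 2).all()
        carriers = cohort.dosages.iloc[:, 0].to_numpy() == 1
        rate_carriers = labels["c"].to_numpy()[carriers].mean()
        n_car = carriers.sum()
        se = np.sqrt(0.1 * 0.9 / n_car)
        assert abs(rate_carriers - 0.1) < 4 * se

    def test_recessive_excess_conditions_on_truth(self):
        # implanted recessive gene: excess case rate among >=2-event
        # individuals, none among exactly-1 (checked on the truth log)
        cfg = pw.SimulationConfig(
            n_individuals=30_000,
            n_genes=1,
            variants_per_gene=6,
            allele_freq_spec={"kind": "fixed", "value": 0.05},
            damage_prob_spec={"kind": "fixed", "value": 0.9},
            seed=29,
            phenotypes=[
                dict(
                    name="c",
                    baseline_prevalence=0.05,
                    causal_effects=[
                        dict(gene_id="GENE0001", mode="recessive", odds_ratio=5)
                    ],
                )
            ],
        )
        cohort = pw.generate_cohort(cfg)
        labels, truth = pw.implant_phenotypes(cohort)
        ev = truth.set_index("individual_id")["n_damaging_events"]
        y = labels["c"]
        rate_two_plus = y[ev >= 2].mean()
        rate_one = y[ev == 1].mean()
        rate_zero = y[ev == 0].mean()
        assert rate_two_plus > 2 * rate_zero
        se_one = np.sqrt(rate_zero * (1 - rate_zero) / (ev == 1).sum())
        assert abs(rate_one - rate_zero) < 4 * se_one

    def test_implant_deterministic(self):
        cfg = pw.SimulationConfig(
            n_individuals=500,
            n_genes=2,
            seed=8,
            phenotypes=[dict(name="c", baseline_prevalence=0.1)],
        )
        cohort = pw.generate_cohort(cfg)
        a, _ = pw.implant_phenotypes(cohort)
        b, _ = pw.implant_phenotypes(cohort)
        pd.testing.assert_frame_equal(a, b)


class TestCohortFilters:
    def _flags_from_counts(self, total, counts):
        reasons = [f"r{i}" for i in range(len(counts))]
        flags = pd.DataFrame(False, index=range(total), columns=reasons)
        start = 0
        for r, c in zip(reasons, counts):
            flags.loc[start : start + c - 1, r] = True
            start += c
        return flags, reasons

    def test_published_style_accounting(self):
        counts = [14, 92_922, 312, 75_848, 58_594]
        flags, reasons = self._flags_from_counts(502_520, counts)
        report = pw.apply_cohort_filters(flags, reasons)
        assert report.remaining == 274_830
        assert list(report.excluded_per_reason.values()) == counts

    def test_no_flags_identity(self):
        flags = pd.DataFrame(False, index=range(10), columns=["a", "b"])
        report = pw.apply_cohort_filters(flags, ["a", "b"])
        assert report.remaining == 10
        assert all(v == 0 for v in report.excluded_per_reason.values())

    def test_double_flag_counted_once_under_earlier_reason(self):
        flags = pd.DataFrame(
            {"a": [True, False, False], "b": [True, True, False]}
        )
        report = pw.apply_cohort_filters(flags, ["a", "b"])
        # brute-force recount: individual 0 only under "a"
        assert report.excluded_per_reason == {"a": 1, "b": 1}
        assert report.remaining == 1

    def test_unknown_reason_rejected(self):
        flags = pd.DataFrame({"a": [False]})
        with pytest.raises(ValueError, match="zz"):
            pw.apply_cohort_filters(flags, ["zz"])

    def test_conservation_on_random_flags(self):
        rng = np.random.default_rng(0)
        flags = pd.DataFrame(
            rng.random((500, 4)) < 0.3, columns=list("abcd")
        )
        report = pw.apply_cohort_filters(flags, list("abcd"))
        assert report.remaining + sum(report.excluded_per_reason.values()) == 500
        # first-match partition equals brute force over rows
        brute = {r: 0 for r in "abcd"}
        kept = 0
        for _, row in flags.iterrows():
            for r in "abcd":
                if row[r]:
                    brute[r] += 1
                    break
            else:
                kept += 1
        assert brute == report.excluded_per_reason
        assert kept == report.remaining
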