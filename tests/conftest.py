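"""Shared fixtures: small synthetic cohorts and enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

import pwascan as pw


def enumerate_gene_scores(alleles):
    """Independent oracle: exhaustive 2^k enumeration of damage outcomes.

    ``alleles`` is a list of (genotype, damage_prob) pairs; returns the
    probabilities of zero and of at most one damaging event by summing over
    every outcome of the per-allele Bernoulli draws.
    """
    ds = []
    for g, d in alleles:
        ds.extend([d] * g)
    p0 = p1 = 0.0
    for outcome in itertools.product((0, 1), repeat=len(ds)):
        pr = 1.0
        for o, d in zip(outcome, ds):
            pr *= d if o else 1.0 - d
        k = sum(outcome)
        if k == 0:
            p0 += pr
        elif k == 1:
            p1 += pr
    return p0, p0 + p1


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with one 5%-prevalence phenotype and no genetic effects."""
    cfg = pw.SimulationConfig(
        n_individuals=4000,
        n_genes=12,
        seed=11,
        phenotypes=[
            dict(
                name="cancer",
                baseline_prevalence=0.05,
                covariate_effects={"pc1": 0.3},
            )
        ],
    )
    cohort = pw.generate_cohort(cfg)
    labels, truth = pw.implant_phenotypes(cohort)
    return cohort, labels, truth


@pytest.fixture(scope="session")
def dominant_cohort():
    """Cohort with one strongly dominant risk gene implanted."""
    cfg = pw.SimulationConfig(
        n_individuals=6000,
        n_genes=10,
        seed=23,
        allele_freq_spec={"kind": "fixed", "value": 0.02},
        damage_prob_spec={
            "kind": "beta_mixture",
            "weights": (0.3, 0.7),
            "alphas": (0.6, 8.0),
            "betas": (8.0, 0.6),
        },
        phenotypes=[
            dict(
                name="cancer",
                baseline_prevalence=0.08,
                causal_effects=[
                    dict(gene_id="GENE0001", mode="dominant", odds_ratio=4.0)
                ],
            )
        ],
    )
    cohort = pw.generate_cohort(cfg)
    labels, truth = pw.implant_phenotypes(cohort)
    scores = pw.score_matrix(cohort.dosages, cohort.variants)
    return cohort, labels, truth, scores
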