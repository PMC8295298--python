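"""Gene- and variant-level case-control association tests.

The gene-level test asks whether a gene's dominant and/or recessive effect
scores carry information about a binary phenotype beyond a set of covariates.
Logistic regressions are fitted for the covariates-only null and for the
null augmented with the dominant score, the recessive score, or both; each
alternative is compared to the null by a likelihood-ratio test (1 df for the
single-score models, 2 df for the combined model, whose null hypothesis is
that both score coefficients are zero).  The variant-level test is the
standard additive logistic regression of the phenotype on alternate-allele
dosage plus covariates, with a Wald p-value, gated on minor allele count.

Multiple testing is handled by Benjamini-Hochberg FDR per phenotype,
separately for the dominant, recessive and combined p-value families.
Directionality is read off Cohen's d, the standardized difference in mean
effect score between cases and controls: because lower scores mean more
gene damage, a *negative* d (cases scoring lower) means damage associates
with elevated risk, and a positive d with reduced risk (protective).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    HessianInversionWarning,
    PerfectSeparationError,
)

__all__ = [
    "SignificanceConfig",
    "GeneTestResult",
    "VariantTestResult",
    "bh_fdr",
    "cohens_d",
    "classify_direction",
    "classify_inheritance",
    "pwas_gene_test",
    "gwas_variant_test",
    "PWASModel",
    "PWASResults",
    "GWASModel",
    "GWASResults",
]

MODELS = ("dominant", "recessive", "combined")


@dataclass
class SignificanceConfig:
    """Significance thresholds used across the pipeline.

    ``gwas_p_threshold`` is the exome-wide per-variant threshold,
    ``pwas_q_threshold`` the FDR threshold for gene tests,
    ``soliton_q_threshold`` the stricter bound used to call single-gene
    (soliton) regions, and ``mac_min`` the minimum minor allele count for a
    variant to be tested at all.
    """

    gwas_p_threshold: float = 5e-7
    pwas_q_threshold: float = 0.05
    soliton_q_threshold: float = 1e-3
    mac_min: int = 20

    def __post_init__(self):
        for name in ("gwas_p_threshold", "pwas_q_threshold", "soliton_q_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.mac_min < 1:
            raise ValueError("mac_min must be >= 1")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Missing entries (NaN) are excluded from the family and returned as NaN;
    the remaining q-values are the cumulative-minimum-adjusted ``p * m / i``
    with m the number of non-missing tests.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        if np.any((p[mask] <= 0) | (p[mask] > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def cohens_d(scores, labels) -> float:
    """Standardized case-control difference in mean effect score.

    ``d = (mean_cases - mean_controls) / pooled_sd``.  Negative values mean
    cases carry lower scores, i.e. more gene damage, i.e. damage associates
    with elevated risk.  A zero pooled SD is degenerate: d is 0.0 when the
    group means also coincide, and a signed infinity when both groups are
    internally constant but separated (the sign still encodes direction).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    cases, controls = s[y == 1], s[y == 0]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    n1, n2 = len(cases), len(controls)
    pooled_var = (
        (n1 - 1) * cases.var(ddof=1) + (n2 - 1) * controls.var(ddof=1)
    ) / (n1 + n2 - 2)
    diff = cases.mean() - controls.mean()
    if pooled_var <= 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(pooled_var))


def classify_inheritance(
    q_dom: float, q_rec: float, config: SignificanceConfig | None = None
) -> str:
    """Partition a gene by which effect-score models pass the FDR threshold."""
    config = config or SignificanceConfig()
    t = config.pwas_q_threshold
    dom = np.isfinite(q_dom) and q_dom < t
    rec = np.isfinite(q_rec) and q_rec < t
    if dom and rec:
        return "both"
    if dom:
        return "dominant"
    if rec:
        return "recessive"
    return "none"


def classify_direction(
    q_dom: float,
    q_rec: float,
    p_dom: float,
    p_rec: float,
    d_dom: float,
    d_rec: float,
    config: SignificanceConfig | None = None,
) -> str | None:
    """Risk/protective call from the Cohen's d of the significant model.

    Uses the d of whichever single-score model is FDR-significant; when both
    are, the one with the smaller p-value.  Risk iff that d is negative
    (cases carry more damage).  Returns None when neither model passes.
    """
    mode = classify_inheritance(q_dom, q_rec, config)
    if mode == "none":
        return None
    if mode == "dominant":
        d = d_dom
    elif mode == "recessive":
        d = d_rec
    else:
        d = d_dom if p_dom <= p_rec else d_rec
    return "risk" if d < 0 else "protective"


# ---------------------------------------------------------------------------
# fitting machinery


def _prepare_design(covariates: pd.DataFrame | None, n: int, index) -> pd.DataFrame:
    """Intercept + variance-standardized numeric covariates.

    Constant columns (e.g. sex in a sex-restricted cohort) are dropped, which
    mirrors excluding sex as a covariate when a phenotype is single-sex.
    """
    if covariates is None:
        return pd.DataFrame({"const": np.ones(n)}, index=index)
    X = covariates.astype(float).copy()
    keep = []
    for c in X.columns:
        sd = X[c].std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            continue
        X[c] = (X[c] - X[c].mean()) / sd
        keep.append(c)
    X = X[keep]
    X.insert(0, "const", 1.0)
    return X


def _fit_logit(y: np.ndarray, X: np.ndarray, start_params=None):
    """Fit a logistic regression, returning None on failure to converge.

    Newton from the supplied start is tried first; a singular Hessian or
    stalled iteration falls back to BFGS (which copes with the extreme
    leverage of near-constant score columns), then L-BFGS.
    """
    model = sm.Logit(y, X)
    attempts = (
        dict(method="newton", maxiter=100, start_params=start_params),
        dict(method="bfgs", maxiter=500),
        dict(method="lbfgs", maxiter=1000),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", HessianInversionWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        for kwargs in attempts:
            try:
                res = model.fit(disp=0, **kwargs)
            except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
                continue
            if res.mle_retvals.get("converged", False) and np.all(
                np.isfinite(res.params)
            ):
                return res
    return None


def _lrt_p(llf_alt: float, llf_null: float, df: int) -> float:
    llr = max(0.0, 2.0 * (llf_alt - llf_null))
    return float(stats.chi2.sf(llr, df)) if df > 0 else 1.0


@dataclass
class GeneTestResult:
    """Per-gene likelihood-ratio test summary for one phenotype."""

    p_dom: float = np.nan
    p_rec: float = np.nan
    p_comb: float = np.nan
    beta_dom: float = np.nan
    beta_rec: float = np.nan
    cohen_d_dom: float = np.nan
    cohen_d_rec: float = np.nan
    n_cases: int = 0
    n_controls: int = 0
    converged: bool = True
    degenerate: bool = False


def pwas_gene_test(
    s_dom,
    s_rec,
    covariates: pd.DataFrame | None,
    labels,
    models: Sequence[str] = MODELS,
    min_informative: int = 20,
    _null_fit=None,
    _design: pd.DataFrame | None = None,
) -> GeneTestResult:
    """Dominant / recessive / combined likelihood-ratio tests for one gene.

    Effect scores are variance-standardized before fitting (which leaves the
    LRT invariant but stabilises the optimiser).  A score column is testable
    only when at least ``min_informative`` individuals deviate from its
    modal value: with fewer, the chi-square reference for the LRT is not
    trustworthy (the same calibration rationale as a minor-allele-count
    gate in variant-level tests), so the column is dropped and the result
    flagged degenerate — a constant column being the extreme case, yielding
    p = 1 for the models that depend on it.  A non-converged fit yields a
    missing p, never a silent 0 or 1.

    ``_null_fit`` / ``_design`` let a caller that tests many genes against
    the same phenotype share the covariates-only null fit, which is
    identical across genes.
    """
    y = np.asarray(labels, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("labels contain missing values; subset before testing")
    res = GeneTestResult(
        n_cases=int((y == 1).sum()), n_controls=int((y == 0).sum())
    )

    X0 = _design if _design is not None else _prepare_design(
        covariates, len(y), getattr(labels, "index", None)
    )
    X0v = X0.to_numpy(dtype=float)

    null = _null_fit if _null_fit is not None else _fit_logit(y, X0v)
    if null is None:
        res.converged = False
        return res

    def standardize(s):
        s = np.asarray(s, dtype=float)
        sd = s.std()
        if sd == 0 or not np.isfinite(sd):
            return None
        _, counts = np.unique(s, return_counts=True)
        if len(s) - counts.max() < min_informative:
            return None
        return (s - s.mean()) / sd

    zd, zr = standardize(s_dom), standardize(s_rec)
    if zd is None or zr is None:
        res.degenerate = True

    if res.n_cases >= 2 and res.n_controls >= 2:
        res.cohen_d_dom = cohens_d(s_dom, y)
        res.cohen_d_rec = cohens_d(s_rec, y)

    def fit_with(cols: list[np.ndarray]) -> tuple[float, np.ndarray | None, int]:
        """LRT p vs null for the design extended with `cols` (rank-aware df)."""
        usable = [c for c in cols if c is not None]
        if not usable:
            return 1.0, None, 0
        added = np.column_stack(usable)
        df = int(np.linalg.matrix_rank(added - added.mean(axis=0)))
        if df < added.shape[1]:
            # collinear score columns: keep a full-rank subset
            keep, basis = [], []
            for i in range(added.shape[1]):
                trial = added[:, keep + [i]]
                if np.linalg.matrix_rank(trial - trial.mean(axis=0)) == len(keep) + 1:
                    keep.append(i)
            added = added[:, keep]
            df = added.shape[1]
        start = np.concatenate([null.params, np.zeros(added.shape[1])])
        fit = _fit_logit(y, np.column_stack([X0v, added]), start_params=start)
        if fit is None:
            return np.nan, None, df
        return _lrt_p(fit.llf, null.llf, df), fit.params[X0v.shape[1]:], df

    if "dominant" in models:
        p, params, _ = fit_with([zd])
        res.p_dom = p
        if params is not None and len(params):
            res.beta_dom = float(params[0])
        res.converged &= not (np.isnan(p) and zd is not None)
    if "recessive" in models:
        p, params, _ = fit_with([zr])
        res.p_rec = p
        if params is not None and len(params):
            res.beta_rec = float(params[0])
        res.converged &= not (np.isnan(p) and zr is not None)
    if "combined" in models:
        p, _, _ = fit_with([zd, zr])
        res.p_comb = p
        res.converged &= not (
            np.isnan(p) and not (zd is None and zr is None)
        )
    return res


@dataclass
class VariantTestResult:
    """Additive per-variant logistic test summary."""

    beta: float = np.nan
    se: float = np.nan
    p: float = np.nan
    maf: float = np.nan
    mac: float = 0.0
    tested: bool = False
    converged: bool = True


def gwas_variant_test(
    dosage,
    covariates: pd.DataFrame | None,
    labels,
    mac_min: int = 20,
    _null_design: pd.DataFrame | None = None,
) -> VariantTestResult:
    """Additive logistic regression of a binary phenotype on one variant.

    Variants with minor allele count below ``mac_min`` are skipped and
    marked untested ("at least ``mac_min`` occurrences" is inclusive).
    Reports the Wald p-value for the dosage coefficient, plus MAF and MAC.
    """
    y = np.asarray(labels, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("labels contain missing values; subset before testing")
    g = np.asarray(dosage, dtype=float)
    if np.any((g < 0) | (g > 2)):
        raise ValueError("dosages must lie in [0, 2]")

    ac = float(g.sum())
    n2 = 2.0 * len(g)
    mac = min(ac, n2 - ac)
    out = VariantTestResult(mac=mac, maf=mac / n2 if n2 else np.nan)
    if mac < mac_min:
        return out
    out.tested = True

    X0 = _null_design if _null_design is not None else _prepare_design(
        covariates, len(y), getattr(labels, "index", None)
    )
    X = np.column_stack([X0.to_numpy(dtype=float), g])
    fit = _fit_logit(y, X)
    if fit is None:
        out.converged = False
        return out
    out.beta = float(fit.params[-1])
    out.se = float(fit.bse[-1])
    out.p = float(fit.pvalues[-1])
    return out


# ---------------------------------------------------------------------------
# Model / Results objects


class PWASModel:
    """Gene-level association model for one binary phenotype.

    Parameters
    ----------
    labels
        Series of case/control status (1/0; NaN = not assessed, dropped).
    scores
        An :class:`~pwascan.scores.EffectScoreMatrix`, or a
        ``(dominant, recessive)`` pair of aligned individuals x genes
        DataFrames.
    covariates
        Optional individuals x covariates DataFrame; an intercept is added
        and numeric columns are variance-standardized.  Constant columns
        (e.g. sex under a sex-restricted phenotype) are dropped.
    models
        Which score models to fit; defaults to all three.

    Examples
    --------
    >>> model = PWASModel(labels, scores, covariates=covar)
    >>> results = model.fit()
    >>> results.significant()           # genes with q_comb < 0.05
    >>> print(results.summary())
    """

    def __init__(
        self,
        labels: pd.Series,
        scores,
        covariates: pd.DataFrame | None = None,
        phenotype: str = "phenotype",
        models: Sequence[str] = MODELS,
        min_informative: int = 20,
    ):
        if hasattr(scores, "dominant"):
            dom, rec = scores.dominant, scores.recessive
        else:
            dom, rec = scores
        bad = [m for m in models if m not in MODELS]
        if bad:
            raise ValueError(f"unknown models: {bad}")
        labels = pd.Series(labels)
        keep = labels.index[labels.notna()]
        self.labels = labels.loc[keep].astype(float)
        self.dominant = dom.loc[keep]
        self.recessive = rec.loc[keep]
        self.covariates = covariates.loc[keep] if covariates is not None else None
        self.phenotype = phenotype
        self.models = tuple(models)
        self.min_informative = int(min_informative)
        self.design = _prepare_design(self.covariates, len(keep), keep)

    @classmethod
    def from_scores(
        cls,
        scores,
        phenotypes: pd.DataFrame,
        phenotype: str,
        covariate_cols: Iterable[str] = (),
        **kwargs,
    ) -> "PWASModel":
        """Build from an effect-score matrix and a phenotype/covariate table."""
        common = scores.individuals.intersection(phenotypes.index)
        covar = phenotypes.loc[common, list(covariate_cols)] if covariate_cols else None
        from .scores import EffectScoreMatrix

        sub = EffectScoreMatrix(
            dominant=scores.dominant.loc[common],
            recessive=scores.recessive.loc[common],
            n_missing=scores.n_missing,
        )
        return cls(
            phenotypes.loc[common, phenotype],
            sub,
            covariates=covar,
            phenotype=phenotype,
            **kwargs,
        )

    def fit(self, config: SignificanceConfig | None = None) -> "PWASResults":
        config = config or SignificanceConfig()
        y = self.labels.to_numpy()
        null = _fit_logit(y, self.design.to_numpy(dtype=float))
        rows = []
        for gene in self.dominant.columns:
            r = pwas_gene_test(
                self.dominant[gene].to_numpy(),
                self.recessive[gene].to_numpy(),
                None,
                self.labels,
                models=self.models,
                min_informative=self.min_informative,
                _null_fit=null,
                _design=self.design,
            )
            rows.append(
                {
                    "gene_id": gene,
                    "phenotype": self.phenotype,
                    "p_dom": r.p_dom,
                    "p_rec": r.p_rec,
                    "p_comb": r.p_comb,
                    "beta_dom": r.beta_dom,
                    "beta_rec": r.beta_rec,
                    "cohen_d_dom": r.cohen_d_dom,
                    "cohen_d_rec": r.cohen_d_rec,
                    "n_cases": r.n_cases,
                    "n_controls": r.n_controls,
                    "converged": r.converged,
                    "degenerate": r.degenerate,
                }
            )
        columns = [
            "gene_id", "phenotype", "p_dom", "p_rec", "p_comb", "beta_dom",
            "beta_rec", "cohen_d_dom", "cohen_d_rec", "n_cases", "n_controls",
            "converged", "degenerate",
        ]
        table = pd.DataFrame(rows, columns=columns)
        for m, col in (("dom", "p_dom"), ("rec", "p_rec"), ("comb", "p_comb")):
            table[f"q_{m}"] = bh_fdr(table[col]) if len(table) else np.nan
        table["inheritance"] = [
            classify_inheritance(qd, qr, config)
            for qd, qr in zip(table.get("q_dom", []), table.get("q_rec", []))
        ]
        table["direction"] = [
            classify_direction(
                row.q_dom, row.q_rec, row.p_dom, row.p_rec,
                row.cohen_d_dom, row.cohen_d_rec, config,
            )
            for row in table.itertuples()
        ]
        return PWASResults(table=table, config=config, phenotype=self.phenotype)


@dataclass
class PWASResults:
    """Fitted gene-level association results for one phenotype."""

    table: pd.DataFrame
    config: SignificanceConfig
    phenotype: str

    def significant(self, model: str = "comb") -> pd.DataFrame:
        q = self.table[f"q_{model}"]
        return self.table[q.notna() & (q < self.config.pwas_q_threshold)]

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("p_comb")
        lines = [
            f"PWAS gene-level results: phenotype={self.phenotype!r}",
            f"  genes tested: {len(t)}   "
            f"cases: {t.n_cases.max() if len(t) else 0}   "
            f"controls: {t.n_controls.max() if len(t) else 0}",
            f"  FDR-significant (combined, q<{self.config.pwas_q_threshold}): "
            f"{len(self.significant())}",
            "",
            t.head(top)[
                ["gene_id", "p_dom", "p_rec", "p_comb", "q_comb",
                 "cohen_d_dom", "cohen_d_rec", "inheritance", "direction"]
            ].to_string(index=False),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


class GWASModel:
    """Per-variant additive association model for one binary phenotype.

    Fits ``logit(P(case)) ~ dosage + covariates`` for every variant whose
    minor allele count reaches ``config.mac_min``.
    """

    def __init__(
        self,
        labels: pd.Series,
        dosages: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        phenotype: str = "phenotype",
    ):
        labels = pd.Series(labels)
        keep = labels.index[labels.notna()]
        self.labels = labels.loc[keep].astype(float)
        self.dosages = dosages.loc[keep]
        self.covariates = covariates.loc[keep] if covariates is not None else None
        self.phenotype = phenotype
        self.design = _prepare_design(self.covariates, len(keep), keep)

    def fit(self, config: SignificanceConfig | None = None) -> "GWASResults":
        config = config or SignificanceConfig()
        rows = []
        for v in self.dosages.columns:
            r = gwas_variant_test(
                self.dosages[v].to_numpy(),
                None,
                self.labels,
                mac_min=config.mac_min,
                _null_design=self.design,
            )
            rows.append(
                {
                    "variant_id": v,
                    "phenotype": self.phenotype,
                    "beta": r.beta,
                    "se": r.se,
                    "p": r.p,
                    "maf": r.maf,
                    "mac": r.mac,
                    "tested": r.tested,
                    "converged": r.converged,
                }
            )
        return GWASResults(
            table=pd.DataFrame(rows), config=config, phenotype=self.phenotype
        )


@dataclass
class GWASResults:
    """Fitted per-variant association results for one phenotype."""

    table: pd.DataFrame
    config: SignificanceConfig
    phenotype: str

    def significant(self) -> pd.DataFrame:
        t = self.table
        return t[t.tested & t.p.notna() & (t.p < self.config.gwas_p_threshold)]

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("p")
        return "\n".join(
            [
                f"GWAS variant-level results: phenotype={self.phenotype!r}",
                f"  variants: {len(t)}   tested (MAC>={self.config.mac_min}): "
                f"{int(t.tested.sum())}   significant "
                f"(p<{self.config.gwas_p_threshold:g}): {len(self.significant())}",
                "",
                t.head(top)[
                    ["variant_id", "beta", "se", "p", "maf", "mac", "tested"]
                ].to_string(index=False),
            ]
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
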