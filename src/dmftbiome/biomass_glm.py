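"""Per-DMFT-category quasi-Poisson models of microbial biomass.

The outcome is a per-sample abundance aggregate (default: total counts,
a biomass proxy); covariates are the clinical attributes plus
family-level relative abundances. Quasi-Poisson means a Poisson log-link
mean model with a freely estimated dispersion phi = Pearson chi^2 /
(n - p): coefficients equal the Poisson ML fit, standard errors scale by
sqrt(phi), and Wald tests use the t reference (matching R's
``glm(..., family = quasipoisson)`` summary). One model is fitted per
DMFT category with an identical covariate set, and the per-category
coefficient tables are aligned for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .feature_table import CATEGORY_ORDER, FeatureTable, SampleMetadata

CLINICAL_COVARIATES = ("sex_male", "hiv_positive", "periodontitis")


@dataclass(frozen=True)
class GlmFit:
    """A fitted quasi-Poisson regression.

    ``dispersion`` is reported even when it is ~1 (equidispersion);
    standard errors are the Poisson ones scaled by sqrt(dispersion).
    """

    coefficients: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    dispersion: float
    deviance: float
    n_obs: int
    converged: bool

    def significant(self, alpha: float = 0.05) -> pd.Series:
        return self.p_values <= alpha


def fit_quasipoisson(
    y,
    design_matrix: pd.DataFrame,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GlmFit:
    """Fit a log-link count regression with free dispersion by IRLS.

    The design matrix must be full rank (aliased columns are named in the
    error) and must include the intercept column if one is wanted.
    Non-convergence is flagged on the result, not raised.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("outcome counts must be non-negative")
    X = pd.DataFrame(design_matrix).astype(float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # name columns whose removal restores full rank
        aliased = []
        base = X.to_numpy()
        for j, col in reversed(list(enumerate(X.columns))):
            reduced = np.delete(base, [X.columns.get_loc(c) for c in aliased] + [j], axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                aliased.append(col)
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=max_iter, tol=tol)
    # quasi-Poisson: same mean fit, Pearson-based dispersion, t reference
    df_resid = n - p
    phi = float(res.pearson_chi2) / df_resid
    se = np.asarray(res.bse) * np.sqrt(phi)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.asarray(res.params) / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    return GlmFit(
        coefficients=pd.Series(res.params, index=X.columns),
        standard_errors=pd.Series(se, index=X.columns),
        p_values=pd.Series(pvals, index=X.columns),
        dispersion=phi,
        deviance=float(res.deviance),
        n_obs=int(n),
        converged=bool(getattr(res, "converged", True)),
    )


@dataclass(frozen=True)
class ModelComparison:
    """Aligned per-category quasi-Poisson fits."""

    fits: Mapping[str, GlmFit]
    covariates: tuple[str, ...]
    skipped: tuple[str, ...] = field(default_factory=tuple)

    def table(self, alpha: float = 0.05, bh_correct: bool = False) -> pd.DataFrame:
        """Coefficients with per-cell significance stars across categories."""
        rows = {}
        pmat = pd.DataFrame(
            {cat: fit.p_values for cat, fit in self.fits.items()}
        )
        if bh_correct:
            from .cooccurrence import bh_fdr

            vals = pmat.to_numpy()
            mask = ~np.isnan(vals)
            adj = vals.copy()
            adj[mask] = bh_fdr(vals[mask])
            pmat = pd.DataFrame(adj, index=pmat.index, columns=pmat.columns)
        for cat, fit in self.fits.items():
            stars = pmat[cat] <= alpha
            rows[cat] = pd.Series(
                {
                    cov: f"{fit.coefficients[cov]:.4f}{'*' if stars[cov] else ''}"
                    for cov in fit.coefficients.index
                }
            )
        return pd.DataFrame(rows)


def _clinical_design(meta: SampleMetadata, sample_ids: Sequence[str]) -> pd.DataFrame:
    df = meta.data.loc[list(sample_ids)]
    out = pd.DataFrame(index=df.index)
    out["intercept"] = 1.0
    out["sex_male"] = (df["sex"] == "male").astype(float)
    out["hiv_positive"] = (df["hiv_status"] == "positive").astype(float)
    out["periodontitis"] = (df["periodontal_status"] == "periodontitis").astype(float)
    return out


def per_category_models(
    table: FeatureTable,
    metadata: SampleMetadata,
    family_table: Optional[FeatureTable] = None,
    families: Optional[Sequence[str]] = None,
    outcome_spec: str = "total",
    alpha: float = 0.05,
) -> ModelComparison:
    """Fit one quasi-Poisson biomass model per DMFT category.

    Outcome: per-sample total counts (``outcome_spec='total'``, the
    biomass proxy). Covariates: sex, HIV status, periodontal status, and
    the relative abundances of the requested families (all but the last
    family when ``families`` is None — one must be dropped since the
    fractions sum to one). Categories with too few samples are skipped
    with a warning.
    """
    if outcome_spec != "total":
        raise ValueError("only outcome_spec='total' is implemented")
    fam_cols: list[str] = []
    fam_rel = None
    if family_table is not None:
        if families is None:
            families = list(family_table.taxon_ids[:-1])
        missing = set(families) - set(family_table.taxon_ids)
        if missing:
            raise KeyError(f"families not in family table: {sorted(missing)}")
        fam_rel = pd.DataFrame(
            family_table.relative_abundance(),
            index=list(family_table.sample_ids),
            columns=list(family_table.taxon_ids),
        )[list(families)]
        fam_cols = [f"fam_{f}" for f in families]
        fam_rel.columns = fam_cols

    fits: dict[str, GlmFit] = {}
    skipped: list[str] = []
    covariates = ("intercept",) + CLINICAL_COVARIATES + tuple(fam_cols)
    for cat in CATEGORY_ORDER:
        sids = [s for s in metadata.samples_in_category(cat) if s in set(table.sample_ids)]
        p = len(covariates)
        if len(sids) <= p:
            warnings.warn(
                f"category {cat.value!r}: n={len(sids)} <= p={p}; model skipped"
            )
            skipped.append(cat.value)
            continue
        sub = table.select_samples(sids)
        y = sub.depths()
        X = _clinical_design(metadata, sub.sample_ids)
        if fam_rel is not None:
            X = X.join(fam_rel.loc[list(sub.sample_ids)])
        # drop covariates aliased within this category (constant, or exactly
        # collinear with earlier columns — easy at small n with binary
        # covariates); they show up as NaN in the comparison table
        keep: list[str] = []
        for c in X.columns:
            trial = X[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(c)
            else:
                warnings.warn(f"category {cat.value!r}: covariate {c!r} aliased; dropped")
        fit = fit_quasipoisson(y, X[keep])
        coeffs = fit.coefficients.reindex(covariates)
        fits[cat.value] = GlmFit(
            coefficients=coeffs,
            standard_errors=fit.standard_errors.reindex(covariates),
            p_values=fit.p_values.reindex(covariates),
            dispersion=fit.dispersion,
            deviance=fit.deviance,
            n_obs=fit.n_obs,
            converged=fit.converged,
        )
    if len(fits) < 2:
        raise ValueError("need at least 2 categories with enough samples")
    return ModelComparison(fits=fits, covariates=covariates, skipped=tuple(skipped))
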