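"""Covariate screening and per-variant additive linear association.

Each variant is tested by ordinary least squares of the continuous pain
outcome (NRS at 6-12 months) on the additive-coded genotype plus the
covariates retained by univariate screening at p < 0.1.  Major
homozygotes are coded 0, heterozygotes 1, minor homozygotes 2.
Individuals missing the genotype at a variant are excluded for that
variant only.  The per-variant scan uses the Frisch-Waugh projection
(residualize outcome and genotype on the covariate design, then simple
regression), which is algebraically identical to the full OLS fit.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix, validate_phenotypes

#: Default pool of non-genetic covariates offered to the screen.
DEFAULT_COVARIATE_CANDIDATES = (
    "casi",
    "preop_pain",
    "sex",
    "race",
    "age",
    "weight",
    "surgical_duration",
    "levels_fused",
    "propofol",
    "remifentanil",
    "auc_pod12",
    "morphine_meq",
)

MIN_COMPLETE_CASES = 10


def additive_code(call, major: str, minor: str) -> int:
    """Minor-allele count of one biallelic call.

    ``call`` may be an "A/G"-style string or a pair of allele strings.
    """
    if isinstance(call, str):
        sep = "/" if "/" in call else "|"
        alleles = call.split(sep)
    else:
        alleles = list(call)
    if len(alleles) != 2:
        raise ValueError(f"not a biallelic call: {call!r}")
    count = 0
    for a in alleles:
        if a == minor:
            count += 1
        elif a != major:
            raise ValueError(f"allele {a!r} is neither major {major!r} nor minor {minor!r}")
    return count


def _design_columns(phenotypes: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design for the covariates (dummy-coded categoricals)."""
    cols = {}
    for c in covariates:
        s = phenotypes[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            for name in dummies.columns:
                cols[name] = dummies[name]
        else:
            cols[c] = s.astype(float)
    return pd.DataFrame(cols, index=phenotypes.index)


def screen_covariates(
    phenotypes: pd.DataFrame,
    candidate_covariates=DEFAULT_COVARIATE_CANDIDATES,
    outcome: str = "nrs_6_12mo",
    p_threshold: float = 0.1,
) -> list:
    """Univariate screen: retain covariates with model p < threshold (strict).

    Each candidate is fit alone against the continuous outcome; the
    overall F p-value of that univariate model is the retention
    criterion (identical to the Wald t p for a single numeric column).
    Constant covariates are dropped with a warning.
    """
    import statsmodels.api as sm

    phen = validate_phenotypes(phenotypes)
    retained = []
    for c in candidate_covariates:
        if c not in phen.columns:
            raise KeyError(f"covariate {c!r} not in phenotype table")
        sub = phen[[outcome, c]].dropna()
        x = _design_columns(sub, [c])
        if x.shape[1] == 0 or (x.nunique() <= 1).all():
            warnings.warn(f"covariate {c!r} is constant; dropped", stacklevel=2)
            continue
        res = sm.OLS(sub[outcome].astype(float), sm.add_constant(x)).fit()
        if np.isfinite(res.f_pvalue) and res.f_pvalue < p_threshold:
            retained.append(c)
    return retained


def snp_association(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    covariates=(),
    outcome: str = "nrs_6_12mo",
) -> pd.DataFrame:
    """Per-variant covariate-adjusted additive OLS scan.

    Returns a DataFrame with columns ``variant_id, beta, se, p_value,
    n_used, untestable``.  Variants with zero genotype variance among
    complete cases (or fewer than 10 complete cases) are flagged
    untestable with beta 0 and p 1.
    """
    phen = validate_phenotypes(phenotypes).set_index("individual_id")
    phen = phen.loc[[s for s in genotypes.individual_ids if s in phen.index]]
    if len(phen) != genotypes.n_individuals:
        missing = set(genotypes.individual_ids) - set(phen.index)
        raise ValueError(f"phenotypes missing for individuals: {sorted(missing)[:5]}")

    x_cov = _design_columns(phen, covariates)
    base = phen[outcome].notna().to_numpy()
    if len(covariates):
        base &= x_cov.notna().all(axis=1).to_numpy()
    y_all = phen[outcome].to_numpy(dtype=float)
    z_all = np.column_stack([np.ones(len(phen))] + [x_cov[c].to_numpy(dtype=float) for c in x_cov])

    rows_base = np.flatnonzero(base)
    y = y_all[rows_base]
    z = z_all[rows_base]
    p = z.shape[1]
    m = genotypes.n_variants

    g = genotypes.calls[rows_base, :].astype(float)
    w = g == MISSING  # per-variant excluded rows
    g0 = np.where(w, 0.0, g)

    # Per-variant OLS of y on [Z, g_j] over that variant's complete cases,
    # via full-data cross-products downdated by the missing rows (exact).
    ztz = z.T @ z
    zty = z.T @ y
    yty = float(y @ y)
    wf = w.astype(float)
    ztz_j = ztz[None, :, :] - np.einsum("ij,ip,iq->jpq", wf, z, z)
    zty_j = zty[None, :] - (wf * y[:, None]).T @ z
    ztg = z.T @ g0  # p x m; zeros at missing rows drop out of the sums
    gtg = np.einsum("ij,ij->j", g0, g0)
    gty = g0.T @ y
    yty_j = yty - wf.T @ (y * y)
    n_j = len(y) - wf.sum(axis=0)

    a = np.empty((m, p + 1, p + 1))
    a[:, :p, :p] = ztz_j
    a[:, :p, p] = ztg.T
    a[:, p, :p] = ztg.T
    a[:, p, p] = gtg
    b = np.empty((m, p + 1))
    b[:, :p] = zty_j
    b[:, p] = gty

    # zero genotype variance among complete cases -> untestable
    g_mean = np.divide(g0.sum(axis=0), n_j, out=np.zeros(m), where=n_j > 0)
    g_var = gtg - n_j * g_mean**2
    df = n_j - (p + 1)
    untestable = (g_var <= 1e-10) | (n_j < MIN_COMPLETE_CASES) | (df <= 0)
    scale = np.prod(np.maximum(np.diagonal(a, axis1=1, axis2=2), 1e-12), axis=1)
    untestable |= np.abs(np.linalg.det(a)) < 1e-9 * scale

    a[untestable] = np.eye(p + 1)[None, :, :]
    coef = np.linalg.solve(a, b[:, :, None])[:, :, 0]
    a_inv = np.linalg.inv(a)
    sse = np.maximum(yty_j - np.einsum("jk,jk->j", coef, b), 0.0)
    df_safe = np.maximum(df, 1)
    sigma2 = sse / df_safe
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sigma2 * a_inv[:, p, p])
        tstat = coef[:, p] / se
        pval = 2 * stats.t.sf(np.abs(tstat), df_safe)

    beta = np.where(untestable, 0.0, coef[:, p])
    se = np.where(untestable | ~np.isfinite(se), np.inf, se)
    pval = np.where(untestable | ~np.isfinite(pval), 1.0, pval)
    return pd.DataFrame(
        {
            "variant_id": genotypes.variant_ids,
            "beta": beta,
            "se": se,
            "p_value": pval,
            "n_used": n_j.astype(int),
            "untestable": untestable,
        }
    )
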