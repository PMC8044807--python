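"""Design power calculations for enrichment and PRS studies.

Three calculations cover the study design questions: (1) a one-sided
two-sample proportion comparison (rate of nominally associated variants
in a selected set vs the chance rate), (2) a two-sample mean comparison
on the PRS scale, and (3) Monte-Carlo power of the single-variant
additive case-control association test at a given per-allele odds ratio
and minor-allele frequency.

The closed forms use the normal approximation with the variance pooled
under the null and unpooled under the alternative, no continuity
correction.
"""
from __future__ import annotations

import numpy as np
from scipy import stats


def power_two_proportions(
    p0: float,
    p1: float,
    n_per_group: int,
    alpha: float = 0.05,
    one_sided: bool = True,
) -> float:
    """Normal-approximation power of a two-sample proportion test.

    Null variance uses the pooled proportion; alternative variance is
    unpooled.  ``p0 == p1`` returns alpha.
    """
    for p in (p0, p1):
        if not 0 < p < 1:
            raise ValueError("proportions must lie strictly in (0, 1)")
    if n_per_group <= 0:
        raise ValueError("n_per_group must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    pbar = 0.5 * (p0 + p1)
    se0 = np.sqrt(2 * pbar * (1 - pbar) / n_per_group)
    se1 = np.sqrt(p0 * (1 - p0) / n_per_group + p1 * (1 - p1) / n_per_group)
    diff = abs(p1 - p0)
    if one_sided:
        z_crit = stats.norm.ppf(1 - alpha)
        return float(stats.norm.cdf((diff - z_crit * se0) / se1))
    z_crit = stats.norm.ppf(1 - alpha / 2)
    upper = stats.norm.cdf((diff - z_crit * se0) / se1)
    lower = stats.norm.cdf((-diff - z_crit * se0) / se1)
    return float(upper + lower)


def proportion_or(p0: float, p1: float) -> float:
    """Odds ratio between two proportions."""
    for p in (p0, p1):
        if not 0 < p < 1:
            raise ValueError("proportions must lie strictly in (0, 1)")
    return float((p1 / (1 - p1)) / (p0 / (1 - p0)))


def power_two_means(
    diff: float, sd: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Two-sided normal-approximation power for a mean difference.

    Common standard deviation ``sd`` in both groups; ``diff == 0``
    returns alpha.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    se = sd * np.sqrt(1.0 / n1 + 1.0 / n2)
    z = abs(diff) / se
    z_crit = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(z - z_crit) + stats.norm.cdf(-z - z_crit))


def _logistic_wald_p(n_case_by_g: np.ndarray, n_ctrl_by_g: np.ndarray) -> np.ndarray:
    """Vectorized Wald p for logit(case) ~ genotype on aggregated counts.

    Rows are replicates; columns genotype values 0/1/2.  Newton-Raphson
    on the two-parameter logistic likelihood with genotype as the only
    regressor; degenerate replicates (no genotype spread) get p = 1.
    """
    xs = np.array([0.0, 1.0, 2.0])
    n_tot = n_case_by_g + n_ctrl_by_g
    r = n_case_by_g.shape[0]
    a = np.zeros(r)
    b = np.zeros(r)
    ok = np.ones(r, dtype=bool)
    for _ in range(60):
        eta = a[:, None] + b[:, None] * xs[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n_tot * mu * (1 - mu)
        g0 = (n_case_by_g - n_tot * mu).sum(axis=1)
        g1 = ((n_case_by_g - n_tot * mu) * xs).sum(axis=1)
        s0 = w.sum(axis=1)
        s1 = (w * xs).sum(axis=1)
        s2 = (w * xs * xs).sum(axis=1)
        det = s0 * s2 - s1 * s1
        ok &= det > 1e-10
        det_safe = np.where(ok, det, 1.0)
        da = (s2 * g0 - s1 * g1) / det_safe
        db = (s0 * g1 - s1 * g0) / det_safe
        da = np.clip(da, -5, 5)
        db = np.clip(db, -5, 5)
        a = np.where(ok, a + da, a)
        b = np.where(ok, b + db, b)
        if np.max(np.abs(np.concatenate([da[ok], db[ok]])) if ok.any() else 0.0) < 1e-10:
            break
    eta = a[:, None] + b[:, None] * xs[None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = n_tot * mu * (1 - mu)
    s0 = w.sum(axis=1)
    s1 = (w * xs).sum(axis=1)
    s2 = (w * xs * xs).sum(axis=1)
    det = s0 * s2 - s1 * s1
    ok &= det > 1e-10
    var_b = np.where(ok, s0 / np.where(det > 0, det, 1.0), np.inf)
    z = np.where(ok, b / np.sqrt(var_b), 0.0)
    return 2 * stats.norm.sf(np.abs(z))


def power_variant_or(
    or_: float,
    maf: float,
    n_case: int = 53,
    n_control: int = 78,
    alpha: float = 0.05,
    n_reps: int = 5000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the additive single-variant case-control test.

    Controls draw Hardy-Weinberg genotypes at ``maf``; cases draw from
    the allele frequency whose odds are ``or_`` times the control allele
    odds (the per-allele odds-ratio shift).  Each replicate is tested by
    an additive logistic Wald test at ``alpha``; the rejection fraction
    is returned.  Default case/control split is 53/78.
    """
    if or_ <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    if n_case <= 0 or n_control <= 0:
        raise ValueError("group sizes must be positive")
    p0 = maf
    odds1 = or_ * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    rng = np.random.default_rng(seed)
    # HWE genotype = Binomial(2, allele frequency); aggregate by genotype value
    g_case = rng.binomial(2, p1, size=(n_reps, n_case))
    g_ctrl = rng.binomial(2, p0, size=(n_reps, n_control))
    case_counts = np.stack([(g_case == k).sum(axis=1) for k in range(3)], axis=1)
    ctrl_counts = np.stack([(g_ctrl == k).sum(axis=1) for k in range(3)], axis=1)
    pvals = _logistic_wald_p(case_counts.astype(float), ctrl_counts.astype(float))
    return float((pvals < alpha).mean())
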