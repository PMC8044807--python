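"""Logistic prediction models, ROC/AUC comparison and bootstrap validation.

The clinical (non-genetic) model is built by forward-stepwise logistic
regression over the screened covariates at p < 0.05; the genetic model
adds the weighted PRS.  Model discrimination is the rank-based AUC with
DeLong asymptotic confidence intervals, and paired model comparison uses
the DeLong test for correlated ROC curves.  Internal validation follows
the standard bootstrap recipe: refit the fixed final model on resamples
drawn with replacement, report per-term bias (bootstrap mean minus
original), the bias-corrected coefficient (original minus bias) and
percentile confidence intervals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class PerfectSeparationError(RuntimeError):
    """Logistic fit failed because the outcome is perfectly separated."""


# --------------------------------------------------------------------------
# DeLong machinery
# --------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    mid = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        mid[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = mid
    return out


def _delong_auc_cov(y: np.ndarray, scores: np.ndarray) -> tuple:
    """AUCs and DeLong covariance matrix for k score vectors.

    ``scores`` is (k, n); ``y`` binary with both classes present.
    """
    y = np.asarray(y).astype(int)
    pos = scores[:, y == 1]
    neg = scores[:, y == 0]
    m, n = pos.shape[1], neg.shape[1]
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    k = scores.shape[0]
    aucs = np.empty(k)
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    for r in range(k):
        both = np.concatenate([pos[r], neg[r]])
        tz = _midranks(both)
        tx = _midranks(pos[r])
        ty = _midranks(neg[r])
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    cov = s01 / m + s10 / n
    return aucs, np.atleast_2d(cov)


def roc_auc(scores, outcomes, alpha: float = 0.05) -> tuple:
    """Rank-based AUC with a DeLong asymptotic confidence interval.

    Equivalent to the Mann-Whitney statistic: the fraction of
    case-control pairs ordered correctly, ties counting one half.
    """
    scores = np.asarray(scores, float)
    aucs, cov = _delong_auc_cov(np.asarray(outcomes), scores[None, :])
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    lo = max(0.0, aucs[0] - z * se)
    hi = min(1.0, aucs[0] + z * se)
    return float(aucs[0]), (lo, hi)


def delong_test(outcomes, scores_a, scores_b) -> tuple:
    """Paired DeLong test; returns (auc_a - auc_b, p_value)."""
    scores = np.vstack([np.asarray(scores_a, float), np.asarray(scores_b, float)])
    aucs, cov = _delong_auc_cov(np.asarray(outcomes), scores)
    diff = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var <= 0:
        return diff, 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return diff, float(2 * stats.norm.sf(abs(z)))


def compare_auc(fit_a, fit_b, paired: bool = True) -> float:
    """p-value for the difference of two models' correlated AUCs.

    ``fit_a``/``fit_b`` are :class:`PredictionResults` on the same
    individuals (paired mode, the only implemented mode).
    """
    if not paired:
        raise NotImplementedError("only the paired (same-cohort) comparison is implemented")
    ids_a = list(fit_a.data["individual_id"]) if "individual_id" in fit_a.data else list(fit_a.data.index)
    ids_b = list(fit_b.data["individual_id"]) if "individual_id" in fit_b.data else list(fit_b.data.index)
    if ids_a != ids_b:
        raise ValueError("paired AUC comparison requires the same individuals in the same order")
    _, p = delong_test(fit_a.y, fit_a.fitted_probabilities, fit_b.fitted_probabilities)
    return p


# --------------------------------------------------------------------------
# Model / Results
# --------------------------------------------------------------------------

def _build_design(data: pd.DataFrame, terms) -> pd.DataFrame:
    cols = {}
    for t in terms:
        s = data[t]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=t, drop_first=True, dtype=float)
            for name in dummies.columns:
                cols[name] = dummies[name]
        else:
            cols[t] = s.astype(float)
    return pd.DataFrame(cols, index=data.index)


def _fit_logit(y: np.ndarray, x: pd.DataFrame):
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError as SmSepError

    design = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (SmSepError, np.linalg.LinAlgError, RuntimeWarning) as exc:
        raise PerfectSeparationError(
            f"logistic fit failed for terms {list(x.columns)}: {exc}"
        ) from exc
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 1e3:
        raise PerfectSeparationError(
            f"logistic fit did not converge for terms {list(x.columns)}; "
            "outcome may be (quasi-)separated"
        )
    return res


class CpspPredictionModel:
    """Logistic prediction model for the dichotomous pain outcome.

    statsmodels-style: construct from a phenotype DataFrame, then
    ``fit(terms)`` or ``fit_stepwise(candidates)`` returns a
    :class:`PredictionResults`.
    """

    def __init__(self, data: pd.DataFrame, outcome: str = "cpsp"):
        if outcome not in data.columns:
            raise ValueError(f"outcome column {outcome!r} missing")
        self.data = data.reset_index(drop=True)
        self.outcome = outcome
        y = self.data[outcome].astype(int).to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError("binary outcome must have both classes present")
        self.y = y

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str = "cpsp"):
        return cls(data, outcome=outcome)

    def fit(self, terms) -> "PredictionResults":
        terms = list(terms)
        x = _build_design(self.data, terms)
        res = _fit_logit(self.y, x)
        return PredictionResults(self, terms, x, res)

    def fit_stepwise(self, candidate_terms, entry_p: float = 0.05) -> "PredictionResults":
        """Forward-stepwise entry/retention at p < entry_p (Wald).

        Terms enter one at a time (best p first, if below the
        threshold); after each entry, any included term whose p rises to
        or above the threshold is dropped.  With no qualifying term the
        intercept-only model is returned.
        """
        included: list = []
        remaining = list(candidate_terms)
        while True:
            best_term, best_p = None, entry_p
            for t in remaining:
                try:
                    fit = self.fit(included + [t])
                except PerfectSeparationError:
                    continue
                p = fit.term_pvalue(t)
                if p < best_p:
                    best_term, best_p = t, p
            if best_term is None:
                break
            included.append(best_term)
            remaining.remove(best_term)
            # backward pass: retention at the same threshold
            changed = True
            while changed and len(included) > 1:
                changed = False
                fit = self.fit(included)
                worst = max(included, key=fit.term_pvalue)
                if fit.term_pvalue(worst) >= entry_p:
                    included.remove(worst)
                    remaining.append(worst)
                    changed = True
        return self.fit(included)


class PredictionResults:
    """Fitted logistic model: coefficients, ORs, AUC, bootstrap, curves."""

    def __init__(self, model: CpspPredictionModel, terms, design: pd.DataFrame, res):
        self.model = model
        self.terms = list(terms)
        self.design = design
        self._res = res
        self.data = model.data
        self.y = model.y

    # -- coefficient table -------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    @property
    def intercept(self) -> float:
        return float(self._res.params["const"])

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self._res.params.drop("const"))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self._res.conf_int(alpha)

    def term_pvalue(self, term: str) -> float:
        """Wald p for a term; multi-column (categorical) terms use an LR test."""
        cols = [c for c in self.design.columns if c == term or c.startswith(term + "_")]
        if not cols:
            raise KeyError(term)
        if len(cols) == 1:
            return float(self._res.pvalues[cols[0]])
        reduced_terms = [t for t in self.terms if t != term]
        reduced = self.model.fit(reduced_terms) if reduced_terms else None
        llr = 2 * (self._res.llf - (reduced._res.llf if reduced else self._res.llnull))
        return float(stats.chi2.sf(llr, df=len(cols)))

    # -- discrimination ----------------------------------------------------
    @property
    def fitted_probabilities(self) -> np.ndarray:
        return np.asarray(self._res.predict())

    @property
    def auc(self) -> float:
        return roc_auc(self.fitted_probabilities, self.y)[0]

    @property
    def auc_ci(self) -> tuple:
        return roc_auc(self.fitted_probabilities, self.y)[1]

    def roc_curve(self) -> pd.DataFrame:
        from sklearn.metrics import roc_curve as _sk_roc

        fpr, tpr, thr = _sk_roc(self.y, self.fitted_probabilities)
        return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        x = _build_design(data, self.terms)
        x = x.reindex(columns=self.design.columns, fill_value=0.0)
        import statsmodels.api as sm

        return np.asarray(self._res.predict(sm.add_constant(x, has_constant="add")))

    # -- reporting ---------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        rows = []
        for name in self._res.params.index:
            beta = float(self._res.params[name])
            rows.append(
                {
                    "term": name,
                    "beta": beta,
                    "se": float(self._res.bse[name]),
                    "or": np.exp(beta) if name != "const" else np.nan,
                    "or_ci_low": np.exp(ci.loc[name, 0]) if name != "const" else np.nan,
                    "or_ci_high": np.exp(ci.loc[name, 1]) if name != "const" else np.nan,
                    "p_value": float(self._res.pvalues[name]),
                }
            )
        out = pd.DataFrame(rows)
        out.attrs["auc"] = self.auc
        out.attrs["auc_ci"] = self.auc_ci
        out.attrs["n"] = len(self.y)
        return out

    # -- extensions --------------------------------------------------------
    def bootstrap(self, n_boot: int = 1000, seed: int = 0) -> "BootstrapSummary":
        return bootstrap_validate(
            self.data, self.terms, outcome=self.model.outcome, n_boot=n_boot, seed=seed
        )

    def probability_curve(self, term: str, grid, fixed: dict | None = None) -> tuple:
        return probability_curve(self, term, grid, fixed or {})


def fit_stepwise_logistic(
    phenotypes: pd.DataFrame,
    candidate_terms,
    entry_p: float = 0.05,
    outcome: str = "cpsp",
) -> PredictionResults:
    """Functional wrapper over :meth:`CpspPredictionModel.fit_stepwise`."""
    return CpspPredictionModel(phenotypes, outcome=outcome).fit_stepwise(
        candidate_terms, entry_p=entry_p
    )


# --------------------------------------------------------------------------
# Bootstrap internal validation
# --------------------------------------------------------------------------

@dataclass
class BootstrapSummary:
    """Per-term bootstrap bias and percentile intervals.

    ``table`` columns: original beta, bootstrap mean, bias (= bootstrap
    mean - original), bias-corrected beta (= original - bias, exact by
    construction), percentile 95% CI and OR equivalents.
    """

    table: pd.DataFrame
    n_boot: int
    seed: int
    n_redraws: int


def bootstrap_validate(
    phenotypes: pd.DataFrame,
    model_terms,
    outcome: str = "cpsp",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapSummary:
    """Refit the fixed final model on ``n_boot`` with-replacement resamples.

    Resamples with a single outcome class (or a separated fit) are
    redrawn so the number of bootstrap fits stays at ``n_boot``; more
    than 10% redraws triggers a warning.
    """
    model = CpspPredictionModel(phenotypes, outcome=outcome)
    original = model.fit(model_terms)
    names = list(original.params.index)
    rng = np.random.default_rng(seed)
    n = len(model.y)

    draws = np.empty((n_boot, len(names)))
    n_redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(model.y[idx])) < 2:
            n_redraws += 1
            continue
        resample = model.data.iloc[idx].reset_index(drop=True)
        try:
            x = _build_design(resample, original.terms).reindex(
                columns=original.design.columns, fill_value=0.0
            )
            res = _fit_logit(model.y[idx], x)
        except PerfectSeparationError:
            n_redraws += 1
            continue
        draws[b] = res.params.reindex(names).to_numpy()
        b += 1
    if n_redraws > 0.10 * n_boot:
        warnings.warn(
            f"{n_redraws} bootstrap resamples redrawn (> 10% of {n_boot})",
            stacklevel=2,
        )

    boot_mean = draws.mean(axis=0)
    orig = original.params.reindex(names).to_numpy()
    bias = boot_mean - orig
    corrected = orig - bias
    lo = np.quantile(draws, alpha / 2, axis=0)
    hi = np.quantile(draws, 1 - alpha / 2, axis=0)
    table = pd.DataFrame(
        {
            "term": names,
            "original": orig,
            "boot_mean": boot_mean,
            "bias": bias,
            "corrected": corrected,
            "ci_low": lo,
            "ci_high": hi,
            "or_original": np.exp(orig),
            "or_corrected": np.exp(corrected),
            "or_ci_low": np.exp(lo),
            "or_ci_high": np.exp(hi),
        }
    )
    return BootstrapSummary(table=table, n_boot=n_boot, seed=seed, n_redraws=n_redraws)


# --------------------------------------------------------------------------
# Probability-vs-PRS curve
# --------------------------------------------------------------------------

def probability_curve(fit: PredictionResults, term: str, grid, fixed: dict) -> tuple:
    """Predicted probability along a grid of one term, others held fixed.

    Returns ``(curve DataFrame, crossing)`` where ``curve`` has the grid
    value, probability and delta-method 95% CI, and ``crossing`` is the
    term value where the probability crosses 0.5 (closed form
    ``-(intercept + fixed contributions) / beta_term``), or None when
    the term's coefficient is zero.
    """
    if term not in fit.design.columns:
        raise ValueError(f"fit does not contain term {term!r}")
    others = [c for c in fit.design.columns if c != term]
    missing = [c for c in others if c not in fixed]
    if missing:
        raise ValueError(f"fixed values required for terms: {missing}")

    grid = np.asarray(grid, float)
    names = ["const"] + list(fit.design.columns)
    x = np.empty((len(grid), len(names)))
    for j, name in enumerate(names):
        if name == "const":
            x[:, j] = 1.0
        elif name == term:
            x[:, j] = grid
        else:
            x[:, j] = float(fixed[name])

    beta = fit.params.reindex(names).to_numpy()
    cov = fit._res.cov_params().reindex(index=names, columns=names).to_numpy()
    eta = x @ beta
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", x, cov, x))
    z = stats.norm.ppf(0.975)
    expit = lambda v: 1.0 / (1.0 + np.exp(-v))
    curve = pd.DataFrame(
        {
            term: grid,
            "probability": expit(eta),
            "ci_low": expit(eta - z * se_eta),
            "ci_high": expit(eta + z * se_eta),
        }
    )

    b_term = float(fit.params[term])
    if b_term == 0:
        crossing = None
    else:
        offset = float(fit.intercept) + sum(
            float(fit.params[c]) * float(fixed[c]) for c in others
        )
        crossing = -offset / b_term
    return curve, crossing
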