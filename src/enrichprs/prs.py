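"""Dual-LASSO variant selection and weighted polygenic risk scores.

Variants from the minimal enriched set are screened by two L1-penalized
regressions — linear on the continuous pain score and logistic on the
dichotomous outcome — with the penalty chosen by cross-validation per
model; the selection is the intersection of the two non-zero-coefficient
sets.  The score for patient n is

    PRS_n = sum_i |b_i| * R_{i,n}

where b_i is the single-variant covariate-adjusted linear-model
coefficient (NOT the LASSO coefficient) and R_{i,n} counts risk alleles:
the minor allele when b_i > 0, otherwise the major allele.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, validate_annotation


@dataclass(frozen=True)
class PRSVariant:
    variant_id: str
    gene: str
    major_allele: str
    minor_allele: str
    risk_allele: str
    weight: float  # |b_i|, NRS units per risk allele


@dataclass
class PRSModel:
    """Selected variants with oriented risk alleles and |b_i| weights."""

    variants: tuple
    source: str = "single-SNP covariate-adjusted linear model"

    def __post_init__(self) -> None:
        self.variants = tuple(
            v if isinstance(v, PRSVariant) else PRSVariant(**v) for v in self.variants
        )
        for v in self.variants:
            if v.weight < 0:
                raise ValueError(f"negative weight for {v.variant_id}")
            if v.risk_allele not in (v.major_allele, v.minor_allele):
                raise ValueError(f"risk allele of {v.variant_id} is neither major nor minor")

    @property
    def m(self) -> int:
        return len(self.variants)

    @property
    def max_score(self) -> float:
        """Upper bound 2 * sum(|b_i|) of any achievable score."""
        return 2.0 * sum(v.weight for v in self.variants)

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {"source": self.source, "variants": [asdict(v) for v in self.variants]}
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path) -> "PRSModel":
        payload = json.loads(Path(path).read_text())
        return cls(variants=tuple(PRSVariant(**v) for v in payload["variants"]),
                   source=payload.get("source", ""))


def load_published_panel() -> PRSModel:
    """The published 20-variant adolescent spine-fusion CPSP risk panel.

    Ships with the package as a worked-example model: seven pain-related
    genes (ATXN1, PRKCA, CACNG2, DRD2, KCNJ3, KCNJ6, KCNK3), linear-model
    weights in NRS units per risk allele.
    """
    with resources.files("enrichprs.data").joinpath("cpsp_prs_panel.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    variants = tuple(
        PRSVariant(
            variant_id=r.variant_id,
            gene=r.gene,
            major_allele=r.major_allele,
            minor_allele=r.minor_allele,
            risk_allele=r.risk_allele,
            weight=float(r.weight),
        )
        for r in df.itertuples()
    )
    return PRSModel(variants=variants, source="published panel")


@dataclass
class LassoSelection:
    selected: tuple
    linear_selected: tuple
    logistic_selected: tuple
    alpha_linear: float
    c_logistic: float


def lasso_select(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    candidate_variants,
    cv_folds: int = 10,
    seed: int = 0,
    standardize: bool = False,
    outcome: str = "nrs_6_12mo",
    binary_outcome: str = "cpsp",
) -> LassoSelection:
    """Dual L1-penalized selection over the candidate variants.

    Fits LASSO linear regression (continuous outcome) and L1-penalized
    logistic regression (dichotomous outcome) over additive-coded
    genotypes; each penalty is chosen by ``cv_folds``-fold
    cross-validation (CV-error minimum, deviance scoring for the
    logistic model); returns the intersection of the two supports.
    Genotypes must be complete — impute first.
    """
    from sklearn.linear_model import LassoCV, LogisticRegressionCV
    from sklearn.model_selection import KFold, StratifiedKFold

    candidate_variants = list(candidate_variants)
    if not candidate_variants:
        raise ValueError("candidate variant set is empty")
    sub = genotypes.subset_variants(candidate_variants)
    if (sub.calls == MISSING).any():
        raise ValueError("missing genotypes among candidates; impute first")

    phen = phenotypes.set_index("individual_id").loc[sub.individual_ids]
    x = sub.calls.astype(float)
    if standardize:
        sd = x.std(axis=0)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    y_cont = phen[outcome].to_numpy(dtype=float)
    y_bin = phen[binary_outcome].to_numpy(dtype=int)

    lin_cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    lin = LassoCV(cv=lin_cv, alphas=100, max_iter=50_000, random_state=seed).fit(x, y_cont)
    linear_sel = tuple(
        v for v, c in zip(candidate_variants, lin.coef_) if c != 0.0
    )

    log_cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    logit = LogisticRegressionCV(
        Cs=20,
        cv=log_cv,
        l1_ratios=(1.0,),
        solver="saga",
        scoring="neg_log_loss",
        max_iter=5_000,
        tol=1e-3,
        random_state=seed,
    ).fit(x, y_bin)
    logistic_sel = tuple(
        v for v, c in zip(candidate_variants, logit.coef_.ravel()) if c != 0.0
    )

    selected = tuple(v for v in candidate_variants if v in set(linear_sel) & set(logistic_sel))
    if not selected:
        warnings.warn("dual-LASSO intersection is empty", stacklevel=2)
    return LassoSelection(
        selected=selected,
        linear_selected=linear_sel,
        logistic_selected=logistic_sel,
        alpha_linear=float(lin.alpha_),
        c_logistic=float(logit.C_[0]),
    )


def impute_missing_mode(
    genotypes: GenotypeMatrix, groups=None
) -> tuple:
    """Replace missing calls by the within-group modal genotype.

    ``groups`` maps individual_id -> group label (e.g. self-reported
    ancestry); ``None`` treats the cohort as one group.  Ties go to the
    smaller genotype code.  Returns (imputed matrix, report dict with
    ``n_imputed`` and ``n_observed``).
    """
    calls = genotypes.calls.copy()
    if groups is None:
        labels = np.zeros(genotypes.n_individuals, dtype=int)
    else:
        mapping = dict(groups) if not isinstance(groups, dict) else groups
        labels_raw = [mapping[s] for s in genotypes.individual_ids]
        _, labels = np.unique(labels_raw, return_inverse=True)

    n_imputed = 0
    for g in np.unique(labels):
        rows = labels == g
        block = calls[rows, :]
        for j in range(block.shape[1]):
            col = block[:, j]
            miss = col == MISSING
            if not miss.any():
                continue
            present = col[~miss]
            if present.size == 0:
                raise ValueError(
                    f"variant {genotypes.variant_ids[j]} missing in every member of a group"
                )
            counts = np.bincount(present, minlength=3)
            col[miss] = int(np.argmax(counts))  # argmax -> smallest on ties
            n_imputed += int(miss.sum())
            block[:, j] = col
        calls[rows, :] = block

    report = {
        "n_imputed": n_imputed,
        "n_observed": int(calls.size - n_imputed),
    }
    return GenotypeMatrix(genotypes.individual_ids, genotypes.variant_ids, calls), report


def orient_risk_allele(beta: float, major_allele: str, minor_allele: str) -> tuple:
    """(risk allele, weight |beta|) for a single-variant linear coefficient.

    beta > 0 on the minor-allele count means the minor allele raises
    pain, so it is the risk allele; beta < 0 flips risk to the major
    allele.  beta = 0 is an error (untestable variants must not reach
    the PRS).
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if beta == 0:
        raise ValueError("beta is 0; variant carries no risk orientation")
    return (minor_allele, float(beta)) if beta > 0 else (major_allele, float(-beta))


def build_prs_model(
    association: pd.DataFrame,
    annotation: pd.DataFrame,
    selected_variants,
) -> PRSModel:
    """PRS model from association betas for the selected variants."""
    assoc = association.set_index("variant_id")
    annot = validate_annotation(annotation)
    variants = []
    for v in selected_variants:
        beta = float(assoc.at[v, "beta"])
        major = annot.at[v, "major_allele"]
        minor = annot.at[v, "minor_allele"]
        risk, weight = orient_risk_allele(beta, major, minor)
        variants.append(
            PRSVariant(
                variant_id=v,
                gene=annot.at[v, "gene"],
                major_allele=major,
                minor_allele=minor,
                risk_allele=risk,
                weight=weight,
            )
        )
    return PRSModel(variants=tuple(variants))


def compute_prs(model: PRSModel, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual weighted risk-allele sums.

    Returns a DataFrame with ``individual_id``, ``prs`` and one
    ``R_<variant>`` risk-allele-count column per model variant.  Errors
    if any model variant is absent from the genotypes or has missing
    calls.
    """
    absent = [v.variant_id for v in model.variants if v.variant_id not in genotypes._vidx]
    if absent:
        raise ValueError(f"model variants absent from genotypes: {absent}")
    out = {"individual_id": list(genotypes.individual_ids)}
    prs = np.zeros(genotypes.n_individuals)
    for v in model.variants:
        calls = genotypes.calls_at(v.variant_id).astype(int)
        if (calls == MISSING).any():
            raise ValueError(f"missing calls at model variant {v.variant_id}")
        r = calls if v.risk_allele == v.minor_allele else 2 - calls
        out[f"R_{v.variant_id}"] = r
        prs = prs + v.weight * r
    out["prs"] = prs
    cols = ["individual_id", "prs"] + [f"R_{v.variant_id}" for v in model.variants]
    return pd.DataFrame(out)[cols]
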