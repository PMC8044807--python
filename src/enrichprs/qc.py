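"""Variant quality control and linkage-disequilibrium pruning.

Filters follow the usual array-QC sequence for a candidate-gene
association study: keep autosomal, gene-annotated, well-called variants
in Hardy-Weinberg equilibrium with minor-allele frequency of at least
10%, then thin residual LD with a PLINK-style sliding-window pruner
(window 50 variants, step 5, r² threshold 0.8).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix, validate_annotation

AUTOSOMES = {str(c) for c in range(1, 23)}

#: Exclusion criteria, applied (and reported) in this fixed order.
EXCLUSION_ORDER = ("non_autosomal", "gene_less", "call_rate", "hwe", "maf")


@dataclass
class QCConfig:
    """Thresholds for variant-level QC and LD pruning."""

    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-4
    maf_min: float = 0.10
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.call_rate_min <= 1:
            raise ValueError("call_rate_min must be in (0, 1]")
        if not 0 <= self.hwe_p_min <= 1:
            raise ValueError("hwe_p_min must be a p-value")
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if self.ld_window < 2:
            raise ValueError("ld_window must be >= 2")
        if self.ld_step < 1:
            raise ValueError("ld_step must be >= 1")
        if not 0 < self.ld_r2_max <= 1:
            raise ValueError("ld_r2_max must be in (0, 1]")


def compute_maf(calls: np.ndarray) -> float:
    """Minor-allele frequency from additive-coded calls.

    ``min(p, 1 - p)`` where ``p`` is the frequency of the counted allele
    among non-missing calls.
    """
    calls = np.asarray(calls)
    ok = calls != MISSING
    n = int(ok.sum())
    if n == 0:
        raise ValueError("all calls missing; MAF undefined")
    p = calls[ok].sum() / (2.0 * n)
    return float(min(p, 1.0 - p))


def genotype_counts(calls: np.ndarray) -> tuple:
    """(n_hom_major, n_het, n_hom_minor) among non-missing calls."""
    calls = np.asarray(calls)
    ok = calls != MISSING
    return (
        int((calls[ok] == 0).sum()),
        int((calls[ok] == 1).sum()),
        int((calls[ok] == 2).sum()),
    )


def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Hardy-Weinberg goodness-of-fit χ² p-value (1 df).

    Observed genotype counts are compared to expectations at the sample
    allele frequency.  Monomorphic variants return p = 1 by convention
    (no test possible).
    """
    n = n_hom_major + n_het + n_hom_minor
    if n <= 0:
        raise ValueError("no genotypes")
    p = (2 * n_hom_minor + n_het) / (2.0 * n)
    if p in (0.0, 1.0):
        return 1.0
    q = 1.0 - p
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    observed = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


@dataclass
class ExclusionReport:
    """Per-criterion exclusion counts plus the per-variant reason."""

    counts: dict
    reasons: pd.Series  # index variant_id -> first failing criterion
    n_input: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": c, "n_excluded": self.counts[c]} for c in EXCLUSION_ORDER]
        rows.append({"criterion": "retained", "n_excluded": self.n_retained})
        return pd.DataFrame(rows)


def filter_variants(
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame,
    config: QCConfig | None = None,
) -> tuple:
    """Apply variant-level QC; returns (filtered genotypes, ExclusionReport).

    Each variant is excluded at the first failing criterion, in the fixed
    order: non-autosomal -> gene-less -> call rate -> HWE -> MAF.
    """
    config = config or QCConfig()
    annot = validate_annotation(annotation)
    missing = [v for v in genotypes.variant_ids if v not in annot.index]
    if missing:
        raise ValueError(f"annotation does not cover variants: {missing[:5]}")
    annot = annot.loc[genotypes.variant_ids]

    calls = genotypes.calls
    ok = calls != MISSING
    n_ok = ok.sum(axis=0)
    n1 = ((calls == 1) & ok).sum(axis=0)
    n2 = ((calls == 2) & ok).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_minor = np.where(n_ok > 0, (2 * n2 + n1) / (2 * n_ok), 0.0)
        maf = np.minimum(p_minor, 1 - p_minor)
        # vectorized 1-df HWE goodness-of-fit chi^2
        q_ = 1 - p_minor
        e0, e1, e2 = n_ok * q_ * q_, 2 * n_ok * p_minor * q_, n_ok * p_minor * p_minor
        o0 = n_ok - n1 - n2
        chi2 = np.where(
            (p_minor > 0) & (p_minor < 1),
            (o0 - e0) ** 2 / np.maximum(e0, 1e-300)
            + (n1 - e1) ** 2 / np.maximum(e1, 1e-300)
            + (n2 - e2) ** 2 / np.maximum(e2, 1e-300),
            0.0,
        )
        hwe_p = np.where((p_minor > 0) & (p_minor < 1), stats.chi2.sf(chi2, 1), 1.0)

    gene = annot["gene"].to_numpy(dtype=object)
    fail = {
        "non_autosomal": ~annot["chrom"].astype(str).isin(AUTOSOMES).to_numpy(),
        "gene_less": np.array([(not g) or pd.isna(g) for g in gene]),
        "call_rate": n_ok / len(genotypes.individual_ids) < config.call_rate_min,
        "hwe": (n_ok > 0) & (hwe_p < config.hwe_p_min),
        "maf": (n_ok == 0) | (maf < config.maf_min),
    }
    counts = {c: 0 for c in EXCLUSION_ORDER}
    reasons = {}
    excluded = np.zeros(genotypes.n_variants, dtype=bool)
    variant_ids = np.asarray(genotypes.variant_ids, dtype=object)
    for crit in EXCLUSION_ORDER:
        hit = fail[crit] & ~excluded
        counts[crit] = int(hit.sum())
        for v in variant_ids[hit]:
            reasons[v] = crit
        excluded |= hit
    kept = list(variant_ids[~excluded])

    report = ExclusionReport(
        counts=counts,
        reasons=pd.Series(reasons, dtype=object),
        n_input=genotypes.n_variants,
        n_retained=len(kept),
    )
    return genotypes.subset_variants(kept), report


def ld_r2(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Squared Pearson correlation of two allele-count vectors.

    Missing calls are excluded pairwise.  A zero-variance vector makes r²
    undefined; it is treated as 0 with a warning.
    """
    a = np.asarray(calls_a, dtype=float)
    b = np.asarray(calls_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("call vectors must cover the same individuals")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in LD pair; r^2 treated as 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pairwise_r2_matrix(calls: np.ndarray) -> np.ndarray:
    """Pairwise-complete r² for a window (individuals x variants, -1 missing)."""
    x = calls.astype(float)
    mask = (x != MISSING).astype(float)
    x = np.where(mask > 0, x, 0.0)
    n = mask.T @ mask
    sx = x.T @ mask
    sxy = x.T @ x
    sxx = (x * x).T @ mask
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        var_a = sxx - sx**2 / n
        var_b = var_a.T
        r2 = cov**2 / (var_a * var_b)
    r2[~np.isfinite(r2)] = 0.0
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.8,
) -> list:
    """PLINK-style indep-pairwise pruning; returns kept variant ids.

    Variants are sorted by (chrom, pos) and windows never span a
    chromosome.  Within each window, while any retained pair exceeds
    ``r2_max``, the member with the lower MAF is dropped (ties: the later
    position).
    """
    if window < 2:
        raise ValueError("window must span at least 2 variants")
    annot = validate_annotation(annotation)
    order = sorted(
        genotypes.variant_ids,
        key=lambda v: (str(annot.at[v, "chrom"]), int(annot.at[v, "pos"])),
    )
    maf = {v: compute_maf(genotypes.calls_at(v)) for v in order}
    removed: set = set()

    by_chrom: dict = {}
    for v in order:
        by_chrom.setdefault(str(annot.at[v, "chrom"]), []).append(v)

    for chrom_variants in by_chrom.values():
        m = len(chrom_variants)
        start = 0
        while True:
            win = chrom_variants[start : start + window]
            idx = [genotypes._vidx[v] for v in win]
            r2 = _pairwise_r2_matrix(genotypes.calls[:, idx])
            active = [v for v in win if v not in removed]
            pos_in_win = {v: k for k, v in enumerate(win)}
            changed = True
            while changed:
                changed = False
                for i in range(len(active)):
                    for j in range(i + 1, len(active)):
                        a, b = active[i], active[j]
                        if r2[pos_in_win[a], pos_in_win[b]] > r2_max:
                            # drop lower MAF; tie -> later position
                            drop = a if maf[a] < maf[b] else b
                            if maf[a] == maf[b]:
                                drop = b
                            removed.add(drop)
                            active.remove(drop)
                            changed = True
                            break
                    if changed:
                        break
            if start + window >= m:
                break
            start += step

    return [v for v in genotypes.variant_ids if v not in removed]
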