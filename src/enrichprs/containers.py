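"""Core in-memory containers shared across pipeline stages.

The analysis moves three tabular objects between stages: an
individuals-by-variants genotype matrix (minor-allele counts with a
missingness mask), a per-variant annotation table, and a ranked gene
universe split into a literature-curated training set, a similarity-ranked
candidate list and a disjoint control pool.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: Columns every variant annotation table must carry.  ``maf`` is the
#: population minor-allele frequency used for band matching; ``gene`` is
#: the annotated symbol or "" for intergenic variants.
ANNOTATION_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "major_allele",
    "minor_allele",
    "gene",
    "maf",
)

PHENOTYPE_COLUMNS = (
    "individual_id",
    "nrs_6_12mo",
    "cpsp",
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


@dataclass
class GenotypeMatrix:
    """Additive-coded genotype calls for a cohort.

    ``calls[i, j]`` is the minor-allele count (0, 1 or 2) of individual
    ``i`` at variant ``j``; missing calls are stored as ``-1``.
    """

    individual_ids: list
    variant_ids: list
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = list(self.individual_ids)
        self.variant_ids = list(self.variant_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individual_ids), len(self.variant_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x "
                f"{len(self.variant_ids)} variants"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype calls must be in {0,1,2} or -1 (missing)")
        self._vidx = {v: j for j, v in enumerate(self.variant_ids)}
        if len(self._vidx) != len(self.variant_ids):
            raise ValueError("duplicate variant ids")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def calls_at(self, variant_id: str) -> np.ndarray:
        """Calls at one variant (missing as -1)."""
        return self.calls[:, self._vidx[variant_id]]

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=0)

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        idx = [self._vidx[v] for v in variant_ids]
        return GenotypeMatrix(
            self.individual_ids, list(variant_ids), self.calls[:, idx].copy()
        )

    def subset_individuals(self, individual_ids) -> "GenotypeMatrix":
        iidx = {s: i for i, s in enumerate(self.individual_ids)}
        idx = [iidx[s] for s in individual_ids]
        return GenotypeMatrix(
            list(individual_ids), self.variant_ids, self.calls[idx, :].copy()
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.individual_ids, self.variant_ids, self.calls.copy())


@dataclass
class RankedGeneSets:
    """Training / ranked-candidate / control gene universe.

    The case universe is ``training ∪ candidates``.  Candidate genes that
    also appear in the training set are de-duplicated into the training
    set; any overlap with the control pool is an error.
    """

    training_genes: tuple
    candidate_genes: tuple  # ordered, rank 1 = best
    control_genes: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        training = tuple(dict.fromkeys(self.training_genes))
        if len(training) != len(tuple(self.training_genes)):
            raise ValueError("duplicate symbols within the training set")
        tset = set(training)
        candidates = tuple(
            dict.fromkeys(g for g in self.candidate_genes if g not in tset)
        )
        control = tuple(dict.fromkeys(self.control_genes))
        case = tset | set(candidates)
        overlap = case & set(control)
        if overlap:
            raise ValueError(
                f"control genes overlap the case universe: {sorted(overlap)[:5]}"
            )
        self.training_genes = training
        self.candidate_genes = candidates
        self.control_genes = control

    @property
    def case_genes(self) -> tuple:
        return self.training_genes + self.candidate_genes

    @property
    def n_case(self) -> int:
        return len(self.case_genes)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check the annotation schema and return the table indexed by variant."""
    missing = set(ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    maf = annotation["maf"].to_numpy(dtype=float)
    known = ~np.isnan(maf)
    if ((maf[known] <= 0) | (maf[known] > 0.5)).any():
        raise ValueError("maf must lie in (0, 0.5]")
    out = annotation.copy()
    out["chrom"] = out["chrom"].astype(str)
    return out.set_index("variant_id", drop=False)


def validate_phenotypes(phenotypes: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Check the phenotype schema and the NRS / CPSP consistency invariant."""
    if "individual_id" not in phenotypes.columns:
        raise ValueError("phenotype table lacks 'individual_id'")
    out = phenotypes.copy()
    if "nrs_6_12mo" in out:
        nrs = out["nrs_6_12mo"].to_numpy(dtype=float)
        ok = np.isnan(nrs) | ((nrs >= 0) & (nrs <= 10))
        if not ok.all():
            raise ValueError("nrs_6_12mo must lie in [0, 10]")
        if "cpsp" in out:
            both = ~np.isnan(nrs) & out["cpsp"].notna().to_numpy()
            expect = (nrs[both] > threshold).astype(int)
            got = out.loc[both, "cpsp"].astype(int).to_numpy()
            if (expect != got).any():
                raise ValueError(f"cpsp must equal (nrs_6_12mo > {threshold})")
    return out
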