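"""Synthetic surgical-cohort generator.

Emulates the data structure of a prospective adolescent spine-fusion
cohort genotyped on candidate-gene panels: Hardy-Weinberg genotypes with
a configurable common-variant MAF spectrum, gene-block structure with
optional within-gene LD (Gaussian copula, AR(1) latent correlation),
additive planted effects of training-gene variants on a continuous
0-10 pain outcome, an anxiety-sensitivity (CASI) covariate with a
positive effect, the dichotomous chronic-pain outcome at NRS > 3 tuned
to a target prevalence, and completely-at-random missing calls.

All randomness flows from a single seed through named substreams so each
component (genotypes, phenotypes, missingness, effects) is independently
reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, MISSING, RankedGeneSets

_NUCLEOTIDES = np.array(list("ACGT"))

# Cohort covariate scales (adolescent spine-fusion population).
_CASI_MEAN, _CASI_SD, _CASI_LO, _CASI_HI = 28.552, 5.531, 18.0, 54.0


@dataclass(frozen=True)
class EffectSpec:
    """A block of planted additive effects: (gene role, #variants, beta)."""

    role: str  # "training" | "candidate" | "control"
    n_variants: int
    beta: float  # NRS units per risk allele


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the prospective cohort the analysis targets: 131
    individuals with outcomes, 31 training genes, 1305 ranked candidate
    genes, ~40% chronic-pain prevalence, a CASI effect of 0.147 NRS per
    point, and common variants (MAF 0.10-0.50).  The control-gene pool
    and per-gene variant counts are desk-scale.
    """

    n_individuals: int = 131
    n_training_genes: int = 31
    n_candidate_genes: int = 1305
    n_control_genes: int = 3000
    variants_per_gene: object = (3, 8)  # int or inclusive (lo, hi) range
    maf_range: tuple = (0.10, 0.50)
    ld_rho: float = 0.3
    effect_variants: tuple = (EffectSpec("training", 20, 0.8),)
    casi_effect: float = 0.147
    noise_sd: float = 2.0
    dichotomize_threshold: float = 3.0
    target_prevalence: float = 0.40
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.10 <= lo <= hi <= 0.50):
            raise ValueError("maf_range must lie within [0.10, 0.50]")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must be in (0, 1)")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for name in ("n_individuals", "n_training_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_candidate_genes < 0 or self.n_control_genes < 0:
            raise ValueError("gene counts must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self.effect_variants = tuple(
            e if isinstance(e, EffectSpec)
            else EffectSpec(**e) if isinstance(e, dict)
            else EffectSpec(*e)
            for e in self.effect_variants
        )

    def variants_for_gene(self, rng: np.random.Generator) -> int:
        if isinstance(self.variants_per_gene, int):
            return self.variants_per_gene
        lo, hi = self.variants_per_gene
        return int(rng.integers(lo, hi + 1))


@dataclass
class SyntheticCohort:
    """A complete simulated study: genotypes, annotation, genes, phenotypes."""

    genotypes: GenotypeMatrix
    annotation: pd.DataFrame
    ranked_genes: RankedGeneSets
    phenotypes: pd.DataFrame
    truth: pd.DataFrame  # variant_id, gene, beta of planted effects
    config: SimConfig

    def write(self, outdir) -> dict:
        """Write VCF + annotation TSV + ranked-gene TSV + phenotype CSV."""
        from . import io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": io.write_vcf(self.genotypes, self.annotation, outdir / "genotypes.vcf"),
            "annotation": io.write_annotation(self.annotation, outdir / "annotation.tsv"),
            "ranked_genes": io.write_ranked_genes(self.ranked_genes, outdir / "ranked_genes.tsv"),
            "phenotypes": io.write_phenotypes(self.phenotypes, outdir / "phenotypes.csv"),
            "truth": io.write_annotation(self.truth, outdir / "truth.tsv"),
        }
        return paths


def _substreams(seed: int) -> dict:
    names = ("structure", "genotypes", "effects", "phenotypes", "covariates", "missingness")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_ranked_genes(config: SimConfig) -> RankedGeneSets:
    """Deterministic gene universe: training, ranked candidates, controls."""
    training = tuple(f"TRN{i:04d}" for i in range(1, config.n_training_genes + 1))
    candidates = tuple(f"CND{i:04d}" for i in range(1, config.n_candidate_genes + 1))
    controls = tuple(f"CTL{i:04d}" for i in range(1, config.n_control_genes + 1))
    return RankedGeneSets(training, candidates, controls)


def _simulate_gene_blocks(
    rng: np.random.Generator, n: int, block_mafs: list, rho: float
) -> np.ndarray:
    """HWE genotypes for all gene blocks (Gaussian copula, AR(1) latent LD).

    Blocks of equal size are drawn together for speed; within a block the
    latent normals follow an AR(1) with coefficient ``rho``, thresholded
    at the cumulative HWE probabilities P(0)=q², P(0 or 1)=q²+2pq.
    """
    sizes = np.array([len(m) for m in block_mafs])
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    calls = np.empty((n, int(sizes.sum())), dtype=np.int8)
    for s in np.unique(sizes):
        which = np.flatnonzero(sizes == s)
        z = rng.standard_normal((n, len(which), s))
        if rho > 0 and s > 1:
            c = np.sqrt(1 - rho**2)
            for j in range(1, s):
                z[:, :, j] = rho * z[:, :, j - 1] + c * z[:, :, j]
        u = stats.norm.cdf(z)
        p = np.stack([block_mafs[i] for i in which])[None, :, :]
        q = 1.0 - p
        g = (u >= q * q).astype(np.int8) + (u >= q * q + 2 * p * q).astype(np.int8)
        for kk, i in enumerate(which):
            calls[:, offsets[i] : offsets[i] + s] = g[:, kk, :]
    return calls


class PrevalenceError(RuntimeError):
    """Raised when the target prevalence cannot be realized."""


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    The outcome model is ``NRS = intercept + Σ beta·g + casi_effect·CASI
    + N(0, noise_sd)``, clipped to the 0-10 scale; the intercept is tuned
    so that the realized prevalence of NRS > threshold matches the
    target.  Raises :class:`PrevalenceError` when clipping makes the
    target unattainable.
    """
    rngs = _substreams(config.seed)
    ranked = simulate_ranked_genes(config)
    n = config.n_individuals

    # --- gene/variant layout (structure stream) -------------------------
    genes, roles = [], []
    for g in ranked.training_genes:
        genes.append(g)
        roles.append("training")
    for r, g in enumerate(ranked.candidate_genes, start=1):
        genes.append(g)
        roles.append(f"candidate:{r}")
    for g in ranked.control_genes:
        genes.append(g)
        roles.append("control")

    srng = rngs["structure"]
    records = []
    blocks = []  # (gene, mafs array)
    pos_by_chrom = {c: 10_000 for c in range(1, 23)}
    vid = 0
    for gene, role in zip(genes, roles):
        k = config.variants_for_gene(srng)
        mafs = srng.uniform(config.maf_range[0], config.maf_range[1], size=k)
        chrom = int(srng.integers(1, 23))
        blocks.append((gene, mafs))
        for maf in mafs:
            vid += 1
            pos_by_chrom[chrom] += int(srng.integers(500, 5_000))
            ref, alt = srng.choice(4, size=2, replace=False)
            records.append(
                {
                    "variant_id": f"var{vid:07d}",
                    "chrom": str(chrom),
                    "pos": pos_by_chrom[chrom],
                    "major_allele": _NUCLEOTIDES[ref],
                    "minor_allele": _NUCLEOTIDES[alt],
                    "gene": gene,
                    "maf": round(float(maf), 6),
                    "role": role,
                }
            )
    annotation = pd.DataFrame.from_records(records)

    # --- genotypes (genotypes stream) -----------------------------------
    grng = rngs["genotypes"]
    calls = _simulate_gene_blocks(
        grng, n, [mafs for _, mafs in blocks], config.ld_rho
    )
    individual_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    variant_ids = annotation["variant_id"].tolist()

    # --- planted effects (effects stream) -------------------------------
    erng = rngs["effects"]
    role_base = annotation["role"].str.split(":").str[0].to_numpy()
    truth_rows = []
    taken: set = set()
    for spec in config.effect_variants:
        pool = np.flatnonzero(role_base == spec.role)
        pool = np.array([j for j in pool if j not in taken])
        if len(pool) < spec.n_variants:
            raise ValueError(
                f"not enough {spec.role} variants to plant {spec.n_variants} effects"
            )
        chosen = erng.choice(pool, size=spec.n_variants, replace=False)
        taken.update(int(j) for j in chosen)
        for j in sorted(int(j) for j in chosen):
            truth_rows.append(
                {
                    "variant_id": variant_ids[j],
                    "gene": annotation.at[j, "gene"],
                    "beta": spec.beta,
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["variant_id", "gene", "beta"])

    # --- covariates (covariates stream) ---------------------------------
    crng = rngs["covariates"]
    casi = stats.truncnorm.rvs(
        (_CASI_LO - _CASI_MEAN) / _CASI_SD,
        (_CASI_HI - _CASI_MEAN) / _CASI_SD,
        loc=_CASI_MEAN,
        scale=_CASI_SD,
        size=n,
        random_state=crng,
    )
    covs = pd.DataFrame(
        {
            "individual_id": individual_ids,
            "casi": np.round(casi, 1),
            "preop_pain": np.clip(np.round(crng.normal(0.6, 1.3, n)), 0, 10),
            "sex": np.where(crng.random(n) < 0.754, "F", "M"),
            "race": np.where(crng.random(n) < 0.818, "white", "non-white"),
            "age": np.round(np.clip(crng.normal(14.5, 1.8, n), 10, 18), 1),
            "weight": np.round(np.clip(crng.normal(57.4, 15.3, n), 25, 120), 1),
            "surgical_duration": np.round(np.clip(crng.normal(4.8, 1.2, n), 1.5, 10), 2),
            "levels_fused": np.clip(np.round(crng.normal(11.5, 2.0, n)), 5, 17).astype(int),
            "propofol": np.round(np.clip(crng.normal(71.8, 27.2, n), 10, 180), 1),
            "remifentanil": np.round(np.clip(crng.normal(113.9, 40.9, n), 10, 280), 1),
            "auc_pod12": np.round(np.clip(crng.normal(200.3, 73.5, n), 20, 480), 1),
            "morphine_meq": np.round(np.clip(crng.normal(1.63, 0.75, n), 0.1, 5), 2),
        }
    )

    # --- outcome (phenotypes stream) ------------------------------------
    prng = rngs["phenotypes"]
    genetic = np.zeros(n)
    if len(truth):
        idx = [variant_ids.index(v) for v in truth["variant_id"]]
        genetic = calls[:, idx].astype(float) @ truth["beta"].to_numpy()
    linpred = genetic + config.casi_effect * covs["casi"].to_numpy()
    noise = prng.normal(0.0, config.noise_sd, n)
    raw = linpred + noise
    intercept = tune_intercept(
        raw, config.dichotomize_threshold, config.target_prevalence
    )
    nrs = np.round(np.clip(raw + intercept, 0.0, 10.0), 3)
    realized = float((nrs > config.dichotomize_threshold).mean())
    if abs(realized - config.target_prevalence) > max(0.05, 2.0 / n):
        raise PrevalenceError(
            f"realized prevalence {realized:.3f} vs target "
            f"{config.target_prevalence:.3f}; effects/noise push the outcome "
            "against the 0-10 bounds"
        )
    phen = covs.copy()
    phen.insert(1, "nrs_6_12mo", nrs)
    phen.insert(2, "cpsp", (nrs > config.dichotomize_threshold).astype(int))

    # --- missingness (missingness stream) -------------------------------
    mrng = rngs["missingness"]
    if config.missing_rate > 0:
        mask = mrng.random(calls.shape) < config.missing_rate
        calls = calls.copy()
        calls[mask] = MISSING

    genotypes = GenotypeMatrix(individual_ids, variant_ids, calls)
    return SyntheticCohort(
        genotypes=genotypes,
        annotation=annotation,
        ranked_genes=ranked,
        phenotypes=phen,
        truth=truth,
        config=config,
    )


def tune_intercept(raw: np.ndarray, threshold: float, target: float) -> float:
    """Intercept making ``mean(raw + intercept > threshold)`` ≈ target.

    Monotone in the target: a higher target prevalence yields a larger
    intercept.  Uses the empirical (1 - target) quantile of ``raw``.
    """
    return float(threshold - np.quantile(raw, 1.0 - target))
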