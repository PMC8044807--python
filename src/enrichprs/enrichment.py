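"""Cumulative gene-set enrichment against MAF-matched resampling nulls.

Candidate genes are consumed as a ranked list.  Variant sets are built
cumulatively: the 0% set holds the training-gene variants, the k-th
decile set adds the variants of the top k*10% ranked candidate genes.
For each set, the observed count of nominally significant variants
(p < alpha) is compared to 10,000 null counts obtained by drawing
control-pool variants matched to the case set's minor-allele-frequency
band profile (bands 10-15 / 15-20 / 20-30 / 30-50 %).  The empirical
p-value is the fraction of null counts at or above the observed count;
a set is flagged enriched when the observed count exceeds the null's
95th percentile.  The earliest enriched set is the "minimal set" whose
variants feed the downstream penalized selection.

Within a draw, control variants are sampled without replacement within
each MAF band.  The null count of significant variants in such a draw is
a sum of independent per-band hypergeometric variables, and the null is
generated in that exact (not approximate) form, which makes the
10,000-run resampling cheap at any pool size.  `draw_matched_control`
materializes explicit control variant sets under the same contract.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RankedGeneSets, validate_annotation

DEFAULT_MAF_BANDS = ((0.10, 0.15), (0.15, 0.20), (0.20, 0.30), (0.30, 0.50))
SET_LABELS = tuple(f"{k}%" for k in range(0, 101, 10))


@dataclass
class EnrichmentConfig:
    """Parameters of the resampling enrichment test."""

    alpha: float = 0.05
    n_runs: int = 10_000
    maf_bands: tuple = DEFAULT_MAF_BANDS
    increment: float = 0.10
    seed: int | None = None
    #: Davison-Hinkley (+1)/(n+1) empirical p instead of the raw count/n.
    add_one_correction: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        bands = tuple(tuple(b) for b in self.maf_bands)
        for (lo1, hi1), (lo2, _) in zip(bands, bands[1:]):
            if hi1 != lo2 or lo1 >= hi1:
                raise ValueError("maf_bands must be contiguous ascending intervals")
        self.maf_bands = bands


def maf_bands_vector(mafs, config: EnrichmentConfig | None = None) -> np.ndarray:
    """1-based MAF band indices; bands are [lo, hi), the last band closed.

    A MAF outside the banded range is an error — such variants should
    have been removed by QC.
    """
    config = config or EnrichmentConfig()
    bands = config.maf_bands
    edges = np.array([b[0] for b in bands] + [bands[-1][1]])
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))
    if (mafs < edges[0]).any():
        bad = float(mafs[mafs < edges[0]][0])
        raise ValueError(f"maf {bad} below the first band edge {edges[0]}")
    if (mafs > edges[-1]).any():
        bad = float(mafs[mafs > edges[-1]][0])
        raise ValueError(f"maf {bad} above the last band edge {edges[-1]}")
    idx = np.searchsorted(edges, mafs, side="right")
    return np.minimum(idx, len(bands)).astype(int)


def assign_maf_band(maf: float, config: EnrichmentConfig | None = None) -> int:
    return int(maf_bands_vector([maf], config)[0])


def cumulative_sets(
    ranked: RankedGeneSets,
    annotation: pd.DataFrame,
    config: EnrichmentConfig | None = None,
) -> list:
    """Ordered [(label, variant_id tuple)] for the 11 cumulative sets.

    Set "0%" holds the training-gene variants; each further set adds the
    variants of the next ceil(10%) slice of ranked candidate genes, so
    the sets are monotonically nested and "100%" covers the whole case
    universe.
    """
    config = config or EnrichmentConfig()
    if not ranked.training_genes:
        raise ValueError("training gene set is empty")
    annot = validate_annotation(annotation)
    by_gene: dict = {}
    for vid, gene in zip(annot["variant_id"], annot["gene"]):
        by_gene.setdefault(gene, []).append(vid)

    n_cand = len(ranked.candidate_genes)
    steps = int(round(1.0 / config.increment))
    sets = []
    current_genes = list(ranked.training_genes)
    variants = [v for g in current_genes for v in by_gene.get(g, [])]
    sets.append((SET_LABELS[0], tuple(variants)))
    prev_cut = 0
    for k in range(1, steps + 1):
        cut = math.ceil(n_cand * k / steps)
        for g in ranked.candidate_genes[prev_cut:cut]:
            variants.extend(by_gene.get(g, []))
        prev_cut = cut
        sets.append((SET_LABELS[k], tuple(variants)))
    return sets


def draw_matched_control(
    case_variants,
    control_pool,
    annotation: pd.DataFrame,
    rng: np.random.Generator,
    config: EnrichmentConfig | None = None,
) -> np.ndarray:
    """One control variant set with the case set's per-band MAF profile.

    Sampling is without replacement within a draw; successive calls with
    the same generator give independent draws.
    """
    config = config or EnrichmentConfig()
    annot = validate_annotation(annotation)
    case_bands = maf_bands_vector(annot.loc[list(case_variants), "maf"], config)
    pool = np.asarray(list(control_pool))
    pool_bands = maf_bands_vector(annot.loc[list(pool), "maf"], config)
    chosen = []
    for b in range(1, len(config.maf_bands) + 1):
        need = int((case_bands == b).sum())
        if need == 0:
            continue
        avail = pool[pool_bands == b]
        if len(avail) < need:
            raise ValueError(
                f"band {b}: control pool has {len(avail)} variants, case set needs {need}"
            )
        chosen.append(rng.choice(avail, size=need, replace=False))
    return np.concatenate(chosen) if chosen else np.array([], dtype=pool.dtype)


@dataclass
class EnrichmentSetResult:
    """Observed vs resampling-null significant-variant counts for one set."""

    set_label: str
    n_case_variants: int
    observed_significant: int
    null_counts: np.ndarray
    empirical_p: float
    enriched: bool

    @property
    def null_95th(self) -> float:
        return float(np.percentile(self.null_counts, 95))


def enrichment_test(
    case_pvals,
    case_bands,
    pool_pvals,
    pool_bands,
    config: EnrichmentConfig,
    rng: np.random.Generator,
    set_label: str = "",
) -> EnrichmentSetResult:
    """Resampling enrichment test for one cumulative variant set.

    observed = #{case p < alpha}; each of ``n_runs`` null counts is the
    number of significant variants in a band-matched without-replacement
    control draw; empirical p = #{null >= observed} / n_runs (or the
    add-one-corrected version when configured); the enriched flag uses
    the observed > null-95th-percentile rule.
    """
    case_pvals = np.asarray(case_pvals, float)
    case_bands = np.asarray(case_bands, int)
    pool_sig = np.asarray(pool_pvals, float) < config.alpha
    pool_bands = np.asarray(pool_bands, int)
    observed = int((case_pvals < config.alpha).sum())

    null_counts = np.zeros(config.n_runs, dtype=np.int64)
    for b in range(1, len(config.maf_bands) + 1):
        k = int((case_bands == b).sum())
        if k == 0:
            continue
        in_band = pool_bands == b
        n_pool = int(in_band.sum())
        if n_pool < k:
            raise ValueError(
                f"band {b}: control pool has {n_pool} variants, case set needs {k}"
            )
        n_sig = int(pool_sig[in_band].sum())
        null_counts += rng.hypergeometric(n_sig, n_pool - n_sig, k, size=config.n_runs)

    empirical_p = empirical_p_value(null_counts, observed, config.add_one_correction)
    enriched = observed > np.percentile(null_counts, 95)
    return EnrichmentSetResult(
        set_label=set_label,
        n_case_variants=len(case_pvals),
        observed_significant=observed,
        null_counts=null_counts,
        empirical_p=float(empirical_p),
        enriched=bool(enriched),
    )


def empirical_p_value(null_counts, observed: int, add_one: bool = False) -> float:
    """Resampling p: #{null counts >= observed} / #runs.

    The optional Davison-Hinkley correction uses (count+1)/(runs+1).
    Non-increasing in ``observed``; 1.0 when observed is 0.
    """
    null_counts = np.asarray(null_counts)
    n_runs = len(null_counts)
    n_ge = int((null_counts >= observed).sum())
    if add_one:
        return (n_ge + 1) / (n_runs + 1)
    return n_ge / n_runs


def minimal_enriched_set(results) -> str | None:
    """Label of the earliest enriched cumulative set, or None."""
    for r in results:
        if r.enriched:
            return r.set_label
    return None


class EnrichmentAnalysis:
    """Cumulative-set enrichment model over an association scan.

    Parameters
    ----------
    association : DataFrame
        Output of :func:`enrichprs.association.snp_association` covering
        both case and control variants.
    annotation : DataFrame
        Variant annotation (gene, maf).
    ranked : RankedGeneSets
        Training / ranked-candidate / control gene universe.
    config : EnrichmentConfig
    """

    def __init__(self, association, annotation, ranked, config=None):
        self.association = association.set_index("variant_id", drop=False)
        self.annotation = validate_annotation(annotation)
        self.ranked = ranked
        self.config = config or EnrichmentConfig()

    def control_pool(self) -> np.ndarray:
        control = set(self.ranked.control_genes)
        annot = self.annotation
        pool = annot.loc[annot["gene"].isin(control), "variant_id"].to_numpy()
        return pool[self.association.index.get_indexer(pool) >= 0]

    def fit(self, seed: int | None = None) -> "EnrichmentResults":
        """Run the resampling test on every cumulative set.

        Each set gets an independent substream of the seed; draws are
        never reused across centiles.
        """
        seed = self.config.seed if seed is None else seed
        sets = cumulative_sets(self.ranked, self.annotation.reset_index(drop=True), self.config)
        assoc_index = self.association.index
        sets = [
            (label, np.asarray(vs, dtype=object)[assoc_index.get_indexer(vs) >= 0])
            for label, vs in sets
        ]
        pool = self.control_pool()
        pool_pvals = self.association.loc[pool, "p_value"].to_numpy()
        pool_bands = maf_bands_vector(self.annotation.loc[pool, "maf"].to_numpy(), self.config)
        streams = np.random.SeedSequence(seed).spawn(len(sets))
        results = []
        for (label, vids), ss in zip(sets, streams):
            pos = assoc_index.get_indexer(vids)
            case_pvals = self.association["p_value"].to_numpy()[pos]
            case_bands = maf_bands_vector(
                self.annotation["maf"].to_numpy()[self.annotation.index.get_indexer(vids)],
                self.config,
            )
            results.append(
                enrichment_test(
                    case_pvals,
                    case_bands,
                    pool_pvals,
                    pool_bands,
                    self.config,
                    np.random.default_rng(ss),
                    set_label=label,
                )
            )
        return EnrichmentResults(results, self.config)


class EnrichmentResults:
    """Per-set resampling results with the minimal-enriched-set rule."""

    def __init__(self, set_results, config):
        self.set_results = list(set_results)
        self.config = config

    @property
    def minimal_enriched_set(self) -> str | None:
        return minimal_enriched_set(self.set_results)

    def summary(self) -> pd.DataFrame:
        rows = []
        for r in self.set_results:
            rows.append(
                {
                    "set_label": r.set_label,
                    "n_case_variants": r.n_case_variants,
                    "observed_significant": r.observed_significant,
                    "null_mean": float(r.null_counts.mean()),
                    "null_95th": r.null_95th,
                    "empirical_p": r.empirical_p,
                    "enriched": r.enriched,
                }
            )
        return pd.DataFrame(rows)

    def __getitem__(self, i):
        return self.set_results[i]

    def __iter__(self):
        return iter(self.set_results)

    def plot(self, ax=None):
        """Observed counts (dots) over null box plots per cumulative set."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        ax.boxplot(
            [r.null_counts for r in self.set_results],
            tick_labels=[r.set_label for r in self.set_results],
            whis=(5, 95),
        )
        ax.plot(
            range(1, len(self.set_results) + 1),
            [r.observed_significant for r in self.set_results],
            "ro",
            label="observed",
        )
        ax.set_xlabel("cumulative ranked gene set (centile)")
        ax.set_ylabel("variants with p < alpha")
        ax.legend()
        return ax
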