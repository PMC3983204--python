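"""Enrichment statistics for C-terminal nsSNPs and motif predictions.

Three test families:

* exact binomial test of nsSNP density in a region (each region position
  is a trial, the proteome-wide nsSNP rate the success probability —
  a binomial rather than a hypergeometric because several nsSNPs can
  hit the same residue);
* one-sided Fisher exact tests of overlap between predicted and curated
  interactions (identical to the hypergeometric upper tail);
* a threshold sweep of motif definitions and a randomization null that
  redraws each variant's alternate residue uniformly from the 19
  non-identical amino acids at the same position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alphabet import AA_INDEX, AMINO_ACIDS, MOTIF_WINDOW
from .proteome import ProteinIsoform, extract_ctermini
from .pwm import PWM
from .variants import (
    ClassificationConfig,
    VariantRecord,
    _ScoreCache,
)

logger = logging.getLogger(__name__)

_ALTERNATIVES = {"greater": "greater", "less": "less", "two": "two-sided"}


@dataclass(frozen=True)
class EnrichmentResult:
    test: str  # "binomial" | "fisher"
    observed: int
    expected: float
    p_value: float
    sidedness: str
    inputs: dict

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "observed": int(self.observed),
            "expected": float(self.expected),
            "p_value": float(self.p_value),
            "sidedness": self.sidedness,
            "inputs": self.inputs,
        }


def binomial_enrichment(
    k_observed: int,
    n_trials: int,
    region_aa: int,
    total_aa: int,
    sidedness: str = "two",
) -> EnrichmentResult:
    """Exact binomial test of nsSNP density in a region of the proteome.

    ``n_trials`` nsSNPs over ``total_aa`` residues define the background
    per-position rate; the observed ``k_observed`` nsSNPs in the
    ``region_aa``-residue region are compared with Binomial(region_aa,
    rate).  The expected count is region_aa * rate = n_trials *
    region_aa / total_aa.  The tail is exact (no normal approximation).
    """
    if sidedness not in _ALTERNATIVES:
        raise ValueError(f"sidedness must be one of {sorted(_ALTERNATIVES)}")
    if total_aa <= 0:
        raise ValueError("total_aa must be positive")
    if region_aa > total_aa:
        raise ValueError("region_aa cannot exceed total_aa")
    if k_observed > n_trials:
        raise ValueError("observed count cannot exceed the number of nsSNPs")
    rate = n_trials / total_aa
    if rate > 1.0:
        raise ValueError(
            f"nsSNP rate {rate:.3g} exceeds 1; binomial over positions undefined"
        )
    if k_observed > region_aa:
        raise ValueError(
            "observed count exceeds region size; binomial over positions undefined"
        )
    p_value = sps.binomtest(
        k_observed, region_aa, rate, alternative=_ALTERNATIVES[sidedness]
    ).pvalue
    return EnrichmentResult(
        test="binomial",
        observed=k_observed,
        expected=n_trials * region_aa / total_aa,
        p_value=float(p_value),
        sidedness=sidedness,
        inputs={
            "n_trials": int(n_trials),
            "region_aa": int(region_aa),
            "total_aa": int(total_aa),
            "rate": rate,
        },
    )


def fisher_overlap(
    universe: int,
    universe_hits: int,
    sample: int,
    sample_hits: int,
    sidedness: str = "greater",
) -> EnrichmentResult:
    """Fisher exact test for enrichment of hits inside a sample.

    2x2 table: [[sample_hits, sample - sample_hits],
                [universe_hits - sample_hits,
                 universe - sample - universe_hits + sample_hits]].
    The one-sided "greater" p-value equals the hypergeometric upper
    tail P(X >= sample_hits) with X ~ Hypergeom(universe,
    universe_hits, sample).
    """
    if sidedness not in _ALTERNATIVES:
        raise ValueError(f"sidedness must be one of {sorted(_ALTERNATIVES)}")
    table = np.array(
        [
            [sample_hits, sample - sample_hits],
            [universe_hits - sample_hits, universe - sample - universe_hits + sample_hits],
        ]
    )
    if (table < 0).any():
        raise ValueError(f"inconsistent counts: contingency table {table.tolist()}")
    if sidedness == "greater":
        p_value = float(sps.hypergeom.sf(sample_hits - 1, universe, universe_hits, sample))
    elif sidedness == "less":
        p_value = float(sps.hypergeom.cdf(sample_hits, universe, universe_hits, sample))
    else:
        p_value = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return EnrichmentResult(
        test="fisher",
        observed=sample_hits,
        expected=sample * universe_hits / universe,
        p_value=min(p_value, 1.0),
        sidedness=sidedness,
        inputs={
            "universe": int(universe),
            "universe_hits": int(universe_hits),
            "sample": int(sample),
            "table": table.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# Threshold sweep over motif definitions

@dataclass(frozen=True)
class SweepResult:
    """Per-threshold motif counts, nsSNP density and under-representation p."""

    table: pd.DataFrame
    background_rate: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def sweep_motif_thresholds(
    score_matrix: pd.DataFrame,
    ctermini: Sequence,
    cterm_variants: Sequence[str],
    threshold_grid: Sequence[float] | None = None,
    background_rate: float | None = None,
) -> SweepResult:
    """Count nsSNPs inside motif-containing C-termini over a threshold grid.

    A C-terminus contains a motif at threshold t when its best score
    over all domains exceeds t.  ``cterm_variants`` lists, one entry
    per nsSNP occurrence, the key of the C-terminus hit.  Per
    threshold: the number of qualifying C-termini, the nsSNPs falling
    in them, their amino-acid total, the density ratio, and the exact
    binomial p-value for under-representation against the global
    C-terminal nsSNP rate.
    """
    if threshold_grid is None:
        threshold_grid = default_threshold_grid()
    grid = sorted(float(t) for t in threshold_grid)[::-1]
    if not grid:
        raise ValueError("empty threshold grid")

    lengths = {}
    for c in ctermini:
        key = c.key if hasattr(c, "key") else str(c)
        lengths[key] = len(c)
    unknown = set(score_matrix.columns) - set(lengths)
    if unknown:
        raise ValueError(f"C-termini missing for scored columns: {sorted(unknown)[:3]}")

    var_counts = pd.Series(cterm_variants).value_counts() if len(cterm_variants) else pd.Series(dtype=int)
    best = score_matrix.max(axis=0)
    total_aa = int(sum(lengths[k] for k in score_matrix.columns))
    if background_rate is None:
        background_rate = len(cterm_variants) / total_aa if total_aa else 0.0
    n_total_variants = len(cterm_variants)

    rows = []
    for t in grid:
        in_motif = best.index[best > t]
        n_aa = int(sum(lengths[k] for k in in_motif))
        n_var = int(var_counts.reindex(in_motif, fill_value=0).sum())
        ratio = n_var / n_aa if n_aa else np.nan
        if n_aa == 0:
            p = np.nan
        elif n_var >= n_aa:
            p = 1.0
        else:
            p = sps.binomtest(n_var, n_aa, background_rate, alternative="less").pvalue
        rows.append(
            {
                "threshold": t,
                "n_motif_ctermini": len(in_motif),
                "n_variants": n_var,
                "n_aa": n_aa,
                "ratio": ratio,
                "p_value": p,
            }
        )
    return SweepResult(table=pd.DataFrame(rows), background_rate=float(background_rate))


def default_threshold_grid(start: float = -12.0, stop: float = -4.0, step: float = 0.1):
    return np.round(np.arange(start, stop + step / 2, step), 10)


# ---------------------------------------------------------------------------
# Randomization null for the disruption fraction

@dataclass(frozen=True)
class RandomizationSummary:
    thresholds: np.ndarray  # s_max grid
    observed: np.ndarray    # fraction of variants called "disrupts"
    null_mean: np.ndarray
    null_sd: np.ndarray     # population sd over replicates
    n_reps: int
    seed: int
    n_variants: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_max": self.thresholds,
                "observed_fraction": self.observed,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
            }
        )


def _disruption_margins(
    variants: Sequence[VariantRecord],
    proteome: Sequence[ProteinIsoform],
    pwms: Sequence[PWM],
    s_min: float,
    window: int = MOTIF_WINDOW,
):
    """For each C-terminal missense variant, the largest wild-type score
    among domains whose mutant score drops below s_min, for every
    possible alternate residue.  A variant is called "disrupts" at
    threshold s_max exactly when that value exceeds s_max, so the
    19-residue substitution null reduces to sampling columns of this
    matrix."""
    cache = _ScoreCache(pwms)
    ctermini = {c.key: c for c in extract_ctermini(proteome, window=window)}
    by_protein: dict[str, list[ProteinIsoform]] = {}
    for iso in proteome:
        by_protein.setdefault(iso.protein_id, []).append(iso)

    log10 = np.log(10.0)
    margins = []   # rows: (n_alt=20) best-disrupting wt score per alt residue
    observed_alt = []
    kept_variants = []
    for var in variants:
        if var.kind != "missense":
            continue
        per_alt = np.full(len(AMINO_ACIDS), -np.inf)
        found = False
        for iso in by_protein.get(var.protein_id, []):
            n = len(iso.sequence)
            if not 1 <= var.position <= n:
                continue
            if iso.sequence[var.position - 1] != var.ref_aa:
                continue
            offset = n - var.position
            if offset >= min(window, n):
                continue
            found = True
            ct = ctermini[iso.key]
            wt = cache.scores(ct.sequence)
            ref_idx = AA_INDEX[var.ref_aa]
            with np.errstate(divide="ignore", invalid="ignore"):
                logp = np.array(
                    [np.log(p.probs[offset]) / log10 for p in pwms]
                )  # (n_dom, 20)
                # mutant score for alt a: wt - logp[:, ref] + logp[:, a];
                # -inf wild types give nan here, which never passes the
                # s_min comparison below (a -inf wild type cannot disrupt)
                mut = wt[:, None] - logp[:, [ref_idx]] + logp  # (n_dom, 20)
            disrupts = mut < s_min
            wt_masked = np.where(disrupts, wt[:, None], -np.inf)
            per_alt = np.maximum(per_alt, wt_masked.max(axis=0))
        if not found:
            continue
        per_alt[AA_INDEX[var.ref_aa]] = np.nan  # synonymous: excluded from null
        margins.append(per_alt)
        observed_alt.append(AA_INDEX[var.alt_aa])
        kept_variants.append(var)
    if margins:
        return np.vstack(margins), np.array(observed_alt), kept_variants
    return np.empty((0, len(AMINO_ACIDS))), np.empty(0, dtype=int), []


def randomized_disruption_fraction(
    cterm_variants: Sequence[VariantRecord],
    proteome: Sequence[ProteinIsoform],
    pwms: Sequence[PWM],
    config: ClassificationConfig = ClassificationConfig(),
    s_max_grid: Sequence[float] | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    window: int = MOTIF_WINDOW,
) -> RandomizationSummary:
    """Observed vs null fraction of missense variants disrupting a motif.

    The observed curve is the fraction of C-terminal missense variants
    classified "disrupts" as s_max varies (s_min fixed at
    ``config.s_min``).  Each of ``n_reps`` randomizations replaces
    every variant's alternate residue with a uniform draw from the 19
    non-identical residues at the same position and reclassifies.
    Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if s_max_grid is None:
        s_max_grid = np.round(np.arange(-8.2, -4.0 + 0.05, 0.1), 10)
    grid = np.asarray(sorted(float(t) for t in s_max_grid), dtype=float)
    bad = grid[grid <= config.s_min]
    if bad.size:
        raise ValueError(f"s_max grid values must exceed s_min={config.s_min}")

    margins, observed_alt, kept = _disruption_margins(
        cterm_variants, proteome, pwms, config.s_min, window=window
    )
    n_var = len(kept)
    if n_var == 0:
        zero = np.zeros(len(grid))
        return RandomizationSummary(
            thresholds=grid, observed=zero, null_mean=zero.copy(),
            null_sd=zero.copy(), n_reps=n_reps, seed=seed, n_variants=0,
        )

    obs_margin = margins[np.arange(n_var), observed_alt]
    observed = (obs_margin[:, None] > grid[None, :]).mean(axis=0)

    rng = np.random.default_rng(seed)
    # sample non-reference alternates: margins row has NaN at the reference
    alt_pool = np.array(
        [np.flatnonzero(~np.isnan(margins[i])) for i in range(n_var)]
    )  # (n_var, 19)
    draws = rng.integers(0, alt_pool.shape[1], size=(n_reps, n_var))
    sampled_alt = np.take_along_axis(
        np.broadcast_to(alt_pool, (n_reps, n_var, alt_pool.shape[1])),
        draws[:, :, None],
        axis=2,
    )[:, :, 0]
    sampled_margin = margins[np.arange(n_var)[None, :], sampled_alt]  # (n_reps, n_var)
    null_curves = (sampled_margin[:, :, None] > grid[None, None, :]).mean(axis=1)
    return RandomizationSummary(
        thresholds=grid,
        observed=observed,
        null_mean=null_curves.mean(axis=0),
        null_sd=null_curves.std(axis=0, ddof=0),
        n_reps=n_reps,
        seed=seed,
        n_variants=n_var,
    )


# ---------------------------------------------------------------------------
# Gold-standard overlap helpers

def gold_standard_fisher(
    score_matrix: pd.DataFrame,
    gold_pairs: Sequence[tuple[str, str]],
    s_min: float = ClassificationConfig().s_min,
) -> EnrichmentResult:
    """Are curated (domain, protein) interactions enriched above S_min?

    The universe is every (domain, protein) pair over the domains that
    occur both in the score matrix and in the gold standard; a protein
    scores with its best isoform.  Mirrors the PDZbase benchmark: known
    interactions scoring below S_min are significantly depleted.
    """
    per_protein = _best_per_protein(score_matrix)
    domains = sorted(
        {d for d, _ in gold_pairs} & set(score_matrix.index)
    )
    if not domains:
        raise ValueError("no gold-standard domain matches the score matrix")
    proteins = list(per_protein.columns)
    universe = len(domains) * len(proteins)
    sub = per_protein.loc[domains]
    universe_hits = int((sub.to_numpy() > s_min).sum())
    in_universe = [
        (d, p) for d, p in set(gold_pairs) if d in set(domains) and p in set(proteins)
    ]
    sample = len(in_universe)
    sample_hits = sum(1 for d, p in in_universe if per_protein.at[d, p] > s_min)
    return fisher_overlap(universe, universe_hits, sample, sample_hits, "greater")


def affected_interaction_fisher(
    affected_pairs: Sequence[tuple[str, str]],
    gold_pairs: Sequence[tuple[str, str]],
    n_proteins: int,
    domains: Sequence[str],
) -> EnrichmentResult:
    """Overlap of truncation-suppressed predictions with a curated network.

    Universe: all (domain-containing protein, protein) pairs for the
    screened domains; sample: the predicted suppressed interactions.
    Mirrors the BioGRID benchmark for stop-gain predictions.
    """
    domains = sorted(set(domains))
    universe = len(domains) * n_proteins
    gold = {(d, p) for d, p in gold_pairs if d in set(domains)}
    universe_hits = len(gold)
    sample_pairs = {(d, p) for d, p in affected_pairs if d in set(domains)}
    sample = len(sample_pairs)
    sample_hits = len(sample_pairs & gold)
    return fisher_overlap(universe, universe_hits, sample, sample_hits, "greater")


def _best_per_protein(score_matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse isoform columns ("protein|isoform") to per-protein maxima."""
    proteins = [c.split("|", 1)[0] for c in score_matrix.columns]
    return score_matrix.T.groupby(proteins, sort=False).max().T
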