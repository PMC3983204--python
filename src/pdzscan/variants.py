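"""Variant application and two-threshold motif classification.

A missense variant disrupts a PDZ-binding motif for domain i when the
wild-type C-terminus scores above S_max while the mutated one drops
below S_min; it creates a motif in the mirror case.  Scores inside the
confidence band [S_min, S_max] never support a call, and both
inequalities are strict.  Stop-gain variants replace the natural
C-terminus with the window upstream of the new stop and are classified
with the same rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, MOTIF_WINDOW
from .proteome import CTerminus, ProteinIsoform, extract_ctermini
from .pwm import PWM, score_cterm

logger = logging.getLogger(__name__)

S_MIN_DEFAULT = -8.3
S_MAX_DEFAULT = -6.4

VARIANT_COLUMNS = [
    "variant_id",
    "protein_id",
    "isoform_id",
    "position",
    "ref_aa",
    "alt_aa",
    "kind",
]


@dataclass(frozen=True)
class VariantRecord:
    """One protein-level nsSNP: a missense substitution or a stop gain."""

    variant_id: str
    protein_id: str
    isoform_id: str
    position: int  # 1-based protein coordinate
    ref_aa: str
    alt_aa: str  # empty for stop_gain
    kind: str  # "missense" | "stop_gain"

    def __post_init__(self):
        if self.kind not in ("missense", "stop_gain"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("position must be 1-based and positive")
        if self.ref_aa not in AA_INDEX:
            raise ValueError(f"invalid reference residue {self.ref_aa!r}")
        if self.kind == "missense":
            if self.alt_aa not in AA_INDEX:
                raise ValueError(f"invalid alternate residue {self.alt_aa!r}")
            if self.ref_aa == self.alt_aa:
                raise ValueError(
                    f"missense variant {self.variant_id} has ref == alt"
                )
        elif self.alt_aa:
            raise ValueError("stop_gain variants carry no alternate residue")


@dataclass(frozen=True)
class ClassificationConfig:
    """Confidence band on PWM scores: calls require crossing the whole band."""

    s_min: float = S_MIN_DEFAULT
    s_max: float = S_MAX_DEFAULT

    def __post_init__(self):
        if not self.s_min < self.s_max:
            raise ValueError(
                f"require s_min < s_max, got {self.s_min} >= {self.s_max}"
            )


@dataclass(frozen=True)
class ClassificationResult:
    variant_id: str
    wt_scores: dict
    mut_scores: dict
    verdict: str  # "disrupts" | "creates" | "neutral"
    disrupt_domains: tuple
    create_domains: tuple

    @property
    def supporting_domains(self) -> tuple:
        if self.verdict == "disrupts":
            return self.disrupt_domains
        if self.verdict == "creates":
            return self.create_domains
        return ()


def mutate_cterm(cterm: CTerminus, variant: VariantRecord) -> CTerminus:
    """Apply a missense substitution inside the C-terminal window."""
    if variant.kind != "missense":
        raise ValueError("mutate_cterm handles missense variants only")
    idx = variant.position - cterm.start_position
    if not 0 <= idx < len(cterm.sequence):
        raise ValueError(
            f"not a C-terminal variant: position {variant.position} outside "
            f"window of {cterm.key} (start {cterm.start_position})"
        )
    if cterm.sequence[idx] != variant.ref_aa:
        raise ValueError(
            f"reference residue mismatch at {cterm.key}:{variant.position}: "
            f"window has {cterm.sequence[idx]!r}, variant states {variant.ref_aa!r}"
        )
    seq = cterm.sequence[:idx] + variant.alt_aa + cterm.sequence[idx + 1 :]
    return CTerminus(
        protein_id=cterm.protein_id,
        isoform_id=cterm.isoform_id,
        sequence=seq,
        start_position=cterm.start_position,
    )


def truncate_at_stop(
    isoform: ProteinIsoform, variant: VariantRecord, window: int = MOTIF_WINDOW
) -> CTerminus:
    """C-terminal window of the protein truncated at a new stop codon.

    The stop replaces the residue at ``variant.position``; the product
    is residues 1..position-1 and its trailing min(window, position-1)
    residues form the new C-terminus.
    """
    if variant.kind != "stop_gain":
        raise ValueError("truncate_at_stop handles stop_gain variants only")
    n = len(isoform.sequence)
    if not 1 <= variant.position <= n:
        raise ValueError(
            f"position {variant.position} out of range for {isoform.key} (length {n})"
        )
    if isoform.sequence[variant.position - 1] != variant.ref_aa:
        raise ValueError(
            f"reference residue mismatch at {isoform.key}:{variant.position}"
        )
    if variant.position < 2:
        raise ValueError("empty protein after truncation")
    truncated_len = variant.position - 1
    w = min(window, truncated_len)
    return CTerminus(
        protein_id=isoform.protein_id,
        isoform_id=isoform.isoform_id,
        sequence=isoform.sequence[truncated_len - w : truncated_len],
        start_position=truncated_len - w + 1,
    )


def classify_variant(
    wt_scores: Mapping[str, float],
    mut_scores: Mapping[str, float],
    config: ClassificationConfig = ClassificationConfig(),
    variant_id: str = "",
) -> ClassificationResult:
    """Apply the two-threshold rule over per-domain score pairs.

    Domain i supports "disrupts" iff S_i(wt) > s_max and S_i(mut) < s_min
    (strict); "creates" is the mirror.  A variant with supporting
    domains on both sides rolls up to "disrupts" (both lists retained).
    """
    if set(wt_scores) != set(mut_scores):
        raise ValueError("wild-type and mutant score vectors cover different domains")
    disrupt, create = [], []
    for dom in wt_scores:
        wt, mut = wt_scores[dom], mut_scores[dom]
        if wt > config.s_max and mut < config.s_min:
            disrupt.append(dom)
        elif wt < config.s_min and mut > config.s_max:
            create.append(dom)
    verdict = "disrupts" if disrupt else ("creates" if create else "neutral")
    return ClassificationResult(
        variant_id=variant_id,
        wt_scores=dict(wt_scores),
        mut_scores=dict(mut_scores),
        verdict=verdict,
        disrupt_domains=tuple(disrupt),
        create_domains=tuple(create),
    )


# ---------------------------------------------------------------------------
# Proteome-wide screen

CLASSIFICATION_COLUMNS = [
    "variant_id",
    "protein_id",
    "isoform_id",
    "kind",
    "wt_cterm",
    "mut_cterm",
    "best_domain",
    "s_wt",
    "s_mut",
    "verdict",
]


class _ScoreCache:
    def __init__(self, pwms: Sequence[PWM]):
        self.pwms = list(pwms)
        self.domain_ids = [p.domain_id for p in pwms]
        self._cache: dict[str, np.ndarray] = {}

    def scores(self, seq: str) -> np.ndarray:
        hit = self._cache.get(seq)
        if hit is None:
            hit = np.array([score_cterm(p, seq) for p in self.pwms])
            self._cache[seq] = hit
        return hit

    def as_dict(self, seq: str) -> dict:
        return dict(zip(self.domain_ids, self.scores(seq)))


@dataclass
class ScreenReport:
    rows: pd.DataFrame
    results: list
    summary: dict
    affected_interactions: set


def screen_variants(
    proteome: Sequence[ProteinIsoform],
    variants: Sequence[VariantRecord],
    pwms: Sequence[PWM],
    config: ClassificationConfig = ClassificationConfig(),
    window: int = MOTIF_WINDOW,
) -> ScreenReport:
    """Classify every C-terminal missense and every stop-gain variant.

    Variants are evaluated per carrying isoform and rolled up with
    precedence disrupts > creates > neutral (the any-splice-variant
    rule).  Per-variant failures are logged and marked ``skipped``,
    never fatal.  Stop-gain bookkeeping also collects the predicted
    PDZ-mediated interactions suppressed by truncation: unique
    (domain, protein) pairs where the wild-type score exceeds s_max and
    the truncated score falls below s_min.
    """
    cache = _ScoreCache(pwms)
    by_protein: dict[str, list[ProteinIsoform]] = {}
    for iso in proteome:
        by_protein.setdefault(iso.protein_id, []).append(iso)
    cterm_by_iso = {
        c.key: c for c in extract_ctermini(proteome, window=window)
    }

    rows = []
    results = []
    affected: set[tuple[str, str]] = set()
    counts = {
        "n_variants": len(variants),
        "n_missense_cterm": 0,
        "n_not_cterminal": 0,
        "n_disrupt": 0,
        "n_create": 0,
        "n_neutral": 0,
        "n_stopgain": 0,
        "n_stopgain_disrupt": 0,
        "n_stopgain_create": 0,
        "n_skipped": 0,
        "n_affected_interactions": 0,
    }

    for var in variants:
        try:
            isoforms = by_protein.get(var.protein_id, [])
            if not any(i.isoform_id == var.isoform_id for i in isoforms):
                raise ValueError(
                    f"isoform {var.protein_id}|{var.isoform_id} not found"
                )
            carrying = [
                iso
                for iso in isoforms
                if 1 <= var.position <= len(iso.sequence)
                and iso.sequence[var.position - 1] == var.ref_aa
            ]
            if not any(i.isoform_id == var.isoform_id for i in carrying):
                named = next(
                    i for i in isoforms if i.isoform_id == var.isoform_id
                )
                if var.position > len(named.sequence):
                    raise ValueError(
                        f"position {var.position} out of range for {named.key}"
                    )
                raise ValueError(
                    f"reference residue mismatch at {named.key}:{var.position}"
                )

            if var.kind == "missense":
                _screen_missense(
                    var, carrying, cterm_by_iso, cache, config, window,
                    rows, results, counts,
                )
            else:
                _screen_stopgain(
                    var, carrying, cterm_by_iso, cache, config, window,
                    rows, results, counts, affected,
                )
        except ValueError as exc:
            logger.warning("variant %s skipped: %s", var.variant_id, exc)
            counts["n_skipped"] += 1
            rows.append(
                dict.fromkeys(CLASSIFICATION_COLUMNS)
                | {
                    "variant_id": var.variant_id,
                    "protein_id": var.protein_id,
                    "isoform_id": var.isoform_id,
                    "kind": var.kind,
                    "verdict": "skipped",
                }
            )

    counts["n_affected_interactions"] = len(affected)
    frame = pd.DataFrame(rows, columns=CLASSIFICATION_COLUMNS)
    return ScreenReport(
        rows=frame, results=results, summary=counts, affected_interactions=affected
    )


def _rollup(per_iso: list[tuple[CTerminus, CTerminus, ClassificationResult]],
            var, config, rows, results, counts, kind_counts_prefix=""):
    disrupt_all = tuple(
        d for _, _, r in per_iso for d in r.disrupt_domains
    )
    create_all = tuple(
        d for _, _, r in per_iso for d in r.create_domains
    )
    verdict = (
        "disrupts" if disrupt_all else ("creates" if create_all else "neutral")
    )
    # report the isoform/domain pair with the largest wt-mut score swing
    best = None
    for wt_ct, mut_ct, res in per_iso:
        pool = (
            res.disrupt_domains
            if verdict == "disrupts"
            else res.create_domains if verdict == "creates" else res.wt_scores
        )
        for dom in pool:
            wt_s, mut_s = res.wt_scores[dom], res.mut_scores[dom]
            # -inf wild-type and mutant scores (kappa = 0) give no swing
            swing = 0.0 if wt_s == mut_s else abs(wt_s - mut_s)
            if best is None or swing > best[0]:
                best = (swing, wt_ct, mut_ct, dom, res)
    _, wt_ct, mut_ct, dom, res = best
    rows.append(
        {
            "variant_id": var.variant_id,
            "protein_id": var.protein_id,
            "isoform_id": wt_ct.isoform_id,
            "kind": var.kind,
            "wt_cterm": wt_ct.sequence,
            "mut_cterm": mut_ct.sequence,
            "best_domain": dom,
            "s_wt": res.wt_scores[dom],
            "s_mut": res.mut_scores[dom],
            "verdict": verdict,
        }
    )
    merged_wt = {f"{c.isoform_id}:{d}": r.wt_scores[d]
                 for c, _, r in per_iso for d in r.wt_scores}
    merged_mut = {f"{c.isoform_id}:{d}": r.mut_scores[d]
                  for c, _, r in per_iso for d in r.mut_scores}
    results.append(
        ClassificationResult(
            variant_id=var.variant_id,
            wt_scores=merged_wt,
            mut_scores=merged_mut,
            verdict=verdict,
            disrupt_domains=disrupt_all,
            create_domains=create_all,
        )
    )
    return verdict


def _screen_missense(var, carrying, cterm_by_iso, cache, config, window,
                     rows, results, counts):
    per_iso = []
    for iso in carrying:
        ct = cterm_by_iso[iso.key]
        if not ct.start_position <= var.position <= len(iso.sequence):
            continue
        mut_ct = mutate_cterm(ct, var)
        res = classify_variant(
            cache.as_dict(ct.sequence),
            cache.as_dict(mut_ct.sequence),
            config,
            variant_id=var.variant_id,
        )
        per_iso.append((ct, mut_ct, res))
    if not per_iso:
        counts["n_not_cterminal"] += 1
        return
    counts["n_missense_cterm"] += 1
    verdict = _rollup(per_iso, var, config, rows, results, counts)
    counts[
        {"disrupts": "n_disrupt", "creates": "n_create", "neutral": "n_neutral"}[
            verdict
        ]
    ] += 1


def _screen_stopgain(var, carrying, cterm_by_iso, cache, config, window,
                     rows, results, counts, affected):
    per_iso = []
    for iso in carrying:
        mut_ct = truncate_at_stop(iso, var, window=window)
        ct = cterm_by_iso[iso.key]
        res = classify_variant(
            cache.as_dict(ct.sequence),
            cache.as_dict(mut_ct.sequence),
            config,
            variant_id=var.variant_id,
        )
        per_iso.append((ct, mut_ct, res))
        for dom in res.disrupt_domains:
            affected.add((dom, iso.protein_id))
    if not per_iso:
        raise ValueError("stop-gain variant carried by no isoform")
    counts["n_stopgain"] += 1
    verdict = _rollup(per_iso, var, config, rows, results, counts)
    if verdict == "disrupts":
        counts["n_stopgain_disrupt"] += 1
    elif verdict == "creates":
        counts["n_stopgain_create"] += 1


# ---------------------------------------------------------------------------
# Variant table I/O

def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(VARIANT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return [
        VariantRecord(
            variant_id=row.variant_id,
            protein_id=row.protein_id,
            isoform_id=row.isoform_id,
            position=int(row.position),
            ref_aa=row.ref_aa,
            alt_aa=row.alt_aa,
            kind=row.kind,
        )
        for row in frame.itertuples()
    ]


def write_variants_tsv(variants: Sequence[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "variant_id": v.variant_id,
                "protein_id": v.protein_id,
                "isoform_id": v.isoform_id,
                "position": v.position,
                "ref_aa": v.ref_aa,
                "alt_aa": v.alt_aa,
                "kind": v.kind,
            }
            for v in variants
        ],
        columns=VARIANT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
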