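"""Synthetic peptides, proteomes, annotations, variants and gold standards.

Everything the screen consumes can be generated here with known ground
truth, so the full pipeline runs and is validated without external
databases.  Ground-truth PWMs are "designed": every column has a peak
residue (p = 0.9), a secondary residue (p = 0.095) and a poison residue
(p = 1e-9), the remaining 17 residues sharing the leftover mass.  The
large peak/poison log-ratio (~9 decades) is what makes single-residue
variants able to jump the whole confidence band [S_min, S_max] with a
comfortable margin; real phage-display PWMs are softer, so planted
variants here are easier than typical real ones by construction.

Planted sequence classes:

* motif proteins     — suffix = consensus with 1-2 positions degraded to
                       the secondary residue (score ~ -1.3 .. -2.3);
* near-motif proteins — one further position carries the poison residue
                       (score < -10): one substitution back to the peak
                       creates a motif;
* background         — uniform-random residues, C-terminus rejected and
                       redrawn if any domain scores it above
                       S_min - margin.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, MOTIF_WINDOW, N_AA
from .proteome import (
    EXTRACELLULAR_TERMS,
    MITO_TERM,
    RESCUE_TERM,
    ProteinIsoform,
    filter_compartments,
    write_proteome_fasta,
)
from .pwm import PWM, PeptideAlignment, position_information_content, score_cterm
from .variants import (
    ClassificationConfig,
    VariantRecord,
    classify_variant,
    mutate_cterm,
    truncate_at_stop,
    write_variants_tsv,
)
from .proteome import CTerminus, extract_ctermini

logger = logging.getLogger(__name__)

_MAX_TRIES = 200


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic study: PWMs, planted proteins, variants."""

    pwms: list
    motif_proteins: list = field(default_factory=list)
    near_motif_proteins: list = field(default_factory=list)
    variants: list = field(default_factory=list)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def intended_verdicts(self) -> dict:
        return {v["variant_id"]: v["intended"] for v in self.variants}

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "pwms": [p.to_dict() for p in self.pwms],
            "motif_proteins": self.motif_proteins,
            "near_motif_proteins": self.near_motif_proteins,
            "variants": self.variants,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def make_designed_pwms(
    n_domains: int = 5,
    seed: int = 0,
    peak: float = 0.9,
    secondary: float = 0.095,
    poison: float = 1e-9,
) -> list[PWM]:
    """Sharp synthetic specificity models with a near-forbidden residue.

    Column structure (peak, secondary, poison, 17 x rest) gives planted
    variants deterministic score jumps: consensus -> poison changes one
    position's log10 probability by ~ -8.95.
    """
    rng = np.random.default_rng(seed)
    rest = (1.0 - peak - secondary - poison) / (N_AA - 3)
    if rest <= 0:
        raise ValueError("peak + secondary + poison must leave mass for the rest")
    pwms = []
    for d in range(n_domains):
        probs = np.full((MOTIF_WINDOW, N_AA), rest)
        for n in range(MOTIF_WINDOW):
            peak_i, secondary_i, poison_i = rng.choice(N_AA, size=3, replace=False)
            probs[n, peak_i] = peak
            probs[n, secondary_i] = secondary
            probs[n, poison_i] = poison
        probs /= probs.sum(axis=1, keepdims=True)
        ic = np.array([position_information_content(row) for row in probs])
        pwms.append(PWM(domain_id=f"DOM{d + 1}", probs=probs, ic=ic))
    return pwms


def simulate_peptides(
    true_pwm: PWM, n: int, seed: int = 0
) -> PeptideAlignment:
    """Sample n 7-mer peptides position-independently from the PWM rows."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    # draw per offset, then assemble N-to-C (offset 6 first)
    cols = [
        rng.choice(N_AA, size=n, p=true_pwm.probs[off])
        for off in range(MOTIF_WINDOW)
    ]
    peptides = [
        "".join(AMINO_ACIDS[cols[off][i]] for off in range(MOTIF_WINDOW - 1, -1, -1))
        for i in range(n)
    ]
    return PeptideAlignment(domain_id=true_pwm.domain_id, peptides=peptides)


def _random_sequence(rng, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, N_AA, size=length))


def _max_score(pwms: Sequence[PWM], seq: str) -> float:
    return max(score_cterm(p, seq) for p in pwms)


def _background_suffix(rng, pwms, ceiling: float) -> str:
    """Random 7-mer whose best score over all domains stays below ceiling."""
    for _ in range(_MAX_TRIES):
        seq = _random_sequence(rng, MOTIF_WINDOW)
        if _max_score(pwms, seq) < ceiling:
            return seq
    raise RuntimeError("could not draw a background C-terminus below the ceiling")


def _role_residues(pwm: PWM):
    """Per-offset (peak, secondary, poison) residue letters of a designed PWM."""
    order = np.argsort(pwm.probs, axis=1)
    peak = [AMINO_ACIDS[order[n, -1]] for n in range(MOTIF_WINDOW)]
    secondary = [AMINO_ACIDS[order[n, -2]] for n in range(MOTIF_WINDOW)]
    poison = [AMINO_ACIDS[order[n, 0]] for n in range(MOTIF_WINDOW)]
    return peak, secondary, poison


def _assemble_from_offsets(residue_by_offset: dict) -> str:
    return "".join(residue_by_offset[n] for n in range(MOTIF_WINDOW - 1, -1, -1))


def simulate_proteome(
    n_proteins: int = 100,
    length_range: tuple[int, int] = (50, 300),
    motif_fraction: float = 0.25,
    pwms: Sequence[PWM] | None = None,
    isoform_rate: float = 0.1,
    seed: int = 0,
    near_motif_fraction: float = 0.15,
    margin: float = 1.0,
    config: ClassificationConfig = ClassificationConfig(),
    extracellular_fraction: float = 0.05,
    mito_fraction: float = 0.05,
) -> tuple[list[ProteinIsoform], SyntheticTruth]:
    """Random proteome with planted motif and near-motif C-termini.

    ``motif_fraction`` of proteins receive a suffix scoring above
    S_max + margin for one ground-truth domain (and at most S_max for
    every other); ``near_motif_fraction`` receive a poisoned motif
    scoring below S_min - margin that one substitution can rescue.
    ``isoform_rate`` adds a second isoform with a background suffix.
    GO compartment terms go to a slice of the plain background proteins
    so the extracellular/mitochondrial filter has work to do.
    """
    if not 0.0 <= motif_fraction <= 1.0:
        raise ValueError("motif_fraction must lie in [0, 1]")
    if motif_fraction + near_motif_fraction > 1.0:
        raise ValueError("motif_fraction + near_motif_fraction exceed 1")
    rng = np.random.default_rng(seed)
    if pwms is None:
        pwms = make_designed_pwms(seed=int(rng.integers(2**31)))
    pwms = list(pwms)
    roles = {p.domain_id: _role_residues(p) for p in pwms}
    lo, hi = length_range
    if lo < MOTIF_WINDOW + 12:
        raise ValueError(f"minimum protein length must be >= {MOTIF_WINDOW + 12}")

    n_motif = int(round(motif_fraction * n_proteins))
    n_near = int(round(near_motif_fraction * n_proteins))
    background_ceiling = config.s_min - margin

    truth = SyntheticTruth(
        pwms=pwms,
        seed=seed,
        params={
            "n_proteins": n_proteins,
            "length_range": list(length_range),
            "motif_fraction": motif_fraction,
            "near_motif_fraction": near_motif_fraction,
            "isoform_rate": isoform_rate,
            "margin": margin,
            "s_min": config.s_min,
            "s_max": config.s_max,
        },
    )

    proteome: list[ProteinIsoform] = []
    annotations: dict[str, set] = {}
    background_ids: list[str] = []

    for idx in range(n_proteins):
        protein_id = f"P{idx + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        body = _random_sequence(rng, length - MOTIF_WINDOW)

        if idx < n_motif:
            suffix, meta = _plant_motif(
                rng, pwms, roles, config, margin, poisoned=False
            )
            truth.motif_proteins.append(
                {"protein_id": protein_id, "isoform_id": "i1", **meta}
            )
        elif idx < n_motif + n_near:
            suffix, meta = _plant_motif(
                rng, pwms, roles, config, margin, poisoned=True
            )
            truth.near_motif_proteins.append(
                {"protein_id": protein_id, "isoform_id": "i1", **meta}
            )
        else:
            suffix = _background_suffix(rng, pwms, background_ceiling)
            background_ids.append(protein_id)

        proteome.append(
            ProteinIsoform(protein_id, "i1", body + suffix)
        )
        if rng.random() < isoform_rate:
            alt_suffix = _background_suffix(rng, pwms, background_ceiling)
            proteome.append(
                ProteinIsoform(protein_id, "i2", body + alt_suffix)
            )

    # compartment annotations on plain background proteins only, so the
    # filter never deletes planted truth
    n_extra = int(round(extracellular_fraction * n_proteins))
    n_mito = int(round(mito_fraction * n_proteins))
    if n_extra + n_mito > len(background_ids):
        raise ValueError("not enough background proteins for GO annotation")
    annotated = rng.permutation(background_ids)[: n_extra + n_mito]
    for i, pid in enumerate(annotated):
        if i < n_extra:
            term = sorted(EXTRACELLULAR_TERMS)[int(rng.integers(2))]
            terms = {term}
            if i % 2 == 0:
                terms.add(RESCUE_TERM)  # plasma-membrane-part rescue
        else:
            terms = {MITO_TERM}
        annotations[pid] = terms
    proteome = [
        ProteinIsoform(
            iso.protein_id,
            iso.isoform_id,
            iso.sequence,
            frozenset(annotations.get(iso.protein_id, ())),
        )
        for iso in proteome
    ]
    truth.params["n_motif"] = n_motif
    truth.params["n_near_motif"] = n_near
    return proteome, truth


def _plant_motif(rng, pwms, roles, config, margin, poisoned: bool):
    """Suffix from one domain's consensus with degradations (and poison)."""
    for _ in range(_MAX_TRIES):
        pwm = pwms[int(rng.integers(len(pwms)))]
        peak, secondary, poison = roles[pwm.domain_id]
        n_degrade = int(rng.integers(1, 3))
        special = rng.choice(MOTIF_WINDOW, size=n_degrade + (1 if poisoned else 0),
                             replace=False)
        degrade = set(int(x) for x in special[:n_degrade])
        poison_offset = int(special[-1]) if poisoned else None
        residues = {}
        for n in range(MOTIF_WINDOW):
            if n == poison_offset:
                residues[n] = poison[n]
            elif n in degrade:
                residues[n] = secondary[n]
            else:
                residues[n] = peak[n]
        seq = _assemble_from_offsets(residues)
        matched = score_cterm(pwm, seq)
        others = [score_cterm(p, seq) for p in pwms if p.domain_id != pwm.domain_id]
        if poisoned:
            # one substitution (poison -> peak) must create a motif
            rescued = dict(residues)
            rescued[poison_offset] = peak[poison_offset]
            rescued_seq = _assemble_from_offsets(rescued)
            ok = (
                matched < config.s_min - margin
                and score_cterm(pwm, rescued_seq) > config.s_max + margin
                and all(s <= config.s_max for s in others)
                and _max_score(pwms, seq) < config.s_min - margin
            )
        else:
            ok = matched > config.s_max + margin and all(
                s <= config.s_max for s in others
            )
        if ok:
            meta = {
                "domain_id": pwm.domain_id,
                "degraded_offsets": sorted(degrade),
                "score": matched,
            }
            if poisoned:
                meta["poison_offset"] = poison_offset
            return seq, meta
    raise RuntimeError("could not plant a motif suffix satisfying the margins")


# ---------------------------------------------------------------------------
# Variant planting

def simulate_variants(
    proteome: Sequence[ProteinIsoform],
    truth: SyntheticTruth,
    n_disrupt: int = 20,
    n_create: int = 10,
    n_neutral: int = 50,
    n_stopgain: int = 10,
    seed: int = 0,
    stopgain_motif_fraction: float = 0.5,
    margin: float | None = None,
    window: int = MOTIF_WINDOW,
) -> tuple[list[VariantRecord], SyntheticTruth]:
    """Plant variants with verified intended verdicts.

    Disrupt variants substitute a consensus residue of a planted motif
    with the domain's poison residue; create variants revert a
    near-motif protein's poison residue to the peak; neutral variants
    hit background C-termini or fall outside the window; stop-gains
    truncate motif-bearing and plain proteins in the stated proportion.
    Every planted variant is re-scored against all ground-truth PWMs
    and its intended verdict verified (with threshold margins for the
    matched domain) before being accepted.
    """
    rng = np.random.default_rng(seed)
    config = ClassificationConfig(
        s_min=truth.params.get("s_min", ClassificationConfig().s_min),
        s_max=truth.params.get("s_max", ClassificationConfig().s_max),
    )
    if margin is None:
        margin = float(truth.params.get("margin", 1.0))
    pwms = list(truth.pwms)
    roles = {p.domain_id: _role_residues(p) for p in pwms}

    surviving, _ = filter_compartments(proteome)
    iso_index = {iso.key: iso for iso in surviving}
    surviving_ids = {iso.protein_id for iso in surviving}
    ct_index = {c.key: c for c in extract_ctermini(surviving, window=window)}

    used_positions: dict[str, set] = {}
    variants: list[VariantRecord] = []
    counter = [0]

    def next_id() -> str:
        counter[0] += 1
        return f"v{counter[0]:04d}"

    def reserve(key: str, position: int) -> bool:
        taken = used_positions.setdefault(key, set())
        if position in taken:
            return False
        taken.add(position)
        return True

    def verdict_of(iso, var) -> tuple[str, dict, dict]:
        ct = ct_index[iso.key]
        if var.kind == "missense":
            mut = mutate_cterm(ct, var)
        else:
            mut = truncate_at_stop(iso, var, window=window)
        wt_scores = {p.domain_id: score_cterm(p, ct.sequence) for p in pwms}
        mut_scores = {p.domain_id: score_cterm(p, mut.sequence) for p in pwms}
        res = classify_variant(wt_scores, mut_scores, config, var.variant_id)
        return res.verdict, wt_scores, mut_scores

    # --- disrupt: motif protein, consensus residue -> poison ----------------
    entries = [e for e in truth.motif_proteins if e["protein_id"] in surviving_ids]
    planted = 0
    attempts = 0
    while planted < n_disrupt:
        if not entries or attempts > n_disrupt * _MAX_TRIES:
            raise ValueError(
                f"infeasible request: planted {planted} of {n_disrupt} disrupt "
                f"variants; {len(entries)} motif proteins available"
            )
        attempts += 1
        entry = entries[attempts % len(entries)]
        iso = iso_index[f"{entry['protein_id']}|{entry['isoform_id']}"]
        peak, secondary, poison = roles[entry["domain_id"]]
        free = [
            n
            for n in range(MOTIF_WINDOW)
            if n not in entry["degraded_offsets"]
        ]
        offset = int(rng.choice(free))
        position = len(iso.sequence) - offset
        if not reserve(iso.key, position):
            continue
        var = VariantRecord(
            next_id(), iso.protein_id, iso.isoform_id, position,
            ref_aa=iso.sequence[position - 1], alt_aa=poison[offset],
            kind="missense",
        )
        verdict, wt_s, mut_s = verdict_of(iso, var)
        dom = entry["domain_id"]
        if (
            verdict == "disrupts"
            and wt_s[dom] > config.s_max + margin
            and mut_s[dom] < config.s_min - margin
        ):
            variants.append(var)
            truth.variants.append(
                {"variant_id": var.variant_id, "intended": "disrupts",
                 "kind": "missense", "protein_id": iso.protein_id,
                 "domain_id": dom}
            )
            planted += 1
        else:
            used_positions[iso.key].discard(position)

    # --- create: near-motif protein, poison residue -> peak -----------------
    near = [e for e in truth.near_motif_proteins if e["protein_id"] in surviving_ids]
    if len(near) < n_create:
        raise ValueError(
            f"infeasible request: {n_create} create variants requested but only "
            f"{len(near)} near-motif proteins available"
        )
    for entry in near[:n_create]:
        iso = iso_index[f"{entry['protein_id']}|{entry['isoform_id']}"]
        peak, secondary, poison = roles[entry["domain_id"]]
        offset = entry["poison_offset"]
        position = len(iso.sequence) - offset
        reserve(iso.key, position)
        var = VariantRecord(
            next_id(), iso.protein_id, iso.isoform_id, position,
            ref_aa=iso.sequence[position - 1], alt_aa=peak[offset],
            kind="missense",
        )
        verdict, wt_s, mut_s = verdict_of(iso, var)
        dom = entry["domain_id"]
        if not (
            verdict == "creates"
            and wt_s[dom] < config.s_min - margin
            and mut_s[dom] > config.s_max + margin
        ):
            raise ValueError(
                f"planted create variant {var.variant_id} failed verification"
            )
        variants.append(var)
        truth.variants.append(
            {"variant_id": var.variant_id, "intended": "creates",
             "kind": "missense", "protein_id": iso.protein_id,
             "domain_id": dom}
        )

    # --- neutral: background C-termini and out-of-window positions ----------
    planted_ids = {e["protein_id"] for e in truth.motif_proteins}
    planted_ids |= {e["protein_id"] for e in truth.near_motif_proteins}
    background = [
        iso for iso in surviving
        if iso.protein_id not in planted_ids and iso.isoform_id == "i1"
    ]
    if not background and n_neutral:
        raise ValueError("infeasible request: no background proteins for neutrals")
    n_inside = n_neutral // 2
    for i in range(n_neutral):
        ok = False
        for _ in range(_MAX_TRIES):
            iso = background[int(rng.integers(len(background)))]
            n = len(iso.sequence)
            if i < n_inside:
                position = int(n - rng.integers(0, window))
            else:
                position = int(rng.integers(1, n - window + 1))
            if not reserve(iso.key, position):
                continue
            ref = iso.sequence[position - 1]
            alt = AMINO_ACIDS[int(rng.integers(N_AA))]
            if alt == ref:
                used_positions[iso.key].discard(position)
                continue
            var = VariantRecord(
                next_id(), iso.protein_id, iso.isoform_id, position,
                ref_aa=ref, alt_aa=alt, kind="missense",
            )
            if position > n - window:
                verdict, _, _ = verdict_of(iso, var)
                if verdict != "neutral":
                    used_positions[iso.key].discard(position)
                    continue
            variants.append(var)
            truth.variants.append(
                {"variant_id": var.variant_id, "intended": "neutral",
                 "kind": "missense", "protein_id": iso.protein_id}
            )
            ok = True
            break
        if not ok:
            raise ValueError(
                f"infeasible request: placed {i} of {n_neutral} neutral variants"
            )

    # --- stop gains ----------------------------------------------------------
    n_stop_motif = int(round(stopgain_motif_fraction * n_stopgain))
    stop_hosts = [
        ("disrupts", entries[i % len(entries)]) for i in range(n_stop_motif)
    ] if n_stop_motif else []
    if n_stop_motif and not entries:
        raise ValueError("infeasible request: stop-gains need motif proteins")
    for i in range(n_stopgain - n_stop_motif):
        if not background:
            raise ValueError("infeasible request: stop-gains need background proteins")
        stop_hosts.append(("neutral", None))

    for intended, entry in stop_hosts:
        ok = False
        for _ in range(_MAX_TRIES):
            if entry is not None:
                iso = iso_index[f"{entry['protein_id']}|{entry['isoform_id']}"]
            else:
                iso = background[int(rng.integers(len(background)))]
            n = len(iso.sequence)
            gap = int(rng.integers(2, 11))
            position = n - window - gap
            if position < window + 1 or not reserve(iso.key, position):
                continue
            var = VariantRecord(
                next_id(), iso.protein_id, iso.isoform_id, position,
                ref_aa=iso.sequence[position - 1], alt_aa="", kind="stop_gain",
            )
            verdict, wt_s, mut_s = verdict_of(iso, var)
            if verdict != intended:
                used_positions[iso.key].discard(position)
                continue
            variants.append(var)
            truth.variants.append(
                {"variant_id": var.variant_id, "intended": intended,
                 "kind": "stop_gain", "protein_id": iso.protein_id}
            )
            ok = True
            break
        if not ok:
            raise ValueError(
                f"infeasible request: could not place a {intended} stop-gain"
            )

    return variants, truth


# ---------------------------------------------------------------------------
# Bundles: everything the pipeline consumes, on disk

def simulate_bundle(
    outdir: str | Path,
    seed: int = 0,
    n_proteins: int = 100,
    n_domains: int = 5,
    n_peptides: int = 2000,
    n_disrupt: int = 20,
    n_create: int = 10,
    n_neutral: int = 50,
    n_stopgain: int = 10,
    n_gold_noise: int = 10,
    **proteome_kwargs,
) -> SyntheticTruth:
    """Write a complete synthetic input bundle and its truth.json.

    Files: peptides/<domain>.txt, proteome.fasta, annotations.tsv,
    variants.tsv, gold_pairs.tsv, truth.json — the same dialects the
    pipeline consumes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    pwms = make_designed_pwms(n_domains=n_domains, seed=int(seeds[0]))
    proteome, truth = simulate_proteome(
        n_proteins=n_proteins, pwms=pwms, seed=int(seeds[1]), **proteome_kwargs
    )
    variants, truth = simulate_variants(
        proteome, truth,
        n_disrupt=n_disrupt, n_create=n_create,
        n_neutral=n_neutral, n_stopgain=n_stopgain,
        seed=int(seeds[2]),
    )

    pep_dir = outdir / "peptides"
    pep_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(int(seeds[3]))
    for pwm in pwms:
        aln = simulate_peptides(pwm, n_peptides, seed=int(rng.integers(2**31)))
        (pep_dir / f"{pwm.domain_id}.txt").write_text(
            "\n".join(aln.peptides) + "\n"
        )

    write_proteome_fasta(proteome, outdir / "proteome.fasta")
    with open(outdir / "annotations.tsv", "w") as fh:
        for iso in proteome:
            if iso.isoform_id != "i1":
                continue
            for term in sorted(iso.go_terms):
                fh.write(f"{iso.protein_id}\t{term}\n")
    write_variants_tsv(variants, outdir / "variants.tsv")

    # gold standard: the true motif interactions plus random noise pairs
    gold = [
        (e["domain_id"], e["protein_id"]) for e in truth.motif_proteins
    ]
    protein_ids = sorted({iso.protein_id for iso in proteome})
    for _ in range(n_gold_noise):
        gold.append(
            (
                pwms[int(rng.integers(len(pwms)))].domain_id,
                protein_ids[int(rng.integers(len(protein_ids)))],
            )
        )
    with open(outdir / "gold_pairs.tsv", "w") as fh:
        for d, p in gold:
            fh.write(f"{d}\t{p}\n")

    truth.to_json(outdir / "truth.json")
    return truth
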