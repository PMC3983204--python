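"""End-to-end screen orchestration with reproducible configuration.

``run_screen`` executes build-PWMs -> compartment filter -> C-terminus
extraction -> scoring -> variant classification -> statistics, and
writes stable TSV/JSON outputs plus a manifest (config, seed, input
checksums).  Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .proteome import (
    extract_ctermini,
    filter_compartments,
    read_go_annotations,
    read_proteome_fasta,
)
from .pwm import build_pwm, read_peptide_dir, score_all, write_pwms_json
from .stats import (
    affected_interaction_fisher,
    binomial_enrichment,
    default_threshold_grid,
    gold_standard_fisher,
    randomized_disruption_fraction,
    sweep_motif_thresholds,
)
from .variants import (
    ClassificationConfig,
    read_variants_tsv,
    screen_variants,
)
from .alphabet import MOTIF_WINDOW

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    peptides_dir: str
    proteome_path: str
    variants_path: str
    annotations_path: str | None = None
    gold_pairs_path: str | None = None
    kappa: float = 1.0
    pseudocount_mode: str = "proportional"
    window: int = MOTIF_WINDOW
    s_min: float = -8.3
    s_max: float = -6.4
    threshold_start: float = -12.0
    threshold_stop: float = -4.0
    threshold_step: float = 0.1
    n_reps: int = 1000
    seed: int = 0
    outdir: str = "pdzscan_out"

    def __post_init__(self):
        if not self.s_min < self.s_max:
            raise ValueError(f"require s_min < s_max, got {self.s_min} >= {self.s_max}")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_screen(config: RunConfig) -> dict:
    """Run the complete screen; returns the report also written to disk."""
    for required in (config.peptides_dir, config.proteome_path, config.variants_path):
        if not Path(required).exists():
            raise FileNotFoundError(f"input not found: {required}")
    for optional in (config.annotations_path, config.gold_pairs_path):
        if optional is not None and not Path(optional).exists():
            raise FileNotFoundError(f"input not found: {optional}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str):
        path = outdir / name
        written.append(path)
        return path

    try:
        # 1. specificity models
        alignments = read_peptide_dir(config.peptides_dir)
        pwms = [
            build_pwm(a, config.kappa, config.pseudocount_mode) for a in alignments
        ]
        write_pwms_json(pwms, emit("pwms.json"))

        # 2. proteome + compartment filter
        annotations = (
            read_go_annotations(config.annotations_path)
            if config.annotations_path
            else {}
        )
        proteome = read_proteome_fasta(config.proteome_path, annotations=annotations)
        filtered, filter_report = filter_compartments(proteome)
        filter_report.to_csv(emit("filter_report.tsv"), sep="\t", index=False)

        # 3. C-termini and scores
        ctermini = extract_ctermini(filtered, window=config.window)
        score_matrix = score_all(pwms, ctermini)

        # 4. variant screen
        variants = read_variants_tsv(config.variants_path)
        cls_config = ClassificationConfig(s_min=config.s_min, s_max=config.s_max)
        screen = screen_variants(
            filtered, variants, pwms, cls_config, window=config.window
        )
        screen.rows.to_csv(emit("classifications.tsv"), sep="\t", index=False)

        # 5. statistics
        report = _compute_statistics(
            config, filtered, ctermini, score_matrix, variants, screen,
            cls_config, pwms,
        )
        (emit("enrichment.json")).write_text(
            json.dumps(report["enrichment"], indent=1, sort_keys=True)
        )
        report["sweep"].to_csv(emit("sweep.tsv"), sep="\t", index=False)
        report["randomization"].to_csv(emit("randomization.tsv"), sep="\t", index=False)

        manifest = {
            "config": config.to_dict(),
            "inputs": {
                "proteome": _sha256(config.proteome_path),
                "variants": _sha256(config.variants_path),
                "peptides": {
                    p.name: _sha256(p)
                    for p in sorted(Path(config.peptides_dir).iterdir())
                    if p.is_file()
                },
            },
            "summary": screen.summary,
        }
        if config.annotations_path:
            manifest["inputs"]["annotations"] = _sha256(config.annotations_path)
        emit("manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

        return {
            "summary": screen.summary,
            "enrichment": report["enrichment"],
            "outdir": str(outdir),
            "n_domains": len(pwms),
            "n_isoforms": len(filtered),
        }
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _read_gold_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        pairs.append((parts[0], parts[1]))
    return pairs


def _compute_statistics(
    config, filtered, ctermini, score_matrix, variants, screen,
    cls_config, pwms,
) -> dict:
    lengths = {c.key: len(c) for c in ctermini}
    region_aa = sum(lengths.values())
    total_aa = sum(len(i.sequence) for i in filtered)

    missense = [v for v in variants if v.kind == "missense"]
    by_protein: dict[str, list] = {}
    for iso in filtered:
        by_protein.setdefault(iso.protein_id, []).append(iso)
    # one entry per (variant, carrying isoform) whose window is hit
    cterm_hits: list[str] = []
    n_cterm_missense = 0
    for var in missense:
        in_ct = False
        for iso in by_protein.get(var.protein_id, []):
            n = len(iso.sequence)
            if not 1 <= var.position <= n:
                continue
            if iso.sequence[var.position - 1] != var.ref_aa:
                continue
            if var.position >= n - (config.window - 1):
                cterm_hits.append(f"{iso.protein_id}|{iso.isoform_id}")
                in_ct = True
        if in_ct:
            n_cterm_missense += 1

    enrichment: dict = {}
    if missense and region_aa and n_cterm_missense <= region_aa:
        enrichment["cterm_binomial"] = binomial_enrichment(
            n_cterm_missense, len(missense), region_aa, total_aa, sidedness="two"
        ).to_dict()

    sweep = sweep_motif_thresholds(
        score_matrix,
        ctermini,
        cterm_hits,
        threshold_grid=default_threshold_grid(
            config.threshold_start, config.threshold_stop, config.threshold_step
        ),
    )
    randomization = randomized_disruption_fraction(
        missense,
        filtered,
        pwms,
        cls_config,
        n_reps=config.n_reps,
        seed=config.seed,
        window=config.window,
    )

    if config.gold_pairs_path:
        gold = _read_gold_pairs(config.gold_pairs_path)
        try:
            enrichment["gold_fisher"] = gold_standard_fisher(
                score_matrix, gold, s_min=cls_config.s_min
            ).to_dict()
        except ValueError as exc:
            logger.warning("gold-standard Fisher test skipped: %s", exc)
        if screen.affected_interactions:
            enrichment["stopgain_gold_fisher"] = affected_interaction_fisher(
                screen.affected_interactions,
                gold,
                n_proteins=len(by_protein),
                domains=[p.domain_id for p in pwms],
            ).to_dict()

    return {
        "enrichment": enrichment,
        "sweep": sweep.table,
        "randomization": randomization.to_frame(),
        "cterm_hits": cterm_hits,
    }
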