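"""Proteome parsing, compartment filtering, and C-terminal windows.

PDZ domains act mainly in the cytoplasm, so extracellular-matrix /
extracellular-space proteins (unless also annotated as plasma-membrane
part) and mitochondrial-part proteins are removed before scanning.
Every splice isoform contributes its own C-terminal window: a variant
counts as C-terminal if it falls in the last seven residues of ANY
isoform carrying it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alphabet import MOTIF_WINDOW, is_valid_sequence, validate_sequence

logger = logging.getLogger(__name__)

# GO categories of the compartment filter
EXTRACELLULAR_TERMS = frozenset({"GO:0031012", "GO:0005615"})
RESCUE_TERM = "GO:0044459"  # plasma membrane part: overrides extracellular
MITO_TERM = "GO:0044429"    # mitochondrial part: removed, no rescue

_GO_RE = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class ProteinIsoform:
    protein_id: str
    isoform_id: str
    sequence: str
    go_terms: frozenset = frozenset()

    def __post_init__(self):
        validate_sequence(self.sequence, context=f"isoform {self.key}")
        object.__setattr__(self, "go_terms", frozenset(self.go_terms))

    @property
    def key(self) -> str:
        return f"{self.protein_id}|{self.isoform_id}"


@dataclass(frozen=True)
class CTerminus:
    """Trailing window of one isoform, at most seven residues.

    ``start_position`` is the 1-based protein coordinate of the first
    window residue; internally PWM offsets count 0-based from the end.
    """

    protein_id: str
    isoform_id: str
    sequence: str
    start_position: int

    @property
    def key(self) -> str:
        return f"{self.protein_id}|{self.isoform_id}"

    def __len__(self) -> int:
        return len(self.sequence)


def read_proteome_fasta(
    path: str | Path,
    annotations: Mapping[str, set] | None = None,
    on_invalid: str = "skip",
) -> list[ProteinIsoform]:
    """Read isoforms from FASTA with ``protein_id|isoform_id`` headers.

    Records with non-standard residues are skipped with a warning
    (``on_invalid="skip"``, the default) or abort (``"raise"``).
    Headers without ``|`` use the whole id for both fields.
    """
    from Bio import SeqIO

    if on_invalid not in ("skip", "raise"):
        raise ValueError("on_invalid must be 'skip' or 'raise'")
    annotations = annotations or {}
    isoforms: list[ProteinIsoform] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        protein_id, _, isoform_id = header.partition("|")
        isoform_id = isoform_id or protein_id
        seq = str(rec.seq).upper()
        if not is_valid_sequence(seq):
            if on_invalid == "raise":
                validate_sequence(seq, context=f"isoform {header}")
            logger.warning("skipping unparseable record %s", header)
            continue
        isoforms.append(
            ProteinIsoform(
                protein_id=protein_id,
                isoform_id=isoform_id,
                sequence=seq,
                go_terms=frozenset(annotations.get(protein_id, ())),
            )
        )
    return isoforms


def write_proteome_fasta(isoforms: Sequence[ProteinIsoform], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iso in isoforms:
            fh.write(f">{iso.key}\n")
            for i in range(0, len(iso.sequence), 60):
                fh.write(iso.sequence[i : i + 60] + "\n")


def read_go_annotations(path: str | Path) -> dict[str, set]:
    """Two-column TSV (protein_id, GO id), one pair per line."""
    table: dict[str, set] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        protein_id, go_id = parts
        if not _GO_RE.match(go_id):
            raise ValueError(f"{path}:{lineno}: malformed GO ID {go_id!r}")
        table.setdefault(protein_id, set()).add(go_id)
    return table


def attach_annotations(
    proteome: Sequence[ProteinIsoform], annotations: Mapping[str, set]
) -> list[ProteinIsoform]:
    return [
        ProteinIsoform(
            iso.protein_id,
            iso.isoform_id,
            iso.sequence,
            frozenset(annotations.get(iso.protein_id, ())),
        )
        for iso in proteome
    ]


def filter_compartments(
    proteome: Sequence[ProteinIsoform],
    extracellular_terms: frozenset = EXTRACELLULAR_TERMS,
    rescue_term: str = RESCUE_TERM,
    mito_term: str = MITO_TERM,
) -> tuple[list[ProteinIsoform], pd.DataFrame]:
    """Drop extracellular (unless plasma-membrane-part) and mitochondrial proteins.

    Membership is by the literal term sets on each protein: no GO-graph
    propagation.  Unannotated proteins are retained.  Returns the
    filtered proteome and a per-removed-protein report with the removal
    reason.
    """
    for term in [*extracellular_terms, rescue_term, mito_term]:
        if not _GO_RE.match(term):
            raise ValueError(f"malformed GO ID {term!r}")

    removed: dict[str, str] = {}
    kept: list[ProteinIsoform] = []
    for iso in proteome:
        terms = iso.go_terms
        if mito_term in terms:
            removed[iso.protein_id] = "mitochondrial"
        elif (terms & extracellular_terms) and rescue_term not in terms:
            removed[iso.protein_id] = "extracellular"
        else:
            kept.append(iso)
    report = pd.DataFrame(
        sorted(removed.items()), columns=["protein_id", "reason"]
    )
    return kept, report


def extract_ctermini(
    proteome: Sequence[ProteinIsoform], window: int = MOTIF_WINDOW
) -> list[CTerminus]:
    """One C-terminal window per isoform (no suffix deduplication)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    out = []
    for iso in proteome:
        n = len(iso.sequence)
        w = min(window, n)
        out.append(
            CTerminus(
                protein_id=iso.protein_id,
                isoform_id=iso.isoform_id,
                sequence=iso.sequence[n - w :],
                start_position=n - w + 1,
            )
        )
    return out


@dataclass(frozen=True)
class CTermMappingReport:
    """Where a variant lands relative to each isoform's C-terminal window."""

    variant_id: str
    per_isoform: dict
    in_cterm: bool


def variant_in_cterm(
    variant, proteome: Sequence[ProteinIsoform], window: int = MOTIF_WINDOW
) -> CTermMappingReport:
    """Is the variant position inside the trailing window of any isoform?

    The variant's named isoform must exist and its reference residue
    must match; sibling isoforms of the same protein are consulted too
    (the variant "carries" onto every isoform where position and
    reference agree), and the overall flag is the OR over them.
    """
    named = None
    siblings = []
    for iso in proteome:
        if iso.protein_id != variant.protein_id:
            continue
        if iso.isoform_id == variant.isoform_id:
            named = iso
        else:
            siblings.append(iso)
    if named is None:
        raise ValueError(
            f"isoform {variant.protein_id}|{variant.isoform_id} not found"
        )
    if not 1 <= variant.position <= len(named.sequence):
        raise ValueError(
            f"position {variant.position} out of range for "
            f"{named.key} (length {len(named.sequence)})"
        )
    if named.sequence[variant.position - 1] != variant.ref_aa:
        raise ValueError(
            f"reference residue mismatch at {named.key}:{variant.position}: "
            f"sequence has {named.sequence[variant.position - 1]!r}, "
            f"variant states {variant.ref_aa!r}"
        )

    per_isoform: dict[str, bool] = {}
    for iso in [named, *siblings]:
        n = len(iso.sequence)
        if not 1 <= variant.position <= n:
            continue
        if iso.sequence[variant.position - 1] != variant.ref_aa:
            continue
        per_isoform[iso.isoform_id] = variant.position >= n - (window - 1)
    return CTermMappingReport(
        variant_id=getattr(variant, "variant_id", ""),
        per_isoform=per_isoform,
        in_cterm=any(per_isoform.values()),
    )
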