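"""Position weight matrices for PDZ C-terminal binding specificity.

A PDZ domain's specificity is modelled as a 7 x 20 probability matrix
built from phage-display peptides aligned at their C-terminus.  Matrix
positions are indexed by offset from the C-terminal residue (offset 0 =
last residue).  A C-terminal sequence j is scored against domain i as

    S_ij = sum_n log10 p_i[n][j(n)]

where j(n) is the residue of j at offset n.  Scores are <= 0; higher
means more similar to the domain's preferred motif.  The uniform
background score for a full 7-mer is 7 * log10(1/20) = -9.103.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS, MOTIF_WINDOW, N_AA, validate_sequence

logger = logging.getLogger(__name__)

MAX_BITS = float(np.log2(N_AA))  # 4.3219... bits, the IC of a one-hot column

PSEUDOCOUNT_MODES = ("proportional", "inverse", "flat")


@dataclass(frozen=True)
class PeptideAlignment:
    """Phage-display peptides for one PDZ domain, C-terminally aligned.

    ``domain_id`` follows the field convention: the host protein name,
    with a ``#k`` suffix when that protein contains several PDZ domains
    (e.g. ``MPDZ#2``).
    """

    domain_id: str
    peptides: tuple[str, ...]

    def __init__(self, domain_id: str, peptides: Iterable[str]):
        object.__setattr__(self, "domain_id", str(domain_id))
        object.__setattr__(self, "peptides", tuple(peptides))
        if not self.peptides:
            raise ValueError(f"empty alignment for domain {self.domain_id!r}")
        for pep in self.peptides:
            validate_sequence(pep, context=f"peptide (domain {self.domain_id})")
            if len(pep) > MOTIF_WINDOW:
                raise ValueError(
                    f"peptide {pep!r} longer than {MOTIF_WINDOW} residues "
                    f"(domain {self.domain_id})"
                )

    def __len__(self) -> int:
        return len(self.peptides)


@dataclass(frozen=True)
class PWM:
    """Per-domain specificity model: probabilities p[offset][residue].

    ``probs`` has shape (7, 20); every row sums to 1.  ``ic`` holds the
    raw per-position information content in bits (before smoothing),
    used both for sequence logos and for the information-content
    pseudocount.  Offsets with no observed residues carry the uniform
    row and zero information.
    """

    domain_id: str
    probs: np.ndarray
    ic: np.ndarray
    kappa: float = 0.0
    mode: str = "proportional"

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        ic = np.asarray(self.ic, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "ic", ic)
        if probs.shape != (MOTIF_WINDOW, N_AA):
            raise ValueError(f"PWM must be {MOTIF_WINDOW}x{N_AA}, got {probs.shape}")
        if (probs < 0).any():
            raise ValueError("PWM entries must be non-negative")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if ic.shape != (MOTIF_WINDOW,):
            raise ValueError("ic must have one entry per offset")
        if (ic < -1e-9).any() or (ic > MAX_BITS + 1e-9).any():
            raise ValueError(f"information content must lie in [0, {MAX_BITS:.4f}]")

    def to_dict(self) -> dict:
        return {
            "domain_id": self.domain_id,
            "kappa": self.kappa,
            "mode": self.mode,
            "matrix": {
                str(n): {aa: float(self.probs[n, i]) for i, aa in enumerate(AMINO_ACIDS)}
                for n in range(MOTIF_WINDOW)
            },
            "ic": [float(x) for x in self.ic],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PWM":
        probs = np.zeros((MOTIF_WINDOW, N_AA))
        for n_str, row in d["matrix"].items():
            n = int(n_str)
            for aa, p in row.items():
                probs[n, AA_INDEX[aa]] = float(p)
        return cls(
            domain_id=d["domain_id"],
            probs=probs,
            ic=np.asarray(d["ic"], dtype=float),
            kappa=float(d.get("kappa", 0.0)),
            mode=d.get("mode", "proportional"),
        )


def position_information_content(frequencies: Sequence[float]) -> float:
    """Information content of one PWM column, in bits.

    Returns log2(20) - H(f) where H is the Shannon entropy of the
    residue frequencies (0 * log 0 := 0).
    """
    f = np.asarray(frequencies, dtype=float)
    if f.shape != (N_AA,):
        raise ValueError(f"expected a {N_AA}-vector of frequencies")
    if (f < 0).any():
        raise ValueError("negative frequency")
    total = f.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"frequencies must sum to 1, got {total}")
    nz = f[f > 0]
    entropy_bits = float(-(nz * np.log2(nz)).sum())
    return MAX_BITS - entropy_bits


def build_pwm(
    alignment: PeptideAlignment,
    pseudocount_weight: float = 1.0,
    pseudocount_mode: str = "proportional",
) -> PWM:
    """Build a specificity PWM from a C-terminally aligned peptide set.

    Two passes: raw per-offset counts give frequencies and per-position
    information content IC_n; smoothed counts then add a pseudocount
    kappa * w(IC_n) / 20 to every cell of row n, with

        w = IC_n              ("proportional", default)
        w = log2(20) - IC_n   ("inverse")
        w = 1                 ("flat")

    Offsets beyond the longest peptide get the uniform row.  With
    kappa = 0 the PWM holds the raw frequencies (zeros permitted).
    """
    if pseudocount_weight < 0:
        raise ValueError("pseudocount weight must be non-negative")
    if pseudocount_mode not in PSEUDOCOUNT_MODES:
        raise ValueError(
            f"unknown pseudocount mode {pseudocount_mode!r}; "
            f"expected one of {PSEUDOCOUNT_MODES}"
        )

    counts = np.zeros((MOTIF_WINDOW, N_AA))
    for pep in alignment.peptides:
        for n in range(len(pep)):
            counts[n, AA_INDEX[pep[-1 - n]]] += 1

    totals = counts.sum(axis=1)
    probs = np.full((MOTIF_WINDOW, N_AA), 1.0 / N_AA)
    ic = np.zeros(MOTIF_WINDOW)
    for n in range(MOTIF_WINDOW):
        if totals[n] == 0:
            continue  # beyond the longest peptide: uniform row, IC 0
        raw = counts[n] / totals[n]
        ic[n] = position_information_content(raw)
        if pseudocount_mode == "proportional":
            w = ic[n]
        elif pseudocount_mode == "inverse":
            w = MAX_BITS - ic[n]
        else:
            w = 1.0
        smoothed = counts[n] + pseudocount_weight * w / N_AA
        denom = smoothed.sum()
        probs[n] = smoothed / denom if denom > 0 else raw

    return PWM(
        domain_id=alignment.domain_id,
        probs=probs,
        ic=ic,
        kappa=pseudocount_weight,
        mode=pseudocount_mode,
    )


def score_cterm(pwm: PWM, cterm: str, log_base: float = 10.0) -> float:
    """Score a C-terminal sequence against one domain PWM.

    The last residue of ``cterm`` is aligned to offset 0.  Sequences
    shorter than 7 residues contribute only their available offsets.
    Returns -inf only when a visited entry has zero probability
    (possible only with kappa = 0).
    """
    seq = cterm.sequence if hasattr(cterm, "sequence") else cterm
    validate_sequence(seq, context="C-terminus")
    if len(seq) > MOTIF_WINDOW:
        raise ValueError(
            f"C-terminal sequence longer than {MOTIF_WINDOW} residues: {seq!r}"
        )
    total = 0.0
    log_conv = np.log(log_base)
    for n in range(len(seq)):
        p = pwm.probs[n, AA_INDEX[seq[-1 - n]]]
        if p == 0.0:
            return float("-inf")
        total += np.log(p) / log_conv
    return float(total)


def _cterm_key_seq(c) -> tuple[str, str]:
    if hasattr(c, "sequence"):
        return c.key, c.sequence
    return str(c), str(c)


def score_all(
    pwms: Sequence[PWM],
    ctermini: Sequence,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Score matrix S_ij over the Cartesian product of domains and C-termini.

    Rows are domain ids, columns C-terminus identifiers, both in input
    order.  ``ctermini`` may be plain strings or CTerminus records.
    """
    if len(pwms) == 0 or len(ctermini) == 0:
        raise ValueError("score_all requires non-empty PWM and C-terminus sets")
    keys, seqs = zip(*(_cterm_key_seq(c) for c in ctermini))
    values = np.empty((len(pwms), len(seqs)))
    for i, pwm in enumerate(pwms):
        for j, seq in enumerate(seqs):
            try:
                values[i, j] = score_cterm(pwm, seq, log_base=log_base)
            except ValueError as exc:
                raise ValueError(
                    f"scoring failed for domain {pwm.domain_id!r}, "
                    f"C-terminus {keys[j]!r}: {exc}"
                ) from exc
    return pd.DataFrame(values, index=[p.domain_id for p in pwms], columns=list(keys))


def consensus(pwm: PWM) -> str:
    """Per-offset argmax residue, written N-to-C (offset 6 first).

    Ties break alphabetically (numpy argmax returns the first index and
    the alphabet is sorted).
    """
    best = pwm.probs.argmax(axis=1)
    return "".join(AMINO_ACIDS[best[n]] for n in range(MOTIF_WINDOW - 1, -1, -1))


# ---------------------------------------------------------------------------
# I/O

def read_peptides(path: str | Path, domain_id: str | None = None) -> PeptideAlignment:
    """Read one domain's peptides from FASTA or one-peptide-per-line text.

    The domain id defaults to the filename stem.
    """
    path = Path(path)
    if domain_id is None:
        domain_id = path.stem
    text = path.read_text()
    peptides: list[str] = []
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            peptides.append(str(rec.seq).upper())
    else:
        for line in text.splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                peptides.append(line.upper())
    return PeptideAlignment(domain_id=domain_id, peptides=peptides)


def read_peptide_dir(directory: str | Path) -> list[PeptideAlignment]:
    """One peptide file per domain; filename stem = domain id."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    if not paths:
        raise ValueError(f"no peptide files found in {directory}")
    return [read_peptides(p) for p in paths]


def write_pwms_json(pwms: Sequence[PWM], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([p.to_dict() for p in pwms], indent=1, sort_keys=True)
    )


def read_pwms_json(path: str | Path) -> list[PWM]:
    return [PWM.from_dict(d) for d in json.loads(Path(path).read_text())]
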