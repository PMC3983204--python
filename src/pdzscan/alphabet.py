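"""The 20-letter amino-acid alphabet and validation helpers.

Offsets count from the C-terminus: offset 0 is the last residue of a
sequence, offset 6 the seventh-from-last.  Non-standard letters
('X', 'U', 'B', 'Z', '*', ...) are rejected at parse time.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA: int = len(AMINO_ACIDS)

#: canonical motif window: the last seven residues of a protein, the
#: typical maximum span recognised by a canonical PDZ domain.
MOTIF_WINDOW: int = 7


def is_valid_sequence(seq: str) -> bool:
    return bool(seq) and all(c in AA_INDEX for c in seq)


def validate_sequence(seq: str, context: str = "sequence") -> str:
    """Return ``seq`` unchanged or raise ``ValueError`` naming the offender."""
    if not seq:
        raise ValueError(f"empty {context}")
    for c in seq:
        if c not in AA_INDEX:
            raise ValueError(
                f"invalid residue {c!r} in {context} {seq!r}; "
                f"expected one of {AMINO_ACIDS}"
            )
    return seq
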