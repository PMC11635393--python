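"""Canonical amino-acid alphabet and tokenization constants.

The package works over the 20 canonical residues only; sequences are flanked
with start/stop special tokens before entering a model, mirroring common
protein language-model tokenizers.
"""

from __future__ import annotations

import numpy as np

#: Canonical amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_AA: int = 20

#: Token ids: 0..19 amino acids, 20 start, 21 stop, 22 padding.
START_TOKEN: int = 20
STOP_TOKEN: int = 21
PAD_TOKEN: int = 22
VOCAB_SIZE: int = 23

#: Number of special tokens flanking a tokenized sequence.
N_SPECIAL: int = 2


def validate_sequence(sequence: str) -> None:
    """Raise ``ValueError`` if *sequence* contains non-canonical letters."""
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-canonical residues in sequence: {sorted(bad)!r}")
    if not sequence:
        raise ValueError("empty sequence")


def encode(sequence: str) -> np.ndarray:
    """Tokenize a sequence: integer ids flanked by start/stop tokens."""
    validate_sequence(sequence)
    ids = np.empty(len(sequence) + N_SPECIAL, dtype=np.int64)
    ids[0] = START_TOKEN
    ids[-1] = STOP_TOKEN
    ids[1:-1] = [AA_INDEX[a] for a in sequence]
    return ids


def aa_track(sequence: str, values: dict[str, float]) -> np.ndarray:
    """Expand a per-amino-acid scalar map into a per-residue track."""
    return np.array([values[a] for a in sequence], dtype=float)
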