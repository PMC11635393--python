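"""Regression-dataset assembly.

Takes a set of proteins with replicated abundance measurements and produces
the table a sequence regressor is trained on: one row per replicate (no
averaging), one composition-preserving shuffled decoy per row pinned to an
effectively-null target, a Box-Cox transform of the targets fitted on
per-protein medians, and train/validation/test splits assigned at the level
of unique sequences so that replicate rows (and decoys) of one sequence can
never leak across splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .alphabet import validate_sequence

#: Target value assigned to shuffled decoy rows (molecules/cell); effectively
#: null but strictly positive so power transforms remain defined.
DECOY_TARGET: float = 1e-5

MIN_LENGTH: int = 100
MAX_LENGTH: int = 1000


@dataclass
class ProteinRecord:
    """A protein sequence with replicated abundance measurements.

    Abundances are absolute (molecules per cell) and strictly positive; one
    protein may carry up to ~21 replicate measurements.
    """

    id: str
    sequence: str
    abundances: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if any(a <= 0 for a in self.abundances):
            raise ValueError(f"{self.id}: abundances must be positive")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def median_abundance(self) -> float:
        return float(np.median(self.abundances))


def length_filter(
    records: list[ProteinRecord],
    min_length: int = MIN_LENGTH,
    max_length: int = MAX_LENGTH,
) -> list[ProteinRecord]:
    """Keep proteins with min_length <= L <= max_length residues."""
    return [r for r in records if min_length <= r.length <= max_length]


def augment_with_replicates(records: list[ProteinRecord]) -> pd.DataFrame:
    """Expand records into one row per abundance replicate.

    Each sequence appears once per replicate measurement, each time with a
    different experimental target value — a regression with replicates, no
    averaging. Columns: ``protein_id, sequence, target_raw, is_decoy``.
    """
    if not records:
        raise ValueError("no records to augment")
    rows = [
        {"protein_id": r.id, "sequence": r.sequence, "target_raw": a, "is_decoy": False}
        for r in records
        for a in r.abundances
    ]
    return pd.DataFrame(rows)


def add_shuffled_decoys(
    rows: pd.DataFrame, decoy_target: float = DECOY_TARGET, seed: int = 0
) -> pd.DataFrame:
    """Add one composition-preserving shuffled decoy per input row.

    Decoys are uniform random permutations of their source sequence assigned
    a constant, effectively-null target. They act as counter-examples that
    force a model to use positional information rather than composition
    alone. Output has exactly twice the input row count.
    """
    if decoy_target <= 0:
        raise ValueError("decoy_target must be positive")
    rng = np.random.default_rng(seed)
    decoys = []
    for row in rows.itertuples(index=False):
        letters = np.array(list(row.sequence))
        shuffled = "".join(letters[rng.permutation(len(letters))])
        decoys.append(
            {
                "protein_id": row.protein_id,
                "sequence": shuffled,
                "target_raw": decoy_target,
                "is_decoy": True,
            }
        )
    out = pd.concat([rows, pd.DataFrame(decoys)], ignore_index=True)
    # decoys inherit their source protein id so splits can follow the source
    return out


@dataclass
class BoxCoxTransform:
    """Box-Cox power transform ``(x**lmbda - 1)/lmbda`` (log at lambda=0)."""

    lmbda: float

    def transform(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("Box-Cox requires strictly positive values")
        return special.boxcox(x, self.lmbda)

    def inverse(self, y):
        return special.inv_boxcox(np.asarray(y, dtype=float), self.lmbda)


def fit_boxcox(values) -> BoxCoxTransform:
    """Fit the Box-Cox exponent by maximum likelihood.

    Fit on per-protein median abundances (not replicate-expanded rows);
    lambda maximizes the standard Box-Cox profile log-likelihood.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    _, lmbda = stats.boxcox(values)
    return BoxCoxTransform(float(lmbda))


@dataclass
class SplitAssignment:
    """Mapping unique sequence -> split name ('train'/'val'/'test')."""

    assignment: dict[str, str]

    def __getitem__(self, sequence: str) -> str:
        return self.assignment[sequence]


def split_unique(
    rows: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> pd.DataFrame:
    """Assign train/val/test splits at the unique-sequence level.

    Real (non-decoy) unique sequences are randomly partitioned by the given
    fractions; every replicate row of a sequence lands in the same split and
    decoys follow the split of their source protein, so no sequence-derived
    information crosses split boundaries.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    real = rows[~rows["is_decoy"]]
    unique_seqs = sorted(real["sequence"].unique())
    if len(unique_seqs) < 10:
        raise ValueError("need at least 10 unique sequences to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique_seqs))
    n = len(unique_seqs)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    split_of_seq: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            split = "train"
        elif rank < n_train + n_val:
            split = "val"
        else:
            split = "test"
        split_of_seq[unique_seqs[idx]] = split
    # decoys follow their source protein's split
    split_of_protein = (
        real.assign(split=real["sequence"].map(split_of_seq))
        .groupby("protein_id")["split"]
        .first()
        .to_dict()
    )
    out = rows.copy()
    out["split"] = [
        split_of_seq.get(s) or split_of_protein[p]
        for s, p in zip(out["sequence"], out["protein_id"])
    ]
    return out


def build_dataset(
    records: list[ProteinRecord],
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    decoy_target: float = DECOY_TARGET,
) -> tuple[pd.DataFrame, BoxCoxTransform]:
    """Full assembly: replicates -> decoys -> Box-Cox -> unique-sequence splits.

    Returns the dataset table (columns ``protein_id, sequence, target_raw,
    target_transformed, is_decoy, split``) and the fitted transform.
    """
    records = length_filter(records)
    rows = augment_with_replicates(records)
    rows = add_shuffled_decoys(rows, decoy_target=decoy_target, seed=seed)
    medians = [r.median_abundance for r in records]
    transform = fit_boxcox(medians)
    rows["target_transformed"] = transform.transform(rows["target_raw"].to_numpy())
    rows = split_unique(rows, fractions=fractions, seed=seed)
    return rows, transform


def write_dataset(rows: pd.DataFrame, transform: BoxCoxTransform, path: str | Path,
                  seed: int | None = None,
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)) -> None:
    """Write the dataset TSV plus a JSON sidecar with the transform metadata."""
    path = Path(path)
    cols = ["protein_id", "sequence", "target_raw", "target_transformed", "is_decoy", "split"]
    rows[cols].to_csv(path, sep="\t", index=False)
    sidecar = {"lambda": transform.lmbda, "seed": seed, "fractions": list(fractions)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_dataset(path: str | Path) -> tuple[pd.DataFrame, BoxCoxTransform]:
    path = Path(path)
    rows = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    return rows, BoxCoxTransform(float(meta["lambda"]))
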