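"""MGEM: Mutation Guided by an Embedded Manifold.

Deterministic sequence redesign toward higher predicted abundance. Residues
with the lowest embedded-ordering values are selected for substitution; each
selected value is shifted upward by a large step Δ (the width of the central
99% interval of the population of projected residue values) and replaced by
the residue whose ordering value, in a high-abundance guide sequence, is
closest to the shifted value. One whole-sequence candidate is built per
guide (10 guides, the highest-abundance training proteins) and the candidate
with the highest predicted abundance wins. A randomized control substitutes
the same number of residues with random amino acids. The leading residue
(position 1, the initiator methionine slot) is never touched, on either
path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import AMINO_ACIDS
from .data import BoxCoxTransform, ProteinRecord
from .ordering import OrderingValues

#: The scheme battery: fixed residue counts and fractions of sequence length.
DEFAULT_SCHEMES: tuple = (2, 5, 10, 20, 0.10, 0.20, 0.30)


@dataclass(frozen=True)
class MutationScheme:
    """Number of lowest-ordering residues to substitute.

    ``amount`` is an absolute count if >= 1, else a fraction of sequence
    length (resolved as floor(fraction * N), minimum 1).
    """

    amount: float

    @property
    def kind(self) -> str:
        return "fixed" if self.amount >= 1 else "fraction"

    def resolve(self, length: int) -> int:
        if self.amount >= 1:
            count = int(self.amount)
        else:
            count = max(1, int(self.amount * length))
        if count >= length:
            raise ValueError(
                f"scheme {self.amount} resolves to {count} >= length {length}"
            )
        return count

    @property
    def label(self) -> str:
        return (f"{int(self.amount)}res" if self.amount >= 1
                else f"{int(round(100 * self.amount))}pct")


@dataclass
class Guide:
    """A high-abundance donor sequence with its residue orderings."""

    protein_id: str
    sequence: str
    ordering: np.ndarray
    abundance: float


@dataclass
class MutationOutcome:
    wildtype_id: str
    wildtype: str
    mutant: str
    scheme: str
    positions: list[int]                    # 1-based substituted positions
    substitutions: list[tuple[str, str]]    # (from_aa, to_aa) per position
    guide_id: str | None
    pred_wt: float                          # transformed scale
    pred_mut: float
    raw_wt: float
    raw_mut: float

    @property
    def pct_change(self) -> float:
        return 100.0 * (self.raw_mut - self.raw_wt) / self.raw_wt


def select_guides(
    records: list[ProteinRecord],
    orderings: dict[str, OrderingValues],
    n_guides: int = 10,
) -> list[Guide]:
    """The top-n proteins by median abundance, as donor guides."""
    ranked = sorted(records, key=lambda r: -r.median_abundance)[:n_guides]
    return [
        Guide(r.id, r.sequence, orderings[r.id].o, r.median_abundance)
        for r in ranked
    ]


def select_targets(ordering: np.ndarray, scheme: MutationScheme) -> list[int]:
    """1-based positions of the lowest-ordering residues, excluding position 1.

    Ties are broken toward the lower position index.
    """
    n = len(ordering)
    count = scheme.resolve(n)
    candidates = np.arange(1, n)            # 0-based, skipping residue 0
    order = np.lexsort((candidates, ordering[candidates]))
    return sorted(int(candidates[i]) + 1 for i in order[:count])


def compute_shift(projected_values: np.ndarray, coverage: float = 0.99) -> float:
    """Δ = width of the central interval containing ``coverage`` of the values."""
    values = np.asarray(projected_values, dtype=float)
    if len(values) < 100:
        raise ValueError("need at least 100 projected values for a stable Δ")
    tail = (1.0 - coverage) / 2.0
    lo, hi = np.quantile(values, [tail, 1.0 - tail])
    delta = float(hi - lo)
    if delta == 0.0:
        import warnings

        warnings.warn("degenerate ordering population: Δ = 0, guided "
                      "substitution reduces to nearest-value copy", stacklevel=2)
    return delta


def propose_from_guide(
    sequence: str,
    targets: list[int],
    ordering: np.ndarray,
    delta: float,
    guide: Guide,
) -> str:
    """Whole-sequence candidate with all target positions donated by one guide.

    For each target the wanted ordering value is the target's own value
    shifted up by Δ; the donor is the guide residue (guide position 1
    excluded) whose ordering value is closest, ties resolved toward the
    lower guide position. Values beyond the guide's range clamp to its
    extreme residue.
    """
    donor_pool = np.arange(1, len(guide.sequence))   # 0-based, skip leading M
    if len(donor_pool) == 0:
        raise ValueError(f"guide {guide.protein_id} has no donor residues")
    pool_values = guide.ordering[donor_pool]
    chars = list(sequence)
    for pos in targets:
        wanted = ordering[pos - 1] + delta
        dist = np.abs(pool_values - wanted)
        donor_idx = donor_pool[int(np.argmin(dist))]   # argmin: lowest index wins
        chars[pos - 1] = guide.sequence[donor_idx]
    return "".join(chars)


def _outcome(record_id, sequence, mutant, scheme, guide_id,
             pred_wt, pred_mut, transform) -> MutationOutcome:
    positions = [i + 1 for i, (a, b) in enumerate(zip(sequence, mutant)) if a != b]
    subs = [(sequence[p - 1], mutant[p - 1]) for p in positions]
    raw_wt = float(transform.inverse(np.array([pred_wt]))[0])
    raw_mut = float(transform.inverse(np.array([pred_mut]))[0])
    return MutationOutcome(record_id, sequence, mutant, scheme.label, positions,
                           subs, guide_id, pred_wt, pred_mut, raw_wt, raw_mut)


def mgem_mutate(
    sequence: str,
    model,
    ordering: np.ndarray,
    guides: list[Guide],
    scheme: MutationScheme,
    delta: float,
    transform: BoxCoxTransform,
    record_id: str = "",
    per_residue: bool = False,
) -> MutationOutcome:
    """Guided mutation: best-of-guides candidate by predicted abundance.

    Deterministic — no randomness anywhere on the guided path. With
    ``per_residue=True`` each target position independently picks the donor
    closest to its shifted value across all guides (a single chimeric
    candidate instead of ten per-guide candidates).
    """
    targets = select_targets(ordering, scheme)
    pred_wt = model.predict(sequence)
    if per_residue:
        pool_seq = "".join(g.sequence[1:] for g in guides)
        pool_vals = np.concatenate([g.ordering[1:] for g in guides])
        chimera = Guide("pooled", "X" + pool_seq,
                        np.concatenate([[np.inf], pool_vals]), np.nan)
        mutant = propose_from_guide(sequence, targets, ordering, delta, chimera)
        return _outcome(record_id, sequence, mutant, scheme, "pooled",
                        pred_wt, model.predict(mutant), transform)
    best: MutationOutcome | None = None
    for guide in guides:
        mutant = propose_from_guide(sequence, targets, ordering, delta, guide)
        pred_mut = model.predict(mutant)
        if best is None or pred_mut > best.pred_mut:
            best = _outcome(record_id, sequence, mutant, scheme,
                            guide.protein_id, pred_wt, pred_mut, transform)
    return best


def random_control(
    sequence: str,
    model,
    scheme: MutationScheme,
    transform: BoxCoxTransform,
    seed: int = 0,
    record_id: str = "",
) -> MutationOutcome:
    """Random control: same substitution count, random positions and residues.

    Positions are drawn uniformly (excluding position 1) and each is replaced
    by a uniformly random *different* amino acid, so the effective
    substitution count always equals the scheme's count.
    """
    rng = np.random.default_rng(seed)
    n = len(sequence)
    count = scheme.resolve(n)
    positions = rng.choice(np.arange(2, n + 1), size=count, replace=False)
    chars = list(sequence)
    for pos in sorted(positions):
        current = chars[pos - 1]
        alternatives = [a for a in AMINO_ACIDS if a != current]
        chars[pos - 1] = alternatives[int(rng.integers(len(alternatives)))]
    mutant = "".join(chars)
    return _outcome(record_id, sequence, mutant, scheme, None,
                    model.predict(sequence), model.predict(mutant), transform)


# ---------------------------------------------------------------------------
# Outcome analytics
# ---------------------------------------------------------------------------

def substitution_rate_profile(
    outcomes: list[MutationOutcome], n_bins: int = 100
) -> pd.DataFrame:
    """Positional substitution-rate map, z-scored per amino acid.

    Positions are normalized to sequence length and binned to two decimals
    (100 bins). Per (wildtype amino acid, bin), the replacement count is
    divided by the wildtype occurrence count; rates are then z-scored within
    each amino acid over its non-empty bins. Empty bins carry NaN.
    """
    if len(outcomes) < 20:
        raise ValueError("need at least 20 outcomes for a stable profile")
    aa_list = list(AMINO_ACIDS)
    wt_counts = np.zeros((len(aa_list), n_bins))
    sub_counts = np.zeros((len(aa_list), n_bins))
    aa_idx = {a: i for i, a in enumerate(aa_list)}
    for out in outcomes:
        n = len(out.wildtype)
        for j, aa in enumerate(out.wildtype):
            b = min(n_bins - 1, int(j / n * n_bins))
            wt_counts[aa_idx[aa], b] += 1
        for pos, (from_aa, _) in zip(out.positions, out.substitutions):
            b = min(n_bins - 1, int((pos - 1) / n * n_bins))
            sub_counts[aa_idx[from_aa], b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(wt_counts > 0, sub_counts / wt_counts, np.nan)
    z = np.full_like(rate, np.nan)
    for i in range(len(aa_list)):
        row = rate[i]
        valid = ~np.isnan(row)
        if valid.sum() > 1 and np.nanstd(row) > 0:
            z[i, valid] = (row[valid] - np.nanmean(row)) / np.nanstd(row)
        elif valid.sum() >= 1:
            z[i, valid] = 0.0
    records = []
    for i, aa in enumerate(aa_list):
        for b in range(n_bins):
            records.append({"aa": aa, "bin": b, "rel_pos": (b + 0.5) / n_bins,
                            "rate": rate[i, b], "z": z[i, b]})
    return pd.DataFrame(records)


def cost_delta(
    outcomes: list[MutationOutcome],
    tables,
) -> pd.DataFrame:
    """Mean per-protein percent change of average residue cost, per table.

    For each feature table, the mean residue cost of each mutant is compared
    with its wildtype as a percent change, and a paired t-test across
    proteins tests whether the shift is systematic.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least 2 outcomes for a paired test")
    rows = []
    for table in tables:
        wt_cost = np.array([table.track(o.wildtype).mean() for o in outcomes])
        mut_cost = np.array([table.track(o.mutant).mean() for o in outcomes])
        pct = 100.0 * (mut_cost - wt_cost) / wt_cost
        if np.allclose(mut_cost, wt_cost):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_rel(mut_cost, wt_cost)
        rows.append({"table": table.name, "mean_pct_change": float(pct.mean()),
                     "t_stat": float(stat), "p": float(p), "n": len(outcomes)})
    return pd.DataFrame(rows)


def outcomes_frame(outcomes: list[MutationOutcome]) -> pd.DataFrame:
    """Tidy TSV-ready view of mutation outcomes."""
    return pd.DataFrame(
        {
            "protein_id": [o.wildtype_id for o in outcomes],
            "scheme": [o.scheme for o in outcomes],
            "guide_id": [o.guide_id for o in outcomes],
            "positions": [",".join(map(str, o.positions)) for o in outcomes],
            "from": ["".join(s[0] for s in o.substitutions) for o in outcomes],
            "to": ["".join(s[1] for s in o.substitutions) for o in outcomes],
            "pred_wt": [o.pred_wt for o in outcomes],
            "pred_mut": [o.pred_mut for o in outcomes],
            "pct_change": [o.pct_change for o in outcomes],
        }
    )
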