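"""Attention-profile analysis with controls.

Turns per-sequence attention tensors into one-dimensional per-residue
profiles ("attended-by" values), filters redundant layer/head matrices,
correlates profiles with per-residue physicochemical tracks under Bonferroni
control, tests secondary-structure enrichment of high-attention positions by
exact hypergeometric tails, compares domain coverage against a
same-length-window expectation, and provides partial correlations for
confound control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import ResidueFeatureTable

logger = logging.getLogger(__name__)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold: alpha divided by the test count."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class AttentionProfile:
    """One-dimensional attention profile of one (layer, head) matrix.

    ``values`` are percent-normalized attended-by weights (they sum to 100
    over the sequence); ``z_scores`` standardize the profile internally.
    """

    protein_id: str
    layer: int
    head: int
    values: np.ndarray
    z_scores: np.ndarray

    @property
    def pattern(self) -> np.ndarray:
        """1-based positions with z-score > 1 (the attention pattern)."""
        return np.flatnonzero(self.z_scores > 1.0) + 1


@dataclass
class ProfileCorrelation:
    protein_id: str
    feature: str
    r: float
    p: float
    layer: int
    head: int


def profile_from_matrix(matrix: np.ndarray, protein_id: str = "",
                        layer: int = 0, head: int = 0,
                        attended_by: bool = True) -> AttentionProfile:
    """Collapse one attention matrix into a per-residue profile.

    Strips the first and last token rows/columns (start/stop), renormalizes
    rows, and averages over the query axis so ``values[j]`` is the percent of
    attention residue j receives from all residues. Set ``attended_by=False``
    to transpose the convention (how much each residue attends out).
    """
    matrix = np.asarray(matrix, dtype=float)
    t = matrix.shape[0]
    if matrix.shape != (t, t):
        raise ValueError("attention matrix must be square")
    if t < 3:
        raise ValueError("no residues left after stripping special tokens")
    row_sums = matrix.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("attention rows must sum to 1")
    inner = matrix[1:-1, 1:-1]
    if not attended_by:
        inner = inner.T
    inner = inner / inner.sum(axis=1, keepdims=True)
    values = 100.0 * inner.mean(axis=0)
    sd = values.std()
    # numerically constant profiles get all-zero z-scores
    if sd <= 1e-9 * max(1.0, float(np.abs(values).max())):
        z = np.zeros_like(values)
    else:
        z = (values - values.mean()) / sd
    return AttentionProfile(protein_id, layer, head, values, z)


def nonredundant_matrices(stack: np.ndarray) -> list[tuple[int, int]]:
    """Select the non-redundant (layer, head) attention matrices.

    A matrix is kept when its flattened Pearson correlation with at least
    90% of the other matrices stays below 0.01 in absolute value. Constant
    matrices (correlation undefined) are treated as redundant and dropped.
    """
    layers, heads = stack.shape[:2]
    flat, index = [], []
    for l in range(layers):
        for h in range(heads):
            m = stack[l, h].ravel()
            if np.ptp(m) == 0 or m.std() == 0:
                logger.info("dropping constant attention matrix (%d, %d)", l, h)
                continue
            flat.append(m)
            index.append((l, h))
    if len(flat) < 2:
        return []
    corr = np.corrcoef(np.stack(flat))
    kept = []
    n_other = len(flat) - 1
    for i, lh in enumerate(index):
        others = np.abs(np.delete(corr[i], i))
        if np.sum(others < 0.01) >= int(np.ceil(0.9 * n_other)):
            kept.append(lh)
    return kept


def profiles_for_sequence(
    model, sequence: str, protein_id: str = "",
    nonredundant: bool = True, attended_by: bool = True,
) -> list[AttentionProfile]:
    """All (non-redundant) attention profiles of one sequence."""
    stack = model.attentions(sequence)
    if nonredundant:
        keep = nonredundant_matrices(stack)
    else:
        layers, heads = stack.shape[:2]
        keep = [(l, h) for l in range(layers) for h in range(heads)
                if np.ptp(stack[l, h]) > 0]
    return [
        profile_from_matrix(stack[l, h], protein_id, l, h, attended_by)
        for l, h in keep
    ]


def correlate_profile_with_feature(
    profiles_by_protein: dict[str, list[AttentionProfile]],
    sequences: dict[str, str],
    table: ResidueFeatureTable,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> list[ProfileCorrelation]:
    """Best significant profile-to-feature correlation per protein.

    For each protein the per-residue feature track is Pearson-correlated
    with every available profile; among correlations whose two-sided p-value
    clears the Bonferroni threshold ``alpha / n_tests`` the one with the
    largest |r| is kept. Proteins with no significant profile, or with a
    zero-variance feature track, are skipped.
    """
    n_tests = n_tests or len(profiles_by_protein)
    threshold = bonferroni_threshold(alpha, n_tests)
    out: list[ProfileCorrelation] = []
    for pid, profiles in profiles_by_protein.items():
        track = table.track(sequences[pid])
        if track.std() == 0:
            logger.info("%s: zero-variance feature track, skipped", pid)
            continue
        best: ProfileCorrelation | None = None
        for prof in profiles:
            if prof.values.std() == 0:
                continue
            r, p = stats.pearsonr(prof.values, track)
            if p < threshold and (best is None or abs(r) > abs(best.r)):
                best = ProfileCorrelation(pid, table.name, float(r), float(p),
                                          prof.layer, prof.head)
        if best is not None:
            out.append(best)
    return out


def correlation_distribution(
    profiles_by_protein: dict[str, list[AttentionProfile]],
    sequences: dict[str, str],
    table: ResidueFeatureTable,
) -> np.ndarray:
    """Per-protein max-|r| profile-to-feature correlations, unthresholded.

    The control-distribution variant of
    :func:`correlate_profile_with_feature`: every protein contributes its
    best correlation regardless of significance, which is what shuffled
    controls are plotted from.
    """
    values = []
    for pid, profiles in profiles_by_protein.items():
        track = table.track(sequences[pid])
        if track.std() == 0:
            continue
        rs = [
            stats.pearsonr(p.values, track)[0]
            for p in profiles
            if p.values.std() > 0
        ]
        if rs:
            values.append(max(rs, key=abs))
    return np.asarray(values)


def reduce_feature_set(
    tables: list[ResidueFeatureTable],
    sequences: list[str],
    cutoff: float = 0.5,
) -> list[ResidueFeatureTable]:
    """Greedy redundancy reduction of feature tables.

    Per-sequence feature tracks are correlated pairwise and the absolute
    correlations averaged across sequences; while any pair exceeds the
    cutoff, the member with the larger mean absolute correlation to all
    others is dropped (ties broken lexicographically by table name). The
    result has all pairwise mean |r| <= cutoff.
    """
    if len(tables) < 2:
        return list(tables)
    names = [t.name for t in tables]
    k = len(tables)
    acc = np.zeros((k, k))
    count = 0
    for seq in sequences:
        tracks = np.stack([t.track(seq) for t in tables])
        sds = tracks.std(axis=1)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(tracks)
        corr[np.isnan(corr)] = 0.0
        corr[sds == 0, :] = 0.0
        corr[:, sds == 0] = 0.0
        acc += np.abs(corr)
        count += 1
    mean_abs = acc / count
    np.fill_diagonal(mean_abs, 0.0)
    alive = list(range(k))
    while True:
        sub = mean_abs[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= cutoff:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        gi, gj = alive[i], alive[j]
        mi, mj = sub[i].mean(), sub[j].mean()
        if mi > mj or (mi == mj and names[gi] > names[gj]):
            alive.remove(gi)
        else:
            alive.remove(gj)
    return [tables[i] for i in alive]


# ---------------------------------------------------------------------------
# Secondary-structure enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    protein_id: str
    letter: str
    sample_count: int
    sample_size: int
    background_count: int
    background_size: int
    p_enriched: float
    p_depleted: float


def structure_enrichment(
    patterns: dict[str, np.ndarray],
    annotations: dict[str, str],
    min_count: int = 10,
    alpha: float = 0.05,
) -> tuple[list[EnrichmentResult], pd.DataFrame]:
    """Hypergeometric enrichment/depletion of annotations at pattern positions.

    For every protein and annotation letter, the letter's count at the
    protein's high-attention positions (the sample) is tested one-sidedly —
    both for enrichment and for depletion — against the pooled letter counts
    across all analyzed proteins (the background population). Letters with a
    sample count <= ``min_count`` for a protein are not tested. The summary
    counts proteins significantly enriched / depleted per letter.
    """
    for pid in patterns:
        if pid not in annotations:
            raise ValueError(f"no annotation for protein {pid}")
    # pooled background
    background: dict[str, int] = {}
    total = 0
    for ann in annotations.values():
        for ch in ann:
            background[ch] = background.get(ch, 0) + 1
        total += len(ann)
    results: list[EnrichmentResult] = []
    for pid, pattern in patterns.items():
        ann = annotations[pid]
        if len(pattern) == 0:
            continue
        if pattern.max() > len(ann):
            raise ValueError(f"{pid}: pattern position beyond annotation length")
        sample = [ann[p - 1] for p in pattern]
        n = len(sample)
        for letter in sorted(set(sample)):
            x = sample.count(letter)
            if x <= min_count:
                continue
            big_k = background[letter]
            p_enr = float(stats.hypergeom.sf(x - 1, total, big_k, n))
            p_dep = float(stats.hypergeom.cdf(x, total, big_k, n))
            results.append(
                EnrichmentResult(pid, letter, x, n, big_k, total, p_enr, p_dep)
            )
    rows = []
    letters = sorted({r.letter for r in results})
    for letter in letters:
        sub = [r for r in results if r.letter == letter]
        rows.append(
            {
                "letter": letter,
                "n_enriched": sum(r.p_enriched < alpha for r in sub),
                "n_depleted": sum(r.p_depleted < alpha for r in sub),
                "n_tested": len(sub),
            }
        )
    return results, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Domain coverage
# ---------------------------------------------------------------------------

@dataclass
class DomainRecord:
    """Protein-coordinate domain interval.

    Stored 0-based half-open; TSV I/O uses 1-based closed coordinates.
    """

    protein_id: str
    database: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad domain interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def domain_coverage(
    patterns: dict[str, list[np.ndarray]],
    domains: list[DomainRecord],
    lengths: dict[str, int],
    max_length_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed vs expected high-attention coverage of domains.

    For each domain (no longer than half its protein), observed coverage is
    the best fraction of domain positions hit by any of the protein's
    attention patterns. The expectation uses the same pattern: its hits
    outside the domain are divided by the number of non-overlapping
    domain-length windows fitting in the outside region, then by the domain
    length — the average coverage a random same-length window would get.
    Per member database, a two-sided Wilcoxon signed-rank test on
    (observed - expected) is reported with Benjamini-Hochberg adjustment.
    """
    per_domain = []
    for dom in domains:
        n = lengths[dom.protein_id]
        if dom.end > n:
            raise ValueError(f"{dom.protein_id}: domain exceeds protein length")
        if dom.length > max_length_fraction * n:
            logger.info("domain %s[%d,%d) longer than %d%% of protein, dropped",
                        dom.protein_id, dom.start, dom.end,
                        int(100 * max_length_fraction))
            continue
        best: tuple[float, float] | None = None
        for pattern in patterns.get(dom.protein_id, []):
            pat0 = np.asarray(pattern) - 1  # to 0-based
            inside = int(np.sum((pat0 >= dom.start) & (pat0 < dom.end)))
            obs = inside / dom.length
            outside_len = n - dom.length
            windows = outside_len // dom.length
            if windows == 0:
                continue
            exp = (len(pat0) - inside) / windows / dom.length
            if best is None or obs > best[0]:
                best = (obs, exp)
        if best is None:
            continue
        best_obs, best_exp = best
        per_domain.append(
            {
                "protein_id": dom.protein_id,
                "database": dom.database,
                "domain_start": dom.start + 1,
                "domain_end": dom.end,
                "observed": best_obs,
                "expected": best_exp,
            }
        )
    detail = pd.DataFrame(per_domain)
    if detail.empty:
        return detail, pd.DataFrame()
    summaries = []
    for db, sub in detail.groupby("database"):
        diff = (sub["observed"] - sub["expected"]).to_numpy()
        if np.allclose(diff, 0):
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(stats.wilcoxon(diff).pvalue)
        summaries.append({"database": db, "n_domains": len(sub),
                          "mean_diff": float(diff.mean()), "p": p})
    summary = pd.DataFrame(summaries)
    _, adj, _, _ = multipletests(summary["p"], method="fdr_bh")
    summary["p_adj"] = adj
    return detail, summary


def read_domains(path) -> list[DomainRecord]:
    """Read domain TSV (``protein_id  db  start  end``, 1-based closed)."""
    df = pd.read_csv(path, sep="\t")
    return [
        DomainRecord(r.protein_id, r.db, int(r.start) - 1, int(r.end))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Partial correlation
# ---------------------------------------------------------------------------

def partial_correlation(x, y, controls=None) -> tuple[float, float]:
    """Pearson correlation of x and y after removing linear effects of controls.

    Computed as the correlation of the residuals of ``x ~ controls`` and
    ``y ~ controls`` (with intercept). With no controls this is the plain
    Pearson correlation. Collinear controls fall back to the least-norm
    solution (with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None or (hasattr(controls, "__len__") and len(controls) == 0):
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    z = np.atleast_2d(np.asarray(controls, dtype=float))
    if z.shape[0] == len(x) and z.shape[1] != len(x):
        pass
    elif z.shape[1] == len(x):
        z = z.T
    if len(x) < z.shape[1] + 3:
        raise ValueError("need at least len(controls)+3 observations")
    design = np.column_stack([z, np.ones(len(x))])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("collinear controls; using least-norm regression",
                      stacklevel=2)
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    r = float(stats.pearsonr(rx, ry).statistic)
    # p-value with degrees of freedom reduced by the controlled covariates
    dof = len(x) - 2 - z.shape[1]
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return r, float(p)
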