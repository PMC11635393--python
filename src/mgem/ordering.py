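"""Embedded ordering: a one-dimensional importance scale over the encoder
manifold.

A well-trained sequence regressor arranges its embedded space so that
sequence representations are approximately ordered by the target value. The
ordering projector maps that space down to one dimension: it is fitted on
the embedded start-token points of training sequences (through which the
attention layers route whole-sequence information) and then applied to
arbitrary embedding points, assigning every residue j of protein i a scalar
importance o_i^j that is comparable across the whole sequence population.
The projector's quality is measured as the Spearman correlation between the
projected centroids of held-out sequence point clouds and their abundance
targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import stats


@runtime_checkable
class OrderingProjector(Protocol):
    """Parametric map from the embedding space to the 1-D ordering scale."""

    def project(self, points: np.ndarray) -> np.ndarray: ...


@dataclass
class IdentityProjector:
    """Read one embedding coordinate as the ordering value.

    The natural projector for the planted-truth oracle, whose embedding
    coordinate 0 is exactly the per-residue contribution.
    """

    coordinate: int = 0
    sign: float = 1.0

    def project(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return self.sign * points[:, self.coordinate]


class NeighborProjector:
    """UMAP-based 1-D projection with a parametric regression readout.

    A 1-D UMAP embedding is fitted on the training points; a ridge-regularized
    polynomial-free linear readout is then fitted from the input space to the
    UMAP coordinate so that arbitrary points (e.g. residue embeddings, which
    live off the start-token cloud) can be projected parametrically. The
    ``mode`` flag switches between that linear readout ("linear") and UMAP's
    own nearest-neighbor transform ("transform").
    """

    def __init__(self, n_neighbors: int, seed: int = 0, mode: str = "linear"):
        if mode not in ("linear", "transform"):
            raise ValueError("mode must be 'linear' or 'transform'")
        self.n_neighbors = n_neighbors
        self.seed = seed
        self.mode = mode
        self.sign = 1.0
        self._reducer = None
        self._readout = None

    def fit(self, points: np.ndarray) -> "NeighborProjector":
        import umap
        from sklearn.linear_model import Ridge

        points = np.asarray(points, dtype=float)
        if np.allclose(points.std(axis=0), 0):
            raise ValueError("degenerate embeddings: no variance to project")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._reducer = umap.UMAP(
                n_components=1,
                n_neighbors=max(2, self.n_neighbors),
                random_state=self.seed,
                transform_seed=self.seed,
            )
            coords = self._reducer.fit_transform(points)[:, 0]
        if self.mode == "linear":
            self._readout = Ridge(alpha=1.0).fit(points, coords)
        return self

    def project(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.mode == "linear":
            vals = self._readout.predict(points)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals = self._reducer.transform(points)[:, 0]
        return self.sign * vals


class WeakLabelProjector:
    """Linear projection fitted on residue points with protein-level labels.

    Every residue embedding of a training sequence inherits the sequence's
    abundance target as a weak label; a ridge regression from embedding
    space onto those labels then defines the 1-D projection. This extracts
    the direction along which the encoder manifold is ordered by abundance
    directly, and is deterministic.
    """

    def __init__(self, alpha: float = 1.0, max_residues_per_seq: int = 60,
                 seed: int = 0):
        self.alpha = alpha
        self.max_residues_per_seq = max_residues_per_seq
        self.seed = seed
        self.sign = 1.0
        self._model = None

    def fit(self, model, sequences: list[str], targets: np.ndarray
            ) -> "WeakLabelProjector":
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(self.seed)
        xs, ys = [], []
        for seq, target in zip(sequences, targets):
            residues, _ = model.embed(seq)
            take = rng.choice(
                len(residues),
                size=min(self.max_residues_per_seq, len(residues)),
                replace=False,
            )
            xs.append(residues[take])
            ys.append(np.full(len(take), target))
        self._model = Ridge(alpha=self.alpha).fit(
            np.concatenate(xs), np.concatenate(ys)
        )
        return self

    def project(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return self.sign * self._model.predict(points)


@dataclass
class OrderingValues:
    """Per-residue ordering values o_i^j of one protein."""

    protein_id: str
    o: np.ndarray
    o_normalized: np.ndarray | None = None


@dataclass
class ProjectorFit:
    projector: OrderingProjector
    holdout_spearman: float
    sweep: list[dict] = field(default_factory=list)
    population_min: float = 0.0
    population_max: float = 1.0


def centroid_spearman(
    model, projector: OrderingProjector, sequences: list[str], targets: np.ndarray
) -> float:
    """Spearman between projected sequence-cloud centroids and targets."""
    centroids = []
    for seq in sequences:
        residues, _ = model.embed(seq)
        centroids.append(float(np.mean(projector.project(residues))))
    return float(stats.spearmanr(centroids, targets).statistic)


def fit_projector(
    model,
    train_sequences: list[str],
    targets: np.ndarray,
    neighbor_grid: tuple[float, ...] = (0.01, 0.05, 0.10, 0.25),
    holdout_fraction: float = 0.10,
    seed: int = 0,
    mode: str = "linear",
    include_weak_label: bool = True,
) -> ProjectorFit:
    """Fit the ordering projector over the encoder manifold.

    Candidate projectors — one UMAP-based projector per neighbor setting
    (fractions of the training count, spanning 1%-25%, fitted on start-token
    points) plus, by default, a supervised :class:`WeakLabelProjector`
    fitted on residue points — are each scored by the Spearman correlation
    between held-out projected cloud centroids and abundance targets, and
    the best is selected. The 1-D axis orientation is then fixed so that
    higher ordering means higher predicted abundance, and the population
    min/max of projected residue values over the training sequences is
    recorded for normalization.
    """
    targets = np.asarray(targets, dtype=float)
    if len(train_sequences) < 50:
        raise ValueError("need at least 50 training sequences")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train_sequences))
    n_hold = max(1, int(holdout_fraction * len(train_sequences)))
    hold_idx, fit_idx = order[:n_hold], order[n_hold:]
    start_points = np.stack(
        [model.embed(train_sequences[i])[1] for i in fit_idx]
    )
    hold_seqs = [train_sequences[i] for i in hold_idx]
    hold_targets = targets[hold_idx]

    sweep = []
    best: tuple[float, OrderingProjector] | None = None
    for frac in neighbor_grid:
        n_neighbors = max(2, int(round(frac * len(fit_idx))))
        proj = NeighborProjector(n_neighbors, seed=seed, mode=mode).fit(start_points)
        rho = centroid_spearman(model, proj, hold_seqs, hold_targets)
        sweep.append({"projector": "umap", "neighbor_fraction": frac,
                      "n_neighbors": n_neighbors, "holdout_spearman": rho})
        if best is None or abs(rho) > abs(best[0]):
            best = (rho, proj)
    if include_weak_label:
        proj = WeakLabelProjector(seed=seed).fit(
            model, [train_sequences[i] for i in fit_idx], targets[fit_idx]
        )
        rho = centroid_spearman(model, proj, hold_seqs, hold_targets)
        sweep.append({"projector": "weak_label", "holdout_spearman": rho})
        if best is None or abs(rho) > abs(best[0]):
            best = (rho, proj)
    rho, projector = best
    if rho < 0:   # orientation is arbitrary; fix higher = more abundant
        projector.sign = -1.0
        rho = -rho
    pop = np.concatenate(
        [projector.project(model.embed(s)[0]) for s in train_sequences]
    )
    return ProjectorFit(projector, float(rho), sweep,
                        float(pop.min()), float(pop.max()))


def residue_ordering(
    model, projector: OrderingProjector, sequence: str, protein_id: str = "",
    population_range: tuple[float, float] | None = None,
) -> OrderingValues:
    """Project every residue embedding of a sequence onto the ordering scale.

    The normalized variant min-max scales against the projected-point
    population (not the single sequence), so values are comparable across
    proteins.
    """
    residues, _ = model.embed(sequence)
    o = np.asarray(projector.project(residues), dtype=float)
    normalized = None
    if population_range is not None:
        lo, hi = population_range
        if hi > lo:
            normalized = (o - lo) / (hi - lo)
    return OrderingValues(protein_id, o, normalized)


def importance_position_profile(
    orderings: list[OrderingValues], grid_size: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Average inverse-rank importance as a function of relative position.

    Per protein, ordering values are converted to inverse ranks (most
    important residue = highest inverse rank; ties get average rank),
    divided by sequence length, linearly interpolated onto a common relative
    position grid, and averaged across proteins. Returns (grid, curve).
    """
    if len(orderings) < 10:
        raise ValueError("need at least 10 proteins for a stable profile")
    grid = np.linspace(0.0, 1.0, grid_size)
    curves = []
    for ov in orderings:
        n = len(ov.o)
        # rank of the ordering value, normalized by length: only the relative
        # order matters, and with the axis oriented so higher = more abundant
        # the most influential residues score highest
        rank = stats.rankdata(ov.o) / n
        rel_pos = np.arange(n) / max(n - 1, 1)
        curves.append(np.interp(grid, rel_pos, rank))
    return grid, np.mean(curves, axis=0)
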