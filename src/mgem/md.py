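"""Cα-trajectory analysis: superposition, RMSF, contacts, convergence,
and mutant-vs-wildtype comparison statistics.

Trajectories are frames x residues x 3 coordinate arrays in Å. Frames are
rigid-body superposed onto the last frame (proper rotations only) before any
fluctuation or RMSD statistic is computed. Simulation itself is out of
scope: trajectories are consumed, never produced (beyond the synthetic toy
generator used for testing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CATrajectory:
    """Cα coordinates over time: ``coords`` with shape (frames, residues, 3)."""

    protein_id: str
    coords: np.ndarray
    frame_spacing_ps: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, residues, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


@dataclass
class ConvergenceReport:
    converged: bool
    fraction_within: float
    margin: float
    rmsd_series: np.ndarray = field(repr=False, default=None)


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper-rotation superposition of one frame onto a reference."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    return rot.apply(mob_c) + reference.mean(axis=0)


def superpose(traj: CATrajectory, reference_frame: int = -1) -> CATrajectory:
    """Least-squares rigid-body fit of every frame onto a reference frame.

    Uses proper rotations only (no reflections), so a mirror-image frame
    retains a nonzero RMSD. The reference frame (default: last) is unchanged.
    """
    ref = traj.coords[reference_frame]
    if np.linalg.matrix_rank(ref - ref.mean(axis=0)) < 2:
        raise ValueError("reference frame is degenerate (collinear atoms)")
    aligned = np.stack([_kabsch(frame, ref) for frame in traj.coords])
    aligned[reference_frame] = ref
    return CATrajectory(traj.protein_id, aligned, traj.frame_spacing_ps)


def rmsd_to_reference(traj: CATrajectory, reference_frame: int = -1) -> np.ndarray:
    """Per-frame RMSD to the reference frame of an (aligned) trajectory."""
    ref = traj.coords[reference_frame]
    d = traj.coords - ref
    return np.sqrt((d**2).sum(axis=2).mean(axis=1))


def rmsf(traj: CATrajectory) -> np.ndarray:
    """Per-residue root-mean-square fluctuation about the time-average position.

    The trajectory is assumed to be superposed already.
    """
    mean_pos = traj.coords.mean(axis=0)
    d = traj.coords - mean_pos
    return np.sqrt((d**2).sum(axis=2).mean(axis=0))


def contacts(coords: np.ndarray, cutoff: float = 8.0) -> int:
    """Count unordered residue pairs with Cα distance <= cutoff (Å).

    ``coords`` is one frame, shape (residues, 3). All pairs are counted;
    there is no minimum sequence-separation exclusion by default.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValueError("contacts expects a single frame (residues, 3)")
    return int(np.count_nonzero(pdist(coords) <= cutoff))


def mean_contacts(traj: CATrajectory, cutoff: float = 8.0,
                  frames: slice | None = None) -> float:
    """Average contact count over a frame range (default: all frames)."""
    sel = traj.coords if frames is None else traj.coords[frames]
    return float(np.mean([contacts(f, cutoff) for f in sel]))


def convergence_from_series(
    rmsd_series: np.ndarray, margin: float = 0.10, fraction: float = 0.80
) -> ConvergenceReport:
    """Convergence rule on an RMSD time series.

    Converged iff at least ``fraction`` of the time points in the final
    quarter lie within ``margin`` (relative) of the final quarter's mean.
    """
    series = np.asarray(rmsd_series, dtype=float)
    quarter = series[-(len(series) // 4):]
    center = quarter.mean()
    if center == 0:
        frac = 1.0
    else:
        frac = float(np.mean(np.abs(quarter - center) <= margin * center))
    return ConvergenceReport(bool(frac >= fraction), frac, margin, series)


def convergence_check(
    traj: CATrajectory, margin: float = 0.10, fraction: float = 0.80
) -> ConvergenceReport:
    """Convergence filter on a trajectory.

    The trajectory is superposed onto its last frame and the per-frame RMSD
    to that reference is thresholded via :func:`convergence_from_series`.
    The reference frame itself (RMSD 0 by construction) is excluded from the
    final-quarter statistics.
    """
    if traj.n_frames < 8:
        raise ValueError("need at least 8 frames for a convergence check")
    aligned = superpose(traj)
    series = rmsd_to_reference(aligned)[:-1]
    return convergence_from_series(series, margin, fraction)


@dataclass
class PairComparison:
    """Mutant-vs-wildtype trajectory comparison for one protein."""

    protein_id: str
    rmsf_wt: np.ndarray
    rmsf_mut: np.ndarray
    ranksum_stat: float
    ranksum_p: float
    z: np.ndarray                      # per-residue (mut - wt)/sd(wt profile)
    frac_lower_2sd: float
    frac_higher_2sd: float
    direct_positions: list[int]        # significant and mutated (1-based)
    indirect_positions: list[int]      # significant, not mutated
    contacts_wt: float | None = None
    contacts_mut: float | None = None
    contact_ratio: float | None = None
    sasa_ratio: float | None = None


def compare_pair(
    wt: CATrajectory,
    mut: CATrajectory,
    mutated_positions: list[int] | None = None,
    cutoff: float = 8.0,
    sasa_wt: np.ndarray | None = None,
    sasa_mut: np.ndarray | None = None,
    z_threshold: float = 2.0,
    require_converged: bool = True,
) -> PairComparison:
    """Compare a mutant trajectory against its wildtype.

    Computes the Wilcoxon rank-sum test between the two RMSF profiles,
    per-residue z-scores of the RMSF difference on the wildtype profile's
    scale, the fractions of residues at least ``z_threshold`` sd lower or
    higher, a direct/indirect classification of significant residues by
    membership in ``mutated_positions`` (1-based), and contact (and
    optionally SASA) ratios over the frames after the trajectory midpoint,
    normalized to wildtype.
    """
    if wt.n_residues != mut.n_residues:
        raise ValueError("wildtype and mutant residue counts differ")
    if require_converged:
        for name, traj in (("wildtype", wt), ("mutant", mut)):
            if not convergence_check(traj).converged:
                warnings.warn(f"{name} trajectory not converged", stacklevel=2)
    prof_wt = rmsf(superpose(wt))
    prof_mut = rmsf(superpose(mut))
    stat, p = stats.ranksums(prof_mut, prof_wt)
    sd = prof_wt.std()
    z = (prof_mut - prof_wt) / sd if sd > 0 else np.zeros_like(prof_wt)
    lower = np.flatnonzero(z <= -z_threshold) + 1
    higher = np.flatnonzero(z >= z_threshold) + 1
    mutated = set(mutated_positions or [])
    significant = sorted(set(lower) | set(higher))
    direct = [p_ for p_ in significant if p_ in mutated]
    indirect = [p_ for p_ in significant if p_ not in mutated]
    half_wt = slice(wt.n_frames // 2, None)
    half_mut = slice(mut.n_frames // 2, None)
    c_wt = mean_contacts(wt, cutoff, half_wt)
    c_mut = mean_contacts(mut, cutoff, half_mut)
    sasa_ratio = None
    if sasa_wt is not None and sasa_mut is not None:
        sasa_wt = np.asarray(sasa_wt, dtype=float)
        sasa_mut = np.asarray(sasa_mut, dtype=float)
        sasa_ratio = float(
            sasa_mut[len(sasa_mut) // 2:].mean() / sasa_wt[len(sasa_wt) // 2:].mean()
        )
    return PairComparison(
        protein_id=wt.protein_id,
        rmsf_wt=prof_wt,
        rmsf_mut=prof_mut,
        ranksum_stat=float(stat),
        ranksum_p=float(p),
        z=z,
        frac_lower_2sd=float(len(lower) / wt.n_residues),
        frac_higher_2sd=float(len(higher) / wt.n_residues),
        direct_positions=[int(x) for x in direct],
        indirect_positions=[int(x) for x in indirect],
        contacts_wt=c_wt,
        contacts_mut=c_mut,
        contact_ratio=float(c_mut / c_wt) if c_wt > 0 else None,
        sasa_ratio=sasa_ratio,
    )


def summarize_comparisons(pairs: list[PairComparison], alpha: float = 0.01) -> pd.DataFrame:
    """Benjamini-Hochberg adjust rank-sum p-values across protein pairs.

    Returns a tidy frame with adjusted p-values and a significantly-lower
    flag (adjusted p below alpha and mutant median RMSF below wildtype).
    """
    if not pairs:
        raise ValueError("no comparisons to summarize")
    pvals = [c.ranksum_p for c in pairs]
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in pairs],
            "p_raw": pvals,
            "p_adj": adj,
            "mut_lower": [
                a < alpha and np.median(c.rmsf_mut) < np.median(c.rmsf_wt)
                for c, a in zip(pairs, adj)
            ],
            "contact_ratio": [c.contact_ratio for c in pairs],
        }
    )


# ---------------------------------------------------------------------------
# I/O: multi-model PDB (Cα only) and plain-text frame tables
# ---------------------------------------------------------------------------

def write_trajectory_pdb(traj: CATrajectory, path: str | Path) -> None:
    """Write a Cα trajectory as a multi-model PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_frames, n_res = traj.n_frames, traj.n_residues
    atoms = struc.AtomArrayStack(n_frames, n_res)
    atoms.coord = traj.coords.astype(np.float32)
    atoms.chain_id = np.full(n_res, "A")
    atoms.res_id = np.arange(1, n_res + 1)
    atoms.res_name = np.full(n_res, "ALA")
    atoms.atom_name = np.full(n_res, "CA")
    atoms.element = np.full(n_res, "C")
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_trajectory_pdb(path: str | Path, protein_id: str | None = None,
                        frame_spacing_ps: float = 1.0) -> CATrajectory:
    """Read a multi-model PDB, extracting Cα atoms by atom name."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    ca = stack[:, stack.atom_name == "CA"]
    return CATrajectory(
        protein_id or Path(path).stem, np.asarray(ca.coord, dtype=float),
        frame_spacing_ps,
    )


def write_trajectory_tsv(traj: CATrajectory, path: str | Path) -> None:
    """Write frames as plain text: ``frame<TAB>residue<TAB>x<TAB>y<TAB>z``."""
    f_idx, r_idx = np.meshgrid(
        np.arange(traj.n_frames), np.arange(1, traj.n_residues + 1), indexing="ij"
    )
    pd.DataFrame(
        {
            "frame": f_idx.ravel(),
            "residue": r_idx.ravel(),
            "x": traj.coords[..., 0].ravel(),
            "y": traj.coords[..., 1].ravel(),
            "z": traj.coords[..., 2].ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def read_trajectory_tsv(path: str | Path, protein_id: str | None = None,
                        frame_spacing_ps: float = 1.0) -> CATrajectory:
    df = pd.read_csv(path, sep="\t")
    n_frames = df["frame"].nunique()
    n_res = df["residue"].nunique()
    df = df.sort_values(["frame", "residue"])
    coords = df[["x", "y", "z"]].to_numpy().reshape(n_frames, n_res, 3)
    return CATrajectory(protein_id or Path(path).stem, coords, frame_spacing_ps)
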