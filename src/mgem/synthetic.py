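"""Planted-signal synthetic proteome.

Every downstream stage of the package (dataset assembly, regressor training,
attention analysis, embedded ordering, guided mutagenesis, trajectory
metrics) is exercised on data from this module, which plants a known
sequence-to-abundance map and records the per-residue ground truth.

The planted map is additive in log10 abundance:

    log10(abundance_i) = base + sum_j c_i^j + eps,   eps ~ Normal(0, noise_sd)

with two per-residue components:

* an N-terminal position-specific score: the leading 20% of each sequence is
  divided into bins, and a bin-specific score matrix ``w[bin, aa]`` (centered
  per amino acid across bins, so the signal cannot be absorbed into overall
  composition) contributes ``pssm_scale * w[bin, aa] / n_lead``;
* a synthesis-cost component ``cost_weight * cost_z[aa] / N`` over all
  residues, with a positive planted per-amino-acid cost table (standardized
  internally).

Sequences are sampled under a selection-like bias: leading-region residues
favor amino acids with high bin scores (per-protein selection strength
``beta``), tail residues mildly favor cheap amino acids. Abundance variation
across proteins is therefore encoded positionally — permuting a sequence
destroys most of its planted contribution — which is exactly the
positional-vs-compositional contrast the downstream analyses probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA
from .data import ProteinRecord
from .md import CATrajectory


@dataclass
class SyntheticConfig:
    """Generation conditions for the planted-signal proteome."""

    n_proteins: int = 500
    length_range: tuple[int, int] = (100, 1000)
    n_replicates_max: int = 21
    noise_sd: float = 0.05           # log10 units, per replicate
    seed: int = 0
    # planted-model shape
    lead_fraction: float = 0.2       # leading part of the sequence carrying the PSSM
    n_bins: int = 2                  # position bins inside the leading region
    pssm_scale: float = 4.0          # log10 units carried by the positional component
    cost_weight: float = -1.0        # log10 units per sd of mean synthesis cost
    base: float = 2.5                # log10 molecules/cell intercept
    selection_range: tuple[float, float] = (0.75, 2.0)   # per-protein beta
    cheap_bias_max: float = 0.3      # tail-region bias toward cheap amino acids

    def validate(self) -> None:
        lo, hi = self.length_range
        if lo < 3 or hi < lo:
            raise ValueError(f"invalid length range {self.length_range}")
        if self.n_replicates_max < 1:
            raise ValueError("n_replicates_max must be >= 1")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0 < self.lead_fraction <= 1:
            raise ValueError("lead_fraction must be in (0, 1]")


@dataclass
class PlantedModel:
    """Ground-truth sequence-to-abundance map with per-residue contributions."""

    pssm: np.ndarray                 # (n_bins, 20), centered per aa across bins
    cost_raw: np.ndarray             # (20,) positive planted synthesis costs
    cost_weight: float
    pssm_scale: float
    lead_fraction: float
    base: float
    per_residue_truth: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def cost_z(self) -> np.ndarray:
        c = self.cost_raw
        return (c - c.mean()) / c.std()

    def n_lead(self, length: int) -> int:
        return max(1, int(self.lead_fraction * length))

    def bin_of(self, j: int, length: int) -> int:
        """Position bin of 0-based residue j, or -1 outside the leading region."""
        n_lead = self.n_lead(length)
        if j >= n_lead:
            return -1
        n_bins = self.pssm.shape[0]
        return min(n_bins - 1, j * n_bins // n_lead)

    def contributions(self, sequence: str) -> np.ndarray:
        """Per-residue contribution c^j to log10 abundance, any sequence."""
        n = len(sequence)
        n_lead = self.n_lead(n)
        idx = np.array([AA_INDEX[a] for a in sequence])
        c = self.cost_weight / n * self.cost_z[idx]
        for j in range(n_lead):
            c[j] += self.pssm_scale / n_lead * self.pssm[self.bin_of(j, n), idx[j]]
        return c

    def log10_abundance(self, sequence: str) -> float:
        """Noise-free log10 abundance of any sequence under the planted map."""
        return self.base + float(self.contributions(sequence).sum())


def _make_pssm(rng: np.random.Generator, n_bins: int) -> np.ndarray:
    w = rng.normal(size=(n_bins, N_AA))
    w -= w.mean(axis=0, keepdims=True)   # center per aa: invisible to composition
    w /= w.std()
    return w


def generate_proteome(config: SyntheticConfig) -> tuple[list[ProteinRecord], PlantedModel]:
    """Generate the planted-signal proteome.

    Returns protein records (each with 1..n_replicates_max positive abundance
    replicates) and the planted model carrying the per-residue ground truth
    for every generated protein. Identical config (including seed) gives
    byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pssm = _make_pssm(rng, config.n_bins)
    cost_raw = rng.uniform(10.0, 60.0, size=N_AA)   # ATP-like positive costs
    truth = PlantedModel(
        pssm=pssm,
        cost_raw=cost_raw,
        cost_weight=config.cost_weight,
        pssm_scale=config.pssm_scale,
        lead_fraction=config.lead_fraction,
        base=config.base,
    )
    cost_z = truth.cost_z
    lo, hi = config.length_range
    records: list[ProteinRecord] = []
    n_digits = len(str(config.n_proteins))
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        n_lead = truth.n_lead(length)
        beta = rng.uniform(*config.selection_range)
        gamma = rng.uniform(0.0, config.cheap_bias_max)
        # leading region: selection toward high bin scores
        lead_idx = np.empty(n_lead, dtype=int)
        p_lead_mean = np.zeros(N_AA)
        for j in range(n_lead):
            logits = beta * pssm[truth.bin_of(j, length)]
            p = np.exp(logits - logits.max())
            p /= p.sum()
            p_lead_mean += p / n_lead
            lead_idx[j] = rng.choice(N_AA, p=p)
        # tail: mild bias toward cheap amino acids, with the leading-region
        # enrichment compensated away so overall composition carries no
        # selection-strength information (the planted signal stays positional)
        q = np.exp(-gamma * cost_z)
        q /= q.sum()
        f_lead = n_lead / length
        p_tail = np.clip((q - f_lead * p_lead_mean) / (1.0 - f_lead), 1e-4, None)
        p_tail /= p_tail.sum()
        tail_idx = rng.choice(N_AA, p=p_tail, size=length - n_lead)
        seq = "".join(AMINO_ACIDS[k] for k in np.concatenate([lead_idx, tail_idx]))
        c = truth.contributions(seq)
        log10_mu = config.base + c.sum()
        n_rep = int(rng.integers(1, config.n_replicates_max + 1))
        eps = rng.normal(0.0, config.noise_sd, size=n_rep)
        abundances = (10.0 ** (log10_mu + eps)).tolist()
        pid = f"SYN{i + 1:0{n_digits}d}"
        records.append(ProteinRecord(pid, seq, abundances))
        truth.per_residue_truth[pid] = c
    return records, truth


# ---------------------------------------------------------------------------
# Per-amino-acid feature tables
# ---------------------------------------------------------------------------

@dataclass
class ResidueFeatureTable:
    """A scalar per amino acid, expandable to a per-residue track."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            raise ValueError(f"{self.name}: need exactly the 20 canonical amino acids")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError(f"{self.name}: non-finite values")

    def track(self, sequence: str) -> np.ndarray:
        return np.array([self.values[a] for a in sequence], dtype=float)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)


def make_feature_tables(
    truth: PlantedModel, seed: int = 0, n_decoys: int = 9
) -> list[ResidueFeatureTable]:
    """Build the per-amino-acid feature-table battery.

    Contains the planted synthesis-cost table (scaled copy), a noisy variant
    correlated with it (|r| > 0.5, to exercise redundancy reduction), and
    independent random physicochemical-style decoy tables. At least 10
    tables in total.
    """
    rng = np.random.default_rng(seed)
    tables = [
        ResidueFeatureTable(
            "cost_planted", dict(zip(AMINO_ACIDS, 0.5 * truth.cost_raw))
        )
    ]
    noisy = truth.cost_z + rng.normal(0.0, 0.5, size=N_AA)
    tables.append(ResidueFeatureTable("cost_noisy", dict(zip(AMINO_ACIDS, noisy))))
    for k in range(n_decoys):
        vals = rng.normal(size=N_AA)
        tables.append(
            ResidueFeatureTable(f"idx_{k + 1:02d}", dict(zip(AMINO_ACIDS, vals)))
        )
    return tables


# ---------------------------------------------------------------------------
# Toy trajectories
# ---------------------------------------------------------------------------

def generate_toy_trajectory(
    n_frames: int,
    n_residues: int,
    rmsf_profile: np.ndarray | float,
    seed: int = 0,
    protein_id: str = "toy",
) -> CATrajectory:
    """Gaussian-fluctuation toy trajectory with a known RMSF profile.

    Residues sit on a fixed helical backbone and receive isotropic Gaussian
    displacements with per-axis sd ``rmsf/sqrt(3)``, so the empirical RMSF
    converges to ``rmsf_profile`` as the number of frames grows.
    """
    profile = np.broadcast_to(
        np.asarray(rmsf_profile, dtype=float), (n_residues,)
    ).copy()
    if np.any(profile < 0):
        raise ValueError("target RMSF values must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_residues)
    backbone = np.column_stack(
        [2.3 * np.cos(t * 100 * np.pi / 180), 2.3 * np.sin(t * 100 * np.pi / 180),
         1.5 * t]
    )
    sd = profile / np.sqrt(3.0)
    disp = rng.normal(size=(n_frames, n_residues, 3)) * sd[None, :, None]
    return CATrajectory(protein_id, backbone[None, :, :] + disp)


# ---------------------------------------------------------------------------
# On-disk artifacts
# ---------------------------------------------------------------------------

def write_proteome(
    records: list[ProteinRecord], truth: PlantedModel, out_dir: str | Path
) -> None:
    """Write FASTA, abundance TSV, truth TSV and feature tables to a directory."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        out / "proteome.fasta",
        "fasta",
    )
    pd.DataFrame(
        [
            {"protein_id": r.id, "replicate_index": k, "abundance": a}
            for r in records
            for k, a in enumerate(r.abundances, start=1)
        ]
    ).to_csv(out / "abundance.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"protein_id": pid, "position": j + 1, "contribution": c}
            for pid, arr in truth.per_residue_truth.items()
            for j, c in enumerate(arr)
        ]
    ).to_csv(out / "truth.tsv", sep="\t", index=False)


def write_feature_tables(tables: list[ResidueFeatureTable], path: str | Path) -> None:
    df = pd.DataFrame({t.name: t.as_array() for t in tables},
                      index=list(AMINO_ACIDS))
    df.index.name = "aa"
    df.to_csv(path, sep="\t")


def read_feature_tables(path: str | Path) -> list[ResidueFeatureTable]:
    df = pd.read_csv(path, sep="\t", index_col="aa")
    return [
        ResidueFeatureTable(col, dict(zip(df.index, df[col].astype(float))))
        for col in df.columns
    ]
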