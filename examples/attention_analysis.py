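"""Attention profiles, feature correlations and the shuffled control.

Uses the planted-truth oracle (whose attention heads track the planted
cost and positional components) to demonstrate the profile pipeline:
redundancy filtering, per-residue profiles, correlation with a
physicochemical table under Bonferroni control, and the collapse of those
correlations on composition-preserving shuffles.
"""

import numpy as np

from mgem.attention import (bonferroni_threshold, correlation_distribution,
                            correlate_profile_with_feature,
                            profiles_for_sequence)
from mgem.data import fit_boxcox
from mgem.predictor import OraclePredictor
from mgem.synthetic import SyntheticConfig, generate_proteome, make_feature_tables

config = SyntheticConfig(n_proteins=60, length_range=(200, 400),
                         n_replicates_max=5, seed=2)
records, truth = generate_proteome(config)
transform = fit_boxcox([r.median_abundance for r in records])
oracle = OraclePredictor(truth, transform,
                         known_sequences={r.sequence for r in records})
cost_table = make_feature_tables(truth, seed=2)[0]

rng = np.random.default_rng(2)
profiles, sequences, shuf_profiles, shuf_sequences = {}, {}, {}, {}
for r in records:
    profiles[r.id] = profiles_for_sequence(oracle, r.sequence, r.id)
    sequences[r.id] = r.sequence
    shuffled = "".join(np.array(list(r.sequence))[rng.permutation(r.length)])
    shuf_profiles[r.id] = profiles_for_sequence(oracle, shuffled, r.id)
    shuf_sequences[r.id] = shuffled

kept = np.mean([len(p) for p in profiles.values()])
hits = correlate_profile_with_feature(profiles, sequences, cost_table,
                                      alpha=0.05, n_tests=len(records))
real = np.abs(correlation_distribution(profiles, sequences, cost_table))
ctrl = np.abs(correlation_distribution(shuf_profiles, shuf_sequences,
                                       cost_table))

print(f"non-redundant attention matrices per sequence: {kept:.1f}")
print(f"Bonferroni threshold (alpha=0.05, n={len(records)}): "
      f"{bonferroni_threshold(0.05, len(records)):.2e}")
print(f"proteins with a significant cost correlation: {len(hits)}/{len(records)}")
print(f"mean |r| vs planted cost table — real: {real.mean():.3f}, "
      f"shuffled control: {ctrl.mean():.3f}")
print("-> attention tracks the planted cost signal on real sequences and")
print("   carries no signal once residue order is destroyed.")
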