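"""Mutant-vs-wildtype trajectory comparison on toy ensembles.

Generates two Gaussian-fluctuation Cα trajectories — a wildtype and a
rigidified mutant — and runs the full comparison: convergence filter, RMSF
profiles with the rank-sum test, per-residue z-scores with direct/indirect
classification, and contact counts after the trajectory midpoint.
"""

import numpy as np

from mgem.md import compare_pair, convergence_check, summarize_comparisons
from mgem.synthetic import generate_toy_trajectory

n_residues = 60
wt_profile = np.linspace(0.8, 1.8, n_residues)
mut_profile = wt_profile.copy()
mut_profile[20:40] *= 0.4          # rigidified stretch, mostly unmutated
mutated_positions = [25, 26, 27]

wt = generate_toy_trajectory(2000, n_residues, wt_profile, seed=0,
                             protein_id="wildtype")
mut = generate_toy_trajectory(2000, n_residues, mut_profile, seed=1,
                              protein_id="mutant")

for traj in (wt, mut):
    rep = convergence_check(traj)
    print(f"{traj.protein_id}: converged={rep.converged} "
          f"(fraction within margin {rep.fraction_within:.2f})")

comp = compare_pair(wt, mut, mutated_positions)
summary = summarize_comparisons([comp])
print(f"\nRMSF medians: wildtype {np.median(comp.rmsf_wt):.2f} A, "
      f"mutant {np.median(comp.rmsf_mut):.2f} A")
print(f"rank-sum p (BH-adjusted): {summary.p_adj.iloc[0]:.2e}")
print(f"residues >=2 sd more rigid: {100 * comp.frac_lower_2sd:.0f}%")
print(f"direct (mutated) flagged positions:   {comp.direct_positions}")
print(f"indirect (unmutated) flagged positions: {comp.indirect_positions[:8]} ...")
print(f"contact ratio mutant/wildtype (second half): {comp.contact_ratio:.3f}")
print("-> the rigidified stretch is flagged significantly lower, and almost")
print("   all flagged residues are classified as indirect effects.")
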