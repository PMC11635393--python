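# Methods

This note documents the models, procedures and numerical choices behind the
package: what is computed, under which assumptions, and which design
decisions were genuinely open.

## Problem setting

The package studies how a protein's amino-acid *sequence* — as opposed to
its amino-acid *composition* — encodes its cellular abundance. Its centre
of gravity is interpretability and design machinery around a per-sequence
abundance regressor: turning attention tensors into per-residue profiles
with enrichment and correlation analyses, building a one-dimensional
*embedded ordering* over the encoder manifold, using that ordering to drive
deterministic guided mutagenesis (MGEM — Mutation Guided by an Embedded
Manifold), and comparing mutant against wildtype Cα trajectories. All
stages run offline on a synthetic planted-signal proteome whose per-residue
ground truth is known, so every claim the test suite makes is checkable
against a constructed truth.

## The planted-signal proteome (`mgem.synthetic`)

The generator emulates a yeast-scale regression-with-replicates dataset:
sequences of 100–1000 residues over the 20 canonical amino acids, up to 21
positive abundance replicates per protein (molecules/cell) spanning roughly
five orders of magnitude, with a planted additive map in log10 space:

    log10(abundance_i) = base + Σ_j c_i^j + ε,   ε ~ Normal(0, noise_sd)

Per-residue contributions `c_i^j` have two components:

* **N-terminal positional score.** The leading 20% of each sequence
  (`lead_fraction`) is split into `n_bins = 2` relative-position bins with
  a score matrix `w[bin, aa]` (unit variance). `w` is centred *per amino
  acid across bins*, so the positional signal is invisible to overall
  composition by construction: an amino acid favourable in the first half
  of the leading region is unfavourable in the second. Each leading residue
  contributes `pssm_scale · w[bin, aa] / n_lead`.
* **Synthesis cost.** A planted positive per-amino-acid cost table
  (uniform on 10–60, ATP-like) contributes `cost_weight · cost_z[aa] / N`
  per residue with `cost_weight = −1` by default (costly residues depress
  abundance).

Sequences are sampled under selection-like bias: leading-region residues
are drawn with probability ∝ exp(β·w[bin, aa]) with a per-protein selection
strength β ~ Uniform(0.75, 2.0), and tail residues favour cheap amino
acids (strength γ ~ Uniform(0, 0.3)). The leading-region enrichment is
*compensated in the tail* — the tail sampling distribution is adjusted so
the protein's expected overall composition is independent of β. Abundance
variation across the proteome is therefore genuinely positional: permuting
a sequence changes Σc for essentially every protein, a frequency-only
regression scores near zero, while the planted oracle is essentially
perfect. β's lower bound keeps real sequences separable from shuffled
decoys (a decoy's leading region has alignment score ≈ 0); its upper bound
keeps the compensation exact (no clipping), which is what bounds the
composition leak. `pssm_scale = 4` and this β window give a ~5–6
order-of-magnitude abundance span.

Defaults are the study conditions; the desk-scale experiments below narrow
only the problem size (protein count, length window, replicate cap), never
the planted mechanism.

What the generator does *not* emulate: homology structure between
sequences (every protein is independent, so exact-string uniqueness equals
biological uniqueness), realistic secondary-structure statistics,
measurement-batch effects, and any coupling between residues. Passing
tests therefore demonstrate that the machinery recovers a planted signal
of the stated shape — not that real proteomes carry such a signal.

Toy Cα trajectories are isotropic Gaussian displacements about a fixed
helical backbone with per-residue amplitude `rmsf/√3` per axis, the
simplest ensemble whose RMSF is known analytically.

## Dataset assembly (`mgem.data`)

Replicate expansion keeps one row per measurement (no averaging). Each row
then receives one composition-preserving shuffled decoy pinned to an
effectively-null target of 1e-5 molecules/cell — counter-examples that
force positional sensitivity. The Box-Cox exponent is fitted by maximum
likelihood (scipy) on per-protein medians, not replicate-expanded rows.
Splits (80/10/10) are assigned to unique sequence strings; replicate rows
and decoys inherit their source's split, so no sequence information
crosses split boundaries. Decoys participate in training and validation
loss; all reported R² values use real rows only, as per-protein medians.

## The regressor contract and its implementations (`mgem.predictor`)

Downstream analyses consume a three-method contract: `predict` (scalar on
the transformed target scale), `embed` (per-residue points plus the
start-token point) and `attentions` (row-stochastic layer×head matrices
over N+2 tokens, sequences being flanked by start/stop tokens).

**Trainable regressor.** A small pre-norm transformer encoder implemented
directly in numpy with hand-written reverse-mode gradients (`mgem.nn`):
token embeddings plus fixed sinusoidal positions plus a learned
relative-position channel (position/length — the planted signal is tied to
relative position, which absolute encodings represent poorly), multi-head
self-attention, ReLU feed-forward blocks, and a linear readout from the
start token. Training minimizes MSE with Adam, gradient-norm clipping at
1.0, early stopping on validation MSE, and a reduce-on-plateau learning
rate (halved after 3 stalled epochs, restarting from the best weights) —
the schedule is what makes desk-scale optimization reliable across seeds.
Gradients are verified against central finite differences in the test
suite. Desk-scale defaults are 2 layers × 2 heads; everything downstream
is architecture-agnostic.

**Planted-truth oracle.** Wraps the generator's ground truth: predictions
are the Box-Cox of the noise-free planted abundance, and embedding
coordinate 0 of residue j is exactly `c_i^j` (the start token carries Σc).
Its attention matrices are synthesized: for sequences of the generated
proteome, three heads carry softmax column mass over the planted cost
component, the planted positional component, and a position wave, each
with independent per-row noise (so the redundancy filter sees genuinely
distinct matrices); a fourth head is uniform (dropped by the filter as
constant). For any *other* sequence — notably composition-preserving
shuffles — attention is deterministic pseudo-random noise keyed by the
sequence hash. This mirrors the behaviour of a model trained with shuffled
decoys, for which permuted input carries no recognizable signal, and is
what makes the shuffled-control contrast reproducible with an oracle.

**Composition baseline.** Ordinary least squares on the 20 amino-acid
frequencies (least-norm under rank deficiency), permutation-invariant by
construction.

## Attention analysis (`mgem.attention`)

Profiles average an attention matrix over the query axis after stripping
the special tokens and renormalizing rows: `values[j]` is the percent of
attention residue j receives (profiles sum to 100). The orientation
("attended-by" = column mean) is exposed as a flag since the convention is
the one genuinely ambiguous choice; the conservation invariant holds
either way. Patterns are positions with within-profile z-score > 1
(z-scores are computed per profile, not pooled across a protein's
profiles).

Redundancy filtering keeps matrices whose flattened Pearson correlation
stays below 0.01 in absolute value against at least 90% of the others;
anticorrelated duplicates are treated as redundant (hence |r|), and
constant matrices are dropped as degenerate. Feature correlations per
protein keep the maximum-|r| profile among those clearing the Bonferroni
threshold α/n; the control variant reports every protein's best
correlation unthresholded, which is what shuffled-control distributions
are drawn from. Feature-set redundancy reduction averages per-sequence
absolute track correlations and greedily drops, from the worst pair, the
member with the larger mean absolute correlation to all others (ties
lexicographic by name), matching the caret `findCorrelation` behaviour.

Secondary-structure enrichment uses one-sided hypergeometric tails in both
directions against the pooled annotation background across all analyzed
proteins, testing only letters with more than 10 pattern-position
occurrences. Domain coverage compares the best pattern's in-domain hit
fraction with an expectation built from the same pattern's outside hits
divided by the number of *non-overlapping* domain-length windows outside
(floor(outside/length) — "how many times the domain could fit"); domains
longer than half their protein are excluded, Wilcoxon signed-rank per
member database with Benjamini–Hochberg across databases. Partial
correlation is the Pearson correlation of least-squares residuals (with
intercept), with the p-value computed on n − 2 − k degrees of freedom so
it matches the field-standard implementation (pingouin, used as the
cross-check oracle in tests).

## Embedded ordering (`mgem.ordering`)

The ordering projector maps encoder-space points to one dimension. It is a
contract; `fit_projector` sweeps candidates and selects by the Spearman
correlation between projected residue-cloud centroids of held-out
sequences (10%) and their abundance targets:

* 1-D UMAP fitted on start-token points, one candidate per neighbor
  setting (1%, 5%, 10%, 25% of the training count), each with a ridge
  readout from embedding space to the UMAP coordinate so arbitrary points
  project parametrically;
* a supervised weak-label ridge projector fitted on residue points, each
  labeled with its protein's target.

On the desk-scale model the UMAP candidates order the manifold only
locally (centroid ρ ≈ 0.6) and the weak-label projector is reliably
selected (ρ ≈ 0.85–0.9); both are deterministic given the seed. The 1-D
axis orientation is arbitrary, so after selection the sign is fixed to
make the centroid–abundance Spearman positive ("higher = more abundant"),
which MGEM depends on. Normalized ordering values min-max scale against
the projected-point population, mapping the population extremes to exactly
0 and 1.

The importance–position curve converts each protein's ordering values to
ranks divided by length, interpolates onto a common relative-position grid
and averages. Ranks ascend with the ordering value, so with the axis
oriented positively the residues that contribute most score highest; under
the planted N-terminal selection the curve peaks inside the leading 20%,
and the guided-mutation map (below) correspondingly spares a well-selected
leading region.

With the planted-truth oracle the identity projector (coordinate 0)
reproduces per-residue contributions exactly. For the trained desk-scale
model, per-residue orderings do not recover planted per-residue
contributions (the 2-layer model's residue embeddings carry protein-level
context rather than linearly-decodable per-residue attributions); the
ordering's validated property is the population-level one — centroids
order held-out sequences by abundance.

## MGEM (`mgem.mutate`)

Deterministic, no randomness on the guided path. Targets are the
lowest-ordering residues of a scheme (fixed counts 2/5/10/20 or fractions
10/20/30%, resolved as floor(fraction·N), minimum 1), always excluding
position 1 (the initiator methionine slot). The shift Δ is the width of
the central 99% interval (quantiles 0.005–0.995) of the population of
projected residue values. Guides are the 10 highest-median-abundance
training proteins with their orderings. For each guide, every target
position j is substituted by the guide residue (guide position 1 excluded)
whose ordering value is closest to `o_j + Δ`, ties toward the lower guide
position, out-of-range values clamping to the guide's extreme; the
candidate (one whole sequence per guide) with the highest predicted
abundance wins. A per-residue donor mode (each target choosing its donor
across all guides) is available behind a flag; the default whole-guide
mode is the one the acceptance experiments exercise. The random control
substitutes the same number of uniformly chosen positions (never position
1) with uniformly chosen *different* amino acids, so the effective
substitution count always matches the scheme.

Percent abundance changes are reported on the raw molecules/cell scale
after inverting the Box-Cox transform. Substitution-rate maps bin relative
position to two decimals (100 bins), divide replacement counts by
wildtype counts per (amino acid, bin) and z-score within each amino acid;
empty bins are masked. Cost deltas compare mean residue cost per protein
between mutant and wildtype as percent change, with a paired t-test across
proteins.

## Trajectory metrics (`mgem.md`)

Frames are rigid-body superposed onto the last frame using proper
rotations only (reflections are never absorbed; implemented via the
standard optimal-superposition construction in scipy). RMSF is the
root-mean-square displacement about the time-average position. Contacts
count unordered Cα pairs within 8 Å with no minimum sequence separation
(an optional exclusion is available). Convergence: per-frame RMSD to the
superposition reference; a run converges iff ≥ 80% of final-quarter time
points lie within ±10% (relative) of that quarter's mean RMSD. The margin
anchor (quarter mean rather than final value) was an open choice, made for
scale-freeness, and both margin and fraction are parameters; the reference
frame itself (RMSD ≡ 0) is excluded from the quarter statistics.
Mutant–wildtype comparison: Wilcoxon rank-sum between the two RMSF
profiles (Benjamini–Hochberg across pairs in the summary), per-residue
z-scores of (mut − wt) on the wildtype profile's scale with ±2 sd
flagging, direct/indirect classification of flagged residues by membership
in the mutated-position set, and contact (and optionally supplied-SASA)
ratios over frames after the trajectory midpoint. SASA is consumed from
input files, never computed.

## Problem sizes and tolerances

The acceptance experiments are sized for a single CPU: the end-to-end
training run uses 500 proteins of 100–300 residues with up to 5 replicates
(≈3,000 dataset rows, a few minutes of training); mutation and
attention-control experiments use 60–120 proteins of 200–400 residues with
the planted-truth oracle (seconds). The 200–400 length window for the
mutation battery keeps every fraction scheme strictly larger than every
fixed-count scheme, making battery monotonicity well posed; it is also the
window used for positional-importance profiles. Numerical tolerances:
attention row-stochasticity at 1e-6; Box-Cox round-trip at 1e-9 relative;
exact hypergeometric agreement at 1e-12 relative on populations ≤ 60;
RMSF recovery at 5% with 8–10k frames. Degenerate inputs (constant
attention matrices, zero-variance feature tracks, collinear controls,
Δ = 0 populations) are dropped, skipped or warned about explicitly rather
than silently propagated.

## Known limitations

* The trained regressor's absolute R² depends on the random seed through
  both the generated proteome and the 10% test split (50 proteins); values
  ≈ 0.5–0.75 are typical at desk scale.
* Per-residue attribution from the trained model is not validated (see
  above); only the oracle path has exact per-residue semantics.
* The attention synthesized by the oracle encodes the planted components
  directly; it validates the analysis machinery, not any claim about what
  attention in a trained model attends to.
* Trajectory tooling assumes equal residue counts between compared
  trajectories and Cα-only coordinates.
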