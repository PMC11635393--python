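"""Guided mutagenesis: target selection, shift computation, donor choice,
determinism, controls, substitution maps, cost accounting."""

import numpy as np
import pytest
from scipy import stats

from mgem.data import fit_boxcox
from mgem.mutate import (
    Guide,
    MutationOutcome,
    MutationScheme,
    compute_shift,
    cost_delta,
    mgem_mutate,
    outcomes_frame,
    propose_from_guide,
    random_control,
    select_guides,
    select_targets,
    substitution_rate_profile,
)
from mgem.ordering import IdentityProjector, residue_ordering
from mgem.predictor import OraclePredictor
from mgem.synthetic import (
    ResidueFeatureTable,
    SyntheticConfig,
    generate_proteome,
    make_feature_tables,
)
from mgem.alphabet import AMINO_ACIDS


@pytest.fixture(scope="module")
def mgem_world():
    """Oracle + orderings + guides over a compact planted proteome."""
    # lengths 200-400 keep the fraction schemes strictly larger than
    # the fixed-count schemes, so the battery-monotonicity property is well
    # posed
    cfg = SyntheticConfig(n_proteins=60, length_range=(200, 400),
                          n_replicates_max=3, seed=17)
    records, truth = generate_proteome(cfg)
    transform = fit_boxcox([r.median_abundance for r in records])
    oracle = OraclePredictor(truth, transform,
                             known_sequences={r.sequence for r in records})
    proj = IdentityProjector()
    orderings = {
        r.id: residue_ordering(oracle, proj, r.sequence, r.id) for r in records
    }
    guides = select_guides(records, orderings, 10)
    population = np.concatenate([orderings[r.id].o for r in records])
    delta = compute_shift(population)
    return records, truth, transform, oracle, orderings, guides, delta


class TestSchemes:
    def test_fixed_and_fraction_resolution(self):
        assert MutationScheme(2).resolve(100) == 2
        assert MutationScheme(0.30).resolve(10) == 3
        assert MutationScheme(0.10).resolve(19) == 1
        assert MutationScheme(0.10).resolve(5) == 1   # floor, minimum 1

    def test_oversized_scheme_rejected(self):
        with pytest.raises(ValueError):
            MutationScheme(10).resolve(10)


class TestSelectTargets:
    def test_lowest_values_selected(self):
        o = np.array([0.5, 0.1, 0.9, 0.2])
        assert select_targets(o, MutationScheme(2)) == [2, 4]

    def test_leading_residue_never_selected(self):
        o = np.array([-5.0, 0.5, 0.1, 0.9])
        targets = select_targets(o, MutationScheme(2))
        assert 1 not in targets
        assert targets == [2, 3]

    def test_ties_break_to_lower_position(self):
        o = np.array([0.9, 0.3, 0.3, 0.3])
        assert select_targets(o, MutationScheme(1)) == [2]


class TestComputeShift:
    def test_uniform_interval_width(self, rng):
        delta = compute_shift(rng.uniform(size=10**6))
        assert delta == pytest.approx(0.99, abs=0.005)

    def test_standard_normal_width(self, rng):
        delta = compute_shift(rng.normal(size=10**6))
        # central 99% of a standard normal: 2 * 2.576 sd
        assert delta == pytest.approx(5.152, abs=0.05)

    def test_degenerate_population_warns(self):
        with pytest.warns(UserWarning):
            assert compute_shift(np.ones(200)) == 0.0

    def test_requires_population(self):
        with pytest.raises(ValueError):
            compute_shift(np.arange(50.0))


class TestProposeFromGuide:
    guide = Guide("G", "MLKW", np.array([9.0, 0.1, 0.5, 0.9]), 1e5)

    def test_nearest_ordering_value_donates(self):
        # target value 0.3 + delta 0.5 = 0.8 -> nearest guide value 0.9 -> W
        mutant = propose_from_guide("MAAA", [3], np.array([9.0, 0.2, 0.3, 0.4]),
                                    0.5, self.guide)
        assert mutant == "MAWA"

    def test_shift_beyond_range_clamps_to_extreme(self):
        mutant = propose_from_guide("MAAA", [2], np.array([9.0, 0.2, 0.3, 0.4]),
                                    50.0, self.guide)
        assert mutant == "MWAA"   # guide maximum

    def test_equidistant_ties_take_lower_guide_position(self):
        guide = Guide("G", "MLKW", np.array([9.0, 0.2, 0.4, 0.6]), 1e5)
        # wanted 0.3 + 0.2 = 0.5 is equidistant from 0.4 (K, pos 3) and
        # 0.6 (W, pos 4); the lower guide position donates
        mutant = propose_from_guide("MAAA", [2], np.array([9.0, 0.1, 0.3, 0.4]),
                                    0.2, guide)
        assert mutant == "MKAA"

    def test_guide_leading_residue_not_donated(self):
        # guide position 1 has the closest value (9.0) but is excluded
        mutant = propose_from_guide("MAAA", [2], np.array([9.0, 8.9, 0.3, 0.4]),
                                    0.0, self.guide)
        assert mutant[1] == "W"


class TestMgemMutate:
    def test_deterministic_and_structure_preserving(self, mgem_world):
        records, _, transform, oracle, orderings, guides, delta = mgem_world
        r = records[0]
        scheme = MutationScheme(5)
        a = mgem_mutate(r.sequence, oracle, orderings[r.id].o, guides, scheme,
                        delta, transform, r.id)
        b = mgem_mutate(r.sequence, oracle, orderings[r.id].o, guides, scheme,
                        delta, transform, r.id)
        assert a.mutant == b.mutant and a.guide_id == b.guide_id
        assert len(a.mutant) == len(r.sequence)
        assert 1 not in a.positions
        assert len(a.positions) <= 5
        untouched = [i for i in range(len(r.sequence))
                     if (i + 1) not in a.positions]
        for i in untouched:
            assert a.mutant[i] == r.sequence[i]

    def test_best_of_guides_optimality(self, mgem_world):
        records, _, transform, oracle, orderings, guides, delta = mgem_world
        r = records[5]
        scheme = MutationScheme(0.10)
        best = mgem_mutate(r.sequence, oracle, orderings[r.id].o, guides,
                           scheme, delta, transform, r.id)
        targets = select_targets(orderings[r.id].o, scheme)
        for guide in guides:
            candidate = propose_from_guide(r.sequence, targets,
                                           orderings[r.id].o, delta, guide)
            assert best.pred_mut >= oracle.predict(candidate) - 1e-12

    def test_guides_are_top_abundance_proteins(self, mgem_world):
        records, _, _, _, orderings, guides, _ = mgem_world
        abundances = sorted((r.median_abundance for r in records), reverse=True)
        guide_abundances = sorted((g.abundance for g in guides), reverse=True)
        assert guide_abundances == abundances[:10]

    def test_scheme_battery_mean_increase_monotone(self, mgem_world):
        records, _, transform, oracle, orderings, guides, delta = mgem_world
        guide_ids = {g.protein_id for g in guides}
        subjects = [r for r in records if r.id not in guide_ids][:30]
        means = []
        for amount in (2, 5, 10, 20, 0.10, 0.20):
            outs = [
                mgem_mutate(r.sequence, oracle, orderings[r.id].o, guides,
                            MutationScheme(amount), delta, transform, r.id)
                for r in subjects
            ]
            means.append(np.mean([o.pct_change for o in outs]))
        assert all(b >= a for a, b in zip(means, means[1:]))
        assert means[0] > 0


class TestRandomControl:
    def test_reproducible_and_counted(self, mgem_world):
        records, _, transform, oracle, _, _, _ = mgem_world
        r = records[1]
        scheme = MutationScheme(0.10)
        a = random_control(r.sequence, oracle, scheme, transform, seed=7)
        b = random_control(r.sequence, oracle, scheme, transform, seed=7)
        assert a.mutant == b.mutant
        assert len(a.positions) == scheme.resolve(r.length)
        assert 1 not in a.positions
        # every substitution is a real change
        assert all(f != t for f, t in a.substitutions)

    def test_mean_change_nonpositive(self, mgem_world):
        records, _, transform, oracle, _, guides, _ = mgem_world
        guide_ids = {g.protein_id for g in guides}
        subjects = [r for r in records if r.id not in guide_ids][:30]
        outs = [
            random_control(r.sequence, oracle, MutationScheme(0.20), transform,
                           seed=100 + i, record_id=r.id)
            for i, r in enumerate(subjects)
        ]
        assert np.mean([o.pct_change for o in outs]) <= 0


class TestSubstitutionRateProfile:
    def _outcome(self, wildtype, mutant):
        positions = [i + 1 for i, (a, b) in enumerate(zip(wildtype, mutant))
                     if a != b]
        subs = [(wildtype[p - 1], mutant[p - 1]) for p in positions]
        return MutationOutcome("P", wildtype, mutant, "test", positions, subs,
                               None, 0.0, 0.0, 1.0, 1.0)

    def test_single_position_maps_to_single_bin(self):
        wt = "A" * 100
        mut = "A" * 50 + "W" + "A" * 49
        outs = [self._outcome(wt, mut)] * 20
        profile = substitution_rate_profile(outs)
        nonzero = profile[(profile.aa == "A") & (profile.rate > 0)]
        assert len(nonzero) == 1
        assert nonzero.iloc[0]["bin"] == 50

    def test_uniform_control_is_flat(self, mgem_world, rng):
        records, _, transform, oracle, _, _, _ = mgem_world
        outs = []
        for i, r in enumerate(records):
            outs.append(
                random_control(r.sequence, oracle, MutationScheme(0.30),
                               transform, seed=i, record_id=r.id)
            )
        profile = substitution_rate_profile(outs)
        z = profile.z.dropna()
        assert (np.abs(z) < 2).mean() > 0.9

    def test_well_selected_leading_region_is_spared(self):
        """Strong selection leaves no low-ordering residues up front, so the
        guided path never substitutes there."""
        cfg = SyntheticConfig(n_proteins=30, length_range=(200, 300),
                              n_replicates_max=3, seed=8,
                              selection_range=(3.5, 4.0))
        records, truth = generate_proteome(cfg)
        transform = fit_boxcox([r.median_abundance for r in records])
        oracle = OraclePredictor(truth, transform,
                                 known_sequences={r.sequence for r in records})
        proj = IdentityProjector()
        orderings = {r.id: residue_ordering(oracle, proj, r.sequence, r.id)
                     for r in records}
        guides = select_guides(records, orderings, 10)
        delta = compute_shift(
            np.concatenate([orderings[r.id].o for r in records])
        )
        lead_hits = total = 0
        for r in records:
            out = mgem_mutate(r.sequence, oracle, orderings[r.id].o, guides,
                              MutationScheme(0.10), delta, transform, r.id)
            n_lead = truth.n_lead(r.length)
            lead_hits += sum(1 for p in out.positions if p <= n_lead)
            total += len(out.positions)
        assert lead_hits / total < 0.05

    def test_needs_twenty_outcomes(self):
        with pytest.raises(ValueError):
            substitution_rate_profile([self._outcome("AA", "AW")] * 5)


class TestCostDelta:
    def _table(self):
        return ResidueFeatureTable(
            "cost", {a: float(10 + i) for i, a in enumerate(AMINO_ACIDS)}
        )

    def test_identity_mutation_reports_no_change(self):
        wt = "ACDEFGHIKL" * 5
        out = MutationOutcome("P", wt, wt, "s", [], [], None, 0, 0, 1, 1)
        df = cost_delta([out, out], [self._table()])
        assert df.mean_pct_change.iloc[0] == 0.0
        assert df.p.iloc[0] == 1.0

    def test_substituting_cheapest_reduces_cost(self):
        wt = "WYWYWYWYWY" * 3   # expensive residues
        mut = "AAAAA" + wt[5:]  # A is the cheapest in the table
        out = MutationOutcome("P", wt, mut, "s",
                              list(range(1, 6)),
                              [(wt[i], "A") for i in range(5)],
                              None, 0, 0, 1, 1)
        df = cost_delta([out, out, out], [self._table()])
        assert df.mean_pct_change.iloc[0] < 0

    def test_planted_cost_direction(self, mgem_world):
        """With a negative planted cost weight, guided mutants get cheaper
        while random mutants (biased wildtypes) get more expensive."""
        records, truth, transform, oracle, orderings, guides, delta = mgem_world
        tables = make_feature_tables(truth, seed=17)
        guide_ids = {g.protein_id for g in guides}
        subjects = [r for r in records if r.id not in guide_ids][:30]
        scheme = MutationScheme(0.20)
        mg = [mgem_mutate(r.sequence, oracle, orderings[r.id].o, guides,
                          scheme, delta, transform, r.id) for r in subjects]
        rc = [random_control(r.sequence, oracle, scheme, transform,
                             seed=200 + i, record_id=r.id)
              for i, r in enumerate(subjects)]
        cost_table = tables[0]
        mg_cost = np.array([cost_table.track(o.mutant).mean() for o in mg])
        rc_cost = np.array([cost_table.track(o.mutant).mean() for o in rc])
        t, p = stats.ttest_rel(mg_cost, rc_cost)
        assert mg_cost.mean() < rc_cost.mean()
        assert p < 0.05
        assert cost_delta(mg, [cost_table]).mean_pct_change.iloc[0] < 0


def test_outcomes_frame_shape(mgem_world):
    records, _, transform, oracle, orderings, guides, delta = mgem_world
    r = records[2]
    out = mgem_mutate(r.sequence, oracle, orderings[r.id].o, guides,
                      MutationScheme(2), delta, transform, r.id)
    df = outcomes_frame([out])
    assert set(df.columns) >= {"protein_id", "scheme", "guide_id", "positions",
                               "from", "to", "pred_wt", "pred_mut", "pct_change"}
    assert df.iloc[0]["protein_id"] == r.id
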