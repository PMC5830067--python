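"""Mann-Whitney screens, loading/p-value association, CD4-slope rule."""

import numpy as np
import pytest

from plscm import (
    CD4Trajectory,
    SyntheticCohortConfig,
    classify_cd4_slope,
    fit_pls,
    generate_cohort,
    loading_pvalue_association,
    mann_whitney,
    partition_by_selection,
    screen_variables,
    two_stage_fit,
)
from plscm.exceptions import InsufficientDataError
from plscm.univariate import significant_indices

from _oracles import mannwhitney_exact_oracle


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(0.1)

    def test_identical_samples_null(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, x)
        assert res.U == pytest.approx(len(x) ** 2 / 2)
        assert res.p_two_sided >= 0.99

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_p_matches_enumeration_oracle(self):
        """Exact p equals full label-arrangement enumeration, n0+n1 <= 10."""
        rng = np.random.default_rng(123)
        for _ in range(15):
            n0 = int(rng.integers(2, 6))
            n1 = int(rng.integers(2, 6))
            pooled = rng.permutation(np.arange(1.0, n0 + n1 + 1))  # no ties
            x0, x1 = pooled[:n0], pooled[n0:]
            res = mann_whitney(x0, x1)
            u_oracle, p_oracle = mannwhitney_exact_oracle(x0, x1)
            assert res.method == "exact"
            assert res.U == pytest.approx(u_oracle)
            assert res.p_two_sided == pytest.approx(p_oracle, abs=1e-12)

    def test_u_complement_identity(self, rng):
        x0 = rng.normal(size=9)
        x1 = rng.normal(size=13)
        a = mann_whitney(x0, x1)
        b = mann_whitney(x1, x0)
        assert a.U + b.U == pytest.approx(len(x0) * len(x1))

    def test_power_at_study_sizes(self):
        """22-vs-14 with a 1.5-SD shift rejects in >=80% of 200 replicates."""
        rng = np.random.default_rng(77)
        rejections = 0
        for _ in range(200):
            x0 = rng.standard_normal(22)
            x1 = rng.standard_normal(14) + 1.5
            rejections += mann_whitney(x0, x1).p_two_sided < 0.05
        assert rejections / 200 >= 0.8

    def test_ties_fall_back_to_normal_approx(self):
        res = mann_whitney([1, 1, 2, 3], [2, 3, 3, 4])
        assert res.method == "normal_approx"


class TestScreenVariables:
    def test_planted_effects_recovered(self):
        recalls = []
        for s in range(20):
            matrix, truth = generate_cohort(
                SyntheticCohortConfig(seed=800 + s, effect_size=1.5)
            )
            screen = screen_variables(matrix)
            sig = set(significant_indices(screen, 0.05))
            planted = set(truth.informative_indices.tolist())
            recalls.append(len(planted & sig) / len(planted))
        assert np.mean(recalls) >= 0.8

    def test_null_calibration_on_independent_variables(self):
        """Under no effect and no correlation, ~5% of variables reject."""
        fracs = []
        for s in range(20):
            matrix, _ = generate_cohort(
                SyntheticCohortConfig(
                    seed=900 + s, effect_size=0.0, factor_strength=0.0,
                    n_variables=200,
                )
            )
            screen = screen_variables(matrix)
            fracs.append(np.mean([r.p_two_sided < 0.05 for r in screen]))
        # 4000 independent tests; binomial SE ~ 0.0034, allow 2x plus
        # the Mann-Whitney test's small-sample conservatism
        assert abs(np.mean(fracs) - 0.05) < 0.02

    def test_constant_variable_not_significant(self):
        matrix, _ = generate_cohort(
            SyntheticCohortConfig(
                seed=4, n_class0=5, n_class1=5, n_variables=3, n_informative=1
            )
        )
        matrix.values[:, 1] = 42.0
        screen = screen_variables(matrix)
        assert screen[1].p_two_sided > 0.9


class TestLoadingPValueAssociation:
    def test_negative_on_discriminative_cohorts(self):
        hits = 0
        for s in range(20):
            matrix, _ = generate_cohort(
                SyntheticCohortConfig(seed=1100 + s, effect_size=1.5)
            )
            sel = two_stage_fit(matrix.values, matrix.class_labels.astype(float), 3)
            screen = screen_variables(matrix)
            screen_sel = [screen[j] for j in sel.selected_indices]
            rho, p = loading_pvalue_association(sel.stage2_model, screen_sel)
            hits += (rho < 0) and (p < 0.05)
        assert hits >= 0.8 * 20

    def test_permuted_screen_labels_mostly_flat(self):
        """With screen p-values computed under permuted class labels —
        independent of the fitted model — the association disappears.

        Screening on the *same* labels the selection used would couple
        |coefficient| and p even at a null effect (selection bias), so the
        null check must break that coupling by permuting the labels that
        the screen sees.
        """
        flat = 0
        rng = np.random.default_rng(2024)
        for s in range(20):
            matrix, _ = generate_cohort(
                SyntheticCohortConfig(seed=1200 + s, effect_size=0.0)
            )
            sel = two_stage_fit(matrix.values, matrix.class_labels.astype(float), 3)
            import copy

            permuted = copy.deepcopy(matrix)
            permuted.class_labels = rng.permutation(matrix.class_labels)
            screen = screen_variables(permuted)
            screen_sel = [screen[j] for j in sel.selected_indices]
            _, p = loading_pvalue_association(sel.stage2_model, screen_sel)
            flat += p > 0.05
        assert flat >= 0.8 * 20

    def test_constant_pvalues_degenerate(self, small_xy):
        from plscm import MannWhitneyResult

        X, y = small_xy
        model = fit_pls(X, y, 2)
        screen = [MannWhitneyResult(5.0, 0.5, "exact") for _ in range(X.shape[1])]
        with pytest.raises(InsufficientDataError):
            loading_pvalue_association(model, screen)

    def test_too_few_variables(self):
        y = np.array([0, 1, 0, 1, 1, 0.0])
        X = np.column_stack([3 * y + 1, y + 2, 2 * y + 1])
        model = fit_pls(X, y, 1)
        from plscm import MannWhitneyResult

        res = [MannWhitneyResult(1.0, p, "exact") for p in (0.1, 0.2, 0.3)]
        with pytest.raises(InsufficientDataError):
            loading_pvalue_association(model, res)


class TestPartition:
    def test_all_selected_all_significant(self):
        from plscm import MannWhitneyResult

        screen = [MannWhitneyResult(1.0, 0.01, "exact") for _ in range(4)]
        part = partition_by_selection([0, 1, 2, 3], screen, 0.05)
        assert part.n_selected_significant == 4
        assert part.total == 4

    def test_disjoint_sets_fixture(self):
        from plscm import MannWhitneyResult

        # 10 variables: 0-2 selected only, 3-4 significant only, rest neither
        pvals = [0.5, 0.5, 0.5, 0.01, 0.01, 0.5, 0.5, 0.5, 0.5, 0.5]
        screen = [MannWhitneyResult(1.0, p, "exact") for p in pvals]
        part = partition_by_selection([0, 1, 2], screen, 0.05)
        assert (
            part.n_selected_significant,
            part.n_selected_nonsignificant,
            part.n_unselected_significant,
            part.n_unselected_nonsignificant,
        ) == (0, 3, 2, 5)

    def test_counts_conserve_panel_size(self, default_cohort):
        matrix, _ = default_cohort
        sel = two_stage_fit(matrix.values, matrix.class_labels.astype(float), 3)
        screen = screen_variables(matrix)
        part = partition_by_selection(sel.selected_indices, screen, 0.05)
        assert part.total == matrix.n_variables


class TestClassifyCD4Slope:
    def test_constant_counts_control(self):
        traj = CD4Trajectory("s", np.arange(5.0), np.full(5, 900.0))
        cls = classify_cd4_slope(traj)
        assert cls.slope == pytest.approx(0.0)
        assert cls.category == "control"

    def test_declining_with_noise_is_case(self):
        rng = np.random.default_rng(6)
        t = np.arange(10.0)
        counts = 1000.0 - 80.0 * t + rng.normal(0, 20, 10)
        cls = classify_cd4_slope(CD4Trajectory("s", t, counts))
        assert cls.category == "case"
        assert cls.slope == pytest.approx(-80.0, abs=15.0)

    def test_significant_increase_is_control(self):
        t = np.arange(8.0)
        counts = 600.0 + 50.0 * t + np.array([1, -2, 0, 3, -1, 2, 0, -3.0])
        cls = classify_cd4_slope(CD4Trajectory("s", t, counts))
        assert cls.slope_p < 0.05 and cls.slope > 0
        assert cls.category == "control"

    def test_invariance_to_origin_and_units(self):
        rng = np.random.default_rng(8)
        t = np.arange(6.0)
        counts = 900.0 - 60.0 * t + rng.normal(0, 15, 6)
        base = classify_cd4_slope(CD4Trajectory("s", t, counts))
        shifted = classify_cd4_slope(CD4Trajectory("s", t + 3.0, counts))
        scaled = classify_cd4_slope(CD4Trajectory("s", t, counts * 2.0))
        assert base.category == shifted.category == scaled.category
        assert shifted.slope == pytest.approx(base.slope)
        assert scaled.slope == pytest.approx(2 * base.slope)
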