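import numpy as np
import pytest

from cascade_chronos import (
    CascadeRegime,
    TwoGeneRegime,
    classify_two_gene,
    fpt_noise_identical,
    fpt_stats_cascade,
    inclusion_criterion,
    min_noise_identical,
    optimal_mean_time_identical,
    optimal_thresholds_general,
    optimize_two_gene,
)


@pytest.mark.parametrize(
    "ratio, gT, expected",
    [
        (2.0, 0.5, TwoGeneRegime.GENE1_ONLY),  # e^0.5 ~ 1.649 < 2
        (1.0, 0.5, TwoGeneRegime.COUPLED),
        (1.0, 3.0, TwoGeneRegime.COUPLED),
        (0.5, 0.5, TwoGeneRegime.GENE2_ONLY),  # e^-0.5 ~ 0.607 > 0.5
        (np.exp(0.5), 0.5, TwoGeneRegime.GENE1_ONLY),  # boundary tie
        (np.exp(-0.5), 0.5, TwoGeneRegime.GENE2_ONLY),
    ],
)
def test_two_gene_regime_classification(ratio, gT, expected):
    assert classify_two_gene(ratio, gT) is expected


def test_coupling_interval_widens_with_dilution():
    """A noise ratio excluded at small gammaT is coupled at larger gammaT."""
    assert classify_two_gene(2.0, 0.5) is TwoGeneRegime.GENE1_ONLY
    assert classify_two_gene(2.0, 1.0) is TwoGeneRegime.COUPLED
    assert classify_two_gene(0.5, 0.5) is TwoGeneRegime.GENE2_ONLY
    assert classify_two_gene(0.5, 1.0) is TwoGeneRegime.COUPLED


def test_symmetric_two_gene_optimum():
    res = optimize_two_gene(0.0045, 0.0045, 2.0)
    assert res.regime is TwoGeneRegime.COUPLED
    assert res.alphas_opt == pytest.approx([1 - np.exp(-1)] * 2, rel=1e-12)


def test_coupled_two_gene_closed_form():
    """CV1/CV2 = 2, gammaT = 2: the quieter gene takes the higher threshold
    and the product identity (1-a1)(1-a2) = e^{-gammaT} holds."""
    res = optimize_two_gene(4 * 0.001, 0.001, 2.0)  # cv ratio CV2/CV1 = 1/2
    a1, a2 = res.alphas_opt
    assert a1 == pytest.approx(0.47973990497711105, rel=1e-10)
    assert a2 == pytest.approx(0.7398699524885555, rel=1e-10)
    assert (1 - a1) * (1 - a2) == pytest.approx(np.exp(-2.0), rel=1e-12)


def test_single_gene_regime_boundary_solution():
    res = optimize_two_gene(0.001, 0.001 * 4.0, 0.5)  # ratio 2 > e^0.5
    assert res.regime is TwoGeneRegime.GENE1_ONLY
    assert res.alphas_opt == pytest.approx([1 - np.exp(-0.5), 0.0], abs=1e-14)
    assert res.excluded_genes == (1,)
    res2 = optimize_two_gene(0.001 * 4.0, 0.001, 0.5)
    assert res2.regime is TwoGeneRegime.GENE2_ONLY
    assert res2.alphas_opt == pytest.approx([0.0, 1 - np.exp(-0.5)], abs=1e-14)


def test_regime_boundaries_are_continuous():
    """Approaching the coupling boundary, the interior optimum slides to
    the single-gene corner solution."""
    gT = 1.0
    eps = 1e-8
    near = optimize_two_gene(0.01, 0.01 * np.exp(2 * gT) * (1 - eps), gT)
    assert near.regime is TwoGeneRegime.COUPLED
    assert near.alphas_opt[1] == pytest.approx(0.0, abs=1e-7)
    assert near.alphas_opt[0] == pytest.approx(1 - np.exp(-gT), abs=1e-7)


def test_general_identical_genes_share_threshold():
    for n in [1, 2, 5, 10]:
        res = optimal_thresholds_general([0.0045] * n, 2.0)
        assert res.regime is CascadeRegime.ALL_INCLUDED
        assert res.alphas_opt == pytest.approx([1 - np.exp(-2.0 / n)] * n, rel=1e-12)


def test_general_reduces_to_two_gene_coupled_formulas():
    res_n = optimal_thresholds_general([0.004, 0.001], 2.0)
    res_2 = optimize_two_gene(0.004, 0.001, 2.0)
    assert res_n.alphas_opt == pytest.approx(res_2.alphas_opt, rel=1e-12)
    assert res_n.cv2_T_opt == pytest.approx(res_2.cv2_T_opt, rel=1e-12)


def test_overnoisy_gene_excluded_then_resolved():
    """CVs (1, 1, 10) at gammaT = 0.3: the third gene fails the inclusion
    interval, is dropped, and the remaining pair shares the time evenly."""
    cv2 = [1.0, 1.0, 100.0]
    assert not inclusion_criterion(10.0, [1.0, 1.0, 10.0], 0.3)
    res = optimal_thresholds_general(cv2, 0.3)
    assert res.regime is CascadeRegime.SOME_EXCLUDED
    assert res.excluded_genes == (2,)
    assert res.alphas_opt[2] == 0.0
    assert res.alphas_opt[:2] == pytest.approx([1 - np.exp(-0.15)] * 2, rel=1e-12)


def test_mean_constraint_and_stationarity_identity(rng):
    """Optimal thresholds satisfy the fixed-mean constraint to 1e-10 and
    the identity CV_i/(1 - alpha_i*) = const across included genes."""
    for _ in range(25):
        n = rng.integers(1, 7)
        gT = rng.uniform(0.2, 3.0)
        cv2 = rng.uniform(1e-4, 0.05, size=n)
        res = optimal_thresholds_general(cv2, gT)
        a = np.array(res.alphas_opt)
        assert np.prod(1 - a) == pytest.approx(np.exp(-gT), rel=1e-10)
        included = [i for i in range(n) if i not in res.excluded_genes]
        vals = np.sqrt(cv2[included]) / (1 - a[included])
        np.testing.assert_allclose(vals, vals[0], rtol=1e-10)


def test_optimum_beats_random_feasible_thresholds(rng):
    """Spot check of global optimality: for 20 random parameter draws the
    closed-form optimum undercuts 1000 random threshold vectors that hit
    the same mean FPT."""
    for _ in range(20):
        n = rng.integers(2, 6)
        gT = rng.uniform(0.3, 3.0)
        cv2 = np.exp(rng.uniform(np.log(1e-4), np.log(0.05), size=n))
        res = optimal_thresholds_general(cv2, gT)
        # random split of the log-time budget across stages
        w = rng.dirichlet(np.ones(n), size=1000)
        alphas = 1.0 - np.exp(-gT * w)
        noises = [
            fpt_stats_cascade(a_row, cv2, gamma=1.0).cv2_T for a_row in alphas
        ]
        assert res.cv2_T_opt <= min(noises) * (1 + 1e-9)


def test_inclusion_reduces_to_two_gene_interval():
    """For N = 2 the criterion is exactly e^{-gT} < CV2/CV1 < e^{gT}."""
    gT = 0.8
    for ratio in [0.2, np.exp(-gT) * 0.999, np.exp(-gT) * 1.001, 1.0, np.exp(gT) * 0.999, np.exp(gT) * 1.001, 5.0]:
        expected = bool(np.exp(-gT) < ratio < np.exp(gT))
        assert inclusion_criterion(ratio, [1.0, ratio], gT) is expected


def test_inclusion_identical_and_no_dilution_limits():
    assert inclusion_criterion(1.0, [1.0] * 5, 0.3)
    # gamma -> 0: the interval collapses; any ratio != 1 is excluded
    assert not inclusion_criterion(1.001, [1.0, 1.001], 1e-9)
    assert not inclusion_criterion(0.999, [1.0, 0.999], 1e-9)


def test_optimal_mean_time_root():
    """(1 - x) e^{2x} = 1 has its positive root at x ~ 0.797, and the
    cascade optimum scales linearly with N."""
    x1 = optimal_mean_time_identical(1)
    assert round(x1, 3) == 0.797
    assert (1 - x1) * np.exp(2 * x1) - 1 == pytest.approx(0.0, abs=1e-12)
    assert optimal_mean_time_identical(5) == pytest.approx(5 * x1, rel=1e-12)


def test_min_noise_identical_values():
    v1 = min_noise_identical(1, 1.0)
    assert v1 == pytest.approx(6.17655460948348, rel=1e-10)
    assert abs(v1 - 6.181) < 1e-2  # three-decimal-rounded-root convention
    assert min_noise_identical(4, 1.0) == pytest.approx(v1 / 4, rel=1e-12)
    assert min_noise_identical(3, 0.0045) == pytest.approx(0.0045 * v1 / 3, rel=1e-12)


def test_min_noise_coincides_with_dense_grid_minimum():
    """Brute-force minimization of the identical-gene noise over gammaT
    lands on the transcendental-root optimum."""
    for n in [1, 3, 5]:
        grid = np.linspace(0.05, 8.0, 200_001)
        vals = fpt_noise_identical(n, 1.0, grid)
        gT_star = optimal_mean_time_identical(n)
        assert grid[np.argmin(vals)] == pytest.approx(gT_star, abs=2 * (grid[1] - grid[0]))
        assert vals.min() == pytest.approx(min_noise_identical(n, 1.0), rel=1e-8)


def test_optimizer_input_validation():
    with pytest.raises(ValueError):
        optimal_thresholds_general([], 1.0)
    with pytest.raises(ValueError):
        optimal_thresholds_general([0.1, -0.1], 1.0)
    with pytest.raises(ValueError):
        classify_two_gene(0.0, 1.0)
    with pytest.raises(ValueError):
        optimal_mean_time_identical(0)
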