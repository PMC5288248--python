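"""Maximum-TSS machinery, the Monte Carlo runner, and the fixed-rate design."""

import numpy as np
import pandas as pd
import pytest

from tssprev.experiment import (
    CutoffGrid,
    SimulationConfig,
    allouche_replication,
    fixed_rate_confusion,
    max_tss,
    run_experiment,
    tss_curve,
)
from tssprev.metrics import UndefinedRateError, tss
from tssprev.simulator import ModelScenario, LabeledPredictions, sample_labeled_predictions

from conftest import brute_force_max_tss, brute_force_tss_curve


def make_data(labels, probs):
    return LabeledPredictions(
        labels=np.asarray(labels, dtype=np.int8),
        probs=np.asarray(probs, dtype=float),
        scenario=ModelScenario.from_name("linear"),
        prevalence=float(np.mean(labels)),
    )


def test_cutoff_grid_default_and_validation():
    grid = CutoffGrid()
    assert len(grid) == 19
    np.testing.assert_allclose(grid.values, np.arange(1, 20) * 0.05)
    with pytest.raises(ValueError):
        CutoffGrid(values=np.array([0.2, 0.1]))
    with pytest.raises(ValueError):
        CutoffGrid(values=np.array([0.0, 0.5]))


def test_tss_curve_separable_example(default_grid):
    data = make_data([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
    curve = tss_curve(data, default_grid)
    for c, v in curve:
        if 0.2 <= c < 0.8:
            assert v == 1.0
        else:
            assert v < 1.0
    np.testing.assert_allclose(
        curve, brute_force_tss_curve(data.labels, data.probs, default_grid.values),
        atol=1e-14,
    )


def test_tss_curve_flat_cases(default_grid):
    constant = make_data([1, 0, 1, 0], [0.4] * 4)
    assert np.all(tss_curve(constant, default_grid)[:, 1] == 0.0)
    perfect = make_data([1, 1, 0, 0], [1.0, 1.0, 0.0, 0.0])
    assert np.all(tss_curve(perfect, default_grid)[:, 1] == 1.0)


def test_tss_curve_single_class_raises(default_grid):
    with pytest.raises(UndefinedRateError):
        tss_curve(make_data([1, 1], [0.5, 0.6]), default_grid)


def test_max_tss_examples_and_tie_break(default_grid):
    assert max_tss(make_data([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]), default_grid) == (1.0, 0.2)
    # flat curve: the smallest cutoff wins the tie
    assert max_tss(make_data([1, 0], [0.3, 0.3]), default_grid) == (0.0, 0.05)
    assert max_tss(make_data([1, 1, 0], [1.0, 1.0, 0.0]), default_grid) == (1.0, 0.05)


@pytest.mark.parametrize("seed", range(8))
def test_max_tss_matches_brute_force_on_random_data(seed, default_grid):
    data = sample_labeled_predictions("square_root", 60, 0.3, seed)
    got = max_tss(data, default_grid)
    expected = brute_force_max_tss(data.labels, data.probs, default_grid.values)
    assert got[0] == pytest.approx(expected[0], abs=1e-14)
    assert got[1] == expected[1]


def test_run_experiment_reproducible_and_subset_stable():
    base = SimulationConfig(
        scenarios=("linear",), sample_sizes=(100,), prevalence_grid=(0.25,),
        n_reps=3, seed=9,
    )
    a = run_experiment(base)
    b = run_experiment(base)
    pd.testing.assert_frame_equal(a, b)
    # the same cell inside a larger factorial reproduces the same numbers
    wider = SimulationConfig(
        scenarios=("quadratic", "linear"), sample_sizes=(100,),
        prevalence_grid=(0.25, 0.5), n_reps=3, seed=9,
    )
    w = run_experiment(wider)
    row = w[(w.scenario == "linear") & (w.prevalence == 0.25)].iloc[0]
    assert row["mean_max_tss"] == a.iloc[0]["mean_max_tss"]
    assert row["sd_max_tss"] == a.iloc[0]["sd_max_tss"]


def test_run_experiment_large_sample_consistency(large_sample_study):
    """At N=10000 the mean maximum approaches the theoretical 0.75."""
    row = large_sample_study[large_sample_study.scenario == "quadratic"].iloc[0]
    assert row["mean_max_tss"] == pytest.approx(0.75, abs=0.01)


def test_bias_decays_with_sample_size():
    """Mean max TSS shrinks toward the theoretical value as N grows."""
    config = SimulationConfig(
        scenarios=("square_root",), sample_sizes=(100, 1000, 10000),
        prevalence_grid=(0.5,), n_reps=200, seed=3,
    )
    res = run_experiment(config).sort_values("n_total")
    means = res["mean_max_tss"].to_numpy()
    assert means[0] > means[1] > means[2]
    star = 1 - 2 * 0.5**1.5
    assert means[2] - star < 0.01


def test_fixed_rate_confusion_real_mode_reproduces_worked_examples():
    cm = fixed_rate_confusion(0.8, 0.8, 0.5, 100, "real")
    assert tss(cm).tss == pytest.approx(0.6)
    cm2 = fixed_rate_confusion(0.7, 0.9, 0.5, 100, "real")
    assert tss(cm2).tss == pytest.approx(0.6)


def test_fixed_rate_confusion_integer_mode_rounding_jitter():
    cm = fixed_rate_confusion(0.8, 0.8, 0.07, 100, "integer")
    assert cm.integer_mode
    assert cm.tp == 6  # round(0.8 * 7) = round(5.6)
    res = tss(cm)
    assert res.tpr == pytest.approx(6 / 7)
    p, nn = 7, 93
    bound = 0.5 * (1 / p + 1 / nn)
    assert abs(res.tss - 0.6) <= bound
    assert res.tss != pytest.approx(0.6, abs=1e-6)  # jitter is real


def test_fixed_rate_confusion_rejects_bad_input():
    with pytest.raises(ValueError):
        fixed_rate_confusion(1.2, 0.8, 0.5, 100)
    with pytest.raises(ValueError):
        fixed_rate_confusion(0.8, 0.8, 0.001, 100)  # P rounds to 0
    with pytest.raises(ValueError):
        fixed_rate_confusion(0.8, 0.8, 0.5, 100, mode="fuzzy")


def test_allouche_replication_constant_real_tss():
    table = allouche_replication(0.8, 0.8, n_total=100)
    assert len(table) == 19
    np.testing.assert_allclose(table["tss_real"], 0.6, atol=1e-12)
    perfect = allouche_replication(1.0, 1.0, n_total=100)
    np.testing.assert_allclose(perfect["tss_real"], 1.0, atol=1e-15)
    np.testing.assert_allclose(perfect["tss_integer"], 1.0, atol=1e-15)


def test_allouche_replication_integer_rounding_bound_large_n():
    table = allouche_replication(0.83, 0.77, n_total=10000)
    assert np.max(np.abs(table["tss_integer"] - 0.6)) < 0.01
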