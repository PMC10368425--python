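"""Global hierarchical model: parameter vector, error model, likelihood."""

import math

import numpy as np
import pandas as pd
import pytest

import bindprof as bp
from bindprof.likelihood import build_layout, make_objective

from conftest import mst_spec

NM = 1e-9
LOG_2PI = math.log(2 * math.pi)


@pytest.mark.parametrize(
    "kind, n_bio, expected",
    [("mst", 3, 16), ("hill", 3, 9), ("mst", 1, 6), ("hill", 1, 5), ("mst", 6, 31)],
)
def test_count_parameters(kind, n_bio, expected):
    assert bp.count_parameters(kind, n_bio) == expected


def test_count_parameters_errors():
    with pytest.raises(ValueError):
        bp.count_parameters("isothermal", 3)
    with pytest.raises(ValueError):
        bp.count_parameters("mst", 0)


@pytest.mark.parametrize(
    "f, sa, sr, expected",
    [(123.0, 1.0, 0.0, 1.0), (0.0, 2.0, 0.5, 2.0), (10.0, 3.0, 0.4, 5.0)],
)
def test_error_sigma(f, sa, sr, expected):
    assert bp.error_sigma(f, bp.ErrorModelParams(sa, sr)) == pytest.approx(expected)


def test_error_sigma_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        bp.error_sigma(1.0, bp.ErrorModelParams(0.0, 0.0))


def _mst_params(labels, kd=10 * NM, sa=1.0, sr=0.0):
    per = {
        label: (
            bp.MstReplicateParams(Btot=10 * NM, Fn_B=0.0, Fn_AB=1.0),
            bp.ErrorModelParams(sa, sr),
        )
        for label in labels
    }
    return bp.GlobalParameterVector("mst", bp.SharedBindingParams(KD=kd), per)


def _dataset(rows):
    return bp.TitrationDataset(
        pd.DataFrame(rows, columns=["dose", "signal", "bio_rep", "tech_rep"])
    )


class TestNegativeLogLikelihood:
    def test_empty_dataset_scores_zero(self):
        data = _dataset([])
        assert bp.negative_log_likelihood(_mst_params([]), data) == 0.0

    def test_point_on_curve_closed_form(self):
        params = _mst_params(["b1"])
        rep, _ = params.per_replicate["b1"]
        f = bp.mst_response(params.shared, rep, 10 * NM)
        data = _dataset([(10 * NM, f, "b1", "t1")])
        assert bp.negative_log_likelihood(params, data) == pytest.approx(0.5 * LOG_2PI)

    def test_two_unit_residuals_closed_form(self):
        params = _mst_params(["b1"])
        rep, _ = params.per_replicate["b1"]
        f1 = bp.mst_response(params.shared, rep, 10 * NM)
        f2 = bp.mst_response(params.shared, rep, 20 * NM)
        data = _dataset([(10 * NM, f1 + 1.0, "b1", "t1"), (20 * NM, f2 - 1.0, "b1", "t1")])
        assert bp.negative_log_likelihood(params, data) == pytest.approx(1.0 + LOG_2PI)

    def test_additive_over_disjoint_datasets(self, mst_dataset):
        params = _mst_params(mst_dataset.bio_labels, sa=0.1)
        half = len(mst_dataset.frame) // 2
        d1 = bp.TitrationDataset(mst_dataset.frame.iloc[:half])
        d2 = bp.TitrationDataset(mst_dataset.frame.iloc[half:])
        total = bp.negative_log_likelihood(params, mst_dataset)
        assert total == pytest.approx(
            bp.negative_log_likelihood(params, d1) + bp.negative_log_likelihood(params, d2)
        )

    def test_invariant_to_technical_replicate_relabelling(self, mst_dataset):
        params = _mst_params(mst_dataset.bio_labels, sa=0.1)
        shuffled = mst_dataset.frame.copy()
        shuffled["tech_rep"] = shuffled["tech_rep"].map(lambda t: f"renamed_{t}")
        assert bp.negative_log_likelihood(params, mst_dataset) == pytest.approx(
            bp.negative_log_likelihood(params, bp.TitrationDataset(shuffled))
        )

    def test_missing_replicate_parameters_named(self, mst_dataset):
        params = _mst_params(["bio1"])
        with pytest.raises(ValueError, match="bio2"):
            bp.negative_log_likelihood(params, mst_dataset)

    def test_minimum_at_truth_on_noise_free_data(self, noise_free_mst_dataset):
        """NLL at the generating truth beats any +/-10% single-parameter nudge."""
        spec = mst_spec(seed=1, sigma_abs=0.0)
        truth = bp.true_parameters(spec)
        # score with a fixed, nonzero error model (curve parameters vary)
        layout = build_layout("mst", noise_free_mst_dataset.bio_labels)
        fun = make_objective(noise_free_mst_dataset, layout)
        per = {
            lab: (rep, bp.ErrorModelParams(0.01, 1e-6))
            for lab, (rep, _) in truth.per_replicate.items()
        }
        x0 = layout.flatten(bp.GlobalParameterVector("mst", truth.shared, per))
        nll0 = fun(x0)[0]
        for i, name in enumerate(layout.names):
            if name.startswith("sigma"):
                continue
            for sign in (+1, -1):
                x = x0.copy()
                if layout.transforms[i] == "log10":
                    x[i] += sign * np.log10(1.1)
                else:
                    x[i] *= 1 + sign * 0.1
                assert fun(x)[0] >= nll0 - 1e-9, name


@pytest.mark.parametrize("kind", ["mst", "hill"])
@pytest.mark.parametrize("n_bio", range(1, 7))
def test_flatten_unflatten_roundtrip(kind, n_bio):
    labels = [f"bio{i}" for i in range(n_bio)]
    layout = build_layout(kind, labels)
    assert layout.n_params == bp.count_parameters(kind, n_bio)
    rng = np.random.default_rng(n_bio)
    x = rng.uniform(-5, -1, layout.n_params)
    # keep linear-scale entries in sensible ranges
    for i, t in enumerate(layout.transforms):
        if t == "linear":
            x[i] = rng.uniform(0.3, 2.0)
    assert np.allclose(layout.flatten(layout.unflatten(x)), x, rtol=1e-12)


@pytest.mark.parametrize("kind", ["mst", "hill"])
def test_objective_matches_reference_nll_and_gradient(kind, mst_dataset, hill_dataset):
    """Fast vectorized objective vs the plain per-replicate NLL, and its
    analytic gradient vs central finite differences."""
    data = mst_dataset if kind == "mst" else hill_dataset
    layout = build_layout(kind, data.bio_labels)
    fun = make_objective(data, layout)
    rng = np.random.default_rng(7)
    if kind == "mst":
        x = np.array([-8.0] + [-8.0, 0.9, 0.55, -1.8, -2.5] * 3)
    else:
        x = np.array([-3.8, 1.4, 0.2, 1.0, 0.25, 0.9, 0.18, 1.1, -1.5])
    x += rng.normal(0, 0.03, x.shape)
    nll, grad = fun(x)
    assert nll == pytest.approx(
        bp.negative_log_likelihood(layout.unflatten(x), data), rel=1e-10
    )
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = 1e-6
        fd = (fun(x + e)[0] - fun(x - e)[0]) / 2e-6
        assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)


def test_dataset_validation_errors():
    with pytest.raises(ValueError, match="bio_rep"):
        bp.TitrationDataset(pd.DataFrame({"dose": [1e-9], "signal": [1.0]}))
    with pytest.raises(ValueError, match="row 1"):
        _dataset([(1e-9, 1.0, "b", "t"), (-1e-9, 1.0, "b", "t")])
    with pytest.raises(ValueError, match="row 0"):
        _dataset([(1e-9, "not-a-number", "b", "t")])
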