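"""Model fitting: round trips, nesting, determinism, error handling."""

import numpy as np
import pytest

from qeeg import (
    BGExpParams,
    FitConfig,
    FittingError,
    HistogramSpec,
    IntervalDistribution,
    QExpParams,
    compare_models,
    fit_bg,
    fit_qexp,
)


def _model_dist(params, n_bins=500, t_max=1000.0):
    return IntervalDistribution.from_model(
        params, HistogramSpec(n_bins=n_bins, t_max=t_max)
    )


class TestNoiselessRoundTrips:
    def test_fig1_parameters_recovered(self, fig1_params):
        res = fit_qexp(_model_dist(fig1_params))
        assert res.converged
        assert res.params.q == pytest.approx(1.22, abs=1e-3)
        assert res.params.c == pytest.approx(2.24, abs=1e-3)
        assert res.params.h == pytest.approx(1.07, abs=1e-3)
        assert res.params.b == pytest.approx(0.14, abs=1e-3)
        assert res.sse < 1e-10
        assert res.r2 > 1 - 1e-9

    def test_bg_parameters_recovered(self):
        truth = BGExpParams(b=0.05, c=1.0, h=1.0)
        res = fit_bg(_model_dist(truth))
        assert res.params.b == pytest.approx(truth.b, abs=1e-3)
        assert res.params.c == pytest.approx(truth.c, abs=1e-3)
        assert res.params.h == pytest.approx(truth.h, abs=1e-3)
        assert res.sse < 1e-10

    def test_recovery_grid(self, rng):
        """Noiseless round trips across the valid parameter space.

        Ground truths are drawn with interval scales inside the
        histogram window; q must come back within 0.01 and the shape
        parameters within 5% relative error.
        """
        n_ok = 0
        draws = 0
        while n_ok < 20 and draws < 60:
            draws += 1
            c = rng.uniform(0.2, 3.5)
            h = rng.uniform(0.6, 1.8)
            u = rng.uniform(0.15, 0.85)
            q = 1 + u * h / (c + 1)
            if not 1.05 <= q <= 1.8:
                continue
            scale = rng.uniform(30.0, 200.0)  # ms
            b = scale ** (-h) / (q - 1)
            truth = QExpParams(b=b, c=c, h=h, q=q)
            dist = _model_dist(truth)
            if np.count_nonzero(dist.probabilities) < 8:
                continue
            res = fit_qexp(dist)
            assert abs(res.params.q - q) < 0.01, (truth, res.params)
            for name in ("b", "c", "h"):
                rel = abs(getattr(res.params, name) - getattr(truth, name)) / abs(
                    getattr(truth, name)
                )
                assert rel < 0.05, (name, truth, res.params)
            n_ok += 1
        assert n_ok >= 20


class TestModelComparison:
    def test_qexp_data_prefers_qexp(self):
        truth = QExpParams(b=0.05, c=0.5, h=1.0, q=1.6)  # heavy tail
        comp = compare_models(_model_dist(truth))
        assert comp.preferred == "qexp"
        assert comp.bg.sse > comp.qexp.sse

    def test_bg_data_pins_q_at_lower_bound(self):
        truth = BGExpParams(b=0.5, c=1.0, h=1.0)
        comp = compare_models(_model_dist(truth, t_max=100.0))
        # nested models: the q-exponential matches the BG fit, with q -> 1
        assert abs(comp.delta_sse) < 1e-9
        assert comp.qexp.params.q < 1.01

    def test_deterministic_given_seed(self, fig1_params):
        dist = _model_dist(fig1_params)
        cfg = FitConfig(seed=7)
        a = compare_models(dist, cfg)
        b = compare_models(dist, cfg)
        assert a.qexp.params == b.qexp.params
        assert a.bg.params == b.bg.params
        assert a.to_dict() == b.to_dict()

    def test_nesting_inequality(self, rng):
        for _ in range(3):
            iv = rng.gamma(2.0, 100.0, 4000)
            counts, edges = np.histogram(iv, bins=np.linspace(0, 1000, 201))
            dist = IntervalDistribution(
                bin_edges=edges,
                probabilities=counts / counts.sum(),
                n_total=int(counts.sum()),
            )
            comp = compare_models(dist)
            assert comp.qexp.sse <= comp.bg.sse * (1 + 1e-6) + 1e-9


class TestErrorsAndConfig:
    def test_too_few_nonzero_bins(self):
        dist = IntervalDistribution(
            bin_edges=np.linspace(0, 10, 11),
            probabilities=np.array([0.5, 0.3, 0.2] + [0.0] * 7),
            n_total=10,
        )
        with pytest.raises(FittingError, match="nonzero"):
            fit_qexp(dist)
        with pytest.raises(FittingError, match="nonzero"):
            fit_bg(dist)

    def test_deviance_loss_needs_counts(self, fig1_params):
        dist = _model_dist(fig1_params)  # model-implied: no counts
        with pytest.raises(FittingError, match="counts"):
            fit_qexp(dist, FitConfig(loss="deviance"))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(n_starts=0)
        with pytest.raises(ValueError):
            FitConfig(loss="huber")

    def test_deviance_loss_fits_counted_data(self, fig1_params, rng):
        from qeeg import sample_qexp_intervals

        iv = sample_qexp_intervals(fig1_params, 8000, seed=rng)
        counts, edges = np.histogram(iv[iv < 1000], bins=np.linspace(0, 1000, 501))
        dist = IntervalDistribution(
            bin_edges=edges,
            probabilities=counts / counts.sum(),
            n_total=int(counts.sum()),
        )
        res = fit_qexp(dist, FitConfig(loss="deviance"))
        # sampling noise dominates; 3 sigma of the estimator's sampling sd
        assert abs(res.params.q - fig1_params.q) < 0.16

    def test_summary_and_serialization(self, fig1_params, tmp_path):
        res = fit_qexp(_model_dist(fig1_params))
        text = res.summary()
        assert "q-exponential" in text and "R^2" in text
        out = tmp_path / "fit.json"
        res.to_json(out)
        import json

        d = json.loads(out.read_text())
        assert d["model"] == "qexp"
        assert d["params"]["q"] == pytest.approx(1.22, abs=1e-3)
        assert "software_version" in d

    def test_plot_overlays_fit(self, fig1_params):
        import matplotlib

        matplotlib.use("Agg")
        res = fit_qexp(_model_dist(fig1_params))
        ax = res.plot()
        assert len(ax.lines) == 2

    def test_standard_errors_reported(self, fig1_params):
        res = fit_qexp(_model_dist(fig1_params))
        assert set(res.bse) == {"b", "c", "h", "q"}
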