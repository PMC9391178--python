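import numpy as np
import pytest

import qams


def ols_normal_equations(x, y):
    """Independent closed-form OLS oracle: slope and intercept from the
    normal equations, computed with plain Python arithmetic."""
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    sxx = sum((xi - xbar) ** 2 for xi in x)
    sxy = sum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    slope = sxy / sxx
    return slope, ybar - slope * xbar


@pytest.fixture(scope="session")
def reference_panel():
    """Noiseless calibration series for the eight-fructan reference panel."""
    models = qams.default_panel()
    tops = qams.default_top_concentrations()
    return {
        aid: qams.make_calibration_series(m, tops[aid])
        for aid, m in models.items()
    }


@pytest.fixture(scope="session")
def reference_curves(reference_panel):
    return {
        aid: qams.fit_loglog_calibration(s) for aid, s in reference_panel.items()
    }


def equal_slope_panel(noise_cv: float, seed: int):
    """A panel sharing one slope but with materially different intercepts —
    the configuration where only the marker-curve readout method (A) can
    absorb the response shift. Returns (series panel, detector models)."""
    intercepts = {
        "GF1": -1.55, "GF2": -1.85, "GF3": -1.70, "GF4": -1.50,
        "GF5": -1.90, "GF6": -1.58, "GF7": -1.82, "GF8": -1.42,
    }
    models = {
        aid: qams.DetectorModel(aid, 1.85, b, noise_cv=noise_cv)
        for aid, b in intercepts.items()
    }
    rng = np.random.default_rng(seed)
    panel = {
        aid: qams.make_calibration_series(m, 1000.0, rng=rng)
        for aid, m in models.items()
    }
    return panel, models


def standard_batch(models, noise_seed: int, jitter_cv: float = 0.10,
                   multipliers=None):
    """A 30-sample batch: 3 raw lots, 3 processing groups x 3 replicates."""
    design = qams.BatchDesign(
        base_content_pct={aid: c for aid, c in zip(
            models, (4.0, 5.5, 5.0, 6.0, 5.5, 6.0, 6.0, 5.5))},
        group_multipliers=multipliers or {},
        batch_jitter_cv=jitter_cv,
        seed=noise_seed,
    )
    return qams.make_sample_batch(design, models)
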