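import numpy as np
import pytest

import kzepi as kz


@pytest.fixture(scope="session")
def default_cfg():
    return kz.scenario_paper_default()


@pytest.fixture(scope="session")
def default_solar(default_cfg):
    return kz.generate_solar_series(default_cfg)


@pytest.fixture(scope="session")
def default_cases(default_cfg, default_solar):
    return kz.generate_case_series(default_solar, default_cfg)


@pytest.fixture(scope="session")
def filtered_pair(default_cfg, default_solar, default_cases):
    """KZ(13-mod, 2)-filtered predictor and detrended log outcome."""
    window = kz.modified_13_window()
    ylog = kz.log_transform(default_cases)
    ydev = kz.detrend(ylog, kz.fit_trend(ylog))
    return (
        kz.kz_filter(default_solar, window, 2),
        kz.kz_filter(ydev, window, 2),
    )


def sinusoid_series(period_months: float, n: int, amplitude: float = 1.0,
                    phase: float = 0.0, start=(1950, 1)) -> kz.MonthlyTimeSeries:
    i = np.arange(n)
    return kz.MonthlyTimeSeries(
        start, amplitude * np.sin(2 * np.pi * (i / period_months + phase))
    )
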