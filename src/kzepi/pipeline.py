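"""End-to-end orchestration: transform -> detrend -> KZ -> spectra -> ccf ->
regression -> percentage effects.

The stage order is fixed to the analysis design and deliberately not
auto-corrected: the outcome series is log-transformed and linearly detrended
*before* KZ filtering, both series are filtered with the same low-pass
filter, the lagged cross-correlation is profiled over the configured latency
window, and the regression is fitted at the best candidate latency.  The
report embeds the effective configuration and input digests so every number
in it is recomputable from inputs plus config alone.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from pydantic import BaseModel

from . import __version__ as _version
from .errors import InvalidParameterError
from .kz import kz_filter, modified_13_window, uniform_window
from .lagcorr import (
    LagCorrelationProfile,
    best_latency,
    ccf_profile,
    find_latency_candidates,
)
from .preprocess import annualize_growth, detrend, fit_trend, log_transform
from .regression import fit_lagged_regression, percent_effect
from .series import MonthlyTimeSeries
from .spectral import dominant_frequency, dz_smooth, raw_periodogram

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Per-stage knobs; defaults reproduce the canonical analysis."""

    log_outcome: bool = True
    detrend_outcome: bool = True
    kz_window: str = "modified13"  # or "uniform:<odd m>"
    kz_k: int = 2
    boundary: str = "trim"
    min_lag_years: float = 0.0
    max_lag_years: float = 70.0
    delta_sn: tuple[float, ...] = (100.0, 150.0, 200.0, 250.0)
    dz_c: float = 0.01
    diagnostic_band_years: tuple[float, float] = (2.0, 30.0)

    def window(self):
        if self.kz_window == "modified13":
            return modified_13_window()
        if self.kz_window.startswith("uniform:"):
            return uniform_window(int(self.kz_window.split(":", 1)[1]))
        raise InvalidParameterError(
            f"kz_window must be 'modified13' or 'uniform:<m>', got {self.kz_window!r}"
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise InvalidParameterError(f"unknown pipeline config keys: {sorted(bad)}")
        d = dict(d)
        for key in ("delta_sn", "diagnostic_band_years"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["delta_sn"] = list(self.delta_sn)
        d["diagnostic_band_years"] = list(self.diagnostic_band_years)
        return d


class TrendSummary(BaseModel):
    slope_per_month: float
    intercept: float
    slope_stderr: float
    annual_growth_pct: float


class SpectraSummary(BaseModel):
    predictor_dominant_period_years: float
    outcome_dominant_period_years: float


class CandidateSummary(BaseModel):
    lag_months: int
    lag_years: float
    r: float
    n: int
    tied_lags: list[int] = []


class FitSummary(BaseModel):
    slope: float
    intercept: float
    r: float
    r_squared: float
    n: int
    lag_months: int


class Provenance(BaseModel):
    config: dict
    predictor_digest: str
    outcome_digest: str
    version: str


class PipelineReport(BaseModel):
    """Validated, JSON-serialisable record of one pipeline run.

    ``PipelineReport.model_json_schema()`` is the shipped report schema.
    """

    trend: TrendSummary | None
    spectra: SpectraSummary
    candidates: list[CandidateSummary]
    best: CandidateSummary
    fit: FitSummary
    percent_effects: dict[str, float]
    provenance: Provenance


def _digest(source) -> str:
    if isinstance(source, (str, Path)):
        return "sha256:" + hashlib.sha256(Path(source).read_bytes()).hexdigest()
    h = hashlib.sha256()
    h.update(str(source.start).encode())
    h.update(np.ascontiguousarray(source.values).tobytes())
    return "series-sha256:" + h.hexdigest()


def _load(source) -> MonthlyTimeSeries:
    if isinstance(source, MonthlyTimeSeries):
        return source
    from .io_csv import read_monthly_csv

    return read_monthly_csv(source)


def _dominant_period_years(series: MonthlyTimeSeries, cfg: PipelineConfig) -> float:
    spec = dz_smooth(raw_periodogram(series), cfg.dz_c)
    lo_y, hi_y = cfg.diagnostic_band_years
    f, _ = dominant_frequency(spec, (1.0 / (12.0 * hi_y), 1.0 / (12.0 * lo_y)))
    return 1.0 / (12.0 * f)


def run_pipeline(x, y, config: PipelineConfig | dict | None = None) -> PipelineReport:
    """Run the full analysis of outcome ``y`` against predictor ``x``.

    ``x`` and ``y`` may be :class:`MonthlyTimeSeries` or CSV paths (generic
    dialect).  The predictor must extend far enough before the outcome to
    cover the latency window being profiled.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    x_series, y_series = _load(x), _load(y)
    x_digest, y_digest = _digest(x), _digest(y)

    y_work = log_transform(y_series) if config.log_outcome else y_series
    trend_summary = None
    if config.detrend_outcome:
        trend = fit_trend(y_work)
        y_work = detrend(y_work, trend)
        trend_summary = TrendSummary(
            slope_per_month=trend.slope,
            intercept=trend.intercept,
            slope_stderr=trend.slope_stderr,
            annual_growth_pct=annualize_growth(trend.slope),
        )

    window = config.window()
    x_filt = kz_filter(x_series, window, config.kz_k, config.boundary)
    y_filt = kz_filter(y_work, window, config.kz_k, config.boundary)

    spectra = SpectraSummary(
        predictor_dominant_period_years=_dominant_period_years(x_filt, config),
        outcome_dominant_period_years=_dominant_period_years(y_filt, config),
    )

    max_lag = int(round(12 * config.max_lag_years))
    profile: LagCorrelationProfile = ccf_profile(x_filt, y_filt, max_lag)
    candidates = find_latency_candidates(
        profile, config.min_lag_years, config.max_lag_years
    )
    best = best_latency(candidates)
    fit = fit_lagged_regression(x_filt, y_filt, best.lag_months)
    effects = {
        str(int(d)) if float(d).is_integer() else str(d): percent_effect(fit.slope, d)
        for d in config.delta_sn
    }

    return PipelineReport(
        trend=trend_summary,
        spectra=spectra,
        candidates=[
            CandidateSummary(
                lag_months=c.lag_months,
                lag_years=c.lag_years,
                r=c.r,
                n=c.n,
                tied_lags=list(c.tied_lags),
            )
            for c in candidates
        ],
        best=CandidateSummary(
            lag_months=best.lag_months,
            lag_years=best.lag_years,
            r=best.r,
            n=best.n,
            tied_lags=list(best.tied_lags),
        ),
        fit=FitSummary(**{k: getattr(fit, k) for k in FitSummary.model_fields}),
        percent_effects=effects,
        provenance=Provenance(
            config=config.to_dict(),
            predictor_digest=x_digest,
            outcome_digest=y_digest,
            version=_version,
        ),
    )
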