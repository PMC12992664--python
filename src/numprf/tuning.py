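"""Neuronal tuning curves, FWHM conversions, the canonical HRF and the
hemodynamic forward model.

The population response of one vertex to numerosity x is modelled as a
Gaussian in logarithmic stimulus space,

    z(x) = exp(-1/2 ((ln x - ln mu) / sigma_log)^2),

peaking at the preferred numerosity mu. Its full width at half maximum
expressed in linear numerosity units is

    omega = exp(ln mu + c sigma_log) - exp(ln mu - c sigma_log)
          = 2 mu sinh(c sigma_log),        c = sqrt(2 ln 2).

A linear-space Gaussian variant is provided for model comparison. Neuronal
responses on a fine time grid are convolved with a canonical double-gamma
HRF and sampled at volume acquisition times to predict the BOLD signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .schedule import StimulusSchedule, numerosity_timecourse

__all__ = [
    "TuningParams",
    "HRFKernel",
    "PredictedTimecourse",
    "tuning_response_log",
    "tuning_response_linear",
    "fwhm_log",
    "fwhm_linear",
    "sigma_log_from_fwhm",
    "canonical_hrf",
    "predict_timecourse",
    "condition_regressors",
]

_C = math.sqrt(2.0 * math.log(2.0))

#: Canonical double-gamma parameters: peak delay 6 s, undershoot delay 16 s,
#: unit dispersions, peak:undershoot ratio 6, 32 s support.
DEFAULT_HRF_PARAMS = {
    "peak_delay": 6.0,
    "undershoot_delay": 16.0,
    "peak_dispersion": 1.0,
    "undershoot_dispersion": 1.0,
    "ratio": 6.0,
    "length": 32.0,
}


@dataclass(frozen=True)
class TuningParams:
    """Tuning-curve parameters in log (default) or linear numerosity space."""

    mu: float
    sigma_log: float | None = None
    sigma_lin: float | None = None
    space: str = "log"

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.space == "log":
            if self.sigma_log is None or self.sigma_log <= 0:
                raise ValueError("log-space tuning requires sigma_log > 0")
        elif self.space == "linear":
            if self.sigma_lin is None or self.sigma_lin <= 0:
                raise ValueError("linear-space tuning requires sigma_lin > 0")
        else:
            raise ValueError(f"unknown tuning space {self.space!r}")

    @property
    def mu_log(self) -> float:
        return math.log(self.mu)

    @property
    def omega(self) -> float:
        """FWHM in linear numerosity units."""
        if self.space == "log":
            return fwhm_log(self.mu, self.sigma_log)
        return fwhm_linear(self.sigma_lin)


@dataclass(frozen=True)
class HRFKernel:
    """Sampled hemodynamic impulse response, first sample at t=0."""

    dt: float
    samples: np.ndarray = field(repr=False)
    params: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt


@dataclass(frozen=True)
class PredictedTimecourse:
    """Model-predicted BOLD signal, one value per acquired volume."""

    values: np.ndarray = field(repr=False)
    tr: float = 2.1
    slice_time_ref: float = 1.025


def tuning_response_log(params: TuningParams, x) -> np.ndarray | float:
    """Log-Gaussian response in (0, 1]; maximal (=1) at x = mu."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("numerosity x must be positive")
    if params.space != "log":
        raise ValueError("params are not log-space")
    z = np.exp(-0.5 * ((np.log(x) - params.mu_log) / params.sigma_log) ** 2)
    return float(z) if z.ndim == 0 else z


def tuning_response_linear(params: TuningParams, x) -> np.ndarray | float:
    """Linear-space Gaussian response variant."""
    if params.space != "linear":
        raise ValueError("params are not linear-space")
    x = np.asarray(x, dtype=float)
    z = np.exp(-0.5 * ((x - params.mu) / params.sigma_lin) ** 2)
    return float(z) if z.ndim == 0 else z


def fwhm_log(mu, sigma_log):
    """FWHM (linear numerosity units) of the log-Gaussian tuning curve."""
    mu = np.asarray(mu, dtype=float)
    sigma_log = np.asarray(sigma_log, dtype=float)
    if np.any(mu <= 0) or np.any(sigma_log <= 0):
        raise ValueError("mu and sigma_log must be positive")
    out = 2.0 * mu * np.sinh(_C * sigma_log)
    return float(out) if out.ndim == 0 else out


def fwhm_linear(sigma_lin):
    """FWHM of the linear-space Gaussian: 2 sqrt(2 ln 2) sigma_lin."""
    sigma_lin = np.asarray(sigma_lin, dtype=float)
    out = 2.0 * _C * sigma_lin
    return float(out) if out.ndim == 0 else out


def sigma_log_from_fwhm(mu, omega):
    """Invert :func:`fwhm_log` for a given preferred numerosity."""
    mu = np.asarray(mu, dtype=float)
    omega = np.asarray(omega, dtype=float)
    out = np.arcsinh(omega / (2.0 * mu)) / _C
    return float(out) if out.ndim == 0 else out


def canonical_hrf(dt: float, params: dict | None = None) -> HRFKernel:
    """Canonical double-gamma HRF, peak-normalized to 1.

    h(t) = Gamma(t; peak_delay) - Gamma(t; undershoot_delay) / ratio, with
    unit dispersions by default, sampled every ``dt`` s over 32 s.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = dict(DEFAULT_HRF_PARAMS)
    if params:
        p.update(params)
    t = np.arange(0.0, p["length"], dt)
    peak = stats.gamma.pdf(t, p["peak_delay"] / p["peak_dispersion"],
                           scale=p["peak_dispersion"])
    under = stats.gamma.pdf(t, p["undershoot_delay"] / p["undershoot_dispersion"],
                            scale=p["undershoot_dispersion"])
    h = peak - under / p["ratio"]
    h = h / h.max()
    return HRFKernel(dt=dt, samples=h, params=p)


def _volume_times(schedule: StimulusSchedule) -> np.ndarray:
    k = np.arange(schedule.n_volumes)
    return k * schedule.tr + schedule.slice_time_ref


def _convolve_and_sample(
    z_fine: np.ndarray, schedule: StimulusSchedule, hrf: HRFKernel
) -> np.ndarray:
    """Causal microtime convolution (dt-scaled) sampled at volume times.

    Volume acquisition times k*tr + slice_time_ref generally fall between
    microtime grid points; the convolved series is linearly interpolated.
    """
    conv = np.convolve(z_fine, hrf.samples)[: len(z_fine)] * hrf.dt
    t_fine = np.arange(len(z_fine)) * hrf.dt
    return np.interp(_volume_times(schedule), t_fine, conv)


def predict_timecourse(
    schedule: StimulusSchedule,
    params: TuningParams,
    hrf: HRFKernel,
    event_level: bool = False,
) -> PredictedTimecourse:
    """Predict the per-volume BOLD response for one tuning parameter set.

    The neuronal response z(x(t)) is evaluated on the microtime grid (0
    where no stimulus is scheduled), convolved with the HRF, and sampled at
    volume times.
    """
    xt = numerosity_timecourse(schedule, hrf.dt, event_level=event_level)
    z = np.zeros_like(xt.values)
    on = ~np.isnan(xt.values)
    if params.space == "log":
        z[on] = tuning_response_log(params, xt.values[on])
    else:
        z[on] = tuning_response_linear(params, xt.values[on])
    vals = _convolve_and_sample(z, schedule, hrf)
    return PredictedTimecourse(values=vals, tr=schedule.tr,
                               slice_time_ref=schedule.slice_time_ref)


def condition_regressors(
    schedule: StimulusSchedule,
    hrf: HRFKernel,
    levels: tuple[int, ...] = (1, 2, 3, 4, 5, 20),
    event_level: bool = False,
) -> np.ndarray:
    """HRF-convolved indicator regressor per numerosity level.

    Returns an (n_volumes, len(levels)) matrix C whose column j is the
    convolved boxcar of level ``levels[j]``. Because x(t) only takes the
    scheduled levels, the prediction for any tuning curve z factorizes as
    C @ [z(level_j)]_j — the basis both for the categorical GLM and for
    fast exhaustive grid search.
    """
    xt = numerosity_timecourse(schedule, hrf.dt, event_level=event_level)
    cols = []
    for lev in levels:
        ind = (xt.values == lev).astype(float)
        cols.append(_convolve_and_sample(ind, schedule, hrf))
    return np.column_stack(cols)
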