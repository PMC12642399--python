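"""Fluorescence correlation spectroscopy: model, fit, and size conversion.

A fluorescent particle diffusing through a 3D-Gaussian confocal volume with
lateral radius r0 and axial radius z0 produces an intensity autocorrelation

    G(t) = 1 + (1/N) * [1 / (1 + t/τD)] * [1 + (t/τD) * (r0/z0)²]^(-1/2)

for a single diffusing component, where N is the mean number of fluorophores
in the detection volume and τD the characteristic diffusion time.  τD maps
to a diffusion coefficient through the focal geometry, τD = r0²/(4D), and D
to a hydrodynamic radius through Stokes–Einstein, Rh = kB·T/(6πηD).
Referencing a calibration measurement (D_ref, τD_ref of a standard dye in
the same volume) eliminates r0:

    Rh = kB·T·τD_sample / (6πη · D_ref · τD_ref)

so the sample radius is linear in its fitted diffusion time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import lmfit
import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "BOLTZMANN_J_PER_K",
    "InstrumentGeometry",
    "Calibration",
    "AutocorrelationTrace",
    "FCSFit",
    "model_autocorrelation",
    "fit_autocorrelation",
    "diffusion_time_to_radius",
    "radius_series",
    "summarize_radii",
    "read_trace",
]

BOLTZMANN_J_PER_K = 1.380649e-23  # SI exact

_N_BOUNDS = (1e-3, 1e6)
_TAUD_BOUNDS = (1e-7, 10.0)  # seconds


@dataclass(frozen=True)
class InstrumentGeometry:
    """Confocal detection-volume geometry (meters)."""

    r0: float  # lateral (x-y) focal radius
    z0: float  # axial (z) focal radius

    def __post_init__(self) -> None:
        if not (self.r0 > 0 and self.z0 > 0):
            raise DomainError("r0 and z0 must be > 0")
        if not (0 < self.structure_ratio <= 1):
            raise DomainError(
                f"structure ratio r0²/z0² must be in (0, 1], got {self.structure_ratio}"
            )

    @property
    def structure_ratio(self) -> float:
        """r0²/z0² — the squared inverse aspect ratio of the focal volume."""
        return (self.r0 / self.z0) ** 2


@dataclass(frozen=True)
class Calibration:
    """Reference constants tying diffusion times to hydrodynamic radii.

    temperature in K, viscosity in Pa·s, d_ref (reference dye diffusion
    coefficient) in m²/s, taud_ref (its diffusion time in the same focal
    volume) in s.
    """

    temperature: float = 295.15
    viscosity: float = 1.0e-3
    d_ref: float = 4.14e-10
    taud_ref: float = 3.0e-5

    def __post_init__(self) -> None:
        for name in ("temperature", "viscosity", "d_ref", "taud_ref"):
            if not (getattr(self, name) > 0):
                raise DomainError(f"{name} must be > 0")

    def taud_to_diffusion_coefficient(self, taud_sample: float) -> float:
        """D_sample = D_ref · τD_ref / τD_sample (same focal volume)."""
        return self.d_ref * self.taud_ref / taud_sample


@dataclass(frozen=True)
class AutocorrelationTrace:
    """One autocorrelation curve: lag times (s) and G values."""

    lags: np.ndarray
    g_values: np.ndarray
    sigma: Optional[np.ndarray] = None  # per-point uncertainty on G

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        g = np.asarray(self.g_values, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g_values", g)
        if lags.shape != g.shape or lags.ndim != 1:
            raise ValidationError("lags and g_values must be matching 1-D arrays")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValidationError("lags must be strictly increasing and > 0")
        if np.any(~np.isfinite(g)):
            raise ValidationError("g_values must be finite")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != g.shape or np.any(s <= 0):
                raise ValidationError("sigma must match g_values and be > 0")


@dataclass(frozen=True)
class FCSFit:
    """Result of a single-component autocorrelation fit."""

    n_particles: float
    diffusion_time: float  # seconds
    residual_norm: float
    converged: bool
    message: str = ""


def model_autocorrelation(
    lag, n_particles: float, taud: float, geometry: InstrumentGeometry
):
    """Single-component 3D-Gaussian autocorrelation G(t); vectorized over lag."""
    if not (n_particles > 0):
        raise DomainError(f"n_particles must be > 0, got {n_particles}")
    if not (taud > 0):
        raise DomainError(f"taud must be > 0, got {taud}")
    lag = np.asarray(lag, dtype=float)
    if np.any(lag < 0):
        raise DomainError("lag must be >= 0")
    x = lag / taud
    g = 1.0 + (1.0 / n_particles) / (1.0 + x) / np.sqrt(1.0 + x * geometry.structure_ratio)
    return g if g.ndim else float(g)


def fit_autocorrelation(
    trace: AutocorrelationTrace,
    geometry: InstrumentGeometry,
    noise_floor: float = 1e-4,
) -> FCSFit:
    """Fit the single-component model to a trace by weighted least squares.

    Initial guesses: N from the first-lag amplitude (G(0) ≈ 1 + 1/N) and τD
    from the lag at which G−1 decays to half its initial value.  A trace
    whose amplitude max(G)−1 is below ``noise_floor`` is returned as
    non-converged rather than raising; likewise a fit that lands on a
    parameter bound.
    """
    if trace.lags.size < 5:
        raise ValidationError(f"need >= 5 points to fit, got {trace.lags.size}")
    amp0 = float(trace.g_values.max() - 1.0)
    if amp0 < noise_floor:
        return FCSFit(math.nan, math.nan, math.nan, False, "flat trace: no correlation amplitude")

    g1 = float(trace.g_values[0] - 1.0)
    n_init = 1.0 / g1 if g1 > 0 else 1.0
    below = np.nonzero(trace.g_values - 1.0 <= 0.5 * g1)[0]
    taud_init = float(trace.lags[below[0]]) if below.size else float(trace.lags[-1])
    n_init = float(np.clip(n_init, *_N_BOUNDS))
    taud_init = float(np.clip(taud_init, *_TAUD_BOUNDS))

    params = lmfit.Parameters()
    params.add("n_particles", value=n_init, min=_N_BOUNDS[0], max=_N_BOUNDS[1])
    params.add("taud", value=taud_init, min=_TAUD_BOUNDS[0], max=_TAUD_BOUNDS[1])
    weights = 1.0 / trace.sigma if trace.sigma is not None else None

    def residual(p):
        model = model_autocorrelation(trace.lags, p["n_particles"].value, p["taud"].value, geometry)
        r = model - trace.g_values
        return r * weights if weights is not None else r

    try:
        result = lmfit.minimize(residual, params, method="least_squares")
    except Exception as exc:  # noqa: BLE001 - solver failure is a diagnostic, not a crash
        return FCSFit(math.nan, math.nan, math.nan, False, f"solver failure: {exc}")

    n_fit = float(result.params["n_particles"].value)
    taud_fit = float(result.params["taud"].value)
    resid_norm = float(np.sqrt(np.sum(np.asarray(result.residual) ** 2)))
    at_bound = any(
        math.isclose(v, b, rel_tol=1e-6)
        for v, bounds in ((n_fit, _N_BOUNDS), (taud_fit, _TAUD_BOUNDS))
        for b in bounds
    )
    ok = bool(result.success) and not at_bound
    msg = "" if ok else ("parameter at bound" if at_bound else str(result.message))
    return FCSFit(n_fit, taud_fit, resid_norm, ok, msg)


def diffusion_time_to_radius(taud_sample: float, cal: Calibration) -> float:
    """Hydrodynamic radius (m) from a fitted diffusion time (s).

    Rh = kB·T·τD_sample / (6πη·D_ref·τD_ref): Stokes–Einstein with the
    sample diffusion coefficient expressed through the calibration point of
    the same focal volume, making Rh linear in τD_sample.
    """
    if not (taud_sample > 0):
        raise DomainError(f"taud_sample must be > 0, got {taud_sample}")
    return (
        BOLTZMANN_J_PER_K
        * cal.temperature
        * taud_sample
        / (6.0 * math.pi * cal.viscosity * cal.d_ref * cal.taud_ref)
    )


def radius_series(
    traces: Sequence[AutocorrelationTrace],
    geometry: InstrumentGeometry,
    cal: Calibration,
) -> tuple:
    """Fit every trace and convert to radii, preserving order.

    Returns ``(radii, fits)`` where ``radii`` is an array with NaN at
    positions whose fit did not converge (the diagnostic lives in the
    corresponding :class:`FCSFit`).
    """
    traces = list(traces)
    if not traces:
        raise ValidationError("radius_series needs at least one trace")
    fits = [fit_autocorrelation(t, geometry) for t in traces]
    radii = np.array(
        [
            diffusion_time_to_radius(f.diffusion_time, cal) if f.converged else math.nan
            for f in fits
        ]
    )
    return radii, fits


def summarize_radii(radii: np.ndarray) -> dict:
    """Median, mean, and interquartile range over the per-trace radii (m)."""
    ok = np.asarray(radii, dtype=float)
    ok = ok[np.isfinite(ok)]
    if ok.size == 0:
        return {"n": 0, "median": math.nan, "mean": math.nan, "iqr": (math.nan, math.nan)}
    q1, q3 = np.percentile(ok, [25, 75])
    return {
        "n": int(ok.size),
        "median": float(np.median(ok)),
        "mean": float(ok.mean()),
        "iqr": (float(q1), float(q3)),
    }


def read_trace(path) -> AutocorrelationTrace:
    """Read a delimited trace file with columns ``lag_s, g``."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need lag_s and g columns")
    return AutocorrelationTrace(
        df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)
    )
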