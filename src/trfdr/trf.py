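"""TRF feature extraction: pulse averaging, lifetime fitting, band ratios.

Five parameters are produced per spot: collagen/NADH and FAD/NADH intensity
ratios and the collagen, NADH and FAD lifetimes.  Each emission wavelength's
11-pulse average is fitted with a mono-exponential decay convolved with the
Gaussian IRF (plus a constant baseline); "intensity" is the time-integrated
fitted decay, amplitude*tau.  Intensities are band-averaged per fluorophore
(inclusive band edges, per the standard emission-band table) and normalised
to the fitted NADH intensity at 460 nm; lifetimes are band-averaged fitted
taus.

The fit uses variable projection: for a trial tau the amplitude and baseline
are solved linearly, and the scalar profile over tau is minimised by a
coarse logarithmic grid followed by bounded Brent refinement.  The procedure
has no random element, so fits are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .core import EMISSION_GRID, SpotMeasurement
from .simulate import EMISSION_BANDS, IRFSpec, convolve_decay

__all__ = ["DecayFit", "TRFFeatures", "InvalidRecordError", "average_pulses",
           "fit_decay", "band_average", "normalize_ratios",
           "extract_trf_features"]

TAU_BOUNDS = (0.05, 20.0)   # ns, fit search range
_COARSE_GRID = np.geomspace(TAU_BOUNDS[0], TAU_BOUNDS[1], 80)


class InvalidRecordError(ValueError):
    """Raised when a spot's features cannot be formed (record is excluded
    from modeling rather than silently zeroed)."""


@dataclass(frozen=True)
class DecayFit:
    """Result of fitting one wavelength's averaged decay."""

    tau: float            # ns
    amplitude: float      # a.u.
    baseline: float       # a.u.
    intensity: float      # a.u., time-integrated fitted decay = amplitude*tau
    fit_residual: float   # root-mean-square residual
    converged: bool


@dataclass(frozen=True)
class TRFFeatures:
    coll_nadh: float
    fad_nadh: float
    tau_coll: float
    tau_nadh: float
    tau_fad: float


def average_pulses(traces: np.ndarray) -> np.ndarray:
    """Element-wise mean over the pulse axis of an (n_pulses, n_time) block."""
    traces = np.asarray(traces, float)
    if traces.ndim != 2 or traces.shape[0] < 1:
        raise ValueError("need a 2-D (n_pulses, n_time) block of traces")
    return traces.mean(axis=0)


def _initial_tau(trace: np.ndarray, time_axis: np.ndarray) -> float:
    """Log-linear slope of the trace tail (fixed, deterministic rule)."""
    peak = int(np.argmax(trace))
    tail = trace[peak:]
    t = time_axis[peak:]
    pos = tail > max(tail.max(), 0.0) * 1e-3
    if pos.sum() < 3:
        return 1.0
    coeff = np.polyfit(t[pos], np.log(tail[pos]), 1)
    slope = coeff[0]
    if slope >= 0:
        return 1.0
    return float(np.clip(-1.0 / slope, *TAU_BOUNDS))


class _DecayModelCache:
    """Coarse-grid model curves and their Gram terms for one (IRF, time axis).

    For the two-column design [m(tau), 1] the least-squares solution and SSE
    reduce to dot products, so the coarse scan over tau is a single matrix-
    vector product per trace.
    """

    def __init__(self, irf: IRFSpec, time_axis: np.ndarray):
        self.t = np.asarray(time_axis, float)
        self.kernel = irf.kernel(self.t)
        self.irf = irf
        self.n = len(self.t)
        self.M = np.vstack([convolve_decay(tau, irf, self.t, self.kernel)
                            for tau in _COARSE_GRID])
        self.mm = np.einsum("ij,ij->i", self.M, self.M)
        self.ms = self.M.sum(axis=1)

    def solve(self, m: np.ndarray, mm: float, ms: float,
              y: np.ndarray, yy: float, ys: float
              ) -> tuple[float, float, float]:
        """SSE, amplitude, baseline for one model curve against trace y."""
        det = mm * self.n - ms * ms
        if det <= 0:
            return yy, 0.0, ys / self.n
        b1 = float(m @ y)
        amp = (self.n * b1 - ms * ys) / det
        base = (mm * ys - ms * b1) / det
        sse = yy - (amp * b1 + base * ys)
        return max(sse, 0.0), amp, base

    def profile(self, tau: float, y: np.ndarray, yy: float, ys: float
                ) -> tuple[float, float, float]:
        m = convolve_decay(tau, self.irf, self.t, self.kernel)
        return self.solve(m, float(m @ m), float(m.sum()), y, yy, ys)


_CACHE: dict[tuple[IRFSpec, bytes], _DecayModelCache] = {}


def _get_cache(irf: IRFSpec, time_axis: np.ndarray) -> _DecayModelCache:
    key = (irf, np.asarray(time_axis, float).tobytes())
    if key not in _CACHE:
        if len(_CACHE) > 8:
            _CACHE.clear()
        _CACHE[key] = _DecayModelCache(irf, time_axis)
    return _CACHE[key]


def fit_decay(trace: np.ndarray, irf: IRFSpec,
              time_axis: np.ndarray) -> DecayFit:
    """Least-squares fit of amplitude*[exp(-t/tau) (*) IRF] + baseline.

    Variable projection over tau: amplitude and baseline are the linear
    least-squares solution at each trial tau; tau itself is located by a
    coarse logarithmic scan refined with bounded Brent search.
    Non-convergence (or an unphysical non-positive amplitude) is reported
    via ``converged=False`` with the diagnostics filled in, never as a
    silent NaN.
    """
    raw = np.asarray(trace, float)
    t = np.asarray(time_axis, float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("trace must be finite")
    cache = _get_cache(irf, t)
    # normalise out the overall scale so the optimisation path (and hence
    # tau) is invariant to detector gain
    norm = float(np.max(np.abs(raw)))
    if norm == 0.0:
        return DecayFit(tau=1.0, amplitude=0.0, baseline=0.0, intensity=0.0,
                        fit_residual=0.0, converged=False)
    trace = raw / norm
    yy = float(trace @ trace)
    ys = float(trace.sum())

    b1 = cache.M @ trace
    det = cache.mm * cache.n - cache.ms**2
    amp_all = (cache.n * b1 - cache.ms * ys) / det
    base_all = (cache.mm * ys - cache.ms * b1) / det
    sse = yy - (amp_all * b1 + base_all * ys)
    i = int(np.argmin(sse))
    lo = _COARSE_GRID[max(i - 1, 0)]
    hi = _COARSE_GRID[min(i + 1, len(_COARSE_GRID) - 1)]
    res = minimize_scalar(lambda tau: cache.profile(tau, trace, yy, ys)[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-9})
    tau_hat = float(res.x)
    sse_hat, amp, base = cache.profile(tau_hat, trace, yy, ys)
    amp, base = amp * norm, base * norm
    rms = float(np.sqrt(sse_hat / len(t))) * norm
    interior = TAU_BOUNDS[0] * 1.001 < tau_hat < TAU_BOUNDS[1] * 0.999
    converged = bool(res.success) and interior and amp > 0
    return DecayFit(tau=tau_hat, amplitude=amp, baseline=base,
                    intensity=max(amp, 0.0) * tau_hat,
                    fit_residual=rms, converged=converged)


def band_average(values: np.ndarray, band: tuple[float, float],
                 wavelengths: np.ndarray | None = None) -> float:
    """Arithmetic mean of per-wavelength values over an inclusive band."""
    wl = EMISSION_GRID.values if wavelengths is None else np.asarray(wavelengths)
    values = np.asarray(values, float)
    mask = (wl >= band[0]) & (wl <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} contains no grid wavelengths")
    return float(values[mask].mean())


def normalize_ratios(band_intensities: dict[str, float],
                     nadh_460_intensity: float) -> tuple[float, float]:
    """Collagen/NADH and FAD/NADH ratios against the 460 nm NADH intensity."""
    if not nadh_460_intensity > 0:
        raise InvalidRecordError(
            f"NADH intensity at 460 nm must be > 0, got {nadh_460_intensity}")
    return (band_intensities["collagen"] / nadh_460_intensity,
            band_intensities["fad"] / nadh_460_intensity)


def extract_trf_features(spot: SpotMeasurement, irf: IRFSpec,
                         return_fits: bool = False):
    """The five TRF parameters for one spot.

    Per band wavelength: average the 11 pulses, fit the decay; then
    band-average intensities and lifetimes and form the two NADH-normalised
    ratios.  A failed denominator or a fully unconverged band raises
    :class:`InvalidRecordError` so the record can be excluded upstream.
    """
    wl = spot.emission_wavelengths
    t = spot.time_axis
    fits: dict[float, DecayFit] = {}
    for name, band in EMISSION_BANDS.items():
        mask = (wl >= band[0]) & (wl <= band[1])
        for j in np.flatnonzero(mask):
            mean_trace = average_pulses(spot.trf_traces[j])
            fits[float(wl[j])] = fit_decay(mean_trace, irf, t)

    intensities = {w: f.intensity for w, f in fits.items()}
    taus = {w: f.tau for w, f in fits.items()}
    wls = np.array(sorted(fits))
    ivec = np.array([intensities[w] for w in wls])
    tvec = np.array([taus[w] for w in wls])

    band_int = {name: band_average(ivec, band, wls)
                for name, band in EMISSION_BANDS.items()}
    band_tau = {name: band_average(tvec, band, wls)
                for name, band in EMISSION_BANDS.items()}
    if any(not np.isfinite(v) or v <= 0 for v in band_tau.values()):
        raise InvalidRecordError("non-positive band-averaged lifetime")

    i460 = fits[460.0].intensity
    coll_nadh, fad_nadh = normalize_ratios(band_int, i460)
    feats = TRFFeatures(coll_nadh=coll_nadh, fad_nadh=fad_nadh,
                        tau_coll=band_tau["collagen"],
                        tau_nadh=band_tau["nadh"],
                        tau_fad=band_tau["fad"])
    if return_fits:
        return feats, fits
    return feats
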