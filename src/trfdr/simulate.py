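"""Synthetic TRF/DR cohort generator.

Stands in for the undeposited patient spectra: it emulates three tissue
classes (adipose, fibroglandular, tumor) with class-dependent fluorophore
amplitudes and lifetimes, class-dependent absorption/scattering spectra,
lognormal between-patient random effects, measurement noise, a water-blank
background, a 99% reflectance standard, and an ink/microsphere phantom grid
for look-up-table construction.  Ground-truth parameter tables are retained
so downstream extraction can be validated by recovery tests.

The default cohort mirrors the study conditions the pipeline targets:
80 patients contributing 761 adipose, 77 fibroglandular and 347 tumor pure
spectra.  Class-model parameter values are illustrative (chosen to give a
plausible degree of class overlap), not measurements of real tissue.

Forward models
--------------
* Fluorescence decay: mono-exponential per fluorophore, convolved with a
  Gaussian instrument response (IRF), sampled at 0.1 ns over a 50 ns window.
* Diffuse reflectance: steady-state spatially resolved reflectance of a
  semi-infinite medium in the diffusion approximation, extrapolated-boundary
  dipole solution, evaluated at each bundle's source-detector separation.
  At 0.64 mm the diffusion approximation is physically marginal; here it
  serves as a self-consistent forward/inverse test bed, not as a claim
  about real tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

from .core import (ANALYSIS_BUNDLE, CLASSES, DR_GRID, DR_SEPARATIONS,
                   EMISSION_GRID, N_PULSES, SpotMeasurement,
                   default_time_axis)

__all__ = [
    "IRFSpec", "FluorophoreSpec", "OpticalSpec", "TissueClassModel",
    "PhantomGrid", "Cohort", "simulate_decay", "forward_reflectance",
    "simulate_phantom_grid", "simulate_spot", "simulate_cohort",
    "default_class_models", "chromophore_basis",
    "DEFAULT_COUNTS", "DEFAULT_N_PATIENTS",
]

#: Default cohort size: (adipose, fibroglandular, tumor) pure spectra.
DEFAULT_COUNTS = (761, 77, 347)
DEFAULT_N_PATIENTS = 80

#: Reference wavelength for the scattering power law, nm.
MUS_REFERENCE_NM = 500.0

#: Internal-reflection parameter A for a tissue-like relative refractive
#: index of 1.4 (Groenhuis empirical formula for the effective reflection
#: coefficient).
_N_REL = 1.4
_R_EFF = (-1.440 / _N_REL**2 + 0.710 / _N_REL + 0.668 + 0.0636 * _N_REL)
BOUNDARY_A = (1.0 + _R_EFF) / (1.0 - _R_EFF)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IRFSpec:
    """Gaussian instrument response: FWHM in ns, centred at ``t0``.

    ``fwhm = 0`` degenerates to a delta response at the grid point nearest
    ``t0``.
    """

    fwhm: float = 0.5
    t0: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm < 0:
            raise ValueError("IRF fwhm must be >= 0")

    @property
    def sigma(self) -> float:
        return self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def kernel(self, time_axis: np.ndarray) -> np.ndarray:
        """Discrete IRF kernel on the given time grid, unit area (sum*dt=1)."""
        t = np.asarray(time_axis, float)
        dt = t[1] - t[0]
        if self.fwhm == 0.0:
            idx = int(round(self.t0 / dt))
            k = np.zeros(idx + 1)
            k[idx] = 1.0 / dt
            return k
        n = int(np.ceil((self.t0 + 6.0 * self.sigma) / dt)) + 1
        tt = dt * np.arange(n)
        k = np.exp(-0.5 * ((tt - self.t0) / self.sigma) ** 2)
        return k / (k.sum() * dt)


def _band_shape(wavelengths: np.ndarray, band: tuple[float, float],
                center: float, width: float) -> np.ndarray:
    """Gaussian emission profile truncated to the band (zero outside)."""
    wl = np.asarray(wavelengths, float)
    shape = np.exp(-0.5 * ((wl - center) / width) ** 2)
    shape[(wl < band[0]) | (wl > band[1])] = 0.0
    return shape


@dataclass(frozen=True)
class FluorophoreSpec:
    """One endogenous fluorophore: emission band, lifetime, amplitude.

    ``band_shape`` gives the relative emission weight at each wavelength of
    the emission grid; it is identically zero outside ``emission_band``.
    """

    name: str
    emission_band: tuple[float, float]
    lifetime: float               # ns
    amplitude: float              # a.u. (peak spectral amplitude)
    band_center: float
    band_width: float

    def __post_init__(self) -> None:
        if self.lifetime <= 0:
            raise ValueError(f"{self.name}: lifetime must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"{self.name}: amplitude must be >= 0")

    def band_shape(self, wavelengths: np.ndarray | None = None) -> np.ndarray:
        wl = EMISSION_GRID.values if wavelengths is None else wavelengths
        return _band_shape(wl, self.emission_band, self.band_center,
                           self.band_width)


#: Emission bands with 355 nm excitation (nm): collagen, NADH, FAD.
EMISSION_BANDS = {
    "collagen": (380.0, 440.0),
    "nadh": (450.0, 500.0),
    "fad": (520.0, 570.0),
}
_BAND_CENTERS = {"collagen": 400.0, "nadh": 460.0, "fad": 535.0}
_BAND_WIDTHS = {"collagen": 28.0, "nadh": 22.0, "fad": 25.0}


def make_fluorophore(name: str, lifetime: float,
                     amplitude: float) -> FluorophoreSpec:
    return FluorophoreSpec(name=name, emission_band=EMISSION_BANDS[name],
                           lifetime=lifetime, amplitude=amplitude,
                           band_center=_BAND_CENTERS[name],
                           band_width=_BAND_WIDTHS[name])


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _oxy_raw(wl: np.ndarray) -> np.ndarray:
    # Soret-band tail rising into the blue plus the 542/576 nm double peak
    return (2.6 * _gauss(wl, 412.0, 30.0) + 0.55 * _gauss(wl, 542.0, 10.0)
            + 0.8 * _gauss(wl, 576.0, 9.0))


def _deoxy_raw(wl: np.ndarray) -> np.ndarray:
    # broader blue shoulder plus the single 556 nm peak
    return 1.5 * _gauss(wl, 430.0, 60.0) + 0.75 * _gauss(wl, 556.0, 13.0)


_BASIS_REF = np.linspace(450.0, 650.0, 2001)
_OXY_NORM = float(_oxy_raw(_BASIS_REF).max())
_DEOXY_NORM = float(_deoxy_raw(_BASIS_REF).max())


def chromophore_basis(wavelengths: np.ndarray) -> np.ndarray:
    """Absorption basis curves, shape (3, n_wavelengths).

    Row 0: oxygenated-hemoglobin-like curve (Soret tail plus the 542/576 nm
    double peak); row 1: deoxygenated-hemoglobin-like curve (blue shoulder
    plus the 556 nm peak); row 2: flat baseline.  Each chromophore curve is
    normalised to unit maximum over the fixed 450-650 nm reference window
    (not over the wavelengths requested), so weights are in mm^-1 and
    evaluations at different wavelength subsets are mutually consistent.
    The steep blue edges mimic hemoglobin's rise toward the Soret band and
    are what makes absorption spectrally separable from power-law
    scattering in a single-distance inversion.
    """
    wl = np.asarray(wavelengths, float)
    return np.vstack([_oxy_raw(wl) / _OXY_NORM,
                      _deoxy_raw(wl) / _DEOXY_NORM,
                      np.ones_like(wl)])


@dataclass(frozen=True)
class OpticalSpec:
    """Absorption/scattering spectra of one tissue instance.

    mu_a(lambda) = sum_k weights[k] * basis_k(lambda)   [mm^-1]
    mu_s'(lambda) = a * (lambda / 500 nm)^(-b)          [mm^-1]
    """

    chromophore_weights: tuple[float, float, float]
    mus_a: float
    mus_b: float

    def mua(self, wavelengths: np.ndarray) -> np.ndarray:
        basis = chromophore_basis(wavelengths)
        return np.asarray(self.chromophore_weights) @ basis

    def mus(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, float)
        return self.mus_a * (wl / MUS_REFERENCE_NM) ** (-self.mus_b)

    def validate(self, wavelengths: np.ndarray | None = None) -> None:
        wl = DR_GRID.values if wavelengths is None else wavelengths
        if np.any(self.mua(wl) <= 0) or np.any(self.mus(wl) <= 0):
            raise ValueError("mu_a and mu_s' must be positive over the grid")


@dataclass(frozen=True)
class TissueClassModel:
    """Population model of one tissue class.

    Mean fluorophore and optical parameters with between-patient spreads:
    lognormal multiplicative effects (given as the log-space sigma) on
    amplitudes, chromophore weights and the scattering prefactor; additive
    normal effects (truncated to stay positive) on lifetimes and the
    scattering power.
    """

    name: str
    fluorophores: tuple[FluorophoreSpec, FluorophoreSpec, FluorophoreSpec]
    optics: OpticalSpec
    amplitude_sigma: float = 0.20      # lognormal sigma, between patients
    lifetime_rel_sd: float = 0.06      # relative sd on lifetimes
    weight_sigma: float = 0.18         # lognormal sigma on chromophore weights
    mus_a_sigma: float = 0.18          # lognormal sigma on scattering prefactor
    mus_b_sd: float = 0.12             # additive sd on scattering power
    spot_amplitude_sigma: float = 0.10  # within-patient, spot level
    spot_lifetime_rel_sd: float = 0.03
    spot_weight_sigma: float = 0.10
    trace_snr: float = 50.0            # peak signal / noise sd, per pulse
    reflectance_snr: float = 100.0     # 1 / relative multiplicative noise sd

    def __post_init__(self) -> None:
        for sd in (self.amplitude_sigma, self.lifetime_rel_sd,
                   self.weight_sigma, self.mus_a_sigma, self.mus_b_sd,
                   self.spot_amplitude_sigma, self.spot_lifetime_rel_sd,
                   self.spot_weight_sigma):
            if sd < 0:
                raise ValueError("all spreads must be >= 0")


def default_class_models() -> dict[str, TissueClassModel]:
    """Illustrative class models for adipose / fibroglandular / tumor.

    Lifetimes and amplitudes are in the physiological ballpark (collagen
    slowest, NADH intermediate, FAD fastest; collagen-rich fibroglandular
    stroma, NADH-elevated tumor) and absorption increases with blood content
    from adipose to tumor.  They are generator settings, not tissue data.
    """
    common = dict(amplitude_sigma=0.35, lifetime_rel_sd=0.12,
                  weight_sigma=0.25, mus_a_sigma=0.16, mus_b_sd=0.12)
    return {
        "adipose": TissueClassModel(
            name="adipose",
            fluorophores=(make_fluorophore("collagen", 5.3, 0.70),
                          make_fluorophore("nadh", 2.7, 1.00),
                          make_fluorophore("fad", 2.0, 0.80)),
            optics=OpticalSpec((0.016, 0.010, 0.006), mus_a=1.10, mus_b=0.50),
            **common),
        "fibroglandular": TissueClassModel(
            name="fibroglandular",
            fluorophores=(make_fluorophore("collagen", 5.6, 1.30),
                          make_fluorophore("nadh", 2.5, 1.00),
                          make_fluorophore("fad", 1.8, 0.60)),
            optics=OpticalSpec((0.060, 0.032, 0.010), mus_a=1.50, mus_b=1.10),
            **common),
        "tumor": TissueClassModel(
            name="tumor",
            fluorophores=(make_fluorophore("collagen", 5.0, 1.00),
                          make_fluorophore("nadh", 2.2, 1.15),
                          make_fluorophore("fad", 1.7, 0.55)),
            optics=OpticalSpec((0.100, 0.055, 0.012), mus_a=1.90, mus_b=1.35),
            **common),
    }


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def simulate_decay(tau: float, amplitude: float, irf: IRFSpec,
                   time_axis: np.ndarray, noise_sd: float = 0.0,
                   seed: int | np.random.Generator | None = None
                   ) -> np.ndarray:
    """Mono-exponential decay convolved with the IRF, plus Gaussian noise.

    trace(t) = amplitude * [exp(-t/tau) (*) IRF](t) + N(0, noise_sd).
    The convolution is the discrete causal convolution on the sampling grid
    (kernel normalised to unit area), so the decay's time-integral equals
    ``amplitude * tau`` up to discretisation.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.asarray(time_axis, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time axis must be strictly increasing")
    trace = amplitude * convolve_decay(tau, irf, t)
    if noise_sd > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        trace = trace + rng.normal(0.0, noise_sd, size=trace.shape)
    return trace


def convolve_decay(tau: float, irf: IRFSpec,
                   time_axis: np.ndarray,
                   kernel: np.ndarray | None = None) -> np.ndarray:
    """Unit-amplitude decay exp(-t/tau) convolved with the IRF kernel."""
    t = np.asarray(time_axis, float)
    dt = t[1] - t[0]
    if kernel is None:
        kernel = irf.kernel(t)
    decay = np.exp(-t / tau)
    return np.convolve(decay, kernel)[: len(t)] * dt


def forward_reflectance(mua: float | np.ndarray, mus: float | np.ndarray,
                        separation: float) -> float | np.ndarray:
    """Spatially resolved diffuse reflectance R(rho), dipole dipole solution.

    Semi-infinite homogeneous medium, extrapolated-boundary dipole source:
    an isotropic source at depth z0 = 1/mus' and a negative image at
    z0 + 2*zb, zb = 2*A*D, observed at radial distance ``separation`` (mm).
    The absorption-independent diffusion coefficient D = 1/(3 mus') is
    used, so the source/image geometry does not shift with mua and the
    reflectance is strictly decreasing in mua at fixed mus'.  Inputs in
    mm^-1; the output is treated as the normalized reflectance used
    throughout the pipeline.
    """
    mua = np.asarray(mua, float)
    mus = np.asarray(mus, float)
    if np.any(mua <= 0) or np.any(mus <= 0) or separation <= 0:
        raise ValueError("mua, mus and separation must be > 0")
    D = 1.0 / (3.0 * mus)
    mueff = np.sqrt(mua / D)
    z0 = 1.0 / mus
    zb = 2.0 * BOUNDARY_A * D
    r1 = np.sqrt(z0**2 + separation**2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + separation**2)
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
    term2 = (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
    out = (term1 + term2) / (4.0 * np.pi)
    return out if out.ndim else float(out)


@dataclass
class PhantomGrid:
    """Reflectance simulated on a (mu_a, mu_s') grid of calibration phantoms.

    ``reflectance`` has shape (n_mua, n_mus, n_wavelengths).  Under the
    dipole forward model the wavelength slices are identical (the optics
    enter only through mu_a and mu_s'); the axis is kept so the container
    matches a per-wavelength phantom measurement.
    """

    mua_values: np.ndarray
    mus_values: np.ndarray
    wavelengths: np.ndarray
    separation: float
    reflectance: np.ndarray

    def validate(self) -> None:
        if np.any(np.diff(self.mua_values) <= 0):
            raise ValueError("mua grid must be strictly increasing")
        if np.any(np.diff(self.mus_values) <= 0):
            raise ValueError("mus grid must be strictly increasing")
        if self.reflectance.shape != (len(self.mua_values),
                                      len(self.mus_values),
                                      len(self.wavelengths)):
            raise ValueError("reflectance shape mismatch")
        if np.any(self.reflectance <= 0):
            raise ValueError("reflectance must be positive")
        if np.any(np.diff(self.reflectance, axis=0) >= 0):
            raise ValueError("reflectance must decrease with mua")


def simulate_phantom_grid(mua_grid: Sequence[float],
                          mus_grid: Sequence[float],
                          wavelengths: Sequence[float] | None = None,
                          separation: float = DR_SEPARATIONS[ANALYSIS_BUNDLE],
                          ) -> PhantomGrid:
    """Fill a phantom calibration grid with forward-model reflectance."""
    mua = np.asarray(mua_grid, float)
    mus = np.asarray(mus_grid, float)
    wl = (DR_GRID.values if wavelengths is None
          else np.asarray(wavelengths, float))
    if mua.size == 0 or mus.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(np.diff(mua) <= 0) or np.any(np.diff(mus) <= 0):
        raise ValueError("grids must be strictly increasing")
    R = forward_reflectance(mua[:, None], mus[None, :], separation)
    refl = np.repeat(R[:, :, None], len(wl), axis=2)
    grid = PhantomGrid(mua_values=mua, mus_values=mus, wavelengths=wl,
                       separation=separation, reflectance=refl)
    grid.validate()
    return grid


# ---------------------------------------------------------------------------
# Spot and cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientEffects:
    """Multiplicative/additive random effects realised for one patient."""

    amplitude_factors: tuple[float, float, float]
    lifetime_shifts: tuple[float, float, float]     # additive, ns
    weight_factors: tuple[float, float, float]
    mus_a_factor: float
    mus_b_shift: float


NEUTRAL_EFFECTS = PatientEffects((1.0, 1.0, 1.0), (0.0, 0.0, 0.0),
                                 (1.0, 1.0, 1.0), 1.0, 0.0)


def _draw_effects(model: TissueClassModel,
                  rng: np.random.Generator) -> PatientEffects:
    amp = tuple(np.exp(rng.normal(0.0, model.amplitude_sigma, 3)))
    taus = [f.lifetime for f in model.fluorophores]
    shifts = []
    for tau in taus:
        shift = rng.normal(0.0, model.lifetime_rel_sd * tau)
        shifts.append(max(shift, 0.2 - tau))   # keep lifetimes >= 0.2 ns
    wt = tuple(np.exp(rng.normal(0.0, model.weight_sigma, 3)))
    a_fac = float(np.exp(rng.normal(0.0, model.mus_a_sigma)))
    b_shift = float(rng.normal(0.0, model.mus_b_sd))
    b_shift = max(b_shift, 0.05 - model.optics.mus_b)
    return PatientEffects(amp, tuple(shifts), wt, a_fac, b_shift)


def _apply_effects(model: TissueClassModel, eff: PatientEffects
                   ) -> tuple[list[FluorophoreSpec], OpticalSpec]:
    fls = [replace(f, amplitude=f.amplitude * a,
                   lifetime=max(f.lifetime + dtau, 0.2))
           for f, a, dtau in zip(model.fluorophores, eff.amplitude_factors,
                                 eff.lifetime_shifts)]
    w = tuple(wi * fi for wi, fi in zip(model.optics.chromophore_weights,
                                        eff.weight_factors))
    optics = OpticalSpec(w, mus_a=model.optics.mus_a * eff.mus_a_factor,
                         mus_b=max(model.optics.mus_b + eff.mus_b_shift, 0.05))
    return fls, optics


def _default_standard(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth lamp x detector response used as the stored standard spectrum."""
    wl = np.asarray(wavelengths, float)
    return 1.0e4 * (1.0 + 0.5 * np.exp(-0.5 * ((wl - 520.0) / 90.0) ** 2))


def _default_blank(wavelengths: np.ndarray) -> np.ndarray:
    """Water-blank background: a small smooth offset (~2% of the standard)."""
    return 0.02 * _default_standard(wavelengths)


def simulate_spot(class_model: TissueClassModel,
                  patient_effects: PatientEffects = NEUTRAL_EFFECTS,
                  irf: IRFSpec = IRFSpec(),
                  seed: int | np.random.Generator | None = None,
                  patient_id: str = "P001", sample_id: str = "P001S1",
                  grid_x: int = 1, grid_y: int = 1,
                  return_truth: bool = False):
    """Simulate one raster spot for a tissue instance.

    TRF traces: per emission wavelength, the band-weighted sum of the three
    fluorophores' IRF-convolved decays, with 11 independently noisy pulse
    replicates.  DR spectra: dipole-model reflectance at each bundle
    separation from the instance's optical spectra, scaled by the stored
    standard and offset by the stored blank (bundle 2 only), with
    multiplicative noise — so downstream background subtraction and
    standard normalisation are exercised.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    t = default_time_axis()
    kernel = irf.kernel(t)
    wl_em = EMISSION_GRID.values
    wl_dr = DR_GRID.values

    fls, optics = _apply_effects(class_model, patient_effects)
    # spot-level variability (within patient)
    amp_fac = np.exp(rng.normal(0.0, class_model.spot_amplitude_sigma, 3))
    tau_fac = 1.0 + rng.normal(0.0, class_model.spot_lifetime_rel_sd, 3)
    wt_fac = np.exp(rng.normal(0.0, class_model.spot_weight_sigma, 3))
    fls = [replace(f, amplitude=f.amplitude * a,
                   lifetime=max(f.lifetime * tf, 0.2))
           for f, a, tf in zip(fls, amp_fac, tau_fac)]
    optics = OpticalSpec(
        tuple(w * f for w, f in zip(optics.chromophore_weights, wt_fac)),
        mus_a=optics.mus_a, mus_b=optics.mus_b)

    # --- TRF traces ------------------------------------------------------
    shapes = np.vstack([f.band_shape(wl_em) for f in fls])   # (3, 39)
    decays = np.vstack([convolve_decay(f.lifetime, irf, t, kernel)
                        for f in fls])                       # (3, n_t)
    amps = np.array([f.amplitude for f in fls])
    # clean trace per wavelength: sum_f amp_f * shape_f(wl) * decay_f(t)
    clean = (amps[:, None] * shapes).T @ decays              # (39, n_t)
    peak = clean.max()
    noise_sd = peak / class_model.trace_snr if class_model.trace_snr > 0 else 0.0
    traces = clean[:, None, :] + rng.normal(
        0.0, noise_sd, size=(len(wl_em), N_PULSES, len(t)))

    # --- DR spectra ------------------------------------------------------
    mua = optics.mua(wl_dr)
    mus = optics.mus(wl_dr)
    standard = _default_standard(wl_dr)
    blank = _default_blank(wl_dr)
    dr = np.empty((len(DR_SEPARATIONS), len(wl_dr)))
    for b, sep in enumerate(DR_SEPARATIONS):
        r_true = forward_reflectance(mua, mus, sep)
        meas = standard * r_true / 0.99
        if b == ANALYSIS_BUNDLE:
            meas = meas + blank
        if class_model.reflectance_snr > 0:
            meas = meas * (1.0 + rng.normal(
                0.0, 1.0 / class_model.reflectance_snr, size=meas.shape))
        dr[b] = meas

    spot = SpotMeasurement(patient_id=patient_id, sample_id=sample_id,
                           grid_x=grid_x, grid_y=grid_y,
                           trf_traces=traces, dr_spectra=dr,
                           time_axis=t, emission_wavelengths=wl_em,
                           dr_wavelengths=wl_dr)
    if not return_truth:
        return spot
    truth = _spot_truth(fls, optics, wl_dr)
    return spot, truth


def _spot_truth(fls: Sequence[FluorophoreSpec], optics: OpticalSpec,
                wl_dr: np.ndarray) -> dict[str, float]:
    """Analytic ground truth for the 13 parameters of one spot."""
    wl_em = EMISSION_GRID.values
    coll, nadh, fad = fls
    sep = DR_SEPARATIONS[ANALYSIS_BUNDLE]

    def band_mean_intensity(f: FluorophoreSpec) -> float:
        lo, hi = f.emission_band
        in_band = (wl_em >= lo) & (wl_em <= hi)
        return float(np.mean(f.amplitude * f.band_shape(wl_em)[in_band]
                             * f.lifetime))

    i460 = nadh.amplitude * nadh.band_shape(wl_em)[
        EMISSION_GRID.index_of(460.0)] * nadh.lifetime
    mua = optics.mua(wl_dr)
    mus = optics.mus(wl_dr)
    idx = {w: DR_GRID.index_of(w) for w in (520.0, 540.0, 560.0, 576.0)}
    r = forward_reflectance(mua, mus, sep)
    return {
        "coll_nadh": band_mean_intensity(coll) / i460,
        "fad_nadh": band_mean_intensity(fad) / i460,
        "tau_coll": coll.lifetime, "tau_nadh": nadh.lifetime,
        "tau_fad": fad.lifetime,
        "amp_coll": coll.amplitude, "amp_nadh": nadh.amplitude,
        "amp_fad": fad.amplitude,
        "r520": float(r[idx[520.0]]), "r560": float(r[idx[560.0]]),
        "mua540": float(mua[idx[540.0]]), "mua560": float(mua[idx[560.0]]),
        "mua576": float(mua[idx[576.0]]),
        "mus540": float(mus[idx[540.0]]), "mus560": float(mus[idx[560.0]]),
        "mus576": float(mus[idx[576.0]]),
    }


@dataclass
class Cohort:
    """A simulated multi-patient cohort with lazy raw-spot generation.

    ``index`` describes every spot (patient, sample, grid position, class,
    per-spot seed); ``labels`` is the histology-style composition table;
    ``truth`` carries the analytic ground-truth parameters realised for each
    spot.  :meth:`iter_spots` regenerates the raw measurements; the same
    cohort seed always reproduces bit-identical spots.
    """

    index: pd.DataFrame
    labels: pd.DataFrame
    truth: pd.DataFrame
    irf: IRFSpec
    class_models: dict[str, TissueClassModel]
    patient_effects: dict[tuple[str, str], PatientEffects]
    seed: int
    blank: np.ndarray = field(
        default_factory=lambda: _default_blank(DR_GRID.values))
    standard: np.ndarray = field(
        default_factory=lambda: _default_standard(DR_GRID.values))

    def __len__(self) -> int:
        return len(self.index)

    def iter_spots(self) -> Iterator[SpotMeasurement]:
        for row in self.index.itertuples():
            yield self._make_spot(row)

    def _make_spot(self, row) -> SpotMeasurement:
        model = self.class_models[row.label]
        eff = self.patient_effects[(row.patient_id, row.label)]
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, int(row.spot_seed)]))
        return simulate_spot(model, eff, self.irf, rng,
                             patient_id=row.patient_id,
                             sample_id=row.sample_id,
                             grid_x=int(row.x), grid_y=int(row.y))


def simulate_cohort(n_patients: int = DEFAULT_N_PATIENTS,
                    spectra_per_class: Sequence[int] = DEFAULT_COUNTS,
                    class_models: dict[str, TissueClassModel] | None = None,
                    seed: int = 0, irf: IRFSpec = IRFSpec(),
                    n_mixed: int = 0) -> Cohort:
    """Simulate a labeled multi-patient cohort.

    Pure spectra are allocated round-robin across patients so every patient
    contributes multiple classes (normal samples hold adipose and
    fibroglandular pixels, tumor samples hold tumor pixels).  ``n_mixed``
    optional mixed-composition pixels are labeled but carry no pure class
    and are excluded from modeling downstream.
    """
    if n_patients < 2:
        raise ValueError("leave-one-patient-out needs n_patients >= 2")
    counts = tuple(int(c) for c in spectra_per_class)
    if len(counts) != 3 or any(c < 0 for c in counts):
        raise ValueError("spectra_per_class must be 3 non-negative counts")
    models = default_class_models() if class_models is None else class_models
    if set(models) != set(CLASSES):
        raise ValueError(f"class_models must cover {CLASSES}")

    master = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    patients = [f"P{i + 1:03d}" for i in range(n_patients)]
    effects = {(pid, cls): _draw_effects(models[cls], master)
               for pid in patients for cls in CLASSES}

    rows, label_rows = [], []
    spot_seed = 0
    grid_pos: dict[str, int] = {}
    for cls, count in zip(CLASSES, counts):
        for k in range(count):
            pid = patients[k % n_patients]
            sid = pid + ("T" if cls == "tumor" else "N")
            pos = grid_pos.get(sid, 0)
            grid_pos[sid] = pos + 1
            x, y = pos % 13 + 1, pos // 13 + 1
            rows.append((pid, sid, x, y, cls, spot_seed))
            pct = {"pct_tumor": 0.0, "pct_fibroglandular": 0.0,
                   "pct_adipose": 0.0}
            pct[f"pct_{'tumor' if cls == 'tumor' else cls}"] = 100.0
            label_rows.append((pid, sid, x, y, pct["pct_tumor"],
                               pct["pct_fibroglandular"], pct["pct_adipose"]))
            spot_seed += 1
    for k in range(n_mixed):
        pid = patients[k % n_patients]
        sid = pid + "M"
        x, y = k % 13 + 1, k // 13 + 1
        frac = master.dirichlet([2.0, 2.0, 2.0]) * 100.0
        frac = np.round(frac, 0)
        frac[2] = 100.0 - frac[0] - frac[1]
        if np.any(frac >= 100.0) or np.any(frac < 0):
            frac = np.array([40.0, 30.0, 30.0])
        label_rows.append((pid, sid, x, y, frac[0], frac[1], frac[2]))

    index = pd.DataFrame(rows, columns=["patient_id", "sample_id", "x", "y",
                                        "label", "spot_seed"])
    labels = pd.DataFrame(label_rows, columns=[
        "patient_id", "sample_id", "x", "y",
        "pct_tumor", "pct_fibroglandular", "pct_adipose"])

    # realise per-spot truth without generating traces: replay the same
    # random draws that simulate_spot makes for the spot-level effects
    truth_rows = []
    for row in index.itertuples():
        model = models[row.label]
        eff = effects[(row.patient_id, row.label)]
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, int(row.spot_seed)]))
        fls, optics = _apply_effects(model, eff)
        amp_fac = np.exp(rng.normal(0.0, model.spot_amplitude_sigma, 3))
        tau_fac = 1.0 + rng.normal(0.0, model.spot_lifetime_rel_sd, 3)
        wt_fac = np.exp(rng.normal(0.0, model.spot_weight_sigma, 3))
        fls = [replace(f, amplitude=f.amplitude * a,
                       lifetime=max(f.lifetime * tf, 0.2))
               for f, a, tf in zip(fls, amp_fac, tau_fac)]
        optics = OpticalSpec(
            tuple(w * f for w, f in zip(optics.chromophore_weights, wt_fac)),
            mus_a=optics.mus_a, mus_b=optics.mus_b)
        rec = _spot_truth(fls, optics, DR_GRID.values)
        rec.update(patient_id=row.patient_id, sample_id=row.sample_id,
                   x=row.x, y=row.y, label=row.label)
        truth_rows.append(rec)
    truth = pd.DataFrame(truth_rows)

    return Cohort(index=index, labels=labels, truth=truth, irf=irf,
                  class_models=models, patient_effects=effects, seed=seed)
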