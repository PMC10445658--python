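"""DR feature extraction: calibration, phantom look-up table, inversion.

Eight parameters are produced per spot from the 0.64 mm bundle: normalized
reflectance at 520 and 560 nm, and mu_a / mu_s' at 540, 560 and 576 nm.
The bundle-2 spectrum is background-corrected with the water blank,
normalized to the 99% reflectance standard, and inverted through a
phantom-derived look-up table (LUT).

A single source-detector separation gives one reflectance value per
wavelength, which cannot determine two optical coefficients per wavelength.
The inversion is therefore spectrally constrained: mu_a(lambda) is a
non-negative combination of chromophore basis curves and mu_s'(lambda) a
power law, and the five coefficients are fitted to the whole 450-650 nm
spectrum at once.  The per-wavelength mu_a/mu_s' parameters are evaluations
of the fitted curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import least_squares

from .core import (ANALYSIS_BUNDLE, DR_ANALYSIS_WAVELENGTHS, DR_GRID,
                   DR_SEPARATIONS, SpotMeasurement)
from .simulate import MUS_REFERENCE_NM, PhantomGrid, chromophore_basis
from .trf import InvalidRecordError

__all__ = ["DRFeatures", "ReflectanceLUT", "InversionModel",
           "subtract_background", "normalize_to_standard", "build_lut",
           "invert_spectrum", "extract_dr_features", "default_lut"]

#: Wavelength window (nm) over which spectra are fitted.
FIT_WINDOW = (450.0, 650.0)

#: Fraction of the 99% standard a perfect standard measurement reads.
STANDARD_REFLECTIVITY = 0.99

#: Records with more than this fraction of clipped (negative) channels
#: after background subtraction are flagged invalid.
MAX_CLIP_FRACTION = 0.10


@dataclass(frozen=True)
class DRFeatures:
    r520: float
    r560: float
    mua540: float
    mua560: float
    mua576: float
    mus540: float
    mus560: float
    mus576: float


def subtract_background(measured: np.ndarray, blank: np.ndarray
                        ) -> tuple[np.ndarray, int]:
    """Element-wise blank subtraction; negatives clipped to 0 and counted."""
    measured = np.asarray(measured, float)
    blank = np.asarray(blank, float)
    if measured.shape != blank.shape:
        raise ValueError(
            f"wavelength grids differ: {measured.shape} vs {blank.shape}")
    diff = measured - blank
    n_clipped = int(np.sum(diff < 0))
    return np.clip(diff, 0.0, None), n_clipped


def normalize_to_standard(spectrum: np.ndarray,
                          standard: np.ndarray) -> np.ndarray:
    """Element-wise ratio to the standard, scaled so a measurement equal to
    the standard reads 0.99 (the standard's reflectivity)."""
    spectrum = np.asarray(spectrum, float)
    standard = np.asarray(standard, float)
    if spectrum.shape != standard.shape:
        raise ValueError("wavelength grids differ")
    if np.any(standard <= 0):
        raise ValueError("standard spectrum must be positive everywhere")
    return STANDARD_REFLECTIVITY * spectrum / standard


@dataclass
class ReflectanceLUT:
    """Bilinear interpolant over the phantom (mu_a, mu_s') grid.

    Exact at the grid nodes; queries outside the grid extrapolate linearly
    during optimisation but are reported through :meth:`in_bounds` so
    out-of-domain fits can be flagged.
    """

    grid: PhantomGrid
    scheme: str = "bilinear"
    _interp: RegularGridInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.grid.validate()
        # wavelength slices are identical under the dipole forward model;
        # interpolate the first slice in (mua, mus)
        self._interp = RegularGridInterpolator(
            (self.grid.mua_values, self.grid.mus_values),
            self.grid.reflectance[:, :, 0],
            method="linear", bounds_error=False, fill_value=None)

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        return {"mua": (float(self.grid.mua_values[0]),
                        float(self.grid.mua_values[-1])),
                "mus": (float(self.grid.mus_values[0]),
                        float(self.grid.mus_values[-1]))}

    def __call__(self, mua: np.ndarray, mus: np.ndarray) -> np.ndarray:
        pts = np.column_stack([np.ravel(mua), np.ravel(mus)])
        return self._interp(pts).reshape(np.shape(mua))

    def in_bounds(self, mua: np.ndarray, mus: np.ndarray) -> bool:
        b = self.bounds
        return bool(np.all((mua >= b["mua"][0]) & (mua <= b["mua"][1])
                           & (mus >= b["mus"][0]) & (mus <= b["mus"][1])))

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("mua_values", data=self.grid.mua_values)
            f.create_dataset("mus_values", data=self.grid.mus_values)
            f.create_dataset("wavelengths", data=self.grid.wavelengths)
            f.create_dataset("reflectance", data=self.grid.reflectance)
            f.attrs["separation_mm"] = self.grid.separation
            f.attrs["scheme"] = self.scheme

    @classmethod
    def load(cls, path: str | Path) -> "ReflectanceLUT":
        with h5py.File(path, "r") as f:
            grid = PhantomGrid(
                mua_values=f["mua_values"][()],
                mus_values=f["mus_values"][()],
                wavelengths=f["wavelengths"][()],
                separation=float(f.attrs["separation_mm"]),
                reflectance=f["reflectance"][()])
            scheme = str(f.attrs.get("scheme", "bilinear"))
        return cls(grid=grid, scheme=scheme)


def build_lut(phantom: PhantomGrid) -> ReflectanceLUT:
    """Bilinear LUT from a phantom calibration grid (exact at nodes)."""
    return ReflectanceLUT(grid=phantom)


def default_lut(n_mua: int = 128, n_mus: int = 128,
                mua_range: tuple[float, float] = (0.001, 1.0),
                mus_range: tuple[float, float] = (0.08, 6.0),
                separation: float = DR_SEPARATIONS[ANALYSIS_BUNDLE]
                ) -> ReflectanceLUT:
    """LUT on log-spaced grids covering the tissue-like parameter domain."""
    from .simulate import simulate_phantom_grid
    mua = np.geomspace(*mua_range, n_mua)
    mus = np.geomspace(*mus_range, n_mus)
    return build_lut(simulate_phantom_grid(mua, mus, DR_GRID.values,
                                           separation))


@dataclass
class InversionModel:
    """Spectrally constrained inversion configuration and (fitted) state.

    mu_a(lambda) = weights @ basis(lambda); mu_s'(lambda) = a*(lambda/500)^-b.
    """

    weights: np.ndarray | None = None        # (3,), mm^-1, >= 0
    mus_a: float | None = None
    mus_b: float | None = None
    cost: float = np.inf
    in_bounds: bool = True
    converged: bool = False
    b_bounds: tuple[float, float] = (0.1, 3.0)
    a_bounds: tuple[float, float] = (0.2, 4.0)
    # per-weight (lower, upper) bounds in mm^-1; the baseline floor keeps
    # mu_a(lambda) positive across the window and inside the LUT domain
    weight_bounds: tuple[tuple[float, float], ...] = (
        (0.0, 0.35), (0.0, 0.35), (0.001, 0.25))

    def mua(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.asarray(self.weights) @ chromophore_basis(wavelengths)

    def mus(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, float)
        return self.mus_a * (wl / MUS_REFERENCE_NM) ** (-self.mus_b)


#: Deterministic multi-start points: (w_oxy, w_deoxy, w_base, a, b).
_STARTS = (
    (0.015, 0.008, 0.006, 1.0, 0.6),
    (0.050, 0.030, 0.010, 1.5, 1.1),
    (0.100, 0.050, 0.012, 1.9, 1.4),
    (0.030, 0.015, 0.008, 1.2, 0.9),
    (0.007, 0.005, 0.004, 0.8, 0.4),
)


def invert_spectrum(normalized: np.ndarray, lut: ReflectanceLUT,
                    model: InversionModel | None = None,
                    wavelengths: np.ndarray | None = None) -> InversionModel:
    """Fit the constrained optics model to a normalized reflectance spectrum.

    Weighted least squares on reflectance over the 450-650 nm window
    (residuals are scaled by the measured reflectance, the inverse-variance
    weighting for multiplicative detector noise), with bounded trust-region
    optimisation from five fixed start points (lowest final cost wins; ties
    go to the earlier start).  A best fit whose mu_a/mu_s' curves leave the
    LUT domain is returned with ``in_bounds=False`` so the record can be
    flagged.
    """
    cfg = model or InversionModel()
    wl = DR_GRID.values if wavelengths is None else np.asarray(wavelengths)
    y = np.asarray(normalized, float)
    window = (wl >= FIT_WINDOW[0]) & (wl <= FIT_WINDOW[1])
    wl_fit = wl[window]
    for need in DR_ANALYSIS_WAVELENGTHS:
        if not (wl_fit[0] <= need <= wl_fit[-1]):
            raise ValueError(
                f"fit window misses analysis wavelength {need} nm")
    y_fit = y[window]
    basis = chromophore_basis(wl_fit)
    lam = wl_fit / MUS_REFERENCE_NM

    scale = np.maximum(y_fit, 1e-3 * np.abs(y_fit).max())

    def residuals(theta: np.ndarray) -> np.ndarray:
        w = theta[:3]
        a, b = theta[3], theta[4]
        mua = w @ basis
        mus = a * lam ** (-b)
        return (lut(mua, mus) - y_fit) / scale

    lower = [wb[0] for wb in cfg.weight_bounds] + [cfg.a_bounds[0],
                                                   cfg.b_bounds[0]]
    upper = [wb[1] for wb in cfg.weight_bounds] + [cfg.a_bounds[1],
                                                   cfg.b_bounds[1]]
    best = None
    for start in _STARTS:
        sol = least_squares(residuals, np.asarray(start, float),
                            bounds=(lower, upper), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    w = best.x[:3]
    a, b = float(best.x[3]), float(best.x[4])
    fitted = InversionModel(weights=w, mus_a=a, mus_b=b,
                            cost=float(best.cost),
                            converged=bool(best.success),
                            b_bounds=cfg.b_bounds, a_bounds=cfg.a_bounds)
    fitted.in_bounds = lut.in_bounds(fitted.mua(wl_fit), fitted.mus(wl_fit))
    return fitted


def extract_dr_features(spot: SpotMeasurement, blank: np.ndarray,
                        standard: np.ndarray, lut: ReflectanceLUT,
                        model: InversionModel | None = None,
                        return_model: bool = False):
    """The eight DR parameters for one spot (0.64 mm bundle).

    subtract background -> normalize to the 99% standard -> read r520/r560
    at their grid wavelengths -> constrained inversion -> evaluate
    mu_a/mu_s' at 540/560/576 nm.  Heavily clipped or out-of-LUT records
    raise :class:`InvalidRecordError`.
    """
    wl = spot.dr_wavelengths
    measured = spot.dr_spectra[ANALYSIS_BUNDLE]
    corrected, n_clipped = subtract_background(measured, blank)
    if n_clipped > MAX_CLIP_FRACTION * len(wl):
        raise InvalidRecordError(
            f"{n_clipped}/{len(wl)} channels clipped after background "
            "subtraction")
    normalized = normalize_to_standard(corrected, standard)

    i520 = DR_GRID.index_of(520.0)
    i560 = DR_GRID.index_of(560.0)
    fitted = invert_spectrum(normalized, lut, model, wavelengths=wl)
    if not fitted.in_bounds:
        raise InvalidRecordError("fitted optics leave the LUT domain")
    lam = np.array([540.0, 560.0, 576.0])
    mua = fitted.mua(lam)
    mus = fitted.mus(lam)
    feats = DRFeatures(r520=float(normalized[i520]),
                       r560=float(normalized[i560]),
                       mua540=float(mua[0]), mua560=float(mua[1]),
                       mua576=float(mua[2]),
                       mus540=float(mus[0]), mus560=float(mus[1]),
                       mus576=float(mus[2]))
    if return_model:
        return feats, fitted
    return feats
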