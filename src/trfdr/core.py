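"""Domain types and file I/O for raster-scanned TRF/DR tissue measurements.

A scan is a collection of per-spot measurements taken on a 1 mm raster grid:
time-resolved fluorescence (TRF) pulse trains at 39 emission wavelengths and
diffuse-reflectance (DR) spectra from three detector bundles.  Histology
assigns each pixel a composition in percent tumor / fibroglandular / adipose;
only pixels that are 100% one class enter the classification model.

Scans are stored in HDF5 (traces are large arrays); feature tables, label
tables and prediction tables are plain CSV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import h5py
import numpy as np
import pandas as pd

#: Fixed class order used everywhere (rows/columns of every 3x3 table).
CLASSES = ("adipose", "fibroglandular", "tumor")

#: Source-detector separations of the three DR detection bundles, in mm.
DR_SEPARATIONS = (0.32, 0.64, 1.5)
#: Index of the bundle used for analysis (0.64 mm; the only one that is
#: background-corrected).
ANALYSIS_BUNDLE = 1

#: The 13 optical parameters, in the canonical column order of the
#: features CSV (5 TRF then 8 DR).
TRF_COLUMNS = ("coll_nadh", "fad_nadh", "tau_coll", "tau_nadh", "tau_fad")
DR_COLUMNS = ("r520", "r560", "mua540", "mua560", "mua576",
              "mus540", "mus560", "mus576")
FEATURE_COLUMNS = TRF_COLUMNS + DR_COLUMNS

#: Full features-CSV header.
FEATURES_CSV_COLUMNS = ("patient_id", "sample_id", "x", "y", "label",
                        *FEATURE_COLUMNS)

LABELS_CSV_COLUMNS = ("patient_id", "sample_id", "x", "y",
                      "pct_tumor", "pct_fibroglandular", "pct_adipose")


class ScanFormatError(ValueError):
    """Raised when a scan file or in-memory scan violates the documented layout.

    The message names the offending group/field.
    """


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nm (inclusive endpoints)."""

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0 or self.stop < self.start:
            raise ValueError("WavelengthGrid requires step > 0 and stop >= start")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return len(self.values)

    def index_of(self, wavelength: float) -> int:
        """Index of an on-grid wavelength; raises if not on the grid."""
        pos = (wavelength - self.start) / self.step
        idx = int(round(pos))
        if not (0 <= idx < len(self)) or abs(pos - idx) > 1e-9:
            raise ValueError(f"wavelength {wavelength} nm not on grid "
                             f"{self.start}-{self.stop} step {self.step}")
        return idx


#: Default emission grid: 380-570 nm in 5 nm steps (39 wavelengths).
EMISSION_GRID = WavelengthGrid(380.0, 570.0, 5.0)
#: DR spectrometer grid used for analysis: 450-650 nm in 2 nm steps.
DR_GRID = WavelengthGrid(450.0, 650.0, 2.0)
#: Wavelengths (nm) at which DR parameters are reported.
DR_ANALYSIS_WAVELENGTHS = (520.0, 540.0, 560.0, 576.0)

#: TRF digitizer time axis: 0.1 ns sampling over a 50 ns window.
TIME_STEP_NS = 0.1
TIME_WINDOW_NS = 50.0


def default_time_axis() -> np.ndarray:
    n = int(round(TIME_WINDOW_NS / TIME_STEP_NS))
    return TIME_STEP_NS * np.arange(n)


def _check_dr_analysis_wavelengths() -> None:
    for wl in DR_ANALYSIS_WAVELENGTHS:
        DR_GRID.index_of(wl)


_check_dr_analysis_wavelengths()

N_PULSES = 11


@dataclass
class SpotMeasurement:
    """One raster-scan pixel: raw TRF pulse trains plus DR bundle spectra.

    ``trf_traces`` has shape (n_wavelengths, n_pulses, n_time); the default
    acquisition is 39 emission wavelengths x 11 pulses.  ``dr_spectra`` has
    shape (3, n_dr_wavelengths) for the three detection bundles.
    """

    patient_id: str
    sample_id: str
    grid_x: int
    grid_y: int
    trf_traces: np.ndarray
    dr_spectra: np.ndarray
    time_axis: np.ndarray = field(default_factory=default_time_axis)
    emission_wavelengths: np.ndarray = field(
        default_factory=lambda: EMISSION_GRID.values)
    dr_wavelengths: np.ndarray = field(default_factory=lambda: DR_GRID.values)

    @classmethod
    def from_trace_list(cls, traces_by_wavelength: Sequence[np.ndarray],
                        emission_wavelengths: np.ndarray | None = None,
                        **kwargs) -> "SpotMeasurement":
        """Build from a per-wavelength list of (n_pulses, n_time) arrays.

        Raises :class:`ScanFormatError` naming the wavelength if any entry
        does not carry the expected number of pulses.
        """
        wls = (EMISSION_GRID.values if emission_wavelengths is None
               else np.asarray(emission_wavelengths))
        if len(traces_by_wavelength) != len(wls):
            raise ScanFormatError(
                f"expected {len(wls)} emission wavelengths, "
                f"got {len(traces_by_wavelength)}")
        for wl, block in zip(wls, traces_by_wavelength):
            block = np.asarray(block)
            if block.ndim != 2 or block.shape[0] != N_PULSES:
                raise ScanFormatError(
                    f"expected {N_PULSES} pulses at wavelength {wl:g} nm, "
                    f"got shape {block.shape}")
        return cls(trf_traces=np.stack(traces_by_wavelength),
                   emission_wavelengths=wls, **kwargs)

    def validate(self) -> None:
        name = f"spot ({self.patient_id}/{self.sample_id}/" \
               f"x{self.grid_x}_y{self.grid_y})"
        if self.trf_traces.ndim != 3:
            raise ScanFormatError(f"{name}: trf traces must be 3-D")
        nwl, npulse, _ = self.trf_traces.shape
        if nwl != len(self.emission_wavelengths):
            raise ScanFormatError(
                f"{name}: {nwl} trace blocks for "
                f"{len(self.emission_wavelengths)} wavelengths")
        if npulse != N_PULSES:
            raise ScanFormatError(
                f"{name}: expected {N_PULSES} pulses per wavelength, "
                f"got {npulse}")
        if self.dr_spectra.shape != (len(DR_SEPARATIONS),
                                     len(self.dr_wavelengths)):
            raise ScanFormatError(
                f"{name}: dr_spectra shape {self.dr_spectra.shape}, expected "
                f"({len(DR_SEPARATIONS)}, {len(self.dr_wavelengths)})")
        if np.any(np.diff(self.time_axis) <= 0):
            raise ScanFormatError(f"{name}: time axis not strictly increasing")
        for fld, arr in (("trf_traces", self.trf_traces),
                         ("dr_spectra", self.dr_spectra)):
            if not np.all(np.isfinite(arr)):
                raise ScanFormatError(f"{name}: non-finite values in {fld}")


@dataclass(frozen=True)
class TissueLabel:
    """Histology composition of one pixel, in percent (sums to 100)."""

    pct_tumor: float
    pct_fibroglandular: float
    pct_adipose: float

    def __post_init__(self) -> None:
        parts = (self.pct_tumor, self.pct_fibroglandular, self.pct_adipose)
        if any(p < 0 or p > 100 for p in parts):
            raise ValueError("percentages must lie in [0, 100]")
        if abs(sum(parts) - 100.0) > 1e-6:
            raise ValueError(f"composition must sum to 100, got {sum(parts)}")

    @property
    def is_pure(self) -> bool:
        return 100.0 in (self.pct_tumor, self.pct_fibroglandular,
                         self.pct_adipose)

    @property
    def pure_class(self) -> str | None:
        if self.pct_adipose == 100.0:
            return "adipose"
        if self.pct_fibroglandular == 100.0:
            return "fibroglandular"
        if self.pct_tumor == 100.0:
            return "tumor"
        return None


def filter_pure(labels: pd.DataFrame) -> pd.DataFrame:
    """Keep only pixels whose composition is 100% a single class.

    ``labels`` must carry ``pct_tumor``, ``pct_fibroglandular`` and
    ``pct_adipose`` columns.  Returns the retained rows with an added
    ``label`` column; mixed pixels are dropped (the classification model is
    trained on pure pixels only).
    """
    pct = labels[["pct_adipose", "pct_fibroglandular", "pct_tumor"]].to_numpy()
    if np.any(pct < 0) or np.any(pct > 100):
        raise ValueError("percentages must lie in [0, 100]")
    if np.any(np.abs(pct.sum(axis=1) - 100.0) > 1e-6):
        raise ValueError("each pixel's composition must sum to 100")
    pure_mask = (pct == 100.0).any(axis=1)
    out = labels.loc[pure_mask].copy()
    which = np.argmax(pct[pure_mask], axis=1)
    out["label"] = np.asarray(CLASSES)[which]
    return out


class Dataset:
    """Feature table for modeling: one row per spectrum.

    Wraps a DataFrame with columns ``patient_id, sample_id, x, y, label``
    plus the 13 optical parameters.  Records with missing/empty patient ids
    or non-finite parameters are rejected.
    """

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in ("patient_id", "label", *FEATURE_COLUMNS)
                   if c not in records.columns]
        if missing:
            raise ValueError(f"Dataset missing columns: {missing}")
        if records["patient_id"].astype(str).str.len().eq(0).any():
            raise ValueError("every record needs a non-empty patient_id")
        bad = ~records["label"].isin(CLASSES)
        if bad.any():
            raise ValueError(
                f"unknown labels: {sorted(records.loc[bad, 'label'].unique())}")
        feats = records[list(FEATURE_COLUMNS)].to_numpy(float)
        if not np.all(np.isfinite(feats)):
            raise ValueError("all 13 optical parameters must be finite")
        self.records = records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        vc = self.records["label"].value_counts()
        return {c: int(vc.get(c, 0)) for c in CLASSES}

    @property
    def patients(self) -> list[str]:
        return sorted(self.records["patient_id"].astype(str).unique())

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        return cls(pd.read_csv(path, dtype={"patient_id": str,
                                            "sample_id": str}))

    def to_csv(self, path: str | Path) -> None:
        cols = [c for c in FEATURES_CSV_COLUMNS if c in self.records.columns]
        cols += [c for c in self.records.columns if c not in cols]
        self.records[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scan container (HDF5)
# ---------------------------------------------------------------------------

@dataclass
class Scan:
    """A scan file's contents: spots plus per-scan DR calibration spectra."""

    spots: list[SpotMeasurement]
    blank: np.ndarray | None = None       # water-blank DR spectrum (bundle 2)
    standard: np.ndarray | None = None    # 99% reflectance standard spectrum

    def __iter__(self) -> Iterator[SpotMeasurement]:
        return iter(self.spots)

    def __len__(self) -> int:
        return len(self.spots)


def write_scan(path: str | Path, spots: Iterable[SpotMeasurement],
               blank: np.ndarray | None = None,
               standard: np.ndarray | None = None) -> None:
    """Write spots to the documented HDF5 layout.

    Layout::

        /axes/{time,emission_wavelengths,dr_wavelengths,dr_separations}
        /calibration/{blank,standard}            (optional)
        /patients/<pid>/samples/<sid>/spots/x<X>_y<Y>/{trf,dr}

    Integer grid indices are stored as attributes and round-trip exactly;
    traces round-trip at full float64 precision.
    """
    spots = list(spots)
    with h5py.File(path, "w") as f:
        if spots:
            ax = f.create_group("axes")
            ax.create_dataset("time", data=spots[0].time_axis)
            ax.create_dataset("emission_wavelengths",
                              data=spots[0].emission_wavelengths)
            ax.create_dataset("dr_wavelengths", data=spots[0].dr_wavelengths)
            ax.create_dataset("dr_separations", data=np.array(DR_SEPARATIONS))
        cal = f.create_group("calibration")
        if blank is not None:
            cal.create_dataset("blank", data=np.asarray(blank, float))
        if standard is not None:
            cal.create_dataset("standard", data=np.asarray(standard, float))
        for spot in spots:
            spot.validate()
            g = f.require_group(
                f"patients/{spot.patient_id}/samples/{spot.sample_id}/spots"
                f"/x{spot.grid_x}_y{spot.grid_y}")
            g.create_dataset("trf", data=spot.trf_traces)
            g.create_dataset("dr", data=spot.dr_spectra)
            g.attrs["grid_x"] = int(spot.grid_x)
            g.attrs["grid_y"] = int(spot.grid_y)


def read_scan(path: str | Path) -> Scan:
    """Read a scan written by :func:`write_scan`, validating the layout.

    Malformed files raise :class:`ScanFormatError` naming the offending
    group or dataset.
    """
    spots: list[SpotMeasurement] = []
    with h5py.File(path, "r") as f:
        if "axes" in f:
            try:
                time_axis = f["axes/time"][()]
                emission = f["axes/emission_wavelengths"][()]
                dr_wl = f["axes/dr_wavelengths"][()]
            except KeyError as exc:
                raise ScanFormatError(f"missing axes dataset: {exc}") from exc
        else:
            time_axis = default_time_axis()
            emission = EMISSION_GRID.values
            dr_wl = DR_GRID.values
        blank = standard = None
        if "calibration" in f:
            cal = f["calibration"]
            blank = cal["blank"][()] if "blank" in cal else None
            standard = cal["standard"][()] if "standard" in cal else None
        if "patients" not in f:
            raise ScanFormatError("missing top-level group 'patients'")
        for pid in f["patients"]:
            pgrp = f[f"patients/{pid}"]
            if "samples" not in pgrp:
                raise ScanFormatError(
                    f"patients/{pid}: missing group 'samples'")
            for sid in pgrp["samples"]:
                sgrp = pgrp[f"samples/{sid}"]
                if "spots" not in sgrp:
                    raise ScanFormatError(
                        f"patients/{pid}/samples/{sid}: missing group 'spots'")
                for key in sgrp["spots"]:
                    g = sgrp[f"spots/{key}"]
                    where = f"patients/{pid}/samples/{sid}/spots/{key}"
                    for ds in ("trf", "dr"):
                        if ds not in g:
                            raise ScanFormatError(
                                f"{where}: missing dataset '{ds}'")
                    trf = g["trf"][()]
                    if trf.ndim != 3 or trf.shape[0] != len(emission):
                        raise ScanFormatError(
                            f"{where}/trf: shape {trf.shape} does not match "
                            f"{len(emission)} emission wavelengths")
                    if trf.shape[1] != N_PULSES:
                        raise ScanFormatError(
                            f"{where}/trf: expected {N_PULSES} pulses per "
                            f"wavelength, got {trf.shape[1]}")
                    spot = SpotMeasurement(
                        patient_id=str(pid), sample_id=str(sid),
                        grid_x=int(g.attrs["grid_x"]),
                        grid_y=int(g.attrs["grid_y"]),
                        trf_traces=trf, dr_spectra=g["dr"][()],
                        time_axis=time_axis,
                        emission_wavelengths=emission, dr_wavelengths=dr_wl)
                    spot.validate()
                    spots.append(spot)
    spots.sort(key=lambda s: (s.patient_id, s.sample_id, s.grid_x, s.grid_y))
    return Scan(spots=spots, blank=blank, standard=standard)


def write_labels(path: str | Path, labels: pd.DataFrame) -> None:
    labels[list(LABELS_CSV_COLUMNS)].to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str, "sample_id": str})
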