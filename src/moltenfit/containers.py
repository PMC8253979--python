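"""In-memory containers for the assay data the pipeline consumes.

Each container is a small validated dataclass wrapping numpy arrays.
Validation happens in ``__post_init__`` so that every downstream
operation can assume the invariants (monotone grids, finite payloads,
non-negative counts) hold.

Unit conventions used throughout the package:

* concentrations — μM for binding titrations, M for denaturant and quencher
* time — ns
* wavelength — nm
* ellipticity — mdeg observed, deg·cm²·dmol⁻¹ mean-residue
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import AlignmentError, ParameterError, ValidationError

__all__ = [
    "EmissionSpectrum",
    "SpectralSeries",
    "TitrationCurve",
    "QuenchSeries",
    "DecayHistogram",
    "PolarizedDecays",
    "CDSpectrum",
    "MRESpectrum",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains NaN or infinite values")
    return arr


@dataclass
class EmissionSpectrum:
    """A single steady-state emission spectrum.

    Parameters
    ----------
    wavelength : array, nm — strictly increasing grid.
    intensity : array, arbitrary units, same length.
    excitation_nm : excitation wavelength, if known.
    denaturant_m : denaturant concentration of this condition, M.
    meta : free-form metadata carried through readers/writers.
    """

    wavelength: np.ndarray
    intensity: np.ndarray
    excitation_nm: Optional[float] = None
    denaturant_m: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelength = _as_float_array(self.wavelength, "wavelength")
        self.intensity = _as_float_array(self.intensity, "intensity")
        if self.wavelength.size != self.intensity.size:
            raise ValidationError("wavelength and intensity lengths differ")
        if self.wavelength.size < 2:
            raise ValidationError("spectrum needs at least 2 points")
        if not np.all(np.diff(self.wavelength) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")

    def __len__(self) -> int:
        return self.wavelength.size


@dataclass
class SpectralSeries:
    """An ordered set of emission spectra sharing a wavelength grid,
    one per denaturant concentration."""

    spectra: list
    denaturant: np.ndarray

    def __post_init__(self):
        self.denaturant = _as_float_array(self.denaturant, "denaturant")
        if len(self.spectra) != self.denaturant.size:
            raise ValidationError("one spectrum per denaturant point required")
        if not self.spectra:
            raise ValidationError("series is empty")
        grid = self.spectra[0].wavelength
        for sp in self.spectra[1:]:
            if sp.wavelength.size != grid.size or not np.allclose(
                sp.wavelength, grid
            ):
                raise AlignmentError("spectra do not share a wavelength grid")

    @property
    def wavelength(self) -> np.ndarray:
        return self.spectra[0].wavelength

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass
class TitrationCurve:
    """Steady-state anisotropy titration at fixed labeled-species
    concentration ``a0`` (μM) against total titrant ``t0`` (μM)."""

    a0: float
    t0: np.ndarray
    r: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.a0 > 0:
            raise ParameterError("a0 must be positive")
        self.t0 = _as_float_array(self.t0, "t0")
        self.r = _as_float_array(self.r, "r")
        if self.t0.size != self.r.size:
            raise ValidationError("t0 and r lengths differ")
        if np.any(self.t0 < 0):
            raise ValidationError("t0 must be non-negative")
        order = np.argsort(self.t0, kind="stable")
        self.t0 = self.t0[order]
        self.r = self.r[order]

    def __len__(self) -> int:
        return self.t0.size


@dataclass
class QuenchSeries:
    """Stern–Volmer ratios (F0/F or τ0/τ) versus quencher concentration (M)."""

    q: np.ndarray
    ratio: np.ndarray
    ratio_kind: str = "intensity"  # or "lifetime"
    a_ex: Optional[np.ndarray] = None
    a_em: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = _as_float_array(self.q, "q")
        self.ratio = _as_float_array(self.ratio, "ratio")
        if self.q.size != self.ratio.size:
            raise ValidationError("q and ratio lengths differ")
        if np.any(self.q < 0):
            raise ValidationError("quencher concentrations must be >= 0")
        if self.ratio_kind not in ("intensity", "lifetime"):
            raise ValidationError("ratio_kind must be 'intensity' or 'lifetime'")
        order = np.argsort(self.q, kind="stable")
        self.q = self.q[order]
        self.ratio = self.ratio[order]
        for attr in ("a_ex", "a_em"):
            val = getattr(self, attr)
            if val is not None:
                val = _as_float_array(val, attr)
                if val.size != self.q.size:
                    raise ValidationError(f"{attr} length mismatch")
                setattr(self, attr, val[order])

    def __len__(self) -> int:
        return self.q.size


@dataclass
class DecayHistogram:
    """A TCSPC photon-count histogram on a uniform channel grid.

    ``counts`` are non-negative integers; ``role`` distinguishes a measured
    decay from an instrument response function (IRF).
    """

    counts: np.ndarray
    channel_width: float = 0.055  # ns
    role: str = "decay"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 2:
            raise ValidationError("counts must be a 1-D array of >= 2 channels")
        if not np.all(np.isfinite(counts.astype(float))):
            raise ValidationError("counts contain NaN or infinite values")
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValidationError("counts must be integers")
        self.counts = np.round(counts).astype(np.int64)
        if not self.channel_width > 0:
            raise ParameterError("channel width must be positive")
        if self.role not in ("decay", "irf"):
            raise ValidationError("role must be 'decay' or 'irf'")

    @property
    def times(self) -> np.ndarray:
        """Channel start times in ns, beginning at 0."""
        return np.arange(self.counts.size) * self.channel_width

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return self.counts.size


@dataclass
class PolarizedDecays:
    """Matched parallel (VV) and perpendicular (VH) decay histograms with
    the instrumental G-factor."""

    parallel: DecayHistogram
    perpendicular: DecayHistogram
    g_factor: float = 1.0

    def __post_init__(self):
        if not self.g_factor > 0:
            raise ParameterError("G-factor must be positive")
        if len(self.parallel) != len(self.perpendicular) or not np.isclose(
            self.parallel.channel_width, self.perpendicular.channel_width
        ):
            raise AlignmentError("polarized decays must share a channel grid")


@dataclass
class CDSpectrum:
    """Far-UV circular dichroism spectrum in observed millidegrees with the
    metadata needed for mean-residue-ellipticity conversion."""

    wavelength: np.ndarray
    ellipticity_mdeg: np.ndarray
    concentration_mg_ml: float
    path_cm: float
    mrw: float  # mean residue weight, Da
    n_residues: Optional[int] = None
    temperature_c: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelength = _as_float_array(self.wavelength, "wavelength")
        self.ellipticity_mdeg = _as_float_array(
            self.ellipticity_mdeg, "ellipticity_mdeg"
        )
        if self.wavelength.size != self.ellipticity_mdeg.size:
            raise ValidationError("wavelength and ellipticity lengths differ")
        if not np.all(np.diff(self.wavelength) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        for name in ("concentration_mg_ml", "path_cm", "mrw"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class MRESpectrum:
    """Mean residue ellipticity [θ] (deg·cm²·dmol⁻¹) on a wavelength grid."""

    wavelength: np.ndarray
    mre: np.ndarray

    def __post_init__(self):
        self.wavelength = _as_float_array(self.wavelength, "wavelength")
        self.mre = _as_float_array(self.mre, "mre")
        if self.wavelength.size != self.mre.size:
            raise ValidationError("wavelength and mre lengths differ")
        if not np.all(np.diff(self.wavelength) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
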