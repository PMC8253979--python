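"""Circular dichroism: mean-residue ellipticity and the double-wavelength
conformational classification.

Observed far-UV ellipticity (mdeg) is normalized per residue,

    [θ](λ) = θ_mdeg(λ) · MRW / (10 · l · c),

with MRW the mean residue weight (Da, mass/(n_residues − 1) by the
per-peptide-bond convention), l the path length (cm) and c the protein
concentration (mg/mL). The point ([θ]200, [θ]222) then places a protein
on the double-wavelength plane where ordered, molten-globule, pre-molten-
globule and coil-like conformations occupy distinct regions. The region
boundaries are data, not code: they ship as an editable JSON asset and can
be replaced by user-supplied polygons.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
from shapely.geometry import Point, Polygon

from .containers import CDSpectrum, MRESpectrum
from .errors import ConfigurationError, RangeError, ValidationError

__all__ = [
    "to_mre",
    "double_wavelength_point",
    "ClassificationRegions",
    "load_default_regions",
    "classify_conformation",
    "mean_residue_weight",
]


def mean_residue_weight(mass_kda: float, n_residues: int) -> float:
    """MRW in Da: molecular mass / (n_residues − 1)."""
    if n_residues < 2:
        raise ValidationError("need at least 2 residues for MRW")
    return mass_kda * 1000.0 / (n_residues - 1)


def to_mre(spectrum: CDSpectrum) -> MRESpectrum:
    """Convert observed mdeg to mean residue ellipticity
    (deg·cm²·dmol⁻¹)."""
    factor = spectrum.mrw / (
        10.0 * spectrum.path_cm * spectrum.concentration_mg_ml
    )
    return MRESpectrum(
        wavelength=spectrum.wavelength.copy(),
        mre=spectrum.ellipticity_mdeg * factor,
    )


def double_wavelength_point(mre: MRESpectrum,
                            wavelengths=(200.0, 222.0)) -> tuple:
    """([θ]200, [θ]222) by linear interpolation at exactly 200 and 222 nm."""
    lo, hi = mre.wavelength[0], mre.wavelength[-1]
    for w in wavelengths:
        if not lo <= w <= hi:
            raise RangeError(
                f"spectrum covers {lo:g}-{hi:g} nm; cannot interpolate at "
                f"{w:g} nm"
            )
    vals = np.interp(wavelengths, mre.wavelength, mre.mre)
    return float(vals[0]), float(vals[1])


class ClassificationRegions:
    """Named polygons in the ([θ]200, [θ]222) plane.

    Construct from a mapping {name: [[x, y], ...]} or load from JSON with
    layout ``{"provenance": "...", "regions": {name: [[x, y], ...]}}``.
    """

    def __init__(self, regions: dict, provenance: str = ""):
        if not regions:
            raise ConfigurationError("no classification regions supplied")
        self.provenance = provenance
        self.polygons = {}
        for name, verts in regions.items():
            poly = Polygon(verts)
            if not poly.is_valid or poly.area <= 0:
                raise ConfigurationError(f"degenerate region {name!r}")
            if name in self.polygons:
                raise ConfigurationError(f"duplicate region name {name!r}")
            self.polygons[name] = poly

    @classmethod
    def from_json(cls, path) -> "ClassificationRegions":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(payload["regions"], payload.get("provenance", ""))

    def names(self):
        return list(self.polygons)


def load_default_regions() -> ClassificationRegions:
    """The packaged double-wavelength regions (synthetic approximate
    transcription; see the asset's provenance note)."""
    ref = resources.files("moltenfit.data").joinpath(
        "uversky_fink_regions.synthetic.json"
    )
    with resources.as_file(ref) as path:
        return ClassificationRegions.from_json(path)


def classify_conformation(point, regions: ClassificationRegions) -> dict:
    """Locate a ([θ]200, [θ]222) point among the conformational regions.

    A point inside (or on the boundary of — closed-region convention) a
    polygon gets that polygon's label. Otherwise the label is
    ``"between: A,B"`` naming the two nearest regions, with distances to
    every region reported.
    """
    p = Point(float(point[0]), float(point[1]))
    distances = {
        name: float(poly.distance(p))
        for name, poly in regions.polygons.items()
    }
    inside = [name for name, poly in regions.polygons.items()
              if poly.covers(p)]
    if inside:
        label = inside[0]
    else:
        nearest = sorted(distances, key=distances.get)[:2]
        label = "between: " + ",".join(sorted(nearest))
    return {"label": label, "distances": distances}
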