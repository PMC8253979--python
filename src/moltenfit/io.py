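"""File formats, run configuration and fit reports.

All assay files are delimited text: optional metadata lines prefixed with
``#`` (``# key: value``), then whitespace- or comma-delimited numeric
columns. Writers emit full double precision (`repr` round-trip); readers
reject NaN/Inf payloads. Fit reports are JSON, one per stage, and
round-trip all numeric fields exactly.
"""

from __future__ import annotations

import json
import logging
import re
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .containers import (
    CDSpectrum,
    DecayHistogram,
    EmissionSpectrum,
    PolarizedDecays,
    QuenchSeries,
    TitrationCurve,
)
from .errors import ConfigurationError, FormatError

__all__ = [
    "RunConfig",
    "FitReport",
    "read_spectrum",
    "write_spectrum",
    "read_titration",
    "write_titration",
    "read_quench_table",
    "write_quench_table",
    "read_decay",
    "write_decay",
    "read_cd_spectrum",
    "write_cd_spectrum",
    "run_pipeline",
]

logger = logging.getLogger("moltenfit")


def _configure_logging(verbose: bool = False) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("moltenfit[%(stage)s] %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


def _stage_log(stage: str, message: str) -> None:
    logger.info(message, extra={"stage": stage})


# ---------------------------------------------------------------------------
# configuration and reports
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Run-wide configuration recorded in every report."""

    random_seed: int = 0
    rel_tolerance: float = 1e-8
    max_iterations: int = 2000
    binding_conc_unit: str = "uM"
    denaturant_unit: str = "M"
    quencher_unit: str = "M"
    time_unit: str = "ns"
    wavelength_unit: str = "nm"
    out_dir: str = "."
    verbose: bool = False

    def __post_init__(self):
        if self.rel_tolerance <= 0 or self.max_iterations <= 0:
            raise ConfigurationError("tolerances must be strictly positive")


# expected free-parameter counts per model identifier
_MODEL_PARAMS = {
    "eq1": 3,           # kd, r_a, r_at
    "eq2": 4,           # lambda_n, lambda_u, midpoint, width
    "eq3": 4,           # y0, area, center, fwhm
    "eq4": 1,           # ksv
    "eq4-product": 2,   # k_dyn, k_static
}


def _expected_n_params(model: str) -> Optional[int]:
    if model in _MODEL_PARAMS:
        return _MODEL_PARAMS[model]
    m = re.fullmatch(r"eq6-n(\d)", model)
    if m:
        return 2 * int(m.group(1)) + 1  # amplitudes, lifetimes, shift
    m = re.fullmatch(r"eq7-n(\d)", model)
    if m:
        return 2 * int(m.group(1)) + 1  # amplitudes, thetas, r_inf
    return None


@dataclass
class FitReport:
    """Serializable record of one fitted analysis stage."""

    stage: str
    model: str
    inputs: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    uncertainties: dict = field(default_factory=dict)
    goodness: dict = field(default_factory=dict)
    seed: Optional[int] = None
    version: str = __version__
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = _expected_n_params(self.model)
        if expected is not None and len(self.parameters) != expected:
            raise ConfigurationError(
                f"model {self.model!r} expects {expected} parameters, got "
                f"{len(self.parameters)}"
            )

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "FitReport":
        text = (
            Path(source).read_text()
            if isinstance(source, (str, Path)) and "\n" not in str(source)
            and Path(source).exists()
            else str(source)
        )
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# delimited text I/O
# ---------------------------------------------------------------------------

def _parse_delimited(path, min_rows: int, n_cols_min: int = 2):
    """Parse '#'-metadata + numeric columns; returns (meta, ndarray)."""
    meta, rows = {}, []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    meta[key.strip()] = val.strip()
                continue
            parts = re.split(r"[,\s]+", line)
            try:
                rows.append([float(p) for p in parts if p])
            except ValueError as err:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric data row"
                ) from err
    if len(rows) < min_rows:
        raise FormatError(f"{path}: fewer than {min_rows} data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: inconsistent column counts {widths}")
    data = np.asarray(rows, dtype=float)
    if data.shape[1] < n_cols_min:
        raise FormatError(f"{path}: need at least {n_cols_min} columns")
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: NaN or infinite payload")
    return meta, data


def _write_delimited(path, meta: dict, columns, header_names) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# columns: " + " ".join(header_names) + "\n")
        for row in zip(*columns):
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _meta_float(meta: dict, key: str, default=None):
    if key in meta:
        return float(meta[key])
    return default


def read_spectrum(path) -> EmissionSpectrum:
    """Read a two-column (wavelength nm, intensity) spectrum file."""
    meta, data = _parse_delimited(path, min_rows=5)
    wl, inten = data[:, 0], data[:, 1]
    if not np.all(np.diff(wl) > 0):
        raise FormatError(f"{path}: wavelengths not strictly increasing")
    return EmissionSpectrum(
        wavelength=wl, intensity=inten,
        excitation_nm=_meta_float(meta, "excitation_nm"),
        denaturant_m=_meta_float(meta, "denaturant_M"),
        meta=meta,
    )


def write_spectrum(path, spectrum: EmissionSpectrum) -> None:
    meta = {k: v for k, v in spectrum.meta.items()
            if isinstance(v, (str, int, float))}
    if spectrum.excitation_nm is not None:
        meta["excitation_nm"] = repr(float(spectrum.excitation_nm))
    if spectrum.denaturant_m is not None:
        meta["denaturant_M"] = repr(float(spectrum.denaturant_m))
    _write_delimited(path, meta, (spectrum.wavelength, spectrum.intensity),
                     ("wavelength_nm", "intensity"))


def read_titration(path) -> TitrationCurve:
    """Read a titration table (columns T0_uM, r) with ``a0_uM`` metadata."""
    meta, data = _parse_delimited(path, min_rows=5)
    if "a0_uM" not in meta:
        raise FormatError(f"{path}: missing required metadata key a0_uM")
    return TitrationCurve(a0=float(meta["a0_uM"]), t0=data[:, 0],
                          r=data[:, 1], meta=meta)


def write_titration(path, curve: TitrationCurve) -> None:
    meta = {"a0_uM": repr(float(curve.a0))}
    meta.update({k: v for k, v in curve.meta.items()
                 if isinstance(v, (str, int, float))})
    _write_delimited(path, meta, (curve.t0, curve.r), ("T0_uM", "r"))


def read_quench_table(path) -> QuenchSeries:
    """Read a quench table (columns Q_M, ratio [, A_ex, A_em])."""
    meta, data = _parse_delimited(path, min_rows=4)
    kwargs = {}
    if data.shape[1] >= 4:
        kwargs["a_ex"] = data[:, 2]
        kwargs["a_em"] = data[:, 3]
    return QuenchSeries(q=data[:, 0], ratio=data[:, 1],
                        ratio_kind=meta.get("ratio_kind", "intensity"),
                        meta=meta, **kwargs)


def write_quench_table(path, series: QuenchSeries) -> None:
    meta = {"ratio_kind": series.ratio_kind}
    cols = [series.q, series.ratio]
    names = ["Q_M", "ratio"]
    if series.a_ex is not None and series.a_em is not None:
        cols += [series.a_ex, series.a_em]
        names += ["A_ex", "A_em"]
    _write_delimited(path, meta, cols, names)


def read_decay(path) -> DecayHistogram:
    """Read a decay/IRF histogram (columns time_ns, counts)."""
    meta, data = _parse_delimited(path, min_rows=10)
    times, counts = data[:, 0], data[:, 1]
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise FormatError(f"{path}: channel grid is not uniform")
    return DecayHistogram(counts=counts, channel_width=float(dt[0]),
                          role=meta.get("role", "decay"), meta=meta)


def write_decay(path, decay: DecayHistogram) -> None:
    meta = {"role": decay.role,
            "channel_width_ns": repr(float(decay.channel_width))}
    _write_delimited(path, meta, (decay.times, decay.counts),
                     ("time_ns", "counts"))


def read_cd_spectrum(path) -> CDSpectrum:
    """Read a CD file (columns wavelength_nm, ellipticity_mdeg) with
    concentration_mg_ml, path_cm and mrw metadata."""
    meta, data = _parse_delimited(path, min_rows=5)
    for key in ("concentration_mg_ml", "path_cm", "mrw"):
        if key not in meta:
            raise FormatError(f"{path}: missing required metadata {key}")
    return CDSpectrum(
        wavelength=data[:, 0], ellipticity_mdeg=data[:, 1],
        concentration_mg_ml=float(meta["concentration_mg_ml"]),
        path_cm=float(meta["path_cm"]), mrw=float(meta["mrw"]),
        n_residues=int(meta["n_residues"]) if "n_residues" in meta else None,
        temperature_c=_meta_float(meta, "temperature_c"), meta=meta,
    )


def write_cd_spectrum(path, spectrum: CDSpectrum) -> None:
    meta = {
        "concentration_mg_ml": repr(float(spectrum.concentration_mg_ml)),
        "path_cm": repr(float(spectrum.path_cm)),
        "mrw": repr(float(spectrum.mrw)),
    }
    if spectrum.n_residues is not None:
        meta["n_residues"] = str(spectrum.n_residues)
    _write_delimited(path, meta,
                     (spectrum.wavelength, spectrum.ellipticity_mdeg),
                     ("wavelength_nm", "ellipticity_mdeg"))


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _stage_binding(entry, config):
    from .binding import fit_binding

    curve = read_titration(entry["path"])
    fit = fit_binding(curve, random_state=config.random_seed)
    return FitReport(
        stage="binding", model="eq1", inputs=[str(entry["path"])],
        parameters={"kd": fit.kd_, "r_a": fit.r_a_, "r_at": fit.r_at_},
        uncertainties={"kd": fit.kd_err_, "r_a": fit.r_a_err_,
                       "r_at": fit.r_at_err_},
        goodness={"rss": fit.rss_,
                  "low_dynamic_range": fit.low_dynamic_range_},
        seed=config.random_seed,
    )


def _stage_transition(entry, config):
    from .transitions import fit_sigmoid_transition

    _, data = _parse_delimited(entry["path"], min_rows=6)
    fit = fit_sigmoid_transition(data[:, :2],
                                 random_state=config.random_seed)
    return FitReport(
        stage="transition", model="eq2", inputs=[str(entry["path"])],
        parameters={"lambda_n": fit.lambda_n_, "lambda_u": fit.lambda_u_,
                    "midpoint": fit.midpoint_, "width": fit.width_},
        uncertainties={"lambda_n": fit.lambda_n_err_,
                       "lambda_u": fit.lambda_u_err_,
                       "midpoint": fit.midpoint_err_,
                       "width": fit.width_err_},
        goodness={"rss": fit.rss_,
                  "low_cooperativity": fit.low_cooperativity_,
                  "midpoint_slope": fit.midpoint_slope_},
        seed=config.random_seed,
        extras={"shift_nm": fit.shift_},
    )


def _stage_quench(entry, config):
    from .quenching import SternVolmer

    series = read_quench_table(entry["path"])
    fit = SternVolmer(model=entry.get("model", "auto")).fit(series)
    if fit.model_ == "linear":
        params = {"ksv": fit.ksv_}
        model_id = "eq4"
    else:
        params = {"k_dyn": fit.k_dyn_, "k_static": fit.k_static_}
        model_id = "eq4-product"
    return FitReport(
        stage="quench", model=model_id, inputs=[str(entry["path"])],
        parameters=params,
        goodness={"rss": fit.rss_, "aicc": fit.aicc_},
        seed=config.random_seed,
    )


def _stage_tcspc(entry, config):
    from .timeresolved import fit_reconvolution

    decay = read_decay(entry["path"])
    irf = read_decay(entry["irf"])
    n = int(entry.get("n_components", 1))
    fit = fit_reconvolution(decay, irf, n_components=n,
                            random_state=config.random_seed)
    params = {}
    for i, (a, tau) in enumerate(zip(fit.amplitudes_, fit.lifetimes_)):
        params[f"a{i}"] = float(a)
        params[f"tau{i}"] = float(tau)
    params["shift"] = fit.shift_
    return FitReport(
        stage="tcspc", model=f"eq6-n{n}",
        inputs=[str(entry["path"]), str(entry["irf"])],
        parameters=params,
        goodness={"chi2_red": fit.chi2_red_, "tau_amp": fit.tau_amp_,
                  "tau_int": fit.tau_int_},
        seed=config.random_seed,
    )


_STAGES = {
    "binding": _stage_binding,
    "transition": _stage_transition,
    "quench": _stage_quench,
    "tcspc": _stage_tcspc,
}


def run_pipeline(config: RunConfig, manifest: list) -> list:
    """Run independent analysis stages and return one FitReport each.

    ``manifest`` is a list of dicts with at least a ``stage`` key
    (binding | transition | quench | tcspc) and stage-specific input
    paths. Stages run in manifest order but are independent.
    """
    _configure_logging(config.verbose)
    reports = []
    for entry in manifest:
        name = entry.get("stage")
        if name not in _STAGES:
            raise ConfigurationError(f"unknown stage {name!r}")
        t0 = time.perf_counter()
        report = _STAGES[name](entry, config)
        elapsed = time.perf_counter() - t0
        _stage_log(name, f"seed={config.random_seed} version={__version__} "
                         f"wall={elapsed:.3f}s")
        report.extras.setdefault("wall_time_s", elapsed)
        reports.append(report)
    return reports
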