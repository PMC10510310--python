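"""File I/O: CSV and JCAMP-DX spectra, spin-system JSON, ensemble CSV.

CSV (two columns, ``frequency_hz,intensity``) is the canonical interchange
format.  JCAMP-DX support covers the AFFN/XYDATA dialect, which is
sufficient for 1D real spectra; vendor raw directories are out of scope.
Frequency axes are stored in Hz relative to the carrier, increasing with
index; ppm rendering is presentation-level only.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .conformer_avg import ConformerEnsemble
from .spin_model import FrequencyGrid, Spectrum1D, SpinSystemSpec

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_spin_system",
    "write_spin_system",
    "read_ensemble",
    "write_ensemble",
]

logger = logging.getLogger(__name__)

_UNIFORMITY_RTOL = 1e-6


def _spectrum_from_arrays(freqs: np.ndarray, y: np.ndarray, **meta) -> Spectrum1D:
    if freqs.size < 2:
        raise ValueError("a spectrum requires at least two points")
    order = np.argsort(freqs)
    freqs, y = freqs[order], y[order]
    steps = np.diff(freqs)
    if np.any(steps <= 0):
        raise ValueError("frequency axis contains duplicates")
    mean_step = steps.mean()
    if np.max(np.abs(steps - mean_step)) > _UNIFORMITY_RTOL * abs(mean_step):
        logger.warning("non-uniform frequency axis; resampling onto a uniform grid")
        uniform = np.linspace(freqs[0], freqs[-1], freqs.size)
        y = np.interp(uniform, freqs, y)
        freqs = uniform
    grid = FrequencyGrid(start=float(freqs[0]), stop=float(freqs[-1]), npoints=int(freqs.size))
    return Spectrum1D(grid=grid, intensities=y, **meta)


def _read_csv_spectrum(path: Path) -> Spectrum1D:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (frequency_hz, intensity)")
    freqs = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    y = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    bad = np.flatnonzero(~(np.isfinite(freqs) & np.isfinite(y)))
    if bad.size:
        # +2 converts 0-based data row to 1-based file line including header
        raise ValueError(f"{path}: non-finite or unparseable value at line {bad[0] + 2}")
    return _spectrum_from_arrays(freqs, y, metadata={"source": str(path)})


# --------------------------------------------------------------------------
# JCAMP-DX (AFFN / XYDATA dialect)


def _write_jcamp(path: Path, spec: Spectrum1D, title: str = "ipapfesta spectrum") -> None:
    y = spec.intensities
    ymax = float(np.max(np.abs(y))) if y.size else 0.0
    yfactor = ymax / 1e9 if ymax > 0 else 1.0
    yi = np.round(y / yfactor).astype(np.int64)
    freqs = spec.frequencies
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=HZ",
        "##YUNITS=ARBITRARY UNITS",
        f"##.OBSERVE FREQUENCY={spec.spectrometer_frequency}",
        f"##FIRSTX={freqs[0]:.10g}",
        f"##LASTX={freqs[-1]:.10g}",
        f"##NPOINTS={spec.grid.npoints}",
        "##XFACTOR=1.0",
        f"##YFACTOR={yfactor:.12e}",
        f"##FIRSTY={y[0]:.10g}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, yi.size, per_line):
        chunk = yi[i : i + per_line]
        lines.append(f"{freqs[i]:.6f} " + " ".join(str(v) for v in chunk))
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def _read_jcamp(path: Path) -> Spectrum1D:
    text = path.read_text()
    header: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            if line.upper().startswith("##XYDATA"):
                in_data = True
                continue
            if line.upper().startswith("##END"):
                in_data = False
                continue
            key, _, val = line[2:].partition("=")
            header[key.strip().upper()] = val.strip()
            continue
        if in_data:
            data_lines.append((lineno, line))
    for req in ("FIRSTX", "LASTX", "NPOINTS", "YFACTOR"):
        if req not in header:
            raise ValueError(f"{path}: missing ##{req}= record")
    npoints = int(float(header["NPOINTS"]))
    firstx, lastx = float(header["FIRSTX"]), float(header["LASTX"])
    yfactor = float(header["YFACTOR"])
    xfactor = float(header.get("XFACTOR", "1"))
    ys: list[float] = []
    for lineno, line in data_lines:
        parts = line.replace(",", " ").split()
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise ValueError(f"{path}: unparseable AFFN value at line {lineno}") from exc
        ys.extend(vals[1:])  # first value on each line is the abscissa check value
    if len(ys) != npoints:
        raise ValueError(f"{path}: expected {npoints} ordinates, found {len(ys)}")
    y = np.asarray(ys, dtype=float) * yfactor
    freqs = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    meta = {"source": str(path), "title": header.get("TITLE", "")}
    obs = header.get(".OBSERVE FREQUENCY")
    kwargs = {"metadata": meta}
    if obs:
        kwargs["spectrometer_frequency"] = float(obs)
    return _spectrum_from_arrays(freqs, y, **kwargs)


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum1D:
    """Read a 1D spectrum from CSV or JCAMP-DX (format inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in {".jdx", ".dx", ".jcamp"} else "csv"
    if format == "csv":
        return _read_csv_spectrum(path)
    if format == "jcamp":
        return _read_jcamp(path)
    raise ValueError(f"unknown spectrum format {format!r}")


def write_spectrum(path: str | Path, spec: Spectrum1D, format: str | None = None) -> None:
    """Write a spectrum as two-column CSV or JCAMP-DX."""
    path = Path(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in {".jdx", ".dx", ".jcamp"} else "csv"
    if format == "csv":
        df = pd.DataFrame(
            {"frequency_hz": spec.frequencies, "intensity": spec.intensities}
        )
        df.to_csv(path, index=False, float_format="%.10g")
    elif format == "jcamp":
        _write_jcamp(path, spec)
    else:
        raise ValueError(f"unknown spectrum format {format!r}")


def read_spin_system(path: str | Path) -> SpinSystemSpec:
    """Load a spin-system specification from JSON (validated)."""
    return SpinSystemSpec.model_validate_json(Path(path).read_text())


def write_spin_system(path: str | Path, spec: SpinSystemSpec) -> None:
    Path(path).write_text(spec.model_dump_json(indent=2) + "\n")


def read_ensemble(path: str | Path, temperature: float = 298.15) -> ConformerEnsemble:
    """Load a conformer ensemble CSV.

    Expected columns: ``conformer``, optional ``group``, one of
    ``gibbs_kj_mol`` / ``population``, then one column per proton site with
    the conformer-specific J in Hz.
    """
    df = pd.read_csv(path)
    if "conformer" not in df.columns:
        raise ValueError(f"{path}: missing 'conformer' column")
    labels = df["conformer"].astype(str).tolist()
    group_of = None
    reserved = {"conformer", "group", "gibbs_kj_mol", "population"}
    if "group" in df.columns:
        group_of = dict(zip(labels, df["group"].astype(str)))
    has_g = "gibbs_kj_mol" in df.columns
    has_p = "population" in df.columns
    if has_g == has_p:
        raise ValueError(f"{path}: need exactly one of 'gibbs_kj_mol' or 'population'")
    site_cols = [c for c in df.columns if c not in reserved]
    couplings = {c: df[c].astype(float).tolist() for c in site_cols}
    kwargs = dict(labels=labels, couplings=couplings, group_of=group_of, temperature=temperature)
    if has_g:
        return ConformerEnsemble(gibbs_energies=df["gibbs_kj_mol"].astype(float).tolist(), **kwargs)
    return ConformerEnsemble(populations=df["population"].astype(float).tolist(), **kwargs)


def write_ensemble(path: str | Path, ensemble: ConformerEnsemble) -> None:
    data: dict = {"conformer": ensemble.labels}
    if ensemble.group_of is not None:
        data["group"] = [ensemble.group_of[lab] for lab in ensemble.labels]
    data["population"] = ensemble.populations
    for site, js in ensemble.couplings.items():
        data[site] = js
    pd.DataFrame(data).to_csv(path, index=False)
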