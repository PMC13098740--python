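"""CSV/JSON measurement and result plumbing with strict schema validation.

Dialects (units fixed at the interface: mm, mm^-1, mm^2/s, Hz, nm, seconds):

* FD CSV: ``frame,time_s,wavelength_nm,mod_freq_hz,amplitude,phase_rad``
* DCS CSV: ``frame,time_s,tau_s,g2``
* Results JSON: per-frame fits plus provenance (LUT hashes, options, version).
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict

import numpy as np
import pandas as pd

from .forward import FDReflectance, G2Curve
from .invert import FrameFit, MeasurementFrame

__all__ = [
    "SchemaError",
    "FD_COLUMNS",
    "DCS_COLUMNS",
    "write_fd_csv",
    "write_dcs_csv",
    "read_measurements",
    "write_results",
]

FD_COLUMNS = ["frame", "time_s", "wavelength_nm", "mod_freq_hz", "amplitude", "phase_rad"]
DCS_COLUMNS = ["frame", "time_s", "tau_s", "g2"]


class SchemaError(ValueError):
    """A measurement file violates the documented schema."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", stacklevel=3)


def _check_finite(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        bad = df.index[~np.isfinite(df[c].to_numpy(dtype=float))].tolist()
        if bad:
            # +2: one for the header line, one for 0- vs 1-based counting
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise SchemaError(f"{path}: non-finite {c!r} at line(s) {lines}")


def write_fd_csv(path, frames: list[MeasurementFrame], sds: float | None = None) -> None:
    rows = []
    for i, fr in enumerate(frames):
        for wl, m in sorted(fr.fd.items()):
            rows.append(
                {
                    "frame": i,
                    "time_s": fr.time_s,
                    "wavelength_nm": wl,
                    "mod_freq_hz": m.mod_freq_hz,
                    "amplitude": m.amplitude,
                    "phase_rad": m.phase_rad,
                }
            )
    pd.DataFrame(rows, columns=FD_COLUMNS).to_csv(path, index=False)


def write_dcs_csv(path, frames: list[MeasurementFrame]) -> None:
    rows = []
    for i, fr in enumerate(frames):
        if fr.g2 is None:
            continue
        for tau, g2 in zip(fr.g2.tau_s, fr.g2.values):
            rows.append({"frame": i, "time_s": fr.time_s, "tau_s": tau, "g2": g2})
    pd.DataFrame(rows, columns=DCS_COLUMNS).to_csv(path, index=False)


def read_measurements(
    fd_path=None,
    dcs_path=None,
    sds: float = 25.0,
    beta: float | None = None,
) -> list[MeasurementFrame]:
    """Read FD and/or DCS CSVs into per-frame measurement bundles.

    Frames are joined on the ``frame`` index; ``sds`` annotates the FD records
    (the CSV dialect does not carry it).  Raises :class:`SchemaError` with line
    numbers for malformed rows (e.g. negative g2).
    """
    if fd_path is None and dcs_path is None:
        raise ValueError("need at least one of fd_path / dcs_path")
    fd_by_frame: dict[int, dict[float, FDReflectance]] = defaultdict(dict)
    time_by_frame: dict[int, float] = {}
    if fd_path is not None:
        df = pd.read_csv(fd_path)
        _check_columns(df, FD_COLUMNS, fd_path)
        _check_finite(df, FD_COLUMNS, fd_path)
        neg = df.index[df["amplitude"] < 0].tolist()
        if neg:
            raise SchemaError(f"{fd_path}: negative amplitude at line {neg[0] + 2}")
        for _, row in df.iterrows():
            fr = int(row["frame"])
            fd_by_frame[fr][float(row["wavelength_nm"])] = FDReflectance(
                wavelength=float(row["wavelength_nm"]),
                mod_freq_hz=float(row["mod_freq_hz"]),
                sds=sds,
                amplitude=float(row["amplitude"]),
                phase_rad=float(row["phase_rad"]),
            )
            time_by_frame.setdefault(fr, float(row["time_s"]))
    g2_by_frame: dict[int, G2Curve] = {}
    if dcs_path is not None:
        df = pd.read_csv(dcs_path)
        _check_columns(df, DCS_COLUMNS, dcs_path)
        _check_finite(df, DCS_COLUMNS, dcs_path)
        neg = df.index[df["g2"] < 0].tolist()
        if neg:
            raise SchemaError(f"{dcs_path}: negative g2 at line {neg[0] + 2}")
        for fr, grp in df.groupby("frame"):
            grp = grp.sort_values("tau_s")
            g2_by_frame[int(fr)] = G2Curve(
                grp["tau_s"].to_numpy(), grp["g2"].to_numpy(), beta if beta is not None else float("nan")
            )
            time_by_frame.setdefault(int(fr), float(grp["time_s"].iloc[0]))
    frames = []
    for fr in sorted(set(fd_by_frame) | set(g2_by_frame)):
        frames.append(
            MeasurementFrame(
                time_s=time_by_frame.get(fr, float(fr)),
                fd=dict(fd_by_frame.get(fr, {})),
                g2=g2_by_frame.get(fr),
            )
        )
    return frames


def write_results(path, fits: list[FrameFit], provenance: dict | None = None) -> None:
    """Serialize per-frame fit results (and optional hemodynamics) to JSON."""
    from . import __version__

    out = {
        "layerlut_version": __version__,
        "provenance": provenance or {},
        "frames": [
            {
                "time_s": f.time_s,
                "failed": f.failed,
                "error": f.error,
                "fd": {
                    f"{wl:g}": {
                        "mua": r.mua,
                        "musp": r.musp,
                        "objective": r.objective,
                        "model_tag": r.model_tag,
                        "boundary_hit": r.boundary_hit,
                    }
                    for wl, r in f.fd.items()
                },
                "dcs": (
                    None
                    if f.dcs is None
                    else {
                        "bfi": f.dcs.bfi,
                        "beta": f.dcs.beta,
                        "residual_rms": f.dcs.residual_rms,
                        "model_tag": f.dcs.model_tag,
                        "boundary_hit": f.dcs.boundary_hit,
                    }
                ),
            }
            for f in fits
        ],
    }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)
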