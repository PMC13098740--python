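"""Build, densify, persist and query look-up tables for FD-NIRS and DCS inversion.

An FD LUT maps bottom-layer ``(mua, musp)`` to complex frequency-domain
reflectance at one (wavelength, modulation frequency, SDS) under fixed
upper-layer assumptions (skin tone, adipose thickness).  It is built from white
Monte Carlo batches at coarse musp nodes (0.1 mm^-1 spacing by default, ten
independent-seed repeats pooled per node), filled along the mua axis by
Beer-Lambert reweighting (exact: scattering paths are mua-independent) and
densified along musp by linear interpolation of the real and imaginary parts.

A DCS LUT stores, per coarse musp node, a compressed photon record (upper-layer
absorption-weighted exit weight, bottom pathlength, and the per-photon
autocorrelation decay rates of the upper layers and of the bottom layer) from
which g1^2 curves for any bottom BFi are evaluated analytically; musp enters via
linear interpolation of g1^2 between bracketing nodes.  The coherence factor
beta is applied at query time, never baked in.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from .forward import absorption_weights, default_tau_grid, k0_per_mm
from .mc import PhotonBatch, SimConfig, pool_batches, run_layered_mc
from .media import LayeredMedium

__all__ = [
    "LUTAxes",
    "FDLUT",
    "DCSLUT",
    "build_fd_lut",
    "build_dcs_lut",
    "build_lut_pair",
    "save_lut",
    "load_lut",
    "ProvenanceError",
    "node_seeds",
]

LUT_SCHEMA_VERSION = 1


class ProvenanceError(RuntimeError):
    """Raised when a persisted LUT fails its schema or integrity check."""


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 12)


@dataclass(frozen=True)
class LUTAxes:
    """Axis definitions for the bottom-layer property grids."""

    musp_min: float = 0.1
    musp_max: float = 1.0
    musp_step: float = 0.1
    musp_dense_step_fd: float = 0.001
    musp_dense_step_dcs: float = 0.05
    mua_min: float = 0.01
    mua_max: float = 0.2
    mua_step: float = 0.001
    bfi_min: float = 0.1e-6
    bfi_max: float = 40e-6
    n_tau: int = 64
    tau_min: float = 1e-7
    tau_max: float = 1e-1

    def __post_init__(self) -> None:
        for name in ("musp_step", "musp_dense_step_fd", "musp_dense_step_dcs", "mua_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.musp_min < self.musp_max and self.mua_min < self.mua_max):
            raise ValueError("axis bounds must be increasing")
        if not (0 < self.bfi_min < self.bfi_max):
            raise ValueError("bfi bounds must be positive and increasing")

    @property
    def musp_coarse(self) -> np.ndarray:
        return _grid(self.musp_min, self.musp_max, self.musp_step)

    @property
    def musp_dense_fd(self) -> np.ndarray:
        return _grid(self.musp_min, self.musp_max, self.musp_dense_step_fd)

    @property
    def musp_dense_dcs(self) -> np.ndarray:
        return _grid(self.musp_min, self.musp_max, self.musp_dense_step_dcs)

    @property
    def mua_grid(self) -> np.ndarray:
        return _grid(self.mua_min, self.mua_max, self.mua_step)

    @property
    def tau_grid(self) -> np.ndarray:
        return default_tau_grid(self.n_tau, self.tau_min, self.tau_max)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "musp_min",
                "musp_max",
                "musp_step",
                "musp_dense_step_fd",
                "musp_dense_step_dcs",
                "mua_min",
                "mua_max",
                "mua_step",
                "bfi_min",
                "bfi_max",
                "n_tau",
                "tau_min",
                "tau_max",
            )
        }


def node_seeds(base_seed: int, node_index: int, n_repeats: int) -> list[int]:
    """Independent, reproducible sub-seeds for the repeats of one musp node."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(node_index),))
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n_repeats)]


def _medium_hash(medium: LayeredMedium) -> str:
    return hashlib.sha256(
        json.dumps(medium.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def _run_node(
    medium_template: LayeredMedium,
    musp_node: float,
    sim: SimConfig,
    wavelength: float,
    node_index: int,
    n_repeats: int,
) -> PhotonBatch:
    """Pool ``n_repeats`` independent-seed white-MC batches at one musp node."""
    musp_map = {wl: float(musp_node) for wl in medium_template.wavelengths}
    medium = medium_template.with_bottom(musp=musp_map)
    seeds = node_seeds(sim.seed, node_index, n_repeats)
    batches = [run_layered_mc(medium, sim.with_(seed=s), wavelength) for s in seeds]
    pooled = pool_batches(batches)
    if pooled.n_detected == 0:
        raise RuntimeError(
            f"LUT build failed: zero detected photons at musp={musp_node} mm^-1 "
            f"(wavelength {wavelength} nm, {n_repeats}x{sim.n_photons} photons, "
            f"sds {sim.sds} mm)"
        )
    return pooled


@dataclass
class FDLUT:
    """Dense map (musp, mua) -> complex FD reflectance for fixed upper layers."""

    axes: LUTAxes
    wavelength: float
    mod_freq_hz: float
    values: np.ndarray  # complex (n_musp_dense, n_mua)
    values_coarse: np.ndarray  # complex (n_musp_coarse, n_mua)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self._amp = None
        self._phase = None

    @property
    def musp_axis(self) -> np.ndarray:
        return self.axes.musp_dense_fd

    @property
    def mua_axis(self) -> np.ndarray:
        return self.axes.mua_grid

    def amplitude_phase(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached amplitude and (positive-delay) phase grids."""
        if self._amp is None:
            self._amp = np.abs(self.values)
            self._phase = -np.angle(self.values)
        return self._amp, self._phase

    def query(self, mua: float, musp: float) -> complex:
        """Bilinear interpolation on real and imaginary parts."""
        mg, sg = self.mua_axis, self.musp_axis
        if not (mg[0] <= mua <= mg[-1]) or not (sg[0] <= musp <= sg[-1]):
            raise ValueError("query point outside LUT axes")
        i = min(np.searchsorted(sg, musp, side="right") - 1, sg.size - 2)
        j = min(np.searchsorted(mg, mua, side="right") - 1, mg.size - 2)
        fs = (musp - sg[i]) / (sg[i + 1] - sg[i])
        fm = (mua - mg[j]) / (mg[j + 1] - mg[j])
        v = self.values
        return complex(
            (1 - fs) * (1 - fm) * v[i, j]
            + (1 - fs) * fm * v[i, j + 1]
            + fs * (1 - fm) * v[i + 1, j]
            + fs * fm * v[i + 1, j + 1]
        )


def _node_batches(
    medium_template: LayeredMedium,
    axes: LUTAxes,
    sim: SimConfig,
    wavelength: float,
    n_repeats: int,
) -> list[PhotonBatch]:
    """One pooled white-MC batch per coarse musp node."""
    return [
        _run_node(medium_template, musp_node, sim, wavelength, i, n_repeats)
        for i, musp_node in enumerate(axes.musp_coarse)
    ]


def build_fd_lut(
    medium_template: LayeredMedium,
    axes: LUTAxes,
    sim: SimConfig,
    wavelength: float,
    mod_freq_hz: float,
    n_repeats: int = 10,
    node_batches: list[PhotonBatch] | None = None,
) -> FDLUT:
    """Build an FD LUT from white MC at the coarse musp nodes.

    The bottom-layer mua of the template is ignored (white MC); the mua axis is
    filled by reweighting the pooled batches, and the musp axis is linearly
    interpolated on the complex values to the dense step.  ``node_batches``
    reuses precomputed per-node batches (e.g. shared with a DCS LUT build).
    """
    coarse = axes.musp_coarse
    mua_axis = axes.mua_grid
    n_layers = len(medium_template.simulation_layers())
    upper_mua = np.array(
        [l.mua[wavelength] for l in medium_template.simulation_layers()[:-1]]
    )
    omega_per_ns = 2.0 * math.pi * mod_freq_hz * 1e-9
    if node_batches is None:
        node_batches = _node_batches(medium_template, axes, sim, wavelength, n_repeats)
    values_coarse = np.empty((coarse.size, mua_axis.size), dtype=complex)
    for i, batch in enumerate(node_batches):
        scale = 1.0 / (batch.n_launched * batch.detector_area)
        phasor = batch.exit_weight * np.exp(-1j * omega_per_ns * batch.time_of_flight_ns())
        if n_layers > 1:
            phasor = phasor * np.exp(-(batch.L[:, :-1] @ upper_mua))
        # mua axis by Beer reweighting of the bottom pathlength (exact)
        attn = np.exp(-np.outer(mua_axis, batch.L[:, -1]))
        values_coarse[i] = scale * (attn @ phasor)
    dense = axes.musp_dense_fd
    values = np.empty((dense.size, mua_axis.size), dtype=complex)
    values.real = np.array(
        [np.interp(dense, coarse, values_coarse[:, j].real) for j in range(mua_axis.size)]
    ).T
    values.imag = np.array(
        [np.interp(dense, coarse, values_coarse[:, j].imag) for j in range(mua_axis.size)]
    ).T
    metadata = {
        "kind": "fd",
        "wavelength_nm": float(wavelength),
        "mod_freq_hz": float(mod_freq_hz),
        "sds_mm": sim.sds,
        "detector_half_width_mm": sim.detector_half_width,
        "n_photons": sim.n_photons,
        "n_repeats": n_repeats,
        "base_seed": sim.seed,
        "phase_mode": sim.phase_mode,
        "max_total_path_mm": sim.max_total_path,
        "medium_hash": _medium_hash(medium_template),
        "medium": medium_template.to_dict(),
        "schema_version": LUT_SCHEMA_VERSION,
    }
    return FDLUT(
        axes=axes,
        wavelength=float(wavelength),
        mod_freq_hz=float(mod_freq_hz),
        values=values,
        values_coarse=values_coarse,
        metadata=metadata,
    )


@dataclass
class DCSLUT:
    """Per-musp-node compressed photon records for analytic-in-BFi g2 curves.

    For each coarse musp node ``i`` the stored arrays (concatenated, delimited
    by ``offsets``) hold per detected photon: ``w0`` exit weight including
    upper-layer and bottom absorption at the build mua, ``rate_upper`` the
    tau-coefficient of the upper layers' Brownian decay (fixed upper BFi), and
    ``rate_bottom`` the tau-coefficient per unit bottom BFi.  Then

        g1_i(tau; BFi) = sum_s w0 exp(-(rate_upper + BFi * rate_bottom) tau) / sum_s w0
    """

    axes: LUTAxes
    wavelength: float  # DCS dynamics wavelength, nm
    props_wavelength: float  # wavelength whose tabulated mua/musp were used
    mua_bottom: float
    w0: np.ndarray
    rate_upper: np.ndarray
    rate_bottom: np.ndarray
    L_bottom: np.ndarray  # per-photon bottom pathlength, mm (for mua adjustment)
    offsets: np.ndarray  # (n_nodes + 1,) into the concatenated arrays
    metadata: dict = field(default_factory=dict)

    @property
    def musp_nodes(self) -> np.ndarray:
        return self.axes.musp_coarse

    @property
    def tau_grid(self) -> np.ndarray:
        return self.axes.tau_grid

    def _node_g1(self, i: int, bfi: float, tau: np.ndarray, mua: float | None) -> np.ndarray:
        sl = slice(self.offsets[i], self.offsets[i + 1])
        w0 = self.w0[sl]
        if mua is not None and mua != self.mua_bottom:
            # exact bottom-mua adjustment (white MC: paths are mua-independent)
            w0 = w0 * np.exp(-(mua - self.mua_bottom) * self.L_bottom[sl])
        rate = self.rate_upper[sl] + bfi * self.rate_bottom[sl]
        return (w0[None, :] * np.exp(-np.outer(tau, rate))).sum(axis=1) / w0.sum()

    def g1_squared(
        self,
        musp: float,
        bfi: float,
        tau: np.ndarray | None = None,
        mua: float | None = None,
    ) -> np.ndarray:
        """g1^2(tau) at arbitrary musp (linear interpolation of g1^2) and BFi.

        ``mua`` optionally replaces the build-time bottom absorption by exact
        Beer reweighting of the stored bottom pathlengths.
        """
        tau = self.tau_grid if tau is None else np.asarray(tau, dtype=float)
        nodes = self.musp_nodes
        if not (nodes[0] <= musp <= nodes[-1]):
            raise ValueError("musp outside LUT axis")
        if not (self.axes.bfi_min <= bfi <= self.axes.bfi_max):
            raise ValueError("bfi outside LUT axis")
        i = min(int(np.searchsorted(nodes, musp, side="right")) - 1, nodes.size - 2)
        f = (musp - nodes[i]) / (nodes[i + 1] - nodes[i])
        g1sq_lo = self._node_g1(i, bfi, tau, mua) ** 2
        g1sq_hi = self._node_g1(i + 1, bfi, tau, mua) ** 2
        return (1 - f) * g1sq_lo + f * g1sq_hi

    def g2(
        self,
        musp: float,
        bfi: float,
        beta: float,
        tau: np.ndarray | None = None,
        mua: float | None = None,
    ) -> np.ndarray:
        return 1.0 + beta * self.g1_squared(musp, bfi, tau, mua)

    def bfi_grid(self, n: int = 61) -> np.ndarray:
        """Log-spaced BFi search grid spanning the axis bounds."""
        return np.logspace(math.log10(self.axes.bfi_min), math.log10(self.axes.bfi_max), n)

    def grid_values(self, beta: float, n_bfi: int = 61) -> np.ndarray:
        """Materialized g2 curves over (musp_dense_dcs, bfi_grid, tau)."""
        dense = self.axes.musp_dense_dcs
        bfis = self.bfi_grid(n_bfi)
        tau = self.tau_grid
        out = np.empty((dense.size, bfis.size, tau.size))
        for i, musp in enumerate(dense):
            for j, bfi in enumerate(bfis):
                out[i, j] = 1.0 + beta * self.g1_squared(musp, bfi, tau)
        return out


def build_dcs_lut(
    medium_template: LayeredMedium,
    axes: LUTAxes,
    sim: SimConfig,
    mua_bottom: float,
    wavelength: float = 850.0,
    props_wavelength: float = 830.0,
    n_repeats: int = 10,
    node_batches: list[PhotonBatch] | None = None,
) -> DCSLUT:
    """Build a DCS LUT: white MC per coarse musp node, BFi analytic.

    ``props_wavelength`` selects which tabulated optical properties drive the
    transport (the DCS laser wavelength is not tabulated; by default the 830 nm
    properties stand in), while ``wavelength`` sets the optical wavenumber k0 in
    the Brownian decay.  ``mua_bottom`` is the bottom-layer absorption baked into
    the stored photon weights.  ``node_batches`` reuses precomputed per-node
    batches (e.g. shared with an FD LUT at the same properties wavelength).
    """
    lays = medium_template.simulation_layers()
    upper_mua = np.array([l.mua[props_wavelength] for l in lays[:-1]])
    upper_bfi = np.array([l.bfi for l in lays[:-1]])
    k0 = np.array([k0_per_mm(l.n, wavelength) for l in lays])
    if node_batches is None:
        node_batches = _node_batches(medium_template, axes, sim, props_wavelength, n_repeats)
    w0_parts, ru_parts, rb_parts, lb_parts = [], [], [], []
    offsets = [0]
    for i, batch in enumerate(node_batches):
        mua_vec = np.concatenate([upper_mua, [mua_bottom]])
        w0 = absorption_weights(batch, mua_vec)
        rate_upper = batch.Y[:, :-1] @ (2.0 * k0[:-1] ** 2 * upper_bfi)
        rate_bottom = batch.Y[:, -1] * (2.0 * k0[-1] ** 2)
        w0_parts.append(w0)
        ru_parts.append(rate_upper)
        rb_parts.append(rate_bottom)
        lb_parts.append(batch.L[:, -1])
        offsets.append(offsets[-1] + w0.size)
    metadata = {
        "kind": "dcs",
        "wavelength_nm": float(wavelength),
        "props_wavelength_nm": float(props_wavelength),
        "mua_bottom": float(mua_bottom),
        "sds_mm": sim.sds,
        "detector_half_width_mm": sim.detector_half_width,
        "n_photons": sim.n_photons,
        "n_repeats": n_repeats,
        "base_seed": sim.seed,
        "phase_mode": sim.phase_mode,
        "max_total_path_mm": sim.max_total_path,
        "medium_hash": _medium_hash(medium_template),
        "medium": medium_template.to_dict(),
        "schema_version": LUT_SCHEMA_VERSION,
    }
    return DCSLUT(
        axes=axes,
        wavelength=float(wavelength),
        props_wavelength=float(props_wavelength),
        mua_bottom=float(mua_bottom),
        w0=np.concatenate(w0_parts),
        rate_upper=np.concatenate(ru_parts),
        rate_bottom=np.concatenate(rb_parts),
        L_bottom=np.concatenate(lb_parts),
        offsets=np.asarray(offsets, dtype=np.int64),
        metadata=metadata,
    )


def build_lut_pair(
    medium_template: LayeredMedium,
    axes: LUTAxes,
    sim: SimConfig,
    wavelength: float = 830.0,
    mod_freq_hz: float = 149e6,
    mua_bottom: float | None = None,
    dcs_wavelength: float = 850.0,
    n_repeats: int = 10,
) -> tuple[FDLUT, DCSLUT]:
    """Build an FD LUT and a DCS LUT from one shared set of node batches.

    Both tables derive from the same white-MC simulations at the properties
    wavelength, so this costs half the transport time of two separate builds.
    ``mua_bottom`` defaults to the template's bottom-layer mua at ``wavelength``.
    """
    batches = _node_batches(medium_template, axes, sim, wavelength, n_repeats)
    fd = build_fd_lut(
        medium_template, axes, sim, wavelength, mod_freq_hz,
        n_repeats=n_repeats, node_batches=batches,
    )
    if mua_bottom is None:
        mua_bottom = medium_template.layers[-1].mua[wavelength]
    dcs = build_dcs_lut(
        medium_template, axes, sim, mua_bottom=mua_bottom,
        wavelength=dcs_wavelength, props_wavelength=wavelength,
        n_repeats=n_repeats, node_batches=batches,
    )
    return fd, dcs


# ---------------------------------------------------------------------------
# Persistence (HDF5, version-stamped, integrity-hashed)
# ---------------------------------------------------------------------------


def _content_hash(arrays: dict[str, np.ndarray], metadata: dict) -> str:
    h = hashlib.sha256()
    for name in sorted(arrays):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arrays[name]).tobytes())
    h.update(json.dumps(metadata, sort_keys=True, default=float).encode())
    return h.hexdigest()


def save_lut(lut, path) -> None:
    """Persist an FD or DCS LUT to HDF5 (lossless, version- and hash-stamped)."""
    if isinstance(lut, FDLUT):
        arrays = {"values": lut.values, "values_coarse": lut.values_coarse}
        extra = {"wavelength": lut.wavelength, "mod_freq_hz": lut.mod_freq_hz}
        kind = "fd"
    elif isinstance(lut, DCSLUT):
        arrays = {
            "w0": lut.w0,
            "rate_upper": lut.rate_upper,
            "rate_bottom": lut.rate_bottom,
            "L_bottom": lut.L_bottom,
            "offsets": lut.offsets,
        }
        extra = {
            "wavelength": lut.wavelength,
            "props_wavelength": lut.props_wavelength,
            "mua_bottom": lut.mua_bottom,
        }
        kind = "dcs"
    else:
        raise TypeError(f"not a LUT: {type(lut)!r}")
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = LUT_SCHEMA_VERSION
        f.attrs["kind"] = kind
        f.attrs["axes_json"] = json.dumps(lut.axes.to_dict(), sort_keys=True)
        f.attrs["metadata_json"] = json.dumps(lut.metadata, sort_keys=True, default=float)
        f.attrs["extra_json"] = json.dumps(extra, sort_keys=True)
        f.attrs["content_hash"] = _content_hash(arrays, lut.metadata)
        for name, arr in arrays.items():
            f.create_dataset(name, data=arr)


def load_lut(path):
    """Load a LUT saved with :func:`save_lut`, verifying schema and integrity."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != LUT_SCHEMA_VERSION:
            raise ProvenanceError(
                f"LUT schema version {version} does not match {LUT_SCHEMA_VERSION}"
            )
        kind = f.attrs["kind"]
        axes = LUTAxes(**json.loads(f.attrs["axes_json"]))
        metadata = json.loads(f.attrs["metadata_json"])
        extra = json.loads(f.attrs["extra_json"])
        arrays = {name: f[name][...] for name in f.keys()}
        stored_hash = f.attrs["content_hash"]
    if _content_hash(arrays, metadata) != stored_hash:
        raise ProvenanceError("LUT content hash mismatch: file corrupted or tampered")
    if kind == "fd":
        return FDLUT(
            axes=axes,
            wavelength=extra["wavelength"],
            mod_freq_hz=extra["mod_freq_hz"],
            values=arrays["values"],
            values_coarse=arrays["values_coarse"],
            metadata=metadata,
        )
    return DCSLUT(
        axes=axes,
        wavelength=extra["wavelength"],
        props_wavelength=extra["props_wavelength"],
        mua_bottom=extra["mua_bottom"],
        w0=arrays["w0"],
        rate_upper=arrays["rate_upper"],
        rate_bottom=arrays["rate_bottom"],
        L_bottom=arrays["L_bottom"],
        offsets=arrays["offsets"],
        metadata=metadata,
    )
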