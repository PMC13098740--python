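"""Layered-slab Monte Carlo photon transport with per-layer bookkeeping.

The engine propagates photons through a stack of plane-parallel layers above a
semi-infinite bottom layer and, for every photon that exits the top surface into
an annular detector, records the per-layer pathlength ``L`` (mm) and the per-layer
dimensionless momentum transfer ``Y = sum(1 - cos(theta))`` over the scattering
events in that layer.  Those two quantities are sufficient to form every forward
observable downstream: Beer-Lambert absorption weights for any per-layer mua
(white Monte Carlo), photon time of flight ``t = sum_j n_j L_j / c`` for
frequency-domain reflectance, and the field-autocorrelation decay for DCS.

By default *no* absorption is baked into propagation (all layers white): scattering
paths are independent of mua, so a single simulation serves the entire mua axis by
post-hoc reweighting.  ``bake_absorption=True`` applies per-layer mua continuously
along the path instead, which is used to verify the equivalence of the two routes.

Geometry: z increases downward from the surface; the source is a pencil beam at
the origin aimed into the tissue; the detector is an annulus of radius ``sds`` and
half-width ``detector_half_width`` centred on the source.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from numba import njit

from .media import LayeredMedium

__all__ = ["SimConfig", "PhotonBatch", "run_layered_mc", "fresnel_reflectance", "pool_batches"]

#: Speed of light in vacuum, mm/ns.
C_MM_PER_NS = 299.792458


@dataclass(frozen=True)
class SimConfig:
    """Simulation controls: photon budget, detector geometry, termination."""

    n_photons: int = 1_000_000
    sds: float = 25.0
    detector_half_width: float = 0.5
    seed: int = 0
    max_total_path: float = 3000.0
    max_depth: float = 150.0
    max_radius: float = math.inf
    radius_center: float | None = None
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    phase_mode: str = "hg"

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if self.sds <= 0 or self.detector_half_width <= 0:
            raise ValueError("sds and detector_half_width must be positive")
        if self.max_total_path <= self.sds:
            raise ValueError("max_total_path must exceed sds")
        if self.max_depth <= 0:
            raise ValueError("max_depth must be positive")
        if self.max_radius <= 0:
            raise ValueError("max_radius must be positive")
        if not 0 < self.roulette_survival <= 1:
            raise ValueError("roulette_survival must be in (0, 1]")
        if self.phase_mode not in ("hg", "reduced"):
            raise ValueError("phase_mode must be 'hg' or 'reduced'")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    @property
    def detector_area(self) -> float:
        """Area of the detection annulus, mm^2."""
        r_in = max(self.sds - self.detector_half_width, 0.0)
        r_out = self.sds + self.detector_half_width
        return math.pi * (r_out**2 - r_in**2)


@dataclass
class PhotonBatch:
    """Per-detected-photon bookkeeping from one (or several pooled) MC runs."""

    L: np.ndarray  # (n_detected, n_layers) per-layer pathlength, mm
    Y: np.ndarray  # (n_detected, n_layers) per-layer momentum transfer
    exit_weight: np.ndarray  # (n_detected,) survival weight at exit
    detector_r: np.ndarray  # (n_detected,) exit radius, mm
    n_launched: int
    layer_n: np.ndarray  # (n_layers,) refractive indices
    sds: float
    detector_half_width: float
    wavelength: float
    seed: int
    accounting: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_detected(self) -> int:
        return self.L.shape[0]

    @property
    def n_layers(self) -> int:
        return self.L.shape[1]

    @property
    def detector_area(self) -> float:
        r_in = max(self.sds - self.detector_half_width, 0.0)
        r_out = self.sds + self.detector_half_width
        return math.pi * (r_out**2 - r_in**2)

    def time_of_flight_ns(self) -> np.ndarray:
        """Per-photon time of flight t = sum_j n_j L_j / c, in ns."""
        return (self.L @ self.layer_n) / C_MM_PER_NS

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("L", data=self.L)
            f.create_dataset("Y", data=self.Y)
            f.create_dataset("exit_weight", data=self.exit_weight)
            f.create_dataset("detector_r", data=self.detector_r)
            f.create_dataset("layer_n", data=self.layer_n)
            f.attrs["n_launched"] = self.n_launched
            f.attrs["sds"] = self.sds
            f.attrs["detector_half_width"] = self.detector_half_width
            f.attrs["wavelength"] = self.wavelength
            f.attrs["seed"] = self.seed
            for k, v in self.accounting.items():
                f.attrs[f"acct_{k}"] = v

    @classmethod
    def from_hdf5(cls, path) -> "PhotonBatch":
        with h5py.File(path, "r") as f:
            acct = {k[5:]: float(v) for k, v in f.attrs.items() if k.startswith("acct_")}
            return cls(
                L=f["L"][...],
                Y=f["Y"][...],
                exit_weight=f["exit_weight"][...],
                detector_r=f["detector_r"][...],
                n_launched=int(f.attrs["n_launched"]),
                layer_n=f["layer_n"][...],
                sds=float(f.attrs["sds"]),
                detector_half_width=float(f.attrs["detector_half_width"]),
                wavelength=float(f.attrs["wavelength"]),
                seed=int(f.attrs["seed"]),
                accounting=acct,
            )


def pool_batches(batches: list[PhotonBatch]) -> PhotonBatch:
    """Concatenate independent-seed batches of the same configuration."""
    if not batches:
        raise ValueError("no batches to pool")
    b0 = batches[0]
    for b in batches[1:]:
        if b.n_layers != b0.n_layers or b.sds != b0.sds or b.wavelength != b0.wavelength:
            raise ValueError("batches are not configuration-compatible")
    acct: dict[str, float] = {}
    for b in batches:
        for k, v in b.accounting.items():
            acct[k] = acct.get(k, 0.0) + v
    return PhotonBatch(
        L=np.concatenate([b.L for b in batches]),
        Y=np.concatenate([b.Y for b in batches]),
        exit_weight=np.concatenate([b.exit_weight for b in batches]),
        detector_r=np.concatenate([b.detector_r for b in batches]),
        n_launched=sum(b.n_launched for b in batches),
        layer_n=b0.layer_n,
        sds=b0.sds,
        detector_half_width=b0.detector_half_width,
        wavelength=b0.wavelength,
        seed=b0.seed,
        accounting=acct,
        meta=dict(b0.meta),
    )


def fresnel_reflectance(n1: float, n2: float, cos_incident: float) -> float:
    """Unpolarized Fresnel reflection probability at a planar index step.

    ``cos_incident`` is the magnitude of the direction cosine against the
    interface normal, in (0, 1].  Returns 1 beyond the critical angle.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    if not 0 < cos_incident <= 1:
        raise ValueError("cos_incident must be in (0, 1]")
    return _fresnel(n1, n2, cos_incident)


@njit(cache=True)
def _fresnel(n1, n2, cosi):
    if n1 == n2:
        return 0.0
    sini = math.sqrt(max(0.0, 1.0 - cosi * cosi))
    sint = sini * n1 / n2
    if sint >= 1.0:
        return 1.0
    cost = math.sqrt(1.0 - sint * sint)
    rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
    rp = (n1 * cost - n2 * cosi) / (n1 * cost + n2 * cosi)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def _rng_next(state):
    """xorshift64* step; returns (u01, new_state) with u01 in (0, 1)."""
    x = state
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x &= np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    u = ((x * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)) & np.uint64(0x1FFFFFFFFFFFFF)
    return (float(u) + 0.5) * (1.0 / 9007199254740992.0), x


@njit(cache=True)
def _rng_seed(seed):
    """splitmix64 scrambling of a small integer seed into an xorshift64* state."""
    z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = np.uint64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True, fastmath=True)
def _mc_kernel(
    z_bot,
    mus,
    g,
    nidx,
    mua_baked,
    n_ambient,
    sds,
    half_width,
    max_path,
    max_depth,
    max_radius,
    radius_cx,
    r_thresh,
    r_surv,
    n_photons,
    seed,
    out_L,
    out_Y,
    out_w,
    out_r,
    acct,
):
    """Transport kernel.  Returns total number of detector hits (may exceed the
    capacity of the output buffers; the wrapper re-runs with a larger buffer).

    acct layout: [0] specular, [1] escaped top (all radii, incl. detected),
    [2] absorbed (baked), [3] path/depth-cap killed, [4] roulette net (killed - gained).
    """
    rng = _rng_seed(seed)
    n_layers = z_bot.shape[0]
    cap = out_w.shape[0]
    r_min = sds - half_width
    r_max = sds + half_width

    Lbuf = np.zeros(n_layers)
    Ybuf = np.zeros(n_layers)

    # specular reflection at normal incidence on the top surface
    rsp = _fresnel(n_ambient, nidx[0], 1.0)

    n_hits = 0
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        w = 1.0 - rsp
        acct[0] += rsp
        for j in range(n_layers):
            Lbuf[j] = 0.0
            Ybuf[j] = 0.0
        total_path = 0.0
        s_left = 0.0
        alive = True

        while alive:
            if s_left <= 0.0:
                u, rng = _rng_next(rng)
                s_left = -math.log(u)
            mut = mus[layer] + mua_baked[layer]
            if mut > 0.0:
                step = s_left / mut
            else:
                step = 1.0e30

            # distance to the layer boundary along the current direction
            if uz > 0.0:
                db = (z_bot[layer] - z) / uz
            elif uz < 0.0:
                z_top = 0.0 if layer == 0 else z_bot[layer - 1]
                db = (z_top - z) / uz
            else:
                db = 1.0e30

            if step < db:
                seg = step
                hit_boundary = False
            else:
                seg = db
                hit_boundary = True

            x += ux * seg
            y += uy * seg
            z += uz * seg
            Lbuf[layer] += seg
            total_path += seg
            if mua_baked[layer] > 0.0:
                w_new = w * math.exp(-mua_baked[layer] * seg)
                acct[2] += w - w_new
                w = w_new

            if total_path >= max_path or z >= max_depth:
                acct[3] += w
                alive = False
                break
            if max_radius < 1.0e29:
                dx = x - radius_cx
                if dx * dx + y * y > max_radius * max_radius:
                    # absorbing lateral boundary (finite slab / simulation volume)
                    acct[3] += w
                    alive = False
                    break

            if not hit_boundary:
                s_left = 0.0
                # Henyey-Greenstein scatter; accumulate momentum transfer here
                gg = g[layer]
                u, rng = _rng_next(rng)
                if gg < 1.0e-6:
                    cost = 2.0 * u - 1.0
                else:
                    tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * u)
                    cost = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                    if cost > 1.0:
                        cost = 1.0
                    elif cost < -1.0:
                        cost = -1.0
                Ybuf[layer] += 1.0 - cost
                sint = math.sqrt(max(0.0, 1.0 - cost * cost))
                u, rng = _rng_next(rng)
                phi = 2.0 * math.pi * u
                cosp = math.cos(phi)
                sinp = math.sin(phi)
                if abs(uz) > 0.99999:
                    ux = sint * cosp
                    uy = sint * sinp
                    uz = cost if uz > 0.0 else -cost
                else:
                    tmp2 = math.sqrt(1.0 - uz * uz)
                    uxn = sint * (ux * uz * cosp - uy * sinp) / tmp2 + ux * cost
                    uyn = sint * (uy * uz * cosp + ux * sinp) / tmp2 + uy * cost
                    uzn = -sint * cosp * tmp2 + uz * cost
                    ux = uxn
                    uy = uyn
                    uz = uzn
            else:
                s_left -= seg * mut
                if s_left < 0.0:
                    s_left = 0.0
                going_down = uz > 0.0
                if going_down:
                    n1 = nidx[layer]
                    n2 = nidx[layer + 1]  # bottom layer is semi-infinite: never exits below
                else:
                    n1 = nidx[layer]
                    n2 = n_ambient if layer == 0 else nidx[layer - 1]
                if n1 == n2:
                    # index-matched: cross with no RNG draw (keeps streams
                    # identical under layer splitting)
                    if going_down:
                        layer += 1
                    elif layer == 0:
                        # exits into the ambient medium
                        acct[1] += w
                        r = math.sqrt(x * x + y * y)
                        if r_min <= r <= r_max:
                            if n_hits < cap:
                                for j in range(n_layers):
                                    out_L[n_hits, j] = Lbuf[j]
                                    out_Y[n_hits, j] = Ybuf[j]
                                out_w[n_hits] = w
                                out_r[n_hits] = r
                            n_hits += 1
                        alive = False
                    else:
                        layer -= 1
                else:
                    cosi = abs(uz)
                    refl = _fresnel(n1, n2, cosi)
                    u, rng = _rng_next(rng)
                    if u < refl:
                        uz = -uz
                    else:
                        # refract (Snell): tangential components scale by n1/n2
                        ratio = n1 / n2
                        sint2 = (1.0 - cosi * cosi) * ratio * ratio
                        cost2 = math.sqrt(max(0.0, 1.0 - sint2))
                        ux *= ratio
                        uy *= ratio
                        uz = cost2 if uz > 0.0 else -cost2
                        if going_down:
                            layer += 1
                        elif layer == 0:
                            acct[1] += w
                            r = math.sqrt(x * x + y * y)
                            if r_min <= r <= r_max:
                                if n_hits < cap:
                                    for j in range(n_layers):
                                        out_L[n_hits, j] = Lbuf[j]
                                        out_Y[n_hits, j] = Ybuf[j]
                                    out_w[n_hits] = w
                                    out_r[n_hits] = r
                                n_hits += 1
                            alive = False
                        else:
                            layer -= 1

            if alive and w < r_thresh:
                u, rng = _rng_next(rng)
                if u < r_surv:
                    gained = w * (1.0 / r_surv - 1.0)
                    acct[4] -= gained
                    w /= r_surv
                else:
                    acct[4] += w
                    alive = False

    return n_hits


def run_layered_mc(
    medium: LayeredMedium,
    sim: SimConfig,
    wavelength: float,
    bake_absorption: bool = False,
) -> PhotonBatch:
    """Run the layered Monte Carlo at one wavelength and collect detected photons.

    With ``bake_absorption=False`` (the default, white Monte Carlo) every layer is
    propagated absorption-free and ``exit_weight`` reflects only surface/boundary
    losses; absorption for *any* per-layer mua is applied afterwards with
    :func:`layerlut.forward.absorption_weights`.  With ``bake_absorption=True``
    the medium's tabulated mua at ``wavelength`` attenuates the weight continuously
    along the path (used for equivalence checks).
    """
    thick, mua, musp, g, n, _bfi = medium.property_arrays(wavelength)
    n_layers = len(thick)
    z_bot = np.cumsum(np.asarray(thick, dtype=np.float64))
    z_bot[-1] = 1.0e30  # semi-infinite bottom
    g_arr = np.asarray(g, dtype=np.float64)
    musp_arr = np.asarray(musp, dtype=np.float64)
    if sim.phase_mode == "reduced":
        # similarity relation: isotropic scattering at mus = musp preserves the
        # diffuse reflectance and the expected momentum transfer per unit path
        # (musp * L); an order of magnitude fewer scattering events per photon
        g_arr = np.zeros(n_layers)
        mus_arr = musp_arr.copy()
    else:
        mus_arr = musp_arr / (1.0 - g_arr)
    n_arr = np.asarray(n, dtype=np.float64)
    mua_baked = np.asarray(mua, dtype=np.float64) if bake_absorption else np.zeros(n_layers)

    seed = int(sim.seed) % (2**31 - 1)
    cap = max(4096, sim.n_photons // 20)
    while True:
        out_L = np.empty((cap, n_layers))
        out_Y = np.empty((cap, n_layers))
        out_w = np.empty(cap)
        out_r = np.empty(cap)
        acct = np.zeros(5)
        n_hits = _mc_kernel(
            z_bot,
            mus_arr,
            g_arr,
            n_arr,
            mua_baked,
            float(medium.ambient_n),
            float(sim.sds),
            float(sim.detector_half_width),
            float(sim.max_total_path),
            float(sim.max_depth),
            float(sim.max_radius) if math.isfinite(sim.max_radius) else 1.0e30,
            float(sim.radius_center if sim.radius_center is not None else sim.sds / 2.0),
            float(sim.roulette_threshold),
            float(sim.roulette_survival),
            int(sim.n_photons),
            seed,
            out_L,
            out_Y,
            out_w,
            out_r,
            acct,
        )
        if n_hits <= cap:
            break
        cap = int(n_hits * 1.2) + 16  # rare: buffer too small, re-run same seed

    if n_hits == 0:
        warnings.warn(
            f"no photons detected after {sim.n_photons} launches "
            f"(sds={sim.sds} mm); returning an empty batch",
            stacklevel=2,
        )

    accounting = {
        "launched_weight": float(sim.n_photons),
        "specular": float(acct[0]),
        "escaped_top": float(acct[1]),
        "absorbed": float(acct[2]),
        "path_capped": float(acct[3]),
        "roulette_net": float(acct[4]),
        "n_detected": float(n_hits),
    }
    return PhotonBatch(
        L=out_L[:n_hits].copy(),
        Y=out_Y[:n_hits].copy(),
        exit_weight=out_w[:n_hits].copy(),
        detector_r=out_r[:n_hits].copy(),
        n_launched=sim.n_photons,
        layer_n=n_arr,
        sds=sim.sds,
        detector_half_width=sim.detector_half_width,
        wavelength=float(wavelength),
        seed=seed,
        accounting=accounting,
        meta=dict(medium.meta),
    )
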