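"""Synthetic measurement generators: phantom-stack sweeps and breathing series.

Everything here is a pure function of (configuration, seed), so every pipeline
stage is testable without an instrument.  Two kinds of fixtures are produced:

* :func:`gen_phantom_dataset` — in-silico analogues of stacked-phantom
  measurements: for each (skin-tone mimic, adipose thickness) stack, layered-MC
  FD reflectance at 730/830 nm and, for the liquid-bottom stack, a g2 curve at
  coherence factor beta = 0.45.  Ground truth is embedded in each record.

* :func:`gen_breathing_timeseries` — an in-vivo-like time series at 0.5 Hz:
  baseline / respiratory-load / recovery, with muscle chromophore and BFi
  trajectories (smoothed-trapezoid load response, 10 s ramps) forward-modelled
  through the subject's multi-layer LUTs, plus seeded instrument noise
  (multiplicative on FD amplitude, additive on phase, additive heteroscedastic
  on g2 with a variance that shrinks at long delays where correlator bins
  average more samples).

The noise defaults are phenomenological choices (1% amplitude, 2 mrad phase,
1e-3 g2), not instrument-derived; amplitude/phase noise is taken independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forward import FDReflectance, G2Curve, fd_from_batch, g1_from_batch, siegert
from .hemodynamics import (
    ChromophoreSet,
    MRO2Params,
    chromophores_to_mua,
    compute_mro2,
    compute_sto2,
    hgb_for_sex,
)
from .invert import MeasurementFrame
from .lut import DCSLUT, FDLUT, node_seeds
from .mc import SimConfig, pool_batches, run_layered_mc
from .media import phantom_medium

__all__ = [
    "PhantomSweepConfig",
    "PhantomRecord",
    "gen_phantom_dataset",
    "BreathingProtocol",
    "Subject",
    "BreathingDataset",
    "gen_breathing_timeseries",
    "TimeSeriesSummary",
    "summarize_timeseries",
]

FD_BANDS = ((730.0, 139e6), (830.0, 149e6))


@dataclass(frozen=True)
class PhantomSweepConfig:
    tones: tuple[str, ...] = ("light", "medium", "dark")
    adipose_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    bottom: str = "silicone_muscle"
    beta: float = 0.45
    bands: tuple[tuple[float, float], ...] = FD_BANDS
    n_repeats: int = 4
    amp_noise_frac: float = 0.0
    phase_noise_rad: float = 0.0
    g2_noise_sd: float = 0.0


@dataclass
class PhantomRecord:
    tone: str
    adipose_mm: float
    bottom: str
    fd: dict[float, FDReflectance]
    g2: G2Curve | None
    truth: dict


@dataclass
class PhantomDataset:
    config: PhantomSweepConfig
    seed: int
    records: list[PhantomRecord]


def gen_phantom_dataset(
    config: PhantomSweepConfig,
    sim: SimConfig,
    seed: int = 0,
    tau_s: np.ndarray | None = None,
) -> PhantomDataset:
    """Simulate FD (and, for a liquid bottom, DCS) measurements of phantom stacks."""
    rng = np.random.default_rng(seed)
    if tau_s is None:
        tau_s = np.logspace(-7, -2, 64)
    records: list[PhantomRecord] = []
    for ti, tone in enumerate(config.tones):
        for ai, adipose in enumerate(config.adipose_mm):
            medium = phantom_medium(tone, adipose, config.bottom)
            bottom = medium.layers[-1]
            fd: dict[float, FDReflectance] = {}
            g2 = None
            for bi, (wl, freq) in enumerate(config.bands):
                seeds = node_seeds(seed + 1000 * ti + 10 * ai + bi, 0, config.n_repeats)
                batch = pool_batches(
                    [run_layered_mc(medium, sim.with_(seed=s), wl) for s in seeds]
                )
                _, mua_vec, _, _, _, bfi_vec = medium.property_arrays(wl)
                meas = fd_from_batch(batch, np.array(mua_vec), freq)
                amp = meas.amplitude * (1.0 + config.amp_noise_frac * rng.standard_normal())
                phase = meas.phase_rad + config.phase_noise_rad * rng.standard_normal()
                fd[wl] = FDReflectance(wl, freq, meas.sds, max(amp, 0.0), phase)
                if wl == 830.0 and bottom.bfi > 0:
                    g1 = g1_from_batch(batch, np.array(mua_vec), np.array(bfi_vec), tau_s, 850.0)
                    g2v = siegert(g1, config.beta).values
                    if config.g2_noise_sd > 0:
                        g2v = g2v + _g2_noise_sigma(tau_s, config.g2_noise_sd) * rng.standard_normal(tau_s.size)
                    g2 = G2Curve(tau_s, g2v, config.beta)
            records.append(
                PhantomRecord(
                    tone=tone,
                    adipose_mm=adipose,
                    bottom=config.bottom,
                    fd=fd,
                    g2=g2,
                    truth={
                        "mua": dict(bottom.mua),
                        "musp": dict(bottom.musp),
                        "bfi": bottom.bfi,
                    },
                )
            )
    return PhantomDataset(config=config, seed=seed, records=records)


def _g2_noise_sigma(tau_s: np.ndarray, sd: float, tau_ref: float = 1e-5) -> np.ndarray:
    """Heteroscedastic g2 noise: larger at short delays, shrinking ~ tau^-1/4."""
    return sd * np.clip((tau_ref / np.asarray(tau_s)) ** 0.25, 0.2, 5.0)


@dataclass(frozen=True)
class BreathingProtocol:
    """Baseline / load / recovery protocol and its synthetic perturbations."""

    baseline_s: float = 60.0
    load_s: float = 60.0
    recovery_s: float = 60.0
    sampling_hz: float = 0.5
    ramp_s: float = 10.0
    oxy_delta_um: float = -15.0
    deoxy_delta_um: float = 10.0
    bfi_delta_frac: float = 0.6
    amp_noise_frac: float = 0.01
    phase_noise_rad: float = 0.002
    g2_noise_sd: float = 1e-3
    beta: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.load_s, self.recovery_s) <= 0:
            raise ValueError("durations must be positive")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.load_s + self.recovery_s

    @property
    def times_s(self) -> np.ndarray:
        n = int(round(self.total_s * self.sampling_hz))
        return np.arange(n) / self.sampling_hz

    @property
    def load_window(self) -> tuple[float, float]:
        return self.baseline_s, self.baseline_s + self.load_s

    def load_shape(self, t: np.ndarray) -> np.ndarray:
        """Smoothed trapezoid: 0 at baseline, 1 on the load plateau, cosine ramps."""
        t = np.asarray(t, dtype=float)
        t0, t1 = self.load_window
        r = max(self.ramp_s, 1e-9)
        up = np.clip((t - t0) / r, 0.0, 1.0)
        down = np.clip((t - t1) / r, 0.0, 1.0)
        smooth = lambda x: 0.5 * (1.0 - np.cos(np.pi * x))
        return smooth(up) - smooth(down)


@dataclass(frozen=True)
class Subject:
    skin_tone: str
    adipose_mm: float
    sex: str = "male"
    ita_deg: float | None = None

    @property
    def hgb_g_per_dl(self) -> float:
        return hgb_for_sex(self.sex)


@dataclass
class BreathingDataset:
    frames: list[MeasurementFrame]
    truth: pd.DataFrame
    protocol: BreathingProtocol
    subject: Subject


def gen_breathing_timeseries(
    protocol: BreathingProtocol,
    subject: Subject,
    fd_luts: dict[float, FDLUT],
    dcs_lut: DCSLUT | None = None,
    baseline_chromophores: ChromophoreSet | None = None,
    musp: tuple[float, float] = (0.65, 0.60),
    baseline_bfi: float = 5.0e-6,
) -> BreathingDataset:
    """Generate a framed synthetic breathing dataset for one subject.

    Muscle chromophore and BFi trajectories are composed from the protocol's
    load shape, converted per frame to (mua730, mua830, BFi), forward-modelled
    through the supplied multi-layer LUTs (which must match the subject's skin
    tone and adipose thickness) and corrupted with seeded noise.  The
    generating truth (concentrations, optical properties, StO2, MRO2) is
    embedded in ``truth``.
    """
    base = baseline_chromophores or ChromophoreSet(oxy=65.0, deoxy=30.0)
    rng = np.random.default_rng(protocol.seed)
    times = protocol.times_s
    shape = protocol.load_shape(times)
    mro2_params = MRO2Params(hgb_g_per_dl=subject.hgb_g_per_dl)
    frames: list[MeasurementFrame] = []
    rows = []
    for t, s in zip(times, shape):
        chrom = replace(
            base,
            oxy=base.oxy + protocol.oxy_delta_um * s,
            deoxy=base.deoxy + protocol.deoxy_delta_um * s,
        )
        mua730, mua830 = chromophores_to_mua(chrom)
        bfi = baseline_bfi * (1.0 + protocol.bfi_delta_frac * s)
        fd: dict[float, FDReflectance] = {}
        for wl, mua_wl, musp_wl in ((730.0, mua730, musp[0]), (830.0, mua830, musp[1])):
            lut = fd_luts[wl]
            c = lut.query(mua_wl, musp_wl)
            amp = abs(c) * (1.0 + protocol.amp_noise_frac * rng.standard_normal())
            phase = -np.angle(c) + protocol.phase_noise_rad * rng.standard_normal()
            fd[wl] = FDReflectance(wl, lut.mod_freq_hz, lut.metadata["sds_mm"], max(amp, 0.0), float(phase))
        g2 = None
        if dcs_lut is not None:
            tau = dcs_lut.tau_grid
            g2v = dcs_lut.g2(musp[1], bfi, protocol.beta, mua=mua830)
            g2v = g2v + _g2_noise_sigma(tau, protocol.g2_noise_sd) * rng.standard_normal(tau.size)
            g2 = G2Curve(tau, g2v, protocol.beta)
        frames.append(MeasurementFrame(time_s=float(t), fd=fd, g2=g2))
        sto2 = compute_sto2(chrom.oxy, chrom.total)
        rows.append(
            {
                "time_s": float(t),
                "oxy_um": chrom.oxy,
                "deoxy_um": chrom.deoxy,
                "total_um": chrom.total,
                "sto2_pct": sto2,
                "bfi": bfi,
                "mua730": mua730,
                "mua830": mua830,
                "musp730": musp[0],
                "musp830": musp[1],
                "mro2": compute_mro2(mro2_params, bfi, sto2),
            }
        )
    return BreathingDataset(
        frames=frames, truth=pd.DataFrame(rows), protocol=protocol, subject=subject
    )


@dataclass(frozen=True)
class TimeSeriesSummary:
    baseline: float
    perturbation_magnitude: float


def summarize_timeseries(
    times_s: np.ndarray,
    values: np.ndarray,
    protocol: BreathingProtocol,
    baseline_window_s: float = 50.0,
    load_windows: list[tuple[float, float]] | None = None,
) -> TimeSeriesSummary:
    """Baseline (mean of the first 50 s) and load-phase perturbation magnitude.

    The perturbation magnitude is the largest absolute deviation from the
    baseline over the load window(s); with several windows (e.g. low and high
    load) the overall largest is reported.
    """
    times = np.asarray(times_s, dtype=float)
    vals = np.asarray(values, dtype=float)
    if times.size != vals.size:
        raise ValueError("times and values must have equal length")
    if times.size == 0 or times.max() < baseline_window_s:
        raise ValueError(f"series must cover at least {baseline_window_s} s of baseline")
    baseline = float(vals[times < baseline_window_s].mean())
    windows = load_windows if load_windows is not None else [protocol.load_window]
    dev = 0.0
    for lo, hi in windows:
        mask = (times >= lo) & (times <= hi)
        if mask.any():
            dev = max(dev, float(np.abs(vals[mask] - baseline).max()))
    return TimeSeriesSummary(baseline=baseline, perturbation_magnitude=dev)
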