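"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (flash counting, mechanics,
spectroscopy, depletion fitting, sensor decoding) is exercised on data
produced here, so each generator returns the ground truth alongside the
dataset and is bit-reproducible given a seed.

The generators emulate the three experimental record kinds of the study:

* dark-room RGB video of compressed dinoflagellate-laden gels, where each
  stimulated cell appears as an unresolved blue Gaussian blob whose
  intensity follows a stretched-exponential (Kohlrausch) flash decay;
* texture-analyser compression records (time, displacement, force) sampled
  at 200 points/s, with the machine's finite acceleration limiting the
  effective strain rate and a single Maxwell branch providing hysteresis;
* single-colony emission-spectrometer time series: photon counts per
  energy bin per 125 ms integration window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    DecayFit,
    DepletionParams,
    DetectorModel,
    ForceRecord,
    FrameStack,
    PeakModel,
    PillarSensor,
    SpectralSeries,
)
from .depletion import simulate_cycles

__all__ = [
    "SyntheticVideoConfig",
    "MachineModel",
    "GroundTruth",
    "gen_flash_stack",
    "gen_force_record",
    "gen_spectral_series",
    "gen_cycle_counts",
    "gen_sensor_trial",
]

MECH_SAMPLING_HZ = 200.0  # texture-analyser recording rate, points/s


@dataclass
class SyntheticVideoConfig:
    """Configuration of a synthetic flash video.

    Cells are isotropic 2-D Gaussian blobs in the blue channel; red and
    green carry only background. After its onset a cell's amplitude follows
    ``I0 * exp[-((t - t_on)/tau)^alpha]``. Defaults marked ``arbitrary``
    in the config snapshot are fixture values; fps and flash kinetics
    defaults reflect the imaging setup (25-30 fps consumer camera) and the
    measured single-colony decay (tau = 238 ms, alpha = 0.85).
    """

    frame_count: int = 60
    fps: float = 30.0
    height: int = 120
    width: int = 120
    cell_count: int = 5
    cell_sigma_px: float = 2.0
    flash_amplitude: float | Sequence[float] = 200.0
    onset_times: Optional[Sequence[float]] = None   # s; None -> random in clip
    cell_positions: Optional[Sequence[tuple]] = None  # (row, col); None -> random
    decay_tau_ms: float = 238.0
    decay_alpha: float = 0.85
    background_mean: float = 8.0
    background_sd: float = 3.0
    reflection_artifacts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        amps = np.atleast_1d(np.asarray(self.flash_amplitude, dtype=float))
        if np.any(amps <= 0) or np.any(amps > 255):
            raise ValueError("flash amplitudes must lie in (0, 255]")
        if not (0 < self.decay_alpha <= 1):
            raise ValueError("decay_alpha must lie in (0, 1]")
        if self.decay_tau_ms <= 0:
            raise ValueError("decay_tau_ms must be positive")
        if self.onset_times is not None:
            t = np.asarray(self.onset_times, dtype=float)
            clip_len = self.frame_count / self.fps
            if np.any(t < 0) or np.any(t >= clip_len):
                raise ValueError("all onset_times must lie within the clip")

    @property
    def clip_seconds(self) -> float:
        return self.frame_count / self.fps


@dataclass
class MachineModel:
    """Mechanical testing machine plus linear-viscoelastic sample model.

    The machine follows a constant-acceleration trapezoidal velocity
    profile, so for short travel the peak ("effective") rate falls below
    the nominal rate: v_peak = min(nominal, sqrt(accel * travel)).
    The sample is a linear spring in parallel with one Maxwell branch
    (stiffness ``maxwell_modulus_kpa``, relaxation time
    ``maxwell_relaxation_s``), the simplest model producing the reversible
    hysteresis loops seen in agar gels.
    """

    nominal_rate: float = 2.5         # mm/s
    max_acceleration: float = 200.0   # mm/s^2
    travel: float = 6.0               # mm
    sample_height: float = 12.0       # mm
    sample_diameter: float = 10.0     # mm
    gel_modulus: float = 22.0         # kPa
    maxwell_relaxation_s: float = 2.0
    maxwell_modulus_kpa: Optional[float] = None  # default 0.25 * gel_modulus

    def __post_init__(self) -> None:
        for name in ("nominal_rate", "max_acceleration", "travel",
                     "sample_height", "sample_diameter", "gel_modulus",
                     "maxwell_relaxation_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.maxwell_modulus_kpa is None:
            self.maxwell_modulus_kpa = 0.25 * self.gel_modulus

    @property
    def sample_area_mm2(self) -> float:
        return math.pi * (self.sample_diameter / 2.0) ** 2

    def peak_velocity(self, distance: float) -> float:
        """Peak velocity of the trapezoidal profile over ``distance`` mm."""
        return min(self.nominal_rate,
                   math.sqrt(self.max_acceleration * distance))


@dataclass
class GroundTruth:
    """Ground truth emitted alongside each synthetic dataset."""

    cell_positions: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    onset_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_cycle_photons: np.ndarray = field(default_factory=lambda: np.empty(0))
    pool_initial: float = 0.0
    pillar_onset_displacements: np.ndarray = field(default_factory=lambda: np.empty(0))
    pillar_actuated: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    peak_velocity_mm_s: float = float("nan")
    decay_tau_ms: float = float("nan")
    decay_alpha: float = float("nan")


def _kohlrausch(t: np.ndarray, tau_s: float, alpha: float) -> np.ndarray:
    """Stretched-exponential kernel exp[-(t/tau)^alpha], zero for t < 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = np.exp(-((t[pos] / tau_s) ** alpha))
    return out


def _circular_mask(height: int, width: int, radius_frac: float = 0.45) -> np.ndarray:
    rr, cc = np.mgrid[0:height, 0:width]
    r0, c0 = (height - 1) / 2.0, (width - 1) / 2.0
    radius = radius_frac * min(height, width)
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2


def _sample_positions(rng: np.random.Generator, mask: np.ndarray, n: int,
                      min_dist: float, margin: float) -> np.ndarray:
    """Rejection-sample ``n`` blob centres inside the mask, pairwise >= min_dist apart."""
    h, w = mask.shape
    positions: list[tuple[float, float]] = []
    attempts = 0
    while len(positions) < n:
        attempts += 1
        if attempts > 20000:
            raise ValueError(
                f"could not place {n} cells >= {min_dist:.1f} px apart; "
                "reduce cell_count or cell_sigma_px"
            )
        r = rng.uniform(margin, h - 1 - margin)
        c = rng.uniform(margin, w - 1 - margin)
        if not mask[int(round(r)), int(round(c))]:
            continue
        if all((r - p[0]) ** 2 + (c - p[1]) ** 2 >= min_dist ** 2
               for p in positions):
            positions.append((r, c))
    return np.asarray(positions)


def _render_blobs(frame: np.ndarray, positions: np.ndarray,
                  amplitudes: np.ndarray, sigma: float) -> None:
    """Add Gaussian blobs in place, truncated at the 4-sigma footprint."""
    h, w = frame.shape
    ext = int(math.ceil(4 * sigma))
    for (r0, c0), amp in zip(positions, amplitudes):
        if amp <= 0:
            continue
        rlo, rhi = max(0, int(r0) - ext), min(h, int(r0) + ext + 1)
        clo, chi = max(0, int(c0) - ext), min(w, int(c0) + ext + 1)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        blob = amp * np.exp(-d2 / (2 * sigma ** 2))
        blob[d2 > (4 * sigma) ** 2] = 0.0
        frame[rlo:rhi, clo:chi] += blob


def gen_flash_stack(config: SyntheticVideoConfig) -> tuple[FrameStack, GroundTruth]:
    """Generate a dark-room flash video with known cell positions and onsets.

    Returns the RGB stack (blue channel carries the flashes, all channels
    carry clipped Gaussian background noise) and the ground truth. Blob
    centres are guaranteed pairwise >= 4 * cell_sigma_px apart so that the
    blobs present separable maxima; explicitly supplied positions violating
    this are rejected.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mask = _circular_mask(cfg.height, cfg.width)
    min_dist = 4.0 * cfg.cell_sigma_px
    margin = 4.0 * cfg.cell_sigma_px + 1

    if cfg.cell_count == 0:
        positions = np.empty((0, 2))
    elif cfg.cell_positions is not None:
        positions = np.asarray(cfg.cell_positions, dtype=float)
        if len(positions) != cfg.cell_count:
            raise ValueError("cell_positions length must equal cell_count")
        for i in range(len(positions)):
            for j in range(i + 1, len(positions)):
                if np.hypot(*(positions[i] - positions[j])) < min_dist:
                    raise ValueError(
                        f"cells {i} and {j} closer than 4*cell_sigma_px"
                    )
    else:
        positions = _sample_positions(rng, mask, cfg.cell_count, min_dist, margin)

    if cfg.cell_count == 0:
        onsets = np.empty(0)
    elif cfg.onset_times is not None:
        onsets = np.asarray(cfg.onset_times, dtype=float)
        if len(onsets) != cfg.cell_count:
            raise ValueError("onset_times length must equal cell_count")
    else:
        onsets = rng.uniform(0.0, 0.6 * cfg.clip_seconds, size=cfg.cell_count)

    amps = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.flash_amplitude, dtype=float)),
        (cfg.cell_count,),
    ).copy()

    tau_s = cfg.decay_tau_ms / 1000.0
    times = np.arange(cfg.frame_count) / cfg.fps
    frames = np.empty((cfg.frame_count, cfg.height, cfg.width, 3), dtype=np.uint8)

    if cfg.reflection_artifacts:
        outside = np.argwhere(~mask)
        n_art = min(12, len(outside))
        art_idx = outside[rng.choice(len(outside), size=n_art, replace=False)]
    else:
        art_idx = np.empty((0, 2), dtype=int)

    for k, t in enumerate(times):
        noise = rng.normal(cfg.background_mean, cfg.background_sd,
                           size=(cfg.height, cfg.width, 3))
        blue = noise[:, :, 2].copy()
        inst = amps * _kohlrausch(t - onsets, tau_s, cfg.decay_alpha)
        if len(positions):
            _render_blobs(blue, positions, inst, cfg.cell_sigma_px)
        if len(art_idx):
            blue[art_idx[:, 0], art_idx[:, 1]] = 220.0
        noise[:, :, 2] = blue
        frames[k] = np.clip(noise, 0, 255).astype(np.uint8)

    truth = GroundTruth(
        cell_positions=positions,
        onset_times=onsets,
        amplitudes=amps,
        decay_tau_ms=cfg.decay_tau_ms,
        decay_alpha=cfg.decay_alpha,
    )
    return FrameStack(frames=frames, timestamps=times, mask=mask), truth


def _trapezoid_position(t: np.ndarray, distance: float, v_nom: float,
                        accel: float) -> np.ndarray:
    """Position along a one-way constant-acceleration move of ``distance``."""
    v_peak = min(v_nom, math.sqrt(accel * distance))
    t_a = v_peak / accel
    d_a = 0.5 * accel * t_a ** 2
    d_cruise = distance - 2 * d_a
    t_cruise = d_cruise / v_peak if v_peak > 0 else 0.0
    t_total = 2 * t_a + t_cruise

    x = np.empty_like(t)
    ph1 = t < t_a
    ph2 = (t >= t_a) & (t < t_a + t_cruise)
    ph3 = (t >= t_a + t_cruise) & (t < t_total)
    ph4 = t >= t_total
    x[ph1] = 0.5 * accel * t[ph1] ** 2
    x[ph2] = d_a + v_peak * (t[ph2] - t_a)
    td = t[ph3] - (t_a + t_cruise)
    x[ph3] = d_a + d_cruise + v_peak * td - 0.5 * accel * td ** 2
    x[ph4] = distance
    return x


def _move_duration(distance: float, v_nom: float, accel: float) -> float:
    v_peak = min(v_nom, math.sqrt(accel * distance))
    t_a = v_peak / accel
    d_cruise = distance - accel * t_a ** 2
    return 2 * t_a + (d_cruise / v_peak if v_peak > 0 else 0.0)


def machine_displacement(machine: MachineModel, distance: float,
                         t: np.ndarray) -> np.ndarray:
    """Loading-then-return displacement profile sampled at times ``t``."""
    t_move = _move_duration(distance, machine.nominal_rate,
                            machine.max_acceleration)
    load = _trapezoid_position(np.minimum(t, t_move), distance,
                               machine.nominal_rate, machine.max_acceleration)
    back = np.where(
        t > t_move,
        _trapezoid_position(np.clip(t - t_move, 0, None), distance,
                            machine.nominal_rate, machine.max_acceleration),
        0.0,
    )
    return load - back


def _maxwell_stress(strain: np.ndarray, t: np.ndarray, modulus: float,
                    relax_s: float) -> np.ndarray:
    """Stress of a Maxwell branch under the given strain history.

    Exponential integrator for  d(sigma)/dt = E de/dt - sigma/tau_r,
    exact for piecewise-linear strain.
    """
    sigma = np.zeros_like(strain)
    for i in range(1, len(t)):
        dt = t[i] - t[i - 1]
        de = strain[i] - strain[i - 1]
        decay = math.exp(-dt / relax_s)
        # response to a constant strain rate over [t_{i-1}, t_i]
        rate = de / dt
        sigma[i] = sigma[i - 1] * decay + modulus * rate * relax_s * (1 - decay)
    return sigma


def gen_force_record(machine: MachineModel,
                     max_strain: float) -> tuple[ForceRecord, GroundTruth]:
    """Generate a load/unload compression record at 200 points/s.

    Displacement follows the machine's trapezoidal velocity profile up to
    ``max_strain * sample_height`` and back; force comes from the
    spring-plus-Maxwell sample model (engineering stress times initial
    area).
    """
    if not (0 < max_strain <= 0.5):
        raise ValueError("max_strain must lie in (0, 0.5]")
    if machine.travel > machine.sample_height:
        raise ValueError("machine travel exceeds sample height")
    distance = max_strain * machine.sample_height
    if distance > machine.travel:
        raise ValueError("requested compression exceeds machine travel")

    t_move = _move_duration(distance, machine.nominal_rate,
                            machine.max_acceleration)
    t_end = 2 * t_move
    t = np.arange(0.0, t_end + 1.0 / MECH_SAMPLING_HZ, 1.0 / MECH_SAMPLING_HZ)
    x = machine_displacement(machine, distance, t)
    strain = x / machine.sample_height

    stress = machine.gel_modulus * strain + _maxwell_stress(
        strain, t, machine.maxwell_modulus_kpa, machine.maxwell_relaxation_s
    )  # kPa
    force = stress * machine.sample_area_mm2 / 1000.0  # kPa * mm^2 -> N

    record = ForceRecord(
        time=t, displacement=x, force=force,
        sample_height=machine.sample_height,
        sample_diameter=machine.sample_diameter,
    )
    truth = GroundTruth(peak_velocity_mm_s=machine.peak_velocity(distance))
    return record, truth


def _window_kernel_integrals(decay: DecayFit, n_windows: int,
                             integration_ms: float) -> np.ndarray:
    """Integral of the Kohlrausch kernel over each integration window."""
    tau_s = decay.tau_ms / 1000.0
    w_s = integration_ms / 1000.0
    out = np.empty(n_windows)
    fine = np.linspace(0.0, w_s, 33)
    for i in range(n_windows):
        vals = _kohlrausch(i * w_s + fine, tau_s, decay.alpha)
        out[i] = np.trapezoid(vals, fine)
    return out


def gen_spectral_series(peaks: PeakModel, decay: DecayFit, total_photons: float,
                        integration_ms: float = 125.0, seed: int = 0, *,
                        energy: Optional[np.ndarray] = None,
                        n_windows: int = 12,
                        detector: Optional[DetectorModel] = None,
                        poisson_noise: bool = True) -> SpectralSeries:
    """Generate a single-colony emission time series on an energy grid.

    Expected emitted counts in bin (E, window) are proportional to the sum
    of Gaussian peaks at E times the Kohlrausch kernel integrated over the
    window, normalised so the expected total emitted equals
    ``total_photons``. Detection applies the detector transmission
    (QE x insertion loss) and, unless ``poisson_noise`` is disabled,
    Poisson sampling.
    """
    if integration_ms <= 0:
        raise ValueError("integration_ms must be positive")
    if len(peaks.centers) == 0:
        raise ValueError("peaks must be non-empty")
    if np.any(peaks.amplitudes < 0):
        raise ValueError("peak amplitudes must be non-negative")
    if total_photons < 0:
        raise ValueError("total_photons must be non-negative")
    if energy is None:
        energy = np.arange(2.0, 3.0 + 1e-12, 0.002)
    detector = detector or DetectorModel()

    spectral = peaks.evaluate(energy)            # (E,)
    temporal = _window_kernel_integrals(decay, n_windows, integration_ms)  # (W,)
    expected = np.outer(temporal, spectral)
    total = expected.sum()
    if total > 0 and total_photons > 0:
        expected *= total_photons / total
    else:
        expected[:] = 0.0

    lam = expected * detector.transmission(energy)
    if poisson_noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam)
    else:
        counts = lam
    return SpectralSeries(energy=energy, counts=counts,
                          integration_ms=integration_ms, detector=detector)


def gen_cycle_counts(params: DepletionParams, rates: Sequence[float],
                     seed: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """Per-cycle observed photon counts under the depletion model.

    Expected counts come from the forward model; observations add Poisson
    noise, clipped sequentially so the cumulative emission never exceeds
    the initial pool (plus any regeneration).
    """
    rng = np.random.default_rng(seed)
    expected = simulate_cycles(params, rates)
    counts = np.empty(len(expected))
    remaining = params.pool_initial
    for k, e in enumerate(expected):
        draw = float(rng.poisson(e))
        draw = min(draw, remaining)
        counts[k] = draw
        remaining = max(remaining - draw + params.regen_per_cycle, 0.0)
    truth = GroundTruth(per_cycle_photons=expected,
                        pool_initial=params.pool_initial)
    return counts, truth


def _pillar_roi_centers(sensor: PillarSensor, height: int,
                        width: int) -> np.ndarray:
    """Default ROI layout: p0 at centre, indicators on a surrounding ring."""
    n = sensor.n_pillars
    r0, c0 = (height - 1) / 2.0, (width - 1) / 2.0
    centers = [(r0, c0)]
    ring = 0.33 * min(height, width)
    for i in range(1, n):
        ang = 2 * math.pi * (i - 1) / max(n - 1, 1)
        centers.append((r0 + ring * math.sin(ang), c0 + ring * math.cos(ang)))
    return np.asarray(centers)


def gen_sensor_trial(sensor: PillarSensor, machine: MachineModel,
                     actuation_strain: Optional[float] = None, *,
                     max_strain: float = 0.385, fps: float = 30.0,
                     frame_shape: tuple[int, int] = (160, 160),
                     flash_amplitude: float = 200.0,
                     background_sd: float = 3.0,
                     preroll_s: float = 1.5,
                     seed: int = 0) -> tuple[FrameStack, ForceRecord, GroundTruth]:
    """Simulate one compression trial of the pillar-array force sensor.

    The flat puncher engages pillars sequentially (tallest first); each
    pillar's ROI lights with a stretched-exponential flash once the global
    displacement reaches ``(h_p0 - h_pi) + actuation_strain * h_pi``. The
    force record is the sum of the engaged pillars' spring forces
    (piecewise-stiffening curve). Recording starts ``preroll_s`` seconds
    before the puncher moves; that dark lead-in supplies the baseline the
    5-sigma actuation detector needs (a short baseline underestimates the
    noise SD often enough to produce spurious onsets).
    """
    if actuation_strain is None:
        actuation_strain = sensor.actuation_strain
    else:
        sensor.actuation_strain = actuation_strain
    rng = np.random.default_rng(seed)
    h0 = sensor.heights[0]
    distance = max_strain * h0
    if distance > machine.travel:
        distance = machine.travel

    t_move = _move_duration(distance, machine.nominal_rate,
                            machine.max_acceleration)
    t_end = preroll_s + t_move + 1.0  # hold to capture the flash decays
    # force record at 200 pps over the loading phase
    tm = np.arange(0.0, t_end, 1.0 / MECH_SAMPLING_HZ)
    xm = _trapezoid_position(
        np.minimum(np.clip(tm - preroll_s, 0.0, None), t_move), distance,
        machine.nominal_rate, machine.max_acceleration)

    # piecewise-stiffening force: every engaged pillar is a linear spring
    force = np.zeros_like(xm)
    for i in range(sensor.n_pillars):
        gap = h0 - sensor.heights[i]
        area = math.pi * (sensor.diameters[i] / 2.0) ** 2
        k_i = machine.gel_modulus * area / sensor.heights[i] / 1000.0  # N/mm
        force += np.where(xm > gap, k_i * (xm - gap), 0.0)

    record = ForceRecord(time=tm, displacement=xm, force=force,
                         sample_height=h0,
                         sample_diameter=sensor.diameters[0])

    onset_disp = np.array([sensor.onset_displacement(i)
                           for i in range(sensor.n_pillars)])
    actuated = onset_disp <= distance + 1e-12
    # time at which the loading profile reaches each onset displacement
    loading = (tm >= preroll_s) & (tm <= preroll_s + t_move)
    onset_t = np.interp(onset_disp, xm[loading], tm[loading], right=np.nan)
    onset_t[~actuated] = np.nan

    hgt, wid = frame_shape
    roi = (sensor.roi_centers if sensor.roi_centers is not None
           else _pillar_roi_centers(sensor, hgt, wid))
    n_frames = int(math.ceil(t_end * fps))
    times = np.arange(n_frames) / fps
    tau_s = 0.238
    frames = np.empty((n_frames, hgt, wid, 3), dtype=np.uint8)
    for k, t in enumerate(times):
        noise = rng.normal(8.0, background_sd, size=(hgt, wid, 3))
        blue = noise[:, :, 2].copy()
        inst = np.where(
            actuated,
            flash_amplitude * _kohlrausch(t - onset_t, tau_s, 0.85),
            0.0,
        )
        _render_blobs(blue, roi, np.nan_to_num(inst), 3.0)
        noise[:, :, 2] = blue
        frames[k] = np.clip(noise, 0, 255).astype(np.uint8)

    stack = FrameStack(frames=frames, timestamps=times)
    truth = GroundTruth(
        pillar_onset_displacements=onset_disp,
        pillar_actuated=actuated,
        onset_times=onset_t,
        peak_velocity_mm_s=machine.peak_velocity(distance),
    )
    return stack, record, truth
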