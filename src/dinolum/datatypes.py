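"""Core data containers for the dinoflagellate mechanoluminescence pipeline.

Each container is a thin validated dataclass around numpy arrays; the
science lives in the operation modules (:mod:`dinolum.flashcount`,
:mod:`dinolum.mechanics`, :mod:`dinolum.spectro`, :mod:`dinolum.depletion`,
:mod:`dinolum.sensor`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FrameStack",
    "ForceRecord",
    "SpectralSeries",
    "LuminescenceTrace",
    "ActivationMap",
    "StressStrain",
    "PeakModel",
    "DecayFit",
    "DetectorModel",
    "DepletionParams",
    "PillarSensor",
    "ActuationEvent",
]


@dataclass
class FrameStack:
    """Time-ordered 8-bit RGB video stack of a compressed gel imaged in darkness.

    Parameters
    ----------
    frames
        ``(T, H, W, 3)`` uint8 array.
    timestamps
        Frame times in seconds, strictly increasing, uniformly spaced
        within 1%.
    mask
        ``(H, W)`` boolean sample mask (True inside the sample region).
        Defaults to all-True.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"frames must be (T, H, W, 3) RGB, got shape {self.frames.shape}"
            )
        if self.frames.dtype != np.uint8:
            raise ValueError(f"frames must be uint8, got {self.frames.dtype}")
        if len(self.timestamps) != self.frames.shape[0]:
            raise ValueError("timestamps length must match frame count")
        if len(self.timestamps) > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if dt.max() > 1.01 * dt.min():
                raise ValueError("timestamps must be uniformly spaced within 1%")
        if self.mask is None:
            self.mask = np.ones(self.frames.shape[1:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[1:3]:
                raise ValueError("mask shape must match frame size")
            if not self.mask.any():
                raise ValueError("mask must be non-empty")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def fps(self) -> float:
        if len(self.timestamps) < 2:
            raise ValueError("fps undefined for single-frame stack")
        return 1.0 / float(np.mean(np.diff(self.timestamps)))


@dataclass
class ForceRecord:
    """Sampled (time, displacement, force) triplets from a uniaxial compression test.

    The texture-analyser setup records at nominally 200 points/s; sampling
    within ±20% of that is accepted.
    """

    time: np.ndarray          # s
    displacement: np.ndarray  # mm
    force: np.ndarray         # N
    sample_height: float      # mm
    sample_diameter: float    # mm

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (len(self.time) == len(self.displacement) == len(self.force)):
            raise ValueError("time, displacement and force must have equal length")
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))


@dataclass
class DetectorModel:
    """Spectrometer detection chain: quantum efficiency and fibre insertion loss.

    Overall transmission is ``QE * 10**(-loss_db/10)``; for the instrument
    used here (QE with a 1.0 dB interconnect loss) it stays below 21%.
    """

    quantum_efficiency: float | np.ndarray = 1.0
    insertion_loss_db: float = 0.0

    def transmission(self, energy: Optional[np.ndarray] = None) -> np.ndarray:
        qe = np.asarray(self.quantum_efficiency, dtype=float)
        if qe.ndim == 1 and energy is not None and len(qe) != len(energy):
            raise ValueError("per-energy QE curve length must match energy grid")
        t = qe * 10.0 ** (-self.insertion_loss_db / 10.0)
        if np.any(t <= 0) or np.any(t > 1):
            raise ValueError("overall transmission must lie in (0, 1]")
        return t


@dataclass
class SpectralSeries:
    """Photon counts on an energy grid per fixed integration window.

    ``counts[w, e]`` is the number of detected photons in energy bin ``e``
    during window ``w``; windows are contiguous with length
    ``integration_ms`` (125 ms for the spectrometer emulated here).
    """

    energy: np.ndarray            # eV, strictly ascending
    counts: np.ndarray            # (windows, energies), non-negative integers
    integration_ms: float = 125.0
    detector: DetectorModel = field(default_factory=DetectorModel)

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.energy.ndim != 1 or np.any(np.diff(self.energy) <= 0):
            raise ValueError("energy grid must be 1-D and strictly ascending")
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.energy):
            raise ValueError("counts must be (windows, energies)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.integration_ms <= 0:
            raise ValueError("integration_ms must be positive")

    @property
    def window_times(self) -> np.ndarray:
        """Start time of each integration window, in seconds."""
        return np.arange(self.counts.shape[0]) * self.integration_ms / 1000.0


@dataclass
class LuminescenceTrace:
    """Per-frame luminescent-cell count and total intensity for one video.

    ``n_max`` is the peak simultaneous cell count; ``unique_cells`` counts
    each cell once over the whole clip (de-duplicated on the maximum
    projection), so ``unique_cells >= n_max`` always.
    """

    time: np.ndarray
    n_cells: np.ndarray
    total_intensity: np.ndarray
    n_max: int
    unique_cells: int
    projected_integral: float = 0.0  # trapz of the max projection, a.u.

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.n_cells = np.asarray(self.n_cells, dtype=int)
        self.total_intensity = np.asarray(self.total_intensity, dtype=float)
        if np.any(self.n_cells < 0):
            raise ValueError("n_cells must be non-negative")
        if len(self.n_cells) and self.n_max != int(self.n_cells.max()):
            raise ValueError("n_max must equal max(n_cells)")
        if self.unique_cells < self.n_max:
            raise ValueError("unique_cells must be >= n_max")


@dataclass
class ActivationMap:
    """Peak cell counts across a (strain, strain-rate) sweep, normalised to [0, 1]."""

    strain_levels: np.ndarray
    rate_levels: np.ndarray
    normalized_counts: np.ndarray

    def __post_init__(self) -> None:
        self.strain_levels = np.asarray(self.strain_levels, dtype=float)
        self.rate_levels = np.asarray(self.rate_levels, dtype=float)
        self.normalized_counts = np.asarray(self.normalized_counts, dtype=float)
        if self.normalized_counts.shape != (
            len(self.strain_levels),
            len(self.rate_levels),
        ):
            raise ValueError("normalized_counts must be (strains, rates)")
        if np.any(self.normalized_counts < 0) or np.any(self.normalized_counts > 1):
            raise ValueError("normalized counts must lie in [0, 1]")


@dataclass
class StressStrain:
    """Engineering stress-strain curve with its extrema.

    Strain is displacement over initial height (dimensionless fraction);
    stress is force over the initial circular cross-section, in kPa.
    """

    strain: np.ndarray
    stress: np.ndarray  # kPa
    eps_max: float
    sigma_max: float

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)


@dataclass
class PeakModel:
    """Gaussian emission-peak parameters, ordered by descending center energy."""

    centers: np.ndarray     # eV
    widths: np.ndarray      # eV (Gaussian sigma)
    amplitudes: np.ndarray  # peak height, counts
    residual_rms: float = float("nan")

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not (len(self.centers) == len(self.widths) == len(self.amplitudes)):
            raise ValueError("centers, widths, amplitudes must have equal length")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be positive")
        if len(self.centers) > 1 and np.any(np.diff(self.centers) >= 0):
            raise ValueError("centers must be strictly descending in energy")

    def evaluate(self, energy: np.ndarray) -> np.ndarray:
        e = np.asarray(energy, dtype=float)[None, :]
        c = self.centers[:, None]
        s = self.widths[:, None]
        a = self.amplitudes[:, None]
        return (a * np.exp(-0.5 * ((e - c) / s) ** 2)).sum(axis=0)


@dataclass
class DecayFit:
    """Kohlrausch (stretched-exponential) decay fit, I(t) = I0 exp[-(t/tau)^alpha]."""

    i0: float
    tau_ms: float
    alpha: float
    i0_stderr: float = float("nan")
    tau_stderr_ms: float = float("nan")
    alpha_stderr: float = float("nan")

    def __post_init__(self) -> None:
        if self.tau_ms <= 0:
            raise ValueError("tau_ms must be positive")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")

    def evaluate(self, t_s: np.ndarray) -> np.ndarray:
        """Intensity at times ``t_s`` (seconds) after onset; zero before."""
        t = np.asarray(t_s, dtype=float)
        tau_s = self.tau_ms / 1000.0
        out = np.zeros_like(t)
        pos = t >= 0
        out[pos] = self.i0 * np.exp(-((t[pos] / tau_s) ** self.alpha))
        return out


@dataclass
class DepletionParams:
    """Parameters of the luciferin-pool depletion model of photon yield vs strain rate.

    Per cycle a fraction ``yield_max * L(rate)`` of the remaining pool is
    emitted, where ``L`` is a logistic activation rescaled so ``L(0) = 0``.
    ``regen_per_cycle`` defaults to 0: metabolic luciferin regeneration is
    far slower than the seconds-apart compression cycles.
    """

    pool_initial: float          # photons
    rate_half: float             # mm/s, half-activation strain rate
    rate_slope: float            # (mm/s)^-1, logistic steepness
    yield_max: float = 1.0      # max pool fraction released per cycle
    regen_per_cycle: float = 0.0  # photons

    def __post_init__(self) -> None:
        for name in ("pool_initial", "rate_half", "rate_slope", "yield_max",
                     "regen_per_cycle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.yield_max > 1:
            raise ValueError("yield_max must be <= 1")


@dataclass
class PillarSensor:
    """Geometry of the pillar-array living force sensor.

    Pillar 0 is the tall, wide stabilising pillar; pillars 1..n are the
    indicator taxels of decreasing height (default diameter 1.6 mm) that
    luminesce sequentially under compression.
    """

    heights: np.ndarray                       # mm, p0 first and tallest
    diameters: Optional[np.ndarray] = None    # mm
    roi_centers: Optional[np.ndarray] = None  # (n, 2) px (row, col)
    actuation_strain: float = 0.02            # min strain to trigger cells

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights[0] != self.heights.max():
            raise ValueError("pillar p0 must be the tallest")
        if np.any(self.heights <= 0):
            raise ValueError("pillar heights must be positive")
        if self.diameters is None:
            d = np.full(len(self.heights), 1.6)
            d[0] = 3.2
            self.diameters = d
        else:
            self.diameters = np.asarray(self.diameters, dtype=float)
            if np.any(self.diameters <= 0):
                raise ValueError("pillar diameters must be positive")
        if self.roi_centers is not None:
            self.roi_centers = np.asarray(self.roi_centers, dtype=float)

    @property
    def n_pillars(self) -> int:
        return len(self.heights)

    def onset_displacement(self, pillar: int) -> float:
        """Global displacement at which a pillar's cells reach actuation strain.

        The puncher first closes the height gap to p0, then compresses the
        pillar itself by ``actuation_strain`` of its own height.
        """
        h0 = self.heights[0]
        hi = self.heights[pillar]
        return (h0 - hi) + self.actuation_strain * hi


@dataclass
class ActuationEvent:
    """Decoded onset of bioluminescence for one pillar."""

    pillar_id: int
    onset_time: float          # s
    onset_displacement: float  # mm
    onset_force: float         # mN
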