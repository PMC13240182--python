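import numpy as np
import pytest
from hypothesis import settings

from dinolum import synth
from dinolum.datatypes import DecayFit, PeakModel

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

# printed single-colony fit values used as generator ground truth
TAU_MS = 238.0
ALPHA = 0.85
PEAK_CENTERS = np.array([2.617, 2.51, 2.35])   # eV, descending
PEAK_SIGMA = 0.05                              # eV
PEAK_RATIOS = np.array([1.0, 0.6, 0.3])
FORCE_CALIBRATION = {1: 214.0, 2: 333.0, 3: 569.0}  # mN


@pytest.fixture
def three_peak_model() -> PeakModel:
    return PeakModel(centers=PEAK_CENTERS, widths=np.full(3, PEAK_SIGMA),
                     amplitudes=PEAK_RATIOS)


@pytest.fixture
def colony_decay() -> DecayFit:
    return DecayFit(i0=1.0, tau_ms=TAU_MS, alpha=ALPHA)


@pytest.fixture
def default_machine() -> synth.MachineModel:
    return synth.MachineModel()


def oracle_visible_per_frame(stack, truth, threshold=70.0, radius=2):
    """Brute-force per-frame visibility count from ground-truth positions.

    A cell counts as luminescent in a frame when any masked,
    threshold-subtracted blue pixel within ``radius`` of its true centre
    is positive — the direct pixel-level criterion, independent of the
    local-maxima detector.
    """
    from dinolum.flashcount import blue_channel, mask_and_threshold

    blue = blue_channel(stack)
    counts = np.zeros(stack.n_frames, dtype=int)
    for k in range(stack.n_frames):
        img = mask_and_threshold(blue[k], stack.mask, threshold)
        n = 0
        for r, c in truth.cell_positions:
            r0, c0 = int(round(r)), int(round(c))
            patch = img[max(0, r0 - radius): r0 + radius + 1,
                        max(0, c0 - radius): c0 + radius + 1]
            if patch.size and patch.max() > 0:
                n += 1
        counts[k] = n
    return counts


def oracle_unique(stack, truth, threshold=70.0, radius=2):
    """Brute-force de-duplicated cell count from the maximum projection."""
    from dinolum.flashcount import blue_channel, mask_and_threshold

    proj = blue_channel(stack).max(axis=0)
    img = mask_and_threshold(proj, stack.mask, threshold)
    n = 0
    for r, c in truth.cell_positions:
        r0, c0 = int(round(r)), int(round(c))
        patch = img[max(0, r0 - radius): r0 + radius + 1,
                    max(0, c0 - radius): c0 + radius + 1]
        if patch.size and patch.max() > 0:
            n += 1
    return n
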