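"""Strain-rate and stress-strain analysis of compression test records.

The testing machine cannot reach high nominal speeds over short travel,
so the rate actually imposed on the gel — the *effective* rate — is taken
as the maximum of consecutive finite-difference displacement rates over
the loading phase. Stress and strain are engineering quantities (initial
area and height, no barreling correction); the elastic modulus is a
linear fit of stress vs strain restricted to the 1-3% strain window.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .datatypes import ForceRecord, StressStrain

__all__ = ["effective_rate", "stress_strain", "elastic_modulus"]


def effective_rate(record: ForceRecord, median_filter: bool = False) -> float:
    """Maximum point rate (dx_i - dx_{i-1}) / (t_i - t_{i-1}) during loading.

    The loading phase runs up to the displacement maximum; retraction is
    excluded. ``median_filter`` applies a 3-point median to displacement
    first, for noisy real records.
    """
    t = record.time
    x = record.displacement
    if len(t) < 2:
        raise ValueError("effective_rate requires at least 2 samples")
    dt = np.diff(t)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps in record")
    if median_filter:
        x = ndimage.median_filter(x, size=3, mode="nearest")
    peak = int(np.argmax(x))
    if peak < 1:
        raise ValueError("no loading phase found (displacement never increases)")
    rates = np.diff(x[: peak + 1]) / dt[:peak]
    return float(rates.max())


def stress_strain(record: ForceRecord) -> StressStrain:
    """Engineering stress-strain curve from a compression record.

    strain = displacement / sample_height (fraction);
    stress = force / (pi (d/2)^2), reported in kPa.
    """
    if record.sample_height <= 0 or record.sample_diameter <= 0:
        raise ValueError("sample height and diameter must be positive")
    strain = record.displacement / record.sample_height
    area_mm2 = math.pi * (record.sample_diameter / 2.0) ** 2
    stress_kpa = record.force / area_mm2 * 1000.0  # N/mm^2 -> kPa
    return StressStrain(strain=strain, stress=stress_kpa,
                        eps_max=float(strain.max()),
                        sigma_max=float(stress_kpa.max()))


def elastic_modulus(ss: StressStrain, window: tuple[float, float] = (0.01, 0.03)
                    ) -> float:
    """Least-squares slope of stress vs strain in the 1-3% strain window.

    Only the loading branch (up to the strain maximum) enters the fit.
    Returns the modulus in kPa.
    """
    lo, hi = window
    peak = int(np.argmax(ss.strain))
    strain = ss.strain[: peak + 1]
    stress = ss.stress[: peak + 1]
    sel = (strain >= lo) & (strain <= hi)
    if sel.sum() < 4:
        raise ValueError(
            f"need >= 4 loading-branch points with strain in [{lo}, {hi}], "
            f"got {int(sel.sum())}"
        )
    slope, _ = np.polyfit(strain[sel], stress[sel], 1)
    return float(slope)
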