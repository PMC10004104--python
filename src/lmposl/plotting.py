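"""Small matplotlib helpers for depth-dose curves and correction results."""

from __future__ import annotations

import numpy as np

from .transport import DepthDose


def plot_depth_dose(dd: DepthDose, ax=None, label: str | None = None, **kwargs):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(dd.depth_mm, dd.dose, label=label, **kwargs)
    ax.set_xlabel("depth in water (mm)")
    ax.set_ylabel(f"relative dose ({dd.normalization})")
    if label:
        ax.legend()
    return ax


def plot_correction(table, ax=None):
    """Uncorrected and corrected foil doses against the ground truth.

    ``table`` is the per-foil frame produced by the closed-loop pipeline.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = table.dropna(subset=["dose_lmp_gy"])
    ax.plot(t["depth_mm"], t["dose_true_gy"], "k-", label="ground truth")
    ax.plot(t["depth_mm"], t["dose_lmp_gy"], "o", ms=4, label="uncorrected")
    ax.plot(t["depth_mm"], t["dose_corrected_gy"], "s", ms=4, label="corrected")
    ax.set_xlabel("depth in water (mm)")
    ax.set_ylabel("dose (Gy)")
    ax.legend()
    return ax


def plot_energy_profile(spectra, ax=None):
    """Median kinetic energy vs depth with IQR error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    occupied = [sp for sp in spectra if not sp.is_empty]
    depths = [sp.depth_mm for sp in occupied]
    medians = [sp.median for sp in occupied]
    iqrs = np.array([sp.iqr for sp in occupied])
    ax.errorbar(depths, medians, yerr=iqrs / 2.0, fmt="o", ms=4)
    ax.set_xlabel("depth in water (mm)")
    ax.set_ylabel("median kinetic energy (MeV)")
    return ax
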