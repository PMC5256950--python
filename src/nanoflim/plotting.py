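"""Small plotting helpers for the CLI and notebooks."""

from __future__ import annotations

import numpy as np

from .frap import FRAPFit, NormalizedFRAP
from .steps import StepFit

__all__ = ["plot_frap_fit", "plot_step_fit", "plot_lifetime_map"]


def plot_frap_fit(norm: NormalizedFRAP, fit: FRAPFit, ax=None):
    """Normalized recovery curve with the fitted exponential overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(norm.times_s, norm.values, ".", ms=3, alpha=0.6, label="normalized")
    t = norm.post_times_s
    if np.isfinite(fit.tau_rec_s):
        y = fit.mobile_fraction_percent / 100.0 * (1 - np.exp(-t / fit.tau_rec_s))
        ax.plot(t + norm.times_s[norm.bleach_index], y, "r-",
                label=f"fit: Mf={fit.mobile_fraction_percent:.1f} %")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized intensity")
    ax.legend()
    return ax


def plot_step_fit(values: np.ndarray, fit: StepFit, ax=None):
    """Bleaching trace with the piecewise-constant segmentation overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(values, ".", ms=3, alpha=0.5, label="trace")
    fitted = np.repeat(fit.segment_means, np.diff(fit.segment_bounds))
    ax.plot(fitted, "r-", lw=1.5,
            label=f"{fit.n_steps} steps, {fit.n_fluorophores} fluorophores")
    ax.set_xlabel("frame")
    ax.set_ylabel("intensity (a.u.)")
    ax.legend()
    return ax


def plot_lifetime_map(image, ax=None, vmin=1500, vmax=2500):
    """False-colour lifetime map, non-accepted pixels masked out."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    tau = np.where(image.accepted, image.tau_map_ps, np.nan)
    im = ax.imshow(tau, cmap="rainbow", vmin=vmin, vmax=vmax)
    plt.colorbar(im, ax=ax, label="lifetime (ps)")
    return ax
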