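"""Static plots: KM curves by volume quartile, the two estimated smooths,
and profile-HR curves by volume quartile. Rendered to files; never a source
of truth for any reported number."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .coxgam import FittedFuncCox, intensity_weight_curve, volume_curve
from .survival import KMResult

__all__ = ["km_plot", "smooth_plot", "profile_hr_plot"]


def km_plot(km: KMResult, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for k, grp in km.curves.groupby("quartile"):
        ax.step(grp["time"], grp["survival"], where="post", label=f"Q{k}")
        ax.fill_between(
            grp["time"], grp["lower"], grp["upper"], step="post", alpha=0.15
        )
    ax.set_xlabel("Years of follow-up")
    ax.set_ylabel("Survival probability")
    title = "Kaplan-Meier by PA volume quartile"
    if km.logrank_p is not None:
        title += f" (log-rank p = {km.logrank_p:.2g})"
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def smooth_plot(fitted: FittedFuncCox, path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    lo, hi = fitted.design.volume_range
    vc = volume_curve(fitted, np.linspace(lo, min(hi, 60.0), 120))
    axes[0].plot(vc["volume"], vc["fit"], color="k")
    axes[0].plot(vc["volume"], vc["lo"], "k--", lw=0.8)
    axes[0].plot(vc["volume"], vc["hi"], "k--", lw=0.8)
    axes[0].set_xlabel("PA volume (mg)")
    axes[0].set_ylabel("log hazard")
    axes[0].set_title("Volume smooth")
    wc = intensity_weight_curve(fitted, np.linspace(3.0, 600.0, 150))
    axes[1].plot(wc["z"], wc["fit"], color="k")
    axes[1].plot(wc["z"], wc["lo"], "k--", lw=0.8)
    axes[1].plot(wc["z"], wc["hi"], "k--", lw=0.8)
    axes[1].axhline(0, color="grey", lw=0.5)
    axes[1].set_xlabel("intensity (mg)")
    axes[1].set_ylabel("weight w(z)")
    axes[1].set_title("Intensity weight function")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def profile_hr_plot(curves: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for k, grp in curves.groupby("quartile"):
        ax.plot(
            grp["risk_position"],
            grp["hr"],
            label=f"Q{k} ({grp['mean_volume'].iloc[0]:.1f} mg)",
        )
    ax.axhline(1.0, color="grey", lw=0.5)
    ax.set_xlabel("risk profile (0 = low risk, 1 = high risk)")
    ax.set_ylabel("hazard ratio vs reference")
    ax.set_title("Profile HRs by PA volume quartile")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
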