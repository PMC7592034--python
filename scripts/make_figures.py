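#!/usr/bin/env python
"""Optional plotting layer: regenerate the standard diagnostic panels.

Writes PNGs under scratch/figures/ (not part of the package outputs):
  * i(tau) and r(tau) for the delay model vs SEIR at tau_i = 1.0, 1.25, 1.5
  * r_inf vs R0 for both model families
  * tau_D vs R0 at three endemic cutoffs
  * i(tau) across the oscillation onset (R0 = 2, tau_i = 0.8 ... 1.4)
  * growth exponent beta vs R0 and vs tau_i

Usage: python scripts/make_figures.py [--outdir scratch/figures]
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from delayepi import (
    EpidemicParams,
    critical_tau_I,
    epidemic_duration,
    final_size,
    growth_exponent_beta,
    infectious_series,
    integrate_nrde,
    integrate_seir,
    recover_compartments,
)


def model_comparison(outdir: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ti, color in zip((1.0, 1.25, 1.5), ("tab:orange", "tab:purple", "tab:green")):
        p = EpidemicParams(r0=2.5, tau_i=ti, s0=0.995)
        cs_d = recover_compartments(integrate_nrde(p, horizon=40, step=0.01))
        cs_o = integrate_seir(p, horizon=40, step=0.01)
        axes[0].plot(cs_d.tau_grid, cs_d.i, color=color, label=f"DDE tau_i={ti}")
        axes[0].plot(cs_o.tau_grid, cs_o.i, color=color, ls="--", label=f"SEIR tau_i={ti}")
        axes[1].plot(cs_d.tau_grid, cs_d.r, color=color)
        axes[1].plot(cs_o.tau_grid, cs_o.r, color=color, ls="--")
    axes[0].set(xlabel="tau", ylabel="i(tau)")
    axes[1].set(xlabel="tau", ylabel="r(tau)")
    axes[0].legend(fontsize=7)
    fig.savefig(outdir / "model_comparison.png", dpi=120, bbox_inches="tight")


def final_size_vs_r0(outdir: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    r0s = np.arange(0.25, 3.51, 0.25)
    for s0, marker in ((0.980, "o"), (0.999, "s")):
        for label, runner in (
            # near-critical R0 drifts for a very long time; a 1e-6 drift
            # tolerance is far below plotting resolution
            ("DDE", lambda p: final_size(recover_compartments(
                integrate_nrde(p, horizon=400, step=0.02)), tol=1e-6)),
            ("SEIR", lambda p: final_size(
                integrate_seir(p, horizon=400, step=0.02), tol=1e-6)),
        ):
            sizes = [runner(EpidemicParams(r0=r, tau_i=1.0, s0=s0)) for r in r0s]
            ax.plot(r0s, sizes, marker=marker, ms=3, lw=0.8,
                    label=f"{label} s0={s0}")
    ax.set(xlabel="R0", ylabel="r_inf")
    ax.legend(fontsize=7)
    fig.savefig(outdir / "final_size_vs_r0.png", dpi=120, bbox_inches="tight")


def duration_vs_r0(outdir: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    r0s = np.arange(0.4, 3.21, 0.2)
    for eps in (0.0001, 0.0005, 0.0010):
        tds = []
        for r in r0s:
            traj = integrate_nrde(EpidemicParams(r0=r, tau_i=1.0, s0=0.995),
                                  horizon=400, step=0.02)
            tds.append(epidemic_duration(infectious_series(traj), eps))
        ax.plot(r0s, tds, marker="o", ms=3, lw=0.8, label=f"eps={eps}")
    ax.set(xlabel="R0", ylabel="tau_D")
    ax.legend(fontsize=8)
    fig.savefig(outdir / "duration_vs_r0.png", dpi=120, bbox_inches="tight")


def oscillation_onset(outdir: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for ti in (0.8, 1.0, 1.2, 1.4):
        traj = integrate_nrde(EpidemicParams(r0=2.0, tau_i=ti, s0=0.99),
                              horizon=30, step=0.01)
        i = infectious_series(traj)
        ax.plot(i.index, i.to_numpy(), lw=1, label=f"tau_i={ti}")
    ax.axhline(0, color="k", lw=0.3)
    ax.set(xlabel="tau", ylabel="i(tau)",
           title=f"onset threshold tau_i_c = {critical_tau_I(2.0):.3f} at R0=2")
    ax.legend(fontsize=8)
    fig.savefig(outdir / "oscillation_onset.png", dpi=120, bbox_inches="tight")


def growth_exponent_panels(outdir: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    r0s = np.linspace(1.01, 3.5, 120)
    for ti in (0.0, 0.05, 0.3, 0.5, 1.0, 1.5):
        axes[0].plot(r0s, [growth_exponent_beta(r, ti) for r in r0s],
                     lw=1, label=f"tau_i={ti}")
    axes[0].set(xlabel="R0", ylabel="beta")
    axes[0].legend(fontsize=7)
    tis = np.linspace(0.0, 2.0, 100)
    for r0 in (1.25, 1.5, 2.0, 2.5, 3.0, 3.5):
        axes[1].plot(tis, [growth_exponent_beta(r0, ti) for ti in tis],
                     lw=1, label=f"R0={r0}")
    axes[1].set(xlabel="tau_i", ylabel="beta")
    axes[1].legend(fontsize=7)
    fig.savefig(outdir / "growth_exponent.png", dpi=120, bbox_inches="tight")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("scratch/figures"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    model_comparison(args.outdir)
    final_size_vs_r0(args.outdir)
    duration_vs_r0(args.outdir)
    oscillation_onset(args.outdir)
    growth_exponent_panels(args.outdir)
    print(f"figures written to {args.outdir}")


if __name__ == "__main__":
    main()
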