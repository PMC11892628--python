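"""Regeneration of the standard figures as vector graphics plus CSVs.

Every figure is computed from scratch at call time; the CSVs written
alongside carry the exact plotted data.  SVG metadata timestamps are
suppressed so identical inputs give byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import nash_analytic as na
from . import scaling, utility
from .params import ModelParams

__all__ = ["reproduce_figures"]

ALPHA_SWEEP = (0.0, 50.0, 100.0, 200.0, 400.0)
R0_DEFAULT = 4.0
_SAVE_KW = {"format": "svg", "metadata": {"Date": None}}


def _equilibria(R0: float, alphas=ALPHA_SWEEP, n_points: int = 1200):
    out = {}
    for alpha in alphas:
        p = ModelParams(R0=R0, alpha=alpha)
        coeffs = na.solve_self_consistent_sf(p)
        out[alpha] = (p, coeffs, na.assemble_equilibrium_trajectory(p, n_points=n_points, coeffs=coeffs))
    return out


def _fig_state_plane(outdir: Path) -> None:
    """s-i plane, k vs r, and the linear k-R0 vs i law."""
    runs = _equilibria(R0_DEFAULT)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.4))
    rows = []
    for alpha, (p, coeffs, traj) in runs.items():
        lbl = rf"$\alpha={alpha:g}$"
        axes[0].plot(traj.r, traj.k, label=lbl)
        axes[1].plot(traj.s, traj.i, label=lbl)
        axes[2].plot(traj.i, traj.k - p.R0, label=lbl)
        rows.append(pd.DataFrame({"alpha": alpha, "t": traj.t, "s": traj.s,
                                  "i": traj.i, "r": traj.r, "k": traj.k}))
    axes[0].set(xlabel="recovered fraction $r$", ylabel="activity $k$")
    axes[1].set(xlabel="susceptible fraction $s$", ylabel="infected fraction $i$")
    axes[2].set(xlabel="infected fraction $i$", ylabel="$k - R_0$")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "state_plane.svg", **_SAVE_KW)
    plt.close(fig)
    pd.concat(rows).to_csv(outdir / "state_plane.csv", index=False, float_format="%.12g")


def _fig_time_course(outdir: Path) -> None:
    """k, s, i against time for the alpha sweep."""
    runs = _equilibria(R0_DEFAULT)
    fig, axes = plt.subplots(3, 1, figsize=(5.5, 7.5), sharex=True)
    rows = []
    for alpha, (p, coeffs, traj) in runs.items():
        lbl = rf"$\alpha={alpha:g}$"
        axes[0].plot(traj.t, traj.k, label=lbl)
        axes[1].plot(traj.t, traj.s, label=lbl)
        axes[2].plot(traj.t, traj.i, label=lbl)
        rows.append(pd.DataFrame({"alpha": alpha, "t": traj.t, "s": traj.s,
                                  "i": traj.i, "r": traj.r, "k": traj.k}))
    axes[0].set(ylabel="activity $k(t)$")
    axes[1].set(ylabel="susceptible $s(t)$")
    axes[2].set(ylabel="infected $i(t)$", xlabel="time $t$ (infectious periods)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "time_course.svg", **_SAVE_KW)
    plt.close(fig)
    pd.concat(rows).to_csv(outdir / "time_course.csv", index=False, float_format="%.12g")


def _fig_scaling(outdir: Path, R0_list=(2.0, 4.0, 8.0), n_alpha: int = 25) -> None:
    """Excess cases and peak vs alpha with asymptotes, crossover stars, collapse insets."""
    fig, axes = plt.subplots(1, 2, figsize=(9.5, 3.6))
    rows = []
    for R0 in R0_list:
        base = ModelParams(R0=R0)
        _, eps0, ipk0 = scaling.nonbehavioral_limit(base)
        a_ex, a_pk = scaling.crossover_costs(base)
        alphas = np.geomspace(1.0, 300.0 * R0, n_alpha)
        eps, ipk = [], []
        for alpha in alphas:
            p = base.with_(alpha=float(alpha))
            coeffs = na.solve_self_consistent_sf(p)
            eps.append(1.0 / R0 - coeffs.sf)
            ipk.append(scaling.infection_peak(coeffs, p)[0])
        eps, ipk = np.array(eps), np.array(ipk)
        (l,) = axes[0].loglog(alphas, eps, label=rf"$R_0={R0:g}$")
        axes[0].loglog(alphas, 2.0 * R0**2 / alphas, "--", lw=0.8, color=l.get_color())
        axes[0].plot([a_ex], [eps0], "*", ms=10, color="black")
        axes[1].loglog(alphas, ipk, color=l.get_color(), label=rf"$R_0={R0:g}$")
        axes[1].loglog(alphas, 2.0 * R0 * (R0 - 1.0) / alphas, "--", lw=0.8, color=l.get_color())
        axes[1].plot([a_pk], [ipk0], "*", ms=10, color="gray")
        rows.append(pd.DataFrame({"R0": R0, "alpha": alphas, "epsilon": eps, "i_peak": ipk,
                                  "alpha_ex_star": a_ex, "alpha_peak_star": a_pk}))
    axes[0].set(xlabel=r"infection cost $\alpha$", ylabel=r"excess cases $\varepsilon$")
    axes[1].set(xlabel=r"infection cost $\alpha$", ylabel=r"infection peak $\hat{i}$")
    axes[0].legend(fontsize=7)
    axes[1].legend(fontsize=7)
    df = pd.concat(rows)

    # collapse insets: rescale alpha by the crossover, observable by its
    # nonbehavioral value; curves for all R0 fall on master curves
    for ax, acol, ycol, norm in (
        (axes[0], "alpha_ex_star", "epsilon", "eps0"),
        (axes[1], "alpha_peak_star", "i_peak", "ipk0"),
    ):
        ins = ax.inset_axes([0.12, 0.12, 0.38, 0.38])
        for R0 in R0_list:
            sub = df[df.R0 == R0]
            base = ModelParams(R0=R0)
            _, eps0, ipk0 = scaling.nonbehavioral_limit(base)
            y0 = eps0 if norm == "eps0" else ipk0
            ins.loglog(sub.alpha / sub[acol], sub[ycol] / y0, lw=0.8)
        ins.tick_params(labelsize=5)
    fig.tight_layout()
    fig.savefig(outdir / "scaling.svg", **_SAVE_KW)
    plt.close(fig)
    df.to_csv(outdir / "scaling.csv", index=False, float_format="%.12g")


def _fig_phase_diagram(outdir: Path, r0_min: float = 1.5, r0_max: float = 16.0, n: int = 60) -> None:
    """Crossover costs over R0: the behavioral phase diagram."""
    grid = np.geomspace(r0_min, r0_max, n)
    df = scaling.phase_table(grid)
    fig, ax = plt.subplots(figsize=(4.6, 3.6))
    ax.loglog(df.alpha_ex_star, df.R0, label=r"$\alpha^\star_{\mathrm{ex}}$")
    ax.loglog(df.alpha_peak_star, df.R0, label=r"$\alpha^\star_{\mathrm{peak}}$")
    ax.set(xlabel=r"infection cost $\alpha$", ylabel="$R_0$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "phase_diagram.svg", **_SAVE_KW)
    plt.close(fig)
    df.to_csv(outdir / "phase_diagram.csv", index=False, float_format="%.12g")


def _fig_utility(outdir: Path, R0: float = R0_DEFAULT, n_alpha: int = 25) -> None:
    """Epidemic cost per infection cost, -U/alpha, with both limit lines."""
    base = ModelParams(R0=R0)
    low, high = utility.utility_limits(base)
    alphas = np.geomspace(1.0, 300.0 * R0, n_alpha)
    vals = []
    for alpha in alphas:
        p = base.with_(alpha=float(alpha))
        coeffs = na.solve_self_consistent_sf(p)
        vals.append(-utility.equilibrium_utility_closed_form(p, coeffs).total / alpha)
    fig, ax = plt.subplots(figsize=(4.6, 3.6))
    ax.semilogx(alphas, vals, label="equilibrium")
    ax.axhline(low, ls=":", color="gray", label="nonbehavioral limit")
    ax.axhline(high, ls="--", color="black", label=r"high-$\alpha$ limit")
    ax.set(xlabel=r"infection cost $\alpha$", ylabel=r"$-U/\alpha$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "utility.svg", **_SAVE_KW)
    plt.close(fig)
    pd.DataFrame({"alpha": alphas, "neg_U_over_alpha": vals,
                  "low_limit": low, "high_limit": high}).to_csv(
        outdir / "utility.csv", index=False, float_format="%.12g")


def reproduce_figures(outdir: str | Path, quick: bool = False) -> list[Path]:
    """Regenerate all standard figures into ``outdir``; returns file paths.

    ``quick`` thins the alpha grids for smoke tests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_alpha = 7 if quick else 25
    _fig_state_plane(outdir)
    _fig_time_course(outdir)
    _fig_scaling(outdir, n_alpha=n_alpha)
    _fig_phase_diagram(outdir, n=12 if quick else 60)
    _fig_utility(outdir, n_alpha=n_alpha)
    return sorted(outdir.glob("*.svg")) + sorted(outdir.glob("*.csv"))
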