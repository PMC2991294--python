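"""Desk-scale experiment presets, robustness scans and figure panels.

All reproduction runs share the scaled-down resolution presets of
:func:`scaled_config`: contact-shell width R0 = 0.095 R, membrane mesh
size 0.15 R for spheres (0.2 R for elongated particles), fluctuation
widths between 4 R0 and the particle's lateral scale, refinement range
R, cell volume 15 times the particle volume.  These are the package's
desk-scale study conditions; the physics (standard parameters, move
amplitude 0.5 mesh size, Metropolis rule, rectification) is unchanged.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from .energy import EnergyParams, standard_parameters
from .simulate import SimulationConfig, run, calibrate_time, Trajectory
from .particles import (Sphere, Spheroid, SpiralRod, make_spiral,
                        spheroid_tip_first, spheroid_side_on)
from .config import characteristic_radius

#: engulfment percentage treated as completed uptake at desk scale;
#: terminal mouth closure is asymptotically slow in this myosin-free model
COMPLETE_PCT = 90.0


def lateral_scale(shape) -> float:
    """Smallest lateral obstacle scale of a particle: the radius for
    spheres, the equatorial semi-axis for spheroids, the tube diameter
    for spirals.  Sets the maximum useful fluctuation width (wider bumps
    mostly collide with the particle)."""
    if isinstance(shape, Spheroid):
        return shape.r1
    if isinstance(shape, SpiralRod):
        return 2.0 * shape.tube_radius
    return characteristic_radius(shape)


def scaled_config(shape, mode: str = "active", seed: int = 0,
                  temperature: float = 310.0, max_sweeps: float = 60.0,
                  scale_radius: float | None = None, **overrides):
    """The desk-scale (config, params) preset for a given particle.

    Spheres use mesh size 0.15 S with a 0.5 R coarse reservoir, where S
    is ``scale_radius`` (default: the particle radius R).  When particle
    sizes are *compared* (small vs large uptake), ``scale_radius`` should
    be the small particle's radius for both: the membrane's fluctuation
    machinery - mesh size, shell width, move amplitude and widths - is a
    property of the cell, not of the particle, and only matched absolute
    scales make the size dependence meaningful.  Elongated particles
    (spheroids, spirals) use 0.2 R with a 0.8 R reservoir, which keeps
    their much longer runs tractable while preserving the wrapping
    behaviour (the refinement range R around the contact is what matters
    for cup progression).
    """
    R = characteristic_radius(shape)
    elongated = not isinstance(shape, Sphere)
    S = scale_radius if scale_radius is not None else R
    params = standard_parameters(R).with_(R0=0.095 * S,
                                          temperature=temperature)
    kw = dict(
        mode=mode,
        mesh_size=(0.2 if elongated else 0.15) * S,
        refine_range=R,
        min_width=4.0 * params.R0,
        max_width=min(S, lateral_scale(shape)),
        coarse_edge=(0.8 if elongated else 0.5) * R,
        seed=seed,
        temperature=temperature,
        max_sweeps=max_sweeps,
        record_every=0.5,
        stretch_limit=5.0,
        complete_pct=COMPLETE_PCT,
        stop_on_stall=False,
    )
    kw.update(overrides)
    config = SimulationConfig(**kw)
    return config, params


def run_condition(shape_factory, mode: str, seeds, max_sweeps: float = 60.0,
                  temperature: float = 310.0, **overrides):
    """Run one condition over several seeds; returns trajectories."""
    out = []
    for seed in seeds:
        shape = shape_factory()
        config, params = scaled_config(shape, mode=mode, seed=seed,
                                       temperature=temperature,
                                       max_sweeps=max_sweeps, **overrides)
        out.append(run(config, params, shape))
    return out


def mean_engulfment_at(trajectories, sweep: float) -> float:
    return float(np.mean([t.engulfment_at(sweep) for t in trajectories]))


def robustness_scan(config, params, shape, parameter: str, folds,
                    repeats: int = 1, budget_factor: float = 2.0):
    """Vary one energy parameter by fold changes; report completion.

    The reference (fold 1.0) engulfment time defines a sweep budget of
    ``budget_factor`` times itself; each variant counts as completed if it
    reaches the completion threshold within the budget.
    """
    import pandas as pd

    if parameter not in ("kappa_b", "sigma", "epsilon", "kappa_P"):
        raise ValueError(f"unknown parameter {parameter!r}")
    ref_time = None
    rows = []
    ref = run(replace(config, seed=config.seed), params,
              _clone_shape(shape))
    ref_time = ref.first_crossing(config.complete_pct)
    if ref_time is None:
        ref_time = config.max_sweeps
    budget = budget_factor * ref_time
    for fold in folds:
        for rep in range(repeats):
            p2 = params.with_(**{parameter: getattr(params, parameter)
                                 * fold})
            c2 = replace(config, seed=config.seed + 1000 * rep + 1,
                         max_sweeps=budget)
            tr = run(c2, p2, _clone_shape(shape))
            t_done = tr.first_crossing(config.complete_pct)
            rows.append({
                "parameter": parameter,
                "fold": fold,
                "repeat": rep,
                "completed": t_done is not None and t_done <= budget,
                "sweeps_to_complete": t_done,
                "budget_sweeps": budget,
                "final_engulfed_pct": tr.records[-1]["engulfed_pct"],
            })
    return pd.DataFrame(rows)


def _clone_shape(shape):
    from .particles import ParticleShape

    return ParticleShape.from_dict(shape.to_dict())


# -- figure panels --------------------------------------------------------


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def figure_cups(outdir: Path, seed: int = 1, quick: bool = True):
    """Thin vs broad phagocytic cup cross-sections.

    Thin cup: tight volume constraint (kappa_P = 1e-2 pN um^-5) with low
    surface tension (sigma = 6.2e-7 mN/m).  Broad cup: high tension
    (sigma = 6.2e-5 mN/m) with a nearly unconstrained volume
    (kappa_P = 3.8e-7 pN um^-5).
    """
    plt = _plt()
    panels = [
        ("thin", dict(kappa_P=1.0e-2, sigma=6.2e-7 * 1e3)),
        ("broad", dict(kappa_P=3.8e-7, sigma=6.2e-5 * 1e3)),
    ]
    sweeps = 10.0 if quick else 40.0
    fig, axes = plt.subplots(1, 2, figsize=(9, 4.5))
    paths = []
    for ax, (tag, over) in zip(axes, panels):
        shape = Sphere(radius=1.5)
        config, params = scaled_config(shape, seed=seed, max_sweeps=sweeps)
        params = params.with_(**over)
        tr = run(config, params, shape)
        mesh = tr.state.mesh
        sel = np.abs(mesh.vertices[:, 1]) < 2.5 * config.mesh_size
        ax.plot(mesh.vertices[sel, 0], mesh.vertices[sel, 2], ".", ms=1.5)
        th = np.linspace(0, 2 * np.pi, 200)
        c = shape.translation
        ax.plot(c[0] + 1.5 * np.cos(th), c[2] + 1.5 * np.sin(th), "k--",
                lw=0.8)
        ax.set_aspect("equal")
        ax.set_title(f"{tag} cup "
                     f"({tr.records[-1]['engulfed_pct']:.0f}% engulfed)")
        ax.set_xlabel("x (um)")
        ax.set_ylabel("z (um)")
    fig.tight_layout()
    p = Path(outdir) / "cups_thin_vs_broad.png"
    fig.savefig(p, dpi=140)
    plt.close(fig)
    paths.append(p)
    return paths


def figure_zippers(outdir: Path, seed: int = 1, quick: bool = True):
    """Active vs passive energy and engulfment time courses (small
    particles), three repeats each."""
    plt = _plt()
    sweeps = 25.0 if quick else 60.0
    seeds = [seed, seed + 1, seed + 2]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for mode, color in (("active", "tab:blue"), ("passive", "tab:red")):
        trs = run_condition(lambda: Sphere(radius=1.5), mode, seeds,
                            max_sweeps=sweeps)
        for tr in trs:
            df = tr.to_dataframe()
            axes[0].plot(df["sweep"], df["engulfed_pct"], color=color,
                         alpha=0.7,
                         label=mode if tr is trs[0] else None)
            axes[1].plot(df["sweep"], df["E_total"], color=color, alpha=0.7)
    axes[0].set_ylabel("engulfed surface (%)")
    axes[1].set_ylabel("E_total (pN um)")
    for ax in axes:
        ax.set_xlabel("sweeps")
    axes[0].legend()
    fig.tight_layout()
    p = Path(outdir) / "zippers_active_vs_passive.png"
    fig.savefig(p, dpi=140)
    plt.close(fig)
    return [p]


def figure_timecourses(outdir: Path, seed: int = 1, quick: bool = True):
    """Small- and large-particle engulfment vs calibrated time, both
    modes.  The sweep-to-minute factor is set once so that 50% mean active
    engulfment of small particles corresponds to 6 minutes.  Large
    particles run with the small-particle membrane scales (see
    :func:`scaled_config`); their active runs grow large refined meshes,
    so quick mode keeps their horizon short.
    """
    plt = _plt()
    sweeps = 30.0 if quick else 80.0
    sweeps_large = 12.0 if quick else 40.0
    seeds = [seed, seed + 1] if quick else [seed, seed + 1, seed + 2]
    conditions = {}
    for mode in ("active", "passive"):
        conditions[("small", mode)] = run_condition(
            lambda: Sphere(radius=1.5), mode, seeds, max_sweeps=sweeps)
        conditions[("large", mode)] = run_condition(
            lambda: Sphere(radius=3.0), mode, seeds,
            max_sweeps=sweeps_large, scale_radius=1.5,
            max_vertices=150_000)
    factor = calibrate_time(conditions[("small", "active")])
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, size in zip(axes, ("small", "large")):
        horizon = sweeps if size == "small" else sweeps_large
        for mode, color in (("active", "tab:blue"), ("passive", "tab:red")):
            trs = conditions[(size, mode)]
            grid = np.linspace(0, horizon, 50)
            eng = np.mean([[t.engulfment_at(s) for s in grid]
                           for t in trs], axis=0)
            ax.plot(grid / factor, eng, color=color, label=mode)
        ax.set_title(f"{size} particles")
        ax.set_xlabel("time (min)")
        ax.legend()
    axes[0].set_ylabel("engulfed surface (%)")
    fig.tight_layout()
    p = Path(outdir) / "timecourses_small_large.png"
    fig.savefig(p, dpi=140)
    plt.close(fig)
    return [p]


def figure_shapes(outdir: Path, seed: int = 1, quick: bool = True):
    """Spheroid orientation dependence and the spiral stall."""
    plt = _plt()
    sweeps = 30.0 if quick else 80.0
    tip = run_condition(spheroid_tip_first, "active", [seed],
                        max_sweeps=sweeps)[0]
    side = run_condition(spheroid_side_on, "active", [seed],
                         max_sweeps=sweeps)[0]
    spiral = run_condition(lambda: make_spiral(2.2), "active", [seed],
                           max_sweeps=min(sweeps, 20.0))[0]
    fig, ax = plt.subplots(figsize=(6, 4))
    for tr, lab in ((tip, "spheroid, tip first"),
                    (side, "spheroid, side on"),
                    (spiral, "spiral rod")):
        df = tr.to_dataframe()
        ax.plot(df["sweep"], df["engulfed_pct"], label=lab)
    ax.set_xlabel("sweeps")
    ax.set_ylabel("engulfed surface (%)")
    ax.legend()
    fig.tight_layout()
    p = Path(outdir) / "shape_dependence.png"
    fig.savefig(p, dpi=140)
    plt.close(fig)
    return [p]
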