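"""Seeded generators for every input class of the analysis pipeline.

Ground-truth-bearing stand-ins for the four experimental data classes:
photon-counting FLIM decay cubes with Poisson statistics, noisy
anterior-declining gradient rows, 12-s-sampled temporal fluctuation
traces with a controllable dominant period, and two-stripe (r3/r5)
expression stacks with controllable boundary roughness and cell-to-cell
expression variance.  Every generator is deterministic given its seed and
returns its full configuration beside its outputs.

Default lifetimes (pure RA 0.35 ns, background autofluorescence 2.5 ns)
are plausible two-photon values chosen for this generator; they are
configurable and not measured quantities.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ranoise.flim_phasor import DecayCube, _wrapped_exponential
from ranoise.gradient_fit import GradientProfile
from ranoise.noise_stats import TemporalTrace
from ranoise.expression_sharpness import LabeledStack

__all__ = [
    "GeneratorConfig",
    "DEFAULT_LIFETIMES",
    "make_flim_cube",
    "make_gradient_rows",
    "make_temporal_trace",
    "make_rhombomere_stack",
    "make_condition_set",
    "make_solution_vs_cell_traces",
]

#: default pure-species lifetimes in ns (RA short-lived; background long)
DEFAULT_LIFETIMES = {"RA": 0.35, "background": 2.5}

#: per-condition effect multipliers used by :func:`make_condition_set`;
#: mirror the stochastic-model perturbation presets qualitatively
CONDITION_EFFECTS = {
    "WT": {"trace_noise": 1.0, "trace_mean": 1.0, "roughness": 1.0, "intensity_cv": 1.0},
    "crabp2a-MO": {"trace_noise": 2.0, "trace_mean": 1.0, "roughness": 2.0, "intensity_cv": 1.8},
    "crabp2a-GOF": {"trace_noise": 0.5, "trace_mean": 1.0, "roughness": 1.8, "intensity_cv": 1.6},
    "cyp26a1-MO": {"trace_noise": 1.0, "trace_mean": 1.6, "roughness": 1.9, "intensity_cv": 1.7},
    "cyp26a1-GOF": {"trace_noise": 1.0, "trace_mean": 0.4, "roughness": 1.7, "intensity_cv": 1.6},
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed plus scenario parameters, serialized beside every output."""

    seed: int
    scenario: str = ""
    params: dict = field(default_factory=dict)

    def spawn(self, key: int) -> "GeneratorConfig":
        return dataclasses.replace(self, seed=(self.seed * 100003 + key) % (2**31))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)


def _as_config(config, scenario: str) -> GeneratorConfig:
    if isinstance(config, GeneratorConfig):
        return config
    if isinstance(config, (int, np.integer)):
        return GeneratorConfig(seed=int(config), scenario=scenario)
    raise TypeError("config must be a GeneratorConfig or an integer seed")


# --------------------------------------------------------------------------
# FLIM decay cubes
# --------------------------------------------------------------------------

def make_flim_cube(
    fraction_map: np.ndarray,
    lifetimes: dict | None = None,
    photons: float = 1000.0,
    config: GeneratorConfig | int = 0,
    rep_rate: float = 80.0,
    n_bins: int = 256,
) -> tuple[DecayCube, dict]:
    """Poisson photon-decay cube for a two-species RA/background mixture.

    ``fraction_map`` gives the per-pixel RA intensity fraction in [0, 1];
    each pixel's expected histogram is ``photons`` times the fraction-
    weighted mix of the species' wrapped-exponential decay profiles, and
    observed counts are Poisson draws.  The ground truth (fractions,
    lifetimes, configuration) is returned beside the cube.
    """
    cfg = _as_config(config, "flim_cube")
    f = np.asarray(fraction_map, dtype=float)
    if not np.isfinite(f).all():
        raise ValueError("fraction map contains non-finite values")
    if f.min() < 0 or f.max() > 1:
        raise ValueError("fractions must lie in [0, 1]")
    if f.ndim != 2:
        raise ValueError("fraction map must be 2-D (y, x)")
    lifetimes = dict(lifetimes or DEFAULT_LIFETIMES)
    if len(lifetimes) < 2:
        raise ValueError("need at least 2 species")
    names = list(lifetimes)
    if "RA" not in names:
        raise ValueError("lifetimes must include an 'RA' entry")
    other = [n for n in names if n != "RA"]
    p_ra = _wrapped_exponential(lifetimes["RA"], rep_rate, n_bins)
    p_bg = np.mean(
        [_wrapped_exponential(lifetimes[n], rep_rate, n_bins) for n in other], axis=0
    )
    lam = photons * (f[None] * p_ra[:, None, None] + (1 - f)[None] * p_bg[:, None, None])
    counts = cfg.rng().poisson(lam)
    cube = DecayCube(
        counts=counts,
        rep_rate=rep_rate,
        bin_width=1e3 / rep_rate / n_bins,
        meta={"generator": "make_flim_cube", "config": cfg.to_json()},
    )
    truth = {
        "fraction_map": f,
        "lifetimes": lifetimes,
        "photons": photons,
        "config": cfg,
    }
    return cube, truth


# --------------------------------------------------------------------------
# gradient rows
# --------------------------------------------------------------------------

def _range_calibration(
    n_rows: int, n_cells: int, rng: np.random.Generator, n_mc: int = 300
) -> float:
    """Expected max-over-rows residual range of unit-variance noise.

    Monte-Carlo estimate including the per-row linear detrend that the
    spatial-noise statistic applies, so that the generator's noise scale
    maps onto the statistic without bias.
    """
    x = np.linspace(0.0, 1.0, n_cells)
    X = np.column_stack([np.ones(n_cells), x])
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    P = np.eye(n_cells) - H
    eps = rng.standard_normal((n_mc, n_rows, n_cells))
    resid = eps @ P.T
    ranges = resid.max(axis=2) - resid.min(axis=2)
    return float(ranges.max(axis=1).mean())


def make_gradient_rows(
    n_rows: int = 5,
    length: int = 200,
    amplitude: float = 0.3,
    noise_pct: float = 45.0,
    shape: str = "linear",
    config: GeneratorConfig | int = 0,
    x_range: tuple = (230.0, 330.0),
    baseline: float = 0.25,
) -> tuple[list, dict]:
    """Parallel rows of cells sharing a base gradient plus per-cell noise.

    The per-cell deviation scale is calibrated (by Monte Carlo, seeded
    from the config) so that the expected spatial-noise statistic of the
    generated rows equals ``noise_pct`` percent of the gradient
    amplitude.  ``shape`` selects a linear or exponential base curve
    rising posteriorly over ``x_range`` um.
    """
    if noise_pct < 0:
        raise ValueError("noise_pct must be non-negative")
    cfg = _as_config(config, "gradient_rows")
    rng = cfg.rng()
    x = np.linspace(*x_range, length)
    if shape == "linear":
        base = baseline + amplitude * (x - x[0]) / (x[-1] - x[0])
    elif shape == "exponential":
        if amplitude <= 0:
            base = np.full_like(x, baseline)
        else:
            rate = np.log((baseline + amplitude) / baseline) / (x[-1] - x[0])
            base = baseline * np.exp(rate * (x - x[0]))
    else:
        raise ValueError(f"unknown shape {shape!r}")
    if noise_pct > 0:
        expected_range = _range_calibration(n_rows, length, rng)
        sigma = (noise_pct / 100.0) * amplitude / expected_range if amplitude > 0 else 0.0
    else:
        sigma = 0.0
    rows = []
    for i in range(n_rows):
        ab = np.clip(base + sigma * rng.standard_normal(length), 0.0, 1.0)
        rows.append(GradientProfile(x, ab, row_id=i))
    truth = {
        "base": base,
        "sigma": sigma,
        "amplitude": amplitude,
        "noise_pct": noise_pct,
        "shape": shape,
        "config": cfg,
    }
    return rows, truth


# --------------------------------------------------------------------------
# temporal traces
# --------------------------------------------------------------------------

def make_temporal_trace(
    period_s: float | None = 162.0,
    dt_s: float = 12.0,
    n_points: int = 300,
    snr: float = 2.0,
    config: GeneratorConfig | int = 0,
    mean: float = 0.5,
    noise_sd: float = 0.05,
    ou_tau_s: float = 6.0,
) -> tuple[TemporalTrace, dict]:
    """Mean-reverting (OU) fluctuations plus an optional periodic component.

    The sinusoid amplitude is ``snr`` times the OU standard deviation
    times sqrt(2), so snr equals the RMS signal-to-noise ratio.  Pass
    ``period_s=None`` for a purely aperiodic trace; a period below twice
    the sampling interval is unresolvable and rejected.
    """
    cfg = _as_config(config, "temporal_trace")
    rng = cfg.rng()
    t = np.arange(n_points) * dt_s
    rho = np.exp(-dt_s / ou_tau_s)
    ou = np.empty(n_points)
    ou[0] = rng.standard_normal()
    innov = rng.standard_normal(n_points - 1) * np.sqrt(1.0 - rho**2)
    for i in range(1, n_points):
        ou[i] = rho * ou[i - 1] + innov[i - 1]
    noise = noise_sd * ou
    if period_s is not None:
        if period_s <= 2.0 * dt_s:
            raise ValueError(
                f"period {period_s} s is unresolvable at dt = {dt_s} s (need > 2 dt)"
            )
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amp = snr * noise_sd * np.sqrt(2.0)
        signal = amp * np.sin(2.0 * np.pi * t / period_s + phase)
    else:
        signal = np.zeros(n_points)
    trace = TemporalTrace(t=t, value=mean + signal + noise, cell_id=f"synthetic-{cfg.seed}")
    truth = {
        "period_s": period_s,
        "snr": snr,
        "noise_sd": noise_sd,
        "mean": mean,
        "config": cfg,
    }
    return trace, truth


# --------------------------------------------------------------------------
# expression stacks
# --------------------------------------------------------------------------

def _rough_edge(
    x0: float, ny: int, roughness: float, rng: np.random.Generator
) -> np.ndarray:
    """Boundary x-position per lateral row: smoothed random walk around x0."""
    if roughness <= 0:
        return np.full(ny, x0)
    walk = np.cumsum(rng.standard_normal(ny))
    walk -= walk.mean()
    # moving-average smoothing keeps the edge wander gentle at cell scale
    kernel = np.ones(7) / 7.0
    walk = np.convolve(walk, kernel, mode="same")
    sd = walk.std()
    if sd > 0:
        walk *= roughness / sd
    return x0 + walk


def make_rhombomere_stack(
    shape: tuple = (8, 512, 512),
    stripes: tuple = ("r3", "r5"),
    roughness: float = 2.0,
    cell_px: int = 85,
    intensity_mean: float = 190_000.0,
    intensity_cv: float = 0.2,
    bit_depth: int = 12,
    config: GeneratorConfig | int = 0,
) -> tuple[LabeledStack, dict]:
    """Two-stripe expression stack with rough boundaries and labeled cells.

    Two expression stripes (r3, r5) separated by a silent gap (r4) run
    laterally across the image; each stripe edge wanders by a smoothed
    random walk of standard deviation ``roughness`` pixels (per slice).
    Cells are tiled from jittered-grid seeds to an average in-plane size
    of ``cell_px`` pixels, and per-cell total fluorescence is lognormal
    with the given mean and CV, spread uniformly over the cell's voxels.
    A default 85-pixel cell of mean total 190,000 stays well inside the
    12-bit range (~2235 < 4095 per pixel).
    """
    if roughness < 0:
        raise ValueError("roughness must be non-negative")
    cfg = _as_config(config, "rhombomere_stack")
    nz, ny, nx = shape
    max_val = 2**bit_depth - 1

    for attempt in range(10):
        rng = cfg.spawn(attempt).rng() if attempt else cfg.rng()
        # nominal stripe edges along x (anterior to posterior)
        edges0 = np.array([0.16, 0.38, 0.56, 0.78]) * nx
        edge_x = np.empty((4, nz, ny))
        for e in range(4):
            for z in range(nz):
                edge_x[e, z] = _rough_edge(edges0[e], ny, roughness, rng)
        if (edge_x[1] < edge_x[2]).all() and (edge_x[0] < edge_x[1]).all() and (
            edge_x[2] < edge_x[3]
        ).all():
            break
    else:
        raise RuntimeError("stripes kept overlapping; lower the roughness")
    if attempt:
        import logging

        logging.getLogger(__name__).info(
            "stripe overlap at roughness %.1f; regenerated with sub-seed %d",
            roughness, attempt,
        )

    xs = np.arange(nx)
    stripe_masks = {}
    for name, (e0, e1) in zip(stripes, ((0, 1), (2, 3))):
        m = (xs[None, None, :] >= edge_x[e0][:, :, None]) & (
            xs[None, None, :] < edge_x[e1][:, :, None]
        )
        stripe_masks[name] = m

    # jittered-grid seeds reach the target mean cell size
    spacing = max(2.0, np.sqrt(cell_px))
    gy = np.arange(spacing / 2, ny, spacing)
    gx = np.arange(spacing / 2, nx, spacing)
    seeds = np.array(
        [
            (y + rng.uniform(-0.3, 0.3) * spacing, x + rng.uniform(-0.3, 0.3) * spacing)
            for y in gy
            for x in gx
        ]
    )
    tree = cKDTree(seeds)
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    _, owner = tree.query(np.column_stack([yy.ravel(), xx.ravel()]))
    owner = owner.reshape(ny, nx) + 1        # 0 reserved for background

    # every cell in the field is segmented (nuclei are everywhere); only
    # cells whose seed falls inside a stripe express above background
    labels = np.ascontiguousarray(
        np.broadcast_to(owner, shape), dtype=np.int32
    )
    mean_edge = edge_x.mean(axis=1)              # (4, ny) z-averaged edges
    seed_y = np.clip(np.round(seeds[:, 0]).astype(int), 0, ny - 1)
    seed_x = seeds[:, 1]
    expressing = np.zeros(seeds.shape[0], dtype=bool)
    for e0, e1 in ((0, 1), (2, 3)):
        expressing |= (seed_x >= mean_edge[e0][seed_y]) & (
            seed_x < mean_edge[e1][seed_y]
        )

    present = np.unique(labels)
    sd_log = np.sqrt(np.log(1.0 + intensity_cv**2)) if intensity_cv > 0 else 0.0
    mu_log = np.log(intensity_mean) - 0.5 * sd_log**2
    totals = rng.lognormal(mu_log, sd_log, size=present.size)
    is_expr = expressing[present - 1]
    totals[~is_expr] *= 0.02                     # residual background signal
    counts = np.bincount(labels.ravel(), minlength=present.max() + 1)
    lut = np.zeros(present.max() + 1)
    lut[present] = totals / counts[present]
    intensity = lut[labels]
    intensity = np.clip(np.rint(intensity), 0, max_val).astype(np.uint16)

    stack = LabeledStack(intensity=intensity, labels=labels)
    truth = {
        "stripe_masks": stripe_masks,
        "cell_totals": pd.DataFrame(
            {"label": present, "true_total": totals, "expressing": is_expr}
        ),
        "edge_x": edge_x,
        "roughness": roughness,
        "config": cfg,
    }
    return stack, truth


# --------------------------------------------------------------------------
# condition bundles and harnesses
# --------------------------------------------------------------------------

def make_condition_set(
    config: GeneratorConfig | int = 0,
    n_points: int = 300,
    stack_shape: tuple = (4, 160, 160),
    base_roughness: float = 1.5,
    base_intensity_cv: float = 0.15,
) -> dict:
    """Five-condition bundle of temporal traces and expression stacks.

    Applies the perturbation presets as noise/mean multipliers on traces
    and as roughness/expression-variance multipliers on stacks, storing
    the true effect sizes beside each condition.  The WT bundle equals
    the single-scenario generator outputs at the same seed.
    """
    cfg = _as_config(config, "condition_set")
    out = {}
    for i, (cond, eff) in enumerate(CONDITION_EFFECTS.items()):
        sub = cfg.spawn(i)
        trace, trace_truth = make_temporal_trace(
            period_s=162.0,
            n_points=n_points,
            config=sub,
            mean=0.5 * eff["trace_mean"],
            noise_sd=0.05 * eff["trace_noise"],
        )
        trace = TemporalTrace(trace.t, trace.value, cell_id=trace.cell_id, condition=cond)
        stack, stack_truth = make_rhombomere_stack(
            shape=stack_shape,
            roughness=base_roughness * eff["roughness"],
            intensity_cv=base_intensity_cv * eff["intensity_cv"],
            config=sub.spawn(99),
        )
        out[cond] = {
            "trace": trace,
            "trace_truth": trace_truth,
            "stack": stack,
            "stack_truth": stack_truth,
            "effects": dict(eff),
        }
    return out


def make_solution_vs_cell_traces(
    config: GeneratorConfig | int = 0,
    n_points: int = 100,
    photons: float = 1e5,
    cell_noise_factor: float = 10.0,
) -> dict:
    """Instrument-floor vs biological-noise comparison harness.

    Solution traces fluctuate only at the photon shot-noise floor for the
    given photon budget; cell traces carry biological fluctuations larger
    by ``cell_noise_factor``.  Used to reproduce the control showing that
    cellular variability exceeds measurement noise.
    """
    from ranoise.flim_phasor import shot_noise_bound

    cfg = _as_config(config, "solution_vs_cell")
    rng = cfg.rng()
    t = np.arange(n_points) * 12.0
    floor = shot_noise_bound(photons).sigma
    solutions = {
        name: TemporalTrace(
            t, 0.5 + floor * rng.standard_normal(n_points), cell_id=name,
            condition="solution",
        )
        for name in ("fluorescein", "rhodamine", "RA")
    }
    cells = {
        f"cell-{i}": TemporalTrace(
            t, 0.5 + cell_noise_factor * floor * rng.standard_normal(n_points),
            cell_id=f"cell-{i}", condition="cell",
        )
        for i in range(9)
    }
    return {
        "solutions": solutions,
        "cells": cells,
        "shot_noise_floor": floor,
        "factor": cell_noise_factor,
        "config": cfg,
    }
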