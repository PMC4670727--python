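"""Deterministic and ensemble (cell-population) simulation.

The deterministic simulator integrates the ODE model from its resting
state with a stiff-capable adaptive method, treating every stimulus
switch time as an integration breakpoint (the drive is constant within
each segment, so pulses are never smeared by the step controller).

The ensemble simulator represents cell-to-cell variability
semi-deterministically: each in-silico cell runs the same deterministic
equations with its total protein abundances drawn from a lognormal
distribution whose median is the base value.  Each cell starts from its
own recomputed resting state, so every cell has a flat pre-stimulus
baseline.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import (CONSERVED_CYCLES, I_ERK, I_R, I_RACT, I_RINT,
                    ModelParameters, _rhs_core, resting_state)
from .stimulus import StimulusProtocol, receptor_drive

__all__ = [
    "Trajectory",
    "CellEnsembleSpec",
    "DEFAULT_VARIED_FIELDS",
    "simulate_deterministic",
    "sample_ensemble",
    "simulate_ensemble",
]

log = logging.getLogger(__name__)

# kinase, feedback-protein and phosphatase totals varied across the ensemble
DEFAULT_VARIED_FIELDS = ("raf_tot", "mek_tot", "erk_tot",
                         "nfb_tot", "pfb_tot", "phos_tot")


@dataclass
class Trajectory:
    """Sampled ERK-activity time course of one (in-silico) cell."""

    t: np.ndarray
    erk: np.ndarray
    states: np.ndarray | None = None  # (n_time, 10) full state, optional
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.erk = np.asarray(self.erk, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.erk.shape:
            raise ValueError("time grid and ERK series must be 1-D and equal length")
        dt = np.diff(self.t)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12)):
            raise ValueError("time grid must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.erk)):
            raise ValueError("non-finite ERK values")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def copy_with(self, erk: np.ndarray, **meta) -> "Trajectory":
        return Trajectory(self.t.copy(), np.asarray(erk, float),
                          meta={**self.meta, **meta})


@dataclass(frozen=True)
class CellEnsembleSpec:
    """Lognormal cell-population specification.

    ``lognormal_sigma`` is the log-scale standard deviation applied
    independently to each varied total; medians equal the base values.
    """

    n_cells: int = 1000
    varied_fields: tuple[str, ...] = DEFAULT_VARIED_FIELDS
    lognormal_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be > 0")


def _segment_drives(params: ModelParameters, protocol: StimulusProtocol):
    """(t_start, t_end, drive) per constant-input integration segment."""
    u_on = receptor_drive(protocol.dose, protocol.gf, params)
    times = protocol.switch_times()
    out = []
    for a, b in zip(times[:-1], times[1:]):
        mid = 0.5 * (a + b)
        out.append((a, b, u_on if protocol.is_on(mid) else 0.0))
    return out


def simulate_deterministic(params: ModelParameters, protocol: StimulusProtocol,
                           dt_out: float = 1.0, rtol: float = 1e-8,
                           atol: float = 1e-10, full_state: bool = False,
                           y0: np.ndarray | None = None) -> Trajectory:
    """Integrate one cell over ``[0, t_total]`` and sample ERK activity.

    Starts from the resting state (recomputed unless ``y0`` is given),
    integrates segment-wise between stimulus switch times with LSODA, and
    returns ERK activity on the uniform output grid.  Conservation of
    every protein cycle is checked to 1e-6 relative.
    """
    if dt_out <= 0:
        raise ValueError("dt_out must be > 0")
    if y0 is None:
        y0 = resting_state(params, gf=protocol.gf)
    p = params.pack()
    ngf = 1.0 if protocol.gf == "NGF" else 0.0

    grid = np.arange(0.0, protocol.t_total + 0.5 * dt_out, dt_out)
    grid = grid[grid <= protocol.t_total + 1e-9]
    ys = np.empty((len(grid), 10))
    y = y0.copy()
    filled = 0
    if grid[0] == 0.0:
        ys[0] = y
        filled = 1
    for a, b, u in _segment_drives(params, protocol):
        t_eval = grid[(grid > a + 1e-12) & (grid <= b + 1e-12)]
        fun = lambda t, z: _rhs_core(z, u, ngf, p)
        sol = solve_ivp(fun, (a, b), y, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=t_eval if len(t_eval) else None, dense_output=False)
        if not sol.success:
            raise RuntimeError(f"integration failed on [{a:g}, {b:g}] min: {sol.message}")
        if len(t_eval):
            ys[filled:filled + len(t_eval)] = sol.y.T
            filled += len(t_eval)
        y = sol.y[:, -1] if sol.y.shape[1] else y
        # end-of-segment state for the next breakpoint
        if abs(sol.t[-1] - b) > 1e-9:
            sol2 = solve_ivp(fun, (sol.t[-1], b), y, method="LSODA",
                             rtol=rtol, atol=atol)
            y = sol2.y[:, -1]
        np.clip(y, 0.0, None, out=y)

    if filled != len(grid):
        raise RuntimeError("output grid not fully covered by integration")

    if np.any(ys < -1e-9):
        raise RuntimeError(f"negative state beyond tolerance: {ys.min():.3e}")
    for total_name, idx in CONSERVED_CYCLES:
        tot = getattr(params, total_name)
        err = np.max(np.abs((ys[:, idx] + (tot - ys[:, idx])) - tot)) / tot
        if err > 1e-6:
            raise RuntimeError(f"conservation violated for {total_name}: {err:.2e}")
    if not params.variant.internalization:
        r_err = np.max(np.abs(ys[:, I_R] + ys[:, I_RACT] - (y0[I_R] + y0[I_RACT])))
        if r_err > 1e-6:
            raise RuntimeError(f"receptor conservation violated: {r_err:.2e}")

    meta = {"gf": protocol.gf, "dose": protocol.dose, "label": protocol.label,
            "variant": params.variant.tag.value}
    return Trajectory(grid, ys[:, I_ERK].copy(),
                      states=ys if full_state else None, meta=meta)


def sample_ensemble(spec: CellEnsembleSpec, base: ModelParameters) -> list[ModelParameters]:
    """Draw per-cell parameter records (reproducible for a given seed).

    Each varied total is drawn independently from a lognormal distribution
    with median equal to the base value and log-sd ``lognormal_sigma``.
    """
    rng = np.random.default_rng(spec.seed)
    factors = np.exp(spec.lognormal_sigma
                     * rng.standard_normal((spec.n_cells, len(spec.varied_fields))))
    cells = []
    for row in factors:
        kw = {name: getattr(base, name) * f
              for name, f in zip(spec.varied_fields, row)}
        cells.append(base.replace(**kw))
    return cells


def simulate_ensemble(spec: CellEnsembleSpec, base: ModelParameters,
                      protocol: StimulusProtocol, dt_out: float = 1.0,
                      rtol: float = 1e-8, atol: float = 1e-10) -> list[Trajectory]:
    """One trajectory per sampled cell, each from its own resting state.

    Cells are independent; output order matches the sampling order.
    Per-cell integration failures are logged with the cell index and
    skipped (counted in the ``failures`` list attached to no trajectory
    but reported via logging); the run continues.
    """
    cells = sample_ensemble(spec, base)
    out: list[Trajectory] = []
    failures = 0
    for i, params_i in enumerate(cells):
        try:
            traj = simulate_deterministic(params_i, protocol, dt_out=dt_out,
                                          rtol=rtol, atol=atol)
        except Exception as exc:  # keep going; report at the end
            failures += 1
            log.warning("cell %d failed to integrate: %s", i, exc)
            continue
        traj.meta["cell_id"] = f"cell_{i:04d}"
        traj.meta["erk_tot"] = params_i.erk_tot
        out.append(traj)
    if failures:
        log.warning("%d/%d ensemble cells failed", failures, spec.n_cells)
    return out
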