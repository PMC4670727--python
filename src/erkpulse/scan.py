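"""Pulse/pause regime scans and the network-ablation comparison suite.

``scan_pulse_pause_grid`` computes integrated ERK activity (ERK^INT) for
every combination of pulse duration, pause duration and dose under
deterministic simulation.  ``run_ablation_suite`` reproduces the published
variant comparisons: DUSP removal, negative-feedback crosstalk removal
with feedback-strength rescans, receptor internalization in place of the
crosstalk, and the positive-feedback variants that lose dose or duration
discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import classify_response, erk_integral, pulse_maxima_decay
from .model import ModelParameters, build_parameters
from .simulate import CellEnsembleSpec, simulate_deterministic, simulate_ensemble
from .stimulus import StimulusProtocol, make_pulse_train

__all__ = ["RegimeGrid", "scan_pulse_pause_grid", "train_protocol",
           "run_ablation_suite", "K3_SCAN_VALUES", "T_HALF_SCAN_VALUES"]

# feedback-strength rescan values for the crosstalk-less variant (per min)
K3_SCAN_VALUES = (0.0286, 0.0045, 0.001)
# internalized-receptor half-life scan (min)
T_HALF_SCAN_VALUES = (15.0, 30.0, 60.0)


@dataclass
class RegimeGrid:
    table: pd.DataFrame          # pulse_min, pause_min, dose, window, erk_int
    gf: str
    horizon: float
    manifest: dict = field(default_factory=dict)


def train_protocol(gf: str, dose: float, pulse: float, pause: float,
                   t_baseline: float, horizon: float) -> StimulusProtocol:
    """Pulse train covering ~``horizon`` minutes with whole pulse periods only.

    The total time is rounded down to a whole number of (pulse + pause)
    periods so the final pulse is never truncated.
    """
    if pause == 0:
        return make_pulse_train(gf, dose, pulse, 0.0, t_baseline, t_baseline + horizon)
    period = pulse + pause
    n = max(1, int((horizon - pulse) // period) + 1)
    return make_pulse_train(gf, dose, pulse, pause, t_baseline, t_baseline + n * period)


def scan_pulse_pause_grid(base: ModelParameters, gf: str, doses, pulses, pauses,
                          horizon: float = 300.0,
                          windows=((0.0, 60.0), (0.0, 90.0)),
                          t_baseline: float = 10.0, dt_out: float = 1.0) -> RegimeGrid:
    """ERK^INT per (pulse, pause, dose) over the stated post-stimulus windows.

    Windows are given relative to stimulus onset.  Per-point failures are
    recorded (``erk_int`` NaN, ``error`` message) and the grid completes.
    """
    rows = []
    for dose in doses:
        for pulse in pulses:
            for pause in pauses:
                try:
                    pr = train_protocol(gf, dose, pulse, pause, t_baseline, horizon)
                    tr = simulate_deterministic(base, pr, dt_out=dt_out)
                    for w0, w1 in windows:
                        w1c = min(w1, tr.t[-1] - t_baseline)
                        val = erk_integral(tr, t_baseline,
                                           t_baseline + w0, t_baseline + w1c)
                        rows.append({"pulse_min": pulse, "pause_min": pause,
                                     "dose": dose, "window": f"{w0:g}-{w1:g}",
                                     "erk_int": val, "error": ""})
                except Exception as exc:  # record and continue
                    for w0, w1 in windows:
                        rows.append({"pulse_min": pulse, "pause_min": pause,
                                     "dose": dose, "window": f"{w0:g}-{w1:g}",
                                     "erk_int": float("nan"), "error": str(exc)})
    table = pd.DataFrame(rows)
    manifest = {"gf": gf, "doses": list(doses), "pulses": list(pulses),
                "pauses": list(pauses), "horizon": horizon,
                "windows": [list(w) for w in windows],
                "variant": base.variant.tag.value}
    return RegimeGrid(table=table, gf=gf, horizon=horizon, manifest=manifest)


def _decay(params, gf, dose, pause, horizon=300.0):
    pr = train_protocol(gf, dose, 3.0, pause, 10.0, horizon)
    tr = simulate_deterministic(params, pr)
    _, ratio = pulse_maxima_decay(tr, pr)
    return tr, pr, ratio


def _sustained_fraction(params, dose, pulse_min, n_cells, seed):
    pr = StimulusProtocol("NGF", dose, 10.0, ((float(pulse_min), True), (60.0, False)))
    trajs = simulate_ensemble(CellEnsembleSpec(n_cells=n_cells, seed=seed),
                              params, pr)
    cl = [classify_response(t, 10.0) for t in trajs]
    return float(np.mean([c == "sustained" for c in cl]))


def run_ablation_suite(base: ModelParameters | None = None,
                       high_egf: float = 25.0, low_egf: float = 1.0,
                       n_cells: int = 200, seed: int = 0) -> dict:
    """Compare the published network variants against the full model.

    Returns a report dict with, per variant, the quantitative signature it
    does or does not reproduce:

    * ``no_dusp`` — long-term decay ratios of 3'/10' trains vs the full
      model (DUSP removal slows long-term decay);
    * ``nfb_crosstalk`` — RMS discrepancy of the crosstalk-less variant
      from the full model at both EGF doses, rescanning the feedback
      strength k3_F (no single value fits both doses);
    * ``receptor_internalization`` — high-vs-low EGF decay difference
      across internalized-receptor half-lives (never dose-discriminating);
    * ``pfb_crosstalk`` — sustained fractions after a 10' NGF pulse at
      both doses (variant loses dose discrimination);
    * ``no_delay`` — sustained fractions after 3' vs 10' high NGF pulses
      (variant loses duration discrimination).
    """
    base = base or build_parameters("FULL")
    report: dict = {}

    # (a) DUSP removal
    nd = build_parameters("NO_DUSP")
    entry = {}
    for dose, tag in ((high_egf, "high"), (low_egf, "low")):
        _, _, r_full = _decay(base, "EGF", dose, 10.0)
        _, _, r_nd = _decay(nd, "EGF", dose, 10.0)
        entry[tag] = {"full": r_full, "no_dusp": r_nd,
                      "slower_decay": bool(r_nd > r_full)}
    report["no_dusp"] = entry

    # (b) NFB crosstalk removal + k3 rescan
    ref = {}
    for dose in (high_egf, low_egf):
        tr, _, _ = _decay(base, "EGF", dose, 10.0)
        ref[dose] = tr.erk
    disc = {}
    for k3 in K3_SCAN_VALUES:
        pv = build_parameters("NO_NFB_CROSSTALK", {"k3_f": k3})
        for dose in (high_egf, low_egf):
            tr, _, _ = _decay(pv, "EGF", dose, 10.0)
            disc[(k3, dose)] = float(np.sqrt(np.mean((tr.erk - ref[dose]) ** 2)))
    pair = {k3: disc[(k3, high_egf)] + disc[(k3, low_egf)] for k3 in K3_SCAN_VALUES}
    best_single = min(disc.values())
    report["nfb_crosstalk"] = {
        "rms": {f"k3={k3:g}": {"high": disc[(k3, high_egf)], "low": disc[(k3, low_egf)]}
                for k3 in K3_SCAN_VALUES},
        "min_summed_rms": min(pair.values()),
        "min_single_rms": best_single,
        "no_single_k3_fits_both": bool(min(pair.values()) >= 2.0 * best_single),
    }

    # (c) receptor internalization half-life scan
    entry = {}
    for th in T_HALF_SCAN_VALUES:
        pv = build_parameters("RECEPTOR_INTERNALIZATION", {"t_half_internal": th})
        _, _, r_h = _decay(pv, "EGF", high_egf, 10.0)
        _, _, r_l = _decay(pv, "EGF", low_egf, 10.0)
        entry[f"t_half={th:g}"] = {"high": r_h, "low": r_l,
                                   "abs_difference": abs(r_h - r_l)}
    report["receptor_internalization"] = {
        "decay_ratios": entry,
        "max_dose_difference": max(v["abs_difference"] for v in entry.values()),
        "dose_insensitive": bool(max(v["abs_difference"] for v in entry.values()) < 0.05),
    }

    # (d) positive-feedback variants: lost dose / duration discrimination
    f_full_h10 = _sustained_fraction(base, 50.0, 10.0, n_cells, seed)
    f_full_l10 = _sustained_fraction(base, 2.0, 10.0, n_cells, seed)
    f_full_h3 = _sustained_fraction(base, 50.0, 3.0, n_cells, seed)
    pv = build_parameters("NO_PFB_CROSSTALK")
    f_v_h10 = _sustained_fraction(pv, 50.0, 10.0, n_cells, seed)
    f_v_l10 = _sustained_fraction(pv, 2.0, 10.0, n_cells, seed)
    report["pfb_crosstalk"] = {
        "full": {"high_10": f_full_h10, "low_10": f_full_l10},
        "variant": {"high_10": f_v_h10, "low_10": f_v_l10},
        "full_separates_doses": bool(f_full_h10 - f_full_l10 > 0.25),
        "variant_fails_dose_separation": bool(abs(f_v_h10 - f_v_l10) < 0.1),
    }
    pv = build_parameters("NO_DELAY_NO_CROSSTALK")
    f_v_h3 = _sustained_fraction(pv, 50.0, 3.0, n_cells, seed)
    f_v_h10 = _sustained_fraction(pv, 50.0, 10.0, n_cells, seed)
    report["no_delay"] = {
        "full": {"high_3": f_full_h3, "high_10": f_full_h10},
        "variant": {"high_3": f_v_h3, "high_10": f_v_h10},
        "full_separates_durations": bool(f_full_h10 - f_full_h3 > 0.25),
        "variant_fails_duration_separation": bool(abs(f_v_h10 - f_v_h3) < 0.1),
    }
    return report
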