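"""Growth-factor stimulation protocols.

A protocol is a piecewise-constant growth-factor input: a flat pre-stimulus
baseline followed by an ordered list of ON/OFF segments. Pulses are ideal
rectangles (the microfluidic delivery is fast relative to 1-min sampling).
Dose (ng/ml) enters the ODE model only through the saturating receptor
drive ``dose / (dose + K_gf)``.

Times are minutes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "StimulusProtocol",
    "make_sustained",
    "make_pulse_train",
    "make_double_pulse",
    "receptor_drive",
]

_GFS = ("EGF", "NGF")


def _validate_gf(gf: str) -> str:
    gf = str(gf).upper()
    if gf not in _GFS:
        raise ValueError(f"unknown growth factor {gf!r}; expected one of {_GFS}")
    return gf


@dataclass(frozen=True)
class StimulusProtocol:
    """Time-resolved growth-factor input.

    Parameters
    ----------
    gf:
        Growth-factor identity, ``"EGF"`` or ``"NGF"``.
    dose:
        Concentration in ng/ml (>= 0). A zero dose yields an identically
        zero input signal.
    t_baseline:
        Minutes of flat, zero-input baseline prepended before the first
        segment.
    segments:
        Ordered ``(duration_min, on)`` pairs covering
        ``[t_baseline, t_total]``.
    label:
        Optional condition label carried into trajectory metadata.
    """

    gf: str
    dose: float
    t_baseline: float
    segments: tuple[tuple[float, bool], ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "gf", _validate_gf(self.gf))
        if self.dose < 0:
            raise ValueError("dose must be >= 0 ng/ml")
        if self.t_baseline < 0:
            raise ValueError("t_baseline must be >= 0 min")
        segs = tuple((float(d), bool(on)) for d, on in self.segments)
        for d, _ in segs:
            if d <= 0:
                raise ValueError("segment durations must be > 0 min")
        object.__setattr__(self, "segments", segs)

    # -- geometry -----------------------------------------------------------

    @property
    def t_total(self) -> float:
        return self.t_baseline + sum(d for d, _ in self.segments)

    @property
    def stim_start(self) -> float:
        """Time of first GF exposure (start of the first ON segment)."""
        t = self.t_baseline
        for d, on in self.segments:
            if on and self.dose > 0:
                return t
            t += d
        return self.t_total

    def switch_times(self) -> np.ndarray:
        """Segment boundaries (integration breakpoints), including 0 and t_total."""
        times = [0.0, self.t_baseline]
        t = self.t_baseline
        for d, _ in self.segments:
            t += d
            times.append(t)
        return np.unique(np.asarray(times, dtype=float))

    def on_intervals(self) -> list[tuple[float, float]]:
        """Half-open ``[start, end)`` intervals of GF exposure."""
        out = []
        t = self.t_baseline
        for d, on in self.segments:
            if on and self.dose > 0:
                out.append((t, t + d))
            t += d
        return out

    def pulse_starts(self) -> np.ndarray:
        return np.asarray([s for s, _ in self.on_intervals()], dtype=float)

    def gf_level(self, t) -> np.ndarray | float:
        """GF concentration at time(s) ``t``: dose on ON segments, else 0."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t_arr)
        for s, e in self.on_intervals():
            out[(t_arr >= s) & (t_arr < e)] = self.dose
        return out if np.ndim(t) else float(out[0])

    def is_on(self, t: float) -> bool:
        return any(s <= t < e for s, e in self.on_intervals())

    def to_dict(self) -> dict:
        return {
            "gf": self.gf,
            "dose_ng_per_ml": self.dose,
            "t_baseline_min": self.t_baseline,
            "segments": [[d, bool(on)] for d, on in self.segments],
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            gf=d["gf"],
            dose=float(d["dose_ng_per_ml"]),
            t_baseline=float(d["t_baseline_min"]),
            segments=tuple((float(x), bool(o)) for x, o in d["segments"]),
            label=d.get("label", ""),
        )


def _merge_segments(segs: Iterable[tuple[float, bool]]) -> tuple[tuple[float, bool], ...]:
    merged: list[list] = []
    for d, on in segs:
        if d <= 0:
            continue
        if merged and merged[-1][1] == on:
            merged[-1][0] += d
        else:
            merged.append([d, on])
    return tuple((d, on) for d, on in merged)


def make_sustained(gf: str, dose: float, t_baseline: float, t_total: float,
                   label: str = "") -> StimulusProtocol:
    """Single uninterrupted GF application over ``[t_baseline, t_total]``."""
    if t_total <= t_baseline:
        raise ValueError("t_total must exceed t_baseline")
    label = label or f"{gf} {dose:g} sustained"
    return StimulusProtocol(gf, dose, t_baseline,
                            ((t_total - t_baseline, True),), label)


def make_pulse_train(gf: str, dose: float, pulse_min: float, pause_min: float,
                     t_baseline: float, t_total: float,
                     label: str = "") -> StimulusProtocol:
    """Alternating ON/OFF train starting ON at ``t_baseline``, truncated at ``t_total``.

    A zero pause is the sustained-stimulation limit.
    """
    if pulse_min <= 0:
        raise ValueError("pulse_min must be > 0")
    if pause_min < 0:
        raise ValueError("pause_min must be >= 0")
    if t_total <= t_baseline:
        raise ValueError("t_total must exceed t_baseline")
    segs: list[tuple[float, bool]] = []
    t = t_baseline
    on = True
    while t < t_total - 1e-12:
        d = min(pulse_min if on else pause_min, t_total - t)
        if d > 0:
            segs.append((d, on))
            t += d
        on = not on
    label = label or f"{gf} {dose:g} {pulse_min:g}'/{pause_min:g}'"
    return StimulusProtocol(gf, dose, t_baseline, _merge_segments(segs), label)


def make_double_pulse(gf: str, dose: float, pulse_min: float, delay_min: float,
                      t_baseline: float, t_total: float,
                      label: str = "") -> StimulusProtocol:
    """Two identical pulses separated by ``delay_min`` of pause.

    A zero delay degenerates to one merged pulse of twice the duration.
    """
    if pulse_min <= 0:
        raise ValueError("pulse_min must be > 0")
    if delay_min < 0:
        raise ValueError("delay_min must be >= 0")
    need = 2 * pulse_min + delay_min
    if t_baseline + need > t_total:
        raise ValueError("two pulses do not fit within t_total")
    segs = [(pulse_min, True), (delay_min, False), (pulse_min, True)]
    rest = t_total - t_baseline - need
    if rest > 0:
        segs.append((rest, False))
    label = label or f"{gf} {dose:g} {pulse_min:g}'/{delay_min:g}'/{pulse_min:g}'"
    return StimulusProtocol(gf, dose, t_baseline, _merge_segments(segs), label)


def receptor_drive(dose: float, gf: str, params) -> float:
    """Dimensionless receptor drive in [0, 1): ``dose / (dose + K_gf)``.

    The half-saturation constants are chosen so that the drive at the low
    reference doses (1 ng/ml EGF, 2 ng/ml NGF) is >= 90% of the drive at
    the high reference doses (25 ng/ml EGF, 50 ng/ml NGF), reflecting the
    saturated, switch-like first-peak responses above threshold dose.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0 ng/ml")
    gf = _validate_gf(gf)
    k = params.k_egf if gf == "EGF" else params.k_ngf
    return float(dose / (dose + k))
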