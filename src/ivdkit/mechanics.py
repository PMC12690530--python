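"""Viscoelastic analysis of cyclic compression tests.

A functional spine unit compressed sinusoidally behaves, at small
amplitude, like a linear viscoelastic solid: force tracks displacement with
a phase lag δ.  Three summary metrics are extracted from the sampled
force/displacement record: the loading slope (stiffness, N/µm) from the
linear region of the loading branch, the loss tangent tan δ from the phase
delay between force and displacement, and the hysteresis energy (N·µm
dissipated per cycle) from the area of the force-displacement loop.

For a noise-free phase-lagged sinusoid with displacement amplitude X0 and
force amplitude F0 these are analytically k·cos δ (over a symmetric fit
window), tan δ, and π·F0·X0·sin δ — the closed forms the test suite checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import LoadingTrace

__all__ = [
    "ViscoelasticResult",
    "extract_cycles",
    "select_cycles",
    "loading_slope",
    "tan_delta",
    "hysteresis_energy",
    "analyze_trace",
]


@dataclass(frozen=True)
class ViscoelasticResult:
    loading_slope: float  # N/µm
    tan_delta: float
    hysteresis_energy: float  # N·µm per cycle
    cycles_used: tuple[int, ...]


def extract_cycles(trace: LoadingTrace) -> list[tuple[int, int]]:
    """Split a trace into cycles at positive-going displacement crossings.

    The displacement is mean-centered and cycle boundaries placed at
    upward zero crossings.  A leading segment starting at the record head
    and a trailing segment reaching the record end are kept when they span
    at least ~80% of the nominal period, so a record of n whole cycles
    yields n segments.  Returns (start, stop) index pairs, stop exclusive.
    """
    x = trace.displacement - trace.displacement.mean()
    if np.allclose(x, 0):
        raise ValueError("constant displacement: no cycles to extract")
    crossings = np.nonzero((x[:-1] < 0) & (x[1:] >= 0))[0] + 1
    dt = float(np.median(np.diff(trace.time)))
    period_samples = 1.0 / (trace.frequency * dt)
    starts = list(crossings)
    if not starts or starts[0] > 0.5 * period_samples:
        starts.insert(0, 0)
    segments = [(s, e) for s, e in zip(starts[:-1], starts[1:])]
    tail = len(x) - starts[-1]
    if tail >= 0.8 * period_samples:
        segments.append((starts[-1], len(x)))
    if len(segments) < 2:
        raise ValueError("fewer than 2 cycles detected")
    return segments


def select_cycles(
    segments: list[tuple[int, int]], selection: str | list[int] = "last10"
) -> list[int]:
    """Resolve a cycle selection to indices into ``segments``.

    ``"last10"`` (default) keeps the final 10 cycles — discarding the
    preconditioning transient of a 20-cycle test — or all cycles when fewer
    are available; ``"all"`` keeps everything; an explicit index list is
    passed through.
    """
    n = len(segments)
    if isinstance(selection, str):
        if selection == "all":
            return list(range(n))
        if selection == "last10":
            return list(range(max(0, n - 10), n))
        raise ValueError(f"unknown cycle selection {selection!r}")
    idx = list(selection)
    if not idx or any(i < 0 or i >= n for i in idx):
        raise ValueError("cycle indices out of range")
    return idx


def loading_slope(
    trace: LoadingTrace,
    cycles: str | list[int] = "last10",
) -> float:
    """Stiffness (N/µm) from the linear region of the loading branch.

    On each selected cycle, samples with increasing displacement form the
    loading branch; the least-squares slope of force against displacement
    is taken over the central 20-80% of the cycle's displacement range
    (a symmetric window, so the elliptic curvature of a lagged loop cancels)
    and averaged across cycles.
    """
    segments = extract_cycles(trace)
    idx = select_cycles(segments, cycles)
    slopes = []
    for i in idx:
        s, e = segments[i]
        x = trace.displacement[s:e]
        f = trace.force[s:e]
        rising = np.gradient(x) > 0
        lo = x.min() + 0.2 * (x.max() - x.min())
        hi = x.min() + 0.8 * (x.max() - x.min())
        sel = rising & (x >= lo) & (x <= hi)
        if sel.sum() < 5:
            raise ValueError(f"cycle {i}: loading branch has < 5 samples")
        slopes.append(np.polyfit(x[sel], f[sel], 1)[0])
    return float(np.mean(slopes))


def _fit_sinusoid(
    t: np.ndarray, y: np.ndarray, frequency: float
) -> tuple[float, float, float]:
    # least-squares y ≈ c + a sin(wt) + b cos(wt); returns (amplitude,
    # phase, relative residual power); phase of A·sin(wt + φ)
    w = 2 * np.pi * frequency
    design = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a, b, c = coef
    resid = y - design @ coef
    signal_power = float(np.sum((y - c) ** 2))
    rel = float(np.sum(resid**2) / signal_power) if signal_power > 0 else 1.0
    return float(np.hypot(a, b)), float(np.arctan2(b, a)), rel


def tan_delta(
    trace: LoadingTrace,
    cycles: str | list[int] = "last10",
    max_residual: float = 0.5,
) -> float:
    """Loss tangent from the force-displacement phase delay.

    Single-frequency sinusoids (amplitude, phase, offset) are fit to the
    displacement and force of the selected cycles by linear least squares
    at the trace's nominal frequency; tan δ = tan(phase_force −
    phase_displacement), with the delay wrapped into [0, π/2).  A fit
    residual above ``max_residual`` of the signal power means the record is
    not sinusoidal and is rejected.
    """
    segments = extract_cycles(trace)
    idx = select_cycles(segments, cycles)
    if len(idx) < 5:
        raise ValueError("need >= 5 full cycles for a phase fit")
    s, e = segments[idx[0]][0], segments[idx[-1]][1]
    t = trace.time[s:e]
    _, phase_x, res_x = _fit_sinusoid(t, trace.displacement[s:e], trace.frequency)
    _, phase_f, res_f = _fit_sinusoid(t, trace.force[s:e], trace.frequency)
    if res_x > max_residual or res_f > max_residual:
        raise ValueError("non-sinusoidal record: fit residual exceeds 50% power")
    delta = (phase_f - phase_x + np.pi) % (2 * np.pi) - np.pi
    delta = abs(delta)
    if delta >= np.pi / 2:
        raise ValueError(f"phase delay {delta:.3f} rad outside [0, pi/2)")
    return float(np.tan(delta))


def hysteresis_energy(
    trace: LoadingTrace,
    cycles: str | list[int] = "last10",
) -> float:
    """Energy dissipated per cycle (N·µm) from the loop area.

    Each selected cycle's force-displacement samples form a closed polygon
    whose shoelace area is the dissipated energy; the absolute areas are
    averaged over cycles.  Invariant to constant force offsets (preload).
    """
    segments = extract_cycles(trace)
    idx = select_cycles(segments, cycles)
    areas = []
    for i in idx:
        s, e = segments[i]
        x = trace.displacement[s:e]
        f = trace.force[s:e]
        if e - s < 8:
            raise ValueError(f"cycle {i}: too few samples for a loop area")
        x_next = np.roll(x, -1)
        f_next = np.roll(f, -1)
        areas.append(0.5 * abs(np.sum(x * f_next - x_next * f)))
    return float(np.mean(areas))


def analyze_trace(
    trace: LoadingTrace, cycles: str | list[int] = "last10"
) -> ViscoelasticResult:
    """All three viscoelastic metrics on one cycle selection."""
    idx = select_cycles(extract_cycles(trace), cycles)
    return ViscoelasticResult(
        loading_slope=loading_slope(trace, cycles),
        tan_delta=tan_delta(trace, cycles),
        hysteresis_energy=hysteresis_energy(trace, cycles),
        cycles_used=tuple(idx),
    )
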