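"""Fusion of normalized inverted temperature, activity and position into
the integrated TAP variable.

TAP is the epoch-wise (weighted) mean of the three normalized channels,
so 0 corresponds to complete rest and sleep and 1 to high arousal and
movement.  Equal weights are the default; weights are exposed only for
sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import EquispacedSeries

__all__ = ["TapSeries", "compose_tap", "write_tap_tsv"]

_EPS = 1e-9


@dataclass
class TapSeries:
    """The fused series plus its three normalized components for audit."""

    series: EquispacedSeries
    t_norm_inverted: EquispacedSeries
    a_norm: EquispacedSeries
    p_norm: EquispacedSeries


def compose_tap(t_norm_inverted: EquispacedSeries,
                a_norm: EquispacedSeries,
                p_norm: EquispacedSeries,
                weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                missing: str = "propagate") -> TapSeries:
    """Average the three normalized channels epoch by epoch.

    ``missing`` is ``"propagate"`` (an epoch with any missing component is
    missing — averaging two of three silently changes the variable's
    meaning) or ``"available"`` (renormalized mean of the present
    components).
    """
    if missing not in ("propagate", "available"):
        raise ValueError(f"missing policy must be 'propagate' or 'available', got {missing!r}")
    components = (t_norm_inverted, a_norm, p_norm)
    for name, s in zip(("t_norm_inverted", "a_norm", "p_norm"), components):
        if not t_norm_inverted.same_grid(s):
            raise ValueError(f"{name} is not on the common grid")
        v = s.values
        if np.nanmin(v) < -_EPS or np.nanmax(v) > 1 + _EPS:
            raise ValueError(f"{name} has values outside [0, 1]; normalize first")
    w = np.asarray(weights, dtype=float)
    if w.min() < 0 or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    stack = np.vstack([s.values for s in components])
    present = ~np.isnan(stack)
    if missing == "propagate":
        tap = np.where(present.all(axis=0), (w[:, None] * stack).sum(axis=0), np.nan)
    else:
        wmat = np.where(present, w[:, None], 0.0)
        denom = wmat.sum(axis=0)
        with np.errstate(invalid="ignore"):
            tap = np.nansum(wmat * stack, axis=0) / np.where(denom > 0, denom, np.nan)
    out = t_norm_inverted.with_values(np.clip(tap, 0.0, 1.0), label="TAP")
    return TapSeries(out, *components)


def write_tap_tsv(tap: TapSeries, path) -> None:
    """Per-subject audit table: timestamp, the three components and TAP."""
    with open(path, "w") as fh:
        fh.write("timestamp\tt_norm_inv\ta_norm\tp_norm\ttap\n")
        rows = zip(tap.series.timestamps(), tap.t_norm_inverted.values,
                   tap.a_norm.values, tap.p_norm.values, tap.series.values)
        for ts, t, a, p, v in rows:
            fh.write(f"{ts.isoformat()}\t{t!r}\t{a!r}\t{p!r}\t{v!r}\n")
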