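"""Seasonal habitat suitability and the movement-rate field it induces.

Each planning unit carries a monthly habitat suitability index (HSI) in
[0, 1].  Seasonality is summarised by fitting one annual sinusoid per PU,

    HSI(t) = mean + amplitude * sin(2*pi*t/12 + phase),

by ordinary least squares on the linearised form
``mean + a*sin(2*pi*t/12) + b*cos(2*pi*t/12)``.  The basic movement rate
of fish out of a PU is the fitted curve reflected over the line y = 0.5
(good habitat retains fish, poor habitat sheds them), evaluated with a
configurable time lag that represents delayed behavioural response to
habitat change:

    m(t) = clamp(1 - HSI_fit(t - lag), 0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridDomain

__all__ = [
    "HSISeries",
    "SinusoidFit",
    "MovementField",
    "fit_seasonal_sinusoid",
    "movement_rate",
    "build_movement_field",
]

PERIOD = 12.0


class InsufficientDataError(ValueError):
    """Too few observations to fit the seasonal model."""


@dataclass(frozen=True)
class HSISeries:
    """Monthly HSI observations for one planning unit."""

    pu_id: int
    values: dict[int, float]  # month (1-12) -> HSI in [0, 1]

    def __post_init__(self) -> None:
        for month, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"HSI out of [0,1] for PU {self.pu_id}, month {month}: {v}"
                )


@dataclass(frozen=True)
class SinusoidFit:
    """Annual-period sinusoid fitted to one PU's HSI series."""

    mean: float
    amplitude: float
    phase: float
    period: float = PERIOD

    def __call__(self, t) -> np.ndarray | float:
        """Evaluate the fitted HSI curve at (fractional) month ``t``."""
        return self.mean + self.amplitude * np.sin(
            2.0 * np.pi * np.asarray(t, dtype=float) / self.period + self.phase
        )


def fit_seasonal_sinusoid(series: HSISeries) -> SinusoidFit:
    """Least-squares fit of a period-12 sinusoid to a monthly HSI series.

    Requires at least 3 distinct months.  A constant series yields
    amplitude 0.  The linearised design is solved with ``lstsq``, so the
    fit needs no starting values and is the global optimum of the
    single-harmonic family.
    """
    months = sorted(series.values)
    if len(months) < 3:
        raise InsufficientDataError(
            f"PU {series.pu_id}: need >= 3 months, got {len(months)}"
        )
    t = np.array(months, dtype=float)
    y = np.array([series.values[m] for m in months], dtype=float)
    w = 2.0 * np.pi * t / PERIOD
    X = np.column_stack([np.ones_like(t), np.sin(w), np.cos(w)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mean, a, b = coef
    amplitude = float(np.hypot(a, b))
    # mean + a sin(w) + b cos(w) = mean + A sin(w + phi), phi = atan2(b, a)
    phase = float(np.arctan2(b, a)) if amplitude > 0 else 0.0
    return SinusoidFit(mean=float(mean), amplitude=amplitude, phase=phase)


def movement_rate(fit: SinusoidFit, t, lag: float = 0.0):
    """Basic movement rate at month ``t``: the lagged fit reflected over 0.5.

    Reflection over y = 0.5 means ``m + HSI_fit(t - lag) = 1`` wherever the
    fitted curve lies inside [0, 1]; outside, m is clamped.
    """
    return np.clip(1.0 - fit(np.asarray(t, dtype=float) - lag), 0.0, 1.0)


@dataclass
class MovementField:
    """Per-PU, per-month basic movement rates on a domain.

    ``rates`` has shape (n_pu, 12) in domain order, columns = months 1..12.
    """

    domain: GridDomain
    rates: np.ndarray
    lag: float
    fits: dict[int, SinusoidFit]

    def month_rates(self, month: int) -> np.ndarray:
        """Movement-rate vector for calendar ``month`` (any integer; period 12)."""
        return self.rates[:, (int(month) - 1) % 12]

    def hsi_month(self, month: int) -> np.ndarray:
        """Fitted (unlagged) HSI vector for ``month``, clamped to [0, 1]."""
        return np.clip(
            np.array([self.fits[pid](month) for pid in self.domain.ids]), 0.0, 1.0
        )


def build_movement_field(
    domain: GridDomain,
    hsi: dict[int, HSISeries] | list[HSISeries],
    lag: float = 1.0,
) -> MovementField:
    """Fit every PU's seasonal sinusoid and assemble the movement field.

    One HSI series per PU is required; missing PUs raise a consistency
    error listing the offending ids.
    """
    if not isinstance(hsi, dict):
        hsi = {s.pu_id: s for s in hsi}
    missing = [int(pid) for pid in domain.ids if int(pid) not in hsi]
    if missing:
        raise ValueError(f"missing HSI series for PU id(s): {missing}")
    fits = {pid: fit_seasonal_sinusoid(hsi[pid]) for pid in domain.ids}
    months = np.arange(1, 13, dtype=float)
    rates = np.vstack(
        [movement_rate(fits[pid], months, lag) for pid in domain.ids]
    )
    return MovementField(domain=domain, rates=rates, lag=lag, fits=fits)
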