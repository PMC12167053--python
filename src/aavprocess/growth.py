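"""Perfusion-culture metabolite balance and lactate-based growth estimation.

The hollow-fiber system is treated as a single well-mixed volume V under
perfusion: fresh media enters at rate Q(t) with feed concentration C_feed,
mixed media leaves at the same rate, and cells produce (lactate, ammonium)
or consume (glucose, glutamine) each analyte at a constant specific rate q
per cell per day. The daily mass balance per analyte is

    V dC/dt = N(t) * q - Q(t) * (C - C_feed)

integrated as a forward difference equation at the sampling times. The cell
estimator inverts exactly that balance for lactate: per sampling interval
the lactate production rate is P = V*dC/dt + Q*(C - C_feed) and the viable
cell number is P / q_lac.

This reconstruction is a modelling choice of this package — it is NOT the
bioreactor vendor's proprietary prediction algorithm, whose functional form
is unpublished.

Units: days, mL, mM (mmol/L), cells, and pmol/cell/day for specific rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_FEED_CONCENTRATIONS_MM,
    DEFAULT_Q_LAC_PMOL_PER_CELL_DAY,
    DEFAULT_SPECIFIC_RATES_PMOL,
    DEFAULT_SYSTEM_VOLUME_ML,
)

ANALYTES = ("glucose", "lactate", "glutamine", "ammonium")

__all__ = [
    "ANALYTES",
    "MetaboliteSeries",
    "GrowthEstimate",
    "estimate_cells_from_lactate",
    "simulate_metabolites",
    "logistic_curve",
]


@dataclass
class MetaboliteSeries:
    """Daily metabolite measurements with the perfusion context."""

    times: np.ndarray  # days from seeding, strictly increasing
    concentrations: dict[str, np.ndarray]  # mM per analyte
    perfusion_rate: np.ndarray  # mL/day, piecewise constant per interval
    system_volume_mL: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.perfusion_rate = np.asarray(self.perfusion_rate, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 1:
            raise ValueError("times must be a 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.perfusion_rate.shape != self.times.shape:
            raise ValueError("perfusion_rate must match times in length")
        if np.any(self.perfusion_rate < 0):
            raise ValueError("perfusion_rate must be >= 0")
        if self.system_volume_mL <= 0:
            raise ValueError("system_volume_mL must be > 0")
        self.concentrations = {
            k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()
        }
        for name, series in self.concentrations.items():
            if series.shape != self.times.shape:
                raise ValueError(f"{name} series must match times in length")

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {"day": self.times}
        for name in self.concentrations:
            data[f"{name}_mM"] = self.concentrations[name]
        data["perfusion_mL_per_day"] = self.perfusion_rate
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> Path:
        self.to_frame().to_csv(path, index=False)
        return Path(path)

    @classmethod
    def from_csv(
        cls, path: str | Path, system_volume_mL: float = DEFAULT_SYSTEM_VOLUME_ML
    ) -> "MetaboliteSeries":
        df = pd.read_csv(path)
        conc = {
            col[: -len("_mM")]: df[col].to_numpy()
            for col in df.columns
            if col.endswith("_mM")
        }
        return cls(
            times=df["day"].to_numpy(),
            concentrations=conc,
            perfusion_rate=df["perfusion_mL_per_day"].to_numpy(),
            system_volume_mL=system_volume_mL,
        )


@dataclass
class GrowthEstimate:
    """Estimated viable cells per sampling interval."""

    times: np.ndarray  # interval start times (days)
    cells: np.ndarray
    q_lac: float  # pmol/cell/day assumed in the inversion
    notes: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.times, "cells": self.cells})


def estimate_cells_from_lactate(
    series: MetaboliteSeries,
    q_lac: float = DEFAULT_Q_LAC_PMOL_PER_CELL_DAY,
    feed_lactate: float = 0.0,
    smooth_window: int | None = None,
    differences: str = "forward",
) -> GrowthEstimate:
    """Invert the lactate mass balance to estimate viable cell numbers.

    ``differences="forward"`` (default) treats each sampling interval as one
    step of the discrete balance and is the exact inverse of
    :func:`simulate_metabolites`; ``"centered"`` uses centered differences at
    interior points (forward/backward at the ends), which trades exactness
    for symmetry on irregularly produced data. Estimates are floored at zero;
    an optional moving-average window smooths the result.
    """
    if q_lac <= 0:
        raise ValueError("q_lac must be > 0")
    if "lactate" not in series.concentrations:
        raise ValueError("series has no lactate measurements")
    t = series.times
    if len(t) < 2:
        raise ValueError("need at least two time points to difference")
    C = series.concentrations["lactate"]
    Q = series.perfusion_rate
    V_L = series.system_volume_mL / 1000.0
    Q_L = Q / 1000.0

    if differences == "forward":
        dt = np.diff(t)
        dCdt = np.diff(C) / dt
        # production over interval i uses interval-start concentration,
        # matching the simulator's explicit step
        prod_mmol_day = V_L * dCdt + Q_L[:-1] * (C[:-1] - feed_lactate)
        times = t[:-1]
    elif differences == "centered":
        dCdt = np.gradient(C, t)
        prod_mmol_day = V_L * dCdt + Q_L * (C - feed_lactate)
        times = t
    else:
        raise ValueError("differences must be 'forward' or 'centered'")

    cells = np.maximum(prod_mmol_day * 1e9 / q_lac, 0.0)
    if smooth_window is not None and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        cells = np.convolve(
            np.pad(cells, (smooth_window // 2,) * 2, mode="edge"),
            kernel,
            mode="valid",
        )[: len(times)]
    return GrowthEstimate(
        times=times,
        cells=cells,
        q_lac=q_lac,
        notes=f"washout mass balance, {differences} differences",
    )


def simulate_metabolites(
    times: Sequence[float],
    cells: Sequence[float],
    rates: Mapping[str, float] | None = None,
    perfusion_rate: Sequence[float] | float | None = None,
    feed_concentrations: Mapping[str, float] | None = None,
    volume_mL: float = DEFAULT_SYSTEM_VOLUME_ML,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> MetaboliteSeries:
    """Forward-integrate the perfusion mass balance for a given growth curve.

    ``rates`` maps analyte -> signed specific rate (pmol/cell/day, positive =
    produced). Concentrations start at the feed levels, are clamped at zero
    during integration, and Gaussian measurement noise (sd in mM) is added
    last. A seed is required whenever ``noise_sd > 0``.
    """
    t = np.asarray(times, dtype=float)
    N = np.asarray(cells, dtype=float)
    if t.shape != N.shape or t.ndim != 1 or len(t) < 2:
        raise ValueError("times and cells must be matching 1-D arrays, n >= 2")
    if np.any(N < 0):
        raise ValueError("cell numbers must be >= 0")
    if volume_mL <= 0:
        raise ValueError("volume_mL must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")

    rates = dict(DEFAULT_SPECIFIC_RATES_PMOL if rates is None else rates)
    feeds = dict(
        DEFAULT_FEED_CONCENTRATIONS_MM
        if feed_concentrations is None
        else feed_concentrations
    )
    for name, q in rates.items():
        if not np.isfinite(q):
            raise ValueError(f"rate for {name!r} must be finite")

    if perfusion_rate is None:
        Q = np.zeros_like(t)
    elif np.isscalar(perfusion_rate):
        Q = np.full_like(t, float(perfusion_rate))
    else:
        Q = np.asarray(perfusion_rate, dtype=float)
        if Q.shape != t.shape:
            raise ValueError("perfusion_rate must match times in length")
    if np.any(Q < 0):
        raise ValueError("perfusion_rate must be >= 0")

    V_L = volume_mL / 1000.0
    conc: dict[str, np.ndarray] = {}
    for name, q in rates.items():
        feed = feeds.get(name, 0.0)
        C = np.empty_like(t)
        C[0] = feed
        for i in range(len(t) - 1):
            dt = t[i + 1] - t[i]
            production = N[i] * q * 1e-9  # mmol/day
            washout = (Q[i] / 1000.0) * (C[i] - feed)  # mmol/day
            C[i + 1] = max(C[i] + dt * (production - washout) / V_L, 0.0)
        conc[name] = C

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for name in conc:
            conc[name] = conc[name] + rng.normal(0.0, noise_sd, size=t.shape)

    return MetaboliteSeries(
        times=t,
        concentrations=conc,
        perfusion_rate=Q,
        system_volume_mL=volume_mL,
    )


def logistic_curve(
    times: Sequence[float],
    plateau: float,
    n0: float = 4.0e7,
    rate: float = 1.2,
) -> np.ndarray:
    """Logistic growth N(t) = K / (1 + (K/N0 - 1) exp(-r t))."""
    if plateau <= 0 or n0 <= 0 or n0 > plateau:
        raise ValueError("need 0 < n0 <= plateau")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    t = np.asarray(times, dtype=float)
    A = plateau / n0 - 1.0
    return plateau / (1.0 + A * np.exp(-rate * t))
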