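"""Face-centred central composite designs and quadratic response surfaces.

The lysis-optimization workflow: build a face-centred CCD over the process
factors (coded levels in {-1, 0, +1}), fit a full quadratic model to the
responses by ordinary least squares in coded units, test overall model
significance with the regression F-test, locate the maximizer of the fitted
surface on the closed coded cube, and export contour grids for plotting.

Fitting is done in coded units for numerical conditioning; locations are
reported in natural units by linear decoding (center +/- half-range).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FactorDef",
    "CCDDesign",
    "RSMFit",
    "FittingError",
    "Optimum",
    "ccd_face_centered",
    "term_names",
    "model_matrix",
    "fit_quadratic",
    "optimum_within_bounds",
    "contour_grid",
]


class FittingError(ValueError):
    """The design cannot support the full quadratic model."""


@dataclass(frozen=True)
class FactorDef:
    """A process factor with natural-unit bounds."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(
                f"factor {self.name!r}: low must be < high "
                f"(got {self.low} >= {self.high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def decode(self, coded):
        return self.center + self.half_range * np.asarray(coded, dtype=float)

    def encode(self, natural):
        return (np.asarray(natural, dtype=float) - self.center) / self.half_range


@dataclass(frozen=True)
class CCDDesign:
    """A face-centred central composite design.

    Rows: 2^k factorial at +/-1, 2k axial points on the cube faces, and
    ``n_center`` center replicates. ``row_labels`` tags each row as
    ``factorial`` / ``axial`` / ``center``.
    """

    factors: tuple[FactorDef, ...]
    coded: np.ndarray
    natural: np.ndarray
    n_center: int
    row_labels: tuple[str, ...]

    @property
    def n_rows(self) -> int:
        return self.coded.shape[0]

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {"label": list(self.row_labels)}
        for j, f in enumerate(self.factors):
            data[f"coded_{f.name}"] = self.coded[:, j]
        for j, f in enumerate(self.factors):
            data[f.name] = self.natural[:, j]
        return pd.DataFrame(data)


def ccd_face_centered(
    factors: Sequence[FactorDef], n_center: int = 3
) -> CCDDesign:
    """Build a face-centred CCD (axial points at coded +/-1 on one axis)."""
    k = len(factors)
    if not 2 <= k <= 6:
        raise ValueError(f"need 2..6 factors, got {k}")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")

    factorial = np.array(
        list(itertools.product((-1.0, 1.0), repeat=k)), dtype=float
    )
    axial = np.zeros((2 * k, k))
    for j in range(k):
        axial[2 * j, j] = -1.0
        axial[2 * j + 1, j] = 1.0
    center = np.zeros((n_center, k))

    coded = np.vstack([factorial, axial, center])
    labels = (
        ["factorial"] * len(factorial)
        + ["axial"] * len(axial)
        + ["center"] * n_center
    )
    natural = np.column_stack(
        [f.decode(coded[:, j]) for j, f in enumerate(factors)]
    )
    return CCDDesign(
        factors=tuple(factors),
        coded=coded,
        natural=natural,
        n_center=n_center,
        row_labels=tuple(labels),
    )


def term_names(factors: Sequence[FactorDef]) -> list[str]:
    """Full-quadratic term order: intercept, linear, square, interaction."""
    names = ["intercept"] + [f.name for f in factors]
    names += [f"{f.name}^2" for f in factors]
    names += [
        f"{a.name}:{b.name}"
        for i, a in enumerate(factors)
        for b in factors[i + 1 :]
    ]
    return names


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """Design matrix for the full quadratic model in coded units."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = coded.shape
    cols = [np.ones(n)]
    cols.extend(coded[:, j] for j in range(k))
    cols.extend(coded[:, j] ** 2 for j in range(k))
    cols.extend(
        coded[:, i] * coded[:, j]
        for i in range(k)
        for j in range(i + 1, k)
    )
    return np.column_stack(cols)


@dataclass(frozen=True)
class RSMFit:
    """A fitted full-quadratic response surface (coded-unit coefficients)."""

    factors: tuple[FactorDef, ...]
    coefficients: np.ndarray  # term order of :func:`term_names`
    term_names: tuple[str, ...]
    residual_variance: float
    model_f: float
    model_p: float
    r_squared: float
    n_obs: int
    dilution_applied: bool = False

    @property
    def k(self) -> int:
        return len(self.factors)

    def predict_coded(self, coded) -> np.ndarray:
        return model_matrix(coded) @ self.coefficients

    def encode(self, natural) -> np.ndarray:
        natural = np.atleast_2d(np.asarray(natural, dtype=float))
        return np.column_stack(
            [f.encode(natural[:, j]) for j, f in enumerate(self.factors)]
        )

    def predict_natural(self, natural) -> np.ndarray:
        return self.predict_coded(self.encode(natural))

    # --- quadratic form pieces: y = c + b.x + x'Ax (A symmetric) ---
    def quadratic_form(self) -> tuple[float, np.ndarray, np.ndarray]:
        k = self.k
        c = float(self.coefficients[0])
        b = np.array(self.coefficients[1 : 1 + k], dtype=float)
        A = np.zeros((k, k))
        np.fill_diagonal(A, self.coefficients[1 + k : 1 + 2 * k])
        idx = 1 + 2 * k
        for i in range(k):
            for j in range(i + 1, k):
                A[i, j] = A[j, i] = 0.5 * self.coefficients[idx]
                idx += 1
        return c, b, A

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "factors": [
                {"name": f.name, "low": f.low, "high": f.high}
                for f in self.factors
            ],
            "term_names": list(self.term_names),
            "coefficients": self.coefficients.tolist(),
            "residual_variance": self.residual_variance,
            "model_f": self.model_f,
            "model_p": self.model_p,
            "r_squared": self.r_squared,
            "n_obs": self.n_obs,
            "dilution_applied": self.dilution_applied,
        }
        Path(path).write_text(json.dumps(payload, indent=2))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "RSMFit":
        payload = json.loads(Path(path).read_text())
        return cls(
            factors=tuple(
                FactorDef(f["name"], f["low"], f["high"])
                for f in payload["factors"]
            ),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            term_names=tuple(payload["term_names"]),
            residual_variance=payload["residual_variance"],
            model_f=payload["model_f"],
            model_p=payload["model_p"],
            r_squared=payload["r_squared"],
            n_obs=payload["n_obs"],
            dilution_applied=payload["dilution_applied"],
        )


def fit_quadratic(
    design: CCDDesign,
    responses: Sequence[float],
    dilution_factors: Sequence[float] | float | None = None,
) -> RSMFit:
    """OLS fit of the full quadratic model on a CCD.

    Responses are multiplied by their dilution factors before fitting (the
    assay dilutes high-density samples; the model works on back-corrected
    titers). Model significance is the F-test of the full model against the
    intercept-only model.
    """
    y = np.asarray(responses, dtype=float)
    if y.shape[0] != design.n_rows:
        raise ValueError(
            f"responses length {y.shape[0]} != design rows {design.n_rows}"
        )
    diluted = False
    if dilution_factors is not None:
        d = np.broadcast_to(
            np.asarray(dilution_factors, dtype=float), y.shape
        ).copy()
        if np.any(d <= 0):
            raise ValueError("dilution factors must be > 0")
        y = y * d
        diluted = not np.allclose(d, 1.0)

    X = model_matrix(design.coded)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p or n < p:
        names = term_names(design.factors)
        deficient = names[rank:] if n >= p else names[n:]
        raise FittingError(
            f"design is rank-deficient for the full quadratic model "
            f"({n} rows, {p} terms, rank {rank}); cannot estimate terms "
            f"such as: {', '.join(deficient)}"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        res = sm.OLS(y, X).fit()
        model_p = float(res.f_pvalue)
        model_f = float(res.fvalue)
        r2 = float(res.rsquared)
    # constant responses: TSS == 0 makes the F-test undefined; report a
    # maximally insignificant model with zero explained variance
    if not math.isfinite(model_p):
        model_p, model_f, r2 = 1.0, 0.0, 0.0
    return RSMFit(
        factors=design.factors,
        coefficients=np.asarray(res.params, dtype=float),
        term_names=tuple(term_names(design.factors)),
        residual_variance=float(res.mse_resid) if n > p else 0.0,
        model_f=model_f,
        model_p=min(max(model_p, np.nextafter(0, 1)), 1.0),
        r_squared=min(max(r2, 0.0), 1.0),
        n_obs=n,
        dilution_applied=diluted,
    )


@dataclass(frozen=True)
class Optimum:
    coded: np.ndarray
    natural: dict[str, float]
    predicted: float


def optimum_within_bounds(
    fit: RSMFit, fixed: Mapping[str, float] | None = None
) -> Optimum:
    """Exact maximizer of the fitted quadratic over the coded cube [-1, 1]^k.

    ``fixed`` pins factors to natural-unit values (e.g. a cell density for a
    contour slice). The maximizer of a quadratic on a box lies either at an
    interior stationary point or on a face; all faces/edges/vertices are
    enumerated by pinning each free coordinate to {-1, +1, interior} and
    solving the stationary system of the restricted quadratic — exact for
    every quadratic, no grid or iterative search involved.
    """
    c, b, A = fit.quadratic_form()
    k = fit.k
    names = [f.name for f in fit.factors]

    pins: dict[int, float] = {}
    if fixed:
        for name, natural_val in fixed.items():
            if name not in names:
                raise KeyError(f"unknown factor {name!r}")
            j = names.index(name)
            pins[j] = float(fit.factors[j].encode(natural_val))

    free_idx = [j for j in range(k) if j not in pins]

    def value(x: np.ndarray) -> float:
        return c + b @ x + x @ A @ x

    best_x: np.ndarray | None = None
    best_val = -np.inf
    for assignment in itertools.product((-1.0, 1.0, None), repeat=len(free_idx)):
        x = np.zeros(k)
        for j, v in pins.items():
            x[j] = v
        interior = [
            free_idx[i] for i, v in enumerate(assignment) if v is None
        ]
        for i, v in enumerate(assignment):
            if v is not None:
                x[free_idx[i]] = v
        if interior:
            F = np.array(interior)
            P = np.array([j for j in range(k) if j not in interior])
            AFF = A[np.ix_(F, F)]
            # stationary point of the restriction: the gradient along F is
            # b_F + 2 A_FF x_F + 2 A_FP x_P = 0
            rhs = -0.5 * b[F]
            if P.size:
                rhs = rhs - A[np.ix_(F, P)] @ x[P]
            try:
                xf = np.linalg.solve(AFF, rhs)
            except np.linalg.LinAlgError:
                continue  # flat along this face; its boundary covers the max
            if np.any(np.abs(xf) > 1.0 + 1e-12):
                continue
            x[F] = np.clip(xf, -1.0, 1.0)
        val = value(x)
        if val > best_val:
            best_val = val
            best_x = x.copy()

    assert best_x is not None  # the vertex set is always evaluated
    natural = {
        f.name: float(f.decode(best_x[j])) for j, f in enumerate(fit.factors)
    }
    return Optimum(coded=best_x, natural=natural, predicted=float(best_val))


def contour_grid(
    fit: RSMFit,
    axis_pair: tuple[str, str],
    fixed_levels: Mapping[str, float] | None = None,
    resolution: int = 50,
) -> pd.DataFrame:
    """Predicted-response grid over two factors in natural units.

    Other factors sit at ``fixed_levels`` (natural units; default: their
    range midpoints). Returns a long-format frame with one row per grid
    point, ready for CSV export and external heat-mapping.
    """
    x_name, y_name = axis_pair
    if x_name == y_name:
        raise ValueError("axis factors must be distinct")
    names = [f.name for f in fit.factors]
    for name in (x_name, y_name):
        if name not in names:
            raise KeyError(f"unknown factor {name!r}")
    fixed_levels = dict(fixed_levels or {})
    for name, val in fixed_levels.items():
        if name not in names:
            raise KeyError(f"unknown factor {name!r}")
        f = fit.factors[names.index(name)]
        if not (f.low <= val <= f.high):
            raise ValueError(
                f"fixed level for {name!r} outside bounds [{f.low}, {f.high}]"
            )
    if resolution < 1:
        raise ValueError("resolution must be >= 1")

    fx = fit.factors[names.index(x_name)]
    fy = fit.factors[names.index(y_name)]
    xs = np.linspace(fx.low, fx.high, resolution)
    ys = np.linspace(fy.low, fy.high, resolution)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")

    points = np.zeros((XX.size, fit.k))
    for j, f in enumerate(fit.factors):
        if f.name == x_name:
            points[:, j] = XX.ravel()
        elif f.name == y_name:
            points[:, j] = YY.ravel()
        else:
            points[:, j] = fixed_levels.get(f.name, f.center)
    preds = fit.predict_natural(points)
    return pd.DataFrame(
        {x_name: XX.ravel(), y_name: YY.ravel(), "predicted": preds}
    )
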