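"""Penalized regression spline bases.

Implements the spline machinery for the habitat model: 1-D smooths as
natural cubic regression splines parameterised by their values at knots
(second-derivative penalty, so constants and straight lines are
unpenalised), cyclic cubic regression splines whose value and first two
derivatives match at the period endpoints (for tidal state, lunar cycle,
aspect and current direction), tensor products of two marginal cubic
bases for the spatial surface, and unpenalised factor (dummy) terms.

Each basis exposes a design-matrix builder and a quadratic roughness
penalty; columns of penalized smooths are centred on the training data so
the intercept stays identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SmoothTermSpec", "SmoothBasis", "build_smooth_basis"]

#: covariates that must be modelled cyclically, with their periods
CYCLIC_PERIODS = {
    "tidal_state": 12.42,       # hours
    "lunar_cycle": 14.77,       # days
    "aspect": 360.0,            # degrees
    "current_direction": 360.0,
}

VALID_BASES = ("linear", "thin_plate", "cyclic_cubic", "tensor_product", "factor")


@dataclass(frozen=True)
class SmoothTermSpec:
    """Specification of one model term.

    ``covariates`` is a 1-tuple except for tensor products (2-tuple).
    ``basis`` is one of linear / thin_plate / cyclic_cubic /
    tensor_product / factor; ``k`` the basis dimension (per margin for
    tensor products); ``period`` is required for cyclic terms.
    """

    covariates: tuple[str, ...]
    basis: str = "thin_plate"
    k: int = 10
    period: float | None = None

    def __post_init__(self) -> None:
        if self.basis not in VALID_BASES:
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.basis == "tensor_product" and len(self.covariates) != 2:
            raise ValueError("tensor_product needs exactly two covariates")
        if self.basis != "tensor_product" and len(self.covariates) != 1:
            raise ValueError(f"{self.basis} takes exactly one covariate")
        if self.basis == "cyclic_cubic" and not self.period:
            name = self.covariates[0]
            if name in CYCLIC_PERIODS:
                object.__setattr__(self, "period", CYCLIC_PERIODS[name])
            else:
                raise ValueError("cyclic basis requires a period")

    @property
    def name(self) -> str:
        inner = ",".join(self.covariates)
        if self.basis == "factor":
            return inner
        if self.basis == "linear":
            return inner
        if self.basis == "tensor_product":
            return f"te({inner})"
        return f"s({inner})"

    @classmethod
    def smooth(cls, cov: str, k: int = 10) -> "SmoothTermSpec":
        if cov in CYCLIC_PERIODS:
            return cls((cov,), "cyclic_cubic", k=8)
        return cls((cov,), "thin_plate", k=k)


# ---------------------------------------------------------------------------
# cubic regression spline building blocks (value-at-knot parameterisation)

def _crs_matrices(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Natural-spline maps: F (values -> 2nd derivs) and penalty S."""
    k = len(knots)
    h = np.diff(knots)
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    Binv = np.linalg.inv(B)
    F = np.zeros((k, k))
    F[1:-1, :] = Binv @ D
    S = D.T @ Binv @ D
    return F, S


def _crs_design(x: np.ndarray, knots: np.ndarray, F: np.ndarray) -> np.ndarray:
    k = len(knots)
    x = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    h = knots[j + 1] - knots[j]
    lo, hi = knots[j], knots[j + 1]
    am = (hi - x) / h
    ap = (x - lo) / h
    cm = ((hi - x) ** 3 / h - h * (hi - x)) / 6.0
    cp = ((x - lo) ** 3 / h - h * (x - lo)) / 6.0
    X = np.zeros((len(x), k))
    rows = np.arange(len(x))
    X[rows, j] += am
    X[rows, j + 1] += ap
    X += cm[:, None] * F[j, :] + cp[:, None] * F[j + 1, :]
    return X


def _cyclic_matrices(knots: np.ndarray, period: float) -> tuple[np.ndarray, np.ndarray]:
    """Cyclic analogue of :func:`_crs_matrices` on ``m`` wrapped knots."""
    m = len(knots)
    h = np.diff(np.append(knots, knots[0] + period))
    B = np.zeros((m, m))
    D = np.zeros((m, m))
    for i in range(m):
        ip, im = (i + 1) % m, (i - 1) % m
        B[i, i] = (h[im] + h[i]) / 3.0
        B[i, ip] += h[i] / 6.0
        B[i, im] += h[im] / 6.0
        D[i, i] = -(1.0 / h[im] + 1.0 / h[i])
        D[i, ip] += 1.0 / h[i]
        D[i, im] += 1.0 / h[im]
    Binv = np.linalg.inv(B)
    F = Binv @ D
    S = D.T @ Binv @ D
    return F, S


def _cyclic_design(x: np.ndarray, knots: np.ndarray, period: float,
                   F: np.ndarray) -> np.ndarray:
    m = len(knots)
    xw = knots[0] + np.mod(x - knots[0], period)
    ext = np.append(knots, knots[0] + period)
    j = np.clip(np.searchsorted(ext, xw, side="right") - 1, 0, m - 1)
    h = ext[j + 1] - ext[j]
    lo, hi = ext[j], ext[j + 1]
    am = (hi - xw) / h
    ap = (xw - lo) / h
    cm = ((hi - xw) ** 3 / h - h * (hi - xw)) / 6.0
    cp = ((xw - lo) ** 3 / h - h * (xw - lo)) / 6.0
    X = np.zeros((len(x), m))
    rows = np.arange(len(x))
    jp = (j + 1) % m
    X[rows, j] += am
    X[rows, jp] += ap
    X += cm[:, None] * F[j, :] + cp[:, None] * F[jp, :]
    return X


def _quantile_knots(x: np.ndarray, k: int) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, k))
    knots = np.unique(qs)
    if len(knots) < k:  # heavy ties: fall back to an even spread
        knots = np.unique(np.linspace(x.min(), x.max(), k))
    if len(knots) < 3:
        raise ValueError("covariate has too few distinct values for a smooth")
    return knots


# ---------------------------------------------------------------------------
# public basis object

@dataclass
class SmoothBasis:
    """A realised basis: design columns, penalty, and a row builder."""

    spec: SmoothTermSpec
    design: np.ndarray
    penalty: np.ndarray
    col_means: np.ndarray
    column_names: list[str]
    _state: dict = field(default_factory=dict, repr=False)

    @property
    def p(self) -> int:
        return self.design.shape[1]

    def rows(self, data: pd.DataFrame) -> np.ndarray:
        """Evaluate the basis (with training centring) on new data."""
        raw = self._raw_rows(data)
        return raw - self.col_means

    def _raw_rows(self, data: pd.DataFrame) -> np.ndarray:
        spec, st = self.spec, self._state
        if spec.basis == "linear":
            return data[spec.covariates[0]].to_numpy(dtype=float)[:, None]
        if spec.basis == "factor":
            col = data[spec.covariates[0]]
            out = np.zeros((len(col), len(st["levels"]) - 1))
            for i, lev in enumerate(st["levels"][1:]):
                out[:, i] = (col == lev).to_numpy(dtype=float)
            return out
        if spec.basis == "thin_plate":
            x = data[spec.covariates[0]].to_numpy(dtype=float)
            return _crs_design(x, st["knots"], st["F"])
        if spec.basis == "cyclic_cubic":
            x = data[spec.covariates[0]].to_numpy(dtype=float)
            return _cyclic_design(x, st["knots"], spec.period, st["F"])
        # tensor product
        x1 = data[spec.covariates[0]].to_numpy(dtype=float)
        x2 = data[spec.covariates[1]].to_numpy(dtype=float)
        X1 = _crs_design(x1, st["knots1"], st["F1"])
        X2 = _crs_design(x2, st["knots2"], st["F2"])
        return np.einsum("ni,nj->nij", X1, X2).reshape(len(x1), -1)


def build_smooth_basis(spec: SmoothTermSpec, data: pd.DataFrame,
                       center: bool = True) -> SmoothBasis:
    """Construct the design columns and penalty matrix for one term."""
    n = len(data)
    state: dict = {}
    if spec.basis == "linear":
        penalty = np.zeros((1, 1))
        names = [spec.covariates[0]]
    elif spec.basis == "factor":
        levels = sorted(pd.unique(data[spec.covariates[0]]).tolist())
        if len(levels) < 2:
            raise ValueError(f"factor {spec.covariates[0]!r} has one level")
        state["levels"] = levels
        penalty = np.zeros((len(levels) - 1, len(levels) - 1))
        names = [f"{spec.covariates[0]}[{lev}]" for lev in levels[1:]]
    elif spec.basis == "thin_plate":
        if spec.k >= n:
            raise ValueError("basis dimension must be below n")
        x = data[spec.covariates[0]].to_numpy(dtype=float)
        knots = _quantile_knots(x, spec.k)
        F, penalty = _crs_matrices(knots)
        state.update(knots=knots, F=F)
        names = [f"{spec.name}.{i}" for i in range(len(knots))]
    elif spec.basis == "cyclic_cubic":
        if spec.k >= n:
            raise ValueError("basis dimension must be below n")
        x0 = data[spec.covariates[0]].to_numpy(dtype=float)
        lo = float(np.min(x0))
        knots = lo + np.linspace(0, spec.period, spec.k + 1)[:-1]
        F, penalty = _cyclic_matrices(knots, spec.period)
        state.update(knots=knots, F=F)
        names = [f"{spec.name}.{i}" for i in range(len(knots))]
    else:  # tensor product
        if spec.k ** 2 >= n:
            raise ValueError("basis dimension must be below n")
        x1 = data[spec.covariates[0]].to_numpy(dtype=float)
        x2 = data[spec.covariates[1]].to_numpy(dtype=float)
        knots1 = _quantile_knots(x1, spec.k)
        knots2 = _quantile_knots(x2, spec.k)
        F1, S1 = _crs_matrices(knots1)
        F2, S2 = _crs_matrices(knots2)
        k1, k2 = len(knots1), len(knots2)
        penalty = np.kron(S1, np.eye(k2)) + np.kron(np.eye(k1), S2)
        state.update(knots1=knots1, F1=F1, knots2=knots2, F2=F2)
        names = [f"{spec.name}.{i}" for i in range(k1 * k2)]

    basis = SmoothBasis(spec, np.empty((0, 0)), penalty,
                        np.zeros(len(names)), names, state)
    raw = basis._raw_rows(data)
    if center and spec.basis not in ("factor",):
        basis.col_means = raw.mean(axis=0)
    basis.design = raw - basis.col_means
    return basis
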