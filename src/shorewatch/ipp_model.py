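"""Inhomogeneous Poisson point-process habitat model via IWLR.

Sightings are modelled as points of a spatiotemporal inhomogeneous
Poisson process whose log-intensity is a sum of smooth covariate
effects. The IPP likelihood is approximated by *infinitely weighted
logistic regression* (IWLR): sightings get response 1 and weight 1,
uniform availability points drawn within each scan's detection wedge get
response 0 and a large case weight ``W``; as ``W`` grows the logistic
slope estimates converge to the IPP log-intensity coefficients.

Model building follows the survey workflow: collinear covariates are
screened (|r| >= 0.8, biological priority deciding which member drops),
terms are added by forward selection scored with leave-one-day-out
cross-validated log-likelihood (CVLL), and effects are reported as rate
ratios exp(beta) and profile prediction curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import EnvironmentBundle, sample_covariates
from .geolocation import Platform, Scan, TransverseMercator

__all__ = [
    "UseAvailabilityRecord",
    "FittedHabitatModel",
    "sample_availability",
    "screen_collinearity",
    "fit_iwlr",
    "rate_ratio",
    "cvll_grouped",
    "forward_select",
    "predict_relative_rate",
]

DEFAULT_W = 1000.0
_RIDGE = 1e-8


@dataclass
class UseAvailabilityRecord:
    """One row of the use-availability design (response 1 = sighting)."""

    response: int
    scan_id: str
    day_id: str
    site: str
    sea_state: int
    x: float
    y: float
    case_weight: float
    covariates: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"response": self.response, "scan_id": self.scan_id,
               "day_id": self.day_id, "site": self.site,
               "sea_state": self.sea_state, "x": self.x, "y": self.y,
               "case_weight": self.case_weight}
        row.update(self.covariates)
        return row


def sample_availability(scan: Scan, platform: Platform, radius: float,
                        env: EnvironmentBundle,
                        n_per_scan: int = 2, seed: int = 0,
                        projection: TransverseMercator | None = None,
                        W: float = DEFAULT_W,
                        max_attempts: int = 100) -> list[UseAvailabilityRecord]:
    """Uniform-by-area availability points inside a scan's detection wedge.

    Radius is drawn as ``R sqrt(u)`` and angle uniformly across the
    sector, which is uniform sampling by area; points landing on nodata
    covariates are redrawn (up to ``max_attempts`` each).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    width = platform.sector_width
    if width <= 0:
        raise ValueError("sector width must be positive")
    proj = projection or TransverseMercator()
    origin = proj.forward(*platform.lonlat)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_per_scan):
        for attempt in range(max_attempts):
            theta = np.radians(platform.sector_start + rng.uniform(0, width))
            r = radius * np.sqrt(rng.uniform())
            x = origin.x + r * np.sin(theta)
            y = origin.y + r * np.cos(theta)
            cov = sample_covariates((x, y), scan.start_time, env,
                                    sea_state=scan.sea_state, site=platform.id)
            if cov.valid:
                break
        else:
            raise RuntimeError(
                f"no valid availability point for scan {scan.id} after "
                f"{max_attempts} attempts")
        out.append(UseAvailabilityRecord(
            response=0, scan_id=scan.id,
            day_id=scan.start_time.strftime("%Y-%m-%d"),
            site=platform.id, sea_state=scan.sea_state,
            x=x, y=y, case_weight=W, covariates=cov.as_dict()))
    return out


# ---------------------------------------------------------------------------
# collinearity screen

def screen_collinearity(records: pd.DataFrame, covariates: list[str],
                        r_threshold: float = 0.8,
                        priority: list[str] | None = None
                        ) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy collinearity screen: drop one of each pair with |r| >= 0.8.

    ``priority`` lists covariates from most to least biologically
    relevant; the lower-priority member of a collinear pair is dropped.
    Covariates not listed rank below all listed ones, in column order.
    """
    if len(covariates) < 2 or len(records) < 10:
        raise ValueError("need >= 2 covariates and >= 10 records")
    pr = priority or []
    rank = {c: (pr.index(c) if c in pr else len(pr) + covariates.index(c))
            for c in covariates}
    corr = records[covariates].corr().abs()
    retained = list(covariates)
    dropped: list[tuple[str, str, float]] = []
    while True:
        worst, pair = 0.0, None
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                r = corr.loc[a, b]
                if r >= r_threshold and r > worst:
                    worst, pair = r, (a, b)
        if pair is None:
            break
        a, b = pair
        loser = b if rank[a] <= rank[b] else a
        keeper = a if loser == b else b
        retained.remove(loser)
        dropped.append((loser, keeper, float(worst)))
    return retained, dropped


# ---------------------------------------------------------------------------
# IWLR fitting

from .smooths import SmoothBasis, SmoothTermSpec, build_smooth_basis  # noqa: E402


@dataclass
class FittedHabitatModel:
    """A fitted IWLR habitat model."""

    terms: list[SmoothTermSpec]
    bases: list[SmoothBasis]
    coef: np.ndarray            # [intercept, term blocks...]
    lambdas: dict[str, float]
    W: float
    deviance: float
    null_deviance: float
    edf: float
    n: int

    @property
    def deviance_explained(self) -> float:
        """Percent of null deviance explained, in [0, 100]."""
        if self.null_deviance == 0:
            return 0.0
        return 100.0 * (1.0 - self.deviance / self.null_deviance)

    def design(self, data: pd.DataFrame) -> np.ndarray:
        blocks = [np.ones((len(data), 1))]
        blocks += [b.rows(data) for b in self.bases]
        return np.hstack(blocks)

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        return self.design(data) @ self.coef

    def predict_probability(self, data: pd.DataFrame) -> np.ndarray:
        eta = np.clip(self.linear_predictor(data), -35, 35)
        return 1.0 / (1.0 + np.exp(-eta))

    def term_slices(self) -> dict[str, slice]:
        out, start = {}, 1
        for spec, basis in zip(self.terms, self.bases):
            out[spec.name] = slice(start, start + basis.p)
            start += basis.p
        return out

    def coefficient_table(self) -> pd.DataFrame:
        names = ["(Intercept)"]
        for basis in self.bases:
            names += basis.column_names
        return pd.DataFrame({"term": names, "coef": self.coef,
                             "rate_ratio": np.exp(self.coef)})


def _assemble(terms: list[SmoothTermSpec], data: pd.DataFrame,
              bases: list[SmoothBasis] | None = None
              ) -> tuple[np.ndarray, list[SmoothBasis], list[np.ndarray]]:
    if bases is None:
        bases = [build_smooth_basis(t, data) for t in terms]
    X = np.hstack([np.ones((len(data), 1))] + [b.design if b.design.shape[0] == len(data)
                                               else b.rows(data) for b in bases])
    penalties = []
    start = 1
    p = X.shape[1]
    for basis in bases:
        S = np.zeros((p, p))
        S[start:start + basis.p, start:start + basis.p] = basis.penalty
        penalties.append(S)
        start += basis.p
    return X, bases, penalties


def _pirls(X: np.ndarray, y: np.ndarray, w: np.ndarray,
           S_total: np.ndarray, max_iter: int = 60,
           tol: float = 1e-9) -> tuple[np.ndarray, float, float]:
    """Penalized IRLS for weighted Bernoulli; returns (beta, deviance, edf)."""
    n, p = X.shape
    beta = np.zeros(p)
    ybar = np.clip(np.average(y, weights=w), 1e-10, 1 - 1e-10)
    beta[0] = np.log(ybar / (1 - ybar))
    dev_old = np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        wt = w * mu * (1 - mu)
        wt = np.maximum(wt, 1e-12)
        z = eta + (y - mu) / np.maximum(mu * (1 - mu), 1e-12)
        XtW = X.T * wt
        A = XtW @ X + S_total + _RIDGE * np.eye(p)
        beta_new = np.linalg.solve(A, XtW @ z)
        eta = np.clip(X @ beta_new, -35, 35)
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        dev = -2.0 * float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))
        beta = beta_new
        if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
            break
        dev_old = dev
    wt = np.maximum(w * mu * (1 - mu), 1e-12)
    XtW = X.T * wt
    A = XtW @ X + S_total + _RIDGE * np.eye(X.shape[1])
    edf = float(np.trace(np.linalg.solve(A, XtW @ X)))
    return beta, dev, edf


def fit_iwlr(records: pd.DataFrame, terms: list[SmoothTermSpec],
             W: float = DEFAULT_W,
             lambdas: dict[str, float] | None = None,
             select_smoothing: bool = True,
             lambda_grid: np.ndarray | None = None,
             response_col: str = "response") -> FittedHabitatModel:
    """Fit the IWLR approximation of the IPP habitat model.

    Case weights are 1 for sightings and ``W`` for availability points.
    Each penalized term's smoothing parameter is chosen by a GCV score
    ``n D / (n - edf)^2`` over a log-spaced grid (one coordinate-descent
    sweep per term, twice), unless explicit ``lambdas`` are given.
    """
    y = records[response_col].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both response classes must be present")
    if W < 100:
        raise ValueError("IWLR weight W must be at least 100")
    w = np.where(y == 1, 1.0, W)
    if "case_weight" in records.columns:
        w = records["case_weight"].to_numpy(dtype=float)
    X, bases, penalties = _assemble(terms, records)
    n = len(records)

    smooth_idx = [i for i, t in enumerate(terms)
                  if t.basis in ("thin_plate", "cyclic_cubic", "tensor_product")]
    lam = {terms[i].name: 1.0 for i in smooth_idx}
    if lambdas is not None:
        lam.update(lambdas)
        select_smoothing = False

    def total_penalty(lam_map):
        S = np.zeros((X.shape[1], X.shape[1]))
        for i in smooth_idx:
            S += lam_map.get(terms[i].name, 1.0) * penalties[i]
        return S

    if select_smoothing and smooth_idx:
        grid = (lambda_grid if lambda_grid is not None
                else np.logspace(-2, 6, 9))
        for _sweep in range(2):
            for i in smooth_idx:
                name = terms[i].name
                best = (np.inf, lam[name])
                for lg in grid:
                    trial = dict(lam); trial[name] = float(lg)
                    _, dev, edf = _pirls(X, y, w, total_penalty(trial))
                    gcv = n * dev / max(n - edf, 1.0) ** 2
                    if gcv < best[0]:
                        best = (gcv, float(lg))
                lam[name] = best[1]

    beta, dev, edf = _pirls(X, y, w, total_penalty(lam))

    # separation guard: huge standardized coefficients trigger a ridge refit
    scale = np.concatenate([[1.0], np.std(X[:, 1:], axis=0) + 1e-12])
    if np.any(np.abs(beta[1:] * scale[1:]) > 20):
        warnings.warn("possible separation; refitting with ridge penalty",
                      stacklevel=2)
        beta, dev, edf = _pirls(X, y, w,
                                total_penalty(lam) + 1e-3 * np.eye(X.shape[1]))

    beta0, dev0, _ = _pirls(np.ones((n, 1)), y, w, np.zeros((1, 1)))
    return FittedHabitatModel(terms=terms, bases=bases, coef=beta,
                              lambdas=lam, W=W, deviance=dev,
                              null_deviance=dev0, edf=edf, n=n)


def rate_ratio(coefficient: float) -> float:
    """Multiplicative effect on the sighting rate: exp(coefficient)."""
    if not np.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    return float(np.exp(coefficient))


# ---------------------------------------------------------------------------
# cross-validation and forward selection

def cvll_grouped(records: pd.DataFrame, terms: list[SmoothTermSpec],
                 W: float = DEFAULT_W, group_col: str = "day_id",
                 lambdas: dict[str, float] | None = None,
                 weighted: bool = True) -> float:
    """Leave-one-day-out cross-validated log-likelihood.

    For each distinct day the model is refitted without that day and the
    held-out weighted Bernoulli log-likelihood is accumulated. Smoothing
    parameters are frozen at their full-data selection (pass ``lambdas``)
    or selected once here if omitted. Folds lacking availability points
    are skipped with a warning.
    """
    days = pd.unique(records[group_col])
    if len(days) < 2:
        raise ValueError("need at least 2 distinct days for grouped CV")
    if lambdas is None:
        full = fit_iwlr(records, terms, W=W)
        lambdas = full.lambdas
    total = 0.0
    for day in days:
        test = records[records[group_col] == day]
        train = records[records[group_col] != day]
        if (test["response"] == 0).sum() == 0:
            warnings.warn(f"fold {day} lacks availability points; skipped",
                          stacklevel=2)
            continue
        if train["response"].min() == train["response"].max():
            warnings.warn(f"fold {day} leaves one response class; skipped",
                          stacklevel=2)
            continue
        model = fit_iwlr(train, terms, W=W, lambdas=lambdas)
        p = np.clip(model.predict_probability(test), 1e-12, 1 - 1e-12)
        yt = test["response"].to_numpy(dtype=float)
        wt = (test["case_weight"].to_numpy(dtype=float)
              if ("case_weight" in test.columns and weighted)
              else np.where(yt == 1, 1.0, W if weighted else 1.0))
        total += float(np.sum(wt * (yt * np.log(p) + (1 - yt) * np.log(1 - p))))
    return total


def forward_select(candidates: list[SmoothTermSpec], records: pd.DataFrame,
                   W: float = DEFAULT_W, group_col: str = "day_id",
                   base_terms: list[SmoothTermSpec] | None = None
                   ) -> tuple[pd.DataFrame, FittedHabitatModel]:
    """Greedy forward selection scored by grouped CVLL.

    At each step the candidate with the highest CVLL is added; selection
    stops when the best remaining candidate no longer improves CVLL
    (first non-positive delta). Remaining candidates are reported with
    their rejected deltas, mirroring the published selection tables.
    """
    if not candidates:
        raise ValueError("need at least one candidate term")
    selected = list(base_terms or [])
    remaining = list(candidates)
    rows = []
    current_cvll = None
    while remaining:
        scores = []
        for cand in remaining:
            try:
                s = cvll_grouped(records, selected + [cand], W=W,
                                 group_col=group_col)
            except Exception:
                s = -np.inf
            scores.append(s)
        order = int(np.argmax(scores))
        best_cand, best_score = remaining[order], scores[order]
        delta = np.nan if current_cvll is None else best_score - current_cvll
        if current_cvll is not None and delta <= 0:
            # stop: report every remaining candidate with its rejected delta
            for cand, s in zip(remaining, scores):
                rows.append({"term": cand.name, "cvll": s,
                             "delta_cvll": s - current_cvll, "retained": False})
            break
        rows.append({"term": best_cand.name, "cvll": best_score,
                     "delta_cvll": delta, "retained": True})
        selected.append(best_cand)
        remaining.pop(order)
        current_cvll = best_score
    table = pd.DataFrame(rows)
    model = fit_iwlr(records, selected, W=W)
    return table, model


def predict_relative_rate(model: FittedHabitatModel, covariate: str,
                          values: np.ndarray,
                          records: pd.DataFrame) -> pd.DataFrame:
    """Profile effect curve: vary one covariate, hold others at medians.

    Factors sit at their reference (first) level. Returns the relative
    sighting rate exp(linear predictor) with an extrapolation flag for
    values outside the training range.
    """
    values = np.asarray(values, dtype=float)
    profile: dict = {}
    for spec in model.terms:
        for cov in spec.covariates:
            if cov == covariate:
                continue
            if spec.basis == "factor":
                levels = sorted(pd.unique(records[cov]).tolist())
                profile[cov] = levels[0]
            else:
                profile[cov] = float(records[cov].median())
    data = pd.DataFrame({covariate: values})
    for k, v in profile.items():
        data[k] = v
    rate = np.exp(model.linear_predictor(data))
    lo, hi = records[covariate].min(), records[covariate].max()
    return pd.DataFrame({covariate: values, "relative_rate": rate,
                         "extrapolated": (values < lo) | (values > hi)})
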