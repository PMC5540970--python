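"""Estimation workflow: decay rates, Hill fits, kinetic refinement, tolerance index.

The calibration stack mirrors how the model's parameters are estimated
from bench experiments:

1. Two-stimulus tolerization assays give, per LPS dose, the fraction of
   control TNF remaining as a function of first-stimulus duration; a
   one-phase exponential decay fitted to each series estimates the
   activation rate at that dose (:func:`fit_decay`,
   :func:`build_activation_table`).
2. The dose → rate tables are fitted with a three-parameter Hill
   function by unweighted nonlinear least squares on the linear
   concentration scale with a log-spaced multistart on the
   half-saturation constant (:func:`fit_hill`).
3. Remaining kinetic parameters are refined against cytokine time
   courses by minimizing the total squared error between simulated and
   observed values over all doses simultaneously
   (:func:`refine_tnf_kinetics`, :func:`fit_ccl2_params`).
4. The intensity of endotoxin tolerance in an unknown culture is
   quantified by the tolerance index — the percentage of monocytes
   starting in the ET pool — estimated by a bounded 1-D search
   minimizing the variance-standardized squared error of the TNF and
   CCL2 predictions jointly (:func:`fit_tolerance_index`).

All fits are deterministic given the data, bounds and the documented
start grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .errors import ConfigurationError, FitError
from .model import ModelParameters
from .simulate import DEFAULT_STEP_H, Scenario, simulate

__all__ = [
    "DoseRateTable",
    "DecaySeries",
    "FitResult",
    "fit_hill",
    "fit_decay",
    "build_activation_table",
    "refine_tnf_kinetics",
    "fit_ccl2_params",
    "fit_tolerance_index",
    "TNF_FREE_PARAMS",
    "CCL2_FREE_PARAMS",
]

#: parameters refined jointly against TNF time courses
TNF_FREE_PARAMS = ("sc50", "immunomodulation_rate", "lps_removal_rate", "tnf_degradation_rate")
#: parameters optimized against CCL2 time courses
CCL2_FREE_PARAMS = (
    "ccl2_synth_resting",
    "ccl2_synth_inflammatory",
    "ccl2_synth_et",
    "ccl2_degradation_rate",
)

# convergence: relative SSE change below this is "converged" for multistarts
_FTOL = 1e-12
_XTOL = 1e-12


@dataclass(frozen=True)
class DoseRateTable:
    """(LPS concentration, rate) pairs for Hill dose–response calibration."""

    lps: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        lps = np.asarray(self.lps, dtype=float)
        rate = np.asarray(self.rate, dtype=float)
        object.__setattr__(self, "lps", lps)
        object.__setattr__(self, "rate", rate)
        if lps.ndim != 1 or lps.shape != rate.shape:
            raise ConfigurationError("lps and rate must be 1-D arrays of equal length")
        if (lps < 0).any():
            raise ConfigurationError("LPS concentrations must be >= 0")
        if len(np.unique(lps)) != len(lps):
            raise ConfigurationError("LPS concentrations must be distinct")
        if (rate < 0).any():
            raise ConfigurationError("rates must be >= 0")

    def __len__(self) -> int:
        return len(self.lps)

    @classmethod
    def from_pairs(cls, pairs: Sequence) -> "DoseRateTable":
        arr = np.asarray(pairs, dtype=float)
        return cls(lps=arr[:, 0], rate=arr[:, 1])

    @classmethod
    def from_csv(cls, path_or_buf) -> "DoseRateTable":
        """Read a two-column CSV (first column LPS ng/ml, second the rate)."""
        df = pd.read_csv(path_or_buf, comment="#")
        if df.shape[1] < 2:
            raise ConfigurationError("dose-rate CSV needs two columns (lps, rate)")
        return cls(lps=df.iloc[:, 0].to_numpy(float), rate=df.iloc[:, 1].to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lps_ng_ml": self.lps, "rate": self.rate})


@dataclass(frozen=True)
class DecaySeries:
    """Fraction-of-control TNF response (%) versus first-stimulus duration.

    ``t_s`` is the duration of the first LPS exposure in hours;
    ``relative_pct`` is TNF after a standard second challenge, as a
    percentage of the unprimed control.  Must include the t_s = 0
    control point; small overshoots above 100% (up to 110) are allowed.
    """

    t_s: np.ndarray
    relative_pct: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        r = np.asarray(self.relative_pct, dtype=float)
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "relative_pct", r)
        if t.ndim != 1 or t.shape != r.shape:
            raise ConfigurationError("t_s and relative_pct must be 1-D arrays of equal length")
        if (t < 0).any():
            raise ConfigurationError("t_s values must be >= 0")
        if not np.isclose(t, 0.0).any():
            raise ConfigurationError("a decay series must include the t_s = 0 control point")
        if (r < 0).any() or (r > 110).any():
            raise ConfigurationError("relative responses must lie in [0, 110] %")

    def __len__(self) -> int:
        return len(self.t_s)

    @classmethod
    def from_csv(cls, path_or_buf) -> "DecaySeries":
        df = pd.read_csv(path_or_buf, comment="#")
        return cls(t_s=df.iloc[:, 0].to_numpy(float), relative_pct=df.iloc[:, 1].to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s_h": self.t_s, "relative_pct": self.relative_pct})


@dataclass
class FitResult:
    """Outcome of a calibration fit."""

    estimates: dict
    sse: float
    n_points: int
    converged: bool
    message: str = ""
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "sse": float(self.sse),
            "n_points": int(self.n_points),
            "converged": bool(self.converged),
            "message": self.message,
            "meta": self.meta,
        }


def _hill_curve(lps: np.ndarray, vmax: float, c50: float, coef: float) -> np.ndarray:
    out = np.zeros_like(lps)
    pos = lps > 0
    x = np.exp(coef * (np.log(lps[pos]) - math.log(c50)))
    out[pos] = vmax * x / (1.0 + x)
    return out


def fit_hill(
    table: DoseRateTable,
    bounds: Optional[dict] = None,
    starts: Optional[Sequence[dict]] = None,
) -> FitResult:
    """Fit ``rate = vmax * L^coef / (c50^coef + L^coef)`` to a dose–rate table.

    Unweighted SSE on the linear rate scale; the optimizer is restarted
    from a log-spaced grid of c50 values crossed with a small set of Hill
    coefficients, and the best of all converged starts is returned.
    Needs at least 4 rows for the 3-parameter fit.
    """
    if len(table) < 4:
        raise FitError(f"need >= 4 dose-rate rows for a 3-parameter Hill fit, got {len(table)}")
    rmax = float(table.rate.max())
    if bounds is None:
        vhi = 10.0 * rmax if rmax > 0 else 1.0
        bounds = {"vmax": (1e-12, vhi), "c50": (1e-4, 10.0), "coef": (0.1, 10.0)}
    for k, (lo, hi) in bounds.items():
        if lo <= 0 or hi <= lo:
            raise ConfigurationError(f"bounds for {k} must be positive with hi > lo")
    if starts is None:
        starts = [
            {"vmax": rmax if rmax > 0 else 0.5, "c50": c0, "coef": k0}
            for c0 in np.geomspace(bounds["c50"][0], bounds["c50"][1], 13)
            for k0 in (0.8, 1.5, 3.0)
        ]

    lo = np.array([bounds["vmax"][0], bounds["c50"][0], bounds["coef"][0]])
    hi = np.array([bounds["vmax"][1], bounds["c50"][1], bounds["coef"][1]])

    def residual(x):
        return _hill_curve(table.lps, *x) - table.rate

    best = None
    n_ok = 0
    for s in starts:
        x0 = np.clip([s["vmax"], s["c50"], s["coef"]], lo, hi)
        try:
            res = least_squares(residual, x0, bounds=(lo, hi), xtol=_XTOL, ftol=_FTOL, gtol=1e-14)
        except Exception:
            continue
        if not res.success:
            continue
        n_ok += 1
        sse = float(2.0 * res.cost)
        if best is None or sse < best[1] - _FTOL * max(best[1], 1.0):
            best = (res.x, sse)
    if best is None:
        raise FitError(
            f"Hill fit failed to converge from any of {len(starts)} starts "
            f"(bounds {bounds})"
        )
    x, sse = best
    return FitResult(
        estimates={"vmax": x[0], "c50": x[1], "coef": x[2]},
        sse=sse,
        n_points=len(table),
        converged=True,
        meta={"bounds": {k: list(v) for k, v in bounds.items()}, "n_starts": len(starts),
              "n_converged_starts": n_ok},
    )


def fit_decay(series: DecaySeries) -> FitResult:
    """Fit a one-phase decay ``100 * exp(-a * t_s)`` to a relative-response series.

    Unweighted least squares with ``a >= 0``.  A non-decaying series
    yields ``a = 0`` at the bound with an explanatory message rather
    than an exception.
    """
    if len(np.unique(series.t_s)) < 3:
        raise FitError(f"need >= 3 distinct t_s points, got {len(np.unique(series.t_s))}")
    t, y = series.t_s, series.relative_pct
    # starting value from a log-linear regression on the decaying points
    mask = (y > 0) & (t > 0)
    if mask.sum() >= 1:
        a0 = max(float(np.mean(-np.log(np.minimum(y[mask], 100.0) / 100.0) / t[mask])), 1e-6)
    else:
        a0 = 1.0

    def residual(x):
        return 100.0 * np.exp(-x[0] * t) - y

    res = least_squares(residual, [a0], bounds=([0.0], [np.inf]), xtol=_XTOL, ftol=_FTOL)
    a = float(res.x[0])
    sse = float(2.0 * res.cost)
    message = ""
    sse_zero = float(np.sum((100.0 - y) ** 2))
    if a <= 1e-8 or sse_zero <= sse * (1.0 + 1e-12):
        a, sse = 0.0, sse_zero
        message = "no decay detected (rate estimate at the zero bound)"
    return FitResult(
        estimates={"decay_rate": a},
        sse=sse,
        n_points=len(series),
        converged=bool(res.success),
        message=message,
    )


def build_activation_table(series_by_dose: Mapping[float, DecaySeries]) -> DoseRateTable:
    """Fit a one-phase decay per dose and assemble the dose → activation-rate table."""
    if not series_by_dose:
        raise FitError("series_by_dose is empty: at least one dose is required")
    doses, rates = [], []
    for dose in sorted(series_by_dose, reverse=True):
        try:
            fit = fit_decay(series_by_dose[dose])
        except FitError as exc:
            raise FitError(f"decay fit failed at LPS dose {dose} ng/ml: {exc}") from exc
        doses.append(float(dose))
        rates.append(fit.estimates["decay_rate"])
    return DoseRateTable(lps=np.array(doses), rate=np.array(rates))


def _as_time_values(course, column: str):
    """Accept a DataFrame with time_h + value column, or a (times, values) pair."""
    if isinstance(course, pd.DataFrame):
        if "time_h" not in course.columns:
            raise ConfigurationError("time course frame needs a 'time_h' column")
        col = column if column in course.columns else course.columns[1]
        return course["time_h"].to_numpy(float), course[col].to_numpy(float)
    t, y = course
    return np.asarray(t, dtype=float), np.asarray(y, dtype=float)


def _weak_identification_message(residual_fn, x_best, sse, n, names) -> str:
    """Flag parameters whose linearized relative standard error exceeds 50%."""
    k = len(x_best)
    if n <= k:
        return "underdetermined: fewer points than free parameters"
    try:
        eps = 1e-6
        r0 = residual_fn(x_best)
        J = np.empty((len(r0), k))
        for j in range(k):
            xp = x_best.copy()
            xp[j] += eps
            J[:, j] = (residual_fn(xp) - r0) / eps
        s2 = sse / (n - k)
        cov = s2 * np.linalg.pinv(J.T @ J)
        rel_se = np.sqrt(np.maximum(np.diag(cov), 0.0))  # log-space SE == relative SE
        weak = [nm for nm, se in zip(names, rel_se) if se > 0.5]
        if weak:
            return "weakly identified: " + ", ".join(weak)
    except Exception:
        pass
    return ""


def _fit_simulated_courses(
    courses: Sequence,
    free: Sequence[str],
    p0: ModelParameters,
    start_overrides: Sequence[dict],
    column: str,
    step: float,
) -> FitResult:
    """Shared engine: minimize total SSE of simulate() outputs vs observed series.

    ``courses`` is a sequence of (scenario, times, observed) triples;
    free parameters are optimized in log space (positivity for free).
    """
    names = list(free)
    unknown = [n for n in names if n not in ModelParameters.field_names()]
    if unknown:
        raise ConfigurationError(f"unknown free parameters: {unknown}")
    n_total = sum(len(t) for _, t, _ in courses)

    def params_at(x) -> ModelParameters:
        return p0.replace(**{n: float(np.exp(v)) for n, v in zip(names, x)})

    def residual(x):
        p = params_at(x)
        out = []
        for scenario, times, obs in courses:
            sim = simulate(scenario, p, step=step, output_times=times)
            out.append(sim.column(column) - obs)
        return np.concatenate(out)

    if n_total <= len(names):
        sse = float(np.sum(residual(np.log([getattr(p0, n) for n in names])) ** 2))
        return FitResult(
            estimates={n: getattr(p0, n) for n in names},
            sse=sse,
            n_points=n_total,
            converged=False,
            message=f"underdetermined: {n_total} points for {len(names)} free parameters",
        )

    x0_base = np.log(np.maximum([getattr(p0, n) for n in names], 1e-12))
    lo = x0_base - math.log(1e4)
    hi = x0_base + math.log(1e4)
    best = None
    for over in start_overrides:
        x0 = x0_base.copy()
        for nm, v in over.items():
            x0[names.index(nm)] = math.log(max(v, 1e-12))
        try:
            res = least_squares(
                residual, np.clip(x0, lo, hi), bounds=(lo, hi), xtol=_XTOL, ftol=_FTOL
            )
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        if best is None or sse < best[1]:
            best = (res, sse)
    if best is None:
        raise FitError("kinetic refinement failed from every start")
    res, sse = best
    message = _weak_identification_message(residual, res.x, sse, n_total, names)
    return FitResult(
        estimates={n: float(np.exp(v)) for n, v in zip(names, res.x)},
        sse=sse,
        n_points=n_total,
        converged=bool(res.success),
        message=message,
        meta={"free": names, "n_starts": len(start_overrides)},
    )


def refine_tnf_kinetics(
    timecourses: Mapping[float, object],
    p0: Optional[ModelParameters] = None,
    free: Sequence[str] = TNF_FREE_PARAMS,
    *,
    total_monocytes: float = 1e6,
    step: float = DEFAULT_STEP_H,
) -> FitResult:
    """Jointly refine kinetic parameters against TNF time courses.

    ``timecourses`` maps an initial LPS dose (ng/ml) to an observed TNF
    series (DataFrame with ``time_h``/``tnf_pg`` or a (times, values)
    pair) from a culture of ``total_monocytes`` resting cells.  All doses
    enter one objective so a single parameter set must explain every
    scenario.  A coarse multistart on sc50 guards against local minima.
    """
    if p0 is None:
        p0 = ModelParameters()
    if not timecourses:
        raise FitError("no time courses supplied")
    courses = []
    for dose, course in sorted(timecourses.items(), reverse=True):
        t, y = _as_time_values(course, "tnf_pg")
        scen = Scenario(
            initial_resting=total_monocytes,
            initial_proinflammatory=0.0,
            initial_et=0.0,
            initial_lps=float(dose),
            horizon=float(t.max()),
            output_step=float(t.max()),
        )
        courses.append((scen, t, y))
    starts = [{}]
    if "sc50" in free:
        starts = [{"sc50": p0.sc50 * f} for f in (1.0, 0.25, 4.0)]
    return _fit_simulated_courses(courses, free, p0, starts, "tnf_pg", step)


#: scenarios behind the named CCL2 calibration series (10^6 monocytes)
_CCL2_SCENARIOS = {
    "control": dict(resting=1e6, proinflammatory=0.0, et=0.0, lps=5.0),
    "et": dict(resting=0.0, proinflammatory=75_000.0, et=925_000.0, lps=5.0),
    "basal": dict(resting=1e6, proinflammatory=0.0, et=0.0, lps=0.0),
}


def fit_ccl2_params(
    timecourses: Mapping[str, object],
    p0: Optional[ModelParameters] = None,
    *,
    step: float = DEFAULT_STEP_H,
) -> FitResult:
    """Optimize the three CCL2 synthesis rates and the degradation rate.

    ``timecourses`` maps scenario names (``control``: 10^6 resting cells
    + 5 ng/ml LPS; ``et``: the 0/75,000/925,000 tolerant split + 5 ng/ml;
    optionally ``basal``: unchallenged) to observed CCL2 series.  The
    result's ``message`` flags weakly identified parameters (e.g. when
    the ET series does not separate the per-pool synthesis rates).
    """
    if p0 is None:
        p0 = ModelParameters()
    if not timecourses:
        raise FitError("no time courses supplied")
    courses = []
    for name, course in timecourses.items():
        if name not in _CCL2_SCENARIOS:
            raise ConfigurationError(
                f"unknown CCL2 scenario {name!r}; valid: {sorted(_CCL2_SCENARIOS)}"
            )
        t, y = _as_time_values(course, "ccl2_pg")
        spec = _CCL2_SCENARIOS[name]
        scen = Scenario(
            initial_resting=spec["resting"],
            initial_proinflammatory=spec["proinflammatory"],
            initial_et=spec["et"],
            initial_lps=spec["lps"],
            horizon=float(t.max()),
            output_step=float(t.max()),
        )
        courses.append((scen, t, y))
    return _fit_simulated_courses(courses, CCL2_FREE_PARAMS, p0, [{}], "ccl2_pg", step)


def fit_tolerance_index(
    observed,
    total: float,
    p: Optional[ModelParameters] = None,
    *,
    initial_lps: float = 5.0,
    step: float = DEFAULT_STEP_H,
) -> FitResult:
    """Estimate the tolerance index (% of monocytes starting in ET) of a culture.

    ``observed`` is a DataFrame with ``time_h``, ``tnf_pg`` and
    ``ccl2_pg`` columns measured after an LPS challenge of ``initial_lps``
    ng/ml applied to ``total`` monocytes.  The objective is the sum of the
    two per-cytokine SSEs, each divided by the variance of its observed
    series so that neither cytokine's scale dominates; it is minimized by
    a coarse scan over [0, 100] followed by a bounded golden-section
    refinement (always returns, no convergence failure mode).
    """
    from .scenarios import ToleranceScenario, tolerance_index_to_initial_states

    if p is None:
        p = ModelParameters()
    if total <= 0:
        raise ConfigurationError(f"total monocyte count must be > 0, got {total}")
    if not isinstance(observed, pd.DataFrame) or len(observed) == 0:
        raise ConfigurationError("observed must be a non-empty DataFrame")
    for col in ("time_h", "tnf_pg", "ccl2_pg"):
        if col not in observed.columns:
            raise ConfigurationError(f"observed is missing column {col!r}")
    t = observed["time_h"].to_numpy(float)
    tnf_obs = observed["tnf_pg"].to_numpy(float)
    ccl2_obs = observed["ccl2_pg"].to_numpy(float)
    w_tnf = float(np.var(tnf_obs))
    w_ccl2 = float(np.var(ccl2_obs))
    w_tnf = w_tnf if w_tnf > 0 else 1.0
    w_ccl2 = w_ccl2 if w_ccl2 > 0 else 1.0
    horizon = float(t.max())

    def objective(index: float) -> float:
        ts = ToleranceScenario(
            total_monocytes=total,
            tolerance_index=float(np.clip(index, 0.0, 100.0)),
            initial_lps=initial_lps,
            horizon=horizon,
            output_step=horizon,
        )
        traj = simulate(tolerance_index_to_initial_states(ts), p, step=step, output_times=t)
        sse_tnf = float(np.sum((traj.column("tnf_pg") - tnf_obs) ** 2))
        sse_ccl2 = float(np.sum((traj.column("ccl2_pg") - ccl2_obs) ** 2))
        return sse_tnf / w_tnf + sse_ccl2 / w_ccl2

    grid = np.linspace(0.0, 100.0, 51)
    vals = [objective(g) for g in grid]
    i_best = int(np.argmin(vals))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4})
    cand = [(float(res.x), float(res.fun)), (float(grid[i_best]), float(vals[i_best]))]
    index, obj = min(cand, key=lambda c: c[1])
    return FitResult(
        estimates={"tolerance_index": index},
        sse=obj,
        n_points=2 * len(t),
        converged=True,
        meta={"objective": "sse_tnf/var_tnf + sse_ccl2/var_ccl2", "grid_points": len(grid)},
    )
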