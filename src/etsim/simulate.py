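"""Scenario definition and integration of the delayed six-stock system.

``simulate`` advances the mass balances of the three monocyte pools, LPS,
TNF and CCL2 with a fixed-step classical RK4 scheme (default h = 0.005 h)
using the method of steps for the TNF-production delay: the step must
divide the delay exactly so delayed values are read from stored nodes.
The pre-history is constant — before t = 0 the proinflammatory pool
equals its initial value, matching an experiment that starts at the
stimulus.  States are never clamped; a state below −1e-9 × the initial
monocyte total raises :class:`~etsim.errors.NumericalError` instead of
being silently repaired.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _integrator
from .errors import ConfigurationError, NumericalError
from .model import FlowVector, ModelParameters, ModelState, flows as eval_flows

__all__ = [
    "Scenario",
    "Trajectory",
    "simulate",
    "cascade_closed_form",
    "DEFAULT_STEP_H",
]

#: default RK4 step, hours; divides the default 1 h TNF delay exactly
DEFAULT_STEP_H = 0.005

_STATE_COLS = ["resting", "proinflammatory", "et", "lps_ng_ml", "tnf_pg", "ccl2_pg"]
_FLOW_COLS = [
    "activation",
    "immunomodulation",
    "lps_removal",
    "tnf_production",
    "tnf_degradation",
    "ccl2_production",
    "ccl2_degradation",
]


@dataclass(frozen=True)
class Scenario:
    """Initial conditions and output grid for one simulation run.

    Monocyte counts and cytokine masses must be non-negative; the default
    24 h horizon sampled every 0.1 h matches the span of the published
    time-course experiments.
    """

    initial_resting: float
    initial_proinflammatory: float
    initial_et: float
    initial_lps: float
    initial_tnf: float = 0.0
    initial_ccl2: float = 0.0
    horizon: float = 24.0
    output_step: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "initial_resting",
            "initial_proinflammatory",
            "initial_et",
            "initial_lps",
            "initial_tnf",
            "initial_ccl2",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v}")
        if self.horizon <= 0:
            raise ConfigurationError(f"horizon must be > 0, got {self.horizon}")
        if not (0 < self.output_step <= self.horizon):
            raise ConfigurationError(
                f"output_step must be in (0, horizon], got {self.output_step}"
            )

    @property
    def initial_state(self) -> ModelState:
        return ModelState(
            resting=self.initial_resting,
            proinflammatory=self.initial_proinflammatory,
            et=self.initial_et,
            lps=self.initial_lps,
            tnf=self.initial_tnf,
            ccl2=self.initial_ccl2,
        )

    @classmethod
    def from_state(cls, state: ModelState, horizon: float, output_step: float = 0.1) -> "Scenario":
        """Continue from an existing state (used to chain protocol phases)."""
        return cls(
            initial_resting=state.resting,
            initial_proinflammatory=state.proinflammatory,
            initial_et=state.et,
            initial_lps=state.lps,
            initial_tnf=state.tnf,
            initial_ccl2=state.ccl2,
            horizon=horizon,
            output_step=output_step,
        )


@dataclass
class Trajectory:
    """Time-indexed solution: states and evaluated flows on the output grid."""

    frame: pd.DataFrame
    parameters: ModelParameters
    scenario: Scenario

    @property
    def times(self) -> np.ndarray:
        return self.frame["time_h"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    def state(self, i: int) -> ModelState:
        row = self.frame.iloc[i]
        return ModelState(
            resting=row["resting"],
            proinflammatory=row["proinflammatory"],
            et=row["et"],
            lps=row["lps_ng_ml"],
            tnf=row["tnf_pg"],
            ccl2=row["ccl2_pg"],
        )

    @property
    def states(self) -> list:
        return [self.state(i) for i in range(len(self))]

    def flow(self, i: int) -> FlowVector:
        row = self.frame.iloc[i]
        return FlowVector(**{c: row[c] for c in _FLOW_COLS})

    @property
    def final_state(self) -> ModelState:
        return self.state(len(self) - 1)

    def to_csv(self, path_or_buf, include_flows: bool = True, header_lines: Sequence[str] = ()) -> None:
        """Write the trajectory; '#' comment lines embed the parameter set."""
        cols = ["time_h"] + _STATE_COLS + (_FLOW_COLS if include_flows else [])
        buf = io.StringIO()
        for line in header_lines:
            buf.write(f"# {line}\n")
        for k, v in self.parameters.to_dict().items():
            buf.write(f"# param {k} = {v:.10g}\n")
        self.frame[cols].to_csv(buf, index=False, float_format="%.10g")
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf, parameters: Optional[ModelParameters] = None) -> "Trajectory":
        """Read a trajectory written by :meth:`to_csv`.

        Parameters embedded in the '#' header are recovered unless an
        explicit set is given.
        """
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        params = {}
        for line in text.splitlines():
            if line.startswith("# param "):
                k, _, v = line[len("# param "):].partition(" = ")
                params[k.strip()] = float(v)
        frame = pd.read_csv(io.StringIO(text), comment="#")
        if parameters is None:
            parameters = ModelParameters(**params) if params else ModelParameters()
        t = frame["time_h"].to_numpy()
        row0 = frame.iloc[0]
        scenario = Scenario(
            initial_resting=max(row0["resting"], 0.0),
            initial_proinflammatory=max(row0["proinflammatory"], 0.0),
            initial_et=max(row0["et"], 0.0),
            initial_lps=max(row0["lps_ng_ml"], 0.0),
            initial_tnf=max(row0["tnf_pg"], 0.0),
            initial_ccl2=max(row0["ccl2_pg"], 0.0),
            horizon=float(t[-1]) if t[-1] > 0 else 1.0,
            output_step=float(t[1] - t[0]) if len(t) > 1 else 1.0,
        )
        return cls(frame=frame, parameters=parameters, scenario=scenario)


def _params_vector(p: ModelParameters) -> np.ndarray:
    return np.array([getattr(p, name) for name in ModelParameters.field_names()])


def _sample(nodes_t: np.ndarray, nodes_y: np.ndarray, t_out: np.ndarray, h: float) -> np.ndarray:
    """Sample node values at t_out; exact node reads, cubic off-grid."""
    idx = t_out / h
    idx_round = np.rint(idx)
    on_grid = np.abs(idx - idx_round) < 1e-9
    out = np.empty((len(t_out), nodes_y.shape[1]))
    if on_grid.all():
        out[:] = nodes_y[idx_round.astype(np.int64)]
        return out
    from scipy.interpolate import CubicSpline

    cs = CubicSpline(nodes_t, nodes_y, axis=0)
    out[:] = cs(t_out)
    out[on_grid] = nodes_y[idx_round[on_grid].astype(np.int64)]
    return out


def simulate(
    scenario: Scenario,
    p: Optional[ModelParameters] = None,
    *,
    step: float = DEFAULT_STEP_H,
    output_times: Optional[np.ndarray] = None,
    include_flows: bool = True,
) -> Trajectory:
    """Integrate the model over a scenario.

    Parameters
    ----------
    scenario : Scenario
        Initial conditions, horizon and output grid.
    p : ModelParameters, optional
        Defaults to the published parameter set.
    step : float
        RK4 step in hours; must divide ``p.tnf_delay_td`` exactly.
    output_times : array-like, optional
        Explicit output grid (hours, within [0, horizon]); overrides the
        scenario's ``output_step``.
    """
    if p is None:
        p = ModelParameters()
    if step <= 0:
        raise ConfigurationError(f"step must be > 0, got {step}")
    td = p.tnf_delay_td
    td_steps_f = td / step
    td_steps = int(round(td_steps_f))
    if abs(td_steps_f - td_steps) > 1e-9:
        raise ConfigurationError(
            f"step {step} h does not divide the TNF delay {td} h exactly; "
            "choose a step h with tnf_delay_td/h integer"
        )

    if output_times is None:
        n_out = int(math.floor(scenario.horizon / scenario.output_step + 1e-9))
        t_out = np.arange(n_out + 1) * scenario.output_step
    else:
        t_out = np.asarray(output_times, dtype=float)
        if t_out.ndim != 1 or len(t_out) == 0:
            raise ConfigurationError("output_times must be a non-empty 1-D array")
        if (t_out < 0).any() or t_out[-1] > scenario.horizon + 1e-9:
            raise ConfigurationError("output_times must lie within [0, horizon]")
        if not (np.diff(t_out) > 0).all():
            raise ConfigurationError("output_times must be strictly increasing")

    n_steps = int(math.ceil(scenario.horizon / step - 1e-9))
    s0 = scenario.initial_state
    y0 = np.array([s0.resting, s0.proinflammatory, s0.et, s0.lps, s0.tnf, s0.ccl2])
    nodes = _integrator.integrate(y0, _params_vector(p), step, n_steps, td_steps)

    if not np.isfinite(nodes).all():
        bad = np.argwhere(~np.isfinite(nodes).all(axis=1)).ravel()[0]
        raise NumericalError(
            f"non-finite state encountered at t = {bad * step:.6g} h"
        )
    total0 = s0.total_monocytes
    floor = -1e-9 * total0 if total0 > 0 else -1e-12
    if nodes.min() < floor:
        raise NumericalError(
            f"state fell below {floor:.3g} during integration "
            "(integration bug, states are never clamped)"
        )

    nodes_t = np.arange(n_steps + 1) * step
    y_out = _sample(nodes_t, nodes, t_out, step)
    # exact initial state at t=0 (guards tiny interpolation round-off)
    y_out[0] = y0

    data = {"time_h": t_out}
    for k, col in enumerate(_STATE_COLS):
        data[col] = y_out[:, k]

    if include_flows:
        # delayed proinflammatory stock at t - TD (constant history before 0)
        if td_steps == 0:
            p_del = y_out[:, 1]
        else:
            t_del = t_out - td
            p_del = np.where(
                t_del <= 0,
                s0.proinflammatory,
                _sample(nodes_t, nodes[:, 1:2], np.clip(t_del, 0.0, None), step)[:, 0],
            )
        fmat = np.empty((len(t_out), len(_FLOW_COLS)))
        for i in range(len(t_out)):
            st = ModelState(
                resting=max(y_out[i, 0], 0.0),
                proinflammatory=max(y_out[i, 1], 0.0),
                et=max(y_out[i, 2], 0.0),
                lps=max(y_out[i, 3], 0.0),
                tnf=max(y_out[i, 4], 0.0),
                ccl2=max(y_out[i, 5], 0.0),
            )
            fv = eval_flows(st, max(p_del[i], 0.0), st.lps, p)
            fmat[i] = [getattr(fv, c) for c in _FLOW_COLS]
        for k, col in enumerate(_FLOW_COLS):
            data[col] = fmat[:, k]

    return Trajectory(frame=pd.DataFrame(data), parameters=p, scenario=scenario)


def cascade_closed_form(r0: float, a: float, i: float, t: float):
    """Analytic resting/proinflammatory/ET pools under a constant activation rate.

    Valid when the activation Hill term is constant (no LPS removal):
    the cascade R → P → E is linear with rates ``a`` and ``i`` and has the
    classical two-exponential solution.  Used as an independent oracle for
    the integrator; requires ``a != i`` (perturb ``a`` for the degenerate
    equal-rate case).
    """
    if a <= 0 or i <= 0:
        raise ValueError(f"rates must be positive, got a={a}, i={i}")
    if a == i:
        raise ValueError("degenerate case a == i; perturb a slightly")
    resting = r0 * math.exp(-a * t)
    proinf = a * r0 * (math.exp(-a * t) - math.exp(-i * t)) / (i - a)
    return resting, proinf, r0 - resting - proinf
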