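"""Published scenario presets, the tolerance index, and synthetic data generation.

The tolerance index quantifies endotoxin-tolerance intensity as the
percentage of an initial monocyte population starting in the ET pool;
:func:`tolerance_index_to_initial_states` converts it to explicit initial
conditions (proinflammatory cells start at zero because transit through
that pool is fast relative to the assay).

The synthetic generators are in-silico twins of the bench experiments the
calibration stack consumes: multi-dose cytokine time courses with
replicate measurement noise (:func:`generate_timecourse`) and the
two-stimulus tolerization protocol — prime, wash, 16 h rest, standard
5 ng/ml re-challenge for 3 h — yielding fraction-of-control TNF decay
series (:func:`generate_decay_protocol`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .calibrate import DecaySeries
from .errors import ConfigurationError, PresetError
from .model import ModelParameters
from .simulate import DEFAULT_STEP_H, Scenario, Trajectory, simulate

__all__ = [
    "ToleranceScenario",
    "NoiseSpec",
    "SyntheticTimecourse",
    "tolerance_index_to_initial_states",
    "preset",
    "PRESET_NAMES",
    "generate_timecourse",
    "generate_decay_protocol",
    "EXPERIMENTAL_GRID_H",
    "DEFAULT_TS_GRID_H",
]

#: sampling times (h) of the published cytokine time-course experiments
EXPERIMENTAL_GRID_H = (1.0, 2.0, 4.0, 8.0, 16.0, 24.0)

#: default first-stimulus durations (h) for the two-stimulus protocol
DEFAULT_TS_GRID_H = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)

#: duration of the post-wash rest phase (h) and of the second challenge (h)
REST_H = 16.0
CHALLENGE_H = 3.0
CHALLENGE_DOSE_NG_ML = 5.0


@dataclass(frozen=True)
class ToleranceScenario:
    """A culture summarized by its tolerance index instead of explicit pools."""

    total_monocytes: float
    tolerance_index: float
    initial_lps: float
    horizon: float = 24.0
    output_step: float = 0.1

    def __post_init__(self) -> None:
        if self.total_monocytes <= 0:
            raise ConfigurationError(
                f"total_monocytes must be > 0, got {self.total_monocytes}"
            )
        if not 0.0 <= self.tolerance_index <= 100.0:
            raise ConfigurationError(
                f"tolerance_index must lie in [0, 100], got {self.tolerance_index}"
            )
        if self.initial_lps < 0:
            raise ConfigurationError(f"initial_lps must be >= 0, got {self.initial_lps}")


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate measurement-noise model: y -> y*(1+eps_mult) + eps_add.

    ``eps_mult ~ N(0, multiplicative_cv^2)`` and
    ``eps_add ~ N(0, additive_sd^2)`` are drawn independently per
    measurement and replicate from a generator seeded with ``seed``.
    ``additive_sd`` is in pg for cytokine series and in percentage points
    for relative-response series.
    """

    additive_sd: float = 0.0
    multiplicative_cv: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.multiplicative_cv < 0:
            raise ConfigurationError("noise magnitudes must be >= 0")
        if self.replicates < 1:
            raise ConfigurationError(f"replicates must be >= 1, got {self.replicates}")


def tolerance_index_to_initial_states(ts: ToleranceScenario) -> Scenario:
    """Convert a tolerance index into explicit initial pool sizes.

    resting = total*(100 - index)/100, ET = total*index/100,
    proinflammatory = 0; cytokines start at zero.
    """
    frac = ts.tolerance_index / 100.0
    return Scenario(
        initial_resting=ts.total_monocytes * (1.0 - frac),
        initial_proinflammatory=0.0,
        initial_et=ts.total_monocytes * frac,
        initial_lps=ts.initial_lps,
        horizon=ts.horizon,
        output_step=ts.output_step,
    )


def _control(lps: float) -> Scenario:
    return Scenario(
        initial_resting=1e6, initial_proinflammatory=0.0, initial_et=0.0, initial_lps=lps
    )


_PRESETS = {
    # five cultures of 10^6 resting monocytes: 5, 0.25, 0.1, 0.05 ng/ml and unchallenged
    "fig4_dose_response": lambda: [_control(d) for d in (5.0, 0.25, 0.1, 0.05, 0.0)],
    # tolerized culture: 0 resting / 75,000 proinflammatory / 925,000 ET, 5 ng/ml
    "fig5_et": lambda: Scenario(
        initial_resting=0.0,
        initial_proinflammatory=75_000.0,
        initial_et=925_000.0,
        initial_lps=5.0,
    ),
    "fig5_control": lambda: _control(5.0),
    # intermediate tolerance: index fitted at 68% for 10^6 cells, 5 ng/ml challenge
    "fig6_tolerance": lambda: ToleranceScenario(
        total_monocytes=1e6, tolerance_index=68.0, initial_lps=5.0
    ),
    # septic-patient emulation: same operating point, 16 h readout
    "sepsis": lambda: ToleranceScenario(
        total_monocytes=1e6, tolerance_index=68.0, initial_lps=5.0, horizon=16.0
    ),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str) -> Union[Scenario, ToleranceScenario, list]:
    """Return the named published scenario (or list of scenarios)."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise PresetError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None
    return factory()


@dataclass
class SyntheticTimecourse:
    """Replicated synthetic cytokine measurements plus their mean ± SEM."""

    replicates: pd.DataFrame  # columns: replicate, time_h, tnf_pg, ccl2_pg
    summary: pd.DataFrame  # columns: time_h, tnf_pg, tnf_sem, ccl2_pg, ccl2_sem
    trajectory: Trajectory  # the noiseless underlying solution


def _apply_noise(values: np.ndarray, rng: np.random.Generator, noise: NoiseSpec) -> np.ndarray:
    mult = rng.normal(0.0, noise.multiplicative_cv, size=values.shape)
    add = rng.normal(0.0, noise.additive_sd, size=values.shape)
    return values * (1.0 + mult) + add


def generate_timecourse(
    scenario: Union[Scenario, ToleranceScenario],
    p: Optional[ModelParameters] = None,
    noise: NoiseSpec = NoiseSpec(),
    times: Sequence[float] = EXPERIMENTAL_GRID_H,
    *,
    step: float = DEFAULT_STEP_H,
) -> SyntheticTimecourse:
    """Simulate a scenario and emulate replicated cytokine measurements.

    Each replicate draws independent multiplicative and additive Gaussian
    noise per measurement; the summary table reports the replicate mean
    and standard error, mimicking mean ± SEM assay reports.  With zero
    noise and one replicate the output equals the simulation exactly.
    """
    if p is None:
        p = ModelParameters()
    if isinstance(scenario, ToleranceScenario):
        scenario = tolerance_index_to_initial_states(scenario)
    t = np.asarray(times, dtype=float)
    traj = simulate(scenario, p, step=step, output_times=t)
    rng = np.random.default_rng(noise.seed)
    rows = []
    for r in range(noise.replicates):
        tnf = _apply_noise(traj.column("tnf_pg"), rng, noise)
        ccl2 = _apply_noise(traj.column("ccl2_pg"), rng, noise)
        rows.append(
            pd.DataFrame(
                {"replicate": r, "time_h": t, "tnf_pg": tnf, "ccl2_pg": ccl2}
            )
        )
    reps = pd.concat(rows, ignore_index=True)
    g = reps.groupby("time_h")
    n = noise.replicates
    sem = 1.0 / math.sqrt(n) if n > 1 else 0.0
    summary = pd.DataFrame(
        {
            "time_h": t,
            "tnf_pg": g["tnf_pg"].mean().reindex(t).to_numpy(),
            "tnf_sem": (g["tnf_pg"].std(ddof=1).reindex(t).to_numpy() * sem if n > 1 else 0.0),
            "ccl2_pg": g["ccl2_pg"].mean().reindex(t).to_numpy(),
            "ccl2_sem": (g["ccl2_pg"].std(ddof=1).reindex(t).to_numpy() * sem if n > 1 else 0.0),
        }
    )
    return SyntheticTimecourse(replicates=reps, summary=summary, trajectory=traj)


def _challenge_tnf(state_resting: float, state_et: float, p: ModelParameters, step: float) -> float:
    """TNF after the standard 5 ng/ml, 3 h re-challenge of a washed culture."""
    scen = Scenario(
        initial_resting=state_resting,
        initial_proinflammatory=0.0,
        initial_et=state_et,
        initial_lps=CHALLENGE_DOSE_NG_ML,
        horizon=CHALLENGE_H,
        output_step=CHALLENGE_H,
    )
    return simulate(scen, p, step=step, include_flows=False).final_state.tnf


def generate_decay_protocol(
    lps_first: float,
    t_s_grid: Sequence[float] = DEFAULT_TS_GRID_H,
    p: Optional[ModelParameters] = None,
    noise: NoiseSpec = NoiseSpec(),
    *,
    step: float = DEFAULT_STEP_H,
) -> DecaySeries:
    """In-silico two-stimulus tolerization assay at one priming dose.

    For each first-stimulus duration t_s: simulate the priming stimulus at
    ``lps_first`` ng/ml for t_s hours; wash (LPS and accumulated TNF set
    to zero); rest 16 h in medium under the model's own dynamics; then —
    because the rest exists precisely to complete tolerization, and
    tolerized cells do not respond — reassign residual proinflammatory
    cells to the ET pool, reset TNF, and apply the standard 5 ng/ml
    challenge for 3 h.  The TNF read out is expressed as % of the
    t_s = 0 control run (which is the unprimed culture), so t_s = 0 is
    100% by construction.  Noise (per replicate, on the % scale for the
    additive part) is averaged over replicates; values are clamped to
    the valid [0, 110]% range.
    """
    if p is None:
        p = ModelParameters()
    if lps_first < 0:
        raise ConfigurationError(f"lps_first must be >= 0, got {lps_first}")
    t_s_grid = np.asarray(sorted(set(float(t) for t in t_s_grid)))
    if len(t_s_grid) == 0:
        raise ConfigurationError("t_s_grid must be non-empty")
    if not np.isclose(t_s_grid, 0.0).any():
        t_s_grid = np.concatenate([[0.0], t_s_grid])

    responses = np.empty(len(t_s_grid))
    for i, t_s in enumerate(t_s_grid):
        if t_s > 0 and lps_first > 0:
            prime = Scenario(
                initial_resting=1e6,
                initial_proinflammatory=0.0,
                initial_et=0.0,
                initial_lps=lps_first,
                horizon=float(t_s),
                output_step=float(t_s),
            )
            washed = simulate(prime, p, step=step, include_flows=False).final_state
            rest = Scenario(
                initial_resting=washed.resting,
                initial_proinflammatory=washed.proinflammatory,
                initial_et=washed.et,
                initial_lps=0.0,  # washed twice: no LPS carry-over
                initial_ccl2=washed.ccl2,
                horizon=REST_H,
                output_step=REST_H,
            )
            rested = simulate(rest, p, step=step, include_flows=False).final_state
            resting, et = rested.resting, rested.et + rested.proinflammatory
        else:
            resting, et = 1e6, 0.0
        responses[i] = _challenge_tnf(resting, et, p, step)

    control = responses[np.isclose(t_s_grid, 0.0)][0]
    rel = 100.0 * responses / control

    rng = np.random.default_rng(noise.seed)
    reps = np.empty((noise.replicates, len(rel)))
    for r in range(noise.replicates):
        noisy = _apply_noise(rel, rng, noise)
        noisy[np.isclose(t_s_grid, 0.0)] = 100.0  # self-normalized control
        reps[r] = np.clip(noisy, 0.0, 110.0)
    return DecaySeries(t_s=t_s_grid, relative_pct=reps.mean(axis=0))
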