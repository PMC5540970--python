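"""Core model: parameters, state, flows and the Hill auxiliaries.

The model partitions a monocyte culture into three functional pools —
resting, proinflammatory and endotoxin-tolerant (ET) — stimulated by
extracellular LPS.  Resting cells are activated at an LPS-dependent rate
(a Hill function of concentration), proinflammatory cells are
immunomodulated into the ET pool at a constant rate, and LPS itself is
cleared first-order.  A second subsystem tracks two cytokine masses:
TNFα, produced by proinflammatory cells with a fixed signalling delay and
an LPS-dependent per-cell synthesis rate, and CCL2, produced by all three
pools at pool-specific rates.  Both cytokines degrade first-order.

Units: monocyte pools are cell counts, LPS is a concentration in ng/ml
(a fixed 1 ml culture volume is assumed throughout, so the LPS stock and
its concentration are numerically identical), cytokines are masses in pg,
time is in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, asdict

from .errors import ConfigurationError

__all__ = [
    "ModelParameters",
    "ModelState",
    "FlowVector",
    "activation_rate",
    "tnf_synthesis_rate",
    "flows",
]


@dataclass(frozen=True)
class ModelParameters:
    """The 14 rate/shape constants of the calibrated model.

    Defaults are the published operating point of the model: Hill
    activation parameters estimated from two-stimulus tolerization assays,
    TNF synthesis parameters from dose–response time courses (with sc50,
    immunomodulation, LPS removal and TNF degradation jointly refined),
    and CCL2 parameters optimized against control/ET chemokine curves.

    Attributes
    ----------
    max_activation_rate : float
        Ceiling of the LPS→activation Hill function, per hour.
    ac50 : float
        LPS concentration giving half-maximal activation, ng/ml.
    hill_n : float
        Hill coefficient (steepness) of the activation function.
    immunomodulation_rate : float
        First-order proinflammatory→ET transition rate, per hour.
    lps_removal_rate : float
        First-order LPS clearance rate, per hour.
    max_tnf_synthesis_rate : float
        Ceiling of per-cell TNF synthesis, pg/h/monocyte.
    sc50 : float
        LPS concentration giving half-maximal TNF synthesis, ng/ml.
    hill_m : float
        Hill coefficient of the TNF synthesis function.
    tnf_delay_td : float
        Signalling delay between activation and TNF output, hours.
    tnf_degradation_rate : float
        First-order TNF decay, per hour.
    ccl2_synth_resting, ccl2_synth_inflammatory, ccl2_synth_et : float
        Per-cell CCL2 synthesis of each pool, pg/h/monocyte.
    ccl2_degradation_rate : float
        First-order CCL2 decay, per hour.
    """

    max_activation_rate: float = 4.4990
    ac50: float = 0.1889
    hill_n: float = 1.4825
    immunomodulation_rate: float = 0.1088
    lps_removal_rate: float = 0.0726
    max_tnf_synthesis_rate: float = 0.0071
    sc50: float = 0.0890
    hill_m: float = 1.7670
    tnf_delay_td: float = 1.0
    tnf_degradation_rate: float = 0.1362
    ccl2_synth_resting: float = 0.1315e-3
    ccl2_synth_inflammatory: float = 0.1315e-3
    ccl2_synth_et: float = 0.4633e-2
    ccl2_degradation_rate: float = 0.2828

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ConfigurationError(f"parameter {f.name} must be a finite number, got {v!r}")
            if v < 0:
                raise ConfigurationError(f"parameter {f.name} must be non-negative, got {v}")
        if self.hill_n <= 0:
            raise ConfigurationError(f"hill_n must be > 0, got {self.hill_n}")
        if self.hill_m <= 0:
            raise ConfigurationError(f"hill_m must be > 0, got {self.hill_m}")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (validated)."""
        d = asdict(self)
        for k in changes:
            if k not in d:
                raise ConfigurationError(f"unknown parameter {k!r}")
        d.update(changes)
        return ModelParameters(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class ModelState:
    """The six stocks at one instant.

    ``resting``, ``proinflammatory`` and ``et`` are monocyte counts;
    ``lps`` is ng/ml; ``tnf`` and ``ccl2`` are pg.
    """

    resting: float
    proinflammatory: float
    et: float
    lps: float
    tnf: float = 0.0
    ccl2: float = 0.0

    @property
    def total_monocytes(self) -> float:
        return self.resting + self.proinflammatory + self.et


@dataclass(frozen=True)
class FlowVector:
    """The seven instantaneous flows of the model.

    ``activation`` and ``immunomodulation`` are monocytes/h,
    ``lps_removal`` is ng/ml/h, the cytokine flows are pg/h.
    """

    activation: float
    immunomodulation: float
    lps_removal: float
    tnf_production: float
    tnf_degradation: float
    ccl2_production: float
    ccl2_degradation: float


def _hill(lps: float, vmax: float, c50: float, coef: float) -> float:
    if lps < 0:
        raise ValueError(f"LPS concentration must be non-negative, got {lps}")
    if lps == 0.0:
        return 0.0
    # compute in log space to tolerate extreme concentration/coefficient combinations
    x = math.exp(coef * (math.log(lps) - math.log(c50)))
    return vmax * x / (1.0 + x)


def activation_rate(lps: float, p: ModelParameters) -> float:
    """LPS-dependent monocyte activation rate (per hour).

    Hill saturation ``max_activation_rate * L^n / (ac50^n + L^n)``:
    zero at zero LPS, half-maximal at ``ac50``, bounded by the maximum.
    """
    return _hill(lps, p.max_activation_rate, p.ac50, p.hill_n)


def tnf_synthesis_rate(lps: float, p: ModelParameters) -> float:
    """LPS-dependent per-cell TNF synthesis rate (pg/h/monocyte).

    Hill saturation ``max_tnf_synthesis_rate * L^m / (sc50^m + L^m)``.
    """
    return _hill(lps, p.max_tnf_synthesis_rate, p.sc50, p.hill_m)


def flows(
    state_now: ModelState,
    proinflammatory_delayed: float,
    lps_now: float,
    p: ModelParameters,
) -> FlowVector:
    """Evaluate the seven instantaneous flows.

    ``proinflammatory_delayed`` is the proinflammatory pool
    ``tnf_delay_td`` hours earlier; TNF production multiplies that delayed
    stock by the synthesis rate evaluated at the *current* LPS
    concentration.  All other flows are products of a current stock and a
    rate.
    """
    s = state_now
    return FlowVector(
        activation=s.resting * activation_rate(lps_now, p),
        immunomodulation=s.proinflammatory * p.immunomodulation_rate,
        lps_removal=s.lps * p.lps_removal_rate,
        tnf_production=proinflammatory_delayed * tnf_synthesis_rate(lps_now, p),
        tnf_degradation=s.tnf * p.tnf_degradation_rate,
        ccl2_production=(
            s.resting * p.ccl2_synth_resting
            + s.proinflammatory * p.ccl2_synth_inflammatory
            + s.et * p.ccl2_synth_et
        ),
        ccl2_degradation=s.ccl2 * p.ccl2_degradation_rate,
    )
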