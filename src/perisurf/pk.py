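"""Two-compartment Dedrick model of intraperitoneal drug transfer.

The model is an application of Fick's law: the instantaneous rate of drug
mass transfer from the peritoneal cavity to the blood is

    rate (mg/min) = PA · (C_P − C_B)

where PA is the permeability–area product (membrane permeability P times
the effective peritoneal contact area A — typically the remaining PSA after
cytoreductive surgery), C_P the peritoneal and C_B the blood concentration.
The full dynamic system realized here — initial conditions, a first-order
body elimination term, AUC outputs — is an extension of that rate law,
needed to make the dose-adjustment argument quantitative:

    dC_P/dt = −(PA/V_P)(C_P − C_B)
    dC_B/dt = +(PA/V_B)(C_P − C_B) − k_e · C_B
    C_P(0) = dose / V_P,   C_B(0) = 0

Unit conventions (printed in every output header): P in cm/min, A in cm²,
volumes in L, concentrations in mg/L, time in min. The cm³→L factor
(1/1000) is applied exactly once, inside the PA usage.

The system is linear and non-stiff, so a fixed-step classical RK4
integrator is used: deterministic, and directly comparable with the
closed-form double-exponential solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PKScenario",
    "PKTrajectory",
    "SensitivityRow",
    "UNIT_CONVENTIONS",
    "effective_permeability_area",
    "mass_transfer_rate",
    "simulate",
    "psa_sensitivity",
]

UNIT_CONVENTIONS = (
    "permeability_cm_per_min, area_cm2, volumes_L, concentrations_mg_per_L, "
    "time_min, dose_mg, auc_mg_min_per_L"
)

CM3_PER_L = 1000.0


class PKError(ValueError):
    """Raised for invalid scenario parameters or a diverged integration."""


def effective_permeability_area(permeability_cm_per_min: float, area_cm2: float) -> float:
    """Permeability–area product PA = P · A, in cm³/min."""
    if not math.isfinite(permeability_cm_per_min) or permeability_cm_per_min <= 0:
        raise PKError(f"permeability must be > 0, got {permeability_cm_per_min!r}")
    if not math.isfinite(area_cm2) or area_cm2 < 0:
        raise PKError(f"area must be >= 0, got {area_cm2!r}")
    return permeability_cm_per_min * area_cm2


def mass_transfer_rate(pa_cm3_per_min: float, c_p_mg_per_L: float, c_b_mg_per_L: float) -> float:
    """Instantaneous peritoneum→blood mass transfer rate, mg/min.

    Positive when the peritoneal concentration exceeds the blood
    concentration. The cm³/min permeability–area is converted to L/min
    internally so that multiplying by mg/L yields mg/min.
    """
    if not math.isfinite(pa_cm3_per_min) or pa_cm3_per_min < 0:
        raise PKError(f"PA must be >= 0, got {pa_cm3_per_min!r}")
    return (pa_cm3_per_min / CM3_PER_L) * (c_p_mg_per_L - c_b_mg_per_L)


@dataclass(frozen=True)
class PKScenario:
    """Parameters of one simulation run.

    ``area_cm2`` is the effective contact area — typically ``psa_after_cm2``
    from a patient's surface report. ``elimination_rate_per_min`` (k_e) is
    first-order clearance from the body compartment; 0 models a closed
    system. No clinical default permeability is shipped: published values
    are drug-specific and must be supplied by the user.
    """

    permeability_cm_per_min: float
    area_cm2: float
    volume_peritoneal_L: float
    volume_body_L: float
    dose_mg: float
    duration_min: float
    step_min: float = 0.1
    elimination_rate_per_min: float = 0.0

    def __post_init__(self) -> None:
        positive = {
            "permeability_cm_per_min": self.permeability_cm_per_min,
            "volume_peritoneal_L": self.volume_peritoneal_L,
            "volume_body_L": self.volume_body_L,
            "duration_min": self.duration_min,
            "step_min": self.step_min,
        }
        for name, v in positive.items():
            if not isinstance(v, (int, float)) or not math.isfinite(v) or v <= 0:
                raise PKError(f"{name} must be finite and > 0, got {v!r}")
        nonneg = {
            "area_cm2": self.area_cm2,
            "dose_mg": self.dose_mg,
            "elimination_rate_per_min": self.elimination_rate_per_min,
        }
        for name, v in nonneg.items():
            if not isinstance(v, (int, float)) or not math.isfinite(v) or v < 0:
                raise PKError(f"{name} must be finite and >= 0, got {v!r}")
        if self.step_min > self.duration_min:
            raise PKError(
                f"step_min ({self.step_min}) must not exceed duration_min ({self.duration_min})"
            )

    @property
    def pa_cm3_per_min(self) -> float:
        return effective_permeability_area(self.permeability_cm_per_min, self.area_cm2)


@dataclass(frozen=True)
class PKTrajectory:
    """Sampled concentration time courses and integral summaries."""

    time_min: np.ndarray
    c_peritoneal_mg_per_L: np.ndarray
    c_blood_mg_per_L: np.ndarray
    eliminated_mg: np.ndarray
    auc_peritoneal_mg_min_per_L: float
    auc_blood_mg_min_per_L: float
    half_equilibration_min: float | None  # None when PA = 0 (sealed membrane)
    scenario: PKScenario

    def mass_in_system_mg(self) -> np.ndarray:
        """V_P·C_P + V_B·C_B at every output time (conservation diagnostic)."""
        s = self.scenario
        return (
            s.volume_peritoneal_L * self.c_peritoneal_mg_per_L
            + s.volume_body_L * self.c_blood_mg_per_L
        )

    def summary(self) -> dict:
        return {
            "units": UNIT_CONVENTIONS,
            "auc_peritoneal_mg_min_per_L": self.auc_peritoneal_mg_min_per_L,
            "auc_blood_mg_min_per_L": self.auc_blood_mg_min_per_L,
            "half_equilibration_min": self.half_equilibration_min,
            "final_c_peritoneal_mg_per_L": float(self.c_peritoneal_mg_per_L[-1]),
            "final_c_blood_mg_per_L": float(self.c_blood_mg_per_L[-1]),
            "final_eliminated_mg": float(self.eliminated_mg[-1]),
        }


def _rhs(state: np.ndarray, pa_L_per_min: float, s: PKScenario) -> np.ndarray:
    c_p, c_b, eliminated, auc_p, auc_b = state
    flux = pa_L_per_min * (c_p - c_b)  # mg/min
    return np.array(
        [
            -flux / s.volume_peritoneal_L,
            flux / s.volume_body_L - s.elimination_rate_per_min * c_b,
            s.elimination_rate_per_min * s.volume_body_L * c_b,
            c_p,
            c_b,
        ]
    )


def simulate(scenario: PKScenario) -> PKTrajectory:
    """Integrate the two-compartment system with fixed-step classical RK4.

    AUCs are accumulated as auxiliary quadrature states, so they carry the
    same fourth-order accuracy as the concentrations. The half-equilibration
    time (first time the peritoneal–blood concentration gap falls to half
    its initial value) is located by linear interpolation on the output
    grid; it is None for a sealed membrane (PA = 0) and when the gap never
    halves within the simulated duration.
    """
    s = scenario
    pa_L = s.pa_cm3_per_min / CM3_PER_L
    n_steps = int(math.ceil(s.duration_min / s.step_min - 1e-12))
    # uniform grid landing exactly on the duration
    h = s.duration_min / n_steps
    times = np.linspace(0.0, s.duration_min, n_steps + 1)

    state = np.array([s.dose_mg / s.volume_peritoneal_L, 0.0, 0.0, 0.0, 0.0])
    out = np.empty((n_steps + 1, 5))
    out[0] = state
    for i in range(n_steps):
        k1 = _rhs(state, pa_L, s)
        k2 = _rhs(state + 0.5 * h * k1, pa_L, s)
        k3 = _rhs(state + 0.5 * h * k2, pa_L, s)
        k4 = _rhs(state + h * k3, pa_L, s)
        state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise PKError(
                f"non-finite state at t={times[i + 1]:.6g} min "
                f"(step {h:.6g} min): {state!r}"
            )
        out[i + 1] = state

    c_p, c_b = out[:, 0], out[:, 1]
    gap = c_p - c_b
    half_t: float | None = None
    if pa_L > 0 and gap[0] > 0:
        target = gap[0] / 2.0
        below = np.nonzero(gap <= target)[0]
        if below.size:
            j = int(below[0])
            if j == 0:
                half_t = 0.0
            else:
                t0, t1 = times[j - 1], times[j]
                g0, g1 = gap[j - 1], gap[j]
                half_t = float(t0 + (g0 - target) / (g0 - g1) * (t1 - t0))

    return PKTrajectory(
        time_min=times,
        c_peritoneal_mg_per_L=c_p,
        c_blood_mg_per_L=c_b,
        eliminated_mg=out[:, 2],
        auc_peritoneal_mg_min_per_L=float(out[-1, 3]),
        auc_blood_mg_min_per_L=float(out[-1, 4]),
        half_equilibration_min=half_t,
        scenario=s,
    )


@dataclass(frozen=True)
class SensitivityRow:
    psa_cm2: float
    auc_peritoneal_mg_min_per_L: float
    auc_blood_mg_min_per_L: float
    half_equilibration_min: float | None


def psa_sensitivity(
    template: PKScenario, psa_values_cm2: Sequence[float]
) -> list[SensitivityRow]:
    """Re-run the simulation across candidate remaining-PSA values.

    Larger remaining surface equilibrates faster (half-equilibration time
    non-increasing in PSA) and, with nonzero body clearance, drains the
    peritoneal exposure (AUC_P non-increasing in PSA).
    """
    if not psa_values_cm2:
        raise PKError("at least one PSA value required")
    rows = []
    for psa in psa_values_cm2:
        traj = simulate(replace(template, area_cm2=float(psa)))
        rows.append(
            SensitivityRow(
                psa_cm2=float(psa),
                auc_peritoneal_mg_min_per_L=traj.auc_peritoneal_mg_min_per_L,
                auc_blood_mg_min_per_L=traj.auc_blood_mg_min_per_L,
                half_equilibration_min=traj.half_equilibration_min,
            )
        )
    return rows
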