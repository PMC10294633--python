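"""Deterministic discrete-time predator–prey infection simulation.

The model tracks three compartments of a closed, well-mixed culture in
which *B. bacteriovorus* preys on a non-replicating host population:

* ``free_predators`` (F) — attack-phase cells searching for prey,
* ``bdelloplasts``   (B) — occupied, rounded prey cells in which one
  predator filament is growing,
* ``unattacked_prey`` (P) — live prey not yet entered.

One time step spans one predator life cycle (``cycle_step_min``, the
measured cycle duration rounded to the nearest 10 min). Per step, every
free predator that can find prey attaches (A = min(F, P)) and converts
that prey into a bdelloplast, while every bdelloplast formed in the
previous step lyses and releases ``progeny_mean`` progeny that
immediately resume the hunt:

    P' = P − A,   B' = A,   F' = (F − A) + progeny_mean · B

Populations are real-valued; no rounding occurs during iteration, so
fractional progeny means (e.g. 3.5) are exact. Complete lysis is declared
at the first step with no unattacked prey *and* no occupied bdelloplasts
(prey inside a bdelloplast is dead but not yet lysed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .killcurve import KillCurve
from .params import PreyParams

__all__ = [
    "PopulationState",
    "Trajectory",
    "step",
    "run",
    "complete_lysis_time",
    "od_projection",
]

DEFAULT_MAX_STEPS = 10_000


@dataclass(frozen=True)
class PopulationState:
    """Compartment counts at one discrete time point."""

    step_index: int
    t_min: float
    free_predators: float
    bdelloplasts: float
    unattacked_prey: float

    def __post_init__(self) -> None:
        if self.step_index < 0:
            raise ValueError("step_index must be >= 0")
        for name in ("free_predators", "bdelloplasts", "unattacked_prey"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def terminated(self) -> bool:
        """True when no prey remains in any pre-lysis compartment."""
        return self.unattacked_prey == 0 and self.bdelloplasts == 0


@dataclass
class Trajectory:
    """Ordered population states of one simulation run."""

    states: list[PopulationState]
    params: PreyParams
    terminated: bool = False
    max_steps_reached: bool = False

    def __len__(self) -> int:
        return len(self.states)

    @property
    def final(self) -> PopulationState:
        return self.states[-1]

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {
            "step": np.array([s.step_index for s in self.states]),
            "t_min": np.array([s.t_min for s in self.states], dtype=float),
            "free_predators": np.array([s.free_predators for s in self.states]),
            "bdelloplasts": np.array([s.bdelloplasts for s in self.states]),
            "unattacked_prey": np.array([s.unattacked_prey for s in self.states]),
        }


def step(state: PopulationState, params: PreyParams) -> PopulationState:
    """Advance the population by one predator life cycle.

    Attachment is capped at the available prey; bdelloplasts carried in
    ``state`` lyse during this step and their progeny join the free pool.
    """
    if params.cycle_step_min is None:
        raise ValueError(
            f"species {params.species!r} has no cycle_step_min; cannot simulate"
        )
    F, B, P = state.free_predators, state.bdelloplasts, state.unattacked_prey
    A = min(F, P)
    return PopulationState(
        step_index=state.step_index + 1,
        t_min=(state.step_index + 1) * params.cycle_step_min,
        free_predators=(F - A) + params.progeny_mean * B,
        bdelloplasts=A,
        unattacked_prey=P - A,
    )


def run(
    params: PreyParams,
    initial_predators: Optional[float] = None,
    initial_prey: Optional[float] = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> Trajectory:
    """Iterate the recursion from the inoculation state until complete lysis.

    Parameters
    ----------
    params
        Prey parameter bundle (supplies progeny mean and step duration).
    initial_predators, initial_prey
        Starting counts; default to the bundle's predator inoculum and
        ``culture_volume_ml × cells_per_ml_at_od1``.
    max_steps
        Safety bound; if reached before termination the trajectory is
        returned with ``max_steps_reached=True`` rather than truncated
        silently.
    """
    if initial_predators is None:
        initial_predators = params.predator_inoculum
    if initial_prey is None:
        initial_prey = params.initial_prey
        if initial_prey is None:
            raise ValueError(
                f"species {params.species!r} has no OD→cells conversion; "
                "pass initial_prey explicitly"
            )
    if initial_predators <= 0 or initial_prey <= 0:
        raise ValueError("initial populations must be positive")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")

    state = PopulationState(
        step_index=0,
        t_min=0.0,
        free_predators=float(initial_predators),
        bdelloplasts=0.0,
        unattacked_prey=float(initial_prey),
    )
    states = [state]
    while not state.terminated and state.step_index < max_steps:
        state = step(state, params)
        states.append(state)
    return Trajectory(
        states=states,
        params=params,
        terminated=state.terminated,
        max_steps_reached=not state.terminated,
    )


def complete_lysis_time(traj: Trajectory) -> float:
    """Time (min) of the first state with zero prey and zero bdelloplasts."""
    for s in traj.states:
        if s.terminated:
            return s.t_min
    raise ValueError(
        "trajectory did not terminate within max_steps; no complete-lysis time"
    )


def od_projection(
    traj: Trajectory,
    od_top: float,
    od_floor: float,
    times: Optional[Sequence[float]] = None,
) -> KillCurve:
    """Project a trajectory onto an OD600-like kill curve.

    The optical signal is assumed proportional to the intact prey material
    (unattacked prey plus occupied bdelloplasts), rescaled between
    ``od_top`` (the inoculation density) and ``od_floor`` (fully lysed):

        OD(t) = od_floor + (od_top − od_floor) · (P_t + B_t) / P_0

    With ``times`` given (e.g. a 20-min plate-reader grid) the discrete
    trajectory is sampled as a step function: each query time takes the
    value of the latest state at or before it.
    """
    if not traj.states:
        raise ValueError("empty trajectory")
    if od_top <= od_floor:
        raise ValueError("od_top must exceed od_floor")
    arr = traj.as_arrays()
    p0 = arr["unattacked_prey"][0]
    frac = (arr["unattacked_prey"] + arr["bdelloplasts"]) / p0
    od_states = od_floor + (od_top - od_floor) * frac
    if times is None:
        t = arr["t_min"]
        od = od_states
    else:
        t = np.asarray(times, dtype=float)
        idx = np.searchsorted(arr["t_min"], t, side="right") - 1
        if (idx < 0).any():
            raise ValueError("query times precede the trajectory start")
        od = od_states[idx]
    return KillCurve(
        times=t,
        od=od,
        meta={"species": traj.params.species, "source": "od_projection"},
    )
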