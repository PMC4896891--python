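"""Four-state electron-conformational kinetic model of the reaction center.

The slow photoinduced electron transport of isolated purple-bacteria reaction
centers (RCs) is modelled as a continuous-time four-state linear system.
State 1 is the dark-adapted state (electron on the donor dimer P); states
2-4 are electron-conformational states populated under illumination.  The
occupancies x1..x4 obey first-order kinetic balance with constant transfer
rates k_ij (s^-1) and the conservation law x1+x2+x3+x4 = 1.

The observable of the experiment -- normalized absorbance at ~865 nm -- is
the first-state occupancy x1(t): 1 in darkness, bleached under light.

Because the system is linear with a conserved total, its solution is a
constant (the stationary distribution) plus exactly three decaying
exponential modes with decrements d1 >= d2 >= d3 > 0 (the negatives of the
nonzero eigenvalues of the generator).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

#: Field order used throughout (column order of the packaged rate tables).
RATE_NAMES: tuple[str, ...] = (
    "k12", "k21", "k23", "k32", "k34", "k43",
    "k13", "k31", "k24", "k42", "k14", "k41",
)

#: Rates that vanish in darkness (no photon flux, no forward pumping from state 1).
LIGHT_DRIVEN: tuple[str, ...] = ("k12", "k13", "k14")

#: Eigenvalue-gap threshold below which the analytic solver falls back to
#: numerical integration (near-degenerate modes make the mode decomposition
#: ill-conditioned).
DEGENERACY_GAP = 1e-9


class RateValidationError(ValueError):
    """A rate constant is negative, non-finite, or violates a constraint."""


@dataclass(frozen=True)
class RateSet:
    """The 12 off-diagonal first-order transfer rates k_ij of the network.

    All rates are in s^-1 and must be nonnegative and finite.  A *dark*
    rate set (reduction phase, light off) additionally has
    ``k12 = k13 = k14 = 0``: no transitions out of the dark-adapted state.
    """

    k12: float = 0.0
    k21: float = 0.0
    k23: float = 0.0
    k32: float = 0.0
    k34: float = 0.0
    k43: float = 0.0
    k13: float = 0.0
    k31: float = 0.0
    k24: float = 0.0
    k42: float = 0.0
    k14: float = 0.0
    k41: float = 0.0

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise RateValidationError(
                    f"rate {name} must be finite and >= 0, got {v!r}"
                )
            object.__setattr__(self, name, float(v))

    @property
    def is_dark(self) -> bool:
        """True when all light-driven rates vanish (reduction-phase constraint)."""
        return all(getattr(self, n) == 0.0 for n in LIGHT_DRIVEN)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RATE_NAMES])

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in RATE_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "RateSet":
        return cls(**{n: float(d[n]) for n in RATE_NAMES})

    def replace(self, **updates: float) -> "RateSet":
        return replace(self, **updates)

    def to_json(self, path, process: str | None = None,
                intensity_mw_cm2: float | None = None) -> None:
        obj: dict = self.to_dict()
        if process is not None:
            obj["process"] = process
        if intensity_mw_cm2 is not None:
            obj["intensity_mw_cm2"] = intensity_mw_cm2
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RateSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class OccupancyState:
    """Occupancies of the four electron-conformational states; sums to 1."""

    x1: float
    x2: float
    x3: float
    x4: float

    def __post_init__(self) -> None:
        v = self.as_array()
        if not np.all(np.isfinite(v)):
            raise ValueError(f"occupancies must be finite, got {v}")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError(f"occupancies must lie in [0, 1], got {v}")
        if abs(v.sum() - 1.0) > 1e-12:
            raise ValueError(f"occupancies must sum to 1 (got {v.sum()!r})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3, self.x4])

    @classmethod
    def from_array(cls, v: Sequence[float]) -> "OccupancyState":
        v = np.asarray(v, dtype=float)
        # clip roundoff-level excursions before validating
        v = np.clip(v, 0.0, 1.0)
        v = v / v.sum()
        return cls(*v)


DARK_ADAPTED = OccupancyState(1.0, 0.0, 0.0, 0.0)


@dataclass
class Trajectory:
    """Occupancies of all four states on a time grid with phase labels."""

    times: np.ndarray          # (N,) strictly increasing, s
    states: np.ndarray         # (N, 4)
    phases: np.ndarray         # (N,) of {"on", "off"}

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.phases = np.asarray(self.phases, dtype=object)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (self.times.size, 4):
            raise ValueError("states must have shape (len(times), 4)")

    @property
    def x1(self) -> np.ndarray:
        return self.states[:, 0]

    def occupancy(self, state: int) -> np.ndarray:
        """Occupancy trace of state 1..4."""
        return self.states[:, state - 1]

    def conservation_error(self) -> float:
        return float(np.max(np.abs(self.states.sum(axis=1) - 1.0)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "x1": self.states[:, 0], "x2": self.states[:, 1],
            "x3": self.states[:, 2], "x4": self.states[:, 3],
            "phase": self.phases,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.15g")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(
            times=df["time_s"].to_numpy(),
            states=df[["x1", "x2", "x3", "x4"]].to_numpy(),
            phases=df["phase"].to_numpy(),
        )


@dataclass
class EigenSolution:
    """Mode decomposition of the conserved four-state system.

    x_i(t) = steady_i + sum_j C[i, j] * exp(-decrements[j] * t)

    ``steady`` is the stationary distribution (the homogenizing offsets of
    the shifted variables y_i = x_i + h_i).  ``complex_modes`` flags
    conjugate eigenvalue pairs; the reconstruction is then real but the
    individual columns of ``C`` are complex.
    """

    decrements: np.ndarray        # (3,), sorted descending by real part
    coefficients: np.ndarray      # (4, 3), possibly complex
    steady: np.ndarray            # (4,)
    complex_modes: bool = False

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        """Occupancies at the given times, shape (N, 4)."""
        t = np.asarray(times, dtype=float)
        modes = np.exp(-np.outer(t, self.decrements))          # (N, 3)
        x = self.steady[None, :] + modes @ self.coefficients.T  # (N, 4)
        return np.real(x)

    def derivative(self, t: float) -> np.ndarray:
        """dx/dt at scalar time t, shape (4,)."""
        modes = -self.decrements * np.exp(-self.decrements * t)
        return np.real(self.coefficients @ modes)


def build_generator(rates: RateSet) -> np.ndarray:
    """Assemble the 4x4 generator matrix Q of the master equation dx/dt = Q x.

    Columns index source states: Q[j, i] = k_ij for i != j and
    Q[i, i] = -sum_j k_ij, so every column sums to zero and the total
    occupancy is conserved.
    """
    Q = np.zeros((4, 4))
    for name in RATE_NAMES:
        i, j = int(name[1]) - 1, int(name[2]) - 1
        k = getattr(rates, name)
        Q[j, i] += k
        Q[i, i] -= k
    return Q


def eigensolution(rates: RateSet, x0: OccupancyState) -> EigenSolution:
    """Analytic mode decomposition for the given initial condition.

    Raises ``np.linalg.LinAlgError`` if the eigenvector basis is singular and
    ``DegenerateModesError`` if two decrements are closer than the
    degeneracy gap (callers fall back to numerical integration).
    """
    Q = build_generator(rates)
    lam, V = np.linalg.eig(Q)
    # a defective (non-diagonalizable) generator shows up as an
    # ill-conditioned eigenvector basis; repeated *zero* eigenvalues of a
    # reducible network are semisimple and pose no problem
    if np.linalg.cond(V) > 1e10:
        raise DegenerateModesError(
            f"near-defective generator, eigenvalues {np.sort(lam)}"
        )
    a = np.linalg.solve(V, x0.as_array().astype(complex))
    zero = np.abs(lam) < DEGENERACY_GAP
    if not zero.any():
        zero[np.argmin(np.abs(lam))] = True   # conservation mode always exists
    steady = np.real(V[:, zero] @ a[zero])
    decs = -lam[~zero]
    C = V[:, ~zero] * a[~zero][None, :]
    # pad extra zero modes (already folded into steady) with null columns
    if decs.size < 3:
        pad = 3 - decs.size
        decs = np.concatenate([decs, np.zeros(pad, dtype=decs.dtype)])
        C = np.hstack([C, np.zeros((4, pad), dtype=C.dtype)])
    order = np.argsort(-decs.real)
    decs, C = decs[order], C[:, order]
    is_complex = bool(np.max(np.abs(decs.imag)) > 1e-12)
    if not is_complex:
        decs, C = decs.real, C.real
    return EigenSolution(decrements=decs, coefficients=C, steady=steady,
                         complex_modes=is_complex)


class DegenerateModesError(RuntimeError):
    """Two eigen-decrements are numerically indistinguishable."""


def decrements(rates: RateSet) -> np.ndarray:
    """The three eigen-decrements d1 >= d2 >= d3 of the conserved system.

    These are the negatives of the nonzero eigenvalues of the generator
    (the zero eigenvalue belongs to the conserved total).  Returned sorted
    descending by real part; the dtype is complex iff a conjugate pair is
    present.
    """
    Q = build_generator(rates)
    lam = np.linalg.eigvals(Q)
    # drop the eigenvalue closest to zero (conservation mode)
    keep = np.argsort(np.abs(lam))[1:]
    d = -lam[keep]
    d = d[np.argsort(-d.real)]
    if np.max(np.abs(d.imag)) <= 1e-12:
        d = d.real
        d[np.abs(d) < 1e-300] = 0.0
    return d


def _integrate(Q: np.ndarray, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Adaptive stiff-capable integration fallback, rtol 1e-10."""
    t0, t1 = float(times[0]), float(times[-1])
    if t1 == t0:
        return np.tile(x0, (times.size, 1))
    sol = solve_ivp(lambda t, x: Q @ x, (t0, t1), x0, t_eval=times,
                    method="LSODA", rtol=1e-10, atol=1e-13)
    if not sol.success:  # pragma: no cover - LSODA is robust for linear systems
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.T


def solve_occupancies(rates: RateSet, x0: OccupancyState,
                      times: np.ndarray, phase: str = "on") -> Trajectory:
    """Solve the master equation on a strictly increasing time grid.

    Uses the analytic eigen-decomposition; falls back to adaptive numerical
    integration (logged) when modes are nearly degenerate.  ``times[0]`` need
    not be 0: the state ``x0`` is taken at t = times[0] and propagated.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be strictly increasing with times[0] >= 0")
    try:
        sol = eigensolution(rates, x0)
        states = sol.evaluate(times - times[0])
    except DegenerateModesError as exc:
        logger.info("analytic solver degenerate (%s); using numerical integration", exc)
        states = _integrate(build_generator(rates), x0.as_array(), times - times[0])
    # remove roundoff drift: renormalize the conserved total
    states = np.clip(states, 0.0, None)
    states /= states.sum(axis=1, keepdims=True)
    phases = np.full(times.size, phase, dtype=object)
    return Trajectory(times=times, states=states, phases=phases)


def steady_state(rates: RateSet) -> OccupancyState:
    """Stationary occupancy distribution of the network.

    For an irreducible network this is the unique normalized null vector of
    the generator.  For a reducible network with a single closed
    communicating class (e.g. darkness, where state 1 is absorbing) it is
    the distribution concentrated on that class.  Multiple closed classes
    have no unique stationary law and raise ``ValueError`` naming them.
    """
    closed = _closed_classes(rates)
    if len(closed) > 1:
        raise ValueError(
            "no unique stationary distribution: multiple closed "
            f"communicating classes {sorted(sorted(c + 1 for c in cl) for cl in closed)} "
            "(states 1-based)"
        )
    Q = build_generator(rates)
    lam, V = np.linalg.eig(Q)
    v = np.real(V[:, np.argmin(np.abs(lam))])
    v = np.abs(v)
    mask = np.zeros(4, dtype=bool)
    mask[list(closed[0])] = True
    v = np.where(mask, v, 0.0)
    return OccupancyState.from_array(v / v.sum())


def _closed_classes(rates: RateSet) -> list[frozenset[int]]:
    """Closed communicating classes of the 4-state transition graph."""
    adj = np.zeros((4, 4), dtype=bool)
    np.fill_diagonal(adj, True)
    for name in RATE_NAMES:
        if getattr(rates, name) > 0:
            adj[int(name[1]) - 1, int(name[2]) - 1] = True
    # transitive closure (4 nodes: 4 passes suffice)
    reach = adj.copy()
    for _ in range(4):
        reach = reach | (reach @ reach)
    classes: set[frozenset[int]] = set()
    for i in range(4):
        cls = frozenset(j for j in range(4) if reach[i, j] and reach[j, i])
        # closed iff nothing outside the class is reachable from it
        if all((not reach[j, k]) or (k in cls) for j in cls for k in range(4)):
            classes.add(cls)
    return sorted(classes, key=min)


def simulate_protocol(ox: RateSet, red: RateSet, x0: OccupancyState,
                      t_on: float, t_total: float, dt: float = 0.01) -> Trajectory:
    """Light-on / light-off excitation protocol.

    Oxidation rates ``ox`` act on [0, t_on]; at light-off the occupancies are
    handed over as initial conditions to the dark (reduction) system ``red``
    on [t_on, t_total].  ``red`` must satisfy the darkness constraint
    k12 = k13 = k14 = 0.
    """
    if not red.is_dark:
        raise RateValidationError(
            "reduction RateSet must be dark: k12 = k13 = k14 = 0 "
            "(no light-driven transitions out of state 1 after light-off)"
        )
    if not (0 < t_on < t_total):
        raise ValueError("need 0 < t_on < t_total")
    times = np.arange(0.0, t_total + dt / 2, dt)
    on = times <= t_on + 1e-12
    traj_on = solve_occupancies(ox, x0, times[on], phase="on")
    x_off = OccupancyState.from_array(
        solve_occupancies(ox, x0, np.array([0.0, t_on])).states[-1]
    )
    t_off_grid = times[~on]
    if t_off_grid.size == 0:
        return traj_on
    traj_off = solve_occupancies(
        red,
        x_off,
        np.concatenate(([t_on], t_off_grid)),
        phase="off",
    )
    return Trajectory(
        times=np.concatenate([traj_on.times, traj_off.times[1:]]),
        states=np.vstack([traj_on.states, traj_off.states[1:]]),
        phases=np.concatenate([traj_on.phases, traj_off.phases[1:]]),
    )


def turning_points(traj: Trajectory, state: int, rates: RateSet,
                   xtol: float = 1e-3) -> list[tuple[float, str]]:
    """Strict local extrema of one occupancy within a single-phase trajectory.

    The derivative is evaluated analytically as the generator applied to the
    state; sign changes between samples are refined by root bracketing to
    ``xtol`` seconds.  A monotone trace yields an empty list.  ``state`` is
    1-based.
    """
    if len(set(traj.phases)) > 1:
        raise ValueError("turning_points expects a single-phase trajectory; "
                         "split the protocol at the light-off boundary first")
    Q = build_generator(rates)
    idx = state - 1
    x0 = OccupancyState.from_array(traj.states[0])
    t0 = traj.times[0]
    try:
        sol = eigensolution(rates, x0)

        def deriv(t: float) -> float:
            return float(sol.derivative(t - t0)[idx])
    except DegenerateModesError:
        def deriv(t: float) -> float:
            tt = np.array([t0, t]) if t > t0 else np.array([t])
            x = _integrate(Q, x0.as_array(), tt)[-1]
            return float((Q @ x)[idx])

    d = np.array([deriv(t) for t in traj.times])
    out: list[tuple[float, str]] = []
    for i in range(len(d) - 1):
        if d[i] == 0.0:
            continue
        if d[i] * d[i + 1] < 0:
            t_star = brentq(deriv, traj.times[i], traj.times[i + 1], xtol=xtol)
            out.append((float(t_star), "max" if d[i] > 0 else "min"))
    return out


def protocol_turning_points(traj: Trajectory, state: int, ox: RateSet,
                            red: RateSet, xtol: float = 1e-3
                            ) -> dict[str, list[tuple[float, str]]]:
    """Turning points per phase of a light-on/light-off protocol trajectory.

    Off-phase times are reported relative to light-off, matching how dark
    relaxation kinetics are read off experimental records.
    """
    out: dict[str, list[tuple[float, str]]] = {}
    on = traj.phases == "on"
    if on.any():
        sub = Trajectory(traj.times[on], traj.states[on], traj.phases[on])
        out["on"] = turning_points(sub, state, ox, xtol=xtol)
    if (~on).any():
        t_off = traj.times[on][-1] if on.any() else traj.times[0]
        sub = Trajectory(traj.times[~on], traj.states[~on], traj.phases[~on])
        out["off"] = [(t - t_off, kind)
                      for t, kind in turning_points(sub, state, red, xtol=xtol)]
    return out
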