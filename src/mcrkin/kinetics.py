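"""Reaction networks for milling kinetics: first-order, autocatalytic and
lag-activated steps, ODE integration, and closed forms used as oracles.

A network is a list of mass-transfer steps over named species.  Three step
kinds cover the phenomenology of liquid-assisted-grinding cocrystallisations:

* ``first_order``          X -> Y at rate k·[X]
* ``autocatalytic``        X + Y -> 2Y at rate k·[X]·[Y]  (Finke-Watzky growth)
* ``lagged_first_order``   X -> Y at rate k·[X] but only for t >= tau
                           (induction periods of mechanochemical phases)

Every step moves mass from one species to another, so total composition is
conserved exactly by the right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "Step",
    "KineticNetwork",
    "rhs",
    "integrate",
    "closed_form_fw",
    "closed_form_chain",
    "preset_network",
    "generator_network",
    "SCENARIOS",
]

SCENARIOS = ("30uL", "60uL", "90uL")

FIRST_ORDER = "first_order"
AUTOCATALYTIC = "autocatalytic"
LAGGED_FIRST_ORDER = "lagged_first_order"
_KINDS = (FIRST_ORDER, AUTOCATALYTIC, LAGGED_FIRST_ORDER)


@dataclass(frozen=True)
class Step:
    """One mass-transfer reaction step.

    ``autocatalytic`` reads as source + target -> 2·target; ``tau`` (minutes)
    is only meaningful for ``lagged_first_order``.
    """

    kind: str
    source: str
    target: str
    rate_name: str
    rate: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown step kind {self.kind!r}; expected one of {_KINDS}")
        if self.rate < 0:
            raise ValueError(f"negative rate {self.rate} for step {self.rate_name}")
        if self.tau < 0:
            raise ValueError(f"negative lag tau {self.tau} for step {self.rate_name}")


@dataclass(frozen=True)
class KineticNetwork:
    """Ordered species, reaction steps and the initial composition y0."""

    species: tuple[str, ...]
    steps: tuple[Step, ...]
    y0: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "steps", tuple(self.steps))
        object.__setattr__(self, "y0", tuple(float(v) for v in self.y0))
        if len(self.y0) != len(self.species):
            raise ValueError("y0 length must equal species count")
        if any(v < 0 for v in self.y0):
            raise ValueError("y0 must be non-negative")
        declared = set(self.species)
        for s in self.steps:
            if s.source not in declared or s.target not in declared:
                raise ValueError(f"step {s.rate_name} references undeclared species")

    @property
    def rate_names(self) -> tuple[str, ...]:
        return tuple(s.rate_name for s in self.steps)

    @property
    def rates(self) -> np.ndarray:
        return np.array([s.rate for s in self.steps], dtype=float)

    @property
    def taus(self) -> tuple[float, ...]:
        """Lag times of the lagged steps, in step order."""
        return tuple(s.tau for s in self.steps if s.kind == LAGGED_FIRST_ORDER)

    def index(self, name: str) -> int:
        return self.species.index(name)

    def with_rates(
        self, rates: Sequence[float] | None = None, taus: Sequence[float] | None = None
    ) -> "KineticNetwork":
        """Return a copy with replaced rate constants (and optionally lags)."""
        steps = list(self.steps)
        if rates is not None:
            if len(rates) != len(steps):
                raise ValueError("rates length must equal step count")
            steps = [replace(s, rate=float(k)) for s, k in zip(steps, rates)]
        if taus is not None:
            lag_idx = [i for i, s in enumerate(steps) if s.kind == LAGGED_FIRST_ORDER]
            if len(taus) != len(lag_idx):
                raise ValueError("taus length must equal lagged step count")
            for i, tau in zip(lag_idx, taus):
                steps[i] = replace(steps[i], tau=float(tau))
        return KineticNetwork(self.species, tuple(steps), self.y0)

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "steps": [
                {
                    "kind": s.kind,
                    "from": s.source,
                    "to": s.target,
                    "rate_name": s.rate_name,
                    "rate": s.rate,
                    "tau": s.tau,
                }
                for s in self.steps
            ],
            "y0": list(self.y0),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticNetwork":
        steps = tuple(
            Step(
                kind=s["kind"],
                source=s["from"],
                target=s["to"],
                rate_name=s["rate_name"],
                rate=float(s["rate"]),
                tau=float(s.get("tau", 0.0)),
            )
            for s in d["steps"]
        )
        return cls(tuple(d["species"]), steps, tuple(d["y0"]))


def _compile(network: KineticNetwork):
    """Precompute index arrays and return a fast rhs(t, y) closure."""
    idx = {name: i for i, name in enumerate(network.species)}
    src = np.array([idx[s.source] for s in network.steps], dtype=int)
    tgt = np.array([idx[s.target] for s in network.steps], dtype=int)
    rates = np.array([s.rate for s in network.steps], dtype=float)
    auto = np.array([s.kind == AUTOCATALYTIC for s in network.steps])
    lagged = np.array([s.kind == LAGGED_FIRST_ORDER for s in network.steps])
    taus = np.array([s.tau for s in network.steps], dtype=float)
    nsp = len(network.species)

    def f(t: float, y: np.ndarray) -> np.ndarray:
        flux = rates * y[src]
        if auto.any():
            flux = np.where(auto, flux * y[tgt], flux)
        if lagged.any():
            flux = np.where(lagged & (t < taus), 0.0, flux)
        dy = np.zeros(nsp)
        np.subtract.at(dy, src, flux)
        np.add.at(dy, tgt, flux)
        return dy

    return f


def rhs(network: KineticNetwork, t: float, y: np.ndarray) -> np.ndarray:
    """Time derivative of the composition vector at time ``t``.

    Pure function; each step contributes an equal-and-opposite pair of terms,
    so the components of the result sum to zero exactly.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != len(network.species):
        raise ValueError("y length must equal species count")
    return _compile(network)(float(t), y)


def _switch_times(network: KineticNetwork, t_end: float) -> list[float]:
    taus = sorted({s.tau for s in network.steps if s.kind == LAGGED_FIRST_ORDER})
    return [t for t in taus if 0.0 < t < t_end]


def integrate(
    network: KineticNetwork,
    times: Sequence[float],
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> np.ndarray:
    """Solve the network ODE, returning composition rows at ``times``.

    Lag activations make the right-hand side discontinuous in t; since the
    switch times are known in advance the integration is split at each tau
    rather than relying on event detection.  Returned values are clipped to
    zero from below (solver undershoot stays within tolerance).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times[0] != 0.0:
        raise ValueError("times must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    y0 = np.array(network.y0, dtype=float)
    if times.size == 1:
        return y0[None, :].copy()

    t_end = float(times[-1])
    breakpoints = [0.0] + _switch_times(network, t_end) + [t_end]
    out = np.empty((times.size, len(network.species)))
    out[0] = y0
    y = y0
    f = _compile(network)
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        # sample strictly inside (a, b]; the segment endpoint is always solved
        # so the state is exact at the next switch
        inside = (times > a) & (times <= b)
        t_eval = np.unique(np.concatenate([times[inside], [b]]))
        sol = solve_ivp(
            f,
            (a, b),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        for tk, yk in zip(sol.t, sol.y.T):
            hits = np.nonzero(inside & np.isclose(times, tk, rtol=0, atol=1e-12))[0]
            out[hits] = yk
        y = sol.y[:, -1]
    return np.clip(out, 0.0, None)


def closed_form_fw(k1: float, k2: float, A0: float, t) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form solution of the Finke-Watzky pair A->B, A+B->2B.

    Nucleation at rate k1·[A], autocatalytic growth at rate k2·[A]·[B];
    returns (A(t), B(t)) with B = A0 - A.  With k2 = 0 this degenerates to
    plain first-order decay.
    """
    t = np.asarray(t, dtype=float)
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    if k2 == 0.0:
        A = A0 * np.exp(-k1 * t)
        return A, A0 - A
    with np.errstate(over="ignore"):
        grow = np.exp((k1 + k2 * A0) * t)
    A = (k1 / k2 + A0) / (1.0 + (k1 / (k2 * A0)) * grow)
    return A, A0 - A


def closed_form_chain(rates: Sequence[float], y0: Sequence[float], t) -> np.ndarray:
    """Exact solution of a linear first-order chain X1 -> X2 -> ... -> Xq.

    ``rates`` has one entry per arrow (length q-1); the terminal species does
    not decay.  Distinct rates use the Bateman cascade formula; repeated rates
    fall back to the matrix exponential of the (lower-bidiagonal) rate matrix,
    which realises the l'Hopital limit of the degenerate cascade exactly.
    Returns an array of shape (len(t), q).
    """
    rates = np.asarray(rates, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    q = y0.size
    if rates.size != q - 1:
        raise ValueError("need exactly one rate per chain arrow (len(y0) - 1)")
    lam = np.concatenate([rates, [0.0]])  # decay constant per species

    distinct = np.min(np.abs(np.subtract.outer(lam, lam) + np.eye(q))) > 1e-12
    if not distinct:
        A = np.diag(-lam) + np.diag(rates, -1)
        return np.stack([expm(A * tk) @ y0 for tk in t])

    out = np.zeros((t.size, q))
    for s in range(q):  # superpose a Bateman cascade started at species s
        if y0[s] == 0.0:
            continue
        for i in range(s, q):
            lam_si = lam[s:i + 1]
            prod_rates = np.prod(rates[s:i]) if i > s else 1.0
            for j, lj in enumerate(lam_si):
                denom = np.prod(np.delete(lam_si, j) - lj) if lam_si.size > 1 else 1.0
                out[:, i] += y0[s] * prod_rates * np.exp(-lj * t) / denom
    return out


def _net(species, steps, y0_map) -> KineticNetwork:
    y0 = tuple(y0_map.get(s, 0.0) for s in species)
    return KineticNetwork(tuple(species), tuple(steps), y0)


def preset_network(scenario: str) -> KineticNetwork:
    """Analysis network for one LAG scenario, used by the kinetic constraint.

    Species: R reagents, A the 1:2 cocrystal formed first, B Form I, C the
    transient unknown phase, D the 2:1/1:2 cocrystal mixture, P the product
    Form II.  At 60/90 µL reagent consumption is faster than the sampling, so
    the merged species RA stands for the jointly unresolvable reagents + A.
    Rate values are synthetic defaults on the 0.02-2 min^-1 scale, placed so
    the transition windows match the qualitative milling timeline (reagents
    gone within ~15 min, product complete by ~60 min at 30 µL, ~20 min
    earlier at 90 µL); they are starting guesses for fitting, not literature
    values.
    """
    if scenario == "30uL":
        return _net(
            ("R", "A", "B", "D", "P"),
            (
                Step(FIRST_ORDER, "R", "A", "k_RA", 0.45),
                Step(FIRST_ORDER, "A", "B", "k_AB", 0.30),
                Step(LAGGED_FIRST_ORDER, "B", "D", "k_BD", 0.15, tau=15.0),
                Step(FIRST_ORDER, "D", "P", "k_DP", 0.008),
                Step(AUTOCATALYTIC, "D", "P", "k_DPP", 0.20),
            ),
            {"R": 1.0},
        )
    if scenario == "60uL":
        return _net(
            ("RA", "B", "C", "D", "P"),
            (
                Step(FIRST_ORDER, "RA", "B", "k_RAB", 0.50),
                Step(FIRST_ORDER, "B", "C", "k_BC", 0.35),
                Step(LAGGED_FIRST_ORDER, "C", "D", "k_CD", 0.20, tau=25.0),
                Step(AUTOCATALYTIC, "C", "D", "k_CDD", 0.80),
                Step(FIRST_ORDER, "D", "P", "k_DP", 0.008),
                Step(AUTOCATALYTIC, "D", "P", "k_DPP", 0.25),
            ),
            {"RA": 1.0},
        )
    if scenario == "90uL":
        return _net(
            ("RA", "B", "C", "D", "P"),
            (
                Step(FIRST_ORDER, "RA", "B", "k_RAB", 0.80),
                Step(FIRST_ORDER, "B", "C", "k_BC", 0.60),
                Step(FIRST_ORDER, "C", "P", "k_CP", 0.06),
                Step(FIRST_ORDER, "C", "D", "k_CD", 0.04),
                Step(FIRST_ORDER, "D", "P", "k_DP", 0.03),
                Step(AUTOCATALYTIC, "D", "P", "k_DPP", 0.50),
            ),
            {"RA": 1.0},
        )
    raise ValueError(f"unknown scenario {scenario!r}; valid: {', '.join(SCENARIOS)}")


# Reagent consumption faster than the frame rate at 60/90 µL: with 0.5 min
# frames, 120 min^-1 puts the R -> A transition entirely between frames.
FAST_RA_RATE = 120.0


def generator_network(scenario: str) -> KineticNetwork:
    """Ground-truth network used by the synthetic data generator.

    At 30 µL this is the analysis network itself.  At 60/90 µL the merged RA
    species of :func:`preset_network` is expanded into explicit R and A with a
    reagent-consumption step much faster than the sampling rate, so that the
    generated series reproduces the rank deficiency that forces the merge.
    """
    if scenario == "30uL":
        return preset_network(scenario)
    merged = preset_network(scenario)
    species = ("R", "A") + merged.species[1:]
    rename = {"RA": "A"}
    steps = [Step(FIRST_ORDER, "R", "A", "k_RA", FAST_RA_RATE)]
    for s in merged.steps:
        steps.append(
            replace(s, source=rename.get(s.source, s.source),
                    target=rename.get(s.target, s.target))
        )
    return _net(species, tuple(steps), {"R": 1.0})
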