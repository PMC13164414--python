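"""Phenomenological milling kinetics: the critical-loading-condition model.

In ball-mill transformations only the powder caught in small, randomly
located volumes experiencing critical loading conditions (CLCs) during an
impact can react.  With n = f·t impacts (f the impact frequency) and a
fraction kappa of the charge processed per impact, phase fractions evolve as

    d(alpha)/dn = kappa · nu(alpha)

where nu is the right-hand side of a local per-impact reaction scheme
(first-order and autocatalytic steps with dimensionless per-impact rate
constants).  A fraction alpha_P_start of the final product can appear already
at the first effective impact and is applied as a state transfer at n = 1.

The cocrystal D is carried as two bookkeeping species: a nucleated form D_n
that must ripen to the growth form D_g (step D_n -> D_g) before converting to
product.  Product formation is autocatalytic (D_g + P -> 2P, reported as the
D -> P step) and is seeded by the first-impact fraction alpha_P_start, which
is what makes that fraction a load-bearing parameter of the model.
Observable profiles report D_n + D_g as phase D.

Identifiability: nu is linear in the local rates, so the embodiment above is
exactly invariant under (kappa, k) -> (c·kappa, k/c) — only the products
kappa·k_i are determined by any trajectory data, shared kappa or not.  The
package pins this gauge by convention: the ripening rate k_DnDg is a fixed
model constant (the same value in every scheme), which makes kappa the
processed fraction per impact expressed on the ripening-step scale.  The
fitter holds k_DnDg fixed by default, reports the gauge-invariant products
alongside the raw parameters, and warns when asked to float the gauge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .kinetics import (
    AUTOCATALYTIC,
    FIRST_ORDER,
    SCENARIOS,
    KineticNetwork,
    Step,
    _compile,
)

__all__ = [
    "CLC_SPECIES",
    "CLCModel",
    "CLCFitResult",
    "impacts_from_time",
    "clc_simulate",
    "observable_profiles",
    "preset_clc_scheme",
    "preset_clc_model",
    "clc_fit",
    "clc_fit_multi",
    "RIPENING_RATE",
]

CLC_SPECIES = ("R", "A", "B", "C", "D_n", "D_g", "P")

# Gauge convention: per-impact rate constant of the D_n -> D_g ripening step.
# Chosen slow enough that ripening is rate-limiting within the D chain, which
# keeps the conventional scale kinetically resolved in the data.
RIPENING_RATE = 0.003


@dataclass
class CLCModel:
    """Impact statistics + local scheme for one milling experiment.

    impact_frequency is in impacts per minute; kappa is the mass fraction of
    powder experiencing CLCs per impact; local_scheme holds dimensionless
    per-impact rate constants; alpha_P_start is the product fraction formed
    at the first effective impact.
    """

    impact_frequency: float
    kappa: float
    local_scheme: KineticNetwork
    alpha_P_start: float = 0.0

    def __post_init__(self) -> None:
        if self.impact_frequency <= 0:
            raise ValueError("impact_frequency must be positive")
        if not 0.0 <= self.kappa < 1.0:
            raise ValueError("kappa must lie in [0, 1)")
        if not 0.0 <= self.alpha_P_start < 1.0:
            raise ValueError("alpha_P_start must lie in [0, 1)")
        unknown = set(self.local_scheme.species) - set(CLC_SPECIES)
        if unknown:
            raise ValueError(f"local scheme uses undeclared species {sorted(unknown)}")


def impacts_from_time(t, f: float):
    """Impact count n = f·t (continuous embodiment of the impact series)."""
    t = np.asarray(t, dtype=float)
    if f <= 0:
        raise ValueError("impact frequency must be positive")
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return f * t


def _first_impact_jump(y: np.ndarray, scheme: KineticNetwork, alpha_P_start: float):
    """Transfer alpha_P_start into P proportionally from the precursor pool."""
    if alpha_P_start <= 0.0:
        return y
    y = y.copy()
    p = scheme.index("P")
    pool_idx = [i for i in range(y.size) if i != p]
    pool = float(y[pool_idx].sum())
    transfer = min(alpha_P_start, pool)
    if pool > 0:
        y[pool_idx] *= (pool - transfer) / pool
        y[p] += transfer
    return y


def clc_simulate(
    model: CLCModel,
    times,
    mode: str = "ode",
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> np.ndarray:
    """Phase-fraction trajectories of the local scheme species at ``times``.

    'ode' integrates d(alpha)/dn = kappa·nu(alpha) continuously in the impact
    number (accurate for the >1e3 impacts of a real experiment); 'discrete'
    iterates the per-impact Euler map alpha_{n+1} = alpha_n + kappa·nu(alpha_n)
    and serves as a cross-validation of the continuum limit.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-empty and strictly increasing")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    scheme = model.local_scheme
    y0 = np.array(scheme.y0, dtype=float)
    if y0.sum() <= 0:
        raise ValueError("invalid initial composition: total mass is zero")
    n_req = impacts_from_time(times, model.impact_frequency)

    if mode == "discrete":
        return _simulate_discrete(model, n_req)
    if mode != "ode":
        raise ValueError("mode must be 'ode' or 'discrete'")

    nu = _compile(scheme)
    kappa = model.kappa

    def f(n, y):
        return kappa * nu(n, y)

    out = np.empty((n_req.size, y0.size))
    # segment [0, 1]: before the first-impact adjustment
    n_max = float(n_req[-1])
    segments = []
    if n_max <= 1.0 or model.alpha_P_start == 0.0:
        segments.append((0.0, n_max, False))
    else:
        segments.append((0.0, 1.0, True))
        segments.append((1.0, n_max, False))
    y = y0
    done = np.zeros(n_req.size, dtype=bool)
    if n_req[0] == 0.0:
        out[0] = y0
        done[0] = True
    for a, b, jump_after in segments:
        inside = (n_req > a) & (n_req <= b) & ~done
        t_eval = np.unique(np.concatenate([n_req[inside], [b]])) if b > a else []
        if b > a:
            sol = solve_ivp(f, (a, b), y, method="LSODA", t_eval=t_eval,
                            rtol=rtol, atol=atol)
            if not sol.success:  # pragma: no cover - defensive
                raise RuntimeError(f"CLC integration failed: {sol.message}")
            for nk, yk in zip(sol.t, sol.y.T):
                hits = np.nonzero(inside & np.isclose(n_req, nk, rtol=0, atol=1e-9))[0]
                out[hits] = yk
                done[hits] = True
            y = sol.y[:, -1]
        if jump_after:
            y = _first_impact_jump(y, scheme, model.alpha_P_start)
            # samples exactly at n=1 report the pre-jump state; the jump
            # applies "after the first impact"
    return np.clip(out, 0.0, None)


def _simulate_discrete(model: CLCModel, n_req: np.ndarray) -> np.ndarray:
    scheme = model.local_scheme
    nu = _compile(scheme)
    y = np.array(scheme.y0, dtype=float)
    n_end = int(np.ceil(n_req[-1]))
    states = {}  # integer n -> state, only around requested points
    wanted = set()
    for nr in n_req:
        wanted.add(int(np.floor(nr)))
        wanted.add(int(np.ceil(nr)))
    if 0 in wanted:
        states[0] = y.copy()
    for n in range(1, n_end + 1):
        y = np.clip(y + model.kappa * nu(float(n - 1), y), 0.0, None)
        if n == 1:
            y = _first_impact_jump(y, scheme, model.alpha_P_start)
        if n in wanted:
            states[n] = y.copy()
    out = np.empty((n_req.size, y.size))
    for i, nr in enumerate(n_req):
        lo, hi = int(np.floor(nr)), int(np.ceil(nr))
        if lo == hi:
            out[i] = states[lo]
        else:
            w = nr - lo
            out[i] = (1 - w) * states[lo] + w * states[hi]
    return out


def observable_profiles(scheme: KineticNetwork, traj: np.ndarray):
    """Collapse D_n/D_g bookkeeping into observable phase D.

    Returns (phase names, profiles) where profiles columns follow the names.
    """
    names: list[str] = []
    cols: list[np.ndarray] = []
    d_sum = None
    for i, sp in enumerate(scheme.species):
        if sp in ("D_n", "D_g"):
            d_sum = traj[:, i] if d_sum is None else d_sum + traj[:, i]
        else:
            names.append(sp)
            cols.append(traj[:, i])
    if d_sum is not None:
        names.append("D")
        cols.append(d_sum)
    return names, np.column_stack(cols)


def _scheme(species, steps, y0_map):
    y0 = tuple(y0_map.get(s, 0.0) for s in species)
    return KineticNetwork(tuple(species), tuple(steps), y0)


def preset_clc_scheme(scenario: str) -> KineticNetwork:
    """Local per-impact scheme for one LAG scenario.

    All three share the A -> B, D_n -> D_g and D -> P steps, the last
    implemented as autocatalytic product growth D_g + P -> 2P seeded by
    alpha_P_start.  Only 30 uL resolves the initial R -> A step; at higher
    LAG content the reagents are consumed before the first measurement and
    the trajectory starts from A.  The transient phase C feeds D entirely at
    60 uL and splits between D and direct product formation at 90 uL.  Rate
    values are synthetic defaults (per impact); k_DnDg is the fixed gauge
    constant.
    """
    if scenario == "30uL":
        return _scheme(
            ("R", "A", "B", "D_n", "D_g", "P"),
            (
                Step(FIRST_ORDER, "R", "A", "k_RA", 0.0139),
                Step(FIRST_ORDER, "A", "B", "k_AB", 0.0093),
                Step(FIRST_ORDER, "B", "D_n", "k_BDn", 0.0046),
                Step(FIRST_ORDER, "D_n", "D_g", "k_DnDg", RIPENING_RATE),
                Step(AUTOCATALYTIC, "D_g", "P", "k_DP", 0.010),
            ),
            {"R": 1.0},
        )
    if scenario == "60uL":
        return _scheme(
            ("A", "B", "C", "D_n", "D_g", "P"),
            (
                Step(FIRST_ORDER, "A", "B", "k_AB", 0.0154),
                Step(FIRST_ORDER, "B", "C", "k_BC", 0.0108),
                Step(FIRST_ORDER, "C", "D_n", "k_CDn", 0.0062),
                Step(FIRST_ORDER, "D_n", "D_g", "k_DnDg", RIPENING_RATE),
                Step(AUTOCATALYTIC, "D_g", "P", "k_DP", 0.010),
            ),
            {"A": 1.0},
        )
    if scenario == "90uL":
        return _scheme(
            ("A", "B", "C", "D_n", "D_g", "P"),
            (
                Step(FIRST_ORDER, "A", "B", "k_AB", 0.0247),
                Step(FIRST_ORDER, "B", "C", "k_BC", 0.0185),
                Step(FIRST_ORDER, "C", "D_n", "k_CDn", 0.0012),
                Step(FIRST_ORDER, "C", "P", "k_CP", 0.0019),
                Step(FIRST_ORDER, "D_n", "D_g", "k_DnDg", RIPENING_RATE),
                Step(AUTOCATALYTIC, "D_g", "P", "k_DP", 0.0154),
            ),
            {"A": 1.0},
        )
    raise ValueError(f"unknown scenario {scenario!r}; valid: {', '.join(SCENARIOS)}")


def preset_clc_model(
    scenario: str,
    impact_frequency: float = 1800.0,
    kappa: float = 0.018,
    alpha_P_start: float = 0.02,
) -> CLCModel:
    """Default CLC model for a scenario (synthetic ground truth for tests)."""
    return CLCModel(impact_frequency, kappa, preset_clc_scheme(scenario),
                    alpha_P_start)


@dataclass
class CLCFitResult:
    """Best-fit CLC parameters for one or several milling experiments."""

    models: list[CLCModel]
    kappa: float | list[float]  # shared value, or one per experiment
    rates: list[dict[str, float]]
    alpha_P_start: list[float]
    products: list[dict[str, float]]  # gauge-invariant kappa·k_i
    rss: float
    bound_hits: list[str]
    shared_kappa: bool

    @property
    def model(self) -> CLCModel:
        return self.models[0]


def _prep_profiles(profiles, phases, scheme):
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] != len(phases):
        raise ValueError("profiles must be (times x phases) matching the phase list")
    sums = profiles.sum(axis=1)
    if np.any(sums < 0.9) or np.any(sums > 1.1):
        raise ValueError("profile rows are not compositions (row sums outside [0.9, 1.1])")
    profiles = profiles / sums[:, None]
    names, _ = observable_profiles(scheme, np.zeros((1, len(scheme.species))))
    missing = [p for p in phases if p not in names]
    if missing:
        raise ValueError(f"phases {missing} not produced by the scheme (has {names})")
    order = [names.index(p) for p in phases]
    return profiles, order


def _fit_core(datasets, f, kappa0, share_kappa, fix_gauge, alpha0_list,
              rate_bound, seed):
    """Joint bounded least squares over kappa, free local rates and
    alpha_P_start for one or more experiments."""
    n_sets = len(datasets)
    free_idx = []  # per dataset: indices of free steps
    for _, _, _, scheme in datasets:
        idx = [i for i, s in enumerate(scheme.steps)
               if not (fix_gauge and s.rate_name == "k_DnDg")]
        free_idx.append(idx)
    if fix_gauge and all(len(i) == len(d[3].steps) for i, d in zip(free_idx, datasets)):
        warnings.warn(
            "no gauge-fixed step in any scheme: kappa and the local rates are "
            "only identifiable as products kappa*k", stacklevel=3)

    n_kappa = 1 if share_kappa else n_sets
    sizes = [len(i) for i in free_idx]

    def split(p):
        kap = p[:n_kappa]
        pos = n_kappa
        rates, alphas = [], []
        for s in sizes:
            rates.append(p[pos:pos + s])
            pos += s
            alphas.append(p[pos])
            pos += 1
        return kap, rates, alphas

    def build_models(p):
        kap, rates, alphas = split(p)
        models = []
        for ds, idx, rr, al in zip(datasets, free_idx, rates, alphas):
            scheme = ds[3]
            full = scheme.rates
            if fix_gauge:
                # the ripening step is the gauge convention, a model constant
                for i, s in enumerate(scheme.steps):
                    if s.rate_name == "k_DnDg":
                        full[i] = RIPENING_RATE
            full[idx] = rr
            k = kap[0] if share_kappa else kap[len(models)]
            models.append(CLCModel(f, float(k), scheme.with_rates(full), float(al)))
        return models

    def residual(p):
        res = []
        for model, (profiles, order, times, scheme) in zip(build_models(p), datasets):
            traj = clc_simulate(model, times, rtol=1e-8, atol=1e-11)
            _, obs = observable_profiles(scheme, traj)
            res.append((profiles - obs[:, order]).ravel())
        out = np.concatenate(res)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite residuals in CLC fit")
        return out

    p0, lo, hi, labels = [], [], [], []
    for k in range(n_kappa):
        p0.append(kappa0[k] if isinstance(kappa0, (list, tuple)) else kappa0)
        lo.append(1e-6)
        hi.append(1.0 - 1e-6)
        labels.append(f"kappa[{k}]" if n_kappa > 1 else "kappa")
    for d, (ds, idx) in enumerate(zip(datasets, free_idx)):
        scheme = ds[3]
        for i in idx:
            p0.append(scheme.steps[i].rate)
            lo.append(0.0)
            hi.append(rate_bound)
            labels.append(f"{scheme.steps[i].rate_name}[{d}]")
        p0.append(alpha0_list[d])
        lo.append(0.0)
        hi.append(0.5)
        labels.append(f"alpha_P_start[{d}]")
    p0 = np.clip(np.asarray(p0, dtype=float), lo, hi)

    sol = least_squares(residual, p0, bounds=(np.asarray(lo), np.asarray(hi)),
                        method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10)
    models = build_models(sol.x)
    span = np.asarray(hi) - np.asarray(lo)
    hit = (np.abs(sol.x - lo) < 1e-9 * span) | (np.abs(sol.x - hi) < 1e-9 * span)
    bound_hits = [lab for lab, h in zip(labels, hit) if h]

    kap, rates, alphas = split(sol.x)
    rate_dicts, prod_dicts = [], []
    for model in models:
        rd = {s.rate_name: s.rate for s in model.local_scheme.steps}
        rate_dicts.append(rd)
        prod_dicts.append({f"kappa*{k}": model.kappa * v for k, v in rd.items()})
    return CLCFitResult(
        models=models,
        kappa=float(kap[0]) if share_kappa else [float(k) for k in kap],
        rates=rate_dicts,
        alpha_P_start=[float(a) for a in alphas],
        products=prod_dicts,
        rss=float(2.0 * sol.cost),
        bound_hits=bound_hits,
        shared_kappa=share_kappa,
    )


def clc_fit(
    profiles,
    times,
    scheme: KineticNetwork,
    f: float,
    phases: list[str] | None = None,
    kappa0: float = 0.02,
    alpha0: float = 0.01,
    fix_gauge: bool = True,
    rate_bound: float = 1.0,
    seed: int = 0,
) -> CLCFitResult:
    """Fit (kappa, per-impact rates, alpha_P_start) to phase-fraction data.

    ``profiles`` rows must be (approximately) compositions; they are
    renormalised when row sums lie within [0.9, 1.1] and rejected otherwise.
    ``phases`` names the profile columns in observable terms (D meaning
    D_n + D_g); by default all observable phases of the scheme in order.
    The scheme's stored rates are the initial guesses.
    """
    times = np.asarray(times, dtype=float)
    if phases is None:
        phases, _ = observable_profiles(scheme, np.zeros((1, len(scheme.species))))
    prof, order = _prep_profiles(profiles, phases, scheme)
    return _fit_core([(prof, order, times, scheme)], f, kappa0, True,
                     fix_gauge, [alpha0], rate_bound, seed)


def clc_fit_multi(
    datasets,
    f: float,
    share_kappa: bool = True,
    kappa0=0.02,
    alpha0: float = 0.01,
    fix_gauge: bool = True,
    rate_bound: float = 1.0,
    seed: int = 0,
) -> CLCFitResult:
    """Joint fit over several experiments.

    ``datasets`` is a list of (profiles, phases, times, scheme).  With
    ``share_kappa`` a single processed fraction is fitted across all
    experiments (the default, reflecting that mechanical activation should
    not depend on the liquid additive); otherwise each experiment is fitted
    independently so the spread of per-experiment kappa values can be
    examined.
    """
    prepped = []
    for profiles, phases, times, scheme in datasets:
        times = np.asarray(times, dtype=float)
        if phases is None:
            phases, _ = observable_profiles(scheme, np.zeros((1, len(scheme.species))))
        prof, order = _prep_profiles(profiles, phases, scheme)
        prepped.append((prof, order, times, scheme))
    alpha0_list = [alpha0] * len(prepped)
    if share_kappa:
        return _fit_core(prepped, f, kappa0, True, fix_gauge, alpha0_list,
                         rate_bound, seed)
    parts = [
        _fit_core([ds], f, kappa0, True, fix_gauge, [alpha0], rate_bound, seed)
        for ds in prepped
    ]
    return CLCFitResult(
        models=[p.models[0] for p in parts],
        kappa=[p.kappa for p in parts],
        rates=[p.rates[0] for p in parts],
        alpha_P_start=[p.alpha_P_start[0] for p in parts],
        products=[p.products[0] for p in parts],
        rss=float(sum(p.rss for p in parts)),
        bound_hits=[b for p in parts for b in p.bound_hits],
        shared_kappa=False,
    )
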