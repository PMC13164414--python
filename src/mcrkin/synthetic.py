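"""Synthetic time-resolved PXRD series for the three LAG milling scenarios.

Ground truth is built bilinearly: condition-specific reaction networks are
integrated to concentration profiles C_true, each phase gets a sharp-peaked
pseudo-Voigt powder pattern (S_true), and the observed series is
D = C_true·S_trueᵀ plus zero-clipped Gaussian noise.

The pure patterns are fictional (the real cocrystal reflections are not
tabulated here): 5-8 peaks per phase over the 5-35 degree 2theta window, with
one reflection position deliberately shared between Form I and the cocrystal
mixture so that downstream resolution must cope with overlapping phases.
Concentrations are mole-fraction-like (initial total 1); differences in
scattering power between phases are folded into the pattern amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataio import DiffractionSeries
from .kinetics import SCENARIOS, KineticNetwork, generator_network, integrate

__all__ = [
    "PurePattern",
    "ScenarioBundle",
    "pseudo_voigt_pattern",
    "synthesize",
    "make_scenario",
    "default_patterns",
    "DEFAULT_TIMES",
    "DEFAULT_GRID",
]

# 0.5 min frames; the first usable frame lands 0.5 min after milling starts
# (acquisition dead time), giving 161 frames to 80.5 min.
DEFAULT_TIMES = np.arange(1, 162) * 0.5
DEFAULT_GRID = np.linspace(5.0, 35.0, 1500)

# Concentrations below this are treated as never observed (species consumed
# entirely before the first frame, e.g. reagents at 60/90 uL).
OBSERVABLE_EPS = 1e-9


@dataclass(frozen=True)
class PurePattern:
    """Peak list describing one phase: (position deg, amplitude, fwhm deg)."""

    name: str
    peaks: tuple[tuple[float, float, float], ...]
    eta: float = 0.5  # Lorentzian fraction of the pseudo-Voigt profile

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        for pos, amp, fwhm in self.peaks:
            if amp <= 0 or fwhm <= 0:
                raise ValueError(f"{self.name}: amplitudes and fwhm must be positive")


def pseudo_voigt_pattern(pattern: PurePattern, grid: np.ndarray) -> np.ndarray:
    """Evaluate a pattern on a 2theta grid.

    Each peak is amplitude x [eta·L + (1-eta)·G] with both the Lorentzian L
    and the Gaussian G height-normalised to 1 at the peak position, so the
    value at an on-grid peak position equals the amplitude.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    out = np.zeros_like(grid)
    for pos, amp, fwhm in pattern.peaks:
        if fwhm <= 0:
            raise ValueError("fwhm must be positive")
        x = grid - pos
        hwhm = fwhm / 2.0
        lorentz = 1.0 / (1.0 + (x / hwhm) ** 2)
        gauss = np.exp(-4.0 * np.log(2.0) * (x / fwhm) ** 2)
        out += amp * (pattern.eta * lorentz + (1.0 - pattern.eta) * gauss)
    return out


# Phase key: R reagents, A 1:2 cocrystal (forms first), B Form I, C transient
# unknown phase, D 2:1/1:2 cocrystal mixture, P product Form II.  B and D
# share the 14.2 degree reflection (overlapping phases); the leading
# multiplier models relative scattering power.
_PEAK_TABLE: dict[str, tuple[float, tuple[tuple[float, float, float], ...]]] = {
    "R": (0.9, ((6.8, 60, 0.20), (11.5, 100, 0.18), (17.3, 80, 0.22),
                (22.1, 45, 0.25), (26.4, 70, 0.24), (31.0, 30, 0.28))),
    "A": (1.1, ((7.9, 55, 0.18), (12.7, 95, 0.20), (16.1, 70, 0.22),
                (20.5, 60, 0.24), (24.8, 40, 0.25), (29.6, 50, 0.26),
                (33.2, 25, 0.30))),
    "B": (1.0, ((8.6, 70, 0.19), (13.4, 85, 0.21), (14.2, 90, 0.20),
                (18.9, 55, 0.23), (23.5, 65, 0.24), (28.1, 35, 0.27))),
    "C": (0.85, ((9.4, 65, 0.18), (12.1, 50, 0.20), (15.5, 100, 0.21),
                 (19.7, 45, 0.23), (25.9, 75, 0.25), (30.5, 40, 0.27),
                 (34.0, 20, 0.30))),
    "D": (1.05, ((10.2, 80, 0.19), (14.2, 75, 0.20), (16.9, 60, 0.22),
                 (21.3, 90, 0.23), (27.2, 45, 0.26), (32.4, 30, 0.28))),
    "P": (1.2, ((7.2, 50, 0.18), (11.0, 70, 0.19), (15.0, 95, 0.20),
                (19.1, 100, 0.22), (24.1, 60, 0.24), (28.8, 45, 0.26),
                (33.6, 25, 0.29))),
}


def default_patterns(species: Sequence[str]) -> list[PurePattern]:
    """Built-in fictional pure patterns for the requested phases."""
    patterns = []
    for name in species:
        base = "A" if name == "RA" else name
        scale, peaks = _PEAK_TABLE[base]
        patterns.append(
            PurePattern(name, tuple((p, scale * a, w) for p, a, w in peaks))
        )
    return patterns


@dataclass
class ScenarioBundle:
    """One synthetic LAG experiment with its full ground truth."""

    name: str
    series: DiffractionSeries
    S_true: np.ndarray  # n x q pure profiles of the observable phases
    C_true: np.ndarray  # m x q concentration profiles of the observable phases
    network: KineticNetwork  # generating network (all species)
    theta_true: np.ndarray  # rates of network.steps
    seed: int
    observable_species: tuple[str, ...]
    dropped_species: tuple[str, ...]  # consumed before the first frame

    @property
    def n_components(self) -> int:
        return len(self.observable_species)


def synthesize(
    S_true: np.ndarray, C_true: np.ndarray, noise_sd: float, seed: int
) -> np.ndarray:
    """Bilinear mixing with zero-clipped Gaussian noise.

    noise_sd is a fraction of the maximum noiseless intensity; identical
    seeds give bit-identical output.
    """
    S_true = np.asarray(S_true, dtype=float)
    C_true = np.asarray(C_true, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    clean = C_true @ S_true.T
    if noise_sd == 0:
        return clean.copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd * clean.max(), size=clean.shape)
    return np.clip(clean + noise, 0.0, None)


def make_scenario(
    name: str,
    times: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    theta: Sequence[float] | None = None,
) -> ScenarioBundle:
    """Build the full synthetic dataset for one LAG scenario.

    At 60/90 uL the generating network consumes the reagents two orders of
    magnitude faster than the frame rate, so their concentration column is
    numerically zero at every sampled frame: the reagent phase is dropped
    from the observable ground truth and the series is rank-deficient with
    respect to the generating species (the merged-first-component effect).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid: {', '.join(SCENARIOS)}")
    times = DEFAULT_TIMES if times is None else np.asarray(times, dtype=float)
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)

    network = generator_network(name)
    if theta is not None:
        network = network.with_rates(theta)
    theta_true = network.rates

    t_solve = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    traj = integrate(network, t_solve)
    if times[0] != 0.0:
        traj = traj[1:]

    observable = [i for i in range(len(network.species))
                  if traj[:, i].max() > OBSERVABLE_EPS]
    dropped = tuple(s for i, s in enumerate(network.species) if i not in observable)
    species = tuple(network.species[i] for i in observable)
    C_true = traj[:, observable]
    S_true = np.column_stack(
        [pseudo_voigt_pattern(p, grid) for p in default_patterns(species)]
    )

    intensities = synthesize(S_true, C_true, noise_sd, seed)
    series = DiffractionSeries(times, grid, intensities)
    return ScenarioBundle(
        name=name,
        series=series,
        S_true=S_true,
        C_true=C_true,
        network=network,
        theta_true=theta_true,
        seed=seed,
        observable_species=species,
        dropped_species=dropped,
    )
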