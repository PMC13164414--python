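"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Decomposes a frames x channels series D into D ~ C·Sᵀ, alternating exact
constrained least-squares solves for the concentration matrix C (given S) and
the pure-profile matrix S (given C).  Non-negativity uses an active-set NNLS
per row/channel — not clip-after-solve — so each half step is an exact
constrained minimiser and the lack of fit can never increase.

Bilinear factorisations carry intrinsic permutation and per-component scale
ambiguity; :func:`match_components` resolves both for comparisons against a
known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .dataio import DiffractionSeries

__all__ = ["MCRConstraints", "MCRResult", "als_fit", "lack_of_fit",
           "match_components"]


@dataclass(frozen=True)
class MCRConstraints:
    """Soft constraints applied during ALS.

    closure rescales every C row to the given total (off by default: PXRD
    intensities are in arbitrary units).  s_normalization fixes the scale
    ambiguity: 'max1' scales each pure profile to unit maximum (comparable to
    reference patterns), 'unit' to unit length, 'none' leaves scales free;
    the compensating factor always moves into C, leaving the fit unchanged.
    """

    nonneg_C: bool = True
    nonneg_S: bool = True
    closure: float | None = None
    s_normalization: str = "max1"

    def __post_init__(self) -> None:
        if self.closure is not None and self.closure <= 0:
            raise ValueError("closure total must be positive")
        if self.s_normalization not in ("none", "max1", "unit"):
            raise ValueError("s_normalization must be 'none', 'max1' or 'unit'")


@dataclass
class MCRResult:
    C: np.ndarray  # m x q concentration profiles (arbitrary units)
    S: np.ndarray  # n x q pure profiles
    times: np.ndarray
    two_theta: np.ndarray
    lof_percent: float
    r2: float
    lof_trace: np.ndarray
    iterations: int
    converged: bool
    fitted_theta: dict[str, float] | None = None
    theta_trace: list[dict[str, float]] | None = None
    scales: np.ndarray | None = None  # per-component scales of the kinetic model


def lack_of_fit(D: np.ndarray, C: np.ndarray, S: np.ndarray) -> tuple[float, float]:
    """Percent lack of fit and explained variance of the model C·Sᵀ.

    LOF = 100·sqrt(sum (d_ij - (CSᵀ)_ij)² / sum d_ij²); r2 = 1 - (LOF/100)².
    """
    D = np.asarray(D, dtype=float)
    denom = float(np.sum(D * D))
    if denom == 0.0:
        raise ValueError("lack of fit undefined for an all-zero data matrix")
    resid = D - C @ S.T
    ratio = float(np.sum(resid * resid)) / denom
    return 100.0 * np.sqrt(ratio), 1.0 - ratio


def _solve_rows(A: np.ndarray, B: np.ndarray, nonneg: bool) -> np.ndarray:
    """Solve min ||A x - b|| for every column b of B; returns (B columns) x q."""
    if not nonneg:
        sol, *_ = np.linalg.lstsq(A, B, rcond=None)
        return sol.T
    out = np.empty((B.shape[1], A.shape[1]))
    for j in range(B.shape[1]):
        out[j], _ = nnls(A, B[:, j])
    return out


def als_fit(
    series,
    init: np.ndarray,
    constraints: MCRConstraints | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    _c_hook=None,
) -> MCRResult:
    """Alternating least squares from an initial S0 (n x q) or C0 (m x q).

    The orientation of ``init`` is inferred from its row count.  Stops when
    the absolute change in LOF drops below ``tol`` or after ``max_iter``
    iterations.  ``_c_hook(C_soft, iteration)`` is an internal extension point
    (the kinetic constraint); it receives the freshly solved C and returns the
    C actually used for the S update.
    """
    if isinstance(series, DiffractionSeries):
        D, times, two_theta = series.intensities, series.times, series.two_theta
    else:
        D = np.asarray(series, dtype=float)
        times = np.arange(D.shape[0], dtype=float)
        two_theta = np.arange(D.shape[1], dtype=float)
    constraints = constraints or MCRConstraints()
    m, n = D.shape

    init = np.asarray(init, dtype=float)
    if init.ndim != 2:
        raise ValueError("init must be a 2-D matrix")
    q = init.shape[1]
    if q > min(m, n):
        raise ValueError(f"q={q} exceeds min(m, n)={min(m, n)}")
    if init.shape[0] == n:
        S, C = init.copy(), None
    elif init.shape[0] == m:
        C, S = init.copy(), None
    else:
        raise ValueError(
            f"init rows {init.shape[0]} match neither n={n} (S0) nor m={m} (C0)"
        )
    if np.any(init < 0) and (constraints.nonneg_C or constraints.nonneg_S):
        warnings.warn("negative entries in init clipped to 0", stacklevel=2)
        if S is not None:
            S = np.clip(S, 0.0, None)
        else:
            C = np.clip(C, 0.0, None)

    if C is not None and S is None:
        # C0 given: get a starting S by one S-solve
        S = _solve_rows(C, D, constraints.nonneg_S)

    lof_trace: list[float] = []
    converged = False
    iterations = 0
    for it in range(1, max_iter + 1):
        C = _solve_rows(S, D.T, constraints.nonneg_C)
        if _c_hook is not None:
            C = _c_hook(C, it)
        S = _solve_rows(C, D, constraints.nonneg_S)

        # fix the scale ambiguity: move S scales into C
        if constraints.s_normalization != "none":
            scale = (S.max(axis=0) if constraints.s_normalization == "max1"
                     else np.linalg.norm(S, axis=0))
            scale = np.where(scale > 0, scale, 1.0)
            S = S / scale
            C = C * scale
        if constraints.closure is not None:
            row_sums = C.sum(axis=1)
            factor = np.where(row_sums > 0, constraints.closure / np.where(
                row_sums > 0, row_sums, 1.0), 1.0)
            C = C * factor[:, None]

        lof, r2 = lack_of_fit(D, C, S)
        lof_trace.append(lof)
        iterations = it
        if len(lof_trace) >= 2 and abs(lof_trace[-2] - lof_trace[-1]) < tol:
            converged = True
            break

    return MCRResult(
        C=C, S=S, times=times, two_theta=two_theta,
        lof_percent=lof_trace[-1], r2=r2, lof_trace=np.asarray(lof_trace),
        iterations=iterations, converged=converged,
    )


def match_components(
    C_est: np.ndarray, C_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the permutation ambiguity against a reference set of profiles.

    Returns ``(perm, sims)`` where ``perm[j]`` is the estimated column
    assigned to reference column j (assignment maximising total cosine
    similarity) and ``sims[j]`` the corresponding similarity.  Cosine
    similarity is scale-invariant; all-zero columns score 0.
    """
    C_est = np.asarray(C_est, dtype=float)
    C_true = np.asarray(C_true, dtype=float)
    if C_est.shape != C_true.shape:
        raise ValueError("component sets must have identical shapes")
    ne = np.linalg.norm(C_est, axis=0)
    nt = np.linalg.norm(C_true, axis=0)
    sim = (C_est.T @ C_true) / np.outer(np.where(ne > 0, ne, 1.0),
                                        np.where(nt > 0, nt, 1.0))
    sim[ne == 0, :] = 0.0
    sim[:, nt == 0] = 0.0
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(C_true.shape[1], dtype=int)
    sims = np.empty(C_true.shape[1])
    for r, c in zip(rows, cols):
        perm[c] = r
        sims[c] = sim[r, c]
    return perm, sims
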