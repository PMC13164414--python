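"""Exploratory chemometrics: rank estimation and SIMPLISMA initial estimates.

SIMPLISMA (SIMPLe-to-use Interactive Self-modelling Mixture Analysis) picks
"purest" variables of a mixture matrix — frames whose diffractogram is closest
to a single-phase pattern, or 2theta channels dominated by a single phase —
and assembles them verbatim into the initial estimate (S0 or C0) that seeds
the alternating least-squares resolution.

Purity of candidate j is sd_j / (mean_j + delta) with delta a noise offset
(a fraction alpha of the largest mean, suppressing spurious purity of weak
noisy variables).  From the second selection round on, purity is weighted by
the Gram determinant of the length-normalised already-selected vectors
augmented with the candidate (correlation around the origin, appropriate for
non-negative signals), which zeroes the weight of anything collinear with
earlier picks and guarantees no variable is selected twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import DiffractionSeries

__all__ = ["RankEstimate", "SimplismaSelection", "estimate_rank", "simplisma"]


@dataclass
class RankEstimate:
    """Singular spectrum with two rank readings.

    ``rank`` counts singular values with sigma_i/sigma_1 above a relative
    threshold (meaningful for noiseless matrices); ``elbow_rank`` takes the
    largest gap in log sigma, a noise-aware reading reported separately.
    """

    rank: int
    elbow_rank: int
    singular_values: np.ndarray
    threshold: float


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, DiffractionSeries):
        return data.intensities
    return np.asarray(data, dtype=float)


def estimate_rank(data, threshold: float = 1e-10) -> RankEstimate:
    """SVD-based rank of a series or matrix; all-zero input has rank 0."""
    X = _as_matrix(data)
    if X.size == 0:
        raise ValueError("empty matrix")
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[0] == 0.0:
        return RankEstimate(0, 0, sv, threshold)
    rank = int(np.sum(sv / sv[0] > threshold))
    positive = sv[sv > 0]
    if positive.size < 2:
        elbow = positive.size
    else:
        gaps = np.diff(np.log(positive))
        elbow = int(np.argmin(gaps)) + 1  # largest downward gap in log sigma
    return RankEstimate(rank, elbow, sv, threshold)


@dataclass
class SimplismaSelection:
    """Pure-variable picks and the initial estimate assembled from them."""

    indices: list[int]
    purity_trace: list[float]
    initial_estimate: np.ndarray  # S0 (n x q) in frames mode, C0 (m x q) in channels mode
    mode: str
    alpha: float


def simplisma(
    series, q: int, alpha: float = 0.03, mode: str = "frames"
) -> SimplismaSelection:
    """Select q purest frames (-> S0) or channels (-> C0).

    frames mode treats each time frame's diffractogram as a candidate pure
    pattern; channels mode treats each 2theta channel's time trace as a
    candidate concentration profile.
    """
    X = _as_matrix(series)
    m, n = X.shape
    if mode not in ("frames", "channels"):
        raise ValueError("mode must be 'frames' or 'channels'")
    if not 1 <= q <= min(m, n):
        raise ValueError(f"q={q} outside 1..min(m, n)={min(m, n)}")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")

    # candidate vectors as columns
    V = X.T if mode == "frames" else X
    mu = V.mean(axis=0)
    sd = V.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("no variance: all candidate vectors are constant")
    delta = alpha * mu.max()
    base_purity = sd / (mu + delta)

    norms = np.linalg.norm(V, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    U = V / safe  # length-normalised candidates
    gram_full = U.T @ U  # correlation around the origin

    selected: list[int] = []
    trace: list[float] = []
    for _ in range(q):
        if not selected:
            weights = np.ones(V.shape[1])
        else:
            weights = np.empty(V.shape[1])
            sel = np.array(selected)
            G_sel = gram_full[np.ix_(sel, sel)]
            cross = gram_full[np.ix_(sel, np.arange(V.shape[1]))]
            for j in range(V.shape[1]):
                G = np.empty((len(sel) + 1, len(sel) + 1))
                G[:-1, :-1] = G_sel
                G[:-1, -1] = cross[:, j]
                G[-1, :-1] = cross[:, j]
                G[-1, -1] = gram_full[j, j]
                weights[j] = max(np.linalg.det(G), 0.0)
        purity = weights * base_purity
        purity[norms == 0] = 0.0
        pick = int(np.argmax(purity))
        selected.append(pick)
        trace.append(float(purity[pick]))

    if mode == "frames":
        estimate = X[selected, :].T  # selected frame patterns as S0 columns
    else:
        estimate = X[:, selected]  # selected channel traces as C0 columns
    return SimplismaSelection(selected, trace, estimate, mode, alpha)
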