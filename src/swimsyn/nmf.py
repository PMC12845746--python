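"""Muscle-synergy extraction by non-negative matrix factorisation.

An envelope cycle ``D`` (muscles x 100, nonnegative) is approximated as
``W @ C`` with ``W >= 0`` (muscles x k synergy weights) and ``C >= 0``
(k x 100 activation coefficients), fitted by Lee-Seung multiplicative
updates on the Frobenius objective. Goodness of fit is the uncentred
variance accounted for, ``VAF = 1 - SSE/SST`` with ``SST = sum(D**2)``
(the convention standard for global synergy VAF; a centred variant is
selectable). The number of synergies is the smallest order whose best-restart
VAF exceeds the threshold (default 0.90), swept over a k range.

Each restart is initialised i.i.d. uniform on (0, max(D)] and run to
convergence (VAF change below ``tol`` over a 10-iteration window); the
restart with the highest VAF wins. Early stopping at the VAF threshold is
deliberately not done within a fit — it would make the reported VAF depend
on iteration scheduling.
"""

from __future__ import annotations

import numpy as np

from .config import SynergyParams
from .core import SynergySet
from .errors import InvalidOrderError, InvalidParameterError, UndefinedVafError

_EPS = 1e-12  # denominator guard in multiplicative updates


def vaf(data: np.ndarray, reconstruction: np.ndarray, *, centered: bool = False) -> float:
    """Variance accounted for: 1 - SSE/SST.

    SST is the uncentred sum of squares of ``data`` unless ``centered``.
    """
    data = np.asarray(data, dtype=float)
    reconstruction = np.asarray(reconstruction, dtype=float)
    if data.shape != reconstruction.shape:
        raise InvalidParameterError("data and reconstruction shapes differ")
    sse = float(np.sum((data - reconstruction) ** 2))
    sst = float(np.sum((data - data.mean()) ** 2) if centered else np.sum(data**2))
    if sst <= 0:
        raise UndefinedVafError("VAF undefined for all-zero data")
    return 1.0 - sse / sst


def _multiplicative_updates(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    centered: bool,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """One NMF restart; returns (W, H, vaf, objective trace every 10 iters)."""
    n, m = V.shape
    vmax = float(V.max())
    W = rng.uniform(0.0, vmax, size=(n, k)) + _EPS  # exclude exact zeros
    H = rng.uniform(0.0, vmax, size=(k, m)) + _EPS
    trace = []
    prev_vaf = -np.inf
    current_vaf = vaf(V, W @ H, centered=centered)
    for it in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ H @ H.T + _EPS)
        if (it + 1) % 10 == 0:
            R = W @ H
            trace.append(float(np.sum((V - R) ** 2)))
            current_vaf = vaf(V, R, centered=centered)
            if abs(current_vaf - prev_vaf) < tol:
                break
            prev_vaf = current_vaf
    current_vaf = vaf(V, W @ H, centered=centered)
    return W, H, current_vaf, np.asarray(trace)


def _normalize_factors(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm weight columns with compensating activation row scaling."""
    norms = np.linalg.norm(W, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return W / safe, H * norms[:, None]


def nmf_fit(
    data: np.ndarray,
    k: int,
    seed: int,
    *,
    n_restarts: int = 20,
    max_iter: int = 1000,
    tol: float = 1e-6,
    centered: bool = False,
    muscle_labels: tuple[str, ...] | None = None,
    subject_id: str = "",
    group: str = "",
    timepoint: str = "",
) -> SynergySet:
    """Best-of-restarts order-k factorisation of one envelope matrix."""
    V = np.asarray(data, dtype=float)
    if V.ndim != 2 or np.any(V < 0):
        raise InvalidParameterError("data must be a nonnegative 2-D matrix")
    if not 1 <= k <= min(V.shape):
        raise InvalidOrderError(f"order k={k} outside [1, {min(V.shape)}]")
    if not np.any(V > 0):
        raise UndefinedVafError("cannot factor an all-zero matrix")
    ss = np.random.SeedSequence([int(seed), k])
    best = None
    for child in ss.spawn(n_restarts):
        W, H, v, trace = _multiplicative_updates(
            V, k, np.random.default_rng(child), max_iter, tol, centered
        )
        if best is None or v > best[2]:
            best = (W, H, v, trace)
    W, H, _, trace = best
    W, H = _normalize_factors(W, H)
    if muscle_labels is None:
        muscle_labels = tuple(f"m{i:02d}" for i in range(V.shape[0]))
    return SynergySet(
        weights=W,
        activations=H,
        vaf=vaf(V, W @ H, centered=centered),
        k=k,
        muscle_labels=muscle_labels,
        restarts_used=n_restarts,
        objective_trace=trace,
        subject_id=subject_id,
        group=group,
        timepoint=timepoint,
    )


def select_order(
    data: np.ndarray,
    seed: int,
    params: SynergyParams | None = None,
    **fit_kwargs,
) -> SynergySet:
    """Smallest order whose VAF exceeds the threshold.

    Sweeps k upward through the configured range (capped at the matrix's
    feasible rank: requesting more synergies than muscles is degenerate) and
    returns the first factorisation with ``vaf > threshold``. If no order
    qualifies, the highest-VAF factorisation is returned with
    ``converged_selection=False``.
    """
    params = params or SynergyParams()
    V = np.asarray(data, dtype=float)
    k_hi = min(params.k_max, min(V.shape))
    if params.k_min < 1 or params.k_min > k_hi:
        raise InvalidOrderError(
            f"empty order range [{params.k_min}, {k_hi}] for shape {V.shape}"
        )
    best = None
    for k in range(params.k_min, k_hi + 1):
        fit = nmf_fit(
            V,
            k,
            seed,
            n_restarts=params.n_restarts,
            max_iter=params.max_iter,
            tol=params.tol,
            centered=params.centered_sst,
            **fit_kwargs,
        )
        if fit.vaf > params.vaf_threshold:
            return fit
        if best is None or fit.vaf > best.vaf:
            best = fit
    best.converged_selection = False
    return best
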