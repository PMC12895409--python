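"""Weighted-ensemble expectation values, populations and coherences.

Individual-trajectory expectation values are quadratic forms
``A_j(t) = sum_{i,i'} c_i*(t) c_i'(t) M_{ii'}(t)`` in the adiabatic
operator matrix ``M`` carried by the trajectory record (for example the
molecular dipole).  They split exactly into a population part
(diagonal of M) and a coherence part (off-diagonal), and ensemble
aggregates are weighted sums ``<A>(t) = sum_j w_j A_j(t)`` with the
scheme's weights; dividing by ``sum_j w_j`` gives the display-normalized
aggregate directly comparable with individual member series.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import au_to_fs

__all__ = [
    "WeightedEnsembleResult",
    "member_expectation",
    "scheme_average",
    "active_state_expectation",
    "standard_series",
    "internal_consistency",
]


@dataclass
class WeightedEnsembleResult:
    """Aggregated time series with its population/coherence split."""

    times: np.ndarray
    member_values: np.ndarray  # (n_members, T)
    weights: np.ndarray
    aggregate: np.ndarray  # (T,)
    pop: np.ndarray  # population contribution
    coh: np.ndarray  # coherence contribution
    normalized: bool


def member_expectation(
    coeffs_series: np.ndarray, matrix_series: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expectation value of one member, split into population + coherence.

    ``coeffs_series`` has shape ``(T, N)``; ``matrix_series`` is either a
    static ``(N, N)`` Hermitian operator matrix or a per-step ``(T, N, N)``
    series.  Returns ``(A, A_pop, A_coh)`` real arrays of length T with
    ``A = A_pop + A_coh`` exactly.
    """
    c = np.asarray(coeffs_series, dtype=complex)
    M = np.asarray(matrix_series)
    if c.ndim != 2:
        raise ValueError("coeffs_series must have shape (T, N)")
    T, N = c.shape
    if M.ndim == 2:
        M = np.broadcast_to(M, (T, N, N))
    if M.shape != (T, N, N):
        raise ValueError(
            f"matrix_series shape {M.shape} incompatible with coefficients {(T, N)}"
        )
    full = np.einsum("ti,tij,tj->t", np.conj(c), M, c)
    diag = np.einsum("ti,tii->t", np.abs(c) ** 2, M.real)
    A = full.real
    return A, diag, A - diag


def scheme_average(
    member_series: Sequence[np.ndarray] | np.ndarray,
    weights: np.ndarray,
    times: np.ndarray,
    normalized: bool = True,
    member_pop: Sequence[np.ndarray] | None = None,
) -> WeightedEnsembleResult:
    """Weighted ensemble aggregate of per-member expectation values.

    ``normalized=True`` divides by ``sum_j w_j`` so the aggregate lives on
    the same scale as the member series; raw mode returns the plain
    weighted sum.  If per-member population parts are given, the
    population/coherence split of the aggregate is carried along.
    """
    A = np.asarray(member_series, dtype=float)
    w = np.asarray(weights, dtype=float)
    if A.shape[0] != w.size:
        raise ValueError("one weight per member series required")
    wsum = w.sum()
    if normalized and wsum == 0:
        raise ValueError("cannot normalize: total weight is zero")
    denom = wsum if normalized else 1.0
    agg = (w @ A) / denom
    if member_pop is not None:
        pop = (w @ np.asarray(member_pop, dtype=float)) / denom
        coh = agg - pop
    else:
        pop = agg
        coh = np.zeros_like(agg)
    return WeightedEnsembleResult(
        times=np.asarray(times),
        member_values=A,
        weights=w,
        aggregate=agg,
        pop=pop,
        coh=coh,
        normalized=normalized,
    )


def active_state_expectation(
    active_series: np.ndarray, matrix_series: np.ndarray
) -> np.ndarray:
    """Active-state-only expectation M_bb(t) (coherences disregarded)."""
    M = np.asarray(matrix_series)
    b = np.asarray(active_series, dtype=int)
    T = b.size
    if M.ndim == 2:
        M = np.broadcast_to(M, (T,) + M.shape)
    return M[np.arange(T), b, b].real


def standard_series(
    coeff_series: Sequence[np.ndarray],
    weights: np.ndarray,
    times: np.ndarray,
    dipole_series: Sequence[np.ndarray] | None = None,
    normalized: bool = True,
) -> dict[str, pd.DataFrame]:
    """Aggregated populations, pairwise coherences and dipole components.

    Returns a dict of tidy DataFrames indexed by time in fs:
    ``populations`` (one column P_i per state), ``coherences``
    (Re(c_i* c_j) per pair i<j) and, when per-member adiabatic dipole
    matrices are supplied, ``dipole`` (x, y, z components).
    """
    w = np.asarray(weights, dtype=float)
    denom = w.sum() if normalized else 1.0
    if denom == 0:
        raise ValueError("total weight is zero")
    cs = np.asarray(coeff_series, dtype=complex)  # (J, T, N)
    J, T, N = cs.shape
    t_fs = au_to_fs(np.asarray(times))

    pops = np.einsum("j,jti->ti", w, np.abs(cs) ** 2) / denom
    out = {
        "populations": pd.DataFrame(
            pops, index=pd.Index(t_fs, name="t_fs"),
            columns=[f"P{i}" for i in range(N)],
        )
    }

    coh_cols = {}
    for i, k in combinations(range(N), 2):
        series = np.einsum("j,jt->t", w, (np.conj(cs[:, :, i]) * cs[:, :, k]).real)
        coh_cols[f"Re_c{i}c{k}"] = series / denom
    out["coherences"] = pd.DataFrame(coh_cols, index=pd.Index(t_fs, name="t_fs"))

    if dipole_series is not None:
        D = np.asarray(dipole_series)  # (J, T, N, N, 3)
        comp = np.einsum("j,jti,jtikx,jtk->tx", w, np.conj(cs), D, cs).real / denom
        out["dipole"] = pd.DataFrame(
            comp, index=pd.Index(t_fs, name="t_fs"), columns=["d_x", "d_y", "d_z"]
        )
    return out


def internal_consistency(
    coeff_series: Sequence[np.ndarray],
    active_series: Sequence[np.ndarray],
) -> np.ndarray:
    """Gap between mean quantum populations and active-state fractions.

    Returns ``|<|c_i|^2> - fraction(b = i)|`` with shape ``(T, N)``; an
    internally consistent ensemble keeps this near zero for every state.
    Both averages are unweighted, as in the consistency criterion.
    """
    cs = np.asarray(coeff_series, dtype=complex)  # (J, T, N)
    act = np.asarray(active_series, dtype=int)  # (J, T)
    J, T, N = cs.shape
    mean_pop = np.mean(np.abs(cs) ** 2, axis=0)
    frac = np.zeros((T, N))
    for i in range(N):
        frac[:, i] = np.mean(act == i, axis=0)
    return np.abs(mean_pop - frac)
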