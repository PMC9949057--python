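"""Alchemical free-energy estimation across a λ schedule.

Given samples from K states with reduced energies u_j(x)/kT known in every
state, the multistate Bennett acceptance ratio (MBAR) equations

    f_j = −ln Σ_n exp(−u_j(x_n)) / Σ_k N_k exp(f_k − u_k(x_n))

are solved self-consistently and refined by Newton iterations on the convex
MBAR objective; uncertainties come from the asymptotic covariance of the
estimator.  Cross-checks against BAR chained over adjacent states (BAR is
the two-state special case of MBAR), forward/reverse exponential averaging
and thermodynamic integration are provided, mirroring the usual practice of
reporting MBAR once the methods agree.

Internally everything is in reduced (kT) units; conversion to kJ/mol happens
only at reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from rndflux.cycles import FreeEnergyLeg

__all__ = [
    "AlchemicalDataset",
    "MbarResult",
    "mbar_solve",
    "mbar_leg",
    "bar_chain",
    "exp_averaging",
    "thermodynamic_integration",
    "cross_check",
    "discard_equilibration",
    "analyse_repeats",
]


@dataclass
class AlchemicalDataset:
    """Per-state samples with reduced energies evaluated in every state.

    ``u[k]`` is a (K, N_k) array: sample n drawn in state k, evaluated in
    every state j, in kT units.  ``ground_truth`` (optional) carries exact
    per-state free energies in kJ/mol relative to state 0, for synthetic
    data.  ``dudl`` (optional, per-state arrays of du/dλ in kT per unit λ)
    enables the TI cross-check.
    """

    u: list
    lambda_schedule: np.ndarray
    kT: float
    ground_truth: np.ndarray | None = None
    dudl: list | None = None
    labels: tuple[str, str] = ("lambda=0", "lambda=1")

    def __post_init__(self) -> None:
        self.u = [np.asarray(uk, dtype=float) for uk in self.u]
        self.lambda_schedule = np.asarray(self.lambda_schedule, dtype=float)
        K = len(self.u)
        if K < 2:
            raise ValueError("at least 2 states are required")
        if self.lambda_schedule.size != K:
            raise ValueError(
                f"lambda schedule has {self.lambda_schedule.size} values for "
                f"{K} sampled states"
            )
        if np.unique(self.lambda_schedule).size != K or np.any(
            np.diff(self.lambda_schedule) <= 0
        ):
            raise ValueError("lambda values must be unique and sorted")
        for k, uk in enumerate(self.u):
            if uk.ndim != 2 or uk.shape[0] != K:
                raise ValueError(
                    f"u[{k}] must have shape (K, N_k); got {uk.shape} with K={K}"
                )
            if uk.shape[1] < 1:
                raise ValueError(f"state {k} has no samples")
            if not np.all(np.isfinite(uk)):
                raise ValueError(f"non-finite reduced energies in state {k}")
        if self.kT <= 0:
            raise ValueError("kT must be positive")

    @property
    def n_states(self) -> int:
        return len(self.u)

    @property
    def N_k(self) -> np.ndarray:
        return np.array([uk.shape[1] for uk in self.u])

    def u_jn(self) -> np.ndarray:
        """All samples flattened in state order: shape (K, Σ_k N_k)."""
        return np.concatenate(self.u, axis=1)

    def reversed(self) -> "AlchemicalDataset":
        """The same data with the state order (and λ direction) reversed."""
        K = self.n_states
        order = np.arange(K)[::-1]
        u_rev = [self.u[k][order, :] for k in order]
        lam = 1.0 - self.lambda_schedule[order] if np.all(
            (self.lambda_schedule >= 0) & (self.lambda_schedule <= 1)
        ) else -self.lambda_schedule[order]
        gt = None
        if self.ground_truth is not None:
            g = self.ground_truth[order]
            gt = g - g[0]
        dudl = None if self.dudl is None else [self.dudl[k] for k in order]
        return AlchemicalDataset(
            u=u_rev,
            lambda_schedule=lam,
            kT=self.kT,
            ground_truth=gt,
            dudl=dudl,
            labels=(self.labels[1], self.labels[0]),
        )

    def subset(self, states: Sequence[int]) -> "AlchemicalDataset":
        states = list(states)
        idx = np.asarray(states)
        return AlchemicalDataset(
            u=[self.u[k][idx, :] for k in states],
            lambda_schedule=self.lambda_schedule[idx],
            kT=self.kT,
            ground_truth=None
            if self.ground_truth is None
            else self.ground_truth[idx] - self.ground_truth[idx[0]],
            dudl=None if self.dudl is None else [self.dudl[k] for k in states],
            labels=self.labels,
        )


@dataclass
class MbarResult:
    """Converged MBAR free energies (kT units, relative to state 0)."""

    f_kT: np.ndarray
    covariance_kT2: np.ndarray
    overlap: np.ndarray
    kT: float
    iterations: int
    gradient_norm: float

    def delta_g(self, i: int = 0, j: int = -1) -> tuple[float, float]:
        """ΔG(i→j) and its standard error in kJ/mol."""
        j = j % self.f_kT.size
        value = (self.f_kT[j] - self.f_kT[i]) * self.kT
        var = (
            self.covariance_kT2[i, i]
            + self.covariance_kT2[j, j]
            - 2.0 * self.covariance_kT2[i, j]
        )
        return float(value), float(self.kT * math.sqrt(max(var, 0.0)))


def _mbar_core(
    u_jn: np.ndarray,
    N_k: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Solve the MBAR equations; returns (f, W, iterations, grad norm)."""
    K, N = u_jn.shape
    log_N = np.log(N_k)
    f = np.zeros(K)

    def log_denom(f):
        return logsumexp(log_N[:, None] + f[:, None] - u_jn, axis=0)

    def gradient(f, d):
        # ∂/∂f_j of Σ_n ln Σ_k N_k exp(f_k − u_kn) − Σ_k N_k f_k
        w_sum = np.exp(logsumexp(f[:, None] - u_jn - d[None, :], axis=1))
        return N_k * (w_sum - 1.0)

    it = 0
    # Self-consistent warm-up.
    for _ in range(100):
        d = log_denom(f)
        f_new = -logsumexp(-u_jn - d[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        it += 1
        if delta < 1e-10:
            break
    # Newton refinement on the convex objective (f_0 fixed as gauge).
    grad_norm = np.inf
    while it < max_iter:
        d = log_denom(f)
        W = np.exp(f[:, None] - u_jn - d[None, :])  # (K, N), cols sum w/ N_k to 1
        g = N_k * (W.sum(axis=1) - 1.0)
        grad_norm = float(np.max(np.abs(g) / N_k))
        if grad_norm < tol:
            break
        WN = W * N_k[:, None]
        H = np.diag((WN).sum(axis=1)) - WN @ WN.T / 1.0  # K x K
        # Hessian of objective: δ_ij Σ_n N_j W_jn − Σ_n N_i W_in N_j W_jn
        try:
            step = np.linalg.solve(H[1:, 1:], g[1:])
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H[1:, 1:], g[1:], rcond=None)[0]
        if not np.all(np.isfinite(step)):
            raise RuntimeError("MBAR Newton step is not finite")
        # Damp long steps to stay in the convergence basin.
        scale = min(1.0, 2.0 / max(np.max(np.abs(step)), 1e-12))
        f[1:] -= scale * step
        it += 1
    else:
        raise RuntimeError(
            f"MBAR did not converge in {max_iter} iterations "
            f"(gradient norm {grad_norm:.3e}, tol {tol:.1e})"
        )
    d = log_denom(f)
    W = np.exp(f[:, None] - u_jn - d[None, :])
    return f, W, it, grad_norm


def _asymptotic_covariance(W: np.ndarray, N_k: np.ndarray) -> np.ndarray:
    """Θ from the SVD form: Θ = V S (I − S Vᵀ diag(N) V S)⁺ S Vᵀ."""
    A = W.T  # (N, K)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    V = Vt.T
    S = np.diag(s)
    inner = np.eye(s.size) - S @ V.T @ (N_k[:, None] * V) @ S
    theta = V @ S @ np.linalg.pinv(inner, rcond=1e-10) @ S @ V.T
    return theta


def _overlap_matrix(W: np.ndarray, N_k: np.ndarray) -> np.ndarray:
    """O_ij = Σ_n W_ni N_j W_nj; rows sum to 1 at the solution."""
    return (W @ W.T) * N_k[None, :]


def mbar_solve(
    data: AlchemicalDataset,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    overlap_warn: float = 0.03,
) -> MbarResult:
    """Solve MBAR for the dataset, with overlap diagnostics.

    Warns when the smallest adjacent-state overlap-matrix entry drops below
    ``overlap_warn`` and raises when adjacent states share essentially no
    overlap (the chain of states is disconnected).
    """
    u_jn = data.u_jn()
    N_k = data.N_k
    f, W, it, grad_norm = _mbar_core(u_jn, N_k, tol, max_iter)
    overlap = _overlap_matrix(W, N_k)
    adj = np.array(
        [
            max(overlap[i, i + 1], overlap[i + 1, i])
            for i in range(data.n_states - 1)
        ]
    )
    if np.any(adj < 1e-12):
        i = int(np.argmin(adj))
        raise ValueError(
            f"no phase-space overlap between adjacent states {i} and {i + 1}; "
            "free energies are not estimable"
        )
    if np.any(adj < overlap_warn):
        i = int(np.argmin(adj))
        warnings.warn(
            f"poor overlap between adjacent states {i} and {i + 1} "
            f"(min overlap {adj[i]:.4f} < {overlap_warn})",
            stacklevel=2,
        )
    theta = _asymptotic_covariance(W, N_k)
    return MbarResult(
        f_kT=f,
        covariance_kT2=theta,
        overlap=overlap,
        kT=data.kT,
        iterations=it,
        gradient_norm=grad_norm,
    )


def mbar_leg(data: AlchemicalDataset, label: str = "") -> FreeEnergyLeg:
    """End-to-end MBAR free-energy leg (state 0 → state K−1) in kJ/mol."""
    res = mbar_solve(data)
    value, err = res.delta_g(0, -1)
    return FreeEnergyLeg(
        value=value,
        error=err,
        from_state=data.labels[0],
        to_state=data.labels[1],
        method="mbar",
        label=label,
    )


def bar_chain(data: AlchemicalDataset) -> tuple[float, float, list]:
    """ΔG(0→K−1) as a chain of pairwise BAR legs (kJ/mol).

    BAR is solved as the two-state special case of MBAR on each adjacent
    pair; pair errors combine in quadrature.  Returns (value, error,
    per-pair list of (value, error)).
    """
    pairs = []
    for i in range(data.n_states - 1):
        sub = data.subset([i, i + 1])
        res = mbar_solve(sub)
        pairs.append(res.delta_g(0, 1))
    value = sum(v for v, _ in pairs)
    error = math.sqrt(sum(e**2 for _, e in pairs))
    return value, error, pairs


def exp_averaging(data: AlchemicalDataset, direction: str = "forward"):
    """ΔG(0→K−1) by exponential averaging over adjacent pairs (kJ/mol).

    forward uses samples of state i:   Δf = −ln⟨exp(−(u_{i+1} − u_i))⟩_i
    reverse uses samples of state i+1: Δf = +ln⟨exp(+(u_{i+1} − u_i))⟩_{i+1}

    Per-pair errors by the delta method, combined in quadrature.  Forward
    averaging is biased high and reverse biased low at finite sample size
    (Jensen's inequality), so the two bracket the converged value.
    """
    total = 0.0
    var = 0.0
    for i in range(data.n_states - 1):
        if direction == "forward":
            w = data.u[i][i + 1, :] - data.u[i][i, :]
            n = w.size
            m = logsumexp(-w) - math.log(n)
            df = -m
            s = np.exp(-w - m)  # mean 1 by construction
        elif direction == "reverse":
            w = data.u[i + 1][i + 1, :] - data.u[i + 1][i, :]
            n = w.size
            m = logsumexp(w) - math.log(n)
            df = m
            s = np.exp(w - m)
        else:
            raise ValueError("direction must be 'forward' or 'reverse'")
        total += df
        var += float(np.var(s, ddof=1)) / n  # var of ln-mean via delta method
    return total * data.kT, math.sqrt(var) * data.kT


def thermodynamic_integration(data: AlchemicalDataset):
    """ΔG(0→K−1) by trapezoid integration of ⟨du/dλ⟩ (kJ/mol).

    Requires ``data.dudl``; raises otherwise.  The quadrature error of the
    trapezoid rule itself is not included — only the statistical error of
    the per-state means, propagated through the trapezoid weights.
    """
    if data.dudl is None:
        raise ValueError("dataset carries no du/dλ samples; TI unavailable")
    lam = data.lambda_schedule
    means = np.array([float(np.mean(d)) for d in data.dudl])
    sems = np.array(
        [float(np.std(d, ddof=1)) / math.sqrt(len(d)) for d in data.dudl]
    )
    # Trapezoid weights over the λ grid.
    w = np.zeros_like(lam)
    dl = np.diff(lam)
    w[:-1] += 0.5 * dl
    w[1:] += 0.5 * dl
    value = float(np.sum(w * means))
    error = float(math.sqrt(np.sum((w * sems) ** 2)))
    return value * data.kT, error * data.kT


def cross_check(data: AlchemicalDataset, flag_sigma: float = 2.0) -> pd.DataFrame:
    """Compare ΔG(0→K−1) across estimators; flag disagreement with MBAR.

    Returns a tidy table (method, value_kJ_mol, error_kJ_mol, flagged); a
    row is flagged when it deviates from the MBAR row by more than
    ``flag_sigma`` combined standard errors.  TI is included only when the
    dataset carries du/dλ samples.
    """
    res = mbar_solve(data)
    mb_v, mb_e = res.delta_g(0, -1)
    rows = [{"method": "mbar", "value_kJ_mol": mb_v, "error_kJ_mol": mb_e}]
    bar_v, bar_e, _ = bar_chain(data)
    rows.append({"method": "bar", "value_kJ_mol": bar_v, "error_kJ_mol": bar_e})
    for direction in ("forward", "reverse"):
        v, e = exp_averaging(data, direction)
        rows.append(
            {"method": f"exp_{direction}", "value_kJ_mol": v, "error_kJ_mol": e}
        )
    if data.dudl is not None:
        v, e = thermodynamic_integration(data)
        rows.append({"method": "ti", "value_kJ_mol": v, "error_kJ_mol": e})
    df = pd.DataFrame(rows)
    comb = np.sqrt(df["error_kJ_mol"] ** 2 + mb_e**2)
    dev = (df["value_kJ_mol"] - mb_v).abs()
    df["flagged"] = (dev > flag_sigma * comb) & (df["method"] != "mbar")
    return df


def discard_equilibration(
    data: AlchemicalDataset, amount: float | int
) -> AlchemicalDataset:
    """Drop leading samples per state.

    ``amount`` in [0, 1) is a leading fraction; an integer >= 1 is an
    absolute per-state sample count (the natural mapping of a fixed
    equilibration time at a fixed sampling interval).  Raises when any state
    would retain no samples.
    """
    if amount == 0:
        return data
    new_u = []
    new_dudl = [] if data.dudl is not None else None
    for k, uk in enumerate(data.u):
        n = uk.shape[1]
        if 0 < amount < 1:
            start = int(math.floor(amount * n))
        elif float(amount).is_integer() and amount >= 1:
            start = int(amount)
        else:
            raise ValueError(
                f"amount must be a fraction in [0,1) or integer count, got {amount}"
            )
        if start >= n:
            raise ValueError(
                f"discard of {start} samples exceeds the {n} available in state {k}"
            )
        new_u.append(uk[:, start:])
        if new_dudl is not None:
            new_dudl.append(data.dudl[k][start:])
    return replace(data, u=new_u, dudl=new_dudl)


def analyse_repeats(
    repeats: Sequence[AlchemicalDataset],
    discard: float | int = 0,
    pooled: bool = False,
) -> FreeEnergyLeg:
    """ΔG over independent repeats: mean ± standard deviation between repeats.

    The equilibration ``discard`` is applied per repeat *before* any
    combination.  With ``pooled=True`` the repeats are concatenated per
    state and analysed as one dataset (error from the MBAR asymptotic
    covariance instead of the between-repeat spread).
    """
    repeats = [discard_equilibration(r, discard) for r in repeats]
    if not repeats:
        raise ValueError("no repeats supplied")
    if pooled:
        first = repeats[0]
        u = [
            np.concatenate([r.u[k] for r in repeats], axis=1)
            for k in range(first.n_states)
        ]
        merged = replace(first, u=u, dudl=None)
        return mbar_leg(merged)
    values = []
    for r in repeats:
        v, _ = mbar_solve(r).delta_g(0, -1)
        values.append(v)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    first = repeats[0]
    return FreeEnergyLeg(
        value=mean,
        error=sd,
        from_state=first.labels[0],
        to_state=first.labels[1],
        method="mbar",
        label=f"mean of {len(repeats)} repeats",
    )
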