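"""Umbrella-sampling PMF estimation by WHAM with Bayesian-bootstrap errors.

Each umbrella window *i* restrains the 1D reaction coordinate ξ with a
harmonic bias w_i(ξ) = ½ k (ξ − ξ₀ᵢ)².  Binning the retained samples of all
windows, the weighted-histogram equations

    p(ξ_b) = Σ_i n_i(b) / Σ_i N_i exp[(f_i − w_i(ξ_b)) / kT]
    f_i    = −kT ln Σ_b p(ξ_b) exp(−w_i(ξ_b) / kT)

are iterated to self-consistency; the unbiased profile is
ΔG(ξ_b) = −kT ln p(ξ_b), shifted so its minimum is zero.  Uncertainty comes
from a Bayesian bootstrap over complete window histograms: each replicate
reweights windows with Dirichlet(1, …, 1) weights and re-solves WHAM, and the
per-bin standard deviation over replicates (after aligning each replicate to
the central profile) is the error band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.special import logsumexp

from rndflux.constants import KT_323
from rndflux.cycles import FreeEnergyLeg

__all__ = [
    "UmbrellaWindow",
    "PmfProfile",
    "wham_solve",
    "bayesian_bootstrap",
    "extract_leg",
    "find_peaks",
]


@dataclass
class UmbrellaWindow:
    """One biased time series of the reaction coordinate.

    ``times`` (ps) and ``xi`` (nm) are parallel arrays; ``discard`` drops
    leading samples before analysis, either as a fraction of the series
    (0 <= discard < 1) or as an absolute time in ps (discard >= 1 is read as
    a time).  A 200 ns equilibration discard is therefore ``discard=200000``.
    """

    center: float
    force_constant: float
    times: np.ndarray
    xi: np.ndarray
    discard: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        if self.times.shape != self.xi.shape or self.times.ndim != 1:
            raise ValueError("times and xi must be 1D arrays of equal length")
        if self.force_constant < 0:
            raise ValueError(
                f"force constant must be >= 0, got {self.force_constant}"
            )  # zero = an unbiased window
        if not np.all(np.isfinite(self.xi)):
            raise ValueError("reaction-coordinate samples must be finite")
        if self.retained().size < 2:
            raise ValueError("fewer than 2 samples retained after discard")

    def retained(self) -> np.ndarray:
        """Samples kept after the equilibration discard."""
        if self.discard == 0:
            return self.xi
        if 0 < self.discard < 1:
            start = int(math.floor(self.discard * self.xi.size))
        else:
            start = int(np.searchsorted(self.times, self.discard, side="left"))
        return self.xi[start:]

    def bias(self, xi: np.ndarray) -> np.ndarray:
        """Harmonic bias energy w(ξ) in kJ/mol."""
        return 0.5 * self.force_constant * (np.asarray(xi) - self.center) ** 2


@dataclass
class PmfProfile:
    """A binned free-energy profile with an error band.

    ``values`` are ΔG(ξ) in kJ/mol with min 0 under the stated ``reference``
    convention; ``errors`` is the per-bin one-sigma band (zeros when no
    bootstrap has been run).  ``diagnostics`` records solver convergence.
    """

    bin_centers: np.ndarray
    values: np.ndarray
    errors: np.ndarray
    kT: float
    reference: str = "minimum of profile set to zero"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if not (self.bin_centers.shape == self.values.shape == self.errors.shape):
            raise ValueError("bin_centers, values and errors must share shape")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.errors < 0):
            raise ValueError("error band must be non-negative")

    def value_at(self, xi: float) -> float:
        """Profile value at the bin nearest to ξ."""
        return float(self.values[int(np.argmin(np.abs(self.bin_centers - xi)))])


def _window_matrices(
    windows: Sequence[UmbrellaWindow],
    bin_edges: np.ndarray,
    kT: float,
):
    """Histogram counts n_ib and reduced bias b_ib = w_i(ξ_b)/kT per window/bin."""
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    counts = np.empty((len(windows), centers.size))
    bias = np.empty_like(counts)
    for i, w in enumerate(windows):
        counts[i], _ = np.histogram(w.retained(), bins=bin_edges)
        bias[i] = w.bias(centers) / kT
    return centers, counts, bias


def _check_connectivity(
    windows: Sequence[UmbrellaWindow], counts: np.ndarray
) -> None:
    """Windows must form one overlap-connected component over the bins."""
    K = len(windows)
    occupied = counts > 0
    parent = list(range(K))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(K):
        for j in range(i + 1, K):
            if np.any(occupied[i] & occupied[j]):
                parent[find(i)] = find(j)
    roots = {find(i) for i in range(K)}
    if len(roots) > 1:
        order = np.argsort([w.center for w in windows])
        comp = [find(i) for i in range(K)]
        for a, b in zip(order[:-1], order[1:]):
            if find(a) != find(b):
                raise ValueError(
                    "umbrella windows are not histogram-connected: gap between "
                    f"window centers {windows[a].center:.3f} and "
                    f"{windows[b].center:.3f} nm"
                )
        raise ValueError(f"umbrella windows split into {len(roots)} components")


def _solve_wham_core(
    counts: np.ndarray,
    bias: np.ndarray,
    tol: float,
    max_iter: int,
    g0: np.ndarray | None = None,
    newton: bool = True,
):
    """Solve the WHAM equations in reduced (kT) units, log space.

    Direct self-consistent iteration, optionally accelerated by Newton
    steps on the equivalent convex objective
    F(g) = Σ_b M_b ln Σ_i N_i exp(g_i − b_ib) − Σ_i N_i g_i
    (M_b: total counts in bin b), whose stationary point is the WHAM fixed
    point.  Direct iteration propagates information one window-overlap per
    sweep and needs O(K²) sweeps on a chain of K windows; Newton converges
    in a handful once in the basin, which is what makes thousands of
    bootstrap re-solves affordable.  counts may be real-valued
    (Dirichlet-weighted histograms).  Returns (log p per occupied bin, g_i,
    iterations, fixed-point residual).
    """
    N_i = counts.sum(axis=1)
    if np.any(N_i <= 0):
        raise ValueError("every window must retain at least one binned sample")
    log_Ni = np.log(N_i)
    M_b = counts.sum(axis=0)  # occupied bins guaranteed upstream
    log_total = np.log(M_b)
    K = counts.shape[0]
    g = np.zeros(K) if g0 is None else g0.copy()

    def step(g):
        # log p_b = log Σ_i n_ib − log Σ_i N_i exp(g_i − b_ib)
        log_den = logsumexp(log_Ni[:, None] + g[:, None] - bias, axis=0)
        log_p = log_total - log_den
        g_new = -logsumexp(log_p[None, :] - bias, axis=1)
        g_new -= g_new[0]  # gauge: first window fixed
        return g_new

    residual = np.inf
    it = 0
    while it < max_iter:
        g_new = step(g)
        residual = float(np.max(np.abs(g_new - g)))
        g = g_new
        it += 1
        if residual < tol:
            break
        if newton and K > 1 and it >= 3:
            a = log_Ni[:, None] + g[:, None] - bias
            logD = logsumexp(a, axis=0)
            P = np.exp(a - logD)  # p_ib, columns sum to 1
            PM = P * M_b[None, :]
            grad = PM.sum(axis=1) - N_i
            H = np.diag(PM.sum(axis=1)) - PM @ P.T
            try:
                delta = np.linalg.solve(H[1:, 1:], grad[1:])
            except np.linalg.LinAlgError:
                continue
            if not np.all(np.isfinite(delta)):
                continue
            scale = min(1.0, 5.0 / max(np.max(np.abs(delta)), 1e-12))
            g_try = g.copy()
            g_try[1:] -= scale * delta
            res_try = float(np.max(np.abs(step(g_try) - g_try)))
            it += 1
            if res_try < residual:
                g = g_try
                residual = res_try
                if residual < tol:
                    g = step(g)
                    break
    log_den = logsumexp(log_Ni[:, None] + g[:, None] - bias, axis=0)
    log_p = log_total - log_den
    return log_p, g, it, residual


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    bins: np.ndarray | None = None,
    kT: float = KT_323,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    bin_width: float = 0.05,
) -> PmfProfile:
    """Solve the WHAM equations over the given bin edges.

    ``bins`` are edges in nm; when omitted, edges of width ``bin_width``
    (default 0.05 nm, the window spacing) spanning all retained samples are
    used.  Empty interior bins are dropped with a warning.  Raises on a
    disconnected window set or non-convergence.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("no umbrella windows supplied")
    if kT <= 0:
        raise ValueError("kT must be positive")
    if bins is None:
        lo = min(w.retained().min() for w in windows)
        hi = max(w.retained().max() for w in windows)
        n = max(int(math.ceil((hi - lo) / bin_width)), 1)
        bins = lo + np.arange(n + 1) * bin_width
    bins = np.asarray(bins, dtype=float)
    if bins.size < 2 or np.any(np.diff(bins) <= 0):
        raise ValueError("bins must be strictly increasing edges (>= 2)")

    centers, counts, bias = _window_matrices(windows, bins, kT)
    occupied = counts.sum(axis=0) > 0
    if not np.all(occupied):
        n_empty = int(np.sum(~occupied))
        warnings.warn(
            f"dropping {n_empty} empty bin(s) from the profile", stacklevel=2
        )
        centers = centers[occupied]
        counts = counts[:, occupied]
        bias = bias[:, occupied]
    if centers.size == 0:
        raise ValueError("no occupied bins: windows do not overlap the bin range")
    _check_connectivity(windows, counts)

    log_p, g, iters, residual = _solve_wham_core(counts, bias, tol, max_iter)
    if residual >= tol:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} kT, tol {tol:.1e})"
        )
    values = -kT * log_p
    values -= values.min()
    return PmfProfile(
        bin_centers=centers,
        values=values,
        errors=np.zeros_like(values),
        kT=kT,
        diagnostics={
            "iterations": iters,
            "residual_kT": residual,
            "n_windows": len(windows),
            "window_free_energies_kT": g.tolist(),
            "bin_edges": bins.tolist(),
        },
    )


def bayesian_bootstrap(
    windows: Sequence[UmbrellaWindow],
    bins: np.ndarray | None = None,
    kT: float = KT_323,
    n_boot: int = 2000,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    bin_width: float = 0.05,
    weight_fn=None,
) -> PmfProfile:
    """Central WHAM profile with a Bayesian-bootstrap error band.

    Per replicate, complete window histograms receive Dirichlet(1,…,1)
    weights (scaled to mean 1) and WHAM is re-solved warm-started from the
    central solution; the band is the per-bin standard deviation over
    replicates after aligning each replicate to the central profile by its
    mean offset.  ``weight_fn(rng, n_windows) -> weights`` overrides the
    Dirichlet draw (testing hook).
    """
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    central = wham_solve(
        windows, bins=bins, kT=kT, tol=tol, max_iter=max_iter, bin_width=bin_width
    )
    edges = np.asarray(central.diagnostics["bin_edges"])
    centers, counts, bias = _window_matrices(list(windows), edges, kT)
    occupied = counts.sum(axis=0) > 0
    centers = centers[occupied]
    counts = counts[:, occupied]
    bias = bias[:, occupied]
    g0 = np.asarray(central.diagnostics["window_free_energies_kT"])

    K = counts.shape[0]
    rng = np.random.default_rng([seed, 0])
    replicates = np.empty((n_boot, centers.size))
    for r in range(n_boot):
        if weight_fn is not None:
            w = np.asarray(weight_fn(rng, K), dtype=float)
        else:
            w = rng.dirichlet(np.ones(K)) * K
        if w.shape != (K,) or np.any(w < 0):
            raise ValueError("replicate weights must be K non-negative numbers")
        wc = counts * w[:, None]
        rep_occ = wc.sum(axis=0) > 0
        log_p, _, it, res = _solve_wham_core(
            wc[:, rep_occ], bias[:, rep_occ], tol, max_iter, g0=g0
        )
        if res >= tol:
            raise RuntimeError(f"bootstrap replicate {r} did not converge")
        prof = np.full(centers.size, np.nan)
        prof[rep_occ] = -kT * log_p
        replicates[r] = prof
    # Align each replicate to the central profile by its mean offset over
    # the bins both define, then take the per-bin spread.
    valid = np.isfinite(replicates)
    for r in range(n_boot):
        m = valid[r]
        replicates[r, m] -= np.mean(replicates[r, m] - central.values[m])
    band = np.zeros(centers.size)
    for b in range(centers.size):
        col = replicates[valid[:, b], b]
        band[b] = float(np.std(col, ddof=0)) if col.size >= 2 else 0.0
    return PmfProfile(
        bin_centers=centers,
        values=central.values,
        errors=band,
        kT=kT,
        reference=central.reference,
        diagnostics={**central.diagnostics, "n_boot": n_boot, "bootstrap_seed": seed},
    )


def extract_leg(
    profile: PmfProfile,
    bound_region: tuple[float, float],
    reference_region: tuple[float, float],
    label: str = "",
    bound_label: str = "bound",
    reference_label: str = "reference",
) -> FreeEnergyLeg:
    """Free-energy leg from a profile: reference-region mean minus bound-site minimum.

    The value is the mean ΔG over ``reference_region`` minus the minimum ΔG
    within ``bound_region`` (both ξ intervals in nm), i.e. the cost of moving
    from the bound well to the reference ("bulk") environment.  The error
    combines the band at the bound minimum and the mean band over the
    reference region in quadrature.
    """
    for name, (lo, hi) in (("bound", bound_region), ("reference", reference_region)):
        if lo > hi:
            raise ValueError(f"{name} region has lo > hi")
    xb = profile.bin_centers
    bound_mask = (xb >= bound_region[0]) & (xb <= bound_region[1])
    ref_mask = (xb >= reference_region[0]) & (xb <= reference_region[1])
    if not bound_mask.any():
        raise ValueError("bound region contains no profile bins")
    if not ref_mask.any():
        raise ValueError("reference region contains no profile bins")
    bound_idx = np.flatnonzero(bound_mask)[np.argmin(profile.values[bound_mask])]
    value = float(np.mean(profile.values[ref_mask]) - profile.values[bound_idx])
    err = math.hypot(
        float(profile.errors[bound_idx]), float(np.mean(profile.errors[ref_mask]))
    )
    return FreeEnergyLeg(
        value=value,
        error=err,
        from_state=bound_label,
        to_state=reference_label,
        method="wham",
        label=label,
    )


def find_peaks(
    profile: PmfProfile, min_prominence: float = 1.0
) -> list[tuple[float, float]]:
    """Local maxima of the profile with prominence >= ``min_prominence`` kJ/mol.

    Returns (ξ, height) pairs sorted by ξ, heights relative to the profile
    minimum.  Plateaus (equal-height adjacent bins) report their leftmost ξ.
    """
    if profile.bin_centers.size < 3:
        raise ValueError("profile needs at least 3 bins for peak finding")
    y = profile.values - profile.values.min()
    idx, props = _scipy_find_peaks(y, prominence=min_prominence, plateau_size=1)
    out = []
    for i, left in zip(idx, props["left_edges"]):
        j = int(left)  # leftmost bin of a plateau peak
        out.append((float(profile.bin_centers[j]), float(y[j])))
    out.sort(key=lambda t: t[0])
    return out
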