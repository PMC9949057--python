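"""Synthetic data with exact analytic ground truth.

Three generators emulate the raw inputs of the free-energy analysis chain so
that every downstream estimator can be validated without running molecular
dynamics:

* :func:`sample_umbrella_windows` draws biased reaction-coordinate series
  from a known analytic PMF under harmonic umbrella biases (Metropolis
  random walk, exact target density),
* :func:`sample_alchemical` draws per-λ-state samples from 1D harmonic
  oscillators whose free-energy differences are known in closed form,
  ΔG_ij = (kT/2)·ln(k_j/k_i),
* :func:`script_trajectory` builds coordinate ensembles that reproduce a
  per-frame script exactly, for geometry operators with planted answers.

Default bias parameters follow the umbrella protocol the package targets:
0.05 nm window spacing and a 1000 kJ mol⁻¹ nm⁻² umbrella force constant.
All generators are bit-reproducible under a fixed seed; per-window and
per-state streams derive from the global seed by fixed offsets
(``default_rng([seed, stream])``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from rndflux.alchemical import AlchemicalDataset
from rndflux.constants import KT_323
from rndflux.pmf import UmbrellaWindow
from rndflux.trajectory import TrajectoryEnsemble

__all__ = [
    "AnalyticPmf",
    "BiasSchedule",
    "sample_umbrella_windows",
    "sample_alchemical",
    "script_trajectory",
]

_PMF_KINDS = ("flat", "harmonic_well", "double_well", "gaussian_wells")


@dataclass(frozen=True)
class AnalyticPmf:
    """A closed-form 1D potential U(ξ) on a closed domain (nm, kJ/mol).

    Kinds
    -----
    flat            : U = c (``parameters = (c,)``)
    harmonic_well   : U = ½ k (ξ − ξ₀)²   (``parameters = (k, ξ₀)``)
    double_well     : U = h·[((ξ − c)/w)² − 1]², wells at c ± w, barrier h
                      at ξ = c (``parameters = (c, w, h)``)
    gaussian_wells  : U = −Σ d·exp(−(ξ − p)²/(2σ²)) over (p, d, σ) triples;
                      a positive depth d digs a well, a negative one plants
                      a barrier.

    Evaluation outside the domain returns +inf (hard walls), which is what
    confines Metropolis sampling to the domain.
    """

    kind: str
    parameters: tuple
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in _PMF_KINDS:
            raise ValueError(f"unknown PMF kind {self.kind!r}; one of {_PMF_KINDS}")
        lo, hi = self.domain
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError(f"domain must be a finite interval, got {self.domain}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def flat(cls, domain: tuple[float, float], value: float = 0.0) -> "AnalyticPmf":
        return cls("flat", (value,), domain)

    @classmethod
    def harmonic_well(
        cls, spring_constant: float, center: float, domain: tuple[float, float]
    ) -> "AnalyticPmf":
        if spring_constant <= 0:
            raise ValueError("spring constant must be positive")
        return cls("harmonic_well", (spring_constant, center), domain)

    @classmethod
    def double_well(
        cls,
        well_a: float,
        well_b: float,
        barrier: float,
        domain: tuple[float, float] | None = None,
    ) -> "AnalyticPmf":
        """Quartic double well with minima at ``well_a``/``well_b`` (value 0)
        and a barrier of height ``barrier`` at their midpoint."""
        if barrier <= 0:
            raise ValueError("barrier height must be positive")
        if well_a >= well_b:
            raise ValueError("well_a must be < well_b")
        c = 0.5 * (well_a + well_b)
        w = 0.5 * (well_b - well_a)
        if domain is None:
            domain = (well_a - 0.5 * w, well_b + 0.5 * w)
        return cls("double_well", (c, w, barrier), domain)

    @classmethod
    def gaussian_wells(
        cls,
        wells: Sequence[tuple[float, float, float]],
        domain: tuple[float, float],
    ) -> "AnalyticPmf":
        wells = tuple((float(p), float(d), float(s)) for p, d, s in wells)
        if any(s <= 0 for _, _, s in wells):
            raise ValueError("gaussian widths must be positive")
        return cls("gaussian_wells", wells, domain)

    # -- evaluation --------------------------------------------------------
    def __call__(self, xi) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        if self.kind == "flat":
            u = np.full_like(xi, self.parameters[0])
        elif self.kind == "harmonic_well":
            k, x0 = self.parameters
            u = 0.5 * k * (xi - x0) ** 2
        elif self.kind == "double_well":
            c, w, h = self.parameters
            u = h * (((xi - c) / w) ** 2 - 1.0) ** 2
        else:  # gaussian_wells
            u = np.zeros_like(xi)
            for p, d, s in self.parameters:
                u = u - d * np.exp(-((xi - p) ** 2) / (2.0 * s**2))
        lo, hi = self.domain
        return np.where((xi < lo) | (xi > hi), np.inf, u)


@dataclass(frozen=True)
class BiasSchedule:
    """Umbrella centers (nm, strictly increasing) and force constant."""

    centers: tuple
    force_constant: float = 1000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", tuple(float(c) for c in self.centers))
        if not self.centers:
            raise ValueError("bias schedule must contain at least one center")
        if any(b <= a for a, b in zip(self.centers, self.centers[1:])):
            raise ValueError("umbrella centers must be strictly increasing")
        if self.force_constant <= 0:
            raise ValueError("umbrella force constant must be positive")

    @classmethod
    def spanning(
        cls,
        lo: float,
        hi: float,
        spacing: float = 0.05,
        force_constant: float = 1000.0,
    ) -> "BiasSchedule":
        """Evenly spaced centers covering [lo, hi] at the given spacing (nm)."""
        n = int(round((hi - lo) / spacing))
        centers = lo + spacing * np.arange(n + 1)
        return cls(tuple(centers), force_constant)


def _tune_step(rng, beta_energy, x0: float, step0: float) -> float:
    """Scalar pilot Metropolis run targeting 30-50% acceptance."""
    step = step0
    x = x0
    e = beta_energy(x)
    for _ in range(8):
        accepted = 0
        n_pilot = 60
        prop = rng.normal(0.0, step, n_pilot)
        logu = np.log(rng.uniform(size=n_pilot))
        for t in range(n_pilot):
            xn = x + prop[t]
            en = beta_energy(xn)
            if logu[t] < e - en:
                x, e, accepted = xn, en, accepted + 1
        acc = accepted / n_pilot
        if acc < 0.30:
            step *= 0.6
        elif acc > 0.50:
            step *= 1.5
        else:
            break
    return step


def sample_umbrella_windows(
    pmf: AnalyticPmf,
    schedule: BiasSchedule,
    n_samples: int = 10_000,
    kT: float = KT_323,
    seed: int = 0,
    thin: int = 1,
    dt: float = 1.0,
) -> list[UmbrellaWindow]:
    """Metropolis samples from exp(−[U(ξ) + ½k(ξ−ξ₀)²]/kT) per window.

    A random-walk Metropolis chain per window (step size pilot-tuned to
    30–50% acceptance, 10% burn-in discarded, optional thinning) returns
    exactly ``n_samples`` per window, timestamped every ``dt`` ps.  The
    chains are serially correlated over a few steps; pass ``thin`` > 1 when
    near-independent draws are needed.
    """
    if n_samples < 100:
        raise ValueError(f"n_samples must be >= 100, got {n_samples}")
    if kT <= 0:
        raise ValueError("kT must be positive")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    lo, hi = pmf.domain
    grid = np.linspace(lo, hi, 512)
    if not np.all(np.isfinite(pmf(grid))):
        raise ValueError("PMF is not finite on its domain")

    centers = np.asarray(schedule.centers)
    k = schedule.force_constant
    K = centers.size

    def beta_energy_vec(x: np.ndarray) -> np.ndarray:
        return (pmf(x) + 0.5 * k * (x - centers) ** 2) / kT

    # Per-window streams by fixed offsets from the global seed.
    rngs = [np.random.default_rng([seed, i]) for i in range(K)]
    sigma0 = math.sqrt(kT / k)
    steps = np.empty(K)
    starts = np.clip(centers, lo, hi)
    for i in range(K):
        be = lambda x, c=centers[i]: float((pmf(x) + 0.5 * k * (x - c) ** 2) / kT)
        steps[i] = _tune_step(rngs[i], be, float(starts[i]), 2.4 * sigma0)

    n_burn = max(int(math.ceil(0.1 * n_samples)), 100)
    n_steps = n_burn + n_samples * thin
    # One proposal/uniform stream per window, stacked for a vectorised chain.
    prop = np.empty((n_steps, K))
    logu = np.empty((n_steps, K))
    for i in range(K):
        prop[:, i] = rngs[i].normal(0.0, steps[i], n_steps)
        logu[:, i] = np.log(rngs[i].uniform(size=n_steps))

    x = starts.copy()
    e = beta_energy_vec(x)
    out = np.empty((n_samples, K))
    kept = 0
    for t in range(n_steps):
        xn = x + prop[t]
        en = beta_energy_vec(xn)
        acc = logu[t] < e - en
        x = np.where(acc, xn, x)
        e = np.where(acc, en, e)
        if t >= n_burn and (t - n_burn) % thin == 0:
            out[kept] = x
            kept += 1
    assert kept == n_samples
    times = dt * np.arange(n_samples)
    return [
        UmbrellaWindow(
            center=float(centers[i]),
            force_constant=k,
            times=times.copy(),
            xi=out[:, i].copy(),
        )
        for i in range(K)
    ]


def sample_alchemical(
    spring_constants: Sequence[float],
    n_samples: int = 1000,
    kT: float = KT_323,
    seed: int = 0,
    lambda_schedule: Sequence[float] | None = None,
    centers: Sequence[float] | None = None,
) -> AlchemicalDataset:
    """Samples from a family of 1D harmonic oscillators with exact ΔG.

    State j has U_j(x) = ½ k_j (x − c_j)²; its configurational partition
    function is ∝ k_j^(−1/2), so the exact free energy relative to state 0 is
    f_j = (kT/2)·ln(k_j/k_0), independent of the centers.  Samples are iid
    Gaussians per state; the reduced-energy matrix u[k][j][n] evaluates every
    sample of state k in every state j.
    """
    ks = np.asarray(list(spring_constants), dtype=float)
    if ks.size < 2:
        raise ValueError("at least 2 states are required")
    if np.any(ks <= 0):
        raise ValueError("spring constants must be positive")
    if centers is None:
        cs = np.zeros(ks.size)
    else:
        cs = np.asarray(list(centers), dtype=float)
        if cs.size != ks.size:
            raise ValueError("centers must match the number of states")
    if lambda_schedule is None:
        lam = np.linspace(0.0, 1.0, ks.size)
    else:
        lam = np.asarray(list(lambda_schedule), dtype=float)
        if lam.size != ks.size:
            raise ValueError(
                f"lambda schedule has {lam.size} values for {ks.size} states"
            )
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if kT <= 0:
        raise ValueError("kT must be positive")

    u_kjn = []
    dudl = []
    # dk/dλ along the (linear-in-λ) interpolation between successive ks is
    # not defined for arbitrary schedules; we attach du/dλ for the linear
    # path k(λ) interpolating the given states, used by the TI cross-check.
    k_of_lam = lambda l: np.interp(l, lam, ks)
    dk_dlam = np.gradient(ks, lam) if ks.size > 2 else np.array(
        [(ks[1] - ks[0]) / (lam[1] - lam[0])] * 2
    )
    for state_k in range(ks.size):
        rng = np.random.default_rng([seed, state_k])
        x = rng.normal(cs[state_k], math.sqrt(kT / ks[state_k]), n_samples)
        u = 0.5 * ks[None, :].T * (x[None, :] - cs[:, None]) ** 2 / kT
        u_kjn.append(u)
        dudl.append(0.5 * dk_dlam[state_k] * (x - cs[state_k]) ** 2 / kT)
    exact_f = 0.5 * kT * np.log(ks / ks[0])
    return AlchemicalDataset(
        u=u_kjn,
        lambda_schedule=lam,
        kT=kT,
        ground_truth=exact_f,
        dudl=dudl,
    )


def script_trajectory(
    script: Sequence[Sequence[tuple]],
    box=None,
    times: Sequence[float] | None = None,
    jitter: float = 0.0,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Build a coordinate ensemble that reproduces a per-frame script.

    ``script`` is a list of frames; each frame is a list of records
    ``(name, resname, resid, chain, (x, y, z))`` with coordinates in nm.
    Labelling must be identical (same records, same order) in every frame.
    Optional Gaussian ``jitter`` (nm std) is added with a seeded stream.
    """
    if not script:
        raise ValueError("script must contain at least one frame")
    labels0 = [tuple(rec[:4]) for rec in script[0]]
    coords = np.empty((len(script), len(labels0), 3))
    for f, frame in enumerate(script):
        labels = [tuple(rec[:4]) for rec in frame]
        if labels != labels0:
            raise ValueError(f"frame {f} labelling differs from frame 0")
        coords[f] = [rec[4] for rec in frame]
    if jitter > 0:
        rng = np.random.default_rng([seed, 0])
        coords = coords + rng.normal(0.0, jitter, coords.shape)
    if times is None:
        times = np.arange(len(script), dtype=float)
    names, resnames, resids, chains = (list(t) for t in zip(*labels0))
    return TrajectoryEnsemble(
        names=np.array(names),
        resnames=np.array(resnames),
        resids=np.array(resids, dtype=int),
        chains=np.array(chains),
        coords=coords,
        times=np.asarray(times, dtype=float),
        box=None if box is None else np.asarray(box, dtype=float),
    )
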