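"""Monte Carlo inversion of b(omega)-tau_R-tau_E signals.

The inverse problem — recovering a nonparametric distribution of
frequency-dispersive axisymmetric diffusion tensors with R1/R2 relaxation
from a few hundred encoded signals — is ill-posed, so it is solved by random
search: candidate components are pseudo-randomly sampled within broad limits
(proliferation), weighted by non-negative least squares against the data,
mutated within a shrinking range (mutation/extinction), and the surviving
set is truncated to a small number of output components.  Repeating the
search on bootstrap resamples of the measurements yields an ensemble of
independent per-voxel solutions whose pooled components form the
nonparametric distribution.

Sampling laws (the search is free to choose these): diffusivities, corner
frequencies and relaxation rates are drawn log-uniformly within their limits
(the bounds span decades); orientations are drawn area-uniformly on the
hemisphere.  The high-frequency diffusivity is forced to dominate the
long-time diffusivities (D_par, D_perp <= D_0) by taking D_0 as the maximum
of the three draws, since the Lorentzian transition disperses upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .forward import IDX, design_matrix

_LOG_FIELDS = [IDX[k] for k in
               ("D_par", "D_perp", "D0", "Gamma_par", "Gamma_perp", "R1", "R2")]


@dataclass(frozen=True)
class InversionLimits:
    """Hard bounds of the primary analysis space.

    Diffusivity bounds apply to D_0, D_par and D_perp alike (m^2/s);
    Gamma bounds to both corner frequencies (rad/s); R1, R2 in 1/s.
    """

    d_min: float = 5e-12
    d_max: float = 5e-9
    gamma_min: float = 0.1
    gamma_max: float = 1e5
    r1_min: float = 0.1
    r1_max: float = 4.0
    r2_min: float = 1.0
    r2_max: float = 150.0

    def __post_init__(self):
        for lo, hi, name in [(self.d_min, self.d_max, "d"),
                             (self.gamma_min, self.gamma_max, "gamma"),
                             (self.r1_min, self.r1_max, "r1"),
                             (self.r2_min, self.r2_max, "r2")]:
            if not 0 < lo <= hi:
                raise ValueError(f"need 0 < {name}_min <= {name}_max")

    @classmethod
    def ex_vivo_rat(cls) -> "InversionLimits":
        return cls()

    @classmethod
    def in_vivo_rat(cls) -> "InversionLimits":
        return cls(r2_min=4.0, r2_max=100.0)

    @classmethod
    def in_vivo_human(cls) -> "InversionLimits":
        return cls(gamma_max=1e4, r1_max=20.0, r2_min=1.0, r2_max=30.0)

    def lower(self) -> np.ndarray:
        """Per-column lower bounds in component-matrix order (angles 0)."""
        lo = np.zeros(9)
        lo[[IDX["D_par"], IDX["D_perp"], IDX["D0"]]] = self.d_min
        lo[[IDX["Gamma_par"], IDX["Gamma_perp"]]] = self.gamma_min
        lo[IDX["R1"]] = self.r1_min
        lo[IDX["R2"]] = self.r2_min
        return lo

    def upper(self) -> np.ndarray:
        hi = np.full(9, np.inf)
        hi[[IDX["D_par"], IDX["D_perp"], IDX["D0"]]] = self.d_max
        hi[[IDX["Gamma_par"], IDX["Gamma_perp"]]] = self.gamma_max
        hi[IDX["R1"]] = self.r1_max
        hi[IDX["R2"]] = self.r2_max
        return hi

    def contains(self, params: np.ndarray) -> np.ndarray:
        params = np.atleast_2d(params)
        lo, hi = self.lower(), self.upper()
        cols = _LOG_FIELDS
        return np.all((params[:, cols] >= lo[cols] * (1 - 1e-12))
                      & (params[:, cols] <= hi[cols] * (1 + 1e-12)), axis=1)


@dataclass(frozen=True)
class InversionConfig:
    """Search schedule of the Monte Carlo inversion."""

    n_proliferation: int = 20
    n_mutation: int = 20
    n_in: int = 200
    n_out: int = 10
    n_bootstrap: int = 100
    mutation_scale: float = 0.5     # initial log-mutation half-range
    mutation_decay: float = 0.8     # per-step geometric shrink
    extinction_tol: float = 1e-6    # weight floor relative to max weight
    seed: int = 0

    def __post_init__(self):
        if min(self.n_proliferation, self.n_mutation, self.n_in, self.n_out,
               self.n_bootstrap) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 < self.mutation_decay < 1:
            raise ValueError("mutation_decay must be in (0, 1)")


def sample_components(limits: InversionLimits, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw n candidate components within the limits (weights unset)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = np.empty((n, 9))
    for col, lo, hi in [
            (IDX["D_par"], limits.d_min, limits.d_max),
            (IDX["D_perp"], limits.d_min, limits.d_max),
            (IDX["D0"], limits.d_min, limits.d_max),
            (IDX["Gamma_par"], limits.gamma_min, limits.gamma_max),
            (IDX["Gamma_perp"], limits.gamma_min, limits.gamma_max),
            (IDX["R1"], limits.r1_min, limits.r1_max),
            (IDX["R2"], limits.r2_min, limits.r2_max)]:
        p[:, col] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    # area-uniform orientations on the upper hemisphere
    p[:, IDX["theta"]] = np.arccos(rng.uniform(0.0, 1.0, size=n))
    p[:, IDX["phi"]] = rng.uniform(0.0, 2.0 * np.pi, size=n)
    _enforce_d0(p)
    return p


def _enforce_d0(p: np.ndarray) -> None:
    """In place: D_0 := max(D_0, D_par, D_perp) so dispersion rises to D_0."""
    cols = [IDX["D_par"], IDX["D_perp"], IDX["D0"]]
    p[:, IDX["D0"]] = p[:, cols].max(axis=1)


def mutate_components(params: np.ndarray, scale: float,
                      limits: InversionLimits,
                      rng: np.random.Generator) -> np.ndarray:
    """Multiplicative perturbation of log-sampled parameters and a small
    random rotation of the symmetry axis, both of magnitude ``scale``."""
    p = np.array(params, dtype=float, copy=True)
    n = p.shape[0]
    factors = np.exp(rng.uniform(-1.0, 1.0, size=(n, len(_LOG_FIELDS))) * scale)
    p[:, _LOG_FIELDS] *= factors
    lo, hi = limits.lower(), limits.upper()
    p[:, _LOG_FIELDS] = np.clip(p[:, _LOG_FIELDS], lo[_LOG_FIELDS],
                                hi[_LOG_FIELDS])
    _enforce_d0(p)
    # axis perturbation: jitter the unit vector, renormalize, fold to z >= 0
    st = np.sin(p[:, IDX["theta"]])
    u = np.stack([st * np.cos(p[:, IDX["phi"]]),
                  st * np.sin(p[:, IDX["phi"]]),
                  np.cos(p[:, IDX["theta"]])], axis=1)
    u = u + rng.normal(0.0, scale, size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    u[u[:, 2] < 0] *= -1.0
    p[:, IDX["theta"]] = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    p[:, IDX["phi"]] = np.mod(np.arctan2(u[:, 1], u[:, 0]), 2.0 * np.pi)
    return p


def fit_weights(params: np.ndarray, protocol, data: np.ndarray
                ) -> tuple[np.ndarray, float]:
    """Non-negative least-squares weights for a candidate component set.

    Returns (weights, residual 2-norm).
    """
    data = np.asarray(data, dtype=float)
    if np.any(~np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    if len(data) != len(protocol):
        raise ValueError(f"data length {len(data)} != protocol rows "
                         f"{len(protocol)}")
    K = design_matrix(params, protocol)
    w, rnorm = nnls(K, data)
    return w, float(rnorm)


def invert_voxel(protocol, data, limits: InversionLimits,
                 cfg: InversionConfig, rng: np.random.Generator,
                 history: list | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """One Monte Carlo search: returns (params (m, 9), weights (m,)),
    m <= cfg.n_out, all weights > 0.

    Survivors are always retained in the next candidate set, so the fitted
    residual is non-increasing across proliferation and mutation steps; pass
    a ``history`` list to record the per-step residuals.
    """
    data = np.asarray(data, dtype=float)
    if len(protocol) < 2:
        raise ValueError("need at least 2 rows to invert")
    if np.any(~np.isfinite(data)):
        raise ValueError("data contains non-finite values")

    survivors = np.empty((0, 9))
    pool, w_last = survivors, np.empty(0)
    for _ in range(cfg.n_proliferation):
        fresh = sample_components(limits, cfg.n_in, rng)
        candidates = np.vstack([survivors, fresh])
        w, rnorm = fit_weights(candidates, protocol, data)
        survivors = _survivors(candidates, w, cfg.extinction_tol)
        pool, w_last = candidates[w > 0], w[w > 0]
        if history is not None:
            history.append(rnorm)

    scale = cfg.mutation_scale
    for _ in range(cfg.n_mutation):
        if survivors.shape[0] == 0:
            break
        n_mut = max(cfg.n_in // max(survivors.shape[0], 1), 1)
        mutated = np.vstack([mutate_components(survivors, scale, limits, rng)
                             for _ in range(n_mut)])
        candidates = np.vstack([survivors, mutated])
        w, rnorm = fit_weights(candidates, protocol, data)
        survivors = _survivors(candidates, w, cfg.extinction_tol)
        pool, w_last = candidates[w > 0], w[w > 0]
        scale *= cfg.mutation_decay
        if history is not None:
            history.append(rnorm)

    if pool.shape[0] == 0:               # data fit by the zero vector
        return np.empty((0, 9)), np.empty(0)

    # a shallow positive support cannot fill a solution; a few extra
    # proliferation fits deepen it at negligible cost
    for _ in range(5):
        if pool.shape[0] >= cfg.n_out:
            break
        candidates = np.vstack([pool, sample_components(limits, cfg.n_in,
                                                        rng)])
        w, _ = fit_weights(candidates, protocol, data)
        if (w > 0).sum() > pool.shape[0]:
            pool, w_last = candidates[w > 0], w[w > 0]

    # Truncate to the n_out highest-weight members of the final positive
    # support and refit.  A plain subset refit generically parks some
    # weights at the non-negativity boundary, which would leave solutions
    # with fewer than n_out components; refill the zeroed slots from the
    # weight-ranked remainder and refit until n_out components carry
    # positive weight (or the pool is exhausted), so full solutions carry
    # NNLS-optimal subset weights.
    target = min(cfg.n_out, pool.shape[0])
    order = np.argsort(w_last)[::-1]
    selected = list(order[:cfg.n_out])
    remaining = list(order[cfg.n_out:])
    while True:
        w, _ = fit_weights(pool[selected], protocol, data)
        positive = w > 0
        if positive.all() and len(selected) >= target:
            return pool[selected], w
        if not remaining:
            break
        selected = [s for s, p in zip(selected, positive) if p]
        while remaining and len(selected) < cfg.n_out:
            selected.append(remaining.pop(0))
    if positive.sum() >= target:
        return pool[selected][positive], w[positive]
    # pool exhausted without a full positive refit: fall back to the n_out
    # strongest members of the full-pool solution (weights all positive)
    keep = order[:cfg.n_out]
    return pool[keep], w_last[keep]


def _survivors(candidates: np.ndarray, w: np.ndarray, tol: float) -> np.ndarray:
    if w.size == 0 or w.max() <= 0:
        return np.empty((0, 9))
    return candidates[w > tol * w.max()]


@dataclass
class VoxelEnsemble:
    """Bootstrap ensemble of Monte Carlo solutions for one voxel."""

    solutions: list  # list of (params (m,9), weights (m,)) tuples
    S0: float        # mean over solutions of per-solution total weight
    voxel_index: tuple = (0, 0, 0)

    @property
    def n_components(self) -> int:
        return sum(p.shape[0] for p, _ in self.solutions)

    def pooled(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Concatenate all solutions: (params, weights, solution_index)."""
        params = np.vstack([p for p, _ in self.solutions]) \
            if self.solutions else np.empty((0, 9))
        weights = np.concatenate([w for _, w in self.solutions]) \
            if self.solutions else np.empty(0)
        sol_idx = np.concatenate(
            [np.full(p.shape[0], s, dtype=int)
             for s, (p, _) in enumerate(self.solutions)]) \
            if self.solutions else np.empty(0, dtype=int)
        return params, weights, sol_idx


def bootstrap_ensemble(protocol, data, limits: InversionLimits,
                       cfg: InversionConfig,
                       rng: np.random.Generator | None = None,
                       voxel_index: tuple = (0, 0, 0)) -> VoxelEnsemble:
    """Repeat the Monte Carlo search on with-replacement resamples of the
    (row, datum) pairs; the pooled solutions form the voxel's distribution."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    data = np.asarray(data, dtype=float)
    n = len(protocol)
    solutions = []
    for _ in range(cfg.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        params, weights = invert_voxel(protocol[idx], data[idx], limits, cfg,
                                       rng)
        solutions.append((params, weights))
    totals = [w.sum() for _, w in solutions]
    return VoxelEnsemble(solutions=solutions, S0=float(np.mean(totals)),
                         voxel_index=voxel_index)


def voxel_rng(seed: int, index: tuple) -> np.random.Generator:
    """Deterministic per-voxel generator, independent of scheduling order."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, index))))


def invert_image(image4d: np.ndarray, protocol, limits: InversionLimits,
                 cfg: InversionConfig, mask: np.ndarray | None = None,
                 n_workers: int = 1) -> dict:
    """Invert every masked voxel of a 4D volume.

    Returns ``{(i, j, k): VoxelEnsemble}``.  Per-voxel seeds derive from
    (cfg.seed, i, j, k), so results do not depend on n_workers.
    """
    image4d = np.asarray(image4d, dtype=float)
    if image4d.ndim != 4:
        raise ValueError("image must be 4D")
    if image4d.shape[3] != len(protocol):
        raise ValueError(f"4th dimension {image4d.shape[3]} != protocol rows "
                         f"{len(protocol)}")
    if mask is None:
        mask = np.ones(image4d.shape[:3], dtype=bool)
    indices = [tuple(ix) for ix in np.argwhere(mask)]

    def one(ix):
        return ix, bootstrap_ensemble(protocol, image4d[ix], limits, cfg,
                                      rng=voxel_rng(cfg.seed, ix),
                                      voxel_index=ix)

    if n_workers == 1:
        results = [one(ix) for ix in indices]
    else:
        results = Parallel(n_jobs=n_workers)(delayed(one)(ix)
                                             for ix in indices)
    return dict(results)


class MonteCarloInverter(BaseEstimator):
    """Estimator interface to the Monte Carlo inversion.

    ``fit(X)`` treats each row of ``X`` (shape ``(n_voxels, n_measurements)``)
    as one voxel's signal vector under ``protocol`` and stores the bootstrap
    ensembles in ``ensembles_``.

    Parameters mirror :class:`InversionConfig`; ``limits`` defaults to the
    ex vivo preset.
    """

    def __init__(self, protocol=None, limits=None, n_proliferation=20,
                 n_mutation=20, n_in=200, n_out=10, n_bootstrap=100,
                 mutation_scale=0.5, mutation_decay=0.8, extinction_tol=1e-6,
                 random_state=0, n_workers=1):
        self.protocol = protocol
        self.limits = limits
        self.n_proliferation = n_proliferation
        self.n_mutation = n_mutation
        self.n_in = n_in
        self.n_out = n_out
        self.n_bootstrap = n_bootstrap
        self.mutation_scale = mutation_scale
        self.mutation_decay = mutation_decay
        self.extinction_tol = extinction_tol
        self.random_state = random_state
        self.n_workers = n_workers

    def _config(self) -> InversionConfig:
        return InversionConfig(
            n_proliferation=self.n_proliferation, n_mutation=self.n_mutation,
            n_in=self.n_in, n_out=self.n_out, n_bootstrap=self.n_bootstrap,
            mutation_scale=self.mutation_scale,
            mutation_decay=self.mutation_decay,
            extinction_tol=self.extinction_tol, seed=self.random_state)

    def fit(self, X, y=None):
        if self.protocol is None:
            raise ValueError("protocol must be set before fitting")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.protocol):
            raise ValueError(f"X has {X.shape[1]} measurements, protocol has "
                             f"{len(self.protocol)} rows")
        limits = self.limits if self.limits is not None else InversionLimits()
        image = X[:, None, None, :]      # voxels along the first axis
        ens = invert_image(image, self.protocol, limits, self._config(),
                           n_workers=self.n_workers)
        self.ensembles_ = [ens[(v, 0, 0)] for v in range(X.shape[0])]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X=None):
        """Return the fitted per-voxel ensembles (X is ignored)."""
        if not hasattr(self, "ensembles_"):
            raise AttributeError("MonteCarloInverter is not fitted yet")
        return self.ensembles_
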