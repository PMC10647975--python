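"""Intravoxel incoherent motion (IVIM) diffusion modelling.

The IVIM model describes diffusion-weighted signal decay in perfused tissue as
a biexponential in the b-value,

    S(b) / S0 = f_p * exp(-b * D_fast) + (1 - f_p) * exp(-b * D_slow),

where ``D_slow`` is the true (molecular) water diffusion coefficient,
``D_fast`` the pseudo-diffusion coefficient driven by capillary blood flow,
and ``f_p`` the perfusion (pseudo-diffusion) signal fraction.  Diffusivities
are carried in SI mm^2/s throughout this module and converted to the
conventional reporting units (x10^-3 mm^2/s, and % for f_p) only at the
summary layer.

Two voxelwise fitters are provided, both sklearn-style estimators operating
on an (n_voxels, n_b) signal matrix:

* :class:`IVIMLeastSquares` — the segmented constrained least-squares
  baseline (log-linear high-b fit, intercept-gap perfusion fraction,
  one-parameter fast-component fit).
* :class:`IVIMBayesian` — independent per-voxel Metropolis-within-Gibbs
  sampling of the biexponential under a Gaussian likelihood, the approach
  known to suppress the notorious noise amplification of the least-squares
  pseudo-diffusion map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator

__all__ = [
    "BValueScheme",
    "DWISeries",
    "IVIMParams",
    "IVIMMaps",
    "PosteriorSummary",
    "McmcConfig",
    "IVIM_BOUNDS",
    "ivim_signal",
    "median_filter_slicewise",
    "resample_inplane",
    "IVIMLeastSquares",
    "IVIMBayesian",
    "fit_ivim_lsq",
    "fit_ivim_bayes",
    "global_liver_summary",
    "si_to_report",
    "report_to_si",
]

# Parameter bounds used by both fitters (SI mm^2/s; f_p as fraction).
IVIM_BOUNDS = {
    "d_slow": (0.1e-3, 3.0e-3),
    "d_fast": (3.0e-3, 300.0e-3),
    "f_p": (0.0, 0.6),
}

#: Clinical 13-b acquisition scheme (s/mm^2) with per-b excitation counts.
TABLE_B_VALUES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0,
                  100.0, 200.0, 400.0, 800.0)
TABLE_AVERAGES = (1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 3)


@dataclass(frozen=True)
class BValueScheme:
    """Ordered diffusion-weighting scheme with per-b excitation counts."""

    b_values: tuple = TABLE_B_VALUES
    averages: tuple = TABLE_AVERAGES

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float)
        a = np.asarray(self.averages, dtype=int)
        if b.size != a.size:
            raise ValueError(
                f"b_values ({b.size}) and averages ({a.size}) lengths differ")
        if b[0] != 0.0:
            raise ValueError("first b-value must be 0")
        if not np.all(np.diff(b) > 0):
            raise ValueError("b_values must be strictly increasing")
        if np.any(a < 1):
            raise ValueError("averages must be >= 1")
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))
        object.__setattr__(self, "averages", tuple(int(x) for x in a))

    def __len__(self):
        return len(self.b_values)

    @property
    def b_array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)


@dataclass
class DWISeries:
    """4D diffusion-weighted series bound to its b-value scheme.

    ``signal`` has axes (x, y, z, b); the b axis length must match the scheme.
    """

    signal: np.ndarray
    scheme: BValueScheme
    voxel_size: tuple = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("DWI signal must be 4D (x, y, z, b)")
        if self.signal.shape[-1] != len(self.scheme):
            raise ValueError(
                f"b axis length {self.signal.shape[-1]} does not match "
                f"scheme length {len(self.scheme)}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.signal.shape[:3]:
                raise ValueError("mask shape does not match signal grid")


@dataclass(frozen=True)
class IVIMParams:
    """Single-voxel IVIM parameter set (SI units)."""

    d_slow: float
    d_fast: float
    f_p: float
    s0: float = 1.0

    def __post_init__(self):
        if not (self.d_slow > 0):
            raise ValueError("d_slow must be positive")
        if not (self.d_fast > self.d_slow):
            raise ValueError("d_fast must exceed d_slow")
        if not (0.0 <= self.f_p <= 1.0):
            raise ValueError("f_p must lie in [0, 1]")


@dataclass
class IVIMMaps:
    """Voxelwise IVIM parameter maps (SI mm^2/s; NaN outside mask)."""

    d_slow: np.ndarray
    d_fast: np.ndarray
    f_p: np.ndarray
    s0: np.ndarray
    mask: np.ndarray
    n_failed: int = 0


@dataclass
class PosteriorSummary:
    """Per-voxel posterior summaries from the Bayesian IVIM fit.

    Arrays are (n_voxels,) for scalar diagnostics and dict-of-arrays keyed by
    parameter name for the location/interval summaries.
    """

    median: dict
    mean: dict
    ci_low: dict
    ci_high: dict
    sigma2: np.ndarray
    acceptance_rate: np.ndarray
    n_iterations: int
    n_burn_in: int
    flagged: np.ndarray = field(default=None)


@dataclass(frozen=True)
class McmcConfig:
    """Configuration of the per-voxel Metropolis-within-Gibbs sampler."""

    n_iterations: int = 10000
    n_burn_in: int = 5000
    adapt_window: int = 50
    estimator: str = "median"
    seed: int = 0
    max_kept: int = 1000

    def __post_init__(self):
        if not self.n_burn_in < self.n_iterations:
            raise ValueError("burn-in must be smaller than iteration count")
        if self.estimator not in ("median", "mean"):
            raise ValueError("estimator must be 'median' or 'mean'")


def si_to_report(maps_or_value, kind: str):
    """Convert SI values to reporting units (x10^-3 mm^2/s, or % for f_p)."""
    v = np.asarray(maps_or_value, dtype=float)
    if kind in ("d_slow", "d_fast"):
        return v * 1e3
    if kind == "f_p":
        return v * 100.0
    raise ValueError(f"unknown parameter kind {kind!r}")


def report_to_si(value, kind: str):
    """Inverse of :func:`si_to_report`."""
    v = np.asarray(value, dtype=float)
    if kind in ("d_slow", "d_fast"):
        return v * 1e-3
    if kind == "f_p":
        return v / 100.0
    raise ValueError(f"unknown parameter kind {kind!r}")


def ivim_signal(params, b):
    """Normalized biexponential IVIM signal S(b)/S0.

    Parameters
    ----------
    params : IVIMParams or tuple (d_slow, d_fast, f_p)
    b : scalar or array of b-values in s/mm^2 (b >= 0)
    """
    if isinstance(params, IVIMParams):
        d_slow, d_fast, f_p = params.d_slow, params.d_fast, params.f_p
    else:
        d_slow, d_fast, f_p = params
        IVIMParams(d_slow, d_fast, f_p)  # validate
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    return f_p * np.exp(-b * d_fast) + (1.0 - f_p) * np.exp(-b * d_slow)


def _forward(b, d_slow, d_fast, f_p, s0):
    """Vectorized forward model; parameters broadcast against b's last axis."""
    return s0[..., None] * (
        f_p[..., None] * np.exp(-b * d_fast[..., None])
        + (1.0 - f_p[..., None]) * np.exp(-b * d_slow[..., None]))


def median_filter_slicewise(series: DWISeries) -> DWISeries:
    """3x3 in-plane median filter applied to every slice of every b-volume.

    Edges are handled by reflection; slice and b axes are untouched.
    """
    sig = series.signal
    size = (3, 3, 1, 1)
    filtered = ndimage.median_filter(sig, size=size, mode="reflect")
    return DWISeries(filtered, series.scheme, series.voxel_size, series.mask)


def resample_inplane(field: np.ndarray, target_inplane, kind: str) -> np.ndarray:
    """Resample only the first two (in-plane) axes of a 2D/3D/4D array.

    ``kind='down_for_fit'`` uses anti-aliased linear interpolation (area-like
    averaging) as appropriate for signal data; ``kind='up_for_maps'`` uses
    plain bilinear interpolation as appropriate for parameter maps.  Constant
    fields are preserved exactly; slice and b axes are untouched.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim < 2 or field.ndim > 4:
        raise ValueError("expected a 2D, 3D or 4D array")
    nx, ny = int(target_inplane[0]), int(target_inplane[1])
    if nx < 2 or ny < 2:
        raise ValueError("target dimensions must be >= 2 per axis")
    if kind not in ("down_for_fit", "up_for_maps"):
        raise ValueError("kind must be 'down_for_fit' or 'up_for_maps'")
    out_shape = (nx, ny) + field.shape[2:]
    if out_shape == field.shape:
        return field.copy()
    anti_alias = kind == "down_for_fit"
    return _sk_resize(field, out_shape, order=1, mode="reflect",
                      anti_aliasing=anti_alias, preserve_range=True)


def _clip_to_bounds(x, lo, hi):
    return np.clip(x, lo, hi)


class IVIMLeastSquares(BaseEstimator):
    """Segmented constrained least-squares IVIM fit.

    The classic baseline: ``d_slow`` and the slow-compartment amplitude come
    from a log-linear fit over ``b >= b_threshold`` (where the fast component
    has decayed away), ``f_p`` from the gap between the measured b=0 signal
    and the slow intercept, and ``d_fast`` from a one-parameter least-squares
    fit of the residual fast component on a log-spaced grid with parabolic
    refinement.  Estimates are clipped to the physiologic bounds.

    Parameters
    ----------
    b_values : sequence of b-values (s/mm^2), first must be 0.
    b_threshold : b-value (s/mm^2) above which the signal is treated as
        monoexponential; default 200.
    n_grid : size of the log-spaced d_fast search grid.

    Attributes (after ``fit``)
    --------------------------
    d_slow_, d_fast_, f_p_, s0_ : (n_voxels,) arrays, NaN where the fit failed
    failed_ : boolean (n_voxels,) failure flags
    n_failed_ : number of failed voxels
    """

    def __init__(self, b_values=TABLE_B_VALUES, b_threshold=200.0,
                 bounds=None, n_grid=400):
        self.b_values = b_values
        self.b_threshold = b_threshold
        self.bounds = bounds
        self.n_grid = n_grid

    def _get_bounds(self):
        return dict(IVIM_BOUNDS if self.bounds is None else self.bounds)

    def fit(self, X, y=None):
        b = np.asarray(self.b_values, dtype=float)
        if np.unique(b).size < 4:
            raise ValueError("need at least 4 distinct b-values")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != b.size:
            raise ValueError("signal column count does not match b_values")
        n_vox = X.shape[0]
        bounds = self._get_bounds()

        hi = b >= self.b_threshold
        if hi.sum() < 2:
            raise ValueError("b_threshold leaves fewer than 2 high-b points")

        s0_meas = X[:, 0]
        failed = ~np.isfinite(X).all(axis=1) | (s0_meas <= 0) | \
            np.any(X[:, hi] <= 0, axis=1)

        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.log(np.where(X[:, hi] > 0, X[:, hi], np.nan))
        bh = b[hi]
        # closed-form per-voxel simple linear regression of log S on b
        bx = bh - bh.mean()
        denom = (bx ** 2).sum()
        slope = (logs * bx).sum(axis=1) / denom
        intercept = logs.mean(axis=1) - slope * bh.mean()
        d_slow = _clip_to_bounds(-slope, *bounds["d_slow"])
        amp_slow = np.exp(intercept)  # S0 * (1 - f_p)

        f_p = _clip_to_bounds(1.0 - amp_slow / np.where(s0_meas > 0,
                                                        s0_meas, np.nan),
                              *bounds["f_p"])
        s0 = s0_meas

        # residual fast component, one-parameter grid fit for d_fast
        resid = X - amp_slow[:, None] * np.exp(-b * d_slow[:, None])
        amp_fast = s0 * f_p
        glo, ghi = bounds["d_fast"]
        grid = np.exp(np.linspace(np.log(glo), np.log(ghi), int(self.n_grid)))
        E = np.exp(-np.outer(grid, b))          # (G, n_b)
        sum_e2 = (E ** 2).sum(axis=1)           # (G,)
        cross = resid @ E.T                     # (n_vox, G)
        sse = (-2.0 * amp_fast[:, None] * cross
               + (amp_fast ** 2)[:, None] * sum_e2[None, :])
        k = np.nanargmin(np.where(np.isfinite(sse), sse, np.inf), axis=1)
        d_fast = grid[k]
        # parabolic refinement on the log grid
        interior = (k > 0) & (k < grid.size - 1)
        if np.any(interior):
            ki = k[interior]
            rows = np.nonzero(interior)[0]
            y0 = sse[rows, ki - 1]
            y1 = sse[rows, ki]
            y2 = sse[rows, ki + 1]
            denom2 = (y0 - 2 * y1 + y2)
            shift = np.where(np.abs(denom2) > 0,
                             0.5 * (y0 - y2) / np.where(denom2 == 0, 1.0,
                                                        denom2), 0.0)
            shift = np.clip(shift, -1.0, 1.0)
            dlog = np.log(grid[1]) - np.log(grid[0])
            d_fast[rows] = np.exp(np.log(grid[ki]) + shift * dlog)
        d_fast = _clip_to_bounds(d_fast, *bounds["d_fast"])
        d_fast = np.maximum(d_fast, d_slow * (1.0 + 1e-6))

        for arr in (d_slow, d_fast, f_p, s0):
            arr[failed] = np.nan
        self.d_slow_, self.d_fast_, self.f_p_, self.s0_ = d_slow, d_fast, f_p, s0
        self.failed_ = failed
        self.n_failed_ = int(failed.sum())
        self.n_features_in_ = b.size
        return self

    def params_array(self):
        """Stacked (n_voxels, 4) array: d_slow, d_fast, f_p, s0."""
        return np.column_stack([self.d_slow_, self.d_fast_,
                                self.f_p_, self.s0_])


class IVIMBayesian(BaseEstimator):
    """Voxelwise Bayesian IVIM fit by Metropolis-within-Gibbs sampling.

    Each voxel is fitted independently.  Sampling is performed on the
    transformed parameter vector

        theta = (log d_slow, log d_fast - log d_slow, logit(f_p / f_max),
                 log s0)

    which enforces ``d_fast > d_slow > 0`` and ``0 <= f_p <= f_max`` by
    construction.  Priors are flat on the transformed scale within finite
    bounds; the noise variance sigma^2 of the Gaussian likelihood is given a
    conjugate inverse-gamma treatment and Gibbs-sampled each iteration, which
    lets the chain anneal from the least-squares initialization.  Proposal
    scales are adapted per voxel during burn-in toward an acceptance rate of
    ~0.3.  All voxel chains run in lockstep as vectorized numpy updates.

    Point maps use the posterior median by default (robust to the skewed
    marginals typical of the fast compartment); the posterior mean is
    available via ``estimator='mean'``.
    """

    _TARGET_ACCEPT = 0.3
    _BASE_STEPS = np.array([0.03, 0.08, 0.20, 0.01])

    def __init__(self, b_values=TABLE_B_VALUES, n_iterations=10000,
                 n_burn_in=5000, adapt_window=50, estimator="median",
                 seed=0, bounds=None, max_kept=1000):
        self.b_values = b_values
        self.n_iterations = n_iterations
        self.n_burn_in = n_burn_in
        self.adapt_window = adapt_window
        self.estimator = estimator
        self.seed = seed
        self.bounds = bounds
        self.max_kept = max_kept

    @classmethod
    def from_config(cls, b_values, config: McmcConfig):
        return cls(b_values=b_values, n_iterations=config.n_iterations,
                   n_burn_in=config.n_burn_in,
                   adapt_window=config.adapt_window,
                   estimator=config.estimator, seed=config.seed,
                   max_kept=config.max_kept)

    def _get_bounds(self):
        return dict(IVIM_BOUNDS if self.bounds is None else self.bounds)

    def fit(self, X, y=None):
        cfg = McmcConfig(self.n_iterations, self.n_burn_in,
                         self.adapt_window, self.estimator, self.seed,
                         self.max_kept)
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 6:
            import warnings
            warnings.warn("fewer than 6 b-values: IVIM parameters are "
                          "weakly identified", stacklevel=2)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != b.size:
            raise ValueError("signal column count does not match b_values")
        n_vox, n_b = X.shape
        bounds = self._get_bounds()
        f_max = bounds["f_p"][1]
        rng = np.random.Generator(np.random.PCG64(cfg.seed))

        bad = ~np.isfinite(X).all(axis=1) | (X[:, 0] <= 0)
        Xw = np.where(bad[:, None], 1.0, X)  # placeholder rows, masked later

        # --- initialization from the segmented LSQ fit -------------------
        lsq = IVIMLeastSquares(b_values=tuple(b), bounds=bounds).fit(Xw)
        eps = 1e-3
        ds0 = np.clip(np.nan_to_num(lsq.d_slow_, nan=1.0e-3),
                      bounds["d_slow"][0] * (1 + eps),
                      bounds["d_slow"][1] * (1 - eps))
        df0 = np.clip(np.nan_to_num(lsq.d_fast_, nan=50.0e-3),
                      bounds["d_fast"][0] * (1 + eps),
                      bounds["d_fast"][1] * (1 - eps))
        df0 = np.maximum(df0, ds0 * 1.05)
        fp0 = np.clip(np.nan_to_num(lsq.f_p_, nan=0.2),
                      0.02 * f_max, 0.98 * f_max)
        s00 = np.clip(np.nan_to_num(lsq.s0_, nan=1.0), 1e-12, None)

        theta = np.column_stack([np.log(ds0), np.log(df0) - np.log(ds0),
                                 np.log(fp0 / (f_max - fp0)), np.log(s00)])

        lo_ds, hi_ds = np.log(bounds["d_slow"][0]), np.log(bounds["d_slow"][1])
        lo_df, hi_df = np.log(bounds["d_fast"][0]), np.log(bounds["d_fast"][1])
        logit_lim = 12.0
        s0_lo = theta[:, 3] - 2.0
        s0_hi = theta[:, 3] + 2.0

        def natural(th):
            d_slow = np.exp(th[:, 0])
            d_fast = np.exp(th[:, 0] + th[:, 1])
            f_p = f_max / (1.0 + np.exp(-th[:, 2]))
            s0 = np.exp(th[:, 3])
            return d_slow, d_fast, f_p, s0

        def sse_of(th):
            d_slow, d_fast, f_p, s0 = natural(th)
            model = _forward(b, d_slow, d_fast, f_p, s0)
            return ((Xw - model) ** 2).sum(axis=1)

        def in_support(th):
            ldf = th[:, 0] + th[:, 1]
            return ((th[:, 0] >= lo_ds) & (th[:, 0] <= hi_ds)
                    & (th[:, 1] > 0)
                    & (ldf >= lo_df) & (ldf <= hi_df)
                    & (np.abs(th[:, 2]) <= logit_lim)
                    & (th[:, 3] >= s0_lo) & (th[:, 3] <= s0_hi))

        sse = sse_of(theta)
        a0 = b0 = 1e-6  # weak inverse-gamma hyperprior on sigma^2
        log_scale = np.zeros(n_vox)

        n_keep_iters = cfg.n_iterations - cfg.n_burn_in
        thin = max(1, int(np.ceil(n_keep_iters / cfg.max_kept)))
        kept = []
        accept_post = np.zeros(n_vox)
        n_post = 0

        for it in range(cfg.n_iterations):
            # Gibbs update of sigma^2 | theta
            shape = a0 + 0.5 * n_b
            scale = b0 + 0.5 * sse
            sigma2 = scale / rng.gamma(shape, 1.0, size=n_vox)
            sigma2 = np.maximum(sigma2, 1e-300)

            # joint random-walk proposal on theta
            step = np.exp(log_scale)[:, None] * self._BASE_STEPS
            prop = theta + step * rng.standard_normal((n_vox, 4))
            ok = in_support(prop)
            sse_prop = sse_of(np.where(ok[:, None], prop, theta))
            log_alpha = np.where(ok, (sse - sse_prop) / (2.0 * sigma2),
                                 -np.inf)
            accept = np.log(rng.random(n_vox)) < log_alpha
            theta = np.where(accept[:, None], prop, theta)
            sse = np.where(accept, sse_prop, sse)

            if it < cfg.n_burn_in:
                acc_prob = np.where(ok, np.exp(np.minimum(log_alpha, 0.0)),
                                    0.0)
                gamma = 1.0 / (1.0 + it / cfg.adapt_window) ** 0.6
                log_scale += gamma * (acc_prob - self._TARGET_ACCEPT)
                log_scale = np.clip(log_scale, -12.0, 3.0)
            else:
                accept_post += accept
                n_post += 1
                if (it - cfg.n_burn_in) % thin == 0:
                    d_slow, d_fast, f_p, s0 = natural(theta)
                    kept.append(np.column_stack(
                        [d_slow, d_fast, f_p, s0, sigma2]))

        samples = np.stack(kept, axis=0)  # (n_kept, n_vox, 5)
        names = ("d_slow", "d_fast", "f_p", "s0")
        med = {k: np.median(samples[:, :, i], axis=0)
               for i, k in enumerate(names)}
        mean = {k: samples[:, :, i].mean(axis=0)
                for i, k in enumerate(names)}
        lo = {k: np.quantile(samples[:, :, i], 0.025, axis=0)
              for i, k in enumerate(names)}
        hi = {k: np.quantile(samples[:, :, i], 0.975, axis=0)
              for i, k in enumerate(names)}
        acc_rate = accept_post / max(n_post, 1)
        # posterior piled against a prior support bound: truth likely
        # outside the support (estimate pinned, not trustworthy)
        at_bound = (
            (med["d_slow"] > 0.90 * bounds["d_slow"][1])
            | (med["d_slow"] < 1.10 * bounds["d_slow"][0])
            | (med["d_fast"] > 0.90 * bounds["d_fast"][1])
            | (med["d_fast"] < 1.10 * bounds["d_fast"][0])
            | (med["f_p"] > 0.95 * f_max))
        flagged = (acc_rate < 0.1) | (acc_rate > 0.6) | bad | at_bound

        point = med if cfg.estimator == "median" else mean
        self.d_slow_ = np.where(bad, np.nan, point["d_slow"])
        self.d_fast_ = np.where(bad, np.nan, point["d_fast"])
        self.f_p_ = np.where(bad, np.nan, point["f_p"])
        self.s0_ = np.where(bad, np.nan, point["s0"])
        self.failed_ = bad
        self.n_failed_ = int(bad.sum())
        self.flagged_ = flagged
        self.at_bound_ = at_bound
        self.posterior_ = PosteriorSummary(
            median=med, mean=mean, ci_low=lo, ci_high=hi,
            sigma2=samples[:, :, 4].mean(axis=0),
            acceptance_rate=acc_rate,
            n_iterations=cfg.n_iterations, n_burn_in=cfg.n_burn_in,
            flagged=flagged)
        self.n_features_in_ = n_b
        return self


def _extract_voxels(series: DWISeries, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != series.signal.shape[:3]:
        raise ValueError("mask shape does not match series grid")
    if not mask.any():
        raise ValueError("mask is empty")
    return series.signal[mask, :], mask


def _maps_from_flat(est, mask) -> IVIMMaps:
    shape = mask.shape
    out = {}
    for name in ("d_slow_", "d_fast_", "f_p_", "s0_"):
        m = np.full(shape, np.nan)
        m[mask] = getattr(est, name)
        out[name.rstrip("_")] = m
    return IVIMMaps(mask=mask, n_failed=est.n_failed_, **out)


def fit_ivim_lsq(series: DWISeries, mask=None, b_threshold=200.0) -> IVIMMaps:
    """Segmented least-squares IVIM fit of all in-mask voxels of a series."""
    if mask is None:
        mask = series.mask
    voxels, mask = _extract_voxels(series, mask)
    est = IVIMLeastSquares(b_values=series.scheme.b_values,
                           b_threshold=b_threshold).fit(voxels)
    return _maps_from_flat(est, mask)


def fit_ivim_bayes(series: DWISeries, mask=None,
                   config: McmcConfig = McmcConfig()):
    """Bayesian voxelwise IVIM fit; returns (IVIMMaps, PosteriorSummary)."""
    if mask is None:
        mask = series.mask
    voxels, mask = _extract_voxels(series, mask)
    est = IVIMBayesian.from_config(series.scheme.b_values, config).fit(voxels)
    return _maps_from_flat(est, mask), est.posterior_


def global_liver_summary(maps: IVIMMaps) -> dict:
    """Whole-liver summary statistics per parameter, in reporting units.

    Mean/median/SD/min/max over in-mask voxels; NaN voxels inside the mask
    are excluded and counted.  Diffusivities in x10^-3 mm^2/s, f_p in %.
    """
    if not maps.mask.any():
        raise ValueError("mask is empty")
    out = {}
    for name in ("d_slow", "d_fast", "f_p"):
        vals = getattr(maps, name)[maps.mask]
        n_nan = int(np.isnan(vals).sum())
        vals = vals[np.isfinite(vals)]
        vals = si_to_report(vals, name)
        out[name] = {
            "mean": float(np.mean(vals)),
            "median": float(np.median(vals)),
            "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
            "n_voxels": int(vals.size),
            "n_excluded": n_nan,
        }
    return out
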