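"""Digital liver phantoms with known ground truth.

Generates two-cohort studies (healthy volunteers vs. mildly impaired
cirrhotic patients) in which every voxel carries known IVIM diffusion
parameters, pre/post-contrast T1, and hepatic extraction fraction, so each
downstream estimator can be scored against truth without any scan data.

Cohort-level parameter distributions default to the study conditions of the
emulated protocol: subject-level medians/SDs of D_slow, F_p and D_fast for
each cohort, a 13-b acquisition scheme with per-b excitation counts, SPGR
imaging at 3/15 degrees with TR 5.08 ms under a smooth multiplicative B1
field, and a low-temporal-resolution DCE time grid out to 1200 s.  T1 and
HEF cohort values, which the emulated protocol reports only qualitatively,
default to literature-typical liver values at 3T (healthy T1 ~810 ms with
strong gadoxetate uptake; cirrhotic T1 higher with reduced uptake).

Distribution families respect parameter invariants: log-normal for the
diffusivities, logit-normal for the fractions, positivity-truncated normal
for T1.  Families are parameterized by (median, SD) so that the configured
median is exact and the configured SD approximately matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import expit, logit

from .hef import DCESeries, build_convolution_matrix, gamma_variate_aif
from .ivim import BValueScheme, DWISeries, _forward
from .t1 import spgr_signal

__all__ = [
    "PhantomTruth",
    "CohortConfig",
    "SubjectData",
    "make_phantom_truth",
    "simulate_dwi",
    "simulate_spgr_pair",
    "simulate_dce",
    "make_cohort",
    "default_b1_field",
    "DEFAULT_GROUP_MEDIANS",
    "DEFAULT_GROUP_SDS",
]

# Subject-level (median, spread) study conditions per cohort.  Diffusivities
# in SI mm^2/s, fractions as fractions, T1 in ms.
DEFAULT_GROUP_MEDIANS = {
    "healthy": {"d_slow": 1.02e-3, "d_fast": 73.5e-3, "f_p": 0.292,
                "t1_pre": 810.0, "t1_post": 310.0, "hef": 0.85},
    "patient": {"d_slow": 0.96e-3, "d_fast": 36.4e-3, "f_p": 0.216,
                "t1_pre": 870.0, "t1_post": 530.0, "hef": 0.55},
}
DEFAULT_GROUP_SDS = {
    "healthy": {"d_slow": 0.15e-3, "d_fast": 25.5e-3, "f_p": 0.051,
                "t1_pre": 60.0, "t1_post": 40.0, "hef": 0.05},
    "patient": {"d_slow": 0.13e-3, "d_fast": 14.2e-3, "f_p": 0.040,
                "t1_pre": 80.0, "t1_post": 80.0, "hef": 0.12},
}

#: Low-temporal-resolution DCE time grid (s): one breath-hold frame per
#: minute out to 20 min post-injection.
DEFAULT_DCE_TIMES = tuple(float(t) for t in range(0, 1201, 60))

#: Typical peak amplitude of a noise-free tissue curve under the default
#: gamma-variate input function and retention time constants (used to refer
#: relative noise levels to the DCE scale).
_DCE_CURVE_SCALE = 50.0


@dataclass
class PhantomTruth:
    """Ground-truth parameter fields of one synthetic subject."""

    shape: tuple
    liver_mask: np.ndarray
    region_labels: np.ndarray
    d_slow: np.ndarray
    d_fast: np.ndarray
    f_p: np.ndarray
    t1_pre: np.ndarray
    t1_post: np.ndarray
    hef: np.ndarray
    cohort: str

    def validate(self):
        m = self.liver_mask
        if self.cohort not in ("healthy", "patient"):
            raise ValueError(f"invalid cohort {self.cohort!r}")
        if not ((self.f_p[m] >= 0).all() and (self.f_p[m] <= 1).all()):
            raise AssertionError("f_p outside [0, 1] inside mask")
        if not (self.d_slow[m] > 0).all():
            raise AssertionError("non-positive d_slow inside mask")
        if not (self.d_fast[m] > self.d_slow[m]).all():
            raise AssertionError("d_fast <= d_slow inside mask")
        if not (self.t1_post[m] <= self.t1_pre[m]).all():
            raise AssertionError("t1_post exceeds t1_pre inside mask")
        if not ((self.hef >= 0).all() and (self.hef <= 1).all()):
            raise AssertionError("hef outside [0, 1]")
        return self


@dataclass(frozen=True)
class CohortConfig:
    """Two-cohort study configuration.

    ``heterogeneity`` scales the within-subject (region-to-region) relative
    scatter as a fraction of each parameter's cohort-level coefficient of
    variation, so degenerate configurations with zero group SD yield
    perfectly uniform livers.
    """

    n_healthy: int = 10
    n_patient: int = 12
    shape: tuple = (64, 64, 8)
    group_medians: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_GROUP_MEDIANS.items()})
    group_sds: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_GROUP_SDS.items()})
    heterogeneity: float = 0.3
    noise_sd: float = 0.0
    s0: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_healthy < 0 or self.n_patient < 0:
            raise ValueError("subject counts must be non-negative")
        if any(s < 16 for s in self.shape[:2]) or self.shape[2] < 3:
            raise ValueError("shape must be at least 16x16x3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for cohort, sds in self.group_sds.items():
            if any(v < 0 for v in sds.values()):
                raise ValueError("group_sds must be non-negative")
        for cohort, med in self.group_medians.items():
            if med["d_slow"] <= 0 or med["d_fast"] <= med["d_slow"]:
                raise ValueError("median diffusivities violate invariants")
            if not 0 < med["f_p"] < 1 or not 0 < med["hef"] < 1:
                raise ValueError("median fractions must lie in (0, 1)")
            if med["t1_post"] > med["t1_pre"]:
                raise ValueError("median t1_post must not exceed t1_pre")


def _lognormal_sigma(median, sd):
    """Sigma of a log-normal with the given median and standard deviation."""
    if sd == 0:
        return 0.0
    c2 = (sd / median) ** 2
    u = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * c2))
    return float(np.sqrt(np.log(u)))


def _draw(rng, family, median, sd, size=None):
    """Median-exact random draw from the family respecting its support."""
    if sd == 0:
        return np.full(size, median) if size else median
    if family == "lognormal":
        sigma = _lognormal_sigma(median, sd)
        return median * np.exp(sigma * rng.standard_normal(size))
    if family == "logitnormal":
        sigma = sd / (median * (1.0 - median))  # delta-method scale
        return expit(logit(median) + sigma * rng.standard_normal(size))
    if family == "truncnormal":
        out = median + sd * rng.standard_normal(size)
        return np.abs(out)  # reflect at zero; negligible for liver T1 scales
    raise ValueError(f"unknown family {family!r}")


_FAMILIES = {"d_slow": "lognormal", "d_fast": "lognormal",
             "f_p": "logitnormal", "hef": "logitnormal",
             "t1_pre": "truncnormal", "t1_post": "truncnormal"}


def _ellipsoid_mask(shape):
    nx, ny, nz = shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    rx, ry, rz = 0.42 * nx, 0.34 * ny, 0.46 * nz
    return (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
            + ((z - cz) / rz) ** 2) <= 1.0


def _segment_labels(mask):
    """Quadrant-style segment labels 1..4 inside the liver mask."""
    nx, ny, _ = mask.shape
    x, y, _z = np.indices(mask.shape)
    lab = 1 + (x >= nx // 2).astype(int) + 2 * (y >= ny // 2).astype(int)
    return np.where(mask, lab, 0)


def _smooth_within(field, mask, sigma=1.5):
    """Gaussian smoothing renormalized inside the mask (no edge decay)."""
    m = mask.astype(float)
    num = ndimage.gaussian_filter(field * m, sigma)
    den = ndimage.gaussian_filter(m, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 1e-12, num / den, 0.0)
    return np.where(mask, out, 0.0)


def make_phantom_truth(config: CohortConfig, cohort: str,
                       seed: int) -> PhantomTruth:
    """Draw one subject's ground-truth parameter fields.

    A subject-level value per parameter is drawn from the cohort
    distribution; region values scatter multiplicatively around it
    (controlled by ``config.heterogeneity``) and are smoothed within the
    liver mask.  Identical seeds give identical subjects.
    """
    if cohort not in config.group_medians:
        raise ValueError(f"invalid cohort label {cohort!r}")
    rng = np.random.Generator(np.random.PCG64(seed))
    shape = tuple(config.shape)
    mask = _ellipsoid_mask(shape)
    labels = _segment_labels(mask)
    n_regions = int(labels.max())

    medians = config.group_medians[cohort]
    sds = config.group_sds[cohort]
    fields = {}
    delta_rel = None
    for name in ("d_slow", "d_fast", "f_p", "t1_pre", "hef"):
        family = _FAMILIES[name]
        subj = _draw(rng, family, medians[name], sds[name])
        cv = sds[name] / medians[name]
        sig_het = config.heterogeneity * cv
        region_mult = np.exp(sig_het * rng.standard_normal(n_regions)) \
            if sig_het > 0 else np.ones(n_regions)
        f = np.zeros(shape)
        for k in range(1, n_regions + 1):
            f[labels == k] = subj * region_mult[k - 1]
        fields[name] = _smooth_within(f, mask)
    # t1_post derived from a per-subject uptake (percent T1 reduction) so
    # t1_post <= t1_pre holds by construction
    delta_med = 1.0 - medians["t1_post"] / medians["t1_pre"]
    delta_sd = delta_med * np.sqrt(
        (sds["t1_post"] / medians["t1_post"]) ** 2 * 0.5) \
        if sds["t1_post"] > 0 else 0.0
    delta_subj = _draw(rng, "logitnormal", delta_med, delta_sd) \
        if delta_sd > 0 else delta_med
    fields["t1_post"] = fields["t1_pre"] * (1.0 - delta_subj)

    fields["f_p"] = np.clip(fields["f_p"], 0.0, 1.0)
    fields["hef"] = np.clip(fields["hef"], 0.0, 1.0)
    fields["d_fast"] = np.maximum(fields["d_fast"],
                                  fields["d_slow"] * 1.05)
    truth = PhantomTruth(shape=shape, liver_mask=mask, region_labels=labels,
                         cohort=cohort, **fields)
    return truth.validate()


def simulate_dwi(truth: PhantomTruth, scheme: BValueScheme = BValueScheme(),
                 noise_sd: float = 0.0, noise_model: str = "gaussian",
                 seed: int = 0, s0: float = 1000.0) -> DWISeries:
    """Forward-simulate a 13-b DWI series from phantom truth.

    Per b-value, the stored volume is the mean of ``averages[k]`` independent
    noisy excitations (Gaussian noise on the complex-free signal, or Rician
    magnitude noise).  Outside the liver the signal is background noise only.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_model not in ("gaussian", "rician"):
        raise ValueError("noise_model must be 'gaussian' or 'rician'")
    rng = np.random.Generator(np.random.PCG64(seed))
    b = scheme.b_array
    m = truth.liver_mask
    clean = np.zeros(truth.shape + (b.size,))
    clean[m] = _forward(b, truth.d_slow[m], truth.d_fast[m],
                        truth.f_p[m], np.full(m.sum(), float(s0)))
    if noise_sd == 0:
        return DWISeries(clean, scheme, mask=m)
    out = np.empty_like(clean)
    for k, n_avg in enumerate(scheme.averages):
        reps_shape = (n_avg,) + truth.shape
        base = clean[..., k]
        if noise_model == "gaussian":
            reps = base + noise_sd * rng.standard_normal(reps_shape)
        else:
            re = base + noise_sd * rng.standard_normal(reps_shape)
            im = noise_sd * rng.standard_normal(reps_shape)
            reps = np.hypot(re, im)
        out[..., k] = reps.mean(axis=0)
    return DWISeries(out, scheme, mask=m)


def default_b1_field(shape, amplitude=0.2):
    """Smooth multiplicative B1 field in [1-amplitude, 1+amplitude].

    Low-order polynomial in normalized coordinates (deterministic): a
    bowl-shaped transmit profile typical of body imaging at 3T.
    """
    nx, ny, nz = shape
    x = np.linspace(-1, 1, nx)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    z = np.linspace(-1, 1, nz)[None, None, :]
    poly = 0.6 * x ** 2 + 0.3 * y ** 2 - 0.25 * x * y + 0.1 * z
    poly = poly - poly.mean()
    poly = poly / np.abs(poly).max()
    return 1.0 + amplitude * np.broadcast_to(poly, shape).copy()


def simulate_spgr_pair(truth: PhantomTruth, phase: str, tr: float = 5.08,
                       flip_angles=(3.0, 15.0), b1_field=None,
                       noise_sd: float = 0.0, seed: int = 0,
                       m0: float = 1000.0) -> dict:
    """Simulate SPGR volumes at each flip angle for the pre/post phase.

    Returns a dict mapping flip angle (degrees) to a noisy 3D volume;
    outside the liver the signal is background noise only.
    """
    if phase not in ("pre", "post"):
        raise ValueError("phase must be 'pre' or 'post'")
    if tr <= 0:
        raise ValueError("TR must be positive")
    angles = tuple(float(a) for a in flip_angles)
    if len(angles) == 0:
        raise ValueError("flip_angles must be non-empty")
    if any(a <= 0 or a > 90 for a in angles):
        raise ValueError("flip angles must lie in (0, 90] degrees")
    if b1_field is None:
        b1_field = default_b1_field(truth.shape)
    b1_field = np.asarray(b1_field, dtype=float)
    if np.any(b1_field <= 0):
        raise ValueError("B1 field must be positive")
    t1 = truth.t1_pre if phase == "pre" else truth.t1_post
    rng = np.random.Generator(np.random.PCG64(seed))
    m = truth.liver_mask
    out = {}
    for a in angles:
        vol = np.zeros(truth.shape)
        vol[m] = spgr_signal(m0, t1[m], tr, a, b1_field[m])
        if noise_sd > 0:
            vol = vol + noise_sd * rng.standard_normal(truth.shape)
        out[a] = vol
    return out


def simulate_dce(truth: PhantomTruth, times=DEFAULT_DCE_TIMES,
                 aif_params=None, tau_fast: float = 60.0,
                 tau_slow: float = 3000.0, noise_sd: float = 0.0,
                 seed: int = 0) -> DCESeries:
    """Forward-simulate a low-temporal-resolution DCE series.

    Each voxel's tissue curve is the discrete convolution (same trapezoid
    operator used by the deconvolution stage) of the input function with the
    two-compartment retention function R(t) parameterized by the voxel HEF.
    """
    times = np.asarray(times, dtype=float)
    if times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must start at 0 and be strictly increasing")
    if not 0 < tau_fast < tau_slow:
        raise ValueError("need 0 < tau_fast < tau_slow")
    aif = gamma_variate_aif(times, **(aif_params or {}))
    A = build_convolution_matrix(aif, times)
    m = truth.liver_mask
    hef = truth.hef[m][:, None]
    r = (1.0 - hef) * np.exp(-times / tau_fast) \
        + hef * np.exp(-times / tau_slow)
    curves = r @ A.T
    sig = np.zeros(truth.shape + (times.size,))
    sig[m] = curves
    if noise_sd > 0:
        rng = np.random.Generator(np.random.PCG64(seed))
        sig = sig + noise_sd * rng.standard_normal(sig.shape)
    return DCESeries(signal=sig, times=times, aif=aif, mask=m)


@dataclass
class SubjectData:
    """One subject's simulated study bundle."""

    subject_id: str
    cohort: str
    truth: PhantomTruth
    dwi: DWISeries
    spgr_pre: dict | None = None
    spgr_post: dict | None = None
    b1_field: np.ndarray | None = None
    dce: DCESeries | None = None
    spgr_tr: float = 5.08
    flip_angles: tuple = (3.0, 15.0)


def make_cohort(config: CohortConfig) -> list:
    """Generate the full two-cohort study bundle.

    Healthy subjects receive only the DWI acquisition (no contrast is given
    to volunteers, so no SPGR/T1 or DCE data exist for them); patients
    receive DWI, pre/post SPGR pairs with a B1 field, and a DCE series.
    Per-subject seeds are spawned deterministically from ``config.seed``.
    """
    n_total = config.n_healthy + config.n_patient
    if n_total == 0:
        raise ValueError("cohort must contain at least one subject")
    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(n_total)]
    subjects = []
    labels = (["healthy"] * config.n_healthy
              + ["patient"] * config.n_patient)
    for i, (cohort, seed) in enumerate(zip(labels, child_seeds)):
        truth = make_phantom_truth(config, cohort, seed)
        dwi = simulate_dwi(truth, noise_sd=config.noise_sd, seed=seed + 1,
                           s0=config.s0)
        subj = SubjectData(subject_id=f"sub-{i + 1:03d}", cohort=cohort,
                           truth=truth, dwi=dwi)
        if cohort == "patient":
            b1 = default_b1_field(truth.shape)
            subj.b1_field = b1
            subj.spgr_pre = simulate_spgr_pair(
                truth, "pre", b1_field=b1, noise_sd=config.noise_sd,
                seed=seed + 2)
            subj.spgr_post = simulate_spgr_pair(
                truth, "post", b1_field=b1, noise_sd=config.noise_sd,
                seed=seed + 3)
            # DCE noise at the same relative level as the DWI noise,
            # referred to the typical tissue-curve amplitude under the
            # default input function and retention time constants
            dce_noise = config.noise_sd / config.s0 * _DCE_CURVE_SCALE
            subj.dce = simulate_dce(truth, noise_sd=dce_noise,
                                    seed=seed + 4)
        subjects.append(subj)
    return subjects
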