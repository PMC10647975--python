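"""Imaging-biomarker statistics.

Repeatability metrics (percent difference to reference, intra/inter-session
coefficient of variation, within-subject CV of scan-rescan pairs), two-group
comparison (Mann-Whitney U), ROC analysis with Youden-index optimal cutoff
and stratified bootstrap confidence intervals, voxelwise Pearson correlation
with Fisher-Z pooling across subjects, and Dice overlap as registration QC.

Conventions: sample SD (ddof=1) throughout, because the emulated study's
group sizes are small; exact Mann-Whitney p-values for small untied samples,
normal approximation with tie correction otherwise; correlation strength
bands |r| 0.1-0.3 small, 0.3-0.5 medium, 0.5-1.0 large.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RepeatabilityResult",
    "GroupComparisonResult",
    "RocResult",
    "percent_difference",
    "coefficient_of_variation",
    "session_cv",
    "within_subject_cv",
    "mann_whitney_u",
    "roc_auc",
    "roc_analysis",
    "bootstrap_validate",
    "voxelwise_pearson",
    "fisher_z_average",
    "correlation_strength",
    "dice_similarity",
]

_EXACT_MWU_MAX_N = 12


@dataclass
class RepeatabilityResult:
    percent_diff_to_reference: float
    intra_session_cv: float
    inter_session_cv: float
    within_subject_cv: float | None = None
    per_subject_cv: dict | None = None


@dataclass
class GroupComparisonResult:
    group_a: dict
    group_b: dict
    u_statistic: float
    p_value: float
    significant: bool
    alpha: float
    method: str


@dataclass
class RocResult:
    auc: float
    direction: str              # 'higher' or 'lower' score indicates disease
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float | None = None
    n_bootstrap: int | None = None


def percent_difference(measured, reference, absolute=False):
    """Signed (or absolute) percent difference 100*(measured-reference)/reference."""
    reference = float(reference)
    if reference == 0:
        raise ValueError("reference must be non-zero")
    d = 100.0 * (float(measured) - reference) / reference
    return abs(d) if absolute else d


def coefficient_of_variation(values):
    """Percent coefficient of variation, 100 * sample SD / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("mean is zero; CV undefined")
    return 100.0 * v.std(ddof=1) / m


def session_cv(values_by_session):
    """Intra- and inter-session CV decomposition.

    ``values_by_session`` is a sequence of per-session repeat lists.
    Intra-session CV = mean of the per-session CVs of repeats;
    inter-session CV = CV of the session means.
    """
    sessions = [np.asarray(s, dtype=float) for s in values_by_session]
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions")
    intra = float(np.mean([coefficient_of_variation(s) for s in sessions]))
    inter = float(coefficient_of_variation([s.mean() for s in sessions]))
    return intra, inter


def within_subject_cv(pairs):
    """Within-subject CV of scan-rescan pairs.

    ``pairs``: mapping subject -> (scan, rescan) or sequence of 2-tuples.
    Returns (per_subject dict in %, summary dict with mean/min/max).
    """
    if hasattr(pairs, "items"):
        items = list(pairs.items())
    else:
        items = list(enumerate(pairs))
    if not items:
        raise ValueError("need at least one subject")
    per_subject = {}
    for key, pair in items:
        pair = np.asarray(pair, dtype=float)
        if pair.size != 2 or not np.isfinite(pair).all():
            raise ValueError(f"subject {key!r}: missing scan or rescan value")
        per_subject[key] = coefficient_of_variation(pair)
    vals = np.array(list(per_subject.values()))
    summary = {"mean": float(vals.mean()), "min": float(vals.min()),
               "max": float(vals.max())}
    return per_subject, summary


def _describe(v):
    v = np.asarray(v, dtype=float)
    return {"n": int(v.size), "median": float(np.median(v)),
            "min": float(v.min()), "max": float(v.max()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0}


def mann_whitney_u(group_a, group_b, alternative="two-sided",
                   alpha=0.05) -> GroupComparisonResult:
    """Mann-Whitney U comparison of two independent samples.

    Uses the exact null distribution when n_a + n_b <= 12 and there are no
    ties, otherwise the normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size + b.size <= _EXACT_MWU_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    p = float(res.pvalue)
    return GroupComparisonResult(
        group_a=_describe(a), group_b=_describe(b),
        u_statistic=float(res.statistic), p_value=p,
        significant=p < alpha, alpha=alpha, method=method)


def roc_auc(scores, labels):
    """Rank-based AUC (ties counted half); labels are 0 (healthy) / 1 (disease)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def roc_analysis(scores, labels, direction="auto") -> RocResult:
    """ROC analysis with Youden-index optimal cutoff.

    The score direction is auto-chosen so that AUC >= 0.5 and reported
    (``'higher'``: larger scores indicate disease; ``'lower'``: smaller
    scores do).  The optimal cutoff maximizes sensitivity + specificity - 1;
    ties are broken toward higher specificity.  The cutoff is the midpoint
    between the adjacent scores it separates.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc = roc_auc(scores, labels)
    if direction == "auto":
        direction = "higher" if auc >= 0.5 else "lower"
    eff = scores if direction == "higher" else -scores
    auc_eff = roc_auc(eff, labels)

    pos = eff[labels == 1]
    neg = eff[labels == 0]
    order = np.sort(np.unique(eff))
    # candidate thresholds: midpoints between consecutive distinct scores,
    # plus sentinels below/above all scores
    mids = (order[:-1] + order[1:]) / 2.0 if order.size > 1 else np.array([])
    cands = np.concatenate([[order[0] - 1.0], mids, [order[-1] + 1.0]])
    sens = np.array([(pos >= c).mean() for c in cands])
    spec = np.array([(neg < c).mean() for c in cands])
    youden = sens + spec - 1.0
    best = youden.max()
    tied = np.isclose(youden, best)
    idx = np.nonzero(tied)[0][np.argmax(spec[tied])]
    cutoff_eff = float(cands[idx])
    cutoff = cutoff_eff if direction == "higher" else -cutoff_eff
    return RocResult(auc=auc_eff, direction=direction, optimal_cutoff=cutoff,
                     sensitivity=float(sens[idx]),
                     specificity=float(spec[idx]))


def bootstrap_validate(scores, labels, statistic="auc", n_samples=1000,
                       level=95.0, seed=0):
    """Stratified percentile-bootstrap CI for an ROC statistic.

    Resamples each class separately (so every resample keeps both classes),
    recomputes the statistic (``'auc'`` or ``'cutoff'``), and returns
    ``(low, high, details)`` at the given confidence level.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    if not 50.0 < level < 100.0:
        raise ValueError("level must lie in (50, 100)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    i0 = np.nonzero(labels == 0)[0]
    i1 = np.nonzero(labels == 1)[0]
    if i0.size == 0 or i1.size == 0:
        raise ValueError("both classes must be present")
    rng = np.random.Generator(np.random.PCG64(seed))
    n_redrawn = 0
    n0, n1 = i0.size, i1.size
    r0 = rng.integers(0, n0, size=(n_samples, n0))
    r1 = rng.integers(0, n1, size=(n_samples, n1))
    s = np.concatenate([scores[i0][r0], scores[i1][r1]], axis=1)
    if statistic == "auc":
        ranks = sps.rankdata(s, axis=1)
        u = ranks[:, n0:].sum(axis=1) - n1 * (n1 + 1) / 2.0
        vals = u / (n0 * n1)
    elif statistic == "cutoff":
        lab = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
        vals = np.array([roc_analysis(row, lab).optimal_cutoff for row in s])
    else:
        raise ValueError("statistic must be 'auc' or 'cutoff'")
    tail = (100.0 - level) / 2.0
    low, high = np.percentile(vals, [tail, 100.0 - tail])
    return float(low), float(high), {"n_samples": n_samples, "level": level,
                                     "n_redrawn": n_redrawn,
                                     "samples": vals}


def _fisher_ci(r, n, level=95.0):
    if n < 4:
        return (np.nan, np.nan)
    if abs(r) >= 1.0:  # degenerate: zero-width interval at the bound
        return (float(r), float(r))
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    q = sps.norm.ppf(0.5 + level / 200.0)
    return float(np.tanh(z - q * se)), float(np.tanh(z + q * se))


def correlation_strength(r):
    """Strength band of a correlation coefficient: small/medium/large/negligible."""
    a = abs(float(r))
    if a >= 0.5:
        return "large"
    if a >= 0.3:
        return "medium"
    if a >= 0.1:
        return "small"
    return "negligible"


def voxelwise_pearson(map_a, map_b, roi, level=95.0):
    """Pearson correlation of two parameter maps over an ROI.

    Returns a dict with r, p, CI bounds (Fisher transform), voxel count and
    the strength band.  Voxels must be finite in both maps; zero variance in
    either map is an error.
    """
    roi = np.asarray(roi).astype(bool)
    a = np.asarray(map_a, dtype=float)[roi]
    b = np.asarray(map_b, dtype=float)[roi]
    good = np.isfinite(a) & np.isfinite(b)
    a, b = a[good], b[good]
    if a.size < 3:
        raise ValueError("ROI must contain at least 3 finite voxel pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in one of the maps over the ROI")
    res = sps.pearsonr(a, b)
    r = float(res.statistic)
    lo, hi = _fisher_ci(r, a.size, level)
    return {"r": r, "p": float(res.pvalue), "ci_low": lo, "ci_high": hi,
            "n_voxels": int(a.size), "strength": correlation_strength(r)}


def fisher_z_average(r_values):
    """Fisher-Z pooled correlation: z_bar = mean(atanh(r)), r_bar = tanh(z_bar)."""
    r = np.asarray(r_values, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one correlation")
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| = 1 cannot be Fisher-averaged; "
                         "exclude degenerate correlations first")
    z_bar = float(np.mean(np.arctanh(r)))
    return float(np.tanh(z_bar)), z_bar


def dice_similarity(mask_a, mask_b):
    """Dice overlap 2|A&B| / (|A|+|B|); both-empty masks score 1.0."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask grids differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
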