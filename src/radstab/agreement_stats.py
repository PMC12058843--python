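"""Agreement and stability statistics: Dice, diameter, ICC, CCC, OCCC.

The central statistic is the overall concordance correlation coefficient
(OCCC), Barnhart's generalization of Lin's CCC to J >= 2 observers::

    OCCC = 2 * sum_{j<k} s_jk
           ---------------------------------------------
           (J-1) * sum_j s_j^2  +  sum_{j<k} (m_j - m_k)^2

with population (1/n) moments, so the J = 2 case reduces exactly to Lin's
CCC.  A feature's OCCC over a study (rows = nodules, columns = observers)
is binned into the stability classes poor (< 0.5), average ([0.5, 0.75)),
good ([0.75, 0.90)) and very good (>= 0.90); OCCC >= 0.75 counts as stable.
OCCC can be negative for strongly discordant columns; negative values are
reported as computed and classified poor, not clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .volume_io import MaskVolume, check_aligned

__all__ = [
    "dice",
    "estimate_diameter",
    "icc",
    "lin_ccc",
    "occc",
    "classify_stability",
    "agreement_record",
    "AgreementRecord",
    "StabilityClass",
    "STABILITY_LABELS",
]

STABILITY_LABELS = ("poor", "average", "good", "very_good")
STABLE_THRESHOLD = 0.75  # OCCC at or above this counts as "good stability"


def dice(a: MaskVolume, b: MaskVolume) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) between two aligned masks."""
    check_aligned(a, b)
    na, nb = a.n_foreground, b.n_foreground
    if na == 0 and nb == 0:
        raise ValueError("both masks are empty: Dice is undefined")
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (na + nb)


def estimate_diameter(m: MaskVolume) -> float:
    """Clinical nodule diameter in cm from the mask.

    On the axial (x-y) slice with the largest in-plane extent: the maximum
    long diameter is the largest pairwise distance between in-slice voxels,
    and the maximum short diameter is the extent measured perpendicular to
    the long-diameter direction on the same slice; the mean of the two is
    returned.  Center-to-center measurements are extended by half an in-plane
    voxel (and floored at one voxel) so a single voxel reports its physical
    size rather than zero.  Ties between slices go to the lowest slice index.
    """
    if m.n_foreground == 0:
        raise ValueError("empty mask")
    sx, sy, _ = m.spacing_mm
    s_inplane = 0.5 * (sx + sy)
    best = None
    for z in range(m.values.shape[2]):
        pts = np.argwhere(m.values[:, :, z]).astype(np.float64)
        if len(pts) == 0:
            continue
        pts *= (sx, sy)
        if len(pts) == 1:
            d_long, direction = 0.0, np.array([1.0, 0.0])
        else:
            from scipy.spatial.distance import pdist, squareform

            dmat = squareform(pdist(pts))
            i, j = np.unravel_index(np.argmax(dmat), dmat.shape)
            d_long = float(dmat[i, j])
            direction = pts[j] - pts[i]
            direction /= np.linalg.norm(direction)
        if best is None or d_long > best[0]:
            best = (d_long, direction, pts)
    d_long, direction, pts = best
    perp = np.array([-direction[1], direction[0]])
    proj = pts @ perp
    d_short = float(proj.max() - proj.min())
    d_long = max(d_long + 0.5 * s_inplane, s_inplane)
    d_short = max(d_short + 0.5 * s_inplane, s_inplane)
    return (d_long + d_short) / 2.0 / 10.0


def icc(
    values: np.ndarray, model: str = "two_way_random_absolute_single"
) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Returns the coefficient and its 95% confidence interval from the
    standard mean-squares decomposition and F-based interval.  Subjects with
    any missing value are dropped.  Zero between-subject variance returns 0
    with a warning (agreement is then meaningless, not perfect).
    """
    if model != "two_way_random_absolute_single":
        raise ValueError(f"unsupported ICC model {model!r}")
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("expected an n x k matrix with k >= 2 raters")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 complete subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= mse or denom <= 0:
        warnings.warn("no between-subject variance: ICC reported as 0", stacklevel=2)
        return 0.0, (0.0, 0.0)
    value = (msr - mse) / denom
    if mse == 0.0 or value >= 1.0:  # perfect agreement: degenerate interval
        return float(value), (float(value), float(value))

    # F-based CI (McGraw & Wong) for ICC(A,1)
    alpha = 0.05
    a = k * value / (n * (1.0 - value))
    b = 1.0 + k * value * (n - 1) / (n * (1.0 - value))
    fj = msc / mse
    v = (a * fj + b) ** 2 / (
        (a * fj) ** 2 / (k - 1) + b**2 / ((n - 1) * (k - 1))
    )
    f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_lo * mse) / (
        f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_hi * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_hi * msr
    )
    return float(value), (float(lower), float(upper))


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient with population moments.

    ``2 s_xy / (s_x^2 + s_y^2 + (m_x - m_y)^2)``.  Two identical constant
    series give 1; two different constant series give 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1D vectors, n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    sx2 = x.var()
    sy2 = y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0.0:
        return 1.0  # identical constant series
    return float(2.0 * sxy / denom)


def occc(values: np.ndarray, drop_nan_rows: bool = True) -> float:
    """Overall CCC of an n-subjects x J-observers measurement matrix.

    Population moments; for J = 2 this equals :func:`lin_ccc` exactly.  Rows
    with missing values are dropped (count noted in a warning).  If all
    columns are constant: identical columns give 1, differing columns 0.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("expected an n x J matrix with J >= 2 observers")
    bad = np.isnan(x).any(axis=1)
    if bad.any():
        if not drop_nan_rows:
            raise ValueError("matrix contains NaN rows")
        warnings.warn(f"dropping {bad.sum()} rows with missing values", stacklevel=2)
        x = x[~bad]
    n, J = x.shape
    if n < 2:
        raise ValueError("need at least 2 complete subjects")
    means = x.mean(axis=0)
    centered = x - means
    cov = centered.T @ centered / n  # population covariance, J x J
    iu = np.triu_indices(J, k=1)
    num = 2.0 * cov[iu].sum()
    mean_gaps = (means[:, None] - means[None, :]) ** 2
    denom = (J - 1) * np.trace(cov) + mean_gaps[iu].sum()
    if denom == 0.0:
        return 1.0  # all columns constant and identical
    return float(num / denom)


@dataclass
class StabilityClass:
    """A feature's stability bin and the OCCC value that produced it."""

    label: str
    occc: float


def classify_stability(occc_value: float) -> StabilityClass:
    """Bin an OCCC into poor / average / good / very_good.

    poor < 0.5 <= average < 0.75 <= good < 0.90 <= very_good; negative values
    are poor; NaN raises (callers exclude NaN features with a report).
    """
    if np.isnan(occc_value):
        raise ValueError("NaN OCCC cannot be classified; exclude the feature")
    if occc_value < 0.5:
        label = "poor"
    elif occc_value < 0.75:
        label = "average"
    elif occc_value < 0.90:
        label = "good"
    else:
        label = "very_good"
    return StabilityClass(label, float(occc_value))


@dataclass
class AgreementRecord:
    """Per-nodule pairwise Dice summary over J observers."""

    nodule_id: str
    observer_ids: list[str]
    dice_matrix: np.ndarray  # J x J, unit diagonal
    median_dc: float  # median of the J(J-1)/2 off-diagonal pairs
    dc_vs_reference: dict[str, float]  # J-1 values against the reference
    excluded: list[str]  # observers dropped for empty masks


def agreement_record(
    masks: list[MaskVolume],
    observer_ids: list[str] | None = None,
    reference_index: int = 0,
    nodule_id: str = "",
) -> AgreementRecord:
    """Full pairwise Dice matrix with the per-nodule median DC.

    Empty masks exclude their observer (reported in ``excluded``); the median
    DC is taken over the strictly-upper-triangle pairwise values, and the
    reference-anchored values are Dice against the reference observer.
    """
    if observer_ids is None:
        observer_ids = [f"obs{i}" for i in range(len(masks))]
    if len(masks) != len(observer_ids):
        raise ValueError("masks and observer_ids length mismatch")
    if len(masks) < 2:
        raise ValueError("need at least 2 observers")
    ref_id = observer_ids[reference_index]
    keep = [i for i, m in enumerate(masks) if m.n_foreground > 0]
    excluded = [observer_ids[i] for i in range(len(masks)) if i not in keep]
    if excluded:
        warnings.warn(f"excluding observers with empty masks: {excluded}", stacklevel=2)
    masks = [masks[i] for i in keep]
    ids = [observer_ids[i] for i in keep]
    J = len(masks)
    if J < 2:
        raise ValueError("fewer than 2 nonempty masks")
    mat = np.eye(J)
    for i in range(J):
        for j in range(i + 1, J):
            mat[i, j] = mat[j, i] = dice(masks[i], masks[j])
    iu = np.triu_indices(J, k=1)
    median_dc = float(np.median(mat[iu]))
    dc_vs_ref = {}
    if ref_id in ids:
        r = ids.index(ref_id)
        dc_vs_ref = {ids[i]: float(mat[r, i]) for i in range(J) if i != r}
    return AgreementRecord(nodule_id, ids, mat, median_dc, dc_vs_ref, excluded)
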