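"""Per-trimer geometry and condition-level statistics.

Everything downstream of trimer identification lives here: triangle
geometry (pairwise distances, vertex angles, circumradius and projected
circumcircle area), condition summaries with chi-square variance
confidence intervals, nonparametric two-condition comparisons
(Kolmogorov-Smirnov on per-molecule mean distances, F-test of equality of
variances, Mann-Whitney on per-angle deviations from threefold symmetry),
Gaussian fits to angle histograms, and the kernel-density mode used to
summarize per-localization distance distributions.

Conventions
-----------
The "average interblade distance" of a molecule is the arithmetic mean of
the three pairwise fluorophore-centre distances.  The projected area of a
molecule is the area pi*R^2 of the circle through its three centres,
computed in 3D.  No multiple-testing correction is applied: pairwise
condition tests are reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError, GeometryError

__all__ = [
    "TrimerGeometry",
    "ConditionSummary",
    "ConditionComparison",
    "AngleFit",
    "trimer_geometry",
    "summarize_condition",
    "summarize_distances",
    "compare_conditions",
    "fit_angle_histogram",
    "density_mode",
    "expansion_vs_model",
    "angle_deviations",
]


@dataclass(frozen=True)
class TrimerGeometry:
    """Geometry of one triangle of fluorophore centres."""

    pairwise_d: np.ndarray  # (3,) nm: d(0,1), d(0,2), d(1,2)
    mean_d: float  # nm
    angles: np.ndarray  # (3,) degrees, at vertices 0, 1, 2
    circumradius: float  # nm
    area: float  # nm^2, projected circumcircle area pi R^2


@dataclass(frozen=True)
class ConditionSummary:
    """Summary of per-molecule mean interblade distances in one condition."""

    n_molecules: int
    mean_d: float  # nm
    sd_d: float  # nm, sample s.d. (n-1)
    variance: float  # nm^2
    variance_ci: tuple[float, float]  # 95% chi-square CI
    mean_area: float | None = None  # nm^2
    sd_area: float | None = None  # nm^2


@dataclass(frozen=True)
class ConditionComparison:
    """Two-condition statistics on distances and angle asymmetry."""

    ks_D: float
    ks_p: float
    f_stat: float  # larger variance / smaller; nan if degenerate
    f_p: float
    mwu_U: float | None
    mwu_p: float | None
    delta_mean: float  # mean_d(a) - mean_d(b), nm


@dataclass(frozen=True)
class AngleFit:
    """Gaussian fit to a binned angle histogram."""

    mu: float  # degrees
    sigma: float  # degrees
    r_squared: float
    bin_width: float  # degrees
    amplitude: float


def trimer_geometry(centres: np.ndarray) -> TrimerGeometry:
    """Triangle geometry of three 3D fluorophore centres.

    Distances are Euclidean in 3D; vertex angles sum to 180 degrees; the
    circumradius is R = abc / (4K) with K the 3D triangle area, and the
    projected area is pi R^2.

    Raises
    ------
    GeometryError
        If the three points are (numerically) collinear or coincident.
    """
    p = np.asarray(centres, dtype=float)
    if p.shape != (3, 3):
        raise ValueError(f"expected three 3D points, got shape {p.shape}")
    a = np.linalg.norm(p[1] - p[2])  # side opposite vertex 0
    b = np.linalg.norm(p[0] - p[2])  # opposite vertex 1
    c = np.linalg.norm(p[0] - p[1])  # opposite vertex 2
    if min(a, b, c) <= 0:
        raise GeometryError("coincident points")
    cross = np.cross(p[1] - p[0], p[2] - p[0])
    triangle_area = 0.5 * np.linalg.norm(cross)
    if triangle_area <= 1e-9 * max(a, b, c) ** 2:
        raise GeometryError("collinear points: circumradius undefined")
    angles = np.degrees(
        [
            np.arccos(np.clip((b * b + c * c - a * a) / (2 * b * c), -1.0, 1.0)),
            np.arccos(np.clip((a * a + c * c - b * b) / (2 * a * c), -1.0, 1.0)),
            np.arccos(np.clip((a * a + b * b - c * c) / (2 * a * b), -1.0, 1.0)),
        ]
    )
    circumradius = a * b * c / (4.0 * triangle_area)
    pairwise = np.array([c, b, a])  # d(0,1), d(0,2), d(1,2)
    return TrimerGeometry(
        pairwise_d=pairwise,
        mean_d=float(pairwise.mean()),
        angles=angles,
        circumradius=float(circumradius),
        area=float(np.pi * circumradius**2),
    )


def summarize_distances(
    distances: Sequence[float], areas: Sequence[float] | None = None
) -> ConditionSummary:
    """Summarize per-molecule mean distances (and optionally areas).

    Variance CI is the standard chi-square interval with n-1 degrees of
    freedom; a zero-variance sample yields the degenerate interval (0, 0).
    """
    d = np.asarray(distances, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError(f"need at least 2 molecules to summarize, got {n}")
    variance = float(d.var(ddof=1))
    if variance == 0.0:
        ci = (0.0, 0.0)
    else:
        ci = (
            float((n - 1) * variance / stats.chi2.ppf(0.975, n - 1)),
            float((n - 1) * variance / stats.chi2.ppf(0.025, n - 1)),
        )
    mean_area = sd_area = None
    if areas is not None:
        arr = np.asarray(areas, dtype=float)
        mean_area = float(arr.mean())
        sd_area = float(arr.std(ddof=1))
    return ConditionSummary(
        n_molecules=n,
        mean_d=float(d.mean()),
        sd_d=float(d.std(ddof=1)),
        variance=variance,
        variance_ci=ci,
        mean_area=mean_area,
        sd_area=sd_area,
    )


def summarize_condition(trimers: Iterable) -> ConditionSummary:
    """Summarize a set of identified trimers (objects with mean_d and area)."""
    trimers = list(trimers)
    return summarize_distances(
        [t.mean_d for t in trimers], areas=[t.area for t in trimers]
    )


def compare_conditions(
    a: Sequence[float],
    b: Sequence[float],
    angle_dev_a: Sequence[float] | None = None,
    angle_dev_b: Sequence[float] | None = None,
) -> ConditionComparison:
    """Compare two conditions' per-molecule mean distances.

    Two-sample two-tailed KS (exact for samples of at most 25, asymptotic
    otherwise); F-test with F = larger sample variance / smaller and a
    two-tailed p from the F distribution; optionally a Mann-Whitney U test
    (normal approximation with tie correction) on per-angle deviations
    from 60 degrees.  ``delta_mean`` is mean(a) - mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    method = "exact" if max(a.size, b.size) <= 25 else "asymp"
    ks = stats.ks_2samp(a, b, method=method)

    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 or vb == 0.0:
        f_stat, f_p = float("nan"), float("nan")
    else:
        if va >= vb:
            f_stat, dfn, dfd = va / vb, a.size - 1, b.size - 1
        else:
            f_stat, dfn, dfd = vb / va, b.size - 1, a.size - 1
        f_p = min(1.0, 2.0 * float(stats.f.sf(f_stat, dfn, dfd)))
        f_stat = float(f_stat)

    mwu_U = mwu_p = None
    if angle_dev_a is not None and angle_dev_b is not None:
        res = stats.mannwhitneyu(
            angle_dev_a, angle_dev_b, alternative="two-sided", method="asymptotic"
        )
        mwu_U, mwu_p = float(res.statistic), float(res.pvalue)

    return ConditionComparison(
        ks_D=float(ks.statistic),
        ks_p=float(ks.pvalue),
        f_stat=f_stat,
        f_p=f_p,
        mwu_U=mwu_U,
        mwu_p=mwu_p,
        delta_mean=float(a.mean() - b.mean()),
    )


def angle_deviations(trimers: Iterable) -> np.ndarray:
    """Pooled per-angle deviations |theta - 60 deg| (three per molecule)."""
    devs = [np.abs(np.asarray(t.angles) - 60.0) for t in trimers]
    if not devs:
        return np.empty(0)
    return np.concatenate(devs)


def _gaussian(x: np.ndarray, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_angle_histogram(angles: Sequence[float], bin_width: float = 10.0) -> AngleFit:
    """Unweighted least-squares Gaussian fit to a binned angle sample.

    The histogram uses bins of ``bin_width`` degrees aligned to multiples
    of the bin width; the fit is A*exp(-(x-mu)^2 / 2 sigma^2) on bin
    centres and R^2 is computed on bin counts.

    Raises
    ------
    FitError
        For degenerate histograms (< 3 occupied bins) or non-convergence,
        with residual diagnostics.
    """
    x = np.asarray(angles, dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 angles, got {x.size}")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < 3:
        raise FitError(
            f"degenerate histogram: only {np.count_nonzero(counts)} occupied "
            f"bin(s) at bin width {bin_width} deg; cannot fit a Gaussian"
        )
    weights = counts / counts.sum()
    mu0 = float(np.sum(centres * weights))
    sigma0 = float(np.sqrt(np.sum((centres - mu0) ** 2 * weights)))
    p0 = (float(counts.max()), mu0, max(sigma0, bin_width / 2))
    try:
        popt, _ = optimize.curve_fit(
            _gaussian,
            centres,
            counts,
            p0=p0,
            bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        resid = counts - _gaussian(centres, *p0)
        raise FitError(
            f"Gaussian fit did not converge (initial residual SS "
            f"{float(resid @ resid):.3g}): {exc}"
        ) from exc
    fitted = _gaussian(centres, *popt)
    ss_res = float(np.sum((counts - fitted) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return AngleFit(
        mu=float(popt[1]),
        sigma=float(abs(popt[2])),
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
        bin_width=bin_width,
        amplitude=float(popt[0]),
    )


def density_mode(distances: Sequence[float], kde_bandwidth: float = 2.5) -> float:
    """Mode of a Gaussian kernel density over a distance sample.

    The density is evaluated on a 0.1 nm grid spanning the data (padded by
    three bandwidths) and the argmax is returned.  The bandwidth is an
    absolute length in nm.
    """
    x = np.asarray(distances, dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 distances, got {x.size}")
    if kde_bandwidth <= 0:
        raise ValueError("kde_bandwidth must be > 0")
    grid = np.arange(
        x.min() - 3 * kde_bandwidth, x.max() + 3 * kde_bandwidth + 0.1, 0.1
    )
    density = np.zeros_like(grid)
    inv_2h2 = 1.0 / (2.0 * kde_bandwidth**2)
    # chunk the sample so grid x sample never materializes at full size
    for chunk in np.array_split(x, max(1, x.size // 2000)):
        density += np.exp(-((grid[:, None] - chunk[None, :]) ** 2) * inv_2h2).sum(axis=1)
    return float(grid[int(np.argmax(density))])


def expansion_vs_model(cell_mean_d: float, model_d: float) -> tuple[float, float]:
    """Expansion of a measured mean distance relative to a structural model.

    Returns ``(delta, percent)`` with delta = cell - model in nm and
    percent = 100 * delta / model.
    """
    if not model_d > 0:
        raise ValueError("model_d must be > 0")
    delta = cell_mean_d - model_d
    return float(delta), float(100.0 * delta / model_d)
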