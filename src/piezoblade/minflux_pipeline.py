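"""Trimer identification from MINFLUX-style 3D localization tables.

The pipeline turns a localization table into identified triple-labelled
molecules in four stages:

1. :func:`filter_traces` — drop blinking traces with per-axis standard
   deviation above 10 nm (background and streaks) or fewer than three
   localizations.
2. :func:`cluster_two_step` — DBSCAN at eps 30 nm / minpts 5 over all
   localizations, then DBSCAN at eps 6.5 nm / minpts 5 within each
   first-step cluster; second-step clusters keep a link to their parent.
3. :func:`fit_fluorophores` — per first-step cluster, a diagonal-covariance
   Gaussian mixture fitted by expectation-maximization with trace-level
   responsibilities; the component count comes from grouping blinking-
   trace means (BIC over localization-level fits as fallback) and
   per-axis sigmas are initialized at 5 nm.  Component means are the
   fluorophore centre estimates, component sigmas their positional
   uncertainty.
4. :func:`identify_trimers` — DBSCAN over fluorophore centres at eps
   100 nm / minpts 3; keep clusters of exactly three whose members are
   mutually separated within the neighbour window (6-50 nm, or 5-60 nm in
   the alternate variant), more than 100 nm from every other fluorophore,
   inside the z gate, and whose triangle has no vertex angle above 120
   degrees.

Reproducibility: density clustering is order-independent in membership;
permuting input rows changes no output beyond cluster ids.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN
from sklearn.mixture import GaussianMixture

from .errors import GeometryError
from .geometry_stats import trimer_geometry
from .localization_io import PipelineConfig, validate_localizations

__all__ = [
    "FluorophoreEstimate",
    "Trimer",
    "Step2Cluster",
    "TwoStepClusters",
    "filter_traces",
    "cluster_two_step",
    "fit_fluorophores",
    "identify_trimers",
    "run_minflux",
    "SIGMA_FLOOR",
]

#: Lower clamp (nm) for a degenerate EM component sigma.
SIGMA_FLOOR = 0.5


@dataclass(frozen=True)
class FluorophoreEstimate:
    """Fitted centre and per-axis sigma of one fluorophore cluster."""

    centre: np.ndarray  # (3,) nm
    sigma: np.ndarray  # (3,) nm, per-axis
    n_localizations: int
    cluster_id: int
    parent: int  # first-step DBSCAN cluster label
    flagged: bool = False  # True if any sigma was clamped to the floor
    truth_id: str | None = None


@dataclass(frozen=True)
class Trimer:
    """An identified triple-labelled molecule."""

    fluors: tuple[FluorophoreEstimate, FluorophoreEstimate, FluorophoreEstimate]
    pairwise_d: np.ndarray  # (3,) nm
    mean_d: float  # nm
    angles: np.ndarray  # (3,) degrees, sum to 180
    circumradius: float  # nm
    area: float  # nm^2
    truth_id: str | None = None  # common generating molecule, if known

    @property
    def centres(self) -> np.ndarray:
        return np.stack([f.centre for f in self.fluors])


@dataclass(frozen=True)
class Step2Cluster:
    """A second-step DBSCAN cluster with a link to its parent."""

    indices: np.ndarray  # positional indices into the filtered table
    parent: int


@dataclass(frozen=True)
class TwoStepClusters:
    """Result of the two-step density clustering."""

    coords: np.ndarray  # (n, 3) of the filtered table
    step1_labels: np.ndarray  # (n,), -1 for noise
    clusters: list[Step2Cluster]
    truth_ids: np.ndarray | None = None
    trace_ids: np.ndarray | None = None


def filter_traces(table: pd.DataFrame, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Keep traces with per-axis s.d. <= max_trace_sd and enough localizations.

    The trace statistic is the largest of the three per-axis sample
    standard deviations (a conservative reading).  Counts removed per
    criterion are reported in ``result.attrs["filter_report"]``.  An empty
    input yields an empty output.
    """
    cfg = cfg or PipelineConfig()
    if len(table) == 0:
        out = table.copy()
        out.attrs["filter_report"] = {
            "n_traces_in": 0,
            "n_traces_kept": 0,
            "removed_high_sd": 0,
            "removed_short": 0,
        }
        return out
    grouped = table.groupby("trace_id", sort=False)
    stds = grouped[["x_nm", "y_nm", "z_nm"]].std(ddof=1).fillna(0.0)
    counts = grouped.size()
    sd_max = stds.max(axis=1)
    high_sd = sd_max > cfg.max_trace_sd
    short = counts < cfg.min_locs_per_trace
    keep_ids = sd_max.index[~(high_sd | short)]
    out = table[table["trace_id"].isin(set(keep_ids))].copy()
    out.attrs["filter_report"] = {
        "n_traces_in": int(counts.size),
        "n_traces_kept": int(keep_ids.size),
        "removed_high_sd": int(high_sd.sum()),
        "removed_short": int(short.sum()),
    }
    return out


def cluster_two_step(
    table: pd.DataFrame, cfg: PipelineConfig | None = None
) -> TwoStepClusters:
    """Two-step DBSCAN over the localizations of a (filtered) table.

    Noise points of either step belong to no cluster; second-step clusters
    retain their first-step parent label.
    """
    cfg = cfg or PipelineConfig()
    coords = table[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    truth = (
        table["truth_id"].to_numpy(dtype=object) if "truth_id" in table.columns else None
    )
    traces = table["trace_id"].to_numpy(dtype=object) if "trace_id" in table.columns else None
    if len(coords) == 0:
        return TwoStepClusters(coords, np.empty(0, dtype=int), [], truth, traces)
    step1 = DBSCAN(eps=cfg.dbscan1_eps, min_samples=cfg.dbscan1_minpts).fit_predict(coords)
    clusters: list[Step2Cluster] = []
    for parent in np.unique(step1):
        if parent == -1:
            continue
        member_idx = np.flatnonzero(step1 == parent)
        sub = DBSCAN(eps=cfg.dbscan2_eps, min_samples=cfg.dbscan2_minpts).fit_predict(
            coords[member_idx]
        )
        for label in np.unique(sub):
            if label == -1:
                continue
            clusters.append(
                Step2Cluster(indices=member_idx[sub == label], parent=int(parent))
            )
    return TwoStepClusters(
        coords=coords,
        step1_labels=step1,
        clusters=clusters,
        truth_ids=truth,
        trace_ids=traces,
    )


def _majority_truth(truth_ids: np.ndarray | None, indices: np.ndarray) -> str | None:
    if truth_ids is None or indices.size == 0:
        return None
    values, counts = np.unique(truth_ids[indices].astype(str), return_counts=True)
    return str(values[np.argmax(counts)])


#: Largest mixture size tried per first-step cluster.  A first-step
#: cluster is at most one trimer plus an occasional stray trace, so
#: fluorophore counts beyond four do not occur at realistic fields.
_MAX_COMPONENTS = 4

#: Minimum localizations for a trace mean to count toward the component
#: number (matches the trace-filter floor).
_TRACE_MEAN_MIN_LOCS = 3

#: Average-linkage cut, in units of the pairwise standard error, grouping
#: trace means into fluorophore candidates.  Distances between trace means
#: are normalized by sqrt(se_i^2 + se_j^2), each SE estimated from the
#: trace's own localization scatter, so the grouping adapts to the data's
#: noise scale: same-emitter means sit ~1.5 normalized units apart
#: regardless of trace length, while emitters separated by several mean
#: errors stay distinct.
_TRACE_CLUSTER_CUT_SIGMA = 4.0

#: Floor (nm) for a trace-mean standard error, so noiseless duplicates
#: compare at a finite scale.
_TRACE_SE_FLOOR = 0.05

#: Post-fit merge radius (nm): fitted components closer than this are
#: indistinguishable (it lies below the smallest neighbour-window floor)
#: and are pooled into one estimate.
_MERGE_RADIUS = 5.0


def _trace_mean_components(
    points: np.ndarray, trace_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | None:
    """Fluorophore candidates from blinking-trace means.

    Each trace re-localizes one emitter, so its mean estimates that
    emitter's position with standard error sd/sqrt(n) — usually far below
    the cloud sigma.  Average-linkage grouping of trace means under the
    SE-normalized metric therefore counts overlapping fluorophores that
    density clustering cannot separate.  Returns (centroids, weights) or
    None if no trace qualifies.
    """
    means, ses, weights = [], [], []
    for tid in pd.unique(trace_ids):
        sel = trace_ids == tid
        n = int(sel.sum())
        if n < _TRACE_MEAN_MIN_LOCS:
            continue
        pts = points[sel]
        means.append(pts.mean(axis=0))
        sd = float(np.sqrt(pts.var(axis=0, ddof=1).mean()))
        ses.append(max(sd / np.sqrt(n), _TRACE_SE_FLOOR))
        weights.append(n)
    if not means:
        return None
    means_arr = np.stack(means)
    se_arr = np.array(ses)
    weights_arr = np.array(weights, dtype=float)
    if len(means_arr) == 1:
        labels = np.zeros(1, dtype=int)
    else:
        diff = np.linalg.norm(means_arr[:, None] - means_arr[None, :], axis=2)
        scale = np.sqrt(se_arr[:, None] ** 2 + se_arr[None, :] ** 2)
        iu = np.triu_indices(len(means_arr), 1)
        labels = hierarchy.fcluster(
            hierarchy.linkage((diff / scale)[iu], method="average"),
            t=_TRACE_CLUSTER_CUT_SIGMA,
            criterion="distance",
        )
    centroids, totals = [], []
    for label in np.unique(labels):
        sel = labels == label
        w = weights_arr[sel]
        centroids.append(np.average(means_arr[sel], axis=0, weights=w))
        totals.append(w.sum())
    return np.stack(centroids), np.array(totals)


def _trace_block_em(
    points: np.ndarray,
    trace_of: np.ndarray,
    means0: np.ndarray,
    weights0: np.ndarray,
    init_sigma: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    reg: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagonal-covariance EM with trace-level responsibilities.

    All localizations of one blinking trace come from one emitter, so the
    E-step assigns whole traces: the log-likelihood of a trace under a
    component is the sum over its localizations.  This removes the
    outward repulsion bias that localization-level EM shows for clouds
    overlapping at separations below ~2.5 sigma — a 20-localization trace
    is decisively assigned where single localizations are ambiguous.

    Returns (means (k,3), variances (k,3), per-point component labels).
    """
    k = len(means0)
    n_traces = int(trace_of.max()) + 1
    counts = np.bincount(trace_of, minlength=n_traces).astype(float)
    sums = np.stack(
        [np.bincount(trace_of, weights=points[:, a], minlength=n_traces) for a in range(3)],
        axis=1,
    )
    sqsums = np.stack(
        [np.bincount(trace_of, weights=points[:, a] ** 2, minlength=n_traces) for a in range(3)],
        axis=1,
    )
    means = means0.astype(float).copy()
    var = np.full((k, 3), float(init_sigma) ** 2)
    weights = weights0 / weights0.sum()
    prev_ll = -np.inf
    resp = np.ones((n_traces, k)) / k
    for _ in range(max_iter):
        quad = (
            sqsums[:, None, :]
            - 2.0 * means[None] * sums[:, None, :]
            + counts[:, None, None] * means[None] ** 2
        ) / var[None]
        log_prob = -0.5 * (
            quad.sum(axis=2)
            + counts[:, None] * np.log(2.0 * np.pi * var).sum(axis=1)[None]
        )
        log_prob += np.log(np.maximum(weights, 1e-300))[None]
        top = log_prob.max(axis=1, keepdims=True)
        lse = top[:, 0] + np.log(np.exp(log_prob - top).sum(axis=1))
        ll = float(lse.sum() / counts.sum())  # per-localization
        resp = np.exp(log_prob - lse[:, None])
        eff = (resp * counts[:, None]).sum(axis=0) + 1e-12
        means = (resp[:, :, None] * sums[:, None, :]).sum(axis=0) / eff[:, None]
        second = (resp[:, :, None] * sqsums[:, None, :]).sum(axis=0) / eff[:, None]
        var = np.maximum(second - means**2, reg)
        weights = eff / eff.sum()
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    trace_labels = np.argmax(resp, axis=1)
    return means, var, trace_labels[trace_of]


def _fit_mixture(
    points: np.ndarray,
    k: int,
    cfg: PipelineConfig,
    means_init: np.ndarray | None,
    weights_init: np.ndarray | None,
) -> GaussianMixture:
    gm = GaussianMixture(
        n_components=k,
        covariance_type="diag",
        tol=1e-6,
        max_iter=500,
        reg_covar=1e-6,
        means_init=means_init,
        weights_init=weights_init,
        precisions_init=np.full((k, 3), 1.0 / cfg.gmm_init_sigma**2),
        init_params="k-means++" if means_init is None else "kmeans",
        random_state=0,
    )
    return gm.fit(points)


def fit_fluorophores(
    two_step: TwoStepClusters, cfg: PipelineConfig | None = None
) -> list[FluorophoreEstimate]:
    """EM Gaussian-mixture fit of fluorophore centres, one parent at a time.

    The mixture size K is not observable from density clustering alone:
    at 6 nm localization error the clouds of fluorophores closer than
    roughly 20 nm overlap enough that eps 6.5 nm density clustering merges
    them, so the second-step cluster count is only a lower bound.  K is
    therefore taken from the blinking-trace structure — average-linkage
    grouping of trace means under an SE-normalized metric (each trace
    re-localizes one emitter with sub-cloud precision) — with means and
    weights initialized at the trace-group centroids, and the EM E-step
    runs at trace granularity (see :func:`_trace_block_em`), which keeps
    centre estimates unbiased even for clouds overlapping at 1-2 sigma.
    Where no trace structure exists, K is selected by BIC over 1-4
    localization-level components (second-step centroids seed the
    matching size).  Per-axis sigmas are initialized at
    ``gmm_init_sigma``; convergence is a log-likelihood change below 1e-6
    or 500 iterations.  Fitted components closer than 5 nm (below any
    neighbour-window floor) are pooled; a component whose sigma collapses
    below 0.5 nm on any axis is clamped to the floor and flagged;
    components assigned fewer than ``dbscan2_minpts`` localizations are
    dropped.
    """
    cfg = cfg or PipelineConfig()
    by_parent: dict[int, list[Step2Cluster]] = {}
    for cl in two_step.clusters:
        by_parent.setdefault(cl.parent, []).append(cl)

    estimates: list[FluorophoreEstimate] = []
    next_id = 0
    for parent in sorted(by_parent):
        children = by_parent[parent]
        parent_idx = np.flatnonzero(two_step.step1_labels == parent)
        points = two_step.coords[parent_idx]

        trace_init = None
        if two_step.trace_ids is not None:
            trace_init = _trace_mean_components(points, two_step.trace_ids[parent_idx])
        if trace_init is not None:
            centroids, weights = trace_init
            trace_codes = pd.factorize(two_step.trace_ids[parent_idx])[0]
            means, variances, labels = _trace_block_em(
                points,
                trace_codes,
                centroids,
                weights,
                cfg.gmm_init_sigma,
            )
        else:
            child_means = np.stack(
                [two_step.coords[c.indices].mean(axis=0) for c in children]
            )
            child_sizes = np.array([c.indices.size for c in children], dtype=float)
            n_children = len(children)
            gm, best_bic = None, np.inf
            for k in range(1, min(_MAX_COMPONENTS, len(points)) + 1):
                means_init = child_means if k == n_children else None
                weights_init = (
                    child_sizes / child_sizes.sum() if k == n_children else None
                )
                cand = _fit_mixture(points, k, cfg, means_init, weights_init)
                bic = cand.bic(points)
                if bic < best_bic:
                    gm, best_bic = cand, bic
            if gm is None:
                continue
            means, variances = gm.means_, gm.covariances_
            labels = gm.predict(points)

        components = []
        for comp in range(len(means)):
            assigned = parent_idx[labels == comp]
            if assigned.size == 0:
                continue
            components.append(
                {
                    "centre": means[comp].copy(),
                    "var": variances[comp].copy(),
                    "assigned": assigned,
                }
            )
        components = _merge_close_components(components)
        for comp in components:
            if comp["assigned"].size < cfg.dbscan2_minpts:
                continue
            sigma = np.sqrt(comp["var"])
            flagged = bool(np.any(sigma < SIGMA_FLOOR))
            sigma = np.maximum(sigma, SIGMA_FLOOR)
            estimates.append(
                FluorophoreEstimate(
                    centre=comp["centre"],
                    sigma=sigma,
                    n_localizations=int(comp["assigned"].size),
                    cluster_id=next_id,
                    parent=int(parent),
                    flagged=flagged,
                    truth_id=_majority_truth(two_step.truth_ids, comp["assigned"]),
                )
            )
            next_id += 1
    return estimates


def _merge_close_components(components: list[dict]) -> list[dict]:
    """Pool fitted components separated by less than the merge radius."""
    merged = True
    while merged and len(components) > 1:
        merged = False
        for i in range(len(components)):
            for j in range(i + 1, len(components)):
                a, b = components[i], components[j]
                if np.linalg.norm(a["centre"] - b["centre"]) < _MERGE_RADIUS:
                    wa, wb = a["assigned"].size, b["assigned"].size
                    centre = (wa * a["centre"] + wb * b["centre"]) / (wa + wb)
                    var = (wa * a["var"] + wb * b["var"]) / (wa + wb)
                    components[i] = {
                        "centre": centre,
                        "var": var,
                        "assigned": np.concatenate([a["assigned"], b["assigned"]]),
                    }
                    del components[j]
                    merged = True
                    break
            if merged:
                break
    return components


def identify_trimers(
    fluors: list[FluorophoreEstimate],
    cfg: PipelineConfig | None = None,
    nn_variant: str = "standard",
) -> list[Trimer]:
    """Select trimers from fluorophore centres by the selection rules.

    Density-cluster centres (eps ``trimer_eps``, minpts ``trimer_minpts``),
    keep clusters of exactly three, require all three pairwise separations
    inside the neighbour window, every member more than ``isolation`` nm
    from any fluorophore outside the cluster, all centres inside
    ``z_range`` (if set), and no vertex angle above ``max_vertex_angle``.
    An empty result is not an error.
    """
    cfg = cfg or PipelineConfig()
    if len(fluors) < 3:
        return []
    centres = np.stack([f.centre for f in fluors])
    labels = DBSCAN(eps=cfg.trimer_eps, min_samples=cfg.trimer_minpts).fit_predict(centres)
    lo, hi = cfg.nn_window(nn_variant)

    trimers: list[Trimer] = []
    for label in np.unique(labels):
        if label == -1:
            continue
        members = np.flatnonzero(labels == label)
        if members.size != 3:
            continue
        pts = centres[members]
        d = np.array(
            [
                np.linalg.norm(pts[0] - pts[1]),
                np.linalg.norm(pts[0] - pts[2]),
                np.linalg.norm(pts[1] - pts[2]),
            ]
        )
        if np.any(d < lo) or np.any(d > hi):
            continue
        others = np.delete(np.arange(len(fluors)), members)
        if others.size and cdist(pts, centres[others]).min() <= cfg.isolation:
            continue
        if cfg.z_range is not None:
            z = pts[:, 2]
            if np.any(z < cfg.z_range[0]) or np.any(z > cfg.z_range[1]):
                continue
        try:
            geom = trimer_geometry(pts)
        except GeometryError:
            continue
        if np.any(geom.angles > cfg.max_vertex_angle):
            continue
        triple = tuple(fluors[i] for i in members)
        truths = {f.truth_id for f in triple}
        truth = truths.pop() if len(truths) == 1 else None
        trimers.append(
            Trimer(
                fluors=triple,  # type: ignore[arg-type]
                pairwise_d=geom.pairwise_d,
                mean_d=geom.mean_d,
                angles=geom.angles,
                circumradius=geom.circumradius,
                area=geom.area,
                truth_id=truth,
            )
        )
    return trimers


def run_minflux(
    table: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    nn_variant: str = "standard",
) -> tuple[list[Trimer], dict]:
    """Full localization-table -> trimers pipeline.

    If ``cfg.z_range`` is None the gate defaults to the 5th-95th percentile
    of the filtered localization z, recorded in the returned log.
    """
    cfg = cfg or PipelineConfig()
    table = validate_localizations(table.copy())
    filtered = filter_traces(table, cfg)
    log: dict = {"n_localizations_in": int(len(table))}
    log.update(filtered.attrs.get("filter_report", {}))
    if cfg.z_range is None and len(filtered):
        z = filtered["z_nm"].to_numpy(dtype=float)
        z_lo, z_hi = float(np.percentile(z, 5)), float(np.percentile(z, 95))
        if z_hi <= z_lo:  # flat z (e.g. noiseless membrane plane)
            z_lo, z_hi = z_lo - 1.0, z_hi + 1.0
        cfg = replace(cfg, z_range=(z_lo, z_hi))
    log["z_range"] = cfg.z_range
    two_step = cluster_two_step(filtered, cfg)
    log["n_step1_clusters"] = int(np.max(two_step.step1_labels, initial=-1) + 1)
    log["n_step2_clusters"] = len(two_step.clusters)
    fluors = fit_fluorophores(two_step, cfg)
    log["n_fluorophores"] = len(fluors)
    trimers = identify_trimers(fluors, cfg, nn_variant=nn_variant)
    log["n_trimers"] = len(trimers)
    return trimers, log
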