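"""iPALM branch: rendering, particle segmentation and super-particle fusion.

This branch emulates the camera-based workflow: localizations are rendered
to a 2D count image at 3 nm per pixel, candidate triple-labelled particles
are segmented with a difference-of-Gaussians bandpass plus local-maximum
peak finding (Crocker-Grier style, centroid-refined), nearest-neighbour
rules (each peak exactly two neighbours at 9-60 nm; every peak more than
60 nm from any non-member localization), a 30 nm peak-to-localization
assignment radius and a 75 nm 3D prune.  Segmented particles are fused
into a single super-particle by a correspondence-based rigid alignment
with threefold symmetry promotion (each aligned particle is rotated by a
seeded random integer multiple of 120 degrees before pooling).

State-of-the-art particle-fusion workflows use all-to-all registration with a
scale sweep and Lie-algebra consistency checks; that algorithm is NOT
re-implemented here.  Because segmentation already yields three matched
blade clusters per particle, a correspondence-based rigid alignment (plane
alignment + in-plane Procrustes over the three cyclic blade
correspondences, against the first particle as reference) substitutes for
it.  This is the largest declared deviation of the package; see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians, threshold_otsu
from sklearn.cluster import KMeans
from sklearn.neighbors import KernelDensity

from .errors import PipelineError, SceneError  # noqa: F401  (SceneError re-export safety)

__all__ = [
    "IpalmConfig",
    "RenderedImage",
    "Particle",
    "SuperParticle",
    "render_projection",
    "segment_particles",
    "fuse_superparticle",
    "kde_local_density",
    "otsu_density_threshold",
    "min_enclosing_density_threshold",
    "cluster_blades",
    "per_localization_interblade",
    "run_ipalm",
    "write_pgm",
]


@dataclass(frozen=True)
class IpalmConfig:
    """Parameters of the iPALM segmentation/fusion branch."""

    pixel_size: float = 3.0  # nm per pixel
    dog_low_sigma: float = 1.0  # px
    dog_high_sigma: float = 3.0  # px
    peak_threshold: float = 0.1  # bandpass amplitude
    peak_min_distance_px: int = 2
    peak_merge_radius: float = 9.0  # nm; peaks below the NN floor are one emitter
    centroid_window_px: int = 5
    nn_min: float = 9.0  # nm, exclusive
    nn_max: float = 60.0  # nm, exclusive
    isolation: float = 60.0  # nm
    assign_radius: float = 30.0  # nm, peak -> localization (2D)
    z_prune: float = 75.0  # nm, 3D distance from particle mean
    kde_bandwidth: float = 2.5  # nm
    max_uncertainty: float | None = None  # optional per-axis sigma filter, nm


@dataclass(frozen=True)
class RenderedImage:
    """2D localization count histogram."""

    counts: np.ndarray  # (ny, nx) int, row = y bin
    pixel_size: float  # nm
    origin: tuple[float, float]  # nm coordinate of the (0, 0) pixel corner


@dataclass(frozen=True)
class Particle:
    """One segmented candidate triple-labelled particle."""

    indices: np.ndarray  # positional row indices into the source table
    coords: np.ndarray  # (n, 3) nm, pruned member localizations
    blade_of: np.ndarray  # (n,) in {0, 1, 2}, nearest-peak assignment
    peaks_xy: np.ndarray  # (3, 2) nm, refined peak positions
    centroids: np.ndarray  # (3, 3) nm, 3D blade centroids


@dataclass(frozen=True)
class SuperParticle:
    """Pooled, aligned localizations from many particles."""

    coords: np.ndarray  # (n, 3) nm
    particle_ids: np.ndarray  # (n,) particle of origin
    density: np.ndarray | None = None  # per-localization KDE density
    blade_labels: np.ndarray | None = None  # (n,) in {0, 1, 2}


def render_projection(table: pd.DataFrame, pixel_size: float = 3.0) -> RenderedImage:
    """Summed z-projection of localizations as a 2D count histogram.

    Bins are half-open ``[origin + i*px, origin + (i+1)*px)``: a
    localization exactly on an interior bin boundary goes to the higher
    bin.  The grid sum equals the number of localizations.
    """
    if len(table) == 0:
        raise ValueError("cannot render an empty table")
    x = table["x_nm"].to_numpy(dtype=float)
    y = table["y_nm"].to_numpy(dtype=float)
    x0 = np.floor(x.min() / pixel_size) * pixel_size
    y0 = np.floor(y.min() / pixel_size) * pixel_size
    nx = int(np.floor((x.max() - x0) / pixel_size)) + 1
    ny = int(np.floor((y.max() - y0) / pixel_size)) + 1
    ix = np.floor((x - x0) / pixel_size).astype(int)
    iy = np.floor((y - y0) / pixel_size).astype(int)
    counts = np.zeros((ny, nx), dtype=np.int64)
    np.add.at(counts, (iy, ix), 1)
    return RenderedImage(counts=counts, pixel_size=pixel_size, origin=(float(x0), float(y0)))


def _refine_peaks(image: RenderedImage, peaks_px: np.ndarray, window: int) -> np.ndarray:
    """Centroid-refine integer peak locations on the raw count image.

    Returns (n, 2) nm coordinates (x, y) at pixel centres.
    """
    half = window // 2
    counts = image.counts
    refined = np.empty((len(peaks_px), 2))
    for i, (row, col) in enumerate(peaks_px):
        r0, r1 = max(0, row - half), min(counts.shape[0], row + half + 1)
        c0, c1 = max(0, col - half), min(counts.shape[1], col + half + 1)
        patch = counts[r0:r1, c0:c1].astype(float)
        total = patch.sum()
        if total == 0:
            com_r, com_c = float(row), float(col)
        else:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            com_r = float((rr * patch).sum() / total)
            com_c = float((cc * patch).sum() / total)
        refined[i, 0] = image.origin[0] + (com_c + 0.5) * image.pixel_size
        refined[i, 1] = image.origin[1] + (com_r + 0.5) * image.pixel_size
    return refined


def _consolidate_peaks(
    peaks_nm: np.ndarray, amplitudes: np.ndarray, merge_radius: float
) -> np.ndarray:
    """Average-linkage merge of peaks closer than the neighbour floor."""
    if len(peaks_nm) < 2 or merge_radius <= 0:
        return peaks_nm
    labels = hierarchy.fcluster(
        hierarchy.linkage(peaks_nm, method="average"),
        t=merge_radius,
        criterion="distance",
    )
    out = []
    for label in np.unique(labels):
        sel = labels == label
        out.append(np.average(peaks_nm[sel], axis=0, weights=amplitudes[sel]))
    return np.stack(out)


def segment_particles(
    image: RenderedImage,
    table: pd.DataFrame,
    cfg: IpalmConfig | None = None,
) -> list[Particle]:
    """Segment candidate triple-labelled particles from a rendered field.

    Bandpass (difference of Gaussians) then local-maximum peak finding
    with centroid refinement.  Detection runs at a fine scale, which may
    split one sparse fluorophore cloud into several maxima, so peaks
    closer than ``peak_merge_radius`` (the neighbour-window floor — two
    distinct fluorophores can never be retained that close) are
    consolidated by average-linkage into amplitude-weighted positions.
    Then retain peak triples where each peak has exactly two neighbours at
    (nn_min, nn_max) nm and all three peaks are more than ``isolation`` nm
    (2D) from every localization that is not a member; members are
    localizations within ``assign_radius`` (2D) of any of the three peaks;
    finally localizations more than ``z_prune`` nm (3D) from the particle
    mean are removed.  An empty result is allowed.
    """
    cfg = cfg or IpalmConfig()
    if cfg.max_uncertainty is not None and {
        "sigma_x_nm",
        "sigma_y_nm",
        "sigma_z_nm",
    } <= set(table.columns):
        keep = (
            (table["sigma_x_nm"] <= cfg.max_uncertainty)
            & (table["sigma_y_nm"] <= cfg.max_uncertainty)
            & (table["sigma_z_nm"] <= cfg.max_uncertainty)
        )
        table = table[keep]
    coords = table[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    if len(coords) == 0:
        return []

    bandpassed = difference_of_gaussians(
        image.counts.astype(np.float32), cfg.dog_low_sigma, cfg.dog_high_sigma
    )
    peaks_px = peak_local_max(
        bandpassed,
        min_distance=cfg.peak_min_distance_px,
        threshold_abs=cfg.peak_threshold,
    )
    if len(peaks_px) < 3:
        return []
    peaks_nm = _refine_peaks(image, peaks_px, cfg.centroid_window_px)
    amplitudes = bandpassed[peaks_px[:, 0], peaks_px[:, 1]].astype(float)
    peaks_nm = _consolidate_peaks(peaks_nm, amplitudes, cfg.peak_merge_radius)
    if len(peaks_nm) < 3:
        return []

    peak_tree = cKDTree(peaks_nm)
    loc_tree = cKDTree(coords[:, :2])

    # exactly-two-neighbours rule at (nn_min, nn_max), exclusive bounds
    neighbour_sets: list[frozenset[int]] = []
    for i, p in enumerate(peaks_nm):
        near = peak_tree.query_ball_point(p, cfg.nn_max)
        ns = frozenset(
            j
            for j in near
            if j != i and cfg.nn_min < np.linalg.norm(peaks_nm[j] - p) < cfg.nn_max
        )
        neighbour_sets.append(ns)

    particles: list[Particle] = []
    seen: set[frozenset[int]] = set()
    for i, ns in enumerate(neighbour_sets):
        if len(ns) != 2:
            continue
        j, k = sorted(ns)
        triple = frozenset((i, j, k))
        if triple in seen:
            continue
        if neighbour_sets[j] != frozenset((i, k)) or neighbour_sets[k] != frozenset((i, j)):
            continue
        seen.add(triple)
        trio = sorted(triple)
        trio_peaks = peaks_nm[trio]

        member_idx: set[int] = set()
        for p in trio_peaks:
            member_idx.update(loc_tree.query_ball_point(p, cfg.assign_radius))
        isolated = True
        for p in trio_peaks:
            for idx in loc_tree.query_ball_point(p, cfg.isolation):
                if idx not in member_idx:
                    isolated = False
                    break
            if not isolated:
                break
        if not isolated or not member_idx:
            continue

        idx = np.array(sorted(member_idx))
        pts = coords[idx]
        centre = pts.mean(axis=0)
        keep = np.linalg.norm(pts - centre, axis=1) <= cfg.z_prune
        idx, pts = idx[keep], pts[keep]
        if idx.size == 0:
            continue
        blade = np.argmin(
            np.linalg.norm(pts[:, None, :2] - trio_peaks[None, :, :], axis=2), axis=1
        )
        if len(np.unique(blade)) != 3:
            continue
        centroids = np.stack([pts[blade == b].mean(axis=0) for b in range(3)])
        particles.append(
            Particle(
                indices=idx,
                coords=pts,
                blade_of=blade,
                peaks_xy=trio_peaks,
                centroids=centroids,
            )
        )
    return particles


def _rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """Rotation matrix taking ``normal`` to +z."""
    n = normal / np.linalg.norm(normal)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(n, z)
    s = np.linalg.norm(v)
    c = float(n @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


_FLIP_X = np.diag([1.0, -1.0, -1.0])  # 180 deg rotation about x


def _inplane_angle(source: np.ndarray, target: np.ndarray) -> float:
    """Rotation angle (about z) minimizing SSD between matched 2D point sets."""
    num = float(np.sum(source[:, 0] * target[:, 1] - source[:, 1] * target[:, 0]))
    den = float(np.sum(source[:, 0] * target[:, 0] + source[:, 1] * target[:, 1]))
    return float(np.arctan2(num, den))


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def fuse_superparticle(
    particles: list[Particle], symmetry: int = 3, seed: int = 0
) -> SuperParticle:
    """Fuse segmented particles into a symmetry-promoted super-particle.

    Each particle is translated so its blade-centroid mean is at the
    origin, rotated so the plane of its three blade centroids lies in x-y
    (both plane orientations are tried), in-plane rotated to best match
    the reference triangle (the first particle's aligned centroids) over
    the three cyclic blade correspondences, and finally rotated by a
    seeded random integer multiple of 2*pi/symmetry before pooling.

    Raises
    ------
    ValueError
        If fewer than two usable particles are supplied.
    """
    rng = np.random.default_rng(seed)
    usable = [p for p in particles if p.centroids.shape == (3, 3)]
    if len(usable) < 2:
        raise ValueError(f"fusion needs >= 2 particles with 3 blade clusters, got {len(usable)}")

    reference: np.ndarray | None = None
    pooled: list[np.ndarray] = []
    ids: list[np.ndarray] = []
    for pid, particle in enumerate(usable):
        origin = particle.centroids.mean(axis=0)
        cent = particle.centroids - origin
        normal = np.cross(cent[1] - cent[0], cent[2] - cent[0])
        if np.linalg.norm(normal) < 1e-12:
            continue
        base = _rotation_to_z(normal)
        if reference is None:
            rot = base
            reference = (base @ cent.T).T[:, :2]
        else:
            best: tuple[float, np.ndarray] | None = None
            for flip in (np.eye(3), _FLIP_X):
                cand = (flip @ base @ cent.T).T
                for shift in range(3):
                    target = np.roll(reference, -shift, axis=0)
                    ang = _inplane_angle(cand[:, :2], target)
                    aligned = (_rot_z(ang) @ cand.T).T
                    ssd = float(np.sum((aligned[:, :2] - target) ** 2))
                    if best is None or ssd < best[0]:
                        best = (ssd, _rot_z(ang) @ flip @ base)
            rot = best[1]  # type: ignore[index]
        k = int(rng.integers(symmetry))
        rot = _rot_z(2.0 * np.pi * k / symmetry) @ rot
        pooled.append((rot @ (particle.coords - origin).T).T)
        ids.append(np.full(len(particle.coords), pid))
    return SuperParticle(coords=np.vstack(pooled), particle_ids=np.concatenate(ids))


def kde_local_density(coords: np.ndarray, bandwidth: float = 2.5) -> np.ndarray:
    """Per-localization Gaussian kernel density over a pooled 3D set (nm^-3)."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 0:
        raise ValueError("empty pooled set")
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth).fit(coords)
    return np.exp(kde.score_samples(coords))


def otsu_density_threshold(density: np.ndarray) -> float:
    """Otsu threshold on the local-density distribution."""
    return float(threshold_otsu(np.asarray(density, dtype=float)))


def min_enclosing_density_threshold(
    coords: np.ndarray, density: np.ndarray, radius: float = 60.0
) -> float:
    """Smallest density threshold confining kept localizations to a sphere.

    Returns the minimum threshold such that every localization above it
    lies within ``radius`` of the super-particle origin — the data-driven
    rule used to isolate the blade cores.
    """
    r = np.linalg.norm(np.asarray(coords, dtype=float), axis=1)
    outside = np.asarray(density)[r > radius]
    if outside.size == 0:
        return 0.0
    return float(outside.max() * (1.0 + 1e-12))


def cluster_blades(coords: np.ndarray, k: int = 3, seed: int = 0, n_restarts: int = 10) -> np.ndarray:
    """k-means blade labels (k = 3) with seeded restarts, best inertia kept."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < k:
        raise ValueError(f"need at least {k} localizations, got {len(coords)}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed) % (2**31))
    return km.fit_predict(coords)


def per_localization_interblade(
    coords: np.ndarray,
    blade_labels: np.ndarray,
    both_neighbours: bool = False,
) -> np.ndarray:
    """Average distance from each localization to a neighbouring blade.

    Blades are put in a fixed cyclic order by the azimuth of their
    centroids about the pooled centre; each localization is averaged
    against all localizations of the next blade in that order (or against
    both other blades if ``both_neighbours``).

    Raises
    ------
    PipelineError
        If fewer than three blades are populated.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(blade_labels)
    present = np.unique(labels)
    if present.size != 3:
        raise PipelineError(f"need exactly 3 populated blades, got {present.size}")
    centre = coords.mean(axis=0)
    centroids = np.stack([coords[labels == b].mean(axis=0) for b in present])
    azimuth = np.arctan2(centroids[:, 1] - centre[1], centroids[:, 0] - centre[0])
    order = present[np.argsort(azimuth)]  # cyclic order
    rank = {int(b): r for r, b in enumerate(order)}

    out = np.empty(len(coords))
    for b in present:
        mask = labels == b
        r = rank[int(b)]
        neighbours = [order[(r + 1) % 3]]
        if both_neighbours:
            neighbours.append(order[(r + 2) % 3])
        targets = coords[np.isin(labels, neighbours)]
        source = coords[mask]
        means = np.empty(len(source))
        chunk = max(1, 2_000_000 // max(1, len(targets)))  # bound peak memory
        for start in range(0, len(source), chunk):
            means[start : start + chunk] = cdist(
                source[start : start + chunk], targets
            ).mean(axis=1)
        out[mask] = means
    return out


def run_ipalm(
    table: pd.DataFrame,
    cfg: IpalmConfig | None = None,
    seed: int = 0,
    density_threshold: str | float = "otsu",
    both_neighbours: bool = False,
) -> dict:
    """Full iPALM branch: render -> segment -> fuse -> threshold -> blades.

    ``density_threshold`` is ``"otsu"``, ``"enclosing"`` (60 nm sphere
    rule) or an absolute density.  Returns a dict with the rendered image,
    particles, super-particle (with density and blade labels on the
    thresholded subset) and the per-localization interblade distance
    sample.
    """
    cfg = cfg or IpalmConfig()
    image = render_projection(table, cfg.pixel_size)
    particles = segment_particles(image, table, cfg)
    sp = fuse_superparticle(particles, symmetry=3, seed=seed)
    density = kde_local_density(sp.coords, cfg.kde_bandwidth)
    if density_threshold == "otsu":
        thr = otsu_density_threshold(density)
    elif density_threshold == "enclosing":
        thr = min_enclosing_density_threshold(sp.coords, density)
    else:
        thr = float(density_threshold)
    keep = density >= thr
    kept = sp.coords[keep]
    labels = cluster_blades(kept, k=3, seed=seed)
    distances = per_localization_interblade(kept, labels, both_neighbours=both_neighbours)
    return {
        "image": image,
        "particles": particles,
        "superparticle": SuperParticle(
            coords=kept,
            particle_ids=sp.particle_ids[keep],
            density=density[keep],
            blade_labels=labels,
        ),
        "density_threshold": thr,
        "interblade_distances": distances,
        "log": {
            "n_localizations": int(len(table)),
            "n_particles": len(particles),
            "n_pooled": int(len(sp.coords)),
            "n_thresholded": int(keep.sum()),
        },
    }


def write_pgm(image: RenderedImage, path) -> None:
    """Dump a rendered image as 16-bit portable graymap (plain text P2)."""
    counts = np.clip(image.counts, 0, 65535)
    with open(path, "w") as fh:
        fh.write(f"P2\n{counts.shape[1]} {counts.shape[0]}\n65535\n")
        for row in counts:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
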