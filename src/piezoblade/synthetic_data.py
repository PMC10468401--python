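"""Ground-truth trimer fields and synthetic localization datasets.

This module generates fields of C3-symmetric trimeric molecules (three
"blade-tip" fluorophores per molecule) together with the blinking-trace
localization data an SMLM instrument would record from them.  The
conformational spread of each molecule is controlled by three independent
per-blade noise terms — radial, azimuthal and out-of-plane — and the
generator can be *calibrated* so that the ground-truth per-molecule mean
pairwise tip distance matches a requested mean and standard deviation.

Model
-----
Tip ``k`` of a molecule sits at polar coordinates::

    r_k     ~ Normal(mu_radius, sigma_radius)
    theta_k = phi + 120 deg * k + Normal(0, sigma_theta)
    z_k     ~ Normal(0, sigma_z)

where ``phi`` is a per-molecule uniform in-plane rotation.  Blades are
independent of each other; correlated conformational models are out of
scope.

Randomness
----------
Every public operation takes a single integer ``seed``.  Internally a
``numpy.random.SeedSequence`` spawns one child stream per stage, in a fixed
documented order (see each function), so partial re-runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import CalibrationError, SceneError

__all__ = [
    "GeometryParams",
    "EmissionParams",
    "MoleculeTruth",
    "GroundTruthScene",
    "calibrate_geometry",
    "generate_scene",
    "emit_localizations",
    "mean_pairwise_tip_distance",
]

#: Nominal blade azimuths of a C3-symmetric trimer (radians).
_BASE_AZIMUTH = np.array([0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0])

#: Half-width (nm) of the uniform z band in which background traces and
#: streaks are placed.  Signal molecules sit in the z = 0 membrane plane.
_BACKGROUND_Z_HALFWIDTH = 40.0

#: Mean number of localizations in a linear streak artefact.
_STREAK_LOCS_MEAN = 20.0


@dataclass(frozen=True)
class GeometryParams:
    """Conformational-spread parameters of a trimer population.

    Parameters
    ----------
    mu_radius : float
        Mean blade-tip radius from the molecule centre (nm).
    sigma_radius : float
        Per-blade radial standard deviation (nm) — the flexibility knob.
    sigma_theta : float
        Per-blade azimuthal jitter about the nominal 0/120/240 degree
        positions (degrees).
    sigma_z : float
        Per-tip out-of-plane standard deviation (nm).
    """

    mu_radius: float
    sigma_radius: float = 0.0
    sigma_theta: float = 8.0
    sigma_z: float = 4.0

    def __post_init__(self) -> None:
        if not self.mu_radius > 0:
            raise ValueError("mu_radius must be > 0")
        for name in ("sigma_radius", "sigma_theta", "sigma_z"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class EmissionParams:
    """Blinking-trace emission model.

    ``sigma_loc`` is the per-axis Gaussian localization error in nm; the
    default of 6 nm matches the median per-axis fluorophore localization
    error of 3D MINFLUX data.  Trace and localization counts are Poisson
    with a minimum of one.  Background traces are isolated fluorophore-like
    localization clouds at uniform positions; streaks are collinear
    localization runs emulating molecules diffusing through the focal
    plane.
    """

    sigma_loc: float = 6.0
    traces_per_fluor_mean: float = 6.0
    locs_per_trace_mean: float = 20.0
    p_label: float = 0.8
    background_trace_density: float = 1.0  # traces per um^2
    streak_density: float = 0.2  # streaks per um^2
    streak_length: float = 300.0  # nm

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_label <= 1.0:
            raise ValueError("p_label must be in [0, 1]")
        for name in (
            "sigma_loc",
            "traces_per_fluor_mean",
            "locs_per_trace_mean",
            "background_trace_density",
            "streak_density",
            "streak_length",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class MoleculeTruth:
    """Ground truth for one trimeric molecule."""

    centre: np.ndarray  # (3,) nm
    tips: np.ndarray  # (3, 3) nm
    labelled: np.ndarray  # (3,) bool
    true_mean_pairwise: float  # nm

    @property
    def fully_labelled(self) -> bool:
        return bool(np.all(self.labelled))


@dataclass(frozen=True)
class GroundTruthScene:
    """A simulated field of trimeric molecules."""

    molecules: list[MoleculeTruth]
    field_extent: tuple[float, float]  # (Lx, Ly) nm
    seed: int
    geometry: GeometryParams | None = field(default=None, compare=False)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)


def _tip_offsets(
    mu_radius: float,
    sigma_radius: float,
    sigma_theta_deg: float,
    sigma_z: float,
    phi: np.ndarray,
    z_r: np.ndarray,
    z_t: np.ndarray,
    z_z: np.ndarray,
) -> np.ndarray:
    """Tip coordinates relative to the molecule centre.

    ``phi`` has shape (n,), the z_* standard-normal draws (n, 3).
    Returns (n, 3, 3): molecule, tip, xyz.
    """
    r = mu_radius + sigma_radius * z_r
    theta = phi[:, None] + _BASE_AZIMUTH[None, :] + np.deg2rad(sigma_theta_deg) * z_t
    return np.stack(
        [r * np.cos(theta), r * np.sin(theta), sigma_z * z_z], axis=-1
    )


def mean_pairwise_tip_distance(tips: np.ndarray) -> np.ndarray:
    """Mean of the three pairwise tip distances, per molecule.

    ``tips`` has shape (..., 3, 3) (molecule, tip, xyz).
    """
    d01 = np.linalg.norm(tips[..., 0, :] - tips[..., 1, :], axis=-1)
    d02 = np.linalg.norm(tips[..., 0, :] - tips[..., 2, :], axis=-1)
    d12 = np.linalg.norm(tips[..., 1, :] - tips[..., 2, :], axis=-1)
    return (d01 + d02 + d12) / 3.0


def _forward_mean_sd(
    mu_radius: float,
    sigma_radius: float,
    sigma_theta: float,
    sigma_z: float,
    z_r: np.ndarray,
    z_t: np.ndarray,
    z_z: np.ndarray,
) -> tuple[float, float]:
    phi = np.zeros(z_r.shape[0])  # rotation-invariant statistic
    tips = _tip_offsets(mu_radius, sigma_radius, sigma_theta, sigma_z, phi, z_r, z_t, z_z)
    dbar = mean_pairwise_tip_distance(tips)
    return float(dbar.mean()), float(dbar.std(ddof=1))


def calibrate_geometry(
    target_mean_d: float,
    target_sd_d: float,
    sigma_theta: float = 8.0,
    sigma_z: float = 4.0,
    n_mc: int = 100_000,
    seed: int = 0,
    tol: float = 0.01,
) -> GeometryParams:
    """Solve for (mu_radius, sigma_radius) matching a distance mean/s.d.

    Inverts the generative model by Monte-Carlo forward simulation with
    common random numbers: a fixed block of ``n_mc`` standard-normal draws
    makes the objective smooth and the result deterministic for a fixed
    ``seed``.  Only the radial parameters are solved; ``sigma_theta`` and
    ``sigma_z`` are held fixed because a distance mean/s.d. pair cannot
    identify more than two parameters.

    Raises
    ------
    CalibrationError
        If the forward simulation at the solution misses either target by
        more than ``tol`` (relative; the s.d. residual is measured against
        ``max(target_sd_d, 0.02 * target_mean_d)`` so a zero target stays
        well defined).
    """
    if not target_mean_d > 0:
        raise ValueError("target_mean_d must be > 0")
    if target_sd_d < 0:
        raise ValueError("target_sd_d must be >= 0")
    if n_mc < 10_000:
        raise ValueError("n_mc must be >= 10^4 for a stable calibration")

    rng = np.random.default_rng(seed)
    z_r = rng.standard_normal((n_mc, 3))
    z_t = rng.standard_normal((n_mc, 3))
    z_z = rng.standard_normal((n_mc, 3))

    sd_scale = max(target_sd_d, 0.02 * target_mean_d)

    def residuals(p: np.ndarray) -> np.ndarray:
        m, s = _forward_mean_sd(p[0], p[1], sigma_theta, sigma_z, z_r, z_t, z_z)
        return np.array(
            [(m - target_mean_d) / target_mean_d, (s - target_sd_d) / sd_scale]
        )

    x0 = np.array([target_mean_d / np.sqrt(3.0), max(target_sd_d * 0.9, 0.0)])
    result = least_squares(
        residuals,
        x0,
        bounds=([1e-6, 0.0], [np.inf, np.inf]),
        diff_step=1e-4,
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=300,
    )
    mu_radius, sigma_radius = result.x
    m, s = _forward_mean_sd(mu_radius, sigma_radius, sigma_theta, sigma_z, z_r, z_t, z_z)
    rel_mean = abs(m - target_mean_d) / target_mean_d
    rel_sd = abs(s - target_sd_d) / sd_scale
    if max(rel_mean, rel_sd) > tol:
        raise CalibrationError(
            "calibration did not reach targets: "
            f"achieved mean {m:.3f} nm (target {target_mean_d}, residual "
            f"{rel_mean:.2%}), s.d. {s:.3f} nm (target {target_sd_d}, "
            f"residual {rel_sd:.2%} of scale {sd_scale:.3f})"
        )
    return GeometryParams(
        mu_radius=float(mu_radius),
        sigma_radius=float(sigma_radius),
        sigma_theta=sigma_theta,
        sigma_z=sigma_z,
    )


def generate_scene(
    geometry: GeometryParams,
    n_molecules: int,
    field_extent: tuple[float, float] | None = None,
    min_separation: float = 150.0,
    p_label: float = 0.8,
    seed: int = 0,
) -> GroundTruthScene:
    """Place trimeric molecules in a field and realize their tip geometry.

    Molecule centres are drawn uniformly with rejection sampling until all
    pairwise separations exceed ``min_separation``.  If ``field_extent`` is
    None, a square field is sized for two molecules per square micron.
    Stream order: placement, geometry (rotations then radial/azimuthal/z
    draws), labelling.

    Raises
    ------
    SceneError
        If placement fails after a bounded number of rejections.
    """
    if not min_separation > 0:
        raise SceneError("min_separation must be > 0")
    if n_molecules < 1:
        raise SceneError("n_molecules must be >= 1")
    if field_extent is None:
        side = float(np.sqrt(n_molecules / 2.0) * 1000.0)  # 2 molecules / um^2
        field_extent = (side, side)
    lx, ly = field_extent
    if lx <= 0 or ly <= 0:
        raise SceneError("field_extent must be positive")

    ss = np.random.SeedSequence(seed)
    r_place, r_geom, r_label = (np.random.default_rng(c) for c in ss.spawn(3))

    centres = np.empty((n_molecules, 2))
    n_placed = 0
    max_attempts = 2000 * n_molecules
    attempts = 0
    min_sep2 = min_separation**2
    while n_placed < n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise SceneError(
                f"placed only {n_placed}/{n_molecules} molecules after "
                f"{max_attempts} attempts; field {lx:.0f} x {ly:.0f} nm is too "
                f"small for min_separation {min_separation} nm"
            )
        cand = r_place.uniform((0.0, 0.0), (lx, ly))
        if n_placed and np.min(
            np.sum((centres[:n_placed] - cand) ** 2, axis=1)
        ) < min_sep2:
            continue
        centres[n_placed] = cand
        n_placed += 1

    phi = r_geom.uniform(0.0, 2.0 * np.pi, n_molecules)
    z_r = r_geom.standard_normal((n_molecules, 3))
    z_t = r_geom.standard_normal((n_molecules, 3))
    z_z = r_geom.standard_normal((n_molecules, 3))
    offsets = _tip_offsets(
        geometry.mu_radius,
        geometry.sigma_radius,
        geometry.sigma_theta,
        geometry.sigma_z,
        phi,
        z_r,
        z_t,
        z_z,
    )
    labelled = r_label.random((n_molecules, 3)) < p_label

    molecules = []
    for i in range(n_molecules):
        centre = np.array([centres[i, 0], centres[i, 1], 0.0])
        tips = centre[None, :] + offsets[i]
        molecules.append(
            MoleculeTruth(
                centre=centre,
                tips=tips,
                labelled=labelled[i],
                true_mean_pairwise=float(mean_pairwise_tip_distance(tips[None])[0]),
            )
        )
    return GroundTruthScene(
        molecules=molecules, field_extent=(lx, ly), seed=seed, geometry=geometry
    )


def emit_localizations(
    scene: GroundTruthScene,
    emission: EmissionParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit blinking-trace localizations for a scene.

    For each labelled tip, ``max(1, Poisson(traces_per_fluor_mean))`` traces
    are drawn, each with ``max(1, Poisson(locs_per_trace_mean))``
    localizations at the tip plus independent per-axis
    ``Normal(0, sigma_loc)`` error.  Background traces (isolated clouds at
    uniform positions) and linear streaks are appended.  Every row carries a
    unique ``trace_id`` and its generating ``truth_id`` (``m<i>`` or
    ``"background"``).  Stream order: signal, background, streaks.

    Returns a localization table with columns
    ``trace_id, x_nm, y_nm, z_nm, truth_id``.
    """
    ss = np.random.SeedSequence(seed)
    r_sig, r_bg, r_st = (np.random.default_rng(c) for c in ss.spawn(3))
    lx, ly = scene.field_extent
    area_um2 = lx * ly / 1e6

    coords: list[np.ndarray] = []
    trace_ids: list[str] = []
    truth_ids: list[str] = []

    def _append(points: np.ndarray, trace: str, truth: str) -> None:
        coords.append(points)
        trace_ids.extend([trace] * len(points))
        truth_ids.extend([truth] * len(points))

    for i, mol in enumerate(scene.molecules):
        truth = f"m{i:04d}"
        for k in range(3):
            if not mol.labelled[k]:
                continue
            n_traces = max(1, int(r_sig.poisson(emission.traces_per_fluor_mean)))
            for j in range(n_traces):
                n_locs = max(1, int(r_sig.poisson(emission.locs_per_trace_mean)))
                pts = mol.tips[k][None, :] + emission.sigma_loc * r_sig.standard_normal(
                    (n_locs, 3)
                )
                _append(pts, f"m{i:04d}f{k}t{j:03d}", truth)

    n_bg = int(r_bg.poisson(emission.background_trace_density * area_um2))
    for b in range(n_bg):
        pos = np.array(
            [
                r_bg.uniform(0.0, lx),
                r_bg.uniform(0.0, ly),
                r_bg.uniform(-_BACKGROUND_Z_HALFWIDTH, _BACKGROUND_Z_HALFWIDTH),
            ]
        )
        n_locs = max(1, int(r_bg.poisson(emission.locs_per_trace_mean)))
        pts = pos[None, :] + emission.sigma_loc * r_bg.standard_normal((n_locs, 3))
        _append(pts, f"bg{b:04d}", "background")

    n_streaks = int(r_st.poisson(emission.streak_density * area_um2))
    for s in range(n_streaks):
        start = np.array(
            [
                r_st.uniform(0.0, lx),
                r_st.uniform(0.0, ly),
                r_st.uniform(-_BACKGROUND_Z_HALFWIDTH, _BACKGROUND_Z_HALFWIDTH),
            ]
        )
        direction = r_st.standard_normal(3)
        direction /= np.linalg.norm(direction)
        n_locs = max(2, int(r_st.poisson(_STREAK_LOCS_MEAN)))
        t = np.sort(r_st.uniform(0.0, 1.0, n_locs))
        pts = (
            start[None, :]
            + (t[:, None] - 0.5) * emission.streak_length * direction[None, :]
            + emission.sigma_loc * r_st.standard_normal((n_locs, 3))
        )
        _append(pts, f"st{s:04d}", "background")

    if coords:
        xyz = np.vstack(coords)
    else:  # no labelled tips and no background
        xyz = np.empty((0, 3))
    return pd.DataFrame(
        {
            "trace_id": pd.array(trace_ids, dtype="str"),
            "x_nm": xyz[:, 0],
            "y_nm": xyz[:, 1],
            "z_nm": xyz[:, 2],
            "truth_id": pd.array(truth_ids, dtype="str"),
        }
    )
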