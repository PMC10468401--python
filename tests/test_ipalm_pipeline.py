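"""Rendering, segmentation, symmetry-promoted fusion and blade statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from piezoblade.errors import PipelineError
from piezoblade.ipalm_pipeline import (
    IpalmConfig,
    Particle,
    cluster_blades,
    fuse_superparticle,
    kde_local_density,
    per_localization_interblade,
    render_projection,
    segment_particles,
    write_pgm,
)


def table_from_coords(coords):
    coords = np.asarray(coords, dtype=float)
    return pd.DataFrame(
        {
            "trace_id": [f"t{i}" for i in range(len(coords))],
            "x_nm": coords[:, 0],
            "y_nm": coords[:, 1],
            "z_nm": coords[:, 2],
        }
    )


def triangle_blob_table(rng, side=25.0, n_per_blade=40, sigma=3.0, offset=(300.0, 300.0)):
    tips = np.array(
        [[0, 0, 0], [side, 0, 0], [side / 2, side * np.sqrt(3) / 2, 0]], dtype=float
    )
    tips[:, 0] += offset[0]
    tips[:, 1] += offset[1]
    pts = np.vstack([t + sigma * rng.standard_normal((n_per_blade, 3)) for t in tips])
    return table_from_coords(pts), tips


def synthetic_particle(rng, side=25.4, nloc=30, sigma=6.0, transform=True):
    r = side / np.sqrt(3)
    tips = np.array(
        [[r * np.cos(a), r * np.sin(a), 0.0] for a in (0, 2 * np.pi / 3, 4 * np.pi / 3)]
    )
    pts, blade = [], []
    for k in range(3):
        pts.append(tips[k] + sigma * rng.standard_normal((nloc, 3)))
        blade += [k] * nloc
    pts = np.vstack(pts)
    blade = np.array(blade)
    if transform:
        rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
        shift = rng.uniform(0, 5000, 3)
        pts = pts @ rot.T + shift
    cents = np.stack([pts[blade == k].mean(axis=0) for k in range(3)])
    return Particle(
        indices=np.arange(len(pts)),
        coords=pts,
        blade_of=blade,
        peaks_xy=cents[:, :2],
        centroids=cents,
    )


class TestRenderProjection:
    def test_single_localization_single_pixel(self):
        img = render_projection(table_from_coords([[10.0, 20.0, 5.0]]))
        assert img.counts.sum() == 1
        assert (img.counts == 1).sum() == 1

    def test_count_conservation(self, rng):
        coords = rng.uniform(0, 1000, size=(5000, 3))
        img = render_projection(table_from_coords(coords))
        assert img.counts.sum() == 5000

    def test_boundary_goes_to_higher_bin(self):
        # origin at 0; a point exactly on the 3 nm boundary joins pixel 1
        img = render_projection(table_from_coords([[0.5, 0.5, 0], [3.0, 0.5, 0]]))
        assert img.origin == (0.0, 0.0)
        assert img.counts[0, 0] == 1 and img.counts[0, 1] == 1

    def test_pgm_dump(self, tmp_path, rng):
        img = render_projection(table_from_coords(rng.uniform(0, 100, (50, 3))))
        path = tmp_path / "img.pgm"
        write_pgm(img, path)
        header = path.read_text().splitlines()
        assert header[0] == "P2"
        body = np.array(" ".join(header[3:]).split(), dtype=int)
        assert body.sum() == 50


class TestSegmentParticles:
    def test_isolated_triangle_segmented_whole(self, rng):
        table, tips = triangle_blob_table(rng)
        img = render_projection(table)
        particles = segment_particles(img, table)
        assert len(particles) == 1
        assert len(particles[0].coords) == len(table)
        peak_err = [
            min(np.linalg.norm(p - t[:2]) for t in tips)
            for p in particles[0].peaks_xy
        ]
        assert max(peak_err) < 4.0

    def test_wide_spacing_rejected(self, rng):
        table, _ = triangle_blob_table(rng, side=70.0)
        img = render_projection(table)
        assert segment_particles(img, table) == []

    def test_outlier_localization_pruned(self, rng):
        table, tips = triangle_blob_table(rng)
        outlier = tips.mean(axis=0) + np.array([0.0, 0.0, 100.0])
        row = pd.DataFrame(
            {"trace_id": ["out"], "x_nm": [outlier[0]], "y_nm": [outlier[1]], "z_nm": [outlier[2]]}
        )
        full = pd.concat([table, row], ignore_index=True)
        img = render_projection(full)
        particles = segment_particles(img, full)
        assert len(particles) == 1
        assert len(particles[0].coords) == len(table)  # 75 nm 3D prune

    def test_nonisolated_triangle_rejected(self, rng):
        table, tips = triangle_blob_table(rng)
        # 55 nm from one peak (inside the 60 nm isolation radius) but more
        # than the 30 nm assignment radius from every peak
        stray = tips[0] + np.array([-55.0, 0.0, 0.0])
        rows = pd.DataFrame(
            {
                "trace_id": ["s0", "s1"],
                "x_nm": [stray[0]] * 2,
                "y_nm": [stray[1]] * 2,
                "z_nm": [0.0] * 2,
            }
        )
        full = pd.concat([table, rows], ignore_index=True)
        img = render_projection(full)
        assert segment_particles(img, full) == []


class TestFusion:
    def test_rigid_copies_fuse_to_original_spread(self, rng):
        """Copies of one particle under rigid motions fuse losslessly."""
        base = synthetic_particle(rng, transform=False)
        particles = []
        for _ in range(40):
            rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            shift = rng.uniform(0, 2000, 3)
            particles.append(
                Particle(
                    indices=base.indices,
                    coords=base.coords @ rot.T + shift,
                    blade_of=base.blade_of,
                    peaks_xy=base.peaks_xy,
                    centroids=base.centroids @ rot.T + shift,
                )
            )
        sp = fuse_superparticle(particles, seed=3)
        labels = cluster_blades(sp.coords, seed=3)
        spreads = [
            np.linalg.norm(
                sp.coords[labels == k] - sp.coords[labels == k].mean(axis=0), axis=1
            ).mean()
            for k in range(3)
        ]
        base_spread = np.mean(
            [
                np.linalg.norm(
                    base.coords[base.blade_of == k]
                    - base.coords[base.blade_of == k].mean(axis=0),
                    axis=1,
                ).mean()
                for k in range(3)
            ]
        )
        assert np.mean(spreads) == pytest.approx(base_spread, rel=0.10)

    def test_single_particle_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 2"):
            fuse_superparticle([synthetic_particle(rng)], seed=0)

    def test_seeded_fusion_is_deterministic(self, rng):
        particles = [synthetic_particle(rng) for _ in range(10)]
        a = fuse_superparticle(particles, seed=11)
        b = fuse_superparticle(particles, seed=11)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_equivariance_under_global_rigid_motion(self, rng):
        """Transforming every particle identically leaves fused geometry."""
        particles = [synthetic_particle(rng) for _ in range(25)]
        rot = Rotation.from_euler("xyz", [0.3, -0.5, 1.1]).as_matrix()
        shift = np.array([100.0, -50.0, 20.0])
        moved = [
            Particle(
                indices=p.indices,
                coords=p.coords @ rot.T + shift,
                blade_of=p.blade_of,
                peaks_xy=p.peaks_xy,
                centroids=p.centroids @ rot.T + shift,
            )
            for p in particles
        ]
        a = fuse_superparticle(particles, seed=7)
        b = fuse_superparticle(moved, seed=7)
        # rotation-invariant summaries agree
        ra = np.sort(np.linalg.norm(a.coords, axis=1))
        rb = np.sort(np.linalg.norm(b.coords, axis=1))
        np.testing.assert_allclose(ra, rb, atol=1e-6)
        np.testing.assert_allclose(
            np.sort(a.coords[:, 2] ** 2), np.sort(b.coords[:, 2] ** 2), atol=1e-6
        )


class TestDensityAndBlades:
    def test_isolated_point_has_lower_density(self, rng):
        blob = rng.normal(scale=3.0, size=(200, 3))
        coords = np.vstack([blob, [[100.0, 0.0, 0.0]]])
        dens = kde_local_density(coords)
        assert dens[-1] < dens[:-1].min()

    def test_uniform_points_near_equal_density(self, rng):
        coords = rng.uniform(0, 1000, size=(50, 3))  # sparse: self-term dominates
        dens = kde_local_density(coords)
        assert dens.max() / dens.min() < 1.5

    def test_three_clouds_exact_partition(self, rng):
        cents = np.array([[0, 0, 0], [60, 0, 0], [30, 52, 0]], dtype=float)
        coords = np.vstack([c + rng.normal(scale=2.0, size=(50, 3)) for c in cents])
        labels = cluster_blades(coords, seed=0)
        truth = np.repeat([0, 1, 2], 50)
        # same partition up to label permutation
        for t in range(3):
            assert len(np.unique(labels[truth == t])) == 1
        assert len(np.unique(labels)) == 3

    def test_kmeans_deterministic_for_seed(self, rng):
        coords = rng.normal(scale=10.0, size=(300, 3))
        a = cluster_blades(coords, seed=5)
        b = cluster_blades(coords, seed=5)
        np.testing.assert_array_equal(a, b)


class TestPerLocalizationInterblade:
    def test_single_point_blades_equilateral(self):
        s = 25.0
        coords = np.array(
            [[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]], dtype=float
        )
        d = per_localization_interblade(coords, np.array([0, 1, 2]))
        np.testing.assert_allclose(d, s, atol=1e-9)

    def test_noiseless_superparticle_side_d(self):
        s = 30.0
        tips = np.array(
            [[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]], dtype=float
        )
        coords = np.repeat(tips, 20, axis=0)
        labels = np.repeat([0, 1, 2], 20)
        d = per_localization_interblade(coords, labels)
        np.testing.assert_allclose(d, s, atol=1e-9)

    def test_label_permutation_invariance(self, rng):
        cents = np.array([[0, 0, 0], [30, 0, 0], [15, 26, 0]], dtype=float)
        coords = np.vstack([c + rng.normal(scale=2.0, size=(30, 3)) for c in cents])
        labels = np.repeat([0, 1, 2], 30)
        d0 = per_localization_interblade(coords, labels)
        remap = np.array([2, 0, 1])[labels]  # relabel clusters
        d1 = per_localization_interblade(coords, remap)
        np.testing.assert_allclose(np.sort(d0), np.sort(d1), atol=1e-9)

    def test_missing_blade_raises(self):
        coords = np.zeros((4, 3))
        with pytest.raises(PipelineError):
            per_localization_interblade(coords, np.array([0, 0, 1, 1]))

    def test_both_neighbours_flag(self, rng):
        cents = np.array([[0, 0, 0], [30, 0, 0], [15, 26, 0]], dtype=float)
        coords = np.vstack([c + rng.normal(scale=1.0, size=(20, 3)) for c in cents])
        labels = np.repeat([0, 1, 2], 20)
        one = per_localization_interblade(coords, labels, both_neighbours=False)
        both = per_localization_interblade(coords, labels, both_neighbours=True)
        assert one.shape == both.shape
        assert not np.allclose(one, both)
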