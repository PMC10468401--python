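"""Trace filtering, clustering, mixture fits and trimer selection."""

import numpy as np
import pandas as pd
import pytest

from piezoblade.localization_io import PipelineConfig
from piezoblade.minflux_pipeline import (
    cluster_two_step,
    filter_traces,
    fit_fluorophores,
    identify_trimers,
    run_minflux,
)
from piezoblade.synthetic_data import EmissionParams, emit_localizations, generate_scene

from conftest import gaussian_blob


def brute_force_dbscan(points, eps, minpts):
    """Reference DBSCAN: core points by neighbour count, BFS expansion."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    core = (d <= eps).sum(axis=1) >= minpts  # neighbourhood includes self
    labels = np.full(n, -1)
    cur = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cur
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in np.flatnonzero(d[j] <= eps):
                if labels[k] == -1:
                    labels[k] = cur
                    if core[k]:
                        stack.append(k)
        cur += 1
    return labels


def table_from_points(points, trace_size=10):
    points = np.asarray(points, dtype=float)
    return pd.DataFrame(
        {
            "trace_id": [f"t{i // trace_size:04d}" for i in range(len(points))],
            "x_nm": points[:, 0],
            "y_nm": points[:, 1],
            "z_nm": points[:, 2],
        }
    )


class TestFilterTraces:
    def test_empty_in_empty_out(self):
        out = filter_traces(pd.DataFrame(columns=["trace_id", "x_nm", "y_nm", "z_nm"]))
        assert len(out) == 0
        assert out.attrs["filter_report"]["n_traces_in"] == 0

    def test_high_sd_traces_removed(self, rng):
        frames = []
        for i in range(100):
            sd = 15.0 if i < 10 else 3.0
            pts = rng.normal(scale=sd, size=(20, 3)) + 1000 * i
            df = table_from_points(pts, trace_size=20)
            df["trace_id"] = f"tr{i:03d}"
            frames.append(df)
        table = pd.concat(frames, ignore_index=True)
        out = filter_traces(table)
        kept = out["trace_id"].nunique()
        report = out.attrs["filter_report"]
        # the s.d. oracle: max per-axis sample s.d. against the 10 nm gate
        expected = sum(
            table[table.trace_id == t][["x_nm", "y_nm", "z_nm"]].std(ddof=1).max() <= 10.0
            for t in table["trace_id"].unique()
        )
        assert kept == expected
        assert report["removed_high_sd"] == 100 - expected
        assert 85 <= kept <= 92  # 10 injected wide traces, rare tail flips

    def test_short_trace_removed(self, rng):
        pts = rng.normal(scale=2.0, size=(2, 3))
        table = table_from_points(pts, trace_size=2)
        out = filter_traces(table)
        assert len(out) == 0
        assert out.attrs["filter_report"]["removed_short"] == 1


class TestClusterTwoStep:
    def test_single_tight_blob(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, size=(10, 3))
        result = cluster_two_step(table_from_points(pts))
        assert len(result.clusters) == 1
        assert result.clusters[0].indices.size == 10

    def test_two_blobs_match_brute_force(self, rng):
        pts = np.vstack(
            [rng.normal(scale=3.0, size=(30, 3)), rng.normal(scale=3.0, size=(30, 3)) + [50, 0, 0]]
        )
        cfg = PipelineConfig()
        result = cluster_two_step(table_from_points(pts), cfg)
        assert len(result.clusters) == 2
        ref1 = brute_force_dbscan(pts, cfg.dbscan1_eps, cfg.dbscan1_minpts)
        # same step-1 partition as the reference implementation
        for lab in np.unique(ref1[ref1 >= 0]):
            ours = set(map(int, np.unique(result.step1_labels[ref1 == lab])))
            assert len(ours) == 1 and -1 not in ours

    def test_isolated_points_are_noise(self):
        pts = np.array([[0, 0, 0], [100, 0, 0], [0, 100, 0], [100, 100, 0]], dtype=float)
        result = cluster_two_step(table_from_points(pts, trace_size=1))
        assert result.clusters == []


class TestFitFluorophores:
    def test_single_cloud_recovery(self, rng):
        mu = np.array([10.0, 20.0, 30.0])
        table = gaussian_blob(rng, mu, 6.0, 1000)
        result = cluster_two_step(table)
        fluors = fit_fluorophores(result)
        assert len(fluors) == 1
        np.testing.assert_allclose(fluors[0].centre, mu, atol=0.6)
        np.testing.assert_allclose(fluors[0].sigma, 6.0, atol=0.5)
        assert fluors[0].truth_id == "m0000"

    def test_two_components_recovered(self, rng):
        t1 = gaussian_blob(rng, [0, 0, 0], 5.0, 200, trace_prefix="a")
        t2 = gaussian_blob(rng, [40, 0, 0], 5.0, 200, trace_prefix="b")
        table = pd.concat([t1, t2], ignore_index=True)
        fluors = fit_fluorophores(cluster_two_step(table))
        assert len(fluors) == 2
        centres = sorted(f.centre[0] for f in fluors)
        assert centres[0] == pytest.approx(0.0, abs=1.0)
        assert centres[1] == pytest.approx(40.0, abs=1.0)

    def test_close_pair_resolved_by_trace_structure(self, rng):
        """Clouds 12 nm apart merge under eps-6.5 DBSCAN but stay two fits."""
        t1 = gaussian_blob(rng, [0, 0, 0], 6.0, 120, trace_prefix="a")
        t2 = gaussian_blob(rng, [12, 0, 0], 6.0, 120, trace_prefix="b")
        table = pd.concat([t1, t2], ignore_index=True)
        fluors = fit_fluorophores(cluster_two_step(table))
        assert len(fluors) == 2

    def test_degenerate_identical_points_clamped_and_flagged(self):
        pts = np.zeros((20, 3))
        fluors = fit_fluorophores(cluster_two_step(table_from_points(pts)))
        assert len(fluors) == 1
        assert fluors[0].flagged
        np.testing.assert_allclose(fluors[0].centre, 0.0, atol=1e-9)
        assert (fluors[0].sigma == 0.5).all()  # floor

    def test_sigma_estimator_consistency(self, rng):
        """Median fitted per-axis sigma approaches 6 nm at >= 500 locs."""
        sigmas = []
        for k in range(12):
            table = gaussian_blob(rng, rng.uniform(0, 50, 3), 6.0, 500, trace_prefix=f"c{k}")
            fluors = fit_fluorophores(cluster_two_step(table))
            assert len(fluors) == 1
            sigmas.append(fluors[0].sigma)
        med = np.median(np.concatenate(sigmas))
        assert med == pytest.approx(6.0, rel=0.05)


class TestIdentifyTrimers:
    @staticmethod
    def _fluors_at(points):
        from piezoblade.minflux_pipeline import FluorophoreEstimate

        return [
            FluorophoreEstimate(
                centre=np.asarray(p, dtype=float),
                sigma=np.full(3, 2.0),
                n_localizations=50,
                cluster_id=i,
                parent=0,
            )
            for i, p in enumerate(points)
        ]

    def test_isolated_equilateral_accepted(self):
        s = 25.0
        fluors = self._fluors_at(
            [[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]]
        )
        trimers = identify_trimers(fluors)
        assert len(trimers) == 1
        assert trimers[0].mean_d == pytest.approx(25.0)

    def test_collinear_rejected(self):
        fluors = self._fluors_at([[0, 0, 0], [25, 0, 0], [50, 0, 0]])
        assert identify_trimers(fluors) == []

    def test_fourth_neighbour_spoils_cluster(self):
        s = 25.0
        fluors = self._fluors_at(
            [[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0], [s + 80.0, 0, 0]]
        )
        assert identify_trimers(fluors) == []

    def test_window_variants(self):
        pts = [[0, 0, 0], [55, 0, 0], [27.5, 47.6, 0]]  # sides 55
        assert identify_trimers(self._fluors_at(pts), nn_variant="standard") == []
        assert len(identify_trimers(self._fluors_at(pts), nn_variant="alt")) == 1

    def test_z_gate(self):
        s = 25.0
        pts = [[0, 0, 40.0], [s, 0, 40.0], [s / 2, s * np.sqrt(3) / 2, 40.0]]
        cfg = PipelineConfig(z_range=(-30.0, 30.0))
        assert identify_trimers(self._fluors_at(pts), cfg) == []
        cfg = PipelineConfig(z_range=(-50.0, 50.0))
        assert len(identify_trimers(self._fluors_at(pts), cfg)) == 1


class TestEndToEnd:
    def test_noiseless_exact_recovery(self, small_scene, noiseless_emission):
        """Zero localization error: centres equal true tips, count equals n."""
        table = emit_localizations(small_scene, noiseless_emission, seed=1)
        trimers, log = run_minflux(table)
        assert len(trimers) == small_scene.n_molecules
        true_tips = {
            f"m{i:04d}": m.tips for i, m in enumerate(small_scene.molecules)
        }
        for t in trimers:
            tips = true_tips[t.truth_id]
            for f in t.fluors:
                err = min(np.linalg.norm(f.centre - tip) for tip in tips)
                assert err < 1e-6

    def test_background_only_yields_no_trimers(self, rigid_geometry):
        """False-positive control across 20 seeds."""
        emission = EmissionParams(sigma_loc=6.0, background_trace_density=1.0, streak_density=0.2)
        scene = generate_scene(
            rigid_geometry, 1, (5000.0, 5000.0), 150.0, p_label=0.0, seed=0
        )  # no labelled tips -> background-only field
        total = 0
        for seed in range(20):
            table = emit_localizations(scene, emission, seed=seed)
            trimers, _ = run_minflux(table)
            total += len(trimers)
        assert total == 0

    def test_row_order_invariance(self, small_scene, clean_emission, rng):
        table = emit_localizations(small_scene, clean_emission, seed=3)
        trimers_a, _ = run_minflux(table)
        shuffled = table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        trimers_b, _ = run_minflux(shuffled)
        da = sorted(t.mean_d for t in trimers_a)
        db = sorted(t.mean_d for t in trimers_b)
        assert da == pytest.approx(db, abs=1e-6)

    def test_stage_log_counts(self, small_table):
        trimers, log = run_minflux(small_table)
        assert log["n_localizations_in"] == len(small_table)
        assert log["n_fluorophores"] >= 3 * len(trimers)
        assert log["z_range"][0] < log["z_range"][1]
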