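"""Tests for the ground-truthed synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from mitoquant import expression, morphometry, respirometry
from mitoquant.synthdata import (
    ImageTruth,
    ParticleSpec,
    TableTruth,
    TraceTruth,
    disk_offsets,
    generate_resp_trace,
    generate_tissue_image,
    generate_tpm_table,
    random_image_truth,
    read_stack,
    write_stack,
)


class TestDiskOffsets:
    @pytest.mark.parametrize("n", [1, 4, 10, 25, 49, 100])
    def test_exact_pixel_count(self, n):
        offs = disk_offsets(n)
        assert offs.shape == (n, 2)
        assert len({tuple(o) for o in offs}) == n

    def test_compact_and_centered(self):
        offs = disk_offsets(25)
        # all included pixels at least as close as any excluded one
        d2 = (offs**2).sum(axis=1)
        assert d2.max() <= 8  # the 25-px discrete disk is {d² <= 8}


class TestTissueImage:
    def test_no_particles_no_noise_is_flat_background(self):
        truth = ImageTruth(
            cell_masks=np.zeros((50, 50), int), particles=[], pixel_size=0.2,
            background_level=77.0,
        )
        stack, _ = generate_tissue_image(truth, seed=0)
        np.testing.assert_array_equal(stack.channel("target"), 77.0)

    def test_recorded_area_is_pixel_count_times_calibration(
        self, single_particle_truth
    ):
        _, realized = generate_tissue_image(single_particle_truth, seed=0)
        assert realized.particles[0].area_um2 == pytest.approx(25 * 0.04)

    def test_small_particle_roundtrip_is_exact(self):
        # a 10-px (0.4 µm²) disk is far below half the median-filter footprint,
        # so detection recovers it with its exact pixel count
        cell = np.zeros((200, 200), np.int32)
        cell[40:160, 40:160] = 1
        truth = ImageTruth(
            cell_masks=cell,
            particles=[ParticleSpec(center=(100, 100), area_um2=0.4)],
            pixel_size=0.2,
        )
        stack, realized = generate_tissue_image(truth, seed=0)
        _, parts, _ = morphometry.run_pipeline(stack, marker="gfap")
        assert len(parts) == 1
        assert parts.particles[0].area_um2 == pytest.approx(
            realized.particles[0].area_um2
        )

    def test_seed_contract(self, single_particle_truth):
        truth = single_particle_truth
        truth.noise_sd = 30.0
        s1, t1 = generate_tissue_image(truth, seed=7)
        s2, t2 = generate_tissue_image(truth, seed=7)
        s3, t3 = generate_tissue_image(truth, seed=8)
        np.testing.assert_array_equal(s1.voxels, s2.voxels)  # identical bytes
        assert not np.array_equal(s1.voxels, s3.voxels)  # new noise realization
        assert t1.particles == t2.particles == t3.particles  # truth unchanged

    def test_out_of_bounds_particle_rejected(self):
        truth = ImageTruth(
            cell_masks=np.zeros((20, 20), int),
            particles=[ParticleSpec(center=(1, 1), area_um2=2.0)],
            pixel_size=0.2,
        )
        with pytest.raises(ValueError, match="outside"):
            generate_tissue_image(truth, seed=0)

    def test_z_extent_limits_particle_slices(self):
        cell = np.zeros((60, 60), int)
        cell[10:50, 10:50] = 1
        truth = ImageTruth(
            cell_masks=cell,
            particles=[ParticleSpec(center=(30, 30), area_um2=1.0)],
            pixel_size=0.2,
            n_slices=5,
            z_extent=(1, 3),
        )
        stack, _ = generate_tissue_image(truth, seed=0)
        target = stack.channel("target")
        assert (target[1] > truth.background_level).any()
        assert not (target[0] > truth.background_level).any()
        assert not (target[4] > truth.background_level).any()

    def test_tiff_roundtrip(self, tmp_path, single_particle_truth):
        stack, _ = generate_tissue_image(single_particle_truth, seed=0)
        write_stack(stack, tmp_path / "s.tif")
        back = read_stack(tmp_path / "s.tif")
        np.testing.assert_array_equal(back.voxels, np.round(stack.voxels))
        assert back.pixel_size == stack.pixel_size
        assert back.channel_roles == stack.channel_roles

    def test_random_truth_spacing_and_placement(self):
        truth = random_image_truth(seed=5, n_inside=40, n_outside=5, sub_threshold=10)
        inside = [p for p in truth.particles if p.inside_cell]
        outside = [p for p in truth.particles if not p.inside_cell]
        assert len(inside) == 50 and len(outside) == 5
        for p in inside:
            assert truth.cell_masks[p.center] > 0
        for p in outside:
            assert truth.cell_masks[p.center] == 0
        centers = np.array([p.center for p in truth.particles], float)
        d = np.sqrt(((centers[None] - centers[:, None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        r_max = np.sqrt(2.0 / np.pi) / truth.pixel_size
        assert d.min() >= 2 * 2 * r_max  # spacing >= two max diameters


class TestRespTrace:
    def test_all_zero_flows_flat_trace(self, suit_truth):
        suit_truth.state_flows = {k: 0.0 for k in suit_truth.state_flows}
        exp, _ = generate_resp_trace(suit_truth, seed=0)
        assert np.ptp(exp.trace["o2_conc"]) == 0

    def test_programmed_slope_recovered_by_finite_difference(self, suit_truth):
        # analytic-slope oracle on the post-ADP window, independent of the
        # least-squares extractor
        exp, truth = generate_resp_trace(suit_truth, seed=0)
        t = exp.trace["time_s"].to_numpy()
        y = exp.trace["o2_conc"].to_numpy()
        sel = (t >= 440) & (t < 530)  # inside the ADP->cytc segment
        slopes = np.diff(y[sel]) / np.diff(t[sel])
        flow = -slopes * 1000.0 / truth.cell_count
        np.testing.assert_allclose(flow, 30.0, rtol=1e-9)

    def test_seed_reproducibility_with_noise(self, suit_truth):
        suit_truth.noise_sd = 0.5
        e1, _ = generate_resp_trace(suit_truth, seed=3)
        e2, _ = generate_resp_trace(suit_truth, seed=3)
        pd.testing.assert_frame_equal(e1.trace, e2.trace)

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            TraceTruth(state_flows={"Ce": -1.0}, injection_times={})

    def test_non_monotone_injections_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            TraceTruth(
                state_flows={"Ce": 1.0},
                injection_times={"digitonin": 100.0, "pyruvate": 50.0},
            )

    def test_injection_artifact_does_not_bias_flows(self, suit_truth):
        suit_truth.injection_artifact = 5.0
        exp, _ = generate_resp_trace(suit_truth, seed=0)
        flows = respirometry.extract_flows(exp)
        assert flows.CI_P == pytest.approx(30.0, rel=1e-6)


class TestTpmTable:
    def test_programmed_fold_definition(self):
        truth = TableTruth(
            genes=["g1"], tpm_a=[5.0], true_fold=[2.0], pvals=[0.5]
        )
        table = generate_tpm_table(truth, seed=0)
        assert table.loc[0, "tpm_b"] == pytest.approx(10.0)

    def test_negative_fold_is_reciprocal(self):
        truth = TableTruth(genes=["g"], tpm_a=[12.0], true_fold=[-3.0], pvals=[0.5])
        assert truth.tpm_b[0] == pytest.approx(4.0)

    def test_silent_gene_removed_by_expression_filter(self):
        truth = TableTruth(
            genes=["off", "on"], tpm_a=[0.0, 1.0], true_fold=[0.0, 1.0],
            pvals=[0.5, 0.5],
        )
        table = generate_tpm_table(truth, seed=0)
        kept = expression.filter_expressed(table)
        assert list(kept["gene"]) == ["on"]

    def test_duplicate_gene_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            TableTruth(genes=["a", "a"], tpm_a=[1, 1], true_fold=[1, 1], pvals=[0.5, 0.5])

    def test_null_table_bh_calibration(self):
        # 100 null genes with uniform p-values: BH at 0.05 yields on average
        # no more than 5% discoveries across seeds
        rng = np.random.default_rng(0)
        fractions = []
        for seed in range(300):
            pvals = rng.uniform(1e-9, 1.0, 100)
            truth = TableTruth(
                genes=[f"g{i}" for i in range(100)],
                tpm_a=np.full(100, 10.0),
                true_fold=np.ones(100),
                pvals=pvals,
            )
            table = generate_tpm_table(truth, seed=seed)
            called = expression.run_de(table)
            fractions.append(called["de_call"].mean())
        assert np.mean(fractions) <= 0.05
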