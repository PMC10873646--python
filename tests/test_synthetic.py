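"""Generator contracts: ground truth is exact, outputs are deterministic."""

import hashlib
import math

import numpy as np
import pandas as pd
import pytest

from sparkquant import synthetic


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


class TestDeterminism:
    def test_cell_images_bit_identical(self):
        a, _ = synthetic.generate_cell_images(synthetic.ImagingGroundTruth(seed=5), [30, 90])
        b, _ = synthetic.generate_cell_images(synthetic.ImagingGroundTruth(seed=5), [30, 90])
        for ca, cb in zip(a, b):
            assert _digest(ca.stack.data) == _digest(cb.stack.data)

    def test_counts_bit_identical(self):
        gt = synthetic.CountsGroundTruth(n_genes=200, seed=9)
        a, _ = synthetic.generate_counts(gt)
        b, _ = synthetic.generate_counts(gt)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a, _ = synthetic.generate_cell_images(synthetic.ImagingGroundTruth(seed=1), [90])
        b, _ = synthetic.generate_cell_images(synthetic.ImagingGroundTruth(seed=2), [90])
        assert _digest(a[0].stack.data) != _digest(b[0].stack.data)


class TestCellImages:
    def test_below_csat_no_condensates(self):
        gt = synthetic.ImagingGroundTruth(csat_nM=40.0, seed=0)
        _, truth = synthetic.generate_cell_images(gt, [10, 20, 39])
        assert (truth["n_condensates"] == 0).all()

    def test_above_csat_condensates_present(self):
        gt = synthetic.ImagingGroundTruth(csat_nM=40.0, seed=0)
        _, truth = synthetic.generate_cell_images(gt, [45, 100, 400])
        assert (truth["n_condensates"] >= 1).all()

    def test_painted_partition_ratio_exact(self):
        """Pre-noise, pre-blur condensate mean / dilute mean equals the
        ground-truth partition ratio exactly."""
        gt = synthetic.ImagingGroundTruth(csat_nM=40.0, partition_ratio=8.0, seed=0)
        cells, _ = synthetic.generate_cell_images(gt, [200.0])
        c = cells[0]
        dense = c.painted[c.condensate_mask].mean()
        dilute = c.painted[c.nucleus_mask & ~c.condensate_mask].mean()
        assert dense / dilute == pytest.approx(8.0, rel=1e-12)

    def test_total_painted_proportional_to_concentration(self):
        gt = synthetic.ImagingGroundTruth(seed=1)
        cells, truth = synthetic.generate_cell_images(gt, [50, 100, 400])
        for c, (_, row) in zip(cells, truth.iterrows()):
            mean = c.painted[c.nucleus_mask].mean()
            assert mean == pytest.approx(
                gt.intensity_per_nM * row["concentration_nM"], rel=1e-9)

    def test_nonpositive_concentration_rejected(self):
        gt = synthetic.ImagingGroundTruth(seed=0)
        with pytest.raises(ValueError):
            synthetic.generate_cell_images(gt, [10, -5])
        with pytest.raises(ValueError):
            synthetic.generate_cell_images(gt, [])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthetic.ImagingGroundTruth(csat_nM=-1)
        with pytest.raises(ValueError):
            synthetic.ImagingGroundTruth(partition_ratio=0.8)


class TestFusionMovies:
    def test_aspect_ratio_follows_closed_form(self):
        """Noiseless rendering: AR measured from the painted ellipse at
        t = tau equals 1 + (AR0-1)/e within rasterization tolerance."""
        gt = synthetic.FusionGroundTruth(
            seed=0, initial_radii_um=[(0.8, 0.8)], noise_sd=0.0,
            psf_sigma_um=0.0, inv_cap_velocity_s_per_um=2.0)
        movies, truth = synthetic.generate_fusion_movie(gt)
        row = truth.iloc[0]
        tau, ar0, onset = row["tau_s"], row["ar0"], int(row["onset_frame"])
        movie = movies[0]
        # frame closest to t = tau after onset
        k = onset + int(round(tau / gt.frame_interval_s))
        from sparkquant.fusion import _aspect_ratio

        frame = movie.data[k]
        mask = frame > frame.mean()
        measured = _aspect_ratio(frame, mask, background=gt.background_counts)
        t = (k - onset) * gt.frame_interval_s
        expected = 1.0 + (ar0 - 1.0) * math.exp(-t / tau)
        assert measured == pytest.approx(expected, abs=0.03)

    def test_final_frame_is_sphere(self):
        gt = synthetic.FusionGroundTruth(seed=0, initial_radii_um=[(0.6, 0.5)],
                                         noise_sd=0.0, psf_sigma_um=0.0)
        movies, _ = synthetic.generate_fusion_movie(gt)
        from sparkquant.fusion import _aspect_ratio

        frame = movies[0].data[-1]
        mask = frame > frame.mean()
        assert _aspect_ratio(frame, mask, gt.background_counts) == pytest.approx(1.0, abs=0.03)

    def test_tiny_radii_rejected(self):
        gt = synthetic.FusionGroundTruth(seed=0, initial_radii_um=[(0.05, 0.05)])
        with pytest.raises(ValueError, match="too small"):
            synthetic.generate_fusion_movie(gt)


class TestDissolutionSeries:
    def test_total_painted_conserved(self):
        gt = synthetic.ImagingGroundTruth(seed=4)
        movie, truth = synthetic.generate_dissolution_series(
            gt, decay_timescale_s=60, n_frames=10, frame_interval_s=30)
        assert (truth["total_painted"].nunique()) == 1  # exact by construction
        clean = movie.meta["clean"]
        totals = clean.reshape(clean.shape[0], -1).sum(axis=1)
        assert np.max(np.abs(totals / totals[0] - 1.0)) < 1e-3

    def test_infinite_timescale_freezes_spark(self):
        gt = synthetic.ImagingGroundTruth(seed=4)
        _, truth = synthetic.generate_dissolution_series(
            gt, decay_timescale_s=np.inf, n_frames=6, frame_interval_s=30)
        assert truth["spark_true"].nunique() == 1

    def test_needs_two_frames_and_supersaturation(self):
        gt = synthetic.ImagingGroundTruth(seed=0)
        with pytest.raises(ValueError):
            synthetic.generate_dissolution_series(gt, n_frames=1)
        with pytest.raises(ValueError):
            synthetic.generate_dissolution_series(gt, concentration_nM=10.0)


class TestColocChannels:
    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_truth_matches_probability_extremes(self, p):
        _, truth = synthetic.generate_coloc_channels(
            8, puncta_per_cell=6, coloc_probability=p, jitter_um=0.0, seed=3)
        assert (truth["n_matched"] == (truth["n_puncta"] if p else 0)).all()

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_coloc_channels(2, coloc_probability=1.5)


class TestCtTable:
    def test_noiseless_ddct_is_minus_log2_fold_change(self):
        tbl = synthetic.generate_ct_table({"G": 0.25}, ct_noise_sd=0.0, seed=0)
        ref = tbl[tbl.gene == "ACTB"].groupby("condition")["ct"].mean()
        tgt = tbl[tbl.gene == "G"].groupby("condition")["ct"].mean()
        ddct = (tgt["treated"] - ref["treated"]) - (tgt["control"] - ref["control"])
        assert ddct == pytest.approx(-math.log2(0.25), abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_ct_table({"G": -1.0})
        with pytest.raises(ValueError):
            synthetic.generate_ct_table({"G": 1.0}, n_replicates=1)


class TestCounts:
    def test_nb_means_match_truth(self):
        gt = synthetic.CountsGroundTruth(n_genes=2000, n_replicates=50,
                                         dispersion=0.05, seed=2,
                                         de_lfc={"gene00010": 2.0, "gene00020": -1.0})
        counts, truth = synthetic.generate_counts(gt)
        ctrl = counts.filter(like="control").mean(axis=1)
        trt = counts.filter(like="treated").mean(axis=1)
        # spiked genes shift by their signed log2FC; nulls share means
        assert np.log2(trt["gene00010"] / ctrl["gene00010"]) == pytest.approx(2.0, abs=0.25)
        assert np.log2(trt["gene00020"] / ctrl["gene00020"]) == pytest.approx(-1.0, abs=0.25)
        nulls = truth.index[~truth["is_de"]][:200]
        ratio = np.log2((trt[nulls] + 1) / (ctrl[nulls] + 1))
        assert np.abs(ratio.mean()) < 0.05

    def test_unknown_de_gene_rejected(self):
        gt = synthetic.CountsGroundTruth(n_genes=10, de_lfc={"nope": 1.0})
        with pytest.raises(ValueError, match="not in gene universe"):
            synthetic.generate_counts(gt)

    def test_study_design_shapes(self):
        counts, design, truth = synthetic.generate_study_counts(
            n_genes=500, n_responsive_up=40, n_responsive_down=30,
            n_ps_up=5, n_ps_down=5, seed=1)
        assert counts.shape == (500, 9)
        assert set(design.unique()) == {"control", "diffuse", "condensed"}
        assert (truth["ps_lfc"] != 0).sum() == 10
        # PS genes and responsive genes are disjoint
        assert ((truth["ps_lfc"] != 0) & (truth["responsive_lfc"] != 0)).sum() == 0
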