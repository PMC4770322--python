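"""Transects, balanced pixel subsets, and contribution partitioning."""

import numpy as np
import pandas as pd
import pytest

from biomemap import fluor, spectral
from biomemap.community import (
    abundance_by_category,
    extract_transect,
    subsample_pixels,
    weighted_contribution,
)
from biomemap.spectral import DerivativeImage, GroupMasks


def _dimg(vals, target=546.0):
    return DerivativeImage(target_nm=target, actual_band_nm=target, values=np.asarray(vals, float))


def _photo(values):
    values = np.asarray(values, dtype=float)
    return fluor.PhotoMap(
        fvfm=values, alpha=values, ek=values, etrmax=values, npqmax=values
    )


class TestTransect:
    def test_constant_layer_gives_constant_profile(self):
        layers = {"a": np.full((20, 30), 2.5)}
        t = extract_transect(layers, [(2, 3), (25, 3), (25, 15)])
        np.testing.assert_array_equal(t.values["a"], 2.5)

    def test_horizontal_line_of_length_L_yields_L_plus_1_samples(self):
        layers = {"a": np.arange(600.0).reshape(20, 30)}
        t = extract_transect(layers, [(4, 7), (14, 7)])  # length 10 px
        assert t.positions.size == 11
        np.testing.assert_array_equal(t.values["a"], layers["a"][7, 4:15])

    def test_unit_arc_spacing(self):
        t = extract_transect({"a": np.zeros((40, 40))}, [(1, 1), (20, 15), (35, 30)])
        np.testing.assert_allclose(np.diff(t.positions), 1.0, atol=1e-9)

    def test_profile_mean_within_traversed_range(self, rng):
        layer = rng.random((30, 30))
        t = extract_transect({"a": layer}, [(2, 4), (27, 25)])
        vals = layer[t.pixels[:, 0], t.pixels[:, 1]]
        assert vals.min() <= t.values["a"].mean() <= vals.max()

    def test_apical_gradient_visible_along_transect(self, noiseless_sample):
        """On a lower-shore frond the diatom δδ546 profile rises toward the apex."""
        res = noiseless_sample
        truth = res.truth
        # follow the main axis: base = bottom-most mask pixel, apex = top-most
        ys, xs = np.nonzero(truth.frond_mask)
        base = (xs[np.argmax(ys)], ys.max())
        apex = (xs[np.argmin(ys)], ys.min())
        t = extract_transect({"dd546": res.derivatives["diatom"].values}, [base, apex])
        prof = t.values["dd546"]
        half = prof.size // 2
        assert np.nanmean(prof[half:]) > np.nanmean(prof[:half])

    def test_polyline_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            extract_transect({"a": np.zeros((10, 10))}, [(0, 0), (50, 0)])


class TestSubsample:
    def test_oversized_request_returns_all_with_warning(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[:2, :3] = True
        with pytest.warns(UserWarning, match="sampling all"):
            df = subsample_pixels(mask, {"v": np.ones((10, 10))}, n=50)
        assert len(df) == 6  # 6 pixels x 1 parameter

    def test_same_seed_reproduces_subset(self):
        mask = np.ones((20, 20), dtype=bool)
        layers = {"v": np.arange(400.0).reshape(20, 20)}
        a = subsample_pixels(mask, layers, n=30, seed=5)
        b = subsample_pixels(mask, layers, n=30, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_mask_gives_empty_table(self):
        with pytest.warns(UserWarning, match="empty group"):
            df = subsample_pixels(np.zeros((4, 4), dtype=bool), {"v": np.zeros((4, 4))}, n=5)
        assert df.empty

    def test_inclusion_frequency_is_uniform(self):
        """Monte-Carlo: each pixel included with frequency n/N (3 binomial sd)."""
        mask = np.zeros((6, 6), dtype=bool)
        mask.ravel()[:30] = True
        layers = {"v": np.zeros((6, 6))}
        n, trials = 10, 800
        counts = np.zeros((6, 6))
        for seed in range(trials):
            df = subsample_pixels(mask, layers, n=n, seed=seed)
            counts[df["row"], df["col"]] += 1
        p = n / 30
        freq = counts[mask] / trials
        tol = 3 * np.sqrt(p * (1 - p) / trials)
        assert np.all(np.abs(freq - p) <= tol)


class TestWeightedContribution:
    def two_group_setup(self, d_host, d_diatom, param):
        shape = np.asarray(d_host).shape
        masks = GroupMasks(
            masks={
                "host": np.asarray(d_host) > 0,
                "diatom": np.asarray(d_diatom) > 0,
                "chlorophyte": np.zeros(shape, dtype=bool),
                "community": np.ones(shape, dtype=bool),
            }
        )
        derivs = {
            "host": _dimg(d_host, 568),
            "diatom": _dimg(d_diatom, 546),
            "chlorophyte": _dimg(np.full(shape, -1.0), 648),
        }
        return masks, derivs, _photo(param)

    def test_single_group_takes_100_percent(self):
        masks, derivs, photo = self.two_group_setup(
            np.full((4, 4), 0.002), np.full((4, 4), -0.001), np.full((4, 4), 50.0)
        )
        out = weighted_contribution(masks, derivs, photo)
        got = dict(zip(out.group, out.percent))
        assert got["host"] == pytest.approx(100.0)
        assert got["diatom"] == 0.0 and got["chlorophyte"] == 0.0

    def test_equal_weights_split_50_50(self):
        masks, derivs, photo = self.two_group_setup(
            np.full((5, 5), 0.001), np.full((5, 5), 0.001), np.full((5, 5), 42.0)
        )
        out = weighted_contribution(masks, derivs, photo)
        got = dict(zip(out.group, out.percent))
        assert got["host"] == pytest.approx(50.0, abs=1e-9)
        assert got["diatom"] == pytest.approx(50.0, abs=1e-9)

    def test_percentages_sum_to_100(self, rng):
        d1 = rng.normal(0.001, 0.001, (8, 8))
        d2 = rng.normal(0.001, 0.001, (8, 8))
        masks, derivs, photo = self.two_group_setup(d1, d2, rng.uniform(10, 90, (8, 8)))
        out = weighted_contribution(masks, derivs, photo)
        assert out.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_count_weighting_ignores_amplitude(self):
        d_host = np.full((4, 4), 0.005)  # 5x the diatom amplitude
        d_diatom = np.full((4, 4), 0.001)
        masks, derivs, photo = self.two_group_setup(d_host, d_diatom, np.full((4, 4), 10.0))
        out = weighted_contribution(masks, derivs, photo, weighting="count")
        got = dict(zip(out.group, out.percent))
        assert got["host"] == pytest.approx(50.0, abs=1e-9)

    def test_negative_derivative_cannot_contribute(self):
        # diatom mask present (just above threshold is impossible here, so
        # force mask true with negative amplitude) -> weight floors at zero
        shape = (3, 3)
        masks = GroupMasks(
            masks={
                "host": np.ones(shape, dtype=bool),
                "diatom": np.ones(shape, dtype=bool),
                "chlorophyte": np.zeros(shape, dtype=bool),
                "community": np.ones(shape, dtype=bool),
            }
        )
        derivs = {
            "host": _dimg(np.full(shape, 0.002), 568),
            "diatom": _dimg(np.full(shape, -0.002), 546),
            "chlorophyte": _dimg(np.zeros(shape), 648),
        }
        out = weighted_contribution(masks, derivs, _photo(np.full(shape, 5.0)))
        got = dict(zip(out.group, out.percent))
        assert got["diatom"] == 0.0 and got["host"] == pytest.approx(100.0)

    def test_all_na_parameter_rejected(self):
        masks, derivs, _ = self.two_group_setup(
            np.full((3, 3), 0.001), np.full((3, 3), 0.001), np.full((3, 3), 1.0)
        )
        with pytest.raises(ValueError, match="entirely NA"):
            weighted_contribution(masks, derivs, _photo(np.full((3, 3), np.nan)))


class TestAbundanceByCategory:
    def frame(self, reps, value):
        return pd.DataFrame(
            {
                "shore_height": ["lower"] * reps,
                "epiphyte_category": ["high"] * reps,
                "group": ["diatom"] * reps,
                "abundance_pct": value if isinstance(value, list) else [value] * reps,
            }
        )

    def test_single_replicate_reports_na_sem(self):
        out = abundance_by_category(self.frame(1, 40.0))
        assert out["abundance_pct_mean"][0] == 40.0
        assert np.isnan(out["abundance_pct_sem"][0])

    def test_identical_replicates_give_zero_sem(self):
        out = abundance_by_category(self.frame(4, 40.0))
        assert out["abundance_pct_sem"][0] == 0.0

    def test_mean_recovers_cell_average(self):
        out = abundance_by_category(self.frame(4, [10.0, 20.0, 30.0, 40.0]))
        assert out["abundance_pct_mean"][0] == pytest.approx(25.0)
        assert out["abundance_pct_count"][0] == 4
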