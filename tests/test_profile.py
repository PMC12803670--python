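"""Slice statistics, region classification and distal extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nervefa.gompertz import GompertzParams, gompertz_eval
from nervefa.profile import (
    NerveProfile,
    NerveSliceStat,
    SegmentationParams,
    classify_regions,
    extract_distal,
    read_profile_table,
    slice_statistics,
    write_profile_table,
)
from nervefa.tensor_model import ScalarMap


def make_profile(fa_values, spacing=0.8, **kw):
    slices = [
        NerveSliceStat(index=i, position=i * spacing, fa_mean=float(v),
                       fa_sd=0.02, n_voxels=10)
        for i, v in enumerate(fa_values)
    ]
    return NerveProfile(slices=slices, slice_spacing=spacing, **kw)


def region_runs(labels):
    runs, prev = [], None
    for l in labels:
        if l != prev:
            runs.append(l)
            prev = l
    return runs


class TestSliceStatistics:
    def _map_and_mask(self, rng, shape=(6, 6, 12)):
        values = rng.uniform(0.2, 0.9, shape)
        mask = rng.random(shape) < 0.5
        mask[..., :] |= ~mask.any(axis=(0, 1))[None, None, :]  # no empty slices
        return ScalarMap(values=values, mask=np.ones(shape, bool)), mask

    def test_matches_bruteforce(self, rng):
        smap, mask = self._map_and_mask(rng)
        prof = slice_statistics(smap, mask, slice_axis=2, slice_spacing=0.8)
        for s in prof.slices:
            vox = smap.values[..., s.index][mask[..., s.index]]
            assert s.fa_mean == pytest.approx(vox.mean(), abs=1e-12)
            expected_sd = vox.std(ddof=1) if vox.size > 1 else 0.0
            assert s.fa_sd == pytest.approx(expected_sd, abs=1e-12)
            assert s.n_voxels == vox.size

    def test_constant_map(self):
        shape = (4, 4, 10)
        smap = ScalarMap(values=np.full(shape, 0.7), mask=np.ones(shape, bool))
        prof = slice_statistics(smap, np.ones(shape, bool))
        assert all(s.fa_mean == pytest.approx(0.7) for s in prof.slices)
        assert all(s.fa_sd == 0.0 for s in prof.slices)

    def test_planted_slice_means_recovered(self):
        shape = (3, 3, 9)
        means = np.linspace(0.6, 0.4, 9)
        values = np.broadcast_to(means, shape).copy()
        smap = ScalarMap(values=values, mask=np.ones(shape, bool))
        prof = slice_statistics(smap, np.ones(shape, bool))
        np.testing.assert_allclose(prof.fa_means, means, atol=1e-15)

    def test_grid_mismatch_is_hard_error(self):
        smap = ScalarMap(values=np.zeros((3, 3, 9)), mask=np.ones((3, 3, 9), bool))
        with pytest.raises(ValueError, match="grid"):
            slice_statistics(smap, np.ones((3, 3, 8), bool))

    def test_empty_mask_is_hard_error(self):
        smap = ScalarMap(values=np.zeros((3, 3, 9)), mask=np.ones((3, 3, 9), bool))
        with pytest.raises(ValueError, match="no voxels"):
            slice_statistics(smap, np.zeros((3, 3, 9), bool))

    def test_too_few_slices_is_hard_error(self):
        shape = (3, 3, 5)
        smap = ScalarMap(values=np.full(shape, 0.5), mask=np.ones(shape, bool))
        with pytest.raises(ValueError, match=">= 8"):
            slice_statistics(smap, np.ones(shape, bool))


class TestClassifyRegions:
    def test_constructed_injury_boundaries_exact(self):
        """Plateau, dip, sigmoid: the injury run is exactly the dip."""
        sigmoid = gompertz_eval(
            GompertzParams(0.60, -0.20, 0.8, 7.0), np.arange(18) * 0.8
        )
        fa = np.concatenate([np.full(10, 0.67), np.full(4, 0.45), sigmoid])
        prof = make_profile(fa)
        lab = classify_regions(prof, SegmentationParams(drop_fraction=0.25))
        assert lab.region_labels[:10] == ["proximal"] * 10
        assert lab.region_labels[10:14] == ["injury"] * 4
        assert lab.region_labels[14:] == ["distal"] * 18
        assert not lab.no_injury_detected

    def test_flat_profile_fallback(self):
        prof = make_profile(np.full(30, 0.70))
        lab = classify_regions(prof)
        assert lab.no_injury_detected
        # terminal ceil(15 / 0.8) = 19 slices labeled distal
        assert lab.region_labels == ["proximal"] * 11 + ["distal"] * 19

    def test_manual_labels_passthrough(self):
        prof = make_profile(np.full(10, 0.70))
        manual = ["proximal"] * 3 + ["injury"] * 2 + ["distal"] * 5
        lab = classify_regions(prof, labels=manual)
        assert lab.region_labels == manual

    def test_manual_labels_validated(self):
        prof = make_profile(np.full(10, 0.70))
        bad = ["distal"] * 5 + ["proximal"] * 5
        with pytest.raises(ValueError, match="contiguous"):
            classify_regions(prof, labels=bad)

    def test_idempotent(self, rng):
        fa = np.concatenate([np.full(12, 0.66), np.full(4, 0.42),
                             np.full(19, 0.5)]) + rng.normal(0, 0.02, 35)
        prof = make_profile(np.clip(fa, 0, 1))
        once = classify_regions(prof)
        twice = classify_regions(once)
        assert once.region_labels == twice.region_labels

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.05, 0.95), min_size=8, max_size=60),
           st.floats(0.05, 0.4))
    def test_label_runs_always_contiguous_and_ordered(self, fa, drop):
        prof = make_profile(np.asarray(fa))
        lab = classify_regions(prof, SegmentationParams(drop_fraction=drop))
        # at most one run per region, in proximal -> injury -> distal order,
        # and a nonempty distal run on every output (runs may be empty,
        # e.g. no proximal slices when the injury starts at slice 0)
        runs = region_runs(lab.region_labels)
        order = ["proximal", "injury", "distal"]
        assert [r for r in order if r in runs] == runs
        assert "distal" in runs


class TestExtractDistal:
    def test_reorigin_and_extent(self):
        prof = make_profile(np.full(30, 0.7))
        lab = classify_regions(prof)  # sham fallback: last 19 slices
        distal = extract_distal(lab)
        assert distal.x[0] == 0.0
        assert distal.x[-1] == pytest.approx(18 * 0.8)
        assert len(distal) == 19

    def test_gaps_preserved(self):
        slices = [
            NerveSliceStat(index=i, position=i * 0.8, fa_mean=0.5, fa_sd=0.0, n_voxels=5)
            for i in range(30) if i != 20
        ]
        prof = NerveProfile(slices=slices, slice_spacing=0.8)
        lab = classify_regions(prof)
        distal = extract_distal(lab)
        dx = np.diff(distal.x)
        assert (np.isclose(dx, 0.8) | np.isclose(dx, 1.6)).all()
        assert np.isclose(dx, 1.6).sum() == 1  # one gap, not interpolated

    def test_roundtrip_parent_indices(self):
        prof = make_profile(np.full(30, 0.7))
        lab = classify_regions(prof)
        distal = extract_distal(lab)
        orig = [s.index for s in lab.slices]
        assert list(distal.parent_indices) == orig[-19:]
        assert distal.parent_ref is lab

    def test_unlabeled_profile_rejected(self):
        prof = make_profile(np.full(10, 0.7))
        with pytest.raises(ValueError, match="labeled"):
            extract_distal(prof)

    def test_empty_distal_names_subject(self):
        prof = make_profile(np.full(10, 0.7), subject_id="r01", timepoint_weeks=4)
        lab = classify_regions(prof, labels=["proximal"] * 10)
        with pytest.raises(ValueError, match="r01"):
            extract_distal(lab)


class TestTableIO:
    def test_roundtrip(self, tmp_path, rng):
        fa = np.clip(rng.normal(0.6, 0.05, 20), 0, 1)
        prof = make_profile(fa)
        lab = classify_regions(prof)
        path = tmp_path / "profile.csv"
        write_profile_table(lab, path)
        back = read_profile_table(path)
        np.testing.assert_allclose(back.fa_means, lab.fa_means)
        assert back.region_labels == lab.region_labels
        assert back.slice_spacing == pytest.approx(0.8)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("slice_index,fa_mean\n0,0.5\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_profile_table(p)
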