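import numpy as np
import pandas as pd
import pytest

import hicdelta as hd
from hicdelta.contact_core import GenomeSpec
from hicdelta.insulation_tads import (
    BoundarySet,
    InsulationTrack,
    boundary_pileup,
    call_boundaries,
    candidate_positions,
    differential_boundaries,
    match_boundaries,
    tads_from_boundaries,
)

from conftest import matrix_from_dense, toy_spec


def track_from_values(values, window=100_000, chrom="chr1", resolution=10_000):
    spec = GenomeSpec((chrom,), (len(values) * resolution,), resolution)
    t = InsulationTrack(spec, window)
    t.log2[chrom] = np.asarray(values, dtype=float)
    t.raw[chrom] = 2.0 ** t.log2[chrom]
    return t


def boundary_set(spec, positions):
    return BoundarySet(
        spec,
        pd.DataFrame(
            [("chr1", b, -1.0, 1.0) for b in positions],
            columns=["chrom", "bin", "log2_is", "strength"],
        ),
    )


class TestInsulationTrack:
    def test_uniform_matrix_flat(self):
        n = 60
        m = matrix_from_dense(np.full((n, n), 5.0))
        m.weights = np.ones(n)
        t = hd.insulation_track(m, window=100_000)
        vals = t.log2["chr1"]
        interior = vals[np.isfinite(vals)]
        assert np.allclose(interior, 0.0, atol=1e-12)
        # normalization invariant: chromosome mean of 2^log2IS is 1
        assert 2.0 ** interior.mean() == pytest.approx(1.0, abs=1e-6)

    def test_two_block_junction_minimum(self):
        n = 60
        dense = np.full((n, n), 1e-3)
        dense[:30, :30] = 5.0
        dense[30:, 30:] = 5.0
        m = matrix_from_dense(dense)
        m.weights = np.ones(n)
        t = hd.insulation_track(m, window=100_000)
        vals = t.log2["chr1"]
        # bins 29 and 30 both see a fully cross-block diamond; either is
        # the junction minimum
        assert np.nanargmin(vals) in (29, 30)

    def test_scale_invariance(self, balanced_pair):
        nb, _ = balanced_pair
        t1 = hd.insulation_track(nb, 100_000)
        scaled = nb.scaled(13.0)
        t2 = hd.insulation_track(scaled, 100_000)
        a, b = t1.log2["chr1"], t2.log2["chr1"]
        ok = np.isfinite(a)
        assert np.allclose(a[ok], b[ok], atol=1e-9)

    def test_window_errors(self):
        m = matrix_from_dense(np.ones((20, 20)))
        m.weights = np.ones(20)
        with pytest.raises(ValueError):
            hd.insulation_track(m, window=15_000)  # not a bin multiple
        with pytest.raises(ValueError):
            hd.insulation_track(m, window=2_000_000)  # too large everywhere


class TestCallBoundaries:
    def test_flat_track_no_boundaries(self):
        t = track_from_values(np.zeros(50))
        assert len(call_boundaries(t).table) == 0

    def test_single_notch(self):
        vals = np.zeros(50)
        vals[25] = -1.0
        vals[24] = vals[26] = -0.4
        bs = call_boundaries(track_from_values(vals), min_strength=0.2)
        assert list(bs.table["bin"]) == [25]
        assert bs.table.loc[0, "strength"] >= 0.2

    def test_count_monotone_in_strength(self, balanced_pair):
        nb, _ = balanced_pair
        t = hd.insulation_track(nb, 100_000)
        counts = [len(call_boundaries(t, s).table) for s in (0.05, 0.2, 0.5, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_planted_recovery(self, truth, balanced_pair):
        for M, col in zip(balanced_pair, ("in_normal", "in_tumour")):
            t = hd.insulation_track(M, 100_000)
            bs = call_boundaries(t, min_strength=0.3)
            planted = truth.boundaries[truth.boundaries[col]]
            hits = 0
            for r in planted.itertuples():
                called = bs.table.loc[bs.table["chrom"] == r.chrom, "bin"].to_numpy()
                hits += len(called) > 0 and np.min(np.abs(called - r.bin)) <= 1
            recall = hits / len(planted)
            prec_hits = 0
            for r in bs.table.itertuples():
                p = planted.loc[planted["chrom"] == r.chrom, "bin"].to_numpy()
                prec_hits += len(p) > 0 and np.min(np.abs(p - r.bin)) <= 1
            precision = prec_hits / len(bs.table)
            assert recall >= 0.9
            assert precision >= 0.9


class TestTads:
    def test_two_boundary_example(self):
        spec = toy_spec(n_bins=40)
        tads = tads_from_boundaries(boundary_set(spec, [10, 20]))
        assert tads.n_tads == 1
        assert tads.table.iloc[0].tolist() == ["chr1", 100_000, 200_000]
        assert tads.mean_adjacent_distance == pytest.approx(100_000)

    def test_single_boundary_no_tads(self):
        spec = toy_spec(n_bins=40)
        assert tads_from_boundaries(boundary_set(spec, [10])).n_tads == 0

    def test_mean_gap_matches_hand_count(self):
        spec = toy_spec(n_bins=100)
        tads = tads_from_boundaries(boundary_set(spec, [10, 20, 45, 90]))
        gaps_bp = [100_000, 250_000, 450_000]
        assert tads.mean_adjacent_distance == pytest.approx(np.mean(gaps_bp))

    def test_short_tads_dropped(self):
        spec = toy_spec(n_bins=40)
        tads = tads_from_boundaries(boundary_set(spec, [10, 12, 30]))
        assert tads.n_tads == 1  # the 2-bin interval is discarded

    def test_tumour_has_more_smaller_tads(self, truth, balanced_pair):
        nb, tb = balanced_pair
        sizes = {}
        for M, name in ((nb, "normal"), (tb, "tumour")):
            t = hd.insulation_track(M, 100_000)
            tads = tads_from_boundaries(call_boundaries(t, 0.3))
            sizes[name] = tads
        assert sizes["tumour"].n_tads > sizes["normal"].n_tads
        assert (
            sizes["tumour"].mean_adjacent_distance < sizes["normal"].mean_adjacent_distance
        )


class TestMatchBoundaries:
    def test_identical_sets_all_conserved(self):
        spec = toy_spec(n_bins=100)
        a = boundary_set(spec, [10, 40, 70])
        m = match_boundaries(a, a, tol_bins=1)
        assert len(m.conserved) == 3
        assert len(m.a_specific) == len(m.b_specific) == 0

    def test_offset_within_tolerance(self):
        spec = toy_spec(n_bins=100)
        a = boundary_set(spec, [10, 40, 70])
        b = boundary_set(spec, [11, 41, 71])
        m = match_boundaries(a, b, tol_bins=1)
        assert len(m.conserved) == 3

    def test_disjoint_sets(self):
        spec = toy_spec(n_bins=100)
        a = boundary_set(spec, [10, 40])
        b = boundary_set(spec, [20, 60])
        m = match_boundaries(a, b, tol_bins=1)
        assert len(m.conserved) == 0
        assert len(m.a_specific) == 2 and len(m.b_specific) == 2

    def test_partition_exhaustive(self):
        spec = toy_spec(n_bins=100)
        a = boundary_set(spec, [10, 40, 70, 90])
        b = boundary_set(spec, [11, 60, 71])
        m = match_boundaries(a, b, tol_bins=1)
        assert 2 * len(m.conserved) + len(m.a_specific) + len(m.b_specific) == 7


class TestDifferentialBoundaries:
    def test_both_positive_excluded(self):
        tn = track_from_values([0.2] * 5)
        tt = track_from_values([0.1] * 5)
        out = differential_boundaries(tn, tt, [("chr1", 2)])
        assert out.loc[0, "class"] == "excluded"
        assert out.loc[0, "reason"] == "both_positive"

    def test_enhanced_below_negative_threshold(self):
        tn = track_from_values([-0.2] * 5)
        tt = track_from_values([-0.7] * 5)
        out = differential_boundaries(tn, tt, [("chr1", 2)])
        assert out.loc[0, "delta"] == pytest.approx(-0.5)
        assert out.loc[0, "class"] == "enhanced"

    def test_small_delta_unchanged(self):
        tn = track_from_values([-0.2] * 5)
        tt = track_from_values([-0.5] * 5)
        out = differential_boundaries(tn, tt, [("chr1", 2)])
        assert out.loc[0, "class"] == "unchanged"

    def test_nan_reported_excluded(self):
        tn = track_from_values([np.nan] * 5)
        tt = track_from_values([-0.5] * 5)
        out = differential_boundaries(tn, tt, [("chr1", 2)])
        assert out.loc[0, "class"] == "excluded"
        assert out.loc[0, "reason"] == "nan_score"

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(5)
        vals_n = rng.normal(-0.5, 0.5, 30)
        vals_t = rng.normal(-0.5, 0.5, 30)
        tn, tt = track_from_values(vals_n), track_from_values(vals_t)
        pos = [("chr1", i) for i in range(30)]
        fwd = differential_boundaries(tn, tt, pos)
        rev = differential_boundaries(tt, tn, pos)
        swap = {"enhanced": "weakened", "weakened": "enhanced",
                "unchanged": "unchanged", "excluded": "excluded"}
        assert [swap[c] for c in fwd["class"]] == list(rev["class"])


class TestPileup:
    def test_flat_tracks_flat_profile(self):
        tn = track_from_values(np.zeros(50))
        tt = track_from_values(np.full(50, -0.2))
        prof = boundary_pileup(tn, tt, [("chr1", 25)], flank_bins=5)
        assert np.allclose(prof["normal"], 0.0)
        assert np.allclose(prof["tumour"], -0.2)

    def test_empty_positions_error(self):
        tn = track_from_values(np.zeros(50))
        with pytest.raises(ValueError):
            boundary_pileup(tn, tn, [], flank_bins=5)

    def test_centre_below_flanks_at_called_boundaries(self, balanced_pair):
        nb, _ = balanced_pair
        t = hd.insulation_track(nb, 100_000)
        bs = call_boundaries(t, 0.3)
        pos = bs.positions()
        prof = boundary_pileup(t, t, pos, flank_bins=8)
        centre = prof.loc[prof["offset"] == 0, "normal"].iloc[0]
        flanks = prof.loc[prof["offset"].abs() >= 6, "normal"].mean()
        assert centre < flanks

    def test_enhanced_centre_lower_in_tumour(self, truth, balanced_pair):
        nb, tb = balanced_pair
        tn = hd.insulation_track(nb, 100_000)
        tt = hd.insulation_track(tb, 100_000)
        enh = truth.boundaries[truth.boundaries["class"] == "enhanced"]
        pos = [(r.chrom, r.bin) for r in enh.itertuples()]
        prof = boundary_pileup(tn, tt, pos, flank_bins=8)
        c = prof["offset"] == 0
        assert prof.loc[c, "tumour"].iloc[0] < prof.loc[c, "normal"].iloc[0]
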