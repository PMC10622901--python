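"""Track merging, pLDDT binning, segmentation and proteome summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idrfold import (
    ResidueTrack,
    bin_residues,
    extract_idr_segments,
    filter_segments_high_plddt,
    merge_tracks,
    proteome_summary,
    read_disorder_track,
)
from idrfold.tracks import plddt_bin_labels, write_disorder_track_tsv


def _track(disorder, plddt=None, pid="P1"):
    disorder = np.asarray(disorder, dtype=float)
    if plddt is None:
        plddt = np.full(len(disorder), 50.0)
    return ResidueTrack(pid, "", np.asarray(plddt, dtype=float), disorder)


def _oracle_segments(scores, threshold):
    """O(n^2) brute force: an interval is a maximal run iff every inside
    position passes and both flanking positions (if any) fail."""
    n = len(scores)
    out = []
    for i in range(n):
        for j in range(i, n):
            inside = all(scores[k] >= threshold for k in range(i, j + 1))
            left_ok = i == 0 or scores[i - 1] < threshold
            right_ok = j == n - 1 or scores[j + 1] < threshold
            if inside and left_ok and right_ok:
                out.append((i + 1, j + 1))
    return out


class TestDisorderTrackIO:
    def test_pass_through(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("P1\t1\t0.2\nP1\t2\t0.5\nP1\t3\t0.9\n")
        tracks = read_disorder_track(p)
        np.testing.assert_allclose(tracks["P1"], [0.2, 0.5, 0.9])

    def test_out_of_range_score(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("P1\t1\t1.2\n")
        with pytest.raises(ValueError, match="outside"):
            read_disorder_track(p)

    def test_non_contiguous_positions(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("P1\t1\t0.2\nP1\t3\t0.4\n")
        with pytest.raises(ValueError, match="contiguous"):
            read_disorder_track(p)

    def test_writer_reader_round_trip(self, tmp_path, rng):
        tracks = {"A": rng.uniform(0, 1, 20).round(4), "B": rng.uniform(0, 1, 5).round(4)}
        p = tmp_path / "w.tsv"
        write_disorder_track_tsv(tracks, p)
        back = read_disorder_track(p)
        for pid in tracks:
            np.testing.assert_allclose(back[pid], tracks[pid], atol=1e-4)


class TestMergeTracks:
    def test_equal_lengths_merge(self):
        t = merge_tracks([50.0] * 10, [0.4] * 10, protein_id="X")
        assert len(t) == 10

    def test_length_mismatch_reports_both(self):
        with pytest.raises(ValueError, match="100.*99"):
            merge_tracks([50.0] * 100, [0.4] * 99)

    def test_empty_merge(self):
        assert len(merge_tracks([], [])) == 0


class TestBinning:
    def test_boundary_70_is_confident(self):
        assert plddt_bin_labels(np.array([70.0]))[0] == "confident"

    def test_boundary_50_is_low_and_100_is_very_confident(self):
        labels = plddt_bin_labels(np.array([50.0, 100.0, 49.999, 89.999, 90.0]))
        assert list(labels) == [
            "low", "very_confident", "very_low", "confident", "very_confident",
        ]

    def test_single_residue_classification(self):
        out = bin_residues([_track([0.6], [70.0])])
        assert out.loc[("disordered", "confident"), "count"] == 1

    def test_counts_conserved_and_fractions_sum(self, small_proteome):
        _, tracks, _ = small_proteome
        out = bin_residues(tracks)
        assert out["count"].sum() == sum(len(t) for t in tracks)
        sums = out.groupby(level="order_class")["fraction_of_class"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_fraction_matches_truncated_normal_integral(self, small_proteome):
        # closed form: fraction of disordered residues with pLDDT >= 70 under
        # the generating truncated-normal mixture
        from scipy.stats import truncnorm

        spec, tracks, _ = small_proteome
        def sf70(mu, sd):
            a, b = (0 - mu) / sd, (100 - mu) / sd
            return truncnorm.sf(70, a, b, loc=mu, scale=sd)

        f_cf = spec.frac_cf_of_disordered
        mu_cf, sd_cf = spec.plddt_params["disordered_cf"]
        mu_n, sd_n = spec.plddt_params["disordered_non_cf"]
        expected = f_cf * sf70(mu_cf, sd_cf) + (1 - f_cf) * sf70(mu_n, sd_n)

        out = bin_residues(tracks)
        dis = out.xs("disordered", level="order_class")
        realized = (
            dis.loc[["confident", "very_confident"], "count"].sum()
            / dis["count"].sum()
        )
        assert realized == pytest.approx(expected, abs=0.02)


class TestSegmentation:
    def test_two_segments(self):
        segs = extract_idr_segments(_track([0.6, 0.7, 0.2, 0.9, 0.9]))
        assert [(s.start, s.end) for s in segs] == [(1, 2), (4, 5)]

    def test_no_segments_below_threshold(self):
        assert extract_idr_segments(_track([0.4] * 6)) == []

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            scores = rng.random(rng.integers(1, 60))
            track = _track(scores)
            got = [(s.start, s.end) for s in extract_idr_segments(track)]
            assert got == _oracle_segments(scores, 0.5)

    def test_segments_tile_thresholded_set(self, rng):
        scores = rng.random(500)
        track = _track(scores)
        covered = np.zeros(500, dtype=bool)
        for s in extract_idr_segments(track):
            assert not covered[s.start - 1 : s.end].any()
            covered[s.start - 1 : s.end] = True
        np.testing.assert_array_equal(covered, scores >= 0.5)


class TestHighPlddtFilter:
    def test_kept_when_run_long_enough(self):
        track = _track([0.9] * 12, [75.0] * 12)
        segs = extract_idr_segments(track)
        assert filter_segments_high_plddt(segs, [track]) == segs

    def test_dropped_when_longest_run_short(self):
        track = _track([0.9] * 12, [75.0] * 9 + [40.0] * 3)
        segs = extract_idr_segments(track)
        assert filter_segments_high_plddt(segs, [track]) == []

    def test_matches_run_length_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 80))
            track = _track(rng.random(n), rng.uniform(0, 100, n))
            segs = extract_idr_segments(track)
            kept = set(
                (s.start, s.end)
                for s in filter_segments_high_plddt(segs, [track], 70, 10)
            )
            for s in segs:
                runs = _oracle_segments(track.plddt[s.start - 1 : s.end], 70)
                longest = max((b - a + 1 for a, b in runs), default=0)
                assert ((s.start, s.end) in kept) == (longest >= 10)

    @given(
        min_plddt=st.sampled_from([50.0, 70.0, 90.0]),
        min_consecutive=st.integers(1, 30),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_both_parameters(self, min_plddt, min_consecutive, seed):
        rng = np.random.default_rng(seed)
        track = _track(rng.random(100), rng.uniform(0, 100, 100))
        segs = extract_idr_segments(track)
        base = set(
            (s.start, s.end)
            for s in filter_segments_high_plddt(segs, [track], min_plddt, min_consecutive)
        )
        stricter = set(
            (s.start, s.end)
            for s in filter_segments_high_plddt(
                segs, [track], min_plddt + 5, min_consecutive + 2
            )
        )
        assert stricter <= base


class TestProteomeSummary:
    def test_all_ordered_reports_absent(self):
        summary = proteome_summary([_track([0.1] * 10)])
        assert summary["pct_disordered"] == 0.0
        assert summary["pct_disordered_plddt_ge_70"] is None

    def test_hand_arithmetic(self):
        track = _track(
            [0.9, 0.9, 0.9, 0.9] + [0.1] * 6,
            [80.0, 75.0, 40.0, 30.0] + [90.0] * 6,
        )
        s = proteome_summary([track])
        assert s["pct_disordered"] == pytest.approx(40.0)
        assert s["pct_disordered_plddt_ge_70"] == pytest.approx(50.0)
        assert s["pct_total_cf_plddt_ge_70"] == pytest.approx(20.0)

    def test_recovers_generator_fractions(self, small_proteome):
        spec, tracks, _ = small_proteome
        s = proteome_summary(tracks)
        assert s["pct_disordered"] / 100 == pytest.approx(
            spec.frac_disordered, abs=0.02
        )
        # CF residues dominate the confident disordered fraction
        assert s["pct_disordered_plddt_ge_70"] / 100 == pytest.approx(
            spec.frac_cf_of_disordered, abs=0.02
        )
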