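"""Tests for site-level stoichiometry aggregation and analyses."""

import numpy as np
import pandas as pd
import pytest

from m6aread.sites import (
    chromosome_profile,
    compare_conditions,
    filter_reads,
    group_stoichiometry,
    proximity_match,
    site_stoichiometry,
    titration_slope,
)


def calls_at_site(probs, contig="chr1", position=100, strand="+", motif="GGACT"):
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(len(probs))],
            "contig": contig,
            "position": position,
            "strand": strand,
            "motif": motif,
            "prob": probs,
        }
    )


class TestStoichiometry:
    def test_all_modified_reads(self):
        sites = site_stoichiometry(calls_at_site([0.9, 0.8, 1.0]), min_coverage=1)
        assert sites.loc[0, "stoichiometry"] == 1.0
        assert sites.loc[0, "coverage"] == 3

    def test_half_threshold_counts_as_modified(self):
        # Theta(P - 0.5) with >=: 0.5, 0.6, 0.9 count, 0.4 does not
        sites = site_stoichiometry(calls_at_site([0.4, 0.5, 0.6, 0.9]), min_coverage=1)
        assert sites.loc[0, "stoichiometry"] == 0.75

    def test_low_coverage_site_suppressed(self):
        calls = calls_at_site([0.9] * 49)
        assert site_stoichiometry(calls, min_coverage=50).empty
        assert len(site_stoichiometry(calls_at_site([0.9] * 50), min_coverage=50)) == 1

    def test_invariant_under_read_permutation(self):
        rng = np.random.default_rng(0)
        calls = pd.concat(
            [
                calls_at_site(rng.random(30), position=10),
                calls_at_site(rng.random(40), position=20),
            ],
            ignore_index=True,
        )
        a = site_stoichiometry(calls, min_coverage=1)
        b = site_stoichiometry(calls.sample(frac=1.0, random_state=1), min_coverage=1)
        pd.testing.assert_frame_equal(a, b)

    def test_stoichiometry_in_unit_interval_and_integer_counts(self):
        rng = np.random.default_rng(1)
        sites = site_stoichiometry(calls_at_site(rng.random(37)), min_coverage=1)
        s, n = sites.loc[0, "stoichiometry"], sites.loc[0, "coverage"]
        assert 0.0 <= s <= 1.0
        assert (s * n) == pytest.approx(round(s * n))


class TestFilterReads:
    def test_mapq_boundary_inclusive(self):
        df = pd.DataFrame({"read_id": ["a", "b"], "mapq": [50, 49]})
        kept = filter_reads(df)
        assert list(kept["read_id"]) == ["a"]

    def test_empty_input(self):
        assert filter_reads(pd.DataFrame({"read_id": [], "mapq": []})).empty

    def test_missing_mapq_removed_with_warning(self):
        df = pd.DataFrame({"read_id": ["a", "b"], "mapq": [60, None]})
        with pytest.warns(UserWarning, match="without mapq"):
            kept = filter_reads(df)
        assert list(kept["read_id"]) == ["a"]


def site_frame(positions, s_values, contig="chr1", strand="+"):
    return pd.DataFrame(
        {
            "contig": contig,
            "position": positions,
            "strand": strand,
            "motif": "GGACT",
            "coverage": 100,
            "stoichiometry": s_values,
        }
    )


class TestCompareConditions:
    def test_identical_conditions_fill_diagonal(self):
        rng = np.random.default_rng(2)
        sites = site_frame(np.arange(50), rng.random(50))
        cmp = compare_conditions(sites, sites)
        # (s, s) always falls on the diagonal of the joint histogram
        assert np.trace(cmp.hist) == 50

    def test_bin_counts_conserve_shared_sites(self):
        rng = np.random.default_rng(3)
        a = site_frame(np.arange(80), rng.random(80))
        b = site_frame(np.arange(40, 120), rng.random(80))
        cmp = compare_conditions(a, b)
        assert cmp.hist.sum() == len(cmp.shared) == 40
        assert cmp.n_only_a == 40 and cmp.n_only_b == 40

    def test_knockout_mass_sits_below_diagonal(self):
        rng = np.random.default_rng(4)
        s_wt = rng.uniform(0.3, 1.0, 60)
        wt = site_frame(np.arange(60), s_wt)
        ko = site_frame(np.arange(60), 0.1 * s_wt)
        cmp = compare_conditions(wt, ko)
        below = np.tril(cmp.hist, k=-1).sum()  # S_ko < S_wt bins
        assert below == 60

    def test_no_shared_sites_rejected(self):
        a = site_frame([1], [0.5])
        b = site_frame([2], [0.5])
        with pytest.raises(ValueError, match="shared"):
            compare_conditions(a, b)


class TestTitrationSlope:
    def test_exact_identity_recovered(self):
        x = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        fit = titration_slope(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.stderr == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_zero_reference_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            titration_slope([0.1, 0.2, 0.3], [0.5, 0.5, 0.5])

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            titration_slope([0.1], [0.2])


class TestChromosomeProfile:
    def test_single_site_occupies_one_bin(self):
        sites = site_frame([5000], [0.7])
        prof = chromosome_profile(sites, contig_length=100_000, n_bins=100)
        assert prof.medians[5] == 0.7
        assert np.isnan(np.delete(prof.medians, 5)).all()

    def test_constant_stoichiometry_everywhere(self):
        sites = site_frame(np.arange(0, 100_000, 997), 0.5)
        prof = chromosome_profile(sites, contig_length=100_000, n_bins=50)
        filled = prof.medians[~np.isnan(prof.medians)]
        assert (filled == 0.5).all()

    def test_matches_brute_force_medians(self):
        rng = np.random.default_rng(5)
        pos = rng.choice(100_000, size=300, replace=False)
        sites = site_frame(pos, rng.random(300))
        n_bins, length = 64, 100_000
        prof = chromosome_profile(sites, contig_length=length, n_bins=n_bins)
        for b in range(n_bins):
            mask = (pos * n_bins // length) == b
            if mask.any():
                assert prof.medians[b] == pytest.approx(
                    float(np.median(sites["stoichiometry"].to_numpy()[mask]))
                )
            else:
                assert np.isnan(prof.medians[b])

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            chromosome_profile(site_frame([101], [0.5]), contig_length=100)


def peaks_frame(positions, contig="chr1", strand="+"):
    return pd.DataFrame(
        {"contig": contig, "position": positions, "strand": strand, "name": "peak"}
    )


class TestProximityMatch:
    def test_within_five_nt_matches(self):
        res = proximity_match(site_frame([100], [0.9]), peaks_frame([104]))
        assert res.fraction == 1.0

    def test_six_nt_does_not_match(self):
        res = proximity_match(site_frame([100], [0.9]), peaks_frame([106]))
        assert res.fraction == 0.0

    def test_empty_peak_list(self):
        res = proximity_match(site_frame([100], [0.9]), peaks_frame([]))
        assert res.fraction == 0.0 and res.n_selected == 1

    def test_strand_must_agree(self):
        res = proximity_match(
            site_frame([100], [0.9], strand="+"), peaks_frame([100], strand="-")
        )
        assert res.fraction == 0.0

    def test_low_stoichiometry_sites_excluded(self):
        sites = site_frame([100, 200], [0.9, 0.2])
        res = proximity_match(sites, peaks_frame([100, 200]), s_min=0.5)
        assert res.n_selected == 1 and res.fraction == 1.0


class TestGroupStoichiometry:
    def test_single_group_reduces_to_site_stoichiometry(self):
        calls = calls_at_site([0.9, 0.1, 0.6, 0.7]).assign(group_id="tx0")
        grouped = group_stoichiometry(calls, min_coverage=1)
        pooled = site_stoichiometry(calls, min_coverage=1)
        assert grouped.loc[0, "stoichiometry"] == pooled.loc[0, "stoichiometry"]

    def test_two_isoforms_recovered_within_binomial_error(self):
        rng = np.random.default_rng(6)
        rows = []
        for gid, s_true in (("txA", 0.9), ("txB", 0.1)):
            mod = rng.random(200) < s_true
            probs = np.where(mod, 0.99, 0.01)
            rows.append(calls_at_site(probs).assign(group_id=gid))
        calls = pd.concat(rows, ignore_index=True)
        calls["read_id"] = [f"r{i}" for i in range(len(calls))]
        grouped = group_stoichiometry(calls, min_coverage=50).set_index("group_id")
        for gid, s_true in (("txA", 0.9), ("txB", 0.1)):
            se = np.sqrt(s_true * (1 - s_true) / 200)
            assert grouped.loc[gid, "stoichiometry"] == pytest.approx(
                s_true, abs=3 * se
            )

    def test_small_group_suppressed_while_pooled_site_passes(self):
        a = calls_at_site([0.9] * 40).assign(group_id="txA")
        b = calls_at_site([0.9] * 20).assign(group_id="txB")
        calls = pd.concat([a, b], ignore_index=True)
        calls["read_id"] = [f"r{i}" for i in range(len(calls))]
        grouped = group_stoichiometry(calls, min_coverage=50)
        pooled = site_stoichiometry(calls, min_coverage=50)
        assert grouped.empty and len(pooled) == 1

    def test_missing_group_column_rejected(self):
        with pytest.raises(ValueError, match="group_id"):
            group_stoichiometry(calls_at_site([0.5]))
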