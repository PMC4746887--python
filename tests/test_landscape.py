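"""Jukes-Cantor correction, divergence landscapes, coverage-table
arithmetic (checked against printed worked examples) and the
genome-size ~ TE-content regression."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teleomob.io import RepeatHit, TEClass
from teleomob.landscape import (
    CoverageRow,
    SizeTEPoint,
    coverage_table,
    jc_correct,
    landscape,
    rollup_rows,
    size_te_regression,
)


def _series_jc(D, terms=60):
    """Independent oracle: power series K = 75 * sum((D/75)^n / n)."""
    x = D / 75.0
    return 75.0 * sum(x ** n / n for n in range(1, terms + 1))


class TestJcCorrect:
    def test_zero_maps_to_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_d10_matches_series_oracle(self):
        assert jc_correct(10.0) == pytest.approx(10.732563, abs=1e-6)
        assert jc_correct(10.0) == pytest.approx(_series_jc(10.0), abs=1e-9)

    def test_matches_direct_formula_on_grid(self):
        D = np.linspace(0, 70, 141)
        direct = -300.0 / 4.0 * np.log(1 - D * 4.0 / 300.0)
        assert np.allclose(jc_correct(D), direct, atol=1e-9)

    def test_domain_boundary(self):
        assert jc_correct(74.9) > 490  # large but finite
        with pytest.raises(ValueError):
            jc_correct(75.0)
        with pytest.raises(ValueError):
            jc_correct(-0.1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=74.0))
    def test_monotone_convex_and_dominates(self, d):
        k = jc_correct(d)
        assert k >= d
        eps = min(0.01, (74.9 - d) / 2)
        assert jc_correct(d + eps) > k
        # convexity: slope increases
        lo = (jc_correct(d) - jc_correct(d - min(0.01, d / 2))) / min(0.01, d / 2)
        hi = (jc_correct(d + eps) - jc_correct(d)) / eps
        assert hi >= lo - 1e-9

    def test_round_trip_recovers_simulated_rates(self):
        """Mutating 100 kb at per-site proportions 5/10/20 %, measuring D
        and correcting recovers the true rate within 0.5 points."""
        from teleomob.simulate import mutate_sequence, random_consensus

        rng = np.random.default_rng(17)
        seq = random_consensus(100_000, rng)
        for k_true in (5.0, 10.0, 20.0):
            jc_sites = _jc_process(seq, k_true / 100, rng)
            D = 100 * sum(a != b for a, b in zip(jc_sites, seq)) / len(seq)
            assert abs(jc_correct(D) - k_true) <= 0.5


def _jc_process(seq, k, rng):
    """Continuous-time Jukes-Cantor process at k expected substitutions
    per site: Poisson number of events per site, each a uniform draw
    among the 3 alternatives."""
    bases = "ACGT"
    arr = list(seq)
    events = rng.poisson(k, size=len(arr))
    for i, n in enumerate(events):
        for _ in range(n):
            arr[i] = bases[(bases.index(arr[i]) + 1 + rng.integers(3)) % 4]
    return "".join(arr)


def _hit(start, end, D, superfamily="hAT-Ac", te_class=TEClass.DNA, family=None):
    return RepeatHit(
        query_genome_seq="g", start=start, end=end, strand="+",
        library_name="x", te_class=te_class, superfamily=superfamily,
        family=family, divergence_D=D,
    )


class TestLandscape:
    def test_single_hit_placement(self):
        bins, spill = landscape([_hit(1, 500, 9.0)], 50_000)
        assert spill == {}
        assert len(bins) == 1
        b = bins[0]
        assert (b.k_low, b.k_high, b.bp) == (9.0, 10.0, 500)  # K(9) ~ 9.59
        assert b.genome_fraction == pytest.approx(0.01)

    def test_zero_divergence_all_in_first_bin(self):
        bins, _ = landscape([_hit(1, 100, 0.0), _hit(201, 300, 0.4)], 1000)
        assert {(b.k_low, b.k_high) for b in bins} == {(0.0, 1.0)}
        assert sum(b.bp for b in bins) == 200

    def test_mass_conservation_with_spill(self):
        hits = [_hit(1, 100, 5.0), _hit(201, 300, 80.0), _hit(401, 500, 12.0)]
        bins, spill = landscape(hits, 1000)
        assert sum(b.bp for b in bins) + sum(spill.values()) == 300
        assert spill == {"hAT-Ac": 100}

    def test_raw_binning_switch(self):
        bins, _ = landscape([_hit(1, 100, 9.7)], 1000, use_correction=False)
        assert bins[0].k_low == 9.0  # raw D binned; corrected would be 10.x

    def test_end_to_end_modal_bin(self, point_mass_sim, point_mass_hits):
        """Simulated 10 % point-mass superfamily: the landscape mode
        lands where the JC correction puts 10 % divergence (K ~ 10.7)."""
        genome, _ = point_mass_sim
        bins, spill = landscape(point_mass_hits, len(genome.seq))
        assert not spill
        modal = max(bins, key=lambda b: b.bp)
        assert 9.0 <= modal.k_low and modal.k_high <= 12.0
        # mass conservation against the hits exactly
        assert sum(b.bp for b in bins) == sum(h.length for h in point_mass_hits)

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            landscape([], 1000, bin_width=0)


class TestCoverageTable:
    def test_empty_hits_empty_table(self):
        assert coverage_table([], 1000) == []

    def test_fragment_counts_and_union_bp(self):
        hits = [_hit(1, 100, 1.0), _hit(51, 150, 2.0), _hit(301, 400, 3.0)]
        rows = coverage_table(hits, 1000, "superfamily")
        sf = [r for r in rows if r.level == "superfamily"][0]
        assert sf.count == 3 and sf.bp == 250
        assert sf.pct == pytest.approx(25.0)

    def test_parent_child_additivity(self, spread_hits, spread_sim):
        genome, _ = spread_sim
        rows = coverage_table(spread_hits, len(genome.seq), "superfamily")
        cls = {r.group: r for r in rows if r.level == "class"}
        sfs = [r for r in rows if r.level == "superfamily"]
        assert sum(r.count for r in sfs) == sum(r.count for r in cls.values())
        assert sum(r.bp for r in sfs) == sum(r.bp for r in cls.values())

    # -- printed worked examples: component rows must add to the printed
    #    superfamily totals --
    def test_zebrafish_hAT_totals(self):
        children = [
            CoverageRow("family", "Ac", 222707, 57824458, 4.22),
            CoverageRow("family", "Charlie", 133312, 26390661, 1.92),
            CoverageRow("family", "Other", 97917, 19890417, 1.45),
            CoverageRow("family", "Unclassified", 254779, 56860037, 4.15),
        ]
        total = rollup_rows(children, "hAT", "superfamily")
        assert total.bp == 160965573
        assert total.count == 708715

    def test_zebrafish_tc1mariner_totals(self):
        children = [
            CoverageRow("family", "Tc1", 122464, 47220045, 3.44),
            CoverageRow("family", "pogo", 5844, 1778814, 0.13),
            CoverageRow("family", "Other", 4632, 1895302, 0.14),
            CoverageRow("family", "Unclassified", 59130, 13263436, 0.97),
        ]
        total = rollup_rows(children, "Tc1/Mariner", "superfamily")
        assert total.bp == 64157597
        assert total.count == 192070

    @pytest.mark.parametrize(
        "species,components,expected_bp",
        [
            ("medaka", [7436916, 20423089, 1871492, 1634286], 31365783),
            ("stickleback", [3811137, 4133497, 511394, 1274694], 9730722),
            ("tetraodon", [339847, 1794070, 362560, 217322], 2713799),
        ],
    )
    def test_hAT_totals_other_species(self, species, components, expected_bp):
        children = [CoverageRow("family", f"c{i}", 0, bp, 0.0) for i, bp in enumerate(components)]
        assert rollup_rows(children, "hAT", "superfamily").bp == expected_bp

    def test_unknown_hierarchy_level(self):
        with pytest.raises(ValueError):
            coverage_table([], 1000, "order")


class TestSizeTERegression:
    def test_collinear_points_perfect_correlation(self):
        pts = [SizeTEPoint(f"s{i}", 100.0 + 50 * i, 5.0 + 2 * i) for i in range(4)]
        slope, intercept, r = size_te_regression(pts)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(0.04)

    def test_matches_covariance_oracle(self):
        pts = [
            SizeTEPoint("a", 120.0, 8.0),
            SizeTEPoint("b", 400.0, 21.0),
            SizeTEPoint("c", 900.0, 33.0),
            SizeTEPoint("d", 1400.0, 55.0),
        ]
        x = np.array([p.genome_size_mb for p in pts])
        y = np.array([p.te_fraction_pct for p in pts])
        slope, intercept, r = size_te_regression(pts)
        cov = ((x - x.mean()) * (y - y.mean())).sum()
        assert slope == pytest.approx(cov / ((x - x.mean()) ** 2).sum())
        assert r == pytest.approx(cov / math.sqrt(((x - x.mean()) ** 2).sum()
                                                  * ((y - y.mean()) ** 2).sum()))

    def test_published_four_species_trend_positive(self):
        """TE fraction rises with genome size across the four teleosts:
        sizes implied by each species' printed (% , Mb) coverage pair."""
        printed = {  # total interspersed repeats: (% of genome, Mb)
            "zebrafish": (56.49, 773.70),
            "medaka": (33.70, 236.28),
            "stickleback": (14.21, 63.48),
            "tetraodon": (7.13, 21.55),
        }
        pts = [
            SizeTEPoint(sp, mb / (pct / 100), pct) for sp, (pct, mb) in printed.items()
        ]
        slope, _, r = size_te_regression(pts)
        assert slope > 0 and r > 0

    def test_too_few_or_degenerate(self):
        with pytest.raises(ValueError):
            size_te_regression([SizeTEPoint("a", 1, 1), SizeTEPoint("b", 2, 2)])
        with pytest.raises(ValueError):
            size_te_regression([SizeTEPoint(s, 100.0, float(i + 1)) for i, s in enumerate("abc")])
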