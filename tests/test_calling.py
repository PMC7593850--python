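"""Methylation-ratio calling, validation and distribution summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import oracle_validate
from picomethyl import calling, genome as gn


def write_bedgraph(tmp_path, rows, name="s_CpG.bedGraph", track=False):
    p = tmp_path / name
    lines = ["track type=bedGraph"] if track else []
    lines += ["\t".join(str(x) for x in r) for r in rows]
    p.write_text("\n".join(lines) + "\n")
    return p


class TestReadBedgraph:
    def test_basic_row(self, tmp_path):
        df = calling.read_bedgraph_counts(write_bedgraph(tmp_path, [("c1", 10, 11, 50.0, 5, 5)]))
        assert df.loc[0, "ratio"] == 0.5
        assert df.loc[0, "pos"] == 10
        assert df.loc[0, "coverage"] == 10

    def test_zero_methylation(self, tmp_path):
        df = calling.read_bedgraph_counts(write_bedgraph(tmp_path, [("c1", 0, 1, 0.0, 0, 20)]))
        assert df.loc[0, "ratio"] == 0.0

    def test_track_line_skipped(self, tmp_path):
        df = calling.read_bedgraph_counts(
            write_bedgraph(tmp_path, [("c1", 3, 4, 100.0, 7, 0)], track=True)
        )
        assert len(df) == 1 and df.loc[0, "ratio"] == 1.0

    def test_percent_disagreement_warns_counts_win(self, tmp_path, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            df = calling.read_bedgraph_counts(
                write_bedgraph(tmp_path, [("c1", 0, 1, 90.0, 5, 5)])
            )
        assert df.loc[0, "ratio"] == 0.5
        assert any("percent column disagrees" in m for m in caplog.messages)

    @pytest.mark.parametrize(
        "row",
        [("c1", 0, 2, 50.0, 5, 5), ("c1", 0, 1, 50.0, -1, 5), ("c1", 0, 1, "x", "y", 5)],
    )
    def test_rejects_malformed(self, tmp_path, row):
        with pytest.raises(calling.BedGraphError):
            calling.read_bedgraph_counts(write_bedgraph(tmp_path, [row]))


class TestComputeRatio:
    @pytest.mark.parametrize("m,u,expected", [(5, 5, 0.5), (41, 9, 0.82), (0, 20, 0.0)])
    def test_values(self, m, u, expected):
        assert calling.compute_ratio(m, u) == pytest.approx(expected)

    def test_zero_coverage_errors(self):
        with pytest.raises(ZeroDivisionError):
            calling.compute_ratio(0, 0)


@pytest.fixture
def toy_catalog():
    return gn.enumerate_sites({"c1": "ACGTTCGACCAGGCATCGN", "c2": "CGCG"})


def make_calls(rows):
    df = pd.DataFrame(rows, columns=["contig", "pos", "n_meth", "n_unmeth"])
    df["coverage"] = df["n_meth"] + df["n_unmeth"]
    df["ratio"] = df["n_meth"] / df["coverage"]
    return df


class TestValidateCalls:
    def test_coverage_threshold_boundary(self, toy_catalog):
        calls = make_calls([("c1", 2, 10, 9), ("c1", 6, 10, 10)])  # cov 19 vs 20
        prof = calling.validate_calls(calls, toy_catalog, min_coverage=20)
        assert list(prof.calls["pos"]) == [6]
        assert prof.drop_tally["low_coverage"] == 1

    def test_position_absent_from_catalog_dropped(self, toy_catalog):
        calls = make_calls([("c1", 0, 30, 0)])  # 'A' position, not a site
        prof = calling.validate_calls(calls, toy_catalog)
        assert prof.calls.empty
        assert prof.drop_tally["not_in_catalog"] == 1

    def test_context_inherited_from_catalog(self, toy_catalog):
        calls = make_calls([("c1", 2, 15, 10)])
        calls["file_context"] = "CHH"  # wrong on purpose
        prof = calling.validate_calls(calls, toy_catalog)
        assert prof.calls.loc[0, "context"] == "CpG"
        assert prof.drop_tally["context_reassigned"] == 1

    def test_matches_bruteforce_filter(self, toy_catalog, rng):
        """Retained set equals an independent loop over the same rows."""
        keys = list(map(tuple, toy_catalog.sites[["contig", "pos"]].itertuples(index=False)))
        ctx = dict(
            zip(keys, toy_catalog.sites["context"])
        )
        rows = []
        for _ in range(200):
            if rng.random() < 0.7:
                contig, pos = keys[rng.integers(len(keys))]
            else:
                contig, pos = "c1", int(rng.integers(0, 25))
            cov = int(rng.integers(0, 40))
            rows.append((contig, pos, cov, 0, cov))
        df = pd.DataFrame(rows, columns=["contig", "pos", "n_meth", "n_unmeth", "coverage"])
        df = df.drop_duplicates(["contig", "pos"])
        df["ratio"] = np.where(df["coverage"] > 0, 1.0, np.nan)
        prof = calling.validate_calls(df, toy_catalog, min_coverage=20)
        expected = oracle_validate(
            df[["contig", "pos", "coverage"]].itertuples(index=False),
            set(keys), ctx, 20,
        )
        got = list(map(tuple, prof.calls[["contig", "pos"]].itertuples(index=False)))
        assert sorted(got) == sorted(expected)


class TestSampleFraction:
    def _profile(self, ratios, covs=None):
        n = len(ratios)
        covs = covs or [10] * n
        calls = pd.DataFrame(
            {
                "contig": "c1",
                "pos": range(n),
                "strand": "+",
                "context": "CpG",
                "n_meth": [round(r * c) for r, c in zip(ratios, covs)],
                "n_unmeth": [c - round(r * c) for r, c in zip(ratios, covs)],
                "coverage": covs,
                "ratio": ratios,
            }
        )
        return calling.SampleProfile("s", 4, "control", 1, calls)

    def test_unweighted_mean(self):
        assert calling.sample_fraction(self._profile([0.1, 0.2, 0.3]), "CpG") == pytest.approx(0.2)

    def test_all_zero(self):
        assert calling.sample_fraction(self._profile([0.0, 0.0]), "CpG") == 0.0

    def test_weighted_variant_pools_reads(self):
        prof = self._profile([0.0, 1.0], covs=[30, 10])
        assert calling.sample_fraction(prof, "CpG", weighted=True) == pytest.approx(10 / 40)

    def test_empty_context_errors(self):
        with pytest.raises(ValueError):
            calling.sample_fraction(self._profile([0.5]), "CHG")

    def test_merged_profile_between_components(self, rng):
        """Fraction of a merged disjoint profile is a weighted mean of the
        two component fractions, hence lies between them."""
        r1 = list(rng.uniform(0, 0.4, 10))
        r2 = list(rng.uniform(0.5, 1.0, 25))
        f1 = calling.sample_fraction(self._profile(r1), "CpG")
        prof2 = self._profile(r2)
        prof2.calls["pos"] += 100
        f2 = calling.sample_fraction(prof2, "CpG")
        merged = self._profile(r1)
        merged.calls = pd.concat([merged.calls, prof2.calls], ignore_index=True)
        fm = calling.sample_fraction(merged, "CpG")
        assert min(f1, f2) <= fm <= max(f1, f2)
        assert fm == pytest.approx((len(r1) * f1 + len(r2) * f2) / (len(r1) + len(r2)))


class TestSummaries:
    def test_single_sample_identity(self):
        tbl = pd.DataFrame({"CpG": [0.123], "CHG": [0.008]})
        out = calling.summarize_fraction_table(tbl)
        assert out["CpG"] == 12.3 and out["CHG"] == 0.8

    def test_genome_wide_percent_zero_and_saturation(self):
        assert calling.genome_wide_percent({"CpG": 0.0}, {"CpG": 100}, 1000) == 0.0
        assert calling.genome_wide_percent({"CpG": 1.0}, {"CpG": 1000}, 1000) == 100.0
        with pytest.raises(ValueError):
            calling.genome_wide_percent({"CpG": 0.1}, {"CpG": 1}, 0)


class TestRatioHistogram:
    def test_exclusion_below_ceiling(self):
        h = calling.ratio_histogram(np.array([0.00, 0.04]))
        assert h.sum() == 0

    def test_binning(self):
        h = calling.ratio_histogram(np.array([0.06, 0.95, 0.97]))
        assert h.iloc[0] == 1 and h.iloc[9] == 2 and h.sum() == 3

    def test_top_edge_inclusive_and_sum_property(self, rng):
        r = np.concatenate([rng.uniform(0, 1, 500), [1.0]])
        h = calling.ratio_histogram(r)
        assert h.sum() == (r >= 0.05).sum()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            calling.ratio_histogram(np.array([1.2]))

    def test_mixture_mass_matches_analytic_cdf(self, rng):
        """Bin masses of draws from a two-component Beta mixture match the
        closed-form mixture CDF within a binomial confidence band."""
        w, n = 0.8, 10_000
        comp = rng.random(n) < w
        r = np.where(comp, rng.beta(0.5, 10, n), rng.beta(20, 3, n))
        h = calling.ratio_histogram(r, exclusion_ceiling=0.05)

        def mix_cdf(x):
            return w * stats.beta.cdf(x, 0.5, 10) + (1 - w) * stats.beta.cdf(x, 20, 3)

        retained_mass = 1 - mix_cdf(0.05)
        edges = np.arange(0.0, 1.01, 0.1)
        for i in range(10):
            lo = max(edges[i], 0.05)
            expect_p = max(mix_cdf(edges[i + 1]) - mix_cdf(lo), 0.0)
            n_expected = n * expect_p
            # 4-sigma binomial band around the expectation
            sd = np.sqrt(n * expect_p * (1 - expect_p))
            assert abs(h.iloc[i] - n_expected) <= 4 * sd + 1
        assert h.sum() == pytest.approx(n * retained_mass, abs=4 * np.sqrt(n * 0.25))


class TestBimodalitySummary:
    def test_strict_boundaries(self):
        out = calling.bimodality_summary(np.array([0.2, 0.8]))
        assert out == {"unmethylated": 0.0, "moderate": 0.0, "methylated": 0.0}

    def test_degenerate_all_moderate(self):
        out = calling.bimodality_summary(np.array([0.5, 0.5]))
        assert out == {"unmethylated": 0.0, "moderate": 1.0, "methylated": 0.0}

    def test_published_high_bin_share(self):
        """48,667 of 699,653 called CpG sites above ratio 0.8 is ~7%."""
        r = np.concatenate([np.full(48_667, 0.9), np.full(699_653 - 48_667, 0.05)])
        out = calling.bimodality_summary(r)
        assert 100 * out["methylated"] == pytest.approx(7.0, abs=0.1)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            calling.bimodality_summary(np.array([]))
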