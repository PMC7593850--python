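"""Simulator determinism, mixture moments and the observation model."""

import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from picomethyl import genome as gn
from picomethyl import simulate as sim


class TestSimulateGenome:
    def test_seed_reproducibility_byte_identical(self, tmp_path):
        cfg = small_config(seed=3)
        p1 = sim.simulate_experiment(cfg, tmp_path / "run1")
        p2 = sim.simulate_experiment(cfg, tmp_path / "run2")
        for name in ("fasta", "gff3", "sample_sheet", "truth", "registry"):
            assert filecmp.cmp(p1[name], p2[name], shallow=False), name
        b1 = sorted((tmp_path / "run1" / "bedgraph").iterdir())
        b2 = sorted((tmp_path / "run2" / "bedgraph").iterdir())
        assert [p.name for p in b1] == [p.name for p in b2]
        for f1, f2 in zip(b1, b2):
            assert filecmp.cmp(f1, f2, shallow=False), f1.name

    def test_gc_zero_means_no_cytosines(self):
        cfg = dataclasses.replace(
            small_config(), gc_fraction=0.0, contig_lengths=(2000,), n_genes=1
        )
        genome, _ = sim.simulate_genome(cfg)
        assert set(genome["contig1"]) <= {"A", "T"}
        cat = gn.enumerate_sites(genome)
        assert len(cat.sites) == 0 and cat.n_sites == 0

    def test_gc_fraction_near_target(self):
        cfg = dataclasses.replace(small_config(), contig_lengths=(50_000,), n_genes=10)
        genome, _ = sim.simulate_genome(cfg)
        seq = genome["contig1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - cfg.gc_fraction) < 0.02

    def test_cpg_count_matches_iid_expectation(self):
        """Under i.i.d. bases, each strand yields a CpG site wherever a CG
        dinucleotide occurs: expected count = 2 (L-1) (gc/2)^2 per contig."""
        L = 100_000
        cfg = dataclasses.replace(
            small_config(seed=11), contig_lengths=(L,), n_genes=10
        )
        genome, _ = sim.simulate_genome(cfg)
        cat = gn.enumerate_sites(genome)
        q = cfg.gc_fraction / 2
        expected = 2 * (L - 1) * q * q
        # CG occurrences are almost independent; 5-sigma binomial band
        sd = np.sqrt(2 * (L - 1) * q * q * (1 - q * q))
        assert abs(cat.context_totals["CpG"] - expected) < 5 * sd

    def test_genes_non_overlapping_with_spacing(self):
        cfg = small_config()
        _, genes = sim.simulate_genome(cfg)
        assert len(genes) == cfg.n_genes
        for _, grp in genes.groupby("contig"):
            grp = grp.sort_values("start")
            gaps = grp["start"].to_numpy()[1:] - grp["end"].to_numpy()[:-1]
            assert (gaps >= cfg.min_gene_spacing).all()

    def test_infeasible_packing_raises(self):
        cfg = dataclasses.replace(small_config(), contig_lengths=(3000,), n_genes=40)
        with pytest.raises(ValueError, match="pack"):
            sim.simulate_genome(cfg)


@pytest.fixture(scope="module")
def catalog():
    cfg = small_config()
    genome, _ = sim.simulate_genome(cfg)
    return gn.enumerate_sites(genome)


@pytest.fixture(scope="module")
def truth(catalog):
    cfg = small_config()
    return sim.simulate_truth(catalog, cfg), cfg


class TestSimulateTruth:
    def test_degenerate_high_mixture(self, catalog):
        cfg = small_config()
        cfg = dataclasses.replace(
            cfg,
            mixtures={
                ctx: sim.BetaMixture((0.0, 0.0, 1.0), (1.0, 1.0, 1000.0), (1.0, 1.0, 1.0))
                for ctx in ("CpG", "CHG", "CHH")
            },
        )
        truth = sim.simulate_truth(catalog, cfg)
        assert (truth.p_true > 0.9).all()

    def test_default_cpg_mean_and_high_mass(self, catalog):
        cfg = small_config(seed=5)
        truth = sim.simulate_truth(catalog, cfg)
        cpg = truth[truth.context == "CpG"].p_true.to_numpy()
        mix = cfg.mixtures["CpG"]
        assert mix.mean == pytest.approx(0.121, abs=1e-9)
        se = cpg.std() / np.sqrt(cpg.size)
        assert abs(cpg.mean() - 0.121) < 3 * se + 0.003
        # heavily methylated share tracks the configured high-component mass
        high = (cpg > 0.8).mean()
        assert abs(high - mix.weights[2]) < 0.02

    def test_reproducible_from_seed(self, catalog):
        cfg = small_config(seed=9)
        t1 = sim.simulate_truth(catalog, cfg)
        t2 = sim.simulate_truth(catalog, cfg)
        assert np.array_equal(t1.p_true, t2.p_true)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sim.BetaMixture((0.5, 0.2, 0.2), (1, 1, 1), (1, 1, 1))


class TestApplyEffects:
    def test_registry_bookkeeping(self, truth):
        base, cfg = truth
        eff = sim.EffectSpec(
            name="probe", n_sites=30, delta_range=(0.14, 0.14), direction="hypo",
            days=[10], treatments=["control"], truth_range=(0.5, 0.95),
        )
        cfg2 = dataclasses.replace(cfg, effects=[eff])
        per_cond, registry = sim.apply_effects(base, cfg2)
        assert len(registry) == 30
        idx = base.reset_index().merge(registry, on=["contig", "pos", "strand"])["index"]
        planted_base = base.p_true.to_numpy()[idx]
        planted_after = per_cond[(10, "control")][idx]
        assert np.allclose(planted_base - planted_after, 0.14)
        untouched = np.setdiff1d(np.arange(len(base)), idx)
        assert np.array_equal(per_cond[(10, "control")][untouched], base.p_true.to_numpy()[untouched])

    def test_clipping_logged(self, truth):
        base, cfg = truth
        eff = sim.EffectSpec(
            name="clip", n_sites=10, delta_range=(0.2, 0.2), direction="hypo",
            days=[10], treatments=["control"], truth_range=(0.0, 0.1),
        )
        per_cond, registry = sim.apply_effects(
            base, dataclasses.replace(cfg, effects=[eff])
        )
        assert registry.attrs["n_clipped"] > 0
        assert per_cond[(10, "control")].min() >= 0.0

    def test_stacked_effects_compose_additively(self, truth):
        """Two effects on overlapping eligible sets compose additively
        before clipping, matching sequential brute-force application."""
        base, cfg = truth
        e1 = sim.EffectSpec(
            name="one", n_sites=50, delta_range=(0.1, 0.1), direction="hypo",
            days=[10], treatments=["control"], truth_range=(0.5, 0.95),
        )
        e2 = sim.EffectSpec(
            name="two", n_sites=50, delta_range=(0.05, 0.05), direction="hypo",
            days=[10], treatments=["control"], truth_range=(0.5, 0.95),
        )
        cfg2 = dataclasses.replace(cfg, effects=[e1, e2])
        per_cond, registry = sim.apply_effects(base, cfg2)
        expected = base.p_true.to_numpy().copy()
        for r in registry.itertuples(index=False):
            i = base.index[
                (base.contig == r.contig) & (base.pos == r.pos) & (base.strand == r.strand)
            ][0]
            expected[i] += r.delta
        np.clip(expected, 0, 1, out=expected)
        assert np.allclose(per_cond[(10, "control")], expected)

    def test_shortfall_raises(self, truth):
        base, cfg = truth
        eff = sim.EffectSpec(
            name="huge", n_sites=10**6, delta_range=(0.1, 0.1), direction="hypo",
        )
        with pytest.raises(ValueError, match="eligible"):
            sim.apply_effects(base, dataclasses.replace(cfg, effects=[eff]))


class TestSimulateCounts:
    def _truth_frame(self, n, p):
        return pd.DataFrame(
            {
                "contig": "c1",
                "pos": np.arange(n),
                "strand": "+",
                "context": "CpG",
                "p_true": np.full(n, p),
            }
        )

    def test_saturated_site_no_nonconversion(self):
        cfg = dataclasses.replace(small_config(), non_conversion=0.0)
        truth = self._truth_frame(500, 1.0)
        counts = sim.simulate_counts_frame(truth, truth.p_true.to_numpy(), cfg, 4, "control", 1)
        covered = counts[counts.coverage > 0]
        assert (covered.ratio == 1.0).all()

    @pytest.mark.parametrize("eps", [0.0, 0.005, 0.02])
    def test_observed_mean_matches_nonconversion(self, eps):
        """Mean observed ratio at truth 0 equals eps within 3 SE."""
        cfg = dataclasses.replace(small_config(), non_conversion=eps)
        n = 20_000
        truth = self._truth_frame(n, 0.0)
        counts = sim.simulate_counts_frame(truth, truth.p_true.to_numpy(), cfg, 4, "control", 1)
        covered = counts[counts.coverage > 0]
        se = np.sqrt(eps * (1 - eps) / covered.coverage.sum()) if eps else 0.001
        assert abs(covered.ratio.mean() - eps) < 3 * se + 1e-4

    def test_expected_ratio_formula(self):
        p = np.array([0.0, 0.3, 1.0])
        assert np.allclose(sim.observed_probability(p, 0.01), [0.01, 0.307, 1.0])

    def test_replicates_differ_but_share_moments(self):
        cfg = small_config()
        truth = self._truth_frame(5000, 0.5)
        c1 = sim.simulate_counts_frame(truth, truth.p_true.to_numpy(), cfg, 4, "control", 1)
        c2 = sim.simulate_counts_frame(truth, truth.p_true.to_numpy(), cfg, 4, "control", 2)
        assert not np.array_equal(c1.n_meth, c2.n_meth)
        assert abs(c1.ratio.mean() - c2.ratio.mean()) < 0.01

    def test_negative_binomial_coverage_overdispersed(self):
        cfg = dataclasses.replace(
            small_config(), coverage_distribution="negative-binomial", nb_dispersion=2.0
        )
        truth = self._truth_frame(20_000, 0.5)
        counts = sim.simulate_counts_frame(truth, truth.p_true.to_numpy(), cfg, 4, "control", 1)
        assert counts.coverage.var() > 2 * counts.coverage.mean()


class TestConfigRoundtrip:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = small_config(seed=13)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = sim.SimulationConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg
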