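"""Synthetic WGBS experiment generator.

Emulates the statistical structure of a bisulfite study on a small haploid
algal genome: an i.i.d.-base genome with a configurable GC fraction and
non-overlapping gene models; a bimodal per-context baseline methylome drawn
from a three-component Beta mixture (most cytosines near 0, a small heavily
methylated component near 0.9); planted condition effects (gradual
nitrogen-starvation hypomethylation over the time course, early
hypomethylation and late hypermethylation under a methyltransferase
inhibitor); and per-replicate binomial read counts at Poisson (or
negative-binomial) coverage with a bisulfite non-conversion rate epsilon, so
an unmethylated cytosine is misread as methylated with probability epsilon:
p_obs = p_true + (1 - p_true) * epsilon.

Default mixture means are 0.121 (CpG), 0.008 (CHG) and 0.009 (CHH); default
coverage is Poisson(50); the default design is days {4,5,6,7,10} x
{control, 5AZA} x 3 replicates on a 100 kb genome.  Everything is
deterministic given (config, seed): per-sample generators are derived from
the master seed with fixed stream keys, so runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import CONTEXTS, SiteCatalog, enumerate_sites

# fixed RNG stream keys so adding a stage never perturbs another stage's draws
_STREAM_GENOME = 1
_STREAM_TRUTH = 2
_STREAM_EFFECTS = 3
_STREAM_COUNTS = 4


@dataclass
class BetaMixture:
    """Three-component (low/mid/high) Beta mixture over [0, 1]."""

    weights: tuple[float, float, float]
    alphas: tuple[float, float, float]
    betas: tuple[float, float, float]

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    @property
    def mean(self) -> float:
        return sum(
            w * a / (a + b) for w, a, b in zip(self.weights, self.alphas, self.betas)
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(3, size=n, p=self.weights)
        a = np.asarray(self.alphas)[comp]
        b = np.asarray(self.betas)[comp]
        return rng.beta(a, b)


def _low_beta_for_mean(target_mean: float, w: tuple[float, float, float],
                       mid_mean: float, high_mean: float, a_low: float) -> tuple[float, float]:
    """Solve the low component's Beta(a, b) so the mixture mean hits target."""
    m_low = (target_mean - w[1] * mid_mean - w[2] * high_mean) / w[0]
    if not 0 < m_low < 1:
        raise ValueError("infeasible mixture mean")
    return a_low, a_low * (1 - m_low) / m_low


def _default_mixtures() -> dict[str, BetaMixture]:
    # CpG: ~83% near-zero, ~7% near 0.9, remainder moderate; overall mean 0.121.
    # CHG/CHH: almost everything near zero with a thin heavily methylated tail
    # (few methylated sites, but high methylation where it occurs).
    out = {}
    specs = {
        "CpG": (0.121, (0.83, 0.10, 0.07), 0.3),
        "CHG": (0.008, (0.991, 0.001, 0.008), 0.05),
        "CHH": (0.009, (0.990, 0.001, 0.009), 0.05),
    }
    for ctx, (mean, w, a_low) in specs.items():
        mid = (5.0, 5.0)       # Beta(5,5), mean 0.5
        high = (45.0, 5.0)     # Beta(45,5), mean 0.9, tight
        a, b = _low_beta_for_mean(mean, w, 0.5, 0.9, a_low)
        out[ctx] = BetaMixture(
            weights=w, alphas=(a, mid[0], high[0]), betas=(b, mid[1], high[1])
        )
    return out


@dataclass
class EffectSpec:
    """A planted methylation change on a subset of eligible sites.

    ``delta_range`` magnitudes are drawn uniformly per site; sign comes from
    ``direction``.  ``ramp=True`` scales each site's delta linearly from 0 on
    the first affected day to full size on the last (a gradual drift);
    otherwise the full delta applies on every affected day.  Eligibility is
    a predicate on context and baseline truth.
    """

    name: str
    n_sites: int
    delta_range: tuple[float, float]  # (low, high) magnitudes, 0 < low <= high
    direction: str  # 'hypo' | 'hyper'
    days: list[int] | None = None  # None = every day
    treatments: list[str] | None = None  # None = every treatment
    context: str = "CpG"
    truth_range: tuple[float, float] = (0.0, 1.0)
    ramp: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("hypo", "hyper"):
            raise ValueError("direction must be 'hypo' or 'hyper'")
        if not (0 < self.delta_range[0] <= self.delta_range[1]):
            raise ValueError("delta_range magnitudes must be positive and ordered")


def default_effects() -> list[EffectSpec]:
    """The default planted-effect set, mirroring the study's qualitative
    findings at a scale suited to a 100 kb genome.

    Nitrogen starvation: gradual hypomethylation of heavily methylated CpG
    sites in both arms across the time course, final deltas in [0.10, 0.36].
    Drug arm: early hypomethylation (days 4-6), late hypermethylation
    (days 7-10) once the inhibitor loses efficacy.
    """
    return [
        EffectSpec(
            name="starvation_hypo", n_sites=150, delta_range=(0.10, 0.36),
            direction="hypo", days=None, treatments=None,
            truth_range=(0.5, 0.95), ramp=True,
        ),
        EffectSpec(
            name="aza_early_hypo", n_sites=100, delta_range=(0.10, 0.30),
            direction="hypo", days=[4, 5, 6], treatments=["5AZA"],
            truth_range=(0.5, 0.95),
        ),
        EffectSpec(
            name="aza_late_hyper", n_sites=150, delta_range=(0.10, 0.30),
            direction="hyper", days=[7, 10], treatments=["5AZA"],
            truth_range=(0.0, 0.6),
        ),
    ]


@dataclass
class SimulationConfig:
    """All simulator parameters; defaults are the scaled study conditions."""

    seed: int = 0
    contig_lengths: tuple[int, ...] = (60_000, 40_000)
    gc_fraction: float = 0.44
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (600, 2000)
    min_gene_spacing: int = 200
    mixtures: dict[str, BetaMixture] = field(default_factory=_default_mixtures)
    coverage_mean: float = 50.0
    coverage_distribution: str = "poisson"  # 'poisson' | 'negative-binomial'
    nb_dispersion: float = 5.0  # NB size parameter when overdispersed
    non_conversion: float = 0.005
    replicates: int = 3
    days: tuple[int, ...] = (4, 5, 6, 7, 10)
    treatments: tuple[str, ...] = ("control", "5AZA")
    effects: list[EffectSpec] = field(default_factory=default_effects)

    def __post_init__(self) -> None:
        if not 0 <= self.non_conversion <= 0.05:
            raise ValueError("non_conversion must be in [0, 0.05]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")

    def conditions(self) -> list[tuple[int, str]]:
        return [(d, t) for t in self.treatments for d in self.days]

    def sample_sheet(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": sample_id(d, t, r),
                "day": d,
                "treatment": t,
                "replicate": r,
            }
            for d, t in self.conditions()
            for r in range(1, self.replicates + 1)
        ]
        return pd.DataFrame(rows)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["mixtures"] = {
            k: BetaMixture(
                weights=tuple(v["weights"]), alphas=tuple(v["alphas"]), betas=tuple(v["betas"])
            )
            for k, v in d.get("mixtures", {}).items()
        } or _default_mixtures()
        d["effects"] = [EffectSpec(**{**e, "delta_range": tuple(e["delta_range"]),
                                      "truth_range": tuple(e["truth_range"])})
                        for e in d.get("effects", [])]
        for key in ("contig_lengths", "gene_length_range", "days", "treatments"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def sample_id(day: int, treatment: str, replicate: int) -> str:
    return f"D{day}_{treatment}_{replicate}"


def _rng(cfg_seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, stream, *extra])


def simulate_genome(cfg: SimulationConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Draw an i.i.d.-base genome and pack non-overlapping gene models.

    Returns (genome dict, genes frame with gene_id/contig/start/end/strand).
    Gene placement walks left to right with random gaps >= min spacing;
    infeasible packing raises.
    """
    rng = _rng(cfg.seed, _STREAM_GENOME)
    gc, at = cfg.gc_fraction / 2, (1 - cfg.gc_fraction) / 2
    genome = {}
    for i, length in enumerate(cfg.contig_lengths):
        bases = rng.choice(np.array(list("ACGT")), size=length, p=[at, gc, gc, at])
        genome[f"contig{i + 1}"] = "".join(bases)

    total_len = sum(cfg.contig_lengths)
    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    need = int(lengths.sum()) + cfg.min_gene_spacing * (cfg.n_genes + len(cfg.contig_lengths))
    if need > total_len:
        raise ValueError(
            f"cannot pack {cfg.n_genes} genes ({need} bp incl. spacing) into {total_len} bp"
        )
    # apportion genes to contigs by length share, then place sequentially
    rows = []
    gi = 0
    contigs = list(genome)
    per_contig = np.floor(
        cfg.n_genes * np.array(cfg.contig_lengths) / total_len
    ).astype(int)
    per_contig[0] += cfg.n_genes - per_contig.sum()
    for ci, contig in enumerate(contigs):
        clen = cfg.contig_lengths[ci]
        n_here = int(per_contig[ci])
        glens = lengths[gi : gi + n_here]
        slack = clen - int(glens.sum()) - cfg.min_gene_spacing * (n_here + 1)
        if slack < 0:
            raise ValueError(f"gene packing infeasible on {contig}")
        # distribute the slack into n_here+1 random gap increments
        cuts = np.sort(rng.integers(0, slack + 1, size=n_here)) if n_here else np.array([], int)
        cursor = cfg.min_gene_spacing
        prev_cut = 0
        for k in range(n_here):
            cursor += int(cuts[k] - prev_cut)
            prev_cut = int(cuts[k])
            start = cursor
            end = start + int(glens[k])
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                {"gene_id": f"NSC_{gi + k + 1:05d}", "contig": contig,
                 "start": start, "end": end, "strand": strand}
            )
            cursor = end + cfg.min_gene_spacing
        gi += n_here
    genes = pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])
    return genome, genes


def write_genome_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genes_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            fh.write(
                f"{g.contig}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def simulate_truth(catalog: SiteCatalog, cfg: SimulationConfig) -> pd.DataFrame:
    """Baseline per-site true methylation probabilities from the Beta mixtures.

    Returns the catalog's non-ambiguous sites with a ``p_true`` column.
    """
    sites = catalog.sites[catalog.sites["context"].isin(CONTEXTS)].reset_index(drop=True)
    rng = _rng(cfg.seed, _STREAM_TRUTH)
    p = np.empty(len(sites))
    for ctx in CONTEXTS:  # fixed context order keeps draws reproducible
        mask = (sites["context"] == ctx).to_numpy()
        p[mask] = cfg.mixtures[ctx].sample(int(mask.sum()), rng)
    out = sites.copy()
    out["p_true"] = p
    return out


def apply_effects(
    truth: pd.DataFrame, cfg: SimulationConfig
) -> tuple[dict[tuple[int, str], np.ndarray], pd.DataFrame]:
    """Plant the configured effects on the baseline truth, per condition.

    Deltas of effects stacking on the same site compose additively before
    clipping to [0, 1] (clip events are recorded).  Returns per-condition
    truth arrays (aligned with ``truth`` rows) and the effect registry.
    """
    rng = _rng(cfg.seed, _STREAM_EFFECTS)
    base = truth["p_true"].to_numpy()
    conditions = cfg.conditions()
    deltas = {cond: np.zeros(len(truth)) for cond in conditions}
    registry_rows = []
    for eff in cfg.effects:
        eligible = (
            (truth["context"] == eff.context)
            & (truth["p_true"] >= eff.truth_range[0])
            & (truth["p_true"] <= eff.truth_range[1])
        ).to_numpy()
        idx_pool = np.flatnonzero(eligible)
        if idx_pool.size < eff.n_sites:
            raise ValueError(
                f"effect {eff.name!r}: {eff.n_sites} sites requested, "
                f"only {idx_pool.size} eligible"
            )
        chosen = rng.choice(idx_pool, size=eff.n_sites, replace=False)
        mag = rng.uniform(eff.delta_range[0], eff.delta_range[1], size=eff.n_sites)
        signed = mag * (-1 if eff.direction == "hypo" else 1)
        days = list(eff.days) if eff.days is not None else list(cfg.days)
        treatments = list(eff.treatments) if eff.treatments is not None else list(cfg.treatments)
        d0, dN = min(days), max(days)
        for day in days:
            scale = (day - d0) / (dN - d0) if (eff.ramp and dN > d0) else 1.0
            if scale == 0:
                continue
            for trt in treatments:
                if (day, trt) not in deltas:
                    continue
                deltas[(day, trt)][chosen] += signed * scale
                for site_i, d in zip(chosen, signed * scale):
                    registry_rows.append(
                        {
                            "effect": eff.name,
                            "contig": truth["contig"].iat[site_i],
                            "pos": int(truth["pos"].iat[site_i]),
                            "strand": truth["strand"].iat[site_i],
                            "day": day,
                            "treatment": trt,
                            "delta": float(d),
                            "direction": eff.direction,
                        }
                    )
    per_condition = {}
    n_clipped = 0
    for cond in conditions:
        raw = base + deltas[cond]
        clipped = np.clip(raw, 0.0, 1.0)
        n_clipped += int((raw != clipped).sum())
        per_condition[cond] = clipped
    registry = pd.DataFrame(
        registry_rows,
        columns=["effect", "contig", "pos", "strand", "day", "treatment", "delta", "direction"],
    )
    registry.attrs["n_clipped"] = n_clipped
    return per_condition, registry


def observed_probability(p_true: np.ndarray, epsilon: float) -> np.ndarray:
    """Expected observed methylation ratio under non-conversion epsilon."""
    return p_true + (1.0 - p_true) * epsilon


def _draw_coverage(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.coverage_distribution == "poisson":
        return rng.poisson(cfg.coverage_mean, size=n)
    if cfg.coverage_distribution == "negative-binomial":
        size = cfg.nb_dispersion
        p = size / (size + cfg.coverage_mean)
        return rng.negative_binomial(size, p, size=n)
    raise ValueError(f"unknown coverage distribution {cfg.coverage_distribution!r}")


def simulate_counts_frame(
    truth: pd.DataFrame,
    p_condition: np.ndarray,
    cfg: SimulationConfig,
    day: int,
    treatment: str,
    replicate: int,
    coverage_mean: float | None = None,
) -> pd.DataFrame:
    """Draw one replicate's counts at every site (in memory).

    Coverage from the configured distribution, n_meth ~ Binomial(coverage,
    p_obs).  The replicate's RNG stream is keyed on (seed, day, treatment,
    replicate) so samples are independent but reproducible.
    """
    trt_key = sum(treatment.encode()) % (2**16)  # stable across runs, unlike hash()
    rng = _rng(cfg.seed, _STREAM_COUNTS, day, trt_key, replicate)
    if coverage_mean is not None:
        cfg = dataclasses.replace(cfg, coverage_mean=coverage_mean)
    cov = _draw_coverage(cfg, len(truth), rng)
    p_obs = observed_probability(p_condition, cfg.non_conversion)
    n_meth = rng.binomial(cov, p_obs)
    out = truth[["contig", "pos", "strand", "context"]].copy()
    out["n_meth"] = n_meth
    out["n_unmeth"] = cov - n_meth
    out["coverage"] = cov
    covered = cov > 0
    out["ratio"] = np.where(covered, n_meth / np.where(covered, cov, 1), np.nan)
    return out


def write_bedgraphs(
    counts: pd.DataFrame, sample: str, outdir: str | Path
) -> list[Path]:
    """Write one MethylDackel-style bedGraph per context for one sample.

    Zero-coverage sites are omitted, as a methylation caller would.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    covered = counts[counts["coverage"] > 0]
    for ctx in CONTEXTS:
        sub = covered[covered["context"] == ctx]
        path = outdir / f"{sample}_{ctx}.bedGraph"
        df = pd.DataFrame(
            {
                "contig": sub["contig"],
                "start": sub["pos"],
                "end": sub["pos"] + 1,
                "percent": (100 * sub["ratio"]).round(2),
                "n_meth": sub["n_meth"],
                "n_unmeth": sub["n_unmeth"],
            }
        )
        df.to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
    return paths


def simulate_experiment(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full synthetic file tree for one experiment.

    Writes genome FASTA, gene GFF3, sample sheet, baseline truth, effect
    registry, and per-sample per-context bedGraphs; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = simulate_genome(cfg)
    paths: dict[str, Path] = {
        "fasta": outdir / "genome.fa",
        "gff3": outdir / "genes.gff3",
        "sample_sheet": outdir / "sample_sheet.tsv",
        "truth": outdir / "truth_baseline.tsv",
        "registry": outdir / "effect_registry.tsv",
        "bedgraph_dir": outdir / "bedgraph",
    }
    write_genome_fasta(genome, paths["fasta"])
    write_genes_gff3(genes, paths["gff3"])
    catalog = enumerate_sites(genome)
    truth = simulate_truth(catalog, cfg)
    per_condition, registry = apply_effects(truth, cfg)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    registry.to_csv(paths["registry"], sep="\t", index=False)
    sheet = cfg.sample_sheet()
    sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
    for row in sheet.itertuples(index=False):
        counts = simulate_counts_frame(
            truth, per_condition[(row.day, row.treatment)], cfg,
            row.day, row.treatment, row.replicate,
        )
        write_bedgraphs(counts, row.sample_id, paths["bedgraph_dir"])
    return paths
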