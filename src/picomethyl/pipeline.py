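"""Stage orchestration, run manifests, packaged fixtures and reports.

Each stage function wraps one library module with file I/O and appends its
row counts and drop tallies to a :class:`RunManifest`, so a finished run
records where every input record went (retained or dropped, with reasons).
All analysis thresholds live in one :class:`Thresholds` namespace with the
study's operative values as defaults.

The packaged metrics fixture (``data/published_sample_metrics.tsv``) carries the
published per-sample WGBS summary table — sequencing metrics, called-site
counts and methylation fractions for 30 samples (days {4,5,6,7,10} x
{control, 5AZA} x 3 replicates) — and drives the printed-table report:
per-context mean methylation percents, called-site percentages against the
assembly's context totals, and the weighted genome-wide percent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, calling, differential, features, genome, simulate

log = logging.getLogger(__name__)

# Published assembly-scale reference inputs (per-context assayable-site
# totals of the real 15.2 Mb genome), used when summarizing the printed
# per-sample metrics table.
REFERENCE_CONTEXT_TOTALS = {"CpG": 1_014_486, "CHG": 1_316_811, "CHH": 4_430_371}
REFERENCE_GENOME_LENGTH = 15_200_000

_METRICS_SHA256 = "d994264bb1bbee58f7eb5775195f39dd959f6b3fa4681f8331348d1262ecb4b2"


@dataclass
class Thresholds:
    """All analysis thresholds in one place; defaults are the study values."""

    min_coverage: int = 20
    p_timecourse: float = 0.01
    p_aza: float = 0.05
    effect_threshold: float = 0.1
    flank: int = 500
    evalue_cutoff: float = 1e-24
    histogram_bin: float = 0.1
    histogram_exclusion: float = 0.05
    genome_length: int | None = None  # None: use the FASTA total length


@dataclass
class RunManifest:
    """Provenance for one pipeline run: digests, counts and drop tallies."""

    tool_version: str
    seed: int | None = None
    config_hash: str | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    drops: dict[str, dict[str, int]] = field(default_factory=dict)
    timestamp: str | None = None

    def add_input(self, name: str, path: str | Path) -> None:
        self.inputs[name] = file_digest(path)

    def add_output(self, name: str, path: str | Path) -> None:
        self.outputs[name] = file_digest(path)

    def write(self, path: str | Path) -> None:
        import datetime

        self.timestamp = datetime.datetime.now().isoformat(timespec="seconds")
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _version() -> str:
    from . import __version__

    return __version__


def new_manifest(seed: int | None = None, config_repr: str | None = None) -> RunManifest:
    cfg_hash = hashlib.sha256(config_repr.encode()).hexdigest() if config_repr else None
    return RunManifest(tool_version=_version(), seed=seed, config_hash=cfg_hash)


def run_simulate(cfg: simulate.SimulationConfig, outdir: str | Path) -> RunManifest:
    manifest = new_manifest(seed=cfg.seed, config_repr=repr(cfg))
    paths = simulate.simulate_experiment(cfg, outdir)
    for name, p in paths.items():
        if p.is_file():
            manifest.add_output(name, p)
    manifest.counts["samples"] = len(cfg.sample_sheet())
    manifest.write(Path(outdir) / "manifest.json")
    return manifest


def load_experiment(
    exp_dir: str | Path, thresholds: Thresholds | None = None
) -> tuple[genome.SiteCatalog, dict[str, calling.SampleProfile], dict[str, str], pd.DataFrame]:
    """Ingest a simulated (or real, same layout) experiment directory.

    Reads the genome, enumerates the site catalog, and validates every
    sample's bedGraph calls.  Returns (catalog, profiles, genome dict,
    sample sheet).
    """
    thresholds = thresholds or Thresholds()
    exp_dir = Path(exp_dir)
    gnm = genome.read_fasta(exp_dir / "genome.fa")
    catalog = genome.enumerate_sites(gnm)
    sheet = pd.read_csv(exp_dir / "sample_sheet.tsv", sep="\t")
    profiles: dict[str, calling.SampleProfile] = {}
    for row in sheet.itertuples(index=False):
        frames = []
        for ctx in genome.CONTEXTS:
            path = exp_dir / "bedgraph" / f"{row.sample_id}_{ctx}.bedGraph"
            if path.exists():
                frames.append(calling.read_bedgraph_counts(path, context=ctx))
        calls = pd.concat(frames, ignore_index=True)
        profiles[row.sample_id] = calling.validate_calls(
            calls, catalog, min_coverage=thresholds.min_coverage,
            sample_id=row.sample_id, day=int(row.day),
            treatment=str(row.treatment), replicate=int(row.replicate),
        )
    return catalog, profiles, gnm, sheet


def run_call(exp_dir: str | Path, outdir: str | Path,
             thresholds: Thresholds | None = None) -> RunManifest:
    thresholds = thresholds or Thresholds()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = new_manifest(config_repr=repr(thresholds))
    catalog, profiles, gnm, _sheet = load_experiment(exp_dir, thresholds)
    catalog.write_tsv(outdir / "site_catalog.tsv")
    manifest.add_output("site_catalog", outdir / "site_catalog.tsv")
    for sid, prof in profiles.items():
        p = outdir / f"{sid}_validated.tsv"
        calling.write_validated_calls(prof, p)
        manifest.add_output(f"calls_{sid}", p)
        manifest.counts[f"retained_{sid}"] = len(prof.calls)
        manifest.drops[sid] = prof.drop_tally or {}
    glen = thresholds.genome_length or sum(len(s) for s in gnm.values())
    table, mean_pct, gw = calling.global_summary(
        list(profiles.values()), catalog.context_totals, glen
    )
    table.to_csv(outdir / "global_summary.tsv", sep="\t", index=False)
    manifest.add_output("global_summary", outdir / "global_summary.tsv")
    manifest.counts["genome_length"] = glen
    manifest.write(outdir / "manifest.json")
    return manifest


def run_features(exp_dir: str | Path, outdir: str | Path,
                 thresholds: Thresholds | None = None) -> pd.DataFrame:
    thresholds = thresholds or Thresholds()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp_dir = Path(exp_dir)
    gnm = genome.read_fasta(exp_dir / "genome.fa")
    lengths = {c: len(s) for c, s in gnm.items()}
    genes = features.read_gff3(exp_dir / "genes.gff3", lengths)
    feats = features.derive_features(genes, lengths, flank=thresholds.flank)
    features.write_features_gff3(feats, outdir / "derived_features.gff3")
    catalog = genome.enumerate_sites(gnm)
    summary = features.density_summary(catalog, feats, drop_zero=True)
    summary.to_csv(outdir / "feature_density.tsv", sep="\t", index=False)
    return summary


def run_diff(exp_dir: str | Path, outdir: str | Path,
             thresholds: Thresholds | None = None) -> dict[str, pd.DataFrame]:
    thresholds = thresholds or Thresholds()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _catalog, profiles, _gnm, _sheet = load_experiment(exp_dir, thresholds)
    tc = differential.timecourse_comparison(
        profiles, p_threshold=thresholds.p_timecourse,
        effect_threshold=thresholds.effect_threshold,
        min_coverage=thresholds.min_coverage,
    )
    tc.to_csv(outdir / "timecourse_differential.tsv", sep="\t", index=False)
    per_day, counts = differential.aza_comparisons(
        profiles, p_threshold=thresholds.p_aza,
        effect_threshold=thresholds.effect_threshold,
        min_coverage=thresholds.min_coverage,
    )
    for day, df in per_day.items():
        df.to_csv(outdir / f"aza_day{day}_differential.tsv", sep="\t", index=False)
    counts.to_csv(outdir / "aza_direction_counts.tsv", sep="\t", index=False)
    days = sorted(per_day)
    if len(days) >= 2:
        fate = differential.persistence(per_day[days[0]], per_day[days[-1]])
        pd.DataFrame(
            {"category": list(fate), "n_sites": [len(v) for v in fate.values()]}
        ).to_csv(outdir / "persistence_summary.tsv", sep="\t", index=False)
    return {"timecourse": tc, "aza_counts": counts, **{f"aza_day{d}": v for d, v in per_day.items()}}


def load_published_metrics(verify_digest: bool = True) -> pd.DataFrame:
    """Load the packaged published per-sample WGBS metrics table (30 rows)."""
    ref = resources.files("picomethyl.data") / "published_sample_metrics.tsv"
    raw = ref.read_bytes()
    if verify_digest and hashlib.sha256(raw).hexdigest() != _METRICS_SHA256:
        raise ValueError("packaged metrics fixture is corrupted (digest mismatch)")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t")


def published_metrics_report(
    table: pd.DataFrame | None = None,
    context_totals: dict[str, int] | None = None,
    genome_length: int | None = None,
) -> dict[str, float]:
    """Summaries of the published per-sample metrics table.

    Per-context mean methylation percents (rounded to the printed precision),
    mean called-site percentages against the assembly context totals, and
    the site-total-weighted genome-wide methylation percent.
    """
    if table is None:
        table = load_published_metrics()
    totals = context_totals or REFERENCE_CONTEXT_TOTALS
    glen = genome_length or REFERENCE_GENOME_LENGTH
    frac = table[["frac_cpg", "frac_chg", "frac_chh"]].rename(
        columns={"frac_cpg": "CpG", "frac_chg": "CHG", "frac_chh": "CHH"}
    )
    mean_pct = calling.summarize_fraction_table(frac)
    called_pct = {
        c: 100.0 * table[f"called_{c.lower()}"].mean() / totals[c]
        for c in ("CpG", "CHG", "CHH")
    }
    gw = calling.genome_wide_percent(
        {c: float(frac[c].mean()) for c in frac.columns}, totals, glen
    )
    site_frac = 100.0 * sum(totals.values()) / glen
    return {
        "mean_frac_CpG_pct": float(mean_pct["CpG"]),
        "mean_frac_CHG_pct": float(mean_pct["CHG"]),
        "mean_frac_CHH_pct": float(mean_pct["CHH"]),
        "called_CpG_pct": called_pct["CpG"],
        "called_CHG_pct": called_pct["CHG"],
        "called_CHH_pct": called_pct["CHH"],
        "genome_wide_methylation_pct": gw,
        "genome_site_fraction_pct": site_frac,
    }


def run_report(outdir: str | Path) -> dict[str, float]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rep = published_metrics_report()
    pd.Series(rep).rename("value").to_csv(outdir / "printed_table_summary.tsv", sep="\t")
    return rep


def run_annotate(
    exp_dir: str | Path,
    diff_path: str | Path,
    outdir: str | Path,
    ko_table_path: str | Path | None = None,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    thresholds = thresholds or Thresholds()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp_dir = Path(exp_dir)
    gnm = genome.read_fasta(exp_dir / "genome.fa")
    lengths = {c: len(s) for c, s in gnm.items()}
    genes = features.read_gff3(exp_dir / "genes.gff3", lengths)
    feats = features.derive_features(genes, lengths, flank=thresholds.flank)
    sites = pd.read_csv(diff_path, sep="\t")
    annotated = annotation.map_sites(sites, feats)
    if ko_table_path is not None:
        ko = pd.read_csv(ko_table_path, sep="\t")
        annotated = annotation.join_ko(annotated, ko, thresholds.evalue_cutoff)
    annotated.to_csv(outdir / "annotated_differential.tsv", sep="\t", index=False)
    return annotated
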