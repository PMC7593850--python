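"""Methylation-ratio calling, validation and global summaries.

The per-site methylation ratio is the fraction of bisulfite reads reporting a
cytosine among reads reporting C or T, i.e. n_meth / (n_meth + n_unmeth).
Counts arrive as MethylDackel-style bedGraph files (one per sample per
context, 0-based half-open coordinates).  Calls are validated against the
genome's site catalog: a call is retained only when its coverage reaches the
minimum (default 20X) and its position exists in the catalog, from which it
inherits the authoritative context.

Global summaries mirror the printed per-sample metrics: the per-context
"methylation fraction" is the unweighted mean of site ratios over validated
calls (a read-weighted pooled ratio is available as an option), and the
genome-wide percent methylation weights each context's mean fraction by its
catalog site total relative to the genome length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import AMBIGUOUS, CONTEXTS, SiteCatalog

log = logging.getLogger(__name__)

BEDGRAPH_COLUMNS = ["contig", "start", "end", "percent", "n_meth", "n_unmeth"]


class BedGraphError(ValueError):
    """Raised for malformed bisulfite-count bedGraph input."""


def read_bedgraph_counts(path: str | Path, context: str | None = None) -> pd.DataFrame:
    """Read one MethylDackel-style bedGraph of per-cytosine counts.

    Columns: chrom, start (0-based), end, methylation percent, n_meth,
    n_unmeth.  The ratio is recomputed from the counts; the percent column is
    advisory only and a disagreement beyond 0.5 percentage points is logged.
    Track/header lines are skipped.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 1 if first.startswith("track") else 0
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=BEDGRAPH_COLUMNS, skiprows=skip, dtype={0: str}
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=BEDGRAPH_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=["contig", "pos", "n_meth", "n_unmeth", "coverage", "ratio"])
    for col in ("start", "end", "n_meth", "n_unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise BedGraphError(f"non-numeric {col} in {path}")
        df[col] = vals.astype(np.int64)
    if (df[["n_meth", "n_unmeth"]] < 0).any().any():
        raise BedGraphError(f"negative counts in {path}")
    if (df["end"] != df["start"] + 1).any():
        raise BedGraphError(f"non single-base interval in {path}")
    out = pd.DataFrame(
        {
            "contig": df["contig"],
            "pos": df["start"],
            "n_meth": df["n_meth"],
            "n_unmeth": df["n_unmeth"],
        }
    )
    out["coverage"] = out["n_meth"] + out["n_unmeth"]
    covered = out["coverage"] > 0
    out["ratio"] = np.where(covered, out["n_meth"] / out["coverage"].where(covered, 1), np.nan)
    n_zero = int((~covered).sum())
    if n_zero:
        log.info("%s: %d zero-coverage rows (ratio undefined)", path.name, n_zero)
    mismatch = covered & (np.abs(df["percent"] - 100 * out["ratio"]) > 0.5)
    if mismatch.any():
        log.warning(
            "%s: percent column disagrees with counts at %d rows; counts win",
            path.name,
            int(mismatch.sum()),
        )
    if context is not None:
        out["file_context"] = context
    return out


def compute_ratio(n_meth: int, n_unmeth: int) -> float:
    """n_meth / (n_meth + n_unmeth); zero coverage is an error."""
    if n_meth < 0 or n_unmeth < 0:
        raise ValueError("counts must be non-negative")
    cov = n_meth + n_unmeth
    if cov == 0:
        raise ZeroDivisionError("ratio undefined at zero coverage")
    return n_meth / cov


@dataclass
class SampleProfile:
    """Validated per-sample methylation calls plus sample metadata."""

    sample_id: str
    day: int
    treatment: str
    replicate: int
    calls: pd.DataFrame  # contig, pos, strand, context, n_meth, n_unmeth, coverage, ratio
    drop_tally: dict[str, int] | None = None

    def calls_in_context(self, context: str) -> pd.DataFrame:
        return self.calls[self.calls["context"] == context]


def validate_calls(
    calls: pd.DataFrame,
    catalog: SiteCatalog,
    min_coverage: int = 20,
    *,
    sample_id: str = "sample",
    day: int = 0,
    treatment: str = "control",
    replicate: int = 1,
) -> SampleProfile:
    """Apply the coverage-and-catalog validation filter to raw calls.

    Retained calls have coverage >= ``min_coverage`` and a position present
    in the catalog; each inherits the catalog strand and context (any
    disagreement with the source file's context is logged and overridden).
    Ambiguous-context catalog sites are excluded.  Drop reasons are tallied.
    """
    tally = {"low_coverage": 0, "not_in_catalog": 0, "ambiguous_context": 0, "context_reassigned": 0}
    covered = calls["coverage"] >= min_coverage
    tally["low_coverage"] = int((~covered).sum())
    kept = calls.loc[covered].merge(
        catalog.sites, on=["contig", "pos"], how="left", validate="many_to_one"
    )
    in_cat = kept["context"].notna()
    tally["not_in_catalog"] = int((~in_cat).sum())
    kept = kept.loc[in_cat]
    amb = kept["context"] == AMBIGUOUS
    tally["ambiguous_context"] = int(amb.sum())
    kept = kept.loc[~amb]
    if "file_context" in kept.columns:
        reassigned = kept["file_context"].notna() & (kept["file_context"] != kept["context"])
        tally["context_reassigned"] = int(reassigned.sum())
        if tally["context_reassigned"]:
            log.info(
                "%s: %d calls re-assigned to catalog context", sample_id, tally["context_reassigned"]
            )
        kept = kept.drop(columns=["file_context"])
    kept = kept[["contig", "pos", "strand", "context", "n_meth", "n_unmeth", "coverage", "ratio"]]
    kept = kept.sort_values(["contig", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    log.info("%s: retained %d calls, dropped %s", sample_id, len(kept), tally)
    return SampleProfile(
        sample_id=sample_id,
        day=day,
        treatment=treatment,
        replicate=replicate,
        calls=kept,
        drop_tally=tally,
    )


def sample_fraction(profile: SampleProfile, context: str, weighted: bool = False) -> float:
    """Per-sample methylation fraction for one context.

    Unweighted mean of validated site ratios by default; ``weighted=True``
    gives the read-weighted pooled ratio sum(n_meth)/sum(coverage).
    """
    sub = profile.calls_in_context(context)
    if sub.empty:
        raise ValueError(f"no validated calls in context {context}")
    if weighted:
        return float(sub["n_meth"].sum() / sub["coverage"].sum())
    return float(sub["ratio"].mean())


def _round_half_up(x: float, decimals: int = 1) -> float:
    scale = 10**decimals
    return np.floor(x * scale + 0.5) / scale


def summarize_fraction_table(fractions: pd.DataFrame) -> pd.Series:
    """Cross-sample mean percent per context, rounded half-up to 1 decimal.

    ``fractions`` is samples x contexts (values in [0, 1]).
    """
    if fractions.empty:
        raise ValueError("empty fraction table")
    return fractions.mean(axis=0).map(lambda f: _round_half_up(100 * f, 1))


def genome_wide_percent(
    context_means: dict[str, float],
    context_totals: dict[str, int],
    genome_length: int,
) -> float:
    """Genome-wide percent methylation.

    Each context's mean site fraction is weighted by the catalog's total site
    count for that context and normalized by genome length:
    100 x sum_c(mean_c x total_c) / genome_length.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return 100.0 * sum(
        context_means[c] * context_totals[c] for c in context_means
    ) / genome_length


def ratio_histogram(
    ratios: np.ndarray | pd.Series,
    bin_width: float = 0.1,
    exclusion_ceiling: float = 0.05,
) -> pd.Series:
    """Histogram of methylation ratios in fixed-width bins.

    Ratios below ``exclusion_ceiling`` are dropped before binning (the mass
    of fully unmethylated cytosines would otherwise dwarf the signal).  Bins
    are [0, w), [w, 2w), ..., with the last bin closed at 1.0.
    """
    r = np.asarray(ratios, dtype=float)
    if r.size and (np.nanmin(r) < 0 or np.nanmax(r) > 1):
        raise ValueError("ratios must lie in [0, 1]")
    r = r[~np.isnan(r)]
    r = r[r >= exclusion_ceiling]
    edges = np.arange(0, 1 + bin_width / 2, bin_width)
    counts, _ = np.histogram(r, bins=edges)
    labels = [f"[{edges[i]:.1f},{edges[i+1]:.1f})" for i in range(len(edges) - 2)]
    labels.append(f"[{edges[-2]:.1f},{edges[-1]:.1f}]")
    return pd.Series(counts, index=labels, name="n_sites")


def bimodality_summary(ratios: np.ndarray | pd.Series) -> dict[str, float]:
    """Fractions of sites largely unmethylated (<0.2, strict), moderately
    methylated ([0.4, 0.6], inclusive) and largely methylated (>0.8, strict)."""
    r = np.asarray(ratios, dtype=float)
    r = r[~np.isnan(r)]
    if r.size == 0:
        raise ValueError("empty ratio collection")
    return {
        "unmethylated": float(np.mean(r < 0.2)),
        "moderate": float(np.mean((r >= 0.4) & (r <= 0.6))),
        "methylated": float(np.mean(r > 0.8)),
    }


def global_summary(
    profiles: list[SampleProfile],
    catalog_totals: dict[str, int],
    genome_length: int,
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Per-sample called counts and fractions, per-context mean percents and
    the genome-wide percent, computed from validated profiles."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "sample": p.sample_id,
            "day": p.day,
            "treatment": p.treatment,
            "replicate": p.replicate,
        }
        for c in CONTEXTS:
            sub = p.calls_in_context(c)
            row[f"called_{c}"] = len(sub)
            row[f"frac_{c}"] = float(sub["ratio"].mean()) if len(sub) else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    frac = table[[f"frac_{c}" for c in CONTEXTS]].rename(
        columns={f"frac_{c}": c for c in CONTEXTS}
    )
    mean_pct = summarize_fraction_table(frac)
    gw = genome_wide_percent(
        {c: float(frac[c].mean()) for c in CONTEXTS}, catalog_totals, genome_length
    )
    return table, mean_pct, gw


def write_validated_calls(profile: SampleProfile, path: str | Path) -> None:
    profile.calls.to_csv(path, sep="\t", index=False)
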