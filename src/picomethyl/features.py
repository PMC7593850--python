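"""Genomic feature derivation and methylation-site density.

Four feature classes partition the genome for density summaries: gene bodies
(the annotated protein-coding span, introns included), promoters (the 500 bp
flank 5' of the gene start, strand-aware), terminators (the 500 bp flank 3'
of the gene end) and intergenic regions (IGR, the per-contig complement of
the union of the other three).  Flanks are truncated at contig edges and may
overlap neighboring gene bodies; a site inside overlapping features counts
once per containing feature.

Per-feature density is 1000 x (site count) / (feature length bp), i.e. sites
per kb; class-level means and SDs are reported with or without zero-count
features.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .genome import AMBIGUOUS, CONTEXTS, SiteCatalog

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("gene_body", "promoter", "terminator", "IGR")


def read_gff3(path: str | Path, contig_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Read gene records from a GFF3 into 0-based half-open intervals.

    Returns columns ``gene_id, contig, start, end, strand``.  ``gene``
    features are used; if the file has none, ``mRNA`` records are used
    instead.  When ``contig_lengths`` is given, genes on unknown contigs or
    outside contig bounds are an error.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    ftypes = set(db.featuretypes())
    ftype = "gene" if "gene" in ftypes else "mRNA"
    rows = []
    for feat in db.features_of_type(ftype, order_by=("seqid", "start")):
        start0, end0 = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
        if end0 <= start0:
            raise ValueError(f"gene {feat.id}: end < start")
        if contig_lengths is not None:
            if feat.seqid not in contig_lengths:
                raise ValueError(f"gene {feat.id} on unknown contig {feat.seqid!r}")
            if end0 > contig_lengths[feat.seqid]:
                raise ValueError(f"gene {feat.id} extends past contig end")
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {"gene_id": gene_id, "contig": feat.seqid, "start": start0, "end": end0,
             "strand": feat.strand if feat.strand in "+-" else "."}
        )
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])


def _complement(intervals: np.ndarray, length: int) -> list[tuple[int, int]]:
    """Complement of a union of [start, end) intervals within [0, length)."""
    if intervals.size == 0:
        return [(0, length)] if length > 0 else []
    order = np.argsort(intervals[:, 0], kind="mergesort")
    out, cursor = [], 0
    for s, e in intervals[order]:
        s, e = max(int(s), 0), min(int(e), length)
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        out.append((cursor, length))
    return out


def derive_features(
    genes: pd.DataFrame, contig_lengths: dict[str, int], flank: int = 500
) -> pd.DataFrame:
    """Derive gene bodies, promoters, terminators and IGR from gene intervals.

    Promoter = ``flank`` bp 5' of the gene start (strand-aware), terminator =
    ``flank`` bp 3' of the gene end, both truncated at contig edges (empty
    truncations are dropped and logged).  IGR is the complement of the union
    of the other three classes, so the classes jointly tile each contig.
    Unstranded genes are treated as forward for flank placement.
    """
    rows = []
    n_empty = 0
    for g in genes.itertuples(index=False):
        clen = contig_lengths[g.contig]
        rows.append(("gene_body", g.contig, g.start, g.end, g.strand, g.gene_id))
        if g.strand == "-":
            prom = (g.end, min(g.end + flank, clen))
            term = (max(g.start - flank, 0), g.start)
        else:
            prom = (max(g.start - flank, 0), g.start)
            term = (g.end, min(g.end + flank, clen))
        for cls, (s, e) in (("promoter", prom), ("terminator", term)):
            if e > s:
                rows.append((cls, g.contig, s, e, g.strand, g.gene_id))
            else:
                n_empty += 1
    if n_empty:
        log.info("dropped %d zero-length truncated flanks", n_empty)
    covered: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    for r in rows:
        covered[r[1]].append((r[2], r[3]))
    for contig, length in contig_lengths.items():
        arr = np.array(covered[contig], dtype=np.int64).reshape(-1, 2)
        for s, e in _complement(arr, length):
            rows.append(("IGR", contig, s, e, ".", None))
    df = pd.DataFrame(
        rows, columns=["feature_class", "contig", "start", "end", "strand", "parent_gene"]
    )
    return df.sort_values(["contig", "start", "end"], kind="mergesort").reset_index(drop=True)


def count_sites_per_feature(sites: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Number of sites whose position falls in each feature's interval.

    ``sites`` needs columns ``contig, pos``; strand is ignored.  Overlapping
    features each count a contained site.  Vectorized per contig via sorted
    position search.
    """
    counts = np.zeros(len(features), dtype=np.int64)
    pos_by_contig = {c: np.sort(g["pos"].to_numpy()) for c, g in sites.groupby("contig")}
    for contig, grp in features.groupby("contig"):
        pos = pos_by_contig.get(contig)
        if pos is None:
            continue
        lo = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, grp["end"].to_numpy(), side="left")
        counts[grp.index.to_numpy()] = hi - lo
    return counts


def density_summary(
    sites: SiteCatalog | pd.DataFrame,
    features: pd.DataFrame,
    drop_zero: bool = True,
) -> pd.DataFrame:
    """Mean and SD of per-feature site density (sites/kb) per class x context.

    ``sites`` may be a SiteCatalog (all assayable sites) or a validated-call
    frame; ambiguous-context sites are excluded.  ``drop_zero`` removes
    zero-count features before averaging, matching how the summary is
    conventionally reported; both variants are computable.
    """
    site_df = sites.sites if isinstance(sites, SiteCatalog) else sites
    site_df = site_df[site_df["context"] != AMBIGUOUS]
    lengths = (features["end"] - features["start"]).to_numpy()
    rows = []
    for context in CONTEXTS:
        ctx_sites = site_df[site_df["context"] == context]
        counts = count_sites_per_feature(ctx_sites, features)
        density = 1000.0 * counts / lengths
        for cls in FEATURE_CLASSES:
            mask = (features["feature_class"] == cls).to_numpy()
            d = density[mask]
            if drop_zero:
                d = d[counts[mask] > 0]
            rows.append(
                {
                    "feature_class": cls,
                    "context": context,
                    "n_features": int(d.size),
                    "mean_density": float(d.mean()) if d.size else np.nan,
                    "sd_density": float(d.std(ddof=1)) if d.size > 1 else np.nan,
                    "drop_zero": drop_zero,
                }
            )
    return pd.DataFrame(rows)


def write_features_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write derived features as GFF3 (1-based inclusive), class in column 3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(features.itertuples(index=False)):
            attrs = f"ID=feat{i}"
            if r.parent_gene:
                attrs += f";parent_gene={r.parent_gene}"
            fh.write(
                f"{r.contig}\tpicomethyl\t{r.feature_class}\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\t{attrs}\n"
            )
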