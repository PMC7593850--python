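"""Site-to-gene annotation, KEGG-orthology joins, and augmented GFF3 export.

Differential sites are mapped to every containing genomic feature (a site in
a gene body that also lies in a neighbor's promoter yields one row per
feature).  Gene-linked rows can then be joined against an externally
computed gene -> KEGG orthology (KO) table: for genes with several candidate
KO rows the assignment with the lowest E-value at or below the cutoff
(default 1e-24) is kept, ties broken by lexicographic KO id for determinism.

Methylation sites are exported as 1-bp ``methylation_site`` GFF3 records
(1-based coordinates, ratio in the score column, context and any
differential statistics in the attributes) so each timepoint x condition can
be loaded as a browser track next to the gene annotation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from urllib.parse import quote, unquote

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SITE_KEY = ["contig", "pos", "strand"]


def map_sites(sites: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Annotate each site with every feature whose interval contains it.

    ``sites`` needs columns ``contig, pos`` (extra columns pass through);
    ``features`` is a derive_features frame.  Because the feature classes
    tile every contig, a site matching no feature is a hard error.  Returns
    one row per (site, containing feature) with ``feature_class`` and
    ``parent_gene`` appended.
    """
    out_frames = []
    matched = np.zeros(len(sites), dtype=bool)
    sites = sites.reset_index(drop=True)
    for contig, feats in features.groupby("contig"):
        sub = sites[sites["contig"] == contig]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        for f in feats.itertuples(index=False):
            inside = (pos >= f.start) & (pos < f.end)
            if not inside.any():
                continue
            hit = sub.loc[sub.index[inside]]
            matched[hit.index.to_numpy()] = True
            ann = hit.copy()
            ann["feature_class"] = f.feature_class
            ann["parent_gene"] = f.parent_gene
            out_frames.append(ann)
    if not matched.all():
        orphans = sites.loc[~matched, SITE_KEY[:2]]
        raise ValueError(
            f"{len(orphans)} sites outside every feature (tiling violated): "
            f"{orphans.head().to_dict('records')}"
        )
    out = pd.concat(out_frames, ignore_index=True)
    return out.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)


def join_ko(
    annotated: pd.DataFrame,
    ko_table: pd.DataFrame,
    evalue_cutoff: float = 1e-24,
) -> pd.DataFrame:
    """Left-join KO assignments onto annotated sites by parent gene.

    ``ko_table`` columns: ``gene_id, ko, definition, evalue`` (optional
    ``pathway``).  Per gene, the row with the smallest E-value at or below
    the cutoff wins; E-value ties break on lexicographic KO id.  Rows are
    never dropped or duplicated; genes with no qualifying KO keep empty KO
    fields.
    """
    keep_cols = ["gene_id", "ko", "definition"]
    if "pathway" in ko_table.columns:
        keep_cols.append("pathway")
    if ko_table.empty:
        best = pd.DataFrame(columns=keep_cols)
    else:
        qualifying = ko_table[ko_table["evalue"] <= evalue_cutoff]
        best = (
            qualifying.sort_values(["gene_id", "evalue", "ko"], kind="mergesort")
            .drop_duplicates("gene_id", keep="first")[keep_cols]
        )
    out = annotated.merge(
        best, how="left", left_on="parent_gene", right_on="gene_id", validate="many_to_one"
    )
    return out.drop(columns=["gene_id"], errors="ignore")


def write_augmented_gff3(sites: pd.DataFrame, path: str | Path) -> None:
    """Write methylation sites as 1-bp GFF3 records for browser viewing.

    Coordinates convert to 1-based inclusive; the score column carries the
    methylation ratio.  ``context`` and, when present, ``delta``, ``p`` and
    ``direction`` go into column 9 attributes.
    """
    extra = [c for c in ("delta", "p", "direction") if c in sites.columns]
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in sites.itertuples(index=False):
            score = f"{r.ratio:.6g}" if "ratio" in sites.columns else "."
            attrs = [f"context={quote(str(r.context))}"]
            for c in extra:
                v = getattr(r, c)
                attrs.append(f"{c}={quote(f'{v:.6g}' if isinstance(v, float) else str(v))}")
            fh.write(
                f"{r.contig}\tpicomethyl\tmethylation_site\t{r.pos + 1}\t{r.pos + 1}\t"
                f"{score}\t{r.strand}\t.\t{';'.join(attrs)}\n"
            )


def read_augmented_gff3(path: str | Path) -> pd.DataFrame:
    """Strict round-trip reader for :func:`write_augmented_gff3` output."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _src, ftype, start, end, score, strand, _phase, attrs = parts
            if ftype != "methylation_site":
                continue
            row = {
                "contig": contig,
                "pos": int(start) - 1,
                "strand": strand,
                "ratio": float(score) if score != "." else np.nan,
            }
            for kv in attrs.split(";"):
                k, _, v = kv.partition("=")
                row[k] = unquote(v)
            rows.append(row)
    return pd.DataFrame(rows)
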