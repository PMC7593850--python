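"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: plain Python
loops, scipy's t-test, and set algebra, so agreement is a genuine
cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
H = {"A", "T", "C"}


def oracle_context(seq: str, pos: int, strand: str) -> str:
    """Position-by-position context classification by direct inspection."""
    if strand == "+":
        b1 = seq[pos + 1] if pos + 1 < len(seq) else None
        b2 = seq[pos + 2] if pos + 2 < len(seq) else None
    else:
        b1 = COMP[seq[pos - 1]] if pos - 1 >= 0 else None
        b2 = COMP[seq[pos - 2]] if pos - 2 >= 0 else None
    if b1 is None or b1 == "N":
        return "ambiguous"
    if b1 == "G":
        return "CpG"
    if b2 is None or b2 == "N":
        return "ambiguous"
    return "CHG" if b2 == "G" else "CHH"


def oracle_enumerate(genome: dict[str, str]) -> set[tuple[str, int, str, str]]:
    """Every cytosine site on both strands, classified independently."""
    out = set()
    for contig, seq in genome.items():
        for i, base in enumerate(seq):
            if base == "C":
                out.add((contig, i, "+", oracle_context(seq, i, "+")))
            if base == "G":
                out.add((contig, i, "-", oracle_context(seq, i, "-")))
    return out


def oracle_validate(rows, catalog_keys, catalog_context, min_coverage):
    """Filter (contig,pos,cov) call rows the slow way; returns retained keys."""
    kept = []
    for contig, pos, cov in rows:
        if cov < min_coverage:
            continue
        if (contig, pos) not in catalog_keys:
            continue
        if catalog_context[(contig, pos)] == "ambiguous":
            continue
        kept.append((contig, pos))
    return kept


def oracle_feature_counts(sites, features):
    """Per-feature containment counts by direct double loop.

    sites: iterable of (contig, pos); features: iterable of
    (feature_class, contig, start, end).  Returns a list aligned with
    ``features``.
    """
    counts = []
    for _cls, fcontig, start, end in features:
        n = sum(1 for contig, pos in sites if contig == fcontig and start <= pos < end)
        counts.append(n)
    return counts


def oracle_compare(site_table, p_threshold, effect_threshold):
    """Brute-force filter chain over a per-site replicate table.

    site_table: dict site_key -> (group_a ratios, group_b ratios, min
    coverage over all samples).  Returns dict site_key -> (delta, p,
    direction) for retained sites, using scipy's t-test as the independent
    statistical engine.
    """
    out = {}
    for key, (a, b, min_cov) in site_table.items():
        if min_cov < 20:
            continue
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if a.max() == a.min() and b.max() == b.min():
            p = 1.0 if a[0] == b[0] else 0.0
        else:
            p = stats.ttest_ind(a, b, equal_var=True).pvalue
        delta = b.mean() - a.mean()
        if p <= p_threshold and abs(delta) >= effect_threshold:
            out[key] = (delta, p, "hypo" if delta < 0 else "hyper")
    return out


def oracle_persistence(a: dict, b: dict):
    """Set-algebra partition of day-a sites by their fate in day-b.

    a, b: dict site_key -> direction.
    """
    persistent = {k for k in a if k in b and a[k] == b[k]}
    reversed_ = {k for k in a if k in b and a[k] != b[k]}
    resolved = {k for k in a if k not in b}
    return persistent, reversed_, resolved
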