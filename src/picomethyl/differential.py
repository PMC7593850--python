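"""Per-site differential methylation with the coverage -> t-test -> effect
filter chain.

Each cytosine covered at >= 20X in every sample of a comparison is tested
with a classical equal-variance two-sample Student's t on the replicate
methylation ratios (df = nA + nB - 2, two-sided p).  Retained sites satisfy
p <= threshold AND |delta| >= 0.1 where delta = mean(B) - mean(A); direction
is hypo for delta < 0, hyper for delta > 0.  The time-course comparison is
Day 4 control vs Day 10 control at p < 0.01; drug comparisons are control vs
5AZA per day at p < 0.05.

Degenerate variance on ratio data (groups saturated at 0 or 1) is handled
deterministically: both groups constant and equal -> p = 1; both constant
and unequal -> p = 0, flagged.  No multiple-testing correction is applied by
default; Benjamini-Hochberg q values are available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import SampleProfile

log = logging.getLogger(__name__)

SITE_KEY = ["contig", "pos", "strand"]


@dataclass
class ComparisonSpec:
    """Selectors and thresholds for one two-group comparison."""

    label: str
    group_a: list[str]
    group_b: list[str]
    p_threshold: float
    effect_threshold: float = 0.1
    min_coverage: int = 20
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if not (0 < self.effect_threshold <= 1):
            raise ValueError("effect_threshold must be in (0, 1]")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each group needs >= 2 replicates")


def _pooled_t(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized equal-variance two-sample t over rows of A (n x nA) and B.

    Returns (t, two-sided p, degenerate flag).  Zero pooled variance:
    equal means -> t=0, p=1; unequal -> t=+/-inf, p=0, flagged.
    """
    nA, nB = A.shape[1], B.shape[1]
    mA, mB = A.mean(axis=1), B.mean(axis=1)
    vA = A.var(axis=1, ddof=1)
    vB = B.var(axis=1, ddof=1)
    df = nA + nB - 2
    sp2 = ((nA - 1) * vA + (nB - 1) * vB) / df
    se = np.sqrt(sp2 * (1 / nA + 1 / nB))
    diff = mB - mA
    # constancy, not se == 0: identical replicate values can leave a tiny
    # nonzero variance through round-off
    const = (A.max(axis=1) == A.min(axis=1)) & (B.max(axis=1) == B.min(axis=1))
    equal = const & (A[:, 0] == B[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(const, np.where(equal, 0.0, np.sign(diff) * np.inf), diff / se)
    p = np.where(
        const,
        np.where(equal, 1.0, 0.0),
        2 * stats.t.sf(np.abs(np.where(const, 0.0, t)), df),
    )
    return t, p, const & ~equal


def students_t(group_a, group_b) -> tuple[float, float]:
    """Equal-variance two-sample Student's t on replicate ratios.

    Scalar convenience wrapper over the vectorized kernel used by
    :func:`compare`; returns (t, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    t, p, _ = _pooled_t(a[None, :], b[None, :])
    return float(t[0]), float(p[0])


def _wide(profiles: dict[str, SampleProfile], samples: list[str], column: str) -> pd.DataFrame:
    frames = []
    for s in samples:
        calls = profiles[s].calls
        frames.append(calls.set_index(SITE_KEY)[column].rename(s))
    return pd.concat(frames, axis=1, join="outer")


def compare(profiles: dict[str, SampleProfile], spec: ComparisonSpec) -> pd.DataFrame:
    """Run one two-group per-site comparison and apply the filter chain.

    Tested sites have coverage >= ``spec.min_coverage`` in every selected
    sample; retained sites satisfy p <= p_threshold and |delta| >=
    effect_threshold (boundaries inclusive).  Output columns: site key,
    context, mean_a, mean_b, delta, t, p, (q,) direction, degenerate,
    comparison.
    """
    samples = spec.group_a + spec.group_b
    missing = [s for s in samples if s not in profiles]
    if missing:
        raise KeyError(f"profiles missing for samples: {missing}")
    cov = _wide(profiles, samples, "coverage")
    eligible = (cov.fillna(0) >= spec.min_coverage).all(axis=1)
    n_skipped = int((~eligible).sum())
    ratio = _wide(profiles, samples, "ratio").loc[eligible]
    if ratio.empty:
        log.info("%s: no eligible sites (%d skipped)", spec.label, n_skipped)
        return _empty_result(spec)
    A = ratio[spec.group_a].to_numpy()
    B = ratio[spec.group_b].to_numpy()
    t, p, degenerate = _pooled_t(A, B)
    delta = B.mean(axis=1) - A.mean(axis=1)
    out = ratio.index.to_frame(index=False)
    # context is identical across validated samples at a site; take the first
    ctx = profiles[samples[0]].calls.set_index(SITE_KEY)["context"]
    out["context"] = ctx.reindex(ratio.index).to_numpy()
    out["mean_a"] = A.mean(axis=1)
    out["mean_b"] = B.mean(axis=1)
    out["delta"] = delta
    out["t"] = t
    out["p"] = p
    keep = (p <= spec.p_threshold) & (np.abs(delta) >= spec.effect_threshold)
    if spec.bh_correction:
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(p, method="fdr_bh")[1]
        keep = (out["q"].to_numpy() <= spec.p_threshold) & (
            np.abs(delta) >= spec.effect_threshold
        )
    out["degenerate"] = degenerate
    out = out.loc[keep].copy()
    out["direction"] = np.where(out["delta"] < 0, "hypo", "hyper")
    out["comparison"] = spec.label
    log.info(
        "%s: %d tested, %d skipped (coverage), %d retained",
        spec.label, len(ratio), n_skipped, len(out),
    )
    return out.reset_index(drop=True)


def _empty_result(spec: ComparisonSpec) -> pd.DataFrame:
    cols = SITE_KEY + ["context", "mean_a", "mean_b", "delta", "t", "p"]
    if spec.bh_correction:
        cols.append("q")
    cols += ["degenerate", "direction", "comparison"]
    return pd.DataFrame(columns=cols)


def select_samples(
    profiles: dict[str, SampleProfile], day: int, treatment: str
) -> list[str]:
    ids = sorted(
        s for s, p in profiles.items() if p.day == day and p.treatment == treatment
    )
    if not ids:
        raise KeyError(f"no samples for day {day}, treatment {treatment!r}")
    return ids


def timecourse_comparison(
    profiles: dict[str, SampleProfile],
    day_a: int = 4,
    day_b: int = 10,
    p_threshold: float = 0.01,
    **kwargs,
) -> pd.DataFrame:
    """Day 4 vs Day 10 control comparison (nitrogen-starvation time course).

    delta = Day 10 mean - Day 4 mean, so starvation-induced hypomethylation
    appears as negative delta / direction 'hypo'.
    """
    spec = ComparisonSpec(
        label=f"Day{day_b}-Day{day_a} control",
        group_a=select_samples(profiles, day_a, "control"),
        group_b=select_samples(profiles, day_b, "control"),
        p_threshold=p_threshold,
        **kwargs,
    )
    return compare(profiles, spec)


def aza_comparisons(
    profiles: dict[str, SampleProfile],
    days: list[int] | None = None,
    p_threshold: float = 0.05,
    **kwargs,
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Control vs 5AZA comparison for each day, with direction accounting.

    delta = 5AZA mean - control mean.  Returns the per-day retained-site
    frames and a per-day count table with hypo/hyper counts and percents
    normalized to that day's total retained sites (percents absent when no
    sites are retained).
    """
    if days is None:
        days = sorted({p.day for p in profiles.values()})
    per_day: dict[int, pd.DataFrame] = {}
    rows = []
    for day in days:
        spec = ComparisonSpec(
            label=f"Day{day} AZA-control",
            group_a=select_samples(profiles, day, "control"),
            group_b=select_samples(profiles, day, "5AZA"),
            p_threshold=p_threshold,
            **kwargs,
        )
        res = compare(profiles, spec)
        per_day[day] = res
        n_hypo = int((res["direction"] == "hypo").sum())
        n_hyper = int((res["direction"] == "hyper").sum())
        total = n_hypo + n_hyper
        rows.append(
            {
                "day": day,
                "n_hypo": n_hypo,
                "n_hyper": n_hyper,
                "pct_hypo": 100 * n_hypo / total if total else np.nan,
                "pct_hyper": 100 * n_hyper / total if total else np.nan,
            }
        )
    return per_day, pd.DataFrame(rows)


def persistence(day_a: pd.DataFrame, day_b: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition day_a's retained sites by their fate in day_b.

    persistent: same site, same direction in both; reversed: same site,
    opposite direction; resolved: absent from day_b.  The partition is
    exhaustive and disjoint over day_a's sites.
    """
    a = day_a.set_index(SITE_KEY)["direction"]
    b = day_b.set_index(SITE_KEY)["direction"]
    joined = a.to_frame("dir_a").join(b.rename("dir_b"), how="left")
    persistent = joined[joined["dir_a"] == joined["dir_b"]]
    reversed_ = joined[joined["dir_b"].notna() & (joined["dir_a"] != joined["dir_b"])]
    resolved = joined[joined["dir_b"].isna()]
    return {
        "persistent": persistent.reset_index(),
        "reversed": reversed_.reset_index(),
        "resolved": resolved.reset_index(),
    }
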