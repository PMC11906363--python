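"""Tumor-contamination (purity) estimation from truncal mutations.

Every cell of the tumor carries the mutations on the trunk of its phylogeny,
so the aggregate variant allele fraction of truncal mutations in any other
sample measures the fraction of tumor cells it contains. At diploid
heterozygous truncal sites the expected aggregate VAF is purity/2, giving
the estimator purity = 2 * (sum alt) / (sum depth), clamped to [0, 1].

Counts are pooled across sites (a single binomial) rather than summarized
per site: at contamination below 1% most individual sites have zero
alternate reads and only the pooled statistic retains sensitivity.
Truncal sites inside tumor LOH segments are hemizygous in the tumor and
break the x2 map; callers should supply diploid-heterozygous truncal sites
only (the simulator's trunk is placed off the LOH chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy.stats import binomtest


@dataclass(frozen=True)
class PurityEstimate:
    sample_id: str
    purity: float
    ci_low: float
    ci_high: float
    n_sites: int
    total_depth: int
    total_alt: int


def estimate_purity(
    truncal_mutation_ids: Iterable[str],
    read_counts: pd.DataFrame,
    sample_id: str | None = None,
    confidence: float = 0.95,
) -> PurityEstimate:
    """Estimate tumor contamination of one sample from truncal read counts.

    Parameters
    ----------
    truncal_mutation_ids
        Identifiers of truncal mutations; ``read_counts`` must carry a
        ``mutation_id`` column covering at least one of them, or — if it has
        no such column — every row is taken to be a truncal site.
    read_counts
        Per-site counts for a single sample with columns ``depth`` and
        ``alt_depth`` (and optionally ``sample_id``, ``mutation_id``).

    The 95% CI is the exact (Clopper-Pearson) binomial interval on the
    pooled (alt, depth) counts mapped through the same x2 transform.
    """
    truncal = set(truncal_mutation_ids)
    if not truncal:
        raise ValueError("truncal mutation set must be non-empty")
    df = read_counts
    if sample_id is not None and "sample_id" in df.columns:
        df = df[df["sample_id"] == sample_id]
    elif "sample_id" in df.columns:
        ids = df["sample_id"].unique()
        if len(ids) > 1:
            raise ValueError("read_counts covers multiple samples; pass sample_id")
        sample_id = ids[0] if len(ids) else "sample"
    if "mutation_id" in df.columns:
        df = df[df["mutation_id"].isin(truncal)]
    if df.empty:
        raise ValueError("read counts cover no truncal site")

    total_depth = int(df["depth"].sum())
    total_alt = int(df["alt_depth"].sum())
    if total_depth == 0:
        raise ValueError("zero total depth over truncal sites: purity undefined")

    purity = min(1.0, 2.0 * total_alt / total_depth)
    ci = binomtest(total_alt, total_depth).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return PurityEstimate(
        sample_id=sample_id or "sample",
        purity=purity,
        ci_low=min(1.0, 2.0 * ci.low),
        ci_high=min(1.0, 2.0 * ci.high),
        n_sites=int(len(df)),
        total_depth=total_depth,
        total_alt=total_alt,
    )


def purity_table(estimates: Iterable[PurityEstimate]) -> pd.DataFrame:
    """Tabulate estimates, one row per sample."""
    return pd.DataFrame([e.__dict__ for e in estimates])


__all__ = ["PurityEstimate", "estimate_purity", "purity_table"]
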