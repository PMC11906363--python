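"""Haplotype-resolved loss-of-heterozygosity calling.

The tumor's complete chromosome-17 LOH (retaining only the haplotype that
carries the germline hit) phases every heterozygous SNP on the chromosome:
whichever allele dominates in a pure tumor sample lies on the retained,
mutant haplotype. Profiling these phased SNPs in every other sample turns
subclonal LOH into aggregate allelic imbalance, tested with a purity-
adjusted two-sided exact binomial test:

* trials   = summed coverage over qualifying phased SNPs,
* successes = summed depth of the tumor-retained alleles,
* null p0  = purity + (1 - purity) * 0.5
  (the tumor contributes retained alleles only — its locus is 2+0 — while
  normal cells contribute each parental allele equally).

P-values are Benjamini-Hochberg corrected across all samples tested in a
run. A sample is flagged as carrying an LOH clone only if q < 0.01, its
median SNP coverage is >= 30x and its tumor purity is < 1%, so that the
imbalance cannot be explained by tumor infiltration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from ._util import bh_qvalues

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhasedSnp:
    chrom: str
    pos: int
    ref: str
    alt: str
    retained_is_alt: bool


@dataclass(frozen=True)
class LohCall:
    sample_id: str
    n_snps_used: int
    trials: int
    successes: int
    p0: float
    p_value: float
    q_value: float
    flagged: bool
    direction: str  # 'wt_loss' | 'mutant_loss' | 'none'
    clone_fraction_cnloh: float
    clone_fraction_deletion: float
    median_coverage: float
    purity: float
    testable: bool


def phase_by_tumor(
    het_snps: Sequence[tuple[str, int, str, str]] | pd.DataFrame,
    tumor_read_counts: pd.DataFrame,
    min_tumor_depth: int = 10,
) -> list[PhasedSnp]:
    """Assign each heterozygous SNP's retained allele from the tumor's VAF.

    The allele with the larger allele fraction in the (near-pure, fully
    LOH) tumor sample is the retained-haplotype allele. SNPs with tumor
    depth below ``min_tumor_depth`` or an exactly tied VAF are dropped and
    logged.
    """
    if isinstance(het_snps, pd.DataFrame):
        snps = list(het_snps[["chrom", "pos", "ref", "alt"]].itertuples(index=False, name=None))
    else:
        snps = list(het_snps)
    if not snps:
        raise ValueError("empty SNP panel")
    counts = tumor_read_counts.set_index(["chrom", "pos"])
    phased: list[PhasedSnp] = []
    n_dropped = 0
    for chrom, pos, ref, alt in snps:
        try:
            row = counts.loc[(chrom, pos)]
        except KeyError:
            n_dropped += 1
            continue
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        depth, alt_depth = int(row["depth"]), int(row["alt_depth"])
        if depth < min_tumor_depth:
            n_dropped += 1
            continue
        if 2 * alt_depth == depth:
            n_dropped += 1  # tied VAF: uninformative
            continue
        phased.append(PhasedSnp(chrom, pos, ref, alt, retained_is_alt=2 * alt_depth > depth))
    if n_dropped:
        logger.info("phase_by_tumor: dropped %d/%d SNPs (low depth or tied VAF)",
                    n_dropped, len(snps))
    return phased


def expected_retained_fraction(purity: float) -> float:
    """Null aggregate retained-allele fraction under tumor contamination only.

    Equals purity + (1 - purity) * 0.5: exactly 0.5 at purity 0 and 1.0 at
    purity 1.
    """
    if not (0 <= purity <= 1):
        raise ValueError("purity must be in [0,1]")
    return purity + (1.0 - purity) * 0.5


def test_loh(
    sample_read_counts: pd.DataFrame,
    phased_snps: Sequence[PhasedSnp],
    purity: float,
    min_site_depth: int = 10,
    sample_id: str | None = None,
) -> LohCall:
    """Exact binomial allelic-imbalance test for one sample.

    Only SNPs with coverage >= ``min_site_depth`` in the sample are kept.
    Reports two clone-size estimates from the aggregate retained fraction
    a = successes/trials (deviation side taken as max(a, 1-a)): under
    copy-neutral LOH, c = 2a - 1; under one-copy deletion, c = (2a - 1)/a.
    q_value and flagged are filled by :func:`correct_loh_calls`.
    """
    if not phased_snps:
        raise ValueError("phased SNP panel must be non-empty")
    df = sample_read_counts
    if sample_id is not None and "sample_id" in df.columns:
        df = df[df["sample_id"] == sample_id]
    elif "sample_id" in df.columns:
        ids = df["sample_id"].unique()
        if len(ids) > 1:
            raise ValueError("read counts cover multiple samples; pass sample_id")
        sample_id = ids[0] if len(ids) else "sample"
    counts = df.set_index(["chrom", "pos"])

    trials = successes = 0
    coverages: list[int] = []
    for snp in phased_snps:
        try:
            row = counts.loc[(snp.chrom, snp.pos)]
        except KeyError:
            continue
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        depth, alt_depth = int(row["depth"]), int(row["alt_depth"])
        if depth < min_site_depth:
            continue
        coverages.append(depth)
        trials += depth
        successes += alt_depth if snp.retained_is_alt else depth - alt_depth

    p0 = expected_retained_fraction(purity)
    if trials == 0:
        return LohCall(sample_id or "sample", 0, 0, 0, p0, np.nan, np.nan, False,
                       "none", np.nan, np.nan, np.nan, purity, testable=False)

    p_value = binomtest(successes, trials, p0, alternative="two-sided").pvalue
    a = successes / trials
    direction = "wt_loss" if a > p0 else ("mutant_loss" if a < p0 else "none")
    a_eff = max(a, 1.0 - a)
    c_cnloh = max(0.0, 2.0 * a_eff - 1.0)
    c_del = max(0.0, (2.0 * a_eff - 1.0) / a_eff)
    return LohCall(
        sample_id=sample_id or "sample",
        n_snps_used=len(coverages),
        trials=trials,
        successes=successes,
        p0=p0,
        p_value=p_value,
        q_value=np.nan,
        flagged=False,
        direction=direction,
        clone_fraction_cnloh=c_cnloh,
        clone_fraction_deletion=c_del,
        median_coverage=float(np.median(coverages)),
        purity=purity,
        testable=True,
    )


def test_loh_many(
    read_counts: pd.DataFrame,
    phased_snps: Sequence[PhasedSnp],
    purities: Mapping[str, float],
    min_site_depth: int = 10,
) -> list[LohCall]:
    """Vectorized :func:`test_loh` over every sample in ``read_counts``.

    Same statistic per sample; one merge + groupby instead of per-SNP
    lookups, so cohort-scale runs stay fast.
    """
    if not phased_snps:
        raise ValueError("phased SNP panel must be non-empty")
    panel = pd.DataFrame(
        {
            "chrom": [s.chrom for s in phased_snps],
            "pos": [s.pos for s in phased_snps],
            "retained_is_alt": [s.retained_is_alt for s in phased_snps],
        }
    )
    df = read_counts.merge(panel, on=["chrom", "pos"], how="inner")
    df = df[df["depth"] >= min_site_depth]
    calls: list[LohCall] = []
    grouped = dict(tuple(df.groupby("sample_id"))) if not df.empty else {}
    for sid in purities:
        purity = purities[sid]
        p0 = expected_retained_fraction(purity)
        g = grouped.get(sid)
        if g is None or g.empty:
            calls.append(LohCall(sid, 0, 0, 0, p0, np.nan, np.nan, False, "none",
                                 np.nan, np.nan, np.nan, purity, testable=False))
            continue
        trials = int(g["depth"].sum())
        retained = np.where(g["retained_is_alt"], g["alt_depth"], g["depth"] - g["alt_depth"])
        successes = int(retained.sum())
        p_value = binomtest(successes, trials, p0, alternative="two-sided").pvalue
        a = successes / trials
        direction = "wt_loss" if a > p0 else ("mutant_loss" if a < p0 else "none")
        a_eff = max(a, 1.0 - a)
        calls.append(
            LohCall(sid, int(len(g)), trials, successes, p0, p_value, np.nan, False,
                    direction, max(0.0, 2 * a_eff - 1), max(0.0, (2 * a_eff - 1) / a_eff),
                    float(g["depth"].median()), purity, testable=True)
        )
    return calls


def correct_loh_calls(
    calls: Iterable[LohCall],
    q_threshold: float = 0.01,
    min_median_coverage: float = 30.0,
    max_purity: float = 0.01,
) -> list[LohCall]:
    """BH-correct a family of LOH tests and apply the flagging gates.

    A sample is flagged only when q < 0.01 AND its median SNP coverage is
    >= 30x AND its tumor purity is < 1% (all thresholds configurable).
    """
    calls = list(calls)
    q = bh_qvalues([c.p_value for c in calls])
    out = []
    for call, qv in zip(calls, q):
        flagged = bool(
            call.testable
            and qv < q_threshold
            and call.median_coverage >= min_median_coverage
            and call.purity < max_purity
        )
        out.append(replace(call, q_value=float(qv), flagged=flagged))
    return out


def loh_table(calls: Iterable[LohCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def phased_snp_table(snps: Iterable[PhasedSnp]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in snps])


__all__ = [
    "PhasedSnp", "LohCall", "phase_by_tumor", "expected_retained_fraction",
    "test_loh", "correct_loh_calls", "loh_table", "phased_snp_table",
]
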