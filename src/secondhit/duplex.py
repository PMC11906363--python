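"""Duplex (two-strand) consensus variant calling.

Duplex sequencing tags both strands of each original DNA molecule; a true
variant is present on both strands, while PCR and sequencing errors almost
always affect one strand only. A call therefore requires, for at least one
molecule, variant support on BOTH strands (strand consensus by simple
majority of that strand's reads; ties yield no consensus) and absence of
the site from the matched-normal call set. With single-strand error rate e
per base, the chance that both strands of a molecule independently acquire
the same specific alternate base is (e/3)^2 — the analytic duplex
false-call floor per molecule.

Duplex coverage at a site counts molecules with reads on both strands,
irrespective of variant content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd


@dataclass(frozen=True)
class DuplexCall:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    n_duplex_support: int
    duplex_coverage: int
    in_normal: bool
    called: bool


def _validate_bundles(bundles: pd.DataFrame) -> None:
    required = {"molecule_id", "chrom", "pos", "strand", "reads", "variant_reads"}
    missing = required - set(bundles.columns)
    if missing:
        raise ValueError(f"bundle table missing columns: {sorted(missing)}")
    if (bundles["variant_reads"] > bundles["reads"]).any():
        raise ValueError("variant_reads exceeds reads in some bundle rows")
    if not bundles["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    dup = bundles.duplicated(subset=["molecule_id", "chrom", "pos", "strand"])
    if dup.any():
        raise ValueError("each molecule_id may have at most one row per strand per site")


def call_duplex(
    bundles: pd.DataFrame,
    matched_normal_calls: Iterable[tuple[str, int, str, str]] = (),
    min_reads_per_strand: int = 1,
) -> list[DuplexCall]:
    """Call variants from duplex bundles.

    Parameters
    ----------
    bundles
        One row per (molecule, strand, site): columns ``molecule_id, chrom,
        pos, strand, reads, variant_reads`` plus ``ref, alt, sample_id``.
    matched_normal_calls
        Sites (chrom, pos, ref, alt) called in the matched normal; duplex
        calls at these sites are suppressed (germline exclusion).
    min_reads_per_strand
        Minimum variant reads required on each strand of a supporting
        molecule (default 1; the both-strand requirement itself is the
        filter, not a depth floor).

    Returns one :class:`DuplexCall` per (sample, site) with any duplex
    coverage.
    """
    if min_reads_per_strand < 1:
        raise ValueError("min_reads_per_strand must be >= 1")
    if bundles.empty:
        return []
    _validate_bundles(bundles)
    normal = {tuple(site) for site in matched_normal_calls}

    df = bundles.copy()
    # strand consensus: simple majority of the strand's reads; tie -> none
    df["consensus_variant"] = (2 * df["variant_reads"] > df["reads"]) & (
        df["variant_reads"] >= min_reads_per_strand
    )
    df["covers"] = df["reads"] >= 1

    site_cols = ["sample_id", "chrom", "pos", "ref", "alt"]
    calls: list[DuplexCall] = []
    for keys, site_df in df.groupby(site_cols, sort=True):
        per_mol = site_df.groupby("molecule_id").agg(
            n_strands=("strand", "nunique"),
            both_variant=("consensus_variant", "all"),
            n_rows=("strand", "size"),
        )
        duplex_mols = per_mol[per_mol["n_strands"] == 2]
        coverage = int(len(duplex_mols))
        support = int((duplex_mols["both_variant"]).sum())
        sample_id, chrom, pos, ref, alt = keys
        in_normal = (chrom, pos, ref, alt) in normal
        calls.append(
            DuplexCall(
                sample_id=sample_id,
                chrom=chrom,
                pos=int(pos),
                ref=ref,
                alt=alt,
                n_duplex_support=support,
                duplex_coverage=coverage,
                in_normal=in_normal,
                called=bool(support >= 1 and not in_normal),
            )
        )
    return calls


def duplex_call_table(calls: Iterable[DuplexCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


__all__ = ["DuplexCall", "call_duplex", "duplex_call_table"]
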