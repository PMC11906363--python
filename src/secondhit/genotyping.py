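"""Error-aware presence genotyping of known candidate mutations.

A candidate mutation is declared present in a sample only when its read
support exceeds what the locus-specific sequencing-error background can
explain. The background is measured by pooling variant and total read
depths over control samples that cannot carry the mutation; presence is a
one-sided Fisher's exact test of the sample's (alt, ref) counts against the
pooled control counts, Benjamini-Hochberg corrected across every
(mutation, sample) pair tested in the run, with presence called at q < 0.01.

The same machinery, pointed at a leave-one-out panel of the other samples
instead of control individuals and given a small minimum-alt-read floor,
serves as the simplified Shearwater-like presence caller used by the
shared-ancestry analysis (the full beta-binomial site-specific error model
is not implemented here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._util import bh_qvalues


@dataclass(frozen=True)
class GenotypeCall:
    mutation_id: str
    sample_id: str
    alt_depth: int
    depth: int
    control_alt_sum: int
    control_depth_sum: int
    p_value: float
    q_value: float
    present: bool


def fisher_presence_pvalues(alt_case, depth_case, alt_ctrl, depth_ctrl) -> np.ndarray:
    """Vectorized one-sided (enrichment) Fisher exact p-values.

    The one-sided Fisher p for the 2x2 table
    [[alt_case, depth_case - alt_case], [alt_ctrl, depth_ctrl - alt_ctrl]]
    with alternative 'case enriched' is the hypergeometric upper tail
    P(X >= alt_case) with population depth_case + depth_ctrl, successes
    alt_case + alt_ctrl and draws depth_case.
    """
    alt_case = np.asarray(alt_case, dtype=np.int64)
    depth_case = np.asarray(depth_case, dtype=np.int64)
    alt_ctrl = np.asarray(alt_ctrl, dtype=np.int64)
    depth_ctrl = np.asarray(depth_ctrl, dtype=np.int64)
    return hypergeom.sf(
        alt_case - 1, depth_case + depth_ctrl, alt_case + alt_ctrl, depth_case
    )


def genotype_presence(
    case_counts: pd.DataFrame,
    control_counts: pd.DataFrame,
    q_threshold: float = 0.01,
    min_alt_reads: int = 0,
) -> pd.DataFrame:
    """Genotype every (mutation, sample) pair in ``case_counts``.

    Parameters
    ----------
    case_counts
        Columns ``mutation_id, sample_id, depth, alt_depth``; one row per
        candidate site per case sample.
    control_counts
        Either per-sample control rows with the same columns (pooled here
        by summation over samples) or pre-pooled rows with columns
        ``mutation_id, control_depth_sum, control_alt_sum``.
    min_alt_reads
        Evidence floor: a sample needs at least this many alternate reads
        to be called present regardless of q (0 disables; the Shearwater-
        like configuration uses 2).

    Returns a genotype table with p, BH q (family = all pairs tested in
    this call) and the presence verdict (q < ``q_threshold``). Pairs with
    zero case depth are reported untested: p and q are NaN, present False.
    """
    if {"control_depth_sum", "control_alt_sum"}.issubset(control_counts.columns):
        pool = control_counts[["mutation_id", "control_alt_sum", "control_depth_sum"]]
    else:
        pool = (
            control_counts.groupby("mutation_id", as_index=False)
            .agg(control_alt_sum=("alt_depth", "sum"), control_depth_sum=("depth", "sum"))
        )
    df = case_counts.merge(pool, on="mutation_id", how="left")
    missing = df["control_depth_sum"].isna() | (df["control_depth_sum"] <= 0)
    if missing.any():
        bad = df.loc[missing, "mutation_id"].unique()
        raise ValueError(f"control pool has no depth for mutation(s): {list(bad)[:5]}")

    tested = df["depth"] > 0
    p = np.full(len(df), np.nan)
    p[tested.values] = fisher_presence_pvalues(
        df.loc[tested, "alt_depth"], df.loc[tested, "depth"],
        df.loc[tested, "control_alt_sum"], df.loc[tested, "control_depth_sum"],
    )
    q = bh_qvalues(p)
    present = (q < q_threshold) & tested.values
    if min_alt_reads > 0:
        present &= df["alt_depth"].values >= min_alt_reads
    out = df[["mutation_id", "sample_id", "alt_depth", "depth",
              "control_alt_sum", "control_depth_sum"]].copy()
    out["control_alt_sum"] = out["control_alt_sum"].astype(int)
    out["control_depth_sum"] = out["control_depth_sum"].astype(int)
    out["p_value"] = p
    out["q_value"] = q
    out["present"] = present
    return out


def presence_matrix(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pivot a genotype table to a mutation x sample boolean matrix."""
    return genotypes.pivot(index="mutation_id", columns="sample_id", values="present").fillna(False)


def leave_one_out_presence(
    counts: pd.DataFrame,
    q_threshold: float = 0.01,
    min_alt_reads: int = 2,
) -> pd.DataFrame:
    """Shearwater-like presence calling against a leave-one-out panel.

    For each (mutation, sample), the error background is the pooled counts
    of every *other* sample at that site; presence requires q below
    ``q_threshold`` and at least ``min_alt_reads`` alternate reads. Suitable
    when most samples do not carry any given low-fraction variant.
    """
    totals = counts.groupby("mutation_id").agg(
        tot_alt=("alt_depth", "sum"), tot_depth=("depth", "sum")
    )
    df = counts.merge(totals, on="mutation_id")
    df["control_alt_sum"] = (df["tot_alt"] - df["alt_depth"]).astype(int)
    df["control_depth_sum"] = (df["tot_depth"] - df["depth"]).astype(int)
    if (df["control_depth_sum"] <= 0).any():
        raise ValueError("leave-one-out panel has zero depth at some site")

    tested = df["depth"] > 0
    p = np.full(len(df), np.nan)
    p[tested.values] = fisher_presence_pvalues(
        df.loc[tested, "alt_depth"], df.loc[tested, "depth"],
        df.loc[tested, "control_alt_sum"], df.loc[tested, "control_depth_sum"],
    )
    q = bh_qvalues(p)
    present = (q < q_threshold) & tested.values
    if min_alt_reads > 0:
        present &= df["alt_depth"].values >= min_alt_reads
    out = df[["mutation_id", "sample_id", "alt_depth", "depth",
              "control_alt_sum", "control_depth_sum"]].copy()
    out["p_value"] = p
    out["q_value"] = q
    out["present"] = present
    return out


__all__ = [
    "GenotypeCall", "fisher_presence_pvalues", "genotype_presence",
    "presence_matrix", "leave_one_out_presence",
]
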