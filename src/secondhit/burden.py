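"""Mutation-burden test for recent clonal expansion.

A clone that expanded recently from a single cell carries that founder
cell's full mutation load; given postnatal somatic mutation rates of tens
of substitutions per year (glia ~27/year, neurons ~17/year, prenatal rates
higher), a recent expansion should add a burden on the order of 100
mutations even in a child. The model is a linear mixed-effects regression
of per-sample substitution count on second-hit (null) status, sequencing
modality (bulk vs laser-capture microdissection) and mean coverage as
fixed effects, with a random intercept per piece of tissue (microbiopsies
cut from the same piece are correlated). The expansion verdict compares
the estimated null-status effect against the ~100-mutation yardstick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

#: Methods-cited per-year substitution rates (documented metadata only).
GLIA_SUBSTITUTIONS_PER_YEAR = 27
NEURON_SUBSTITUTIONS_PER_YEAR = 17

EXPANSION_YARDSTICK = 100.0


@dataclass(frozen=True)
class BurdenFit:
    effect_of_null: float
    se: float
    p_value: float
    ci_low: float
    ci_high: float
    expansion_verdict: bool
    n_samples: int
    n_tissue_pieces: int
    method: str  # 'mixed' | 'ols'


def fit_burden_model(
    records: pd.DataFrame,
    expansion_threshold: float = EXPANSION_YARDSTICK,
) -> BurdenFit:
    """Fit the burden model and judge the clonal-expansion yardstick.

    ``records`` needs columns ``sample_id, substitution_count, nf1_null
    (bool), modality ('bulk'|'lcm'), coverage, tissue_piece_id``. Requires
    both null-status groups; with fewer than two tissue pieces (degenerate
    grouping) an ordinary least-squares fit is used with a warning.
    """
    required = {"substitution_count", "nf1_null", "modality", "coverage", "tissue_piece_id"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"burden records missing columns: {sorted(missing)}")
    df = records.copy()
    df["nf1_null"] = df["nf1_null"].astype(int)
    if df["nf1_null"].nunique() < 2:
        raise ValueError("both second-hit groups must be represented")
    df["is_lcm"] = (df["modality"] == "lcm").astype(int)
    n_pieces = df["tissue_piece_id"].nunique()

    formula = "substitution_count ~ nf1_null + is_lcm + coverage"
    if n_pieces >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # singular random-effect variance is fine
            model = smf.mixedlm(formula, df, groups=df["tissue_piece_id"])
            fit = model.fit(reml=True)
        method = "mixed"
    else:
        warnings.warn("only one tissue piece: falling back to ordinary least squares",
                      stacklevel=2)
        fit = smf.ols(formula, df).fit()
        method = "ols"

    effect = float(fit.params["nf1_null"])
    se = float(fit.bse["nf1_null"])
    p = float(fit.pvalues["nf1_null"])
    ci = fit.conf_int().loc["nf1_null"]
    return BurdenFit(
        effect_of_null=effect,
        se=se,
        p_value=p,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        expansion_verdict=bool(effect >= expansion_threshold),
        n_samples=int(len(df)),
        n_tissue_pieces=int(n_pieces),
        method=method,
    )


def simulate_burden_records(
    n_pieces: int,
    samples_per_piece: int,
    baseline: float,
    null_effect: float,
    piece_sd: float,
    noise_sd: float,
    seed: int,
    lcm_effect: float = 0.0,
    coverage_mean: float = 30.0,
) -> pd.DataFrame:
    """Generate burden records under the fitted model's own assumptions.

    Half of the samples in each piece are marked second-hit (null); counts
    are Gaussian around baseline + effects with a per-piece random
    intercept. Used for parameter-recovery and power checks.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for piece in range(n_pieces):
        intercept = rng.normal(0.0, piece_sd)
        for j in range(samples_per_piece):
            is_null = j % 2 == 0
            modality = "lcm" if (j // 2) % 2 == 0 else "bulk"
            coverage = rng.normal(coverage_mean, 3.0)
            mean = (
                baseline
                + intercept
                + (null_effect if is_null else 0.0)
                + (lcm_effect if modality == "lcm" else 0.0)
            )
            count = max(0.0, rng.normal(mean, noise_sd))
            rows.append(
                (f"p{piece}_s{j}", count, is_null, modality, coverage, f"piece{piece}")
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "substitution_count", "nf1_null", "modality",
                 "coverage", "tissue_piece_id"],
    )


__all__ = [
    "BurdenFit", "fit_burden_model", "simulate_burden_records",
    "GLIA_SUBSTITUTIONS_PER_YEAR", "NEURON_SUBSTITUTIONS_PER_YEAR",
    "EXPANSION_YARDSTICK",
]
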