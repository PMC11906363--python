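"""Permutation test for shared somatic ancestry between tissues.

Two tissues share a somatic variant either because they inherited it from a
common ancestral cell or because it arose twice independently. Tissues with
a recent common ancestor share many genome-wide substitutions; unrelated
tissues share few. To decide whether tissues carrying the same second hit
are unusually related, the mean number of shared substitutions over the
test pairs is compared with means of equally many pair-sharing counts drawn
at random, without replacement, from a control pool of pairs of comparable
normal tissues (low contamination, no second hit, stratified by germ
layer). The one-sided P value is the fraction of draws whose control mean
strictly exceeds the test mean; with 1,000 draws a zero exceedance count is
displayed as "<0.001" (and stored as 0.0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PairSharing:
    sample_a: str
    sample_b: str
    shared_count: int
    group: str  # 'test' | 'control'


@dataclass(frozen=True)
class PermutationResult:
    test_mean: float
    n_test_pairs: int
    n_draws: int
    exceed_count: int
    p_value: float
    p_display: str


def count_shared_substitutions(
    sample_a: str,
    sample_b: str,
    presence: pd.DataFrame | Callable[[str], Iterable[str]],
) -> int:
    """Number of substitutions called present in both samples.

    ``presence`` is either a mutation x sample boolean matrix (e.g. from
    :func:`secondhit.genotyping.presence_matrix`) or a callable mapping a
    sample id to its set of present mutation ids. Candidate sites are
    somatic substitutions; germline variants are excluded upstream.
    """
    if callable(presence):
        return len(set(presence(sample_a)) & set(presence(sample_b)))
    for s in (sample_a, sample_b):
        if s not in presence.columns:
            raise KeyError(f"sample {s!r} missing from presence matrix")
    return int((presence[sample_a] & presence[sample_b]).sum())


def pairwise_sharing(
    presence: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    group: str,
) -> list[PairSharing]:
    """Shared-substitution counts for a list of sample pairs."""
    return [
        PairSharing(a, b, count_shared_substitutions(a, b, presence), group)
        for a, b in pairs
    ]


def permutation_test(
    test_counts: Sequence[int] | Sequence[PairSharing],
    control_pool: Sequence[int] | Sequence[PairSharing],
    n_draws: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """One-sided permutation test of pair-sharing against a control pool.

    Each of ``n_draws`` repetitions draws ``len(test_counts)`` counts from
    the control pool without replacement and records its mean; the P value
    is the fraction of draws whose mean is strictly greater than the test
    mean (ties count as non-exceedances). Deterministic given ``seed``.
    """
    test = np.array([c.shared_count if isinstance(c, PairSharing) else c
                     for c in test_counts], dtype=float)
    pool = np.array([c.shared_count if isinstance(c, PairSharing) else c
                     for c in control_pool], dtype=float)
    if test.size == 0:
        raise ValueError("empty test pair set")
    if pool.size < test.size:
        raise ValueError(
            f"control pool ({pool.size}) smaller than number of test pairs ({test.size})"
        )
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")

    rng = np.random.default_rng(seed)
    test_mean = float(test.mean())
    k = test.size
    exceed = 0
    for _ in range(n_draws):
        draw = rng.choice(pool, size=k, replace=False)
        if draw.mean() > test_mean:
            exceed += 1
    p = exceed / n_draws
    display = f"<{1.0 / n_draws:g}" if exceed == 0 else f"{p:g}"
    return PermutationResult(
        test_mean=test_mean,
        n_test_pairs=k,
        n_draws=n_draws,
        exceed_count=exceed,
        p_value=p,
        p_display=display,
    )


def sharing_table(records: Iterable[PairSharing]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


__all__ = [
    "PairSharing", "PermutationResult", "count_shared_substitutions",
    "pairwise_sharing", "permutation_test", "sharing_table",
]
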