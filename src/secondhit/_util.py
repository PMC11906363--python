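"""Shared helpers: deterministic seed derivation and FDR correction."""

from __future__ import annotations

import hashlib

import numpy as np
from statsmodels.stats.multitest import multipletests

MAX_SEED = 2**31 - 1


def child_seed(master_seed: int, label: str) -> int:
    """Derive a stage-specific seed from a master seed, deterministically.

    Hash-based so that adding or reordering stages never shifts the streams
    of unrelated stages.
    """
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % MAX_SEED


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs propagate as NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q
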