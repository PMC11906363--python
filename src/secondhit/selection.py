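"""Single-gene dN/dS selection inference.

Estimates the strength of selection on truncating (nonsense + essential
splice) and missense variants in one gene from a list of observed somatic
mutations. The neutral expectation is built by exhaustively enumerating all
single-base substitutions in the coding sequence (plus configured essential
splice-site positions), classifying each by codon translation, and
weighting by a trinucleotide-context mutation spectrum. With observed class
counts n and neutral class proportions e, the model is

    n_syn   ~ Poisson(lam * e_syn)
    n_class ~ Poisson(lam * e_class * omega_class),   omega_syn = 1,

the gene-level rate lam profiled out. The maximum-likelihood ratio is
omega_class = (n_class / e_class) / (n_syn / e_syn); 95% intervals come
from profile-likelihood inversion at the chi-square(1) 0.95 quantile.
Positive selection is declared when the lower bound exceeds 1.

This is the single-gene core of the genome-wide dN/dS machinery: no
covariates, no indel-rate model, and by default a uniform spectrum over the
192 (trinucleotide context, alternate base) classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import xlogy
from scipy.stats import chi2

_BASES = ("A", "C", "G", "T")

#: Standard genetic code (DNA codons).
CODON_TABLE: dict[str, str] = {}
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"[
                16 * "TCAG".index(_b1) + 4 * "TCAG".index(_b2) + "TCAG".index(_b3)
            ]


@dataclass
class GeneModel:
    """A gene's coding model: ordered exons, CDS and splice positions.

    ``cds_sequence`` is the spliced coding sequence in translation order
    (already reverse-complemented for minus-strand genes); ``exons`` are
    1-based closed genomic intervals; ``splice_site_positions`` are genomic
    positions of essential splice sites (donor/acceptor, +-2 bases of each
    intron boundary), mutations at which are classified truncating.
    """

    gene_id: str
    strand: str
    exons: list[tuple[str, int, int]]
    cds_sequence: str
    splice_site_positions: set[int] = field(default_factory=set)

    def __post_init__(self):
        self.cds_sequence = self.cds_sequence.upper()
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(
                f"CDS length {len(self.cds_sequence)} not divisible by 3"
            )
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        exon_len = sum(e - s + 1 for _, s, e in self.exons)
        if self.exons and exon_len != len(self.cds_sequence):
            raise ValueError(
                f"exon span ({exon_len}) does not reproduce CDS length "
                f"({len(self.cds_sequence)})"
            )

    @classmethod
    def default_splice_sites(cls, exons: Sequence[tuple[str, int, int]],
                             strand: str = "+") -> set[int]:
        """Donor/acceptor +-2 positions flanking each internal intron."""
        sites: set[int] = set()
        ordered = sorted(exons, key=lambda e: e[1])
        for (_, _, end), (_, start, _) in zip(ordered, ordered[1:]):
            sites.update({end + 1, end + 2, start - 2, start - 1})
        return sites


def translate(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i:i + 3]] for i in range(0, len(cds), 3))


def _context(cds: str, i: int) -> str:
    left = cds[i - 1] if i > 0 else "N"
    right = cds[i + 1] if i < len(cds) - 1 else "N"
    return left + cds[i] + right


def enumerate_impacts(gene_model: GeneModel) -> pd.DataFrame:
    """Exhaustively classify all single-base substitutions in the gene.

    Returns one row per (CDS position, alternate base): columns ``cds_pos``
    (1-based; 0 for splice-site rows), ``genomic_pos`` (NaN when unmapped),
    ``ref``, ``alt``, ``impact`` in {synonymous, missense, nonsense,
    splice}, and ``context`` (ref-centered trinucleotide; 'N'-padded at
    CDS edges and splice sites).
    """
    cds = gene_model.cds_sequence
    rows = []
    for i, ref in enumerate(cds):
        codon_start = 3 * (i // 3)
        codon = cds[codon_start:codon_start + 3]
        pos_in_codon = i - codon_start
        aa_ref = CODON_TABLE[codon]
        ctx = _context(cds, i)
        for alt in _BASES:
            if alt == ref:
                continue
            mutant = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1:]
            aa_alt = CODON_TABLE[mutant]
            if aa_alt == aa_ref:
                impact = "synonymous"
            elif aa_alt == "*":
                impact = "nonsense"
            else:
                impact = "missense"  # includes stop-loss: protein-altering, non-truncating
            rows.append((i + 1, np.nan, ref, alt, impact, ctx))
    for pos in sorted(gene_model.splice_site_positions):
        for alt in _BASES:
            # intronic base unknown to the CDS; enumerate all four alts
            rows.append((0, float(pos), "N", alt, "splice", "NNN"))
    df = pd.DataFrame(rows, columns=["cds_pos", "genomic_pos", "ref", "alt",
                                     "impact", "context"])
    # exactly three substitutions per CDS position by construction
    return df


IMPACT_CLASS = {
    "synonymous": "syn",
    "missense": "mis",
    "nonsense": "trunc",
    "splice": "trunc",
}


def _spectrum_weights(impact_table: pd.DataFrame,
                      spectrum: Mapping[tuple[str, str], float] | None) -> np.ndarray:
    if spectrum is None:
        return np.ones(len(impact_table))
    rates = dict(spectrum)
    if any(r < 0 for r in rates.values()):
        raise ValueError("spectrum rates must be nonnegative")
    mean_rate = float(np.mean(list(rates.values()))) if rates else 0.0
    w = np.empty(len(impact_table))
    for idx, (ctx, alt) in enumerate(zip(impact_table["context"], impact_table["alt"])):
        if "N" in ctx:
            w[idx] = mean_rate  # edge/splice rows: no defined context
        else:
            w[idx] = rates.get((ctx, alt), 0.0)
    if w.sum() <= 0:
        raise ValueError("spectrum assigns zero rate to every substitution in the gene")
    return w


def expected_class_fractions(
    impact_table: pd.DataFrame,
    spectrum: Mapping[tuple[str, str], float] | None = None,
) -> tuple[float, float, float]:
    """Spectrum-weighted neutral proportions (e_syn, e_mis, e_trunc).

    Uniform spectrum when ``spectrum`` is None. The three fractions sum
    to 1; scaling the spectrum by any positive constant leaves them
    unchanged.
    """
    w = _spectrum_weights(impact_table, spectrum)
    classes = impact_table["impact"].map(IMPACT_CLASS)
    tot = w.sum()
    e_syn = float(w[(classes == "syn").values].sum() / tot)
    e_mis = float(w[(classes == "mis").values].sum() / tot)
    e_trunc = float(w[(classes == "trunc").values].sum() / tot)
    return e_syn, e_mis, e_trunc


@dataclass(frozen=True)
class SelectionEstimate:
    omega_truncating: float
    omega_missense: float
    ci_low_truncating: float
    ci_high_truncating: float
    ci_low_missense: float
    ci_high_missense: float
    n_syn: int
    n_mis: int
    n_trunc: int
    e_syn: float
    e_mis: float
    e_trunc: float
    positive_selection: bool
    testable: bool = True


def _profile_loglik(omega: float, n_s: int, n_c: int, e_s: float, e_c: float) -> float:
    """Log-likelihood of (n_s, n_c) at omega, gene rate lam profiled out."""
    denom = e_s + e_c * omega
    lam = (n_s + n_c) / denom if denom > 0 else 0.0
    return float(
        xlogy(n_s, lam * e_s) + xlogy(n_c, lam * e_c * omega) - lam * denom
    )


def _omega_ci(n_s: int, n_c: int, e_s: float, e_c: float,
              confidence: float = 0.95) -> tuple[float, float, float]:
    """(MLE, lo, hi) for one omega class by profile-likelihood inversion."""
    if n_s + n_c == 0:
        return np.nan, np.nan, np.nan
    crit = chi2.ppf(confidence, df=1) / 2.0
    if n_s > 0:
        mle = (n_c / e_c) / (n_s / e_s)
        l_max = _profile_loglik(max(mle, 1e-300), n_s, n_c, e_s, e_c) if mle > 0 else \
            _profile_loglik(1e-300, n_s, n_c, e_s, e_c)
    else:
        mle = np.inf
        # omega -> inf: the synonymous term vanishes, saturated Poisson on n_c
        l_max = float(xlogy(n_c, n_c) - n_c)

    def deficit(log_omega: float) -> float:
        return (l_max - _profile_loglik(np.exp(log_omega), n_s, n_c, e_s, e_c)) - crit

    # lower bound
    if n_c == 0:
        lo = 0.0
    else:
        lo_bracket = np.log(mle) if np.isfinite(mle) and mle > 0 else 20.0
        left = lo_bracket - 1.0
        while deficit(left) < 0 and left > -60:
            left -= 2.0
        lo = 0.0 if deficit(left) < 0 else float(np.exp(brentq(deficit, left, lo_bracket)))
    # upper bound
    if not np.isfinite(mle):
        hi = np.inf
    else:
        hi_bracket = np.log(mle) if mle > 0 else -20.0
        right = hi_bracket + 1.0
        while deficit(right) < 0 and right < 60:
            right += 2.0
        hi = np.inf if deficit(right) < 0 else float(np.exp(brentq(deficit, hi_bracket, right)))
    return mle, lo, hi


def classify_observed(observed: pd.DataFrame, impact_table: pd.DataFrame) -> pd.Series:
    """Map observed mutations to impact classes via the enumeration table.

    ``observed`` needs columns ``cds_pos, ref, alt`` (``cds_pos`` 0 with a
    ``genomic_pos`` column for splice-site mutations). Raises if any row is
    not classifiable.
    """
    cds_rows = impact_table[impact_table["cds_pos"] > 0]
    lookup = {(int(r.cds_pos), r.ref, r.alt): r.impact
              for r in cds_rows.itertuples()}
    splice_pos = set(impact_table.loc[impact_table["impact"] == "splice",
                                      "genomic_pos"].dropna().astype(int))
    impacts = []
    for r in observed.itertuples():
        if getattr(r, "cds_pos", 0) and int(r.cds_pos) > 0:
            key = (int(r.cds_pos), r.ref, r.alt)
            if key not in lookup:
                raise ValueError(f"observed mutation {key} not classifiable")
            impacts.append(lookup[key])
        else:
            gpos = int(getattr(r, "genomic_pos"))
            if gpos not in splice_pos:
                raise ValueError(f"observed splice mutation at {gpos} outside model")
            impacts.append("splice")
    return pd.Series(impacts, index=observed.index)


def estimate_dnds(
    observed_mutations: pd.DataFrame | Mapping[str, int],
    impact_table: pd.DataFrame,
    spectrum: Mapping[tuple[str, str], float] | None = None,
    confidence: float = 0.95,
) -> SelectionEstimate:
    """Estimate omega for truncating and missense variants in one gene.

    ``observed_mutations`` is either a mutation table classifiable with
    :func:`classify_observed` or a precomputed mapping with keys
    ``n_syn, n_mis, n_trunc``. With zero synonymous mutations the omega MLE
    is +inf with a finite lower bound; with zero observed mutations overall
    the result is marked untestable.
    """
    if isinstance(observed_mutations, Mapping):
        n_syn = int(observed_mutations["n_syn"])
        n_mis = int(observed_mutations["n_mis"])
        n_trunc = int(observed_mutations["n_trunc"])
    else:
        classes = classify_observed(observed_mutations, impact_table).map(IMPACT_CLASS)
        n_syn = int((classes == "syn").sum())
        n_mis = int((classes == "mis").sum())
        n_trunc = int((classes == "trunc").sum())

    e_syn, e_mis, e_trunc = expected_class_fractions(impact_table, spectrum)
    if n_syn + n_mis + n_trunc == 0:
        return SelectionEstimate(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            0, 0, 0, e_syn, e_mis, e_trunc, False, testable=False,
        )
    om_t, lo_t, hi_t = _omega_ci(n_syn, n_trunc, e_syn, e_trunc, confidence)
    om_m, lo_m, hi_m = _omega_ci(n_syn, n_mis, e_syn, e_mis, confidence)
    return SelectionEstimate(
        omega_truncating=om_t,
        omega_missense=om_m,
        ci_low_truncating=lo_t,
        ci_high_truncating=hi_t,
        ci_low_missense=lo_m,
        ci_high_missense=hi_m,
        n_syn=n_syn,
        n_mis=n_mis,
        n_trunc=n_trunc,
        e_syn=e_syn,
        e_mis=e_mis,
        e_trunc=e_trunc,
        positive_selection=bool(np.isfinite(lo_t) and lo_t > 1),
    )


def gene_model_from_files(cds_fasta: str, exon_tsv: str, gene_id: str | None = None,
                          strand: str = "+") -> GeneModel:
    """Build a GeneModel from a CDS FASTA and an exon-coordinate TSV.

    The TSV needs columns ``chrom, start, end`` (1-based closed). Splice
    sites default to donor/acceptor +-2 of each internal intron boundary.
    """
    from Bio import SeqIO

    record = next(SeqIO.parse(cds_fasta, "fasta"))
    exons_df = pd.read_csv(exon_tsv, sep="\t")
    exons = [(r.chrom, int(r.start), int(r.end)) for r in exons_df.itertuples()]
    return GeneModel(
        gene_id=gene_id or record.id,
        strand=strand,
        exons=exons,
        cds_sequence=str(record.seq),
        splice_site_positions=GeneModel.default_splice_sites(exons, strand),
    )


__all__ = [
    "CODON_TABLE", "GeneModel", "SelectionEstimate", "translate",
    "enumerate_impacts", "expected_class_fractions", "classify_observed",
    "estimate_dnds", "gene_model_from_files", "IMPACT_CLASS",
]
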