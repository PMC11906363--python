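"""Single-gene dN/dS: impact enumeration oracle, MLE/CI behavior, power."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from secondhit import selection as sel


TOY_CDS = "ATGTGGAAGTAA"  # M W K *


def biopython_impact_oracle(cds, i, alt):
    """Classify a substitution by translating with Biopython."""
    ref_aa = str(Seq(cds).translate())
    mutant = cds[:i] + alt + cds[i + 1:]
    alt_aa = str(Seq(mutant).translate())
    codon_idx = i // 3
    if alt_aa[codon_idx] == ref_aa[codon_idx]:
        return "synonymous"
    if alt_aa[codon_idx] == "*":
        return "nonsense"
    return "missense"


class TestEnumerateImpacts:
    def test_all_substitutions_match_translation_oracle(self):
        gm = sel.GeneModel("toy", "+", [], TOY_CDS)
        table = sel.enumerate_impacts(gm)
        cds_rows = table[table["cds_pos"] > 0]
        assert len(cds_rows) == 3 * len(TOY_CDS)
        for r in cds_rows.itertuples():
            assert r.impact == biopython_impact_oracle(TOY_CDS, r.cds_pos - 1, r.alt), \
                (r.cds_pos, r.ref, r.alt)

    def test_wobble_position_synonymous(self):
        gm = sel.GeneModel("toy", "+", [], "GGGAAATAA")
        table = sel.enumerate_impacts(gm)
        row = table[(table["cds_pos"] == 3) & (table["alt"] == "A")].iloc[0]
        assert row["impact"] == "synonymous"  # GGG -> GGA, both Gly

    def test_tryptophan_to_stop_is_nonsense(self):
        gm = sel.GeneModel("toy", "+", [], TOY_CDS)
        table = sel.enumerate_impacts(gm)
        # TGG codon at cds positions 4-6; G->A at position 5 gives TAG
        row = table[(table["cds_pos"] == 5) & (table["alt"] == "A")].iloc[0]
        assert row["impact"] == "nonsense"

    def test_splice_rows_classified_truncating(self):
        gm = sel.GeneModel("toy", "+", [], TOY_CDS, splice_site_positions={501, 502})
        table = sel.enumerate_impacts(gm)
        splice = table[table["impact"] == "splice"]
        assert set(splice["genomic_pos"].astype(int)) == {501, 502}
        assert (splice["cds_pos"] == 0).all()

    def test_cds_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            sel.GeneModel("bad", "+", [], "ATGA")

    def test_exon_projection_must_reproduce_cds(self):
        with pytest.raises(ValueError, match="exon"):
            sel.GeneModel("bad", "+", [("chr17", 1, 5)], TOY_CDS)


class TestExpectedClassFractions:
    def test_uniform_spectrum_matches_hand_enumeration(self):
        gm = sel.GeneModel("toy", "+", [], TOY_CDS)
        table = sel.enumerate_impacts(gm)
        counts = table["impact"].map(sel.IMPACT_CLASS).value_counts()
        n = counts.sum()
        e_syn, e_mis, e_trunc = sel.expected_class_fractions(table)
        assert e_syn == pytest.approx(counts.get("syn", 0) / n)
        assert e_mis == pytest.approx(counts.get("mis", 0) / n)
        assert e_trunc == pytest.approx(counts.get("trunc", 0) / n)

    def test_fractions_sum_to_one_for_any_spectrum(self):
        rng = np.random.default_rng(0)
        gm = sel.GeneModel("toy", "+", [], TOY_CDS)
        table = sel.enumerate_impacts(gm)
        spectrum = {(c, a): float(rng.random())
                    for c in set(table["context"]) for a in "ACGT"}
        fracs = sel.expected_class_fractions(table, spectrum)
        assert sum(fracs) == pytest.approx(1.0)

    def test_spectrum_scaling_invariance(self):
        gm = sel.GeneModel("toy", "+", [], TOY_CDS)
        table = sel.enumerate_impacts(gm)
        rng = np.random.default_rng(1)
        spectrum = {(c, a): float(rng.random())
                    for c in set(table["context"]) for a in "ACGT"}
        scaled = {k: 7.3 * v for k, v in spectrum.items()}
        assert sel.expected_class_fractions(table, spectrum) == pytest.approx(
            sel.expected_class_fractions(table, scaled)
        )

    def test_spectrum_with_no_mass_on_gene_rejected(self):
        gm = sel.GeneModel("toy", "+", [], TOY_CDS)
        table = sel.enumerate_impacts(gm)
        dead = {(c, a): 0.0 for c in set(table["context"]) for a in "ACGT"}
        with pytest.raises(ValueError, match="zero rate"):
            sel.expected_class_fractions(table, dead)


def _neutral_gene(n_codons=120, seed=0):
    rng = np.random.default_rng(seed)
    body = "".join(rng.choice(list("ACGT"), size=3 * n_codons))
    return sel.GeneModel("g", "+", [], "ATG" + body + "TAA")


class TestEstimateDnds:
    def test_counts_proportional_to_expectation_give_omega_one(self):
        gm = _neutral_gene()
        table = sel.enumerate_impacts(gm)
        e_syn, e_mis, e_trunc = sel.expected_class_fractions(table)
        scale = 1000
        est = sel.estimate_dnds(
            {"n_syn": round(scale * e_syn), "n_mis": round(scale * e_mis),
             "n_trunc": round(scale * e_trunc)},
            table,
        )
        assert est.omega_truncating == pytest.approx(1.0, abs=0.05)
        assert est.omega_missense == pytest.approx(1.0, abs=0.02)

    def test_mle_equals_closed_form_ratio_oracle(self):
        gm = sel.GeneModel("toy", "+", [], TOY_CDS)
        table = sel.enumerate_impacts(gm)
        e_syn, e_mis, e_trunc = sel.expected_class_fractions(table)
        n = {"n_syn": 4, "n_mis": 9, "n_trunc": 3}
        est = sel.estimate_dnds(n, table)
        assert est.omega_truncating == pytest.approx(
            (n["n_trunc"] / e_trunc) / (n["n_syn"] / e_syn), rel=1e-9
        )
        assert est.omega_missense == pytest.approx(
            (n["n_mis"] / e_mis) / (n["n_syn"] / e_syn), rel=1e-9
        )

    def test_zero_synonymous_gives_infinite_mle_finite_lower_bound(self):
        gm = _neutral_gene()
        table = sel.enumerate_impacts(gm)
        est = sel.estimate_dnds({"n_syn": 0, "n_mis": 2, "n_trunc": 8}, table)
        assert np.isinf(est.omega_truncating)
        assert np.isfinite(est.ci_low_truncating) and est.ci_low_truncating > 0
        assert np.isinf(est.ci_high_truncating)

    def test_zero_observed_mutations_untestable(self):
        table = sel.enumerate_impacts(_neutral_gene())
        est = sel.estimate_dnds({"n_syn": 0, "n_mis": 0, "n_trunc": 0}, table)
        assert est.testable is False and est.positive_selection is False

    def test_positive_selection_iff_ci_low_above_one(self):
        table = sel.enumerate_impacts(_neutral_gene())
        strong = sel.estimate_dnds({"n_syn": 2, "n_mis": 10, "n_trunc": 25}, table)
        assert strong.ci_low_truncating > 1 and strong.positive_selection
        weak = sel.estimate_dnds({"n_syn": 10, "n_mis": 20, "n_trunc": 1}, table)
        assert weak.ci_low_truncating <= 1 and not weak.positive_selection

    def test_observed_mutation_table_classification(self):
        gm = sel.GeneModel("toy", "+", [], TOY_CDS, splice_site_positions={900})
        table = sel.enumerate_impacts(gm)
        observed = pd.DataFrame({
            "cds_pos": [5, 9, 0], "ref": ["G", "G", "N"],
            "alt": ["A", "A", "T"], "genomic_pos": [np.nan, np.nan, 900],
        })
        est = sel.estimate_dnds(observed, table)
        # TGG->TAG nonsense + splice are truncating; AAG->AAA is synonymous
        assert (est.n_trunc, est.n_syn) == (2, 1)

    def test_unclassifiable_observation_rejected(self):
        gm = sel.GeneModel("toy", "+", [], TOY_CDS)
        table = sel.enumerate_impacts(gm)
        bad = pd.DataFrame({"cds_pos": [2], "ref": ["G"], "alt": ["A"]})
        # cds position 2 is 'T' in ATG..., ref mismatch
        with pytest.raises(ValueError, match="not classifiable"):
            sel.estimate_dnds(bad, table)


class TestCalibrationAndPower:
    def test_neutral_simulation_ci_covers_one(self):
        """Neutral multinomial draws (n=50): the 95% truncating CI covers
        1 in ~95% of 1,000 replicates and the median MLE is near 1."""
        table = sel.enumerate_impacts(_neutral_gene(seed=3))
        e = sel.expected_class_fractions(table)
        rng = np.random.default_rng(23)
        covered, omegas = 0, []
        n_rep = 1000
        for _ in range(n_rep):
            n_syn, n_mis, n_trunc = rng.multinomial(50, e)
            est = sel.estimate_dnds(
                {"n_syn": n_syn, "n_mis": n_mis, "n_trunc": n_trunc}, table
            )
            lo = est.ci_low_truncating if np.isfinite(est.ci_low_truncating) else 0.0
            hi = est.ci_high_truncating if not np.isnan(est.ci_high_truncating) else np.inf
            covered += lo <= 1.0 <= hi
            if np.isfinite(est.omega_truncating):
                omegas.append(est.omega_truncating)
        assert 0.92 <= covered / n_rep <= 0.99
        assert 0.8 <= float(np.median(omegas)) <= 1.25

    def test_tenfold_truncating_excess_detected(self):
        """10x excess of truncating mutations: positive selection called in
        >90% of replicates at n=40 observed mutations."""
        table = sel.enumerate_impacts(_neutral_gene(seed=3))
        e_syn, e_mis, e_trunc = sel.expected_class_fractions(table)
        probs = np.array([e_syn, e_mis, 10 * e_trunc])
        probs /= probs.sum()
        rng = np.random.default_rng(31)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            n_syn, n_mis, n_trunc = rng.multinomial(40, probs)
            est = sel.estimate_dnds(
                {"n_syn": n_syn, "n_mis": n_mis, "n_trunc": n_trunc}, table
            )
            hits += est.positive_selection
        assert hits / n_rep > 0.9
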