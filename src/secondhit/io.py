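"""File interchange: TSV tables, VCF variants, JSON truth and configs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .simulate import Cohort, Individual, Variant


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_config(path) -> dict:
    """Read a JSON or YAML run/cohort configuration."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _vcf_header(genome: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in genome.items():
        header.contigs.add(chrom, length=length)
    header.info.add("ORIGIN", 1, "String", "Variant origin (germline/somatic/second_hit)")
    header.info.add("MUTID", 1, "String", "Simulator mutation identifier")
    return header


def write_variants_vcf(
    variants: Iterable[tuple[Variant, str, str]],
    genome: Mapping[str, int],
    path,
) -> None:
    """Write (variant, origin, mutation_id) triples to an uncompressed VCF."""
    header = _vcf_header(genome)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        records = sorted(variants, key=lambda t: (t[0].chrom, t[0].pos))
        for var, origin, mid in records:
            rec = vcf.new_record(
                contig=var.chrom, start=var.pos - 1, stop=var.pos,
                alleles=(var.ref, var.alt),
            )
            rec.info["ORIGIN"] = origin
            rec.info["MUTID"] = mid
            vcf.write(rec)


def read_variants_vcf(path) -> pd.DataFrame:
    """Read a VCF into a site table (chrom, pos, ref, alt, origin, mutation_id)."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            rows.append(
                (
                    rec.contig, rec.pos, rec.ref, rec.alts[0] if rec.alts else ".",
                    rec.info.get("ORIGIN", "."), rec.info.get("MUTID", "."),
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "origin", "mutation_id"])


def individual_truth(ind: Individual) -> dict:
    """JSON-serializable ground truth for one simulated individual."""
    return {
        "individual_id": ind.individual_id,
        "tree": {
            "parents": {str(n): p for n, p in ind.tree.parents.items()},
            "branch_mutations": {
                str(n): sorted(m) for n, m in ind.tree.branch_mutations.items()
            },
        },
        "catalog": {
            mid: {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt}
            for mid, v in ind.tree.catalog.items()
        },
        "clones": {
            str(n): (
                None
                if c.second_hit is None
                else {
                    "kind": c.second_hit.kind,
                    "mutation_id": c.second_hit.mutation_id,
                    "lost_haplotype": c.second_hit.lost_haplotype,
                    "mechanism": c.second_hit.mechanism,
                }
            )
            for n, c in ind.clones.items()
        },
        "samples": [
            {
                "sample_id": s.sample_id,
                "modality": s.modality,
                "clone_fractions": {str(k): v for k, v in s.clone_fractions.items()},
                "tumor_contamination": s.tumor_contamination,
                "target_depth": s.target_depth,
                "error_rate": s.error_rate,
            }
            for s in ind.samples
        ],
        "germline_hit": None
        if ind.germline_hit is None
        else {
            "chrom": ind.germline_hit.chrom,
            "pos": ind.germline_hit.pos,
            "ref": ind.germline_hit.ref,
            "alt": ind.germline_hit.alt,
        },
        "snp_panel": [
            {
                "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
                "alt_on_mutant": s.alt_on_mutant,
            }
            for s in ind.germline_hets.values()
        ],
        "tumor_node": ind.tumor_node,
        "truncal_mutation_ids": sorted(ind.truncal_mutation_ids),
        "gene_footprint": list(ind.gene_footprint),
        "genome": dict(ind.genome),
    }


def write_cohort_truth(cohort: Cohort, path) -> None:
    write_json({ind.individual_id: individual_truth(ind) for ind in cohort.individuals}, path)


def cohort_variants(ind: Individual) -> list[tuple[Variant, str, str]]:
    """All of an individual's variants, labeled by origin, for VCF export."""
    out: list[tuple[Variant, str, str]] = []
    if ind.germline_hit is not None:
        g = ind.germline_hit
        out.append((Variant(g.chrom, g.pos, g.ref, g.alt), "germline", "germline_hit"))
    for s in ind.germline_hets.values():
        out.append((Variant(s.chrom, s.pos, s.ref, s.alt), "germline", "."))
    second_hit_ids = {
        c.second_hit.mutation_id
        for c in ind.clones.values()
        if c.second_hit is not None and c.second_hit.kind == "point"
    }
    for mid, v in ind.tree.catalog.items():
        origin = "second_hit" if mid in second_hit_ids else "somatic"
        out.append((v, origin, mid))
    return out


__all__ = [
    "write_tsv", "read_tsv", "read_config", "write_json",
    "write_variants_vcf", "read_variants_vcf",
    "individual_truth", "write_cohort_truth", "cohort_variants",
]
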