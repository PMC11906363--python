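"""Synthetic cohort simulator with lineage-tree ground truth.

The simulator reproduces the statistical structure that the downstream
modules assume, so that every caller can be validated against known truth:

* a proband carrying a heterozygous germline truncating variant in a
  recessive predisposition gene on chromosome 17, whose tumor shows complete
  chromosome-17 copy-neutral LOH retaining the mutant haplotype;
* normal samples that are mixtures of lineage-tree clones, some carrying
  independent somatic "second hits" — point mutations in the gene footprint
  or LOH of either parental haplotype (copy-neutral or one-copy deletion);
* low-level tumor contamination of normal samples;
* binomial read sampling with a uniform substitution-error model (an error
  lands on a specific alternate base with probability e/3);
* duplex read bundles: per-molecule, per-strand read counts with independent
  single-strand errors.

The genome model is diploid everywhere except simulated LOH segments.
Coordinates are 1-based and fully closed, as in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import child_seed

_BASES = np.array(list("ACGT"))

#: Default genome: three autosomes; chromosome 17 carries the predisposition
#: gene, lineage (somatic background) mutations are placed on the others so
#: that truncal sites stay diploid-heterozygous.
DEFAULT_GENOME: dict[str, int] = {
    "chr2": 240_000_000,
    "chr7": 159_000_000,
    "chr17": 83_000_000,
}

#: Predisposition-gene footprint (the large recessive gene on 17q).
DEFAULT_GENE_FOOTPRINT = ("chr17", 31_094_927, 31_377_677)


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GermlineHet:
    """A heterozygous germline variant with (optional) haplotype phase.

    ``alt_on_mutant`` is True when the alternate allele lies on the
    haplotype that carries the germline predisposition hit, False when it
    lies on the wild-type haplotype, and None when unphased (control
    individuals, whose gene locus never undergoes LOH in the tumor, cannot
    be phased).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_on_mutant: bool | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class LineageTree:
    """A clonal genealogy: rooted tree with mutations assigned to branches.

    A node's genotype is the union of the branch mutation sets on its path
    to the root. The root branch is empty (the root is the zygote; somatic
    mutations accrue on the branches below it).
    """

    def __init__(
        self,
        parents: Mapping[int, int | None],
        branch_mutations: Mapping[int, frozenset[str]],
        catalog: Mapping[str, Variant],
    ):
        self.parents = dict(parents)
        self.branch_mutations = {n: frozenset(m) for n, m in branch_mutations.items()}
        self.catalog = dict(catalog)
        self._genotype_cache: dict[int, frozenset[str]] = {}
        self._validate()

    def _validate(self) -> None:
        roots = [n for n, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for node in self.parents:
            seen = set()
            cur: int | None = node
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle detected through node {node}")
                seen.add(cur)
                cur = self.parents[cur]
        all_ids = [m for s in self.branch_mutations.values() for m in s]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("mutation ids must be globally unique across branches")
        missing = set(all_ids) - set(self.catalog)
        if missing:
            raise ValueError(f"mutations missing from catalog: {sorted(missing)[:5]}")

    @property
    def nodes(self) -> list[int]:
        return sorted(self.parents)

    def path_to_root(self, node: int) -> list[int]:
        path = []
        cur: int | None = node
        while cur is not None:
            path.append(cur)
            cur = self.parents[cur]
        return path

    def genotype(self, node: int) -> frozenset[str]:
        """Somatic mutations carried by cells of ``node``."""
        cached = self._genotype_cache.get(node)
        if cached is not None:
            return cached
        out: set[str] = set()
        for n in self.path_to_root(node):
            out |= self.branch_mutations.get(n, frozenset())
        result = frozenset(out)
        self._genotype_cache[node] = result
        return result

    def shared_mutations(self, a: int, b: int) -> frozenset[str]:
        return self.genotype(a) & self.genotype(b)


@dataclass(frozen=True)
class SecondHit:
    """Somatic inactivation of the remaining wild-type allele.

    Either a point mutation inside the gene footprint (``kind='point'``,
    carried on the wild-type haplotype) or an LOH event losing one parental
    haplotype by copy-neutral replacement or one-copy deletion.
    """

    kind: str  # 'point' | 'loh'
    mutation_id: str | None = None
    lost_haplotype: str | None = None  # 'wt' | 'mutant'
    mechanism: str | None = None  # 'cnloh' | 'deletion'

    def __post_init__(self):
        if self.kind == "point":
            if self.mutation_id is None:
                raise ValueError("point second hit needs a mutation_id")
        elif self.kind == "loh":
            if self.lost_haplotype not in ("wt", "mutant"):
                raise ValueError("loh second hit needs lost_haplotype in {'wt','mutant'}")
            if self.mechanism not in ("cnloh", "deletion"):
                raise ValueError("loh second hit needs mechanism in {'cnloh','deletion'}")
        else:
            raise ValueError(f"unknown second-hit kind {self.kind!r}")


@dataclass(frozen=True)
class Clone:
    node_id: int
    second_hit: SecondHit | None = None


@dataclass(frozen=True)
class SampleSpec:
    """A sequenced sample: a mixture of clones plus tumor contamination.

    Clone fractions plus ``tumor_contamination`` must sum to at most 1; the
    remainder is wild-type background (cells carrying only the germline
    genotype of the root lineage).
    """

    sample_id: str
    modality: str = "bulk"  # 'bulk' | 'lcm'
    clone_fractions: Mapping[int, float] = field(default_factory=dict)
    tumor_contamination: float = 0.0
    target_depth: float = 30.0
    error_rate: float = 1e-3

    def __post_init__(self):
        if self.modality not in ("bulk", "lcm"):
            raise ValueError(f"modality must be 'bulk' or 'lcm', got {self.modality!r}")
        total = sum(self.clone_fractions.values()) + self.tumor_contamination
        if total > 1 + 1e-9:
            raise ValueError(
                f"clone fractions + contamination sum to {total:.4f} > 1 "
                f"in sample {self.sample_id}"
            )
        if any(f < 0 for f in self.clone_fractions.values()):
            raise ValueError("clone fractions must be nonnegative")
        if not (0 <= self.tumor_contamination <= 1):
            raise ValueError("tumor_contamination must be in [0,1]")
        if self.target_depth < 0:
            raise ValueError("target_depth must be >= 0")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0,1)")


@dataclass
class Individual:
    individual_id: str
    tree: LineageTree
    clones: dict[int, Clone]
    samples: list[SampleSpec]
    germline_hets: dict[tuple[str, int], GermlineHet]
    germline_hit: GermlineHet | None
    gene_footprint: tuple[str, int, int]
    tumor_node: int | None
    truncal_mutation_ids: frozenset[str]
    genome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))

    def clone_for_node(self, node_id: int) -> Clone:
        return self.clones.get(node_id, Clone(node_id=node_id))


@dataclass
class Cohort:
    proband: Individual
    controls: list[Individual]

    @property
    def individuals(self) -> list[Individual]:
        return [self.proband, *self.controls]


# ---------------------------------------------------------------------------
# Lineage simulation


def _random_variants(rng: np.random.Generator, n: int, genome: Mapping[str, int],
                     exclude_chroms: Sequence[str] = ()) -> list[Variant]:
    chroms = [c for c in genome if c not in exclude_chroms]
    if not chroms and n > 0:
        raise ValueError("no chromosomes available for mutation placement")
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    out: list[Variant] = []
    used: set[tuple[str, int]] = set()
    while len(out) < n:
        ci = rng.choice(len(chroms), p=lengths / lengths.sum())
        pos = int(rng.integers(1, genome[chroms[ci]] + 1))
        if (chroms[ci], pos) in used:
            continue  # collisions are vanishingly rare; resample
        used.add((chroms[ci], pos))
        ref, alt = rng.choice(4, size=2, replace=False)
        out.append(Variant(chroms[ci], pos, str(_BASES[ref]), str(_BASES[alt])))
    return out


def simulate_lineage(
    n_nodes: int,
    branch_mutation_rate: float,
    seed: int,
    genome: Mapping[str, int] | None = None,
    exclude_chroms: Sequence[str] = ("chr17",),
    id_prefix: str = "m",
    topology: str = "random",
) -> LineageTree:
    """Simulate a clonal genealogy with Poisson branch mutations.

    Node 0 is the root (zygote, empty branch); with ``topology='random'``
    each later node attaches to a uniformly chosen earlier node, while
    ``topology='star'`` attaches every node directly to the root (mutually
    unrelated clones — exact ground truth for explicit clone plans). Each
    non-root node acquires Poisson(``branch_mutation_rate``) private
    mutations on its branch. Deterministic given ``seed``.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if branch_mutation_rate < 0:
        raise ValueError("branch_mutation_rate must be >= 0")
    if topology not in ("random", "star"):
        raise ValueError("topology must be 'random' or 'star'")
    genome = dict(genome or DEFAULT_GENOME)
    rng = np.random.default_rng(seed)

    parents: dict[int, int | None] = {0: None}
    for i in range(1, n_nodes):
        parents[i] = 0 if topology == "star" else int(rng.integers(0, i))

    counts = rng.poisson(branch_mutation_rate, size=n_nodes)
    counts[0] = 0
    variants = _random_variants(rng, int(counts.sum()), genome, exclude_chroms)

    branch_mutations: dict[int, frozenset[str]] = {}
    catalog: dict[str, Variant] = {}
    k = 0
    for node in range(n_nodes):
        ids = []
        for _ in range(counts[node]):
            mid = f"{id_prefix}{k}"
            catalog[mid] = variants[k]
            ids.append(mid)
            k += 1
        branch_mutations[node] = frozenset(ids)
    return LineageTree(parents, branch_mutations, catalog)


# ---------------------------------------------------------------------------
# Cohort configuration


@dataclass
class CloneSpecConfig:
    node_id: int
    second_hit: SecondHit | None


@dataclass
class CohortConfig:
    """Explicit cohort plan: the clone plan is configuration, not random,

    so that ground truth is exactly known. Defaults emulate the study
    conditions: a predisposed child whose normal tissues harbor independent
    second-hit clones at cell fractions seen in microdissections (point-hit
    clones up to 56% of cells, haplotype-resolved LOH clones of 2-13%, plus
    rare mutant-allele-loss clones in mesodermal tissue), a 95%-pure tumor
    sample, and low-level (<1%) tumor contamination of normal samples.
    """

    genome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    gene_footprint: tuple[str, int, int] = DEFAULT_GENE_FOOTPRINT
    n_snps: int = 200
    n_lineage_nodes: int = 12
    branch_mutation_rate: float = 150.0
    tumor_truncal_mutations: int = 300
    normal_contamination: float = 0.005
    tumor_purity: float = 0.95
    target_depth: float = 30.0
    error_rate: float = 1e-3
    clone_plan: list[CloneSpecConfig] | None = None
    sample_plan: list[SampleSpec] | None = None

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "clone_plan" in d and d["clone_plan"] is not None:
            plan = []
            for c in d["clone_plan"]:
                hit = c.get("second_hit")
                plan.append(
                    CloneSpecConfig(
                        node_id=int(c["node_id"]),
                        second_hit=SecondHit(**hit) if hit else None,
                    )
                )
            d["clone_plan"] = plan
        if "sample_plan" in d and d["sample_plan"] is not None:
            d["sample_plan"] = [
                SampleSpec(
                    sample_id=s["sample_id"],
                    modality=s.get("modality", "bulk"),
                    clone_fractions={int(k): float(v) for k, v in s.get("clone_fractions", {}).items()},
                    tumor_contamination=float(s.get("tumor_contamination", 0.0)),
                    target_depth=float(s.get("target_depth", 30.0)),
                    error_rate=float(s.get("error_rate", 1e-3)),
                )
                for s in d["sample_plan"]
            ]
        if "gene_footprint" in d:
            d["gene_footprint"] = tuple(d["gene_footprint"])
        return cls(**d)


def _default_clone_plan() -> list[CloneSpecConfig]:
    return [
        # point second hit (truncating, on the wild-type haplotype)
        CloneSpecConfig(2, SecondHit(kind="point", mutation_id="second_hit_point")),
        # CN-LOH clones losing the wild-type haplotype (13% and 2% cell fractions)
        CloneSpecConfig(3, SecondHit(kind="loh", lost_haplotype="wt", mechanism="cnloh")),
        CloneSpecConfig(4, SecondHit(kind="loh", lost_haplotype="wt", mechanism="cnloh")),
        # deletion losing the *mutant* haplotype (mesodermal phenomenon)
        CloneSpecConfig(5, SecondHit(kind="loh", lost_haplotype="mutant", mechanism="deletion")),
    ]


def _default_sample_plan(cfg: CohortConfig) -> list[SampleSpec]:
    c, d, e = cfg.normal_contamination, cfg.target_depth, cfg.error_rate
    return [
        SampleSpec("tumor_bulk", "bulk", {}, cfg.tumor_purity, d, e),
        SampleSpec("lcm_parietal", "lcm", {2: 0.56}, c, d, e),
        SampleSpec("bulk_parietal", "bulk", {2: 0.19}, c, d, e),
        SampleSpec("lcm_occipital", "lcm", {3: 0.13}, c, d, e),
        SampleSpec("lcm_cerebellum", "lcm", {4: 0.02}, c, d, e),
        SampleSpec("lcm_bladder", "lcm", {5: 0.10}, c, d, e),
        SampleSpec("lcm_clean_1", "lcm", {6: 0.30}, c, d, e),
        SampleSpec("lcm_clean_2", "lcm", {7: 0.30}, c, d, e),
        SampleSpec("bulk_clean_1", "bulk", {}, c, d, e),
        SampleSpec("bulk_clean_2", "bulk", {}, 0.0, d, e),
    ]


def _control_sample_plan(cfg: CohortConfig, ind: str) -> list[SampleSpec]:
    d, e = cfg.target_depth, cfg.error_rate
    return [
        SampleSpec(f"{ind}_lcm_1", "lcm", {2: 0.4}, 0.0, d, e),
        SampleSpec(f"{ind}_lcm_2", "lcm", {3: 0.4}, 0.0, d, e),
        SampleSpec(f"{ind}_bulk_1", "bulk", {}, 0.0, d, e),
    ]


def _make_snp_panel(rng: np.random.Generator, cfg: CohortConfig,
                    phased: bool) -> dict[tuple[str, int], GermlineHet]:
    chrom, length = "chr17", cfg.genome["chr17"]
    positions = np.sort(rng.choice(np.arange(10_000, length - 10_000), size=cfg.n_snps,
                                   replace=False))
    panel = {}
    for pos in positions:
        ref, alt = rng.choice(4, size=2, replace=False)
        on_mut = bool(rng.integers(0, 2)) if phased else None
        snp = GermlineHet(chrom, int(pos), str(_BASES[ref]), str(_BASES[alt]), on_mut)
        panel[(chrom, int(pos))] = snp
    return panel


def simulate_cohort(config: CohortConfig | Mapping | None = None, seed: int = 0) -> Cohort:
    """Simulate a proband and two unaffected control individuals.

    The proband carries a heterozygous germline truncating hit in the gene
    footprint in every cell; its tumor node has whole-chromosome-17 CN-LOH
    retaining the mutant haplotype; the clone plan is realized exactly.
    Controls carry no germline hit and no second-hit clones.
    """
    if config is None:
        config = CohortConfig()
    elif not isinstance(config, CohortConfig):
        config = CohortConfig.from_dict(config)

    clone_plan = config.clone_plan if config.clone_plan is not None else _default_clone_plan()
    sample_plan = config.sample_plan if config.sample_plan is not None else _default_sample_plan(config)
    for s in sample_plan:
        total = sum(s.clone_fractions.values()) + s.tumor_contamination
        if total > 1 + 1e-9:
            raise ValueError(f"sample {s.sample_id}: clone fractions exceed 1")

    individuals: list[Individual] = []
    for idx, ind_id in enumerate(["proband", "control_1", "control_2"]):
        is_proband = idx == 0
        ind_seed = child_seed(seed, f"individual:{ind_id}")
        rng = np.random.default_rng(ind_seed)
        n_nodes = max(config.n_lineage_nodes,
                      1 + max((c.node_id for c in clone_plan), default=0))
        tree = simulate_lineage(
            n_nodes, config.branch_mutation_rate,
            seed=child_seed(ind_seed, "lineage"), genome=config.genome,
            topology="star",
        )

        panel = _make_snp_panel(np.random.default_rng(child_seed(ind_seed, "snps")),
                                config, phased=is_proband)

        germline_hit = None
        tumor_node = None
        truncal: frozenset[str] = frozenset()
        clones: dict[int, Clone] = {}

        if is_proband:
            chrom, start, end = config.gene_footprint
            hit_pos = (start + end) // 2
            germline_hit = GermlineHet(chrom, hit_pos, "G", "A", alt_on_mutant=True)

            # graft a tumor node onto node 1 with its own truncal branch
            tumor_node = n_nodes
            parents = dict(tree.parents)
            parents[tumor_node] = 1
            trunk_vars = _random_variants(
                np.random.default_rng(child_seed(ind_seed, "trunk")),
                config.tumor_truncal_mutations, config.genome, exclude_chroms=("chr17",),
            )
            catalog = dict(tree.catalog)
            trunk_ids = []
            for j, v in enumerate(trunk_vars):
                mid = f"trunk{j}"
                catalog[mid] = v
                trunk_ids.append(mid)
            branch = dict(tree.branch_mutations)
            branch[tumor_node] = frozenset(trunk_ids)
            tree = LineageTree(parents, branch, catalog)
            # the trunk of the tumor phylogeny: everything present in all tumor cells
            truncal = tree.genotype(tumor_node)

            hit_rng = np.random.default_rng(child_seed(ind_seed, "second_hits"))
            for cs in clone_plan:
                hit = cs.second_hit
                if hit is not None and hit.kind == "point":
                    # materialize the point hit inside the gene footprint
                    pos = int(hit_rng.integers(start, end + 1))
                    ref, alt = hit_rng.choice(4, size=2, replace=False)
                    mid = hit.mutation_id
                    catalog = dict(tree.catalog)
                    catalog[mid] = Variant(chrom, pos, str(_BASES[ref]), str(_BASES[alt]))
                    branch = dict(tree.branch_mutations)
                    branch[cs.node_id] = branch.get(cs.node_id, frozenset()) | {mid}
                    tree = LineageTree(tree.parents, branch, catalog)
                clones[cs.node_id] = Clone(cs.node_id, hit)
            samples = sample_plan
        else:
            samples = _control_sample_plan(config, ind_id)

        individuals.append(
            Individual(
                individual_id=ind_id,
                tree=tree,
                clones=clones,
                samples=list(samples),
                germline_hets=panel,
                germline_hit=germline_hit,
                gene_footprint=config.gene_footprint,
                tumor_node=tumor_node,
                truncal_mutation_ids=truncal,
                genome=dict(config.genome),
            )
        )

    return Cohort(proband=individuals[0], controls=individuals[1:])


# ---------------------------------------------------------------------------
# Read-count emission


def _haplotype_copies(second_hit: SecondHit | None) -> tuple[float, float]:
    """(mutant-haplotype copies, wt-haplotype copies) for cells of a clone."""
    if second_hit is None or second_hit.kind == "point":
        return 1.0, 1.0
    lost_mut = second_hit.lost_haplotype == "mutant"
    if second_hit.mechanism == "cnloh":
        return (0.0, 2.0) if lost_mut else (2.0, 0.0)
    return (0.0, 1.0) if lost_mut else (1.0, 0.0)


_CATALOG_INDEX_CACHE: dict[int, tuple[object, dict]] = {}


def _catalog_index(individual: Individual) -> dict[tuple[str, int, str], str]:
    """(chrom, pos, alt) -> mutation_id lookup, memoized per tree object."""
    key = id(individual.tree)
    cached = _CATALOG_INDEX_CACHE.get(key)
    if cached is not None and cached[0] is individual.tree.catalog:
        return cached[1]
    index = {(v.chrom, v.pos, v.alt): mid for mid, v in individual.tree.catalog.items()}
    _CATALOG_INDEX_CACHE[key] = (individual.tree.catalog, index)
    return index


def true_vaf(individual: Individual, sample_spec: SampleSpec,
             chrom: str, pos: int, alt: str) -> float:
    """Expected alternate-allele fraction at a site, before sequencing error.

    Mixture over clones, tumor contamination and wild-type background, with
    per-haplotype copy numbers on chromosome-17 LOH events. Sites carrying
    no simulated variant return 0.
    """
    pops: list[tuple[float, SecondHit | None, frozenset[str]]] = []
    total_clone = 0.0
    for node, f in sample_spec.clone_fractions.items():
        pops.append((f, individual.clone_for_node(node).second_hit, individual.tree.genotype(node)))
        total_clone += f
    t = sample_spec.tumor_contamination
    if t > 0:
        if individual.tumor_node is None:
            raise ValueError(f"{individual.individual_id} has no tumor node but "
                             f"sample {sample_spec.sample_id} requests contamination")
        tumor_hit = SecondHit(kind="loh", lost_haplotype="wt", mechanism="cnloh")
        pops.append((t, tumor_hit, individual.tree.genotype(individual.tumor_node)))
    bg = 1.0 - total_clone - t
    if bg > 1e-12:
        pops.append((bg, None, frozenset()))

    germ = individual.germline_hets.get((chrom, pos))
    if germ is None and individual.germline_hit is not None and \
            (chrom, pos) == (individual.germline_hit.chrom, individual.germline_hit.pos):
        germ = individual.germline_hit

    somatic_id = _catalog_index(individual).get((chrom, pos, alt))

    alt_copies = 0.0
    tot_copies = 0.0
    on_gene_chrom = chrom == individual.gene_footprint[0]
    for f, hit, genotype in pops:
        if germ is not None and germ.alt == alt and on_gene_chrom:
            mut_c, wt_c = _haplotype_copies(hit)
            if germ.alt_on_mutant is None:
                # unphased het in a control: LOH clones exist only without
                # predisposition context; treat as diploid het
                a, n = 1.0, 2.0
            else:
                a = mut_c if germ.alt_on_mutant else wt_c
                n = mut_c + wt_c
        elif germ is not None and germ.alt == alt:
            a, n = 1.0, 2.0
        elif somatic_id is not None:
            carried = somatic_id in genotype
            if hit is not None and hit.kind == "point" and hit.mutation_id == somatic_id:
                carried = True
            a, n = (1.0 if carried else 0.0), 2.0
        else:
            a, n = 0.0, 2.0
        alt_copies += f * a
        tot_copies += f * n
    if tot_copies <= 0:
        return 0.0
    return alt_copies / tot_copies


def emit_read_counts(
    individual: Individual,
    sample_spec: SampleSpec,
    sites: Iterable[tuple[str, int, str, str]],
    seed: int,
) -> pd.DataFrame:
    """Emit a per-site read-count table for one sample.

    depth ~ Poisson(target_depth); alt_depth ~ Binomial(depth, v') with
    v' = v(1-e) + (1-v)e/3, where v is the error-free allele fraction and e
    the per-base error rate. Columns: sample_id, chrom, pos, ref, alt,
    depth, alt_depth.
    """
    rng = np.random.default_rng(seed)
    sites = list(sites)
    for chrom, pos, _, _ in sites:
        if chrom not in individual.genome:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (1 <= pos <= individual.genome[chrom]):
            raise ValueError(f"position {chrom}:{pos} outside simulated genome")
    if not sites:
        return pd.DataFrame(
            columns=["sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_depth"]
        )
    e = sample_spec.error_rate
    v = np.array([true_vaf(individual, sample_spec, c, p, a) for c, p, _, a in sites])
    p = v * (1 - e) + (1 - v) * e / 3.0
    depth = rng.poisson(sample_spec.target_depth, size=len(sites))
    alt = rng.binomial(depth, p)
    return pd.DataFrame(
        {
            "sample_id": sample_spec.sample_id,
            "chrom": [s[0] for s in sites],
            "pos": [s[1] for s in sites],
            "ref": [s[2] for s in sites],
            "alt": [s[3] for s in sites],
            "depth": depth,
            "alt_depth": alt,
        }
    )


def snp_panel_sites(individual: Individual) -> list[tuple[str, int, str, str]]:
    """The phase panel as (chrom, pos, ref, alt) site tuples."""
    return [(s.chrom, s.pos, s.ref, s.alt) for s in individual.germline_hets.values()]


def catalog_sites(individual: Individual, mutation_ids: Iterable[str]) -> list[tuple[str, int, str, str]]:
    out = []
    for mid in mutation_ids:
        v = individual.tree.catalog[mid]
        out.append((v.chrom, v.pos, v.ref, v.alt))
    return out


# ---------------------------------------------------------------------------
# Duplex bundles


def emit_duplex_reads(
    individual: Individual,
    sample_spec: SampleSpec,
    sites: Iterable[tuple[str, int, str, str]],
    single_strand_error: float,
    seed: int,
    mean_molecules: float | None = None,
    reads_per_strand: int = 1,
) -> pd.DataFrame:
    """Emit duplex read bundles: one row per (molecule, strand) per site.

    Each sampled molecule derives from a single cell; a molecule carrying
    the variant shows it on both strands, while single-strand errors are
    injected independently per strand with per-base rate
    ``single_strand_error`` (landing on the specific alternate base with
    probability e/3). Columns: molecule_id, sample_id, chrom, pos, ref, alt,
    strand, reads, variant_reads.
    """
    if not (0 <= single_strand_error < 1):
        raise ValueError("single_strand_error must be in [0,1)")
    if reads_per_strand < 1:
        raise ValueError("reads_per_strand must be >= 1")
    rng = np.random.default_rng(seed)
    if mean_molecules is None:
        mean_molecules = sample_spec.target_depth
    rows = []
    e3 = single_strand_error / 3.0
    for chrom, pos, ref, alt in sites:
        if chrom not in individual.genome or not (1 <= pos <= individual.genome[chrom]):
            raise ValueError(f"site {chrom}:{pos} outside simulated genome")
        v = true_vaf(individual, sample_spec, chrom, pos, alt)
        n_mol = rng.poisson(mean_molecules)
        if n_mol == 0:
            continue
        carrier = rng.random(n_mol) < v
        for i in range(n_mol):
            mol_id = f"{sample_spec.sample_id}:{chrom}:{pos}:mol{i}"
            for strand in ("+", "-"):
                if carrier[i]:
                    var_reads = reads_per_strand
                else:
                    var_reads = int(rng.binomial(reads_per_strand, e3))
                rows.append((mol_id, sample_spec.sample_id, chrom, pos, ref, alt,
                             strand, reads_per_strand, var_reads))
    return pd.DataFrame(
        rows,
        columns=["molecule_id", "sample_id", "chrom", "pos", "ref", "alt",
                 "strand", "reads", "variant_reads"],
    )


__all__ = [
    "Variant", "GermlineHet", "LineageTree", "SecondHit", "Clone", "SampleSpec",
    "Individual", "Cohort", "CohortConfig", "CloneSpecConfig",
    "simulate_lineage", "simulate_cohort", "emit_read_counts", "emit_duplex_reads",
    "true_vaf", "snp_panel_sites", "catalog_sites",
    "DEFAULT_GENOME", "DEFAULT_GENE_FOOTPRINT",
]
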