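"""Seeded simulator of CRISPRi screens with the structure the pipeline assumes.

The generator emulates a bacterial chromosome organised into operons,
a random PAM-constrained guide library on both strands, essential and
near-essential genes whose coding-strand guides deplete over ~17
generations of growth, strand-dependent repression (strong on the
coding strand, weak on the template strand except for dosage-"sensitive"
genes), polar silencing of all downstream operon genes, a phage screen
where guides silencing host factors enrich because their cells survive
lysis, and a cosmid transduction screen whose packaged output depends
jointly on guide fitness and capsid-competence genes.

Counts are drawn multinomially at the configured sequencing depth and
then overdispersed with a gamma-Poisson (negative-binomial) stage.  All
randomness flows from the single seed in :class:`SimulationConfig`;
identical configurations are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import CONTROL_SPACER, Genome, annotate_library, find_protospacers
from .qc import BAD_SEEDS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_library",
    "true_guide_fitness",
    "simulate_growth_screen",
    "simulate_phage_screen",
    "simulate_transduction",
    "simulate_screen_suite",
    "make_design",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic screen; the seed is mandatory.

    Fitness effects are per-generation log2 growth-rate costs: full
    silencing of an essential gene costs ~0.4 doublings per generation,
    so over the default 17 generations a fully effective coding-strand
    guide reaches a log2FC around -6.
    """

    seed: int
    genome_length: int = 200_000
    n_genes: int = 200
    tu_size_mean: float = 2.0  # geometric operon-size distribution
    gene_length_range: tuple[int, int] = (300, 1200)
    intergenic_range: tuple[int, int] = (20, 200)
    fraction_essential: float = 0.20
    fraction_near_essential: float = 0.10
    fraction_sensitive: float = 0.15  # of essential genes
    polar_tail_prob: float = 0.35  # chance an essential operon is labelled tail-only
    coding_effect_mean: float = -0.4  # per generation, full silencing
    coding_effect_sd: float = 0.1
    near_essential_scale: float = 0.3  # of the essential cost
    template_effect_scale: float = 0.1
    repression_efficiency_range: tuple[float, float] = (0.75, 1.0)
    generations: float = 17.0
    polar: bool = True
    bad_seed_penalty: float = -0.08  # per generation, any bad-seed guide
    library_size: int = 8_000
    depth: int = 1_000_000
    n_replicates: int = 3
    dispersion: float = 0.05
    abundance_sigma: float = 0.7  # lognormal initial library skew
    # phage screen
    n_host_factors: int = 10
    protection_effect: float = 0.8  # survival prob. when a host factor is silenced
    survival_floor: float = 0.02  # survival prob. otherwise
    phage_pre_generations: float = 8.0  # growth before the pre-infection sample
    # transduction screen
    n_capsid_genes: int = 10
    packaging_penalty: float = -3.0  # log2 units on packaged output

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("fraction_essential", "fraction_near_essential",
                     "fraction_sensitive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth <= 0 or self.library_size <= 0 or self.genome_length <= 0:
            raise ValueError("depth, library_size and genome_length must be positive")


@dataclass
class GroundTruth:
    """Planted labels and effects backing a simulated screen."""

    genes: pd.DataFrame  # name -> essential, near_essential, sensitive, host_factor, capsid_gene
    gene_cost: pd.Series  # per-generation fitness cost of full silencing
    guide_fitness: pd.Series | None = None  # per-generation effect w per guide
    abundance: pd.Series | None = None  # initial relative library abundance
    survival: pd.Series | None = None  # per-guide survival prob. under phage

    def label_set(self, column: str) -> set[str]:
        return set(self.genes.index[self.genes[column].astype(bool)])


def _stable_stream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named RNG stream (hash() is salted, so avoid it)."""
    tag = int.from_bytes(name.encode(), "little") % (2**31 - 1)
    return np.random.default_rng([int(seed) % 2**31, tag])


def simulate_genome(
    config: SimulationConfig,
) -> tuple[Genome, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Random circular genome with operon-packed genes and planted labels.

    Genes are packed 5'->3' into transcription units of geometric size
    whose members share a strand; labels (essential, near-essential,
    sensitive, host factor, capsid gene) are drawn per the configured
    fractions with exact planted counts recorded in the ground truth.
    """
    rng = _stable_stream(config.seed, "genome")
    seq = "".join(rng.choice(list("ACGT"), size=config.genome_length))
    genome = Genome("sim", seq, circular=True)

    # operon-packed gene placement
    gene_rows = []
    tu_rows = []
    pos = int(rng.integers(0, 1000))
    gi = 0
    tu_i = 0
    p_geo = 1.0 / config.tu_size_mean
    lo_g, hi_g = config.gene_length_range
    lo_i, hi_i = config.intergenic_range
    while gi < config.n_genes:
        size = min(int(rng.geometric(p_geo)), config.n_genes - gi)
        strand = "+" if rng.random() < 0.5 else "-"
        tu_id = f"TU{tu_i:04d}"
        members = []
        for _ in range(size):
            length = int(rng.integers(lo_g, hi_g + 1))
            left, right = pos, pos + length
            if right > config.genome_length - 100:
                raise ValueError(
                    f"genes do not fit in genome_length={config.genome_length}"
                )
            members.append((f"g{gi:04d}", left, right))
            pos = right + int(rng.integers(lo_i // 4 + 1, max(lo_i // 2, 2)))
            gi += 1
        # transcription order: genomic order on '+', reversed on '-'
        ordered = members if strand == "+" else members[::-1]
        for rank, (name, left, right) in enumerate(ordered, start=1):
            gene_rows.append(
                {"name": name, "left": left, "right": right, "strand": strand,
                 "tu_id": tu_id, "tu_rank": rank}
            )
            tu_rows.append({"tu_id": tu_id, "gene": name, "rank": rank,
                            "strand": strand})
        pos += int(rng.integers(lo_i, hi_i + 1))
        tu_i += 1

    genes = pd.DataFrame(gene_rows).sort_values("left", ignore_index=True)
    tus = pd.DataFrame(tu_rows)

    names = genes["name"].tolist()
    n = len(names)
    n_ess = round(config.fraction_essential * n)
    n_near = round(config.fraction_near_essential * n)

    # Essential genes cluster in operons; occasionally only the tail of
    # an operon is essential, leaving upstream genes as polar
    # false-positive generators.
    tu_order = {t: grp.sort_values("rank")["gene"].tolist()
                for t, grp in tus.groupby("tu_id")}
    shuffled = list(tu_order)
    rng.shuffle(shuffled)
    ess_set: set[str] = set()
    near_set: set[str] = set()
    for tu in shuffled:
        members = tu_order[tu]
        if len(ess_set) < n_ess:
            if len(members) > 1 and rng.random() < config.polar_tail_prob:
                k = int(rng.integers(1, len(members)))
                chosen = members[-k:]  # downstream tail only
            else:
                chosen = members
            ess_set.update(chosen[: n_ess - len(ess_set)])
        elif len(near_set) < n_near:
            near_set.update(members[: n_near - len(near_set)])
        else:
            break
    ess = np.array([g in ess_set for g in names])
    near = np.array([g in near_set for g in names])
    sens = np.zeros(n, dtype=bool)
    ess_positions = np.flatnonzero(ess)
    n_sens = round(config.fraction_sensitive * len(ess_positions))
    sens[rng.choice(ess_positions, size=n_sens, replace=False)] = True

    # host factors and capsid genes among non-essential genes
    free = np.flatnonzero(~ess & ~near)
    pick = rng.choice(free, size=min(len(free),
                                     config.n_host_factors + config.n_capsid_genes),
                      replace=False)
    host = np.zeros(n, dtype=bool)
    capsid = np.zeros(n, dtype=bool)
    host[pick[: config.n_host_factors]] = True
    capsid[pick[config.n_host_factors :]] = True

    cost = np.zeros(n)
    cost[ess] = rng.normal(config.coding_effect_mean, config.coding_effect_sd,
                           size=int(ess.sum()))
    cost[near] = config.near_essential_scale * rng.normal(
        config.coding_effect_mean, config.coding_effect_sd, size=int(near.sum())
    )
    cost = np.minimum(cost, 0.0)

    truth_genes = pd.DataFrame(
        {"essential": ess, "near_essential": near, "sensitive": sens,
         "host_factor": host, "capsid_gene": capsid},
        index=pd.Index(names, name="gene"),
    )
    genes["essential"] = genes["name"].map(truth_genes["essential"])
    truth = GroundTruth(
        genes=truth_genes,
        gene_cost=pd.Series(cost, index=truth_genes.index, name="cost"),
    )
    return genome, genes, tus, truth


def simulate_library(
    genome: Genome,
    genes: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Uniform sample of protospacer sites plus the non-targeting control.

    Guides are annotated with their target gene and strand semantics;
    ``n_perfect_sites`` counts exact 20-nt+NGG occurrences via the full
    enumerated site list.
    """
    rng = _stable_stream(config.seed, "library")
    sites = find_protospacers(genome)
    if config.library_size > len(sites):
        raise ValueError(
            f"library_size={config.library_size} exceeds the "
            f"{len(sites)} available protospacers"
        )
    take = np.sort(rng.choice(len(sites), size=config.library_size, replace=False))
    lib = sites.iloc[take].reset_index(drop=True)
    # every perfect site of a sampled spacer is itself an enumerated site
    site_counts = sites["spacer"].value_counts()
    lib["n_perfect_sites"] = lib["spacer"].map(site_counts).astype(int)
    lib.insert(0, "guide_id", [f"sg{i:05d}" for i in range(len(lib))])
    lib["is_control"] = False
    lib = annotate_library(lib, genes, genome)
    lib["start"] = lib["start"].astype("Int64")
    control = lib.iloc[:1].copy()  # clone dtypes, then overwrite values
    control.loc[:, ["guide_id", "spacer", "is_control"]] = [
        "control", CONTROL_SPACER, True
    ]
    control.loc[:, "start"] = pd.NA
    control.loc[:, ["strand", "pam", "gene"]] = None
    control.loc[:, "targets_coding"] = pd.NA
    control.loc[:, "n_perfect_sites"] = 0
    return pd.concat([lib, control], ignore_index=True)


def _clean_column(values: pd.Series) -> list:
    """Nullable column -> list of python bools/str with None for missing."""
    return [None if pd.isna(v) else v for v in values]


def _silenced_genes(
    gene: str | None, genes_by_name: pd.DataFrame,
    tu_members: dict[str, list[str]], polar: bool,
) -> list[str]:
    """Target gene plus, under polar silencing, its downstream TU genes."""
    if gene is None:
        return []
    silenced = [gene]
    if polar:
        tu = genes_by_name.loc[gene, "tu_id"]
        if isinstance(tu, str):
            members = tu_members[tu]
            i = members.index(gene)
            silenced += members[i + 1 :]
    return silenced


def true_guide_fitness(
    library: pd.DataFrame,
    genes: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
) -> pd.Series:
    """Per-generation fitness effect w of every guide.

    ``w = efficiency * sum over silenced genes of strand-scaled cost``;
    silencing covers the target gene and, when polar, all downstream TU
    genes.  Template-strand targeting scales each gene's cost by
    ``template_effect_scale`` unless that gene is dosage-sensitive.
    Bad-seed guides additionally pay ``bad_seed_penalty``; intergenic
    clean guides have w = 0.  The control guide has w = 0 exactly.
    """
    rng = _stable_stream(config.seed, "fitness")
    lo, hi = config.repression_efficiency_range
    eff = rng.uniform(lo, hi, size=len(library))

    genes_by_name = genes.set_index("name")
    tu_members = {
        tu: grp.sort_values("tu_rank")["name"].tolist()
        for tu, grp in genes.dropna(subset=["tu_id"]).groupby("tu_id")
    }
    cost = truth.gene_cost
    sensitive = truth.genes["sensitive"]

    is_ctrl = library["is_control"].astype(bool).to_numpy()
    target = _clean_column(library["gene"])
    coding = _clean_column(library["targets_coding"])
    spacers = library["spacer"].tolist()

    w = np.zeros(len(library))
    for i in range(len(library)):
        if is_ctrl[i]:
            continue
        total = 0.0
        for g in _silenced_genes(target[i], genes_by_name, tu_members, config.polar):
            scale = 1.0
            if coding[i] is not None and not coding[i] and not bool(sensitive.get(g, False)):
                scale = config.template_effect_scale
            total += scale * cost.get(g, 0.0)
        wi = eff[i] * total
        if spacers[i][-5:] in BAD_SEEDS:
            wi += config.bad_seed_penalty
        w[i] = wi
    return pd.Series(w, index=library["guide_id"].to_numpy(), name="w")


def make_design(n_replicates: int, prefix: str = "") -> pd.DataFrame:
    """Paired before/after design table for ``n_replicates`` replicates."""
    rows = []
    for r in range(1, n_replicates + 1):
        rows.append({"sample_id": f"{prefix}before_{r}", "condition": "before",
                     "replicate": f"r{r}"})
        rows.append({"sample_id": f"{prefix}after_{r}", "condition": "after",
                     "replicate": f"r{r}"})
    return pd.DataFrame(rows)


def _initial_abundance(library: pd.DataFrame, config: SimulationConfig) -> pd.Series:
    rng = _stable_stream(config.seed, "abundance")
    a = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(library))
    return pd.Series(a, index=library["guide_id"].to_numpy(), name="abundance")


def _multinomial_expected(abund: np.ndarray, depth: int,
                          rng: np.random.Generator) -> np.ndarray:
    p = abund / abund.sum()
    return rng.multinomial(depth, p)


def _overdisperse(m: np.ndarray, dispersion: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson stage: mean m, variance m + dispersion * m^2."""
    if dispersion <= 0:
        return m.copy()
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * np.maximum(m, 1e-12))
    return rng.poisson(lam)


def _sample_counts(
    abundances: dict[str, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
    index: pd.Index,
) -> pd.DataFrame:
    cols = {}
    for sample, abund in abundances.items():
        m = _multinomial_expected(abund, config.depth, rng)
        cols[sample] = _overdisperse(m, config.dispersion, rng)
    return pd.DataFrame(cols, index=index)


def simulate_growth_screen(
    library: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired before/after counts of the growth (essentiality) screen.

    Before counts are drawn from the initial lognormal abundances; the
    after abundance of guide g is ``a_g * 2**(w_g * generations)``.
    Returns (counts, design).
    """
    if truth.guide_fitness is None or truth.abundance is None:
        raise ValueError("truth needs guide_fitness and abundance; "
                         "use simulate_screen_suite or fill them first")
    rng = _stable_stream(config.seed, "growth-counts")
    a0 = truth.abundance.to_numpy()
    w = truth.guide_fitness.to_numpy()
    a_after = a0 * np.exp2(w * config.generations)
    design = make_design(config.n_replicates)
    abundances = {}
    for r in range(1, config.n_replicates + 1):
        abundances[f"before_{r}"] = a0
        abundances[f"after_{r}"] = a_after
    idx = pd.Index(library["guide_id"].to_numpy(), name="guide_id")
    counts = _sample_counts(abundances, config, rng, idx)
    return counts[[s for s in design["sample_id"]]], design


def _survival(library: pd.DataFrame, genes: pd.DataFrame, truth: GroundTruth,
              config: SimulationConfig) -> pd.Series:
    """Per-guide survival probability under phage challenge.

    A guide protects its cell when it effectively silences (directly or
    through the polar effect) a host-factor gene — effective silencing
    requires coding-strand hybridization.
    """
    genes_by_name = genes.set_index("name")
    tu_members = {
        tu: grp.sort_values("tu_rank")["name"].tolist()
        for tu, grp in genes.dropna(subset=["tu_id"]).groupby("tu_id")
    }
    host = truth.label_set("host_factor")
    is_ctrl = library["is_control"].astype(bool).to_numpy()
    target = _clean_column(library["gene"])
    coding = _clean_column(library["targets_coding"])
    s = np.full(len(library), config.survival_floor)
    for i in range(len(library)):
        if is_ctrl[i] or not coding[i]:
            continue
        silenced = _silenced_genes(target[i], genes_by_name, tu_members, config.polar)
        if any(g in host for g in silenced):
            s[i] = config.protection_effect
    return pd.Series(s, index=library["guide_id"].to_numpy(), name="survival")


def simulate_phage_screen(
    library: pd.DataFrame,
    genes: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired counts of the phage lysis screen.

    The before sample is taken after ``phage_pre_generations`` of
    dCas9-induced growth; the after abundance multiplies it by the
    guide's survival probability (protection when a host factor is
    silenced, the survival floor otherwise).
    """
    if truth.guide_fitness is None or truth.abundance is None:
        raise ValueError("truth needs guide_fitness and abundance")
    rng = _stable_stream(config.seed, "phage-counts")
    a_pre = truth.abundance.to_numpy() * np.exp2(
        truth.guide_fitness.to_numpy() * config.phage_pre_generations
    )
    surv = _survival(library, genes, truth, config)
    truth.survival = surv
    a_after = a_pre * surv.to_numpy()
    design = make_design(config.n_replicates, prefix="phage_")
    abundances = {}
    for r in range(1, config.n_replicates + 1):
        abundances[f"phage_before_{r}"] = a_pre
        abundances[f"phage_after_{r}"] = a_after
    idx = pd.Index(library["guide_id"].to_numpy(), name="guide_id")
    counts = _sample_counts(abundances, config, rng, idx)
    return counts[[s for s in design["sample_id"]]], design


def simulate_transduction(
    library: pd.DataFrame,
    genes: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired counts of the cosmid transduction screen.

    The before sample is the initial (pre-induction) pool; the packaged
    output reflects growth over the full induction (``generations``),
    the lysed fraction (guides that protect from lysis package fewer
    cosmids) and a ``packaging_penalty`` when a capsid-competence gene
    is silenced.
    """
    if truth.guide_fitness is None or truth.abundance is None:
        raise ValueError("truth needs guide_fitness and abundance")
    rng = _stable_stream(config.seed, "transduction-counts")
    a0 = truth.abundance.to_numpy()
    w = truth.guide_fitness.to_numpy()
    surv = _survival(library, genes, truth, config).to_numpy()
    lysed = np.clip(1.0 - surv, 1e-6, 1.0)

    genes_by_name = genes.set_index("name")
    tu_members = {
        tu: grp.sort_values("tu_rank")["name"].tolist()
        for tu, grp in genes.dropna(subset=["tu_id"]).groupby("tu_id")
    }
    capsid = truth.label_set("capsid_gene")
    is_ctrl = library["is_control"].astype(bool).to_numpy()
    target = _clean_column(library["gene"])
    coding = _clean_column(library["targets_coding"])
    pack = np.ones(len(library))
    for i in range(len(library)):
        if is_ctrl[i] or not coding[i]:
            continue
        silenced = _silenced_genes(target[i], genes_by_name, tu_members, config.polar)
        if any(g in capsid for g in silenced):
            pack[i] = np.exp2(config.packaging_penalty)

    a_after = a0 * np.exp2(w * config.generations) * lysed * pack
    design = make_design(config.n_replicates, prefix="trans_")
    abundances = {}
    for r in range(1, config.n_replicates + 1):
        abundances[f"trans_before_{r}"] = a0
        abundances[f"trans_after_{r}"] = a_after
    idx = pd.Index(library["guide_id"].to_numpy(), name="guide_id")
    counts = _sample_counts(abundances, config, rng, idx)
    return counts[[s for s in design["sample_id"]]], design


def simulate_screen_suite(config: SimulationConfig) -> dict:
    """Run the full generator: genome, library, truth and all three screens.

    Returns a dict with keys ``genome, genes, tus, library, truth,
    growth (counts, design), phage (counts, design),
    transduction (counts, design)``.
    """
    genome, genes, tus, truth = simulate_genome(config)
    library = simulate_library(genome, genes, config)
    truth.guide_fitness = true_guide_fitness(library, genes, truth, config)
    truth.abundance = _initial_abundance(library, config)
    growth = simulate_growth_screen(library, truth, config)
    phage = simulate_phage_screen(library, genes, truth, config)
    trans = simulate_transduction(library, genes, truth, config)
    return {
        "genome": genome, "genes": genes, "tus": tus, "library": library,
        "truth": truth, "growth": growth, "phage": phage, "transduction": trans,
    }
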