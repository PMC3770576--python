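"""Synthetic genotype + phenotype generator with full ground truth.

Emulates the statistical structure a haplotype-network endophenotype scan
assumes: a few hundred haploid individuals collapsing onto a few dozen
haplotypes with skewed frequencies, a genealogy generated under the
infinite-sites model (each panel site mutates on at most one branch, so the
true network is a unique tree with single-SNP edges), covariate effects
(age, sex, APOE e4), one clade carrying a planted phenotype shift of
``delta`` phenotype standard deviations, Gaussian noise, optional
completely-at-random missingness, and optionally one homoplasy event (a
site reused on a second branch) that produces exactly one ambiguity loop in
the estimated network.

Everything needed for recovery testing is recorded in :class:`SimTruth`:
the genealogy and its edge-to-site map, the planted branch and its member
individuals, the true regression coefficients, and the noiseless phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    Haplotype,
    VariantDef,
    write_genotype_table,
    write_site_map,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_haplotypes",
    "sample_individuals",
    "simulate_subjects",
    "simulate_dataset",
    "write_fixture",
    "find_planted_contrast",
]

# Region-class composition of the 138-site genotyping panel.
_REGION_COUNTS_138 = {
    "noncoding": 21,
    "protein": 91,
    "rRNA": 4,
    "tRNA": 11,
    "termination": 1,
}
_RCRS_LENGTH = 16569
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the scale of the motivating cohort scaled to desk
    size: a few hundred individuals, the 138-site mtDNA panel, skewed
    haplotype frequencies, ages ~75 +- 7 years, ~55% male, ~50% APOE e4
    carriers, and a CN/MCI/AD mix.
    """

    n_individuals: int = 500
    n_sites: int = 138
    n_haplotypes: int = 40
    skew: float = 1.0  # power-law exponent for haplotype frequencies
    clade_target_size: int = 30  # planted branch: closest subtree tally
    delta: float = 0.0  # clade effect in phenotype-SD units
    beta_age: float = 0.05
    beta_sex: float = 0.5
    beta_apoe: float = -0.5
    intercept: float = 0.0
    sigma: float = 1.0  # phenotype noise SD
    missing_rate: float = 0.0  # phenotype MCAR rate
    genotype_missing_rate: float = 0.0  # genotype MCAR rate
    n_homoplasy: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate <= 1 and 0 <= self.genotype_missing_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_sites < self.n_haplotypes - 1 + self.n_homoplasy:
            raise ValueError(
                "n_sites must cover one distinct site per genealogy edge "
                "(infinite-sites regime) plus homoplasy reuse"
            )
        if self.n_individuals < self.n_haplotypes:
            raise ValueError("need at least one individual per haplotype")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    parent: dict[int, int] = field(default_factory=dict)  # child node -> parent
    edge_site: dict[int, int] = field(default_factory=dict)  # child node -> site
    homoplasy_edges: list[int] = field(default_factory=list)  # children of reused-site edges
    vectors: np.ndarray | None = None  # H x L allele vectors
    assignments: dict[str, int] = field(default_factory=dict)  # individual -> node
    planted_child: int | None = None
    clade_nodes: frozenset[int] = frozenset()
    clade_ids: frozenset[str] = frozenset()
    coefficients: dict[str, float] = field(default_factory=dict)
    noiseless: dict[str, float] = field(default_factory=dict)

    def subtree(self, child: int) -> frozenset[int]:
        """Nodes at or below ``child`` in the genealogy."""
        children: dict[int, list[int]] = {}
        for c, p in self.parent.items():
            children.setdefault(p, []).append(c)
        out, stack = set(), [child]
        while stack:
            n = stack.pop()
            out.add(n)
            stack.extend(children.get(n, []))
        return frozenset(out)


# ---------------------------------------------------------------------------
# genealogy and haplotypes
# ---------------------------------------------------------------------------

def _make_variants(config: SimConfig, rng: np.random.Generator) -> list[VariantDef]:
    positions = np.sort(
        rng.choice(np.arange(1, _RCRS_LENGTH + 1), size=config.n_sites, replace=False)
    )
    if config.n_sites == 138:
        # the published composition sums to 128; the remainder is padded
        # with protein-coding sites (the dominant class)
        classes = [c for c, k in _REGION_COUNTS_138.items() for _ in range(k)]
        classes += ["protein"] * (138 - len(classes))
        classes = list(rng.permutation(classes))
    else:
        names = list(_REGION_COUNTS_138)
        probs = np.array(list(_REGION_COUNTS_138.values()), float)
        classes = list(rng.choice(names, size=config.n_sites, p=probs / probs.sum()))
    variants = []
    for i, pos in enumerate(positions):
        ref, alt = rng.choice(4, size=2, replace=False)
        variants.append(
            VariantDef(
                site_index=i,
                rcrs_position=int(pos),
                ref_allele=str(_BASES[ref]),
                alt_allele=str(_BASES[alt]),
                region_class=str(classes[i]),
            )
        )
    return variants


def simulate_haplotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, SimTruth]:
    """Grow a random genealogy and derive haplotype allele vectors.

    The tree grows by sequential uniform attachment over ``n_haplotypes``
    nodes; every edge carries one distinct site (infinite sites), so a
    node's vector is the XOR of the mutations on its root path.  With
    ``n_homoplasy`` > 0, a site is reused on an additional branch separated
    from its first use by exactly one edge, which shows up in the estimated
    network as one ambiguity loop per event.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    H, L = config.n_haplotypes, config.n_sites
    truth = SimTruth()
    site_pool = list(rng.permutation(L))
    for child in range(1, H):
        truth.parent[child] = int(rng.integers(0, child))
        truth.edge_site[child] = int(site_pool.pop())

    if config.n_homoplasy:
        _plant_homoplasy(config, truth, rng)

    vectors = np.zeros((H, L), dtype=np.int8)
    for node in range(1, H):
        vec = vectors[truth.parent[node]].copy()
        site = truth.edge_site[node]
        vec[site] ^= 1
        vectors[node] = vec
    if len({tuple(v) for v in vectors}) != H:
        raise RuntimeError("duplicate haplotype vectors; homoplasy placement failed")
    truth.vectors = vectors
    return vectors, truth


def _plant_homoplasy(config: SimConfig, truth: SimTruth, rng: np.random.Generator) -> None:
    """Reuse the site of a grandparent edge on a descendant edge.

    For a chain h -> g -> p -> v the site of edge (h,g) replaces the site of
    edge (p,v); h and v then differ at a single site, creating an equally
    parsimonious alternative connection (one loop) in the network.
    """
    candidates = []
    for v in range(1, config.n_haplotypes):
        p = truth.parent.get(v)
        g = truth.parent.get(p) if p else None
        if p and g is not None and g in truth.parent:
            candidates.append(v)
    if len(candidates) < config.n_homoplasy:
        raise ValueError(
            "genealogy too shallow to place the requested homoplasy events; "
            "increase n_haplotypes or reseed"
        )
    order = list(rng.permutation(candidates))
    used: set[int] = set()
    planted = 0
    for v in order:
        if planted >= config.n_homoplasy:
            break
        p = truth.parent[v]
        g = truth.parent[p]
        if {v, p, g} & used:
            continue
        truth.edge_site[v] = truth.edge_site[g]
        truth.homoplasy_edges.append(v)
        used |= {v, p, g, truth.parent[g]}
        planted += 1
    if planted < config.n_homoplasy:
        raise ValueError("could not place disjoint homoplasy events; reseed")


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------

def sample_individuals(
    vectors: np.ndarray,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    variants: Sequence[VariantDef] | None = None,
) -> GenotypeMatrix:
    """Draw individuals onto haplotypes with power-law-skewed weights.

    Every haplotype receives at least one individual, so collapsing the
    matrix inverts the assignment exactly (when genotype missingness is
    zero).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    H = vectors.shape[0]
    if variants is None:
        variants = _make_variants(config, rng)
    ranks = rng.permutation(H)
    w = (1.0 + ranks).astype(float) ** (-config.skew)
    w /= w.sum()
    counts = np.ones(H, dtype=int)
    extra = config.n_individuals - H
    if extra > 0:
        counts += rng.multinomial(extra, w)
    ids, rows = [], []
    k = 0
    for node in range(H):
        for _ in range(counts[node]):
            k += 1
            ind = f"S{k:04d}"
            ids.append(ind)
            rows.append(vectors[node])
            truth.assignments[ind] = node
    calls = np.array(rows, dtype=np.int8)
    if config.genotype_missing_rate > 0:
        mask = rng.random(calls.shape) < config.genotype_missing_rate
        calls = calls.copy()
        calls[mask] = MISSING
    return GenotypeMatrix(individual_ids=ids, variants=list(variants), calls=calls)


def _choose_planted_branch(truth: SimTruth, config: SimConfig) -> None:
    """Pick the genealogy edge whose subtree tally is closest to target."""
    tallies: dict[int, int] = {}
    node_counts: dict[int, int] = {}
    for node in truth.assignments.values():
        node_counts[node] = node_counts.get(node, 0) + 1
    best = None
    for child in truth.parent:
        size = sum(node_counts.get(n, 0) for n in truth.subtree(child))
        score = (abs(size - config.clade_target_size), child)
        if best is None or score < best[0]:
            best = (score, child, size)
    assert best is not None
    truth.planted_child = best[1]
    truth.clade_nodes = truth.subtree(best[1])
    truth.clade_ids = frozenset(
        ind for ind, node in truth.assignments.items() if node in truth.clade_nodes
    )


def simulate_subjects(
    matrix: GenotypeMatrix,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate covariates and the phenotype with the planted clade shift.

    y = b0 + b_age*age + b_sex*male + b_apoe*apoe4 + delta*sigma*1[clade] + e,
    e ~ N(0, sigma^2).  Phenotype missingness is completely at random.
    The noiseless values are stored in ``truth.noiseless``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    if truth.planted_child is None:
        _choose_planted_branch(truth, config)
    ids = matrix.individual_ids
    missing_truth = [i for i in ids if i not in truth.assignments]
    if missing_truth:
        raise ValueError(f"truth does not cover individuals {missing_truth[:5]}")
    n = len(ids)
    age = rng.normal(75.0, 7.0, size=n).clip(40.0, 100.0)
    male = rng.random(n) < 0.55
    apoe_count = rng.choice([0, 1, 2], size=n, p=[0.5, 0.4, 0.1])
    diagnosis = rng.choice(["CN", "MCI", "AD"], size=n, p=[0.27, 0.49, 0.24])
    clade = np.array([i in truth.clade_ids for i in ids])
    noiseless = (
        config.intercept
        + config.beta_age * age
        + config.beta_sex * male
        + config.beta_apoe * (apoe_count > 0)
        + config.delta * config.sigma * clade
    )
    y = noiseless + rng.normal(0.0, config.sigma, size=n)
    if config.missing_rate > 0:
        y = np.where(rng.random(n) < config.missing_rate, np.nan, y)
    truth.coefficients = {
        "intercept": config.intercept,
        "beta_age": config.beta_age,
        "beta_sex": config.beta_sex,
        "beta_apoe": config.beta_apoe,
        "clade_effect": config.delta * config.sigma,
    }
    truth.noiseless = dict(zip(ids, noiseless))
    df = pd.DataFrame(
        {
            "individual_id": ids,
            "age": age,
            "sex": np.where(male, "male", "female"),
            "apoe4": (apoe_count > 0).astype(int),
            "apoe4_count": apoe_count,
            "diagnosis": diagnosis,
            "y": y,
        }
    )
    return df.set_index("individual_id", drop=False)


@dataclass
class SimData:
    config: SimConfig
    truth: SimTruth
    matrix: GenotypeMatrix
    subjects: pd.DataFrame
    haplotypes: list[Haplotype]


def simulate_dataset(config: SimConfig) -> SimData:
    """Full generation chain with a single seeded stream."""
    from .genotype_io import collapse_haplotypes, handle_missing

    rng = np.random.default_rng(config.seed)
    vectors, truth = simulate_haplotypes(config, rng)
    matrix = sample_individuals(vectors, truth, config, rng)
    subjects = simulate_subjects(matrix, truth, config, rng)
    complete = matrix
    if config.genotype_missing_rate > 0:
        complete, _ = handle_missing(matrix, max_missing_rate=1.0)
    haplotypes = collapse_haplotypes(complete)
    return SimData(config, truth, matrix, subjects, haplotypes)


def find_planted_contrast(contrasts, truth: SimTruth):
    """The enumerated contrast matching the planted clade, if any."""
    for c in contrasts:
        if c.individuals_a == truth.clade_ids or c.individuals_b == truth.clade_ids:
            return c
    return None


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(
    matrix: GenotypeMatrix,
    subjects: pd.DataFrame,
    truth: SimTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write genotype TSV + VCF + site map + subject TSV + truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes_tsv": out / "genotypes.tsv",
        "genotypes_vcf": out / "genotypes.vcf",
        "site_map": out / "site_map.tsv",
        "subjects": out / "subjects.tsv",
        "truth": out / "truth.yaml",
    }
    write_genotype_table(matrix, paths["genotypes_tsv"])
    write_vcf(matrix, paths["genotypes_vcf"])
    write_site_map(matrix.variants, paths["site_map"])
    subjects.to_csv(paths["subjects"], sep="\t", index=False)
    manifest = {
        "planted_child": truth.planted_child,
        "clade_ids": sorted(truth.clade_ids),
        "coefficients": truth.coefficients,
        "parent": {int(k): int(v) for k, v in truth.parent.items()},
        "edge_site": {int(k): int(v) for k, v in truth.edge_site.items()},
        "homoplasy_edges": [int(x) for x in truth.homoplasy_edges],
        "assignments": {k: int(v) for k, v in truth.assignments.items()},
    }
    paths["truth"].write_text(yaml.safe_dump(manifest, sort_keys=True))
    return paths
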