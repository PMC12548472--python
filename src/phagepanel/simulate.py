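"""Synthetic phage-panel datasets with planted receptor types.

The generator emulates the data structure the pipeline consumes: phages are
assigned round-robin to planted receptor types, each type carries a
distinct host-gene requirement vector, knockout strains (single- and
double-gene) probe those requirements through spot-test titers (with ND
events and log-scale measurement noise), and a mixed phenotype table
(binary host-range bits plus quantitative physiology features) mirrors the
planted partition with tunable noise. At zero noise the full pipeline —
EoP calls, profile derivation, typing, Gower clustering, silhouette
k-selection — recovers the planted structure exactly; that exactness is
engineered by truncating permissive log-EoP draws above the -1 reduction
threshold and is the generator's core testable contract.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .eop import ReceptorProfile, _type_letters
from .io import (
    FeatureSpec,
    InfectionMatrix,
    MutantGeneMap,
    Partition,
    PhenotypeTable,
    TiterObservation,
    write_infection_matrix,
    write_mutant_genes,
    write_phenotype_table,
    write_titers,
    write_partition,
)

__all__ = ["SyntheticConfig", "SyntheticBundle", "simulate_dataset"]

#: id of the wild-type reference strain included in every titer set
REFERENCE_STRAIN = "WT"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped generator settings.

    Defaults mirror the reference screen: 13 phages in 6 receptor types,
    a 1e7 PFU-equivalent reference titer, 3 spot-test replicates, about
    half of blocked spots reading ND, a 16-strain binary host-range panel
    and 4 quantitative physiology features.
    """

    n_phages: int = 13
    n_types: int = 6
    genes_per_type: int = 2
    n_single_mutant_strains: int | None = None  # None -> one knockout per gene
    n_double_mutant_strains: int = 2
    reference_titer: float = 1e7
    n_replicates: int = 3
    noise_sd: float = 0.3  # sd of permissive log10-EoP measurement noise
    p_spurious_drop: float = 0.02
    p_nd_given_blocked: float = 0.5
    n_binary_hosts: int = 16
    n_quant_features: int = 4
    delta: float = 2.0  # between-type separation of quantitative features
    sigma: float = 0.5  # within-type sd of quantitative features
    epsilon: float = 0.05  # host-range bit-flip rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types > self.n_phages:
            raise ValueError("n_types cannot exceed n_phages")
        if self.n_types < 1 or self.n_phages < 1:
            raise ValueError("need at least one phage and one type")
        if not 1 <= self.genes_per_type <= 3:
            raise ValueError("genes_per_type must be in 1..3")
        for name in ("p_spurious_drop", "p_nd_given_blocked", "epsilon"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.delta < 0 or self.sigma < 0 or self.noise_sd < 0:
            raise ValueError("delta, sigma and noise_sd must be >= 0")
        if self.reference_titer <= 0:
            raise ValueError("reference_titer must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SyntheticBundle:
    """Everything one simulated screen produces, plus its ground truth."""

    config: SyntheticConfig
    truth: Partition  # planted type letters per phage
    profile: ReceptorProfile  # planted gene-requirement matrix
    titers: list[TiterObservation]
    genes: MutantGeneMap
    phenotypes: PhenotypeTable
    infections: InfectionMatrix

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_titers(self.titers, out / "titers.tsv")
        write_mutant_genes(self.genes, out / "mutants.tsv")
        write_phenotype_table(self.phenotypes, out / "phenotypes.tsv")
        write_infection_matrix(self.infections, out / "infections.tsv")
        write_partition(self.truth, out / "truth.json")
        self.profile.to_frame().to_csv(out / "profile.tsv", sep="\t",
                                       index_label="phage")
        with open(out / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2)
            fh.write("\n")


def _planted_gene_sets(cfg: SyntheticConfig) -> list[frozenset[str]]:
    """One distinct requirement set per type: a unit gene each, padded with
    private genes to ``genes_per_type``; type 2 is type 1's set plus its own
    unit gene, reproducing the near-identical one-bit type pair seen in real
    requirement tables."""
    def gname(i: int) -> str:
        return f"g{i + 1:02d}"

    sets: list[frozenset[str]] = []
    counter = cfg.n_types  # private-gene name counter, after unit genes
    for t in range(cfg.n_types):
        genes = {gname(t)}
        if t == 1 and cfg.n_types >= 2:
            genes = set(sets[0]) | {gname(1)}  # superset of type 1: one-bit pair
        else:
            while len(genes) < cfg.genes_per_type:
                genes.add(gname(counter))
                counter += 1
        sets.append(frozenset(genes))
    return sets


def _distinct_type_patterns(rng: np.random.Generator, n_types: int,
                            n_hosts: int) -> np.ndarray:
    """Per-type binary host-range patterns, redrawn until pairwise distinct."""
    while True:
        pats = rng.integers(0, 2, size=(n_types, n_hosts))
        if len({tuple(r) for r in pats}) == n_types:
            return pats


def simulate_dataset(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a fully reproducible synthetic screen from ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    phages = [f"phage{i + 1:02d}" for i in range(cfg.n_phages)]
    types = [i % cfg.n_types for i in range(cfg.n_phages)]  # round-robin
    letters = list(itertools.islice(_type_letters(), cfg.n_types))
    truth = Partition(phages, [letters[t] for t in types])

    gene_sets = _planted_gene_sets(cfg)
    gene_pool = sorted({g for s in gene_sets for g in s})
    profile_values = np.array(
        [[1 if g in gene_sets[t] else 0 for g in gene_pool] for t in types],
        dtype=np.int8,
    )
    profile = ReceptorProfile(phages, gene_pool, profile_values)

    # knockout strains: singles (one per gene by default) + random doubles
    single_genes = gene_pool if cfg.n_single_mutant_strains is None else \
        gene_pool[: cfg.n_single_mutant_strains]
    strain_map: dict[str, list[str]] = {f"KO-{g}": [g] for g in single_genes}
    if cfg.n_double_mutant_strains > 0 and len(gene_pool) >= 2:
        pairs = [(a, b) for i, a in enumerate(gene_pool) for b in gene_pool[i + 1:]]
        picks = rng.choice(len(pairs),
                           size=min(cfg.n_double_mutant_strains, len(pairs)),
                           replace=False)
        for idx in sorted(picks):
            a, b = pairs[idx]
            strain_map[f"KO-{a}-{b}"] = [a, b]
    genes = MutantGeneMap(strain_map)

    # spot-test titers: blocked pairs drop hard (or read ND); permissive
    # pairs stay above the -1 reduction threshold unless a spurious drop fires
    titers: list[TiterObservation] = []
    required = {p: gene_sets[t] for p, t in zip(phages, types)}
    for p in phages:
        for rep in range(1, cfg.n_replicates + 1):
            titers.append(TiterObservation(p, REFERENCE_STRAIN,
                                           cfg.reference_titer, rep))
        for s in genes.strain_ids:
            blocked = bool(required[p] & genes[s])
            for rep in range(1, cfg.n_replicates + 1):
                if blocked:
                    if rng.random() < cfg.p_nd_given_blocked:
                        titers.append(TiterObservation(p, s, None, rep))
                        continue
                    log_eop = rng.uniform(-5.0, -2.0)
                elif rng.random() < cfg.p_spurious_drop:
                    log_eop = rng.uniform(-4.0, -1.5)
                elif cfg.noise_sd == 0:
                    log_eop = 0.0
                else:
                    a = (-1.0 - 0.0) / cfg.noise_sd  # truncate above -1
                    log_eop = float(stats.truncnorm.rvs(
                        a, np.inf, loc=0.0, scale=cfg.noise_sd, random_state=rng))
                titers.append(
                    TiterObservation(p, s, cfg.reference_titer * 10.0 ** log_eop, rep)
                )

    # phenotypes: type-specific host-range bits (flipped at rate epsilon)
    # plus Gaussian quantitative features with type means separated by delta
    host_pats = _distinct_type_patterns(rng, cfg.n_types, cfg.n_binary_hosts)
    bits = host_pats[types]
    if cfg.epsilon > 0:
        flips = rng.random(bits.shape) < cfg.epsilon
        bits = np.where(flips, 1 - bits, bits)
    host_cols = [f"host{j + 1:02d}" for j in range(cfg.n_binary_hosts)]

    mu = cfg.delta * rng.standard_normal((cfg.n_types, cfg.n_quant_features))
    quant = mu[types] + cfg.sigma * rng.standard_normal(
        (cfg.n_phages, cfg.n_quant_features))
    quant_cols = [f"quant{j + 1:02d}" for j in range(cfg.n_quant_features)]

    frame = pd.DataFrame(
        np.hstack([bits.astype(float), quant]),
        index=phages, columns=host_cols + quant_cols,
    )
    feats = [FeatureSpec(c, "binary") for c in host_cols] + \
            [FeatureSpec(c, "quantitative") for c in quant_cols]
    phenotypes = PhenotypeTable(phages, feats, frame)

    infections = InfectionMatrix(phages, host_cols, bits.astype(np.int8))

    return SyntheticBundle(cfg, truth, profile, titers, genes, phenotypes, infections)
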