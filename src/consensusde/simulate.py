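"""Synthetic count data with the study's nested pooled-replicate structure.

The generator emulates a design of two invasion categories (ancient /
recent) × four sites per category × two pooled-RNA replicate libraries per
site, i.e. 16 libraries per species, each library pooling 6-10 individuals
with a balanced sex ratio. Counts are negative binomial:

    c_gj ~ NB(mean = s_j * q_g * 2**(x_j * beta_g + u_{g, site(j)}),
              dispersion = phi_g)

with x_j = 1 for recent sites, log-normal library factors s_j and baseline
means q_g, gene-wise log-normal dispersions phi_g, Gaussian per-gene
per-site log2-scale random effects u, and planted signed log2 fold changes
beta_g for a DE fraction of genes; DE genes from a labeled "immune" subset
receive an additional additive LFC shift. All randomness flows from one
seed through counter-based (Philox) streams split per stage, so every
intermediate is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import CountMatrix, GeneSetCollection, StudyDesign, DESIGN_COLUMNS

_STAGES = ("libsize", "baseline", "dispersion", "effects", "sites", "counts",
           "pools")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset; defaults mirror the study design."""

    n_genes: int = 5000
    n_sites_per_category: int = 4
    n_pools_per_site: int = 2
    frac_de: float = 0.05
    lfc_magnitude: float = 2.0
    site_sd: float = 0.5
    dispersion_location: float = float(np.log(0.1))
    dispersion_sd: float = 0.5
    libsize_location: float = 0.0
    libsize_sd: float = 0.2
    baseline_location: float = float(np.log(50.0))
    baseline_sd: float = 1.5
    frac_immune: float = 0.1
    immune_lfc_shift: float = 1.0
    seed: int = 0
    species: str = "mus"
    shared_site_effects: bool = False  # one site effect shared by all genes

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        for name in ("frac_de", "frac_immune"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        for name in ("site_sd", "dispersion_sd", "libsize_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.lfc_magnitude <= 0:
            raise ParameterError("lfc_magnitude must be positive")
        if self.n_sites_per_category < 1 or self.n_pools_per_site < 1:
            raise ParameterError("need >= 1 site per category and pool per site")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset (per gene, per site, per term)."""

    genes: pd.DataFrame          # gene_id, true_lfc, is_de, is_immune, true_dispersion
    site_effects: pd.DataFrame   # genes x sites, log2-scale random effects
    terms: Optional[pd.DataFrame] = None  # term_id, is_enriched

    def __post_init__(self) -> None:
        g = self.genes
        if (g.loc[~g["is_de"], "true_lfc"] != 0).any():
            raise ParameterError("non-DE genes must have true_lfc = 0")
        if (g["true_dispersion"] <= 0).any():
            raise ParameterError("true dispersions must be positive")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STAGES))
    return {name: np.random.Generator(np.random.Philox(child))
            for name, child in zip(_STAGES, children)}


def simulate_dataset(config: SimulationConfig,
                     ) -> tuple[CountMatrix, StudyDesign, SimulationTruth]:
    """Draw one synthetic dataset; identical config => bit-identical output."""
    cfg = config
    rng = _streams(cfg.seed)
    G = cfg.n_genes
    S = cfg.n_sites_per_category
    P = cfg.n_pools_per_site

    sites = ([f"{cfg.species}_anc{i + 1}" for i in range(S)]
             + [f"{cfg.species}_rec{i + 1}" for i in range(S)])
    site_cat = {s: ("ancient" if s.split("_")[-1].startswith("anc") else "recent")
                for s in sites}
    lib_site = [s for s in sites for _ in range(P)]
    lib_pool = [p + 1 for _ in sites for p in range(P)]
    library_ids = [f"{s}_p{p}" for s, p in zip(lib_site, lib_pool)]
    J = len(library_ids)
    x = np.array([1.0 if site_cat[s] == "recent" else 0.0 for s in lib_site])

    gene_ids = [f"g{i + 1:05d}" for i in range(G)]
    s_j = rng["libsize"].lognormal(cfg.libsize_location, cfg.libsize_sd, size=J)
    q_g = rng["baseline"].lognormal(cfg.baseline_location, cfg.baseline_sd, size=G)
    phi_g = rng["dispersion"].lognormal(cfg.dispersion_location,
                                        cfg.dispersion_sd, size=G)

    eff = rng["effects"]
    n_de = int(round(cfg.frac_de * G))
    de_idx = eff.choice(G, size=n_de, replace=False)
    is_de = np.zeros(G, dtype=bool)
    is_de[de_idx] = True
    n_imm = int(round(cfg.frac_immune * G))
    imm_idx = eff.choice(G, size=n_imm, replace=False)
    is_immune = np.zeros(G, dtype=bool)
    is_immune[imm_idx] = True
    magnitude = np.abs(eff.normal(cfg.lfc_magnitude, cfg.lfc_magnitude / 4.0,
                                  size=G))
    sign = eff.choice([-1.0, 1.0], size=G)
    beta = np.where(is_de, sign * magnitude, 0.0)
    beta = np.where(is_de & is_immune, beta + cfg.immune_lfc_shift, beta)

    if cfg.shared_site_effects:
        u_site = rng["sites"].normal(0.0, cfg.site_sd, size=len(sites))
        u = np.tile(u_site, (G, 1))
    else:
        u = rng["sites"].normal(0.0, cfg.site_sd, size=(G, len(sites)))
    site_index = np.array([sites.index(s) for s in lib_site])

    log2_mean = x[None, :] * beta[:, None] + u[:, site_index]
    mean = s_j[None, :] * q_g[:, None] * np.exp2(log2_mean)
    r = 1.0 / phi_g
    p_nb = r[:, None] / (r[:, None] + mean)
    counts = rng["counts"].negative_binomial(r[:, None], p_nb)

    pool_rng = rng["pools"]
    pool_sizes = pool_rng.integers(6, 11, size=J)
    n_males = np.where(np.arange(J) % 2 == 0,
                       np.floor(pool_sizes / 2), np.ceil(pool_sizes / 2)
                       ).astype(int)
    design = StudyDesign(pd.DataFrame({
        "library_id": library_ids,
        "species": cfg.species,
        "site": lib_site,
        "invasion_category": [site_cat[s] for s in lib_site],
        "pool_index": lib_pool,
        "pool_size": pool_sizes,
        "n_males": n_males,
        "n_females": pool_sizes - n_males,
    }, columns=DESIGN_COLUMNS))

    truth = SimulationTruth(
        genes=pd.DataFrame({
            "gene_id": gene_ids,
            "true_lfc": beta,
            "is_de": is_de,
            "is_immune": is_immune,
            "true_dispersion": phi_g,
        }),
        site_effects=pd.DataFrame(u, index=gene_ids, columns=sites),
    )
    matrix = CountMatrix(gene_ids, library_ids, counts.astype(np.int64))
    return matrix, design, truth


def simulate_annotation(truth: SimulationTruth, n_terms: int,
                        term_size_range: tuple[int, int],
                        n_enriched_terms: int, enrichment_odds: float,
                        seed: int) -> tuple[GeneSetCollection, SimulationTruth]:
    """Random gene sets; enriched terms oversample DE genes by ``enrichment_odds``."""
    if n_enriched_terms > n_terms:
        raise ParameterError("n_enriched_terms must not exceed n_terms")
    if enrichment_odds <= 0:
        raise ParameterError("enrichment_odds must be positive")
    genes = truth.genes["gene_id"].to_numpy()
    is_de = truth.genes["is_de"].to_numpy()
    lo, hi = term_size_range
    if not 1 <= lo <= hi or hi > len(genes):
        raise ParameterError("term_size_range must satisfy 1 <= lo <= hi <= n_genes")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    weights_enriched = np.where(is_de, float(enrichment_odds), 1.0)
    weights_enriched = weights_enriched / weights_enriched.sum()
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    enriched_flags = []
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        enriched = i < n_enriched_terms
        probs = weights_enriched if enriched else None
        members = rng.choice(genes, size=size, replace=False, p=probs)
        terms[f"T{i + 1:04d}"] = ("simulated gene set", frozenset(members))
        enriched_flags.append(enriched)
    collection = GeneSetCollection(terms)
    term_table = pd.DataFrame({"term_id": list(terms), "is_enriched": enriched_flags})
    updated = replace(truth, terms=term_table)
    return collection, updated
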