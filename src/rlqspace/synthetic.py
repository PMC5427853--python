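"""Synthetic forest-plot generator.

Produces coupled stem-map / trait / phylogeny / environment datasets with a
known assembly rule, emulating a 20-ha tropical forest dynamics plot: a
rectangular stem map of tagged individuals, spatially autocorrelated
environmental surfaces on the finest (10 m) quadrat grid, an ultrametric
pure-birth phylogeny, Brownian traits with tunable phylogenetic signal
(Pagel's lambda), and abundance assembly in which one designated trait is
matched against one environmental surface with tunable filtering strength.
The known niche optima and filtering strength are carried along as a truth
record so downstream statistics can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .errors import InvalidArgumentError
from .io import StemMap, write_stem_map, write_newick
from .ordination import patristic_distance
from .spatial import QuadratGrid

#: side of the finest quadrat grid on which environment is generated (m)
BASE_QUADRAT = 10.0
#: Fisher's alpha of the regional log-series abundance curve; calibrated so
#: roughly 1% of species hold about half of the stems (tropical-plot-like
#: dominance) at the default 400 species / 50k stems
FISHER_ALPHA = 10.0


@dataclass
class SimConfig:
    """Generation parameters; the defaults emulate the study system
    (20-ha plot, ~400 taxa, 10 environmental variables, 11 traits)."""

    plot_width: float = 500.0
    plot_height: float = 400.0
    n_species: int = 400
    n_individuals: int = 50_000
    env_range_param: float = 50.0
    n_env_vars: int = 10
    n_traits: int = 11
    signal_lambda: float = 0.5
    filtering_strength: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.plot_width <= 0 or self.plot_height <= 0:
            raise InvalidArgumentError("plot dimensions must be positive")
        if self.n_species < 2:
            raise InvalidArgumentError("need at least 2 species")
        if not 0.0 <= self.signal_lambda <= 1.0:
            raise InvalidArgumentError("signal_lambda must lie in [0, 1]")
        if self.filtering_strength < 0:
            raise InvalidArgumentError("filtering_strength must be >= 0")
        if self.env_range_param <= 0:
            raise InvalidArgumentError("env_range_param must be positive")


@dataclass
class EnvironmentFields:
    """Standardized environmental surfaces on the finest quadrat grid."""

    values: pd.DataFrame  # quadrats x variables
    grid: QuadratGrid


@dataclass
class SyntheticDataset:
    stem_map: StemMap
    phylogeny: dendropy.Tree
    traits: pd.DataFrame
    env: EnvironmentFields
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def _species_labels(n: int) -> list[str]:
    return [f"sp{i + 1:04d}" for i in range(n)]


def simulate_phylogeny(n_species: int, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with root-to-tip depth scaled to 1 and tips
    relabelled sp0001..spN in a deterministic traversal order.

    The process starts at the root split with 2 lineages, waits
    Exp(k)-distributed times between successive splits of a uniformly
    chosen lineage, and extends terminal branches by a final Exp(n) hold
    so tips have positive length; the tree is then rescaled so every
    root-to-tip path equals 1 (max patristic distance 2).
    """
    if n_species < 2:
        raise InvalidArgumentError("need at least 2 species for a phylogeny")
    rng = np.random.default_rng(int(seed))
    root = dendropy.Node()
    birth_time = {id(root): 0.0}
    # root splits at time 0 into two lineages
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        birth_time[id(child)] = 0.0
        root.add_child(child)
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        parent = active.pop(int(rng.integers(k)))
        parent.edge.length = t - birth_time[id(parent)]
        for _ in range(2):
            child = dendropy.Node()
            birth_time[id(child)] = t
            parent.add_child(child)
            active.append(child)
    t += rng.exponential(1.0 / n_species)  # tail so tips have length
    for leaf in active:
        leaf.edge.length = t - birth_time[id(leaf)]
    tree = dendropy.Tree(seed_node=root)
    # scale depth to 1
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t
    labels = _species_labels(n_species)
    tree.taxon_namespace = dendropy.TaxonNamespace()
    for k, leaf in enumerate(tree.leaf_node_iter()):
        taxon = dendropy.Taxon(label=labels[k])
        tree.taxon_namespace.add_taxon(taxon)
        leaf.taxon = taxon
    return tree


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_traits(
    tree: dendropy.Tree,
    n_traits: int = 11,
    signal_lambda: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Brownian-motion traits on a Pagel-lambda-transformed tree.

    lambda = 1 keeps the full phylogenetic covariance (shared root-to-MRCA
    path lengths); lambda = 0 gives independent draws.  Each trait column
    is standardized to zero mean and unit variance across species.
    """
    if not 0.0 <= signal_lambda <= 1.0:
        raise InvalidArgumentError("signal_lambda must lie in [0, 1]")
    D = patristic_distance(tree)
    labels = list(D.ids)
    depth_by_tip = {
        leaf.taxon.label: leaf.distance_from_root()
        for leaf in tree.leaf_node_iter()
    }
    depths = np.array([depth_by_tip[l] for l in labels])
    if np.ptp(depths) > 1e-6 * depths.max():
        raise InvalidArgumentError("tree must be ultrametric")
    T = depths.mean()
    C = T - D.data / 2.0  # shared path length from root
    np.fill_diagonal(C, T)
    C = signal_lambda * C
    np.fill_diagonal(C, T)
    n = len(labels)
    rng = np.random.default_rng(seed)
    Lc = np.linalg.cholesky(C + 1e-12 * T * np.eye(n))
    X = Lc @ rng.standard_normal((n, n_traits))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    cols = [f"trait_{k + 1:02d}" for k in range(n_traits)]
    return pd.DataFrame(X, index=labels, columns=cols)


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def simulate_environment(config: SimConfig) -> EnvironmentFields:
    """Gaussian random fields with exponential covariance
    exp(-d / env_range_param) on the finest quadrat grid, each field
    standardized to zero mean, unit variance."""
    grid = QuadratGrid(config.plot_width, config.plot_height, BASE_QUADRAT)
    cent = grid.centroids
    d = np.sqrt(
        (cent[:, None, 0] - cent[None, :, 0]) ** 2
        + (cent[:, None, 1] - cent[None, :, 1]) ** 2
    )
    C = np.exp(-d / config.env_range_param)
    Lc = np.linalg.cholesky(C + 1e-10 * np.eye(len(cent)))
    rng = np.random.default_rng(config.seed + 1)
    Z = Lc @ rng.standard_normal((len(cent), config.n_env_vars))
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
    cols = [f"env_{k + 1:02d}" for k in range(config.n_env_vars)]
    values = pd.DataFrame(Z, index=grid.quadrat_ids, columns=cols)
    return EnvironmentFields(values=values, grid=grid)


# ---------------------------------------------------------------------------
# regional abundance and community assembly
# ---------------------------------------------------------------------------

def fisher_logseries_abundances(
    n_species: int, n_individuals: int, alpha: float = FISHER_ALPHA
) -> np.ndarray:
    """Ranked regional relative abundances from the expected Fisher
    log-series curve phi_n = alpha x^n / n (x = N/(N+alpha)), inverted to
    per-rank abundances; normalized to probabilities."""
    x = n_individuals / (n_individuals + alpha)
    nmax = max(10 * n_individuals, 1000)
    ns = np.arange(1, nmax + 1, dtype=float)
    phi = alpha * np.power(x, ns) / ns
    cum = np.cumsum(phi[::-1])[::-1]  # species with abundance >= n
    ranks = np.arange(1, n_species + 1, dtype=float)
    ab = np.interp(ranks, cum[::-1], ns[::-1])
    return ab / ab.sum()


def assemble_community(
    traits: pd.DataFrame,
    env: EnvironmentFields,
    config: SimConfig,
) -> StemMap:
    """Place individuals by trait-environment matching.

    Species are drawn from the log-series regional abundance curve; each
    individual lands in a quadrat with probability proportional to
    exp(-filtering_strength * (trait1(sp) - env1(quadrat))^2), then
    uniformly within the quadrat.  filtering_strength = 0 reduces to
    uniform random placement.
    """
    if traits.shape[0] == 0:
        raise InvalidArgumentError("empty trait table")
    rng = np.random.default_rng(config.seed + 2)
    species = list(traits.index)
    regional = fisher_logseries_abundances(len(species), config.n_individuals)
    # random assignment of abundance ranks to species (decoupled from traits)
    rank_of = rng.permutation(len(species))
    p_species = regional[rank_of]
    counts = rng.multinomial(config.n_individuals, p_species)

    t1 = traits.iloc[:, 0].values
    e1 = env.values.iloc[:, 0].values
    grid = env.grid

    tags, sp_col, xs, ys = [], [], [], []
    tag_counter = 1
    for s_idx, (sp, k) in enumerate(zip(species, counts)):
        if k == 0:
            continue
        logw = -config.filtering_strength * (t1[s_idx] - e1) ** 2
        w = np.exp(logw - logw.max())
        w /= w.sum()
        qcounts = rng.multinomial(k, w)
        occupied = np.flatnonzero(qcounts)
        for q in occupied:
            m = qcounts[q]
            qx = (q % grid.n_x) * grid.scale
            qy = (q // grid.n_x) * grid.scale
            xs.append(qx + rng.random(m) * grid.scale)
            ys.append(qy + rng.random(m) * grid.scale)
            sp_col.extend([sp] * m)
            tags.extend(
                f"t{t:06d}" for t in range(tag_counter, tag_counter + m)
            )
            tag_counter += m
    df = pd.DataFrame(
        {
            "tag": tags,
            "species": sp_col,
            "x": np.concatenate(xs) if xs else np.array([]),
            "y": np.concatenate(ys) if ys else np.array([]),
        }
    )
    return StemMap(df, config.plot_width, config.plot_height)


# ---------------------------------------------------------------------------
# one-call generation and persistence
# ---------------------------------------------------------------------------

def generate(config: SimConfig) -> SyntheticDataset:
    """Full coupled dataset under one seed, with the truth record."""
    tree = simulate_phylogeny(config.n_species, seed=config.seed)
    traits = simulate_traits(
        tree, config.n_traits, config.signal_lambda, seed=config.seed
    )
    env = simulate_environment(config)
    stem_map = assemble_community(traits, env, config)
    truth = {
        "niche_trait": traits.columns[0],
        "niche_env": env.values.columns[0],
        "filtering_strength": config.filtering_strength,
        "signal_lambda": config.signal_lambda,
        "config": asdict(config),
    }
    return SyntheticDataset(
        stem_map=stem_map, phylogeny=tree, traits=traits, env=env, truth=truth
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Persist a dataset (TSV stem map, CSV traits/env, Newick tree,
    YAML truth record); returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stem_map": outdir / "stem_map.tsv",
        "traits": outdir / "traits.csv",
        "env": outdir / "environment.csv",
        "tree": outdir / "phylogeny.nwk",
        "truth": outdir / "truth.yaml",
    }
    write_stem_map(ds.stem_map, paths["stem_map"])
    ds.traits.to_csv(paths["traits"], index_label="species")
    ds.env.values.to_csv(paths["env"], index_label="quadrat")
    write_newick(ds.phylogeny, paths["tree"])
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(ds.truth, fh)
    return {k: str(v) for k, v in paths.items()}
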