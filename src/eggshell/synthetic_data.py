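"""Synthetic trees, trait tables and height maps with known ground truth.

The generator emulates the statistical structure assumed by the analysis
pipeline so that every stage can be exercised against a known truth:

* an ultrametric Yule (pure-birth) species tree, rescaled to unit height;
* species trait values drawn multivariate-normal with the Brownian-motion
  covariance ``sigma2_p * A`` of that tree, plus an optional fixed shift
  for parasitic species and an optional convex "convergence" pull of each
  parasite's species value toward its host's value (weight ``w``: 0 = no
  convergence, 1 = parasite equals host exactly);
* independent egg-level Gaussian noise ``sigma2_e`` around the species
  value, several eggs per species, so the implied phylogenetic
  heritability is ``H2 = sigma2_p/(sigma2_p + sigma2_e)``;
* profilometry height maps: a smooth quadratic curvature surface plus an
  i.i.d. Gaussian roughness field.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .hostmatch import HOST_SEPARATOR, HostMap
from .measurements import HeightMap
from .phylo import Phylogeny, covariance_from_tree, read_newick, write_newick

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_traits",
    "simulate_dataset",
    "simulate_heightmap",
    "EGG_TABLE_COLUMNS",
]

EGG_TABLE_COLUMNS = [
    "egg_id",
    "species",
    "parasitic",
    "host_species",
    "sa_nm",
    "ca_deg",
    "caco3_pct",
    "nest_type",
    "source",
]


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one synthetic study.

    Defaults mirror the scale of the empirical study this pipeline targets:
    45 species of which 14 are obligate brood parasites, 2-10 eggs per
    species, a strongly phylogenetic trait on the surface-roughness scale
    (species-level sd ~450 nm around a 1500 nm mean, H2 ~ 0.95), no
    parasitism effect and no host convergence unless requested.
    """

    n_species: int = 45
    birth_rate: float = 1.0
    n_parasites: int = 14
    eggs_per_species: int | tuple[int, int] = (2, 10)
    trait: str = "sa_nm"
    trait_mean: float = 1500.0
    sigma2_p: float = 202_500.0
    sigma2_e: float = 10_700.0
    beta_parasitism: float = 0.0
    convergence_w: float = 0.0
    host_assignment: str = "random"  # or "nearest_nonparasite"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("need at least 3 species")
        if not (0 < self.n_parasites < self.n_species):
            raise ValueError("0 < n_parasites < n_species required")
        if self.sigma2_p < 0 or self.sigma2_e <= 0:
            raise ValueError("sigma2_p >= 0 and sigma2_e > 0 required")
        if not (0 <= self.convergence_w <= 1):
            raise ValueError("convergence_w must lie in [0, 1]")
        if self.host_assignment not in ("random", "nearest_nonparasite"):
            raise ValueError(f"unknown host_assignment {self.host_assignment!r}")

    @property
    def true_h2(self) -> float:
        return self.sigma2_p / (self.sigma2_p + self.sigma2_e)


@dataclass
class SyntheticDataset:
    """Tree + egg table + host map + the generating truth."""

    tree: Phylogeny
    table: pd.DataFrame
    hostmap: HostMap
    truth: dict = field(default_factory=dict)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_newick(self.tree, path / "tree.nwk")
        self.table.to_csv(path / "eggs.csv", index=False)
        self.hostmap.to_csv(path / "hosts.csv")
        with open(path / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)

    @classmethod
    def from_dir(cls, path) -> "SyntheticDataset":
        path = Path(path)
        tree = read_newick(path / "tree.nwk")
        table = pd.read_csv(
            path / "eggs.csv", dtype={"host_species": str}, keep_default_na=True
        )
        table["host_species"] = table["host_species"].fillna("")
        hostmap = HostMap.from_csv(path / "hosts.csv")
        with open(path / "truth.json") as fh:
            truth = json.load(fh)
        return cls(tree=tree, table=table, hostmap=hostmap, truth=truth)


def simulate_tree(
    n_species: int,
    birth_rate: float = 1.0,
    rng_seed: int = 0,
    rescale: bool = True,
) -> Phylogeny:
    """Simulate a Yule (pure-birth) species tree.

    Starting from two lineages, inter-speciation waits while k lineages
    are extant are Exp(k * birth_rate); after the nth speciation the tips
    are extended by a final Exp(n * birth_rate) hold time (the time to the
    unobserved next event), which avoids zero-length terminal cherries.
    With ``rescale`` (default) the tree is scaled to unit root height, so
    branch lengths are in units of total tree depth.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = random.Random(rng_seed)
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = tree.seed_node
    tips: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        tips.append(child)
    k = 2
    while k < n_species:
        dt = rng.expovariate(k * birth_rate)
        for tip in tips:
            tip.edge.length += dt
        split = tips.pop(rng.randrange(len(tips)))
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            split.add_child(child)
            tips.append(child)
        k += 1
    dt = rng.expovariate(k * birth_rate)
    for tip in tips:
        tip.edge.length += dt

    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxon_namespace.new_taxon(label=f"S{i:0{width}d}")

    if rescale:
        height = max(Phylogeny(tree).tip_depths().values())
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= height
    return Phylogeny(tree)


def _patristic_distances(tree: Phylogeny) -> pd.DataFrame:
    cov = covariance_from_tree(tree)
    C = cov.C
    d = np.diag(C)
    dist = d[:, None] + d[None, :] - 2 * C
    return pd.DataFrame(dist, index=cov.species_order, columns=cov.species_order)


def simulate_traits(
    tree: Phylogeny | None, config: SimulationConfig
) -> SyntheticDataset:
    """Simulate an egg-level trait table on a tree under the mixed model.

    Species effects are drawn MVN(0, sigma2_p * A) via a symmetric matrix
    square root; parasites then receive the fixed shift and the convex
    convergence pull toward their host's species value; finally each egg
    adds independent N(0, sigma2_e) noise.  If ``tree`` is None a Yule
    tree is simulated from the same seed.
    """
    rng = np.random.default_rng(config.rng_seed)
    if tree is None:
        tree = simulate_tree(
            config.n_species, config.birth_rate, rng_seed=config.rng_seed
        )
    species = tree.taxa
    if len(species) != config.n_species:
        raise ValueError("tree tip count does not match config.n_species")
    cov = covariance_from_tree(tree)
    order = cov.species_order
    A = cov.A
    # symmetric PSD square root (eigh) tolerates the rank deficiencies a
    # Cholesky would reject on trees with very short internal branches
    lam, U = np.linalg.eigh(A)
    lam = np.clip(lam, 0.0, None)
    sqrtA = U @ (np.sqrt(lam)[:, None] * U.T)

    parasites = list(
        rng.choice(np.asarray(order), size=config.n_parasites, replace=False)
    )
    nonparasites = [s for s in order if s not in parasites]

    if config.host_assignment == "random":
        hosts = {
            p: str(nonparasites[int(rng.integers(len(nonparasites)))])
            for p in parasites
        }
    else:
        dist = _patristic_distances(tree)
        hosts = {
            p: str(dist.loc[p, nonparasites].idxmin()) for p in parasites
        }
    hostmap = HostMap({p: [h] for p, h in hosts.items()})

    u = np.sqrt(config.sigma2_p) * (sqrtA @ rng.standard_normal(len(order)))
    values = dict(zip(order, config.trait_mean + u))
    for p in parasites:
        values[p] = values[p] + config.beta_parasitism
    w = config.convergence_w
    pulled = dict(values)
    for p in parasites:
        pulled[p] = (1 - w) * values[p] + w * values[hosts[p]]
    values = pulled

    if isinstance(config.eggs_per_species, int):
        egg_counts = {s: config.eggs_per_species for s in order}
    else:
        lo, hi = config.eggs_per_species
        egg_counts = {s: int(rng.integers(lo, hi + 1)) for s in order}

    rows = []
    egg_no = 0
    for s in order:
        is_parasite = s in hosts
        for _ in range(egg_counts[s]):
            egg_no += 1
            y = values[s] + np.sqrt(config.sigma2_e) * rng.standard_normal()
            rows.append(
                {
                    "egg_id": f"E{egg_no:04d}",
                    "species": s,
                    "parasitic": bool(is_parasite),
                    "host_species": hosts[s] if is_parasite else "",
                    config.trait: float(y),
                    "nest_type": "",
                    "source": "synthetic",
                }
            )
    table = pd.DataFrame(rows)
    for col in EGG_TABLE_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    table = table[EGG_TABLE_COLUMNS]

    truth = dataclasses.asdict(config)
    truth.update(
        {
            "true_h2": config.true_h2,
            "parasites": sorted(map(str, parasites)),
            "hosts": {str(k): v for k, v in hosts.items()},
            "species_values": {s: float(values[s]) for s in order},
        }
    )
    if not isinstance(config.eggs_per_species, int):
        truth["eggs_per_species"] = list(config.eggs_per_species)
    return SyntheticDataset(tree=tree, table=table, hostmap=hostmap, truth=truth)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Convenience: simulate tree and traits from one config/seed."""
    return simulate_traits(None, config)


def simulate_heightmap(
    rows: int,
    cols: int,
    curvature_coeffs=(0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    roughness_sd: float = 0.0,
    rng_seed: int = 0,
) -> HeightMap:
    """Quadratic curvature surface plus an i.i.d. Gaussian roughness field.

    ``curvature_coeffs = (a, b, c, d, e, f)`` gives the smooth surface
    ``z = a x^2 + b x y + c y^2 + d x + e y + f`` over raw pixel indices
    (x = column, y = row); heights are in nanometres.
    """
    if rows < 8 or cols < 8:
        raise ValueError("need at least an 8x8 grid")
    if roughness_sd < 0:
        raise ValueError("roughness_sd must be non-negative")
    a, b, c, d, e, f = curvature_coeffs
    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    surface = a * x * x + b * x * y + c * y * y + d * x + e * y + f
    rng = np.random.default_rng(rng_seed)
    noise = roughness_sd * rng.standard_normal((rows, cols)) if roughness_sd else 0.0
    return HeightMap(surface + noise)
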