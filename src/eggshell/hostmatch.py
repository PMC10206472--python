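"""Parasite-host trait convergence: pairwise differences and their test.

For each parasitic egg with trait data two pairs are formed: a **host
pair** (absolute trait difference to a reference value from its host
species) and a **random pair** (absolute difference to a randomly chosen
egg of a non-parasitic species, by default excluding that parasite's own
hosts).  If the eggs of brood parasites converge on their hosts' nest
environment, host-pair differences should be systematically smaller than
random-pair differences.

The host reference value follows the study design for host generalists:
when the laying host of a particular egg is known, one egg of that host
species is used; when a parasite has several candidate hosts and the
laying host of the egg is unrecorded, the mean of the host species' mean
trait values is used (e.g. the common cuckoo, whose museum eggs came from
nests of one of three hosts).

The group contrast is tested twice: an ordinary two-sample t on the
absolute differences (OLS of |d| on pair type), and a label-shuffling
permutation test whose two-sided p-value carries the standard +1/(B+1)
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HostMap",
    "PairingSet",
    "GroupComparisonResult",
    "host_reference_value",
    "build_pairs",
    "compare_pair_types",
]

logger = logging.getLogger(__name__)

HOST_SEPARATOR = ";"


@dataclass
class HostMap:
    """Parasite species -> list of candidate host species."""

    hosts: dict[str, list[str]]

    def __post_init__(self) -> None:
        for parasite, host_list in self.hosts.items():
            if not host_list:
                raise ValueError(f"parasite {parasite!r} has an empty host list")
            if parasite in host_list:
                raise ValueError(f"parasite {parasite!r} maps to itself")

    @classmethod
    def from_csv(cls, path) -> "HostMap":
        """Two-column CSV (parasite, host); repeated rows add hosts."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("host map CSV needs two columns: parasite, host")
        pcol, hcol = df.columns[:2]
        hosts: dict[str, list[str]] = {}
        for parasite, host in zip(df[pcol].astype(str), df[hcol].astype(str)):
            hosts.setdefault(parasite, [])
            if host not in hosts[parasite]:
                hosts[parasite].append(host)
        return cls(hosts)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "HostMap":
        """Collect per-egg host annotations from an egg table."""
        hosts: dict[str, list[str]] = {}
        parasitic = table[table["parasitic"].astype(bool)]
        for species, host_field in zip(
            parasitic["species"], parasitic.get("host_species", pd.Series(dtype=str))
        ):
            if not isinstance(host_field, str) or not host_field:
                continue
            for host in host_field.split(HOST_SEPARATOR):
                host = host.strip()
                if host:
                    hosts.setdefault(str(species), [])
                    if host not in hosts[str(species)]:
                        hosts[str(species)].append(host)
        return cls(hosts)

    def to_csv(self, path) -> None:
        rows = [
            {"parasite": p, "host": h} for p, hl in self.hosts.items() for h in hl
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def validate_against(self, table: pd.DataFrame) -> None:
        """Hosts must be non-parasitic species present in the egg table."""
        by_species = table.groupby("species")["parasitic"].agg(lambda s: bool(s.any()))
        for parasite, host_list in self.hosts.items():
            for host in host_list:
                if host not in by_species.index:
                    raise ValueError(f"host {host!r} of {parasite!r} not in egg table")
                if by_species[host]:
                    raise ValueError(
                        f"host {host!r} of {parasite!r} is itself parasitic"
                    )


@dataclass
class PairingSet:
    """Parasite-host and parasite-random pairs for one trait."""

    pairs: pd.DataFrame  # columns: parasite_egg, parasite_species, partner, pair_type, abs_difference
    trait: str
    rng_seed: int
    n_host_pairs: int = field(init=False)
    n_random_pairs: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_host_pairs = int((self.pairs["pair_type"] == "host").sum())
        self.n_random_pairs = int((self.pairs["pair_type"] == "random").sum())
        if len(self.pairs) and (self.pairs["abs_difference"] < 0).any():
            raise ValueError("absolute differences must be non-negative")


@dataclass
class GroupComparisonResult:
    """Host-pair vs random-pair contrast in mean absolute difference."""

    estimate: float  # mean(random) - mean(host); positive = hosts more similar
    se: float
    t: float
    df: int
    p_parametric: float
    p_permutation: float
    n_host_pairs: int
    n_random_pairs: int
    n_permutations: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _egg_values(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = table.dropna(subset=[trait])
    return sub


def host_reference_value(
    parasite_egg: pd.Series,
    table: pd.DataFrame,
    hostmap: HostMap,
    trait: str,
    rng: np.random.Generator | None = None,
) -> float | None:
    """Host-side trait value for one parasitic egg, or None if no host data.

    Egg-level host known -> one egg value of that host species (sampled
    when the host has several measured eggs).  Host unknown with one or
    more candidate hosts -> mean of the host species' mean trait values.
    """
    species = str(parasite_egg["species"])
    candidates = hostmap.hosts.get(species, [])
    host_field = parasite_egg.get("host_species")
    known = (
        isinstance(host_field, str)
        and host_field != ""
        and len(host_field.split(HOST_SEPARATOR)) == 1
    )
    data = _egg_values(table, trait)
    if known:
        host = host_field.strip()
        values = data.loc[data["species"] == host, trait].to_numpy()
        if len(values) == 0:
            logger.warning(
                "no measured %s eggs for host %s of egg %s; pair skipped",
                trait, host, parasite_egg.get("egg_id"),
            )
            return None
        if rng is None:
            rng = np.random.default_rng(0)
        return float(rng.choice(values))
    species_means = []
    for host in candidates:
        values = data.loc[data["species"] == host, trait]
        if len(values):
            species_means.append(float(values.mean()))
    if not species_means:
        logger.warning(
            "no measured %s eggs for any host of %s; pair skipped", trait, species
        )
        return None
    return float(np.mean(species_means))


def build_pairs(
    table: pd.DataFrame,
    hostmap: HostMap,
    trait: str,
    rng_seed: int,
    exclude_hosts_from_random: bool = True,
    target_counts: tuple[int, int] | None = None,
) -> PairingSet:
    """Construct host and random pairs of per-egg trait values.

    Each eligible parasitic egg yields at most one host pair and one
    random pair; the random partner is drawn uniformly (seeded) from
    measured non-parasitic eggs, excluding the focal parasite's host
    species unless ``exclude_hosts_from_random=False``.
    ``target_counts=(n_host, n_random)`` subsamples the built pairs to
    mimic unequal group sizes arising from data availability.
    """
    rng = np.random.default_rng(rng_seed)
    data = _egg_values(table, trait)
    parasitic = data[data["parasitic"].astype(bool)]
    if parasitic.empty:
        logger.warning("no parasitic eggs with %s data; empty pairing set", trait)
        return PairingSet(
            pairs=pd.DataFrame(
                columns=[
                    "parasite_egg", "parasite_species", "partner",
                    "pair_type", "abs_difference",
                ]
            ),
            trait=trait,
            rng_seed=rng_seed,
        )
    nonparasitic = data[~data["parasitic"].astype(bool)]
    rows = []
    for _, egg in parasitic.iterrows():
        value = float(egg[trait])
        species = str(egg["species"])
        host_species = hostmap.hosts.get(species, [])
        ref = host_reference_value(egg, table, hostmap, trait, rng)
        if ref is not None:
            rows.append(
                {
                    "parasite_egg": egg["egg_id"],
                    "parasite_species": species,
                    "partner": "host_reference",
                    "pair_type": "host",
                    "abs_difference": abs(value - ref),
                }
            )
        pool = nonparasitic
        if exclude_hosts_from_random:
            pool = pool[~pool["species"].isin(host_species)]
        if pool.empty:
            logger.warning(
                "no eligible random partner for egg %s; random pair skipped",
                egg["egg_id"],
            )
            continue
        partner = pool.iloc[int(rng.integers(len(pool)))]
        rows.append(
            {
                "parasite_egg": egg["egg_id"],
                "parasite_species": species,
                "partner": str(partner["egg_id"]),
                "pair_type": "random",
                "abs_difference": abs(value - float(partner[trait])),
            }
        )
    pairs = pd.DataFrame(rows)
    if target_counts is not None and len(pairs):
        kept = []
        for pair_type, target in zip(("host", "random"), target_counts):
            group = pairs[pairs["pair_type"] == pair_type]
            if target < len(group):
                keep_idx = rng.choice(len(group), size=target, replace=False)
                group = group.iloc[np.sort(keep_idx)]
            kept.append(group)
        pairs = pd.concat(kept, ignore_index=True)
    return PairingSet(pairs=pairs.reset_index(drop=True), trait=trait, rng_seed=rng_seed)


def compare_pair_types(
    pairing: PairingSet,
    n_permutations: int = 10_000,
    rng_seed: int = 0,
) -> GroupComparisonResult:
    """Test whether host pairs differ less than random pairs.

    ``estimate`` is mean(|d| random) - mean(|d| host) (positive when
    parasite eggs are closer to host eggs), with pooled-variance SE, t
    and two-sided p on ``n_pairs - 2`` degrees of freedom, plus a
    two-sided label-shuffling permutation p-value on |estimate| with the
    +1/(B+1) correction.
    """
    pairs = pairing.pairs
    host = pairs.loc[pairs["pair_type"] == "host", "abs_difference"].to_numpy(float)
    rand = pairs.loc[pairs["pair_type"] == "random", "abs_difference"].to_numpy(float)
    if len(host) < 2 or len(rand) < 2:
        raise ValueError("need at least 2 pairs of each type")
    n_h, n_r = len(host), len(rand)
    estimate = float(rand.mean() - host.mean())
    df = n_h + n_r - 2
    pooled = ((n_h - 1) * host.var(ddof=1) + (n_r - 1) * rand.var(ddof=1)) / df
    se = float(np.sqrt(pooled * (1 / n_h + 1 / n_r)))
    t = estimate / se if se > 0 else 0.0
    p_param = float(2 * stats.t.sf(abs(t), df)) if se > 0 else 1.0

    values = np.concatenate([host, rand])
    labels = np.zeros(len(values), dtype=bool)
    labels[:n_h] = True  # True = host
    rng = np.random.default_rng(rng_seed)
    perm = np.tile(labels, (n_permutations, 1))
    perm = rng.permuted(perm, axis=1)
    mean_host = perm @ values / n_h
    mean_rand = (~perm) @ values / n_r
    stat = np.abs(mean_rand - mean_host)
    exceed = int(np.sum(stat >= abs(estimate) - 1e-12))
    p_perm = (1 + exceed) / (n_permutations + 1)

    return GroupComparisonResult(
        estimate=estimate,
        se=se,
        t=float(t),
        df=int(df),
        p_parametric=p_param,
        p_permutation=float(p_perm),
        n_host_pairs=n_h,
        n_random_pairs=n_r,
        n_permutations=int(n_permutations),
    )
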