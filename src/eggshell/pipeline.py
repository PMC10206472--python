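"""End-to-end analysis: from tree + egg table to a structured report.

Stages, in order: input validation and tree/table reconciliation;
per-trait phylogenetic mixed models with parasitic status as predictor
(REML components and H², ML likelihood-ratio test of the status effect);
a contact-angle-on-roughness mixed model with a plain species random
intercept; Pearson correlation blocks (all eggs / parasitic only /
non-parasitic only); host-match pairwise-difference tests for roughness
and contact angle; and a descriptive summary.  Every random element
(random pair partners, permutations) derives from one top-level seed via
deterministic per-stage spawning, so a report is reproducible
byte-for-byte from its own config echo.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .hostmatch import HostMap, build_pairs, compare_pair_types
from .measurements import classify_wettability
from .phylo import Phylogeny, covariance_from_tree
from .pmm import ModelSpec, fit_mixed, lrt_fixed_effect, pearson_ci
from .synthetic_data import EGG_TABLE_COLUMNS

__all__ = [
    "AnalysisConfig",
    "run_analysis",
    "descriptive_summary",
    "load_egg_table",
    "render_report_markdown",
    "TRAIT_COLUMNS",
]

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = {"Sa": "sa_nm", "CA": "ca_deg", "CaCO3": "caco3_pct"}


@dataclass
class AnalysisConfig:
    """Everything needed to (re)run one analysis."""

    tree_path: str | None = None
    eggs_path: str | None = None
    hosts_path: str | None = None
    traits: list[str] = field(default_factory=lambda: ["Sa", "CA", "CaCO3"])
    n_permutations: int = 10_000
    rng_seed: int = 0
    strict: bool = False
    standardize_A: bool = True
    exclude_hosts_from_random: bool = True
    grafen_if_missing_lengths: bool = False

    def to_dict(self) -> dict:
        return {
            "tree_path": self.tree_path,
            "eggs_path": self.eggs_path,
            "hosts_path": self.hosts_path,
            "traits": list(self.traits),
            "n_permutations": self.n_permutations,
            "rng_seed": self.rng_seed,
            "strict": self.strict,
            "standardize_A": self.standardize_A,
            "exclude_hosts_from_random": self.exclude_hosts_from_random,
            "grafen_if_missing_lengths": self.grafen_if_missing_lengths,
        }


def load_egg_table(path, strict: bool = False) -> pd.DataFrame:
    """Read an egg table CSV and validate its schema and ranges."""
    table = pd.read_csv(path, dtype={"host_species": str})
    return validate_egg_table(table, strict=strict)


def validate_egg_table(table: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Validate schema; out-of-range trait values are dropped (NaN) with a
    logged reason, or raise in strict mode.  Structural problems
    (missing columns, duplicate egg ids, host annotations on
    non-parasitic eggs) always raise."""
    required = ["egg_id", "species", "parasitic"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"egg table lacks required columns: {missing}")
    table = table.copy()
    if "host_species" not in table.columns:
        table["host_species"] = ""
    table["host_species"] = table["host_species"].fillna("").astype(str)
    table["parasitic"] = table["parasitic"].astype(bool)
    for col in TRAIT_COLUMNS.values():
        if col not in table.columns:
            table[col] = np.nan
    if table["egg_id"].duplicated().any():
        raise ValueError("duplicate egg_id values")
    range_checks = {
        "sa_nm": lambda v: v > 0,
        "ca_deg": lambda v: (v > 0) & (v < 180),
        "caco3_pct": lambda v: (v >= 0) & (v <= 100),
    }
    for col, ok in range_checks.items():
        values = table[col]
        bad = values.notna() & ~ok(values)
        if bad.any():
            msg = (
                f"{int(bad.sum())} out-of-range {col} value(s) on eggs "
                f"{table.loc[bad, 'egg_id'].tolist()}"
            )
            if strict:
                raise ValueError(msg)
            logger.warning("%s; dropped from analysis", msg)
            table.loc[bad, col] = np.nan
    nonpar_with_host = table[~table["parasitic"] & (table["host_species"] != "")]
    if len(nonpar_with_host):
        raise ValueError("host_species set on non-parasitic eggs")
    return table


def _reconcile(table: pd.DataFrame, tree: Phylogeny, strict: bool) -> pd.DataFrame:
    tips = set(tree.taxa)
    present = table["species"].isin(tips)
    dropped = sorted(table.loc[~present, "species"].unique())
    if dropped:
        msg = f"species absent from tree, dropped: {dropped}"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    out = table[present]
    if out["species"].nunique() < 3:
        raise ValueError("fewer than 3 species shared between table and tree")
    return out


def descriptive_summary(table: pd.DataFrame) -> dict:
    """Per-group trait ranges and wettability category tallies."""
    if table.empty:
        raise ValueError("empty egg table")
    out: dict = {"traits": {}, "wettability_counts": {}}
    for trait, col in TRAIT_COLUMNS.items():
        out["traits"][trait] = {}
        for label, group in (
            ("parasitic", table[table["parasitic"]]),
            ("non_parasitic", table[~table["parasitic"]]),
        ):
            values = group[col].dropna()
            if values.empty:
                out["traits"][trait][label] = {"n": 0}
                continue
            out["traits"][trait][label] = {
                "n": int(len(values)),
                "n_species": int(group.loc[values.index, "species"].nunique()),
                "min": float(values.min()),
                "max": float(values.max()),
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
            }
    ca = table["ca_deg"].dropna()
    counts = {"hydrophilic": 0, "hydrophobic": 0, "superhydrophobic": 0}
    for v in ca:
        counts[classify_wettability(float(v))] += 1
    out["wettability_counts"] = counts
    return out


def _pearson_block(table: pd.DataFrame) -> dict:
    out = {}
    for label, group in (
        ("all", table),
        ("parasitic", table[table["parasitic"]]),
        ("non_parasitic", table[~table["parasitic"]]),
    ):
        sub = group.dropna(subset=["sa_nm", "ca_deg"])
        if len(sub) < 4:
            out[label] = {"n": int(len(sub)), "note": "insufficient paired data"}
            continue
        try:
            res = pearson_ci(sub["sa_nm"], sub["ca_deg"])
        except ValueError as err:
            out[label] = {"n": int(len(sub)), "note": str(err)}
            continue
        out[label] = {
            "r": res.r, "ci_low": res.ci_low, "ci_high": res.ci_high, "n": res.n,
        }
    return out


def run_analysis(
    config: AnalysisConfig,
    tree: Phylogeny | None = None,
    table: pd.DataFrame | None = None,
    hostmap: HostMap | None = None,
) -> dict:
    """Run the full comparative analysis and return the report dict.

    Inputs may be passed in memory or read from the paths in ``config``.
    """
    from .phylo import assign_branch_lengths, read_newick

    if tree is None:
        if config.tree_path is None:
            raise ValueError("no tree given")
        tree = read_newick(config.tree_path)
    if table is None:
        if config.eggs_path is None:
            raise ValueError("no egg table given")
        table = load_egg_table(config.eggs_path, strict=config.strict)
    else:
        table = validate_egg_table(table, strict=config.strict)
    if hostmap is None and config.hosts_path is not None:
        hostmap = HostMap.from_csv(config.hosts_path)

    if not tree.has_branch_lengths:
        if not config.grafen_if_missing_lengths:
            raise ValueError(
                "tree lacks branch lengths; rerun with grafen_if_missing_lengths=True "
                "to apply Grafen's ultrametricization"
            )
        tree = assign_branch_lengths(tree, method="grafen")

    dropped_species = sorted(set(table["species"]) - set(tree.taxa))
    table = _reconcile(table, tree, config.strict)
    if hostmap is not None:
        hostmap.validate_against(table)

    seed_seq = np.random.SeedSequence(config.rng_seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ["pairs_Sa", "perm_Sa", "pairs_CA", "perm_CA"], seed_seq.spawn(4)
        )
    }

    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": stage_seeds,
        "dropped_species": dropped_species,
        "pmm": {},
        "ca_on_sa": None,
        "pearson": _pearson_block(table),
        "hostmatch": {},
        "descriptives": descriptive_summary(table),
    }

    for trait in config.traits:
        col = TRAIT_COLUMNS[trait]
        sub = table.dropna(subset=[col])
        if sub["species"].nunique() < 3:
            report["pmm"][trait] = {"note": "fewer than 3 species with data"}
            continue
        cov = covariance_from_tree(tree, sorted(sub["species"].unique()))
        full = ModelSpec(response=col, fixed_effects=["parasitic"], species_cov=cov)
        reduced = ModelSpec(response=col, fixed_effects=[], species_cov=cov)
        fit = fit_mixed(full, sub, criterion="REML")
        lrt = lrt_fixed_effect(full, reduced, sub)
        report["pmm"][trait] = {
            "fit": fit.to_dict(),
            "H2": fit.H2,
            "lrt": {"chi2": lrt.chi2, "df": lrt.df, "p_value": lrt.p_value},
        }

    both = table.dropna(subset=["sa_nm", "ca_deg"])
    if both["species"].nunique() >= 2 and len(both) >= 6:
        try:
            spec_full = ModelSpec(response="ca_deg", fixed_effects=["sa_nm"])
            spec_red = ModelSpec(response="ca_deg", fixed_effects=[])
            fit = fit_mixed(spec_full, both, criterion="REML")
            lrt = lrt_fixed_effect(spec_full, spec_red, both)
            report["ca_on_sa"] = {
                "fit": fit.to_dict(),
                "lrt": {"chi2": lrt.chi2, "df": lrt.df, "p_value": lrt.p_value},
                "n_eggs": int(len(both)),
                "n_species": int(both["species"].nunique()),
            }
        except ValueError as err:
            report["ca_on_sa"] = {"note": str(err)}
    else:
        report["ca_on_sa"] = {"note": "insufficient paired S_a/CA data"}

    if hostmap is not None:
        for trait in ("Sa", "CA"):
            if trait not in config.traits:
                continue
            col = TRAIT_COLUMNS[trait]
            pairing = build_pairs(
                table,
                hostmap,
                col,
                rng_seed=stage_seeds[f"pairs_{trait}"],
                exclude_hosts_from_random=config.exclude_hosts_from_random,
            )
            if pairing.n_host_pairs < 2 or pairing.n_random_pairs < 2:
                report["hostmatch"][trait] = {
                    "note": "too few pairs",
                    "n_host_pairs": pairing.n_host_pairs,
                    "n_random_pairs": pairing.n_random_pairs,
                }
                continue
            result = compare_pair_types(
                pairing,
                n_permutations=config.n_permutations,
                rng_seed=stage_seeds[f"perm_{trait}"],
            )
            report["hostmatch"][trait] = result.to_dict()

    return report


def write_report(report: dict, out_dir) -> None:
    """Write JSON, markdown and a flat CSV of headline numbers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "report.md", "w") as fh:
        fh.write(render_report_markdown(report))
    rows = []
    for trait, block in report.get("pmm", {}).items():
        if "fit" not in block:
            continue
        rows.append(
            {
                "analysis": f"pmm_{trait}",
                "H2": block["H2"],
                "estimate": block["fit"]["beta"].get("parasitic", {}).get("estimate"),
                "p_value": block["lrt"]["p_value"],
            }
        )
    for trait, block in report.get("hostmatch", {}).items():
        if "estimate" not in block:
            continue
        rows.append(
            {
                "analysis": f"hostmatch_{trait}",
                "estimate": block["estimate"],
                "p_value": block["p_permutation"],
            }
        )
    pd.DataFrame(rows).to_csv(out / "headline.csv", index=False)


def render_report_markdown(report: dict) -> str:
    """Human-readable rendering of the JSON report (same numbers)."""
    lines = [
        "# Eggshell trait analysis report",
        "",
        f"package version {report['version']}; seed {report['config']['rng_seed']}",
        "",
        "## Phylogenetic mixed models (trait ~ parasitic status)",
        "",
    ]
    for trait, block in report.get("pmm", {}).items():
        if "fit" not in block:
            lines.append(f"- **{trait}**: {block.get('note')}")
            continue
        beta = block["fit"]["beta"].get("parasitic", {})
        lrt = block["lrt"]
        lines.append(
            f"- **{trait}**: H2 = {block['H2']:.3f}; parasitic-status estimate = "
            f"{beta.get('estimate', float('nan')):.4g} (se {beta.get('se', float('nan')):.3g}, "
            f"t {beta.get('t', float('nan')):.3g}); LRT chi2 = {lrt['chi2']:.3g}, "
            f"df = {lrt['df']}, p = {lrt['p_value']:.3g}"
        )
    lines += ["", "## Contact angle on roughness (species random intercept)", ""]
    block = report.get("ca_on_sa") or {}
    if "fit" in block:
        slope = block["fit"]["beta"].get("sa_nm", {})
        lines.append(
            f"- slope = {slope.get('estimate', float('nan')):.4g} "
            f"(se {slope.get('se', float('nan')):.3g}, t {slope.get('t', float('nan')):.3g}); "
            f"LRT p = {block['lrt']['p_value']:.3g}; n = {block['n_eggs']} eggs, "
            f"{block['n_species']} species"
        )
    else:
        lines.append(f"- {block.get('note', 'not run')}")
    lines += ["", "## Pearson correlation (S_a vs CA)", ""]
    for label, corr in report.get("pearson", {}).items():
        if "r" in corr:
            lines.append(
                f"- {label}: r = {corr['r']:.3f}, 95% CI "
                f"[{corr['ci_low']:.3f}, {corr['ci_high']:.3f}], n = {corr['n']}"
            )
        else:
            lines.append(f"- {label}: {corr.get('note')} (n = {corr.get('n')})")
    lines += ["", "## Host-match pairwise comparisons", ""]
    for trait, block in report.get("hostmatch", {}).items():
        if "estimate" in block:
            lines.append(
                f"- **{trait}**: estimate = {block['estimate']:.4g} "
                f"(se {block['se']:.3g}), t_{block['df']} = {block['t']:.3g}, "
                f"parametric p = {block['p_parametric']:.3g}, permutation p = "
                f"{block['p_permutation']:.3g} "
                f"({block['n_host_pairs']} host / {block['n_random_pairs']} random pairs)"
            )
        else:
            lines.append(f"- **{trait}**: {block.get('note')}")
    lines += ["", "## Descriptives", ""]
    for trait, groups in report.get("descriptives", {}).get("traits", {}).items():
        for label, s in groups.items():
            if s.get("n", 0) == 0:
                continue
            lines.append(
                f"- {trait} {label}: n = {s['n']}, range {s['min']:.4g}-{s['max']:.4g}, "
                f"mean {s['mean']:.4g} (sd {s['sd']:.3g})"
            )
    counts = report.get("descriptives", {}).get("wettability_counts", {})
    if counts:
        lines.append(
            "- wettability: "
            + ", ".join(f"{k} = {v}" for k, v in counts.items())
        )
    return "\n".join(lines) + "\n"
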