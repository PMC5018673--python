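"""End-to-end orchestration: signal → correlations → node scan → clade ANOVA.

One :class:`RunConfig` drives all four analysis stages on a tree, a genus
table (or a species table aggregated on the fly) and a clade classification,
writing diff-able TSV reports plus a JSON manifest that fully specifies a
rerun.  Each trait is analyzed independently with per-trait tip matching, so
richness and range use every genus while abundance uses only the genera
with an estimate.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bm_models import compare_models
from .clade_compare import load_clade_table, one_way_anova
from .contrasts import pearson_pic, pearson_raw, pic
from .errors import AmaztraitsError
from .node_scan import permutation_scan, scan_report
from .phylo_core import (
    Phylogeny,
    read_newick_file,
    resolve_polytomies,
    write_newick,
)
from .trait_table import (
    LOG_TRAITS,
    aggregate_to_genus,
    load_species_table,
    match_tree_and_traits,
    read_genus_table,
)

__all__ = ["RunConfig", "run_full_analysis"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    tree_path: str | None = None
    genus_table_path: str | None = None
    species_table_path: str | None = None
    clade_table_path: str | None = None
    output_dir: str = "amaztraits_out"
    traits: tuple[str, ...] = LOG_TRAITS
    n_perm: int = 1000
    seed: int = 0
    run_signal: bool = True
    run_correlations: bool = True
    run_nodescan: bool = True
    run_clades: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        stages = raw.pop("stages", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        for stage, enabled in stages.items():
            attr = f"run_{stage}"
            if not hasattr(cfg, attr):
                raise ValueError(f"unknown stage {stage!r}")
            setattr(cfg, attr, bool(enabled))
        if isinstance(cfg.traits, list):
            cfg.traits = tuple(cfg.traits)
        return cfg

    def validate(self) -> None:
        if self.tree_path is None and (self.run_signal or self.run_correlations or self.run_nodescan):
            raise ValueError("tree_path is required for the enabled stages")
        if self.genus_table_path is None and self.species_table_path is None:
            raise ValueError("provide a genus table or a species table")
        if self.run_clades and self.clade_table_path is None:
            raise ValueError("clade_table_path is required for the clade stage")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_full_analysis(
    config: RunConfig,
    tree: Phylogeny | None = None,
    genus_table: pd.DataFrame | None = None,
    clades: pd.Series | None = None,
) -> dict:
    """Run the enabled stages and write one report artifact per stage.

    Inputs may be passed in memory (``tree``, ``genus_table``, ``clades``)
    or read from the configured paths.  Outputs, all under
    ``config.output_dir``: ``signal.tsv`` (three-model λ/ΔAIC table per
    trait), ``correlations.tsv`` (raw and contrast Pearson r/p per trait
    pair), ``nodescan_<trait>.tsv`` plus an annotated Newick with high/low
    classifications on internal labels, ``anova_<trait>.tsv`` and
    ``tukey_<trait>.tsv``, and ``manifest.json``.  Identical config and
    seed give byte-identical outputs.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "traits": list(config.traits),
        "inputs": {
            "tree": config.tree_path,
            "genus_table": config.genus_table_path,
            "species_table": config.species_table_path,
            "clade_table": config.clade_table_path,
        },
        "stages": {},
    }
    results: dict = {"manifest": manifest}

    if tree is None and config.tree_path is not None:
        tree = read_newick_file(config.tree_path)
    if genus_table is None:
        if config.genus_table_path is not None:
            genus_table = read_genus_table(config.genus_table_path)
        else:
            genus_table = aggregate_to_genus(
                load_species_table(config.species_table_path)
            )
    if clades is None and config.clade_table_path is not None:
        clades = load_clade_table(config.clade_table_path)

    matched: dict[str, tuple[Phylogeny, np.ndarray]] = {}

    def matched_for(trait: str):
        if trait not in matched:
            matched[trait] = match_tree_and_traits(tree, genus_table, trait)
        return matched[trait]

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except AmaztraitsError as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, outdir, partial=True)
            raise
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
        }

    # -- stage 1: phylogenetic signal --------------------------------------
    if config.run_signal:
        def signal_stage():
            rows = []
            for trait in config.traits:
                pt, x = matched_for(trait)
                mc = compare_models(pt, x)
                for mode, label in (
                    ("ml", "Estimated lambda"),
                    ("fixed_zero", "No phylogenetic dependence"),
                    ("fixed_one", "Brownian motion"),
                ):
                    f = mc.fits[mode]
                    rows.append(
                        {
                            "trait": trait,
                            "model": label,
                            "lambda": f.lam,
                            "sigma2": f.sigma2,
                            "loglik": f.loglik,
                            "AIC": f.aic,
                            "delta_AIC": mc.delta_aic[mode],
                            "n": f.n,
                        }
                    )
            df = pd.DataFrame(rows)
            results["signal"] = df
            _write_tsv(df, outdir / "signal.tsv")
            manifest["sample_sizes"] = {
                t: int(matched[t][0].n_tips) for t in config.traits
            }
        run_stage("signal", signal_stage)

    # -- stage 2: raw and contrast correlations ----------------------------
    if config.run_correlations:
        def correlation_stage():
            rows = []
            for i in range(len(config.traits)):
                for j in range(i + 1, len(config.traits)):
                    ta, tb = config.traits[i], config.traits[j]
                    # pairwise-complete matching on the two traits
                    both = genus_table[[ta, tb]].dropna()
                    sub = genus_table.loc[both.index]
                    pt, xa = match_tree_and_traits(tree, sub, ta)
                    xb = sub.loc[pt.tip_labels, tb].to_numpy(float)
                    raw = pearson_raw(xa, xb)
                    bt = resolve_polytomies(pt, seed=config.seed)
                    cs_a = pic(bt, xa)
                    cs_b = pic(bt, xb)
                    picr = pearson_pic(cs_a, cs_b)
                    rows.append(
                        {
                            "trait_a": ta,
                            "trait_b": tb,
                            "r_raw": raw.r,
                            "p_raw": raw.p_value,
                            "n_raw": raw.n_effective,
                            "r_pic": picr.r,
                            "p_pic": picr.p_value,
                            "n_contrasts": picr.n_effective,
                            "pic_slope_through_origin": picr.slope,
                        }
                    )
            df = pd.DataFrame(rows)
            results["correlations"] = df
            _write_tsv(df, outdir / "correlations.tsv")
        run_stage("correlations", correlation_stage)

    # -- stage 3: ancestral-state node scans --------------------------------
    if config.run_nodescan:
        def nodescan_stage():
            for trait in config.traits:
                pt, x = matched_for(trait)
                bt = resolve_polytomies(pt, seed=config.seed)
                scan = permutation_scan(bt, x, n_perm=config.n_perm, seed=config.seed)
                report = scan_report(scan)
                results[f"nodescan_{trait}"] = report
                _write_tsv(report, outdir / f"nodescan_{trait}.tsv")
                cls = dict(zip(scan.node_ids.tolist(), scan.classification))
                annotated = bt.copy()
                for node in annotated.internal_nodes:
                    node.label = cls.get(node.id, "ns")
                with open(outdir / f"nodescan_{trait}.nwk", "w") as fh:
                    fh.write(write_newick(annotated))
        run_stage("nodescan", nodescan_stage)

    # -- stage 4: clade ANOVA / Tukey ---------------------------------------
    if config.run_clades:
        def clade_stage():
            for trait in config.traits:
                sub = genus_table[genus_table[trait].notna()]
                common = sub.index.intersection(clades.index)
                res = one_way_anova(
                    sub.loc[common, trait].to_numpy(float),
                    clades.loc[common].to_numpy(),
                )
                df = pd.DataFrame(
                    [
                        {
                            "trait": trait,
                            "F": res.F,
                            "df_between": res.df_between,
                            "df_within": res.df_within,
                            "p_value": res.p_value,
                            "r_squared": res.r_squared,
                            **{f"mean_{g}": m for g, m in sorted(res.group_means.items())},
                        }
                    ]
                )
                results[f"anova_{trait}"] = df
                results[f"tukey_{trait}"] = res.tukey
                _write_tsv(df, outdir / f"anova_{trait}.tsv")
                _write_tsv(res.tukey, outdir / f"tukey_{trait}.tsv")
        run_stage("clades", clade_stage)

    manifest["total_seconds"] = round(time.perf_counter() - t_start, 3)
    _write_manifest(manifest, outdir, partial=False)
    return results


def _write_manifest(manifest: dict, outdir: Path, partial: bool) -> None:
    # stage timings vary between runs; the TSV artifacts are the
    # byte-reproducible surface
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(dict(manifest, partial=partial), fh, indent=2, sort_keys=True)
        fh.write("\n")
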