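"""End-to-end orchestration: preprocess -> diversity -> assembly ->
biogeography/core -> statistics, driven by a single YAML config.

Every Monte-Carlo step takes an explicit seed recorded in the run report,
so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assembly import AssemblyConfig, assembly_pipeline
from .biogeo import abundance_occupancy, core_coverage, ddr, venn_partition
from .containers import ValidationError, environment_columns
from .diversity import alpha_diversity, bray_curtis, envfit, pcoa
from .io import align_inputs, read_count_table, read_metadata, read_taxonomy, read_tree
from .preprocess import (
    css_normalize,
    filter_by_taxonomy,
    filter_low_depth_samples,
    filter_rare,
    rarefy,
    to_relative_abundance,
)
from .stats import permanova

logger = logging.getLogger("streamcom")

KNOWN_KEYS = {
    "counts",
    "counts_orientation",
    "tree",
    "taxonomy",
    "metadata",
    "output_dir",
    "min_reads",
    "max_total",
    "rarefaction_depth",
    "css_quantile",
    "n_null",
    "n_perm",
    "weighted",
    "group_by",
    "ddr_subset",
    "seed",
}


@dataclass
class RunConfig:
    """Validated settings for one full pipeline run."""

    counts: Path
    tree: Path
    taxonomy: Path
    metadata: Path
    output_dir: Path
    counts_orientation: str = "samples"
    min_reads: int = 1000
    max_total: int = 2
    rarefaction_depth: int | None = None  # None = smallest library
    css_quantile: float = 0.5
    n_null: int = 999
    n_perm: int = 999
    weighted: bool = True
    group_by: str = "season"
    ddr_subset: list[str] | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return d


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str], list[str]]:
    """Load a YAML config, collecting *all* errors rather than the first.

    Returns (config_or_None, errors, warnings). Unknown keys warn but do
    not fail, for forward compatibility.
    """
    errors: list[str] = []
    warnings: list[str] = []
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except Exception as exc:
        return None, [f"cannot parse config: {exc}"], []
    if not isinstance(raw, dict):
        return None, ["config must be a mapping"], []
    for key in raw:
        if key not in KNOWN_KEYS:
            warnings.append(f"unknown config key {key!r} ignored")
    for key in ("counts", "tree", "taxonomy", "metadata"):
        if key not in raw:
            errors.append(f"missing required key {key!r}")
        elif not Path(raw[key]).exists():
            errors.append(f"path for {key!r} does not exist: {raw[key]}")
    if "output_dir" not in raw:
        errors.append("missing required key 'output_dir'")
    if errors:
        return None, errors, warnings
    cfg = RunConfig(
        counts=Path(raw["counts"]),
        tree=Path(raw["tree"]),
        taxonomy=Path(raw["taxonomy"]),
        metadata=Path(raw["metadata"]),
        output_dir=Path(raw["output_dir"]),
        counts_orientation=raw.get("counts_orientation", "samples"),
        min_reads=int(raw.get("min_reads", 1000)),
        max_total=int(raw.get("max_total", 2)),
        rarefaction_depth=raw.get("rarefaction_depth"),
        css_quantile=float(raw.get("css_quantile", 0.5)),
        n_null=int(raw.get("n_null", 999)),
        n_perm=int(raw.get("n_perm", 999)),
        weighted=bool(raw.get("weighted", True)),
        group_by=raw.get("group_by", "season"),
        ddr_subset=raw.get("ddr_subset"),
        seed=int(raw.get("seed", 0)),
    )
    return cfg, errors, warnings


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise ValidationError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all TSV outputs plus a JSON run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "version": __version__, "stages": {}}

    with _stage("read"):
        table = read_count_table(config.counts, config.counts_orientation)
        tree = read_tree(config.tree)
        tax = read_taxonomy(config.taxonomy)
        meta = read_metadata(config.metadata)

    with _stage("align"):
        bundle = align_inputs(table, tree, tax, meta)
        report["stages"]["align"] = {
            "n_taxa_dropped": bundle.n_taxa_dropped,
            "n_samples_dropped": bundle.n_samples_dropped,
        }

    with _stage("preprocess"):
        t1, rep_tax = filter_by_taxonomy(bundle.table, bundle.taxonomy)
        t2, rep_rare = filter_rare(t1, config.max_total)
        t3, rep_depth = filter_low_depth_samples(t2, config.min_reads)
        rarefied = rarefy(t3, config.rarefaction_depth, seed=config.seed)
        css, factors = css_normalize(t3, config.css_quantile)
        pd.concat(
            [rep_tax.as_frame(), rep_rare.as_frame(), rep_depth.as_frame()]
        ).to_csv(out / "filter_report.tsv", sep="\t", index=False)
        report["stages"]["preprocess"] = {
            "taxa_removed_taxonomy": rep_tax.n_taxa_removed,
            "taxa_removed_rare": rep_rare.n_taxa_removed,
            "samples_removed_depth": rep_depth.n_samples_removed,
            "rarefaction_depth": int(rarefied.sample_sums().iloc[0]),
        }
        meta_kept = bundle.metadata.loc[
            [s for s in rarefied.sample_ids if s in bundle.metadata.index]
        ]

    with _stage("diversity"):
        alpha = alpha_diversity(rarefied)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        bc = bray_curtis(rarefied)
        pd.DataFrame(bc.data, index=bc.ids, columns=bc.ids).to_csv(
            out / "bray_curtis.tsv", sep="\t", index_label="id"
        )
        ordination = pcoa(bc)
        scores = ordination.scores_frame()
        scores.to_csv(out / "pcoa_scores.tsv", sep="\t", index_label="sample_id")
        env_vars = [
            c
            for c in environment_columns(meta_kept)
            if c != "position_m" and meta_kept[c].nunique() > 1
        ]
        fits = envfit(ordination, meta_kept, env_vars, n_perm=config.n_perm, seed=config.seed)
        pd.DataFrame(
            [
                {
                    "variable": f.variable,
                    "axis1": f.direction[0],
                    "axis2": f.direction[1],
                    "r_squared": f.r_squared,
                    "p_value": f.p_value,
                }
                for f in fits
            ]
        ).to_csv(out / "envfit.tsv", sep="\t", index=False)
        perm_results = {}
        for factor in ("stream_type", "season", "year"):
            if meta_kept[factor].nunique() < 2:
                continue
            counts_per_level = meta_kept[factor].value_counts()
            if (counts_per_level < 2).any():
                continue
            r = permanova(bc, meta_kept[factor], n_perm=config.n_perm, seed=config.seed)
            perm_results[factor] = {
                "pseudo_F": r.pseudo_f,
                "r_squared": r.r_squared,
                "p_value": r.p_value,
            }
        pd.DataFrame(perm_results).T.to_csv(out / "permanova.tsv", sep="\t", index_label="factor")
        report["stages"]["diversity"] = {"permanova": perm_results}

    with _stage("assembly"):
        acfg = AssemblyConfig(
            n_null=config.n_null,
            seed=config.seed,
            weighted=config.weighted,
            group_by=config.group_by,
        )
        pairs, fractions = assembly_pipeline(rarefied, bundle.tree, meta_kept, acfg)
        pairs.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
        fractions.to_csv(out / "process_fractions.tsv", sep="\t")
        report["stages"]["assembly"] = {
            "n_pairs": len(pairs),
            "fractions": fractions.to_dict(orient="index"),
        }

    with _stage("biogeo"):
        fit_all, ddr_pairs = ddr(css, meta_kept, subset=None, subset_label="all")
        ddr_pairs.to_csv(out / "ddr_pairs.tsv", sep="\t", index=False)
        fits = [fit_all]
        if config.ddr_subset:
            subset = [s for s in config.ddr_subset if s in css.data.index]
            fit_sub, _ = ddr(css, meta_kept, subset=subset, subset_label="subset")
            fits.append(fit_sub)
        pd.DataFrame([dataclasses.asdict(f) for f in fits]).to_csv(
            out / "ddr_fit.tsv", sep="\t", index=False
        )
        rel = to_relative_abundance(rarefied)
        core_table = abundance_occupancy(rel, meta_kept)
        core_table.to_csv(out / "core_table.tsv", sep="\t")
        core_taxa = list(core_table.index[core_table["membership"] == "core"])
        coverage = core_coverage(rel, core_taxa, meta_kept)
        coverage.to_csv(out / "core_coverage.tsv", sep="\t", index_label="stream_type")
        venn = venn_partition(rel, meta_kept)
        pd.Series(venn, name="n_taxa").to_csv(out / "venn_regions.tsv", sep="\t", index_label="region")
        report["stages"]["biogeo"] = {
            "ddr_slope_all": fit_all.slope,
            "n_core_taxa": len(core_taxa),
            "core_coverage": coverage.to_dict(),
            "venn": venn,
        }

    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
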