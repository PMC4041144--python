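"""End-to-end orchestration: validated run configuration, staged execution,
and report files.

A run consumes a YAML configuration naming the input files (gapped FASTA
alignment, rooted newick tree, phenotype CSV), the outgroup, per-analysis
exclusion lists and thresholds, and writes TSV reports shaped like the
study's tables: model fits with flagged sites, the indel event map and
summary, per-species lengths, lineage omegas and the comparative
regressions. Exclusions are declarative configuration, never code, so every
report carries the exclusion list actually applied.

Two method substitutions relative to the classic toolchain are logged
prominently in every run: positively selected sites use naive empirical
Bayes (plug-in MLEs) rather than Bayes empirical Bayes, and per-branch
rates use the parsimony + Nei-Gojobori counting estimator rather than a
free-ratio maximum-likelihood fit.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codon_evolution import (
    LRT_DF,
    build_codon_alignment,
    branch_rates_counting,
    eb_sites,
    fits_to_table,
    lineage_omegas,
    lrt,
    m0_fit,
    nested_start,
    site_model_fit,
)
from .comparative_stats import run_comparative_suite
from .errors import ConfigError, PhyloindelError, PipelineDependencyError
from .indel_coding import check_frame, code_indels, find_gap_blocks, ungapped_lengths
from .indel_events import (
    annotated_newick,
    events_to_frame,
    map_all_events,
    summarize_events,
)
from .io_formats import (
    read_alignment,
    read_phenotypes,
    read_tree,
    species_consensus_alignment,
)
from .residue_stats import (
    content_shifts_on_tree,
    histidine_table,
    positive_site_histidine_overlap,
)

logger = logging.getLogger("phyloindel")

METHOD_NOTES = (
    "site identification: naive empirical Bayes (plug-in MLEs), not BEB; "
    "branch rates: ancestral-parsimony + Nei-Gojobori counting, not a "
    "free-ratio ML fit"
)

_KNOWN_KEYS = {
    "alignment", "tree", "phenotypes", "outgroup", "species_delimiter",
    "output_dir", "seed", "site_models", "frequencies", "n_beta_categories",
    "eb_threshold", "studentized_cutoff", "rtm_a", "rtm_b", "length_unit",
    "exclusions", "histidine_shift_threshold",
}


@dataclass
class RunConfig:
    alignment: str
    tree: str
    phenotypes: str
    outgroup: str
    output_dir: str = "phyloindel_run"
    species_delimiter: str = "|"
    seed: int = 0
    site_models: list[str] = field(
        default_factory=lambda: ["M1a", "M2a", "M7", "M8", "M8a"]
    )
    frequencies: str = "F3x4"
    n_beta_categories: int = 10
    eb_threshold: float = 0.95
    studentized_cutoff: float = 3.0
    rtm_a: float = 0.031
    rtm_b: float = 0.77
    length_unit: str = "aa"
    exclusions: dict[str, list[str]] = field(default_factory=dict)
    histidine_shift_threshold: float = 0.02


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    All problems are collected and reported together in a single
    :class:`ConfigError`; unknown keys only warn.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        logger.warning("unknown config keys ignored: %s", sorted(unknown))
        raw = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
    for key in ("alignment", "tree", "phenotypes", "outgroup"):
        if key not in raw:
            errors.append(f"missing required key: {key}")
    base = Path(path).parent
    for key in ("alignment", "tree", "phenotypes"):
        if key in raw:
            p = Path(raw[key])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                errors.append(f"{key} file not found: {p}")
            raw[key] = str(p)
    if "eb_threshold" in raw and not (0 < float(raw["eb_threshold"]) <= 1):
        errors.append("eb_threshold must be in (0, 1]")
    if "length_unit" in raw and raw["length_unit"] not in ("aa", "nt"):
        errors.append("length_unit must be 'aa' or 'nt'")
    if errors:
        raise ConfigError(errors)
    return RunConfig(**raw)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write reports; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("method substitutions in effect: %s", METHOD_NOTES)

    def stage(name):
        logger.info("stage: %s", name)

    results: dict[str, object] = {}
    try:
        stage("io")
        tree = read_tree(config.tree, outgroup=config.outgroup)
        raw_aln = read_alignment(
            config.alignment,
            outgroup=config.outgroup,
            species_delimiter=config.species_delimiter,
        )
        aln, poly_reports = species_consensus_alignment(raw_aln)
        phenotypes = read_phenotypes(config.phenotypes, tree=tree)
        indel_poly = {
            sp: rep.indel_columns
            for sp, rep in poly_reports.items()
            if rep.indel_columns
        }
        if indel_poly:
            logger.warning("indel polymorphism within species: %s", indel_poly)

        stage("indel_coding")
        blocks = find_gap_blocks(aln)
        matrix = code_indels(blocks, aln)
        frame = check_frame(blocks)
        lengths = ungapped_lengths(aln)
        frame.to_frame().to_csv(out / "frame_report.tsv", sep="\t", index=False)
        lengths.data.to_csv(out / "lengths.tsv", sep="\t", index=False)
        (out / "indel_characters.nex").write_text(matrix.to_nexus())
        matrix.to_frame().to_csv(out / "indel_characters.tsv", sep="\t")

        stage("indel_events")
        events, skipped = map_all_events(matrix, tree)
        summary = summarize_events(events, tree)
        events_to_frame(events).to_csv(out / "events.tsv", sep="\t", index=False)
        (out / "event_map.nwk").write_text(annotated_newick(tree, events) + "\n")

        stage("codon_evolution")
        caln = build_codon_alignment(aln)
        m0 = m0_fit(caln, tree, frequencies=config.frequencies)
        fits = {"M0": m0}
        for model in config.site_models:
            extra = []
            for (null_m, alt_m) in LRT_DF:
                if alt_m == model and null_m in fits:
                    extra.append(nested_start(fits[null_m], model))
            fits[model] = site_model_fit(
                caln, tree, model, m0=m0,
                frequencies=config.frequencies,
                n_beta_categories=config.n_beta_categories,
                extra_starts=extra, seed=config.seed,
            )
        lrts = {}
        for (null_m, alt_m), df in LRT_DF.items():
            if null_m in fits and alt_m in fits:
                lrts[f"{null_m}_vs_{alt_m}"] = lrt(fits[null_m], fits[alt_m], df)
        fits_to_table(list(fits.values())).to_csv(
            out / "model_fits.tsv", sep="\t", index=False
        )
        sites = None
        for alt in ("M2a", "M8"):
            if alt in fits and fits[alt].positive_class_index is not None:
                sites = eb_sites(fits[alt], config.eb_threshold)
                sites.to_frame().to_csv(
                    out / f"selected_sites_{alt}.tsv", sep="\t", index=False
                )
        rates = branch_rates_counting(caln, tree)
        rates.data.to_csv(out / "branch_rates.tsv", sep="\t")
        omegas = lineage_omegas(rates, tree)
        omegas.to_csv(out / "lineage_omega.tsv", sep="\t", index=False)

        stage("residue_stats")
        proteins = {t: caln.protein(t) for t in tree.ingroup_tip_labels()}
        hist = histidine_table(proteins)
        hist.to_csv(out / "histidines.tsv", sep="\t", index=False)
        ingroup = tree.prune_to(tree.ingroup_tip_labels())
        shifts = content_shifts_on_tree(
            hist, ingroup, threshold=config.histidine_shift_threshold
        )
        shifts.data.to_csv(out / "histidine_shifts.tsv", sep="\t", index=False)
        overlap = (0.0, 0, 0)
        if sites is not None:
            overlap = positive_site_histidine_overlap(sites, caln)

        stage("comparative_stats")
        suite = run_comparative_suite(
            lengths.data, omegas, hist, phenotypes, tree,
            config={
                "rtm_a": config.rtm_a,
                "rtm_b": config.rtm_b,
                "length_unit": config.length_unit,
                "exclusions": config.exclusions,
            },
        )
        suite["table2"].to_csv(out / "table2.tsv", sep="\t", index=False)
        suite["table3"].to_csv(out / "table3.tsv", sep="\t", index=False)
        suite["histidine"].to_csv(out / "histidine_pgls.tsv", sep="\t", index=False)

        results = {
            "version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "method_notes": METHOD_NOTES,
            "n_columns": aln.n_columns,
            "n_codons": caln.n_codons,
            "frame_pass": frame.passed,
            "skipped_characters": skipped,
            "event_summary": {
                "total": summary.total_events,
                "unique": summary.unique_events,
                "homoplasious": summary.homoplasious_events,
                "terminal": summary.terminal_events,
                "internal": summary.internal_events,
                "insertions": summary.insertions,
                "deletions": summary.deletions,
                "unresolved": summary.unresolved,
            },
            "lrts": {
                k: {"statistic": v.statistic, "df": v.df, "p": v.p_value}
                for k, v in lrts.items()
            },
            "positive_site_histidine_overlap": {
                "fraction": overlap[0], "hits": overlap[1], "flagged": overlap[2],
            },
            "exclusions": config.exclusions,
        }
    except PhyloindelError:
        raise
    except Exception as exc:  # annotate unexpected failures with context
        raise PipelineDependencyError(f"pipeline failed: {exc}") from exc
    (out / "run_log.json").write_text(json.dumps(results, indent=1, default=str))
    return out
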