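"""End-to-end comparative analysis: from trait table (+ optional tree) to a
structured report.

The report mirrors the standard layout of a Rensch's-rule study:
dimorphism classification, normality checks of the indices, Model I/II
allometry of male on female log size in species space (all species and
the female-biased subset), and — when a tree is given — the same
quantities in contrast space with through-origin statistics, plus
standardization and residual diagnostics.  Every number in the report is
produced by exactly one upstream call; the reporter only collects.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from ._errors import DegenerateInputError, InsufficientDataError, RenschError
from .allometry import fit_ols, fit_rma, test_isometry
from .indices import DEFAULT_SSD_VARIANT, FEMALE_BIASED, classify_table
from .phylo import (
    METHODS,
    PhyloTree,
    compute_contrasts,
    prune_and_align,
    standardization_check,
)
from .stattests import ks_normality, pearson, residual_diagnostics
from .table_io import TraitTable, aggregate_populations

logger = logging.getLogger(__name__)

MIN_REGRESSION_N = 3


@dataclass
class AnalysisOptions:
    """Pipeline switches; every CLI flag has a counterpart here."""

    ssd_variant: str = DEFAULT_SSD_VARIANT
    tie_tolerance: float = 0.0
    swap_axes: bool = False  # regress female on male instead
    standardize_contrasts: bool = True
    contrast_methods: tuple[str, ...] = METHODS
    aggregate_weighting: str = "by_sample_size"


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _axes(table: TraitTable, swap: bool) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) = (log female, log male) size, or swapped."""
    lf = np.log10([r.female_size for r in table])
    lm = np.log10([r.male_size for r in table])
    return (lm, lf) if swap else (lf, lm)


def _regression_cell(x: np.ndarray, y: np.ndarray, through_origin: bool) -> dict:
    out: dict[str, Any] = {}
    for name, fitter in (("OLS", fit_ols), ("RMA", fit_rma)):
        try:
            fit = fitter(x, y, through_origin=through_origin)
        except (DegenerateInputError, InsufficientDataError) as exc:
            out[name] = {"skipped": str(exc)}
            continue
        verdict = test_isometry(fit)
        out[name] = {
            "fit": fit,
            "isometric": verdict.isometric,
            "direction_if_rejected": verdict.direction_if_rejected,
        }
    return out


def run_full_analysis(
    table: TraitTable,
    tree: PhyloTree | None = None,
    options: AnalysisOptions | None = None,
    input_checksums: dict[str, str] | None = None,
) -> dict:
    """Execute the full analysis and return a JSON-serializable report.

    Sections requiring missing inputs (no tree → contrast space; no ages
    → SAD analyses) are marked skipped rather than failing.  Per-species
    validation problems are collected under ``classification.errors``.
    """
    opts = options or AnalysisOptions()
    report: dict[str, Any] = {
        "software": {"package": "renschrule", "version": __version__},
        "options": _to_jsonable(opts),
        "input_checksums": input_checksums or {},
    }

    table = aggregate_populations(table, weighting=opts.aggregate_weighting)
    report["n_species"] = len(table)

    # --- indices and classification -------------------------------------
    cls = classify_table(table, variant=opts.ssd_variant, tie_tolerance=opts.tie_tolerance)
    ssd = np.array([r.ssd for r in cls.records])
    sad_records = [r for r in cls.records if r.sad is not None]
    sad = np.array([r.sad for r in sad_records])
    report["classification"] = {
        "counts": cls.counts,
        "records": cls.records,
        "errors": cls.errors,
    }

    # --- normality of the indices ----------------------------------------
    ks_section: dict[str, Any] = {}
    try:
        ks_section["ssd"] = ks_normality(ssd)
    except (RenschError, ValueError) as exc:
        ks_section["ssd"] = {"skipped": str(exc)}
    if sad.size >= 5:
        ks_section["sad"] = ks_normality(sad)
    else:
        ks_section["sad"] = {"skipped": "fewer than 5 species with both ages"}
    report["ks"] = ks_section

    # --- species-space allometry -----------------------------------------
    species_space: dict[str, Any] = {}
    subsets = {
        "all": table,
        "female_biased": table.subset(
            r.species for r in cls.records if r.direction == FEMALE_BIASED
        ),
    }
    for label, sub in subsets.items():
        if len(sub) < MIN_REGRESSION_N:
            species_space[label] = {
                "skipped": f"only {len(sub)} species; regression needs "
                f">= {MIN_REGRESSION_N}"
            }
            continue
        x, y = _axes(sub, opts.swap_axes)
        species_space[label] = {"n": len(sub)} | _regression_cell(x, y, False)
    report["species_means"] = species_space

    # --- SSD ~ SAD across species ----------------------------------------
    if len(sad_records) >= MIN_REGRESSION_N:
        ssd_for_sad = np.array([r.ssd for r in sad_records])
        report["ssd_sad_correlation"] = pearson(ssd_for_sad, sad)
    else:
        report["ssd_sad_correlation"] = {"skipped": "insufficient species with ages"}

    # --- contrast space ----------------------------------------------------
    if tree is None:
        report["contrasts"] = {"skipped": "no tree supplied"}
        return _to_jsonable(report)

    tree_p, table_p = prune_and_align(tree, table)
    cls_p = classify_table(table_p, variant=opts.ssd_variant, tie_tolerance=opts.tie_tolerance)
    by_species = {r.species: r for r in cls_p.records}
    x_map, y_map = {}, {}
    for rec in table_p:
        lf, lm = np.log10(rec.female_size), np.log10(rec.male_size)
        x_map[rec.species] = lm if opts.swap_axes else lf
        y_map[rec.species] = lf if opts.swap_axes else lm

    contrast_report: dict[str, Any] = {"n_tips": len(table_p)}
    for method in opts.contrast_methods:
        sec: dict[str, Any] = {}
        cs_size = compute_contrasts(
            tree_p, x_map, y_map, method=method,
            standardize=opts.standardize_contrasts,
        )
        sec["n_contrasts"] = len(cs_size)
        sec["allometry"] = _regression_cell(cs_size.x, cs_size.y, True)
        if opts.standardize_contrasts:
            sec["standardization_check_size"] = standardization_check(cs_size)

        aged = [r.species for r in table_p if r.has_ages]
        if len(aged) >= MIN_REGRESSION_N + 1:
            if len(aged) < len(table_p):
                tree_a, _ = prune_and_align(tree_p, table_p.subset(aged))
            else:
                tree_a = tree_p
            ssd_map = {s: by_species[s].ssd for s in aged}
            sad_map = {s: by_species[s].sad for s in aged}
            cs_idx = compute_contrasts(
                tree_a, sad_map, ssd_map, method=method,
                standardize=opts.standardize_contrasts,
            )
            sec["ssd_sad_through_origin"] = pearson(
                cs_idx.y, cs_idx.x, through_origin=True
            )
            sec["ks_ssd_contrasts"] = _maybe_ks(cs_idx.y)
            sec["ks_sad_contrasts"] = _maybe_ks(cs_idx.x)
            try:
                fit0 = fit_ols(cs_idx.x, cs_idx.y, through_origin=True)
                sec["residual_diagnostics"] = residual_diagnostics(
                    fit0, cs_idx.x, cs_idx.y
                )
            except (RenschError, ValueError) as exc:
                sec["residual_diagnostics"] = {"skipped": str(exc)}
        else:
            sec["ssd_sad_through_origin"] = {
                "skipped": "too few species with ages; SAD contrasts unavailable"
            }
        contrast_report[method] = sec
    report["contrasts"] = contrast_report
    return _to_jsonable(report)


def _maybe_ks(values: np.ndarray) -> Any:
    try:
        return ks_normality(values)
    except (RenschError, ValueError) as exc:
        return {"skipped": str(exc)}


def report_to_json(report: dict, indent: int = 2) -> str:
    return json.dumps(report, indent=indent, sort_keys=True)


def report_to_text(report: dict) -> str:
    """Human-readable digest of the main report quantities."""
    lines: list[str] = []
    add = lines.append
    add(f"renschrule {report['software']['version']} — Rensch's rule analysis")
    add(f"species analysed: {report['n_species']}")
    counts = report["classification"]["counts"]
    add(
        "classification: "
        + ", ".join(f"{k.replace('_', '-')} {v}" for k, v in counts.items())
    )
    for label, cell in report["species_means"].items():
        if "skipped" in cell:
            add(f"[species means, {label}] skipped: {cell['skipped']}")
            continue
        for model in ("OLS", "RMA"):
            entry = cell[model]
            if "skipped" in entry:
                add(f"[species means, {label}] {model} skipped: {entry['skipped']}")
                continue
            fit = entry["fit"]
            lo, hi = fit["ci95"]
            verdict = "isometric" if entry["isometric"] else entry["direction_if_rejected"]
            add(
                f"[species means, {label}] {model}: slope {fit['slope']:.3f} "
                f"± {fit['slope_se']:.3f} (95% CI {lo:.3f}–{hi:.3f}, "
                f"R² {fit['r2']:.3f}, n {fit['n']}) → {verdict}"
            )
    corr = report.get("ssd_sad_correlation", {})
    if "skipped" not in corr:
        add(
            f"SSD~SAD (species): r = {corr['statistic']:.3f}, "
            f"p = {corr['p_value']:.4g}, n = {corr['n']}"
        )
    contrasts = report.get("contrasts", {})
    if "skipped" in contrasts:
        add(f"contrast space skipped: {contrasts['skipped']}")
        return "\n".join(lines)
    for method in METHODS:
        sec = contrasts.get(method)
        if not sec:
            continue
        for model in ("OLS", "RMA"):
            entry = sec["allometry"][model]
            if "skipped" in entry:
                continue
            fit = entry["fit"]
            verdict = "isometric" if entry["isometric"] else entry["direction_if_rejected"]
            add(
                f"[contrasts, {method}] {model} through origin: slope "
                f"{fit['slope']:.3f} ± {fit['slope_se']:.3f} → {verdict}"
            )
        corr = sec.get("ssd_sad_through_origin", {})
        if "skipped" not in corr:
            add(
                f"[contrasts, {method}] SSD~SAD through origin: "
                f"r = {corr['statistic']:.3f}, p = {corr['p_value']:.4g}, "
                f"n = {corr['n']}"
            )
    return "\n".join(lines)
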