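"""End-to-end study driver: descriptives, index comparisons, selection, CV.

Reproduces the shape of a full index-abbreviation study on any item matrix:
survey-weighted descriptives per stratum, cross-tabulations of candidate
indices against the full-item reference, greedy selection (pure-empirical and
enriched by a locked core set), cross-validated kappa curves, item lists with
selection order, and sensitivity analyses (tertiles/deciles, facility-type
subgroups). All outputs are plain CSV/JSON and byte-stable for a fixed
config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    classify_quantiles,
    cohen_kappa,
    confusion_matrix,
    crosstab_frame,
    percent_agreement,
)
from .core import (
    DomainMap,
    IndexDefinition,
    ItemMatrix,
    compute_index,
    weighted_mean,
    weighted_sd,
)
from .crossval import cv_kappa_curve
from .io import read_domain_config, read_item_matrix
from .selection import backward_select, index_at, selection_order_report

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of one study run.

    ``m_list`` are the candidate index lengths reported in full-sample
    cross-tabs (lengths include locked items). Enriched comparisons are made
    for the lengths strictly greater than the locked set.
    """

    outdir: str
    q: int = 5
    k: int = 10
    seed: int = 7
    m_list: tuple = (10, 20)
    directions: tuple = ("backward", "forward")
    tertiles: bool = True
    deciles: bool = True
    by_facility_type: bool = True
    matrix_path: str | None = None
    domain_config_path: str | None = None
    locked_set: str | None = None       # item-set name in the domain config

    def __post_init__(self):
        if self.q < 2:
            raise ValueError("q must be at least 2")
        bad = [d for d in self.directions if d not in ("backward", "forward")]
        if bad:
            raise ValueError(f"unknown directions: {bad}")

    def analysis_params(self) -> dict:
        """The configuration fields that determine the results (not where
        they are written)."""
        params = asdict(self)
        params.pop("outdir")
        return params

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.analysis_params(), sort_keys=True,
                       default=str).encode()
        ).hexdigest()[:16]


def _load_inputs(config, matrix, domain_map, locked):
    if matrix is None:
        if config.matrix_path is None or config.domain_config_path is None:
            raise ValueError(
                "pass matrix/domain_map/locked or set paths in the config"
            )
        matrix = read_item_matrix(config.matrix_path)
        domain_map, sets = read_domain_config(config.domain_config_path)
        if locked is None:
            if config.locked_set is not None:
                locked = tuple(sets[config.locked_set].item_ids)
            else:
                locked = ()
    return matrix, domain_map, tuple(locked or ())


def _write_csv(df: pd.DataFrame, path: Path, index=False):
    df.to_csv(path, index=index, float_format="%.10g")


def _comparison(reference, cand_cls, name, m):
    cm = confusion_matrix(reference, cand_cls)
    return cm, {
        "comparison": name,
        "M": m,
        "q": reference.q,
        "kappa": cohen_kappa(cm),
        "percent_agreement": percent_agreement(cm),
    }


def run_study(
    config: StudyConfig,
    matrix: ItemMatrix | None = None,
    domain_map: DomainMap | None = None,
    locked=None,
) -> dict:
    """Run the whole study and write the report bundle to ``config.outdir``.

    Returns a dict with the in-memory report objects: ``descriptives``,
    ``agreement_summary``, ``crosstabs``, ``cv_curves``,
    ``selection_orders``, ``sensitivity`` and ``manifest``.
    """
    matrix, domain_map, locked = _load_inputs(config, matrix, domain_map, locked)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    q = config.q
    p = matrix.n_items

    logger.info("scoring full index (%d items, %d facilities)", p,
                matrix.n_facilities)
    full_def = IndexDefinition(matrix.item_ids, domain_map)
    full_scores = compute_index(matrix, full_def)
    reference = classify_quantiles(full_scores, q)

    locked_def = IndexDefinition(locked, domain_map) if locked else None
    locked_scores = compute_index(matrix, locked_def) if locked else None

    # --- 1. survey-weighted descriptives per stratum -----------------------
    rows = []
    strata = list(dict.fromkeys(matrix.country.tolist()))
    for stratum in strata + ["(all)"]:
        sub = (
            matrix
            if stratum == "(all)"
            else matrix.subset_facilities(matrix.country == stratum)
        )
        row = {"country": stratum, "n": sub.n_facilities}
        sub_full = compute_index(sub, full_def)
        row["full_index_mean"] = weighted_mean(sub_full, sub)
        row["full_index_sd"] = weighted_sd(sub_full, sub)
        if locked_def is not None:
            sub_locked = compute_index(sub, locked_def)
            row["locked_index_mean"] = weighted_mean(sub_locked, sub)
            row["locked_index_sd"] = weighted_sd(sub_locked, sub)
        rows.append(row)
    descriptives = pd.DataFrame(rows)
    _write_csv(descriptives, outdir / "descriptives.csv")

    # --- 2. full-sample selection paths ------------------------------------
    logger.info("backward selection on the full sample (pure empirical)")
    trace_pure = backward_select(matrix, domain_map, reference, (), 1)
    traces = {"empirical": trace_pure}
    if locked:
        logger.info("backward selection on the full sample (enriched)")
        traces["enriched"] = backward_select(
            matrix, domain_map, reference, locked, len(locked)
        )
    selection_orders = {}
    for mode, trace in traces.items():
        report = selection_order_report(trace)
        selection_orders[mode] = report
        _write_csv(report, outdir / f"selection_order_{mode}.csv")

    # --- 3. cross-tabs of candidate indices vs the full reference ----------
    summary_rows = []
    crosstabs = {}

    def add_comparison(name, m, cand_cls, ref=reference):
        cm, row = _comparison(ref, cand_cls, name, m)
        summary_rows.append(row)
        frame = crosstab_frame(cm)
        crosstabs[name] = frame
        _write_csv(frame, outdir / f"crosstab_{name}.csv", index=True)
        logger.info("%s: kappa=%.3f agreement=%.1f%%", name, row["kappa"],
                    row["percent_agreement"])

    if locked:
        add_comparison(
            "locked_vs_full", len(locked), classify_quantiles(locked_scores, q)
        )
    for m in config.m_list:
        defn = index_at(trace_pure, m)
        cls = classify_quantiles(compute_index(matrix, defn), q)
        add_comparison(f"empirical_{m}_vs_full", m, cls)
    enriched_cls_last = None
    if locked:
        for m in [m for m in config.m_list if m > len(locked)]:
            defn = index_at(traces["enriched"], m)
            cls = classify_quantiles(compute_index(matrix, defn), q)
            add_comparison(f"enriched_{m}_vs_full", m, cls)
            enriched_cls_last = (m, cls)
        if enriched_cls_last is not None:
            m, cls = enriched_cls_last
            cm, row = _comparison(
                classify_quantiles(locked_scores, q), cls,
                f"enriched_{m}_vs_locked", m,
            )
            summary_rows.append(row)
            frame = crosstab_frame(cm)
            crosstabs[row["comparison"]] = frame
            _write_csv(frame, outdir / f"crosstab_{row['comparison']}.csv",
                       index=True)

    # --- 4. cross-validated kappa curves ------------------------------------
    curve_frames = []
    modes = [("pure", ())] + ([("enriched", locked)] if locked else [])
    for mode, locked_set in modes:
        for direction in config.directions:
            logger.info("CV curve: mode=%s direction=%s k=%d", mode,
                        direction, config.k)
            curve = cv_kappa_curve(
                matrix, domain_map, k=config.k, seed=config.seed,
                locked=locked_set, direction=direction, q=q,
            )
            frame = curve.to_frame()
            frame.insert(2, "mode", mode)
            curve_frames.append(frame)
    cv_curves = pd.concat(curve_frames, ignore_index=True)
    _write_csv(cv_curves, outdir / "cv_curves.csv")

    # --- 5. sensitivity analyses --------------------------------------------
    sens_rows = []
    m_top = max(config.m_list)
    for q_alt, enabled in ((3, config.tertiles), (10, config.deciles)):
        if not enabled or q_alt > matrix.n_facilities:
            continue
        ref_alt = classify_quantiles(full_scores, q_alt)
        defn = index_at(trace_pure, m_top)
        cls = classify_quantiles(compute_index(matrix, defn), q_alt)
        cm, row = _comparison(ref_alt, cls, f"empirical_{m_top}_vs_full", m_top)
        row["subset"] = f"all (q={q_alt})"
        sens_rows.append(row)
    if config.by_facility_type:
        for ftype in dict.fromkeys(matrix.facility_type.tolist()):
            sub = matrix.subset_facilities(matrix.facility_type == ftype)
            if sub.n_facilities < q:
                continue
            # the reference is re-derived within the subgroup
            sub_ref = classify_quantiles(compute_index(sub, full_def), q)
            sub_trace = backward_select(sub, domain_map, sub_ref, (), m_top)
            defn = index_at(sub_trace, m_top)
            cls = classify_quantiles(compute_index(sub, defn), q)
            cm, row = _comparison(sub_ref, cls, f"empirical_{m_top}_vs_full",
                                  m_top)
            row["subset"] = ftype
            sens_rows.append(row)
            if locked:
                cls = classify_quantiles(compute_index(sub, locked_def), q)
                cm, row = _comparison(sub_ref, cls, "locked_vs_full",
                                      len(locked))
                row["subset"] = ftype
                sens_rows.append(row)
    sensitivity = pd.DataFrame(sens_rows)
    _write_csv(sensitivity, outdir / "sensitivity.csv")

    agreement_summary = pd.DataFrame(summary_rows)
    _write_csv(agreement_summary, outdir / "agreement_summary.csv")

    # --- 6. manifest ---------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config": config.analysis_params(),
        "config_digest": config.digest(),
        "n_facilities": int(matrix.n_facilities),
        "n_items": int(p),
        "locked_items": list(locked),
        "report_files": sorted(f.name for f in outdir.iterdir()
                               if f.suffix in (".csv",)),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )

    return {
        "descriptives": descriptives,
        "agreement_summary": agreement_summary,
        "crosstabs": crosstabs,
        "cv_curves": cv_curves,
        "selection_orders": selection_orders,
        "sensitivity": sensitivity,
        "manifest": manifest,
    }
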