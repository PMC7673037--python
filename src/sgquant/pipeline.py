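"""End-to-end orchestration: segmentation -> puncta -> SG calling -> tables.

``quantify_field`` processes one in-memory field; ``run_quantification`` maps
it over a field list, writes per-object CSVs and a run manifest, and is fully
deterministic (identical config and inputs give byte-identical outputs).
``run_screen`` scores plate CSVs and writes the ranked hit report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import Field, FieldInput, PipelineConfig, read_field
from .puncta import channel_background, detect_puncta
from .screen import call_hits, compute_zscores, counter_screen_filter
from .segmentation import (
    cytoplasm_mask,
    detect_nuclei,
    filter_nuclei_to_cells,
    propagate_cells,
)
from .sg_calling import call_stress_granules, match_puncta, per_cell_sg_counts

log = logging.getLogger(__name__)

__all__ = ["FieldResult", "quantify_field", "run_quantification", "run_screen"]


@dataclass
class FieldResult:
    """Per-field outputs: label maps, per-object tables, stage counts."""

    field_id: str
    nuclei: np.ndarray
    cells: np.ndarray
    cytoplasm: np.ndarray
    puncta_m1: list
    puncta_m2: list
    stress_granules: list
    cell_table: pd.DataFrame
    counts: dict[str, int]


def quantify_field(fld: Field, config: PipelineConfig) -> FieldResult:
    """Run the full quantification on one field."""
    seg, pp, sgp = config.segmentation, config.puncta, config.sg_calling
    nuclei = detect_nuclei(fld.channels["nuclei"], seg)
    cells = propagate_cells(nuclei, fld.channels["membrane"], seg)
    nuclei_kept = filter_nuclei_to_cells(nuclei, cells)
    cyto = cytoplasm_mask(cells, nuclei_kept)

    p1 = detect_puncta(fld.channels["marker1"], cyto, pp, channel="marker1")
    p2 = detect_puncta(fld.channels["marker2"], cyto, pp, channel="marker2")
    bg1 = channel_background(fld.channels["marker1"], cyto, p1)
    bg2 = channel_background(fld.channels["marker2"], cyto, p2)
    match = match_puncta(p1, p2, sgp)
    sgs = call_stress_granules(
        match.pairs, fld.channels["marker1"], fld.channels["marker2"], bg1, bg2, sgp
    )
    cell_table = per_cell_sg_counts(sgs, cells)
    cell_table.insert(0, "field", fld.field_id)

    counts = {
        "nuclei": int(nuclei.max()),
        "cells": int(len(np.unique(cells)) - (1 if (cells == 0).any() else 0)),
        "puncta_marker1": len(p1),
        "puncta_marker2": len(p2),
        "matched_pairs": len(match.pairs),
        "stress_granules": len(sgs),
    }
    log.info("field %s: %s", fld.field_id, counts)
    return FieldResult(
        field_id=fld.field_id,
        nuclei=nuclei_kept,
        cells=cells,
        cytoplasm=cyto,
        puncta_m1=p1,
        puncta_m2=p2,
        stress_granules=sgs,
        cell_table=cell_table,
        counts=counts,
    )


def _puncta_frame(result: FieldResult) -> pd.DataFrame:
    rows = []
    for p in result.puncta_m1 + result.puncta_m2:
        rows.append(
            (
                result.field_id,
                p.channel,
                p.punctum_id,
                p.cell_label,
                p.centroid[0],
                p.centroid[1],
                p.area,
                p.mean_intensity,
                p.integrated_intensity,
                p.peak_intensity,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "field",
            "channel",
            "punctum_id",
            "cell_label",
            "centroid_row",
            "centroid_col",
            "area",
            "mean_intensity",
            "integrated_intensity",
            "peak_intensity",
        ],
    )


def _sg_frame(result: FieldResult) -> pd.DataFrame:
    rows = [
        (
            result.field_id,
            sg.sg_id,
            sg.cell_label,
            sg.correlation,
            sg.centroid[0],
            sg.centroid[1],
            sg.integrated_intensity,
        )
        for sg in result.stress_granules
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "field",
            "sg_id",
            "cell_label",
            "r",
            "centroid_row",
            "centroid_col",
            "integrated_intensity",
        ],
    )


def run_quantification(
    config: PipelineConfig,
    fields: list[FieldInput] | list[tuple[Field, str, str]],
    outdir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Quantify a list of fields and write the per-object CSV tables.

    ``fields`` may be :class:`FieldInput` pointers (TIFFs on disk) or
    ``(Field, condition, replicate)`` tuples for in-memory use.  Writes
    ``cells.csv``, ``puncta.csv``, ``stress_granules.csv`` and
    ``manifest.json`` under ``outdir`` (defaults to ``config.outdir``).
    Any stage failure aborts with the stage and field named.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cell_tables, puncta_tables, sg_tables = [], [], []
    per_field_counts = {}
    for entry in fields:
        if isinstance(entry, FieldInput):
            fld = read_field(entry.channel_paths, field_id=entry.field_id)
            condition, replicate = entry.condition, entry.replicate
        else:
            fld, condition, replicate = entry
        try:
            result = quantify_field(fld, config)
        except Exception as exc:  # re-raise with field context
            raise RuntimeError(f"quantification failed on field {fld.field_id!r}: {exc}") from exc
        ct = result.cell_table.copy()
        ct.insert(1, "condition", condition)
        ct.insert(2, "replicate", replicate)
        cell_tables.append(ct)
        pt = _puncta_frame(result)
        pt.insert(1, "condition", condition)
        puncta_tables.append(pt)
        st = _sg_frame(result)
        st.insert(1, "condition", condition)
        sg_tables.append(st)
        per_field_counts[fld.field_id] = result.counts

    tables = {
        "cells": pd.concat(cell_tables, ignore_index=True) if cell_tables else pd.DataFrame(),
        "puncta": pd.concat(puncta_tables, ignore_index=True) if puncta_tables else pd.DataFrame(),
        "stress_granules": pd.concat(sg_tables, ignore_index=True) if sg_tables else pd.DataFrame(),
    }
    tables["cells"].to_csv(outdir / "cells.csv", index=False)
    tables["puncta"].to_csv(outdir / "puncta.csv", index=False)
    tables["stress_granules"].to_csv(outdir / "stress_granules.csv", index=False)

    manifest = {
        "tool": "sgquant",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_fields": len(per_field_counts),
        "per_field_counts": per_field_counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return tables


def run_screen(
    config: PipelineConfig,
    hypoxia_plate: pd.DataFrame,
    normoxia_plate: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Score a screen: z-scores, ranked hits, optional counter-screen filter.

    Writes ``zscores.csv``, ``hits.csv`` (final candidates), ``excluded.csv``
    when a normoxia arm is given, and a human-readable ``screen_report.txt``.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scored = compute_zscores(hypoxia_plate, ddof=config.control_sd_ddof)
    hits = call_hits(scored, config.hit_threshold_sd, config.two_sided_hits)
    excluded = pd.DataFrame(columns=hits.columns)
    final = hits
    norm_scored = None
    if normoxia_plate is not None:
        norm_scored = compute_zscores(normoxia_plate, ddof=config.control_sd_ddof)
        final, excluded = counter_screen_filter(
            hits, norm_scored, config.hit_threshold_sd, config.two_sided_hits
        )

    scored.ranked_drugs().to_csv(outdir / "zscores.csv", index=False)
    final.to_csv(outdir / "hits.csv", index=False)
    excluded.to_csv(outdir / "excluded.csv", index=False)

    n_drugs = int((scored.wells["kind"] == "drug").sum())
    lines = [
        "sgquant screen report",
        f"drug wells scored: {n_drugs}",
        f"control mean granules/cell: {scored.control_mean:.4f} (SD {scored.control_sd:.4f})",
        f"hit threshold: z >= {config.hit_threshold_sd:g}"
        + (" (two-sided)" if config.two_sided_hits else " (one-sided)"),
        f"hits before counter-screen: {len(hits)}",
        f"excluded by normoxia counter-screen: {len(excluded)}",
        f"final candidates: {len(final)}",
    ]
    if "is_true_hit" in final.columns and final["is_true_hit"].notna().all():
        truth = hypoxia_plate[(hypoxia_plate["kind"] == "drug") & hypoxia_plate["is_true_hit"]]
        if len(truth):
            sens = final["is_true_hit"].sum() / len(truth)
            lines.append(f"sensitivity vs planted truth: {sens:.3f} ({int(final['is_true_hit'].sum())}/{len(truth)})")
    (outdir / "screen_report.txt").write_text("\n".join(lines) + "\n")
    return {
        "scored": scored,
        "normoxia_scored": norm_scored,
        "hits": hits,
        "final": final,
        "excluded": excluded,
    }
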