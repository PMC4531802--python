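"""Simulation-based validation routines.

These run the full pipeline (simulate, analyze, call, summarize) against
the simulator's exact ground truth, in memory, and report recovery
metrics: per-channel spot-detection accuracy, event-rate estimates versus
the realized geometrically detectable rates, and titration series. They
back both the test suite and the reproduction script.

Note on "detectable": a distance-thresholded caller measures realized
probe geometry, not the latent allele state — an allele whose probes
happen to separate by less than the threshold is invisible to any
distance-based method (the false-negative regime of break-apart assays).
Recovery is therefore scored against the realized thresholded geometry
recorded in the ground truth, with the latent-state rates reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import events as ev
from . import imaging as im
from . import simulate as sim
from .config import (
    CellModel,
    ImagingConfig,
    NoiseSpec,
    RenderParams,
    SegmentationParams,
    SpotParams,
    Thresholds,
)

__all__ = [
    "detection_accuracy",
    "ConditionRecovery",
    "recover_condition",
    "titration_series",
]


def _analyze_fields(
    cell_model,
    n_cells: int,
    seed: int,
    imaging: ImagingConfig,
    noise: NoiseSpec,
    render: RenderParams,
    seg: SegmentationParams | None,
    spot: SpotParams | None,
    cells_per_field: int,
    field_offset: int = 0,
):
    """Simulate and analyze enough fields to cover ``n_cells`` cells."""
    gts, recss = [], []
    remaining, fidx = n_cells, field_offset
    while remaining > 0:
        n = min(cells_per_field, remaining)
        stacks, gt = sim.simulate_field(
            cell_model, n, imaging, noise, seed=seed, render=render,
            field_index=fidx, field_id=f"f{fidx:04d}",
        )
        recs = im.analyze_field(
            im.FieldImage(f"f{fidx:04d}", stacks, imaging), seg, spot)
        gts.append(gt)
        recss.extend(recs)
        remaining -= n
        fidx += 1
    return sim.GroundTruth.concat(gts), recss, fidx


def detection_accuracy(
    cell_model: CellModel | None = None,
    n_nuclei: int = 1000,
    seed: int = 0,
    noise: NoiseSpec | None = None,
    imaging: ImagingConfig | None = None,
    cells_per_field: int = 30,
    match_radius_px: float = 2.0,
) -> dict[str, float]:
    """Per-channel spot-detection accuracy against simulator ground truth.

    Simulates ``n_nuclei`` cells, runs the full image-analysis stage, and
    scores the fraction of ground-truth spots matched by a detection within
    ``match_radius_px`` in the parent nucleus. Returns
    ``{channel: percent correctly detected}`` plus ``"n_spots"``.
    """
    cell_model = cell_model or CellModel(name="benchmark")
    imaging = imaging or ImagingConfig()
    noise = noise if noise is not None else NoiseSpec()
    gt, recs, _ = _analyze_fields(
        cell_model, n_nuclei, seed, imaging, noise, RenderParams(),
        None, None, cells_per_field)

    ok = [r for r in recs if not r.excluded]
    cent = np.array([r.centroid for r in ok]) if ok else np.empty((0, 2))
    tree = cKDTree(cent) if len(cent) else None
    matched = {ch: 0 for ch in ("Green", "Red", "FarRed")}
    total = {ch: 0 for ch in ("Green", "Red", "FarRed")}
    for (fid, cid), cell_spots in gt.spots.groupby(["field_id", "cell_id"]):
        cell = gt.cells[(gt.cells.field_id == fid) & (gt.cells.cell_id == cid)].iloc[0]
        rec = None
        if tree is not None:
            d, i = tree.query([cell.cx_px, cell.cy_px])
            cand = ok[int(i)]
            if d <= 5 and cand.field_id == fid:
                rec = cand
        for ch, grp in cell_spots.groupby("channel"):
            truth = grp[["x_px", "y_px"]].to_numpy()
            total[ch] += len(truth)
            if rec is None or not rec.spots.get(ch):
                continue
            det = np.array([[s.x, s.y] for s in rec.spots[ch]])
            dd, _ = cKDTree(det).query(truth)
            matched[ch] += int((dd <= match_radius_px).sum())
    out = {ch: 100.0 * matched[ch] / total[ch] for ch in total if total[ch]}
    out["n_spots"] = float(sum(total.values()))
    return out


@dataclass
class ConditionRecovery:
    """Pipeline estimates vs ground truth for one simulated condition.

    Event rates are per analyzed (QC-passing) nucleus, as the assay reports
    them; ``truth_detectable`` is therefore computed over the ground-truth
    cells matched (by nucleus centroid) to those same analyzed nuclei, while
    ``truth_state`` reports the latent-state rates over the whole simulated
    population for reference.
    """

    n_cells: int
    n_qc_pass: int
    estimate: dict[str, float]       # breakage / translocation (pipeline)
    truth_detectable: dict[str, float]  # realized geometry, analyzed nuclei
    truth_state: dict[str, float]       # latent allele-state rates, all cells
    positives: dict[str, int]           # positive QC-passing nuclei counts


def recover_condition(
    cell_model,
    n_cells: int,
    seed: int = 0,
    imaging: ImagingConfig | None = None,
    noise: NoiseSpec | None = None,
    thresholds: Thresholds | None = None,
    cells_per_field: int = 30,
    field_offset: int = 0,
) -> ConditionRecovery:
    """Full image pipeline on one simulated condition; rates vs truth."""
    imaging = imaging or ImagingConfig()
    noise = noise if noise is not None else NoiseSpec()
    thresholds = thresholds or Thresholds()
    gt, recs, _ = _analyze_fields(
        cell_model, n_cells, seed, imaging, noise, RenderParams(),
        None, None, cells_per_field, field_offset)
    nuclei, spots = im.records_to_tables(recs)
    _, summaries = ev.call_events(nuclei, spots, thresholds)
    passing = summaries[summaries["qc_pass"]]
    n_pass = len(passing)
    estimate = {
        "breakage": float(passing["breakage_positive"].mean()) if n_pass else np.nan,
        "translocation": float(passing["translocation_positive"].mean()) if n_pass else np.nan,
    }

    # restrict the geometric truth to the ground-truth cells whose nuclei
    # were actually analyzed (QC-passing), matched by centroid per field
    t = thresholds.proximity_px
    a = gt.alleles
    sep = a["rg_sep_px"] > t
    per_cell = pd.DataFrame({
        "breakage": sep,
        "translocation": sep & (a["rfr_min_px"] <= t),
    }).groupby([a["field_id"], a["cell_id"]]).any()
    analyzed_keys: list[tuple] = []
    nuc_pass = nuclei.merge(
        passing[["field_id", "nucleus_id"]], on=["field_id", "nucleus_id"])
    for fid, grp in nuc_pass.groupby("field_id"):
        cells_f = gt.cells[gt.cells["field_id"] == fid]
        if cells_f.empty:
            continue
        tree = cKDTree(cells_f[["cx_px", "cy_px"]].to_numpy())
        d, idx = tree.query(grp[["cx_px", "cy_px"]].to_numpy())
        for dist, i in zip(np.atleast_1d(d), np.atleast_1d(idx)):
            if dist <= 5:
                analyzed_keys.append((fid, int(cells_f.iloc[int(i)]["cell_id"])))
    matched = per_cell.reindex(analyzed_keys).fillna(False)
    rates_all = gt.positive_rates(t)
    return ConditionRecovery(
        n_cells=len(gt.cells),
        n_qc_pass=n_pass,
        estimate=estimate,
        truth_detectable={
            "breakage": float(matched["breakage"].mean()) if len(matched) else np.nan,
            "translocation": float(matched["translocation"].mean()) if len(matched) else np.nan,
        },
        truth_state={
            "breakage": rates_all["breakage"],
            "translocation": rates_all["translocation"],
        },
        positives={
            "breakage": int(passing["breakage_positive"].sum()),
            "translocation": int(passing["translocation_positive"].sum()),
        },
    )


def titration_series(
    fractions,
    n_cells_per_point: int,
    positive: CellModel | None = None,
    negative: CellModel | None = None,
    seed: int = 0,
    cells_per_field: int = 30,
) -> pd.DataFrame:
    """Detected translocation-positive cell fraction across a dilution series."""
    from .config import negative_cell_model, positive_cell_model

    positive = positive or positive_cell_model()
    negative = negative or negative_cell_model()
    rows = []
    offset = 0
    for f in fractions:
        model = (positive if f == 1.0 else negative if f == 0.0
                 else [(positive, f), (negative, 1.0 - f)])
        rec = recover_condition(model, n_cells_per_point, seed=seed,
                                cells_per_field=cells_per_field,
                                field_offset=offset)
        offset += -(-n_cells_per_point // cells_per_field)
        rows.append((f, rec.n_qc_pass, rec.estimate["translocation"],
                     rec.truth_detectable["translocation"],
                     rec.truth_state["translocation"]))
    return pd.DataFrame(
        rows, columns=["fraction", "n_qc_pass", "detected",
                       "truth_detectable", "truth_state"],
    )
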