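"""Per-allele distance computation and break/translocation event calling.

A nucleus enters the analysis only if it passes the signal-count QC filter:
at least two signals in each of the Green, Red and FarRed channels, and
equal Green and Red counts (guarding against missed or spurious
detections). For every Red signal the minimum center-to-center Euclidean 2D
distance to any Green (``rg_min``) and any FarRed (``rfr_min``) signal in
the same nucleus is computed. Event definitions, at proximity threshold
``t`` (default 4 px = 1.28 um at 320 nm/px):

* breakage:       ``rg_min > t``  (the break-apart pair has separated);
* translocation:  ``rg_min > t`` and ``rfr_min <= t`` (the separated Red
  signal is joined to a partner-gene signal);
* intact otherwise. Distances exactly at ``t`` count as proximal.

Every translocation therefore also satisfies the breakage condition, and a
translocated allele is counted in breakage tallies. A nucleus is positive
for an event class if it carries at least one event of that class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .config import Thresholds
from .imaging import NucleusRecord

__all__ = [
    "QCVerdict",
    "AlleleDistanceRecord",
    "NucleusEventSummary",
    "qc_filter",
    "pairwise_distances",
    "classify_red_signal",
    "summarize_nucleus",
    "call_events",
    "INTACT",
    "BREAKAGE",
    "TRANSLOCATION",
]

INTACT = "intact"
BREAKAGE = "breakage"
TRANSLOCATION = "translocation"


@dataclass(frozen=True)
class QCVerdict:
    passed: bool
    reason: str = ""


@dataclass
class AlleleDistanceRecord:
    """One Red FISH signal with its per-signal minimum distances (pixels)."""

    red_spot_id: int
    nucleus_id: int
    field_id: str = ""
    rg_distances: np.ndarray = field(default_factory=lambda: np.empty(0))
    rfr_distances: np.ndarray = field(default_factory=lambda: np.empty(0))
    rg_min: float = np.nan
    rfr_min: float = np.nan
    event_class: str = ""


@dataclass(frozen=True)
class NucleusEventSummary:
    nucleus_id: int
    field_id: str
    qc_pass: bool
    qc_reason: str
    n_green: int
    n_red: int
    n_farred: int
    n_breakage_events: int
    n_translocation_events: int
    breakage_positive: bool
    translocation_positive: bool


def qc_filter(nucleus) -> QCVerdict:
    """Signal-count admission filter.

    ``nucleus`` is a :class:`~hibafish.imaging.NucleusRecord` or a
    ``(n_green, n_red, n_farred)`` triple. Pass requires >= 2 signals per
    FISH channel and equal Green and Red counts; the reason names the first
    failed clause.
    """
    if isinstance(nucleus, NucleusRecord):
        g, r, fr = (nucleus.spot_count(c) for c in ("Green", "Red", "FarRed"))
    else:
        g, r, fr = nucleus
    for count, name in ((g, "Green"), (r, "Red"), (fr, "FarRed")):
        if count < 2:
            return QCVerdict(False, f"{name} signal count {count} < 2")
    if g != r:
        return QCVerdict(False, f"unequal Green ({g}) and Red ({r}) signal counts")
    return QCVerdict(True)


def pairwise_distances(
    red_xy: np.ndarray,
    green_xy: np.ndarray,
    farred_xy: np.ndarray,
    nucleus_id: int = 0,
    field_id: str = "",
    red_ids: Sequence[int] | None = None,
) -> list[AlleleDistanceRecord]:
    """All Red-to-Green and Red-to-FarRed 2D distances, with per-Red minima.

    Inputs are ``(n, 2)`` coordinate arrays in pixel units. Post-QC the
    Green and FarRed lists are non-empty; empty ones signal a contract
    violation.
    """
    red_xy = np.atleast_2d(np.asarray(red_xy, dtype=float))
    green_xy = np.atleast_2d(np.asarray(green_xy, dtype=float))
    farred_xy = np.atleast_2d(np.asarray(farred_xy, dtype=float))
    if red_xy.size and (green_xy.size == 0 or farred_xy.size == 0):
        raise ValueError("pairwise_distances requires Green and FarRed signals (QC contract)")
    if red_xy.size == 0:
        return []
    dg = cdist(red_xy, green_xy)
    df = cdist(red_xy, farred_xy)
    ids = list(red_ids) if red_ids is not None else list(range(len(red_xy)))
    return [
        AlleleDistanceRecord(
            red_spot_id=int(ids[i]),
            nucleus_id=nucleus_id,
            field_id=field_id,
            rg_distances=dg[i],
            rfr_distances=df[i],
            rg_min=float(dg[i].min()),
            rfr_min=float(df[i].min()),
        )
        for i in range(len(red_xy))
    ]


def classify_red_signal(record: AlleleDistanceRecord,
                        thresholds: Thresholds | None = None) -> str:
    """Assign the event class from the per-Red minima (see module docstring)."""
    t = (thresholds or Thresholds()).proximity_px
    if not np.isfinite(record.rg_min) or not np.isfinite(record.rfr_min):
        raise ValueError("minima not computed before classification")
    if record.rg_min > t:
        return TRANSLOCATION if record.rfr_min <= t else BREAKAGE
    return INTACT


def summarize_nucleus(
    records: Sequence[AlleleDistanceRecord],
    qc: QCVerdict,
    counts: tuple[int, int, int] | None = None,
) -> NucleusEventSummary:
    """Collapse per-Red records of one nucleus into an event summary.

    Breakage tallies include translocation events (a translocated allele
    satisfies the breakage condition). QC-failed nuclei report zero events.
    """
    ids = {(r.field_id, r.nucleus_id) for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple nuclei: {sorted(ids)}")
    field_id, nucleus_id = next(iter(ids)) if ids else ("", -1)
    g, r, fr = counts if counts is not None else (len(records), len(records), 0)
    if not qc.passed:
        return NucleusEventSummary(nucleus_id, field_id, False, qc.reason,
                                   g, r, fr, 0, 0, False, False)
    classes = [rec.event_class for rec in records]
    if any(c == "" for c in classes):
        raise ValueError("classify records before summarizing")
    n_tr = classes.count(TRANSLOCATION)
    n_br = classes.count(BREAKAGE) + n_tr
    return NucleusEventSummary(
        nucleus_id, field_id, True, "", g, r, fr,
        n_breakage_events=n_br,
        n_translocation_events=n_tr,
        breakage_positive=n_br > 0,
        translocation_positive=n_tr > 0,
    )


def call_events(
    nuclei: pd.DataFrame,
    spots: pd.DataFrame,
    thresholds: Thresholds | None = None,
    coordinate_unit: str = "px",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Batch event calling over the (nuclei, spots) table dialect.

    Applies the QC filter per nucleus, computes per-Red minima, classifies
    events and returns ``(alleles, summaries)`` tables. Excluded nuclei
    (morphology/border) are dropped; QC-failed nuclei appear in the summary
    with zero events. ``coordinate_unit="um"`` converts spot coordinates to
    pixels via the thresholds' pixel size before thresholding.
    """
    thresholds = thresholds or Thresholds()
    if coordinate_unit not in ("px", "um"):
        raise ValueError("coordinate_unit must be 'px' or 'um'")
    spots = spots.copy()
    if coordinate_unit == "um":
        spots[["x_px", "y_px"]] = spots[["x_px", "y_px"]] / thresholds.pixel_size_um

    if "excluded" in nuclei.columns:
        nuclei = nuclei[~nuclei["excluded"].astype(bool)]

    grouped = {k: g for k, g in spots.groupby(["field_id", "nucleus_id"], sort=False)}
    allele_rows, summary_rows = [], []
    for nrow in nuclei.itertuples():
        key = (nrow.field_id, nrow.nucleus_id)
        g = grouped.get(key)
        by_ch = ({} if g is None else
                 {ch: sub for ch, sub in g.groupby("channel", sort=False)})
        counts = tuple(len(by_ch.get(ch, ())) for ch in ("Green", "Red", "FarRed"))
        verdict = qc_filter(counts)
        if not verdict.passed:
            s = summarize_nucleus([], verdict, counts)
        else:
            red = by_ch["Red"]
            recs = pairwise_distances(
                red[["x_px", "y_px"]].to_numpy(),
                by_ch["Green"][["x_px", "y_px"]].to_numpy(),
                by_ch["FarRed"][["x_px", "y_px"]].to_numpy(),
                nucleus_id=nrow.nucleus_id,
                field_id=nrow.field_id,
                red_ids=red["spot_id"].tolist(),
            )
            for rec in recs:
                rec.event_class = classify_red_signal(rec, thresholds)
                allele_rows.append(
                    (rec.field_id, rec.nucleus_id, rec.red_spot_id,
                     rec.rg_min, rec.rfr_min, rec.event_class)
                )
            s = summarize_nucleus(recs, verdict, counts)
        summary_rows.append(
            (s.field_id, s.nucleus_id, s.qc_pass, s.qc_reason,
             s.n_green, s.n_red, s.n_farred,
             s.n_breakage_events, s.n_translocation_events,
             s.breakage_positive, s.translocation_positive)
        )

    alleles = pd.DataFrame(
        allele_rows,
        columns=["field_id", "nucleus_id", "red_spot_id",
                 "rg_min_px", "rfr_min_px", "event_class"],
    )
    summaries = pd.DataFrame(
        summary_rows,
        columns=["field_id", "nucleus_id", "qc_pass", "qc_reason",
                 "n_green", "n_red", "n_farred",
                 "n_breakage_events", "n_translocation_events",
                 "breakage_positive", "translocation_positive"],
    )
    # global hierarchy invariant: translocation implies breakage
    assert (summaries["n_translocation_events"]
            <= summaries["n_breakage_events"]).all()
    return alleles, summaries
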