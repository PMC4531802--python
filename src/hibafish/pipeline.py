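"""Batch orchestration: dataset discovery to condition summaries on disk.

A dataset directory holds one sub-directory per experimental condition,
named with the underscore-delimited metadata pattern. Each condition
directory holds per-field OME-TIFF stacks. The pipeline analyzes every
field (projection, segmentation, spot detection), concatenates the
per-field tables, calls events per nucleus, and emits condition summaries
and pairwise comparisons. Per-field failures are logged and quarantined;
the run fails only if every field of every condition fails.
"""

from __future__ import annotations

import logging
import platform
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import events as ev
from . import imaging as im
from . import io as hio
from . import stats as st
from .config import RunConfig

__all__ = ["RunResult", "run_pipeline", "analyze_condition_dir"]

log = logging.getLogger("hibafish")


@dataclass
class RunResult:
    output_dir: Path
    condition_summary: pd.DataFrame
    comparisons: pd.DataFrame
    quarantined: list[str] = field(default_factory=list)
    n_fields_analyzed: int = 0

    @property
    def fully_failed(self) -> bool:
        return self.n_fields_analyzed == 0


def _provenance(config: RunConfig) -> str:
    return (
        f"hibafish {__version__} | python {platform.python_version()}\n"
        f"seed={config.seed} proximity_px={config.thresholds.proximity_px} "
        f"pixel_size_um={config.thresholds.pixel_size_um}"
    )


def analyze_condition_dir(
    cond_dir: Path,
    config: RunConfig,
    quarantined: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Analyze every field of one condition directory into tables."""
    nuc_parts, spot_parts = [], []
    n_ok = 0
    for files in hio.discover_fields(cond_dir):
        try:
            stacks: dict = {}
            for f in files:
                stacks.update(hio.read_field_tiff(f))
            m = re.search(r"_(f\d+)", files[0].name)
            fid = m.group(1) if m else files[0].stem
            fieldimg = im.FieldImage(field_id=fid, stacks=stacks, imaging=config.imaging)
            records = im.analyze_field(fieldimg, config.segmentation, config.spots)
            nuc, spot = im.records_to_tables(records)
            nuc_parts.append(nuc)
            spot_parts.append(spot)
            n_ok += 1
        except Exception as exc:  # quarantine the field, keep the run alive
            name = f"{cond_dir.name}/{files[0].name}"
            log.warning("quarantined field %s: %s", name, exc)
            quarantined.append(f"{name}\t{exc}")
    nuclei = (pd.concat(nuc_parts, ignore_index=True)
              if nuc_parts else im.records_to_tables([])[0])
    spots = (pd.concat(spot_parts, ignore_index=True)
             if spot_parts else im.records_to_tables([])[1])
    return nuclei, spots, n_ok


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full workflow over every condition directory of a dataset."""
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    prov = _provenance(config)
    log.info("run start | %s", prov.replace("\n", " | "))

    conditions: list[tuple[hio.ExperimentMetadata, Path]] = []
    for sub in sorted(p for p in in_dir.iterdir() if p.is_dir()):
        try:
            conditions.append((hio.parse_metadata(sub.name), sub))
        except hio.MetadataError as exc:
            log.warning("skipping unparseable directory: %s", exc)

    quarantined: list[str] = []
    summaries_by_condition: dict[str, pd.DataFrame] = {}
    n_fields = 0
    try:
        for meta, cdir in conditions:
            label = f"{meta.cell_line}/{meta.treatment}/{meta.probe_set}"
            nuclei, spots, ok = analyze_condition_dir(cdir, config, quarantined)
            n_fields += ok
            if ok == 0:
                continue
            alleles, nuc_events = ev.call_events(nuclei, spots, config.thresholds)
            cres = out_dir / cdir.name
            hio.write_table(nuclei, cres / "nuclei.tsv", prov)
            hio.write_table(spots, cres / "spots.tsv", prov)
            hio.write_table(alleles, cres / "allele_distances.tsv", prov)
            hio.write_table(nuc_events, cres / "nucleus_events.tsv", prov)
            if nuc_events["qc_pass"].any():
                summaries_by_condition[label] = nuc_events
            log.info("condition %s: %d nuclei, %d QC-pass", label,
                     len(nuc_events), int(nuc_events["qc_pass"].sum()))

        if summaries_by_condition:
            summary = st.condition_summaries(summaries_by_condition)
            comparisons = st.pairwise_comparisons(summary)
        else:
            summary = st.condition_summaries({})
            comparisons = pd.DataFrame(
                columns=["event_class", "condition_a", "condition_b",
                         "p_value", "fold_change"])
        hio.write_table(summary, out_dir / "condition_summary.tsv", prov)
        hio.write_table(comparisons, out_dir / "comparisons.tsv", prov)
        if quarantined:
            (out_dir / "quarantine.log").write_text("\n".join(quarantined) + "\n")
        log.info("run done: %d fields analyzed, %d quarantined",
                 n_fields, len(quarantined))
    finally:
        log.removeHandler(handler)
        handler.close()
    return RunResult(out_dir, summary, comparisons, quarantined, n_fields)
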