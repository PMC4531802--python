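"""Table and image I/O plus filename-metadata parsing.

Tables are UTF-8, tab-delimited, one header line, preceded by a
``#``-prefixed provenance preamble. Images are OME-TIFF z-stacks, either
one multi-channel file per field (axes CZYX) or one file per channel
(axes ZYX) — both dialects are written and read. Experimental metadata
(experiment name, cell line, construct, probe set, treatment) is encoded
positionally in underscore-delimited directory/file names, e.g.
``BC_140713_K299_K299_ALK_UN``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .config import CHANNEL_ROLES, ImagingConfig

__all__ = [
    "MetadataError",
    "ExperimentMetadata",
    "parse_metadata",
    "write_table",
    "read_table",
    "write_field_tiff",
    "read_field_tiff",
    "discover_fields",
]


class MetadataError(ValueError):
    """A file or directory name does not conform to the naming pattern."""


@dataclass(frozen=True)
class ExperimentMetadata:
    """Metadata parsed from an underscore-delimited dataset name."""

    experiment: str
    cell_line: str
    construct: str
    probe_set: str
    treatment: str

    def as_dict(self) -> dict[str, str]:
        return {
            "experiment": self.experiment,
            "cell_line": self.cell_line,
            "construct": self.construct,
            "probe_set": self.probe_set,
            "treatment": self.treatment,
        }


# <experiment: 2 tokens>_<cellline>_<construct>_<probeset>_<treatment>
_N_TOKENS = 6


def parse_metadata(name: str | Path) -> ExperimentMetadata:
    """Parse positional metadata from a dataset name.

    The experiment field spans the first two underscore-delimited tokens
    (prefix + date-like token); the remaining four tokens are cell line,
    construct, probe set and treatment. Trailing field/extension suffixes
    (``_f012``, ``.ome.tif``, ``.zip``) are stripped first.
    """
    stem = Path(name).name
    stem = re.sub(r"(\.ome)?\.(tiff?|zip|txt|tsv)$", "", stem, flags=re.I)
    stem = re.sub(r"_f\d+(_[A-Za-z]+)?$", "", stem)  # per-field / per-channel suffix
    tokens = stem.split("_")
    if len(tokens) != _N_TOKENS or any(t == "" for t in tokens):
        raise MetadataError(
            f"cannot parse metadata from {name!r}: expected "
            f"{_N_TOKENS} underscore-delimited tokens, got {len(tokens)}"
        )
    return ExperimentMetadata(
        experiment="_".join(tokens[:2]),
        cell_line=tokens[2],
        construct=tokens[3],
        probe_set=tokens[4],
        treatment=tokens[5],
    )


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, provenance: str = "") -> None:
    """Write a tab-delimited table with a ``#`` provenance preamble."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in filter(None, provenance.splitlines() or [provenance]):
            fh.write(f"# {line}\n" if line else "")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_table` (``#`` lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# OME-TIFF stacks
# ---------------------------------------------------------------------------

def write_field_tiff(
    path: str | Path,
    stacks: Mapping[str, np.ndarray],
    imaging: ImagingConfig | None = None,
) -> None:
    """Write channel stacks as OME-TIFF.

    A single channel writes a ZYX stack; several channels write one CZYX
    file with the channel names recorded in the OME metadata.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    channels = list(stacks)
    data = np.stack([np.asarray(stacks[ch], dtype=np.float32) for ch in channels])
    meta = {"axes": "CZYX", "Channel": {"Name": channels}}
    if imaging is not None:
        meta["PhysicalSizeX"] = imaging.pixel_size_um
        meta["PhysicalSizeY"] = imaging.pixel_size_um
        meta["PhysicalSizeZ"] = imaging.z_spacing_um
    if len(channels) == 1:
        tifffile.imwrite(path, data[0], metadata={**meta, "axes": "ZYX"})
    else:
        tifffile.imwrite(path, data, metadata=meta)


def read_field_tiff(path: str | Path) -> dict[str, np.ndarray]:
    """Read an OME-TIFF written by :func:`write_field_tiff`.

    Returns ``{channel_name: (z, y, x) array}``. Single-channel files fall
    back to the channel name encoded in a ``_<Channel>`` filename suffix, or
    ``"channel0"`` if absent.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        names = None
        if tf.ome_metadata:
            names = re.findall(r'Channel[^>]*Name="([^"]+)"', tf.ome_metadata)
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 3:  # single channel ZYX
        if not names:
            m = re.search(r"_([A-Za-z]+)(?:\.ome)?\.tiff?$", path.name)
            names = [m.group(1)] if m and m.group(1) in CHANNEL_ROLES else ["channel0"]
        return {names[0]: data}
    if data.ndim != 4:
        raise ValueError(f"unsupported TIFF dimensionality {data.shape} in {path}")
    if not names or len(names) != data.shape[0]:
        names = [f"channel{i}" for i in range(data.shape[0])]
    return {n: data[i] for i, n in enumerate(names)}


def discover_fields(condition_dir: str | Path) -> list[list[Path]]:
    """Group a condition directory's TIFFs into per-field file lists.

    Multi-channel fields appear as a singleton list; per-channel dialects
    group the channel files of one field together (by the ``_fNNN`` token).
    """
    condition_dir = Path(condition_dir)
    paths = sorted(
        p for p in condition_dir.iterdir()
        if re.search(r"\.(ome\.)?tiff?$", p.name, flags=re.I)
    )
    groups: dict[str, list[Path]] = {}
    for p in paths:
        m = re.search(r"_(f\d+)", p.name)
        key = m.group(1) if m else p.stem
        groups.setdefault(key, []).append(p)
    return [groups[k] for k in sorted(groups)]
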