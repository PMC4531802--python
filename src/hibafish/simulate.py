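"""Synthetic three-color break-apart FISH fields with exact ground truth.

The generator emulates a high-throughput confocal screen of interphase
nuclei: each field holds non-overlapping elliptical nuclei (DAPI channel);
each nucleus carries a configurable number of break-apart loci (gene A,
probed in Green + Red) and partner loci (gene B, FarRed). Per gene-A allele
a latent state is drawn — intact, broken, or translocated (broken and joined
to a gene-B partner) — and probe positions are placed accordingly:

* intact: Red sits a small Rayleigh-distributed offset from Green
  (mean ``intact_offset_um``, default 0.32 um = 1 px);
* broken: the Red probe is displaced by a large Rayleigh offset
  (mean ``broken_offset_um``, default 3.2 um), isotropic direction;
* translocated: additionally one gene-B FarRed probe is relocated next to
  the displaced Red probe (Rayleigh mean ``proximity_offset_um``).

Spots are rendered as 3D Gaussians into per-channel z-stacks and Poisson +
Gaussian read noise is applied. Every random draw flows from one
``numpy`` Generator; per-field generators are derived from the master seed
with ``SeedSequence(seed, spawn_key=(field_index,))`` so any field can be
re-simulated independently and reproducibly.

Ground truth is returned as three tables (cells, alleles, spots). Besides
the latent allele state, the allele table records the *realized* Red/Green
separation and the true minimum Red/FarRed distance, from which the
geometrically detectable event rates at any distance threshold can be
computed — a distance-based caller can only ever recover the realized
geometry, not the latent label, so parameter-recovery checks compare
against these.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import (
    CellModel,
    ConfigurationError,
    ImagingConfig,
    NoiseSpec,
    RenderParams,
)
from . import io as hio

__all__ = [
    "GroundTruth",
    "Condition",
    "SimulationError",
    "simulate_ground_truth",
    "render_field",
    "simulate_field",
    "simulate_experiment",
    "titration_conditions",
    "spot_tables_from_ground_truth",
    "field_rng",
]

#: Rayleigh scale for a requested mean: mean = sigma * sqrt(pi/2).
_RAYLEIGH_MEAN_TO_SCALE = 1.0 / math.sqrt(math.pi / 2.0)


class SimulationError(RuntimeError):
    """Raised when a field cannot be realized (e.g. too dense to place)."""


def field_rng(seed: int, field_index: int) -> np.random.Generator:
    """Per-field generator: ``SeedSequence(seed, spawn_key=(field_index,))``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(field_index,)))


@dataclass
class GroundTruth:
    """Simulator ground truth for one or more fields.

    Attributes
    ----------
    cells
        One row per simulated cell: field_id, cell_id, model, nucleus
        geometry (center, semi-axes, orientation), allele counts and event
        summary columns (``n_broken``, ``n_transloc``).
    alleles
        One row per gene-A allele: latent ``state`` (intact / broken /
        translocated), realized ``rg_sep_px`` (true Red-Green separation)
        and ``rfr_min_px`` (true minimum Red-FarRed distance), and the
        partner gene-B allele id for translocations (-1 otherwise).
    spots
        One row per true probe signal: field_id, cell_id, allele_id,
        channel, x_px, y_px, z_plane. Coordinates are 0-based pixels,
        origin top-left, x = column.
    """

    cells: pd.DataFrame
    alleles: pd.DataFrame
    spots: pd.DataFrame

    def positive_rates(self, proximity_px: float = 4.0) -> dict[str, float]:
        """Per-cell event rates, both latent and geometrically detectable.

        ``breakage`` / ``translocation`` are latent-state rates (fraction of
        cells with >= 1 broken / translocated allele). ``breakage_detectable``
        counts cells with >= 1 allele whose realized separation exceeds the
        threshold; ``translocation_detectable`` additionally requires the true
        Red-FarRed minimum at or below the threshold.
        """
        a = self.alleles
        sep = a["rg_sep_px"] > proximity_px
        prox = a["rfr_min_px"] <= proximity_px
        key = ["field_id", "cell_id"]
        per_cell = pd.DataFrame(
            {
                "breakage": a["state"].isin(["broken", "translocated"]),
                "translocation": a["state"] == "translocated",
                "breakage_detectable": sep,
                "translocation_detectable": sep & prox,
            }
        ).groupby([a[k] for k in key]).any()
        n = len(self.cells)
        if n == 0:
            return {c: 0.0 for c in per_cell.columns}
        # cells with zero gene-A alleles contribute negatives
        return {c: float(per_cell[c].sum()) / n for c in per_cell.columns}

    @staticmethod
    def concat(parts: Iterable["GroundTruth"]) -> "GroundTruth":
        parts = list(parts)
        if not parts:
            return GroundTruth(_empty_cells(), _empty_alleles(), _empty_spots())
        return GroundTruth(
            pd.concat([p.cells for p in parts], ignore_index=True),
            pd.concat([p.alleles for p in parts], ignore_index=True),
            pd.concat([p.spots for p in parts], ignore_index=True),
        )

    def write(self, out_dir: str | Path, provenance: str = "") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        hio.write_table(self.cells, out_dir / "gt_cells.tsv", provenance)
        hio.write_table(self.alleles, out_dir / "gt_alleles.tsv", provenance)
        hio.write_table(self.spots, out_dir / "gt_spots.tsv", provenance)

    @classmethod
    def read(cls, in_dir: str | Path) -> "GroundTruth":
        in_dir = Path(in_dir)
        return cls(
            hio.read_table(in_dir / "gt_cells.tsv"),
            hio.read_table(in_dir / "gt_alleles.tsv"),
            hio.read_table(in_dir / "gt_spots.tsv"),
        )


def _empty_cells() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["field_id", "cell_id", "model", "cx_px", "cy_px", "a_px", "b_px",
                 "theta_rad", "n_alleles_A", "n_alleles_B", "n_broken", "n_transloc"]
    )


def _empty_alleles() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["field_id", "cell_id", "allele_id", "state",
                 "rg_sep_px", "rfr_min_px", "partner_b"]
    )


def _empty_spots() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["field_id", "cell_id", "allele_id", "channel",
                 "x_px", "y_px", "z_plane"]
    )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _inside_ellipse(x: float, y: float, cx: float, cy: float,
                    a: float, b: float, theta: float, scale: float = 1.0) -> bool:
    dx, dy = x - cx, y - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / (a * scale)
    v = (-dx * st + dy * ct) / (b * scale)
    return u * u + v * v <= 1.0


def _sample_in_ellipse(rng: np.random.Generator, cx: float, cy: float,
                       a: float, b: float, theta: float, scale: float) -> tuple[float, float]:
    # uniform point in the scaled ellipse via unit-disk sampling
    r = math.sqrt(rng.random())
    phi = rng.uniform(0, 2 * math.pi)
    u, v = r * math.cos(phi) * a * scale, r * math.sin(phi) * b * scale
    ct, st = math.cos(theta), math.sin(theta)
    return cx + u * ct - v * st, cy + u * st + v * ct


def _place_nuclei(rng: np.random.Generator, n: int, shape: tuple[int, int],
                  render: RenderParams) -> list[tuple[float, float, float, float, float]]:
    """Place n non-overlapping ellipses fully inside the field (with margin)."""
    h, w = shape
    placed: list[tuple[float, float, float, float, float]] = []
    for _ in range(n):
        ok = False
        for _attempt in range(300):
            a = rng.uniform(render.nucleus_min_radius_px, render.nucleus_max_radius_px)
            b = rng.uniform(render.nucleus_min_radius_px, render.nucleus_max_radius_px)
            theta = rng.uniform(0, math.pi)
            rmax = max(a, b)
            lo = rmax + render.nucleus_margin_px
            if w - lo <= lo or h - lo <= lo:
                raise SimulationError("field too small for configured nucleus size")
            cx = rng.uniform(lo, w - lo)
            cy = rng.uniform(lo, h - lo)
            if all(
                math.hypot(cx - px, cy - py)
                >= rmax + max(pa, pb) + render.nucleus_margin_px
                for px, py, pa, pb, _t in placed
            ):
                placed.append((cx, cy, a, b, theta))
                ok = True
                break
        if not ok:
            raise SimulationError(
                f"could not place nucleus {len(placed) + 1}/{n}: field too dense"
            )
    return placed


def _sample_anchors(rng: np.random.Generator, k: int, nucleus, min_sep: float,
                    scale: float = 0.8) -> list[tuple[float, float]]:
    """k anchor points inside the nucleus with pairwise minimum separation."""
    cx, cy, a, b, theta = nucleus
    anchors: list[tuple[float, float]] = []
    sep = min_sep
    for _ in range(k):
        for attempt in range(200):
            x, y = _sample_in_ellipse(rng, cx, cy, a, b, theta, scale)
            if all(math.hypot(x - qx, y - qy) >= sep for qx, qy in anchors):
                anchors.append((x, y))
                break
            if attempt == 120:  # crowded nucleus: relax rather than fail
                sep *= 0.5
        else:
            anchors.append(_sample_in_ellipse(rng, cx, cy, a, b, theta, scale))
    return anchors


def _offset_point(rng: np.random.Generator, origin: tuple[float, float],
                  mean_px: float, nucleus) -> tuple[float, float]:
    """Point at a Rayleigh(mean)-distributed distance from origin, kept inside
    the nucleus by re-drawing the direction (then the distance) as needed."""
    cx, cy, a, b, theta = nucleus
    if mean_px <= 0:
        return origin
    scale = mean_px * _RAYLEIGH_MEAN_TO_SCALE
    for _dist_try in range(40):
        d = rng.rayleigh(scale)
        for _dir_try in range(40):
            phi = rng.uniform(0, 2 * math.pi)
            x = origin[0] + d * math.cos(phi)
            y = origin[1] + d * math.sin(phi)
            if _inside_ellipse(x, y, cx, cy, a, b, theta, scale=0.97):
                return x, y
    return origin  # pathological geometry; keep the probe at its anchor


# ---------------------------------------------------------------------------
# ground truth generation
# ---------------------------------------------------------------------------

ModelSpec = "CellModel | Sequence[tuple[CellModel, float]]"


def _choose_models(rng: np.random.Generator, cell_model, n_cells: int) -> list[CellModel]:
    if isinstance(cell_model, CellModel):
        return [cell_model] * n_cells
    models = [m for m, _w in cell_model]
    weights = np.asarray([w for _m, w in cell_model], dtype=float)
    if len(models) == 0 or weights.sum() <= 0 or (weights < 0).any():
        raise ConfigurationError("mixture weights must be non-negative and sum > 0")
    idx = rng.choice(len(models), size=n_cells, p=weights / weights.sum())
    return [models[i] for i in idx]


def simulate_ground_truth(
    cell_model,
    n_cells: int,
    imaging: ImagingConfig | None = None,
    render: RenderParams | None = None,
    rng: np.random.Generator | None = None,
    field_id: str = "f000",
) -> GroundTruth:
    """Draw nucleus geometry, allele states and true probe positions.

    ``cell_model`` may be a single :class:`CellModel` or a sequence of
    ``(model, weight)`` pairs describing a mixed population (e.g. a titration
    of translocation-positive into negative cells).
    """
    imaging = imaging or ImagingConfig()
    render = render or RenderParams()
    rng = rng if rng is not None else np.random.default_rng(0)
    if n_cells < 0:
        raise ConfigurationError("n_cells must be >= 0")

    models = _choose_models(rng, cell_model, n_cells)
    nuclei = _place_nuclei(rng, n_cells, imaging.field_shape_px, render)

    z_lo, z_hi = 1.0, max(1.0, imaging.z_planes - 2.0)
    cells, alleles, spots = [], [], []
    for cid, (model, nucleus) in enumerate(zip(models, nuclei)):
        cx, cy, a, b, theta = nucleus
        mean_intact = imaging.um_to_px(model.intact_offset_um)
        mean_broken = imaging.um_to_px(model.broken_offset_um)
        mean_prox = imaging.um_to_px(model.proximity_offset_um)

        # latent states; translocations are capped by available partners
        broken = rng.random(model.n_alleles_A) < model.p_break
        transloc = broken & (rng.random(model.n_alleles_A) < model.p_transloc_given_break)
        if transloc.sum() > model.n_alleles_B:
            keep = np.flatnonzero(transloc)
            drop = rng.permutation(keep)[model.n_alleles_B:]
            transloc[drop] = False

        anchors_a = _sample_anchors(rng, model.n_alleles_A, nucleus,
                                    render.allele_min_separation_px)
        anchors_b = _sample_anchors(rng, model.n_alleles_B, nucleus,
                                    render.allele_min_separation_px)
        farred = [list(p) for p in anchors_b]

        # assign one distinct gene-B partner per translocated allele
        partner_of = {}
        free_b = list(rng.permutation(model.n_alleles_B))
        for ai in np.flatnonzero(transloc):
            partner_of[int(ai)] = int(free_b.pop())

        reds, greens = [], []
        for ai in range(model.n_alleles_A):
            gx, gy = anchors_a[ai]
            mean = mean_broken if broken[ai] else mean_intact
            rx, ry = _offset_point(rng, (gx, gy), mean, nucleus)
            greens.append((gx, gy))
            reds.append((rx, ry))
            if transloc[ai]:
                farred[partner_of[ai]] = list(
                    _offset_point(rng, (rx, ry), mean_prox, nucleus)
                )

        # realized geometry per gene-A allele
        for ai in range(model.n_alleles_A):
            rx, ry = reds[ai]
            rg_sep = math.hypot(rx - greens[ai][0], ry - greens[ai][1])
            rfr = min(
                (math.hypot(rx - fx, ry - fy) for fx, fy in farred),
                default=float("inf"),
            )
            state = ("translocated" if transloc[ai]
                     else "broken" if broken[ai] else "intact")
            alleles.append((field_id, cid, ai, state, rg_sep, rfr,
                            partner_of.get(ai, -1)))

        # spots: paired probes share an axial position (small jitter)
        for ai in range(model.n_alleles_A):
            z = rng.uniform(z_lo, z_hi)
            zr = float(np.clip(z + rng.normal(0, 0.3), 0, imaging.z_planes - 1))
            spots.append((field_id, cid, ai, "Green", greens[ai][0], greens[ai][1], z))
            spots.append((field_id, cid, ai, "Red", reds[ai][0], reds[ai][1], zr))
        for bi in range(model.n_alleles_B):
            z = rng.uniform(z_lo, z_hi)
            spots.append((field_id, cid, 100 + bi, "FarRed", farred[bi][0], farred[bi][1], z))

        cells.append((field_id, cid, model.name, cx, cy, a, b, theta,
                      model.n_alleles_A, model.n_alleles_B,
                      int(broken.sum()), int(transloc.sum())))

    return GroundTruth(
        pd.DataFrame(cells, columns=_empty_cells().columns) if cells else _empty_cells(),
        pd.DataFrame(alleles, columns=_empty_alleles().columns) if alleles else _empty_alleles(),
        pd.DataFrame(spots, columns=_empty_spots().columns) if spots else _empty_spots(),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_field(
    gt: GroundTruth,
    imaging: ImagingConfig,
    render: RenderParams,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Render one field's ground truth into four (z, y, x) float32 stacks."""
    h, w = imaging.field_shape_px
    nz = imaging.z_planes
    stacks = {ch: np.zeros((nz, h, w), dtype=np.float32) for ch in imaging.channels}

    # DAPI: smooth-edged ellipses with a Gaussian axial profile
    dapi2d = np.zeros((h, w), dtype=np.float32)
    yy, xx = np.mgrid[0:h, 0:w]
    for row in gt.cells.itertuples():
        r = int(math.ceil(max(row.a_px, row.b_px))) + 3
        y0, y1 = max(0, int(row.cy_px) - r), min(h, int(row.cy_px) + r + 1)
        x0, x1 = max(0, int(row.cx_px) - r), min(w, int(row.cx_px) + r + 1)
        ys, xs = yy[y0:y1, x0:x1], xx[y0:y1, x0:x1]
        ct, st = math.cos(row.theta_rad), math.sin(row.theta_rad)
        dx, dy = xs - row.cx_px, ys - row.cy_px
        u = (dx * ct + dy * st) / row.a_px
        v = (-dx * st + dy * ct) / row.b_px
        dapi2d[y0:y1, x0:x1][u * u + v * v <= 1.0] = render.dapi_amplitude
    if render.dapi_edge_sigma_px > 0 and len(gt.cells):
        dapi2d = gaussian_filter(dapi2d, render.dapi_edge_sigma_px)
    z_mid = (nz - 1) / 2.0
    axial = np.exp(-((np.arange(nz) - z_mid) ** 2) / (2 * max(1.0, nz / 3.5) ** 2))
    stacks["DAPI"][:] = axial[:, None, None].astype(np.float32) * dapi2d[None]

    # FISH spots: 3D Gaussians added in local windows
    half = int(math.ceil(4 * render.spot_sigma_px)) + 1
    zz = np.arange(nz, dtype=np.float32)
    for s in gt.spots.itertuples():
        x0 = max(0, int(round(s.x_px)) - half)
        x1 = min(w, int(round(s.x_px)) + half + 1)
        y0 = max(0, int(round(s.y_px)) - half)
        y1 = min(h, int(round(s.y_px)) + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.exp(-((np.arange(x0, x1) - s.x_px) ** 2)
                    / (2 * render.spot_sigma_px ** 2)).astype(np.float32)
        gy = np.exp(-((np.arange(y0, y1) - s.y_px) ** 2)
                    / (2 * render.spot_sigma_px ** 2)).astype(np.float32)
        gz = np.exp(-((zz - s.z_plane) ** 2)
                    / (2 * render.spot_sigma_z_planes ** 2)).astype(np.float32)
        stacks[s.channel][:, y0:y1, x0:x1] += (
            render.spot_amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )

    if not noise.is_none:
        for ch in imaging.channels:
            img = stacks[ch]
            img += noise.background
            if noise.poisson:
                img = rng.poisson(img).astype(np.float32)
            if noise.read_sigma > 0:
                img += noise.read_sigma * rng.standard_normal(img.shape, dtype=np.float32)
            np.clip(img, 0.0, None, out=img)
            stacks[ch] = img
    return stacks


def simulate_field(
    cell_model,
    n_cells: int,
    imaging: ImagingConfig | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    render: RenderParams | None = None,
    field_index: int = 0,
    field_id: str | None = None,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Simulate one field of view: four channel stacks plus ground truth.

    Deterministic given ``(seed, field_index)`` and identical arguments.
    """
    imaging = imaging or ImagingConfig()
    noise = noise if noise is not None else NoiseSpec()
    render = render or RenderParams()
    if not isinstance(noise, NoiseSpec):
        raise ConfigurationError("noise must be a NoiseSpec")
    rng = field_rng(seed, field_index)
    gt = simulate_ground_truth(
        cell_model, n_cells, imaging, render, rng,
        field_id=field_id or f"f{field_index:03d}",
    )
    stacks = render_field(gt, imaging, render, noise, rng)
    return stacks, gt


# ---------------------------------------------------------------------------
# experiments on disk
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """One experimental condition: a (possibly mixed) cell population.

    The output directory name encodes the metadata the analysis stage parses
    back out: ``<experiment>_<cellline>_<construct>_<probeset>_<treatment>``
    where ``experiment`` itself carries one underscore (prefix + date-like
    token). Tokens must therefore not contain underscores.
    """

    label: str
    cell_model: "CellModel | tuple"
    n_cells: int
    experiment: str = "SIM_000001"
    cell_line: str | None = None
    construct: str = "GFP"
    probe_set: str = "ALK"

    @property
    def treatment(self) -> str:
        return self.label

    @property
    def dirname(self) -> str:
        line = self.cell_line
        if line is None:
            line = (self.cell_model.name if isinstance(self.cell_model, CellModel)
                    else "MIX")
        tokens = [line, self.construct, self.probe_set, self.treatment]
        if any("_" in t for t in tokens):
            raise ConfigurationError("metadata tokens must not contain underscores")
        return "_".join([self.experiment] + tokens)


def simulate_experiment(
    conditions: Sequence[Condition],
    imaging: ImagingConfig | None = None,
    seed: int = 0,
    out_dir: str | Path = "simulated",
    noise: NoiseSpec | None = None,
    render: RenderParams | None = None,
    cells_per_field: int = 25,
    multichannel: bool = True,
    overwrite: bool = False,
    write_images: bool = True,
) -> Path:
    """Write a simulated dataset to disk, one directory per condition.

    Each condition directory holds per-field OME-TIFF stacks (one
    multi-channel file per field, or one file per channel when
    ``multichannel=False``) plus the ground-truth tables. Field RNG streams
    are indexed by a global field counter, so the dataset is reproducible
    field-by-field from ``seed``. Refuses to overwrite an existing
    condition directory unless ``overwrite`` is set.
    """
    imaging = imaging or ImagingConfig()
    noise = noise if noise is not None else NoiseSpec()
    render = render or RenderParams()
    labels = [c.label for c in conditions]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("condition labels must be unique")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    field_counter = 0
    for cond in conditions:
        cdir = out_dir / cond.dirname
        if cdir.exists() and not overwrite:
            raise FileExistsError(
                f"{cdir} exists; pass overwrite=True to replace it"
            )
        cdir.mkdir(parents=True, exist_ok=True)
        parts = []
        remaining = cond.n_cells
        local = 0
        while remaining > 0 or (cond.n_cells == 0 and local == 0):
            n = min(cells_per_field, remaining)
            fid = f"f{local:03d}"
            rng = field_rng(seed, field_counter)
            gt = simulate_ground_truth(cond.cell_model, n, imaging, render, rng, field_id=fid)
            if write_images:
                stacks = render_field(gt, imaging, render, noise, rng)
                base = cdir / f"{cond.dirname}_{fid}"
                if multichannel:
                    hio.write_field_tiff(f"{base}.ome.tif", stacks, imaging)
                else:
                    for ch in imaging.channels:
                        hio.write_field_tiff(f"{base}_{ch}.ome.tif",
                                             {ch: stacks[ch]}, imaging)
            parts.append(gt)
            field_counter += 1
            local += 1
            remaining -= n
            if cond.n_cells == 0:
                break
        GroundTruth.concat(parts).write(cdir, provenance=f"simulated seed={seed}")
    return out_dir


def titration_conditions(
    fractions: Sequence[float],
    positive: CellModel,
    negative: CellModel,
    n_cells: int,
    probe_set: str = "ALK",
) -> list[Condition]:
    """Mixture series: each condition holds ``fraction`` positive cells.

    Mirrors a sensitivity titration of translocation-positive cells diluted
    into a negative population (fractions from 0 to 1).
    """
    conds = []
    for f in fractions:
        if not (0 <= f <= 1):
            raise ConfigurationError("titration fractions must be in [0, 1]")
        label = f"T{f:.4f}".replace(".", "p")
        model = (positive if f == 1.0 else negative if f == 0.0
                 else [(positive, f), (negative, 1.0 - f)])
        conds.append(Condition(label=label, cell_model=model, n_cells=n_cells,
                               cell_line="TITR", probe_set=probe_set))
    return conds


def spot_tables_from_ground_truth(
    gt: GroundTruth,
    jitter_px: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert ground truth into the analysis-stage table dialect.

    Returns ``(nuclei, spots)`` tables in the same layout the image-analysis
    stage emits, so simulated data can enter the pipeline mid-way without
    rendering images. ``jitter_px`` adds isotropic Gaussian localization
    error to every spot (emulating detection noise on real images).
    """
    if jitter_px > 0 and rng is None:
        rng = np.random.default_rng(0)
    nuclei = pd.DataFrame(
        {
            "field_id": gt.cells["field_id"],
            "nucleus_id": gt.cells["cell_id"],
            "cx_px": gt.cells["cx_px"],
            "cy_px": gt.cells["cy_px"],
            "area_px2": np.pi * gt.cells["a_px"] * gt.cells["b_px"],
            "roundness": np.minimum(gt.cells["a_px"], gt.cells["b_px"])
            / np.maximum(gt.cells["a_px"], gt.cells["b_px"]),
            "touches_border": False,
            "excluded": False,
            "exclusion_reason": "",
        }
    )
    x = gt.spots["x_px"].to_numpy(dtype=float, copy=True)
    y = gt.spots["y_px"].to_numpy(dtype=float, copy=True)
    if jitter_px > 0:
        x = x + rng.normal(0, jitter_px, size=x.shape)
        y = y + rng.normal(0, jitter_px, size=y.shape)
    spots = pd.DataFrame(
        {
            "field_id": gt.spots["field_id"],
            "nucleus_id": gt.spots["cell_id"],
            "spot_id": np.arange(len(gt.spots)),
            "channel": gt.spots["channel"],
            "x_px": x,
            "y_px": y,
            "peak_intensity": 1.0,
            "integrated_intensity": 1.0,
        }
    )
    return nuclei, spots
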