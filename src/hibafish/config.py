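"""Parameter containers shared by the simulator and the analysis pipeline.

All spatial parameters are expressed either in pixels (detection, thresholds)
or in micrometers (physical offsets); every container records which. The
acquisition geometry defaults emulate a 40x confocal screen: 320 nm pixels
(camera binning 2) and seven z-planes spaced 1.5 um apart, with DAPI plus
three FISH channels (Green/Alexa488, Red/Alexa568, FarRed/Cy5) acquired
sequentially.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: Canonical channel roles, in acquisition order.
CHANNEL_ROLES = ("DAPI", "Green", "Red", "FarRed")
#: FISH channels only (spot detection runs on these).
FISH_CHANNELS = ("Green", "Red", "FarRed")


class ConfigurationError(ValueError):
    """Raised when a parameter container violates its invariants."""


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition geometry shared by the simulator and the analysis.

    Parameters
    ----------
    pixel_size_um
        Lateral size of one pixel in micrometers.
    z_planes
        Number of confocal planes per stack.
    z_spacing_um
        Axial distance between consecutive planes.
    field_shape_px
        ``(height, width)`` of one field of view in pixels.
    channels
        Ordered channel roles; must contain each of DAPI, Green, Red and
        FarRed exactly once.
    """

    pixel_size_um: float = 0.32
    z_planes: int = 7
    z_spacing_um: float = 1.5
    field_shape_px: tuple[int, int] = (512, 512)
    channels: tuple[str, ...] = CHANNEL_ROLES

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if self.z_planes < 1:
            raise ConfigurationError("z_planes must be >= 1")
        if self.z_spacing_um <= 0:
            raise ConfigurationError("z_spacing_um must be positive")
        if len(self.field_shape_px) != 2 or any(s < 1 for s in self.field_shape_px):
            raise ConfigurationError("field_shape_px must be a positive (height, width)")
        object.__setattr__(self, "field_shape_px", tuple(self.field_shape_px))
        object.__setattr__(self, "channels", tuple(self.channels))
        if sorted(self.channels) != sorted(CHANNEL_ROLES):
            raise ConfigurationError(
                f"channels must contain each of {CHANNEL_ROLES} exactly once, got {self.channels}"
            )

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_size_um

    def px_to_um(self, px: float) -> float:
        return px * self.pixel_size_um


@dataclass(frozen=True)
class NoiseSpec:
    """Camera/photon noise model for simulated stacks.

    ``background`` is a constant offset (counts) added to every voxel before
    shot noise; ``read_sigma`` is the Gaussian read-noise s.d. in counts;
    ``poisson`` toggles Poisson (shot) noise on the offset signal.
    """

    background: float = 100.0
    read_sigma: float = 2.0
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.background < 0 or self.read_sigma < 0:
            raise ConfigurationError("noise levels must be non-negative")

    @classmethod
    def none(cls) -> "NoiseSpec":
        """Noise-free imaging: no background, no shot noise, no read noise."""
        return cls(background=0.0, read_sigma=0.0, poisson=False)

    @property
    def is_none(self) -> bool:
        return self.background == 0 and self.read_sigma == 0 and not self.poisson


@dataclass(frozen=True)
class CellModel:
    """Allele configuration and event probabilities for one simulated cell type.

    Gene A is the locus probed by the two-color break-apart pair (Green +
    Red); gene B is the putative translocation partner probed in FarRed.
    A break-apart locus whose Red and Green probes separate is "broken"; a
    broken locus whose Red probe is joined to a gene-B partner is
    "translocated". Offsets are the means of Rayleigh-distributed 2D
    separations, in micrometers.
    """

    name: str = "cell"
    n_alleles_A: int = 3
    n_alleles_B: int = 2
    p_break: float = 0.0
    p_transloc_given_break: float = 0.0
    intact_offset_um: float = 0.32
    broken_offset_um: float = 3.2
    proximity_offset_um: float = 0.32

    def __post_init__(self) -> None:
        if not (0 <= self.p_break <= 1):
            raise ConfigurationError("p_break must be in [0, 1]")
        if not (0 <= self.p_transloc_given_break <= 1):
            raise ConfigurationError("p_transloc_given_break must be in [0, 1]")
        if self.n_alleles_A < 0 or self.n_alleles_B < 0:
            raise ConfigurationError("allele counts must be >= 0")
        if self.broken_offset_um <= self.intact_offset_um:
            raise ConfigurationError("broken_offset_um must exceed intact_offset_um")

    @classmethod
    def from_cell_rates(
        cls,
        breakage_rate: float,
        translocation_rate: float = 0.0,
        **kwargs,
    ) -> "CellModel":
        """Build a model whose per-cell event rates match the targets.

        ``breakage_rate`` is the probability that a cell carries at least one
        broken gene-A allele; with ``k = n_alleles_A`` independent alleles the
        per-allele probability solves ``1 - (1 - p)**k = rate``. The
        translocation rate is matched in expectation via
        ``p_transloc_given_break = translocation_rate / breakage_rate``
        (exact for cells with at most one broken allele, which dominates at
        the low rates this is used for).
        """
        if not (0 <= translocation_rate <= breakage_rate <= 1):
            raise ConfigurationError("need 0 <= translocation_rate <= breakage_rate <= 1")
        k = kwargs.pop("n_alleles_A", cls.n_alleles_A)
        p_break = 1.0 - (1.0 - breakage_rate) ** (1.0 / k) if k else 0.0
        p_t = translocation_rate / breakage_rate if breakage_rate > 0 else 0.0
        return cls(n_alleles_A=k, p_break=p_break, p_transloc_given_break=p_t, **kwargs)


@dataclass(frozen=True)
class RenderParams:
    """Optical/photometric rendering parameters for the simulator."""

    spot_sigma_px: float = 1.0          # lateral PSF s.d. of one FISH spot
    spot_sigma_z_planes: float = 0.75   # axial PSF s.d., in plane units
    spot_amplitude: float = 500.0       # peak counts of one spot at focus
    dapi_amplitude: float = 300.0       # nuclear DAPI plateau, counts
    dapi_edge_sigma_px: float = 1.5     # smoothing of the nuclear edge
    nucleus_min_radius_px: float = 14.0
    nucleus_max_radius_px: float = 22.0
    nucleus_margin_px: float = 6.0      # clearance between nuclei and to the border
    allele_min_separation_px: float = 8.0  # territory-like spacing of same-channel loci

    def __post_init__(self) -> None:
        if self.spot_sigma_px <= 0 or self.spot_amplitude <= 0:
            raise ConfigurationError("spot rendering parameters must be positive")
        if self.nucleus_min_radius_px > self.nucleus_max_radius_px:
            raise ConfigurationError("nucleus radius range inverted")


@dataclass(frozen=True)
class SegmentationParams:
    """DAPI nucleus segmentation and morphology filters.

    Nuclei outside ``[min_area_px, max_area_px]`` or below ``min_roundness``
    (roundness = 4*pi*A/P^2), and nuclei touching the field border, are
    flagged excluded and take no further part in the analysis.
    """

    smooth_sigma_px: float = 2.0
    min_area_px: float = 500.0
    max_area_px: float = 15000.0
    min_roundness: float = 0.5
    split_touching: bool = False  # optional watershed splitting

    def __post_init__(self) -> None:
        if self.min_area_px <= 0 or self.max_area_px < self.min_area_px:
            raise ConfigurationError("invalid nucleus area range")
        if not (0 < self.min_roundness <= 1):
            raise ConfigurationError("min_roundness must be in (0, 1]")


@dataclass(frozen=True)
class SpotParams:
    """FISH spot detection parameters (difference-of-Gaussians pipeline)."""

    sigma_px: float = 1.0          # spot scale for the band-pass
    dog_ratio: float = 1.6         # sigma ratio of the two Gaussians
    threshold_k: float = 10.0      # peaks must exceed median + k*MAD of the DoG
    min_separation_px: int = 3     # minimum peak-to-peak distance; brighter wins
    centroid_halfwidth_px: int = 2 # window half-width for sub-pixel centroids

    def __post_init__(self) -> None:
        if self.sigma_px <= 0 or self.dog_ratio <= 1:
            raise ConfigurationError("sigma_px must be > 0 and dog_ratio > 1")
        if self.threshold_k < 0 or self.min_separation_px < 1:
            raise ConfigurationError("invalid spot threshold/separation")


@dataclass(frozen=True)
class Thresholds:
    """Distance thresholds for event calling.

    A Red signal farther than ``proximity_px`` from every Green signal is a
    breakage event; a breakage-event Red signal within ``proximity_px`` of a
    FarRed signal is a translocation event. Distances at exactly the
    threshold count as proximal.
    """

    proximity_px: float = 4.0
    pixel_size_um: float = 0.32

    def __post_init__(self) -> None:
        if self.proximity_px <= 0:
            raise ConfigurationError("proximity_px must be positive")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")

    @property
    def proximity_um(self) -> float:
        return self.proximity_px * self.pixel_size_um


@dataclass
class RunConfig:
    """End-to-end pipeline run configuration (serializable to YAML/JSON)."""

    input_dir: str = "."
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    spots: SpotParams = field(default_factory=SpotParams)
    thresholds: Thresholds = field(default_factory=Thresholds)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("imaging", ImagingConfig),
            ("segmentation", SegmentationParams),
            ("spots", SpotParams),
            ("thresholds", Thresholds),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


#: Cell types used throughout the examples and tests. The translocation-
#: negative line carries three gene-A and two gene-B alleles (modal counts);
#: the translocation-positive line carries four of each, with roughly half of
#: its gene-A alleles rearranged so that nearly every cell shows at least one
#: separated, partner-joined locus.
def negative_cell_model(**overrides) -> CellModel:
    kw = dict(name="negative", n_alleles_A=3, n_alleles_B=2,
              p_break=0.0, p_transloc_given_break=0.0)
    kw.update(overrides)
    return CellModel(**kw)


def positive_cell_model(**overrides) -> CellModel:
    kw = dict(name="positive", n_alleles_A=4, n_alleles_B=4,
              p_break=0.5, p_transloc_given_break=1.0)
    kw.update(overrides)
    return CellModel(**kw)
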