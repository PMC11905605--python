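"""Core domain containers for en face OCTA nonperfusion analysis.

The study objects are 3 x 3-mm macular OCT angiography scans rasterized on a
304 x 304 grid.  Each scan carries a co-registered pair of images -- the
angiographic (decorrelation) channel and the structural (reflectance) channel
-- for one anatomical slab, plus acquisition metadata: the device signal
strength index (SSI, 0-100), the ETDRS diabetic-retinopathy severity level of
the eye, and participant/eye/visit identifiers used for clustering in the
statistics layer.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

#: Default grid edge (A-lines per B-scan = B-scans per volume).
GRID = 304
#: Default field of view in mm.
FOV_MM = 3.0
#: Default pixel pitch in mm (3-mm field over 304 samples).
PIXEL_PITCH_MM = FOV_MM / GRID

#: ETDRS severity levels supported by the simulator; 10 = no retinopathy.
ETDRS_LEVELS = (10, 20, 35, 43, 47, 53, 61, 65, 71, 75, 81, 85)

#: Severity cutoffs: referable DR is ETDRS >= 35, vision-threatening >= 53.
REFERABLE_CUTOFF = 35
VISION_THREATENING_CUTOFF = 53

NONREFERABLE = "nonreferable"
REFERABLE = "referable"
VISION_THREATENING = "vision_threatening"
SEVERITY_GROUPS = (NONREFERABLE, REFERABLE, VISION_THREATENING)


class Slab(str, enum.Enum):
    """Anatomical slab of the en face projection.

    SVC = superficial vascular complex, ICP = intermediate capillary plexus,
    DCP = deep capillary plexus, INNER = the combined inner retina (union of
    the three plexuses).
    """

    SVC = "SVC"
    ICP = "ICP"
    DCP = "DCP"
    INNER = "INNER"


PLEXUSES = (Slab.SVC, Slab.ICP, Slab.DCP)


def severity_group(etdrs: int) -> str:
    """Map an ETDRS level to the study's three clinical severity groups."""
    if etdrs < REFERABLE_CUTOFF:
        return NONREFERABLE
    if etdrs < VISION_THREATENING_CUTOFF:
        return REFERABLE
    return VISION_THREATENING


@dataclass
class EnFaceScan:
    """One slab's co-registered angiographic + structural en face image pair."""

    angio: np.ndarray
    structure: np.ndarray
    slab: Slab
    ssi: float
    etdrs: int
    participant_id: str
    eye_id: str
    visit_index: int
    pixel_pitch_mm: float = PIXEL_PITCH_MM

    def __post_init__(self) -> None:
        self.slab = Slab(self.slab)
        if self.angio.shape != self.structure.shape:
            raise ValueError(
                f"angio shape {self.angio.shape} != structure shape "
                f"{self.structure.shape}"
            )
        if not (0.0 <= self.ssi <= 100.0):
            raise ValueError(f"ssi must lie in [0, 100], got {self.ssi}")
        if self.etdrs not in ETDRS_LEVELS:
            raise ValueError(f"unsupported ETDRS level {self.etdrs}")

    @property
    def severity_group(self) -> str:
        return severity_group(self.etdrs)

    @property
    def shape(self) -> tuple[int, int]:
        return self.angio.shape


@dataclass
class GroundTruth:
    """Simulator-side truth for one scan.

    ``npa_mask`` is the true nonperfusion area (foveal avascular zone plus any
    planted capillary-dropout lesions); ``vessel_mask`` is the perfused
    vasculature; ``shadow_mask`` marks artifact regions where both channels
    were attenuated.  Vessels and NPA are disjoint by construction.
    """

    npa_mask: np.ndarray
    vessel_mask: np.ndarray
    shadow_mask: np.ndarray
    fovea_center_px: tuple[float, float]
    fovea_radius_px: float

    def __post_init__(self) -> None:
        for name in ("npa_mask", "vessel_mask", "shadow_mask"):
            arr = getattr(self, name)
            if arr.dtype != bool:
                setattr(self, name, arr.astype(bool))
        if np.any(self.npa_mask & self.vessel_mask):
            raise ValueError("npa_mask and vessel_mask must be disjoint")


class Method(str, enum.Enum):
    """Provenance of an NPA mask."""

    RB = "RB"
    AI = "AI"
    MANUAL = "MANUAL"
    TRUTH = "TRUTH"


@dataclass
class NPAMask:
    """A binary nonperfusion map with physical area bookkeeping.

    ``exclusion``, when present, marks pixels that are ignored both for the
    area measurement and for agreement metrics (regions affected by artifacts
    in the manual-grading protocol).
    """

    mask: np.ndarray
    pixel_pitch_mm: float
    method: Method = Method.TRUTH
    exclusion: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        self.method = Method(self.method)
        if self.exclusion is not None:
            if self.exclusion.shape != self.mask.shape:
                raise ValueError("exclusion shape must match mask shape")
            if self.exclusion.dtype != bool:
                self.exclusion = self.exclusion.astype(bool)

    @property
    def included(self) -> np.ndarray:
        """Mask restricted to evaluable (non-excluded) pixels."""
        if self.exclusion is None:
            return self.mask
        return self.mask & ~self.exclusion

    @property
    def area_mm2(self) -> float:
        """NPA in mm^2: included pixel count times pixel pitch squared."""
        return float(np.count_nonzero(self.included)) * self.pixel_pitch_mm**2


def disk_mask(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> np.ndarray:
    """Boolean disk of the given radius (px) on a grid of ``shape``."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
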