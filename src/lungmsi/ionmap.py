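"""Ion-intensity maps: extraction, normalization, tissue masking, thresholding.

Each ion image is built by summing, per pixel, all centroid intensities
within a tolerance window around a target m/z (0.005 Da for the small-
molecule targets, 1 Da for the SP-C lipopeptide).  The drug image is divided
pixel-wise by the internal-standard image (derivatized triamcinolone,
568.283 m/z), which cancels pixel-to-pixel ionization efficiency.  Tissue is
located from the heme ion (616.176 m/z), which only ionizes where tissue is
present, and a detection threshold for the drug is taken as a high quantile
of the pooled on-tissue intensities of budesonide-free control sections.

Off-tissue and dropped pixels are *missing* (NaN), never zero, so every
downstream statistic runs over tissue pixels only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .imzml import MSIDataset, monoisotopic_mass

__all__ = [
    "IonTarget",
    "IonImage",
    "TissueMask",
    "DEFAULT_TARGETS",
    "extract_ion_image",
    "normalize_image",
    "tissue_mask_from_heme",
    "control_threshold",
    "above_threshold_map",
    "log_intensity_values",
]


@dataclass(frozen=True)
class IonTarget:
    """A registered ion to extract: name, target m/z and window half-width."""

    name: str
    target_mz: float
    tolerance_da: float
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.tolerance_da <= 0:
            raise ValueError(f"{self.name}: tolerance_da must be positive")
        if self.formula is not None:
            computed = monoisotopic_mass(self.formula, charge=1)
            if abs(computed - self.target_mz) > 2 * self.tolerance_da:
                raise ValueError(
                    f"{self.name}: formula {self.formula} gives m/z "
                    f"{computed:.4f}, not within 2x tolerance of {self.target_mz}"
                )


#: The four study targets: GirP-derivatized budesonide, the derivatized
#: triamcinolone internal standard, the heme tissue marker, and porcine SP-C.
DEFAULT_TARGETS: dict[str, IonTarget] = {
    "budesonide": IonTarget("budesonide", 564.308, 0.005),
    "internal_standard": IonTarget("internal_standard", 568.283, 0.005),
    "heme": IonTarget("heme", 616.176, 0.005, formula="C34H32FeN4O4"),
    "spc": IonTarget("spc", 4188.0, 1.0),
}


@dataclass
class IonImage:
    """A 2D intensity raster for one ion target; NaN marks missing pixels."""

    values: np.ndarray  # float64, shape (rows, cols), NaN = missing
    pixel_pitch_um: float
    target: IonTarget
    section_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def finite_values(self) -> np.ndarray:
        v = self.values
        return v[np.isfinite(v)]


@dataclass
class TissueMask:
    """Boolean on-tissue grid derived from the heme channel."""

    on_tissue: np.ndarray  # bool, shape (rows, cols)
    source: str = "heme"

    @property
    def shape(self) -> tuple[int, int]:
        return self.on_tissue.shape

    @property
    def n_pixels(self) -> int:
        return int(self.on_tissue.sum())


def extract_ion_image(dataset: MSIDataset, target: IonTarget) -> IonImage:
    """Sum per-pixel centroid intensities within ``target_mz ± tolerance_da``.

    Pixels absent from the dataset are missing (NaN).  The window must
    overlap the dataset's declared m/z range.
    """
    lo, hi = dataset.mz_range
    wlo, whi = target.target_mz - target.tolerance_da, target.target_mz + target.tolerance_da
    if whi < lo or wlo > hi:
        raise ValueError(
            f"target {target.name} window [{wlo:.4f}, {whi:.4f}] lies outside "
            f"dataset m/z range [{lo}, {hi}]"
        )
    values = np.full(dataset.grid_shape, np.nan)
    for (x, y), spec in dataset.pixels.items():
        mz = spec.mz
        i0 = np.searchsorted(mz, wlo, side="left")
        i1 = np.searchsorted(mz, whi, side="right")
        values[y, x] = float(spec.intensity[i0:i1].sum()) if i1 > i0 else 0.0
    return IonImage(values, dataset.pixel_pitch_um, target, dataset.section_id)


def normalize_image(analyte: IonImage, reference: IonImage) -> tuple[IonImage, int]:
    """Pixel-wise analyte/reference ratio.

    Pixels where the reference is missing or ≤ 0 become missing; the second
    return value is the count of pixels dropped that way (on top of pixels
    already missing in the analyte).
    """
    if analyte.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: analyte {analyte.shape} vs reference {reference.shape}"
        )
    a, r = analyte.values, reference.values
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(r > 0, a / r, np.nan)
    dropped = int(np.sum(np.isfinite(a) & ~(r > 0)))
    return IonImage(out, analyte.pixel_pitch_um, analyte.target, analyte.section_id), dropped


def tissue_mask_from_heme(heme: IonImage, min_fraction: float = 0.05) -> TissueMask:
    """Tissue mask: pixels whose heme intensity exceeds ``min_fraction`` of
    the median positive heme intensity; only the largest 8-connected
    component is kept (stray off-tissue ionization is discarded)."""
    v = heme.values
    positive = v[np.isfinite(v) & (v > 0)]
    if positive.size == 0:
        raise ValueError("heme image has no positive signal; no tissue detectable")
    cut = min_fraction * float(np.median(positive))
    raw = np.isfinite(v) & (v > cut)
    labels, n = ndimage.label(raw, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("no tissue pixels above the heme cut")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return TissueMask(labels == keep, source=heme.target.name)


def control_threshold(
    control_images: list[IonImage],
    masks: list[TissueMask],
    quantile: float = 0.99,
) -> float:
    """Detection threshold from budesonide-free controls.

    The given quantile (linear-interpolation convention) of the pooled
    on-tissue normalized intensities across all control sections.
    """
    if not control_images:
        raise ValueError("at least one control image is required")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    pool = []
    for img, mask in zip(control_images, masks):
        v = img.values[mask.on_tissue]
        pool.append(v[np.isfinite(v)])
    pooled = np.concatenate(pool) if pool else np.array([])
    if pooled.size == 0:
        raise ValueError("pooled control intensity set is empty")
    return float(np.quantile(pooled, quantile, method="linear"))


def above_threshold_map(image: IonImage, mask: TissueMask, threshold: float) -> IonImage:
    """Keep on-tissue values strictly above the threshold; everything else
    becomes missing."""
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    v = image.values
    keep = mask.on_tissue & np.isfinite(v) & (v > threshold)
    out = np.where(keep, v, np.nan)
    return IonImage(out, image.pixel_pitch_um, image.target, image.section_id)


def log_intensity_values(image: IonImage, mask: TissueMask) -> tuple[np.ndarray, int]:
    """Natural logs of the strictly positive on-tissue intensities.

    Non-positive (or missing) on-tissue values are excluded; the second
    return value tallies the excluded non-positive finite values.
    """
    v = image.values[mask.on_tissue]
    finite = v[np.isfinite(v)]
    positive = finite[finite > 0]
    return np.log(positive), int(finite.size - positive.size)
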