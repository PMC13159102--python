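"""Condensate image quantification.

Re-implements a particle-analysis pipeline: global threshold (Otsu by
default), 8-connected components, a minimum-area filter, per-droplet
area/intensity statistics, the condensate/dilute-phase partition
coefficient and phase-diagram classification over a condition grid.

Conventions: the dilute phase is the image minus a 2-pixel dilation ring
around the droplet mask.  The partition coefficient is the raw ratio of
phase means by default; an optional camera-offset subtraction (explicit
value, or a low-percentile estimate for images with true dark regions) is
available but not applied by default, since a percentile of a shot-noise
limited dilute phase underestimates nothing but the noise floor and badly
inflates the ratio.  Droplets touching the image border are counted for
density but excluded from size statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .errors import GridError

MIN_AREA_PX = 4
DILUTE_EXCLUSION_PX = 2
BACKGROUND_PERCENTILE = 1.0
#: Otsu threshold rejected (no droplets) when the foreground/background mean
#: ratio falls below this — an automatic split of a unimodal noise histogram
#: otherwise floods the image with spurious particles
MIN_OTSU_CONTRAST = 1.5


@dataclass
class DropletTable:
    """Per-droplet measurements plus image-level summaries."""

    droplets: pd.DataFrame          # id, area_um2, equiv_diameter_um, mean_intensity, on_border
    count: int                      # all droplets, border-touching included
    density_per_100um2: float
    dilute_mean_intensity: float
    mask: np.ndarray                # boolean droplet mask
    pixel_size: float               # µm


def _saturated(image: np.ndarray) -> bool:
    if np.issubdtype(image.dtype, np.integer):
        return bool(np.all(image == np.iinfo(image.dtype).max))
    return False


def detect_droplets(
    image: np.ndarray,
    pixel_size: float,
    threshold_method: str | float = "otsu",
    min_area_px: int = MIN_AREA_PX,
) -> DropletTable:
    """Detect droplets in a single-channel 2-D image.

    ``threshold_method`` is ``"otsu"`` or an explicit intensity threshold.
    A constant (blank) image yields zero droplets; an empty or fully
    saturated image is an error.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {image.shape}")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if _saturated(image):
        raise ValueError("image is fully saturated")

    img = image.astype(float)
    area_um2_px = pixel_size**2
    field_area_um2 = image.size * area_um2_px

    if np.ptp(img) == 0:
        mask = np.zeros(image.shape, dtype=bool)
    elif threshold_method == "otsu":
        thr = threshold_otsu(img)
        mask = img > thr
        # contrast guard: a unimodal (droplet-free) histogram still yields an
        # Otsu split, but its two classes have nearly equal means
        fg, bg = img[mask], img[~mask]
        if not mask.any() or not (~mask).any() or (
            np.mean(bg) > 0 and np.mean(fg) / np.mean(bg) < MIN_OTSU_CONTRAST
        ):
            mask = np.zeros(image.shape, dtype=bool)
    else:
        mask = img > float(threshold_method)

    lab = label(mask, connectivity=2)  # 8-connected
    rows = []
    keep_mask = np.zeros_like(mask)
    h, w = image.shape
    for rp in regionprops(lab, intensity_image=img):
        if rp.area < min_area_px:
            continue
        minr, minc, maxr, maxc = rp.bbox
        on_border = minr == 0 or minc == 0 or maxr == h or maxc == w
        rows.append(
            {
                "id": rp.label,
                "area_um2": rp.area * area_um2_px,
                "equiv_diameter_um": rp.equivalent_diameter_area * pixel_size,
                "mean_intensity": rp.intensity_mean,
                "on_border": on_border,
            }
        )
        keep_mask[lab == rp.label] = True

    df = pd.DataFrame(
        rows, columns=["id", "area_um2", "equiv_diameter_um", "mean_intensity", "on_border"]
    )
    dilute = ~binary_dilation(keep_mask, structure=disk(DILUTE_EXCLUSION_PX))
    dilute_mean = float(np.mean(img[dilute])) if np.any(dilute) else float("nan")
    return DropletTable(
        droplets=df,
        count=len(df),
        density_per_100um2=100.0 * len(df) / field_area_um2,
        dilute_mean_intensity=dilute_mean,
        mask=keep_mask,
        pixel_size=pixel_size,
    )


def partition_coefficient(
    image: np.ndarray,
    droplet_mask: np.ndarray,
    background: float | str = 0.0,
) -> float:
    """Mean condensate intensity over mean dilute-phase intensity.

    ``background`` is a camera offset subtracted from both means before the
    ratio: a number (default 0, the raw ratio), or ``"percentile"`` to
    estimate it as the image's 1st percentile — only meaningful for images
    that contain genuinely dark regions.
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(droplet_mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape must match image")
    if not mask.any():
        raise ValueError("droplet mask is empty")
    if mask.all():
        raise ValueError("droplet mask covers the full frame")
    dilute = ~binary_dilation(mask, structure=disk(DILUTE_EXCLUSION_PX))
    if not dilute.any():
        raise ValueError("no dilute-phase pixels outside the dilated droplet mask")
    inside = float(np.mean(img[mask]))
    outside = float(np.mean(img[dilute]))
    if outside <= 0:
        raise ValueError("dilute-phase mean intensity is non-positive")
    bg = (
        float(np.percentile(img, BACKGROUND_PERCENTILE))
        if background == "percentile"
        else float(background)
    )
    if outside - bg <= 0:
        raise ValueError("dilute-phase mean does not exceed the background estimate")
    return (inside - bg) / (outside - bg)


# ---------------------------------------------------------------------- #
# phase diagram


@dataclass
class PhaseDiagram:
    protein_values: np.ndarray
    salt_values: np.ndarray
    counts: np.ndarray              # (n_protein, n_salt)
    has_droplets: np.ndarray        # bool, counts >= min_count
    boundary: np.ndarray            # bool, droplet cells adjacent to no-droplet cells
    min_count: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.protein_values):
            for j, s in enumerate(self.salt_values):
                rows.append(
                    {
                        "protein_conc": p,
                        "salt_mM": s,
                        "droplet_count": int(self.counts[i, j]),
                        "droplets": bool(self.has_droplets[i, j]),
                        "boundary": bool(self.boundary[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def classify_phase_grid(counts: pd.DataFrame, min_count: int = 5) -> PhaseDiagram:
    """Classify a (protein_conc, salt_mM, droplet_count) grid.

    A cell has droplets when its count reaches ``min_count``; boundary cells
    are droplet cells with at least one 4-neighbor no-droplet cell.  The
    grid must be complete and rectangular.
    """
    required = {"protein_conc", "salt_mM", "droplet_count"}
    if not required.issubset(counts.columns):
        raise GridError(f"grid table needs columns {sorted(required)}")
    proteins = np.array(sorted(counts["protein_conc"].unique()))
    salts = np.array(sorted(counts["salt_mM"].unique()))
    grid = np.full((len(proteins), len(salts)), -1, dtype=int)
    for _, row in counts.iterrows():
        i = int(np.searchsorted(proteins, row["protein_conc"]))
        j = int(np.searchsorted(salts, row["salt_mM"]))
        grid[i, j] = int(row["droplet_count"])
    missing = [
        (proteins[i], salts[j])
        for i in range(len(proteins))
        for j in range(len(salts))
        if grid[i, j] < 0
    ]
    if missing:
        raise GridError(f"incomplete condition grid; missing cells: {missing}")
    has = grid >= min_count
    boundary = np.zeros_like(has)
    padded = np.pad(has, 1, constant_values=True)  # outside neighbors do not create boundary
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neighbor = padded[1 + di : 1 + di + has.shape[0], 1 + dj : 1 + dj + has.shape[1]]
        boundary |= has & ~neighbor
    return PhaseDiagram(
        protein_values=proteins,
        salt_values=salts,
        counts=grid,
        has_droplets=has,
        boundary=boundary,
        min_count=min_count,
    )


def render_phase_diagram(diagram: PhaseDiagram, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for i, p in enumerate(diagram.protein_values):
        for j, s in enumerate(diagram.salt_values):
            color = "tab:red" if diagram.has_droplets[i, j] else "tab:blue"
            marker = "s" if diagram.boundary[i, j] else "o"
            ax.scatter(s, p, c=color, marker=marker, s=60)
    ax.set_xlabel("salt (mM)")
    ax.set_ylabel("protein concentration")
    ax.set_title("red: droplets, blue: none; squares: boundary")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
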