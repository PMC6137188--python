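"""Single-cell quantification: membrane segmentation, scar/foci calling, relation.

The pipeline mirrors a classic cell-image workflow for ring-stained yeast:

1. ``enhance_circular`` — close the membrane annuli into solid discs
   (greyscale closing at the largest expected cell scale) and flatten the
   background (white top-hat), so cells become compact bright blobs.
2. ``segment_cells`` — adaptive (windowed) Otsu two-class threshold, scaled
   by a correction factor that keeps background noise from being called
   cells; connected components are declumped by shape (distance-transform
   watershed with h-maxima seed suppression), filtered to the admissible
   equivalent-diameter range, and border-touching objects are discarded.
3. ``detect_puncta`` — bud scars (and GFP foci) are called on the *raw*
   channel inside each cell's dilated mask with a robust per-object
   background threshold (trim the intensity extremes, then mean + k*SD,
   times a correction factor).
4. ``relate`` — each punctum is attributed to the nearest containing cell
   and the per-cell measurement table is assembled.

All size parameters are exposed; defaults follow the 0.1 um/px calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology, segmentation
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import ConfigError

__all__ = [
    "SegmentationParams",
    "SegmentedCell",
    "SegmentationResult",
    "enhance_circular",
    "multiscale_ring_response",
    "adaptive_otsu_threshold",
    "segment_cells",
    "robust_background_threshold",
    "detect_puncta",
    "relate",
    "measure_scene",
    "match_to_ground_truth",
    "DEFAULT_SEGMENTATION",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the quantification pipeline.

    ``threshold_correction_cells`` multiplies the adaptive Otsu threshold
    (raise to suppress background pickup); ``threshold_correction_puncta``
    multiplies the robust per-object background threshold.  Both have
    sensible validated ranges around their defaults of 2.0 and 1.5.
    """

    d_min_um: float = 1.5
    d_max_um: float = 15.0
    pixel_size_um: float = 0.1
    threshold_correction_cells: float = 2.0
    threshold_correction_puncta: float = 1.5
    adaptive_window_px: int = 200
    declump_h_px: float = 2.0
    dilation_px: float = 2.0
    trim_fraction: float = 0.05
    robust_sd_mult: float = 2.0
    min_punctum_px: int = 3
    min_region_px: int = 20
    edge_erosion_px: float = 2.0
    border_policy: str = "discard"

    def __post_init__(self) -> None:
        if not (self.d_min_um < self.d_max_um):
            raise ConfigError("need d_min < d_max")
        if not (1.5 <= self.threshold_correction_cells <= 2.5):
            raise ConfigError("threshold_correction_cells valid range is 1.5-2.5")
        if not (1.0 <= self.threshold_correction_puncta <= 2.0):
            raise ConfigError("threshold_correction_puncta valid range is 1.0-2.0")
        if not (0.0 <= self.trim_fraction < 0.5):
            raise ConfigError("trim_fraction must lie in [0, 0.5)")
        if self.border_policy != "discard":
            raise ConfigError("only the 'discard' border policy is supported")

    @property
    def d_min_px(self) -> float:
        return self.d_min_um / self.pixel_size_um

    @property
    def d_max_px(self) -> float:
        return self.d_max_um / self.pixel_size_um


DEFAULT_SEGMENTATION = SegmentationParams()


def _disk(radius: float):
    return morphology.disk(max(int(round(radius)), 1), decomposition="sequence")



def _fill_ring_interiors(img: np.ndarray) -> np.ndarray:
    """Greyscale hole fill: raise dark basins not connected to the border."""
    seed = np.full_like(img, img.max())
    seed[0, :] = img[0, :]
    seed[-1, :] = img[-1, :]
    seed[:, 0] = img[:, 0]
    seed[:, -1] = img[:, -1]
    return morphology.reconstruction(seed, img, method="erosion")

def enhance_circular(
    image: np.ndarray, params: SegmentationParams = DEFAULT_SEGMENTATION
) -> np.ndarray:
    """Turn ring-stained cells into compact bright blobs on a flat background.

    Greyscale hole filling (morphological reconstruction by erosion from
    the image border) raises the dark annulus interiors to the ring level
    without ever bridging separate cells; a white top-hat with a disc
    larger than any admissible cell then removes the background pedestal.
    A constant image maps to (numerically) zero.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ConfigError("enhance_circular expects a single-channel 2-D image")
    filled = _fill_ring_interiors(img)
    background = morphology.opening(filled, _disk(params.d_max_px * 0.75))
    return np.clip(filled - background, 0.0, None)


def multiscale_ring_response(
    image: np.ndarray,
    scales_px: np.ndarray | list[float],
    params: SegmentationParams = DEFAULT_SEGMENTATION,
) -> dict[float, np.ndarray]:
    """Scale-normalised blob response of the ring-filled image per scale.

    For each target radius r the response is ``-sigma^2 * LoG`` at
    ``sigma = r / sqrt(2)``; a ring of radius r responds maximally at its
    matched scale, which is what makes the bank scale-selective.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ConfigError("expected a 2-D image")
    filled = _fill_ring_interiors(img)
    out: dict[float, np.ndarray] = {}
    for r in scales_px:
        sigma = float(r) / math.sqrt(2.0)
        out[float(r)] = -(sigma**2) * ndimage.gaussian_laplace(filled, sigma)
    return out


def adaptive_otsu_threshold(
    image: np.ndarray, window_px: int, correction: float = 1.0
) -> np.ndarray:
    """Per-window Otsu thresholds, bilinearly interpolated to a full map.

    Each window is thresholded at the geometric mean of its two Otsu
    classes (the log-scale Otsu placement that is standard for
    fluorescence, where the background class is tight and the signal
    class spans a decade).  Windows without dynamic range inherit the
    global value.  The map is multiplied by ``correction``.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if window_px > max(h, w):
        raise ConfigError("adaptive window is larger than the image")

    def log_otsu(arr: np.ndarray) -> float:
        """Threshold at the geometric mean of the two Otsu classes.

        Equivalent to an Otsu split on log intensities (the standard
        fluorescence choice: the background class is tight, the signal
        class spans a decade); unlike a literal log transform it is
        exactly scale-covariant, so 8-bit, 16-bit and float renderings
        of the same scene threshold identically.
        """
        t = threshold_otsu(arr)
        lo = arr[arr <= t]
        hi = arr[arr > t]
        if hi.size == 0 or lo.size == 0:
            return float(t)
        mu1 = float(hi.mean())
        mu0 = max(float(lo.mean()), 1e-4 * mu1)
        return math.sqrt(mu0 * mu1)

    ny = max(1, round(h / window_px))
    nx = max(1, round(w / window_px))
    glob = log_otsu(img) if np.ptp(img) > 0 else 0.0
    grid = np.full((ny, nx), glob)
    for iy in range(ny):
        for ix in range(nx):
            tile = img[
                iy * h // ny : (iy + 1) * h // ny, ix * w // nx : (ix + 1) * w // nx
            ]
            if np.ptp(tile) > 0:
                grid[iy, ix] = log_otsu(tile)
    if ny == 1 and nx == 1:
        tmap = np.full((h, w), grid[0, 0])
    else:
        tmap = ndimage.zoom(grid, (h / ny, w / nx), order=1, grid_mode=True, mode="nearest")
        tmap = tmap[:h, :w]
    return tmap * correction


@dataclass(frozen=True)
class SegmentedCell:
    """One retained cell object."""

    label: int
    centroid: tuple[float, float]  # (row, col)
    area_px: int
    equivalent_diameter_um: float
    touches_border: bool


@dataclass
class SegmentationResult:
    """Label image plus per-cell records; border/size-filtered labels are 0."""

    labels: np.ndarray
    cells: list[SegmentedCell]
    n_raw_objects: int
    n_discarded_border: int
    n_discarded_size: int

    @property
    def retained_labels(self) -> list[int]:
        return [c.label for c in self.cells]


def segment_cells(
    enhanced: np.ndarray, params: SegmentationParams = DEFAULT_SEGMENTATION
) -> SegmentationResult:
    """Adaptive-Otsu segmentation with shape declumping and border discard."""
    img = np.asarray(enhanced, dtype=float)
    tmap = adaptive_otsu_threshold(
        img, params.adaptive_window_px, params.threshold_correction_cells
    )
    binary = img > tmap
    binary = ndimage.binary_fill_holes(binary)
    if params.edge_erosion_px > 0:
        # compensate the PSF halo the threshold admits around each cell
        # (also clears speckle the size filter would otherwise keep)
        binary = morphology.erosion(
            binary, morphology.disk(int(round(params.edge_erosion_px)))
        )
    min_area = math.pi / 4.0 * (0.7 * params.d_min_px) ** 2
    binary = morphology.remove_small_objects(binary, max_size=max(int(min_area) - 1, 0))

    # declump by shape: watershed of the distance transform, seeds from
    # h-maxima so shallow necks split but single cells stay whole
    dist = ndimage.distance_transform_edt(binary)
    hmax = morphology.h_maxima(dist, params.declump_h_px)
    markers = cc_label(hmax)
    if markers.max() == 0:
        labels = cc_label(binary)
    else:
        labels = segmentation.watershed(-dist, markers=markers, mask=binary)
    n_raw = int(labels.max())

    h, w = labels.shape
    cells: list[SegmentedCell] = []
    n_border = n_size = 0
    keep = np.zeros(n_raw + 1, dtype=bool)
    for rp in regionprops(labels):
        eq_d_um = rp.equivalent_diameter_area * params.pixel_size_um
        minr, minc, maxr, maxc = rp.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        if not (params.d_min_um <= eq_d_um <= params.d_max_um):
            n_size += 1
            continue
        if touches:
            n_border += 1
            continue
        keep[rp.label] = True
        cells.append(
            SegmentedCell(
                label=rp.label,
                centroid=tuple(rp.centroid),
                area_px=int(rp.area),
                equivalent_diameter_um=float(eq_d_um),
                touches_border=touches,
            )
        )
    clean = np.where(keep[labels], labels, 0)
    return SegmentationResult(
        labels=clean,
        cells=cells,
        n_raw_objects=n_raw,
        n_discarded_border=n_border,
        n_discarded_size=n_size,
    )


def robust_background_threshold(
    pixels: np.ndarray,
    correction: float,
    trim_fraction: float = 0.05,
    sd_mult: float = 2.0,
) -> float:
    """Robust per-object threshold: trim both intensity extremes, then
    ``(mean + sd_mult * SD) * correction`` of the trimmed set.

    Insensitive to the brightest ``trim_fraction`` of pixels by
    construction, which is what lets bright puncta sit inside the
    background region without inflating their own threshold.
    """
    px = np.sort(np.asarray(pixels, dtype=float).ravel())
    if px.size < 20:
        raise ValueError("need at least 20 pixels for a robust background estimate")
    lo = int(math.floor(px.size * trim_fraction))
    hi = px.size - lo
    core = px[lo:hi]
    return float((core.mean() + sd_mult * core.std()) * correction)


def _expanded_labels(seg: SegmentationResult, dilation_px: float) -> np.ndarray:
    return segmentation.expand_labels(seg.labels, distance=dilation_px)


def detect_puncta(
    raw: np.ndarray,
    seg: SegmentationResult,
    params: SegmentationParams = DEFAULT_SEGMENTATION,
    kind: str = "scar",
) -> pd.DataFrame:
    """Call puncta on a raw channel within each cell's dilated mask.

    Per cell, the robust background threshold is computed from the raw
    pixels of its (dilated) region; connected components above threshold
    and of at least ``min_punctum_px`` pixels become puncta.  Structures
    outside every cell mask are never reported.  Returns a DataFrame with
    columns ``cell_label``, ``y``, ``x``, ``intensity``, ``kind``.
    """
    img = np.asarray(raw, dtype=float)
    if img.shape != seg.labels.shape:
        raise ConfigError("channel and segmentation shapes differ")
    rows: list[dict] = []
    if not seg.cells:
        return pd.DataFrame(columns=["cell_label", "y", "x", "intensity", "kind"])
    expanded = _expanded_labels(seg, params.dilation_px)
    global_pixels = img[expanded > 0]
    global_thr = (
        robust_background_threshold(
            global_pixels,
            params.threshold_correction_puncta,
            params.trim_fraction,
            params.robust_sd_mult,
        )
        if global_pixels.size >= 20
        else math.inf
    )
    slices = ndimage.find_objects(expanded)
    for cell in seg.cells:
        sl = slices[cell.label - 1]
        if sl is None:  # pragma: no cover
            continue
        region = expanded[sl] == cell.label
        values = img[sl][region]
        if values.size >= max(20, params.min_region_px):
            thr = robust_background_threshold(
                values,
                params.threshold_correction_puncta,
                params.trim_fraction,
                params.robust_sd_mult,
            )
        else:  # tiny object: fall back to the global background estimate
            thr = global_thr
        above = (img[sl] > thr) & region
        lab = cc_label(above)
        for rp in regionprops(lab, intensity_image=img[sl]):
            if rp.area < params.min_punctum_px:
                continue
            cy, cx = rp.centroid_weighted
            rows.append(
                {
                    "cell_label": cell.label,
                    "y": cy + sl[0].start,
                    "x": cx + sl[1].start,
                    "intensity": float(rp.intensity_max),
                    "kind": kind,
                }
            )
    return pd.DataFrame(rows, columns=["cell_label", "y", "x", "intensity", "kind"])


def relate(
    puncta: pd.DataFrame,
    seg: SegmentationResult,
    params: SegmentationParams = DEFAULT_SEGMENTATION,
    channels: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assemble the per-cell measurement table.

    Each punctum is attributed to the cell whose dilated mask contains it
    (the dilation assigns boundary pixels to the nearest cell, which also
    resolves ties deterministically); puncta outside every dilated mask
    are dropped.  Diameters are reported in micrometres; per-channel mean
    intensities are added when ``channels`` is given.
    """
    expanded = _expanded_labels(seg, params.dilation_px) if len(puncta) else seg.labels
    counts: dict[int, dict[str, int]] = {c.label: {} for c in seg.cells}
    for row in puncta.itertuples(index=False):
        iy, ix = int(round(row.y)), int(round(row.x))
        if not (0 <= iy < expanded.shape[0] and 0 <= ix < expanded.shape[1]):
            continue
        lab = int(expanded[iy, ix])
        if lab == 0 or lab not in counts:
            continue  # punctum contained by no cell: dropped
        kind_counts = counts[lab]
        kind_counts[row.kind] = kind_counts.get(row.kind, 0) + 1
    records = []
    for cell in seg.cells:
        rec = {
            "cell_label": cell.label,
            "cy_px": cell.centroid[0],
            "cx_px": cell.centroid[1],
            "area_px": cell.area_px,
            "diameter_um": cell.equivalent_diameter_um,
            "scar_count": counts[cell.label].get("scar", 0),
            "foci_count": counts[cell.label].get("focus", 0),
        }
        records.append(rec)
    table = pd.DataFrame(
        records,
        columns=[
            "cell_label", "cy_px", "cx_px", "area_px",
            "diameter_um", "scar_count", "foci_count",
        ],
    )
    if channels:
        for name, img in channels.items():
            means = ndimage.labeled_comprehension(
                np.asarray(img, dtype=float),
                seg.labels,
                table["cell_label"].to_numpy(),
                np.mean,
                float,
                math.nan,
            ) if len(table) else []
            table[f"mean_{name}"] = means
    return table


def measure_scene(
    channels: dict[str, np.ndarray],
    params: SegmentationParams = DEFAULT_SEGMENTATION,
) -> pd.DataFrame:
    """Full pipeline on a scene's channels: segment, call puncta, relate.

    ``channels`` must contain "membrane" and "scars"; "gfp" is optional.
    """
    if "membrane" not in channels or "scars" not in channels:
        raise ConfigError("need 'membrane' and 'scars' channels")
    enhanced = enhance_circular(channels["membrane"], params)
    seg = segment_cells(enhanced, params)
    puncta = detect_puncta(channels["scars"], seg, params, kind="scar")
    if "gfp" in channels:
        foci = detect_puncta(channels["gfp"], seg, params, kind="focus")
        frames = [f for f in (puncta, foci) if len(f)]
        if frames:
            puncta = pd.concat(frames, ignore_index=True)
    return relate(puncta, seg, params, channels=channels)


def match_to_ground_truth(
    measurements: pd.DataFrame,
    ground_truth: pd.DataFrame,
    max_dist_px: float = 15.0,
) -> pd.DataFrame:
    """Greedily match measured cells to ground-truth cells by centre distance.

    Border-touching truth cells are excluded (the pipeline discards them
    by contract).  Returns the inner join with both diameters and scar
    counts, one row per matched pair.
    """
    truth = ground_truth[~ground_truth["touches_border"]].reset_index(drop=True)
    if len(measurements) == 0 or len(truth) == 0:
        return pd.DataFrame(
            columns=["cell_id", "cell_label", "dist_px", "diameter_um_true",
                     "diameter_um", "scars_true", "scar_count", "foci_true",
                     "foci_count"]
        )
    mc = measurements[["cy_px", "cx_px"]].to_numpy()
    tc = truth[["cy_px", "cx_px"]].to_numpy()
    d = np.hypot(mc[:, None, 0] - tc[None, :, 0], mc[:, None, 1] - tc[None, :, 1])
    pairs = []
    used_m: set[int] = set()
    used_t: set[int] = set()
    for idx in np.argsort(d, axis=None):
        i, j = divmod(idx, d.shape[1])
        if d[i, j] > max_dist_px:
            break
        if i in used_m or j in used_t:
            continue
        used_m.add(i)
        used_t.add(j)
        pairs.append((i, j, d[i, j]))
    rows = []
    for i, j, dist in pairs:
        m = measurements.iloc[i]
        t = truth.iloc[j]
        rows.append(
            {
                "cell_id": int(t["cell_id"]),
                "cell_label": int(m["cell_label"]),
                "dist_px": float(dist),
                "diameter_um_true": float(t["diameter_um"]),
                "diameter_um": float(m["diameter_um"]),
                "scars_true": int(t["scars"]),
                "scar_count": int(m["scar_count"]),
                "foci_true": int(t.get("hsp104_foci", 0)),
                "foci_count": int(m["foci_count"]),
            }
        )
    return pd.DataFrame(rows)
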