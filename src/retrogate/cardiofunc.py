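"""Cardiac-function readouts from per-phase reconstructions.

Given one reconstructed image per cardiac phase bin, this module segments
the contrast-enhanced left-ventricular cavity in every phase, takes
end-diastole (ED) and end-systole (ES) as the phases of maximal/minimal
cavity volume, and derives the standard echo-style readouts:

* EDV/ESV and ejection fraction  EF = (EDV − ESV) / EDV × 100
* LV internal diameters and fractional shortening
  FS = (LVIDd − LVIDs) / LVIDd × 100
* segmental myocardial strain ΔL/L₀ along the endocardial contour
  (6 segments from posterior base to anterior base) and its mean, the
  global longitudinal strain (GLS) — negative during systolic shortening
* heart-failure severity from EF (severe < 20%, moderate 20-40%,
  mild > 40%) and fibrosis severity from a scar-area fraction
  (severe > 40%, moderate 20-40%, mild < 20%)
* cycle length and phase duration (e.g. 400 bpm -> 150 ms cycle and
  12.5 ms per phase with 12 bins).

In 2D-slice mode volumes are area x 1 mm slice thickness, reported in µL
(1 mm^3 = 1 µL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import filters, measure

from .recon import ReconImage

__all__ = [
    "PhaseSeries",
    "CardiacMetrics",
    "segment_lv_cavity",
    "ejection_fraction",
    "fractional_shortening",
    "lv_internal_diameter",
    "strain",
    "segmental_strain",
    "classify_heart_failure",
    "classify_fibrosis",
    "cycle_length_ms",
    "phase_duration_ms",
    "compute_metrics",
]

SEGMENT_NAMES = (
    "posterior base", "posterior mid", "posterior apex",
    "anterior apex", "anterior mid", "anterior base",
)

SLICE_THICKNESS_MM = 1.0


@dataclass
class PhaseSeries:
    """Reconstructed images per phase bin, ordered by bin id."""

    images: list  # list[ReconImage]
    pixel_mm: float

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("phase series is empty")

    @property
    def n_bins(self) -> int:
        return len(self.images)

    @property
    def phase_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins


@dataclass
class CardiacMetrics:
    edv_ul: float
    esv_ul: float
    ef_pct: float
    lvidd_mm: float
    lvids_mm: float
    fs_pct: float
    segment_strain: dict
    gls: float
    hf_class: str
    cycle_ms: float
    phase_duration_ms: float
    ed_bin: int
    es_bin: int
    volumes_ul: np.ndarray
    fibrosis_class: str | None = None
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# segmentation and geometry

def segment_lv_cavity(image: ReconImage, window_frac: float = 0.5
                      ) -> tuple[np.ndarray, float]:
    """Segment the contrast-filled LV cavity (the brightest compartment).

    An Otsu threshold is computed inside a centred square window covering
    ``window_frac`` of the image side (the cardiac window); the mask is
    the largest connected component above threshold within the window.
    Returns (mask, volume_µL).  Scale invariant: rescaling intensities
    leaves the mask unchanged.
    """
    vals = image.values
    n = vals.shape[0]
    half = int(round(n * window_frac / 2.0))
    c = n // 2
    window = np.zeros_like(vals, dtype=bool)
    window[c - half:c + half, c - half:c + half] = True
    wv = vals[window]
    if np.ptp(wv) == 0:
        raise ValueError("cavity not found: flat cardiac window")
    thresh = filters.threshold_otsu(wv)
    cand = (vals > thresh) & window
    if not cand.any():
        raise ValueError("cavity not found: nothing above threshold")
    labels = measure.label(cand)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    volume = float(mask.sum()) * image.pixel_mm ** 2 * SLICE_THICKNESS_MM
    return mask, volume


def lv_internal_diameter(mask: np.ndarray, pixel_mm: float) -> float:
    """LV internal diameter (mm): the chord through the cavity centroid
    along the minor-axis direction of the mask — the echo-LVID analog of
    an M-mode cursor across the short axis of the ventricle."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cavity mask")
    props = measure.regionprops(mask.astype(int))[0]
    cy, cx = props.centroid
    theta = props.orientation  # major axis vs rows
    # minor-axis direction, in (row, col)
    d = np.array([math.sin(theta), math.cos(theta)])
    n = mask.shape[0]
    step = 0.1
    ts = np.arange(-n, n, step)
    rows = cy + ts * d[0]
    cols = cx + ts * d[1]
    from scipy import ndimage

    vals = ndimage.map_coordinates(mask.astype(float), [rows, cols],
                                   order=1, mode="constant", cval=0.0)
    inside = vals >= 0.5
    if not inside.any():
        raise ValueError("centroid chord misses the mask")
    # longest contiguous run through the centroid
    runs = np.flatnonzero(np.diff(np.concatenate([[0], inside.view(np.int8), [0]])))
    starts, ends = runs[::2], runs[1::2]
    centre_idx = np.argmin(np.abs(ts))
    for s, e in zip(starts, ends):
        if s <= centre_idx < e:
            return float((e - s) * step * pixel_mm)
    lengths = ends - starts
    return float(lengths.max() * step * pixel_mm)


# ---------------------------------------------------------------------------
# scalar definitions

def ejection_fraction(edv_ul: float, esv_ul: float) -> float:
    """EF (%) = (EDV − ESV)/EDV x 100.  A negative result (ESV > EDV, a
    noise artefact) is returned as-is; callers may warn."""
    if edv_ul <= 0:
        raise ValueError("EDV must be positive")
    return (edv_ul - esv_ul) / edv_ul * 100.0


def fractional_shortening(lvidd_mm: float, lvids_mm: float) -> float:
    """FS (%) = (LVIDd − LVIDs)/LVIDd x 100."""
    if lvidd_mm <= 0:
        raise ValueError("LVIDd must be positive")
    return (lvidd_mm - lvids_mm) / lvidd_mm * 100.0


def strain(l0: float, l: float) -> float:
    """ΔL/L₀ — fractional length change; negative when shortening."""
    if l0 <= 0:
        raise ValueError("reference length must be positive")
    return (l - l0) / l0


def classify_heart_failure(ef_pct: float) -> str:
    """Severity class from EF: severe < 20, moderate 20-40 (inclusive),
    mild > 40."""
    if ef_pct < 20.0:
        return "severe"
    if ef_pct <= 40.0:
        return "moderate"
    return "mild"


def classify_fibrosis(fraction_pct: float) -> str:
    """Severity class from fibrotic-area fraction of the LV surface:
    severe > 40, moderate 20-40 (inclusive), mild < 20."""
    if fraction_pct > 40.0:
        return "severe"
    if fraction_pct >= 20.0:
        return "moderate"
    return "mild"


def cycle_length_ms(bpm: float) -> float:
    """Average cardiac cycle length in ms (150 ms at 400 bpm)."""
    if bpm <= 0:
        raise ValueError("bpm must be positive")
    return 60000.0 / bpm


def phase_duration_ms(bpm: float, n_bins: int = 12) -> float:
    """Average phase duration in ms: 1/n_bins of the cycle length
    (12.5 ms at 400 bpm with 12 phases)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    return cycle_length_ms(bpm) / n_bins


# ---------------------------------------------------------------------------
# segmental strain

def _closed_contour(mask: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no endocardial contour found")
    contour = max(contours, key=len)
    if not np.allclose(contour[0], contour[-1]):
        raise ValueError("endocardial contour is not closed")
    return contour[:-1]


def _segment_lengths(mask: np.ndarray, n_segments: int,
                     pixel_mm: float) -> np.ndarray:
    """Arc lengths (mm) of equal-arc contour segments, starting at the
    posterior-base anchor (the contour point with the largest row, i.e.
    the most caudal point) and proceeding counter-clockwise."""
    contour = _closed_contour(mask)
    area2 = np.sum(contour[:, 0] * np.roll(contour[:, 1], -1)
                   - np.roll(contour[:, 0], -1) * contour[:, 1])
    if area2 < 0:
        contour = contour[::-1]
    anchor = int(np.argmax(contour[:, 0]))
    contour = np.roll(contour, -anchor, axis=0)
    closed = np.vstack([contour, contour[:1]])
    steps = np.linalg.norm(np.diff(closed, axis=0), axis=1) * pixel_mm
    total = steps.sum()
    edges = np.linspace(0.0, total, n_segments + 1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    return np.diff(np.interp(edges, cum, cum))


def segmental_strain(ed_mask: np.ndarray, es_mask: np.ndarray,
                     n_segments: int = 6, pixel_mm: float = 1.0
                     ) -> tuple[dict, float]:
    """Per-segment endocardial strain between end-diastole and
    end-systole, plus the global (mean) strain.

    The endocardial contour of each mask is arc-length parameterised from
    the posterior-base anchor and split into ``n_segments`` equal-arc
    segments; segment strain is (L_es − L_ed)/L_ed.  For an identity
    deformation every segment is exactly 0; for a uniform isotropic
    shrink by factor c every segment approaches c − 1.
    """
    led = _segment_lengths(ed_mask, n_segments, pixel_mm)
    les = _segment_lengths(es_mask, n_segments, pixel_mm)
    names = (SEGMENT_NAMES if n_segments == len(SEGMENT_NAMES)
             else [f"segment {i}" for i in range(n_segments)])
    seg = {name: strain(l0, l) for name, l0, l in zip(names, led, les)}
    gls = float(np.mean(list(seg.values())))
    return seg, gls


# ---------------------------------------------------------------------------
# end-to-end metrics

def compute_metrics(series: PhaseSeries, est_bpm: float,
                    fibrosis_pct: float | None = None,
                    n_bins_timing: int | None = None) -> CardiacMetrics:
    """Segment every phase, identify ED/ES as the max/min-volume bins,
    and compute EF, FS, segmental strain, severity classes and phase
    timing."""
    masks = []
    volumes = []
    for img in series.images:
        m, v = segment_lv_cavity(img)
        masks.append(m)
        volumes.append(v)
    volumes = np.asarray(volumes)
    ed = int(np.argmax(volumes))
    es = int(np.argmin(volumes))
    edv, esv = float(volumes[ed]), float(volumes[es])
    warns = []
    ef = ejection_fraction(edv, esv)
    if ef < 0:
        warns.append("ESV exceeded EDV (noise); EF is negative")
    lvidd = lv_internal_diameter(masks[ed], series.pixel_mm)
    lvids = lv_internal_diameter(masks[es], series.pixel_mm)
    fs = fractional_shortening(lvidd, lvids)
    seg, gls = segmental_strain(masks[ed], masks[es],
                                pixel_mm=series.pixel_mm)
    nb = n_bins_timing if n_bins_timing is not None else series.n_bins
    return CardiacMetrics(
        edv_ul=edv, esv_ul=esv, ef_pct=float(ef),
        lvidd_mm=lvidd, lvids_mm=lvids, fs_pct=float(fs),
        segment_strain=seg, gls=gls,
        hf_class=classify_heart_failure(float(ef)),
        fibrosis_class=(classify_fibrosis(fibrosis_pct)
                        if fibrosis_pct is not None else None),
        cycle_ms=cycle_length_ms(est_bpm),
        phase_duration_ms=phase_duration_ms(est_bpm, nb),
        ed_bin=ed, es_bin=es, volumes_ul=volumes, warnings=warns,
    )
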