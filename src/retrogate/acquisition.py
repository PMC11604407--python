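"""Continuous-rotation scan simulation and the parallel-beam projector.

The scanner is modelled as a parallel-beam system rotating continuously at
a fixed frame rate: frame ``i`` is acquired at ``t = i / frame_rate`` and
at angle ``(i * 360 / n_angles_per_rotation) mod 360``, so time and angle
sampling are coupled one-projection-per-frame.  Projections are stored as
line integrals (post-log, mm^-1 * mm); optional Poisson photon noise is
applied in the count domain and log-converted back.

The same projector (and its exact adjoint) is reused by the iterative
reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .phantom import PhantomConfig, render_thorax

__all__ = [
    "ScanGeometry",
    "ProjectionStream",
    "forward_project",
    "back_project_adjoint",
    "simulate_scan",
    "save_stream",
    "load_stream",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition geometry and timing.

    ``photon_count_I0`` is the expected photon count per detector pixel for
    an unattenuated ray; 0 disables noise.  The frame rate should exceed
    twice the upper edge of the cardiac band (Nyquist guard; violating it
    triggers a warning, not an error).
    """

    n_angles_per_rotation: int = 720
    detector_pixels: int = 160
    detector_pitch_mm: float = 0.2
    frame_rate_hz: float = 40.0
    duration_s: float = 60.0
    photon_count_I0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_angles_per_rotation < 2:
            raise ValueError("n_angles_per_rotation must be >= 2")
        if self.detector_pixels < 1 or self.detector_pitch_mm <= 0:
            raise ValueError("invalid detector definition")
        if self.frame_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("frame_rate_hz and duration_s must be positive")
        if self.photon_count_I0 < 0:
            raise ValueError("photon_count_I0 must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    def angle_of(self, i) -> np.ndarray:
        return (np.asarray(i) * 360.0 / self.n_angles_per_rotation) % 360.0

    def with_(self, **kw) -> "ScanGeometry":
        return replace(self, **kw)


@dataclass
class ProjectionStream:
    """Time-stamped, angle-stamped stack of 1D line-integral projections."""

    projections: np.ndarray  # (n_frames, detector_pixels)
    angles_deg: np.ndarray
    timestamps_s: np.ndarray
    geometry: ScanGeometry
    phantom: PhantomConfig | None = None
    truth_cardiac_fraction: np.ndarray | None = None
    truth_resp_state: np.ndarray | None = None  # array of str

    def __post_init__(self) -> None:
        n = len(self.projections)
        if not (len(self.angles_deg) == len(self.timestamps_s) == n):
            raise ValueError("projections, angles and timestamps must align")
        if n > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.projections)


# ---------------------------------------------------------------------------
# projector

def _ray_coords(n: int, pixel_mm: float, angle_deg: float,
                geometry: ScanGeometry) -> tuple[np.ndarray, np.ndarray, float]:
    """Bilinear sampling coordinates (rows, cols) for all rays of one view.

    Rays are parallel, rotation about the grid centre; detector coordinate
    u along ``e_u = (cos a, sin a)``, integration coordinate s along the
    perpendicular.  Sample step along s equals the image pixel pitch."""
    a = np.deg2rad(angle_deg)
    nd = geometry.detector_pixels
    u = (np.arange(nd) - (nd - 1) / 2.0) * geometry.detector_pitch_mm
    half_diag = n * pixel_mm / np.sqrt(2.0)
    ns = int(np.ceil(2.0 * half_diag / pixel_mm)) + 1
    s = (np.arange(ns) - (ns - 1) / 2.0) * pixel_mm
    # x = u*cos - s*sin ; y = u*sin + s*cos   (mm, centre origin)
    x = u[:, None] * np.cos(a) - s[None, :] * np.sin(a)
    y = u[:, None] * np.sin(a) + s[None, :] * np.cos(a)
    centre = (n - 1) / 2.0
    rows = y / pixel_mm + centre
    cols = x / pixel_mm + centre
    return rows, cols, pixel_mm


def forward_project(image: np.ndarray, angle_deg: float,
                    geometry: ScanGeometry, pixel_mm: float) -> np.ndarray:
    """Parallel-beam line integrals (mm^-1 * mm) of a square image at one
    view angle; linear interpolation along rays sampled at
    ``detector_pitch_mm`` across the detector and ``pixel_mm`` along the ray.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square 2D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    rows, cols, ds = _ray_coords(image.shape[0], pixel_mm, angle_deg, geometry)
    samples = _bilinear_gather(image, rows, cols)
    return samples.sum(axis=1) * ds


def _bilinear_gather(image: np.ndarray, rows: np.ndarray,
                     cols: np.ndarray) -> np.ndarray:
    """Bilinear sampling with zero outside the grid, written as the exact
    transpose of the scatter in :func:`back_project_adjoint`."""
    n = image.shape[0]
    padded = np.zeros((n + 2, n + 2))
    padded[1:-1, 1:-1] = image
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    out = np.zeros(rows.shape)
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = np.clip(r0 + dr + 1, 0, n + 1)
        cc = np.clip(c0 + dc + 1, 0, n + 1)
        out += padded[rr, cc] * w
    return out


def back_project_adjoint(proj: np.ndarray, angle_deg: float,
                         geometry: ScanGeometry, n: int,
                         pixel_mm: float) -> np.ndarray:
    """Exact adjoint of :func:`forward_project` for one view: smears each
    detector value back over its ray's bilinear sampling footprint."""
    rows, cols, ds = _ray_coords(n, pixel_mm, angle_deg, geometry)
    vals = (np.asarray(proj, dtype=float)[:, None] * ds
            * np.ones(rows.shape[1])).ravel()
    r = rows.ravel()
    c = cols.ravel()
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr = r - r0
    fc = c - c0
    out = np.zeros((n + 2) * (n + 2))  # 1-px guard ring absorbs border spill
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr + 1
        cc = c0 + dc + 1
        ok = (rr >= 0) & (rr < n + 2) & (cc >= 0) & (cc < n + 2)
        out += np.bincount(rr[ok] * (n + 2) + cc[ok], weights=vals[ok] * w[ok],
                           minlength=(n + 2) * (n + 2))
    return out.reshape(n + 2, n + 2)[1:-1, 1:-1]


# ---------------------------------------------------------------------------
# scan simulation

def _apply_poisson_noise(p: np.ndarray, i0: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Count-domain Poisson noise on line integrals, log-converted back.
    Zero counts are clamped to 1 (photon starvation guard)."""
    expected = i0 * np.exp(-p)
    if np.any(expected < 1.0):
        warnings.warn("photon starvation: expected counts < 1 on some rays")
    counts = rng.poisson(expected).astype(float)
    counts = np.maximum(counts, 1.0)
    return -np.log(counts / i0)


def simulate_scan(config: PhantomConfig, geometry: ScanGeometry,
                  keep_truth: bool = True) -> ProjectionStream:
    """Simulate a continuous-rotation scan of the time-varying phantom.

    Frame ``i`` renders the phantom at ``t = i / frame_rate`` and projects
    it at the rotation angle of that frame.  The result is exactly
    reproducible from (config, geometry) including both seeds.
    """
    fov = config.grid_n * config.pixel_mm
    if geometry.detector_pixels * geometry.detector_pitch_mm < fov:
        raise ValueError("detector does not cover the phantom field of view")
    cardiac_hz = config.heart_rate_bpm / 60.0
    if geometry.frame_rate_hz <= 2.0 * cardiac_hz:
        warnings.warn(
            "frame rate below 2x the cardiac frequency: cardiac signal "
            "will alias"
        )
    n = geometry.n_frames
    idx = np.arange(n)
    timestamps = idx / geometry.frame_rate_hz
    angles = geometry.angle_of(idx)
    projections = np.empty((n, geometry.detector_pixels))
    frac = np.empty(n)
    resp = np.empty(n, dtype=object)
    for i in range(n):
        frame = render_thorax(config, timestamps[i])
        projections[i] = forward_project(
            frame.values, angles[i], geometry, config.pixel_mm
        )
        frac[i] = frame.truth_cardiac_fraction
        resp[i] = frame.truth_resp_state
    if geometry.photon_count_I0 > 0:
        rng = np.random.default_rng(geometry.seed)
        projections = _apply_poisson_noise(
            projections, geometry.photon_count_I0, rng
        )
    return ProjectionStream(
        projections=projections,
        angles_deg=angles,
        timestamps_s=timestamps,
        geometry=geometry,
        phantom=config,
        truth_cardiac_fraction=frac if keep_truth else None,
        truth_resp_state=resp.astype(str) if keep_truth else None,
    )


# ---------------------------------------------------------------------------
# stream I/O: multi-page TIFF (projections as rows) + CSV sidecar

def save_stream(stream: ProjectionStream, directory) -> None:
    """Write ``projections.tiff`` and ``frames.csv`` into ``directory``.
    The CSV carries index, angle, timestamp and (if present) truth columns,
    round-tripping bit-exactly via float hex encoding alongside the
    readable decimal columns."""
    import tifffile
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / "projections.tiff",
                     stream.projections.astype(np.float32))
    cols = {
        "index": np.arange(len(stream)),
        "angle_deg": stream.angles_deg,
        "timestamp_s": stream.timestamps_s,
        "angle_deg_hex": [float(a).hex() for a in stream.angles_deg],
        "timestamp_s_hex": [float(t).hex() for t in stream.timestamps_s],
    }
    if stream.truth_cardiac_fraction is not None:
        cols["truth_cardiac_fraction"] = stream.truth_cardiac_fraction
        cols["truth_resp_state"] = stream.truth_resp_state
    pd.DataFrame(cols).to_csv(d / "frames.csv", index=False)
    meta = {"geometry": _dataclass_dict(stream.geometry)}
    if stream.phantom is not None:
        meta["phantom"] = _dataclass_dict(stream.phantom)
    import json

    (d / "meta.json").write_text(json.dumps(meta, indent=2))


def load_stream(directory) -> ProjectionStream:
    """Inverse of :func:`save_stream` (projection dtype float32)."""
    import json
    import tifffile
    from pathlib import Path

    d = Path(directory)
    proj = np.asarray(tifffile.imread(d / "projections.tiff"), dtype=float)
    df = pd.read_csv(d / "frames.csv")
    meta = json.loads((d / "meta.json").read_text())
    geo = ScanGeometry(**meta["geometry"])
    phantom = None
    if "phantom" in meta:
        p = dict(meta["phantom"])
        for key in ("lv_epi_semiaxes_mm", "lv_endo_semiaxes_mm"):
            p[key] = tuple(p[key])
        phantom = PhantomConfig(**p)
    angles = np.array([float.fromhex(h) for h in df["angle_deg_hex"]])
    times = np.array([float.fromhex(h) for h in df["timestamp_s_hex"]])
    truth_f = truth_r = None
    if "truth_cardiac_fraction" in df.columns:
        truth_f = df["truth_cardiac_fraction"].to_numpy()
        truth_r = df["truth_resp_state"].to_numpy().astype(str)
    return ProjectionStream(
        projections=proj, angles_deg=angles, timestamps_s=times,
        geometry=geo, phantom=phantom,
        truth_cardiac_fraction=truth_f, truth_resp_state=truth_r,
    )


def _dataclass_dict(obj) -> dict:
    import dataclasses

    return dataclasses.asdict(obj)
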