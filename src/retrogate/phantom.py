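"""Digital 4D mouse-thorax phantom with analytically known cardiac state.

A single axial slice through the mid-thorax is modelled as a composite of
ellipses: a soft-tissue body outline, two lung fields, a spine disk, and a
myocardial annulus surrounding a contrast-enhanced left-ventricular cavity.
The cavity contracts periodically (heart beat, with optional per-beat
cycle-length jitter) and the lung/abdomen boundary (the "diaphragm") is
displaced cranio-caudally by breathing, with a distinct inspiration
sub-phase.  Every frame carries its ground-truth cardiac-cycle fraction and
respiratory state, so downstream gating and cardiac-function estimates can
be validated against an exact oracle.

Volumes are reported for the 2D slice as area x 1 mm slice thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhantomConfig",
    "ThoraxImage",
    "beat_boundaries",
    "cardiac_phase_truth",
    "resp_state_truth",
    "contraction_waveform",
    "render_thorax",
    "lv_cavity_area_truth",
]

#: default attenuation coefficients, mm^-1 (approx. 80 kVp soft-tissue scale;
#: cavity value reflects iodinated blood-pool contrast)
DEFAULT_MU = {
    "soft": 0.022,
    "myocardium": 0.025,
    "cavity_contrast": 0.080,
    "lung": 0.005,
    "bone": 0.060,
}

#: cardiac-cycle fraction at which end-systole occurs
SYSTOLE_PHASE = 0.35


@dataclass(frozen=True)
class PhantomConfig:
    """Full parametric description of the synthetic thorax.

    Attributes
    ----------
    grid_n : int
        Pixels per side of the square axial slice (>= 32).
    pixel_mm : float
        Pixel pitch in mm.
    heart_rate_bpm, resp_rate_bpm : float
        Mean cardiac and respiratory rates.
    inspiratory_fraction : float
        Fraction of each respiratory cycle spent in inspiration, in (0, 1).
    cycle_jitter_cv : float
        Coefficient of variation of per-beat cardiac cycle length.
    lv_epi_semiaxes_mm, lv_endo_semiaxes_mm : (float, float)
        Ellipse semi-axes of the epicardium / contrast-filled cavity at
        end-diastole.
    contraction_factor : float
        Multiplicative shrink ``s`` of the endocardial semi-axes at
        end-systole, in (0, 1].  Area-EF ground truth is ``(1 - s^2) * 100``;
        the default 0.632 gives an EF of ~60% (healthy mouse).
    diaphragm_amp_mm : float
        Peak cranio-caudal diaphragm displacement during inspiration.
    mu : dict
        Attenuation coefficients per tissue, mm^-1, keys
        {soft, myocardium, cavity_contrast, lung, bone}.
    seed : int
        Seed for the per-beat jitter stream.
    """

    grid_n: int = 160
    pixel_mm: float = 0.2
    heart_rate_bpm: float = 400.0
    resp_rate_bpm: float = 80.0
    inspiratory_fraction: float = 0.30
    cycle_jitter_cv: float = 0.05
    lv_epi_semiaxes_mm: tuple[float, float] = (4.6, 3.8)
    lv_endo_semiaxes_mm: tuple[float, float] = (3.2, 2.6)
    contraction_factor: float = 0.632
    diaphragm_amp_mm: float = 1.5
    mu: dict = field(default_factory=lambda: dict(DEFAULT_MU))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_n < 32:
            raise ValueError(f"grid_n must be >= 32, got {self.grid_n}")
        if not 0.0 < self.inspiratory_fraction < 1.0:
            raise ValueError("inspiratory_fraction must lie in (0, 1)")
        if not 0.0 < self.contraction_factor <= 1.0:
            raise ValueError("contraction_factor must lie in (0, 1]")
        if self.cycle_jitter_cv < 0:
            raise ValueError("cycle_jitter_cv must be >= 0")
        if self.heart_rate_bpm <= 0 or self.resp_rate_bpm <= 0:
            raise ValueError("rates must be positive")
        missing = set(DEFAULT_MU) - set(self.mu)
        if missing:
            raise ValueError(f"mu missing tissues: {sorted(missing)}")
        if any(v < 0 for v in self.mu.values()):
            raise ValueError("attenuation coefficients must be >= 0")
        ea, eb = self.lv_epi_semiaxes_mm
        na, nb = self.lv_endo_semiaxes_mm
        if not (0 < na < ea and 0 < nb < eb):
            raise ValueError(
                "endocardial semi-axes must be strictly inside epicardial"
            )
        half_fov = self.grid_n * self.pixel_mm / 2.0
        if max(ea, eb) >= half_fov:
            raise ValueError("epicardium exceeds the image grid")

    def with_(self, **kw) -> "PhantomConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


@dataclass(frozen=True)
class ThoraxImage:
    """One rendered frame of the phantom with its ground-truth state."""

    values: np.ndarray  # 2D attenuation map, mm^-1
    timestamp_s: float
    truth_cardiac_fraction: float
    truth_resp_state: str  # "inspiration" | "expiration"
    pixel_mm: float


# ---------------------------------------------------------------------------
# cardiac timing truth

def beat_boundaries(config: PhantomConfig, t_max: float) -> np.ndarray:
    """Cumulative beat-start times covering ``[0, t_max]``.

    Beat lengths are drawn sequentially from ``Normal(mean, cv*mean)`` with
    ``mean = 60/heart_rate_bpm`` s, z-scores clipped at +/-3, using
    ``numpy.random.default_rng(seed)``.  This recipe is deliberately simple
    enough to replay in any language; identical seeds give bitwise-identical
    sequences.
    """
    mean = 60.0 / config.heart_rate_bpm
    cv = config.cycle_jitter_cv
    if cv == 0.0:
        n = int(math.floor(t_max / mean)) + 2
        return mean * np.arange(n + 1)
    rng = np.random.default_rng(config.seed)
    bounds = [0.0]
    # draw in chunks; sequential order is part of the documented recipe
    while bounds[-1] <= t_max:
        z = np.clip(rng.standard_normal(256), -3.0, 3.0)
        lengths = mean * (1.0 + cv * z)
        bounds.extend(bounds[-1] + np.cumsum(lengths))
    return np.asarray(bounds)


def cardiac_phase_truth(config: PhantomConfig, t: float) -> float:
    """Ground-truth cardiac-cycle fraction in [0, 1) at time ``t`` (s).

    Phase rises piecewise-linearly across the seeded sequence of beat
    lengths and resets to 0 at each beat boundary.
    """
    t = float(t)
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    bounds = beat_boundaries(config, t)
    i = int(np.searchsorted(bounds, t, side="right")) - 1
    frac = (t - bounds[i]) / (bounds[i + 1] - bounds[i])
    return float(min(frac, np.nextafter(1.0, 0.0)))


# ---------------------------------------------------------------------------
# respiratory truth

def resp_state_truth(config: PhantomConfig, t: float) -> tuple[str, float]:
    """Respiratory state and diaphragm displacement (mm) at time ``t``.

    The respiratory cycle is periodic with period ``60/resp_rate_bpm``;
    inspiration occupies the leading ``inspiratory_fraction`` of each cycle.
    Displacement is a raised-cosine pulse peaking mid-inspiration and
    exactly 0 throughout the end-expiratory plateau.
    """
    t = float(t)
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    period = 60.0 / config.resp_rate_bpm
    phase = (t / period) % 1.0
    fi = config.inspiratory_fraction
    if phase < fi:
        disp = config.diaphragm_amp_mm * math.sin(math.pi * phase / fi) ** 2
        return "inspiration", disp
    return "expiration", 0.0


# ---------------------------------------------------------------------------
# geometry

def contraction_waveform(phase) -> np.ndarray:
    """Raised-cosine contraction weight w(phase): 0 at end-diastole
    (phase 0), 1 at end-systole (phase ``SYSTOLE_PHASE``), back to 0 at the
    next beat.  Asymmetric rise/fall, C1-continuous."""
    p = np.asarray(phase, dtype=float) % 1.0
    up = 0.5 * (1.0 - np.cos(np.pi * p / SYSTOLE_PHASE))
    down = 0.5 * (1.0 + np.cos(np.pi * (p - SYSTOLE_PHASE) / (1.0 - SYSTOLE_PHASE)))
    return np.where(p <= SYSTOLE_PHASE, up, down)


def _scale(config: PhantomConfig, phase: float) -> float:
    w = float(contraction_waveform(phase))
    return 1.0 - (1.0 - config.contraction_factor) * w


def _ellipse(xx, yy, cx, cy, a, b):
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


# fixed slice anatomy (mm, relative to grid centre; +y is caudal/"down")
_BODY = (0.0, 0.0, 15.0, 12.5)
_LUNG_L = (-7.0, 1.5, 5.2, 6.5)
_LUNG_R = (7.0, 1.5, 5.2, 6.5)
_SPINE = (0.0, -10.0, 2.0, 1.8)
_HEART_CENTRE = (0.0, -1.0)
_DIAPHRAGM_Y0 = 5.5  # lung tissue below this line is abdomen at end-expiration


def render_thorax(config: PhantomConfig, t: float) -> ThoraxImage:
    """Render the attenuation slice at time ``t``.

    The endocardial semi-axes are scaled by ``s(t)`` derived from the
    cardiac phase; the diaphragm line moves cranially (here: -y) by the
    respiratory displacement, converting lung voxels to soft tissue.  With
    zero jitter the image is exactly periodic in both cycles.
    """
    frac = cardiac_phase_truth(config, t)
    state, disp = resp_state_truth(config, t)
    mu = config.mu
    n = config.grid_n
    half = n * config.pixel_mm / 2.0
    c = (np.arange(n) + 0.5) * config.pixel_mm - half
    xx, yy = np.meshgrid(c, c)

    img = np.zeros((n, n))
    body = _ellipse(xx, yy, *_BODY)
    img[body] = mu["soft"]
    diaphragm_y = _DIAPHRAGM_Y0 - disp
    lungs = (_ellipse(xx, yy, *_LUNG_L) | _ellipse(xx, yy, *_LUNG_R)) & body
    img[lungs & (yy <= diaphragm_y)] = mu["lung"]
    img[_ellipse(xx, yy, *_SPINE) & body] = mu["bone"]

    hx, hy = _HEART_CENTRE
    ea, eb = config.lv_epi_semiaxes_mm
    s = _scale(config, frac)
    na, nb = config.lv_endo_semiaxes_mm
    img[_ellipse(xx, yy, hx, hy, ea, eb)] = mu["myocardium"]
    img[_ellipse(xx, yy, hx, hy, na * s, nb * s)] = mu["cavity_contrast"]

    return ThoraxImage(
        values=img,
        timestamp_s=float(t),
        truth_cardiac_fraction=frac,
        truth_resp_state=state,
        pixel_mm=config.pixel_mm,
    )


def lv_cavity_area_truth(config: PhantomConfig, phase: float) -> float:
    """Analytic LV cavity area (mm^2) at the given cardiac-cycle fraction:
    ``pi * a * b * s(phase)^2`` with (a, b) the end-diastolic endocardial
    semi-axes."""
    a, b = config.lv_endo_semiaxes_mm
    s = _scale(config, float(phase))
    return math.pi * a * b * s * s
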