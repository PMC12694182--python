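"""Numerical reconstruction of off-axis holograms.

Pipeline: demodulate the +1 diffraction order to baseband, refocus with the
angular spectrum method (optionally choosing the distance by a sharpness
metric), and remove the system's background phase with a sample-free
reference reconstruction.

Conventions
-----------
Arrays are (rows, cols) = (y, x); pixel (0, 0) is top-left.  Frequencies are
in cycles/pixel.  ``z > 0`` propagates away from the recorded plane toward
the source, so refocusing a hologram recorded a distance ``d`` past focus
requires ``z = -d``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .optics import OpticalConfig

__all__ = [
    "ComplexField",
    "ReconSettings",
    "PhaseMap",
    "demodulate_offaxis",
    "angular_spectrum_propagate",
    "autofocus",
    "correct_aberration",
    "reconstruct_pair",
]


@dataclass
class ComplexField:
    """A sampled 2-D complex wave with its physical sampling metadata.

    ``pitch`` is the object-plane pixel pitch (m/pixel) and ``z_offset`` the
    remaining distance (m) to the nominal focal plane: propagating by
    ``z`` decrements it, so a field synthesized with defocus ``d`` carries
    ``z_offset = d`` and reaches focus after ``propagate(z=-d)``... see
    :func:`angular_spectrum_propagate` for the sign convention.
    """

    data: np.ndarray
    pitch: float
    wavelength: float
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValueError("ComplexField data must be 2-D")
        if not np.all(np.isfinite(self.data.view(np.float64))):
            raise ValueError("ComplexField data must be finite")
        if self.pitch <= 0 or self.wavelength <= 0:
            raise ValueError("pitch and wavelength must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.data)

    def energy(self) -> float:
        return float(np.sum(np.abs(self.data) ** 2))


@dataclass
class ReconSettings:
    """Knobs of the demodulation/autofocus stage.

    filter_radius : cycles/pixel; 0 selects the config's effective band
        radius automatically.
    carrier_mode : "auto-peak" locates the +1 order as the strongest spectral
        peak outside a DC-exclusion disk in the half-plane fy > 0 (ties:
        larger magnitude, then lexicographic (fy, fx)); "explicit" uses the
        config's carrier.
    z_search : (z_min, z_max, coarse_step, refinement_levels) in metres for
        the autofocus scan.
    focus_metric : score maximized by the autofocus.  The default,
        ``neg_variance_amplitude``, exploits the fact that a pure phase
        specimen has minimal amplitude contrast exactly at focus — the
        sharpest usable extremum for these samples.  ``tenengrad_phase``
        (mean squared phase gradient) and ``tamura_amplitude`` are kept
        selectable for amplitude-contrast specimens.
    window : spectral window applied around the +1 order.
    """

    filter_radius: float = 0.0
    carrier_mode: str = "auto-peak"
    z_search: Tuple[float, float, float, int] = (-200e-6, 200e-6, 10e-6, 1)
    focus_metric: str = "neg_variance_amplitude"
    window: str = "hard_disk"

    def __post_init__(self) -> None:
        if self.carrier_mode not in ("auto-peak", "explicit"):
            raise ValueError(f"unknown carrier_mode {self.carrier_mode!r}")
        if self.focus_metric not in (
            "tenengrad_phase",
            "tamura_amplitude",
            "neg_variance_amplitude",
        ):
            raise ValueError(f"unknown focus_metric {self.focus_metric!r}")
        if self.window not in ("hard_disk", "gaussian_soft"):
            raise ValueError(f"unknown window {self.window!r}")
        z_min, z_max, step, levels = self.z_search
        if not (z_min < z_max):
            raise ValueError("z_search requires z_min < z_max")
        if step <= 0:
            raise ValueError("z_search coarse_step must be positive")
        if int(levels) < 0:
            raise ValueError("refinement_levels must be >= 0")


@dataclass
class PhaseMap:
    """An aberration-corrected quantitative phase image (radians)."""

    phase: np.ndarray
    pitch: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.phase.ndim != 2:
            raise ValueError("phase must be 2-D")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase must be finite")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.phase.shape


# ----------------------------------------------------------------------
# Demodulation
# ----------------------------------------------------------------------

def _locate_carrier_peak(
    spectrum: np.ndarray, exclusion_radius: float
) -> Tuple[float, float]:
    """Strongest peak outside the DC disk, restricted to fy > 0.

    Returns (fx, fy) in cycles/pixel.  Ties are broken toward larger
    magnitude (trivially satisfied by argmax) then lexicographic (fy, fx).
    """
    h, w = spectrum.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    mag = np.abs(spectrum)
    valid = (np.hypot(fx, fy) > exclusion_radius) & (fy > 0)
    if not valid.any():
        raise ValueError("no carrier found: DC exclusion covers the spectrum")
    mag = np.where(valid, mag, -1.0)
    peak = mag.max()
    # noise floor: median magnitude of the valid region
    floor = np.median(np.abs(spectrum)[valid])
    if peak <= 10 * floor:
        raise ValueError(
            "no carrier found: no spectral peak above the noise floor "
            "outside the DC-exclusion disk"
        )
    candidates = np.argwhere(mag >= peak * (1 - 1e-12))
    # lexicographic on (fy, fx)
    keys = [(float(fy[r, 0]), float(fx[0, c])) for r, c in candidates]
    best = min(range(len(keys)), key=lambda i: keys[i])
    r, c = candidates[best]
    return float(fx[0, c]), float(fy[r, 0])


def demodulate_offaxis(
    hologram: np.ndarray,
    cfg: OpticalConfig,
    settings: Optional[ReconSettings] = None,
) -> ComplexField:
    """Recover the complex object wave from an off-axis hologram.

    The +1 order is located (automatically or from ``cfg.carrier``),
    windowed, shifted to baseband and inverse-transformed.  The returned
    field carries ``z_offset = cfg.defocus_z``: it still needs refocusing
    if the hologram was recorded out of focus.
    """
    settings = settings or ReconSettings()
    holo = np.asarray(hologram, dtype=np.float64)
    if holo.ndim != 2:
        raise ValueError("hologram must be a 2-D real image")
    if np.ptp(holo) == 0:
        raise ValueError("hologram is constant: no fringes to demodulate")

    spectrum = np.fft.fft2(holo)
    h, w = holo.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]

    radius = settings.filter_radius if settings.filter_radius > 0 else cfg.band_radius
    if settings.carrier_mode == "explicit":
        cfx, cfy = cfg.carrier
    else:
        cfx, cfy = _locate_carrier_peak(spectrum, exclusion_radius=2 * radius)

    # clip the window against Nyquist
    nyq_margin = 0.5 - max(abs(cfx), abs(cfy))
    if radius > nyq_margin:
        warnings.warn(
            f"order-selection window (r={radius:.3f}) clipped by Nyquist "
            f"(margin {nyq_margin:.3f} cycles/px)",
            stacklevel=2,
        )

    dist = np.hypot(fx - cfx, fy - cfy)
    # the +1 order may straddle the frequency wrap-around; measure distance
    # on the torus
    for sx in (-1.0, 0.0, 1.0):
        for sy in (-1.0, 0.0, 1.0):
            if sx == 0.0 and sy == 0.0:
                continue
            dist = np.minimum(dist, np.hypot(fx - cfx + sx, fy - cfy + sy))
    if settings.window == "hard_disk":
        win = (dist <= radius).astype(np.float64)
    else:  # gaussian_soft: ~1 inside, smooth roll-off at the rim
        win = np.exp(-0.5 * (dist / (radius / 2.0)) ** 8)

    selected = spectrum * win
    # shift the +1 order to baseband in the spatial domain
    y = np.arange(h)[:, None]
    x = np.arange(w)[None, :]
    field_ = np.fft.ifft2(selected) * np.exp(-2j * np.pi * (cfx * x + cfy * y))
    return ComplexField(
        data=field_,
        pitch=cfg.object_pixel,
        wavelength=cfg.wavelength,
        z_offset=cfg.defocus_z,
    )


# ----------------------------------------------------------------------
# Angular spectrum propagation
# ----------------------------------------------------------------------

def angular_spectrum_propagate(field_: ComplexField, z: float) -> ComplexField:
    """Propagate a complex field by ``z`` metres (exact scalar diffraction).

    The spectrum is multiplied by ``exp(i 2 pi z sqrt(1/lambda^2 - fx^2 -
    fy^2))``; evanescent components (``fx^2 + fy^2 > 1/lambda^2``) are
    zeroed.  Energy on the propagating band is conserved, and
    ``propagate(z1) o propagate(z2) == propagate(z1 + z2)``.
    """
    if not np.isfinite(z):
        raise ValueError("propagation distance must be finite")
    if z == 0.0:
        return ComplexField(
            field_.data.copy(), field_.pitch, field_.wavelength, field_.z_offset
        )
    h, w = field_.shape
    # frequencies in cycles/metre
    fy = np.fft.fftfreq(h, d=field_.pitch)[:, None]
    fx = np.fft.fftfreq(w, d=field_.pitch)[None, :]
    k2 = 1.0 / field_.wavelength**2 - fx**2 - fy**2
    propagating = k2 >= 0
    kz = np.sqrt(np.where(propagating, k2, 0.0))
    transfer = np.where(propagating, np.exp(2j * np.pi * z * kz), 0.0)
    out = np.fft.ifft2(np.fft.fft2(field_.data) * transfer)
    return ComplexField(out, field_.pitch, field_.wavelength, field_.z_offset - z)


# ----------------------------------------------------------------------
# Autofocus
# ----------------------------------------------------------------------

def _focus_score(field_: ComplexField, metric: str) -> float:
    if metric == "tenengrad_phase":
        p = np.angle(field_.data)
        gy, gx = np.gradient(p)
        return float(np.mean(gx**2 + gy**2))
    a = np.abs(field_.data)
    if metric == "tamura_amplitude":
        m = float(np.mean(a))
        return float(np.sqrt(np.std(a) / m)) if m > 0 else 0.0
    # neg_variance_amplitude: phase objects have flattest amplitude at focus
    return float(-np.var(a))


def autofocus(
    field_: ComplexField, settings: Optional[ReconSettings] = None
) -> Tuple[float, List[Tuple[float, float]]]:
    """Find the propagation distance maximizing the focus metric.

    Coarse grid scan over ``[z_min, z_max]``, then at each refinement level
    a re-scan of +-1 previous step around the argmax with a 10x finer step.
    Ties are broken toward the smallest ``|z|``.  Returns the best distance
    and the full (z, score) curve; a warning is emitted if the optimum sits
    on the search boundary.  Refocusing inverts the recording defocus: a
    hologram recorded ``d`` past focus autofocuses at ``z_best = -d``.
    """
    settings = settings or ReconSettings()
    z_min, z_max, step, levels = settings.z_search
    curve: List[Tuple[float, float]] = []

    def scan(zs: np.ndarray) -> float:
        best_z, best_s = None, -np.inf
        for z in zs:
            s = _focus_score(angular_spectrum_propagate(field_, float(z)), settings.focus_metric)
            curve.append((float(z), s))
            better = s > best_s or (s == best_s and abs(z) < abs(best_z))
            if better:
                best_z, best_s = float(z), s
        return best_z

    n = int(np.floor((z_max - z_min) / step)) + 1
    z_best = scan(z_min + step * np.arange(n))
    if abs(z_best - z_min) < 0.5 * step or abs(z_best - (z_min + step * (n - 1))) < 0.5 * step:
        warnings.warn(
            "autofocus optimum at the search boundary; the z range is "
            "likely too narrow",
            stacklevel=2,
        )
    cur = step
    for _ in range(int(levels)):
        fine = cur / 10.0
        z_best = scan(z_best - cur + fine * np.arange(21))
        cur = fine
    return z_best, curve


# ----------------------------------------------------------------------
# Aberration correction
# ----------------------------------------------------------------------

def correct_aberration(sample: ComplexField, reference: ComplexField) -> PhaseMap:
    """Remove the system's background phase using a sample-free reference.

    Implemented as ``angle(sample * conj(reference) / max(|reference|, eps))``
    - a complex-ratio subtraction that is immune to 2-pi wraps in either
    map (equivalent to subtracting the background phase wherever that
    subtraction is well defined).
    """
    if sample.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: sample {sample.shape} vs reference {reference.shape}"
        )
    eps = 1e-12
    amp = np.abs(reference.data)
    near_zero = amp < eps
    if near_zero.mean() > 0.01:
        warnings.warn(
            f"reference amplitude near zero over {near_zero.mean():.1%} of "
            "pixels; correction is unreliable there",
            stacklevel=2,
        )
    ratio = sample.data * np.conj(reference.data) / np.maximum(amp, eps)
    return PhaseMap(
        phase=np.angle(ratio),
        pitch=sample.pitch,
        provenance={"aberration_corrected": True, "z_offset": sample.z_offset},
    )


# ----------------------------------------------------------------------
# Convenience: full reconstruction of a hologram pair
# ----------------------------------------------------------------------

def reconstruct_pair(
    hologram: np.ndarray,
    reference_hologram: np.ndarray,
    cfg: OpticalConfig,
    settings: Optional[ReconSettings] = None,
    run_autofocus: bool = True,
) -> PhaseMap:
    """Demodulate a sample/reference hologram pair, refocus the sample wave,
    and return the aberration-corrected phase.

    Both holograms are demodulated with identical settings (a requirement of
    the correction step).  When ``run_autofocus`` is false, the field is
    refocused by ``-cfg.defocus_z`` directly.
    """
    settings = settings or ReconSettings()
    obj = demodulate_offaxis(hologram, cfg, settings)
    ref = demodulate_offaxis(reference_hologram, cfg, settings)
    if run_autofocus:
        z_best, _ = autofocus(obj, settings)
    else:
        z_best = -cfg.defocus_z
    if z_best != 0.0:
        obj = angular_spectrum_propagate(obj, z_best)
        ref = angular_spectrum_propagate(ref, z_best)
    pm = correct_aberration(obj, ref)
    pm.provenance.update({"z_best": z_best, "settings": settings.__dict__.copy()})
    return pm
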