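"""Optical system configuration shared by the simulator and the reconstruction.

The geometry mirrors an off-axis digital holographic microscope: a coherent
532 nm source, a 20x / NA 0.50 objective, and a 5.5 um-pitch sensor.  All
spatial frequencies in this package are expressed in cycles per (object-plane)
pixel, where the object-plane pixel pitch is ``camera_pixel / magnification``
(0.275 um at the defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np

__all__ = ["OpticalConfig"]


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and sampling of the holographic imaging system.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in metres.
    magnification : float
        Objective magnification (object -> sensor).
    numerical_aperture : float
        Objective NA; sets the coherent diffraction cutoff NA/lambda.
    camera_pixel : float
        Sensor pixel pitch in metres.
    sensor_shape : (int, int)
        Sensor size in pixels, (rows, cols).
    carrier : (float, float)
        Off-axis carrier frequency (fx, fy) in cycles/pixel.  The reference
        wave is ``exp(i 2 pi (fx x + fy y))`` with x = column, y = row index.
    defocus_z : float
        Propagation distance (m) between the object plane and the recorded
        plane; 0 means the hologram is recorded in focus.
    bit_depth : int
        0 keeps holograms as floats; 8 or 16 quantizes them on synthesis.
    band_fraction : float
        Fraction of the coherent NA cutoff actually occupied by the object
        spectrum.  The smooth phase specimens simulated here concentrate
        their energy well inside the NA limit, and the off-axis carrier of
        the physical system only separates this effective band (the full NA
        band would not fit beside its twin at a 5.5 um pitch).
    """

    wavelength: float = 532e-9
    magnification: float = 20.0
    numerical_aperture: float = 0.50
    camera_pixel: float = 5.5e-6
    sensor_shape: Tuple[int, int] = (2048, 2048)
    carrier: Tuple[float, float] = (0.25, 0.25)
    defocus_z: float = 0.0
    bit_depth: int = 0
    band_fraction: float = 0.55

    def __post_init__(self) -> None:
        if self.wavelength <= 0 or self.magnification <= 0:
            raise ValueError("wavelength and magnification must be positive")
        if self.camera_pixel <= 0:
            raise ValueError("camera_pixel must be positive")
        if not (0 < self.numerical_aperture < 1):
            raise ValueError("numerical_aperture must lie in (0, 1)")
        if len(self.sensor_shape) != 2 or any(int(s) < 8 for s in self.sensor_shape):
            raise ValueError(f"sensor_shape {self.sensor_shape} too small")
        if not (0 < self.band_fraction <= 1):
            raise ValueError("band_fraction must lie in (0, 1]")
        if self.bit_depth not in (0, 8, 16):
            raise ValueError("bit_depth must be 0 (float), 8 or 16")
        b = self.band_radius
        f = self.carrier_magnitude
        if not (b < f):
            raise ValueError(
                f"carrier |f|={f:.4f} cycles/px must exceed the object band "
                f"radius b={b:.4f}: the +1 order would overlap DC"
            )
        if not (f + b < 0.5):
            raise ValueError(
                f"carrier |f|={f:.4f} plus band radius b={b:.4f} reaches "
                "Nyquist (0.5 cycles/px): the +1 order would alias"
            )

    # ------------------------------------------------------------------
    @property
    def object_pixel(self) -> float:
        """Object-plane pixel pitch in metres (camera_pixel / magnification)."""
        return self.camera_pixel / self.magnification

    @property
    def na_band_radius(self) -> float:
        """Coherent NA cutoff in cycles/pixel at the object-plane pitch."""
        return self.numerical_aperture / self.wavelength * self.object_pixel

    @property
    def band_radius(self) -> float:
        """Effective object band radius (cycles/pixel) used for separability
        checks and as the default demodulation filter radius."""
        return self.band_fraction * self.na_band_radius

    @property
    def carrier_magnitude(self) -> float:
        fx, fy = self.carrier
        return float(np.hypot(fx, fy))

    def frequency_grids(self, shape: Tuple[int, int] | None = None):
        """Return (fx, fy) grids in cycles/pixel for an FFT of ``shape``."""
        h, w = shape if shape is not None else self.sensor_shape
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.fftfreq(w)[None, :]
        return fx, fy

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sensor_shape"] = list(self.sensor_shape)
        d["carrier"] = list(self.carrier)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        d = dict(d)
        if "sensor_shape" in d:
            d["sensor_shape"] = tuple(int(v) for v in d["sensor_shape"])
        if "carrier" in d:
            d["carrier"] = tuple(float(v) for v in d["carrier"])
        return cls(**d)
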