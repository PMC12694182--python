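"""Synthetic liquid-cytology fields, off-axis holograms and fluorescence.

The generator emulates a smear of peripheral blood mononuclear cells (PBMCs,
small and optically thin) spiked with rare HCT116-like tumor cells (larger
and optically denser) at PBMC:tumor ratios of 10:1, 50:1 and 1000:1, imaged
by an off-axis digital holographic microscope with a parallel fluorescence
channel.  Every operation is a pure function of its inputs and a seed.

Cells are modeled as spherical-cap phase profiles,
``peak * sqrt(max(0, 1 - (d/r)^2))``.  Cells lie in a monolayer: where
footprints overlap, the taller profile wins (elementwise max), so the
field's phase never exceeds the tallest cell's peak and, with tumor peaks
capped below pi, the reconstructed phase never wraps (phase unwrapping is
deliberately outside this package's scope).  The takeover creases between
adherent cells are exactly what the phase-gradient input channels make
visible to the network.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field, asdict
from typing import List, Optional, Tuple

import numpy as np

from .optics import OpticalConfig
from .recon import ComplexField, angular_spectrum_propagate

__all__ = [
    "CellRecord",
    "CellPopulationSpec",
    "GroundTruthField",
    "RawFluorescence",
    "FluorescenceParams",
    "sample_cell_field",
    "synthesize_hologram",
    "synthesize_reference_hologram",
    "render_fluorescence",
    "polynomial_aberration",
    "random_aberration",
    "tumor_count",
]

PBMC = "PBMC"
TUMOR = "TUMOR"


class GenerationError(RuntimeError):
    """Raised when a field cannot be generated under the given constraints."""


@dataclass(frozen=True)
class CellRecord:
    """One cell of the ground truth: kind, centre (pixels), radius (pixels),
    peak optical phase (radians)."""

    kind: str
    row: float
    col: float
    radius_px: float
    peak_phase: float

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CellRecord":
        return cls(**d)


@dataclass(frozen=True)
class CellPopulationSpec:
    """Composition of a simulated smear.

    Radii are in metres, peak phases in radians.  ``donor_jitter`` is a
    per-donor multiplicative spread applied to radii and phases (the stand-in
    for biological inter-donor variation); the per-donor factors are a
    deterministic function of ``donor_id``.  ``adhesion_prob`` is the
    probability that a new cell is placed tangent to an existing one,
    producing the adherent clusters that are the hard case for phase-only
    staining.
    """

    ratio_pbmc_to_tumor: int = 10
    cells_per_field: int = 200
    pbmc_radius: Tuple[float, float] = (3.5e-6, 5.0e-6)
    tumor_radius: Tuple[float, float] = (7.0e-6, 12.0e-6)
    pbmc_peak_phase: Tuple[float, float] = (0.6, 1.2)
    tumor_peak_phase: Tuple[float, float] = (1.8, 2.8)
    adhesion_prob: float = 0.15
    donor_id: str = "donor00"
    donor_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio_pbmc_to_tumor < 1:
            raise ValueError("ratio_pbmc_to_tumor must be >= 1")
        if self.cells_per_field < 1:
            raise ValueError("cells_per_field must be >= 1")
        for name in ("pbmc_radius", "tumor_radius", "pbmc_peak_phase", "tumor_peak_phase"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive ordered range, got {(lo, hi)}")
        if self.tumor_peak_phase[1] >= np.pi:
            raise ValueError(
                "tumor peak phase must stay below pi to keep the "
                "reconstruction wrap-free"
            )
        if not (0 <= self.adhesion_prob <= 1):
            raise ValueError("adhesion_prob must lie in [0, 1]")
        if self.donor_jitter < 0:
            raise ValueError("donor_jitter must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("pbmc_radius", "tumor_radius", "pbmc_peak_phase", "tumor_peak_phase"):
            d[k] = list(d[k])
        return d


@dataclass
class GroundTruthField:
    """A simulated field: cell records, true phase map (radians, object
    plane) and the true cancer mask (union of tumor footprints)."""

    cells: List[CellRecord]
    phase: np.ndarray
    cancer_mask: np.ndarray
    field_id: str = ""
    donor_id: str = ""
    ratio: int = 0

    def __post_init__(self) -> None:
        if self.phase.shape != self.cancer_mask.shape:
            raise ValueError("phase and cancer_mask must share a shape")

    @property
    def tumor_cells(self) -> List[CellRecord]:
        return [c for c in self.cells if c.kind == TUMOR]

    @property
    def pbmc_cells(self) -> List[CellRecord]:
        return [c for c in self.cells if c.kind == PBMC]


@dataclass(frozen=True)
class FluorescenceParams:
    """Imaging imperfections of the fluorescence channel: PSF blur,
    constant background, excitation bleed-through onto PBMCs, and shot-like
    Gaussian noise."""

    psf_sigma: float = 4.0
    background_level: float = 0.05
    leakage_level: float = 0.15
    noise_sigma: float = 0.02

    def __post_init__(self) -> None:
        for name in ("psf_sigma", "background_level", "leakage_level", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RawFluorescence:
    """A rendered raw fluorescence image together with the parameters that
    produced it."""

    image: np.ndarray
    params: FluorescenceParams = dc_field(default_factory=FluorescenceParams)

    def __post_init__(self) -> None:
        if self.image.ndim != 2:
            raise ValueError("fluorescence image must be 2-D")
        if np.any(self.image < 0):
            raise ValueError("fluorescence image must be non-negative")


# ----------------------------------------------------------------------
# Field sampling
# ----------------------------------------------------------------------

def tumor_count(spec: CellPopulationSpec) -> int:
    """Number of tumor cells in a field: ``max(1, round(n / (ratio+1)))``.

    The ``max(1, .)`` floor guarantees that even 1000:1 fields contain a
    tumor cell, mirroring how rare-cell smears are actually screened.
    """
    r = spec.ratio_pbmc_to_tumor
    return max(1, int(np.floor(spec.cells_per_field / (r + 1) + 0.5)))


def _donor_factors(donor_id: str, jitter: float) -> Tuple[float, float]:
    """Deterministic per-donor multiplicative factors (radius, phase)."""
    rng = np.random.default_rng(zlib.crc32(donor_id.encode("utf8")))
    f = 1.0 + jitter * rng.standard_normal(2)
    return float(np.clip(f[0], 0.5, 1.5)), float(np.clip(f[1], 0.5, 1.5))


def _render_cap(phase: np.ndarray, row: float, col: float, r: float, peak: float) -> None:
    h, w = phase.shape
    r0, r1 = max(0, int(np.floor(row - r))), min(h, int(np.ceil(row + r)) + 1)
    c0, c1 = max(0, int(np.floor(col - r))), min(w, int(np.ceil(col + r)) + 1)
    yy = np.arange(r0, r1)[:, None] - row
    xx = np.arange(c0, c1)[None, :] - col
    d2 = (yy**2 + xx**2) / r**2
    cap = peak * np.sqrt(np.maximum(0.0, 1.0 - d2))
    np.maximum(phase[r0:r1, c0:c1], cap, out=phase[r0:r1, c0:c1])


def _footprint(mask: np.ndarray, row: float, col: float, r: float) -> None:
    h, w = mask.shape
    r0, r1 = max(0, int(np.floor(row - r))), min(h, int(np.ceil(row + r)) + 1)
    c0, c1 = max(0, int(np.floor(col - r))), min(w, int(np.ceil(col + r)) + 1)
    yy = np.arange(r0, r1)[:, None] - row
    xx = np.arange(c0, c1)[None, :] - col
    mask[r0:r1, c0:c1] |= (yy**2 + xx**2) <= r**2


def sample_cell_field(
    spec: CellPopulationSpec,
    cfg: OpticalConfig,
    seed: Optional[int] = None,
) -> GroundTruthField:
    """Draw a random smear and render its true phase map and cancer mask.

    The tumor-cell count follows :func:`tumor_count`; the rest are PBMCs.
    Placement is sequential: with probability ``adhesion_prob`` a new cell
    is set tangent to a random existing cell, otherwise positions are drawn
    uniformly with a soft overlap rejection (centre separation at least
    0.85 of the radius sum, relaxed progressively when the field is
    crowded — smears at ~200 cells per field are dense enough that cells
    touch).  Overlapping profiles combine by elementwise max (monolayer
    model; see the module docstring).
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    h, w = cfg.sensor_shape
    pitch = cfg.object_pixel

    n_tumor = tumor_count(spec)
    if n_tumor > spec.cells_per_field:
        raise GenerationError(
            f"tumor count {n_tumor} exceeds cells_per_field {spec.cells_per_field}"
        )
    kinds = [TUMOR] * n_tumor + [PBMC] * (spec.cells_per_field - n_tumor)
    rng.shuffle(kinds)

    rf, pf = _donor_factors(spec.donor_id, spec.donor_jitter)
    max_tumor_r_px = spec.tumor_radius[1] * rf / pitch
    if 2 * max_tumor_r_px >= min(h, w):
        raise GenerationError(
            f"field {h}x{w} px too small for tumor cells of radius "
            f"{max_tumor_r_px:.1f} px"
        )

    cells: List[CellRecord] = []
    for kind in kinds:
        if kind == TUMOR:
            r_m = rng.uniform(*spec.tumor_radius) * rf
            peak = rng.uniform(*spec.tumor_peak_phase) * pf
            peak = min(peak, np.pi - 0.05)
        else:
            r_m = rng.uniform(*spec.pbmc_radius) * rf
            peak = rng.uniform(*spec.pbmc_peak_phase) * pf
        r_px = r_m / pitch
        if 2 * r_px >= min(h, w):
            raise GenerationError(f"field too small for a cell of radius {r_px:.1f} px")

        placed = False
        if cells and rng.random() < spec.adhesion_prob:
            # adherent placement: tangent to a random existing cell
            for _ in range(20):
                host = cells[rng.integers(len(cells))]
                ang = rng.uniform(0, 2 * np.pi)
                d = host.radius_px + r_px
                row = host.row + d * np.sin(ang)
                col = host.col + d * np.cos(ang)
                if r_px <= row <= h - 1 - r_px and r_px <= col <= w - 1 - r_px:
                    placed = True
                    break
        if not placed:
            # uniform placement with soft overlap rejection; the acceptance
            # threshold relaxes in stages so dense fields still fill (cells
            # end up touching and partially stacking, as in a real smear)
            if cells:
                crows = np.array([c.row for c in cells])
                ccols = np.array([c.col for c in cells])
                cradii = np.array([c.radius_px for c in cells])
            for sep in (0.85, 0.7, 0.55, 0.45, 0.35, 0.25, 0.0):
                for _ in range(40):
                    row = rng.uniform(r_px, h - 1 - r_px)
                    col = rng.uniform(r_px, w - 1 - r_px)
                    if not cells or sep == 0.0:
                        placed = True
                        break
                    d = np.hypot(row - crows, col - ccols)
                    if np.all(d >= sep * (r_px + cradii)):
                        placed = True
                        break
                if placed:
                    break
            if not placed:  # only reachable when the margin leaves no room
                raise GenerationError(
                    f"could not place cell {len(cells) + 1}/{spec.cells_per_field} "
                    f"in a {h}x{w} px field after bounded retries "
                    "(field too small for the requested cell sizes)"
                )
        cells.append(CellRecord(kind, float(row), float(col), float(r_px), float(peak)))

    phase = np.zeros((h, w), dtype=np.float64)
    cancer_mask = np.zeros((h, w), dtype=bool)
    for c in cells:
        _render_cap(phase, c.row, c.col, c.radius_px, c.peak_phase)
        if c.kind == TUMOR:
            _footprint(cancer_mask, c.row, c.col, c.radius_px)

    return GroundTruthField(
        cells=cells,
        phase=phase,
        cancer_mask=cancer_mask,
        donor_id=spec.donor_id,
        ratio=spec.ratio_pbmc_to_tumor,
    )


# ----------------------------------------------------------------------
# Aberrations
# ----------------------------------------------------------------------

def polynomial_aberration(
    shape: Tuple[int, int],
    tilt: Tuple[float, float] = (0.0, 0.0),
    defocus: float = 0.0,
    astigmatism: Tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Low-order background phase map (radians): tilt + defocus +
    astigmatism over normalized coordinates u, v in [-1, 1]."""
    h, w = shape
    v = np.linspace(-1.0, 1.0, h)[:, None]
    u = np.linspace(-1.0, 1.0, w)[None, :]
    ax, ay = tilt
    a0, a45 = astigmatism
    return ax * u + ay * v + defocus * (u**2 + v**2) + a0 * (u**2 - v**2) + a45 * (2 * u * v)


def random_aberration(
    shape: Tuple[int, int], seed: int, max_tilt: float = 0.5, max_quad: float = 0.3
) -> np.ndarray:
    """Random low-order aberration with coefficients bounded by
    ``max_tilt`` (rad) for tilt and ``max_quad`` (rad) for the quadratic
    terms."""
    rng = np.random.default_rng(seed)
    return polynomial_aberration(
        shape,
        tilt=tuple(rng.uniform(-max_tilt, max_tilt, 2)),
        defocus=float(rng.uniform(-max_quad, max_quad)),
        astigmatism=tuple(rng.uniform(-max_quad, max_quad, 2)),
    )


# ----------------------------------------------------------------------
# Holograms
# ----------------------------------------------------------------------

def _interfere(
    phase: np.ndarray,
    cfg: OpticalConfig,
    aberration: Optional[np.ndarray],
    noise_sigma: float,
    seed: int,
) -> np.ndarray:
    if phase.shape != tuple(cfg.sensor_shape):
        raise ValueError(
            f"phase shape {phase.shape} does not match sensor {cfg.sensor_shape}"
        )
    total = phase if aberration is None else phase + aberration
    if aberration is not None and aberration.shape != phase.shape:
        raise ValueError("aberration map shape must match the field")

    obj = np.exp(1j * total)
    if cfg.defocus_z != 0.0:
        fld = ComplexField(obj, cfg.object_pixel, cfg.wavelength, z_offset=0.0)
        obj = angular_spectrum_propagate(fld, cfg.defocus_z).data

    h, w = phase.shape
    y = np.arange(h)[:, None]
    x = np.arange(w)[None, :]
    fx, fy = cfg.carrier
    # conjugate tilt: the O-bearing cross term O*conj(R) then sits at
    # +carrier in the spectrum, which is where the demodulator looks
    ref = np.exp(-2j * np.pi * (fx * x + fy * y))
    intensity = np.abs(obj + ref) ** 2

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sigma, intensity.shape)
    intensity = np.maximum(intensity, 0.0)

    if cfg.bit_depth > 0:
        levels = 2**cfg.bit_depth - 1
        peak = intensity.max()
        if peak > 0:
            q = np.round(intensity / peak * levels)
        else:
            q = intensity
        dtype = np.uint8 if cfg.bit_depth == 8 else np.uint16
        return q.astype(dtype)
    return intensity


def synthesize_hologram(
    field: GroundTruthField,
    cfg: OpticalConfig,
    aberration: Optional[np.ndarray] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Off-axis hologram of a field: the unit-amplitude object wave
    ``exp(i(phi + aberration))`` is propagated by ``cfg.defocus_z`` and
    interfered with a tilted plane reference; Gaussian sensor noise is
    added and the result clipped at zero (and quantized when the config
    sets a bit depth)."""
    return _interfere(field.phase, cfg, aberration, noise_sigma, seed)


def synthesize_reference_hologram(
    cfg: OpticalConfig,
    aberration: Optional[np.ndarray] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sample-free hologram recorded under identical optical conditions
    (same aberration map and defocus as the paired sample hologram)."""
    zero = np.zeros(tuple(cfg.sensor_shape), dtype=np.float64)
    return _interfere(zero, cfg, aberration, noise_sigma, seed)


# ----------------------------------------------------------------------
# Fluorescence
# ----------------------------------------------------------------------

def render_fluorescence(
    field: GroundTruthField,
    params: Optional[FluorescenceParams] = None,
    seed: int = 0,
) -> RawFluorescence:
    """Raw fluorescence image of a field.

    Tumor footprints emit at unit intensity; PBMC footprints at
    ``leakage_level`` (residual excitation bleed-through); the scene is
    blurred by a Gaussian PSF, offset by a constant background, corrupted
    by Gaussian noise and clipped at zero.
    """
    params = params or FluorescenceParams()
    scene = field.cancer_mask.astype(np.float64)
    if params.leakage_level > 0:
        pbmc = np.zeros(field.phase.shape, dtype=bool)
        for c in field.pbmc_cells:
            _footprint(pbmc, c.row, c.col, c.radius_px)
        scene = scene + params.leakage_level * pbmc

    if params.psf_sigma > 0:
        from scipy.ndimage import gaussian_filter

        scene = gaussian_filter(scene, params.psf_sigma)
    img = scene + params.background_level
    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    return RawFluorescence(image=np.maximum(img, 0.0), params=params)
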