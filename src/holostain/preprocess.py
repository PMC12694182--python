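"""Network input/target construction and dataset bookkeeping.

Inputs are 3-channel stacks (x-gradient, y-gradient, phase) built by the
one-pixel shift-and-subtract rule; targets overlay the fluorescence-derived
cancer mask on the normalized phase map (0.5 x phase outside the mask, 1.0
inside), so the mask is exactly recoverable by thresholding the target at
0.75.  Also provides centroid-based translation registration between tiles
or modalities, co-registered crop extraction, and the 3:1:1
train/val/test split with the unseen-donor pool quarantined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_fill_holes, binary_opening, gaussian_filter, label
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .optics import OpticalConfig
from .recon import PhaseMap
from .simulate import CellPopulationSpec, RawFluorescence

__all__ = [
    "InputStack",
    "StainTarget",
    "CentroidSet",
    "MASK_THRESHOLD",
    "gradient_channels",
    "fluo_to_mask",
    "default_min_area_px",
    "compose_target",
    "register_by_centroids",
    "RegistrationError",
    "crop_pairs",
    "split_manifest",
    "split_counts",
]

#: Stain level of masked (cancer) pixels in the target, and the threshold at
#: which the mask is recovered from a stain image.  Shared by target
#: composition and cell extraction so the two stages cannot drift apart.
MASK_THRESHOLD = 0.75


@dataclass
class InputStack:
    """3-channel network input, ordered (gradient_x, gradient_y, phase).

    Each channel is min-max normalized to [0, 1]; ``norm_params`` records
    the per-channel (offset, scale) so the normalization is invertible:
    ``raw = normalized * scale + offset``.
    """

    channels: np.ndarray  # (3, H, W)
    norm_params: List[Tuple[float, float]]
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError("InputStack requires a (3, H, W) array")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.channels.shape[1:]


@dataclass
class StainTarget:
    """Single-channel stain target in [0, 1] plus the mask it encodes."""

    image: np.ndarray
    mask: np.ndarray
    phase_norm: Tuple[float, float] = (0.0, 1.0)
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("target image and mask must share a shape")


@dataclass
class CentroidSet:
    """Cell-centroid coordinates of one tile/modality, as (x, y) pixels."""

    points: np.ndarray  # (N, 2) as (x, y)
    source: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)


class RegistrationError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# Input channels
# ----------------------------------------------------------------------

def _minmax(c: np.ndarray) -> Tuple[np.ndarray, Tuple[float, float]]:
    lo = float(c.min())
    span = float(c.max() - lo)
    if span == 0.0:
        return np.zeros_like(c), (lo, 1.0)
    return (c - lo) / span, (lo, span)


def gradient_channels(phase: PhaseMap | np.ndarray, normalize: bool = True) -> InputStack:
    """Build the (gx, gy, phase) input stack by one-pixel shift-and-subtract.

    ``gx[i, j] = phi[i, j] - phi[i, j-1]`` and ``gy[i, j] = phi[i, j] -
    phi[i-1, j]``; the first column/row (no left/up neighbour) is 0,
    i.e. the shifted copy uses replicate padding.  Channels are then
    min-max normalized with recorded parameters (``normalize=False``
    keeps the raw values and records identity parameters).
    """
    provenance: dict = {}
    if isinstance(phase, PhaseMap):
        provenance = dict(phase.provenance)
        phase = phase.phase
    phi = np.asarray(phase, dtype=np.float64)
    if phi.ndim != 2:
        raise ValueError("phase must be 2-D")
    if not np.all(np.isfinite(phi)):
        raise ValueError("phase must be finite")

    gx = np.zeros_like(phi)
    gx[:, 1:] = phi[:, 1:] - phi[:, :-1]
    gy = np.zeros_like(phi)
    gy[1:, :] = phi[1:, :] - phi[:-1, :]

    norms = []
    chans = []
    for c in (gx, gy, phi):
        if normalize:
            n, p = _minmax(c)
        else:
            n, p = c, (0.0, 1.0)
        chans.append(n)
        norms.append(p)
    return InputStack(
        channels=np.stack(chans), norm_params=norms, provenance=provenance
    )


# ----------------------------------------------------------------------
# Fluorescence -> mask
# ----------------------------------------------------------------------

def default_min_area_px(cfg: OpticalConfig, spec: CellPopulationSpec) -> int:
    """Quarter of the smallest tumor-cell footprint, in pixels: small
    enough to keep every genuine tumor cell, large enough to reject
    leakage speckle."""
    r_px = spec.tumor_radius[0] / cfg.object_pixel
    return int(0.25 * np.pi * r_px**2)


def fluo_to_mask(
    fluo: RawFluorescence | np.ndarray,
    blur_sigma: float = 1.0,
    threshold_mode: str = "otsu",
    fixed_threshold: Optional[float] = None,
    min_area_px: int = 0,
    opening_radius_px: int = 2,
    fill_holes: bool = True,
) -> np.ndarray:
    """Segment cancer cells from a raw fluorescence image.

    Gaussian denoise -> global threshold (Otsu by default, which lands
    between the bright tumor signal and the PBMC leakage/background) ->
    morphological opening -> small-component removal -> hole filling.
    An empty mask is legitimate (a field or crop may contain no tumor
    cell) and triggers a warning rather than an error.
    """
    img = fluo.image if isinstance(fluo, RawFluorescence) else np.asarray(fluo)
    if img.ndim != 2:
        raise ValueError("fluorescence image must be 2-D")
    if np.any(img < 0):
        raise ValueError("fluorescence image must be non-negative")

    sm = gaussian_filter(img.astype(np.float64), blur_sigma) if blur_sigma > 0 else img
    if threshold_mode == "fixed":
        if fixed_threshold is None:
            raise ValueError("threshold_mode='fixed' requires fixed_threshold")
        t = float(fixed_threshold)
    elif threshold_mode == "otsu":
        if np.ptp(sm) == 0:
            t = np.inf  # constant image: nothing to segment
        else:
            t = threshold_otsu(sm)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    mask = sm > t
    if opening_radius_px > 0:
        mask = binary_opening(mask, structure=disk(opening_radius_px))
    if min_area_px > 0:
        lab, n = label(mask)
        if n:
            areas = np.bincount(lab.ravel())
            small = np.flatnonzero(areas < int(min_area_px))
            mask &= ~np.isin(lab, small[small > 0])
    if fill_holes:
        mask = binary_fill_holes(mask)
    if not mask.any():
        warnings.warn(
            "fluorescence thresholding produced an empty mask "
            "(no cancer cells detected)",
            stacklevel=2,
        )
    return mask


# ----------------------------------------------------------------------
# Target composition
# ----------------------------------------------------------------------

def compose_target(phase: PhaseMap | np.ndarray, mask: np.ndarray) -> StainTarget:
    """Combine the phase map and the segmentation mask into the stain target.

    The normalized phase is kept at half dynamic range outside the mask
    (cellular context stays visible) and cancer regions are saturated at
    1.0.  The rule is fixed: targets are recomputable from their parts and
    thresholding at :data:`MASK_THRESHOLD` recovers the mask exactly.
    """
    if isinstance(phase, PhaseMap):
        phase = phase.phase
    phi = np.asarray(phase, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if phi.shape != mask.shape:
        raise ValueError(f"shape mismatch: phase {phi.shape} vs mask {mask.shape}")
    norm, params = _minmax(phi)
    image = np.where(mask, 1.0, 0.5 * norm)
    return StainTarget(image=image, mask=mask, phase_norm=params)


# ----------------------------------------------------------------------
# Centroid registration
# ----------------------------------------------------------------------

def register_by_centroids(
    a: CentroidSet,
    b: CentroidSet,
    max_match_dist: float = 3.0,
    bin_size: float = 4.0,
) -> Tuple[Tuple[float, float], List[Tuple[int, int]], float]:
    """Estimate the translation taking set ``a`` onto set ``b``.

    A 2-D histogram of all pairwise offsets (bin ``bin_size`` px) provides
    a coarse shift; mutual nearest neighbours under that shift become
    candidate matches; the translation is the component-wise median of the
    matched offsets.  Matches whose residual exceeds ``max_match_dist``
    are dropped and the translation re-estimated once.

    Returns ``((dx, dy), matches, residual)`` with ``residual`` the median
    Euclidean deviation of the surviving matches.
    """
    pa, pb = a.points, b.points
    if len(pa) < 3 or len(pb) < 3:
        raise RegistrationError("registration failed: need at least 3 points per set")

    offsets = (pb[None, :, :] - pa[:, None, :]).reshape(-1, 2)
    ox, oy = offsets[:, 0], offsets[:, 1]
    bx = np.floor(ox / bin_size).astype(int)
    by = np.floor(oy / bin_size).astype(int)
    keys, counts = np.unique(np.stack([bx, by], axis=1), axis=0, return_counts=True)
    order = np.argsort(-counts)
    best = keys[order[0]]
    # ambiguity: a second, non-adjacent mode within 10% of the strongest
    for idx in order[1:]:
        if counts[idx] < 0.9 * counts[order[0]]:
            break
        other = keys[idx]
        if np.max(np.abs(best - other)) > 1:
            c0 = (best + 0.5) * bin_size
            c1 = (other + 0.5) * bin_size
            raise RegistrationError(
                "ambiguous offset histogram: candidate shifts "
                f"~({c0[0]:.0f}, {c0[1]:.0f}) and ~({c1[0]:.0f}, {c1[1]:.0f}) "
                "have comparable support"
            )
    coarse = (best + 0.5) * bin_size

    def estimate(pairs: List[Tuple[int, int]]):
        offs = np.array([pb[j] - pa[i] for i, j in pairs])
        t = np.median(offs, axis=0)
        res = np.hypot(*(offs - t).T)
        return t, res

    # mutual nearest neighbours under the coarse shift
    shifted = pa + coarse
    d = np.hypot(
        shifted[:, None, 0] - pb[None, :, 0], shifted[:, None, 1] - pb[None, :, 1]
    )
    nn_ab = np.argmin(d, axis=1)
    nn_ba = np.argmin(d, axis=0)
    pairs = [(i, int(nn_ab[i])) for i in range(len(pa)) if nn_ba[nn_ab[i]] == i]
    if len(pairs) < 3:
        raise RegistrationError("registration failed: fewer than 3 mutual matches")

    t, res = estimate(pairs)
    keep = [p for p, r in zip(pairs, res) if r <= max_match_dist]
    if len(keep) < 3:
        raise RegistrationError(
            "registration failed: fewer than 3 matches within "
            f"max_match_dist={max_match_dist}"
        )
    if len(keep) < len(pairs):
        t, res2 = estimate(keep)
        residual = float(np.median(res2))
    else:
        residual = float(np.median(res))
    return (float(t[0]), float(t[1])), keep, residual


# ----------------------------------------------------------------------
# Crops
# ----------------------------------------------------------------------

def crop_origins(shape: Tuple[int, int], size: int) -> List[Tuple[int, int]]:
    """Valid crop origins on a grid with stride size/4 (keeps crops from
    being near-duplicates of each other)."""
    h, w = shape
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds image dims {shape}")
    stride = max(1, size // 4)
    rows = list(range(0, h - size + 1, stride))
    cols = list(range(0, w - size + 1, stride))
    return [(r, c) for r in rows for c in cols]


def crop_pairs(
    stack: InputStack,
    target: StainTarget,
    size: int,
    n: int,
    seed: int = 0,
    extras: Optional[Dict[str, np.ndarray]] = None,
) -> List[dict]:
    """Draw ``n`` co-registered crops from an input stack and its target.

    Origins are sampled uniformly without replacement on the stride-size/4
    grid; identical origins are applied to every channel, the target, and
    any ``extras`` maps (e.g. the fluorescence image).  Returns a list of
    dicts with keys ``origin``, ``input`` (3, s, s), ``target`` (s, s) and
    one key per extra.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if stack.shape != target.image.shape:
        raise ValueError("stack and target shapes differ")
    origins = crop_origins(stack.shape, size)
    if n > len(origins):
        raise ValueError(
            f"requested {n} crops but only {len(origins)} origins available "
            f"for size {size} on {stack.shape}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(origins), size=n, replace=False)
    out = []
    for idx in chosen:
        r, c = origins[int(idx)]
        item = {
            "origin": (r, c),
            "input": stack.channels[:, r : r + size, c : c + size].copy(),
            "target": target.image[r : r + size, c : c + size].copy(),
        }
        for k, v in (extras or {}).items():
            item[k] = v[r : r + size, c : c + size].copy()
        out.append(item)
    return out


# ----------------------------------------------------------------------
# Splitting
# ----------------------------------------------------------------------

def split_counts(n: int, ratio: Tuple[int, int, int] = (3, 1, 1)) -> Tuple[int, int, int]:
    """Sizes of train/val/test for ``n`` examples at the given ratio,
    remainders assigned train-first (then val, then test)."""
    total = sum(ratio)
    base = [n * r // total for r in ratio]
    rem = n - sum(base)
    i = 0
    while rem > 0:
        base[i % 3] += 1
        rem -= 1
        i += 1
    return tuple(base)  # type: ignore[return-value]


def split_manifest(
    entries: List[dict],
    ratio: Tuple[int, int, int] = (3, 1, 1),
    seed: int = 0,
    stratify_by: Sequence[str] = ("donor_id", "ratio"),
) -> List[dict]:
    """Assign train/val/test labels 3:1:1 within each (donor, ratio)
    stratum of the primary pool.

    Entries already labeled ``"unseen"`` are never touched (the unseen-donor
    pool is structurally quarantined from training).  Shuffling is seeded;
    strata smaller than 5 fall back to the same arithmetic with a warning.
    Returns the same entry dicts with their ``split`` fields set.
    """
    rng = np.random.default_rng(seed)
    primary = [e for e in entries if e.get("split") != "unseen"]
    strata: Dict[tuple, List[dict]] = {}
    for e in primary:
        key = tuple(e[k] for k in stratify_by)
        strata.setdefault(key, []).append(e)
    for key in sorted(strata.keys(), key=str):
        group = strata[key]
        if len(group) < 5:
            warnings.warn(
                f"stratum {key} has only {len(group)} examples; the 3:1:1 "
                "split is approximate",
                stacklevel=2,
            )
        order = rng.permutation(len(group))
        n_tr, n_va, n_te = split_counts(len(group), ratio)
        for pos, idx in enumerate(order):
            if pos < n_tr:
                group[idx]["split"] = "train"
            elif pos < n_tr + n_va:
                group[idx]["split"] = "val"
            else:
                group[idx]["split"] = "test"
    return entries
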