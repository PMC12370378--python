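"""Gold fiducial-marker extraction from susceptibility maps.

Post-processing chain: dilate the prostate mask into a search region,
threshold the chi histogram at the gold/calcification midpoint, remove
isolated voxels, keep slice-connected regions, and localize and classify
each region's centroid by its mean susceptibility. Gold (-36 +/- 4 ppm),
calcification (-21 +/- 3 ppm) and air (+0.024 ppm) occupy disjoint chi
bands, which is what makes the discrimination work.

:func:`detect_markers` composes the whole pipeline (field fit ->
background removal -> inversion -> extraction) when given raw echoes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .core import GridMeta, MultiEchoGRE, SusceptibilityMap

GOLD_NOMINAL_PPM = -36.0
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DetectionParams:
    """Tunable knobs of the extraction chain (defaults per the pelvis task)."""

    search_margin_mm: float = 3.0        # markers sit at the gland edge
    chi_threshold_ppm: float = -28.0     # midpoint of gold/calcification bands
    min_voxels: int = 2
    min_slice_span: int = 2
    class_bands: dict = dc_field(default_factory=lambda: {
        "gold": (-48.0, -24.0),          # nominal +/- 3 sigma
        "calcification": (-24.0, -10.0),
        "air": (0.0, np.inf),
    })
    max_markers: int = 3
    slice_axis: int = 2
    adaptive_threshold: bool = True
    adaptive_percentile: float = 5.0
    centroid_weighting: str = "chi"      # or "geometric"

    def __post_init__(self) -> None:
        if self.min_voxels < 1 or self.min_slice_span < 1:
            raise ValueError("min_voxels and min_slice_span must be >= 1")


@dataclass
class MarkerCandidate:
    """One detected chi region."""

    centroid_mm: tuple[float, float, float]
    centroid_voxel: tuple[float, float, float]
    n_voxels: int
    slice_span: int
    chi_mean: float
    chi_min: float
    label: str
    score: float
    surplus: bool = False
    is_detection: bool = False
    region_label: int = 0     # label in the region volume this came from


# --------------------------------------------------------------------------
# chain steps
# --------------------------------------------------------------------------

def make_search_mask(
    prostate_mask: np.ndarray, margin_mm: float, grid: GridMeta
) -> np.ndarray:
    """Dilate the prostate mask by a box reaching `margin_mm` per axis.

    The per-axis radius is the number of whole voxels covered by the
    margin (margin // voxel size), so a 1 mm margin on 2 mm slices does
    not cross a slice.
    """
    mask = np.asarray(prostate_mask, dtype=bool)
    if not mask.any():
        raise ValueError("prostate mask is empty")
    if margin_mm <= 0:
        return mask.copy()
    radii = [int(margin_mm / v + 1e-9) for v in grid.voxel_size]
    if all(r == 0 for r in radii):
        return mask.copy()
    struct = np.ones(tuple(2 * r + 1 for r in radii), dtype=bool)
    return ndimage.binary_dilation(mask, structure=struct)


def threshold_candidates(
    chi: SusceptibilityMap | np.ndarray,
    search_mask: np.ndarray,
    params: DetectionParams | None = None,
) -> np.ndarray:
    """Histogram cut: voxels in the search region with chi at or below
    the threshold. If the fixed cut selects nothing and adaptive mode is
    on, fall back to the low percentile of chi within the search region."""
    params = params or DetectionParams()
    chi_vol = chi.chi if isinstance(chi, SusceptibilityMap) else np.asarray(chi)
    search = np.asarray(search_mask, dtype=bool)
    sel = search & (chi_vol <= params.chi_threshold_ppm)
    if not sel.any() and params.adaptive_threshold and search.any():
        thr = float(np.percentile(chi_vol[search], params.adaptive_percentile))
        sel = search & (chi_vol <= thr)
    return sel


def prune_isolated(binary: np.ndarray, min_voxels: int = 2) -> np.ndarray:
    """Remove 26-connected components smaller than `min_voxels`."""
    binary = np.asarray(binary, dtype=bool)
    if min_voxels <= 1 or not binary.any():
        return binary.copy()
    labels, n = ndimage.label(binary, structure=_CONN26)
    if n == 0:
        return binary.copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    return keep[labels]


def slice_connected_regions(
    binary: np.ndarray, params: DetectionParams | None = None
) -> np.ndarray:
    """26-connected labeling keeping regions spanning enough slices.

    Returns a labeled volume (consecutive labels from 1) containing only
    regions whose extent along the slice axis is >= min_slice_span.
    """
    params = params or DetectionParams()
    binary = np.asarray(binary, dtype=bool)
    labels, n = ndimage.label(binary, structure=_CONN26)
    if n == 0:
        return labels
    ax = params.slice_axis
    out = np.zeros_like(labels)
    next_label = 1
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        span = sl[ax].stop - sl[ax].start
        if span >= params.min_slice_span:
            out[labels == lab] = next_label
            next_label += 1
    return out


def summarize_and_classify(
    regions: np.ndarray,
    chi: SusceptibilityMap | np.ndarray,
    params: DetectionParams | None = None,
    grid: GridMeta | None = None,
) -> list[MarkerCandidate]:
    """Centroid, statistics and chi-band classification per region.

    The centroid is the |chi|-weighted mean of voxel centers in world mm
    (geometric mean available via ``centroid_weighting="geometric"``).
    Candidates are sorted by score = |chi_mean - gold nominal|; at most
    `max_markers` gold candidates are flagged as detections, extra gold
    regions are flagged ``surplus``.
    """
    params = params or DetectionParams()
    if isinstance(chi, SusceptibilityMap):
        chi_vol, grid = chi.chi, chi.grid
    else:
        chi_vol = np.asarray(chi)
        if grid is None:
            raise ValueError("grid is required when chi is a bare array")
    ax = params.slice_axis
    n_regions = int(regions.max())
    candidates: list[MarkerCandidate] = []
    for lab in range(1, n_regions + 1):
        idx = np.argwhere(regions == lab)
        vals = chi_vol[tuple(idx.T)]
        if params.centroid_weighting == "chi":
            w = np.abs(vals)
            w = w if w.sum() > 0 else np.ones_like(w)
        else:
            w = np.ones(len(idx))
        cvox = (idx * w[:, None]).sum(axis=0) / w.sum()
        cmm = grid.voxel_to_world(cvox)
        chi_mean = float(vals.mean())
        label = "unknown"
        for name, (lo, hi) in params.class_bands.items():
            if lo <= chi_mean <= hi:
                label = name
                break
        candidates.append(MarkerCandidate(
            centroid_mm=tuple(float(c) for c in cmm),
            centroid_voxel=tuple(float(c) for c in cvox),
            n_voxels=int(len(idx)),
            slice_span=int(idx[:, ax].max() - idx[:, ax].min() + 1),
            chi_mean=chi_mean,
            chi_min=float(vals.min()),
            label=label,
            score=float(abs(chi_mean - GOLD_NOMINAL_PPM)),
            region_label=lab,
        ))
    candidates.sort(key=lambda c: c.score)
    n_gold = 0
    for c in candidates:
        if c.label == "gold":
            n_gold += 1
            if n_gold <= params.max_markers:
                c.is_detection = True
            else:
                c.surplus = True
    return candidates


# --------------------------------------------------------------------------
# composed pipeline
# --------------------------------------------------------------------------

def extract_candidates(
    chi: SusceptibilityMap | np.ndarray,
    prostate_mask: np.ndarray,
    params: DetectionParams | None = None,
    grid: GridMeta | None = None,
    return_regions: bool = False,
):
    """Run the four extraction steps on an existing chi map."""
    params = params or DetectionParams()
    if isinstance(chi, SusceptibilityMap) and grid is None:
        grid = chi.grid
    if grid is None:
        raise ValueError("grid is required when chi is a bare array")
    search = make_search_mask(prostate_mask, params.search_margin_mm, grid)
    sel = threshold_candidates(chi, search, params)
    sel = prune_isolated(sel, params.min_voxels)
    regions = slice_connected_regions(sel, params)
    candidates = summarize_and_classify(regions, chi, params, grid)
    if return_regions:
        return candidates, regions
    return candidates


def detect_markers(
    data,
    body_mask: np.ndarray | None = None,
    prostate_mask: np.ndarray | None = None,
    params: DetectionParams | None = None,
    inversion: str = "tkd",
    return_intermediates: bool = False,
):
    """Full detection chain from raw echoes or from a chi map.

    When `data` is a :class:`MultiEchoGRE`, runs field estimation,
    PDF background removal and dipole inversion (`inversion` in
    {"tkd", "medi0"}) before candidate extraction; when it is already a
    chi map, only the extraction steps run. Deterministic given inputs.
    """
    params = params or DetectionParams()
    if isinstance(data, MultiEchoGRE):
        if body_mask is None or prostate_mask is None:
            raise ValueError("body and prostate masks are required for raw echoes")
        from .fieldmap import estimate_fieldmap
        from .background import pdf_remove
        from .inversion import (
            complete_field, default_reference_mask, invert_medi0, invert_tkd,
        )

        fm = estimate_fieldmap(data, mask=body_mask)
        local, bg = pdf_remove(
            fm.field_ppm, body_mask, fm.reliability, data.grid,
            pad_factor=1.5,
        )
        # fill the unmeasurable signal-void field values (marker/air
        # interiors) by source-support consistency before inverting
        local_c, void = complete_field(local, fm.reliability, body_mask, data.grid)
        chi_tkd = invert_tkd(local_c, body_mask, data.grid)
        if inversion == "tkd":
            chi_map = chi_tkd
        elif inversion == "medi0":
            ref = default_reference_mask(body_mask, prostate_mask, chi_tkd.chi)
            mag = data.magnitude[0]
            # completed voids carry physics-consistent values: give them
            # moderate confidence in the data weighting
            w = np.maximum(fm.reliability, np.where(void, 0.5, 0.0))
            chi_map = invert_medi0(
                local_c, mag, body_mask, ref, data.grid,
                weights=w, init=chi_tkd.chi * body_mask,
            )
        else:
            raise ValueError(f"unknown inversion {inversion!r}")
        intermediates = {
            "fieldmap": fm, "local_field": local_c, "background_field": bg,
            "chi": chi_map,
        }
    elif isinstance(data, (SusceptibilityMap, np.ndarray)):
        if prostate_mask is None:
            raise ValueError("prostate mask is required")
        chi_map = data
        intermediates = {"chi": chi_map}
    else:
        raise TypeError(f"cannot detect markers from {type(data).__name__}")

    if not np.asarray(prostate_mask, dtype=bool).any():
        candidates: list[MarkerCandidate] = []
        intermediates["regions"] = None
    else:
        candidates, regions = extract_candidates(
            chi_map, prostate_mask, params, return_regions=True
        )
        intermediates["regions"] = regions
    if return_intermediates:
        return candidates, intermediates
    return candidates


def gold_detections(candidates: list[MarkerCandidate]) -> list[MarkerCandidate]:
    """The candidates reported as gold markers (at most max_markers)."""
    return [c for c in candidates if c.is_detection]
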