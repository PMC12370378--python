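"""NIfTI/JSON/CSV readers and writers for the pipeline's exchange formats.

Layout written by ``qsmfid simulate`` and consumed by ``qsmfid detect``:

    mag_e{j}.nii.gz / phs_e{j}.nii.gz   per-echo magnitude and phase
    body.nii.gz / prostate.nii.gz       masks
    acq.json                            acquisition sidecar (TEs s, B0 T,
                                        b0 axis, voxel size / origin mm)
    truth.json                          ground-truth marker positions (mm)

Coordinate convention: 0-based voxel indices; world mm = NIfTI affine
applied to indices (diagonal affine, origin at voxel (0,0,0) center).
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import GridMeta, MultiEchoGRE, wrap_phase
from .detection import MarkerCandidate
from . import phantom as ph


# --------------------------------------------------------------------------
# sidecar
# --------------------------------------------------------------------------

@dataclass
class AcquisitionSidecar:
    tes_s: list[float]
    b0_T: float = 1.5
    b0_axis: int = 2
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gamma_bar_MHz_per_T: float = 42.577

    def to_grid(self, shape) -> GridMeta:
        return GridMeta(
            shape=tuple(int(n) for n in shape),
            voxel_size=tuple(float(v) for v in self.voxel_size_mm),
            origin=tuple(float(v) for v in self.origin_mm),
            b0_axis=int(self.b0_axis),
            b0=float(self.b0_T),
            gamma_bar=float(self.gamma_bar_MHz_per_T),
        )

    @staticmethod
    def from_grid(grid: GridMeta, tes) -> "AcquisitionSidecar":
        return AcquisitionSidecar(
            tes_s=[float(t) for t in tes],
            b0_T=grid.b0,
            b0_axis=grid.b0_axis,
            voxel_size_mm=tuple(grid.voxel_size),
            origin_mm=tuple(grid.origin),
            gamma_bar_MHz_per_T=grid.gamma_bar,
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @staticmethod
    def load(path) -> "AcquisitionSidecar":
        d = json.loads(Path(path).read_text())
        d["voxel_size_mm"] = tuple(d["voxel_size_mm"])
        d["origin_mm"] = tuple(d["origin_mm"])
        return AcquisitionSidecar(**d)


def _affine(grid: GridMeta) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.voxel_size)
    aff[:3, 3] = grid.origin
    return aff


def save_volume(vol: np.ndarray, grid: GridMeta, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol), _affine(grid)), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


# --------------------------------------------------------------------------
# multi-echo round trip
# --------------------------------------------------------------------------

def write_multiecho(outdir, gre: MultiEchoGRE, masks: dict | None = None,
                    truth=None) -> None:
    """Write per-echo magnitude/phase NIfTI volumes plus sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = gre.grid
    for j in range(gre.n_echoes):
        save_volume(np.abs(gre.data[j]), grid, outdir / f"mag_e{j + 1}.nii.gz")
        save_volume(
            wrap_phase(np.angle(gre.data[j])), grid, outdir / f"phs_e{j + 1}.nii.gz"
        )
    AcquisitionSidecar.from_grid(grid, gre.tes).save(outdir / "acq.json")
    for name, m in (masks or {}).items():
        save_volume(np.asarray(m, dtype=np.uint8), grid, outdir / f"{name}.nii.gz")
    if truth is not None:
        payload = {
            "marker_positions_mm": np.asarray(truth.marker_positions).tolist(),
            "confounders": [
                {"label": lab, "position_mm": list(pos)}
                for lab, pos in truth.confounder_positions
            ],
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=2))


def _echo_index(path: Path) -> int:
    m = re.search(r"_e(\d+)\.nii(\.gz)?$", path.name)
    if not m:
        raise ValueError(f"cannot parse echo index from {path.name}")
    return int(m.group(1))


def read_multiecho(source, sidecar: AcquisitionSidecar | None = None) -> MultiEchoGRE:
    """Assemble complex multi-echo data from NIfTI magnitude/phase pairs.

    `source` is a directory containing ``mag_e*.nii[.gz]``/``phs_e*``
    files and (unless `sidecar` is given) an ``acq.json``. Phase volumes
    stored in a (0, 2*pi] convention are normalized to (-pi, pi]; header
    scl slope/intercept scaling is applied by the NIfTI reader.
    """
    src = Path(source)
    mags = sorted(src.glob("mag_e*.nii*"), key=_echo_index)
    phss = sorted(src.glob("phs_e*.nii*"), key=_echo_index)
    if not mags:
        raise FileNotFoundError(f"no mag_e*.nii[.gz] volumes in {src}")
    if len(mags) != len(phss):
        raise ValueError(
            f"{len(mags)} magnitude but {len(phss)} phase volumes in {src}"
        )
    if sidecar is None:
        sidecar = AcquisitionSidecar.load(src / "acq.json")
    if len(sidecar.tes_s) != len(mags):
        raise ValueError(
            f"sidecar lists {len(sidecar.tes_s)} echoes, found {len(mags)} volumes"
        )

    vols = []
    ref_shape = None
    for mp, pp in zip(mags, phss):
        mag, aff_m = load_volume(mp)
        phs, aff_p = load_volume(pp)
        for path, arr, aff in ((mp, mag, aff_m), (pp, phs, aff_p)):
            if ref_shape is None:
                ref_shape, ref_aff = arr.shape, aff
            elif arr.shape != ref_shape or not np.allclose(aff, ref_aff, atol=1e-4):
                raise ValueError(f"grid mismatch in {path.name}")
        if phs.max() > np.pi + 1e-3:
            phs = wrap_phase(phs)
        vols.append(mag * np.exp(1j * phs))

    grid = sidecar.to_grid(ref_shape)
    hdr_vox = np.sqrt((ref_aff[:3, :3] ** 2).sum(axis=0))
    if not np.allclose(hdr_vox, grid.voxel_size, atol=1e-3):
        raise ValueError(
            f"sidecar voxel size {grid.voxel_size} does not match NIfTI "
            f"header {tuple(hdr_vox)}"
        )
    return MultiEchoGRE(
        data=np.stack(vols), tes=np.asarray(sidecar.tes_s), grid=grid
    )


def read_mask(path) -> np.ndarray:
    vol, _ = load_volume(path)
    return vol > 0.5


def read_truth(path) -> np.ndarray:
    d = json.loads(Path(path).read_text())
    return np.asarray(d["marker_positions_mm"], dtype=float).reshape(-1, 3)


# --------------------------------------------------------------------------
# marker reports
# --------------------------------------------------------------------------

_CSV_FIELDS = [
    "index", "label", "x_mm", "y_mm", "z_mm", "i_vox", "j_vox", "k_vox",
    "n_voxels", "slice_span", "chi_mean_ppm", "chi_min_ppm", "score",
    "is_detection", "surplus",
]


def write_markers(
    candidates: list[MarkerCandidate],
    grid: GridMeta,
    outdir,
    regions: np.ndarray | None = None,
    provenance: dict | None = None,
) -> None:
    """CSV + JSON candidate report and an optional labeled NIfTI mask.

    The mask labels voxels of candidate k (1-based row order) with k.
    Floating-point columns use fixed 6-decimal formatting so identical
    inputs produce byte-identical CSV files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, c in enumerate(candidates, start=1):
        rows.append({
            "index": k,
            "label": c.label,
            "x_mm": f"{c.centroid_mm[0]:.6f}",
            "y_mm": f"{c.centroid_mm[1]:.6f}",
            "z_mm": f"{c.centroid_mm[2]:.6f}",
            "i_vox": f"{c.centroid_voxel[0]:.6f}",
            "j_vox": f"{c.centroid_voxel[1]:.6f}",
            "k_vox": f"{c.centroid_voxel[2]:.6f}",
            "n_voxels": c.n_voxels,
            "slice_span": c.slice_span,
            "chi_mean_ppm": f"{c.chi_mean:.6f}",
            "chi_min_ppm": f"{c.chi_min:.6f}",
            "score": f"{c.score:.6f}",
            "is_detection": int(c.is_detection),
            "surplus": int(c.surplus),
        })
    with open(outdir / "markers.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
    report = {
        "candidates": rows,
        "detections_mm": [
            list(c.centroid_mm) for c in candidates if c.is_detection
        ],
        "provenance": provenance or {},
    }
    (outdir / "markers.json").write_text(json.dumps(report, indent=2))
    if regions is not None:
        labeled = np.zeros(regions.shape, dtype=np.int16)
        for k, c in enumerate(candidates, start=1):
            labeled[regions == c.region_label] = k
        save_volume(labeled, grid, outdir / "markers_mask.nii.gz")


def read_marker_positions(path) -> np.ndarray:
    """Detected gold positions (mm) from a markers.json report."""
    d = json.loads(Path(path).read_text())
    return np.asarray(d["detections_mm"], dtype=float).reshape(-1, 3)


# --------------------------------------------------------------------------
# phantom spec YAML
# --------------------------------------------------------------------------

def phantom_spec_to_yaml(spec: ph.PhantomSpec, path) -> None:
    def inc(i: ph.InclusionSpec) -> dict:
        return {
            "shape_kind": i.shape_kind, "center": list(i.center),
            "dimensions": list(i.dimensions), "chi": i.chi,
            "r2star": i.r2star, "m0": i.m0, "label": i.label,
        }

    payload = {
        "grid": {
            "shape": list(spec.grid.shape),
            "voxel_size": list(spec.grid.voxel_size),
            "origin": list(spec.grid.origin),
            "b0_axis": spec.grid.b0_axis,
            "b0": spec.grid.b0,
            "gamma_bar": spec.grid.gamma_bar,
        },
        "body": inc(spec.body),
        "prostate": inc(spec.prostate),
        "inclusions": [inc(i) for i in spec.inclusions],
        "background_chi": spec.background_chi,
        "background_r2star": spec.background_r2star,
        "background_m0": spec.background_m0,
        "oversample": spec.oversample,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def phantom_spec_from_yaml(path) -> ph.PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())

    def inc(v: dict) -> ph.InclusionSpec:
        return ph.InclusionSpec(
            shape_kind=v["shape_kind"], center=tuple(v["center"]),
            dimensions=tuple(v["dimensions"]), chi=float(v.get("chi", 0.0)),
            r2star=float(v.get("r2star", 0.0)), m0=float(v.get("m0", 1.0)),
            label=v.get("label", "other"),
        )

    g = d["grid"]
    grid = GridMeta(
        shape=tuple(g["shape"]), voxel_size=tuple(g["voxel_size"]),
        origin=tuple(g["origin"]), b0_axis=int(g.get("b0_axis", 2)),
        b0=float(g.get("b0", 1.5)), gamma_bar=float(g.get("gamma_bar", 42.577)),
    )
    return ph.PhantomSpec(
        grid=grid, body=inc(d["body"]), prostate=inc(d["prostate"]),
        inclusions=[inc(v) for v in d.get("inclusions", [])],
        background_chi=float(d.get("background_chi", 0.0)),
        background_r2star=float(d.get("background_r2star", 0.0)),
        background_m0=float(d.get("background_m0", 0.0)),
        oversample=int(d.get("oversample", 2)),
        noise_sigma=float(d.get("noise_sigma", 0.01)),
        seed=int(d.get("seed", 0)),
    )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
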