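"""NIfTI / CSV / JSON readers and writers.

NIfTI is the sole volumetric format.  On disk the data axes are
``(row, col, slice)`` with voxel spacing (mm) on the affine diagonal; in
memory the package uses ``(slice, row, col)`` arrays and ``(row, col,
slice)`` spacing tuples, and this module performs the transpose at the
boundary.  Voxel indices are 0-based everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import MultiEchoVolume, PlaqueTruth
from .volumetry import QuantReport

__all__ = [
    "read_multiecho",
    "write_multiecho",
    "write_truth_csv",
    "read_truth_csv",
    "write_report",
    "read_relaxivity_csv",
]

_SPACING_TOL = 1e-6  # mm


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_multiecho(mev: MultiEchoVolume, out_dir, stem: str = "echo") -> list[Path]:
    """Write one NIfTI per echo as ``<stem>_te<TE>ms.nii``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for te, vol in zip(mev.te_list, mev.volumes):
        data = np.transpose(vol, (1, 2, 0))  # (row, col, slice) on disk
        img = nib.Nifti1Image(data.astype(np.float64), _affine(mev.spacing))
        p = out_dir / f"{stem}_te{te:g}ms.nii"
        nib.save(img, p)
        paths.append(p)
    return paths


def read_multiecho(paths, te_list) -> MultiEchoVolume:
    """Load per-echo NIfTI files into a :class:`MultiEchoVolume`.

    ``te_list`` gives the echo time (ms) of each path, in the same order;
    volumes are returned sorted by ascending TE regardless of input order.
    Shapes and header spacings must agree across files (tolerance 1e-6 mm).
    """
    paths = [Path(p) for p in paths]
    te = [float(t) for t in te_list]
    if len(paths) != len(te):
        raise ValueError("need one echo time per file")
    if len(set(te)) != len(te):
        raise ValueError("duplicate echo times")
    vols, spacings, shapes = {}, [], []
    for p, t in zip(paths, te):
        if not p.exists():
            raise FileNotFoundError(f"missing echo file: {p}")
        img = nib.load(p)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        data = np.transpose(np.asarray(img.dataobj, dtype=float), (2, 0, 1))
        vols[t] = data
        spacings.append(zooms)
        shapes.append(data.shape)
    if len(set(shapes)) != 1:
        raise ValueError(f"echo volumes disagree in shape: {sorted(set(shapes))}")
    ref = spacings[0]
    for sp in spacings[1:]:
        if any(abs(a - b) > _SPACING_TOL for a, b in zip(ref, sp)):
            raise ValueError(f"echo volumes disagree in spacing: {ref} vs {sp}")
    order = sorted(te)
    return MultiEchoVolume(
        volumes=[vols[t] for t in order],
        spacing=ref,
        te_list=tuple(order),
    )


def write_truth_csv(truths: list[PlaqueTruth], path) -> Path:
    """Ground-truth plaque table: centers/radius in mm, true sphere volume in mm^3."""
    path = Path(path)
    pd.DataFrame(
        {
            "center_x": [t.center[0] for t in truths],
            "center_y": [t.center[1] for t in truths],
            "center_z": [t.center[2] for t in truths],
            "radius_mm": [t.radius for t in truths],
            "delta_r2star": [t.delta_r2star for t in truths],
            "true_volume_mm3": [t.true_volume for t in truths],
        }
    ).to_csv(path, index=False)
    return path


def read_truth_csv(path) -> list[PlaqueTruth]:
    df = pd.read_csv(path)
    return [
        PlaqueTruth(
            center=(row.center_x, row.center_y, row.center_z),
            radius=row.radius_mm,
            delta_r2star=row.delta_r2star,
        )
        for row in df.itertuples()
    ]


def write_report(
    report: QuantReport,
    out_dir,
    mask: np.ndarray | None = None,
    mask_spacing: tuple[float, float, float] | None = None,
) -> dict[str, Path]:
    """Write a report as JSON + CSV tables (+ optional segmentation NIfTI).

    The JSON is canonical (sorted keys, fixed layout), so rerunning an
    identical analysis reproduces identical bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    jp = out_dir / "report.json"
    jp.write_text(report.to_json())
    files["report"] = jp

    cp = out_dir / "components.csv"
    pd.DataFrame(
        {
            "label": [c.label for c in report.components],
            "voxel_count": [c.voxel_count for c in report.components],
            "volume_mm3": [c.volume_mm3 for c in report.components],
            "equivalent_diameter_um": [
                round(c.equivalent_diameter_um, 1) for c in report.components
            ],
            "centroid_row_mm": [c.centroid_mm[0] for c in report.components],
            "centroid_col_mm": [c.centroid_mm[1] for c in report.components],
            "centroid_slice_mm": [c.centroid_mm[2] for c in report.components],
            "slice_first": [c.slice_extent[0] for c in report.components],
            "slice_last": [c.slice_extent[1] for c in report.components],
        }
    ).to_csv(cp, index=False)
    files["components"] = cp

    sp = out_dir / "slices.csv"
    pd.DataFrame(
        {
            "slice_id": [s.slice_id for s in report.per_slice],
            "plaque_count": [s.plaque_count for s in report.per_slice],
            "area_fraction_pct": [s.area_fraction_pct for s in report.per_slice],
            "defined": [s.defined for s in report.per_slice],
        }
    ).to_csv(sp, index=False)
    files["slices"] = sp

    if mask is not None:
        spacing = mask_spacing or tuple(
            report.parameters.get("config", {}).get("out_spacing", (1.0, 1.0, 1.0))
        )
        img = nib.Nifti1Image(
            np.transpose(mask.astype(np.uint8), (1, 2, 0)), _affine(spacing)
        )
        mp = out_dir / "segmentation.nii"
        nib.save(img, mp)
        files["segmentation"] = mp
    return files


def read_relaxivity_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Dilution-series table -> (concentration mM, relaxation rate s^-1).

    Accepts either a ``rate_s`` column, a ``t2_ms`` column (converted as
    1000/T2), or a ``mean_intensity`` column with ``s0``/``te_ms`` columns.
    """
    from .relaxometry import rate_from_intensity, rate_from_t2

    df = pd.read_csv(path)
    if "concentration_mM" not in df.columns:
        raise ValueError("relaxivity CSV needs a 'concentration_mM' column")
    c = df["concentration_mM"].to_numpy(float)
    if "rate_s" in df.columns:
        r = df["rate_s"].to_numpy(float)
    elif "t2_ms" in df.columns:
        r = rate_from_t2(df["t2_ms"].to_numpy(float))
    elif {"mean_intensity", "s0", "te_ms"} <= set(df.columns):
        r = np.array(
            [
                rate_from_intensity(row.mean_intensity, row.s0, row.te_ms)
                for row in df.itertuples()
            ]
        )
    else:
        raise ValueError("need 'rate_s', 't2_ms', or 'mean_intensity'+'s0'+'te_ms' columns")
    return c, r


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, sort_keys=True, indent=2))
    return path
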