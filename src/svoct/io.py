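"""Volume and table I/O: multi-page TIFF / NIfTI with YAML spacing
sidecars, histogram and metric CSVs.

Voxel spacing is never assumed: TIFF volumes carry a ``<name>.yaml``
sidecar recording spacing (μm) and axis order; NIfTI volumes encode
spacing in the affine.  Loading a TIFF without a sidecar or explicit
spacing raises.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .metrics import DNVHistogram, MetricRecord
from .volume import BinaryVascularMask, VOIMask, Volume

__all__ = [
    "save_volume",
    "load_volume",
    "load_mask",
    "load_voi",
    "save_histogram_csv",
    "load_histogram_csv",
    "metrics_to_frame",
    "save_axes_csv",
]

_AXES = "ZXY"  # array axis order used throughout the package


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def save_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF (+ YAML sidecar) or NIfTI,
    chosen by extension.  Boolean data is stored as uint8 0/1."""
    path = Path(path)
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if path.suffix in {".tif", ".tiff"}:
        tifffile.imwrite(path, np.ascontiguousarray(data), photometric="minisblack")
        sidecar = {
            "spacing_um": [float(s) for s in vol.spacing],
            "axes": _AXES,
            "dtype": str(vol.data.dtype),
        }
        with open(_sidecar_path(path), "w") as fh:
            yaml.safe_dump(sidecar, fh)
    elif path.suffix in {".nii", ".gz"} or str(path).endswith(".nii.gz"):
        affine = np.diag([*vol.spacing, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    return path


def _load_array(path: Path, spacing: Sequence[float] | None):
    if path.suffix in {".tif", ".tiff"}:
        data = tifffile.imread(path)
        sidecar = _sidecar_path(path)
        if spacing is None:
            if not sidecar.exists():
                raise ValueError(
                    f"no spacing given and no sidecar {sidecar.name}: "
                    "refusing to assume isotropy"
                )
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh)
            spacing = meta["spacing_um"]
            if str(meta.get("dtype", "")) == "bool":
                data = data.astype(bool)
    elif path.suffix == ".nii" or str(path).endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if spacing is None:
            spacing = [float(z) for z in img.header.get_zooms()[:3]]
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    return data, tuple(float(s) for s in spacing)


def load_volume(
    path: str | Path, spacing: Sequence[float] | None = None, layout: str = "3d"
) -> Volume:
    """Load a 3D scalar volume.  ``layout`` declares the expected file
    dimensionality ("3d" only here; 4D frame stacks are loaded with
    :func:`load_frame_stack`)."""
    if layout != "3d":
        raise ValueError(f"load_volume handles layout '3d', got {layout!r}")
    data, sp = _load_array(Path(path), spacing)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: declared layout '3d' but file has {data.ndim} dimensions"
        )
    return Volume(data=data, spacing=sp)  # type: ignore[arg-type]


def load_frame_stack(path: str | Path, spacing: Sequence[float] | None = None):
    """Load a 4D repeated-B-scan stack ``(z, x, y, frames)``."""
    from .synthetic import BScanStack

    data, sp = _load_array(Path(path), spacing)
    if data.ndim != 4:
        raise ValueError(
            f"{path}: declared layout '4d' but file has {data.ndim} dimensions"
        )
    return BScanStack(intensities=np.asarray(data, dtype=float), spacing=sp)


def save_frame_stack(stack, path: str | Path) -> Path:
    """Write a 4D frame stack as TIFF + sidecar."""
    path = Path(path)
    if path.suffix not in {".tif", ".tiff"}:
        raise ValueError("frame stacks are written as TIFF")
    tifffile.imwrite(path, np.ascontiguousarray(stack.intensities), photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(
            {
                "spacing_um": [float(s) for s in stack.spacing],
                "axes": _AXES + "T",
                "dtype": str(np.asarray(stack.intensities).dtype),
            },
            fh,
        )
    return path


def load_mask(path: str | Path, spacing: Sequence[float] | None = None) -> BinaryVascularMask:
    vol = load_volume(path, spacing)
    return BinaryVascularMask(data=vol.data.astype(bool), spacing=vol.spacing)


def load_voi(path: str | Path, spacing: Sequence[float] | None = None) -> VOIMask:
    vol = load_volume(path, spacing)
    return VOIMask(data=vol.data.astype(bool), spacing=vol.spacing,
                   meta={"provenance": "supplied"})


def save_histogram_csv(hist: DNVHistogram, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "bin_lo_um": hist.bin_edges[:-1],
            "bin_hi_um": hist.bin_edges[1:],
            "count": hist.counts,
            "density": hist.density,
        }
    ).to_csv(path, index=False)
    return path


def load_histogram_csv(path: str | Path) -> DNVHistogram:
    df = pd.read_csv(path)
    edges = np.append(df["bin_lo_um"].to_numpy(), df["bin_hi_um"].to_numpy()[-1])
    return DNVHistogram(bin_edges=edges, counts=df["count"].to_numpy())


def metrics_to_frame(record: MetricRecord) -> pd.DataFrame:
    """Flatten a MetricRecord into a one-row DataFrame for CSV export."""
    row: dict[str, float | int | None] = {
        f"DLF_{lam:g}": v for lam, v in record.dlf.items()
    }
    if record.convexity is not None:
        row["lambda"] = record.convexity.exponent
        row["lambda_stderr"] = record.convexity.stderr
        row["lambda_r_squared"] = record.convexity.r_squared
    else:
        row["lambda"] = np.nan
    row["VVD"] = record.vvd
    row["tissue_voxel_count"] = record.tissue_voxel_count
    row["vessel_voxel_count"] = record.vessel_voxel_count
    return pd.DataFrame([row])


def save_axes_csv(points: np.ndarray, path: str | Path) -> Path:
    """Ground-truth cylinder axis positions (cross-section μm) as CSV."""
    path = Path(path)
    pd.DataFrame(np.atleast_2d(points), columns=["u_um", "v_um"]).to_csv(
        path, index=False
    )
    return path
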