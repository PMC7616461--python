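"""NIfTI and JSON input/output for sessions and parameter maps.

Volumes are NIfTI-1 with RAS+ affines; masks are written as uint8 and
parameter maps as 32-bit float with NaN marking masked-out or invalid
voxels.  A JSON summary accompanies every map directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .pipeline import AcquisitionSpec, DualExcitationSeries, ParameterMaps

__all__ = [
    "load_session",
    "save_session",
    "save_maps",
    "load_maps",
    "save_ground_truth",
]


def _load_img(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input: {path}")
    try:
        img = nib.load(str(path))
        img.get_fdata()  # force a read so truncation surfaces here
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"could not read NIfTI file {path}: {exc}") from exc
    return img


def load_session(
    echo1_path: str | Path,
    echo2_path: str | Path,
    pd_path: str | Path,
    spec: AcquisitionSpec | None = None,
) -> tuple[DualExcitationSeries, np.ndarray, np.ndarray]:
    """Load a dual-echo session and its PD calibration volume.

    Validates that all grids and affines agree, that the series are
    4-D with an even volume count, and returns
    ``(series, pd_volume, affine)``.
    """
    e1, e2, pd = (_load_img(p) for p in (echo1_path, echo2_path, pd_path))
    affine = e1.affine
    for name, img in (("echo2", e2), ("pd", pd)):
        if not np.allclose(img.affine, affine, atol=1e-5):
            raise ValueError(f"{name} affine does not match echo1")
    d1, d2 = e1.get_fdata(), e2.get_fdata()
    if d1.ndim != 4 or d2.ndim != 4:
        raise ValueError("echo series must be 4-D")
    if d1.shape != d2.shape:
        raise ValueError("echo1/echo2 shapes differ")
    if d1.shape[-1] % 2:
        raise ValueError("odd volume count: incomplete tag/control pairs")
    pd_data = pd.get_fdata()
    if pd_data.ndim == 4:
        pd_data = pd_data[..., 0]
    if pd_data.shape != d1.shape[:3]:
        raise ValueError("PD volume grid does not match the echo series")
    series = DualExcitationSeries(echo1=d1, echo2=d2,
                                  spec=spec or AcquisitionSpec())
    return series, pd_data, affine


def save_session(
    out_dir: str | Path,
    series: DualExcitationSeries,
    pd_volume: np.ndarray,
    affine: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write echo1/echo2/pd NIfTI files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4) if affine is None else affine
    paths = {}
    for name, data in (("echo1", series.echo1), ("echo2", series.echo2),
                       ("pd", pd_volume)):
        p = out / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(data, np.float32), aff), str(p))
        paths[name] = p
    return paths


def save_maps(
    maps: ParameterMaps,
    out_dir: str | Path,
    affine: np.ndarray | None = None,
    extra_meta: dict | None = None,
) -> dict[str, Path]:
    """Write one NIfTI per parameter map plus ``summary.json``.

    The summary holds the grey-matter means/SDs, voxel rejection
    counts and the software version; write-then-read round-trips the
    in-memory values (float32 precision for maps).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4) if affine is None else affine
    paths: dict[str, Path] = {}
    for name in ParameterMaps._MAP_NAMES:
        p = out / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(
            np.asarray(getattr(maps, name), np.float32), aff), str(p))
        paths[name] = p
    for name in ("gm_mask", "brain_mask"):
        p = out / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(
            np.asarray(getattr(maps, name), np.uint8), aff), str(p))
        paths[name] = p
    summary = dict(maps.summary)
    summary["software_version"] = __version__
    summary["regressor"] = [float(v) for v in maps.regressor.values]
    if extra_meta:
        summary.update(extra_meta)
    sp = out / "summary.json"
    sp.write_text(json.dumps(summary, indent=2))
    paths["summary"] = sp
    return paths


def load_maps(map_dir: str | Path) -> dict[str, np.ndarray]:
    """Read back a map directory into plain arrays (+ ``summary`` dict)."""
    map_dir = Path(map_dir)
    out: dict[str, np.ndarray] = {}
    for name in ParameterMaps._MAP_NAMES + ("gm_mask", "brain_mask"):
        p = map_dir / f"{name}.nii.gz"
        if p.exists():
            out[name] = _load_img(p).get_fdata()
    sp = map_dir / "summary.json"
    if sp.exists():
        out["summary"] = json.loads(sp.read_text())
    if not out:
        raise FileNotFoundError(f"no parameter maps found in {map_dir}")
    return out


def save_ground_truth(gt, out_dir: str | Path) -> Path:
    """JSON sidecar with the simulator's scalar truth and the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gm = gt.gm_truth
    record = {
        "Hb": gt.Hb,
        "PaO2_0": gt.PaO2_0,
        "PaO2_bh": gt.PaO2_bh,
        "m0": gt.m0,
        "noise_sigma_echo1": gt.noise_sigma_echo1,
        "noise_sigma_echo2": gt.noise_sigma_echo2,
        "seed": gt.seed,
        "gm_mean_oef0": float(np.nanmean(gt.oef0[gm])),
        "gm_mean_cbf0": float(gt.cbf0[gm].mean()),
        "gm_mean_frac_cbf": float(gt.frac_cbf[gm].mean()),
        "n_gm_voxels": int(gm.sum()),
    }
    p = out / "ground_truth.json"
    p.write_text(json.dumps(record, indent=2))
    return p
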