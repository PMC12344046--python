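"""Reading scan slices (DICOM or 16-bit raster) and writing pipeline outputs."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import tifffile

from .gradation import (DEFAULT_WINDOW, DISPLAY_MAX, GradationError,
                        RawScanSlice, first_scalar)
from .simplenet import NetworkConfig, NetworkParams
from .train import TrainingTrace


def read_dicom_slice(path: str | Path, modality_label: str = "") -> RawScanSlice:
    """One DICOM file -> RawScanSlice (rescale/window/geometry tags included).

    Multi-valued window tags take their first entry.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    pixels = ds.pixel_array
    if pixels.ndim != 2:
        raise GradationError(f"{path}: expected a single-frame 2-D image")
    position = 0.0
    if getattr(ds, "ImagePositionPatient", None) is not None:
        position = float(ds.ImagePositionPatient[2])
    elif getattr(ds, "SliceLocation", None) is not None:
        position = float(ds.SliceLocation)
    spacing = (1.0, 1.0)
    if getattr(ds, "PixelSpacing", None) is not None:
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return RawScanSlice(
        pixels=pixels.astype(np.int64),
        rescale_slope=float(getattr(ds, "RescaleSlope", 1.0)),
        rescale_intercept=float(getattr(ds, "RescaleIntercept", 0.0)),
        window_center=first_scalar(getattr(ds, "WindowCenter", DEFAULT_WINDOW.center)),
        window_width=first_scalar(getattr(ds, "WindowWidth", DEFAULT_WINDOW.width)),
        slice_position=position,
        pixel_spacing=spacing,
        modality_label=modality_label or str(getattr(ds, "Modality", "")),
    )


def write_display_image(path: str | Path, img: np.ndarray) -> None:
    """Write a display image as 16-bit TIFF (or PNG by extension)."""
    img = np.asarray(img)
    if img.min() < 0 or img.max() > DISPLAY_MAX:
        raise GradationError("display image out of range")
    arr = img.astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr)
    else:
        from PIL import Image

        Image.fromarray(arr).save(str(path))


def read_display_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        from PIL import Image

        arr = np.asarray(Image.open(str(path)))
    return arr.astype(np.int32)


def write_field(path: str | Path, field: np.ndarray) -> None:
    """Deformation field as a 2-channel float32 TIFF (row, col displacements)."""
    tifffile.imwrite(str(path), np.asarray(field, dtype=np.float32))


def read_field(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float64)


def save_checkpoint(path: str | Path, params: NetworkParams,
                    extra: dict | None = None) -> None:
    """Trained per-pair parameters, with config and seed embedded."""
    arrays = {f"w{i}": w for i, w in enumerate(params.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(params.biases)})
    meta = {"n_layers": params.config.n_layers, "channels": params.config.channels,
            "seed": -1 if params.seed is None else params.seed}
    meta.update(extra or {})
    np.savez_compressed(str(path), __meta__=np.array([repr(meta)]), **arrays)


def load_checkpoint(path: str | Path) -> NetworkParams:
    import ast

    with np.load(str(path)) as z:
        meta = ast.literal_eval(str(z["__meta__"][0]))
        cfg = NetworkConfig(n_layers=int(meta["n_layers"]),
                            channels=int(meta["channels"]))
        weights = [z[f"w{i}"] for i in range(cfg.n_layers)]
        biases = [z[f"b{i}"] for i in range(cfg.n_layers)]
    seed = meta.get("seed", -1)
    return NetworkParams(weights, biases, cfg, None if seed == -1 else seed)


def write_trace(path: str | Path, trace: TrainingTrace) -> None:
    """Training trace as CSV: step, loss, lr."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["step", "loss", "lr"])
        for i, (loss, lr) in enumerate(zip(trace.losses, trace.lrs), start=1):
            w.writerow([i, f"{loss:.10g}", f"{lr:.10g}"])


def read_pairing_csv(path: str | Path) -> list[tuple[int, int]]:
    """Explicit pairing table: rows of (patient_id, cbct_index, planct_index)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append((int(row["cbct_index"]), int(row["planct_index"])))
    return out
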