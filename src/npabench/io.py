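"""File interchange: TIFF image export/import, cohort tables, mask files.

Images are stored one TIFF per scan per channel,
``{participant}_{eye}_{visit}_{slab}_{angio|struct}.tif`` (16-bit, linear
scale over [0, 1]); masks as single-bit TIFF; probability maps as 32-bit
float TIFF.  The cohort table travels as CSV alongside the images.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import EnFaceScan, GroundTruth, Slab

__all__ = [
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_probability_map",
    "export_cohort",
    "load_cohort",
]


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Save a [0, 1] float image as linearly scaled 16-bit TIFF."""
    scaled = np.clip(np.asarray(image, float), 0.0, 1.0)
    tifffile.imwrite(str(path), (scaled * 65535.0 + 0.5).astype(np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    raw = tifffile.imread(str(path))
    if raw.dtype == np.uint8:
        return raw.astype(np.float32) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(np.float32) / 65535.0
    return np.asarray(raw, np.float32)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(mask, bool))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), bool)


def write_probability_map(path: str | Path, probs: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(probs, np.float32))


def _stem(scan: EnFaceScan) -> str:
    eye = scan.eye_id
    if eye.startswith(scan.participant_id + "_"):
        eye = eye[len(scan.participant_id) + 1 :]
    return f"{scan.participant_id}_{eye}_{scan.visit_index}_{scan.slab.value}"


def export_cohort(
    records: list[tuple[EnFaceScan, GroundTruth]],
    table: pd.DataFrame,
    out_dir: str | Path,
    write_truth: bool = True,
) -> pd.DataFrame:
    """Write a generated cohort to disk; returns the table with file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = table.copy()
    angio_paths, struct_paths, npa_paths = [], [], []
    for idx in table["scan_index"]:
        scan, truth = records[idx]
        stem = _stem(scan)
        a = out / f"{stem}_angio.tif"
        s = out / f"{stem}_struct.tif"
        write_image(a, scan.angio)
        write_image(s, scan.structure)
        angio_paths.append(a.name)
        struct_paths.append(s.name)
        if write_truth:
            n = out / f"{stem}_npa.tif"
            write_mask(n, truth.npa_mask)
            write_mask(out / f"{stem}_vessels.tif", truth.vessel_mask)
            write_mask(out / f"{stem}_shadow.tif", truth.shadow_mask)
            npa_paths.append(n.name)
        else:
            npa_paths.append("")
    table["angio_path"] = angio_paths
    table["struct_path"] = struct_paths
    table["npa_path"] = npa_paths
    table.to_csv(out / "cohort.csv", index=False)
    return table


def load_cohort(
    in_dir: str | Path,
) -> tuple[list[tuple[EnFaceScan, GroundTruth | None]], pd.DataFrame]:
    """Read a cohort written by :func:`export_cohort` (or user-supplied images
    with a matching ``cohort.csv``)."""
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "cohort.csv")
    records: list[tuple[EnFaceScan, GroundTruth | None]] = []
    for _, row in table.iterrows():
        scan = EnFaceScan(
            angio=read_image(in_dir / row["angio_path"]),
            structure=read_image(in_dir / row["struct_path"]),
            slab=Slab(row["slab"]),
            ssi=float(row["ssi"]),
            etdrs=int(row["etdrs"]),
            participant_id=str(row["participant_id"]),
            eye_id=str(row["eye_id"]),
            visit_index=int(row["visit_index"]),
        )
        truth = None
        npa_path = row.get("npa_path", "")
        if isinstance(npa_path, str) and npa_path:
            stem = npa_path[: -len("_npa.tif")]
            truth = GroundTruth(
                npa_mask=read_mask(in_dir / npa_path),
                vessel_mask=read_mask(in_dir / f"{stem}_vessels.tif"),
                shadow_mask=read_mask(in_dir / f"{stem}_shadow.tif"),
                fovea_center_px=(scan.shape[0] / 2.0, scan.shape[1] / 2.0),
                fovea_radius_px=float(row.get("fovea_radius_px", 0.0)),
            )
        records.append((scan, truth))
    table["scan_index"] = np.arange(len(records))
    return records, table
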