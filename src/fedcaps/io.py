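"""File I/O: 16-bit PNG images, tab-separated manifests, model checkpoints.

Checkpoints are a single ``.npz`` archive holding the flat float64 weight
vector, the shape registry and the configuration — the same canonical
ordering the ledger digests, so a checkpoint can be audited against a
recorded round.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .synthetic_data import LabeledScan

__all__ = [
    "write_png16",
    "read_png16",
    "write_manifest",
    "read_manifest",
    "export_dataset",
    "save_checkpoint",
    "load_checkpoint_arrays",
    "export_nifti",
]

MANIFEST_COLUMNS = ["path", "label", "tumor_type", "client_id", "modality", "seed"]


def write_png16(image: np.ndarray, path: str | Path) -> None:
    """Save a [0, 1] float image as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 65535.0).round().astype(np.uint16)).save(str(path))


def read_png16(path: str | Path) -> np.ndarray:
    """Load a PNG as floats in [0, 1] (8- or 16-bit input)."""
    img = Image.open(str(path))
    arr = np.asarray(img, dtype=float)
    peak = 65535.0 if img.mode.startswith("I") or arr.max() > 255 else 255.0
    return arr / peak


def write_manifest(records: Sequence[dict], path: str | Path) -> None:
    lines = ["\t".join(MANIFEST_COLUMNS)]
    for rec in records:
        lines.append("\t".join(str(rec.get(c, "")) for c in MANIFEST_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> list[dict]:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:] if line.strip()]


def export_dataset(
    scans: Sequence[LabeledScan], out_dir: str | Path
) -> Path:
    """Write PNGs plus a tab-separated manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for i, scan in enumerate(scans):
        name = scan.scan_id or f"scan-{i:05d}"
        rel = f"{name}.png"
        write_png16(scan.image, out / rel)
        records.append(
            {
                "path": rel,
                "label": scan.label,
                "tumor_type": scan.tumor_type or "",
                "client_id": scan.client_id or "",
                "modality": scan.modality,
                "seed": scan.seed,
            }
        )
    manifest = out / "manifest.tsv"
    write_manifest(records, manifest)
    return manifest


def export_nifti(volume: np.ndarray, path: str | Path) -> None:
    """Optional NIfTI export for stacks of slices (H x W x n)."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), np.eye(4)), str(path))


def save_checkpoint(model, path: str | Path) -> None:
    """Single-file archive: flat weights + shape registry + config."""
    registry = model.shape_registry()
    config = getattr(model, "config", None)
    config_json = json.dumps(
        {k: v for k, v in (config.__dict__ if config else {}).items()},
        sort_keys=True, default=str,
    )
    np.savez(
        str(path),
        weights=model.get_flat(),
        registry=json.dumps([[n, list(s)] for n, s in registry]),
        config=config_json,
    )


def load_checkpoint_arrays(path: str | Path):
    """Return (flat weights, registry, config dict) from a checkpoint."""
    with np.load(str(path), allow_pickle=False) as data:
        weights = data["weights"]
        registry = [(n, tuple(s)) for n, s in json.loads(str(data["registry"]))]
        config = json.loads(str(data["config"]))
    return weights, registry, config
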