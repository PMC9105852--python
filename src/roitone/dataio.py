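"""Dataset and results I/O: PNG/PGM images, manifests, result tables.

Datasets live on disk as a directory with ``normal/`` and ``cirrhosis/``
subdirectories of single-channel images plus a ``manifest.csv`` with columns
``id,label,file`` and a ``dataset.json`` recording ``fmax``, image size and
the generating configuration.  8-bit data uses 8-bit PNG or binary PGM;
higher bit depths (e.g. 12-bit, fmax 4095) are stored in 16-bit PNG
containers with the true fmax recorded in the manifest metadata.

Evaluation results are written as a CSV table (fixed column order: method,
mean_error, ci_halfwidth, n_trials, split_hash) paired with a JSON document
holding the per-trial detail and full provenance (config, seeds, library
versions).
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .evaluate import EvalSummary, TrialResult
from .synthdata import LABEL_NAMES, LabeledDataset, SyntheticConfig

__all__ = [
    "read_image",
    "write_image",
    "save_dataset",
    "load_dataset",
    "write_results",
    "read_results",
]

RESULT_COLUMNS = ["method", "mean_error", "ci_halfwidth", "n_trials", "split_hash"]


def write_image(path: str | Path, pixels: np.ndarray, fmax: int = 255) -> None:
    """Write a single-channel integer image; container chosen by fmax."""
    path = Path(path)
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError(f"{path}: image must be 2-D, got shape {pixels.shape}")
    if fmax <= 255:
        img = Image.fromarray(pixels.astype(np.uint8), mode="L")
    else:
        img = Image.fromarray(pixels.astype(np.uint16))
        if path.suffix.lower() != ".png":
            raise ValueError(f"{path}: >8-bit data requires a 16-bit PNG container")
    img.save(path)


def read_image(path: str | Path, fmax: int = 255) -> np.ndarray:
    """Read a single-channel image and validate it against ``fmax``."""
    path = Path(path)
    with Image.open(path) as img:
        if img.mode not in ("L", "I", "I;16", "P"):
            raise ValueError(f"{path}: expected a single-channel image, got mode {img.mode!r}")
        arr = np.asarray(img.convert("I") if img.mode == "P" else img)
    arr = arr.astype(np.int64)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected one channel, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > fmax:
        raise ValueError(f"{path}: pixel values outside [0, {fmax}]")
    return arr


def save_dataset(
    dataset: LabeledDataset,
    root: str | Path,
    image_format: str = "png",
    config: SyntheticConfig | None = None,
) -> Path:
    """Write the dataset as class subdirectories + manifest.csv + dataset.json."""
    if image_format not in ("png", "pgm"):
        raise ValueError(f"unsupported image format {image_format!r}")
    if dataset.fmax > 255 and image_format != "png":
        raise ValueError(">8-bit datasets must use the png format")
    root = Path(root)
    rows = []
    for name in LABEL_NAMES:
        (root / name).mkdir(parents=True, exist_ok=True)
    for i in range(len(dataset)):
        label = LABEL_NAMES[dataset.labels[i]]
        rel = f"{label}/{dataset.ids[i]}.{image_format}"
        write_image(root / rel, dataset.images[i], dataset.fmax)
        rows.append({"id": dataset.ids[i], "label": label, "file": rel})
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)
    meta = {"fmax": int(dataset.fmax), "size": int(dataset.size), "n": len(dataset)}
    if config is not None:
        meta["config"] = asdict(config)
    (root / "dataset.json").write_text(json.dumps(meta, indent=2))
    return root


def load_dataset(root: str | Path) -> LabeledDataset:
    """Load a dataset directory (manifest-driven if manifest.csv exists).

    Every image is validated against the declared size and fmax; any bad
    file fails the load with its path in the message.  Images are ordered by
    id for a stable layout.
    """
    root = Path(root)
    fmax, size = 255, None
    meta_path = root / "dataset.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        fmax = int(meta.get("fmax", 255))
        size = meta.get("size")
    manifest_path = root / "manifest.csv"
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path, dtype=str)
        missing = {"id", "label", "file"} - set(manifest.columns)
        if missing:
            raise ValueError(f"{manifest_path}: missing columns {sorted(missing)}")
        if manifest["id"].duplicated().any():
            dup = manifest["id"][manifest["id"].duplicated()].iloc[0]
            raise ValueError(f"{manifest_path}: duplicate id {dup!r}")
        records = list(manifest.itertuples(index=False))
    else:
        records = []
        for label in LABEL_NAMES:
            subdir = root / label
            if not subdir.is_dir():
                continue
            for p in sorted(subdir.iterdir()):
                if p.suffix.lower() in (".png", ".pgm"):
                    records.append(
                        pd.Series({"id": p.stem, "label": label, "file": f"{label}/{p.name}"})
                    )
        if not records:
            raise ValueError(f"{root}: no manifest.csv and no normal/ or cirrhosis/ images")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{root}: duplicate image ids across class directories")
    records = sorted(records, key=lambda r: r.id)
    images, labels, ids = [], [], []
    for rec in records:
        if rec.label not in LABEL_NAMES:
            raise ValueError(f"{root}: unknown label {rec.label!r} for id {rec.id!r}")
        arr = read_image(root / rec.file, fmax)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError(f"{root / rec.file}: image is {arr.shape}, expected square")
        if size is not None and arr.shape != (size, size):
            raise ValueError(
                f"{root / rec.file}: image is {arr.shape}, expected ({size}, {size})"
            )
        if images and arr.shape != images[0].shape:
            raise ValueError(f"{root / rec.file}: size differs from the rest of the dataset")
        images.append(arr)
        labels.append(LABEL_NAMES.index(rec.label))
        ids.append(rec.id)
    return LabeledDataset(np.stack(images), np.array(labels, np.int8), tuple(ids), fmax)


def _versions() -> dict:
    import sklearn
    import scipy

    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def write_results(
    summaries: Sequence[EvalSummary],
    destination: str | Path,
    config: dict | None = None,
) -> tuple[Path, Path]:
    """Write summaries to ``<destination>.csv`` and ``<destination>.json``.

    The JSON side carries per-trial errors and provenance (resolved config —
    including seeds, even defaulted ones — plus library versions) so a run
    is reproducible from its outputs alone.
    """
    if not summaries:
        raise ValueError("no summaries to write")
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    csv_path = destination.with_suffix(".csv")
    json_path = destination.with_suffix(".json")
    frame = pd.DataFrame(
        [
            {
                "method": s.method,
                "mean_error": s.mean_error,
                "ci_halfwidth": s.ci_halfwidth,
                "n_trials": s.n_trials,
                "split_hash": s.split_hash,
            }
            for s in summaries
        ],
        columns=RESULT_COLUMNS,
    )
    frame.to_csv(csv_path, index=False)
    doc = {
        "provenance": {"config": config or {}, "versions": _versions()},
        "summaries": [
            {
                "method": s.method,
                "mean_error": s.mean_error,
                "ci_halfwidth": s.ci_halfwidth,
                "split_hash": s.split_hash,
                "per_trial": [
                    {"trial_index": t.trial_index, "error_rate": t.error_rate}
                    for t in s.per_trial
                ],
            }
            for s in summaries
        ],
    }
    json_path.write_text(json.dumps(doc, indent=2))
    return csv_path, json_path


def read_results(destination: str | Path) -> list[EvalSummary]:
    """Rebuild :class:`EvalSummary` objects from a results JSON document."""
    json_path = Path(destination).with_suffix(".json")
    doc = json.loads(json_path.read_text())
    out = []
    for s in doc["summaries"]:
        out.append(
            EvalSummary(
                method=s["method"],
                mean_error=s["mean_error"],
                ci_halfwidth=s["ci_halfwidth"],
                per_trial=tuple(
                    TrialResult(t["trial_index"], t["error_rate"]) for t in s["per_trial"]
                ),
                split_hash=s["split_hash"],
            )
        )
    return out
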