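"""Serialization: TSV tables, YAML configs/headers, JSON results, NIfTI runs.

All timing in files is in seconds; TR-index arithmetic happens only inside
the decoding module.  Synthetic runs serialize as NIfTI with a 1 x 1 x V x T
layout so the real-data loaders round-trip them unchanged.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .bold import BoldRun
from .design import ContextSet, DesignParams, ExperimentDesign

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_json",
    "write_yaml",
    "read_yaml",
    "write_design",
    "read_design",
    "save_run_nifti",
    "load_run_nifti",
    "load_masked_series",
]


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path


def write_yaml(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_jsonable(obj), sort_keys=True))
    return path


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def write_design(design: ExperimentDesign, out_dir) -> Path:
    """Serialize a design: words.tsv, contexts.tsv + a YAML header."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    words = pd.DataFrame(
        [{"word_id": w, "context_id": cs.id, "seed": design.seed}
         for cs in design.context_sets for w in cs.word_ids]
    )
    contexts = pd.DataFrame(
        [{"context_id": cs.id, "picture_kind": cs.picture_kind, "side": cs.side,
          "seed": design.seed} for cs in design.context_sets]
    )
    write_tsv(words, out / "words.tsv")
    write_tsv(contexts, out / "contexts.tsv")
    header = dataclasses.asdict(design.params)
    header["seed"] = design.seed
    write_yaml(header, out / "design.yaml")
    return out


def read_design(in_dir) -> ExperimentDesign:
    in_dir = Path(in_dir)
    header = read_yaml(in_dir / "design.yaml")
    seed = header.pop("seed")
    if header.get("context_kinds") is not None:
        header["context_kinds"] = tuple(tuple(k) for k in header["context_kinds"])
    params = DesignParams(**header)
    words = read_tsv(in_dir / "words.tsv")
    contexts = read_tsv(in_dir / "contexts.tsv")
    sets = []
    for row in contexts.itertuples():
        wids = tuple(words.loc[words["context_id"] == row.context_id, "word_id"])
        sets.append(ContextSet(id=row.context_id, picture_kind=row.picture_kind,
                               side=row.side, word_ids=wids))
    return ExperimentDesign(words=tuple(sorted(words["word_id"])),
                            context_sets=tuple(sets), params=params, seed=int(seed))


def save_run_nifti(run: BoldRun, path) -> Path:
    """Store a (T, V) run as a 1 x 1 x V x T NIfTI image."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vol = run.data.T[None, None, :, :]  # (1, 1, V, T)
    img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine=np.eye(4))
    img.header["pixdim"][4] = run.tr_seconds
    nib.save(img, str(path))
    return path


def load_run_nifti(path, tr_seconds: float | None = None, label: str = "") -> BoldRun:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI image")
    V = int(np.prod(data.shape[:3]))
    series = data.reshape(V, data.shape[3]).T  # (T, V)
    tr = tr_seconds if tr_seconds is not None else float(img.header["pixdim"][4]) or 1.0
    return BoldRun(tr_seconds=tr, data=series, label=label)


def load_masked_series(bold_path, mask_path, tr_seconds: float | None = None,
                       discard_volumes: int = 0, label: str = "") -> BoldRun:
    """Load a 4-D NIfTI, flatten voxels inside a binary mask to (T, V)."""
    img = nib.load(str(bold_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError("BOLD image must be 4-D")
    mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape does not match BOLD volume shape")
    series = data[mask].T  # (T, V)
    if discard_volumes:
        series = series[discard_volumes:]
    tr = tr_seconds if tr_seconds is not None else float(img.header["pixdim"][4]) or 1.0
    return BoldRun(tr_seconds=tr, data=series, label=label)
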