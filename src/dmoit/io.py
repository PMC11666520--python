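"""Delimited-matrix readers/writers, sample alignment and label tables.

File layout: first column sample IDs, header row feature IDs, tab-delimited
by default (comma auto-detected from a ``.csv`` extension). Missing cells
are empty strings or ``NA`` on read and written back as ``NA``.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import LabelVector, OmicsBundle, OmicsMatrix, RunConfig

_NA_STRINGS = ("", "NA", "NaN", "nan")


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_omics_matrix(path: str, layer_kind: str, name: str | None = None) -> OmicsMatrix:
    """Read one omics layer from delimited text.

    Raises ``ValueError`` on duplicate IDs (naming the duplicate), on
    non-numeric cells (naming row and column), and on ternary layers
    containing values outside {-1, 0, +1}.
    """
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, header=0, dtype=str,
        keep_default_na=False,
    )
    sample_ids = [str(s) for s in df.index]
    feature_ids = [str(f) for f in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip() if isinstance(raw[i, j], str) else raw[i, j]
            if cell in _NA_STRINGS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {cell!r} at sample {sample_ids[i]!r}, "
                    f"feature {feature_ids[j]!r} in {path}"
                ) from None
    if name is None:
        name = os.path.splitext(os.path.basename(str(path)))[0]
    return OmicsMatrix(sample_ids, feature_ids, values, layer_kind, name)


def write_omics_matrix(m: OmicsMatrix, path: str) -> None:
    """Write a layer so that :func:`read_omics_matrix` round-trips it."""
    df = m.to_frame()
    df.to_csv(path, sep=_sep_for(path), na_rep="NA")


def read_labels(path: str, label_names: dict[int, str] | None = None) -> LabelVector:
    """Read a two-column (sample_id, label) table."""
    df = pd.read_csv(path, sep=_sep_for(path), header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label table {path} needs two columns (sample_id, label)")
    ids = [str(s) for s in df.iloc[:, 0]]
    labels = df.iloc[:, 1].astype(int).to_numpy()
    return LabelVector(ids, labels, label_names or {0: "0", 1: "1"})


def write_labels(lv: LabelVector, path: str) -> None:
    pd.DataFrame({"sample_id": lv.sample_ids, "label": lv.labels}).to_csv(
        path, sep=_sep_for(path), index=False
    )


def align_bundle(
    matrices: Sequence[OmicsMatrix], labels: LabelVector
) -> tuple[OmicsBundle, LabelVector]:
    """Keep samples present in every layer and the label table.

    Output sample order is canonical (lexicographically sorted IDs); all
    downstream stages assume this order. Raises on an empty intersection.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    common = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        common &= set(m.sample_ids)
    common &= set(labels.sample_ids)
    if not common:
        raise ValueError("no samples shared by all layers and the label table")
    order = sorted(common)
    aligned = []
    for m in matrices:
        pos = {s: i for i, s in enumerate(m.sample_ids)}
        aligned.append(m.select_samples([pos[s] for s in order]))
    lpos = {s: i for i, s in enumerate(labels.sample_ids)}
    new_labels = labels.select([lpos[s] for s in order])
    return OmicsBundle(aligned), new_labels


def read_config(path: str) -> RunConfig:
    """Read a flat ``key = value`` / ``key: value`` configuration file."""
    cfg = RunConfig()
    listy = {k for k in cfg.grid}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            for sep in ("=", ":"):
                if sep in line:
                    key, _, val = line.partition(sep)
                    break
            else:
                raise ValueError(f"cannot parse config line: {line!r}")
            key, val = key.strip(), val.strip()
            if key in listy:
                cfg.grid[key] = [float(v) if "." in v else int(v) for v in val.split(",")]
            elif hasattr(cfg, key):
                cur = getattr(cfg, key)
                if isinstance(cur, bool):
                    setattr(cfg, key, val.lower() in ("1", "true", "yes"))
                elif isinstance(cur, int):
                    setattr(cfg, key, int(val))
                elif isinstance(cur, float):
                    setattr(cfg, key, float(val))
                else:
                    setattr(cfg, key, val)
            else:
                raise ValueError(f"unknown config key {key!r}")
    cfg.__post_init__()
    return cfg
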