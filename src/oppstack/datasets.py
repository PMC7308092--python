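"""Containers and delimited-table I/O for multimodal feature blocks.

The on-disk format is deliberately plain: tab-delimited text with a header
row, ``subject_id`` as the first column, ``NA`` for missing cells and
``#``-prefixed metadata lines (config hash, seed) before the header.
Neuroimaging file formats are out of scope — feature tables are the
ingestion boundary.
"""

from __future__ import annotations

import hashlib

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"


@dataclass
class Block:
    """One modality: a subjects x features matrix plus availability mask.

    Rows of ``X`` for unavailable subjects are present but ignored (NaN by
    convention); ``mask[i]`` says whether subject ``i`` was observed for
    this modality.
    """

    name: str
    X: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.X.ndim != 2:
            raise ValueError(f"block {self.name!r}: X must be 2-D")
        if self.mask.shape != (self.X.shape[0],):
            raise ValueError(f"block {self.name!r}: mask/matrix row mismatch")
        if self.X.shape[1] < 1:
            raise ValueError(f"block {self.name!r}: needs at least one feature")
        if not self.mask.any():
            raise ValueError(f"block {self.name!r}: zero observed subjects")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class MultimodalDataset:
    """Subject IDs, an age vector and named feature blocks with masks."""

    subject_ids: np.ndarray
    age: np.ndarray
    blocks: dict[str, Block]
    health: np.ndarray | None = None  # latent ground truth, simulation only
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.age = np.asarray(self.age, dtype=float)
        n = len(self.subject_ids)
        if len(np.unique(self.subject_ids)) != n:
            raise ValueError("duplicate subject_id")
        if self.age.shape != (n,):
            raise ValueError("age vector does not match subject_ids")
        for blk in self.blocks.values():
            if blk.X.shape[0] != n:
                raise ValueError(f"block {blk.name!r} row count != n_subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def block_names(self) -> list[str]:
        return list(self.blocks)

    def observed_any(self) -> np.ndarray:
        """Boolean mask of subjects with at least one observed block."""
        out = np.zeros(self.n_subjects, dtype=bool)
        for blk in self.blocks.values():
            out |= blk.mask
        return out

    def complete_cases(self) -> np.ndarray:
        """Boolean mask of subjects observed in every block."""
        out = np.ones(self.n_subjects, dtype=bool)
        for blk in self.blocks.values():
            out &= blk.mask
        return out

    def subset(self, idx: np.ndarray) -> "MultimodalDataset":
        idx = np.asarray(idx)
        return MultimodalDataset(
            subject_ids=self.subject_ids[idx],
            age=self.age[idx],
            blocks={
                name: Block(name, blk.X[idx], blk.mask[idx])
                for name, blk in self.blocks.items()
            },
            health=None if self.health is None else self.health[idx],
            meta=dict(self.meta),
        )


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping (for output headers)."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def write_table(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """Write a tab-delimited table with '#' metadata header lines."""
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        # %.17g keeps float round-trips bit-exact
        df.to_csv(fh, sep="\t", index=False, na_rep=MISSING_TOKEN,
                  float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING_TOKEN],
                       float_precision="round_trip")


def write_block_table(path, X: np.ndarray, subject_ids, feature_names=None,
                      meta: dict | None = None) -> None:
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=list(feature_names))
    df.insert(0, "subject_id", subject_ids)
    write_table(path, df, meta)


def read_block_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a block table; returns (matrix with NaN for missing, subject_ids).

    Raises on duplicate subject IDs or non-numeric cells other than the
    declared missing token.
    """
    df = read_table(path)
    if df.columns[0] != "subject_id":
        raise ValueError(f"{path}: first column must be 'subject_id'")
    ids = df["subject_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate subject_id")
    body = df.drop(columns="subject_id")
    try:
        X = body.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in feature columns") from exc
    return X, ids


def write_signal(path, data: np.ndarray, fs: float) -> None:
    """Write a channels x samples signal as delimited text with fs metadata."""
    df = pd.DataFrame(np.asarray(data, dtype=float))
    write_table(path, df, {"fs_hz": fs})


def read_signal(path) -> tuple[np.ndarray, float]:
    fs = None
    with open(path) as fh:
        head = []
        for line in fh:
            if line.startswith("#"):
                head.append(line)
                if "fs_hz" in line:
                    fs = float(line.split(":", 1)[1])
            else:
                break
    if fs is None:
        raise ValueError(f"{path}: missing '# fs_hz:' metadata line")
    df = read_table(path)
    return df.to_numpy(dtype=float), fs


def dataset_to_tables(dataset: MultimodalDataset, outdir, meta=None) -> dict[str, str]:
    """Serialize a dataset: one table per block, a 0/1 mask table, ages."""
    import os

    paths = {}
    os.makedirs(outdir, exist_ok=True)
    age_path = os.path.join(outdir, "age.tsv")
    write_table(age_path, pd.DataFrame(
        {"subject_id": dataset.subject_ids, "age": dataset.age}), meta)
    paths["age"] = age_path
    mask_df = pd.DataFrame({"subject_id": dataset.subject_ids})
    for name, blk in dataset.blocks.items():
        X = blk.X.copy()
        X[~blk.mask] = np.nan
        p = os.path.join(outdir, f"block_{name}.tsv")
        write_block_table(p, X, dataset.subject_ids, meta=meta)
        paths[f"block_{name}"] = p
        mask_df[name] = blk.mask.astype(int)
    mask_path = os.path.join(outdir, "mask.tsv")
    write_table(mask_path, mask_df, meta)
    paths["mask"] = mask_path
    return paths


def dataset_from_tables(age_path, block_paths: dict[str, str]) -> MultimodalDataset:
    """Load a dataset from an age table plus named block tables.

    A subject counts as missing for a block when its row is absent from the
    block table or entirely NaN.
    """
    age_df = read_table(age_path)
    ids = age_df["subject_id"].to_numpy()
    age = age_df["age"].to_numpy(dtype=float)
    order = {s: i for i, s in enumerate(ids)}
    blocks = {}
    for name, path in block_paths.items():
        Xb, bids = read_block_table(path)
        X = np.full((len(ids), Xb.shape[1]), np.nan)
        for row, sid in enumerate(bids):
            if sid not in order:
                raise ValueError(f"block {name!r}: unknown subject {sid!r}")
            X[order[sid]] = Xb[row]
        mask = ~np.isnan(X).all(axis=1)
        if np.isnan(X[mask]).any():
            raise ValueError(f"block {name!r}: partially missing feature rows")
        blocks[name] = Block(name, X, mask)
    return MultimodalDataset(ids, age, blocks)
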