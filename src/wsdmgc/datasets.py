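"""Sample containers, image/feature-table ingestion and label masking.

A :class:`SampleSet` holds either a stack of equally sized grayscale image
patches (N, H, W) or a plain feature matrix (N, d), together with ground
truth class ids (where known) and the labeled/unlabeled flags that define
the weakly supervised setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger("wsdmgc")

TABLE_COLUMNS = ["sample_id", "filepath", "label", "labeled"]


class DataFormatError(ValueError):
    """A file does not match the expected on-disk dialect."""


class DataValidationError(ValueError):
    """Contents are well-formed but violate a dataset invariant."""


@dataclass
class Sample:
    """A single image patch or feature vector with its label metadata."""

    id: str
    data: np.ndarray
    true_label: int | None
    is_labeled: bool


@dataclass
class SampleSet:
    """An ordered collection of samples with weak-supervision flags.

    Attributes
    ----------
    ids : array of str, shape (N,)
    X : ndarray
        Images as (N, H, W) floats in [0, 1], or features as (N, d).
    y : int array, shape (N,)
        Ground-truth class ids in 0..n_classes-1, or -1 where unknown.
    labeled : bool array, shape (N,)
        Which samples count as labeled for training. Unlabeled samples may
        still carry a hidden ``y`` for evaluation.
    label_names : dict or None
        Dense class id -> original external label string.
    filepaths : array of str or None
        Original file paths, retained so the sample table round-trips.
    """

    ids: np.ndarray
    X: np.ndarray
    y: np.ndarray
    labeled: np.ndarray
    label_names: dict[int, str] | None = None
    filepaths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.labeled = np.asarray(self.labeled, dtype=bool)
        n = len(self.ids)
        if not (self.X.shape[0] == self.y.shape[0] == self.labeled.shape[0] == n):
            raise DataValidationError("ids, X, y and labeled must have equal length")
        if len(np.unique(self.ids)) != n:
            raise DataValidationError("sample ids must be unique")
        if np.any(self.y[self.labeled] < 0):
            raise DataValidationError("labeled samples must carry a class label")
        if n and self.is_image and (self.X.min() < -1e-9
                                    or self.X.max() > 1 + 1e-9):
            raise DataValidationError("image pixel values must lie in [0, 1]")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, i: int) -> Sample:
        lab = int(self.y[i])
        return Sample(
            id=str(self.ids[i]),
            data=self.X[i],
            true_label=lab if lab >= 0 else None,
            is_labeled=bool(self.labeled[i]),
        )

    def __iter__(self) -> Iterator[Sample]:
        return (self[i] for i in range(len(self)))

    # -- derived properties -------------------------------------------------
    @property
    def is_image(self) -> bool:
        return self.X.ndim == 3

    @property
    def n_classes(self) -> int:
        known = self.y[self.y >= 0]
        return int(known.max()) + 1 if known.size else 0

    @property
    def labeled_fraction(self) -> float:
        return float(self.labeled.mean()) if len(self) else 0.0

    @property
    def features(self) -> np.ndarray:
        """Flattened numeric view: (N, H*W) for images, (N, d) otherwise."""
        return self.X.reshape(len(self), -1)

    def subset(self, index) -> "SampleSet":
        index = np.asarray(index)
        return SampleSet(
            ids=self.ids[index],
            X=self.X[index],
            y=self.y[index],
            labeled=self.labeled[index],
            label_names=self.label_names,
            filepaths=None if self.filepaths is None else self.filepaths[index],
        )


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def _read_grayscale_png(path: Path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG, rescaled to [0, 1] by the format max."""
    with Image.open(path) as im:
        mode = im.mode
        arr = np.asarray(im)
    if mode == "L":
        return arr.astype(np.float64) / 255.0
    if mode in ("I", "I;16", "I;16B"):
        return arr.astype(np.float64) / 65535.0
    raise DataFormatError(f"{path}: unsupported image mode {mode!r}; "
                          "expected 8- or 16-bit grayscale")


def _read_table(table_path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(table_path, dtype={"sample_id": str, "filepath": str,
                                           "label": str})
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise DataFormatError(
            f"sample table {table_path} is missing column(s): {', '.join(missing)}")
    dup = table["sample_id"][table["sample_id"].duplicated()].tolist()
    if dup:
        raise DataValidationError(f"duplicate sample_id values: {dup}")
    return table


def _encode_labels(table: pd.DataFrame) -> tuple[np.ndarray, dict[int, str]]:
    raw = table["label"].fillna("").astype(str).str.strip()
    labeled = table["labeled"].astype(int).to_numpy()
    bad = table["sample_id"][(labeled == 1) & (raw == "")].tolist()
    if bad:
        raise DataValidationError(
            f"samples flagged labeled=1 but with empty label: {bad}")
    names = sorted({v for v in raw if v != ""})
    code = {name: i for i, name in enumerate(names)}
    y = np.array([code[v] if v != "" else -1 for v in raw], dtype=np.int64)
    mapping = {i: name for name, i in code.items()}
    logger.info("label mapping: %s", mapping)
    return y, mapping


def load_image_dataset(image_dir: str | Path, table_path: str | Path) -> SampleSet:
    """Load grayscale PNG patches listed in a sample table.

    The table is a CSV with header ``sample_id,filepath,label,labeled``;
    ``label`` may be empty for unlabeled rows. Pixel values are rescaled to
    [0, 1] by the format maximum; external label strings are re-coded to
    dense ids 0..n-1 (mapping logged and stored on the set). Row order is
    preserved.
    """
    image_dir = Path(image_dir)
    table = _read_table(table_path)
    missing_files = [sid for sid, fp in zip(table["sample_id"], table["filepath"])
                     if not (image_dir / fp).is_file()]
    if missing_files:
        raise DataValidationError(
            f"image file missing for sample_id(s): {missing_files}")
    images = [_read_grayscale_png(image_dir / fp) for fp in table["filepath"]]
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise DataValidationError(f"images have mismatched shapes: {sorted(shapes)}")
    y, mapping = _encode_labels(table)
    return SampleSet(
        ids=table["sample_id"].to_numpy(dtype=object),
        X=np.stack(images),
        y=y,
        labeled=table["labeled"].astype(int).to_numpy().astype(bool),
        label_names=mapping,
        filepaths=table["filepath"].to_numpy(dtype=object),
    )


def load_feature_dataset(features_path: str | Path,
                         table_path: str | Path | None = None) -> SampleSet:
    """Load a plain numeric feature table (TSV: ``sample_id`` then d columns).

    If ``table_path`` is given, its ``label``/``labeled`` columns supply the
    supervision flags (matched on sample_id); otherwise all samples are
    unlabeled.
    """
    feats = pd.read_csv(features_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in feats.columns:
        raise DataFormatError(f"{features_path} must have a sample_id column")
    X = feats.drop(columns="sample_id").to_numpy(dtype=np.float64)
    ids = feats["sample_id"].to_numpy(dtype=object)
    if table_path is None:
        n = len(ids)
        return SampleSet(ids=ids, X=X, y=np.full(n, -1), labeled=np.zeros(n, bool))
    table = _read_table(table_path).set_index("sample_id").loc[list(ids)].reset_index()
    y, mapping = _encode_labels(table)
    return SampleSet(ids=ids, X=X, y=y,
                     labeled=table["labeled"].astype(int).to_numpy().astype(bool),
                     label_names=mapping)


def write_table(dataset: SampleSet, path: str | Path) -> None:
    """Write the sample table in the ingestion dialect (CSV)."""
    names = dataset.label_names or {}
    label = ["" if lab < 0 else names.get(int(lab), str(int(lab)))
             for lab in dataset.y]
    fp = dataset.filepaths if dataset.filepaths is not None \
        else [f"{sid}.png" for sid in dataset.ids]
    pd.DataFrame({
        "sample_id": dataset.ids,
        "filepath": fp,
        "label": label,
        "labeled": dataset.labeled.astype(int),
    }).to_csv(path, index=False)


def save_image_dataset(dataset: SampleSet, out_dir: str | Path) -> Path:
    """Write 16-bit grayscale PNGs plus the sample table under ``out_dir``."""
    if not dataset.is_image:
        raise DataValidationError("save_image_dataset requires an image SampleSet")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    filepaths = []
    for i, sid in enumerate(dataset.ids):
        rel = f"images/{sid}.png"
        arr = np.round(dataset.X[i] * 65535.0).astype(np.uint16)
        Image.fromarray(arr).save(out_dir / rel)
        filepaths.append(rel)
    ds = SampleSet(ids=dataset.ids, X=dataset.X, y=dataset.y,
                   labeled=dataset.labeled, label_names=dataset.label_names,
                   filepaths=np.array(filepaths, dtype=object))
    table_path = out_dir / "samples.csv"
    write_table(ds, table_path)
    return table_path


# ---------------------------------------------------------------------------
# label masking
# ---------------------------------------------------------------------------

def mask_labels(dataset: SampleSet, fraction: float, seed: int) -> SampleSet:
    """Create the weakly supervised setting from a fully labeled set.

    Exactly ``max(1, round(fraction * class_size))`` samples per class keep
    ``is_labeled=True`` (stratified — every class retains at least one
    labeled sample); all others are flagged unlabeled but retain their
    hidden true label for evaluation. Deterministic given ``seed``.
    """
    if not (0 < fraction <= 1):
        raise DataValidationError("fraction must be in (0, 1]")
    if np.any(dataset.y < 0) or not dataset.labeled.all():
        raise DataValidationError("mask_labels requires a fully labeled dataset")
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(dataset), dtype=bool)
    for cls in range(dataset.n_classes):
        members = np.flatnonzero(dataset.y == cls)
        if members.size == 0:
            raise DataValidationError(f"class {cls} has no members")
        n_keep = max(1, int(np.floor(fraction * members.size + 0.5)))
        chosen = rng.choice(members, size=min(n_keep, members.size), replace=False)
        keep[chosen] = True
    return SampleSet(ids=dataset.ids, X=dataset.X, y=dataset.y, labeled=keep,
                     label_names=dataset.label_names, filepaths=dataset.filepaths)
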