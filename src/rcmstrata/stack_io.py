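"""Reading and writing RCM stacks, per-slice strata labels and predictions.

An RCM *stack* is a set of grayscale confocal images acquired at one lateral
skin position over consecutive depths; each image is a *slice*.  Slices are
ordered shallow to deep and separated by a fixed axial step in micrometres.
Per-slice ground-truth labels name the stratum dominating each slice:
epidermis (0), dermal-epidermal junction / DEJ (1) or dermis (2); the
stratum corneum, the topmost epidermal layer, is merged into epidermis on
ingest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "RCMStack", "StrataLabelSequence", "LABEL_NAMES", "LABEL_CODES",
    "read_stack", "write_stack", "read_labels", "write_labels",
    "pad_and_mask", "write_predictions", "read_predictions",
    "natural_sort_key",
]

#: Canonical class order: strata are ordinal, shallow to deep.
LABEL_NAMES = ("epidermis", "DEJ", "dermis")

#: Accepted label strings (case-insensitive) -> integer code.
LABEL_CODES = {
    "stratum_corneum": 0,  # merged into epidermis unless merging is disabled
    "epidermis": 0,
    "dej": 1,
    "dermis": 2,
}


@dataclass
class RCMStack:
    """Ordered grayscale slices with their axial geometry.

    ``slices`` is a float array of shape (n_slices, H, W) with values in
    [0, 1]; slice ``i`` sits at depth ``depth_origin_um + i * axial_step_um``.
    """

    slices: np.ndarray
    axial_step_um: float
    depth_origin_um: float = 0.0
    stack_id: str = ""
    subject_id: str = ""

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (n, h, w) array")
        if len(self.slices) < 2:
            raise ValueError("a stack needs at least 2 slices")
        if self.axial_step_um <= 0:
            raise ValueError("axial_step_um must be positive")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def depths_um(self) -> np.ndarray:
        return self.depth_origin_um + self.axial_step_um * np.arange(len(self))


@dataclass
class StrataLabelSequence:
    """Per-slice ordinal labels, epidermis(0) < DEJ(1) < dermis(2)."""

    labels: np.ndarray
    stack_id: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if len(self.labels) and not np.isin(self.labels, (0, 1, 2)).all():
            raise ValueError("labels must be in {0, 1, 2}")

    def __len__(self) -> int:
        return len(self.labels)


_NUM_RE = re.compile(r"(\d+)")


def natural_sort_key(name: str) -> tuple:
    """Numeric-aware sort key: ``s2`` sorts before ``s10``.

    The raw string is appended as a tie-break so names that differ only in
    zero padding (``a2`` vs ``a02``) still order deterministically.
    """
    name = str(name)
    tokens = tuple(int(tok) if tok.isdigit() else tok.lower()
                   for tok in _NUM_RE.split(name))
    return (tokens, name)


def _to_unit_float(img: np.ndarray) -> np.ndarray:
    """Grayscale-reduce and map pixel values to [0, 1] by the dtype range."""
    img = np.asarray(img)
    dtype = img.dtype
    if img.ndim == 3:  # multi-channel -> channel mean
        img = img.mean(axis=-1)
    if img.ndim != 2:
        raise ValueError(f"slice has unsupported shape {img.shape}")
    if np.issubdtype(dtype, np.integer):
        return img.astype(np.float64) / np.iinfo(dtype).max
    return img.astype(np.float64)


_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


def read_stack(path, axial_step_um: float, depth_origin_um: float = 0.0,
               stack_id: str | None = None,
               subject_id: str = "") -> RCMStack:
    """Read a multi-page TIFF or a directory of slice images as one stack.

    TIFF pages keep their page order; directory entries are ordered by
    natural sort of their filenames (clinical exports number slices, and
    plain lexicographic order would put ``s10`` before ``s2``).  Pixel
    values are mapped to [0, 1]; multi-channel slices are reduced to one
    channel by the channel mean.
    """
    path = Path(path)
    if axial_step_um <= 0:
        raise ValueError("axial_step_um must be positive")
    if path.is_dir():
        files = sorted((p for p in path.iterdir()
                        if p.suffix.lower() in _IMAGE_SUFFIXES),
                       key=lambda p: natural_sort_key(p.name))
        if not files:
            raise ValueError(f"no slices found in {path}")
        imgs = [_to_unit_float(iio.imread(f)) for f in files]
    else:
        raw = tifffile.imread(path)
        if raw.ndim == 2:
            raw = raw[None]
        imgs = [_to_unit_float(p) for p in raw]
    if not imgs:
        raise ValueError(f"no slices found in {path}")
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError(f"ragged stack: slice shapes {sorted(shapes)}")
    return RCMStack(np.stack(imgs), axial_step_um=axial_step_um,
                    depth_origin_um=depth_origin_um,
                    stack_id=stack_id if stack_id is not None else path.stem,
                    subject_id=subject_id)


def write_stack(stack: RCMStack, path, dtype: str = "uint16") -> None:
    """Write a stack as a multi-page TIFF (values rescaled to the dtype max)."""
    info = np.iinfo(dtype)
    data = np.clip(stack.slices, 0.0, 1.0)
    pages = np.round(data * info.max).astype(dtype)
    tifffile.imwrite(path, pages)


def read_labels(path, merge_sc: bool = True,
                stack_id: str = "") -> StrataLabelSequence:
    """Read per-slice labels from a CSV/TSV of (slice_index, label) rows.

    The delimiter is auto-detected (comma or tab) and a header row is
    optional.  Label strings are case-insensitive; ``stratum_corneum`` maps
    to epidermis when ``merge_sc`` is on (the default) and is rejected
    otherwise.
    """
    text = Path(path).read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    first = text.splitlines()[0].split(sep)[0].strip()
    header = 0 if not first.lstrip("-").isdigit() else None
    df = pd.read_csv(path, sep=sep, header=header)
    df.columns = ["slice_index", "label"] + list(df.columns[2:])
    if df["slice_index"].duplicated().any():
        raise ValueError("duplicate slice_index in label file")
    df = df.sort_values("slice_index")
    codes = []
    for raw in df["label"].astype(str):
        key = raw.strip().lower()
        if key not in LABEL_CODES:
            raise ValueError(f"unknown stratum label: {raw!r}")
        if key == "stratum_corneum" and not merge_sc:
            raise ValueError("stratum_corneum present but merge_sc is off")
        codes.append(LABEL_CODES[key])
    return StrataLabelSequence(np.array(codes, dtype=np.int64),
                               stack_id=stack_id)


def write_labels(labels: StrataLabelSequence, path) -> None:
    pd.DataFrame({
        "slice_index": np.arange(len(labels)),
        "label": [LABEL_NAMES[v] for v in labels.labels],
    }).to_csv(path, index=False)


def pad_and_mask(feature_sequences, max_len: int = 71):
    """Pad variable-length feature sequences into one batch with a mask.

    Sequences longer than ``max_len`` keep their first ``max_len``
    (shallowest) elements; shorter ones are zero-padded at the tail.  The
    boolean mask marks real positions.  Returns ``(batch, mask)`` with
    shapes (B, max_len, d) and (B, max_len).
    """
    seqs = [np.asarray(getattr(s, "vectors", s), dtype=np.float64)
            for s in feature_sequences]
    if not seqs:
        raise ValueError("no feature sequences to pad")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    d = seqs[0].shape[1]
    batch = np.zeros((len(seqs), max_len, d))
    mask = np.zeros((len(seqs), max_len), dtype=bool)
    for i, s in enumerate(seqs):
        n = min(len(s), max_len)
        batch[i, :n] = s[:n]
        mask[i, :n] = True
    return batch, mask


PREDICTION_COLUMNS = ["stack_id", "slice_index", "depth_um", "p_epidermis",
                      "p_DEJ", "p_dermis", "argmax_label",
                      "postprocessed_label"]


def write_predictions(table: pd.DataFrame, path) -> None:
    """Write a per-slice prediction table as CSV with the fixed schema.

    Refuses tables whose probability rows do not sum to one (within 1e-6)
    or whose slice indices are not strictly increasing per stack.
    """
    missing = [c for c in PREDICTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"prediction table missing columns: {missing}")
    probs = table[["p_epidermis", "p_DEJ", "p_dermis"]].to_numpy()
    if (probs < 0).any() or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must be non-negative and sum to 1")
    for _, grp in table.groupby("stack_id"):
        idx = grp["slice_index"].to_numpy()
        if not (np.diff(idx) > 0).all():
            raise ValueError("slice_index must be strictly increasing per stack")
    table[PREDICTION_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"prediction file missing columns: {missing}")
    return df
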