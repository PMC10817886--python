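"""Feature matrices: the in-memory container and its CSV round-trip.

A feature matrix is N samples by u real-valued features, one benign/malignant
label per sample, plus a *level tag* recording where the features came from:
raw backbone embeddings (``raw``), the 24- or 64-unit fully connected taps of
the trained head (``fea24`` / ``fea64``), or their concatenation
(``fea24_64``).

On disk a feature matrix is a UTF-8 CSV with header
``sample_id,label,f0000,...``; the level tag and format version are carried in
``#``-prefixed comment lines before the header.  Labels are the case-sensitive
literals ``benign`` and ``malignant`` — strictness is preferred over dialect
guessing.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "CLASS_ORDER",
    "POSITIVE_CLASS",
    "LEVEL_TAGS",
    "FORMAT_VERSION",
    "FeatureMatrix",
    "concat_features",
    "read_feature_csv",
    "write_feature_csv",
]

#: Fixed class order; the first class wins score ties, the positive class is
#: malignant for every threshold-free metric.
CLASS_ORDER = ("benign", "malignant")
POSITIVE_CLASS = "malignant"
LEVEL_TAGS = ("raw", "fea24", "fea64", "fea24_64")
FORMAT_VERSION = "1"


@dataclass
class FeatureMatrix:
    """N×u feature matrix with per-sample ids and labels.

    Parameters
    ----------
    values : (N, u) float array, all finite.
    sample_ids : length-N sequence of unique identifier strings.
    labels : length-N sequence drawn from :data:`CLASS_ORDER`.
    level_tag : one of :data:`LEVEL_TAGS`.
    """

    values: np.ndarray
    sample_ids: list[str] = field(repr=False)
    labels: list[str] = field(repr=False)
    level_tag: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n, u = self.values.shape
        if n < 1 or u < 1:
            raise ValidationError("feature matrix must have N >= 1 and u >= 1")
        if not np.isfinite(self.values).all():
            raise ValidationError("feature values must all be finite")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(s) for s in self.labels]
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValidationError("sample_ids/labels length must equal row count")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids must be unique")
        bad = sorted({l for l in self.labels} - set(CLASS_ORDER))
        if bad:
            raise ValidationError(
                f"labels must be drawn from {CLASS_ORDER}; found {bad}"
            )
        if self.level_tag not in LEVEL_TAGS:
            raise ValidationError(
                f"unknown level_tag {self.level_tag!r}; expected one of {LEVEL_TAGS}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def classes_present(self) -> tuple[str, ...]:
        present = set(self.labels)
        return tuple(c for c in CLASS_ORDER if c in present)

    def subset(self, idx) -> "FeatureMatrix":
        """Row subset / reorder by integer index array."""
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            level_tag=self.level_tag,
        )


def concat_features(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of two feature matrices over the same samples.

    The inputs must carry the same sample ids, in the same order, with the
    same labels.  A fea24 + fea64 pair yields the ``fea24_64`` tag; any other
    combination falls back to ``raw``.
    """
    if a.sample_ids != b.sample_ids:
        diverge = next(
            (i for i, (x, y) in enumerate(zip(a.sample_ids, b.sample_ids)) if x != y),
            min(len(a.sample_ids), len(b.sample_ids)),
        )
        raise ValidationError(
            f"sample ids differ; first divergence at row {diverge}"
        )
    if a.labels != b.labels:
        diverge = next(i for i, (x, y) in enumerate(zip(a.labels, b.labels)) if x != y)
        raise ValidationError(f"labels differ at row {diverge}")
    tag = "fea24_64" if {a.level_tag, b.level_tag} == {"fea24", "fea64"} else "raw"
    return FeatureMatrix(
        values=np.hstack([a.values, b.values]),
        sample_ids=list(a.sample_ids),
        labels=list(a.labels),
        level_tag=tag,
    )


def write_feature_csv(matrix: FeatureMatrix, path: str | os.PathLike) -> None:
    """Write a feature matrix as strict CSV with a level-tag comment header.

    Values are written with 17 significant digits so a round-trip is lossless
    at double precision.
    """
    u = matrix.n_features
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# format_version={FORMAT_VERSION}\n")
        fh.write(f"# level_tag={matrix.level_tag}\n")
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "label"] + [f"f{j:04d}" for j in range(u)])
        for i in range(matrix.n_samples):
            row = [matrix.sample_ids[i], matrix.labels[i]]
            row += [format(v, ".17g") for v in matrix.values[i]]
            writer.writerow(row)


def read_feature_csv(path: str | os.PathLike) -> FeatureMatrix:
    """Read a feature CSV written by :func:`write_feature_csv`.

    Malformed headers, non-numeric cells, unknown labels and duplicate ids are
    rejected with the offending 1-based line number.
    """
    level_tag = "raw"
    ids: list[str] = []
    labels: list[str] = []
    rows: list[list[float]] = []
    # read lines first so errors can carry 1-based line numbers
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    data_start = 0
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                if key.strip() == "level_tag":
                    level_tag = val.strip()
            data_start = lineno
            continue
        break
    content = lines[data_start:]
    if not content:
        raise ValidationError(f"{path}: no header row found")
    parsed = list(csv.reader(io.StringIO("\n".join(content))))
    header = parsed[0]
    if len(header) < 3 or header[0] != "sample_id" or header[1] != "label":
        raise ValidationError(
            f"{path}, line {data_start + 1}: malformed header "
            f"(expected 'sample_id,label,f0000,...')"
        )
    u = len(header) - 2
    seen: set[str] = set()
    for off, row in enumerate(parsed[1:], start=2):
        lineno = data_start + off
        if not row:
            continue
        if len(row) != u + 2:
            raise ValidationError(
                f"{path}, line {lineno}: expected {u + 2} fields, got {len(row)}"
            )
        sid, label = row[0], row[1]
        if sid in seen:
            raise ValidationError(f"{path}, line {lineno}: duplicate sample_id {sid!r}")
        seen.add(sid)
        if label not in CLASS_ORDER:
            raise ValidationError(
                f"{path}, line {lineno}: unknown label {label!r} "
                f"(labels are case-sensitive literals {CLASS_ORDER})"
            )
        try:
            vals = [float(x) for x in row[2:]]
        except ValueError as exc:
            raise ValidationError(f"{path}, line {lineno}: non-numeric cell ({exc})")
        ids.append(sid)
        labels.append(label)
        rows.append(vals)
    if not rows:
        raise ValidationError(f"{path}: empty data section")
    return FeatureMatrix(
        values=np.asarray(rows, dtype=float),
        sample_ids=ids,
        labels=labels,
        level_tag=level_tag,
    )
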