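"""Readers/writers for fingerprint datasets and persisted models.

Two text dataset formats are supported:

``csv-bits``
    Delimited rows ``id, label, bits`` where ``bits`` is either a single
    bitstring column (e.g. ``"10110"``) or ``L`` separate 0/1 columns.

``hex-fps``
    A header line ``#L=<dim>`` followed by rows ``id, label, hex`` where the
    hex string has ``ceil(L/4)`` nibbles encoding the bits
    most-significant-first (the common fingerprint convention): with
    ``L = 4``, hex ``9`` decodes to ``(1, 0, 0, 1)``.

Malformed rows (ragged length, non-binary/non-hex symbols) raise
:class:`ParseError` naming the offending line; nothing is silently coerced.
Labels are kept as opaque strings -- class identifiers are categorical.

Models persist as a versioned JSON container holding the kernel parameters,
priors, and per class the statistics ``(N_w, a, z, z', Q)`` with ``Q`` as an
upper-triangle triplet list.  Integers round-trip bit-exactly and reals to
full double precision (JSON ``repr`` of Python floats is lossless).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .compressed import ClassSummary, CompressedModel
from .exact import LabeledDataset, PriorVector
from .kernels import KernelParams

__all__ = [
    "DatasetFileSpec",
    "ParseError",
    "IntegrityError",
    "UnsupportedVersionError",
    "read_dataset",
    "write_dataset",
    "save_model",
    "load_model",
    "MODEL_MAGIC",
    "MODEL_VERSION",
]

MODEL_MAGIC = "aaparzen-model"
MODEL_VERSION = 1

_FORMATS = ("csv-bits", "hex-fps")


class ParseError(ValueError):
    """A dataset file row could not be parsed."""


class IntegrityError(ValueError):
    """A model file is corrupt or not a model file at all."""


class UnsupportedVersionError(IntegrityError):
    """A model file declares a format version this library cannot read."""


@dataclass(frozen=True)
class DatasetFileSpec:
    """Location and format of a fingerprint dataset file."""

    path: str | Path
    format: str = "csv-bits"
    delimiter: str = ","
    has_header: bool = False

    def __post_init__(self) -> None:
        if self.format not in _FORMATS:
            raise ValueError(f"format must be one of {_FORMATS}; got {self.format!r}")


def read_dataset(spec: DatasetFileSpec | str | Path, **kwargs) -> LabeledDataset:
    """Read a labeled dataset; ``L`` is inferred and enforced across rows."""
    if not isinstance(spec, DatasetFileSpec):
        spec = DatasetFileSpec(path=spec, **kwargs)
    lines = Path(spec.path).read_text().splitlines()
    if spec.format == "csv-bits":
        return _read_csv_bits(lines, spec)
    return _read_hex_fps(lines, spec)


def _read_csv_bits(lines, spec) -> LabeledDataset:
    patterns, labels = [], []
    L = None
    start = 1 if spec.has_header else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(spec.delimiter)]
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: expected at least 3 fields, got {len(fields)}")
        _, label = fields[0], fields[1]
        if len(fields) == 3:
            bits = fields[2]
        else:
            bits = "".join(fields[2:])
        if not bits or any(ch not in "01" for ch in bits):
            raise ParseError(f"line {lineno}: non-binary symbol in bit field {bits!r}")
        if L is None:
            L = len(bits)
        elif len(bits) != L:
            raise ParseError(
                f"line {lineno}: ragged row, {len(bits)} bits where previous rows had {L}"
            )
        patterns.append([int(ch) for ch in bits])
        labels.append(label)
    if not patterns:
        raise ParseError("file contains no data rows")
    return LabeledDataset(np.array(patterns, dtype=np.int64), labels)


def _read_hex_fps(lines, spec) -> LabeledDataset:
    L = None
    patterns, labels = [], []
    data_started = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if data_started:
                raise ParseError(f"line {lineno}: header line after data rows")
            body = stripped.lstrip("#").strip()
            if body.startswith("L="):
                try:
                    L = int(body[2:])
                except ValueError:
                    raise ParseError(f"line {lineno}: bad dimension header {stripped!r}")
            continue
        if L is None:
            raise ParseError(f"line {lineno}: data row before the '#L=<dim>' header")
        data_started = True
        fields = [f.strip() for f in stripped.split(spec.delimiter)]
        if len(fields) != 3:
            raise ParseError(f"line {lineno}: expected 3 fields (id,label,hex), got {len(fields)}")
        _, label, hexstr = fields
        n_nibbles = math.ceil(L / 4)
        if len(hexstr) != n_nibbles:
            raise ParseError(
                f"line {lineno}: expected {n_nibbles} hex nibbles for L={L}, "
                f"got {len(hexstr)}"
            )
        try:
            value = int(hexstr, 16)
        except ValueError:
            raise ParseError(f"line {lineno}: non-hex symbol in {hexstr!r}")
        total_bits = 4 * n_nibbles
        bits = [(value >> (total_bits - 1 - l)) & 1 for l in range(L)]
        pad = value & ((1 << (total_bits - L)) - 1) if total_bits > L else 0
        if pad:
            raise ParseError(f"line {lineno}: nonzero padding bits beyond L={L}")
        patterns.append(bits)
        labels.append(label)
    if not patterns:
        raise ParseError("file contains no data rows")
    return LabeledDataset(np.array(patterns, dtype=np.int64), labels)


def write_dataset(
    dataset: LabeledDataset,
    spec: DatasetFileSpec | str | Path,
    ids=None,
    **kwargs,
) -> None:
    """Write a labeled dataset; ``read_dataset`` round-trips it bit-exactly."""
    if not isinstance(spec, DatasetFileSpec):
        spec = DatasetFileSpec(path=spec, **kwargs)
    if ids is None:
        ids = [f"p{i}" for i in range(dataset.N)]
    lines = []
    if spec.format == "csv-bits":
        if spec.has_header:
            lines.append(spec.delimiter.join(["id", "label", "bits"]))
        for pid, label, row in zip(ids, dataset.labels, dataset.patterns):
            bits = "".join(str(int(b)) for b in row)
            lines.append(spec.delimiter.join([str(pid), str(label), bits]))
    else:
        L = dataset.L
        n_nibbles = math.ceil(L / 4)
        total_bits = 4 * n_nibbles
        lines.append(f"#L={L}")
        for pid, label, row in zip(ids, dataset.labels, dataset.patterns):
            value = 0
            for l, b in enumerate(row):
                if b:
                    value |= 1 << (total_bits - 1 - l)
            lines.append(
                spec.delimiter.join([str(pid), str(label), format(value, f"0{n_nibbles}x")])
            )
    Path(spec.path).write_text("\n".join(lines) + "\n")


def _summary_to_json(s: ClassSummary) -> dict:
    upper = sp.triu(s.Q).tocoo()
    return {
        "n_omega": s.n_omega,
        "a": s.a,
        "z": [int(v) for v in s.z],
        "z_prime": [float(v) for v in s.z_prime],
        "q_triplets": [
            [int(r), int(c), float(v)] for r, c, v in zip(upper.row, upper.col, upper.data)
        ],
    }


def _summary_from_json(d: dict, L: int, lam: float) -> ClassSummary:
    rows, cols, vals = [], [], []
    for r, c, v in d["q_triplets"]:
        rows.append(r)
        cols.append(c)
        vals.append(v)
        if r != c:  # mirror the upper triangle
            rows.append(c)
            cols.append(r)
            vals.append(v)
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(L, L)).tocsr()
    return ClassSummary(
        n_omega=int(d["n_omega"]),
        a=float(d["a"]),
        z=np.array(d["z"], dtype=np.int64),
        z_prime=np.array(d["z_prime"], dtype=float),
        Q=Q,
        lam=lam,
    )


def save_model(model: CompressedModel, path: str | Path) -> None:
    """Persist a compressed model as versioned JSON."""
    classes = model.classes
    doc = {
        "magic": MODEL_MAGIC,
        "version": MODEL_VERSION,
        "L": model.L,
        "lambda": model.params.lam,
        "prior_mode": model.priors.mode,
        "classes": [str(c) for c in classes],
        "priors": {str(c): model.priors[c] for c in classes},
        "summaries": {str(c): _summary_to_json(model.summaries[c]) for c in classes},
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> CompressedModel:
    """Load a model saved by :func:`save_model`.

    Raises :class:`IntegrityError` on corrupt/foreign files and
    :class:`UnsupportedVersionError` on a version this library cannot read.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise IntegrityError(f"model file is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("magic") != MODEL_MAGIC:
        raise IntegrityError(f"not a {MODEL_MAGIC} file: bad or missing header magic")
    if doc.get("version") != MODEL_VERSION:
        raise UnsupportedVersionError(
            f"model format version {doc.get('version')!r} is not supported "
            f"(this library reads version {MODEL_VERSION})"
        )
    required = {"L", "lambda", "prior_mode", "classes", "priors", "summaries"}
    missing = required - doc.keys()
    if missing:
        raise IntegrityError(f"model file is missing fields: {sorted(missing)}")
    L = int(doc["L"])
    lam = float(doc["lambda"])
    params = KernelParams(lam=lam, L=L)
    priors = PriorVector(
        priors={c: float(p) for c, p in doc["priors"].items()}, mode=doc["prior_mode"]
    )
    summaries = {
        c: _summary_from_json(d, L, lam) for c, d in doc["summaries"].items()
    }
    if set(summaries) != set(doc["classes"]):
        raise IntegrityError("class list and summaries disagree")
    return CompressedModel(summaries=summaries, params=params, priors=priors)
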