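"""Core tabular data structures and their TSV readers/writers.

Every on-disk artifact is a plain TSV dialect:

* OTU table — first column OTU IDs, header row sample IDs (default
  orientation ``otus_as_rows``; the transpose is selectable).
* Guild annotation — columns ``otu_id``, ``trophic_mode``, ``guild``,
  ``confidence``.
* Sample metadata — one row per sample, fixed identity columns plus free
  named environmental variables.
* Trait table — long format, one row per (quadrat, species).
* Plant community — quadrats x species relative abundances.
* Distance matrix — square, labelled on both axes; signed matrices (for
  null-deviation output) carry a ``# signed`` comment line.

Run configuration is YAML with a closed key set and documented defaults.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ParseError, ValidationError

__all__ = [
    "OtuTable",
    "GuildRecord",
    "GuildAnnotation",
    "DistanceMatrix",
    "CONFIDENCE_LEVELS",
    "DEPTH_LAYERS",
    "read_otu_table",
    "write_otu_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_annotation",
    "write_annotation",
    "read_metadata",
    "write_metadata",
    "read_plant_community",
    "write_plant_community",
    "read_trait_table",
    "write_trait_table",
    "load_config",
    "DEFAULT_CONFIG",
]

CONFIDENCE_LEVELS = ("Highly Probable", "Probable", "Possible", "Unassigned")
DEPTH_LAYERS = ("surface", "subsurface")

_FLOAT_FMT = "%.10g"


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


# ---------------------------------------------------------------------------
# OTU table


@dataclass(frozen=True)
class OtuTable:
    """Samples x OTUs non-negative integer count matrix with labels."""

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_samples, n_otus), int64

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D array")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64, copy=True)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def select_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        wanted = list(otu_ids)
        index = {o: k for k, o in enumerate(self.otu_ids)}
        missing = [o for o in wanted if o not in index]
        if missing:
            raise ValidationError(f"unknown OTU ids: {missing[:5]}")
        cols = [index[o] for o in wanted]
        return OtuTable(self.sample_ids, tuple(wanted), self.counts[:, cols])

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        wanted = list(sample_ids)
        index = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in wanted]
        return OtuTable(tuple(wanted), self.otu_ids, self.counts[rows, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.sample_ids),
                            columns=list(self.otu_ids))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (self.sample_ids == other.sample_ids
                and self.otu_ids == other.otu_ids
                and np.array_equal(self.counts, other.counts))


def write_otu_table(table: OtuTable, path, orientation: str = "otus_as_rows") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if orientation == "otus_as_rows":
            fh.write("otu_id\t" + "\t".join(table.sample_ids) + "\n")
            for j, otu in enumerate(table.otu_ids):
                fh.write(otu + "\t"
                         + "\t".join(str(int(c)) for c in table.counts[:, j])
                         + "\n")
        elif orientation == "samples_as_rows":
            fh.write("sample_id\t" + "\t".join(table.otu_ids) + "\n")
            for i, sample in enumerate(table.sample_ids):
                fh.write(sample + "\t"
                         + "\t".join(str(int(c)) for c in table.counts[i, :])
                         + "\n")
        else:
            raise ValidationError(f"unknown orientation {orientation!r}")


def read_otu_table(path, orientation: str = "otus_as_rows") -> OtuTable:
    """Parse an OTU count TSV; failures name the offending line/column."""
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty OTU table", path=path, line=1)
    header = lines[0].split("\t")
    col_labels = header[1:]
    if not col_labels:
        raise ParseError("header has no sample/OTU columns", path=path, line=1)
    row_labels: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, found {len(fields)}",
                path=path, line=lineno)
        row_labels.append(fields[0])
        row: list[int] = []
        for colno, tok in enumerate(fields[1:], start=2):
            try:
                val = int(tok)
            except ValueError:
                raise ParseError(f"non-integer count {tok!r}",
                                 path=path, line=lineno, column=colno) from None
            if val < 0:
                raise ParseError(f"negative count {val}",
                                 path=path, line=lineno, column=colno)
            row.append(val)
        rows.append(row)
    if not rows:
        raise ParseError("OTU table has no data rows", path=path, line=2)
    mat = np.array(rows, dtype=np.int64)
    try:
        if orientation == "otus_as_rows":
            return OtuTable(tuple(col_labels), tuple(row_labels), mat.T)
        return OtuTable(tuple(row_labels), tuple(col_labels), mat)
    except ValidationError as exc:
        raise ParseError(str(exc), path=path) from exc


# ---------------------------------------------------------------------------
# Distance matrix


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled square symmetric matrix with zero diagonal.

    ``signed=True`` relaxes non-negativity (null-deviation matrices).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    signed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(s) for s in self.labels))
        _check_unique(self.labels, "sample")
        vals = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValidationError(
                f"matrix shape {vals.shape} does not match {n} labels")
        if not np.allclose(vals, vals.T, atol=1e-9, equal_nan=True):
            raise ValidationError("matrix is not symmetric within 1e-9")
        diag = np.diagonal(vals)
        if not np.allclose(diag, 0.0, atol=1e-12):
            raise ValidationError("matrix diagonal is not zero")
        if not self.signed and np.nanmin(vals) < -1e-12:
            raise ValidationError(
                "negative entries in an unsigned distance matrix "
                "(pass signed=True for deviation matrices)")
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 0.0)
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Canonical lower-triangle vectorization (scipy squareform order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    @classmethod
    def from_condensed(cls, labels: Sequence[str], condensed: np.ndarray,
                       signed: bool = False) -> "DistanceMatrix":
        n = len(labels)
        vals = np.zeros((n, n), dtype=float)
        iu = np.triu_indices(n, k=1)
        condensed = np.asarray(condensed, dtype=float)
        if condensed.shape != (n * (n - 1) // 2,):
            raise ValidationError("condensed vector length does not match labels")
        vals[iu] = condensed
        vals = vals + vals.T
        return cls(tuple(labels), vals, signed=signed)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = {lab: k for k, lab in enumerate(self.labels)}
        try:
            order = [idx[lab] for lab in labels]
        except KeyError as exc:
            raise ValidationError(f"unknown label {exc.args[0]!r}") from None
        return DistanceMatrix(tuple(labels),
                              self.values[np.ix_(order, order)],
                              signed=self.signed)


def write_distance_matrix(m: DistanceMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if m.signed:
            fh.write("# signed\n")
        fh.write("label\t" + "\t".join(m.labels) + "\n")
        for i, lab in enumerate(m.labels):
            fh.write(lab + "\t"
                     + "\t".join(_FLOAT_FMT % v for v in m.values[i]) + "\n")


def read_distance_matrix(path, signed: bool | None = None) -> DistanceMatrix:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    offset = 0
    file_signed = False
    while offset < len(lines) and lines[offset].startswith("#"):
        if lines[offset].strip("# ").strip() == "signed":
            file_signed = True
        offset += 1
    if signed is None:
        signed = file_signed
    if offset >= len(lines):
        raise ParseError("empty distance matrix", path=path, line=1)
    header = lines[offset].split("\t")
    labels = header[1:]
    n = len(labels)
    rows: list[list[float]] = []
    row_labels: list[str] = []
    for lineno, line in enumerate(lines[offset + 1:], start=offset + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n + 1:
            raise ParseError(f"expected {n + 1} fields, found {len(fields)}",
                             path=path, line=lineno)
        row_labels.append(fields[0])
        try:
            rows.append([float(tok) for tok in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"non-numeric entry: {exc}", path=path,
                             line=lineno) from None
    if len(row_labels) != n:
        raise ParseError(
            f"matrix is not square: {n} columns vs {len(row_labels)} rows",
            path=path)
    if row_labels != labels:
        raise ParseError("row labels do not match column labels", path=path)
    vals = np.array(rows, dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-6, equal_nan=True):
        i, j = np.argwhere(np.abs(vals - vals.T) > 1e-6)[0]
        raise ParseError(
            f"asymmetry beyond 1e-6 between {labels[i]!r} and {labels[j]!r}",
            path=path)
    vals = (vals + vals.T) / 2.0
    try:
        return DistanceMatrix(tuple(labels), vals, signed=signed)
    except ValidationError as exc:
        raise ParseError(str(exc), path=path) from exc


# ---------------------------------------------------------------------------
# Guild annotation


@dataclass(frozen=True)
class GuildRecord:
    otu_id: str
    trophic_mode: str
    guild: str
    confidence: str

    def __post_init__(self) -> None:
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValidationError(
                f"unknown confidence {self.confidence!r} for OTU "
                f"{self.otu_id!r}; expected one of {CONFIDENCE_LEVELS}")


@dataclass(frozen=True)
class GuildAnnotation:
    """Per-OTU trophic mode / guild / confidence records, unique by OTU."""

    records: tuple[GuildRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        _check_unique([r.otu_id for r in self.records], "OTU")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, otu_id: str) -> GuildRecord | None:
        return self.by_otu().get(otu_id)

    def by_otu(self) -> dict[str, GuildRecord]:
        cached = getattr(self, "_by_otu", None)
        if cached is None:
            cached = {r.otu_id: r for r in self.records}
            object.__setattr__(self, "_by_otu", cached)
        return cached


_ANNOTATION_COLUMNS = ("otu_id", "trophic_mode", "guild", "confidence")


def write_annotation(annotation: GuildAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOTATION_COLUMNS) + "\n")
        for r in annotation:
            fh.write(f"{r.otu_id}\t{r.trophic_mode}\t{r.guild}\t{r.confidence}\n")


def read_annotation(path) -> GuildAnnotation:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty annotation file", path=path, line=1)
    header = tuple(lines[0].split("\t"))
    if header != _ANNOTATION_COLUMNS:
        raise ParseError(
            f"expected header {list(_ANNOTATION_COLUMNS)}, found {list(header)}",
            path=path, line=1)
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"expected 4 fields, found {len(fields)}",
                             path=path, line=lineno)
        try:
            records.append(GuildRecord(*fields))
        except ValidationError as exc:
            raise ParseError(str(exc), path=path, line=lineno) from exc
    try:
        return GuildAnnotation(tuple(records))
    except ValidationError as exc:
        raise ParseError(str(exc), path=path) from exc


# ---------------------------------------------------------------------------
# Metadata / plant community / traits (pandas-backed)

_METADATA_ID_COLUMNS = ("sample_id", "site_id", "quadrat_id", "depth_layer",
                        "latitude", "longitude", "vegetation_type")


def _validate_metadata(df: pd.DataFrame, path=None) -> pd.DataFrame:
    for col in _METADATA_ID_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"metadata missing required column {col!r}",
                             path=path)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample_id {dup!r}", path=path)
    bad_depth = set(df["depth_layer"]) - set(DEPTH_LAYERS)
    if bad_depth:
        raise ParseError(
            f"depth_layer values {sorted(bad_depth)} not in {DEPTH_LAYERS}",
            path=path)
    if (df["latitude"].abs() > 90).any():
        raise ParseError("latitude outside [-90, 90]", path=path)
    if (df["longitude"].abs() > 180).any():
        raise ParseError("longitude outside [-180, 180]", path=path)
    return df.set_index("sample_id", drop=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site_id": str,
                                            "quadrat_id": str})
    return _validate_metadata(df, path=path)


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_plant_community(path) -> pd.DataFrame:
    """Quadrat x species relative abundances; rows must sum to 1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    sums = df.sum(axis=1)
    bad = sums.index[np.abs(sums.values - 1.0) > 1e-6]
    if len(bad):
        raise ParseError(
            f"plant community rows do not sum to 1: {list(bad[:3])}", path=path)
    if (df.values < 0).any():
        raise ParseError("negative relative abundance", path=path)
    df.index.name = "quadrat_id"
    return df


def write_plant_community(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="quadrat_id", float_format=_FLOAT_FMT)


def read_trait_table(path) -> pd.DataFrame:
    """Long-format trait table indexed by (quadrat_id, species)."""
    df = pd.read_csv(path, sep="\t", dtype={"quadrat_id": str, "species": str},
                     na_values=["NA"], keep_default_na=False)
    for col in ("quadrat_id", "species"):
        if col not in df.columns:
            raise ParseError(f"trait table missing column {col!r}", path=path)
    if df.duplicated(subset=["quadrat_id", "species"]).any():
        raise ParseError("duplicate (quadrat_id, species) row", path=path)
    return df.set_index(["quadrat_id", "species"])


def write_trait_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Run configuration

DEFAULT_CONFIG: dict = {
    "inputs": None,
    "simulate": None,
    "out_dir": "run",
    "depth_layer": "both",
    "guilds": ["total", "mycorrhizal", "saprotrophic", "pathotrophic"],
    "n_null": 999,
    "n_perm": 999,
    "alpha": 0.05,
    "seed": 0,
    "rarefy_depth": "auto",
    "deviation_mode": "ses",
    "transforms": {
        "sqrt": ["SM", "SEC", "SAP", "NH4N", "NO3N"],
        "log10": ["LA", "SLA", "RL", "SRL", "RNC"],
    },
}

_REQUIRED_INPUT_PATHS = ("otu_table", "annotation", "metadata",
                         "plant_community", "trait_table")


def load_config(path) -> dict:
    """Load and validate a YAML run configuration, applying defaults.

    Unknown top-level keys are rejected with a closest-match suggestion;
    exactly one of ``inputs`` (paths) or ``simulate`` (scenario parameters)
    must be present.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = set(DEFAULT_CONFIG)
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {key!r}{suffix}")
    config = {**DEFAULT_CONFIG, **raw}
    config["transforms"] = {**DEFAULT_CONFIG["transforms"],
                            **(raw.get("transforms") or {})}
    if (config["inputs"] is None) == (config["simulate"] is None):
        raise ConfigError("exactly one of 'inputs' or 'simulate' must be set")
    if config["inputs"] is not None:
        missing = [k for k in _REQUIRED_INPUT_PATHS if k not in config["inputs"]]
        if missing:
            raise ConfigError(f"inputs missing required paths: {missing}")
    if config["depth_layer"] not in ("both",) + DEPTH_LAYERS:
        raise ConfigError(f"depth_layer must be one of "
                          f"{('both',) + DEPTH_LAYERS}")
    if not (isinstance(config["n_null"], int) and config["n_null"] >= 1):
        raise ConfigError("n_null must be a positive integer")
    if not (isinstance(config["n_perm"], int) and config["n_perm"] >= 1):
        raise ConfigError("n_perm must be a positive integer")
    if not (0 < config["alpha"] < 1):
        raise ConfigError("alpha must lie in (0, 1)")
    return config
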