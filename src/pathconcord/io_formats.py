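"""Readers and writers for the text formats the pipeline touches.

Supported formats: GMT (Broad dialect) for gene-set collections, GCT 1.2 and
plain TSV for expression matrices, CLS (categorical, two-class) and two-column
TSV for phenotype labels, and TSV/JSON for result tables. Expression values
are used exactly as given; no normalisation or log transform is applied. The
assumed scale can be recorded in the run summary for provenance but never
changes the numbers.
"""

from __future__ import annotations

import io
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("pathconcord")

__all__ = [
    "FormatError",
    "GeneSetCollection",
    "ExpressionDataset",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_gct",
    "read_phenotype",
    "write_cls",
    "read_symbol_map",
    "write_results",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) with unique names and deduplicated members.

    ``sets`` maps set name -> tuple of member symbols (original order, first
    occurrence kept); ``descriptions`` maps set name -> free-text description.
    """

    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                self.sets[name] = tuple(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ExpressionDataset:
    """Feature × sample expression matrix with a two-class phenotype.

    ``values`` is a DataFrame indexed by feature id (probe or gene symbol)
    with sample ids as columns. ``phenotype`` assigns each sample to one of
    exactly two classes; ``case`` and ``control`` designate the classes that
    are compared (disease/treatment vs control).
    """

    values: pd.DataFrame
    phenotype: pd.Series
    case: str
    control: str
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.phenotype.index)
        if missing:
            raise ValueError(f"samples without phenotype: {sorted(missing)}")
        self.phenotype = self.phenotype.loc[self.values.columns]
        classes = set(self.phenotype.unique())
        if classes != {self.case, self.control}:
            raise ValueError(
                f"phenotype classes {sorted(classes)} do not match "
                f"case={self.case!r}/control={self.control!r}"
            )
        for cls in (self.case, self.control):
            n = int((self.phenotype == cls).sum())
            if n < 2:
                raise ValueError(f"class {cls!r} has {n} samples; need >= 2")

    @property
    def case_samples(self) -> list[str]:
        return list(self.phenotype.index[self.phenotype == self.case])

    @property
    def control_samples(self) -> list[str]:
        return list(self.phenotype.index[self.phenotype == self.control])

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def _open_text(path):
    # accepts both LF and CRLF; UTF-8 only
    return open(path, "r", encoding="utf-8", newline=None)


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Duplicate member symbols within a line are collapsed (first kept); empty
    member fields from trailing tabs are ignored; symbol case is preserved.
    A line with fewer than three fields or a repeated set name is an error.
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line has {len(fields)} "
                    "fields; need name, description and >= 1 member"
                )
            name, desc = fields[0], fields[1]
            members = tuple(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise FormatError(
                    f"{path}: line {lineno}: gene set {name!r} has no members"
                )
            if name in sets:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate set name {name!r}"
                )
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names:
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *collection.members(name)]) + "\n")


def read_expression(path: str | os.PathLike, format: str = "gct") -> pd.DataFrame:
    """Read a feature × sample matrix from GCT 1.2 or plain TSV.

    GCT declared dimensions must match the parsed body. TSV is a header row
    of sample ids followed by one row per feature (first column = feature id).
    Non-numeric cells are an error naming the offending coordinates.
    """
    if format == "gct":
        return _read_gct(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return _check_numeric(df, path)
    raise ValueError(f"unknown expression format {format!r}")


def _read_gct(path) -> pd.DataFrame:
    with _open_text(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected GCT header '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        body = pd.read_csv(io.StringIO(fh.read()), sep="\t")
    if body.shape[0] != n_rows or body.shape[1] - 2 != n_cols:
        raise FormatError(
            f"{path}: GCT declares {n_rows} rows x {n_cols} samples but body "
            f"has {body.shape[0]} rows x {body.shape[1] - 2} samples"
        )
    df = body.set_index(body.columns[0]).drop(columns=[body.columns[1]])
    df.index.name = "NAME"
    return _check_numeric(df, path)


def _check_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise FormatError(
            f"{path}: non-numeric cell at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if out.isna().any().any():
        r, c = np.argwhere(out.isna().values)[0]
        raise FormatError(
            f"{path}: missing value at feature {out.index[r]!r}, "
            f"sample {out.columns[c]!r}"
        )
    return out.astype(float)


def write_gct(values: pd.DataFrame, path: str | os.PathLike,
              descriptions: pd.Series | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{values.shape[0]}\t{values.shape[1]}\n")
        body = values.copy()
        body.insert(0, "Description", descriptions if descriptions is not None else "na")
        body.index.name = "NAME"
        body.to_csv(fh, sep="\t")


def read_phenotype(path: str | os.PathLike, format: str = "cls") -> pd.Series:
    """Read per-sample class labels from CLS or two-column TSV.

    CLS must declare exactly two classes; returns a Series of labels. For CLS
    the index is positional (sample order of the companion matrix); for TSV
    the first column gives sample ids.
    """
    if format == "cls":
        return _read_cls(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"],
                         dtype=str)
        labels = pd.Series(df["label"].values, index=df["sample"].values)
        if labels.nunique() != 2:
            raise FormatError(
                f"{path}: need exactly 2 classes, got {labels.nunique()}"
            )
        return labels
    raise ValueError(f"unknown phenotype format {format!r}")


def _read_cls(path) -> pd.Series:
    with _open_text(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS needs 3 non-empty lines")
    head = lines[0].split()
    n_samples, n_classes = int(head[0]), int(head[1])
    if n_classes != 2:
        raise FormatError(
            f"{path}: {n_classes}-class designs unsupported; need exactly 2"
        )
    names = lines[1].split()
    if names[0] != "#":
        raise FormatError(f"{path}: CLS second line must start with '#'")
    class_names = names[1:]
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise FormatError(
            f"{path}: CLS declares {n_samples} samples, label line has {len(tokens)}"
        )
    # tokens may be class names or 0/1 indices
    if set(tokens) <= set(class_names):
        labels = tokens
    else:
        try:
            labels = [class_names[int(t)] for t in tokens]
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: unrecognised CLS labels") from exc
    return pd.Series(labels)


def write_cls(phenotype: pd.Series, case: str, control: str,
              path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(phenotype)} 2 1\n")
        fh.write(f"# {control} {case}\n")
        fh.write(" ".join(phenotype.values) + "\n")


def read_symbol_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV (source id, target symbol) into a mapping.

    A source id that maps to two different targets is an error; empty targets
    are errors. Repeated identical pairs are tolerated.
    """
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: need 2 columns")
            src, tgt = fields[0], fields[1]
            if not tgt:
                raise FormatError(f"{path}: line {lineno}: empty target symbol")
            if src in mapping and mapping[src] != tgt:
                raise FormatError(
                    f"{path}: line {lineno}: source {src!r} maps to both "
                    f"{mapping[src]!r} and {tgt!r}"
                )
            mapping[src] = tgt
    return mapping


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | os.PathLike,
                  summary: dict | None = None) -> list[str]:
    """Write result tables as TSV plus an optional JSON run summary.

    Each entry of ``tables`` becomes ``<out_dir>/<name>.tsv`` with a stable
    column order (as stored in the DataFrame). Floats are printed with
    repr-level precision so reruns with identical inputs are byte-identical.
    Returns the list of files written.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, table in tables.items():
        dest = os.path.join(out_dir, f"{name}.tsv")
        table.to_csv(dest, sep="\t", index=False, lineterminator="\n",
                     float_format="%.10g")
        written.append(dest)
    if summary is not None:
        dest = os.path.join(out_dir, "run_summary.json")
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        written.append(dest)
    return written
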