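"""Readers and writers for the on-disk formats the pipeline touches.

Abundance data travel as a plain TSV matrix (rows = isoforms, columns =
sample ids) plus a sample sheet (sample_id, stage, fraction, replicate).
Gene sets use standard GMT. All writers emit deterministic, diff-able TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Closed vocabulary of gradient pools: unfractionated total RNA, the
#: 40S-60S-80S (monosome) pool, and the polysome pool.
FRACTIONS = ("input", "monosome", "polysome")

SAMPLE_SHEET_COLUMNS = ("sample_id", "stage", "fraction", "replicate")

#: Fixed float rendering for result files, so identical inputs give
#: byte-identical outputs.
FLOAT_FORMAT = "%.10g"


@dataclass
class AbundanceMatrix:
    """Isoform x sample abundance table with per-sample design metadata.

    Parameters
    ----------
    values
        DataFrame of non-negative FPKM-like abundances; index = isoform ids,
        columns = sample ids.
    sample_meta
        DataFrame indexed by sample id with columns ``stage``, ``fraction``
        (one of :data:`FRACTIONS`) and ``replicate`` (positive int).

    Stage labels are free strings (e.g. ``"E13"``/``"E16"``); the first
    label encountered in the sample sheet plays role A (earlier stage) and
    the second role B (later stage), so "derepression" always means an
    A-to-B increase in polysome association.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        v, meta = self.values, self.sample_meta
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate isoform id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if not np.issubdtype(np.asarray(v.values).dtype, np.number):
            raise ValidationError("abundance matrix contains non-numeric values")
        if (np.asarray(v.values) < 0).any():
            iso = v.index[np.where(v.values < 0)[0][0]]
            raise ValidationError(f"negative abundance for isoform {iso!r}")
        missing = [c for c in ("stage", "fraction", "replicate") if c not in meta.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if meta.index.duplicated().any():
            dup = meta.index[meta.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id in sample sheet: {dup!r}")
        extra = set(v.columns) ^ set(meta.index)
        if extra:
            raise ValidationError(
                f"sample ids differ between matrix and sheet: {sorted(extra)}"
            )
        bad = meta.index[~meta["fraction"].isin(FRACTIONS)]
        if len(bad):
            frac = meta.loc[bad[0], "fraction"]
            raise ValidationError(
                f"sample {bad[0]!r} has unknown fraction {frac!r}; "
                f"expected one of {FRACTIONS}"
            )
        if meta["stage"].isna().any() or (meta["stage"].astype(str) == "").any():
            raise ValidationError("every sample needs a non-empty stage label")
        reps = pd.to_numeric(meta["replicate"], errors="coerce")
        if reps.isna().any() or (reps < 1).any():
            bad_id = meta.index[reps.isna() | (reps < 1)][0]
            raise ValidationError(f"sample {bad_id!r} has invalid replicate index")

    # -- convenience ----------------------------------------------------
    @property
    def isoform_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def stages(self) -> tuple[str, str]:
        """Ordered (stage A, stage B) labels, by first appearance in the sheet."""
        seen: list[str] = []
        for s in self.sample_meta["stage"]:
            if s not in seen:
                seen.append(s)
        if len(seen) != 2:
            raise ValidationError(
                f"expected exactly 2 stages, found {len(seen)}: {seen}"
            )
        return seen[0], seen[1]

    def samples_for(self, stage: str, fraction: str) -> list[str]:
        meta = self.sample_meta
        mask = (meta["stage"] == stage) & (meta["fraction"] == fraction)
        return list(meta.index[mask])

    def fraction_values(self, fraction: str, stage: str) -> pd.DataFrame:
        """Isoform x replicate slice for one (stage, fraction) cell."""
        cols = self.samples_for(stage, fraction)
        return self.values[cols]


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional background universe.

    Members are opaque, case-sensitive strings; no identifier conversion
    is attempted.
    """

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if any((not isinstance(m, str)) or m == "" for m in members):
                raise ValidationError(f"gene set {name!r} has empty/non-string members")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers


def read_abundance(matrix_path: str | Path, sample_sheet_path: str | Path) -> AbundanceMatrix:
    """Read an abundance TSV and its sample sheet into a validated matrix.

    Row and column order are preserved from file. Raises
    :class:`~polystate.errors.ValidationError` naming the offending record
    on any inconsistency.
    """
    matrix_path, sample_sheet_path = Path(matrix_path), Path(sample_sheet_path)
    for p in (matrix_path, sample_sheet_path):
        if not p.exists():
            raise ValidationError(f"file not found: {p}")
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values = values.astype(float)
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    meta = sheet.set_index("sample_id")
    return AbundanceMatrix(values=values, sample_meta=meta)


def write_abundance(matrix: AbundanceMatrix, matrix_path: str | Path,
                    sample_sheet_path: str | Path) -> None:
    """Write the matrix TSV and sample sheet; round-trips with read_abundance."""
    # %.17g round-trips IEEE doubles exactly
    matrix.values.to_csv(matrix_path, sep="\t", index_label="isoform_id",
                         float_format="%.17g")
    sheet = matrix.sample_meta.reset_index()
    sheet.columns = list(SAMPLE_SHEET_COLUMNS)
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Duplicate members within a line are collapsed (sets); the description
    column is ignored for membership. An empty file yields an empty
    collection. A line with fewer than 3 fields is a parse error reported
    with its line number.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in fields[2:] if m != "")
            sets[name] = members
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            members = sorted(collection[name])
            fh.write("\t".join([name, description, *members]) + "\n")


def read_universe(path: str | Path) -> frozenset[str]:
    """Read a background universe file: one gene id per line."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return frozenset(ids)


def read_fraction_profiles(path: str | Path) -> pd.DataFrame:
    """Read a fraction-profile TSV: columns condition, replicate, F, M, LP, HP."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    required = ["condition", "replicate", "F", "M", "LP", "HP"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"profile table missing columns: {missing}")
    return df[required]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table: columns condition, ct_target, ct_reference."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    required = ["condition", "ct_target", "ct_reference"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# result writers


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False,
                index_label: str | None = None) -> Path:
    """Write one result table as TSV with a header and fixed float precision."""
    path = Path(path)
    os.makedirs(path.parent, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format=FLOAT_FORMAT)
    return path


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write each named table to ``<out_dir>/<name>.tsv``; returns the paths.

    Column and row order are taken from each table as given, so reruns on
    identical inputs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        paths[name] = write_table(df, out_dir / f"{name}.tsv")
    return paths


def read_id_list(path: str | Path) -> list[str]:
    """One id per line; order preserved, duplicates kept for the caller."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
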