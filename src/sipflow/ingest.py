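"""Reading, validation and bundling of count matrices and sample metadata.

A dataset is a gene-by-sample matrix of non-negative integer counts plus a
sample table describing mating type, time point, condition and replicate.
Counts and metadata travel together as an :class:`ExperimentBundle` whose
columns are guaranteed to be aligned with the metadata rows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix


class ValidationError(ValueError):
    """Input violates a structural contract (ids, signs, integrality)."""


class SchemaError(ValueError):
    """A required column or file component is missing."""


class AlignmentError(ValueError):
    """Count columns and metadata rows cannot be reconciled."""


#: Labels accepted for the two experimental conditions. The treated arm is
#: the pheromone (SIP) exposure; assays label it differently.
CONDITION_ALIASES: dict[str, str] = {
    "control": "control",
    "ctrl": "control",
    "mock": "control",
    "untreated": "control",
    "treated": "treated",
    "sip": "treated",
    "sip-": "treated",
    "sip+": "treated",
    "pheromone": "treated",
}

REQUIRED_SAMPLE_COLUMNS = (
    "sample_id",
    "dataset",
    "mating_type",
    "timepoint",
    "condition",
    "replicate",
)

MATING_TYPES = ("MTplus", "MTminus")

_TIME_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(min|m|h|hr|hours?)?\s*$", re.I)


def parse_timepoint(label: object) -> int:
    """Convert a time-point label such as ``"15min"`` or ``"3h"`` to minutes.

    Bare numbers are taken to already be minutes.
    """
    if isinstance(label, (int, np.integer)):
        return int(label)
    if isinstance(label, float):
        if not float(label).is_integer():
            raise ValidationError(f"non-integer timepoint in minutes: {label!r}")
        return int(label)
    m = _TIME_RE.match(str(label))
    if m is None:
        raise ValidationError(f"cannot parse timepoint label {label!r}")
    value, unit = float(m.group(1)), (m.group(2) or "min").lower()
    minutes = value * 60.0 if unit.startswith("h") else value
    if not minutes.is_integer():
        raise ValidationError(f"timepoint {label!r} is not a whole minute")
    return int(minutes)


@dataclass
class CountMatrix:
    """Genes-by-samples matrix of non-negative integer counts.

    ``counts`` is a DataFrame indexed by gene id with sample ids as columns.
    Invariants (unique ids, integral non-negative entries, at least one gene
    and two samples) are enforced at construction.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise ValidationError(
                f"need >=1 gene and >=2 samples, got {df.shape[0]}x{df.shape[1]}"
            )
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            g, s = np.argwhere((arr < 0) | (arr != np.floor(arr)))[0]
            raise ValidationError(
                f"negative or non-integer count for gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}: {arr[g, s]}"
            )
        self.counts = df.astype(np.int64)
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()


def read_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from TSV (dense) or MatrixMarket (sparse).

    The canonical TSV dialect has gene ids in a first column named
    ``gene_id`` and one column per sample. MTX input expects sibling files
    ``<stem>.rows.txt`` / ``<stem>.cols.txt`` carrying gene and sample ids.
    """
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.ParserError as exc:  # ragged rows etc.
            raise SchemaError(f"cannot parse {path}: {exc}") from exc
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return CountMatrix(df)
    if format == "mtx":
        rows = Path(str(path.with_suffix("")) + ".rows.txt")
        cols = Path(str(path.with_suffix("")) + ".cols.txt")
        if not rows.exists() or not cols.exists():
            raise SchemaError(f"MTX input requires {rows.name} and {cols.name}")
        mat = np.asarray(mmread(path).todense())
        gene_ids = rows.read_text().split()
        sample_ids = cols.read_text().split()
        if mat.shape != (len(gene_ids), len(sample_ids)):
            raise ValidationError(
                f"MTX shape {mat.shape} does not match id files "
                f"({len(gene_ids)} genes, {len(sample_ids)} samples)"
            )
        return CountMatrix(pd.DataFrame(mat, index=gene_ids, columns=sample_ids))
    raise ValueError(f"unknown format {format!r}")


def write_counts(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a count matrix in the canonical TSV dialect or as MTX."""
    path = Path(path)
    if format == "tsv":
        out = cm.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
    elif format == "mtx":
        sparse = coo_matrix(cm.values)
        mmwrite(str(path), sparse)
        stem = str(path.with_suffix(""))
        Path(stem + ".rows.txt").write_text("\n".join(cm.gene_ids) + "\n")
        Path(stem + ".cols.txt").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def _normalize_condition(label: object, aliases: dict[str, str]) -> str:
    key = str(label).strip().lower()
    if key not in aliases:
        raise ValidationError(f"unknown condition label {label!r}")
    return aliases[key]


def make_sample_table(df: pd.DataFrame,
                      aliases: dict[str, str] | None = None) -> pd.DataFrame:
    """Validate a raw metadata frame into a canonical sample table.

    Adds ``timepoint_min`` (minutes, the internal encoding) and normalizes
    condition labels through the alias map. Original row order is kept; only
    the categorical ordering of timepoints is by time value.
    """
    aliases = {**CONDITION_ALIASES, **(aliases or {})}
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample table missing columns: {missing}")
    out = df.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    if out["sample_id"].duplicated().any():
        dups = out.loc[out["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    bad_mt = set(out["mating_type"].astype(str)) - set(MATING_TYPES)
    if bad_mt:
        raise ValidationError(
            f"unknown mating_type values {sorted(bad_mt)}; expected {MATING_TYPES}"
        )
    out["condition"] = [_normalize_condition(c, aliases) for c in out["condition"]]
    out["timepoint_min"] = [parse_timepoint(t) for t in out["timepoint"]]
    levels = sorted(out["timepoint_min"].unique())
    out["timepoint_min"] = pd.Categorical(out["timepoint_min"], categories=levels,
                                          ordered=True)
    out["replicate"] = out["replicate"].astype(int)
    if "experiment_batch" not in out.columns:
        out["experiment_batch"] = out["dataset"].astype(str)
    return out.reset_index(drop=True)


def read_samples(path: str | Path,
                 aliases: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a sample metadata TSV."""
    df = pd.read_csv(path, sep="\t")
    return make_sample_table(df, aliases=aliases)


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in samples.columns if c != "timepoint_min"]
    samples[cols].to_csv(path, sep="\t", index=False)


@dataclass
class ExperimentBundle:
    """One dataset's counts and metadata with columns aligned to rows."""

    counts: CountMatrix
    samples: pd.DataFrame
    aligned: bool = field(default=False)

    @property
    def n_genes(self) -> int:
        return self.counts.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.counts.shape[1]

    def groups(self) -> pd.Series:
        """(timepoint_min, condition) cell label per sample."""
        s = self.samples
        return pd.Series(
            [f"t{int(t)}_{c}" for t, c in zip(s["timepoint_min"], s["condition"])],
            index=s["sample_id"].to_numpy(), name="cell",
        )


def bundle(counts: CountMatrix, samples: pd.DataFrame) -> ExperimentBundle:
    """Align count columns to metadata rows and assert the ids match.

    Columns are reordered to the metadata row order; any asymmetric id is an
    error. Bundling an already aligned bundle's parts is a no-op.
    """
    count_ids = set(counts.sample_ids)
    meta_ids = set(samples["sample_id"])
    if count_ids != meta_ids:
        only_counts = sorted(count_ids - meta_ids)
        only_meta = sorted(meta_ids - count_ids)
        raise AlignmentError(
            f"sample id mismatch: only in counts {only_counts[:5]}, "
            f"only in metadata {only_meta[:5]}"
        )
    ordered = counts.counts.loc[:, list(samples["sample_id"])]
    cells = samples.groupby(["timepoint_min", "condition"], observed=True).size()
    n_two_sided = (
        samples.groupby("timepoint_min", observed=True)["condition"].nunique() >= 2
    ).sum()
    if n_two_sided < 1:
        raise ValidationError(
            "need at least one timepoint with both conditions; cells found: "
            f"{list(cells.index)}"
        )
    return ExperimentBundle(CountMatrix(ordered), samples.reset_index(drop=True),
                            aligned=True)
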