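"""Readers and writers for the pipeline's on-disk artifacts.

All tabular artifacts are UTF-8 TSV with '.' as the decimal separator,
matching GEO series-matrix-derived exports and the B3DB distribution.
Result tables are written with leading ``#`` comment lines recording the
tool version and the parameters that produced them, so every number in a
run directory is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

VALID_GROUPS = frozenset({"control", "case"})

#: number of significant digits used when writing floats; chosen so that a
#: write -> read round trip is an identity for all practical purposes.
FLOAT_FORMAT = "%.12g"


class ValidationError(ValueError):
    """Raised when an on-disk artifact violates its contract."""


@dataclass
class ExpressionDataset:
    """One cohort: a genes x samples matrix plus a per-sample manifest.

    Parameters
    ----------
    dataset_id : str
        Identifier of the cohort (doubles as the batch label downstream).
    matrix : pandas.DataFrame
        Expression values, rows indexed by unique gene symbol, columns by
        sample id. Log-intensity scale is assumed but not enforced.
    manifest : pandas.DataFrame
        Columns ``sample_id``, ``group`` (control/case) and ``batch``.
    """

    dataset_id: str
    matrix: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        self.manifest = self.manifest.reset_index(drop=True)
        required = {"sample_id", "group", "batch"}
        missing = required - set(self.manifest.columns)
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        bad_groups = set(self.manifest["group"]) - VALID_GROUPS
        if bad_groups:
            raise ValidationError(
                f"unknown group labels {sorted(bad_groups)}; expected one of "
                f"{sorted(VALID_GROUPS)}"
            )
        mat_cols = list(self.matrix.columns)
        man_ids = list(self.manifest["sample_id"])
        if set(mat_cols) != set(man_ids) or len(mat_cols) != len(man_ids):
            only_mat = sorted(set(mat_cols) - set(man_ids))
            only_man = sorted(set(man_ids) - set(mat_cols))
            raise ValidationError(
                "manifest and matrix samples disagree: "
                f"matrix-only={only_mat}, manifest-only={only_man}"
            )
        if self.matrix.index.has_duplicates:
            raise ValidationError("gene ids not unique")
        if self.matrix.isna().any().any():
            raise ValidationError("matrix contains missing values")
        counts = self.manifest["group"].value_counts()
        for grp in sorted(VALID_GROUPS):
            if counts.get(grp, 0) < 2:
                raise ValidationError(f"group '{grp}' has fewer than 2 samples")
        # canonical sample order: manifest order
        self.matrix = self.matrix.loc[:, man_ids]

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.manifest["sample_id"])

    def group_samples(self, group: str) -> list[str]:
        return list(self.manifest.loc[self.manifest["group"] == group, "sample_id"])

    def equals(self, other: "ExpressionDataset") -> bool:
        if self.dataset_id != other.dataset_id:
            return False
        a = self.matrix.sort_index().sort_index(axis=1)
        b = other.matrix.sort_index().sort_index(axis=1)
        ma = self.manifest.sort_values("sample_id").reset_index(drop=True)
        mb = other.manifest.sort_values("sample_id").reset_index(drop=True)
        return a.round(9).equals(b.round(9)) and ma.equals(mb)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), order preserving."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set '{name}' is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class BBBTable:
    """Compound -> blood-brain-barrier permeability label.

    Names are case-folded and whitespace-trimmed; labels are normalized to
    ``permeable`` / ``non_permeable``.
    """

    labels: dict[str, str] = field(default_factory=dict)

    def lookup(self, name: str) -> str:
        return self.labels.get(_norm_name(name), "unknown")

    def __len__(self) -> int:
        return len(self.labels)


def _norm_name(name: str) -> str:
    return name.strip().casefold()


_BBB_LABEL_MAP = {
    "bbb+": "permeable",
    "bbb-": "non_permeable",
    "permeable": "permeable",
    "non_permeable": "non_permeable",
}


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path_matrix, path_manifest, dataset_id: str) -> ExpressionDataset:
    """Load one cohort from a matrix TSV and a manifest TSV.

    The matrix has gene ids in the first column and sample ids in the
    header. Rows containing any missing value are dropped (with a logged
    count); duplicated gene ids are collapsed by row mean.
    """
    matrix = pd.read_csv(path_matrix, sep="\t", index_col=0, comment="#")
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "gene"
    n_before = len(matrix)
    matrix = matrix.dropna(axis=0, how="any")
    dropped = n_before - len(matrix)
    if dropped:
        logger.info("%s: dropped %d gene rows with missing values", dataset_id, dropped)
    if matrix.index.has_duplicates:
        n_dup = matrix.index.duplicated().sum()
        logger.info("%s: collapsed %d duplicate gene rows by mean", dataset_id, n_dup)
        matrix = matrix.groupby(level=0, sort=False).mean()
    manifest = pd.read_csv(path_manifest, sep="\t", comment="#", dtype=str)
    return ExpressionDataset(dataset_id=dataset_id, matrix=matrix, manifest=manifest)


def write_expression(ds: ExpressionDataset, path_matrix, path_manifest) -> None:
    ds.matrix.to_csv(path_matrix, sep="\t", float_format=FLOAT_FORMAT)
    ds.manifest.to_csv(path_manifest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file: name <tab> description <tab> gene ...."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}: duplicate set name '{name}'")
            sets[name] = [g for g in fields[2:] if g]
    if not sets:
        raise ValidationError(f"{path}: no gene sets")
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection:
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# B3DB-dialect BBB tables
# ---------------------------------------------------------------------------

def read_bbb_table(path, label_column: str | None = None) -> BBBTable:
    """Read a B3DB-dialect TSV with ``compound_name`` and a BBB+/BBB- column."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "compound_name" not in df.columns:
        raise ValidationError(f"{path}: missing 'compound_name' column")
    if label_column is None:
        candidates = [c for c in df.columns if c.lower() in ("bbb", "bbb+/bbb-", "bbb_label")]
        if not candidates:
            raise ValidationError(f"{path}: no BBB label column found")
        label_column = candidates[0]
    labels: dict[str, str] = {}
    for _, row in df.iterrows():
        name = _norm_name(str(row["compound_name"]))
        raw = str(row[label_column]).strip().casefold()
        if raw not in _BBB_LABEL_MAP:
            raise ValidationError(f"{path}: unmappable BBB label value '{row[label_column]}'")
        label = _BBB_LABEL_MAP[raw]
        if name in labels and labels[name] != label:
            raise ValidationError(f"{path}: conflicting BBB labels for '{name}'")
        labels[name] = label
    return BBBTable(labels=labels)


def write_bbb_table(table: BBBTable, path) -> None:
    rev = {"permeable": "BBB+", "non_permeable": "BBB-"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound_name\tBBB+/BBB-\n")
        for name in sorted(table.labels):
            fh.write(f"{name}\t{rev[table.labels[name]]}\n")


# ---------------------------------------------------------------------------
# drug signature libraries (long-format TSV)
# ---------------------------------------------------------------------------

def read_drug_library(path):
    """Read a long-format drug library TSV.

    Columns: ``drug``, ``replicate_id``, ``fda_approved`` then one column
    per gene carrying the replicate z-score.
    """
    from .drugsig import DrugSignatureLibrary  # local import to avoid cycle

    df = pd.read_csv(path, sep="\t", comment="#")
    meta_cols = ["drug", "replicate_id", "fda_approved"]
    for c in meta_cols:
        if c not in df.columns:
            raise ValidationError(f"{path}: missing column '{c}'")
    gene_cols = [c for c in df.columns if c not in meta_cols]
    universe = pd.Index(gene_cols, name="gene")
    replicates: dict[str, list] = {}
    fda: dict[str, bool] = {}
    for drug, sub in df.groupby("drug", sort=False):
        replicates[str(drug)] = sub[gene_cols].to_numpy(dtype=float)
        flags = set(sub["fda_approved"].astype(bool))
        if len(flags) > 1:
            raise ValidationError(f"{path}: inconsistent fda_approved flags for '{drug}'")
        fda[str(drug)] = flags.pop()
    return DrugSignatureLibrary(universe=universe, replicates=replicates, fda_approved=fda)


def write_drug_library(library, path) -> None:
    rows = []
    for drug in library.drug_names:
        reps = library.replicates[drug]
        for i in range(reps.shape[0]):
            rows.append(
                {
                    "drug": drug,
                    "replicate_id": f"{drug}_r{i + 1}",
                    "fda_approved": library.fda_approved[drug],
                    **dict(zip(library.universe, reps[i])),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# result tables with provenance headers
# ---------------------------------------------------------------------------

def write_result_table(df: pd.DataFrame, path, params: Mapping | None = None,
                       index: bool = False) -> None:
    """Write a result TSV with ``#`` header comments carrying provenance."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# metareverse {__version__}\n")
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_result_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
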