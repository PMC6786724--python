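"""Tabular containers and I/O for genus-level microbiome abundance data.

The common currency of the package is the :class:`GenusAbundanceTable`: a
samples × genera matrix of relative abundances (fractions summing to 1 per
sample). Upstream of it sits the :class:`FeatureTable` (ASV/OTU-level counts
or relative abundances plus a taxonomy lineage per feature), which is
converted with :func:`to_relative_abundance` and :func:`collapse_to_genus`.

All tables read and write plain UTF-8 TSV with a header row; the first
column is ``sample_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenusAbundanceTable",
    "FeatureTable",
    "SampleMetadata",
    "UNCLASSIFIED",
    "read_abundance_table",
    "read_feature_table",
    "read_metadata",
    "to_relative_abundance",
    "collapse_to_genus",
    "parse_genus",
    "normalize_genus_name",
]

#: Reserved genus column receiving features with no usable genus assignment.
UNCLASSIFIED = "unclassified"

#: Row-sum tolerance for relative-abundance validation. Survives upstream
#: rounding without silently rescaling genuinely unnormalized data.
ROW_SUM_TOL = 1e-6

#: Genus tokens treated as "no assignment" after stripping the rank prefix.
_AMBIGUOUS_GENERA = {"", "uncultured", "unclassified", "unknown", "ambiguous_taxa"}


class TableValidationError(ValueError):
    """Raised when a table violates its structural invariants."""


def normalize_genus_name(name: str) -> str:
    """Strip whitespace and a leading ``g__`` rank prefix from a genus label."""
    name = name.strip()
    if name.startswith("g__"):
        name = name[3:]
    return name


def parse_genus(lineage: str) -> str:
    """Extract the genus from a semicolon-delimited taxonomy lineage.

    Accepts both the GreenGenes dialect (``k__...;p__...;...;g__Genus;s__``)
    and plain rank-ordered lineages (genus = 6th field). Returns the
    :data:`UNCLASSIFIED` sentinel when no usable genus is present.
    """
    ranks = [r.strip() for r in lineage.split(";")]
    genus = None
    for rank in ranks:
        if rank.startswith("g__"):
            genus = rank
            break
    if genus is None:
        # plain lineage: kingdom;phylum;class;order;family;genus[;species]
        if len(ranks) >= 6:
            genus = ranks[5]
        else:
            return UNCLASSIFIED
    genus = normalize_genus_name(genus)
    if genus.lower() in _AMBIGUOUS_GENERA:
        return UNCLASSIFIED
    return genus


def _check_unique(values, what: str) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()]
    if len(dup):
        raise TableValidationError(f"duplicate {what}: {sorted(set(dup))}")


@dataclass
class GenusAbundanceTable:
    """Samples × genera relative-abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with genus names as columns. All
        values are fractions ≥ 0 and each row sums to 1 within ``1e-6``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "genus names")
        if (self.data.values < 0).any():
            bad = self.data.stack()
            bad = bad[bad < 0].index[0]
            raise TableValidationError(
                f"negative abundance at sample {bad[0]!r}, genus {bad[1]!r}"
            )
        sums = self.data.sum(axis=1)
        off = sums[(sums - 1.0).abs() > ROW_SUM_TOL]
        if len(off):
            raise TableValidationError(
                "rows do not sum to 1 (pass normalize=True to renormalize): "
                f"{dict(off.head().round(6))}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def genus_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids) -> "GenusAbundanceTable":
        return GenusAbundanceTable(self.data.loc[list(sample_ids)].copy())

    def write_tsv(self, path) -> None:
        write_table_tsv(self.data, path)

    @classmethod
    def read_tsv(cls, path, normalize: bool = False) -> "GenusAbundanceTable":
        return read_abundance_table(path, normalize=normalize)


@dataclass
class FeatureTable:
    """ASV/OTU-level table with a taxonomy lineage per feature.

    ``kind`` is ``"counts"`` (non-negative integers) or ``"relative"``.
    Every feature id must have a taxonomy entry, though the genus field may
    be unassigned.
    """

    data: pd.DataFrame
    taxonomy: pd.Series
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise TableValidationError(f"unknown table kind {self.kind!r}")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.taxonomy = self.taxonomy.astype(str)
        self.taxonomy.index = self.taxonomy.index.astype(str)
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "feature ids")
        missing = [f for f in self.data.columns if f not in self.taxonomy.index]
        if missing:
            raise TableValidationError(f"features without taxonomy entry: {missing[:5]}")
        if (self.data.values < 0).any():
            raise TableValidationError("negative values in feature table")
        if self.kind == "counts":
            vals = self.data.to_numpy()
            if not np.allclose(vals, np.round(vals)):
                raise TableValidationError("count table contains non-integer values")


@dataclass
class SampleMetadata:
    """Per-sample roles, study labels, response outcomes and donor links.

    Columns: ``role`` (donor/patient), ``study``, ``response`` (response /
    no_response / NA), ``linked_donor`` (sample id of the donor material a
    patient received, NA for donors).
    """

    data: pd.DataFrame

    ROLES = ("donor", "patient")
    RESPONSES = ("response", "no_response")

    def __post_init__(self) -> None:
        self.data.index = self.data.index.astype(str)
        _check_unique(self.data.index, "sample ids")
        for col in ("role", "study", "response", "linked_donor"):
            if col not in self.data.columns:
                raise TableValidationError(f"metadata missing column {col!r}")
        bad_role = set(self.data["role"]) - set(self.ROLES)
        if bad_role:
            raise TableValidationError(f"unknown roles: {sorted(bad_role)}")
        resp = self.data["response"].dropna()
        bad_resp = set(resp) - set(self.RESPONSES)
        if bad_resp:
            raise TableValidationError(f"unknown response labels: {sorted(bad_resp)}")
        links = self.data["linked_donor"].dropna()
        donors = set(self.data.index[self.data["role"] == "donor"])
        orphan = set(links) - donors
        if orphan:
            raise TableValidationError(
                f"linked_donor ids not present as donor samples: {sorted(orphan)[:5]}"
            )

    @property
    def donors(self) -> list[str]:
        return list(self.data.index[self.data["role"] == "donor"])

    @property
    def patients(self) -> list[str]:
        return list(self.data.index[self.data["role"] == "patient"])

    def write_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def read_tsv(cls, path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str,
                         na_values=["NA"], keep_default_na=False)
        return cls(df)


# ---------------------------------------------------------------------------
# readers / writers


def _read_numeric_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0]
            raise TableValidationError(
                f"malformed numeric cell at row {row!r}, column {col!r}: {bad.iloc[0]!r}"
            ) from None
    return out


def write_table_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    # 17 significant digits round-trips doubles exactly
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_abundance_table(path, normalize: bool = False) -> GenusAbundanceTable:
    """Read a genus relative-abundance TSV (first column ``sample_id``).

    With ``normalize=True`` rows are rescaled to sum to 1; otherwise rows
    that do not already sum to 1 (tolerance 1e-6) raise a validation error.
    All-zero rows are always rejected.
    """
    df = _read_numeric_tsv(path)
    if (df.values < 0).any():
        # let the table's own validation produce the precise message
        return GenusAbundanceTable(df)
    sums = df.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise TableValidationError(f"all-zero sample rows: {list(zero.index)[:5]}")
    if normalize:
        df = df.div(sums, axis=0)
    return GenusAbundanceTable(df)


def read_feature_table(table_path, taxonomy_path, kind: str = "counts") -> FeatureTable:
    """Read a feature TSV plus a two-column taxonomy TSV (feature_id, lineage)."""
    df = _read_numeric_tsv(table_path)
    tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str).iloc[:, 0]
    return FeatureTable(df, tax, kind=kind)


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata.read_tsv(path)


# ---------------------------------------------------------------------------
# transforms


def to_relative_abundance(table: FeatureTable) -> FeatureTable:
    """Divide each sample row by its total reads.

    Raises for samples with zero total reads (relative abundance undefined).
    Idempotent on already-normalized relative tables.
    """
    sums = table.data.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise TableValidationError(
            f"samples with zero total reads: {list(zero.index)[:5]}"
        )
    rel = table.data.div(sums, axis=0)
    return FeatureTable(rel, table.taxonomy, kind="relative")


def collapse_to_genus(table: FeatureTable) -> GenusAbundanceTable:
    """Sum feature-level relative abundances into one column per genus.

    Features whose lineage has no usable genus pool into the reserved
    ``unclassified`` column. Per-sample total abundance is conserved.
    """
    if table.kind != "relative":
        raise TableValidationError(
            "collapse_to_genus requires a relative-abundance table; "
            "apply to_relative_abundance first"
        )
    genera = table.taxonomy.loc[table.data.columns].map(parse_genus)
    collapsed = table.data.T.groupby(genera.values).sum().T
    # stable, reproducible column order: named genera sorted, unclassified last
    cols = sorted(c for c in collapsed.columns if c != UNCLASSIFIED)
    if UNCLASSIFIED in collapsed.columns:
        cols.append(UNCLASSIFIED)
    return GenusAbundanceTable(collapsed[cols])
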