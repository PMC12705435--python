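"""Readers, writers and validation for the formats the pipeline touches.

The expression input is the 10x-style MatrixMarket triplet (matrix.mtx +
features/barcodes files) plus two CSV tables: per-cell annotations
(barcode, donor_id, celltype_major, celltype_minor) and per-donor metadata
(donor_id, age, subtype).  Gene sets come in the MSigDB GMT dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

CELL_COLUMNS = ["barcode", "donor_id", "celltype_major", "celltype_minor"]
DONOR_COLUMNS = ["donor_id", "age", "subtype"]


class FormatError(ValueError):
    """A structured problem with an input file (dimension mismatch, bad line...)."""


_HEADER_TOKENS = {
    "gene", "genes", "gene_id", "gene_ids", "feature", "features", "symbol",
    "name", "id", "barcode", "barcodes", "cell", "cells",
}


def _read_id_column(path: str | Path, n_expected: int | None = None) -> list[str]:
    """Read the first tab-separated column of a features/barcodes file.

    Files circulate with or without a header line; the first line is
    dropped only when the file is one line longer than the matrix dimension
    and that line is a recognizable header token — a plain length mismatch
    stays an error.
    """
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if (
        n_expected is not None
        and len(ids) == n_expected + 1
        and ids
        and ids[0].strip().lower() in _HEADER_TOKENS
    ):
        ids = ids[1:]
    return ids


def disambiguate(names: list[str]) -> list[str]:
    """Suffix repeated identifiers with an occurrence index: ACTB, ACTB.1, ACTB.2."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        k = seen.get(name, 0)
        out.append(name if k == 0 else f"{name}.{k}")
        seen[name] = k + 1
    return out


def read_matrix_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read a genes x cells MatrixMarket triplet.

    Returns the sparse matrix in its on-disk orientation (genes as rows)
    together with disambiguated gene identifiers and cell barcodes.
    """
    mat = scipy.io.mmread(str(matrix_path))
    mat = sp.csr_matrix(mat)
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{matrix_path}: negative entries in count matrix")
    genes = _read_id_column(features_path, n_expected=mat.shape[0])
    barcodes = _read_id_column(barcodes_path, n_expected=mat.shape[1])
    if len(genes) != mat.shape[0]:
        raise FormatError(
            f"{features_path}: {len(genes)} features but matrix has {mat.shape[0]} rows"
        )
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix has "
            f"{mat.shape[1]} columns"
        )
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"{barcodes_path}: duplicate cell barcodes")
    return mat, disambiguate(genes), barcodes


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the 50 MSigDB Hallmark pathways)."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path, provenance: str = "") -> GeneSetCollection:
    """Parse a GMT file: tab-separated name, description, members...

    Duplicate members within a set are dropped (order preserved); duplicate
    set names and empty member lists are rejected.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets, provenance=provenance)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            fh.write("\t".join([name, collection.provenance or "na", *members]) + "\n")


@dataclass
class ExpressionDataset:
    """Annotated single-cell counts with donor ages.

    ``adata`` holds cells x genes counts in ``X`` (raw) and, after
    :func:`lognormalize`, a ``"lognorm"`` layer; ``adata.obs`` carries
    donor_id / celltype_major / celltype_minor per barcode.  ``donors`` is
    indexed by donor_id with ``age`` (years) and ``subtype`` columns.
    """

    adata: AnnData
    donors: pd.DataFrame

    @classmethod
    def from_parts(
        cls,
        counts: sp.spmatrix,
        gene_ids: list[str],
        barcodes: list[str],
        cells: pd.DataFrame,
        donors: pd.DataFrame,
    ) -> "ExpressionDataset":
        """Assemble from a genes x cells matrix and the two annotation tables."""
        cells = cells.copy()
        if "barcode" in cells.columns:
            cells = cells.set_index("barcode")
        cells.index = cells.index.astype(str)
        cells = cells.reindex(barcodes)
        donors = donors.copy()
        if "donor_id" in donors.columns:
            donors = donors.set_index("donor_id")
        adata = AnnData(
            X=sp.csr_matrix(counts.T),
            obs=cells,
            var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
        )
        return cls(adata=adata, donors=donors)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.adata.var_names)

    @property
    def cell_barcodes(self) -> list[str]:
        return list(self.adata.obs_names)

    @property
    def cells(self) -> pd.DataFrame:
        return self.adata.obs

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_genes(self) -> int:
        return self.adata.n_vars

    def counts_matrix(self) -> sp.csr_matrix:
        """Raw counts, genes x cells (the on-disk orientation)."""
        return sp.csr_matrix(self.adata.X.T)

    def lognorm_matrix(self) -> sp.csr_matrix:
        if "lognorm" not in self.adata.layers:
            raise ValueError("dataset has no lognorm layer; call lognormalize first")
        return sp.csr_matrix(self.adata.layers["lognorm"])

    def ages_for(self, donor_ids) -> np.ndarray:
        return self.donors.loc[list(donor_ids), "age"].to_numpy(dtype=float)


def lognormalize(
    dataset: ExpressionDataset, scale_factor: float = 10_000.0, base: float = math.e
) -> ExpressionDataset:
    """Add the per-cell log-normalized layer: log(1 + count / cell_total * sf).

    Natural log by default; the raw layer is kept in ``X``.  Cells with zero
    total counts make the formula undefined and raise, listing the barcodes.
    """
    X = sp.csr_matrix(dataset.adata.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        bad = [b for b, z in zip(dataset.cell_barcodes, zero) if z]
        raise ValueError(f"cells with zero total counts: {bad}")
    norm = X.multiply(scale_factor / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    if base != math.e:
        norm.data /= math.log(base)
    dataset.adata.layers["lognorm"] = norm
    return dataset


@dataclass
class ValidationReport:
    """Dataset invariant violations; empty in every field iff the dataset is consistent."""

    orphan_barcodes: list[str] = field(default_factory=list)
    orphan_donors: list[str] = field(default_factory=list)
    missing_ages: list[str] = field(default_factory=list)
    nonfinite: list[str] = field(default_factory=list)
    negative_counts: bool = False

    @property
    def ok(self) -> bool:
        return (
            not self.orphan_barcodes
            and not self.orphan_donors
            and not self.missing_ages
            and not self.nonfinite
            and not self.negative_counts
        )

    def summary(self) -> str:
        if self.ok:
            return "dataset consistent"
        parts = []
        if self.orphan_barcodes:
            parts.append(f"barcodes without annotation: {self.orphan_barcodes}")
        if self.orphan_donors:
            parts.append(f"annotated donors missing from donor table: {self.orphan_donors}")
        if self.missing_ages:
            parts.append(f"donors without age: {self.missing_ages}")
        if self.nonfinite:
            parts.append(f"non-finite values in layers: {self.nonfinite}")
        if self.negative_counts:
            parts.append("negative raw counts")
        return "; ".join(parts)


def validate_dataset(dataset: ExpressionDataset) -> ValidationReport:
    """Check the cross-table invariants without throwing."""
    report = ValidationReport()
    obs = dataset.cells
    for col in ("donor_id", "celltype_major", "celltype_minor"):
        if col in obs.columns:
            missing = obs.index[obs[col].isna()]
            report.orphan_barcodes.extend(b for b in missing if b not in report.orphan_barcodes)
        else:
            report.orphan_barcodes.extend(
                b for b in obs.index if b not in report.orphan_barcodes
            )
    if "donor_id" in obs.columns:
        annotated = set(obs["donor_id"].dropna().astype(str))
        known = set(dataset.donors.index.astype(str))
        report.orphan_donors = sorted(annotated - known)
    if "age" in dataset.donors.columns:
        ages = pd.to_numeric(dataset.donors["age"], errors="coerce")
        report.missing_ages = sorted(
            str(d) for d in dataset.donors.index[ages.isna() | (ages <= 0)]
        )
    else:
        report.missing_ages = sorted(str(d) for d in dataset.donors.index)
    X = sp.csr_matrix(dataset.adata.X)
    if X.nnz and X.data.min() < 0:
        report.negative_counts = True
    for name, layer in dataset.adata.layers.items():
        data = sp.csr_matrix(layer).data
        if data.size and not np.all(np.isfinite(data)):
            report.nonfinite.append(name)
    return report


def read_cells_csv(path: str | Path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return cells


def read_donors_csv(path: str | Path) -> pd.DataFrame:
    donors = pd.read_csv(path)
    missing = [c for c in DONOR_COLUMNS if c not in donors.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return donors


def load_dataset(
    matrix_path, features_path, barcodes_path, cells_path, donors_path
) -> ExpressionDataset:
    """Read the full triplet + annotation bundle into an ExpressionDataset."""
    counts, genes, barcodes = read_matrix_triplet(matrix_path, features_path, barcodes_path)
    cells = read_cells_csv(cells_path)
    donors = read_donors_csv(donors_path)
    return ExpressionDataset.from_parts(counts, genes, barcodes, cells, donors)
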