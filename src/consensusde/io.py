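"""Core data containers and the pipeline's tab-separated file formats.

The pipeline starts after alignment and read counting: its canonical inputs
are a gene × library integer count matrix (TSV, first column gene id), a
library design table describing the nested invasion-category / site /
replicate-pool structure, and a GMT gene-set annotation. All files are
UTF-8 with LF line endings; reals in result tables are written with six
significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

INVASION_CATEGORIES = ("ancient", "recent")

DESIGN_COLUMNS = [
    "library_id",
    "species",
    "site",
    "invasion_category",
    "pool_index",
    "pool_size",
    "n_males",
    "n_females",
]


@dataclass
class CountMatrix:
    """Integer gene × library read counts.

    ``counts[i, j]`` is the number of reads assigned to ``gene_ids[i]`` in
    library ``library_ids[j]``. Gene and library order is preserved from the
    source file / generator and is meaningful downstream (library order is
    the design-table order everywhere).
    """

    gene_ids: list[str]
    library_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.library_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.library_ids)} libraries"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        if len(set(self.library_ids)) != len(self.library_ids):
            raise FormatError("duplicate library identifiers")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_libraries(self) -> int:
        return len(self.library_ids)

    def subset_libraries(self, library_ids: list[str]) -> "CountMatrix":
        """Return a new matrix restricted to ``library_ids`` in the given order."""
        idx = [self.library_ids.index(l) for l in library_ids]
        return CountMatrix(list(self.gene_ids), list(library_ids), self.counts[:, idx])

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Return a new matrix keeping genes where boolean ``keep`` is True."""
        keep = np.asarray(keep, dtype=bool)
        genes = [g for g, k in zip(self.gene_ids, keep) if k]
        return CountMatrix(genes, list(self.library_ids), self.counts[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.library_ids)


@dataclass
class StudyDesign:
    """Per-library metadata for the nested 2-category / sites / 2-pool design.

    Each library is one sequencing pool of several individuals from a single
    site; each site belongs to exactly one invasion category and contributes
    at most one library per replicate-pool index (per species).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"design table missing columns: {missing}")
        t = t.loc[:, DESIGN_COLUMNS].reset_index(drop=True)
        if t["library_id"].duplicated().any():
            raise DesignError("duplicate library_id in design")
        bad = ~t["invasion_category"].isin(INVASION_CATEGORIES)
        if bad.any():
            raise DesignError(
                f"invasion_category must be one of {INVASION_CATEGORIES}; "
                f"got {sorted(t.loc[bad, 'invasion_category'].unique())}"
            )
        if not t["pool_index"].isin([1, 2]).all():
            raise DesignError("pool_index must be 1 or 2")
        # one invasion category per site
        cats = t.groupby("site")["invasion_category"].nunique()
        if (cats > 1).any():
            raise DesignError(
                f"sites mapped to multiple invasion categories: "
                f"{sorted(cats[cats > 1].index)}"
            )
        dup = t.duplicated(subset=["species", "site", "pool_index"])
        if dup.any():
            raise DesignError("duplicated (species, site, pool_index)")
        if (t["pool_size"] < 1).any():
            raise DesignError("pool_size must be >= 1")
        if not (t["pool_size"] == t["n_males"] + t["n_females"]).all():
            raise DesignError("pool_size must equal n_males + n_females")
        self.table = t

    @property
    def library_ids(self) -> list[str]:
        return self.table["library_id"].tolist()

    @property
    def sites(self) -> list[str]:
        """Sites in first-appearance order."""
        return list(dict.fromkeys(self.table["site"]))

    @property
    def n_libraries(self) -> int:
        return len(self.table)

    def category_of_library(self) -> pd.Series:
        return self.table.set_index("library_id")["invasion_category"]

    def subset(self, library_ids: list[str]) -> "StudyDesign":
        t = self.table.set_index("library_id").loc[library_ids].reset_index()
        return StudyDesign(t)


@dataclass
class GeneSetCollection:
    """Mapping term_id -> (description, member gene ids)."""

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, genes) in self.terms.items():
            if len(genes) == 0:
                raise FormatError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def genes(self, term: str) -> frozenset[str]:
        return self.terms[term][1]

    def description(self, term: str) -> str:
        return self.terms[term][0]


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene × library count TSV (header row of library ids)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) != len(set(header)):
        raise FormatError("duplicate library identifiers in header")
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError("count file needs a gene column and >= 1 library column")
    gene_col = df.columns[0]
    libs = list(df.columns[1:])
    genes = df[gene_col].tolist()
    values = df[libs].to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        raise FormatError("count cells must be integers")
    return CountMatrix(genes, libs, values)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.to_csv(path, sep="\t", lineterminator="\n")


def read_design(path: str | Path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", header=0, dtype={"library_id": str, "site": str,
                                                      "species": str})
    return StudyDesign(df)


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a gene-set file in the standard GMT dialect.

    Each line: term TAB description TAB gene [TAB gene ...]; lines with
    fewer than three fields are rejected.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            term, desc, genes = fields[0], fields[1], fields[2:]
            if term in terms:
                raise FormatError(f"GMT line {lineno}: duplicate term {term!r}")
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"GMT line {lineno}: empty gene list")
            terms[term] = (desc, frozenset(genes))
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term, (desc, genes) in collection.terms.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a result table (DE / consensus / enrichment) as TSV.

    Column order is the DataFrame's order; reals carry six significant
    digits, enough to round-trip every decision threshold.
    """
    results.to_csv(path, sep="\t", index=False, float_format="%.6g",
                   lineterminator="\n")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=0)
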