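"""Readers, writers and core containers for the MTIS pipeline.

Conventions
-----------
* Count matrices are **cells x genes** everywhere in memory. On disk the
  MatrixMarket triplet follows the 10x convention (genes x cells) and is
  transposed on read/write.
* Gene symbols are uppercased and whitespace-stripped on load; no alias
  mapping is attempted, so target intersections are deterministic.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """An on-disk file does not satisfy the expected format contract."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetSet:
    """A named set of gene symbols (e.g. a plant's or a disease's targets)."""

    label: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        cleaned = frozenset(_clean_symbol(s) for s in self.symbols)
        if any(not s for s in cleaned):
            raise ValueError("TargetSet symbols must be non-empty strings")
        object.__setattr__(self, "symbols", cleaned)

    def __len__(self) -> int:
        return len(self.symbols)

    def sorted_symbols(self) -> list[str]:
        return sorted(self.symbols)


@dataclass
class CellGeneMatrix:
    """Integer count matrix with cell and gene identifiers.

    ``counts[i, j]`` is the UMI/read count of gene ``gene_symbols[j]`` in
    cell ``cell_ids[i]``.
    """

    cell_ids: list[str]
    gene_symbols: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        n, q = self.counts.shape
        if n != len(self.cell_ids) or q != len(self.gene_symbols):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_symbols)} genes"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids must be unique")
        if len(set(self.gene_symbols)) != q:
            raise ValueError("gene_symbols must be unique")
        if self.counts.size:
            if np.issubdtype(self.counts.dtype, np.floating):
                if not np.all(np.isfinite(self.counts)) or np.any(
                    self.counts != np.round(self.counts)
                ):
                    raise FormatError("counts must be integral")
            if np.any(self.counts < 0):
                raise FormatError("counts must be nonnegative")
        self.counts = self.counts.astype(np.int64, copy=False)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: j for j, g in enumerate(self.gene_symbols)}


@dataclass
class CellAnnotation:
    """Validated per-cell annotation table.

    Columns: ``cell_id``, ``group``, and optionally ``cell_type``,
    ``pseudotime``, ``embed_x``, ``embed_y`` (missing values allowed in the
    optional columns).
    """

    df: pd.DataFrame
    groups: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        df = self.df
        if "cell_id" not in df.columns or "group" not in df.columns:
            raise FormatError("annotation requires cell_id and group columns")
        if df["cell_id"].duplicated().any():
            dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
            raise FormatError(f"duplicate cell ids in annotation: {dupes[:5]}")
        for col in ("cell_type", "pseudotime", "embed_x", "embed_y"):
            if col not in df.columns:
                df[col] = np.nan
        if not self.groups:
            self.groups = tuple(pd.unique(df["group"].astype(str)))
        unknown = set(df["group"].astype(str)) - set(self.groups)
        if unknown:
            raise FormatError(f"groups outside the declared label set: {sorted(unknown)}")
        if (pd.to_numeric(df["pseudotime"], errors="coerce").dropna() < 0).any():
            raise FormatError("pseudotime must be nonnegative")
        self.df = df.reset_index(drop=True)


@dataclass
class InteractionNetwork:
    """Undirected interaction edges with confidence scores in [0, 1]."""

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], float] = {}
        for a, b, s in self.edges:
            a, b = _clean_symbol(a), _clean_symbol(b)
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"score {s} outside [0, 1] for edge {a}-{b}")
            key = (a, b) if a < b else (b, a)
            seen[key] = max(s, seen.get(key, 0.0))
        self.edges = [(a, b, s) for (a, b), s in sorted(seen.items())]

    def neighbors(self, gene: str, min_score: float = 0.0) -> set[str]:
        gene = _clean_symbol(gene)
        out: set[str] = set()
        for a, b, s in self.edges:
            if s < min_score:
                continue
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out


def _clean_symbol(s: str) -> str:
    return str(s).strip().upper()


# ---------------------------------------------------------------------------
# Count matrix I/O
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_triplet_member(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / f"{stem}{suffix}"
            if p.exists():
                return p
    raise FormatError(f"none of {list(stems)} found in {directory}")


def _dedupe_symbols(symbols: Iterable[str]) -> list[str]:
    # Duplicate symbols are disambiguated deterministically in file order:
    # second occurrence gets ".1", third ".2", ...
    counts: dict[str, int] = {}
    out = []
    for s in symbols:
        k = counts.get(s, 0)
        out.append(s if k == 0 else f"{s}.{k}")
        counts[s] = k + 1
    return out


def read_counts(path: str | Path, format: str = "mtx-triplet") -> CellGeneMatrix:
    """Read a count matrix from disk.

    Parameters
    ----------
    path
        For ``mtx-triplet``: a directory holding ``matrix.mtx``,
        ``barcodes.tsv`` and ``features.tsv`` (``genes.tsv`` accepted;
        gzip optional). For ``dense-csv``: a CSV whose header row holds gene
        symbols and whose first column holds cell ids.
    format
        ``"mtx-triplet"`` or ``"dense-csv"``.
    """
    path = Path(path)
    if format == "mtx-triplet":
        directory = path if path.is_dir() else path.parent
        mtx = _find_triplet_member(directory, ["matrix.mtx"])
        barcodes = _find_triplet_member(directory, ["barcodes.tsv"])
        features = _find_triplet_member(directory, ["features.tsv", "genes.tsv"])
        try:
            mat = scipy.io.mmread(str(mtx))
        except Exception as exc:  # malformed MatrixMarket header/body
            raise FormatError(f"cannot parse MatrixMarket file {mtx}: {exc}") from exc
        mat = scipy.sparse.coo_matrix(mat)
        with _open_maybe_gzip(barcodes) as fh:
            cell_ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
        with _open_maybe_gzip(features) as fh:
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        # 10x features files carry (id, symbol, type); symbol in 2nd column.
        symbols = [_clean_symbol(r[1] if len(r) > 1 else r[0]) for r in rows]
        # On disk the matrix is genes x cells; transpose to cells x genes.
        if mat.shape != (len(symbols), len(cell_ids)):
            raise FormatError(
                f"matrix is {mat.shape} but features/barcodes give "
                f"{len(symbols)} genes x {len(cell_ids)} cells"
            )
        dense = np.asarray(mat.T.todense())
        return CellGeneMatrix(cell_ids, _dedupe_symbols(symbols), dense)
    if format == "dense-csv":
        df = pd.read_csv(path, index_col=0)
        symbols = _dedupe_symbols([_clean_symbol(c) for c in df.columns])
        try:
            return CellGeneMatrix([str(i) for i in df.index], symbols, df.to_numpy())
        except FormatError:
            raise
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
    raise ValueError(f"unknown format {format!r}")


def write_counts(cg: CellGeneMatrix, path: str | Path, format: str = "mtx-triplet") -> Path:
    """Write a count matrix; inverse of :func:`read_counts`."""
    path = Path(path)
    if format == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.csr_matrix(cg.counts.T)  # genes x cells on disk
        scipy.io.mmwrite(str(path / "matrix.mtx"), sparse, field="integer")
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cg.cell_ids))
        (path / "features.tsv").write_text(
            "".join(f"{g}\t{g}\tGene Expression\n" for g in cg.gene_symbols)
        )
        return path
    if format == "dense-csv":
        df = pd.DataFrame(cg.counts, index=cg.cell_ids, columns=cg.gene_symbols)
        df.to_csv(path)
        return path
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Target lists, annotations, networks
# ---------------------------------------------------------------------------


def read_targets(path: str | Path, label: str | None = None) -> TargetSet:
    """Read a target list: CSV with one symbol per row, optional 'symbol' header."""
    path = Path(path)
    rows = [r.strip() for r in path.read_text().splitlines() if r.strip()]
    if rows and rows[0].split(",")[0].strip().lower() == "symbol":
        rows = rows[1:]
    symbols = [_clean_symbol(r.split(",")[0]) for r in rows]
    symbols = [s for s in symbols if s]
    return TargetSet(label or path.stem, frozenset(symbols))


def read_annotations(path: str | Path, groups: Sequence[str] | None = None) -> CellAnnotation:
    """Read the per-cell annotation TSV (cell_id, group, cell_type, ...)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "group": str})
    return CellAnnotation(df, tuple(groups) if groups else ())


def read_network(path: str | Path) -> InteractionNetwork:
    """Read the interaction edge TSV (gene_a, gene_b, score).

    Self-loops are dropped with a warning; duplicate undirected edges keep
    their maximum score.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "score"}
    if not required.issubset(df.columns):
        raise FormatError(f"network file needs columns {sorted(required)}")
    edges = []
    n_loops = 0
    for a, b, s in df[["gene_a", "gene_b", "score"]].itertuples(index=False):
        a, b = _clean_symbol(a), _clean_symbol(b)
        if a == b:
            n_loops += 1
            continue
        edges.append((a, b, float(s)))
    if n_loops:
        warnings.warn(f"dropped {n_loops} self-loop edge(s)", stacklevel=2)
    return InteractionNetwork(edges)


# ---------------------------------------------------------------------------
# Target intersection and QC
# ---------------------------------------------------------------------------


def intersect_targets(plant: TargetSet, disease: TargetSet) -> TargetSet:
    """Common targets between two lists (symbols present in both)."""
    common = plant.symbols & disease.symbols
    return TargetSet(f"{plant.label}∩{disease.label}", frozenset(common)) if common else TargetSet(
        f"{plant.label}∩{disease.label}", frozenset()
    )


def filter_qc(
    cg: CellGeneMatrix,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 200,
) -> CellGeneMatrix:
    """Joint cell/gene quality filter.

    Both criteria are evaluated on the *input* matrix in a single pass
    (object-creation semantics): keep genes detected (count > 0) in at least
    ``min_cells_per_gene`` input cells, and cells with at least
    ``min_genes_per_cell`` detected genes in the input. Order is preserved.
    """
    if min_cells_per_gene < 0 or min_genes_per_cell < 0:
        raise ValueError("thresholds must be nonnegative")
    detected = cg.counts > 0
    gene_keep = detected.sum(axis=0) >= min_cells_per_gene
    cell_keep = detected.sum(axis=1) >= min_genes_per_cell
    if not gene_keep.any() or not cell_keep.any():
        warnings.warn(
            "QC filter removed all cells and/or genes; returning empty matrix",
            stacklevel=2,
        )
    return CellGeneMatrix(
        [c for c, k in zip(cg.cell_ids, cell_keep) if k],
        [g for g, k in zip(cg.gene_symbols, gene_keep) if k],
        cg.counts[np.ix_(cell_keep, gene_keep)],
    )


def subset_to_targets(
    cg: CellGeneMatrix, cts: TargetSet
) -> tuple[CellGeneMatrix, list[str]]:
    """Restrict columns to the target genes.

    Returns the submatrix (columns in the targets' sorted order) and the
    sorted list of target symbols absent from the matrix.
    """
    index = cg.gene_index()
    present = [g for g in cts.sorted_symbols() if g in index]
    missing = [g for g in cts.sorted_symbols() if g not in index]
    if not present:
        raise ValueError(
            f"no overlap between matrix genes and target set {cts.label!r}"
        )
    cols = [index[g] for g in present]
    sub = CellGeneMatrix(list(cg.cell_ids), present, cg.counts[:, cols])
    return sub, missing
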