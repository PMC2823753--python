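"""Regulatory-network containers and TSV readers/writers.

Two matrix representations are used throughout:

* :class:`WeightedNet` — signed real weights, 0 meaning "no edge"; produced
  by the evolution simulator and by structure learning.
* :class:`TernaryNet` — entries in {0, 1, x} over a (possibly shared) gene
  list, where ``x`` marks the row and column of a gene absent from the
  organism.  Ancestral reconstruction and refinement operate on these.

Matrix orientation convention: rows are regulators, columns are targets, so
``matrix[i, j] == 1`` means gene ``i`` regulates gene ``j``.  The special
character ``x`` is stored internally as the integer :data:`X` (= -1).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "X",
    "TernaryNet",
    "WeightedNet",
    "gene_family",
    "sort_genes",
    "embed",
    "embed_union",
    "read_network",
    "write_network",
]

#: Integer code for the ternary character ``x`` (absent gene).
X: int = -1


def gene_family(gene: str) -> str:
    """Family identifier of a gene id (the part before the first '.')."""
    return gene.split(".", 1)[0]


def _copy_index(gene: str) -> int:
    parts = gene.split(".", 1)
    return int(parts[1]) if len(parts) > 1 else 0


def sort_genes(genes) -> list[str]:
    """Deterministic gene ordering: by family, then copy index."""
    return sorted(set(genes), key=lambda g: (gene_family(g), _copy_index(g), g))


def _check_square(genes, matrix) -> np.ndarray:
    matrix = np.asarray(matrix)
    n = len(genes)
    if matrix.shape != (n, n):
        raise ValueError(f"matrix shape {matrix.shape} does not match {n} genes")
    if len(set(genes)) != n:
        raise ValueError("duplicate gene ids in one network")
    return matrix


@dataclass
class TernaryNet:
    """Square adjacency matrix with entries in {0, 1, x} (x stored as -1)."""

    genes: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.genes = list(self.genes)
        self.matrix = _check_square(self.genes, self.matrix).astype(np.int8)
        bad = ~np.isin(self.matrix, (0, 1, X))
        if bad.any():
            raise ValueError("ternary entries must be 0, 1 or x")

    @property
    def n(self) -> int:
        return len(self.genes)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    @property
    def present_genes(self) -> set[str]:
        """Genes whose row/column is not all-x."""
        present = ~np.all(self.matrix == X, axis=1)
        return {g for g, p in zip(self.genes, present) if p}

    def validate_content(self) -> None:
        """Check that x entries are exactly the rows/columns of absent genes."""
        absent = np.array([g not in self.present_genes for g in self.genes])
        expect_x = absent[:, None] | absent[None, :]
        actual_x = self.matrix == X
        if not np.array_equal(expect_x, actual_x):
            raise ValueError("x entries are not exactly the absent-gene rows/columns")

    def copy(self) -> "TernaryNet":
        return TernaryNet(list(self.genes), self.matrix.copy())

    def edges(self) -> set[tuple[str, str]]:
        rows, cols = np.nonzero(self.matrix == 1)
        return {(self.genes[i], self.genes[j]) for i, j in zip(rows, cols)}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TernaryNet)
            and self.genes == other.genes
            and np.array_equal(self.matrix, other.matrix)
        )


@dataclass
class WeightedNet:
    """Square adjacency matrix of signed real weights; 0 means no edge."""

    genes: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.genes = list(self.genes)
        self.matrix = _check_square(self.genes, self.matrix).astype(float)

    @property
    def n(self) -> int:
        return len(self.genes)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def binarize(self) -> TernaryNet:
        """Support pattern as a ternary net (no x entries)."""
        return TernaryNet(list(self.genes), (self.matrix != 0).astype(np.int8))

    def copy(self) -> "WeightedNet":
        return WeightedNet(list(self.genes), self.matrix.copy())

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.matrix))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WeightedNet)
            and self.genes == other.genes
            and np.array_equal(self.matrix, other.matrix)
        )


def embed_union(nets: list[TernaryNet | WeightedNet]) -> list[TernaryNet]:
    """Embed per-organism networks into a shared union gene space.

    Each output shares one ordered union gene list; entries between genes
    present in the input are copied unchanged, and rows/columns of genes the
    organism lacks are filled with ``x``.  Weighted inputs are binarized
    first.  Idempotent: embedding already-embedded nets is a no-op apart
    from gene reordering into the canonical union order.
    """
    ternary = [n.binarize() if isinstance(n, WeightedNet) else n for n in nets]
    union = sort_genes(g for net in ternary for g in net.present_genes)
    pos = {g: i for i, g in enumerate(union)}
    out = []
    for net in ternary:
        m = np.full((len(union), len(union)), X, dtype=np.int8)
        own = [g for g in net.genes if g in net.present_genes]
        idx_own = [net.gene_index()[g] for g in own]
        idx_uni = [pos[g] for g in own]
        m[np.ix_(idx_uni, idx_uni)] = net.matrix[np.ix_(idx_own, idx_own)]
        out.append(TernaryNet(list(union), m))
    return out


def embed(net: TernaryNet | WeightedNet, union: list[str]) -> TernaryNet:
    """Embed one network into a given union gene list (absent genes -> x)."""
    ternary = net.binarize() if isinstance(net, WeightedNet) else net
    own = ternary.present_genes
    missing = own - set(union)
    if missing:
        raise ValueError(f"genes not in the union list: {sorted(missing)}")
    pos = {g: i for i, g in enumerate(union)}
    m = np.full((len(union), len(union)), X, dtype=np.int8)
    own_sorted = [g for g in ternary.genes if g in own]
    idx_own = [ternary.gene_index()[g] for g in own_sorted]
    idx_uni = [pos[g] for g in own_sorted]
    m[np.ix_(idx_uni, idx_uni)] = ternary.matrix[np.ix_(idx_own, idx_own)]
    return TernaryNet(list(union), m)


def write_network(net: TernaryNet | WeightedNet, path: str | Path) -> None:
    """Write a network as TSV with a gene-id header row and column.

    Ternary entries are written as ``0``, ``1`` or the literal ``x``;
    weights are printed with 10 significant digits.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join([""] + list(net.genes)) + "\n")
        for g, row in zip(net.genes, net.matrix):
            if isinstance(net, TernaryNet):
                cells = ["x" if v == X else str(int(v)) for v in row]
            else:
                cells = [f"{v:.10g}" for v in row]
            fh.write("\t".join([g] + cells) + "\n")


def read_network(path: str | Path, kind: str = "auto") -> TernaryNet | WeightedNet:
    """Read a network TSV written by :func:`write_network`.

    ``kind`` is ``"ternary"``, ``"weighted"`` or ``"auto"`` (ternary when
    every entry is 0, 1 or x, weighted otherwise).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    if list(map(str, df.columns)) != genes:
        raise ValueError(f"{path}: header row and column gene lists differ")
    raw = df.to_numpy()
    is_x = raw == "x"
    values = np.zeros(raw.shape)
    mask = ~is_x
    try:
        values[mask] = raw[mask].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric non-x entry: {exc}") from exc
    looks_ternary = is_x.any() or np.isin(values[mask], (0.0, 1.0)).all()
    if kind == "auto":
        kind = "ternary" if looks_ternary else "weighted"
    if kind == "ternary":
        if not np.isin(values[mask], (0.0, 1.0)).all():
            raise ValueError(f"{path}: ternary entries must be 0, 1 or x")
        m = values.astype(np.int8)
        m[is_x] = X
        return TernaryNet(genes, m)
    if is_x.any():
        raise ValueError(f"{path}: weighted network cannot contain x")
    return WeightedNet(genes, values)
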