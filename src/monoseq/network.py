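"""Gene-interaction networks as sparse symmetric adjacency matrices.

A :class:`GeneNetwork` holds the undirected 0/1 adjacency matrix ``W`` over an
ordered gene axis, together with the per-gene degree vector (the diagonal of
the degree matrix ``D`` used by the GeneRank transform).  Networks are read
from plain two-column edge lists (one interaction per line, HPRD-style
exports) and can be re-aligned to the gene axis of an expression matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["GeneNetwork", "read_edge_list", "align_to_genes"]


@dataclass
class GeneNetwork:
    """Undirected gene-interaction network.

    Parameters
    ----------
    genes
        Ordered, unique gene identifiers (length ``p``).
    adjacency
        ``p x p`` sparse CSR matrix with entries in {0, 1}, symmetric, zero
        diagonal.

    The degree vector is derived from the adjacency row sums and cached.
    """

    genes: list[str]
    adjacency: sp.csr_matrix
    _degree: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        p = len(self.genes)
        A = sp.csr_matrix(self.adjacency, dtype=np.int8, shape=(p, p))
        A.eliminate_zeros()
        if A.shape != (p, p):
            raise ValueError(f"adjacency shape {A.shape} does not match {p} genes")
        if A.diagonal().any():
            raise ValueError("adjacency has nonzero diagonal entries")
        if (A != A.T).nnz != 0:
            raise ValueError("adjacency is not symmetric")
        if A.nnz and not np.all(A.data == 1):
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = A
        self._degree = np.asarray(A.sum(axis=1)).ravel().astype(np.int64)

    @property
    def degree(self) -> np.ndarray:
        """Number of interaction partners per gene (adjacency row sums)."""
        return self._degree

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def gene_index(self) -> dict[str, int]:
        return {g: k for k, g in enumerate(self.genes)}

    def edges(self) -> set[tuple[str, str]]:
        """Undirected edge set as sorted identifier pairs."""
        coo = self.adjacency.tocoo()
        out: set[tuple[str, str]] = set()
        for i, j in zip(coo.row, coo.col):
            if i < j:
                a, b = self.genes[i], self.genes[j]
                out.add((a, b) if a <= b else (b, a))
        return out


def _network_from_edges(
    genes: Sequence[str], edge_pairs: set[tuple[int, int]]
) -> GeneNetwork:
    p = len(genes)
    if edge_pairs:
        r = np.fromiter((i for i, _ in edge_pairs), dtype=np.int64, count=len(edge_pairs))
        c = np.fromiter((j for _, j in edge_pairs), dtype=np.int64, count=len(edge_pairs))
        data = np.ones(2 * len(edge_pairs), dtype=np.int8)
        A = sp.coo_matrix(
            (data, (np.concatenate([r, c]), np.concatenate([c, r]))), shape=(p, p)
        ).tocsr()
    else:
        A = sp.csr_matrix((p, p), dtype=np.int8)
    return GeneNetwork(list(genes), A)


def read_edge_list(
    path,
    dedupe: bool = True,
    allow_sif: bool = False,
    comment: str = "#",
) -> GeneNetwork:
    """Read an undirected network from a two-column delimited edge list.

    Each non-comment line names one interaction ``geneA geneB`` (tab- or
    whitespace-delimited).  Reversed and repeated duplicates collapse to a
    single undirected edge; self-loops are dropped with a warning.  With
    ``allow_sif`` a three-column ``node relation node`` dialect is tolerated
    (the middle column is ignored).

    Raises
    ------
    ValueError
        If a line does not have exactly two (or, with ``allow_sif``, three)
        columns; the message names the offending line number.
    """
    genes: list[str] = []
    index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    n_self = 0
    n_lines = 0

    def intern(g: str) -> int:
        k = index.get(g)
        if k is None:
            k = len(genes)
            index[g] = k
            genes.append(g)
        return k

    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(comment):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) == 3 and allow_sif:
                a, _, b = fields
            elif len(fields) == 2:
                a, b = fields
            else:
                raise ValueError(
                    f"line {lineno}: expected 2 columns, found {len(fields)}"
                )
            if not a or not b:
                raise ValueError(f"line {lineno}: empty gene identifier")
            n_lines += 1
            if a == b:
                n_self += 1
                intern(a)
                continue
            i, j = intern(a), intern(b)
            edge = (i, j) if i < j else (j, i)
            if not dedupe and edge in edges:
                logger.warning("duplicate edge %s-%s kept as single edge", a, b)
            edges.add(edge)

    if n_self:
        logger.warning("dropped %d self-loop line(s)", n_self)
    if n_lines == 0:
        logger.warning("edge list %s contains no interactions; empty network", path)
    return _network_from_edges(genes, edges)


def align_to_genes(
    net: GeneNetwork,
    gene_universe: Sequence[str],
    isolated_policy: str = "keep",
) -> GeneNetwork:
    """Re-index a network onto the gene axis of an expression matrix.

    ``isolated_policy='keep'`` returns a network over exactly
    ``gene_universe``: genes absent from ``net`` become isolated nodes with
    degree 0, so they still receive a (purely expression-driven) GeneRank.
    ``'drop'`` restricts to the intersection, preserving universe order.
    Edges between genes outside the universe are discarded either way.
    """
    universe = list(gene_universe)
    if len(set(universe)) != len(universe):
        raise ValueError("gene_universe has duplicate identifiers")
    if isolated_policy not in ("keep", "drop"):
        raise ValueError(f"unknown isolated_policy {isolated_policy!r}")

    have = set(net.genes)
    if isolated_policy == "drop":
        universe = [g for g in universe if g in have]
        if not universe:
            raise ValueError(
                "no genes shared between network and expression matrix; "
                "check that both use the same identifier namespace "
                "(e.g. HGNC symbols vs probe IDs)"
            )
    new_index = {g: k for k, g in enumerate(universe)}
    old_edges = net.edges()
    edges: set[tuple[int, int]] = set()
    for a, b in old_edges:
        ia, ib = new_index.get(a), new_index.get(b)
        if ia is None or ib is None:
            continue
        edges.add((ia, ib) if ia < ib else (ib, ia))
    dropped = len(old_edges) - len(edges)
    if dropped:
        logger.info("alignment dropped %d edge(s) outside the gene universe", dropped)
    return _network_from_edges(universe, edges)
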