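"""Pairwise p-distances, neighbor joining, locus bootstrap, Newick I/O.

Pseudomolecules are equal-length by construction (one character per panel
locus), so multiple alignment is the identity and distances are computed
positionally.  The distance is the p-distance with pairwise-complete sites:
for each pair of accessions, sites where either call is N are excluded and
the distance is mismatches / comparable sites.

Two comparison modes:

* strict (default): calls are compared as literal characters, so a
  heterozygote ambiguity letter mismatches its constituent homozygote.
* allele-aware: each call is expanded to its diploid allele pair and the
  per-site distance is 1 - shared_alleles/2 (het vs constituent homozygote
  counts 0.5).

Neighbor joining follows Saitou & Nei's agglomeration with the standard
Q-criterion, limb-length and reduction formulas; ties in Q are broken by the
lowest (row, column) index pair in the working matrix, which makes the
output fully deterministic; negative limb lengths are clamped to zero and
logged.  On additive matrices NJ provably recovers the generating topology,
which is the principal oracle used by the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .core_io import GenotypeMatrix, HET_ALLELES

logger = logging.getLogger(__name__)

DEFAULT_MIN_SITES = 50


class PairComparabilityError(ValueError):
    """A pair of accessions shares fewer comparable sites than required."""

    def __init__(self, label_i: str, label_j: str, n: int, min_sites: int):
        self.pair = (label_i, label_j)
        self.n = n
        super().__init__(
            f"pair ({label_i!r}, {label_j!r}) has {n} comparable sites "
            f"(min_sites={min_sites})"
        )


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair comparable-site counts."""

    labels: list[str]
    d: np.ndarray
    n_comparable: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if (self.d < 0).any() or (self.d > 1).any():
            raise ValueError("p-distances must lie in [0, 1]")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.d):
                fh.write(label + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# call encoding and distances

_CODES = "ACGTRYSWKMN"  # other ambiguity letters are treated as missing
_CODE_OF = {c: i for i, c in enumerate(_CODES)}
_MISSING = _CODE_OF["N"]


def _allele_pairs() -> list[tuple[str, ...]]:
    pairs: list[tuple[str, ...]] = []
    for c in _CODES:
        if c in "ACGT":
            pairs.append((c, c))
        elif c in HET_ALLELES:
            pairs.append(HET_ALLELES[c])
        else:
            pairs.append(())
    return pairs


def _allele_distance_table() -> np.ndarray:
    """Per-site distance lookup: 1 - shared_alleles/2 under best pairing."""
    pairs = _allele_pairs()
    t = np.full((len(_CODES), len(_CODES)), np.nan)
    for i, pi in enumerate(pairs):
        for j, pj in enumerate(pairs):
            if not pi or not pj:
                continue
            shared = 0
            remaining = list(pj)
            for a in pi:
                if a in remaining:
                    remaining.remove(a)
                    shared += 1
            t[i, j] = 1.0 - shared / 2.0
    return t


_ALLELE_DIST = _allele_distance_table()


def encode_calls(calls: np.ndarray) -> np.ndarray:
    """Map a '<U1' call array to small int codes (unknown letters -> missing)."""
    out = np.full(calls.shape, _MISSING, dtype=np.int8)
    for ch, code in _CODE_OF.items():
        out[calls == ch] = code
    return out


def _pdist_encoded(
    codes: np.ndarray, allele_aware: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Distance and comparable-site count matrices from encoded calls."""
    n = codes.shape[0]
    d = np.zeros((n, n))
    nc = np.zeros((n, n), dtype=int)
    np.fill_diagonal(nc, codes.shape[1])
    for i in range(n):
        xi = codes[i]
        for j in range(i + 1, n):
            xj = codes[j]
            valid = (xi != _MISSING) & (xj != _MISSING)
            nv = int(valid.sum())
            nc[i, j] = nc[j, i] = nv
            if nv == 0:
                continue
            if allele_aware:
                dist = float(_ALLELE_DIST[xi[valid], xj[valid]].sum()) / nv
            else:
                dist = float((xi[valid] != xj[valid]).sum()) / nv
            d[i, j] = d[j, i] = dist
    np.fill_diagonal(nc, codes.shape[1])
    return d, nc


def p_distance_matrix(
    matrix: GenotypeMatrix,
    min_sites: int = DEFAULT_MIN_SITES,
    allele_aware: bool = False,
) -> DistanceMatrix:
    """Pairwise p-distances over pairwise-complete sites.

    Raises :class:`PairComparabilityError` naming the first pair whose
    comparable-site count falls below ``min_sites``.
    """
    if len(matrix.accessions) < 2:
        raise ValueError("need at least 2 accessions")
    codes = encode_calls(matrix.calls)
    d, nc = _pdist_encoded(codes, allele_aware)
    n = len(matrix.accessions)
    for i in range(n):
        for j in range(i + 1, n):
            if nc[i, j] < min_sites:
                raise PairComparabilityError(
                    matrix.accessions[i], matrix.accessions[j], int(nc[i, j]), min_sites
                )
    return DistanceMatrix(list(matrix.accessions), d, nc)


# ---------------------------------------------------------------------------
# trees


@dataclass
class Node:
    """Tree node; ``length`` is the branch length above the node."""

    label: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary internal root (trifurcation)."""

    root: Node

    def leaves(self) -> list[Node]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def bipartitions(self) -> dict[int, frozenset[str]]:
        """Canonical non-trivial splits keyed by id() of the internal node
        below each edge.

        Each split is represented by the leaf side NOT containing the
        lexicographically smallest leaf, so representations agree across
        rootings.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        result: dict[int, frozenset[str]] = {}

        def clade(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            s = frozenset().union(*(clade(c) for c in node.children))
            return s

        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = clade(node)
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                result[id(node)] = side
        return result

    def bipartition_set(self) -> frozenset[frozenset[str]]:
        return frozenset(self.bipartitions().values())

    def leaf_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Patristic (path-length) distances between all leaf pairs.

        Returns sorted leaf names and the matching symmetric matrix; used to
        verify additivity (NJ on an additive matrix reproduces it exactly).
        """
        names = sorted(self.leaf_names())
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def below(node: Node) -> dict[str, float]:
            """leaf -> distance up to this node; fills d for pairs meeting here."""
            if node.is_leaf:
                return {node.label: 0.0}
            child_maps = []
            for child in node.children:
                m = below(child)
                edge = child.length or 0.0
                child_maps.append({k: v + edge for k, v in m.items()})
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for la, da in child_maps[a].items():
                        for lb, db in child_maps[b].items():
                            d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
            merged: dict[str, float] = {}
            for m in child_maps:
                merged.update(m)
            return merged

        below(self.root)
        return names, d


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined (ties: lowest (row, column) pair in the working matrix); limb
    lengths come from the standard formulas and negative limbs are clamped
    to zero.  The two joined rows are removed and the new node's row is
    appended, so the iteration order is fully determined by the input.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    d = dm.d.astype(float).copy()
    nodes: list[Node] = [Node(label=l) for l in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) among ties: argmin of flattened C-order scan
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            logger.info(
                "clamped negative limb length at join (%s, %s): %.3g / %.3g",
                nodes[i].label or "internal",
                nodes[j].label or "internal",
                li,
                lj,
            )
        ni, nj_ = nodes[i], nodes[j]
        ni.length = max(li, 0.0)
        nj_.length = max(lj, 0.0)
        new = Node(children=[ni, nj_])
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]

    # final three-way join: limb lengths from the three-point formulas
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return Tree(Node(children=[a, b, c]))


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    matrix: GenotypeMatrix,
    replicates: int = 1000,
    seed: int = 0,
    allele_aware: bool = False,
    min_sites: int = DEFAULT_MIN_SITES,
) -> Tree:
    """Locus-resampling bootstrap supports on the NJ tree of ``matrix``.

    Loci are resampled with replacement per replicate; the distance matrix
    and NJ tree are recomputed and each internal bipartition of the original
    tree is scored by the percent of replicates containing it.  Replicates
    where some pair has zero comparable sites are skipped (with a warning)
    and excluded from the denominator.  Fixed seed -> bit-identical supports.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    dm = p_distance_matrix(matrix, min_sites=min_sites, allele_aware=allele_aware)
    tree = nj_tree(dm)
    splits = tree.bipartitions()
    counts = {node_id: 0 for node_id in splits}

    codes = encode_calls(matrix.calls)
    n_loci = codes.shape[1]
    rng = np.random.default_rng(seed)
    completed = 0
    skipped = 0
    for _ in range(replicates):
        idx = rng.integers(0, n_loci, size=n_loci)
        rep_codes = codes[:, idx]
        d, nc = _pdist_encoded(rep_codes, allele_aware)
        off_diag = nc[~np.eye(nc.shape[0], dtype=bool)]
        if (off_diag == 0).any():
            skipped += 1
            continue
        rep_splits = nj_tree(
            DistanceMatrix(list(matrix.accessions), d, nc)
        ).bipartition_set()
        completed += 1
        for node_id, split in splits.items():
            if split in rep_splits:
                counts[node_id] += 1
    if skipped:
        logger.warning("skipped %d degenerate bootstrap replicates", skipped)
    if completed == 0:
        raise ValueError("all bootstrap replicates were degenerate")
    for node in tree.root.walk():
        if id(node) in counts:
            node.support = 100.0 * counts[id(node)] / completed
    return tree


# ---------------------------------------------------------------------------
# Newick I/O


class NewickParseError(ValueError):
    """Malformed Newick input; carries the character index of the failure."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at character {position})")


def _format_length(x: float) -> str:
    return f"{x:.6g}"


def write_newick(tree: Tree) -> str:
    """Serialize to Newick; supports become internal node labels."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = node.label or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = _format_length(node.support)
            elif node.label:
                label = node.label
            s = f"({inner}){label}"
        if node.length is not None:
            s += f":{_format_length(node.length)}"
        return s

    return fmt(tree.root) + ";"


def read_newick(text: str) -> Tree:
    """Parse a Newick string; errors report the character index of failure."""
    text = text.strip()
    pos = 0

    def error(msg: str):
        raise NewickParseError(msg, pos)

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(text) and text[pos] not in ",():;":
            pos += 1
        return text[start:pos].strip()

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(text) and text[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while pos < len(text) and text[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if pos >= len(text) or text[pos] != ")":
                error("expected ')' or ','")
            pos += 1
            label = parse_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.label = label
        else:
            label = parse_label()
            if not label:
                error("expected a leaf label")
            node.label = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            try:
                node.length = float(text[start:pos])
            except ValueError:
                pos = start
                error("malformed branch length")
        return node

    root = parse_node()
    if pos >= len(text) or text[pos] != ";":
        error("expected ';'")
    return Tree(root)


def write_newick_file(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


def read_newick_file(path) -> Tree:
    with open(path) as fh:
        return read_newick(fh.read())
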