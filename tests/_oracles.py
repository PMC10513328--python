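"""Independent oracles shared across test modules.

These deliberately avoid the code paths they check: placement uses a direct
numpy window scan instead of k-mer seeding, and reference trees come from
dendropy's simulators with patristic distances read back from dendropy.
"""

import random as _random

import dendropy
import numpy as np

from snpanchor import revcomp
from snpanchor.probe_map import Placement


def brute_force_place(probe, genome, min_identity):
    """Exhaustive both-strand ungapped identity scan over every offset."""
    plen = len(probe.sequence)
    best_identity = 0.0
    best = []
    for si, rec in enumerate(genome):
        g = np.frombuffer(rec.sequence.encode(), dtype="S1")
        if len(g) < plen:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(g, plen)
        not_n = windows != b"N"
        for strand, q in (("+", probe.sequence), ("-", revcomp(probe.sequence))):
            qa = np.frombuffer(q.encode(), dtype="S1")
            ident = ((windows == qa) & not_n).sum(axis=1) / plen
            for start in np.flatnonzero(ident >= best_identity - 1e-12):
                iv = float(ident[start])
                if iv > best_identity + 1e-12:
                    best_identity = iv
                    best = [(si, int(start), strand)]
                elif abs(iv - best_identity) <= 1e-12 and iv > 0:
                    best.append((si, int(start), strand))
    if not best or best_identity < min_identity:
        return Placement(probe.probe_id, None, None, None, None, None, 0, "unplaced")
    by_location = {}
    for si, start, strand in sorted(set(best)):
        by_location.setdefault((si, start), strand)
    best = [(si, start, s) for (si, start), s in sorted(by_location.items())]
    si, start, strand = best[0]
    status = "ambiguous" if len(best) > 1 else "unique"
    return Placement(
        probe.probe_id, genome[si].id, start, start + plen, strand,
        best_identity, len(best), status,
    )


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths via dendropy."""
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=taxa,
        rng=_random.Random(int(rng.integers(2**31))),
    )
    for edge in tree.preorder_edge_iter():
        edge.length = rng.uniform(0.5, 2.0)
    return tree


def additive_matrix(tree):
    """Leaf labels (sorted) and the patristic distance matrix of ``tree``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[i], taxa[j])
    return labels, d


def normalized_splits(tree, labels):
    """Non-trivial bipartitions of a dendropy tree, canonicalized like
    snpanchor's Tree.bipartition_set (side not containing the min label)."""
    anchor = min(labels)
    all_set = frozenset(labels)
    out = set()
    for b in tree.encode_bipartitions():
        s = frozenset(t.label for t in b.leafset_taxa(tree.taxon_namespace))
        side = all_set - s if anchor in s else s
        if 1 < len(side) < len(all_set) - 1:
            out.add(frozenset(side))
    return out
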