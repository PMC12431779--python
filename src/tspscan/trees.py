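"""Posterior tree-sample I/O, burn-in, replicate combination, MCC summary, ESS.

A :class:`TreeSample` wraps an ordered list of dendropy trees over a fixed
tip set, together with (replicate, state) provenance for every tree.  The
operations mirror the standard post-processing of Bayesian phylogenetic
output: discard an initial burn-in fraction, concatenate independent
replicate chains, summarize the sample by its maximum-clade-credibility
(MCC) tree, and gate on the effective sample size of scalar traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter
from typing import Optional, Sequence

import dendropy
import numpy as np

from .labels import TaxonLabel, parse_taxon_labels

__all__ = [
    "TreeSample",
    "read_tree_samples",
    "write_tree_samples",
    "apply_burnin",
    "combine_replicates",
    "mcc_tree",
    "ess",
]


class TipSetError(ValueError):
    """Raised when trees in a sample do not share a common tip set."""


@dataclass
class TreeSample:
    """An ordered sample of phylogenies over a shared tip set.

    ``provenance[i]`` is a ``(replicate_id, state_index)`` pair for
    ``trees[i]``.  All trees share one dendropy ``TaxonNamespace``.
    """

    trees: list[dendropy.Tree]
    provenance: list[tuple[str, int]]
    tip_labels: list[TaxonLabel] = field(default_factory=list)
    _edge_cache: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.trees) != len(self.provenance):
            raise ValueError("provenance length must match number of trees")
        if not self.tip_labels and self.trees:
            raws = sorted(t.taxon.label for t in self.trees[0].leaf_node_iter())
            self.tip_labels = parse_taxon_labels(raws)
        _validate_shared_tips(self.trees, self.tip_label_set())

    @property
    def n(self) -> int:
        return len(self.trees)

    def tip_label_set(self) -> frozenset[str]:
        return frozenset(t.raw for t in self.tip_labels)

    def edge_matrix(self) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
        """(E, tree_idx, label_to_col): one boolean row per internal edge.

        ``E[k, j]`` is True when tip ``j`` lies below edge ``k``;
        ``tree_idx[k]`` names the tree the edge belongs to.  Cached.
        """
        if self._edge_cache is None:
            labels = sorted(self.tip_label_set())
            col = {lab: j for j, lab in enumerate(labels)}
            ntips = len(labels)
            rows: list[np.ndarray] = []
            tree_of: list[int] = []
            for ti, tree in enumerate(self.trees):
                masks: dict[int, np.ndarray] = {}
                for node in tree.postorder_node_iter():
                    if node.is_leaf():
                        m = np.zeros(ntips, dtype=bool)
                        m[col[node.taxon.label]] = True
                    else:
                        m = np.zeros(ntips, dtype=bool)
                        for ch in node.child_nodes():
                            m |= masks[id(ch)]
                    masks[id(node)] = m
                    if not node.is_leaf() and node.parent_node is not None:
                        c = int(m.sum())
                        if 1 < c < ntips:
                            rows.append(m)
                            tree_of.append(ti)
            E = np.array(rows, dtype=bool) if rows else np.zeros((0, ntips), dtype=bool)
            self._edge_cache = (E, np.asarray(tree_of, dtype=np.int64), col)
        return self._edge_cache


def _validate_shared_tips(trees: Sequence[dendropy.Tree], expected: frozenset[str]) -> None:
    for i, tree in enumerate(trees):
        tips = frozenset(t.taxon.label for t in tree.leaf_node_iter())
        if tips != expected:
            missing = sorted(expected - tips)
            extra = sorted(tips - expected)
            raise TipSetError(
                f"tree {i + 1} does not match the shared tip set "
                f"(missing: {missing}, unexpected: {extra})"
            )


def read_tree_samples(
    path: str,
    format: str = "nexus",
    replicate_id: Optional[str] = None,
    species_table: Optional[Sequence[str]] = None,
) -> TreeSample:
    """Read a posterior tree sample from a Nexus (BEAST-style, with optional
    translate block) or plain Newick (one tree per line) file.

    Trees are returned in file order; tip labels are resolved through the
    translate table when present.  Every tree must carry the same tip set.
    """
    rep = replicate_id if replicate_id is not None else str(path)
    if format not in ("nexus", "newick"):
        raise ValueError(f"unsupported tree format: {format!r}")
    ns = dendropy.TaxonNamespace()
    trees: list[dendropy.Tree] = []
    if format == "newick":
        with open(path, "r", encoding="utf-8") as fh:
            lines = [ln.strip() for ln in fh]
        idx = 0
        for ln in lines:
            if not ln:
                continue
            idx += 1
            try:
                tree = dendropy.Tree.get(
                    data=ln, schema="newick", taxon_namespace=ns,
                    suppress_internal_node_taxa=True,
                    preserve_underscores=True,
                )
            except Exception as exc:  # dendropy raises assorted error types
                raise ValueError(f"malformed Newick at tree {idx} of {path}: {exc}") from exc
            trees.append(tree)
    else:
        try:
            tl = dendropy.TreeList.get(path=path, schema="nexus", taxon_namespace=ns,
                                       preserve_underscores=True)
        except Exception as exc:
            raise ValueError(f"could not parse Nexus tree file {path}: {exc}") from exc
        trees = list(tl)
    if not trees:
        raise ValueError(f"no trees found in {path}")
    raws = sorted(t.taxon.label for t in trees[0].leaf_node_iter())
    labels = parse_taxon_labels(raws, species_table)
    sample = TreeSample(
        trees=trees,
        provenance=[(rep, i) for i in range(len(trees))],
        tip_labels=labels,
    )
    return sample


def write_tree_samples(sample: TreeSample, path: str, format: str = "newick") -> None:
    """Serialize a sample; Newick is one tree per line with branch lengths."""
    tl = dendropy.TreeList(sample.trees, taxon_namespace=sample.trees[0].taxon_namespace)
    schema = "newick" if format == "newick" else "nexus"
    if schema == "newick":
        tl.write(path=path, schema="newick", suppress_rooting=True,
                 unquoted_underscores=True)
    else:
        tl.write(path=path, schema="nexus", unquoted_underscores=True)


def apply_burnin(sample: TreeSample, burnin_fraction: float) -> TreeSample:
    """Drop the first ``floor(burnin_fraction * n)`` trees.

    The default convention in this pipeline is a 10% burn-in, matching the
    usual practice of discarding the first tenth of sampled MCMC states.
    """
    if not (0 <= burnin_fraction < 1):
        raise ValueError(f"burnin_fraction must be in [0, 1), got {burnin_fraction}")
    if sample.n == 0:
        raise ValueError("empty tree sample")
    k = math.floor(burnin_fraction * sample.n)
    return TreeSample(
        trees=sample.trees[k:],
        provenance=sample.provenance[k:],
        tip_labels=sample.tip_labels,
    )


def combine_replicates(samples: Sequence[TreeSample]) -> TreeSample:
    """Concatenate replicate samples (LogCombiner-style).

    All replicates must share the identical tip set; provenance keeps the
    replicate identity of every tree.
    """
    if not samples:
        raise ValueError("no samples to combine")
    first = samples[0]
    expected = first.tip_label_set()
    ns = first.trees[0].taxon_namespace if first.trees else dendropy.TaxonNamespace()
    trees: list[dendropy.Tree] = list(first.trees)
    prov: list[tuple[str, int]] = list(first.provenance)
    for i, s in enumerate(samples[1:], start=2):
        if s.tip_label_set() != expected:
            raise TipSetError(
                f"replicate 1 and replicate {i} have different tip sets: "
                f"{sorted(expected ^ s.tip_label_set())} differ"
            )
        for t in s.trees:
            if t.taxon_namespace is not ns:
                t = t.clone(depth=1)
                t.migrate_taxon_namespace(ns)
            trees.append(t)
        prov.extend(s.provenance)
    return TreeSample(trees=trees, provenance=prov, tip_labels=first.tip_labels)


def _clade_keys(tree: dendropy.Tree, col: dict[str, int], rooted: bool) -> frozenset:
    """Non-trivial clade (or bipartition) keys of one tree as bit patterns."""
    ntips = len(col)
    full = (1 << ntips) - 1
    keys = set()
    masks: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            m = 1 << col[node.taxon.label]
        else:
            m = 0
            for ch in node.child_nodes():
                m |= masks[id(ch)]
        masks[id(node)] = m
        if not node.is_leaf() and node.parent_node is not None:
            c = bin(m).count("1")
            if 1 < c < ntips:
                if rooted:
                    keys.add(m)
                else:
                    # canonical side: the one not containing tip 0
                    keys.add(m if not (m & 1) else (full ^ m))
    return frozenset(keys)


def mcc_tree(sample: TreeSample, rooted: Optional[bool] = None) -> dendropy.Tree:
    """Maximum-clade-credibility tree of the sample.

    Returns the member tree that maximizes the product of posterior clade
    frequencies, with clades counted over the whole sample — rooted clades
    when the trees are rooted, unrooted bipartitions otherwise.  Ties are
    broken by the lowest sample index.  Node heights/branch lengths of the
    winning tree are passed through unmodified.
    """
    if sample.n < 1:
        raise ValueError("empty tree sample")
    if rooted is None:
        rooted = bool(sample.trees[0].is_rooted)
    labels = sorted(sample.tip_label_set())
    col = {lab: j for j, lab in enumerate(labels)}
    per_tree = [_clade_keys(t, col, rooted) for t in sample.trees]
    counts: Counter = Counter()
    for keys in per_tree:
        counts.update(keys)
    n = sample.n
    best_i, best_score = 0, -math.inf
    for i, keys in enumerate(per_tree):
        score = sum(math.log(counts[k] / n) for k in keys)
        if score > best_score:
            best_i, best_score = i, score
    return sample.trees[best_i]


def ess(series: Sequence[float]) -> float:
    """Effective sample size of an MCMC scalar trace.

    Uses the autocorrelation-time estimator with initial-positive-sequence
    truncation: the autocorrelation sum runs over increasing lag until the
    first non-positive autocorrelation.  A constant (zero-variance) series
    is reported as ESS = length by convention.  Deterministic for a fixed
    input; the conventional acceptance gate for posterior samples is
    ESS >= 100.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 values to estimate ESS")
    xc = x - x.mean()
    var = float(np.dot(xc, xc)) / n
    if var == 0:
        return float(n)
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n] / n
    rho = acov / acov[0]
    tau = 1.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        tau += 2.0 * float(rho[k])
    return float(min(n, n / tau))
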