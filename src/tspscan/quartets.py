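"""Quartet monophyly classification and Bayes factors for trans-species
polymorphism (TSP).

The test takes four alleles at a time: two from a focal taxon group A and
two from a comparison group B.  In an unrooted tree the quartet has three
possible resolutions; only one of them places the two A alleles together.
Counting resolutions over a posterior sample of trees gives the posterior
odds for non-monophyly of A (the TSP hypothesis Hᶜ) versus monophyly (H),
and multiplying by the prior odds of H (1/2, since two of the three random
resolutions are non-monophyletic) gives the Bayes factor

    K = Pr(Hᶜ | D) / Pr(H | D) × 1/2 .

When either topology count is zero its posterior probability is set to
p = 1/(n+1) (and the complement to 1 − p), so the reported K is a bound and
is flagged as such.  K > 100 is conventionally decisive support for TSP;
K < 1 is evidence for species monophyly.  For a pair of taxon groups the
maximum K over all tested quartets is reported, since the question is
whether *any* quartet shows compelling evidence of TSP.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .trees import TreeSample

__all__ = [
    "Quartet",
    "QuartetCount",
    "BayesFactorResult",
    "NotEnoughAllelesError",
    "DECISIVE_BAYES_FACTOR",
    "quartet_topology",
    "count_topologies",
    "bayes_factor",
    "enumerate_quartets",
    "max_bayes_factor",
    "bf_matrix",
]

#: conventional "decisive" threshold; used for rendering only, never computation
DECISIVE_BAYES_FACTOR = 100.0

MONOPHYLETIC = "monophyletic"
NONMONOPHYLETIC = "nonmonophyletic"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class Quartet:
    """Two tips from group A and two from group B (all distinct)."""

    a1: str
    a2: str
    b1: str
    b2: str

    def __post_init__(self) -> None:
        tips = (self.a1, self.a2, self.b1, self.b2)
        if len(set(tips)) != 4:
            raise ValueError(f"quartet tips must be distinct: {tips}")

    @property
    def tips(self) -> tuple[str, str, str, str]:
        return (self.a1, self.a2, self.b1, self.b2)


@dataclass
class QuartetCount:
    """Topology tallies for one quartet over a tree sample."""

    n_mono: int
    n_nonmono: int
    n_uninformative: int = 0

    @property
    def n(self) -> int:
        """Number of informative trees."""
        return self.n_mono + self.n_nonmono


@dataclass
class BayesFactorResult:
    K: float
    is_lower_bound: bool
    counts: QuartetCount
    best_quartet: Optional[Quartet] = None
    n_quartets_tested: int = 1


class NotEnoughAllelesError(ValueError):
    """Fewer than two alleles available on one side of a comparison."""


def quartet_topology(tree: dendropy.Tree, q: Quartet) -> str:
    """Classify the quartet induced by four tips in one (unrooted) tree.

    Returns ``monophyletic`` iff some edge of the tree separates
    ``{a1, a2}`` from ``{b1, b2}``; ``uninformative`` iff the induced
    quartet is an unresolved star.
    """
    leaf = {t.taxon.label: t for t in tree.leaf_node_iter()}
    for tip in q.tips:
        if tip not in leaf:
            raise KeyError(f"tip {tip!r} not present in tree")
    want = set(q.tips)
    mono_pairs = ({q.a1, q.a2}, {q.b1, q.b2})
    seen_mixed = False
    masks: dict[int, set] = {}
    ntips = sum(1 for _ in tree.leaf_node_iter())
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            masks[id(node)] = {lab} if lab in want else set()
            continue
        s: set = set()
        for ch in node.child_nodes():
            s |= masks[id(ch)]
        masks[id(node)] = s
        if node.parent_node is None:
            continue
        if len(s) == 2:
            if s in mono_pairs:
                return MONOPHYLETIC
            seen_mixed = True
    return NONMONOPHYLETIC if seen_mixed else UNINFORMATIVE


def count_topologies(sample: TreeSample, q: Quartet) -> QuartetCount:
    """Tally quartet topologies over every tree of the sample (vectorized)."""
    E, tree_idx, col = sample.edge_matrix()
    for tip in q.tips:
        if tip not in col:
            raise KeyError(f"tip {tip!r} not present in the sample's tip set")
    ntrees = sample.n
    cols = [col[t] for t in q.tips]
    S = E[:, cols]  # edges × (a1, a2, b1, b2)
    two = S.sum(axis=1) == 2
    aa = S[:, 0] & S[:, 1]
    bb = S[:, 2] & S[:, 3]
    mono_edge = two & (aa | bb)
    mixed_edge = two & ~(aa | bb)
    mono_t = np.zeros(ntrees, dtype=bool)
    mixed_t = np.zeros(ntrees, dtype=bool)
    if mono_edge.any():
        mono_t[np.unique(tree_idx[mono_edge])] = True
    if mixed_edge.any():
        mixed_t[np.unique(tree_idx[mixed_edge])] = True
    n_mono = int(mono_t.sum())
    n_nonmono = int((~mono_t & mixed_t).sum())
    return QuartetCount(
        n_mono=n_mono,
        n_nonmono=n_nonmono,
        n_uninformative=ntrees - n_mono - n_nonmono,
    )


def bayes_factor(c: QuartetCount, prior_odds_H: float = 0.5) -> BayesFactorResult:
    """Bayes factor for TSP from one quartet's topology counts.

    ``K = (f_nonmono / f_mono) × prior_odds_H`` with the zero-count rule:
    a zero fraction is replaced by ``1/(n+1)`` and its complement by
    ``1 − 1/(n+1)``, and the result is flagged as a lower (or upper) bound.
    E.g. with n = 14,000 informative trees and no monophyletic ones,
    K = 14,000 × 1/2 = 7,000 and is a lower bound.
    """
    n = c.n
    if n < 1:
        raise ValueError("no informative trees: Bayes factor undefined")
    is_bound = False
    if c.n_mono == 0:
        f_mono = 1.0 / (n + 1)
        f_non = 1.0 - f_mono
        is_bound = True
    elif c.n_nonmono == 0:
        f_non = 1.0 / (n + 1)
        f_mono = 1.0 - f_non
        is_bound = True
    else:
        f_non = c.n_nonmono / n
        f_mono = c.n_mono / n
    K = (f_non / f_mono) * prior_odds_H
    return BayesFactorResult(K=K, is_lower_bound=is_bound, counts=c)


def enumerate_quartets(
    groupA_tips: Iterable[str],
    groupB_tips: Iterable[str],
    excluded: Iterable[str] = (),
    cap: int = 10_000,
    seed: int = 0,
) -> list[Quartet]:
    """All (|A| choose 2) × (|B| choose 2) quartets, deterministically
    subsampled to ``cap`` when the exhaustive set is larger.

    Tips in ``excluded`` (e.g. gene-conversion acceptors) never appear.
    Raises :class:`NotEnoughAllelesError` when either side has fewer than
    two usable alleles — at least two from each group are required.
    """
    excl = set(excluded)
    A = sorted(set(groupA_tips) - excl)
    B = sorted(set(groupB_tips) - excl)
    if len(A) < 2 or len(B) < 2:
        raise NotEnoughAllelesError(
            f"not enough alleles after exclusion (|A|={len(A)}, |B|={len(B)}; need 2+2)"
        )
    overlap = set(A) & set(B)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    apairs = list(itertools.combinations(A, 2))
    bpairs = list(itertools.combinations(B, 2))
    total = len(apairs) * len(bpairs)
    if total <= cap:
        return [Quartet(a1, a2, b1, b2) for (a1, a2) in apairs for (b1, b2) in bpairs]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(total, size=cap, replace=False)
    chosen.sort()
    nb = len(bpairs)
    out = []
    for k in chosen:
        a1, a2 = apairs[int(k) // nb]
        b1, b2 = bpairs[int(k) % nb]
        out.append(Quartet(a1, a2, b1, b2))
    return out


def max_bayes_factor(
    sample: TreeSample,
    groupA_tips: Iterable[str],
    groupB_tips: Iterable[str],
    excluded: Iterable[str] = (),
    cap: int = 10_000,
    seed: int = 0,
    prior_odds_H: float = 0.5,
) -> BayesFactorResult:
    """Maximum Bayes factor over the enumerated quartets between two groups.

    Ties are resolved in favor of the first (lowest-index) maximizing
    quartet.  The returned result records the best quartet, its counts,
    whether the maximum relied on zero-count regularization, and the number
    of quartets tested.
    """
    quartets = enumerate_quartets(groupA_tips, groupB_tips, excluded, cap, seed)
    best: Optional[BayesFactorResult] = None
    for q in quartets:
        c = count_topologies(sample, q)
        if c.n == 0:
            continue
        r = bayes_factor(c, prior_odds_H)
        if best is None or r.K > best.K:
            r.best_quartet = q
            best = r
    if best is None:
        raise ValueError("no quartet yielded informative trees")
    best.n_quartets_tested = len(quartets)
    return best


def _resolve_group(sample: TreeSample, species_codes: Iterable[str]) -> list[str]:
    codes = set(species_codes)
    return [t.raw for t in sample.tip_labels if t.species_code in codes]


def bf_matrix(
    samples: Mapping[str, TreeSample],
    comparisons: Sequence[tuple[str, Iterable[str], Iterable[str]]],
    exclusions: Optional[Mapping[str, Iterable[str]]] = None,
    cap: int = 10_000,
    seed: int = 0,
    prior_odds_H: float = 0.5,
) -> pd.DataFrame:
    """Bayes-factor table: one row per (comparison × gene region).

    ``samples`` maps region names to tree samples; each comparison is
    ``(name, species_codes_A, species_codes_B)``, resolved against each
    sample's parsed tip labels.  ``exclusions`` maps region name to tips to
    drop (typically gene-conversion acceptors for that exon).  Cells where
    a side has fewer than two alleles are emitted blank (``K`` = NaN), and
    lower-bound cells are flagged (rendered with a ``>`` prefix).
    """
    exclusions = exclusions or {}
    rows = []
    for comp_name, codesA, codesB in comparisons:
        for region, sample in samples.items():
            A = _resolve_group(sample, codesA)
            B = _resolve_group(sample, codesB)
            excl = set(exclusions.get(region, ()))
            try:
                r = max_bayes_factor(sample, A, B, excl, cap, seed, prior_odds_H)
                prefix = ""
                if r.is_lower_bound:
                    # zero monophyletic trees -> K is a lower bound (">");
                    # zero non-monophyletic trees -> an upper bound ("<")
                    prefix = ">" if r.counts.n_mono == 0 else "<"
                rows.append(
                    {
                        "comparison": comp_name,
                        "region": region,
                        "K": r.K,
                        "lower_bound": r.is_lower_bound,
                        "n_quartets": r.n_quartets_tested,
                        "best_quartet": "|".join(r.best_quartet.tips),
                        "label": prefix + f"{r.K:.3g}",
                    }
                )
            except NotEnoughAllelesError:
                rows.append(
                    {
                        "comparison": comp_name,
                        "region": region,
                        "K": float("nan"),
                        "lower_bound": False,
                        "n_quartets": 0,
                        "best_quartet": "",
                        "label": "",
                    }
                )
    return pd.DataFrame(rows)
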