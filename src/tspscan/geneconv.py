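"""Gene-conversion fragment detection, direction inference, and exclusion
lists.

Gene conversion — the unidirectional copying of a DNA tract from a donor to
an acceptor sequence — makes acceptor alleles cluster with their donors
rather than with their relatives by descent, which can mimic trans-species
polymorphism.  This module provides a simplified within-alignment ("global
inner") fragment detector in the spirit of Sawyer's runs statistic: for
every sequence pair the alignment is restricted to polymorphic columns, the
best run of consecutive matching polymorphic sites is scored, and its
significance is assessed against seeded permutations of polymorphic-column
order with a Bonferroni-style correction over pairs.  All sites are used
(not silent sites only), which can slightly overestimate tract lengths but
is robust when polymorphism is extreme.

Direction of conversion is then inferred by comparing how the two fragment
sequences cluster using sites inside versus outside the fragment (within
the same exon), and acceptor sequences — or both sequences when the
direction is undetermined — are excluded from downstream quartet tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ConversionFragment",
    "GAP_CHARS",
    "detect_fragments",
    "read_geneconv_output",
    "assign_direction",
    "exclusion_list",
    "read_fasta_alignment",
    "write_fragments",
    "read_fragments",
]

GAP_CHARS = frozenset("-.")

I_IS_ACCEPTOR = "i_is_acceptor"
J_IS_ACCEPTOR = "j_is_acceptor"
UNDETERMINED = "undetermined"

AlignmentLike = Union[Mapping[str, str], Sequence[tuple[str, str]]]


@dataclass(frozen=True)
class ConversionFragment:
    """A candidate gene-conversion tract between two aligned sequences.

    ``start``/``end`` are 1-based inclusive alignment columns; ``sim_pval``
    is the (multiple-comparison corrected) permutation p-value.
    """

    seq_i: str
    seq_j: str
    start: int
    end: int
    score: float
    sim_pval: float
    direction: str = UNDETERMINED
    region: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad fragment bounds [{self.start}, {self.end}]")
        if not (0.0 <= self.sim_pval <= 1.0):
            raise ValueError(f"sim_pval out of [0,1]: {self.sim_pval}")


def _as_dict(alignment: AlignmentLike) -> dict[str, str]:
    if hasattr(alignment, "items"):
        d = {str(k): str(v).upper() for k, v in alignment.items()}
    else:
        d = {str(k): str(v).upper() for k, v in alignment}
    lens = {len(s) for s in d.values()}
    if len(lens) > 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lens)}")
    return d


def read_fasta_alignment(path: str) -> dict[str, str]:
    """Read a gapped FASTA alignment into an ordered id → sequence map."""
    from Bio import SeqIO

    d = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    if not d:
        raise ValueError(f"no sequences in {path}")
    return _as_dict(d)


def _polymorphic_columns(seqs: dict[str, str]) -> np.ndarray:
    """Alignment columns (0-based) with >= 2 distinct non-gap residues."""
    mat = np.array([list(s) for s in seqs.values()])
    L = mat.shape[1]
    out = []
    for j in range(L):
        col = {c for c in mat[:, j] if c not in GAP_CHARS}
        if len(col) >= 2:
            out.append(j)
    return np.asarray(out, dtype=np.int64)


def _best_run(values: np.ndarray) -> tuple[float, int, int]:
    """Best-scoring contiguous segment (Kadane); returns (score, lo, hi)."""
    best, cur = -np.inf, 0.0
    lo = hi = cur_lo = 0
    for k, v in enumerate(values):
        if cur <= 0:
            cur = float(v)
            cur_lo = k
        else:
            cur += float(v)
        if cur > best:
            best, lo, hi = cur, cur_lo, k
    return best, lo, hi


def _perm_best_scores(match: np.ndarray, penalty: Optional[float], n_perms: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Best segment score per permuted row, vectorized over permutations."""
    M = np.tile(match, (n_perms, 1))
    M = rng.permuted(M, axis=1)
    if penalty is None:
        # longest run of consecutive matches
        run = np.zeros(M.shape[0], dtype=np.int64)
        best = np.zeros(M.shape[0], dtype=np.int64)
        for j in range(M.shape[1]):
            run = np.where(M[:, j], run + 1, 0)
            best = np.maximum(best, run)
        return best.astype(float)
    V = np.where(M, 1.0, -penalty)
    cur = np.zeros(V.shape[0])
    best = np.full(V.shape[0], -np.inf)
    for j in range(V.shape[1]):
        cur = np.where(cur <= 0, V[:, j], cur + V[:, j])
        best = np.maximum(best, cur)
    return best


def detect_fragments(
    alignment: AlignmentLike,
    n_perms: int = 10_000,
    mismatch_penalty: Optional[float] = None,
    seed: int = 0,
    alpha: float = 0.05,
    region: str = "",
) -> list[ConversionFragment]:
    """Detect candidate gene-conversion fragments between all sequence pairs.

    For each pair, the alignment is restricted to polymorphic columns where
    both sequences are ungapped.  With the default ``mismatch_penalty=None``
    a fragment is the longest run of consecutive matching polymorphic sites
    (no mismatches allowed within a run); a finite penalty instead scores
    maximal segments at +1 per match and −penalty per mismatch.  The best
    observed score is compared with best scores over ``n_perms`` seeded
    permutations of polymorphic-column order; the permutation p-value is
    Bonferroni-corrected across pairs, and fragments with corrected
    p < ``alpha`` are returned with bounds mapped back to alignment columns
    (1-based inclusive).  Deterministic for a fixed seed.
    """
    if n_perms < 100:
        raise ValueError("n_perms must be >= 100")
    seqs = _as_dict(alignment)
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences to define polymorphic sites")
    ids = sorted(seqs)
    poly = _polymorphic_columns(seqs)
    if poly.size < 2:
        return []
    arr = {i: np.array(list(seqs[i]))[poly] for i in ids}
    pairs = list(itertools.combinations(ids, 2))
    n_pairs = len(pairs)
    frags: list[ConversionFragment] = []
    for pi, (i, j) in enumerate(pairs):
        si, sj = arr[i], arr[j]
        ok = np.array([c not in GAP_CHARS for c in si]) & \
             np.array([c not in GAP_CHARS for c in sj])
        cols = poly[ok]
        if cols.size < 2:
            continue
        match = (si[ok] == sj[ok])
        if match.all() or not match.any():
            continue  # no run structure to test
        if mismatch_penalty is None:
            # pure runs: mismatches terminate a segment outright
            obs, lo, hi = _best_run(np.where(match, 1.0, -np.inf))
        else:
            obs, lo, hi = _best_run(np.where(match, 1.0, -float(mismatch_penalty)))
        rng = np.random.default_rng(np.random.SeedSequence([seed, pi]))
        perm_best = _perm_best_scores(match, mismatch_penalty, n_perms, rng)
        p = (1.0 + float(np.sum(perm_best >= obs))) / (n_perms + 1.0)
        p_corr = min(1.0, p * n_pairs)
        if p_corr < alpha and obs > 0:
            frags.append(
                ConversionFragment(
                    seq_i=i,
                    seq_j=j,
                    start=int(cols[lo]) + 1,
                    end=int(cols[hi]) + 1,
                    score=float(obs),
                    sim_pval=p_corr,
                    region=region,
                )
            )
    return frags


def read_geneconv_output(path: str) -> list[ConversionFragment]:
    """Read global-inner (GI) rows from a GENECONV ``.frags``-style table.

    Expected whitespace-separated columns per GI row:
    ``GI  name1;name2  sim_pval  ka_pval  begin  end  ...``.  Only GI rows
    are parsed; comment lines (``#``) and other row types are ignored.
    """
    frags: list[ConversionFragment] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            tok = s.split()
            if tok[0] != "GI":
                continue
            try:
                names = tok[1].split(";")
                if len(names) != 2:
                    raise ValueError("pair field must be 'name1;name2'")
                sim_pval = float(tok[2])
                start, end = int(tok[4]), int(tok[5])
                frags.append(
                    ConversionFragment(
                        seq_i=names[0], seq_j=names[1],
                        start=start, end=end,
                        score=float("nan"), sim_pval=sim_pval,
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"unparseable GI row at line {lineno} of {path}: {exc}") from exc
    return frags


_FRAG_COLS = ["seq_i", "seq_j", "start", "end", "score", "sim_pval", "direction", "region"]


def write_fragments(frags: Sequence[ConversionFragment], path: str) -> None:
    pd.DataFrame([vars(f) for f in frags], columns=_FRAG_COLS).to_csv(path, sep="\t", index=False)


def read_fragments(path: str) -> list[ConversionFragment]:
    df = pd.read_csv(path, sep="\t", dtype={"region": str}, keep_default_na=False)
    return [
        ConversionFragment(
            seq_i=r.seq_i, seq_j=r.seq_j, start=int(r.start), end=int(r.end),
            score=float(r.score), sim_pval=float(r.sim_pval),
            direction=r.direction, region=str(r.region),
        )
        for r in df.itertuples()
    ]


def _p_distance(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.array([c not in GAP_CHARS for c in a]) & \
         np.array([c not in GAP_CHARS for c in b])
    n = int(ok.sum())
    if n == 0:
        return float("inf")
    return float(np.sum(a[ok] != b[ok])) / n


def _nearest_neighbor(focal: str, others: Iterable[str], mat: dict[str, np.ndarray],
                      cols: np.ndarray) -> Optional[str]:
    """Closest sequence to ``focal`` by p-distance over ``cols``; ties broken
    lexicographically for determinism."""
    best: Optional[tuple[float, str]] = None
    for o in sorted(others):
        d = _p_distance(mat[focal][cols], mat[o][cols])
        if not np.isfinite(d):
            continue
        if best is None or (d, o) < best:
            best = (d, o)
    return None if best is None else best[1]


def assign_direction(
    alignment: AlignmentLike,
    fragment: ConversionFragment,
    region_bounds: tuple[int, int],
    min_informative: int = 5,
) -> ConversionFragment:
    """Infer donor/acceptor direction for a fragment.

    For each member of the pair, the nearest neighbor (minimum p-distance,
    among sequences other than the pair itself) is computed twice: over
    polymorphic columns inside the fragment bounds and over polymorphic
    columns outside the fragment but within ``region_bounds`` (the exon).
    A converted acceptor carries the donor's tract, so inside the fragment
    it clusters with the donor's relatives while outside it clusters with
    its own: the member whose nearest neighbor changes between inside and
    outside — while the partner's does not — is labeled the acceptor.  If
    the signature holds for both members or for neither, or either side has
    fewer than ``min_informative`` polymorphic columns, the direction is
    undetermined.
    """
    lo, hi = region_bounds
    if not (1 <= lo <= fragment.start and fragment.end <= hi):
        raise ValueError(
            f"region bounds [{lo}, {hi}] must contain fragment "
            f"[{fragment.start}, {fragment.end}]"
        )
    seqs = _as_dict(alignment)
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences to infer direction")
    for sid in (fragment.seq_i, fragment.seq_j):
        if sid not in seqs:
            raise KeyError(f"fragment sequence {sid!r} not in alignment")
    mat = {i: np.array(list(s)) for i, s in seqs.items()}
    poly = _polymorphic_columns(seqs)
    inside = poly[(poly >= fragment.start - 1) & (poly <= fragment.end - 1)]
    outside = poly[((poly >= lo - 1) & (poly < fragment.start - 1))
                   | ((poly > fragment.end - 1) & (poly <= hi - 1))]
    if inside.size < min_informative or outside.size < min_informative:
        return replace(fragment, direction=UNDETERMINED)
    pair = {fragment.seq_i, fragment.seq_j}
    others = [i for i in seqs if i not in pair]
    moved = {}
    for sid in (fragment.seq_i, fragment.seq_j):
        nn_in = _nearest_neighbor(sid, others, mat, inside)
        nn_out = _nearest_neighbor(sid, others, mat, outside)
        if nn_in is None or nn_out is None:
            return replace(fragment, direction=UNDETERMINED)
        moved[sid] = nn_in != nn_out
    if moved[fragment.seq_i] and not moved[fragment.seq_j]:
        return replace(fragment, direction=I_IS_ACCEPTOR)
    if moved[fragment.seq_j] and not moved[fragment.seq_i]:
        return replace(fragment, direction=J_IS_ACCEPTOR)
    return replace(fragment, direction=UNDETERMINED)


def exclusion_list(fragments: Iterable[ConversionFragment]) -> dict[str, set[str]]:
    """Per-region sequence exclusions implied by significant fragments.

    Acceptor sequences are excluded for the fragment's region; when the
    direction is undetermined, both sequences are excluded.  Monotone:
    adding fragments never removes exclusions.
    """
    out: dict[str, set[str]] = {}
    for f in fragments:
        bucket = out.setdefault(f.region, set())
        if f.direction == I_IS_ACCEPTOR:
            bucket.add(f.seq_i)
        elif f.direction == J_IS_ACCEPTOR:
            bucket.add(f.seq_j)
        else:
            bucket.update((f.seq_i, f.seq_j))
    return out
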