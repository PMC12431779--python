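"""Per-site evolutionary-rate normalization and summaries.

Site-partitioned Bayesian samplers emit a relative substitution rate per
alignment column per sampled state.  Rates are averaged over states, then
normalized against a "gappy" baseline: the mean rate among columns that are
gapped in every designated backbone allele (mostly-gap columns behave
similarly across runs and serve as a run-internal reference).  Normalized
rates are expressed as base-2 log fold changes — fold change >= 1 means
more than twice the baseline rate, > 2 means more than four times.

Downstream summaries: per-codon (amino-acid) rates as the mean of the three
member columns, per-exon counts of rapidly-evolving sites with Fisher exact
comparisons against the pooled non-binding-region exons, and an OLS
regression of trait-association counts on amino-acid rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SiteRatePosterior",
    "RateProfile",
    "RAPID_PRESETS",
    "read_rate_posterior",
    "write_rate_posterior",
    "mean_site_rates",
    "identify_baseline_sites",
    "fold_changes",
    "codon_rates",
    "exon_rapid_summary",
    "association_regression",
]

GAP_CHARS = frozenset("-.")

#: named rapid-site thresholds: (fold-change cutoff, inclusive comparison)
RAPID_PRESETS: dict[str, tuple[float, bool]] = {
    "twice": (1.0, True),      # fold change >= 1  (more than twice baseline)
    "fourfold": (2.0, False),  # fold change > 2   (more than four times)
}


@dataclass
class SiteRatePosterior:
    """Posterior samples of per-column relative rates (state × column)."""

    rates: np.ndarray
    column_ids: Sequence[int]
    provenance: Optional[Sequence] = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2:
            raise ValueError("rates must be a (state × column) matrix")
        if self.rates.shape[1] != len(self.column_ids):
            raise ValueError("column_ids length must match the rate matrix")
        if not np.all(self.rates > 0):
            raise ValueError("all rates must be > 0")

    @property
    def n_states(self) -> int:
        return self.rates.shape[0]


@dataclass
class RateProfile:
    """Posterior-mean rates with baseline normalization per column."""

    mean_rate: np.ndarray
    baseline_mask: np.ndarray
    baseline_mean: float
    fold_change: np.ndarray
    column_ids: Optional[Sequence[int]] = None


def read_rate_posterior(path: str) -> SiteRatePosterior:
    """TSV with a header of column ids and one row per sampled state.

    Burn-in is assumed to have been applied upstream.
    """
    df = pd.read_csv(path, sep="\t")
    return SiteRatePosterior(rates=df.to_numpy(dtype=float),
                             column_ids=[int(c) for c in df.columns])


def write_rate_posterior(post: SiteRatePosterior, path: str) -> None:
    pd.DataFrame(post.rates, columns=[str(c) for c in post.column_ids]).to_csv(
        path, sep="\t", index=False
    )


def mean_site_rates(post: SiteRatePosterior) -> np.ndarray:
    """Arithmetic mean of each column's rate over all sampled states."""
    if post.n_states < 1:
        raise ValueError("posterior has no states")
    return post.rates.mean(axis=0)


def identify_baseline_sites(
    alignment: Union[Mapping[str, str], Sequence[tuple[str, str]]],
    backbone_ids: Sequence[str],
) -> np.ndarray:
    """Boolean mask of columns gapped in ALL backbone sequences."""
    seqs = dict(alignment.items()) if hasattr(alignment, "items") else dict(alignment)
    if not backbone_ids:
        raise ValueError("at least one backbone id is required")
    for b in backbone_ids:
        if b not in seqs:
            raise KeyError(f"backbone sequence {b!r} not in alignment")
    L = len(next(iter(seqs.values())))
    mask = np.ones(L, dtype=bool)
    for b in backbone_ids:
        s = seqs[b]
        if len(s) != L:
            raise ValueError(f"backbone {b!r} has length {len(s)} != {L}")
        mask &= np.array([c in GAP_CHARS for c in s])
    return mask


def fold_changes(means: np.ndarray, baseline_mask: np.ndarray,
                 column_ids: Optional[Sequence[int]] = None) -> RateProfile:
    """Base-2 log fold change of each column's mean rate over the baseline
    mean (mean rate across baseline-masked columns).

    By construction the mean of ``2**fold_change`` over baseline columns is
    exactly 1, and fold changes are invariant to rescaling all rates.
    """
    means = np.asarray(means, dtype=float)
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    if means.shape != baseline_mask.shape:
        raise ValueError("means and baseline_mask must have the same length")
    if not baseline_mask.any():
        raise ValueError("no baseline sites")
    baseline_mean = float(means[baseline_mask].mean())
    if baseline_mean <= 0:
        raise ValueError("baseline mean rate must be positive")
    fc = np.log2(means / baseline_mean)
    return RateProfile(
        mean_rate=means,
        baseline_mask=baseline_mask,
        baseline_mean=baseline_mean,
        fold_change=fc,
        column_ids=column_ids,
    )


def codon_rates(
    values: np.ndarray,
    cds_map: Mapping[int, tuple[int, int]],
) -> dict[int, float]:
    """Per-amino-acid values as the mean of the three codon member columns.

    ``cds_map`` maps 0-based alignment column → (codon index, position in
    codon 0..2).  Codons missing any of their three columns, or whose
    member values are NaN (e.g. gap columns), are emitted as NaN.
    """
    by_codon: dict[int, dict[int, float]] = {}
    values = np.asarray(values, dtype=float)
    for col, (ci, pos) in cds_map.items():
        if not 0 <= pos <= 2:
            raise ValueError(f"position-in-codon must be 0..2, got {pos}")
        by_codon.setdefault(ci, {})[pos] = values[col]
    out: dict[int, float] = {}
    for ci, members in sorted(by_codon.items()):
        if len(members) != 3 or any(np.isnan(v) for v in members.values()):
            out[ci] = float("nan")
        else:
            out[ci] = float(np.mean([members[p] for p in (0, 1, 2)]))
    return out


def exon_rapid_summary(
    profile: RateProfile,
    exon_bounds: Sequence[tuple[str, int, int]],
    threshold: float = 2.0,
    inclusive: bool = False,
    pbr_exons: Iterable[str] = ("2", "3"),
    exclude_baseline: bool = True,
) -> pd.DataFrame:
    """Per-exon rapid-site counts with Fisher exact tests vs the pooled
    "other" exons.

    ``exon_bounds`` is a list of ``(name, start, end)`` with 1-based
    inclusive, disjoint alignment-column intervals.  A site is rapid when
    its fold change exceeds ``threshold`` (``>=`` when ``inclusive``; the
    named presets in :data:`RAPID_PRESETS` cover the twice/fourfold
    conventions).  The "other" pool consists of exons not named in
    ``pbr_exons`` (for Class I genes pass ``("2", "3", "4")``); each exon is
    compared two-sided against the pool excluding itself.  Baseline
    (mostly-gap) columns are not counted as sites unless
    ``exclude_baseline=False``.
    """
    fc = profile.fold_change
    usable = ~profile.baseline_mask if exclude_baseline else np.ones_like(fc, dtype=bool)
    rapid = (fc >= threshold) if inclusive else (fc > threshold)
    covered = np.zeros(fc.size, dtype=bool)
    per_exon = {}
    pbr = set(pbr_exons)
    for name, lo, hi in exon_bounds:
        if not (1 <= lo <= hi <= fc.size):
            raise ValueError(f"exon {name!r} bounds [{lo}, {hi}] outside alignment")
        sel = np.zeros(fc.size, dtype=bool)
        sel[lo - 1: hi] = True
        if (sel & covered).any():
            raise ValueError(f"exon {name!r} overlaps a previous exon")
        covered |= sel
        sel &= usable
        n_sites = int(sel.sum())
        per_exon[name] = (n_sites, int((rapid & sel).sum()))
    rows = []
    for name, lo, hi in exon_bounds:
        n_sites, n_rapid = per_exon[name]
        if n_sites == 0:
            continue  # empty exon: excluded from the summary
        pool = [e for e in per_exon if e not in pbr and e != name]
        pool_sites = sum(per_exon[e][0] for e in pool)
        pool_rapid = sum(per_exon[e][1] for e in pool)
        if pool_sites > 0:
            _, p = stats.fisher_exact(
                [[n_rapid, n_sites - n_rapid],
                 [pool_rapid, pool_sites - pool_rapid]],
                alternative="two-sided",
            )
        else:
            p = float("nan")
        rows.append(
            {
                "exon": name,
                "n_sites": n_sites,
                "n_rapid": n_rapid,
                "proportion": n_rapid / n_sites,
                "fisher_p_vs_other": p,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pvalue: float
    n: int


def association_regression(
    aa_rates: Mapping[int, float],
    assoc_counts: Mapping[int, float],
) -> RegressionResult:
    """OLS of per-position trait-association counts on evolutionary rate.

    Positions present in both inputs with finite values are used; the
    p-value is the two-sided t-test on the slope.
    """
    import statsmodels.api as sm

    pos = sorted(set(aa_rates) & set(assoc_counts))
    x = np.array([aa_rates[p] for p in pos], dtype=float)
    y = np.array([assoc_counts[p] for p in pos], dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 positions with both rate and count, got {x.size}")
    if np.allclose(x, x[0]):
        raise ValueError("zero-variance predictor: slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        pvalue=float(res.pvalues[1]),
        n=int(x.size),
    )
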