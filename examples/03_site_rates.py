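"""Per-site rate normalization and rapid-site summaries.

Builds a synthetic site-rate posterior with planted multipliers (0.5x, 1x,
4x against a mostly-gap baseline), normalizes posterior-mean rates to
base-2 log fold changes, summarizes rapid sites per exon, and regresses
synthetic trait-association counts on per-codon rates.
"""

import numpy as np

from tspscan import (
    association_regression,
    codon_rates,
    exon_rapid_summary,
    fold_changes,
    mean_site_rates,
    simulate_rate_posterior,
    RAPID_PRESETS,
)

# 90 coding columns in three 30-column "exons", plus 30 baseline columns
truth = np.concatenate([
    np.full(30, 1.0),   # exon 1: background
    np.full(30, 4.0),   # exon 2: peptide-binding, fast
    np.full(30, 0.5),   # exon 5: conserved
    np.ones(30),        # mostly-gap baseline columns
])
post, _ = simulate_rate_posterior(truth, n_states=1000, noise_sigma=0.2, seed=11)

baseline_mask = np.zeros(truth.size, bool)
baseline_mask[90:] = True
profile = fold_changes(mean_site_rates(post), baseline_mask)
print(f"baseline mean rate: {profile.baseline_mean:.3f} "
      f"(mean 2^fold_change over baseline = "
      f"{np.mean(2.0 ** profile.fold_change[baseline_mask]):.6f})")
print(f"median fold change per exon: "
      f"exon1 {np.median(profile.fold_change[0:30]):+.2f}, "
      f"exon2 {np.median(profile.fold_change[30:60]):+.2f}, "
      f"exon5 {np.median(profile.fold_change[60:90]):+.2f}")

thr, inclusive = RAPID_PRESETS["fourfold"]
summary = exon_rapid_summary(
    profile,
    exon_bounds=[("1", 1, 30), ("2", 31, 60), ("5", 61, 90)],
    threshold=thr, inclusive=inclusive, pbr_exons=("2",),
)
print()
print(summary.to_string(index=False))

# per-codon rates and a synthetic association-count regression
cds_map = {col: (col // 3, col % 3) for col in range(90)}
aa = codon_rates(profile.fold_change, cds_map)
rng = np.random.default_rng(12)
counts = {pos: float(rng.poisson(max(rate + 1.5, 0.05) * 2))
          for pos, rate in aa.items()}
res = association_regression(aa, counts)
print()
print(f"association counts ~ rate: slope {res.slope:.2f}, p = {res.pvalue:.2e} "
      f"({res.n} amino acids)")
print()
print("Fold change 2 means a site evolves at four times the baseline rate;")
print("the planted fast exon shows the highest rapid-site proportion, and")
print("association counts rise with per-codon rate by construction.")
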