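"""Mapping evolutionary rates onto a peptide-binding structure.

Generates a toy PDB structure whose groove residues sit < 4 Å from a bound
peptide, assigns fast rates to groove residues, and regresses rate on the
per-residue minimum atom-atom distance to the peptide — the signature of
binding-site-driven rapid evolution is a negative slope.
"""

import tempfile

import numpy as np

from tspscan import (
    align_to_structure,
    average_distances,
    chain_sequence,
    map_distances,
    min_distance_to_peptide,
    rate_distance_regression,
    read_structure,
    residue_rate_table,
    synth_structure,
)

groove = list(range(10, 40))
pdb_text, truth = synth_structure(
    n_residues=150, peptide_length=9, groove_positions=groove, seed=4
)
with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
    fh.write(pdb_text)
record = read_structure(fh.name)

dists = min_distance_to_peptide(record, mhc_chains=["A"], peptide_chain="P")["A"]
print(f"structure: {len(record.chains['A'])} MHC residues, "
      f"{len(record.chains['P'])}-mer peptide")
print(f"groove residues within 4 A: "
      f"{sum(dists[p - 1] < 4 for p in groove)}/{len(groove)}; "
      f"non-groove minimum distance: "
      f"{min(d for i, d in enumerate(dists) if (i + 1) not in set(groove)):.1f} A")

# rates: fold change ~2 at groove residues, ~0 elsewhere, with noise
rng = np.random.default_rng(5)
rates = {i + 1: (2.0 if (i + 1) in set(groove) else 0.0) + rng.normal(0, 0.3)
         for i in range(150)}

pos_map = align_to_structure(truth["mhc_sequence"], chain_sequence(record, "A"))
table = residue_rate_table(rates, average_distances([map_distances(pos_map, dists)]))
slope, pval = rate_distance_regression(table)
print(f"rate ~ distance regression: slope {slope:.3f} per A, p = {pval:.2e}")
print()
print("A negative slope means rapidly-evolving residues cluster near the")
print("bound peptide, as expected when selection acts on peptide binding.")
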