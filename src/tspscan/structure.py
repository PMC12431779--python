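"""Mapping evolutionary rates onto peptide-binding protein structures.

Nucleotide alignments are translated, aligned to the amino-acid sequence of
a structure's MHC chain, and per-codon rates are carried onto residues.
For every MHC-chain residue the minimum Euclidean distance over all
(residue atom × peptide-chain atom) pairs is computed and averaged over
alternative structures of the same protein, and rate is regressed on
distance — rapidly-evolving residues of classical MHC proteins are
expected to sit close to the bound peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "StructureRecord",
    "PositionMap",
    "translate_cds",
    "align_to_structure",
    "read_structure",
    "chain_sequence",
    "min_distance_to_peptide",
    "map_distances",
    "average_distances",
    "rate_distance_regression",
    "residue_rate_table",
]

GAP_CHARS = frozenset("-.")

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Atom:
    name: str
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Residue:
    number: int          # author-assigned residue number
    code: str            # one-letter residue type ('X' for nonstandard)
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class StructureRecord:
    """Coordinates grouped by chain; residues kept in file order."""

    structure_id: str
    chains: dict[str, list[Residue]]


def translate_cds(seq: str, frame: int = 0) -> str:
    """Translate a (possibly gapped) nucleotide sequence.

    Codons containing any gap character translate to ``-``; codons with an
    ambiguous base translate to ``X``; stop codons are ``*``.  A trailing
    partial codon is dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame offset must be 0, 1 or 2, got {frame}")
    s = seq.upper().replace("U", "T")
    out = []
    for k in range(frame, len(s) - 2, 3):
        codon = s[k:k + 3]
        if any(c in GAP_CHARS for c in codon):
            out.append("-")
        elif codon in _CODON_TABLE:
            out.append(_CODON_TABLE[codon])
        else:
            out.append("X")
    return "".join(out)


@dataclass
class PositionMap:
    """One-to-one map from 1-based query positions to 0-based residue
    indices of a structure chain, with alignment identity bookkeeping."""

    mapping: dict[int, int]
    identity: float
    low_identity: bool


def align_to_structure(
    query: str,
    chain_seq: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
    identity_warn: float = 0.30,
) -> PositionMap:
    """Global pairwise alignment of a translated query to a structure-chain
    sequence; gap residues in the query are stripped before aligning and
    their positions never map.

    Identity below ``identity_warn`` (fraction of matching aligned pairs)
    sets the ``low_identity`` flag — usually a sign of the wrong chain.
    """
    from Bio import Align

    if not query or not chain_seq:
        raise ValueError("both sequences must be nonempty")
    # strip gap residues but remember original positions (1-based)
    kept = [(i + 1, c) for i, c in enumerate(query) if c not in GAP_CHARS]
    q = "".join(c for _, c in kept)
    if not q:
        raise ValueError("query has no ungapped residues")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(q, chain_seq)[0]
    mapping: dict[int, int] = {}
    n_pairs = 0
    n_match = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        for off in range(qe - qs):
            qi, si = qs + off, ss + off
            mapping[kept[qi][0]] = si
            n_pairs += 1
            if q[qi] == chain_seq[si]:
                n_match += 1
    identity = n_match / n_pairs if n_pairs else 0.0
    return PositionMap(mapping=mapping, identity=identity,
                       low_identity=identity < identity_warn)


def read_structure(path: str, structure_id: Optional[str] = None,
                   keep_het_chains: Iterable[str] = ()) -> StructureRecord:
    """Read a PDB (or mmCIF) coordinate file into a :class:`StructureRecord`.

    Only the first model is used; waters are always dropped; heteroatom
    residues are dropped except in chains named in ``keep_het_chains``
    (declare the peptide chain there if it is deposited as HETATM).
    Alternate locations are resolved to the highest-occupancy conformer
    (ties: lowest altloc letter).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    keep_het = set(keep_het_chains)
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            name = res.name.strip().upper()
            if name == "HOH":
                continue
            is_standard = name in _THREE_TO_ONE
            if not is_standard and res.het_flag == "H" and chain.name not in keep_het:
                continue
            best: dict[str, Atom] = {}
            best_key: dict[str, tuple[float, str]] = {}
            for atom in res:
                alt = atom.altloc or ""
                key = (-float(atom.occ), alt if alt else "A")
                if atom.name not in best or key < best_key[atom.name]:
                    best[atom.name] = Atom(atom.name, atom.pos.x, atom.pos.y, atom.pos.z)
                    best_key[atom.name] = key
            if best:
                residues.append(
                    Residue(
                        number=res.seqid.num,
                        code=_THREE_TO_ONE.get(name, "X"),
                        atoms=list(best.values()),
                    )
                )
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise ValueError(f"no usable chains in {path}")
    return StructureRecord(structure_id=structure_id or st.name or str(path), chains=chains)


def chain_sequence(record: StructureRecord, chain: str) -> str:
    if chain not in record.chains:
        raise KeyError(f"chain {chain!r} not in structure {record.structure_id}")
    return "".join(r.code for r in record.chains[chain])


def min_distance_to_peptide(
    record: StructureRecord,
    mhc_chains: Sequence[str],
    peptide_chain: str,
) -> dict[str, np.ndarray]:
    """Per-residue minimum atom-atom distance (Å) to the peptide chain.

    For each residue of each MHC chain, the minimum Euclidean distance over
    all pairs of (residue atom, peptide atom).
    """
    if peptide_chain not in record.chains or not record.chains[peptide_chain]:
        raise ValueError(f"peptide chain {peptide_chain!r} empty or absent")
    pep_coords = np.array(
        [a.xyz for res in record.chains[peptide_chain] for a in res.atoms]
    )
    tree = cKDTree(pep_coords)
    out: dict[str, np.ndarray] = {}
    for ch in mhc_chains:
        if ch not in record.chains:
            raise KeyError(f"MHC chain {ch!r} not in structure {record.structure_id}")
        dists = []
        for res in record.chains[ch]:
            coords = np.array([a.xyz for a in res.atoms])
            d, _ = tree.query(coords)
            dists.append(float(np.min(d)))
        out[ch] = np.asarray(dists)
    return out


def map_distances(pos_map: PositionMap, distances: np.ndarray) -> dict[int, float]:
    """Compose a query→residue position map with per-residue distances."""
    out = {}
    for pos, ridx in pos_map.mapping.items():
        if 0 <= ridx < len(distances):
            out[pos] = float(distances[ridx])
    return out


def average_distances(per_structure: Sequence[Mapping[int, float]]) -> pd.DataFrame:
    """Mean per-position distance over structures where the position is
    resolved; positions resolved in no structure are omitted.

    Returns a DataFrame with columns ``position``, ``min_dist``,
    ``n_structures``; invariant under the order of structures.
    """
    if not per_structure:
        raise ValueError("need at least one structure")
    acc: dict[int, list[float]] = {}
    for dmap in per_structure:
        for pos, d in dmap.items():
            acc.setdefault(int(pos), []).append(float(d))
    rows = [
        {"position": pos, "min_dist": float(np.mean(v)), "n_structures": len(v)}
        for pos, v in sorted(acc.items())
    ]
    return pd.DataFrame(rows)


def residue_rate_table(
    aa_rates: Mapping[int, float],
    distances: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-position rates with averaged distances into the final
    residue map (columns: position, rate, min_dist, n_structures)."""
    rows = []
    for r in distances.itertuples():
        rate = aa_rates.get(int(r.position))
        if rate is None or not np.isfinite(rate):
            continue
        rows.append(
            {"position": int(r.position), "rate": float(rate),
             "min_dist": float(r.min_dist), "n_structures": int(r.n_structures)}
        )
    return pd.DataFrame(rows)


def rate_distance_regression(residue_map: pd.DataFrame) -> tuple[float, float]:
    """OLS slope (rate per Å) and two-sided p-value of rate on distance."""
    import statsmodels.api as sm

    if len(residue_map) < 3:
        raise ValueError("need >= 3 residues for the regression")
    x = residue_map["min_dist"].to_numpy(dtype=float)
    y = residue_map["rate"].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero-variance distance: slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.pvalues[1])
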