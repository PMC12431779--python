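"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis consumes output of external samplers or
databases (posterior tree samples, site-rate posteriors, alignments, PDB
structures).  This module generates all of them at desk scale with known
ground truth, so parameter-recovery and calibration tests can score every
operation without downloads:

* posterior tree sets under species-monophyly versus trans-species
  polymorphism (TSP) genealogies, with NNI topology-sampling noise;
* alignments evolved under a Jukes-Cantor process with planted per-column
  rate classes, mostly-gap baseline columns, and injected gene-conversion
  tracts;
* site-rate posteriors with multiplicative lognormal sampling noise;
* toy single-atom-per-residue PDB structures with a peptide chain seated
  in a binding groove.

All generators are seed-deterministic: identical configuration and seed
give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import dendropy
import numpy as np

from .rates import SiteRatePosterior
from .trees import TreeSample

__all__ = [
    "ScenarioConfig",
    "DEFAULT_SPECIES_TREE",
    "simulate_posterior_sample",
    "simulate_alignment",
    "inject_gene_conversion",
    "simulate_rate_posterior",
    "synth_structure",
]

#: default species phylogeny: human, chimpanzee, gorilla, rhesus macaque,
#: with split depths in arbitrary time units
DEFAULT_SPECIES_TREE = "(((HLA:6.0,Patr:6.0):2.0,Gogo:8.0):24.0,Mamu:32.0)"

GAP = "-"
_BASES = np.array(list("ACGT"))

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class ScenarioConfig:
    """Configuration of a synthetic posterior tree sample.

    ``monophyly`` emulates neutral lineage sorting (each species' alleles
    coalesce within the species); ``tsp`` first assigns alleles to
    ``n_lineages`` ancient allelic lineages whose splits predate all
    species splits, producing lineage-major, species-minor clades.  Each
    emitted tree is independently perturbed by one random
    nearest-neighbor-interchange (NNI) move with probability ``epsilon``.
    """

    scenario: str = "monophyly"
    species_tree: str = DEFAULT_SPECIES_TREE
    n_alleles_per_species: Union[int, Mapping[str, int]] = 3
    n_lineages: int = 2
    epsilon: float = 0.0
    n_trees: int = 200
    seed: int = 0
    within_scale: float = 0.3   # scale of within-species coalescence lengths

    def __post_init__(self) -> None:
        if self.scenario not in ("monophyly", "tsp"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "tsp" and self.n_lineages < 2:
            raise ValueError("tsp scenario requires n_lineages >= 2")
        if not (0 <= self.epsilon < 0.5):
            raise ValueError("epsilon must be in [0, 0.5): larger noise would swamp the signal")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def _species_topology(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick + ";", schema="newick",
                             preserve_underscores=True)


def _random_join(items: list[str], rng: np.random.Generator, scale: float) -> str:
    """Random binary topology over pre-rendered newick items."""
    items = list(items)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(int(j))
        a = items.pop(int(i))
        la = rng.exponential(scale) + 1e-3
        lb = rng.exponential(scale) + 1e-3
        items.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return items[0]


def _render_species_subtree(
    node: dendropy.Node,
    alleles: Mapping[str, Sequence[str]],
    rng: np.random.Generator,
    within_scale: float,
) -> Optional[str]:
    """Newick (lengthless at the top) of the species subtree restricted to
    species with alleles, with each species leaf replaced by a random
    within-species allele subtree."""
    if node.is_leaf():
        sp = node.taxon.label
        labs = list(alleles.get(sp, ()))
        if not labs:
            return None
        return _random_join(labs, rng, within_scale)
    parts = []
    for ch in node.child_nodes():
        sub = _render_species_subtree(ch, alleles, rng, within_scale)
        if sub is None:
            continue
        el = ch.edge.length if ch.edge.length is not None else 1.0
        parts.append((sub, el))
    if not parts:
        return None
    if len(parts) == 1:
        # collapse unary node; keep the child's rendered form
        sub, _ = parts[0]
        return sub
    return "(" + ",".join(f"{s}:{l:.6f}" for s, l in parts) + ")"


def _nni(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    """One random NNI move in place."""
    cand = []
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        if nd.child_nodes():
            cand.append(nd)
    if not cand:
        return
    v = cand[int(rng.integers(len(cand)))]
    u = v.parent_node
    sibs = [c for c in u.child_nodes() if c is not v]
    if not sibs:
        return
    s = sibs[int(rng.integers(len(sibs)))]
    kids = v.child_nodes()
    x = kids[int(rng.integers(len(kids)))]
    u.remove_child(s)
    v.remove_child(x)
    u.add_child(x)
    v.add_child(s)


def _allele_labels(cfg: ScenarioConfig, species: list[str]) -> dict[str, list[str]]:
    if isinstance(cfg.n_alleles_per_species, Mapping):
        counts = {sp: int(cfg.n_alleles_per_species.get(sp, 0)) for sp in species}
    else:
        counts = {sp: int(cfg.n_alleles_per_species) for sp in species}
    if any(c < 1 for c in counts.values()):
        raise ValueError("every species needs at least one allele")
    return {sp: [f"{sp}_B{i + 1:02d}" for i in range(counts[sp])] for sp in species}


def simulate_posterior_sample(cfg: ScenarioConfig) -> tuple[TreeSample, dict]:
    """Emulate a posterior sample of allele genealogies.

    Under ``monophyly`` every emitted tree keeps each species' alleles
    monophyletic (within-species resolutions are re-drawn per tree to mimic
    topology-sampling variation); under ``tsp`` alleles are assigned
    round-robin to ancient lineages whose splits are deeper than all
    species splits.  Each tree is then perturbed by one random NNI with
    probability ``epsilon``.  Returns the sample and a truth record with
    each allele's species and (for TSP) lineage, plus the per-tree
    perturbation flags.
    """
    rng = np.random.default_rng(cfg.seed)
    sp_tree = _species_topology(cfg.species_tree)
    species = [t.label for t in sp_tree.taxon_namespace]
    alleles = _allele_labels(cfg, species)
    depth = max(
        sum(
            (a.edge.length or 1.0)
            for a in [nd, *nd.ancestor_iter()]
            if a.parent_node is not None
        )
        for nd in sp_tree.leaf_node_iter()
    )
    lineage_of: dict[str, int] = {}
    if cfg.scenario == "tsp":
        for sp in species:
            for i, lab in enumerate(alleles[sp]):
                lineage_of[lab] = i % cfg.n_lineages
    else:
        for sp in species:
            for lab in alleles[sp]:
                lineage_of[lab] = 0

    newicks: list[str] = []
    for _ in range(cfg.n_trees):
        if cfg.scenario == "monophyly":
            body = _render_species_subtree(
                sp_tree.seed_node, alleles, rng, cfg.within_scale
            )
        else:
            lin_subs = []
            for lin in range(cfg.n_lineages):
                sub_alleles = {
                    sp: [a for a in alleles[sp] if lineage_of[a] == lin]
                    for sp in species
                }
                sub = _render_species_subtree(
                    sp_tree.seed_node, sub_alleles, rng, cfg.within_scale
                )
                if sub is not None:
                    lin_subs.append(sub)
            # ancient lineage splits: deeper than every species split
            deep = [
                f"{s}:{2.0 * depth + rng.exponential(depth):.6f}" for s in lin_subs
            ]
            body = "(" + ",".join(deep) + ")" if len(deep) > 1 else lin_subs[0]
        newicks.append(body + ";")

    perturb = rng.random(cfg.n_trees) < cfg.epsilon
    ns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList.get(
        data="\n".join(newicks), schema="newick", taxon_namespace=ns,
        preserve_underscores=True
    )
    for t, hit in zip(trees, perturb):
        if hit:
            _nni(t, rng)
    sample = TreeSample(
        trees=list(trees),
        provenance=[("sim", i) for i in range(cfg.n_trees)],
    )
    truth = {
        "scenario": cfg.scenario,
        "species": {lab: sp for sp in species for lab in alleles[sp]},
        "lineage": dict(lineage_of),
        "perturbed": perturb.tolist(),
        "species_tree": cfg.species_tree,
    }
    return sample, truth


def simulate_alignment(
    tree: Union[str, dendropy.Tree],
    n_columns: int,
    site_classes: Optional[Sequence[tuple[tuple[int, int], float]]] = None,
    gappy_columns: Sequence[int] = (),
    backbone_ids: Sequence[str] = (),
    seed: int = 0,
    scale: float = 1.0,
) -> tuple[dict[str, str], dict]:
    """Evolve a gapped alignment down a tree under Jukes-Cantor with
    per-column rate multipliers.

    ``site_classes`` is a list of ``((start, end), multiplier)`` with
    1-based inclusive, disjoint column intervals (unlisted columns have
    multiplier 1).  ``gappy_columns`` (1-based) are overwritten with gaps
    in the designated ``backbone_ids`` rows, emulating the mostly-gap
    baseline columns of a multi-gene backbone alignment.  Branch lengths
    are interpreted as expected substitutions per site after multiplying
    by ``scale``.  Returns the alignment and a truth record with the true
    per-column rate multipliers.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree if tree.endswith(";") else tree + ";",
                                 schema="newick", preserve_underscores=True)
    rates = np.ones(n_columns, dtype=float)
    claimed = np.zeros(n_columns, dtype=bool)
    for (lo, hi), mult in (site_classes or ()):
        if not (1 <= lo <= hi <= n_columns):
            raise ValueError(f"site class [{lo}, {hi}] outside 1..{n_columns}")
        if mult <= 0:
            raise ValueError("rate multipliers must be > 0")
        if claimed[lo - 1: hi].any():
            raise ValueError(f"site class [{lo}, {hi}] overlaps another class")
        claimed[lo - 1: hi] = True
        rates[lo - 1: hi] = mult
    rng = np.random.default_rng(seed)
    root = rng.integers(4, size=n_columns)
    seqs: dict[str, np.ndarray] = {}
    state: dict[int, np.ndarray] = {id(tree.seed_node): root}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = state[id(node.parent_node)]
        t = (node.edge.length if node.edge.length is not None else 1.0) * scale
        p_sub = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * t * rates))
        hit = rng.random(n_columns) < p_sub
        child = parent.copy()
        if hit.any():
            shift = rng.integers(1, 4, size=int(hit.sum()))
            child[hit] = (child[hit] + shift) % 4
        state[id(node)] = child
        if node.is_leaf():
            seqs[node.taxon.label] = child
    aln = {lab: "".join(_BASES[s]) for lab, s in sorted(seqs.items())}
    gappy = sorted(set(int(c) for c in gappy_columns))
    if gappy:
        if not backbone_ids:
            raise ValueError("gappy_columns requires backbone_ids")
        for b in backbone_ids:
            if b not in aln:
                raise KeyError(f"backbone id {b!r} not a tip of the tree")
            chars = list(aln[b])
            for c in gappy:
                if not (1 <= c <= n_columns):
                    raise ValueError(f"gappy column {c} outside 1..{n_columns}")
                chars[c - 1] = GAP
            aln[b] = "".join(chars)
    truth = {
        "rates": rates,
        "gappy_columns": set(gappy),
        "backbone_ids": list(backbone_ids),
    }
    return aln, truth


def inject_gene_conversion(
    alignment: Mapping[str, str],
    donor: str,
    acceptor: str,
    start: int,
    end: int,
    seed: int = 0,
) -> tuple[dict[str, str], dict]:
    """Overwrite the acceptor's columns in [start, end] (1-based inclusive)
    with the donor's, emulating a unidirectional gene-conversion event."""
    if donor not in alignment or acceptor not in alignment:
        raise KeyError(f"donor {donor!r} or acceptor {acceptor!r} not in alignment")
    L = len(alignment[donor])
    if not (1 <= start <= end <= L):
        raise ValueError(f"tract [{start}, {end}] outside 1..{L}")
    out = dict(alignment)
    acc = out[acceptor]
    out[acceptor] = acc[: start - 1] + out[donor][start - 1: end] + acc[end:]
    truth = {"donor": donor, "acceptor": acceptor, "tract": (start, end)}
    return out, truth


def simulate_rate_posterior(
    true_rates: Sequence[float],
    n_states: int = 1000,
    noise_sigma: float = 0.2,
    seed: int = 0,
) -> tuple[SiteRatePosterior, dict]:
    """Posterior rate samples: truth × lognormal(0, sigma) per state/column.

    Note the lognormal deviate has mean ``exp(sigma^2 / 2)``, so posterior
    means are inflated by that factor uniformly across columns — it cancels
    in baseline-normalized fold changes.
    """
    truth = np.asarray(true_rates, dtype=float)
    if np.any(truth <= 0):
        raise ValueError("true rates must be > 0")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.lognormal(mean=0.0, sigma=noise_sigma, size=(n_states, truth.size)) \
        if noise_sigma > 0 else np.ones((n_states, truth.size))
    post = SiteRatePosterior(
        rates=truth[None, :] * noise,
        column_ids=list(range(1, truth.size + 1)),
        provenance=[("sim", i) for i in range(n_states)],
    )
    return post, {"rates": truth, "noise_sigma": noise_sigma}


def synth_structure(
    n_residues: int,
    peptide_length: int,
    groove_positions: Sequence[int],
    seed: int = 0,
    mhc_chain: str = "A",
    peptide_chain: str = "P",
) -> tuple[str, dict]:
    """A toy PDB structure: a single-atom-per-residue MHC chain with the
    designated groove residues seated < 4 Å from a straight peptide chain
    and all other residues > 8 Å away.

    Returns valid PDB ATOM-record text and a truth record (groove set and
    the MHC chain's residue sequence).
    """
    groove = sorted(set(int(p) for p in groove_positions))
    if n_residues < 1 or peptide_length < 1:
        raise ValueError("n_residues and peptide_length must be >= 1")
    if groove and not (1 <= groove[0] and groove[-1] <= n_residues):
        raise ValueError("groove_positions must lie in 1..n_residues")
    if len(groove) > 8 * peptide_length:
        raise ValueError(
            f"{len(groove)} groove residues cannot all be packed within 4 Å "
            f"of a {peptide_length}-residue peptide"
        )
    rng = np.random.default_rng(seed)
    aas = list(_ONE_TO_THREE)
    seq = [aas[int(k)] for k in rng.integers(len(aas), size=n_residues)]
    groove_set = set(groove)
    lines = []
    serial = 1

    def atom_line(serial, res3, chain, num, x, y, z):
        return (
            f"ATOM  {serial:5d}  CA  {res3:>3s} {chain:1s}{num:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{'C':>2s}"
        )

    grank = {p: k for k, p in enumerate(groove)}
    for i in range(1, n_residues + 1):
        if i in groove_set:
            x = 3.5 * (grank[i] % peptide_length) + rng.uniform(-0.5, 0.5)
            y = 3.0 + rng.uniform(-0.3, 0.3)
            z = rng.uniform(-0.3, 0.3)
        else:
            x = 3.5 * (i % max(peptide_length, 2)) + rng.uniform(-1.0, 1.0)
            y = 12.0 + rng.uniform(-1.0, 1.0)
            z = rng.uniform(-1.0, 1.0)
        lines.append(atom_line(serial, _ONE_TO_THREE[seq[i - 1]], mhc_chain, i, x, y, z))
        serial += 1
    lines.append(f"TER   {serial:5d}      {_ONE_TO_THREE[seq[-1]]:>3s} {mhc_chain:1s}{n_residues:4d}")
    serial += 1
    for k in range(peptide_length):
        lines.append(atom_line(serial, "GLY", peptide_chain, k + 1, 3.5 * k, 0.0, 0.0))
        serial += 1
    lines.append("END")
    truth = {
        "groove_positions": groove_set,
        "mhc_sequence": "".join(seq),
        "peptide_length": peptide_length,
        "mhc_chain": mhc_chain,
        "peptide_chain": peptide_chain,
    }
    return "\n".join(lines) + "\n", truth
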