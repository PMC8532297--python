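"""Synthetic mitogenome sets with known evolutionary ground truth.

Sequences evolve along a user-supplied newick tree under HKY: the fewest
parameters that give both the AT-rich composition bias of insect
mitogenomes and the transition/transversion distinction K2P-style
distances can see.  Branch lengths are expected substitutions per site at
rate multiplier 1; each gene carries its own multiplier, and
protein-coding genes additionally apply deterministic codon-position
multipliers (third position fastest, second slowest) normalized to mean 1
within the gene, so the per-gene expected distance bookkeeping stays
exact.  Simulated alignments are gap-free; gap handling is exercised by
masking columns in dedicated tests.

The frozen :func:`paper_like_config` mirrors the structure of a real
tortricid-style study set: a 30-tip clock-like tree spanning two
subfamilies, six tribes, genera with 2-3 species and one species sampled
as six near-identical conspecific individuals; 37 genes with realistic
lengths; ~80% A+T equilibrium composition with negative GC-skew; rate
multipliers spanning a slow nad5-like to a fast nad6-like protein gene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import expm

from .genome_io import (AlignmentBlock, GeneFeature, MitoRecord, Taxonomy,
                        expected_type)
from .phylo_trees import parse_newick

DEFAULT_BASE_FREQS = (0.405, 0.115, 0.078, 0.402)  # A, C, G, T
DEFAULT_POS_MULTIPLIERS = (1.0, 0.4, 5.0)

_BASES = np.array(list("ACGT"))
_BASE_TO_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class GenePlan:
    """One gene to simulate: name, type, length, rate, optional freqs."""
    name: str
    gene_type: str                   # PCG | rRNA | tRNA
    length: int
    rate: float
    base_freqs: tuple | None = None  # None -> config default

    def __post_init__(self):
        if self.length <= 0 or self.rate <= 0:
            raise ValueError(f"{self.name}: length and rate must be > 0")
        if self.gene_type == "PCG" and self.length % 3:
            raise ValueError(f"{self.name}: PCG length must be a multiple "
                             "of 3")
        if expected_type(self.name) not in (self.gene_type, None):
            raise ValueError(f"{self.name}: type mismatch")


@dataclass
class SimulationConfig:
    """Everything needed for one reproducible simulated mitogenome set."""
    tree: str                        # newick with branch lengths
    seed: int
    gene_plan: list
    taxonomy: dict                   # tip label -> Taxonomy
    base_freqs: tuple = DEFAULT_BASE_FREQS
    kappa: float = 4.0
    codon_pos_multipliers: tuple = DEFAULT_POS_MULTIPLIERS

    def __post_init__(self):
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if any(f <= 0 for f in self.base_freqs):
            raise ValueError("base frequencies must be positive")
        if any(r <= 0 for r in self.codon_pos_multipliers):
            raise ValueError("codon-position multipliers must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass
class SimulatedSet:
    """Simulated records, true alignments, and the generating truth."""
    records: list
    blocks: dict                     # gene -> AlignmentBlock (gap-free)
    tree: str
    expected_distances: dict         # gene -> {(tip_a, tip_b): expectation}
    partition_rates: dict            # partition label -> mean multiplier
    config: SimulationConfig


def hky_rate_matrix(base_freqs, kappa: float) -> np.ndarray:
    """HKY Q (order A, C, G, T), scaled to one expected event per unit time."""
    pi = np.asarray(base_freqs, dtype=float)
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(pi, np.diag(q))
    return q / scale


def _transition_matrix(q: np.ndarray, t: float) -> np.ndarray:
    p = expm(q * t)
    p = np.clip(p, 0, None)
    return p / p.sum(axis=1, keepdims=True)


def _site_multipliers(plan: GenePlan, pos_mult) -> np.ndarray:
    """Per-site rate multipliers for one gene (codon classes for PCGs)."""
    if plan.gene_type != "PCG":
        return np.full(plan.length, plan.rate)
    r = np.asarray(pos_mult, dtype=float)
    r = r / r.mean()                 # normalize to mean 1 within the gene
    return plan.rate * np.tile(r, plan.length // 3)


def simulate_set(config: SimulationConfig) -> SimulatedSet:
    """Evolve every gene of the plan along the tree; deterministic by seed."""
    tree = parse_newick(config.tree)
    tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    missing = [t for t in tips if t not in config.taxonomy]
    if missing or len(config.taxonomy) != len(tips):
        raise ValueError(
            f"taxonomy does not match tree tips (missing {missing}, "
            f"{len(config.taxonomy)} taxonomy entries for {len(tips)} tips)")

    rng = np.random.default_rng(config.seed)
    nodes = list(tree.preorder_node_iter())
    blocks: dict = {}
    for plan in config.gene_plan:
        freqs = np.asarray(plan.base_freqs or config.base_freqs, dtype=float)
        q = hky_rate_matrix(freqs, config.kappa)
        mults = _site_multipliers(plan, config.codon_pos_multipliers)
        classes, class_ids = np.unique(mults, return_inverse=True)
        seqs: dict = {}
        root_states = rng.choice(4, size=plan.length, p=freqs)
        states = {id(nodes[0]): root_states}
        for node in nodes:
            if node is nodes[0]:
                continue
            parent = states[id(node.parent_node)]
            t = node.edge.length or 0.0
            child = parent.copy()
            if t > 0:
                for ci, rate in enumerate(classes):
                    mask = class_ids == ci
                    p = _transition_matrix(q, t * rate)
                    cum = np.cumsum(p, axis=1)
                    u = rng.random(int(mask.sum()))
                    child[mask] = (u[:, None] >
                                   cum[parent[mask]]).sum(axis=1)
            states[id(node)] = child
            if node.is_leaf():
                seqs[node.taxon.label] = child
        matrix = np.array([_BASES[seqs[t]] for t in tips], dtype="<U1")
        blocks[plan.name] = AlignmentBlock(
            gene=plan.name, samples=list(tips), matrix=matrix,
            is_coding=(plan.gene_type == "PCG"), reading_frame_offset=0)

    records = _assemble_records(config, blocks, tips)
    expected = _expected_distances(tree, config)
    return SimulatedSet(records=records, blocks=blocks, tree=config.tree,
                        expected_distances=expected,
                        partition_rates=_partition_rates(config),
                        config=config)


def _assemble_records(config, blocks, tips) -> list:
    records = []
    for tip in tips:
        parts = []
        features = []
        pos = 1
        for plan in config.gene_plan:
            seq = blocks[plan.name].row(tip)
            parts.append(seq)
            features.append(GeneFeature(
                name=plan.name, type=plan.gene_type, start=pos,
                end=pos + plan.length - 1, strand="+"))
            pos += plan.length
        records.append(MitoRecord(
            sample_id=tip, sequence="".join(parts), circular=True,
            complete=False, features=features,
            taxonomy=config.taxonomy[tip]))
    return records


def _path_lengths(tree: dendropy.Tree) -> dict:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            out[(a.label, b.label)] = float(pdm.patristic_distance(a, b))
    return out

def _expected_distances(tree, config) -> dict:
    paths = _path_lengths(tree)
    return {plan.name: {pair: t * plan.rate for pair, t in paths.items()}
            for plan in config.gene_plan}


def _partition_rates(config) -> dict:
    r = np.asarray(config.codon_pos_multipliers, dtype=float)
    r = r / r.mean()
    pcgs = [p for p in config.gene_plan if p.gene_type == "PCG"]
    out = {p.name: p.rate for p in config.gene_plan}
    if pcgs:
        w = np.array([p.length / 3 for p in pcgs], dtype=float)
        rates = np.array([p.rate for p in pcgs])
        mean_pcg_rate = float((w * rates).sum() / w.sum())
        for k, pos in enumerate(("pos1", "pos2", "pos3")):
            out[pos] = mean_pcg_rate * float(r[k])
    return out


# ---------------------------------------------------------------------------
# the frozen study-like configuration

# gene lengths typical of a lepidopteran mitogenome (all PCGs in frame)
_PCG_PLAN = [
    ("cox1", 1536, 0.75), ("cox2", 684, 0.80), ("atp8", 162, 1.45),
    ("atp6", 678, 1.30), ("cox3", 786, 1.00), ("nad3", 354, 1.10),
    ("nad5", 1737, 0.60), ("nad4", 1341, 0.85), ("nad4l", 291, 0.90),
    ("nad6", 531, 1.90), ("cob", 1149, 1.15), ("nad1", 942, 0.95),
    ("nad2", 1023, 1.25),
]
_RRNA_PLAN = [("rrnL", 1350, 0.55), ("rrnS", 780, 0.50)]
_TRNA_NAMES_ORDERED = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY")
_RRNA_FREQS = (0.43, 0.066, 0.085, 0.419)   # more AT-rich than the PCGs

# ultrametric species tree: split heights per rank (expected subs/site at
# multiplier 1).  Pairwise expectations (2x height) land on the divergence
# scale the rank-stratified distances of real tortricid-style data show:
# ~0.002 within species, ~0.06 among congeneric species, ~0.10 among
# genera, ~0.12-0.14 among tribes, ~0.17 between subfamilies.
_H_SUBFAMILY = 0.085
_H_TRIBE = 0.06
_H_GENUS = 0.05
_H_SPECIES = 0.03
_H_INDIVIDUAL = 0.001


def _clade(children, height, child_heights) -> str:
    parts = [f"{c}:{height - h!r}" for c, h in zip(children, child_heights)]
    return "(" + ",".join(parts) + ")"


def paper_like_config(seed: int = 20210) -> SimulationConfig:
    """The frozen study-structure configuration (30 tips, 37 genes).

    Two subfamilies of three tribes each; every tribe holds two genera;
    genera carry two species (one genus carries three); the first species
    of the first genus is sampled as six conspecific individuals on
    near-zero terminal branches.  Tip heights are clock-like, so
    rank-stratified mean distances increase with rank by construction.
    """
    taxonomy: dict = {}
    tribe_newicks = []
    species_counter = 0
    for sf_i in range(2):
        sf = f"SF{sf_i + 1}"
        for tr_i in range(3):
            tribe_idx = sf_i * 3 + tr_i
            tribe = f"TR{tribe_idx + 1}"
            genus_newicks = []
            for g_i in range(2):
                genus_idx = tribe_idx * 2 + g_i
                genus = f"G{genus_idx + 1}"
                n_species = 3 if genus_idx == 3 else 2
                tip_newicks = []
                tip_heights = []
                for s_i in range(n_species):
                    species_counter += 1
                    species = f"{genus}_sp{s_i + 1}"
                    if sf_i == 0 and tr_i == 0 and g_i == 0 and s_i == 0:
                        # the multiply-sampled species: six individuals
                        ind_labels = [f"{species}_i{k + 1}" for k in range(6)]
                        for lab in ind_labels:
                            taxonomy[lab] = Taxonomy(sf, tribe, genus,
                                                     species, lab)
                        nwk = "(" + ",".join(
                            f"{lab}:{_H_INDIVIDUAL!r}"
                            for lab in ind_labels) + ")"
                        tip_newicks.append(nwk)
                        tip_heights.append(_H_INDIVIDUAL)
                    else:
                        lab = f"{species}_i1"
                        taxonomy[lab] = Taxonomy(sf, tribe, genus, species,
                                                 lab)
                        tip_newicks.append(lab)
                        tip_heights.append(0.0)
                if len(tip_newicks) == 1:
                    genus_nwk, genus_h = tip_newicks[0], tip_heights[0]
                else:
                    # ladderize multi-species genera at the species height
                    genus_nwk = _clade(tip_newicks[:2], _H_SPECIES,
                                       tip_heights[:2])
                    genus_h = _H_SPECIES
                    for extra, h in zip(tip_newicks[2:], tip_heights[2:]):
                        genus_nwk = _clade([genus_nwk, extra],
                                           _H_SPECIES * 1.2, [genus_h, h])
                        genus_h = _H_SPECIES * 1.2
                genus_newicks.append((genus_nwk, genus_h))
            tribe_nwk = _clade([g for g, _ in genus_newicks], _H_GENUS,
                               [h for _, h in genus_newicks])
            tribe_newicks.append((tribe_nwk, _H_GENUS))
        # collapse this subfamily's three tribes
    sf_newicks = []
    for sf_i in range(2):
        tribes = tribe_newicks[sf_i * 3:(sf_i + 1) * 3]
        nwk = _clade([t for t, _ in tribes[:2]], _H_TRIBE,
                     [h for _, h in tribes[:2]])
        nwk = _clade([nwk, tribes[2][0]], _H_TRIBE * 1.2,
                     [_H_TRIBE, tribes[2][1]])
        sf_newicks.append((nwk, _H_TRIBE * 1.2))
    root = _clade([s for s, _ in sf_newicks], _H_SUBFAMILY,
                  [h for _, h in sf_newicks]) + ";"

    gene_plan = (
        [GenePlan(n, "PCG", ln, r) for n, ln, r in _PCG_PLAN]
        + [GenePlan(n, "rRNA", ln, r, base_freqs=_RRNA_FREQS)
           for n, ln, r in _RRNA_PLAN]
        + [GenePlan(n, "tRNA", 65 + (i * 3) % 8, 0.30)
           for i, n in enumerate(_TRNA_NAMES_ORDERED)]
    )
    return SimulationConfig(tree=root, seed=seed, gene_plan=gene_plan,
                            taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# serialization

def write_truth_json(simset: SimulatedSet, path) -> None:
    payload = {
        "tree": simset.tree,
        "partition_rates": simset.partition_rates,
        "expected_distances": {
            gene: {f"{a}|{b}": v for (a, b), v in pairs.items()}
            for gene, pairs in simset.expected_distances.items()},
        "seed": simset.config.seed,
        "base_freqs": list(simset.config.base_freqs),
        "kappa": simset.config.kappa,
        "codon_pos_multipliers": list(
            simset.config.codon_pos_multipliers),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
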