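"""Pairwise divergence: K2P distances, nucleotide diversity, and Ka/Ks.

Gap handling follows the conventions of the programs each statistic comes
from, and the two deliberately differ: K2P uses pairwise deletion (sites
with a gap or N in either member of the pair are excluded, per pair), while
nucleotide diversity uses complete deletion (columns containing any gap or
N are removed for all samples before anything is computed).

K2P separates transition (P) and transversion (Q) proportions:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Nucleotide diversity pi is the mean per-site difference proportion over all
unordered sequence pairs, profiled in sliding windows (default 300 bp
window, 25 bp step).  Ka/Ks uses the Nei-Gojobori (1986) counting method
with Jukes-Cantor correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .genetic_code import GeneticCode
from .genome_io import AlignmentBlock, Taxonomy

log = logging.getLogger(__name__)

RANK_CATEGORIES = ("within_species", "among_species_within_genus",
                   "among_genera_within_tribe",
                   "among_tribes_within_subfamily", "between_subfamilies")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class K2PComponents:
    """Transition/transversion proportions and the resulting distance.

    ``d`` is NaN for a saturated pair (log argument non-positive) or when
    no comparable sites remain.
    """
    P: float
    Q: float
    sites_compared: int
    d: float

    @property
    def saturated(self) -> bool:
        return self.sites_compared > 0 and math.isnan(self.d)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with sample labels."""
    gene: str
    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.values)
        if not np.array_equal(finite, finite.T) or not np.allclose(
                self.values[finite & finite.T],
                self.values.T[finite & finite.T]):
            raise ValueError("matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.values).any())


@dataclass
class DiversityProfile:
    """Sliding-window nucleotide-diversity profile for one gene."""
    gene: str
    window_length: int
    step: int
    window_midpoints: np.ndarray
    pi_values: np.ndarray
    mean_pi: float          # genewide pi on the gap-stripped columns


@dataclass(frozen=True)
class KaKsResult:
    """Nei-Gojobori Ka/Ks with site counts (S + N = 3 x codons compared)."""
    Ka: float
    Ks: float
    S: float
    N: float
    codons_compared: int

    @property
    def ratio(self) -> float:
        if not math.isfinite(self.Ks) or self.Ks == 0:
            return math.nan
        return self.Ka / self.Ks


# ---------------------------------------------------------------------------
# K2P

def _to_array(seq) -> np.ndarray:
    if isinstance(seq, str):
        return np.frombuffer(seq.encode(), dtype="S1")
    return np.asarray(seq, dtype="S1")


def k2p(seq_a, seq_b) -> K2PComponents:
    """Kimura two-parameter distance between two aligned rows.

    Sites where either row holds '-' or 'N' are excluded (pairwise
    deletion).  Saturated pairs (1-2P-Q <= 0 or 1-2Q <= 0) and pairs with
    no comparable sites return NaN distances rather than raising.
    """
    a = _to_array(seq_a)
    b = _to_array(seq_b)
    if a.size != b.size:
        raise ValueError("aligned rows differ in length")
    usable = ~(np.isin(a, (b"-", b"N")) | np.isin(b, (b"-", b"N")))
    a, b = a[usable], b[usable]
    n = int(a.size)
    if n == 0:
        return K2PComponents(math.nan, math.nan, 0, math.nan)
    diff = a != b
    purine_a = np.isin(a, (b"A", b"G"))
    purine_b = np.isin(b, (b"A", b"G"))
    transitions = int(np.count_nonzero(diff & (purine_a == purine_b)))
    transversions = int(np.count_nonzero(diff & (purine_a != purine_b)))
    P = transitions / n
    Q = transversions / n
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PComponents(P, Q, n, math.nan)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PComponents(P, Q, n, d)


def p_distance(seq_a, seq_b) -> float:
    """Proportion of differing sites under pairwise deletion."""
    a = _to_array(seq_a)
    b = _to_array(seq_b)
    usable = ~(np.isin(a, (b"-", b"N")) | np.isin(b, (b"-", b"N")))
    a, b = a[usable], b[usable]
    return math.nan if a.size == 0 else float(np.mean(a != b))


def pairwise_matrix(block: AlignmentBlock) -> DistanceMatrix:
    """All-pairs K2P distances for an alignment block."""
    n = len(block.samples)
    if n < 2:
        raise ValueError(f"{block.gene}: need at least 2 samples")
    vals = np.zeros((n, n))
    rows = block.matrix
    for i, j in combinations(range(n), 2):
        d = k2p(rows[i], rows[j]).d
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix(gene=block.gene, labels=list(block.samples),
                          values=vals)


# ---------------------------------------------------------------------------
# rank stratification

def rank_category(tax_a: Taxonomy, tax_b: Taxonomy) -> str:
    """Most-specific-shared-rank category for one unordered sample pair."""
    if tax_a.species == tax_b.species and tax_a.genus == tax_b.genus:
        return "within_species"
    if tax_a.genus == tax_b.genus and tax_a.tribe == tax_b.tribe:
        return "among_species_within_genus"
    if tax_a.tribe == tax_b.tribe and tax_a.subfamily == tax_b.subfamily:
        return "among_genera_within_tribe"
    if tax_a.subfamily == tax_b.subfamily:
        return "among_tribes_within_subfamily"
    return "between_subfamilies"


def rank_mean_distances(matrix: DistanceMatrix,
                        taxonomy: dict) -> pd.DataFrame:
    """Mean K2P distance per taxonomic-rank category for one gene.

    Every unordered pair falls in exactly one category.  Saturated (NaN)
    pairs are excluded from means and counted separately; categories with
    zero pairs are omitted.
    """
    sums: dict = {}
    counts: dict = {}
    saturated: dict = {}
    for i, j in combinations(range(len(matrix.labels)), 2):
        cat = rank_category(taxonomy[matrix.labels[i]],
                            taxonomy[matrix.labels[j]])
        d = matrix.values[i, j]
        if math.isnan(d):
            saturated[cat] = saturated.get(cat, 0) + 1
            continue
        sums[cat] = sums.get(cat, 0.0) + d
        counts[cat] = counts.get(cat, 0) + 1
    rows = []
    for cat in RANK_CATEGORIES:
        if cat not in counts and cat not in saturated:
            continue
        n = counts.get(cat, 0)
        rows.append({"gene": matrix.gene, "rank_category": cat,
                     "mean_distance": sums.get(cat, math.nan) / n
                     if n else math.nan,
                     "n_pairs": n,
                     "n_saturated": saturated.get(cat, 0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nucleotide diversity

def _complete_deletion(block: AlignmentBlock) -> np.ndarray:
    m = block.matrix
    keep = ~np.any((m == "-") | (m == "N"), axis=0)
    return m[:, keep]


def nucleotide_diversity(block: AlignmentBlock) -> float:
    """Genewide pi: mean pairwise difference proportion, complete deletion."""
    m = _complete_deletion(block)
    if m.shape[0] < 2:
        raise ValueError(f"{block.gene}: need at least 2 samples")
    if m.shape[1] == 0:
        return math.nan
    return _pi_of(m)


def _pi_of(m: np.ndarray) -> float:
    n = m.shape[0]
    total = 0.0
    for i, j in combinations(range(n), 2):
        total += np.mean(m[i] != m[j])
    return total / (n * (n - 1) / 2)


def sliding_pi(block: AlignmentBlock, window: int = 300,
               step: int = 25) -> DiversityProfile:
    """Sliding-window pi over gap-stripped columns.

    Window coordinates are on the columns remaining after complete
    deletion, reported at the window midpoint.  If fewer than ``window``
    usable columns remain, the profile is empty and only the genewide value
    is reported.
    """
    if window <= step or step <= 0:
        raise ValueError("need window > step > 0")
    m = _complete_deletion(block)
    if m.shape[0] < 2:
        raise ValueError(f"{block.gene}: need at least 2 samples")
    length = m.shape[1]
    mean_pi = _pi_of(m) if length else math.nan
    if length < window:
        log.warning("%s: usable length %d < window %d; genewide pi only",
                    block.gene, length, window)
        return DiversityProfile(block.gene, window, step,
                                np.array([]), np.array([]), mean_pi)
    n_windows = (length - window) // step + 1
    mids = np.empty(n_windows)
    pis = np.empty(n_windows)
    # per-column pairwise difference count, then windowed sums
    n = m.shape[0]
    diff_per_col = np.zeros(length)
    for i, j in combinations(range(n), 2):
        diff_per_col += (m[i] != m[j])
    diff_per_col /= (n * (n - 1) / 2)
    csum = np.concatenate([[0.0], np.cumsum(diff_per_col)])
    for w in range(n_windows):
        lo = w * step
        hi = lo + window
        pis[w] = (csum[hi] - csum[lo]) / window
        mids[w] = (lo + hi - 1) / 2 + 1  # 1-based midpoint
    return DiversityProfile(block.gene, window, step, mids, pis, mean_pi)


# ---------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks

def syn_site_fraction(codon: str, code: GeneticCode) -> float:
    """Synonymous site count of one sense codon (0..3).

    Each position contributes the fraction of its viable single-base
    mutations (those not creating a stop codon) that are synonymous.
    """
    aa = code.forward.get(codon)
    if aa is None:
        raise ValueError(f"{codon} is not a sense codon")
    s = 0.0
    for pos in range(3):
        syn = viable = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in code.stop_codons:
                continue
            viable += 1
            if code.forward[mut] == aa:
                syn += 1
        if viable:
            s += syn / viable
    return s


def _pathway_counts(codon_a: str, codon_b: str, code: GeneticCode):
    """Mean (synonymous, nonsynonymous) step counts over mutational paths.

    Paths are all orderings of the differing positions; orderings passing
    through a stop codon are excluded (if every ordering does, all are
    kept, which cannot drop the comparison silently).
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    results = []
    for order in permutations(diff):
        cur = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in code.stop_codons:
                blocked = True
                break
            if code.forward[cur] == code.forward[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            results.append((sd, nd))
    if not results:
        for order in permutations(diff):
            cur = codon_a
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
                same = (code.translate(cur) == code.translate(nxt))
                sd += same
                nd += not same
                cur = nxt
            results.append((sd, nd))
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


def nei_gojobori(cds_a: str, cds_b: str, code: GeneticCode) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Codons containing gaps, N, or a stop in either sequence are skipped
    pairwise.  Synonymous-site counts are averaged between the two
    sequences; observed differences average over mutational pathways.
    Saturation (p >= 3/4) or S = 0 yields NaN rates.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("CDS lengths differ")
    n_codons = len(cds_a) // 3
    S = N = Sd = Nd = 0.0
    compared = 0
    for i in range(n_codons):
        ca = cds_a[3 * i:3 * i + 3]
        cb = cds_b[3 * i:3 * i + 3]
        if (set(ca + cb) - set("ACGT")) or \
                ca in code.stop_codons or cb in code.stop_codons:
            continue
        compared += 1
        s = 0.5 * (syn_site_fraction(ca, code) + syn_site_fraction(cb, code))
        S += s
        N += 3 - s
        if ca != cb:
            sd, nd = _pathway_counts(ca, cb, code)
            Sd += sd
            Nd += nd
    if compared == 0 or S == 0:
        return KaKsResult(math.nan, math.nan, S, N, compared)
    ps = Sd / S
    pn = Nd / N
    return KaKsResult(_jc_correct(pn), _jc_correct(ps), S, N, compared)


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1 - 4 * p / 3)
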