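"""Codon-usage bias statistics under an injected genetic code.

Implements the classical indices used in comparative mitogenomics:

* RSCU (relative synonymous codon usage): observed count divided by the
  expectation under uniform synonym usage within the amino-acid family.
* ENC (effective number of codons, Wright's Nc): generalized to the active
  code's family-size structure; maximal (62 for the invertebrate
  mitochondrial code, table 5) under uniform usage, 20 when a single codon
  serves each amino acid.
* CBI (codon bias index): excess usage of a designated optimal codon per
  family over the random expectation, 0 under uniform usage, 1 at total
  bias.
* GC3s: G+C fraction at third positions of codons in multi-codon families.

All statistics take the :class:`~mitocomp.genetic_code.GeneticCode` as a
parameter so the standard code (table 1, which unlike table 5 has
single-codon families) exercises the same code paths in tests.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import GeneticCode, get_code
from .genome_io import PCG_NAMES, extract_gene

log = logging.getLogger(__name__)

UNDEFINED = math.nan


def codon_counts(cds_list, code: GeneticCode) -> dict:
    """Count sense codons over a list of in-frame CDS strings.

    Stop codons and codons containing N or '-' are excluded; internal stop
    codons are logged as a warning.  Trailing partial codons are dropped.
    """
    counts: dict = {}
    for cds in cds_list:
        if len(cds) < 3:
            raise ValueError(f"CDS shorter than one codon: {len(cds)} nt")
        n_codons = len(cds) // 3
        internal_stops = 0
        for i in range(n_codons):
            codon = cds[3 * i:3 * i + 3]
            if set(codon) - set("ACGT"):
                continue
            if codon in code.stop_codons:
                internal_stops += i < n_codons - 1
                continue
            counts[codon] = counts.get(codon, 0) + 1
        if internal_stops:
            log.warning("%d internal stop codon(s) excluded from a %d-codon "
                        "CDS", internal_stops, n_codons)
    return counts


def rscu(counts: dict, code: GeneticCode) -> dict:
    """RSCU(c) = observed(c) / (family total / family size).

    Codons of an entirely unobserved family map to NaN (undefined), while a
    codon absent from an otherwise observed family has RSCU 0.
    """
    out = {}
    for aa, family in code.families.items():
        total = sum(counts.get(c, 0) for c in family)
        for c in family:
            out[c] = (UNDEFINED if total == 0
                      else len(family) * counts.get(c, 0) / total)
    return out


def _family_homozygosity(counts: dict, code: GeneticCode) -> dict:
    """Wright's F per amino acid with >= 2 observed codons, keyed by aa."""
    out = {}
    for aa, family in code.families.items():
        k = len(family)
        if k < 2:
            continue
        ns = np.array([counts.get(c, 0) for c in family], dtype=float)
        n = ns.sum()
        if n < 2:
            continue
        p = ns / n
        f = (n * (p ** 2).sum() - 1) / (n - 1)
        out[aa] = f
    return out


def enc(counts: dict, code: GeneticCode) -> float:
    """Wright's effective number of codons for the active code.

    ENC = N1 + sum_k N_k / F_k_bar over multi-codon family sizes k, where
    F_k_bar averages the family homozygosities of size-k families and N_k
    counts them (N1 = number of single-codon families).  When no size-k
    family is observable, F_k_bar is imputed as the family-count-weighted
    mean of the observable classes.  The result is capped at the number of
    sense codons; NaN when nothing is observable.
    """
    fams = _family_homozygosity(counts, code)
    size_of = {aa: len(f) for aa, f in code.families.items()}
    by_size: dict = {}
    for aa, f in fams.items():
        by_size.setdefault(size_of[aa], []).append(f)
    class_counts = code.family_size_counts()
    fbar = {k: float(np.mean(v)) for k, v in by_size.items() if v}
    # guard: F of 0 would blow up 1/F; can only arise from pathological
    # float cancellation, clamp to a tiny positive value
    fbar = {k: max(f, 1e-12) for k, f in fbar.items()}
    if not fbar:
        return UNDEFINED
    # impute missing size classes from observed ones (weighted by the
    # number of families in each observed class)
    weights = {k: class_counts[k] for k in fbar}
    imputed = (sum(fbar[k] * w for k, w in weights.items())
               / sum(weights.values()))
    total = 0.0
    for k, n_k in class_counts.items():
        if k == 1:
            total += n_k
        else:
            total += n_k / fbar.get(k, imputed)
    return min(total, float(code.n_sense))


def optimal_codons(counts: dict, code: GeneticCode) -> dict:
    """Most frequent synonym per multi-codon family (ties: lexicographic).

    This collapses the external reference-set notion of "optimal" codons to
    self-reference on the pooled dataset under analysis; the chosen set is
    recorded in report metadata.
    """
    out = {}
    for aa, family in code.families.items():
        if len(family) < 2:
            continue
        out[aa] = max(sorted(family), key=lambda c: counts.get(c, 0))
    return out


def cbi(counts: dict, code: GeneticCode, optimal: dict) -> float:
    """Codon bias index: (N_opt - N_ran) / (N_tot - N_ran).

    N_tot counts codons in multi-codon families, N_opt those matching the
    designated optimal codon of their family, and N_ran the expectation of
    N_opt under uniform synonym usage (sum of n_a / k_a).  NaN when the
    denominator degenerates.
    """
    n_tot = n_opt = n_ran = 0.0
    for aa, family in code.families.items():
        k = len(family)
        if k < 2:
            continue
        n_a = sum(counts.get(c, 0) for c in family)
        if n_a == 0:
            continue
        n_tot += n_a
        n_opt += counts.get(optimal[aa], 0)
        n_ran += n_a / k
    if n_tot == 0 or math.isclose(n_tot, n_ran):
        return UNDEFINED
    return (n_opt - n_ran) / (n_tot - n_ran)


def gc3s(counts: dict, code: GeneticCode) -> float:
    """G+C fraction at third codon positions of multi-codon families."""
    eligible = gc = 0
    for aa, family in code.families.items():
        if len(family) < 2:
            continue
        for c in family:
            n = counts.get(c, 0)
            eligible += n
            if c[2] in "GC":
                gc += n
    return UNDEFINED if eligible == 0 else gc / eligible


def top_codons(counts: dict, k: int) -> list:
    """The k most frequent codons, ties broken lexicographically."""
    if k > 64:
        raise ValueError("k exceeds the number of codons")
    ranked = sorted(counts, key=lambda c: (-counts[c], c))
    return ranked[:k]


def correlate(xs, ys) -> tuple:
    """Pearson correlation (r, two-sided p); NaN r on a constant vector."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.allclose(xs, xs[0]) or np.allclose(ys, ys[0]):
        return (UNDEFINED, UNDEFINED)
    r, p = stats.pearsonr(xs, ys)
    return (float(r), float(p))


# ---------------------------------------------------------------------------
# dataset-level reports

def _record_pcg_cds(record) -> list:
    return [extract_gene(record, g) for g in PCG_NAMES
            if record.has_gene(g)]


def indices_table(records, code: GeneticCode | None = None) -> pd.DataFrame:
    """Per-sample ENC, CBI and GC3s on the concatenated protein genes.

    CBI's optimal-codon set is fixed from the pooled counts of the whole
    dataset so every sample is scored against the same reference.
    """
    code = code or get_code(5)
    pooled: dict = {}
    per_sample = {}
    for rec in records:
        c = codon_counts(_record_pcg_cds(rec), code)
        per_sample[rec.sample_id] = c
        for codon, n in c.items():
            pooled[codon] = pooled.get(codon, 0) + n
    optimal = optimal_codons(pooled, code)
    rows = []
    for rec in records:
        c = per_sample[rec.sample_id]
        tax = rec.taxonomy
        rows.append({
            "sample_id": rec.sample_id,
            "tribe": tax.tribe if tax else None,
            "n_codons": sum(c.values()),
            "enc": enc(c, code),
            "cbi": cbi(c, code, optimal),
            "gc3s": gc3s(c, code),
        })
    df = pd.DataFrame(rows)
    df.attrs["optimal_codons"] = optimal
    return df


def tribe_mean_indices(indices: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-tribe means of the per-sample indices."""
    return (indices.dropna(subset=["tribe"])
            .groupby("tribe", sort=True)[["enc", "cbi", "gc3s"]]
            .mean().reset_index())


def rscu_table(records, taxonomy=None, code: GeneticCode | None = None,
               by: str = "tribe") -> pd.DataFrame:
    """Long-format RSCU table (group, codon, amino acid, count, RSCU)."""
    code = code or get_code(5)
    groups: dict = {}
    for rec in records:
        tax = rec.taxonomy or (taxonomy or {}).get(rec.sample_id)
        key = getattr(tax, by) if (by != "sample" and tax) else rec.sample_id
        counts = codon_counts(_record_pcg_cds(rec), code)
        g = groups.setdefault(key, {})
        for codon, n in counts.items():
            g[codon] = g.get(codon, 0) + n
    rows = []
    for group in sorted(groups):
        counts = groups[group]
        r = rscu(counts, code)
        for codon in sorted(code.forward):
            rows.append({"group": group, "codon": codon,
                         "amino_acid": code.forward[codon],
                         "count": counts.get(codon, 0),
                         "rscu": r[codon]})
    return pd.DataFrame(rows)
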