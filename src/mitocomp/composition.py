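"""Nucleotide composition and strand-asymmetry statistics.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C), computed on the
majority (annotated) strand; minus-strand genes are reverse-complemented
before pooling into gene-class partitions, since skew is strand-dependent.
Insect mitogenomes are strongly AT-rich (around 80% A+T) with a negative
GC-skew on the majority strand, and the partition-level report exposes that
structure per sample and as unweighted per-tribe means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import (MitoRecord, MitoValidationError, PCG_NAMES,
                        RRNA_NAMES, TRNA_NAMES, extract_gene)

log = logging.getLogger(__name__)

PARTITIONS = ("whole", "PCGs", "pos1", "pos2", "pos3", "rRNAs", "tRNAs")

_COUNT_ALPHABET = frozenset("ACGTN-")


@dataclass(frozen=True)
class CompositionSummary:
    """Base counts, percentages and skews for one group x partition."""
    group_label: str
    partition: str
    count_A: int
    count_T: int
    count_G: int
    count_C: int
    pct_A: float
    pct_T: float
    pct_G: float
    pct_C: float
    at_content: float
    at_skew: float
    gc_skew: float


def base_counts(seq: str) -> tuple:
    """Counts of (A, T, G, C); N and '-' are excluded from every count."""
    bad = set(seq) - _COUNT_ALPHABET
    if bad:
        raise MitoValidationError(
            f"disallowed symbols {sorted(bad)} in sequence")
    return (seq.count("A"), seq.count("T"), seq.count("G"), seq.count("C"))


def at_skew(counts) -> float:
    """(A - T)/(A + T); NaN when A + T = 0."""
    a, t = counts[0], counts[1]
    return math.nan if a + t == 0 else (a - t) / (a + t)


def gc_skew(counts) -> float:
    """(G - C)/(G + C); NaN when G + C = 0."""
    g, c = counts[2], counts[3]
    return math.nan if g + c == 0 else (g - c) / (g + c)


def codon_position_subsequence(cds: str, position: int) -> str:
    """Concatenate the bases at one codon position of an in-frame CDS.

    Trailing bases that do not complete a codon are dropped (with a logged
    warning), so the output length is floor(len(cds)/3).
    """
    if position not in (1, 2, 3):
        raise ValueError(f"codon position must be 1, 2 or 3, got {position}")
    extra = len(cds) % 3
    if extra:
        log.warning("dropping %d trailing base(s) of an out-of-frame CDS "
                    "tail", extra)
        cds = cds[:len(cds) - extra]
    return cds[position - 1::3]


def summarize(group_label: str, partition: str, seq: str) -> CompositionSummary:
    """Build a :class:`CompositionSummary` from a pooled sequence."""
    counts = base_counts(seq)
    total = sum(counts)
    if total == 0:
        raise MitoValidationError(f"{group_label}/{partition}: no countable "
                                  "bases")
    a, t, g, c = counts
    return CompositionSummary(
        group_label=group_label, partition=partition,
        count_A=a, count_T=t, count_G=g, count_C=c,
        pct_A=100 * a / total, pct_T=100 * t / total,
        pct_G=100 * g / total, pct_C=100 * c / total,
        at_content=100 * (a + t) / total,
        at_skew=at_skew(counts), gc_skew=gc_skew(counts))


def _partition_sequence(record: MitoRecord, partition: str) -> str:
    """Pool the sequence of one partition, strand-aware, for one record."""
    if partition == "whole":
        return record.sequence
    if partition == "PCGs":
        return "".join(extract_gene(record, g) for g in PCG_NAMES)
    if partition in ("pos1", "pos2", "pos3"):
        pos = int(partition[-1])
        return "".join(
            codon_position_subsequence(extract_gene(record, g), pos)
            for g in PCG_NAMES)
    if partition == "rRNAs":
        return "".join(extract_gene(record, g) for g in RRNA_NAMES)
    if partition == "tRNAs":
        return "".join(extract_gene(record, g) for g in TRNA_NAMES)
    raise ValueError(f"unknown partition {partition!r}")


def composition_report(records, taxonomy: dict | None = None,
                       partitions=PARTITIONS) -> pd.DataFrame:
    """Per-sample composition summaries plus unweighted per-tribe means.

    Pooling concatenates gene sequences before counting.  A record missing
    any gene of a partition is flagged incomplete for that partition,
    logged, and excluded from the tribe mean.  Tribe rows average the
    per-sample percentages and skews without weighting by genome length.
    """
    rows = []
    for rec in records:
        tax = rec.taxonomy or (taxonomy or {}).get(rec.sample_id)
        tribe = tax.tribe if tax is not None else None
        for part in partitions:
            try:
                seq = _partition_sequence(rec, part)
            except KeyError as exc:
                log.warning("%s/%s incomplete: %s", rec.sample_id, part, exc)
                rows.append({"group_label": rec.sample_id, "level": "sample",
                             "tribe": tribe, "partition": part,
                             "incomplete": True})
                continue
            s = summarize(rec.sample_id, part, seq)
            rows.append({"group_label": rec.sample_id, "level": "sample",
                         "tribe": tribe, "partition": part,
                         "incomplete": False,
                         "count_A": s.count_A, "count_T": s.count_T,
                         "count_G": s.count_G, "count_C": s.count_C,
                         "pct_A": s.pct_A, "pct_T": s.pct_T,
                         "pct_G": s.pct_G, "pct_C": s.pct_C,
                         "at_content": s.at_content,
                         "at_skew": s.at_skew, "gc_skew": s.gc_skew})
    df = pd.DataFrame(rows)
    sample_df = df[(df["level"] == "sample") & (~df["incomplete"])]
    tribe_rows = []
    if "tribe" in sample_df and sample_df["tribe"].notna().any():
        value_cols = ["pct_A", "pct_T", "pct_G", "pct_C", "at_content",
                      "at_skew", "gc_skew"]
        grouped = sample_df.groupby(["tribe", "partition"], sort=True)
        for (tribe, part), sub in grouped:
            row = {"group_label": tribe, "level": "tribe", "tribe": tribe,
                   "partition": part, "incomplete": False}
            row.update({c: float(np.mean(sub[c])) for c in value_cols})
            tribe_rows.append(row)
    return pd.concat([df, pd.DataFrame(tribe_rows)], ignore_index=True)


def pooled_composition(records, partition: str = "whole") -> CompositionSummary:
    """Composition of one partition pooled over all records (summed counts)."""
    seq = "".join(_partition_sequence(r, partition) for r in records)
    return summarize("pooled", partition, seq)
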