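"""Concatenated-dataset assembly and partition (charset) export.

Four schemes are supported, mirroring standard mitogenomic practice:

* ``P12``    - first and second codon positions of the 13 protein genes
* ``P123``   - all codon positions of the protein genes
* ``P123R``  - P123 plus the two rRNAs
* ``P123RT`` - P123R plus the 22 tRNAs

Genes are concatenated in the canonical lepidopteran mitogenome order;
samples missing a gene are padded with '-' and listed in a coverage
report.  Every supermatrix column carries provenance (gene, original
column, codon position), and charset definitions are exported in NEXUS
``sets`` or RAxML dialects with stride notation for codon positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import AlignmentBlock, TRNA_NAMES

# canonical lepidopteran mitogenome gene order for concatenation
PCG_ORDER = ("cox1", "cox2", "atp8", "atp6", "cox3", "nad3", "nad5",
             "nad4", "nad4l", "nad6", "cob", "nad1", "nad2")
RRNA_ORDER = ("rrnL", "rrnS")
TRNA_ORDER = tuple(sorted(TRNA_NAMES))

SCHEMES = ("P12", "P123", "P123R", "P123RT")


@dataclass
class Supermatrix:
    """A concatenated alignment with charsets and column provenance."""
    name: str
    samples: list
    matrix: np.ndarray                  # (n_samples, n_columns), '<U1'
    charsets: list                      # [(label, start, stop)] half-open
    provenance: list                    # per column: (gene, orig_col, pos)
    coverage: dict = field(default_factory=dict)  # sample -> missing genes

    def __post_init__(self):
        n_cols = self.matrix.shape[1]
        if len(self.provenance) != n_cols:
            raise ValueError("provenance does not cover all columns")
        covered = []
        for _, start, stop in self.charsets:
            covered.extend(range(start, stop))
        if sorted(covered) != list(range(n_cols)):
            raise ValueError("charsets must tile the matrix exactly")

    @property
    def n_columns(self) -> int:
        return int(self.matrix.shape[1])

    def columns_for(self, gene: str, codon_position=None) -> list:
        return [i for i, (g, _, p) in enumerate(self.provenance)
                if g == gene and (codon_position is None
                                  or p == codon_position)]


def _scheme_genes(scheme: str):
    if scheme == "P12" or scheme == "P123":
        return PCG_ORDER, ()
    if scheme == "P123R":
        return PCG_ORDER, RRNA_ORDER
    if scheme == "P123RT":
        return PCG_ORDER, RRNA_ORDER + TRNA_ORDER
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def _selected_columns(block: AlignmentBlock, scheme: str):
    """(column indices, codon positions) retained from one block."""
    n = block.n_sites
    if not block.is_coding:
        return list(range(n)), [0] * n
    off = block.reading_frame_offset
    usable = n - off - (n - off) % 3
    cols, poss = [], []
    for i in range(off, off + usable):
        pos = (i - off) % 3 + 1
        if scheme == "P12" and pos == 3:
            continue
        cols.append(i)
        poss.append(pos)
    return cols, poss


def build_dataset(blocks, scheme: str) -> Supermatrix:
    """Assemble one partitioning scheme from per-gene alignment blocks.

    ``blocks`` maps gene name -> AlignmentBlock (a list is also accepted).
    The sample universe is the union over blocks, ordered by first
    appearance in canonical gene order; samples absent from a block are
    padded with '-'.
    """
    if not isinstance(blocks, dict):
        blocks = {b.gene: b for b in blocks}
    pcgs, rnas = _scheme_genes(scheme)
    order = [g for g in pcgs + rnas if g in blocks]
    if not any(g in blocks for g in pcgs):
        raise ValueError(f"scheme {scheme} requires at least one coding "
                         "block")
    samples: list = []
    for g in order:
        for s in blocks[g].samples:
            if s not in samples:
                samples.append(s)

    col_arrays = []
    charsets = []
    provenance = []
    coverage: dict = {}
    offset = 0
    for g in order:
        blk = blocks[g]
        cols, poss = _selected_columns(blk, scheme)
        width = len(cols)
        sub = np.full((len(samples), width), "-", dtype="<U1")
        index = {s: i for i, s in enumerate(blk.samples)}
        for row, s in enumerate(samples):
            if s in index:
                sub[row] = blk.matrix[index[s], cols]
            else:
                coverage.setdefault(s, []).append(g)
        col_arrays.append(sub)
        charsets.append((g, offset, offset + width))
        provenance.extend((g, c, p) for c, p in zip(cols, poss))
        offset += width
    matrix = np.concatenate(col_arrays, axis=1) if col_arrays else \
        np.empty((len(samples), 0), dtype="<U1")
    return Supermatrix(name=scheme, samples=samples, matrix=matrix,
                       charsets=charsets, provenance=provenance,
                       coverage=coverage)


# ---------------------------------------------------------------------------
# partition export

def _runs(cols):
    """Describe a sorted column list as (start, stop, stride) or None."""
    if not cols:
        return None
    if len(cols) == 1:
        return (cols[0], cols[0], 1)
    strides = {b - a for a, b in zip(cols, cols[1:])}
    if len(strides) == 1:
        return (cols[0], cols[-1], strides.pop())
    return None


def _charset_expr(cols) -> str:
    run = _runs(cols)
    if run is not None:
        start, stop, stride = run
        if start == stop:
            return f"{start + 1}"
        if stride == 1:
            return f"{start + 1}-{stop + 1}"
        return f"{start + 1}-{stop + 1}\\{stride}"
    return " ".join(str(c + 1) for c in cols)


def partition_definitions(sm: Supermatrix) -> list:
    """(label, 1-based charset expression) per partition.

    Coding genes are split per codon position (stride notation); RNA genes
    get a single contiguous interval.
    """
    out = []
    for gene, start, stop in sm.charsets:
        positions = sorted({p for g, _, p in sm.provenance
                            if g == gene and p})
        if positions:
            for p in positions:
                cols = sm.columns_for(gene, p)
                out.append((f"{gene}_pos{p}", _charset_expr(cols)))
        else:
            out.append((gene, _charset_expr(list(range(start, stop)))))
    return out


def export_partitions(sm: Supermatrix, dialect: str = "nexus_sets") -> str:
    """Render charsets as a NEXUS sets block or RAxML partition file."""
    defs = partition_definitions(sm)
    if dialect == "nexus_sets":
        lines = ["#NEXUS", "begin sets;"]
        lines += [f"    charset {label} = {expr};" for label, expr in defs]
        lines += ["end;", ""]
        return "\n".join(lines)
    if dialect == "raxml":
        return "\n".join(f"DNA, {label} = {expr}" for label, expr in defs) \
            + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


def parse_nexus_charsets(text: str) -> dict:
    """Parse a NEXUS sets block back to {label: sorted 0-based columns}."""
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line.lower().startswith("charset "):
            continue
        head, _, expr = line[len("charset "):].partition("=")
        label = head.strip()
        cols: list = []
        for token in expr.strip().rstrip(";").split():
            stride = 1
            if "\\" in token:
                token, s = token.split("\\")
                stride = int(s)
            if "-" in token:
                a, b = token.split("-")
                cols.extend(range(int(a) - 1, int(b), stride))
            else:
                cols.append(int(token) - 1)
        out[label] = sorted(cols)
    return out


def write_supermatrix_fasta(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sm.samples):
            fh.write(f">{s}\n{''.join(sm.matrix[i])}\n")


def write_supermatrix_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP: name, whitespace, full sequence per line."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.samples)} {sm.n_columns}\n")
        for i, s in enumerate(sm.samples):
            fh.write(f"{s}  {''.join(sm.matrix[i])}\n")
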