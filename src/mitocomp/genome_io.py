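"""Mitogenome record, feature, taxonomy and alignment I/O.

Parses annotated mitogenomes (GenBank flat files), normalizes gene names to
the 37 canonical insect mitochondrial gene symbols, extracts strand-aware
gene sequences (reverse-complementing minus-strand genes, handling features
that wrap the origin of a circular molecule), and reads/writes aligned
per-gene FASTA blocks and taxonomy tables.

Coordinates follow the GenBank convention throughout: 1-based, inclusive.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

PCG_NAMES = ("atp6", "atp8", "cob", "cox1", "cox2", "cox3",
             "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6")
RRNA_NAMES = ("rrnL", "rrnS")
TRNA_NAMES = ("trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH",
              "trnI", "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP",
              "trnQ", "trnR", "trnS1", "trnS2", "trnT", "trnV", "trnW",
              "trnY")
CANONICAL_GENES = PCG_NAMES + RRNA_NAMES + TRNA_NAMES  # the 37 genes

SEQ_ALPHABET = frozenset("ACGTN")
ALIGN_ALPHABET = frozenset("ACGTN-")

# one-letter amino acid -> canonical tRNA symbol (Leu/Ser need a tag)
_AA_TO_TRNA = {
    "A": "trnA", "C": "trnC", "D": "trnD", "E": "trnE", "F": "trnF",
    "G": "trnG", "H": "trnH", "I": "trnI", "K": "trnK", "M": "trnM",
    "N": "trnN", "P": "trnP", "Q": "trnQ", "R": "trnR", "T": "trnT",
    "V": "trnV", "W": "trnW", "Y": "trnY",
}
_AA3 = {"ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
        "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
        "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
        "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V"}

# codon-degeneracy tags and anticodons disambiguating the duplicated tRNAs
_LEU_SER_TAGS = {
    ("L", "CUN"): "trnL1", ("L", "UUR"): "trnL2",
    ("S", "AGN"): "trnS1", ("S", "UCN"): "trnS2",
    # anticodons (RNA or DNA spelling)
    ("L", "UAG"): "trnL1", ("L", "TAG"): "trnL1",
    ("L", "UAA"): "trnL2", ("L", "TAA"): "trnL2",
    ("S", "UCU"): "trnS1", ("S", "TCT"): "trnS1", ("S", "GCU"): "trnS1",
    ("S", "GCT"): "trnS1",
    ("S", "UGA"): "trnS2", ("S", "TGA"): "trnS2",
}

_SYNONYMS = {
    "coi": "cox1", "co1": "cox1", "cox1": "cox1", "coxi": "cox1",
    "coii": "cox2", "co2": "cox2", "cox2": "cox2", "coxii": "cox2",
    "coiii": "cox3", "co3": "cox3", "cox3": "cox3", "coxiii": "cox3",
    "atp6": "atp6", "atpase6": "atp6", "atp8": "atp8", "atpase8": "atp8",
    "cytb": "cob", "cob": "cob", "cb": "cob",
    "nd1": "nad1", "nad1": "nad1", "nd2": "nad2", "nad2": "nad2",
    "nd3": "nad3", "nad3": "nad3", "nd4": "nad4", "nad4": "nad4",
    "nd4l": "nad4l", "nad4l": "nad4l", "nd5": "nad5", "nad5": "nad5",
    "nd6": "nad6", "nad6": "nad6",
    "16s": "rrnL", "lrrna": "rrnL", "rrnl": "rrnL", "l-rrna": "rrnL",
    "16srrna": "rrnL", "16srdna": "rrnL",
    "12s": "rrnS", "srrna": "rrnS", "rrns": "rrnS", "s-rrna": "rrnS",
    "12srrna": "rrnS", "12srdna": "rrnS",
    "dloop": "control_region", "d-loop": "control_region",
    "controlregion": "control_region", "atrichregion": "control_region",
    "a+t-richregion": "control_region",
}


class MitoValidationError(ValueError):
    """A record, feature or alignment violates a structural invariant."""


class MitoParseError(ValueError):
    """Malformed input text (GenBank, FASTA, newick, taxonomy)."""


@dataclass(frozen=True)
class Taxonomy:
    """Five-level label set for one sampled individual.

    ``individual`` distinguishes conspecific samples; rank-stratified
    distance summaries rely on all five levels being present.
    """
    subfamily: str
    tribe: str
    genus: str
    species: str
    individual: str

    def __post_init__(self):
        for rank in ("subfamily", "tribe", "genus", "species", "individual"):
            if not getattr(self, rank):
                raise MitoValidationError(f"taxonomy rank '{rank}' is empty")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: canonical name, type, 1-based inclusive span."""
    name: str
    type: str              # PCG | tRNA | rRNA | control_region
    start: int             # 1-based inclusive
    end: int               # 1-based inclusive; end < start marks origin wrap
    strand: str            # '+' or '-'

    def __post_init__(self):
        if self.strand not in "+-":
            raise MitoValidationError(f"bad strand {self.strand!r}")
        if self.type not in ("PCG", "tRNA", "rRNA", "control_region"):
            raise MitoValidationError(f"bad feature type {self.type!r}")
        if self.start < 1 or self.end < 1:
            raise MitoValidationError("coordinates are 1-based; got "
                                      f"{self.start}..{self.end}")
        expected = expected_type(self.name)
        if expected is not None and expected != self.type:
            raise MitoValidationError(
                f"feature {self.name} typed {self.type}, expected {expected}")

    @property
    def wraps(self) -> bool:
        return self.end < self.start


def expected_type(name: str):
    if name in PCG_NAMES:
        return "PCG"
    if name in RRNA_NAMES:
        return "rRNA"
    if name in TRNA_NAMES:
        return "tRNA"
    if name == "control_region":
        return "control_region"
    return None


@dataclass
class MitoRecord:
    """One annotated mitogenome with its taxonomy labels."""
    sample_id: str
    sequence: str
    circular: bool
    complete: bool
    features: list
    taxonomy: Taxonomy | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.sequence:
            raise MitoValidationError(f"{self.sample_id}: empty sequence")
        bad = set(self.sequence) - SEQ_ALPHABET
        if bad:
            raise MitoValidationError(
                f"{self.sample_id}: disallowed symbols {sorted(bad)} "
                "(only A/C/G/T/N accepted; other ambiguity codes would "
                "corrupt composition counts)")
        n = len(self.sequence)
        if self.complete and not 14000 <= n <= 17000:
            raise MitoValidationError(
                f"{self.sample_id}: complete mitogenome length {n} outside "
                "the sanity range 14000-17000")
        seen: set = set()
        for f in self.features:
            if f.start > n or f.end > n:
                raise MitoValidationError(
                    f"{self.sample_id}:{f.name}: coordinates "
                    f"{f.start}..{f.end} outside [1, {n}]")
            if f.wraps and not self.circular:
                raise MitoValidationError(
                    f"{self.sample_id}:{f.name}: wraps the origin but the "
                    "record is not circular")
            if f.name != "control_region":
                if f.name not in CANONICAL_GENES:
                    raise MitoValidationError(
                        f"{self.sample_id}: non-canonical gene name "
                        f"{f.name!r} (trnL/trnS require a (UUR)/(CUN)/(AGN)/"
                        "(UCN) tag or anticodon)")
                if f.name in seen:
                    raise MitoValidationError(
                        f"{self.sample_id}: duplicate gene {f.name}")
                seen.add(f.name)

    def feature_by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"{self.sample_id}: no feature named {name!r}")

    def has_gene(self, name: str) -> bool:
        return any(f.name == name for f in self.features)


@dataclass
class AlignmentBlock:
    """A per-gene sample x site alignment over {A,C,G,T,-,N}.

    For coding blocks, ``reading_frame_offset`` columns precede the first
    complete codon and trailing partial codons are ignored by downstream
    codon arithmetic.
    """
    gene: str
    samples: list
    matrix: np.ndarray          # shape (n_samples, n_sites), dtype '<U1'
    is_coding: bool = False
    reading_frame_offset: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.samples):
            raise MitoValidationError(
                f"{self.gene}: matrix shape {self.matrix.shape} does not "
                f"match {len(self.samples)} samples")
        if len(set(self.samples)) != len(self.samples):
            raise MitoValidationError(f"{self.gene}: duplicate sample ids")
        bad = set(self.matrix.ravel()) - ALIGN_ALPHABET
        if bad:
            raise MitoValidationError(
                f"{self.gene}: disallowed alignment symbols {sorted(bad)}")
        if self.reading_frame_offset not in (0, 1, 2):
            raise MitoValidationError("reading_frame_offset must be 0, 1 or 2")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, sample_id: str) -> str:
        i = self.samples.index(sample_id)
        return "".join(self.matrix[i])

    def sequences(self) -> dict:
        return {s: "".join(r) for s, r in zip(self.samples, self.matrix)}

    def subset_columns(self, cols) -> "AlignmentBlock":
        blk = AlignmentBlock(self.gene, list(self.samples),
                             self.matrix[:, list(cols)],
                             is_coding=False, reading_frame_offset=0)
        return blk


# ---------------------------------------------------------------------------
# gene-name canonicalization

def canonicalize_gene_name(raw: str) -> str:
    """Map a free-form gene/product label to one of the 37 canonical symbols.

    Total function: unmapped input returns ``"unknown"``; a Leu/Ser tRNA
    without a disambiguating tag or anticodon returns the bare ``trnL`` /
    ``trnS`` placeholder, which record validation rejects (better to fail
    than to guess which paralog was meant).
    """
    if not raw:
        return "unknown"
    s = raw.strip()
    low = s.lower()

    # tRNA forms: tRNA-Leu(UUR), trnL2, trnS1(gct), trnW ...
    tag = None
    base = low
    if "(" in low and low.endswith(")"):
        base, _, tag_part = low.partition("(")
        tag = tag_part[:-1].upper()
    base = base.replace(" ", "").replace("_", "").rstrip("-")

    if base.startswith("trna-") or base.startswith("trna"):
        rest = base[5:] if base.startswith("trna-") else base[4:]
        aa = _AA3.get(rest[:3]) if len(rest) >= 3 else None
        if aa is None and len(rest) == 1 and \
                (rest.upper() in _AA_TO_TRNA or rest.upper() in ("L", "S")):
            aa = rest.upper()
        if aa:
            return _trna_symbol(aa, tag)
    if base.startswith("trn") and len(base) >= 4:
        aa = base[3].upper()
        suffix = base[4:]
        if aa in ("L", "S") and suffix in ("1", "2"):
            return f"trn{aa}{suffix}"
        if suffix == "" and (aa in _AA_TO_TRNA or aa in ("L", "S")):
            return _trna_symbol(aa, tag)

    key = base.replace("-", "")
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    return "unknown"


def _trna_symbol(aa: str, tag):
    if aa in _AA_TO_TRNA:
        return _AA_TO_TRNA[aa]
    if aa in ("L", "S"):
        if tag is not None:
            sym = _LEU_SER_TAGS.get((aa, tag))
            if sym is not None:
                return sym
        return f"trn{aa}"  # ambiguous placeholder; rejected at validation
    return "unknown"


# ---------------------------------------------------------------------------
# GenBank parsing

_FEATURE_TYPES = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                  "D-loop": "control_region", "misc_feature": None,
                  "gene": None}


def parse_genbank(text: str, taxonomy: Taxonomy | None = None) -> MitoRecord:
    """Parse a single GenBank flat-file record into a :class:`MitoRecord`.

    Gene and product qualifiers are normalized with
    :func:`canonicalize_gene_name`; features that cannot be mapped are
    skipped with a logged warning unless they are annotated control regions.
    """
    try:
        rec = SeqIO.read(io.StringIO(text), "genbank")
    except Exception as exc:  # biopython raises plain ValueError
        raise MitoParseError(f"malformed GenBank record: {exc}") from exc

    seq = str(rec.seq).upper()
    circular = (rec.annotations.get("topology", "") == "circular")
    complete = "complete" in rec.description.lower()
    n = len(seq)

    features = []
    for feat in rec.features:
        ftype = _FEATURE_TYPES.get(feat.type, None)
        if feat.type == "source":
            continue
        label = (feat.qualifiers.get("gene") or
                 feat.qualifiers.get("product") or
                 feat.qualifiers.get("note") or [""])[0]
        name = canonicalize_gene_name(label)
        anticodon = feat.qualifiers.get("anticodon")
        if name in ("trnL", "trnS") and anticodon:
            ac = anticodon[0].split(":")[-1].strip("()").upper()
            name = _LEU_SER_TAGS.get((name[3], ac), name)
        if ftype is None:
            if name == "control_region":
                ftype = "control_region"
            else:
                log.warning("skipping unrecognized feature %s (%r)",
                            feat.type, label)
                continue
        if name == "unknown":
            log.warning("skipping %s feature with unmapped label %r",
                        feat.type, label)
            continue
        if ftype == "control_region":
            name = "control_region"
        start, end, strand, wraps = _location_span(feat, n)
        features.append(GeneFeature(name=name, type=ftype, start=start,
                                    end=end, strand=strand))

    sample_id = rec.id if rec.id not in ("", "<unknown id>") else rec.name
    return MitoRecord(sample_id=sample_id, sequence=seq, circular=circular,
                      complete=complete, features=features, taxonomy=taxonomy)


def _location_span(feat: SeqFeature, n: int):
    loc = feat.location
    strand = "-" if loc.strand == -1 else "+"
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # a join(a..N,1..b) wrap of the circular origin
        if len(parts) == 2 and int(parts[1].end) == n and int(parts[0].start) == 0:
            return int(parts[1].start) + 1, int(parts[0].end), strand, True
        raise MitoParseError(
            f"unsupported compound location {loc} (only origin wraps are "
            "accepted)")
    start = int(loc.start) + 1  # biopython is 0-based half-open
    end = int(loc.end)
    if not (1 <= start <= n and 1 <= end <= n):
        raise MitoValidationError(
            f"feature coordinates {start}..{end} outside sequence [1, {n}]")
    return start, end, strand, False


REVCOMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(REVCOMP)[::-1]


def extract_gene(record: MitoRecord, name: str) -> str:
    """Return the gene's sequence on its annotated strand.

    Minus-strand genes are reverse-complemented; features wrapping the
    origin of a circular molecule concatenate the 3' tail and the 5' head.
    """
    feat = record.feature_by_name(name)
    seq = record.sequence
    if feat.wraps:
        if not record.circular:
            raise MitoValidationError(
                f"{record.sample_id}:{name}: origin wrap on a non-circular "
                "record")
        sub = seq[feat.start - 1:] + seq[:feat.end]
    else:
        sub = seq[feat.start - 1:feat.end]
    return reverse_complement(sub) if feat.strand == "-" else sub


# ---------------------------------------------------------------------------
# taxonomy tables

TAXONOMY_COLUMNS = ("sample_id", "subfamily", "tribe", "genus", "species",
                    "individual")


def load_taxonomy(path_or_buf) -> dict:
    """Read a TSV taxonomy table into ``{sample_id: Taxonomy}``."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    missing = set(TAXONOMY_COLUMNS) - set(df.columns)
    if missing:
        raise MitoParseError(f"taxonomy table missing columns "
                             f"{sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise MitoValidationError(f"duplicate sample_id {dup!r}")
    out = {}
    for _, row in df.iterrows():
        if row.isna().any():
            raise MitoParseError(
                f"taxonomy row for {row['sample_id']!r} has empty fields")
        out[row["sample_id"]] = Taxonomy(
            subfamily=row["subfamily"], tribe=row["tribe"],
            genus=row["genus"], species=row["species"],
            individual=row["individual"])
    return out


def write_taxonomy(taxonomy: dict, path) -> None:
    rows = [{"sample_id": sid, "subfamily": t.subfamily, "tribe": t.tribe,
             "genus": t.genus, "species": t.species,
             "individual": t.individual}
            for sid, t in taxonomy.items()]
    pd.DataFrame(rows, columns=TAXONOMY_COLUMNS).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# aligned FASTA

def read_aligned_fasta(path_or_buf, gene: str, is_coding: bool = False,
                       frame: int = 0) -> AlignmentBlock:
    """Read an aligned FASTA file into an :class:`AlignmentBlock`."""
    records = list(SeqIO.parse(path_or_buf, "fasta"))
    if not records:
        raise MitoParseError(f"{gene}: no sequences in FASTA input")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise MitoParseError(
            f"{gene}: ragged alignment, lengths {sorted(lengths)}")
    samples = [r.id for r in records]
    rows = []
    for r in records:
        s = str(r.seq).upper()
        bad = set(s) - ALIGN_ALPHABET
        if bad:
            col = next(i for i, c in enumerate(s) if c in bad)
            raise MitoParseError(
                f"{gene}:{r.id}: disallowed symbol {s[col]!r} at column "
                f"{col + 1}")
        rows.append(list(s))
    return AlignmentBlock(gene=gene, samples=samples,
                          matrix=np.array(rows, dtype="<U1"),
                          is_coding=is_coding, reading_frame_offset=frame)


def write_fasta(obj, path) -> None:
    """Write an AlignmentBlock or MitoRecord (or list of either) as FASTA."""
    items = obj if isinstance(obj, (list, tuple)) else [obj]
    seqrecs = []
    for item in items:
        if isinstance(item, AlignmentBlock):
            for sid, seq in item.sequences().items():
                seqrecs.append(SeqRecord(Seq(seq), id=sid, description=""))
        elif isinstance(item, MitoRecord):
            seqrecs.append(SeqRecord(Seq(item.sequence), id=item.sample_id,
                                     description=""))
        else:
            raise TypeError(f"cannot write {type(item).__name__} as FASTA")
    SeqIO.write(seqrecs, path, "fasta")


def write_genbank(record: MitoRecord, path) -> None:
    """Serialize a MitoRecord as a GenBank flat file (round-trippable)."""
    n = len(record.sequence)
    seqrec = SeqRecord(Seq(record.sequence), id=record.sample_id,
                       name=record.sample_id[:16].replace(".", "_"),
                       description="mitochondrion, complete genome"
                       if record.complete else "mitochondrion, partial")
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = ("circular" if record.circular
                                      else "linear")
    gb_type = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
               "control_region": "D-loop"}
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps:
            loc = CompoundLocation([
                FeatureLocation(f.start - 1, n, strand),
                FeatureLocation(0, f.end, strand)])
        else:
            loc = FeatureLocation(f.start - 1, f.end, strand)
        seqrec.features.append(
            SeqFeature(loc, type=gb_type[f.type],
                       qualifiers={"gene": [f.name]}))
    SeqIO.write(seqrec, path, "genbank")
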