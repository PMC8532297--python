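"""Genetic-code tables and synonymous-codon family structure.

Codon-usage statistics (RSCU, ENC, CBI, GC3s) and Ka/Ks counting all depend
on the synonymous-family structure of the active code.  The default is NCBI
translation table 5 (invertebrate mitochondrial), where AGA/AGG encode Ser
and TGA encodes Trp, giving 62 sense codons in 20 families: twelve two-fold,
six four-fold, one six-fold (Leu) and one eight-fold (Ser) family.  Tables
are taken from Biopython's NCBI registry, never hand-typed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

BASES = "TCAG"
ALL_CODONS = tuple("".join(c) for c in product("ACGT", repeat=3))


@dataclass(frozen=True)
class GeneticCode:
    """A translation table with its synonymous-family decomposition.

    Attributes
    ----------
    table_id : NCBI translation table number.
    forward : codon (DNA alphabet) -> one-letter amino acid, sense codons only.
    stop_codons : frozenset of stop codons.
    families : amino acid -> tuple of its synonymous codons (sorted).
    """

    table_id: int
    forward: dict = field(repr=False)
    stop_codons: frozenset = field(repr=False)
    families: dict = field(repr=False)

    @property
    def sense_codons(self) -> tuple:
        return tuple(sorted(self.forward))

    @property
    def n_sense(self) -> int:
        return len(self.forward)

    def family_of(self, codon: str):
        """Synonymous family (tuple of codons) of a sense codon, else None."""
        aa = self.forward.get(codon)
        return None if aa is None else self.families[aa]

    def family_size_counts(self) -> dict:
        """Map family size k -> number of amino-acid families of that size."""
        out: dict = {}
        for codons in self.families.values():
            out[len(codons)] = out.get(len(codons), 0) + 1
        return out

    def translate(self, codon: str):
        """Amino acid for a sense codon, '*' for a stop, None otherwise."""
        if codon in self.stop_codons:
            return "*"
        return self.forward.get(codon)


@lru_cache(maxsize=None)
def get_code(table_id: int = 5) -> GeneticCode:
    """Load an NCBI translation table as a :class:`GeneticCode`.

    ``table_id=5`` is the invertebrate mitochondrial code used throughout;
    ``table_id=1`` (standard) is useful in tests because its family-size
    structure differs (it has one-fold families, Met and Trp).
    """
    ncbi = CodonTable.unambiguous_dna_by_id[table_id]
    forward = dict(ncbi.forward_table)
    stops = frozenset(ncbi.stop_codons)
    families: dict = {}
    for codon, aa in forward.items():
        families.setdefault(aa, []).append(codon)
    families = {aa: tuple(sorted(cs)) for aa, cs in families.items()}
    return GeneticCode(table_id=table_id, forward=forward,
                       stop_codons=stops, families=families)
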