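"""Codon tables and nucleotide-level annotation of designed variants.

The synthesized coding sequence of the library is not part of the design
spec, but the read-count filters need a consistent definition of "reachable
by a single nucleotide change". We therefore fix one representative codon
per amino acid (an E. coli-biased usage table) and derive the WT coding
sequence from it; a caller may supply a different table or an explicit WT
nucleotide sequence instead.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

#: one representative (E. coli high-usage) codon per amino acid
DEFAULT_CODON_TABLE: dict[str, str] = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACC", "V": "GTT", "W": "TGG", "Y": "TAC",
}

#: all sense codons per amino acid under the standard genetic code
SENSE_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    SENSE_CODONS.setdefault(_aa, ())
    SENSE_CODONS[_aa] += (_codon,)


def reverse_translate_seq(protein: str, codon_table: dict[str, str] | None = None) -> str:
    """One deterministic coding sequence for ``protein`` under ``codon_table``."""
    table = codon_table or DEFAULT_CODON_TABLE
    try:
        return "".join(table[aa] for aa in protein)
    except KeyError as exc:  # pragma: no cover - config error
        raise KeyError(f"codon table lacks an assignment for {exc.args[0]!r}") from exc


def min_nt_changes(wt_codon: str, target_aa: str) -> int:
    """Minimum nucleotide substitutions turning ``wt_codon`` into ``target_aa``.

    Minimized over every sense codon of the target residue in the standard
    genetic code, not just the representative codon, because any of them
    realizes the amino-acid change.
    """
    if len(wt_codon) != 3:
        raise ValueError("wt_codon must be a triplet")
    codons = SENSE_CODONS.get(target_aa)
    if not codons:
        raise KeyError(f"no sense codons for {target_aa!r}")
    return min(sum(a != b for a, b in zip(wt_codon, c)) for c in codons)
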