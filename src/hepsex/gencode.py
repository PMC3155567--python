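"""Universal genetic-code helpers shared by the codon simulator and NG86 counting."""

from __future__ import annotations

from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = ("A", "C", "G", "T")

#: codon -> one-letter amino acid, with '*' for the three stop codons
CODON_TO_AA: dict[str, str] = {
    "".join(c): _TABLE.forward_table.get("".join(c), "*")
    for c in product(NUCLEOTIDES, repeat=3)
}

STOP_CODONS = frozenset(_TABLE.stop_codons)
NONSTOP_CODONS = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


@lru_cache(maxsize=None)
def neighbours(codon: str) -> tuple[str, ...]:
    """All non-stop codons one nucleotide away from ``codon``."""
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if alt not in STOP_CODONS:
                    out.append(alt)
    return tuple(out)


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """NG86 synonymous and non-synonymous site counts for one codon.

    At each position the fraction of synonymous changes is computed over the
    single-nucleotide changes that do not create a stop codon (nonsense
    changes are disregarded, as in the original counting method); each
    position contributes one site, so the counts sum to 3.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        alts = [
            codon[:pos] + nt + codon[pos + 1 :]
            for nt in NUCLEOTIDES
            if nt != codon[pos]
        ]
        sense = [a for a in alts if a not in STOP_CODONS]
        if sense:
            syn += sum(CODON_TO_AA[a] == aa for a in sense) / len(sense)
    return syn, 3.0 - syn
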