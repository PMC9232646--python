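"""Low-level DNA string helpers shared across the package.

Coordinates are 0-based half-open on the stored forward strand. Circular
molecules are stored as plain strings with an implicit origin at index 0;
positions are normalized modulo length where a function says so.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGT")

#: 34-bp symmetric Cre recognition site (self-reverse-complementary).
LOXPSYM = "ATAACTTCGTATAATGTACATTATACGAAGTTAT"
PMEI_SITE = "GTTTAAAC"
NOTI_SITE = "GCGGCCGC"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # {TAA, TAG, TGA}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate an in-frame DNA string with the standard nuclear code."""
    return str(Seq(seq).translate())


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def validate_dna(seq: str, *, context: str = "sequence") -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"{context} contains characters outside A/C/G/T: {sorted(bad)!r}"
        )


def rotate(seq: str, offset: int) -> str:
    """Rotate a circular sequence so old position ``offset`` becomes 0."""
    if not seq:
        return seq
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def find_all(haystack: str, needle: str, *, circular: bool = False) -> list[int]:
    """Start positions of every (possibly overlapping) occurrence.

    With ``circular=True`` occurrences wrapping the origin are found too and
    reported modulo ``len(haystack)``.
    """
    if not needle:
        raise ValueError("empty needle")
    n = len(haystack)
    search_in = haystack + haystack[: len(needle) - 1] if circular else haystack
    out: list[int] = []
    i = search_in.find(needle)
    while i != -1:
        out.append(i % n if circular else i)
        i = search_in.find(needle, i + 1)
    return out


def count_occurrences(haystack: str, needle: str, *, circular: bool = False) -> int:
    return len(find_all(haystack, needle, circular=circular))


def rotations_equal(a: str, b: str) -> bool:
    """True if ``a`` is a rotation of ``b`` (both read as circles)."""
    return len(a) == len(b) and (not a or a in b + b)


# --- codon synonym machinery (standard nuclear code) -----------------------

_CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in STOP_CODONS:
    _CODON_TO_AA[_stop] = "*"

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)


def synonymous_codons(codon: str) -> list[str]:
    """All codons (sorted) encoding the same residue, excluding ``codon``."""
    aa = _CODON_TO_AA[codon]
    return [c for c in _AA_TO_CODONS[aa] if c != codon]


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b, strict=True))


def alternate_codon(codon: str) -> str | None:
    """The synonym at maximal nucleotide Hamming distance from ``codon``.

    Ties resolve to the lexicographically smallest synonym; ``None`` when the
    codon has no synonym (Met, Trp).
    """
    syns = synonymous_codons(codon)
    if not syns:
        return None
    return max(syns, key=lambda c: (hamming(codon, c), [-ord(x) for x in c]))
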