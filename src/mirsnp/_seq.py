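"""Small sequence helpers shared across modules (RNA alphabet, complements)."""

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def dna_complement(base: str) -> str:
    return base.translate(_DNA_COMP)


def dna_revcomp(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def rna_complement(base: str) -> str:
    return base.translate(_RNA_COMP)


def rna_revcomp(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")
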