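"""Genetic-code tables and small sequence helpers (standard code)."""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

_TABLE = unambiguous_dna_by_id[1]

BASES = "ACGT"
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
CODONS = tuple(
    sorted(c for c in _TABLE.forward_table if set(c) <= set(BASES))
)  # 61 sense codons
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AA_OF = dict(_TABLE.forward_table)

#: aa by 6-bit codon integer (A=0 C=1 G=2 T=3); '*' for stops
AA_BY_INT = np.array(["?"] * 64)
STOP_INTS = set()
for _i0 in range(4):
    for _i1 in range(4):
        for _i2 in range(4):
            _c = BASES[_i0] + BASES[_i1] + BASES[_i2]
            _ci = 16 * _i0 + 4 * _i1 + _i2
            if _c in AA_OF:
                AA_BY_INT[_ci] = AA_OF[_c]
            else:
                AA_BY_INT[_ci] = "*"
                STOP_INTS.add(_ci)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
#: base-code transition partner (A<->G, C<->T)
TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.uint8)


def is_transition(a: str, b: str) -> bool:
    return (a, b) in TRANSITIONS


def codon_int(b0: int, b1: int, b2: int) -> int:
    return 16 * b0 + 4 * b1 + b2


def translate(cds: str) -> str:
    """Translate a CDS (stop codon, if present, is dropped from the protein)."""
    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def spliced_cds(genome: dict[str, str], chrom: str, strand: str, cds) -> str:
    """Concatenate CDS intervals (0-based half-open) honouring strand."""
    s = "".join(genome[chrom][iv.start : iv.end] for iv in cds)
    return revcomp(s) if strand == "-" else s
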