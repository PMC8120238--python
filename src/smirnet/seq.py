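"""Small RNA-sequence utilities shared by the generator and the target scanner."""

from __future__ import annotations

_RC = str.maketrans("ACGUN", "UGCAN")


def to_rna(seq: str) -> str:
    """Uppercase and transcribe DNA (T -> U)."""
    return seq.upper().replace("T", "U")


def revcomp_rna(seq: str) -> str:
    """Reverse complement on the RNA alphabet (N maps to N)."""
    return seq.translate(_RC)[::-1]


def complement_rna(base: str) -> str:
    return base.translate(_RC)
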