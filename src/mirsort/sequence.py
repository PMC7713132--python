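"""Small RNA-sequence helpers: alphabet normalization, complements, base pairing.

All sequences are handled 5'→3' as RNA (U canonical); DNA input (T) is
accepted everywhere and converted on entry.
"""

from __future__ import annotations

from .errors import ValidationError

RNA_ALPHABET = frozenset("ACGU")

#: Allowed base pairs: Watson-Crick plus the G:U wobble.
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})
PAIRS = WC_PAIRS | WOBBLE_PAIRS

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def clean_rna(seq: str, *, name: str = "sequence") -> str:
    """Upper-case, convert T→U, and validate the alphabet."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValidationError(
            f"{name} contains non-RNA characters: {sorted(bad)!r}"
        )
    return s


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (5'→3' in, 5'→3' out)."""
    return seq.translate(_COMPLEMENT)[::-1]


def can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIRS


def is_wc(a: str, b: str) -> bool:
    return (a, b) in WC_PAIRS


def is_wobble(a: str, b: str) -> bool:
    return (a, b) in WOBBLE_PAIRS


def pairing_partners(base: str) -> frozenset[str]:
    """All bases that ``base`` can pair with (WC or wobble)."""
    return frozenset(b for a, b in PAIRS if a == base)
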