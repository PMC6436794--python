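"""Degenerate (IUPAC) primer handling and in-silico PCR.

The assay's primer pair brackets a fixed-length insert on the
cytochrome-b gene. Primers are written with IUPAC ambiguity codes;
matching is asymmetric: a degenerate primer code matches any base in its
expansion, but the template must be a concrete A/C/G/T (an ``N`` in the
template fails every comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterator

from .panel import DiagnosticWindow, Haplotype

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# The assay primer pair (whitespace in printed sequences is stripped on input).
FORWARD_PRIMER_SEQ = "TGATGAAAYTTYGGMTCYCTHCTAGG"
REVERSE_PRIMER_SEQ = "AARAAGAATGATGCYCCRTTRGC"

__all__ = [
    "DegeneratePrimer",
    "AmpliconDefinition",
    "PrimerSiteError",
    "iupac_match",
    "degeneracy",
    "expand",
    "reverse_complement",
    "find_primer_sites",
    "extract_insert",
    "default_amplicon",
]


class PrimerSiteError(ValueError):
    """No usable primer binding site (absent or ambiguous) on a reference."""


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware (R<->Y, etc.)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegeneratePrimer:
    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        cleaned = "".join(self.sequence.split()).upper()
        object.__setattr__(self, "sequence", cleaned)
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        bad = set(cleaned) - set(IUPAC)
        if bad:
            raise ValueError(f"primer {self.name!r} has non-IUPAC characters {sorted(bad)}")
        if len(cleaned) < 10:
            raise ValueError(f"primer {self.name!r} is too short ({len(cleaned)} nt)")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AmpliconDefinition:
    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    insert_window: DiagnosticWindow = field(default_factory=DiagnosticWindow)

    @property
    def expected_insert_length(self) -> int:
        return self.insert_window.length


def default_amplicon() -> AmpliconDefinition:
    """The cytb assay: 26 nt forward + 23 nt reverse primer, 135 nt insert."""
    return AmpliconDefinition(
        forward=DegeneratePrimer("cytb_assay_F", FORWARD_PRIMER_SEQ, "forward"),
        reverse=DegeneratePrimer("cytb_assay_R", REVERSE_PRIMER_SEQ, "reverse"),
        insert_window=DiagnosticWindow("cytb", 114, 248),
    )


def iupac_match(code: str, base: str) -> bool:
    """True iff concrete template ``base`` lies in the expansion of ``code``.

    Asymmetric by design: ``code`` may be degenerate, ``base`` must be one
    of A/C/G/T; any other template character (including N) matches nothing.
    """
    try:
        expansion = IUPAC[code.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {code!r}") from None
    return base.upper() in expansion and base.upper() in "ACGT"


def degeneracy(primer: DegeneratePrimer) -> int:
    """Number of concrete oligos the degenerate primer encodes."""
    n = 1
    for c in primer.sequence:
        n *= len(IUPAC[c])
    return n


def expand(primer: DegeneratePrimer) -> Iterator[str]:
    """Enumerate every concrete expansion (degeneracy() of them)."""
    for combo in product(*(IUPAC[c] for c in primer.sequence)):
        yield "".join(combo)


def count_mismatches(pattern: str, text: str) -> int:
    """Mismatches of a degenerate pattern against a same-length concrete text."""
    return sum(0 if iupac_match(p, b) else 1 for p, b in zip(pattern, text))


def find_primer_sites(
    seq: str, primer: DegeneratePrimer, max_mismatch: int = 0
) -> list[tuple[int, str, int]]:
    """All binding sites of a primer on a concrete sequence.

    Scans both the given strand (``+``) and the reverse complement of the
    primer on the same coordinates (``-``). Returns ``(start, strand,
    mismatches)`` with 1-based starts, sorted by start position.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq = seq.upper()
    hits: list[tuple[int, str, int]] = []
    for strand, pattern in (("+", primer.sequence), ("-", reverse_complement(primer.sequence))):
        k = len(pattern)
        for start in range(len(seq) - k + 1):
            mm = 0
            window = seq[start : start + k]
            for p, b in zip(pattern, window):
                if not iupac_match(p, b):
                    mm += 1
                    if mm > max_mismatch:
                        break
            else:
                hits.append((start + 1, strand, mm))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def extract_insert(
    reference: Haplotype,
    amp: AmpliconDefinition,
    max_mismatch: int = 1,
    segment: str | None = None,
) -> tuple[str, tuple[int, int]]:
    """In-silico PCR: the bases strictly between the two primer sites.

    The forward primer must bind the given strand and the reverse primer's
    reverse complement must bind downstream of it; the insert excludes both
    primers. Returns ``(insert, (start, end))`` with 1-based inclusive
    template coordinates. A missing or multiply-binding primer raises
    :class:`PrimerSiteError` naming the offending primer.

    ``max_mismatch`` defaults to 1: the reverse-primer footprint overlaps
    one documented template polymorphism (cytb 258), so reference alleles
    there can mismatch the printed primer by a single base.
    """
    segment = segment or amp.insert_window.segment
    seq = reference.segment_sequences[segment]
    fwd_plus = [h for h in find_primer_sites(seq, amp.forward, max_mismatch) if h[1] == "+"]
    if fwd_plus:
        if len(fwd_plus) > 1:
            raise PrimerSiteError(
                f"forward primer {amp.forward.name!r} binds {len(fwd_plus)} sites on {reference.label!r}"
            )
        rev = [h for h in find_primer_sites(seq, amp.reverse, max_mismatch) if h[1] == "-"]
        rev = [h for h in rev if h[0] > fwd_plus[0][0] + len(amp.forward) - 1]
        if not rev:
            raise PrimerSiteError(f"reverse primer {amp.reverse.name!r} not found on {reference.label!r}")
        if len(rev) > 1:
            raise PrimerSiteError(
                f"reverse primer {amp.reverse.name!r} binds {len(rev)} sites on {reference.label!r}"
            )
        start = fwd_plus[0][0] + len(amp.forward)  # first insert base, 1-based
        end = rev[0][0] - 1  # last insert base
        if end < start:
            raise PrimerSiteError("primer sites overlap; no insert between them")
        return seq[start - 1 : end], (start, end)

    # Reverse-orientation reference: the forward primer appears reverse-
    # complemented downstream and the reverse primer's own pattern upstream;
    # the insert between them is the reverse complement of the forward-
    # orientation insert, at mirrored coordinates.
    fwd_minus = [h for h in find_primer_sites(seq, amp.forward, max_mismatch) if h[1] == "-"]
    if not fwd_minus:
        raise PrimerSiteError(f"forward primer {amp.forward.name!r} not found on {reference.label!r}")
    if len(fwd_minus) > 1:
        raise PrimerSiteError(
            f"forward primer {amp.forward.name!r} binds {len(fwd_minus)} sites on {reference.label!r}"
        )
    rev = [h for h in find_primer_sites(seq, amp.reverse, max_mismatch) if h[1] == "+"]
    rev = [h for h in rev if h[0] + len(amp.reverse) - 1 < fwd_minus[0][0]]
    if not rev:
        raise PrimerSiteError(f"reverse primer {amp.reverse.name!r} not found on {reference.label!r}")
    if len(rev) > 1:
        raise PrimerSiteError(
            f"reverse primer {amp.reverse.name!r} binds {len(rev)} sites on {reference.label!r}"
        )
    start = rev[0][0] + len(amp.reverse)
    end = fwd_minus[0][0] - 1
    if end < start:
        raise PrimerSiteError("primer sites overlap; no insert between them")
    return seq[start - 1 : end], (start, end)
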