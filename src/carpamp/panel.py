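"""Haplotype reference panels built from printed variant tables.

Mitochondrial haplotype surveys are usually published as a compact key:
one fully spelled-out reference haplotype plus, for every other haplotype,
the positions at which it differs (dots marking identity). This module
parses such keys, re-installs them onto a backbone sequence, and derives
the quantities a targeted assay designer needs: pairwise Hamming
distances and the partition of haplotypes that a fixed diagnostic window
can actually tell apart.

Coordinates are 1-based and inclusive throughout, numbered within each
gene segment (e.g. ``cytb:117`` is the 117th base of the cytochrome-b
gene), matching how such tables are printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

__all__ = [
    "VariantTable",
    "Haplotype",
    "ReferencePanel",
    "DiagnosticWindow",
    "VariantTableError",
    "parse_variant_table",
    "load_silver_carp_table",
    "reconstruct_haplotypes",
    "hamming_distance",
    "distance_matrix",
    "collapse_classes",
    "derive_variant_rows",
]


class VariantTableError(ValueError):
    """Malformed or internally inconsistent variant-table input."""


@dataclass(frozen=True)
class DiagnosticWindow:
    """A contiguous 1-based inclusive slice of one gene segment.

    The default assay window is the 135 nt cytochrome-b insert spanning
    positions 114-248, whose variable sites fall at 117-228.
    """

    segment: str = "cytb"
    start: int = 114
    end: int = 248

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid window bounds {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, segment: str, position: int) -> bool:
        return segment == self.segment and self.start <= position <= self.end

    @classmethod
    def parse(cls, text: str) -> "DiagnosticWindow":
        """Parse ``segment:start-end`` (e.g. ``cytb:114-248``)."""
        try:
            segment, span = text.split(":")
            start, end = (int(x) for x in span.split("-"))
        except ValueError as exc:
            raise ValueError(f"cannot parse window {text!r}; expected seg:start-end") from exc
        return cls(segment, start, end)


@dataclass
class VariantTable:
    """A printed haplotype key: positions, reference alleles, substitution rows.

    ``rows`` stores only the substitutions; ``None`` means "same as the
    reference haplotype" (a dot in print).
    """

    segments: list[tuple[str, int]]
    reference_label: str
    positions: list[tuple[str, int]]
    reference_alleles: list[str]
    rows: dict[str, list[str | None]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seg_len = dict(self.segments)
        prev: dict[str, int] = {}
        for seg, pos in self.positions:
            if seg not in seg_len:
                raise VariantTableError(f"position references undeclared segment {seg!r}")
            if pos > seg_len[seg]:
                raise VariantTableError(f"position {seg}:{pos} exceeds segment length {seg_len[seg]}")
            if seg in prev and pos <= prev[seg]:
                raise VariantTableError(f"positions not strictly increasing at {seg}:{pos}")
            prev[seg] = pos
        if len(self.reference_alleles) != len(self.positions):
            raise VariantTableError("reference allele count does not match position count")
        for base in self.reference_alleles:
            if base not in VALID_BASES:
                raise VariantTableError(f"invalid reference allele {base!r}")
        for label, alleles in self.rows.items():
            if len(alleles) != len(self.positions):
                raise VariantTableError(f"row {label!r} has {len(alleles)} entries, expected {len(self.positions)}")
            for (seg, pos), a in zip(self.positions, alleles):
                if a is not None and a not in VALID_BASES:
                    raise VariantTableError(f"invalid allele {a!r} in row {label!r} at {seg}:{pos}")
        # rows must be pairwise distinct over the full position set
        resolved = {label: tuple(self.resolved_alleles(label)) for label in self.rows}
        seen: dict[tuple, str] = {}
        for label, key in resolved.items():
            if key in seen:
                raise VariantTableError(f"rows {seen[key]!r} and {label!r} are identical")
            seen[key] = label

    @property
    def labels(self) -> list[str]:
        return sorted(self.rows)

    def resolved_alleles(self, label: str) -> list[str]:
        """Alleles of one haplotype with dots filled in from the reference."""
        return [ref if a is None else a for ref, a in zip(self.reference_alleles, self.rows[label])]

    def substitution_count(self, label: str) -> int:
        return sum(a is not None for a in self.rows[label])


@dataclass(frozen=True)
class Haplotype:
    label: str
    species: str
    segment_sequences: Mapping[str, str]
    provenance: str = "provided"  # or "reconstructed"

    def sequence(self, segment: str) -> str:
        return self.segment_sequences[segment]


@dataclass
class ReferencePanel:
    """Haplotypes grouped by species, with shared segment lengths per species."""

    entries: dict[str, list[Haplotype]] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def add(self, hap: Haplotype) -> None:
        haps = self.entries.setdefault(hap.species, [])
        if any(h.label == hap.label for h in haps):
            raise ValueError(f"duplicate haplotype label {hap.label!r} for {hap.species!r}")
        if haps:
            ref = haps[0]
            for seg, seq in hap.segment_sequences.items():
                if seg in ref.segment_sequences and len(ref.segment_sequences[seg]) != len(seq):
                    raise ValueError(f"segment length mismatch for {hap.species}/{hap.label}/{seg}")
        haps.append(hap)

    def species(self) -> list[str]:
        return sorted(self.entries)

    def all_haplotypes(self) -> list[Haplotype]:
        out: list[Haplotype] = []
        for sp in self.species():
            out.extend(sorted(self.entries[sp], key=lambda h: h.label))
        return out

    def get(self, species: str, label: str) -> Haplotype:
        for h in self.entries[species]:
            if h.label == label:
                return h
        raise KeyError(f"{species}/{label}")


def parse_variant_table(table_text: str) -> VariantTable:
    """Parse a dot-matrix haplotype key from TSV text.

    Layout: ``#segment <name> <length>`` header lines; a column header row
    (``label`` then ``<segment>:<pos>`` columns); one row per haplotype
    with ``.`` marking identity to the reference. The first haplotype row
    is the reference and must spell out every allele.
    """
    segments: list[tuple[str, int]] = []
    positions: list[tuple[str, int]] | None = None
    reference_label: str | None = None
    reference_alleles: list[str] = []
    rows: dict[str, list[str | None]] = {}

    for lineno, raw in enumerate(table_text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if parts[0].startswith("#segment"):
            if len(parts) != 3:
                raise VariantTableError(f"line {lineno}: expected '#segment name length'")
            name, length = parts[1], parts[2]
            if any(s == name for s, _ in segments):
                raise VariantTableError(f"line {lineno}: duplicate segment {name!r}")
            segments.append((name, int(length)))
            continue
        if parts[0] == "label":
            cols = parts[1:]
            parsed = []
            for i, col in enumerate(cols):
                try:
                    seg, pos = col.split(":")
                    parsed.append((seg, int(pos)))
                except ValueError as exc:
                    raise VariantTableError(f"line {lineno}, column {i + 2}: bad position header {col!r}") from exc
            positions = parsed
            continue
        if positions is None:
            raise VariantTableError(f"line {lineno}: haplotype row before position header")
        label, cells = parts[0], parts[1:]
        if label in rows or label == reference_label:
            raise VariantTableError(f"line {lineno}: duplicate haplotype label {label!r}")
        if len(cells) != len(positions):
            raise VariantTableError(f"line {lineno}: row {label!r} has {len(cells)} cells, expected {len(positions)}")
        if reference_label is None:
            reference_label = label
            for i, cell in enumerate(cells):
                if cell not in VALID_BASES:
                    raise VariantTableError(
                        f"line {lineno}, column {i + 2}: reference row must be concrete, got {cell!r}"
                    )
                reference_alleles.append(cell)
            rows[label] = [None] * len(positions)
            continue
        row: list[str | None] = []
        for i, cell in enumerate(cells):
            if cell == ".":
                row.append(None)
            elif cell in VALID_BASES:
                row.append(None if cell == reference_alleles[i] else cell)
            else:
                raise VariantTableError(f"line {lineno}, column {i + 2}: invalid allele {cell!r} in row {label!r}")
        rows[label] = row

    if positions is None or reference_label is None:
        raise VariantTableError("table has no position header or no haplotype rows")
    return VariantTable(segments, reference_label, positions, reference_alleles, rows)


def load_silver_carp_table() -> VariantTable:
    """The bundled North American silver carp cytb/COI haplotype key (A-H)."""
    text = resources.files("carpamp").joinpath("data/silver_carp_variants.tsv").read_text()
    return parse_variant_table(text)


def reconstruct_haplotypes(
    vt: VariantTable,
    backbone: Mapping[str, str],
    species: str = "silver carp",
) -> list[Haplotype]:
    """Install each variant row onto a backbone, yielding full sequences.

    The backbone must match the declared segment lengths and must carry
    the reference allele at every variant position; conflicts are reported
    together rather than one at a time.
    """
    seg_len = dict(vt.segments)
    for seg, length in seg_len.items():
        if seg not in backbone:
            raise VariantTableError(f"backbone missing segment {seg!r}")
        if len(backbone[seg]) != length:
            raise VariantTableError(
                f"backbone segment {seg!r} length {len(backbone[seg])} != declared {length}"
            )
    conflicts = [
        f"{seg}:{pos} backbone={backbone[seg][pos - 1]} reference={ref}"
        for (seg, pos), ref in zip(vt.positions, vt.reference_alleles)
        if backbone[seg][pos - 1].upper() != ref
    ]
    if conflicts:
        raise VariantTableError("backbone conflicts with reference alleles at: " + ", ".join(conflicts))

    out = []
    for label in vt.labels:
        seqs = {seg: list(backbone[seg].upper()) for seg in seg_len}
        for (seg, pos), allele in zip(vt.positions, vt.rows[label]):
            if allele is not None:
                seqs[seg][pos - 1] = allele
        out.append(
            Haplotype(
                label=label,
                species=species,
                segment_sequences={seg: "".join(s) for seg, s in seqs.items()},
                provenance="reconstructed",
            )
        )
    return out


def derive_variant_rows(haplotypes: Sequence[Haplotype], reference_label: str) -> VariantTable:
    """Invert reconstruction: re-derive the dot-matrix key from full sequences.

    Positions are those at which any haplotype differs from the reference.
    Used for the parse -> reconstruct -> derive round-trip check.
    """
    ref = next(h for h in haplotypes if h.label == reference_label)
    segments = [(seg, len(seq)) for seg, seq in ref.segment_sequences.items()]
    positions: list[tuple[str, int]] = []
    for seg, _ in segments:
        rseq = ref.segment_sequences[seg]
        for i in range(len(rseq)):
            if any(h.segment_sequences[seg][i] != rseq[i] for h in haplotypes):
                positions.append((seg, i + 1))
    reference_alleles = [ref.segment_sequences[seg][pos - 1] for seg, pos in positions]
    rows: dict[str, list[str | None]] = {}
    for h in haplotypes:
        row: list[str | None] = []
        for (seg, pos), ref_a in zip(positions, reference_alleles):
            a = h.segment_sequences[seg][pos - 1]
            row.append(None if a == ref_a else a)
        rows[h.label] = row
    return VariantTable(segments, reference_label, positions, reference_alleles, rows)


def _compared_indices(h1: Haplotype, window: DiagnosticWindow | None) -> dict[str, range]:
    if window is None:
        return {seg: range(len(seq)) for seg, seq in h1.segment_sequences.items()}
    if window.segment not in h1.segment_sequences:
        raise ValueError(f"window segment {window.segment!r} absent from haplotype {h1.label!r}")
    return {window.segment: range(window.start - 1, window.end)}


def hamming_distance(h1: Haplotype, h2: Haplotype, window: DiagnosticWindow | None = None) -> int:
    """Count of differing positions, optionally restricted to a window."""
    total = 0
    for seg, idx in _compared_indices(h1, window).items():
        s1, s2 = h1.segment_sequences[seg], h2.segment_sequences.get(seg)
        if s2 is None or len(s1) != len(s2):
            raise ValueError(f"segment {seg!r} length mismatch between {h1.label!r} and {h2.label!r}")
        total += sum(1 for i in idx if s1[i] != s2[i])
    return total


def distance_matrix(panel: ReferencePanel, window: DiagnosticWindow | None = None) -> pd.DataFrame:
    """Symmetric pairwise Hamming distances over every haplotype in the panel.

    Rows/columns are labelled ``species|label`` and ordered species-then-label.
    """
    haps = panel.all_haplotypes()
    if not haps:
        raise ValueError("panel is empty")
    labels = [f"{h.species}|{h.label}" for h in haps]
    n = len(haps)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = hamming_distance(haps[i], haps[j], window)
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def collapse_classes(panel: ReferencePanel, window: DiagnosticWindow) -> dict[str, list[str]]:
    """Partition each species' haplotypes into window-indistinguishable classes.

    Two haplotypes share a class iff their windowed distance is zero. Class
    names join member labels with ``/`` in alphabetical order (``A/C``).
    Returns mapping species -> sorted list of class names.
    """
    out: dict[str, list[str]] = {}
    for sp in panel.species():
        haps = sorted(panel.entries[sp], key=lambda h: h.label)
        classes: list[list[Haplotype]] = []
        for h in haps:
            for cl in classes:
                if hamming_distance(h, cl[0], window) == 0:
                    cl.append(h)
                    break
            else:
                classes.append([h])
        out[sp] = sorted("/".join(sorted(x.label for x in cl)) for cl in classes)
    return out
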