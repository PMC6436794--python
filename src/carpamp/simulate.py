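"""Synthetic backbones, panels, and full sequencing-run simulation.

Real reference backbones for the assay live in public archives; for
self-contained testing this module builds seeded pseudorandom stand-ins
that honour everything the variant table and primer pair constrain: the
declared segment lengths, the reference allele at every variant
position, and concrete primer-compatible sequence at the two binding
sites flanking the insert.

The run simulator emits paired-end reads with the full library
structure (spacer + primer + template), per-base substitution errors,
index hopping between libraries, primer dimers, and two-parent
chimeras, together with a per-read truth table for auditing every
downstream filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FastqRead, write_fastq
from .panel import DiagnosticWindow, ReferencePanel, VariantTable, reconstruct_haplotypes
from .pipeline import SpacerScheme
from .primers import (
    IUPAC,
    AmpliconDefinition,
    default_amplicon,
    reverse_complement,
)

__all__ = [
    "RunSimulationSpec",
    "SimulatedRun",
    "make_backbone",
    "build_silver_panel",
    "build_synthetic_bighead_inserts",
    "make_control_inserts",
    "simulate_run",
    "write_run",
    "default_spacer_schemes",
]

BASES = "ACGT"
_Q_GOOD, _Q_ERR = chr(35 + 33), chr(15 + 33)  # Q35 correct bases, Q15 injected errors


def _first_expansion(pattern: str) -> str:
    return "".join(IUPAC[c][0] for c in pattern)


def make_backbone(
    vt: VariantTable,
    amp: AmpliconDefinition | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Seeded pseudorandom reference sequences consistent with a variant table.

    Bases are drawn uniformly, then reference alleles are installed at
    every variant position, then concrete expansions of the two primers
    are installed immediately flanking the insert window (degenerate
    primer positions take the expansion base; where a literal primer base
    disagrees with an already-installed reference allele, the reference
    allele wins — the binding site then carries that one mismatch).
    Deterministic for a given seed.
    """
    amp = amp or default_amplicon()
    rng = np.random.default_rng(seed)
    seqs = {
        seg: list("".join(rng.choice(list(BASES), size=length)))
        for seg, length in vt.segments
    }
    for (seg, pos), ref in zip(vt.positions, vt.reference_alleles):
        seqs[seg][pos - 1] = ref

    win = amp.insert_window
    seg = win.segment
    fwd_start = win.start - len(amp.forward) - 1  # 0-based
    rev_start = win.end  # 0-based start of the reverse site
    if fwd_start < 0 or rev_start + len(amp.reverse) > len(seqs[seg]):
        raise ValueError("primer sites do not fit inside the segment")
    variant_pos = {p for s, p in vt.positions if s == seg}
    for start0, pattern in (
        (fwd_start, amp.forward.sequence),
        (rev_start, reverse_complement(amp.reverse.sequence)),
    ):
        for i, code in enumerate(pattern):
            pos1 = start0 + i + 1
            current = seqs[seg][start0 + i]
            if pos1 in variant_pos:
                # reference allele already installed there; it wins even when
                # it falls outside this primer character's expansion (the
                # binding site then carries that one mismatch)
                continue
            if current not in IUPAC[code]:
                seqs[seg][start0 + i] = IUPAC[code][0]
    return {s: "".join(b) for s, b in seqs.items()}


def build_silver_panel(
    vt: VariantTable, backbone: dict[str, str], species: str = "silver carp"
) -> ReferencePanel:
    panel = ReferencePanel(metadata={"backbone": "synthetic (seeded pseudorandom)"})
    for hap in reconstruct_haplotypes(vt, backbone, species=species):
        panel.add(hap)
    return panel


def build_synthetic_bighead_inserts(
    silver_inserts: dict[str, str],
    vt: VariantTable,
    window: DiagnosticWindow | None = None,
) -> dict[str, str]:
    """Synthetic bighead carp inserts (labels I-L) at assay-realistic distances.

    Real bighead sequences are not bundled; these stand-ins are built from
    the silver "A" insert by substituting 14 window positions that carry no
    silver variant, so that haplotype "L" sits exactly 14 nt from silver
    "A" and 15 nt from silver "B" — the distances the assay is known to
    resolve. "I"-"K" add 1-3 further substitutions on top of "L".
    """
    window = window or DiagnosticWindow()
    base = silver_inserts["A"]
    length = len(base)
    # insert-relative 0-based indices of silver variant positions
    variant_idx = {
        pos - window.start
        for seg, pos in vt.positions
        if seg == window.segment and window.start <= pos <= window.end
    }
    free = [i for i in range(length) if i not in variant_idx]
    chosen = free[:: max(1, len(free) // 18)][:17]  # spread 17 editable sites
    if len(chosen) < 17:
        raise ValueError("insert too short to place synthetic bighead substitutions")

    def flip(seq: str, idx: list[int]) -> str:
        s = list(seq)
        for i in idx:
            s[i] = BASES[(BASES.index(s[i]) + 1) % 4]
        return "".join(s)

    l_insert = flip(base, chosen[:14])
    return {
        "I": flip(l_insert, chosen[14:17]),
        "J": flip(l_insert, chosen[14:16]),
        "K": flip(l_insert, chosen[14:15]),
        "L": l_insert,
    }


def make_control_inserts(
    panel_inserts: dict[tuple[str, str], str],
    n_species: int = 10,
    min_distance: int = 30,
    seed: int = 0,
) -> dict[str, str]:
    """Mock positive-control species: random inserts far from every panel insert.

    Emulates a control mixture of species absent from the study area; each
    mock insert is at least ``min_distance`` nt from all panel inserts.
    """
    rng = np.random.default_rng(seed)
    length = len(next(iter(panel_inserts.values())))
    out: dict[str, str] = {}
    while len(out) < n_species:
        cand = "".join(rng.choice(list(BASES), size=length))
        ok = all(
            sum(1 for a, b in zip(cand, ref) if a != b) >= min_distance
            for ref in list(panel_inserts.values()) + list(out.values())
        )
        if ok:
            out[f"M{len(out) + 1:02d}"] = cand
    return out


def default_spacer_schemes(sample_ids: list[str]) -> dict[str, SpacerScheme]:
    """Deterministic unique (forward, reverse) spacer pair per library.

    Frameshifting spacers of 4-8 nt, enumerated so no two libraries share
    a pair.
    """
    schemes = {}
    for idx, sid in enumerate(sorted(sample_ids)):
        f = _encode_spacer(2 * idx, 4 + (idx % 5))
        r = _encode_spacer(2 * idx + 1, 4 + ((idx + 2) % 5))
        schemes[sid] = SpacerScheme(forward=f, reverse=r)
    return schemes


def _encode_spacer(value: int, length: int) -> str:
    digits = []
    v = value
    for _ in range(length):
        digits.append(BASES[v & 3])
        v >>= 2
    return "".join(digits)


@dataclass
class RunSimulationSpec:
    """Study conditions for one simulated sequencing run.

    ``compositions`` maps sample_id -> {insert_key: fraction}; insert keys
    index ``inserts`` (e.g. ``silver carp|A`` or ``control|M01``).
    Fractions per sample must sum to 1. NTC samples have empty
    compositions and emit only artifacts. The seed is mandatory.
    """

    inserts: dict[str, str]
    compositions: dict[str, dict[str, float]]
    roles: dict[str, str]
    schemes: dict[str, SpacerScheme]
    seed: int
    reads_per_sample: int = 5000
    error_rate: float = 0.001
    hop_rate: float = 0.0
    dimer_rate: float = 0.0
    chimera_rate: float = 0.0
    read_length: int = 150
    amp: AmpliconDefinition = field(default_factory=default_amplicon)

    def __post_init__(self) -> None:
        for rate in (self.error_rate, self.hop_rate, self.dimer_rate, self.chimera_rate):
            if not (0 <= rate < 1):
                raise ValueError("rates must be in [0, 1)")
        for sid, comp in self.compositions.items():
            if self.roles.get(sid) == "ntc":
                if comp:
                    raise ValueError(f"NTC {sid!r} must have an empty composition")
                continue
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition of {sid!r} sums to {total}, not 1")
            unknown = set(comp) - set(self.inserts)
            if unknown:
                raise ValueError(f"composition of {sid!r} references unknown inserts {sorted(unknown)}")


@dataclass
class SimulatedRun:
    pairs_by_library: dict[str, list[tuple[FastqRead, FastqRead]]]
    schemes: dict[str, SpacerScheme]
    roles: dict[str, str]
    truth: pd.DataFrame  # read_id, origin_sample, library, template, artifact_class


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def _sequence_read(construct: str, read_length: int, rng, error_rate: float) -> tuple[str, str]:
    raw = construct[:read_length]
    n = len(raw)
    if error_rate <= 0:
        return raw, _Q_GOOD * n
    errs = np.flatnonzero(rng.random(n) < error_rate)
    if errs.size == 0:
        return raw, _Q_GOOD * n
    idx = _BASE_INDEX[np.frombuffer(raw.encode(), dtype=np.uint8)]
    # substitute uniformly among the three other bases
    idx[errs] = (idx[errs] + rng.integers(1, 4, size=errs.size)) % 4
    seq = _BASE_BYTES[idx].tobytes().decode()
    qual = bytearray(_Q_GOOD.encode() * n)
    for e in errs:
        qual[e] = ord(_Q_ERR)
    return seq, qual.decode()


def simulate_run(spec: RunSimulationSpec) -> SimulatedRun:
    """Emit paired-end reads for every library, plus a per-read truth table.

    Each read pair is built as spacer + primer oligo + template (the
    amplicon's forward strand and its reverse complement, truncated to the
    read length). Artifact classes: ``clean`` (error-free template read),
    ``error`` (>=1 substitution injected), ``hop`` (emitted into another
    library while keeping its origin spacers), ``dimer`` (short
    primer-concatemer template), ``chimera`` (template spliced from two
    haplotypes at a uniform breakpoint). Byte-identical output for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    fwd_oligo = _first_expansion(spec.amp.forward.sequence)
    rev_oligo = _first_expansion(spec.amp.reverse.sequence)
    libraries = sorted(spec.compositions)
    pairs: dict[str, list[tuple[FastqRead, FastqRead]]] = {lib: [] for lib in libraries}
    truth_rows = []

    for sample in libraries:
        comp = spec.compositions[sample]
        scheme = spec.schemes[sample]
        labels = sorted(comp)
        probs = np.array([comp[k] for k in labels]) if labels else None
        is_ntc = spec.roles.get(sample) == "ntc"
        n_reads = (
            int(round(spec.reads_per_sample * spec.dimer_rate)) if is_ntc else spec.reads_per_sample
        )
        for i in range(n_reads):
            rid = f"{sample}:{i:06d}"
            if is_ntc or rng.random() < spec.dimer_rate:
                template = "".join(rng.choice(list(BASES), size=int(rng.integers(0, 41))))
                template_label, artifact = "-", "dimer"
            elif spec.chimera_rate > 0 and rng.random() < spec.chimera_rate and len(labels) >= 2:
                k1, k2 = rng.choice(len(labels), size=2, replace=False)
                t1, t2 = spec.inserts[labels[k1]], spec.inserts[labels[k2]]
                bp = int(rng.integers(1, len(t1)))
                template = t1[:bp] + t2[bp:]
                template_label, artifact = f"{labels[k1]}x{labels[k2]}@{bp}", "chimera"
            else:
                label = labels[int(rng.choice(len(labels), p=probs))]
                template = spec.inserts[label]
                template_label, artifact = label, "template"

            construct = scheme.forward + fwd_oligo + template + reverse_complement(rev_oligo) + reverse_complement(scheme.reverse)
            rc = reverse_complement(construct)
            s1, q1 = _sequence_read(construct, spec.read_length, rng, spec.error_rate)
            s2, q2 = _sequence_read(rc, spec.read_length, rng, spec.error_rate)
            if artifact == "template":
                artifact = "clean" if (s1 == construct[: len(s1)] and s2 == rc[: len(s2)]) else "error"

            library = sample
            if spec.hop_rate > 0 and len(libraries) > 1 and rng.random() < spec.hop_rate:
                others = [x for x in libraries if x != sample]
                library = others[int(rng.integers(len(others)))]
                artifact = "hop"
            pairs[library].append((FastqRead(rid, s1, q1), FastqRead(rid + "/2", s2, q2)))
            truth_rows.append(
                {
                    "read_id": rid,
                    "origin_sample": sample,
                    "library": library,
                    "template": template_label,
                    "artifact_class": artifact,
                }
            )

    truth = pd.DataFrame(truth_rows, columns=["read_id", "origin_sample", "library", "template", "artifact_class"])
    return SimulatedRun(pairs_by_library=pairs, schemes=spec.schemes, roles=dict(spec.roles), truth=truth)


def write_run(run: SimulatedRun, outdir: str | Path) -> Path:
    """Write FASTQ.gz pairs, manifest TSV, and truth TSV; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for lib in sorted(run.pairs_by_library):
        r1 = outdir / f"{lib}_R1.fastq.gz"
        r2 = outdir / f"{lib}_R2.fastq.gz"
        write_fastq(r1, [p[0] for p in run.pairs_by_library[lib]])
        write_fastq(r2, [p[1] for p in run.pairs_by_library[lib]])
        scheme = run.schemes[lib]
        rows.append(
            {
                "sample_id": lib,
                "role": run.roles.get(lib, "sample"),
                "fastq_r1": r1.name,
                "fastq_r2": r2.name,
                "spacer_f": scheme.forward,
                "spacer_r": scheme.reverse,
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    run.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return manifest
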