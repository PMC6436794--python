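"""Paired-end amplicon read processing.

The chain mirrors a targeted metabarcoding workflow with library-specific
spacer inserts: each read pair must carry its library's exact spacer and
both template primers and yield a template of the expected length
(rejecting index hops and primer dimers), mates are merged by best
ungapped overlap with quality-aware consensus, merged templates are
dereplicated into exact amplicon sequence variants (ASVs), low-count
ASVs explainable as sequencing error around an abundant parent are
absorbed under a Poisson model, and two-parent chimeras are removed.

A per-sample filter ledger records every read's fate; the counts are
conserved at each stage (raw = verified + all rejections; verified =
merged + merge rejections).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import poisson

from .io import FastqRead, RunConfig
from .primers import AmpliconDefinition, count_mismatches, reverse_complement

__all__ = [
    "SpacerScheme",
    "TrimmedPair",
    "Rejection",
    "ASVTable",
    "FilterLedger",
    "verify_and_trim",
    "merge_pair",
    "dereplicate",
    "denoise",
    "remove_chimeras",
    "process_sample_pairs",
]

VERIFY_REJECTIONS = ("spacer_mismatch", "missing_primer", "bad_length", "ambiguous_base")
MERGE_REJECTIONS = ("no_overlap", "excess_mismatch", "wrong_length")


@dataclass(frozen=True)
class SpacerScheme:
    """Expected (forward, reverse) spacer pair for one library.

    Spacers sit between the sequencing-adapter tail and the template
    primer; each library's pair is unique within a run, so a read whose
    spacer belongs to another library marks an index hop.
    """

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, s in (("forward", self.forward), ("reverse", self.reverse)):
            if not s or set(s) - set("ACGT"):
                raise ValueError(f"{name} spacer must be non-empty ACGT, got {s!r}")


@dataclass(frozen=True)
class TrimmedPair:
    """Both mates reduced to their template (insert) portions.

    ``t1`` is on the template's forward strand; ``t2`` is the raw second
    mate (reverse strand) — merging reverse-complements it.
    """

    id: str
    t1: str
    q1: str
    t2: str
    q2: str


@dataclass(frozen=True)
class Rejection:
    id: str
    reason: str


class FilterLedger:
    """Per-sample read-fate counters along the verification/merge chain."""

    def __init__(self) -> None:
        self.counts: dict[str, Counter] = {}

    def tally(self, sample: str, stage: str, n: int = 1) -> None:
        self.counts.setdefault(sample, Counter())[stage] += n

    def get(self, sample: str, stage: str) -> int:
        return self.counts.get(sample, Counter())[stage]

    def samples(self) -> list[str]:
        return sorted(self.counts)

    def check_conservation(self, sample: str) -> bool:
        c = self.counts.get(sample, Counter())
        verify_ok = c["raw"] == c["verified"] + sum(c[r] for r in VERIFY_REJECTIONS)
        merge_ok = c["verified"] == c["merged"] + sum(c[r] for r in MERGE_REJECTIONS)
        return verify_ok and merge_ok

    def to_rows(self) -> list[dict]:
        stages = ["raw", *VERIFY_REJECTIONS, "verified", *MERGE_REJECTIONS, "merged"]
        return [
            {"sample_id": s, **{st: self.counts[s][st] for st in stages}}
            for s in self.samples()
        ]


@lru_cache(maxsize=32)
def _pattern_sets(pattern: str) -> tuple[frozenset, ...]:
    from .primers import IUPAC

    return tuple(frozenset(IUPAC[c]) for c in pattern)


def _find_pattern(template: str, pattern: str, max_mismatch: int) -> int | None:
    """Leftmost start (0-based) of a degenerate pattern in a concrete string."""
    sets = _pattern_sets(pattern)
    k = len(pattern)
    for start in range(len(template) - k + 1):
        mm = 0
        for i in range(k):
            if template[start + i] not in sets[i]:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return start
    return None


def _verify_mate(
    seq: str, qual: str, spacer: str, primer_seq: str, cfg: RunConfig
) -> tuple[str, str] | str:
    """Strip spacer + primer from one mate; return (template, quals) or a reason."""
    if not seq.startswith(spacer):
        return "spacer_mismatch"
    rest = seq[len(spacer) :]
    k = len(primer_seq)
    if len(rest) < k or count_mismatches(primer_seq, rest[:k]) > cfg.primer_mismatch:
        return "missing_primer"
    cut = len(spacer) + k
    return seq[cut:], qual[cut:]


def verify_and_trim(
    pair: tuple[FastqRead, FastqRead],
    scheme: SpacerScheme,
    amp: AmpliconDefinition,
    cfg: RunConfig,
) -> TrimmedPair | Rejection:
    """Check spacer (exact), primers (IUPAC, <= cfg.primer_mismatch), length.

    The spacer comparison is deliberately exact: spacers are the index-hop
    sentinel, and any tolerance would defeat that purpose. After trimming,
    a mate that reads through into the opposite primer reveals the full
    template length, which must be within ``cfg.length_tolerance`` of the
    expected insert length (primer dimers fail here). Templates containing
    N are rejected separately (``ambiguous_base``).
    """
    r1, r2 = pair
    expected = amp.expected_insert_length

    out1 = _verify_mate(r1.sequence, r1.quality, scheme.forward, amp.forward.sequence, cfg)
    if isinstance(out1, str):
        return Rejection(r1.id, out1)
    out2 = _verify_mate(r2.sequence, r2.quality, scheme.reverse, amp.reverse.sequence, cfg)
    if isinstance(out2, str):
        return Rejection(r1.id, out2)
    t1, q1 = out1
    t2, q2 = out2

    # Read-through: the opposite primer's reverse complement inside the
    # template exposes the template's true 3' end on that mate.
    for which, opposite in ((1, amp.reverse), (2, amp.forward)):
        t, q = (t1, q1) if which == 1 else (t2, q2)
        pos = _find_pattern(t, reverse_complement(opposite.sequence), cfg.primer_mismatch)
        observed_end = pos is not None
        if observed_end:
            t, q = t[:pos], q[:pos]
        if observed_end and abs(len(t) - expected) > cfg.length_tolerance:
            return Rejection(r1.id, "bad_length")
        if not observed_end and len(t) > expected + cfg.length_tolerance:
            return Rejection(r1.id, "bad_length")
        if which == 1:
            t1, q1 = t, q
        else:
            t2, q2 = t, q

    if "N" in t1 or "N" in t2:
        return Rejection(r1.id, "ambiguous_base")
    return TrimmedPair(r1.id, t1, q1, t2, q2)


def merge_pair(pre: TrimmedPair, cfg: RunConfig) -> str | Rejection:
    """Merge mates by best ungapped overlap with quality-aware consensus.

    The second mate is reverse-complemented onto the forward strand and
    slid along the first; the overlap with the fewest mismatches (ties to
    the longer overlap) wins, provided it spans at least ``cfg.min_overlap``
    bases with a mismatch fraction at most ``cfg.max_overlap_mismatch``.
    Disagreements take the higher-quality base (first mate wins exact
    quality ties); agreements keep the higher of the two quality scores.
    """
    t1, q1 = pre.t1, pre.q1
    t2 = reverse_complement(pre.t2)
    q2 = pre.q2[::-1]
    n1, n2 = len(t1), len(t2)
    if min(n1, n2) < cfg.min_overlap:
        return Rejection(pre.id, "no_overlap")

    a1 = np.frombuffer(t1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(t2.encode(), dtype=np.uint8)
    best: tuple[int, int, int] | None = None  # (mismatches, -overlap, offset)
    for offset in range(0, n1 - cfg.min_overlap + 1):
        overlap = min(n1 - offset, n2)
        if overlap < cfg.min_overlap:
            break
        mm = int(np.count_nonzero(a1[offset : offset + overlap] != a2[:overlap]))
        cand = (mm, -overlap, offset)
        if best is None or cand < best:
            best = cand
    if best is None:
        return Rejection(pre.id, "no_overlap")
    mm, neg_overlap, offset = best
    overlap = -neg_overlap
    if mm / overlap > cfg.max_overlap_mismatch:
        return Rejection(pre.id, "excess_mismatch")

    merged = list(t1[:offset])
    for i in range(overlap):
        b1, b2 = t1[offset + i], t2[i]
        if b1 == b2:
            merged.append(b1)
        else:
            merged.append(b1 if q1[offset + i] >= q2[i] else b2)
    merged.extend(t2[overlap:])
    return "".join(merged)


@dataclass
class ASVTable:
    """Dereplicated amplicon sequence variants with per-sample counts.

    ``records`` maps asv_id -> (sequence, {sample: count}); ids are
    assigned in descending total abundance (ties broken by sequence).
    """

    records: dict[str, tuple[str, dict[str, int]]] = field(default_factory=dict)
    samples: list[str] = field(default_factory=list)
    ledger: FilterLedger = field(default_factory=FilterLedger)

    @property
    def sequences(self) -> dict[str, str]:
        return {aid: seq for aid, (seq, _) in self.records.items()}

    def total(self, asv_id: str) -> int:
        return sum(self.records[asv_id][1].values())

    def sample_total(self, sample: str) -> int:
        return sum(counts.get(sample, 0) for _, counts in self.records.values())

    def sample_counts(self, sample: str) -> dict[str, int]:
        return {
            aid: counts[sample]
            for aid, (_, counts) in self.records.items()
            if counts.get(sample, 0) > 0
        }

    def to_frame(self):
        import pandas as pd

        rows = []
        for aid, (seq, counts) in self.records.items():
            rows.append({"asv_id": aid, "sequence": seq, **{s: counts.get(s, 0) for s in self.samples}})
        return pd.DataFrame(rows, columns=["asv_id", "sequence", *self.samples])


def _build_table(
    seq_counts: dict[str, dict[str, int]], samples: list[str], ledger: FilterLedger
) -> ASVTable:
    order = sorted(seq_counts, key=lambda s: (-sum(seq_counts[s].values()), s))
    width = max(4, len(str(len(order))))
    records = {
        f"ASV_{i + 1:0{width}d}": (seq, dict(seq_counts[seq])) for i, seq in enumerate(order)
    }
    return ASVTable(records=records, samples=list(samples), ledger=ledger)


def dereplicate(
    merged_by_sample: dict[str, list[str]], ledger: FilterLedger | None = None
) -> ASVTable:
    """Group identical merged templates into ASVs, keeping per-sample counts."""
    seq_counts: dict[str, dict[str, int]] = {}
    for sample, seqs in merged_by_sample.items():
        for seq in seqs:
            seq_counts.setdefault(seq, {}).setdefault(sample, 0)
            seq_counts[seq][sample] += 1
    return _build_table(seq_counts, sorted(merged_by_sample), ledger or FilterLedger())


def _hamming(a: str, b: str) -> int | None:
    if len(a) != len(b):
        return None
    return sum(1 for x, y in zip(a, b) if x != y)


def denoise(table: ASVTable, error_rate: float | None = None, alpha: float | None = None,
            cfg: RunConfig | None = None) -> ASVTable:
    """Absorb error-explainable minor ASVs into more abundant parents.

    For a minor ASV at Hamming distance ``d`` from a more abundant parent
    with ``N`` reads, the expected number of parent reads miscalled into
    exactly the minor's sequence is ``lam = N * (e/3)**d * (1-e)**(L-d)``
    (substitutions independent per base at rate ``e``, each of the three
    alternative bases equally likely). The minor is absorbed — its counts
    added to the parent — when the Poisson upper tail
    ``P(X >= count | lam)`` exceeds ``alpha``, i.e. when its abundance is
    unsurprising under errors alone. Passes repeat until no ASV moves, so
    the operation is idempotent. Total counts are conserved.
    """
    cfg = cfg or RunConfig()
    e = cfg.denoise_error_rate if error_rate is None else error_rate
    a = cfg.denoise_alpha if alpha is None else alpha
    if not (0 < e < 0.1):
        raise ValueError("error_rate must be in (0, 0.1)")
    if not (0 < a < 1):
        raise ValueError("alpha must be in (0, 1)")

    seq_counts = {seq: dict(counts) for _, (seq, counts) in table.records.items()}

    changed = True
    while changed:
        changed = False
        order = sorted(seq_counts, key=lambda s: (-sum(seq_counts[s].values()), s))
        for seq in reversed(order):  # least abundant first within the pass
            if seq not in seq_counts:
                continue
            n_minor = sum(seq_counts[seq].values())
            best_parent, best_tail = None, a
            for parent in order:
                if parent == seq or parent not in seq_counts:
                    continue
                n_parent = sum(seq_counts[parent].values())
                if n_parent <= n_minor:
                    continue
                d = _hamming(parent, seq)
                if d is None or d == 0:
                    continue
                length = len(seq)
                lam = n_parent * (e / 3.0) ** d * (1.0 - e) ** (length - d)
                tail = poisson.sf(n_minor - 1, lam)  # P(X >= n_minor)
                if tail > best_tail:
                    best_parent, best_tail = parent, tail
            if best_parent is not None:
                for sample, c in seq_counts[seq].items():
                    seq_counts[best_parent].setdefault(sample, 0)
                    seq_counts[best_parent][sample] += c
                del seq_counts[seq]
                changed = True
    return _build_table(seq_counts, table.samples, table.ledger)


def remove_chimeras(table: ASVTable, cfg: RunConfig | None = None) -> ASVTable:
    """Drop ASVs that split cleanly into two abundant parents (bimeras).

    An ASV is removed when some breakpoint divides it into a prefix that
    exactly matches one parent and a suffix that exactly matches another,
    with both parents at least ``cfg.chimera_fold`` times more abundant.
    Removed reads are recorded in the ledger (stage ``chimera``), not
    reassigned.
    """
    cfg = cfg or RunConfig()
    entries = [(seq, counts, sum(counts.values())) for _, (seq, counts) in table.records.items()]
    keep: dict[str, dict[str, int]] = {}
    for seq, counts, total in entries:
        length = len(seq)
        parents = [p for p, _, pt in entries if p != seq and len(p) == length and pt >= cfg.chimera_fold * total]
        is_chimera = False
        if len(parents) >= 2:
            # longest exact prefix/suffix agreement with each candidate parent
            pref = {p: _shared_prefix(seq, p) for p in parents}
            suff = {p: _shared_suffix(seq, p) for p in parents}
            for p1 in parents:
                if is_chimera:
                    break
                for p2 in parents:
                    if p1 == p2:
                        continue
                    # need breakpoint b in 1..length-1 with pref(p1) >= b and suff(p2) >= length-b
                    if pref[p1] >= 1 and suff[p2] >= 1 and pref[p1] + suff[p2] >= length:
                        is_chimera = True
                        break
        if is_chimera:
            for sample, c in counts.items():
                table.ledger.tally(sample, "chimera", c)
        else:
            keep[seq] = counts
    return _build_table(keep, table.samples, table.ledger)


def _shared_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _shared_suffix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(reversed(a), reversed(b)):
        if x != y:
            break
        n += 1
    return n


def process_sample_pairs(
    pairs_by_sample: dict[str, list[tuple[FastqRead, FastqRead]]],
    schemes: dict[str, SpacerScheme],
    amp: AmpliconDefinition,
    cfg: RunConfig,
) -> ASVTable:
    """Full chain: verify/trim -> merge -> dereplicate -> denoise -> de-chimera.

    Returns the final ASV table; the embedded ledger carries per-sample
    counts for every stage. Samples with zero surviving reads still appear
    in the table's sample list (and ledger).
    """
    ledger = FilterLedger()
    merged_by_sample: dict[str, list[str]] = {}
    expected = amp.expected_insert_length
    for sample in sorted(pairs_by_sample):
        merged_by_sample[sample] = []
        scheme = schemes[sample]
        for pair in pairs_by_sample[sample]:
            ledger.tally(sample, "raw")
            out = verify_and_trim(pair, scheme, amp, cfg)
            if isinstance(out, Rejection):
                ledger.tally(sample, out.reason)
                continue
            ledger.tally(sample, "verified")
            merged = merge_pair(out, cfg)
            if isinstance(merged, Rejection):
                ledger.tally(sample, merged.reason)
                continue
            if abs(len(merged) - expected) > cfg.length_tolerance:
                ledger.tally(sample, "wrong_length")
                continue
            ledger.tally(sample, "merged")
            merged_by_sample[sample].append(merged)
    table = dereplicate(merged_by_sample, ledger)
    table = denoise(table, cfg=cfg)
    table = remove_chimeras(table, cfg)
    return table
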