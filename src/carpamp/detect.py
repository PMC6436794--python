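"""Positive-control calibration, NTC checks, and species/haplotype assignment.

Every sequencing run carries positive controls (a mixture of known
species absent from the study area) and no-template controls (NTCs).
Any positive-control ASV that is not exactly one of the expected
sequences is erroneous — the product of PCR/sequencing error or index
hopping — and the largest single erroneous-ASV fraction observed becomes
the run's detection cutoff: a sample ASV below that fraction is not
trusted on abundance alone.

ASVs are assigned to species and haplotype classes by Hamming distance
against a curated panel of amplicon inserts (exact match -> known; a
near match unique to one species -> novel haplotype; ties between
species -> ambiguous). A below-cutoff ASV is normally discarded, but is
flagged as a putative detection requiring confirmation when it matches a
panel species and is too divergent (>10% of the insert length) from
every retained ASV in its sample to be an error derivative of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import RunConfig
from .panel import ReferencePanel
from .pipeline import ASVTable

__all__ = [
    "RunCalibration",
    "Assignment",
    "DetectionRow",
    "DetectionReport",
    "PanelIndex",
    "build_panel_index",
    "index_from_inserts",
    "CalibrationError",
    "calibrate",
    "check_ntc",
    "apply_cutoff",
    "assign_asv",
    "flag_below_cutoff",
    "summarize",
    "detect_run",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class RunCalibration:
    """Run-level erroneous-ASV cutoff derived from positive controls."""

    cutoff_fraction: float
    evidence: dict[str, float]  # positive-control sample -> max erroneous ASV fraction
    ntc_status: dict[str, str] = field(default_factory=dict)  # ntc sample -> pass|fail

    def to_dict(self) -> dict:
        return {
            "cutoff_fraction": round(self.cutoff_fraction, 6),
            "evidence": {k: round(v, 6) for k, v in sorted(self.evidence.items())},
            "ntc_status": dict(sorted(self.ntc_status.items())),
        }


@dataclass(frozen=True)
class Assignment:
    asv_id: str
    species: str | None
    haplotype_class: str | None
    distance: int | None
    status: str  # known | novel | ambiguous | unassigned
    nearest_label: str | None = None


@dataclass(frozen=True)
class DetectionRow:
    species: str
    haplotype_class: str
    asv_id: str
    reads: int
    fraction: float
    status: str
    flag: str  # none | below_cutoff_removed | below_cutoff_flagged | requires_confirmation


@dataclass
class DetectionReport:
    sample_id: str
    rows: list[DetectionRow] = field(default_factory=list)
    merged_total: int = 0
    valid: bool = True  # False when an NTC failure invalidates the run's libraries

    def species_detected(self) -> dict[str, list[str]]:
        """species -> sorted haplotype classes among retained panel assignments.

        Only rows actually assigned to a panel species (known or novel)
        count; retained ASVs that are unassigned or ambiguous are listed in
        ``rows`` but are not species detections.
        """
        out: dict[str, set[str]] = {}
        for r in self.rows:
            if r.flag in ("none", "requires_confirmation") and r.status in ("known", "novel"):
                out.setdefault(r.species, set()).add(r.haplotype_class)
        return {sp: sorted(cls) for sp, cls in sorted(out.items())}


@dataclass
class PanelIndex:
    """Assignment-ready view of a reference panel: one insert per haplotype.

    ``inserts`` maps (species, label) -> insert sequence; ``classes`` maps
    (species, label) -> the haplotype's diagnostic-window class name.
    """

    inserts: dict[tuple[str, str], str]
    classes: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.inserts.values()}
        if len(lengths) > 1:
            raise ValueError(f"panel inserts have mixed lengths {sorted(lengths)}")

    @property
    def insert_length(self) -> int:
        return len(next(iter(self.inserts.values())))


def index_from_inserts(inserts: dict[tuple[str, str], str]) -> PanelIndex:
    """Build a :class:`PanelIndex` from bare insert sequences.

    Because the diagnostic window *is* the insert, two haplotypes of one
    species are window-indistinguishable exactly when their inserts are
    identical; each group of identical inserts forms a class named by
    joining its labels with ``/`` in alphabetical order.
    """
    classes: dict[tuple[str, str], str] = {}
    by_species: dict[str, dict[str, str]] = {}
    for (sp, label), seq in inserts.items():
        by_species.setdefault(sp, {})[label] = seq
    for sp, labelled in by_species.items():
        groups: dict[str, list[str]] = {}
        for label, seq in sorted(labelled.items()):
            groups.setdefault(seq, []).append(label)
        for seq, labels in groups.items():
            name = "/".join(sorted(labels))
            for label in labels:
                classes[(sp, label)] = name
    return PanelIndex(inserts=dict(inserts), classes=classes)


def build_panel_index(
    panel: ReferencePanel,
    amp=None,
    extra_inserts: dict[tuple[str, str], str] | None = None,
) -> PanelIndex:
    """Run in-silico PCR on every panel haplotype and index the inserts.

    ``extra_inserts`` lets callers add insert-only references (species
    without full-length backbones, keyed ``(species, label)``).
    """
    from .primers import default_amplicon, extract_insert

    amp = amp or default_amplicon()
    inserts: dict[tuple[str, str], str] = {}
    for hap in panel.all_haplotypes():
        insert, _ = extract_insert(hap, amp)
        inserts[(hap.species, hap.label)] = insert
    if extra_inserts:
        inserts.update(extra_inserts)
    return index_from_inserts(inserts)


def calibrate(
    table: ASVTable, positive_controls: list[str], expected_sequences: list[str]
) -> RunCalibration:
    """Cutoff = the largest single erroneous-ASV fraction across controls.

    An ASV is erroneous when its sequence is not exactly one of the
    expected positive-control sequences. A control with only expected
    sequences contributes 0; an empty control is an error.
    """
    if not positive_controls:
        raise CalibrationError("no positive-control samples")
    if not expected_sequences:
        raise CalibrationError("expected positive-control sequences are empty")
    expected = set(expected_sequences)
    evidence: dict[str, float] = {}
    for pc in positive_controls:
        total = table.sample_total(pc)
        if total == 0:
            raise CalibrationError(f"positive control {pc!r} has no reads in the ASV table")
        worst = 0.0
        for aid, count in table.sample_counts(pc).items():
            if table.sequences[aid] not in expected:
                worst = max(worst, count / total)
        evidence[pc] = worst
    return RunCalibration(cutoff_fraction=max(evidence.values()), evidence=evidence)


def check_ntc(sample: str, table: ASVTable, cfg: RunConfig) -> str:
    """``pass`` unless the NTC's verified-read count exceeds the allowance.

    Reads that were rejected at verification (wrong spacer, no primer, bad
    length) do not count against the control — only reads that look like
    genuine template do.
    """
    verified = table.ledger.get(sample, "verified")
    return "fail" if verified > cfg.ntc_max_reads else "pass"


def apply_cutoff(
    table: ASVTable, sample: str, cal: RunCalibration
) -> tuple[dict[str, float], dict[str, float]]:
    """Split one sample's ASVs into retained and below-cutoff sets.

    Fractions are of the sample's ASV-table total. The boundary is kept:
    an ASV exactly at the cutoff is retained. Returns two asv_id ->
    fraction mappings (retained, below).
    """
    total = table.sample_total(sample)
    if total == 0:
        return {}, {}
    retained: dict[str, float] = {}
    below: dict[str, float] = {}
    for aid, count in table.sample_counts(sample).items():
        frac = count / total
        (retained if frac >= cal.cutoff_fraction else below)[aid] = frac
    return retained, below


def assign_asv(
    asv_id: str, sequence: str, panel: PanelIndex, cfg: RunConfig | None = None
) -> Assignment:
    """Best Hamming match of an ASV against every panel insert.

    Distance 0 -> ``known`` with the matched haplotype's class; a unique
    best species within ``cfg.novel_max`` -> ``novel``; an exact tie
    between species -> ``ambiguous`` (never silently resolved); anything
    farther -> ``unassigned``. ASVs whose length differs from the panel
    insert length are unassigned outright.
    """
    cfg = cfg or RunConfig()
    if len(sequence) != panel.insert_length:
        return Assignment(asv_id, None, None, None, "unassigned")
    best_d = None
    best_hits: list[tuple[str, str]] = []
    for (species, label), insert in sorted(panel.inserts.items()):
        d = sum(1 for a, b in zip(sequence, insert) if a != b)
        if best_d is None or d < best_d:
            best_d, best_hits = d, [(species, label)]
        elif d == best_d:
            best_hits.append((species, label))
    assert best_d is not None
    species_hit = sorted({sp for sp, _ in best_hits})
    if best_d == 0:
        sp, label = best_hits[0]
        if len(species_hit) > 1:
            return Assignment(asv_id, None, None, 0, "ambiguous")
        return Assignment(asv_id, sp, panel.classes[(sp, label)], 0, "known", label)
    if best_d <= cfg.novel_max:
        if len(species_hit) > 1:
            return Assignment(asv_id, None, None, best_d, "ambiguous")
        sp, label = best_hits[0]
        return Assignment(asv_id, sp, "novel", best_d, "novel", label)
    return Assignment(asv_id, None, None, best_d, "unassigned")


def flag_below_cutoff(
    below: dict[str, float],
    retained: dict[str, float],
    table: ASVTable,
    panel: PanelIndex,
    cfg: RunConfig | None = None,
) -> dict[str, str]:
    """Decide each below-cutoff ASV's fate: flagged putative detection or removed.

    Flagged (``below_cutoff_flagged``) when the ASV (i) assigns to a panel
    species (known or novel) and (ii) differs from every retained ASV in
    the sample by more than ``cfg.divergence_floor_fraction`` of the
    insert length — too divergent to be an error derivative of anything
    retained. Otherwise ``below_cutoff_removed``.
    """
    cfg = cfg or RunConfig()
    floor = cfg.divergence_floor_fraction * panel.insert_length  # strict >
    flags: dict[str, str] = {}
    for aid in sorted(below):
        seq = table.sequences[aid]
        assignment = assign_asv(aid, seq, panel, cfg)
        if assignment.status not in ("known", "novel"):
            flags[aid] = "below_cutoff_removed"
            continue
        divergent = True
        for rid in retained:
            rseq = table.sequences[rid]
            if len(rseq) == len(seq):
                d = sum(1 for a, b in zip(seq, rseq) if a != b)
                if d <= floor:
                    divergent = False
                    break
        flags[aid] = "below_cutoff_flagged" if divergent else "below_cutoff_removed"
    return flags


def summarize(
    sample: str,
    table: ASVTable,
    retained: dict[str, float],
    flags: dict[str, str],
    panel: PanelIndex,
    cfg: RunConfig | None = None,
) -> DetectionReport:
    """One report row per retained or flagged ASV, ordered by fraction.

    Fractions are recomputed over the sample's merged-read total from the
    ledger (chimera-removed reads stay in the denominator). Positive panel
    detections always carry ``requires_confirmation``: a detection stands
    only after re-sequencing on an independent run.
    """
    cfg = cfg or RunConfig()
    merged_total = table.ledger.get(sample, "merged")
    denom = merged_total if merged_total > 0 else table.sample_total(sample)
    rows: list[DetectionRow] = []
    counts = table.sample_counts(sample)
    for aid, _ in sorted(retained.items(), key=lambda kv: (-kv[1], kv[0])):
        a = assign_asv(aid, table.sequences[aid], panel, cfg)
        reads = counts[aid]
        rows.append(
            DetectionRow(
                species=a.species or "unassigned",
                haplotype_class=a.haplotype_class or "-",
                asv_id=aid,
                reads=reads,
                fraction=reads / denom if denom else 0.0,
                status=a.status,
                flag="requires_confirmation" if a.status in ("known", "novel") else "none",
            )
        )
    for aid, flag in sorted(flags.items()):
        if flag != "below_cutoff_flagged":
            continue
        a = assign_asv(aid, table.sequences[aid], panel, cfg)
        reads = counts[aid]
        rows.append(
            DetectionRow(
                species=a.species or "unassigned",
                haplotype_class=a.haplotype_class or "-",
                asv_id=aid,
                reads=reads,
                fraction=reads / denom if denom else 0.0,
                status=a.status,
                flag="below_cutoff_flagged",
            )
        )
    return DetectionReport(sample_id=sample, rows=rows, merged_total=merged_total)


def detect_run(
    table: ASVTable,
    roles: dict[str, str],
    expected_control_sequences: list[str],
    panel: PanelIndex,
    cfg: RunConfig | None = None,
) -> tuple[RunCalibration, dict[str, DetectionReport]]:
    """Calibrate from positive controls, check NTCs, and report every sample.

    ``roles`` maps sample_id -> sample|positive_control|ntc. A failing NTC
    marks every report in the run invalid (detections are still listed so
    the evidence stays inspectable).
    """
    cfg = cfg or RunConfig()
    controls = sorted(s for s, r in roles.items() if r == "positive_control")
    ntcs = sorted(s for s, r in roles.items() if r == "ntc")
    samples = sorted(s for s, r in roles.items() if r == "sample")

    cal = calibrate(table, controls, expected_control_sequences)
    ntc_status = {s: check_ntc(s, table, cfg) for s in ntcs}
    cal = RunCalibration(cal.cutoff_fraction, cal.evidence, ntc_status)
    run_valid = all(v == "pass" for v in ntc_status.values())

    reports: dict[str, DetectionReport] = {}
    for s in samples:
        retained, below = apply_cutoff(table, s, cal)
        flags = flag_below_cutoff(below, retained, table, panel, cfg)
        report = summarize(s, table, retained, flags, panel, cfg)
        report.valid = run_valid
        reports[s] = report
    return cal, reports
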