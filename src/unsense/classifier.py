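"""Evidence-driven classification of coding variants.

Codon-level categories come from :mod:`unsense.genetic_code`; the final
label additionally depends on experimental evidence records.  A variant that
merely *looks* synonymous at codon level is labelled ``unverified`` until
evidence shows either no effect (verified synonymous), an RNA-level
splicing/regulatory effect (unsense), or an effect at another level
(synonymous with effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from unsense.genetic_code import (
    Category,
    CodonTable,
    classify_codon_substitution,
    _normalize_codon,
)
from unsense.taxonomy import (
    EffectTag,
    Level,
    MechanismTag,
    UNSENSE_MECHANISMS,
)


class ClassifierError(ValueError):
    pass


class LinkageError(ClassifierError):
    """Evidence attached to a different variant than the one classified."""


class FinalLabel(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    UNSENSE = "unsense"
    SYNONYMOUS_WITH_EFFECT = "synonymous_with_effect"
    VERIFIED_SYNONYMOUS = "verified_synonymous"
    UNVERIFIED_SYNONYMOUS_PREDICTED = "unverified_synonymous_predicted"


class EvidenceStatus(str, Enum):
    NONE = "none"
    EFFECT_SHOWN = "effect_shown"
    NO_EFFECT_SHOWN = "no_effect_shown"


class FrameStatus(str, Enum):
    IN_FRAME = "in_frame"
    FRAMESHIFT = "frameshift"


class Verdict(str, Enum):
    CONFIRMED = "confirmed"
    OVERCLAIMED_SYNONYMOUS = "overclaimed_synonymous"
    MISLABELED = "mislabeled"


# ---------------------------------------------------------------------------
# transcript model and coordinate arithmetic


@dataclass(frozen=True)
class TranscriptModel:
    """Exon lengths (transcript order, 5'->3') plus a CDS span.

    Coordinates are 1-based inclusive positions in transcript space.
    """

    transcript_id: str
    exon_lengths: tuple[int, ...]
    cds_start: int
    cds_end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "exon_lengths", tuple(self.exon_lengths))
        if len(self.exon_lengths) < 1:
            raise ClassifierError(f"{self.transcript_id}: at least one exon required")
        if any(l <= 0 for l in self.exon_lengths):
            raise ClassifierError(f"{self.transcript_id}: exon lengths must be positive")
        if self.cds_start < 1:
            raise ClassifierError(f"{self.transcript_id}: cds_start must be >= 1")
        if self.cds_end > self.length:
            raise ClassifierError(
                f"{self.transcript_id}: cds_end {self.cds_end} exceeds "
                f"transcript length {self.length}"
            )
        if self.cds_length % 3 != 0:
            raise ClassifierError(
                f"{self.transcript_id}: CDS length {self.cds_length} "
                f"not divisible by 3"
            )
        if self.strand not in (None, "+", "-"):
            raise ClassifierError(f"{self.transcript_id}: strand must be +/-/None")

    @property
    def length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    def exon_span(self, exon_index: int) -> tuple[int, int]:
        """1-based inclusive transcript span of exon ``exon_index`` (1-based)."""
        if not 1 <= exon_index <= self.n_exons:
            raise ClassifierError(
                f"{self.transcript_id}: exon {exon_index} out of range "
                f"1..{self.n_exons}"
            )
        start = sum(self.exon_lengths[: exon_index - 1]) + 1
        return start, start + self.exon_lengths[exon_index - 1] - 1

    def exon_of(self, tx_pos: int) -> int:
        """1-based exon index containing a transcript position."""
        if not 1 <= tx_pos <= self.length:
            raise ClassifierError(
                f"{self.transcript_id}: position {tx_pos} outside transcript"
            )
        for i in range(1, self.n_exons + 1):
            s, e = self.exon_span(i)
            if s <= tx_pos <= e:
                return i
        raise AssertionError("unreachable")

    def coding_length_of_exon(self, exon_index: int) -> int:
        """Number of CDS bases falling inside the exon (0 if non-coding)."""
        s, e = self.exon_span(exon_index)
        return max(0, min(e, self.cds_end) - max(s, self.cds_start) + 1)

    def cds_to_tx(self, cds_pos: int) -> int:
        """Convert a 1-based CDS position to a transcript position."""
        if not 1 <= cds_pos <= self.cds_length:
            raise ClassifierError(
                f"{self.transcript_id}: CDS position {cds_pos} outside "
                f"1..{self.cds_length}"
            )
        return self.cds_start + cds_pos - 1

    def to_dict(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "exon_lengths": list(self.exon_lengths),
            "cds_start": self.cds_start,
            "cds_end": self.cds_end,
            "strand": self.strand,
        }


def map_cds_position(cds_pos: int, transcript: TranscriptModel | None = None) -> tuple[int, int]:
    """(codon_index, codon_pos) for a 1-based CDS position.

    codon_index = ceil(pos/3), codon_pos in 1..3; 3*(codon_index-1)+codon_pos
    round-trips to the input.
    """
    if cds_pos < 1:
        raise ClassifierError(f"CDS position must be >= 1, got {cds_pos}")
    if transcript is not None and cds_pos > transcript.cds_length:
        raise ClassifierError(
            f"{transcript.transcript_id}: CDS position {cds_pos} exceeds "
            f"CDS length {transcript.cds_length}"
        )
    codon_index = (cds_pos + 2) // 3
    codon_pos = (cds_pos - 1) % 3 + 1
    return codon_index, codon_pos


@dataclass(frozen=True)
class VariantObservation:
    transcript_id: str
    cds_pos: int
    ref_base: str
    alt_base: str
    claimed_label: Optional[str] = None
    variant_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cds_pos < 1:
            raise ClassifierError(f"cds_pos must be >= 1, got {self.cds_pos}")
        object.__setattr__(self, "ref_base", _normalize_codon(self.ref_base * 3)[0])
        object.__setattr__(self, "alt_base", _normalize_codon(self.alt_base * 3)[0])
        if self.ref_base == self.alt_base:
            raise ClassifierError("ref and alt base identical: not a substitution")
        if self.variant_id is None:
            object.__setattr__(self, "variant_id", self.key)

    @property
    def key(self) -> str:
        return f"{self.transcript_id}:c.{self.cds_pos}{self.ref_base}>{self.alt_base}"

    @property
    def codon_index(self) -> int:
        return map_cds_position(self.cds_pos)[0]

    @property
    def codon_pos(self) -> int:
        return map_cds_position(self.cds_pos)[1]


def variant_codons(cds_sequence: str, obs: VariantObservation) -> tuple[str, str]:
    """Extract (ref_codon, alt_codon) for a variant from its CDS sequence."""
    seq = cds_sequence.upper().replace("U", "T")
    if obs.cds_pos > len(seq):
        raise ClassifierError(
            f"{obs.variant_id}: CDS position {obs.cds_pos} beyond sequence "
            f"of length {len(seq)}"
        )
    i = obs.codon_index
    ref_codon = seq[3 * (i - 1): 3 * i]
    if len(ref_codon) != 3:
        raise ClassifierError(f"{obs.variant_id}: truncated codon at index {i}")
    if ref_codon[obs.codon_pos - 1] != obs.ref_base:
        raise ClassifierError(
            f"{obs.variant_id}: reference base mismatch — sequence has "
            f"{ref_codon[obs.codon_pos - 1]} at c.{obs.cds_pos}, variant says "
            f"{obs.ref_base}"
        )
    alt_codon = (
        ref_codon[: obs.codon_pos - 1] + obs.alt_base + ref_codon[obs.codon_pos:]
    )
    return ref_codon, alt_codon


# ---------------------------------------------------------------------------
# evidence


@dataclass(frozen=True)
class EvidenceRecord:
    """One experimental observation attached to a variant."""

    variant_id: str
    assay: str
    mechanism: MechanismTag
    effect: EffectTag
    level: Level

    def __post_init__(self) -> None:
        object.__setattr__(self, "mechanism", MechanismTag(self.mechanism))
        object.__setattr__(self, "effect", EffectTag(self.effect))
        object.__setattr__(self, "level", Level(self.level))
        if (
            self.mechanism is not MechanismTag.NONE_OBSERVED
            and self.mechanism.level is not self.level
        ):
            raise ClassifierError(
                f"{self.variant_id}: mechanism {self.mechanism.value} operates at "
                f"{self.mechanism.level.value}, record says {self.level.value}"
            )

    @property
    def shows_effect(self) -> bool:
        return (
            self.effect is not EffectTag.NO_EFFECT
            and self.mechanism is not MechanismTag.NONE_OBSERVED
        )


# ---------------------------------------------------------------------------
# NMD / splice-consequence rules


@dataclass(frozen=True)
class NmdConfig:
    """Escape window: premature stops within ``penultimate_window_nt`` of the
    3' end of the penultimate exon (or anywhere in the last exon) escape decay."""

    penultimate_window_nt: int = 50

    def __post_init__(self) -> None:
        if self.penultimate_window_nt < 0:
            raise ClassifierError("NMD window must be >= 0")


def nmd_escapes(
    transcript: TranscriptModel, ptc_tx_pos: int, nmd: NmdConfig | None = None
) -> bool:
    """True iff a premature stop at the given transcript position escapes decay.

    Escape iff the position lies in the last exon, or within the configured
    window upstream of the penultimate exon's 3' end.  Monotone: escape at p
    implies escape at every position > p.
    """
    nmd = nmd or NmdConfig()
    if transcript.n_exons == 1:
        return True
    penult_end = sum(transcript.exon_lengths[:-1])  # 3' end of penultimate exon
    return ptc_tx_pos > penult_end - nmd.penultimate_window_nt


@dataclass(frozen=True)
class ExonSkipEvent:
    """Skipping of exon ``exon_index`` (1-based, transcript order).

    ``ptc_tx_pos``, when measured, is the premature-stop position in the
    coordinates of the *reduced* transcript (the one NMD surveys).
    """

    exon_index: int
    ptc_tx_pos: Optional[int] = None


@dataclass(frozen=True)
class SegmentEvent:
    """Insertion or deletion of ``length`` nt of coding sequence at
    transcript position ``tx_pos`` (used for the frame rule only)."""

    tx_pos: int
    length: int
    kind: str  # "del" | "ins"
    ptc_tx_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("del", "ins"):
            raise ClassifierError(f"segment kind must be del/ins, got {self.kind!r}")
        if self.length < 1:
            raise ClassifierError("segment length must be >= 1")


@dataclass(frozen=True)
class SpliceConsequence:
    frame_status: FrameStatus
    ptc_tx_pos: Optional[int]
    nmd_predicted: bool
    effects: tuple[EffectTag, ...]
    affects_coding: bool = True


def splice_consequence(
    transcript: TranscriptModel,
    event: ExonSkipEvent | SegmentEvent,
    nmd: NmdConfig | None = None,
) -> SpliceConsequence:
    """Frame and decay consequence of an exon skip or coding del/ins.

    In-frame iff the affected coding length is divisible by 3.  On frameshift
    a premature stop is assumed downstream; it escapes decay only in the last
    exon or within the configured window of the penultimate exon's 3' end,
    otherwise the transcript is predicted degraded (effect: missing RNA).
    """
    nmd = nmd or NmdConfig()
    if isinstance(event, ExonSkipEvent):
        if transcript.n_exons == 1:
            raise ClassifierError(
                f"{transcript.transcript_id}: cannot skip the only exon"
            )
        coding_len = transcript.coding_length_of_exon(event.exon_index)
        if coding_len == 0:
            return SpliceConsequence(
                frame_status=FrameStatus.IN_FRAME,
                ptc_tx_pos=None,
                nmd_predicted=False,
                effects=(),
                affects_coding=False,
            )
        base_effects = [EffectTag.EXON_SKIPPING, EffectTag.ABERRANT_SPLICING]
        # transcript as surveyed after the skip
        reduced_exons = (
            transcript.exon_lengths[: event.exon_index - 1]
            + transcript.exon_lengths[event.exon_index:]
        )
        surveyed = _unchecked_model(transcript.transcript_id, reduced_exons)
        skipped_start, _ = transcript.exon_span(event.exon_index)
        default_ptc = min(max(skipped_start, 1), sum(reduced_exons))
        ptc = event.ptc_tx_pos if event.ptc_tx_pos is not None else default_ptc
    else:
        coding_len = event.length
        base_effects = [EffectTag.ABERRANT_SPLICING]
        surveyed = transcript
        ptc = event.ptc_tx_pos if event.ptc_tx_pos is not None else event.tx_pos

    if coding_len % 3 == 0:
        return SpliceConsequence(
            frame_status=FrameStatus.IN_FRAME,
            ptc_tx_pos=None,
            nmd_predicted=False,
            effects=tuple(base_effects),
        )

    escapes = nmd_escapes(surveyed, ptc, nmd)
    effects = base_effects + [EffectTag.FRAMESHIFT, EffectTag.PREMATURE_STOP]
    if not escapes:
        effects.append(EffectTag.MISSING_RNA)
    return SpliceConsequence(
        frame_status=FrameStatus.FRAMESHIFT,
        ptc_tx_pos=ptc,
        nmd_predicted=not escapes,
        effects=tuple(effects),
    )


def _unchecked_model(tid: str, exon_lengths: Sequence[int]) -> TranscriptModel:
    # minimal stand-in whose CDS constraints are irrelevant to NMD geometry
    total = sum(exon_lengths)
    return TranscriptModel(
        transcript_id=tid,
        exon_lengths=tuple(exon_lengths),
        cds_start=1,
        cds_end=total - (total % 3),
    ) if total >= 3 else TranscriptModel(tid, (3,), 1, 3)


# ---------------------------------------------------------------------------
# final-label rules


@dataclass(frozen=True)
class ClassificationResult:
    variant_id: str
    codon_category: Category
    final_label: FinalLabel
    mechanisms: tuple[MechanismTag, ...]
    effects: tuple[EffectTag, ...]
    levels: tuple[Level, ...]
    evidence_status: EvidenceStatus
    conflict: bool = False

    def __post_init__(self) -> None:
        if self.final_label is FinalLabel.UNSENSE and not (
            set(self.mechanisms) & UNSENSE_MECHANISMS
        ):
            raise ClassifierError(
                f"{self.variant_id}: unsense label requires a splicing/"
                f"regulatory mechanism"
            )
        syn_like = {
            FinalLabel.VERIFIED_SYNONYMOUS,
            FinalLabel.UNVERIFIED_SYNONYMOUS_PREDICTED,
            FinalLabel.SYNONYMOUS_WITH_EFFECT,
            FinalLabel.UNSENSE,
        }
        if self.final_label in syn_like and self.codon_category not in (
            Category.SYNONYMOUS,
            Category.STOP_TO_STOP,
        ):
            raise ClassifierError(
                f"{self.variant_id}: label {self.final_label.value} requires a "
                f"codon-synonymous change, got {self.codon_category.value}"
            )
        if self.evidence_status is EvidenceStatus.NONE and self.final_label not in (
            FinalLabel.MISSENSE,
            FinalLabel.NONSENSE,
            FinalLabel.UNVERIFIED_SYNONYMOUS_PREDICTED,
        ):
            raise ClassifierError(
                f"{self.variant_id}: evidence-free result cannot carry label "
                f"{self.final_label.value}"
            )
        if EffectTag.NO_EFFECT in self.effects and len(self.effects) > 1:
            raise ClassifierError(
                f"{self.variant_id}: NO_EFFECT is exclusive of other effect tags"
            )

    def to_dict(self) -> dict:
        return {
            "variant_id": self.variant_id,
            "codon_category": self.codon_category.value,
            "final_label": self.final_label.value,
            "mechanisms": [m.value for m in self.mechanisms],
            "effects": [e.value for e in self.effects],
            "levels": [l.value for l in self.levels],
            "evidence_status": self.evidence_status.value,
            "conflict": self.conflict,
        }


def classify_variant(
    obs: VariantObservation,
    codons: tuple[str, str],
    evidence: Iterable[EvidenceRecord] = (),
    table: CodonTable | None = None,
    nmd: NmdConfig | None = None,
) -> ClassificationResult:
    """Assign the final label from codon-level category plus evidence.

    Rule order: a nonsynonymous codon category decides by itself (evidence is
    reported as co-annotation); a codon-synonymous change is unverified
    without evidence, unsense when any effect-showing record carries a
    splicing/splicing-regulation/miRNA mechanism, synonymous-with-effect when
    effects are confined to DNA, protein, or mRNA-stability mechanisms, and
    verified synonymous when all records show no effect.  Stop<->stop changes
    follow the same evidence rules as synonymous ones.
    """
    table = table or CodonTable.standard()
    ref_codon = _normalize_codon(codons[0])
    alt_codon = _normalize_codon(codons[1])
    if ref_codon[obs.codon_pos - 1] != obs.ref_base:
        raise ClassifierError(
            f"{obs.variant_id}: ref codon {ref_codon} does not carry "
            f"{obs.ref_base} at codon position {obs.codon_pos}"
        )
    if alt_codon[obs.codon_pos - 1] != obs.alt_base:
        raise ClassifierError(
            f"{obs.variant_id}: alt codon {alt_codon} does not carry "
            f"{obs.alt_base} at codon position {obs.codon_pos}"
        )
    category = classify_codon_substitution(ref_codon, alt_codon, table)

    evidence = list(evidence)
    for rec in evidence:
        if rec.variant_id != obs.variant_id:
            raise LinkageError(
                f"evidence for {rec.variant_id!r} supplied to variant "
                f"{obs.variant_id!r}"
            )

    effectful = [r for r in evidence if r.shows_effect]
    null_records = [r for r in evidence if not r.shows_effect]
    mechanisms = tuple(
        dict.fromkeys(r.mechanism for r in effectful)
    )
    effects = tuple(dict.fromkeys(r.effect for r in effectful))
    levels = tuple(dict.fromkeys(r.level for r in effectful))
    conflict = bool(effectful and null_records)

    if not evidence:
        status = EvidenceStatus.NONE
    elif effectful:
        status = EvidenceStatus.EFFECT_SHOWN
    else:
        status = EvidenceStatus.NO_EFFECT_SHOWN

    if category in (Category.MISSENSE, Category.NONSENSE, Category.STOP_LOSS):
        final = (
            FinalLabel.NONSENSE
            if category is Category.NONSENSE
            else FinalLabel.MISSENSE
        )
        return ClassificationResult(
            variant_id=obs.variant_id,
            codon_category=category,
            final_label=final,
            mechanisms=mechanisms,
            effects=effects,
            levels=levels,
            evidence_status=status,
            conflict=conflict,
        )

    # codon-synonymous route (incl. stop<->stop)
    if not evidence:
        return ClassificationResult(
            variant_id=obs.variant_id,
            codon_category=category,
            final_label=FinalLabel.UNVERIFIED_SYNONYMOUS_PREDICTED,
            mechanisms=(),
            effects=(),
            levels=(),
            evidence_status=EvidenceStatus.NONE,
        )
    if effectful:
        if set(mechanisms) & UNSENSE_MECHANISMS:
            final = FinalLabel.UNSENSE
        else:
            final = FinalLabel.SYNONYMOUS_WITH_EFFECT
        return ClassificationResult(
            variant_id=obs.variant_id,
            codon_category=category,
            final_label=final,
            mechanisms=mechanisms,
            effects=effects,
            levels=levels,
            evidence_status=EvidenceStatus.EFFECT_SHOWN,
            conflict=conflict,
        )
    return ClassificationResult(
        variant_id=obs.variant_id,
        codon_category=category,
        final_label=FinalLabel.VERIFIED_SYNONYMOUS,
        mechanisms=(),
        effects=(EffectTag.NO_EFFECT,),
        levels=(),
        evidence_status=EvidenceStatus.NO_EFFECT_SHOWN,
    )


# ---------------------------------------------------------------------------
# audit


_SYNONYMOUS_CLAIMS = {"synonymous", "silent", "ssnv", "verified_synonymous"}

_CLAIM_TO_LABEL = {
    "missense": FinalLabel.MISSENSE,
    "nonsense": FinalLabel.NONSENSE,
    "unsense": FinalLabel.UNSENSE,
    "synonymous": FinalLabel.VERIFIED_SYNONYMOUS,
    "silent": FinalLabel.VERIFIED_SYNONYMOUS,
    "ssnv": FinalLabel.VERIFIED_SYNONYMOUS,
    "verified_synonymous": FinalLabel.VERIFIED_SYNONYMOUS,
    "synonymous_with_effect": FinalLabel.SYNONYMOUS_WITH_EFFECT,
    "unverified_synonymous_predicted": FinalLabel.UNVERIFIED_SYNONYMOUS_PREDICTED,
    "stop_loss": FinalLabel.MISSENSE,
}


@dataclass
class AuditEntry:
    variant_id: str
    claimed_label: str
    computed_label: FinalLabel
    codon_category: Category
    verdict: Verdict


@dataclass
class AuditReport:
    entries: list[AuditEntry] = field(default_factory=list)
    skipped: int = 0

    @property
    def counts(self) -> dict[str, int]:
        c = {v.value: 0 for v in Verdict}
        for e in self.entries:
            c[e.verdict.value] += 1
        return c

    def summary(self) -> dict:
        return {
            "audited": len(self.entries),
            "skipped": self.skipped,
            **self.counts,
        }

    def to_tsv(self) -> str:
        lines = ["variant_id\tclaimed_label\tcomputed_label\tcodon_category\tverdict"]
        for e in self.entries:
            lines.append(
                f"{e.variant_id}\t{e.claimed_label}\t{e.computed_label.value}"
                f"\t{e.codon_category.value}\t{e.verdict.value}"
            )
        return "\n".join(lines) + "\n"


def audit_annotations(
    records: Iterable[VariantObservation],
    evidence_by_variant: Mapping[str, Sequence[EvidenceRecord]],
    sequences: Mapping[str, str],
    table: CodonTable | None = None,
    nmd: NmdConfig | None = None,
) -> AuditReport:
    """Check externally claimed labels against computed final labels.

    Verdicts: confirmed (claim matches), overclaimed_synonymous (claimed
    synonymous but computation yields unverified, unsense, or
    synonymous-with-effect), mislabeled (any other mismatch).  Records
    without a claimed label are skipped and counted.
    """
    table = table or CodonTable.standard()
    report = AuditReport()
    for obs in records:
        if not obs.claimed_label:
            report.skipped += 1
            continue
        codons = variant_codons(sequences[obs.transcript_id], obs)
        result = classify_variant(
            obs,
            codons,
            evidence_by_variant.get(obs.variant_id, ()),
            table=table,
            nmd=nmd,
        )
        claim = obs.claimed_label.strip().lower()
        expected = _CLAIM_TO_LABEL.get(claim)
        if expected is not None and expected is result.final_label:
            verdict = Verdict.CONFIRMED
        elif claim in _SYNONYMOUS_CLAIMS and result.final_label in (
            FinalLabel.UNVERIFIED_SYNONYMOUS_PREDICTED,
            FinalLabel.UNSENSE,
            FinalLabel.SYNONYMOUS_WITH_EFFECT,
        ):
            verdict = Verdict.OVERCLAIMED_SYNONYMOUS
        else:
            verdict = Verdict.MISLABELED
        report.entries.append(
            AuditEntry(
                variant_id=obs.variant_id,
                claimed_label=obs.claimed_label,
                computed_label=result.final_label,
                codon_category=result.codon_category,
                verdict=verdict,
            )
        )
    return report
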