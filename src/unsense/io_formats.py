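"""Readers and writers for the formats the toolkit touches.

Supported: the HGVS coding-substitution subset (plus length-bearing del/ins,
parsed only for the frame rule), VCF 4.x annotation in transcript
coordinates, transcript models as JSON or a GFF3 subset, and TSV evidence /
claim tables.  Everything else in the HGVS grammar is an explicit
out-of-scope error, never a silent skip.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils

from unsense.classifier import (
    ClassifierError,
    EvidenceRecord,
    NmdConfig,
    TranscriptModel,
    VariantObservation,
    classify_variant,
    variant_codons,
)
from unsense.genetic_code import BASES, CodonTable


class HgvsParseError(ValueError):
    """Malformed HGVS string; carries the character position of failure."""

    def __init__(self, text: str, pos: int, message: str):
        self.text = text
        self.pos = pos
        super().__init__(f"{message} in {text!r} at position {pos}")


class NonExonicError(HgvsParseError):
    """Intronic/UTR-offset descriptions: syntactically valid but out of scope."""


@dataclass(frozen=True)
class HgvsCodingSub:
    """A simple coding substitution, e.g. ``NM_000000.0:c.6C>T``."""

    cds_pos: int
    ref_base: str
    alt_base: str
    accession: Optional[str] = None

    def format(self) -> str:
        prefix = f"{self.accession}:" if self.accession else ""
        return f"{prefix}c.{self.cds_pos}{self.ref_base}>{self.alt_base}"


@dataclass(frozen=True)
class HgvsCodingIndel:
    """A length-bearing del/ins, e.g. ``c.88del3`` — kept only for the frame rule."""

    cds_pos: int
    kind: str  # "del" | "ins"
    length: int
    accession: Optional[str] = None

    def format(self) -> str:
        prefix = f"{self.accession}:" if self.accession else ""
        return f"{prefix}c.{self.cds_pos}{self.kind}{self.length}"


_POS_RE = re.compile(r"(\d+)")
_OFFSET_RE = re.compile(r"[+\-−]\d+")


def parse_hgvs_c(text: str) -> HgvsCodingSub | HgvsCodingIndel:
    """Parse the supported HGVS coding subset.

    Accepts an optional accession prefix, ``c.<pos><ref>><alt>`` substitutions
    and ``c.<pos>del<len>`` / ``c.<pos>ins<len>``.  Intronic offsets raise
    :class:`NonExonicError`; protein-level descriptions and everything else
    raise :class:`HgvsParseError` with the failure position.
    """
    if not isinstance(text, str) or not text.strip():
        raise HgvsParseError(str(text), 0, "empty HGVS description")
    s = text.strip()
    accession = None
    body = s
    offset = 0
    if ":" in s:
        accession, body = s.split(":", 1)
        accession = accession.strip() or None
        offset = s.index(":") + 1
    if body.startswith("p."):
        raise HgvsParseError(s, offset, "protein-level description out of scope")
    if not body.startswith("c."):
        raise HgvsParseError(s, offset, "expected 'c.' prefix")
    rest = body[2:]
    cursor = offset + 2
    m = _POS_RE.match(rest)
    if not m:
        raise HgvsParseError(s, cursor, "expected a CDS position")
    pos = int(m.group(1))
    if pos < 1:
        raise HgvsParseError(s, cursor, "CDS position must be >= 1")
    rest = rest[m.end():]
    cursor += m.end()
    if _OFFSET_RE.match(rest):
        raise NonExonicError(s, cursor, "intronic offset: non-exonic, out of scope")
    sub = re.match(rf"([{BASES}U])>([{BASES}U])$", rest, re.IGNORECASE)
    if sub:
        ref = sub.group(1).upper().replace("U", "T")
        alt = sub.group(2).upper().replace("U", "T")
        if ref == alt:
            raise HgvsParseError(s, cursor, "ref and alt base identical")
        return HgvsCodingSub(cds_pos=pos, ref_base=ref, alt_base=alt,
                             accession=accession)
    indel = re.match(r"(del|ins)(\d+)$", rest)
    if indel:
        return HgvsCodingIndel(cds_pos=pos, kind=indel.group(1),
                               length=int(indel.group(2)), accession=accession)
    if re.match(r"(del|ins|dup|inv)", rest):
        raise HgvsParseError(
            s, cursor, "del/ins supported only with an explicit length"
        )
    raise HgvsParseError(s, cursor, "unsupported HGVS description")


def format_hgvs_c(v: HgvsCodingSub | HgvsCodingIndel) -> str:
    return v.format()


# ---------------------------------------------------------------------------
# transcript models


def read_transcript_models(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from JSON or a GFF3 subset (by file suffix)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_models_gff3(path)
    return _read_models_json(path)


def _read_models_json(path: Path) -> list[TranscriptModel]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = data.get("transcripts", [])
    models = []
    for obj in data:
        try:
            models.append(
                TranscriptModel(
                    transcript_id=obj["transcript_id"],
                    exon_lengths=tuple(obj["exon_lengths"]),
                    cds_start=obj["cds_start"],
                    cds_end=obj["cds_end"],
                    strand=obj.get("strand"),
                )
            )
        except ClassifierError as exc:
            raise ClassifierError(f"{path}: {exc}") from exc
    return models


def write_transcript_models_json(
    models: Iterable[TranscriptModel], path: str | Path
) -> None:
    payload = {"transcripts": [m.to_dict() for m in models]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _read_models_gff3(path: Path) -> list[TranscriptModel]:
    """GFF3 subset: exon and CDS features sharing a Parent transcript ID.

    Coordinates are 1-based inclusive.  Exons are ordered 5'->3' along the
    transcript (reverse genomic order on the minus strand) and the CDS span
    is converted to transcript coordinates.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        from_string=False,
        merge_strategy="create_unique",
        keep_order=True,
    )
    by_parent: dict[str, dict[str, list]] = {}
    strands: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        parents = feat.attributes.get("Parent") or [feat.id]
        for parent in parents:
            slot = by_parent.setdefault(parent, {"exon": [], "CDS": []})
            slot[feat.featuretype].append((feat.start, feat.end))
            strands[parent] = feat.strand
    models = []
    for tid in sorted(by_parent):
        exons = by_parent[tid]["exon"]
        cds = by_parent[tid]["CDS"]
        if not exons or not cds:
            raise ClassifierError(f"{path}: transcript {tid} lacks exon or CDS rows")
        strand = strands[tid]
        reverse = strand == "-"
        exons = sorted(exons, reverse=reverse)
        lengths = tuple(e - s + 1 for s, e in exons)
        cds_lo = min(s for s, _ in cds)
        cds_hi = max(e for _, e in cds)
        g_first = cds_hi if reverse else cds_lo  # genomic pos of CDS 5' end
        g_last = cds_lo if reverse else cds_hi
        cds_start = _genomic_to_tx(exons, g_first, reverse)
        cds_end = _genomic_to_tx(exons, g_last, reverse)
        try:
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    exon_lengths=lengths,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    strand=strand if strand in "+-" else None,
                )
            )
        except ClassifierError as exc:
            raise ClassifierError(f"{path}: {exc}") from exc
    return models


def _genomic_to_tx(
    exons: Sequence[tuple[int, int]], gpos: int, reverse: bool
) -> int:
    offset = 0
    for s, e in exons:
        if s <= gpos <= e:
            return offset + (e - gpos + 1 if reverse else gpos - s + 1)
        offset += e - s + 1
    raise ClassifierError(f"genomic position {gpos} not inside any exon")


# ---------------------------------------------------------------------------
# evidence and claim tables

EVIDENCE_COLUMNS = ["variant_id", "assay", "mechanism", "effect", "level"]
CLAIM_COLUMNS = [
    "variant_id", "transcript_id", "cds_pos", "ref_base", "alt_base",
    "claimed_label",
]


def read_evidence_tsv(path: str | Path) -> dict[str, list[EvidenceRecord]]:
    """Evidence TSV (variant_id, assay, mechanism, effect, level) keyed by variant."""
    store: dict[str, list[EvidenceRecord]] = {}
    lines = Path(path).read_text().splitlines()
    if not lines:
        return store
    header = lines[0].rstrip("\n").split("\t")
    if header != EVIDENCE_COLUMNS:
        raise ClassifierError(
            f"{path}: expected columns {EVIDENCE_COLUMNS}, got {header}"
        )
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(EVIDENCE_COLUMNS):
            raise ClassifierError(f"{path}:{lineno}: wrong number of columns")
        rec = EvidenceRecord(
            variant_id=fields[0],
            assay=fields[1],
            mechanism=fields[2],
            effect=fields[3],
            level=fields[4],
        )
        store.setdefault(rec.variant_id, []).append(rec)
    return store


def write_evidence_tsv(
    records: Iterable[EvidenceRecord], path: str | Path
) -> None:
    lines = ["\t".join(EVIDENCE_COLUMNS)]
    for r in records:
        lines.append(
            f"{r.variant_id}\t{r.assay}\t{r.mechanism.value}"
            f"\t{r.effect.value}\t{r.level.value}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_claims_tsv(path: str | Path) -> list[VariantObservation]:
    """Variant claims TSV -> observations with claimed labels attached."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    if header != CLAIM_COLUMNS:
        raise ClassifierError(
            f"{path}: expected columns {CLAIM_COLUMNS}, got {header}"
        )
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(CLAIM_COLUMNS):
            raise ClassifierError(f"{path}:{lineno}: wrong number of columns")
        out.append(
            VariantObservation(
                variant_id=fields[0],
                transcript_id=fields[1],
                cds_pos=int(fields[2]),
                ref_base=fields[3],
                alt_base=fields[4],
                claimed_label=fields[5] or None,
            )
        )
    return out


def write_claims_tsv(
    records: Iterable[VariantObservation], path: str | Path
) -> None:
    lines = ["\t".join(CLAIM_COLUMNS)]
    for r in records:
        lines.append(
            f"{r.variant_id}\t{r.transcript_id}\t{r.cds_pos}"
            f"\t{r.ref_base}\t{r.alt_base}\t{r.claimed_label or ''}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF annotation

VCF_INFO_HEADERS = [
    '##INFO=<ID=UNS_CAT,Number=.,Type=String,'
    'Description="Codon-level substitution category">',
    '##INFO=<ID=UNS_LABEL,Number=.,Type=String,'
    'Description="Final variant label from codon category plus evidence">',
    '##INFO=<ID=UNS_MECH,Number=.,Type=String,'
    'Description="Comma-joined evidence mechanisms">',
    '##INFO=<ID=UNS_EVID,Number=.,Type=String,'
    'Description="Evidence status: none, effect_shown or no_effect_shown">',
]


def annotate_vcf(
    in_vcf: str | Path,
    transcripts: Mapping[str, TranscriptModel],
    sequences: Mapping[str, str],
    evidence_by_variant: Mapping[str, Sequence[EvidenceRecord]],
    out_vcf: str | Path,
    table: CodonTable | None = None,
    nmd: NmdConfig | None = None,
) -> int:
    """Annotate a transcript-coordinate VCF with UNS_* INFO keys.

    CHROM is the transcript ID and POS the transcript position; positions
    inside the CDS are classified, everything else (unknown transcript,
    non-coding position) passes through with ``UNS_LABEL=.``.  Only the INFO
    column is modified; columns CHROM..FILTER are copied byte-for-byte.
    Returns the number of records annotated.
    """
    table = table or CodonTable.standard()
    in_path, out_path = Path(in_vcf), Path(out_vcf)
    out_lines: list[str] = []
    annotated = 0
    saw_header = False
    for raw in in_path.read_text().splitlines():
        if raw.startswith("##"):
            out_lines.append(raw)
            continue
        if raw.startswith("#CHROM"):
            out_lines.extend(VCF_INFO_HEADERS)
            out_lines.append(raw)
            saw_header = True
            continue
        if not raw.strip():
            continue
        if not saw_header:
            raise ClassifierError(f"{in_path}: VCF record before #CHROM header")
        fields = raw.split("\t")
        if len(fields) < 8:
            raise ClassifierError(f"{in_path}: VCF record with <8 columns")
        chrom, pos, _vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
        info = fields[7]
        new_info = _annotate_record(
            chrom, int(pos), ref, alt, transcripts, sequences,
            evidence_by_variant, table, nmd,
        )
        if new_info is None:
            addition = "UNS_LABEL=."
        else:
            addition = new_info
            annotated += 1
        fields[7] = addition if info in (".", "") else f"{info};{addition}"
        out_lines.append("\t".join(fields))
    out_path.write_text("\n".join(out_lines) + "\n")
    return annotated


def _annotate_record(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    transcripts: Mapping[str, TranscriptModel],
    sequences: Mapping[str, str],
    evidence_by_variant: Mapping[str, Sequence[EvidenceRecord]],
    table: CodonTable,
    nmd: NmdConfig | None,
) -> Optional[str]:
    model = transcripts.get(chrom)
    if model is None:
        warnings.warn(f"unknown transcript {chrom!r}; record passed through")
        return None
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return None
    if not (model.cds_start <= pos <= model.cds_end):
        return None
    cds_pos = pos - model.cds_start + 1
    obs = VariantObservation(
        transcript_id=chrom, cds_pos=cds_pos, ref_base=ref, alt_base=alt
    )
    seq = sequences.get(chrom)
    if seq is None:
        warnings.warn(f"no CDS sequence for {chrom!r}; record passed through")
        return None
    codons = variant_codons(seq, obs)
    result = classify_variant(
        obs, codons, evidence_by_variant.get(obs.variant_id, ()),
        table=table, nmd=nmd,
    )
    parts = [
        f"UNS_CAT={result.codon_category.value}",
        f"UNS_LABEL={result.final_label.value}",
    ]
    if result.mechanisms:
        parts.append("UNS_MECH=" + ",".join(m.value for m in result.mechanisms))
    parts.append(f"UNS_EVID={result.evidence_status.value}")
    return ";".join(parts)
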