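"""Seeded generator of toy transcripts, CDS sequences, variants, claimed
labels and planted evidence.

Everything is derived from a single integer seed through ``random.Random``
(integer draws only), so identical specs reproduce identical bundles on any
platform.  Evidence is planted by exact count (round half-up of fraction x
eligible) so downstream tests are deterministic; a Bernoulli mode exists for
stochastic testing.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional

from unsense.classifier import (
    EvidenceRecord,
    TranscriptModel,
    VariantObservation,
    Verdict,
    FinalLabel,
    variant_codons,
    classify_codon_substitution,
)
from unsense.genetic_code import BASES, Category, CodonTable, STOP
from unsense.taxonomy import EffectTag, Level, MechanismTag
from unsense.io_formats import (
    write_claims_tsv,
    write_evidence_tsv,
    write_transcript_models_json,
)


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic bundle.

    The evidence fractions apply to the codon-synonymous variants: splicing /
    miRNA fractions plant RNA-regulatory (unsense) evidence, the protein
    fraction plants protein-level effect evidence, and
    ``fraction_claimed_synonymous_without_evidence`` leaves variants
    evidence-free while still claimed synonymous.  Remaining synonymous
    variants receive explicit no-effect evidence.
    """

    seed: int = 0
    n_transcripts: int = 3
    exons_per_transcript: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (60, 180)
    n_variants: int = 100
    fraction_splicing_evidence: float = 0.23
    fraction_mirna_evidence: float = 0.05
    fraction_protein_evidence: float = 0.05
    fraction_claimed_synonymous_without_evidence: float = 0.30
    planting: str = "exact"  # "exact" | "bernoulli"

    def __post_init__(self) -> None:
        fractions = (
            self.fraction_splicing_evidence,
            self.fraction_mirna_evidence,
            self.fraction_protein_evidence,
            self.fraction_claimed_synonymous_without_evidence,
        )
        if any(not 0.0 <= f <= 1.0 for f in fractions):
            raise FixtureError("fractions must lie in [0, 1]")
        if sum(fractions) > 1.0 + 1e-9:
            raise FixtureError("fractions must jointly be <= 1")
        if self.planting not in ("exact", "bernoulli"):
            raise FixtureError("planting must be 'exact' or 'bernoulli'")
        for lo, hi in (self.exons_per_transcript, self.exon_length):
            if lo < 1 or hi < lo:
                raise FixtureError("ranges must satisfy 1 <= lo <= hi")


def _round_half_up(fraction: float, n: int) -> int:
    return int(
        (Decimal(str(fraction)) * n).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    transcripts: list[TranscriptModel]
    sequences: dict[str, str]  # transcript_id -> CDS sequence (incl. stop)
    variants: list[VariantObservation]
    evidence: list[EvidenceRecord]
    manifest: dict = field(default_factory=dict)

    @property
    def evidence_by_variant(self) -> dict[str, list[EvidenceRecord]]:
        store: dict[str, list[EvidenceRecord]] = {}
        for rec in self.evidence:
            store.setdefault(rec.variant_id, []).append(rec)
        return store

    def write(self, outdir: str | Path) -> None:
        """Write the bundle as plain-text files consumed by the CLI."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_transcript_models_json(self.transcripts, outdir / "transcripts.json")
        _write_fasta(self.sequences, outdir / "cds_sequences.fasta")
        _write_vcf(self, outdir / "variants.vcf")
        write_claims_tsv(self.variants, outdir / "claims.tsv")
        write_evidence_tsv(self.evidence, outdir / "evidence.tsv")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2) + "\n"
        )


_CODING_CODONS = sorted(
    c for c, a in CodonTable.standard().codon_to_aa.items() if a != STOP
)
_STOP_CODONS = sorted(CodonTable.standard().stop_codons)

_SPLICING_MECHS = [MechanismTag.SPLICE_SITE, MechanismTag.ESE, MechanismTag.ESS]
_PROTEIN_PLANT = [
    (MechanismTag.CODON_USAGE_TRANSLATION, EffectTag.PROTEIN_ABUNDANCE_CHANGE),
    (MechanismTag.COTRANSLATIONAL_FOLDING, EffectTag.CONFORMATION_CHANGE),
    (MechanismTag.PTM, EffectTag.PTM_LOSS),
]


def _make_transcript(rng: random.Random, spec: FixtureSpec, idx: int):
    tid = f"TX{idx:03d}"
    n_exons = rng.randint(*spec.exons_per_transcript)
    exons = tuple(rng.randint(*spec.exon_length) for _ in range(n_exons))
    total = sum(exons)
    if total < 12:
        raise FixtureError(
            f"transcript too short ({total} nt); increase exon_length"
        )
    utr5 = rng.randint(0, min(30, total - 12))
    room = total - utr5
    n_codons = room // 3
    # keep a short 3' UTR when there is slack
    n_codons -= min(rng.randint(0, 3), n_codons - 4)
    cds_len = 3 * n_codons
    cds_start = utr5 + 1
    cds_end = utr5 + cds_len
    model = TranscriptModel(
        transcript_id=tid,
        exon_lengths=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        strand="+",
    )
    codons = [rng.choice(_CODING_CODONS) for _ in range(n_codons - 1)]
    codons.append(rng.choice(_STOP_CODONS))
    return model, "".join(codons)


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Build one deterministic bundle from the spec's seed."""
    rng = random.Random(spec.seed)
    transcripts: list[TranscriptModel] = []
    sequences: dict[str, str] = {}
    for i in range(spec.n_transcripts):
        model, cds_seq = _make_transcript(rng, spec, i + 1)
        transcripts.append(model)
        sequences[model.transcript_id] = cds_seq

    # candidate positions exclude the terminal stop codon
    positions = [
        (m.transcript_id, p)
        for m in transcripts
        for p in range(1, m.cds_length - 3 + 1)
    ]
    if spec.n_variants > len(positions):
        raise FixtureError(
            f"n_variants={spec.n_variants} exceeds {len(positions)} available "
            f"CDS positions"
        )
    chosen = rng.sample(positions, spec.n_variants)
    chosen.sort()

    variants: list[VariantObservation] = []
    categories: dict[str, Category] = {}
    for tid, cds_pos in chosen:
        seq = sequences[tid]
        ref = seq[cds_pos - 1]
        alt = rng.choice([b for b in BASES if b != ref])
        obs = VariantObservation(
            transcript_id=tid, cds_pos=cds_pos, ref_base=ref, alt_base=alt
        )
        ref_codon, alt_codon = variant_codons(seq, obs)
        categories[obs.variant_id] = classify_codon_substitution(
            ref_codon, alt_codon
        )
        variants.append(obs)

    synonymous = [
        v for v in variants if categories[v.variant_id] is Category.SYNONYMOUS
    ]
    rng.shuffle(synonymous)
    n_syn = len(synonymous)
    if spec.planting == "exact":
        n_spl = _round_half_up(spec.fraction_splicing_evidence, n_syn)
        n_mir = _round_half_up(spec.fraction_mirna_evidence, n_syn)
        n_prot = _round_half_up(spec.fraction_protein_evidence, n_syn)
        n_unv = _round_half_up(
            spec.fraction_claimed_synonymous_without_evidence, n_syn
        )
    else:
        draws = [rng.random() for _ in range(n_syn)]
        f1 = spec.fraction_splicing_evidence
        f2 = f1 + spec.fraction_mirna_evidence
        f3 = f2 + spec.fraction_protein_evidence
        f4 = f3 + spec.fraction_claimed_synonymous_without_evidence
        n_spl = sum(d < f1 for d in draws)
        n_mir = sum(f1 <= d < f2 for d in draws)
        n_prot = sum(f2 <= d < f3 for d in draws)
        n_unv = sum(f3 <= d < f4 for d in draws)
    cut = 0
    groups: dict[str, list[VariantObservation]] = {}
    for name, n in (
        ("unsense_splicing", n_spl),
        ("unsense_mirna", n_mir),
        ("protein_effect", n_prot),
        ("unverified", n_unv),
    ):
        groups[name] = synonymous[cut: cut + n]
        cut += n
    groups["verified"] = synonymous[cut:]

    evidence: list[EvidenceRecord] = []
    planted: dict[str, str] = {}
    for v in groups["unsense_splicing"]:
        mech = rng.choice(_SPLICING_MECHS)
        evidence.append(
            EvidenceRecord(
                variant_id=v.variant_id,
                assay="minigene",
                mechanism=mech,
                effect=EffectTag.MISSING_RNA,
                level=Level.RNA,
            )
        )
        planted[v.variant_id] = "unsense_splicing"
    for v in groups["unsense_mirna"]:
        evidence.append(
            EvidenceRecord(
                variant_id=v.variant_id,
                assay="reporter",
                mechanism=MechanismTag.MIRNA_BINDING,
                effect=EffectTag.EXPRESSION_CHANGE,
                level=Level.RNA,
            )
        )
        planted[v.variant_id] = "unsense_mirna"
    for v in groups["protein_effect"]:
        mech, eff = rng.choice(_PROTEIN_PLANT)
        evidence.append(
            EvidenceRecord(
                variant_id=v.variant_id,
                assay="biochemical",
                mechanism=mech,
                effect=eff,
                level=Level.PROTEIN,
            )
        )
        planted[v.variant_id] = "protein_effect"
    for v in groups["unverified"]:
        planted[v.variant_id] = "unverified"
    for v in groups["verified"]:
        evidence.append(
            EvidenceRecord(
                variant_id=v.variant_id,
                assay="rna-seq",
                mechanism=MechanismTag.NONE_OBSERVED,
                effect=EffectTag.NO_EFFECT,
                level=Level.RNA,
            )
        )
        planted[v.variant_id] = "verified"

    # claimed labels: naive codon-level annotation, as a legacy pipeline would
    claimed_variants: list[VariantObservation] = []
    manifest_variants = []
    expected_label = {
        "unsense_splicing": FinalLabel.UNSENSE,
        "unsense_mirna": FinalLabel.UNSENSE,
        "protein_effect": FinalLabel.SYNONYMOUS_WITH_EFFECT,
        "unverified": FinalLabel.UNVERIFIED_SYNONYMOUS_PREDICTED,
        "verified": FinalLabel.VERIFIED_SYNONYMOUS,
    }
    for v in variants:
        cat = categories[v.variant_id]
        if cat is Category.SYNONYMOUS:
            claim = "synonymous"
            group = planted[v.variant_id]
            final = expected_label[group]
            verdict = (
                Verdict.CONFIRMED
                if group == "verified"
                else Verdict.OVERCLAIMED_SYNONYMOUS
            )
        else:
            claim = cat.value if cat is not Category.STOP_LOSS else "stop_loss"
            group = cat.value
            final = (
                FinalLabel.NONSENSE
                if cat is Category.NONSENSE
                else FinalLabel.MISSENSE
            )
            verdict = Verdict.CONFIRMED
        claimed = VariantObservation(
            variant_id=v.variant_id,
            transcript_id=v.transcript_id,
            cds_pos=v.cds_pos,
            ref_base=v.ref_base,
            alt_base=v.alt_base,
            claimed_label=claim,
        )
        claimed_variants.append(claimed)
        manifest_variants.append(
            {
                "variant_id": v.variant_id,
                "transcript_id": v.transcript_id,
                "cds_pos": v.cds_pos,
                "ref_base": v.ref_base,
                "alt_base": v.alt_base,
                "codon_category": cat.value,
                "planted_group": group,
                "claimed_label": claim,
                "expected_final_label": final.value,
                "expected_verdict": verdict.value,
            }
        )

    manifest = {
        "spec": asdict(spec),
        "n_synonymous": n_syn,
        "planted_counts": {k: len(v) for k, v in groups.items()},
        "planted_unsense": sorted(
            v.variant_id
            for g in ("unsense_splicing", "unsense_mirna")
            for v in groups[g]
        ),
        "expected_overclaimed": sorted(
            m["variant_id"]
            for m in manifest_variants
            if m["expected_verdict"] == Verdict.OVERCLAIMED_SYNONYMOUS.value
        ),
        "variants": manifest_variants,
    }
    return FixtureBundle(
        spec=spec,
        transcripts=transcripts,
        sequences=sequences,
        variants=claimed_variants,
        evidence=evidence,
        manifest=manifest,
    )


def _write_fasta(sequences: dict[str, str], path: Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(seq), id=tid, description="CDS")
        for tid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _write_vcf(bundle: FixtureBundle, path: Path) -> None:
    by_id = {m.transcript_id: m for m in bundle.transcripts}
    lines = ["##fileformat=VCFv4.2"]
    for m in bundle.transcripts:
        lines.append(f"##contig=<ID={m.transcript_id},length={m.length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in bundle.variants:
        model = by_id[v.transcript_id]
        tx_pos = model.cds_to_tx(v.cds_pos)
        lines.append(
            f"{v.transcript_id}\t{tx_pos}\t{v.variant_id}\t{v.ref_base}"
            f"\t{v.alt_base}\t.\t.\t."
        )
    path.write_text("\n".join(lines) + "\n")
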