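import pytest
from hypothesis import given, strategies as st

from unsense.classifier import (
    ClassificationResult,
    ClassifierError,
    EvidenceRecord,
    EvidenceStatus,
    ExonSkipEvent,
    FinalLabel,
    FrameStatus,
    LinkageError,
    NmdConfig,
    SegmentEvent,
    TranscriptModel,
    VariantObservation,
    Verdict,
    audit_annotations,
    classify_variant,
    map_cds_position,
    nmd_escapes,
    splice_consequence,
    variant_codons,
)
from unsense.genetic_code import Category
from unsense.taxonomy import EffectTag, Level, MechanismTag


def ev(variant_id, mechanism, effect, level, assay="assay"):
    return EvidenceRecord(
        variant_id=variant_id, assay=assay, mechanism=mechanism,
        effect=effect, level=level,
    )


class TestTranscriptModel:
    def test_basic_geometry(self):
        m = TranscriptModel("tx", (100, 80, 120), cds_start=10, cds_end=249)
        assert m.length == 300
        assert m.cds_length == 240
        assert m.exon_span(2) == (101, 180)
        assert m.exon_of(150) == 2
        assert m.coding_length_of_exon(1) == 91
        assert m.cds_to_tx(1) == 10

    def test_cds_not_multiple_of_three_rejected(self):
        with pytest.raises(ClassifierError, match="divisible"):
            TranscriptModel("tx", (100,), cds_start=1, cds_end=100)

    def test_no_exons_rejected(self):
        with pytest.raises(ClassifierError, match="exon"):
            TranscriptModel("tx", (), cds_start=1, cds_end=3)

    def test_cds_end_beyond_transcript_rejected(self):
        with pytest.raises(ClassifierError, match="exceeds"):
            TranscriptModel("tx", (30,), cds_start=1, cds_end=33)


class TestMapCdsPosition:
    @pytest.mark.parametrize(
        "pos,expected", [(840, (280, 3)), (1, (1, 1)), (5, (2, 2)), (3, (1, 3))]
    )
    def test_examples(self, pos, expected):
        assert map_cds_position(pos) == expected

    @given(st.integers(min_value=1, max_value=10**9))
    def test_round_trip(self, pos):
        idx, cpos = map_cds_position(pos)
        assert 3 * (idx - 1) + cpos == pos
        assert 1 <= cpos <= 3

    def test_out_of_range_with_transcript(self):
        m = TranscriptModel("tx", (100,), cds_start=1, cds_end=99)
        with pytest.raises(ClassifierError, match="exceeds"):
            map_cds_position(100, m)

    def test_nonpositive_rejected(self):
        with pytest.raises(ClassifierError):
            map_cds_position(0)


class TestNmdRule:
    def test_single_exon_always_escapes(self):
        m = TranscriptModel("tx", (300,), cds_start=1, cds_end=300)
        assert nmd_escapes(m, 1)

    def test_last_exon_escapes(self):
        m = TranscriptModel("tx", (100, 100, 100), cds_start=1, cds_end=300)
        assert nmd_escapes(m, 201)  # first base of last exon

    def test_window_boundary(self):
        m = TranscriptModel("tx", (100, 100, 100), cds_start=1, cds_end=300)
        nmd = NmdConfig(penultimate_window_nt=50)
        assert nmd_escapes(m, 151, nmd)       # within 50 nt of junction
        assert not nmd_escapes(m, 150, nmd)   # one base too far upstream

    def test_zero_window(self):
        m = TranscriptModel("tx", (100, 100, 100), cds_start=1, cds_end=300)
        nmd = NmdConfig(penultimate_window_nt=0)
        assert not nmd_escapes(m, 200, nmd)
        assert nmd_escapes(m, 201, nmd)

    @given(
        exons=st.lists(st.integers(min_value=30, max_value=200),
                       min_size=2, max_size=6),
        window=st.integers(min_value=0, max_value=100),
        data=st.data(),
    )
    def test_escape_monotone_in_position(self, exons, window, data):
        total = sum(exons)
        m = TranscriptModel("tx", tuple(exons), cds_start=1,
                            cds_end=total - total % 3)
        nmd = NmdConfig(window)
        p = data.draw(st.integers(min_value=1, max_value=total - 1))
        if nmd_escapes(m, p, nmd):
            assert nmd_escapes(m, p + 1, nmd)


class TestSpliceConsequence:
    @pytest.fixture
    def model(self):
        # 3 exons of 100 nt; CDS covers 10..249
        return TranscriptModel("tx", (100, 100, 100), cds_start=10, cds_end=249)

    def test_in_frame_skip(self):
        m = TranscriptModel("tx", (60, 54, 60), cds_start=1, cds_end=174)
        out = splice_consequence(m, ExonSkipEvent(exon_index=2))
        assert out.frame_status is FrameStatus.IN_FRAME
        assert not out.nmd_predicted
        assert EffectTag.EXON_SKIPPING in out.effects
        assert EffectTag.MISSING_RNA not in out.effects

    def test_frameshift_internal_ptc_degraded(self):
        # skipping exon 2 of four leaves a 3-exon transcript; PTC at 110 sits
        # in the internal second exon, far from the penultimate junction
        m = TranscriptModel("tx", (100, 100, 100, 100), cds_start=10,
                            cds_end=369)
        out = splice_consequence(m, ExonSkipEvent(exon_index=2, ptc_tx_pos=110))
        assert out.frame_status is FrameStatus.FRAMESHIFT
        assert out.nmd_predicted
        assert EffectTag.MISSING_RNA in out.effects
        assert EffectTag.FRAMESHIFT in out.effects

    def test_frameshift_last_exon_ptc_escapes(self, model):
        # reduced transcript after skipping exon 2 has exons (100, 100)
        out = splice_consequence(
            model, ExonSkipEvent(exon_index=2, ptc_tx_pos=150)
        )
        assert out.frame_status is FrameStatus.FRAMESHIFT
        assert not out.nmd_predicted
        assert EffectTag.MISSING_RNA not in out.effects

    def test_segment_in_frame(self, model):
        out = splice_consequence(model, SegmentEvent(tx_pos=50, length=54,
                                                     kind="del"))
        assert out.frame_status is FrameStatus.IN_FRAME

    def test_segment_frameshift(self, model):
        out = splice_consequence(model, SegmentEvent(tx_pos=50, length=100,
                                                     kind="del", ptc_tx_pos=60))
        assert out.frame_status is FrameStatus.FRAMESHIFT
        assert out.nmd_predicted

    def test_skip_only_exon_rejected(self):
        m = TranscriptModel("tx", (99,), cds_start=1, cds_end=99)
        with pytest.raises(ClassifierError, match="only exon"):
            splice_consequence(m, ExonSkipEvent(exon_index=1))

    def test_noncoding_exon_noop(self):
        m = TranscriptModel("tx", (50, 90, 60), cds_start=51, cds_end=140)
        out = splice_consequence(m, ExonSkipEvent(exon_index=1))
        assert not out.affects_coding
        assert out.effects == ()
        assert not out.nmd_predicted

    @given(length=st.integers(min_value=1, max_value=300))
    def test_frame_rule_is_mod3(self, length):
        m = TranscriptModel("tx", (200, 200), cds_start=1, cds_end=399)
        out = splice_consequence(
            m, SegmentEvent(tx_pos=10, length=length, kind="ins", ptc_tx_pos=20)
        )
        expected = FrameStatus.IN_FRAME if length % 3 == 0 else FrameStatus.FRAMESHIFT
        assert out.frame_status is expected


class TestClassifyVariant:
    """The worked examples: evidence decides among synonymous-looking labels."""

    def obs(self, pos=6, ref="C", alt="T", tid="TX"):
        return VariantObservation(transcript_id=tid, cds_pos=pos,
                                  ref_base=ref, alt_base=alt)

    def test_ess_creation_is_unsense(self):
        # C>T at codon position 3 of a Phe codon: TTC -> TTT, synonymous
        obs = self.obs()
        result = classify_variant(
            obs, ("TTC", "TTT"),
            [ev(obs.variant_id, MechanismTag.ESS, EffectTag.MISSING_RNA,
                Level.RNA, assay="minigene")],
        )
        assert result.final_label is FinalLabel.UNSENSE
        assert result.mechanisms == (MechanismTag.ESS,)
        assert EffectTag.MISSING_RNA in result.effects
        assert result.codon_category is Category.SYNONYMOUS

    def test_mirna_site_loss_is_unsense(self):
        # Leu codon CTC -> CTT at codon position 3
        obs = self.obs(pos=315, ref="C", alt="T")
        result = classify_variant(
            obs, ("CTC", "CTT"),
            [ev(obs.variant_id, MechanismTag.MIRNA_BINDING,
                EffectTag.EXPRESSION_CHANGE, Level.RNA, assay="reporter")],
        )
        assert result.final_label is FinalLabel.UNSENSE
        assert result.mechanisms == (MechanismTag.MIRNA_BINDING,)

    def test_phosphorylation_loss_is_synonymous_with_effect(self):
        obs = self.obs(pos=66, ref="G", alt="A")
        result = classify_variant(
            obs, ("CTG", "CTA"),
            [ev(obs.variant_id, MechanismTag.PTM, EffectTag.PTM_LOSS,
                Level.PROTEIN, assay="phosphoassay")],
        )
        assert result.final_label is FinalLabel.SYNONYMOUS_WITH_EFFECT
        assert result.levels == (Level.PROTEIN,)
        assert result.effects == (EffectTag.PTM_LOSS,)

    def test_no_evidence_is_unverified(self):
        result = classify_variant(self.obs(), ("TTC", "TTT"), [])
        assert result.final_label is FinalLabel.UNVERIFIED_SYNONYMOUS_PREDICTED
        assert result.evidence_status is EvidenceStatus.NONE

    def test_missense_decided_by_codon_level(self):
        obs = self.obs(pos=4, ref="T", alt="A")
        result = classify_variant(
            obs, ("TTT", "ATT"),
            [ev(obs.variant_id, MechanismTag.ESS, EffectTag.MISSING_RNA,
                Level.RNA)],
        )
        assert result.final_label is FinalLabel.MISSENSE
        # evidence kept as co-annotation
        assert result.mechanisms == (MechanismTag.ESS,)

    def test_nonsense(self):
        obs = self.obs(pos=4, ref="C", alt="T")
        result = classify_variant(obs, ("CAG", "TAG"), [])
        assert result.final_label is FinalLabel.NONSENSE

    def test_stop_loss_reported_as_missense_with_category(self):
        obs = self.obs(pos=4, ref="T", alt="C")
        result = classify_variant(obs, ("TAA", "CAA"), [])
        assert result.codon_category is Category.STOP_LOSS
        assert result.final_label is FinalLabel.MISSENSE

    def test_no_effect_evidence_verifies_synonymous(self):
        obs = self.obs()
        result = classify_variant(
            obs, ("TTC", "TTT"),
            [ev(obs.variant_id, MechanismTag.NONE_OBSERVED, EffectTag.NO_EFFECT,
                Level.RNA, assay="rna-seq")],
        )
        assert result.final_label is FinalLabel.VERIFIED_SYNONYMOUS
        assert result.evidence_status is EvidenceStatus.NO_EFFECT_SHOWN
        assert result.effects == (EffectTag.NO_EFFECT,)

    def test_mixed_mechanisms_unsense_dominates(self):
        obs = self.obs()
        result = classify_variant(
            obs, ("TTC", "TTT"),
            [
                ev(obs.variant_id, MechanismTag.PTM, EffectTag.PTM_LOSS,
                   Level.PROTEIN),
                ev(obs.variant_id, MechanismTag.ESE, EffectTag.EXON_SKIPPING,
                   Level.RNA),
            ],
        )
        assert result.final_label is FinalLabel.UNSENSE
        assert set(result.mechanisms) == {MechanismTag.PTM, MechanismTag.ESE}
        assert set(result.levels) == {Level.PROTEIN, Level.RNA}

    def test_dna_level_effect_is_synonymous_with_effect(self):
        obs = self.obs()
        result = classify_variant(
            obs, ("TTC", "TTT"),
            [ev(obs.variant_id, MechanismTag.TF_BINDING,
                EffectTag.EXPRESSION_CHANGE, Level.DNA)],
        )
        assert result.final_label is FinalLabel.SYNONYMOUS_WITH_EFFECT
        assert result.levels == (Level.DNA,)

    def test_mrna_stability_is_synonymous_with_effect(self):
        obs = self.obs()
        result = classify_variant(
            obs, ("TTC", "TTT"),
            [ev(obs.variant_id, MechanismTag.MRNA_STRUCTURE_STABILITY,
                EffectTag.PROTEIN_ABUNDANCE_CHANGE, Level.RNA)],
        )
        assert result.final_label is FinalLabel.SYNONYMOUS_WITH_EFFECT

    def test_conflicting_evidence_flags_conflict(self):
        obs = self.obs()
        result = classify_variant(
            obs, ("TTC", "TTT"),
            [
                ev(obs.variant_id, MechanismTag.NONE_OBSERVED,
                   EffectTag.NO_EFFECT, Level.RNA),
                ev(obs.variant_id, MechanismTag.ESS, EffectTag.MISSING_RNA,
                   Level.RNA),
            ],
        )
        assert result.conflict
        assert result.final_label is FinalLabel.UNSENSE

    def test_stop_to_stop_routed_like_synonymous(self):
        obs = self.obs(pos=6, ref="A", alt="G")
        result = classify_variant(obs, ("TAA", "TAG"), [])
        assert result.codon_category is Category.STOP_TO_STOP
        assert result.final_label is FinalLabel.UNVERIFIED_SYNONYMOUS_PREDICTED

    def test_foreign_evidence_is_linkage_error(self):
        obs = self.obs()
        with pytest.raises(LinkageError):
            classify_variant(
                obs, ("TTC", "TTT"),
                [ev("OTHER:c.1A>G", MechanismTag.ESS, EffectTag.MISSING_RNA,
                    Level.RNA)],
            )

    def test_inconsistent_codons_rejected(self):
        with pytest.raises(ClassifierError, match="ref codon"):
            classify_variant(self.obs(), ("TTA", "TTG"), [])

    def test_determinism(self):
        obs = self.obs()
        evs = [ev(obs.variant_id, MechanismTag.ESS, EffectTag.MISSING_RNA,
                  Level.RNA)]
        assert classify_variant(obs, ("TTC", "TTT"), evs) == classify_variant(
            obs, ("TTC", "TTT"), evs
        )


class TestEvidenceRecord:
    def test_level_mismatch_rejected(self):
        with pytest.raises(ClassifierError, match="operates at"):
            EvidenceRecord("v", "a", MechanismTag.ESS, EffectTag.MISSING_RNA,
                           Level.PROTEIN)

    def test_none_observed_any_level(self):
        rec = EvidenceRecord("v", "a", MechanismTag.NONE_OBSERVED,
                             EffectTag.NO_EFFECT, Level.PROTEIN)
        assert not rec.shows_effect


class TestResultInvariants:
    def test_unsense_requires_mechanism(self):
        with pytest.raises(ClassifierError, match="unsense"):
            ClassificationResult(
                variant_id="v", codon_category=Category.SYNONYMOUS,
                final_label=FinalLabel.UNSENSE, mechanisms=(),
                effects=(), levels=(), evidence_status=EvidenceStatus.EFFECT_SHOWN,
            )

    def test_synonymous_labels_require_synonymous_codon(self):
        with pytest.raises(ClassifierError, match="codon-synonymous"):
            ClassificationResult(
                variant_id="v", codon_category=Category.MISSENSE,
                final_label=FinalLabel.VERIFIED_SYNONYMOUS, mechanisms=(),
                effects=(), levels=(),
                evidence_status=EvidenceStatus.NO_EFFECT_SHOWN,
            )

    def test_no_effect_exclusive(self):
        with pytest.raises(ClassifierError, match="NO_EFFECT"):
            ClassificationResult(
                variant_id="v", codon_category=Category.SYNONYMOUS,
                final_label=FinalLabel.VERIFIED_SYNONYMOUS, mechanisms=(),
                effects=(EffectTag.NO_EFFECT, EffectTag.MISSING_RNA), levels=(),
                evidence_status=EvidenceStatus.NO_EFFECT_SHOWN,
            )


class TestAudit:
    # one transcript whose CDS starts with known codons
    SEQ = "TTCTTATTGCTACTCCTGATGTAA"  # F L L L L L M *

    def make_obs(self, pos, ref, alt, claimed):
        return VariantObservation(
            transcript_id="TX", cds_pos=pos, ref_base=ref, alt_base=alt,
            claimed_label=claimed,
        )

    def test_four_unverified_synonymous_claims(self):
        # 4 synonymous codon changes claimed synonymous, no evidence
        records = [
            self.make_obs(3, "C", "T", "synonymous"),    # TTC>TTT Phe
            self.make_obs(6, "A", "G", "synonymous"),    # TTA>TTG Leu
            self.make_obs(15, "C", "T", "synonymous"),   # CTC>CTT Leu
            self.make_obs(18, "G", "A", "synonymous"),   # CTG>CTA Leu
            # six other records with correct nonsynonymous claims
            self.make_obs(1, "T", "A", "missense"),      # TTC>ATC Phe>Ile
            self.make_obs(5, "T", "C", "missense"),      # TTA>TCA Leu>Ser
            self.make_obs(8, "T", "C", "missense"),      # TTG>TCG Leu>Ser
            self.make_obs(20, "T", "A", "missense"),     # ATG>AAG Met>Lys
            self.make_obs(19, "A", "T", "missense"),     # ATG>TTG Met>Leu
            self.make_obs(11, "T", "A", "missense"),     # CTA>CAA Leu>Gln
        ]
        report = audit_annotations(
            records, {}, {"TX": self.SEQ}
        )
        assert report.counts["overclaimed_synonymous"] == 4
        assert report.counts["confirmed"] == 6
        assert report.counts["mislabeled"] == 0
        assert sum(report.counts.values()) == len(report.entries) == 10

    def test_synonymous_claim_with_ess_evidence_overclaimed(self):
        obs = self.make_obs(3, "C", "T", "synonymous")
        evidence = {
            obs.variant_id: [
                ev(obs.variant_id, MechanismTag.ESS, EffectTag.MISSING_RNA,
                   Level.RNA)
            ]
        }
        report = audit_annotations([obs], evidence, {"TX": self.SEQ})
        entry = report.entries[0]
        assert entry.verdict is Verdict.OVERCLAIMED_SYNONYMOUS
        assert entry.computed_label is FinalLabel.UNSENSE

    def test_correct_missense_claim_confirmed(self):
        obs = self.make_obs(1, "T", "A", "missense")
        report = audit_annotations([obs], {}, {"TX": self.SEQ})
        assert report.entries[0].verdict is Verdict.CONFIRMED

    def test_wrong_claim_mislabeled(self):
        obs = self.make_obs(1, "T", "A", "nonsense")  # actually missense
        report = audit_annotations([obs], {}, {"TX": self.SEQ})
        assert report.entries[0].verdict is Verdict.MISLABELED

    def test_synonymous_claim_with_no_effect_evidence_confirmed(self):
        obs = self.make_obs(3, "C", "T", "synonymous")
        evidence = {
            obs.variant_id: [
                ev(obs.variant_id, MechanismTag.NONE_OBSERVED,
                   EffectTag.NO_EFFECT, Level.RNA)
            ]
        }
        report = audit_annotations([obs], evidence, {"TX": self.SEQ})
        assert report.entries[0].verdict is Verdict.CONFIRMED

    def test_missing_claim_skipped_with_count(self):
        obs = VariantObservation(transcript_id="TX", cds_pos=3, ref_base="C",
                                 alt_base="T")
        report = audit_annotations([obs], {}, {"TX": self.SEQ})
        assert report.skipped == 1
        assert report.entries == []

    def test_report_tsv_shape(self):
        obs = self.make_obs(3, "C", "T", "synonymous")
        report = audit_annotations([obs], {}, {"TX": self.SEQ})
        lines = report.to_tsv().strip().split("\n")
        assert lines[0].split("\t") == [
            "variant_id", "claimed_label", "computed_label", "codon_category",
            "verdict",
        ]
        assert len(lines) == 2


class TestVariantCodons:
    def test_extraction(self):
        obs = VariantObservation(transcript_id="TX", cds_pos=5, ref_base="T",
                                 alt_base="C")
        assert variant_codons("TTCTTA", obs) == ("TTA", "TCA")

    def test_ref_mismatch_rejected(self):
        obs = VariantObservation(transcript_id="TX", cds_pos=5, ref_base="G",
                                 alt_base="C")
        with pytest.raises(ClassifierError, match="mismatch"):
            variant_codons("TTCTTA", obs)

    def test_position_beyond_sequence(self):
        obs = VariantObservation(transcript_id="TX", cds_pos=50, ref_base="A",
                                 alt_base="C")
        with pytest.raises(ClassifierError, match="beyond"):
            variant_codons("TTCTTA", obs)
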