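"""Read filters, allele observation, evidence bookkeeping, decisions."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phasepolish.phase_calling import (
    OTHER,
    ReadFilterPolicy,
    decide_phase,
    observe_alleles,
    observe_target,
    polish_sample,
    read_pair_passes_filters,
    read_passes_filters,
    summarize_evidence,
)
from phasepolish.records import (
    Anchor,
    EvidenceSummary,
    Orientation,
    Outcome,
    ReadObservation,
    SiteRecord,
    TargetRecord,
)

from conftest import make_read

POLICY = ReadFilterPolicy()


class TestReadFilters:
    def test_mapq_just_below_floor_rejected(self):
        assert not read_passes_filters(make_read("r", 100, "ACGT", mapq=49), POLICY)

    def test_clean_fr_pair_accepted(self):
        r = make_read("r", 100, "ACGT", mapq=60)
        assert read_passes_filters(r, POLICY)

    def test_same_strand_pair_rejected(self):
        r = make_read("r", 100, "ACGT", reverse=False, mate_reverse=False)
        assert not read_passes_filters(r, POLICY)

    def test_duplicate_rejected(self):
        assert not read_passes_filters(make_read("r", 100, "ACGT", duplicate=True), POLICY)

    def test_unpaired_rejected(self):
        assert not read_passes_filters(make_read("r", 100, "ACGT", paired=False), POLICY)

    def test_mate_unmapped_rejected(self):
        assert not read_passes_filters(
            make_read("r", 100, "ACGT", mate_unmapped=True), POLICY
        )

    def test_pair_spelling_requires_both_mates_pass(self):
        good = make_read("r", 100, "ACGT", mapq=60)
        bad = make_read("r", 300, "ACGT", mapq=10, reverse=True, mate_reverse=False)
        assert read_pair_passes_filters([good], POLICY)
        assert not read_pair_passes_filters([good, bad], POLICY)


TARGET = SiteRecord("chr1", 101, "A", "C", 20, 1, 5)  # 0-based 100
ANCHOR = SiteRecord("chr1", 111, "G", "T", 20, 10, 6)  # 0-based 110


def _span(seq20: str, start=95):
    """A 20 bp read covering both sites (offsets 5 and 15 in the read)."""
    return make_read("p", start, seq20)


def _seq(target_base: str, anchor_base: str) -> str:
    s = list("AAAAA" + "A" + "AAAA" + "AAAAA" + "G" + "AAAA")
    s[5] = target_base
    s[15] = anchor_base
    return "".join(s)


class TestObserveAlleles:
    def test_planted_pairs_enumerated_exactly(self):
        # seven informative fragments with hand-known allele content
        reads = []
        expected = {}
        plan = [
            ("f1", "C", "T"),
            ("f2", "C", "G"),
            ("f3", "A", "T"),
            ("f4", "A", "G"),
            ("f5", "C", "T"),
            ("f6", "A", "G"),
            ("f7", "C", "G"),
        ]
        for name, tb, ab in plan:
            r = make_read(name, 95, _seq(tb, ab))
            reads.append(r)
            expected[name] = (0 if tb == "A" else 1, 0 if ab == "G" else 1)
        obs = observe_alleles(TARGET, ANCHOR, reads, POLICY)
        assert len(obs) == 7
        got = {o.pair_id: (o.target_allele, o.anchor_allele) for o in obs}
        assert got == expected

    def test_base_matching_neither_allele_is_other(self):
        obs = observe_alleles(TARGET, ANCHOR, [_span(_seq("T", "G"))], POLICY)
        assert obs[0].target_allele == OTHER

    def test_low_quality_base_is_other(self):
        quals = [37] * 20
        quals[5] = 11
        r = make_read("p", 95, _seq("C", "T"), quals=quals)
        obs = observe_alleles(TARGET, ANCHOR, [r], POLICY)
        assert obs[0].target_allele == OTHER and obs[0].anchor_allele == 1

    def test_agreeing_mates_give_one_observation(self):
        r1 = make_read("p", 95, _seq("C", "T"))
        r2 = make_read("p", 95, _seq("C", "T"), reverse=True, mate_reverse=False)
        obs = observe_alleles(TARGET, ANCHOR, [r1, r2], POLICY)
        assert len(obs) == 1
        assert obs[0].target_allele == 1

    def test_disagreeing_mates_discard_the_pair(self):
        r1 = make_read("p", 95, _seq("C", "T"))
        r2 = make_read("p", 95, _seq("A", "T"), reverse=True, mate_reverse=False)
        assert observe_alleles(TARGET, ANCHOR, [r1, r2], POLICY) == []

    def test_no_spanning_read_yields_nothing(self):
        r = make_read("p", 200, "A" * 20)  # overlaps neither site
        assert observe_alleles(TARGET, ANCHOR, [r], POLICY) == []


def _record(orientation: Orientation) -> TargetRecord:
    # target het 1|0 (ALT on hap0); anchor chosen to realize the orientation
    if orientation is Orientation.CIS:
        anchor = Anchor(ANCHOR.site_index, 1, 0, Orientation.CIS)
    else:
        anchor = Anchor(ANCHOR.site_index, 0, 1, Orientation.TRANS)
    return TargetRecord(0, TARGET.site_index, 1, 0, 0.9, [anchor])


class TestSummarizeEvidence:
    def test_trans_pair_target_alt_with_anchor_ref_confirms(self):
        rec = _record(Orientation.TRANS)
        obs = [ReadObservation("p", 1, ANCHOR.site_index, 0)]
        ev = summarize_evidence(rec, obs)
        assert (ev.confirming, ev.contradicting) == (1, 0)

    def test_same_pair_under_cis_contradicts(self):
        rec = _record(Orientation.CIS)
        obs = [ReadObservation("p", 1, ANCHOR.site_index, 0)]
        ev = summarize_evidence(rec, obs)
        assert (ev.confirming, ev.contradicting) == (0, 1)

    def test_other_alleles_contribute_nothing(self):
        rec = _record(Orientation.CIS)
        obs = [
            ReadObservation("p", OTHER, ANCHOR.site_index, 1),
            ReadObservation("q", 1, ANCHOR.site_index, OTHER),
        ]
        ev = summarize_evidence(rec, obs)
        assert (ev.confirming, ev.contradicting) == (0, 0)

    @given(
        pairs=st.lists(
            st.tuples(st.integers(0, 1), st.integers(0, 1)), max_size=30
        )
    )
    def test_flipping_stored_orientation_swaps_counts(self, pairs):
        rec = _record(Orientation.CIS)
        flipped = TargetRecord(
            rec.sample_index,
            rec.site_index,
            rec.hap1_allele,
            rec.hap0_allele,
            rec.pp,
            rec.anchors,
        )
        obs = [
            ReadObservation(f"p{i}", t, ANCHOR.site_index, a)
            for i, (t, a) in enumerate(pairs)
        ]
        ev = summarize_evidence(rec, obs)
        ev_f = summarize_evidence(flipped, obs)
        assert (ev.confirming, ev.contradicting) == (ev_f.contradicting, ev_f.confirming)
        d, d_f = decide_phase(ev, rec), decide_phase(ev_f, flipped)
        swap = {
            Outcome.VALIDATED: Outcome.SWITCHED,
            Outcome.SWITCHED: Outcome.VALIDATED,
            Outcome.UNRESOLVED: Outcome.UNRESOLVED,
        }
        assert d_f.outcome == swap[d.outcome]


def _ev(c, x):
    e = EvidenceSummary()
    e.confirming, e.contradicting = c, x
    return e


REC = _record(Orientation.CIS)


class TestDecidePhase:
    @pytest.mark.parametrize(
        "c,x,policy,outcome,support",
        [
            (0, 2, "strict", Outcome.SWITCHED, 2),
            (3, 0, "strict", Outcome.VALIDATED, 3),
            (1, 4, "strict", Outcome.UNRESOLVED, 0),
            (0, 0, "strict", Outcome.UNRESOLVED, 0),
            (1, 4, "majority", Outcome.SWITCHED, 4),
            (4, 1, "majority", Outcome.VALIDATED, 4),
            (2, 2, "majority", Outcome.UNRESOLVED, 0),
        ],
    )
    def test_decision_table(self, c, x, policy, outcome, support):
        d = decide_phase(_ev(c, x), REC, policy)
        assert d.outcome is outcome and d.supporting_reads == support
        assert (d.confirming, d.contradicting) == (c, x)


class TestPolishSample:
    def test_planted_flips_all_corrected_on_clean_reads(self, perfect_run):
        flips = {
            (s, j) for s, j, k in perfect_run.fixture.cohort.registry if k == "flip"
        }
        switched = {
            (d.sample_index, d.site_index)
            for d in perfect_run.decisions
            if d.outcome is Outcome.SWITCHED
        }
        linked = {
            (d.sample_index, d.site_index)
            for d in perfect_run.decisions
            if d.outcome is not Outcome.UNRESOLVED
        }
        assert switched <= flips  # zero false switches
        assert linked & flips == switched  # every linked flip corrected
        # with the separable score model, extraction targets exactly the flips
        assert {
            (r.sample_index, r.site_index) for r in perfect_run.store.records()
        } == flips

    def test_rerun_is_deterministic(self, perfect_run):
        redo = polish_sample(
            perfect_run.store, perfect_run.fixture.bams[3], sample=3
        )
        assert redo == [d for d in perfect_run.decisions if d.sample_index == 3]

    def test_targets_without_anchors_unresolved(self, noisy_run):
        by_key = {(d.sample_index, d.site_index): d for d in noisy_run.decisions}
        for rec in noisy_run.store.records():
            if not rec.anchors:
                d = by_key[(rec.sample_index, rec.site_index)]
                assert d.outcome is Outcome.UNRESOLVED

    def test_missing_index_fatal(self, noisy_run, tmp_path):
        import shutil

        orphan = tmp_path / "noindex.bam"
        shutil.copy(noisy_run.fixture.bams[0], orphan)
        with pytest.raises(FileNotFoundError, match="index"):
            polish_sample(noisy_run.store, orphan, sample=0)

    def test_stricter_filters_never_add_observations(self, noisy_run):
        import pysam

        store = noisy_run.store
        recs = [r for r in store.records_by_sample.get(0, []) if r.anchors][:10]
        with pysam.AlignmentFile(str(noisy_run.fixture.bams[0])) as bam:
            for rec in recs:
                base = len(observe_target(rec, store.sites, bam, ReadFilterPolicy()))
                for policy in (
                    ReadFilterPolicy(min_mapq=60),
                    ReadFilterPolicy(min_base_quality=40),
                ):
                    assert len(observe_target(rec, store.sites, bam, policy)) <= base
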