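"""Read-backed phase checking of extracted targets.

For each target the sample's paired-end reads over the target and its
anchors are piled up; each accepted read pair covering the target and an
anchor contributes one unit of evidence. A pair *confirms* the stored
phase when the two alleles it carries lie on a single haplotype under the
current orientation, and *contradicts* it when they only do so under the
flipped orientation. Under the default strict policy a target is switched
only when at least one pair contradicts and none confirms — the evidence
filter is deliberately severe so that polishing can only remove errors,
not introduce them. The opt-in majority policy resolves mixed evidence
toward the larger count (useful when several anchors disagree because one
of them is itself mis-phased), with ties left unresolved.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional

import pysam

from .records import (
    EvidenceSummary,
    Orientation,
    Outcome,
    PhaseDecision,
    ReadObservation,
    SiteRecord,
    TargetRecord,
)
from .variant_io import PathLike, TargetStore

OTHER = -1  # allele code for bases matching neither REF nor ALT


@dataclass(frozen=True)
class ReadFilterPolicy:
    """Acceptance rules for reads used as phase evidence.

    Defaults follow a very strict regime: MAPQ >= 50, properly oriented
    (FR) primary read pairs with both mates mapped and no duplicate flag.
    ``min_base_quality`` additionally masks individual base calls below
    the floor (masked bases count as "other", never as evidence).
    """

    min_mapq: int = 50
    require_paired: bool = True
    require_both_mapped: bool = True
    require_fr_orientation: bool = True
    reject_duplicates: bool = True
    min_base_quality: int = 20

    def __post_init__(self) -> None:
        if self.min_mapq < 0 or self.min_base_quality < 0:
            raise ValueError("quality floors must be >= 0")


def read_passes_filters(read: pysam.AlignedSegment, policy: ReadFilterPolicy) -> bool:
    """Pure accept/reject predicate on one alignment record.

    Pair-level conditions (mate unmapped, orientation) are evaluated via
    the record's mate flags; MAPQ is evaluated per record, so a pair is
    rejected if either mate used for an observation fails.
    """
    if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_qcfail:
        return False
    if policy.require_paired and not read.is_paired:
        return False
    if policy.require_both_mapped and (not read.is_paired or read.mate_is_unmapped):
        return False
    if policy.reject_duplicates and read.is_duplicate:
        return False
    if policy.require_fr_orientation:
        if not read.is_paired or read.is_reverse == read.mate_is_reverse:
            return False
    if read.mapping_quality < policy.min_mapq:
        return False
    return True


# kept as the documented pair-level spelling of the predicate
def read_pair_passes_filters(
    pair: Iterable[pysam.AlignedSegment], policy: ReadFilterPolicy
) -> bool:
    reads = list(pair)
    return bool(reads) and all(read_passes_filters(r, policy) for r in reads)


def allele_at(
    read: pysam.AlignedSegment, pos0: int, ref: str, alt: str, min_base_quality: int
) -> Optional[int]:
    """Allele carried by one read at a 0-based reference position.

    Returns 0 (REF), 1 (ALT), OTHER (mismatching base, low-quality base,
    deletion or reference skip at the position), or None when the read
    does not span the position at all.
    """
    if (
        read.reference_start is None
        or read.reference_end is None
        or pos0 < read.reference_start
        or pos0 >= read.reference_end
    ):
        return None
    found = False
    qpos = None
    for q, r in read.get_aligned_pairs(matches_only=False):
        if r == pos0:
            qpos = q  # None here means a deletion/refskip spans the site
            found = True
            break
    if not found or read.query_sequence is None:
        return None
    return _allele_from_query(read, qpos, ref, alt, min_base_quality)


def _allele_from_query(
    read: pysam.AlignedSegment,
    qpos: Optional[int],
    ref: str,
    alt: str,
    min_base_quality: int,
) -> int:
    if qpos is None:  # deletion or refskip at the site
        return OTHER
    base = read.query_sequence[qpos]
    quals = read.query_qualities
    if quals is not None and quals[qpos] < min_base_quality:
        return OTHER
    if base == ref:
        return 0
    if base == alt:
        return 1
    return OTHER


def _site_alleles_by_pair(
    reads: Iterable[pysam.AlignedSegment],
    sites: list[SiteRecord],
    policy: ReadFilterPolicy,
) -> dict[str, dict[int, int]]:
    """Per read pair, the merged allele call at each covered site.

    Mates are merged per site: if both cover a site and agree, one call;
    if they disagree, the whole pair is discarded for this target (the
    fragment's information is internally inconsistent).
    """
    calls: dict[str, dict[int, list[int]]] = {}
    positions = {s.site_index: (s.pos - 1, s.ref, s.alt) for s in sites}
    for read in reads:
        if not read_passes_filters(read, policy):
            continue
        for sidx, (pos0, ref, alt) in positions.items():
            a = allele_at(read, pos0, ref, alt, policy.min_base_quality)
            if a is None:
                continue
            calls.setdefault(read.query_name, {}).setdefault(sidx, []).append(a)
    merged: dict[str, dict[int, int]] = {}
    for name, per_site in calls.items():
        ok = True
        flat: dict[int, int] = {}
        for sidx, alleles in per_site.items():
            if len(set(alleles)) > 1:
                ok = False
                break
            flat[sidx] = alleles[0]
        if ok:
            merged[name] = flat
    return merged


def observe_alleles(
    target_site: SiteRecord,
    anchor_site: SiteRecord,
    reads: Iterable[pysam.AlignedSegment],
    policy: Optional[ReadFilterPolicy] = None,
) -> list[ReadObservation]:
    """Observations of one (target, anchor) site pair from a read stream.

    One observation per accepted read pair covering both positions.
    """
    policy = policy or ReadFilterPolicy()
    merged = _site_alleles_by_pair(reads, [target_site, anchor_site], policy)
    out = []
    for name in sorted(merged):
        flat = merged[name]
        if target_site.site_index in flat and anchor_site.site_index in flat:
            out.append(
                ReadObservation(
                    pair_id=name,
                    target_allele=flat[target_site.site_index],
                    anchor_site_index=anchor_site.site_index,
                    anchor_allele=flat[anchor_site.site_index],
                )
            )
    return out


def summarize_evidence(
    record: TargetRecord, observations: Iterable[ReadObservation]
) -> EvidenceSummary:
    """Count confirming vs contradicting pairs against the stored phase."""
    anchors = {a.site_index: a for a in record.anchors}
    ev = EvidenceSummary()
    for obs in observations:
        if obs.target_allele == OTHER or obs.anchor_allele == OTHER:
            continue
        anchor = anchors.get(obs.anchor_site_index)
        if anchor is None:
            raise ValueError(
                f"observation references anchor {obs.anchor_site_index} "
                "not attached to this target"
            )
        # haplotype index carrying the observed allele, both sites het
        t_hap = 0 if record.hap0_allele == obs.target_allele else 1
        a_hap = 0 if anchor.hap0_allele == obs.anchor_allele else 1
        ev.add(obs.anchor_site_index, confirms=(t_hap == a_hap))
    return ev


DecisionPolicy = Literal["strict", "majority"]


def decide_phase(
    evidence: EvidenceSummary,
    record: TargetRecord,
    policy: DecisionPolicy = "strict",
) -> PhaseDecision:
    """Turn an evidence summary into validated / switched / unresolved.

    strict: switch only on contradiction with zero confirmation, validate
    only on confirmation with zero contradiction, anything else (including
    no evidence and mixed evidence) unresolved. majority: the larger count
    wins, ties unresolved.
    """
    c, x = evidence.confirming, evidence.contradicting
    if policy == "strict":
        if x >= 1 and c == 0:
            outcome, support = Outcome.SWITCHED, x
        elif c >= 1 and x == 0:
            outcome, support = Outcome.VALIDATED, c
        else:
            outcome, support = Outcome.UNRESOLVED, 0
    elif policy == "majority":
        if x > c:
            outcome, support = Outcome.SWITCHED, x
        elif c > x and c >= 1:
            outcome, support = Outcome.VALIDATED, c
        else:
            outcome, support = Outcome.UNRESOLVED, 0
    else:
        raise ValueError(f"unknown decision policy {policy!r}")
    return PhaseDecision(
        sample_index=record.sample_index,
        site_index=record.site_index,
        outcome=outcome,
        supporting_reads=support,
        confirming=c,
        contradicting=x,
        original_pp=record.pp,
    )


def observe_target(
    record: TargetRecord,
    sites: list[SiteRecord],
    bam: pysam.AlignmentFile,
    policy: ReadFilterPolicy,
    fetch_margin: int = 300,
) -> list[ReadObservation]:
    """All (pair, anchor) observations for one target from an open BAM/CRAM.

    One fetch spans the target and all anchors (plus a margin for reads
    whose mates extend beyond the outermost site).
    """
    if not record.anchors:
        return []
    involved = [sites[record.site_index]] + [sites[a.site_index] for a in record.anchors]
    contig = involved[0].chrom
    lo = min(s.pos for s in involved) - 1 - fetch_margin
    hi = max(s.pos for s in involved) + fetch_margin
    reads = list(bam.fetch(contig, max(0, lo), hi))
    merged = _site_alleles_by_pair(reads, involved, policy)
    t_idx = record.site_index
    out: list[ReadObservation] = []
    for name in sorted(merged):
        flat = merged[name]
        if t_idx not in flat:
            continue
        for a in record.anchors:
            if a.site_index in flat:
                out.append(
                    ReadObservation(
                        pair_id=name,
                        target_allele=flat[t_idx],
                        anchor_site_index=a.site_index,
                        anchor_allele=flat[a.site_index],
                    )
                )
    return out


def polish_sample(
    store: TargetStore,
    alignments: PathLike,
    reference: Optional[PathLike] = None,
    sample: Optional[int] = None,
    sample_name: Optional[str] = None,
    read_policy: Optional[ReadFilterPolicy] = None,
    decision_policy: DecisionPolicy = "strict",
) -> list[PhaseDecision]:
    """Decide every target of one sample against its sequencing reads.

    ``alignments`` is a coordinate-sorted, indexed BAM or CRAM (CRAM
    needs ``reference``). Targets without anchors are unresolved.
    Deterministic given identical inputs.
    """
    read_policy = read_policy or ReadFilterPolicy()
    if sample is None:
        if sample_name is None:
            raise ValueError("give sample index or sample name")
        sample = store.sample_names.index(sample_name)
    records = store.records_by_sample.get(sample, [])
    decisions: list[PhaseDecision] = []
    kwargs = {}
    if reference is not None:
        kwargs["reference_filename"] = str(reference)
    with pysam.AlignmentFile(str(alignments), **kwargs) as bam:
        if not bam.has_index():
            raise FileNotFoundError(f"{alignments}: missing BAM/CRAM index")
        contigs = set(bam.references)
        for rec in records:
            site = store.sites[rec.site_index]
            if site.chrom not in contigs:
                raise ValueError(
                    f"contig {site.chrom!r} from the variant file is absent from "
                    f"{alignments}; check that VCF and alignments share naming"
                )
            obs = observe_target(rec, store.sites, bam, read_policy)
            ev = summarize_evidence(rec, obs)
            decisions.append(decide_phase(ev, rec, decision_policy))
    return decisions


# ---------------------------------------------------------------------------
# Decision (de)serialization: tab-delimited, one row per target
# ---------------------------------------------------------------------------

_DEC_COLUMNS = [
    "sample_index",
    "chrom",
    "pos",
    "site_index",
    "outcome",
    "supporting_reads",
    "confirming",
    "contradicting",
    "original_pp",
]


def write_decisions(
    path: PathLike, decisions: Iterable[PhaseDecision], sites: list[SiteRecord]
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_DEC_COLUMNS)
        for d in decisions:
            site = sites[d.site_index]
            w.writerow(
                [
                    d.sample_index,
                    site.chrom,
                    site.pos,
                    d.site_index,
                    d.outcome.value,
                    d.supporting_reads,
                    d.confirming,
                    d.contradicting,
                    "" if d.original_pp is None else f"{d.original_pp:.6f}",
                ]
            )


def read_decisions(path: PathLike) -> list[PhaseDecision]:
    out: list[PhaseDecision] = []
    with open(path, newline="") as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            out.append(
                PhaseDecision(
                    sample_index=int(row["sample_index"]),
                    site_index=int(row["site_index"]),
                    outcome=Outcome(row["outcome"]),
                    supporting_reads=int(row["supporting_reads"]),
                    confirming=int(row["confirming"]),
                    contradicting=int(row["contradicting"]),
                    original_pp=float(row["original_pp"]) if row["original_pp"] else None,
                )
            )
    return out
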