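"""Naive reference implementations used to cross-check the fast paths.

These deliberately share no code with the production extraction and
evidence-counting routines: the anchor search is a quadratic scan over
the full genotype table, and the evidence recount enumerates every
alignment record of the BAM from scratch, re-deriving filters, mate
merging and orientation bookkeeping in the most literal way possible.
They exist only for verification; runtime does not scale.
"""

from __future__ import annotations

from typing import Optional

import pysam

from .extraction import ExtractionConfig, classify_genotype
from .records import PhasedGenotype, SiteRecord


def nearest_anchor_search(
    sites: list[SiteRecord],
    genotypes: dict[int, list[PhasedGenotype]],
    config: ExtractionConfig,
) -> dict[tuple[int, int], list[int]]:
    """Quadratic nearest-eligible-anchor search.

    ``genotypes`` maps sample_index -> per-site genotype list aligned
    with ``sites``. Returns, for every (sample, target site) pair, the
    sorted site indices of up to two eligible anchors on each side.
    """
    out: dict[tuple[int, int], list[int]] = {}
    for s, gts in genotypes.items():
        roles = [classify_genotype(g, site, config) for g, site in zip(gts, sites)]
        for j, role in enumerate(roles):
            if role != "target":
                continue
            chrom = sites[j].chrom
            before = [
                k
                for k in range(j - 1, -1, -1)
                if roles[k] == "anchor" and sites[k].chrom == chrom
            ][:2]
            after = [
                k
                for k in range(j + 1, len(sites))
                if roles[k] == "anchor" and sites[k].chrom == chrom
            ][:2]
            out[(s, j)] = sorted(before + after)
    return out


def recount_sample_evidence(
    bam_path: str,
    sites: list[SiteRecord],
    records,
    min_mapq: int = 50,
    min_base_quality: int = 20,
    reference: Optional[str] = None,
) -> dict[tuple[int, int], tuple[int, int]]:
    """Exhaustive (confirming, contradicting) recount for one sample.

    ``records`` are the sample's target records. Scans *every* record of
    the BAM (no targeted fetch), applies the strict filters literally,
    merges mate base calls per fragment and site, then counts each
    fragment once per (target, anchor) link. A fragment whose mates
    disagree at any site relevant to a target is dropped for that target.
    """
    records = list(records)
    wanted: dict[int, SiteRecord] = {}
    for rec in records:
        wanted[rec.site_index] = sites[rec.site_index]
        for a in rec.anchors:
            wanted[a.site_index] = sites[a.site_index]
    by_pos: dict[tuple[str, int], list[int]] = {}
    for sidx, site in wanted.items():
        by_pos.setdefault((site.chrom, site.pos - 1), []).append(sidx)

    kwargs = {"reference_filename": reference} if reference else {}
    fragments: dict[str, dict[int, set[str]]] = {}
    with pysam.AlignmentFile(bam_path, **kwargs) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_qcfail or read.is_duplicate:
                continue
            if not read.is_paired or read.mate_is_unmapped:
                continue
            if read.is_reverse == read.mate_is_reverse:
                continue
            if read.mapping_quality < min_mapq:
                continue
            ref_positions = read.get_reference_positions(full_length=True)
            seq = read.query_sequence
            quals = read.query_qualities
            chrom = read.reference_name
            for qpos, rpos in enumerate(ref_positions):
                if rpos is None or (chrom, rpos) not in by_pos:
                    continue
                for sidx in by_pos[(chrom, rpos)]:
                    site = wanted[sidx]
                    base = seq[qpos]
                    if quals is not None and quals[qpos] < min_base_quality:
                        call = "other"
                    elif base == site.ref:
                        call = "ref"
                    elif base == site.alt:
                        call = "alt"
                    else:
                        call = "other"
                    fragments.setdefault(read.query_name, {}).setdefault(
                        sidx, set()
                    ).add(call)

    out: dict[tuple[int, int], tuple[int, int]] = {}
    for rec in records:
        confirming = 0
        contradicting = 0
        t_idx = rec.site_index
        relevant = [t_idx] + [a.site_index for a in rec.anchors]
        for calls in fragments.values():
            if any(len(calls.get(sidx, ())) > 1 for sidx in relevant):
                continue  # mates disagree at a relevant site
            if t_idx not in calls:
                continue
            t_call = next(iter(calls[t_idx]))
            if t_call == "other":
                continue
            t_allele = 0 if t_call == "ref" else 1
            t_hap = 0 if rec.hap0_allele == t_allele else 1
            for a in rec.anchors:
                if a.site_index not in calls:
                    continue
                a_call = next(iter(calls[a.site_index]))
                if a_call == "other":
                    continue
                a_allele = 0 if a_call == "ref" else 1
                a_hap = 0 if a.hap0_allele == a_allele else 1
                if t_hap == a_hap:
                    confirming += 1
                else:
                    contradicting += 1
        out[(rec.sample_index, rec.site_index)] = (confirming, contradicting)
    return out
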