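"""Selection of low-confidence heterozygous targets and their anchors.

For every sample, each phased heterozygous genotype below the confidence
threshold (or, in MAF-proxy mode, below the frequency threshold) is
extracted together with its nearest eligible heterozygous neighbors — up
to two upstream and two downstream. Eligible anchors are the confidently
phased genotypes the read evidence will be compared against: common hets,
or rare hets whose reported confidence reaches the threshold. A
low-confidence het never anchors another target; anchoring on uncertain
phase would propagate errors.

The scan is a single coordinate-order pass with a bounded per-sample
buffer (two most recent anchors plus the targets still waiting for
downstream anchors), so memory is O(samples), independent of site count.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Literal, Optional

from .records import Anchor, PhasedGenotype, SiteRecord, TargetRecord, relative_orientation
from .variant_io import (
    PP_CEILING,
    PathLike,
    TargetStore,
    read_phased_sites,
    vcf_samples,
)

Role = Literal["target", "anchor", "neither"]


@dataclass(frozen=True)
class ExtractionConfig:
    """Thresholds governing target/anchor selection.

    ``pp_threshold`` (default 0.99): hets with confidence below it are
    targets, at or above it anchors. ``maf_threshold`` (default 0.001)
    separates rare from common sites; in ``maf_proxy`` mode it replaces
    the confidence score entirely (for phasers that emit none).
    """

    pp_threshold: float = PP_CEILING
    maf_threshold: float = 0.001
    mode: Literal["pp", "maf_proxy"] = "pp"
    snv_only: bool = True

    def __post_init__(self) -> None:
        if not (0.5 < self.pp_threshold <= 1.0):
            raise ValueError("pp_threshold must be in (0.5, 1.0]")
        if not (0.0 < self.maf_threshold <= 0.5):
            raise ValueError("maf_threshold must be in (0, 0.5]")
        if self.mode not in ("pp", "maf_proxy"):
            raise ValueError(f"unknown mode {self.mode!r}")


def classify_genotype(
    gt: PhasedGenotype, site: SiteRecord, config: ExtractionConfig
) -> Role:
    """Classify one genotype as target, anchor or neither.

    Homozygous and unphased genotypes are always "neither". Non-SNVs are
    excluded from both roles when ``snv_only`` is set (the read-evidence
    stage only handles substitutions).
    """
    if not gt.phased or not gt.is_het:
        return "neither"
    if config.snv_only and not site.is_snv:
        return "neither"
    if config.mode == "maf_proxy":
        return "target" if site.maf < config.maf_threshold else "anchor"
    if gt.pp is not None and gt.pp < config.pp_threshold:
        return "target"
    if gt.pp is not None:  # pp >= threshold: confidently phased, any frequency
        return "anchor"
    # no confidence reported: trust common sites, distrust-but-skip rare ones
    return "anchor" if site.maf >= config.maf_threshold else "neither"


@dataclass
class _PendingTarget:
    record: TargetRecord
    downstream: int = 0  # downstream anchors attached so far


class _SampleState:
    __slots__ = ("recent", "pending")

    def __init__(self) -> None:
        self.recent: deque[tuple[int, int, int]] = deque(maxlen=2)
        self.pending: list[_PendingTarget] = []


def extract_targets(
    vcf_path: PathLike,
    config: Optional[ExtractionConfig] = None,
    region: Optional[str] = None,
    region_padding: int = 2000,
) -> TargetStore:
    """Single-pass extraction of target records from a phased VCF/BCF.

    When ``region`` is given, a ±``region_padding`` bp margin is also
    scanned so anchors near the region edges are not truncated; targets
    are only created inside the core region. Targets with no eligible
    anchor on either side are kept with an empty anchor list (they will
    come out unresolved downstream).
    """
    config = config or ExtractionConfig()
    samples = vcf_samples(vcf_path)
    states: dict[int, _SampleState] = {}
    done: dict[int, list[TargetRecord]] = {i: [] for i in range(len(samples))}
    sites: list[SiteRecord] = []

    core = None
    scan_region = region
    if region is not None:
        from .variant_io import _parse_region

        contig, span = _parse_region(region)
        if span is not None:
            core = span
            scan_region = (
                f"{contig}:{max(1, span[0] - region_padding)}-{span[1] + region_padding}"
            )

    last_contig: Optional[str] = None
    for site, gts in read_phased_sites(vcf_path, region=scan_region):
        if site.chrom != last_contig:
            # anchors never span a contig boundary: flush pending targets
            for st in states.values():
                st.recent.clear()
                for pend in st.pending:
                    done[pend.record.sample_index].append(pend.record)
                st.pending.clear()
            last_contig = site.chrom
        sites.append(site)
        in_core = core is None or (core[0] <= site.pos <= core[1])
        for gt in gts:
            role = classify_genotype(gt, site, config)
            if role == "neither":
                continue
            st = states.get(gt.sample_index)
            if st is None:
                st = states[gt.sample_index] = _SampleState()
            if role == "anchor":
                still_pending: list[_PendingTarget] = []
                for pend in st.pending:
                    t = pend.record
                    t.anchors.append(
                        Anchor(
                            site.site_index,
                            gt.hap0_allele,
                            gt.hap1_allele,
                            relative_orientation(
                                t.hap0_allele,
                                t.hap1_allele,
                                gt.hap0_allele,
                                gt.hap1_allele,
                            ),
                        )
                    )
                    pend.downstream += 1
                    if pend.downstream >= 2:
                        done[t.sample_index].append(t)
                    else:
                        still_pending.append(pend)
                st.pending = still_pending
                st.recent.append((site.site_index, gt.hap0_allele, gt.hap1_allele))
            else:  # target
                if not in_core:
                    continue
                rec = TargetRecord(
                    sample_index=gt.sample_index,
                    site_index=site.site_index,
                    hap0_allele=gt.hap0_allele,
                    hap1_allele=gt.hap1_allele,
                    pp=gt.pp,
                    anchors=[
                        Anchor(
                            a_idx,
                            a0,
                            a1,
                            relative_orientation(
                                gt.hap0_allele, gt.hap1_allele, a0, a1
                            ),
                        )
                        for a_idx, a0, a1 in st.recent
                    ],
                )
                st.pending.append(_PendingTarget(rec))

    for st_idx, st in states.items():
        for pend in st.pending:
            done[pend.record.sample_index].append(pend.record)

    for recs in done.values():
        recs.sort(key=lambda r: r.site_index)

    store = TargetStore(
        sites=sites,
        sample_names=samples,
        records_by_sample={s: r for s, r in done.items() if r},
    )
    store.validate()
    return store
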