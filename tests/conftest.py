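"""Shared fixtures: hand-built VCFs/reads and session-scoped simulated cohorts."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pysam
import pytest
from hypothesis import HealthCheck, settings

from phasepolish.extraction import ExtractionConfig, extract_targets
from phasepolish.phase_calling import polish_sample
from phasepolish.records import PhaseDecision
from phasepolish.simulate import Fixture, SimConfig, write_fixture
from phasepolish.variant_io import TargetStore
from phasepolish.vcf_update import UpdatePlan, apply_decisions

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


def write_text_vcf(path: Path, samples: list[str], rows: list[tuple], with_pp=True) -> Path:
    """Write a small uncompressed VCF by hand.

    Each row: (chrom, pos, ref, alt, [(gt_string, pp_or_None), ...]).
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=1000000>",
        "##contig=<ID=chr2,length=1000000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if with_pp:
        lines.append(
            '##FORMAT=<ID=PP,Number=1,Type=Float,Description="Phasing confidence">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    fmt = "GT:PP" if with_pp else "GT"
    for chrom, pos, ref, alt, calls in rows:
        cells = []
        for gt, pp in calls:
            if with_pp:
                cells.append(f"{gt}:{pp:.4f}" if pp is not None else f"{gt}:.")
            else:
                cells.append(gt)
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


_READ_HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "chr1", "LN": 1_000_000}]}
)


def make_read(
    qname: str,
    start: int,
    seq: str,
    mapq: int = 60,
    reverse: bool = False,
    mate_reverse: bool = True,
    paired: bool = True,
    mate_unmapped: bool = False,
    duplicate: bool = False,
    quals: list[int] | None = None,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(_READ_HEADER)
    a.query_name = qname
    a.query_sequence = seq
    a.reference_id = 0
    a.reference_start = start
    a.cigarstring = f"{len(seq)}M"
    a.mapping_quality = mapq
    a.is_paired = paired
    a.is_proper_pair = paired
    a.is_reverse = reverse
    a.mate_is_reverse = mate_reverse
    a.mate_is_unmapped = mate_unmapped
    a.is_duplicate = duplicate
    a.next_reference_id = 0
    a.next_reference_start = start
    a.query_qualities = quals if quals is not None else [37] * len(seq)
    return a


@dataclass
class PipelineRun:
    fixture: Fixture
    store: TargetStore
    decisions: list[PhaseDecision]
    polished: Path
    plan: UpdatePlan


def run_pipeline(fixture: Fixture, out_name: str = "polished.bcf") -> PipelineRun:
    config = ExtractionConfig(maf_threshold=fixture.config.rare_maf)
    store = extract_targets(fixture.vcf, config)
    decisions: list[PhaseDecision] = []
    for s in range(fixture.truth.n_samples):
        decisions.extend(polish_sample(store, fixture.bams[s], sample=s))
    plan = UpdatePlan(decisions)
    polished = fixture.directory / out_name
    apply_decisions(fixture.vcf, plan, polished)
    return PipelineRun(fixture, store, decisions, polished, plan)


def perfect_config(**overrides) -> SimConfig:
    """Error-free reads, flat 30% flip rate at rare hets, separable scores."""
    base = dict(
        n_samples=10,
        region_length=60_000,
        n_sites=400,
        rare_maf=0.13,
        base_error=0.0,
        low_baseq_fraction=0.0,
        low_mapq_fraction=0.0,
        duplicate_fraction=0.0,
        switch_rate=0.0,
        pp_model="separated",
        flip_curve=tuple((u, 0.30) for u, _ in SimConfig().flip_curve),
    )
    base.update(overrides)
    return SimConfig(**base)


def noisy_config(**overrides) -> SimConfig:
    """Small noisy cohort: defaults scaled down to a 10-sample 60 kb region."""
    base = dict(n_samples=10, region_length=60_000, n_sites=400, rare_maf=0.13)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def perfect_run(tmp_path_factory) -> PipelineRun:
    fx = write_fixture(perfect_config(), tmp_path_factory.mktemp("perfect") / "fx", seed=7)
    return run_pipeline(fx)


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory) -> PipelineRun:
    fx = write_fixture(noisy_config(), tmp_path_factory.mktemp("noisy") / "fx", seed=5)
    return run_pipeline(fx)
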