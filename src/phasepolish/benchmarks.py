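"""Canned benchmark scenarios exercising the whole pipeline.

Each scenario builds synthetic cohorts from a seed, runs the pipeline,
and returns plain-number metrics. They serve as reproducible end-to-end
checks: oracle agreement between the production paths and the naive
reference implementations, exact correction on error-free reads, error
reduction under realistic noise, update safety, and confidence-score
calibration.
"""

from __future__ import annotations

from pathlib import Path
from tempfile import TemporaryDirectory
from typing import Optional

import numpy as np

from . import evaluate as ev
from ._bruteforce import nearest_anchor_search, recount_sample_evidence
from .extraction import ExtractionConfig, extract_targets
from .phase_calling import polish_sample
from .records import Outcome, PhaseDecision
from .simulate import Fixture, SimConfig, write_fixture
from .variant_io import (
    TargetStore,
    decode_confidence,
    encode_confidence,
    open_variant_file,
    read_phased_sites,
)
from .vcf_update import UpdatePlan, apply_decisions, verify_update


def _subseed(seed: int, k: int) -> int:
    return (seed * 1000 + k) % (2**31 - 1)


def run_cohort(fixture: Fixture):
    """Extract, polish every sample, and apply decisions for one cohort."""
    config = ExtractionConfig(maf_threshold=fixture.config.rare_maf)
    store = extract_targets(fixture.vcf, config)
    decisions: list[PhaseDecision] = []
    for s in range(fixture.truth.n_samples):
        decisions.extend(polish_sample(store, fixture.bams[s], sample=s))
    plan = UpdatePlan(decisions)
    polished = fixture.directory / "polished.bcf"
    apply_decisions(fixture.vcf, plan, polished)
    return store, decisions, plan, polished


def perfect_data_config() -> SimConfig:
    """Error-free 30x reads, 30% flips at rare hets, separable scores."""
    return SimConfig(
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


def calibration_config() -> SimConfig:
    """Dense cohort sized for per-bin calibration resolution."""
    return SimConfig(
        n_samples=300, region_length=100_000, n_sites=2000, coverage=12.0
    )


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

def mac_conversion_metrics() -> dict[str, float]:
    from .variant_io import mac_threshold

    return {
        "mac_at_maf_0_001_n147754": float(mac_threshold(0.001, 147754)),
        "mac_at_maf_0_0002_n147754": float(mac_threshold(0.0002, 147754)),
    }


def oracle_agreement_metrics(
    seed: int, n_cohorts: int = 100, work_dir: Optional[Path] = None
) -> dict[str, float]:
    """Randomized mini-cohorts: fast paths vs brute-force recounts.

    Per cohort, the single-pass anchor extraction is compared with a
    quadratic nearest-eligible-neighbor search over every sample, and the
    targeted-pileup evidence counts of one rotating sample are compared
    with an exhaustive whole-BAM recount.
    """
    rng = np.random.default_rng(seed)
    anchor_sets = anchor_mismatches = 0
    evidence_counts = evidence_mismatches = 0
    with TemporaryDirectory(dir=work_dir) as td:
        for k in range(n_cohorts):
            cfg = SimConfig(
                n_samples=int(rng.integers(3, 7)),
                region_length=20_000,
                n_sites=int(rng.integers(100, 160)),
                rare_maf=0.2,
                coverage=float(rng.uniform(6, 10)),
                switch_rate=0.01,
                duplicate_fraction=0.05,
            )
            probe = int(rng.integers(cfg.n_samples))
            fx = write_fixture(cfg, Path(td) / f"c{k}", seed=_subseed(seed, k))
            ec = ExtractionConfig(maf_threshold=cfg.rare_maf)
            store = extract_targets(fx.vcf, ec)

            gts_by_sample = {s: [] for s in range(cfg.n_samples)}
            sites = []
            for site, gts in read_phased_sites(fx.vcf):
                sites.append(site)
                for g in gts:
                    gts_by_sample[g.sample_index].append(g)
            oracle = nearest_anchor_search(sites, gts_by_sample, ec)
            mine = {
                (r.sample_index, r.site_index): sorted(
                    a.site_index for a in r.anchors
                )
                for r in store.records()
            }
            anchor_sets += len(oracle)
            if mine != oracle:
                anchor_mismatches += sum(
                    1 for key in set(mine) | set(oracle) if mine.get(key) != oracle.get(key)
                )

            decisions = polish_sample(store, fx.bams[probe], sample=probe)
            counts = recount_sample_evidence(
                str(fx.bams[probe]),
                store.sites,
                store.records_by_sample.get(probe, []),
            )
            for d in decisions:
                evidence_counts += 1
                if counts[(d.sample_index, d.site_index)] != (
                    d.confirming,
                    d.contradicting,
                ):
                    evidence_mismatches += 1
    return {
        "oracle_cohorts": float(n_cohorts),
        "anchor_sets_compared": float(anchor_sets),
        "anchor_set_mismatches": float(anchor_mismatches),
        "evidence_targets_compared": float(evidence_counts),
        "evidence_count_mismatches": float(evidence_mismatches),
    }


def perfect_data_metrics(
    seed: int, work_dir: Optional[Path] = None
) -> dict[str, float]:
    """Exact correction on error-free reads: planted flips vs decisions."""
    with TemporaryDirectory(dir=work_dir) as td:
        fx = write_fixture(perfect_data_config(), Path(td) / "fx", seed=seed)
        store, decisions, plan, polished = run_cohort(fx)
        flips = {(s, j) for s, j, k in fx.cohort.registry if k == "flip"}
        switched = {
            (d.sample_index, d.site_index)
            for d in decisions
            if d.outcome is Outcome.SWITCHED
        }
        linked = {
            (d.sample_index, d.site_index)
            for d in decisions
            if d.outcome is not Outcome.UNRESOLVED
        }
        _, e0, e1, _ = ev.load_phase_matrix(polished)
        tkeys = {(r.sample_index, r.site_index) for r in store.records()}
        n_eval, n_disc, subset = ev.rephased_subset_ser(
            e0,
            e1,
            fx.truth.haps[0::2],
            fx.truth.haps[1::2],
            fx.truth.macs,
            decisions,
            targets=tkeys,
        )
    return {
        "planted_flips": float(len(flips)),
        "linked_flips": float(len(linked & flips)),
        "linked_flips_corrected": float(len(switched & flips)),
        "false_switches": float(len(switched - flips)),
        "linked_subset_ser_pct": 100.0 * (subset if subset is not None else float("nan")),
        "linked_subset_pairs": float(n_eval),
    }


def noisy_data_metrics(seed: int, work_dir: Optional[Path] = None) -> dict[str, float]:
    """Error reduction on the default noisy cohort (0.1% base error, 30x)."""
    with TemporaryDirectory(dir=work_dir) as td:
        fx = write_fixture(SimConfig(), Path(td) / "fx", seed=seed)
        store, decisions, plan, polished = run_cohort(fx)
        t0, t1 = fx.truth.haps[0::2], fx.truth.haps[1::2]
        macs = fx.truth.macs
        _, p0, p1, _ = ev.load_phase_matrix(fx.vcf)
        _, e0, e1, _ = ev.load_phase_matrix(polished)
        pre = ev.switch_error_rate(p0, p1, t0, t1, macs)
        post = ev.switch_error_rate(e0, e1, t0, t1, macs)
        tkeys = {(r.sample_index, r.site_index) for r in store.records()}
        n_eval, n_disc, subset = ev.rephased_subset_ser(
            e0, e1, t0, t1, macs, decisions, targets=tkeys
        )
        link = ev.linkage_stats(store, decisions)
        overall = link[link.mac_bin == "overall"]
        singleton_link = link[link.mac_bin == "1"]
    return {
        "singleton_pairs": float(pre.iloc[0]["evaluated_pairs"]),
        "singleton_ser_pre_pct": 100.0 * pre.iloc[0]["ser"],
        "singleton_ser_post_pct": 100.0 * post.iloc[0]["ser"],
        "singleton_flip_rate_pct": 100.0 * SimConfig().flip_rate(1),
        "linked_subset_ser_pct": 100.0 * (subset if subset is not None else float("nan")),
        "linked_subset_pairs": float(n_eval),
        "linked_fraction_pct": 100.0 * overall.linked_fraction.item(),
        "singleton_linked_fraction_pct": 100.0 * singleton_link.linked_fraction.item(),
        "switched_fraction_of_linked_pct": 100.0
        * overall.switched_fraction_of_linked.item(),
    }


def safety_metrics(seed: int, work_dir: Optional[Path] = None) -> dict[str, float]:
    """Update verification plus the confidence-encoding round trip."""
    with TemporaryDirectory(dir=work_dir) as td:
        cfg = SimConfig(n_samples=10, region_length=60_000, n_sites=400, rare_maf=0.13)
        fx = write_fixture(cfg, Path(td) / "fx", seed=seed)
        store, decisions, plan, polished = run_cohort(fx)
        report = verify_update(fx.vcf, polished, plan)

        # corruption drills: damage one genotype / rephase a confident one
        corrupt_detected = 0
        for drill in ("hom", "confident"):
            bad = Path(td) / f"bad_{drill}.bcf"
            _corrupt_one(polished, bad, drill)
            if not verify_update(fx.vcf, bad).ok:
                corrupt_detected += 1

    max_err = 0.0
    for pp100 in range(50, 99):
        for n in range(1, 51):
            pp = pp100 / 100
            got_pp, got_n, _ = decode_confidence(encode_confidence(pp, n))
            max_err = max(max_err, abs(got_pp - pp), float(got_n != n))
    return {
        "verify_violations": float(len(report.violations)),
        "genotypes_verified": float(report.genotypes_checked),
        "corruptions_detected": float(corrupt_detected),
        "corruption_drills": 2.0,
        "encode_decode_max_error": max_err,
    }


def _corrupt_one(src: Path, dst: Path, drill: str) -> None:
    done = False
    with open_variant_file(src) as vf:
        hdr = vf.header.copy()
        with open_variant_file(str(dst), "wb", header=hdr) as out:
            for rec in vf:
                rec.translate(hdr)
                if not done:
                    for s in rec.samples.values():
                        gt = s["GT"]
                        pp = s.get("PP")
                        if gt is None or None in gt or gt[0] == gt[1]:
                            continue
                        if drill == "hom":
                            s["GT"] = (1, 1)
                            s.phased = True
                            done = True
                            break
                        if pp is not None and 0.99 <= float(pp) <= 1.0:
                            s["GT"] = (gt[1], gt[0])
                            s.phased = True
                            done = True
                            break
                out.write(rec)
    if not done:
        raise RuntimeError("corruption drill found no suitable genotype")


def calibration_metrics(seed: int, work_dir: Optional[Path] = None) -> dict[str, float]:
    """Confidence-bin error rates under the miscalibrated score model."""
    with TemporaryDirectory(dir=work_dir) as td:
        fx = write_fixture(calibration_config(), Path(td) / "fx", seed=seed)
        store, decisions, plan, polished = run_cohort(fx)
        table = ev.calibration_table(decisions)
    out = {
        "calibration_monotone_decreasing": float(table.attrs["monotone_decreasing"]),
        "calibration_decided_calls": float((table.validated + table.switched).sum()),
    }
    for _, row in table.iterrows():
        key = row.pp_bin.strip("[)").replace(",", "_").replace(".", "")
        out[f"switched_fraction_pct_pp_{key}"] = 100.0 * row.switched_fraction
    return out
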