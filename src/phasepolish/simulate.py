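"""Synthetic diploid cohorts for exercising the polishing pipeline.

The generator produces, from one seed: a random reference sequence, true
haplotypes for a cohort at biallelic SNVs whose allele frequencies follow
a rare-skewed Beta law, a "statistically phased" VCF derived from the
truth by injecting frequency-dependent phasing errors with correlated
confidence scores, and per-sample coordinate-sorted paired-end reads
drawn from the *true* haplotypes.

Error model. Common heterozygous genotypes are phased nearly perfectly
and fail only through *switch errors* (the remainder of the sample's
haplotype labels inverts, at a small per-interval rate). Rare
heterozygous genotypes fail through *flip errors*: a single genotype is
assigned to the wrong haplotype with a probability that decays with
minor allele count (about a third of singletons by default). Confidence
(PP) scores are emitted for rare hets only, drawn conditionally on
whether the emitted phase is locally correct; the default model is
mildly overconfident, with a conditional error probability falling
roughly from a third at PP 0.5 to an eighth near 0.99.

Reads are emitted pre-aligned at their generative coordinates (the
haplotypes differ from the reference only by SNVs, so placements are
exact and the evidence available to the polisher is fully checkable);
no external aligner is involved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pysam

from .records import SiteRecord
from .variant_io import PathLike, open_variant_file, quiet_htslib

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# (upper MAC bound inclusive, flip probability); open-ended last bin
DEFAULT_FLIP_CURVE: tuple[tuple[float, float], ...] = (
    (1, 0.34),
    (5, 0.20),
    (10, 0.12),
    (20, 0.08),
    (50, 0.05),
    (100, 0.03),
    (200, 0.015),
    (float("inf"), 0.005),
)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic cohort.

    Defaults describe the regime the polisher is designed for: a
    high-coverage short-read cohort (30x, 2x150 bp, ~450 bp inserts)
    with a rare-skewed frequency spectrum, singleton flip rates around
    34% decaying with MAC, rare switch errors at common hets, and
    confidence scores that are informative but miscalibrated. ``rare_maf``
    plays the role the 0.001 MAF cutoff plays at biobank scale: sites
    below it are "rare" (flip-prone, confidence-scored), sites at or
    above it are "common" (switch-prone, no score).
    """

    n_samples: int = 30
    region_length: int = 200_000
    n_sites: int = 1300
    contig: str = "chr1"
    # allele-frequency law: f = 1/2N + (0.5 - 1/2N) * Beta(a, b)
    af_alpha: float = 0.35
    af_beta: float = 2.5
    rare_maf: float = 0.05
    # sequencing
    coverage: float = 30.0
    read_length: int = 150
    insert_mean: float = 450.0
    insert_sd: float = 100.0
    base_error: float = 0.001
    mapq_high: int = 60
    mapq_low: int = 20
    low_mapq_fraction: float = 0.02
    low_baseq_fraction: float = 0.02
    base_quality: int = 37
    low_base_quality: int = 11
    duplicate_fraction: float = 0.02
    # phasing-error model
    flip_curve: tuple[tuple[float, float], ...] = DEFAULT_FLIP_CURVE
    switch_rate: float = 0.001
    pp_model: Literal["miscalibrated", "separated"] = "miscalibrated"
    pp_error_at_half: float = 0.337
    pp_error_at_ceiling: float = 0.125
    pp_high_conf_mass: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "rare_maf",
            "base_error",
            "low_mapq_fraction",
            "low_baseq_fraction",
            "duplicate_fraction",
            "switch_rate",
            "pp_error_at_half",
            "pp_error_at_ceiling",
            "pp_high_conf_mass",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for _, rate in self.flip_curve:
            if not (0.0 <= rate <= 1.0):
                raise ValueError("flip rates must be in [0, 1]")
        if self.n_sites > self.region_length // 4:
            raise ValueError("n_sites exceeds region capacity")

    def flip_rate(self, mac: int) -> float:
        for upper, rate in self.flip_curve:
            if mac <= upper:
                return rate
        return self.flip_curve[-1][1]


@dataclass
class Truth:
    """Ground-truth cohort: reference, site list and true haplotypes."""

    reference: str
    sites: list[SiteRecord]
    haps: np.ndarray  # (2 * n_samples, n_sites) uint8
    config: SimConfig

    @property
    def n_samples(self) -> int:
        return self.haps.shape[0] // 2

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites])

    @property
    def macs(self) -> np.ndarray:
        return np.array([s.mac for s in self.sites])


@dataclass
class PhasedCohort:
    """Emitted (error-injected) phased calls plus the error registry.

    ``hap0``/``hap1`` are the emitted haplotype alleles per sample/site;
    ``pp`` the emitted confidence (NaN = absent); ``flip`` marks injected
    flip errors and ``parity`` the cumulative switch state. The registry
    lists every injected error as (sample, site_index, kind).
    """

    hap0: np.ndarray
    hap1: np.ndarray
    pp: np.ndarray
    flip: np.ndarray
    parity: np.ndarray
    registry: list[tuple[int, int, str]]


@dataclass
class TruthSet:
    """Truth plus injected errors: the ground truth for all evaluations."""

    truth: Truth
    cohort: PhasedCohort

    def discordance_mask(self) -> np.ndarray:
        """(n_samples, n_sites) bool: emitted het phase differs from truth.

        Defined at het sites only (False elsewhere). Equals flip XOR
        parity — the registry reconstructs it exactly; an independent
        matrix diff is used by tests to cross-check.
        """
        n = self.truth.n_samples
        t0 = self.truth.haps[0::2]
        t1 = self.truth.haps[1::2]
        het = t0 != t1
        return het & (self.cohort.hap0 != t0)

    def expected_discordance_from_registry(self) -> np.ndarray:
        n = self.truth.n_samples
        m = len(self.truth.sites)
        parity = np.zeros((n, m), dtype=bool)
        flip = np.zeros((n, m), dtype=bool)
        for s, j, kind in self.cohort.registry:
            if kind == "switch-start":
                parity[s, j:] ^= True
            elif kind == "flip":
                flip[s, j] ^= True
        t0 = self.truth.haps[0::2]
        t1 = self.truth.haps[1::2]
        het = t0 != t1
        return het & (parity ^ flip)


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def simulate_truth(config: SimConfig, seed: int) -> Truth:
    """Reference sequence, site list and true haplotypes for one cohort.

    Site positions are uniform without collision; allele frequencies are
    drawn from the configured Beta law on [1/2N, 0.5]; haplotype alleles
    are i.i.d. Bernoulli(f) per site. Monomorphic draws are dropped, so
    the realized site count can be slightly below ``n_sites``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    L = config.region_length
    ref = rng.choice(_BASES, size=L)
    positions = np.sort(
        rng.choice(np.arange(60, L - 60), size=config.n_sites, replace=False)
    )
    two_n = 2 * config.n_samples
    lo = 1.0 / two_n
    freqs = lo + (0.5 - lo) * rng.beta(config.af_alpha, config.af_beta, config.n_sites)
    haps = (rng.random((two_n, config.n_sites)) < freqs).astype(np.uint8)

    ac = haps.sum(axis=0)
    keep = (ac > 0) & (ac < two_n)
    positions = positions[keep]
    haps = haps[:, keep]
    ac = ac[keep]

    sites: list[SiteRecord] = []
    ref_str = ref.tobytes().decode()
    for j, (pos, count) in enumerate(zip(positions, ac)):
        ref_base = ref_str[pos]  # pos used as 0-based here; VCF pos below is pos+1
        alts = [b for b in "ACGT" if b != ref_base]
        alt_base = alts[rng.integers(0, 3)]
        sites.append(
            SiteRecord(
                chrom=config.contig,
                pos=int(pos) + 1,
                ref=ref_base,
                alt=alt_base,
                an=two_n,
                ac=int(count),
                site_index=j,
            )
        )
    return Truth(reference=ref_str, sites=sites, haps=haps, config=config)


def expected_mac_probability(config: SimConfig, mac: int, grid: int = 20001) -> float:
    """P(realized MAC = mac | site polymorphic) under the configured law.

    The expectation over the Beta frequency law is evaluated on an
    equal-probability quantile grid of the law (robust to the density's
    endpoint singularity at small shape parameters) — the analytic
    yardstick for the generator's frequency spectrum.
    """
    from scipy import stats

    two_n = 2 * config.n_samples
    lo = 1.0 / two_n
    u = (np.arange(grid) + 0.5) / grid
    x = stats.beta.ppf(u, config.af_alpha, config.af_beta)
    f = lo + (0.5 - lo) * x
    p_poly = 1.0 - stats.binom.pmf(0, two_n, f) - stats.binom.pmf(two_n, two_n, f)
    if mac == two_n - mac:
        p_mac = stats.binom.pmf(mac, two_n, f)
    else:
        p_mac = stats.binom.pmf(mac, two_n, f) + stats.binom.pmf(two_n - mac, two_n, f)
    return float(p_mac.mean() / p_poly.mean())


# ---------------------------------------------------------------------------
# Phasing-error injection
# ---------------------------------------------------------------------------

def _pp_sampler(config: SimConfig, rng: np.random.Generator):
    """Return draw(correct_mask) -> pp array, per the configured model."""
    if config.pp_model == "separated":

        def draw(correct: np.ndarray) -> np.ndarray:
            return np.where(correct, 0.995, 0.98)

        return draw

    # miscalibrated: marginal PP has pp_high_conf_mass above 0.99, the rest
    # spread over [0.5, 0.99); conditional error falls linearly across the
    # low range and is flat above the ceiling.
    n_low, n_high = 490, 20
    low = np.linspace(0.5, 0.99, n_low, endpoint=False)
    high = np.linspace(0.99, 1.0, n_high, endpoint=False)
    grid = np.concatenate([low, high])
    m = np.concatenate(
        [
            np.full(n_low, (1.0 - config.pp_high_conf_mass) / n_low),
            np.full(n_high, config.pp_high_conf_mass / n_high),
        ]
    )
    e0, e1 = config.pp_error_at_half, config.pp_error_at_ceiling
    err = np.where(
        grid < 0.99, e0 + (e1 - e0) * (grid - 0.5) / 0.49, e1
    )
    w_wrong = m * err
    w_right = m * (1.0 - err)
    w_wrong /= w_wrong.sum()
    w_right /= w_right.sum()
    cell = np.diff(np.append(grid, 1.0))

    def draw(correct: np.ndarray) -> np.ndarray:
        out = np.empty(correct.shape, dtype=float)
        idx_r = rng.choice(grid.size, size=int(correct.sum()), p=w_right)
        idx_w = rng.choice(grid.size, size=int((~correct).sum()), p=w_wrong)
        jit = rng.random(correct.size).reshape(correct.shape)
        vals = np.empty(correct.shape, dtype=float)
        vals[correct] = grid[idx_r] + jit[correct] * cell[idx_r]
        vals[~correct] = grid[idx_w] + jit[~correct] * cell[idx_w]
        np.clip(vals, 0.5, 1.0, out=out)
        return out

    return draw


def inject_phasing_errors(truth: Truth, seed: int) -> PhasedCohort:
    """Derive the emitted phased calls from the truth.

    Rare hets flip independently at the MAC-binned rate; at each common
    het after a sample's first, a switch starts with ``switch_rate``
    probability, inverting the remainder of the sample's labels.
    Confidence scores are drawn for rare hets conditionally on local
    correctness (flips are "wrong"); common hets carry no score.
    """
    config = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    n, m = truth.n_samples, len(truth.sites)
    t0 = truth.haps[0::2].copy()
    t1 = truth.haps[1::2].copy()
    het = t0 != t1
    macs = truth.macs
    mafs = macs / (2 * n)
    rare = mafs < config.rare_maf

    flip_p = np.array([config.flip_rate(int(c)) for c in macs])
    flip = het & rare & (rng.random((n, m)) < flip_p[None, :])

    parity = np.zeros((n, m), dtype=bool)
    registry: list[tuple[int, int, str]] = []
    common_het = het & ~rare
    switch_draw = rng.random((n, m))
    for s in range(n):
        idx = np.flatnonzero(common_het[s])
        state = False
        boundaries = []
        for j in idx[1:]:  # a switch starts at a common-het interval
            if switch_draw[s, j] < config.switch_rate:
                boundaries.append(j)
        for j in boundaries:
            parity[s, j:] ^= True
            registry.append((s, int(j), "switch-start"))
    for s, j in zip(*np.nonzero(flip)):
        registry.append((int(s), int(j), "flip"))
    registry.sort()

    wrong = parity ^ flip
    h0 = np.where(wrong, t1, t0).astype(np.uint8)
    h1 = np.where(wrong, t0, t1).astype(np.uint8)

    pp = np.full((n, m), np.nan)
    scored = het & rare
    if scored.any():
        draw = _pp_sampler(config, rng)
        pp[scored] = draw(~flip[scored])
    return PhasedCohort(hap0=h0, hap1=h1, pp=pp, flip=flip, parity=parity,
                        registry=registry)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def sample_names(n: int) -> list[str]:
    return [f"S{i:03d}" for i in range(n)]


def write_reference(truth: Truth, path: PathLike) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{truth.config.contig}\n")
        seq = truth.reference
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    pysam.faidx(str(path))


def write_phased_vcf(truth: Truth, cohort: PhasedCohort, path: PathLike) -> None:
    """Emit the error-injected cohort as a phased VCF/BCF with PP scores."""
    config = truth.config
    names = sample_names(truth.n_samples)
    header = pysam.VariantHeader()
    header.contigs.add(config.contig, length=config.region_length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PP", 1, "Float", "Phasing confidence in [0.5, 1.0]")
    for s in names:
        header.add_sample(s)
    mode = "wb" if str(path).endswith(".bcf") else ("wz" if str(path).endswith(".gz") else "w")
    with open_variant_file(path, mode, header=header) as out:
        for j, site in enumerate(truth.sites):
            rec = out.new_record(
                contig=site.chrom, start=site.pos - 1, alleles=(site.ref, site.alt)
            )
            for s in range(truth.n_samples):
                smp = rec.samples[s]
                smp["GT"] = (int(cohort.hap0[s, j]), int(cohort.hap1[s, j]))
                smp.phased = True
                if not np.isnan(cohort.pp[s, j]):
                    smp["PP"] = float(cohort.pp[s, j])
            out.write(rec)


def simulate_reads(
    truth: Truth, sample: int, path: PathLike, seed: int
) -> None:
    """Write one sample's paired-end reads as a sorted, indexed BAM.

    Fragments alternate uniformly between the sample's two true
    haplotypes at the configured coverage; mates carry proper FR flags
    and exact coordinates; base errors are uniform substitutions; a
    configured fraction of reads gets low MAPQ and a configured fraction
    of fragments the duplicate flag.
    """
    config = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303, sample]))
    L = config.region_length
    rl = config.read_length
    ref = np.frombuffer(truth.reference.encode(), dtype="S1").copy()
    hapseqs = []
    pos0 = truth.positions - 1
    for h in (truth.haps[2 * sample], truth.haps[2 * sample + 1]):
        seq = ref.copy()
        alt_mask = h == 1
        alt_bases = np.array(
            [s.alt.encode() for s in truth.sites], dtype="S1"
        )
        seq[pos0[alt_mask]] = alt_bases[alt_mask]
        hapseqs.append(seq)

    n_frags = int(round(config.coverage * L / (2 * rl)))
    hap_choice = rng.integers(0, 2, n_frags)
    inserts = np.clip(
        rng.normal(config.insert_mean, config.insert_sd, n_frags), rl, L - 1
    ).astype(int)
    starts = (rng.random(n_frags) * (L - inserts)).astype(int)
    dup = rng.random(n_frags) < config.duplicate_fraction

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": config.contig, "LN": L}],
        }
    )
    segments = []
    for i in range(n_frags):
        hap = hapseqs[hap_choice[i]]
        s1 = int(starts[i])
        s2 = int(starts[i] + inserts[i] - rl)
        for mate, (start, reverse) in enumerate(((s1, False), (s2, True))):
            seq = hap[start : start + rl].copy()
            quals = np.full(rl, config.base_quality, dtype=np.uint8)
            low_bq = rng.random(rl) < config.low_baseq_fraction
            quals[low_bq] = config.low_base_quality
            n_err = rng.binomial(rl, config.base_error)
            if n_err:
                err_pos = rng.choice(rl, size=n_err, replace=False)
                for p in err_pos:
                    choices = [b for b in b"ACGT" if bytes([b]) != seq[p]]
                    seq[p] = bytes([choices[rng.integers(0, 3)]])
            a = pysam.AlignedSegment(header)
            a.query_name = f"frag{i:07d}"
            a.query_sequence = seq.tobytes().decode()
            a.reference_id = 0
            a.reference_start = start
            a.cigarstring = f"{rl}M"
            a.query_qualities = quals.tolist()
            a.mapping_quality = (
                config.mapq_low
                if rng.random() < config.low_mapq_fraction
                else config.mapq_high
            )
            a.is_paired = True
            a.is_proper_pair = True
            a.is_read1 = mate == 0
            a.is_read2 = mate == 1
            a.is_reverse = reverse
            a.mate_is_reverse = not reverse
            a.is_duplicate = bool(dup[i])
            a.next_reference_id = 0
            a.next_reference_start = s2 if mate == 0 else s1
            a.template_length = int(inserts[i]) if mate == 0 else -int(inserts[i])
            segments.append(a)

    segments.sort(key=lambda r: r.reference_start)
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for a in segments:
            out.write(a)
    pysam.index(path)


@dataclass
class Fixture:
    """A complete on-disk synthetic cohort."""

    directory: Path
    seed: int
    config: SimConfig
    truth: Truth
    cohort: PhasedCohort
    vcf: Path
    reference: Path
    bams: list[Path]

    @property
    def truth_set(self) -> TruthSet:
        return TruthSet(self.truth, self.cohort)

    @property
    def sample_names(self) -> list[str]:
        return sample_names(self.truth.n_samples)


def write_fixture(
    config: SimConfig, out_dir: PathLike, seed: int, reads: bool = True
) -> Fixture:
    """Generate a complete self-consistent cohort under ``out_dir``.

    Refuses to write into an existing non-empty directory. The manifest
    (``truth.json``) records the config, seed and error registry so the
    cohort can be regenerated or evaluated independently.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        raise FileExistsError(f"{out}: refusing to overwrite a non-empty directory")
    out.mkdir(parents=True, exist_ok=True)

    truth = simulate_truth(config, seed)
    cohort = inject_phasing_errors(truth, seed)

    ref_path = out / "reference.fa"
    write_reference(truth, ref_path)
    vcf_path = out / "phased.bcf"
    write_phased_vcf(truth, cohort, vcf_path)
    import pysam.bcftools

    with quiet_htslib():
        pysam.bcftools.index("-f", str(vcf_path), catch_stdout=False)

    bam_paths: list[Path] = []
    if reads:
        for s in range(truth.n_samples):
            bam = out / f"{sample_names(truth.n_samples)[s]}.bam"
            simulate_reads(truth, s, bam, seed)
            bam_paths.append(bam)

    manifest = {
        "seed": seed,
        "config": asdict(config),
        "positions": [s.pos for s in truth.sites],
        "ref_alleles": [s.ref for s in truth.sites],
        "alt_alleles": [s.alt for s in truth.sites],
        "mac": [s.mac for s in truth.sites],
        "haplotypes": truth.haps.astype(int).tolist(),
        "registry": [[s, j, kind] for s, j, kind in cohort.registry],
        "correct": (~cohort.flip).astype(int).tolist(),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(manifest, fh)

    return Fixture(
        directory=out,
        seed=seed,
        config=config,
        truth=truth,
        cohort=cohort,
        vcf=vcf_path,
        reference=ref_path,
        bams=bam_paths,
    )


def load_manifest(directory: PathLike) -> dict:
    with open(Path(directory) / "truth.json") as fh:
        return json.load(fh)
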