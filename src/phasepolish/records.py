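"""Domain records shared across the polishing pipeline.

A *site* is one biallelic variant locus; a *phased genotype* is one sample's
call at a site with an explicit haplotype assignment; a *target* is a
low-confidence heterozygous genotype selected for read-backed re-phasing,
together with its nearby confidently phased *anchor* heterozygous genotypes.
Evidence and decisions describe the outcome of comparing sequencing reads
against the stored phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Orientation(Enum):
    """Relative phase of a target/anchor pair.

    CIS: the target's ALT allele sits on the same haplotype as the anchor's
    ALT allele; TRANS: on opposite haplotypes.
    """

    CIS = 0
    TRANS = 1


class Outcome(Enum):
    VALIDATED = "validated"
    SWITCHED = "switched"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic variant site.

    ``an``/``ac`` are the called-allele total and ALT count at the site
    (computed from called genotypes, so sites with missing calls use the
    called subset). ``site_index`` is the ordinal of the record in the
    coordinate-sorted stream.
    """

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    an: int
    ac: int
    site_index: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"site {self.chrom}:{self.pos} has ref == alt")
        if not (0 <= self.ac <= self.an):
            raise ValueError(f"site {self.chrom}:{self.pos}: ac outside [0, an]")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def mac(self) -> int:
        return min(self.ac, self.an - self.ac)

    @property
    def maf(self) -> float:
        return self.mac / self.an if self.an else 0.0


@dataclass(frozen=True)
class PhasedGenotype:
    """One sample's diploid call at a site.

    ``hap0_allele``/``hap1_allele`` are 0 (REF) or 1 (ALT); ``phased`` is
    False for ``/``-separated or missing calls, which never become targets
    or anchors. ``pp`` is the phaser's confidence in [0.5, 1.0], or None
    when the field is absent.
    """

    sample_index: int
    site_index: int
    hap0_allele: int
    hap1_allele: int
    phased: bool
    pp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pp is not None and not (0.5 <= self.pp <= 1.0):
            raise ValueError(f"pp {self.pp} outside [0.5, 1.0]")

    @property
    def is_het(self) -> bool:
        return self.hap0_allele != self.hap1_allele


@dataclass(frozen=True)
class Anchor:
    """A confidently phased heterozygous neighbor of a target."""

    site_index: int
    hap0_allele: int
    hap1_allele: int
    orientation: Orientation

    def __post_init__(self) -> None:
        if self.hap0_allele == self.hap1_allele:
            raise ValueError("anchor must be heterozygous")


def relative_orientation(
    t_hap0: int, t_hap1: int, a_hap0: int, a_hap1: int
) -> Orientation:
    """Orientation of a target het relative to an anchor het.

    CIS iff the two ALT alleles are assigned to the same haplotype.
    """
    t_alt_hap = 0 if t_hap0 == 1 else 1
    a_alt_hap = 0 if a_hap0 == 1 else 1
    return Orientation.CIS if t_alt_hap == a_alt_hap else Orientation.TRANS


@dataclass
class TargetRecord:
    """A low-confidence het genotype plus its eligible anchor neighbors.

    Anchors are stored in ascending site order: up to the two nearest
    eligible het neighbors on each side of the target.
    """

    sample_index: int
    site_index: int
    hap0_allele: int
    hap1_allele: int
    pp: Optional[float]
    anchors: list[Anchor] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.hap0_allele == self.hap1_allele:
            raise ValueError("target must be heterozygous")
        if len(self.anchors) > 4:
            raise ValueError("at most 4 anchors per target")
        for a in self.anchors:
            if a.site_index == self.site_index:
                raise ValueError("anchor cannot be the target site itself")


@dataclass(frozen=True)
class ReadObservation:
    """Allele content of one accepted read pair at (target, anchor).

    Alleles are 0 (REF), 1 (ALT) or -1 ("other": base mismatching both
    alleles, base below quality floor, deletion/refskip). "Other" never
    counts as evidence.
    """

    pair_id: str
    target_allele: int
    anchor_site_index: int
    anchor_allele: int


@dataclass
class EvidenceSummary:
    """Read-pair counts for and against a target's stored orientation."""

    confirming: int = 0
    contradicting: int = 0
    per_anchor: dict[int, tuple[int, int]] = field(default_factory=dict)

    def add(self, anchor_site_index: int, confirms: bool) -> None:
        c, x = self.per_anchor.get(anchor_site_index, (0, 0))
        if confirms:
            self.confirming += 1
            self.per_anchor[anchor_site_index] = (c + 1, x)
        else:
            self.contradicting += 1
            self.per_anchor[anchor_site_index] = (c, x + 1)


@dataclass(frozen=True)
class PhaseDecision:
    """Outcome of read-backed phase checking for one target."""

    sample_index: int
    site_index: int
    outcome: Outcome
    supporting_reads: int
    confirming: int = 0
    contradicting: int = 0
    original_pp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.outcome is not Outcome.UNRESOLVED and self.supporting_reads < 1:
            raise ValueError("a resolved decision needs at least one supporting read")


def is_finite_prob(x: float) -> bool:
    return math.isfinite(x) and 0.0 <= x <= 1.0
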