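"""Phased-VCF streaming, the composite confidence encoding, and the target store.

The composite phase-confidence annotation written back to the PP FORMAT
field packs two numbers into one non-negative float::

    value = original_pp + confirming_reads + 1        (polished genotype)

so any value > 1.0 marks a genotype whose phase was checked against
sequencing reads: the fractional part is the original statistical
confidence and ``floor(value) - 1`` the number of read pairs supporting
the final phase. Values <= 1.0 are untouched original confidences.

Target store on-disk layout (``<prefix>.tgt``), all little-endian:

=====================  =======================================================
offset                 content
=====================  =======================================================
0                      magic ``b"PPTG"``
4                      version ``u16`` (currently 1)
6                      reserved ``u16``
8                      n_samples ``u32``
12                     sample table: n_samples x (record_count ``u32``,
                       byte offset ``u64``) — offsets from file start
12 + 12*n_samples      sample names: n_samples x (length ``u16``, utf-8 bytes)
...                    fixed-width 43-byte records, grouped by sample and
                       sorted by site_index within each sample
=====================  =======================================================

Record layout (43 bytes): site_index ``u32``, hap0 ``u8``, hap1 ``u8``,
pp ``f64`` (NaN = missing), n_anchors ``u8``, then four anchor slots of
(site_index ``u32``, hap0 ``u8``, hap1 ``u8``, orientation ``u8``; empty
slots carry orientation 0xFF). Splitting per-sample records from the
site-only variant file gives O(1) random access to any sample's targets.
"""

from __future__ import annotations

import math
import struct
import warnings
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pysam

from .records import (
    Anchor,
    Orientation,
    PhasedGenotype,
    SiteRecord,
    TargetRecord,
)

_MAGIC = b"PPTG"
_VERSION = 1
_HEADER = struct.Struct("<4sHHI")
_SAMPLE_ENTRY = struct.Struct("<IQ")
_REC_HEAD = struct.Struct("<IBBdB")
_REC_ANCHOR = struct.Struct("<IBBB")
_REC_SIZE = _REC_HEAD.size + 4 * _REC_ANCHOR.size
_NO_ANCHOR = 0xFF

PathLike = Union[str, Path]


@contextmanager
def quiet_htslib():
    """Mute htslib chatter (e.g. reserved-tag header warnings for PP)."""
    old = pysam.set_verbosity(0)
    try:
        yield
    finally:
        pysam.set_verbosity(old)


def open_variant_file(path: "PathLike", mode: str = "r", header=None) -> pysam.VariantFile:
    """Open a VCF/BCF with htslib warnings muted during header parsing."""
    with quiet_htslib():
        if header is not None:
            return pysam.VariantFile(str(path), mode, header=header)
        return pysam.VariantFile(str(path), mode)


class MultiallelicError(ValueError):
    """Raised on records with more than one ALT allele."""


# ---------------------------------------------------------------------------
# VCF streaming
# ---------------------------------------------------------------------------

def vcf_samples(vcf_path: PathLike) -> list[str]:
    with open_variant_file(vcf_path) as vf:
        return list(vf.header.samples)


def read_phased_sites(
    vcf_path: PathLike,
    region: Optional[str] = None,
) -> Iterator[tuple[SiteRecord, list[PhasedGenotype]]]:
    """Stream (site, per-sample genotypes) from a phased VCF/BCF.

    Yields biallelic records in coordinate order. Multiallelic records are
    rejected (input must be pre-split). Unphased or partially missing
    genotypes are yielded with ``phased=False`` so downstream stages can
    skip them. ``region`` uses samtools syntax, ``contig[:start-end]``
    with a 1-based inclusive range.
    """
    with open_variant_file(vcf_path) as vf:
        if "GT" not in vf.header.formats:
            raise ValueError(f"{vcf_path}: no GT FORMAT field in header")
        if region is not None:
            try:
                iterator = vf.fetch(region=region)
            except ValueError as exc:  # no index available: filter a full scan
                contig, span = _parse_region(region)
                iterator = (
                    rec
                    for rec in vf
                    if rec.chrom == contig
                    and (span is None or span[0] <= rec.pos <= span[1])
                )
                del exc
        else:
            iterator = iter(vf)

        site_index = 0
        last: tuple[str, int] | None = None
        for rec in iterator:
            if rec.alts is None or len(rec.alts) != 1:
                raise MultiallelicError(
                    f"{rec.chrom}:{rec.pos}: multiallelic input; split first "
                    "(e.g. bcftools norm -m -)"
                )
            if last is not None and last[0] == rec.chrom and rec.pos < last[1]:
                raise ValueError(f"{vcf_path}: unsorted input at {rec.chrom}:{rec.pos}")
            last = (rec.chrom, rec.pos)

            gts: list[PhasedGenotype] = []
            an = 0
            ac = 0
            for s_idx, sample in enumerate(rec.samples.values()):
                alleles = sample["GT"]
                pp = sample.get("PP")
                if pp is not None:
                    pp = float(pp)
                    # guard against float32 roundoff at the boundaries
                    pp = min(1.0, max(0.5, pp))
                if (
                    alleles is None
                    or len(alleles) != 2
                    or alleles[0] is None
                    or alleles[1] is None
                ):
                    gts.append(
                        PhasedGenotype(s_idx, site_index, 0, 0, phased=False, pp=pp)
                    )
                    continue
                a0, a1 = int(alleles[0]), int(alleles[1])
                an += 2
                ac += (a0 == 1) + (a1 == 1)
                gts.append(
                    PhasedGenotype(
                        s_idx, site_index, a0, a1, phased=bool(sample.phased), pp=pp
                    )
                )
            site = SiteRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alts[0],
                an=an,
                ac=ac,
                site_index=site_index,
            )
            yield site, gts
            site_index += 1


def _parse_region(region: str) -> tuple[str, Optional[tuple[int, int]]]:
    if ":" not in region:
        return region, None
    contig, span = region.rsplit(":", 1)
    beg, end = span.replace(",", "").split("-")
    return contig, (int(beg), int(end))


# ---------------------------------------------------------------------------
# Composite confidence encoding
# ---------------------------------------------------------------------------

PP_CEILING = 0.99  # genotypes at or above this confidence are never rephased


def encode_confidence(original_pp: float, confirming_reads: int) -> float:
    """Pack (original confidence, supporting read count) into one float.

    Only low-confidence genotypes (pp < 0.99) are ever polished, and a
    polished genotype has at least one supporting read, so the encoded
    value is always > 1.0 and the fractional part stays in [0.5, 0.99).
    """
    if not (0.5 <= original_pp < PP_CEILING):
        raise ValueError(
            f"refusing to encode pp={original_pp!r}: only genotypes with "
            f"confidence in [0.5, {PP_CEILING}) are polished"
        )
    if confirming_reads < 1:
        raise ValueError("a polished genotype needs >= 1 confirming read")
    return round(original_pp, 6) + confirming_reads + 1


def decode_confidence(value: float) -> tuple[float, int, bool]:
    """Inverse of :func:`encode_confidence`.

    Returns ``(original_pp, confirming_reads, polished)``. Values <= 1.0
    are unpolished confidences and pass through with a zero read count.
    """
    if value < 0 or not math.isfinite(value):
        raise ValueError(f"invalid confidence value {value!r}")
    if value <= 1.0:
        return float(value), 0, False
    whole = math.floor(value)
    frac = round(value - whole, 6)
    if not (0.5 <= frac < PP_CEILING):
        warnings.warn(
            f"polished confidence {value} has fractional part {frac} outside "
            f"[0.5, {PP_CEILING}); decoding best-effort",
            stacklevel=2,
        )
    return frac, whole - 1, True


def mac_threshold(maf: float, n_samples: int) -> int:
    """Translate a MAF cutoff into a minor-allele-count cutoff.

    Assumes complete diploid calls (AN = 2 * n_samples) and floors the
    product, e.g. MAF 0.001 in a 147,754-sample cohort corresponds to
    MAC 295.
    """
    if not (0.0 <= maf <= 0.5):
        raise ValueError("maf must be in [0, 0.5]")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    # small epsilon so decimal-intent products (e.g. 0.3 * 10) floor as written
    return int(math.floor(2 * n_samples * maf + 1e-9))


# ---------------------------------------------------------------------------
# Target store
# ---------------------------------------------------------------------------

@dataclass
class TargetStore:
    """Per-sample target records plus the site list they reference.

    ``records_by_sample`` maps sample_index -> records sorted by
    site_index; ``sites`` is the full coordinate-ordered site list of the
    extracted stream (``site_index`` indexes into it).
    """

    sites: list[SiteRecord]
    sample_names: list[str]
    records_by_sample: dict[int, list[TargetRecord]]

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    @property
    def n_targets(self) -> int:
        return sum(len(v) for v in self.records_by_sample.values())

    def records(self, sample: Optional[int] = None) -> list[TargetRecord]:
        if sample is not None:
            return list(self.records_by_sample.get(sample, []))
        out: list[TargetRecord] = []
        for s in sorted(self.records_by_sample):
            out.extend(self.records_by_sample[s])
        return out

    def validate(self) -> None:
        n_sites = len(self.sites)
        for s, recs in self.records_by_sample.items():
            if not (0 <= s < self.n_samples):
                raise ValueError(f"sample index {s} outside sample table")
            prev = -1
            for r in recs:
                if not (0 <= r.site_index < n_sites):
                    raise ValueError(f"record references unknown site {r.site_index}")
                if r.site_index <= prev:
                    raise ValueError("records not sorted by site_index")
                prev = r.site_index
                for a in r.anchors:
                    if not (0 <= a.site_index < n_sites):
                        raise ValueError(
                            f"anchor references unknown site {a.site_index}"
                        )

    # -- persistence --------------------------------------------------------

    def save(self, prefix: PathLike) -> tuple[Path, Path]:
        """Write ``<prefix>.tgt`` and the site-only ``<prefix>.sites.bcf``."""
        self.validate()
        prefix = Path(prefix)
        tgt = prefix.with_suffix(prefix.suffix + ".tgt") if prefix.suffix else Path(
            str(prefix) + ".tgt"
        )
        sites_path = Path(str(prefix) + ".sites.bcf")
        write_target_records(tgt, self.sample_names, self.records_by_sample)
        write_site_list(sites_path, self.sites)
        return tgt, sites_path

    @classmethod
    def load(cls, prefix: PathLike, sample: Optional[int] = None) -> "TargetStore":
        prefix = Path(prefix)
        tgt = Path(str(prefix) + ".tgt")
        sites_path = Path(str(prefix) + ".sites.bcf")
        names, by_sample = read_target_records(tgt, sample=sample)
        sites = read_site_list(sites_path)
        return cls(sites=sites, sample_names=names, records_by_sample=by_sample)


def _pack_record(rec: TargetRecord) -> bytes:
    pp = float("nan") if rec.pp is None else float(rec.pp)
    out = [_REC_HEAD.pack(rec.site_index, rec.hap0_allele, rec.hap1_allele, pp,
                          len(rec.anchors))]
    for i in range(4):
        if i < len(rec.anchors):
            a = rec.anchors[i]
            out.append(
                _REC_ANCHOR.pack(
                    a.site_index, a.hap0_allele, a.hap1_allele, a.orientation.value
                )
            )
        else:
            out.append(_REC_ANCHOR.pack(0, 0, 0, _NO_ANCHOR))
    return b"".join(out)


def _unpack_record(sample_index: int, buf: bytes) -> TargetRecord:
    site_index, h0, h1, pp, n_anchors = _REC_HEAD.unpack_from(buf, 0)
    anchors: list[Anchor] = []
    off = _REC_HEAD.size
    for i in range(4):
        a_site, a0, a1, orient = _REC_ANCHOR.unpack_from(buf, off)
        off += _REC_ANCHOR.size
        if i < n_anchors:
            if orient == _NO_ANCHOR:
                raise ValueError("anchor count disagrees with anchor slots")
            anchors.append(Anchor(a_site, a0, a1, Orientation(orient)))
    return TargetRecord(
        sample_index=sample_index,
        site_index=site_index,
        hap0_allele=h0,
        hap1_allele=h1,
        pp=None if math.isnan(pp) else pp,
        anchors=anchors,
    )


def write_target_records(
    path: PathLike,
    sample_names: Sequence[str],
    records_by_sample: dict[int, list[TargetRecord]],
) -> None:
    n = len(sample_names)
    name_blobs = [s.encode() for s in sample_names]
    names_size = sum(2 + len(b) for b in name_blobs)
    data_start = _HEADER.size + n * _SAMPLE_ENTRY.size + names_size

    counts = [len(records_by_sample.get(s, [])) for s in range(n)]
    offsets = []
    off = data_start
    for c in counts:
        offsets.append(off)
        off += c * _REC_SIZE

    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(_MAGIC, _VERSION, 0, n))
        for c, o in zip(counts, offsets):
            fh.write(_SAMPLE_ENTRY.pack(c, o))
        for b in name_blobs:
            fh.write(struct.pack("<H", len(b)))
            fh.write(b)
        for s in range(n):
            for rec in records_by_sample.get(s, []):
                fh.write(_pack_record(rec))


def read_target_records(
    path: PathLike, sample: Optional[int] = None
) -> tuple[list[str], dict[int, list[TargetRecord]]]:
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
        if len(head) < _HEADER.size:
            raise ValueError(f"{path}: truncated header at offset {len(head)}")
        magic, version, _, n = _HEADER.unpack(head)
        if magic != _MAGIC:
            raise ValueError(f"{path}: bad magic {magic!r}")
        if version != _VERSION:
            raise ValueError(f"{path}: unsupported version {version}")
        table = []
        for _ in range(n):
            buf = fh.read(_SAMPLE_ENTRY.size)
            if len(buf) < _SAMPLE_ENTRY.size:
                raise ValueError(f"{path}: truncated sample table at offset {fh.tell()}")
            table.append(_SAMPLE_ENTRY.unpack(buf))
        names = []
        for _ in range(n):
            lb = fh.read(2)
            if len(lb) < 2:
                raise ValueError(f"{path}: truncated name table at offset {fh.tell()}")
            (ln,) = struct.unpack("<H", lb)
            nb = fh.read(ln)
            if len(nb) < ln:
                raise ValueError(f"{path}: truncated name table at offset {fh.tell()}")
            names.append(nb.decode())

        wanted = range(n) if sample is None else [sample]
        by_sample: dict[int, list[TargetRecord]] = {}
        for s in wanted:
            if not (0 <= s < n):
                raise ValueError(f"sample index {s} not in store (n={n})")
            count, offset = table[s]
            if count == 0:
                continue
            fh.seek(offset)
            blob = fh.read(count * _REC_SIZE)
            if len(blob) < count * _REC_SIZE:
                raise ValueError(
                    f"{path}: truncated records for sample {s} at offset "
                    f"{offset + len(blob)}"
                )
            by_sample[s] = [
                _unpack_record(s, blob[i * _REC_SIZE : (i + 1) * _REC_SIZE])
                for i in range(count)
            ]
    return names, by_sample


# ---------------------------------------------------------------------------
# Site-only variant file
# ---------------------------------------------------------------------------

def write_site_list(path: PathLike, sites: Iterable[SiteRecord]) -> None:
    """Write a sample-free BCF holding the extracted loci, in order."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AC,Number=A,Type=Integer,Description="ALT allele count">')
    header.add_line('##INFO=<ID=AN,Number=1,Type=Integer,Description="Called alleles">')
    header.add_line(
        '##INFO=<ID=SIDX,Number=1,Type=Integer,Description="Ordinal in source stream">'
    )
    sites = list(sites)
    for contig in dict.fromkeys(s.chrom for s in sites):
        header.contigs.add(contig)
    mode = "wb" if str(path).endswith(".bcf") else "w"
    with open_variant_file(path, mode, header=header) as out:
        for s in sites:
            rec = out.new_record(
                contig=s.chrom, start=s.pos - 1, alleles=(s.ref, s.alt)
            )
            rec.info["AC"] = (s.ac,)
            rec.info["AN"] = s.an
            rec.info["SIDX"] = s.site_index
            out.write(rec)


def read_site_list(path: PathLike) -> list[SiteRecord]:
    sites: list[SiteRecord] = []
    with open_variant_file(path) as vf:
        for rec in vf:
            ac = rec.info["AC"]
            sites.append(
                SiteRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    an=int(rec.info["AN"]),
                    ac=int(ac[0] if isinstance(ac, tuple) else ac),
                    site_index=int(rec.info["SIDX"]),
                )
            )
    return sites
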