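"""Benchmarking of phased call sets against a known truth.

The switch error rate (SER) is the fraction of successive heterozygous
genotype pairs of a sample whose relative orientation disagrees with the
truth — a definition invariant under whole-sample relabeling of either
input's haplotypes. Errors are stratified by minor allele count, each
pair attributed to the bin of its rarer variant, so flip errors at rare
hets land in the rare bins. The rephased-subset SER restricts the
attributed variant to targets that carry a read-backed decision, and the
calibration table bins decided targets by their original confidence
score to measure how often the statistical phaser's call survived read
checking.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import Outcome, PhaseDecision, SiteRecord
from .variant_io import PathLike, TargetStore, read_phased_sites

DEFAULT_MAC_EDGES: tuple[int, ...] = (1, 2, 6, 11, 21, 51, 101, 201)
DEFAULT_PP_EDGES: tuple[float, ...] = (0.5, 0.625, 0.75, 0.875, 0.99)


def mac_bin_labels(edges: Sequence[int]) -> list[str]:
    labels = []
    for i, lo in enumerate(edges):
        hi = edges[i + 1] - 1 if i + 1 < len(edges) else None
        if hi is None:
            labels.append(f"{lo}+")
        elif hi == lo:
            labels.append(f"{lo}")
        else:
            labels.append(f"{lo}-{hi}")
    return labels


def mac_bin_index(mac: np.ndarray, edges: Sequence[int]) -> np.ndarray:
    return np.searchsorted(np.asarray(edges), mac, side="right") - 1


def load_phase_matrix(
    vcf_path: PathLike,
) -> tuple[list[SiteRecord], np.ndarray, np.ndarray, np.ndarray]:
    """Load a phased VCF into (sites, hap0, hap1, pp) dense matrices."""
    sites: list[SiteRecord] = []
    h0_rows, h1_rows, pp_rows = [], [], []
    for site, gts in read_phased_sites(vcf_path):
        sites.append(site)
        h0_rows.append([g.hap0_allele for g in gts])
        h1_rows.append([g.hap1_allele for g in gts])
        pp_rows.append([np.nan if g.pp is None else g.pp for g in gts])
    h0 = np.array(h0_rows, dtype=np.uint8).T
    h1 = np.array(h1_rows, dtype=np.uint8).T
    pp = np.array(pp_rows, dtype=float).T
    return sites, h0, h1, pp


def _pair_table(
    est_h0: np.ndarray,
    est_h1: np.ndarray,
    true_h0: np.ndarray,
    true_h1: np.ndarray,
    macs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Enumerate successive-het pairs for every sample.

    Returns arrays (sample, left site, right site, attributed-mac,
    discordant) over all pairs. The phase bit of a het is the allele on
    haplotype 0; a pair is discordant iff the XOR of its two phase bits
    differs between estimate and truth (label-invariant).
    """
    n, m = est_h0.shape
    het_est = est_h0 != est_h1
    het_true = true_h0 != true_h1
    het = het_est & het_true
    samples, lefts, rights, pair_mac, disc = [], [], [], [], []
    for s in range(n):
        idx = np.flatnonzero(het[s])
        if idx.size < 2:
            continue
        a, b = idx[:-1], idx[1:]
        rel_est = est_h0[s, a] ^ est_h0[s, b]
        rel_true = true_h0[s, a] ^ true_h0[s, b]
        samples.append(np.full(a.size, s))
        lefts.append(a)
        rights.append(b)
        pair_mac.append(np.minimum(macs[a], macs[b]))
        disc.append(rel_est != rel_true)
    if not samples:
        z = np.array([], dtype=int)
        return z, z, z, z, z.astype(bool)
    return (
        np.concatenate(samples),
        np.concatenate(lefts),
        np.concatenate(rights),
        np.concatenate(pair_mac),
        np.concatenate(disc),
    )


def switch_error_rate(
    est_h0: np.ndarray,
    est_h1: np.ndarray,
    true_h0: np.ndarray,
    true_h1: np.ndarray,
    macs: np.ndarray,
    edges: Sequence[int] = DEFAULT_MAC_EDGES,
) -> pd.DataFrame:
    """SER per MAC bin plus an overall row.

    Inputs are (n_samples, n_sites) haplotype-allele matrices for the
    estimate and the truth over the same sites, and the per-site minor
    allele counts used for binning.
    """
    _, _, _, pair_mac, disc = _pair_table(est_h0, est_h1, true_h0, true_h1, macs)
    bins = mac_bin_index(pair_mac, edges)
    rows = []
    for b, label in enumerate(mac_bin_labels(edges)):
        sel = bins == b
        n_pairs = int(sel.sum())
        n_disc = int(disc[sel].sum())
        rows.append(
            {
                "mac_bin": label,
                "evaluated_pairs": n_pairs,
                "discordant_pairs": n_disc,
                "ser": n_disc / n_pairs if n_pairs else np.nan,
            }
        )
    rows.append(
        {
            "mac_bin": "overall",
            "evaluated_pairs": int(disc.size),
            "discordant_pairs": int(disc.sum()),
            "ser": float(disc.mean()) if disc.size else np.nan,
        }
    )
    return pd.DataFrame(rows)


def rephased_subset_ser(
    est_h0: np.ndarray,
    est_h1: np.ndarray,
    true_h0: np.ndarray,
    true_h1: np.ndarray,
    macs: np.ndarray,
    decisions: Iterable[PhaseDecision],
    targets: Optional[set[tuple[int, int]]] = None,
) -> tuple[int, int, Optional[float]]:
    """SER over pairs attributed to read-decided targets only.

    A pair enters the subset iff its attributed variant (the rarer of
    the two; MAC ties go left) carries a validated or switched decision
    for that sample, and the pair involves no *unchecked* suspect: when
    ``targets`` is given, pairs touching a target without a decision are
    excluded, since such a pair measures the unchecked genotype rather
    than the read-polished one. Returns (evaluated, discordant, SER or
    None when the subset is empty).
    """
    decisions = list(decisions)
    decided = {
        (d.sample_index, d.site_index)
        for d in decisions
        if d.outcome in (Outcome.VALIDATED, Outcome.SWITCHED)
    }
    if targets is None:
        targets = {(d.sample_index, d.site_index) for d in decisions}
    samples, lefts, rights, _, disc = _pair_table(
        est_h0, est_h1, true_h0, true_h1, macs
    )
    n_eval = 0
    n_disc = 0
    for s, a, b, d in zip(samples, lefts, rights, disc):
        ka, kb = (int(s), int(a)), (int(s), int(b))
        if (ka in targets and ka not in decided) or (
            kb in targets and kb not in decided
        ):
            continue
        attributed = ka if macs[a] <= macs[b] else kb
        if attributed in decided:
            n_eval += 1
            n_disc += int(d)
    return n_eval, n_disc, (n_disc / n_eval if n_eval else None)


def linkage_stats(
    store: TargetStore,
    decisions: Iterable[PhaseDecision],
    edges: Sequence[int] = DEFAULT_MAC_EDGES,
) -> pd.DataFrame:
    """Per MAC bin: targets, linked fraction, switched fraction among linked.

    A target is *linked* when at least one accepted read pair connected
    it to an anchor, i.e. its decision is not unresolved.
    """
    by_key = {(d.sample_index, d.site_index): d for d in decisions}
    labels = mac_bin_labels(edges)
    counts = {k: [0, 0, 0] for k in labels + ["overall"]}  # targets, linked, switched
    for rec in store.records():
        site = store.sites[rec.site_index]
        label = labels[int(mac_bin_index(np.array([site.mac]), edges)[0])]
        d = by_key.get((rec.sample_index, rec.site_index))
        linked = d is not None and d.outcome is not Outcome.UNRESOLVED
        switched = d is not None and d.outcome is Outcome.SWITCHED
        for k in (label, "overall"):
            counts[k][0] += 1
            counts[k][1] += int(linked)
            counts[k][2] += int(switched)
    rows = []
    for label in labels + ["overall"]:
        t, l, sw = counts[label]
        rows.append(
            {
                "mac_bin": label,
                "targets": t,
                "linked": l,
                "linked_fraction": l / t if t else np.nan,
                "switched": sw,
                "switched_fraction_of_linked": sw / l if l else np.nan,
            }
        )
    return pd.DataFrame(rows)


def calibration_table(
    decisions: Iterable[PhaseDecision],
    edges: Sequence[float] = DEFAULT_PP_EDGES,
) -> pd.DataFrame:
    """Validated/switched counts per original-confidence bin.

    Only decided targets that carry an original confidence enter; the
    switched fraction per bin is the read-measured error rate of the
    statistical phaser at that confidence level.
    """
    edges = list(edges)
    labels = [f"[{edges[i]:.2f},{edges[i+1]:.2f})" for i in range(len(edges) - 1)]
    val = np.zeros(len(labels), dtype=int)
    sw = np.zeros(len(labels), dtype=int)
    for d in decisions:
        if d.outcome is Outcome.UNRESOLVED or d.original_pp is None:
            continue
        b = int(np.searchsorted(edges, d.original_pp, side="right")) - 1
        if not (0 <= b < len(labels)):
            continue
        if d.outcome is Outcome.SWITCHED:
            sw[b] += 1
        else:
            val[b] += 1
    total = val + sw
    frac = np.divide(sw, total, out=np.full(len(labels), np.nan), where=total > 0)
    df = pd.DataFrame(
        {
            "pp_bin": labels,
            "validated": val,
            "switched": sw,
            "switched_fraction": frac,
        }
    )
    nonempty = df.loc[total > 0, "switched_fraction"].to_numpy()
    df.attrs["monotone_decreasing"] = bool(
        np.all(np.diff(nonempty) <= 1e-12) if nonempty.size > 1 else True
    )
    return df
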