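"""Pooled low-coverage whole-genome-sequencing analysis.

Three stages over per-site pooled allele counts from two DNA pools
(pool A = strain-A-like, pool B = strain-B-like):

* **support classification** — does the pooled sequencing confirm a reported
  strain-distinguishing SNP?  A site is evaluated only when covered in both
  pools and each pool is internally homozygous (a pool with more than one
  read showing both alleles is ambiguous); it is *supported* when the two
  pools' consensus alleles differ.
* **novel-SNP hard-filter cascade** — six filters applied to candidate sites:
  at least two alternate-allele reads, site quality > 30, mapping quality
  > 40, combined depth > 4 and < 80, not in repeat-masked sequence, and not
  in a dense local cluster (> 3 candidates in any 10-bp window removes all
  sites in the window).  Every filter is evaluated for every site; a verdict
  lists every failure.
* **window scans** — 10-Mb sliding-window pooled strain-allele fractions
  (the bulk-segregant enrichment scan) and 200-kb SNP-density tilings.

Coordinates: variant sites are 1-based (VCF convention); windows and repeat
masks are 0-based half-open (BED convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sim import PileupSummary, VariantSite

# ---------------------------------------------------------------------------
# Support classification of reported strain SNPs
# ---------------------------------------------------------------------------

SUPPORTED = "supported"
NOT_SUPPORTED = "not_supported"
NOT_COVERED = "not_covered"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SupportCall:
    chrom: str
    pos: int
    call: str  # {supported, not_supported, not_covered, ambiguous}
    reason: str


def _pool_consensus(ref_reads: int, alt_reads: int) -> str | None:
    """Consensus allele of one pool, or None if the pool is not homozygous.

    A single read is its own consensus; with two or more reads the pool must
    be unanimous.
    """
    if ref_reads > 0 and alt_reads > 0:
        return None
    return "ref" if ref_reads > 0 else "alt"


def classify_support(pileup: PileupSummary) -> SupportCall:
    """Classify whether pooled sequencing supports a strain-distinguishing SNP."""
    if pileup.depth_a == 0 or pileup.depth_b == 0:
        return SupportCall(pileup.chrom, pileup.pos, NOT_COVERED,
                           "no reads in at least one pool")
    cons_a = _pool_consensus(pileup.a_ref, pileup.a_alt)
    cons_b = _pool_consensus(pileup.b_ref, pileup.b_alt)
    if cons_a is None or cons_b is None:
        return SupportCall(pileup.chrom, pileup.pos, AMBIGUOUS,
                           "both alleles observed within one pool (non-homozygous)")
    if cons_a != cons_b:
        return SupportCall(pileup.chrom, pileup.pos, SUPPORTED,
                           f"pool consensus alleles differ (A={cons_a}, B={cons_b})")
    return SupportCall(pileup.chrom, pileup.pos, NOT_SUPPORTED,
                       f"pool consensus alleles agree ({cons_a})")


def classify_support_table(pileups: pd.DataFrame) -> pd.DataFrame:
    """Vectorised support classification of a pileup table.

    Expects columns chrom, pos, a_ref, a_alt, b_ref, b_alt; returns the table
    with a ``call`` column added.
    """
    da = pileups["a_ref"].to_numpy() + pileups["a_alt"].to_numpy()
    db = pileups["b_ref"].to_numpy() + pileups["b_alt"].to_numpy()
    mixed_a = (pileups["a_ref"].to_numpy() > 0) & (pileups["a_alt"].to_numpy() > 0)
    mixed_b = (pileups["b_ref"].to_numpy() > 0) & (pileups["b_alt"].to_numpy() > 0)
    cons_a_alt = pileups["a_alt"].to_numpy() > 0  # valid where not mixed
    cons_b_alt = pileups["b_alt"].to_numpy() > 0
    call = np.where(
        (da == 0) | (db == 0), NOT_COVERED,
        np.where(mixed_a | mixed_b, AMBIGUOUS,
                 np.where(cons_a_alt != cons_b_alt, SUPPORTED, NOT_SUPPORTED)))
    out = pileups.copy()
    out["call"] = call
    return out


@dataclass
class SupportSummary:
    n_sites: int
    n_covered: int
    n_supported: int
    n_not_supported: int
    n_ambiguous: int
    covered_fraction: float
    confirmation_rate: float | None  # supported / (supported + not_supported)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def support_summary(calls: Iterable[SupportCall] | pd.DataFrame) -> SupportSummary:
    """Coverage and confirmation rates over a set of support calls.

    Coverage counts sites with at least one read in both pools; the
    confirmation rate is computed among covered, unambiguous sites only.
    """
    if isinstance(calls, pd.DataFrame):
        labels = calls["call"].to_numpy()
    else:
        labels = np.array([c.call for c in calls])
    if labels.size == 0:
        raise ValueError("no support calls to summarise")
    n = labels.size
    n_nc = int((labels == NOT_COVERED).sum())
    n_sup = int((labels == SUPPORTED).sum())
    n_not = int((labels == NOT_SUPPORTED).sum())
    n_amb = int((labels == AMBIGUOUS).sum())
    evaluable = n_sup + n_not
    return SupportSummary(
        n_sites=n, n_covered=n - n_nc, n_supported=n_sup, n_not_supported=n_not,
        n_ambiguous=n_amb, covered_fraction=(n - n_nc) / n,
        confirmation_rate=(n_sup / evaluable) if evaluable else None,
    )


# ---------------------------------------------------------------------------
# Novel-SNP hard-filter cascade
# ---------------------------------------------------------------------------

FILTER_CODES = ["min_alt_reads", "site_quality", "mapping_quality",
                "depth_range", "repeat_mask", "snp_cluster"]

MIN_ALT_READS = 2
MIN_SITE_QUALITY = 30.0   # strict: qual must exceed this
MIN_MAPPING_QUALITY = 40.0
DEPTH_MIN_EXCLUSIVE = 4   # combined depth must exceed this ...
DEPTH_MAX_EXCLUSIVE = 80  # ... and stay below this
CLUSTER_WINDOW_BP = 10
CLUSTER_MAX_SNPS = 3      # more than this many candidates in a window fails


@dataclass(frozen=True)
class FilterVerdict:
    chrom: str
    pos: int
    passed: bool
    failed_filters: tuple[str, ...]


class RepeatMask:
    """Merged 0-based half-open intervals per chromosome with point queries."""

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in (intervals or {}).items():
            if not ivs:
                continue
            arr = sorted((int(s), int(e)) for s, e in ivs)
            merged: list[list[int]] = []
            for s, e in arr:
                if e <= s:
                    raise ValueError(f"{chrom}: empty/inverted interval [{s}, {e})")
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged])
            self._ends[chrom] = np.array([m[1] for m in merged])

    def contains(self, chrom: str, pos_1based: int | np.ndarray) -> bool | np.ndarray:
        """Membership of 1-based site positions (converted to 0-based internally)."""
        p0 = np.asarray(pos_1based) - 1
        if chrom not in self._starts:
            res = np.zeros(p0.shape, dtype=bool)
        else:
            i = np.searchsorted(self._starts[chrom], p0, side="right") - 1
            res = (i >= 0) & (p0 < self._ends[chrom][np.maximum(i, 0)])
        return bool(res) if np.ndim(pos_1based) == 0 else res


def _cluster_flags(positions: np.ndarray) -> np.ndarray:
    """Flag candidates lying in any 10-bp window holding > 3 candidates.

    Positions must be sorted.  The window slides over base pairs, so four
    candidates spanning <= 9 bp constitute a violation; every candidate in
    the offending span is removed.
    """
    n = len(positions)
    flags = np.zeros(n, dtype=bool)
    k = CLUSTER_MAX_SNPS  # a run of k+1 candidates within the window trips the filter
    for i in range(n - k):
        if positions[i + k] - positions[i] <= CLUSTER_WINDOW_BP - 1:
            flags[i:i + k + 1] = True
    return flags


def novel_snp_filter(candidates: Sequence[tuple[VariantSite, PileupSummary]],
                     repeat_mask: RepeatMask | None = None) -> list[FilterVerdict]:
    """Apply the six-filter hard cascade to candidate novel SNPs.

    ``candidates`` must be sorted by (chrom, pos).  All filters are evaluated
    for every site (no short-circuiting) and each verdict lists every failed
    filter in cascade order.
    """
    keys = [(s.chrom, s.pos) for s, _ in candidates]
    if keys != sorted(keys):
        raise ValueError("candidates must be sorted by (chrom, pos)")
    repeat_mask = repeat_mask or RepeatMask()

    # cluster filter is a pure function of candidate positions, per chromosome
    cluster = np.zeros(len(candidates), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for i, (site, _) in enumerate(candidates):
        by_chrom.setdefault(site.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        pos = np.array([candidates[i][0].pos for i in idx])
        cluster[np.array(idx)] = _cluster_flags(pos)

    verdicts: list[FilterVerdict] = []
    for i, (site, pile) in enumerate(candidates):
        failed: list[str] = []
        if pile.a_alt + pile.b_alt < MIN_ALT_READS:
            failed.append("min_alt_reads")
        if not (pile.site_quality > MIN_SITE_QUALITY):
            failed.append("site_quality")
        if not (pile.mapping_quality > MIN_MAPPING_QUALITY):
            failed.append("mapping_quality")
        depth = pile.depth_a + pile.depth_b
        if not (DEPTH_MIN_EXCLUSIVE < depth < DEPTH_MAX_EXCLUSIVE):
            failed.append("depth_range")
        if site.in_repeat or repeat_mask.contains(site.chrom, site.pos):
            failed.append("repeat_mask")
        if cluster[i]:
            failed.append("snp_cluster")
        verdicts.append(FilterVerdict(site.chrom, site.pos, not failed, tuple(failed)))
    return verdicts


# ---------------------------------------------------------------------------
# Window scans
# ---------------------------------------------------------------------------

WINDOW_BP_DEFAULT = 10_000_000
STEP_BP_DEFAULT = 1_000_000
LOW_DENSITY_MAX_SNPS = 4
DENSITY_WINDOW_BP_DEFAULT = 200_000


def window_allele_scan(counts: pd.DataFrame, chrom_lengths: Mapping[str, int],
                       window_bp: int = WINDOW_BP_DEFAULT,
                       step_bp: int = STEP_BP_DEFAULT) -> pd.DataFrame:
    """Sliding-window pooled strain-allele fractions.

    ``counts`` has one row per strain-informative site with columns
    chrom, pos (1-based), a_reads (reads carrying the strain-A allele) and
    b_reads.  Windows tile each chromosome from 0 with the given step; the
    last window is truncated at the chromosome end.  A window's fraction is
    strain-A reads over all informative reads, reported as missing (NaN) when
    the window holds no informative reads; ``low_density`` flags windows with
    at most four sites.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    key = counts["chrom"].astype(str)
    rows: list[pd.DataFrame] = []
    for chrom, clen in chrom_lengths.items():
        sub = counts[key == chrom]
        pos0 = sub["pos"].to_numpy() - 1  # to 0-based for half-open windows
        order = np.argsort(pos0, kind="mergesort")
        pos0 = pos0[order]
        a = sub["a_reads"].to_numpy()[order].astype(np.int64)
        b = sub["b_reads"].to_numpy()[order].astype(np.int64)
        ca = np.concatenate([[0], np.cumsum(a)])
        cb = np.concatenate([[0], np.cumsum(b)])
        starts = np.arange(0, clen, step_bp)
        ends = np.minimum(starts + window_bp, clen)
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, ends, side="left")
        n_snps = hi - lo
        wa = ca[hi] - ca[lo]
        wb = cb[hi] - cb[lo]
        denom = wa + wb
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(denom > 0, wa / np.maximum(denom, 1), np.nan)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "n_snps": n_snps, "strainA_reads": wa, "strainB_reads": wb,
            "strainA_fraction": frac,
            "low_density": n_snps <= LOW_DENSITY_MAX_SNPS,
        }))
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "end", "n_snps", "strainA_reads",
                 "strainB_reads", "strainA_fraction", "low_density"])
    out.attrs["window_bp"] = window_bp
    out.attrs["step_bp"] = step_bp
    return out


def window_fraction_ci(windows: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Wilson binomial confidence intervals for window strain-A fractions.

    Treats each informative read as an independent strain-allele draw; no
    significance calls are made — enrichment judgements are left to the user.
    """
    from scipy import stats as _stats
    z = float(_stats.norm.ppf(0.5 + level / 2.0))
    n = (windows["strainA_reads"] + windows["strainB_reads"]).to_numpy().astype(float)
    k = windows["strainA_reads"].to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        phat = np.where(n > 0, k / np.maximum(n, 1), np.nan)
        denom = 1 + z ** 2 / n
        centre = (phat + z ** 2 / (2 * n)) / denom
        half = z * np.sqrt(phat * (1 - phat) / n + z ** 2 / (4 * n ** 2)) / denom
    out = windows.copy()
    out["ci_low"] = np.where(n > 0, np.clip(centre - half, 0, 1), np.nan)
    out["ci_high"] = np.where(n > 0, np.clip(centre + half, 0, 1), np.nan)
    return out


def top_window(windows: pd.DataFrame) -> pd.Series:
    """The window with the genome-wide maximum strain-A fraction (ties: most
    informative reads, then first genome position)."""
    w = windows.dropna(subset=["strainA_fraction"])
    if w.empty:
        raise ValueError("no window has informative reads")
    w = w.sort_values(["strainA_fraction", "strainA_reads"],
                      ascending=[False, False], kind="mergesort")
    return w.iloc[0]


def snp_density_profile(sites: Sequence[VariantSite] | pd.DataFrame,
                        chrom_lengths: Mapping[str, int],
                        window_bp: int = DENSITY_WINDOW_BP_DEFAULT) -> pd.DataFrame:
    """Non-overlapping SNP-density tiling (default 200 kb) per chromosome.

    Returns one row per tile with the SNP count and a presence flag ("window
    contains at least one SNP").  The fraction of non-overlapping 10-Mb tiles
    holding at most four SNPs — the low-density share of the genome — is
    reported in ``df.attrs['low_density_fraction_10mb']``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if isinstance(sites, pd.DataFrame):
        chroms = sites["chrom"].to_numpy()
        pos = sites["pos"].to_numpy()
    else:
        chroms = np.array([s.chrom for s in sites])
        pos = np.array([s.pos for s in sites], dtype=int)
    rows: list[pd.DataFrame] = []
    low_counts: list[int] = []
    low_total = 0
    for chrom, clen in chrom_lengths.items():
        p0 = np.sort(pos[chroms == chrom]) - 1
        starts = np.arange(0, clen, window_bp)
        ends = np.minimum(starts + window_bp, clen)
        n = np.searchsorted(p0, ends, side="left") - np.searchsorted(p0, starts, side="left")
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "n_snps": n, "has_snp": n > 0,
        }))
        big_starts = np.arange(0, clen, WINDOW_BP_DEFAULT)
        big_ends = np.minimum(big_starts + WINDOW_BP_DEFAULT, clen)
        nb = (np.searchsorted(p0, big_ends, side="left")
              - np.searchsorted(p0, big_starts, side="left"))
        low_counts.append(int((nb <= LOW_DENSITY_MAX_SNPS).sum()))
        low_total += len(big_starts)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "end", "n_snps", "has_snp"])
    out.attrs["window_bp"] = window_bp
    out.attrs["low_density_fraction_10mb"] = (sum(low_counts) / low_total) if low_total else np.nan
    return out
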