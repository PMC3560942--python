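"""File formats, run configuration and the pipeline orchestrator.

Tabular interchange formats (UTF-8, headers mandatory, '.' decimal):

* marker map TSV — ``id, chrom, pos_bp, pos_cM, kind, alleleA, alleleB``
* genotype CSV — rows = individuals (first column ``id``), columns = marker
  ids, values in {0, 1, 2, -9}
* phenotype CSV — ``id, phenotype, scoring_age`` with phenotype in
  {affected, unaffected, unscored}
* pileup TSV — ``chrom, pos, ref, alt, poolA_ref, poolA_alt, poolB_ref,
  poolB_alt, qual, mq``
* variant sites — VCF 4.x (1-based POS; ``STATUS`` and ``REPEAT`` INFO
  fields; FILTER column populated from hard-filter reason codes)
* repeat masks / windows — BED (0-based half-open)

All writers and readers satisfy round-trip identity; schema violations raise
errors naming the file and the offending row/column.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from ._version import __version__
from .sim import (AFFECTED, GENO_MISSING, PHENOTYPE_CODES, PHENOTYPE_LABELS, UNSCORED,
                  Cohort, CrossDesign, GeneticMap, Marker, PenetranceModel, PileupSummary,
                  PoolSpec, VariantSite, apply_penetrance, default_marker_set,
                  default_mouse_map, simulate_cross, simulate_pileups, sites_from_markers,
                  substream)
from .segscan import ScanConfig, genome_scan
from .poolscan import (FILTER_CODES, FilterVerdict, RepeatMask, classify_support_table,
                       novel_snp_filter, snp_density_profile, support_summary,
                       window_allele_scan)

# ---------------------------------------------------------------------------
# Marker maps
# ---------------------------------------------------------------------------

MAP_COLUMNS = ["id", "chrom", "pos_bp", "pos_cM", "kind", "alleleA", "alleleB"]


def write_marker_map(markers: Sequence[Marker], path: str | Path) -> None:
    pd.DataFrame({
        "id": [m.id for m in markers],
        "chrom": [m.chrom for m in markers],
        "pos_bp": [m.pos_bp for m in markers],
        "pos_cM": [m.pos_cM for m in markers],
        "kind": [m.kind for m in markers],
        "alleleA": [m.alleles[0] for m in markers],
        "alleleB": [m.alleles[1] for m in markers],
    }).to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path) -> list[Marker]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: marker map is missing column(s) {missing}")
    markers: list[Marker] = []
    for i, row in df.iterrows():
        try:
            markers.append(Marker(
                id=str(row["id"]), chrom=str(row["chrom"]), pos_bp=int(row["pos_bp"]),
                pos_cM=float(row["pos_cM"]), kind=str(row["kind"]),
                alleles=(str(row["alleleA"]), str(row["alleleB"])),
            ))
        except (ValueError, TypeError) as e:
            raise ValueError(f"{path}: line {i + 2}: {e}") from None
    prev: dict[str, Marker] = {}
    for m in markers:
        if m.chrom in prev and m.pos_bp < prev[m.chrom].pos_bp:
            raise ValueError(f"{path}: marker {m.id} is out of order on {m.chrom} "
                             f"(pos {m.pos_bp} after {prev[m.chrom].id} at {prev[m.chrom].pos_bp})")
        prev[m.chrom] = m
    return markers


# ---------------------------------------------------------------------------
# Genotypes and phenotypes
# ---------------------------------------------------------------------------


def write_genotypes(cohort: Cohort, path: str | Path) -> None:
    df = pd.DataFrame(cohort.genotypes(), columns=[m.id for m in cohort.markers])
    df.insert(0, "id", cohort.ids)
    df.to_csv(path, index=False)


def read_genotypes(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Returns (individual ids, marker ids, genotype code matrix)."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: genotype table must have an 'id' first column")
    ids = df["id"].tolist()
    marker_ids = [c for c in df.columns if c != "id"]
    G = df[marker_ids].to_numpy()
    valid = np.isin(G, (0, 1, 2, GENO_MISSING))
    if not valid.all():
        r, c = np.argwhere(~valid)[0]
        raise ValueError(f"{path}: invalid genotype value {G[r, c]!r} for individual "
                         f"{ids[r]!r} at marker {marker_ids[c]!r} (line {r + 2})")
    return ids, marker_ids, G.astype(np.int8)


def write_phenotypes(cohort: Cohort, path: str | Path) -> None:
    pd.DataFrame({
        "id": cohort.ids,
        "phenotype": [PHENOTYPE_LABELS[int(p)] for p in cohort.phenotype],
        "scoring_age": [a if a is not None else "" for a in cohort.scoring_age],
    }).to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "scoring_age": str}, keep_default_na=False)
    for col in ("id", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"{path}: phenotype table must have a {col!r} column")
    bad = ~df["phenotype"].isin(PHENOTYPE_CODES)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: line {i + 2}: unknown phenotype "
                         f"{df['phenotype'].iloc[i]!r} (column 'phenotype')")
    return df


def read_cohort(genotypes_path: str | Path, phenotypes_path: str | Path,
                map_path: str | Path) -> Cohort:
    """Assemble a cohort from the three tabular files."""
    markers = read_marker_map(map_path)
    ids, marker_ids, G = read_genotypes(genotypes_path)
    by_id = {m.id: m for m in markers}
    missing = [mid for mid in marker_ids if mid not in by_id]
    if missing:
        raise ValueError(f"{genotypes_path}: marker(s) {missing[:5]} absent from {map_path}")
    cohort_markers = [by_id[mid] for mid in marker_ids]
    phen = read_phenotypes(phenotypes_path).set_index("id")
    phenotype = np.full(len(ids), UNSCORED, dtype=np.int8)
    ages: list[str | None] = [None] * len(ids)
    for i, ind in enumerate(ids):
        if ind in phen.index:
            phenotype[i] = PHENOTYPE_CODES[phen.loc[ind, "phenotype"]]
            age = phen.loc[ind].get("scoring_age", "")
            ages[i] = age if age else None
    return Cohort(markers=cohort_markers, ids=ids, genotypes_=G,
                  phenotype=phenotype, scoring_age=ages)


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

_PILEUP_FILE_COLUMNS = ["chrom", "pos", "ref", "alt", "poolA_ref", "poolA_alt",
                        "poolB_ref", "poolB_alt", "qual", "mq"]
_PILEUP_RENAME = {"a_ref": "poolA_ref", "a_alt": "poolA_alt",
                  "b_ref": "poolB_ref", "b_alt": "poolB_alt"}


def write_pileups(pileups: pd.DataFrame, path: str | Path) -> None:
    out = pileups.rename(columns=_PILEUP_RENAME)[_PILEUP_FILE_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def read_pileups(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _PILEUP_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: pileup table is missing column(s) {missing}")
    df = df.rename(columns={v: k for k, v in _PILEUP_RENAME.items()})
    counts = df[["a_ref", "a_alt", "b_ref", "b_alt"]].to_numpy()
    if np.any(counts < 0):
        r, c = np.argwhere(counts < 0)[0]
        col = ["poolA_ref", "poolA_alt", "poolB_ref", "poolB_alt"][c]
        raise ValueError(f"{path}: line {r + 2}: negative read count in column {col!r}")
    return df


def pileup_records(pileups: pd.DataFrame) -> list[PileupSummary]:
    """Materialise pileup table rows as PileupSummary records."""
    return [
        PileupSummary(chrom=str(r.chrom), pos=int(r.pos), ref_allele=str(r.ref),
                      alt_allele=str(r.alt), a_ref=int(r.a_ref), a_alt=int(r.a_alt),
                      b_ref=int(r.b_ref), b_alt=int(r.b_alt),
                      site_quality=float(r.qual), mapping_quality=float(r.mq))
        for r in pileups.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# VCF and BED
# ---------------------------------------------------------------------------


def write_vcf(sites: Sequence[VariantSite], path: str | Path,
              chrom_lengths: Mapping[str, int] | None = None,
              verdicts: Sequence[FilterVerdict] | None = None) -> None:
    """Write variant sites as an uncompressed VCF 4.x file.

    When filter ``verdicts`` are given (aligned with ``sites``), the FILTER
    column carries PASS or the failed reason codes.
    """
    if verdicts is not None and len(verdicts) != len(sites):
        raise ValueError("verdicts must align one-to-one with sites")
    header = pysam.VariantHeader()
    lengths = dict(chrom_lengths or {})
    for s in sites:
        lengths.setdefault(s.chrom, 0)
        lengths[s.chrom] = max(lengths[s.chrom], s.pos)
    for chrom, ln in lengths.items():
        header.contigs.add(chrom, length=int(ln))
    header.info.add("STATUS", 1, "String", "Site status: known, imputed or candidate")
    header.info.add("REPEAT", 0, "Flag", "Site lies in repeat-masked sequence")
    for code in FILTER_CODES:
        header.filters.add(code, None, None, f"Failed hard filter: {code}")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, s in enumerate(sites):
            rec = vf.new_record(contig=s.chrom, start=s.pos - 1,
                                alleles=(s.ref_allele, s.alt_allele))
            rec.info["STATUS"] = s.status
            if s.in_repeat:
                rec.info["REPEAT"] = True
            if verdicts is not None:
                v = verdicts[i]
                if v.passed:
                    rec.filter.add("PASS")
                else:
                    for code in v.failed_filters:
                        rec.filter.add(code)
            vf.write(rec)


def read_vcf(path: str | Path) -> list[VariantSite]:
    """Read site records from a VCF; POS is 1-based throughout the package."""
    sites: list[VariantSite] = []
    try:
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                if rec.alts is None or len(rec.alts) != 1:
                    raise ValueError(f"{path}: record {rec.contig}:{rec.pos} must be "
                                     "a biallelic site")
                sites.append(VariantSite(
                    chrom=rec.contig, pos=rec.pos, ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    status=rec.info.get("STATUS", "candidate"),
                    in_repeat=bool(rec.info.get("REPEAT", False)),
                ))
    except (OSError, ValueError) as e:
        raise ValueError(f"malformed VCF {path}: {e}") from None
    return sites


def read_bed(path: str | Path) -> RepeatMask:
    """Read a BED3+ interval file into a repeat mask (0-based half-open)."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: BED needs >= 3 columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer BED coordinates") from None
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: empty/inverted interval")
            intervals.setdefault(chrom, []).append((start, end))
    return RepeatMask(intervals)


def write_bed(intervals: Mapping[str, Sequence[tuple[int, int]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in intervals.items():
            for s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def write_window_scan(windows: pd.DataFrame, path: str | Path) -> None:
    """BED-graph-style TSV of a window allele scan."""
    out = windows[["chrom", "start", "end", "n_snps", "strainA_fraction", "low_density"]].copy()
    out["strainA_fraction"] = out["strainA_fraction"].map(
        lambda v: "" if pd.isna(v) else f"{v:.4g}")
    out.to_csv(path, sep="\t", index=False)


def write_scan(scan: pd.DataFrame, path: str | Path) -> None:
    out = scan.copy()
    for col in ("chi2", "p", "neg_log10_p"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.4g}")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration, manifest, pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``arc`` selects the analysis: ``cross_scan`` simulates (or loads) a cross
    cohort, applies penetrance and runs the affected-only genome scan;
    ``pool_scan`` simulates (or loads) two-pool pileups and runs support
    classification, the novel-SNP filter cascade and the window scans.
    Explicit input paths override simulation.
    """

    arc: str = "cross_scan"
    seed: int = 0
    out_dir: str = "pssmap_run"

    # optional inputs (paths); when None the synthetic generator supplies them
    map_path: str | None = None
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    sites_path: str | None = None
    mask_path: str | None = None
    pileups_path: str | None = None

    # cross-arc parameters
    design: str = "F2"
    n_offspring: int = 481
    n_markers: int = 874
    trait_chrom: str = "chr11"
    trait_cm: float = 10.44
    penetrance: dict = field(default_factory=lambda: {"P21": [0.02, 0.02, 0.9]})
    background_rate: float = 0.0
    scoring_age: str = "P21"
    alpha: float = 0.05
    n_tests: int | None = None

    # pool-arc parameters
    n_sites: int = 20_000
    n_pool_members: int = 9
    depth_a: float = 2.3
    depth_b: float = 2.9
    base_error_rate: float = 0.001
    window_bp: int = 10_000_000
    step_bp: int = 1_000_000
    density_window_bp: int = 200_000

    def __post_init__(self) -> None:
        if self.arc not in ("cross_scan", "pool_scan"):
            raise ValueError(f"unknown arc {self.arc!r}")
        for p in (self.map_path, self.genotypes_path, self.phenotypes_path,
                  self.sites_path, self.mask_path, self.pileups_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    master_seed: int
    input_checksums: dict
    stage_counts: dict
    stage_seconds: dict

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute one analysis arc end to end, writing stage outputs and a manifest.

    Deterministic given the master seed: every stage draws from a named
    substream of ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {p: _file_checksum(p) for p in
                 (config.map_path, config.genotypes_path, config.phenotypes_path,
                  config.sites_path, config.mask_path, config.pileups_path) if p}
    counts: dict[str, int] = {}
    seconds: dict[str, float] = {}

    try:
        if config.arc == "cross_scan":
            _run_cross_arc(config, out, counts, seconds)
        else:
            _run_pool_arc(config, out, counts, seconds)
    except Exception as e:
        manifest = RunManifest(__version__, config.digest(), config.seed,
                               checksums, counts, seconds)
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"pipeline aborted in arc {config.arc!r}: {e}") from e

    manifest = RunManifest(__version__, config.digest(), config.seed,
                           checksums, counts, seconds)
    manifest.write(out / "manifest.json")
    return manifest


def _timed(seconds: dict, name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *a):
            seconds[name] = round(time.perf_counter() - self.t0, 3)
            return False
    return _T()


def _run_cross_arc(config: RunConfig, out: Path, counts: dict, seconds: dict) -> None:
    with _timed(seconds, "simulate"):
        if config.genotypes_path and config.phenotypes_path and config.map_path:
            cohort = read_cohort(config.genotypes_path, config.phenotypes_path,
                                 config.map_path)
        else:
            gmap = default_mouse_map()
            markers = default_marker_set(gmap, config.n_markers)
            design = CrossDesign(type=config.design, n_offspring=config.n_offspring,
                                 recurrent_parent="B" if config.design == "BC" else None)
            cohort = simulate_cross(design, gmap, markers, substream(config.seed, "cross"))
            trait_marker = min(
                (m for m in markers if m.chrom == config.trait_chrom),
                key=lambda m: abs(m.pos_cM - config.trait_cm))
            model = PenetranceModel(
                trait_locus=trait_marker.id,
                penetrance={a: tuple(v) for a, v in config.penetrance.items()},
                background_rate=config.background_rate)
            cohort = apply_penetrance(cohort, model, config.scoring_age,
                                      substream(config.seed, "phenotype"))
            write_marker_map(markers, out / "markers.tsv")
            write_genotypes(cohort, out / "genotypes.csv")
            write_phenotypes(cohort, out / "phenotypes.csv")
        counts["simulate"] = len(cohort)

    with _timed(seconds, "scan"):
        affected = cohort.affected_only()
        ratio = (1, 2, 1) if config.design == "F2" else (1, 1)
        scan = genome_scan(affected, config=ScanConfig(
            expected_ratio=ratio, alpha=config.alpha, n_tests=config.n_tests))
        write_scan(scan, out / "scan.tsv")
        counts["scan"] = int(scan["tested"].sum())


def _run_pool_arc(config: RunConfig, out: Path, counts: dict, seconds: dict) -> None:
    gmap = default_mouse_map()
    lengths = gmap.lengths_bp()
    with _timed(seconds, "pool"):
        if config.pileups_path:
            pileups = read_pileups(config.pileups_path)
            sites = (read_vcf(config.sites_path) if config.sites_path else
                     [VariantSite(chrom=str(r.chrom), pos=int(r.pos), ref_allele=str(r.ref),
                                  alt_allele=str(r.alt))
                      for r in pileups.itertuples(index=False)])
        else:
            markers = default_marker_set(gmap, config.n_sites)
            sites = sites_from_markers(markers, status="known")
            design = CrossDesign(type="F2", n_offspring=config.n_pool_members)
            cohort = simulate_cross(design, gmap, markers, substream(config.seed, "pool_cross"))
            pool_a = PoolSpec(strain="A", mean_depth=config.depth_a,
                              base_error_rate=config.base_error_rate)
            pool_b = PoolSpec(members=list(range(len(cohort))), mean_depth=config.depth_b,
                              base_error_rate=config.base_error_rate)
            pileups = simulate_pileups(sites, pool_a, pool_b, cohort_b=cohort,
                                       rng=substream(config.seed, "pool_reads"))
            write_pileups(pileups, out / "pileups.tsv")
            write_vcf(sites, out / "sites.vcf", chrom_lengths=lengths)
        counts["pool"] = len(pileups)

    with _timed(seconds, "concordance"):
        calls = classify_support_table(pileups)
        summary = support_summary(calls)
        with open(out / "support_summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2)
            fh.write("\n")
        counts["concordance"] = summary.n_sites

    with _timed(seconds, "filter"):
        mask = read_bed(config.mask_path) if config.mask_path else RepeatMask()
        records = pileup_records(pileups)
        pairs = sorted(zip(sites, records), key=lambda sr: (sr[0].chrom, sr[0].pos))
        verdicts = novel_snp_filter(pairs, mask)
        write_vcf([s for s, _ in pairs], out / "filtered.vcf",
                  chrom_lengths=lengths, verdicts=verdicts)
        counts["filter"] = sum(v.passed for v in verdicts)

    with _timed(seconds, "window_scan"):
        # informative reads in the segregating pool (pool B): alt = strain-A allele
        informative = pd.DataFrame({
            "chrom": pileups["chrom"], "pos": pileups["pos"],
            "a_reads": pileups["b_alt"], "b_reads": pileups["b_ref"],
        })
        windows = window_allele_scan(informative, lengths,
                                     window_bp=config.window_bp, step_bp=config.step_bp)
        write_window_scan(windows, out / "windows.tsv")
        density = snp_density_profile(pileups[["chrom", "pos"]], lengths,
                                      window_bp=config.density_window_bp)
        density.to_csv(out / "density.tsv", sep="\t", index=False)
        counts["window_scan"] = len(windows)
        counts["density"] = len(density)
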