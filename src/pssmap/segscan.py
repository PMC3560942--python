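"""Cross statistics for an incompletely penetrant binary trait.

Mendelian goodness-of-fit tests, the affected-only per-marker chi-square
genome scan with Bonferroni correction, closed-vs-open genotype-distribution
comparisons, and a single-locus feasibility diagnostic that asks whether any
penetrance triple (p0, p1, p2) could jointly produce the affected proportions
observed across cross designs.

All chi-square statistics are Pearson statistics with no continuity
correction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sim import AFFECTED, GENO_MISSING, Cohort, GeneticMap, Marker

# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


@dataclass
class GofResult:
    chi2: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray
    notes: list[str] = field(default_factory=list)


def _pearson(observed: np.ndarray, expected: np.ndarray) -> tuple[float, list[str]]:
    if np.any(expected == 0):
        raise ValueError("an expected count of zero makes the chi-square statistic undefined")
    notes = []
    if np.any(expected < 5):
        notes.append("expected count < 5 in at least one cell; the chi-square "
                     "approximation may be rough")
        warnings.warn(notes[-1], stacklevel=3)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, notes


def mendelian_gof(n_affected: int, n_unaffected: int,
                  expected_affected_fraction: float) -> GofResult:
    """Test observed affected/unaffected counts against a Mendelian fraction.

    One-degree-of-freedom Pearson chi-square with no continuity correction,
    e.g. ``expected_affected_fraction`` 0.25 for autosomal recessive
    inheritance in an F2 intercross, 0.5 in a backcross to the carrier strain.
    """
    if n_affected < 0 or n_unaffected < 0:
        raise ValueError("counts must be non-negative")
    total = n_affected + n_unaffected
    if total == 0:
        raise ValueError("total count must be positive")
    if not (0.0 < expected_affected_fraction < 1.0):
        raise ValueError("expected_affected_fraction must lie strictly in (0, 1)")
    observed = np.array([n_affected, n_unaffected], dtype=float)
    expected = total * np.array([expected_affected_fraction, 1.0 - expected_affected_fraction])
    chi2, notes = _pearson(observed, expected)
    return GofResult(chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, 1)),
                     observed=observed, expected=expected, notes=notes)


def marker_genotype_gof(counts: Sequence[int],
                        expected_ratio: Sequence[float] = (1, 2, 1)) -> GofResult:
    """Test genotype-class counts against an expected ratio (default 1:2:1).

    Pearson chi-square with df = #classes - 1 and no continuity correction;
    for the 2-df case the p-value reduces to exp(-chi2/2).
    """
    observed = np.asarray(counts, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if observed.shape != ratio.shape:
        raise ValueError("counts and expected_ratio must have the same length")
    if np.any(observed < 0):
        raise ValueError("counts must be non-negative")
    if np.any(ratio <= 0):
        raise ValueError("expected_ratio entries must be positive")
    total = observed.sum()
    if total == 0:
        raise ValueError("all genotype counts are zero")
    expected = total * ratio / ratio.sum()
    chi2, notes = _pearson(observed, expected)
    df = len(observed) - 1
    return GofResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)),
                     observed=observed, expected=expected, notes=notes)


def group_comparison(closed_counts: Sequence[int], open_counts: Sequence[int]) -> GofResult:
    """Compare genotype distributions between closed- and open-phenotype groups.

    Pearson chi-square test of independence on the 2 x k contingency table
    (k = 3 genotype classes in an F2, 2 in a backcross), no continuity
    correction.  A genotype class empty in both groups is dropped with a
    warning before testing.
    """
    closed = np.asarray(closed_counts, dtype=float)
    opened = np.asarray(open_counts, dtype=float)
    if closed.shape != opened.shape:
        raise ValueError("both groups must have the same genotype classes")
    if closed.sum() == 0 or opened.sum() == 0:
        raise ValueError("both groups must be non-empty")
    keep = (closed + opened) > 0
    notes: list[str] = []
    if not keep.all():
        notes.append(f"dropped {int((~keep).sum())} genotype class(es) empty in both groups")
        warnings.warn(notes[-1], stacklevel=2)
        closed, opened = closed[keep], opened[keep]
    table = np.vstack([closed, opened])
    res = stats.chi2_contingency(table, correction=False)
    return GofResult(chi2=float(res.statistic), df=int(res.dof), p=float(res.pvalue),
                     observed=table, expected=res.expected_freq, notes=notes)


# ---------------------------------------------------------------------------
# Affected-only genome scan
# ---------------------------------------------------------------------------


@dataclass
class ScanConfig:
    """Configuration of the affected-only segregation-distortion scan.

    ``threshold`` is the Bonferroni-corrected per-marker significance level
    alpha / n_tests; when ``n_tests`` is None it defaults to the number of
    markers actually tested.  ``threshold_override`` reproduces a literal
    published cut (e.g. 5e-5) instead of the exact division.
    """

    expected_ratio: tuple[float, ...] = (1, 2, 1)
    alpha: float = 0.05
    n_tests: int | None = None
    threshold_override: float | None = None
    # genotype codes the ratio refers to; inferred when None: (0, 1, 2) for a
    # three-class F2 ratio, (1, 2) for a two-class backcross-to-B ratio
    genotype_classes: tuple[int, ...] | None = None

    def classes(self) -> tuple[int, ...]:
        if self.genotype_classes is not None:
            if len(self.genotype_classes) != len(self.expected_ratio):
                raise ValueError("genotype_classes and expected_ratio must align")
            return self.genotype_classes
        if len(self.expected_ratio) == 3:
            return (0, 1, 2)
        if len(self.expected_ratio) == 2:
            return (1, 2)
        raise ValueError("cannot infer genotype classes; set genotype_classes")

    def threshold(self, n_tested: int) -> float:
        if self.threshold_override is not None:
            t = self.threshold_override
        else:
            n = self.n_tests if self.n_tests is not None else n_tested
            if n <= 0:
                raise ValueError("number of tests must be positive")
            t = self.alpha / n
        if not (0.0 < t < 1.0):
            raise ValueError("significance threshold must lie in (0, 1)")
        return t


SCAN_COLUMNS = ["marker", "chrom", "pos_bp", "n0", "n1", "n2",
                "chi2", "p", "neg_log10_p", "significant", "tested"]


def genome_scan(cohort: Cohort | np.ndarray, markers: Sequence[Marker] | None = None,
                config: ScanConfig | None = None) -> pd.DataFrame:
    """Per-marker chi-square scan for segregation distortion in affected individuals.

    Accepts an affected-only :class:`Cohort` (its markers are used) or a raw
    (n, m) genotype matrix plus ``markers``.  Each marker's genotype counts
    among non-missing individuals are tested against ``config.expected_ratio``
    (1:2:1 for an F2).  Markers with no genotyped individual are reported with
    ``tested = False`` rather than dropped.  Output rows are sorted by
    (chrom, pos_bp); the Bonferroni threshold is stored in ``df.attrs``.
    """
    config = config or ScanConfig()
    if isinstance(cohort, Cohort):
        if len(cohort) == 0:
            raise ValueError("empty cohort")
        scored = cohort.phenotype != -9
        if np.any(cohort.phenotype[scored] != AFFECTED):
            raise ValueError("genome_scan expects an affected-only cohort")
        G = cohort.genotypes()
        markers = cohort.markers
    else:
        G = np.asarray(cohort)
        if G.shape[0] == 0:
            raise ValueError("empty cohort")
        if markers is None:
            raise ValueError("markers are required with a raw genotype matrix")
    if G.shape[1] != len(markers):
        raise ValueError("genotype matrix and marker list disagree in length")

    ratio = np.asarray(config.expected_ratio, dtype=float)
    classes = config.classes()
    class_counts = np.stack([(G == c).sum(axis=0) for c in classes], axis=1).astype(float)
    full_counts = np.stack([(G == c).sum(axis=0) for c in (0, 1, 2)], axis=1)
    total = class_counts.sum(axis=1)
    tested = total > 0

    chi2 = np.full(len(markers), np.nan)
    p = np.full(len(markers), np.nan)
    if tested.any():
        expected = total[tested, None] * (ratio / ratio.sum())[None, :]
        chi2[tested] = ((class_counts[tested] - expected) ** 2 / expected).sum(axis=1)
        p[tested] = stats.chi2.sf(chi2[tested], len(ratio) - 1)

    threshold = config.threshold(int(tested.sum()))
    with np.errstate(divide="ignore"):
        nlp = -np.log10(p)
    df = pd.DataFrame({
        "marker": [m.id for m in markers],
        "chrom": [m.chrom for m in markers],
        "pos_bp": [m.pos_bp for m in markers],
        "n0": full_counts[:, 0],
        "n1": full_counts[:, 1],
        "n2": full_counts[:, 2],
        "chi2": chi2,
        "p": p,
        "neg_log10_p": nlp,
        "significant": tested & (p < threshold),
        "tested": tested,
    })
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(df["chrom"]))}
    df = (df.assign(_rank=df["chrom"].map(chrom_order))
            .sort_values(["_rank", "pos_bp"], kind="mergesort")
            .drop(columns="_rank").reset_index(drop=True))
    df.attrs["threshold"] = threshold
    df.attrs["alpha"] = config.alpha
    df.attrs["n_tests"] = config.n_tests if config.n_tests is not None else int(tested.sum())
    return df


def scan_peak(scan: pd.DataFrame) -> pd.Series:
    """The scan's peak marker: smallest p, ties broken by largest chi2, then
    lowest genomic coordinate (rows are already genome-ordered)."""
    tested = scan[scan["tested"]]
    if tested.empty:
        raise ValueError("no tested markers in scan")
    best = tested.sort_values(["p", "chi2"], ascending=[True, False], kind="mergesort")
    return best.iloc[0]


def manhattan_table(scan: pd.DataFrame, gmap: GeneticMap) -> pd.DataFrame:
    """Genome-ordered plotting track for a scan: one row per tested marker with
    a cumulative genome coordinate; the significance threshold rides along in
    ``df.attrs['threshold']``."""
    if scan.empty:
        raise ValueError("empty scan")
    offsets: dict[str, int] = {}
    run = 0
    for c in gmap.chromosomes:
        offsets[c.name] = run
        run += c.length_bp
    rows = scan[scan["tested"]].copy()
    rows["_rank"] = rows["chrom"].map({n: i for i, n in enumerate(gmap.names)})
    if rows["_rank"].isna().any():
        bad = rows.loc[rows["_rank"].isna(), "chrom"].iloc[0]
        raise KeyError(f"scan chromosome {bad!r} is not in the map")
    rows = rows.sort_values(["_rank", "pos_bp"], kind="mergesort")
    out = pd.DataFrame({
        "chrom": rows["chrom"].to_numpy(),
        "pos_bp": rows["pos_bp"].to_numpy(),
        "cum_pos_bp": rows["pos_bp"].to_numpy() + rows["chrom"].map(offsets).to_numpy(),
        "neg_log10_p": rows["neg_log10_p"].to_numpy(),
        "significant": rows["significant"].to_numpy(),
    })
    out.attrs["threshold"] = scan.attrs.get("threshold")
    return out


# ---------------------------------------------------------------------------
# Single-locus feasibility diagnostic
# ---------------------------------------------------------------------------

# Expected affected proportion per design as a linear function of (p0, p1, p2):
# F1 offspring of two inbreds are all heterozygous; an F2 segregates 1:2:1;
# a backcross to strain B segregates 1:1 het : B/B (and to strain A, A/A : het).
_DESIGN_COEFFS: dict[str, np.ndarray] = {
    "F1": np.array([0.0, 1.0, 0.0]),
    "F2": np.array([0.25, 0.5, 0.25]),
    "BC": np.array([0.0, 0.5, 0.5]),     # backcross to strain B
    "BC_A": np.array([0.5, 0.5, 0.0]),   # backcross to strain A
}


@dataclass
class FeasibilityReport:
    """Outcome of the single-locus feasibility search.

    ``feasible`` says whether some (p0, p1, p2) in [0,1]^3 reproduces every
    observed affected proportion exactly (at the point estimates);
    ``best_fit`` minimises the binomial deviance regardless.  When infeasible,
    ``certificate`` is a human-readable argument (if a pin-and-propagate bound
    proves it) and ``max_residual`` the least-squares gap.
    """

    feasible: bool
    best_fit: tuple[float, float, float]
    deviance: float
    max_residual: float
    fitted_proportions: dict[str, float]
    observed_proportions: dict[str, float]
    certificate: str | None = None


def _binomial_deviance(p: np.ndarray, designs: list[str], ks: np.ndarray, ns: np.ndarray) -> float:
    A = np.stack([_DESIGN_COEFFS[d] for d in designs])
    pi = np.clip(A @ p, 1e-12, 1.0 - 1e-12)
    k, n = ks, ns
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(k / (n * pi)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log((n - k) / (n - n * pi)), 0.0)
    return float(2.0 * (t1 + t2).sum())


def _pin_and_propagate(designs: list[str], props: np.ndarray, tol: float = 1e-9) -> str | None:
    """Try to prove infeasibility by interval propagation.

    A design with observed proportion 0 forces every penetrance parameter it
    weights to 0 (and proportion 1 forces them to 1, since the weights sum
    to 1).  With those pins applied, if another design's observed proportion
    falls outside the attainable range of its expectation over the remaining
    box, no single-locus model fits.
    """
    lo = np.zeros(3)
    hi = np.ones(3)
    pins: list[str] = []
    for d, y in zip(designs, props):
        c = _DESIGN_COEFFS[d]
        if y <= tol:
            hi[c > 0] = 0.0
            pins.append(f"{d} proportion 0 forces {_names(c)} = 0")
        elif y >= 1.0 - tol:
            lo[c > 0] = 1.0
            pins.append(f"{d} proportion 1 forces {_names(c)} = 1")
    if np.any(lo > hi):
        return "; ".join(pins) + "; the pins are mutually contradictory"
    for d, y in zip(designs, props):
        c = _DESIGN_COEFFS[d]
        mn, mx = float(c @ lo), float(c @ hi)
        if y < mn - tol or y > mx + tol:
            pre = ("; ".join(pins) + "; then " ) if pins else ""
            return (f"{pre}{d} expected proportion is confined to "
                    f"[{mn:.3f}, {mx:.3f}] but {y:.3f} was observed")
    return None


def _names(coef: np.ndarray) -> str:
    return ", ".join(n for n, c in zip(("p0", "p1", "p2"), coef) if c > 0)


def single_locus_feasibility(observed: Mapping[str, tuple[int, int]],
                             tol: float = 1e-8) -> FeasibilityReport:
    """Can one locus with penetrances (p0, p1, p2) explain all cross results?

    ``observed`` maps design labels ("F1", "F2", "BC" = backcross to strain B,
    "BC_A") to (n_affected, n_total).  The expected affected proportion of
    each design is linear in (p0, p1, p2), so exact feasibility at the point
    estimates is a bounded least-squares problem; the best fit under sampling
    noise minimises the binomial deviance over [0, 1]^3 (coarse grid followed
    by a Nelder-Mead polish).
    """
    if len(observed) < 2:
        raise ValueError("need observations from at least two cross designs")
    designs = list(observed)
    for d in designs:
        if d not in _DESIGN_COEFFS:
            raise KeyError(f"unknown cross design {d!r}; expected one of {sorted(_DESIGN_COEFFS)}")
    ks = np.array([observed[d][0] for d in designs], dtype=float)
    ns = np.array([observed[d][1] for d in designs], dtype=float)
    if np.any(ns <= 0) or np.any(ks < 0) or np.any(ks > ns):
        raise ValueError("each design needs 0 <= n_affected <= n_total with n_total > 0")
    props = ks / ns
    A = np.stack([_DESIGN_COEFFS[d] for d in designs])

    # Exact feasibility at the point estimates: the expected proportions are
    # linear in (p0, p1, p2), so matching them inside [0,1]^3 is a linear
    # program (solved exactly by HiGHS); least squares quantifies the gap.
    lp = optimize.linprog(c=np.zeros(3), A_eq=A, b_eq=props, bounds=[(0.0, 1.0)] * 3,
                          method="highs")
    feasible = bool(lp.status == 0)
    ls = optimize.lsq_linear(A, props, bounds=(0.0, 1.0), tol=1e-14, lsmr_tol=1e-14)
    max_residual = 0.0 if feasible else float(np.max(np.abs(A @ ls.x - props)))

    # Best fit by binomial deviance: grid multistart + local polish.
    grid = np.linspace(0.0, 1.0, 21)
    P = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1).reshape(-1, 3)
    pi = np.clip(P @ A.T, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(ks > 0, ks * np.log(ks / (ns * pi)), 0.0)
        t2 = np.where(ns - ks > 0, (ns - ks) * np.log((ns - ks) / (ns - ns * pi)), 0.0)
    dev = 2.0 * (t1 + t2).sum(axis=1)
    starts = [P[int(np.argmin(dev))], ls.x]
    best_p, best_dev = None, np.inf
    for x0 in starts:
        res = optimize.minimize(_binomial_deviance, x0, args=(designs, ks, ns),
                                method="Nelder-Mead",
                                bounds=[(0.0, 1.0)] * 3,
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        if res.fun < best_dev:
            best_p, best_dev = np.clip(res.x, 0.0, 1.0), max(0.0, float(res.fun))

    certificate = None
    if not feasible:
        certificate = _pin_and_propagate(designs, props)
        if certificate is None:
            certificate = (f"bounded least squares leaves a residual of {max_residual:.4f} "
                           f"in the expected proportions; no (p0, p1, p2) in [0,1]^3 matches")
    fitted = {d: float(_DESIGN_COEFFS[d] @ best_p) for d in designs}
    return FeasibilityReport(
        feasible=feasible,
        best_fit=tuple(float(v) for v in best_p),
        deviance=best_dev,
        max_residual=max_residual,
        fitted_proportions=fitted,
        observed_proportions={d: float(y) for d, y in zip(designs, props)},
        certificate=certificate,
    )
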