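"""Two-sample Mendelian randomization.

Instrument selection (p-value threshold, greedy LD clumping, F-statistic
filter), allele harmonization of exposure and outcome summary statistics,
five causal-effect estimators (inverse-variance weighted, MR-Egger,
weighted median, simple and weighted mode) and the standard diagnostic
suite (Cochran's Q heterogeneity, Egger intercept pleiotropy test,
MR-PRESSO outlier detection, leave-one-out).

All estimators operate on a :class:`HarmonizedSet` of per-SNP aligned
(beta_exp, se_exp, beta_out, se_out) pairs with first-order weights
w_j = se_out_j^-2.  Effects are on the log-odds scale; ``beta_to_or``
converts to the OR / 95% CI presentation.

Conventions: IVW uses multiplicative random effects — the fixed-effect SE
inflated by max(1, sqrt(Q/(k-1))) — and normal p-values, so its CI never
narrows below the fixed-effect one.  MR-Egger uses the plain weighted
least-squares residual variance (no floor) and Student-t p-values with
k-2 degrees of freedom, the classical exact test for a weighted linear
model; the median and mode estimators use seeded parametric bootstrap
standard errors and normal p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True, slots=True)
class SnpAssociation:
    """Summary statistics of one SNP for one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int = 0

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.snp_id}: eaf out of [0, 1]")

    @property
    def f_stat(self) -> float:
        return f_statistic(self.beta, self.se)

    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F-statistic (beta/se)^2; F > 10 is the usual bar."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


class LdMatrix:
    """Symmetric pairwise r-squared lookup; absent pairs read as 0."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        for (i, j), r2 in (pairs or {}).items():
            self.set(i, j, r2)

    def set(self, snp_i: str, snp_j: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 out of [0, 1]: {r2}")
        self._r2[frozenset((snp_i, snp_j))] = r2

    def get(self, snp_i: str, snp_j: str) -> float:
        if snp_i == snp_j:
            return 1.0
        return self._r2.get(frozenset((snp_i, snp_j)), 0.0)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdMatrix":
        """3-column TSV: snp_i, snp_j, r2 (header optional)."""
        df = pd.read_csv(path, sep="\t")
        if list(df.columns[:3]) != ["snp_i", "snp_j", "r2"]:
            df = pd.read_csv(path, sep="\t", header=None, names=["snp_i", "snp_j", "r2"])
        m = cls()
        for row in df.itertuples(index=False):
            m.set(str(row.snp_i), str(row.snp_j), float(row.r2))
        return m


def select_instruments(
    exp: Sequence[SnpAssociation],
    p_thresh: float = 5e-6,
    ld: LdMatrix | None = None,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
    f_min: float = 10.0,
) -> tuple[list[SnpAssociation], list[tuple[str, str]]]:
    """Threshold, clump and strength-filter exposure SNPs.

    Greedy clumping: candidates with p < ``p_thresh`` are visited in
    ascending-p order; each retained index SNP discards every remaining
    same-chromosome SNP within ``window_kb`` whose r2 with it exceeds
    ``r2_max``.  Retained SNPs with F = (beta/se)^2 <= ``f_min`` are then
    dropped.  Returns the survivors plus an exclusion log of
    (snp_id, reason); an empty survivor set is an error.
    """
    ld = ld or LdMatrix()
    exclusions: list[tuple[str, str]] = []
    candidates = []
    for s in exp:
        if s.p < p_thresh:
            candidates.append(s)
        else:
            exclusions.append((s.snp_id, f"p {s.p:.3g} >= threshold {p_thresh:g}"))
    candidates.sort(key=lambda s: (s.p, s.snp_id))

    retained: list[SnpAssociation] = []
    remaining = list(candidates)
    while remaining:
        index = remaining.pop(0)
        retained.append(index)
        kept = []
        for s in remaining:
            if s.chrom == index.chrom and abs(s.pos - index.pos) <= window_kb * 1000:
                r2 = ld.get(index.snp_id, s.snp_id)
                if r2 > r2_max:
                    exclusions.append(
                        (s.snp_id, f"clumped: r2 {r2:.3g} with {index.snp_id}")
                    )
                    continue
            kept.append(s)
        remaining = kept

    survivors = []
    for s in retained:
        if s.f_stat <= f_min:
            exclusions.append((s.snp_id, f"weak instrument: F {s.f_stat:.2f} <= {f_min:g}"))
        else:
            survivors.append(s)
    if not survivors:
        raise ValueError("no instruments survive selection")
    for snp, reason in exclusions:
        log.info("select_instruments: dropped %s (%s)", snp, reason)
    return survivors, exclusions


@dataclass(slots=True)
class HarmonizedSet:
    """Allele-aligned per-SNP exposure/outcome pairs.

    Exposure betas are oriented nonnegative (both betas of a SNP are
    sign-flipped together, which leaves the ratio invariant); ``flipped``
    records the orientation applied.
    """

    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    flipped: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if self.k < 1:
            raise ValueError("HarmonizedSet needs at least one SNP")
        if self.flipped.size == 0:
            self.flipped = np.zeros(self.k, bool)

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    @property
    def ratio(self) -> np.ndarray:
        """Per-SNP Wald ratio beta_out / beta_exp."""
        return self.beta_out / self.beta_exp

    @property
    def se_ratio(self) -> np.ndarray:
        """First-order ratio SE: se_out / |beta_exp|."""
        return self.se_out / np.abs(self.beta_exp)

    @property
    def weight(self) -> np.ndarray:
        """First-order inverse-variance weights se_out^-2."""
        return self.se_out ** -2.0

    def drop(self, index: int) -> "HarmonizedSet":
        keep = [i for i in range(self.k) if i != index]
        return HarmonizedSet(
            [self.snp_ids[i] for i in keep],
            self.beta_exp[keep], self.se_exp[keep],
            self.beta_out[keep], self.se_out[keep],
            self.flipped[keep], list(self.exclusions),
        )


def harmonize(
    exp: Sequence[SnpAssociation],
    out: Sequence[SnpAssociation],
    ambiguous_eaf: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align outcome effects to the exposure effect allele.

    Intersects on snp_id; flips the outcome beta (and complements its EAF)
    when the outcome's effect allele matches the exposure's other allele,
    handling strand (complement) differences.  Palindromic A/T and C/G
    SNPs are oriented by allele frequency when both EAFs are away from 0.5
    and dropped as ambiguous when either EAF lies in ``ambiguous_eaf``.
    Irreconcilable allele pairs are dropped.  Every action is logged.
    Finally exposure betas are oriented nonnegative.
    """
    out_by_id = {s.snp_id: s for s in out}
    exclusions: list[tuple[str, str]] = []
    ids, bx, sx, by, so = [], [], [], [], []
    for e in exp:
        o = out_by_id.get(e.snp_id)
        if o is None:
            exclusions.append((e.snp_id, "absent from outcome"))
            continue
        ea_e, oa_e = e.effect_allele, e.other_allele
        ea_o, oa_o = o.effect_allele, o.other_allele
        comp_ea_o = _COMPLEMENT.get(ea_o, "?")
        comp_oa_o = _COMPLEMENT.get(oa_o, "?")
        beta_o = o.beta
        if e.is_palindromic():
            lo, hi = ambiguous_eaf
            if lo <= e.eaf <= hi or lo <= o.eaf <= hi:
                exclusions.append((e.snp_id, "palindromic with ambiguous eaf"))
                continue
            if {ea_o, oa_o} not in ({ea_e, oa_e}, {comp_ea_o, comp_oa_o}):
                exclusions.append((e.snp_id, "incompatible alleles"))
                continue
            # orient by frequency: effect alleles agree iff eafs fall on the
            # same side of 0.5
            if (e.eaf - 0.5) * (o.eaf - 0.5) < 0:
                beta_o = -beta_o
        elif (ea_o, oa_o) == (ea_e, oa_e) or (comp_ea_o, comp_oa_o) == (ea_e, oa_e):
            pass
        elif (oa_o, ea_o) == (ea_e, oa_e) or (comp_oa_o, comp_ea_o) == (ea_e, oa_e):
            beta_o = -beta_o
        else:
            exclusions.append((e.snp_id, "incompatible alleles"))
            continue
        ids.append(e.snp_id)
        bx.append(e.beta)
        sx.append(e.se)
        by.append(beta_o)
        so.append(o.se)
    if not ids:
        raise ValueError("no overlapping instruments after harmonization")
    for snp, reason in exclusions:
        log.info("harmonize: dropped %s (%s)", snp, reason)
    bx = np.asarray(bx)
    by = np.asarray(by)
    flip = bx < 0
    bx = np.where(flip, -bx, bx)
    by = np.where(flip, -by, by)
    return HarmonizedSet(ids, bx, np.asarray(sx), by, np.asarray(so), flip, exclusions)


@dataclass(frozen=True, slots=True)
class MrEstimate:
    method: str
    beta: float
    se: float
    p: float
    or_point: float
    ci_low: float
    ci_high: float
    k_snps: int
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True, slots=True)
class HeterogeneityResult:
    model: str  # ivw | egger
    Q: float
    df: int
    p: float


def beta_to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Log-odds effect to OR with Wald 95% CI."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return math.exp(beta), math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)


def _estimate(method: str, beta: float, se: float, p: float, k: int,
              extras: dict | None = None) -> MrEstimate:
    orp, lo, hi = beta_to_or(beta, se)
    return MrEstimate(method, beta, se, p, orp, lo, hi, k, extras or {})


def _ivw_slope(h: HarmonizedSet) -> tuple[float, float, float]:
    """Fixed-effect IVW slope, its SE and Cochran's Q."""
    w = h.weight
    denom = float(np.sum(h.beta_exp ** 2 * w))
    beta = float(np.sum(h.beta_exp * h.beta_out * w)) / denom
    se_fixed = denom ** -0.5
    q = float(np.sum(w * (h.beta_out - beta * h.beta_exp) ** 2))
    return beta, se_fixed, q


def wald_ratio(h: HarmonizedSet) -> MrEstimate:
    """Single-instrument Wald ratio (explicit k = 1 convenience path)."""
    if h.k != 1:
        raise ValueError("wald_ratio requires exactly one SNP")
    beta = float(h.ratio[0])
    se = float(h.se_ratio[0])
    p = 2 * float(stats.norm.sf(abs(beta / se)))
    return _estimate("wald_ratio", beta, se, p, 1)


def ivw(h: HarmonizedSet, random_effects: bool = True) -> MrEstimate:
    """Inverse-variance weighted estimate (regression through the origin).

    With ``random_effects`` (default) the fixed-effect SE is inflated by
    max(1, sqrt(Q/(k-1))) — multiplicative random effects, which never
    narrows the CI.  p is two-sided normal.
    """
    if h.k < 2:
        raise ValueError("ivw requires k >= 2 (use wald_ratio for k = 1)")
    beta, se, q = _ivw_slope(h)
    if random_effects:
        se *= max(1.0, math.sqrt(q / (h.k - 1)))
    p = 2 * float(stats.norm.sf(abs(beta / se)))
    return _estimate("ivw", beta, se, p, h.k, {"Q": q})


def egger(h: HarmonizedSet) -> MrEstimate:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    The slope is the causal estimate; the intercept estimates directional
    pleiotropy (extras carry its value, SE and two-sided t p-value with
    k-2 df).  SEs use the WLS residual variance; an all-equal beta_exp
    design is non-identifiable and raises.
    """
    if h.k < 3:
        raise ValueError("egger requires k >= 3")
    w = h.weight
    X = np.column_stack([np.ones(h.k), h.beta_exp])
    xtwx = X.T @ (w[:, None] * X)
    if np.linalg.cond(xtwx) > 1e10:
        raise ValueError("egger non-identifiable: exposure betas (nearly) constant")
    coef = np.linalg.solve(xtwx, X.T @ (w * h.beta_out))
    resid = h.beta_out - X @ coef
    q = float(np.sum(w * resid ** 2))
    df = h.k - 2
    sigma2 = q / df
    cov = np.linalg.inv(xtwx) * sigma2
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    t_slope = coef[1] / se_slope
    t_int = coef[0] / se_int
    p_slope = 2 * float(stats.t.sf(abs(t_slope), df))
    p_int = 2 * float(stats.t.sf(abs(t_int), df))
    return _estimate(
        "egger", float(coef[1]), se_slope, p_slope, h.k,
        {"intercept": float(coef[0]), "intercept_se": se_int, "intercept_p": p_int,
         "Q": q},
    )


def _weighted_median(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Interpolated weighted median (cumulative weight crossing 0.5)."""
    order = np.argsort(ratio)
    r = ratio[order]
    w = weight[order] / weight.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


def _bootstrap_se(h: HarmonizedSet, statistic, n_boot: int, rng: np.random.Generator) -> float:
    """Parametric bootstrap: resample betas from their sampling normals."""
    vals = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(h.beta_exp, h.se_exp)
        by = rng.normal(h.beta_out, h.se_out)
        vals[b] = statistic(bx, by)
    return float(vals.std(ddof=1))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int | np.random.Generator = 0
) -> MrEstimate:
    """Weighted-median estimator, consistent when valid instruments carry
    more than half the weight; SE by seeded parametric bootstrap."""
    if h.k < 3:
        raise ValueError("weighted_median requires k >= 3")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    wr = h.se_ratio ** -2.0
    beta = _weighted_median(h.ratio, wr)

    def stat(bx, by):
        return _weighted_median(by / bx, (np.abs(bx) / h.se_out) ** 2)

    se = _bootstrap_se(h, stat, n_boot, rng)
    p = 2 * float(stats.norm.sf(abs(beta / se)))
    return _estimate("weighted_median", beta, se, p, h.k)


def _mode_point(ratio: np.ndarray, weight: np.ndarray, bandwidth_factor: float,
                grid_size: int = 512) -> float:
    """Argmax of the weighted normal-kernel density of the ratios.

    Bandwidth is the modified Silverman rule on the ratios:
    0.9 min(sd, mad/0.6745) k^(-1/5), scaled by ``bandwidth_factor``.
    """
    k = len(ratio)
    sd = float(np.std(ratio, ddof=1)) if k > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratio, scale="normal"))
    s = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 1e-8
    bw = bandwidth_factor * 0.9 * s * k ** (-1 / 5)
    grid = np.linspace(ratio.min() - 3 * bw, ratio.max() + 3 * bw, grid_size)
    w = weight / weight.sum()
    dens = (w[None, :] * stats.norm.pdf((grid[:, None] - ratio[None, :]) / bw)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    h: HarmonizedSet,
    variant: str = "weighted",
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MrEstimate:
    """Mode-based estimator: argmax of the kernel-smoothed density of the
    per-SNP ratios (simple = equal weights, weighted = se_ratio^-2 weights);
    consistent when the largest group of instruments is valid.  SE by
    seeded parametric bootstrap."""
    if variant not in ("simple", "weighted"):
        raise ValueError("variant must be 'simple' or 'weighted'")
    if h.k < 3:
        raise ValueError("mode_estimate requires k >= 3")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed

    def weights_for(bx):
        if variant == "simple":
            return np.ones(h.k)
        return (np.abs(bx) / h.se_out) ** 2

    beta = _mode_point(h.ratio, weights_for(h.beta_exp), bandwidth_factor)

    def stat(bx, by):
        return _mode_point(by / bx, weights_for(bx), bandwidth_factor)

    se = _bootstrap_se(h, stat, n_boot, rng)
    p = 2 * float(stats.norm.sf(abs(beta / se)))
    return _estimate(f"{variant}_mode", beta, se, p, h.k)


def q_pvalue(q: float, df: int) -> float:
    """Upper-tail chi-square probability of a heterogeneity statistic."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(q, df))


def cochran_q(h: HarmonizedSet, model: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q about the fixed-effect IVW or Egger fit.

    Q = sum_j se_out_j^-2 (beta_out_j - fitted_j)^2 with df k-1 (ivw) or
    k-2 (egger); p is the upper chi-square tail.
    """
    if model == "ivw":
        if h.k < 2:
            raise ValueError("cochran_q(ivw) requires k >= 2")
        _, _, q = _ivw_slope(h)
        df = h.k - 1
    elif model == "egger":
        est = egger(h)  # enforces k >= 3
        q = est.extras["Q"]
        df = h.k - 2
    else:
        raise ValueError("model must be 'ivw' or 'egger'")
    return HeterogeneityResult(model, q, df, q_pvalue(q, df))


@dataclass(frozen=True, slots=True)
class PressoResult:
    global_rss: float
    global_p: float
    outlier_p: np.ndarray      # Bonferroni-adjusted per-SNP p-values
    outlier_flags: np.ndarray  # boolean, at alpha
    n_sim: int


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slope for each SNP (vectorized)."""
    num = bx * by * w
    den = bx * bx * w
    return (num.sum() - num) / (den.sum() - den)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global and per-SNP outlier test.

    The observed weighted residual sum of squares about leave-one-out IVW
    fits is ranked against ``n_sim`` parametric simulations under the
    fitted no-outlier model; the global p is the simulation tail
    probability and per-SNP outlier p-values are the tails of each SNP's
    simulated residual distribution, Bonferroni-adjusted by k.
    """
    if h.k < 4:
        raise ValueError("mr_presso requires k >= 4")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    w = h.weight
    loo = _loo_slopes(h.beta_exp, h.beta_out, w)
    obs_res2 = w * (h.beta_out - loo * h.beta_exp) ** 2
    obs_rss = float(obs_res2.sum())

    # simulate under the no-outlier model: expected outcome beta of SNP j is
    # its leave-one-out fitted value
    bx_sim = rng.normal(h.beta_exp, h.se_exp, size=(n_sim, h.k))
    by_sim = rng.normal(loo * h.beta_exp, h.se_out, size=(n_sim, h.k))
    num = bx_sim * by_sim * w
    den = bx_sim * bx_sim * w
    loo_sim = (num.sum(axis=1, keepdims=True) - num) / (den.sum(axis=1, keepdims=True) - den)
    sim_res2 = w * (by_sim - loo_sim * bx_sim) ** 2
    sim_rss = sim_res2.sum(axis=1)

    global_p = (1 + int(np.sum(sim_rss >= obs_rss))) / (n_sim + 1)
    tail = (1 + (sim_res2 >= obs_res2[None, :]).sum(axis=0)) / (n_sim + 1)
    outlier_p = np.minimum(1.0, tail * h.k)
    return PressoResult(obs_rss, global_p, outlier_p, outlier_p < alpha, n_sim)


@dataclass(frozen=True, slots=True)
class LeaveOneOutResult:
    rows: pd.DataFrame          # excluded snp_id, beta, se, p, or + CI
    full: MrEstimate            # all-SNP reference estimate
    influential: bool           # any row outside the full-set CI


def leave_one_out(h: HarmonizedSet, random_effects: bool = True) -> LeaveOneOutResult:
    """IVW re-estimated k times, each with one SNP removed."""
    if h.k < 3:
        raise ValueError("leave_one_out requires k >= 3")
    full = ivw(h, random_effects=random_effects)
    rows = []
    influential = False
    for i, snp in enumerate(h.snp_ids):
        est = ivw(h.drop(i), random_effects=random_effects)
        outside = not (full.ci_low <= est.or_point <= full.ci_high)
        influential |= outside
        rows.append(
            {"excluded": snp, "beta": est.beta, "se": est.se, "p": est.p,
             "or": est.or_point, "ci_low": est.ci_low, "ci_high": est.ci_high,
             "outside_full_ci": outside}
        )
    return LeaveOneOutResult(pd.DataFrame(rows), full, influential)


def all_estimates(
    h: HarmonizedSet,
    n_boot: int = 1000,
    bandwidth_factor: float = 1.0,
    seed: int | np.random.Generator = 0,
    random_effects: bool = True,
) -> list[MrEstimate]:
    """The five-estimator bundle in the conventional reporting order,
    skipping (with a log line) estimators whose k precondition fails."""
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    out: list[MrEstimate] = []
    specs = [
        ("egger", lambda: egger(h)),
        ("weighted_median", lambda: weighted_median(h, n_boot, rng)),
        ("ivw", lambda: ivw(h, random_effects)),
        ("simple_mode", lambda: mode_estimate(h, "simple", bandwidth_factor, n_boot, rng)),
        ("weighted_mode", lambda: mode_estimate(h, "weighted", bandwidth_factor, n_boot, rng)),
    ]
    for name, fn in specs:
        try:
            out.append(fn())
        except ValueError as exc:
            log.info("all_estimates: skipping %s (%s)", name, exc)
    return out


# --- GWAS summary-statistics I/O ------------------------------------------

#: default logical -> column names for GWAS summary TSV
GWAS_COLUMNS = {
    "snp_id": "snp_id", "chrom": "chrom", "pos": "pos",
    "effect_allele": "effect_allele", "other_allele": "other_allele",
    "eaf": "eaf", "beta": "beta", "se": "se", "p": "p", "n": "n",
}


def read_gwas(path: str | Path, columns: Mapping[str, str] | None = None) -> list[SnpAssociation]:
    """Read whitespace/tab-delimited GWAS summary statistics.

    ``columns`` maps the logical names of :data:`GWAS_COLUMNS` to the
    file's header names for nonstandard dialects.
    """
    cols = dict(GWAS_COLUMNS)
    cols.update(columns or {})
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [src for src in cols.values() if src not in df.columns and src != cols["n"]]
    if missing:
        raise ValueError(f"GWAS file missing columns: {missing}")
    has_n = cols["n"] in df.columns
    out = []
    for i in range(len(df)):
        row = df.iloc[i]
        out.append(
            SnpAssociation(
                snp_id=str(row[cols["snp_id"]]),
                chrom=str(row[cols["chrom"]]),
                pos=int(row[cols["pos"]]),
                effect_allele=str(row[cols["effect_allele"]]).upper(),
                other_allele=str(row[cols["other_allele"]]).upper(),
                eaf=float(row[cols["eaf"]]),
                beta=float(row[cols["beta"]]),
                se=float(row[cols["se"]]),
                p=float(row[cols["p"]]),
                n=int(row[cols["n"]]) if has_n else 0,
            )
        )
    return out


def write_gwas(assocs: Iterable[SnpAssociation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "snp_id": s.snp_id, "chrom": s.chrom, "pos": s.pos,
                "effect_allele": s.effect_allele, "other_allele": s.other_allele,
                "eaf": s.eaf, "beta": s.beta, "se": s.se, "p": s.p, "n": s.n,
            }
            for s in assocs
        ]
    ).to_csv(path, sep="\t", index=False)


def estimates_table(estimates: Sequence[MrEstimate]) -> pd.DataFrame:
    """Estimates in the standard reporting layout (method, k, OR CI, p)."""
    return pd.DataFrame(
        [
            {
                "method": e.method, "n_snps": e.k_snps, "beta": e.beta, "se": e.se,
                "or": e.or_point, "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.p,
            }
            for e in estimates
        ]
    )
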