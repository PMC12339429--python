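"""Disproportionality analysis of drug x event reporting.

Builds the 2x2 contingency table for a (drug, PT) pair over a deduplicated
report set and computes the three classical spontaneous-reporting signal
statistics:

* ROR, the reporting odds ratio ad/bc with a log-normal 95% CI
  (signal when a >= 3 and the CI lower bound > 1);
* PRR, the proportional reporting ratio [a/(a+b)] / [c/(c+d)] with the
  Pearson chi-square of the table (signal when a >= 3, PRR >= 2, chi2 >= 4);
* IC, the shrinkage information component log2 of observed-to-expected
  co-reporting with its lower 95% credibility bound IC025
  (signal when IC025 > 0).

A pair is declared an overall signal when at least two of the three methods
flag it.  ``volcano_stats`` supplies the per-PT Fisher-exact / Bonferroni
statistics behind a volcano plot of all events co-reported with a drug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reports import ReportSet

Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Counts for one drug x event pair.

    a: target drug and target event; b: target drug, other events;
    c: other drugs, target event; d: neither.  A report contributes to
    exactly one cell.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Expected count in cell a under drug/event independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def haldane(self) -> tuple[float, float, float, float]:
        """All four cells with the Haldane–Anscombe 0.5 added."""
        return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    def doubled(self) -> "ContingencyTable":
        return ContingencyTable(2 * self.a, 2 * self.b, 2 * self.c, 2 * self.d)


@dataclass(frozen=True, slots=True)
class SignalStat:
    """One method's statistic for one table.

    ``interval_high`` is None for IC (only the lower bound IC025 is used);
    ``chi2`` is set for PRR only.  ``corrected`` marks a Haldane–Anscombe
    zero-cell correction.
    """

    method: str
    point: float
    interval_low: float
    interval_high: float | None
    flag: bool
    chi2: float | None = None
    corrected: bool = False


@dataclass(frozen=True, slots=True)
class SignalResult:
    drug: str
    pt: str
    table: ContingencyTable
    stats: tuple[SignalStat, ...]
    n_positive_methods: int = field(init=False)
    is_signal: bool = field(init=False)

    def __post_init__(self) -> None:
        n_pos = sum(s.flag for s in self.stats)
        object.__setattr__(self, "n_positive_methods", n_pos)
        object.__setattr__(self, "is_signal", n_pos >= 2)

    def stat(self, method: str) -> SignalStat:
        for s in self.stats:
            if s.method == method:
                return s
        raise KeyError(method)


def contingency_table(rs: ReportSet, drug: str, pt: int | str) -> ContingencyTable:
    """Count reports into the 2x2 table for (drug, pt).

    Membership is set-valued: a report listing the drug or the PT any number
    of times contributes once.
    """
    if len(rs) == 0:
        raise ValueError("empty ReportSet")
    from .reports import normalize_drug_name

    drug_norm = normalize_drug_name(drug)
    by_code = isinstance(pt, int)
    a = b = c = d = 0
    for r in rs:
        has_d = drug_norm in r.drugs
        has_e = pt in r.pt_codes if by_code else r.has_pt(pt)
        if has_d and has_e:
            a += 1
        elif has_d:
            b += 1
        elif has_e:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def ror(t: ContingencyTable) -> SignalStat:
    """Reporting odds ratio with log-normal 95% CI.

    Signal criterion: a >= 3 and CI lower bound > 1.  Any zero cell triggers
    the Haldane–Anscombe correction (0.5 to all four cells), marked in the
    result.
    """
    corrected = 0 in (t.a, t.b, t.c, t.d)
    a, b, c, d = t.haldane() if corrected else (t.a, t.b, t.c, t.d)
    point = (a * d) / (b * c)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(point) - Z95 * se_log)
    hi = math.exp(math.log(point) + Z95 * se_log)
    flag = t.a >= 3 and lo > 1.0
    return SignalStat("ROR", point, lo, hi, flag, corrected=corrected)


def chi_square(t: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-square of the 2x2 table (optional Yates correction)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    num = abs(a * d - b * c)
    if yates:
        num = max(0.0, num - n / 2)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("chi-square undefined: zero margin")
    return n * num * num / denom


def prr(t: ContingencyTable, yates: bool = False) -> SignalStat:
    """Proportional reporting ratio with the table's Pearson chi-square.

    Signal criterion: a >= 3, PRR >= 2 and chi2 >= 4.  Zero row margins are
    a domain error; a zero in c alone is handled with the Haldane
    correction so the point estimate stays finite.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("PRR undefined: zero row margin")
    corrected = t.c == 0
    a, b, c, d = t.haldane() if corrected else (t.a, t.b, t.c, t.d)
    point = (a / (a + b)) / (c / (c + d))
    chi2 = chi_square(t, yates=yates)
    flag = t.a >= 3 and point >= 2.0 and chi2 >= 4.0
    return SignalStat("PRR", point, float("nan"), None, flag, chi2=chi2, corrected=corrected)


def ic(t: ContingencyTable) -> SignalStat:
    """Shrinkage information component with its lower 95% bound IC025.

    IC = log2((a + 0.5) / (E[a] + 0.5)) where E[a] = (a+b)(a+c)/N;
    IC025 = IC - 3.3 (a+0.5)^(-1/2) - 2 (a+0.5)^(-3/2).
    Signal criterion: IC025 > 0.  The shrinkage makes all cells safe.
    """
    expected = t.expected_a
    point = math.log2((t.a + 0.5) / (expected + 0.5))
    shrink = 3.3 * (t.a + 0.5) ** -0.5 + 2.0 * (t.a + 0.5) ** -1.5
    ic025 = point - shrink
    return SignalStat("IC", point, ic025, None, ic025 > 0)


def classify_signal(
    drug: str,
    pt: str,
    table: ContingencyTable,
    yates: bool = False,
) -> SignalResult:
    """Compute all three statistics on one table and apply the 2-of-3 rule."""
    return SignalResult(drug, pt, table, (ror(table), prr(table, yates=yates), ic(table)))


def volcano_stats(rs: ReportSet, drug: str) -> pd.DataFrame:
    """Fisher-exact / Bonferroni statistics for every PT co-reported with a drug.

    One row per distinct PT appearing on at least one report that lists the
    drug, with the two-sided Fisher exact p of that PT's 2x2 table, the
    Bonferroni-adjusted p (m = number of PTs tested for this drug), the
    log10 ROR for the x axis and -log10(adjusted p) for the y axis.
    """
    if len(rs) == 0:
        raise ValueError("empty ReportSet")
    seen: set[tuple[int, str]] = set()
    for r in rs:
        if r.has_drug(drug):
            seen |= set(r.pts)
    pts = sorted(seen)
    m = len(pts)
    rows = []
    for code, name in pts:
        t = contingency_table(rs, drug, code)
        _, p_fisher = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
        p_bonf = min(1.0, p_fisher * m)
        r_stat = ror(t)
        rows.append(
            {
                "pt_code": code,
                "pt_name": name,
                "n": t.a,
                "log_ror": math.log10(r_stat.point),
                "p_fisher": p_fisher,
                "p_bonferroni": p_bonf,
                "neg_log10_p": -math.log10(p_bonf) if p_bonf > 0 else math.inf,
            }
        )
    return pd.DataFrame(rows)


def signal_table(rs: ReportSet, drug: str, pts: list[int | str] | None = None,
                 yates: bool = False) -> pd.DataFrame:
    """One row per drug x PT with counts, all statistics, flags and verdict.

    ``pts`` defaults to every PT co-reported with the drug.
    """
    if pts is None:
        seen = set()
        for r in rs:
            if r.has_drug(drug):
                seen |= set(r.pts)
        pt_list: list[tuple[int, str]] = sorted(seen)
    else:
        names = {code: name for r in rs for code, name in r.pts}
        pt_list = [(p, names.get(p, "")) if isinstance(p, int) else (-1, p) for p in pts]
    rows = []
    for code, name in pt_list:
        t = contingency_table(rs, drug, code if code >= 0 else name)
        res = classify_signal(drug, name or str(code), t, yates=yates)
        r_s, p_s, i_s = res.stats
        rows.append(
            {
                "drug": drug,
                "pt_code": code,
                "pt_name": name,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "ror": r_s.point, "ror_ci_low": r_s.interval_low,
                "ror_ci_high": r_s.interval_high, "ror_flag": r_s.flag,
                "prr": p_s.point, "chi2": p_s.chi2, "prr_flag": p_s.flag,
                "ic": i_s.point, "ic025": i_s.interval_low, "ic_flag": i_s.flag,
                "n_positive_methods": res.n_positive_methods,
                "is_signal": res.is_signal,
            }
        )
    return pd.DataFrame(rows)
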