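"""Disproportionality statistics and the joint four-algorithm signal rule.

For a 2x2 table (a, b, c, d) with N = a+b+c+d the package computes:

* ROR  = (a/c)/(b/d) = ad/bc, with the log-symmetric 95% interval
  exp(ln ROR +/- 1.96*sqrt(1/a + 1/b + 1/c + 1/d));
* PRR  = [a/(a+b)] / [c/(c+d)], with interval
  exp(ln PRR +/- 1.96*sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)));
* Pearson chi-squared, N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)), optionally with
  the Yates continuity correction (report-only, not part of the signal rule);
* the BCPNN information component IC = log2(aN/((a+b)(a+c))) together with
  its posterior expectation E(IC), variance V(IC) under Dirichlet/Beta
  priors, and the lower credibility bound IC025 = E(IC) - 2*sqrt(V(IC));
* EBGM = aN/((a+b)(a+c)) — the relative reporting ratio, identical to 2^IC —
  with the same log-symmetric interval as the ROR; its lower bound is EBGM05.

A drug-event pair is a *signal* only when every algorithm's threshold is met
simultaneously with at least ``min_a`` (3) reports: ROR >= 2 with lower CI
bound > 1, PRR >= 2 with lower CI bound > 1, IC025 > 0 and EBGM05 > 2.
Statistics on tables with a < 3 or with a zero in b, c or d are marked
not-applicable (NaN) and fail their criterion; no continuity correction is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

from .contingency import ContingencyTable, EventTableSet

Z95 = 1.96
NA = float("nan")


@dataclass(frozen=True)
class BcpnnPriors:
    """Hyperparameters of the BCPNN closed-form posterior.

    ``gamma_ij`` is the Dirichlet prior count on the joint (drug, event)
    cell; ``alpha_i``/``beta_j`` the Beta prior counts on the drug and event
    margins; ``alpha``/``beta`` their totals. The defaults (1, 1, 1, 2, 2)
    are the standard single-drug/single-event choice, under which an exactly
    independent table has E(IC) = 0.
    """

    gamma_ij: float = 1.0
    alpha_i: float = 1.0
    beta_j: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        for name in ("gamma_ij", "alpha_i", "beta_j", "alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior {name} must be positive")


@dataclass(frozen=True)
class Thresholds:
    """Signal thresholds; defaults follow the four-algorithm criterion."""

    min_a: int = 3
    ror_min: float = 2.0
    ror_ci_lo_min: float = 1.0
    prr_min: float = 2.0
    prr_ci_lo_min: float = 1.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0


DEFAULT_PRIORS = BcpnnPriors()
DEFAULT_THRESHOLDS = Thresholds()


def _applicable(t: ContingencyTable, min_a: int) -> bool:
    return t.a >= min_a and t.b > 0 and t.c > 0 and t.d > 0


def _log_symmetric_ci(point: float, se_log: float) -> tuple[float, float]:
    half = Z95 * se_log
    return point * math.exp(-half), point * math.exp(half)


def compute_ror(
    t: ContingencyTable, min_a: int = 3
) -> tuple[float, float, float]:
    """Reporting odds ratio ad/(bc) with 95% CI; NaN triple if a < min_a or
    any of b, c, d is zero."""
    if not _applicable(t, min_a):
        return NA, NA, NA
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    lo, hi = _log_symmetric_ci(ror, se)
    return ror, lo, hi


def compute_prr(
    t: ContingencyTable, min_a: int = 3
) -> tuple[float, float, float]:
    """Proportional reporting ratio [a/(a+b)]/[c/(c+d)] with 95% CI."""
    if not _applicable(t, min_a):
        return NA, NA, NA
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se = math.sqrt(1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d))
    lo, hi = _log_symmetric_ci(prr, se)
    return prr, lo, hi


def compute_chi2(t: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-squared for the 2x2 table; 0 for degenerate margins.

    With ``yates``, |ad - bc| is reduced by N/2 (floored at zero) before
    squaring. Chi-squared is reported alongside the signal table but plays
    no part in the joint criterion.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    return n * diff * diff / denom


def compute_bcpnn(
    t: ContingencyTable, priors: BcpnnPriors = DEFAULT_PRIORS
) -> tuple[float, float, float, float]:
    """BCPNN information component: (IC, E(IC), V(IC), IC025).

    IC is the observed log2 ratio of the joint reporting probability to the
    product of its margins. E(IC) and V(IC) are the closed-form posterior
    moments under the Dirichlet/Beta priors; IC025 = E(IC) - 2*sqrt(V(IC)).
    Degenerate margins (a+b = 0 or a+c = 0) return NaNs for IC only; the
    posterior moments remain defined through the priors.
    """
    a = t.a
    n = t.n
    row = t.a + t.b
    col = t.a + t.c
    ic = math.log2(a * n / (row * col)) if a > 0 and row > 0 and col > 0 else NA

    g_ij, a_i, b_j, al, be = (
        priors.gamma_ij,
        priors.alpha_i,
        priors.beta_j,
        priors.alpha,
        priors.beta,
    )
    gamma = g_ij * (n + al) * (n + be) / ((row + a_i) * (col + b_j))
    e_ic = math.log2(
        (a + g_ij) * (n + al) * (n + be) / ((n + gamma) * (row + a_i) * (col + b_j))
    )
    ln2_sq = math.log(2) ** 2
    v_ic = (
        (n - a + gamma - g_ij) / ((a + g_ij) * (1 + n + gamma))
        + (n - row + al - a_i) / ((row + a_i) * (1 + n + al))
        + (n - col + be - b_j) / ((col + b_j) * (1 + n + be))
    ) / ln2_sq
    ic025 = e_ic - 2.0 * math.sqrt(v_ic)
    return ic, e_ic, v_ic, ic025


def compute_ebgm(
    t: ContingencyTable, min_a: int = 3
) -> tuple[float, float, float]:
    """Relative reporting ratio aN/((a+b)(a+c)) with log-symmetric 95% CI.

    Equals 2**IC exactly. The lower bound is the EBGM05 used by the signal
    criterion. No empirical-Bayes shrinkage is applied (none is defined for
    this closed form).
    """
    if not _applicable(t, min_a):
        return NA, NA, NA
    ebgm = t.a * t.n / ((t.a + t.b) * (t.a + t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    lo, hi = _log_symmetric_ci(ebgm, se)
    return ebgm, lo, hi


@dataclass
class SignalStatistics:
    """Every statistic for one drug-event 2x2 table plus the joint decision."""

    a: int
    ror: float = NA
    ror_lo: float = NA
    ror_hi: float = NA
    prr: float = NA
    prr_lo: float = NA
    prr_hi: float = NA
    chi2: float = NA
    ic: float = NA
    ic_expect: float = NA
    ic_var: float = NA
    ic025: float = NA
    ebgm: float = NA
    ebgm05: float = NA
    ebgm95: float = NA
    flags: dict[str, bool] = field(default_factory=dict)
    signal: bool = False


def evaluate_signal(
    stats: SignalStatistics, th: Thresholds = DEFAULT_THRESHOLDS
) -> SignalStatistics:
    """Apply the joint criterion; NaN statistics fail their flag.

    Point thresholds are inclusive (>=); CI-bound thresholds are strict (>).
    """
    flags = {
        "min_a": stats.a >= th.min_a,
        "ror": stats.ror >= th.ror_min and stats.ror_lo > th.ror_ci_lo_min,
        "prr": stats.prr >= th.prr_min and stats.prr_lo > th.prr_ci_lo_min,
        "bcpnn": stats.ic025 > th.ic025_min,
        "ebgm": stats.ebgm05 > th.ebgm05_min,
    }
    return replace(stats, flags=flags, signal=all(flags.values()))


def compute_all(
    t: ContingencyTable,
    th: Thresholds = DEFAULT_THRESHOLDS,
    priors: BcpnnPriors = DEFAULT_PRIORS,
    yates: bool = False,
) -> SignalStatistics:
    """All five statistics plus the joint signal decision for one table."""
    ror, ror_lo, ror_hi = compute_ror(t, th.min_a)
    prr, prr_lo, prr_hi = compute_prr(t, th.min_a)
    chi2 = compute_chi2(t, yates=yates)
    ic, e_ic, v_ic, ic025 = compute_bcpnn(t, priors)
    ebgm, ebgm05, ebgm95 = compute_ebgm(t, th.min_a)
    stats = SignalStatistics(
        a=t.a,
        ror=ror, ror_lo=ror_lo, ror_hi=ror_hi,
        prr=prr, prr_lo=prr_lo, prr_hi=prr_hi,
        chi2=chi2,
        ic=ic, ic_expect=e_ic, ic_var=v_ic, ic025=ic025,
        ebgm=ebgm, ebgm05=ebgm05, ebgm95=ebgm95,
    )
    return evaluate_signal(stats, th)


def signal_table(
    table_set: EventTableSet,
    th: Thresholds = DEFAULT_THRESHOLDS,
    priors: BcpnnPriors = DEFAULT_PRIORS,
    yates: bool = False,
) -> dict[str, SignalStatistics]:
    """Statistics for every event in a table set, keyed by event name."""
    return {
        event: compute_all(t, th, priors, yates)
        for event, t in table_set.tables.items()
    }


_CSV_FIELDS = [
    "a", "ror", "ror_lo", "ror_hi", "prr", "prr_lo", "prr_hi", "chi2",
    "ic", "ic_expect", "ic_var", "ic025", "ebgm", "ebgm05", "ebgm95",
]
_FLAG_FIELDS = ["min_a", "ror", "prr", "bcpnn", "ebgm"]


def write_signal_csv(
    stats_by_event: dict[str, SignalStatistics], path: Union[str, Path]
) -> Path:
    """One row per event: full-precision statistics, a 2-decimal display
    column in the conventional ``point (lo, hi)`` style, per-criterion flags
    and the decision."""
    path = Path(path)
    header = (
        ["event"] + _CSV_FIELDS + ["ror_display"]
        + [f"flag_{f}" for f in _FLAG_FIELDS] + ["signal"]
    )
    lines = [",".join(header)]
    for event, s in stats_by_event.items():
        escaped = '"' + event.replace('"', '""') + '"' if "," in event else event
        display = (
            f"{s.ror:.2f} ({s.ror_lo:.2f}, {s.ror_hi:.2f})"
            if not math.isnan(s.ror)
            else "NA"
        )
        row = [escaped]
        row += [repr(getattr(s, fld)) for fld in _CSV_FIELDS]
        row += ['"' + display + '"']
        row += [str(s.flags.get(f, False)) for f in _FLAG_FIELDS]
        row.append(str(s.signal))
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
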