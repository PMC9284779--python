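"""Two-stage meta-analysis of odds ratios.

Per-study effects enter either as 2x2 counts or as summaries (log-OR and
standard error, recoverable from a published OR with its 95% CI).  Pooling:

* fixed effects, inverse variance:  b = sum(w b_i)/sum(w),  w = 1/se^2
* fixed effects, Mantel-Haenszel on counts, with the
  Robins-Breslow-Greenland variance for the CI
* random effects, DerSimonian-Laird:
  tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),
  then inverse variance with weights 1/(se^2 + tau2)

Heterogeneity is Cochran's Q with a chi-square upper-tail p at k-1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

Z95 = 1.959964


@dataclass
class StudyEffect:
    """One study's effect, as a summary (b, se) or a 2x2 count table."""

    label: str
    b: float | None = None
    se: float | None = None
    counts: tuple[float, float, float, float] | None = None  # a, b, c, d

    def __post_init__(self) -> None:
        if self.counts is not None:
            a, bb, c, d = self.counts
            if min(a, bb, c, d) < 0:
                raise ValueError("negative cell count")
            if self.b is None:
                a2, b2, c2, d2 = [x + 0.5 if 0 in self.counts else x
                                  for x in self.counts]
                self.b = float(np.log(a2 * d2 / (b2 * c2)))
                self.se = float(np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2))
        if self.b is None or self.se is None:
            raise ValueError("study needs either counts or (b, se)")
        if self.se <= 0:
            raise ValueError("standard error must be positive")

    @property
    def weight(self) -> float:
        return 1.0 / self.se**2


@dataclass
class MetaResult:
    method: str  # "FE-IV" | "FE-MH" | "RE-DL"
    b: float
    se: float
    Q: float
    df: int
    q_p: float
    tau2: float = 0.0
    warning: str | None = None

    @property
    def OR(self) -> float:
        return float(np.exp(self.b))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.b - Z95 * self.se)),
                float(np.exp(self.b + Z95 * self.se)))

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.b / self.se)))


def logor_from_or_ci(or_: float, ci_low: float, ci_high: float
                     ) -> tuple[float, float]:
    """Recover (log-OR, SE) from a published OR with its 95% CI.

    se = (ln(hi) - ln(lo)) / (2 * 1.959964); rejects degenerate or
    non-positive inputs.
    """
    if min(or_, ci_low, ci_high) <= 0:
        raise ValueError("OR and CI bounds must be positive")
    if not (ci_low <= or_ <= ci_high):
        raise ValueError("CI must bracket the OR")
    se = (np.log(ci_high) - np.log(ci_low)) / (2 * Z95)
    if se <= 0:
        raise ValueError("degenerate CI: SE must be positive")
    return float(np.log(or_)), float(se)


def _q_stat(b: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    pooled = float(np.sum(w * b) / np.sum(w))
    return float(np.sum(w * (b - pooled) ** 2)), pooled


def fixed_effects_iv(studies: list[StudyEffect]) -> MetaResult:
    """Inverse-variance fixed-effects pooling of summary effects."""
    if not studies:
        raise ValueError("need at least one study")
    b = np.array([s.b for s in studies])
    w = np.array([s.weight for s in studies])
    Q, pooled = _q_stat(b, w)
    df = len(studies) - 1
    q_p = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0
    return MetaResult("FE-IV", pooled, float(1.0 / np.sqrt(w.sum())),
                      Q, df, q_p)


def cochran_q(studies: list[StudyEffect]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic with chi-square p at k-1 df."""
    if len(studies) < 2:
        raise ValueError("heterogeneity needs at least 2 studies")
    r = fixed_effects_iv(studies)
    return r.Q, r.df, r.q_p


def dersimonian_laird(studies: list[StudyEffect]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    With a single study returns the fixed-effects result with a warning.
    tau2 is truncated at zero, so homogeneous inputs reduce exactly to
    inverse-variance fixed effects.
    """
    if not studies:
        raise ValueError("need at least one study")
    if len(studies) == 1:
        fe = fixed_effects_iv(studies)
        return MetaResult("RE-DL", fe.b, fe.se, fe.Q, fe.df, fe.q_p,
                          tau2=0.0, warning="single study: no heterogeneity")
    b = np.array([s.b for s in studies])
    w = np.array([s.weight for s in studies])
    Q, _ = _q_stat(b, w)
    df = len(studies) - 1
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (1.0 / w + tau2)
    pooled = float(np.sum(w_re * b) / np.sum(w_re))
    se = float(1.0 / np.sqrt(w_re.sum()))
    return MetaResult("RE-DL", pooled, se, Q, df,
                      float(stats.chi2.sf(Q, df)), tau2=tau2)


def mantel_haenszel(count_tables: list[tuple[float, float, float, float]],
                    ) -> MetaResult:
    """Mantel-Haenszel fixed-effects pooled OR from 2x2 strata (a, b, c, d).

    Variance of the log pooled OR by Robins-Breslow-Greenland.
    """
    if not count_tables:
        raise ValueError("need at least one stratum")
    a = np.array([t[0] for t in count_tables], float)
    b = np.array([t[1] for t in count_tables], float)
    c = np.array([t[2] for t in count_tables], float)
    d = np.array([t[3] for t in count_tables], float)
    n = a + b + c + d
    R = a * d / n
    S = b * c / n
    if R.sum() == 0 or S.sum() == 0:
        raise ValueError("MH odds ratio undefined: zero numerator/denominator")
    or_mh = R.sum() / S.sum()
    P = (a + d) / n
    Qv = (b + c) / n
    var = (np.sum(P * R) / (2 * R.sum() ** 2)
           + np.sum(P * S + Qv * R) / (2 * R.sum() * S.sum())
           + np.sum(Qv * S) / (2 * S.sum() ** 2))
    # heterogeneity from the per-stratum Woolf effects
    studies = []
    for k, t in enumerate(count_tables):
        try:
            studies.append(StudyEffect(f"stratum{k}", counts=t))
        except ValueError:
            continue
    if len(studies) >= 2:
        Q, df, q_p = cochran_q(studies)
    else:
        Q, df, q_p = 0.0, 0, 1.0
    return MetaResult("FE-MH", float(np.log(or_mh)), float(np.sqrt(var)),
                      Q, df, q_p)


def meta_from_or_ci(label: str, stage_summaries: list[tuple[float, float, float]]
                    ) -> dict[str, MetaResult]:
    """Convenience: pool printed (OR, lo, hi) stage summaries, FE + RE."""
    studies = [
        StudyEffect(f"{label}_stage{k + 1}", *logor_from_or_ci(*s))
        for k, s in enumerate(stage_summaries)
    ]
    return {"FE": fixed_effects_iv(studies), "RE": dersimonian_laird(studies)}
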