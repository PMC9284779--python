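"""Case-control association: additive logistic regression, haplotype odds
ratios with Fisher exact p-values, per-block omnibus tests, stratified
subsets and Benjamini-Hochberg FDR.

Per-haplotype effects are estimated two ways, matching common reporting:
a Wald test from an additive-dosage logistic model (with principal-component
covariates), and a sample odds ratio on chromosome-level counts against the
most common haplotype, with a two-sided Fisher exact p.  The per-block
signal is an omnibus likelihood-ratio test of all non-reference haplotype
dosages jointly against a covariates-only model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

Z95 = 1.959964


@dataclass
class AssocResult:
    unit: str  # "variant" | "block" | "haplotype"
    label: str
    beta: float = np.nan
    se: float = np.nan
    p_wald: float = np.nan
    p_lrt: float = np.nan
    p_fisher: float = np.nan
    fdr_q: float = np.nan
    n_case: int = 0
    n_control: int = 0
    reference: str | None = None
    df: int | None = None
    flagged: str | None = None  # separation / non-convergence / zero-cell note

    @property
    def OR(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.beta - Z95 * self.se)),
                float(np.exp(self.beta + Z95 * self.se)))


def _design(dosage: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(len(dosage))]
    d = np.atleast_2d(np.asarray(dosage, dtype=float))
    if d.shape[0] == 1 and d.shape[1] == len(dosage) and d.ndim == 2:
        d = d.T
    cols.append(d)
    if covariates is not None and np.size(covariates):
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        cols.append(c)
    return np.column_stack(cols)


def logistic_additive(
    dosage: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    label: str = "dosage",
) -> AssocResult:
    """Additive logistic regression of case status on one dosage column.

    Fits by iteratively reweighted least squares (Newton); returns the Wald
    log-OR, SE and p for the dosage term.  Perfect separation and
    non-convergence are flagged on the result rather than silently returned.
    """
    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status)
    if dosage.std() == 0:
        raise ValueError("zero-variance dosage")
    X = _design(dosage, covariates)
    res = AssocResult("variant", label,
                      n_case=int(status.sum()),
                      n_control=int(len(status) - status.sum()))
    try:
        fit = sm.Logit(status, X).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        res.flagged = f"separation: {exc}"
        return res
    if not fit.mle_retvals.get("converged", True):
        res.flagged = "non-convergence"
    res.beta = float(fit.params[1])
    res.se = float(fit.bse[1])
    res.p_wald = float(fit.pvalues[1])
    return res


def _drop_aliased(X: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Remove linearly dependent columns (keep leftmost), return kept indices."""
    from scipy.linalg import qr as _qr

    _, r, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    return X[:, keep], keep


def block_omnibus_test(
    dosage_matrix: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    label: str = "block",
) -> AssocResult:
    """Likelihood-ratio omnibus test of a block's haplotype dosages.

    ``dosage_matrix`` holds the non-reference haplotype dosages (the most
    common haplotype is excluded to break the rows-sum-to-2 collinearity).
    The full model (dosages + covariates) is compared with a covariates-only
    model; df = number of dosage columns retained after dropping aliased
    ones.
    """
    D = np.asarray(dosage_matrix, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    status = np.asarray(status)
    ok = ~np.isnan(D).any(axis=1)
    D, status = D[ok], status[ok]
    cov = None if covariates is None else np.asarray(covariates, float)[ok]
    if D.shape[1] == 0:
        raise ValueError("no non-reference haplotypes to test (df = 0)")

    base_cols = [np.ones(len(status))]
    if cov is not None and np.size(cov):
        c = cov if cov.ndim == 2 else cov[:, None]
        base_cols.append(c)
    X0 = np.column_stack(base_cols)
    X1_raw = np.column_stack([X0, D])
    X1, keep = _drop_aliased(X1_raw)
    n_base = X0.shape[1]
    df = sum(1 for k in keep if k >= n_base)
    if df < X1_raw.shape[1] - n_base:
        logger.info("omnibus: dropped %d aliased dosage columns",
                    X1_raw.shape[1] - n_base - df)
    if df == 0:
        raise ValueError("all dosage columns aliased (df = 0)")
    fit1 = sm.Logit(status, X1).fit(disp=0, maxiter=200)
    fit0 = sm.Logit(status, X0).fit(disp=0, maxiter=200)
    lr = 2.0 * (fit1.llf - fit0.llf)
    p = float(stats.chi2.sf(max(lr, 0.0), df))
    res = AssocResult("block", label, p_lrt=p, df=df,
                      n_case=int(status.sum()),
                      n_control=int(len(status) - status.sum()))
    if not fit1.mle_retvals.get("converged", True):
        res.flagged = "non-convergence"
    return res


def haplotype_or_fisher(
    target_case: int, target_control: int,
    ref_case: int, ref_control: int,
    label: str = "haplotype", reference: str = "reference",
) -> AssocResult:
    """Sample odds ratio and Fisher exact p for one haplotype vs the reference.

    Counts are chromosome-level (expected dosage sums rounded to integers).
    OR = (target_case * ref_control) / (target_control * ref_case), with a
    Woolf CI from log-OR +/- 1.96 * sqrt(sum 1/count); zero cells take a
    Haldane-Anscombe 0.5 correction for the OR/CI (flagged; the Fisher p is
    computed on the uncorrected table).
    """
    table = np.array([[target_case, target_control],
                      [ref_case, ref_control]], dtype=float)
    if (table < 0).any():
        raise ValueError("negative count")
    _, p_fisher = stats.fisher_exact(table, alternative="two-sided")
    flagged = None
    if (table == 0).any():
        table = table + 0.5
        flagged = "zero-cell: Haldane-Anscombe correction applied to OR/CI"
    beta = float(np.log(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0])))
    se = float(np.sqrt((1.0 / table).sum()))
    return AssocResult("haplotype", label, beta=beta, se=se,
                       p_fisher=float(p_fisher), reference=reference,
                       n_case=int(target_case + ref_case),
                       n_control=int(target_control + ref_control),
                       flagged=flagged)


def chromosome_counts(
    dosages: np.ndarray, status: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rounded chromosome-level haplotype counts in cases and controls."""
    d = np.nan_to_num(np.asarray(dosages, float), nan=0.0)
    status = np.asarray(status).astype(bool)
    case = np.rint(d[status].sum(axis=0)).astype(int)
    ctrl = np.rint(d[~status].sum(axis=0)).astype(int)
    return case, ctrl


def block_association(
    dosages: np.ndarray,
    status: np.ndarray,
    labels: list[str],
    covariates: np.ndarray | None = None,
    reference_index: int | None = None,
    block_id: str = "block",
) -> list[AssocResult]:
    """Per-block association bundle: omnibus LRT + per-haplotype OR/Fisher/Wald.

    ``dosages`` is the full individual-by-haplotype expected-count matrix;
    the reference (most common haplotype unless given) is excluded from the
    dosage design and used as the denominator of every 2x2 comparison.
    """
    dosages = np.asarray(dosages, float)
    freqs = np.nanmean(dosages, axis=0) / 2.0
    if reference_index is None:
        reference_index = int(np.argmax(freqs))
    non_ref = [k for k in range(dosages.shape[1]) if k != reference_index]
    results = [block_omnibus_test(dosages[:, non_ref], status, covariates,
                                  label=block_id)]
    case, ctrl = chromosome_counts(dosages, status)
    for k in non_ref:
        r = haplotype_or_fisher(case[k], ctrl[k],
                                case[reference_index], ctrl[reference_index],
                                label=labels[k],
                                reference=labels[reference_index])
        ok = ~np.isnan(dosages[:, k])
        if dosages[ok, k].std() > 0:
            cov_ok = None if covariates is None else \
                np.asarray(covariates, float)[ok]
            w = logistic_additive(dosages[ok, k], np.asarray(status)[ok],
                                  cov_ok, label=labels[k])
            r.p_wald = w.p_wald
        results.append(r)
    return results


def stratified_subset(indices: np.ndarray, *arrays):
    """Subset every array/frame to the given sample indices (e.g. H1/H1 only)."""
    if len(indices) == 0:
        raise ValueError("stratum contains zero samples")
    out = []
    for a in arrays:
        if isinstance(a, (pd.DataFrame, pd.Series)):
            out.append(a.iloc[indices].reset_index(drop=True))
        else:
            out.append(np.asarray(a)[indices])
    return out[0] if len(out) == 1 else tuple(out)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def results_frame(results: list[AssocResult]) -> pd.DataFrame:
    """Flatten AssocResults into the standard results table."""
    rows = []
    for r in results:
        lo, hi = r.ci95
        rows.append({
            "id": r.label, "type": r.unit, "beta": r.beta, "se": r.se,
            "OR": r.OR, "ci_low": lo, "ci_high": hi,
            "p_wald": r.p_wald, "p_lrt": r.p_lrt, "p_fisher": r.p_fisher,
            "fdr_q": r.fdr_q, "n_case": r.n_case, "n_control": r.n_control,
            "reference": r.reference, "flagged": r.flagged,
        })
    return pd.DataFrame(rows)
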