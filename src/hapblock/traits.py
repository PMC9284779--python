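"""Quantitative-trait association with sub-haplotype dosage.

The expression pathway mirrors the standard brain-eQTL recipe: per-dataset
covariate residualization (sex, age, post-mortem interval, RNA integrity),
z-scoring, concatenation across datasets, then linear regression of the
combined z-scores on non-reference haplotype dosages.  Copy-number traits
ride the same regression; dPCR quantification uses the standard Poisson
partition model (lambda = -ln(1 - positive fraction)), with copies per
genome obtained as a ratio to a two-copy reference assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class TraitAssocResult:
    trait: str
    haplotype: str
    beta: float
    se: float
    p: float
    r2: float
    n: int
    dataset: str = "combined"


@dataclass
class DPCRMeasurement:
    """One digital-PCR assay: positive partitions out of total."""

    target: str
    positives: int
    total: int
    volume_nl: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.positives <= self.total):
            raise ValueError("positives must lie in [0, total]")
        if self.total <= 0:
            raise ValueError("total partitions must be positive")

    @property
    def lam(self) -> float:
        """Mean molecules per partition, -ln(1 - positive fraction)."""
        frac = self.positives / self.total
        if frac >= 1.0:
            raise ValueError(f"{self.target}: saturated (all partitions "
                             "positive), cannot quantify")
        return float(-np.log1p(-frac))


def residualize(trait: np.ndarray, covariates: pd.DataFrame | np.ndarray
                ) -> np.ndarray:
    """OLS residuals of a trait on covariates (plus intercept).

    Rows with a missing trait or covariate are dropped (logged); the
    returned vector is aligned with the input and NaN at dropped rows.
    Residuals are orthogonal to the intercept and every covariate column.
    """
    y = np.asarray(trait, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    ok = np.isfinite(y) & np.isfinite(C).all(axis=1)
    if (~ok).any():
        logger.info("residualize: dropping %d incomplete rows", (~ok).sum())
    X = np.column_stack([np.ones(ok.sum()), C[ok]])
    beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    out = np.full(y.shape, np.nan)
    out[ok] = y[ok] - X @ beta
    return out


def zscore_combine(residuals_by_dataset: dict[str, np.ndarray]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each dataset's residuals (mean 0, sd 1, ddof=1), concatenate.

    Returns (combined z vector, dataset label array).  The concatenated
    vector is not re-standardized.
    """
    if not residuals_by_dataset:
        raise ValueError("need at least one dataset")
    zs, labels = [], []
    for name, r in residuals_by_dataset.items():
        r = np.asarray(r, dtype=float)
        ok = np.isfinite(r)
        if ok.sum() < 3:
            raise ValueError(f"dataset {name}: need >= 3 samples")
        mu = r[ok].mean()
        sd = r[ok].std(ddof=1)
        z = np.full(r.shape, np.nan)
        z[ok] = (r[ok] - mu) / sd
        zs.append(z)
        labels.append(np.full(r.shape, name, dtype=object))
    return np.concatenate(zs), np.concatenate(labels)


def subhap_trait_regression(
    z_trait: np.ndarray,
    dosage_matrix: np.ndarray,
    labels: list[str],
    reference_index: int,
    trait_name: str = "trait",
) -> list[TraitAssocResult]:
    """Joint linear model of the (combined) z-scores on non-reference dosages.

    Each retained haplotype's coefficient is its contrast against the
    reference (most common) haplotype; collinear dosage columns are dropped
    with a log entry.  The model R^2 is attached to every row.
    """
    y = np.asarray(z_trait, dtype=float)
    D = np.asarray(dosage_matrix, dtype=float)
    non_ref = [k for k in range(D.shape[1]) if k != reference_index]
    ok = np.isfinite(y) & np.isfinite(D).all(axis=1)
    y, D = y[ok], D[ok]
    X = np.column_stack([np.ones(len(y)), D[:, non_ref]])
    from scipy.linalg import qr as _qr

    _, r, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [non_ref[k - 1] for k in range(1, X.shape[1]) if k not in keep]
    if dropped:
        logger.info("trait regression: dropped aliased dosage columns %s",
                    [labels[k] for k in dropped])
    fit = sm.OLS(y, X[:, keep]).fit()
    out = []
    for col_pos, k in enumerate(keep):
        if k == 0:
            continue
        hap = non_ref[k - 1]
        out.append(TraitAssocResult(
            trait=trait_name, haplotype=labels[hap],
            beta=float(fit.params[col_pos]), se=float(fit.bse[col_pos]),
            p=float(fit.pvalues[col_pos]), r2=float(fit.rsquared),
            n=len(y),
        ))
    return out


def dpcr_copy_number(
    target: DPCRMeasurement,
    reference: DPCRMeasurement,
    reference_copies: float = 2.0,
) -> float:
    """Copies per genome: reference_copies * lambda_target / lambda_reference."""
    if reference.positives == 0:
        raise ValueError("reference assay has no positive partitions")
    if target.volume_nl and reference.volume_nl:
        scale = reference.volume_nl / target.volume_nl
    else:
        scale = 1.0
    return float(reference_copies * (target.lam * scale) / reference.lam)


def trait_results_frame(results: list[TraitAssocResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
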