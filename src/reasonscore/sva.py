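"""Surrogate-variable estimation for batch adjustment.

Candidate surrogate variables are the right singular vectors of the
row-centered M-value matrix.  Centering (an intercept-only residual) rather
than outcome-residualization is deliberate: residualizing on the outcome
makes every singular vector exactly orthogonal to it, which would render
the outcome-correlation screen vacuous.  With centering, a surrogate that
happens to track the survival contrast can be detected and excluded
(|r| > 0.2 rule), protecting the contrast from being absorbed by the
adjustment.  The number of components under ``n_sv="auto"`` comes from
parallel analysis: keep components whose singular value exceeds the 95th
percentile of singular values of within-row-permuted matrices (permutation
preserves row means and variances, so the null spectra are comparable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MethylationDataset
from .dm import beta_to_m

logger = logging.getLogger(__name__)

#: Exclusion threshold on |Pearson r| between a surrogate variable and outcome.
OUTCOME_CORR_THRESHOLD = 0.2


@dataclass
class SurrogateVariableSet:
    """Estimated surrogate variables with outcome-correlation screening.

    Attributes
    ----------
    values
        samples x k DataFrame; columns ``SV1..SVk``, orthonormal.
    outcome_corr
        Per-SV Pearson (point-biserial) correlation with the binary outcome.
    retained
        Per-SV flag: True iff ``|outcome_corr| <= 0.2``.
    singular_values
        Singular value associated with each component.
    """

    values: pd.DataFrame
    outcome_corr: pd.Series
    retained: pd.Series
    singular_values: pd.Series

    @property
    def n_sv(self) -> int:
        return self.values.shape[1]

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "singular_value": self.singular_values,
                "outcome_corr": self.outcome_corr,
                "retained": self.retained,
            }
        )


def _centered_matrix(m_values: np.ndarray) -> np.ndarray:
    """Row-centered M-values (intercept-only residual)."""
    return m_values - m_values.mean(axis=1, keepdims=True)


def _fix_signs(v: np.ndarray) -> np.ndarray:
    """Deterministic sign: the largest-|.| loading of each SV is positive."""
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    return v * signs


def estimate_surrogates(
    dataset: MethylationDataset,
    n_sv: int | str = "auto",
    n_permutations: int = 20,
    quantile: float = 0.95,
    random_state: int = 0,
) -> SurrogateVariableSet:
    """Estimate surrogate variables from the outcome-residual M-value matrix.

    Parameters
    ----------
    dataset
        Filtered methylation dataset with outcome labels.
    n_sv
        Fixed component count, or ``"auto"`` for parallel analysis.
    n_permutations, quantile
        Parallel-analysis settings: each permutation shuffles every probe's
        residuals independently across samples and records the singular
        values of the permuted matrix.
    random_state
        Seed for the permutation draws; the SVD itself is deterministic.

    Raises
    ------
    ValueError
        If fewer than 3 samples, or a fixed ``n_sv >= n_samples``.
    """
    n = dataset.n_samples
    if n < 3:
        raise ValueError("surrogate estimation requires at least 3 samples")
    y = dataset.outcome_array()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; cannot protect the survival contrast")
    m = beta_to_m(dataset.beta.to_numpy())
    resid = _centered_matrix(m)

    max_k = n - 2  # leave residual df for the intercept + outcome model
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    if isinstance(n_sv, str):
        if n_sv != "auto":
            raise ValueError(f"n_sv must be an integer or 'auto', got {n_sv!r}")
        rng = np.random.default_rng(random_state)
        perm_s = np.empty((n_permutations, len(s)))
        for b in range(n_permutations):
            perm = resid.copy()
            # independent within-row shuffles break sample-level structure
            idx = np.argsort(rng.random(perm.shape), axis=1)
            perm = np.take_along_axis(perm, idx, axis=1)
            perm_s[b] = np.linalg.svd(perm, compute_uv=False)
        thresh = np.quantile(perm_s, quantile, axis=0)
        k = int(np.sum(s > thresh))
        k = min(k, max_k)
        logger.info("parallel analysis selected k=%d surrogate variables", k)
    else:
        k = int(n_sv)
        if k < 0:
            raise ValueError("n_sv must be non-negative")
        if k >= n:
            raise ValueError(f"n_sv={k} must be smaller than n_samples={n}")
        k = min(k, max_k)

    v = _fix_signs(vt[:k].T)  # samples x k
    names = [f"SV{i + 1}" for i in range(k)]
    values = pd.DataFrame(v, index=dataset.sample_ids, columns=names)
    if k:
        yc = y - y.mean()
        vc = v - v.mean(axis=0)
        denom = np.sqrt((vc**2).sum(axis=0) * (yc**2).sum())
        corr = np.where(denom > 0, (vc * yc[:, None]).sum(axis=0) / denom, 0.0)
    else:
        corr = np.empty(0)
    outcome_corr = pd.Series(corr, index=names, name="outcome_corr")
    retained = outcome_corr.abs() <= OUTCOME_CORR_THRESHOLD
    logger.info(
        "excluded %d of %d surrogate variables (|r| > %.2f with outcome)",
        int((~retained).sum()),
        k,
        OUTCOME_CORR_THRESHOLD,
    )
    return SurrogateVariableSet(
        values=values,
        outcome_corr=outcome_corr,
        retained=retained.rename("retained"),
        singular_values=pd.Series(s[:k], index=names, name="singular_value"),
    )


def select_covariates(svs: SurrogateVariableSet) -> pd.DataFrame:
    """Return the retained surrogate variables, preserving order.

    An empty frame (all components excluded) is valid: the downstream model
    then runs outcome-only.
    """
    return svs.values.loc[:, svs.retained.to_numpy()]
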