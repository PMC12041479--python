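"""Per-feature linear mixed models and multicollinearity matrices.

Overlapping windows from one chip are not independent samples, so plain
two-sample tests would overstate significance.  Each feature is therefore
tested with a linear mixed model on window-level values,

    feature ~ condition  (fixed)  +  (1 | chip)  (random intercept),

fit by maximum likelihood; the p-value comes from the likelihood-ratio test
against the condition-free null.  Significance codes follow the conventional
star annotation (ns, *, **, ***, ****).  A Benjamini-Hochberg q-value column
is emitted as supplementary output; the per-feature codes themselves are
uncorrected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .classify_explain import feature_columns, labels

logger = logging.getLogger(__name__)

#: (upper bound, code); a p-value maps to the first bin it does not exceed
_SIGNIFICANCE_BINS = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
    (1.0, "ns"),
)


@dataclass
class LmmResult:
    feature: str
    estimate: float | None
    p_value: float | None
    code: str | None
    converged: bool


def significance_code(p: float) -> str:
    """Map a p-value in (0, 1] to its star annotation.

    Boundaries belong to the stricter bin: p = 0.05 -> '*', p = 1e-4 -> '****'.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    for upper, code in _SIGNIFICANCE_BINS:
        if p <= upper:
            return code
    raise AssertionError("unreachable")


def lmm_test(ft: pd.DataFrame, feature: str) -> LmmResult:
    """Random-intercept LMM test of one feature's condition effect.

    Fits ``feature ~ 1 + condition`` and ``feature ~ 1`` (both with a chip
    random intercept, maximum likelihood) and compares them by a 1-df
    likelihood-ratio test.
    """
    chips = ft["chip_id"].unique()
    if len(chips) < 3:
        raise ValueError(f"LMM needs >= 3 chips, got {len(chips)}")
    y = ft[feature].to_numpy(dtype=float)
    cond = labels(ft).astype(float)
    groups = ft["chip_id"].to_numpy()
    if np.std(y) == 0:
        logger.warning("feature %s is constant; LMM degenerate", feature)
        return LmmResult(feature, None, None, None, converged=False)
    exog_full = np.column_stack([np.ones_like(y), cond])
    exog_null = np.ones((y.size, 1))

    def _fit(exog):
        # the random-intercept variance often sits on the boundary; walk a
        # ladder of optimizers before declaring non-convergence
        last = None
        for method in (None, "powell", "cg", "lbfgs"):
            kwargs = {"reml": False}
            if method is not None:
                kwargs["method"] = method
            result = MixedLM(y, exog, groups=groups).fit(**kwargs)
            last = result
            # some optimizers report success with a non-finite likelihood
            if bool(getattr(result, "converged", True)) and np.isfinite(result.llf):
                return result, True
        return last, False

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full, full_ok = _fit(exog_full)
            null, null_ok = _fit(exog_null)
        converged = full_ok and null_ok
    except Exception as err:  # singular fits on degenerate inputs
        logger.warning("feature %s: LMM failed (%s)", feature, err)
        return LmmResult(feature, None, None, None, converged=False)
    if not converged:
        return LmmResult(feature, float(full.params[1]), None, None, converged=False)
    lr = 2.0 * (full.llf - null.llf)
    p = float(chi2.sf(max(lr, 0.0), df=1))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return LmmResult(
        feature, float(full.params[1]), p, significance_code(p), converged=True
    )


def lmm_table(ft: pd.DataFrame) -> pd.DataFrame:
    """LMM results for every feature column, plus Benjamini-Hochberg q-values."""
    results = [lmm_test(ft, f) for f in feature_columns(ft)]
    table = pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "estimate": [r.estimate for r in results],
            "p_value": [r.p_value for r in results],
            "code": [r.code for r in results],
            "converged": [r.converged for r in results],
        }
    )
    valid = table["p_value"].notna()
    q = np.full(len(table), np.nan)
    if valid.any():
        q[valid.to_numpy()] = multipletests(
            table.loc[valid, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    table["bh_q"] = q
    return table


def feature_correlation(ft: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Pearson feature x feature correlation over one condition's windows.

    Zero-variance features get a 0 row/column (warned), unit diagonal.
    """
    feats = feature_columns(ft)
    if len(feats) < 2:
        raise ValueError("need >= 2 features")
    sub = ft[ft["condition"] == condition]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 rows for condition {condition!r}")
    X = sub[feats].to_numpy(dtype=float)
    sd = X.std(axis=0)
    degenerate = [f for f, s in zip(feats, sd) if s == 0]
    if degenerate:
        warnings.warn(f"zero-variance features {degenerate}; correlation set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=feats, columns=feats)
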