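"""Per-item DIF testing with nested proportional-odds models.

For each item, three cumulative-logit models are fit to the item response
Y with matching score theta (the observed total score) and group g
(0 = reference, 1 = focal):

    Model 1:  logit P(Y <= k) = alpha_k + beta1 * theta
    Model 2:  ... + beta2 * g
    Model 3:  ... + beta3 * g * theta

Twice the log-likelihood gain of Model 2 over Model 1 tests uniform DIF,
and of Model 3 over Model 2 nonuniform DIF; each statistic is referred to
a chi-square distribution with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .grm import ResponseData
from .olr import DegenerateDataError, fit_proportional_odds


class DegenerateDesignError(ValueError):
    """Raised when the data do not contain both comparison groups."""


@dataclass(frozen=True)
class DIFResult:
    """Likelihood-ratio DIF statistics for one item.

    ``valid`` is True only if all three model fits converged; tiny
    negative LRT values (numerical noise on nested fits) are clamped to 0.
    """

    item: int
    lrt_uniform: float
    p_uniform: float
    lrt_nonuniform: float
    p_nonuniform: float
    valid: bool


def _lrt(ll_full: float, ll_reduced: float) -> tuple[float, float, bool]:
    """LRT statistic, p-value, and whether nesting held numerically.

    A materially negative statistic means the larger model's optimizer
    stopped short of the smaller model's optimum, so the pair is flagged
    rather than trusted; tiny negatives are rounding noise and clamped.
    """
    stat = 2.0 * (ll_full - ll_reduced)
    ok = stat >= -1e-6
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df=1)), ok


def test_item_dif(
    item: int, data: ResponseData, matching: str = "total"
) -> DIFResult:
    """Test one item for uniform and nonuniform DIF.

    Parameters
    ----------
    item
        0-based item index.
    data
        Responses, group labels and total scores for both groups.
    matching
        ``"total"`` uses the total score over all items (including the
        studied item) as the matching variable; ``"rest"`` removes the
        studied item's contribution.
    """
    g = np.asarray(data.group, dtype=float)
    if len(np.unique(g)) < 2:
        raise DegenerateDesignError("both reference and focal groups are required")
    y = data.responses[:, item]
    if len(np.unique(y)) < 2:
        raise DegenerateDataError(
            f"item {item} has a single observed category in the pooled sample"
        )
    if matching == "total":
        theta = data.total_score.astype(float)
    elif matching == "rest":
        theta = (data.total_score - y).astype(float)
    else:
        raise ValueError(f"unknown matching mode {matching!r}")

    X1 = theta[:, None]
    X2 = np.column_stack([theta, g])
    X3 = np.column_stack([theta, g, g * theta])

    fit1 = fit_proportional_odds(y, X1)
    warm2 = np.concatenate([fit1.intercepts, fit1.slopes, [0.0]])
    fit2 = fit_proportional_odds(y, X2, start=warm2)
    warm3 = np.concatenate([fit2.intercepts, fit2.slopes, [0.0]])
    fit3 = fit_proportional_odds(y, X3, start=warm3)

    lrt_u, p_u, ok_u = _lrt(fit2.loglik, fit1.loglik)
    lrt_n, p_n, ok_n = _lrt(fit3.loglik, fit2.loglik)
    return DIFResult(
        item=item,
        lrt_uniform=lrt_u,
        p_uniform=p_u,
        lrt_nonuniform=lrt_n,
        p_nonuniform=p_n,
        valid=fit1.converged
        and fit2.converged
        and fit3.converged
        and ok_u
        and ok_n,
    )


def classify_replication(
    results: list[DIFResult], dif_item: int, alpha: float = 0.05
) -> tuple[bool, int, int]:
    """Bookkeeping for one replication: detection flag and false positives.

    Returns ``(dif_detected, false_positives, n_valid_null_items)`` where
    detection means the designated DIF item's uniform-DIF p-value is at or
    below ``alpha``, and false positives are counted over the remaining
    (truly DIF-free) items with valid fits.  Type-I error rates pool false
    positives across all null items and replications.
    """
    dif_detected = False
    false_positives = 0
    n_valid_null = 0
    for r in results:
        if r.item == dif_item:
            dif_detected = r.p_uniform <= alpha
        elif r.valid:
            n_valid_null += 1
            if r.p_uniform <= alpha:
                false_positives += 1
    return dif_detected, false_positives, n_valid_null
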