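"""Mix-up-rate budgeting: estimate the cohort mix-up rate and select a
subset of samples whose residual mix-up rate stays below a target.

The sex check catches only the fraction 2 f_m (1 - f_m) of random swaps
that happen to cross sexes, so the count it flags can be inflated into an
estimate of the total swap count, and hence (after removing everything any
check already caught) of the residual cohort mix-up rate:

    mr_estimated = (swaps_sexcheck / (2 (1 - f_m) f_m) - swaps_total) / N

Given a score threshold, the *sensitivity* — the fraction of mix-ups the
threshold would catch — is estimated from the permuted-pair score
distribution (permuted pairings are distributionally equivalent to real
mix-ups).  The mix-up rate expected among the n_pass samples at or below
the threshold is then

    mr_pass = mr_estimated * (1 - sensitivity) * N / n_pass

i.e. the undetected share of the expected mr_estimated * N mix-ups spread
over the passers.  Samples whose mr_pass is below the configured maximum
rate pass the filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MAX_MIXUP_RATE = 0.0001  # 0.01%, the strict end of the diagnostic range


@dataclass
class MixupRateEstimate:
    swaps_sexcheck: int
    swaps_total: int
    male_fraction: float
    n_remaining: int
    mr_estimated: float


def estimate_mixup_rate(swaps_sexcheck: int, swaps_total: int,
                        male_fraction: float, n_remaining: int) -> MixupRateEstimate:
    """Estimate the residual cohort mix-up rate from the sex-check yield.

    ``swaps_total`` counts every sample already removed by any mix-up check
    (sex check, pedigree, ...); ``n_remaining`` is the cohort size after
    those removals.  A negative estimate is clamped to zero with a warning.
    """
    if n_remaining <= 0:
        raise ValidationError("n_remaining must be positive")
    if not 0 < male_fraction < 1:
        raise ValidationError(
            "sex check undefined in single-sex cohorts (male_fraction in {0,1})")
    expected_total = swaps_sexcheck / (2.0 * (1.0 - male_fraction) * male_fraction)
    mr = (expected_total - swaps_total) / n_remaining
    if mr < 0:
        logger.warning("estimated mix-up rate %.3g < 0; clamped to 0", mr)
        mr = 0.0
    return MixupRateEstimate(swaps_sexcheck, swaps_total, male_fraction,
                             n_remaining, mr)


def sensitivity_at(score_threshold: float, permuted_scores) -> float:
    """Fraction of permuted-pair (mix-up-proxy) scores strictly above the
    threshold; non-increasing in the threshold."""
    scores = np.asarray(permuted_scores, dtype=float)
    if scores.size == 0:
        raise ValidationError("need at least one permuted score")
    return float(np.mean(scores > score_threshold))


def mixup_rate_pass(mr_estimated: float, sensitivity: float,
                    n_total: int, n_pass: int) -> float:
    """Residual mix-up rate among passers at a given sensitivity."""
    if n_pass <= 0:
        raise ValidationError("n_pass must be positive")
    if not 0 <= sensitivity <= 1:
        raise ValidationError("sensitivity must lie in [0, 1]")
    if n_pass > n_total:
        raise ValidationError("n_pass cannot exceed the number of assessed samples")
    return mr_estimated * (1.0 - sensitivity) * n_total / n_pass


def select_passing(scores: pd.DataFrame, permuted_scores,
                   mr_estimated: float,
                   max_rate: float = DEFAULT_MAX_MIXUP_RATE) -> pd.DataFrame:
    """Per-sample pass/fail decisions at a maximum acceptable mix-up rate.

    Each sample's own combined score is treated as a candidate threshold:
    its sensitivity is read off the permuted-score distribution, n_pass is
    the number of samples scoring at or below it, and the sample passes iff
    the implied mr_pass is below ``max_rate``.  Samples flagged
    ``insufficient_data`` never pass.

    ``scores`` must carry a ``combined_score`` column indexed by sample
    (the output of :func:`pgsmixup.aggregate.score_samples`).
    """
    if max_rate <= 0:
        raise ValidationError("max_rate must be positive")
    perm = np.sort(np.asarray(permuted_scores, dtype=float))
    if perm.size == 0:
        raise ValidationError("need permuted scores to estimate sensitivity")

    s = np.asarray(scores["combined_score"], dtype=float)
    n_total = len(s)
    order = np.argsort(s, kind="stable")
    ranked = s[order]
    # n_pass at each sample's score: count of samples <= that score
    n_pass_sorted = np.searchsorted(ranked, ranked, side="right")
    sens_sorted = 1.0 - np.searchsorted(perm, ranked, side="right") / perm.size

    mr_pass = np.empty(n_total)
    mr_pass[order] = mr_estimated * (1.0 - sens_sorted) * n_total / n_pass_sorted
    sens = np.empty(n_total)
    sens[order] = sens_sorted
    n_pass = np.empty(n_total, dtype=int)
    n_pass[order] = n_pass_sorted

    out = pd.DataFrame({
        "combined_score": s,
        "sensitivity_at_score": sens,
        "mr_pass": mr_pass,
        "n_pass": n_pass,
    }, index=scores.index)
    passes = out["mr_pass"] < max_rate
    if "insufficient_data" in scores.columns:
        passes &= ~scores["insufficient_data"].astype(bool)
    out["passes"] = passes
    if not passes.any():
        logger.info("no sample satisfies max mix-up rate %.4g", max_rate)
    return out
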