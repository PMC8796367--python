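"""Likelihood models over residual distributions and log-likelihood ratios.

Two density families are fitted per trait, one to the residuals of the
*provided* sample mappings and one to the residuals of *permuted* mappings.
A residual r is then scored with the log-likelihood ratio

    LLR(r) = ln[ f_permuted(r) / f_provided(r) ]

oriented so that larger values mean more evidence that the sample mapping is
a mix-up.  Continuous traits use Gaussian densities (their residuals are
approximately normal); binary and ordinal traits use histogram densities on
equal-width bins (default 80 provided samples per bin on average, 10
minimum per bin), with an equal-frequency scheme available as well.  For
ordinal traits a separate density pair is fitted per observed phenotype
category, and each residual is scored with its own category's pair.

Bin breaks are always derived from the provided-mapping residuals and then
applied unchanged to the permuted residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import BINARY, ORDINAL, QUANTITATIVE, TraitSpec
from .exceptions import FitError, ValidationError
from .mapping import ResidualMatrix

logger = logging.getLogger(__name__)

DEFAULT_AVG_PER_BIN = 80
DEFAULT_MIN_PER_BIN = 10

GAUSSIAN = "gaussian"
EQUAL_WIDTH = "equal_width"
EQUAL_FREQUENCY = "equal_frequency"


@dataclass
class GaussianLikelihood:
    """Gaussian densities fitted to the two residual arms."""

    mean_provided: float
    sd_provided: float
    mean_permuted: float
    sd_permuted: float

    def __post_init__(self):
        if self.sd_provided <= 0 or self.sd_permuted <= 0:
            raise FitError("Gaussian likelihood requires positive standard deviations")


@dataclass
class BinnedLikelihood:
    """Histogram densities on shared breaks, Laplace-smoothed.

    ``density_provided`` / ``density_permuted`` are per-bin probability
    masses computed as (count + 1) / (n + n_bins), so each sums to one and
    no bin has zero mass.  Residuals outside the break range fall into the
    nearest terminal bin.
    """

    breaks: np.ndarray
    density_provided: np.ndarray
    density_permuted: np.ndarray
    min_per_bin: int
    scheme: str

    def __post_init__(self):
        self.breaks = np.asarray(self.breaks, dtype=float)
        self.density_provided = np.asarray(self.density_provided, dtype=float)
        self.density_permuted = np.asarray(self.density_permuted, dtype=float)
        if np.any(np.diff(self.breaks) <= 0):
            raise FitError("bin breaks must be strictly increasing")
        for arm in (self.density_provided, self.density_permuted):
            if len(arm) != len(self.breaks) - 1 or abs(arm.sum() - 1.0) > 1e-9:
                raise FitError("per-bin masses must sum to 1 over n_bins entries")


def fit_gaussian_likelihood(provided_residuals, permuted_residuals) -> GaussianLikelihood:
    """Sample mean/sd (ddof=1) of each arm; errors on degenerate variance."""
    out = []
    for name, arm in (("provided", provided_residuals), ("permuted", permuted_residuals)):
        a = np.asarray(arm, dtype=float)
        if len(a) < 2:
            raise FitError(f"{name} arm has fewer than 2 residuals")
        sd = float(np.std(a, ddof=1))
        if sd == 0:
            raise FitError(f"{name} arm has zero variance")
        out.append((float(np.mean(a)), sd))
    (mp, sp), (mm, sm_) = out
    return GaussianLikelihood(mp, sp, mm, sm_)


def _histogram_counts(breaks: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Counts per bin with out-of-range values clipped into terminal bins."""
    idx = np.clip(np.searchsorted(breaks, values, side="right") - 1, 0, len(breaks) - 2)
    return np.bincount(idx, minlength=len(breaks) - 1)


def equal_width_bins(provided_residuals, avg_per_bin: int = DEFAULT_AVG_PER_BIN,
                     min_per_bin: int = DEFAULT_MIN_PER_BIN) -> np.ndarray:
    """Equal-width breaks over the provided residuals, with occupancy pruning.

    The provided-residual range is cut into floor(n/avg_per_bin) equal
    intervals (at least two).  The terminal bins are then extended inward
    (absorbing their neighbours) until each holds at least ``min_per_bin``
    provided samples; any interior bin still below the minimum is split at
    its midpoint, each half merging into its nearest neighbour, iterating
    until every bin satisfies the minimum.
    """
    if avg_per_bin < min_per_bin or min_per_bin < 1:
        raise ValidationError("require avg_per_bin >= min_per_bin >= 1")
    x = np.sort(np.asarray(provided_residuals, dtype=float))
    n = len(x)
    if n < 2 * min_per_bin:
        raise FitError(
            f"{n} provided residuals cannot form >= 2 bins of {min_per_bin}")
    n_bins = max(n // avg_per_bin, 2)
    breaks = np.linspace(x[0], x[-1], n_bins + 1)

    while True:
        counts = _histogram_counts(breaks, x)
        if np.all(counts >= min_per_bin):
            return breaks
        if len(breaks) == 3 and (counts[0] < min_per_bin or counts[1] < min_per_bin):
            # two bins left: place the single interior break directly
            lo, hi = x[min_per_bin - 1], x[n - min_per_bin]
            if lo >= hi:
                raise FitError(
                    "ties in provided residuals prevent forming 2 bins of "
                    f"{min_per_bin}")
            mid = 0.5 * (lo + hi)
            if mid <= lo:  # float midpoint collapse onto the lower value
                mid = hi
            breaks = np.array([breaks[0], mid, breaks[-1]])
            continue
        if counts[0] < min_per_bin:
            breaks = np.delete(breaks, 1)       # extend the lowest bin inward
        elif counts[-1] < min_per_bin:
            breaks = np.delete(breaks, -2)      # extend the highest bin inward
        else:
            i = int(np.flatnonzero(counts < min_per_bin)[0])  # leftmost first
            mid = 0.5 * (breaks[i] + breaks[i + 1])
            breaks = np.concatenate([breaks[:i], [mid], breaks[i + 2:]])


def equal_frequency_bins(provided_residuals, avg_per_bin: int = DEFAULT_AVG_PER_BIN) -> np.ndarray:
    """Quantile breaks so per-bin provided counts differ by at most one.

    Ties that would produce non-increasing breaks are collapsed (bins
    merged) with a warning; fully degenerate input yields a single bin.
    """
    if avg_per_bin < 1:
        raise ValidationError("avg_per_bin must be >= 1")
    x = np.sort(np.asarray(provided_residuals, dtype=float))
    n = len(x)
    if n < 2 * avg_per_bin:
        raise FitError(f"{n} provided residuals cannot form >= 2 bins of {avg_per_bin}")
    n_bins = n // avg_per_bin
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    cuts = np.cumsum(sizes)[:-1]
    inner = 0.5 * (x[cuts - 1] + x[cuts])
    # a float midpoint can collapse onto the lower value (adjacent floats);
    # the upper value itself then separates, since bins are half-open
    collapsed = inner <= x[cuts - 1]
    inner[collapsed] = x[cuts][collapsed]
    breaks = np.concatenate([[x[0]], inner, [x[-1]]])
    unique = np.unique(breaks)
    if len(unique) < len(breaks):
        logger.warning("equal-frequency binning: %d duplicate breaks collapsed (ties)",
                       len(breaks) - len(unique))
        breaks = unique
    if len(breaks) < 2:  # all residuals identical
        breaks = np.array([x[0] - 0.5, x[0] + 0.5])
        logger.warning("equal-frequency binning: degenerate input, single unit-width bin")
    return breaks


def fit_binned_likelihood(provided_residuals, permuted_residuals,
                          scheme: str = EQUAL_WIDTH,
                          avg_per_bin: int = DEFAULT_AVG_PER_BIN,
                          min_per_bin: int = DEFAULT_MIN_PER_BIN) -> BinnedLikelihood:
    """Fit histogram densities: breaks from the provided arm only, masses
    Laplace-smoothed with pseudo-count one per bin in both arms."""
    if scheme == EQUAL_WIDTH:
        breaks = equal_width_bins(provided_residuals, avg_per_bin, min_per_bin)
    elif scheme == EQUAL_FREQUENCY:
        breaks = equal_frequency_bins(provided_residuals, avg_per_bin)
    else:
        raise ValidationError(f"unknown binning scheme {scheme!r}")
    n_bins = len(breaks) - 1
    dens = []
    for arm in (provided_residuals, permuted_residuals):
        counts = _histogram_counts(breaks, np.asarray(arm, dtype=float))
        dens.append((counts + 1.0) / (counts.sum() + n_bins))
    return BinnedLikelihood(breaks=breaks, density_provided=dens[0],
                            density_permuted=dens[1], min_per_bin=min_per_bin,
                            scheme=scheme)


def llr(likelihood, residual):
    """ln of permuted-over-provided likelihood at the residual(s); positive
    values favour the mix-up hypothesis."""
    r = np.asarray(residual, dtype=float)
    if isinstance(likelihood, GaussianLikelihood):
        out = (norm.logpdf(r, likelihood.mean_permuted, likelihood.sd_permuted)
               - norm.logpdf(r, likelihood.mean_provided, likelihood.sd_provided))
    elif isinstance(likelihood, BinnedLikelihood):
        idx = np.clip(np.searchsorted(likelihood.breaks, r, side="right") - 1,
                      0, len(likelihood.breaks) - 2)
        out = np.log(likelihood.density_permuted[idx] / likelihood.density_provided[idx])
    else:
        raise ValidationError(f"unsupported likelihood type {type(likelihood).__name__}")
    return float(out) if np.ndim(residual) == 0 else out


@dataclass
class LikelihoodConfig:
    """Which density family each trait type gets, and binning parameters."""

    continuous_method: str = GAUSSIAN   # gaussian | equal_width | equal_frequency
    discrete_scheme: str = EQUAL_WIDTH  # equal_width | equal_frequency
    avg_per_bin: int = DEFAULT_AVG_PER_BIN
    min_per_bin: int = DEFAULT_MIN_PER_BIN


@dataclass
class TraitLikelihood:
    """Fitted likelihood model(s) for one trait.

    ``kind`` is ``"single"`` (one density pair: continuous and binary
    traits) or ``"per_category"`` (ordinal traits: one pair per observed
    category; categories excluded for lack of data map to None and score 0).
    """

    trait: str
    kind: str
    model: object | None = None
    per_category: dict = field(default_factory=dict)


@dataclass
class LLRMatrix:
    """Per-trait LLRs for provided samples and permuted pairs; higher =
    more evidence for a mix-up (orientation fixed across traits)."""

    trait: str
    provided_llr: pd.Series
    permuted_llr: pd.DataFrame  # phenotype_sample, genotype_sample, llr


def _fit_single(trait: TraitSpec, provided, permuted, config: LikelihoodConfig):
    if trait.data_type == QUANTITATIVE and config.continuous_method == GAUSSIAN:
        return fit_gaussian_likelihood(provided, permuted)
    scheme = (config.continuous_method if trait.data_type == QUANTITATIVE
              else config.discrete_scheme)
    return fit_binned_likelihood(provided, permuted, scheme=scheme,
                                 avg_per_bin=config.avg_per_bin,
                                 min_per_bin=config.min_per_bin)


def fit_trait_likelihood(trait: TraitSpec, matrix: ResidualMatrix,
                         config: LikelihoodConfig | None = None) -> TraitLikelihood:
    """Fit the trait's likelihood model(s) from a residual matrix.

    Ordinal traits get one provided/permuted density pair per observed
    phenotype category; a category with too few provided residuals to bin
    is excluded (scores 0) with a warning.
    """
    config = config or LikelihoodConfig()
    if trait.data_type != ORDINAL:
        model = _fit_single(trait, matrix.provided.to_numpy(),
                            matrix.permuted["residual"].to_numpy(), config)
        return TraitLikelihood(trait=trait.name, kind="single", model=model)

    row_cat = matrix.row_phenotype.astype(str)
    perm_cat = row_cat.loc[matrix.permuted["phenotype_sample"]].to_numpy()
    per_category = {}
    for cat in trait.categories:
        prov = matrix.provided[row_cat == cat].to_numpy()
        perm = matrix.permuted["residual"].to_numpy()[perm_cat == cat]
        try:
            per_category[cat] = fit_binned_likelihood(
                prov, perm, scheme=config.discrete_scheme,
                avg_per_bin=config.avg_per_bin, min_per_bin=config.min_per_bin)
        except FitError as exc:
            logger.warning("trait %s category %r: %s; LLRs set to 0 and excluded",
                           trait.name, cat, exc)
            per_category[cat] = None
    return TraitLikelihood(trait=trait.name, kind="per_category",
                           per_category=per_category)


def llr_matrix_for_trait(trait_likelihood: TraitLikelihood,
                         matrix: ResidualMatrix) -> LLRMatrix:
    """Score every provided and permuted residual of a trait with its LLR."""
    if trait_likelihood.kind == "single":
        prov = llr(trait_likelihood.model, matrix.provided.to_numpy())
        perm = llr(trait_likelihood.model, matrix.permuted["residual"].to_numpy())
    else:
        row_cat = matrix.row_phenotype.astype(str)
        perm_cat = row_cat.loc[matrix.permuted["phenotype_sample"]].to_numpy()
        prov = np.zeros(len(matrix.provided))
        perm = np.zeros(len(matrix.permuted))
        for cat, model in trait_likelihood.per_category.items():
            if model is None:
                continue
            pmask = (row_cat == cat).to_numpy()
            mmask = perm_cat == cat
            if pmask.any():
                prov[pmask] = llr(model, matrix.provided.to_numpy()[pmask])
            if mmask.any():
                perm[mmask] = llr(model, matrix.permuted["residual"].to_numpy()[mmask])
    permuted = matrix.permuted[["phenotype_sample", "genotype_sample"]].copy()
    permuted["llr"] = np.asarray(perm, dtype=float)
    return LLRMatrix(
        trait=trait_likelihood.trait,
        provided_llr=pd.Series(np.asarray(prov, dtype=float),
                               index=matrix.phenotype_samples, name="llr"),
        permuted_llr=permuted,
    )


# -- serialization (used by the JSON model file) -------------------------

def likelihood_to_dict(tl: TraitLikelihood) -> dict:
    def one(model):
        if model is None:
            return None
        if isinstance(model, GaussianLikelihood):
            return {"type": "gaussian", "mean_provided": model.mean_provided,
                    "sd_provided": model.sd_provided,
                    "mean_permuted": model.mean_permuted,
                    "sd_permuted": model.sd_permuted}
        return {"type": "binned", "breaks": model.breaks.tolist(),
                "density_provided": model.density_provided.tolist(),
                "density_permuted": model.density_permuted.tolist(),
                "min_per_bin": model.min_per_bin, "scheme": model.scheme}

    d = {"trait": tl.trait, "kind": tl.kind}
    if tl.kind == "single":
        d["model"] = one(tl.model)
    else:
        d["per_category"] = {cat: one(m) for cat, m in tl.per_category.items()}
    return d


def likelihood_from_dict(d: dict) -> TraitLikelihood:
    def one(rec):
        if rec is None:
            return None
        if rec["type"] == "gaussian":
            return GaussianLikelihood(rec["mean_provided"], rec["sd_provided"],
                                      rec["mean_permuted"], rec["sd_permuted"])
        return BinnedLikelihood(breaks=np.asarray(rec["breaks"]),
                                density_provided=np.asarray(rec["density_provided"]),
                                density_permuted=np.asarray(rec["density_permuted"]),
                                min_per_bin=rec["min_per_bin"], scheme=rec["scheme"])

    if d["kind"] == "single":
        return TraitLikelihood(trait=d["trait"], kind="single", model=one(d["model"]))
    return TraitLikelihood(trait=d["trait"], kind="per_category",
                           per_category={c: one(m) for c, m in d["per_category"].items()})
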