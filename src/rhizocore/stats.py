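"""Statistical engines for the coring study.

* TOST equivalence between replicate sets of RLD estimates and truth
  (Welch-type two one-sided t-tests against symmetric bounds).
* One-way / two-way ANOVA with Tukey HSD (delegated to scipy/statsmodels).
* Quadratic discriminant analysis: per-class Gaussian score with
  class-specific covariance, equal priors, rank-deficiency detection.
* Resampling power analysis: proportion of significant one-way ANOVAs on
  per-core depth metrics as a function of cores per phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

_COND_THRESHOLD = 1e10


class RankDeficiencyError(ValueError):
    """A class covariance matrix is singular or ill-conditioned."""


class ZeroVarianceError(ValueError):
    """Degenerate input: no variance where a t-test needs one."""


# --------------------------------------------------------------------------
# TOST equivalence
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TOSTConfig:
    """Equivalence margin and significance level.

    ``margin`` is a fraction of the reference mean when ``margin_type`` is
    "relative", otherwise an absolute difference in the data's units.
    """

    margin_type: str = "relative"
    margin: float = 0.25
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.margin_type not in ("relative", "absolute"):
            raise ValueError("margin_type must be 'relative' or 'absolute'")
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class TOSTResult:
    p_value: float
    equivalent: bool
    lower_bound: float
    upper_bound: float
    mean_difference: float


def tost_equivalence(sample_a: Sequence[float], reference: Sequence[float], config: TOSTConfig) -> TOSTResult:
    """Two one-sided Welch t-tests of sample_a vs reference within +-margin.

    Equivalence bounds are reference_mean +- delta.  The reported p-value is
    the max of the two one-sided p-values; equivalence is declared when it
    is below alpha.
    """
    a = np.asarray(sample_a, dtype=float)
    r = np.asarray(reference, dtype=float)
    if len(a) < 2 or len(r) < 2:
        raise ValueError("each sample needs at least 2 observations")
    mean_a, mean_r = a.mean(), r.mean()
    var_a = a.var(ddof=1)
    var_r = r.var(ddof=1)
    diff = mean_a - mean_r
    if config.margin_type == "relative":
        delta = config.margin * abs(mean_r)
    else:
        delta = config.margin
    if delta <= 0:
        raise ValueError("equivalence margin evaluates to zero (reference mean is 0?)")

    if var_a == 0 and var_r == 0:
        if abs(diff) < delta:
            # both samples constant and inside the bounds: certain equivalence
            return TOSTResult(
                p_value=np.finfo(float).tiny,
                equivalent=True,
                lower_bound=mean_r - delta,
                upper_bound=mean_r + delta,
                mean_difference=diff,
            )
        raise ZeroVarianceError("both samples have zero variance and differ by >= the margin")

    se = np.sqrt(var_a / len(a) + var_r / len(r))
    num = (var_a / len(a) + var_r / len(r)) ** 2
    den = (var_a / len(a)) ** 2 / (len(a) - 1) + (var_r / len(r)) ** 2 / (len(r) - 1)
    df = num / den

    t_lower = (diff + delta) / se  # H0: diff <= -delta
    t_upper = (diff - delta) / se  # H0: diff >= +delta
    p_lower = sps.t.sf(t_lower, df)
    p_upper = sps.t.cdf(t_upper, df)
    p = float(max(p_lower, p_upper))
    return TOSTResult(
        p_value=p,
        equivalent=p < config.alpha,
        lower_bound=mean_r - delta,
        upper_bound=mean_r + delta,
        mean_difference=diff,
    )


# --------------------------------------------------------------------------
# ANOVA + Tukey HSD
# --------------------------------------------------------------------------

@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], dict]  # (a, b) -> {p_adj, significant, mean_diff}

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, res in self.pairwise.items() if res["significant"]]


def anova_tukey(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA across groups followed by Tukey HSD pairwise comparisons."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs at least 2 observations")
    if all(v.var(ddof=1) == 0 for v in arrays.values()) and len({v.mean() for v in arrays.values()}) == 1:
        # identical constant groups: F undefined; report no differences
        keys = sorted(arrays)
        pairwise = {
            (a, b): {"p_adj": 1.0, "significant": False, "mean_diff": 0.0}
            for i, a in enumerate(keys)
            for b in keys[i + 1 :]
        }
        return AnovaTukeyResult(f_statistic=0.0, p_value=1.0, pairwise=pairwise)

    f_stat, p_val = sps.f_oneway(*arrays.values())

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([np.full(len(v), k, dtype=object) for k, v in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairwise = {}
    for row in tukey.summary().data[1:]:
        a, b = str(row[0]), str(row[1])
        pairwise[(a, b)] = {
            "p_adj": float(row[3]),
            "significant": bool(row[6]),
            "mean_diff": float(row[2]),
        }
    return AnovaTukeyResult(f_statistic=float(f_stat), p_value=float(p_val), pairwise=pairwise)


def anova_two_way(df: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> pd.DataFrame:
    """Two-way ANOVA with interaction (type II) via statsmodels OLS."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    frame = df.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.index = [
        str(idx).replace("C(_a)", factor_a).replace("C(_b)", factor_b) for idx in table.index
    ]
    return table


# --------------------------------------------------------------------------
# Quadratic discriminant analysis
# --------------------------------------------------------------------------

@dataclass
class QDAModel:
    """Per-class Gaussian discriminant with class-specific covariances."""

    classes: tuple[str, ...]
    means: np.ndarray  # (k, d)
    covariances: np.ndarray  # (k, d, d)
    priors: np.ndarray  # (k,)
    _inv: np.ndarray = field(repr=False, default=None)
    _logdet: np.ndarray = field(repr=False, default=None)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def scores(self, x: Sequence[float]) -> np.ndarray:
        """Quadratic discriminant score of x for every class.

        score_i = -1/2 log|S_i| - 1/2 (x - mean_i)' S_i^-1 (x - mean_i) + log p_i
        """
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_features,):
            raise ValueError(f"expected a vector of length {self.n_features}")
        out = np.empty(len(self.classes))
        for i in range(len(self.classes)):
            dev = x - self.means[i]
            out[i] = (
                -0.5 * self._logdet[i]
                - 0.5 * dev @ self._inv[i] @ dev
                + np.log(self.priors[i])
            )
        return out


def fit_qda(
    training: Mapping[str, np.ndarray] | tuple[np.ndarray, np.ndarray],
    priors: Sequence[float] | None = None,
    cond_threshold: float = _COND_THRESHOLD,
    context: str = "",
) -> QDAModel:
    """Fit per-class means and covariances; detect rank deficiency.

    ``training`` is either a mapping class -> (n_i, d) array or an (X, y)
    pair.  Priors default to equal.  A covariance that fails Cholesky or has
    condition number above ``cond_threshold`` raises RankDeficiencyError
    (``context`` names the offending data source, e.g. a coring location).
    """
    if isinstance(training, Mapping):
        groups = {str(k): np.asarray(v, dtype=float) for k, v in training.items()}
    else:
        X, y = training
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        groups = {str(c): X[y == c] for c in np.unique(y)}
    classes = tuple(sorted(groups))
    d = next(iter(groups.values())).shape[1]
    for c, arr in groups.items():
        if arr.ndim != 2 or arr.shape[1] != d:
            raise ValueError("all classes must share the same feature dimension")
        if arr.shape[0] <= d:
            raise RankDeficiencyError(
                f"class {c!r} has n={arr.shape[0]} <= d={d} samples{_ctx(context)}"
            )
    if priors is None:
        priors = np.full(len(classes), 1.0 / len(classes))
    else:
        priors = np.asarray(priors, dtype=float)
        if abs(priors.sum() - 1.0) > 1e-9 or (priors <= 0).any():
            raise ValueError("priors must be positive and sum to 1")

    means = np.stack([groups[c].mean(axis=0) for c in classes])
    covs = np.stack([np.cov(groups[c], rowvar=False, ddof=1) for c in classes])
    if d == 1:
        covs = covs.reshape(len(classes), 1, 1)

    inv = np.empty_like(covs)
    logdet = np.empty(len(classes))
    for i, c in enumerate(classes):
        try:
            chol = np.linalg.cholesky(covs[i])
        except np.linalg.LinAlgError:
            raise RankDeficiencyError(
                f"covariance of class {c!r} is not positive definite{_ctx(context)}"
            ) from None
        if np.linalg.cond(covs[i]) > cond_threshold:
            raise RankDeficiencyError(
                f"covariance of class {c!r} is ill-conditioned{_ctx(context)}"
            )
        logdet[i] = 2.0 * np.log(np.diag(chol)).sum()
        inv[i] = np.linalg.inv(covs[i])
    return QDAModel(
        classes=classes, means=means, covariances=covs, priors=priors, _inv=inv, _logdet=logdet
    )


def _ctx(context: str) -> str:
    return f" ({context})" if context else ""


def classify(model: QDAModel, x: Sequence[float]) -> str:
    """Assign x to the class with the largest discriminant score (ties -> first class)."""
    scores = model.scores(x)
    best = int(np.argmax(scores))
    ties = np.flatnonzero(scores == scores[best])
    if len(ties) > 1:
        logger.info("tie between classes %s; returning the first", [model.classes[i] for i in ties])
    return model.classes[best]


def _classify_batch(model: QDAModel, X: np.ndarray) -> np.ndarray:
    """Vectorized argmax classification of an (n, d) matrix; returns class indices."""
    n = X.shape[0]
    scores = np.empty((n, len(model.classes)))
    for i in range(len(model.classes)):
        dev = X - model.means[i]
        maha = np.einsum("nj,jk,nk->n", dev, model._inv[i], dev)
        scores[:, i] = -0.5 * model._logdet[i] - 0.5 * maha + np.log(model.priors[i])
    return np.argmax(scores, axis=1)


def qda_experiment(
    class_vectors: Mapping[str, np.ndarray],
    training_sizes: Sequence[int] = (8, 10, 15, 20, 25, 30, 35, 40, 45, 50),
    n_test: int = 50,
    n_draws: int = 20,
    rng: np.random.Generator | None = None,
    context: str = "",
) -> pd.DataFrame:
    """Train/test misclassification sweep over training-set sizes.

    From each class's pool, ``n_test`` replicates are reserved as a fixed
    test set; for each training size, ``n_draws`` random training subsets
    are drawn from the remainder, a QDA fit on each, and the
    misclassification rate on the test set recorded.  Returns a tidy frame
    with columns training_size, misclassification, se.
    """
    rng = rng if rng is not None else np.random.default_rng()
    pools = {str(k): np.asarray(v, dtype=float) for k, v in class_vectors.items()}
    classes = tuple(sorted(pools))
    min_pool = min(len(v) for v in pools.values())
    if n_test >= min_pool:
        raise ValueError(f"n_test={n_test} leaves no training data (pool size {min_pool})")
    max_train = min_pool - n_test
    for size in training_sizes:
        if size > max_train:
            raise ValueError(
                f"training size {size} exceeds available pool ({max_train} after reserving the test set)"
            )

    test_sets = {}
    train_pools = {}
    for c in classes:
        perm = rng.permutation(len(pools[c]))
        test_sets[c] = pools[c][perm[:n_test]]
        train_pools[c] = pools[c][perm[n_test:]]

    X_test = np.vstack([test_sets[c] for c in classes])
    y_test = np.concatenate([np.full(n_test, i) for i in range(len(classes))])

    rows = []
    for size in training_sizes:
        rates = []
        for _ in range(n_draws):
            training = {}
            for c in classes:
                idx = rng.choice(len(train_pools[c]), size=size, replace=False)
                training[c] = train_pools[c][idx]
            model = fit_qda(training, context=context)
            pred = _classify_batch(model, X_test)
            rates.append(float(np.mean(pred != y_test)))
        rates = np.asarray(rates)
        rows.append(
            {
                "training_size": size,
                "misclassification": rates.mean(),
                "se": rates.std(ddof=1) / np.sqrt(len(rates)) if len(rates) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Resampling power analysis
# --------------------------------------------------------------------------

@dataclass
class PowerCurve:
    location_id: int | str
    metric_p: float
    sample_sizes: np.ndarray
    proportion_significant: np.ndarray
    n_replicates: int
    redraws: int = 0

    def __post_init__(self) -> None:
        prop = np.asarray(self.proportion_significant, dtype=float)
        if ((prop < 0) | (prop > 1)).any():
            raise ValueError("proportions must lie in [0, 1]")


def _f_oneway_vectorized(samples: np.ndarray) -> np.ndarray:
    """One-way ANOVA p-values for a batch: samples has shape (reps, k, n)."""
    reps, k, n = samples.shape
    group_means = samples.mean(axis=2)  # (reps, k)
    grand = samples.mean(axis=(1, 2))  # (reps,)
    ssb = n * ((group_means - grand[:, None]) ** 2).sum(axis=1)
    ssw = ((samples - group_means[:, :, None]) ** 2).sum(axis=(1, 2))
    df_b = k - 1
    df_w = k * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = sps.f.sf(f, df_b, df_w)
    # zero within-group variance: F infinite -> significant iff between-group
    # variance is nonzero
    degenerate = ssw <= 0
    p[degenerate & (ssb > 0)] = 0.0
    p[degenerate & (ssb <= 0)] = 1.0
    return p


def resampling_power(
    metric_values: Mapping[str, Sequence[float]],
    location_id: int | str,
    metric_p: float,
    n_range: Sequence[int] = tuple(range(2, 21)),
    reps: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    redraws: int = 0,
) -> PowerCurve:
    """Proportion of significant one-way ANOVAs across phenotypes vs cores per phenotype.

    ``metric_values`` maps phenotype -> per-core depth-metric values (cores
    with zero root length must be excluded upstream; pass the exclusion
    count as ``redraws`` for the log).  For each n in ``n_range``, ``reps``
    resamples of n cores per phenotype are drawn with replacement and
    tested at ``alpha``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    pools = [np.asarray(v, dtype=float) for v in metric_values.values()]
    if len(pools) < 2:
        raise ValueError("need at least 2 phenotypes")
    for v in pools:
        if len(v) < 2:
            raise ValueError("each phenotype needs at least 2 cores")
    if redraws:
        logger.info("location %s: %d zero-length cores excluded and redrawn", location_id, redraws)

    sizes = np.asarray(list(n_range), dtype=int)
    props = np.empty(len(sizes))
    for j, n in enumerate(sizes):
        samples = np.stack(
            [pool[rng.integers(0, len(pool), size=(reps, n))] for pool in pools], axis=1
        )  # (reps, k, n)
        p = _f_oneway_vectorized(samples)
        props[j] = float(np.mean(p < alpha))
    return PowerCurve(
        location_id=location_id,
        metric_p=metric_p,
        sample_sizes=sizes,
        proportion_significant=props,
        n_replicates=reps,
        redraws=redraws,
    )
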