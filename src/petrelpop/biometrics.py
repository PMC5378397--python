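"""Sexual size dimorphism, two-sample tests and discriminant sexing.

Many petrels are monomorphic in plumage; sexing birds in the hand relies
on small but consistent biometric differences between the sexes.  This
module quantifies dimorphism (SDI), tests per-trait differences (pooled
and Welch two-sample t, from raw values or published summaries, with
Bonferroni control), fits a linear discriminant function on a stratified
training split, and measures observer repeatability with an intra-class
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiometricRecord",
    "DiscriminantModel",
    "sdi",
    "pooled_t",
    "pooled_t_summary",
    "welch_t_summary",
    "bonferroni_alpha",
    "lda_fit",
    "lda_classify",
    "icc_repeatability",
    "read_biometrics_csv",
    "write_biometrics_csv",
]

TRAITS = ["tarsus", "bill", "depth_base", "depth_nostril", "head", "wing"]


@dataclass
class BiometricRecord:
    """One measured bird: six measurements in mm and a (possibly unknown) sex."""

    bird_id: str
    sex: str  # "male" | "female" | "unknown"
    tarsus: float = np.nan
    bill: float = np.nan
    depth_base: float = np.nan
    depth_nostril: float = np.nan
    head: float = np.nan
    wing: float = np.nan

    def __post_init__(self):
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"sex must be male/female/unknown, got {self.sex!r}")
        for t in TRAITS:
            v = getattr(self, t)
            if not np.isnan(v) and v <= 0:
                raise ValueError(f"{t} must be strictly positive")

    def values(self, traits=TRAITS) -> np.ndarray:
        return np.array([getattr(self, t) for t in traits], dtype=float)


def sdi(mean_male: float, mean_female: float) -> float:
    """Sexual size dimorphism index, % of the male mean, to 1 dp.

    ``SDI = 100 * (male - female) / male``; positive when males are larger.
    """
    if mean_male <= 0:
        raise ValueError("male mean must be positive")
    return round(100.0 * (mean_male - mean_female) / mean_male, 1)


def pooled_t(group_a, group_b):
    """Classic equal-variance two-sample t-test on raw values.

    Returns ``(t, df, p)`` with ``df = n_a + n_b - 2``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            raise ValueError("zero pooled variance with equal means: t undefined")
        return float("inf"), len(a) + len(b) - 2, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), len(a) + len(b) - 2, float(p)


def pooled_t_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Equal-variance two-sample t from group summaries alone."""
    _check_summary(sd1, n1, sd2, n2)
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), n1 + n2 - 2, float(res.pvalue)


def welch_t_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Welch two-sample t with Satterthwaite df from group summaries.

    This is the form used to compare a measured population against
    literature means (only mean, SD and n are available).
    """
    _check_summary(sd1, n1, sd2, n2)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _check_summary(sd1, n1, sd2, n2):
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both variances zero: t undefined")


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted critical p-value ``alpha / m``, to 3 dp."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return round(alpha / m, 3)


# ---------------------------------------------------------------------------
# Discriminant sexing

@dataclass
class DiscriminantModel:
    """Per-class linear classification functions with equal priors.

    A record with trait vector ``x`` is scored ``c_k . x + const_k`` for
    each class ``k``; it is assigned to the class with the larger score
    (exact ties break to female).  The coefficients are the classic
    discriminant-function-analysis form ``Sigma^-1 mu_k`` with constants
    ``-0.5 mu_k' Sigma^-1 mu_k`` on the pooled within-group covariance.
    """

    traits: list
    classes: list  # ["female", "male"]
    coef: np.ndarray  # (2, n_traits)
    const: np.ndarray  # (2,)
    pooled_cov: np.ndarray
    means: np.ndarray  # (2, n_traits)

    def scores(self, x: np.ndarray) -> np.ndarray:
        return x @ self.coef.T + self.const


def lda_fit(records, train_fraction: float = 0.8, seed: int = 0, traits=None):
    """Fit a linear discriminant sexing function on a stratified split.

    ``train_fraction`` of each sex (rounded down, at least 2 per sex) is
    drawn at random for training; the remainder is returned for testing.
    The pooled within-group covariance uses the unbiased (n - 2) divisor.
    Raises on singular pooled covariance, naming the collinear traits.
    """
    if traits is None:
        traits = TRAITS
    sexed = [r for r in records if r.sex in ("male", "female")]
    complete = [r for r in sexed if not np.isnan(r.values(traits)).any()]
    rng = np.random.default_rng(seed)

    train, test = [], []
    for sex in ("female", "male"):
        group = [r for r in complete if r.sex == sex]
        n_train = int(np.floor(train_fraction * len(group)))
        if n_train < 2 or len(group) < 2:
            raise ValueError(f"need at least 2 training records for sex {sex}")
        idx = rng.permutation(len(group))
        train += [group[i] for i in idx[:n_train]]
        test += [group[i] for i in idx[n_train:]]

    classes = ["female", "male"]
    X = {s: np.array([r.values(traits) for r in train if r.sex == s]) for s in classes}
    means = np.array([X[s].mean(axis=0) for s in classes])
    n_tot = sum(len(X[s]) for s in classes)
    pooled = sum(
        (X[s] - X[s].mean(axis=0)).T @ (X[s] - X[s].mean(axis=0)) for s in classes
    ) / (n_tot - 2)

    try:
        prec = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        corr = np.corrcoef(np.vstack([X[s] for s in classes]).T)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"singular pooled covariance; traits {traits[i]!r} and "
            f"{traits[j]!r} are collinear"
        ) from None

    coef = means @ prec
    const = -0.5 * np.einsum("ki,ij,kj->k", means, prec, means)
    model = DiscriminantModel(
        traits=list(traits), classes=classes, coef=coef, const=const,
        pooled_cov=pooled, means=means,
    )
    return model, test


def lda_classify(model: DiscriminantModel, record: BiometricRecord):
    """Assign a sex by the larger classification-function value.

    Returns ``(sex, {class: score})``.  Exact ties break to female.
    """
    x = record.values(model.traits)
    if np.isnan(x).any():
        missing = [t for t, v in zip(model.traits, x) if np.isnan(v)]
        raise ValueError(f"record {record.bird_id}: missing traits {missing}")
    s = model.scores(x)
    scores = dict(zip(model.classes, map(float, s)))
    sex = "male" if scores["male"] > scores["female"] else "female"
    return sex, scores


# ---------------------------------------------------------------------------
# Repeatability

def icc_repeatability(duplicates) -> tuple[float, float]:
    """One-way random-effects intra-class correlation of duplicate measures.

    ``duplicates`` is an (n_birds, 2) array of repeated measurements.
    Returns ``(ICC, p)`` from the one-way ANOVA decomposition
    ``ICC = (MSB - MSW) / (MSB + (k - 1) MSW)`` with the F-test p-value of
    the between-bird effect.  Zero between-bird variance yields ICC 0.
    """
    d = np.asarray(duplicates, dtype=float)
    if d.ndim != 2 or d.shape[1] < 2:
        raise ValueError("need an (n_birds, k>=2) array of repeated measures")
    n, k = d.shape
    if n < 5:
        raise ValueError("need at least 5 birds measured twice")
    grand = d.mean()
    row_means = d.mean(axis=1)
    msb = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msw = ((d - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    if msb == 0:
        warnings.warn("zero between-bird variance; ICC set to 0")
        return 0.0, float("nan")
    if msw == 0:
        return 1.0, 0.0
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f = msb / msw
    p = float(stats.f.sf(f, n - 1, n * (k - 1)))
    return float(icc), p


# ---------------------------------------------------------------------------
# CSV I/O: one row per bird, columns id,sex,tarsus,bill,depth_base,
# depth_nostril,head,wing

def read_biometrics_csv(path) -> list:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            BiometricRecord(
                bird_id=str(row["id"]),
                sex=str(row["sex"]),
                **{t: float(row[t]) if t in row and pd.notna(row[t]) else np.nan
                   for t in TRAITS},
            )
        )
    return records


def write_biometrics_csv(records, path) -> None:
    rows = [
        {"id": r.bird_id, "sex": r.sex, **{t: getattr(r, t) for t in TRAITS}}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
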