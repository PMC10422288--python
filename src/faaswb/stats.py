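"""Per-participant slope estimation and group-level inference.

The raw (FAA, SWB) pairs of one participant are heavily imbalanced toward
mid-scale scores, so an ordinary regression overfits the centre.  The chain
applied per participant is therefore:

1. drop every pair whose SWB score occurs fewer than 3 times; if fewer than
   3 distinct scores remain, exclude the participant;
2. oversample minority scores with SMOTE on the one-dimensional FAA feature
   (synthetic value ``x + u·(x_nn − x)``, ``u ~ U(0,1)``, ``x_nn`` one of
   the ``k = min(5, n_class − 1)`` nearest same-class neighbours) until
   every score has as many pairs as the most frequent one;
3. ordinary least squares of FAA on SWB;
4. repeat 2–3 ten times (SMOTE is stochastic) and average slope/intercept.

The averaged slopes of all included (right-handed) participants are then
tested with a one-sample one-sided t-test of mean > 0; the one-sided 95 %
confidence region for the mean slope is [mean − t₀.₉₅,df·SE, ∞).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from sklearn.base import BaseEstimator

__all__ = [
    "ParticipantResult",
    "GroupResult",
    "filter_pairs",
    "SmoteBalancer",
    "smote_balance",
    "fit_line",
    "ParticipantSlopeEstimator",
    "participant_slope",
    "GroupSlopeTest",
    "group_test",
]


@dataclass
class ParticipantResult:
    participant_id: str
    n_pairs_used: int
    unique_swb: int
    slope_mean: float | None
    intercept_mean: float | None
    n_repeats: int
    excluded: bool
    exclusion_reason: str | None = None
    handedness: str = "right"


@dataclass
class GroupResult:
    n_participants: int
    df: int
    t_stat: float
    p_value: float
    ci_lower: float
    mean_pairs_per_participant: float


def filter_pairs(
    faa: np.ndarray,
    swb: np.ndarray,
    min_class_count: int = 3,
    min_unique_classes: int = 3,
) -> tuple[np.ndarray, np.ndarray, str | None]:
    """Apply the per-participant inclusion rules.

    Drops every pair whose SWB class has fewer than ``min_class_count``
    members; returns ``(faa_kept, swb_kept, reason)`` where ``reason`` is
    ``'too_few_unique_swb'`` if fewer than ``min_unique_classes`` distinct
    scores survive (participant excluded), else ``None``.
    """
    faa = np.asarray(faa, dtype=float)
    swb = np.asarray(swb, dtype=int)
    classes, counts = np.unique(swb, return_counts=True)
    keep_classes = classes[counts >= min_class_count]
    mask = np.isin(swb, keep_classes)
    faa_kept, swb_kept = faa[mask], swb[mask]
    reason = None
    if len(np.unique(swb_kept)) < min_unique_classes:
        reason = "too_few_unique_swb"
    return faa_kept, swb_kept, reason


class SmoteBalancer(BaseEstimator):
    """SMOTE oversampler on the 1-D FAA feature with SWB as class label.

    Every class is brought up to the majority count by interpolating
    between a random class member and one of its ``k`` nearest same-class
    neighbours (``k = min(k_neighbors, n_class − 1)``; distance ties broken
    by lower index).  Original pairs are always kept, synthetic ones are
    appended, and no label is ever changed.
    """

    def __init__(self, k_neighbors: int = 5,
                 random_state: int | np.random.Generator | None = None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(
        self, X: np.ndarray, y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=int)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        rng = self.random_state if isinstance(self.random_state, np.random.Generator) \
            else np.random.default_rng(self.random_state)

        classes, counts = np.unique(y, return_counts=True)
        n_max = counts.max()
        new_x, new_y = [x], [y]
        for cls, n_c in zip(classes, counts):
            need = int(n_max - n_c)
            if need == 0:
                continue
            if n_c < 2:
                raise ValueError(
                    f"class {cls} has {n_c} member(s); need at least 2 to interpolate")
            members = x[y == cls]
            k = min(self.k_neighbors, n_c - 1)
            dist = np.abs(members[:, None] - members[None, :])
            np.fill_diagonal(dist, np.inf)
            neighbors = np.argsort(dist, axis=1, kind="stable")[:, :k]
            base = rng.integers(0, n_c, size=need)
            pick = rng.integers(0, k, size=need)
            u = rng.random(size=need)
            nn = neighbors[base, pick]
            synth = members[base] + u * (members[nn] - members[base])
            new_x.append(synth)
            new_y.append(np.full(need, cls, dtype=int))
        return np.concatenate(new_x), np.concatenate(new_y)


def smote_balance(
    faa: np.ndarray,
    swb: np.ndarray,
    k_neighbors: int = 5,
    random_state: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Functional form of :class:`SmoteBalancer`."""
    return SmoteBalancer(k_neighbors, random_state).fit_resample(faa, swb)


def fit_line(faa: np.ndarray, swb: np.ndarray) -> tuple[float, float]:
    """OLS of FAA (response) on SWB (predictor): returns (slope, intercept)."""
    faa = np.asarray(faa, dtype=float)
    swb = np.asarray(swb, dtype=float)
    if len(np.unique(swb)) < 2:
        raise ValueError("need at least 2 distinct SWB values to fit a line")
    slope, intercept = np.polyfit(swb, faa, 1)
    return float(slope), float(intercept)


class ParticipantSlopeEstimator(BaseEstimator):
    """One participant's SMOTE-corrected FAA–SWB slope.

    ``fit`` applies the inclusion filter, then runs (SMOTE → OLS)
    ``n_repeats`` times on independent substreams and averages.  Fitted
    attributes: ``slope_mean_``, ``intercept_mean_``, ``slopes_``,
    ``intercepts_``, ``n_pairs_used_``, ``unique_swb_``, ``excluded_``,
    ``exclusion_reason_``.
    """

    def __init__(
        self,
        n_repeats: int = 10,
        k_neighbors: int = 5,
        min_class_count: int = 3,
        min_unique_classes: int = 3,
        random_state: int | np.random.Generator | None = None,
    ):
        self.n_repeats = n_repeats
        self.k_neighbors = k_neighbors
        self.min_class_count = min_class_count
        self.min_unique_classes = min_unique_classes
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ParticipantSlopeEstimator":
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")
        faa, swb, reason = filter_pairs(
            X, y, self.min_class_count, self.min_unique_classes)
        self.n_pairs_used_ = len(faa)
        self.unique_swb_ = len(np.unique(swb))
        self.excluded_ = reason is not None
        self.exclusion_reason_ = reason
        self.slopes_ = None
        self.intercepts_ = None
        self.slope_mean_ = None
        self.intercept_mean_ = None
        if self.excluded_:
            return self

        rng = self.random_state if isinstance(self.random_state, np.random.Generator) \
            else np.random.default_rng(self.random_state)
        slopes, intercepts = [], []
        for child in rng.spawn(self.n_repeats):
            bal_faa, bal_swb = SmoteBalancer(self.k_neighbors, child).fit_resample(faa, swb)
            s, i = fit_line(bal_faa, bal_swb)
            slopes.append(s)
            intercepts.append(i)
        self.slopes_ = np.array(slopes)
        self.intercepts_ = np.array(intercepts)
        self.slope_mean_ = float(self.slopes_.mean())
        self.intercept_mean_ = float(self.intercepts_.mean())
        return self


def participant_slope(
    faa: np.ndarray,
    swb: np.ndarray,
    n_repeats: int = 10,
    k_neighbors: int = 5,
    random_state: int | np.random.Generator | None = None,
    participant_id: str = "P000",
    handedness: str = "right",
) -> ParticipantResult:
    """Functional form of :class:`ParticipantSlopeEstimator`."""
    est = ParticipantSlopeEstimator(
        n_repeats=n_repeats, k_neighbors=k_neighbors, random_state=random_state
    ).fit(faa, swb)
    return ParticipantResult(
        participant_id=participant_id,
        n_pairs_used=est.n_pairs_used_,
        unique_swb=est.unique_swb_,
        slope_mean=est.slope_mean_,
        intercept_mean=est.intercept_mean_,
        n_repeats=n_repeats,
        excluded=est.excluded_,
        exclusion_reason=est.exclusion_reason_,
        handedness=handedness,
    )


class GroupSlopeTest(BaseEstimator):
    """One-sided group test of the mean participant slope against zero.

    ``fit(slopes)`` computes a one-sample t-test of H₀: mean = 0 against
    H₁: mean > 0 and the one-sided (1−alpha) confidence bound.  Fitted
    attributes: ``t_stat_``, ``p_value_``, ``df_``, ``ci_lower_``,
    ``n_participants_``, ``mean_slope_``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, slopes: np.ndarray) -> "GroupSlopeTest":
        slopes = np.asarray(slopes, dtype=float)
        if len(slopes) < 2:
            raise ValueError("need at least 2 participants for the group test")
        if np.allclose(slopes, slopes[0]):
            raise ValueError("zero variance in participant slopes")
        res = scipy.stats.ttest_1samp(slopes, 0.0, alternative="greater")
        n = len(slopes)
        se = slopes.std(ddof=1) / np.sqrt(n)
        self.n_participants_ = n
        self.df_ = n - 1
        self.t_stat_ = float(res.statistic)
        self.p_value_ = float(res.pvalue)
        self.mean_slope_ = float(slopes.mean())
        self.ci_lower_ = float(
            slopes.mean() - scipy.stats.t.ppf(1.0 - self.alpha, n - 1) * se)
        return self


def group_test(
    results: list[ParticipantResult],
    alpha: float = 0.05,
    exclude_left_handed: bool = True,
) -> GroupResult:
    """Group-level inference over per-participant results.

    Excluded participants are dropped; left-handed ones too when
    ``exclude_left_handed`` (handedness effects on the asymmetry measure
    are unresolved, so they are filtered rather than modelled).
    """
    usable = [r for r in results if not r.excluded]
    if exclude_left_handed:
        usable = [r for r in usable if r.handedness != "left"]
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable participants")
    slopes = np.array([r.slope_mean for r in usable])
    test = GroupSlopeTest(alpha=alpha).fit(slopes)
    return GroupResult(
        n_participants=test.n_participants_,
        df=test.df_,
        t_stat=test.t_stat_,
        p_value=test.p_value_,
        ci_lower=test.ci_lower_,
        mean_pairs_per_participant=float(np.mean([r.n_pairs_used for r in usable])),
    )
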