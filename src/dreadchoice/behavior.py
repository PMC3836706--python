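"""Model-free behavioral summaries and subject classification.

The central summary is the proportion of trials on which the more-delayed
option was chosen -- p(Choose S2) in the shock task, p(Choose A2) in the
dental task -- as a function of the delay difference between the options,
binned into zero / short / medium / long.  On a counterbalanced design the
zero-delay-difference proportion is theoretically bounded at 0.5, so values
below 0.5 at positive delay differences indicate negative time preference
(a preference to expedite pain).

Subjects are classified into four mutually exclusive phenotypes from the
per-bin counts: *zero* (no significant deflection from 0.5 in any bin, exact
binomial test), and otherwise *positive*, *negative* or *reversing* according
to whether the curve shows significant increases, decreases, or both.
Changes are assessed between pairs of populated bins by two-sided exact
tests on the 2x2 counts (all pairs by default); in addition, the first
binomial-significant bin counts as a change from the theoretical 0.5 anchor
at zero delay difference (this is what identifies a subject sitting
uniformly below 0.5 with no between-bin trend as *negative*).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .designs import bin_delay_difference
from .likelihood import ChoiceDataset

__all__ = [
    "BIN_ORDER",
    "ChoiceCurve",
    "PhenotypeLabel",
    "choice_curve",
    "pooled_choice_curve",
    "classify_time_preference",
    "framing_effect_test",
    "FramingTestResult",
    "apply_exclusions",
    "repeated_measures_anova",
]

BIN_ORDER = ("zero", "short", "medium", "long")


@dataclass
class ChoiceCurve:
    """Per-delay-difference-bin counts of later-option choices."""

    n_later: dict[str, int]
    n_total: dict[str, int]
    experiment: int = 1

    @property
    def proportions(self) -> dict[str, float]:
        """p(choose later) per bin; empty bins map to nan (flagged)."""
        return {
            b: (self.n_later[b] / self.n_total[b] if self.n_total[b] > 0
                else float("nan"))
            for b in BIN_ORDER
        }

    @property
    def populated_bins(self) -> list[str]:
        return [b for b in BIN_ORDER if self.n_total[b] > 0]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": list(BIN_ORDER),
            "n_later": [self.n_later[b] for b in BIN_ORDER],
            "n_total": [self.n_total[b] for b in BIN_ORDER],
            "p_choose_later": [self.proportions[b] for b in BIN_ORDER],
        })


@dataclass
class PhenotypeLabel:
    """Time-preference phenotype plus the supporting test results."""

    label: str  # zero | positive | negative | reversing | unclassifiable
    binomial_p: dict[str, float] = field(default_factory=dict)
    change_tests: list[dict] = field(default_factory=list)


def choice_curve(data: ChoiceDataset, experiment: int = 1) -> ChoiceCurve:
    """Bin one dataset's choices by delay difference."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    dd = (data.t_later - data.t_sooner).astype(int)
    n_later = {b: 0 for b in BIN_ORDER}
    n_total = {b: 0 for b in BIN_ORDER}
    for d, c in zip(dd, data.choice):
        b = bin_delay_difference(int(d), experiment)
        n_total[b] += 1
        n_later[b] += int(c)
    return ChoiceCurve(n_later=n_later, n_total=n_total, experiment=experiment)


def pooled_choice_curve(datasets: list[ChoiceDataset], experiment: int = 1,
                        how: str = "counts") -> ChoiceCurve | dict[str, float]:
    """Combine several frames of one subject.

    how="counts" pools the raw counts into one curve (used for
    classification); how="mean" averages the two frames' proportions per bin
    and returns the averaged proportions.
    """
    curves = [choice_curve(d, experiment) for d in datasets]
    if how == "counts":
        return ChoiceCurve(
            n_later={b: sum(c.n_later[b] for c in curves) for b in BIN_ORDER},
            n_total={b: sum(c.n_total[b] for c in curves) for b in BIN_ORDER},
            experiment=experiment,
        )
    if how == "mean":
        return {
            b: float(np.mean([c.proportions[b] for c in curves]))
            for b in BIN_ORDER
        }
    raise ValueError("how must be 'counts' or 'mean'")


def classify_time_preference(curve: ChoiceCurve, alpha_level: float = 0.05,
                             comparisons: str = "all_pairs") -> PhenotypeLabel:
    """Assign a zero/positive/negative/reversing phenotype from a choice curve.

    comparisons="all_pairs" (default) tests every ordered pair of populated
    bins -- a reversing subject's recovery is typically spread over two bin
    steps, so adjacent-only testing under-detects it; "adjacent" restricts
    to consecutive populated bins.
    """
    bins = curve.populated_bins
    if len(bins) < 2:
        return PhenotypeLabel(label="unclassifiable")

    binom_p = {}
    deflection = {}
    for b in bins:
        k, n = curve.n_later[b], curve.n_total[b]
        res = stats.binomtest(k, n, 0.5, alternative="two-sided")
        binom_p[b] = float(res.pvalue)
        deflection[b] = np.sign(k / n - 0.5)

    significant = [b for b in bins if binom_p[b] < alpha_level]
    if not significant:
        return PhenotypeLabel(label="zero", binomial_p=binom_p)

    has_increase = False
    has_decrease = False
    changes: list[dict] = []

    # anchor: the first significant deflection is a change from the 0.5 bound
    first_sig = significant[0]
    anchor_dir = deflection[first_sig]
    changes.append({"from": "anchor_0.5", "to": first_sig,
                    "p": binom_p[first_sig], "direction": anchor_dir})
    has_increase |= anchor_dir > 0
    has_decrease |= anchor_dir < 0

    if comparisons == "adjacent":
        pairs = list(zip(bins[:-1], bins[1:]))
    elif comparisons == "all_pairs":
        pairs = list(itertools.combinations(bins, 2))
    else:
        raise ValueError("comparisons must be 'adjacent' or 'all_pairs'")

    props = curve.proportions
    for b1, b2 in pairs:
        table = [
            [curve.n_later[b1], curve.n_total[b1] - curve.n_later[b1]],
            [curve.n_later[b2], curve.n_total[b2] - curve.n_later[b2]],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        direction = np.sign(props[b2] - props[b1])
        changes.append({"from": b1, "to": b2, "p": float(p),
                        "direction": direction})
        if p < alpha_level:
            has_increase |= direction > 0
            has_decrease |= direction < 0

    if has_increase and has_decrease:
        label = "reversing"
    elif has_increase:
        label = "positive"
    else:
        label = "negative"
    return PhenotypeLabel(label=label, binomial_p=binom_p, change_tests=changes)


@dataclass
class FramingTestResult:
    p_sooner_pain: float
    p_sooner_relief: float
    p_value: float
    direction: int  # +1: more sooner choices in the pain frame (expected)


def framing_effect_test(pain_data: ChoiceDataset,
                        relief_data: ChoiceDataset) -> FramingTestResult:
    """Per-subject exact test for a framing effect on sooner-choice frequency.

    Tests the 2x2 table of sooner/later counts by frame; the direction flag
    is positive when sooner pain is chosen more often in the pain frame (the
    expected direction of a relief-framing effect).
    """
    if len(pain_data) == 0 or len(relief_data) == 0:
        raise ValueError("both frames must be non-empty")
    s_pain = int(np.sum(pain_data.choice == 0))
    s_rel = int(np.sum(relief_data.choice == 0))
    table = [
        [s_pain, len(pain_data) - s_pain],
        [s_rel, len(relief_data) - s_rel],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    f_pain = s_pain / len(pain_data)
    f_rel = s_rel / len(relief_data)
    return FramingTestResult(
        p_sooner_pain=f_pain, p_sooner_relief=f_rel, p_value=float(p),
        direction=int(np.sign(f_pain - f_rel)))


def apply_exclusions(cohort: dict[str, dict],
                     rating_threshold: float = 4.0) -> tuple[list[str], list[dict]]:
    """Apply the inclusion rules to a cohort.

    ``cohort`` maps subject -> {"datasets": [ChoiceDataset, ...],
    "max_rate_rating": float | None}.  A subject is excluded if (a) the
    end-of-session rating of the maximum shock rate is below the threshold
    (significant adaptation), or (b) they chose the sooner option on 100% of
    choices in at least one frame ("maximum dreaders", whose indifference
    points lie outside the offered choice set).
    """
    included: list[str] = []
    excluded: list[dict] = []
    for sid in sorted(cohort):
        entry = cohort[sid]
        rating = entry.get("max_rate_rating")
        if rating is not None and rating < rating_threshold:
            excluded.append({"subject_id": sid, "reason": "adaptation",
                             "detail": f"max-rate rating {rating} < {rating_threshold}"})
            continue
        dreader = None
        for ds in entry["datasets"]:
            if len(ds) > 0 and np.all(ds.choice == 0):
                dreader = ds.frame
                break
        if dreader is not None:
            excluded.append({"subject_id": sid, "reason": "max_dreader",
                             "detail": f"100% sooner choices in {dreader} frame"})
            continue
        included.append(sid)
    return included, excluded


def repeated_measures_anova(df: pd.DataFrame, dv: str, subject: str,
                            within: list[str]) -> pd.DataFrame:
    """Convenience repeated-measures ANOVA via statsmodels (non-bespoke).

    Thin wrapper over ``statsmodels.stats.anova.AnovaRM`` for the standard
    frame x delay-bin group inference on choice proportions.
    """
    from statsmodels.stats.anova import AnovaRM

    return AnovaRM(df, depvar=dv, subject=subject, within=within).fit().anova_table
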