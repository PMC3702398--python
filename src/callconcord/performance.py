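"""Per-caller performance from validation labels and detection patterns.

Turns a labeling scheme's per-site statuses plus the K-caller detection
patterns into confusion counts, error rates, ROC-like curves over a
threshold sweep (true positive rate against false *discovery* rate — on an
ascertained candidate set only relative false-positive rates are
meaningful, and FDR has an intuitive scale), prevalence-rescaled FP rates
for cross-scheme comparison, and an ascertainment diagnostic that flags a
validation set drawn from one caller's calls only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .callset_io import Pattern, VariantSite
from .latent_class import LcmFit
from .validation import ValidationStatus

__all__ = [
    "ConfusionCounts",
    "RocPoint",
    "confusion_per_caller",
    "roc_like_curve",
    "rescale_fp",
    "ascertainment_crosstab",
    "method_comparison_report",
]

_POSITIVE_LABELS = {ValidationStatus.SOMATIC, ValidationStatus.POSITIVE}
_UNSCORED = {
    ValidationStatus.NOT_ATTEMPTED,
    ValidationStatus.NOT_EVALUABLE,
    ValidationStatus.UNKNOWN,
    ValidationStatus.NONMAF,
    ValidationStatus.AMBIGUOUS,
}


@dataclass
class ConfusionCounts:
    """Per-caller confusion table against one labeling scheme."""

    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0
    n_not_attempted: int = 0

    @property
    def fp_rate(self) -> float | None:
        d = self.FP + self.TN
        return self.FP / d if d else None

    @property
    def fn_rate(self) -> float | None:
        d = self.FN + self.TP
        return self.FN / d if d else None

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN + self.n_not_attempted


@dataclass
class RocPoint:
    """One point of a threshold sweep: positives called at `threshold`."""

    threshold: float
    TP: int
    FP: int
    tpr: float
    fdr: float | None  # None when no positives were called

    @property
    def n_positive(self) -> int:
        return self.TP + self.FP


def confusion_per_caller(
    patterns: Mapping[VariantSite, Pattern],
    labels: Mapping[VariantSite, ValidationStatus],
    caller_order: Sequence[str],
    ascertainment_mask: set[VariantSite] | None = None,
) -> dict[str, ConfusionCounts]:
    """Confusion counts per caller against a scheme's labels.

    Sites outside ``ascertainment_mask`` (when given), or whose label is
    unknown / not attempted / not evaluable, count as not-attempted and
    never enter a rate denominator.
    """
    out = {c: ConfusionCounts() for c in caller_order}
    for site, pat in patterns.items():
        label = labels.get(site, ValidationStatus.NOT_ATTEMPTED)
        masked = ascertainment_mask is not None and site not in ascertainment_mask
        scored = not masked and label not in _UNSCORED
        truth = label in _POSITIVE_LABELS
        for k, caller in enumerate(caller_order):
            cc = out[caller]
            if not scored:
                cc.n_not_attempted += 1
            elif pat[k] and truth:
                cc.TP += 1
            elif pat[k]:
                cc.FP += 1
            elif truth:
                cc.FN += 1
            else:
                cc.TN += 1
    return out


def roc_like_curve(
    scores: np.ndarray | Sequence[float],
    truth: np.ndarray | Sequence[bool],
    thresholds: Sequence[float],
    filter_flags: np.ndarray | Sequence[bool] | None = None,
) -> list[RocPoint]:
    """TPR-vs-FDR sweep: positives are sites with score strictly above threshold.

    ``truth`` marks validated somatic sites; ``filter_flags`` (optional)
    marks sites a strand-bias filter removes — filtered sites are never
    counted as positives, so the filter can only shrink the positive set.
    The TPR denominator is the total number of true sites in the sweep
    universe, fixed across thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must align")
    keep = (
        np.ones_like(truth)
        if filter_flags is None
        else ~np.asarray(filter_flags, dtype=bool)
    )
    n_true = int(truth.sum())
    points = []
    for thr in thresholds:
        pos = (scores > thr) & keep
        tp = int((pos & truth).sum())
        fp = int((pos & ~truth).sum())
        fdr = fp / (tp + fp) if (tp + fp) > 0 else None
        tpr = tp / n_true if n_true else float("nan")
        points.append(RocPoint(threshold=float(thr), TP=tp, FP=fp, tpr=tpr, fdr=fdr))
    return points


def rescale_fp(
    fp_count: int, n_true_pos_eval: int, ref_prevalence: float = 0.03
) -> float:
    """FP rate rescaled to a common reference prevalence of true somatics.

    Absolute FP rates are not comparable across evaluation universes of
    different composition; assuming a fixed share ``ref_prevalence`` of
    any screened universe is truly somatic, the implied negative count per
    ``n_true_pos_eval`` true positives is
    ``n_true_pos_eval * (1 - p) / p``, and the rescaled rate is the FP
    count divided by that.
    """
    if n_true_pos_eval <= 0:
        raise ValueError("n_true_pos_eval must be positive")
    if not 0 < ref_prevalence < 1:
        raise ValueError("ref_prevalence must lie in (0, 1)")
    expected_neg = n_true_pos_eval * (1 - ref_prevalence) / ref_prevalence
    return fp_count / expected_neg


def ascertainment_crosstab(
    labels: Mapping[VariantSite, ValidationStatus],
    patterns: Mapping[VariantSite, Pattern],
    caller_order: Sequence[str],
    flag_share: float = 0.99,
) -> tuple[pd.DataFrame, str | None]:
    """Cross-tabulate detection pattern against validation group; flag bias.

    If at least ``flag_share`` of the attempted-validation sites carry one
    caller's bit, validation was almost surely ascertained on that caller's
    calls, and rates computed from these labels are unfair to every other
    caller.  Returns the full crosstab and the flagged caller (or None).
    """
    rows = []
    for site, pat in patterns.items():
        label = labels.get(site, ValidationStatus.NOT_ATTEMPTED)
        attempted = label not in {
            ValidationStatus.NOT_ATTEMPTED,
            ValidationStatus.NONMAF,
            ValidationStatus.UNKNOWN,
        }
        rows.append(
            {
                "pattern": "".join(map(str, pat)),
                "group": label.value,
                "attempted": attempted,
                **{c: pat[k] for k, c in enumerate(caller_order)},
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(), None
    table = pd.crosstab(df["pattern"], df["group"])
    attempted = df[df["attempted"]]
    flagged = None
    if len(attempted):
        for caller in caller_order:
            if attempted[caller].mean() >= flag_share:
                flagged = caller
                break
    return table, flagged


def method_comparison_report(
    patterns: Mapping[VariantSite, Pattern],
    scheme_labels: Mapping[str, Mapping[VariantSite, ValidationStatus]],
    caller_order: Sequence[str],
    lcm_fits: Mapping[str, LcmFit] | None = None,
    ref_prevalence: float = 0.03,
) -> dict:
    """Per-caller per-scheme FP (raw + rescaled) and FN rates, plus agreement.

    Rates come from :func:`confusion_per_caller` per scheme; latent-class
    fits contribute model-based rows without any labels.  Scheme agreement
    is the fraction of identically-labeled sites over each pair's shared
    evaluable universe.  Undefined rates propagate as NaN, never 0.
    """
    if not scheme_labels and not lcm_fits:
        raise ValueError("at least one labeling scheme or LCM fit is required")
    rows = []
    for scheme, labels in scheme_labels.items():
        conf = confusion_per_caller(patterns, labels, caller_order)
        for caller, cc in conf.items():
            fp_rescaled = (
                rescale_fp(cc.FP, cc.TP + cc.FN, ref_prevalence)
                if (cc.TP + cc.FN) > 0
                else float("nan")
            )
            rows.append(
                {
                    "scheme": scheme,
                    "caller": caller,
                    "fp_rate": cc.fp_rate if cc.fp_rate is not None else float("nan"),
                    "fp_rate_rescaled": fp_rescaled,
                    "fn_rate": cc.fn_rate if cc.fn_rate is not None else float("nan"),
                    "n_scored": cc.total - cc.n_not_attempted,
                    "n_not_attempted": cc.n_not_attempted,
                }
            )
    if lcm_fits:
        from .latent_class import LcmCIParams, marginal_rates

        for name, fit in lcm_fits.items():
            if isinstance(fit.params, LcmCIParams):
                fps, fns = fit.params.fp, fit.params.fn
            else:
                fps, fns = marginal_rates(fit.params)
            eta = fit.params.eta
            for k, caller in enumerate(caller_order):
                # implied FP count per expected negative at the reference
                # prevalence: fp * (1-eta)/eta sites per true positive,
                # against (1-p)/p negatives per true positive
                rescaled = (
                    float(fps[k])
                    * ((1 - eta) / eta)
                    * (ref_prevalence / (1 - ref_prevalence))
                    if 0 < eta < 1
                    else float("nan")
                )
                rows.append(
                    {
                        "scheme": f"latent:{name}",
                        "caller": caller,
                        "fp_rate": float(fps[k]),
                        "fp_rate_rescaled": rescaled,
                        "fn_rate": float(fns[k]),
                        "n_scored": 0,
                        "n_not_attempted": 0,
                    }
                )
    rates = pd.DataFrame(rows)

    agreement = {}
    names = list(scheme_labels)
    for i, s1 in enumerate(names):
        for s2 in names[i + 1 :]:
            l1, l2 = scheme_labels[s1], scheme_labels[s2]
            shared = [
                site
                for site in patterns
                if l1.get(site, ValidationStatus.NOT_ATTEMPTED) not in _UNSCORED
                and l2.get(site, ValidationStatus.NOT_ATTEMPTED) not in _UNSCORED
            ]
            if not shared:
                agreement[(s1, s2)] = float("nan")
                continue
            same = sum(
                (l1[site] in _POSITIVE_LABELS) == (l2[site] in _POSITIVE_LABELS)
                for site in shared
            )
            agreement[(s1, s2)] = same / len(shared)
    return {"rates": rates, "scheme_agreement": agreement}
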