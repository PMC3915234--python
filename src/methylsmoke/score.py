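"""Weighted methylation smoking score.

A sample's smoking score summarises, over a panel of smoking-associated
CpG sites, how far its methylation has moved from never-smoker reference
levels in the direction expected of a current smoker:

    score = sum_hyper w_i * (beta_i - ref_i) + sum_hypo w_i * (ref_i - beta_i)

where ``ref_i`` is the panel's never-smoker median beta at CpG i and the
weight ``w_i = |e_i| / mean(|e|)`` is the CpG's catalogued effect-size
magnitude relative to the panel average (so weights average exactly 1).

The score of a never-smoker-like sample is near 0; current smokers score
high. The threshold separating the two classes is learned with an
ensemble of bootstrapped single-split decision trees (stumps) on the
one-dimensional score: the reported threshold is the mean of the root
split points over the ensemble (500 trees by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier
from sklearn.tree._tree import TREE_UNDEFINED

__all__ = [
    "HYPER", "HYPO",
    "compute_weights", "validate_panel", "compute_score",
    "learn_threshold", "classify", "evaluate",
    "cross_apply_thresholds", "score_report",
    "ScoreEvaluation", "ScoreReport",
]

HYPER = "hyper_in_smokers"
HYPO = "hypo_in_smokers"

#: fraction of panel CpGs that may be absent from a beta matrix before
#: scoring is refused outright (absent CpGs below this are dropped, with
#: no weight renormalisation).
MAX_MISSING_FRACTION = 0.10


def compute_weights(effect_sizes) -> np.ndarray:
    """Per-CpG weights: |effect| divided by the panel-mean |effect|.

    By construction the weights are strictly positive and average to 1.
    """
    mags = np.abs(np.asarray(effect_sizes, dtype=float))
    if mags.size == 0:
        raise ValueError("empty effect-size vector")
    if np.any(mags <= 0) or not np.all(np.isfinite(mags)):
        raise ValueError("all effect-size magnitudes must be positive and finite")
    return mags / mags.mean()


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check a reference panel's invariants; returns the panel unchanged.

    Expected columns: probe_id, direction ({hyper,hypo}_in_smokers),
    effect_size (positive magnitude), reference_beta in (0,1), weight
    (positive, mean 1 within 1e-9).
    """
    required = {"probe_id", "direction", "effect_size", "reference_beta", "weight"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns {sorted(missing)}")
    if len(panel) < 1:
        raise ValueError("panel must contain at least one CpG")
    if panel["probe_id"].duplicated().any():
        raise ValueError("duplicated probe ids in panel")
    if not panel["direction"].isin([HYPER, HYPO]).all():
        raise ValueError(f"direction must be one of {HYPER!r}, {HYPO!r}")
    if np.any(panel["effect_size"].values <= 0):
        raise ValueError("effect sizes must be positive magnitudes")
    ref = panel["reference_beta"].values
    if np.any((ref <= 0) | (ref >= 1)):
        raise ValueError("reference betas must lie in (0, 1)")
    w = panel["weight"].values
    if np.any(w <= 0) or abs(w.mean() - 1.0) > 1e-9:
        raise ValueError("weights must be positive with mean 1")
    return panel


def compute_score(sample_betas, panel: pd.DataFrame):
    """Weighted smoking score of one sample or a whole beta matrix.

    Parameters
    ----------
    sample_betas : Series (one sample, indexed by probe) or DataFrame
        (probes x samples).
    panel : reference panel (see :func:`validate_panel`).

    Returns a float for a Series input, or a Series of per-sample scores
    (with ``attrs['panel_coverage']`` recording the fraction of panel CpGs
    actually used). Up to 10% of panel CpGs may be missing from the input;
    they are dropped with a warning and weights are *not* renormalised.
    """
    validate_panel(panel)
    single = isinstance(sample_betas, pd.Series)
    betas = sample_betas.to_frame() if single else sample_betas

    present = panel["probe_id"].isin(betas.index)
    n_missing = int((~present).sum())
    coverage = 1.0 - n_missing / len(panel)
    if n_missing / len(panel) > MAX_MISSING_FRACTION:
        raise ValueError(
            f"{n_missing}/{len(panel)} panel CpGs missing from the beta matrix "
            f"(more than {MAX_MISSING_FRACTION:.0%})"
        )
    used = panel[present]
    if n_missing:
        warnings.warn(
            f"{n_missing} panel CpG(s) missing; scoring on {coverage:.1%} of the panel "
            "without weight renormalisation", stacklevel=2,
        )

    sign = np.where(used["direction"].values == HYPER, 1.0, -1.0)
    b = betas.loc[used["probe_id"]].values  # panel CpGs x samples
    dev = sign[:, None] * (b - used["reference_beta"].values[:, None])
    scores = (used["weight"].values[:, None] * dev).sum(axis=0)
    if single:
        return float(scores[0])
    out = pd.Series(scores, index=betas.columns, name="smoking_score")
    out.attrs["panel_coverage"] = coverage
    return out


def _fit_stump(values: np.ndarray, labels: np.ndarray) -> float:
    """Root split point of a depth-1 Gini tree, or nan if no split helps."""
    tree = DecisionTreeClassifier(max_depth=1).fit(values[:, None], labels)
    t = tree.tree_.threshold[0]
    return float(t) if t != TREE_UNDEFINED else float("nan")


def learn_threshold(scores, labels, n_trees: int = 500, seed=None,
                    max_retries: int = 100) -> float:
    """Score threshold separating current from never smokers.

    Fits ``n_trees`` decision stumps, each on a bootstrap resample of the
    (score, label) pairs, and returns the mean of their split points
    (sklearn's midpoint convention per stump). Former smokers are excluded
    from fitting. A resample containing a single class, or on which no
    split reduces impurity, is redrawn up to ``max_retries`` times.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    keep = labels != "former"
    s, y = scores[keep], labels[keep] == "current"
    if not (y.any() and (~y).any()):
        raise ValueError("both current and never smokers are required")
    rng = np.random.default_rng(seed)
    splits = np.empty(n_trees)
    for i in range(n_trees):
        for _ in range(max_retries):
            idx = rng.integers(0, len(s), len(s))
            yi = y[idx]
            if not (yi.any() and (~yi).any()):
                continue
            t = _fit_stump(s[idx], yi)
            if np.isfinite(t):
                splits[i] = t
                break
        else:
            raise RuntimeError(
                f"could not draw a splittable bootstrap resample in {max_retries} tries"
            )
    return float(splits.mean())


def classify(scores, threshold: float) -> np.ndarray:
    """Predicted current-smoker indicator: score strictly above threshold."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return scores > threshold


@dataclass
class ScoreEvaluation:
    """Confusion counts and rates for current-smoker prediction.

    Sensitivity is computed over current smokers; specificity over never
    and former smokers pooled (both are the 'negative' class).
    """

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
                "sensitivity": self.sensitivity, "specificity": self.specificity}


def evaluate(predicted_current, true_status) -> ScoreEvaluation:
    """Sensitivity/specificity of predicted current-smoker labels."""
    pred = np.asarray(predicted_current, dtype=bool)
    status = np.asarray(true_status)
    valid = {"never", "former", "current"}
    if not set(np.unique(status)) <= valid:
        raise ValueError(f"true_status values must be in {sorted(valid)}")
    positive = status == "current"
    return ScoreEvaluation(
        tp=int((pred & positive).sum()),
        fn=int((~pred & positive).sum()),
        tn=int((~pred & ~positive).sum()),
        fp=int((pred & ~positive).sum()),
    )


def cross_apply_thresholds(scores, true_status, threshold: float) -> ScoreEvaluation:
    """Evaluate one group's scores under a threshold learned elsewhere."""
    return evaluate(classify(scores, threshold), true_status)


@dataclass
class ScoreReport:
    per_sample: pd.DataFrame
    thresholds: dict
    evaluations: dict
    cross: dict

    def summary(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "evaluations": {g: e.as_dict() for g, e in self.evaluations.items()},
            "cross_applied": {k: e.as_dict() for k, e in self.cross.items()},
        }


def score_report(scores: pd.Series, sheet: pd.DataFrame, group_col: str = "ethnicity",
                 n_trees: int = 500, seed=None) -> ScoreReport:
    """Group-wise thresholds, classifications and cross-applied evaluations.

    For each level of ``group_col`` a threshold is learned within-group
    (formers excluded), every group member is classified, and each group is
    additionally evaluated under every *other* group's threshold.
    """
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    sheet = sheet.loc[scores.index]
    groups = sheet[group_col].unique().tolist()
    rng = np.random.default_rng(seed)
    thresholds, evaluations, rows = {}, {}, []
    for g in groups:
        mask = (sheet[group_col] == g).values
        thresholds[g] = learn_threshold(
            scores.values[mask], sheet["smoking_status"].values[mask],
            n_trees=n_trees, seed=rng.integers(2**31),
        )
        pred = classify(scores.values[mask], thresholds[g])
        evaluations[g] = evaluate(pred, sheet["smoking_status"].values[mask])
        rows.append(pd.DataFrame({
            "score": scores.values[mask],
            "group": g,
            "smoking_status": sheet["smoking_status"].values[mask],
            "predicted_current": pred,
        }, index=scores.index[mask]))
    cross = {}
    for g in groups:
        mask = (sheet[group_col] == g).values
        for other in groups:
            if other == g:
                continue
            cross[f"{g}|threshold:{other}"] = cross_apply_thresholds(
                scores.values[mask], sheet["smoking_status"].values[mask],
                thresholds[other],
            )
    return ScoreReport(pd.concat(rows), thresholds, evaluations, cross)
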