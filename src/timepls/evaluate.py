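"""Variable-selection evaluation and the five-model simulation benchmark.

Selection quality is judged against the simulator's known truth with the
confusion counts (TP/FP/FN/TN), recall, precision and F1, and the
variable-selection ROC: sweeping a threshold over the per-variable
ranking score (VIP* - sigma_VIP) gives a TPR/FPR curve over variables
whose area (AUVSC) summarizes how well the score ranks discriminating
above non-discriminating variables.  Predictive quality on held-out
subjects is summarized by Q² of the model's own dummy response and the
ROC AUC of predicted scores against group membership.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

from .bilinear import q2_score, roc_auc
from .data import DataCube, DesignError, LongTable
from .pipeline import as_cube, auto_n_latent, cv_q2, fit_model
from .responses import ModelSpec, ResponseDesign
from .vip import bootstrap_vip, select_variables

__all__ = [
    "ConfusionCounts",
    "confusion",
    "prf_scores",
    "vs_roc",
    "permutation_test",
    "ttest_flag",
    "run_benchmark",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int


def _truth_flags(truth) -> np.ndarray:
    if isinstance(truth, pd.DataFrame):
        return truth["discriminating"].to_numpy(dtype=bool)
    return np.asarray(truth, dtype=bool)


def confusion(selected, truth) -> ConfusionCounts:
    """Cross-tabulate a selected index set against the truth flags."""
    flags = _truth_flags(truth)
    J = len(flags)
    selected = np.asarray(selected, dtype=int)
    if selected.size and (selected.min() < 0 or selected.max() >= J):
        raise IndexError(f"selected index outside 0..{J - 1}")
    sel = np.zeros(J, dtype=bool)
    sel[selected] = True
    return ConfusionCounts(
        TP=int(np.sum(sel & flags)),
        FP=int(np.sum(sel & ~flags)),
        FN=int(np.sum(~sel & flags)),
        TN=int(np.sum(~sel & ~flags)),
    )


def prf_scores(c: ConfusionCounts, beta: float = 1.0):
    """Recall, precision and F_beta from the confusion counts.

    Recall = TP/(TP+FN); Precision = TP/(TP+FP);
    F = (beta^2+1) * P * R / (beta^2 * (P + R)).  Undefined ratios are
    returned as NaN.
    """
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else float("nan")
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else float("nan")
    if np.isnan(recall) or np.isnan(precision) or (precision + recall) == 0:
        f = float("nan")
    else:
        f = (beta**2 + 1) * precision * recall / (beta**2 * (precision + recall))
    return recall, precision, f


def vs_roc(stats_or_scores, truth):
    """Variable-selection ROC curve and its area.

    Ranks variables by the selection score (VIP* - sigma_VIP when given
    a ``VipStats``); sweeping the threshold from +inf down gives the
    fraction of discriminating (TPR) and non-discriminating (FPR)
    variables selected.  The trapezoidal area equals the Mann-Whitney
    statistic between the two truth classes.
    """
    flags = _truth_flags(truth)
    scores = getattr(stats_or_scores, "score", stats_or_scores)
    scores = np.asarray(scores, dtype=float)
    if flags.all() or not flags.any():
        raise ValueError("variable-selection ROC undefined with a single truth class")
    fpr, tpr, thr = roc_curve(flags, scores)
    return (fpr, tpr), float(roc_auc_score(flags, scores))


def permutation_test(
    data: LongTable | DataCube,
    spec: ModelSpec,
    design: ResponseDesign,
    A: int,
    n_perm: int = 1000,
    seed=None,
    n_folds: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Unit-level group-label permutation test of model validity.

    The statistic is the cross-validated Q² of the model's dummy
    response; p = (1 + #{perm >= observed}) / (n_perm + 1).
    Returns (p, observed Q², permuted Q² values).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cube = as_cube(data)
    groups = cube.group.astype(str)
    if min((groups == g).sum() for g in np.unique(groups)) < 2:
        raise DesignError("need at least 2 units per group")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = cv_q2(cube, spec, design, A=A, n_folds=n_folds, seed=0)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = replace(cube, group=cube.group[rng.permutation(cube.shape[0])])
        null[i] = cv_q2(perm, spec, design, A=A, n_folds=n_folds, seed=0)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return p, observed, null


def ttest_flag(table: LongTable, alpha: float = 0.05) -> np.ndarray:
    """Two-sample Welch t-test per variable at each time point; a variable
    is flagged when at least one time point reaches p < alpha."""
    groups = np.unique(table.group.astype(str))
    if len(groups) != 2:
        raise DesignError("t-test flagging needs exactly two groups")
    pvals = []
    for t in table.times:
        m0 = (table.group.astype(str) == groups[0]) & (table.time == t)
        m1 = (table.group.astype(str) == groups[1]) & (table.time == t)
        if m0.sum() < 2 or m1.sum() < 2:
            raise DesignError(f"a group has < 2 samples at time {t}")
        res = sps.ttest_ind(table.X[m1], table.X[m0], equal_var=False, axis=0)
        pvals.append(res.pvalue)
    pmin = np.vstack(pvals).min(axis=0)
    return pmin < alpha


# ---------------------------------------------------------------------------
# benchmark harness


def run_benchmark(
    config,
    models=(1, 2, 3, 4, 5),
    n_repeats: int = 10,
    B: int = 200,
    seed: int | None = 0,
    design: ResponseDesign | None = None,
    A_max: int = 10,
    selection_rule: str = "vip",
) -> pd.DataFrame:
    """Train/test simulation benchmark of the model variants.

    Per repeat: a paired train/test dataset is simulated; the number of
    latent variables is chosen once per model by cross-validated RMSECV
    on the first repeat's training set (simulated repeats share their
    parameters, so the choice transfers) and reused afterwards;
    bootstrapped-VIP selection runs on the training set and is scored
    against the truth; Q² of the model's dummy response and the
    group-classification AUC are computed on the test set using all
    variables.

    Returns one row per (repeat, model) with aggregate mean/sd available
    via ``groupby("model").agg(...)``.
    """
    from .simulate import simulate_train_test

    design = design or ResponseDesign()
    specs = [m if isinstance(m, ModelSpec) else ModelSpec(m) for m in models]
    master = np.random.default_rng(seed)
    data_seeds = master.integers(0, 2**31 - 1, size=n_repeats)
    boot_seeds = master.integers(0, 2**31 - 1, size=(n_repeats, len(specs)))

    chosen_A: dict[int, int] = {}
    rows = []
    for r in range(n_repeats):
        train, test, truth = simulate_train_test(config, seed=int(data_seeds[r]))
        flags = _truth_flags(truth)
        for m, spec in enumerate(specs):
            if spec.model_id not in chosen_A:
                if spec.n_latent == "auto":
                    a, _ = auto_n_latent(train, spec, design, A_max=A_max, seed=0)
                else:
                    a = spec.n_latent
                chosen_A[spec.model_id] = a
            A = chosen_A[spec.model_id]
            stats = bootstrap_vip(
                train, spec, design, A=A, B=B, seed=int(boot_seeds[r, m]), rule=selection_rule
            )
            sel = select_variables(stats)
            c = confusion(sel, flags)
            recall, precision, f1 = prf_scores(c)
            _, auvsc = vs_roc(stats, flags)
            fm = fit_model(train, spec, design, n_components=A)
            yhat = fm.predict_response(test)
            ytrue = fm.true_response(test)
            q2 = q2_score(np.ravel(ytrue), np.ravel(yhat))
            scores, labels = fm.group_scores(test)
            auc = roc_auc(scores, labels)
            rows.append(
                {
                    "repeat": r,
                    "model": spec.model_id,
                    "n_latent": A,
                    "n_selected": len(sel),
                    "TP": c.TP,
                    "FP": c.FP,
                    "FN": c.FN,
                    "TN": c.TN,
                    "recall": recall,
                    "precision": precision,
                    "f1": f1,
                    "auvsc": auvsc,
                    "q2": q2,
                    "auc": auc,
                }
            )
    return pd.DataFrame(rows)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Mean (sd) per model in the layout # LV, Q², AUC, # Varsel, # TP,
    recall, precision, F1, AUVSC."""
    cols = ["n_latent", "q2", "auc", "n_selected", "TP", "recall", "precision", "f1", "auvsc"]
    agg = results.groupby("model")[cols].agg(["mean", "std"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    return agg
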