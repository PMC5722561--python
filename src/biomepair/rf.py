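"""Random-forest classification layer with OOB vote statistics.

A forest of ``ntree`` trees (``mtry`` candidate features per split, bootstrap
resampling per tree) is fit on the merged samples x genera proportion
matrix.  Everything downstream is driven by out-of-bag (OOB) information:

* the **vote fraction** of a sample — among trees where the sample was out
  of bag, the fraction voting "tumor"; > 0.5 means predicted tumor;
* the OOB error rate (misclassification at the 0.5 vote threshold);
* permutation importance (mean decrease in OOB accuracy per feature);
* an importance **null band** from refits on label-permuted data;
* **backward variable elimination** dropping a fixed fraction of the least
  important features per step, ranked once on the full model;
* the **0.632+ bootstrap** prediction-error estimate blending apparent and
  leave-one-out bootstrap error via the no-information rate;
* the per-patient paired **vote-fraction difference**
  d = vote(tumor) - vote(non-tumor), and its comparison across clinical
  groups (the "field effect" statistic: attenuated d in one group means the
  normal tissue there looks tumor-like to the model).

Tumor and non-tumor samples of one patient are treated as independent rows
during fitting; the pairing enters only through d.  Patient-grouped
bootstrap resampling is available as an extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier

from .core import PairedCohort, ValidationError

logger = logging.getLogger("biomepair")

POSITIVE_CLASS = "tumor"


@dataclass
class RFConfig:
    """Forest and resampling settings."""

    ntree: int = 2001
    mtry: int = 10
    seed: int = 0
    n_random_models: int = 20
    n_bootstrap: int = 1000
    drop_fraction: float = 0.2
    #: SD multiplier for the parsimony rule in backward elimination; 0 picks
    #: the outright minimum-error subset (ties toward the smallest subset)
    c_sd: float = 0.0

    def validate(self, n_features: Optional[int] = None) -> None:
        if self.ntree % 2 == 0:
            raise ValidationError("ntree must be odd to avoid vote ties")
        if self.ntree < 1 or self.mtry < 1:
            raise ValidationError("ntree and mtry must be positive")
        if n_features is not None and self.mtry > n_features:
            raise ValidationError(f"mtry={self.mtry} exceeds {n_features} features")
        if not 0.0 < self.drop_fraction < 1.0:
            raise ValidationError("drop_fraction must lie in (0, 1)")


def _as_matrix(features) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(features, pd.DataFrame):
        return (
            features.to_numpy(dtype=float),
            [str(c) for c in features.columns],
            [str(i) for i in features.index],
        )
    x = np.asarray(features, dtype=float)
    return x, [f"f{i}" for i in range(x.shape[1])], [str(i) for i in range(x.shape[0])]


def _as_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == bool:
        return y
    return y == POSITIVE_CLASS


@dataclass
class RFFit:
    """Fitted-forest summary built from out-of-bag information."""

    sample_ids: list[str]
    feature_names: list[str]
    y: np.ndarray  # True = tumor
    vote_fraction: np.ndarray  # OOB tumor-vote fraction per sample
    oob_error: float
    importance: Optional[pd.Series]  # mean decrease in OOB accuracy
    model: RandomForestClassifier

    @property
    def oob_prediction(self) -> np.ndarray:
        return self.vote_fraction > 0.5

    def votes(self) -> pd.Series:
        return pd.Series(self.vote_fraction, index=self.sample_ids)


def fit_rf(
    features,
    labels,
    config: RFConfig,
    *,
    compute_importance: bool = False,
    seed: Optional[int] = None,
) -> RFFit:
    """Fit the forest and extract OOB votes, error and (optionally) the
    permutation importance.

    ``features`` is a samples x features DataFrame (or array); ``labels``
    holds 'tumor'/'nontumor' strings or booleans (True = tumor).
    """
    x, feat_names, sample_ids = _as_matrix(features)
    y = _as_labels(labels)
    if x.shape[0] != y.size:
        raise ValidationError("features and labels disagree on sample count")
    if np.isnan(x).any():
        raise ValidationError("missing values in feature matrix")
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValidationError("need at least 2 samples per class")
    config.validate(n_features=x.shape[1])
    rf_seed = config.seed if seed is None else seed
    model = RandomForestClassifier(
        n_estimators=config.ntree,
        max_features=min(config.mtry, x.shape[1]),
        bootstrap=True,
        random_state=int(rf_seed) % (2**31 - 1),
        n_jobs=1,
    )
    model.fit(x, y.astype(int))
    n = x.shape[0]
    tumor_class_index = int(np.flatnonzero(model.classes_ == 1)[0])

    in_bag = np.zeros((config.ntree, n), dtype=bool)
    for t, sampled in enumerate(model.estimators_samples_):
        in_bag[t, sampled] = True

    votes_tumor = np.zeros(n)
    votes_total = np.zeros(n)
    per_tree_oob: list[np.ndarray] = []
    per_tree_pred: list[np.ndarray] = []
    for t, tree in enumerate(model.estimators_):
        oob = np.flatnonzero(~in_bag[t])
        per_tree_oob.append(oob)
        if oob.size == 0:
            per_tree_pred.append(np.empty(0, dtype=int))
            continue
        pred = tree.predict(x[oob]).astype(int)
        per_tree_pred.append(pred)
        votes_tumor[oob] += pred == 1
        votes_total[oob] += 1

    never_oob = np.flatnonzero(votes_total == 0)
    if never_oob.size:
        raise ValidationError(
            f"samples {[sample_ids[i] for i in never_oob]} were out of bag in no "
            f"tree; increase ntree (currently {config.ntree})"
        )
    vote_fraction = votes_tumor / votes_total
    oob_error = float(np.mean((vote_fraction > 0.5) != y))

    importance = None
    if compute_importance:
        perm_rng = np.random.default_rng((int(rf_seed) * 7919 + 13) % (2**31 - 1))
        imp = np.zeros(x.shape[1])
        for t, tree in enumerate(model.estimators_):
            oob = per_tree_oob[t]
            if oob.size == 0:
                continue
            y_oob = y[oob].astype(int)
            base_acc = float(np.mean(per_tree_pred[t] == y_oob))
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            x_oob = x[oob]
            for f in used:
                perm = perm_rng.permutation(oob.size)
                x_perm = x_oob.copy()
                x_perm[:, f] = x_oob[perm, f]
                acc = float(np.mean(tree.predict(x_perm).astype(int) == y_oob))
                imp[f] += base_acc - acc
        importance = pd.Series(imp / config.ntree, index=feat_names)

    return RFFit(
        sample_ids=sample_ids,
        feature_names=feat_names,
        y=y,
        vote_fraction=vote_fraction,
        oob_error=oob_error,
        importance=importance,
        model=model,
    )


@dataclass
class ImportanceNull:
    """Observed importance curve vs refits on randomized groupings."""

    observed_curve: np.ndarray  # sorted non-increasing
    null_curves: np.ndarray  # n_random_models x n_features, each sorted
    observed_features: list[str]  # feature names in observed-curve order

    @property
    def null_mean(self) -> np.ndarray:
        return self.null_curves.mean(axis=0)

    @property
    def null_sd(self) -> np.ndarray:
        return self.null_curves.std(axis=0, ddof=1)


def importance_null(features, labels, config: RFConfig) -> ImportanceNull:
    """Compare the sorted importance curve against models fit to random
    groupings (label permutations preserving class sizes)."""
    if config.n_random_models < 2:
        raise ValidationError("need at least 2 random models")
    observed = fit_rf(features, labels, config, compute_importance=True)
    obs_sorted = observed.importance.sort_values(ascending=False)
    y = _as_labels(labels)
    rng = np.random.default_rng((config.seed * 104729 + 1) % (2**31 - 1))
    curves = []
    for m in range(config.n_random_models):
        perm_y = y[rng.permutation(y.size)]
        fit = fit_rf(
            features, perm_y, config, compute_importance=True,
            seed=config.seed + 1000 + m,
        )
        curves.append(np.sort(fit.importance.to_numpy())[::-1])
    return ImportanceNull(
        observed_curve=obs_sorted.to_numpy(),
        null_curves=np.array(curves),
        observed_features=list(obs_sorted.index),
    )


@dataclass
class SelectionResult:
    subset_sizes: list[int]
    oob_errors: list[float]
    selected_features: list[str]
    ranking: list[str]  # all features, most important first
    full_fit: RFFit


def drop_schedule(n_features: int, drop_fraction: float) -> list[int]:
    """Subset sizes visited by backward elimination, full set down to 2."""
    sizes = [n_features]
    size = n_features
    while size > 2:
        nxt = int(size * (1.0 - drop_fraction))
        if nxt >= size:
            nxt = size - 1
        size = max(2, nxt)
        sizes.append(size)
    return sizes


def backward_variable_selection(
    features, labels, config: RFConfig, *, seed: Optional[int] = None
) -> SelectionResult:
    """Backward elimination of the least important features.

    Features are ranked once by the full model's permutation importance (not
    re-ranked after drops, avoiding selection bias); each step removes
    ``drop_fraction`` of the remaining features and records the refit OOB
    error.  The selected subset minimizes OOB error; with ``c_sd > 0`` the
    smallest subset within ``c_sd`` standard errors of the minimum is taken,
    and exact ties always resolve toward the smaller subset.
    """
    x, feat_names, _ = _as_matrix(features)
    if x.shape[1] < 2:
        raise ValidationError("need at least 2 features")
    base_seed = config.seed if seed is None else seed
    full = fit_rf(features, labels, config, compute_importance=True, seed=base_seed)
    ranking = full.importance.sort_values(ascending=False, kind="stable").index.tolist()
    df = features if isinstance(features, pd.DataFrame) else pd.DataFrame(x, columns=feat_names)

    sizes = drop_schedule(x.shape[1], config.drop_fraction)
    errors: list[float] = []
    for size in sizes:
        if size == x.shape[1]:
            errors.append(full.oob_error)
            continue
        sub = df[ranking[:size]]
        sub_cfg = RFConfig(**{**vars(config), "mtry": min(config.mtry, size)})
        fit = fit_rf(sub, labels, sub_cfg, seed=base_seed)
        errors.append(fit.oob_error)

    n = x.shape[0]
    err = np.asarray(errors)
    best = float(err.min())
    if config.c_sd > 0:
        se = np.sqrt(best * (1.0 - best) / n)
        threshold = best + config.c_sd * se
    else:
        threshold = best
    # sizes are non-increasing, so the last qualifying index is the smallest
    chosen_idx = max(i for i, e in enumerate(err) if e <= threshold)
    selected = ranking[: sizes[chosen_idx]]
    return SelectionResult(
        subset_sizes=sizes,
        oob_errors=errors,
        selected_features=selected,
        ranking=ranking,
        full_fit=full,
    )


def no_information_rate(labels, predictions) -> float:
    """gamma-hat = sum_k p_k (1 - q_k): expected error if predictions were
    independent of the truth, from observed class and prediction marginals."""
    y = _as_labels(labels)
    pred = _as_labels(predictions)
    if y.size == 0 or y.size != pred.size:
        raise ValidationError("labels and predictions must be equal-length, non-empty")
    p1 = float(np.mean(y))
    q1 = float(np.mean(pred))
    return p1 * (1.0 - q1) + (1.0 - p1) * q1


def estimate_632plus(
    err_apparent: float, err1: float, gamma: float
) -> tuple[float, float, float, float]:
    """Combine apparent error, leave-one-out bootstrap error and the
    no-information rate into the 0.632+ estimate.

    Returns ``(err1_clipped, relative_overfitting, weight, err_632plus)``:
    Err1' = min(Err1, gamma); R = (Err1' - err) / (gamma - err) clipped to
    [0, 1] and defined as 0 when Err1' <= err or gamma <= err;
    w = 0.632 / (1 - 0.368 R); estimate = (1 - w) err + w Err1'.
    """
    err1_clipped = min(err1, gamma)
    if gamma > err_apparent and err1_clipped > err_apparent:
        r_hat = (err1_clipped - err_apparent) / (gamma - err_apparent)
    else:
        r_hat = 0.0
    r_hat = float(np.clip(r_hat, 0.0, 1.0))
    w_hat = 0.632 / (1.0 - 0.368 * r_hat)
    err632 = (1.0 - w_hat) * err_apparent + w_hat * err1_clipped
    return err1_clipped, r_hat, float(w_hat), float(err632)


@dataclass
class BootstrapEval:
    """0.632+ bootstrap evaluation internals."""

    err_apparent: float  # training error of the full-data model
    err_loo_bootstrap: float  # Err1: mean per-item held-out error
    gamma: float  # no-information rate
    err1_clipped: float  # min(Err1, gamma)
    relative_overfitting: float  # R-hat in [0, 1]
    weight: float  # w-hat in [0.632, 1]
    err_632plus: float
    per_item_error: pd.Series
    selection_frequency: Optional[pd.Series] = None
    error_curves: Optional[list[tuple[list[int], list[float]]]] = None
    selected_sets: Optional[list[list[str]]] = None


def bootstrap_632plus(
    features,
    labels,
    config: RFConfig,
    *,
    with_selection: bool = False,
    patient_ids: Optional[Sequence[str]] = None,
) -> BootstrapEval:
    """0.632+ bootstrap estimate of prediction error.

    Each iteration resamples rows (or whole patients when ``patient_ids`` is
    given) with replacement as the training set and predicts the never-drawn
    rows.  With ``with_selection`` backward elimination runs inside each
    bootstrap and the held-out rows are predicted by the model refit on the
    selected subset, so selection frequencies and per-iteration error curves
    are also reported.
    """
    x, feat_names, sample_ids = _as_matrix(features)
    y = _as_labels(labels)
    n = x.shape[0]
    df = features if isinstance(features, pd.DataFrame) else pd.DataFrame(x, columns=feat_names)

    full = fit_rf(features, labels, config)
    apparent_pred = full.model.predict(x).astype(bool)
    err_apparent = float(np.mean(apparent_pred != y))
    gamma = no_information_rate(y, apparent_pred)

    rng = np.random.default_rng((config.seed * 15485863 + 7) % (2**31 - 1))
    loss_sum = np.zeros(n)
    loss_count = np.zeros(n)
    sel_counts = np.zeros(len(feat_names))
    curves: list[tuple[list[int], list[float]]] = []
    sets: list[list[str]] = []
    groups = None
    if patient_ids is not None:
        patient_ids = np.asarray(patient_ids)
        groups = {p: np.flatnonzero(patient_ids == p) for p in np.unique(patient_ids)}
        group_keys = sorted(groups)

    for b in range(config.n_bootstrap):
        for _ in range(100):
            if groups is None:
                idx = rng.integers(0, n, size=n)
            else:
                drawn = rng.integers(0, len(group_keys), size=len(group_keys))
                idx = np.concatenate([groups[group_keys[g]] for g in drawn])
            held = np.setdiff1d(np.arange(n), idx)
            if held.size and len(np.unique(y[idx])) == 2:
                break
        else:  # pragma: no cover - pathological label imbalance
            raise ValidationError("could not draw a two-class bootstrap sample")
        boot_seed = int(rng.integers(0, 2**31 - 1))
        x_tr = df.iloc[idx]
        y_tr = y[idx]
        if with_selection:
            sel = backward_variable_selection(x_tr, y_tr, config, seed=boot_seed)
            curves.append((sel.subset_sizes, sel.oob_errors))
            sets.append(sel.selected_features)
            for f in sel.selected_features:
                sel_counts[feat_names.index(f)] += 1
            sub_cfg = RFConfig(**{**vars(config), "mtry": min(config.mtry, len(sel.selected_features))})
            fit = fit_rf(x_tr[sel.selected_features], y_tr, sub_cfg, seed=boot_seed)
            pred = fit.model.predict(df[sel.selected_features].iloc[held]).astype(bool)
        else:
            fit = fit_rf(x_tr, y_tr, config, seed=boot_seed)
            pred = fit.model.predict(x[held]).astype(bool)
        loss_sum[held] += pred != y[held]
        loss_count[held] += 1

    never = np.flatnonzero(loss_count == 0)
    if never.size:
        raise ValidationError(
            f"samples {[sample_ids[i] for i in never]} were never held out; "
            f"increase n_bootstrap (currently {config.n_bootstrap})"
        )
    per_item = loss_sum / loss_count
    err1 = float(per_item.mean())
    err1_clipped, r_hat, w_hat, err632 = estimate_632plus(err_apparent, err1, gamma)
    return BootstrapEval(
        err_apparent=err_apparent,
        err_loo_bootstrap=err1,
        gamma=gamma,
        err1_clipped=err1_clipped,
        relative_overfitting=r_hat,
        weight=float(w_hat),
        err_632plus=float(err632),
        per_item_error=pd.Series(per_item, index=sample_ids),
        selection_frequency=(
            pd.Series(sel_counts / config.n_bootstrap, index=feat_names)
            if with_selection
            else None
        ),
        error_curves=curves if with_selection else None,
        selected_sets=sets if with_selection else None,
    )


@dataclass
class VoteDiffResult:
    """Per-patient paired vote-fraction differences."""

    patients: list[str]
    d: np.ndarray  # vote(tumor) - vote(nontumor), in [-1, 1]
    tumor_vote: np.ndarray
    nontumor_vote: np.ndarray
    correct_tumor: np.ndarray  # tumor sample predicted tumor
    correct_nontumor: np.ndarray
    excluded_patients: list[str]

    @property
    def correct_direction(self) -> np.ndarray:
        return self.d > 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patients,
                "tumor_vote": self.tumor_vote,
                "nontumor_vote": self.nontumor_vote,
                "d": self.d,
                "correct_tumor": self.correct_tumor,
                "correct_nontumor": self.correct_nontumor,
            }
        )


def vote_fraction_differences(fit: RFFit, cohort: PairedCohort) -> VoteDiffResult:
    """d = voteFraction(tumor) - voteFraction(non-tumor) per patient.

    A sample is classified correctly iff its vote fraction exceeds 0.5
    exactly when the sample is tumor tissue; d > 0 means the pair trends in
    the correct direction even if one member is misclassified.
    """
    votes = {s: v for s, v in zip(fit.sample_ids, fit.vote_fraction)}
    patients, ds, tv, nv, ct, cn, excluded = [], [], [], [], [], [], []
    for pid, (t, nt) in cohort.pairs.items():
        if t not in votes or nt not in votes:
            excluded.append(pid)
            continue
        patients.append(pid)
        tv.append(votes[t])
        nv.append(votes[nt])
        ds.append(votes[t] - votes[nt])
        ct.append(votes[t] > 0.5)
        cn.append(votes[nt] <= 0.5)
    if excluded:
        logger.warning("pairs without vote fractions excluded: %s", excluded)
    return VoteDiffResult(
        patients=patients,
        d=np.asarray(ds),
        tumor_vote=np.asarray(tv),
        nontumor_vote=np.asarray(nv),
        correct_tumor=np.asarray(ct, dtype=bool),
        correct_nontumor=np.asarray(cn, dtype=bool),
        excluded_patients=excluded,
    )


@dataclass
class FieldEffectResult:
    grouping: str
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    statistic: float
    p_value: float
    method: str

    @property
    def direction(self) -> str:
        ordered = sorted(self.group_means, key=self.group_means.get)
        return f"mean d: {ordered[0]} < {ordered[-1]}"


def field_effect_test(
    votediff: VoteDiffResult,
    cohort: PairedCohort,
    grouping: str = "t_stage",
    method: str = "welch",
) -> FieldEffectResult:
    """Compare per-patient d across two clinical groups.

    An attenuated mean d in one group (e.g. high T-stage) indicates the
    normal tissue there carries a tumor-like profile — a field effect.
    Welch's t by default; ``method='ranksum'`` for Mann-Whitney.
    """
    meta = cohort.metadata_frame()
    if grouping not in meta.columns:
        raise ValidationError(f"unknown grouping {grouping!r}")
    per_patient = (
        meta.drop_duplicates("patient_id").set_index("patient_id")[grouping].dropna()
    )
    d_by_group: dict[str, list[float]] = {}
    for pid, d in zip(votediff.patients, votediff.d):
        if pid in per_patient.index:
            d_by_group.setdefault(str(per_patient[pid]), []).append(float(d))
    if len(d_by_group) != 2:
        raise ValidationError(
            f"grouping {grouping!r} must yield exactly 2 groups, got {sorted(d_by_group)}"
        )
    (ga, xs), (gb, ys) = sorted(d_by_group.items())
    if len(xs) < 2 or len(ys) < 2:
        raise ValidationError("each group needs at least 2 patients")
    xa, ya = np.asarray(xs), np.asarray(ys)
    if np.array_equal(np.sort(xa), np.sort(ya)) or (
        np.ptp(np.concatenate([xa, ya])) == 0
    ):
        stat, p = 0.0, 1.0
    elif method == "welch":
        stat, p = sps.ttest_ind(xa, ya, equal_var=False)
    elif method == "ranksum":
        stat, p = sps.mannwhitneyu(xa, ya, alternative="two-sided")
    else:
        raise ValidationError(f"unknown method {method!r}")
    return FieldEffectResult(
        grouping=grouping,
        group_means={ga: float(xa.mean()), gb: float(ya.mean())},
        group_sizes={ga: len(xs), gb: len(ys)},
        statistic=float(stat),
        p_value=float(p),
        method=method,
    )
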