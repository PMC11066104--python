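"""Progression targets, relevance-map compression, and the model-comparison suite.

Targets: for subject p at visit t and horizon γ (years), z=1 when t+γ reaches
the first dementia visit, z=0 when t+γ is still within the last known
non-dementia visit, NA in the uncertain gap.  Maps are compressed by PCA into
component vectors.  Three nested-cross-validated l1-penalized logistic models
of increasing richness (covariates only / + classifier prediction /
+ component vector) are compared fold-wise with a one-sided signed-rank test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import balanced_accuracy_score, roc_auc_score

from .phantoms import trajectory_labels

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# targets


def exclude_ambiguous(visits: pd.DataFrame) -> pd.DataFrame:
    """Drop subjects whose diagnostic trajectory is outside the clean grammars."""
    traj = trajectory_labels(visits)
    keep = traj[traj != "ambiguous"].index
    return visits[visits["subject_id"].isin(keep)].copy()


def build_targets(visits: pd.DataFrame, horizons=(1, 2, 3, 4, 5)) -> pd.DataFrame:
    """One row per (subject, visit, horizon) with z ∈ {1.0, 0.0, NaN}.

    Assumes ambiguous-trajectory subjects were already excluded
    (:func:`exclude_ambiguous`).  t_neg is the last non-dementia visit, t_pos
    the first dementia visit (if any); a subject without a dementia visit can
    never be positive.
    """
    rows = []
    v = visits.sort_values("visit_date")
    for sid, grp in v.groupby("subject_id"):
        days = grp["visit_date"].to_numpy(dtype=float)
        diags = grp["diagnosis"].to_numpy()
        dem = days[diags == "DEM"]
        t_pos = float(dem.min()) if dem.size else np.inf
        nondem = days[diags != "DEM"]
        t_neg = float(nondem.max()) if nondem.size else -np.inf
        for t in days:
            for gamma in horizons:
                reach = t + gamma * DAYS_PER_YEAR
                if reach >= t_pos:
                    z = 1.0
                elif reach <= t_neg:
                    z = 0.0
                else:
                    z = np.nan
                rows.append({"subject_id": sid, "t": float(t),
                             "horizon": int(gamma), "z": z})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# map compression


@dataclass
class MapPCA:
    pca: PCA
    components: np.ndarray  # (n_maps, k) loadings
    shape: tuple

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_

    def transform(self, maps) -> np.ndarray:
        x = _stack_maps(maps, self.shape)
        return self.pca.transform(x)

    def reconstruct(self, loadings) -> np.ndarray:
        flat = self.pca.inverse_transform(np.atleast_2d(loadings))
        return flat.reshape((-1,) + self.shape)


def _as_array(m) -> np.ndarray:
    data = m.data if hasattr(m, "meta") and hasattr(m, "data") else m
    return np.asarray(data, dtype=float)


def _stack_maps(maps, shape=None) -> np.ndarray:
    arrs = [_as_array(m) for m in maps]
    if shape is not None:
        for a in arrs:
            if a.shape != shape:
                raise ValueError("map grid mismatch")
    return np.stack([a.ravel() for a in arrs])


def fit_map_pca(maps, k: int = 64, seed: int = 0) -> MapPCA:
    """PCA basis over (pre-smoothed) maps; k capped at the data rank."""
    x = _stack_maps(maps)
    max_rank = min(len(x) - 1, x.shape[1])
    if k > max_rank:
        raise ValueError(f"k={k} exceeds max rank {max_rank} for {len(x)} maps")
    pca = PCA(n_components=k, svd_solver="full", random_state=seed)
    comps = pca.fit_transform(x)
    return MapPCA(pca=pca, components=comps, shape=_as_array(maps[0]).shape)


# ---------------------------------------------------------------------------
# folds


def stratified_subject_folds(subjects: pd.DataFrame, k: int = 5,
                             seed: int = 0) -> dict[str, int]:
    """Subject-disjoint folds stratified on (z, sex, 10-year age bin).

    ``subjects`` has one row per subject with columns subject_id, z, sex, age.
    Tiny strata degrade gracefully: members are dealt round-robin across folds.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    df = subjects.copy()
    df["age_bin"] = (df["age"] // 10).astype(int)
    assign: dict[str, int] = {}
    offset = 0
    for _, grp in df.groupby(["z", "sex", "age_bin"], sort=True, dropna=False):
        ids = grp["subject_id"].tolist()
        rng.shuffle(ids)
        for j, sid in enumerate(ids):
            assign[sid] = (j + offset) % k
        offset += len(ids)
    return assign


# ---------------------------------------------------------------------------
# model suite


MODEL_NAMES = ("M_base", "M_pred", "M_comp")


def _design(df: pd.DataFrame, which: str, comp_cols) -> np.ndarray:
    sex = (df["sex"] == "F").astype(float).to_numpy()
    age = df["age"].to_numpy(dtype=float)
    cols = [age, sex, age * sex]
    if which in ("M_pred", "M_comp"):
        yhat = df["yhat"].to_numpy(dtype=float)
        cols += [yhat, age * yhat]
    if which == "M_comp":
        cols += [df[c].to_numpy(dtype=float) for c in comp_cols]
    return np.column_stack(cols)


def _metrics(y_true, y_prob) -> dict:
    y_true = np.asarray(y_true)
    y_pred = (np.asarray(y_prob) > 0.5).astype(int)
    out = {}
    if len(np.unique(y_true)) < 2:
        return {m: np.nan for m in ("auc", "balanced_accuracy", "ppv",
                                    "sensitivity", "specificity")}
    out["auc"] = roc_auc_score(y_true, y_prob)
    out["balanced_accuracy"] = balanced_accuracy_score(y_true, y_pred)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    out["ppv"] = tp / (tp + fp) if tp + fp else np.nan
    out["sensitivity"] = tp / (tp + fn) if tp + fn else np.nan
    out["specificity"] = tn / (tn + fp) if tn + fp else np.nan
    return out


@dataclass
class SuiteResult:
    metrics: pd.DataFrame      # horizon, model, fold, auc, ...
    comparisons: pd.DataFrame  # horizon, comparison, p_value (one-sided)
    fold_assignments: dict     # horizon -> {subject_id: fold}
    test_rows: pd.DataFrame    # horizon, model, fold, subject_id, t, z, prob


def run_model_suite(
    targets: pd.DataFrame,
    features: pd.DataFrame,
    horizons=(1, 2, 3, 4, 5),
    n_folds: int = 5,
    inner_folds: int = 3,
    seed: int = 0,
    Cs: int = 8,
) -> SuiteResult:
    """Nested-CV comparison of M_base / M_pred / M_comp per horizon.

    ``targets`` comes from :func:`build_targets`; ``features`` has one row per
    (subject_id, t) with columns age, sex, yhat and component columns ``c0..``.
    All timepoints of the training subjects are used for fitting; at test time
    one random timepoint per subject is drawn (one seeded draw shared by all
    three models per horizon, so comparisons are paired).  Regularization is
    tuned on inner subject-grouped folds only.
    """
    comp_cols = sorted(c for c in features.columns if c.startswith("c")
                       and c[1:].isdigit())
    met_rows, test_rows = [], []
    fold_assignments = {}
    for gamma in horizons:
        sub = targets[(targets["horizon"] == gamma) & targets["z"].notna()]
        data = sub.merge(features, on=["subject_id", "t"], how="inner")
        if data.empty:
            continue
        subj = (data.groupby("subject_id")
                .agg(z=("z", "max"), sex=("sex", "first"), age=("age", "first"))
                .reset_index())
        folds = stratified_subject_folds(subj, k=n_folds, seed=seed + gamma)
        fold_assignments[gamma] = folds
        data = data.assign(fold=data["subject_id"].map(folds))
        rng = np.random.default_rng(seed + 100 * gamma)
        for f in range(n_folds):
            train = data[data["fold"] != f]
            test_all = data[data["fold"] == f]
            if train.empty or test_all.empty:
                continue
            # one random timepoint per test subject, shared across models
            test = (test_all.sample(frac=1.0, random_state=rng.integers(2**31))
                    .groupby("subject_id").head(1))
            if train["z"].nunique() < 2 or test["z"].nunique() < 2:
                for name in MODEL_NAMES:
                    met_rows.append({"horizon": gamma, "model": name, "fold": f,
                                     **{m: np.nan for m in ("auc", "balanced_accuracy",
                                                            "ppv", "sensitivity",
                                                            "specificity")}})
                continue
            inner = _grouped_inner_splits(train["subject_id"].to_numpy(),
                                          inner_folds, rng)
            for name in MODEL_NAMES:
                xtr = _design(train, name, comp_cols)
                xte = _design(test, name, comp_cols)
                mu, sd = xtr.mean(axis=0), xtr.std(axis=0)
                sd[sd == 0] = 1.0
                clf = LogisticRegressionCV(
                    Cs=Cs, cv=inner, l1_ratios=(1.0,), solver="liblinear",
                    scoring="roc_auc", max_iter=2000,
                    use_legacy_attributes=False,
                    random_state=int(rng.integers(2**31)),
                )
                clf.fit((xtr - mu) / sd, train["z"].to_numpy(dtype=int))
                prob = clf.predict_proba((xte - mu) / sd)[:, 1]
                met_rows.append({"horizon": gamma, "model": name, "fold": f,
                                 **_metrics(test["z"], prob)})
                for sid, t, z, p in zip(test["subject_id"], test["t"],
                                        test["z"], prob):
                    test_rows.append({"horizon": gamma, "model": name, "fold": f,
                                      "subject_id": sid, "t": t, "z": z,
                                      "prob": float(p)})
    metrics = pd.DataFrame(met_rows)
    comparisons = _compare_models(metrics)
    return SuiteResult(metrics=metrics, comparisons=comparisons,
                       fold_assignments=fold_assignments,
                       test_rows=pd.DataFrame(test_rows))


def _grouped_inner_splits(subject_ids: np.ndarray, k: int, rng) -> list:
    """Subject-grouped inner-CV splits as (train_idx, test_idx) pairs."""
    uniq = np.array(sorted(set(subject_ids)))
    perm = rng.permutation(len(uniq))
    fold_of = {sid: perm[i] % k for i, sid in enumerate(uniq)}
    row_fold = np.array([fold_of[s] for s in subject_ids])
    splits = []
    for f in range(k):
        te = np.flatnonzero(row_fold == f)
        tr = np.flatnonzero(row_fold != f)
        if len(te) and len(tr):
            splits.append((tr, te))
    return splits


def _compare_models(metrics: pd.DataFrame) -> pd.DataFrame:
    """One-sided Wilcoxon signed-rank across folds: richer model > simpler."""
    rows = []
    if metrics.empty:
        return pd.DataFrame(rows, columns=["horizon", "comparison", "p_value"])
    for gamma, grp in metrics.groupby("horizon"):
        by = {name: grp[grp["model"] == name].sort_values("fold")["auc"].to_numpy()
              for name in MODEL_NAMES}
        for a, b in (("M_pred", "M_base"), ("M_comp", "M_pred")):
            x, y = by[a], by[b]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 2 and np.any(x[ok] != y[ok]):
                p = float(wilcoxon(x[ok], y[ok], alternative="greater").pvalue)
            else:
                p = np.nan
            rows.append({"horizon": gamma, "comparison": f"{a}>{b}", "p_value": p})
    return pd.DataFrame(rows)


def audit_no_leakage(fold_assignments: dict, test_rows: pd.DataFrame) -> bool:
    """Every test prediction's subject must sit in exactly its own test fold."""
    for gamma, folds in fold_assignments.items():
        sub = test_rows[test_rows["horizon"] == gamma]
        for _, row in sub.iterrows():
            if folds[row["subject_id"]] != row["fold"]:
                return False
    return True


# ---------------------------------------------------------------------------
# morphological record


def export_morphological_record(
    subject_id: str,
    visits,  # iterable of dicts: {date, yhat, map_ref}
    progression_probs: dict | None = None,
) -> dict:
    """Per-subject longitudinal bundle: ŷ series, map references, two-visit
    annual slope, and per-horizon progression probabilities."""
    vs = sorted(visits, key=lambda v: v["date"])
    if len(vs) == 0:
        raise ValueError("need at least one visit with a prediction")
    record = {
        "subject_id": subject_id,
        "visits": [
            {"date": float(v["date"]), "yhat": float(v["yhat"]),
             "map_ref": v.get("map_ref")}
            for v in vs
        ],
        "progression_probs": {str(k): float(v)
                              for k, v in (progression_probs or {}).items()},
    }
    if len(vs) >= 2:
        dy = vs[1]["yhat"] - vs[0]["yhat"]
        dt_years = (vs[1]["date"] - vs[0]["date"]) / DAYS_PER_YEAR
        record["slope_per_year"] = float(dy / dt_years) if dt_years else None
    else:
        record["slope_per_year"] = None
    return record


def record_roundtrip(record: dict) -> dict:
    """Serialize and reload a record (lossless by construction)."""
    return json.loads(json.dumps(record))
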