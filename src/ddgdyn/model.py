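"""Feature assembly and ensemble-tree regression of stability changes.

A mutation is represented by one fixed-order feature vector:

* signature block — flattened cumulative pharmacophore-pair counts of the
  wild-type residue environment (36 pairs x 6 thresholds = 216 under
  defaults);
* dynamics block — 4 per-site elastic-network features (fluctuation,
  fluctuation percentile, mean |cross-correlation|, first-mode displacement
  norm);
* interaction block — hydrophobic contact count and contact-potential score;
* substitution block — BLOSUM62 propensity, volume change, hydrophobicity
  change (antisymmetric under wt/mut swap);
* relative solvent accessibility of the site.

Multiple (2-3 site) mutations aggregate per-site vectors: count-type blocks
(signature, hydrophobic contacts) are summed, intensity-type ones (dynamics,
contact potential, RSA) averaged, the substitution block summed, plus an
explicit site-count feature.

The regressor is a random forest (scikit-learn); features are chosen by
incremental forward greedy selection maximizing mean cross-validated
Pearson r. Singles and multiples are intended to be trained as two separate
models.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold

from . import nma
from .dataset import StabilityRecord, classify_sign
from .evaluation import Metrics, score
from .interactions import (INTERACTION_FEATURE_NAMES,
                           SUBSTITUTION_FEATURE_NAMES, contact_potential_score,
                           hydrophobic_contacts, substitution_features)
from .pharmaco_signatures import (DEFAULT_RADIUS, DEFAULT_THRESHOLDS,
                                  build_environment, compute_signature, flatten,
                                  signature_feature_names)
from .structure_io import (MultiMutation, MutationSpec, Structure,
                           locate_site, relative_solvent_accessibility)

__all__ = ["FeatureConfig", "Featurizer", "TrainedModel", "feature_names",
           "featurize_single", "featurize_multi", "train", "greedy_select",
           "predict", "cross_validate", "save_model", "load_model"]


@dataclass(frozen=True)
class FeatureConfig:
    radius: float = DEFAULT_RADIUS
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    contact_threshold: float = 4.5
    cb_cutoff: float = 8.0
    force_field: str = "anm"
    nma_cutoff: float = 15.0

    def hash(self, multi: bool = False) -> str:
        payload = json.dumps({"config": asdict(self), "multi": multi,
                              "features": feature_names(self, multi=multi)},
                             sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


def feature_names(config: FeatureConfig = FeatureConfig(),
                  multi: bool = False) -> list[str]:
    names = (signature_feature_names(config.thresholds)
             + list(nma.DYNAMICS_FEATURE_NAMES)
             + list(INTERACTION_FEATURE_NAMES)
             + list(SUBSTITUTION_FEATURE_NAMES)
             + ["rsa"])
    if multi:
        names.append("n_sites")
    return names


# count-type features are summed over sites in multi-mutations, the rest
# averaged; the substitution block is summed (additive direction effects).
def _is_summed(name: str) -> bool:
    return (name.startswith("sig_") or name == "int_hydrophobic_contacts"
            or name.startswith("sub_"))


class Featurizer:
    """Feature pipeline with per-structure caching of the NMA profile."""

    def __init__(self, config: FeatureConfig = FeatureConfig()):
        self.config = config
        self._profiles: dict[int, nma.DynamicsProfile] = {}

    def _profile(self, structure: Structure) -> nma.DynamicsProfile:
        key = id(structure)
        if key not in self._profiles:
            net = nma.build_network(structure, force_field=self.config.force_field,
                                    cutoff=self.config.nma_cutoff)
            self._profiles[key] = nma.dynamics_profile(nma.compute_modes(net))
        return self._profiles[key]

    def featurize_single(self, structure: Structure, spec: MutationSpec,
                         reverse: bool = False) -> pd.Series:
        """Feature vector for one point mutation.

        For hypothetical reverse records (``reverse=True``) the structure
        holds the forward wild type (= ``spec.mut``); the environment,
        dynamics and RSA blocks are those of the same site, while the
        substitution block uses the record's own (wt, mut) direction.
        """
        site = locate_site(structure, spec, match_mut=reverse)
        cfg = self.config
        env = build_environment(structure, site, radius=cfg.radius)
        sig = flatten(compute_signature(env, thresholds=cfg.thresholds))

        profile = self._profile(structure)
        ca_order = structure.ca_indices()
        site_ca = site.atom_index(structure, "CA")
        site_idx = ca_order.index(site_ca)
        dyn = nma.site_dynamics_features(profile, site_idx)

        inter = np.array([
            float(hydrophobic_contacts(structure, site,
                                       threshold=cfg.contact_threshold)),
            contact_potential_score(structure, site, cb_cutoff=cfg.cb_cutoff),
        ])
        sub = substitution_features(spec.wt, spec.mut)
        rsa = relative_solvent_accessibility(structure, site)
        values = np.concatenate([sig, dyn, inter, sub, [rsa]])
        fv = pd.Series(values, index=feature_names(cfg))
        if not np.all(np.isfinite(fv.to_numpy())):
            bad = fv.index[~np.isfinite(fv.to_numpy())].tolist()
            raise ValueError(f"non-finite features: {bad}")
        return fv

    def featurize_multi(self, structure: Structure, multi: MultiMutation,
                        reverse: bool = False) -> pd.Series:
        """Aggregated feature vector for a 1-3 site mutation group.

        Sites are processed in a canonical order so the result is exactly
        invariant to the order the mutations were written in.
        """
        ordered = sorted(multi, key=lambda s: s.site_key)
        singles = [self.featurize_single(structure, s, reverse=reverse)
                   for s in ordered]
        stacked = pd.concat(singles, axis=1)
        summed = stacked.sum(axis=1)
        meaned = stacked.mean(axis=1)
        agg = pd.Series({name: (summed[name] if _is_summed(name)
                                else meaned[name])
                         for name in stacked.index})
        agg["n_sites"] = float(len(multi))
        return agg.reindex(feature_names(self.config, multi=True))

    def featurize_record(self, structure: Structure,
                         record: StabilityRecord) -> pd.Series:
        if record.is_single:
            return self.featurize_single(structure, record.mutation.specs[0],
                                         reverse=record.is_reverse)
        return self.featurize_multi(structure, record.mutation,
                                    reverse=record.is_reverse)


def featurize_single(structure: Structure, spec: MutationSpec,
                     config: FeatureConfig = FeatureConfig(),
                     reverse: bool = False) -> pd.Series:
    return Featurizer(config).featurize_single(structure, spec, reverse=reverse)


def featurize_multi(structure: Structure, multi: MultiMutation,
                    config: FeatureConfig = FeatureConfig()) -> pd.Series:
    return Featurizer(config).featurize_multi(structure, multi)


# ---------------------------------------------------------------------------
# learning

@dataclass
class TrainedModel:
    learner: RandomForestRegressor
    selected_features: list[str]
    config_hash: str
    training_meta: dict = field(default_factory=dict)

    def predict_frame(self, X: pd.DataFrame) -> np.ndarray:
        return self.learner.predict(X[self.selected_features].to_numpy())


def _check_features(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    if not np.all(np.isfinite(arr)):
        bad = X.columns[~np.isfinite(arr).all(axis=0)].tolist()
        raise ValueError(f"non-finite feature columns: {bad}")


def train(X: pd.DataFrame, y: Sequence[float],
          selected: Optional[Sequence[str]] = None,
          n_trees: int = 500, min_leaf: int = 3, seed: int = 42,
          config_hash: str = "", cv_summary: Optional[dict] = None
          ) -> TrainedModel:
    """Fit a bagged regression-tree ensemble to (features -> ddG)."""
    if len(X) < 20:
        raise ValueError("need at least 20 training records")
    _check_features(X)
    cols = list(selected) if selected is not None else list(X.columns)
    rf = RandomForestRegressor(n_estimators=n_trees, min_samples_leaf=min_leaf,
                               random_state=seed, n_jobs=1)
    y = np.asarray(y, float)
    rf.fit(X[cols].to_numpy(), y)
    meta = {"n_records": len(X), "seed": seed,
            "hyperparams": {"n_trees": n_trees, "min_leaf": min_leaf},
            "cv_summary": cv_summary or {}}
    return TrainedModel(learner=rf, selected_features=cols,
                        config_hash=config_hash, training_meta=meta)


def _cv_pearson(X: np.ndarray, y: np.ndarray, k_folds: int, seed: int,
                n_trees: int, min_leaf: int) -> float:
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    rs = []
    for tr, te in kf.split(X):
        rf = RandomForestRegressor(n_estimators=n_trees,
                                   min_samples_leaf=min_leaf,
                                   random_state=seed, n_jobs=1)
        rf.fit(X[tr], y[tr])
        p = rf.predict(X[te])
        if np.std(p) == 0.0 or np.std(y[te]) == 0.0:
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(p, y[te])[0, 1]))
    return float(np.mean(rs))


def greedy_select(X: pd.DataFrame, y: Sequence[float], k_folds: int = 5,
                  max_features: int = 30, seed: int = 42, n_trees: int = 30,
                  min_leaf: int = 3, tol: float = 1e-3, patience: int = 3
                  ) -> tuple[list[str], list[float]]:
    """Incremental stepwise forward selection.

    Starting from the empty set, each step adds the feature whose inclusion
    maximizes the mean k-fold CV Pearson r of a (lighter) forest; selection
    stops when the improvement stays below ``tol`` for ``patience``
    consecutive steps, or at ``max_features``. Returns the selection order
    and the per-step best scores.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    _check_features(X)
    y = np.asarray(y, float)
    candidates = [c for c in X.columns if X[c].nunique() > 1]
    arr = {c: X[c].to_numpy(float) for c in candidates}
    selected: list[str] = []
    scores: list[float] = []
    best_so_far = -np.inf
    stall = 0
    while candidates and len(selected) < max_features:
        step_best, step_feat = -np.inf, None
        base = [arr[c] for c in selected]
        for c in candidates:
            Xc = np.column_stack(base + [arr[c]])
            r = _cv_pearson(Xc, y, k_folds, seed, n_trees, min_leaf)
            if r > step_best:
                step_best, step_feat = r, c
        selected.append(step_feat)
        scores.append(step_best)
        candidates.remove(step_feat)
        if step_best - best_so_far < tol:
            stall += 1
            if stall >= patience:
                break
        else:
            stall = 0
        best_so_far = max(best_so_far, step_best)
    return selected, scores


def predict(model: TrainedModel, fv: pd.Series,
            config_hash: str = "") -> tuple[float, str]:
    """Predicted ddG (kcal/mol) and sign label for one feature vector."""
    if config_hash and model.config_hash and config_hash != model.config_hash:
        raise ValueError(
            "feature configuration mismatch: vector computed under "
            f"{config_hash}, model trained under {model.config_hash}")
    missing = [f for f in model.selected_features if f not in fv.index]
    if missing:
        raise ValueError(f"feature vector missing: {missing}")
    x = fv[model.selected_features].to_numpy(float).reshape(1, -1)
    ddg = float(model.learner.predict(x)[0])
    return ddg, classify_sign(ddg)


def cross_validate(X: pd.DataFrame, y: Sequence[float], k: int = 10,
                   seed: int = 42, n_trees: int = 500, min_leaf: int = 3,
                   selected: Optional[Sequence[str]] = None) -> dict:
    """k-fold CV stratified by sign class; per-fold and pooled metrics.

    Returns {"per_fold": [Metrics...], "pooled": Metrics,
    "mean_over_folds": {...}, "predictions": array aligned with input}.
    """
    y = np.asarray(y, float)
    if k > len(y):
        raise ValueError("k exceeds number of records")
    cols = list(selected) if selected is not None else list(X.columns)
    labels = np.array([classify_sign(v) for v in y])
    arr = X[cols].to_numpy(float)
    if len(set(labels)) > 1 and min(np.bincount(
            (labels == "stabilizing").astype(int))) >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(arr, labels)
    else:  # fall back when a class is too small to stratify
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(arr)
    pred = np.empty_like(y)
    per_fold = []
    for tr, te in folds:
        rf = RandomForestRegressor(n_estimators=n_trees,
                                   min_samples_leaf=min_leaf,
                                   random_state=seed, n_jobs=1)
        rf.fit(arr[tr], y[tr])
        pred[te] = rf.predict(arr[te])
        if len(te) >= 2 and np.std(pred[te]) > 0 and np.std(y[te]) > 0:
            per_fold.append(score(pred[te], y[te]))
    pooled = score(pred, y)
    mean_over_folds = {
        k_: float(np.nanmean([getattr(m, k_) for m in per_fold]))
        for k_ in ("pearson_r", "rmse", "mae")} if per_fold else {}
    return {"per_fold": per_fold, "pooled": pooled,
            "mean_over_folds": mean_over_folds, "predictions": pred}


# ---------------------------------------------------------------------------
# persistence

def save_model(model: TrainedModel, path) -> None:
    joblib.dump({"learner": model.learner,
                 "selected_features": model.selected_features,
                 "config_hash": model.config_hash,
                 "training_meta": model.training_meta}, path)


def load_model(path) -> TrainedModel:
    blob = joblib.load(path)
    return TrainedModel(learner=blob["learner"],
                        selected_features=blob["selected_features"],
                        config_hash=blob["config_hash"],
                        training_meta=blob["training_meta"])
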