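"""Replicated k-fold cross-validation of genomic prediction models.

Each replication splits the genotypes into ``n_folds`` disjoint,
near-equal subsets (optionally stratified by half-sib family); each
fold in turn is predicted from a model trained on the remaining folds.
Out-of-fold predictions are pooled within a replication and correlated
with the observed adjusted entry means; predictive ability is the mean
of these per-replication Pearson correlations, and PRESS the pooled
squared prediction error.  ``compare_td_dd`` runs every model twice on
the same marker panel and fold assignments — once on tetraploid dosage
codes (0..4) and once on diploidized codes (0..2) — and reports the
percent superiority of the tetraploid coding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from polygs.dosage import DosageMatrix, diploidize, filter_dd_informative
from polygs.kinship import RelationshipMatrix, blend, build_k
from polygs.wgr import GblupFit, WgrSpec, fit_bayesian, fit_gblup, predict_gebv

logger = logging.getLogger(__name__)

__all__ = [
    "CvPlan",
    "CvResult",
    "make_folds",
    "run_cv",
    "press",
    "compare_td_dd",
    "model_average",
    "percent_superiority",
]


@dataclass
class CvPlan:
    """Fold layout and replication protocol.

    Replication defaults follow common practice for this analysis:
    Bayesian samplers are costly, so fewer replications than for the
    closed-form frequentist model.
    """

    n_folds: int = 5
    n_replications: int = 100
    sampling: str = "random"  # random | stratified
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.sampling not in ("random", "stratified"):
            raise ValueError("sampling must be 'random' or 'stratified'")


@dataclass
class CvResult:
    """Per-replication correlations and PRESS with pooled summaries."""

    replications: pd.DataFrame  # replication, correlation, press, press_std
    predictive_ability: float
    press_mean: float
    press_std_mean: float
    n_excluded: int
    folds: list = field(repr=False, default_factory=list)


def make_folds(
    ids: Sequence,
    plan: CvPlan,
    families: Mapping | None = None,
) -> list[np.ndarray]:
    """Fold labels (0..n_folds-1) per genotype, one array per replication.

    Random mode permutes genotypes and deals them into folds of sizes
    differing by at most one.  Stratified mode deals within each family
    so every family is spread across folds.
    """
    ids = list(ids)
    n = len(ids)
    if n < plan.n_folds:
        raise ValueError("fewer genotypes than folds")
    if plan.sampling == "stratified" and families is None:
        raise ValueError("stratified sampling needs a genotype -> family mapping")
    rng = np.random.default_rng(plan.seed)
    assignments = []
    for _ in range(plan.n_replications):
        labels = np.empty(n, dtype=np.int64)
        if plan.sampling == "random":
            perm = rng.permutation(n)
            labels[perm] = np.arange(n) % plan.n_folds
        else:
            fam = pd.Series([families[i] for i in ids])
            offset = rng.integers(plan.n_folds)
            # rotate the dealing start so small families still rotate folds
            for _, members in fam.groupby(fam, sort=False):
                order = rng.permutation(members.index.to_numpy())
                labels[order] = (np.arange(len(order)) + offset) % plan.n_folds
        assignments.append(labels)
    return assignments


def press(observed, predicted, standardize: bool = False) -> float:
    """Predicted residual error sum of squares, Σ(ŷ - y)².

    The standardized variant divides by the total sum of squares of the
    observed values, so a mean-only predictor scores 1.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted lengths differ")
    value = float(np.sum((predicted - observed) ** 2))
    if standardize:
        tss = float(np.sum((observed - observed.mean()) ** 2))
        if tss <= 0:
            raise ValueError("cannot standardize PRESS: observed values are constant")
        value /= tss
    return value


def _fit_predict(
    spec: WgrSpec,
    X: np.ndarray | None,
    K: RelationshipMatrix | None,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    seed: int,
) -> np.ndarray:
    if spec.model == "GBLUP":
        K_train = RelationshipMatrix(
            K.values[np.ix_(train, train)], K.ids[train], K.provenance, K.ploidy
        )
        fit = fit_gblup(K_train, y[train])
        K_cross = K.values[np.ix_(test, train)]
        return fit.mu + predict_gebv(fit, K_cross=K_cross)
    fit = fit_bayesian(replace(spec, seed=seed), X[train], y[train])
    return fit.mu + np.asarray(predict_gebv(fit, X[test]))


def run_cv(
    spec: WgrSpec,
    y: pd.Series | np.ndarray,
    X: DosageMatrix | np.ndarray | None = None,
    K: RelationshipMatrix | None = None,
    plan: CvPlan | None = None,
    families: Mapping | None = None,
    folds: list[np.ndarray] | None = None,
) -> CvResult:
    """Replicated k-fold cross-validation of one prediction model.

    Supply ``X`` (dosages) for the Bayesian marker models or ``K`` (a
    positive-definite relationship matrix) for GBLUP.  Precomputed
    ``folds`` override the plan's own assignment — used to share folds
    across models and codings.
    """
    plan = plan or CvPlan()
    if spec.model == "GBLUP":
        if K is None:
            raise ValueError("GBLUP cross-validation needs K")
        ids = list(K.ids)
    else:
        if X is None:
            raise ValueError("marker-model cross-validation needs X")
        ids = (
            list(X.individuals)
            if isinstance(X, DosageMatrix)
            else list(range(np.asarray(X).shape[0]))
        )
    if isinstance(y, pd.Series):
        ya = y.reindex(pd.Index(ids)).to_numpy(dtype=float)
        if np.isnan(ya).any():
            raise ValueError("y missing for some genotypes")
    else:
        ya = np.asarray(y, dtype=float)
    Xa = X.complete_array() if isinstance(X, DosageMatrix) else (
        np.asarray(X, dtype=float) if X is not None else None
    )
    if folds is None:
        folds = make_folds(ids, plan, families)

    rows = []
    n_excluded = 0
    for rep, labels in enumerate(folds):
        pred = np.full(len(ids), np.nan)
        failed = False
        for f in range(plan.n_folds):
            test = np.flatnonzero(labels == f)
            train = np.flatnonzero(labels != f)
            try:
                pred[test] = _fit_predict(
                    spec, Xa, K, ya, train, test, seed=plan.seed + 7919 * rep + f
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("replication %d fold %d failed: %s", rep, f, exc)
                failed = True
                break
        if failed or np.isnan(pred).any():
            n_excluded += 1
            continue
        if np.std(pred) == 0 or np.std(ya) == 0:
            logger.warning("replication %d: constant predictions, excluded", rep)
            n_excluded += 1
            continue
        corr = float(np.corrcoef(ya, pred)[0, 1])
        rows.append(
            {
                "replication": rep,
                "correlation": corr,
                "press": press(ya, pred),
                "press_std": press(ya, pred, standardize=True),
            }
        )
    if not rows:
        raise RuntimeError("all cross-validation replications failed")
    table = pd.DataFrame(rows)
    return CvResult(
        replications=table,
        predictive_ability=float(table["correlation"].mean()),
        press_mean=float(table["press"].mean()),
        press_std_mean=float(table["press_std"].mean()),
        n_excluded=n_excluded,
        folds=folds,
    )


def model_average(per_model_abilities: Mapping[str, float]) -> float:
    """Arithmetic mean predictive ability over models for one coding."""
    if not per_model_abilities:
        raise ValueError("no abilities to average")
    return float(np.mean(list(per_model_abilities.values())))


def percent_superiority(mean_td: float, mean_dd: float) -> float:
    """Percent superiority of the tetraploid coding, 100 (TD/DD - 1)."""
    return 100.0 * (mean_td / mean_dd - 1.0)


def _gblup_matrix(
    dosages: DosageMatrix, A: RelationshipMatrix | None, w: float
) -> RelationshipMatrix:
    K = build_k(dosages)
    if A is not None:
        return blend(K, A.subset(dosages.individuals), w)
    # identity fallback keeps K invertible when no pedigree is supplied
    eye = RelationshipMatrix(
        np.eye(dosages.n_individuals), dosages.individuals, "pedigree", dosages.ploidy
    )
    return blend(K, eye, w)


def compare_td_dd(
    dosages: DosageMatrix,
    y: pd.Series,
    models: Sequence[WgrSpec],
    plan: CvPlan | None = None,
    A: RelationshipMatrix | None = None,
    blend_weight: float = 0.99,
    families: Mapping | None = None,
) -> dict:
    """Tetraploid- versus diploid-coding comparison on a common panel.

    Markers carrying only doses {0, 1} are removed first (they collapse
    to monomorphic after diploidization); every model then runs with
    identical fold assignments on the tetraploid codes and on the
    diploidized codes of the same panel.
    """
    if dosages.ploidy != 4:
        raise ValueError("compare_td_dd expects tetraploid input")
    plan = plan or CvPlan()
    panel = filter_dd_informative(dosages)
    if panel.n_markers == 0:
        raise ValueError("no markers remain after the doses-{0,1}-only filter")
    dd = diploidize(panel)
    folds = make_folds(list(panel.individuals), plan, families)

    abilities: dict[str, dict[str, float]] = {"TD": {}, "DD": {}}
    results: dict[str, dict[str, CvResult]] = {"TD": {}, "DD": {}}
    for spec in models:
        for coding, dmat in (("TD", panel), ("DD", dd)):
            if spec.model == "GBLUP":
                K = _gblup_matrix(dmat, A, blend_weight)
                res = run_cv(spec, y, K=K, plan=plan, folds=folds)
            else:
                res = run_cv(spec, y, X=dmat, plan=plan, folds=folds)
            abilities[coding][spec.model] = res.predictive_ability
            results[coding][spec.model] = res
    mean_td = model_average(abilities["TD"])
    mean_dd = model_average(abilities["DD"])
    table = pd.DataFrame(
        {
            "TD": pd.Series(abilities["TD"]),
            "DD": pd.Series(abilities["DD"]),
        }
    )
    table["superiority_pct"] = 100.0 * (table["TD"] / table["DD"] - 1.0)
    return {
        "table": table,
        "mean_td": mean_td,
        "mean_dd": mean_dd,
        "superiority_pct": percent_superiority(mean_td, mean_dd),
        "n_markers": panel.n_markers,
        "results": results,
        "folds": folds,
    }
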