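"""Phylogeny-informed random forest: model and results objects.

The procedure has three steps. (1) Features are partitioned into
phylogenetic clusters by PAM on the cophenetic distance matrix, with the
number of clusters chosen by average silhouette width. (2) Within each
cluster, permutation importance scores are computed from small forests
(averaged over three mtry candidates), negative scores are clipped to zero,
the clipped scores are normalized into cluster-specific probabilities v,
and each v is scaled by its cluster's size share q_k/p, yielding
community-level selection probabilities w that sum to one. (3) A final
forest is trained whose per-node split candidates are drawn with
probability proportional to w, with its mtry tuned by OOB error over three
candidates derived from p' (the number of non-zero probabilities).

Two boundary clusterings bracket the method: fully disjoint clusters
(k = p) reduce w to the exactly uniform standard random forest, and a
single cluster (k = 1) reduces w to clipped-normalized global importance.

``PIRF`` holds the data (statsmodels-style); ``fit`` runs the pipeline and
returns a ``PIRFResults`` carrying the cluster assignment, probabilities,
tuned mtry, forest, OOB error, and prediction/serialization methods.
"""

from __future__ import annotations

import contextlib
import json
import math
import warnings
from dataclasses import dataclass, field, replace, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .clustering import ClusterAssignment, select_k_phylo
from .errors import DataError, PIRFError, ValidationError
from .forest import (ForestModel, ImportanceVector, default_min_node_size,
                     grow_forest, oob_error, permutation_importance)
from .phylo import PhyloTree, align_to_table, cophenetic_matrix, read_newick

__all__ = ["PIRF", "PIRFResults", "PIRFConfig", "SelectionProbabilities",
           "preprocess", "mtry_candidates", "cluster_importance_scores",
           "compute_probabilities", "tune_global_mtry"]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PIRFConfig:
    """All tunable knobs with the method's stated defaults."""

    cluster_mode: str = "phylo"       # "phylo" | "single" | "disjoint"
    k_min: int = 2
    k_max: int = 10
    n_trees: int = 10000              # tuning + final forest
    n_trees_cluster: int = 1000       # per-cluster importance forests
    n_permutations: int = 1
    min_node_size: Optional[int] = None   # None -> 1 (clf) / 5 (reg)
    mtry_grid: str = "sqrt"           # "sqrt" | "literal" second candidate
    preprocess: bool = True           # applied only to count input
    min_reads: float = 2000.0
    min_mean_abundance: float = 1e-5
    missing_features: str = "error"   # tree-alignment policy: error | warn

    def __post_init__(self):
        if self.cluster_mode not in ("phylo", "single", "disjoint"):
            raise ValidationError(f"unknown cluster_mode {self.cluster_mode!r}")
        if self.mtry_grid not in ("sqrt", "literal"):
            raise ValidationError(f"unknown mtry_grid {self.mtry_grid!r}")


def _subseed(ss: np.random.SeedSequence) -> int:
    """A reproducible 31-bit integer seed derived from a SeedSequence."""
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _stage_seeds(seed: Optional[int]) -> dict:
    """Expand one global seed into independent per-stage seed sequences."""
    root = np.random.SeedSequence(seed)
    names = ("importance", "tuning", "final")
    return dict(zip(names, root.spawn(len(names))))


@contextlib.contextmanager
def _stage(name: str):
    """Re-raise stage errors with the stage named, preserving the type."""
    try:
        yield
    except PIRFError as exc:
        exc.args = (f"[stage: {name}] {exc.args[0] if exc.args else ''}",) \
            + exc.args[1:]
        raise


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(table: pd.DataFrame, min_reads: float = 2000.0,
               min_mean_abundance: float = 1e-5):
    """Quality filters and relative-abundance normalization for raw counts.

    Samples with total reads <= ``min_reads`` are removed, counts are
    converted to relative abundances (row sums 1), and features whose mean
    relative abundance is <= ``min_mean_abundance`` are removed (strictly
    greater retention on both filters). After feature removal rows are
    renormalized over the retained features, which is what prediction on a
    new table replicates. Returns ``(relative_table, record)``.
    """
    counts = table.astype(float)
    if (counts.values < 0).any():
        raise ValidationError("counts must be non-negative")
    totals = counts.sum(axis=1)
    keep_samples = totals > min_reads
    if not keep_samples.any():
        raise DataError(f"all samples have <= {min_reads} total reads")
    dropped_samples = list(counts.index[~keep_samples])
    counts = counts.loc[keep_samples]
    rel = counts.div(counts.sum(axis=1), axis=0)
    keep_features = rel.mean(axis=0) > min_mean_abundance
    if not keep_features.any():
        raise DataError("all features fall below the mean-abundance filter")
    dropped_features = list(rel.columns[~keep_features])
    rel = rel.loc[:, keep_features]
    rel = rel.div(rel.sum(axis=1), axis=0)
    record = {
        "normalize": True,
        "min_reads": min_reads,
        "min_mean_abundance": min_mean_abundance,
        "samples_removed": dropped_samples,
        "features_removed": dropped_features,
    }
    return rel, record


# ---------------------------------------------------------------------------
# selection probabilities (the method's core arithmetic)


@dataclass
class SelectionProbabilities:
    """Community-level selection probabilities w and their components.

    ``v`` holds the cluster-specific probabilities (unit-sum within each
    non-degenerate cluster); ``w = v * q_k / p`` renormalized to unit sum
    over all features; ``p_prime`` counts the strictly positive entries of w.
    Clusters whose clipped scores are all zero are recorded as degenerate:
    their features are eliminated (w = 0) and the remaining mass is
    renormalized, preserving relative masses among the surviving clusters.
    """

    labels: tuple
    w: np.ndarray
    v: np.ndarray
    cluster_of: np.ndarray
    cluster_sizes: np.ndarray
    degenerate_clusters: tuple = ()

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def p_prime(self) -> int:
        return int(np.count_nonzero(self.w > 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": list(self.labels),
                             "cluster": self.cluster_of + 1,
                             "v": self.v, "w": self.w})


def compute_probabilities(scores, assignment: ClusterAssignment,
                          ) -> SelectionProbabilities:
    """Convert cluster-local importance scores into selection probabilities.

    Negative scores are clipped to zero (feature elimination); within each
    cluster, v_j = s_j / sum of the cluster's clipped scores; w_j = v_j *
    q_k / p, renormalized to unit sum. If every cluster is degenerate (all
    clipped scores zero), falls back to uniform w with a warning.
    """
    s = scores.scores if isinstance(scores, ImportanceVector) \
        else np.asarray(scores, dtype=float)
    p = len(assignment.labels)
    if s.shape != (p,):
        raise ValidationError("need exactly one score per feature")
    s = np.clip(s, 0.0, None)
    sizes = assignment.cluster_sizes
    v = np.zeros(p)
    degenerate = []
    for k in range(assignment.k):
        members = assignment.members(k)
        total = s[members].sum()
        if total > 0:
            v[members] = s[members] / total
        else:
            degenerate.append(k)
    w = v * sizes[assignment.cluster_of] / p
    total = w.sum()
    if total <= 0:
        warnings.warn("all clusters degenerate (no positive importance); "
                      "falling back to uniform probabilities", stacklevel=2)
        w = np.full(p, 1.0 / p)
    else:
        w = w / total
    return SelectionProbabilities(
        labels=assignment.labels, w=w, v=v,
        cluster_of=assignment.cluster_of.copy(),
        cluster_sizes=sizes, degenerate_clusters=tuple(degenerate))


def uniform_probabilities(labels: Sequence[str]) -> SelectionProbabilities:
    """The k = p boundary: every feature its own cluster, w exactly uniform."""
    p = len(labels)
    return SelectionProbabilities(
        labels=tuple(labels), w=np.full(p, 1.0 / p), v=np.ones(p),
        cluster_of=np.arange(p), cluster_sizes=np.ones(p, dtype=int))


# ---------------------------------------------------------------------------
# mtry candidates, cluster importance, tuning


def mtry_candidates(q: int, grid: str = "sqrt") -> list:
    """The three mtry candidates {ceil(q/10), ceil(sqrt(q)), ceil(log2 q)},
    clamped to [1, q] and deduplicated (ascending). ``grid="literal"`` uses
    q itself as the second candidate instead of its square root."""
    if q < 1:
        raise ValidationError("q must be >= 1")
    second = q if grid == "literal" else math.isqrt(q - 1) + 1 if q > 1 else 1
    cands = [math.ceil(q / 10), second,
             math.ceil(math.log2(q)) if q > 1 else 1]
    return sorted({min(max(c, 1), q) for c in cands})


def cluster_importance_scores(X, y, task: str, assignment: ClusterAssignment,
                              n_trees: int = 1000, n_permutations: int = 1,
                              min_node_size: Optional[int] = None,
                              mtry_grid: str = "sqrt",
                              seed=None) -> ImportanceVector:
    """Localized permutation importance (one forest per mtry candidate per
    cluster, scores averaged across candidates).

    Returns a single vector over all features, ordered as
    ``assignment.labels``; each feature's score was computed within its own
    cluster only.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p != len(assignment.labels):
        raise ValidationError("X and assignment disagree on feature count")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    cluster_seeds = ss.spawn(assignment.k)
    scores = np.zeros(p)
    for k in range(assignment.k):
        members = assignment.members(k)
        q = members.size
        Xk = X[:, members]
        cands = mtry_candidates(q, mtry_grid)
        sub = cluster_seeds[k].spawn(2 * len(cands))
        acc = np.zeros(q)
        for i, mtry in enumerate(cands):
            forest = grow_forest(
                Xk, y, task, mtry=mtry, n_trees=n_trees,
                min_node_size=min_node_size, seed=_subseed(sub[2 * i]),
                compute_oob=False)
            imp = permutation_importance(
                forest, Xk, y, n_permutations=n_permutations,
                seed=_subseed(sub[2 * i + 1]))
            acc += imp.scores
        scores[members] = acc / len(cands)
    return ImportanceVector(labels=assignment.labels, scores=scores)


def tune_global_mtry(X, y, task: str, probs: SelectionProbabilities,
                     n_trees: int = 10000,
                     min_node_size: Optional[int] = None,
                     mtry_grid: str = "sqrt", seed=None):
    """Pick the final forest's mtry by OOB error.

    Candidates are {ceil(p'/10), ceil(sqrt(p')), ceil(log2 p')} on p' (the
    non-zero-probability count); each is evaluated with the *same* seed so
    the comparison is paired; ties break toward the smaller candidate.
    Returns ``(mtry, {candidate: oob_error})``.
    """
    if probs.p_prime < 1:
        raise ValidationError("p_prime must be >= 1")
    cands = mtry_candidates(probs.p_prime, mtry_grid)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    forest_seed = _subseed(ss)
    errors = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mtry in cands:
            forest = grow_forest(X, y, task, mtry=mtry, n_trees=n_trees,
                                 weights=probs.w, min_node_size=min_node_size,
                                 seed=forest_seed)
            errors[mtry] = forest.oob_error_
    best = min(cands, key=lambda c: (errors[c], c))
    return best, errors


# ---------------------------------------------------------------------------
# the model object


class PIRF:
    """Phylogeny-informed random forest model.

    Parameters
    ----------
    endog : array-like or pandas Series
        Outcome per sample: binary labels for classification, numeric for
        regression (multiclass is rejected).
    exog : DataFrame or 2-D array
        Abundance table, samples x features. Raw counts by default;
        declare pre-normalized input with ``input_type="relative"`` to skip
        the read/abundance filters and normalization.
    tree : PhyloTree, path, or Newick string
        Rooted phylogeny with branch lengths; leaf labels must cover the
        table's features (policy for missing ones set by
        ``config.missing_features``).
    task : {"classification", "regression"}

    Examples
    --------
    >>> data = simulate_dataset(SimulationConfig(seed=7))      # doctest: +SKIP
    >>> model = PIRF.from_dataframe(data.counts, data.y.to_frame(),
    ...                             outcome="outcome", tree=data.tree)
    >>> res = model.fit(seed=1, n_trees=300)                   # doctest: +SKIP
    >>> print(res.summary())                                   # doctest: +SKIP
    """

    def __init__(self, endog, exog, tree, task: str = "classification",
                 feature_names: Optional[Sequence[str]] = None,
                 sample_ids: Optional[Sequence[str]] = None,
                 input_type: str = "counts",
                 config: Optional[PIRFConfig] = None, **overrides):
        if task not in ("classification", "regression"):
            raise ValidationError(f"unknown task {task!r}")
        if input_type not in ("counts", "relative"):
            raise ValidationError(f"unknown input_type {input_type!r}")
        if isinstance(exog, pd.DataFrame):
            feature_names = [str(c) for c in exog.columns]
            sample_ids = [str(i) for i in exog.index]
            exog = exog.values
        exog = np.asarray(exog, dtype=float)
        if exog.ndim != 2:
            raise ValidationError("exog must be 2-D (samples x features)")
        n, p = exog.shape
        if feature_names is None:
            feature_names = [f"f{j + 1}" for j in range(p)]
        if sample_ids is None:
            sample_ids = [f"s{i + 1}" for i in range(n)]
        endog = pd.Series(np.asarray(endog).ravel())
        if len(endog) != n:
            raise ValidationError("endog and exog have different lengths")
        if task == "classification":
            classes = endog.unique()
            if len(classes) < 2:
                raise ValidationError("classification needs two classes")
            if len(classes) > 2:
                raise ValidationError(
                    "only binary classification is supported; found "
                    f"{len(classes)} classes")
        if not isinstance(tree, PhyloTree):
            tree = read_newick(tree)
        self.endog = endog
        self.exog = pd.DataFrame(exog, index=list(sample_ids),
                                 columns=[str(f).strip() for f in feature_names])
        self.tree = tree
        self.task = task
        self.input_type = input_type
        self.config = replace(config) if config else PIRFConfig()
        for key, val in overrides.items():
            if not hasattr(self.config, key):
                raise ValidationError(f"unknown config option {key!r}")
            setattr(self.config, key, val)
        self.config.__post_init__()
        self._prepared = False

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, metadata: pd.DataFrame,
                       outcome: str, tree, task: str = "classification",
                       **kwargs) -> "PIRF":
        """Build from a feature table and a metadata frame sharing sample ids."""
        if outcome not in metadata.columns:
            raise ValidationError(f"outcome column {outcome!r} not in metadata")
        meta = metadata.copy()
        meta.index = meta.index.map(str)
        table = table.copy()
        table.index = table.index.map(str)
        common = [s for s in table.index if s in meta.index]
        if not common:
            raise ValidationError("no shared sample ids between table and "
                                  "metadata")
        y = meta.loc[common, outcome]
        if y.isna().any():
            keep = ~y.isna()
            common = list(np.asarray(common)[keep.values])
            y = y[keep]
        return cls(y.values, table.loc[common], tree, task=task, **kwargs)

    # -- pipeline --------------------------------------------------------

    def _prepare(self) -> None:
        """Preprocess, align to the tree, and cluster (tree-only stages).

        None of this touches the outcome, so it is shared across CV folds.
        """
        if self._prepared:
            return
        cfg = self.config
        table = self.exog
        y = self.endog.copy()
        y.index = table.index

        with _stage("preprocess"):
            if cfg.preprocess and self.input_type == "counts":
                rel, record = preprocess(table, cfg.min_reads,
                                         cfg.min_mean_abundance)
                y = y.loc[rel.index]
            else:
                rel, record = table, {"normalize": False,
                                      "samples_removed": [],
                                      "features_removed": []}

        with _stage("align_to_table"):
            tree = align_to_table(self.tree, rel.columns,
                                  missing=cfg.missing_features)
            kept = [f for f in rel.columns if f in set(tree.leaf_labels)]
            rel = rel[kept]

        features = tuple(rel.columns)
        with _stage("phylogenetic_clusters"):
            if cfg.cluster_mode == "disjoint":
                assignment = None
            else:
                dist = cophenetic_matrix(tree).subset(features)
                if cfg.cluster_mode == "single":
                    medoid = int(np.argmin(dist.values.sum(axis=0)))
                    cost = float(dist.values[:, medoid].sum())
                    assignment = ClusterAssignment(
                        labels=features,
                        cluster_of=np.zeros(len(features), dtype=int),
                        medoids=np.array([medoid]),
                        k=1, cost=cost, build_cost=cost)
                else:
                    assignment = select_k_phylo(dist, (cfg.k_min, cfg.k_max))

        self._X = rel.values.astype(float)
        self._y = y
        self._features = features
        self._aligned_tree = tree
        self._assignment = assignment
        self._preprocessing = record
        self._prepared = True

    def fit(self, seed: Optional[int] = 0, **overrides) -> "PIRFResults":
        """Run the full pipeline and return the fitted results.

        ``overrides`` may adjust any :class:`PIRFConfig` field for this fit
        (e.g. ``n_trees=500`` for a quick run).
        """
        for key, val in overrides.items():
            if not hasattr(self.config, key):
                raise ValidationError(f"unknown config option {key!r}")
            setattr(self.config, key, val)
            self._prepared = False if key in (
                "cluster_mode", "k_min", "k_max", "preprocess", "min_reads",
                "min_mean_abundance", "missing_features") else self._prepared
        self._prepare()
        return self._fit_rows(np.arange(self._X.shape[0]), seed=seed)

    def _fit_rows(self, rows: np.ndarray, seed: Optional[int]) -> "PIRFResults":
        """Fit on a subset of samples (the CV harness passes training rows).

        Only the rows given ever reach the importance, tuning, and training
        stages; the clustering was computed from the tree alone.
        """
        cfg = self.config
        X = self._X[rows]
        y = self._y.iloc[rows].values
        seeds = _stage_seeds(seed)

        if cfg.cluster_mode == "disjoint":
            importance = None
            probs = uniform_probabilities(self._features)
        else:
            with _stage("cluster_importance"):
                importance = cluster_importance_scores(
                    X, y, self.task, self._assignment,
                    n_trees=cfg.n_trees_cluster,
                    n_permutations=cfg.n_permutations,
                    min_node_size=cfg.min_node_size, mtry_grid=cfg.mtry_grid,
                    seed=seeds["importance"])
            with _stage("compute_probabilities"):
                probs = compute_probabilities(importance, self._assignment)

        with _stage("tune_global_mtry"):
            mtry, tuning_errors = tune_global_mtry(
                X, y, self.task, probs, n_trees=cfg.n_trees,
                min_node_size=cfg.min_node_size, mtry_grid=cfg.mtry_grid,
                seed=seeds["tuning"])

        with _stage("grow_forest"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                forest = grow_forest(
                    X, y, self.task, mtry=mtry, n_trees=cfg.n_trees,
                    weights=probs.w, min_node_size=cfg.min_node_size,
                    seed=_subseed(seeds["final"]),
                    feature_names=self._features)

        return PIRFResults(
            model=self, task=self.task, feature_names=self._features,
            assignment=self._assignment, probabilities=probs,
            importance=importance, mtry=mtry, tuning_errors=tuning_errors,
            forest=forest, oob_error_=forest.oob_error_,
            preprocessing=self._preprocessing, seed=seed,
            cluster_mode=cfg.cluster_mode, version=_version)


# ---------------------------------------------------------------------------
# results


@dataclass
class PIRFResults:
    """A fitted phylogeny-informed random forest."""

    task: str
    feature_names: tuple
    assignment: Optional[ClusterAssignment]
    probabilities: SelectionProbabilities
    importance: Optional[ImportanceVector]
    mtry: int
    tuning_errors: dict
    forest: ForestModel
    oob_error_: Optional[float]
    preprocessing: dict
    seed: Optional[int]
    cluster_mode: str
    version: str
    model: Optional[PIRF] = None

    @property
    def w(self) -> np.ndarray:
        return self.probabilities.w

    @property
    def k_phylo(self) -> Optional[int]:
        return None if self.assignment is None else self.assignment.k

    # -- prediction ------------------------------------------------------

    def _matrix_from(self, table) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            cols = [str(c).strip() for c in table.columns]
            missing = [f for f in self.feature_names if f not in set(cols)]
            if missing:
                raise ValidationError(
                    f"new table is missing {len(missing)} model features: "
                    f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
            extra = [c for c in cols if c not in set(self.feature_names)]
            if extra:
                warnings.warn(f"dropping {len(extra)} features unknown to "
                              "the model", stacklevel=3)
            table = table.copy()
            table.columns = cols
            X = table[list(self.feature_names)].values.astype(float)
        else:
            X = np.asarray(table, dtype=float)
            if X.ndim != 2 or X.shape[1] != len(self.feature_names):
                raise ValidationError(
                    f"expected {len(self.feature_names)} features in the "
                    "model's order")
        if self.preprocessing.get("normalize"):
            sums = X.sum(axis=1)
            if np.any(sums <= 0):
                raise DataError("a sample has zero total abundance")
            X = X / sums[:, None]
        return X

    def predict(self, table):
        """Predict outcomes for a new table (counts or matching matrix).

        The stored preprocessing convention (relative-abundance
        normalization over the model's features) is applied; clusters,
        probabilities and the forest are reused as trained.
        """
        return self.forest.predict(self._matrix_from(table))

    def predict_proba(self, table) -> np.ndarray:
        return self.forest.predict_proba(self._matrix_from(table))

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        lines = ["Phylogeny-Informed Random Forest Results",
                 "=" * 44,
                 f"Task:                {self.task}",
                 f"Features (p):        {len(self.feature_names)}",
                 f"Cluster mode:        {self.cluster_mode}"]
        if self.assignment is not None:
            sizes = ", ".join(str(s) for s in self.assignment.cluster_sizes)
            lines += [f"Clusters (k):        {self.assignment.k}",
                      f"Cluster sizes q_k:   {sizes}"]
            if self.assignment.avg_silhouette is not None:
                lines.append(
                    f"Avg silhouette:      {self.assignment.avg_silhouette:.4f}")
        lines += [f"Non-zero probs p':   {self.probabilities.p_prime}",
                  f"mtry (tuned):        {self.mtry}  "
                  f"(candidates OOB: "
                  + ", ".join(f"{c}={e:.4f}" for c, e
                              in sorted(self.tuning_errors.items())) + ")",
                  f"Trees:               {self.forest.n_trees}",
                  f"OOB error:           {self.oob_error_:.4f}"
                  if self.oob_error_ is not None else "OOB error:           n/a",
                  "", "Top features by selection probability w:"]
        order = np.argsort(self.w)[::-1][:10]
        for j in order:
            lines.append(f"  {self.feature_names[j]:<16} w={self.w[j]:.4f}")
        return "\n".join(lines)

    def plot_selection_probabilities(self, ax=None):
        """Bar plot of w per feature, colored by cluster (diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        colors = self.probabilities.cluster_of % 10
        ax.bar(np.arange(len(self.w)), self.w,
               color=plt.get_cmap("tab10")(colors))
        ax.set_xlabel("feature index")
        ax.set_ylabel("selection probability w")
        ax.set_title(f"selection probabilities ({self.cluster_mode})")
        return ax

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        prob = self.probabilities
        return {
            "format": "pirf-model",
            "version": 1,
            "software_version": self.version,
            "task": self.task,
            "cluster_mode": self.cluster_mode,
            "feature_names": list(self.feature_names),
            "seed": self.seed,
            "mtry": int(self.mtry),
            "tuning_errors": {str(k): v for k, v in self.tuning_errors.items()},
            "oob_error": self.oob_error_,
            "preprocessing": self.preprocessing,
            "probabilities": {
                "w": prob.w.tolist(), "v": prob.v.tolist(),
                "cluster_of": prob.cluster_of.tolist(),
                "cluster_sizes": prob.cluster_sizes.tolist(),
                "degenerate_clusters": list(prob.degenerate_clusters),
            },
            "assignment": None if self.assignment is None else {
                "cluster_of": self.assignment.cluster_of.tolist(),
                "medoids": self.assignment.medoids.tolist(),
                "k": self.assignment.k,
                "cost": self.assignment.cost,
                "build_cost": self.assignment.build_cost,
                "avg_silhouette": self.assignment.avg_silhouette,
            },
            "importance": None if self.importance is None
                          else self.importance.scores.tolist(),
            "forest": self.forest.to_dict(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "PIRFResults":
        if d.get("format") != "pirf-model":
            raise ValidationError("not a pirf model serialization")
        features = tuple(d["feature_names"])
        pr = d["probabilities"]
        probs = SelectionProbabilities(
            labels=features, w=np.asarray(pr["w"]), v=np.asarray(pr["v"]),
            cluster_of=np.asarray(pr["cluster_of"], dtype=int),
            cluster_sizes=np.asarray(pr["cluster_sizes"], dtype=int),
            degenerate_clusters=tuple(pr["degenerate_clusters"]))
        assignment = None
        if d["assignment"] is not None:
            a = d["assignment"]
            assignment = ClusterAssignment(
                labels=features,
                cluster_of=np.asarray(a["cluster_of"], dtype=int),
                medoids=np.asarray(a["medoids"], dtype=int), k=a["k"],
                cost=a["cost"], build_cost=a["build_cost"],
                avg_silhouette=a["avg_silhouette"])
        importance = None
        if d["importance"] is not None:
            importance = ImportanceVector(labels=features,
                                          scores=np.asarray(d["importance"]))
        return cls(
            model=None, task=d["task"], feature_names=features,
            assignment=assignment, probabilities=probs, importance=importance,
            mtry=d["mtry"],
            tuning_errors={int(k): v for k, v in d["tuning_errors"].items()},
            forest=ForestModel.from_dict(d["forest"]),
            oob_error_=d["oob_error"], preprocessing=d["preprocessing"],
            seed=d["seed"], cluster_mode=d["cluster_mode"],
            version=d["software_version"])

    @classmethod
    def load(cls, path) -> "PIRFResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
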