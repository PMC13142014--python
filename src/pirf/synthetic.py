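"""Synthetic microbiome data with clade-localized signal.

The generator emulates the situation the method is built for: an abundance
table whose informative features are concentrated in one clade of the
accompanying phylogeny. It produces

* a pure-birth (Yule) tree over p leaves with i.i.d. exponential branch
  lengths,
* zero-inflated, log-normally skewed counts obtained by scaling a per-sample
  relative profile to a random library size (uniform on [5000, 50000]) and
  Bernoulli-masking zeros, and
* an outcome driven by the summed relative abundance of one signal clade:
  a Bernoulli draw on the logistic scale for classification, a linear model
  with Gaussian noise for regression.

A ``scattered`` mode places the same number of signal features at random
(non-clade) positions, giving a no-phylogenetic-advantage regime for
negative controls. With a fixed seed the whole (tree, table, outcome) triple
is bit-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .phylo import PhyloTree, read_newick

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_tree",
           "simulate_dataset", "write_dataset"]


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults follow the regime the method targets: n=120 samples, p=40
    features, a signal clade holding ~25% of the features, a strong effect
    (beta=5 on the standardized clade abundance), 50% structural zeros, and
    unit log-normal dispersion on top of a unit-variance per-feature
    baseline.
    """

    n_samples: int = 120
    n_features: int = 40
    signal_fraction: float = 0.25
    effect_size: float = 5.0
    zero_inflation: float = 0.5
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    feature_sd: float = 1.0          # spread of per-feature baseline log-means
    branch_mean: float = 0.1         # mean of exponential branch lengths
    library_size_range: tuple = (5000, 50000)
    noise_sd: float = 1.0            # regression residual sd
    task: str = "classification"
    scattered: bool = False          # signal features random, not a clade
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_samples < 10:
            raise ValidationError("n_samples must be >= 10")
        if self.n_features < 10:
            raise ValidationError("n_features must be >= 10")
        if not 0 <= self.zero_inflation < 1:
            raise ValidationError("zero_inflation must be in [0, 1)")
        if self.lognormal_sigma <= 0:
            raise ValidationError("lognormal_sigma must be > 0")
        if self.task not in ("classification", "regression"):
            raise ValidationError(f"unknown task {self.task!r}")


@dataclass
class SimulatedDataset:
    """Tree, count table, outcome, and the ground-truth signal features."""

    tree: PhyloTree
    counts: pd.DataFrame            # samples x features, integer counts
    y: pd.Series
    signal_features: tuple
    config: SimulationConfig


def simulate_tree(n_features: int, branch_mean: float = 0.1,
                  seed=None) -> PhyloTree:
    """Pure-birth topology with i.i.d. exponential branch lengths.

    Starting from a cherry, a uniformly random extant lineage splits until
    there are ``n_features`` leaves (the Yule process); every edge then gets
    an independent Exp(mean=branch_mean) length. Leaves are labelled
    f1..fp in left-to-right order.
    """
    if n_features < 2:
        raise ValidationError("a tree needs at least 2 leaves")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    # nested-list topology: leaves are ints, internal nodes are [left, right]
    children: dict = {0: None, 1: None}
    next_id = 2
    leaves = [0, 1]
    while len(leaves) < n_features:
        pick = int(rng.integers(len(leaves)))
        node = leaves.pop(pick)
        a, b = next_id, next_id + 1
        next_id += 2
        children[node] = (a, b)
        children[a] = None
        children[b] = None
        leaves.insert(pick, a)
        leaves.insert(pick + 1, b)

    counter = [0]

    def newick(node) -> str:
        length = rng.exponential(branch_mean)
        if children[node] is None:
            counter[0] += 1
            return f"f{counter[0]}:{length!r}"
        a, b = children[node]
        return f"({newick(a)},{newick(b)}):{length!r}"

    a, b = 0, 1
    text = f"({newick(a)},{newick(b)});"
    return read_newick(text)


def _clades(tree: PhyloTree):
    """Leaf-label sets of every internal node (proper clades only)."""
    out = []
    for node in tree.dendropy_tree.preorder_internal_node_iter():
        labels = tuple(l.taxon.label for l in node.leaf_iter())
        if 1 < len(labels) < tree.n_leaves:
            out.append(labels)
    return out


def _pick_signal_clade(tree: PhyloTree, fraction: float,
                       rng: np.random.Generator) -> tuple:
    p = tree.n_leaves
    target = fraction * p
    clades = _clades(tree)
    if not clades:
        raise DataError("tree has no proper clades")
    devs = np.array([abs(len(c) - target) for c in clades])
    best = devs.min()
    if best > 0.5 * target:
        raise DataError(
            f"no clade within 50% of the target size {target:.1f}; "
            "try a different signal_fraction")
    candidates = [c for c, d in zip(clades, devs) if d == best]
    return candidates[int(rng.integers(len(candidates)))]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw a complete (tree, counts, outcome) triple under ``config``."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_features, config.branch_mean, seed=rng)
    n, p = config.n_samples, config.n_features
    labels = tree.leaf_labels

    if config.scattered:
        size = max(2, int(round(config.signal_fraction * p)))
        signal = tuple(sorted(
            np.asarray(labels)[rng.choice(p, size=size, replace=False)],
            key=lambda s: int(s[1:])))
    else:
        signal = _pick_signal_clade(tree, config.signal_fraction, rng)

    # zero-inflated log-normal counts
    baseline = rng.normal(0.0, config.feature_sd, size=p)
    log_abund = (config.lognormal_mu + baseline[None, :]
                 + rng.normal(0.0, config.lognormal_sigma, size=(n, p)))
    raw = np.exp(log_abund)
    present = rng.random(size=(n, p)) >= config.zero_inflation
    raw *= present
    row_sums = raw.sum(axis=1)
    if np.any(row_sums == 0):       # vanishingly rare for p >= 10
        raise DataError("a sample lost all features to zero inflation; "
                        "lower zero_inflation or raise n_features")
    rel = raw / row_sums[:, None]
    lo, hi = config.library_size_range
    library = rng.integers(lo, hi + 1, size=n)
    counts = np.rint(rel * library[:, None]).astype(int)

    # outcome driven by the signal clade's summed relative abundance
    sig_idx = [labels.index(f) for f in signal]
    t = rel[:, sig_idx].sum(axis=1)
    sd = t.std()
    z = (t - t.mean()) / (sd if sd > 0 else 1.0)
    if config.task == "classification":
        prob = 1.0 / (1.0 + np.exp(-config.effect_size * z))
        y = pd.Series(np.where(rng.random(n) < prob, "case", "control"),
                      index=[f"s{i + 1}" for i in range(n)], name="outcome")
    else:
        y = pd.Series(config.effect_size * z
                      + rng.normal(0.0, config.noise_sd, size=n),
                      index=[f"s{i + 1}" for i in range(n)], name="outcome")

    table = pd.DataFrame(counts, index=y.index, columns=list(labels))
    return SimulatedDataset(tree=tree, counts=table, y=y,
                            signal_features=tuple(signal), config=config)


def write_dataset(data: SimulatedDataset, outdir) -> dict:
    """Write Newick + TSV table + TSV metadata consumable by the CLI."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "tree": os.path.join(outdir, "tree.nwk"),
        "table": os.path.join(outdir, "table.tsv"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
        "signal": os.path.join(outdir, "signal_features.txt"),
    }
    data.tree.write(paths["tree"])
    data.counts.to_csv(paths["table"], sep="\t", index_label="sample_id")
    meta = pd.DataFrame({"outcome": data.y})
    meta.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    with open(paths["signal"], "w") as fh:
        fh.write("\n".join(data.signal_features) + "\n")
    return paths
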