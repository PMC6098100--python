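"""Construction of the species-pair (bsi) and meta-training (mt) tables.

The pipeline in brief: sample species pairs ``(A_i, B_j)`` from interaction
webs, describe each node by its entropy profile ``Sh_0..Sh_5`` plus the
pairwise differences ``dSh_k = Sh_ki - Sh_kj`` (18 features), and label the
pair by the adjacency element ``A_ij`` (link present / absent).  Train a pool
of base neural-network classifiers on that table, then record — pair by pair,
classifier by classifier — whether each classifier got the link right.  The
resulting meta-table (the 18 pair features plus the classifier topology's 6
``annSh_k`` descriptors, 24 features in all) carries a meta-label of 1 iff
the named classifier correctly predicted ``A_ij``; it is what the screening
meta-model is trained on.

Column order of the exported tables: provenance (network_id, node_i, node_j,
[ann_id]), features in k-major order (Sh_0i..Sh_5i, Sh_0j..Sh_5j,
dSh_0..dSh_5, [annSh_0..annSh_5]), label last.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .anntopo import AnnTopology
from .entropy import K_MAX_DEFAULT, node_entropies
from .graphio import Network

__all__ = [
    "FEATURES_I",
    "FEATURES_J",
    "FEATURES_D",
    "FEATURES_BSI",
    "FEATURES_ANN",
    "FEATURES_MT",
    "BaseClassifier",
    "SklearnBaseClassifier",
    "NoisyOracleClassifier",
    "sample_pairs",
    "build_bsi",
    "train_base_pool",
    "build_mt",
    "split_dataset",
]

_K = range(K_MAX_DEFAULT + 1)
FEATURES_I = [f"Sh_{k}i" for k in _K]
FEATURES_J = [f"Sh_{k}j" for k in _K]
FEATURES_D = [f"dSh_{k}" for k in _K]
FEATURES_BSI = FEATURES_I + FEATURES_J + FEATURES_D
FEATURES_ANN = [f"annSh_{k}" for k in _K]
FEATURES_MT = FEATURES_BSI + FEATURES_ANN


# ---------------------------------------------------------------------------
# Base classifiers
# ---------------------------------------------------------------------------

@runtime_checkable
class BaseClassifier(Protocol):
    """Contract every base (and meta) classifier obeys.

    Implementations are deterministic given a seed, expose the topology whose
    ``annSh_k`` descriptors they contribute to the meta-table, and after
    ``fit`` never error on ``predict_score`` over the training schema.
    """

    topology: AnnTopology

    def fit(self, features: pd.DataFrame, labels: np.ndarray) -> "BaseClassifier": ...

    def predict_score(self, features: pd.DataFrame) -> np.ndarray: ...


class SklearnBaseClassifier:
    """Feed-forward base classifier with a given topology's hidden layers.

    Linear (LNN) topologies — no hidden layer — map to logistic regression;
    topologies with hidden layers map to a multilayer perceptron of the same
    hidden sizes.  Scores are class-1 probabilities in [0, 1].
    """

    def __init__(self, topology: AnnTopology, seed: int = 0, max_iter: int = 300):
        self.topology = topology
        self.seed = seed
        if topology.hidden_sizes:
            self._est = MLPClassifier(
                hidden_layer_sizes=topology.hidden_sizes,
                activation="logistic",
                solver="adam",
                max_iter=max_iter,
                random_state=seed,
            )
        else:
            self._est = LogisticRegression(max_iter=1000, random_state=seed)
        self._columns: Optional[list[str]] = None

    def fit(self, features: pd.DataFrame, labels: np.ndarray) -> "SklearnBaseClassifier":
        self._columns = list(features.columns)
        with warnings.catch_warnings():
            warnings.filterwarnings("always", category=ConvergenceWarning)
            self._est.fit(features.to_numpy(), np.asarray(labels))
        return self

    def predict_score(self, features: pd.DataFrame) -> np.ndarray:
        if self._columns is not None:
            features = features[self._columns]
        return self._est.predict_proba(features.to_numpy())[:, 1]


class NoisyOracleClassifier:
    """Synthetic diagnostic classifier with a controlled accuracy.

    Memorizes the training rows and answers with the true label flipped at a
    fixed per-row rate, so ``accuracy=0.95`` is a deliberately strong base
    classifier and ``accuracy=0.1`` a deliberately weak (anti-correlated)
    one.  Exists to exercise the meta-learning layer under known conditions;
    it is not a model of anything and never sees unseen-row generalization
    (unknown rows score 0.5).
    """

    def __init__(self, topology: AnnTopology, accuracy: float, seed: int = 0):
        if not 0.0 <= accuracy <= 1.0:
            raise ValueError("accuracy must be in [0, 1]")
        self.topology = topology
        self.accuracy = accuracy
        self.seed = seed
        self._memory: dict[bytes, float] = {}

    @staticmethod
    def _key(row: np.ndarray) -> bytes:
        return np.round(row.astype(float), 9).tobytes()

    def fit(self, features: pd.DataFrame, labels: np.ndarray) -> "NoisyOracleClassifier":
        rng = np.random.default_rng(self.seed)
        x = features.to_numpy()
        y = np.asarray(labels, dtype=float)
        flip = rng.random(len(y)) > self.accuracy
        answers = np.where(flip, 1.0 - y, y)
        self._memory = {self._key(x[i]): answers[i] for i in range(len(y))}
        return self

    def predict_score(self, features: pd.DataFrame) -> np.ndarray:
        x = features.to_numpy()
        return np.array([self._memory.get(self._key(row), 0.5) for row in x])


# ---------------------------------------------------------------------------
# Pair sampling and the bsi table
# ---------------------------------------------------------------------------

def _candidate_pairs(net: Network) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(linked, unlinked) index pairs; one orientation per unordered pair.

    In bipartite webs ``i`` always comes from the row partition and ``j``
    from the column partition (fixing the sign of dSh); in unipartite webs
    ``i`` is the lower node index so mirrored duplicates never appear.
    """
    adj = net.adjacency
    if net.bipartite_partition is not None:
        idx = {lab: i for i, lab in enumerate(net.node_ids)}
        rows = sorted(idx[x] for x in net.bipartite_partition[0])
        cols = sorted(idx[x] for x in net.bipartite_partition[1])
        pairs = [(i, j) for i in rows for j in cols]
    else:
        n = net.n
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pos = [(i, j) for i, j in pairs if adj[i, j] > 0]
    neg = [(i, j) for i, j in pairs if adj[i, j] == 0]
    return pos, neg


def sample_pairs(
    net: Network,
    n_pos: int,
    n_neg: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniformly sample linked and unlinked node pairs without replacement.

    Returns a frame with columns node_i, node_j, A_ij; reproducible by seed.
    """
    pos, neg = _candidate_pairs(net)
    if n_pos > len(pos):
        raise ValueError(f"requested {n_pos} linked pairs but only {len(pos)} exist")
    if n_neg > len(neg):
        raise ValueError(f"requested {n_neg} unlinked pairs but only {len(neg)} exist")
    rng = np.random.default_rng(seed)
    take_pos = [pos[i] for i in rng.choice(len(pos), size=n_pos, replace=False)]
    take_neg = [neg[i] for i in rng.choice(len(neg), size=n_neg, replace=False)]
    records = [
        (net.node_ids[i], net.node_ids[j], 1) for i, j in take_pos
    ] + [(net.node_ids[i], net.node_ids[j], 0) for i, j in take_neg]
    return pd.DataFrame(records, columns=["node_i", "node_j", "A_ij"])


def build_bsi(
    nets: Sequence[Network],
    n_pos_per_net: Optional[int] = None,
    n_neg_per_net: Optional[int] = None,
    seed: int = 0,
    network_ids: Optional[Sequence[str]] = None,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Assemble the species-pair table over a collection of webs.

    For each web, ``n_pos_per_net`` linked and ``n_neg_per_net`` unlinked
    pairs are sampled (defaults: all links, and unlinked pairs matched 1:1 —
    balanced classes).  Features come from the entropy profiles of the pair's
    own network.  Output: provenance columns, the 18 features, label last.
    """
    if network_ids is None:
        network_ids = [f"net{idx}" for idx in range(len(nets))]
    frames = []
    for offset, (net_id, net) in enumerate(zip(network_ids, nets)):
        pos, neg = _candidate_pairs(net)
        n_pos = len(pos) if n_pos_per_net is None else n_pos_per_net
        n_neg = min(n_pos, len(neg)) if n_neg_per_net is None else n_neg_per_net
        pairs = sample_pairs(net, n_pos, n_neg, seed=seed + offset)
        profiles = {
            p.node_id: p.sh for p in node_entropies(net, log_base=log_base)
        }
        sh_i = np.stack([profiles[lab] for lab in pairs["node_i"]])
        sh_j = np.stack([profiles[lab] for lab in pairs["node_j"]])
        frame = pd.DataFrame(
            {
                "network_id": net_id,
                "node_i": pairs["node_i"],
                "node_j": pairs["node_j"],
                **{FEATURES_I[k]: sh_i[:, k] for k in _K},
                **{FEATURES_J[k]: sh_j[:, k] for k in _K},
                **{FEATURES_D[k]: sh_i[:, k] - sh_j[:, k] for k in _K},
                "A_ij": pairs["A_ij"].to_numpy(),
            }
        )
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    if not np.isfinite(out[FEATURES_BSI].to_numpy()).all():
        raise ValueError("non-finite feature values in bsi table")
    return out


# ---------------------------------------------------------------------------
# Base pool and the mt table
# ---------------------------------------------------------------------------

def train_base_pool(
    bsi: pd.DataFrame,
    topologies: Sequence[AnnTopology],
    train_fraction: float = 0.75,
    seed: int = 0,
) -> list[SklearnBaseClassifier]:
    """Train one base classifier per topology on the bsi training portion.

    The pool preserves topology order.  A classifier that fails to converge
    within its iteration budget is kept with a warning — its predictions are
    still defined.
    """
    train, _ = split_dataset(bsi, fraction=train_fraction, seed=seed)
    x = train[FEATURES_BSI]
    y = train["A_ij"].to_numpy()
    pool = []
    for rank, topo in enumerate(topologies):
        clf = SklearnBaseClassifier(topo, seed=seed + rank)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(x, y)
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                warnings.warn(
                    f"base classifier {topo.name!r} did not converge; retained",
                    stacklevel=2,
                )
        pool.append(clf)
    return pool


def build_mt(
    bsi: pd.DataFrame,
    pool: Sequence[BaseClassifier],
    threshold: float = 0.5,
    descriptor_source: str = "computed",
) -> pd.DataFrame:
    """Meta-table: one row per (pair, classifier), 24 features, meta-label last.

    ``meta_label`` is 1 iff the classifier's thresholded score equals the
    pair's ``A_ij``.  Row count is always ``len(bsi) * len(pool)``.
    ``descriptor_source`` selects the topology descriptors appended to each
    row: ``"computed"`` (this package's entropy convention) or ``"printed"``
    (the registry's MI-NODES fixture values, where available).
    """
    if descriptor_source not in ("computed", "printed"):
        raise ValueError("descriptor_source must be 'computed' or 'printed'")
    missing = [c for c in FEATURES_BSI + ["A_ij"] if c not in bsi.columns]
    if missing:
        raise ValueError(f"bsi table is missing columns: {missing}")
    x = bsi[FEATURES_BSI]
    y = bsi["A_ij"].to_numpy()
    frames = []
    for clf in pool:
        scores = np.asarray(clf.predict_score(x))
        pred = (scores >= threshold).astype(int)
        if descriptor_source == "printed":
            desc = clf.topology.printed_descriptors
            if desc is None:
                raise ValueError(
                    f"topology {clf.topology.name!r} has no printed descriptors"
                )
        else:
            desc = clf.topology.descriptors
        frame = bsi[["network_id", "node_i", "node_j"]].copy()
        frame["ann_id"] = clf.topology.name
        frame[FEATURES_BSI] = x.to_numpy()
        for k in _K:
            frame[FEATURES_ANN[k]] = desc[k]
        frame["A_ij"] = y
        frame["meta_label"] = (pred == y).astype(int)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_dataset(
    table: pd.DataFrame,
    fraction: float = 0.75,
    seed: int = 0,
    stratify_on: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split: disjoint, exhaustive, seed-deterministic.

    Strata default to label (meta_label if present, else A_ij) crossed with
    network_id; within every stratum the train share is ``fraction`` rounded
    to the nearest row, so class proportions are preserved to within one row
    per stratum.  Singleton strata go to the training side.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if stratify_on is None:
        label = "meta_label" if "meta_label" in table.columns else "A_ij"
        stratify_on = [c for c in (label, "network_id") if c in table.columns]
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    if stratify_on:
        groups = [np.asarray(g) for g in table.groupby(list(stratify_on), sort=True).indices.values()]
    else:
        groups = [np.arange(len(table))]
    # largest-remainder allocation: per-stratum train counts differ from the
    # exact share by < 1 row while the global train count hits round(f * N)
    target_total = int(round(fraction * len(table)))
    base = [int(np.floor(fraction * len(g))) for g in groups]
    remainder = [fraction * len(g) - b for g, b in zip(groups, base)]
    short = target_total - sum(base)
    for rank in np.argsort(remainder)[::-1][:max(short, 0)]:
        base[rank] += 1
    for idx, n_train in zip(groups, base):
        n_train = min(max(n_train, 1), len(idx))  # singleton strata go to train
        perm = rng.permutation(len(idx))
        train_idx.append(idx[perm[:n_train]])
        test_idx.append(idx[perm[n_train:]])
    train = table.iloc[np.sort(np.concatenate(train_idx))].reset_index(drop=True)
    test_parts = [a for a in test_idx if len(a)]
    test = table.iloc[
        np.sort(np.concatenate(test_parts)) if test_parts else np.array([], dtype=int)
    ].reset_index(drop=True)
    return train, test
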