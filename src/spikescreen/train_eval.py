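"""Mini-batch surrogate-gradient training and repeated nested CV.

Training runs shuffled mini-batches of 64 fingerprints through the
spiking classifier, backpropagates a rate-coded cross-entropy on the
output spike counts, and applies one of seven optimizers, optionally
with global-norm gradient clipping.

Model selection and evaluation are separated by nested cross-validation:
the inner loop scores randomly drawn hyperparameter points by mean
inner-fold balanced accuracy, the outer loop retrains the selected point
and measures balanced accuracy and ROC AUC on the held-out fold. The
whole procedure is repeated (ten times by default) and summarized as the
mean and standard deviation over repetitions.

Class balancing by minority oversampling can be applied either once to
the whole dataset before splitting (``balance="paper"``, which lets
duplicated minority records straddle folds) or inside each training
portion only (``balance="safe"``, which keeps held-out folds free of
training duplicates). Both modes record index bookkeeping so the
disjointness of selection and evaluation data can be asserted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from spikescreen.chem_encode import FingerprintDataset, oversample_indices
from spikescreen.lif_core import LIFParams, SurrogateParams
from spikescreen.optimizers import (
    OPTIMIZER_NAMES,
    Optimizer,
    build_optimizer,
    clip_grads_global_norm,
)
from spikescreen.snn_model import (
    NetworkSpec,
    SpikingNet,
    backward_batch,
    forward_batch,
    init_network,
    predict_batch,
    rate_loss_grad,
    scores_batch,
)

BATCH_SIZE = 64
CLIP_NORM = 1.0


@dataclass(frozen=True)
class HyperParamPoint:
    """One configuration drawn from the search grid."""

    n_hidden: int = 1000
    beta: float = 0.95
    slope: float = 50.0
    optimizer: str = "Adamax"
    lr: float = 2e-3
    wd: float = 0.0
    gc: bool = False
    epochs: int = 25

    def __post_init__(self):
        if self.optimizer not in OPTIMIZER_NAMES:
            raise ValueError(
                f"unknown optimizer {self.optimizer!r}; choose from {OPTIMIZER_NAMES}"
            )
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if self.wd < 0:
            raise ValueError("wd must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class SearchGrid:
    """Level sets for each searched hyperparameter."""

    n_hidden: tuple[int, ...]
    beta: tuple[float, ...]
    slope: tuple[float, ...]
    optimizer: tuple[str, ...]
    lr: tuple[float, ...]
    wd: tuple[float, ...]
    gc: tuple[bool, ...]
    epochs: tuple[int, ...]

    def draw(self, rng: np.random.Generator) -> HyperParamPoint:
        """One uniform draw per hyperparameter axis."""
        pick = lambda levels: levels[rng.integers(len(levels))]
        return HyperParamPoint(
            n_hidden=int(pick(self.n_hidden)),
            beta=float(pick(self.beta)),
            slope=float(pick(self.slope)),
            optimizer=str(pick(self.optimizer)),
            lr=float(pick(self.lr)),
            wd=float(pick(self.wd)),
            gc=bool(pick(self.gc)),
            epochs=int(pick(self.epochs)),
        )

    def all_points(self):
        """Iterate the full Cartesian product (for exhaustive small grids)."""
        axes = (
            self.n_hidden, self.beta, self.slope, self.optimizer,
            self.lr, self.wd, self.gc, self.epochs,
        )
        for vals in itertools.product(*axes):
            yield HyperParamPoint(*vals)


def _lr_levels(n_levels: int = 15) -> tuple[float, ...]:
    # learning rates seen in published result tables, padded log-uniformly
    observed = [1e-5, 5e-5, 1e-4, 1e-3, 2e-3, 5e-3, 1e-2]
    pad = list(np.geomspace(1e-5, 0.5, n_levels))
    merged = sorted(set(observed))
    for p in pad:
        if len(merged) >= n_levels:
            break
        if all(abs(np.log10(p / m)) > 0.15 for m in merged):
            merged.append(float(p))
    return tuple(sorted(merged)[:n_levels])


def default_grid() -> SearchGrid:
    """The default hyperparameter grid used for random search.

    Hidden-layer sizes span 500-2000; the membrane decay beta has six
    regularly spaced levels on [0.6, 0.95]; the surrogate slope takes
    {25, 50, 75}; learning rates mix published values with a log-uniform
    padding of [1e-5, 0.5]; weight decay includes 0 and a geometric
    ladder of [0.001, 0.05].
    """
    return SearchGrid(
        n_hidden=(500, 800, 1000, 1200, 1500, 2000),
        beta=tuple(np.round(np.linspace(0.6, 0.95, 6), 3)),
        slope=(25.0, 50.0, 75.0),
        optimizer=OPTIMIZER_NAMES,
        lr=_lr_levels(),
        wd=(0.0, 1e-4) + tuple(np.round(np.geomspace(0.001, 0.05, 4), 5)),
        gc=(False, True),
        epochs=(10, 25, 50, 100),
    )


def spec_for(point: HyperParamPoint, n_inputs: int, n_steps: int = 25) -> NetworkSpec:
    """Network spec implied by a hyperparameter point and input width."""
    return NetworkSpec(
        n_inputs=n_inputs,
        n_hidden=point.n_hidden,
        n_steps=n_steps,
        lif=LIFParams(beta=point.beta),
        surrogate=SurrogateParams(slope=point.slope),
    )


def make_optimizer(point: HyperParamPoint, network: SpikingNet) -> Optimizer:
    """Optimizer handle for a network, configured from the point."""
    params = {"W1": network.W1, "W2": network.W2}
    return build_optimizer(point.optimizer, params, lr=point.lr, wd=point.wd)


def train(
    network: SpikingNet,
    data: FingerprintDataset,
    point: HyperParamPoint,
    seed: int,
    batch_size: int = BATCH_SIZE,
) -> tuple[SpikingNet, list[float]]:
    """Train in place for point.epochs passes of shuffled mini-batches.

    Returns the trained network and the per-epoch mean batch loss.
    Reproducible from the seed, which drives only the shuffling.
    """
    if data.n_samples == 0:
        raise ValueError("empty dataset")
    X = data.bits.astype(np.float64)
    y = data.labels
    rng = np.random.default_rng(seed)
    opt = make_optimizer(point, network)
    history: list[float] = []
    for _ in range(point.epochs):
        order = rng.permutation(data.n_samples)
        losses = []
        for start in range(0, data.n_samples, batch_size):
            idx = order[start : start + batch_size]
            counts, _, cache = forward_batch(network, X[idx], cache=True)
            loss, d_counts = rate_loss_grad(counts, y[idx])
            grads = backward_batch(network, cache, d_counts)
            if point.gc:
                clip_grads_global_norm(grads, CLIP_NORM)
            opt.step(grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return network, history


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of sensitivity and specificity, as a percentage in [0, 100]."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("y_true must contain both classes")
    return 100.0 * float(balanced_accuracy_score(y_true, y_pred))


def auc(y_true, scores) -> float:
    """Area under the ROC curve (midrank tie handling)."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("y_true must contain both classes")
    return float(roc_auc_score(y_true, scores))


@dataclass
class SearchRecord:
    """One scored hyperparameter draw from an inner search."""

    point: HyperParamPoint
    mean_ba: float
    std_ba: float = 0.0
    fold_bas: tuple[float, ...] = ()


def _fit_and_score(
    X_tr, y_tr, X_te, y_te, point: HyperParamPoint, n_steps: int, seed: int
) -> float:
    net = init_network(spec_for(point, X_tr.shape[1], n_steps), seed)
    train(net, FingerprintDataset(X_tr, y_tr), point, seed=seed + 1)
    return balanced_accuracy(y_te, predict_batch(net, X_te))


def random_search(
    dataset: FingerprintDataset,
    grid: SearchGrid,
    n_draws: int,
    k_inner: int = 3,
    seed: int = 0,
    n_steps: int = 25,
) -> tuple[HyperParamPoint, list[SearchRecord]]:
    """Draw n_draws points from the grid, score each by inner-fold BA.

    Returns the best point (ties resolved in draw order) and the scored
    records for all draws.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    X, y = dataset.bits, dataset.labels
    records: list[SearchRecord] = []
    skf = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed % 2**31)
    splits = list(skf.split(X, y))
    for d in range(n_draws):
        point = grid.draw(rng)
        fold_bas = []
        for f, (tr, te) in enumerate(splits):
            fold_bas.append(
                _fit_and_score(
                    X[tr], y[tr], X[te], y[te], point, n_steps,
                    seed=int(rng.integers(2**31)),
                )
            )
        records.append(
            SearchRecord(
                point=point,
                mean_ba=float(np.mean(fold_bas)),
                std_ba=float(np.std(fold_bas)),
                fold_bas=tuple(fold_bas),
            )
        )
    best = max(records, key=lambda r: r.mean_ba)  # max is stable: first wins ties
    return best.point, records


@dataclass
class CVSummary:
    """Aggregate of a repeated nested cross-validation run."""

    rep_fold_ba: np.ndarray  # (n_repeats, k_outer) percentages
    rep_fold_auc: np.ndarray  # (n_repeats, k_outer)
    mean_ba: float
    std_ba: float
    mean_auc: float
    std_auc: float
    chosen_points: list[list[HyperParamPoint]]
    bookkeeping: list[dict] = field(default_factory=list)
    search_records: list[SearchRecord] = field(default_factory=list)


def nested_cv(
    dataset: FingerprintDataset,
    grid: SearchGrid,
    k_outer: int = 5,
    k_inner: int = 3,
    n_repeats: int = 10,
    seed: int = 0,
    n_draws: int = 10,
    balance: str = "safe",
    n_steps: int = 25,
) -> CVSummary:
    """Repeated nested CV with inner random search and outer evaluation.

    Every repetition reshuffles the outer folds. Mean/std statistics are
    taken over the per-repetition means, mirroring reporting of CV
    repetitions. Bookkeeping entries record, per repetition and outer
    fold, the dataset-row and original-record indices used for inner
    search versus outer testing.
    """
    if k_outer < 2 or k_inner < 2:
        raise ValueError("k_outer and k_inner must be >= 2")
    if balance not in ("none", "paper", "safe"):
        raise ValueError("balance must be 'none', 'paper' or 'safe'")
    ss = np.random.SeedSequence(seed)
    balance_seed, *rep_seeds = [
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_repeats + 1)
    ]

    orig_ids = np.arange(dataset.n_samples)
    if balance == "paper":
        idx = oversample_indices(dataset.labels, balance_seed)
        dataset = FingerprintDataset(dataset.bits[idx], dataset.labels[idx])
        orig_ids = orig_ids[idx]
    X, y = dataset.bits, dataset.labels

    rep_fold_ba = np.zeros((n_repeats, k_outer))
    rep_fold_auc = np.zeros((n_repeats, k_outer))
    chosen: list[list[HyperParamPoint]] = []
    bookkeeping: list[dict] = []
    all_records: list[SearchRecord] = []

    for r, rseed in enumerate(rep_seeds):
        skf = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=rseed)
        rng = np.random.default_rng(rseed)
        rep_points: list[HyperParamPoint] = []
        for f, (tr, te) in enumerate(skf.split(X, y)):
            if balance == "safe":
                tr_rows = tr[oversample_indices(y[tr], int(rng.integers(2**31)))]
            else:
                tr_rows = tr
            inner = FingerprintDataset(X[tr_rows], y[tr_rows])
            point, records = random_search(
                inner, grid, n_draws, k_inner,
                seed=int(rng.integers(2**31)), n_steps=n_steps,
            )
            all_records.extend(records)
            net = init_network(
                spec_for(point, X.shape[1], n_steps), int(rng.integers(2**31))
            )
            train(net, inner, point, seed=int(rng.integers(2**31)))
            rep_fold_ba[r, f] = balanced_accuracy(y[te], predict_batch(net, X[te]))
            rep_fold_auc[r, f] = auc(y[te], scores_batch(net, X[te]))
            rep_points.append(point)
            bookkeeping.append(
                {
                    "repeat": r,
                    "outer_fold": f,
                    "outer_test_rows": te.tolist(),
                    "inner_train_rows": sorted(set(tr_rows.tolist())),
                    "outer_test_orig": sorted(set(orig_ids[te].tolist())),
                    "inner_train_orig": sorted(set(orig_ids[tr_rows].tolist())),
                }
            )
        chosen.append(rep_points)

    rep_means_ba = rep_fold_ba.mean(axis=1)
    rep_means_auc = rep_fold_auc.mean(axis=1)
    return CVSummary(
        rep_fold_ba=rep_fold_ba,
        rep_fold_auc=rep_fold_auc,
        mean_ba=float(rep_means_ba.mean()),
        std_ba=float(rep_means_ba.std(ddof=0)),
        mean_auc=float(rep_means_auc.mean()),
        std_auc=float(rep_means_auc.std(ddof=0)),
        chosen_points=chosen,
        bookkeeping=bookkeeping,
        search_records=all_records,
    )


def rank_models(records: list[SearchRecord], top_k: int = 5):
    """Top configurations by mean balanced accuracy, result-table style.

    Returns a pandas DataFrame with one row per configuration, sorted
    descending by mean BA (stable, so equal means keep insertion order).
    """
    import pandas as pd

    if not records:
        raise ValueError("no records to rank")
    rows = [
        {
            "hidden": r.point.n_hidden,
            "beta": r.point.beta,
            "slope": r.point.slope,
            "optimizer": r.point.optimizer,
            "lr": r.point.lr,
            "wd": r.point.wd,
            "gc": r.point.gc,
            "mean_ba": r.mean_ba,
            "std_ba": r.std_ba,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    return (
        df.sort_values("mean_ba", ascending=False, kind="stable")
        .head(top_k)
        .reset_index(drop=True)
    )


def holdout_split(
    dataset: FingerprintDataset, test_frac: float = 0.2, seed: int = 0
) -> tuple[FingerprintDataset, FingerprintDataset]:
    """Stratified train/test split used by the quick-evaluation paths."""
    rng = np.random.default_rng(seed)
    tr_idx, te_idx = [], []
    for cls in (0, 1):
        rows = np.flatnonzero(dataset.labels == cls)
        rng.shuffle(rows)
        n_te = max(1, int(round(test_frac * len(rows))))
        te_idx.extend(rows[:n_te])
        tr_idx.extend(rows[n_te:])
    tr = np.sort(np.array(tr_idx))
    te = np.sort(np.array(te_idx))
    return (
        FingerprintDataset(dataset.bits[tr], dataset.labels[tr]),
        FingerprintDataset(dataset.bits[te], dataset.labels[te]),
    )
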