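"""Single-cell MLP classification with sample-level majority calling.

The classifier is a one-hidden-layer perceptron (tanh hidden units, a
single logistic output) trained by maximizing the Bernoulli likelihood
(equivalently minimizing cross-entropy) with Moller's scaled conjugate
gradient (SCG) -- a Hessian-free second-order method that needs no
user-tuned learning rate.  A plain gradient-descent optimizer is kept as a
cross-check that results do not depend on the optimizer.

Protocol: the cell table is split 50/25/25 into training, test and
validation sets, stratified by class.  Model structure (feature subset and
hidden-unit count) is chosen by the average test-set accuracy over repeated
train/test repartitions of the non-validation pool; the winner is refit on
train+test and evaluated exactly once on the untouched validation set.

Sample-level calling emulates assaying a biopsy: draw paired random samples
of ``sample_size`` validation cells from each class, compute the fraction P
predicted class 1, and call the sample class 1 iff P > threshold (0.6 by
default, strictly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


@dataclass
class MLPSpec:
    features: tuple[str, ...]
    hidden_units: int = 5
    max_iter: int = 300
    tol: float = 1e-8
    seed: int = 0
    optimizer: str = "scg"  # or "gd" (cross-check fallback)
    restarts: int = 3       # seeded re-inits; best final loss kept

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if not self.features:
            raise ValueError("feature subset must be non-empty")


@dataclass
class DataPartition:
    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray
    fractions: tuple[float, float, float]
    seed: int


@dataclass
class SampleClassificationReport:
    n_sample_pairs: int
    sample_size: int
    threshold: float
    tp: int
    tn: int
    fp: int
    fn: int
    seed: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def fnr(self) -> float:
        return self.fn / (self.fn + self.tp)

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    def as_dict(self) -> dict:
        d = asdict(self)
        d.update(accuracy=self.accuracy, fnr=self.fnr, tpr=self.tpr)
        return d


# ---------------------------------------------------------------------------
# network


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLP:
    """One-hidden-layer perceptron: tanh hidden layer, logistic output,
    cross-entropy objective."""

    def __init__(self, n_inputs: int, hidden_units: int, seed: int = 0):
        self.n_inputs = n_inputs
        self.hidden = hidden_units
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(n_inputs + 1)
        self._shapes = [
            (n_inputs, hidden_units), (hidden_units,), (hidden_units,), ()
        ]
        self.w = rng.uniform(
            -scale, scale, size=n_inputs * hidden_units + 2 * hidden_units + 1
        )

    def _unpack(self, w):
        d, h = self.n_inputs, self.hidden
        W1 = w[: d * h].reshape(d, h)
        b1 = w[d * h: d * h + h]
        w2 = w[d * h + h: d * h + 2 * h]
        b2 = w[-1]
        return W1, b1, w2, b2

    def forward(self, X: np.ndarray, w=None) -> np.ndarray:
        W1, b1, w2, b2 = self._unpack(self.w if w is None else w)
        z = np.tanh(X @ W1 + b1)
        return _sigmoid(z @ w2 + b2)

    def loss_grad(self, w, X, y):
        W1, b1, w2, b2 = self._unpack(w)
        z = np.tanh(X @ W1 + b1)
        p = _sigmoid(z @ w2 + b2)
        eps = 1e-12
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        n = len(y)
        delta_out = (p - y) / n                      # d loss / d (output pre-act)
        g_w2 = z.T @ delta_out
        g_b2 = delta_out.sum()
        delta_h = np.outer(delta_out, w2) * (1 - z**2)
        g_W1 = X.T @ delta_h
        g_b1 = delta_h.sum(axis=0)
        grad = np.concatenate([g_W1.ravel(), g_b1, g_w2, [g_b2]])
        if not np.isfinite(grad).all():
            raise FloatingPointError("non-finite gradient during training")
        return loss, grad


def scg_minimize(fun, w0: np.ndarray, max_iter: int = 300, tol: float = 1e-8):
    """Moller's scaled conjugate gradient (1993).

    ``fun(w) -> (loss, grad)``.  Returns (w, losses at accepted steps).
    The objective is non-increasing across accepted steps by construction.
    """
    sigma0 = 1e-4
    lam, lam_bar = 1e-6, 0.0
    w = w0.copy()
    f, g = fun(w)
    r = -g
    p = r.copy()
    success = True
    losses = [f]
    n = len(w)
    k = 0
    for _ in range(max_iter):
        k += 1
        p2 = p @ p
        if p2 < 1e-300:
            break
        pnorm = np.sqrt(p2)
        if success:
            sigma = sigma0 / pnorm
            _, g_sigma = fun(w + sigma * p)
            s = (g_sigma - g) / sigma
            delta = p @ s
        delta += (lam - lam_bar) * p2
        if delta <= 0:               # make Hessian surrogate positive definite
            lam_bar = 2.0 * (lam - delta / p2)
            delta = -delta + lam * p2
            lam = lam_bar
        mu = p @ r
        alpha = mu / delta
        f_new, g_new = fun(w + alpha * p)
        Delta = 2.0 * delta * (f - f_new) / mu**2    # comparison parameter
        if Delta >= 0:               # accept the step
            w = w + alpha * p
            f_prev = f
            f, g = f_new, g_new
            r_new = -g
            lam_bar = 0.0
            success = True
            if k % n == 0:
                p = r_new.copy()     # restart along steepest descent
            else:
                beta = (r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if Delta >= 0.75:
                lam = max(lam / 4.0, 1e-15)
            losses.append(f)
            if abs(f_prev - f) < tol:
                break
        else:
            lam_bar = lam
            success = False
        if Delta < 0.25:
            lam = min(lam + delta * (1 - Delta) / (p @ p), 1e100)
    return w, losses


def gd_minimize(fun, w0: np.ndarray, max_iter: int = 2000, lr: float = 0.5,
                tol: float = 1e-10):
    """Plain gradient descent with backtracking; optimizer cross-check."""
    w = w0.copy()
    f, g = fun(w)
    losses = [f]
    step = lr
    for _ in range(max_iter):
        w_new = w - step * g
        f_new, g_new = fun(w_new)
        if f_new <= f:
            if f - f_new < tol:
                w, f = w_new, f_new
                losses.append(f)
                break
            w, f, g = w_new, f_new, g_new
            losses.append(f)
            step *= 1.05
        else:
            step *= 0.5
            if step < 1e-12:
                break
    return w, losses


@dataclass
class TrainedModel:
    """A fitted MLP plus the z-scoring statistics of its training data."""

    spec: MLPSpec
    net: MLP
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    losses: list[float] = field(default_factory=list)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_sd

    def predict_proba(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = self._features(X)
        p1 = self.net.forward(self._standardize(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def _features(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.spec.features if f not in X.columns]
            if missing:
                raise KeyError(f"missing features: {missing}")
            return X[list(self.spec.features)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.spec.features):
            raise ValueError("feature count mismatch")
        return X

    def save(self, path) -> None:
        payload = {
            "spec": {**asdict(self.spec), "features": list(self.spec.features)},
            "weights": self.net.w.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            payload = json.load(fh)
        spec_d = payload["spec"]
        spec_d["features"] = tuple(spec_d["features"])
        spec = MLPSpec(**spec_d)
        net = MLP(len(spec.features), spec.hidden_units, seed=spec.seed)
        net.w = np.array(payload["weights"])
        return cls(
            spec=spec, net=net,
            feature_mean=np.array(payload["feature_mean"]),
            feature_sd=np.array(payload["feature_sd"]),
        )


def train_scg(X: np.ndarray, y: np.ndarray, spec: MLPSpec) -> TrainedModel:
    """Fit the MLP; features are z-scored on the training statistics."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    minimize = scg_minimize if spec.optimizer == "scg" else gd_minimize
    best: tuple[float, MLP, list[float]] | None = None
    # tiny tanh networks have symmetric local minima (XOR-style plateaus at
    # ln(2)/2); a few seeded re-inits make training reliable
    for attempt in range(max(1, spec.restarts)):
        net = MLP(X.shape[1], spec.hidden_units,
                  seed=(spec.seed * 7919 + attempt) % 2**31)
        fun = lambda w: net.loss_grad(w, Z, y)  # noqa: E731
        w, losses = minimize(fun, net.w, max_iter=spec.max_iter, tol=spec.tol)
        net.w = w
        if best is None or losses[-1] < best[0]:
            best = (losses[-1], net, losses)
    _, net, losses = best
    return TrainedModel(spec=spec, net=net, feature_mean=mean, feature_sd=sd,
                        losses=losses)


# ---------------------------------------------------------------------------
# protocol


def partition_data(table: pd.DataFrame, class_col: str,
                   fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
                   seed: int = 0) -> DataPartition:
    """Stratified train/test/validation split (fractions of each class)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    train, test, val = [], [], []
    for cls, group in table.groupby(class_col, sort=True):
        idx = group.index.to_numpy()
        if len(idx) < 8:
            raise ValueError(f"class {cls!r} has < 8 cells")
        idx = rng.permutation(idx)
        n_train = int(round(fractions[0] * len(idx)))
        n_test = int(round(fractions[1] * len(idx)))
        train.extend(idx[:n_train])
        test.extend(idx[n_train:n_train + n_test])
        val.extend(idx[n_train + n_test:])
    return DataPartition(
        train=np.array(sorted(train)), test=np.array(sorted(test)),
        validation=np.array(sorted(val)), fractions=fractions, seed=seed,
    )


def _xy(table: pd.DataFrame, idx, features, class_col, positive_class):
    sub = table.loc[idx]
    X = sub[list(features)].to_numpy(dtype=float)
    y = (sub[class_col] == positive_class).to_numpy(dtype=float)
    return X, y


def select_model(candidates: list[MLPSpec], table: pd.DataFrame,
                 class_col: str, positive_class: str,
                 partition: DataPartition, n_repartitions: int = 5,
                 seed: int = 0) -> tuple[MLPSpec, pd.DataFrame]:
    """Choose the spec with the best average test accuracy over repeated
    train/test repartitions of the non-validation pool.

    The validation rows are never touched.  Ties break toward fewer hidden
    units, then fewer features.
    """
    if not candidates:
        raise ValueError("need >= 1 candidate spec")
    pool = table.loc[np.concatenate([partition.train, partition.test])]
    train_frac = partition.fractions[0] / (partition.fractions[0]
                                           + partition.fractions[1])
    rows = []
    for ci, spec in enumerate(candidates):
        accs = []
        for rep in range(n_repartitions):
            rep_seed = (seed * 1009 + rep) % 2**31
            rng = np.random.default_rng(rep_seed)
            tr_idx, te_idx = [], []
            for _, group in pool.groupby(class_col, sort=True):
                idx = rng.permutation(group.index.to_numpy())
                n_tr = int(round(train_frac * len(idx)))
                tr_idx.extend(idx[:n_tr])
                te_idx.extend(idx[n_tr:])
            Xtr, ytr = _xy(pool, tr_idx, spec.features, class_col, positive_class)
            Xte, yte = _xy(pool, te_idx, spec.features, class_col, positive_class)
            model = train_scg(Xtr, ytr, spec)
            accs.append(float(np.mean(model.predict(Xte) == yte)))
        rows.append({
            "candidate": ci, "hidden_units": spec.hidden_units,
            "n_features": len(spec.features),
            "mean_test_accuracy": float(np.mean(accs)),
        })
    scores = pd.DataFrame(rows)
    best = scores.sort_values(
        by=["mean_test_accuracy", "hidden_units", "n_features"],
        ascending=[False, True, True], kind="stable",
    ).iloc[0]
    return candidates[int(best["candidate"])], scores


def final_fit_and_validate(spec: MLPSpec, table: pd.DataFrame, class_col: str,
                           positive_class: str, partition: DataPartition
                           ) -> tuple[TrainedModel, float]:
    """Refit on train+test, evaluate once on the untouched validation set."""
    fit_idx = np.concatenate([partition.train, partition.test])
    Xf, yf = _xy(table, fit_idx, spec.features, class_col, positive_class)
    model = train_scg(Xf, yf, spec)
    Xv, yv = _xy(table, partition.validation, spec.features, class_col,
                 positive_class)
    accuracy = float(np.mean(model.predict(Xv) == yv))
    return model, accuracy


def classify_samples(model, validation: pd.DataFrame, class_col: str,
                     positive_class: str, n_pairs: int = 100,
                     sample_size: int = 10, threshold: float = 0.6,
                     seed: int = 0) -> SampleClassificationReport:
    """Paired-sample majority calling on the validation pool.

    ``model`` needs only a ``predict`` method over the feature columns, so a
    stub predictor can stand in for simulation studies.  Per pair, one
    sample of ``sample_size`` cells is drawn from each class without
    replacement within the sample (independently across pairs); the sample
    is called class 1 iff the predicted class-1 fraction P exceeds the
    threshold strictly.
    """
    rng = np.random.default_rng(seed)
    pos_pool = validation.loc[validation[class_col] == positive_class]
    neg_pool = validation.loc[validation[class_col] != positive_class]
    if len(pos_pool) < sample_size or len(neg_pool) < sample_size:
        raise ValueError("validation pool smaller than sample_size")
    tp = tn = fp = fn = 0
    for _ in range(n_pairs):
        for pool, is_positive in ((pos_pool, True), (neg_pool, False)):
            take = pool.iloc[rng.choice(len(pool), sample_size, replace=False)]
            pred = model.predict(take)
            p_frac = float(np.mean(pred == 1))
            called_positive = p_frac > threshold
            if is_positive and called_positive:
                tp += 1
            elif is_positive:
                fn += 1
            elif called_positive:
                fp += 1
            else:
                tn += 1
    return SampleClassificationReport(
        n_sample_pairs=n_pairs, sample_size=sample_size, threshold=threshold,
        tp=tp, tn=tn, fp=fp, fn=fn, seed=seed,
    )


def threshold_sweep(model, validation: pd.DataFrame, class_col: str,
                    positive_class: str, thresholds=(0.5, 0.6, 0.7, 0.8, 0.9),
                    n_pairs: int = 100, sample_size: int = 10,
                    seed: int = 0) -> pd.DataFrame:
    """classify_samples rerun per threshold on the same seeded samples."""
    rows = []
    for thr in thresholds:
        rep = classify_samples(model, validation, class_col, positive_class,
                               n_pairs=n_pairs, sample_size=sample_size,
                               threshold=thr, seed=seed)
        rows.append({"threshold": thr, "accuracy": rep.accuracy,
                     "fnr": rep.fnr, "tpr": rep.tpr,
                     "call_rate": (rep.tp + rep.fp) / (2 * n_pairs)})
    return pd.DataFrame(rows)


def candidate_specs(features, hidden_units=(2, 5, 10),
                    seed: int = 0) -> list[MLPSpec]:
    """All-features candidates, one per hidden-layer width."""
    features = tuple(features)
    return [MLPSpec(features=features, hidden_units=h, seed=seed)
            for h in hidden_units]


def greedy_forward_selection(features, table: pd.DataFrame, class_col: str,
                             positive_class: str, partition: DataPartition,
                             hidden_units: int = 5, n_repartitions: int = 3,
                             max_features: int | None = None,
                             seed: int = 0) -> MLPSpec:
    """Greedy forward search over the descriptor roster.

    Starting from the empty set, repeatedly add the feature whose addition
    maximizes the average test accuracy (select_model machinery, validation
    untouched); stop when no addition improves or ``max_features`` reached.
    Exhaustive subset search over 29 descriptors is intractable; greedy is
    the standard surrogate.
    """
    remaining = list(features)
    chosen: list[str] = []
    best_score = -np.inf
    limit = max_features or len(remaining)
    while remaining and len(chosen) < limit:
        cands = [MLPSpec(features=tuple(chosen + [f]), hidden_units=hidden_units,
                         seed=seed) for f in remaining]
        spec, scores = select_model(cands, table, class_col, positive_class,
                                    partition, n_repartitions=n_repartitions,
                                    seed=seed)
        score = scores["mean_test_accuracy"].max()
        if score <= best_score:
            break
        best_score = score
        new_feature = spec.features[-1]
        chosen.append(new_feature)
        remaining.remove(new_feature)
    if not chosen:
        chosen = [remaining[0]]
    return MLPSpec(features=tuple(chosen), hidden_units=hidden_units, seed=seed)
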