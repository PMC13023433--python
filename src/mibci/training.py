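"""Supervised training, evaluation protocols, and comparison statistics.

Training uses decoupled weight decay (AdamW), linear learning-rate warm-up
followed by plateau decay, gradient-norm clipping, and early stopping on
validation loss.  Three protocols mirror standard BCI evaluation practice:
within-subject (stratified split per subject), leave-one-subject-out
(LOSO), and LOSO followed by subject-specific fine-tuning on a few labeled
calibration trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as scistats

from . import _autodiff as ad
from ._seeds import derive_seed, rng_for
from .model import CBTNet, ModelConfig, cross_entropy
from .preprocessing import TrialSet

__all__ = [
    "TrainConfig",
    "Metrics",
    "ProtocolResult",
    "PlateauState",
    "AdamW",
    "lr_schedule",
    "train_supervised",
    "evaluate",
    "stratified_split",
    "within_subject_protocol",
    "loso_protocol",
    "finetune_protocol",
    "audit_disjoint",
    "paired_ttest",
    "wilcoxon_signed_rank",
    "cohens_d",
]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adamw"
    lr: float = 3e-4
    weight_decay: float = 1e-2
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    warmup_epochs: int = 10
    plateau_decay: float = 0.5
    grad_clip_norm: float = 1.0
    restore_best: bool = True  # return best-validation checkpoint vs final
    seed: int = 0

    def __post_init__(self):
        if min(self.lr, self.weight_decay, self.batch_size, self.max_epochs,
               self.early_stop_patience, self.warmup_epochs, self.plateau_decay,
               self.grad_clip_norm) <= 0:
            raise ValueError("all training hyperparameters must be positive")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


def desk_scale_train_config(**overrides) -> TrainConfig:
    """Training regimen matched to desk-scale runs: the small model and
    small trial counts need a larger step size, a short warm-up, and
    smaller batches than the full-scale regimen."""
    base = dict(lr=2e-3, warmup_epochs=3, batch_size=16, max_epochs=30,
                early_stop_patience=10)
    base.update(overrides)
    return TrainConfig(**base)


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    macro_f1: float
    confusion: np.ndarray

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int) -> "Metrics":
        from sklearn.metrics import accuracy_score, confusion_matrix, f1_score

        labels = np.arange(n_classes)
        return cls(
            accuracy=float(accuracy_score(y_true, y_pred)),
            macro_f1=float(
                f1_score(y_true, y_pred, labels=labels, average="macro",
                         zero_division=0)
            ),
            confusion=confusion_matrix(y_true, y_pred, labels=labels),
        )


@dataclass
class ProtocolResult:
    """Per-unit metric records plus aggregate summaries."""

    protocol: str
    records: list  # dicts: subject, run, metrics (+ protocol-specific keys)

    def accuracies(self) -> np.ndarray:
        return np.array([r["metrics"].accuracy for r in self.records])

    def macro_f1s(self) -> np.ndarray:
        return np.array([r["metrics"].macro_f1 for r in self.records])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies().mean())

    @property
    def sd_accuracy(self) -> float:
        accs = self.accuracies()
        return float(accs.std(ddof=1)) if len(accs) > 1 else 0.0

    def subject_accuracies(self) -> dict:
        """Mean accuracy per subject across runs."""
        out: dict = {}
        for r in self.records:
            out.setdefault(r["subject"], []).append(r["metrics"].accuracy)
        return {s: float(np.mean(v)) for s, v in out.items()}

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.records:
            row = {k: v for k, v in r.items() if k != "metrics"}
            row["protocol"] = self.protocol
            row["accuracy"] = r["metrics"].accuracy
            row["macro_f1"] = r["metrics"].macro_f1
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class PlateauState:
    """Tracks validation loss and halves the LR factor on plateau."""

    def __init__(self, patience: int, decay: float):
        self.patience = max(1, patience)
        self.decay = decay
        self.factor = 1.0
        self.best = np.inf
        self.bad = 0

    def update(self, val_loss: float) -> None:
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.bad = 0
        else:
            self.bad += 1
            if self.bad >= self.patience:
                self.factor *= self.decay
                self.bad = 0


def lr_schedule(epoch: int, cfg: TrainConfig, plateau_state: PlateauState | None = None):
    """Linear warm-up to ``cfg.lr`` then constant, scaled by plateau decay."""
    if epoch < 1:
        raise ValueError("epochs count from 1")
    factor = plateau_state.factor if plateau_state is not None else 1.0
    if epoch <= cfg.warmup_epochs:
        return cfg.lr * epoch / cfg.warmup_epochs * factor
    return cfg.lr * factor


class AdamW:
    """Adam with decoupled weight decay on matrix-shaped parameters.

    Bias vectors and normalization scales/shifts (1-D parameters) are
    exempt from decay, the usual convention.
    """

    def __init__(self, params: dict, weight_decay: float = 1e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for k, p in self.params.items():
            g = grads[k].data if isinstance(grads[k], ad.Tensor) else grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
            if p.data.ndim >= 2 and self.weight_decay > 0:
                p.data -= lr * self.weight_decay * p.data


def clip_gradients(grads: dict, max_norm: float) -> float:
    """Scale gradients in place so the global L2 norm is at most max_norm."""
    total = np.sqrt(sum(float((g.data**2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g.data *= scale
    return total


# ---------------------------------------------------------------------------
# supervised training
# ---------------------------------------------------------------------------

def _mean_loss(model: CBTNet, ts: TrialSet, batch_size: int) -> float:
    losses, weights = [], []
    with ad.no_grad():
        for lo in range(0, len(ts), batch_size):
            X = ts.trials[lo : lo + batch_size]
            y = ts.labels[lo : lo + batch_size]
            logits = model.logits(X)
            losses.append(cross_entropy(logits, y).item())
            weights.append(len(y))
    return float(np.average(losses, weights=weights))


def train_supervised(model: CBTNet, train: TrialSet, val: TrialSet,
                     cfg: TrainConfig | None = None):
    """Cross-entropy training with the standard regimen.

    Returns ``(model, history)``; the model carries the parameters of the
    best-validation epoch.  ``history`` has one entry per epoch run with
    train/val loss and the learning rate used.
    """
    cfg = cfg or TrainConfig()
    if len(train) == 0 or len(val) == 0:
        raise ValueError("empty train or validation split")
    opt = AdamW(model.params, weight_decay=cfg.weight_decay)
    plateau = PlateauState(cfg.early_stop_patience // 2, cfg.plateau_decay)
    rng = rng_for(cfg.seed, "train")
    drop_rng = rng_for(cfg.seed, "dropout")

    best_val = np.inf
    best_params = {k: v.data.copy() for k, v in model.params.items()}
    best_bn = {k: {kk: (vv.copy() if isinstance(vv, np.ndarray) else vv)
                   for kk, vv in st.items()} for k, st in model.bn_state.items()}
    bad_epochs = 0
    history = []

    for epoch in range(1, cfg.max_epochs + 1):
        lr = lr_schedule(epoch, cfg, plateau)
        order = rng.permutation(len(train))
        epoch_losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            X = train.trials[idx]
            y = train.labels[idx]
            logits = model.logits(X, train=True, rng=drop_rng)
            loss = cross_entropy(logits, y)
            grads = ad.grad(loss, list(model.params.values()))
            gdict = dict(zip(model.params.keys(), grads))
            clip_gradients(gdict, cfg.grad_clip_norm)
            opt.step(gdict, lr)
            epoch_losses.append(loss.item())

        # exact full-data normalization statistics: EMA running stats lag
        # badly at small batch counts, corrupting eval-mode validation
        refresh_bn_stats(model, train, cfg.batch_size)
        val_loss = _mean_loss(model, val, cfg.batch_size)
        plateau.update(val_loss)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
             "val_loss": val_loss, "lr": lr}
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = {k: v.data.copy() for k, v in model.params.items()}
            best_bn = {k: {kk: (vv.copy() if isinstance(vv, np.ndarray) else vv)
                           for kk, vv in st.items()}
                       for k, st in model.bn_state.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.early_stop_patience:
                break

    if cfg.restore_best:
        for k, v in best_params.items():
            model.params[k].data = v
        model.bn_state = best_bn
    return model, history


def refresh_bn_stats(model: CBTNet, data: TrialSet, batch_size: int = 64) -> None:
    """Re-estimate batch-norm running statistics under current parameters.

    Used after optimization phases that move parameters without updating
    the normalization statistics (e.g. episodic meta-updates), so that
    eval-mode forward passes see statistics consistent with the weights.
    """
    saved_momentum = {k: st["momentum"] for k, st in model.bn_state.items()}
    for st in model.bn_state.values():
        st["initialized"] = False
    with ad.no_grad():
        for i, lo in enumerate(range(0, len(data), batch_size)):
            # harmonic momentum turns the EMA into an exact running average
            for st in model.bn_state.values():
                st["momentum"] = 1.0 / (i + 1)
            X = data.trials[lo : lo + batch_size]
            model.encode_spatial_spectral(X, train=True, bn_mode="batch")
    for k, st in model.bn_state.items():
        st["momentum"] = saved_momentum[k]


def evaluate(model: CBTNet, test: TrialSet, params=None) -> Metrics:
    """Accuracy, macro-F1 and confusion matrix on a held-out set."""
    if len(test) == 0:
        raise ValueError("empty test set")
    preds = model.predict(test.trials, params)
    return Metrics.from_predictions(test.labels, preds, len(test.classes))


# ---------------------------------------------------------------------------
# splits and protocols
# ---------------------------------------------------------------------------

def stratified_split(ts: TrialSet, fraction: float, seed: int):
    """Index split with per-class proportions preserved.

    Returns ``(first_idx, second_idx)`` where the first part holds
    ``fraction`` of each class.
    """
    rng = rng_for(seed, "split")
    first, second = [], []
    for c in np.unique(ts.labels):
        idx = np.flatnonzero(ts.labels == c)
        perm = rng.permutation(len(idx))
        cut = int(round(fraction * len(idx)))
        first.extend(idx[perm[:cut]])
        second.extend(idx[perm[cut:]])
    return np.sort(first), np.sort(second)


def audit_disjoint(*index_sets) -> bool:
    """Certify that index collections are pairwise disjoint."""
    sets = [set(np.asarray(s).ravel().tolist()) for s in index_sets]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if sets[i] & sets[j]:
                raise ValueError(f"index sets {i} and {j} overlap")
    return True


def _run_seeds(master: int, n_runs: int):
    return [derive_seed(master, "run", i) for i in range(n_runs)]


def within_subject_protocol(data: TrialSet, cfg: TrainConfig | None = None,
                            model_config: ModelConfig | None = None,
                            n_runs: int = 5, split: float = 0.5,
                            val_fraction: float = 0.2, seed: int = 0) -> ProtocolResult:
    """Train and test per subject on disjoint stratified halves."""
    cfg = cfg or TrainConfig()
    model_config = model_config or ModelConfig()
    records = []
    for run, run_seed in enumerate(_run_seeds(seed, n_runs)):
        for subject in data.subjects:
            sub = data.for_subject(subject)
            if min(np.bincount(sub.labels, minlength=len(sub.classes))) < 2:
                raise ValueError(f"subject {subject} has < 2 trials in a class")
            tr_idx, te_idx = stratified_split(
                sub, split, derive_seed(run_seed, "ws", subject)
            )
            tr2_idx, val_idx = stratified_split(
                sub.subset(tr_idx), 1 - val_fraction,
                derive_seed(run_seed, "ws-val", subject),
            )
            audit_disjoint(tr_idx[tr2_idx], tr_idx[val_idx], te_idx)
            model = CBTNet(model_config, seed=derive_seed(run_seed, "init", subject))
            model, history = train_supervised(
                model, sub.subset(tr_idx[tr2_idx]), sub.subset(tr_idx[val_idx]),
                replace(cfg, seed=derive_seed(run_seed, "fit", subject)),
            )
            metrics = evaluate(model, sub.subset(te_idx))
            records.append({"subject": int(subject), "run": run,
                            "metrics": metrics, "epochs": len(history)})
    return ProtocolResult("within_subject", records)


def loso_protocol(data: TrialSet, cfg: TrainConfig | None = None,
                  model_config: ModelConfig | None = None,
                  n_runs: int = 1, val_fraction: float = 0.2,
                  seed: int = 0) -> ProtocolResult:
    """Leave-one-subject-out: the held-out subject never touches training."""
    cfg = cfg or TrainConfig()
    model_config = model_config or ModelConfig()
    subjects = data.subjects
    if len(subjects) < 3:
        raise ValueError("LOSO needs at least 3 subjects")
    records = []
    for run, run_seed in enumerate(_run_seeds(seed, n_runs)):
        for subject in subjects:
            test_idx = np.flatnonzero(data.subject_ids == subject)
            rest_idx = np.flatnonzero(data.subject_ids != subject)
            rest = data.subset(rest_idx)
            tr_idx, val_idx = stratified_split(
                rest, 1 - val_fraction, derive_seed(run_seed, "loso", subject)
            )
            audit_disjoint(rest_idx[tr_idx], rest_idx[val_idx], test_idx)
            model = CBTNet(model_config, seed=derive_seed(run_seed, "init", subject))
            model, history = train_supervised(
                model, rest.subset(tr_idx), rest.subset(val_idx),
                replace(cfg, seed=derive_seed(run_seed, "fit", subject)),
            )
            metrics = evaluate(model, data.subset(test_idx))
            records.append({"subject": int(subject), "run": run,
                            "metrics": metrics, "epochs": len(history)})
    return ProtocolResult("loso", records)


def finetune_protocol(data: TrialSet, cfg: TrainConfig | None = None,
                      model_config: ModelConfig | None = None,
                      shots_per_class: int = 10, adapt_epochs: int = 20,
                      adapt_lr: float = 1e-4, n_runs: int = 1,
                      val_fraction: float = 0.2, seed: int = 0) -> ProtocolResult:
    """LOSO pretraining plus fine-tuning on a small calibration subset.

    With ``shots_per_class == 0`` this degenerates to plain LOSO.
    """
    cfg = cfg or TrainConfig()
    model_config = model_config or ModelConfig()
    subjects = data.subjects
    if len(subjects) < 3:
        raise ValueError("needs at least 3 subjects")
    records = []
    for run, run_seed in enumerate(_run_seeds(seed, n_runs)):
        for subject in subjects:
            held = data.for_subject(subject)
            rest = data.subset(np.flatnonzero(data.subject_ids != subject))
            tr_idx, val_idx = stratified_split(
                rest, 1 - val_fraction, derive_seed(run_seed, "ft", subject)
            )
            model = CBTNet(model_config, seed=derive_seed(run_seed, "init", subject))
            model, _ = train_supervised(
                model, rest.subset(tr_idx), rest.subset(val_idx),
                replace(cfg, seed=derive_seed(run_seed, "fit", subject)),
            )
            if shots_per_class == 0:
                metrics = evaluate(model, held)
                records.append({"subject": int(subject), "run": run,
                                "metrics": metrics, "pre_metrics": metrics,
                                "shots": 0})
                continue
            counts = np.bincount(held.labels, minlength=len(held.classes))
            if counts.min() <= shots_per_class:
                raise ValueError(
                    f"subject {subject}: needs > {shots_per_class} trials per class"
                )
            sup_idx, test_idx = [], []
            rng = rng_for(run_seed, "ft-split", subject)
            for c in range(len(held.classes)):
                cls = np.flatnonzero(held.labels == c)
                perm = rng.permutation(len(cls))
                sup_idx.extend(cls[perm[:shots_per_class]])
                test_idx.extend(cls[perm[shots_per_class:]])
            audit_disjoint(sup_idx, test_idx)
            support, test = held.subset(np.sort(sup_idx)), held.subset(np.sort(test_idx))
            pre = evaluate(model, test)
            opt = AdamW(model.params, weight_decay=cfg.weight_decay)
            drop_rng = rng_for(run_seed, "ft-dropout", subject)
            for _ in range(adapt_epochs):
                logits = model.logits(support.trials, train=True, rng=drop_rng)
                loss = cross_entropy(logits, support.labels)
                grads = dict(zip(model.params.keys(),
                                 ad.grad(loss, list(model.params.values()))))
                clip_gradients(grads, cfg.grad_clip_norm)
                opt.step(grads, adapt_lr)
            post = evaluate(model, test)
            records.append({"subject": int(subject), "run": run, "metrics": post,
                            "pre_metrics": pre, "shots": shots_per_class})
    return ProtocolResult("finetune", records)


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------

def paired_ttest(a, b):
    """Two-sided paired t-test on matched per-subject scores."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = a - b
    if np.allclose(d, 0):
        return 0.0, 1.0
    res = scistats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(a, b):
    """Two-sided Wilcoxon signed-rank test; W = min(W+, W−).

    Zero differences are dropped (standard convention); an all-zero
    difference vector is an error.  Exact p-value for n <= 12, normal
    approximation above.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        raise ValueError("all differences are zero; Wilcoxon test undefined")
    method = "exact" if len(nz) <= 12 else "approx"
    res = scistats.wilcoxon(a, b, zero_method="wilcox",
                            alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cohens_d(a, b) -> float:
    """Cohen's d with pooled standard deviation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 samples per group")
    sa2, sb2 = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)
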