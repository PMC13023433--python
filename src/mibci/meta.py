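"""MAML-style subject adaptation.

Each subject is a task with a small labeled *support* set and a held-out
*query* set.  The inner loop takes a few full-batch gradient steps on the
support loss from shared initialization θ, producing task parameters θ′;
the outer loop updates θ to minimize the query loss at θ′ summed over a
meta-batch of tasks.  The second-order variant (default) differentiates
through the inner steps; the first-order variant stops gradients at θ′.

The generic inner/outer operations work on any ``{name: Tensor}``
parameter dict and any differentiable loss function, which is what the
closed-form unit tests exercise; model-specific wrappers bind them to the
decoder and EEG trial sets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from . import _autodiff as ad
from ._seeds import derive_seed, rng_for
from .model import CBTNet, cross_entropy
from .preprocessing import TrialSet
from .training import (
    TrainConfig,
    clip_gradients,
    evaluate,
    refresh_bn_stats,
    train_supervised,
)

__all__ = [
    "MetaTask",
    "MetaConfig",
    "inner_adapt_generic",
    "meta_step_generic",
    "inner_adapt",
    "meta_step",
    "meta_train",
    "few_shot_evaluate",
]


@dataclass(frozen=True)
class MetaTask:
    """Support/query split for one subject."""

    support: TrialSet
    query: TrialSet
    subject_id: int
    support_indices: tuple = ()
    query_indices: tuple = ()

    def __post_init__(self):
        if len(self.support) == 0 or len(self.query) == 0:
            raise ValueError("support and query must be nonempty")
        if self.support_indices and self.query_indices:
            if set(self.support_indices) & set(self.query_indices):
                raise ValueError("support and query overlap")


@dataclass(frozen=True)
class MetaConfig:
    inner_lr: float = 0.01
    outer_lr: float = 0.001
    inner_steps_train: int = 5
    inner_steps_deploy: tuple = (5, 10, 20)
    meta_batch: int = 4
    warm_start_epochs: int = 20
    support_sizes: tuple = (5, 10, 15, 20)
    second_order: bool = True
    n_meta_steps: int = 30
    outer_optimizer: str = "sgd"  # "sgd" follows the plain meta-update rule

    def __post_init__(self):
        if self.inner_lr < 0 or self.outer_lr < 0:
            raise ValueError("learning rates must be nonnegative")
        if self.inner_steps_train < 0:
            raise ValueError("inner steps must be >= 0")


def desk_scale_meta_config(**overrides) -> MetaConfig:
    """Meta-learning knobs for desk-scale runs.

    The small decoder and small support sets need a larger inner step
    than the full-scale setting for five adaptation steps to matter.
    The outer rule is plain SGD on the clipped second-order
    meta-gradient: at this scale the first-order approximation
    systematically erodes the warm-started solution, and adaptive outer
    optimizers turn a saturated meta objective into parameter drift.
    """
    base = dict(inner_lr=0.05, outer_lr=0.02, inner_steps_train=5,
                meta_batch=4, warm_start_epochs=20, second_order=True,
                outer_optimizer="sgd", n_meta_steps=20)
    base.update(overrides)
    return MetaConfig(**base)


# ---------------------------------------------------------------------------
# generic MAML math (loss-function agnostic)
# ---------------------------------------------------------------------------

def inner_adapt_generic(loss_fn, params: dict, alpha: float, steps: int,
                        second_order: bool = True) -> dict:
    """``steps`` gradient steps on ``loss_fn`` from ``params``.

    The input dict is never mutated.  With ``second_order=True`` the
    returned parameters stay attached to the tape, so a later outer
    gradient differentiates through the inner trajectory; otherwise the
    inner gradients are treated as constants (first-order MAML).
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    adapted = dict(params)
    if steps == 0 or alpha == 0.0:
        return adapted
    with ad.enable_grad():  # inner steps need the tape even inside no_grad
        for _ in range(steps):
            loss = loss_fn(adapted)
            names = list(adapted.keys())
            grads = ad.grad(loss, [adapted[n] for n in names],
                            create_graph=second_order)
            adapted = {
                n: ad.add(adapted[n], ad.mul(g, -alpha))
                for n, g in zip(names, grads)
            }
    return adapted


def meta_gradient_generic(theta: dict, task_loss_fns, cfg: MetaConfig) -> dict:
    """Meta-gradient ∇θ Σᵢ Lᵢ(θᵢ′) over a meta-batch of tasks.

    ``task_loss_fns`` is a list of ``(support_loss_fn, query_loss_fn)``
    pairs.  θ is untouched.
    """
    names = list(theta.keys())
    total = None
    with ad.enable_grad():
        for support_loss, query_loss in task_loss_fns:
            adapted = inner_adapt_generic(
                support_loss, theta, cfg.inner_lr, cfg.inner_steps_train,
                second_order=cfg.second_order,
            )
            q = query_loss(adapted)
            total = q if total is None else ad.add(total, q)
        grads = ad.grad(total, [theta[n] for n in names])
    return dict(zip(names, grads))


def meta_step_generic(theta: dict, task_loss_fns, cfg: MetaConfig) -> dict:
    """One outer update: θ ← θ − β ∇θ Σᵢ Lᵢ(θᵢ′).  Returns a fresh dict."""
    grads = meta_gradient_generic(theta, task_loss_fns, cfg)
    return {
        n: ad.parameter(theta[n].data - cfg.outer_lr * grads[n].data)
        for n in theta
    }


# ---------------------------------------------------------------------------
# model-bound operations
# ---------------------------------------------------------------------------

def _support_loss_fn(model: CBTNet, ts: TrialSet):
    """Full-batch cross-entropy on a trial set, batch-norm in batch mode."""
    X, y = ts.trials, ts.labels

    def loss_fn(params):
        logits = model.logits(X, params, bn_mode="batch")
        return cross_entropy(logits, y)

    return loss_fn


def inner_adapt(model: CBTNet, theta: dict, support: TrialSet, alpha: float,
                steps: int, second_order: bool = False) -> dict:
    """Task-specific parameters after ``steps`` support gradient steps."""
    if steps > 0 and len(support) == 0:
        raise ValueError("empty support set with steps > 0")
    return inner_adapt_generic(
        _support_loss_fn(model, support), theta, alpha, steps, second_order
    )


def meta_step(model: CBTNet, theta: dict, tasks, cfg: MetaConfig) -> dict:
    """Outer update over a meta-batch of subject tasks."""
    if len(tasks) != cfg.meta_batch:
        raise ValueError(f"expected meta-batch of {cfg.meta_batch} tasks")
    pairs = [
        (_support_loss_fn(model, t.support), _support_loss_fn(model, t.query))
        for t in tasks
    ]
    return meta_step_generic(theta, pairs, cfg)


def meta_train(model: CBTNet, tasks, cfg: MetaConfig | None = None,
               train_cfg: TrainConfig | None = None,
               heldout_subjects=(), seed: int = 0, log_every: int = 5):
    """Warm-start supervised phase, then episodic meta-optimization.

    ``tasks`` are the meta-training subjects' support/query splits; any
    overlap with ``heldout_subjects`` is an error.  Returns
    ``(model, log)`` where the model holds the meta-trained
    initialization and the log carries per-episode query accuracies.
    """
    cfg = cfg or MetaConfig()
    train_cfg = train_cfg or TrainConfig()
    task_subjects = {t.subject_id for t in tasks}
    overlap = task_subjects & set(heldout_subjects)
    if overlap:
        raise ValueError(f"meta-training subjects overlap held-out set: {overlap}")

    # warm start: conventional supervised training on pooled task data
    pooled_trials = np.concatenate(
        [t.support.trials for t in tasks] + [t.query.trials for t in tasks]
    )
    pooled_labels = np.concatenate(
        [t.support.labels for t in tasks] + [t.query.labels for t in tasks]
    )
    pooled_subjects = np.concatenate(
        [np.full(len(t.support), t.subject_id) for t in tasks]
        + [np.full(len(t.query), t.subject_id) for t in tasks]
    )
    ref = tasks[0].support
    pooled = TrialSet(pooled_trials, pooled_labels, pooled_subjects,
                      rate=ref.rate, window=ref.window, classes=ref.classes)
    if cfg.warm_start_epochs > 0:
        from .training import stratified_split

        tr_idx, val_idx = stratified_split(pooled, 0.85, derive_seed(seed, "warm"))
        warm_cfg = dc_replace(
            train_cfg,
            max_epochs=cfg.warm_start_epochs,
            early_stop_patience=min(train_cfg.early_stop_patience,
                                    cfg.warm_start_epochs),
            seed=derive_seed(seed, "warm-fit"),
        )
        model, _ = train_supervised(model, pooled.subset(tr_idx),
                                    pooled.subset(val_idx), warm_cfg)

    # episodic phase (switch-over after the warm start); plain SGD on the
    # clipped meta-gradient is the default outer rule — an adaptive
    # optimizer renormalizes near-zero meta-gradients into a parameter
    # random walk once the meta objective saturates
    from .training import AdamW

    theta = model.params
    outer = AdamW(theta, weight_decay=0.0) if cfg.outer_optimizer == "adamw" else None
    rng = rng_for(seed, "episodes")
    log = []
    task_list = list(tasks)
    order = rng.permutation(len(task_list))
    cursor = 0
    for step in range(cfg.n_meta_steps):
        if cursor + cfg.meta_batch > len(task_list):
            order = rng.permutation(len(task_list))
            cursor = 0
        batch_ids = [order[(cursor + i) % len(task_list)]
                     for i in range(cfg.meta_batch)]
        cursor += cfg.meta_batch
        batch = [task_list[i] for i in batch_ids]
        pairs = [
            (_support_loss_fn(model, t.support), _support_loss_fn(model, t.query))
            for t in batch
        ]
        grads = meta_gradient_generic(theta, pairs, cfg)
        for g in grads.values():
            g.data /= cfg.meta_batch
        clip_gradients(grads, train_cfg.grad_clip_norm)
        if outer is not None:
            outer.step(grads, cfg.outer_lr)
        else:
            for name, g in grads.items():
                theta[name].data -= cfg.outer_lr * g.data
        if step % max(1, log_every) == 0 or step == cfg.n_meta_steps - 1:
            with ad.no_grad():
                pre, post = [], []
                for t in batch:
                    pre.append(evaluate(model, t.query, theta).accuracy)
                    adapted = inner_adapt(model, theta, t.support, cfg.inner_lr,
                                          cfg.inner_steps_train,
                                          second_order=False)
                    post.append(evaluate(model, t.query, adapted).accuracy)
            log.append({"step": step, "pre_query_acc": float(np.mean(pre)),
                        "post_query_acc": float(np.mean(post)),
                        "tasks": [int(task_list[i].subject_id)
                                  for i in batch_ids]})
    # normalization statistics must track the meta-updated weights
    refresh_bn_stats(model, pooled)
    return model, log


def few_shot_evaluate(model: CBTNet, task: MetaTask, steps: int = 5,
                      alpha: float = 0.01, theta: dict | None = None,
                      recalibrate_bn: bool = True):
    """Query metrics before and after inner-loop adaptation.

    With ``recalibrate_bn`` the batch-norm statistics are re-estimated on
    the support set for both evaluations (deployment-realistic: the
    calibration trials are available, and the inner loop itself adapts
    under support statistics). The model's stored statistics are restored
    afterwards.
    """
    import copy

    from .training import refresh_bn_stats

    theta = theta or model.params
    saved = copy.deepcopy(model.bn_state) if recalibrate_bn else None
    try:
        if recalibrate_bn:
            refresh_bn_stats(model, task.support)
        pre = evaluate(model, task.query, theta)
        if steps == 0:
            return pre, pre
        adapted = inner_adapt(model, theta, task.support, alpha, steps,
                              second_order=False)
        post = evaluate(model, task.query, adapted)
    finally:
        if saved is not None:
            model.bn_state = saved
    return pre, post
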