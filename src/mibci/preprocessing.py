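"""EEG signal conditioning: filtering, resampling, epoching, artifact
rejection, channel selection, and per-trial normalization.

All operations are pure — they return new objects and never mutate their
inputs — and each output carries a ``history`` provenance list.  Filtering
uses zero-phase (forward–backward) application, so the passband phase lag
is zero and the effective magnitude response is the square of the filter's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "ContinuousRecording",
    "TrialSet",
    "PreprocessConfig",
    "bandpass_filter",
    "notch_filter",
    "resample",
    "epoch_trials",
    "reject_amplitude",
    "reject_joint_probability",
    "zscore_trials",
    "select_channels",
    "read_edf",
    "save_trialset",
    "load_trialset",
]


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class ContinuousRecording:
    """Multi-channel continuous EEG with event markers."""

    signals: np.ndarray  # (channels, samples)
    rate: float
    channel_names: tuple
    events: tuple = ()  # ((sample_index, class_label), ...)
    history: tuple = ()

    def __post_init__(self):
        if self.rate <= 0:
            raise PreprocessError("rate must be positive")
        for idx, _ in self.events:
            if not 0 <= idx < self.signals.shape[1]:
                raise PreprocessError(f"event index {idx} out of bounds")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]


@dataclass(frozen=True)
class TrialSet:
    """Labeled epoched trials with subject identifiers.

    ``trials`` has shape (n_trials, channels, samples); ``labels`` are
    integer class codes indexing ``classes``.
    """

    trials: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    rate: float
    window: tuple = (0.0, 4.0)  # seconds relative to cue
    classes: tuple = ("left_hand", "right_hand", "feet", "tongue")
    channel_names: tuple = ()
    history: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "trials", np.asarray(self.trials))
        object.__setattr__(self, "labels", np.asarray(self.labels))
        object.__setattr__(self, "subject_ids", np.asarray(self.subject_ids))
        n = self.trials.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise PreprocessError("labels/subject_ids length mismatch")
        if n and (self.labels.min() < 0 or self.labels.max() >= len(self.classes)):
            raise PreprocessError("labels outside configured class set")

    def __len__(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)

    def subset(self, idx) -> "TrialSet":
        idx = np.asarray(idx)
        return replace(
            self,
            trials=self.trials[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
        )

    def for_subject(self, subject) -> "TrialSet":
        return self.subset(np.flatnonzero(self.subject_ids == subject))

    def with_history(self, entry) -> "TrialSet":
        return replace(self, history=self.history + (entry,))


@dataclass(frozen=True)
class PreprocessConfig:
    """Defaults of the signal-conditioning chain."""

    band: tuple = (4.0, 40.0)
    filter_order: int = 4
    zero_phase: bool = True
    notch_hz: float | None = 50.0
    notch_q: float = 30.0
    amp_threshold_uv: float = 100.0
    jointprob_sd: float = 3.0
    epoch_window_s: tuple = (0.0, 4.0)
    target_rate_hz: float = 250.0
    baseline: str = "auto"  # pre-cue mean when window starts < 0, else whole trial


def _check_band(band, rate):
    low, high = band
    if not 0 < low < high < rate / 2:
        raise PreprocessError(
            f"band {band} invalid for rate {rate} (Nyquist {rate / 2})"
        )


def bandpass_filter(
    rec: ContinuousRecording, cfg: PreprocessConfig | None = None
) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass, applied per channel."""
    cfg = cfg or PreprocessConfig()
    _check_band(cfg.band, rec.rate)
    sos = sps.butter(
        cfg.filter_order, cfg.band, btype="bandpass", fs=rec.rate, output="sos"
    )
    filt = sps.sosfiltfilt if cfg.zero_phase else sps.sosfilt
    out = filt(sos, rec.signals, axis=1)
    return replace(
        rec,
        signals=np.ascontiguousarray(out),
        history=rec.history + (f"bandpass {cfg.band} order {cfg.filter_order}",),
    )


def notch_filter(
    rec: ContinuousRecording, cfg: PreprocessConfig | None = None
) -> ContinuousRecording:
    """Zero-phase IIR notch at the mains frequency."""
    cfg = cfg or PreprocessConfig()
    if cfg.notch_hz is None:
        return rec
    if not 0 < cfg.notch_hz < rec.rate / 2:
        raise PreprocessError(f"notch {cfg.notch_hz} above Nyquist")
    b, a = sps.iirnotch(cfg.notch_hz, cfg.notch_q, fs=rec.rate)
    out = sps.filtfilt(b, a, rec.signals, axis=1)
    return replace(
        rec,
        signals=np.ascontiguousarray(out),
        history=rec.history + (f"notch {cfg.notch_hz} Hz",),
    )


def resample(rec: ContinuousRecording, target_rate: float) -> ContinuousRecording:
    """Polyphase resampling; event indices are rescaled to the new rate."""
    if target_rate <= 0:
        raise PreprocessError("target_rate must be positive")
    if target_rate == rec.rate:
        return rec
    from fractions import Fraction

    frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(rec.signals, up, down, axis=1)
    events = tuple(
        (int(round(idx * target_rate / rec.rate)), lab) for idx, lab in rec.events
    )
    events = tuple((min(i, out.shape[1] - 1), lab) for i, lab in events)
    return replace(
        rec,
        signals=out,
        rate=target_rate,
        events=events,
        history=rec.history + (f"resample {rec.rate} -> {target_rate} Hz",),
    )


def epoch_trials(
    rec: ContinuousRecording,
    events=None,
    window_s: tuple = (0.0, 4.0),
    subject_id=0,
    classes: tuple = ("left_hand", "right_hand", "feet", "tongue"),
    baseline: str = "auto",
) -> TrialSet:
    """Slice trials around cue events with baseline correction.

    The baseline subtracted per channel is the pre-cue mean when the
    window starts before the cue, otherwise the whole-trial mean.
    Out-of-bounds events are skipped with a warning.
    """
    events = rec.events if events is None else tuple(events)
    start_s, end_s = window_s
    n_samp = int(round((end_s - start_s) * rec.rate))
    pre_samp = max(0, int(round(-start_s * rec.rate)))
    trials, labels, skipped = [], [], 0
    for idx, label in events:
        lo = idx + int(round(start_s * rec.rate))
        hi = lo + n_samp
        if lo < 0 or hi > rec.signals.shape[1]:
            skipped += 1
            continue
        trial = rec.signals[:, lo:hi].copy()
        if pre_samp > 0:
            base = trial[:, :pre_samp].mean(axis=1, keepdims=True)
        else:
            base = trial.mean(axis=1, keepdims=True)
        trials.append(trial - base)
        labels.append(label)
    if skipped:
        warnings.warn(f"skipped {skipped} out-of-bounds event(s)", stacklevel=2)
    trials = np.stack(trials) if trials else np.empty((0, rec.n_channels, n_samp))
    labels = np.asarray(labels, dtype=int)
    return TrialSet(
        trials=trials,
        labels=labels,
        subject_ids=np.full(len(labels), subject_id),
        rate=rec.rate,
        window=window_s,
        classes=classes,
        channel_names=rec.channel_names,
        history=rec.history + (f"epoch {window_s}, skipped {skipped}",),
    )


def reject_amplitude(trials: TrialSet, threshold_uv: float | None = None):
    """Drop trials whose absolute amplitude strictly exceeds the threshold.

    Returns ``(kept_trialset, rejected_indices)``.
    """
    thr = PreprocessConfig().amp_threshold_uv if threshold_uv is None else threshold_uv
    if thr <= 0:
        raise PreprocessError("threshold must be positive")
    peak = np.abs(trials.trials).max(axis=(1, 2))
    rejected = np.flatnonzero(peak > thr)
    kept = trials.subset(np.flatnonzero(peak <= thr)).with_history(
        f"amplitude reject >{thr} uV: {len(rejected)}/{len(trials)}"
    )
    return kept, rejected


def joint_probability_statistic(trials: TrialSet, n_bins: int | None = None):
    """Per-trial improbability: −mean log empirical density of its samples.

    The density is a per-channel histogram over all trials pooled
    (Freedman–Diaconis bin rule, clamped to [10, 200] bins).
    """
    X = trials.trials  # (n, C, T)
    n, C, T = X.shape
    stats = np.zeros(n)
    for c in range(C):
        vals = X[:, c, :].ravel()
        if n_bins is None:
            q75, q25 = np.percentile(vals, [75, 25])
            iqr = q75 - q25
            width = 2 * iqr / (len(vals) ** (1 / 3)) if iqr > 0 else 0
            bins = (
                int(np.clip(np.ceil((vals.max() - vals.min()) / width), 10, 200))
                if width > 0
                else 50
            )
        else:
            bins = n_bins
        counts, edges = np.histogram(vals, bins=bins)
        probs = counts / counts.sum()
        idx = np.clip(np.searchsorted(edges, X[:, c, :], side="right") - 1, 0, bins - 1)
        logp = np.log(np.maximum(probs[idx], 1e-12))
        stats += -logp.mean(axis=1)
    return stats / C


def reject_joint_probability(trials: TrialSet, sd_limit: float | None = None):
    """Single-pass rejection of trials with improbable sample distributions.

    A trial is rejected when its joint-probability statistic exceeds
    ``mean + sd_limit * SD`` across trials.
    """
    sd_limit = PreprocessConfig().jointprob_sd if sd_limit is None else sd_limit
    if len(trials) < 5:
        raise PreprocessError("need at least 5 trials for joint-probability rejection")
    stats = joint_probability_statistic(trials)
    mu, sd = stats.mean(), stats.std(ddof=1)
    rejected = np.flatnonzero(stats > mu + sd_limit * sd) if np.isfinite(sd_limit) else np.array([], dtype=int)
    keep = np.setdiff1d(np.arange(len(trials)), rejected)
    kept = trials.subset(keep).with_history(
        f"jointprob reject >{sd_limit} SD: {len(rejected)}/{len(trials)}"
    )
    return kept, rejected


def zscore_trials(trials: TrialSet) -> TrialSet:
    """Per-trial, per-channel z-score normalization (idempotent)."""
    X = trials.trials
    mean = X.mean(axis=2, keepdims=True)
    sd = X.std(axis=2, keepdims=True)
    bad = np.argwhere(sd[:, :, 0] == 0)
    if len(bad):
        t, c = bad[0]
        raise PreprocessError(f"zero-variance channel {c} in trial {t}")
    return replace(trials, trials=(X - mean) / sd).with_history("zscore per trial/channel")


def select_channels(obj, names):
    """Channel subset (in the requested order) of a recording or trial set."""
    have = list(obj.channel_names)
    missing = [n for n in names if n not in have]
    if missing:
        raise PreprocessError(f"channels not present: {missing}")
    idx = [have.index(n) for n in names]
    if isinstance(obj, ContinuousRecording):
        return replace(
            obj,
            signals=obj.signals[idx],
            channel_names=tuple(names),
            history=obj.history + (f"select {len(idx)} channels",),
        )
    return replace(
        obj,
        trials=obj.trials[:, idx, :],
        channel_names=tuple(names),
        history=obj.history + (f"select {len(idx)} channels",),
    )


# ---------------------------------------------------------------------------
# I/O adapters
# ---------------------------------------------------------------------------

def read_edf(path, event_map=None) -> ContinuousRecording:
    """Read a continuous EDF recording (requires the optional mne extra)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    events = ()
    if event_map:
        ev, ev_id = mne.events_from_annotations(raw, verbose="error")
        events = tuple(
            (int(s), event_map[code])
            for s, _, code in ev
            if code in event_map
        )
    return ContinuousRecording(
        signals=raw.get_data(),
        rate=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        events=events,
        history=(f"edf {path}",),
    )


def save_trialset(ts: TrialSet, path) -> None:
    """Compressed array container with structured-text sidecar metadata."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(
        path,
        trials=ts.trials.astype(np.float32),
        labels=ts.labels,
        subject_ids=ts.subject_ids,
    )
    meta = {
        "rate": ts.rate,
        "window": list(ts.window),
        "classes": list(ts.classes),
        "channel_names": list(ts.channel_names),
        "history": list(ts.history),
    }
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1))


def load_trialset(path) -> TrialSet:
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        trials = data["trials"].astype(np.float64)
        labels = data["labels"]
        subject_ids = data["subject_ids"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return TrialSet(
        trials=trials,
        labels=labels,
        subject_ids=subject_ids,
        rate=meta["rate"],
        window=tuple(meta["window"]),
        classes=tuple(meta["classes"]),
        channel_names=tuple(meta["channel_names"]),
        history=tuple(meta["history"]),
    )
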