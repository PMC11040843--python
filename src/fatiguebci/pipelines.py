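"""Motor-imagery and P300 decoding pipelines and the game's selection logic.

The two decoders follow the calibration protocols of the crossover study:

* **MI** — the 5-min calibration run holds 18 alternating left/right
  imagined-squeeze selections (12 s each); every 2 s window is band-passed
  5-30 Hz (5th-order Butterworth, causal), summarized by its spatial
  covariance, mapped to the tangent space at the Riemannian mean of the
  training covariances, and classified with L2 logistic regression.  The
  online feedback classifier is retrained from scratch every two selections;
  the interim models are kept as a feedback trace.

* **P300** — 9 selections on a 3x3 flash grid; 600 ms post-flash windows are
  band-passed 0.1-15 Hz, ensemble-averaged to one window per box per
  selection (15 flashes each), converted to XDawn-augmented covariances,
  tangent-space mapped, and classified target vs non-target with shrinkage
  LDA.  A selection compares the per-box target posteriors and takes the
  argmax.

In the game, an MI selection needs a *net* of four same-direction classifier
outputs (opposite outputs must be compensated); a P300 selection is the box
with the greatest posterior probability.  Chance performance is 50% for the
binary MI choice and 1/9 (~11%) for the 9-box grid.

Both decoders are scikit-learn estimators (``fit`` on epochs arrays,
``predict``/``predict_proba``); :func:`train_mi` and :func:`train_p300` are
protocol-aware wrappers that go from a raw recording + event markers to a
fitted decoder with cross-validated training metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import simulate as sim
from .riemann import (
    Covariances,
    TangentSpace,
    XdawnCovariances,
    LinearClassifier,
    TrainingMetrics,
    fit_classifier,
    kfold_scores,
)
from .signals import EEGRecording, EventMarker, bandpass, extract_epochs, sliding_windows

__all__ = [
    "MIDecoder",
    "P300Decoder",
    "SelectionOutcome",
    "train_mi",
    "train_p300",
    "mi_select",
    "p300_select",
    "game_performance",
    "play_mi_game",
    "play_p300_game",
    "decoder_to_json",
    "decoder_from_json",
]

MI_BAND = (5.0, 30.0)
P300_BAND = (0.1, 15.0)
FILTER_ORDER = 5
P300_WINDOW_S = 0.6


@dataclass
class SelectionOutcome:
    """One game selection.

    ``chosen`` is ``"left"``/``"right"`` (MI), a box index 1-9 (P300), or
    ``None`` when the MI stream was exhausted before a net-four decision
    (a *no-selection*, counted as incorrect by :func:`game_performance`).
    ``posteriors`` is the per-candidate probability vector (sums to 1);
    ``steps`` counts classifier outputs consumed (MI only; >= 4 for any
    completed selection).
    """

    chosen: object
    posteriors: np.ndarray
    correct: bool
    requested: object
    steps: int | None = None

    @property
    def no_selection(self) -> bool:
        return self.chosen is None


class MIDecoder(BaseEstimator, ClassifierMixin):
    """Tangent-space logistic-regression decoder for 2 s motor-imagery windows.

    ``fit`` consumes band-passed epochs (n, channels, samples) with labels
    ``"left"``/``"right"``.
    """

    paradigm = "MI"

    def __init__(self, k: int = 5, C: float = 1.0, seed: int = 0,
                 band: tuple = MI_BAND, order: int = FILTER_ORDER,
                 window_s: float = sim.MI_WINDOW_S):
        self.k = k
        self.C = C
        self.seed = seed
        self.band = band
        self.order = order
        self.window_s = window_s

    def _features(self, X: np.ndarray) -> np.ndarray:
        covs = Covariances().transform(X)
        return self.tangent_.transform(covs)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        covs = Covariances().transform(X)
        self.tangent_ = TangentSpace().fit(covs)
        feats = self.tangent_.transform(covs)
        self.rule_ = fit_classifier(feats, y, kind="logistic", C=self.C)
        self.classes_ = self.rule_.classes
        self.training_metrics_ = kfold_scores(
            feats, y, k=self.k, kind="logistic", seed=self.seed
        )
        return self

    @property
    def reference_(self) -> np.ndarray:
        return self.tangent_.reference_

    def predict(self, X):
        check_is_fitted(self, "rule_")
        return self.rule_.predict(self._features(np.asarray(X, float)))

    def predict_proba(self, X):
        check_is_fitted(self, "rule_")
        return self.rule_.predict_proba(self._features(np.asarray(X, float)))


class P300Decoder(BaseEstimator, ClassifierMixin):
    """XDawn + tangent-space + shrinkage-LDA decoder for ensemble-averaged
    600 ms flash windows, labeled ``"target"`` / ``"nontarget"``."""

    paradigm = "P300"

    def __init__(self, n_filters: int = 4, shrinkage: float | None = None,
                 k: int = 5, seed: int = 0, band: tuple = P300_BAND,
                 order: int = FILTER_ORDER, window_s: float = P300_WINDOW_S):
        self.n_filters = n_filters
        self.shrinkage = shrinkage
        self.k = k
        self.seed = seed
        self.band = band
        self.order = order
        self.window_s = window_s

    def _features(self, X: np.ndarray) -> np.ndarray:
        covs = self.xdawn_.transform(X)
        return self.tangent_.transform(covs)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if "target" not in set(y):
            raise ValueError("training epochs carry no target labels")
        self.xdawn_ = XdawnCovariances(
            n_filters=self.n_filters, target_label="target"
        ).fit(X, y)
        covs = self.xdawn_.transform(X)
        self.tangent_ = TangentSpace().fit(covs)
        feats = self.tangent_.transform(covs)
        self.rule_ = fit_classifier(feats, y, kind="slda", shrinkage=self.shrinkage)
        self.classes_ = self.rule_.classes
        self.training_metrics_ = kfold_scores(
            feats, y, k=self.k, kind="slda", shrinkage=self.shrinkage,
            pos_label="target", seed=self.seed,
        )
        return self

    @property
    def reference_(self) -> np.ndarray:
        return self.tangent_.reference_

    def target_scores(self, X) -> np.ndarray:
        """Monotone score for 'this window contains the evoked target response'.

        The sLDA decision score is oriented so that larger means more
        target-like regardless of the lexicographic class order.
        """
        check_is_fitted(self, "rule_")
        s = self.rule_.decision(self._features(np.asarray(X, float)))
        # classes are sorted; decision > 0 predicts classes[1]
        return s if self.rule_.classes[1] == "target" else -s

    def predict(self, X):
        check_is_fitted(self, "rule_")
        return self.rule_.predict(self._features(np.asarray(X, float)))

    def predict_proba(self, X):
        check_is_fitted(self, "rule_")
        return self.rule_.predict_proba(self._features(np.asarray(X, float)))


# ---------------------------------------------------------------------------
# calibration wrappers


def _mi_events(events: list[EventMarker]) -> list[EventMarker]:
    return [e for e in events if e.kind in ("mi_left", "mi_right")]


def train_mi(
    recording: EEGRecording,
    events: list[EventMarker] | None = None,
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
    feedback_trace: bool = True,
) -> MIDecoder:
    """Train the MI decoder from a calibration recording.

    Band-passes the recording 5-30 Hz (causal), cuts each 12 s imagery trial
    into six non-overlapping 2 s windows, and fits the tangent-space
    logistic pipeline.  The online feedback classifiers refit after every
    two selections are exposed on ``decoder.interim_`` (final model trained
    on all selections).
    """
    mi_evts = _mi_events(events if events is not None else recording.events)
    n_left = sum(e.kind == "mi_left" for e in mi_evts)
    n_right = sum(e.kind == "mi_right" for e in mi_evts)
    if n_left < 1 or n_right < 1:
        raise ValueError(
            f"need at least one selection per class (got {n_left} left, {n_right} right)"
        )
    filtered = bandpass(recording, *MI_BAND, order=FILTER_ORDER)
    windows_per_trial = int(round(sim.MI_TRIAL_S / sim.MI_WINDOW_S))
    epochs, labels, sel_idx = [], [], []
    for s, ev in enumerate(mi_evts):
        block = extract_epochs(
            filtered,
            events=[EventMarker(onset=ev.onset + j * sim.MI_WINDOW_S, kind=ev.kind)
                    for j in range(windows_per_trial)],
            window_s=sim.MI_WINDOW_S,
        )
        epochs.append(block.epochs)
        labels.extend(["left" if ev.kind == "mi_left" else "right"] * windows_per_trial)
        sel_idx.extend([s] * windows_per_trial)
    X = np.concatenate(epochs, axis=0)
    y = np.asarray(labels)
    sel_idx = np.asarray(sel_idx)

    decoder = MIDecoder(k=k, C=C, seed=seed).fit(X, y)
    decoder.channel_labels_ = filtered.good_channels
    decoder.interim_ = []
    if feedback_trace:
        for upto in range(2, len(mi_evts), 2):
            mask = sel_idx < upto
            if len(np.unique(y[mask])) < 2:
                continue
            decoder.interim_.append(MIDecoder(k=k, C=C, seed=seed).fit(X[mask], y[mask]))
    return decoder


def _group_selections(flashes: list[EventMarker]) -> list[list[EventMarker]]:
    """Chunk a calibration flash stream into per-selection groups of 135."""
    per_sel = sim.FLASHES_PER_BOX * sim.N_BOXES
    if len(flashes) % per_sel:
        raise ValueError(
            f"flash count {len(flashes)} is not a multiple of {per_sel} per selection"
        )
    return [flashes[i : i + per_sel] for i in range(0, len(flashes), per_sel)]


def _ensemble_average(
    recording: EEGRecording, flashes: list[EventMarker], window_s: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Ensemble-average one selection's flash windows to one window per box.

    Returns (windows 9 x C x T in box order 1..9, labels, target_box)."""
    counts = {b: 0 for b in range(1, sim.N_BOXES + 1)}
    for e in flashes:
        counts[e.box] += 1
    missing = [b for b, c in counts.items() if c != sim.FLASHES_PER_BOX]
    if missing:
        raise ValueError(
            f"incomplete flash schedule: boxes {missing} do not have "
            f"{sim.FLASHES_PER_BOX} flashes"
        )
    ep = extract_epochs(recording, events=flashes, window_s=window_s)
    boxes = np.array([e.box for e in flashes])
    windows = np.stack(
        [ep.epochs[boxes == b].mean(axis=0) for b in range(1, sim.N_BOXES + 1)]
    )
    targets = {e.box for e in flashes if e.is_target}
    target_box = targets.pop() if targets else None
    labels = np.array(
        ["target" if b == target_box else "nontarget"
         for b in range(1, sim.N_BOXES + 1)]
    )
    return windows, labels, target_box


def train_p300(
    recording: EEGRecording,
    events: list[EventMarker] | None = None,
    k: int = 5,
    seed: int = 0,
    n_filters: int = 4,
    shrinkage: float | None = None,
) -> P300Decoder:
    """Train the P300 decoder from a calibration recording.

    Band-passes 0.1-15 Hz (causal), cuts 600 ms windows from each flash
    onset, ensemble-averages the 15 windows per box per selection, and fits
    the XDawn / tangent-space / shrinkage-LDA pipeline on the resulting
    target vs non-target problem (1:8 imbalance).
    """
    evts = events if events is not None else recording.events
    flashes = [e for e in evts if e.kind == "flash"]
    groups = _group_selections(flashes)
    if len(groups) < 2:
        raise ValueError(f"need >= 2 selections to train, got {len(groups)}")
    filtered = bandpass(recording, *P300_BAND, order=FILTER_ORDER)
    all_windows, all_labels = [], []
    for g in groups:
        w, lab, target = _ensemble_average(filtered, g, P300_WINDOW_S)
        if target is None:
            raise ValueError("a training selection has no target-labeled flashes")
        all_windows.append(w)
        all_labels.append(lab)
    X = np.concatenate(all_windows, axis=0)
    y = np.concatenate(all_labels)
    decoder = P300Decoder(
        n_filters=n_filters, shrinkage=shrinkage, k=k, seed=seed
    ).fit(X, y)
    decoder.channel_labels_ = filtered.good_channels
    return decoder


# ---------------------------------------------------------------------------
# online selection logic


def mi_select(
    decoder: MIDecoder,
    window_stream,
    requested: str,
    max_steps: int = 60,
) -> SelectionOutcome:
    """Consume classifier outputs until a net of four agree on a direction.

    A right output adds +1 to a signed accumulator, a left output -1; the
    selection terminates when the accumulator reaches +/-4 (opposite outputs
    must be compensated).  An exhausted stream yields an explicit
    no-selection outcome rather than an exception.  ``posteriors`` is the
    mean (left, right) posterior over the windows consumed.
    """
    if getattr(decoder, "paradigm", None) != "MI":
        raise ValueError("mi_select requires an MI decoder")
    acc = 0
    steps = 0
    probas = []
    for window in window_stream:
        if steps >= max_steps:
            break
        p = decoder.predict_proba(window[None])[0]
        probas.append(p)
        label = decoder.classes_[int(np.argmax(p))]
        acc += 1 if label == "right" else -1
        steps += 1
        if abs(acc) == 4:
            chosen = "right" if acc > 0 else "left"
            return SelectionOutcome(
                chosen=chosen,
                posteriors=_mean_lr_posterior(probas, decoder.classes_),
                correct=(chosen == requested),
                requested=requested,
                steps=steps,
            )
    return SelectionOutcome(
        chosen=None,
        posteriors=_mean_lr_posterior(probas, decoder.classes_),
        correct=False,
        requested=requested,
        steps=steps,
    )


def _mean_lr_posterior(probas: list, classes: np.ndarray) -> np.ndarray:
    if not probas:
        return np.array([0.5, 0.5])
    mean = np.mean(probas, axis=0)
    order = np.argsort(classes)  # ("left", "right") alphabetical already
    return mean[order]


def p300_select(
    decoder: P300Decoder,
    trial_events: list[EventMarker],
    recording: EEGRecording,
    requested: int,
) -> SelectionOutcome:
    """Score one full flash sequence and pick the most target-like box.

    Builds the nine ensemble-averaged windows, scores each with the binary
    classifier, converts the scores to a probability vector over boxes by a
    softmax, and returns the argmax (ties broken toward the lowest box
    index).
    """
    if getattr(decoder, "paradigm", None) != "P300":
        raise ValueError("p300_select requires a P300 decoder")
    flashes = [e for e in trial_events if e.kind == "flash"]
    filtered = bandpass(recording, *decoder.band, order=decoder.order)
    windows, _, _ = _ensemble_average(filtered, flashes, decoder.window_s)
    scores = decoder.target_scores(windows)
    z = scores - scores.max()
    posteriors = np.exp(z) / np.exp(z).sum()
    chosen = int(np.argmax(posteriors)) + 1  # argmax takes the lowest index on ties
    return SelectionOutcome(
        chosen=chosen,
        posteriors=posteriors,
        correct=(chosen == requested),
        requested=requested,
    )


def game_performance(outcomes: list[SelectionOutcome]) -> float:
    """Fraction of correct selections; no-selections count as incorrect."""
    if not outcomes:
        raise ValueError("game_performance needs at least one outcome")
    return sum(o.correct for o in outcomes) / len(outcomes)


# ---------------------------------------------------------------------------
# end-to-end game play on synthetic streams


def play_mi_game(
    decoder: MIDecoder,
    config: sim.SimulationConfig,
    n_trials: int = 10,
    max_steps: int = 60,
    stream: tuple[int, ...] = (21,),
) -> list[SelectionOutcome]:
    """Simulate game trials: random requested sides, sustained-imagery streams."""
    rng = config.rng(*stream, 0)
    outcomes = []
    for i in range(n_trials):
        side = str(rng.choice(["left", "right"]))
        rec = sim.gen_mi_stream(config, side, n_windows=max_steps, stream=(*stream, i + 1))
        filtered = bandpass(rec, *decoder.band, order=decoder.order)
        windows = sliding_windows(filtered, 0.0, decoder.window_s, max_steps)
        outcomes.append(mi_select(decoder, windows, side, max_steps=max_steps))
    return outcomes


def play_p300_game(
    decoder: P300Decoder,
    config: sim.SimulationConfig,
    n_trials: int = 6,
    stream: tuple[int, ...] = (31,),
) -> list[SelectionOutcome]:
    """Simulate game trials: random target boxes, full flash sequences."""
    rng = config.rng(*stream, 0)
    outcomes = []
    for i in range(n_trials):
        target = int(rng.integers(1, sim.N_BOXES + 1))
        rec, events = sim.gen_p300_selection(config, target, stream=(*stream, i + 1))
        outcomes.append(p300_select(decoder, events, rec, target))
    return outcomes


# ---------------------------------------------------------------------------
# serialization


SCHEMA_VERSION = 1


def decoder_to_json(decoder) -> str:
    """Serialize a fitted decoder to a versioned JSON document."""
    rule: LinearClassifier = decoder.rule_
    doc = {
        "schema_version": SCHEMA_VERSION,
        "paradigm": decoder.paradigm,
        "band": list(decoder.band),
        "order": decoder.order,
        "window_s": decoder.window_s,
        "reference": decoder.reference_.tolist(),
        "classifier": {
            "weights": rule.weights.tolist(),
            "bias": rule.bias,
            "kind": rule.kind,
            "classes": [str(c) for c in rule.classes],
            "shrinkage": rule.shrinkage,
        },
        "channel_labels": list(getattr(decoder, "channel_labels_", [])),
        "training_metrics": (
            decoder.training_metrics_.as_dict()
            if hasattr(decoder, "training_metrics_") else None
        ),
    }
    if decoder.paradigm == "P300":
        doc["xdawn"] = {
            "filters": decoder.xdawn_.filters_.tolist(),
            "template": decoder.xdawn_.template_.tolist(),
            "n_filters": decoder.xdawn_.n_filters,
        }
    return json.dumps(doc)


def decoder_from_json(text: str):
    """Rebuild a decoder from :func:`decoder_to_json` output.

    The round trip is exact: JSON serializes IEEE doubles losslessly, so
    reloaded decoders make bit-identical selections.
    """
    doc = json.loads(text)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported decoder schema version {doc.get('schema_version')}")
    cls_doc = doc["classifier"]
    rule = LinearClassifier(
        weights=np.array(cls_doc["weights"]),
        bias=cls_doc["bias"],
        kind=cls_doc["kind"],
        classes=np.array(cls_doc["classes"]),
        shrinkage=cls_doc["shrinkage"],
    )
    tangent = TangentSpace()
    tangent.reference_ = np.array(doc["reference"])
    if doc["paradigm"] == "MI":
        decoder = MIDecoder(band=tuple(doc["band"]), order=doc["order"],
                            window_s=doc["window_s"])
    else:
        xd_doc = doc["xdawn"]
        decoder = P300Decoder(band=tuple(doc["band"]), order=doc["order"],
                              window_s=doc["window_s"],
                              n_filters=xd_doc["n_filters"])
        xd = XdawnCovariances(n_filters=xd_doc["n_filters"])
        xd.filters_ = np.array(xd_doc["filters"])
        xd.template_ = np.array(xd_doc["template"])
        xd.eigenvalues_ = None
        decoder.xdawn_ = xd
    decoder.tangent_ = tangent
    decoder.rule_ = rule
    decoder.classes_ = rule.classes
    decoder.channel_labels_ = doc.get("channel_labels", [])
    return decoder
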