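"""Pseudo-online ERN vs. background detection and the IDR metric.

Each error (ERN) trial contributes one evaluation block covering
[-2000, 700) ms around the error onset.  A 500 ms window slides over the
block in 20 ms steps; every window is classified ERN vs. background by the
same xDAWN/tangent-space/SVM chain used for synchronous classification
(fit independently here).  An *error event* is emitted whenever the last
``n`` consecutive windows were all classified ERN (``n`` is the detector's
sensitivity level).

Timing conventions.  A window's stamp is its end time (a causal decision is
available only once the window is complete).  An emitted event therefore
carries two times: the decision stamp and the estimated response onset
(stamp minus the window length -- the classifier is trained on windows
aligned to [0, 500) ms after onset, so a positive window implies the
response began at the window start).  Trial outcomes judge premature firing
on decision stamps (an event decided before the error even began is a false
alarm) and detection latency on estimated onsets (within the 200 ms
tolerance of the true onset).

The incidence-detection rate summarises the three outcome rates:
``IDR = CD * (1 - ID + ln(1 + ND))``, which is 1 when every trial is
correctly detected and 0 when none is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ernbci.io_core import EpochSet, EventList, Recording, ValidationError
from ernbci.riemann_features import FeatureChain
from ernbci.sync_classify import train_classifier

logger = logging.getLogger("ernbci")


@dataclass
class DetectorConfig:
    """Sliding-window detector parameters."""

    window_ms: float = 500.0
    step_ms: float = 20.0
    n_consecutive: int = 1
    latency_tolerance_ms: float = 200.0
    block_window_ms: tuple[float, float] = (-2000.0, 700.0)
    background_region_ms: tuple[float, float] = (-2000.0, -500.0)
    n_background_per_block: int = 4
    retrigger: bool = True
    svm_c: float = 1.0

    def __post_init__(self):
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise ValidationError("window and step must be positive")
        if self.n_consecutive < 1:
            raise ValidationError("sensitivity n must be >= 1")


@dataclass
class EvaluationBlock:
    """Continuous preprocessed segment around one error onset."""

    data: np.ndarray          # (n_channels, n_samples)
    fs: float
    onset_index: int          # sample index of the error onset within data
    block_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2:
            raise ValidationError("block data must be (channels, samples)")


@dataclass
class IDRReport:
    """Outcome rates with bootstrap CIs and the IDR value (fractions)."""

    cd: float
    id_rate: float
    nd: float
    idr_value: float
    ci99: dict                    # rate name -> (lo, hi)
    n_boot: int
    n_consecutive: int
    chance_idr: float | None = None

    def as_dict(self) -> dict:
        return {
            "CD": self.cd, "ID": self.id_rate, "ND": self.nd,
            "IDR": self.idr_value,
            "ci99": {k: [float(x) for x in v] for k, v in self.ci99.items()},
            "n_boot": self.n_boot, "n": self.n_consecutive,
            "chance_idr": self.chance_idr,
        }


# ---------------------------------------------------------------------------
# Blocks and windows
# ---------------------------------------------------------------------------


def build_blocks(recording: Recording, events: EventList,
                 config: DetectorConfig | None = None,
                 subject_id: str = "") -> list[EvaluationBlock]:
    """One evaluation block per usable ERN event; blocks lacking context
    (onset too close to either record edge) are dropped with a warning."""
    config = config or DetectorConfig()
    fs = recording.fs
    t0, t1 = config.block_window_ms
    pre = int(round(-t0 / 1000.0 * fs))
    post = int(round(t1 / 1000.0 * fs))
    blocks = []
    anchors = events.anchors(code="times_up", conditions=("ERN",))
    for _, row in anchors.iterrows():
        onset = int(row["onset_sample"])
        if onset - pre < 0 or onset + post > recording.n_samples:
            import warnings
            warnings.warn(f"trial {row['trial_id']}: insufficient context for "
                          "an evaluation block; dropped", stacklevel=2)
            continue
        blocks.append(EvaluationBlock(
            data=recording.data[onset - pre:onset + post].T.copy(),
            fs=fs, onset_index=pre,
            block_id=f"{subject_id}:{row['trial_id']}"))
    logger.info("build_blocks: %d blocks (%s)", len(blocks), subject_id or "-")
    return blocks


def slide_windows(block: EvaluationBlock, config: DetectorConfig | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """All fully contained windows plus their end-time stamps.

    Returns ``(windows, stamps_ms)`` where windows has shape
    ``(n_windows, n_channels, window_samples)`` and stamps are window end
    times in ms relative to the error onset.  Each window is mean-subtracted
    per channel, mirroring epoch preprocessing.
    """
    config = config or DetectorConfig()
    fs = block.fs
    wlen = int(round(config.window_ms / 1000.0 * fs))
    step = int(round(config.step_ms / 1000.0 * fs))
    n = block.data.shape[1]
    if n < wlen:
        raise ValidationError("block shorter than the analysis window")
    starts = np.arange(0, n - wlen + 1, step)
    windows = np.stack([block.data[:, s:s + wlen] for s in starts])
    windows -= windows.mean(axis=2, keepdims=True)
    stamps = (starts + wlen - block.onset_index) / fs * 1000.0
    return windows, stamps


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------


@dataclass
class AsyncDetector:
    """Fitted window classifier: feature chain + SVM."""

    chain: FeatureChain
    model: object
    config: DetectorConfig

    def predict_windows(self, block: EvaluationBlock
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Boolean ERN predictions and end stamps for a block's windows."""
        windows, stamps = slide_windows(block, self.config)
        features = self.chain.transform(windows)
        pred = self.model.predict(features)
        return pred == "ERN", stamps


def _training_windows(blocks: list[EvaluationBlock], config: DetectorConfig,
                      rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Positive ([0, 500) ms post-onset) and background training windows.

    Background exemplars are drawn from the pre-onset region
    ``background_region_ms`` on the detector's 20 ms step grid, a fixed
    number per block, without replacement.
    """
    fs = blocks[0].fs
    wlen = int(round(config.window_ms / 1000.0 * fs))
    step = int(round(config.step_ms / 1000.0 * fs))
    r0, r1 = config.background_region_ms
    xs, ys = [], []
    for block in blocks:
        onset = block.onset_index
        pos = block.data[:, onset:onset + wlen]
        xs.append(pos - pos.mean(axis=1, keepdims=True))
        ys.append("ERN")
        lo = onset + int(round(r0 / 1000.0 * fs))
        hi = onset + int(round(r1 / 1000.0 * fs)) - wlen
        grid = np.arange(max(lo, 0), hi + 1, step)
        if len(grid) < config.n_background_per_block:
            raise ValidationError("insufficient background windows in block")
        for s in rng.choice(grid, size=config.n_background_per_block,
                            replace=False):
            w = block.data[:, s:s + wlen]
            xs.append(w - w.mean(axis=1, keepdims=True))
            ys.append("background")
    return np.stack(xs), np.array(ys)


def fit_async_classifier(train_blocks: list[EvaluationBlock],
                         config: DetectorConfig | None = None,
                         rng=None,
                         permute_labels: bool = False) -> AsyncDetector:
    """Fit the window classifier on training blocks only.

    ``permute_labels`` shuffles the training-window labels uniformly at
    random -- the null model used for the chance-IDR permutation test.
    """
    config = config or DetectorConfig()
    if len(train_blocks) < 2:
        raise ValidationError("need >= 2 training blocks")
    rng = np.random.default_rng(rng)
    x, y = _training_windows(train_blocks, config, rng)
    if permute_labels:
        y = rng.permutation(y)
    chain = FeatureChain(classes=("ERN", "background"))
    features = chain.fit_transform(x, y)
    model = train_classifier(features, y, c=config.svm_c)
    return AsyncDetector(chain, model, config)


# ---------------------------------------------------------------------------
# Event rule and outcome taxonomy
# ---------------------------------------------------------------------------


def detect_events(labels: np.ndarray, stamps: np.ndarray, n: int,
                  retrigger: bool = True) -> np.ndarray:
    """Stamps of emitted error events for an ordered prediction stream.

    With ``retrigger`` (default) an event is emitted at every window whose
    trailing ``n`` predictions are all ERN.  With ``retrigger=False`` each
    maximal run of consecutive ERN predictions with length >= n emits a
    single event, at its n-th window's stamp.
    """
    labels = np.asarray(labels, bool)
    stamps = np.asarray(stamps, float)
    if labels.shape != stamps.shape:
        raise ValidationError("labels and stamps must align")
    if n < 1:
        raise ValidationError("n must be >= 1")
    run = 0
    out = []
    for i, lab in enumerate(labels):
        run = run + 1 if lab else 0
        if run >= n and (retrigger or run == n):
            out.append(stamps[i])
    return np.asarray(out)


def classify_trial_outcome(event_times: np.ndarray, onset_ms: float = 0.0,
                           tolerance_ms: float = 200.0,
                           window_ms: float | None = None,
                           event_decisions: np.ndarray | None = None) -> str:
    """Outcome of one trial: ``correct`` | ``incorrect`` | ``none``.

    ``correct``: no event before the error onset and at least one event
    within ``tolerance_ms`` of it; ``none``: no event anywhere in the block;
    ``incorrect``: everything else.

    ``event_times`` are the events' (estimated) onset times.  When the
    events come from the sliding-window detector, pass the decision stamps
    as ``event_decisions`` (or just ``window_ms`` if ``event_times`` holds
    decision stamps): premature firing is then judged on decision times
    while the latency tolerance applies to estimated onsets.
    """
    event_times = np.asarray(event_times, float)
    if event_times.size == 0:
        return "none"
    if window_ms is not None and event_decisions is None:
        event_decisions = event_times
        event_times = event_times - window_ms
    if event_decisions is None:
        event_decisions = event_times
    event_decisions = np.asarray(event_decisions, float)
    premature = np.any(event_decisions < onset_ms)
    in_window = np.any((event_times >= onset_ms)
                       & (event_times <= onset_ms + tolerance_ms))
    if not premature and in_window:
        return "correct"
    return "incorrect"


def idr(cd: float, id_rate: float, nd: float) -> float:
    """Incidence-detection rate CD * (1 - ID + ln(1 + ND)), as a fraction."""
    rates = np.array([cd, id_rate, nd], float)
    if np.any(rates < 0):
        raise ValidationError("rates must be non-negative")
    if abs(rates.sum() - 1.0) > 1e-9:
        raise ValidationError(f"rates must sum to 1, got {rates.sum()!r}")
    return float(cd * (1.0 - id_rate + np.log1p(nd)))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _outcomes_to_rates(outcomes: list[str]) -> tuple[float, float, float]:
    n = len(outcomes)
    cd = outcomes.count("correct") / n
    idr_ = outcomes.count("incorrect") / n
    nd = outcomes.count("none") / n
    return cd, idr_, nd


def _evaluate_predictions(pred: np.ndarray, stamps: np.ndarray,
                          config: DetectorConfig, n: int) -> str:
    events = detect_events(pred, stamps, n, config.retrigger)
    return classify_trial_outcome(events, 0.0, config.latency_tolerance_ms,
                                  window_ms=config.window_ms)


def loo_bootstrap_evaluate(blocks: list[EvaluationBlock],
                           config: DetectorConfig | None = None,
                           n_boot: int = 100,
                           seed=None,
                           n_values: tuple[int, ...] | None = None,
                           detector_factory=None,
                           permute_labels: bool = False
                           ) -> dict[int, IDRReport]:
    """Leave-one-out evaluation with bootstrap-resampled training sets.

    For every bootstrap repetition and every held-out block, the detector is
    trained on a with-replacement resample of the remaining blocks and
    applied to the held-out block.  CD/ID/ND are computed per repetition
    across held-out blocks, 99 % CIs are percentile intervals over
    repetitions, and the IDR is evaluated at the mean rates.  Window
    predictions are computed once per (repetition, block) and reused across
    sensitivity levels.

    ``detector_factory(train_blocks, config, rng)`` may replace
    :func:`fit_async_classifier` (used by tests to inject stub detectors).
    """
    config = config or DetectorConfig()
    if len(blocks) < 10:
        raise ValidationError("need >= 10 blocks for LOO evaluation")
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    if n_values is None:
        n_values = (config.n_consecutive,)
    if detector_factory is None:
        def detector_factory(tb, cfg, rng):
            return fit_async_classifier(tb, cfg, rng,
                                        permute_labels=permute_labels)

    rng = np.random.default_rng(seed)
    n_blocks = len(blocks)
    rates = {n: np.empty((n_boot, 3)) for n in n_values}
    for rep in range(n_boot):
        outcomes = {n: [] for n in n_values}
        for i in range(n_blocks):
            rest = [blocks[j] for j in range(n_blocks) if j != i]
            resample = [rest[k] for k in
                        rng.integers(0, len(rest), size=len(rest))]
            detector = detector_factory(resample, config, rng)
            pred, stamps = detector.predict_windows(blocks[i])
            for n in n_values:
                outcomes[n].append(
                    _evaluate_predictions(pred, stamps, config, n))
        for n in n_values:
            rates[n][rep] = _outcomes_to_rates(outcomes[n])

    reports = {}
    for n in n_values:
        mean = rates[n].mean(axis=0)
        ci = {name: tuple(np.percentile(rates[n][:, k], [0.5, 99.5]))
              for k, name in enumerate(("CD", "ID", "ND"))}
        reports[n] = IDRReport(cd=float(mean[0]), id_rate=float(mean[1]),
                               nd=float(mean[2]),
                               idr_value=idr(*np.clip(mean, 0, 1)
                                             / mean.sum()),
                               ci99=ci, n_boot=n_boot, n_consecutive=n)
        logger.info("loo_bootstrap n=%d: CD=%.3f ID=%.3f ND=%.3f IDR=%.3f",
                    n, *mean, reports[n].idr_value)
    return reports


def chance_idr(blocks: list[EvaluationBlock],
               config: DetectorConfig | None = None,
               n_perm: int = 100, seed=None,
               n_values: tuple[int, ...] | None = None) -> dict[int, float]:
    """Chance-level IDR from label-permuted detectors.

    Repeats the LOO evaluation with training-window labels permuted
    uniformly at random; each permutation is one bootstrap repetition and
    the chance level is the IDR at the mean rates.
    """
    reports = loo_bootstrap_evaluate(blocks, config, n_boot=n_perm, seed=seed,
                                     n_values=n_values, permute_labels=True)
    return {n: r.idr_value for n, r in reports.items()}


def sensitivity_sweep(blocks: list[EvaluationBlock],
                      config: DetectorConfig | None = None,
                      n_values: tuple[int, ...] = (1, 2, 3),
                      n_boot: int = 100, seed=None,
                      with_chance: bool = False,
                      n_perm: int = 20) -> dict[int, IDRReport]:
    """Full evaluation per sensitivity level n (rates, CIs, IDR, chance)."""
    config = config or DetectorConfig()
    reports = loo_bootstrap_evaluate(blocks, config, n_boot=n_boot, seed=seed,
                                     n_values=n_values)
    if with_chance:
        chance = chance_idr(blocks, config, n_perm=n_perm, seed=seed,
                            n_values=n_values)
        for n in n_values:
            reports[n].chance_idr = chance[n]
    return reports
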