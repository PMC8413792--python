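"""Network construction: state epoching, Pearson matrices, and thresholding.

Functional connectivity is estimated per brain state from 10-s signal
segments: the six finger-tapping epochs are used whole, and the resting
state contributes one 10-s window centred in the 60-s rest period, so all
seven states enter with the same number of samples.  Pairwise Pearson
correlations of the (HbT) channel signals form a symmetric connection
matrix, from which edges are retained by one of three complementary rules:

* ``absolute`` — keep coefficients at or above a fixed positive cutoff;
* ``cost`` — keep the strongest fixed fraction of positive coefficients;
* ``surrogate`` — keep coefficients individually significant at level
  alpha (one-sided on the positive side, exact t transform).

Negative coefficients never survive any scheme.  Thresholded networks may
then be binarised (all surviving edges set to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .montage import TASK_STATES, EventSchedule
from .preprocess import HemoSignals

ABSOLUTE_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.15, 0.751, 0.05), 2))
COST_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.851, 0.05), 2))
SURROGATE_ALPHA = 0.05


@dataclass(frozen=True)
class StateSegment:
    """One brain state's sample window, half-open [start, stop)."""

    label: str
    start: int
    stop: int

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass
class ConnectionMatrix:
    """Symmetric matrix of pairwise Pearson coefficients; diagonal fixed at 0."""

    r: np.ndarray
    n_samples: int
    label: str = ""
    subject_id: str = ""
    sleep_state: str = ""
    zero_variance_channels: tuple[int, ...] = ()

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]


@dataclass
class ThresholdedNetwork:
    """Nonnegative symmetric weight matrix after one thresholding scheme."""

    weights: np.ndarray
    scheme: str
    parameter: float
    binary: bool = False

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))


def extract_segments(
    n_samples: int, fs_hz: float, events: EventSchedule
) -> list[StateSegment]:
    """Equal-length 10-s sample windows for the seven task states.

    Stimulus epochs are used in full; the rest window is the 10-s span
    centred on the midpoint of the rest period (samples covering
    [mid-5 s, mid+5 s)).  Segment length is floor(10 s * fs) samples for
    every state.
    """
    labels = set(events.labels)
    missing = [s for s in TASK_STATES if s not in labels]
    if missing:
        raise ValueError(f"schedule is missing states: {missing}")
    rest_onset, rest_dur = events.get("Rest")
    _, stim_dur = events.get("Stim1")
    seg_len = int(np.floor(stim_dur * fs_hz))
    segments = []
    rest_mid = rest_onset + rest_dur / 2.0
    rest_start = int(np.floor((rest_mid - stim_dur / 2.0) * fs_hz))
    segments.append(StateSegment("Rest", rest_start, rest_start + seg_len))
    for k in range(1, 7):
        onset, _ = events.get(f"Stim{k}")
        start = int(np.floor(onset * fs_hz))
        segments.append(StateSegment(f"Stim{k}", start, start + seg_len))
    for seg in segments:
        if seg.stop > n_samples:
            raise ValueError(
                f"segment {seg.label} [{seg.start}, {seg.stop}) extends past "
                f"the {n_samples}-sample recording"
            )
    return segments


def segment_signal(hemo: HemoSignals, segment: StateSegment) -> np.ndarray:
    """The HbT block for one state, shape (segment samples, channels)."""
    return hemo.hbt[segment.start:segment.stop]


def pearson_matrix(block: np.ndarray, **meta) -> ConnectionMatrix:
    """Sample Pearson correlations between all channel pairs of a segment.

    Zero-variance channels get zero rows/columns (and are listed in the
    result) rather than being dropped, keeping the node count constant
    across states.
    """
    block = np.asarray(block, dtype=float)
    if block.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation")
    sd = block.std(axis=0)
    flat = np.where(sd == 0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(block, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    return ConnectionMatrix(r=r, n_samples=block.shape[0],
                            zero_variance_channels=tuple(flat), **meta)


def threshold_absolute(cm: ConnectionMatrix, tau: float) -> ThresholdedNetwork:
    """Keep coefficients >= tau (coefficients *below* the cutoff are discarded)."""
    if not 0 < tau < 1:
        raise ValueError("absolute threshold must lie in (0, 1)")
    w = np.where(cm.r >= tau, cm.r, 0.0)
    np.fill_diagonal(w, 0.0)
    return ThresholdedNetwork(weights=w, scheme="absolute", parameter=tau)


def threshold_cost(cm: ConnectionMatrix, cost: float) -> ThresholdedNetwork:
    """Keep the round(cost * M) strongest positive coefficients (M = N(N-1)/2).

    Fewer edges survive when fewer positive coefficients exist.  Ties in
    coefficient value are broken by (row, column) lexicographic order, which
    makes the retained edge sets nested across increasing costs.
    """
    if not 0 < cost <= 1:
        raise ValueError("cost fraction must lie in (0, 1]")
    n = cm.n_nodes
    iu, ju = np.triu_indices(n, 1)
    vals = cm.r[iu, ju]
    m = vals.size
    k = int(np.round(cost * m))
    order = np.lexsort((ju, iu, -vals))  # strongest first, then (row, col)
    keep = order[:k]
    keep = keep[vals[keep] > 0]
    w = np.zeros_like(cm.r)
    w[iu[keep], ju[keep]] = vals[keep]
    w[ju[keep], iu[keep]] = vals[keep]
    return ThresholdedNetwork(weights=w, scheme="cost", parameter=cost)


def correlation_p_value(r: float | np.ndarray, n: int) -> float | np.ndarray:
    """Two-sided p for a sample Pearson r via t = r*sqrt((n-2)/(1-r^2))."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sstats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def threshold_surrogate(
    cm: ConnectionMatrix, alpha: float = SURROGATE_ALPHA
) -> ThresholdedNetwork:
    """Keep positive coefficients whose individual correlation p is below alpha."""
    if cm.n_samples < 4:
        raise ValueError("surrogate thresholding needs at least 4 samples")
    p = correlation_p_value(cm.r, cm.n_samples)
    w = np.where((cm.r > 0) & (p < alpha), cm.r, 0.0)
    np.fill_diagonal(w, 0.0)
    return ThresholdedNetwork(weights=w, scheme="surrogate", parameter=alpha)


def binarize(net: ThresholdedNetwork) -> ThresholdedNetwork:
    """Replace every surviving edge weight with 1."""
    return ThresholdedNetwork(
        weights=(net.weights > 0).astype(float),
        scheme=net.scheme, parameter=net.parameter, binary=True,
    )
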