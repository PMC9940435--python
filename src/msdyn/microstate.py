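"""Microstate segmentation: polarity-invariant k-means and temporal statistics.

Resting EEG topographies alternate between a small number of quasi-stable
configurations ("microstates", canonically four classes A–D).  The standard
analysis clusters the instantaneous topographies at global-field-power peaks
with a *modified* k-means that ignores map polarity: a sample map and its
negation belong to the same state.  Each sample of the recording is then
"backfit" to the template with the highest absolute spatial correlation, and
the resulting label sequence is summarised by coverage (fraction of time),
occurrence (episodes per second), mean duration (ms) and the segment-level
Markov transition matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .eeg import EEGRecording, GFPSeries, gfp as _gfp

logger = logging.getLogger(__name__)

__all__ = [
    "MicrostateModel",
    "Segmentation",
    "MicrostateParameters",
    "extract_peak_maps",
    "fit_microstates",
    "cv_criterion",
    "canonical_reference_maps",
    "order_templates",
    "backfit",
    "microstate_parameters",
    "aggregate_parameters",
    "DEFAULT_LABELS",
]

DEFAULT_LABELS = ["A", "B", "C", "D"]
UNASSIGNED = -1


@dataclass
class MicrostateModel:
    """k unit-norm, zero-mean template topographies with labels and fit quality.

    ``gev`` is the global explained variance: the GFP-weighted fraction of
    topographic variance the templates account for, in [0, 1].
    """

    maps: np.ndarray               # k x n_channels
    labels: list[str]
    gev: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be k x n_channels")
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("one label per map required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass
class Segmentation:
    """Per-sample microstate labels (indices into ``labels``; -1 = unassigned)."""

    states: np.ndarray
    sfreq: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)

    @property
    def n_samples(self) -> int:
        return self.states.size

    def runs(self) -> list[tuple[int, int, int]]:
        """Maximal runs as (state, start, length) triples, in temporal order."""
        s = self.states
        if s.size == 0:
            return []
        change = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [s.size]])
        return [(int(s[a]), int(a), int(b - a)) for a, b in zip(starts, ends)]


@dataclass
class MicrostateParameters:
    """Temporal statistics of a segmentation.

    coverage
        Fraction of assigned samples spent in each state (sums to 1 when
        every sample is assigned).
    occurrence
        Number of maximal episodes of each state per second.
    duration
        Mean episode length per state in milliseconds.
    transition
        Row-stochastic segment-level transition matrix with zero diagonal;
        rows of states with no exits are NaN and flagged in ``undefined``.
    """

    coverage: np.ndarray
    occurrence: np.ndarray
    duration: np.ndarray
    transition: np.ndarray
    labels: list[str]
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, float]:
        """Flatten into named scalars (coverage_A, ..., transition_A_to_B, ...)."""
        out: dict[str, float] = {}
        for i, lab in enumerate(self.labels):
            out[f"coverage_{lab}"] = float(self.coverage[i])
            out[f"occurrence_{lab}"] = float(self.occurrence[i])
            out[f"duration_{lab}"] = float(self.duration[i])
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if i != j:
                    out[f"transition_{a}_to_{b}"] = float(self.transition[i, j])
        return out


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Zero-mean each map across channels and scale to unit L2 norm."""
    maps = np.asarray(maps, dtype=float)
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("constant map cannot be normalized")
    return maps / norms


def extract_peak_maps(rec: EEGRecording, gfp_series: GFPSeries | None = None,
                      min_peak_distance_ms: float = 10.0) -> np.ndarray:
    """Topographies at GFP peaks (rows), with their GFP values as weights.

    Returns the raw (unnormalized) maps; clustering normalizes internally.
    """
    if gfp_series is None:
        gfp_series = _gfp(rec, min_peak_distance_ms=min_peak_distance_ms)
    return rec.data[:, gfp_series.peak_indices].T.copy()


def fit_microstates(peak_maps: np.ndarray, k: int = 4, n_restarts: int = 10,
                    tol: float = 1e-7, max_iter: int = 200, seed: int | None = None,
                    channel_names: list[str] | None = None) -> MicrostateModel:
    """Polarity-invariant (modified) k-means clustering of topographic maps.

    Samples are assigned to the template with the largest *squared* spatial
    correlation, so a map and its negation are equivalent.  The centroid
    update is the dominant eigenvector of the sum of outer products of the
    assigned maps — the least-squares optimal template under sign ambiguity.
    The best of ``n_restarts`` random initialisations by global explained
    variance (GEV) is kept; iteration stops when the GEV improvement drops
    below ``tol``.

    Parameters
    ----------
    peak_maps : ndarray, shape (n_maps, n_channels)
        Topographies (typically at GFP peaks, pooled across subjects).
    k : int
        Number of microstate classes (4 for the canonical A–D set).
    """
    peak_maps = np.asarray(peak_maps, dtype=float)
    n_maps, n_ch = peak_maps.shape
    if n_maps < 10 * k:
        raise ValueError(f"need at least {10 * k} maps to fit {k} states, got {n_maps}")
    if k > n_ch:
        raise ValueError("k cannot exceed the channel count")

    gfp_w = peak_maps.std(axis=1, ddof=0)          # GFP of each map
    X = _normalize_maps(peak_maps)                 # n_maps x n_ch, unit norm
    w2 = gfp_w ** 2
    denom = w2.sum()
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray] | None = None
    for _ in range(n_restarts):
        T = X[rng.choice(n_maps, size=k, replace=False)].copy()
        prev_gev = -np.inf
        for _it in range(max_iter):
            corr = X @ T.T                          # n_maps x k
            assign = np.argmax(corr ** 2, axis=1)
            for j in range(k):
                idx = np.flatnonzero(assign == j)
                if idx.size == 0:
                    # re-seed an empty cluster from a random map
                    logger.info("re-seeding empty microstate cluster %d", j)
                    T[j] = X[rng.integers(n_maps)]
                    continue
                Xa = X[idx] * gfp_w[idx, None]
                S = Xa.T @ Xa
                vals, vecs = np.linalg.eigh(S)
                T[j] = vecs[:, -1]
            T = _normalize_maps(T)
            corr = X @ T.T
            assign = np.argmax(corr ** 2, axis=1)
            gev = float(np.sum(w2 * corr[np.arange(n_maps), assign] ** 2) / denom)
            if gev - prev_gev < tol:
                break
            prev_gev = gev
        if best is None or gev > best[0]:
            best = (gev, T.copy())

    gev, T = best
    labels = DEFAULT_LABELS[:k] if k <= len(DEFAULT_LABELS) else [
        f"S{i}" for i in range(k)]
    return MicrostateModel(maps=T, labels=list(labels), gev=gev,
                           channel_names=channel_names)


def cv_criterion(peak_maps: np.ndarray, k_range, n_restarts: int = 5,
                 seed: int | None = None) -> dict[int, float]:
    """Cross-validation criterion CV(k) for the number of microstates.

    CV(k) = sigma2 * ((n-1)/(n-1-k))^2, where sigma2 is the mean variance the
    k templates leave unexplained per map and n the channel count.  Smaller is
    better; the criterion penalises extra templates.  Diagnostic only — the
    standard resting-state analysis fixes k = 4.
    """
    peak_maps = np.asarray(peak_maps, dtype=float)
    n_ch = peak_maps.shape[1]
    out: dict[int, float] = {}
    Xraw = peak_maps - peak_maps.mean(axis=1, keepdims=True)
    for k in sorted(k_range):
        if k >= n_ch:
            raise ValueError(f"k={k} must be below the channel count {n_ch}")
        model = fit_microstates(peak_maps, k=k, n_restarts=n_restarts, seed=seed)
        proj = Xraw @ model.maps.T
        assign = np.argmax(proj ** 2, axis=1)
        resid = np.sum(Xraw ** 2, axis=1) - proj[np.arange(len(assign)), assign] ** 2
        sigma2 = float(resid.sum() / (len(assign) * (n_ch - 1)))
        out[k] = sigma2 * ((n_ch - 1) / (n_ch - 1 - k)) ** 2
    return out


#: Approximate 10–20 electrode positions on the unit disc (x = right,
#: y = anterior), used only to construct reference topographies.
_POS_1020 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.52), "F4": (0.45, 0.52), "F8": (0.81, 0.59),
    "T3": (-1.00, 0.00), "C3": (-0.50, 0.00), "C4": (0.50, 0.00), "T4": (1.00, 0.00),
    "T5": (-0.81, -0.59), "P3": (-0.45, -0.52), "P4": (0.45, -0.52), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}


def canonical_reference_maps(channel_names: list[str]) -> np.ndarray:
    """Synthetic reference topographies for the canonical A–D classes.

    Built from idealised 10–20 electrode positions as simple field patterns:
    A — left-posterior to right-anterior diagonal gradient; B — the mirrored
    right-posterior diagonal; C — occipital maximum with an annular
    curvature term; D — fronto-central focal maximum.  The diagonal slope
    (0.65) and curvature weight (1.1) are chosen so all pairwise absolute
    spatial correlations stay below 0.5 while the shapes remain
    recognisable.  These are geometric approximations of the published
    canonical maps (synthetic, not copied from any atlas); they fix a
    reproducible A–D labelling and can be overridden with user maps.
    """
    try:
        xy = np.array([_POS_1020[ch] for ch in channel_names])
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"no reference position for channel {e}") from None
    x, y = xy[:, 0], xy[:, 1]
    q = x ** 2 + y ** 2
    maps = np.stack([
        -x + 0.65 * y,          # A: right-posterior/left-frontal diagonal axis
        x + 0.65 * y,           # B: mirrored diagonal axis
        -y + 1.1 * q,           # C: occipital max, steep frontal negativity
        -q,                     # D: fronto-central focal max
    ])
    return _normalize_maps(maps)


def order_templates(model: MicrostateModel, reference_maps: np.ndarray | None = None
                    ) -> MicrostateModel:
    """Relabel templates A–D by optimal matching to reference topographies.

    Solves the one-to-one assignment maximizing total absolute spatial
    correlation (Hungarian algorithm, hence globally optimal rather than
    greedy) and reorders maps to reference order.  Polarity is ignored.
    """
    from scipy.optimize import linear_sum_assignment

    if reference_maps is None:
        if model.channel_names is None:
            raise ValueError("reference_maps required when model has no channel names")
        reference_maps = canonical_reference_maps(model.channel_names)
    R = _normalize_maps(np.asarray(reference_maps, dtype=float))
    if R.shape[0] != model.k:
        raise ValueError("reference map count must equal k")
    M = _normalize_maps(model.maps)
    cost = -np.abs(R @ M.T)                 # k_ref x k_model
    ref_idx, mod_idx = linear_sum_assignment(cost)
    order = mod_idx[np.argsort(ref_idx)]
    return MicrostateModel(maps=model.maps[order].copy(), labels=list(model.labels),
                           gev=model.gev, channel_names=model.channel_names)


def backfit(rec: EEGRecording, model: MicrostateModel,
            min_segment_ms: float = 10.0, mode: str = "peak_window",
            min_trough_distance_ms: float = 10.0) -> Segmentation:
    """Label the recording with its best-matching templates.

    Assignment maximizes the absolute spatial correlation between a
    topography and the templates (equivalently minimizes the polarity-
    invariant GMD).  Two labelling conventions are offered:

    ``mode="peak_window"`` (default)
        The classical segmentation convention: microstate transitions occur
        at global-field-power minima, so the recording is cut at GFP troughs
        (at least ``min_trough_distance_ms`` apart) and every sample of an
        inter-trough window inherits the label of the window's GFP peak —
        the moment of highest topographic signal-to-noise.  Adjacent windows
        with the same winning template merge into one run.

    ``mode="sample"``
        Every sample is labelled independently by its own topography.

    In both modes, runs shorter than ``min_segment_ms`` are then dissolved:
    each of their samples is reassigned to whichever neighbouring run's
    template correlates better with it (set ``min_segment_ms=0`` to disable).
    """
    from scipy.signal import find_peaks

    X = rec.data - rec.data.mean(axis=0, keepdims=True)    # average-reference
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    T = _normalize_maps(model.maps)
    abs_corr = np.abs((T @ X) / norms)                     # k x n_samples

    if mode == "sample":
        states = np.argmax(abs_corr, axis=0)
    elif mode == "peak_window":
        g = X.std(axis=0)
        distance = max(1, int(round(min_trough_distance_ms / 1000.0 * rec.sfreq)))
        troughs, _ = find_peaks(-g, distance=distance)
        bounds = np.concatenate([[0], troughs, [g.size]])
        states = np.empty(g.size, dtype=int)
        for a, b in zip(bounds[:-1], bounds[1:]):
            if a == b:
                continue
            peak = a + int(np.argmax(g[a:b]))
            states[a:b] = int(np.argmax(abs_corr[:, peak]))
    else:
        raise ValueError("mode must be 'peak_window' or 'sample'")

    min_len = int(round(min_segment_ms / 1000.0 * rec.sfreq))
    if min_len > 1:
        states = _smooth_short_segments(states, abs_corr, min_len)
    return Segmentation(states=states, sfreq=rec.sfreq, labels=list(model.labels))


def _smooth_short_segments(states: np.ndarray, abs_corr: np.ndarray,
                           min_len: int) -> np.ndarray:
    """Dissolve runs shorter than ``min_len`` into their neighbours.

    A short run between labels L and R is cut at the split point that
    maximizes the total correlation of its left part with L and its right
    part with R (edge runs join their only neighbour whole).  Each dissolved
    run reduces the run count, so the sweep converges; it repeats until no
    short run remains or only one run covers the recording.
    """
    states = states.copy()
    n = states.size
    while True:
        runs = Segmentation(states=states, sfreq=1.0, labels=[]).runs()
        short = [i for i, (_, _, ln) in enumerate(runs)
                 if ln < min_len and ln < n]
        if not short:
            break
        # within one sweep only touch runs with untouched neighbourhoods, so
        # every dissolve sees fresh neighbour labels; each dissolve merges
        # runs, so the run count strictly decreases and the loop terminates
        last_touched = -10
        progressed = False
        for i in short:
            if i - last_touched < 3:
                continue
            state, start, ln = runs[i]
            left = runs[i - 1][0] if i > 0 else None
            right = runs[i + 1][0] if i < len(runs) - 1 else None
            if left is None and right is None:
                continue
            if left is None:
                states[start:start + ln] = right
            elif right is None:
                states[start:start + ln] = left
            else:
                cl = abs_corr[left, start:start + ln]
                cr = abs_corr[right, start:start + ln]
                # split s: samples [0, s) join L, [s, ln) join R
                gains = [np.sum(cl[:s]) + np.sum(cr[s:]) for s in range(ln + 1)]
                s = int(np.argmax(gains))
                states[start:start + s] = left
                states[start + s:start + ln] = right
            last_touched = i
            progressed = True
        if not progressed:
            break
    return states


def aggregate_parameters(segs: list[Segmentation]) -> MicrostateParameters:
    """Pool temporal statistics over several segmentations (e.g. epochs).

    Counts (assigned samples, runs, segment transitions) are accumulated per
    epoch — runs never span epoch boundaries — and the statistics are formed
    from the pooled counts, so epochs contribute in proportion to their
    length.
    """
    if not segs:
        raise ValueError("no segmentations to aggregate")
    labels = segs[0].labels
    sfreq = segs[0].sfreq
    for s in segs[1:]:
        if s.labels != labels or s.sfreq != sfreq:
            raise ValueError("segmentations must share labels and sfreq")
    k = len(labels)
    cov_samples = np.zeros(k)
    n_runs = np.zeros(k)
    trans_counts = np.zeros((k, k))
    total_assigned = 0
    total_seconds = 0.0
    for seg in segs:
        runs = [(s, a, ln) for s, a, ln in seg.runs() if s != UNASSIGNED]
        total_seconds += seg.n_samples / seg.sfreq
        for s, _, ln in runs:
            cov_samples[s] += ln
            n_runs[s] += 1
            total_assigned += ln
        rs = [s for s, _, _ in runs]
        for a, b in zip(rs[:-1], rs[1:]):
            if a != b:
                trans_counts[a, b] += 1
    coverage = cov_samples / total_assigned if total_assigned else cov_samples
    occurrence = n_runs / total_seconds
    with np.errstate(invalid="ignore", divide="ignore"):
        duration = (cov_samples / n_runs) / sfreq * 1000.0
        transition = trans_counts / trans_counts.sum(axis=1, keepdims=True)
    undefined = [labels[i] for i in range(k)
                 if n_runs[i] == 0 or trans_counts[i].sum() == 0]
    return MicrostateParameters(coverage=coverage, occurrence=occurrence,
                                duration=duration, transition=transition,
                                labels=list(labels), undefined=undefined)


def microstate_parameters(seg: Segmentation) -> MicrostateParameters:
    """Coverage, occurrence, mean duration and transition matrix of a segmentation.

    Coverage is the assigned-sample fraction per state; occurrence the number
    of maximal runs per second; duration the mean run length in ms.  The
    transition matrix is estimated from the *segment* sequence (consecutive
    run pairs), has zero diagonal by construction and row sums of 1 for every
    state with at least one exit; states that never occur (or never exit) get
    NaN parameters and are listed in ``undefined``.
    """
    if seg.n_samples == 0:
        raise ValueError("empty segmentation")
    k = len(seg.labels) if seg.labels else int(seg.states.max()) + 1
    runs = [(s, a, ln) for s, a, ln in seg.runs() if s != UNASSIGNED]
    total_assigned = sum(ln for _, _, ln in runs)
    total_seconds = seg.n_samples / seg.sfreq

    coverage = np.zeros(k)
    n_runs = np.zeros(k)
    run_len = np.zeros(k)
    for s, _, ln in runs:
        coverage[s] += ln
        n_runs[s] += 1
        run_len[s] += ln
    coverage = coverage / total_assigned if total_assigned else coverage
    occurrence = n_runs / total_seconds
    with np.errstate(invalid="ignore", divide="ignore"):
        duration = (run_len / n_runs) / seg.sfreq * 1000.0

    transition = np.zeros((k, k))
    run_states = [s for s, _, _ in runs]
    for a, b in zip(run_states[:-1], run_states[1:]):
        if a != b:  # same-state pairs only arise across unassigned gaps
            transition[a, b] += 1
    exits = transition.sum(axis=1)
    undefined = []
    with np.errstate(invalid="ignore", divide="ignore"):
        transition = transition / exits[:, None]
    for i in range(k):
        lab = seg.labels[i] if seg.labels else str(i)
        if n_runs[i] == 0:
            coverage[i] = 0.0
            occurrence[i] = 0.0
            duration[i] = np.nan
            transition[i] = np.nan
            undefined.append(lab)
        elif exits[i] == 0:
            transition[i] = np.nan
            if lab not in undefined:
                undefined.append(lab)
    if undefined:
        warnings.warn(f"states with no runs or no exits: {undefined}", stacklevel=2)
    labels = seg.labels if seg.labels else [str(i) for i in range(k)]
    return MicrostateParameters(coverage=coverage, occurrence=occurrence,
                                duration=duration, transition=transition,
                                labels=list(labels), undefined=undefined)
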