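"""Resting-state functional connectivity over an atlas network partition.

Per-subject ROI time series (e.g. the 400 regions of the Schaefer
parcellation) are band-pass filtered in the classic resting-state band
(0.01–0.1 Hz), correlated pairwise (Pearson), and summarised as the mean
edge value within each of the 7 canonical networks (7 intra values) and
between each unordered network pair (21 inter values).  Subjects with mean
Jenkinson framewise displacement at or above a threshold are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_NETWORKS",
    "ROITimeSeries",
    "AtlasPartition",
    "FCMatrix",
    "NetworkFC",
    "bandpass_bold",
    "fd_exclude",
    "fc_matrix",
    "network_summaries",
    "load_default_partition",
]

#: The seven canonical resting-state networks.
DEFAULT_NETWORKS = ["DMN", "SMN", "DAN", "VAN", "ECN", "VN", "limbic"]


@dataclass
class ROITimeSeries:
    """ROI x timepoints BOLD matrix with repetition time (s) and ROI ids."""

    data: np.ndarray
    tr: float
    roi_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (ROI x time)")
        if self.data.shape[0] != len(self.roi_ids):
            raise ValueError("one ROI id per row required")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_roi(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class AtlasPartition:
    """Mapping of each ROI to exactly one network."""

    mapping: dict[str, str]
    networks: list[str]

    def __post_init__(self) -> None:
        extra = set(self.mapping.values()) - set(self.networks)
        if extra:
            raise ValueError(f"mapping uses networks not listed: {sorted(extra)}")

    @property
    def n_roi(self) -> int:
        return len(self.mapping)

    def indices(self, roi_ids: list[str]) -> dict[str, np.ndarray]:
        """Row indices of each network for a given ROI ordering."""
        missing = [r for r in roi_ids if r not in self.mapping]
        if missing:
            raise ValueError(f"ROIs absent from partition: {missing[:5]}...")
        nets = np.array([self.mapping[r] for r in roi_ids])
        return {net: np.flatnonzero(nets == net) for net in self.networks}


@dataclass
class FCMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    r: np.ndarray
    roi_ids: list[str]


@dataclass
class NetworkFC:
    """Mean edge correlation within each network and between each pair.

    ``intra`` maps each of the 7 network tags to the mean off-diagonal edge
    within it; ``inter`` maps each of the C(7,2)=21 unordered pairs to the
    mean between-network edge.
    """

    intra: dict[str, float]
    inter: dict[tuple[str, str], float]

    def to_dict(self) -> dict[str, float]:
        out = {f"intra_{n}": v for n, v in self.intra.items()}
        out.update({f"inter_{a}_{b}": v for (a, b), v in self.inter.items()})
        return out


def bandpass_bold(ts: ROITimeSeries, low: float = 0.01, high: float = 0.1
                  ) -> ROITimeSeries:
    """Zero-phase temporal band-pass of every ROI row (default 0.01–0.1 Hz).

    Rows are linearly detrended, then filtered forward-backward with a
    2nd-order Butterworth band-pass (an effective 4th-order zero-phase
    response) — appropriate for the short series typical of resting fMRI.
    """
    from scipy.signal import butter, detrend, filtfilt

    nyq = 1.0 / (2.0 * ts.tr)
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high={high} Hz must be below Nyquist ({nyq} Hz)")
    b, a = butter(2, [low / nyq, high / nyq], btype="band")
    data = detrend(ts.data, axis=1, type="linear")
    padlen = min(3 * (max(len(a), len(b)) - 1) * 4, ts.n_timepoints - 1)
    filtered = filtfilt(b, a, data, axis=1, padlen=padlen)
    return ROITimeSeries(data=filtered, tr=ts.tr, roi_ids=list(ts.roi_ids))


def fd_exclude(subjects: pd.DataFrame, threshold: float = 0.2,
               fd_column: str = "fd") -> pd.DataFrame:
    """Drop subjects whose mean framewise displacement is >= ``threshold``.

    The threshold is inclusive (FD = 0.2 is excluded).  Returns the retained
    rows; the ids of excluded subjects are reported via a warning so runs
    leave an exclusion trail.
    """
    if fd_column not in subjects.columns:
        raise ValueError(f"subject table lacks an {fd_column!r} column")
    fd = subjects[fd_column].to_numpy(dtype=float)
    if np.any(fd < 0) or np.any(np.isnan(fd)):
        raise ValueError("FD values must be nonnegative and non-missing")
    drop = subjects.index[fd >= threshold]
    if len(drop):
        ids = (subjects.loc[drop, "subject_id"].tolist()
               if "subject_id" in subjects.columns else list(drop))
        warnings.warn(f"excluding {len(drop)} subject(s) with mean FD >= "
                      f"{threshold}: {ids}", stacklevel=2)
    return subjects.drop(index=drop)


def fc_matrix(ts: ROITimeSeries) -> FCMatrix:
    """Pairwise Pearson correlation between ROI time series.

    Constant rows have no defined correlation; their entries are set to NaN
    and flagged with a warning rather than failing the whole subject.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    data = ts.data
    sd = data.std(axis=1)
    scale = np.maximum(np.abs(data).max(axis=1), 1.0)
    constant = np.flatnonzero(sd <= 1e-12 * scale)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if constant.size:
        warnings.warn(
            f"{constant.size} constant ROI row(s); their correlations are NaN",
            stacklevel=2)
        r[constant, :] = np.nan
        r[:, constant] = np.nan
        r[constant, constant] = 1.0
    return FCMatrix(r=r, roi_ids=list(ts.roi_ids))


def network_summaries(fc: FCMatrix, partition: AtlasPartition) -> NetworkFC:
    """Mean edge value within and between networks.

    Intra-network values average the off-diagonal upper-triangle entries of
    each network's block; inter-network values average the full rectangular
    block between two networks.  Raw correlations are averaged (no Fisher
    transform); each unordered ROI pair contributes once.  A network with
    fewer than two ROIs has no within edges — its intra value is NaN and
    flagged.
    """
    n = fc.r.shape[0]
    if partition.n_roi != n:
        raise ValueError(
            f"FC matrix has {n} ROIs but partition maps {partition.n_roi}")
    idx = partition.indices(fc.roi_ids)
    intra: dict[str, float] = {}
    for net, rows in idx.items():
        if rows.size < 2:
            warnings.warn(f"network {net} has <2 ROIs; intra-FC undefined",
                          stacklevel=2)
            intra[net] = np.nan
            continue
        block = fc.r[np.ix_(rows, rows)]
        iu = np.triu_indices(rows.size, k=1)
        intra[net] = float(np.mean(block[iu]))
    inter: dict[tuple[str, str], float] = {}
    for a, b in combinations(partition.networks, 2):
        inter[(a, b)] = float(np.mean(fc.r[np.ix_(idx[a], idx[b])]))
    return NetworkFC(intra=intra, inter=inter)


def load_default_partition() -> AtlasPartition:
    """Packaged 400-ROI / 7-network lookup table.

    This is a synthetic stand-in for the Schaefer-400 7-network label file
    (which cannot be redistributed here): ROI ids ROI001..ROI400 assigned to
    the seven canonical networks in contiguous blocks with realistic
    per-network sizes.  Analyses accept any user-supplied partition TSV with
    columns (roi_id, network).
    """
    path = resources.files("msdyn.data") / "schaefer400_7networks_synthetic.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    mapping = dict(zip(df["roi_id"], df["network"]))
    return AtlasPartition(mapping=mapping, networks=list(DEFAULT_NETWORKS))
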