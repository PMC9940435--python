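"""File formats: plain-text EEG matrices, EDF, BOLD TSV, subject CSV.

EEG travels either as European Data Format (EDF) or as tab-separated text
matrices (header row of channel names, then one row per channel).  EDF
reading goes through mne; writing uses a compact EDF+ compatible writer
implemented here (a fixed-layout 16-bit integer format), since no installed
library exposes an EDF writer.  BOLD ROI time series are TSV with the ROI id
in the first column; subject tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg import EEGRecording
from .network import AtlasPartition, ROITimeSeries, DEFAULT_NETWORKS

__all__ = [
    "write_eeg_text", "read_eeg_text", "write_edf", "read_edf",
    "write_bold_tsv", "read_bold_tsv", "write_subjects_csv",
    "read_subjects_csv", "read_partition_tsv", "write_partition_tsv",
    "write_ground_truth_json",
]


def write_eeg_text(rec: EEGRecording, path: str | Path) -> None:
    """Tab-separated channels x samples matrix with a channel-name header."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("\t".join(rec.channel_names) + "\n")
        np.savetxt(f, rec.data, fmt="%.6f", delimiter="\t")


def read_eeg_text(path: str | Path, sfreq: float) -> EEGRecording:
    """Read a tab-separated channels x samples matrix written by write_eeg_text."""
    path = Path(path)
    with open(path) as f:
        names = f.readline().rstrip("\n").split("\t")
        data = np.loadtxt(f, delimiter="\t", ndmin=2)
    return EEGRecording(data=data, sfreq=sfreq, channel_names=names)


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a minimal EDF file (one data record, 16-bit integer samples).

    Physical units are µV; each channel is scaled to the full digital range,
    so the quantization error is below half of (peak-to-peak)/65535.
    """
    path = Path(path)
    data = rec.data
    n_ch, n_samp = data.shape
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = phys_max - phys_min
    span[span == 0] = 1.0
    dig_min, dig_max = -32768, 32767
    scaled = (data - phys_min[:, None]) / span[:, None]
    digital = np.round(scaled * (dig_max - dig_min) + dig_min).astype("<i2")

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)
    header += _edf_field("Startdate X X X X", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (1 + n_ch), 8)
    header += _edf_field("", 44)
    header += _edf_field(1, 8)                                  # data records
    header += _edf_field(f"{n_samp / rec.sfreq:.5g}", 8)        # record length (s)
    header += _edf_field(n_ch, 4)
    for width, values in [
        (16, rec.channel_names),
        (80, [""] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [f"{v:.6g}" for v in phys_min]),
        (8, [f"{v:.6g}" for v in phys_max]),
        (8, [dig_min] * n_ch),
        (8, [dig_max] * n_ch),
        (80, [""] * n_ch),
        (8, [n_samp] * n_ch),
        (32, [""] * n_ch),
    ]:
        for v in values:
            header += _edf_field(v, width)
    with open(path, "wb") as f:
        f.write(header)
        f.write(digital.tobytes())          # channel-sequential within record


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF recording (via mne) into an EEGRecording in µV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    return EEGRecording(data=raw.get_data() * 1e6, sfreq=float(raw.info["sfreq"]),
                        channel_names=list(raw.ch_names))


def write_bold_tsv(ts: ROITimeSeries, path: str | Path) -> None:
    """ROI x time TSV with the ROI id as the first column."""
    df = pd.DataFrame(ts.data, index=pd.Index(ts.roi_ids, name="roi_id"))
    df.columns = [f"t{j}" for j in range(ts.n_timepoints)]
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_bold_tsv(path: str | Path, tr: float) -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ROITimeSeries(data=df.to_numpy(dtype=float), tr=tr,
                         roi_ids=[str(i) for i in df.index])


def write_subjects_csv(subjects: pd.DataFrame, path: str | Path) -> None:
    subjects.to_csv(path, index=False)


def read_subjects_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_partition_tsv(path: str | Path,
                       networks: list[str] | None = None) -> AtlasPartition:
    """Partition table with columns (roi_id, network)."""
    df = pd.read_csv(path, sep="\t")
    if not {"roi_id", "network"} <= set(df.columns):
        raise ValueError("partition TSV needs columns 'roi_id' and 'network'")
    mapping = dict(zip(df["roi_id"].astype(str), df["network"]))
    if networks is None:
        seen = list(dict.fromkeys(df["network"]))
        networks = [n for n in DEFAULT_NETWORKS if n in seen] or seen
    return AtlasPartition(mapping=mapping, networks=networks)


def write_partition_tsv(partition: AtlasPartition, path: str | Path) -> None:
    df = pd.DataFrame({"roi_id": list(partition.mapping),
                       "network": list(partition.mapping.values())})
    df.to_csv(path, sep="\t", index=False)


def write_ground_truth_json(truth, path: str | Path) -> None:
    """Serialize per-group GroundTruth objects to JSON."""
    def encode(gt):
        return {
            "templates": gt.templates.tolist(),
            "transition_matrix": gt.transition_matrix.tolist(),
            "mean_durations_ms": gt.mean_durations_ms.tolist(),
            "fc_blocks": gt.fc_blocks.tolist(),
            "group_effects": gt.group_effects,
            "trait_couplings": [list(t) for t in gt.trait_couplings],
        }
    payload = {group: encode(gt) for group, gt in truth.items()}
    Path(path).write_text(json.dumps(payload, indent=1))
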