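"""End-to-end orchestration: simulate -> preprocess -> microstates -> FC -> stats.

``run_simulate`` materialises a synthetic cohort on disk (EEG text/EDF, BOLD
TSV, subject CSV, ground-truth JSON); ``run_analysis`` executes the full
analysis over a cohort — per-subject EEG preprocessing and microstate
statistics, per-subject network FC, covariate-adjusted group comparisons of
both feature families and MIDAS correlations within patients — and returns a
:class:`RunReport`.  Everything is configuration-driven and deterministic
under a fixed seed; the configuration is embedded in the report for
provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .eeg import EEGRecording, average_reference, bandpass_filter, select_epochs
from .microstate import (aggregate_parameters, backfit, extract_peak_maps,
                         fit_microstates, order_templates)
from .network import (AtlasPartition, bandpass_bold, fc_matrix, fd_exclude,
                      network_summaries)
from .stats import compare_features, correlate_features
from .synthetic import CohortConfig, CohortDataset, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_simulate", "run_analysis",
           "analyze_cohort", "validate_inputs", "load_cohort",
           "MICROSTATE_FEATURES", "NETWORK_FEATURES"]

_LABELS = ["A", "B", "C", "D"]
MICROSTATE_FEATURES = (
    [f"{p}_{s}" for p in ("coverage", "occurrence", "duration") for s in _LABELS]
    + [f"transition_{a}_to_{b}" for a, b in permutations(_LABELS, 2)]
)


def _network_features(networks: list[str]) -> list[str]:
    from itertools import combinations

    return ([f"intra_{n}" for n in networks]
            + [f"inter_{a}_{b}" for a, b in combinations(networks, 2)])


from .network import DEFAULT_NETWORKS  # noqa: E402

NETWORK_FEATURES = _network_features(DEFAULT_NETWORKS)


@dataclass
class RunConfig:
    """All knobs of a pipeline run, serialized into every output.

    Defaults mirror the standard resting-state settings: 1–45 Hz EEG band,
    five 10-s epochs, k = 4 microstates, 0.01–0.1 Hz BOLD band, FD exclusion
    at 0.2, 10 000 permutations, alpha = 0.05.
    """

    # EEG
    eeg_band: tuple[float, float] = (1.0, 45.0)
    n_epochs: int = 5
    epoch_s: float = 10.0
    k: int = 4
    n_restarts: int = 10
    min_segment_ms: float = 10.0
    min_peak_distance_ms: float = 10.0
    # fMRI
    bold_band: tuple[float, float] = (0.01, 0.1)
    fd_threshold: float = 0.2
    # stats
    ms_covariates: tuple[str, ...] = ("age", "sex")
    fc_covariates: tuple[str, ...] = ("age", "sex", "fd")
    n_iter: int = 10000
    alpha: float = 0.05
    seed: int = 0
    # simulate block (None = analysis of existing data only)
    simulate: CohortConfig | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("eeg_band", "bold_band", "ms_covariates", "fc_covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if sim is not None:
            simknown = {f.name for f in dataclasses.fields(CohortConfig)}
            bad = set(sim) - simknown
            if bad:
                raise ValueError(f"unknown simulate keys: {sorted(bad)}")
            cfg.simulate = CohortConfig(**sim)
        return cfg


@dataclass
class RunReport:
    """Results and logs of one pipeline run."""

    config: dict
    ms_parameters: pd.DataFrame          # one row per subject, EEG features
    network_fc: pd.DataFrame             # one row per subject, FC features
    ms_comparison: pd.DataFrame
    fc_comparison: pd.DataFrame
    ms_midas_correlation: pd.DataFrame
    fc_midas_correlation: pd.DataFrame
    model_maps: np.ndarray
    gev: float
    logs: list[str] = field(default_factory=list)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(json.dumps(self.config, indent=1))
        self.ms_parameters.to_csv(outdir / "microstate_parameters.tsv",
                                  sep="\t", index=False)
        self.network_fc.to_csv(outdir / "network_fc.tsv", sep="\t", index=False)
        self.ms_comparison.to_csv(outdir / "microstate_comparison.tsv",
                                  sep="\t", index=False)
        self.fc_comparison.to_csv(outdir / "network_comparison.tsv",
                                  sep="\t", index=False)
        self.ms_midas_correlation.to_csv(outdir / "microstate_midas_correlation.tsv",
                                         sep="\t", index=False)
        self.fc_midas_correlation.to_csv(outdir / "network_midas_correlation.tsv",
                                         sep="\t", index=False)
        np.savetxt(outdir / "template_maps.tsv", self.model_maps, delimiter="\t")
        summary = {
            "gev": self.gev,
            "significant_microstate_features":
                self.ms_comparison.loc[self.ms_comparison["significant"],
                                       "feature"].tolist(),
            "significant_network_features":
                self.fc_comparison.loc[self.fc_comparison["significant"],
                                       "feature"].tolist(),
            "logs": self.logs,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))


def run_simulate(config: RunConfig, outdir: str | Path,
                 write_edf: bool = False) -> CohortDataset:
    """Generate a synthetic cohort and write it to ``outdir``.

    Layout: ``subjects.csv``, ``partition.tsv``, ``ground_truth.json``,
    ``eeg/<subject>.tsv`` (and optionally ``.edf``), ``bold/<subject>.tsv``.
    """
    if config.simulate is None:
        raise ValueError("config has no simulate block")
    outdir = Path(outdir)
    (outdir / "eeg").mkdir(parents=True, exist_ok=True)
    (outdir / "bold").mkdir(parents=True, exist_ok=True)
    dataset = simulate_cohort(config.simulate, seed=config.seed)
    msio.write_subjects_csv(dataset.subjects, outdir / "subjects.csv")
    msio.write_partition_tsv(dataset.partition, outdir / "partition.tsv")
    msio.write_ground_truth_json(dataset.truth, outdir / "ground_truth.json")
    for sid, rec in dataset.eeg.items():
        msio.write_eeg_text(rec, outdir / "eeg" / f"{sid}.tsv")
        if write_edf:
            msio.write_edf(rec, outdir / "eeg" / f"{sid}.edf")
    for sid, ts in dataset.bold.items():
        msio.write_bold_tsv(ts, outdir / "bold" / f"{sid}.tsv")
    logger.info("wrote %d subjects to %s", len(dataset.subjects), outdir)
    return dataset


def load_cohort(indir: str | Path, sfreq: float = 500.0, tr: float = 2.0
                ) -> CohortDataset:
    """Load a cohort previously written by :func:`run_simulate`."""
    indir = Path(indir)
    subjects = msio.read_subjects_csv(indir / "subjects.csv")
    partition = msio.read_partition_tsv(indir / "partition.tsv")
    eeg = {}
    bold = {}
    for sid in subjects["subject_id"]:
        edf = indir / "eeg" / f"{sid}.edf"
        txt = indir / "eeg" / f"{sid}.tsv"
        if txt.exists():
            eeg[sid] = msio.read_eeg_text(txt, sfreq=sfreq)
        elif edf.exists():
            eeg[sid] = msio.read_edf(edf)
        else:
            raise FileNotFoundError(f"no EEG file for {sid}")
        bold[sid] = msio.read_bold_tsv(indir / "bold" / f"{sid}.tsv", tr=tr)
    return CohortDataset(subjects=subjects, eeg=eeg, bold=bold, truth={},
                         true_sequences={}, config=None, partition=partition)


def analyze_cohort(dataset: CohortDataset, config: RunConfig | None = None
                   ) -> RunReport:
    """Run the full analysis on an in-memory cohort."""
    config = config or RunConfig()
    logs: list[str] = []

    # ---- EEG stage: preprocess, pooled clustering, per-subject backfit
    prep: dict[str, list[EEGRecording]] = {}
    peak_pool = []
    for sid, rec in dataset.eeg.items():
        rec = bandpass_filter(rec, *config.eeg_band)
        rec = average_reference(rec)
        epochs = select_epochs(rec, config.n_epochs, config.epoch_s)
        prep[sid] = epochs
        for ep in epochs:
            peak_pool.append(extract_peak_maps(
                ep, min_peak_distance_ms=config.min_peak_distance_ms))
    pooled = np.vstack(peak_pool)
    logs.append(f"pooled {pooled.shape[0]} GFP-peak maps from "
                f"{len(prep)} subjects")
    model = fit_microstates(pooled, k=config.k, n_restarts=config.n_restarts,
                            seed=config.seed,
                            channel_names=next(iter(dataset.eeg.values())).channel_names)
    model = order_templates(model)
    logs.append(f"fitted {config.k} templates, GEV = {model.gev:.3f}")

    ms_rows = []
    for sid, epochs in prep.items():
        segs = [backfit(ep, model, min_segment_ms=config.min_segment_ms)
                for ep in epochs]
        params = aggregate_parameters(segs)
        row = {"subject_id": sid}
        row.update(params.to_dict())
        ms_rows.append(row)
    ms_parameters = pd.DataFrame(ms_rows)

    # ---- fMRI stage
    networks = dataset.partition.networks
    fc_rows = []
    for sid, ts in dataset.bold.items():
        ts = bandpass_bold(ts, *config.bold_band)
        fc = fc_matrix(ts)
        nfc = network_summaries(fc, dataset.partition)
        row = {"subject_id": sid}
        row.update(nfc.to_dict())
        fc_rows.append(row)
    network_fc = pd.DataFrame(fc_rows)

    # ---- stats stage
    subjects = dataset.subjects
    ms_table = subjects.merge(ms_parameters, on="subject_id")
    fc_subjects = fd_exclude(subjects, threshold=config.fd_threshold)
    n_excl = len(subjects) - len(fc_subjects)
    if n_excl:
        logs.append(f"excluded {n_excl} subject(s) at FD >= {config.fd_threshold}")
    fc_table = fc_subjects.merge(network_fc, on="subject_id")

    net_features = _network_features(networks)
    ms_comparison = compare_features(
        ms_table, MICROSTATE_FEATURES, covariates=list(config.ms_covariates),
        n_iter=config.n_iter, alpha=config.alpha, seed=config.seed)
    fc_comparison = compare_features(
        fc_table, net_features, covariates=list(config.fc_covariates),
        n_iter=config.n_iter, alpha=config.alpha, seed=config.seed + 1)

    patients_ms = ms_table[ms_table["group"] == "patient"]
    patients_fc = fc_table[fc_table["group"] == "patient"]

    def _correlate(table, features, covariates):
        # partial correlation needs n > #covariates + 3 patients
        if len(table) <= len(covariates) + 3:
            logs.append(f"skipped trait correlations: only {len(table)} "
                        "patients for the covariate set")
            return pd.DataFrame(columns=["feature", "trait", "r", "ci_lo",
                                         "ci_hi", "p", "n", "q",
                                         "significant"])
        return correlate_features(table, features, "midas",
                                  covariates=covariates, alpha=config.alpha)

    ms_midas = _correlate(patients_ms, MICROSTATE_FEATURES,
                          list(config.ms_covariates))
    fc_midas = _correlate(patients_fc, net_features,
                          list(config.fc_covariates))

    return RunReport(config=config.to_dict(), ms_parameters=ms_parameters,
                     network_fc=network_fc, ms_comparison=ms_comparison,
                     fc_comparison=fc_comparison,
                     ms_midas_correlation=ms_midas,
                     fc_midas_correlation=fc_midas,
                     model_maps=model.maps, gev=model.gev, logs=logs)


def run_analysis(config: RunConfig, indir: str | Path,
                 outdir: str | Path | None = None,
                 sfreq: float = 500.0, tr: float = 2.0) -> RunReport:
    """Load a cohort from disk, analyze it, and optionally save the report."""
    dataset = load_cohort(indir, sfreq=sfreq, tr=tr)
    report = analyze_cohort(dataset, config)
    if outdir is not None:
        report.save(outdir)
    return report


def validate_inputs(indir: str | Path, expected_channels: int = 16,
                    sfreq: float = 500.0, tr: float = 2.0) -> list[str]:
    """Schema checks on an on-disk cohort; returns a list of failures."""
    indir = Path(indir)
    problems: list[str] = []
    subj_path = indir / "subjects.csv"
    if not subj_path.exists():
        return [f"missing {subj_path}"]
    subjects = msio.read_subjects_csv(subj_path)
    for col in ("subject_id", "group", "age", "sex", "fd"):
        if col not in subjects.columns:
            problems.append(f"subject table lacks column {col!r}")
    if "group" in subjects.columns:
        bad = set(subjects["group"]) - {"patient", "control"}
        if bad:
            problems.append(f"unknown group labels: {sorted(bad)}")
    partition = None
    part_path = indir / "partition.tsv"
    if part_path.exists():
        partition = msio.read_partition_tsv(part_path)
    else:
        problems.append(f"missing {part_path}")
    for sid in subjects.get("subject_id", []):
        txt = indir / "eeg" / f"{sid}.tsv"
        if not txt.exists():
            problems.append(f"missing EEG for {sid}")
        else:
            rec = msio.read_eeg_text(txt, sfreq=sfreq)
            if rec.n_channels != expected_channels:
                problems.append(
                    f"{sid}: {rec.n_channels} EEG channels, expected "
                    f"{expected_channels}")
        bpath = indir / "bold" / f"{sid}.tsv"
        if not bpath.exists():
            problems.append(f"missing BOLD for {sid}")
        elif partition is not None:
            ts = msio.read_bold_tsv(bpath, tr=tr)
            if ts.n_roi != partition.n_roi:
                problems.append(
                    f"{sid}: {ts.n_roi} ROIs vs partition {partition.n_roi}")
    return problems
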