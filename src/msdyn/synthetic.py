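"""Synthetic resting-state cohort with planted, recoverable ground truth.

Generates the three data streams the analysis pipeline consumes:

* 16-channel EEG built from k hidden template topographies visited by a
  segment-level Markov chain, with gamma-distributed dwell times, a half-wave
  amplitude envelope per segment, random segment polarity (the property the
  polarity-invariant clustering must cope with) and additive white sensor
  noise at a controlled SNR;
* ROI x time BOLD series drawn from a multivariate normal whose correlation
  matrix is block-structured over a 7-network partition;
* a subject covariate table (age, sex, motion, MIDAS disability, clinical
  descriptors) with group effects and trait couplings planted at known
  magnitudes.

Patients differ from controls in the generating chain (longer microstate-B
and shorter microstate-D dwell times), in connectivity (weaker intra-ECN and
DAN–ECN blocks) and in a planted MIDAS coupling to the microstate-C dwell
parameter, mirroring the effect directions such cohorts are reported to show.
Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .eeg import EEGRecording, STANDARD_CHANNELS
from .network import AtlasPartition, ROITimeSeries, DEFAULT_NETWORKS

__all__ = [
    "GroundTruth",
    "CohortConfig",
    "CohortDataset",
    "make_templates",
    "simulate_state_sequence",
    "simulate_eeg",
    "simulate_bold",
    "default_ground_truth",
    "simulate_cohort",
    "simulate_feature_cohort",
    "DEFAULT_FEATURE_EFFECTS",
    "FEATURE_NAMES",
]


@dataclass
class GroundTruth:
    """Generating parameters for one group's synthetic data."""

    templates: np.ndarray                # k x n_channels, zero-mean unit-norm
    transition_matrix: np.ndarray        # k x k row-stochastic, zero diagonal
    mean_durations_ms: np.ndarray        # per-state dwell means
    fc_blocks: np.ndarray                # 7 x 7 symmetric planted correlations
    group_effects: dict = field(default_factory=dict)
    trait_couplings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.mean_durations_ms = np.asarray(self.mean_durations_ms, dtype=float)
        self.fc_blocks = np.asarray(self.fc_blocks, dtype=float)
        _check_transition_matrix(self.transition_matrix)
        if np.any(self.mean_durations_ms <= 0):
            raise ValueError("mean durations must be positive")
        if not np.allclose(self.fc_blocks, self.fc_blocks.T):
            raise ValueError("fc_blocks must be symmetric")
        if np.any(np.diag(self.fc_blocks) <= 0) or np.any(np.diag(self.fc_blocks) > 1):
            raise ValueError("fc_blocks diagonal must lie in (0, 1]")

    @property
    def k(self) -> int:
        return self.templates.shape[0]


def _check_transition_matrix(P: np.ndarray) -> None:
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must be nonnegative and sum to 1")
    if np.any(np.diag(P) != 0):
        raise ValueError("transition matrix must have zero diagonal (segment-level chain)")


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults follow the design of the emulated study: 24 patients and 26
    controls, 16-channel EEG at 500 Hz, BOLD with 176 retained volumes at
    TR = 2 s over a 400-ROI / 7-network parcellation.  EEG length defaults
    to 50 s per subject (the five 10-s epochs the analysis uses).  Effect
    magnitudes on the generating scale are free parameters of the generator,
    not estimates from any cohort.
    """

    n_patients: int = 24
    n_controls: int = 26
    n_channels: int = 16
    sfreq: float = 500.0
    eeg_duration_s: float = 50.0
    snr: float = 5.0
    k: int = 4
    bold_timepoints: int = 176
    tr: float = 2.0
    # generating-scale group effects (patients vs controls)
    msb_duration_factor: float = 1.35    # microstate-B dwell elevation
    msd_duration_factor: float = 0.70    # microstate-D dwell reduction
    msb_transition_factor: float = 1.30  # inflow to B (patient chain)
    msd_transition_factor: float = 0.70  # inflow to D (patient chain)
    ecn_delta: float = -0.08             # intra-ECN correlation shift
    dan_ecn_delta: float = -0.06         # DAN-ECN correlation shift
    midas_msc_r: float = 0.5             # MIDAS ~ MsC dwell coupling
    subject_sd: float = 0.12             # between-subject lognormal dwell spread
    male_fraction: float = 0.16


@dataclass
class CohortDataset:
    """A full synthetic cohort plus everything needed to score recovery."""

    subjects: pd.DataFrame
    eeg: dict[str, EEGRecording]
    bold: dict[str, ROITimeSeries]
    truth: dict[str, GroundTruth]        # per group
    true_sequences: dict[str, np.ndarray]
    config: CohortConfig = None
    partition: AtlasPartition = None


def make_templates(n_channels: int, k: int, seed: int | None = None) -> np.ndarray:
    """k mutually decorrelated zero-mean unit-norm topographies.

    Random Gaussian maps are average-referenced and orthonormalized within
    the zero-mean subspace, so pairwise spatial correlations are exactly 0.
    The zero-mean subspace has dimension n_channels - 1, so at most that many
    decorrelated maps exist (two channels admit a single map only).
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if k > n_channels:
        raise ValueError("k cannot exceed the channel count")
    if k > n_channels - 1:
        raise ValueError(
            f"at most {n_channels - 1} mutually decorrelated zero-mean maps "
            f"exist for {n_channels} channels (requested {k})")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_channels, k))
    X -= X.mean(axis=0, keepdims=True)
    Q, R = np.linalg.qr(X)
    Q *= np.sign(np.diag(R))             # deterministic orientation
    T = Q.T
    T -= T.mean(axis=1, keepdims=True)   # QR preserves zero-mean; re-assert
    return T / np.linalg.norm(T, axis=1, keepdims=True)


def simulate_state_sequence(truth: GroundTruth, n_samples: int, sfreq: float,
                            seed: int | None = None) -> np.ndarray:
    """Hidden per-sample state labels from the segment-level Markov chain.

    Segment dwell times are drawn from a gamma distribution with shape 2
    whose mean matches the state's planted mean duration, discretized to at
    least one sample (microstate dwell-time distributions are unimodal and
    non-exponential; shape 2 avoids a pile-up of 1-sample segments).
    Successive segment states follow the planted zero-diagonal transition
    matrix.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if sfreq <= 0:
        raise ValueError("sfreq must be positive")
    P = truth.transition_matrix
    _check_transition_matrix(P)
    k = P.shape[0]
    mean_samples = truth.mean_durations_ms / 1000.0 * sfreq
    rng = np.random.default_rng(seed)
    out = np.empty(n_samples, dtype=int)
    state = int(rng.integers(k))
    t = 0
    while t < n_samples:
        # gamma(shape=2, scale=mean/2), rounded, floored at 1 sample
        dur = max(1, int(round(rng.gamma(2.0, mean_samples[state] / 2.0))))
        dur = min(dur, n_samples - t)
        out[t:t + dur] = state
        t += dur
        state = int(rng.choice(k, p=P[state]))
    return out


def simulate_eeg(templates: np.ndarray, state_sequence: np.ndarray, snr: float,
                 sfreq: float, seed: int | None = None, amplitude: float = 15.0,
                 polarity_flips: bool = True,
                 channel_names: list[str] | None = None) -> EEGRecording:
    """Sensor EEG from templates and a hidden state sequence.

    Each maximal segment of the sequence gets a random polarity s in {-1,+1}
    and a strictly positive half-sine amplitude envelope (rising then
    falling, so global-field-power peaks fall inside segments); sample t is
    ``amplitude * envelope(t) * s * template[state(t)]`` plus white Gaussian
    channel noise scaled so that the ratio of time-averaged signal variance
    to noise variance, averaged over channels, equals ``snr``.  ``snr=inf``
    yields noise-free data.
    """
    templates = np.asarray(templates, dtype=float)
    state_sequence = np.asarray(state_sequence, dtype=int)
    if state_sequence.size == 0:
        raise ValueError("state sequence is empty")
    if snr <= 0:
        raise ValueError("snr must be positive")
    k, n_ch = templates.shape
    rng = np.random.default_rng(seed)

    n = state_sequence.size
    change = np.flatnonzero(np.diff(state_sequence)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    env = np.empty(n)
    sign = np.empty(n)
    for a, b in zip(starts, ends):
        ln = b - a
        env[a:b] = np.sin(np.pi * (np.arange(ln) + 0.5) / ln)
        sign[a:b] = rng.choice([-1.0, 1.0]) if polarity_flips else 1.0
    signal = (amplitude * env * sign) * templates[state_sequence].T  # n_ch x n

    if np.isfinite(snr):
        signal_power = float(np.mean(signal ** 2))
        noise_sd = np.sqrt(signal_power / snr)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    if channel_names is None:
        channel_names = (list(STANDARD_CHANNELS) if n_ch == 16
                         else [f"CH{i + 1}" for i in range(n_ch)])
    return EEGRecording(data=signal, sfreq=sfreq, channel_names=channel_names)


def _nearest_correlation(R: np.ndarray, min_eig: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clipped positive-definite repair, rescaled to unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= min_eig:
        return R, False
    vals = np.clip(vals, min_eig, None)
    R2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2, True


def simulate_bold(partition: AtlasPartition, fc_blocks: np.ndarray,
                  n_timepoints: int, seed: int | None = None, tr: float = 2.0,
                  roi_ids: list[str] | None = None) -> ROITimeSeries:
    """Block-correlated BOLD: multivariate normal over the ROI partition.

    The ROI-level correlation matrix takes the value ``fc_blocks[u, u]``
    between distinct ROIs of network u and ``fc_blocks[u, w]`` between
    networks u and w.  If that matrix is not positive definite it is repaired
    by eigenvalue clipping (reported via a warning).  With fewer timepoints
    than ROIs the sample is rank-deficient — valid data, just a singular
    empirical covariance.
    """
    fc_blocks = np.asarray(fc_blocks, dtype=float)
    if not np.allclose(fc_blocks, fc_blocks.T):
        raise ValueError("fc_blocks must be symmetric")
    if n_timepoints < 20:
        raise ValueError("need at least 20 timepoints")
    if roi_ids is None:
        roi_ids = sorted(partition.mapping)
    net_of = [partition.mapping[r] for r in roi_ids]
    net_index = {n: i for i, n in enumerate(partition.networks)}
    ui = np.array([net_index[n] for n in net_of])
    R = fc_blocks[np.ix_(ui, ui)].copy()
    np.fill_diagonal(R, 1.0)
    R, repaired = _nearest_correlation(R)
    if repaired:
        warnings.warn("planted correlation matrix was not positive definite; "
                      "repaired by eigenvalue clipping", stacklevel=2)
    L = np.linalg.cholesky(R + 1e-10 * np.eye(R.shape[0]))
    rng = np.random.default_rng(seed)
    data = L @ rng.standard_normal((len(roi_ids), n_timepoints))
    return ROITimeSeries(data=data, tr=tr, roi_ids=list(roi_ids))


# ---------------------------------------------------------------------------
# cohort-level defaults

#: Control-group dwell means (ms) for states A-D: within the 60-90 ms range
#: typical of resting microstates.
_BASE_DURATIONS_MS = np.array([70.0, 70.0, 80.0, 75.0])

#: Control-group planted network correlations (diagonal = intra, off = inter).
_BASE_FC_BLOCKS = np.array([
    #  DMN   SMN   DAN   VAN   ECN   VN  limbic
    [0.40, 0.12, 0.10, 0.12, 0.15, 0.10, 0.08],   # DMN
    [0.12, 0.42, 0.15, 0.14, 0.10, 0.12, 0.08],   # SMN
    [0.10, 0.15, 0.38, 0.15, 0.18, 0.14, 0.07],   # DAN
    [0.12, 0.14, 0.15, 0.36, 0.14, 0.10, 0.09],   # VAN
    [0.15, 0.10, 0.18, 0.14, 0.40, 0.12, 0.08],   # ECN
    [0.10, 0.12, 0.14, 0.10, 0.12, 0.45, 0.10],   # VN
    [0.08, 0.08, 0.07, 0.09, 0.08, 0.10, 0.30],   # limbic
])

_ECN = DEFAULT_NETWORKS.index("ECN")
_DAN = DEFAULT_NETWORKS.index("DAN")


def default_ground_truth(config: CohortConfig, seed: int | None = None
                         ) -> dict[str, GroundTruth]:
    """Control and patient GroundTruth objects under a config.

    Both groups share the template set and a uniform off-diagonal transition
    matrix; patients get scaled B/D dwell means, a chain with increased
    inflow to B and reduced inflow to D, and shifted ECN-related
    connectivity blocks.  For the standard 16-channel, 4-state setting the
    templates are the canonical A-D reference topographies (so planted
    state effects land on their like-named labels); otherwise mutually
    decorrelated random maps are drawn from ``seed``.
    """
    if config.n_channels == 16 and config.k == 4:
        from .eeg import STANDARD_CHANNELS
        from .microstate import canonical_reference_maps

        templates = canonical_reference_maps(list(STANDARD_CHANNELS))
    else:
        templates = make_templates(config.n_channels, config.k, seed=seed)
    k = config.k
    P = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(P, 0.0)

    control = GroundTruth(
        templates=templates,
        transition_matrix=P,
        mean_durations_ms=_BASE_DURATIONS_MS[:k].copy(),
        fc_blocks=_BASE_FC_BLOCKS.copy(),
        group_effects={},
        trait_couplings=[("duration_C", "midas", config.midas_msc_r)],
    )
    dur = _BASE_DURATIONS_MS[:k].copy()
    Pp = P.copy()
    if k >= 2:
        dur[1] *= config.msb_duration_factor
        Pp[:, 1] *= config.msb_transition_factor
    if k >= 4:
        dur[3] *= config.msd_duration_factor
        Pp[:, 3] *= config.msd_transition_factor
    np.fill_diagonal(Pp, 0.0)
    Pp /= Pp.sum(axis=1, keepdims=True)
    fc = _BASE_FC_BLOCKS.copy()
    fc[_ECN, _ECN] += config.ecn_delta
    fc[_DAN, _ECN] += config.dan_ecn_delta
    fc[_ECN, _DAN] += config.dan_ecn_delta
    patient = GroundTruth(
        templates=templates,
        transition_matrix=Pp,
        mean_durations_ms=dur,
        fc_blocks=fc,
        group_effects={
            "duration_B_factor": config.msb_duration_factor,
            "duration_D_factor": config.msd_duration_factor,
            "intra_ECN_delta": config.ecn_delta,
            "inter_DAN_ECN_delta": config.dan_ecn_delta,
        },
        trait_couplings=[("duration_C", "midas", config.midas_msc_r)],
    )
    return {"control": control, "patient": patient}


def simulate_cohort(config: CohortConfig | None = None, seed: int | None = None,
                    partition: AtlasPartition | None = None) -> CohortDataset:
    """Full synthetic cohort: EEG + BOLD + covariates for every subject.

    Each subject gets individual dwell means (group mean times a lognormal
    multiplier with spread ``config.subject_sd``), an EEG realisation at the
    configured SNR, a BOLD realisation from the group's connectivity blocks,
    and covariates; patients' MIDAS scores are coupled to their individual
    microstate-C dwell multiplier at the planted correlation.  Ages and sex
    are drawn from the same distributions for both groups (balanced by
    design).
    """
    config = config or CohortConfig()
    if config.n_patients < 3 or config.n_controls < 3:
        raise ValueError("each group needs at least 3 subjects")
    if partition is None:
        from .network import load_default_partition
        partition = load_default_partition()
    root = np.random.default_rng(seed)
    truth = default_ground_truth(config, seed=int(root.integers(2 ** 31)))
    n_samples = int(round(config.eeg_duration_s * config.sfreq))
    roi_ids = sorted(partition.mapping)

    rows = []
    eeg: dict[str, EEGRecording] = {}
    bold: dict[str, ROITimeSeries] = {}
    seqs: dict[str, np.ndarray] = {}
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    for i, group in enumerate(groups):
        sid = f"sub-{i + 1:03d}"
        gt = truth[group]
        # individual dwell means: lognormal multiplier per state
        zmult = root.standard_normal(gt.k)
        mult = np.exp(config.subject_sd * zmult - config.subject_sd ** 2 / 2)
        subj_gt = replace(gt, mean_durations_ms=gt.mean_durations_ms * mult)
        seq = simulate_state_sequence(subj_gt, n_samples, config.sfreq,
                                      seed=int(root.integers(2 ** 31)))
        eeg[sid] = simulate_eeg(gt.templates, seq, config.snr, config.sfreq,
                                seed=int(root.integers(2 ** 31)))
        seqs[sid] = seq
        bold[sid] = simulate_bold(partition, gt.fc_blocks,
                                  config.bold_timepoints,
                                  seed=int(root.integers(2 ** 31)),
                                  tr=config.tr, roi_ids=roi_ids)
        age = float(np.clip(root.normal(36.0, 9.0), 18, 60))
        sex = "M" if root.random() < config.male_fraction else "F"
        fd = float(np.clip(root.normal(0.075, 0.02), 0.01, 0.30))
        if group == "patient":
            r = config.midas_msc_r
            z_c = zmult[2] if gt.k >= 3 else root.standard_normal()
            latent = r * z_c + np.sqrt(1 - r ** 2) * root.standard_normal()
            midas = int(round(max(0.0, 7.2 + 6.2 * latent)))
            duration_years = float(root.gamma(1.4, 7.65 / 1.4))
            attacks = float(root.gamma(1.4, 2.79 / 1.4))
            pain_side = root.choice(["left", "right", "bilateral"], p=[0.5, 0.3, 0.2])
            medication = root.choice(["ibuprofen", "paracetamol"])
        else:
            midas = 0
            duration_years = np.nan
            attacks = np.nan
            pain_side = ""
            medication = ""
        rows.append(dict(subject_id=sid, group=group, age=age, sex=sex, fd=fd,
                         midas=midas, duration_years=duration_years,
                         attacks_per_month=attacks, pain_side=pain_side,
                         medication=medication))
    subjects = pd.DataFrame(rows)
    return CohortDataset(subjects=subjects, eeg=eeg, bold=bold, truth=truth,
                         true_sequences=seqs, config=config, partition=partition)


# ---------------------------------------------------------------------------
# feature-level cohort (for inference calibration and power studies)

def _feature_names(networks: list[str] = DEFAULT_NETWORKS) -> list[str]:
    from itertools import combinations, permutations

    labels = ["A", "B", "C", "D"]
    names = [f"{p}_{s}" for p in ("coverage", "occurrence", "duration")
             for s in labels]
    names += [f"transition_{a}_to_{b}" for a, b in permutations(labels, 2)]
    names += [f"intra_{n}" for n in networks]
    names += [f"inter_{a}_{b}" for a, b in combinations(networks, 2)]
    return names


#: 24 microstate features (12 parameters + 12 transitions) and 28 network
#: features (7 intra + 21 inter), in canonical order.
FEATURE_NAMES = _feature_names()

#: Default planted standardized group effects (patient minus control, in
#: residual SD units): elevated microstate-B and reduced microstate-D
#: statistics plus weakened ECN-related connectivity, at the magnitudes such
#: cohorts are reported to show.
DEFAULT_FEATURE_EFFECTS = {
    "coverage_B": 1.377, "occurrence_B": 1.336, "duration_B": 1.281,
    "coverage_D": -1.958, "occurrence_D": -1.743, "duration_D": -1.633,
    "intra_ECN": -0.657, "inter_DAN_ECN": -1.633,
}


def simulate_feature_cohort(n_patients: int = 24, n_controls: int = 26,
                            effects: dict[str, float] | None = None,
                            seed: int | None = None,
                            age_loading: float = 0.3,
                            sex_loading: float = 0.3) -> pd.DataFrame:
    """Subject-level feature table with planted standardized group effects.

    Draws each of the 52 canonical features as unit-variance Gaussian noise
    plus age and sex contributions (so covariate adjustment matters) plus the
    planted shift for patients.  ``effects`` maps feature names to Cohen's-d
    shifts; pass an empty dict for a global-null cohort.  This is the
    desk-scale surrogate for a full cohort when only the inferential
    machinery is under study.
    """
    if effects is None:
        effects = dict(DEFAULT_FEATURE_EFFECTS)
    unknown = set(effects) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n = n_patients + n_controls
    group = np.array(["patient"] * n_patients + ["control"] * n_controls)
    age = np.clip(rng.normal(36.0, 9.0, size=n), 18, 60)
    sex = (rng.random(n) < 0.16).astype(float)        # 1 = male
    fd = np.clip(rng.normal(0.075, 0.02, size=n), 0.01, 0.30)
    age_z = (age - age.mean()) / age.std()
    table = pd.DataFrame({
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "group": group, "age": age,
        "sex": np.where(sex > 0, "M", "F"), "fd": fd,
    })
    is_pat = (group == "patient").astype(float)
    for feat in FEATURE_NAMES:
        y = (rng.standard_normal(n) + age_loading * age_z + sex_loading * sex
             + effects.get(feat, 0.0) * is_pat)
        table[feat] = y
    return table
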