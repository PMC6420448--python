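"""Synthetic BOLD: category-selective voxel patterns, HRF convolution, noise.

Voxels here are abstract features with no spatial geometry — the decoding
analyses are pattern-based, so only the multivariate structure matters.  A
pattern bank holds one unit-norm vector per stimulus class (the four trained
context classes face-left/face-right/scene-left/scene-right plus object and
scrambled-scene patterns for the untrained localizer blocks).  Neural time
courses are boxcars (localizer miniblocks) or trace-driven amplitudes (task
trials), convolved with a double-gamma hemodynamic response peaking at 5 s,
with AR(1)-plus-white noise added.

The task simulator maps latent reinstatement intensity e to pattern
amplitude through an affine transfer amp0 + amp_scale * e, calibrated so
that the decoder's probability readout tracks e approximately one-to-one
(see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .behavior import PERIODS, ReinstatementTrace
from .design import DNMSTrialSpec, ExperimentDesign

__all__ = [
    "TRAINED_CLASSES",
    "LOCALIZER_KINDS",
    "VoxelPatternBank",
    "BoldRun",
    "BoldParams",
    "make_pattern_bank",
    "hrf_kernel",
    "hrf_convolve",
    "simulate_localizer_run",
    "simulate_dnms_run",
    "highpass",
    "context_class",
]

TRAINED_CLASSES = ("face-left", "face-right", "scene-left", "scene-right")
_EXTRA_CLASSES = ("object", "scrambled")
LOCALIZER_KINDS = TRAINED_CLASSES + (
    "object-left", "object-right", "scrambled-left", "scrambled-right",
)


def context_class(design: ExperimentDesign, context_id: str) -> str:
    """Map a context set to its decoder class name (picture kind + side)."""
    cs = design.set_by_id(context_id)
    return f"{cs.picture_kind}-{cs.side}"


@dataclass
class VoxelPatternBank:
    patterns: dict[str, np.ndarray]
    selectivity: float

    @property
    def n_voxels(self) -> int:
        return len(next(iter(self.patterns.values())))

    def pattern_for_kind(self, kind: str) -> np.ndarray:
        """Localizer block kind -> pattern (object/scrambled are side-agnostic)."""
        if kind in self.patterns:
            return self.patterns[kind]
        base = kind.rsplit("-", 1)[0]
        return self.patterns[base]


@dataclass
class BoldRun:
    tr_seconds: float
    data: np.ndarray  # (T, V)
    label: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (T, V)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD run contains missing samples")

    @property
    def n_trs(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class BoldParams:
    """Acquisition and noise settings shared by the run simulators.

    The default selectivity/noise pair is chosen so four-way localizer
    decoding lands near the two-thirds accuracy regime typical of
    category-selective visual ROIs, rather than at ceiling.
    """

    tr_seconds: float = 1.0
    n_voxels: int = 48
    selectivity: float = 0.6
    lead_in_s: float = 12.0
    lead_out_s: float = 8.0
    noise_sd: float = 1.0
    ar_rho: float = 0.3
    # localizer timing
    stim_s: float = 0.5
    isi_s: float = 1.5
    stims_per_block: int = 10
    interblock_s: float = 12.0
    blocks_per_kind: int = 3
    # task timing
    target_s: float = 2.0
    delay_s: float = 18.0
    probe_s: float = 4.0
    iti_s: float = 6.0
    # intensity -> amplitude transfer (calibrated; see docs/methods.md)
    amp0: float = 0.0
    amp_scale: float = 1.0
    task_noise_sd: float | None = None  # defaults to noise_sd

    @property
    def block_s(self) -> float:
        return self.stims_per_block * (self.stim_s + self.isi_s)


def low_noise_bold_params(**overrides) -> BoldParams:
    """Low-noise acquisition used for parameter-recovery experiments.

    High pattern selectivity, moderate localizer noise (so logistic margins
    stay finite), very low task-run noise, and an amplitude scale calibrated
    so the decoder's probability output tracks the latent intensity with
    unit slope (a constant offset is absorbed by the regression intercepts).
    Pair with a strong ridge (lam ~ 50) when decoding, which keeps the
    probability readout in its linear range; see docs/methods.md.
    """
    base = dict(selectivity=3.0, noise_sd=0.6, task_noise_sd=0.02,
                amp0=0.0, amp_scale=1.8)
    base.update(overrides)
    return BoldParams(**base)


def make_pattern_bank(n_voxels: int, selectivity: float, seed) -> VoxelPatternBank:
    """Class patterns = shared component + selectivity x class-specific
    component, renormalized to unit norm.  selectivity = 0 makes every class
    pattern identical (no decodable signal)."""
    if n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    shared = rng.normal(size=n_voxels)
    patterns = {}
    for name in TRAINED_CLASSES + _EXTRA_CLASSES:
        specific = rng.normal(size=n_voxels)
        v = shared + selectivity * specific
        patterns[name] = v / np.linalg.norm(v)
    return VoxelPatternBank(patterns=patterns, selectivity=float(selectivity))


def hrf_kernel(tr_seconds: float, duration_s: float = 30.0) -> np.ndarray:
    """Double-gamma hemodynamic response sampled at the TR; peak at ~5 s.

    Positive lobe Gamma(shape=6, scale=1) (mode 5 s), undershoot
    Gamma(shape=16, scale=1) weighted 1/6; normalized to peak 1.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration_s + 1e-9, tr_seconds)
    h = gamma_dist.pdf(t, a=6.0, scale=1.0) - gamma_dist.pdf(t, a=16.0, scale=1.0) / 6.0
    return h / h.max()


def hrf_convolve(neural: np.ndarray, tr_seconds: float) -> np.ndarray:
    """Causal linear convolution of a (T,) or (T, V) neural series with the
    double-gamma kernel, truncated to the input length."""
    neural = np.asarray(neural, dtype=float)
    h = hrf_kernel(tr_seconds)
    if neural.ndim == 1:
        return signal.fftconvolve(neural, h)[: len(neural)]
    out = signal.fftconvolve(neural, h[:, None], axes=0)
    return out[: neural.shape[0]]


def _noise(rng: np.random.Generator, shape: tuple[int, int], sd: float, rho: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    white = rng.normal(0.0, sd, size=shape)
    if rho == 0:
        return white
    # AR(1) along time, stationary-variance scaled
    ar = signal.lfilter([1.0], [1.0, -rho], white, axis=0)
    return ar * np.sqrt(1.0 - rho**2)


def simulate_localizer_run(
    bank: VoxelPatternBank,
    params: BoldParams,
    seed,
) -> tuple[BoldRun, pd.DataFrame]:
    """One localizer run: 24 miniblocks (8 kinds x 3), 20-s blocks of ten
    2-s stimulus slots, 12-s interblock intervals.

    Events table columns: onset, duration, trial_type, block, trial (the
    within-block stimulus index; two of the ten stimuli per block repeat the
    previous image, which does not change the neural model here).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    kinds = np.repeat(np.asarray(LOCALIZER_KINDS, dtype=object), params.blocks_per_kind)
    kinds = rng.permutation(kinds)
    tr = params.tr_seconds
    total_s = params.lead_in_s + len(kinds) * (params.block_s + params.interblock_s)
    n_trs = int(round(total_s / tr))
    neural = np.zeros((n_trs, bank.n_voxels))
    rows = []
    t0 = params.lead_in_s
    for b, kind in enumerate(kinds):
        onset = t0 + b * (params.block_s + params.interblock_s)
        i0, i1 = int(round(onset / tr)), int(round((onset + params.block_s) / tr))
        neural[i0:i1] += bank.pattern_for_kind(str(kind))
        rows.append({"onset": onset, "duration": params.block_s,
                     "trial_type": str(kind), "block": b, "trial": b})
    clean = hrf_convolve(neural, tr)
    data = clean + _noise(rng, clean.shape, params.noise_sd, params.ar_rho)
    return BoldRun(tr_seconds=tr, data=data, label="localizer"), pd.DataFrame(rows)


def simulate_dnms_run(
    trials: list[DNMSTrialSpec],
    trace: ReinstatementTrace,
    bank: VoxelPatternBank,
    design: ExperimentDesign,
    params: BoldParams,
    seed,
) -> tuple[BoldRun, pd.DataFrame]:
    """One DNMS task run coupled to the latent reinstatement trace.

    Trial timeline: targets ``target_s`` (2 s), delay ``delay_s`` (18 s; probe
    onset at 20 s), probe ``probe_s``, then ITI.  During each period every
    context's class pattern enters the neural signal with amplitude
    amp0 + amp_scale * trace intensity.
    """
    if trace.intensity.shape[0] < len(trials):
        raise ValueError("trace does not cover all trials")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tr = params.tr_seconds
    trial_s = params.target_s + params.delay_s + params.probe_s + params.iti_s
    total_s = params.lead_in_s + len(trials) * trial_s + params.lead_out_s
    n_trs = int(round(total_s / tr))
    neural = np.zeros((n_trs, bank.n_voxels))
    class_patterns = np.stack(
        [bank.patterns[context_class(design, c)] for c in trace.context_ids]
    )  # (n_contexts, V)
    period_bounds = {
        "target_presentation": (0.0, params.target_s),
        "delay": (params.target_s, params.target_s + params.delay_s),
        "probe_presentation": (
            params.target_s + params.delay_s,
            params.target_s + params.delay_s + params.probe_s,
        ),
    }
    rows = []
    for i, t in enumerate(trials):
        t_on = params.lead_in_s + i * trial_s
        for p, period in enumerate(PERIODS):
            lo, hi = period_bounds[period]
            i0, i1 = int(round((t_on + lo) / tr)), int(round((t_on + hi) / tr))
            amps = params.amp0 + params.amp_scale * trace.intensity[i, p, :]
            neural[i0:i1] += amps @ class_patterns
            rows.append({"onset": t_on + lo, "duration": hi - lo,
                         "trial_type": period, "block": i, "trial": t.index})
    clean = hrf_convolve(neural, tr)
    sd = params.noise_sd if params.task_noise_sd is None else params.task_noise_sd
    data = clean + _noise(rng, clean.shape, sd, params.ar_rho)
    return BoldRun(tr_seconds=tr, data=data, label="dnms"), pd.DataFrame(rows)


def highpass(run: BoldRun, cutoff_seconds: float = 128.0) -> BoldRun:
    """Remove drifts slower than the cutoff by regressing out a
    discrete-cosine basis (plus the mean)."""
    T = run.n_trs
    if T * run.tr_seconds <= cutoff_seconds:
        raise ValueError("run shorter than one cutoff period")
    n_basis = int(np.floor(2.0 * T * run.tr_seconds / cutoff_seconds))
    t = np.arange(T)
    basis = [np.ones(T)]
    for k in range(1, n_basis + 1):
        basis.append(np.cos(np.pi * k * (t + 0.5) / T))
    X = np.column_stack(basis)
    beta, *_ = np.linalg.lstsq(X, run.data, rcond=None)
    return BoldRun(tr_seconds=run.tr_seconds, data=run.data - X @ beta, label=run.label)
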