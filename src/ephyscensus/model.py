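"""Core domain containers: cell model parameters, recordings, cohort designs.

Units follow whole-cell patch-clamp conventions: potentials in mV, currents
in pA, capacitance in pF, membrane resistance in GOhm, access resistance in
MOhm, times in ms unless noted. Note the convenient identities
GOhm * pF = ms and GOhm * pA = mV, which the simulator exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from enum import Enum
import numpy as np

FS_HZ = 10_000.0
"""Sampling rate of every recording (Hz); all protocols are digitized at 10 kHz."""

DT_MS = 1000.0 / FS_HZ


class Protocol(str, Enum):
    IV_STEPS = "iv_steps"
    CURRENT_STEPS = "current_steps"
    COSINE = "cosine"
    SYNAPTIC = "synaptic"
    SPONTANEOUS = "spontaneous"


class StageGroup(str, Enum):
    S43_44 = "s43_44"
    S45_46 = "s45_46"
    S47 = "s47"
    S48_49 = "s48_49"


class Condition(str, Enum):
    NAIVE = "naive"
    STIMULATED = "stimulated"


# Protocol constants (Materials-and-methods level description of the rig
# protocols the simulator reproduces).
IV_STEP_POTENTIALS_MV = tuple(float(v) for v in range(-65, 116, 20))  # 10 steps
IV_STEP_DURATION_MS = 150.0
CURRENT_STEPS_PA = tuple(float(i) for i in range(0, 181, 20))  # 10 steps
COSINE_FREQS_HZ = (100.0, 50.0, 30.0, 25.0, 20.0)
COSINE_BOUT_MS = 200.0
COSINE_AMP_PA = 135.0
COSINE_N_SWEEPS = 10
SYNAPTIC_ISIS_MS = (10.0, 20.0, 30.0, 40.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0)
SYNAPTIC_N_REPEATS = 5
SYNAPTIC_N_STIMULI = 5
SPONTANEOUS_DURATION_S = 60.0


@dataclass
class CellModelParams:
    """Ground-truth generative parameters of one simulated tectal cell.

    The generator is phenomenological: every extracted variable has an exact
    generative counterpart here, so recovery tests have a closed-form oracle.
    """

    # passive / seal-test
    cm: float = 10.0          # membrane capacitance, pF
    rm: float = 1.5           # membrane resistance, GOhm
    ra: float = 40.0          # access resistance, MOhm
    e_rest: float = -49.0     # resting potential, mV
    # voltage-gated currents (IV-curve ground truth)
    na_act: float = -35.0     # Na+ half-activation, mV
    na_max: float = -400.0    # peak Na+ current, pA (<= 0)
    ks_act: float = -20.0     # stable-K+ empirical activation potential, mV
    ks_max: float = 300.0     # stable-K+ current at the top of the IV range, pA
    kt_act: float = -25.0     # transient-K+ half-activation, mV
    kt_max: float = 250.0     # transient-K+ peak current, pA
    # step-current spiking
    spike_gain: float = 5.0   # peak of the spikes-vs-current tuning curve
    spike_adapt: float = 60.0  # current-domain decay scale of that curve, pA
    spike_thresh: float = -40.0  # kink (threshold) potential, mV
    # spike waveform ground truth
    spike_amp: float = 55.0   # kink-to-peak amplitude, mV
    spike_rise: float = 0.5   # 10-90% rise time, ms
    spike_width: float = 1.2  # width at half-height, ms
    # spike-train dynamics
    isi_first: float = 18.0   # first inter-spike interval at the best current, ms
    isi_accom: float = 1.25   # ISI2/ISI1 ratio (>1 = slowing)
    amp_accom: float = 0.9    # amplitude2/amplitude1 ratio (<1 = accommodation)
    spike_jitter: float = 0.8  # SD of per-sweep spike-time jitter, ms
    # cosine-injection tuning
    cos_resonance: float = 40.0  # optimal cosine period, ms
    cos_width: float = 60.0      # build-up scale b of the period tuning curve, ms
    cos_gain: float = 0.8        # peak spikes per cosine wave
    wave_buildup: float = 4.0    # wave index of maximal spiking at 100 Hz
    wave_decay: float = 3.0      # decay constant of per-wave adaptation (waves)
    # synaptic stimulation
    syn_amp: float = 1.0      # unitary (non-facilitated) charge per stimulus, pA*s
    syn_facil: float = 0.8    # fractional facilitation at the optimal ISI
    syn_tau: float = 40.0     # ISI of maximal facilitation, ms
    poly_amp: float = 0.0     # mean polysynaptic current in the late window, pA
    # spontaneous activity
    mini_rate: float = 1.0    # mEPSC rate, Hz
    mini_amp: float = 12.0    # mean mEPSC amplitude, pA
    # shared
    noise_sd: float = 2.0     # Gaussian noise SD (pA in VC, mV in CC)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cm <= 0 or self.rm <= 0:
            raise ValueError("cm and rm must be positive")
        if self.na_max > 0:
            raise ValueError("na_max is the peak inward current and must be <= 0")
        if self.ks_max < 0 or self.kt_max < 0:
            raise ValueError("potassium current amplitudes must be >= 0")
        if self.mini_rate < 0 or self.noise_sd < 0:
            raise ValueError("mini_rate and noise_sd must be >= 0")
        if self.spike_width <= self.spike_rise / 0.8 / 2:
            raise ValueError("spike_width too small for the requested rise time")

    @property
    def tau_m(self) -> float:
        """Membrane time constant, ms (rm [GOhm] * cm [pF])."""
        return self.rm * self.cm

    @property
    def i_hold(self) -> float:
        """Holding current to keep the membrane at -65 mV, pA.

        I_hold = (-65 - Em) / Rm with Rm in GOhm giving pA directly.
        """
        return (-65.0 - self.e_rest) / self.rm

    def replace(self, **kw) -> "CellModelParams":
        return replace(self, **kw)


@dataclass
class Recording:
    """A protocol-tagged set of equally sampled sweeps with stimulus metadata.

    ``sweeps`` is (n_sweeps, n_samples), mV for current-clamp protocols and pA
    for voltage-clamp protocols. ``stimulus`` is a per-sweep list of dicts
    describing the command (step potential, injected current, cosine bout
    layout, or shock times).
    """

    protocol: Protocol
    sweeps: np.ndarray
    stimulus: list[dict]
    cell_id: str = "cell"
    stage_group: StageGroup = StageGroup.S48_49
    condition: Condition = Condition.NAIVE
    fs: float = FS_HZ
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim == 1:
            self.sweeps = self.sweeps[None, :]
        if len(self.stimulus) != self.sweeps.shape[0]:
            raise ValueError("stimulus descriptors must cover every sweep")
        if self.fs != FS_HZ:
            raise ValueError("all recordings are digitized at 10 kHz")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(self.sweeps.shape[1]) * (1000.0 / self.fs)


@dataclass
class GroupSpec:
    """Distribution of CellModelParams within one (stage_group, condition) cell group."""

    n_cells: int
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class CohortDesign:
    """Design of a synthetic cohort: group sizes, parameter distributions, missingness."""

    groups: dict[tuple[StageGroup, Condition], GroupSpec]
    missing_rate: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_cells(self) -> int:
        return sum(g.n_cells for g in self.groups.values())


def param_names() -> list[str]:
    return [f.name for f in fields(CellModelParams)]
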