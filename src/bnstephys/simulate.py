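"""Single-compartment simulator for the four intrinsic phenotypes.

The model is a phenomenological hybrid: a leaky single compartment carrying
slow gated currents, with threshold spike emission (reset, refractory period,
spike-triggered adaptation) instead of explicit Na/K spike currents.

Membrane equation (current clamp)::

    C dV/dt = -I_leak - I_h - I_T - I_D - I_R - w + I_bias + I_inj + noise

with

``I_leak = g_L (V - E_L)``
    passive leak; sets input resistance and, together with I_h, the RMP.
``I_h = g_h r (V - E_h)``
    hyperpolarization-activated cation current (HCN).  One first-order gate
    ``r`` with sigmoidal steady state (half-activation ``vhalf_h``) and fixed
    time constant ``tau_h``; produces the voltage sag and the slow inward
    relaxation seen in voltage clamp.
``I_T = g_T m_inf(V)^2 h (V - E_T)``
    low-threshold transient current.  Activation instantaneous, inactivation
    gate ``h`` de-inactivates during hyperpolarization and produces rebound
    bursts on release.  Only the Type II template carries it.
``I_D = g_D a_inf(V) b (V - E_K)``
    slowly inactivating K+ (D-type) current.  Fast perithreshold activation
    plus slow inactivation ``b`` delays the first spike and raises rheobase;
    only the "Others" template carries it.
``I_R = g_R a_R(V) (V - E_K)``
    instantaneous outward rectifier engaged above ~-20 mV.  It bounds the
    depolarized plateau during depolarization block so that blocked sweeps sit
    in a realistic -25..-5 mV band.
``w``
    spike-triggered adaptation current, incremented by ``adapt_inc`` per
    spike and decaying with ``adapt_tau``.

Spikes: when V crosses the dynamic threshold (and the neuron is not
refractory or blocked) a spike is pasted into the trace at ``V_PEAK`` and V
is reset.  The threshold itself adapts: it climbs by ``th_adapt_inc`` per
spike and relaxes with ``th_adapt_tau`` — the phenomenological counterpart
of cumulative Na-channel inactivation.  Under sustained strong drive the
threshold (and with it the inter-spike voltage range) ratchets upward until
the 5 ms low-pass-filtered voltage exceeds ``V_block``, which disables spike
emission — the depolarization-block rule.  Emission stays disabled while the
filtered voltage remains above ``V_block``; since the blocked plateau
(bounded by the rectifier) sits above every template's ``V_block``, block
latches for the rest of the step, as observed in these neurons.  During the
refractory period V keeps integrating without emitting, so at very strong
drive the refractory excursions alone can trigger the same rule.

Voltage clamp is ideal: V follows the command exactly and the recorded
current is the sum of ionic currents (outward positive).

Units: mV, ms, pA, pF, nS throughout (so g*V is pA and C dV/dt balances).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .protocols import ProtocolSpec, EXCITABILITY, IH, MFR, RMP, CANONICAL
from .traces import Sweep, SweepSet, NeuronRecord, AP_PLANES

# ---------------------------------------------------------------------------
# fixed channel-shape constants (shared by all phenotypes)

E_K = -90.0          # K+ reversal, mV
E_T = 40.0           # low-threshold current reversal, mV

MT_HALF, MT_K = -52.0, 5.0       # I_T activation
HT_HALF, HT_K = -78.0, 5.0       # I_T inactivation
TAU_HT_DEP, TAU_HT_HYP = 25.0, 100.0   # I_T inactivation tau, depol/hyperpol
AD_HALF, AD_K = -50.0, 4.0       # I_D activation (instantaneous)
BD_HALF, BD_K = -58.0, 4.0       # I_D inactivation
TAU_BD = 300.0                   # I_D inactivation tau, ms
AR_HALF, AR_K = -15.0, 5.0       # outward rectifier activation
G_R = 25.0                       # outward rectifier conductance, nS
V_PEAK = 35.0                    # pasted spike peak, mV
TAU_FILT = 5.0                   # block-rule low-pass filter, ms


class SimulationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass(frozen=True)
class PhenotypeParams:
    """Ground-truth parameters of one synthetic neuron."""

    phenotype: str               # one of {"I", "II", "III", "Others"}
    C_m: float                   # capacitance, pF
    g_L: float                   # leak conductance, nS
    E_L: float                   # leak reversal, mV
    g_h: float                   # HCN maximal conductance, nS
    g_T: float                   # low-threshold conductance, nS (Type II only)
    g_D: float                   # slowly inactivating K conductance, nS
    E_h: float = -50.0           # effective I_h reversal, mV
    vhalf_h: float = -82.0       # I_h half-activation, mV
    k_h: float = 6.0             # I_h activation slope, mV
    tau_h: float = 100.0         # I_h gate time constant, ms
    threshold: float = -52.0     # spike emission threshold (resting), mV
    reset: float = -56.0         # post-spike reset, mV
    refractory: float = 3.0      # ms
    adapt_inc: float = 10.0      # adaptation increment per spike, pA
    adapt_tau: float = 150.0     # adaptation decay, ms
    adapt_max: float = 1e9       # adaptation saturation, pA
    th_adapt_inc: float = 0.0    # threshold climb per spike, mV
    th_adapt_tau: float = 200.0  # threshold relaxation, ms
    V_block: float = -35.0       # depolarization-block voltage, mV
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.phenotype not in ("I", "II", "III", "Others"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")
        if self.g_L <= 0:
            raise ValueError("g_L must be > 0")
        for name in ("g_h", "g_T", "g_D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def pack(self) -> np.ndarray:
        """Flatten to the float vector consumed by the numba kernels."""
        return np.array(
            [
                self.C_m, self.g_L, self.E_L,
                self.g_h, self.E_h, self.vhalf_h, self.tau_h,
                self.g_T, self.g_D,
                self.threshold, self.reset, self.refractory,
                self.adapt_inc, self.adapt_tau, self.V_block,
                self.th_adapt_inc, self.th_adapt_tau,
                self.adapt_max, self.k_h,
            ],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class SimConfig:
    """Integration settings shared across a cohort."""

    dt: float = 0.05             # ms; fixed-step explicit integration
    noise_sd: float = 0.0        # per-sample injected current noise, pA
    holding_potential: float = -60.0   # mV, current-clamp holding
    jitter: float = 0.1          # lognormal sd for cohort parameter jitter
    n_per_type: tuple = (30, 30, 30, 30)

    def __post_init__(self) -> None:
        if not (0 < self.dt <= 0.05):
            raise ValueError("dt must satisfy 0 < dt <= 0.05 ms")
        if any(n < 0 for n in self.n_per_type):
            raise ValueError("n_per_type entries must be >= 0")


# ---------------------------------------------------------------------------
# template parameter sets
#
# Tuned so that each template expresses its class-defining signature with wide
# margins: Type I — large sag, no rebound; Type II — sag, rebound burst, high
# input resistance, early depolarization block; Type III — no sag, no rebound;
# "Others" — late single-spike firing (D-current), hyperpolarized RMP, large
# capacitance, deeply-activating I_h (big clamp current, no sag).

TEMPLATES: dict[str, PhenotypeParams] = {
    "I": PhenotypeParams(
        phenotype="I", C_m=50.0, g_L=1.4, E_L=-66.0,
        g_h=1.8, g_T=0.0, g_D=0.0, vhalf_h=-102.0, k_h=4.0, tau_h=100.0,
        threshold=-54.0, reset=-60.0, refractory=3.0,
        adapt_inc=15.0, adapt_tau=150.0,
        th_adapt_inc=2.1, th_adapt_tau=100.0, V_block=-36.0,
    ),
    "II": PhenotypeParams(
        phenotype="II", C_m=25.0, g_L=0.8, E_L=-69.0,
        g_h=0.4, g_T=8.0, g_D=0.0, vhalf_h=-110.0, k_h=4.0, tau_h=100.0,
        threshold=-51.0, reset=-55.0, refractory=3.0,
        adapt_inc=4.0, adapt_tau=120.0,
        th_adapt_inc=0.25, th_adapt_tau=200.0, V_block=-40.0,
    ),
    "III": PhenotypeParams(
        phenotype="III", C_m=55.0, g_L=1.3, E_L=-64.0,
        g_h=0.05, g_T=0.0, g_D=0.0, vhalf_h=-95.0, k_h=6.0, tau_h=100.0,
        threshold=-54.5, reset=-60.5, refractory=3.0,
        adapt_inc=12.0, adapt_tau=150.0,
        th_adapt_inc=2.0, th_adapt_tau=70.0, V_block=-34.0,
    ),
    "Others": PhenotypeParams(
        phenotype="Others", C_m=110.0, g_L=4.0, E_L=-76.0,
        g_h=10.0, g_T=0.0, g_D=2.0, vhalf_h=-112.0, k_h=5.0, tau_h=150.0,
        threshold=-50.0, reset=-55.0, refractory=2.0,
        adapt_inc=60.0, adapt_tau=2000.0, adapt_max=300.0,
        th_adapt_inc=0.02, th_adapt_tau=200.0, V_block=-24.0,
    ),
}

PHENOTYPES = ("I", "II", "III", "Others")


# ---------------------------------------------------------------------------
# gate steady states (python side, used for bias / analytic ground truth)

def _sig(v: float, half: float, k: float) -> float:
    return 1.0 / (1.0 + math.exp((v - half) / k))


def r_inf(v: float, p: PhenotypeParams) -> float:
    return _sig(v, p.vhalf_h, p.k_h)


def mT_inf(v: float) -> float:
    return _sig(v, MT_HALF, -MT_K)


def hT_inf(v: float) -> float:
    return _sig(v, HT_HALF, HT_K)


def aD_inf(v: float) -> float:
    return _sig(v, AD_HALF, -AD_K)


def bD_inf(v: float) -> float:
    return _sig(v, BD_HALF, BD_K)


def aR_inf(v: float) -> float:
    return _sig(v, AR_HALF, -AR_K)


def steady_state_current(v: float, p: PhenotypeParams) -> float:
    """Total steady-state ionic current (pA, outward positive) at voltage v."""
    i = p.g_L * (v - p.E_L)
    i += p.g_h * r_inf(v, p) * (v - p.E_h)
    i += p.g_T * mT_inf(v) ** 2 * hT_inf(v) * (v - E_T)
    i += p.g_D * aD_inf(v) * bD_inf(v) * (v - E_K)
    i += G_R * aR_inf(v) * (v - E_K)
    return i


def holding_bias(p: PhenotypeParams, holding: float = -60.0) -> float:
    """Constant bias current (pA) that holds the neuron at ``holding`` mV.

    Mirrors what the amplifier does: pre-computed once per neuron, applied
    throughout current-clamp sweeps.
    """
    return steady_state_current(holding, p)


def resting_potential(p: PhenotypeParams) -> float:
    """Analytic zero-current fixed point (ground-truth RMP, mV)."""
    from scipy.optimize import brentq

    return float(brentq(lambda v: steady_state_current(v, p), -110.0, -35.0,
                        xtol=1e-10))


def steady_state_voltage(p: PhenotypeParams, current: float,
                         holding: float = -60.0) -> float:
    """Steady-state V (mV) under bias + ``current`` pA injected (ground truth)."""
    from scipy.optimize import brentq

    total = holding_bias(p, holding) + current
    return float(brentq(lambda v: steady_state_current(v, p) - total,
                        -150.0, 20.0, xtol=1e-10))


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _cc_kernel(cmd, dt, pp, bias, noise, v0, r0, h0, b0):  # pragma: no cover
    C = pp[0]; gL = pp[1]; EL = pp[2]
    gh = pp[3]; Eh = pp[4]; vh = pp[5]; tau_h = pp[6]
    gT = pp[7]; gD = pp[8]
    vth = pp[9]; vreset = pp[10]; refrac = pp[11]
    winc = pp[12]; wtau = pp[13]; vblock = pp[14]
    qinc = pp[15]; qtau = pp[16]
    wmax = pp[17]; kh = pp[18]

    n = cmd.shape[0]
    out = np.empty(n, dtype=np.float64)
    v = v0
    r = r0
    h = h0
    b = b0
    w = 0.0
    q = 0.0
    vf = v0
    refrac_steps = int(refrac / dt + 0.5)
    i_allowed = 0
    armed = v0 < vth    # emission needs an upward crossing of the threshold
    a_r = math.exp(-dt / tau_h)
    a_b = math.exp(-dt / TAU_BD)
    a_w = math.exp(-dt / wtau)
    a_q = math.exp(-dt / qtau)
    a_f = math.exp(-dt / TAU_FILT)

    for i in range(n):
        ih = gh * r * (v - Eh)
        mt = 1.0 / (1.0 + math.exp((v - MT_HALF) / (-MT_K)))
        it = gT * mt * mt * h * (v - E_T)
        ad = 1.0 / (1.0 + math.exp((v - AD_HALF) / (-AD_K)))
        idcur = gD * ad * b * (v - E_K)
        ar = 1.0 / (1.0 + math.exp((v - AR_HALF) / (-AR_K)))
        ir = G_R * ar * (v - E_K)
        ileak = gL * (v - EL)

        dv = (-(ileak + ih + it + idcur + ir) - w + bias + cmd[i] + noise[i]) / C
        v = v + dt * dv

        rss = 1.0 / (1.0 + math.exp((v - vh) / kh))
        r = rss + (r - rss) * a_r
        hss = 1.0 / (1.0 + math.exp((v - HT_HALF) / HT_K))
        tau_ht = TAU_HT_DEP + (TAU_HT_HYP - TAU_HT_DEP) / (
            1.0 + math.exp((v + 70.0) / 5.0))
        h = hss + (h - hss) * math.exp(-dt / tau_ht)
        bss = 1.0 / (1.0 + math.exp((v - BD_HALF) / BD_K))
        b = bss + (b - bss) * a_b
        w = w * a_w
        q = q * a_q
        vf = v + (vf - v) * a_f

        if v < vth + q:
            armed = True
        if vf > vblock:
            armed = False       # re-arming requires recovery from block
        if armed and v >= vth + q and i >= i_allowed and vf <= vblock:
            out[i] = V_PEAK
            v = vreset + q          # reset tracks the adapted threshold
            w = min(w + winc, wmax)
            q = q + qinc
            i_allowed = i + refrac_steps
            armed = False
        else:
            out[i] = v
    return out


@njit(cache=True)
def _vc_kernel(cmd, dt, pp, r0, h0, b0):  # pragma: no cover
    gL = pp[1]; EL = pp[2]
    gh = pp[3]; Eh = pp[4]; vh = pp[5]; tau_h = pp[6]
    gT = pp[7]; gD = pp[8]
    kh = pp[18]

    n = cmd.shape[0]
    out = np.empty(n, dtype=np.float64)
    r = r0
    h = h0
    b = b0
    a_r = math.exp(-dt / tau_h)
    a_b = math.exp(-dt / TAU_BD)

    for i in range(n):
        v = cmd[i]
        ih = gh * r * (v - Eh)
        mt = 1.0 / (1.0 + math.exp((v - MT_HALF) / (-MT_K)))
        it = gT * mt * mt * h * (v - E_T)
        ad = 1.0 / (1.0 + math.exp((v - AD_HALF) / (-AD_K)))
        idcur = gD * ad * b * (v - E_K)
        ar = 1.0 / (1.0 + math.exp((v - AR_HALF) / (-AR_K)))
        ir = G_R * ar * (v - E_K)
        out[i] = gL * (v - EL) + ih + it + idcur + ir

        rss = 1.0 / (1.0 + math.exp((v - vh) / kh))
        r = rss + (r - rss) * a_r
        hss = 1.0 / (1.0 + math.exp((v - HT_HALF) / HT_K))
        tau_ht = TAU_HT_DEP + (TAU_HT_HYP - TAU_HT_DEP) / (
            1.0 + math.exp((v + 70.0) / 5.0))
        h = hss + (h - hss) * math.exp(-dt / tau_ht)
        bss = 1.0 / (1.0 + math.exp((v - BD_HALF) / BD_K))
        b = bss + (b - bss) * a_b
    return out


# ---------------------------------------------------------------------------
# public simulation entry points

def simulate_current_clamp(
    params: PhenotypeParams,
    protocol: ProtocolSpec,
    config: SimConfig = SimConfig(),
    rng: Optional[np.random.Generator] = None,
) -> SweepSet:
    """Simulate voltage responses to every step of a current-clamp protocol.

    If ``protocol.apply_holding`` a per-neuron bias current holds the cell at
    the holding potential and the sweep starts from that steady state;
    otherwise (RMP measurement) no bias is applied and the sweep starts from
    the leak reversal, settling to the zero-current fixed point.
    """
    if protocol.mode != "current_clamp":
        raise ValueError(
            f"protocol {protocol.name!r} is not a current-clamp protocol")
    dt = config.dt
    pp = params.pack()
    hold = getattr(protocol, "apply_holding", True)
    if hold:
        v0 = config.holding_potential
        bias = holding_bias(params, v0)
    else:
        v0 = params.E_L
        bias = 0.0
    r0 = r_inf(v0, params)
    h0 = hT_inf(v0)
    b0 = bD_inf(v0)
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)

    sweeps = []
    for amp in protocol.amplitudes:
        cmd = protocol.command_waveform(amp, dt)
        if config.noise_sd > 0:
            noise = rng.normal(0.0, config.noise_sd, size=cmd.size)
        else:
            noise = np.zeros(cmd.size)
        resp = _cc_kernel(cmd, dt, pp, bias, noise, v0, r0, h0, b0)
        if not np.all(np.isfinite(resp)):
            raise SimulationError(
                f"non-finite state in sweep {protocol.name}@{amp:g} pA")
        sweeps.append(Sweep(dt=dt, command=cmd, response=resp,
                            step_amplitude=amp, mode="current_clamp",
                            protocol=protocol))
    return SweepSet(protocol=protocol, sweeps=sweeps)


def simulate_voltage_clamp(
    params: PhenotypeParams,
    protocol: ProtocolSpec,
    config: SimConfig = SimConfig(),
) -> SweepSet:
    """Simulate clamp currents for every step of a voltage-clamp protocol."""
    if protocol.mode != "voltage_clamp":
        raise ValueError(
            f"protocol {protocol.name!r} is not a voltage-clamp protocol")
    dt = config.dt
    pp = params.pack()
    v0 = protocol.holding
    r0 = r_inf(v0, params)
    h0 = hT_inf(v0)
    b0 = bD_inf(v0)

    sweeps = []
    for amp in protocol.amplitudes:
        cmd = protocol.command_waveform(amp, dt)
        resp = _vc_kernel(cmd, dt, pp, r0, h0, b0)
        if not np.all(np.isfinite(resp)):
            raise SimulationError(
                f"non-finite state in sweep {protocol.name}@{amp:g} mV")
        sweeps.append(Sweep(dt=dt, command=cmd, response=resp,
                            step_amplitude=amp, mode="voltage_clamp",
                            protocol=protocol))
    return SweepSet(protocol=protocol, sweeps=sweeps)


# ---------------------------------------------------------------------------
# cohorts

#: sampling weights of the four rostro-caudal recording planes (caudal-heavy,
#: matching the anatomical distribution of the projection)
AP_WEIGHTS = (0.10, 0.45, 0.35, 0.10)

_JITTERED = ("C_m", "g_L", "g_h", "g_T", "g_D")
_EL_JITTER_SCALE = 20.0   # additive E_L sd = jitter * this, mV


def make_cohort(
    n_per_type: Sequence[int] = (30, 30, 30, 30),
    jitter: float = 0.1,
    seed: int = 0,
) -> list[PhenotypeParams]:
    """Draw a cohort of jittered neurons around the four templates.

    Multiplicative lognormal jitter (sd ``jitter`` in log space, clipped to
    ±2.5 sd) on capacitance and conductances, additive Gaussian jitter on
    E_L.  Conductances that are zero in a template stay exactly zero, so the
    template-level constraints (e.g. Type III never gains a sag-producing
    g_h) survive jitter.  Deterministic given ``seed``.
    """
    if len(n_per_type) != 4:
        raise ValueError("n_per_type must have one entry per phenotype")
    if any(int(n) < 0 for n in n_per_type):
        raise ValueError("n_per_type entries must be >= 0")
    rng = np.random.default_rng(seed)
    cohort: list[PhenotypeParams] = []
    idx = 0
    for pheno, n in zip(PHENOTYPES, n_per_type):
        tpl = TEMPLATES[pheno]
        for _ in range(int(n)):
            upd: dict = {}
            for name in _JITTERED:
                base = getattr(tpl, name)
                z = float(np.clip(rng.standard_normal(), -2.5, 2.5))
                upd[name] = base * math.exp(jitter * z) if base > 0 else 0.0
            zel = float(np.clip(rng.standard_normal(), -2.5, 2.5))
            upd["E_L"] = tpl.E_L + jitter * _EL_JITTER_SCALE * zel
            upd["rng_seed"] = int(rng.integers(0, 2**31 - 1))
            cohort.append(replace(tpl, **upd))
            idx += 1
    return cohort


def simulate_neuron(
    params: PhenotypeParams,
    config: SimConfig = SimConfig(),
    neuron_id: str = "n0",
    mouse_id: str = "",
    ap_position_mm: Optional[float] = None,
) -> NeuronRecord:
    """Run all four canonical protocols for one neuron."""
    rng = np.random.default_rng(params.rng_seed)
    rec = NeuronRecord(neuron_id=neuron_id, mouse_id=mouse_id,
                       ap_position_mm=ap_position_mm)
    rec.sweep_sets["rmp"] = simulate_current_clamp(params, RMP, config, rng)
    rec.sweep_sets["excitability"] = simulate_current_clamp(
        params, EXCITABILITY, config, rng)
    rec.sweep_sets["mfr"] = simulate_current_clamp(params, MFR, config, rng)
    rec.sweep_sets["ih"] = simulate_voltage_clamp(params, IH, config)
    return rec
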