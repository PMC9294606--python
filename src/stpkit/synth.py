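"""Ground-truthed synthetic recordings for every protocol the analyses expect.

Every generator is a pure function of (parameters, seed) and returns the
rendered trace(s) together with a :class:`GroundTruth` record of the true
event times / amplitudes / spike features, so detection and measurement
code can be scored exactly.

Default kinetic and rate parameters describe a wild-type cerebellar
nuclear neuron recorded at 50 kHz: ~78 Hz miniature IPSCs of ~57 pA with
biexponential decay (tau_fast 6.25 ms, tau_slow 13.4 ms), 100 Hz evoked
trains, and fast (~0.3 ms half-width) action potentials.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .depletion import AmplitudeSeries, DepletionParams, simulate_train
from .errors import ParameterError
from .signal_core import StimulusProtocol, SweepSet, Trace

__all__ = [
    "KernelParams",
    "GroundTruth",
    "APTemplateSpec",
    "make_kernel",
    "make_ap_template",
    "gen_mini_trace",
    "gen_evoked_sweeps",
    "gen_ap_sweeps",
]


@dataclass(frozen=True)
class KernelParams:
    """Postsynaptic-current kernel: single-exponential rise, biexponential decay.

    All time constants in milliseconds.  ``fast_fraction`` is the weight of
    the fast decay component; ``polarity`` is 'inward' (negative, the usual
    convention for IPSCs with a high-Cl internal) or 'outward'.
    """

    tau_rise: float = 1.3
    tau_fast: float = 6.25
    tau_slow: float = 13.4
    fast_fraction: float = 0.6
    polarity: str = "inward"

    def __post_init__(self):
        if self.tau_rise < 0 or self.tau_fast <= 0 or self.tau_slow <= 0:
            raise ParameterError("time constants must be positive (tau_rise may be 0)")
        if self.tau_slow < self.tau_fast:
            raise ParameterError(
                f"tau_slow ({self.tau_slow}) must be >= tau_fast ({self.tau_fast})"
            )
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise ParameterError("fast_fraction must lie in [0, 1]")
        if self.polarity not in ("inward", "outward"):
            raise ParameterError("polarity must be 'inward' or 'outward'")


@dataclass
class GroundTruth:
    """What the generator actually put into a trace."""

    event_times: np.ndarray          # s, aligned to the sample grid
    amplitudes: np.ndarray | None    # pA (None for voltage traces)
    seed: int | None
    params: dict
    features: dict | None = None               # per-spike construction features
    sweep_amplitudes: np.ndarray | None = None  # (n_sweeps, n_stimuli) pA
    latency_ms: float | None = None             # closed-form first-spike latency


def make_kernel(
    kp: KernelParams,
    sampling_rate: float = 50_000.0,
    duration_ms: float | None = None,
) -> Trace:
    """Peak-normalized synaptic kernel k(t), rendered on the sample grid.

    k(t) = (1 - exp(-t/tau_rise)) * (w exp(-t/tau_fast) + (1-w) exp(-t/tau_slow)),
    scaled so max |k| = 1 and signed by polarity.
    """
    if duration_ms is None:
        duration_ms = 7.0 * kp.tau_slow
    if duration_ms < 5.0 * kp.tau_slow:
        raise ParameterError("kernel duration must be at least 5 * tau_slow")
    n = int(round(duration_ms * 1e-3 * sampling_rate))
    t = np.arange(n) / sampling_rate * 1e3  # ms
    rise = 1.0 - np.exp(-t / kp.tau_rise) if kp.tau_rise > 0 else np.ones_like(t)
    if kp.tau_rise > 0:
        rise[0] = 0.0
    decay = kp.fast_fraction * np.exp(-t / kp.tau_fast) + (
        1.0 - kp.fast_fraction
    ) * np.exp(-t / kp.tau_slow)
    k = rise * decay
    k /= np.max(np.abs(k))
    if kp.polarity == "inward":
        k = -k
    return Trace(k, sampling_rate, kind="current", metadata={"kernel": asdict(kp)})


def _lognormal_amps(
    rng: np.random.Generator, n: int, mean: float, cv: float
) -> np.ndarray:
    """Log-normal amplitudes with the requested arithmetic mean and CV."""
    if mean <= 0:
        raise ParameterError("amp_mean must be > 0")
    if cv < 0:
        raise ParameterError("amp_cv must be >= 0")
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def gen_mini_trace(
    rate: float = 78.1,
    duration: float = 60.0,
    amp_mean: float = 57.4,
    amp_cv: float = 0.3,
    kp: KernelParams | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    sampling_rate: float = 50_000.0,
) -> tuple[Trace, GroundTruth]:
    """Poisson miniature-IPSC trace plus ground truth.

    Event times are homogeneous Poisson at ``rate`` Hz, snapped to the
    sample grid; amplitudes are log-normal with mean ``amp_mean`` (pA) and
    coefficient of variation ``amp_cv``; the rendered trace is the linear
    sum of scaled kernels plus Gaussian noise.  ``noise_sd`` defaults to
    ``amp_mean / 5`` (signal-to-noise ratio 5).
    """
    if rate <= 0 or duration <= 0:
        raise ParameterError("rate and duration must be > 0")
    if kp is None:
        kp = KernelParams()
    if noise_sd is None:
        noise_sd = amp_mean / 5.0
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * sampling_rate))
    n_events = rng.poisson(rate * duration)
    idx = np.sort(rng.integers(0, n_samples, size=n_events))
    amps = _lognormal_amps(rng, n_events, amp_mean, amp_cv)

    impulses = np.zeros(n_samples)
    np.add.at(impulses, idx, amps)
    kernel = make_kernel(kp, sampling_rate).samples
    samples = fftconvolve(impulses, kernel)[:n_samples]
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, size=n_samples)
    trace = Trace(samples, sampling_rate, kind="current", metadata={"synthetic": "minis"})
    truth = GroundTruth(
        event_times=idx / sampling_rate,
        amplitudes=amps,
        seed=seed,
        params={
            "rate": rate,
            "duration": duration,
            "amp_mean": amp_mean,
            "amp_cv": amp_cv,
            "noise_sd": noise_sd,
            "kernel": asdict(kp),
        },
    )
    return trace, truth


def gen_evoked_sweeps(
    dp: DepletionParams,
    protocol: StimulusProtocol,
    kp: KernelParams | None = None,
    noise_sd: float = 0.0,
    n_sweeps: int = 10,
    seed: int = 0,
    sampling_rate: float = 50_000.0,
    pre: float = 0.020,
    post: float = 0.060,
) -> tuple[SweepSet, GroundTruth]:
    """Evoked IPSC sweeps rendered from the depletion model.

    Each sweep draws an amplitude series from :func:`simulate_train`
    (identical across sweeps in deterministic mode), places an impulse of
    that amplitude at each stimulus time and convolves with the synaptic
    kernel; overlapping kernels sum linearly.  The trace spans ``pre``
    seconds before the first stimulus to ``post`` seconds after the last.
    """
    if protocol.n_stimuli < 1:
        raise ParameterError("protocol must contain at least one stimulus")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if kp is None:
        kp = KernelParams()
    kernel = make_kernel(kp, sampling_rate).samples
    t0 = protocol.stimulus_times[0] - pre
    n_samples = int(round((protocol.stimulus_times[-1] + post - t0) * sampling_rate))
    stim_idx = np.round((protocol.stimulus_times - t0) * sampling_rate).astype(int)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_sweeps)
    sweeps = []
    per_sweep = np.empty((n_sweeps, protocol.n_stimuli))
    for s in range(n_sweeps):
        rng = np.random.default_rng(children[s])
        series: AmplitudeSeries = simulate_train(dp, protocol, rng=rng)
        per_sweep[s] = series.amplitude
        impulses = np.zeros(n_samples)
        impulses[stim_idx] = series.amplitude
        samples = fftconvolve(impulses, kernel)[:n_samples]
        if noise_sd > 0:
            samples = samples + rng.normal(0.0, noise_sd, size=n_samples)
        sweeps.append(
            Trace(samples, sampling_rate, start_time=t0, kind="current",
                  metadata={"synthetic": "evoked", "sweep": s})
        )
    truth = GroundTruth(
        event_times=stim_idx / sampling_rate + t0,
        amplitudes=per_sweep.mean(axis=0),
        seed=seed,
        params={"depletion": asdict(dp), "noise_sd": noise_sd, "kernel": asdict(kp)},
        sweep_amplitudes=per_sweep,
    )
    return SweepSet(sweeps, protocol), truth


# ---------------------------------------------------------------------------
# Action-potential templates and sweeps


@dataclass(frozen=True)
class APTemplateSpec:
    """Construction targets for a feature-parameterized spike waveform.

    threshold : mV, membrane potential at the 20 mV/ms dV/dt crossing
    amplitude : mV, peak minus threshold
    half_width : ms, width at threshold + amplitude/2
    max_rise / max_fall : mV/ms, maximal de-/re-polarization rates (both
        positive magnitudes)
    ahp : mV, after-hyperpolarization depth below threshold
    """

    threshold: float = -45.0
    amplitude: float = 80.0
    half_width: float = 0.40
    max_rise: float = 300.0
    max_fall: float = 200.0
    ahp: float = 15.0

    def __post_init__(self):
        if self.amplitude <= 0 or self.half_width <= 0:
            raise ParameterError("amplitude and half_width must be > 0")
        if self.max_rise <= 0 or self.max_fall <= 0:
            raise ParameterError("max_rise and max_fall must be > 0")
        if self.ahp < 0:
            raise ParameterError("ahp must be >= 0")


def make_ap_template(
    spec: APTemplateSpec,
    sampling_rate: float = 50_000.0,
    dvdt_threshold: float = 20.0,
    foot_drop: float = 10.0,
    trough_hold_ms: float = 0.1,
    recovery_tau_ms: float = 2.0,
) -> Trace:
    """Piecewise spike waveform whose measured features equal the spec.

    Layout: flat hold at ``threshold - foot_drop``; a quadratic foot whose
    dV/dt ramps linearly up to ``dvdt_threshold`` exactly at the threshold
    voltage (so the threshold sample is exact); a two-slope upstroke and a
    two-slope downstroke whose fast limbs realize ``max_rise``/``max_fall``
    and whose slow limbs (which contain the half-amplitude crossings) are
    chosen to realize ``half_width``; a flat trough at ``threshold - ahp``;
    and an exponential recovery.  Threshold, peak and trough land exactly
    on sample times, so sample-grid measurements are exact by construction.

    Raises :class:`ParameterError` when the half-width is shorter than the
    minimum compatible with the requested slopes.
    """
    dt = 1e3 / sampling_rate  # ms per sample
    a = spec.amplitude
    hw_min = (a / 2.0) * (1.0 / spec.max_rise + 1.0 / spec.max_fall)
    c = hw_min / spec.half_width
    if c > 0.995:
        raise ParameterError(
            f"half_width {spec.half_width} ms infeasible: the requested slopes "
            f"allow at minimum {hw_min:.4f} ms (need some slack below the max "
            "slopes for the half-amplitude limbs)"
        )
    r2 = spec.max_rise * c   # slow-up slope containing the rising half-crossing
    f2 = spec.max_fall * c   # slow-down slope containing the falling half-crossing

    # upstroke: fast limb threshold -> threshold + alpha_u*a at max_rise,
    # slow limb -> peak at r2; choose alpha_u so the total duration is an
    # integer number of samples (threshold and peak both on the grid).
    def _solve_alpha(duration: float, per_fast: float, per_slow: float, offset: float) -> float:
        # duration = alpha*A/fast + (1-alpha)*A/slow + offset   (offset for ahp limb)
        denom = a / per_fast - a / per_slow
        return (duration - a / per_slow - offset) / denom

    d_up0 = 0.25 * a / spec.max_rise + 0.75 * a / r2
    n_up = max(int(round(d_up0 / dt)), 4)
    alpha_u = _solve_alpha(n_up * dt, spec.max_rise, r2, 0.0)
    d_dn0 = 0.75 * a / f2 + (0.25 * a + spec.ahp) / spec.max_fall
    n_dn = max(int(round(d_dn0 / dt)), 4)
    alpha_d = _solve_alpha(n_dn * dt, spec.max_fall, f2, spec.ahp / spec.max_fall)
    for name, alpha in (("rising", alpha_u), ("falling", alpha_d)):
        if not 0.02 < alpha < 0.48:
            raise ParameterError(
                f"cannot place the {name} half-amplitude crossing away from the "
                "fast limb at this sampling rate; adjust half_width or slopes"
            )

    # quadratic foot: dV/dt ramps 0 -> dvdt_threshold over t_foot, rising by
    # dvdt_threshold*t_foot/2; snap t_foot to the grid and adapt the drop.
    n_foot = max(int(round(2.0 * foot_drop / dvdt_threshold / dt)), 10)
    t_foot = n_foot * dt
    drop = dvdt_threshold * t_foot / 2.0
    v_rest = spec.threshold - drop
    n_hold = max(int(round(0.2 / dt)), 3)
    n_trough = max(int(round(trough_hold_ms / dt)), 3)
    v_trough = spec.threshold - spec.ahp
    v_end = max(v_trough, v_rest)
    n_rec = int(round(5.0 * recovery_tau_ms / dt))

    idx_thr = n_hold + n_foot
    idx_peak = idx_thr + n_up
    idx_trough = idx_peak + n_dn
    n_total = idx_trough + n_trough + n_rec

    v = np.empty(n_total)
    v[:n_hold] = v_rest
    tf = (np.arange(n_foot + 1)) * dt
    v[n_hold : idx_thr + 1] = v_rest + dvdt_threshold / (2.0 * t_foot) * tf**2
    # upstroke (exclusive of threshold sample, inclusive of peak)
    t_kink_u = alpha_u * a / spec.max_rise
    tu = np.arange(1, n_up + 1) * dt
    up = np.where(
        tu <= t_kink_u,
        spec.threshold + spec.max_rise * tu,
        spec.threshold + alpha_u * a + r2 * (tu - t_kink_u),
    )
    v[idx_thr + 1 : idx_peak + 1] = up
    v[idx_peak] = spec.threshold + a  # exact
    # downstroke
    t_kink_d = (1.0 - alpha_d) * a / f2
    td = np.arange(1, n_dn + 1) * dt
    peak_v = spec.threshold + a
    dn = np.where(
        td <= t_kink_d,
        peak_v - f2 * td,
        peak_v - (1.0 - alpha_d) * a - spec.max_fall * (td - t_kink_d),
    )
    v[idx_peak + 1 : idx_trough + 1] = dn
    v[idx_trough] = v_trough  # exact
    v[idx_trough : idx_trough + n_trough] = v_trough
    tr = np.arange(n_rec) * dt
    v[idx_trough + n_trough :] = v_end + (v_trough - v_end) * np.exp(-tr / recovery_tau_ms)

    return Trace(
        v,
        sampling_rate,
        kind="voltage",
        metadata={
            "template": asdict(spec),
            "threshold_index": idx_thr,
            "peak_index": idx_peak,
            "trough_index": idx_trough,
            "rest_potential": v_rest,
        },
    )


def first_spike_latency_ms(
    v_range: float, i_pa: float, r_m_mohm: float, tau_m_ms: float
) -> float:
    """Closed-form latency of a leaky integrator to reach threshold.

    ``v_range`` is threshold minus baseline (mV); the steady-state drive is
    ``i_pa * r_m_mohm / 1000`` mV.  Returns ms; ``inf`` if subthreshold.
    """
    drive = i_pa * r_m_mohm / 1000.0
    if drive <= v_range:
        return math.inf
    return -tau_m_ms * math.log(1.0 - v_range / drive)


def gen_ap_sweeps(
    spec: APTemplateSpec | None = None,
    step_protocol: StimulusProtocol | None = None,
    spont_rate: float | None = None,
    duration: float = 1.0,
    seed: int = 0,
    sampling_rate: float = 50_000.0,
    tau_m_ms: float = 20.0,
    r_m_mohm: float = 350.0,
    noise_sd: float = 0.0,
) -> tuple[SweepSet, GroundTruth]:
    """Current-clamp sweeps built from feature-parameterized AP templates.

    With ``step_protocol``, a leaky integrator (time constant ``tau_m_ms``,
    input resistance ``r_m_mohm``) charges from the baseline potential
    toward ``baseline + I*R_m`` during the step; a spike is scheduled when
    it reaches the template threshold, with the closed-form latency
    ``-tau_m * ln(1 - V_range/(I*R_m))``, and the template peak is placed
    at that time (snapped to the sample grid).  After each spike the
    integrator restarts from baseline at the end of the template.

    With ``spont_rate``, spikes are placed on a regular schedule at
    ``spont_rate`` Hz over ``duration`` seconds.

    Ground truth carries the scheduled peak times, the construction
    features and (for steps) the closed-form first-spike latency in ms.
    """
    if spec is None:
        spec = APTemplateSpec()
    if (step_protocol is None) == (spont_rate is None):
        raise ParameterError("provide exactly one of step_protocol or spont_rate")
    template = make_ap_template(spec, sampling_rate)
    tpl = template.samples
    idx_peak = template.metadata["peak_index"]
    dt = 1.0 / sampling_rate
    rng = np.random.default_rng(seed)

    if spont_rate is not None:
        if spont_rate <= 0:
            raise ParameterError("spont_rate must be > 0")
        n_samples = int(round(duration * sampling_rate))
        v_rest = template.metadata["rest_potential"]
        v = np.full(n_samples, v_rest)
        peak_times = []
        k = 0
        while (k + 0.5) / spont_rate < duration:
            peak_idx = int(round((k + 0.5) / spont_rate * sampling_rate))
            start = peak_idx - idx_peak
            lo, hi = max(0, start), min(n_samples, start + len(tpl))
            v[lo:hi] = tpl[lo - start : hi - start]
            peak_times.append(peak_idx * dt)
            k += 1
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, n_samples)
        sweep = Trace(v, sampling_rate, kind="voltage",
                      metadata={"synthetic": "spontaneous_aps"})
        truth = GroundTruth(
            event_times=np.asarray(peak_times),
            amplitudes=None,
            seed=seed,
            params={"spont_rate": spont_rate, "template": asdict(spec)},
            features=asdict(spec),
        )
        return SweepSet([sweep]), truth

    # step-evoked mode
    p = step_protocol
    if p.step_onset is None or p.step_duration is None or p.step_amplitude is None:
        raise ParameterError("step_protocol must define onset, duration and amplitude")
    v0 = p.baseline_potential if p.baseline_potential is not None else -60.0
    v_range = spec.threshold - v0
    if v_range <= 0:
        raise ParameterError("baseline potential must lie below the AP threshold")
    total = p.step_onset + p.step_duration + 0.05
    n_samples = int(round(total * sampling_rate))
    t = np.arange(n_samples) * dt
    drive = p.step_amplitude * r_m_mohm / 1000.0  # mV

    v = np.full(n_samples, v0)
    in_step = (t >= p.step_onset) & (t < p.step_onset + p.step_duration)
    lat_ms = first_spike_latency_ms(v_range, p.step_amplitude, r_m_mohm, tau_m_ms)
    peak_times: list[float] = []
    if math.isinf(lat_ms):
        v[in_step] = v0 + drive * (1.0 - np.exp(-(t[in_step] - p.step_onset) / (tau_m_ms * 1e-3)))
    else:
        tau_s = tau_m_ms * 1e-3
        t_charge = p.step_onset  # charging restarts here after each spike
        step_end = p.step_onset + p.step_duration
        while True:
            # the template peak is placed at the closed-form threshold-reach
            # time, so measured spike latency equals the analytic latency
            t_peak = t_charge + lat_ms * 1e-3
            peak_idx = int(round(t_peak / dt))
            if peak_idx * dt > step_end or peak_idx - idx_peak < 0:
                # no further spike: render subthreshold charging to step end
                seg = (t >= t_charge) & (t < step_end)
                v[seg] = v0 + drive * (1.0 - np.exp(-(t[seg] - t_charge) / tau_s))
                break
            start = peak_idx - idx_peak
            seg = (t >= t_charge) & (t < start * dt)
            v[seg] = v0 + drive * (1.0 - np.exp(-(t[seg] - t_charge) / tau_s))
            stop = min(start + len(tpl), n_samples)
            v[start:stop] = tpl[: stop - start]
            peak_times.append(peak_idx * dt)
            t_charge = stop * dt
            if t_charge >= step_end:
                break
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, n_samples)
    sweep = Trace(v, sampling_rate, kind="voltage",
                  metadata={"synthetic": "evoked_aps", "step_pA": p.step_amplitude})
    truth = GroundTruth(
        event_times=np.asarray(peak_times),
        amplitudes=None,
        seed=seed,
        params={
            "template": asdict(spec), "tau_m_ms": tau_m_ms, "r_m_mohm": r_m_mohm,
            "step_pA": p.step_amplitude, "baseline_mV": v0,
        },
        features=asdict(spec),
        latency_ms=lat_ms if not math.isinf(lat_ms) else None,
    )
    return SweepSet([sweep], p), truth
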