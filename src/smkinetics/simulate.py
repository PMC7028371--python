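"""Stochastic generators for CoSMoS-style recordings and FCS titrations.

Every analysis input the package consumes can be generated here with known
ground truth: promoter visits following the two-closed-complex scheme
(Gillespie simulation), equilibrium-occupancy partitioning of arrivals into
SCF-bound and SCF-free polymerase, transcription-probe intervals from a
first-order initiation commitment, nonspecific surface background binding,
frame discretization with a >=50 %-overlap detection rule, label efficiency,
photobleaching, per-frame detection misses, and noisy multi-component FCS
autocorrelation curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .fcs import FCSCurve, FCSModelParams, NM_TO_UM3, exact_bound_fraction, fcs_model
from .scheme import SchemeRates
from .types import CHANNELS, FrameInterval, Location, RecordingSet

__all__ = [
    "SimConfig",
    "simulate_scheme_dwell",
    "simulate_scheme_dwells",
    "simulate_dwell_sample",
    "simulate_cosmos_recording",
    "simulate_fcs_titration",
]


@dataclass
class SimConfig:
    """Configuration of a synthetic CoSMoS recording.

    Default values reproduce the reference experimental condition of the
    colocalization measurements: 0.5 s/frame recordings of 1 nM labeled
    holoenzyme plus 10 nM labeled GreB (93 % dye labeling) binding DNA at an
    rRNA promoter, with dwell kinetics given by the two-closed-complex rate
    sets and K_D = 10 nM setting the fraction of arrivals carrying GreB.
    """

    seed: int = 0
    frame_interval_s: float = 0.5
    n_frames: int = 2684  # 1342 s at 0.5 s/frame
    n_dna_locations: int = 227
    n_control_locations: int = 227
    active_fraction: float = 0.95
    rnap_conc_M: float = 1e-9
    greb_conc_M: float = 10e-9
    kd_greb_M: float = 10e-9
    greb_label_eff: float = 0.93
    rnap_label_eff: float = 1.0
    rates_free: SchemeRates = field(
        default_factory=lambda: SchemeRates(
            k1=2.2e6, k_m1=0.3530, k2=0.02857, k_m2=0.03668
        )
    )
    rates_greb: SchemeRates = field(
        default_factory=lambda: SchemeRates(
            k1=2.4e6, k_m1=0.2670, k2=0.02487, k_m2=0.02470, primed=True
        )
    )
    # nonspecific surface association, per channel (M^-1 s^-1)
    k_bkgnd_Msi: dict = field(
        default_factory=lambda: {"rnap": 0.037e6, "greb": 1.4e4, "probe": 0.0}
    )
    bkgnd_dwell_mean_s: float = 5.0
    k_init_si: float = 0.0  # commitment rate during GreB-free visits (s^-1)
    probe_dwell_mean_s: float = 60.0
    probe_conc_M: float = 10e-9
    bleach_rate_si: float = 0.0
    miss_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "active_fraction",
            "greb_label_eff",
            "rnap_label_eff",
            "miss_prob",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames <= 0 or self.n_dna_locations + self.n_control_locations <= 0:
            raise ValueError("need at least one frame and one location")
        for c, v in (
            ("rnap_conc_M", self.rnap_conc_M),
            ("greb_conc_M", self.greb_conc_M),
            ("kd_greb_M", self.kd_greb_M),
        ):
            if v < 0:
                raise ValueError(f"{c} must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def greb_occupancy(self) -> float:
        """Equilibrium fraction of polymerase carrying GreB in solution."""
        if self.greb_conc_M == 0:
            return 0.0
        return self.greb_conc_M / (self.greb_conc_M + self.kd_greb_M)


def simulate_scheme_dwell(rates: SchemeRates, rng) -> float:
    """One Gillespie dwell of the RP1 <-> RP2 scheme (exit only via RP1).

    ``rng`` is a seed or a :class:`numpy.random.Generator`.  Returns the
    time from entry into RP1 until dissociation, in seconds.
    """
    return float(simulate_scheme_dwells(rates, 1, rng)[0])


def simulate_scheme_dwells(rates: SchemeRates, n: int, rng) -> np.ndarray:
    """Vector of ``n`` independent Gillespie dwells from the scheme.

    Direct stochastic simulation of the embedded jump chain; deliberately
    independent of the analytic eigendecomposition in :mod:`.scheme` so the
    two can cross-validate each other.
    """
    if rates.k_m1 <= 0:
        raise ValueError("k_m1 must be > 0: with no exit channel the dwell is infinite")
    if rates.k2 > 0 and rates.k_m2 <= 0:
        raise ValueError("k2 > 0 with k_m2 = 0 traps the walker in RP2 forever")
    rng = np.random.default_rng(rng)
    out = np.empty(n)
    exit_rate1 = rates.k_m1 + rates.k2
    p_leave = rates.k_m1 / exit_rate1
    for i in range(n):
        t = 0.0
        while True:
            # state RP1
            t += rng.exponential(1.0 / exit_rate1)
            if rng.random() < p_leave:
                break
            # state RP2
            t += rng.exponential(1.0 / rates.k_m2)
        out[i] = t
    return out


def simulate_dwell_sample(
    a: float,
    tau1_s: float,
    tau2_s: float,
    n: int,
    frame_interval_s: float,
    seed,
) -> tuple[np.ndarray, int]:
    """Frame-discretized sample from the biexponential dwell mixture.

    Draws ``n`` dwells from ``a Exp(tau1) + (1-a) Exp(tau2)``, discards
    dwells shorter than one frame (returning the discard count) and rounds
    the survivors up to whole frames.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("a must lie in [0, 1]")
    if not 0.0 < tau1_s <= tau2_s:
        raise ValueError("need 0 < tau1 <= tau2")
    if n <= 0:
        raise ValueError("n must be > 0")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be > 0")
    rng = np.random.default_rng(seed)
    fast = rng.random(n) < a
    t = np.where(
        fast, rng.exponential(tau1_s, n), rng.exponential(tau2_s, n)
    )
    keep = t >= frame_interval_s
    n_discarded = int(n - keep.sum())
    t = t[keep]
    frames = np.ceil(t / frame_interval_s)
    return frames * frame_interval_s, n_discarded


# ---------------------------------------------------------------------------
# CoSMoS recording simulation
# ---------------------------------------------------------------------------


def _discretize_events(events, frame_interval_s, n_frames, miss_prob, rng):
    """Continuous (t0, t1) events -> sorted disjoint frame intervals.

    Detection rule: an event is detected in frame k iff it overlaps at least
    half of that frame's duration.  Overlapping events are merged at the
    frame level; per-frame false negatives (miss_prob) can split runs.
    """
    detected = np.zeros(n_frames, dtype=bool)
    dt = frame_interval_s
    for t0, t1 in events:
        if t1 <= 0 or t0 >= n_frames * dt:
            continue
        k0 = max(int(math.floor(t0 / dt)), 0)
        k1 = min(int(math.ceil(t1 / dt)), n_frames)
        for k in range(k0, k1):
            overlap = min(t1, (k + 1) * dt) - max(t0, k * dt)
            if overlap >= 0.5 * dt:
                detected[k] = True
    if miss_prob > 0:
        detected &= rng.random(n_frames) >= miss_prob
    # contiguous runs -> half-open intervals
    intervals = []
    idx = np.flatnonzero(detected)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([idx[0]], idx[breaks + 1]))
        ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
        intervals = list(zip(starts.tolist(), ends.tolist()))
    return intervals


def _truncate_bleach(t0, t1, rate, rng):
    if rate <= 0:
        return t1
    return min(t1, t0 + rng.exponential(1.0 / rate))


def simulate_cosmos_recording(config: SimConfig) -> tuple[RecordingSet, dict]:
    """Simulate a full multi-channel recording; returns (recording, truth).

    Active DNA locations receive polymerase arrivals as a renewal process
    (exponential waiting at the summed occupancy-weighted association rate,
    arrivals blocked while the promoter is occupied).  Each arrival carries
    GreB with the equilibrium occupancy probability; dwells are Gillespie
    draws from the matching rate set.  GreB-free visits may commit to
    initiation (first-order rate ``k_init_si``), spawning a probe interval;
    GreB-bound visits never initiate.  All locations additionally receive
    per-channel nonspecific background events.  The truth sidecar records
    continuous-time event data and hidden flags for recovery tests.
    """
    n_loc = config.n_dna_locations + config.n_control_locations
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(n_loc + 1)
    rng_global = np.random.default_rng(children[0])

    p_occ = config.greb_occupancy
    # total promoter association rate, weighting the two holoenzyme species
    # by solution occupancy (they may have different k1)
    rate_free = (1.0 - p_occ) * config.rates_free.k1 * config.rnap_conc_M
    rate_greb = p_occ * config.rates_greb.k1 * config.rnap_conc_M
    rate_total = rate_free + rate_greb
    duration = config.duration_s

    locations: list[Location] = []
    intervals: list[FrameInterval] = []
    truth_locs = []
    active_flags = rng_global.random(config.n_dna_locations) < config.active_fraction

    for i in range(n_loc):
        is_dna = i < config.n_dna_locations
        kind = "dna" if is_dna else "control"
        active = bool(active_flags[i]) if is_dna else False
        locations.append(Location(location_id=i, kind=kind))
        rng = np.random.default_rng(children[i + 1])

        events: dict[str, list] = {ch: [] for ch in CHANNELS}
        visits = []
        if is_dna and active and rate_total > 0:
            t = rng.exponential(1.0 / rate_total)
            while t < duration:
                greb_bound = rng.random() < (rate_greb / rate_total)
                greb_labeled = greb_bound and rng.random() < config.greb_label_eff
                rates = config.rates_greb if greb_bound else config.rates_free
                dwell = simulate_scheme_dwell(rates, rng)
                t_end = t + dwell
                initiated = False
                t_commit = None
                if not greb_bound and config.k_init_si > 0:
                    commit = rng.exponential(1.0 / config.k_init_si)
                    if commit < dwell:
                        initiated = True
                        t_commit = t + commit
                        t_end = t_commit  # polymerase escapes the promoter
                        events["probe"].append(
                            (
                                t_commit,
                                t_commit + rng.exponential(config.probe_dwell_mean_s),
                            )
                        )
                if rng.random() < config.rnap_label_eff:
                    events["rnap"].append((t, t_end))
                if greb_labeled:
                    events["greb"].append((t, t_end))
                visits.append(
                    {
                        "t_arrival": t,
                        "t_departure": t_end,
                        "greb_bound": greb_bound,
                        "greb_labeled": greb_labeled,
                        "initiated": initiated,
                        "t_commit": t_commit,
                    }
                )
                t = t_end + rng.exponential(1.0 / rate_total)

        # nonspecific surface background on every location, every channel
        conc = {
            "rnap": config.rnap_conc_M,
            "greb": config.greb_conc_M,
            "probe": config.probe_conc_M,
        }
        n_bkgnd = {}
        for ch in CHANNELS:
            rate = config.k_bkgnd_Msi.get(ch, 0.0) * conc[ch]
            n_bkgnd[ch] = 0
            if rate <= 0:
                continue
            t = rng.exponential(1.0 / rate)
            while t < duration:
                events[ch].append(
                    (t, t + rng.exponential(config.bkgnd_dwell_mean_s))
                )
                n_bkgnd[ch] += 1
                t += rng.exponential(1.0 / rate)

        for ch in CHANNELS:
            evs = [
                (t0, _truncate_bleach(t0, t1, config.bleach_rate_si, rng))
                for t0, t1 in events[ch]
            ]
            for s, e in _discretize_events(
                evs, config.frame_interval_s, config.n_frames, config.miss_prob, rng
            ):
                intervals.append(
                    FrameInterval(
                        location_id=i, channel=ch, start_frame=s, end_frame=e
                    )
                )

        truth_locs.append(
            {
                "location_id": i,
                "kind": kind,
                "active": active,
                "visits": visits,
                "n_background_events": n_bkgnd,
            }
        )

    rec = RecordingSet(
        frame_interval_s=config.frame_interval_s,
        n_frames=config.n_frames,
        locations=locations,
        intervals=intervals,
        concentrations={
            "rnap": config.rnap_conc_M,
            "greb": config.greb_conc_M,
            "probe": config.probe_conc_M,
        },
    )
    truth = {
        "seed": config.seed,
        "greb_occupancy": p_occ,
        "locations": truth_locs,
    }
    return rec, truth


# ---------------------------------------------------------------------------
# FCS titration simulation
# ---------------------------------------------------------------------------


def simulate_fcs_titration(
    kd_M: float,
    d_free: float,
    d_bound: float,
    label_conc_M: float,
    rt_list_M,
    omega_o: float,
    s_ratio: float,
    noise_rms: float,
    n_curves: int = 1,
    seed=None,
    lags: np.ndarray | None = None,
) -> list[tuple[float, list[FCSCurve]]]:
    """Noisy two-component titration curves with exact-binding ground truth.

    For each total partner concentration ``R_T`` the bound fraction is the
    exact 1:1 solution with depletion (quadratic), the two-component model
    is evaluated on a log-spaced lag grid, and multiplicative Gaussian noise
    of the given rms is added per lag point (``sigma_G = noise_rms * G``).

    Returns ``[(r_t, [FCSCurve] * n_curves), ...]``.
    """
    if noise_rms < 0:
        raise ValueError("noise_rms must be >= 0")
    if any(r < 0 for r in rt_list_M):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    if lags is None:
        lags = np.logspace(-6, 0, 120)  # 1 us .. 1 s
    out = []
    for r_t in rt_list_M:
        f_b = 0.0 if r_t == 0 else exact_bound_fraction(label_conc_M, r_t, kd_M)
        if f_b == 0.0:
            comps = [{"f": 1.0, "d": d_free}]
        elif f_b == 1.0:
            comps = [{"f": 1.0, "d": d_bound}]
        else:
            comps = [{"f": 1.0 - f_b, "d": d_free}, {"f": f_b, "d": d_bound}]
        params = FCSModelParams(
            omega_o=omega_o,
            s_ratio=s_ratio,
            c_avg=label_conc_M * 1e9 * NM_TO_UM3,
            components=comps,
        )
        g_true = fcs_model(lags, params)
        curves = []
        for _ in range(n_curves):
            if noise_rms > 0:
                g = g_true * (1.0 + noise_rms * rng.standard_normal(lags.size))
                sigma = noise_rms * g_true
            else:
                g = g_true.copy()
                sigma = None
            curves.append(FCSCurve(lags=lags.copy(), g=g, sigma=sigma))
        out.append((float(r_t), curves))
    return out
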