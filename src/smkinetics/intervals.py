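"""Dwell-time and first-binding kinetics from interval recordings.

Dwell-time distributions are fit by maximum likelihood to single- or
bi-exponential mixtures.  Observed durations are whole frames; the
likelihood treats each recorded duration ``d`` as interval-censored on
``(d - dt + off, d + off]`` (``dt`` = frame interval, ``off`` the sample's
discretization offset) and conditions on the detection threshold
(left truncation).  Dwells still in progress at the end of a recording
enter as right-censored survival terms.

Time-to-first-binding curves are fit jointly over target (DNA) and control
locations: control locations bind only nonspecifically, at rate
``k_bkgnd * C``; a fraction ``A_f`` of DNA locations is binding-competent
and accrues specific binding at ``k_a * C`` on top of background, while the
remaining ``1 - A_f`` behaves like background only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .types import RecordingSet

__all__ = [
    "DwellSample",
    "BiexpFit",
    "ArrivalTimes",
    "FirstBindingFit",
    "SecondOrderRate",
    "InitiationSummary",
    "PhotobleachVerdict",
    "extract_dwells",
    "dwell_sample_from_durations",
    "fit_biexponential",
    "first_binding_times",
    "fit_first_binding",
    "initiation_rate",
    "summarize_initiation",
    "rate_from_counts",
    "kd_from_kinetics",
    "photobleach_check",
]


@dataclass
class DwellSample:
    """Frame-quantized dwell durations with censoring and truncation metadata.

    ``window_offset_s`` states the discretization convention: a recorded
    duration ``d`` corresponds to a true dwell in ``(d - dt + off, d + off]``.
    ``min_observed_s`` is the smallest recorded duration that qualifies for
    the sample (the detection/filter threshold).
    """

    durations: np.ndarray  # seconds
    frame_interval_s: float
    censored: np.ndarray | None = None
    location_ids: np.ndarray | None = None
    min_observed_s: float = 0.0
    window_offset_s: float = 0.0
    n_discarded_subframe: int = 0

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(self.durations.size, dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool)
        if self.location_ids is not None:
            self.location_ids = np.asarray(self.location_ids)

    @property
    def n(self) -> int:
        return int(self.durations.size)

    @property
    def truncation_s(self) -> float:
        """Lower bound of the true-dwell support given detection."""
        return max(self.min_observed_s - self.frame_interval_s + self.window_offset_s, 0.0)


@dataclass
class BiexpFit:
    """Biexponential dwell fit: S(t) = a e^{-t/tau1} + (1-a) e^{-t/tau2}."""

    a: float
    tau1_s: float
    tau2_s: float
    se_a: float = 0.0
    se_tau1: float = 0.0
    se_tau2: float = 0.0
    n: int = 0
    loglik: float = float("nan")
    flags: list = field(default_factory=list)

    @property
    def mean_s(self) -> float:
        return self.a * self.tau1_s + (1.0 - self.a) * self.tau2_s


def extract_dwells(
    rec: RecordingSet, channel: str, min_duration_s: float | None = None
) -> DwellSample:
    """Collect dwell durations of one channel over all locations.

    Durations are interval lengths in frames times the frame interval.
    Intervals abutting the final frame are right-censored.  ``min_duration_s``
    drops shorter events (used with 5 s for transcript-probe scoring; the
    default keeps everything >= 1 frame).
    """
    if channel not in rec.channels() and not any(
        iv.channel == channel for iv in rec.intervals
    ):
        raise ValueError(f"channel {channel!r} not present in recording")
    dt = rec.frame_interval_s
    min_d = dt if min_duration_s is None else max(min_duration_s, dt)
    durations, censored, locs = [], [], []
    n_drop = 0
    for iv in rec.intervals:
        if iv.channel != channel:
            continue
        d = iv.n_frames * dt
        cens = iv.end_frame >= rec.n_frames
        if d < min_d and not cens:
            n_drop += 1
            continue
        durations.append(d)
        censored.append(cens)
        locs.append(iv.location_id)
    return DwellSample(
        durations=np.array(durations),
        frame_interval_s=dt,
        censored=np.array(censored, dtype=bool),
        location_ids=np.array(locs),
        min_observed_s=min_d,
        window_offset_s=0.5 * dt,  # >=50 %-overlap detection rule
        n_discarded_subframe=n_drop,
    )


def dwell_sample_from_durations(
    durations, frame_interval_s: float, n_discarded: int = 0
) -> DwellSample:
    """Wrap the output of ``simulate_dwell_sample`` (ceil-to-frame convention:
    a recorded d corresponds to a true dwell in (d - dt, d])."""
    return DwellSample(
        durations=np.asarray(durations, dtype=float),
        frame_interval_s=frame_interval_s,
        min_observed_s=2.0 * frame_interval_s,
        window_offset_s=0.0,
        n_discarded_subframe=n_discarded,
    )


def _biexp_survival(t, a, tau1, tau2):
    return a * np.exp(-t / tau1) + (1.0 - a) * np.exp(-t / tau2)


def _biexp_nll(theta, d, cens, dt, off, t_trunc):
    a = expit(theta[0])
    tau1 = math.exp(theta[1])
    tau2 = tau1 + math.exp(theta[2])
    norm = _biexp_survival(t_trunc, a, tau1, tau2)
    obs = ~cens
    if dt > 0:
        # window clipped at the truncation point so no probability mass below
        # the detection threshold can enter the numerator
        lo = np.maximum(d[obs] - dt + off, t_trunc)
        p = _biexp_survival(lo, a, tau1, tau2) - _biexp_survival(
            d[obs] + off, a, tau1, tau2
        )
    else:
        p = a / tau1 * np.exp(-d[obs] / tau1) + (1.0 - a) / tau2 * np.exp(
            -d[obs] / tau2
        )
    p = np.clip(p, 1e-300, None)
    s_c = np.clip(_biexp_survival(d[cens] + off, a, tau1, tau2), 1e-300, None)
    return -(np.log(p).sum() + np.log(s_c).sum()) + d.size * math.log(max(norm, 1e-300))


def _fit_biexp_once(d, cens, dt, off, t_trunc):
    m = float(np.mean(d))
    q25 = max(float(np.quantile(d, 0.25)), dt if dt > 0 else m * 0.05)
    q90 = max(float(np.quantile(d, 0.90)), q25 * 2)
    starts = [
        (0.9, q25, q90),
        (0.6, 0.5 * m, 2.0 * m),
        (0.98, q25, 5.0 * q90),
    ]
    best = None
    for a0, t1, t2 in starts:
        theta0 = [logit(a0), math.log(t1), math.log(max(t2 - t1, 1e-3))]
        res = minimize(
            _biexp_nll,
            theta0,
            args=(d, cens, dt, off, t_trunc),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    a = float(expit(best.x[0]))
    tau1 = math.exp(best.x[1])
    tau2 = tau1 + math.exp(best.x[2])
    return a, tau1, tau2, -best.fun


def fit_biexponential(
    sample: DwellSample, n_boot: int = 1000, seed=None
) -> BiexpFit:
    """Maximum-likelihood biexponential fit of a dwell sample.

    Left truncation at the sample's detection threshold; right-censored
    dwells contribute survival terms.  Standard errors come from a
    bootstrap resampled over molecules (locations) when location ids are
    available, over individual dwells otherwise.  Components are ordered
    tau1 <= tau2; ``a`` is the probability fraction of the fast phase.
    """
    d, cens = sample.durations, sample.censored
    if d.size < 2 or d.size - cens.sum() < 2:
        raise ValueError("need at least two uncensored dwells")
    dt, off, t0 = sample.frame_interval_s, sample.window_offset_s, sample.truncation_s
    a, tau1, tau2, ll = _fit_biexp_once(d, cens, dt, off, t0)
    flags = []
    # likelihood-ratio check against the nested single-exponential model:
    # an insignificant improvement means the second phase is not resolved
    from scipy.optimize import minimize_scalar

    res1 = minimize_scalar(
        lambda lt: _biexp_nll([50.0, lt, -20.0], d, cens, dt, off, t0),
        bounds=(math.log(max(dt, 1e-3) * 0.2), math.log(np.max(d) * 10.0)),
        method="bounded",
    )
    lr = 2.0 * (ll + res1.fun)
    if a < 0.005:
        flags += ["single_exponential_adequate", "tau1_unidentifiable"]
    elif lr < 4.0 or a > 0.995 or tau2 < 1.05 * tau1:
        flags += ["single_exponential_adequate", "tau2_unidentifiable"]
    se = [0.0, 0.0, 0.0]
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        groups = None
        if sample.location_ids is not None and sample.location_ids.size == d.size:
            uniq = np.unique(sample.location_ids)
            if uniq.size >= 10:
                groups = [np.flatnonzero(sample.location_ids == u) for u in uniq]
        draws = []
        for _ in range(n_boot):
            if groups is not None:
                pick = rng.integers(0, len(groups), len(groups))
                idx = np.concatenate([groups[i] for i in pick])
            else:
                idx = rng.integers(0, d.size, d.size)
            if np.sum(~cens[idx]) < 2:
                continue
            try:
                ab, t1b, t2b, _ = _fit_biexp_once(d[idx], cens[idx], dt, off, t0)
            except Exception:
                continue
            draws.append((ab, t1b, t2b))
        if len(draws) >= 10:
            arr = np.array(draws)
            se = arr.std(axis=0, ddof=1).tolist()
    return BiexpFit(
        a=a,
        tau1_s=tau1,
        tau2_s=tau2,
        se_a=se[0],
        se_tau1=se[1],
        se_tau2=se[2],
        n=int(d.size),
        loglik=ll,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# time to first binding
# ---------------------------------------------------------------------------


@dataclass
class ArrivalTimes:
    """Per-location first-event times; censored entries mark locations with
    no qualifying event before the end of the recording."""

    times: np.ndarray  # seconds
    censored: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass
class FirstBindingFit:
    """Joint first-binding fit: specific rate, background rate, active fraction.

    Rates are second order (M^-1 s^-1) when fit with a concentration, first
    order (s^-1) when ``conc_M`` is 1 (probe/initiation experiments).
    """

    k_a: float
    k_bkgnd: float
    a_f: float
    se_k_a: float = 0.0
    se_k_bkgnd: float = 0.0
    se_a_f: float = 0.0
    n_dna: int = 0
    n_control: int = 0
    conc_M: float = 1.0
    loglik: float = float("nan")
    flags: list = field(default_factory=list)


def first_binding_times(
    rec: RecordingSet, channel: str, min_duration_s: float | None = None
) -> dict[str, ArrivalTimes]:
    """First qualifying event time per DNA and per control location.

    The event time is the interval's start frame times the frame interval;
    locations with no qualifying event are censored at the recording end.
    """
    dt = rec.frame_interval_s
    min_frames = 1 if min_duration_s is None else int(round(min_duration_s / dt))
    by_loc = rec.intervals_by_location(channel)
    out = {}
    for kind in ("dna", "control"):
        times, cens = [], []
        for loc in rec.locations_of_kind(kind):
            first = None
            for iv in by_loc.get(loc.location_id, []):
                if iv.n_frames >= min_frames or iv.end_frame >= rec.n_frames:
                    first = iv.start_frame * dt
                    break
            if first is None:
                times.append(rec.duration_s)
                cens.append(True)
            else:
                times.append(first)
                cens.append(False)
        out[kind] = ArrivalTimes(np.array(times), np.array(cens, dtype=bool))
    return out


def _first_binding_nll(theta, dna, ctrl, conc, fix_af, fix_kb):
    ka = math.exp(theta[0]) * conc
    kb = (fix_kb if fix_kb is not None else math.exp(theta[1])) * conc
    af = fix_af if fix_af is not None else expit(theta[2])
    nll = 0.0
    t, c = ctrl.times, ctrl.censored
    # control: pure background exponential
    if kb > 0:
        nll -= np.sum(np.log(kb) - kb * t[~c])
    elif np.any(~c):
        return 1e300
    nll += kb * np.sum(t[c])
    # DNA: active-fraction mixture of (specific + background) and background
    t, c = dna.times, dna.censored
    lam = ka + kb
    pdf = af * lam * np.exp(-lam * t[~c]) + (1.0 - af) * kb * np.exp(-kb * t[~c])
    nll -= np.sum(np.log(np.clip(pdf, 1e-300, None)))
    surv = af * np.exp(-lam * t[c]) + (1.0 - af) * np.exp(-kb * t[c])
    nll -= np.sum(np.log(np.clip(surv, 1e-300, None)))
    return nll


def _fit_fb_once(dna, ctrl, conc, fix_af, fix_kb):
    # moment-based starting guesses
    t_mean_dna = max(float(np.mean(dna.times)), 1e-6)
    ka0 = 1.0 / (conc * t_mean_dna)
    if np.any(~ctrl.censored):
        kb0 = max(np.sum(~ctrl.censored) / (conc * np.sum(ctrl.times)), ka0 * 1e-6)
    else:
        kb0 = ka0 * 1e-4
    best = None
    for ka_s, af_s in ((ka0, 0.9), (ka0 * 5, 0.5), (ka0 * 0.2, 0.99)):
        theta0 = [
            math.log(ka_s),
            math.log(kb0) if fix_kb is None else 0.0,
            logit(min(max(af_s, 1e-3), 1 - 1e-3)),
        ]
        res = minimize(
            _first_binding_nll,
            theta0,
            args=(dna, ctrl, conc, fix_af, fix_kb),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    ka = math.exp(best.x[0])
    kb = fix_kb if fix_kb is not None else math.exp(best.x[1])
    af = fix_af if fix_af is not None else float(expit(best.x[2]))
    return ka, kb, af, -best.fun


def fit_first_binding(
    times_dna: ArrivalTimes,
    times_control: ArrivalTimes,
    conc_M: float = 1.0,
    fix_a_f: float | None = None,
    fix_k_bkgnd: float | None = None,
    n_boot: int = 200,
    seed=None,
) -> FirstBindingFit:
    """Joint MLE of (k_a, k_bkgnd, A_f) from first-binding times.

    Control locations follow ``1 - exp(-k_bkgnd C t)``; DNA locations follow
    ``A_f [1 - exp(-(k_a + k_bkgnd) C t)] + (1 - A_f)[1 - exp(-k_bkgnd C t)]``.
    Censored locations contribute survival terms.  Pass ``conc_M=1`` for
    first-order (probe) experiments.  SEs by bootstrap over locations.
    """
    if times_dna.n == 0 or times_control.n == 0:
        raise ValueError("need both DNA and control locations")
    ka, kb, af, ll = _fit_fb_once(times_dna, times_control, conc_M, fix_a_f, fix_k_bkgnd)
    flags = []
    if ka < 2.0 * kb:
        flags.append("k_a_not_resolved_from_background")
    se = [0.0, 0.0, 0.0]
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_boot):
            i = rng.integers(0, times_dna.n, times_dna.n)
            j = rng.integers(0, times_control.n, times_control.n)
            db = ArrivalTimes(times_dna.times[i], times_dna.censored[i])
            cb = ArrivalTimes(times_control.times[j], times_control.censored[j])
            if np.all(db.censored):
                continue
            try:
                draws.append(_fit_fb_once(db, cb, conc_M, fix_a_f, fix_kb=fix_k_bkgnd)[:3])
            except Exception:
                continue
        if len(draws) >= 10:
            arr = np.array(draws)
            se = arr.std(axis=0, ddof=1).tolist()
    return FirstBindingFit(
        k_a=ka,
        k_bkgnd=kb,
        a_f=af,
        se_k_a=se[0],
        se_k_bkgnd=se[1],
        se_a_f=se[2],
        n_dna=times_dna.n,
        n_control=times_control.n,
        conc_M=conc_M,
        loglik=ll,
        flags=flags,
    )


def initiation_rate(
    rec: RecordingSet,
    min_duration_s: float = 5.0,
    fix_a_f: float | None = None,
    n_boot: int = 200,
    seed=None,
) -> FirstBindingFit:
    """Transcription initiation rate from probe first-arrival times.

    Same joint model as :func:`fit_first_binding` but with first-order rates
    (s^-1): ``k_a`` is the initiation rate ``k_init`` corrected for the
    nonspecific probe-binding rate ``k_bkgnd`` measured at DNA-free control
    locations.  Only probe events of at least ``min_duration_s`` qualify.
    ``fix_a_f`` pins the active fraction to a reference condition's value.
    """
    if not rec.locations_of_kind("control"):
        raise ValueError("no control locations: background rate cannot be estimated")
    fb = first_binding_times(rec, "probe", min_duration_s=min_duration_s)
    return fit_first_binding(
        fb["dna"], fb["control"], conc_M=1.0, fix_a_f=fix_a_f, n_boot=n_boot, seed=seed
    )


@dataclass
class InitiationSummary:
    """Per-condition average initiation rate and fold inhibition."""

    avg_k_init: dict  # condition -> (mean, se)
    fold_inhibition: dict  # condition -> (fold, se)
    reference: str


def summarize_initiation(replicates: dict, reference: str) -> InitiationSummary:
    """Average replicate initiation rates and compute fold inhibition.

    ``replicates`` maps condition name -> list of ``(k_init, se)`` pairs (or
    bare rates).  ``Avg k_init`` is the unweighted mean over replicates; its
    SE combines the replicate SEs in quadrature with the spread of the mean.
    Fold inhibition is ``Avg(reference) / Avg(condition)`` with relative
    errors propagated in quadrature.
    """
    if reference not in replicates:
        raise ValueError(f"reference condition {reference!r} missing")
    avg = {}
    for cond, reps in replicates.items():
        if not reps:
            raise ValueError(f"condition {cond!r} has no replicates")
        vals = np.array([r[0] if isinstance(r, (tuple, list)) else r for r in reps], float)
        ses = np.array(
            [r[1] if isinstance(r, (tuple, list)) and len(r) > 1 else 0.0 for r in reps],
            float,
        )
        mean = float(vals.mean())
        se = float(np.sqrt(np.sum(ses**2)) / vals.size)
        if vals.size > 1:
            se = float(math.hypot(se, vals.std(ddof=1) / math.sqrt(vals.size)))
        avg[cond] = (mean, se)
    ref_mean, ref_se = avg[reference]
    if ref_mean == 0:
        raise ValueError("reference mean initiation rate is zero")
    fold = {}
    for cond, (m, s) in avg.items():
        if m == 0:
            raise ValueError(f"zero mean initiation rate in condition {cond!r}")
        f = ref_mean / m
        rel = math.sqrt((ref_se / ref_mean) ** 2 + (s / m) ** 2) if m else 0.0
        fold[cond] = (f, f * rel)
    return InitiationSummary(avg_k_init=avg, fold_inhibition=fold, reference=reference)


# ---------------------------------------------------------------------------
# count-based rates and derived constants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SecondOrderRate:
    """k = n / (T C) with Poisson standard error sqrt(n) / (T C)."""

    k: float
    se: float
    n_events: int
    total_time_s: float
    conc_M: float


def rate_from_counts(n_events: int, total_time_s: float, conc_M: float) -> SecondOrderRate:
    """Second-order association rate constant from event counts.

    Exact arithmetic: ``k = n / (T C)``, ``se = sqrt(n) / (T C)`` (Poisson
    counting error).
    """
    if total_time_s <= 0 or conc_M <= 0:
        raise ValueError("total_time_s and conc_M must be > 0")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    denom = total_time_s * conc_M
    return SecondOrderRate(
        k=n_events / denom,
        se=math.sqrt(n_events) / denom,
        n_events=n_events,
        total_time_s=total_time_s,
        conc_M=conc_M,
    )


def kd_from_kinetics(k_on: float, tau1_s: float) -> float:
    """Kinetic dissociation constant K_D = 1 / (k_on tau1), in molar."""
    if k_on <= 0 or tau1_s <= 0:
        raise ValueError("k_on and tau1 must be > 0")
    return 1.0 / (k_on * tau1_s)


# ---------------------------------------------------------------------------
# photobleaching control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhotobleachVerdict:
    k_bleach: float  # s^-1
    threshold: float  # 0.1 / tau2
    negligible: bool


def photobleach_check(dye_sample: DwellSample, tau2_s: float) -> PhotobleachVerdict:
    """Single-exponential disappearance rate of immobilized dye vs tau2.

    Fits ``k_bl`` by censoring-aware exponential MLE (events / total observed
    time) on a dye-only recording under identical illumination.  The verdict
    is "negligible" iff ``k_bl < 0.1 / tau2``, i.e. bleaching shortens the
    slow dwell phase by less than ten percent.
    """
    if tau2_s <= 0:
        raise ValueError("tau2_s must be > 0")
    total = float(np.sum(dye_sample.durations))
    n_events = int(np.sum(~dye_sample.censored))
    k_bl = n_events / total if total > 0 else 0.0
    thresh = 0.1 / tau2_s
    return PhotobleachVerdict(k_bleach=k_bl, threshold=thresh, negligible=k_bl < thresh)
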