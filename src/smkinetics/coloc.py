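"""Two-channel coincidence statistics for interval recordings.

Arrival and departure events are the start and end frames of detected
intervals.  Two events coincide when their frame indices differ by at most
the coincidence window (default +/-1 frame, inclusive).  The randomized
pairing control builds the chance-coincidence null by pairing absolute
departure times drawn from *different* locations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .intervals import DwellSample, SecondOrderRate, rate_from_counts
from .types import RecordingSet

__all__ = [
    "CoincidenceResult",
    "PairingControl",
    "coarrival_fraction",
    "codeparture_fraction",
    "randomized_pairing_control",
    "departure_times_by_location",
    "predicted_coarrival",
    "recruitment_rate",
    "split_dwells_by_coarrival",
]


@dataclass(frozen=True)
class CoincidenceResult:
    n_events: int
    n_coincident: int
    fraction: float
    se: float  # binomial
    window_frames: int


def _binomial(n_hit: int, n: int, window: int) -> CoincidenceResult:
    f = n_hit / n if n else 0.0
    se = math.sqrt(f * (1.0 - f) / n) if n else 0.0
    return CoincidenceResult(
        n_events=n, n_coincident=n_hit, fraction=f, se=se, window_frames=window
    )


def _starts(rec: RecordingSet, channel: str) -> dict[int, np.ndarray]:
    out: dict[int, list] = {}
    for iv in rec.intervals:
        if iv.channel == channel:
            out.setdefault(iv.location_id, []).append(iv.start_frame)
    return {k: np.array(v) for k, v in out.items()}


def coarrival_fraction(
    rec: RecordingSet, ch_a: str, ch_b: str, window_frames: int = 1
) -> CoincidenceResult:
    """Fraction of ch_a arrivals with a ch_b arrival within the window.

    Each ch_a interval start at a location is coincident iff some ch_b
    interval at the same location starts within ``window_frames`` frames
    (inclusive).
    """
    starts_b = _starts(rec, ch_b)
    n = n_hit = 0
    for iv in rec.intervals:
        if iv.channel != ch_a:
            continue
        n += 1
        sb = starts_b.get(iv.location_id)
        if sb is not None and np.any(np.abs(sb - iv.start_frame) <= window_frames):
            n_hit += 1
    return _binomial(n_hit, n, window_frames)


def _coarrived_pairs(rec: RecordingSet, ch_a: str, ch_b: str, window: int):
    """(interval_a, interval_b) pairs whose arrivals coincide, nearest-start
    matching, each b interval used at most once per location."""
    by_loc_b: dict[int, list] = {}
    for iv in rec.intervals:
        if iv.channel == ch_b:
            by_loc_b.setdefault(iv.location_id, []).append(iv)
    pairs = []
    for iv in rec.intervals:
        if iv.channel != ch_a:
            continue
        cands = by_loc_b.get(iv.location_id, [])
        best = None
        for jv in cands:
            dlt = abs(jv.start_frame - iv.start_frame)
            if dlt <= window and (best is None or dlt < abs(best.start_frame - iv.start_frame)):
                best = jv
        if best is not None:
            pairs.append((iv, best))
            cands.remove(best)
    return pairs


def codeparture_fraction(
    rec: RecordingSet,
    ch_a: str,
    ch_b: str,
    window_frames: int = 1,
    condition: str = "co-arrived",
) -> CoincidenceResult:
    """Fraction of co-arrived complexes whose departures also coincide.

    Restricted (by default) to complexes whose two channels arrived within
    the window; departure is coincident iff the end frames differ by at most
    ``window_frames``.
    """
    if condition != "co-arrived":
        raise ValueError("only the co-arrived conditioning is implemented")
    pairs = _coarrived_pairs(rec, ch_a, ch_b, window_frames)
    n_hit = sum(
        1 for a, b in pairs if abs(a.end_frame - b.end_frame) <= window_frames
    )
    return _binomial(n_hit, len(pairs), window_frames)


@dataclass
class PairingControl:
    n_pairs: int
    n_coincident: int
    fraction_coincident: float
    delta_t_s: np.ndarray  # signed departure-time differences (s)
    window_frames: int


def departure_times_by_location(rec: RecordingSet, channel: str) -> dict[int, list[int]]:
    """Absolute departure frames of every interval, grouped by location."""
    out: dict[int, list[int]] = {}
    for iv in rec.intervals:
        if iv.channel == channel:
            out.setdefault(iv.location_id, []).append(iv.end_frame)
    return out


def randomized_pairing_control(
    departures: dict[int, list],
    window_frames: int = 1,
    seed=None,
    frame_interval_s: float = 1.0,
) -> PairingControl:
    """Chance-coincidence null by random pairing across locations.

    Pools all absolute departure times, then pairs each event with a
    randomly chosen event from a *different* location (a seeded
    derangement-style shuffle: no event is paired with itself and same-
    location pairings are repaired by swaps).  Returns the signed time
    differences and the fraction coincident within the window.
    """
    locs, times = [], []
    for loc, ts in departures.items():
        for t in ts:
            locs.append(loc)
            times.append(t)
    if len(set(locs)) < 2:
        raise ValueError("need departures from at least two locations")
    locs = np.array(locs)
    times = np.array(times, dtype=float)
    n = times.size
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    # repair self- and same-location pairings by swapping with random partners
    for _ in range(200):
        bad = np.flatnonzero(locs[perm] == locs)
        if bad.size == 0:
            break
        for i in bad:
            j = rng.integers(0, n)
            perm[i], perm[j] = perm[j], perm[i]
    delta_frames = times - times[perm]
    n_hit = int(np.sum(np.abs(delta_frames) <= window_frames))
    return PairingControl(
        n_pairs=n,
        n_coincident=n_hit,
        fraction_coincident=n_hit / n,
        delta_t_s=delta_frames * frame_interval_s,
        window_frames=window_frames,
    )


def predicted_coarrival(conc_M: float, kd_M: float, label_eff: float = 1.0) -> float:
    """Equilibrium-model co-arrival prediction: label_eff * conc/(conc + K_D).

    Assumes SCF-bound and SCF-free polymerase bind the promoter with equal
    association rate constants, so the co-arriving fraction equals the
    solution occupancy times the labeling efficiency.
    """
    if conc_M < 0 or kd_M < 0 or not 0.0 <= label_eff <= 1.0:
        raise ValueError("need conc, kd >= 0 and label_eff in [0, 1]")
    if conc_M == 0:
        return 0.0
    return label_eff * conc_M / (conc_M + kd_M)


def recruitment_rate(
    rec: RecordingSet,
    target_channel: str,
    visitor_channel: str,
    conc_M: float,
    window_frames: int = 1,
) -> SecondOrderRate:
    """Second-order rate of visitor binding onto preformed target complexes.

    Counts visitor arrivals strictly inside target-bound intervals (start
    later than the co-arrival window after target arrival and before target
    departure) and divides by summed target-bound time and visitor
    concentration.
    """
    starts_v = _starts(rec, visitor_channel)
    n_events = 0
    bound_frames = 0
    for iv in rec.intervals:
        if iv.channel != target_channel:
            continue
        bound_frames += iv.n_frames
        sv = starts_v.get(iv.location_id)
        if sv is not None:
            n_events += int(
                np.sum((sv > iv.start_frame + window_frames) & (sv < iv.end_frame))
            )
    if bound_frames == 0:
        raise ValueError("no target-bound time in recording")
    return rate_from_counts(n_events, bound_frames * rec.frame_interval_s, conc_M)


def split_dwells_by_coarrival(
    rec: RecordingSet,
    target_channel: str = "rnap",
    partner_channel: str = "greb",
    window_frames: int = 1,
    min_duration_s: float | None = None,
) -> tuple[DwellSample, DwellSample]:
    """Partition target dwells into co-arrived and lone subsets.

    Exhaustive and disjoint: every target interval lands in exactly one
    subset, classified by whether a partner-channel arrival coincided with
    its start (within the window).  Both subsets carry the same censoring
    and truncation conventions as :func:`~smkinetics.intervals.extract_dwells`.
    """
    starts_p = _starts(rec, partner_channel)
    dt = rec.frame_interval_s
    min_d = dt if min_duration_s is None else max(min_duration_s, dt)
    sets: dict[bool, dict[str, list]] = {
        True: {"d": [], "c": [], "l": []},
        False: {"d": [], "c": [], "l": []},
    }
    for iv in rec.intervals:
        if iv.channel != target_channel:
            continue
        d = iv.n_frames * dt
        cens = iv.end_frame >= rec.n_frames
        if d < min_d and not cens:
            continue
        sp = starts_p.get(iv.location_id)
        co = sp is not None and bool(
            np.any(np.abs(sp - iv.start_frame) <= window_frames)
        )
        sets[co]["d"].append(d)
        sets[co]["c"].append(cens)
        sets[co]["l"].append(iv.location_id)

    def build(s):
        return DwellSample(
            durations=np.array(s["d"]),
            frame_interval_s=dt,
            censored=np.array(s["c"], dtype=bool),
            location_ids=np.array(s["l"]),
            min_observed_s=min_d,
            window_offset_s=0.5 * dt,
        )

    return build(sets[True]), build(sets[False])
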