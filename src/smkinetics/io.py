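"""File formats, configuration and the analysis pipeline driver.

Recordings travel as tab-separated text with two header lines
(``#frame_interval_s=<v>``, ``#n_frames=<v>``) followed by columns
``location_id  kind  channel  start_frame  end_frame`` (half-open, 0-based).
FCS curves are 2- or 3-column numeric text (``lag_s  G  [sigma_G]``).
Analysis reports are JSON for diff-ability and provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .fcs import FCSCurve
from .types import FrameInterval, Location, RecordingSet

__all__ = [
    "read_recording",
    "write_recording",
    "read_fcs_curve",
    "write_fcs_curve",
    "write_truth",
    "AnalysisConfig",
    "run_pipeline",
]


class FormatError(ValueError):
    """Malformed input file (message carries the line number)."""


def write_recording(rec: RecordingSet, path) -> None:
    path = Path(path)
    lines = [
        f"#frame_interval_s={rec.frame_interval_s!r}",
        f"#n_frames={rec.n_frames}",
    ]
    for ch, c in sorted(rec.concentrations.items()):
        lines.append(f"#conc_{ch}_M={c!r}")
    kinds = {loc.location_id: loc.kind for loc in rec.locations}
    # locations without intervals still need their kind on record
    seen = {iv.location_id for iv in rec.intervals}
    for loc in rec.locations:
        if loc.location_id not in seen:
            lines.append(f"#empty_location={loc.location_id}\t{loc.kind}")
    for iv in sorted(rec.intervals):
        lines.append(
            f"{iv.location_id}\t{kinds.get(iv.location_id, 'dna')}\t"
            f"{iv.channel}\t{iv.start_frame}\t{iv.end_frame}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_recording(path) -> RecordingSet:
    path = Path(path)
    frame_interval = None
    n_frames = None
    concentrations: dict[str, float] = {}
    kinds: dict[int, str] = {}
    intervals: list[FrameInterval] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: malformed header {line!r}")
            key, _, val = line[1:].partition("=")
            if key == "frame_interval_s":
                frame_interval = float(val)
            elif key == "n_frames":
                n_frames = int(val)
            elif key.startswith("conc_") and key.endswith("_M"):
                concentrations[key[5:-2]] = float(val)
            elif key == "empty_location":
                loc_id, _, kind = val.partition("\t")
                kinds[int(loc_id)] = kind.strip()
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise FormatError(
                f"{path}:{lineno}: expected 5 tab-separated columns, got {len(parts)}"
            )
        try:
            loc_id = int(parts[0])
            start, end = int(parts[3]), int(parts[4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        kind, channel = parts[1], parts[2]
        if loc_id in kinds and kinds[loc_id] != kind:
            raise FormatError(
                f"{path}:{lineno}: location {loc_id} listed with conflicting kinds"
            )
        kinds[loc_id] = kind
        try:
            intervals.append(
                FrameInterval(
                    location_id=loc_id, channel=channel,
                    start_frame=start, end_frame=end,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    if frame_interval is None or n_frames is None:
        raise FormatError(
            f"{path}: missing #frame_interval_s / #n_frames header lines"
        )
    locations = [Location(location_id=i, kind=k) for i, k in sorted(kinds.items())]
    try:
        return RecordingSet(
            frame_interval_s=frame_interval,
            n_frames=n_frames,
            locations=locations,
            intervals=intervals,
            concentrations=concentrations,
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_fcs_curve(curve: FCSCurve, path) -> None:
    cols = [curve.lags, curve.g]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    np.savetxt(path, np.column_stack(cols), header="lag_s G sigma_G"[: 11 + 8 * (len(cols) - 2)])


def read_fcs_curve(path) -> FCSCurve:
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] not in (2, 3):
        raise FormatError(f"{path}: expected 2 or 3 numeric columns")
    sigma = data[:, 2] if data.shape[1] == 3 else None
    try:
        return FCSCurve(lags=data[:, 0], g=data[:, 1], sigma=sigma)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, default=float))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Configuration of a full recording analysis.

    Channels default to the standard naming (polymerase ``rnap``, factor
    ``greb``, transcript ``probe``); concentrations are molar unless given
    with an explicit ``_nM`` suffix in the YAML file.
    """

    recording: str = ""
    target_channel: str = "rnap"
    partner_channel: str = "greb"
    probe_channel: str = "probe"
    min_probe_duration_s: float = 5.0
    coincidence_window_frames: int = 1
    n_boot: int = 200
    seed: int = 0
    concentrations_M: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        conc = {}
        for key in list(raw.keys()):
            if key.endswith("_conc_nM"):
                conc[key[: -len("_conc_nM")]] = float(raw.pop(key)) * 1e-9
            elif key.endswith("_conc_M"):
                conc[key[: -len("_conc_M")]] = float(raw.pop(key))
        raw.setdefault("concentrations_M", {}).update(conc)
        cfg = cls(**raw)
        if cfg.recording and not Path(cfg.recording).exists():
            raise FileNotFoundError(cfg.recording)
        return cfg


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full stage sequence on one recording; returns a report bundle.

    Stages: dwell extraction and biexponential fits (all events and the
    co-arrival split), first-binding fit, coincidence statistics with the
    randomized-pairing control, scheme-rate assembly, and (when a probe
    channel is present) the initiation-rate fit.  Every estimate carries its
    N and SE; the report echoes the config, the seed, and input hashes.
    """
    from .coloc import (
        coarrival_fraction,
        codeparture_fraction,
        departure_times_by_location,
        randomized_pairing_control,
        split_dwells_by_coarrival,
    )
    from .intervals import (
        extract_dwells,
        first_binding_times,
        fit_biexponential,
        fit_first_binding,
        initiation_rate,
    )
    from .scheme import assemble_scheme

    rec = read_recording(config.recording)
    report: dict = {
        "software": {"name": "smkinetics", "version": __version__},
        "config": asdict(config),
        "inputs": {"recording": {"path": str(config.recording), "sha256": _sha256(config.recording)}},
        "stages": {},
    }
    channels = rec.channels()
    tgt, prt = config.target_channel, config.partner_channel
    conc = dict(rec.concentrations)
    conc.update(config.concentrations_M)
    warnings: list[str] = []

    def stage(name, fn):
        try:
            report["stages"][name] = fn()
        except Exception as exc:  # stage-tagged diagnostics
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # dwell fits
    def dwell_stage():
        sample = extract_dwells(rec, tgt)
        fit = fit_biexponential(sample, n_boot=config.n_boot, seed=config.seed)
        return {
            "n": fit.n,
            "n_censored": int(sample.censored.sum()),
            "a": fit.a, "se_a": fit.se_a,
            "tau1_s": fit.tau1_s, "se_tau1": fit.se_tau1,
            "tau2_s": fit.tau2_s, "se_tau2": fit.se_tau2,
            "loglik": fit.loglik, "flags": fit.flags,
        }

    stage("dwells", dwell_stage)

    # first binding
    have_controls = bool(rec.locations_of_kind("control"))
    if have_controls:
        def fb_stage():
            fb = first_binding_times(rec, tgt)
            fit = fit_first_binding(
                fb["dna"], fb["control"], conc_M=conc.get(tgt, 1.0),
                n_boot=config.n_boot, seed=config.seed,
            )
            return {
                "k_a": fit.k_a, "se_k_a": fit.se_k_a,
                "k_bkgnd": fit.k_bkgnd, "se_k_bkgnd": fit.se_k_bkgnd,
                "a_f": fit.a_f, "se_a_f": fit.se_a_f,
                "n_dna": fit.n_dna, "n_control": fit.n_control,
                "loglik": fit.loglik, "flags": fit.flags,
            }

        stage("first_binding", fb_stage)
    else:
        warnings.append("no control locations: no background estimate; "
                        "first-binding and initiation stages skipped")

    # coincidence
    if prt in channels:
        def coloc_stage():
            w = config.coincidence_window_frames
            arr = coarrival_fraction(rec, tgt, prt, w)
            dep = codeparture_fraction(rec, tgt, prt, w)
            ctl = randomized_pairing_control(
                departure_times_by_location(rec, tgt), w,
                seed=config.seed, frame_interval_s=rec.frame_interval_s,
            )
            return {
                "coarrival": {"n": arr.n_events, "fraction": arr.fraction, "se": arr.se},
                "codeparture": {"n": dep.n_events, "fraction": dep.fraction, "se": dep.se},
                "pairing_control": {
                    "n_pairs": ctl.n_pairs,
                    "fraction_coincident": ctl.fraction_coincident,
                },
            }

        stage("coincidence", coloc_stage)

        def split_stage():
            co, lone = split_dwells_by_coarrival(rec, tgt, prt,
                                                 config.coincidence_window_frames)
            out = {}
            for name, sample in (("co_arrived", co), ("lone", lone)):
                if sample.n - sample.censored.sum() >= 50:
                    f = fit_biexponential(sample, n_boot=config.n_boot, seed=config.seed)
                    out[name] = {"n": f.n, "a": f.a, "tau1_s": f.tau1_s,
                                 "tau2_s": f.tau2_s, "se_a": f.se_a,
                                 "se_tau1": f.se_tau1, "se_tau2": f.se_tau2}
                else:
                    out[name] = {"n": sample.n, "skipped": "fewer than 50 dwells"}
            return out

        stage("dwells_by_coarrival", split_stage)

    # scheme assembly
    if have_controls:
        def scheme_stage():
            d = report["stages"]["dwells"]
            f = report["stages"]["first_binding"]

            class _D:  # lightweight adapters for assemble_scheme
                a, tau1_s, tau2_s = d["a"], d["tau1_s"], d["tau2_s"]
                se_a, se_tau1, se_tau2 = d["se_a"], d["se_tau1"], d["se_tau2"]

            class _F:
                k_a, se_k_a = f["k_a"], f["se_k_a"]

            rates = assemble_scheme(_F, _D, n_boot=config.n_boot, seed=config.seed)
            return {"k1": rates.k1, "k_m1": rates.k_m1, "k2": rates.k2,
                    "k_m2": rates.k_m2, "se": rates.se}

        stage("scheme", scheme_stage)

    # initiation
    if config.probe_channel in channels and have_controls:
        def init_stage():
            fit = initiation_rate(
                rec, min_duration_s=config.min_probe_duration_s,
                n_boot=config.n_boot, seed=config.seed,
            )
            return {"k_init": fit.k_a, "se_k_init": fit.se_k_a,
                    "k_bkgnd": fit.k_bkgnd, "se_k_bkgnd": fit.se_k_bkgnd,
                    "a_f": fit.a_f, "se_a_f": fit.se_a_f,
                    "n_dna": fit.n_dna, "n_control": fit.n_control}

        stage("initiation", init_stage)

    report["warnings"] = warnings
    return report
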