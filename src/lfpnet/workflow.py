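"""Study configuration, file I/O and pipeline orchestration.

Recordings travel as EDF (European Data Format: ASCII header + 16-bit
samples), the open interchange standard for electrophysiology; evoked sweeps
and all result tables are plain tab-separated text.  Every written table is
stamped with the configuration hash and master seed so reruns are auditable.

The pipeline runs simulate -> preprocess -> spectra / coherence / PAC ->
TFCE group statistics, plus the LTP arm, and returns a bundle of tidy
result tables.  All randomness flows from the master seed.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import connectivity, evoked, pac, spectral
from .groupstats import TFCEResult, tfce_permutation, two_sample_test
from .preprocess import (
    Recording,
    accepted_segments,
    bandpass,
    reject_artifacts,
    remove_line_noise,
    segment_epochs,
)
from .synthgen import AgedEffects, GroupDataset, generate_group_dataset
from .evoked import Sweep

__all__ = [
    "StudyConfig",
    "write_edf",
    "read_recording",
    "write_table",
    "read_table",
    "simulate_study",
    "write_dataset",
    "load_dataset",
    "run_pipeline",
    "ALL_STAGES",
]

log = logging.getLogger("lfpnet")

ALL_STAGES = ("preprocess", "spectra", "coherence", "pac", "tfce", "ltp")


@dataclass
class StudyConfig:
    """All tunable pipeline parameters plus the master seed."""

    n_young: int = 8
    n_aged: int = 8
    duration_s: float = 120.0
    aged_effects: dict = field(
        default_factory=lambda: asdict(AgedEffects())
    )
    line_freq: float = 50.0
    band_lo: float = 1.0
    band_hi: float = 256.0
    win_s: float = 2.0
    stride_s: float = 1.0
    motion_threshold: float = 0.2
    amp_limit_uv: float = 1000.0
    slow_power_limit: float = 0.6
    spectra_channels: tuple = ("OBL", "ECL", "CA1L", "BLA")
    pairs: tuple = connectivity.DEFAULT_PAIRS
    pac_channels: tuple = ("OBL", "CA1L")
    n_cycles: float = 7.0
    bands: dict = field(default_factory=lambda: dict(spectral.BANDS))
    tfce_h: float = 2.0
    tfce_e: float = 0.5
    tfce_alpha: float = 0.05
    tfce_n_perm: int = 1000
    tfce_fmax: float = 100.0
    tfce_pairs: tuple = (("OBL", "OBR"),)
    blanking_ms: float = 1.5
    baseline_mode: str = "window"
    baseline_n_points: int = 12
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spectra_channels"] = list(self.spectra_channels)
        d["pac_channels"] = list(self.pac_channels)
        d["pairs"] = [list(p) for p in self.pairs]
        d["tfce_pairs"] = [list(p) for p in self.tfce_pairs]
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        for key in ("spectra_channels", "pac_channels"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("pairs", "tfce_pairs"):
            if key in d:
                d[key] = tuple(tuple(p) for p in d[key])
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# EDF read/write
# ---------------------------------------------------------------------------

MOTION_LABEL = "MOTION"


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, rec: Recording) -> None:
    """Write a recording (LFP channels + MOTION trace) as EDF.

    One data record per second; each channel gets a tight symmetric physical
    range so 16-bit quantisation error is bounded by its own amplitude /
    2^16 rather than by the amplifier's full range.
    """
    rate = rec.rate
    spr = int(round(rate))
    if abs(spr - rate) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    labels = sorted(rec.channel_map, key=rec.channel_map.get)
    series = [rec.channel(lb) for lb in labels] + [rec.motion]
    labels = labels + [MOTION_LABEL]
    dims = ["uV"] * (len(labels) - 1) + ["a.u."]
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF record")

    phys_max = []
    for x in series:
        pm = float(np.abs(x).max()) * 1.0001 + 1e-6
        phys_max.append(float(f"{pm:.6g}"))
    dmin, dmax = -32768, 32767

    ns = len(labels)
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("synthetic animal", 80),
            _ascii("lfpnet synthetic recording", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (ns + 1), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),
            _ascii(ns, 4),
        ]
    )
    header += b"".join(_ascii(lb, 16) for lb in labels)
    header += b"".join(_ascii("synthetic", 80) for _ in labels)
    header += b"".join(_ascii(d, 8) for d in dims)
    header += b"".join(_ascii(f"{-pm:.6g}", 8) for pm in phys_max)
    header += b"".join(_ascii(f"{pm:.6g}", 8) for pm in phys_max)
    header += b"".join(_ascii(dmin, 8) for _ in labels)
    header += b"".join(_ascii(dmax, 8) for _ in labels)
    header += b"".join(_ascii("", 80) for _ in labels)
    header += b"".join(_ascii(spr, 8) for _ in labels)
    header += b"".join(_ascii("", 32) for _ in labels)

    digital = []
    for x, pm in zip(series, phys_max):
        gain = 2 * pm / (dmax - dmin)
        d = np.round((x[: n_records * spr] + pm) / gain + dmin)
        digital.append(np.clip(d, dmin, dmax).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for d in digital:
                fh.write(d[r * spr : (r + 1) * spr].tobytes())


def read_recording(path) -> Recording:
    """Read an EDF written by :func:`write_edf` back into a Recording.

    Refuses files without a MOTION channel, listing the labels found.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_records = int(head[236:244].decode().strip())
        ns = int(head[252:256].decode().strip())
        sig = fh.read(256 * ns)

        def fields(offset, width):
            start = offset * ns
            return [
                sig[start + i * width : start + (i + 1) * width].decode().strip()
                for i in range(ns)
            ]

        labels = fields(0, 16)
        # layout: label(16) transducer(80) dim(8) pmin(8) pmax(8) dmin(8)
        # dmax(8) prefilter(80) samples-per-record(8) reserved(32)
        base = 16 * ns  # past labels
        base += 80 * ns  # transducer
        base += 8 * ns  # dim
        pmin = [float(sig[base + i * 8 : base + (i + 1) * 8]) for i in range(ns)]
        base += 8 * ns
        pmax = [float(sig[base + i * 8 : base + (i + 1) * 8]) for i in range(ns)]
        base += 8 * ns
        dmin = [int(sig[base + i * 8 : base + (i + 1) * 8]) for i in range(ns)]
        base += 8 * ns
        dmax = [int(sig[base + i * 8 : base + (i + 1) * 8]) for i in range(ns)]
        base += 8 * ns
        base += 80 * ns  # prefilter
        spr = [int(sig[base + i * 8 : base + (i + 1) * 8]) for i in range(ns)]

        data = np.fromfile(fh, dtype="<i2")

    if MOTION_LABEL not in labels:
        raise ValueError(
            f"EDF lacks a {MOTION_LABEL} channel; found labels: {', '.join(labels)}"
        )
    if len(set(spr)) != 1:
        raise ValueError("mixed sampling rates are not supported")
    spr0 = spr[0]
    expected = n_records * ns * spr0
    data = data[:expected].reshape(n_records, ns, spr0)
    series = []
    for i in range(ns):
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        x = (data[:, i, :].reshape(-1).astype(float) - dmin[i]) * gain + pmin[i]
        series.append(x)
    motion = series[labels.index(MOTION_LABEL)]
    lfp_labels = [lb for lb in labels if lb != MOTION_LABEL]
    arr = np.vstack([series[labels.index(lb)] for lb in lfp_labels])
    channel_map = {lb: i for i, lb in enumerate(lfp_labels)}
    return Recording(arr, float(spr0), channel_map, motion)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, stamp: Mapping[str, object] | None = None) -> None:
    """Write a tidy table as TSV with ``#`` header lines naming parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# lfpnet results table\n")
        for key, val in (stamp or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# dataset persistence
# ---------------------------------------------------------------------------

def simulate_study(config: StudyConfig) -> GroupDataset:
    """Generate the synthetic cohort the configuration describes."""
    return generate_group_dataset(
        n_young=config.n_young,
        n_aged=config.n_aged,
        aged_effects=AgedEffects(**config.aged_effects),
        duration_s=config.duration_s,
        seed=config.seed,
    )


def _sweep_rows(animal: str, arm: str, sweep_id: int, sw: Sweep) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": animal,
            "arm": arm,
            "sweep_id": sweep_id,
            "intensity_mV": sw.stim_intensity_mv,
            "timepoint_min": np.nan if sw.timepoint_min is None else sw.timepoint_min,
            "time_ms": sw.time_ms,
            "voltage_uV": sw.voltage_uv,
        }
    )


def write_dataset(ds: GroupDataset, outdir, config: StudyConfig | None = None) -> None:
    """Persist a cohort: EDF per animal, sweep tables, groups, ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for animal, rec in ds.recordings.items():
        write_edf(outdir / f"{animal}.edf", rec)
    write_table(
        pd.DataFrame(
            {"animal_id": list(ds.groups), "group": list(ds.groups.values())}
        ),
        outdir / "groups.tsv",
    )
    rows = []
    sid = 0
    for animal, by_int in ds.io_sweeps.items():
        for inten, sweeps in by_int.items():
            for sw in sweeps:
                rows.append(_sweep_rows(animal, "io", sid, sw))
                sid += 1
    for animal, sweeps in ds.ltp_sweeps.items():
        for sw in sweeps:
            rows.append(_sweep_rows(animal, "ltp", sid, sw))
            sid += 1
    if rows:
        write_table(pd.concat(rows, ignore_index=True), outdir / "sweeps.tsv")
    truths = {
        animal: asdict(t) for animal, t in ds.lfp_truths.items()
    }
    with open(outdir / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(truths, fh, sort_keys=True)
    if config is not None:
        config.to_yaml(outdir / "config.yaml")


def load_dataset(indir) -> GroupDataset:
    """Load a cohort written by :func:`write_dataset`."""
    indir = Path(indir)
    groups_df = read_table(indir / "groups.tsv")
    groups = dict(zip(groups_df["animal_id"], groups_df["group"]))
    recordings = {
        animal: read_recording(indir / f"{animal}.edf") for animal in groups
    }
    io_sweeps: dict[str, dict[float, list[Sweep]]] = {a: {} for a in groups}
    ltp_sweeps: dict[str, list[Sweep]] = {a: [] for a in groups}
    sweeps_path = indir / "sweeps.tsv"
    if sweeps_path.exists():
        df = read_table(sweeps_path)
        for (animal, arm, sid), g in df.groupby(["animal_id", "arm", "sweep_id"]):
            tp = g["timepoint_min"].iloc[0]
            sw = Sweep(
                g["time_ms"].to_numpy(),
                g["voltage_uV"].to_numpy(),
                stim_intensity_mv=float(g["intensity_mV"].iloc[0]),
                timepoint_min=None if pd.isna(tp) else float(tp),
            )
            if arm == "io":
                io_sweeps[animal].setdefault(sw.stim_intensity_mv, []).append(sw)
            else:
                ltp_sweeps[animal].append(sw)
    return GroupDataset(recordings, groups, {}, {}, io_sweeps, ltp_sweeps)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _stage_guard(stage: str, animal: str):
    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(
                    f"stage {stage!r} failed for animal {animal!r}: {exc}"
                ) from exc

    return _Guard()


def run_pipeline(
    config: StudyConfig,
    dataset: GroupDataset | None = None,
    indir=None,
    outdir=None,
    stages: Sequence[str] | None = None,
) -> dict:
    """Run the full analysis and return a bundle of result tables.

    ``dataset`` (in-memory) or ``indir`` (files from ``write_dataset``)
    provide the cohort; otherwise it is simulated from the config.  ``stages``
    selects a subset of :data:`ALL_STAGES`; preprocessing always runs when any
    LFP stage is enabled.  With ``outdir`` set, every table is written as TSV
    stamped with the config hash and seed.
    """
    stages = set(stages if stages is not None else ALL_STAGES)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if dataset is None:
        dataset = load_dataset(indir) if indir else simulate_study(config)
    stamp = {"config_hash": config.config_hash, "seed": config.seed}
    bundle: dict = {"config_hash": config.config_hash, "seed": config.seed}
    groups = dataset.groups
    young = [a for a, g in groups.items() if g == "young"]
    aged = [a for a, g in groups.items() if g == "aged"]

    lfp_stages = {"preprocess", "spectra", "coherence", "pac", "tfce"} & stages
    epochs = {}
    recs = {}
    if lfp_stages:
        epoch_rows = []
        for animal, rec in dataset.recordings.items():
            with _stage_guard("preprocess", animal):
                r = remove_line_noise(rec, config.line_freq)
                r = bandpass(r, config.band_lo, config.band_hi)
                eps = segment_epochs(
                    r, config.win_s, config.stride_s, config.motion_threshold
                )
                eps = reject_artifacts(
                    r, eps, config.amp_limit_uv, config.slow_power_limit
                )
            recs[animal] = r
            epochs[animal] = eps
            for (s, e), lab in zip(eps.windows, eps.labels):
                epoch_rows.append(
                    {
                        "animal_id": animal,
                        "group": groups[animal],
                        "start_s": s / r.rate,
                        "end_s": e / r.rate,
                        "label": lab,
                    }
                )
        bundle["epochs"] = pd.DataFrame(epoch_rows)
        log.info("preprocess: %d animals", len(recs))

    rel_by_channel: dict[str, dict[str, np.ndarray]] = {}
    grid = None
    if {"spectra", "tfce"} & stages:
        spec_rows, band_rows = [], []
        for animal in groups:
            for ch in config.spectra_channels:
                with _stage_guard("spectra", animal):
                    freqs, psd = spectral.welch_psd(recs[animal], epochs[animal], ch)
                    grid, rel = spectral.relative_power(freqs, psd)
                rel_by_channel.setdefault(ch, {})[animal] = rel
                for f, v in zip(grid, rel):
                    spec_rows.append(
                        {
                            "animal_id": animal,
                            "group": groups[animal],
                            "channel": ch,
                            "freq_hz": f,
                            "rel_power": v,
                        }
                    )
                for bname, band in config.bands.items():
                    band_rows.append(
                        {
                            "animal_id": animal,
                            "group": groups[animal],
                            "channel": ch,
                            "band": bname,
                            "value": spectral.band_power(grid, rel, tuple(band)),
                        }
                    )
        if "spectra" in stages:
            bundle["spectra"] = pd.DataFrame(spec_rows)
            bundle["band_summary"] = pd.DataFrame(band_rows)
            tests = []
            for ch in config.spectra_channels:
                for bname, band in config.bands.items():
                    yv = [
                        spectral.band_power(grid, rel_by_channel[ch][a], tuple(band))
                        for a in young
                    ]
                    av = [
                        spectral.band_power(grid, rel_by_channel[ch][a], tuple(band))
                        for a in aged
                    ]
                    res = two_sample_test(av, yv)
                    tests.append(
                        {
                            "channel": ch,
                            "band": bname,
                            "metric": "rel_power",
                            "young_mean": float(np.mean(yv)),
                            "aged_mean": float(np.mean(av)),
                            "t": res.t,
                            "p": res.p,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                        }
                    )
            bundle["band_tests"] = pd.DataFrame(tests)

    imcoh_by_pair: dict[tuple, dict[str, np.ndarray]] = {}
    coh_grid = None
    if {"coherence", "tfce"} & stages:
        coh_rows, sum_rows = [], []
        for animal in groups:
            for pair in config.pairs:
                pair = tuple(pair)
                with _stage_guard("coherence", animal):
                    freqs, sab, saa, sbb = connectivity.cross_spectra(
                        recs[animal], epochs[animal], pair
                    )
                    coh = connectivity.coherency(sab, saa, sbb)
                    mscv = connectivity.msc(coh)
                    imv = connectivity.imcoh(coh)
                mask = (freqs >= spectral.FMIN) & (freqs < spectral.FMAX)
                coh_grid = freqs[mask]
                imcoh_by_pair.setdefault(pair, {})[animal] = imv[mask]
                if "coherence" in stages:
                    for f, m, im in zip(coh_grid, mscv[mask], imv[mask]):
                        coh_rows.append(
                            {
                                "animal_id": animal,
                                "group": groups[animal],
                                "pair": "-".join(pair),
                                "freq_hz": f,
                                "msc": m,
                                "imcoh": im,
                            }
                        )
                    sum_rows.append(
                        {
                            "animal_id": animal,
                            "group": groups[animal],
                            "pair": "-".join(pair),
                            "metric": "imcoh_25_35",
                            "value": connectivity.band_imcoh(coh_grid, imv[mask]),
                        }
                    )
        if "coherence" in stages:
            bundle["coherence"] = pd.DataFrame(coh_rows)
            df = pd.DataFrame(sum_rows)
            bundle["imcoh_summary"] = df
            tests = []
            for pair in config.pairs:
                pname = "-".join(pair)
                sel = df[df["pair"] == pname]
                yv = sel[sel["group"] == "young"]["value"].to_numpy()
                av = sel[sel["group"] == "aged"]["value"].to_numpy()
                res = two_sample_test(av, yv)
                tests.append(
                    {
                        "pair": pname,
                        "metric": "imcoh_25_35",
                        "young_mean": float(yv.mean()),
                        "aged_mean": float(av.mean()),
                        "t": res.t,
                        "p": res.p,
                    }
                )
            bundle["imcoh_tests"] = pd.DataFrame(tests)

    if "pac" in stages:
        pac_rows = []
        comods: dict[tuple, pac.Comodulogram] = {}
        for animal in groups:
            for ch in config.pac_channels:
                with _stage_guard("pac", animal):
                    segs = accepted_segments(recs[animal], epochs[animal], ch)
                    if not segs:
                        raise ValueError("no accepted segments")
                    cm = pac.comodulogram(
                        segs, recs[animal].rate, n_cycles=config.n_cycles
                    )
                comods[(animal, ch)] = cm
                pac_rows.append(
                    {
                        "animal_id": animal,
                        "group": groups[animal],
                        "channel": ch,
                        "pac_full": pac.pac_summary(cm, pac.FULL_WINDOW),
                        "pac_theta_gamma": pac.pac_summary(cm, pac.THETA_GAMMA_WINDOW),
                    }
                )
        df = pd.DataFrame(pac_rows)
        bundle["pac_summary"] = df
        bundle["comodulograms"] = comods
        tests = []
        for ch in config.pac_channels:
            sel = df[df["channel"] == ch]
            for metric in ("pac_full", "pac_theta_gamma"):
                yv = sel[sel["group"] == "young"][metric].to_numpy()
                av = sel[sel["group"] == "aged"][metric].to_numpy()
                res = two_sample_test(av, yv)
                tests.append(
                    {
                        "channel": ch,
                        "metric": metric,
                        "young_mean": float(yv.mean()),
                        "aged_mean": float(av.mean()),
                        "t": res.t,
                        "p": res.p,
                    }
                )
        bundle["pac_tests"] = pd.DataFrame(tests)

    if "tfce" in stages:
        tfce_results: dict[str, TFCEResult] = {}
        tfce_rows = []
        for ch in config.spectra_channels:
            mask = grid <= config.tfce_fmax
            ym = np.vstack([rel_by_channel[ch][a][mask] for a in young])
            am = np.vstack([rel_by_channel[ch][a][mask] for a in aged])
            res = tfce_permutation(
                am, ym, freqs=grid[mask],
                H=config.tfce_h, E=config.tfce_e, alpha=config.tfce_alpha,
                n_perm=config.tfce_n_perm, seed=config.seed,
            )
            tfce_results[f"relpower:{ch}"] = res
            tfce_rows += _tfce_rows("relpower", ch, res)
        for pair in config.tfce_pairs:
            pair = tuple(pair)
            mask = coh_grid <= config.tfce_fmax
            ym = np.vstack([imcoh_by_pair[pair][a][mask] for a in young])
            am = np.vstack([imcoh_by_pair[pair][a][mask] for a in aged])
            res = tfce_permutation(
                am, ym, freqs=coh_grid[mask],
                H=config.tfce_h, E=config.tfce_e, alpha=config.tfce_alpha,
                n_perm=config.tfce_n_perm, seed=config.seed,
            )
            tfce_results[f"imcoh:{'-'.join(pair)}"] = res
            tfce_rows += _tfce_rows("imcoh", "-".join(pair), res)
        bundle["tfce"] = tfce_results
        bundle["tfce_table"] = pd.DataFrame(tfce_rows)

    if "ltp" in stages:
        io_rows = []
        timecourses: dict[str, evoked.LTPTimecourse] = {}
        tc_rows = []
        for animal in groups:
            with _stage_guard("ltp", animal):
                curve = evoked.build_io_curve(
                    {
                        inten: [
                            evoked.extract_features(sw, config.blanking_ms)
                            for sw in sweeps
                        ]
                        for inten, sweeps in dataset.io_sweeps[animal].items()
                    }
                )
                io_rows.append(
                    {
                        "animal_id": animal,
                        "group": groups[animal],
                        "half_max_mv": curve.half_max_mv,
                        "test_stimulus_mv": curve.test_stimulus_mv,
                        "flagged": curve.flagged,
                    }
                )
                sweeps = [
                    evoked.extract_features(sw, config.blanking_ms)
                    for sw in dataset.ltp_sweeps[animal]
                ]
                tps, fepsp, psa = evoked.timecourse_from_sweeps(sweeps)
                tc = evoked.normalize_timecourse(
                    tps, fepsp, psa,
                    baseline_mode=config.baseline_mode,
                    baseline_n_points=config.baseline_n_points,
                )
            timecourses[animal] = tc
            for t, fv, pv in zip(tc.timepoints_min, tc.fepsp_pct, tc.psa_pct):
                tc_rows.append(
                    {
                        "animal_id": animal,
                        "group": groups[animal],
                        "timepoint_min": t,
                        "fepsp_pct": fv,
                        "psa_pct": pv,
                    }
                )
        bundle["io_summary"] = pd.DataFrame(io_rows)
        bundle["ltp_timecourse"] = pd.DataFrame(tc_rows)
        stats = evoked.ltp_phase_stats(
            [timecourses[a] for a in young], [timecourses[a] for a in aged]
        )
        bundle["ltp_phase_stats"] = stats
        bundle["ltp_phase_table"] = stats.table

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, val in bundle.items():
            if isinstance(val, pd.DataFrame):
                write_table(val, outdir / f"{key}.tsv", stamp)
        if "ltp_phase_stats" in bundle:
            write_table(bundle["ltp_phase_stats"].anova, outdir / "ltp_anova.tsv", stamp)
            write_table(
                bundle["ltp_phase_stats"].dunnett, outdir / "ltp_dunnett.tsv", stamp
            )
    return bundle


def _tfce_rows(metric: str, where: str, res: TFCEResult) -> list[dict]:
    rows = []
    for f, t, tf, p, sig in zip(
        res.freqs, res.t_stat, res.tfce_stat, res.p_values, res.sig_mask
    ):
        rows.append(
            {
                "metric": metric,
                "where": where,
                "freq_hz": f,
                "t": t,
                "tfce": tf,
                "p_fw": p,
                "sig": bool(sig),
            }
        )
    return rows
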