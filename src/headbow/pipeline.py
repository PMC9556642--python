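"""Pipeline orchestration: simulate -> preprocess -> analyze -> report.

Owns the study configuration, the fixed stage order, the tidy result
tables and the run manifest.  Every stage is deterministic given the
configuration and seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hbio
from .core import LEVELS, LEVEL_LABELS, BeatGrid, Passage, PassageSet
from .kinematics import PreprocessedTrial, preprocess_trial
from .phase import phase_coupling_take
from .spatial import summarize_take
from .spectral import metrical_power_series, power_correlation
from .stats import compare_conditions
from .synth import (
    ConditionProfile,
    GapSpec,
    StudyDesign,
    SyntheticTrial,
    TempoConfig,
    TrialRecord,
    default_passages,
    generate_dataset,
)
from .timing import tempo_summary
from .xcorr import LagGrid, aggregate_take, take_window_functions

__version__ = "0.1.0"


@dataclass
class StudyConfig:
    """Everything a run needs; defaults are the study's stated parameters."""

    rate: float = 100.0
    design: StudyDesign = field(default_factory=StudyDesign)
    lag_grid: LagGrid = field(default_factory=LagGrid)
    window_ms: float = 1000.0
    window_overlap: float = 0.5
    band_low: float = 0.5
    band_high: float = 12.0
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        """Build and validate a config from a plain (YAML) mapping."""
        raw = dict(raw or {})
        known = {
            "rate", "seed", "window_ms", "window_overlap", "band_low",
            "band_high", "lag_grid", "tempo", "passages", "gaps",
            "conditions", "n_violinists", "takes_per_condition",
            "violinist_amplitude",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        rate = float(raw.get("rate", 100.0))
        tempo = TempoConfig(**raw.get("tempo", {"drift_amplitude": 0.02}))
        if "passages" in raw:
            if not raw["passages"]:
                raise ValueError("passage list must not be empty")
            passages = PassageSet([Passage(**p) for p in raw["passages"]])
        else:
            passages = default_passages()
        gaps = GapSpec(**{k: tuple(v) if k == "gap_length_range" else v
                          for k, v in raw.get("gaps", {}).items()})
        if "conditions" in raw:
            conditions = {
                name: ConditionProfile(**prof)
                for name, prof in raw["conditions"].items()
            }
        else:
            conditions = StudyDesign().conditions
        design = StudyDesign(
            n_violinists=int(raw.get("n_violinists", 4)),
            takes_per_condition=int(raw.get("takes_per_condition", 6)),
            conditions=conditions,
            tempo=tempo,
            passages=passages,
            gaps=gaps,
            violinist_amplitude=tuple(
                raw.get("violinist_amplitude", (0.8, 1.0, 1.2, 1.4))
            ),
        )
        lg = raw.get("lag_grid", {})
        return cls(
            rate=rate,
            design=design,
            lag_grid=LagGrid(
                max_lag_ms=float(lg.get("max_lag_ms", 60.0)),
                step_ms=float(lg.get("step_ms", 10.0)),
                rate=rate,
            ),
            window_ms=float(raw.get("window_ms", 1000.0)),
            window_overlap=float(raw.get("window_overlap", 0.5)),
            band_low=float(raw.get("band_low", 0.5)),
            band_high=float(raw.get("band_high", 12.0)),
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        d = self.design
        return {
            "rate": self.rate,
            "seed": self.seed,
            "window_ms": self.window_ms,
            "window_overlap": self.window_overlap,
            "band_low": self.band_low,
            "band_high": self.band_high,
            "lag_grid": {"max_lag_ms": self.lag_grid.max_lag_ms,
                         "step_ms": self.lag_grid.step_ms},
            "tempo": asdict(d.tempo),
            "passages": [
                {"start_step": p.start_step, "end_step": p.end_step,
                 "note_value": p.note_value}
                for p in d.passages
            ],
            "gaps": {"gap_rate": d.gaps.gap_rate,
                     "gap_length_range": list(d.gaps.gap_length_range)},
            "conditions": {
                name: {
                    "level_amplitudes": dict(prof.level_amplitudes),
                    "bow_amplitude": prof.bow_amplitude,
                    "head_bow_lag": prof.head_bow_lag,
                    "phase_noise_kappa": prof.phase_noise_kappa,
                    "noise_sd": prof.noise_sd,
                    "amplitude_scale": prof.amplitude_scale,
                }
                for name, prof in d.conditions.items()
            },
            "n_violinists": d.n_violinists,
            "takes_per_condition": d.takes_per_condition,
            "violinist_amplitude": list(d.violinist_amplitude),
        }

    def hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def analyze_trial(
    trial: SyntheticTrial | dict,
    config: StudyConfig | None = None,
    pre: PreprocessedTrial | None = None,
) -> dict[str, float]:
    """All per-take measures of one trial.

    ``trial`` may be a SyntheticTrial or a dict with keys head_markers,
    bow_marker, beat_grid, passages (as produced by the file readers).
    """
    config = config or StudyConfig()
    if isinstance(trial, dict):
        head_markers = trial["head_markers"]
        bow_marker = trial["bow_marker"]
        grid: BeatGrid = trial["beat_grid"]
        passages: PassageSet = trial["passages"]
    else:
        head_markers, bow_marker = trial.head_markers, trial.bow_marker
        grid, passages = trial.beat_grid, trial.passages
    pre = pre or preprocess_trial(
        head_markers, bow_marker, grid, passages,
        low=config.band_low, high=config.band_high,
    )
    window_samples = int(round(config.window_ms / 1000.0 * config.rate))

    measures: dict[str, float] = {}
    ts = tempo_summary(grid)
    measures["take_length_s"] = ts.take_length
    measures["tempo_bpm"] = ts.bpm
    measures["tempo_cv"] = ts.cv

    funcs = take_window_functions(
        pre.head_speed, pre.bow_speed, config.lag_grid,
        window_samples, config.window_overlap,
    )
    idx = aggregate_take(funcs)
    measures["peak_r"] = idx.peak_r
    measures["mean_lag_ms"] = idx.mean_lag
    measures["mean_abs_lag_ms"] = idx.mean_abs_lag
    measures["lag_sd_ms"] = idx.lag_sd
    measures["n_xcorr_windows"] = idx.n_windows

    for label, traj in (("head", pre.head_center), ("bow", pre.bow_filled)):
        sp = summarize_take(traj, pre.passage_slices, window_samples,
                            config.window_overlap)
        measures[f"{label}_interdistance_mm"] = sp.mean_interdistance
        measures[f"{label}_hull_cm3"] = sp.hull_volume

    head_power = metrical_power_series(pre.head_speed, grid, passages, config.rate,
                                       companion_passages=pre.bow_speed)
    bow_power = metrical_power_series(pre.bow_speed, grid, passages, config.rate,
                                      companion_passages=pre.head_speed)
    for lvl in LEVELS:
        lab = LEVEL_LABELS[lvl]
        hp, bp = head_power.take_means()[lvl], bow_power.take_means()[lvl]
        measures[f"head_power_{lab}"] = hp
        measures[f"bow_power_{lab}"] = bp
    for lvl, r in power_correlation(head_power, bow_power).items():
        measures[f"power_corr_{LEVEL_LABELS[lvl]}"] = r

    coupling = phase_coupling_take(pre.head_speed, pre.bow_speed, grid,
                                   passages, config.rate)
    for lvl in LEVELS:
        lab = LEVEL_LABELS[lvl]
        if lvl in coupling.levels:
            lc = coupling[lvl]
            measures[f"vl_{lab}"] = lc.vl
            measures[f"ma_{lab}"] = lc.ma
            measures[f"maa_{lab}"] = lc.maa
    return measures


#: Measures that are condition-compared in the results report (tempo and
#: bookkeeping columns are reported but not tested).
COMPARED_MEASURES_PREFIXES = (
    "peak_r", "mean_lag_ms", "mean_abs_lag_ms", "lag_sd_ms",
    "head_interdistance_mm", "head_hull_cm3",
    "bow_interdistance_mm", "bow_hull_cm3",
    "head_power_", "bow_power_", "power_corr_", "vl_", "ma_", "maa_",
    "tempo_cv",
)


def analyze_dataset(
    records: list[TrialRecord] | list[dict], config: StudyConfig | None = None
) -> pd.DataFrame:
    """Tidy per-take measure table for a whole study."""
    config = config or StudyConfig()
    rows = []
    for rec in records:
        if isinstance(rec, TrialRecord):
            v, c, t, trial = rec.violinist, rec.condition, rec.take, rec.trial
        else:
            v, c, t, trial = (rec["violinist"], rec["condition"],
                              rec["take"], rec["trial"])
        for measure, value in analyze_trial(trial, config).items():
            rows.append(
                {"violinist": v, "condition": c, "take": t,
                 "measure": measure, "value": value}
            )
    return pd.DataFrame(rows)


def condition_comparison(measure_table: pd.DataFrame) -> pd.DataFrame:
    """Friedman condition comparison for every compared measure.

    Measures whose design is incomplete after dropping undefined values
    (e.g. a power correlation that was degenerate in some take) are
    skipped: the test requires every block x replicate x condition cell.
    """
    mask = measure_table["measure"].map(
        lambda m: any(m.startswith(p) for p in COMPARED_MEASURES_PREFIXES)
    )
    sub = measure_table[mask & measure_table["value"].notna()]
    frames = []
    for measure, mdf in sub.groupby("measure", sort=True):
        try:
            frames.append(compare_conditions(mdf))
        except ValueError:
            continue  # incomplete design for this measure: skip
    if not frames:
        raise ValueError("no measure had a complete design")
    return pd.concat(frames, ignore_index=True)


@dataclass
class RunManifest:
    config_hash: str
    code_version: str
    seed: int
    files: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def simulate_to_dir(config: StudyConfig, out_dir: str | Path) -> RunManifest:
    """Generate the synthetic study and write marker/beat/truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.hash(), __version__, config.seed)
    records = generate_dataset(config.design, config.seed)
    for rec in records:
        stem = f"v{rec.violinist}_{rec.condition}_take{rec.take}"
        markers = {m.name: m for m in rec.trial.head_markers}
        markers["bow"] = rec.trial.bow_marker
        mpath = out / f"{stem}_markers.tsv"
        bpath = out / f"{stem}_beats.csv"
        tpath = out / f"{stem}_truth.json"
        hbio.write_marker_table(mpath, markers)
        hbio.write_beat_csv(bpath, rec.trial.beat_grid, take_id=stem)
        hbio.write_truth_json(tpath, rec.trial.ground_truth)
        for p in (mpath, bpath, tpath):
            manifest.files[p.name] = hbio.file_sha256(p)
    hbio.dump_yaml(config.to_dict(), out / "config.yaml")
    manifest.files["config.yaml"] = hbio.file_sha256(out / "config.yaml")
    manifest.write(out / "manifest.json")
    return manifest


def load_trials_from_dir(in_dir: str | Path, config: StudyConfig) -> list[dict]:
    """Read simulated trials back from disk into analyzable records."""
    in_dir = Path(in_dir)
    records = []
    for bpath in sorted(in_dir.glob("*_beats.csv")):
        stem = bpath.name.replace("_beats.csv", "")
        take_id, grid = hbio.read_beat_csv(bpath)
        markers = hbio.read_marker_table(in_dir / f"{stem}_markers.tsv", config.rate)
        v, cond, take = stem.split("_")
        records.append(
            {
                "violinist": int(v[1:]),
                "condition": cond,
                "take": int(take.replace("take", "")),
                "trial": {
                    "head_markers": [markers["head1"], markers["head2"],
                                     markers["head3"]],
                    "bow_marker": markers["bow"],
                    "beat_grid": grid,
                    "passages": config.design.passages,
                },
            }
        )
    if not records:
        raise ValueError(f"no trials found in {in_dir}")
    return records


def run_pipeline(
    config: StudyConfig, out_dir: str | Path, records=None
) -> tuple[RunManifest, pd.DataFrame, pd.DataFrame]:
    """Full in-memory run: simulate, analyze, compare, write result tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.hash(), __version__, config.seed)
    if records is None:
        records = generate_dataset(config.design, config.seed)
    measures = analyze_dataset(records, config)
    results = condition_comparison(measures)
    mpath = out / "measures.csv"
    rpath = out / "condition_tests.csv"
    measures.to_csv(mpath, index=False)
    results.to_csv(rpath, index=False)
    stats_json = {
        "note": "Friedman condition comparisons; no multiple-comparison "
                "correction is applied.",
        "results": results.to_dict(orient="records"),
    }
    jpath = out / "condition_tests.json"
    jpath.write_text(json.dumps(stats_json, indent=1, sort_keys=True))
    for p in (mpath, rpath, jpath):
        manifest.files[p.name] = hbio.file_sha256(p)
    manifest.write(out / "manifest.json")
    return manifest, measures, results
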