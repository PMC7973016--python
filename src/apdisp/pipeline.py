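"""End-to-end orchestration: movie -> APD -> dispersion -> pattern report.

A :class:`RunConfig` gathers every stage's parameters; `run_pipeline`
executes simulate/load -> preprocess -> APD map -> dispersion map ->
binarize -> area fraction -> islands -> pattern classification ->
(optional) phase/SPD analysis, writing maps, island tables, a tidy
metrics CSV and a serialized copy of the configuration to the output
directory.  The run is deterministic given (inputs, seed) and the
configuration hash is recorded in every report.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sp_stats

from . import dispersion as disp
from . import patterns as pat
from . import phase as ph
from . import synthetic as syn
from .io import VoltageMovie, read_movie, write_map, write_metrics
from .signal import SignalConfig, compute_apd_map, preprocess

logger = logging.getLogger("apdisp")


@dataclass
class RunConfig:
    """Validated, serializable configuration for one pipeline run."""

    signal: SignalConfig = dc_field(default_factory=SignalConfig)
    window_px: int = 10
    threshold_ms: float = 10.0
    statistic: str = "std"
    alpha: float = 0.05
    quadrat_size_px: int = 20
    band_hz: tuple = (1.0, 40.0)
    run_phase: bool = False
    seed: int = 0
    outdir: str | None = None
    subject_label: str = "synthetic"
    chamber: str = "unknown"
    scenario: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_px < 2:
            raise ValueError("window_px must be >= 2")
        if self.threshold_ms < 0:
            raise ValueError("threshold_ms must be >= 0")
        if self.statistic not in disp.STATISTICS:
            raise ValueError(f"statistic must be one of {disp.STATISTICS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_hz"] = list(self.band_hz)
        return d

    def sha(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "signal" in d and isinstance(d["signal"], dict):
            d["signal"] = SignalConfig(**d["signal"])
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def movie_from_scenario(scenario: dict, seed: int) -> tuple[VoltageMovie, syn.GroundTruth | None]:
    """Build a movie from a simulation scenario dict (or load from disk).

    Scenario keys: ``kind`` (paced | spiral | file), then the generator
    parameters (``pattern``, ``grid``, ``baseline_apd_ms``, ``islands``,
    ``pacing``, ``wave``, ``noise`` for paced; ``rotation_freq_hz``,
    ``core``/``cores``, ``chirality`` for spiral; ``path``/``format`` for
    file).
    """
    kind = scenario.get("kind", "paced")
    if kind == "file":
        return read_movie(scenario["path"], format=scenario.get("format", "tiff_stack"),
                          mask=scenario.get("mask")), None
    if kind == "spiral":
        return syn.generate_spiral_movie(
            rotation_freq_hz=scenario.get("rotation_freq_hz", 10.0),
            core=tuple(scenario.get("core", (50, 50))),
            chirality=scenario.get("chirality", 1),
            cores=scenario.get("cores"), seed=seed)
    islands = scenario.get("islands")
    params = syn.IslandParams(**islands) if isinstance(islands, dict) else islands
    field = syn.generate_apd_field(
        pattern=scenario.get("pattern", "clustered"),
        grid=tuple(scenario.get("grid", (100, 100))),
        baseline_apd_ms=scenario.get("baseline_apd_ms", 50.0),
        island_params=params, seed=seed)
    return syn.synthesize_movie(
        field, pacing=tuple(scenario.get("pacing", (100.0, 4))),
        wave=tuple(scenario.get("wave", (0.0, 0.3))),
        noise=tuple(scenario.get("noise", (0.0, 0.0))), seed=seed)


def run_pipeline(config: RunConfig, movie: VoltageMovie | None = None) -> dict:
    """Run the full analysis; returns the report bundle as a dict.

    When ``movie`` is None the configured scenario is simulated with the
    configured seed.  If ``config.outdir`` is set, maps (CSV + PNG), the
    island table, the pattern report, a tidy metrics CSV and the
    serialized configuration are written there.
    """
    t0 = time.perf_counter()
    truth = None
    stage = "simulate/load"
    try:
        if movie is None:
            movie, truth = movie_from_scenario(config.scenario, config.seed)
        stage = "preprocess"
        pre = preprocess(movie, config.signal)
        stage = "apd_map"
        apd = compute_apd_map(pre, config.signal, preprocessed=True)
        stage = "dispersion"
        dmap = disp.dispersion_map(apd, config.window_px, config.statistic)
        stage = "binarize"
        bmap = disp.binarize(dmap, config.threshold_ms)
        stage = "area_fraction"
        frac = disp.area_fraction(bmap, movie.mask)
        stage = "islands"
        islands = disp.extract_islands(bmap, movie.meta.pixel_pitch_mm)
        stage = "patterns"
        report = pat.classify_pattern(
            islands.centroids(), region=movie.mask, dmap=dmap,
            alpha=config.alpha, quadrat_size_px=config.quadrat_size_px)
        phase_out = None
        if config.run_phase:
            stage = "phase"
            pm = ph.phase_movie(movie)
            sing = ph.detect_singularities(pm, spd_window_px=config.window_px)
            dfmap = ph.dominant_frequency_map(movie, config.band_hz)
            phase_out = {"n_singularities": sing.total_count(),
                         "singularities": sing,
                         "df_map": dfmap}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    bundle = {
        "config_sha": config.sha(),
        "subject_label": config.subject_label,
        "chamber": config.chamber,
        "apd_map": apd,
        "dispersion_map": dmap,
        "binary_map": bmap,
        "area_fraction_pct": frac,
        "islands": islands,
        "pattern": report,
        "phase": phase_out,
        "ground_truth": truth,
        "runtime_s": time.perf_counter() - t0,
    }

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump({"config": config.to_dict(), "config_sha": config.sha()},
                           fh, sort_keys=True)
        write_map(apd.values, out / "apd_map.csv", "csv", valid=apd.valid)
        write_map(apd.values, out / "apd_map.png", "png", valid=apd.valid)
        write_map(dmap.values, out / "dispersion_map.csv", "csv", valid=dmap.valid)
        write_map(dmap.values, out / "dispersion_map.png", "png", valid=dmap.valid)
        write_map(bmap.above, out / "binary_map.csv", "csv", valid=bmap.valid)
        write_map(bmap.above, out / "binary_map.png", "png", valid=bmap.valid)
        islands.to_frame().to_csv(out / "islands.csv", index=False,
                                  float_format="%.10g")
        with open(out / "pattern.yaml", "w") as fh:
            yaml.safe_dump({k: (v if isinstance(v, str) else float(v) if
                                isinstance(v, (int, float, np.floating)) else v)
                            for k, v in asdict(report).items()}, fh, sort_keys=True)
        metrics = metrics_records(bundle)
        write_metrics(metrics, out / "metrics.csv")
        logger.info("pipeline finished in %.2f s (config %s)",
                    bundle["runtime_s"], config.sha())
    return bundle


def metrics_records(bundle: dict) -> list[dict]:
    """Tidy metric rows for one pipeline run."""
    subj, chamber = bundle["subject_label"], bundle["chamber"]

    def rec(metric, value):
        return {"subject_label": subj, "chamber": chamber,
                "metric": metric, "value": float(value)}

    apd = bundle["apd_map"]
    rows = [
        rec("area_fraction_pct", bundle["area_fraction_pct"]),
        rec("n_islands", len(bundle["islands"])),
        rec("mean_apd_ms", np.nanmean(apd.values[apd.valid]) if apd.valid.any() else np.nan),
        rec("max_apd_ms", np.nanmax(apd.values[apd.valid]) if apd.valid.any() else np.nan),
        rec("mean_dispersion_ms",
            np.nanmean(bundle["dispersion_map"].values[bundle["dispersion_map"].valid])
            if bundle["dispersion_map"].valid.any() else np.nan),
        rec("morans_i", bundle["pattern"].morans_i),
        rec("clark_evans_r", bundle["pattern"].clark_evans_r),
        rec("vmr", bundle["pattern"].vmr),
    ]
    return rows


def cohort_summary(metric_files: list, group_labels: dict | list,
                   null_value: float = 0.0,
                   metric: str = "area_fraction_pct") -> pd.DataFrame:
    """Per-group mean +/- SEM with one-sample and between-group t-tests.

    ``metric_files`` are tidy CSVs from :func:`run_pipeline`;
    ``group_labels`` maps subject_label -> group (or is a parallel list
    of group names per file).  Each group is tested one-sample against
    ``null_value``; with exactly two groups a two-sample (Welch) contrast
    is appended as a ``contrast`` row.
    """
    frames = []
    for i, f in enumerate(metric_files):
        df = pd.read_csv(f)
        df = df[df["metric"] == metric]
        if isinstance(group_labels, dict):
            df = df.assign(group=df["subject_label"].map(group_labels))
        else:
            df = df.assign(group=group_labels[i])
        frames.append(df)
    alld = pd.concat(frames, ignore_index=True)
    if alld["group"].isna().any():
        raise ValueError("some subjects have no group label")
    chambers = alld.get("chamber")
    if chambers is not None and alld["chamber"].nunique() > 1:
        raise ValueError("mixed chambers: group explicitly before summarizing")

    out = []
    for g, sub in alld.groupby("group", sort=True):
        vals = sub["value"].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(f"group '{g}' needs >= 2 subjects")
        gs = disp.group_stats(vals, null_value=null_value)
        out.append({"group": g, "metric": metric, **gs, "null_value": null_value})
    table = pd.DataFrame(out)
    groups = list(table["group"])
    if len(groups) == 2:
        a = alld.loc[alld["group"] == groups[0], "value"].to_numpy(dtype=float)
        b = alld.loc[alld["group"] == groups[1], "value"].to_numpy(dtype=float)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t2, p2 = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            res = sp_stats.ttest_ind(a, b, equal_var=False)
            t2, p2 = float(res.statistic), float(res.pvalue)
        table = pd.concat([table, pd.DataFrame([{
            "group": f"contrast:{groups[0]}-vs-{groups[1]}", "metric": metric,
            "n": len(a) + len(b), "mean": a.mean() - b.mean(), "sem": np.nan,
            "t": t2, "df": len(a) + len(b) - 2, "p": p2,
            "significant": bool(p2 < 0.05), "null_value": np.nan}])],
            ignore_index=True)
    return table
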