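"""End-to-end study orchestration: recordings -> rhythm metrics -> inference.

:func:`run_study` sequences the whole chain under one config and master
seed: generate (or load) activity recordings, compute per-series tempo
traits with the fixed rescale -> smooth -> wavelet order (colony series
truncated to the individual-series length first, so the two levels are
compared on records of equal length), derive species tip values, and run
the comparative analyses — bootstrap rate comparison, PGLS with a
sensitivity variant, and phenospace disparity. Everything is reproducible
from (config, seed); the config hash and seed are stamped into the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparative as cmp
from .phylo import Chronogram
from .rhythm import series_metrics
from .series import ActivityTimeSeries, read_series_csv
from .synth import SyntheticStudyConfig, simulate_study_dataset

__all__ = [
    "PipelineConfig",
    "StudyReport",
    "ValidationCheck",
    "run_study",
    "validate_inputs",
    "compute_metric_tables",
]

log = logging.getLogger("tempoevo.pipeline")

TRAITS = ("rhythmicity_beta", "dominant_period_min")


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and settings for one full study run.

    ``mode`` selects the input source: ``"synthetic"`` generates a study
    from ``study``; ``"csv"`` reads a long-format series CSV plus a Newick
    chronogram. Rhythm settings feed :func:`tempoevo.rhythm.series_metrics`;
    ``n_boot``/``sensitivity_iter`` size the comparative resampling.
    """

    mode: str = "synthetic"
    study: SyntheticStudyConfig = field(default_factory=SyntheticStudyConfig)
    series_csv: str | None = None
    tree_path: str | None = None
    smooth_window: int = 15
    wavelet_family: str = "morlet"
    voices_per_octave: int = 12
    truncate_colony_to_individual: bool = True
    n_boot: int = 10_000
    sensitivity_iter: int = 10_000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if self.mode == "csv" and (self.series_csv is None or self.tree_path is None):
            raise ValueError("csv mode requires series_csv and tree_path")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class ValidationCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class StudyReport:
    """All study-level outputs plus the metadata to reproduce them."""

    metrics: pd.DataFrame
    tip_values: pd.DataFrame
    rate_comparisons: dict[str, cmp.RateComparisonResult]
    pgls_fits: dict[str, cmp.PGLSFit]
    sensitivity_fits: dict[str, cmp.SensitivityPGLSResult]
    disparity: cmp.DisparityResult
    metadata: dict

    def to_json_dict(self) -> dict:
        rates = {
            trait: {
                "observed_colony": r.observed_colony,
                "observed_individual": r.observed_individual,
                "observed_difference": r.observed_difference,
                "p_value": r.p_value,
                "n_boot": r.n_boot,
                "colony": cmp.summarize_draws(r.sigma2_colony_draws),
                "individual": cmp.summarize_draws(r.sigma2_individual_draws),
            }
            for trait, r in self.rate_comparisons.items()
        }
        pgls = {
            trait: {"slope": f.slope, "intercept": f.intercept,
                    "t_statistic": f.t_statistic, "p_value": f.p_value, "df": f.df}
            for trait, f in self.pgls_fits.items()
        }
        sens = {
            trait: {"median_p": s.median_p, "median_slope": s.median_slope,
                    "n_iter": s.n_iter}
            for trait, s in self.sensitivity_fits.items()
        }
        d = self.disparity
        return {
            "metadata": self.metadata,
            "tip_values": self.tip_values.reset_index().to_dict(orient="records"),
            "rate_comparisons": rates,
            "pgls": pgls,
            "sensitivity_pgls": sens,
            "disparity": {
                "sum_of_variances_colony": d.sum_of_variances_colony,
                "sum_of_variances_individual": d.sum_of_variances_individual,
                "p_value": d.p_value,
                "n_boot": d.n_boot,
                "colony": cmp.summarize_draws(d.colony_draws),
                "individual": cmp.summarize_draws(d.individual_draws),
            },
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=2, sort_keys=True) + "\n"
        )
        self.tip_values.to_csv(out / "tip_values.csv")
        self.metrics.to_csv(out / "metrics.csv", index=False)


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % 2**31) for s in state]


def compute_metric_tables(
    series: list[ActivityTimeSeries],
    smooth_window: int = 15,
    wavelet_family: str = "morlet",
    voices_per_octave: int = 12,
    truncate_colony_to: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-recording rhythm metrics, split into colony and individual tables."""
    rows = []
    for ts in series:
        target = truncate_colony_to if ts.level == "colony" else None
        m = series_metrics(
            ts, smooth_window=smooth_window, family=wavelet_family,
            voices_per_octave=voices_per_octave, truncate_to=target,
        )
        rows.append(
            {"series_id": ts.series_id, "species": ts.species,
             "colony_id": ts.colony_id, "individual_id": ts.individual_id,
             "level": ts.level, "rhythmicity_beta": m.rhythmicity_beta,
             "dominant_period_min": m.dominant_period_min}
        )
    df = pd.DataFrame(rows)
    colony = df[df["level"] == "colony"].drop(columns=["individual_id"]).reset_index(drop=True)
    indiv = df[df["level"] == "individual"].reset_index(drop=True)
    return colony, indiv


def _load_inputs(config: PipelineConfig) -> tuple[list[ActivityTimeSeries], Chronogram]:
    if config.mode == "synthetic":
        seed = _child_seeds(config.seed, 1)[0]
        study = dataclasses.replace(config.study, seed=seed)
        ds = simulate_study_dataset(study)
        return ds.series, ds.tree
    series = read_series_csv(config.series_csv)
    tree = Chronogram.from_newick(Path(config.tree_path))
    return series, tree


def run_study(config: PipelineConfig) -> StudyReport:
    """Execute the full study and return (optionally write) the report."""
    seeds = _child_seeds(config.seed, 8)
    series, tree = _load_inputs(config)
    log.info("loaded %d series, %d-tip chronogram", len(series), tree.n_tips)

    indiv_lens = [len(ts) for ts in series if ts.level == "individual"]
    truncate_to = min(indiv_lens) if (config.truncate_colony_to_individual and indiv_lens) else None
    colony_tab, indiv_tab = compute_metric_tables(
        series, smooth_window=config.smooth_window,
        wavelet_family=config.wavelet_family,
        voices_per_octave=config.voices_per_octave,
        truncate_colony_to=truncate_to,
    )
    metrics = pd.concat([colony_tab.assign(individual_id=None), indiv_tab],
                        ignore_index=True)
    log.info("computed metrics for %d colony and %d individual recordings",
             len(colony_tab), len(indiv_tab))

    missing = sorted(set(metrics["species"].astype(str)) - set(tree.taxa))
    if missing:
        raise ValueError(f"species missing from chronogram: {missing}")

    tips_c = cmp.species_tip_values(colony_tab, traits=list(TRAITS))
    tips_i = cmp.species_tip_values(indiv_tab, traits=list(TRAITS))
    tip_values = pd.DataFrame(
        {
            "colony_rhythmicity": tips_c["rhythmicity_beta"],
            "individual_rhythmicity": tips_i["rhythmicity_beta"],
            "colony_period_min": tips_c["dominant_period_min"],
            "individual_period_min": tips_i["dominant_period_min"],
        }
    )

    rate_comparisons = {
        trait: cmp.bootstrap_rate_comparison(
            colony_tab, indiv_tab, tree, trait,
            n_boot=config.n_boot, seed=seeds[1 + k],
        )
        for k, trait in enumerate(TRAITS)
    }

    pgls_fits = {}
    sensitivity_fits = {}
    for k, trait in enumerate(TRAITS):
        x = tips_i[trait].dropna().to_dict()
        y = tips_c[trait].dropna().to_dict()
        pgls_fits[trait] = cmp.pgls(tree, x, y)
        sd_i = indiv_tab.groupby("species")[trait].std(ddof=1).fillna(0.0).to_dict()
        sd_c = colony_tab.groupby("species")[trait].std(ddof=1).fillna(0.0).to_dict()
        sensitivity_fits[trait] = cmp.sensitivity_pgls(
            tree, x, y, sd_i, sd_c,
            n_iter=config.sensitivity_iter, seed=seeds[3 + k],
        )

    disparity = cmp.disparity_comparison(
        tip_values[["colony_rhythmicity", "colony_period_min"]],
        tip_values[["individual_rhythmicity", "individual_period_min"]],
        n_boot=config.n_boot, seed=seeds[5],
    )

    metadata = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "mode": config.mode,
        "n_series": len(series),
        "n_species": int(metrics["species"].nunique()),
        "truncated_colony_len": truncate_to,
        "n_boot": config.n_boot,
    }
    report = StudyReport(
        metrics=metrics, tip_values=tip_values,
        rate_comparisons=rate_comparisons, pgls_fits=pgls_fits,
        sensitivity_fits=sensitivity_fits, disparity=disparity,
        metadata=metadata,
    )
    if config.out_dir is not None:
        report.write(config.out_dir)
        log.info("report written to %s", config.out_dir)
    return report


def validate_inputs(config: PipelineConfig) -> list[ValidationCheck]:
    """Structured pre-flight checks; reports failures rather than raising."""
    checks: list[ValidationCheck] = []

    def add(name: str, passed: bool, detail: str = "") -> None:
        checks.append(ValidationCheck(name=name, passed=passed, detail=detail))

    add("n_boot_at_least_100", config.n_boot >= 100, f"n_boot={config.n_boot}")
    if config.mode == "synthetic":
        add("synthetic_config_valid", True,
            f"{config.study.n_species} species")
        return checks

    csv_path = Path(config.series_csv)
    tree_path = Path(config.tree_path)
    add("series_csv_exists", csv_path.exists(), str(csv_path))
    add("tree_exists", tree_path.exists(), str(tree_path))
    if not (csv_path.exists() and tree_path.exists()):
        return checks
    try:
        df = pd.read_csv(csv_path)
        required = {"series_id", "species", "colony_id", "level",
                    "frame_index", "time_s", "activity"}
        missing_cols = sorted(required - set(df.columns))
        add("csv_schema", not missing_cols,
            f"missing columns: {missing_cols}" if missing_cols else "all columns present")
        if missing_cols:
            return checks
    except Exception as exc:  # malformed file
        add("csv_schema", False, str(exc))
        return checks

    gaps = []
    for sid, g in df.groupby("series_id"):
        fi = g.sort_values("frame_index")["frame_index"].to_numpy()
        if not np.array_equal(fi, np.arange(fi[0], fi[0] + len(fi))):
            gaps.append(str(sid))
    add("frame_index_contiguous", not gaps, f"series with gaps: {gaps[:5]}")

    try:
        tree = Chronogram.from_newick(tree_path)
        add("tree_ultrametric", True, f"{tree.n_tips} tips")
        extra = sorted(set(df["species"].astype(str)) - set(tree.taxa))
        add("species_in_tree", not extra, f"missing from tree: {extra}")
    except Exception as exc:
        add("tree_ultrametric", False, str(exc))

    lens = df.groupby("series_id").size()
    levels = df.groupby("series_id")["level"].first()
    indiv_lens = lens[levels == "individual"]
    colony_lens = lens[levels == "colony"]
    if config.truncate_colony_to_individual and len(indiv_lens) and len(colony_lens):
        ok = colony_lens.min() >= indiv_lens.min()
        add("colony_series_cover_truncation", bool(ok),
            f"min colony len {colony_lens.min()}, target {indiv_lens.min()}")
    return checks
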