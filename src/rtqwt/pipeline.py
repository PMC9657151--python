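"""End-to-end workflow: preprocess -> tune -> decompose -> features ->
channel selection -> screening -> per-subband LS-SVM evaluation.

The pipeline is deliberately explicit about randomness: one integer
seed in the configuration drives the synthetic generator, the tuner
and the cross-validation shuffles, so two runs with the same
configuration produce identical reports.  A JSON manifest (config,
seeds, stage timings, warnings such as clamped tuning starts or
imputed features) is written next to the intermediate CSV artifacts
when an output directory is configured.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from .channel_selection import kw_screen, laplacian_scores, select_channel
from .exceptions import InvalidInputError, InvalidParameterError
from .features import FEATURE_NAMES, FeatureTable, build_feature_table
from .lssvm import CVResult, KernelSpec, cross_validate
from .preprocessing import EpochedDataset, bandpass
from .tqwt import TQWTParams, lmax
from .tuning import OptimizerConfig, SearchSpace, lopt, robust_tqwt_tune

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    # input
    input_path: str | None = None  # npz epoch container; None -> dataset passed in
    # preprocessing
    apply_bandpass: bool = True
    band_low: float = 7.0
    band_high: float = 30.0
    filter_order: int = 6
    # tuning
    optimizer: Literal["pso", "abc", "cs"] = "cs"
    tuning_granularity: Literal["per_epoch", "global"] = "global"
    n_agents: int = 10
    n_iters: int = 10
    q_bounds: tuple[float, float] = (1.0, 10.0)
    r_bounds: tuple[float, float] = (3.0, 10.0)
    levels_override: int | None = None  # skip tuning entirely if set
    # channel selection
    selection_direction: Literal["highest", "lowest"] = "lowest"
    # classification
    kernel: str = "rbf"
    kernel_degree: int = 3
    kernel_sigma: float = 1.0
    kernel_scale: float = 1.0
    kernel_omega0: float = 5.0
    gamma: float = 10.0
    cv_folds: int = 10
    # bookkeeping
    seed: int = 0
    output_dir: str | None = None

    def kernel_spec(self) -> KernelSpec:
        return KernelSpec(
            kind=self.kernel,
            degree=self.kernel_degree,
            sigma=self.kernel_sigma,
            scale=self.kernel_scale,
            omega0=self.kernel_omega0,
        )

    def search_space(self) -> SearchSpace:
        return SearchSpace(q_bounds=tuple(self.q_bounds), r_bounds=tuple(self.r_bounds))

    def optimizer_config(self) -> OptimizerConfig:
        return OptimizerConfig(n_agents=self.n_agents, n_iters=self.n_iters, seed=self.seed)

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["q_bounds"] = list(d["q_bounds"])
        d["r_bounds"] = list(d["r_bounds"])
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("q_bounds", "r_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunReport:
    config: RunConfig
    tuned_q: float
    tuned_r: float
    levels: int
    selected_channel: int
    channel_scores: np.ndarray
    kw_pvalues: dict[int, dict[str, float]]  # subband -> feature -> p
    subband_results: dict[int, CVResult]  # subband (1-based) -> CV result
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def best_subband(self) -> int:
        return max(self.subband_results, key=lambda s: self.subband_results[s].panel["ACC"])

    def summary(self) -> dict:
        return {
            "tuned_q": self.tuned_q,
            "tuned_r": self.tuned_r,
            "levels": self.levels,
            "selected_channel": self.selected_channel,
            "best_subband": self.best_subband,
            "panels": {
                sb: {**{k: round(v, 4) for k, v in res.panel.items()}, "AUC": round(res.auc, 4)}
                for sb, res in self.subband_results.items()
            },
        }


def run_pipeline(config: RunConfig, dataset: EpochedDataset | None = None) -> RunReport:
    """Execute the full workflow on an epoched dataset.

    The dataset is either passed directly (e.g. freshly generated
    synthetic epochs) or loaded from ``config.input_path``.
    """
    timings: dict[str, float] = {}
    warnings_log: list[str] = []

    def stage(name: str):
        return _StageTimer(name, timings)

    if dataset is None:
        if config.input_path is None:
            raise InvalidInputError("provide a dataset or set input_path in the config")
        dataset = EpochedDataset.load(config.input_path)

    with stage("preprocess"):
        if config.apply_bandpass:
            filtered = bandpass(
                dataset.epochs, dataset.fs, config.band_low, config.band_high, config.filter_order
            )
            dataset = EpochedDataset(
                epochs=filtered,
                labels=dataset.labels,
                fs=dataset.fs,
                channel_names=list(dataset.channel_names),
            )

    with stage("tune"):
        space = config.search_space()
        opt_cfg = config.optimizer_config()
        m = dataset.epoch_length
        if config.levels_override is not None:
            q_best, r_best = space.q_bounds[0], space.r_bounds[0]
            levels = config.levels_override
            warnings_log.append(f"tuning skipped: levels overridden to {levels}")
        elif config.tuning_granularity == "global":
            result = robust_tqwt_tune(
                dataset.epochs[0, 0], optimizer=config.optimizer, space=space, config=opt_cfg
            )
            q_best, r_best = result.best_params
            levels = lopt(
                [[result.lmax_at_best] for _ in dataset.classes]
            )
        else:  # per_epoch: tune each epoch on the channel-averaged signal
            lmax_by_class: dict[str, list[int]] = {str(c): [] for c in dataset.classes}
            q_list, r_list = [], []
            for e in range(dataset.n_epochs):
                sig = dataset.epochs[e].mean(axis=0)
                res = robust_tqwt_tune(
                    sig, optimizer=config.optimizer, space=space, config=opt_cfg
                )
                q_list.append(res.best_params[0])
                r_list.append(res.best_params[1])
                lmax_by_class[str(dataset.labels[e])].append(res.lmax_at_best)
            q_best, r_best = float(np.median(q_list)), float(np.median(r_list))
            levels = lopt(lmax_by_class.values())
        levels = min(levels, lmax(m, q_best, r_best))
        params = TQWTParams(q=q_best, r=r_best, levels=levels)

    with stage("features"):
        table = build_feature_table(dataset, params, levels)
        if table.n_imputed:
            warnings_log.append(f"{table.n_imputed} feature entries imputed")

    with stage("select_channel"):
        per_channel = [table.channel_matrix(c) for c in range(dataset.n_channels)]
        score_table = laplacian_scores(
            per_channel, feature_names=FEATURE_NAMES, channel_names=dataset.channel_names
        )
        channel = select_channel(score_table, direction=config.selection_direction)

    with stage("kw_screen"):
        kw: dict[int, dict[str, float]] = {}
        for sb in range(table.n_subbands):
            df = kw_screen(table.values[:, channel, sb, :], table.labels, FEATURE_NAMES)
            kw[sb + 1] = dict(zip(df["feature"], df["p"]))

    with stage("classify"):
        results: dict[int, CVResult] = {}
        for sb in range(table.n_subbands):
            results[sb + 1] = cross_validate(
                table.values[:, channel, sb, :],
                table.labels,
                spec=config.kernel_spec(),
                gamma=config.gamma,
                k=config.cv_folds,
                seed=config.seed,
            )

    report = RunReport(
        config=config,
        tuned_q=float(q_best),
        tuned_r=float(r_best),
        levels=int(levels),
        selected_channel=int(channel),
        channel_scores=score_table.scores,
        kw_pvalues=kw,
        subband_results=results,
        stage_seconds=timings,
        warnings=warnings_log,
    )
    if config.output_dir:
        _write_artifacts(report, score_table, table, Path(config.output_dir))
    return report


class _StageTimer:
    def __init__(self, name: str, sink: dict[str, float]):
        self.name, self.sink = name, sink

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.sink[self.name] = round(time.perf_counter() - self.t0, 3)
        return False


def _write_artifacts(report: RunReport, score_table, table: FeatureTable, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    score_table.to_frame().to_csv(outdir / "laplacian_scores.csv")
    table.to_csv(outdir / "features.csv")
    manifest = {
        "config": {**asdict(report.config)},
        "seed": report.config.seed,
        "stage_seconds": report.stage_seconds,
        "warnings": report.warnings,
        "summary": report.summary(),
        "kw_pvalues": {str(k): v for k, v in report.kw_pvalues.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
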