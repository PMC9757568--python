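"""End-to-end orchestration: simulate -> window -> levels A/B/C -> classify ->
attribute -> report, from a single config, with reproducible provenance.

A single master seed spawns named sub-seeds (cohort, split, cv, detection,
attribution, curve) so each stage is independently reproducible; regenerating
from the same config reproduces every number in the report exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .classify import (SplitPlan, default_grid, evaluate, grid_search_fit,
                       learning_curve, split_data)
from .connectivity import assemble_level_b, connectivity_matrices
from .data import FeatureTable, Recording, WindowSpec, assemble_level_a, split_windows
from .graphs import GraphConfig, assemble_level_c, window_measure_summary
from .io import read_cohort, write_cohort, write_feature_table
from .montage import MONTAGE_62
from .shapley import rank_features, shapley_attributions
from .simulate import CohortSpec, EffectSpec, generate_cohort

_SEED_STREAMS = ("cohort", "split", "cv", "detection", "attribution", "curve", "extra")


@dataclass
class AttributionConfig:
    n_permutations: int = 10
    background_size: int = 50
    rows: str = "test"  # "test", "train" or "all"
    max_rows: int = 100  # cap on explained rows (subsampled, seeded)

    def __post_init__(self) -> None:
        if self.rows not in ("test", "train", "all"):
            raise ValueError("attribution rows must be 'test', 'train' or 'all'")


@dataclass
class RunConfig:
    """Schema-validated description of one pipeline run."""

    seed: int = 0
    output_dir: str = "run"
    levels: tuple[str, ...] = ("A", "B", "C")
    cohort: CohortSpec = field(default_factory=CohortSpec)
    data_manifest: str | None = None  # load instead of simulating, if given
    windows: list[WindowSpec] | None = None  # default: the cohort's windows
    graph: GraphConfig = field(default_factory=GraphConfig)
    split: SplitPlan = field(default_factory=SplitPlan)
    hyper_grid: list[dict[str, list[Any]]] = field(default_factory=default_grid)
    attribution: AttributionConfig = field(default_factory=AttributionConfig)
    level_a_decimate: int = 100
    level_b_epochs: int = 1
    write_intermediates: bool = True

    def __post_init__(self) -> None:
        bad = [lv for lv in self.levels if lv not in ("A", "B", "C")]
        if bad:
            raise ValueError(f"unknown levels {bad}; choose from A, B, C")
        if not self.levels:
            raise ValueError("select at least one level")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            c = dict(raw["cohort"])
            if "effect" in c and isinstance(c["effect"], dict):
                e = dict(c["effect"])
                if "amplitude_targets" in e:
                    e["amplitude_targets"] = [tuple(t) for t in e["amplitude_targets"]]
                if "coupling_targets" in e:
                    e["coupling_targets"] = [(tuple(pair), d_) for pair, d_ in e["coupling_targets"]]
                if e.get("community_effect") is not None:
                    e["community_effect"] = tuple(tuple(b) for b in e["community_effect"])
                c["effect"] = EffectSpec(**e)
            if "windows" in c:
                c["windows"] = [WindowSpec(**w) if isinstance(w, dict) else w
                                for w in c["windows"]]
            if "montage" in c:
                c["montage"] = tuple(c["montage"])
            raw["cohort"] = CohortSpec(**c)
        if raw.get("windows"):
            raw["windows"] = [WindowSpec(**w) if isinstance(w, dict) else w
                              for w in raw["windows"]]
        if "graph" in raw and isinstance(raw["graph"], dict):
            raw["graph"] = GraphConfig(**raw["graph"])
        if "split" in raw and isinstance(raw["split"], dict):
            raw["split"] = SplitPlan(**raw["split"])
        if "attribution" in raw and isinstance(raw["attribution"], dict):
            raw["attribution"] = AttributionConfig(**raw["attribution"])
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sub_seeds(master: int) -> dict[str, int]:
    rng = np.random.default_rng(master)
    return {name: int(rng.integers(2**31)) for name in _SEED_STREAMS}


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable results of one run; serializable deterministically."""

    payload: dict[str, Any]

    def to_json(self) -> str:
        return json.dumps(self.payload, sort_keys=True, indent=1)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _attribution_rows(train: FeatureTable, test: FeatureTable,
                      cfg: AttributionConfig, seed: int) -> FeatureTable:
    table = {"test": test, "train": train}.get(cfg.rows)
    if table is None:  # "all"
        mask = np.ones(train.n_rows + test.n_rows, dtype=bool)
        table = FeatureTable(
            level=train.level,
            feature_names=list(train.feature_names),
            X=np.vstack([train.X, test.X]),
            y=np.concatenate([train.y, test.y]),
            groups=np.concatenate([train.groups, test.groups]),
        )
    if table.n_rows > cfg.max_rows:
        rng = np.random.default_rng(seed)
        idx = rng.choice(table.n_rows, size=cfg.max_rows, replace=False)
        table = table.subset(np.isin(np.arange(table.n_rows), idx))
    return table


def _run_level(level: str, table: FeatureTable, config: RunConfig,
               seeds: dict[str, int], out_dir: Path | None) -> dict[str, Any]:
    plan = SplitPlan(**{**asdict(config.split), "seed": seeds["split"]})
    train, test = split_data(table, plan)
    model = grid_search_fit(train, config.hyper_grid, k=plan.cv_folds, seed=seeds["cv"])
    report: dict[str, Any] = {
        "level": level,
        "n_rows": int(table.n_rows),
        "n_features": len(table.feature_names),
        "selected_params": model.best_params,
        "cv_best_mean_accuracy": model.cv_best_mean_accuracy,
        "train": evaluate(model, train, "train"),
        "test": evaluate(model, test, "test"),
        "learning_curve": learning_curve(
            train, test, model_params=model.best_params, seed=seeds["curve"]),
    }
    bg_rng = np.random.default_rng(seeds["attribution"])
    n_bg = min(config.attribution.background_size, train.n_rows)
    background = train.X[bg_rng.choice(train.n_rows, size=n_bg, replace=False)]
    rows = _attribution_rows(train, test, config.attribution, seeds["attribution"])
    result = shapley_attributions(
        model, rows, background,
        n_permutations=config.attribution.n_permutations,
        seed=seeds["attribution"],
    )
    ranking = rank_features(result)
    report["attribution"] = {
        "base_value": result.base_value,
        "efficiency_gap": result.efficiency_gap,
        "n_rows_explained": int(rows.n_rows),
        "n_permutations": config.attribution.n_permutations,
        "ranking": ranking.to_dict(orient="records"),
    }
    if out_dir is not None:
        write_feature_table(table, out_dir / f"level_{level}_features.csv")
        ranking.to_csv(out_dir / f"level_{level}_attribution.csv", index=False)
    return report


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the selected levels end to end and write the run report.

    Any stage error aborts with the stage name; partial outputs already
    written are retained alongside a failure marker.
    """
    seeds = _sub_seeds(config.seed)
    out_dir = Path(config.output_dir) if config.write_intermediates else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if config.data_manifest is not None:
            recordings = read_cohort(config.data_manifest)
            windows = config.windows
            if windows is None:
                raise ValueError("windows must be given when loading external data")
        else:
            cohort_spec = CohortSpec(**{**asdict_cohort(config.cohort),
                                        "seed": seeds["cohort"]})
            recordings = generate_cohort(cohort_spec)
            windows = config.windows or cohort_spec.windows
            if out_dir is not None:
                write_cohort(recordings, out_dir / "cohort")

        stage = "window"
        segments = [seg for rec in recordings for seg in split_windows(rec, windows)]

        levels: dict[str, Any] = {}
        matrices = None
        if "B" in config.levels or "C" in config.levels:
            stage = "connectivity"
            matrices = connectivity_matrices(segments, config.level_b_epochs)

        if "A" in config.levels:
            stage = "level A"
            table_a = assemble_level_a(segments, decimate=config.level_a_decimate)
            levels["A"] = _run_level("A", table_a, config, seeds, out_dir)
        if "B" in config.levels:
            stage = "level B"
            levels["B"] = _run_level("B", assemble_level_b(matrices), config, seeds, out_dir)
        if "C" in config.levels:
            stage = "level C"
            table_c = assemble_level_c(matrices, config.graph, seed=seeds["detection"])
            levels["C"] = _run_level("C", table_c, config, seeds, out_dir)
            levels["C"]["window_summary"] = window_measure_summary(
                table_c).to_dict(orient="records")
    except Exception as exc:
        if out_dir is not None:
            (out_dir / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = RunReport(payload={
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "config_hash": _config_hash(config),
        "seeds": seeds,
        "version": __version__,
        "levels": levels,
        "comparison": compare_levels_payload(levels),
    })
    if out_dir is not None:
        report.write(out_dir / "report.json")
    return report


def asdict_cohort(cohort: CohortSpec) -> dict[str, Any]:
    d = asdict(cohort)
    d["montage"] = tuple(d["montage"])
    d["windows"] = [WindowSpec(**w) for w in d["windows"]]
    e = d["effect"]
    e["amplitude_targets"] = [tuple(t) for t in e["amplitude_targets"]]
    e["coupling_targets"] = [(tuple(p), dl) for p, dl in e["coupling_targets"]]
    if e["community_effect"] is not None:
        e["community_effect"] = tuple(tuple(b) for b in e["community_effect"])
    d["effect"] = EffectSpec(**e)
    return d


def compare_levels_payload(levels: dict[str, Any]) -> list[dict[str, Any]]:
    """Levels ordered by test accuracy (ties: test macro-AUC, then level name)."""
    rows = []
    for name, rep in levels.items():
        rows.append({
            "level": name,
            "test_accuracy": rep["test"]["accuracy"],
            "test_auc_macro": rep["test"]["roc"]["macro"]["auc"],
            "test_f1": rep["test"]["f1"],
            "test_recall": rep["test"]["recall"],
            "test_precision": rep["test"]["precision"],
            "train_accuracy": rep["train"]["accuracy"],
            "train_auc_macro": rep["train"]["roc"]["macro"]["auc"],
        })
    rows.sort(key=lambda r: (-r["test_accuracy"], -r["test_auc_macro"], r["level"]))
    return rows


def demo_config(seed: int = 0, output_dir: str = "demo_run") -> RunConfig:
    """Desk-scale demonstration run: a 24-channel, 8-subject cohort with one
    planted amplitude effect (T8, gain 2) and one planted coupling effect
    (F3-P8, +0.4), all three levels, thresholded graphs for speed."""
    return RunConfig(
        seed=seed,
        output_dir=output_dir,
        levels=("A", "B", "C"),
        cohort=CohortSpec(
            n_subjects=8,
            montage=MONTAGE_62[:24],
            n_latent_sources=4,
            effect=EffectSpec(
                amplitude_targets=[("T8", 2.0)],
                coupling_targets=[(("F3", "P8"), 0.4)],
            ),
        ),
        graph=GraphConfig(threshold=0.2),
        level_a_decimate=150,
        level_b_epochs=2,
        attribution=AttributionConfig(n_permutations=10, background_size=50,
                                      max_rows=40),
    )


def compare_levels(report: RunReport):
    """Table-2-shaped summary (rows = levels, metric columns) as a DataFrame."""
    import pandas as pd

    if len(report.payload["levels"]) < 2:
        raise ValueError("need at least two levels to compare")
    return pd.DataFrame(compare_levels_payload(report.payload["levels"]))
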