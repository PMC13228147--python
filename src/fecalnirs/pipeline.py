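"""End-to-end study workflow: simulate/load -> preprocess -> split -> screen
-> tune -> evaluate -> compare -> power, driven by one serializable config.

Every stage logs one accounting line (row counts in/out, exclusions) and
registers its output files in a :class:`RunManifest`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import ReferenceSet, SpectraSet
from .evaluation import (
    REFERENCE_METHOD_SE,
    compact_letter_display,
    compare_models,
    evaluate,
    minimum_detectable_difference,
    power_table,
)
from .local import METHODS, TuningGrid, cross_validate, predictor_for
from .preprocess import PreprocessConfig, preprocess
from .sampling import kennard_stone, pca_scores, screen_outliers
from .simulate import SyntheticConfig, generate_dataset

__all__ = ["ExperimentConfig", "RunManifest", "run_experiment", "describe_dataset"]

log = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Everything one run needs; round-trips losslessly through YAML."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    spectra_csv: str | None = None  # if set, load data instead of simulating
    reference_csv: str | None = None
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_validation: int = 76
    test_holdout: str = "trial"  # "trial" (second trial of each cluster) or "cluster"
    outlier_threshold: float = 3.0
    grid_profile: str = "reduced"  # "reduced" or "full"
    grid_nlv_max: int = 15
    methods: tuple[str, ...] = METHODS
    n_folds: int = 5
    alpha: float = 0.05
    reference_se: float = REFERENCE_METHOD_SE
    effect_size_d: float = 0.024
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("synthetic", "preprocessing"):
            d[key] = {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in d[key].items()
            }
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        for k in ("band_center_range_nm", "band_width_range_nm", "trial_fractions"):
            if k in syn and isinstance(syn[k], list):
                syn[k] = tuple(syn[k])
        pre = d.pop("preprocessing", {})
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(synthetic=SyntheticConfig(**syn), preprocessing=PreprocessConfig(**pre), **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def grid(self) -> TuningGrid:
        if self.grid_profile == "full":
            return TuningGrid.full()
        if self.grid_profile == "reduced":
            return TuningGrid.reduced(self.grid_nlv_max)
        if self.grid_profile == "tiny":
            return TuningGrid.tiny(self.grid_nlv_max)
        raise ValueError(f"unknown grid profile {self.grid_profile!r}")


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict
    version: str
    seed: int
    stage_counts: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def register(self, name: str, path: Path) -> None:
        if not path.exists() or path.stat().st_size == 0:
            raise RuntimeError(f"stage output {name} missing or empty: {path}")
        self.files[name] = str(path)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def describe_dataset(spectra: SpectraSet, reference: ReferenceSet):
    """Per-subset OMD descriptives plus PC1/PC2 scores for plotting.

    Returns ``(stats_df, scores_df, explained_variance_ratio)``.
    """
    rows = []
    subsets = ["calibration", "validation", "test", "unassigned", "all"]
    for name in subsets:
        mask = (
            np.ones(len(reference.omd), dtype=bool)
            if name == "all"
            else reference.subset == name
        )
        vals = reference.omd[mask]
        if len(vals) == 0:
            if name != "all":
                log.warning("subset %r is empty; omitted from the summary", name)
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                "subset": name,
                "N": int(len(vals)),
                "Mean": mean,
                "Median": float(np.median(vals)),
                "Min": float(np.min(vals)),
                "Max": float(np.max(vals)),
                "SD": sd,
                "CV%": 100.0 * sd / mean if mean != 0 else float("nan"),
            }
        )
    stats_df = pd.DataFrame(rows)
    scores, evr = pca_scores(spectra.absorbance, variance_target=0.99)
    ncomp = min(2, scores.shape[1])
    scores_df = pd.DataFrame(
        {
            "sample_id": spectra.sample_ids,
            **{f"PC{i + 1}": scores[:, i] for i in range(ncomp)},
            "subset": reference.subset,
        }
    )
    return stats_df, scores_df, evr


def plot_scores(scores_df: pd.DataFrame, evr, path) -> None:
    """Cosmetic PC1/PC2 score plot colored by subset."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for name, grp in scores_df.groupby("subset"):
        ax.scatter(grp["PC1"], grp["PC2"], s=12, label=name, alpha=0.7)
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.0f}%)")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.0f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _assign_subsets(reference: ReferenceSet, spectra_pp: SpectraSet,
                    config: ExperimentConfig, rng: np.random.Generator) -> np.ndarray:
    """Test subset by held-out trial (or cluster) label, then Kennard-Stone
    validation selection from the remaining pool."""
    n = len(reference.omd)
    labels = np.array(["calibration"] * n, dtype=object)
    if config.test_holdout == "trial":
        # trials suffixed beyond "-Ta" emulate later campaigns of each trial
        is_test = np.array([not t.endswith("-Ta") for t in reference.trial_id])
    elif config.test_holdout == "cluster":
        if reference.cluster_labels is None:
            raise ValueError("cluster holdout requires cluster labels")
        held = np.max(reference.cluster_labels)
        is_test = reference.cluster_labels == held
    else:
        raise ValueError(f"unknown test_holdout {config.test_holdout!r}")
    labels[is_test] = "test"
    pool = np.flatnonzero(~is_test)
    n_val = min(config.n_validation, max(len(pool) - 2, 0))
    if n_val >= 2:
        split = kennard_stone(
            spectra_pp.absorbance[pool], n_val, ids=pool, select="validation"
        )
        labels[split.validation_ids] = "validation"
    return labels.astype(str)


def run_experiment(config: ExperimentConfig, out_dir) -> RunManifest:
    """Execute the full workflow; returns the manifest (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    t_all = time.time()

    def stage(name):
        manifest.timings_s[name] = time.time()

    def stage_done(name):
        manifest.timings_s[name] = round(time.time() - manifest.timings_s[name], 3)

    # -- data -----------------------------------------------------------
    stage("data")
    if config.spectra_csv:
        spectra = SpectraSet.from_csv(config.spectra_csv)
        reference = ReferenceSet.from_csv(config.reference_csv)
    else:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        spectra, reference = generate_dataset(syn)
    if not reference.aligned_with(spectra):
        raise RuntimeError("data stage: spectra and reference ids do not align")
    spectra.to_csv(out / "spectra_raw.csv")
    manifest.stage_counts["data"] = {"samples": spectra.n_samples,
                                     "channels": spectra.n_wavelengths}
    log.info("data: %d samples x %d channels", spectra.n_samples, spectra.n_wavelengths)
    stage_done("data")

    # -- preprocessing ---------------------------------------------------
    stage("preprocess")
    spectra_pp = preprocess(spectra, config.preprocessing)
    spectra_pp.to_csv(out / "spectra_preprocessed.csv")
    manifest.stage_counts["preprocess"] = {"channels": spectra_pp.n_wavelengths}
    log.info("preprocess: %d -> %d channels", spectra.n_wavelengths, spectra_pp.n_wavelengths)
    stage_done("preprocess")

    # -- split -----------------------------------------------------------
    stage("split")
    labels = _assign_subsets(reference, spectra_pp, config, rng)
    reference = reference.with_subset(labels)
    reference.to_csv(out / "reference.csv")
    counts = {s: int(np.sum(labels == s)) for s in np.unique(labels)}
    manifest.stage_counts["split"] = counts
    log.info("split: %s", counts)
    stage_done("split")

    # -- outlier screening -----------------------------------------------
    stage("screen")
    cal_mask = labels == "calibration"
    cal_pp = spectra_pp.subset(cal_mask)
    reports = {}
    kept = {}
    for name in ("calibration", "validation", "test"):
        mask = labels == name
        if not mask.any():
            continue
        rep = screen_outliers(spectra_pp.subset(mask), cal_pp,
                              threshold=config.outlier_threshold)
        reports[name] = rep
        kept[name] = rep.kept_ids
        log.info("screen[%s]: %d of %d excluded (H > %g)",
                 name, len(rep.excluded_ids), int(mask.sum()), config.outlier_threshold)
    screen_df = pd.concat(
        [
            pd.DataFrame({"sample_id": r.sample_ids, "subset": name,
                          "H": r.h_values, "excluded": r.h_values > r.threshold})
            for name, r in reports.items()
        ],
        ignore_index=True,
    )
    screen_df.to_csv(out / "outliers.csv", index=False)
    manifest.stage_counts["screen"] = {
        name: int(len(r.excluded_ids)) for name, r in reports.items()
    }
    stage_done("screen")

    # -- tuning ----------------------------------------------------------
    stage("tune")
    cal_ids = kept["calibration"]
    Xcal = spectra_pp.subset(cal_ids).absorbance
    ycal = reference.subset_rows(cal_ids).omd
    grid = config.grid()
    tuning_rows = []
    selected = {}
    tables = []
    for method in config.methods:
        specs = grid.specs(method, n_cal=len(ycal))
        result = cross_validate(specs, Xcal, ycal, n_folds=config.n_folds)
        selected[method] = result.selected
        tables.append(result.table)
        s = result.selected
        tuning_rows.append(
            {
                "model": method,
                "h": s.h,
                "k": s.k if s.k is not None else len(ycal),
                "nlv": f"{s.nlv_min} to {s.nlv_max}" if method == "KNN-LWPLSR-AGG" else s.nlv,
                "RMSECV": result.selected_rmsecv,
                "R2CV": result.selected_r2cv,
            }
        )
        log.info("tune[%s]: selected %s  RMSECV=%.4f", method, s, result.selected_rmsecv)
    pd.DataFrame(tuning_rows).to_csv(out / "calibration_report.csv", index=False)
    pd.concat(tables, ignore_index=True).to_csv(out / "tuning_tables.csv", index=False)
    stage_done("tune")

    # -- prediction & evaluation ----------------------------------------
    stage("evaluate")
    eval_rows = []
    errors = {}
    pred_frames = []
    for subset_name in ("validation", "test"):
        if subset_name not in kept or len(kept[subset_name]) < 2:
            continue
        ids = kept[subset_name]
        Xs = spectra_pp.subset(ids).absorbance
        obs = reference.subset_rows(ids).omd
        for method in config.methods:
            model = predictor_for(selected[method], Xcal, ycal)
            pred = model.predict(Xs)
            rep = evaluate(pred, obs, label=method)
            row = {"subset": subset_name, **rep.to_row()}
            eval_rows.append(row)
            pred_frames.append(pd.DataFrame({
                "sample_id": ids, "subset": subset_name, "model": method,
                "omd_obs": obs, "omd_pred": pred,
            }))
            if subset_name == "test":
                errors[method] = pred - obs
            log.info("evaluate[%s/%s]: %s", subset_name, method, rep.summary())
    report_df = pd.DataFrame(eval_rows)
    report_df.to_csv(out / "prediction_report.csv", index=False)
    pd.concat(pred_frames, ignore_index=True).to_csv(out / "predictions.csv", index=False)
    stage_done("evaluate")

    # -- model comparison -------------------------------------------------
    stage("compare")
    comp_rows = []
    bias_p, sep_p = {}, {}
    methods_present = [m for m in config.methods if m in errors]
    for i, a in enumerate(methods_present):
        for b in methods_present[i + 1 :]:
            c = compare_models(errors[a], errors[b], a, b, alpha=config.alpha)
            comp_rows.append(dataclasses.asdict(c))
            bias_p[frozenset({a, b})] = c.bias_p
            sep_p[frozenset({a, b})] = c.sep_p
    if methods_present:
        rank_order = sorted(
            methods_present, key=lambda m: float(np.std(errors[m], ddof=1))
        )
        bias_letters = compact_letter_display(methods_present, bias_p,
                                              config.alpha, order=rank_order)
        sep_letters = compact_letter_display(methods_present, sep_p,
                                             config.alpha, order=rank_order)
        for row in comp_rows:
            row["bias_ci"] = list(row["bias_ci"])
            row["sep_ci"] = list(row["sep_ci"])
        comp_df = pd.DataFrame(comp_rows)
        comp_df.to_csv(out / "comparison.csv", index=False)
        pd.DataFrame(
            {
                "model": methods_present,
                "bias_letters": [bias_letters[m] for m in methods_present],
                "rmsepc_letters": [sep_letters[m] for m in methods_present],
            }
        ).to_csv(out / "comparison_letters.csv", index=False)
    stage_done("compare")

    # -- power analysis ---------------------------------------------------
    stage("power")
    test_rows = report_df[report_df["subset"] == "test"] if len(report_df) else report_df
    rmseps = (
        dict(zip(test_rows["model"], test_rows["RMSEP"])) if len(test_rows) else {}
    )
    rmseps["reference method"] = config.reference_se
    pt = power_table(rmseps, d=config.effect_size_d)
    pt["mdd"] = [minimum_detectable_difference(r) for r in pt["RMSEP"]]
    pt.to_csv(out / "power.csv", index=False)
    stage_done("power")

    # -- describe ---------------------------------------------------------
    stage("describe")
    stats_df, scores_df, evr = describe_dataset(spectra_pp, reference)
    stats_df.to_csv(out / "descriptives.csv", index=False)
    scores_df.to_csv(out / "pca_scores.csv", index=False)
    stage_done("describe")

    for name in (
        "spectra_raw.csv", "spectra_preprocessed.csv", "reference.csv",
        "outliers.csv", "calibration_report.csv", "tuning_tables.csv",
        "prediction_report.csv", "predictions.csv", "power.csv",
        "descriptives.csv", "pca_scores.csv",
    ):
        manifest.register(name, out / name)
    if (out / "comparison.csv").exists():
        manifest.register("comparison.csv", out / "comparison.csv")
        manifest.register("comparison_letters.csv", out / "comparison_letters.csv")
    manifest.timings_s["total"] = round(time.time() - t_all, 3)
    manifest.to_json(out / "manifest.json")
    return manifest
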