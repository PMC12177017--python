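"""End-to-end orchestration: ingest -> windows -> features -> classifier for
every (position, window length, sampling frequency) grid cell, then the
position/frequency beta-regression comparison on the resulting accuracy
table."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (
    EvalReport,
    SplitSpec,
    blocked_cv_tune,
    evaluate,
    filter_rare_behaviours,
    split_train_test,
)
from .features import build_feature_table
from .ingest import align_labels, read_accel_csv, read_annotation_csv
from .inferstats import (
    RegressionDesign,
    contrasts_to_frame,
    fit_beta_regression,
    pairwise_contrasts,
    wald_tests,
)
from .types import AccelTrace, AnnotationSet, SUPPORTED_FREQUENCIES, SUPPORTED_WINDOWS
from .windows import resample, segment

log = logging.getLogger("accethogram")

__all__ = ["PipelineSettings", "run_pipeline", "load_cohort_dir", "position_effect_analysis"]


@dataclass
class PipelineSettings:
    """Settings grid for one pipeline run."""

    window_lengths: tuple[float, ...] = (1, 2)
    frequencies: tuple[float, ...] = SUPPORTED_FREQUENCIES
    positions: tuple[str, ...] = ("scute1", "scute3")
    trim_s: float = 1.0
    split: SplitSpec = field(default_factory=SplitSpec)
    mtry_grid: tuple[int, ...] = (2, 4, 6)
    n_trees: int = 1000
    registry: str = "canonical18"

    def __post_init__(self) -> None:
        if len(self.frequencies) == 0:
            raise ValueError("frequency list must be non-empty")
        bad = [f for f in self.frequencies if f not in SUPPORTED_FREQUENCIES]
        if bad:
            raise ValueError(f"unsupported frequencies {bad}")
        bad_w = [w for w in self.window_lengths if w not in SUPPORTED_WINDOWS]
        if bad_w:
            raise ValueError(f"unsupported window lengths {bad_w}")


def load_cohort_dir(in_dir: str | Path) -> list[tuple[AccelTrace, AnnotationSet]]:
    """Read every ``<id>_<position>.csv`` logger file and its
    ``<id>_annotations.csv`` companion from a directory."""
    in_dir = Path(in_dir)
    out = []
    for path in sorted(in_dir.glob("*_scute*.csv")):
        trace = read_accel_csv(path)
        if not trace.species:
            # fixture ids are "<species>_<number>"
            trace.species = trace.individual_id.split("_")[0]
        ann_path = in_dir / f"{trace.individual_id}_annotations.csv"
        ann = read_annotation_csv(ann_path)
        out.append((trace, ann))
    return out


def run_pipeline(
    cohort: list[tuple[AccelTrace, AnnotationSet]],
    settings: PipelineSettings | None = None,
) -> tuple[pd.DataFrame, dict[tuple, EvalReport]]:
    """Run the classification pipeline over the full settings grid.

    For every (position, window length, frequency) cell: align labels with
    bout trimming, segment into windows at the native rate, decimate,
    compute summary metrics, drop rare behaviours, split 70/30 stratified
    by behaviour, tune mtry by individual-blocked CV with within-fold
    up-sampling, refit and evaluate on the held-out 30%.

    Returns the tidy accuracy table (one row per cell) and the EvalReport
    per cell keyed by (species, position, window_s, freq_hz).  A failing
    cell is logged and skipped; the run continues.
    """
    settings = settings or PipelineSettings()
    reports: dict[tuple, EvalReport] = {}
    rows = []
    for position in settings.positions:
        members = [(tr, ann) for tr, ann in cohort if tr.position == position]
        if not members:
            continue
        species = members[0][0].species
        for window_s in settings.window_lengths:
            native = []
            for trace, ann in members:
                series = align_labels(trace, ann, trim_s=settings.trim_s)
                native.extend(segment(series, window_s))
            log.info(
                "%s/%s w=%ss: %d native windows", species, position, window_s, len(native)
            )
            for freq in settings.frequencies:
                key = (species, position, window_s, freq)
                try:
                    wins = [resample(w, freq) for w in native]
                    table = build_feature_table(wins, registry=settings.registry)
                    table, removed = filter_rare_behaviours(table, return_report=True)
                    if removed:
                        log.info("%s: removed rare behaviours %s", key, removed)
                    train, test = split_train_test(table, settings.split)
                    model = blocked_cv_tune(
                        train,
                        mtry_grid=list(settings.mtry_grid),
                        n_trees=settings.n_trees,
                        seed=settings.split.seed,
                    )
                    report = evaluate(model, test)
                except Exception:  # partial-grid failure: report and continue
                    log.exception("pipeline cell %s failed", key)
                    continue
                reports[key] = report
                row = {
                    "species": species,
                    "position": position,
                    "window_s": window_s,
                    "freq_hz": freq,
                    "accuracy": report.overall_accuracy,
                    "auc": report.auc,
                    "mtry": model.mtry,
                    "cv_auc": model.cv_auc,
                    "n_test": report.n_test,
                    "n_classes": len(report.classes),
                }
                for cls, ba in report.balanced_accuracy.items():
                    row[f"balanced_{cls}"] = ba
                rows.append(row)
    return pd.DataFrame(rows), reports


def position_effect_analysis(accuracy_table: pd.DataFrame, rhs: str | None = None) -> dict:
    """Beta regression of overall accuracy on the settings grid, with
    Tukey-adjusted pairwise position contrasts.

    The default design uses position and (when they vary) frequency,
    species and window length; frequency enters as a numeric covariate.
    """
    df = accuracy_table.copy()
    if rhs is None:
        terms = ["position"]
        if df["freq_hz"].nunique() > 1:
            terms.append("freq_hz")
        if "species" in df and df["species"].nunique() > 1:
            terms.append("species")
        candidates = []
        if len(terms) > 1:
            extra = ["window_s"] if "window_s" in df and df["window_s"].nunique() > 1 else []
            candidates.append(" + ".join([" * ".join(terms)] + extra))
            candidates.append(" + ".join(terms + extra))
        candidates.append("position")
    else:
        candidates = [rhs]
    fit = None
    for cand in candidates:  # back off to an additive / smaller design on tiny grids
        design = RegressionDesign(response="accuracy", rhs=cand)
        try:
            fit = fit_beta_regression(design, df)
            if fit.converged:
                break
        except ValueError:
            fit = None
        if cand is candidates[-1] and fit is None:
            raise ValueError("beta regression failed on every candidate design")
    if not fit.converged:
        raise ValueError(
            "beta regression did not converge on the accuracy grid "
            "(too few or degenerate accuracy values)"
        )
    contrasts = pairwise_contrasts(fit, "position")
    return {
        "fit": fit,
        "coefficients": wald_tests(fit),
        "contrasts": contrasts,
        "contrast_table": contrasts_to_frame(contrasts),
    }


def write_manifest(path: str | Path, settings: PipelineSettings, seeds: dict) -> None:
    """Record every seed and the package version next to the outputs."""
    payload = {
        "package_version": __version__,
        "settings": {
            "window_lengths": list(settings.window_lengths),
            "frequencies": list(settings.frequencies),
            "positions": list(settings.positions),
            "trim_s": settings.trim_s,
            "train_fraction": settings.split.train_fraction,
            "mtry_grid": list(settings.mtry_grid),
            "n_trees": settings.n_trees,
        },
        "seeds": seeds,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
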