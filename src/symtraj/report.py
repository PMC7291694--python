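"""Class-group summaries, trajectory tables and end-to-end orchestration.

`run_pipeline` executes the full analysis on a panel + covariate pair:
covariate preparation, class enumeration, the chosen-K fit, posterior
classification, reliable-change rates, the 3-step regression and the
class-group summary, writing every artifact with the seed and configuration
captured.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import covariates as covmod
from .mixture import EMConfig, MixtureModel, fit_em, modal_assignment
from .scales import GAD7, PHQ9, classify_change_panel
from .selection import EnumerationConfig, SelectionTable, enumerate_classes
from .simulate import PanelDataset, VISIT_WEEKS, OUTCOMES
from .threestep import (classification_matrix, or_table,
                        three_step_regression)

__all__ = [
    "ClassGrouping",
    "summarize_class_groups",
    "trajectory_table",
    "plot_trajectories",
    "PipelineConfig",
    "ReportBundle",
    "run_pipeline",
]

logger = logging.getLogger("symtraj")


@dataclass(frozen=True)
class ClassGrouping:
    """Named, disjoint groups of class ids (e.g. remission / improvement /
    chronic)."""

    groups: dict

    def validate(self, n_classes: Optional[int] = None) -> None:
        seen: set = set()
        for name, ids in self.groups.items():
            ids = set(ids)
            overlap = seen & ids
            if overlap:
                raise ValueError(f"group {name!r} overlaps earlier groups "
                                 f"on class ids {sorted(overlap)}")
            seen |= ids
            if n_classes is not None:
                bad = [i for i in ids if not 0 <= i < n_classes]
                if bad:
                    raise ValueError(f"group {name!r} references unknown "
                                     f"class ids {bad}")


def summarize_class_groups(proportions: Sequence[float],
                           grouping: ClassGrouping) -> dict:
    """Sum member class proportions per group, as percentages (1 decimal).

    ``proportions`` may be fractions (summing to ~1) or percentages
    (summing to ~100); the scale is detected from the total.
    """
    props = np.asarray(list(proportions), dtype=float)
    if np.any(props < 0):
        raise ValueError("proportions must be non-negative")
    grouping.validate(n_classes=len(props))
    total = props.sum()
    scale = 1.0 if total > 1.5 else 100.0  # already percent vs fraction
    return {name: round(float(props[list(ids)].sum() * scale), 1)
            for name, ids in grouping.groups.items()}


def trajectory_table(model: MixtureModel,
                     weeks: Sequence[int] = VISIT_WEEKS,
                     class_names: Optional[Sequence[str]] = None
                     ) -> pd.DataFrame:
    """Model-implied per-class, per-visit PHQ-9 and GAD-7 means (tidy)."""
    mu = model.cell_means()  # (K, 2, V)
    if class_names is None:
        class_names = [f"class_{c}" for c in range(model.n_classes)]
    rows = []
    for c in range(model.n_classes):
        for v, wk in enumerate(weeks):
            rows.append({"class": class_names[c], "week": wk,
                         "weight": float(model.weights[c]),
                         "phq9": float(mu[c, 0, v]),
                         "gad7": float(mu[c, 1, v])})
    return pd.DataFrame(rows)


def plot_trajectories(model: MixtureModel, path,
                      class_names: Optional[Sequence[str]] = None) -> None:
    """Two-panel trajectory plot (PHQ-9, GAD-7) of the fitted classes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = trajectory_table(model, class_names=class_names)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, outcome, title in zip(axes, OUTCOMES, ("PHQ-9", "GAD-7")):
        for cls, sub in table.groupby("class", sort=False):
            pct = 100 * sub["weight"].iloc[0]
            ax.plot(sub["week"], sub[outcome], marker="o",
                    label=f"{cls} ({pct:.1f}%)")
        ax.axhline(10, color="grey", ls=":", lw=1)
        ax.set_xlabel("week")
        ax.set_title(title)
    axes[0].set_ylabel("estimated total score")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class PipelineConfig:
    """End-to-end settings; everything needed to reproduce a report."""

    k_max: int = 7
    chosen_k: Optional[int] = None  # default: the enumeration recommendation
    seed: int = 0
    em: EMConfig = field(default_factory=EMConfig)
    enumeration: EnumerationConfig = field(
        default_factory=EnumerationConfig)
    impute: covmod.ImputeConfig = field(
        default_factory=covmod.ImputeConfig)
    grouping: Optional[ClassGrouping] = None
    ref_classes: tuple = (0,)
    make_plots: bool = False


@dataclass
class ReportBundle:
    selection: SelectionTable
    chosen_k: int
    model: MixtureModel
    posteriors: np.ndarray
    modal_labels: np.ndarray
    change_summary: pd.DataFrame
    trajectory: pd.DataFrame
    three_step: Optional[object]
    or_table: Optional[pd.DataFrame]
    group_summary: Optional[dict]
    imputation_report: object
    config: PipelineConfig

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.selection.table.to_csv(out / "selection_table.csv", index=False)
        with open(out / "model.json", "w") as fh:
            json.dump(self.model.to_dict(), fh, indent=2)
        pd.DataFrame(self.posteriors).to_csv(out / "posteriors.csv",
                                             index=False)
        self.change_summary.to_csv(out / "change_summary.csv", index=False)
        self.trajectory.to_csv(out / "trajectory_table.csv", index=False)
        if self.or_table is not None:
            self.or_table.to_csv(out / "or_table.csv", index=False)
        summary = {
            "chosen_k": int(self.chosen_k),
            "seed": int(self.config.seed),
            "group_summary": self.group_summary,
            "class_weights": self.model.weights.tolist(),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)


def _change_summary(panel: PanelDataset) -> pd.DataFrame:
    rows = []
    for column, scale in (("phq9", PHQ9), ("gad7", GAD7)):
        cls = classify_change_panel(panel.visits, column, scale)
        rows.append({
            "scale": scale.name,
            "n": len(cls),
            "improved_pct": round(100 * cls["improved"].mean(), 2),
            "below_threshold_pct": round(
                100 * cls["below_threshold_at_last"].mean(), 2),
            "mean_delta": round(cls["delta"].mean(), 2),
        })
    return pd.DataFrame(rows)


def run_pipeline(panel: PanelDataset, covariate_table: pd.DataFrame,
                 config: Optional[PipelineConfig] = None) -> ReportBundle:
    """Run the full trajectory analysis and return the report bundle.

    Stages: covariate preparation -> class enumeration -> chosen-K fit ->
    posterior classification -> reliable-change summary -> 3-step
    regression -> class-group summary.  A stage failure propagates with the
    stage name attached; earlier artifacts stay on the bundle-in-progress
    via the raised exception's ``partial`` attribute.
    """
    if config is None:
        config = PipelineConfig()
    partial: dict = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        name = stage("covariate_prep")
        prepared, imp_report = covmod.prepare_covariates(
            covariate_table, impute=config.impute)
        partial["covariates"] = prepared

        name = stage("enumeration")
        import dataclasses as _dc
        enum_cfg = _dc.replace(config.enumeration,
                               em=_dc.replace(config.enumeration.em,
                                              seed=config.seed))
        selection = enumerate_classes(panel, config.k_max, enum_cfg)
        partial["selection"] = selection

        name = stage("final_fit")
        chosen_k = config.chosen_k or selection.recommended_k
        if chosen_k in selection.models:
            model = selection.models[chosen_k]
            post = selection.posteriors[chosen_k]
        else:
            em_cfg = _dc.replace(config.em, seed=config.seed)
            model, post = fit_em(panel, chosen_k, em_cfg)
        labels = modal_assignment(post)

        name = stage("change_classification")
        change = _change_summary(panel)

        name = stage("three_step")
        three = None
        table = None
        if chosen_k >= 2:
            Q = classification_matrix(post, labels)
            order = np.argsort(panel.subject_ids)
            del order  # prepared is already aligned to panel order
            three = three_step_regression(
                labels, Q, prepared.drop(columns=["subject_id"]),
                ref_class=min(config.ref_classes))
            table = or_table(three, ref_classes=list(config.ref_classes))

        name = stage("summaries")
        traj = trajectory_table(model)
        groups = None
        if config.grouping is not None:
            groups = summarize_class_groups(model.weights, config.grouping)
    except Exception as exc:
        exc.partial = partial  # type: ignore[attr-defined]
        raise RuntimeError(f"pipeline failed at stage {name!r}: {exc}") \
            from exc

    return ReportBundle(selection=selection, chosen_k=chosen_k, model=model,
                        posteriors=post, modal_labels=labels,
                        change_summary=change, trajectory=traj,
                        three_step=three, or_table=table,
                        group_summary=groups,
                        imputation_report=imp_report, config=config)
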