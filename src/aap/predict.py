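"""Combined prediction, |DTV| validation reports, and parameter tuning.

The two modules are blended per cell line by the similarity score itself:

    GI50 = GI50(FP) * S + GI50(CL) * (1 - S)

so a query that is (nearly) a training compound inherits experimental
values, while a novel scaffold leans on the per-cell-line templates.  When
the best-matching training compound has no experimental value for a cell
line, the prediction falls back to the template value alone.

Accuracy is reported as |DTV(GI50)| — the absolute deviation between
predicted and experimental pGI50 — aggregated per compound, per cell line,
per subpanel (unweighted mean of its cell-line means) and overall, plus the
fraction of deviations within +/-1 log unit.

Tuning evaluates a grid of (N, Z, G) parameter combinations on an internal
validation subset of the training compounds, scoring the template module
alone, and picks the run with the smallest mean |DTV| at each granularity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AapError,
    ActivityMatrix,
    DescriptorMatrix,
    ModelBundle,
)
from .descriptors import CLParams, G_MODES, zero_filter
from .fingerprint import fp_predict
from .templates import build_templates, cl_predict

logger = logging.getLogger("aap")

PREDICTION_COLUMNS = [
    "query_id", "cell_line", "panel", "S", "best_match_id",
    "gi50_fp", "gi50_cl", "cl_bin", "cl_score", "gi50",
]


def combine(gi50_fp: float, gi50_cl: float, S: float) -> float:
    """Blend the similarity-transferred and template values with weight S.

    ``S=1`` returns the FP value, ``S=0`` the CL value; a missing (NaN) FP
    value falls back to the CL value regardless of S.
    """
    if not 0.0 <= S <= 1.0:
        raise AapError(f"S must be in [0, 1], got {S}")
    if gi50_fp is None or (isinstance(gi50_fp, float) and math.isnan(gi50_fp)):
        return float(gi50_cl)
    return float(gi50_fp) * S + float(gi50_cl) * (1.0 - S)


def build_model(
    desc: DescriptorMatrix,
    act: ActivityMatrix,
    params: CLParams,
    backend_id: str = "precomputed",
    min_members: int = 1,
) -> ModelBundle:
    """Train a full model: zero-filter, build templates, record exclusions."""
    if desc.row_ids != act.row_ids:
        act = act.subset_rows(desc.row_ids)
    filtered = zero_filter(desc, params.Z)
    template_set = build_templates(filtered, act, params, min_members=min_members)
    excluded = [c for c in act.col_ids if c not in template_set.templates]
    return ModelBundle(
        descriptor_backend_id=backend_id,
        descriptor_list=filtered.col_ids,
        training_descriptors=filtered,
        training_activity=act,
        template_set=template_set,
        build_params=params,
        excluded_cell_lines=excluded,
    )


def predict_batch(
    queries: DescriptorMatrix,
    model: ModelBundle,
    params: CLParams | None = None,
) -> pd.DataFrame:
    """Predict pGI50 for every (query, active cell line) pair.

    Each query gets one FP pass (a single S score and best match over the
    whole training set) and one CL pass per cell line; the two are blended
    by :func:`combine`.  Returns a long DataFrame with one row per (query,
    cell line), including the audit columns S, best_match_id, gi50_fp,
    gi50_cl and the winning bin/score.
    """
    if params is None:
        params = model.build_params
    missing = [c for c in model.descriptor_list if c not in queries.col_ids]
    if missing:
        raise AapError(
            f"query descriptor matrix lacks {len(missing)} model descriptors, "
            f"e.g. {missing[:5]}"
        )
    q_aligned = queries.subset_cols(model.descriptor_list)
    panel_of = model.training_activity.panel_of
    rows = []
    for qid in q_aligned.row_ids:
        qvec = q_aligned.row(qid)
        try:
            fp = fp_predict(
                qvec, model.training_descriptors, model.training_activity, qid
            )
            s, best_id, fp_row = fp.S, fp.best_match_id, fp.gi50_fp
        except AapError:
            logger.warning(
                "query %r has no descriptor overlap with the training set; "
                "similarity transfer disabled", qid,
            )
            s, best_id = 0.0, None
            fp_row = pd.Series(np.nan, index=model.training_activity.col_ids)
        cl_out = cl_predict(qvec, model.template_set, params)
        for cl in model.template_set.cell_lines:
            fp_val = float(fp_row.get(cl, np.nan))
            if cl in cl_out:
                cl_val, cl_bin, cl_score = cl_out[cl]
            else:
                cl_val, cl_bin, cl_score = np.nan, None, np.nan
            if np.isnan(cl_val):
                gi50 = fp_val  # template unusable: similarity value or missing
            else:
                gi50 = combine(fp_val, cl_val, s)
            rows.append(
                {
                    "query_id": qid,
                    "cell_line": cl,
                    "panel": panel_of.get(cl),
                    "S": s,
                    "best_match_id": best_id,
                    "gi50_fp": fp_val,
                    "gi50_cl": cl_val,
                    "cl_bin": cl_bin,
                    "cl_score": cl_score,
                    "gi50": gi50,
                }
            )
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """|DTV(GI50)| aggregates at every granularity.

    ``dtv`` holds one row per (compound, cell line) pair where both the
    prediction and the experimental value exist; every aggregate is an exact
    function of that table.
    """

    dtv: pd.DataFrame                 # query_id, cell_line, panel, predicted, experimental, dtv
    per_compound: pd.Series
    per_cell_line: pd.Series
    per_panel: pd.Series
    overall_mean: float
    within1_fraction: float
    n_pairs: int

    def summary(self) -> str:
        lines = [
            f"pairs evaluated : {self.n_pairs}",
            f"mean |DTV|      : {self.overall_mean:.4f}",
            f"within +/-1     : {100 * self.within1_fraction:.1f}%",
            "per-panel mean |DTV|:",
        ]
        for panel, v in self.per_panel.items():
            lines.append(f"  {panel:<12s} {v:.4f}")
        return "\n".join(lines)


def dtv_report(
    predicted: pd.DataFrame, experimental: ActivityMatrix
) -> ValidationReport:
    """Compare predictions with experimental activities.

    ``predicted`` is a long frame with columns query_id, cell_line, gi50 (the
    output of :func:`predict_batch`, or any frame with those columns).  Pairs
    where either side is missing are dropped; no overlap at all raises.
    """
    need = {"query_id", "cell_line", "gi50"}
    if not need <= set(predicted.columns):
        raise AapError(f"prediction frame lacks columns {need - set(predicted.columns)}")
    exp_long = experimental.to_long().rename(
        columns={"pGI50": "experimental", "compound_id": "query_id", "panel": "panel_exp"}
    )
    merged = predicted.merge(exp_long, on=["query_id", "cell_line"], how="inner")
    merged = merged[merged["gi50"].notna() & merged["experimental"].notna()]
    if len(merged) == 0:
        raise AapError("no (compound, cell line) pair has both prediction and experiment")
    panel_col = "panel_exp" if "panel_exp" in merged.columns else "panel"
    dtv = pd.DataFrame(
        {
            "query_id": merged["query_id"],
            "cell_line": merged["cell_line"],
            "panel": merged[panel_col],
            "predicted": merged["gi50"],
            "experimental": merged["experimental"],
            "dtv": (merged["gi50"] - merged["experimental"]).abs(),
        }
    ).reset_index(drop=True)
    per_cell_line = dtv.groupby("cell_line")["dtv"].mean()
    panel_of = experimental.panel_of
    per_panel = per_cell_line.groupby(
        per_cell_line.index.map(panel_of)
    ).mean()  # unweighted mean of member cell-line means
    return ValidationReport(
        dtv=dtv,
        per_compound=dtv.groupby("query_id")["dtv"].mean(),
        per_cell_line=per_cell_line,
        per_panel=per_panel,
        overall_mean=float(dtv["dtv"].mean()),
        within1_fraction=float((dtv["dtv"] <= 1.0).mean()),
        n_pairs=int(len(dtv)),
    )


def fp_only_report(
    validation: Sequence[str] | DescriptorMatrix,
    model: ModelBundle,
    experimental: ActivityMatrix | None = None,
) -> ValidationReport:
    """|DTV| report for the similarity module alone.

    ``validation`` is either a list of training compound ids (internal
    validation) or a descriptor matrix of external queries.  Predictions are
    the best match's experimental activities (missing where the match was
    never assayed); compared against ``experimental`` (defaults to the
    model's training activities).
    """
    if experimental is None:
        experimental = model.training_activity
    if isinstance(validation, DescriptorMatrix):
        queries = validation.subset_cols(model.descriptor_list)
    else:
        queries = model.training_descriptors.subset_rows(list(validation))
    rows = []
    for qid in queries.row_ids:
        fp = fp_predict(
            queries.row(qid),
            model.training_descriptors,
            model.training_activity,
            qid,
        )
        for cl, v in fp.gi50_fp.items():
            rows.append({"query_id": qid, "cell_line": cl, "gi50": v})
    return dtv_report(pd.DataFrame(rows), experimental)


def cl_only_report(
    queries: DescriptorMatrix,
    model: ModelBundle,
    experimental: ActivityMatrix,
    params: CLParams | None = None,
) -> ValidationReport:
    """|DTV| report for the template module alone (no similarity transfer)."""
    if params is None:
        params = model.build_params
    q = queries.subset_cols(model.descriptor_list)
    rows = []
    for qid in q.row_ids:
        out = cl_predict(q.row(qid), model.template_set, params)
        for cl, (val, _b, _s) in out.items():
            rows.append({"query_id": qid, "cell_line": cl, "gi50": val})
    return dtv_report(pd.DataFrame(rows), experimental)


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------


@dataclass
class TuningRun:
    run_id: int
    params: CLParams
    report: ValidationReport


@dataclass
class TuningResult:
    runs: list[TuningRun]
    best_overall: int                       # run_id
    best_per_panel: dict[str, int]
    best_per_cell_line: dict[str, int]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run_id": [r.run_id for r in self.runs],
                "N": [r.params.N for r in self.runs],
                "Z": [r.params.Z for r in self.runs],
                "G": [r.params.G for r in self.runs],
                "mean_dtv": [r.report.overall_mean for r in self.runs],
                "within1_fraction": [r.report.within1_fraction for r in self.runs],
            }
        )


#: Default N values of the tuning grid; run 1 is (N=240, Z=50, G=a).
DEFAULT_GRID_N = (240, 360, 480, 600, 720, 800)
DEFAULT_GRID_Z = 50.0


def default_grid() -> list[CLParams]:
    """The shipped 18-combination tuning grid: 6 N values x 3 G modes, Z=50."""
    return [CLParams(N=n, Z=DEFAULT_GRID_Z, G=g) for n in DEFAULT_GRID_N for g in G_MODES]


def tune(
    grid: Sequence[CLParams],
    desc: DescriptorMatrix,
    act: ActivityMatrix,
    validation_ids: Sequence[str],
    min_members: int = 1,
) -> TuningResult:
    """Evaluate a parameter grid on an internal validation subset.

    For each combination the descriptor matrix is re-filtered at that Z, the
    templates rebuilt on the full training set, and the validation compounds
    scored through the template module alone; |DTV| against their
    experimental values ranks the runs.  Ties at any granularity go to the
    lower run_id.
    """
    if len(grid) == 0:
        raise AapError("empty tuning grid")
    validation_ids = list(validation_ids)
    unknown = [i for i in validation_ids if i not in desc.values.index]
    if unknown:
        raise AapError(f"validation ids not in training set: {unknown}")
    val_act = act.subset_rows(validation_ids)
    runs: list[TuningRun] = []
    for run_id, params in enumerate(grid, start=1):
        model = build_model(desc, act, params, min_members=min_members)
        val_desc = model.training_descriptors.subset_rows(validation_ids)
        report = cl_only_report(val_desc, model, val_act)
        runs.append(TuningRun(run_id, params, report))
        logger.info(
            "tuning run %d (N=%d, Z=%g, G=%s): mean |DTV| %.4f",
            run_id, params.N, params.Z, params.G, report.overall_mean,
        )

    def argmin(values: dict[int, float]) -> int:
        return min(values, key=lambda rid: (values[rid], rid))

    best_overall = argmin({r.run_id: r.report.overall_mean for r in runs})
    panels = sorted({p for r in runs for p in r.report.per_panel.index})
    best_per_panel = {
        p: argmin(
            {
                r.run_id: float(r.report.per_panel[p])
                for r in runs
                if p in r.report.per_panel.index
            }
        )
        for p in panels
    }
    lines = sorted({c for r in runs for c in r.report.per_cell_line.index})
    best_per_cell_line = {
        c: argmin(
            {
                r.run_id: float(r.report.per_cell_line[c])
                for r in runs
                if c in r.report.per_cell_line.index
            }
        )
        for c in lines
    }
    return TuningResult(runs, best_overall, best_per_panel, best_per_cell_line)
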