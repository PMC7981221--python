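"""End-to-end orchestration: ingest -> movements -> labels -> inference.

``run_frames`` takes the three in-memory tables (the library entry point);
``run`` reads them from the configured CSV paths.  Both produce a
``RunResult`` carrying every intermediate product, write the artifact
bundle (movements CSV, thresholds JSON, model table CSV, model summary
JSON, text report) and reconcile all counts in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import covariates as _cov
from . import inference as _inf
from . import io as _io
from . import movements as _mov
from .config import RunConfig
from .glmm import CATEGORICAL, fit_glmm

logger = logging.getLogger(__name__)

__all__ = ["RunResult", "run", "run_frames", "summarise_movements", "render_report"]


@dataclass
class RunResult:
    labelled: pd.DataFrame
    thresholds: dict
    model_table: pd.DataFrame
    vif: pd.DataFrame
    global_fit: object
    model_set: object
    pruned_set: object
    selection: object
    r2: tuple
    cond_modes: dict
    auc: float
    diagnostics: dict
    summary: pd.DataFrame
    report: str


def summarise_movements(model_table: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of restricted / out-of-range movements.

    One row per species overall and per species x diel and species x
    season cell; the two percentages in each row sum to 100.
    """
    rows = []

    def cell(scope: str, value: str, sub: pd.DataFrame) -> None:
        n = len(sub)
        oor = float(sub["label"].mean()) * 100 if n else float("nan")
        rows.append((sub["species"].iloc[0] if n else "", scope, value, n,
                     round(100 - oor, 1), round(oor, 1)))

    for sp, sub in model_table.groupby("species", sort=True):
        cell("overall", "all", sub)
        for diel, s2 in sub.groupby("diel", sort=True):
            cell("diel", diel, s2)
        for season, s2 in sub.groupby("season", sort=True):
            cell("season", season, s2)
    return pd.DataFrame(
        rows, columns=["species", "scope", "value", "n", "pct_restricted", "pct_out_of_range"]
    )


def render_report(result: "RunResult", config: RunConfig) -> str:
    lines = ["# Detection-gap analysis report", ""]
    lab = result.labelled
    n_rec = int((lab["kind"] == "recursion").sum())
    n_tr = int((lab["kind"] == "transition").sum())
    n_oor = int(lab["label"].sum())
    lines += [
        "## Movements",
        f"total movements: {len(lab)} (recursions {n_rec}, transitions {n_tr})",
        f"restricted: {len(lab) - n_oor}  out-of-range: {n_oor}",
        "",
        "## Thresholds",
    ]
    for sp, t in sorted(result.thresholds.items()):
        lines.append(
            f"{sp}: recursion {t.recursion_threshold_min:.0f} min, "
            f"RDET {t.transition_rdet_threshold:.3f}"
        )
    lines += ["", "## Movement summary (per species)", result.summary.to_string(index=False), ""]
    lines += ["## Collinearity (VIF)", result.vif.to_string(index=False), ""]
    lines += [
        "## Model selection",
        f"candidates fitted: {len(result.model_set.models)}; "
        f"after nested-model removal: {len(result.pruned_set.models)}",
        result.pruned_set.table.head(10).to_string(index=False),
        "",
        f"selection rule outcome: {result.selection.kind}",
        f"final terms: {' + '.join(result.selection.model.terms) or '1'}",
        "",
        "## Coefficients",
        result.selection.coef.round(4).to_string(),
        "",
        "## Variance components (logit scale)",
    ]
    for f, s2 in result.selection.model.sigma2.items():
        lines.append(f"{f}: variance {s2:.2f}, SD {np.sqrt(s2):.2f}")
    r2m, r2c = result.r2
    lines += ["", f"R2 marginal: {r2m:.3f}  R2 conditional: {r2c:.3f}", ""]
    lines += ["## Conditional modes: fraction of levels with CI excluding 0"]
    for f, fr in result.cond_modes["fraction_significant"].items():
        lines.append(f"{f}: {fr * 100:.0f}%")
    for sp, fr in result.cond_modes.get("fraction_significant_by_species", {}).items():
        lines.append(f"tag_id[{sp}]: {fr * 100:.0f}%")
    lines += [
        "",
        f"## Cross-validation\nAUC ({config.train_fraction:.0%} train, "
        f"seed {config.cv_seed}): {result.auc:.3f}",
        "",
        "## Residual diagnostics (advisory)",
        f"lag-1 ACF: {result.diagnostics['lag1_acf']:.3f} "
        f"(white-noise band +/-{result.diagnostics['white_noise_band']:.3f}); "
        f"{result.diagnostics['frac_acf_within_band'] * 100:.0f}% of lags 1-20 within band",
        f"residual SD spread ratio across fitted bins: {result.diagnostics['spread_ratio']:.2f}",
        "",
    ]
    return "\n".join(lines)


def _usable_terms(table: pd.DataFrame, terms) -> tuple[str, ...]:
    """Drop terms whose categorical variable is single-level in this data.

    A window entirely inside one season (or one-sex data) cannot estimate
    that contrast; the term and its interactions are removed with a
    warning rather than failing the whole run.
    """
    degenerate = {
        v for v in CATEGORICAL
        if v in table.columns and table[v].nunique() < 2
    }
    kept = tuple(t for t in terms if not degenerate & set(t.split(":")))
    dropped = set(terms) - set(kept)
    if dropped:
        logger.warning("dropping inestimable terms %s (single-level: %s)",
                       sorted(dropped), sorted(degenerate))
    return kept


def run_frames(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    individuals: pd.DataFrame,
    config: RunConfig | None = None,
    outdir=None,
) -> RunResult:
    """Run the full analysis on in-memory tables; optionally write artifacts."""
    config = config or RunConfig()
    species_of = dict(zip(individuals["tag_id"], individuals["species"]))

    det = _io.filter_known_tags(detections, individuals)
    if det.empty:
        raise ValueError("no detections from known tags")
    stations = set(det["receiver_id"]) - set(receivers["receiver_id"])
    if stations:
        raise KeyError(f"detections at receivers without coordinates: {sorted(stations)[:5]}")

    mov = _mov.extract_movements(det)
    mov = _mov.filter_recursions(mov, config.min_recursion_gap_s)
    dist = _mov.interreceiver_distances(receivers)
    mov = _mov.compute_rdet(mov, dist, species_of, config.swim_speeds)
    mov = _mov.filter_transitions(mov, config.rdet_max)

    thresholds = _classify.derive_thresholds(mov, species_of)
    labelled = _classify.classify_movements(mov, thresholds, species_of)

    table = _cov.build_model_table(
        labelled, individuals, tz=config.local_tz, anchor=config.anchor,
        receiver_role=config.receiver_role, day_start=config.day_start,
        day_end=config.day_end, wet_months=config.wet_months,
    )
    vif_table = _inf.vif(table)

    global_terms = _usable_terms(table, config.global_terms)
    global_fit = fit_glmm(table, global_terms, config.re_factors)
    model_set = _inf.dredge(table, global_terms, config.re_factors, global_fit=global_fit)
    pruned = _inf.remove_nested(model_set)
    selection = _inf.select_or_average(pruned, config.weight_threshold)
    r2 = _inf.nakagawa_r2(selection.model)
    cond = _inf.conditional_modes(selection.model, individuals)
    auc = _inf.crossval_auc(table, selection.model.terms, config.re_factors,
                            config.train_fraction, config.cv_seed)
    diag = _inf.residual_diagnostics(global_fit)
    summary = summarise_movements(table)

    result = RunResult(labelled, thresholds, table, vif_table, global_fit, model_set,
                       pruned, selection, r2, cond, auc, diag, summary, "")
    result.report = render_report(result, config)
    if outdir is not None:
        _write_artifacts(result, config, outdir)
    return result


def run(config: RunConfig, outdir=None) -> RunResult:
    """Read the configured CSVs and run the full analysis."""
    det = _io.read_detections(config.detections_path, tz=config.input_tz,
                              columns=config.detection_columns or None)
    rec = _io.read_receivers(config.receivers_path, columns=config.receiver_columns or None)
    ind = _io.read_individuals(config.individuals_path, columns=config.individual_columns or None)
    return run_frames(det, rec, ind, config, outdir=outdir or config.output_dir)


def _write_artifacts(result: RunResult, config: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lab = result.labelled.copy()
    for c in ("t_start", "t_end"):
        lab[c] = lab[c].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    lab.to_csv(outdir / "movements.csv", index=False)
    with open(outdir / "thresholds.json", "w") as fh:
        json.dump(
            {
                sp: {
                    "recursion_threshold_min": t.recursion_threshold_min,
                    "transition_rdet_threshold": t.transition_rdet_threshold,
                }
                for sp, t in result.thresholds.items()
            },
            fh, indent=1, sort_keys=True,
        )
    result.model_table.to_csv(outdir / "model_table.csv", index=False)
    sel = result.selection
    summary = {
        "selection_kind": sel.kind,
        "final_terms": list(sel.model.terms),
        "coefficients": {
            name: {k: float(v) for k, v in row.items()}
            for name, row in sel.coef.round(6).iterrows()
        },
        "variance_components": {f: float(s2) for f, s2 in sel.model.sigma2.items()},
        "r2_marginal": result.r2[0],
        "r2_conditional": result.r2[1],
        "auc": result.auc,
        "fraction_significant": result.cond_modes["fraction_significant"],
        "fraction_significant_by_species": result.cond_modes.get(
            "fraction_significant_by_species", {}),
        "selection_table": result.pruned_set.table.to_dict(orient="records"),
        "aicc_best": float(result.pruned_set.table["AICc"].iloc[0]),
    }
    with open(outdir / "model_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    (outdir / "report.txt").write_text(result.report)
    logger.info("artifacts written to %s", outdir)
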