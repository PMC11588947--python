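"""End-to-end orchestration: generate/load -> score -> analyze -> report.

Stages run in a fixed order (scoring, group statistics, ROC, power) and the
bundle written to the output directory contains every intermediate artifact:
``dscores.csv``, ``slopes.csv``, ``ksog_scores.csv``, ``stats_report.json``,
``roc_report.json``, ``power_report.json``, a run log recording every
exclusion decision, and a markdown summary. Analysis denominators are
derived per measure: participants excluded from the IRAP still contribute
FAST and KSOG data, so the IRAP statistics are computed on the eligible
subset while the FAST and KSOG statistics use everyone available.

Sign conventions are never altered in stored scores; the report layer alone
flips the female-picture trial-types when it presents "pro-female bias"
panels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import fast, io, irap, ksog, roc, stats
from .power import (
    f_to_eta2p,
    mde_two_sample_t,
    mde_within_between_interaction,
)
from .simulate import Cohort, GeneratorConfig, generate_cohort
from .types import ExclusionReason, Orientation

D_COLUMNS = ["d_tt1", "d_tt2", "d_tt3", "d_tt4"]
ROC_PREDICTORS = [
    "d_avg", "d_tt1", "d_tt2", "d_tt3", "d_tt4", "d_male", "d_female",
    "slope_difference",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineBundle:
    manifest: pd.DataFrame
    dscores: pd.DataFrame
    slopes: pd.DataFrame
    ksog_scores: pd.DataFrame
    stats_report: dict
    roc_report: dict
    power_report: dict
    exclusion_log: list[str]


def load_inputs(input_dir: str | Path) -> Cohort:
    """Read the four interchange CSVs from a directory."""
    d = Path(input_dir)
    for name in ("manifest.csv", "irap.csv", "fast.csv", "ksog.csv"):
        if not (d / name).exists():
            raise StageError(f"load: missing input file {d / name}")
    return Cohort(
        participants=io.read_manifest(d / "manifest.csv"),
        irap_trials=io.read_irap_log(d / "irap.csv"),
        fast_trials=io.read_fast_log(d / "fast.csv"),
        ksog_cells=io.read_ksog(d / "ksog.csv"),
    )


def write_synthetic_inputs(cohort: Cohort, out_dir: str | Path) -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    io.write_manifest(cohort.participants, d / "manifest.csv")
    io.write_irap_log(cohort.irap_trials, d / "irap.csv")
    io.write_fast_log(cohort.fast_trials, d / "fast.csv")
    io.write_ksog(cohort.ksog_cells, d / "ksog.csv")


def _split_by_orientation(df: pd.DataFrame, col: str):
    x = df.loc[df["orientation"] == Orientation.STRAIGHT.value, col].dropna()
    y = df.loc[df["orientation"] == Orientation.LESBIAN.value, col].dropna()
    return x.to_numpy(), y.to_numpy()


def _effect_json(rep) -> dict:
    return {
        k: (None if v is None or (isinstance(v, float) and math.isnan(v)) else v)
        for k, v in vars(rep).items()
    }


def analyze(cohort: Cohort) -> PipelineBundle:
    """Score all three measures and run the full statistical battery."""
    manifest = cohort.participants[["participant_id", "orientation"]].copy()
    log: list[str] = []

    try:
        dscores = irap.score_cohort(cohort.irap_trials).merge(manifest)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"irap-scoring: {e}") from e
    for _, row in dscores.iterrows():
        if row["excluded_reason"] != ExclusionReason.NONE.value:
            log.append(
                f"IRAP exclusion: {row['participant_id']} ({row['excluded_reason']})"
            )

    try:
        slopes = fast.score_cohort(cohort.fast_trials).merge(manifest)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"fast-scoring: {e}") from e
    try:
        kscores = ksog.score_cohort(cohort.ksog_cells).merge(manifest)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"ksog-scoring: {e}") from e
    for _, row in kscores.iterrows():
        if math.isnan(row["ksog_score"]):
            log.append(f"KSOG missing: {row['participant_id']} (no rated cells)")

    eligible = dscores[dscores["excluded_reason"] == ExclusionReason.NONE.value]
    stats_report: dict = {"n": {}}
    stats_report["n"]["irap"] = int(len(eligible))
    stats_report["n"]["fast"] = int(slopes["slope_difference"].notna().sum())
    stats_report["n"]["ksog"] = int(kscores["ksog_score"].notna().sum())

    try:
        for measure, frame in [
            ("ksog_score", kscores),
            ("slope_difference", slopes),
            ("d_avg", eligible),
            *[(c, eligible) for c in D_COLUMNS],
        ]:
            x, y = _split_by_orientation(frame, measure)
            stats_report[measure] = _effect_json(stats.compare_groups(x, y))
            stats_report[measure]["n_straight"] = int(len(x))
            stats_report[measure]["n_lesbian"] = int(len(y))

        # per-block FAST slopes within each orientation
        for orientation in (Orientation.STRAIGHT.value, Orientation.LESBIAN.value):
            sub = slopes[slopes["orientation"] == orientation]
            rep = stats.rank_sum_test(sub["slope_straight"], sub["slope_lesbian"])
            stats_report[f"fast_blocks_{orientation}"] = {
                "w_statistic": rep.w_statistic,
                "p": rep.w_p_value,
                "cliffs_delta": stats.cliffs_delta(
                    sub["slope_straight"], sub["slope_lesbian"]
                ),
                "mean_slope_straight_block": float(sub["slope_straight"].mean()),
                "mean_slope_lesbian_block": float(sub["slope_lesbian"].mean()),
            }

        # one-sample t of each group's averaged D against zero
        for orientation in (Orientation.STRAIGHT.value, Orientation.LESBIAN.value):
            vals = eligible.loc[
                eligible["orientation"] == orientation, "d_avg"
            ].to_numpy()
            t, df, p = stats.one_sample_t(vals)
            stats_report[f"d_avg_vs_zero_{orientation}"] = {"t": t, "df": df, "p": p}

        # split-plot ANOVA on the four trial-type D scores
        fit = stats.split_plot_anova(
            eligible[D_COLUMNS], eligible["orientation"]
        )
        stats_report["anova"] = json.loads(fit.table.to_json(orient="index"))
        contrasts = stats.pairwise_contrasts(fit)
        stats_report["contrasts"] = {
            k: json.loads(v.to_json(orient="records")) for k, v in contrasts.items()
        }

        # Spearman correlations of every measure with the KSOG
        merged = kscores.merge(slopes, on=["participant_id", "orientation"]).merge(
            eligible, on=["participant_id", "orientation"], how="left"
        )
        stats_report["spearman_vs_ksog"] = {}
        for measure in ["slope_difference", "d_avg", *D_COLUMNS, "d_male", "d_female"]:
            sub = merged[["ksog_score", measure]].dropna()
            rho, p = stats.spearman_rho(sub["ksog_score"], sub[measure])
            stats_report["spearman_vs_ksog"][measure] = {
                "rho": rho, "p": p, "n": int(len(sub))
            }
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stats: {e}") from e

    try:
        roc_report: dict = {}
        for pred in ROC_PREDICTORS:
            frame = slopes if pred == "slope_difference" else eligible
            scores = frame[pred].to_numpy(dtype=float)
            labels = (frame["orientation"] == Orientation.LESBIAN.value).to_numpy()
            roc_report[pred] = {
                "auc": roc.auc(scores, labels),
                "variance": roc.delong_variance(scores, labels),
                "n": int(len(scores)),
            }
        # unpaired comparison: averaged D (eligible) vs slope diff (everyone)
        d_scores = eligible["d_avg"].to_numpy(dtype=float)
        d_labels = (
            eligible["orientation"] == Orientation.LESBIAN.value
        ).to_numpy()
        s_scores = slopes["slope_difference"].to_numpy(dtype=float)
        s_labels = (slopes["orientation"] == Orientation.LESBIAN.value).to_numpy()
        stat, df, p = roc.delong_test_unpaired(d_scores, d_labels, s_scores, s_labels)
        roc_report["delong_d_avg_vs_slope_difference"] = {
            "statistic": stat, "df": df, "p": p
        }
        # paired comparison: male-picture vs female-picture D (same participants)
        stat, df, p = roc.delong_test_paired(
            eligible["d_male"].to_numpy(dtype=float),
            -eligible["d_female"].to_numpy(dtype=float),
            d_labels,
        )
        roc_report["delong_d_male_vs_d_female"] = {
            "statistic": stat, "df": df, "p": p
        }
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(f"roc: {e}") from e

    try:
        n1 = int((eligible["orientation"] == Orientation.STRAIGHT.value).sum())
        n2 = int((eligible["orientation"] == Orientation.LESBIAN.value).sum())
        mde_d = mde_two_sample_t(n1, n2)
        mde_f = mde_within_between_interaction(n1 + n2, 2, 4)
        power_report = {
            "mde_d_two_sample": {"value": mde_d, "n1": n1, "n2": n2},
            "mde_f_interaction": {
                "value": mde_f,
                "eta2p": f_to_eta2p(mde_f),
                "n_total": n1 + n2,
            },
            "alpha": 0.05,
            "power": 0.80,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(f"power: {e}") from e

    return PipelineBundle(
        manifest=manifest,
        dscores=dscores,
        slopes=slopes,
        ksog_scores=kscores,
        stats_report=stats_report,
        roc_report=roc_report,
        power_report=power_report,
        exclusion_log=log,
    )


def write_bundle(bundle: PipelineBundle, out_dir: str | Path) -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    bundle.dscores.to_csv(d / "dscores.csv", index=False)
    bundle.slopes.to_csv(d / "slopes.csv", index=False)
    bundle.ksog_scores.to_csv(d / "ksog_scores.csv", index=False)
    for name, payload in [
        ("stats_report.json", bundle.stats_report),
        ("roc_report.json", bundle.roc_report),
        ("power_report.json", bundle.power_report),
    ]:
        (d / name).write_text(json.dumps(payload, indent=2, default=float) + "\n")
    (d / "run_log.txt").write_text(
        "\n".join(bundle.exclusion_log) + ("\n" if bundle.exclusion_log else "")
    )
    (d / "summary.md").write_text(render_report(bundle))


def run_pipeline(
    input_dir: str | Path | None = None,
    output_dir: str | Path = "out",
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    synthetic: bool = False,
) -> PipelineBundle:
    """Run the whole pipeline from a directory of CSVs or a synthetic cohort."""
    if synthetic:
        cfg = config or GeneratorConfig.default()
        cohort = generate_cohort(cfg, seed=seed)
        write_synthetic_inputs(cohort, Path(output_dir) / "inputs")
    elif input_dir is not None:
        cohort = load_inputs(input_dir)
    else:
        raise StageError("configuration: provide input_dir or synthetic=True")
    bundle = analyze(cohort)
    write_bundle(bundle, output_dir)
    return bundle


def render_report(bundle: PipelineBundle) -> str:
    """Markdown summary shaped like the study's descriptive tables.

    The pro-male/pro-female panel flips the sign of the female-picture
    trial-types for display only; stored scores are untouched.
    """
    lines = ["# Pipeline summary", ""]
    lines.append(
        f"Participants: IRAP n={bundle.stats_report['n']['irap']}, "
        f"FAST n={bundle.stats_report['n']['fast']}, "
        f"KSOG n={bundle.stats_report['n']['ksog']}"
    )
    lines.append("")
    lines.append("## Group comparisons")
    lines.append("")
    lines.append("| measure | W | r | Cliff's d | A | t | df | Cohen's d |")
    lines.append("|---|---|---|---|---|---|---|---|")
    for measure in ["ksog_score", "slope_difference", "d_avg", *D_COLUMNS]:
        if measure not in bundle.stats_report:
            lines.append(f"| {measure} | (absent) | | | | | | |")
            continue
        s = bundle.stats_report[measure]

        def fmt(key):
            v = s.get(key)
            return "" if v is None else f"{v:.3f}"

        lines.append(
            f"| {measure} | {fmt('w_statistic')} | {fmt('r_estimator')} "
            f"| {fmt('cliffs_delta')} | {fmt('vd_a')} | {fmt('t_statistic')} "
            f"| {fmt('t_df')} | {fmt('cohens_d')} |"
        )
    lines.append("")
    if bundle.roc_report:
        lines.append("## ROC AUCs (controls > cases, cases = lesbian)")
        lines.append("")
        lines.append("| predictor | AUC | DeLong variance |")
        lines.append("|---|---|---|")
        for pred in ROC_PREDICTORS:
            if pred in bundle.roc_report:
                r = bundle.roc_report[pred]
                lines.append(f"| {pred} | {r['auc']:.3f} | {r['variance']:.5f} |")
    else:
        lines.append("## ROC AUCs: section absent (no ROC results in bundle)")
    lines.append("")
    lines.append("## Picture-gender biases (display sign flip on female pictures)")
    lines.append("")
    elig = bundle.dscores[
        bundle.dscores["excluded_reason"] == ExclusionReason.NONE.value
    ]
    lines.append("| group | pro-male bias | pro-female bias |")
    lines.append("|---|---|---|")
    for orientation, sub in elig.groupby("orientation"):
        male = sub["d_male"].mean()
        female = -sub["d_female"].mean()
        lines.append(f"| {orientation} | {male:+.3f} | {female:+.3f} |")
    lines.append("")
    mde = bundle.power_report
    lines.append(
        "Sensitivity: minimal detectable d = "
        f"{mde['mde_d_two_sample']['value']:.3f} "
        f"(n {mde['mde_d_two_sample']['n1']}/{mde['mde_d_two_sample']['n2']}); "
        f"minimal detectable f = {mde['mde_f_interaction']['value']:.3f} "
        f"(eta2p {mde['mde_f_interaction']['eta2p']:.3f})."
    )
    lines.append("")
    return "\n".join(lines)
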