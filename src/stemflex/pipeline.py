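"""End-to-end orchestration: specimens -> traits -> class-pooled summaries.

Joins image morphometrics and bending mechanics per specimen, pools stem
segments into diameter classes, and produces (i) a summary table of trait
means +- SD per growth category per class with Kruskal-Wallis p-values and
Dunn compact letters, (ii) scatter exports of diameter vs. E per category and
of wood-type contributions to I vs. E with Spearman statistics, and (iii)
per-class box-plot data. Outputs are plain tidy tables; plotting is left to
the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from stemflex import mech, morpho, stats, synthgen
from stemflex.morpho import TISSUES

#: traits summarized in the Table-1-style output, in row order
TRAIT_COLUMNS = (
    "diameter_mm", "area_mm2",
    "pct_area_cortex", "pct_area_wood1", "pct_area_wood2", "pct_area_pith",
    "I_mm4", "E_MPa", "EI_Nmm2",
    "pct_I_cortex", "pct_I_wood1", "pct_I_wood2", "pct_I_pith",
)


def cohort_to_frames(specimens: list[synthgen.Specimen],
                     morphometrics: str = "raster") -> pd.DataFrame:
    """Reduce a cohort to one tidy row per bending test (stem segment).

    ``morphometrics`` selects whether tissue areas and second moments come
    from the rasterized section (``"raster"``, study-faithful) or from the
    layout's closed forms (``"analytic"``, exact and fast). Specimens without
    a raster fall back to the analytic route.
    """
    if not specimens:
        raise ValueError("empty cohort: nothing to reduce")
    rows = []
    for sp in specimens:
        if morphometrics == "raster" and sp.section is not None:
            tm = morpho.compute_metrics(sp.section)
            morpho_cols = {
                "area_mm2": tm.area_total, "I_morpho_mm4": tm.I_total,
                **{f"pct_area_{t}": tm.pct_area[t] for t in TISSUES},
                **{f"pct_I_{t}": tm.pct_I[t] for t in TISSUES},
            }
        else:
            A = sp.layout.tissue_areas()
            I = sp.layout.tissue_second_moments()
            at, it = sum(A.values()), sum(I.values())
            morpho_cols = {
                "area_mm2": at, "I_morpho_mm4": it,
                **{f"pct_area_{t}": 100.0 * A[t] / at for t in TISSUES},
                **{f"pct_I_{t}": 100.0 * I[t] / it for t in TISSUES},
            }
        for k, test in enumerate(sp.tests):
            tr = mech.reduce_test(test)
            rows.append({
                "specimen_id": sp.specimen_id, "test_index": k,
                "category": sp.category,
                "diameter_mm": tr.diameter,
                "I_mm4": tr.I, "E_MPa": tr.E, "EI_Nmm2": tr.EI,
                "r_squared": tr.r_squared,
                "span_to_depth": tr.span_to_depth,
                **morpho_cols,
                "EI_true": sp.truth["EI"], "E_true": sp.truth["E"],
            })
    return pd.DataFrame(rows)


@dataclass
class SummaryResult:
    """Pipeline outputs: Table-1-style summary plus scatter exports."""

    summary: pd.DataFrame                 # trait x class x category cells
    kw: pd.DataFrame                      # KW p per trait x class
    scatter: dict[str, pd.DataFrame]      # diameter_vs_E, wood1_I_vs_E, ...
    spearman: dict[str, stats.CorrelationResult]
    boxplot: pd.DataFrame                 # tidy rows for per-class box plots
    exclusions: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary_table.csv", index=False)
        self.kw.to_csv(out / "kw_pvalues.csv", index=False)
        self.boxplot.to_csv(out / "boxplot_data.csv", index=False)
        for name, df in self.scatter.items():
            df.to_csv(out / f"scatter_{name}.csv", index=False)
        sp = pd.DataFrame(
            [{"pair": k, "rs": v.rs, "n": v.n, "t": v.t, "p": v.p}
             for k, v in self.spearman.items()])
        sp.to_csv(out / "spearman.csv", index=False)
        if self.exclusions:
            (out / "exclusions.log").write_text("\n".join(self.exclusions) + "\n")


def summarize_frame(df: pd.DataFrame,
                    bounds: stats.ClassBounds = stats.ClassBounds(),
                    alpha: float = 0.05,
                    adjustment: str = "none",
                    min_group_size: int = 3,
                    aggregate: str = "segment") -> SummaryResult:
    """Pool a tidy trait frame into the class-by-category summary.

    ``aggregate="segment"`` treats every bending test (stem segment) as one
    sample; ``"individual"`` averages a specimen's tests first.
    """
    if df.empty:
        raise ValueError("empty trait frame")
    if df["category"].isna().any():
        bad = df.loc[df["category"].isna(), "specimen_id"].tolist()
        raise ValueError(f"specimens missing category labels: {bad}")
    work = df.copy()
    if aggregate == "individual":
        num = work.select_dtypes(np.number).columns
        work = (work.groupby(["specimen_id", "category"], as_index=False)[list(num)]
                .mean())
    elif aggregate != "segment":
        raise ValueError("aggregate must be 'segment' or 'individual'")

    work["diameter_class"] = [
        stats.assign_diameter_class(d, bounds) for d in work["diameter_mm"]]
    exclusions = []
    below = work["diameter_class"] == "below"
    if below.any():
        for sid in work.loc[below, "specimen_id"].unique():
            exclusions.append(f"{sid}: diameter below {bounds.lower} mm range")
        work = work[~below]

    summary_rows, kw_rows = [], []
    for trait in TRAIT_COLUMNS:
        if trait not in work.columns:
            continue
        for cls in stats.CLASS_ORDER:
            sub = work[work["diameter_class"] == cls]
            if sub.empty:
                continue
            groups = {c: sub.loc[sub["category"] == c, trait].to_numpy()
                      for c in synthgen.CATEGORIES
                      if (sub["category"] == c).any()}
            letters: dict[str, str] = {}
            kw_p = np.nan
            try:
                kw = stats.kruskal_wallis(groups, min_size=min_group_size)
                kw_p = kw.p
                for g, why in kw.excluded.items():
                    exclusions.append(f"{trait}/{cls}/{g}: {why}")
                tested = {g: groups[g] for g in kw.groups}
                _, p_mat = stats.dunn_posthoc(tested, adjustment=adjustment)
                letters = stats.compact_letter_display(p_mat, alpha=alpha)
            except ValueError as e:
                exclusions.append(f"{trait}/{cls}: KW not performed ({e})")
            kw_rows.append({"trait": trait, "diameter_class": cls, "p": kw_p})
            for cat, vals in groups.items():
                summary_rows.append({
                    "trait": trait, "diameter_class": cls, "category": cat,
                    "mean": float(np.mean(vals)) if len(vals) else np.nan,
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    "n": len(vals),
                    "letter": letters.get(cat, ""),
                })

    scatter = {
        "diameter_vs_E": work[["specimen_id", "category", "diameter_mm",
                               "E_MPa"]].reset_index(drop=True),
        "wood1_I_vs_E": work[["specimen_id", "category", "pct_I_wood1",
                              "E_MPa"]].reset_index(drop=True),
        "wood2_I_vs_E": work[["specimen_id", "category", "pct_I_wood2",
                              "E_MPa"]].reset_index(drop=True),
    }
    spearman = {
        "pct_I_wood1~E": stats.spearman_t(work["pct_I_wood1"], work["E_MPa"]),
        "pct_I_wood2~E": stats.spearman_t(work["pct_I_wood2"], work["E_MPa"]),
    }
    box_cols = ["E_MPa", "pct_area_wood1", "pct_area_wood2",
                "pct_area_pith", "pct_area_cortex"]
    boxplot = work[["specimen_id", "category", "diameter_class"]
                   + box_cols].reset_index(drop=True)
    return SummaryResult(
        summary=pd.DataFrame(summary_rows), kw=pd.DataFrame(kw_rows),
        scatter=scatter, spearman=spearman, boxplot=boxplot,
        exclusions=exclusions)


def run_pipeline(config: synthgen.CohortConfig,
                 out_dir: str | Path | None = None,
                 morphometrics: str = "raster",
                 **summary_kwargs) -> SummaryResult:
    """Generate a cohort, reduce it, and summarize it in one call."""
    specimens = synthgen.generate_cohort(config)
    df = cohort_to_frames(specimens, morphometrics=morphometrics)
    result = summarize_frame(df, **summary_kwargs)
    if out_dir is not None:
        result.write(out_dir)
    return result


def classify_threshold_report(df: pd.DataFrame,
                              threshold: float = 5.9) -> pd.DataFrame:
    """Per-category maximum diameter and count above a threshold diameter.

    On field-like cohorts this quantifies the developmental rule that only
    attached (climbing, fixed) stems keep thickening past 5-6 mm.
    """
    if df.empty:
        raise ValueError("empty trait frame")
    rows = []
    for cat, sub in df.groupby("category"):
        d = sub["diameter_mm"]
        rows.append({"category": cat, "n": len(sub),
                     "max_diameter_mm": float(d.max()),
                     "n_above_threshold": int((d > threshold).sum()),
                     "threshold_mm": threshold})
    return pd.DataFrame(rows)
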