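"""Per-lineage phenotype extraction, trench-wise baseline rescaling,
per-sgRNA bootstrap aggregation and volcano-style effect calls.

Six phenotypic parameters are tracked per lineage: cell length L, width W,
instantaneous growth rate lambda (doublings/h, from log2-length differences
between consecutive frames inside one interdivision interval), interdivision
time tau (h, between consecutive division events), septum-placement error
L_s = |L_daughter - L_mother/2| / L_mother, and reporter intensity I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PARAMETERS",
    "extract_phenotypes",
    "baseline_rescale",
    "window_lineage_means",
    "aggregate_sgrna",
    "volcano",
    "spherocylinder_volume",
]

#: channel order shared with the clustering module
PARAMETERS = ["length", "width", "growth_rate", "interdivision_time", "septum_error", "intensity"]


def extract_phenotypes(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-frame phenotype table from raw cell records.

    Adds ``growth_rate`` (per frame pair, NaN across divisions),
    ``interdivision_time`` and ``septum_error`` (defined at division frames
    only).  Trenches without divisions keep NaN for the division-derived
    parameters but still report L, W, I and growth rate.
    """
    required = {"trench_id", "time_min", "length", "division_flag"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table lacks columns: {sorted(missing)}")
    cells = cells.sort_values(["trench_id", "time_min"]).copy()
    g = cells.groupby("trench_id", sort=False)

    dt_h = (g["time_min"].shift(-1) - cells["time_min"]) / 60.0
    log2_next = np.log2(g["length"].shift(-1))
    growth = (log2_next - np.log2(cells["length"])) / dt_h
    # a division between t and t+dt makes the frame-pair slope meaningless
    next_divides = g["division_flag"].shift(-1).fillna(1).astype(bool)
    growth[next_divides] = np.nan
    cells["growth_rate"] = growth

    div = cells["division_flag"].astype(bool)
    time_col = "div_time_min" if "div_time_min" in cells.columns else "time_min"
    div_rows = cells.loc[div]
    tau = div_rows.groupby("trench_id")[time_col].diff() / 60.0
    cells["interdivision_time"] = np.nan
    cells.loc[div, "interdivision_time"] = tau

    if {"div_mother_length", "div_daughter_length"} <= set(cells.columns):
        mother = cells["div_mother_length"]
        daughter = cells["div_daughter_length"]
        cells["septum_error"] = (np.abs(daughter - mother / 2.0) / mother).where(div)
    else:
        cells["septum_error"] = np.nan
    return cells


@dataclass
class RescaleResult:
    lineages: pd.DataFrame
    dropped: pd.DataFrame  # trench_id, reason


def baseline_rescale(
    lineages: pd.DataFrame,
    induction_time_min: float,
    min_pre_frames: int = 3,
    robust_sd_limit: float = 3.0,
) -> RescaleResult:
    """Divide each trench's measured parameters by their pre-induction means.

    Removes static trench-to-trench biases (illumination, focus, trench
    geometry), which act multiplicatively on the measured length, width and
    intensity.  Growth rate, interdivision time and septum error are ratios
    or time differences and are invariant to such biases, so they are left
    on their natural scales.  Trenches are dropped when they lack a
    pre-induction window (< ``min_pre_frames`` frames), had no pre-induction
    division, or their pre-induction growth rate lies more than
    ``robust_sd_limit`` robust SDs (1.4826 * MAD) from the chip median.
    """
    pre = lineages[lineages["time_min"] < induction_time_min]
    pre_by_trench = pre.groupby("trench_id")
    pre_counts = pre_by_trench.size()
    pre_growth = pre_by_trench["growth_rate"].mean()
    pre_divs = pre_by_trench["division_flag"].sum()

    med = pre_growth.median()
    mad = np.median(np.abs(pre_growth - med))
    robust_sd = 1.4826 * mad

    drops: list[tuple[int, str]] = []
    all_trenches = lineages["trench_id"].unique()
    for t in all_trenches:
        if t not in pre_counts.index or pre_counts[t] < min_pre_frames:
            drops.append((t, "missing pre-induction window"))
        elif pre_divs[t] < 1:
            drops.append((t, "no pre-induction division"))
        elif robust_sd > 0 and abs(pre_growth[t] - med) > robust_sd_limit * robust_sd:
            drops.append((t, "pre-induction growth outlier"))
    dropped_ids = {t for t, _ in drops}

    kept = lineages[~lineages["trench_id"].isin(dropped_ids)].copy()
    rescale_cols = [c for c in ("length", "width", "intensity") if c in kept.columns]
    pre_means = (
        kept[kept["time_min"] < induction_time_min]
        .groupby("trench_id")[rescale_cols]
        .mean()
    )
    for c in rescale_cols:
        denom = kept["trench_id"].map(pre_means[c])
        kept[c] = kept[c] / denom
    dropped = pd.DataFrame(drops, columns=["trench_id", "reason"])
    return RescaleResult(lineages=kept, dropped=dropped)


def window_lineage_means(
    lineages: pd.DataFrame,
    window_min: tuple[float, float],
) -> pd.DataFrame:
    """Per-trench mean of each parameter within an absolute time window (min)."""
    lo, hi = window_min
    if hi <= lo:
        raise ValueError("empty aggregation window")
    sel = lineages[(lineages["time_min"] >= lo) & (lineages["time_min"] < hi)]
    if sel.empty:
        raise ValueError("no frames inside the aggregation window")
    params = [p for p in PARAMETERS if p in sel.columns]
    out = sel.groupby("trench_id")[params].mean()
    meta = sel.groupby("trench_id")[["sgrna_id"]].first()
    if "gene" in sel.columns:
        meta["gene"] = sel.groupby("trench_id")["gene"].first()
    return meta.join(out).reset_index()


def _bootstrap_sem_of_median(values: np.ndarray, n_boot: int, rng: np.random.Generator) -> float:
    if values.size < 2:
        return 0.0
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    medians = np.median(values[idx], axis=1)
    return float(medians.std(ddof=1))


def aggregate_sgrna(
    lineage_means: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    min_lineages: int = 7,
    max_cv_sem: float = 0.2,
) -> pd.DataFrame:
    """Per-sgRNA point estimates with bootstrap uncertainty.

    The estimate for each parameter is the median of lineage means; its SEM
    is the SD of the bootstrap distribution of that median (resampling
    lineages).  Quality passes only when the sgRNA has strictly more than
    ``min_lineages`` lineages and every parameter's CV_SEM = SEM/|estimate|
    is below ``max_cv_sem``.
    """
    rng = np.random.default_rng(seed)
    params = [p for p in PARAMETERS if p in lineage_means.columns]
    rows = []
    for sgrna, grp in lineage_means.groupby("sgrna_id"):
        n = len(grp)
        rec: dict = {"sgrna_id": sgrna, "n_lineages": n}
        if "gene" in grp.columns:
            rec["gene"] = grp["gene"].iloc[0]
        cv_ok = True
        for p in params:
            vals = grp[p].dropna().to_numpy()
            if vals.size == 0:
                rec[f"{p}_estimate"] = np.nan
                rec[f"{p}_sem"] = np.nan
                rec[f"{p}_cv_sem"] = np.nan
                continue
            est = float(np.median(vals))
            sem = _bootstrap_sem_of_median(vals, n_boot, rng)
            cv = sem / abs(est) if est != 0 else np.inf
            rec[f"{p}_estimate"] = est
            rec[f"{p}_sem"] = sem
            rec[f"{p}_cv_sem"] = cv
            if np.isfinite(cv) and cv >= max_cv_sem:
                cv_ok = False
            if not np.isfinite(cv):
                cv_ok = False
        rec["quality_pass"] = bool(n > min_lineages and cv_ok)
        rows.append(rec)
    return pd.DataFrame(rows)


def volcano(
    lineage_means: pd.DataFrame,
    summaries: pd.DataFrame,
    control_sgrnas: list[str],
    effect_sd_threshold: float = 2.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Effect size (in control-sgRNA SDs) and BH-adjusted Mann-Whitney p per
    sgRNA and parameter.

    The effect scale is the SD of the distribution of *control-sgRNA
    estimates*; the p-value compares the sgRNA's lineage means against the
    pooled control lineage means.  A call requires q < ``fdr`` and
    |effect| >= ``effect_sd_threshold`` (inclusive).
    """
    controls = set(control_sgrnas)
    if len(controls) < 10:
        raise ValueError("need at least 10 control sgRNAs")
    params = [p for p in PARAMETERS if p in lineage_means.columns]
    ctrl_lineages = lineage_means[lineage_means["sgrna_id"].isin(controls)]
    ctrl_summ = summaries[summaries["sgrna_id"].isin(controls)]
    records = []
    for p in params:
        ctrl_est = ctrl_summ[f"{p}_estimate"].dropna()
        mu, sd = float(ctrl_est.mean()), float(ctrl_est.std(ddof=1))
        pooled_ctrl = ctrl_lineages[p].dropna().to_numpy()
        pvals, sgrnas, effects = [], [], []
        for _, row in summaries.iterrows():
            sg = row["sgrna_id"]
            vals = lineage_means.loc[lineage_means["sgrna_id"] == sg, p].dropna().to_numpy()
            est = row[f"{p}_estimate"]
            if vals.size == 0 or not np.isfinite(est) or sd == 0:
                continue
            effect = (est - mu) / sd
            try:
                pv = stats.mannwhitneyu(vals, pooled_ctrl, alternative="two-sided").pvalue
            except ValueError:  # all-identical degenerate input
                pv = 1.0
            sgrnas.append(sg)
            effects.append(effect)
            pvals.append(pv)
        if not pvals:
            continue
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for sg, eff, pv, qv in zip(sgrnas, effects, pvals, qvals):
            records.append(
                {
                    "sgrna_id": sg,
                    "parameter": p,
                    "effect_sd": eff,
                    "pvalue": pv,
                    "qvalue": qv,
                    "called": bool(qv < fdr and abs(eff) >= effect_sd_threshold),
                }
            )
    return pd.DataFrame(records)


def spherocylinder_volume(L, W):
    """Volume, mid-cell perimeter and cross-section of a spherocylinder.

    V = pi (W/2)^2 (L - W) + 4/3 pi (W/2)^3 for total length L >= width W.
    Returns (V, perimeter pi*W, cross_section pi*(W/2)^2); vectorised.
    """
    L = np.asarray(L, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(W <= 0) or np.any(L < W):
        raise ValueError("requires L >= W > 0")
    r = W / 2.0
    V = np.pi * r**2 * (L - W) + (4.0 / 3.0) * np.pi * r**3
    perimeter = np.pi * W
    cross_section = np.pi * r**2
    if V.ndim == 0:
        return float(V), float(perimeter), float(cross_section)
    return V, perimeter, cross_section
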