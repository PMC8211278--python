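"""Spatial-tracking analysis: from per-frame ant coordinates to r.m.s.d.,
colony-level summaries, and mixing-effect statistics.

Because work in ant colonies is spatially organized (nursing happens at the
nest, foraging and waste disposal away from it), the spread of an individual's
positions is a proxy for its propensity to perform extranidal tasks.  It is
measured as the two-dimensional root-mean-square deviation of the ant's
detected coordinates about their own centroid:

    rmsd = sqrt( sum_i ((x_i - xbar)^2 + (y_i - ybar)^2) / F ),

with F the number of frames in which the ant was detected.  Ants detected in
less than 30% of the frames of the considered time frame are excluded; for
ants that died, the considered time frame ends at death.

Colony summaries mirror the simulation metrics: mean behavior (mean r.m.s.d.
of included ants), behavioral variation (s.d. of r.m.s.d.), and
specialization (mean Spearman rank correlation of per-day r.m.s.d. between
consecutive days).  The mixing comparison contrasts between-type differences
across arbitrarily paired pure colonies with within-colony differences in
mixed colonies, using unpaired t tests.

Expected tracking-table columns: colony, treatment (pure_x | pure_y | mixed),
replicate, ant, type, day, frame, x, y, detected, and optionally death_day
(first day the ant was no longer alive; NaN if it survived).  A column-mapping
dict can adapt external layouts without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from antdol.dol_metrics import MixingReport, classify_effect

__all__ = [
    "REQUIRED_COLUMNS",
    "rmsd",
    "load_tracking",
    "detection_filter",
    "ant_summaries",
    "colony_summaries",
    "compare_mixing",
    "analyze_tracking",
]

REQUIRED_COLUMNS = (
    "colony",
    "treatment",
    "replicate",
    "ant",
    "type",
    "day",
    "frame",
    "x",
    "y",
    "detected",
)

TREATMENTS = ("pure_x", "pure_y", "mixed")


def rmsd(coords: np.ndarray) -> float:
    """Root-mean-square deviation of 2D points about their centroid.

    ``coords`` is an (F, 2) array of detected positions; F >= 1.  Invariant
    under translation and rotation; scales linearly with the units.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (F, 2) array")
    if coords.shape[0] == 0:
        raise ValueError("rmsd requires at least one detected frame")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def load_tracking(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a tracking CSV, optionally renaming external column names.

    ``column_map`` maps external names to the canonical schema, e.g.
    ``{"ant_id": "ant", "X_mm": "x"}``.
    """
    table = pd.read_csv(path)
    if column_map:
        table = table.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"tracking table is missing columns: {missing}")
    return table


def _alive_frames(table: pd.DataFrame) -> pd.DataFrame:
    """Restrict each ant's rows to the days preceding its death (if any)."""
    if "death_day" not in table.columns:
        return table
    death = table["death_day"]
    return table[death.isna() | (table["day"] < death)]


def detection_filter(
    table: pd.DataFrame, threshold: float = 0.30, per_day: bool = False
) -> pd.DataFrame:
    """Per-ant detection rates and inclusion flags.

    An ant is included iff it was detected in at least ``threshold`` of the
    frames of its considered time frame — the whole observation phase by
    default, or each day separately with ``per_day=True`` (day-level rows are
    then returned).  For ants with a recorded death day, only frames before
    death count.
    """
    alive = _alive_frames(table)
    keys = ["colony", "ant"] + (["day"] if per_day else [])
    rate = alive.groupby(keys)["detected"].mean().rename("detection_rate").reset_index()
    rate["included"] = rate["detection_rate"] >= threshold
    return rate


def ant_summaries(table: pd.DataFrame, threshold: float = 0.30) -> pd.DataFrame:
    """Per-ant r.m.s.d. over the whole phase, detection rate, inclusion flag.

    The r.m.s.d. uses detected frames from the days preceding death; excluded
    ants (detection rate below ``threshold``) get ``rmsd = NaN``.
    """
    alive = _alive_frames(table)
    flags = detection_filter(table, threshold=threshold)
    det = alive[alive["detected"].astype(bool)]
    meta = (
        alive.groupby(["colony", "ant"])
        .agg(
            treatment=("treatment", "first"),
            replicate=("replicate", "first"),
            type=("type", "first"),
        )
        .reset_index()
    )
    # rmsd^2 = population variance of x plus population variance of y
    var = det.groupby(["colony", "ant"])[["x", "y"]].var(ddof=0)
    values = np.sqrt(var["x"] + var["y"]).rename("rmsd").reset_index()
    out = meta.merge(flags, on=["colony", "ant"], how="left").merge(
        values, on=["colony", "ant"], how="left"
    )
    out["included"] = out["included"].fillna(False).astype(bool)
    out.loc[~out["included"], "rmsd"] = np.nan
    return out[
        [
            "colony",
            "ant",
            "treatment",
            "replicate",
            "type",
            "detection_rate",
            "included",
            "rmsd",
        ]
    ]


def _daily_rmsd(table: pd.DataFrame, included: pd.DataFrame) -> pd.DataFrame:
    """Per (colony, ant, day) r.m.s.d. from that day's detected frames, with
    the day's own centroid; included ants only."""
    alive = _alive_frames(table)
    det = alive[alive["detected"].astype(bool)]
    det = det.merge(included[["colony", "ant"]], on=["colony", "ant"], how="inner")
    var = det.groupby(["colony", "ant", "day"])[["x", "y"]].var(ddof=0)
    return np.sqrt(var["x"] + var["y"]).rename("rmsd").reset_index()


def colony_summaries(table: pd.DataFrame, threshold: float = 0.30) -> pd.DataFrame:
    """Per-colony mean behavior, behavioral variation, specialization, and
    type-specific means.

    * mean behavior: average r.m.s.d. of included ants;
    * behavioral variation: sample s.d. of those r.m.s.d. values (>= 2 ants);
    * specialization: Spearman rank correlation of per-day r.m.s.d. between
      consecutive days, averaged over day pairs (>= 2 days required).
    """
    ants = ant_summaries(table, threshold=threshold)
    included = ants[ants["included"]]
    if included.groupby("colony")["ant"].count().min() < 2:
        raise ValueError("colony summaries require >= 2 included ants per colony")
    daily = _daily_rmsd(table, included)

    rows = []
    for colony, grp in included.groupby("colony"):
        values = grp["rmsd"].to_numpy()
        row = {
            "colony": colony,
            "treatment": grp["treatment"].iloc[0],
            "replicate": grp["replicate"].iloc[0],
            "n_ants": len(grp),
            "mean_behavior": values.mean(),
            "variation": values.std(ddof=1),
        }
        for lab, tgrp in grp.groupby("type"):
            row[f"mean_{lab}"] = tgrp["rmsd"].mean()
        # day-to-day rank consistency
        cd = daily[daily["colony"] == colony].pivot(index="ant", columns="day", values="rmsd")
        days = sorted(cd.columns)
        if len(days) < 2:
            raise ValueError(f"colony {colony!r} has < 2 days; specialization undefined")
        rhos = []
        for d1, d2 in zip(days[:-1], days[1:]):
            pair = cd[[d1, d2]].dropna()
            if len(pair) >= 2:
                rho = stats.spearmanr(pair[d1], pair[d2]).statistic
                if np.isfinite(rho):
                    rhos.append(rho)
        row["specialization"] = float(np.mean(rhos)) if rhos else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def compare_mixing(
    summaries: pd.DataFrame,
    type_x: str,
    type_y: str,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> MixingReport:
    """Mixing-effect t tests from per-colony summaries.

    Pure-arm between-type differences pair the pure-X and pure-Y colonies
    that share a replicate number (arbitrary pairing); mixed-arm differences
    are formed within each mixed colony.  The primary unpaired t test
    compares Y_p - X_p against Y_m - X_m; the asymmetry test compares
    |X_m - X_p| with |Y_m - Y_p| across replicate pairings.  Student's t
    (equal variances) is the default, matching common practice for unpaired
    two-sample comparisons; ``equal_var=False`` switches to Welch.
    """
    arms = {t: summaries[summaries["treatment"] == t] for t in TREATMENTS}
    for t, arm in arms.items():
        if len(arm) < 2:
            raise ValueError(f"need >= 2 colonies in arm {t!r}")

    px = arms["pure_x"].set_index("replicate")
    py = arms["pure_y"].set_index("replicate")
    shared = px.index.intersection(py.index)
    if len(shared) < 2:
        raise ValueError("pure arms share fewer than 2 replicate numbers; cannot pair")
    pure_x = px.loc[shared, "mean_behavior"].to_numpy(float)
    pure_y = py.loc[shared, "mean_behavior"].to_numpy(float)

    mixed = arms["mixed"]
    cx, cy = f"mean_{type_x}", f"mean_{type_y}"
    if cx not in mixed.columns or cy not in mixed.columns:
        raise KeyError(f"mixed colonies lack type means {cx!r}/{cy!r}")
    mixed_x = mixed[cx].to_numpy(float)
    mixed_y = mixed[cy].to_numpy(float)

    lab_x, lab_y = type_x, type_y
    if pure_y.mean() < pure_x.mean():
        pure_x, pure_y = pure_y, pure_x
        mixed_x, mixed_y = mixed_y, mixed_x
        lab_x, lab_y = lab_y, lab_x

    pure_diff = pure_y - pure_x
    mixed_diff = mixed_y - mixed_x
    if pure_diff.std(ddof=1) == 0 and mixed_diff.std(ddof=1) == 0:
        raise ValueError("zero variance in both arms; t test undefined")
    effect = mixed_diff.mean() - pure_diff.mean()
    se = np.sqrt(mixed_diff.var(ddof=1) / len(mixed_diff) + pure_diff.var(ddof=1) / len(pure_diff))
    t_stat, p_value = stats.ttest_ind(mixed_diff, pure_diff, equal_var=equal_var)
    classification = classify_effect(effect, p_value, mixed_y.mean() > mixed_x.mean(), alpha)

    # asymmetry: per-replicate |type shift between pure and mixed|, unpaired t
    mr = mixed.set_index("replicate")
    shared_m = shared.intersection(mr.index)
    asym_t = asym_p = np.nan
    ax_mean = ay_mean = np.nan
    if len(shared_m) >= 2:
        # match the X/Y orientation chosen above: lab_x's pure values live in
        # the arm that houses that type
        pure_of = {type_x: px, type_y: py}
        ax = np.abs(
            mr.loc[shared_m, f"mean_{lab_x}"].to_numpy(float)
            - pure_of[lab_x].loc[shared_m, "mean_behavior"].to_numpy(float)
        )
        ay = np.abs(
            mr.loc[shared_m, f"mean_{lab_y}"].to_numpy(float)
            - pure_of[lab_y].loc[shared_m, "mean_behavior"].to_numpy(float)
        )
        asym_t, asym_p = stats.ttest_ind(ax, ay, equal_var=equal_var)
        ax_mean, ay_mean = float(np.mean(ax)), float(np.mean(ay))

    return MixingReport(
        label_x=lab_x,
        label_y=lab_y,
        x_pure=float(pure_x.mean()),
        y_pure=float(pure_y.mean()),
        x_mixed=float(mixed_x.mean()),
        y_mixed=float(mixed_y.mean()),
        effect=float(effect),
        effect_se=float(se),
        t_stat=float(t_stat),
        p_value=float(p_value),
        classification=classification,
        asymmetry_x=ax_mean,
        asymmetry_y=ay_mean,
        asymmetry_t=float(asym_t),
        asymmetry_p=float(asym_p),
        alpha=alpha,
    )


@dataclass
class TrackingAnalysis:
    """Bundled outputs of the full tracking pipeline."""

    ants: pd.DataFrame
    colonies: pd.DataFrame
    report: MixingReport
    normality: pd.DataFrame


def analyze_tracking(
    table: pd.DataFrame,
    type_x: str,
    type_y: str,
    threshold: float = 0.30,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> TrackingAnalysis:
    """Full pipeline: filter, per-ant r.m.s.d., colony summaries, mixing tests.

    Normality of the two difference samples entering the primary t test is
    reported (Shapiro-Wilk) but never gates the analysis.
    """
    ants = ant_summaries(table, threshold=threshold)
    colonies = colony_summaries(table, threshold=threshold)
    report = compare_mixing(colonies, type_x, type_y, alpha=alpha, equal_var=equal_var)

    arms = {t: colonies[colonies["treatment"] == t] for t in TREATMENTS}
    px = arms["pure_x"].set_index("replicate")["mean_behavior"]
    py = arms["pure_y"].set_index("replicate")["mean_behavior"]
    shared = px.index.intersection(py.index)
    pure_diff = (py.loc[shared] - px.loc[shared]).to_numpy(float)
    mixed_diff = (arms["mixed"][f"mean_{type_y}"] - arms["mixed"][f"mean_{type_x}"]).to_numpy(float)
    norm_rows = []
    for name, sample in (("pure_diff", pure_diff), ("mixed_diff", mixed_diff)):
        if len(sample) >= 3 and np.std(sample) > 0:
            w, p = stats.shapiro(sample)
        else:
            w, p = np.nan, np.nan
        norm_rows.append({"sample": name, "n": len(sample), "shapiro_w": w, "shapiro_p": p})
    return TrackingAnalysis(ants, colonies, report, pd.DataFrame(norm_rows))
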