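"""Descriptive summaries of the everyday acoustic environment and HR.

Implements the figure-level computations of the analysis: per-class
cumulative distributions of the acoustic variables (median across
participants per percentile with a bootstrap CI), hourly quartiles and
soundscape occupancy, marginal-mean heart rate over deciles of each
standardized acoustic variable (with an SPL-stratified variant), and a
one-way repeated-measures ANOVA of mean HR by soundscape with
Greenhouse-Geisser correction and Bonferroni post hocs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ACOUSTIC_VARS, SOUNDSCAPES

__all__ = [
    "leq",
    "class_cdfs",
    "hourly_summaries",
    "marginal_means",
    "MarginalMeanResult",
    "rm_anova_soundscape",
    "AnovaResult",
]


def leq(levels_db) -> float:
    """Equivalent continuous level: energy mean of dB values.

    ``10 log10( mean( 10^(L/10) ) )``; always at least the arithmetic dB
    mean of the same values (Jensen's inequality).
    """
    levels_db = np.asarray(levels_db, dtype=float)
    return float(10.0 * np.log10(np.mean(10.0 ** (levels_db / 10.0))))


def class_cdfs(sound_logs: pd.DataFrame, variables=ACOUSTIC_VARS,
               percentiles=None, n_boot: int = 200,
               seed: int = 0) -> pd.DataFrame:
    """Across-participant median CDF per soundscape class.

    For each participant and class the percentiles 1-99 of each acoustic
    variable are computed; the table reports the across-participant median
    per percentile with a bootstrap (over participants) 95% CI.  Classes
    observed for fewer than 2 participants are omitted with a warning;
    with a single participant overall the CI columns are NaN and a
    ``degenerate`` flag is set.
    """
    percentiles = np.asarray(percentiles if percentiles is not None
                             else np.arange(1, 100), dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for cls in SOUNDSCAPES:
        sub = sound_logs.loc[sound_logs["soundscape"] == cls]
        pids = sub["participant_id"].unique()
        if len(sub) == 0 or len(pids) < 2:
            if len(sub) > 0:
                import warnings

                warnings.warn(f"class {cls!r} present for fewer than 2 participants; "
                              "omitted" if len(pids) < 2 else "")
            if len(pids) == 1:
                # degenerate single-participant call: report flagged medians
                for var in variables:
                    qs = np.percentile(sub[var].to_numpy(float), percentiles)
                    for p, q in zip(percentiles, qs):
                        rows.append({"soundscape": cls, "variable": var,
                                     "percentile": p, "median": q,
                                     "ci_lower": np.nan, "ci_upper": np.nan,
                                     "degenerate": True})
            continue
        for var in variables:
            mat = np.vstack([np.percentile(g[var].to_numpy(float), percentiles)
                             for _, g in sub.groupby("participant_id")])
            med = np.median(mat, axis=0)
            idx = rng.integers(0, mat.shape[0], size=(n_boot, mat.shape[0]))
            boots = np.median(mat[idx], axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
            for p, m, l, h in zip(percentiles, med, lo, hi):
                rows.append({"soundscape": cls, "variable": var, "percentile": p,
                             "median": m, "ci_lower": l, "ci_upper": h,
                             "degenerate": False})
    return pd.DataFrame(rows)


def hourly_summaries(sound_logs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hourly quartiles of the acoustic variables and class occupancy.

    Quartiles are the grand median across participants of each
    participant's hourly quartiles; occupancy is the mean percentage of
    each class per hour across participants (rows sum to 100%).
    """
    logs = sound_logs.copy()
    logs["hour"] = pd.to_datetime(logs["timestamp"]).dt.hour
    qrows = []
    for (hour,), g in logs.groupby(["hour"]):
        per_part = g.groupby("participant_id")[list(ACOUSTIC_VARS)].quantile(
            [0.25, 0.5, 0.75])
        for var in ACOUSTIC_VARS:
            q = per_part[var].unstack(level=-1).median(axis=0)
            qrows.append({"hour": hour, "variable": var,
                          "q25": q[0.25], "q50": q[0.5], "q75": q[0.75]})
    quart = pd.DataFrame(qrows)

    occ_rows = []
    for (hour,), g in logs.groupby(["hour"]):
        shares = (g.groupby("participant_id")["soundscape"]
                  .value_counts(normalize=True).unstack(fill_value=0.0))
        for cls in SOUNDSCAPES:
            if cls not in shares.columns:
                shares[cls] = 0.0
        mean_share = shares[list(SOUNDSCAPES)].mean(axis=0) * 100.0
        row = {"hour": hour}
        row.update({cls: float(mean_share[cls]) for cls in SOUNDSCAPES})
        occ_rows.append(row)
    occupancy = pd.DataFrame(occ_rows)
    return quart, occupancy


@dataclass
class MarginalMeanResult:
    """Decile-binned marginal mean HR versus one acoustic variable."""

    variable: str
    spl_stratum: str            # "all" | "low" | "high"
    bin_centers: np.ndarray     # 10 mid-decile quantiles of the z-scored variable
    bin_means: np.ndarray       # mean standardized HR per bin
    slope: float
    intercept: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    r2: float


def marginal_means(records: pd.DataFrame, variable: str,
                   spl_stratum: str = "all",
                   spl_threshold_db: float = 60.0,
                   reestimate_threshold: bool = False) -> MarginalMeanResult:
    """Marginal mean standardized HR in deciles of one acoustic variable.

    HR and the acoustic variable are z-scored per participant (removing
    between-person offsets such as microphone placement), optionally
    stratified into records with window SPL at or below / above 60 dB
    (the printed overall median; ``reestimate_threshold`` recomputes the
    median from the data instead), pooled, binned into deciles of the
    standardized variable (pooled edges, ties to the lower bin), and the
    10 bin means are regressed on the 10 bin centers by OLS with an
    F(1, 8) test.
    """
    if variable not in records.columns:
        raise ValueError(f"unknown variable {variable!r}")
    if spl_stratum not in ("all", "low", "high"):
        raise ValueError("spl_stratum must be 'all', 'low' or 'high'")
    rec = records.copy()
    if reestimate_threshold:
        spl_threshold_db = float(np.median(rec["spl"].to_numpy(float)))
    if spl_stratum == "low":
        rec = rec.loc[rec["spl"] <= spl_threshold_db]
    elif spl_stratum == "high":
        rec = rec.loc[rec["spl"] > spl_threshold_db]

    def zscore(s: pd.Series) -> pd.Series:
        sd = s.std(ddof=0)
        return (s - s.mean()) / (sd if sd > 0 else 1.0)

    z_hr = rec.groupby("participant_id")["hr"].transform(zscore).to_numpy(float)
    z_x = rec.groupby("participant_id")[variable].transform(zscore).to_numpy(float)
    if len(np.unique(z_x)) < 10:
        raise ValueError(f"fewer than 10 distinct standardized values of {variable!r}")

    edges = np.quantile(z_x, np.linspace(0, 1, 11)[1:-1])
    labels = np.searchsorted(edges, z_x, side="left")   # ties to the lower bin
    centers = np.quantile(z_x, np.linspace(0.05, 0.95, 10))
    means = np.full(10, np.nan)
    for b in range(10):
        sel = labels == b
        if not sel.any():
            raise ValueError("a decile bin is empty; need >= 10 populated bins")
        means[b] = z_hr[sel].mean()

    # closed-form simple regression of the 10 bin means on the bin centers
    x, y = centers, means
    sxx = np.sum((x - x.mean()) ** 2)
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    yhat = intercept + slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    df1, df2 = 1, 8
    if ss_res == 0:
        f = np.inf
        p = 0.0
    else:
        f = (ss_tot - ss_res) / df1 / (ss_res / df2)
        p = float(stats.f.sf(f, df1, df2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return MarginalMeanResult(variable=variable, spl_stratum=spl_stratum,
                              bin_centers=centers, bin_means=means, slope=slope,
                              intercept=intercept, f_stat=float(f), df=(df1, df2),
                              p_value=p, r2=float(r2))


@dataclass
class AnovaResult:
    """Repeated-measures ANOVA of participant-mean HR by soundscape."""

    f_stat: float
    df1: float
    df2: float
    p_value: float
    gg_epsilon: float
    n_participants: int
    pairwise: pd.DataFrame      # columns: a, b, mean_diff, p_raw, p_bonferroni

    def to_dict(self) -> dict:
        return {"F": self.f_stat, "df1": self.df1, "df2": self.df2,
                "p": self.p_value, "gg_epsilon": self.gg_epsilon,
                "n_participants": self.n_participants,
                "pairwise": self.pairwise.to_dict(orient="records")}


def rm_anova_soundscape(records: pd.DataFrame,
                        correction: str = "gg") -> AnovaResult:
    """One-way repeated-measures ANOVA of mean HR across soundscapes.

    Each participant contributes one mean HR per soundscape class;
    participants lacking any class are dropped (logged).  The main effect
    is sphericity-corrected (Greenhouse-Geisser by default, Huynh-Feldt
    via ``correction="hf"``), and all 6 pairwise class comparisons are
    paired t-tests with Bonferroni adjustment.
    """
    import pingouin as pg

    cell = (records.groupby(["participant_id", "soundscape"])["hr"]
            .mean().unstack())
    for cls in SOUNDSCAPES:
        if cls not in cell.columns:
            cell[cls] = np.nan
    complete = cell[list(SOUNDSCAPES)].dropna()
    n_dropped = len(cell) - len(complete)
    if n_dropped:
        import warnings

        warnings.warn(f"dropped {n_dropped} participants lacking some soundscape")
    if len(complete) < 3:
        raise ValueError("repeated-measures ANOVA needs >= 3 complete participants")

    k = len(SOUNDSCAPES)
    n = len(complete)
    cell = complete[list(SOUNDSCAPES)].to_numpy(float)
    ss_class = n * np.sum((cell.mean(axis=0) - cell.mean()) ** 2)
    if ss_class < 1e-12 * max(np.sum((cell - cell.mean()) ** 2), 1.0):
        # degenerate: no between-class variation at all
        f, p, eps = 0.0, 1.0, 1.0
        df1, df2 = float(k - 1), float((k - 1) * (n - 1))
    else:
        long = complete.reset_index().melt(id_vars="participant_id",
                                           var_name="soundscape", value_name="hr")
        aov = pg.rm_anova(data=long, dv="hr", within="soundscape",
                          subject="participant_id", correction=True, detailed=True)
        row = aov.iloc[0]
        f = float(row["F"])
        eps_col = float(row["eps"]) if "eps" in aov.columns else np.nan
        if correction == "gg":
            eps = eps_col if np.isfinite(eps_col) else 1.0
        else:
            eps = float(pg.epsilon(complete[list(SOUNDSCAPES)], correction="hf"))
            eps = min(1.0, eps) if np.isfinite(eps) else 1.0
        df1 = eps * (k - 1)
        df2 = eps * (k - 1) * (n - 1)
        p = float(stats.f.sf(f, df1, df2))

    pairs = []
    classes = list(SOUNDSCAPES)
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            a, b = classes[i], classes[j]
            t, p_raw = stats.ttest_rel(complete[a], complete[b])
            pairs.append({"a": a, "b": b,
                          "mean_diff": float(complete[a].mean() - complete[b].mean()),
                          "p_raw": float(p_raw),
                          "p_bonferroni": float(min(1.0, p_raw * n_pairs))})
    return AnovaResult(f_stat=f, df1=float(df1), df2=float(df2), p_value=p,
                       gg_epsilon=eps, n_participants=n,
                       pairwise=pd.DataFrame(pairs))
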