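"""Salinity-screening statistics for a balanced two-environment trial.

The chain is: log-transform the long trait table, run the nested
randomized-block ANOVA (replicates nested within environment), keep
the stress-significant traits, estimate per-environment BLUEs
(block-adjusted genotype means), and condense the two environments
into the stress tolerance index

    STI_g = (Y_g,normal * Y_g,saline) / mean(Y_normal)^2

(Fernandez form, with the unstressed environment as the "potential"
denominator).  Relative decrease/increase metrics and the K+/Na+
summary serve the physiological validation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "UnbalancedDesignError",
    "StiResult",
    "log_transform",
    "inverse_log_transform",
    "nested_anova",
    "anova_table",
    "filter_traits",
    "blue_estimate",
    "sti",
    "relative_change",
    "k_na_summary",
]

TABLE_COLUMNS = ["genotype", "environment", "replicate", "sample", "trait", "value"]


class UnbalancedDesignError(ValueError):
    """The trait table is not a complete balanced design."""


def _check_table(t: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TABLE_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"trait table lacks columns {missing}")
    keys = t[["genotype", "environment", "replicate", "sample", "trait"]]
    if keys.duplicated().any():
        raise ValueError("trait table contains duplicated design keys")
    return t


def log_transform(t: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Return a copy with value <- log10(value + offset).

    Raises if any shifted value is non-positive, listing the rows.
    """
    t = _check_table(t)
    shifted = t["value"] + offset
    bad = shifted <= 0
    if bad.any():
        rows = t.index[bad].tolist()[:20]
        raise ValueError(
            f"log transform undefined for {int(bad.sum())} row(s) with "
            f"value + {offset} <= 0 (first rows: {rows})"
        )
    out = t.copy()
    out["value"] = np.log10(shifted)
    return out


def inverse_log_transform(t: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    out = t.copy()
    out["value"] = np.power(10.0, out["value"]) - offset
    return out


def _balanced_array(sub: pd.DataFrame) -> tuple[np.ndarray, list, list, list]:
    """Pivot one trait's rows to a (g, e, r, s) array; raise if any
    cell is missing or duplicated."""
    G = sorted(sub["genotype"].unique())
    E = sorted(sub["environment"].unique())
    R = sorted(sub["replicate"].unique())
    S = sorted(sub["sample"].unique())
    expected = len(G) * len(E) * len(R) * len(S)
    if len(sub) != expected:
        raise UnbalancedDesignError(
            f"expected {expected} rows for a complete {len(G)}x{len(E)}x"
            f"{len(R)}x{len(S)} design, found {len(sub)}"
        )
    idx = sub.set_index(["genotype", "environment", "replicate", "sample"])["value"]
    try:
        arr = idx.reindex(pd.MultiIndex.from_product([G, E, R, S])).to_numpy()
    except Exception as exc:  # pragma: no cover - defensive
        raise UnbalancedDesignError(str(exc)) from exc
    if np.isnan(arr).any():
        raise UnbalancedDesignError("design has missing cells")
    return arr.reshape(len(G), len(E), len(R), len(S)), G, E, R


def _anova_single(arr: np.ndarray) -> dict[str, float]:
    """Balanced nested-RBD decomposition of a (g, e, r) plot array.

    Sources: stress (tested against replicate-within-stress), genotype
    and genotype x stress (tested against the residual).
    """
    g, e, r = arr.shape
    m = arr.mean()
    m_e = arr.mean(axis=(0, 2))          # per environment
    m_er = arr.mean(axis=0)              # environment x replicate
    m_g = arr.mean(axis=(1, 2))          # per genotype
    m_ge = arr.mean(axis=2)              # genotype x environment
    ss_stress = g * r * np.sum((m_e - m) ** 2)
    ss_rep = g * np.sum((m_er - m_e[:, None]) ** 2)
    ss_geno = e * r * np.sum((m_g - m) ** 2)
    ss_gxs = r * np.sum((m_ge - m_g[:, None] - m_e[None, :] + m) ** 2)
    ss_total = np.sum((arr - m) ** 2)
    # subtraction can go infinitesimally negative in float arithmetic
    ss_res = max(ss_total - ss_stress - ss_rep - ss_geno - ss_gxs, 0.0)
    df_stress, df_rep = e - 1, e * (r - 1)
    df_geno, df_gxs = g - 1, (g - 1) * (e - 1)
    df_res = g * e * r - 1 - df_stress - df_rep - df_geno - df_gxs
    ms_rep = ss_rep / df_rep if df_rep else np.nan
    ms_res = ss_res / df_res if df_res else np.nan

    def f_p(ss, df, denom_ms, denom_df):
        if denom_ms is None or not np.isfinite(denom_ms) or denom_ms <= 0:
            return np.nan, 1.0  # zero-variance degenerate input
        f = (ss / df) / denom_ms
        return f, float(stats.f.sf(f, df, denom_df))

    f_stress, p_stress = f_p(ss_stress, df_stress, ms_rep, df_rep)
    f_geno, p_geno = f_p(ss_geno, df_geno, ms_res, df_res)
    f_gxs, p_gxs = f_p(ss_gxs, df_gxs, ms_res, df_res)
    cv = 100.0 * np.sqrt(ms_res) / m if m != 0 and np.isfinite(ms_res) else np.nan
    return {
        "ss_stress": ss_stress, "ss_rep": ss_rep, "ss_genotype": ss_geno,
        "ss_gxs": ss_gxs, "ss_residual": ss_res, "ss_total": ss_total,
        "df_stress": df_stress, "df_rep": df_rep, "df_genotype": df_geno,
        "df_gxs": df_gxs, "df_residual": df_res,
        "F_stress": f_stress, "F_genotype": f_geno, "F_gxs": f_gxs,
        "p_stress": p_stress, "p_genotype": p_geno, "p_gxs": p_gxs,
        "cv_trans": cv, "grand_mean": m,
    }


def nested_anova(t: pd.DataFrame, use_plot_means: bool = True) -> pd.DataFrame:
    """Per-trait nested ANOVA of a balanced trait table.

    Returns a DataFrame indexed by trait with p_stress / p_genotype /
    p_gxs, the F statistics and CV_trans (percent, on the analysed
    scale).  By default samples are averaged to plot means before the
    decomposition; ``use_plot_means=False`` keeps samples as the
    residual replication unit.
    """
    t = _check_table(t)
    results = {}
    for trait, sub in t.groupby("trait", sort=False):
        arr, G, E, R = _balanced_array(sub)
        if len(G) < 2 or len(E) != 2 or len(R) < 2:
            raise ValueError(
                "need >= 2 genotypes, exactly 2 environments, >= 2 replicates"
            )
        if use_plot_means:
            plot = arr.mean(axis=3)
        else:
            # treat each sample as a residual-level observation by
            # folding the sample axis into the replicate variance
            g, e, r, s = arr.shape
            plot = arr.reshape(g, e, r * s) if s == 1 else None
            if plot is None:
                res = _anova_sample_level(arr)
                results[trait] = res
                continue
        res = _anova_single(plot)
        if not np.isfinite(res["F_stress"]) and res["ss_total"] == 0:
            warnings.warn(
                f"trait {trait!r}: zero variance everywhere; p-values reported as 1",
                stacklevel=2,
            )
        results[trait] = res
    return pd.DataFrame(results).T.rename_axis("trait")


def _anova_sample_level(arr: np.ndarray) -> dict[str, float]:
    """Sample-level variant: same fixed sources, with the within-plot
    sampling variation pooled into the residual."""
    g, e, r, s = arr.shape
    plot = arr.mean(axis=3)
    res = _anova_single(plot)
    # rescale plot-level SS to the sample scale and add sampling stratum
    for k in ("ss_stress", "ss_rep", "ss_genotype", "ss_gxs", "ss_residual"):
        res[k] *= s
    ss_total = float(np.sum((arr - arr.mean()) ** 2))
    ss_sampling = ss_total - sum(
        res[k] for k in ("ss_stress", "ss_rep", "ss_genotype", "ss_gxs", "ss_residual")
    )
    res["ss_residual"] += ss_sampling
    res["df_residual"] += g * e * r * (s - 1)
    res["ss_total"] = ss_total
    ms_res = res["ss_residual"] / res["df_residual"]
    ms_rep = res["ss_rep"] / res["df_rep"]
    res["F_stress"] = (res["ss_stress"] / res["df_stress"]) / ms_rep if ms_rep > 0 else np.nan
    res["p_stress"] = (
        float(stats.f.sf(res["F_stress"], res["df_stress"], res["df_rep"]))
        if np.isfinite(res["F_stress"]) else 1.0
    )
    for src in ("genotype", "gxs"):
        f = (res[f"ss_{src}"] / res[f"df_{src}"]) / ms_res if ms_res > 0 else np.nan
        res[f"F_{src}"] = f
        res[f"p_{src}"] = (
            float(stats.f.sf(f, res[f"df_{src}"], res["df_residual"]))
            if np.isfinite(f) else 1.0
        )
    res["cv_trans"] = (
        100.0 * np.sqrt(ms_res) / res["grand_mean"] if res["grand_mean"] != 0 else np.nan
    )
    return res


def anova_table(t: pd.DataFrame, trait: str, use_plot_means: bool = True) -> pd.DataFrame:
    """Classical source table (df, SS, MS, F, p) for one trait."""
    row = nested_anova(t[t["trait"] == trait], use_plot_means=use_plot_means).loc[trait]
    sources = [
        ("stress", "ss_stress", "df_stress", "F_stress", "p_stress"),
        ("replicate(stress)", "ss_rep", "df_rep", None, None),
        ("genotype", "ss_genotype", "df_genotype", "F_genotype", "p_genotype"),
        ("genotype x stress", "ss_gxs", "df_gxs", "F_gxs", "p_gxs"),
        ("residual", "ss_residual", "df_residual", None, None),
    ]
    recs = []
    for name, ss, df, f, p in sources:
        recs.append({
            "source": name, "df": int(row[df]), "SS": row[ss],
            "MS": row[ss] / row[df] if row[df] else np.nan,
            "F": row[f] if f else np.nan, "p": row[p] if p else np.nan,
        })
    return pd.DataFrame(recs).set_index("source")


def filter_traits(anova_result: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Traits whose stress p-value is below alpha, in input order."""
    return [t for t in anova_result.index if anova_result.loc[t, "p_stress"] < alpha]


def blue_estimate(t: pd.DataFrame) -> pd.DataFrame:
    """Per-environment block-adjusted genotype means.

    For each environment and trait, fits the fixed-effects model
    value ~ genotype + replicate by least squares and reports each
    genotype's mean prediction averaged over replicate blocks.  On a
    balanced design this equals the genotype x environment cell mean
    (identity exploited in tests, not in the code path).

    Returns a DataFrame with columns genotype, environment, trait, value.
    """
    t = _check_table(t)
    for trait, sub in t.groupby("trait", sort=False):
        _balanced_array(sub)  # raises UnbalancedDesignError if incomplete
    rows = []
    for (trait, env), sub in t.groupby(["trait", "environment"], sort=False):
        model = smf.ols("value ~ C(genotype) + C(replicate)", data=sub).fit()
        reps = sorted(sub["replicate"].unique())
        for geno in sorted(sub["genotype"].unique()):
            grid = pd.DataFrame({"genotype": geno, "replicate": reps})
            rows.append((geno, env, trait, float(model.predict(grid).mean())))
    return pd.DataFrame(rows, columns=["genotype", "environment", "trait", "value"])


@dataclass
class StiResult:
    """Stress tolerance indices per genotype (rows) and trait (columns),
    with the per-trait mean over genotypes."""

    values: pd.DataFrame
    trait_means: pd.Series

    def with_mean_row(self) -> pd.DataFrame:
        out = self.values.copy()
        out.loc["Mean"] = self.trait_means
        return out


def sti(blue: pd.DataFrame, normal_label: str = "normal",
        saline_label: str = "saline") -> StiResult:
    """Fernandez stress tolerance index from a BLUE table.

    STI_g = (Y_g,normal * Y_g,saline) / mean(Y_normal)^2 per trait.
    """
    wide = blue.pivot_table(index="genotype", columns=["trait", "environment"],
                            values="value")
    traits = blue["trait"].unique()
    out = {}
    for trait in traits:
        try:
            yn = wide[(trait, normal_label)]
            ys = wide[(trait, saline_label)]
        except KeyError as exc:
            raise ValueError(f"trait {trait!r}: missing environment {exc}") from exc
        if yn.isna().any() or ys.isna().any():
            raise ValueError(f"trait {trait!r}: missing genotype cells")
        denom = yn.mean() ** 2
        if denom == 0:
            raise ZeroDivisionError(
                f"trait {trait!r}: mean normal-environment value is zero"
            )
        out[trait] = yn * ys / denom
    values = pd.DataFrame(out)
    return StiResult(values=values, trait_means=values.mean(axis=0))


def relative_change(blue: pd.DataFrame, mode: str = "decrease",
                    scale: str = "percent", normal_label: str = "normal",
                    saline_label: str = "saline") -> pd.DataFrame:
    """Relative decrease (normal-saline)/normal or increase
    (saline-normal)/normal per genotype x trait; x100 when
    scale='percent'.  The mode/scale are recorded in ``.attrs``."""
    if mode not in ("decrease", "increase"):
        raise ValueError("mode must be 'decrease' or 'increase'")
    if scale not in ("percent", "proportion"):
        raise ValueError("scale must be 'percent' or 'proportion'")
    wide = blue.pivot_table(index="genotype", columns=["trait", "environment"],
                            values="value")
    out = {}
    for trait in blue["trait"].unique():
        yn = wide[(trait, normal_label)]
        ys = wide[(trait, saline_label)]
        if (yn == 0).any():
            bad = yn.index[yn == 0].tolist()
            raise ZeroDivisionError(
                f"trait {trait!r}: zero normal-environment value for {bad}"
            )
        change = (yn - ys) / yn if mode == "decrease" else (ys - yn) / yn
        out[trait] = change * (100.0 if scale == "percent" else 1.0)
    res = pd.DataFrame(out)
    res.attrs.update({"mode": mode, "scale": scale})
    return res


def k_na_summary(ion: pd.DataFrame, normal_label: str = "normal",
                 saline_label: str = "saline") -> pd.DataFrame:
    """Per-genotype ion summary: Na+, K+ and K+/Na+ per environment,
    plus the relative increase (proportion) of each under salinity."""
    for col in ("genotype", "environment", "na", "k"):
        if col not in ion.columns:
            raise ValueError(f"ion table lacks column {col!r}")
    if (ion["na"] <= 0).any():
        raise ValueError("Na+ content must be positive in every cell")
    wide = ion.pivot_table(index="genotype", columns="environment",
                           values=["na", "k"])
    rows = {}
    for geno in wide.index:
        nan_, nas = wide.loc[geno, ("na", normal_label)], wide.loc[geno, ("na", saline_label)]
        kn, ks = wide.loc[geno, ("k", normal_label)], wide.loc[geno, ("k", saline_label)]
        rn, rs = kn / nan_, ks / nas
        rows[geno] = {
            "na_normal": nan_, "na_saline": nas,
            "k_normal": kn, "k_saline": ks,
            "k_na_normal": rn, "k_na_saline": rs,
            "ri_na": (nas - nan_) / nan_,
            "ri_k": (ks - kn) / kn,
            "ri_k_na": (rs - rn) / rn,
        }
    return pd.DataFrame(rows).T.rename_axis("genotype")
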