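"""Per-CpG association testing between smoking and methylation.

The core model is a two-factor additive ANOVA fitted per CpG on M-values
restricted to never and current smokers:

    M ~ smoking_status + ethnic_group

with the smoking term assessed by a partial (type-II) F-test. Genome-wide
significance uses a Bonferroni family-wise threshold alpha / n_tests over
the post-QC probe count. Effect sizes are reported on the beta scale as
the signed median difference (current - never). At each multi-CpG locus
the sentinel is the significant CpG with the smallest p-value. For
sentinels, an ethnicity x smoking interaction test (partial F of the
interaction term), per-ethnicity stratified tests, an ethnicity
main-effect test and a never-smoker between-ethnicity t-test are added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import m_to_beta

__all__ = [
    "fwer_threshold", "fit_cpg_anova", "interaction_test", "effect_size",
    "group_t_test", "select_sentinels", "run_ewas", "dose_regression",
    "EwasResult",
]


def fwer_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni family-wise p-value threshold: alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y on the design X."""
    Q, _ = np.linalg.qr(X)
    fitted = Q.T @ Y
    rss = (Y * Y).sum(axis=0) - (fitted * fitted).sum(axis=0)
    return np.maximum(rss, 0.0)


def _partial_f(Y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray):
    """Vectorised partial F-test comparing nested designs over many probes.

    Y is n_samples x n_probes. Returns (F, p) arrays. Probes with a
    constant outcome are flagged NaN; probes fitted exactly by the full
    model (zero residual) get F = inf and p = 0.
    """
    n = Y.shape[0]
    rank_f = np.linalg.matrix_rank(X_full)
    rank_r = np.linalg.matrix_rank(X_reduced)
    q = rank_f - rank_r
    df_resid = n - rank_f
    if q < 1:
        raise ValueError("designs are not strictly nested")
    if df_resid < 1:
        raise ValueError("zero residual degrees of freedom")
    rss_f = _rss(Y, X_full)
    rss_r = _rss(Y, X_reduced)
    scale = (Y * Y).sum(axis=0) + 1.0
    constant = Y.std(axis=0) == 0
    exact = (rss_f / scale) < 1e-14

    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_r - rss_f) / q) / (rss_f / df_resid)
    p = stats.f.sf(F, q, df_resid)
    F[exact] = np.inf
    p[exact] = 0.0
    F[constant] = np.nan
    p[constant] = np.nan
    return F, p


def _design(smoking_status: np.ndarray, ethnicity: np.ndarray, interaction: bool = False):
    current = (smoking_status == "current").astype(float)
    eth_levels = np.unique(ethnicity)
    cols = [np.ones(len(current))]
    for lvl in eth_levels[1:]:
        cols.append((ethnicity == lvl).astype(float))
    X_reduced = np.column_stack(cols)
    X_additive = np.column_stack(cols + [current])
    if not interaction:
        return X_additive, X_reduced
    inter_cols = [current * (ethnicity == lvl).astype(float) for lvl in eth_levels[1:]]
    X_inter = np.column_stack([X_additive] + inter_cols)
    return X_inter, X_additive


def _restrict(smoking_status):
    status = np.asarray(smoking_status)
    mask = np.isin(status, ("never", "current"))
    if not mask.any():
        raise ValueError("no never/current samples present")
    return status, mask


def fit_cpg_anova(m_row, smoking_status, ethnicity):
    """Partial F-test of the smoking term, adjusting for ethnic group.

    Restricted to never and current smokers; former smokers in the input
    are dropped. A constant outcome yields (nan, nan) rather than raising;
    a perfectly separating outcome yields (inf, 0.0), i.e. p below any
    representable positive double.
    """
    status, mask = _restrict(smoking_status)
    y = np.asarray(m_row, dtype=float)[mask]
    status = status[mask]
    eth = np.asarray(ethnicity)[mask]
    if len(np.unique(status)) < 2:
        raise ValueError("both never and current smokers are required")
    X_full, X_red = _design(status, eth)
    F, p = _partial_f(y[:, None], X_full, X_red)
    return float(F[0]), float(p[0])


def interaction_test(m_row, smoking_status, ethnicity):
    """Partial F-test of the smoking x ethnicity interaction term.

    Compares the model with the interaction against the additive model,
    on never and current smokers. An empty cell in the smoking x ethnicity
    design yields (nan, nan) with a warning.
    """
    status, mask = _restrict(smoking_status)
    y = np.asarray(m_row, dtype=float)[mask]
    status = status[mask]
    eth = np.asarray(ethnicity)[mask]
    cells = pd.crosstab(pd.Series(status), pd.Series(eth))
    if cells.shape != (2, len(np.unique(eth))) or (cells.values == 0).any():
        warnings.warn("empty cell in the smoking x ethnicity design; "
                      "interaction not estimable", stacklevel=2)
        return float("nan"), float("nan")
    X_full, X_add = _design(status, eth, interaction=True)
    F, p = _partial_f(y[:, None], X_full, X_add)
    return float(F[0]), float(p[0])


def effect_size(beta_row, groups) -> float:
    """Signed median beta difference: median(current) - median(never)."""
    groups = np.asarray(groups)
    beta_row = np.asarray(beta_row, dtype=float)
    cur = beta_row[groups == "current"]
    nev = beta_row[groups == "never"]
    if cur.size == 0 or nev.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(np.median(cur) - np.median(nev))


def group_t_test(values, group_labels, equal_var: bool = False):
    """Two-sided two-sample t-test (Welch by default) between two groups."""
    labels = np.asarray(group_labels)
    values = np.asarray(values, dtype=float)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(levels)}")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf * np.sign(a.mean() - b.mean())), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def select_sentinels(ewas_table: pd.DataFrame, manifest: pd.DataFrame) -> pd.Series:
    """Sentinel CpG per locus: the smallest-p CpG among those provided.

    Ties on p are broken by larger absolute effect size, then by
    lexicographic probe id. A probe absent from the manifest becomes its
    own singleton locus (with a warning). Returns a Series mapping locus
    label to sentinel probe id.
    """
    loci = manifest.set_index("probe_id")["locus"] if "probe_id" in manifest.columns \
        else manifest["locus"]
    table = ewas_table.copy()
    table["locus"] = loci.reindex(table["probe_id"]).values
    unmapped = table["locus"].isna()
    if unmapped.any():
        warnings.warn(
            f"{int(unmapped.sum())} CpG(s) missing from the manifest; "
            "treated as singleton loci", stacklevel=2)
        table.loc[unmapped, "locus"] = table.loc[unmapped, "probe_id"]
    table = table.assign(abs_effect=table["effect_size"].abs()).sort_values(
        by=["p_value", "abs_effect", "probe_id"], ascending=[True, False, True])
    sentinels = table.groupby("locus", sort=True)["probe_id"].first()
    sentinels.name = "sentinel_probe"
    return sentinels


@dataclass
class EwasResult:
    """Output of :func:`run_ewas`: the per-CpG table plus run metadata."""

    table: pd.DataFrame
    threshold: float
    n_tests: int
    alpha: float
    adjusted_table: pd.DataFrame | None = None

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def sentinels(self) -> pd.DataFrame:
        return self.table[self.table["sentinel"]]


def _ewas_pass(m_sub, beta_sub, status, eth):
    X_full, X_red = _design(status, eth)
    F, p = _partial_f(m_sub.values.T, X_full, X_red)
    eff = (np.median(beta_sub.values[:, status == "current"], axis=1)
           - np.median(beta_sub.values[:, status == "never"], axis=1))
    return F, p, eff


def run_ewas(beta: pd.DataFrame, m: pd.DataFrame, sheet: pd.DataFrame,
             manifest: pd.DataFrame, alpha: float = 0.05,
             cell_proportions: pd.DataFrame | None = None) -> EwasResult:
    """Genome-wide smoking EWAS with sentinel, interaction and stratified tests.

    Inputs are assumed QC-filtered and (for `m`) batch-centered; `beta` is
    only used for effect sizes. Samples are restricted to never and
    current smokers. Probes whose test is not estimable (constant outcome)
    are kept as flagged NA rows and excluded from the test count.

    With ``cell_proportions`` given, the full pass is repeated on
    composition-adjusted M-values and returned as ``adjusted_table``.
    """
    from .cellcomp import adjust_for_composition

    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    sheet = sheet.loc[m.columns]
    mask = sheet["smoking_status"].isin(["never", "current"]).values
    status = sheet["smoking_status"].values[mask]
    eth = sheet["ethnicity"].values[mask]
    m_sub = m.loc[:, mask]
    beta_sub = beta.loc[m.index, m.columns].loc[:, mask]

    F, p, eff = _ewas_pass(m_sub, beta_sub, status, eth)
    n_tests = int((~np.isnan(p)).sum())
    threshold = fwer_threshold(alpha, n_tests)

    info = manifest.set_index("probe_id").reindex(m.index)
    table = pd.DataFrame({
        "probe_id": m.index,
        "chr": info["chr"].values,
        "position": info["position"].values,
        "locus": info["locus"].values,
        "median_never": np.median(beta_sub.values[:, status == "never"], axis=1),
        "median_current": np.median(beta_sub.values[:, status == "current"], axis=1),
        "effect_size": eff,
        "F_statistic": F,
        "p_value": p,
    })
    table["na_flag"] = np.isnan(p)
    table["significant"] = table["p_value"] <= threshold

    # ranks by ascending p among significant CpGs
    table["rank"] = np.nan
    sig_idx = table.index[table["significant"]]
    order = table.loc[sig_idx].sort_values(["p_value", "probe_id"]).index
    table.loc[order, "rank"] = np.arange(1, len(order) + 1)

    # sentinels among significant CpGs
    table["sentinel"] = False
    if len(sig_idx):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sentinels = select_sentinels(table.loc[sig_idx], manifest)
        table.loc[table["probe_id"].isin(sentinels.values), "sentinel"] = True

    # sentinel-level follow-up analyses
    for col in ("interaction_F", "interaction_p", "ethnicity_F", "ethnicity_p",
                "never_smoker_t", "never_smoker_p"):
        table[col] = np.nan
    for e in np.unique(eth):
        table[f"F_{e}"] = np.nan
        table[f"p_{e}"] = np.nan
        table[f"effect_size_{e}"] = np.nan

    sent_rows = table.index[table["sentinel"]]
    for i in sent_rows:
        probe = table.at[i, "probe_id"]
        row = m_sub.loc[probe].values
        brow = beta_sub.loc[probe].values
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table.loc[i, ["interaction_F", "interaction_p"]] = interaction_test(
                row, status, eth)
        # main effect of ethnicity: partial F dropping ethnicity
        current = (status == "current").astype(float)
        X_full, _ = _design(status, eth)
        X_no_eth = np.column_stack([np.ones(len(current)), current])
        Fe, pe = _partial_f(row[:, None], X_full, X_no_eth)
        table.loc[i, ["ethnicity_F", "ethnicity_p"]] = Fe[0], pe[0]
        nev = status == "never"
        if len(np.unique(eth[nev])) == 2:
            table.loc[i, ["never_smoker_t", "never_smoker_p"]] = group_t_test(
                row[nev], eth[nev])
        for e in np.unique(eth):
            sel = eth == e
            if len(np.unique(status[sel])) < 2:
                continue
            Xf, Xr = _design(status[sel], eth[sel])
            Fs, ps = _partial_f(row[sel][:, None], Xf, Xr)
            table.at[i, f"F_{e}"] = Fs[0]
            table.at[i, f"p_{e}"] = ps[0]
            table.at[i, f"effect_size_{e}"] = effect_size(brow[sel], status[sel])

    adjusted = None
    if cell_proportions is not None:
        m_adj = adjust_for_composition(m, cell_proportions).loc[:, mask]
        beta_adj = m_to_beta(m_adj)
        Fa, pa, effa = _ewas_pass(m_adj, beta_adj, status, eth)
        adjusted = pd.DataFrame({
            "probe_id": m.index,
            "F_statistic": Fa,
            "p_value": pa,
            "effect_size": effa,
            "significant": pa <= threshold,
        })

    return EwasResult(table=table, threshold=threshold, n_tests=n_tests,
                      alpha=alpha, adjusted_table=adjusted)


def dose_regression(m_row, dose):
    """Unadjusted linear regression of sentinel M-values on a dose variable.

    Used for methylation vs cigarettes/day or pack-years in current
    smokers. Returns (slope, ci_low, ci_high, p_value); rows with missing
    dose are dropped.
    """
    import statsmodels.api as sm

    y = np.asarray(m_row, dtype=float)
    x = np.asarray(dose, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete observations")
    fit = sm.OLS(y[ok], sm.add_constant(x[ok])).fit()
    lo, hi = fit.conf_int()[1]
    return float(fit.params[1]), float(lo), float(hi), float(fit.pvalues[1])
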