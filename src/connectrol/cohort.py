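"""Cohort-level statistics for connectome metric tables.

Centre-piece operations:

* rank -> z normalisation of per-parcel metric ranks against the healthy
  control cohort (the control group itself has per-parcel mean z = 0 and
  sd = 1 by construction);
* covariate-adjusted group comparisons with a generalised linear model,
  reporting estimated marginal means, unadjusted pairwise (Fisher's LSD)
  contrasts and Cohen's d on the residual scale;
* node-level flagging of parcels whose group-mean |z| exceeds a threshold
  (default 3.1, treated as a given constant correcting for 253 parcel-wise
  comparisons);
* group mean-matrix differences stratified by anatomical edge class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import Connectome, Parcellation, SubjectRecord

METRICS = ("weighted_degree", "average_controllability", "modal_controllability")
RANK_COLS = {"weighted_degree": "wd_rank",
             "average_controllability": "ac_rank",
             "modal_controllability": "mc_rank"}
Z_COLS = {"weighted_degree": "wd_z",
          "average_controllability": "ac_z",
          "modal_controllability": "mc_z"}
DEFAULT_Z_THRESHOLD = 3.1
DEFAULT_LOW_WEIGHT_CUTOFF = 100.0


class MetricCorrelations(NamedTuple):
    wd_ac: float
    wd_mc: float
    ac_mc: float


def metric_correlations(node_table: pd.DataFrame) -> MetricCorrelations:
    """Pearson correlations between the within-subject rank columns.

    Equivalent to Spearman correlations of the raw metric values, hence
    invariant to any monotone transform of the metrics.
    """
    ranks = {m: node_table[RANK_COLS[m]].to_numpy() for m in METRICS}
    for m, r in ranks.items():
        if np.ptp(r) == 0:
            raise ValueError(f"undefined correlation: constant rank column {m}")
    corr = lambda a, b: float(np.corrcoef(a, b)[0, 1])
    return MetricCorrelations(
        wd_ac=corr(ranks["weighted_degree"], ranks["average_controllability"]),
        wd_mc=corr(ranks["weighted_degree"], ranks["modal_controllability"]),
        ac_mc=corr(ranks["average_controllability"],
                   ranks["modal_controllability"]),
    )


@dataclass
class ZScoreTable:
    """Per subject x parcel z-scores of metric ranks vs the control cohort."""

    data: pd.DataFrame  # columns: subject_id, parcel_id, wd_z, ac_z, mc_z
    control_ids: tuple[str, ...]
    control_mean: pd.DataFrame  # per-parcel mean rank over controls
    control_sd: pd.DataFrame    # per-parcel sd of ranks (ddof=1)

    def subject(self, subject_id: str) -> pd.DataFrame:
        sub = self.data[self.data["subject_id"] == subject_id]
        if sub.empty:
            raise KeyError(f"no z-scores for subject {subject_id!r}")
        return sub.sort_values("parcel_id").reset_index(drop=True)


def zscore_vs_controls(node_tables: dict[str, pd.DataFrame],
                       control_ids: Sequence[str]) -> ZScoreTable:
    """Normalise per-parcel metric ranks to the control mean and sd.

    z = (rank - control_mean_rank) / control_sd_rank per parcel and metric,
    with the sd taken over controls with ddof=1.
    """
    control_ids = list(control_ids)
    if len(control_ids) < 2:
        raise ValueError("need at least 2 controls to define rank z-scores")
    rank_stack = {sid: node_tables[sid][list(RANK_COLS.values())].to_numpy()
                  for sid in node_tables}
    ctrl = np.stack([rank_stack[sid] for sid in control_ids])
    mean = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    zero = np.argwhere(sd == 0)
    if zero.size:
        parcel, metric = zero[0]
        raise ValueError(
            f"zero control SD for parcel {parcel} "
            f"({list(RANK_COLS)[metric]}); z-score undefined")
    frames = []
    n = mean.shape[0]
    for sid, ranks in rank_stack.items():
        z = (ranks - mean) / sd
        frames.append(pd.DataFrame({
            "subject_id": sid, "parcel_id": np.arange(n),
            "wd_z": z[:, 0], "ac_z": z[:, 1], "mc_z": z[:, 2]}))
    data = pd.concat(frames, ignore_index=True)
    cols = list(RANK_COLS.values())
    return ZScoreTable(data, tuple(control_ids),
                       pd.DataFrame(mean, columns=cols),
                       pd.DataFrame(sd, columns=cols))


@dataclass
class ComparisonResult:
    response: str
    contrast: str                  # "groupA - groupB"
    emm: dict[str, float]          # estimated marginal mean per group
    mean_difference: float         # EMM difference on the response scale
    cohen_d: float
    p_unadjusted: float
    p_adjusted: float | None = None
    adjustment: str = "fisher_lsd"


def _reference_grid(design_info, data: pd.DataFrame, group_col: str,
                    group_level: str) -> np.ndarray:
    """Design row for one group with covariates at means / balanced levels."""
    import patsy
    grid = data.copy()
    grid[group_col] = group_level
    X = np.asarray(patsy.build_design_matrices([design_info], grid)[0])
    return X.mean(axis=0)


def glm_group_compare(table: pd.DataFrame, response: str,
                      covariates: Sequence[str] = ("age", "sex", "fsiq_class",
                                                   "mean_wd"),
                      family: str = "gaussian",
                      group_col: str = "group",
                      adjust: str | None = None) -> list[ComparisonResult]:
    """Covariate-adjusted pairwise group comparisons of one response.

    Fits ``response ~ group + covariates`` with a Gaussian (identity link)
    or gamma (log link) GLM, computes estimated marginal means on a
    reference grid (continuous covariates at their observed values averaged
    over the cohort, categorical covariates at observed composition), and
    reports all pairwise group contrasts with unadjusted Wald p-values
    (Fisher's LSD).  Cohen's d = |EMM difference| / residual-scale SD.

    ``adjust='bh'`` additionally fills BH-FDR adjusted p-values across the
    contrasts of this response.
    """
    data = table.dropna(subset=[response, group_col, *covariates]).copy()
    groups = list(dict.fromkeys(data[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    if family == "gamma":
        if (data[response] <= 0).any():
            raise ValueError("gamma family requires a strictly positive response")
        fam = sm.families.Gamma(link=sm.families.links.Log())
    elif family == "gaussian":
        fam = sm.families.Gaussian()
    else:
        raise ValueError(f"unknown family {family!r}")

    cat_covs = [c for c in covariates
                if data[c].dtype == object or str(data[c].dtype) == "category"]
    terms = [f"C({group_col})"]
    terms += [f"C({c})" if c in cat_covs else c for c in covariates]
    formula = f"{response} ~ " + " + ".join(terms)
    import statsmodels.formula.api as smf
    try:
        model = smf.glm(formula, data=data, family=fam)
        fit = model.fit()
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError(f"GLM fit failed (singular design?): {exc}") from exc
    if not np.isfinite(fit.params).all():
        raise ValueError("GLM fit failed: non-finite coefficients "
                         "(separation or singular design)")

    design_info = model.data.design_info
    rows = {g: _reference_grid(design_info, data, group_col, g) for g in groups}
    linkinv = fam.link.inverse
    emm = {g: float(linkinv(rows[g] @ fit.params)) for g in groups}
    resid_sd = float(np.std(data[response] - fit.fittedvalues, ddof=len(fit.params)))

    results = []
    cov = fit.cov_params().to_numpy()
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            L = rows[ga] - rows[gb]
            est = float(L @ fit.params)        # linear-predictor scale
            se = float(np.sqrt(L @ cov @ L))
            zstat = est / se if se > 0 else np.inf
            p = 2 * stats.norm.sf(abs(zstat))
            diff = emm[ga] - emm[gb]
            d = abs(diff) / resid_sd if resid_sd > 0 else np.inf
            results.append(ComparisonResult(
                response=response, contrast=f"{ga} - {gb}", emm=emm,
                mean_difference=diff, cohen_d=d, p_unadjusted=float(p)))
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests
        padj = multipletests([r.p_unadjusted for r in results],
                             method="fdr_bh")[1]
        for r, pa in zip(results, padj):
            r.p_adjusted = float(pa)
            r.adjustment = "bh_fdr"
    return results


def node_level_flags(Z: ZScoreTable, subject_ids: Iterable[str],
                     threshold: float = DEFAULT_Z_THRESHOLD
                     ) -> dict[str, dict[str, set[int]]]:
    """Parcels whose group-mean z crosses +/- threshold, per metric.

    Returns {metric: {"above": set, "below": set}} for the given subject
    group.
    """
    sub = Z.data[Z.data["subject_id"].isin(set(subject_ids))]
    mean_z = sub.groupby("parcel_id")[list(Z_COLS.values())].mean()
    flags: dict[str, dict[str, set[int]]] = {}
    for metric, col in Z_COLS.items():
        flags[metric] = {
            "above": set(mean_z.index[mean_z[col] > threshold]),
            "below": set(mean_z.index[mean_z[col] < -threshold]),
        }
    return flags


@dataclass
class EdgeDifferenceSummary:
    """Group mean-matrix difference with low-weight increase counts.

    ``counts`` are raw counts of increased entries below the cutoff per
    anatomical class; ``rates`` normalise by the number of pairs in each
    class, and ``majority_class`` is the class with the highest rate —
    "localised to" is judged by enrichment, not by class abundance.
    """

    difference: np.ndarray          # mean(groupB) - mean(groupA)
    cutoff: float
    counts: dict[str, int] = field(default_factory=dict)
    rates: dict[str, float] = field(default_factory=dict)

    @property
    def majority_class(self) -> str:
        return max(self.rates, key=self.rates.get)


def edge_class_masks(parcellation: Parcellation) -> dict[str, np.ndarray]:
    """Upper-triangle boolean masks for anatomical edge classes."""
    hemi = parcellation.hemisphere
    thal = parcellation.thalamic
    cort = parcellation.cortical
    same = (hemi[:, None] == hemi[None, :]) & (hemi[:, None] != "midline")
    tc = same & ((thal[:, None] & cort[None, :]) | (cort[:, None] & thal[None, :]))
    n = len(parcellation)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    return {
        "thalamocortical_ipsilateral": tc & upper,
        "other_ipsilateral": same & ~tc & upper,
        "contralateral": ~same & upper,
    }


def mean_matrix_difference(group_a: Sequence[Connectome],
                           group_b: Sequence[Connectome],
                           low_weight_cutoff: float = DEFAULT_LOW_WEIGHT_CUTOFF
                           ) -> EdgeDifferenceSummary:
    """Element-wise difference of group mean matrices (B - A) and counts of
    low-magnitude increases per anatomical edge class.

    An entry is counted when 0 < difference < cutoff, stratified into
    ipsilateral thalamocortical, other ipsilateral and contralateral (pairs
    involving midline parcels fall in the contralateral stratum).
    """
    parc = group_a[0].parcellation
    mean_a = np.mean([c.weights for c in group_a], axis=0)
    mean_b = np.mean([c.weights for c in group_b], axis=0)
    diff = mean_b - mean_a
    low_increase = (diff > 0) & (diff < low_weight_cutoff)
    masks = edge_class_masks(parc)
    counts = {k: int((low_increase & m).sum()) for k, m in masks.items()}
    rates = {k: counts[k] / max(int(m.sum()), 1) for k, m in masks.items()}
    return EdgeDifferenceSummary(diff, low_weight_cutoff, counts, rates)


def subset_sensitivity(table: pd.DataFrame, min_age: float,
                       age_col: str = "age") -> pd.DataFrame:
    """Restrict a cohort table to subjects strictly older than ``min_age``."""
    out = table[table[age_col] > min_age].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"empty subset: no subjects with {age_col} > {min_age}")
    return out


def build_cohort_table(records: Sequence[SubjectRecord],
                       node_tables: dict[str, pd.DataFrame],
                       graph_metrics: dict[str, "object"]) -> pd.DataFrame:
    """Assemble the per-subject cohort table used in group comparisons."""
    rows = []
    for r in records:
        t = node_tables[r.subject_id]
        corr = metric_correlations(t)
        g = graph_metrics[r.subject_id]
        rows.append({
            "subject_id": r.subject_id, "group": r.group, "age": r.age,
            "sex": r.sex, "fsiq_class": r.fsiq_class, "outcome": r.outcome,
            "mean_wd": t["weighted_degree"].mean(),
            "mean_ac": t["average_controllability"].mean(),
            "mean_mc": t["modal_controllability"].mean(),
            "wd_ac_corr": corr.wd_ac, "wd_mc_corr": corr.wd_mc,
            "ac_mc_corr": corr.ac_mc,
            "density": g.density, "modularity": g.modularity,
            "global_eff": g.global_efficiency,
            "diffusion_eff": g.diffusion_efficiency,
        })
    return pd.DataFrame(rows)
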