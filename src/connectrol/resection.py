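"""Resected-parcel statistics and virtual-resection null models.

The resected parcel set operationalises the putative epileptogenic zone.
Its control-referenced rank z-scores (weighted degree, average and modal
controllability) are summarised as set means and compared, per subject,
against (i) the whole-brain mean, (ii) the distribution over random
"virtual resections" of equally many cortical parcels, and (iii) a
node-deletion post-operative surrogate connectome.

The tractography-based expected post-operative connectome of the original
analysis requires imaging; here the surrogate simply removes the resected
rows/columns and re-references the reduced graph's metric ranks against
controls reduced by the same parcel set.  It is flagged ``surrogate=True``
in provenance metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .controllability import node_metrics
from .cohort import METRICS, Z_COLS, ZScoreTable
from .core import Connectome, Parcellation, SubjectRecord, validate_connectome

RESECTION_METRIC_COLS = list(Z_COLS.values())  # wd_z, ac_z, mc_z


def set_mean_z(Z: ZScoreTable, subject_id: str,
               parcel_set: set[int] | frozenset[int]) -> dict[str, float]:
    """Arithmetic mean z over a parcel set, per metric."""
    if not parcel_set:
        raise ValueError("empty parcel set")
    sub = Z.subject(subject_id)
    rows = sub[sub["parcel_id"].isin(parcel_set)]
    return {c: float(rows[c].mean()) for c in RESECTION_METRIC_COLS}


def virtual_resections(parcellation: Parcellation, k: int, n_virtual: int,
                       rng: np.random.Generator,
                       hemisphere: str | None = None) -> list[frozenset[int]]:
    """``n_virtual`` uniform random sets of ``k`` distinct cortical parcels.

    Sets may overlap the real resection and are not contiguity-constrained.
    ``hemisphere`` optionally restricts sampling to one hemisphere.
    """
    mask = parcellation.cortical.copy()
    if hemisphere is not None:
        mask &= parcellation.hemisphere == hemisphere
    candidates = np.nonzero(mask)[0]
    if k > candidates.size:
        raise ValueError(f"k={k} exceeds {candidates.size} cortical parcels")
    return [frozenset(rng.choice(candidates, size=k, replace=False).tolist())
            for _ in range(n_virtual)]


def resection_zscore(real_means: dict[str, float],
                     virtual_means: pd.DataFrame) -> dict[str, float]:
    """Standardise the real-set mean against virtual-set means (ddof=1)."""
    if len(virtual_means) < 2:
        raise ValueError("need at least 2 virtual sets")
    out = {}
    for c in RESECTION_METRIC_COLS:
        mu = virtual_means[c].mean()
        sd = virtual_means[c].std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero sd of virtual-set means for {c}")
        out[c] = float((real_means[c] - mu) / sd)
    return out


def postop_surrogate(C: Connectome,
                     resected: set[int] | frozenset[int]) -> Connectome:
    """Graph-level post-operative surrogate: delete resected rows/columns.

    Returns an (N-k)-parcel connectome on a renumbered parcellation;
    errors if the remaining graph is disconnected.
    """
    if not resected:
        return C.copy()
    keep = np.ones(C.n, dtype=bool)
    keep[list(resected)] = False
    W = C.weights[np.ix_(keep, keep)]
    out = Connectome(W, C.parcellation.subset(keep), C.subject_id,
                     {**C.meta, "surrogate": True,
                      "removed_parcels": sorted(resected)})
    report = validate_connectome(out)
    if not report.passed:
        raise ValueError(
            f"post-op surrogate invalid for {C.subject_id!r}: {report.failures}")
    return out


def _rank_z_reduced(patient: Connectome, controls: list[Connectome],
                    resected: frozenset[int], mode: str) -> dict[str, float]:
    """Mean rank-z of the reduced patient graph vs equally reduced controls."""
    pat = postop_surrogate(patient, resected)
    pat_ranks = node_metrics(pat, mode)[["wd_rank", "ac_rank", "mc_rank"]].to_numpy()
    ctrl = []
    for c in controls:
        red = postop_surrogate(c, resected)
        ctrl.append(node_metrics(red, mode)[["wd_rank", "ac_rank",
                                             "mc_rank"]].to_numpy())
    ctrl = np.stack(ctrl)
    mean = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    sd[sd == 0] = np.nan
    z = (pat_ranks - mean) / sd
    return dict(zip(RESECTION_METRIC_COLS, np.nanmean(z, axis=0)))


def build_resection_summary(records: list[SubjectRecord],
                            Z: ZScoreTable,
                            connectomes: dict[str, Connectome] | None = None,
                            control_connectomes: list[Connectome] | None = None,
                            n_virtual: int = 1000,
                            seed: int | None = None,
                            stabilization: str = "spectral") -> pd.DataFrame:
    """Per-subject resection z summary for the resective cohort.

    For each resective subject with a non-empty resected set: mean z over
    resected and non-resected parcels, whole-brain mean z, the
    virtual-resection z (real-set mean standardised against ``n_virtual``
    random cortical sets of the same size), and — when connectomes are
    supplied — the post-operative surrogate mean z.
    """
    rng = np.random.default_rng(seed)
    parc = None
    rows = []
    for r in records:
        if r.group != "resective" or not r.resected_parcels:
            continue
        sub = Z.subject(r.subject_id)
        if parc is None:
            n = len(sub)
        all_parcels = set(range(len(sub)))
        res = set(r.resected_parcels)
        nonres = all_parcels - res
        whole = {c: float(sub[c].mean()) for c in RESECTION_METRIC_COLS}
        res_mean = set_mean_z(Z, r.subject_id, res)
        nonres_mean = set_mean_z(Z, r.subject_id, nonres)
        if connectomes is not None:
            parcellation = connectomes[r.subject_id].parcellation
        else:
            parcellation = None
        row = {"subject_id": r.subject_id, "outcome": r.outcome,
               "n_resected": len(res)}
        row.update({f"resected_{c}": v for c, v in res_mean.items()})
        row.update({f"nonresected_{c}": v for c, v in nonres_mean.items()})
        row.update({f"whole_{c}": v for c, v in whole.items()})
        if parcellation is not None:
            vsets = virtual_resections(parcellation, len(res), n_virtual, rng)
            vmeans = pd.DataFrame([set_mean_z(Z, r.subject_id, s)
                                   for s in vsets])
            vz = resection_zscore(res_mean, vmeans)
            row.update({f"virtual_{c}": v for c, v in vz.items()})
        if connectomes is not None and control_connectomes:
            pz = _rank_z_reduced(connectomes[r.subject_id],
                                 control_connectomes,
                                 r.resected_parcels, stabilization)
            row.update({f"postop_{c}": v for c, v in pz.items()})
        rows.append(row)
    if not rows:
        raise ValueError("no resective subjects with resected parcels")
    return pd.DataFrame(rows)


def resection_group_tests(summary: pd.DataFrame,
                          min_stratum: int = 2,
                          histology: pd.Series | None = None) -> pd.DataFrame:
    """Outcome-stratified tests on the resection z summaries.

    Within each outcome stratum: paired t-tests of resected-set,
    non-resected-set and post-op-surrogate mean z against the whole-brain
    mean z, and one-sample t-tests of the virtual-resection z against 0;
    BH-FDR applied across the metric x contrast family within each stratum.
    Optionally a Kruskal-Wallis test of resected-set means across histology
    groups (unstratified).
    """
    rows = []
    for outcome, sub in summary.groupby("outcome"):
        if len(sub) < min_stratum:
            raise ValueError(
                f"stratum too small: outcome {outcome!r} has {len(sub)} "
                f"subjects (< {min_stratum})")
        for c in RESECTION_METRIC_COLS:
            for label, col in [("resected - whole", f"resected_{c}"),
                               ("nonresected - whole", f"nonresected_{c}"),
                               ("postop - whole", f"postop_{c}")]:
                if col not in sub.columns:
                    continue
                d = sub[col] - sub[f"whole_{c}"]
                if np.allclose(d, 0.0):  # degenerate: no difference at all
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_1samp(d, 0.0)
                rows.append({"outcome": outcome, "metric": c,
                             "contrast": label, "mean_diff": float(d.mean()),
                             "t": float(t), "p": float(p)})
            vcol = f"virtual_{c}"
            if vcol in sub.columns:
                t, p = stats.ttest_1samp(sub[vcol], 0.0)
                rows.append({"outcome": outcome, "metric": c,
                             "contrast": "virtual z vs 0",
                             "mean_diff": float(sub[vcol].mean()),
                             "t": float(t), "p": float(p)})
    tests = pd.DataFrame(rows)
    tests["q"] = np.nan
    for outcome, idx in tests.groupby("outcome").groups.items():
        tests.loc[idx, "q"] = multipletests(tests.loc[idx, "p"],
                                            method="fdr_bh")[1]
    if histology is not None:
        hrows = []
        joined = summary.join(histology.rename("histology"), on="subject_id")
        for c in RESECTION_METRIC_COLS:
            groups = [g[f"resected_{c}"].to_numpy()
                      for _, g in joined.groupby("histology")]
            if len(groups) >= 2:
                h, p = stats.kruskal(*groups)
                hrows.append({"outcome": "all", "metric": c,
                              "contrast": "histology kruskal-wallis",
                              "mean_diff": np.nan, "t": float(h),
                              "p": float(p), "q": np.nan})
        tests = pd.concat([tests, pd.DataFrame(hrows)], ignore_index=True)
    return tests
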