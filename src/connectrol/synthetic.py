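"""Synthetic parcellations, connectomes and labelled cohorts.

Stands in for the clinical dataset so every pipeline stage is testable
offline.  The generator emulates the study's data *structure*, not its
exact metric distributions:

* a 253-parcel layout (219 cortical, 30 subcortical including 7 thalamic
  nuclei per hemisphere, 4 midline brainstem parcels), with tags for
  thalamic nuclei and posterior/isthmus cingulate parcels;
* connectomes from a stochastic block model (hemisphere and within-lobe
  blocks, an elevated ipsilateral thalamocortical block) calibrated to a
  target density of 0.63 for controls.  Cortico-cortical edge weights are
  heavy-tailed Weibull(scale 0.717, shape 0.325) draws scaled to a
  configurable streamline range (the raw draw is capped so single freak
  edges do not dominate the spectrum) and modulated by per-node log-normal
  hub factors, so hubness lives in the weighted (not binary) degree;
  ipsilateral thalamocortical edges instead carry many moderate,
  low-variance log-normal weights, mirroring the numerous thin
  thalamocortical projections and letting the coherent thalamic eigenmode
  sit near the top of the spectrum;
* "patient" groups receive a fixed-size positive boost of ipsilateral
  thalamocortical edge weights plus random edge additions up to density
  0.71;
* seizure-free resective subjects carry a planted resection zone of 3-24
  cortical parcels (median 12) whose incident edge weights are deflated,
  giving the zone low weighted degree and, consequently, elevated modal
  controllability;
* demographics reproduce the cohort imbalance direction (patients younger,
  lower FSIQ classes) so covariate adjustment is exercised.

Every generated cohort passes ``validate_connectome`` and a fixed master
seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import Connectome, ParcelInfo, Parcellation, SubjectRecord, \
    write_connectome, write_manifest
from .simulate import add_random_edges, boost_edges, edge_pool

THALAMIC_NUCLEI = ("anterior", "medio-dorsal", "pulvinar",
                   "central-lateral_lateral-posterior_medial-pulvinar",
                   "ventral-latero-dorsal", "ventral-latero-ventral",
                   "ventral-anterior")
SUBCORTICAL_STRUCTURES = ("caudate", "putamen", "pallidum", "accumbens",
                          "hippocampus", "amygdala", "hypothalamus",
                          "ventral-dc")
BRAINSTEM_STRUCTURES = ("midbrain", "pons", "medulla",
                        "superior-cerebellar-peduncle")
FSIQ_CLASSES = ("low", "borderline", "average", "high")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults define the study layout."""

    n_parcels: int = 253
    # block model
    target_density_controls: float = 0.63
    target_density_patients: float = 0.71
    weibull_scale: float = 0.717
    weibull_shape: float = 0.325
    weight_scale: float = 15.0
    weibull_clip: float = 80.0
    hub_sigma: float = 0.4
    hub_jitter: float = 0.2
    edge_jitter: float = 0.35
    anatomy_seed: int = 20180313
    tc_weight_mean: float = 90.0
    tc_weight_sigma: float = 0.3
    nucleus_sigma: float = 0.3   # anatomical size spread across thalamic nuclei
    thalamic_nontc_factor: float = 0.2
    # ipsilateral subcortico-subcortical (incl. thalamo-thalamic) edges:
    # moderate uniform weights bind the deep grey structures into their own
    # community so thalamocortical edges are between-module
    subcortical_weight_mean: float = 250.0
    subcortical_weight_sigma: float = 0.3
    subcortical_block: float = 3.0
    within_hemisphere: float = 1.15
    between_hemisphere: float = 0.7
    n_lobes: int = 5
    within_lobe: float = 1.6
    within_lobe_weight: float = 3.0
    thalamocortical_block: float = 3.0
    max_edge_probability: float = 0.995
    # patient (epilepsy) effect
    boost_n_edges: int = 1440
    boost_edge_fraction: float = 0.045
    boost_mean: float = 50.0
    boost_sd: float = 15.0
    # subject-level severity of the thalamocortical effect (log-normal
    # multiplier on the boost weights): epilepsy severity varies widely
    severity_sigma: float = 0.5
    # resection effect (seizure-free resective subjects only)
    resection_size_mean: float = 12.0
    resection_size_sd: float = 4.5
    resection_size_min: int = 3
    resection_size_max: int = 24
    resection_deflation: float = 0.45
    # demographics
    n_controls: int = 16
    n_resective: int = 52
    n_vns: int = 27
    n_seizure_free: int = 33
    n_vns_responders: int = 11
    control_age_range: tuple[float, float] = (12.0, 19.0)
    patient_age_range: tuple[float, float] = (3.0, 18.0)
    fsiq_probs_controls: tuple[float, ...] = (0.05, 0.15, 0.55, 0.25)
    fsiq_probs_patients: tuple[float, ...] = (0.30, 0.30, 0.30, 0.10)


@dataclass
class GroundTruth:
    """Per-subject planted effects, sufficient to verify detection claims."""

    boosted_edges: dict[str, np.ndarray] = field(default_factory=dict)
    resection_sets: dict[str, frozenset[int]] = field(default_factory=dict)
    deflation: dict[str, float] = field(default_factory=dict)


def make_parcellation(n_parcels: int = 253) -> Parcellation:
    """Anatomical label table with the study's class layout.

    For ``n_parcels=253`` the exact counts are 219 cortical (110 left,
    109 right), 30 subcortical (7 thalamic + 8 other per hemisphere) and
    4 midline brainstem parcels.  Other sizes scale the layout
    proportionally, keeping at least one thalamic parcel per hemisphere.
    """
    if n_parcels == 253:
        n_thal, n_sub, n_stem = 7, 8, 4
    else:
        n_thal = max(1, round(n_parcels * 7 / 253))
        n_sub = max(1, round(n_parcels * 8 / 253))
        n_stem = max(1, round(n_parcels * 4 / 253))
    n_cort = n_parcels - 2 * (n_thal + n_sub) - n_stem
    if n_cort < 4:
        raise ValueError(f"n_parcels={n_parcels} too small for the layout")
    n_cort_left = (n_cort + 1) // 2
    parcels: list[ParcelInfo] = []
    i = 0
    for hemi, n_c in (("left", n_cort_left), ("right", n_cort - n_cort_left)):
        for c in range(n_c):
            tags = set()
            if c == 0:
                tags.add("posterior_cingulate")
            elif c == 1:
                tags.add("isthmus_cingulate")
            parcels.append(ParcelInfo(i, f"ctx-{hemi[0]}h-{c:03d}", hemi,
                                      "cortical", frozenset(tags)))
            i += 1
    for hemi in ("left", "right"):
        for t in range(n_thal):
            name = THALAMIC_NUCLEI[t % len(THALAMIC_NUCLEI)]
            parcels.append(ParcelInfo(i, f"thal-{hemi[0]}h-{name}", hemi,
                                      "thalamic", frozenset({name})))
            i += 1
        for s in range(n_sub):
            name = SUBCORTICAL_STRUCTURES[s % len(SUBCORTICAL_STRUCTURES)]
            parcels.append(ParcelInfo(i, f"sub-{hemi[0]}h-{name}", hemi,
                                      "subcortical", frozenset()))
            i += 1
    for s in range(n_stem):
        name = BRAINSTEM_STRUCTURES[s % len(BRAINSTEM_STRUCTURES)]
        parcels.append(ParcelInfo(i, f"bstem-{name}", "midline", "brainstem",
                                  frozenset()))
        i += 1
    # ids were appended hemisphere-blockwise for cortex; rebuild contiguous ids
    return Parcellation([ParcelInfo(j, p.label, p.hemisphere, p.klass, p.tags)
                         for j, p in enumerate(parcels)])


def _tc_mask(parc: Parcellation) -> np.ndarray:
    hemi = parc.hemisphere
    same = (hemi[:, None] == hemi[None, :]) & (hemi[:, None] != "midline")
    thal, cort = parc.thalamic, parc.cortical
    return same & ((thal[:, None] & cort[None, :])
                   | (cort[:, None] & thal[None, :]))


def _subcortical_mask(parc: Parcellation) -> np.ndarray:
    """Ipsilateral pairs within the deep grey (thalamic + subcortical) set."""
    hemi = parc.hemisphere
    same = (hemi[:, None] == hemi[None, :]) & (hemi[:, None] != "midline")
    deep = parc.thalamic | (parc.klass == "subcortical")
    return same & deep[:, None] & deep[None, :]


def _edge_probabilities(parc: Parcellation, cfg: GeneratorConfig,
                        target_density: float) -> np.ndarray:
    """Upper-triangle edge probabilities of the block model.

    Connection probabilities carry only the block structure (hemisphere,
    lobe, thalamocortical); per-node heterogeneity lives in the weights.
    """
    n = len(parc)
    hemi = parc.hemisphere
    same = (hemi[:, None] == hemi[None, :]) & (hemi[:, None] != "midline")
    blk = np.where(same, cfg.within_hemisphere, cfg.between_hemisphere)
    mid = (hemi[:, None] == "midline") | (hemi[None, :] == "midline")
    blk[mid] = 1.0
    # within-lobe blocks: contiguous chunks of cortical parcels per hemisphere
    lobe = _lobe_labels(parc, cfg.n_lobes)
    same_lobe = (lobe[:, None] == lobe[None, :]) & (lobe[:, None] >= 0)
    blk[same_lobe] *= cfg.within_lobe
    blk[_tc_mask(parc)] *= cfg.thalamocortical_block
    blk[_subcortical_mask(parc)] *= cfg.subcortical_block
    iu = np.triu_indices(n, k=1)
    return _calibrate(blk[iu], target_density, cfg.max_edge_probability)


def _lobe_labels(parc: Parcellation, n_lobes: int) -> np.ndarray:
    lobe = np.full(len(parc), -1)
    for h_i, h in enumerate(("left", "right")):
        idx = np.nonzero(parc.cortical & (parc.hemisphere == h))[0]
        for li, chunk in enumerate(np.array_split(idx, n_lobes)):
            lobe[chunk] = h_i * n_lobes + li
    return lobe


def _calibrate(m: np.ndarray, target_density: float,
               pmax: float) -> np.ndarray:
    """Scale relative rates ``m`` so mean clipped probability hits the target."""
    lo, hi = 0.0, 1e6
    for _ in range(80):
        s = (lo + hi) / 2
        if np.clip(s * m, 0, pmax).mean() < target_density:
            lo = s
        else:
            hi = s
    return np.clip(s * m, 0, pmax)


def _ensure_connected(W: np.ndarray, rng: np.random.Generator,
                      typical_weight: float) -> None:
    """Join stray components to the largest one with typical-weight edges."""
    while True:
        n_comp, labels = connected_components(csr_matrix(W != 0),
                                              directed=False)
        if n_comp == 1:
            return
        sizes = np.bincount(labels)
        main = np.argmax(sizes)
        stray = np.nonzero(labels != main)[0]
        i = rng.choice(stray)
        j = rng.choice(np.nonzero(labels == main)[0])
        W[i, j] = W[j, i] = typical_weight


def simulate_connectome(cfg: GeneratorConfig, group: str,
                        rng: np.random.Generator,
                        parcellation: Parcellation | None = None,
                        subject_id: str = ""
                        ) -> tuple[Connectome, dict]:
    """One synthetic connectome; patient groups get the planted effects.

    Returns the connectome and a dict of planted ground truth (boosted
    thalamocortical edge indices, if any).
    """
    parc = parcellation or make_parcellation(cfg.n_parcels)
    n = len(parc)
    p = _edge_probabilities(parc, cfg, cfg.target_density_controls)
    iu = np.triu_indices(n, k=1)
    present = rng.random(p.size) < p
    # anatomy (per-parcel hub propensity and per-pair base weight) is shared
    # across subjects, emulating the strong cross-subject consistency of
    # white-matter bundles; per-subject log-normal jitter models individual
    # variability.  Edge presence is drawn per subject.
    anatomy = np.random.default_rng(cfg.anatomy_seed)
    theta_bar = anatomy.lognormal(0.0, cfg.hub_sigma, n)
    base_raw = np.minimum(anatomy.weibull(cfg.weibull_shape, p.size),
                          cfg.weibull_clip)
    tc_base = anatomy.lognormal(np.log(cfg.tc_weight_mean),
                                cfg.tc_weight_sigma, p.size)
    # thalamic nuclei differ in size, hence in the calibre of their cortical
    # projections; the per-nucleus factor is anatomical (shared)
    nucleus_factor = np.ones(n)
    thal_idx = np.nonzero(parc.thalamic)[0]
    nucleus_factor[thal_idx] = anatomy.lognormal(0.0, cfg.nucleus_sigma,
                                                 thal_idx.size)
    tc_base *= np.outer(nucleus_factor, nucleus_factor)[iu]
    theta = theta_bar * rng.lognormal(0.0, cfg.hub_jitter, n)
    # thalamic weight is carried almost entirely by the thalamocortical
    # projections (set below); other thalamic edges are kept thin so the
    # nuclei have a consistent, boost-sensitive weighted degree
    theta[parc.thalamic] *= cfg.thalamic_nontc_factor
    w = np.maximum(base_raw * cfg.weibull_scale * cfg.weight_scale, 1e-6)
    w *= np.outer(theta, theta)[iu]
    if cfg.within_lobe_weight != 1.0:
        lobe = _lobe_labels(parc, cfg.n_lobes)
        same_lobe = (lobe[:, None] == lobe[None, :]) & (lobe[:, None] >= 0)
        w[same_lobe[iu]] *= cfg.within_lobe_weight
    tc_edges = _tc_mask(parc)[iu]
    w[tc_edges] = tc_base[tc_edges]
    deep_edges = _subcortical_mask(parc)[iu]
    w[deep_edges] = anatomy.lognormal(np.log(cfg.subcortical_weight_mean),
                                      cfg.subcortical_weight_sigma,
                                      int(deep_edges.sum()))
    w *= rng.lognormal(0.0, cfg.edge_jitter, p.size)
    w[~present] = 0.0
    W = np.zeros((n, n))
    W[iu] = w
    W = W + W.T
    median_w = float(np.median(w[present])) if present.any() else 1.0
    _ensure_connected(W, rng, median_w)
    C = Connectome(W, parc, subject_id)
    # guarantee the thalamocortical pool can absorb the boost
    n_boost = _operative_boost_edges(cfg, C)
    _top_up_tc_pool(C, n_boost, cfg, rng)
    planted: dict = {}
    if group != "control":
        pool = edge_pool(C, "thalamocortical_ipsilateral")
        # mean-one log-normal: the cohort-average effect stays at boost_mean
        severity = float(rng.lognormal(-cfg.severity_sigma**2 / 2,
                                       cfg.severity_sigma))
        C = boost_edges(C, pool, n_boost, rng,
                        cfg.boost_mean * severity, cfg.boost_sd * severity)
        planted["boosted_pool"] = pool
        planted["severity"] = severity
        C = add_random_edges(C, cfg.target_density_patients, rng,
                             cfg.weibull_scale, cfg.weibull_shape,
                             cfg.weight_scale, cfg.weibull_clip)
        C.subject_id = subject_id
    return C, planted


def _operative_boost_edges(cfg: GeneratorConfig, C: Connectome) -> int:
    if C.n == 253:
        return cfg.boost_n_edges
    iu = np.triu_indices(C.n, k=1)
    n_existing = int((C.weights[iu] > 0).sum())
    return min(cfg.boost_n_edges, int(cfg.boost_edge_fraction * n_existing))


def _top_up_tc_pool(C: Connectome, n_required: int, cfg: GeneratorConfig,
                    rng: np.random.Generator) -> None:
    """Add absent thalamocortical edges until the pool holds n_required."""
    tc = _tc_mask(C.parcellation)
    tc &= np.triu(np.ones_like(tc), k=1).astype(bool)
    i, j = np.nonzero(tc)
    existing = C.weights[i, j] > 0
    deficit = n_required - int(existing.sum())
    if deficit <= 0:
        return
    absent = np.nonzero(~existing)[0]
    if deficit > absent.size:
        raise ValueError("thalamocortical pair space too small for boost size")
    pick = rng.choice(absent, size=deficit, replace=False)
    w = rng.lognormal(np.log(cfg.tc_weight_mean), cfg.tc_weight_sigma, deficit)
    C.weights[i[pick], j[pick]] = w
    C.weights[j[pick], i[pick]] = w


def _draw_resection(cfg: GeneratorConfig, parc: Parcellation,
                    rng: np.random.Generator) -> frozenset[int]:
    """Random within-hemisphere cortical parcel set, size ~N(12, 4.5) in 3..24."""
    k = int(np.clip(round(rng.normal(cfg.resection_size_mean,
                                     cfg.resection_size_sd)),
                    cfg.resection_size_min, cfg.resection_size_max))
    hemi = "left" if rng.random() < 0.5 else "right"
    candidates = np.nonzero(parc.cortical & (parc.hemisphere == hemi))[0]
    k = min(k, candidates.size)
    return frozenset(rng.choice(candidates, size=k, replace=False).tolist())


def _apply_resection_effect(C: Connectome, rset: frozenset[int],
                            factor: float) -> None:
    """Deflate all edges incident to the planted epileptogenic zone."""
    idx = list(rset)
    C.weights[idx, :] *= factor
    C.weights[:, idx] *= factor


def simulate_cohort(cfg: GeneratorConfig | None = None,
                    seed: int | None = None,
                    out_dir: str | Path | None = None
                    ) -> tuple[list[SubjectRecord], dict[str, Connectome],
                               GroundTruth]:
    """Full labelled cohort: manifest records, connectomes and ground truth.

    Group sizes default to 16 controls / 52 resective / 27 VNS.  Seizure
    -free resective subjects get a planted low-degree resection zone; other
    resective subjects get a random resected set with no planted effect.
    When ``out_dir`` is given, matrices, manifest, parcellation and truth
    are written to disk.
    """
    cfg = cfg or GeneratorConfig()
    parc = make_parcellation(cfg.n_parcels)
    ss = np.random.SeedSequence(seed)
    specs: list[tuple[str, str, str]] = []
    for i in range(cfg.n_controls):
        specs.append((f"con{i:03d}", "control", "none"))
    for i in range(cfg.n_resective):
        outcome = ("seizure_free" if i < cfg.n_seizure_free
                   else "not_seizure_free")
        specs.append((f"res{i:03d}", "resective", outcome))
    for i in range(cfg.n_vns):
        outcome = "responder" if i < cfg.n_vns_responders else "non_responder"
        specs.append((f"vns{i:03d}", "vns", outcome))

    records: list[SubjectRecord] = []
    connectomes: dict[str, Connectome] = {}
    truth = GroundTruth()
    for (sid, group, outcome), child in zip(specs, ss.spawn(len(specs))):
        rng = np.random.default_rng(child)
        C, planted = simulate_connectome(cfg, group, rng, parc, sid)
        resected: frozenset[int] = frozenset()
        if group == "resective":
            resected = _draw_resection(cfg, parc, rng)
            if outcome == "seizure_free":
                _apply_resection_effect(C, resected, cfg.resection_deflation)
                truth.resection_sets[sid] = resected
                truth.deflation[sid] = cfg.resection_deflation
        if "boosted_pool" in planted:
            truth.boosted_edges[sid] = np.vstack(planted["boosted_pool"])
        lo, hi = (cfg.control_age_range if group == "control"
                  else cfg.patient_age_range)
        age = round(float(rng.uniform(lo, hi)), 1)
        sex = "M" if rng.random() < 0.5 else "F"
        probs = (cfg.fsiq_probs_controls if group == "control"
                 else cfg.fsiq_probs_patients)
        fsiq = FSIQ_CLASSES[rng.choice(len(FSIQ_CLASSES), p=probs)]
        path = f"matrices/{sid}.csv" if out_dir else ""
        records.append(SubjectRecord(sid, group, age, sex, fsiq, outcome,
                                     resected, path))
        connectomes[sid] = C

    if out_dir is not None:
        out = Path(out_dir)
        (out / "matrices").mkdir(parents=True, exist_ok=True)
        parc.to_tsv(out / "parcellation.tsv")
        write_manifest(records, out / "manifest.csv")
        for sid, C in connectomes.items():
            write_connectome(C, out / "matrices" / f"{sid}.csv")
        _write_truth(truth, out / "truth.json")
    return records, connectomes, truth


def _write_truth(truth: GroundTruth, path: Path) -> None:
    import json
    payload = {
        "boosted_edges": {k: v.tolist() for k, v in truth.boosted_edges.items()},
        "resection_sets": {k: sorted(v) for k, v in truth.resection_sets.items()},
        "deflation": truth.deflation,
    }
    path.write_text(json.dumps(payload))
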