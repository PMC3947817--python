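"""FAR/FRR/EER evaluation, score fusion and the end-to-end pipeline.

Scores are dissimilarities (lower = better match).  Sweeping a decision
threshold tau over the observed scores gives the false acceptance rate
FAR(tau) = #{impostor <= tau} / #impostor and the false rejection rate
FRR(tau) = #{genuine > tau} / #genuine; the equal error rate (EER) is the
value where the two curves cross, found by linear interpolation between
the bracketing thresholds and reported in percent.

The two feature channels (WLPP and LBPV_LPP) produce one distance matrix
each; after min-max normalization they are fused as
w * d1 + (1 - w) * d2 and the weight grid w in {0, step, ..., 1} is
searched exhaustively for the smallest EER.  Because the endpoints are in
the grid, the fused EER never exceeds either single-channel EER.

:func:`run_pipeline` chains everything — enhancement, both feature
channels, LPP, per-metric distance matrices, fusion — and also runs the
structural ablations (no enhancement, no LPP, single channels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from veinverify.synthgen import LabelledDataset, GrayImage
from veinverify.enhance import MatchedFilterParams, enhance
from veinverify.features_wavelet import (WaveletSpec, wavelet_approx, znorm_fit, znorm_apply,
                                         build_wlpp_raw, fit_wlpp_stats)
from veinverify.features_lbpv import LBPParams, lbpv_sources, fit_lbpv_stats, SOURCE_ORDER
from veinverify import lpp as lpp_mod
from veinverify.lpp import LPPConfig
from veinverify.matching import DistanceMatrix, distance_matrix, nn_identify, METRICS

__all__ = ["EvalResult", "FusionResult", "PipelineConfig", "far_frr",
           "minmax_normalize", "fuse_and_search", "run_pipeline", "EXPERIMENTS"]

EXPERIMENTS = ("full", "no_enhancement", "no_lpp", "wlpp_only", "lbpv_only")


@dataclass
class EvalResult:
    """FAR/FRR sweep over thresholds plus the interpolated EER (percent)."""

    thresholds: np.ndarray
    far: np.ndarray
    frr: np.ndarray
    eer: float                      # percent
    eer_threshold: float

    @property
    def roc(self) -> np.ndarray:
        """(FAR, 1 - FRR) pairs, one row per threshold."""
        return np.stack([self.far, 1.0 - self.frr], axis=1)


def far_frr(genuine: np.ndarray, impostor: np.ndarray) -> EvalResult:
    """FAR/FRR curves and EER for genuine and impostor score lists.

    Thresholds sweep the union of observed scores; the EER is linearly
    interpolated at the FAR - FRR sign change (before the first observed
    score FAR = 0 and FRR = 1).
    """
    genuine = np.asarray(genuine, dtype=float).ravel()
    impostor = np.asarray(impostor, dtype=float).ravel()
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("genuine and impostor score lists must be nonempty")

    thresholds = np.unique(np.concatenate([genuine, impostor]))
    gs = np.sort(genuine)
    isort = np.sort(impostor)
    far = np.searchsorted(isort, thresholds, side="right") / impostor.size
    frr = 1.0 - np.searchsorted(gs, thresholds, side="right") / genuine.size

    diff = far - frr                          # nondecreasing in tau
    i = int(np.argmax(diff >= 0))
    if diff[i] == 0:
        eer, thr = far[i], thresholds[i]
    else:
        if i > 0:
            far_p, frr_p, thr_p = far[i - 1], frr[i - 1], thresholds[i - 1]
        else:                                 # virtual point below all scores
            far_p, frr_p, thr_p = 0.0, 1.0, thresholds[0]
        denom = (far[i] - far_p) + (frr_p - frr[i])
        alpha = (frr_p - far_p) / denom if denom > 0 else 0.5
        eer = far_p + alpha * (far[i] - far_p)
        thr = thr_p + alpha * (thresholds[i] - thr_p)
    return EvalResult(thresholds=thresholds, far=far, frr=frr,
                      eer=100.0 * float(eer), eer_threshold=float(thr))


def minmax_normalize(d: DistanceMatrix) -> DistanceMatrix:
    """Map all entries to [0, 1] by a global min-max; monotone, so any
    single-channel EER is unchanged.  A constant matrix maps to zeros."""
    v = d.values
    lo, hi = v.min(), v.max()
    if hi > lo:
        values = (v - lo) / (hi - lo)
    else:
        warnings.warn("constant distance matrix; normalized to all zeros")
        values = np.zeros_like(v)
    return replace(d, values=values)


@dataclass
class FusionResult:
    """Best weighted-sum fusion of two normalized distance matrices."""

    weight: float                   # weight of channel 1; channel 2 gets 1 - w
    fused: DistanceMatrix
    result: EvalResult
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))
    eers: np.ndarray = field(default_factory=lambda: np.empty(0))


def fuse_and_search(d1: DistanceMatrix, d2: DistanceMatrix, step: float = 0.01,
                    per_claim_min: bool = False) -> FusionResult:
    """Exhaustive weight search minimizing the fused EER.

    Both matrices are min-max normalized first (their raw scales differ
    between metrics and channels, so the weight would otherwise be
    meaningless).  Ties go to the smallest weight.
    """
    if d1.values.shape != d2.values.shape:
        raise ValueError("distance matrices have different shapes")
    if not np.array_equal(d1.genuine_mask, d2.genuine_mask):
        raise ValueError("distance matrices have inconsistent genuine masks")
    n1, n2 = minmax_normalize(d1), minmax_normalize(d2)
    g1 = n1.genuine_scores(per_claim_min)
    i1 = n1.impostor_scores(per_claim_min)
    g2 = n2.genuine_scores(per_claim_min)
    i2 = n2.impostor_scores(per_claim_min)

    weights = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    eers = np.array([far_frr(w * g1 + (1 - w) * g2, w * i1 + (1 - w) * i2).eer
                     for w in weights])
    best = int(np.argmin(eers))               # first minimum = smallest weight
    w = float(weights[best])
    fused = replace(n1, values=w * n1.values + (1 - w) * n2.values, metric="fused")
    res = far_frr(fused.genuine_scores(per_claim_min), fused.impostor_scores(per_claim_min))
    return FusionResult(weight=w, fused=fused, result=res, weights=weights, eers=eers)


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the verification pipeline needs beyond the dataset."""

    filter_params: MatchedFilterParams = MatchedFilterParams()
    wavelet_spec: WaveletSpec = WaveletSpec()
    lbp_params: LBPParams = LBPParams()
    lpp_wlpp: LPPConfig = LPPConfig()
    lpp_lbpv: LPPConfig = LPPConfig()
    metrics: tuple[str, ...] = METRICS
    fusion_step: float = 0.01
    per_claim_min: bool = False
    experiments: tuple[str, ...] = EXPERIMENTS

    def __post_init__(self) -> None:
        for e in self.experiments:
            if e not in EXPERIMENTS:
                raise ValueError(f"unknown experiment {e!r}; choose from {EXPERIMENTS}")
        for m in self.metrics:
            if m not in METRICS:
                raise ValueError(f"unknown metric {m!r}")


def _raw_channels(images: list[GrayImage], enroll_idx: np.ndarray,
                  cfg: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    """Raw WLPP and LBPV feature matrices for a list of base images.

    Z-normalization statistics come from the enrollment rows only so the
    test split never leaks into the normalization.
    """
    spec, lbp = cfg.wavelet_spec, cfg.lbp_params
    lls = [{w: wavelet_approx(im, spec, w) for w in spec.wavelets} for im in images]

    w_stats = fit_wlpp_stats([images[i] for i in enroll_idx], spec)
    wlpp = np.stack([build_wlpp_raw(im, spec, w_stats) for im in images])

    src_rows = [lbpv_sources(im, ll["db2"], ll["sym2"], lbp) for im, ll in zip(images, lls)]
    l_stats = fit_lbpv_stats([src_rows[i] for i in enroll_idx])
    lbpv = np.stack([
        np.concatenate([znorm_apply(row[name], l_stats[name]) for name in SOURCE_ORDER])
        for row in src_rows
    ])
    return wlpp, lbpv


def _embed(raw: np.ndarray, enroll_idx: np.ndarray, lpp_cfg: LPPConfig) -> np.ndarray:
    model = lpp_mod.fit(raw[enroll_idx], lpp_cfg)
    return model.transform(raw)


def _channel_result(feats: np.ndarray, enroll_idx: np.ndarray, test_idx: np.ndarray,
                    subjects: np.ndarray, samples: np.ndarray, metric: str,
                    per_claim_min: bool) -> tuple[DistanceMatrix, EvalResult]:
    d = distance_matrix(feats[test_idx], feats[enroll_idx], metric,
                        subjects[test_idx], subjects[enroll_idx],
                        samples[test_idx], samples[enroll_idx])
    res = far_frr(d.genuine_scores(per_claim_min), d.impostor_scores(per_claim_min))
    return d, res


def run_pipeline(dataset: LabelledDataset, config: PipelineConfig = PipelineConfig()) -> dict:
    """Run the verification pipeline and its ablations on a labelled dataset.

    Returns a JSON-serializable report: per experiment and per distance
    metric, the channel EERs, the fused EER and the optimal fusion weight
    (all in percent / [0, 1]); plus rank-1 identification accuracy for the
    full pipeline under the Euclidean metric.
    """
    if not dataset.split or "enroll" not in dataset.split or "test" not in dataset.split:
        raise ValueError("dataset needs a nonempty enroll/test split")
    split = np.asarray(dataset.split)
    enroll_idx = np.flatnonzero(split == "enroll")
    test_idx = np.flatnonzero(split == "test")
    subjects = dataset.subject_ids
    samples = np.array([im.sample_index for im in dataset.images])

    needs_enhanced = any(e != "no_enhancement" for e in config.experiments)
    needs_raw_base = "no_enhancement" in config.experiments
    enhanced = ([enhance(im, config.filter_params) for im in dataset.images]
                if needs_enhanced else None)

    # feature caches keyed by base ("enhanced" | "original") and stage
    raw_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    emb_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def raw_feats(base: str) -> tuple[np.ndarray, np.ndarray]:
        if base not in raw_cache:
            imgs = enhanced if base == "enhanced" else dataset.images
            raw_cache[base] = _raw_channels(imgs, enroll_idx, config)
        return raw_cache[base]

    def embedded(base: str) -> tuple[np.ndarray, np.ndarray]:
        if base not in emb_cache:
            wlpp_raw, lbpv_raw = raw_feats(base)
            emb_cache[base] = (_embed(wlpp_raw, enroll_idx, config.lpp_wlpp),
                              _embed(lbpv_raw, enroll_idx, config.lpp_lbpv))
        return emb_cache[base]

    report: dict = {
        "n_subjects": int(len(np.unique(subjects))),
        "n_enroll": int(enroll_idx.size),
        "n_test": int(test_idx.size),
        "experiments": {},
    }

    def eval_pair(wlpp_f: np.ndarray | None, lbpv_f: np.ndarray | None) -> dict:
        per_metric: dict = {}
        for metric in config.metrics:
            row: dict = {}
            dms = []
            for name, feats in (("wlpp", wlpp_f), ("lbpv_lpp", lbpv_f)):
                if feats is None:
                    continue
                d, res = _channel_result(feats, enroll_idx, test_idx, subjects, samples,
                                         metric, config.per_claim_min)
                row[f"{name}_eer"] = res.eer
                dms.append(d)
            if len(dms) == 2:
                fr = fuse_and_search(dms[0], dms[1], config.fusion_step, config.per_claim_min)
                row["fused_eer"] = fr.result.eer
                row["fusion_weight"] = fr.weight
            per_metric[metric] = row
        return per_metric

    for exp in config.experiments:
        if exp == "full":
            w, l = embedded("enhanced")
            per_metric = eval_pair(w, l)
        elif exp == "no_enhancement":
            w, l = embedded("original")
            per_metric = eval_pair(w, l)
        elif exp == "no_lpp":
            w, l = raw_feats("enhanced")
            per_metric = eval_pair(w, l)
        elif exp == "wlpp_only":
            per_metric = eval_pair(embedded("enhanced")[0], None)
        else:  # lbpv_only
            per_metric = eval_pair(None, embedded("enhanced")[1])
        key = "fused_eer" if any("fused_eer" in r for r in per_metric.values()) else \
              ("wlpp_eer" if exp == "wlpp_only" else "lbpv_lpp_eer")
        best_metric = min(per_metric, key=lambda m: per_metric[m][key])
        report["experiments"][exp] = {
            "per_metric": per_metric,
            "best": {"metric": best_metric, "eer": per_metric[best_metric][key]},
        }

    if needs_enhanced and "euclidean" in config.metrics:
        w, l = embedded("enhanced")
        d, _ = _channel_result(w, enroll_idx, test_idx, subjects, samples,
                               "euclidean", config.per_claim_min)
        pred = nn_identify(d)
        report["identification_accuracy_wlpp"] = float(np.mean(pred == subjects[test_idx]))
    return report
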