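"""Prediction accuracy and QTL-localization assessment.

Accuracy of a prediction equation ``GEBV = B g_hat`` is summarized by the
Pearson correlation between GEBV and true breeding value (TBV), overall and
per validation generation; the ordinary-least-squares slope of TBV on GEBV
(1 = unbiased); and Pearson/Spearman correlations restricted to the top 10%
of individuals ranked on TBV.  Localization asks how far each large QTL is
from the nearest SNP with a high posterior probability of being in LD with
QTL (distances within a chromosome only).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulate import QTLTruth

__all__ = ["AccuracyReport", "LocalizationReport", "predict_gebv",
           "accuracy_report", "qtl_localization"]


def predict_gebv(B_val: np.ndarray, g_hat: np.ndarray) -> np.ndarray:
    """GEBV = B g_hat for (validation) standardized genotypes."""
    B_val = np.asarray(B_val, dtype=float)
    g_hat = np.asarray(g_hat, dtype=float)
    if B_val.shape[1] != g_hat.shape[0]:
        raise ValueError(
            f"B has {B_val.shape[1]} columns but g_hat has {g_hat.shape[0]} entries"
        )
    return B_val @ g_hat


@dataclass
class AccuracyReport:
    pearson_all: float
    slope_tbv_on_gebv: float
    pearson_top10: float
    spearman_top10: float
    n_top10: int
    pearson_by_generation: dict = field(default_factory=dict)
    slope_by_generation: dict = field(default_factory=dict)
    n_per_group: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def clean(v):
            if isinstance(v, dict):
                return {str(k): clean(x) for k, x in v.items()}
            if isinstance(v, float) and math.isnan(v):
                return None
            return v

        return json.dumps({k: clean(v) for k, v in self.__dict__.items()}, indent=2)

    def to_text(self) -> str:
        lines = [
            f"pearson_all {self.pearson_all:.6g}",
            f"slope_tbv_on_gebv {self.slope_tbv_on_gebv:.6g}",
            f"pearson_top10 {self.pearson_top10:.6g}",
            f"spearman_top10 {self.spearman_top10:.6g}",
            f"n_top10 {self.n_top10}",
        ]
        for g in sorted(self.pearson_by_generation):
            lines.append(
                f"generation {g} n {self.n_per_group[g]} "
                f"pearson {self.pearson_by_generation[g]:.6g} "
                f"slope {self.slope_by_generation[g]:.6g}"
            )
        return "\n".join(lines) + "\n"


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return float("nan")  # undefined marker, not an exception
    return float(np.corrcoef(a, b)[0, 1])


def _slope(tbv: np.ndarray, gebv: np.ndarray) -> float:
    """OLS slope of TBV regressed on GEBV."""
    v = np.var(gebv)
    if v == 0.0:
        return float("nan")
    return float(np.cov(tbv, gebv, bias=True)[0, 1] / v)


def accuracy_report(
    gebv: np.ndarray,
    tbv: np.ndarray,
    generation_labels: np.ndarray | None = None,
    top_fraction: float = 0.1,
) -> AccuracyReport:
    """Accuracy summary of GEBV against TBV.

    The top group holds the ``ceil(top_fraction * n)`` individuals with the
    largest TBV (ties broken by stable input order).
    """
    gebv = np.asarray(gebv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    if gebv.shape != tbv.shape:
        raise ValueError("gebv and tbv lengths differ")
    n = gebv.size
    n_top = int(math.ceil(top_fraction * n))
    # stable selection of the n_top largest TBV
    order = np.argsort(-tbv, kind="stable")[:n_top]
    top = np.sort(order)
    if np.std(gebv[top]) == 0.0 or np.std(tbv[top]) == 0.0:
        sp = float("nan")
    else:
        sp = float(stats.spearmanr(gebv[top], tbv[top]).statistic)
    rep = AccuracyReport(
        pearson_all=_pearson(gebv, tbv),
        slope_tbv_on_gebv=_slope(tbv, gebv),
        pearson_top10=_pearson(gebv[top], tbv[top]),
        spearman_top10=sp,
        n_top10=n_top,
    )
    if generation_labels is not None:
        labels = np.asarray(generation_labels)
        for g in np.unique(labels):
            mask = labels == g
            rep.pearson_by_generation[int(g)] = _pearson(gebv[mask], tbv[mask])
            rep.slope_by_generation[int(g)] = _slope(tbv[mask], gebv[mask])
            rep.n_per_group[int(g)] = int(mask.sum())
    return rep


@dataclass
class LocalizationReport:
    """Distances (cM) between large QTL and high-posterior-probability SNP.

    ``qtl_to_snp`` has one entry per QTL above the variance threshold: the
    distance to the nearest SNP with gamma_j >= prob_threshold on the same
    chromosome (NaN when that chromosome has none).  ``snp_to_qtl`` has one
    entry per SNP above the probability threshold.
    """

    prob_threshold: float
    var_threshold_pct: float
    qtl_to_snp: np.ndarray
    snp_to_qtl: np.ndarray
    n_qtl_considered: int
    n_snp_above: int
    counts_above: dict = field(default_factory=dict)

    @property
    def mean_qtl_to_snp(self) -> float:
        d = self.qtl_to_snp[~np.isnan(self.qtl_to_snp)]
        return float(d.mean()) if d.size else float("nan")

    @property
    def max_qtl_to_snp(self) -> float:
        d = self.qtl_to_snp[~np.isnan(self.qtl_to_snp)]
        return float(d.max()) if d.size else float("nan")

    @property
    def mean_snp_to_qtl(self) -> float:
        d = self.snp_to_qtl[~np.isnan(self.snp_to_qtl)]
        return float(d.mean()) if d.size else float("nan")

    def to_text(self) -> str:
        return (
            f"prob_threshold {self.prob_threshold}\n"
            f"var_threshold_pct {self.var_threshold_pct}\n"
            f"n_qtl_considered {self.n_qtl_considered}\n"
            f"n_snp_above {self.n_snp_above}\n"
            f"mean_qtl_to_snp_cM {self.mean_qtl_to_snp:.6g}\n"
            f"max_qtl_to_snp_cM {self.max_qtl_to_snp:.6g}\n"
            f"mean_snp_to_qtl_cM {self.mean_snp_to_qtl:.6g}\n"
        )


def _nearest_distance(
    q_chrom, q_pos, t_chrom, t_pos
) -> np.ndarray:
    """For every query point, distance (cM) to the nearest target on the
    same chromosome; NaN if none."""
    out = np.full(len(q_pos), np.nan)
    for i, (c, p) in enumerate(zip(q_chrom, q_pos)):
        mask = t_chrom == c
        if np.any(mask):
            out[i] = np.min(np.abs(t_pos[mask] - p))
    return out


def qtl_localization(
    gamma_post: np.ndarray,
    snp_chrom: np.ndarray,
    snp_pos_cm: np.ndarray,
    truth: QTLTruth,
    prob_threshold: float = 0.9,
    var_threshold_pct: float = 1.0,
    count_cutoffs=(0.1, 0.5, 0.9),
) -> LocalizationReport:
    """How well do high-probability SNP tag the QTL that matter?"""
    gamma_post = np.asarray(gamma_post, dtype=float)
    snp_chrom = np.asarray(snp_chrom)
    snp_pos_cm = np.asarray(snp_pos_cm, dtype=float)
    big_qtl = truth.variance_share_pct > var_threshold_pct
    hot_snp = gamma_post >= prob_threshold
    qtl_to_snp = _nearest_distance(
        truth.chrom[big_qtl],
        truth.pos_cm[big_qtl],
        snp_chrom[hot_snp],
        snp_pos_cm[hot_snp],
    )
    snp_to_qtl = _nearest_distance(
        snp_chrom[hot_snp],
        snp_pos_cm[hot_snp],
        truth.chrom[big_qtl],
        truth.pos_cm[big_qtl],
    )
    counts = {c: int(np.sum(gamma_post > c)) for c in count_cutoffs}
    return LocalizationReport(
        prob_threshold=prob_threshold,
        var_threshold_pct=var_threshold_pct,
        qtl_to_snp=qtl_to_snp,
        snp_to_qtl=snp_to_qtl,
        n_qtl_considered=int(big_qtl.sum()),
        n_snp_above=int(hot_snp.sum()),
        counts_above=counts,
    )
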