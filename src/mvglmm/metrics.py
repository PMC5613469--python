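"""Predictive-accuracy metrics: RMSE, absolute bias, ROC/AUC, DeLong's
paired AUC comparison, and credible-interval coverage.

RMSE_k and AB_k pool all subject-visit terms of outcome k:

    RMSE_k = sqrt( sum_ij (Y_ikj - E[Y_ikj|X,Z])^2 / sum_i n_i )
    AB_k   =       sum_ij |Y_ikj - E[Y_ikj|X,Z]|   / sum_i n_i

For the binary outcome, discrimination is assessed by the empirical ROC
over all distinct predicted-probability thresholds; the trapezoidal AUC
equals the pair-counting estimator with ties counted 1/2.  Two fits scored
on the same labels are compared with DeLong's nonparametric paired test on
placement values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
import sklearn.metrics as _skm

from .cohort import CohortDataset, DataError
from .model import PosteriorSamples

__all__ = [
    "rmse", "absolute_bias", "roc_curve", "auc", "delong_test",
    "interval_coverage", "evaluate_fit", "EvalReport", "DeLongResult",
]


def _paired(observed, predicted):
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("empty inputs")
    return obs, pred


def rmse(observed, predicted) -> float:
    """Root mean squared error pooled over all subject-visit terms."""
    obs, pred = _paired(observed, predicted)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def absolute_bias(observed, predicted) -> float:
    """Mean absolute error pooled over all subject-visit terms."""
    obs, pred = _paired(observed, predicted)
    return float(np.mean(np.abs(obs - pred)))


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=float)
    if not set(np.unique(y)) == {0.0, 1.0}:
        raise DataError("labels must contain both classes (0 and 1)")
    return y


def roc_curve(labels, scores):
    """Empirical ROC: (fpr, tpr) at every distinct score threshold plus the
    (0,0) and (1,1) endpoints; both coordinates nondecreasing."""
    y = _check_labels(labels)
    fpr, tpr, _ = _skm.roc_curve(y, np.asarray(scores, float), drop_intermediate=False)
    return fpr, tpr


def auc(labels, scores) -> float:
    """Trapezoidal area under the empirical ROC (= ties-1/2 pair counting)."""
    y = _check_labels(labels)
    return float(_skm.roc_auc_score(y, np.asarray(scores, float)))


class DeLongResult(NamedTuple):
    auc_a: float
    auc_b: float
    z: float
    p_value: float
    degenerate: bool


def _placements(y: np.ndarray, s: np.ndarray):
    """DeLong placement values: V10 (per positive) and V01 (per negative)."""
    pos = s[y == 1.0]
    neg = s[y == 0.0]
    cmp = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_test(labels, scores_a, scores_b) -> DeLongResult:
    """DeLong's paired test for the difference of two correlated AUCs.

    Both score vectors must be computed on the same labels.  Degenerate
    variance (e.g., identical scores) yields z = 0, p = 1 with a flag.
    """
    y = _check_labels(labels)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != y.shape or sb.shape != y.shape:
        raise ValueError("scores must align with labels")
    v10a, v01a = _placements(y, sa)
    v10b, v01b = _placements(y, sb)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    m, n = len(v10a), len(v01a)
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(d01, ddof=1) / n if n > 1 else 0.0)
    if var <= 1e-16:
        return DeLongResult(auc_a, auc_b, 0.0, 1.0, True)
    z = (auc_a - auc_b) / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, float(z), p, False)


def interval_coverage(observed, intervals) -> float:
    """Fraction of observations inside their closed [lo, hi] interval."""
    obs = np.asarray(observed, dtype=float)
    iv = np.asarray(intervals, dtype=float)
    if iv.ndim != 2 or iv.shape[1] != 2 or iv.shape[0] != obs.shape[0]:
        raise ValueError("intervals must be (n, 2) aligned with observed")
    if np.any(iv[:, 0] > iv[:, 1]):
        raise DataError("interval with lo > hi")
    return float(np.mean((iv[:, 0] <= obs) & (obs <= iv[:, 1])))


@dataclass
class EvalReport:
    """Fit/prediction accuracy summary; JSON round-trippable."""

    continuous: dict = field(default_factory=dict)   # name -> {rmse, ab, n}
    binary: dict = field(default_factory=dict)       # name -> {auc, roc, n}
    delong: dict | None = None
    coverage: float | None = None
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "EvalReport":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls(**json.loads(text))


def _fitted_values(samples: PosteriorSamples, frame: pd.DataFrame,
                   conditional: bool = True):
    """Posterior-mean fitted values per outcome for training subjects.

    ``conditional`` uses the subject-specific linear predictor (with the
    stored gamma draws); otherwise gamma is integrated out (marginal mean,
    MC-averaged over MVN(mu, Sigma) for the logistic outcome).
    """
    from .model import _build_design, ModelSpec
    spec = ModelSpec(outcomes=samples.outcomes, covariates=samples.covariates,
                     correlation_mode=samples.correlation_mode)
    sids, ys, Xs, subjs = _build_design(frame, spec)
    remap = []
    for s in sids:
        remap.append(samples.subject_index(s) if conditional else -1)
    remap = np.array(remap)
    out = {}
    for k, (name, fam) in enumerate(samples.outcomes):
        lin = samples.beta[:, k, :] @ Xs[k].T                  # (M, n_k)
        if conditional:
            lin = lin + samples.gamma[:, remap[subjs[k]], k]
            fitted = lin.mean(axis=0) if fam == "gaussian" else expit(lin).mean(axis=0)
        else:
            lin = lin + samples.mu[:, k][:, None]
            if fam == "gaussian":
                fitted = lin.mean(axis=0)
            else:
                # marginal logistic mean: Gauss-Hermite over gamma ~ N(mu, Sigma_kk)
                nodes, weights = np.polynomial.hermite_e.hermegauss(15)
                weights = weights / weights.sum()
                sd = np.sqrt(samples.Sigma[:, k, k])[:, None]
                fitted = np.zeros(lin.shape[1])
                for q, w in zip(nodes, weights):
                    fitted += w * expit(lin + sd * q).mean(axis=0)
        out[name] = (ys[k], fitted)
    return out


def evaluate_fit(samples: PosteriorSamples, dataset: CohortDataset,
                 samples_b: PosteriorSamples | None = None,
                 role: str | None = "train",
                 conditional: bool = True) -> EvalReport:
    """RMSE/AB per continuous outcome and ROC/AUC for the binary outcome,
    using posterior-mean subject-level fitted values on the training data;
    optionally a DeLong comparison against a second posterior."""
    if role == "train" and "role" not in dataset.subjects.columns:
        role = None
    frame = dataset.frame(role=role)
    fitted = _fitted_values(samples, frame, conditional=conditional)
    report = EvalReport(provenance={
        "mode": samples.correlation_mode, "role": role or "all",
        "conditional": conditional, "n_draws": samples.n_draws,
    })
    for k, (name, fam) in enumerate(samples.outcomes):
        y, f = fitted[name]
        if fam == "gaussian":
            report.continuous[name] = {
                "rmse": rmse(y, f), "ab": absolute_bias(y, f), "n": int(len(y)),
            }
        else:
            fpr, tpr = roc_curve(y, f)
            report.binary[name] = {
                "auc": auc(y, f), "n": int(len(y)),
                "roc": [fpr.tolist(), tpr.tolist()],
            }
            if samples_b is not None:
                fitted_b = _fitted_values(samples_b, frame, conditional=conditional)
                yb, fb = fitted_b[name]
                if len(yb) != len(y):
                    raise ValueError("posteriors score different row sets")
                res = delong_test(y, f, fb)
                report.delong = {
                    "auc_a": res.auc_a, "auc_b": res.auc_b,
                    "z": res.z, "p_value": res.p_value,
                    "degenerate": res.degenerate,
                }
    return report
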