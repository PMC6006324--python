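"""Agreement and reproducibility statistics for joint space width maps.

Conventions follow standard method-comparison practice: *accuracy* (bias) is
the mean of A − B over matched vertices, *precision* the sample SD (n−1) of
those differences, Bland-Altman 95% limits of agreement are 1.96 × SD, and
reproducibility is summarised as the root-mean-square coefficient of
variation, RMSCV = 100 × sqrt(mean CV²) with per-pair CV = SD/mean (the
two-value sample SD |a−b|/√2).  High-resolution reference data are trimmed
to their central 95% range before comparison to remove noise at the
extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class AgreementReport:
    n_pairs: int
    bias: float
    precision: float
    loa: float
    rmscv: float = float("nan")
    per_vertex: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"n_pairs": self.n_pairs, "bias_mm": self.bias,
                "precision_mm": self.precision, "loa_mm": self.loa,
                "rmscv_percent": self.rmscv}


def trim_95(values: np.ndarray, min_values: int = 40) -> np.ndarray:
    """Mask values outside the central 95% range to NaN.

    Candidates fall strictly outside the [2.5, 97.5] linear-interpolation
    percentiles of the finite values; at most ``floor(0.025 * n)`` values are
    removed per side, counting entries already missing (assumed symmetric)
    against that budget.  The budget accounting makes the operation
    idempotent and leaves an all-equal sample untouched.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < min_values:
        raise ValueError(f"need >= {min_values} finite values, "
                         f"got {int(finite.sum())}")
    n = len(values)
    budget = int(np.floor(0.025 * n)) - int((n - finite.sum()) // 2)
    out = values.copy()
    if budget <= 0:
        return out
    lo, hi = np.percentile(values[finite], [2.5, 97.5])
    fv = values[finite]
    low_candidates = np.sort(fv[fv < lo])
    high_candidates = np.sort(fv[fv > hi])[::-1]
    if len(low_candidates):
        cut = low_candidates[: budget][-1]
        out[finite & (values <= cut) & (values < lo)] = np.nan
    if len(high_candidates):
        cut = high_candidates[: budget][-1]
        out[finite & (values >= cut) & (values > hi)] = np.nan
    return out


def accuracy_precision(map_a, map_b) -> tuple[float, float]:
    """Bias (mean of A − B) and precision (sample SD of A − B) over vertices
    valued in both maps.  Accepts JSWMap objects or plain arrays."""
    a = _values(map_a)
    b = _values(map_b)
    if len(a) != len(b):
        raise ValueError("maps must share a surface (equal vertex counts)")
    both = np.isfinite(a) & np.isfinite(b)
    if not both.any():
        raise ValueError("no vertices carry values in both maps")
    d = a[both] - b[both]
    sd = float(np.std(d, ddof=1)) if both.sum() > 1 else 0.0
    return float(np.mean(d)), sd


def bland_altman(pairs: np.ndarray) -> tuple[AgreementReport, pd.DataFrame]:
    """Bias and 1.96 × SD limits of agreement for paired measurements.

    ``pairs`` is (n, 2): operator 1 and operator 2 (or any two methods).
    The returned frame holds per-pair means and differences for plotting.
    """
    pairs = np.asarray(pairs, dtype=float)
    pairs = pairs[np.all(np.isfinite(pairs), axis=1)]
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 2:
        raise ValueError("need at least 2 finite pairs")
    d = pairs[:, 0] - pairs[:, 1]
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    report = AgreementReport(n_pairs=len(pairs), bias=bias, precision=sd,
                             loa=1.96 * sd)
    frame = pd.DataFrame({"mean": pairs.mean(axis=1), "difference": d})
    return report, frame


def rmscv(pairs: np.ndarray) -> float:
    """Root-mean-square coefficient of variation, in percent.

    Per pair: CV = SD/mean with the two-value sample SD |a − b|/√2; the
    summary is 100 × sqrt(mean of CV²).  Scale-invariant; requires all pair
    means to be positive.
    """
    pairs = np.asarray(pairs, dtype=float)
    pairs = pairs[np.all(np.isfinite(pairs), axis=1)]
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 1:
        raise ValueError("need at least 1 finite pair")
    means = pairs.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("pair mean <= 0: CV undefined")
    sds = np.abs(pairs[:, 0] - pairs[:, 1]) / np.sqrt(2.0)
    cv = sds / means
    return float(100.0 * np.sqrt(np.mean(cv ** 2)))


def agreement_report(map_a, map_b, trim_b: bool = False) -> AgreementReport:
    """Full agreement summary between two maps on a shared surface."""
    a = _values(map_a)
    b = _values(map_b)
    if trim_b:
        b = trim_95(b)
    both = np.isfinite(a) & np.isfinite(b)
    if not both.any():
        raise ValueError("no matched vertices")
    d = a[both] - b[both]
    sd = float(np.std(d, ddof=1)) if both.sum() > 1 else 0.0
    pos = both & (a + b > 0)
    r = rmscv(np.stack([a[pos], b[pos]], axis=1)) if pos.any() else np.nan
    return AgreementReport(n_pairs=int(both.sum()), bias=float(np.mean(d)),
                           precision=sd, loa=1.96 * sd, rmscv=r)


def per_vertex_maps(
    collection_a: np.ndarray,
    collection_b: np.ndarray,
    min_subjects: int = 3,
) -> dict[str, np.ndarray]:
    """Vertex-wise bias/precision/RMSCV fields across a subject collection.

    ``collection_a``/``collection_b`` are (n_subjects, n_vertices) arrays on
    a common (average) surface; at each vertex the global formulas run down
    the subject axis.  Vertices with fewer than ``min_subjects`` subjects
    contributing to both collections are masked to NaN.
    """
    A = np.asarray(collection_a, dtype=float)
    B = np.asarray(collection_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("collections must share shape "
                         "(same subjects, same surface)")
    both = np.isfinite(A) & np.isfinite(B)
    count = both.sum(axis=0)
    D = np.where(both, A - B, np.nan)
    with np.errstate(invalid="ignore"):
        bias = np.nanmean(D, axis=0)
        precision = np.full(A.shape[1], np.nan)
        enough2 = count >= 2
        precision[enough2] = np.nanstd(D[:, enough2], axis=0, ddof=1)
        means = np.where(both, (A + B) / 2.0, np.nan)
        sds = np.where(both, np.abs(A - B) / np.sqrt(2.0), np.nan)
        cv2 = (sds / means) ** 2
        rms = 100.0 * np.sqrt(np.nanmean(cv2, axis=0))
    mask = count < min_subjects
    for arr in (bias, precision, rms):
        arr[mask] = np.nan
    return {"bias": bias, "precision": precision,
            "loa": 1.96 * precision, "rmscv": rms,
            "n_subjects": count}


def _values(m) -> np.ndarray:
    if hasattr(m, "jsw"):
        return np.asarray(m.jsw, dtype=float)
    return np.asarray(m, dtype=float)
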