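"""Integrated-gradients attribution for the mutability regressor.

Attribution of the scalar prediction F(x) relative to an all-zero
baseline: scores = x * (mean gradient of F along the straight path from
0 to x).  By the completeness axiom the scores sum to F(x) - F(0) in the
limit of infinitely many path steps; the residual at finite step count
is recorded on every attribution.  Because the input is one-hot, the
elementwise product masks every row that is not the realised base, so a
15-mer reduces to a 15-vector of per-position scores of the realised
bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmers import ROW_ORDER, one_hot_encode

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AttributionMatrix:
    """Per-base, per-position importance scores for one prediction."""

    scores: np.ndarray  # 4 x k
    prediction: float
    baseline_prediction: float

    @property
    def completeness_residual(self) -> float:
        return abs(float(self.scores.sum()) - (self.prediction - self.baseline_prediction))


def integrated_gradients(model, x, steps: int = 50, method: str = "right") -> AttributionMatrix:
    """Attribute F(x) against a zero baseline with a Riemann path sum.

    ``method='right'`` evaluates gradients at (k/steps)*x for k=1..steps
    (the default); ``'trapezoid'`` additionally includes the baseline
    endpoint with half weights, refining the same integral.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if not (hasattr(model, "input_gradients") and hasattr(model, "predict")):
        raise TypeError("model must expose predict() and input_gradients() for attribution")
    x = np.asarray(x, dtype=float)
    if method == "right":
        alphas = np.arange(1, steps + 1) / steps
        weights = np.full(steps, 1.0 / steps)
    elif method == "trapezoid":
        alphas = np.arange(0, steps + 1) / steps
        weights = np.full(steps + 1, 1.0 / steps)
        weights[0] = weights[-1] = 0.5 / steps
    else:
        raise ValueError(f"unknown method {method!r}")
    grads = model.input_gradients(alphas[:, None, None] * x[None, :, :])
    avg = np.tensordot(weights, grads, axes=1)
    scores = x * avg
    return AttributionMatrix(
        scores=scores,
        prediction=float(model.predict(x)),
        baseline_prediction=float(model.predict(np.zeros_like(x))),
    )


def position_scores(attrib: AttributionMatrix, kmer: str) -> np.ndarray:
    """Collapse a (masked) attribution matrix to one score per position:
    entry j is the score of the base actually present at position j."""
    onehot = one_hot_encode(kmer)
    if attrib.scores.shape != onehot.shape:
        raise ValueError("k-mer length does not match the attribution matrix")
    off_rows = attrib.scores[onehot == 0]
    if off_rows.size and np.abs(off_rows).max() > 0:
        raise ValueError("attribution has non-zero scores off the realised bases; "
                         "k-mer does not match the attributed input")
    rows = [ROW_ORDER.index(b) for b in kmer]
    return attrib.scores[rows, np.arange(len(kmer))]


def summarize_by_subregion(
    records, subregions: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Box-plot summaries and logo letter frequencies per subregion.

    ``records`` is a list of ``(KmerRecord, position_scores_vector)``
    pairs.  Returns ``(summary, logo)``:

    * summary: subregion, position, n, median, q1, q3, whisker_lo,
      whisker_hi — quartiles by linear interpolation between order
      statistics; whiskers are the most extreme observations within
      1.5 x IQR of the quartiles (Tukey convention).
    * logo: subregion, position, base, freq — per-column base
      frequencies (each column sums to 1).
    """
    records = list(records)
    by_region: dict[str, list] = {}
    for rec, scores in records:
        by_region.setdefault(rec.subregion, []).append((rec, np.asarray(scores, float)))
    if subregions:
        for name in subregions:
            if name not in by_region:
                logger.warning("subregion %s has no records; omitted from summary", name)

    summary_rows, logo_rows = [], []
    for region, items in by_region.items():
        mat = np.stack([s for _, s in items])  # (n_records, k)
        kmers = [rec.kmer for rec, _ in items]
        n, k = mat.shape
        for j in range(k):
            col = mat[:, j]
            q1, med, q3 = np.percentile(col, [25, 50, 75])
            iqr = q3 - q1
            inside = col[(col >= q1 - 1.5 * iqr) & (col <= q3 + 1.5 * iqr)]
            summary_rows.append(
                {
                    "subregion": region,
                    "position": j + 1,
                    "n": n,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_lo": inside.min(),
                    "whisker_hi": inside.max(),
                }
            )
            for base in ROW_ORDER:
                logo_rows.append(
                    {
                        "subregion": region,
                        "position": j + 1,
                        "base": base,
                        "freq": sum(km[j] == base for km in kmers) / n,
                    }
                )
    return pd.DataFrame(summary_rows), pd.DataFrame(logo_rows)


def attribution_table(model, records, steps: int = 50, method: str = "right") -> pd.DataFrame:
    """Long-format attribution table for a list of KmerRecords:
    allele_id, central_pos, subregion, position (1..k), base, score."""
    rows = []
    for rec in records:
        attrib = integrated_gradients(model, one_hot_encode(rec.kmer).astype(float),
                                      steps=steps, method=method)
        scores = position_scores(attrib, rec.kmer)
        for j, (base, score) in enumerate(zip(rec.kmer, scores), start=1):
            rows.append(
                {
                    "allele_id": rec.allele_id,
                    "central_pos": rec.central_pos,
                    "subregion": rec.subregion,
                    "agct_role": rec.agct_role,
                    "position": j,
                    "base": base,
                    "score": score,
                }
            )
    return pd.DataFrame(rows)
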