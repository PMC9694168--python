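"""Finger-print (FP) module: descriptor-tolerance similarity and read-across.

The similarity score between a query and a training compound is the fraction
of descriptors whose query value falls inside the training value's +/-5%
window:

    S = N(within tolerance) / N(descriptors usable on both sides)

Positions where either vector is missing are excluded from both counts, so S
always lies in [0, 1].  The tolerance is relative to the *training* value
(D_i +/- D_i * 0.05), which makes the score deliberately asymmetric; a
training value of exactly 0 only matches a query value of exactly 0.

The module transfers the experimental activity row of the best-scoring
training compound to the query verbatim (classical read-across): cell lines
where that compound was never assayed stay missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import AapError, ActivityMatrix, DescriptorMatrix

#: Relative half-width of the per-descriptor tolerance window.
FP_TOLERANCE = 0.05


@dataclass
class FPResult:
    """Similarity-transfer result for one query compound."""

    query_id: str
    best_match_id: str
    S: float
    gi50_fp: pd.Series  # pGI50 per cell line, NaN where the match lacks data


def similarity_score(query_vec: np.ndarray, ref_vec: np.ndarray) -> float:
    """Fraction of mutually observed descriptors within the ref's 5% window.

    Raises :class:`AapError` when the two vectors share no observed position.
    """
    q = np.asarray(query_vec, dtype=float)
    r = np.asarray(ref_vec, dtype=float)
    if q.shape != r.shape:
        raise AapError(f"vector length mismatch: {q.shape} vs {r.shape}")
    usable = ~np.isnan(q) & ~np.isnan(r)
    n = int(usable.sum())
    if n == 0:
        raise AapError("no descriptor observed in both query and reference")
    hit = np.abs(q[usable] - r[usable]) <= FP_TOLERANCE * np.abs(r[usable])
    return float(hit.sum()) / n


def similarity_profile(
    query_vec: np.ndarray, training_desc: DescriptorMatrix
) -> np.ndarray:
    """Vectorized S score of one query against every training row.

    Rows sharing no observed descriptor with the query get NaN.
    """
    q = np.asarray(query_vec, dtype=float)
    R = training_desc.values.to_numpy()
    if R.shape[1] != q.shape[0]:
        raise AapError(
            f"query has {q.shape[0]} descriptors, training matrix has {R.shape[1]}"
        )
    usable = ~np.isnan(q)[None, :] & ~np.isnan(R)
    with np.errstate(invalid="ignore"):
        hit = np.abs(q[None, :] - R) <= FP_TOLERANCE * np.abs(R)
    n = usable.sum(axis=1)
    num = (hit & usable).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(n > 0, num / np.maximum(n, 1), np.nan)
    return s


def fp_predict(
    query_vec: np.ndarray,
    training_desc: DescriptorMatrix,
    training_act: ActivityMatrix,
    query_id: str = "query",
) -> FPResult:
    """Assign the experimental activity row of the best-scoring training compound.

    The winner is the argmax of :func:`similarity_score` over all training
    rows.  Ties on S prefer the compound with more observed activity entries
    (it transfers more information), then the lexicographically smaller id.
    """
    if len(training_desc.row_ids) == 0:
        raise AapError("empty training set")
    if training_desc.row_ids != training_act.row_ids:
        raise AapError("training descriptor and activity matrices are not row-aligned")
    s = similarity_profile(query_vec, training_desc)
    if np.all(np.isnan(s)):
        raise AapError("query shares no observed descriptor with any training compound")
    best_s = np.nanmax(s)
    tied = np.flatnonzero(s == best_s)
    if len(tied) > 1:
        n_act = training_act.values.notna().sum(axis=1).to_numpy()
        ids = training_act.row_ids
        tied = sorted(tied, key=lambda k: (-n_act[k], ids[k]))
    best = int(tied[0])
    best_id = training_act.row_ids[best]
    return FPResult(
        query_id=query_id,
        best_match_id=best_id,
        S=float(best_s),
        gi50_fp=training_act.values.iloc[best].copy(),
    )
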