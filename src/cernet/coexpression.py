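"""Pearson coexpression filters for ceRNA evidence.

Two filters are applied downstream of target prediction:

* lncRNA-mRNA coexpression: r > 0.90 and P < 0.001 (strict), the
  evidence that the two transcripts co-move as competing targets;
* miRNA-target anticorrelation: r < 0 with P < 0.05, the sponge
  signature that a miRNA suppresses both of its targets.

Correlations are computed across ALL samples pooled over both
conditions: the condition shift itself is part of the co-movement a
ceRNA relationship predicts, and with a handful of samples per
condition a P < 0.001 cut is only reachable on the pooled vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from cernet.core_io import ExpressionBundle
from cernet.errors import UndefinedCorrelationError, ValidationError
from cernet.targets import TargetPair

logger = logging.getLogger(__name__)

DEFAULT_R_MIN = 0.90
DEFAULT_COEXPR_P = 0.001
DEFAULT_ANTICORR_P = 0.05


@dataclass(frozen=True)
class CoexpressionEdge:
    a_id: str
    a_class: str
    b_id: str
    b_class: str
    r: float
    p_value: float
    n_samples: int


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-transform p-value.

    p is derived from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom; |r| = 1 maps to p = 0.  Zero variance in either vector
    raises :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_with_p requires two equal-length vectors")
    n = x.size
    if n < 3:
        raise ValidationError("pearson_with_p requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("pearson_with_p requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a zero-variance vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def _corr_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise correlations of every row of `a` against every row of `b`.

    Returns (r matrix, valid mask); rows with zero variance are flagged
    invalid rather than raising, so callers can skip-and-warn per pair.
    """
    n = a.shape[1]
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    sa = az.std(axis=1)
    sb = bz.std(axis=1)
    valid = np.outer(sa > 0, sb > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / n / np.outer(np.where(sa > 0, sa, 1.0), np.where(sb > 0, sb, 1.0))
    return np.clip(r, -1.0, 1.0), valid


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def lncrna_mrna_edges(
    bundle: ExpressionBundle,
    lnc_ids: Iterable[str],
    mrna_ids: Iterable[str],
    r_min: float = DEFAULT_R_MIN,
    p_max: float = DEFAULT_COEXPR_P,
) -> list[CoexpressionEdge]:
    """Strongly positive lncRNA-mRNA coexpression edges (r > r_min, p < p_max)."""
    lnc_ids = sorted(set(lnc_ids))
    mrna_ids = sorted(set(mrna_ids))
    for fid in lnc_ids:
        if fid not in bundle.lncrna.index:
            raise ValidationError(f"lncRNA '{fid}' not in bundle")
    for fid in mrna_ids:
        if fid not in bundle.mrna.index:
            raise ValidationError(f"mRNA '{fid}' not in bundle")
    if not lnc_ids or not mrna_ids:
        return []
    a = bundle.lncrna.loc[lnc_ids].to_numpy(dtype=float)
    b = bundle.mrna.loc[mrna_ids].to_numpy(dtype=float)
    n = a.shape[1]
    r, valid = _corr_matrix(a, b)
    p = _p_from_r(r, n)
    if not valid.all():
        logger.warning("skipped %d lncRNA-mRNA pairs with zero variance", int((~valid).sum()))
    edges = []
    for i, lnc in enumerate(lnc_ids):
        for j, mrna in enumerate(mrna_ids):
            if valid[i, j] and r[i, j] > r_min and p[i, j] < p_max:
                edges.append(CoexpressionEdge(lnc, "lncRNA", mrna, "mRNA",
                                              float(r[i, j]), float(p[i, j]), n))
    return edges


def mirna_anticorrelation_filter(
    bundle: ExpressionBundle,
    pairs: list[TargetPair],
    p_max: float = DEFAULT_ANTICORR_P,
) -> list[tuple[TargetPair, CoexpressionEdge]]:
    """Retain predicted pairs whose miRNA-target correlation is negative.

    A pair survives when pooled-sample r < 0 with p < p_max; each
    retained pair is annotated with its coexpression edge.  Zero
    variance pairs are skipped with a warning.
    """
    class_to_matrix = {"lncRNA": bundle.lncrna, "mRNA": bundle.mrna}
    kept: list[tuple[TargetPair, CoexpressionEdge]] = []
    for pair in pairs:
        mat = class_to_matrix.get(pair.target_class)
        if mat is None:
            raise ValidationError(f"unsupported target class '{pair.target_class}'")
        if pair.mirna_id not in bundle.mirna.index:
            raise ValidationError(f"miRNA '{pair.mirna_id}' not in bundle")
        if pair.target_id not in mat.index:
            raise ValidationError(f"{pair.target_class} '{pair.target_id}' not in bundle")
        x = bundle.mirna.loc[pair.mirna_id].to_numpy(dtype=float)
        y = mat.loc[pair.target_id].to_numpy(dtype=float)
        try:
            r, p = pearson_with_p(x, y)
        except UndefinedCorrelationError:
            logger.warning("skipping pair (%s, %s): zero variance", pair.mirna_id, pair.target_id)
            continue
        if r < 0 and p < p_max:
            kept.append((pair, CoexpressionEdge(pair.mirna_id, "miRNA", pair.target_id,
                                                pair.target_class, r, p, x.size)))
    return kept
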