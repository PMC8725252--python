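"""Two-class differential screening of each RNA class.

The screen follows microarray convention: a pooled-variance (Student's)
two-sample t-test on log2 values, a signed linear fold change computed
from the difference of log2 means (a geometric-mean ratio), and the
dual cut fold change > 2 with raw P < 0.05 to call up/down features.
Thresholds are strict inequalities.  Raw P drives the call; a
Benjamini-Hochberg q-value is emitted for information only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cernet.core_io import ExpressionBundle, RNA_CLASSES
from cernet.errors import ValidationError

DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_P_THRESHOLD = 0.05


@dataclass(frozen=True)
class DERecord:
    """Per-feature differential result.

    ``signed_fold_change`` is linear-scale and sign-coded: +2^d for a
    log2 difference d >= 0 (induced minus control), -2^(-d) otherwise,
    so |signed_fold_change| >= 1 always.  ``degenerate`` flags the
    zero-variance unequal-means case where p is reported as 0.
    """

    feature_id: str
    feature_class: str
    mean_induced: float
    mean_control: float
    signed_fold_change: float
    t_statistic: float
    p_value: float
    bh_q: float
    direction: str  # up | down | ns
    degenerate: bool = False


def signed_fold_change(log2_delta: float) -> float:
    """Map a log2 mean difference to the signed linear fold change."""
    if log2_delta >= 0:
        return float(2.0 ** log2_delta)
    return float(-(2.0 ** (-log2_delta)))


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Pooled-variance two-sample t on log2 values.

    Returns (t, two-sided p, degenerate).  Degenerate cases: identical
    means with zero pooled variance give t=0, p=1; distinct means with
    zero pooled variance give p=0 with the degenerate flag raised so
    noiseless synthetic data can pass through the screen.
    """
    n1, n2 = len(x), len(y)
    s2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    delta = float(np.mean(x) - np.mean(y))
    if s2 == 0.0:
        if delta == 0.0:
            return 0.0, 1.0, False
        return float(np.sign(delta)) * np.inf, 0.0, True
    t = delta / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return float(t), float(p), False


def two_class_de(
    bundle: ExpressionBundle,
    rna_class: str,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    welch: bool = False,
) -> list[DERecord]:
    """Screen one RNA class of the bundle for differential expression.

    Parameters
    ----------
    welch:
        Use the Welch (unequal-variance) t-test instead of the default
        pooled-variance Student's t.
    """
    if rna_class not in RNA_CLASSES:
        raise ValidationError(f"unknown RNA class '{rna_class}'")
    mat = bundle.matrix(rna_class)
    induced = np.asarray(bundle.sheet.mask("induced"))
    control = np.asarray(bundle.sheet.mask("control"))
    if induced.sum() < 2 or control.sum() < 2:
        raise ValidationError("two_class_de requires >= 2 samples per condition")

    rows: list[dict] = []
    for feature_id, values in mat.iterrows():
        v = values.to_numpy(dtype=float)
        x, y = v[induced], v[control]
        if welch:
            t, p = stats.ttest_ind(x, y, equal_var=False)
            t, p, degen = float(t), float(p), False
            if np.isnan(t):  # zero variance both groups
                delta0 = float(np.mean(x) - np.mean(y))
                t = 0.0 if delta0 == 0 else float(np.sign(delta0)) * np.inf
                p, degen = (1.0, False) if delta0 == 0 else (0.0, True)
        else:
            t, p, degen = _pooled_t(x, y)
        if degen:
            warnings.warn(
                f"{rna_class} feature '{feature_id}': zero variance with unequal means; p set to 0",
                stacklevel=2,
            )
        mi, mc = float(np.mean(x)), float(np.mean(y))
        rows.append(dict(
            feature_id=str(feature_id), feature_class=rna_class,
            mean_induced=mi, mean_control=mc,
            signed_fold_change=signed_fold_change(mi - mc),
            t_statistic=t, p_value=p, degenerate=degen,
        ))

    qs = multipletests([r["p_value"] for r in rows], method="fdr_bh")[1] if rows else []
    records = []
    for r, q in zip(rows, qs):
        direction = _call_direction(r["signed_fold_change"], r["p_value"], fc_threshold, p_threshold)
        records.append(DERecord(bh_q=float(q), direction=direction, **r))
    return records


def _call_direction(sfc: float, p: float, fc_threshold: float, p_threshold: float) -> str:
    if sfc > fc_threshold and p < p_threshold:
        return "up"
    if sfc < -fc_threshold and p < p_threshold:
        return "down"
    return "ns"


def stratify(
    records: list[DERecord],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> dict[str, set[str]]:
    """Partition features into up/down id sets at strict thresholds.

    A record with signed fold change exactly at the threshold, or p
    exactly at the cut, is not significant (strict > and <).
    """
    up = {r.feature_id for r in records
          if _call_direction(r.signed_fold_change, r.p_value, fc_threshold, p_threshold) == "up"}
    down = {r.feature_id for r in records
            if _call_direction(r.signed_fold_change, r.p_value, fc_threshold, p_threshold) == "down"}
    return {"up": up, "down": down}


def de_table(records: list[DERecord]) -> pd.DataFrame:
    """Tabulate DE records in the pipeline's output TSV layout."""
    return pd.DataFrame(
        [
            dict(
                feature_id=r.feature_id, feature_class=r.feature_class,
                mean_induced=r.mean_induced, mean_control=r.mean_control,
                signed_fold_change=r.signed_fold_change,
                t=r.t_statistic, p=r.p_value, bh_q=r.bh_q, direction=r.direction,
            )
            for r in records
        ],
        columns=["feature_id", "feature_class", "mean_induced", "mean_control",
                 "signed_fold_change", "t", "p", "bh_q", "direction"],
    )
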