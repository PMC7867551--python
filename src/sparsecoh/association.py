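"""Coherence-symptom association on the classifier's selected connections.

After the sparse classifier identifies its nonzero-weight connections,
post-treatment coherence on those connections is correlated with percent
symptom change (IDS-SR for depressive symptoms, PCL-5 for PTSD symptoms;
positive change = improvement in both). Connections sharing a weight sign
form a *set*; the per-set coherence is the mean over member pairs, and
each set is tested separately against each instrument.

Pearson's r is the primary statistic (a Spearman flag is available); the
two-sided p-value comes from the t distribution with n - 2 degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .svm import SparseHingeSVM


class AssociationError(ValueError):
    pass


@dataclass
class AssociationResult:
    connection: str  # set label or single pair name
    instrument: str  # "ids_sr" | "pcl5"
    r: float
    p: float
    n: int
    method: str = "pearson"

    def to_dict(self) -> dict:
        return {
            "connection": self.connection,
            "instrument": self.instrument,
            "r": self.r,
            "p": self.p,
            "n": self.n,
            "method": self.method,
        }


def zscore_coherence(values) -> np.ndarray:
    """Z-score across participants (mean 0, SD 1 with n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise AssociationError("need >= 3 participants to z-score")
    sd = v.std(ddof=1)
    if sd == 0:
        raise AssociationError("zero variance: cannot z-score")
    return (v - v.mean()) / sd


def correlate_symptoms(
    coherence,
    change,
    connection: str = "",
    instrument: str = "",
    method: str = "pearson",
) -> AssociationResult:
    """Correlate (standardized) coherence with percent symptom change."""
    x = np.asarray(coherence, dtype=float)
    y = np.asarray(change, dtype=float)
    if x.shape != y.shape:
        raise AssociationError("coherence/change length mismatch")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise AssociationError("need >= 4 complete pairs")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise AssociationError(f"unknown method {method!r}")
    return AssociationResult(
        connection=connection, instrument=instrument,
        r=float(r), p=float(p), n=len(x), method=method,
    )


def connection_sets(model: SparseHingeSVM) -> dict[str, list[str]]:
    """Group the model's nonzero connections by weight sign.

    Returns ``{"increase": [...], "decrease": [...]}`` (empty lists for
    absent signs), mirroring how a sparse model's surviving connections
    split into coherence-increased and coherence-decreased sets in the
    positive class.
    """
    sets: dict[str, list[str]] = {"increase": [], "decrease": []}
    for name, _w, direction in model.nonzero_connections():
        sets[direction].append(name)
    return sets


def model_symptom_associations(
    model: SparseHingeSVM,
    features: pd.DataFrame,
    feature_columns: list[str],
    instruments: tuple[str, ...] = ("ids_sr", "pcl5"),
    method: str = "pearson",
) -> list[AssociationResult]:
    """Correlate per-set post-treatment coherence with symptom change.

    ``features`` holds one row per participant with the coherence columns
    plus ``<instrument>_pct_change`` columns. Each sign-consistent set of
    nonzero-weight connections is reduced to its mean member coherence
    (single-pair sets pass through), z-scored, and tested against each
    instrument.
    """
    out: list[AssociationResult] = []
    for direction, members in connection_sets(model).items():
        members = [m for m in members if m in feature_columns]
        if not members:
            continue
        set_coh = features[members].to_numpy(dtype=float).mean(axis=1)
        label = members[0] if len(members) == 1 else (
            f"{direction}-set(" + "+".join(members) + ")"
        )
        try:
            z = zscore_coherence(set_coh)
        except AssociationError:
            continue  # too few participants or constant coherence
        for inst in instruments:
            col = f"{inst}_pct_change"
            if col not in features.columns:
                continue
            try:
                out.append(
                    correlate_symptoms(
                        z, features[col], connection=label,
                        instrument=inst, method=method,
                    )
                )
            except AssociationError:
                continue
    return out
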