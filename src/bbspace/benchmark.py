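"""Spatial benchmarking of coefficient maps and two-stage patient selection.

A symptom-neural coefficient map is anchored by correlating it against
independent reference maps in the same parcel space (pharmacological
contrast maps, gene-expression topographies).  Rank (Spearman) correlation
is the default similarity since reference maps live on arbitrary scales;
Pearson is available by flag.  Maps in different parcel spaces must be
symmetrized explicitly before comparison — there is no implicit resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = ["ReferenceMap", "map_similarity", "pharma_contrast", "select_patients",
           "similarity_distribution"]

_SPACE_BY_LENGTH = {718: "718-parcel", 360: "360-cortex", 180: "180-symmetrized"}


@dataclass
class ReferenceMap:
    """A labeled parcel-space vector used as a benchmarking target."""

    values: np.ndarray
    label: str = ""
    space: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 1:
            raise ValueError("reference map must be a 1-D parcel vector")
        if not np.isfinite(self.values).all():
            raise ValueError("reference map contains non-finite values")
        inferred = _SPACE_BY_LENGTH.get(self.values.shape[0], f"{self.values.shape[0]}-parcel")
        if self.space is None:
            self.space = inferred
        elif self.space != inferred:
            raise ValueError(f"space {self.space!r} inconsistent with length {self.values.shape[0]}")

    def __len__(self) -> int:
        return self.values.shape[0]


def _as_values(m) -> np.ndarray:
    return m.values if isinstance(m, ReferenceMap) else np.asarray(m, float)


def map_similarity(a, b, method: str = "spearman", subset=None) -> float:
    """Spatial similarity between two parcel vectors in [-1, 1].

    ``method`` is ``"spearman"`` (rank correlation, default) or
    ``"pearson"``; ``subset`` optionally restricts both maps to a common
    parcel index set before correlating.
    """
    x, y = _as_values(a), _as_values(b)
    if subset is not None:
        subset = np.asarray(subset, int)
        x, y = x[subset], y[subset]
    if x.shape != y.shape:
        raise ValueError("maps have different lengths")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 parcels to correlate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant map; correlation undefined")
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def pharma_contrast(gbc_drug, gbc_placebo, paired: bool = True) -> ReferenceMap:
    """Drug-versus-placebo GBC contrast as a Z-scored t-map.

    Computes a per-parcel paired (default) or independent-samples t
    statistic between the two GBC matrices, then Z-scores the t values
    across parcels, yielding a unit-scale reference topography.
    """
    drug = np.asarray(getattr(gbc_drug, "values", gbc_drug), float)
    plac = np.asarray(getattr(gbc_placebo, "values", gbc_placebo), float)
    if drug.shape[1] != plac.shape[1]:
        raise ValueError("parcel dimensions differ between conditions")
    if paired:
        if drug.shape[0] != plac.shape[0]:
            raise ValueError("paired contrast requires matched subjects")
        sub_d = getattr(gbc_drug, "subject_ids", None)
        sub_p = getattr(gbc_placebo, "subject_ids", None)
        if sub_d is not None and sub_p is not None and list(sub_d) != list(sub_p):
            raise ValueError("paired contrast requires identical subject ordering")
        diff = drug - plac
        if np.allclose(diff, 0):
            t = np.zeros(drug.shape[1])
        else:
            t = stats.ttest_rel(drug, plac, axis=0).statistic
            t = np.nan_to_num(t, nan=0.0)
    else:
        t = stats.ttest_ind(drug, plac, axis=0).statistic
        t = np.nan_to_num(t, nan=0.0)
    sd = t.std()
    z = (t - t.mean()) / sd if sd > 0 else t - t.mean()
    return ReferenceMap(z, label="pharma_contrast")


def select_patients(
    scores: np.ndarray,
    delta_values: np.ndarray,
    beta_map: np.ndarray,
    symptom_threshold: float,
    neural_threshold: float,
    subset=None,
    subject_ids=None,
    method: str = "spearman",
):
    """Two-stage patient selection on a bi-directional symptom axis.

    Stage 1 keeps subjects with ``|score| >= symptom_threshold`` (both poles
    of the axis are symptomatic).  Stage 2 keeps those whose per-subject
    neural-similarity (correlation between their GBC deviation map and the
    reference coefficient map over ``subset``) has magnitude at or above
    ``neural_threshold`` and sign consistent with the sign of their score.

    Returns (selected indices or ids, scores, similarities).
    """
    if symptom_threshold < 0 or neural_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    scores = np.asarray(scores, float)
    delta = np.asarray(delta_values, float)
    beta = _as_values(beta_map)
    if subset is not None and len(np.asarray(subset)) == 0:
        raise ValueError("empty parcel subset")
    n = scores.shape[0]
    sims = np.array([map_similarity(delta[i], beta, method=method, subset=subset)
                     for i in range(n)])
    stage1 = np.abs(scores) >= symptom_threshold
    keep = stage1 & (np.abs(sims) >= neural_threshold) & (np.sign(sims) == np.sign(scores))
    idx = np.flatnonzero(keep)
    ids = idx if subject_ids is None else [subject_ids[i] for i in idx]
    return ids, scores[idx], sims[idx]


def similarity_distribution(bbs_map, reference_dir, method: str = "spearman"):
    """Correlate one coefficient map against a directory of reference vectors.

    Reads every ``*.tsv`` two-column (parcel_id, value) file under
    ``reference_dir`` and returns the similarity per reference, sorted
    descending — the ranked-distribution benchmarking readout.
    """
    from . import io as bio

    out = {}
    for path in sorted(Path(reference_dir).glob("*.tsv")):
        ref = bio.read_vector(path)
        out[path.stem] = map_similarity(bbs_map, ref.to_numpy(), method=method)
    return dict(sorted(out.items(), key=lambda kv: -kv[1]))
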