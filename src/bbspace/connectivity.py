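"""Frame scrubbing, parcellation and global brain connectivity (GBC).

GBC summarizes each region's resting-state functional connectivity as the
mean Fisher-z-transformed Pearson correlation with every other region.  The
parcellate-before-GBC ordering (average member-vertex series first, then
correlate parcels) is the supported workflow; the same ``compute_gbc``
operation applies unchanged to dense vertex-level matrices.

Units: GBC values are Fisher z (atanh r), not raw correlations.  The
self-correlation term (r = 1, atanh infinite) is excluded from the average,
which is the only finite reading of a "mean connectivity with all other
regions" summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameStats",
    "ParcelTimeSeries",
    "GBCMatrix",
    "scrub_mask",
    "frame_flag_fraction",
    "parcellate",
    "compute_gbc",
    "symmetrize_cortex",
    "residualize",
]

#: frame-displacement threshold in mm (assumes a 50 mm cortical sphere radius)
DEFAULT_FD_THRESHOLD = 0.5
#: intensity-RMS threshold as a multiple of the per-scan median
DEFAULT_RMS_MULTIPLIER = 1.6
#: subjects with more than this fraction of frames flagged should be excluded
MAX_FLAGGED_FRACTION = 0.5


@dataclass
class FrameStats:
    """Per-frame motion statistics for one BOLD run.

    frame_displacement
        Sum of displacement across the six rigid-body motion parameters, mm.
    intensity_rms
        Root-mean-square of frame-to-frame intensity change, normalized by
        mean intensity.
    """

    frame_displacement: np.ndarray
    intensity_rms: np.ndarray

    def __post_init__(self):
        self.frame_displacement = np.asarray(self.frame_displacement, float)
        self.intensity_rms = np.asarray(self.intensity_rms, float)
        if self.frame_displacement.ndim != 1 or self.intensity_rms.ndim != 1:
            raise ValueError("frame statistics must be 1-D vectors")
        if len(self.frame_displacement) != len(self.intensity_rms):
            raise ValueError("frame_displacement and intensity_rms differ in length")
        if len(self.frame_displacement) == 0:
            raise ValueError("empty frame statistics")
        if (self.frame_displacement < 0).any() or (self.intensity_rms < 0).any():
            raise ValueError("frame statistics must be non-negative")


@dataclass
class ParcelTimeSeries:
    """Region-by-timepoint matrix with a fixed parcel ordering."""

    values: np.ndarray
    parcel_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("values must be parcels x timepoints")
        if not self.parcel_ids:
            self.parcel_ids = [f"p{i}" for i in range(self.values.shape[0])]
        if len(self.parcel_ids) != self.values.shape[0]:
            raise ValueError("parcel_ids length does not match values")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contain non-finite values")


@dataclass
class GBCMatrix:
    """Subjects x parcels GBC values in Fisher-z units."""

    values: np.ndarray
    parcel_ids: list = field(default_factory=list)
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("values must be subjects x parcels")
        n, p = self.values.shape
        if not self.parcel_ids:
            self.parcel_ids = [f"p{i}" for i in range(p)]
        if not self.subject_ids:
            self.subject_ids = [f"s{i}" for i in range(n)]
        if len(self.parcel_ids) != p or len(self.subject_ids) != n:
            raise ValueError("label lengths do not match value dimensions")
        if not np.isfinite(self.values).all():
            raise ValueError("GBC values contain non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


def _flagged(stats: FrameStats, fd_threshold: float, rms_multiplier: float) -> np.ndarray:
    med = np.median(stats.intensity_rms)
    return (stats.frame_displacement > fd_threshold) | (
        stats.intensity_rms > rms_multiplier * med
    )


def scrub_mask(
    stats: FrameStats,
    fd_threshold: float = DEFAULT_FD_THRESHOLD,
    rms_multiplier: float = DEFAULT_RMS_MULTIPLIER,
) -> np.ndarray:
    """Boolean keep-mask for movement scrubbing.

    A frame is flagged when frame displacement exceeds ``fd_threshold`` (mm)
    or intensity RMS exceeds ``rms_multiplier`` times the median RMS of the
    scan.  Flagged frames plus the frame immediately preceding and following
    each are discarded.  Neighbor removal is single-pass: a frame removed
    only as a neighbor does not itself spawn further removals.

    Returns a boolean vector, True for frames to keep.
    """
    if fd_threshold <= 0 or rms_multiplier <= 0:
        raise ValueError("thresholds must be positive")
    flagged = _flagged(stats, fd_threshold, rms_multiplier)
    discard = flagged.copy()
    discard[:-1] |= flagged[1:]
    discard[1:] |= flagged[:-1]
    return ~discard


def frame_flag_fraction(
    stats: FrameStats,
    fd_threshold: float = DEFAULT_FD_THRESHOLD,
    rms_multiplier: float = DEFAULT_RMS_MULTIPLIER,
) -> float:
    """Fraction of frames flagged (before neighbor expansion).

    Subjects with a fraction above :data:`MAX_FLAGGED_FRACTION` should be
    excluded from analysis.
    """
    return float(_flagged(stats, fd_threshold, rms_multiplier).mean())


def parcellate(dense_series: np.ndarray, parcel_assignment, parcel_ids=None) -> ParcelTimeSeries:
    """Average member-vertex time series into parcel time series.

    Parameters
    ----------
    dense_series : vertices x timepoints array
    parcel_assignment : sequence mapping each vertex to a parcel id
    parcel_ids : optional explicit parcel ordering; defaults to order of
        first appearance in ``parcel_assignment``.
    """
    dense = np.asarray(dense_series, float)
    assignment = np.asarray(parcel_assignment)
    if dense.ndim != 2 or len(assignment) != dense.shape[0]:
        raise ValueError("parcel_assignment must have one entry per vertex")
    if parcel_ids is None:
        parcel_ids = list(dict.fromkeys(assignment.tolist()))
    values = np.empty((len(parcel_ids), dense.shape[1]))
    for i, pid in enumerate(parcel_ids):
        members = assignment == pid
        if not members.any():
            raise ValueError(f"parcel {pid!r} has no assigned vertices")
        values[i] = dense[members].mean(axis=0)
    return ParcelTimeSeries(values, list(parcel_ids))


def compute_gbc(series: ParcelTimeSeries) -> np.ndarray:
    """Per-parcel GBC: mean Fisher-z correlation with all other parcels.

    Requires at least three timepoints and nonzero variance in every parcel
    series; a zero-variance parcel makes the correlation undefined and
    raises an error naming the parcel.
    """
    values = series.values
    if values.shape[1] < 3:
        raise ValueError("need at least 3 timepoints to compute GBC")
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = series.parcel_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"parcel {bad!r} has zero variance; correlation undefined")
    r = np.corrcoef(values)
    np.fill_diagonal(r, 0.0)
    z = np.arctanh(np.clip(r, -1.0, 1.0))
    return z.sum(axis=1) / (values.shape[0] - 1)


def symmetrize_cortex(cortical_map: np.ndarray, homologue_pairs) -> np.ndarray:
    """Average homologous left/right cortical parcels into one value per pair.

    ``homologue_pairs`` is a list of (left, right) index pairs that must form
    a perfect matching of the input parcels.  Output order follows the pair
    list.
    """
    m = np.asarray(cortical_map, float)
    pairs = [(int(l), int(r)) for l, r in homologue_pairs]
    used = [i for pair in pairs for i in pair]
    if sorted(used) != list(range(m.shape[0])):
        raise ValueError("homologue pairs do not form a perfect matching of the parcels")
    left = np.array([l for l, _ in pairs])
    right = np.array([r for _, r in pairs])
    return 0.5 * (m[left] + m[right])


def residualize(series: ParcelTimeSeries, regressors: np.ndarray) -> ParcelTimeSeries:
    """OLS-residualize each parcel series on a nuisance regressor matrix.

    ``regressors`` is timepoints x k (e.g. ventricle / white-matter / global
    signals and their derivatives); an intercept column is always added.
    """
    t = series.values.shape[1]
    reg = np.asarray(regressors, float)
    if reg.ndim == 1:
        reg = reg[:, None]
    if reg.shape[0] != t:
        raise ValueError("regressor rows must match timepoints")
    design = np.column_stack([np.ones(t), reg])
    beta, *_ = np.linalg.lstsq(design, series.values.T, rcond=None)
    resid = series.values.T - design @ beta
    return ParcelTimeSeries(resid.T, list(series.parcel_ids))
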