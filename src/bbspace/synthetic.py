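"""Synthetic cohorts with planted symptom-neural structure.

The generator emulates the statistical skeleton of a multi-site psychosis
cohort: a battery of correlated clinical items driven by a handful of latent
symptom factors, and per-subject parcellated GBC maps whose inter-subject
variance is dominated by large symptom-irrelevant shared components with a
smaller set of parcels linearly coupled to the latent factors.  Every
planted object (factor scores, item loadings, coefficient maps, shared
components) is recorded so downstream estimators can be scored against
ground truth.

Default condition choices
-------------------------
* five latent factors with decaying variance fractions summing to ~0.52 of
  item variance, so a cohort of a few hundred subjects yields exactly five
  permutation-significant symptom components;
* three shared symptom-irrelevant neural components carrying ~45% of parcel
  variance (the leading one ~22%), so the first neural PC always dominates
  any symptom-coupled component;
* each factor coupled to its own random set of 60 parcels (of 718) with
  coupling strength 0.7, making full-sample univariate coefficient maps
  recoverable at n in the hundreds while single-subject neural prediction
  stays far from perfect.

All randomness flows from one seed through named sub-streams, so individual
blocks (factors, maps, noise, labels) are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .benchmark import ReferenceMap
from .connectivity import GBCMatrix
from .symptom_pca import SymptomMatrix
from . import io as bio

__all__ = ["CohortConfig", "CohortTruth", "SyntheticCohort", "generate_cohort",
           "generate_reference_map", "write_cohort"]

_DEFAULT_FRACTIONS = (0.16, 0.12, 0.10, 0.08, 0.06)


@dataclass
class CohortConfig:
    """Generative parameters for one synthetic cohort.

    latent_variance_fractions
        Per-factor proportion of item variance; entries in (0, 1), sum < 1
        (the remainder is item-level noise).
    item_noise_sd
        Scale factor on the variance-completing item noise (each item's
        noise SD is ``item_noise_sd * sqrt(1 - communality)``); the default
        1.0 gives unit item variance in the population, 0 gives noiseless
        rank-``n_latent`` items.
    coupling_strengths
        Per-factor scalar multiplying ``factor_score x planted map`` in the
        GBC model (map entries are standard normal on the signal parcels).
    signal_parcel_sets
        Per-factor parcel index lists carrying the coupling; ``None`` draws
        disjoint random sets of ``min(60, n_parcels // (2 * n_latent))``
        parcels each.
    shared_neural_variance_fraction
        Total parcel-variance share of the symptom-irrelevant shared
        components (split geometrically across components).
    site_item_sd, site_parcel_sd
        SDs of additive per-site intercepts; 0 disables site effects.
    """

    n_subjects: int = 436
    n_items: int = 36
    n_parcels: int = 718
    n_latent: int = 5
    latent_variance_fractions: tuple = _DEFAULT_FRACTIONS
    item_noise_sd: float | None = None
    n_shared_neural_pcs: int = 3
    shared_neural_variance_fraction: float = 0.45
    coupling_strengths: tuple = (0.7, 0.7, 0.7, 0.7, 0.7)
    signal_parcel_sets: list | None = None
    parcel_noise_sd: float | None = None
    factor_correlation: np.ndarray | None = None
    n_sites: int = 6
    n_groups: int = 3
    site_item_sd: float = 0.0
    site_parcel_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        frac = np.asarray(self.latent_variance_fractions, float)
        if len(frac) != self.n_latent:
            raise ValueError("latent_variance_fractions length must equal n_latent")
        if ((frac <= 0) | (frac >= 1)).any() or frac.sum() >= 1:
            raise ValueError("latent_variance_fractions must lie in (0,1) and sum to < 1")
        if len(self.coupling_strengths) != self.n_latent:
            raise ValueError("coupling_strengths length must equal n_latent")
        if self.signal_parcel_sets is not None:
            if len(self.signal_parcel_sets) != self.n_latent:
                raise ValueError("signal_parcel_sets length must equal n_latent")
            for s in self.signal_parcel_sets:
                arr = np.asarray(s, int)
                if arr.size and (arr.min() < 0 or arr.max() >= self.n_parcels):
                    raise ValueError("signal parcel indices out of range")
        if self.item_noise_sd is None:
            self.item_noise_sd = 1.0
        if self.parcel_noise_sd is None:
            self.parcel_noise_sd = float(np.sqrt(1.0 - self.shared_neural_variance_fraction))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class CohortTruth:
    """Planted ground-truth objects for one cohort."""

    item_loadings: np.ndarray        # items x factors
    factor_scores: np.ndarray        # subjects x factors
    coefficient_maps: np.ndarray     # factors x parcels (zero off signal sets)
    signal_parcel_sets: list         # per-factor index arrays
    shared_maps: np.ndarray          # shared components x parcels
    shared_scores: np.ndarray        # subjects x shared components
    gbc_offset: np.ndarray           # parcel baseline map


@dataclass
class SyntheticCohort:
    symptoms: SymptomMatrix
    gbc: GBCMatrix
    truth: CohortTruth
    config: CohortConfig = field(repr=False, default=None)


def _streams(seed: int, names: list[str]) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort from the planted generative model.

    Symptom items are ``factor scores x loadings + noise`` standardized per
    item; GBC is ``baseline + shared components + coupled factor signal +
    parcel noise``.  Diagnosis labels are assigned by quantiles of the first
    factor score (overlapping group distributions); labels do not enter the
    neural generative model and exist only to stratify resampling.
    """
    cfg = config
    rng = _streams(cfg.seed, [
        "factors", "loadings", "item_noise", "signal_sets", "maps",
        "shared", "parcel_noise", "labels", "offset", "site",
    ])
    n, k = cfg.n_subjects, cfg.n_latent
    frac = np.asarray(cfg.latent_variance_fractions, float)

    # latent factor scores (independent standard normals unless an oblique
    # factor correlation is requested)
    z = rng["factors"].standard_normal((n, k))
    if cfg.factor_correlation is not None:
        chol = np.linalg.cholesky(np.asarray(cfg.factor_correlation, float))
        z = z @ chol.T

    # item loadings: each factor loads on its own disjoint block of items
    # (mirroring distinct clinical subscales), with random magnitudes and
    # signs.  Loadings are expressed directly in the unit-variance item
    # metric (item = a * factor + noise_scale * sqrt(1 - a^2) * eps), so
    # with the default noise scale the population item correlation matrix
    # is exactly block structured with factor eigenvalues
    # ``frac * n_items`` — disjoint support keeps factor directions
    # orthogonal even after per-item standardization.
    blocks = np.array_split(rng["loadings"].permutation(cfg.n_items), k)
    load = np.zeros((cfg.n_items, k))
    for f, block in enumerate(blocks):
        target = frac[f] * cfg.n_items
        if target > 0.95 * len(block):
            raise ValueError(
                f"latent factor {f} needs item variance {target:.2f} but only "
                f"{len(block)} items are available in its block"
            )
        w2 = (0.75 + 0.5 * rng["loadings"].random(len(block))) ** 2
        for _ in range(20):  # scale to the target sum with loadings capped at 0.95
            w2 = np.minimum(w2 * target / w2.sum(), 0.95)
            if abs(w2.sum() - target) < 1e-12:
                break
        a = np.sqrt(w2) * rng["loadings"].choice([-1.0, 1.0], len(block))
        load[block, f] = a

    unique_sd = np.sqrt(np.clip(1.0 - (load**2).sum(axis=1), 0.0, None))
    items = z @ load.T + cfg.item_noise_sd * unique_sd * \
        rng["item_noise"].standard_normal((n, cfg.n_items))

    # site and diagnosis labels
    site_idx = rng["site"].permutation(np.arange(n) % cfg.n_sites)
    if cfg.site_item_sd > 0:
        items += rng["site"].normal(0, cfg.site_item_sd, (cfg.n_sites, cfg.n_items))[site_idx]
    order = np.argsort(z[:, 0], kind="stable")
    group_of_rank = np.minimum((np.arange(n) * cfg.n_groups) // n, cfg.n_groups - 1)
    diagnosis_idx = np.empty(n, int)
    diagnosis_idx[order] = group_of_rank

    sd = items.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    items = (items - items.mean(axis=0)) / sd

    # signal parcel sets
    if cfg.signal_parcel_sets is None:
        per = max(1, min(60, cfg.n_parcels // (2 * k)))
        chosen = rng["signal_sets"].choice(cfg.n_parcels, size=per * k, replace=False)
        sets = [np.sort(chosen[f * per:(f + 1) * per]) for f in range(k)]
    else:
        sets = [np.sort(np.asarray(s, int)) for s in cfg.signal_parcel_sets]

    # planted coefficient maps: signed near-unit magnitudes on the signal
    # set, so every signal parcel carries a comparable, resolvable effect
    maps = np.zeros((k, cfg.n_parcels))
    for f, s in enumerate(sets):
        mag = 1.0 + 0.2 * rng["maps"].uniform(-1.0, 1.0, len(s))
        maps[f, s] = mag * rng["maps"].choice([-1.0, 1.0], len(s))

    # shared symptom-irrelevant components with geometrically decaying shares
    n_shared = cfg.n_shared_neural_pcs
    shares = 0.6 ** np.arange(n_shared)
    shares = cfg.shared_neural_variance_fraction * shares / shares.sum()
    shared_maps = rng["shared"].standard_normal((n_shared, cfg.n_parcels))
    shared_scores = rng["shared"].standard_normal((n, n_shared))
    shared_signal = (shared_scores * np.sqrt(shares)) @ shared_maps

    offset = 0.5 + 0.3 * rng["offset"].standard_normal(cfg.n_parcels)
    coupling = (z * np.asarray(cfg.coupling_strengths)) @ maps
    noise = cfg.parcel_noise_sd * rng["parcel_noise"].standard_normal((n, cfg.n_parcels))
    gbc = offset + shared_signal + coupling + noise
    if cfg.site_parcel_sd > 0:
        gbc += rng["site"].normal(0, cfg.site_parcel_sd, (cfg.n_sites, cfg.n_parcels))[site_idx]

    subject_ids = [f"sub{i:05d}" for i in range(n)]
    group_names = [f"G{g + 1}" for g in range(cfg.n_groups)]
    diagnosis = np.array([group_names[g] for g in diagnosis_idx])
    site = np.array([f"site{s + 1}" for s in site_idx])

    symptoms = SymptomMatrix(
        items, [f"item{i + 1:02d}" for i in range(cfg.n_items)],
        subject_ids, diagnosis, site,
    )
    gbc_matrix = GBCMatrix(gbc, [f"parcel{i + 1:04d}" for i in range(cfg.n_parcels)], subject_ids)
    truth = CohortTruth(load, z, maps, sets, shared_maps, shared_scores, offset)
    return SyntheticCohort(symptoms, gbc_matrix, truth, cfg)


def generate_reference_map(truth_map: np.ndarray, target_similarity: float, seed: int = 0) -> ReferenceMap:
    """Construct a parcel vector with a chosen Pearson correlation to a map.

    Mixes the (centered, normalized) source map with an orthogonal random
    residual so the in-sample correlation equals ``target_similarity``
    exactly up to floating point.  Stands in for external reference maps
    (pharmacological contrasts, gene-expression patterns) at a controlled
    similarity level.
    """
    s = float(target_similarity)
    if abs(s) > 1:
        raise ValueError("target_similarity must lie in [-1, 1]")
    t = np.asarray(truth_map, float)
    t0 = t - t.mean()
    norm = np.linalg.norm(t0)
    if norm == 0:
        raise ValueError("truth_map is constant; correlation undefined")
    t0 = t0 / norm
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(t.shape[0])
    g = g - g.mean()
    g = g - (g @ t0) * t0
    gn = np.linalg.norm(g)
    if gn < 1e-8:  # draw (anti)parallel to the map; reroll deterministically
        alt = np.random.default_rng(np.random.SeedSequence((seed, 1)).generate_state(1)[0])
        g = alt.standard_normal(t.shape[0])
        g = g - g.mean()
        g = g - (g @ t0) * t0
        gn = np.linalg.norm(g)
    values = s * t0 + np.sqrt(max(0.0, 1.0 - s * s)) * g / gn
    return ReferenceMap(values, label=f"synthetic_similarity_{s:+.2f}")


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write symptoms, GBC, labels and planted truth as tab-delimited text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sym, gbc, truth = cohort.symptoms, cohort.gbc, cohort.truth
    bio.write_matrix(pd.DataFrame(sym.values, index=sym.subject_ids, columns=sym.item_ids),
                     out / "symptoms.tsv")
    bio.write_matrix(pd.DataFrame(gbc.values, index=gbc.subject_ids, columns=gbc.parcel_ids),
                     out / "gbc.tsv")
    labels = pd.DataFrame({"diagnosis": sym.diagnosis, "site": sym.site}, index=sym.subject_ids)
    labels.to_csv(out / "labels.tsv", sep="\t", index_label="id")
    k = truth.factor_scores.shape[1]
    factors = [f"factor{f + 1}" for f in range(k)]
    bio.write_matrix(pd.DataFrame(truth.factor_scores, index=sym.subject_ids, columns=factors),
                     out / "truth_factor_scores.tsv")
    bio.write_matrix(pd.DataFrame(truth.item_loadings, index=sym.item_ids, columns=factors),
                     out / "truth_item_loadings.tsv")
    bio.write_matrix(pd.DataFrame(truth.coefficient_maps.T, index=gbc.parcel_ids, columns=factors),
                     out / "truth_coefficient_maps.tsv")
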