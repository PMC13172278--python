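"""Tiered species distribution modeling.

Species are routed by cleaned record count into three strategies:

* **tier 1** (>= 6 records): an ensemble of interchangeable member families
  evaluated by 5-fold cross-validation repeated 5 times, retained at mean
  TSS >= 0.7, TSS-weighted into a continuous suitability map, and binarized
  at the threshold that maximizes sensitivity + specificity (maxSSS);
* **tier 2** (2-5 records): presence-only plausibility models in
  environmental space, each binarized at the 5% quantile of its scores at
  the presence points, filtered at AUC >= 0.7 against background, and
  combined by union;
* **tier 3** (1 record): a fixed-radius buffer around the single record,
  held static under every future scenario.

The three built-in tier-1 families (logistic-linear, percentile envelope,
kernel-density ratio) are deliberately simple; the ensemble framework —
cross-validation, TSS retention, TSS weighting, maxSSS binarization,
training-threshold projection — is the specified computation and is
independent of the family roster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .evaluation import ModelEvaluation, evaluate_predictions
from .grids import EnvStack, GridSpec

__all__ = [
    "SDMConfig",
    "SuitabilityMap",
    "SpeciesRange",
    "RangeAtlas",
    "sample_background",
    "fit_tier1_ensemble",
    "fit_tier2_small",
    "buffer_single",
    "binarize_range",
    "build_range_atlas",
]


@dataclass(frozen=True)
class SDMConfig:
    """Knobs of the tiered modeling protocol (defaults are the study values)."""

    min_records_tier1: int = 6
    background_n: int = 1000
    tss_retain: float = 0.7
    auc_retain: float = 0.7
    presence_quantile: float = 0.05
    buffer_km: float = 5.0
    cv_folds: int = 5
    cv_repeats: int = 5
    kde_bandwidth_floor: float = 0.1
    envelope_tau_floor: float = 0.5


@dataclass
class SuitabilityMap:
    species_id: str
    scenario_tag: str
    values: np.ndarray  # in [0, 1] within the analysis mask
    weights: dict[str, float] = field(default_factory=dict)


@dataclass
class SpeciesRange:
    species_id: str
    scenario_tag: str
    presence: np.ndarray  # boolean grid, subset of the analysis mask
    tier: str = ""
    threshold: float = float("nan")
    flags: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return int(self.presence.sum())


# --------------------------------------------------------------------------
# helpers


def sample_background(
    grid: GridSpec, presence_cells: set[tuple[int, int]], n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform background cells from the analysis mask, excluding presences."""
    rows, cols = np.nonzero(grid.analysis_mask)
    free = np.array([(r, c) not in presence_cells for r, c in zip(rows, cols)])
    rows, cols = rows[free], cols[free]
    k = min(n, len(rows))
    idx = rng.choice(len(rows), size=k, replace=False)
    return rows[idx], cols[idx]


class _Scaler:
    """Per-variable standardization frozen at training time."""

    def fit(self, X: np.ndarray) -> "_Scaler":
        self.mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu) / self.sd


class DiagonalKde:
    """Product-Gaussian KDE with per-dimension bandwidths and a floor.

    Robust to tiny samples (n < d, or identical points): bandwidths follow
    Silverman's rule per dimension but never drop below ``bw_floor``, so the
    density stays finite and smooth even for two coincident presences.
    """

    def __init__(self, X: np.ndarray, bw_floor: float = 0.1):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        n, d = self.X.shape
        sd = self.X.std(axis=0, ddof=1) if n > 1 else np.zeros(d)
        factor = (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))
        self.bw = np.maximum(sd * factor, bw_floor)

    def pdf(self, Y: np.ndarray, chunk: int = 8192) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        n, d = self.X.shape
        norm = 1.0 / (n * np.prod(self.bw * np.sqrt(2 * np.pi)))
        Xs = self.X / self.bw
        x_sq = (Xs**2).sum(axis=1)
        out = np.empty(len(Y))
        for start in range(0, len(Y), chunk):
            Ys = Y[start : start + chunk] / self.bw
            # squared distances via the expansion |y|^2 + |x|^2 - 2 y.x
            sq = (Ys**2).sum(axis=1)[:, None] + x_sq[None, :] - 2.0 * (Ys @ Xs.T)
            np.maximum(sq, 0.0, out=sq)
            out[start : start + chunk] = norm * np.exp(-0.5 * sq).sum(axis=1)
        return out


# --------------------------------------------------------------------------
# tier-1 member families (fit on labeled presence/background points)


class LogisticLinearFamily:
    name = "logistic"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LogisticLinearFamily":
        self._clf = LogisticRegression(max_iter=1000)
        self._clf.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._clf.predict_proba(X)[:, 1]


class PercentileEnvelopeFamily:
    """BIOCLIM-style envelope: per-variable percentile position among the
    presences, folded so the presence median scores 1 and the tails 0; the
    cell score is the minimum over variables."""

    name = "envelope"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PercentileEnvelopeFamily":
        self._sorted = [np.sort(col) for col in X[y == 1].T]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = np.ones(len(X))
        for k, col in enumerate(self._sorted):
            f = np.searchsorted(col, X[:, k], side="right") / len(col)
            scores = np.minimum(scores, 1.0 - 2.0 * np.abs(f - 0.5))
        return scores


class KdeRatioFamily:
    """Density-ratio score p/(p+b) from presence and background KDEs."""

    name = "kde_ratio"

    def __init__(self, bw_floor: float = 0.1):
        self.bw_floor = bw_floor

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KdeRatioFamily":
        self._kp = DiagonalKde(X[y == 1], self.bw_floor)
        self._kb = DiagonalKde(X[y == 0], self.bw_floor)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self._kp.pdf(X)
        b = self._kb.pdf(X)
        return p / (p + b + 1e-300)


def default_tier1_families(config: SDMConfig) -> list:
    return [LogisticLinearFamily(), PercentileEnvelopeFamily(), KdeRatioFamily(config.kde_bandwidth_floor)]


# --------------------------------------------------------------------------
# tier 1


@dataclass
class Tier1Ensemble:
    """A fitted TSS-weighted ensemble for one species.

    Carries the refit member families, their cross-validation record, the
    ensemble rescaling and the maxSSS threshold, so future scenarios are
    projected with the training-period threshold and scaling (no
    re-thresholding).
    """

    species_id: str
    layer_names: list[str]
    scaler: _Scaler
    members: list
    weights: dict[str, float]
    cv_table: pd.DataFrame
    evaluation: ModelEvaluation
    rescale: tuple[float, float]
    fallback: bool
    config: SDMConfig

    def _ensemble_scores(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(X)
        acc = np.zeros(len(X))
        for fam in self.members:
            acc += self.weights[fam.name] * fam.predict(Xs)
        lo, hi = self.rescale
        if hi > lo:
            acc = (acc - lo) / (hi - lo)
        return np.clip(acc, 0.0, 1.0)

    def predict_suitability(self, env: EnvStack) -> SuitabilityMap:
        missing = [n for n in self.layer_names if n not in env.layers]
        if missing:
            raise KeyError(f"future stack is missing trained layers: {missing}")
        grid = env.grid
        out = grid.zeros()
        mask = grid.analysis_mask
        rows, cols = np.nonzero(mask)
        out[rows, cols] = self._ensemble_scores(env.values_at(rows, cols, self.layer_names))
        return SuitabilityMap(self.species_id, env.scenario_tag, out, dict(self.weights))

    def predict_range(self, env: EnvStack) -> SpeciesRange:
        suit = self.predict_suitability(env)
        rng = binarize_range(suit, self.evaluation, env.grid)
        rng.tier = "tier1"
        if self.fallback:
            rng.flags.append("tss_fallback")
        return rng


def _cv_fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::folds] for i in range(folds)]


def fit_tier1_ensemble(
    presence_rc: np.ndarray,
    env: EnvStack,
    background_rc: np.ndarray,
    config: SDMConfig = SDMConfig(),
    seed: int = 0,
    species_id: str = "",
    families: list | None = None,
) -> Tier1Ensemble:
    """Fit the cross-validated, TSS-weighted tier-1 ensemble.

    ``presence_rc`` and ``background_rc`` are (n, 2) arrays of (row, col)
    cells.  Each member family is scored by 5-fold CV repeated 5 times
    (reduced towards leave-one-out when records are scarce); families with
    mean TSS >= ``tss_retain`` are refit on all records and averaged with
    TSS weights; if none qualify the best family is kept with a fallback
    flag.
    """
    rng = np.random.default_rng(seed)
    families = default_tier1_families(config) if families is None else families
    layer_names = env.layer_names
    Xp = env.values_at(presence_rc[:, 0], presence_rc[:, 1], layer_names)
    Xb = env.values_at(background_rc[:, 0], background_rc[:, 1], layer_names)
    scaler = _Scaler().fit(np.vstack([Xp, Xb]))
    Zp, Zb = scaler.transform(Xp), scaler.transform(Xb)

    folds = config.cv_folds
    if len(Zp) < folds:
        warnings.warn(
            f"{species_id}: only {len(Zp)} records; fold count reduced to leave-one-out"
        )
        folds = max(2, len(Zp))

    records = []
    for rep in range(config.cv_repeats):
        p_folds = _cv_fold_indices(len(Zp), folds, rng)
        b_folds = _cv_fold_indices(len(Zb), folds, rng)
        for k in range(folds):
            p_test, b_test = p_folds[k], b_folds[k]
            p_train = np.setdiff1d(np.arange(len(Zp)), p_test)
            b_train = np.setdiff1d(np.arange(len(Zb)), b_test)
            X_train = np.vstack([Zp[p_train], Zb[b_train]])
            y_train = np.concatenate([np.ones(len(p_train)), np.zeros(len(b_train))])
            for fam in families:
                fam.fit(X_train, y_train)
                ev = evaluate_predictions(fam.predict(Zp[p_test]), fam.predict(Zb[b_test]))
                records.append({"family": fam.name, "repeat": rep, "fold": k, "tss": ev.tss, "auc": ev.auc})
    cv_table = pd.DataFrame(records)
    means = cv_table.groupby("family", sort=False)[["tss", "auc"]].mean()

    retained = [f for f in families if means.loc[f.name, "tss"] >= config.tss_retain]
    fallback = False
    if not retained:
        best = means["tss"].idxmax()
        retained = [f for f in families if f.name == best]
        fallback = True
        warnings.warn(f"{species_id}: no family reached TSS {config.tss_retain}; falling back to {best!r}")
    total = sum(means.loc[f.name, "tss"] for f in retained)
    weights = {f.name: float(means.loc[f.name, "tss"] / total) if total > 0 else 1.0 / len(retained) for f in retained}

    X_all = np.vstack([Zp, Zb])
    y_all = np.concatenate([np.ones(len(Zp)), np.zeros(len(Zb))])
    for fam in retained:
        fam.fit(X_all, y_all)

    # raw ensemble over the analysis mask fixes the [0, 1] rescaling
    mask = env.grid.analysis_mask
    rows, cols = np.nonzero(mask)
    Z_grid = scaler.transform(env.values_at(rows, cols, layer_names))
    raw = np.zeros(len(rows))
    for fam in retained:
        raw += weights[fam.name] * fam.predict(Z_grid)
    rescale = (float(raw.min()), float(raw.max()))

    ens = Tier1Ensemble(
        species_id=species_id,
        layer_names=layer_names,
        scaler=scaler,
        members=retained,
        weights=weights,
        cv_table=cv_table,
        evaluation=ModelEvaluation(0, 0, 0, 0, 0),  # placeholder, set below
        rescale=rescale,
        fallback=fallback,
        config=config,
    )
    ens.evaluation = evaluate_predictions(ens._ensemble_scores(Xp), ens._ensemble_scores(Xb))
    return ens


def binarize_range(suit: SuitabilityMap, evaluation: ModelEvaluation, grid: GridSpec) -> SpeciesRange:
    """Threshold a suitability map at the evaluation's maxSSS threshold."""
    if not np.isfinite(evaluation.threshold):
        raise ValueError("binarization threshold must be finite")
    presence = (suit.values >= evaluation.threshold) & grid.analysis_mask
    rng = SpeciesRange(
        suit.species_id, suit.scenario_tag, presence, threshold=float(evaluation.threshold)
    )
    if not presence.any():
        warnings.warn(f"{suit.species_id} [{suit.scenario_tag}]: empty binary range")
        rng.flags.append("empty")
    return rng


# --------------------------------------------------------------------------
# tier 2 (2-5 records)


class Tier2KdeRatio:
    name = "kde_ratio"

    def __init__(self, bw_floor: float):
        self.bw_floor = bw_floor

    def fit(self, Zp: np.ndarray, Zb: np.ndarray) -> "Tier2KdeRatio":
        self._kp = DiagonalKde(Zp, self.bw_floor)
        self._kb = DiagonalKde(Zb, self.bw_floor)
        return self

    def predict(self, Z: np.ndarray) -> np.ndarray:
        p = self._kp.pdf(Z)
        return p / (p + self._kb.pdf(Z) + 1e-300)


class Tier2PresenceKde:
    name = "presence_kde"

    def __init__(self, bw_floor: float):
        self.bw_floor = bw_floor

    def fit(self, Zp: np.ndarray, Zb: np.ndarray) -> "Tier2PresenceKde":
        self._kp = DiagonalKde(Zp, self.bw_floor)
        self._norm = max(self._kp.pdf(Zp).max(), 1e-300)
        return self

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return np.clip(self._kp.pdf(Z) / self._norm, 0.0, 1.0)


class Tier2Envelope:
    """Exponential decay with environmental distance to the presence centroid."""

    name = "envelope"

    def __init__(self, tau_floor: float):
        self.tau_floor = tau_floor

    def fit(self, Zp: np.ndarray, Zb: np.ndarray) -> "Tier2Envelope":
        self._mu = Zp.mean(axis=0)
        d = np.linalg.norm(Zp - self._mu, axis=1)
        self._tau = max(float(d.mean()), self.tau_floor)
        return self

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return np.exp(-np.linalg.norm(Z - self._mu, axis=1) / self._tau)


@dataclass
class Tier2Model:
    """Small-sample union-of-models range estimator for one species."""

    species_id: str
    layer_names: list[str]
    scaler: _Scaler
    members: list  # fitted member models
    thresholds: dict[str, float]
    aucs: dict[str, float]
    retained: list[str]
    fallback: bool
    config: SDMConfig

    def predict_range(self, env: EnvStack) -> SpeciesRange:
        missing = [n for n in self.layer_names if n not in env.layers]
        if missing:
            raise KeyError(f"future stack is missing trained layers: {missing}")
        grid = env.grid
        rows, cols = np.nonzero(grid.analysis_mask)
        Z = self.scaler.transform(env.values_at(rows, cols, self.layer_names))
        union = np.zeros(len(rows), dtype=bool)
        for m in self.members:
            if m.name in self.retained:
                union |= m.predict(Z) >= self.thresholds[m.name]
        presence = grid.zeros(bool)
        presence[rows, cols] = union
        rng = SpeciesRange(self.species_id, env.scenario_tag, presence, tier="tier2")
        if self.fallback:
            rng.flags.append("auc_fallback")
        if not presence.any():
            rng.flags.append("empty")
        return rng


def fit_tier2_small(
    presence_rc: np.ndarray,
    env: EnvStack,
    background_rc: np.ndarray,
    config: SDMConfig = SDMConfig(),
    species_id: str = "",
) -> Tier2Model:
    """Fit the small-sample (2-5 records) union-of-plausibility-models range.

    Each member is thresholded at the 5% linear-interpolation quantile of its
    scores at the presence points; members with AUC < ``auc_retain`` against
    background are discarded; the range is the union of the survivors (best
    single member if none survive, with a fallback flag).
    """
    layer_names = env.layer_names
    Xp = env.values_at(presence_rc[:, 0], presence_rc[:, 1], layer_names)
    Xb = env.values_at(background_rc[:, 0], background_rc[:, 1], layer_names)
    scaler = _Scaler().fit(Xb)  # background carries the landscape scale
    Zp, Zb = scaler.transform(Xp), scaler.transform(Xb)
    members = [
        Tier2KdeRatio(config.kde_bandwidth_floor),
        Tier2PresenceKde(config.kde_bandwidth_floor),
        Tier2Envelope(config.envelope_tau_floor),
    ]
    thresholds, aucs = {}, {}
    for m in members:
        m.fit(Zp, Zb)
        scores_p = m.predict(Zp)
        thresholds[m.name] = float(np.quantile(scores_p, config.presence_quantile))
        aucs[m.name] = evaluate_predictions(scores_p, m.predict(Zb)).auc
    retained = [m.name for m in members if aucs[m.name] >= config.auc_retain]
    fallback = False
    if not retained:
        best = max(aucs, key=aucs.get)
        retained = [best]
        fallback = True
        warnings.warn(f"{species_id}: all tier-2 members below AUC {config.auc_retain}; keeping {best!r}")
    return Tier2Model(
        species_id=species_id,
        layer_names=layer_names,
        scaler=scaler,
        members=members,
        thresholds=thresholds,
        aucs=aucs,
        retained=retained,
        fallback=fallback,
        config=config,
    )


# --------------------------------------------------------------------------
# tier 3 (single record)


def buffer_single(x: float, y: float, radius: float, grid: GridSpec, species_id: str = "") -> SpeciesRange:
    """Buffer of ``radius`` (km) around a single record: presence = cells
    whose centers lie within the radius.  Static under every scenario."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if grid.point_to_cell(x, y) is None:
        raise ValueError(f"{species_id}: record ({x}, {y}) lies outside the grid")
    xs, ys = grid.cell_centers()
    presence = (np.hypot(xs - x, ys - y) <= radius) & grid.analysis_mask
    return SpeciesRange(species_id, "current", presence, tier="tier3", threshold=radius)


# --------------------------------------------------------------------------
# atlas


@dataclass
class RangeAtlas:
    """Per-species binary ranges for every scenario."""

    grid: GridSpec
    ranges: dict[tuple[str, str], SpeciesRange]
    species: list[str]
    scenarios: list[str]

    def get(self, species_id: str, scenario: str) -> SpeciesRange:
        return self.ranges[(species_id, scenario)]

    def stack(self, scenario: str, species: list[str] | None = None) -> np.ndarray:
        """(n_species, n_rows, n_cols) boolean presence stack."""
        species = self.species if species is None else species
        return np.stack([self.ranges[(s, scenario)].presence for s in species])

    def summary(self) -> pd.DataFrame:
        """Range size per species x scenario with change flags vs. current."""
        rows = []
        for s in self.species:
            current_n = self.ranges[(s, "current")].n_cells if ("current" in self.scenarios) else None
            for scen in self.scenarios:
                r = self.ranges[(s, scen)]
                flag = ""
                if current_n is not None and scen != "current":
                    if r.n_cells == 0:
                        flag = "loss"
                    elif r.n_cells < current_n:
                        flag = "contraction"
                    elif r.n_cells > current_n:
                        flag = "expansion"
                    else:
                        flag = "stable"
                rows.append(
                    {"species": s, "scenario": scen, "tier": r.tier, "n_cells": r.n_cells, "change": flag}
                )
        return pd.DataFrame(rows)


def build_range_atlas(
    results: dict[tuple[str, str], SpeciesRange], species: list[str], scenarios: list[str], grid: GridSpec
) -> RangeAtlas:
    """Assemble and validate the full species x scenario range atlas."""
    for s in species:
        for scen in scenarios:
            if (s, scen) not in results:
                raise KeyError(f"missing range for species {s!r} under scenario {scen!r}")
    for rng in results.values():
        if rng.n_cells == 0 and "loss" not in rng.flags and rng.scenario_tag != "current":
            rng.flags.append("loss")
    return RangeAtlas(grid, dict(results), list(species), list(scenarios))
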