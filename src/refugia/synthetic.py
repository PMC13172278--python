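"""Synthetic landscapes, species, and trees with known ground truth.

Every generator is a pure function of its arguments including the seed, so
the whole downstream pipeline can be validated against a ground truth that
real occurrence data never provides: environmental layers are seeded
smoothed-noise fields with an optional latitudinal trend, species are virtual
taxa with Gaussian niches in environmental space, the phylogeny is a Yule
tree, traits evolve by Brownian motion along its branches, and protected
areas are unions of grown disks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import EnvStack, GridSpec, PAMask

__all__ = [
    "generate_environment",
    "generate_future_environment",
    "scenario_preset",
    "SCENARIO_PRESETS",
    "generate_phylogeny",
    "generate_traits",
    "generate_virtual_species",
    "sample_occurrences",
    "generate_protected_areas",
    "generate_human_influence",
    "TrueSpecies",
    "TraitMatrix",
]


class GenerationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# environment


def generate_environment(
    grid: GridSpec,
    n_layers: int = 5,
    correlation_length: float = 8.0,
    seed: int = 0,
    latitudinal_trend: float = 0.5,
) -> EnvStack:
    """Seeded stack of standardized smoothed-noise layers.

    Each layer is white noise convolved with an isotropic Gaussian kernel of
    sigma ``correlation_length`` (cells), standardized to mean 0 / sd 1 over
    the analysis mask, plus ``latitudinal_trend`` times a north-south ramp in
    [-1, 1].  The first ceil(n/2) layers are named ``temp*`` (the ones the
    scenario presets warm), the rest ``prec*``.
    """
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    if correlation_length < 0:
        raise ValueError("correlation_length must be >= 0")
    rng = np.random.default_rng(seed)
    mask = grid.analysis_mask
    ramp = np.linspace(1.0, -1.0, grid.n_rows)[:, None] * np.ones((1, grid.n_cols))
    n_temp = (n_layers + 1) // 2
    layers: dict[str, np.ndarray] = {}
    for i in range(n_layers):
        noise = rng.standard_normal(grid.shape)
        if correlation_length > 0:
            noise = ndimage.gaussian_filter(noise, sigma=correlation_length, mode="reflect")
        mu, sd = noise[mask].mean(), noise[mask].std()
        layer = (noise - mu) / (sd if sd > 0 else 1.0) + latitudinal_trend * ramp
        name = f"temp{i + 1}" if i < n_temp else f"prec{i - n_temp + 1}"
        layers[name] = layer
    return EnvStack(grid, layers, scenario_tag="current")


@dataclass(frozen=True)
class ScenarioPreset:
    """Additive deltas applied to the current climate, by layer family."""

    name: str
    temp_shift: float
    prec_shift: float
    drift: float = 0.0


#: Ordinal severity presets standing in for the SSP126 < SSP370 < SSP585 ladder.
SCENARIO_PRESETS: dict[str, ScenarioPreset] = {
    "mild": ScenarioPreset("mild", temp_shift=1.0, prec_shift=-0.2),
    "moderate": ScenarioPreset("moderate", temp_shift=2.5, prec_shift=-0.5),
    "severe": ScenarioPreset("severe", temp_shift=4.0, prec_shift=-1.0),
}


def generate_future_environment(
    current: EnvStack,
    shift: dict[str, float] | float = 0.0,
    drift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    scenario_tag: str = "future",
) -> EnvStack:
    """Shifted copy of the current stack for one future scenario.

    ``future = current + shift + drift * ramp + noise`` with the same
    north-south ramp used by :func:`generate_environment`.
    """
    if isinstance(shift, dict):
        unknown = set(shift) - set(current.layers)
        if unknown:
            raise KeyError(f"shift names layers not in the stack: {sorted(unknown)}")
        shifts = {name: shift.get(name, 0.0) for name in current.layers}
    else:
        shifts = {name: float(shift) for name in current.layers}
    rng = np.random.default_rng(seed)
    grid = current.grid
    ramp = np.linspace(1.0, -1.0, grid.n_rows)[:, None] * np.ones((1, grid.n_cols))
    layers = {}
    for name, arr in current.layers.items():
        noise = rng.standard_normal(grid.shape) * noise_sd if noise_sd > 0 else 0.0
        layers[name] = arr + shifts[name] + drift * ramp + noise
    return EnvStack(grid, layers, scenario_tag=scenario_tag)


def scenario_preset(
    current: EnvStack, name: str, horizon: str = "2050s", seed: int = 0, noise_sd: float = 0.05
) -> EnvStack:
    """Apply a named severity preset (mild/moderate/severe) to the stack."""
    preset = SCENARIO_PRESETS[name]
    shift = {
        ln: (preset.temp_shift if ln.startswith("temp") else preset.prec_shift)
        for ln in current.layers
    }
    return generate_future_environment(
        current,
        shift=shift,
        drift=preset.drift,
        noise_sd=noise_sd,
        seed=seed,
        scenario_tag=f"{name}-{horizon}",
    )


def generate_human_influence(grid: GridSpec, correlation_length: float = 6.0, seed: int = 0) -> np.ndarray:
    """Human-influence surface in [0, 1] (rank-normalized smoothed noise)."""
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    if correlation_length > 0:
        noise = ndimage.gaussian_filter(noise, sigma=correlation_length, mode="reflect")
    flat = noise[grid.analysis_mask]
    ranks = flat.argsort().argsort().astype(float)
    out = grid.zeros()
    out[grid.analysis_mask] = ranks / max(len(ranks) - 1, 1)
    return out


# --------------------------------------------------------------------------
# phylogeny and traits


def generate_phylogeny(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Simulate a Yule (pure-birth) tree with exactly ``n_species`` tips.

    Waiting times between speciations are Exponential(k * birth_rate) while k
    lineages are extant; after the last split the tree is extended to the
    present by one further exponential draw, so all branch lengths are
    strictly positive.  Tips are labelled ``s001`` ... in left-to-right order.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.birth_time = 0.0
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        child.birth_time = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        node.split_time = t
        for _ in range(2):
            child = node.new_child()
            child.birth_time = t
            active.append(child)
    t_present = t + rng.exponential(1.0 / (birth_rate * n_species))
    width = max(3, len(str(n_species)))
    i = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        end = getattr(node, "split_time", t_present)
        node.edge.length = end - node.birth_time
        if node.is_leaf():
            i += 1
            node.taxon = taxa.new_taxon(f"s{i:0{width}d}")
    return tree


@dataclass
class TraitMatrix:
    """Species x trait table with declared column kinds and missingness."""

    data: pd.DataFrame
    kinds: dict[str, str]
    imputed: pd.DataFrame | None = None  # boolean flags, set by the imputer

    def __post_init__(self) -> None:
        unknown = set(self.kinds.values()) - {"continuous", "ordinal", "categorical", "binary"}
        if unknown:
            raise ValueError(f"unknown trait kinds: {sorted(unknown)}")
        if set(self.kinds) != set(self.data.columns):
            raise ValueError("kinds must cover exactly the trait columns")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def is_complete(self) -> bool:
        return not self.data.isna().any().any()


def _brownian_tip_values(tree: dendropy.Tree, rate: float, rng: np.random.Generator) -> pd.Series:
    value = {tree.seed_node: 0.0}
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            sd = np.sqrt(max(rate, 0.0) * float(node.edge.length or 0.0))
            value[node] = value[node.parent_node] + (rng.standard_normal() * sd if sd > 0 else 0.0)
        if node.is_leaf():
            out[node.taxon.label] = value[node]
    return pd.Series(out)


def generate_traits(
    tree: dendropy.Tree,
    n_continuous: int = 4,
    n_categorical: int = 2,
    signal: float = 1.0,
    missing_fraction: float = 0.0,
    n_states: int = 3,
    seed: int = 0,
    max_retries: int = 50,
) -> TraitMatrix:
    """Traits with phylogenetic signal and controlled missingness.

    Continuous traits evolve by Brownian motion with variance ``signal`` per
    unit branch length; categorical traits threshold an underlying Brownian
    trait into ``n_states`` states at tip-value quantiles.  Exactly
    ``floor(missing_fraction * n_species * n_traits)`` entries are masked
    uniformly at random, never silencing an entire species row.
    """
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cols: dict[str, pd.Series] = {}
    kinds: dict[str, str] = {}
    for i in range(n_continuous):
        cols[f"cont{i + 1}"] = _brownian_tip_values(tree, signal, rng)
        kinds[f"cont{i + 1}"] = "continuous"
    state_labels = [chr(ord("a") + k) for k in range(n_states)]
    for i in range(n_categorical):
        latent = _brownian_tip_values(tree, signal, rng)
        if latent.std() == 0:
            states = pd.Series(state_labels[0], index=latent.index)
        else:
            qs = np.quantile(latent, np.linspace(0, 1, n_states + 1)[1:-1])
            states = pd.Series(
                [state_labels[int(np.searchsorted(qs, v, side="right"))] for v in latent],
                index=latent.index,
            )
        cols[f"cat{i + 1}"] = states
        kinds[f"cat{i + 1}"] = "categorical"
    data = pd.DataFrame(cols).sort_index()
    n_missing = int(np.floor(missing_fraction * data.shape[0] * data.shape[1]))
    if n_missing:
        n_cells = data.shape[0] * data.shape[1]
        for attempt in range(max_retries):
            flat = rng.choice(n_cells, size=n_missing, replace=False)
            mask = np.zeros(n_cells, dtype=bool)
            mask[flat] = True
            mask = mask.reshape(data.shape)
            if not mask.all(axis=1).any():  # never blank a whole species row
                break
        else:
            raise GenerationError("could not draw a missingness mask sparing every species row")
        data = data.mask(mask)
    return TraitMatrix(data, kinds)


# --------------------------------------------------------------------------
# virtual species and occurrences


@dataclass
class TrueSpecies:
    """A virtual species with a Gaussian niche and a known true range."""

    species_id: str
    niche_center: dict[str, float]
    niche_breadth: dict[str, float]
    true_suitability: np.ndarray
    true_range: np.ndarray
    tier: str = ""


def gaussian_suitability(env: EnvStack, center: dict[str, float], breadth: dict[str, float]) -> np.ndarray:
    """exp(-sum_k (e_k - mu_k)^2 / (2 sigma_k^2)) on the full grid."""
    log_s = np.zeros(env.grid.shape)
    for name, mu in center.items():
        sigma = breadth[name]
        log_s -= (env.layers[name] - mu) ** 2 / (2.0 * sigma**2)
    out = np.exp(log_s)
    out[~env.grid.analysis_mask] = 0.0
    return out


def generate_virtual_species(
    env: EnvStack,
    species_ids: list[str],
    presence_cutoff: float = 0.5,
    breadth_range: tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
    max_retries: int = 20,
) -> list[TrueSpecies]:
    """Virtual species whose niche centers sit at observed environments.

    Each species' niche center is the environment of a randomly drawn
    analysis cell (guaranteeing a nonempty true range for any cutoff < 1)
    and its per-layer breadth is uniform on ``breadth_range`` (layers are
    standardized, so breadth is in sd units).
    """
    if not 0 < presence_cutoff < 1:
        raise ValueError("presence_cutoff must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(env.grid.analysis_mask)
    out: list[TrueSpecies] = []
    for sid in species_ids:
        for attempt in range(max_retries):
            i = rng.integers(len(rows))
            center = {name: float(env.layers[name][rows[i], cols[i]]) for name in env.layers}
            breadth = {name: float(rng.uniform(*breadth_range)) for name in env.layers}
            suit = gaussian_suitability(env, center, breadth)
            rng_mask = suit >= presence_cutoff
            if rng_mask.any():
                out.append(TrueSpecies(sid, center, breadth, suit, rng_mask))
                break
        else:
            raise GenerationError(f"could not place species {sid!r} after {max_retries} retries")
    return out


def sample_occurrences(
    species: list[TrueSpecies],
    tier_plan: dict[str, int],
    coordinate_noise: float = 0.0,
    seed: int = 0,
    grid: GridSpec | None = None,
    replace: bool = True,
    source_tag: str = "synthetic",
) -> pd.DataFrame:
    """Occurrence records sampled from true ranges, suitability-weighted.

    Cells are drawn from each species' true range with probability
    proportional to true suitability (with replacement by default; without,
    the target is capped at the number of presence cells with a warning).
    Records sit at cell centers, optionally jittered by ``coordinate_noise``
    cell fractions.
    """
    if grid is None:
        raise ValueError("grid is required to place records at cell centers")
    rng = np.random.default_rng(seed)
    xs, ys = grid.cell_centers()
    records = []
    for sp in species:
        target = tier_plan[sp.species_id]
        rs, cs = np.nonzero(sp.true_range)
        if not replace and target > len(rs):
            warnings.warn(
                f"{sp.species_id}: target {target} exceeds {len(rs)} presence cells; capped"
            )
            target = len(rs)
        w = sp.true_suitability[rs, cs]
        idx = rng.choice(len(rs), size=target, replace=replace, p=w / w.sum())
        jitter = (
            rng.uniform(-0.5, 0.5, size=(target, 2)) * coordinate_noise * grid.cell_size
            if coordinate_noise > 0
            else np.zeros((target, 2))
        )
        for j, k in enumerate(idx):
            records.append(
                {
                    "species": sp.species_id,
                    "x": xs[rs[k], cs[k]] + jitter[j, 0],
                    "y": ys[rs[k], cs[k]] + jitter[j, 1],
                    "source": source_tag,
                }
            )
    return pd.DataFrame(records, columns=["species", "x", "y", "source"])


# --------------------------------------------------------------------------
# protected areas


def generate_protected_areas(
    grid: GridSpec, target_coverage: float = 0.1, n_patches: int = 5, seed: int = 0
) -> PAMask:
    """Patchy protected-area mask: union of disks grown to a target coverage.

    ``n_patches`` seed cells are drawn inside the analysis mask and a common
    disk radius is grown until the union reaches the target; the outermost
    cells are then trimmed (farthest-first) to land within +/-10% relative of
    the requested coverage — exactly when the cell budget allows.
    """
    if not 0 < target_coverage < 1:
        raise ValueError("target_coverage must be in (0, 1)")
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    rng = np.random.default_rng(seed)
    mask = grid.analysis_mask
    rows, cols = np.nonzero(mask)
    n_cells = len(rows)
    target_n = max(1, round(target_coverage * n_cells))
    picks = rng.choice(n_cells, size=min(n_patches, n_cells), replace=False)
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    dist = np.full(grid.shape, np.inf)
    for p in picks:
        d = np.hypot(rr - rows[p], cc - cols[p])
        dist = np.minimum(dist, d)
    dist[~mask] = np.inf
    order = np.argsort(dist[mask], kind="stable")  # nearest-first within the mask
    chosen = order[:target_n]
    pa = np.zeros(grid.shape, dtype=bool)
    pa[rows[chosen], cols[chosen]] = True
    achieved = target_n / n_cells
    warn = abs(achieved - target_coverage) > 0.1 * target_coverage
    if warn:
        warnings.warn(
            f"protected-area coverage {achieved:.4f} outside +/-10% of target {target_coverage:.4f}"
        )
    return PAMask(grid, pa, achieved_coverage=achieved, coverage_warning=bool(warn))
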