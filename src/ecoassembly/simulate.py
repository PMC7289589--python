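"""Synthetic metacommunities with known assembly processes.

The generator emulates the processed form of a depth-stratified soil 16S
survey: a rarefied OTU table (5 depth layers × 4 treatments × 3 replicates),
a matching ultrametric phylogeny, phylum labels, and layered environmental
gradients whose heterogeneity decreases with depth. Each layer is assembled
under one known regime so that the full inference chain can be tested for
process recovery without any external data:

``selection_variable``
    A Gaussian niche filter on a latent environmental axis, with the axis
    value differing between samples; taxa optima evolve by Brownian motion
    on the tree, so selection leaves a phylogenetic signal.
``selection_homogeneous``
    The same filter at a constant axis value for every sample.
``homogenizing_dispersal``
    Every sample drawn multinomially from one shared pool.
``dispersal_limitation``
    Each sample's pool is an independent Dirichlet perturbation of the
    metacommunity (few effective colonists) with extra lognormal drift.
``neutral``
    Each sample's pool drawn from the stationary distribution of
    drift–migration balance (per-taxon Beta(Nmp, Nm(1−p))), the regime the
    Sloan model describes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from .carbon import GUILDS, SAMPLING_DAYS, BiologPlate, MineralizationSeries
from .community_io import CommunityTable, SampleTable

__all__ = [
    "REGIMES",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_tree",
    "evolve_niche",
    "simulate_metacommunity",
    "assemble_samples",
    "simulate_dataset",
    "simulate_plate",
    "simulate_co2",
]

REGIMES = (
    "selection_variable",
    "selection_homogeneous",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "neutral",
)

# phylum labels assigned to basal clades of the simulated tree, echoing the
# dominant soil phyla this pipeline is aimed at
_PHYLA = (
    "Chloroflexi", "Acidobacteria", "Actinobacteria", "Alphaproteobacteria",
    "Firmicutes", "Deltaproteobacteria", "Betaproteobacteria",
    "Gammaproteobacteria",
)

_EXPECTED_PROCESS = {
    "selection_variable": "variable_selection",
    "selection_homogeneous": "homogeneous_selection",
    "homogenizing_dispersal": "homogenizing_dispersal",
    "dispersal_limitation": "dispersal_limitation",
    # pure drift produces more taxonomic turnover than the fixed-richness
    # multinomial null, so it surfaces as dispersal limitation / undominated
    "neutral": ("dispersal_limitation", "undominated"),
}


@dataclass
class SimulationConfig:
    """Generating conditions for one synthetic dataset.

    Defaults are desk-scale: 200 taxa, 5 layers × 12 samples
    (4 treatments × 3 replicates), 2000 reads per sample, one regime per
    layer covering all five processes. ``sigma_sel`` is the niche-filter
    width in units of the standard deviation of the simulated optima;
    ``env_heterogeneity`` scales both the latent-axis spread and the noise
    of the recorded environmental variables, decreasing with depth.
    """

    n_taxa: int = 400
    n_layers: int = 5
    samples_per_layer: int = 12
    n_treatments: int = 4
    reads_per_sample: int = 2000
    regimes: tuple = REGIMES
    sigma_sel: float = 0.2
    homogeneous_jitter: float = 0.1
    selection_drift_sd: float = 1.0
    sigma_bm: float = 1.0
    m_true: float = 0.1
    dirichlet_alpha: float = 50.0
    drift_lognormal_sd: float = 2.0
    lognormal_sigma: float = 1.5
    env_heterogeneity: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if len(self.regimes) != self.n_layers:
            raise ValueError("one regime per layer required")
        for r in self.regimes:
            if r not in REGIMES:
                raise ValueError(f"unknown regime {r!r}")
        if self.env_heterogeneity is None:
            self.env_heterogeneity = tuple(
                np.linspace(1.0, 0.2, self.n_layers))
        if self.sigma_sel <= 0 and any(r.startswith("selection") for r in self.regimes):
            raise ValueError("sigma_sel must be positive for selection regimes")


@dataclass
class SimulationTruth:
    """Everything needed to predict the expected classification."""

    tree: TreeNode
    optima: pd.Series
    metacommunity: pd.Series
    env: pd.DataFrame
    regime_by_layer: dict[str, str]
    m_true: float
    expected_process: dict[str, object] = field(default_factory=dict)


def simulate_tree(n_taxa: int, seed=None, birth_rate: float = 1.0) -> TreeNode:
    """Ultrametric Yule (pure-birth) tree with exponential waiting times."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None)
    birth = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        kids = [TreeNode(name=None), TreeNode(name=None)]
        for k in kids:
            birth[id(k)] = t
            node.append(k)
            active.append(k)
    t += rng.exponential(1.0 / (birth_rate * len(active)))  # stem to present
    width = len(str(n_taxa))
    for i, tip in enumerate(root.tips()):  # traversal order is deterministic
        tip.name = f"t{i + 1:0{width}d}"
    for node in root.traverse(include_self=False):
        end = birth[id(node.children[0])] if node.children else t
        node.length = end - birth[id(node)]
    root.length = 0.0
    return root


def evolve_niche(tree: TreeNode, sigma_bm: float, seed=None) -> pd.Series:
    """Brownian-motion niche optima along the tree, root value 0.

    Tip variance ≈ sigma_bm² × root-to-tip depth; sister tips correlate
    through their shared path.
    """
    rng = np.random.default_rng(seed)
    values = {id(tree): 0.0}
    out = {}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, sigma_bm * np.sqrt(node.length)) if node.length > 0 else 0.0
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    return pd.Series(out, name="optimum")


def simulate_metacommunity(n_taxa: int, lognormal_sigma: float = 1.5,
                           seed=None, taxon_ids=None) -> pd.Series:
    """Lognormal regional species-abundance distribution, normalized to 1."""
    if lognormal_sigma <= 0:
        raise ValueError("lognormal_sigma must be positive")
    rng = np.random.default_rng(seed)
    ab = rng.lognormal(0.0, lognormal_sigma, size=n_taxa)
    ab /= ab.sum()
    if taxon_ids is None:
        width = len(str(n_taxa))
        taxon_ids = [f"t{i + 1:0{width}d}" for i in range(n_taxa)]
    return pd.Series(ab, index=list(taxon_ids), name="metacommunity")


def assign_phyla(tree: TreeNode, n_phyla: int = 8) -> pd.Series:
    """Label basal clades of the tree with phylum names.

    The largest clade is split repeatedly until ``n_phyla`` groups exist, so
    labels are monophyletic — per-phylum analyses then work on coherent
    subtrees.
    """
    clades = [tree]
    while len(clades) < n_phyla:
        clades.sort(key=lambda c: sum(1 for _ in c.tips()), reverse=True)
        big = clades.pop(0)
        if not big.children:
            clades.append(big)
            break
        clades.extend(big.children)
    labels = {}
    for i, clade in enumerate(clades):
        name = _PHYLA[i % len(_PHYLA)] if i < len(_PHYLA) else f"Phylum{i + 1}"
        tips = [clade.name] if clade.is_tip() else [t.name for t in clade.tips()]
        for t in tips:
            labels[t] = name
    return pd.Series(labels, name="phylum")


def _select_clade(tree: TreeNode, rng, min_frac: float = 1 / 8,
                  max_frac: float = 1 / 4) -> set[str]:
    """Pick a moderately sized clade (seeded) as the selected lineage."""
    n = sum(1 for _ in tree.tips())
    candidates = []
    for node in tree.non_tips(include_self=False):
        tips = frozenset(t.name for t in node.tips())
        if min_frac * n <= len(tips) <= max_frac * n:
            candidates.append(tips)
    if not candidates:  # very small or pathological trees
        tips = sorted(t.name for t in tree.tips())
        return set(tips[: max(2, n // 4)])
    candidates.sort(key=lambda s: (len(s), min(s)))
    return set(candidates[rng.integers(len(candidates))])


def _local_pool(regime: str, e_s: float, meta: np.ndarray, optima: np.ndarray,
                filter_width: float, cfg: SimulationConfig, rng,
                clade_mask: np.ndarray | None = None) -> np.ndarray:
    if regime == "selection_variable":
        dev = np.abs(e_s - optima)
        w = meta * np.exp(-(dev ** 2) / (2.0 * filter_width ** 2))
        # hard niche boundary: outside the tolerance range fitness is zero,
        # otherwise the Gaussian tail admits phylogenetically scattered taxa
        # that dilute the selection signature
        w[dev > 3.0 * filter_width] = 0.0
        if w.sum() <= 0:
            raise ValueError("niche filter removed all taxa; widen sigma_sel")
        # selection fixes the trait neighborhood, sample-level drift picks its
        # members: without it, paired communities share nearly all their mass
        w = w * rng.lognormal(0.0, cfg.selection_drift_sd, size=meta.size)
        return w / w.sum()
    if regime == "selection_homogeneous":
        # a consistent environment selecting one habitat-adapted lineage:
        # membership is confined to the chosen clade and sample-level drift
        # decides which clade members dominate each community
        w = meta * clade_mask
        w = w * rng.lognormal(0.0, cfg.selection_drift_sd, size=meta.size)
        if w.sum() <= 0:
            raise ValueError("empty selection clade")
        return w / w.sum()
    if regime == "homogenizing_dispersal":
        return meta
    if regime == "dispersal_limitation":
        pool = rng.dirichlet(cfg.dirichlet_alpha * meta + 1e-9)
        drift = rng.lognormal(0.0, cfg.drift_lognormal_sd, size=meta.size)
        pool = pool * drift
        return pool / pool.sum()
    if regime == "neutral":
        nm = cfg.reads_per_sample * cfg.m_true
        p = rng.beta(np.maximum(nm * meta, 1e-9),
                     np.maximum(nm * (1.0 - meta), 1e-9))
        total = p.sum()
        if total <= 0:
            raise ValueError("degenerate neutral pool")
        return p / total
    raise ValueError(f"unknown regime {regime!r}")


def _stationary_counts(y: np.ndarray, n_reads: int) -> np.ndarray:
    """Discretize equilibrium frequencies into a community of n_reads reads.

    A taxon whose equilibrium frequency amounts to fewer than one individual
    is absent — the detection semantics the neutral occupancy model assumes
    — and the leftover reads go to the detected taxa with the largest
    remainders, keeping the column sum exact.
    """
    base = np.floor(y * n_reads).astype(np.int64)
    rem = n_reads - int(base.sum())
    if rem > 0:
        frac = np.where(base >= 1, y * n_reads - base, -1.0)
        order = np.argsort(-frac)
        base[order[:rem]] += 1
    return base


def assemble_samples(config: SimulationConfig, tree: TreeNode | None = None,
                     optima: pd.Series | None = None,
                     meta: pd.Series | None = None):
    """Draw the full sample set under the configured per-layer regimes.

    Returns ``(CommunityTable, SampleTable, SimulationTruth)``. Counts are
    multinomial at ``reads_per_sample`` (so every column sums exactly to
    the read depth, as a rarefied table would). Environmental variables are
    the latent axis (``env1``) plus three noise variables whose per-layer
    spread follows ``env_heterogeneity``.
    """
    cfg = config
    root_ss = np.random.SeedSequence(cfg.seed)
    ss_tree, ss_bm, ss_meta, ss_asm = root_ss.spawn(4)
    if tree is None:
        tree = simulate_tree(cfg.n_taxa, seed=ss_tree)
    taxa = [t.name for t in tree.tips()]
    if optima is None:
        optima = evolve_niche(tree, cfg.sigma_bm, seed=ss_bm)
    if meta is None:
        meta = simulate_metacommunity(cfg.n_taxa, cfg.lognormal_sigma,
                                      seed=ss_meta, taxon_ids=taxa)
    optima = optima.reindex(taxa)
    meta = meta.reindex(taxa)
    opt = optima.to_numpy()
    mvec = meta.to_numpy()
    mu, sd = float(opt.mean()), float(opt.std(ddof=0))
    filter_width = cfg.sigma_sel * sd
    rng = np.random.default_rng(ss_asm)

    counts = {}
    env_rows = {}
    layers = {}
    treatments = {}
    regime_by_layer = {}
    reps = cfg.samples_per_layer // cfg.n_treatments
    for li in range(cfg.n_layers):
        layer = f"L{li + 1}"
        regime = cfg.regimes[li]
        regime_by_layer[layer] = regime
        h = cfg.env_heterogeneity[li]
        n_s = cfg.samples_per_layer
        clade_mask = None
        if regime == "selection_variable":
            axis = mu + sd * 1.5 * h * np.linspace(-1.0, 1.0, n_s)
        elif regime == "selection_homogeneous":
            # the consistent environment selects one habitat-adapted lineage;
            # the recorded axis value is that clade's trait mean (constant up
            # to measurement jitter)
            clade_tips = _select_clade(tree, rng)
            clade_mask = np.array([t in clade_tips for t in taxa], dtype=float)
            anchor = float(optima.loc[sorted(clade_tips)].mean())
            axis = anchor + cfg.homogeneous_jitter * sd * rng.standard_normal(n_s)
        else:
            axis = mu + 0.1 * sd * h * rng.standard_normal(n_s)
        for si in range(n_s):
            trt = f"M{si // reps}" if reps else f"M{si % cfg.n_treatments}"
            sid = f"{layer}_{trt}_R{si % reps + 1}" if reps else f"{layer}_S{si + 1}"
            pool = _local_pool(regime, axis[si], mvec, opt, filter_width, cfg, rng,
                               clade_mask=clade_mask)
            if regime == "neutral":
                # the community IS the stationary state; a second multinomial
                # layer would double-count drift noise
                counts[sid] = _stationary_counts(pool, cfg.reads_per_sample)
            else:
                counts[sid] = rng.multinomial(cfg.reads_per_sample, pool)
            env_rows[sid] = {
                "env1": axis[si],
                "env2": 5.0 - li + h * rng.standard_normal(),
                "env3": 2.0 + 0.5 * li + h * rng.standard_normal(),
                "env4": 1.0 + h * rng.standard_normal(),
            }
            layers[sid] = layer
            treatments[sid] = trt

    counts_df = pd.DataFrame(counts, index=taxa)
    taxonomy = assign_phyla(tree)
    table = CommunityTable(counts_df, taxonomy)
    meta_df = pd.DataFrame(env_rows).T
    meta_df.insert(0, "layer", pd.Series(layers))
    meta_df.insert(1, "treatment", pd.Series(treatments))
    samples = SampleTable(meta_df)
    truth = SimulationTruth(
        tree=tree, optima=optima, metacommunity=meta,
        env=meta_df.drop(columns=["layer", "treatment"]),
        regime_by_layer=regime_by_layer, m_true=cfg.m_true,
        expected_process={l: _EXPECTED_PROCESS[r] for l, r in regime_by_layer.items()},
    )
    return table, samples, truth


def simulate_dataset(config: SimulationConfig | None = None, **kwargs):
    """Convenience wrapper: config → (table, samples, truth)."""
    if config is None:
        config = SimulationConfig(**kwargs)
    return assemble_samples(config)


# ---------------------------------------------------------------------------
# Carbon-metabolism fixtures
# ---------------------------------------------------------------------------

# standard six-guild partition of the 31 EcoPlate substrates
_GUILD_SIZES = {"carbohydrates": 10, "carboxylic_acids": 7, "amino_acids": 6,
                "polymers": 4, "phenolic_acids": 2, "amines": 2}
# relative guild activity (weighted to average exactly 1 over 31 wells)
_GUILD_FACTORS = {"carbohydrates": 1.2, "carboxylic_acids": 1.0,
                  "amino_acids": 1.1, "polymers": 0.8,
                  "phenolic_acids": 0.6, "amines": 0.7}


def simulate_plate(awcd_target: float, noise_sd: float = 0.0, seed=None,
                   hours=(24, 48, 72, 96, 120, 144, 168),
                   blank_od: float = 0.05) -> BiologPlate:
    """Synthetic EcoPlate whose 96-h AWCD equals ``awcd_target`` at zero noise.

    Well color develops along a saturating curve scaled so the 96-h reading
    hits the target exactly; guilds differ in activity; Gaussian noise with
    sd ``noise_sd`` is added to substrate wells (clamped at 0).
    """
    if awcd_target < 0:
        raise ValueError("awcd_target must be non-negative")
    rng = np.random.default_rng(seed)
    w = sum(_GUILD_SIZES[g] * _GUILD_FACTORS[g] for g in GUILDS) / 31.0
    wells, guilds = [], {}
    for g in GUILDS:
        for i in range(_GUILD_SIZES[g]):
            wid = f"{g}_{i + 1}"
            wells.append(wid)
            guilds[wid] = g
    curve = {h: (1 - np.exp(-h / 40.0)) / (1 - np.exp(-96 / 40.0)) for h in hours}
    data = {}
    for h in hours:
        col = {}
        for wid in wells:
            base = awcd_target * (_GUILD_FACTORS[guilds[wid]] / w) * curve[h]
            col[wid] = max(base + blank_od + (rng.normal(0, noise_sd) if noise_sd else 0.0), 0.0)
        col["blank"] = blank_od
        data[h] = col
    od = pd.DataFrame(data).loc[wells + ["blank"]]
    return BiologPlate(od590=od, guilds=pd.Series(guilds))


def simulate_co2(C0: float, k: float, noise_sd: float = 0.0, seed=None,
                 days=SAMPLING_DAYS) -> MineralizationSeries:
    """First-order cumulative CO2-C curve with relative Gaussian noise.

    ``noise_sd`` is the relative (fractional) noise level, e.g. 0.05 for 5%.
    """
    if C0 <= 0 or k <= 0:
        raise ValueError("C0 and k must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(days, dtype=float)
    ct = C0 * (1.0 - np.exp(-k * t))
    if noise_sd:
        ct = np.clip(ct * (1.0 + rng.normal(0, noise_sd, size=t.size)), 0.0, None)
    return MineralizationSeries(t=t, ct=ct)
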