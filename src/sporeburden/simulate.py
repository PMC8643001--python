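"""Synthetic cleanroom-study generator.

Emulates the sampling design of a spacecraft-assembly-facility floor
survey: 13 locations at known radial distances from the entrance sampled
over 11 sessions, each sampling event split into a PMA-naive and a
PMA-treated wipe, plus field, negative (wipe-only) and extraction
controls. Features are tips of a simulated phylogeny carrying a
phylogenetically conserved binary spore-former trait; spore-formers'
expected abundance decays (or grows) exponentially with radius; a dead
biomass layer is visible only to PMA-naive samples; a small contaminant
set appears in every control and dominates control reads.

Every stage downstream of the generator therefore has exact ground
truth: the true trait per feature, the true live fraction, and the true
contaminant set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .table import FeatureTable, SampleMetadata


# ---------------------------------------------------------------------------
# trees and traits
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int) -> skbio.TreeNode:
    """Random rooted binary tree with exponential(1) branch lengths.

    Built by iteratively joining two uniformly chosen lineages, so the
    topology is exchangeable across tips. Tips are labeled ``t0..t{n-1}``.
    Deterministic under ``seed``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = [skbio.TreeNode(name=f"t{i}") for i in range(n_tips)]
    for node in nodes:
        node.length = float(rng.exponential(1.0))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = skbio.TreeNode(children=[left, right])
        parent.length = float(rng.exponential(1.0))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def simulate_binary_trait(
    tree: skbio.TreeNode,
    rate: float,
    root_state_prob: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """Simulate a two-state trait root-to-tip along the tree.

    The model is the equal-input continuous-time Markov chain with
    stationary distribution (1-p, p) where p = ``root_state_prob``:
    over a branch of length t the chance of ending in state j is
    ``pi_j + (delta_ij - pi_j) * exp(-rate * t)``. At rate 0 every tip
    inherits the root state; as rate grows, tip states decorrelate toward
    independent Bernoulli(p).

    Returns a boolean Series over tip labels (True = state 1, e.g.
    spore-former).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if not 0.0 <= root_state_prob <= 1.0:
        raise ValueError("root_state_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = root_state_prob
    states: dict[int, int] = {id(tree): int(rng.random() < p)}
    for node in tree.preorder(include_self=False):
        parent_state = states[id(node.parent)]
        t = node.length or 0.0
        decay = np.exp(-rate * t)
        p_one = p + ((1.0 if parent_state == 1 else 0.0) - p) * decay
        states[id(node)] = int(rng.random() < p_one)
    out = {tip.name: bool(states[id(tip)]) for tip in tree.tips()}
    return pd.Series(out, dtype=bool)


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Knobs of the synthetic study; defaults mirror the floor-survey design."""

    n_locations: int = 13
    radii: np.ndarray | None = None          # default linspace(50, 1000)
    n_sessions: int = 11
    n_floor_events: int = 98                 # (location, session) events; each → PMA pair
    n_field_controls: int = 12
    n_negative_controls: int = 12
    n_extraction_controls: int = 8
    n_features: int = 300
    spore_fraction: float = 0.3              # trait root/stationary probability
    trait_rate: float = 0.1                  # transitions per unit branch length
    gradient_beta: float = -0.002            # per radius unit, on spore-formers
    live_fraction_alpha: float = 1.0         # Beta(a, b) per-taxon live fraction
    live_fraction_beta: float = 2.0          # mean 1/3
    n_contaminants: int = 7
    depth_mean: float = 50_000.0
    depth_dispersion: float = 5.0            # NB shape; variance = m + m^2/k
    low_depth_fraction: float = 0.2          # samples forced below min QC depth
    qc_depth: int = 5000
    base_sigma: float = 1.5                  # lognormal sd of per-taxon baselines
    contaminant_floor_weight: float = 0.01   # contaminant share of floor intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radii is None:
            self.radii = np.linspace(50.0, 1000.0, self.n_locations)
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.radii) != self.n_locations:
            raise ValueError("radii must have n_locations entries")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        for name in ("spore_fraction", "low_depth_fraction",
                     "contaminant_floor_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_contaminants >= self.n_features:
            raise ValueError("contaminant set must be smaller than feature set")
        if self.n_floor_events > self.n_locations * self.n_sessions:
            raise ValueError("more floor events than location × session cells")
        if self.trait_rate < 0 or self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("rates and depth parameters must be positive")


@dataclass
class StudyBundle:
    """A complete synthetic study plus its ground truth."""

    table: FeatureTable
    metadata: SampleMetadata
    tree: skbio.TreeNode
    true_traits: pd.Series            # feature → spore-former (bool)
    live_fraction: pd.Series          # feature → fraction of biomass that is live
    contaminants: list[str]           # ground-truth contaminant feature ids
    config: StudyConfig


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def _draw_depths(rng, n: int, cfg: StudyConfig) -> np.ndarray:
    """NB depths with a forced low-depth subset (below the QC gate)."""
    k = cfg.depth_dispersion
    m = cfg.depth_mean
    depths = rng.negative_binomial(k, k / (k + m), size=n).astype(np.int64)
    depths = np.maximum(depths, 10)
    n_low = int(round(cfg.low_depth_fraction * n))
    if n_low:
        idx = rng.choice(n, size=n_low, replace=False)
        depths[idx] = rng.integers(100, cfg.qc_depth, size=n_low)
    return depths


def _multinomial_with_guaranteed(rng, depth: int, weights: np.ndarray,
                                 guaranteed: np.ndarray) -> np.ndarray:
    """Multinomial draw at ``depth`` giving one seed read to each
    guaranteed index first (so those features can never drop out)."""
    counts = np.zeros(len(weights), dtype=np.int64)
    g = guaranteed[guaranteed < len(weights)]
    n_seed = min(len(g), depth)
    counts[g[:n_seed]] += 1
    remaining = depth - n_seed
    if remaining > 0:
        p = weights / weights.sum()
        counts += rng.multinomial(remaining, p)
    return counts


def simulate_cleanroom_study(config: StudyConfig) -> StudyBundle:
    """Generate the full study: table, metadata, tree and ground truth.

    Expected floor composition per taxon f in a sample at radius r:
    ``base_f * exp(beta * r * [f is spore-former])``, split into a live
    part (fraction ``live_f``) seen by all samples and a dead part seen
    only by PMA-naive samples. Controls carry the contaminant set at high
    intensity (plus a faint well-to-well background) and are guaranteed a
    nonzero contaminant count. Column sums equal the drawn depths exactly.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    tree = simulate_tree(cfg.n_features, seed=int(rng.integers(2**31)))
    traits = simulate_binary_trait(
        tree, cfg.trait_rate, cfg.spore_fraction, seed=int(rng.integers(2**31))
    )
    feature_ids = [f"t{i}" for i in range(cfg.n_features)]
    traits = traits.reindex(feature_ids)
    spore = traits.to_numpy()

    base = rng.lognormal(0.0, cfg.base_sigma, size=cfg.n_features)
    live_frac = rng.beta(cfg.live_fraction_alpha, cfg.live_fraction_beta,
                         size=cfg.n_features)
    contaminant_idx = rng.choice(cfg.n_features, size=cfg.n_contaminants,
                                 replace=False)
    contaminant_idx.sort()
    contam_mask = np.zeros(cfg.n_features, dtype=bool)
    contam_mask[contaminant_idx] = True
    contam_weights = rng.lognormal(0.0, 0.5, size=cfg.n_contaminants)

    # ---- sampling plan ----------------------------------------------------
    cells = [(loc, ses) for ses in range(1, cfg.n_sessions + 1)
             for loc in range(1, cfg.n_locations + 1)]
    chosen = rng.choice(len(cells), size=cfg.n_floor_events, replace=False)
    rows = []
    for k in sorted(chosen):
        loc, ses = cells[k]
        radius = cfg.radii[loc - 1]
        for pma in (False, True):
            tag = "pma" if pma else "raw"
            rows.append((f"F{ses:02d}L{loc:02d}.{tag}", "floor", pma, loc,
                         radius, ses))
    for i in range(cfg.n_field_controls):
        rows.append((f"FC{i:02d}", "field_control", i % 2 == 0, None, None,
                     1 + i % cfg.n_sessions))
    for i in range(cfg.n_negative_controls):
        rows.append((f"NC{i:02d}", "negative_control", i % 2 == 0, None, None,
                     1 + i % cfg.n_sessions))
    for i in range(cfg.n_extraction_controls):
        rows.append((f"XC{i:02d}", "extraction_control", False, None, None,
                     1 + i % cfg.n_sessions))
    meta = pd.DataFrame(
        rows,
        columns=["sample_id", "sample_type", "pma_treated", "location_id",
                 "radius", "session_index"],
    ).set_index("sample_id")
    meta["location_id"] = meta["location_id"].astype("Int64")
    meta["session_index"] = meta["session_index"].astype("Int64")
    start = pd.Timestamp("2016-03-02")
    meta["session_date"] = [
        (start + pd.Timedelta(days=14 * (int(s) - 1))).date().isoformat()
        for s in meta["session_index"]
    ]

    # ---- expected intensities --------------------------------------------
    n_samples = len(meta)
    depths = _draw_depths(rng, n_samples, cfg)
    counts = np.zeros((cfg.n_features, n_samples), dtype=np.int64)

    contam_full = np.zeros(cfg.n_features)
    contam_full[contaminant_idx] = contam_weights

    for j, (sid, row) in enumerate(meta.iterrows()):
        if row["sample_type"] == "floor":
            lam = base * np.exp(cfg.gradient_beta * row["radius"] * spore)
            live = lam * live_frac
            dead = lam * (1.0 - live_frac)
            intensity = live if row["pma_treated"] else live + dead
            total = intensity.sum()
            intensity = intensity + cfg.contaminant_floor_weight * total * (
                contam_full / max(contam_full.sum(), 1e-12)
            )
            counts[:, j] = rng.multinomial(depths[j],
                                           intensity / intensity.sum())
        else:
            # controls: contaminants dominate; faint well-to-well background
            background = base * (0.02 if row["sample_type"] == "field_control"
                                 else 0.005)
            intensity = contam_full * base.mean() * 50.0 + background
            counts[:, j] = _multinomial_with_guaranteed(
                rng, depths[j], intensity, contaminant_idx
            )

    lineages = [
        f"k__Bacteria; p__P{i % 7}; c__C{i % 11}; o__O{i % 17}; "
        f"f__F{i % 23}; g__G{i:03d}; s__"
        for i in range(cfg.n_features)
    ]
    table = FeatureTable(
        pd.DataFrame(counts, index=feature_ids, columns=meta.index),
        taxonomy=pd.Series(lineages, index=feature_ids),
    )
    return StudyBundle(
        table=table,
        metadata=SampleMetadata(meta),
        tree=tree,
        true_traits=traits,
        live_fraction=pd.Series(live_frac, index=feature_ids),
        contaminants=[feature_ids[i] for i in contaminant_idx],
        config=cfg,
    )
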