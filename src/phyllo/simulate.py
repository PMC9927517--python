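"""Synthetic ASV communities with known ground truth.

Generators emulating the paired wild/cultivated phyllosphere study design
(2 genotypes x 3 sites x 5 replicates, bacteria + fungi) under controllable
assembly regimes:

* ``neutral`` — two-stage beta/multinomial sampling that is the exact
  generative inverse of the Sloan neutral-model fit, so migration rates can
  be recovered by the downstream estimator.
* ``heterogeneous_selection`` / ``homogeneous_selection`` — Brownian traits
  evolved on a simulated phylogeny; Gaussian environmental filtering of the
  source pool produces phylogenetically structured communities.
* ``dispersal_limitation`` — each sample colonises from its own random
  subset of the pool, decoupled from phylogeny.
* ``planted_network`` — latent shared Gaussian log-abundance factors plant
  known positive/negative pairwise correlations.
* ``core_and_enrichment`` — taxa forced to fixed high abundance in every
  sample (core) or multiplied by a known fold change in one genotype
  (enriched).

All randomness flows from one explicit seed through a single
:class:`numpy.random.Generator`; identical inputs give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables import FeatureTable, SampleMetadata

SITE_NAMES = ("QH", "WC", "WN")  # extended as site4, site5, ... if needed


@dataclass(frozen=True)
class DesignSpec:
    """Sampling design: sites x genotypes x replicates, per-kingdom taxa.

    Defaults mirror the field design this package emulates: 3 sites, wild
    and cultivated genotypes, 5 replicates (30 samples), 200 taxa per
    kingdom, uniform depth of 20,000 reads per sample.
    """

    n_sites: int = 3
    n_genotypes: int = 2
    n_replicates: int = 5
    n_taxa_per_kingdom: int = 200
    reads_per_sample: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_genotypes", "n_replicates", "n_taxa_per_kingdom", "reads_per_sample"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_genotypes > 2:
            raise ValidationError("at most two genotypes (wild, cultivated) are supported")

    @property
    def n_samples(self) -> int:
        return self.n_sites * self.n_genotypes * self.n_replicates

    def site_names(self) -> list[str]:
        base = list(SITE_NAMES[: self.n_sites])
        base += [f"site{i}" for i in range(len(base) + 1, self.n_sites + 1)]
        return base

    def genotype_names(self) -> list[str]:
        return ["wild", "cultivated"][: self.n_genotypes]


SCENARIOS = (
    "neutral",
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "planted_network",
    "core_and_enrichment",
)


@dataclass
class ScenarioParams:
    """Per-scenario generator knobs; only the chosen scenario's fields are used."""

    scenario: str = "neutral"
    pool_shape: float = 1.5
    nm: float = 50.0  # neutral: metacommunity size x migration rate
    trait_sd: float = 0.5  # selection: width of the Gaussian fitness kernel, trait-SD units
    env_values: dict[str, float] = field(default_factory=lambda: {"wild": 2.0, "cultivated": -2.0})
    subsample_fraction: float = 0.2  # dispersal: fraction of the taxon ring each sample colonises
    planted_edges: list[tuple[int, int, int]] = field(default_factory=list)
    noise_sd: float = 0.3  # planted_network: independent noise on latent log-abundance
    latent_sd: float = 1.0  # planted_network: scale of shared and background factors
    core_taxa: dict[str, float] = field(default_factory=dict)  # taxon -> target relabund
    enriched_taxa: list[tuple[str, str, float]] = field(default_factory=list)  # (taxon, group, log2fc)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        for i, j, s in self.planted_edges:
            if s not in (1, -1):
                raise ValidationError(f"planted edge sign must be +1/-1, got {s}")
            if i == j:
                raise ValidationError(f"planted self-edge ({i}, {i}) is invalid")
        if not 0 < self.subsample_fraction <= 1:
            raise ValidationError("subsample_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# metacommunity pool and phylogeny


def simulate_metacommunity(n_taxa: int, shape: float, seed: int | np.random.Generator) -> np.ndarray:
    """Lognormal ranked-abundance source pool, normalised to sum 1.

    ``shape`` is the lognormal sigma: 0 gives a uniform pool, larger values
    give steeper rank-abundance curves (a few dominant taxa, a long rare
    tail), as is typical for amplicon communities.
    """
    if n_taxa < 2:
        raise ValidationError(f"n_taxa must be >= 2, got {n_taxa}")
    if shape < 0:
        raise ValidationError(f"shape must be >= 0, got {shape}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = np.exp(rng.normal(0.0, shape, size=n_taxa))
    x = np.sort(x)[::-1]
    return x / x.sum()


def simulate_tree(
    n_taxa: int,
    seed: int | np.random.Generator,
    labels: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Pure-birth (Yule) tree with depth scaled to 1, binary and ultrametric.

    Tip labels default to ``ASV1..ASVn``; pass ``labels`` to match a table.
    """
    if n_taxa < 2:
        raise ValidationError(f"n_taxa must be >= 2, got {n_taxa}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if labels is None:
        labels = [f"ASV{i + 1}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ValidationError("labels length must equal n_taxa")

    # grow: the root splits at time 0 into two lineages; nodes recorded as
    # (parent, birth_time) and tips resolved at the final present time
    parents: list[int | None] = [None, 0, 0]
    times: list[float] = [0.0, 0.0, 0.0]
    active = [1, 2]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        for _ in range(2):
            parents.append(node)
            times.append(t)
            active.append(len(parents) - 1)
    present = t + rng.exponential(1.0 / n_taxa)

    children: dict[int, list[int]] = {}
    for idx, par in enumerate(parents):
        if par is not None:
            children.setdefault(par, []).append(idx)

    tip_labels = iter(labels)

    def newick(idx: int) -> str:
        start = times[idx]
        if idx in children:
            end = times[children[idx][0]]
            sub = ",".join(newick(c) for c in children[idx])
            body = f"({sub})"
        else:
            end = present
            body = next(tip_labels)
        return f"{body}:{(end - start) / present:.10f}"

    nwk = newick(0).rsplit(":", 1)[0] + ";"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    return tree


def brownian_traits(tree: dendropy.Tree, rng: np.random.Generator) -> dict[str, float]:
    """Brownian-motion trait values at the tips (root value 0, rate 1).

    On a unit-depth ultrametric tree the root-to-tip trait SD is 1, so
    environmental offsets are expressed in trait-SD units.
    """
    values: dict[int, float] = {}
    traits: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            bl = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + rng.normal(0.0, np.sqrt(max(bl, 0.0)))
        if node.is_leaf():
            traits[node.taxon.label] = values[id(node)]
    return traits


# ---------------------------------------------------------------------------
# per-regime count generators (taxon x sample integer tables)


def _multinomial_columns(q: np.ndarray, reads: int, rng: np.random.Generator) -> np.ndarray:
    """Sample one multinomial column per row of ``q`` (samples x taxa)."""
    out = np.empty((q.shape[1], q.shape[0]), dtype=np.int64)
    for s in range(q.shape[0]):
        out[:, s] = rng.multinomial(reads, q[s] / q[s].sum())
    return out


def simulate_neutral_counts(
    pool: np.ndarray,
    nm: float,
    n_samples: int,
    reads_per_sample: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Neutral-assembly counts: Beta(Nm*p, Nm*(1-p)) local abundances, then reads.

    This inverts the Sloan neutral-model fit: under neutral immigration at
    rate ``Nm`` the local relative abundance of a taxon with pool abundance
    ``p`` is beta-distributed around ``p``; multinomial read sampling then
    yields an integer table whose occurrence frequencies follow the model.
    """
    if nm <= 0:
        raise ValidationError(f"Nm must be > 0, got {nm}")
    if reads_per_sample <= 0:
        raise ValidationError(f"reads_per_sample must be > 0, got {reads_per_sample}")
    p = np.asarray(pool, dtype=float)
    q = rng.beta(np.maximum(nm * p, 1e-12), np.maximum(nm * (1.0 - p), 1e-12), size=(n_samples, p.size))
    q = np.clip(q, 1e-300, None)
    return _multinomial_columns(q, reads_per_sample, rng)


def simulate_selection_counts(
    pool: np.ndarray,
    tree: dendropy.Tree,
    taxon_ids: Sequence[str],
    env_per_sample: np.ndarray,
    trait_sd: float,
    reads_per_sample: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Environmentally filtered counts with phylogenetically conserved traits.

    A Brownian trait is evolved on ``tree``; sample-level fitness
    ``exp(-(trait - env)^2 / (2 trait_sd^2))`` multiplies the pool abundance
    before multinomial read sampling.  Samples with contrasting ``env``
    therefore favour phylogenetically distinct clades.
    """
    env = np.asarray(env_per_sample, dtype=float)
    if env.size == 0:
        raise ValidationError("env_per_sample must be non-empty")
    if not np.all(np.isfinite(env)):
        raise ValidationError("env values must be finite")
    if trait_sd <= 0:
        raise ValidationError(f"trait_sd must be > 0, got {trait_sd}")
    traits_by_label = brownian_traits(tree, rng)
    missing = [t for t in taxon_ids if t not in traits_by_label]
    if missing:
        raise ValidationError(f"taxa missing from tree: {missing}")
    traits = np.array([traits_by_label[t] for t in taxon_ids])
    p = np.asarray(pool, dtype=float)
    w = np.exp(-((traits[None, :] - env[:, None]) ** 2) / (2.0 * trait_sd**2))
    q = np.clip(p[None, :] * w, 1e-300, None)
    return _multinomial_columns(q, reads_per_sample, rng)


def simulate_dispersal_limited_counts(
    pool: np.ndarray,
    subsample_fraction: float,
    n_samples: int,
    reads_per_sample: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dispersal-limited counts: spatially structured colonisation.

    Taxa are placed on a latent ring in random order (independent of
    phylogeny and abundance); each sample colonises a contiguous window
    covering ``subsample_fraction`` of the ring around a random centre, and
    reads are multinomial on the renormalised pool restricted to that
    window.  Samples with distant centres share few or no taxa, so pairs
    are more dissimilar than an occupancy-proportional stochastic null
    expects (RC -> +1) with no phylogenetic signal (βNTI ~ 0); a purely
    random subset per sample would instead reproduce the null itself.
    """
    p = np.asarray(pool, dtype=float)
    t = p.size
    k = max(2, int(round(subsample_fraction * t)))
    ring = rng.permutation(t)
    q = np.zeros((n_samples, t))
    for s in range(n_samples):
        start = int(rng.integers(t))
        idx = ring[(start + np.arange(k)) % t]
        q[s, idx] = p[idx]
    return _multinomial_columns(q, reads_per_sample, rng)


def simulate_planted_network_counts(
    pool: np.ndarray,
    planted_edges: Sequence[tuple[int, int, int]],
    noise_sd: float,
    n_samples: int,
    reads_per_sample: int,
    rng: np.random.Generator,
    latent_sd: float = 1.0,
) -> np.ndarray:
    """Counts with known planted pairwise correlations.

    Planted pairs share a latent Gaussian log-abundance factor (sign-flipped
    for negative edges) plus independent noise of scale ``noise_sd``; all
    other taxa fluctuate independently at scale ``latent_sd``.  Planted
    pairs then exceed the background |Spearman rho| in expectation.
    """
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    p = np.asarray(pool, dtype=float)
    seen: set[int] = set()
    for i, j, s in planted_edges:
        if i == j:
            raise ValidationError(f"planted self-edge ({i}, {i}) is invalid")
        if not (0 <= i < p.size and 0 <= j < p.size):
            raise ValidationError(f"planted edge ({i}, {j}) outside taxon range")
        if s not in (1, -1):
            raise ValidationError(f"planted edge sign must be +1/-1, got {s}")
        if i in seen or j in seen:
            raise ValidationError("each taxon may appear in at most one planted pair")
        seen.update((i, j))
    log_ab = np.log(p)[None, :] + latent_sd * rng.normal(size=(n_samples, p.size))
    for i, j, s in planted_edges:
        z = rng.normal(size=n_samples)
        log_ab[:, i] = np.log(p[i]) + latent_sd * (z + noise_sd * rng.normal(size=n_samples))
        log_ab[:, j] = np.log(p[j]) + latent_sd * (s * z + noise_sd * rng.normal(size=n_samples))
    q = np.exp(log_ab - log_ab.max(axis=1, keepdims=True))
    return _multinomial_columns(q, reads_per_sample, rng)


def simulate_core_enrichment_counts(
    pool: np.ndarray,
    taxon_ids: Sequence[str],
    groups: Sequence[str],
    core_taxa: dict[str, float],
    enriched_taxa: Sequence[tuple[str, str, float]],
    reads_per_sample: int,
    rng: np.random.Generator,
    overdispersion_sd: float = 0.5,
) -> np.ndarray:
    """Counts with designated core and group-enriched taxa.

    Core taxa are pinned at a fixed target relative abundance in every
    sample (so prevalence is 1 by construction); enriched taxa get a
    ``2**log2fc`` multiplier in the named group; the remaining taxa carry
    mild lognormal sample-to-sample noise.
    """
    index = {t: k for k, t in enumerate(taxon_ids)}
    p = np.asarray(pool, dtype=float).copy()
    for taxon, target in core_taxa.items():
        if taxon not in index:
            raise ValidationError(f"unknown core taxon {taxon!r}")
        p[index[taxon]] = target
    n_samples = len(groups)
    noise = np.exp(overdispersion_sd * rng.normal(size=(n_samples, p.size)))
    q = p[None, :] * noise
    for taxon, group, lfc in enriched_taxa:
        if taxon not in index:
            raise ValidationError(f"unknown enriched taxon {taxon!r}")
        mask = np.array([g == group for g in groups])
        if not mask.any():
            raise ValidationError(f"enrichment group {group!r} matches no samples")
        q[mask, index[taxon]] *= 2.0**lfc
    for taxon in core_taxa:
        q[:, index[taxon]] = p[index[taxon]]  # core pinned, no noise
    return _multinomial_columns(q, reads_per_sample, rng)


# ---------------------------------------------------------------------------
# design-level assembly


def design_metadata(design: DesignSpec) -> SampleMetadata:
    """Sample sheet for the full sites x genotypes x replicates design."""
    rows = []
    for site in design.site_names():
        for geno in design.genotype_names():
            for rep in range(1, design.n_replicates + 1):
                rows.append((f"{site}_{geno}_{rep}", site, geno, rep))
    frame = pd.DataFrame(rows, columns=["sample_id", "site", "genotype", "replicate"])
    return SampleMetadata(frame.set_index("sample_id"))


def taxon_labels(design: DesignSpec) -> tuple[list[str], pd.Series]:
    n = design.n_taxa_per_kingdom
    ids = [f"BASV{i + 1}" for i in range(n)] + [f"FASV{i + 1}" for i in range(n)]
    kingdom = pd.Series(["bacteria"] * n + ["fungi"] * n, index=ids)
    return ids, kingdom


@dataclass
class SimulatedDataset:
    """A complete synthetic study: table, metadata, per-kingdom trees, truth."""

    table: FeatureTable
    metadata: SampleMetadata
    trees: dict[str, dendropy.Tree]
    truth: dict


def simulate_scenario(design: DesignSpec, params: ScenarioParams) -> SimulatedDataset:
    """Generate a full dataset under one assembly regime.

    Bacteria and fungi are simulated independently (separate pools and
    trees) and stacked into one two-kingdom table aligned to the design's
    sample sheet.
    """
    rng = np.random.default_rng(design.seed)
    meta = design_metadata(design)
    ids, kingdom = taxon_labels(design)
    n = design.n_taxa_per_kingdom
    blocks = []
    trees: dict[str, dendropy.Tree] = {}
    truth: dict = {"scenario": params.scenario}
    groups = list(meta.frame["genotype"])
    for king, king_ids in (("bacteria", ids[:n]), ("fungi", ids[n:])):
        pool = simulate_metacommunity(n, params.pool_shape, rng)
        tree = simulate_tree(n, rng, labels=king_ids)
        trees[king] = tree
        if params.scenario == "neutral":
            counts = simulate_neutral_counts(pool, params.nm, design.n_samples, design.reads_per_sample, rng)
            truth.setdefault("nm", params.nm)
        elif params.scenario in ("heterogeneous_selection", "homogeneous_selection"):
            if params.scenario == "homogeneous_selection":
                env = np.zeros(design.n_samples)
            else:
                env = np.array([params.env_values[g] for g in groups])
            counts = simulate_selection_counts(
                pool, tree, king_ids, env, params.trait_sd, design.reads_per_sample, rng
            )
            truth.setdefault("env_values", dict(params.env_values))
        elif params.scenario == "dispersal_limitation":
            counts = simulate_dispersal_limited_counts(
                pool, params.subsample_fraction, design.n_samples, design.reads_per_sample, rng
            )
        elif params.scenario == "planted_network":
            edges = [(i, j, s) for i, j, s in params.planted_edges] if king == "bacteria" else []
            counts = simulate_planted_network_counts(
                pool, edges, params.noise_sd, design.n_samples, design.reads_per_sample, rng,
                latent_sd=params.latent_sd,
            )
            truth.setdefault("planted_edges", [(ids[i], ids[j], s) for i, j, s in params.planted_edges])
        elif params.scenario == "core_and_enrichment":
            core = {t: a for t, a in params.core_taxa.items() if t in king_ids}
            enr = [(t, g, f) for t, g, f in params.enriched_taxa if t in king_ids]
            counts = simulate_core_enrichment_counts(
                pool, king_ids, groups, core, enr, design.reads_per_sample, rng
            )
            truth.setdefault("core_taxa", dict(params.core_taxa))
            truth.setdefault("enriched_taxa", list(params.enriched_taxa))
        else:  # pragma: no cover - guarded by ScenarioParams
            raise ValidationError(f"unknown scenario {params.scenario!r}")
        blocks.append(pd.DataFrame(counts, index=king_ids, columns=meta.sample_ids))
        truth.setdefault("pool", {})[king] = pool
    table = FeatureTable(pd.concat(blocks), kingdom)
    return SimulatedDataset(table=table, metadata=meta, trees=trees, truth=truth)
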