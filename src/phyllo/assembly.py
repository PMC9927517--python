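"""Community assembly processes: neutral fit, phylogenetic and taxonomic
null models, process partitioning, and niche breadth.

The Sloan neutral community model predicts a taxon's occurrence frequency
across samples from its mean relative abundance ``p`` via a beta
distribution governed by ``Nm`` (metacommunity size x migration rate):
``pred_freq = 1 - BetaCDF(d; Nm*p, Nm*(1-p))`` at detection limit ``d``.
``Nm`` is fitted by bounded least squares; taxa are partitioned by whether
their observed frequency falls above, within, or below the Wilson 95 %
band around the prediction.

The five-process framework combines the beta nearest-taxon index (βNTI, a
z-score of abundance-weighted βMNTD against a tip-shuffle null) with the
Bray-Curtis Raup-Crick index (RCbray, a rescaled rank of observed
dissimilarity within a stochastic-assembly null):

* βNTI > +2  -> heterogeneous (variable) selection
* βNTI < -2  -> homogeneous selection
* |βNTI| <= 2 and RC > +0.95 -> dispersal limitation (with drift)
* |βNTI| <= 2 and RC < -0.95 -> homogenizing dispersal
* otherwise -> drift alone

Levins' niche breadth: B_i = 1 / sum_j P_ij^2 where P_ij is the fraction
of taxon i's total abundance found in sample j; Bcom is the mean over taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial.distance import pdist, squareform
from scipy.stats import beta as beta_dist
from statsmodels.stats.proportion import proportion_confint

from .errors import ComputationError, ValidationError
from .tables import FeatureTable, tree_distance_matrix

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


# ---------------------------------------------------------------------------
# Sloan neutral community model


@dataclass
class NeutralFit:
    m: float  # migration rate, Nm / N
    nm: float
    n: float  # community size used (mean sample depth)
    r2: float
    detection_limit: float
    per_taxon: pd.DataFrame  # mean_relabund, obs_freq, pred_freq, lower, upper, partition
    fraction_above: float
    fraction_within: float
    fraction_below: float

    @property
    def fraction_deviating(self) -> float:
        return self.fraction_above + self.fraction_below


def fit_neutral(table: FeatureTable, detection_limit: float | None = None) -> NeutralFit:
    """Fit the Sloan neutral model to occurrence frequency vs abundance.

    ``N`` is the mean per-sample total count and the detection limit
    defaults to ``1/N``.  Requires at least 10 samples.  When every taxon
    occurs in every sample the fit is degenerate; it is still reported
    (R^2 becomes NaN) rather than raised.
    """
    n_samples = len(table.sample_ids)
    if n_samples < 10:
        raise ValidationError(f"neutral fit needs >= 10 samples, got {n_samples}")
    counts = table.counts.to_numpy()
    big_n = float(counts.sum(axis=0).mean())
    d = detection_limit if detection_limit is not None else 1.0 / big_n
    rel = table.relative_abundance().to_numpy()
    p = rel.mean(axis=1)
    keep = p > 0
    p = p[keep]
    taxa = table.counts.index[keep]
    obs_freq = (counts[keep] > 0).mean(axis=1)

    def predict(nm: float) -> np.ndarray:
        return 1.0 - beta_dist.cdf(d, nm * p, nm * (1.0 - p))

    def sse(log_nm: float) -> float:
        resid = obs_freq - predict(10.0**log_nm)
        return float(resid @ resid)

    res = optimize.minimize_scalar(sse, bounds=(-1.0, np.log10(big_n) + 2.0), method="bounded")
    if not res.success:
        raise ComputationError(f"neutral fit failed: {res}")
    nm = float(10.0**res.x)
    pred = predict(nm)
    ss_res = float(np.sum((obs_freq - pred) ** 2))
    ss_tot = float(np.sum((obs_freq - obs_freq.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("all taxa share one occurrence frequency; R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    lower, upper = proportion_confint(
        np.round(pred * n_samples), n_samples, alpha=0.05, method="wilson"
    )
    partition = np.where(obs_freq > upper, "above", np.where(obs_freq < lower, "below", "within"))
    per_taxon = pd.DataFrame(
        {
            "mean_relabund": p,
            "obs_freq": obs_freq,
            "pred_freq": pred,
            "lower": lower,
            "upper": upper,
            "partition": partition,
        },
        index=taxa,
    )
    frac = per_taxon["partition"].value_counts(normalize=True)
    return NeutralFit(
        m=nm / big_n,
        nm=nm,
        n=big_n,
        r2=r2,
        detection_limit=d,
        per_taxon=per_taxon,
        fraction_above=float(frac.get("above", 0.0)),
        fraction_within=float(frac.get("within", 0.0)),
        fraction_below=float(frac.get("below", 0.0)),
    )


# ---------------------------------------------------------------------------
# beta-MNTD / beta-NTI


def _beta_mntd_from_dist(rel: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Abundance-weighted βMNTD for all sample pairs.

    ``rel``: taxon x sample relative abundances; ``dist``: taxon x taxon
    patristic distances.  For each sample the nearest-taxon distance vector
    is min over its present taxa, giving βMNTD(k, l) = 0.5 * (f_k . dmin_l
    + f_l . dmin_k).
    """
    present = rel > 0
    n_taxa, n_samples = rel.shape
    dmin = np.empty((n_taxa, n_samples))
    for s in range(n_samples):
        dmin[:, s] = dist[:, present[:, s]].min(axis=1)
    half = rel.T @ dmin  # (k, l): sum_i f_ik * dmin_l[i]
    out = 0.5 * (half + half.T)
    np.fill_diagonal(out, 0.0)
    return out


def beta_mntd(table: FeatureTable, tree: dendropy.Tree, weighted: bool = True) -> pd.DataFrame:
    """Observed between-community mean nearest-taxon distance matrix."""
    dist = tree_distance_matrix(tree, table.taxon_ids)
    rel = table.relative_abundance().to_numpy()
    if not weighted:
        rel = (rel > 0) / (rel > 0).sum(axis=0)
    vals = _beta_mntd_from_dist(rel, dist)
    return pd.DataFrame(vals, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class BetaNTIResult:
    beta_nti: pd.DataFrame
    observed_bmntd: pd.DataFrame
    n_null: int
    n_undefined_pairs: int


def beta_nti(
    table: FeatureTable,
    tree: dendropy.Tree,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> BetaNTIResult:
    """βNTI: z-score of observed βMNTD against a tip-label-shuffle null.

    The null shuffles taxon labels across all tree tips; one shuffle
    sequence is shared by every sample pair, keeping the cost
    O(n_null * pairs).  Pairs with zero null SD are reported as NaN with a
    warning.
    """
    dist = tree_distance_matrix(tree, table.taxon_ids)
    rel = table.relative_abundance().to_numpy()
    if not weighted:
        rel = (rel > 0) / (rel > 0).sum(axis=0)
    obs = _beta_mntd_from_dist(rel, dist)
    rng = np.random.default_rng(seed)
    n = obs.shape[0]
    mean = np.zeros((n, n))
    m2 = np.zeros((n, n))
    for t in range(n_null):
        perm = rng.permutation(dist.shape[0])
        null = _beta_mntd_from_dist(rel, dist[np.ix_(perm, perm)])
        delta = null - mean
        mean += delta / (t + 1)
        m2 += delta * (null - mean)
    sd = np.sqrt(m2 / max(n_null - 1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mean) / sd
    np.fill_diagonal(z, 0.0)
    iu = np.triu_indices(n, 1)
    undefined = int(np.sum(~np.isfinite(z[iu])))
    if undefined:
        warnings.warn(f"{undefined} sample pair(s) have zero null SD; βNTI undefined", stacklevel=2)
    z[~np.isfinite(z)] = np.nan
    np.fill_diagonal(z, 0.0)
    ids = table.sample_ids
    return BetaNTIResult(
        beta_nti=pd.DataFrame(z, index=ids, columns=ids),
        observed_bmntd=pd.DataFrame(obs, index=ids, columns=ids),
        n_null=n_null,
        n_undefined_pairs=undefined,
    )


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis


def raup_crick_bray(table: FeatureTable, n_null: int = 999, seed: int = 0) -> pd.DataFrame:
    """RCbray: rescaled rank of observed Bray-Curtis within an assembly null.

    Null communities preserve each sample's observed richness and total
    reads: taxa are drawn without replacement with probability proportional
    to occupancy across all samples, then reads are allocated
    multinomially in proportion to total relative abundance among the drawn
    taxa.  One null table per iteration serves every pair.  RC is rescaled
    to [-1, 1]; values near +1 mean less similar than the null expects.
    """
    counts = table.counts.to_numpy()
    n_taxa, n_samples = counts.shape
    if n_samples < 2:
        raise ValidationError("Raup-Crick requires at least 2 samples")
    richness = (counts > 0).sum(axis=0)
    if (richness == 0).any():
        bad = table.sample_ids[int(np.argmax(richness == 0))]
        raise ValidationError(f"sample {bad!r} has richness 0")
    reads = counts.sum(axis=0)
    occupancy = (counts > 0).mean(axis=1)
    abundance = counts.sum(axis=1).astype(float)
    abundance /= abundance.sum()
    occ_p = occupancy / occupancy.sum()
    rel = counts / reads
    obs_bc = pdist(rel.T, metric="braycurtis")

    rng = np.random.default_rng(seed)
    less = np.zeros_like(obs_bc)
    equal = np.zeros_like(obs_bc)
    null_rel = np.empty((n_samples, n_taxa))
    for _ in range(n_null):
        null_rel[:] = 0.0
        for s in range(n_samples):
            drawn = rng.choice(n_taxa, size=richness[s], replace=False, p=occ_p)
            probs = abundance[drawn]
            tot = probs.sum()
            if tot <= 0:
                probs = np.ones(len(drawn))
                tot = float(len(drawn))
            alloc = rng.multinomial(reads[s], probs / tot)
            null_rel[s, drawn] = alloc / reads[s]
        null_bc = pdist(null_rel, metric="braycurtis")
        less += null_bc < obs_bc - 1e-12
        equal += np.abs(null_bc - obs_bc) <= 1e-12
    rc = (less + 0.5 * equal) / n_null
    rc = (rc - 0.5) * 2.0
    ids = table.sample_ids
    return pd.DataFrame(squareform(rc), index=ids, columns=ids)


# ---------------------------------------------------------------------------
# five-process partition


@dataclass
class ProcessFractions:
    fractions: dict[str, float]
    n_pairs: int
    n_excluded: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.n_pairs and abs(total - 1.0) > 1e-12:
            raise ComputationError(f"process fractions sum to {total}, expected 1")


def classify_pair(nti: float, rc: float, nti_cut: float = 2.0, rc_cut: float = 0.95) -> str:
    if nti > nti_cut:
        return "heterogeneous_selection"
    if nti < -nti_cut:
        return "homogeneous_selection"
    if rc > rc_cut:
        return "dispersal_limitation"
    if rc < -rc_cut:
        return "homogenizing_dispersal"
    return "drift"


def partition_processes(
    beta_nti_matrix: pd.DataFrame,
    rc_matrix: pd.DataFrame,
    nti_cut: float = 2.0,
    rc_cut: float = 0.95,
) -> ProcessFractions:
    """Assign each sample pair to one of the five assembly processes.

    Pairs with undefined βNTI are excluded from the denominator and their
    count reported.
    """
    if not beta_nti_matrix.index.equals(rc_matrix.index):
        raise ValidationError("βNTI and RC matrices are not aligned")
    n = beta_nti_matrix.shape[0]
    iu = np.triu_indices(n, 1)
    nti = beta_nti_matrix.to_numpy()[iu]
    rc = rc_matrix.to_numpy()[iu]
    ok = np.isfinite(nti) & np.isfinite(rc)
    counts = {proc: 0 for proc in PROCESSES}
    for z, r in zip(nti[ok], rc[ok]):
        counts[classify_pair(z, r, nti_cut, rc_cut)] += 1
    n_ok = int(ok.sum())
    fractions = {k: (v / n_ok if n_ok else 0.0) for k, v in counts.items()}
    return ProcessFractions(fractions=fractions, n_pairs=n_ok, n_excluded=int((~ok).sum()))


# ---------------------------------------------------------------------------
# Levins' niche breadth


@dataclass
class NicheBreadth:
    per_taxon: pd.Series  # Levins B per taxon
    community_mean: float  # Bcom
    n_excluded: int


def niche_breadth(table: FeatureTable) -> NicheBreadth:
    """Levins' B = 1 / sum_j P_ij^2 per taxon; Bcom = mean over taxa.

    ``P_ij`` is the proportion of taxon i's total abundance found in sample
    j, so B ranges from 1 (single-sample specialist) to n_samples (evenly
    spread generalist).  All-zero taxa are excluded with a warning.
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    excluded = int((totals == 0).sum())
    if excluded:
        warnings.warn(f"{excluded} all-zero taxa excluded from niche breadth", stacklevel=2)
    keep = totals > 0
    p = counts[keep] / totals[keep, None]
    b = 1.0 / (p**2).sum(axis=1)
    series = pd.Series(b, index=table.counts.index[keep], name="levins_b")
    return NicheBreadth(per_taxon=series, community_mean=float(series.mean()), n_excluded=excluded)
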