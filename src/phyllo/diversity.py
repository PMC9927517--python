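"""Alpha/beta diversity, ordination, PERMANOVA, core taxa, and enrichment.

All statistics operate on relative abundances (no rarefaction by default;
:meth:`phyllo.tables.FeatureTable.rarefy` is available for sensitivity
checks).  Shannon uses the natural log.  PERMANOVA is the one-factor,
free-permutation form (no strata), with the pseudo-F computed from total
vs within-group sums of squared Bray-Curtis distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError, ValidationError
from .tables import FeatureTable, SampleMetadata


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("distance matrix shape does not match sample_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        self.values = v

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def shannon(counts: np.ndarray | pd.Series) -> float:
    """Shannon diversity H = -sum p ln p of one sample's counts."""
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValidationError("cannot compute Shannon index of an all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: FeatureTable) -> pd.Series:
    return pd.Series(
        {s: shannon(table.counts[s]) for s in table.sample_ids}, name="shannon"
    )


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on per-sample relative abundances.

    d(j, k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik); entries in [0, 1].
    """
    if len(table.sample_ids) < 2:
        raise ValidationError("Bray-Curtis requires at least 2 samples")
    rel = table.relative_abundance().to_numpy()
    diff = np.abs(rel[:, :, None] - rel[:, None, :]).sum(axis=0)
    tot = (rel[:, :, None] + rel[:, None, :]).sum(axis=0)
    d = diff / tot
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.sample_ids, (d + d.T) / 2.0)


@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # all eigenvalues, descending (may include < 0)
    proportion_explained: np.ndarray  # per retained axis, positive-eigenvalue denominator
    warnings: list[str]


def pcoa(dm: DistanceMatrix, k: int = 2) -> PcoaResult:
    """Principal coordinates: eigendecomposition of the Gower-centred matrix.

    Negative eigenvalues are retained in the eigenvalue report but excluded
    from the proportion-explained denominator; no Cailliez correction.  If
    fewer than ``k`` positive eigenvalues exist the embedding is truncated
    and a warning recorded.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    d2 = dm.values**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10 * max(eigval.max(), 1.0)
    n_pos = int(pos.sum())
    warnings = []
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.append(f"requested {k} axes but only {n_pos} positive eigenvalues; truncated")
    coords = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])
    denom = eigval[pos].sum()
    prop = eigval[:k_eff] / denom if denom > 0 else np.zeros(k_eff)
    return PcoaResult(dm.sample_ids, coords, eigval, prop, warnings)


@dataclass
class PermanovaResult:
    factor: str
    r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix,
    metadata: SampleMetadata,
    factor: str,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA with free permutation of sample labels.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations);
    R^2 = SS_between / SS_total.
    """
    meta = metadata.frame.loc[dm.sample_ids]
    labels = meta[factor].to_numpy()
    levels, inv = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        raise ValidationError(f"factor {factor!r} has a single level; PERMANOVA undefined")
    n = len(labels)
    a = len(levels)
    d2 = dm.values**2

    # vectorised: SSW per permutation via one-hot quadratic forms
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def ssw(assign: np.ndarray) -> np.ndarray:
        # assign: (m, n) int level codes; returns (m,) within-group SS
        out = np.zeros(assign.shape[0])
        for g in range(a):
            h = (assign == g).astype(float)  # (m, n)
            ng = h.sum(axis=1)
            quad = np.einsum("mi,ij,mj->m", h, d2, h) / 2.0
            out += np.where(ng > 0, quad / np.maximum(ng, 1), 0.0)
        return out

    obs_ssw = ssw(inv[None, :])[0]
    ss_between = ss_total - obs_ssw
    df_between, df_within = a - 1, n - a
    if df_within <= 0 or obs_ssw <= 0:
        raise ComputationError("PERMANOVA degenerate: no within-group degrees of freedom")
    obs_f = (ss_between / df_between) / (obs_ssw / df_within)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(inv) for _ in range(n_permutations)])
    perm_ssw = ssw(perms)
    perm_f = ((ss_total - perm_ssw) / df_between) / (perm_ssw / df_within)
    p = (1.0 + np.sum(perm_f >= obs_f)) / (1.0 + n_permutations)
    return PermanovaResult(factor, float(ss_between / ss_total), float(obs_f), float(p), n_permutations)


@dataclass
class CoreTaxaResult:
    core_ids: list[str]
    prevalence: pd.Series  # all taxa
    mean_relabund: pd.Series  # all taxa


def core_taxa(
    table: FeatureTable,
    prevalence_min: float = 1.0,
    abundance_min: float = 0.001,
) -> CoreTaxaResult:
    """Core microbiome: taxa present in every sample at >0.1 % mean abundance.

    ``prevalence_min`` defaults to 1.0 (100 % prevalence: occurrence in all
    samples) and ``abundance_min`` to 0.001 (mean relative abundance must
    exceed 0.1 %); both thresholds follow the published core definition.
    """
    if not 0 < prevalence_min <= 1 or not 0 < abundance_min <= 1:
        raise ValidationError("thresholds must be in (0, 1]")
    rel = table.relative_abundance()
    prevalence = (table.counts > 0).mean(axis=1)
    mean_rel = rel.mean(axis=1)
    core = table.counts.index[(prevalence >= prevalence_min) & (mean_rel > abundance_min)]
    return CoreTaxaResult(list(core), prevalence, mean_rel)


def enrichment(
    table: FeatureTable,
    metadata: SampleMetadata,
    group_factor: str = "genotype",
    lfc_min: float = 2.0,
    fdr_max: float = 0.01,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Differential abundance between two groups with the published cut-offs.

    Per taxon: log2 fold change of group mean relative abundances (with a
    pseudocount of half the smallest nonzero mean, unless given), a
    two-sided Wilcoxon rank-sum test on per-sample relative abundances, and
    Benjamini-Hochberg adjustment across taxa.  A taxon is called enriched
    in a group when |log2FC| > ``lfc_min`` and adjusted p < ``fdr_max``.

    Returns a DataFrame indexed by taxon with columns ``log2fc``, ``p``,
    ``p_adj`` and ``enriched_in`` (group name or ``"unchanged"``).
    """
    meta = metadata.align_to(table).frame
    groups = list(pd.unique(meta[group_factor]))
    if len(groups) != 2:
        raise ValidationError(f"{group_factor!r} must have exactly 2 levels, got {groups}")
    g1, g2 = groups
    s1 = meta.index[meta[group_factor] == g1]
    s2 = meta.index[meta[group_factor] == g2]
    if len(s1) < 3 or len(s2) < 3:
        raise ValidationError("each group needs >= 3 samples for the rank-sum test")
    rel = table.relative_abundance()
    m1, m2 = rel[s1].mean(axis=1), rel[s2].mean(axis=1)
    if pseudocount is None:
        nz = pd.concat([m1[m1 > 0], m2[m2 > 0]])
        pseudocount = float(nz.min()) / 2.0 if len(nz) else 1e-9
    log2fc = np.log2((m1 + pseudocount) / (m2 + pseudocount))
    pvals = np.ones(len(rel))
    x1, x2 = rel[s1].to_numpy(), rel[s2].to_numpy()
    for i in range(len(rel)):
        if np.ptp(np.concatenate([x1[i], x2[i]])) == 0:
            pvals[i] = 1.0
        else:
            pvals[i] = mannwhitneyu(x1[i], x2[i], alternative="two-sided").pvalue
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    enriched = np.where(
        (np.abs(log2fc) > lfc_min) & (p_adj < fdr_max),
        np.where(log2fc > 0, g1, g2),
        "unchanged",
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "p_adj": p_adj, "enriched_in": enriched},
        index=rel.index,
    )
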