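"""Alpha diversity, genus composition, ordination and treatment comparison.

Shannon uses natural log by default (the R convention); Chao1 is the
bias-corrected estimator S_obs + F1(F1-1)/(2(F2+1)) so it stays finite
when no doubletons are observed. Composition is summarized by the first
principal coordinate (classical PCoA) of Bray-Curtis dissimilarities on
relative abundances. Treatment comparison is one-way ANOVA with all-pairs
Tukey HSD summarized as a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway, pearsonr
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i (natural log unless ``base``)."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("Shannon undefined for an all-zero sample")
    return float(_skbio_shannon(counts, base=base))


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness from singleton/doubleton counts; integer counts only."""
    counts = np.asarray(counts)
    if not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError("Chao1 is undefined on non-integer (relative) abundances")
    counts = counts.astype(int)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return float(_skbio_chao1(counts, bias_corrected=bias_corrected))


def diversity_table(table, base: float | None = None) -> pd.DataFrame:
    """Per-sample Shannon and Chao1 for one OTU table."""
    rows = []
    for sample in table.sample_ids:
        counts = table.counts[sample].to_numpy()
        rows.append({
            "sample_id": sample,
            "gene_tag": table.gene_tag,
            "shannon": shannon(counts, base=base),
            "chao1": chao1(counts),
        })
    return pd.DataFrame(rows)


def genus_composition(table, threshold: float = 0.0,
                      others_label: str = "Others") -> pd.DataFrame:
    """Genus x sample relative-abundance matrix (columns sum to 1).

    OTUs without a genus label are pooled as ``unclassified``; genera whose
    mean relative abundance across samples falls below ``threshold`` are
    pooled into ``others_label``.
    """
    rel = table.relative_abundance()
    genus = table.genus.replace("", "unclassified").fillna("unclassified")
    comp = rel.groupby(genus).sum()
    if threshold > 0:
        minor = comp.index[comp.mean(axis=1) < threshold]
        if len(minor) > 0:
            pooled = comp.loc[minor].sum(axis=0)
            comp = comp.drop(index=minor)
            comp.loc[others_label] = comp.loc[others_label] + pooled \
                if others_label in comp.index else pooled
    return comp.sort_values(comp.columns[0], ascending=False) if comp.shape[1] else comp


def bray_curtis(table) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity on relative abundances."""
    rel = table.relative_abundance().to_numpy().T  # samples x OTUs
    d = squareform(pdist(rel, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def pcoa_ordination(dissimilarity: pd.DataFrame):
    """Classical (metric) PCoA; returns (coordinates DataFrame, eigenvalues).

    Negative eigenvalues (non-Euclidean dissimilarities) are dropped with a
    warning; no Lingoes/Cailliez correction is applied.
    """
    dm = DistanceMatrix(dissimilarity.to_numpy(), ids=list(dissimilarity.index))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*negative eigenvalues.*")
        res = _skbio_pcoa(dm, method="eigh")
    eigvals = res.eigvals.to_numpy()
    if (eigvals < -1e-8 * max(eigvals.max(), 1.0)).any():
        warnings.warn("negative PCoA eigenvalues dropped (non-Euclidean dissimilarity)")
    keep = eigvals > 0
    coords = res.samples.iloc[:, : int(keep.sum())]
    coords.index = dissimilarity.index
    return coords, eigvals[keep]


def composition_pc1(table, orient_by=None) -> pd.Series:
    """Per-sample community-composition score: PC1 of Bray-Curtis PCoA.

    The axis sign is arbitrary in PCoA; it is fixed deterministically so the
    score correlates positively with ``orient_by`` (any per-sample covariate,
    e.g. sample order) or, absent one, so the largest-magnitude score is
    positive.
    """
    if len(table.sample_ids) < 3:
        raise ValueError("composition PC1 needs at least 3 samples")
    d = bray_curtis(table)
    if np.allclose(d.to_numpy(), 0):
        raise ValueError("all samples identical; PC1 undefined")
    coords, _ = pcoa_ordination(d)
    pc1 = coords.iloc[:, 0].rename("PC1")
    if orient_by is not None:
        ref = np.asarray(pd.Series(orient_by).loc[pc1.index]
                         if isinstance(orient_by, pd.Series) else orient_by, dtype=float)
        c = np.corrcoef(pc1.to_numpy(), ref)[0, 1]
        if np.isfinite(c) and c < 0:
            pc1 = -pc1
    elif pc1.iloc[np.argmax(np.abs(pc1.to_numpy()))] < 0:
        pc1 = -pc1
    return pc1


@dataclass
class LetterSummary:
    treatment: str
    mean: float
    sd: float
    letters: str


def tukey_pvalues(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD p-values (long frame: group1, group2, p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if min((groups == g).sum() for g in labels) < 2:
        raise ValueError("need at least 2 replicates per group")
    pooled = [values[groups == g] for g in labels]
    mse = np.sum([np.sum((v - v.mean()) ** 2) for v in pooled]) / (len(values) - len(labels))
    rows = []
    if mse == 0:
        # degenerate: no within-group variance; differing means separate at p -> 0
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                equal = np.isclose(pooled[i].mean(), pooled[j].mean())
                rows.append((labels[i], labels[j], 1.0 if equal else 0.0))
        return pd.DataFrame(rows, columns=["group1", "group2", "p"])
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    pairs = list(combinations(res.groupsunique, 2))
    return pd.DataFrame({"group1": [a for a, _ in pairs],
                         "group2": [b for _, b in pairs],
                         "p": np.asarray(res.pvalues, dtype=float)})


def _compact_letters(labels_desc, sig_pairs) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one set holding every group and splits it for each
    significant pair, so non-significant pairs always share a letter and
    significant pairs never do. ``labels_desc`` fixes letter order
    (descending mean, design order on ties).
    """
    sets: list[set] = [set(labels_desc)]
    for a, b in sig_pairs:
        for s in [s for s in sets if a in s and b in s]:
            sets.remove(s)
            for dropped in (a, b):
                cand = s - {dropped}
                if not any(cand <= other for other in sets):
                    sets.append(cand)
    sets = [s for s in sets if s]
    order = {g: i for i, g in enumerate(labels_desc)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    letters = {g: "" for g in labels_desc}
    for i, s in enumerate(sets):
        ch = chr(ord("a") + i)
        for g in labels_desc:
            if g in s:
                letters[g] += ch
    return letters


def tukey_letters(values, groups, alpha: float = 0.05,
                  group_order=None) -> tuple[pd.DataFrame, float]:
    """One-way ANOVA + Tukey HSD compact letters per treatment.

    Returns (summary frame with treatment/mean/sd/letters, ANOVA p).
    Treatments sharing a letter are not significantly different at ``alpha``.
    Ties in means are broken by ``group_order`` (defaults to first
    appearance).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(group_order) if group_order is not None else list(pd.unique(groups))
    samples = [values[groups == g] for g in labels]
    if np.all(values == values[0]):
        anova_p = 1.0
    else:
        anova_p = float(f_oneway(*samples).pvalue)
    pvals = tukey_pvalues(values, groups, alpha=alpha)
    means = {g: float(v.mean()) for g, v in zip(labels, samples)}
    rank = {g: i for i, g in enumerate(labels)}
    labels_desc = sorted(labels, key=lambda g: (-means[g], rank[g]))
    sig = [(r.group1, r.group2) for r in pvals.itertuples() if r.p < alpha]
    letters = _compact_letters(labels_desc, sig)
    rows = [LetterSummary(g, means[g], float(v.std(ddof=1)), letters[g])
            for g, v in zip(labels, samples)]
    summary = pd.DataFrame([vars(r) for r in rows])
    return summary, anova_p


def correlation_matrix(x: pd.DataFrame, y: pd.DataFrame, adjust: bool = False):
    """Pearson r and two-sided p between rows of ``x`` and rows of ``y``.

    Both frames are variables x samples sharing sample columns. Pairs are
    evaluated pairwise-complete; a zero-variance variable yields NaN (missing),
    never 0. Returns (r, p, n) DataFrames; with ``adjust`` the p layer is
    Benjamini-Hochberg corrected across all finite cells.
    """
    common = [s for s in x.columns if s in set(y.columns)]
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    xv, yv = x[common], y[common]
    r = pd.DataFrame(np.nan, index=x.index, columns=y.index)
    p = pd.DataFrame(np.nan, index=x.index, columns=y.index)
    n = pd.DataFrame(0, index=x.index, columns=y.index)
    for xi in x.index:
        a = xv.loc[xi].to_numpy(dtype=float)
        for yi in y.index:
            b = yv.loc[yi].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            n.loc[xi, yi] = int(ok.sum())
            if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
                continue
            rr, pp = pearsonr(a[ok], b[ok])
            r.loc[xi, yi] = rr
            p.loc[xi, yi] = pp
    if adjust:
        flat = p.to_numpy().ravel()
        mask = np.isfinite(flat)
        if mask.any():
            flat[mask] = multipletests(flat[mask], method="fdr_bh")[1]
            p = pd.DataFrame(flat.reshape(p.shape), index=p.index, columns=p.columns)
    return r, p, n
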