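"""Module eigengenes and the module-trait correlation matrix.

An eigengene summarizes one network module as the first principal component
of its member OTUs' standardized abundance profiles (the WGCNA definition);
its sign is fixed so the mean loading of member OTUs is positive, and the
per-sample scores are standardized to mean 0, unit variance. The
module-trait matrix correlates eigengenes and community summaries
(abundance, diversity, composition PC1) with soil properties, potential
denitrification activity (PDA) and cumulative N2O, with */** marking
p < 0.05 / p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .diversity import chao1, composition_pc1, correlation_matrix
from .io import OtuTable


@dataclass
class ModuleEigengene:
    module_id: str
    scores: pd.Series            # per sample, mean 0 and unit variance
    variance_explained: float    # lambda_1 / sum(lambda)
    loadings: pd.Series          # per member OTU


def module_eigengene(table: OtuTable, members, module_id: str = "I",
                     standardize: bool = True) -> ModuleEigengene:
    """First principal component of the samples x member-OTUs matrix.

    Member OTUs with zero variance across samples carry no signal and are
    dropped with a warning; if none remain the eigengene is undefined.
    """
    members = list(members)
    if len(members) == 0:
        raise ValueError("module has no member OTUs")
    if table.shape[1] < 2:
        raise ValueError("eigengene needs at least 2 samples")
    X = table.relative_abundance().loc[members].to_numpy(dtype=float).T  # samples x otus
    sd = X.std(axis=0)
    if (sd == 0).any():
        dropped = [m for m, s in zip(members, sd) if s == 0]
        warnings.warn(f"dropping zero-variance module members: {dropped}")
        keep = sd > 0
        members = [m for m, k in zip(members, keep) if k]
        X, sd = X[:, keep], sd[keep]
        if X.shape[1] == 0:
            raise ValueError("all module members have zero variance")
    if standardize:
        X = (X - X.mean(axis=0)) / sd
    else:
        X = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = u[:, 0] * s[0]
    loadings = vt[0]
    if loadings.mean() < 0:          # orient: mean member loading positive
        scores, loadings = -scores, -loadings
    scores = (scores - scores.mean()) / scores.std()
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return ModuleEigengene(module_id, pd.Series(scores, index=table.sample_ids),
                           var_explained, pd.Series(loadings, index=members))


class ModuleEigengenes(TransformerMixin, BaseEstimator):
    """Transformer: OTU table + module assignment -> samples x eigengenes.

    Parameters
    ----------
    standardize : z-score member profiles before the PCA (WGCNA convention).
    min_members : modules smaller than this are skipped.
    """

    def __init__(self, standardize: bool = True, min_members: int = 1):
        self.standardize = standardize
        self.min_members = min_members

    def fit(self, table: OtuTable, modules: pd.Series):
        """``modules`` maps OTU id -> module label (I, II, ...)."""
        self.eigengenes_ = {}
        self.variance_explained_ = {}
        for label in sorted(modules.unique()):
            members = [m for m in modules.index[modules == label] if m in table.counts.index]
            if len(members) < self.min_members:
                continue
            eg = module_eigengene(table, members, module_id=str(label),
                                  standardize=self.standardize)
            self.eigengenes_[str(label)] = eg
            self.variance_explained_[str(label)] = eg.variance_explained
        self.sample_ids_ = table.sample_ids
        return self

    def transform(self, table: OtuTable | None = None) -> pd.DataFrame:
        """Samples x modules eigengene score matrix of the fitted table."""
        return pd.DataFrame({k: v.scores for k, v in self.eigengenes_.items()},
                            index=self.sample_ids_)


def community_summaries(table: OtuTable, frame: pd.DataFrame | None = None,
                        copy_number_col: str | None = None) -> pd.DataFrame:
    """Per-sample community summary rows for the trait matrix.

    abundance: qPCR gene copy numbers when a ``copy_number_col`` is present
    in the metadata frame, otherwise summed counts; diversity: Chao1
    richness; composition: first principal coordinate of Bray-Curtis.
    """
    if copy_number_col is not None and frame is not None and copy_number_col in frame.columns:
        abundance = frame.set_index("sample_id")[copy_number_col].loc[table.sample_ids]
    else:
        abundance = table.counts.sum(axis=0)
    out = pd.DataFrame({
        "abundance": abundance.to_numpy(dtype=float),
        "diversity": [chao1(table.counts[s].to_numpy()) for s in table.sample_ids],
        "composition": composition_pc1(table).to_numpy(),
    }, index=table.sample_ids)
    return out


@dataclass
class ModuleTraitMatrix:
    """Correlation layers between module/community rows and trait columns."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame

    def to_csv(self, path) -> None:
        """r and p layers side by side, star-annotated."""
        annotated = self.r.round(3).astype(str) + self.stars
        combined = pd.concat({"r": annotated, "p": self.p.round(4)}, axis=1)
        combined.to_csv(path, encoding="utf-8")


def _stars(p: pd.DataFrame) -> pd.DataFrame:
    return p.map(lambda v: "**" if v < 0.01 else ("*" if v < 0.05 else "")
                 if np.isfinite(v) else "")


def trait_correlations(eigengenes: pd.DataFrame, summaries: pd.DataFrame | None,
                       frame: pd.DataFrame, traits=None,
                       adjust: bool = False) -> ModuleTraitMatrix:
    """Pearson correlations of eigengenes (+ community summaries) with traits.

    ``eigengenes``/``summaries`` are samples x variables; ``frame`` is the
    sample metadata with a ``sample_id`` column. ``traits`` defaults to every
    numeric metadata column (soil properties, PDA, N2O). Cells are
    pairwise-complete with per-cell n reported.
    """
    left = eigengenes if summaries is None else pd.concat([eigengenes, summaries], axis=1)
    meta = frame.set_index("sample_id").loc[left.index]
    if traits is None:
        traits = [c for c in meta.columns
                  if c not in ("treatment", "replicate") and
                  pd.api.types.is_numeric_dtype(meta[c])]
    x = left.T            # variables x samples
    y = meta[list(traits)].T
    r, p, n = correlation_matrix(x, y, adjust=adjust)
    return ModuleTraitMatrix(r, p, n, _stars(p))


def plot_module_trait_heatmap(matrix: ModuleTraitMatrix, path) -> None:
    """Optional heatmap of the r layer with star annotations (blue positive,
    red negative)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = matrix.r
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * r.shape[1], 1.0 + 0.45 * r.shape[0]))
    im = ax.imshow(r.to_numpy(dtype=float), cmap="RdBu", vmin=-1, vmax=1)
    ax.set_xticks(range(r.shape[1]), r.columns, rotation=45, ha="right")
    ax.set_yticks(range(r.shape[0]), r.index)
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            val = r.iloc[i, j]
            if np.isfinite(val):
                ax.text(j, i, f"{val:.2f}{matrix.stars.iloc[i, j]}",
                        ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
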