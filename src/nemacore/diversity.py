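"""Alpha and beta diversity from their definitions.

Alpha: observed ASVs, Shannon entropy (log2), Pielou's evenness and Faith's
phylogenetic diversity (rooted convention: the minimal subtree always includes
the root).  Beta: unweighted and weighted UniFrac, computed from a per-branch
decomposition of the tree; PCoA of the resulting distance matrix and biplot
feature loadings.

The branch decomposition is shared by Faith's PD and both UniFrac modes: each
branch of the tree contributes its length, weighted by which samples have
reads below it (presence for the unweighted metrics, the fraction of the
sample's reads for the weighted one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .data_model import FeatureTable, ValidationError, relative_abundance


# ---------------------------------------------------------------------------
# Branch decomposition
# ---------------------------------------------------------------------------

def _branch_table(tree: TreeNode, feature_ids: list[str]):
    """Lengths and tip-membership of every non-root branch.

    Returns ``(lengths, membership)`` where ``lengths`` has one entry per
    branch and ``membership`` is a (branches x features) boolean matrix:
    ``membership[b, f]`` is True when feature ``f`` is a tip descending
    through branch ``b``.  Features absent from the tree raise
    :class:`ValidationError`.
    """
    col = {f: i for i, f in enumerate(feature_ids)}
    tip_names = {t.name for t in tree.tips()}
    missing = [f for f in feature_ids if f not in tip_names]
    if missing:
        raise ValidationError(f"features missing from tree: {sorted(missing)}")

    lengths: list[float] = []
    members: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(len(feature_ids), dtype=bool)
            if node.name in col:
                vec[col[node.name]] = True
        else:
            vec = np.zeros(len(feature_ids), dtype=bool)
            for child in node.children:
                vec |= below[id(child)]
        below[id(node)] = vec
        if node.parent is not None:  # the root has no branch above it
            lengths.append(float(node.length or 0.0))
            members.append(vec)
    return np.asarray(lengths), np.asarray(members)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def shannon_entropy(counts: np.ndarray) -> float:
    """Shannon index H = -sum p log2 p over features with positive count."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample with zero total count")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def faith_pd(table: FeatureTable, tree: TreeNode) -> pd.Series:
    """Faith's PD per sample: total branch length of the minimal rooted
    subtree spanning the sample's observed features and the root."""
    lengths, members = _branch_table(tree, table.feature_ids)
    presence = table.presence().to_numpy()  # (S, F)
    has_obs = members.astype(float) @ presence.T > 0  # (B, S)
    return pd.Series(lengths @ has_obs, index=table.sample_ids, name="faith_pd")


def alpha_diversity(table: FeatureTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Observed ASVs, Shannon (bits), Pielou's evenness and (with a tree)
    Faith's PD for every sample.

    Pielou's evenness is Shannon divided by log2(observed); it is undefined
    (NaN) for samples with fewer than two observed features.
    """
    counts = table.data.to_numpy(dtype=float)
    observed = (counts > 0).sum(axis=1)
    shannon = np.array([shannon_entropy(row) for row in counts])
    with np.errstate(divide="ignore", invalid="ignore"):
        pielou = np.where(observed >= 2, shannon / np.log2(observed), np.nan)
    out = pd.DataFrame({"observed": observed.astype(int),
                        "shannon": shannon,
                        "pielou": pielou},
                       index=table.sample_ids)
    if tree is not None:
        out["faith_pd"] = faith_pd(table, tree)
    return out


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def unifrac(table: FeatureTable, tree: TreeNode, mode: str = "unweighted",
            normalized: bool = False) -> DistanceMatrix:
    """Pairwise UniFrac distances between all samples.

    ``mode="unweighted"``: fraction of the two communities' combined branch
    length unique to one of them.  ``mode="weighted"``: per-branch
    read-mass difference ``sum_b l_b |p_A(b) - p_B(b)|``, where ``p_X(b)`` is
    the fraction of X's reads descending through branch ``b``; with
    ``normalized`` the sum is divided by ``sum_b l_b (p_A(b) + p_B(b))`` so
    values fall in [0, 1].
    """
    if mode not in ("unweighted", "weighted"):
        raise ValueError(f"unknown UniFrac mode {mode!r}")
    lengths, members = _branch_table(tree, table.feature_ids)
    if mode == "unweighted":
        presence = table.presence().to_numpy().astype(float)
        P = (members.astype(float) @ presence.T) > 0  # (B, S) branch presence
        Pf = P.astype(float)
        shared = (Pf * lengths[:, None]).T @ Pf          # sum l over a&b
        own = lengths @ Pf                               # per-sample branch length
        union = own[:, None] + own[None, :] - shared
        uniq = own[:, None] + own[None, :] - 2.0 * shared
        with np.errstate(divide="ignore", invalid="ignore"):
            dm = np.where(union > 0, uniq / np.where(union > 0, union, 1.0), 0.0)
    else:
        rel = relative_abundance(table).to_numpy()
        M = members.astype(float) @ rel.T               # (B, S) branch mass
        L = lengths[:, None] * M
        S = table.n_samples
        dm = np.zeros((S, S))
        for i in range(S):
            dm[i] = np.abs(L - L[:, [i]]).sum(axis=0)
        if normalized:
            denom = (lengths @ M)[:, None] + (lengths @ M)[None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                dm = np.where(denom > 0, dm / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(dm, 0.0)
    dm = np.maximum((dm + dm.T) / 2.0, 0.0)  # exact symmetry, no -0 noise
    return DistanceMatrix(dm, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Principal-coordinate decomposition of a distance matrix.

    ``coordinates`` holds samples x retained axes (eigenvectors scaled by the
    square root of their eigenvalue); axes are sorted by decreasing
    eigenvalue.  Negative eigenvalues are dropped; their magnitudes are kept
    in ``negative_eigenvalues`` for diagnostics.  ``proportion_explained``
    uses the sum of positive eigenvalues as denominator.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray
    features: pd.DataFrame | None = None

    def write(self, prefix) -> list:
        """Write coordinates (+ loadings) as TSV with an eigenvalue header."""
        from pathlib import Path
        prefix = Path(prefix)
        paths = []
        coord_path = prefix.with_suffix(".coords.tsv")
        with open(coord_path, "w") as fh:
            fh.write("# eigenvalues\t" + "\t".join(f"{e:.10g}" for e in self.eigenvalues) + "\n")
            fh.write("# proportion_explained\t" +
                     "\t".join(f"{p:.10g}" for p in self.proportion_explained) + "\n")
            self.coordinates.to_csv(fh, sep="\t", index_label="sample_id",
                                    float_format="%.10g")
        paths.append(coord_path)
        if self.features is not None:
            fpath = prefix.with_suffix(".loadings.tsv")
            self.features.to_csv(fpath, sep="\t", index_label="feature_id",
                                 float_format="%.10g")
            paths.append(fpath)
        return paths


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric MDS: eigendecomposition of the double-centered
    ``-1/2 D^2`` matrix."""
    D = np.asarray(dm.data, dtype=float)
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("distance matrix is not symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * abs(evals).max()) if evals.size else 0.0
    pos = evals > tol
    neg_mags = np.abs(evals[evals < -tol])
    evals_pos = evals[pos]
    coords = evecs[:, pos] * np.sqrt(evals_pos)
    if n_axes is not None:
        coords = coords[:, :n_axes]
        evals_pos = evals_pos[:n_axes]
    total = evals[pos].sum()
    prop = evals_pos / total if total > 0 else np.zeros_like(evals_pos)
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=evals_pos,
        proportion_explained=prop,
        negative_eigenvalues=neg_mags,
    )


def biplot_loadings(ordination: OrdinationResult, rel_abundance: pd.DataFrame,
                    n_features: int | None = None) -> pd.DataFrame:
    """Feature loadings for a PCoA biplot.

    Each feature is placed at the abundance-weighted average of the sample
    coordinates (weights: the feature's relative abundance across samples,
    normalized to sum to 1).  Features absent everywhere are excluded.
    The result is ranked by loading-vector norm (descending).
    """
    coords = ordination.coordinates
    missing = [s for s in coords.index if s not in rel_abundance.index]
    if missing:
        raise ValidationError(f"samples missing from abundance matrix: {missing}")
    W = rel_abundance.loc[coords.index]
    totals = W.sum(axis=0)
    kept = totals[totals > 0].index
    weights = W[kept] / totals[kept]
    loadings = weights.T @ coords
    norm = np.linalg.norm(loadings.to_numpy(), axis=1)
    loadings = loadings.assign(norm=norm).sort_values(
        "norm", ascending=False, kind="mergesort")
    if n_features is not None:
        loadings = loadings.head(n_features)
    return loadings
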