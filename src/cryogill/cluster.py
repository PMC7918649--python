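"""Expression transforms for heatmaps, hierarchical clustering, and the
gene-family expression-share statistic.

Two published transforms are implemented:

* ``row_zscore_log10`` — genes x tissues heatmap: keep genes reaching a
  minimum TPM in at least one tissue, take log10(TPM+1), Z-score each
  row, cluster genes by average linkage on Pearson distance (1 - r).
* ``sqrt_max_median`` — species expression profiles on a high-consistency
  ortholog subset: square-root TPM, standardize each gene on its maximum
  across species, subtract the per-gene median; cluster species by
  average linkage on Euclidean distance.

The agglomeration is a plain average-linkage (UPGMA-style) loop with a
deterministic tie-break: among equal-distance candidate pairs, the pair
whose sorted member-label tuple is lexicographically smallest merges
first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .ortholog import OrthologExpressionTable
from .tissue import TissuePanel

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Average-linkage dendrogram


@dataclass
class DendrogramTree:
    """Binary merge tree over labels with non-negative merge heights.

    ``merges`` lists (left, right, height, size) in merge order, where
    left/right are either leaf labels or indices of earlier merges
    (as ints offset by the leaf count, scipy linkage convention).
    """

    labels: list[str]
    linkage: np.ndarray  # (n-1) x 4 scipy-style matrix

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Serialize as an ultrametric newick string; branch lengths are
        half the merge-height difference (average-linkage convention)."""
        n = len(self.labels)
        if n == 1:
            return f"{self.labels[0]};"
        node_height = {i: 0.0 for i in range(n)}
        newick = {i: lab for i, lab in enumerate(self.labels)}
        for m, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h / 2.0 - node_height[a] / 2.0
            lb = h / 2.0 - node_height[b] / 2.0
            node_height[n + m] = h
            newick[n + m] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
        return newick[n + len(self.linkage) - 1] + ";"


def average_linkage(dist: pd.DataFrame) -> DendrogramTree:
    """Agglomerative average-linkage clustering of a square symmetric
    distance matrix (labels on both axes).

    Inter-cluster distance is the mean over all cross pairs; ties are
    broken on the lexicographically smallest sorted label tuple of the
    candidate pair, making the tree fully deterministic.
    """
    labels = list(dist.index)
    n = len(labels)
    if n < 1 or list(dist.columns) != labels:
        raise ValidationError("distance matrix must be square with matching labels")
    d = dist.to_numpy().astype(float)
    if d.size and (d < -1e-12).any():
        raise ValidationError("distances must be non-negative")

    # active cluster state: id -> (member leaf indices, sorted label key, height)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    keys: dict[int, tuple[str, ...]] = {i: (labels[i],) for i in range(n)}
    dists: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    Z = np.zeros((n - 1, 4))
    next_id = n
    active = set(range(n))
    for step in range(n - 1):
        best = None
        for (i, j), dij in dists.items():
            cand_key = tuple(sorted((keys[i], keys[j])))
            if best is None or (dij, cand_key) < (best[0], best[1]):
                best = (dij, cand_key, i, j)
        dij, _, i, j = best
        new_members = members.pop(i) + members.pop(j)
        # average-linkage update: d(new, k) = (|i| d(i,k) + |j| d(j,k)) / (|i|+|j|)
        li, lj = len(keys[i]), len(keys[j])
        for k in active - {i, j}:
            dik = dists.pop((min(i, k), max(i, k)))
            djk = dists.pop((min(j, k), max(j, k)))
            dists[(min(next_id, k), max(next_id, k))] = (li * dik + lj * djk) / (
                li + lj
            )
        dists.pop((i, j))
        members[next_id] = new_members
        keys[next_id] = tuple(sorted(keys[i] + keys[j]))
        del keys[i], keys[j]
        active -= {i, j}
        active.add(next_id)
        Z[step] = (min(i, j), max(i, j), dij, len(new_members))
        next_id += 1
    return DendrogramTree(labels=labels, linkage=Z)


# ---------------------------------------------------------------------------
# Transforms


@dataclass
class TransformedMatrix:
    values: pd.DataFrame
    transform: str  # "row_zscore_log10" | "sqrt_max_median"


def pearson_distance(rows: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between rows (anti-correlation is maximal
    distance; |r| is deliberately not used)."""
    d = pdist(rows.to_numpy(), metric="correlation")
    return pd.DataFrame(
        squareform(np.clip(d, 0.0, None)), index=rows.index, columns=rows.index
    )


def gene_heatmap_transform(
    panel: TissuePanel, min_max_tpm: float = 1000.0
) -> tuple[TransformedMatrix, DendrogramTree]:
    """Heatmap-ready gene x tissue matrix and gene dendrogram.

    Keeps genes whose maximum TPM over tissues reaches ``min_max_tpm``
    (inclusive), transforms to log10(TPM+1), Z-scores each row, and
    clusters genes by average linkage on Pearson distances. Rows with
    zero variance (flat profiles) cannot be Z-scored or correlated and
    are dropped with a warning.
    """
    keep = panel.values.max(axis=1) >= min_max_tpm
    if not keep.any():
        raise ValidationError(
            f"no gene reaches the minimum of {min_max_tpm} TPM in any tissue"
        )
    logv = np.log10(panel.values.loc[keep] + 1.0)
    sd = logv.std(axis=1, ddof=0)
    # constant rows can come out as sd ~ 1e-16 in floating point
    flat = sd <= 1e-12 * logv.abs().max(axis=1).clip(lower=1.0)
    if flat.any():
        log.warning("dropping %d zero-variance rows from the heatmap", flat.sum())
        logv = logv.loc[~flat]
        sd = sd.loc[~flat]
    if logv.empty:
        raise ValidationError("all retained genes have flat profiles")
    z = logv.sub(logv.mean(axis=1), axis=0).div(sd, axis=0)
    tree = average_linkage(pearson_distance(z))
    return TransformedMatrix(values=z, transform="row_zscore_log10"), tree


def species_profile_transform(
    table: OrthologExpressionTable,
    cs_records: pd.DataFrame,
    cs_min: int = 42,
) -> tuple[TransformedMatrix, DendrogramTree]:
    """Species-profile matrix and species dendrogram on the
    high-consistency ortholog subset.

    Per gene g and species s: sqrt TPM, standardized on the maximum over
    species, median-subtracted: v_gs = s_gs / max_s s_gs - median_s(...).
    All values lie in [-1, 1]. Species are clustered by average linkage
    on Euclidean distance between their profile columns. Genes that are
    zero in every species have no defined maximum and are excluded.
    """
    high = cs_records.index[cs_records["cs"] >= cs_min]
    if len(high) == 0:
        raise ValidationError(f"no ortholog reaches consistency score {cs_min}")
    sub = table.values.loc[high]
    s = np.sqrt(sub)
    mx = s.max(axis=1)
    allzero = mx == 0
    if allzero.any():
        log.warning("excluding %d all-zero orthologs from the profile", allzero.sum())
        s = s.loc[~allzero]
        mx = mx.loc[~allzero]
    u = s.div(mx, axis=0)
    v = u.sub(u.median(axis=1), axis=0)
    dcols = pdist(v.to_numpy().T, metric="euclidean")
    dist = pd.DataFrame(squareform(dcols), index=v.columns, columns=v.columns)
    tree = average_linkage(dist)
    return TransformedMatrix(values=v, transform="sqrt_max_median"), tree


# ---------------------------------------------------------------------------
# Expression share


def expression_share(
    table: OrthologExpressionTable, gene_set: Sequence[str]
) -> tuple[pd.Series, pd.DataFrame]:
    """Percent of each species' summed ortholog TPM contributed by
    ``gene_set``, plus a per-group mean +/- sample sd summary.

    This is the "relative contribution to the total transcriptional
    effort" statistic for a gene family (e.g. carbonic anhydrases),
    computed on the single-copy ortholog expression table.
    """
    gene_set = list(dict.fromkeys(gene_set))
    missing = set(gene_set) - set(table.values.index)
    if missing:
        raise ValidationError(f"gene_set members not in table: {sorted(missing)[:3]}")
    totals = table.values.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValidationError(f"species {bad!r} has an all-zero column; share undefined")
    subset = table.values.loc[gene_set].sum(axis=0) if gene_set else 0.0
    share = 100.0 * subset / totals
    share.name = "share_pct"
    rows = []
    for grp in ("antarctic", "other"):
        sp = table.species_of(grp)
        vals = share.loc[sp]
        sd = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append((grp, vals.mean(), sd, len(vals)))
    summary = pd.DataFrame(
        rows, columns=["group", "mean_pct", "sd_pct", "n_species"]
    ).set_index("group")
    return share, summary


def plot_heatmap(matrix: TransformedMatrix, path: str, cmap: str = "RdBu_r") -> None:
    """Render a transformed matrix as a simple heatmap image (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * matrix.values.shape[1]), max(3, 0.12 * len(matrix.values)))
    )
    im = ax.imshow(matrix.values.to_numpy(), aspect="auto", cmap=cmap)
    ax.set_xticks(range(matrix.values.shape[1]))
    ax.set_xticklabels(matrix.values.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label=matrix.transform)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
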