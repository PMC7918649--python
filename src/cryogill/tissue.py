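"""Tissue-specific gene selection and term over-representation testing.

A gene is called specific to a target tissue (e.g. gills) when it sits
in the top decile of that tissue's expression ranking and exceeds a
10-fold margin over every other assayed tissue. The selected set is then
screened for over-represented GO terms and Pfam domains with a one-sided
hypergeometric test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import TermAnnotation
from .diffexp import DEFAULT_PSEUDOCOUNT, bh_adjust
from .errors import ValidationError


@dataclass
class TissuePanel:
    """One-species multi-tissue TPM table (genes x tissues, libraries
    pre-averaged)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValidationError("tissue panel labels must be unique")
        arr = self.values.to_numpy()
        if arr.size and (not np.all(np.isfinite(arr)) or arr.min() < 0):
            raise ValidationError("tissue panel values must be finite and >= 0")

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def select_tissue_specific(
    panel: TissuePanel,
    target: str,
    top_fraction: float = 0.10,
    fc_min: float = 10.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[str]:
    """Genes specific to ``target``: top ``top_fraction`` of the target
    column's expression ranking (descending, boundary ties included) AND
    fold change > ``fc_min`` against every other tissue, with a
    pseudocount on both sides of each ratio.

    Returns selected gene IDs in panel order.
    """
    if target not in panel.tissues:
        raise ValidationError(f"target tissue {target!r} not in panel")
    if len(panel.tissues) < 2:
        raise ValidationError("tissue specificity requires >=2 tissues")
    if not (0 < top_fraction <= 1):
        raise ValidationError("top_fraction must be in (0, 1]")
    if fc_min <= 0:
        raise ValidationError("fc_min must be > 0")

    tgt = panel.values[target]
    n = len(tgt)
    cutoff_rank = math.ceil(top_fraction * n)
    # value held by the gene at the cutoff rank; ties at this value stay in
    cutoff_value = tgt.sort_values(ascending=False).iloc[cutoff_rank - 1]
    in_top = tgt >= cutoff_value

    others = panel.values.drop(columns=target)
    # (tgt + d) / (other + d) > fc_min for every other tissue
    lhs = (tgt.to_numpy() + pseudocount)[:, None]
    rhs = fc_min * (others.to_numpy() + pseudocount)
    fold_ok = (lhs > rhs).all(axis=1)

    mask = in_top.to_numpy() & fold_ok
    return [g for g, m in zip(panel.gene_ids, mask) if m]


def _term_family(term: str) -> str:
    return "GO" if term.startswith("GO:") else "Pfam"


def hypergeometric_enrichment(
    selected: Iterable[str],
    universe: Iterable[str],
    annotations: TermAnnotation,
) -> pd.DataFrame:
    """One-sided over-representation test per annotation term.

    For each term carried by >=1 universe gene: with N the universe size,
    K the universe genes carrying the term, n the selected-set size and k
    the selected genes carrying it, p = P(X >= k), X ~ Hypergeom(N, K, n).
    Genes without annotations count in N and n but in no K. q-values are
    BH-adjusted separately within the GO and Pfam term families.

    Returns a DataFrame indexed by term with columns ``family``, ``k``,
    ``K``, ``n``, ``N``, ``p_value``, ``q_value``, sorted by p ascending.
    """
    selected = list(dict.fromkeys(selected))
    universe_set = set(universe)
    if not set(selected) <= universe_set:
        stray = sorted(set(selected) - universe_set)[:3]
        raise ValidationError(f"selected genes not in universe: {stray}")
    unknown = set(annotations.terms) - universe_set
    if unknown:
        warnings.warn(
            f"{len(unknown)} annotated genes are outside the universe and "
            "are ignored",
            stacklevel=2,
        )

    N = len(universe_set)
    n = len(selected)
    term_to_universe: dict[str, int] = {}
    term_to_selected: dict[str, int] = {}
    selected_set = set(selected)
    for gene in universe_set:
        for term in annotations.terms.get(gene, ()):
            term_to_universe[term] = term_to_universe.get(term, 0) + 1
            if gene in selected_set:
                term_to_selected[term] = term_to_selected.get(term, 0) + 1

    rows = []
    for term in sorted(term_to_universe):
        K = term_to_universe[term]
        k = term_to_selected.get(term, 0)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, _term_family(term), k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["term", "family", "k", "K", "n", "N", "p_value"]
    ).set_index("term")
    df["q_value"] = np.nan
    for fam, sub in df.groupby("family"):
        df.loc[sub.index, "q_value"] = bh_adjust(sub["p_value"].to_numpy())
    return df.sort_values("p_value")
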