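"""Consistency-score statistic and two-group differential expression.

The consistency score (CS) of an ortholog counts the (Antarctic species,
non-Antarctic species) pairs whose expression ratio exceeds a fold-change
threshold; with 6 Antarctic and 8 other species it ranges 0..48, and the
candidate threshold CS >= 36 demands a higher Antarctic value in at least
75% of all cross-group comparisons. The CS is a robustness filter against
outlier species and mis-assembled contigs; statistical significance comes
from a Welch two-sample t-test on log2(TPM+1) with species as the
biological replicates, Benjamini-Hochberg adjusted across orthologs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .ortholog import OrthologExpressionTable

#: Default pseudocount (TPM) added to both sides of every expression
#: ratio. Missing orthologs are imputed as TPM 0, which would make bare
#: ratios undefined; a small delta keeps "0 vs expressed" attained while
#: damping trace-level noise.
DEFAULT_PSEUDOCOUNT = 0.1


def consistency_score(
    table: OrthologExpressionTable,
    fc_threshold: float = 1.5,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-ortholog consistency score and group-mean fold change.

    CS_g = |{(a, b) : a antarctic, b other,
             (TPM_ga + d) / (TPM_gb + d) > fc_threshold}|, d = pseudocount.

    With ``pseudocount=0`` the comparison is evaluated multiplicatively
    (TPM_a > fc_threshold * TPM_b), so 0/0 counts as not attained and
    x/0 (x > 0) as attained.

    Returns a DataFrame indexed by ortholog with columns ``cs``,
    ``n_comparisons``, ``antarctic_mean``, ``other_mean``, ``fold_change``.
    """
    if fc_threshold <= 0:
        raise ValidationError("fc_threshold must be > 0")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    ant = table.species_of("antarctic")
    oth = table.species_of("other")
    if not ant or not oth:
        raise ValidationError("consistency score requires >=1 species per group")

    a = table.values[ant].to_numpy() + pseudocount  # G x n_ant
    b = table.values[oth].to_numpy() + pseudocount  # G x n_oth
    # (a + d) / (b + d) > thr, evaluated without division so d = 0 is safe
    attained = a[:, :, None] > fc_threshold * b[:, None, :]
    cs = attained.sum(axis=(1, 2))

    ant_mean = table.values[ant].mean(axis=1)
    oth_mean = table.values[oth].mean(axis=1)
    if pseudocount == 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(oth_mean > 0, ant_mean / oth_mean, np.inf)
            fc = np.where((ant_mean == 0) & (oth_mean == 0), 1.0, fc)
    else:
        fc = (ant_mean + pseudocount) / (oth_mean + pseudocount)
    return pd.DataFrame(
        {
            "cs": cs.astype(int),
            "n_comparisons": len(ant) * len(oth),
            "antarctic_mean": ant_mean,
            "other_mean": oth_mean,
            "fold_change": fc,
        },
        index=table.values.index,
    )


def two_group_test(table: OrthologExpressionTable) -> pd.Series:
    """One-sided Welch t-test per ortholog: antarctic > other on
    log2(TPM + 1), species as replicates.

    Degenerate orthologs (zero variance in both groups) get p = 1 when
    the Antarctic mean does not exceed the other mean, and the smallest
    positive float under perfect separation (p must stay in (0, 1]).
    """
    ant = table.species_of("antarctic")
    oth = table.species_of("other")
    if len(ant) < 2 or len(oth) < 2:
        raise ValidationError(
            "two_group_test requires >=2 species per group (variance "
            "undefined otherwise); use the consistency score alone for "
            "smaller designs"
        )
    a = np.log2(table.values[ant].to_numpy() + 1.0)
    b = np.log2(table.values[oth].to_numpy() + 1.0)
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance rows trip scipy's precision-loss warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False, alternative="greater")
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        up = a.mean(axis=1) > b.mean(axis=1)
        p[bad & up] = np.finfo(float).tiny
        p[bad & ~up] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.Series(p, index=table.values.index, name="p_value")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_candidates(
    records: pd.DataFrame, cs_min: int = 36, q_max: float = 0.05
) -> pd.DataFrame:
    """Flag candidate up-regulated orthologs.

    ``records`` must carry ``cs``, ``n_comparisons``, ``fold_change`` and
    ``q_value``. Selection: CS >= cs_min AND q < q_max (strict) AND
    Antarctic-up fold change (> 1). Returns a copy with a boolean
    ``selected`` column.
    """
    n_comp = int(records["n_comparisons"].max())
    if cs_min > n_comp:
        raise ValidationError(
            f"unsatisfiable threshold: cs_min={cs_min} exceeds the "
            f"{n_comp} cross-group comparisons of this design"
        )
    out = records.copy()
    out["selected"] = (
        (out["cs"] >= cs_min)
        & (out["q_value"] < q_max)
        & (out["fold_change"] > 1.0)
    )
    return out


def shortlist(records: pd.DataFrame) -> pd.DataFrame:
    """Selected orthologs ordered by q ascending then CS descending,
    with the headline columns (CS, q-value, fold change)."""
    sel = records[records["selected"]]
    sel = sel.sort_values(["q_value", "cs"], ascending=[True, False])
    return sel[["cs", "q_value", "fold_change"]]


def differential_expression(
    table: OrthologExpressionTable,
    fc_threshold: float = 1.5,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    cs_min: int = 36,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Full comparative pipeline on one ortholog table: consistency
    scores, Welch test, BH adjustment, candidate selection."""
    rec = consistency_score(table, fc_threshold=fc_threshold, pseudocount=pseudocount)
    rec["p_value"] = two_group_test(table)
    rec["q_value"] = bh_adjust(rec["p_value"].to_numpy())
    return select_candidates(rec, cs_min=cs_min, q_max=q_max)
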