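"""Synthetic cross-species and multi-tissue expression datasets with
known planted structure.

The cross-species generator emulates the comparative study design: two
species groups (6 Antarctic, 8 temperate by default), a few thousand
single-copy orthologs with lognormal baseline expression shared across
species, a planted fraction of orthologs consistently up-regulated in
the Antarctic group, independent per-(gene, species) multiplicative
noise, occasional missing orthologs (absent rows, exercising the
downstream TPM=0 imputation), and one or more libraries per species.

Generative model on the log10-TPM scale::

    log10 TPM_gsl = baseline_g + effect_g * 1[antarctic & planted]
                    + eps_gs + eps_gsl

with ``eps_gs ~ N(0, noise_sd)`` per (gene, species) and the
between-replicate term ``eps_gsl ~ N(0, noise_sd / 2)`` drawn per
library when a species has two or more libraries (a lone library
observes the species-level value directly). TPM columns are deliberately not
renormalized to sum to 1e6 after planting: the analysis operates on
ortholog subsets where the TPM-sum identity cannot hold anyway.

All randomness flows from one master seed through named substreams, so
adding a component never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, SpeciesConfig, TermAnnotation
from .errors import ValidationError
from .tissue import TissuePanel

_TISSUE_NAMES = ("gills", "heart", "skeletal_muscle", "liver", "head_kidney")


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream of the master seed."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode()) & 0x7FFFFFFF])


@dataclass(frozen=True)
class SimulationParams:
    """Cross-species generator parameters (defaults are the study-like
    conditions the property tests run under)."""

    seed: int
    n_antarctic: int = 6
    n_other: int = 8
    n_orthologs: int = 2000
    baseline_log10_mean: float = 1.0
    baseline_log10_sd: float = 0.8
    planted_deg_fraction: float = 0.05
    effect_fold_change: float = 10.0
    noise_sd: float = 0.3
    missing_prob: float = 0.01
    libraries_per_species: int = 1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is required (no implicit entropy)")
        if self.n_antarctic < 1 or self.n_other < 1:
            raise ValidationError("need >=1 species per group")
        if not (0 <= self.planted_deg_fraction <= 1):
            raise ValidationError("planted_deg_fraction must be in [0, 1]")
        if self.effect_fold_change <= 1:
            raise ValidationError("effect_fold_change must be > 1")
        if not (0 <= self.missing_prob < 1):
            raise ValidationError("missing_prob must be in [0, 1)")
        if self.noise_sd < 0 or self.libraries_per_species < 1:
            raise ValidationError("invalid noise_sd or libraries_per_species")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure of a synthetic dataset (immutable)."""

    seed: int
    params: dict = field(default_factory=dict)
    planted_deg: dict[str, float] = field(default_factory=dict)  # gene -> true fold
    tissue_specific: dict[str, str] = field(default_factory=dict)  # gene -> tissue
    enriched_terms: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = [("deg", g, str(f)) for g, f in self.planted_deg.items()]
        rows += [("tissue_specific", g, t) for g, t in self.tissue_specific.items()]
        rows += [("enriched_term", t, "") for t in self.enriched_terms]
        return pd.DataFrame(rows, columns=["kind", "id", "value"])


def simulate_cross_species(
    params: SimulationParams,
) -> tuple[dict[str, ExpressionMatrix], SpeciesConfig, SyntheticTruth]:
    """Generate per-species TPM matrices, a species config and the truth.

    Planted orthologs carry an Antarctic expectation of
    ``effect_fold_change x`` the baseline on the TPM scale and are never
    missing in Antarctic species (planting overrides missingness); any
    other (species, ortholog) cell may be missing, realized as an absent
    row in that species' matrix.
    """
    p = params
    genes = [f"og{i:05d}" for i in range(p.n_orthologs)]
    species = [f"ant_{i+1:02d}" for i in range(p.n_antarctic)] + [
        f"oth_{i+1:02d}" for i in range(p.n_other)
    ]
    groups = {sp: ("antarctic" if sp.startswith("ant_") else "other") for sp in species}

    baseline = _rng(p.seed, "baseline").normal(
        p.baseline_log10_mean, p.baseline_log10_sd, p.n_orthologs
    )
    n_planted = round(p.planted_deg_fraction * p.n_orthologs)
    order = _rng(p.seed, "planted").permutation(p.n_orthologs)
    planted_idx = np.sort(order[:n_planted])
    planted_mask = np.zeros(p.n_orthologs, dtype=bool)
    planted_mask[planted_idx] = True
    effect = np.log10(p.effect_fold_change)

    matrices: dict[str, ExpressionMatrix] = {}
    samples: dict[str, list[str]] = {}
    for sp in species:
        is_ant = groups[sp] == "antarctic"
        mu = baseline + (effect * planted_mask if is_ant else 0.0)
        eps_sp = _rng(p.seed, f"species:{sp}").normal(0.0, p.noise_sd, p.n_orthologs)
        lib_rng = _rng(p.seed, f"library:{sp}")
        cols = {}
        for lib in range(p.libraries_per_species):
            if p.libraries_per_species > 1:
                eps_lib = lib_rng.normal(0.0, p.noise_sd / 2.0, p.n_orthologs)
            else:
                eps_lib = 0.0
            cols[f"{sp}_lib{lib+1}"] = 10.0 ** (mu + eps_sp + eps_lib)
        df = pd.DataFrame(cols, index=genes)
        if p.missing_prob > 0:
            miss = (
                _rng(p.seed, f"missing:{sp}").random(p.n_orthologs) < p.missing_prob
            )
            if is_ant:
                miss &= ~planted_mask  # planting overrides missingness
            df = df.loc[~miss]
        meta = pd.DataFrame(
            {
                "species": sp,
                "tissue": "gills",
                "library": [c.rsplit("_", 1)[1] for c in df.columns],
            },
            index=df.columns,
        )
        matrices[sp] = ExpressionMatrix(values=df, mode="tpm", sample_meta=meta)
        samples[sp] = list(df.columns)

    config = SpeciesConfig(groups=groups, samples=samples)
    truth = SyntheticTruth(
        seed=p.seed,
        params=asdict(p),
        planted_deg={genes[i]: p.effect_fold_change for i in planted_idx},
    )
    return matrices, config, truth


def identity_membership(
    matrices: dict[str, ExpressionMatrix]
) -> dict[str, dict[str, str]]:
    """Membership map for simulated data, where gene IDs are ortholog IDs:
    each species maps every gene present in its matrix to itself."""
    return {sp: {g: g for g in m.gene_ids} for sp, m in matrices.items()}


def simulate_tissue_panel(
    n_genes: int = 500,
    n_tissues: int = 5,
    n_specific: int = 25,
    specific_fold: float = 50.0,
    baseline_log10_mean: float = 1.0,
    baseline_log10_sd: float = 0.3,
    noise_sd: float = 0.1,
    *,
    seed: int,
) -> tuple[TissuePanel, SyntheticTruth]:
    """Generate a one-species multi-tissue panel with planted
    tissue-specific genes.

    The first tissue (gills) is the target. Every tissue shares a gene's
    baseline expectation; planted genes get ``specific_fold x`` that
    expectation in the target tissue, so their target expectation is
    ``specific_fold x`` the maximum other-tissue expectation.
    """
    if n_tissues < 2:
        raise ValidationError("a tissue panel needs >=2 tissues")
    if n_specific > n_genes:
        raise ValidationError("n_specific cannot exceed n_genes")
    if specific_fold <= 1:
        raise ValidationError("specific_fold must be > 1")
    tissues = list(_TISSUE_NAMES[:n_tissues]) + [
        f"tissue_{i+1}" for i in range(len(_TISSUE_NAMES), n_tissues)
    ]
    genes = [f"g{i:05d}" for i in range(n_genes)]
    baseline = _rng(seed, "panel-baseline").normal(
        baseline_log10_mean, baseline_log10_sd, n_genes
    )
    order = _rng(seed, "panel-specific").permutation(n_genes)
    spec_idx = np.sort(order[:n_specific])
    spec_mask = np.zeros(n_genes, dtype=bool)
    spec_mask[spec_idx] = True

    noise_rng = _rng(seed, "panel-noise")
    cols = {}
    for t_i, t in enumerate(tissues):
        mu = baseline + (np.log10(specific_fold) * spec_mask if t_i == 0 else 0.0)
        cols[t] = 10.0 ** (mu + noise_rng.normal(0.0, noise_sd, n_genes))
    panel = TissuePanel(values=pd.DataFrame(cols, index=genes))
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_tissues": n_tissues,
            "n_specific": n_specific,
            "specific_fold": specific_fold,
            "baseline_log10_mean": baseline_log10_mean,
            "baseline_log10_sd": baseline_log10_sd,
            "noise_sd": noise_sd,
        },
        tissue_specific={genes[i]: tissues[0] for i in spec_idx},
    )
    return panel, truth


def simulate_annotations(
    gene_ids: Sequence[str],
    n_terms: int = 50,
    terms_per_gene: float = 3.0,
    n_enriched_terms: int = 2,
    target_set: Sequence[str] = (),
    enrichment_odds: float = 20.0,
    *,
    seed: int,
) -> tuple[TermAnnotation, SyntheticTruth]:
    """Generate a gene -> GO-style term map with terms enriched in a
    target gene set.

    Background: each gene carries each term independently with
    probability ``terms_per_gene / n_terms``. For the first
    ``n_enriched_terms`` terms, members of ``target_set`` carry the term
    with probability ``min(1, odds x background)``; with odds 1 the
    assignment is exchangeable.
    """
    gene_ids = list(gene_ids)
    unknown = set(target_set) - set(gene_ids)
    if unknown:
        raise ValidationError(f"target_set genes not in gene_ids: {sorted(unknown)[:3]}")
    if enrichment_odds < 1:
        raise ValidationError("enrichment_odds must be >= 1")
    if not (0 < n_terms and 0 <= n_enriched_terms <= n_terms):
        raise ValidationError("invalid term counts")
    terms = [f"GO:{i+1:07d}" for i in range(n_terms)]
    p0 = terms_per_gene / n_terms
    rng = _rng(seed, "annotations")
    target = set(target_set)
    p1 = min(1.0, p0 * enrichment_odds)
    tmap: dict[str, frozenset[str]] = {}
    draws = rng.random((len(gene_ids), n_terms))
    for gi, gene in enumerate(gene_ids):
        probs = np.full(n_terms, p0)
        if gene in target:
            probs[:n_enriched_terms] = p1
        tmap[gene] = frozenset(t for t, u, pr in zip(terms, draws[gi], probs) if u < pr)
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_terms": n_terms,
            "terms_per_gene": terms_per_gene,
            "n_enriched_terms": n_enriched_terms,
            "enrichment_odds": enrichment_odds,
        },
        enriched_terms=tuple(terms[:n_enriched_terms]),
    )
    return TermAnnotation(terms=tmap), truth
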