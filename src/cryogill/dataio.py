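"""Readers, writers and validated in-memory containers for the pipeline's
external file formats.

All tables are tab-separated, UTF-8, ``.`` decimal separator, no quoting.
Lines starting with ``#`` are comments (used for one-line provenance
headers on outputs). Gene, sample and species labels are matched exactly
and case-sensitively throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

GROUPS = ("antarctic", "other")
BUSCO_STATUSES = ("Complete", "Duplicated", "Fragmented", "Missing")


# ---------------------------------------------------------------------------
# Expression matrices


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table for one species.

    ``values`` holds TPM (``mode="tpm"``) or raw read counts
    (``mode="counts"``); in counts mode ``lengths`` carries the per-gene
    effective length in nucleotides, needed for TPM conversion downstream.
    ``sample_meta`` optionally maps each sample to (species, tissue,
    library) labels.
    """

    values: pd.DataFrame
    mode: str = "tpm"
    lengths: pd.Series | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("tpm", "counts"):
            raise ValidationError(f"unknown expression mode {self.mode!r}")
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene ID {dup!r}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample ID {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {idx[g]!r}, sample {cols[s]!r}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("non-finite expression value")
        if self.mode == "counts":
            if self.lengths is None:
                raise ValidationError("counts mode requires per-gene lengths")
            missing = idx.difference(self.lengths.index)
            if len(missing):
                raise ValidationError(f"missing length for gene {missing[0]!r}")
            self.lengths = self.lengths.loc[idx].astype(float)
            if (self.lengths <= 0).any():
                bad = self.lengths.index[self.lengths <= 0][0]
                raise ValidationError(f"non-positive length for gene {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def read_expression_tsv(path: str | Path, mode: str = "tpm") -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    First column: gene IDs; header row: sample IDs. In counts mode a
    column named ``length`` carries effective lengths and is not treated
    as a sample.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        comment="#",
        dtype={0: str},
        float_precision="round_trip",
    )
    df.index = df.index.astype(str)
    lengths = None
    if mode == "counts":
        if "length" not in df.columns:
            raise ValidationError(f"{path}: counts mode requires a 'length' column")
        lengths = df["length"].astype(float)
        df = df.drop(columns="length")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric expression value ({exc})") from exc
    try:
        return ExpressionMatrix(values=df, mode=mode, lengths=lengths)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_expression_tsv(
    path: str | Path,
    matrix: ExpressionMatrix,
    provenance: str | None = None,
) -> None:
    """Write an expression matrix as TSV (full float precision round trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df = matrix.values
        if matrix.mode == "counts":
            df = df.copy()
            df.insert(0, "length", matrix.lengths)
        df.to_csv(fh, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Species configuration


@dataclass
class SpeciesConfig:
    """Species -> group membership (antarctic vs other Eupercaria), with
    optional per-species sample ID lists."""

    groups: dict[str, str]
    samples: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, grp in self.groups.items():
            if grp not in GROUPS:
                raise ValidationError(
                    f"species {sp!r}: group {grp!r} not in {GROUPS}"
                )
        unknown = set(self.samples) - set(self.groups)
        if unknown:
            raise ValidationError(f"samples listed for unknown species {sorted(unknown)}")

    @property
    def species(self) -> list[str]:
        return list(self.groups)

    def group_members(self, group: str) -> list[str]:
        return [sp for sp, g in self.groups.items() if g == group]

    def require_comparative(self) -> None:
        """Both groups must be populated before any cross-group statistic."""
        for grp in GROUPS:
            if not self.group_members(grp):
                raise ValidationError(f"comparative run requires >=1 {grp!r} species")


def read_species_config(path: str | Path) -> SpeciesConfig:
    """Read a YAML species config: ``species: {group: ..., samples: [...]}``
    or the shorthand ``species: group``."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValidationError(f"{path}: expected a mapping of species")
    groups: dict[str, str] = {}
    samples: dict[str, list[str]] = {}
    for sp, entry in raw.items():
        if isinstance(entry, str):
            groups[str(sp)] = entry
        elif isinstance(entry, Mapping):
            if "group" not in entry:
                raise ValidationError(f"{path}: species {sp!r} has no 'group'")
            groups[str(sp)] = entry["group"]
            if "samples" in entry:
                samples[str(sp)] = [str(s) for s in entry["samples"]]
        else:
            raise ValidationError(f"{path}: malformed entry for species {sp!r}")
    try:
        return SpeciesConfig(groups=groups, samples=samples)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_species_config(path: str | Path, config: SpeciesConfig) -> None:
    doc: dict[str, object] = {}
    for sp, grp in config.groups.items():
        if sp in config.samples:
            doc[sp] = {"group": grp, "samples": list(config.samples[sp])}
        else:
            doc[sp] = grp
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# BUSCO full tables


@dataclass
class BuscoTable:
    """Parsed BUSCO full_table records (odb9-era 5-column layout)."""

    records: pd.DataFrame  # ortholog_id, status, contig_id, score, length

    def complete_map(self) -> dict[str, str]:
        """ortholog -> contig for single-copy Complete records only.

        Duplicated BUSCOs are excluded: the comparative procedure is
        defined on single-copy orthologs.
        """
        sub = self.records[self.records["status"] == "Complete"]
        return dict(zip(sub["ortholog_id"], sub["contig_id"]))


def read_busco_table(path: str | Path) -> BuscoTable:
    """Parse a BUSCO full_table TSV; ``#`` comment lines are skipped."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: expected >=2 columns")
            oid, status = parts[0], parts[1]
            if status not in BUSCO_STATUSES:
                raise ValidationError(
                    f"{path}:{lineno}: unknown BUSCO status {status!r}"
                )
            if status == "Missing":
                contig, score, length = "", np.nan, np.nan
            else:
                if len(parts) < 3 or not parts[2]:
                    raise ValidationError(
                        f"{path}:{lineno}: status {status} requires a contig"
                    )
                contig = parts[2]
                score = float(parts[3]) if len(parts) > 3 and parts[3] else np.nan
                length = float(parts[4]) if len(parts) > 4 and parts[4] else np.nan
            rows.append((oid, status, contig, score, length))
    df = pd.DataFrame(
        rows, columns=["ortholog_id", "status", "contig_id", "score", "length"]
    )
    return BuscoTable(records=df)


# ---------------------------------------------------------------------------
# Term annotations (GO / Pfam)


@dataclass
class TermAnnotation:
    """gene -> set of term IDs. Term strings are treated opaquely; the
    ``GO:`` prefix is only used downstream to split correction families."""

    terms: dict[str, frozenset[str]]

    def genes_with_term(self, term: str) -> set[str]:
        return {g for g, ts in self.terms.items() if term in ts}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.terms.values():
            out |= ts
        return out


def read_annotation_tsv(path: str | Path) -> TermAnnotation:
    """Read a two-column TSV: gene ID, ``;``-separated term list (may be
    empty). Term sets are de-duplicated."""
    terms: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            gene, blob = parts
            tset = frozenset(t for t in blob.split(";") if t)
            terms[gene] = tset
    return TermAnnotation(terms=terms)


def write_annotation_tsv(
    path: str | Path, annotation: TermAnnotation, provenance: str | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        for gene, ts in annotation.terms.items():
            fh.write(f"{gene}\t{';'.join(sorted(ts))}\n")


def read_manual_additions(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a manual ortholog-additions TSV (ortholog_id, species, gene_id)
    into species -> {ortholog -> gene}."""
    out: dict[str, dict[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            oid, species, gene = parts
            out.setdefault(species, {})[oid] = gene
    return out
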