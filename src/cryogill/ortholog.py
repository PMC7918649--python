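"""Build the orthologs x species TPM table that the comparative
statistics operate on.

The comparative design: each species contributes one averaged TPM value
per single-copy ortholog. Multiple sequencing libraries for a species
are averaged arithmetically; an ortholog with no assembled contig in a
species is treated as evidence of lack of expression and assigned TPM 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, SpeciesConfig, GROUPS
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class OrthologExpressionTable:
    """orthologs x species averaged-TPM matrix with a group label per
    species; the substrate of the consistency-score statistic."""

    values: pd.DataFrame  # rows: ortholog IDs, columns: species
    groups: pd.Series  # species -> {"antarctic", "other"}

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups, dtype=object)
        if set(self.values.columns) - set(self.groups.index):
            raise ValidationError("group label missing for some species")
        self.groups = self.groups.loc[self.values.columns]
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels {sorted(bad)}")
        arr = self.values.to_numpy()
        if arr.size and (not np.all(np.isfinite(arr)) or arr.min() < 0):
            raise ValidationError("ortholog table values must be finite and >= 0")

    @property
    def ortholog_ids(self) -> list[str]:
        return list(self.values.index)

    def species_of(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def compute_tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million from raw counts and effective lengths (nt).

    TPM_g = 1e6 * (count_g / length_g) / sum_j (count_j / length_j);
    the result sums to 1e6.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValidationError("counts and lengths must have equal length")
    if np.any(counts < 0):
        raise ValidationError("negative count")
    if np.any(lengths <= 0):
        raise ValidationError("lengths must be positive")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        raise ValidationError("all-zero counts: TPM normalization undefined")
    return 1e6 * rates / total


def to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a counts-mode matrix to TPM column by column."""
    if matrix.mode == "tpm":
        return matrix
    cols = {
        s: compute_tpm(matrix.values[s].to_numpy(), matrix.lengths.to_numpy())
        for s in matrix.values.columns
    }
    df = pd.DataFrame(cols, index=matrix.values.index)
    return ExpressionMatrix(values=df, mode="tpm", sample_meta=matrix.sample_meta)


def filter_low_expression(
    matrix: ExpressionMatrix, min_tpm: float = 1.0
) -> ExpressionMatrix:
    """Discard genes whose maximum TPM across samples is below ``min_tpm``.

    Strictly-below genes are removed (a gene at exactly ``min_tpm`` is
    kept); gene order is preserved. Intended for removing contaminants
    and poorly assembled contigs from a reference transcriptome.
    """
    if matrix.mode != "tpm":
        raise ValidationError("filter_low_expression requires a TPM matrix")
    keep = matrix.values.max(axis=1) >= min_tpm
    return ExpressionMatrix(
        values=matrix.values.loc[keep],
        mode="tpm",
        sample_meta=matrix.sample_meta,
    )


def build_ortholog_table(
    matrices: Mapping[str, ExpressionMatrix],
    membership: Mapping[str, Mapping[str, str]],
    config: SpeciesConfig,
) -> OrthologExpressionTable:
    """Assemble the orthologs x species table.

    ``membership`` maps species -> {ortholog -> gene/contig ID in that
    species' matrix} (typically from single-copy Complete BUSCO records,
    optionally merged with manual additions). Rows are the union of
    ortholog IDs over species; each cell is the arithmetic mean of the
    mapped gene's TPM across that species' libraries, or 0 when the
    ortholog is unmapped or the mapped gene is absent from the matrix.
    """
    config.require_comparative()
    missing_species = [sp for sp in config.species if sp not in matrices]
    if missing_species:
        raise ValidationError(f"no expression matrix for species {missing_species}")

    all_orthologs: list[str] = []
    seen: set[str] = set()
    for sp in config.species:
        for oid in membership.get(sp, {}):
            if oid not in seen:
                seen.add(oid)
                all_orthologs.append(oid)

    data = np.zeros((len(all_orthologs), len(config.species)))
    n_unmapped = 0
    for j, sp in enumerate(config.species):
        mat = to_tpm(matrices[sp])
        means = mat.values.mean(axis=1)
        mapping = membership.get(sp, {})
        for i, oid in enumerate(all_orthologs):
            gene = mapping.get(oid)
            if gene is None:
                continue  # missing ortholog: lack of expression, TPM 0
            if gene not in means.index:
                n_unmapped += 1
                continue
            data[i, j] = means.loc[gene]
    if n_unmapped:
        log.warning(
            "%d ortholog->gene mappings referenced genes absent from their "
            "species matrix; treated as missing (TPM 0)",
            n_unmapped,
        )
    df = pd.DataFrame(data, index=all_orthologs, columns=config.species)
    groups = pd.Series(config.groups)
    return OrthologExpressionTable(values=df, groups=groups)


def write_ortholog_table(
    path: str | Path,
    table: OrthologExpressionTable,
    provenance: str | None = None,
) -> None:
    """Write the table as TSV with a ``#group:`` header line."""
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        pairs = ",".join(f"{sp}={g}" for sp, g in table.groups.items())
        fh.write(f"#group: {pairs}\n")
        table.values.to_csv(fh, sep="\t", index_label="ortholog_id")


def read_ortholog_table(path: str | Path) -> OrthologExpressionTable:
    groups: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body: list[str] = []
    for line in lines:
        if line.startswith("#group:"):
            blob = line[len("#group:"):].strip()
            for pair in blob.split(","):
                sp, grp = pair.split("=")
                groups[sp.strip()] = grp.strip()
        elif not line.startswith("#"):
            body.append(line)
    if not groups:
        raise ValidationError(f"{path}: no '#group:' header line")
    from io import StringIO

    df = pd.read_csv(
        StringIO("".join(body)), sep="\t", index_col=0, float_precision="round_trip"
    )
    df.index = df.index.astype(str)
    return OrthologExpressionTable(values=df.astype(float), groups=pd.Series(groups))
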