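"""Readers and writers for expression matrices, GMT gene-set collections, phenotypes.

On disk the expression matrix follows the community convention of genes as
rows and samples as columns; internally everything is a subjects x genes
:class:`pandas.DataFrame`.  Gene sets use the tab-separated GMT format
(name, description, then gene identifiers).  Phenotype tables are TSV/CSV
with the subject identifier in the first column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .endpoints import Endpoint
from .exceptions import InputError

__all__ = [
    "GeneSet",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_phenotype",
    "align_subjects",
]

logger = logging.getLogger("gsda")


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered list of gene identifiers."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if not self.genes:
            raise InputError(f"gene set {self.name!r} is empty")
        seen, unique = set(), []
        for g in self.genes:
            if g in seen:
                continue
            seen.add(g)
            unique.append(g)
        if len(unique) != len(self.genes):
            logger.warning(
                "gene set %s: %d duplicate gene id(s) removed",
                self.name, len(self.genes) - len(unique),
            )
            object.__setattr__(self, "genes", tuple(unique))

    def __len__(self) -> int:
        return len(self.genes)


def _read_table(path, sep=None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_expression(path, orientation: str = "genes_by_samples") -> pd.DataFrame:
    """Load and validate an expression matrix.

    Parameters
    ----------
    path : str or Path
        TSV (default) or CSV file; first row and column are identifiers.
    orientation : {'genes_by_samples', 'samples_by_genes'}
        Layout of the file.  The returned frame is always subjects x genes.

    Raises
    ------
    InputError
        On duplicate identifiers, missing cells, or non-numeric cells —
        with the offending coordinates named.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise InputError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate row identifiers in {path}: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise InputError(f"duplicate column identifiers in {path}: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.nonzero(bad.to_numpy())
        cells = [f"(row {df.index[i]!r}, column {df.columns[j]!r})" for i, j in zip(r[:5], c[:5])]
        raise InputError(f"missing or non-numeric cell(s) in {path}: {', '.join(cells)}")
    numeric = numeric.astype(float)
    if orientation == "genes_by_samples":
        numeric = numeric.T
    numeric.index.name = "subject"
    numeric.columns.name = "gene"
    return numeric


def write_expression(X: pd.DataFrame, path, orientation: str = "genes_by_samples") -> None:
    """Write a subjects x genes frame to TSV/CSV in the requested layout."""
    path = Path(path)
    out = X.T if orientation == "genes_by_samples" else X
    out.to_csv(path, sep="," if path.suffix.lower() == ".csv" else "\t")


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT gene-set collection: ``name TAB description TAB gene ...``."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path}:{lineno}: malformed GMT line (need name, description, >=1 gene)"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise InputError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, genes=tuple(genes), description=desc))
    if not sets:
        raise InputError(f"{path}: empty gene-set collection")
    return sets


def write_gmt(collection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_phenotype(
    path,
    column: str | None = None,
    endpoint_type: str | None = None,
    time_col: str | None = None,
    status_col: str | None = None,
) -> Endpoint:
    """Load a typed endpoint from a phenotype table.

    Either ``column`` (with ``endpoint_type`` 'quantitative' or 'categorical')
    or the pair ``time_col``/``status_col`` (survival; status coded 1 = event,
    0 = censored) must be given.
    """
    df = _read_table(path)
    if df.index.duplicated().any():
        raise InputError(f"duplicate subject identifiers in {path}")
    ids = df.index.tolist()
    if time_col is not None or status_col is not None:
        if time_col is None or status_col is None:
            raise InputError("survival endpoints need both time_col and status_col")
        for col in (time_col, status_col):
            if col not in df.columns:
                raise InputError(f"column {col!r} not found in {path}")
        return Endpoint.survival(
            pd.to_numeric(df[time_col], errors="raise"),
            df[status_col].to_numpy(),
            subject_ids=ids,
        )
    if column is None:
        raise InputError("name an endpoint column or a time/status column pair")
    if column not in df.columns:
        raise InputError(f"column {column!r} not found in {path}")
    if endpoint_type == "categorical":
        return Endpoint.categorical(df[column].astype(str).to_numpy(), subject_ids=ids)
    if endpoint_type in (None, "quantitative"):
        return Endpoint.quantitative(
            pd.to_numeric(df[column], errors="raise"), subject_ids=ids
        )
    raise InputError(f"unknown endpoint type {endpoint_type!r}")


def align_subjects(X: pd.DataFrame, endpoint: Endpoint) -> tuple[pd.DataFrame, Endpoint]:
    """Inner-join expression subjects with endpoint subjects, reporting drops.

    Alignment is explicit so the analysis n always equals the logged
    post-join subject count.  Raises if the endpoint carries no ids and the
    lengths disagree.
    """
    if endpoint.subject_ids is None:
        if endpoint.n != X.shape[0]:
            raise InputError(
                f"endpoint has {endpoint.n} subjects but expression has {X.shape[0]} "
                "and no subject ids to join on"
            )
        return X, endpoint
    ep_ids = list(endpoint.subject_ids)
    common = [s for s in X.index if s in set(ep_ids)]
    dropped_x = X.shape[0] - len(common)
    dropped_y = len(ep_ids) - len(common)
    if dropped_x or dropped_y:
        logger.info(
            "subject alignment: %d analysis subjects (%d expression-only, %d endpoint-only dropped)",
            len(common), dropped_x, dropped_y,
        )
    if not common:
        raise InputError("no subjects shared between expression matrix and endpoint")
    pos = {s: k for k, s in enumerate(ep_ids)}
    ep = endpoint.subset([pos[s] for s in common])
    return X.loc[common], ep
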