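"""Tabular input/output and count normalization.

Three tab-separated tables move through the pipeline:

* **count table** — integer OTU reads, taxa as rows, samples as columns;
* **taxonomy table** — one row per taxon with the six ranks
  kingdom..genus (any rank may be blank);
* **sample metadata** — one row per sample with crop, treatment,
  replicate and any number of numeric trait / enzyme columns.

Two normalizations are provided: rarefaction (random subsampling of each
sample without replacement to a common depth) and conversion to relative
abundance (per-sample closure to 1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

TAXON_INDEX = "taxon_id"
SAMPLE_INDEX = "sample_id"
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


class TableFormatError(ValueError):
    """A table violates the format contract (duplicates, negatives, ...)."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate {what} ids: {dupes}")


def validate_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a count table (taxa x samples, nonnegative ints)."""
    _check_unique(counts.index, "taxon")
    _check_unique(counts.columns, "sample")
    for col in counts.columns:
        vals = counts[col]
        if not np.issubdtype(vals.dtype, np.number):
            bad = vals[pd.to_numeric(vals, errors="coerce").isna()]
            raise TableFormatError(
                f"non-numeric count at row {bad.index[0]!r}, column {col!r}"
            )
        arr = vals.to_numpy()
        if np.any(arr < 0):
            row = vals.index[np.argmax(arr < 0)]
            raise TableFormatError(f"negative count at row {row!r}, column {col!r}")
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            row = vals.index[np.argmax(np.mod(arr, 1) != 0)]
            raise TableFormatError(f"non-integer count at row {row!r}, column {col!r}")
    out = counts.astype(np.int64)
    out.index.name = TAXON_INDEX
    out.columns.name = SAMPLE_INDEX
    return out


def read_count_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_count_table(df)


def write_count_table(counts: pd.DataFrame, path) -> None:
    validate_count_table(counts).to_csv(path, sep="\t", index_label=TAXON_INDEX)


def read_taxonomy(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    return validate_taxonomy(tax)


def validate_taxonomy(tax: pd.DataFrame) -> pd.DataFrame:
    _check_unique(tax.index, "taxon")
    missing = [r for r in RANKS if r not in tax.columns]
    if missing:
        raise TableFormatError(f"taxonomy table lacks rank columns: {missing}")
    tax = tax.loc[:, list(RANKS)].fillna("")
    tax.index.name = TAXON_INDEX
    return tax


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    validate_taxonomy(tax).to_csv(path, sep="\t", index_label=TAXON_INDEX)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(meta.index, "sample")
    meta.index.name = SAMPLE_INDEX
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    _check_unique(meta.index, "sample")
    meta.to_csv(path, sep="\t", index_label=SAMPLE_INDEX)


def rarefy(counts: pd.DataFrame, depth: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Subsample every sample to ``depth`` reads without replacement.

    Each column is drawn from a multivariate hypergeometric distribution,
    i.e. ``depth`` reads are drawn from the sample's read pool without
    replacement, so a zero count can never become positive and the
    expected rarefied count of taxon *i* is ``depth * count_i / total``.

    Parameters
    ----------
    depth:
        Target reads per sample. Defaults to the minimum sample total.
    seed:
        Seed for the subsampling random stream.
    """
    counts = validate_count_table(counts)
    totals = counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    shallow = totals.index[totals < depth].tolist()
    if shallow:
        raise ValueError(
            f"rarefaction depth {depth} exceeds the total reads of samples: {shallow}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for col in counts.columns:
        out[col] = rng.multivariate_hypergeometric(
            counts[col].to_numpy(), depth, method="marginals"
        )
    rare = pd.DataFrame(out, index=counts.index, dtype=np.int64)
    rare.index.name = TAXON_INDEX
    rare.columns.name = SAMPLE_INDEX
    return rare


def to_relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Close each sample to 1 (columns sum to unity)."""
    counts = validate_count_table(counts)
    totals = counts.sum(axis=0)
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise ValueError(f"all-zero samples cannot be normalized: {empty}")
    rel = counts / totals
    return rel


def collapse_genus(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, genus: str
) -> tuple[list, pd.Series]:
    """Return the OTUs annotated to ``genus`` and their per-sample summed counts.

    The genus match is case-insensitive exact. An unknown genus yields an
    empty member list with a warning (never a silent zero row).
    """
    taxonomy = validate_taxonomy(taxonomy)
    mask = taxonomy["genus"].str.lower() == str(genus).lower()
    members = taxonomy.index[mask].intersection(counts.index).tolist()
    if not members:
        warnings.warn(f"genus {genus!r} not found in taxonomy", stacklevel=2)
        return [], pd.Series(0, index=counts.columns, dtype=np.int64)
    return members, counts.loc[members].sum(axis=0)


def genus_members(taxonomy: pd.DataFrame, genus: str) -> list:
    """Taxon ids annotated to ``genus`` (case-insensitive exact match)."""
    taxonomy = validate_taxonomy(taxonomy)
    mask = taxonomy["genus"].str.lower() == str(genus).lower()
    return taxonomy.index[mask].tolist()
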