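"""Readers and writers for the pipeline's text formats.

Everything is plain UTF-8 text: TSV feature tables (dense or sparse
triplet), a metadata TSV, Newick trees, and FASTA sequence files. Lines
starting with '#' are treated as comments except for the metadata header
conventions noted in `read_metadata`.
"""

from __future__ import annotations

import logging
import warnings
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
import skbio
from Bio import SeqIO

from .table import FeatureTable, FormatError, SampleMetadata

log = logging.getLogger(__name__)

_IUPAC = set("ACGTURYSWKMBDHVN")


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def _noncomment_lines(path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def read_feature_table(
    path,
    dialect: str = "dense-tsv",
    samples_as_rows: bool = False,
    taxonomy_column: str | None = None,
) -> FeatureTable:
    """Read a feature table from TSV.

    Parameters
    ----------
    dialect : {"dense-tsv", "sparse-triplet"}
        ``dense-tsv``: features as rows, first column holds feature ids,
        header row holds sample ids. ``sparse-triplet``: three columns
        (feature, sample, count); unlisted cells are zero; a repeated
        (feature, sample) pair is an error, never summed.
    samples_as_rows : bool
        For the dense dialect only: transpose on read when the file has
        samples as rows.
    taxonomy_column : str, optional
        Name of a dense-dialect column holding lineage strings; split off
        into `FeatureTable.taxonomy`.
    """
    lines = _noncomment_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty table")
    if dialect == "dense-tsv":
        df = pd.read_csv(StringIO("\n".join(lines)), sep="\t", index_col=0)
        taxonomy = None
        if taxonomy_column is None and "taxonomy" in df.columns:
            taxonomy_column = "taxonomy"  # QIIME-style convention
        if taxonomy_column is not None:
            if taxonomy_column not in df.columns:
                raise FormatError(f"{path}: no taxonomy column {taxonomy_column!r}")
            taxonomy = df[taxonomy_column].astype(str)
            df = df.drop(columns=[taxonomy_column])
        if samples_as_rows:
            df = df.T
            if taxonomy is not None:
                raise FormatError("taxonomy column not supported with samples_as_rows")
        _check_integral(df, path)
        return FeatureTable(df.astype(np.int64), taxonomy)
    if dialect == "sparse-triplet":
        df = pd.read_csv(
            StringIO("\n".join(lines)),
            sep="\t",
            header=None,
            names=["feature", "sample", "count"],
            dtype={"feature": str, "sample": str},
        )
        # tolerate a header row
        if df.iloc[0]["feature"].lower() in {"feature", "feature_id"}:
            df = df.iloc[1:].reset_index(drop=True)
        dup = df.duplicated(subset=["feature", "sample"])
        if dup.any():
            f, s = df.loc[dup.idxmax(), ["feature", "sample"]]
            raise FormatError(
                f"{path}: duplicate triplet for feature {f!r}, sample {s!r}"
            )
        counts = pd.to_numeric(df["count"], errors="coerce")
        if counts.isna().any():
            row = df.loc[counts.isna().idxmax()]
            raise FormatError(f"{path}: non-numeric count in row {row.tolist()}")
        df["count"] = counts
        wide = df.pivot(index="feature", columns="sample", values="count").fillna(0)
        wide.index.name = None
        wide.columns.name = None
        _check_integral(wide, path)
        return FeatureTable(wide.astype(np.int64))
    raise ValueError(f"unknown dialect {dialect!r}")


def _check_integral(df: pd.DataFrame, path) -> None:
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric counts present")
    bad = ~np.isfinite(arr) | (arr != np.floor(arr))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-integer count {arr[i, j]!r} at feature "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"{path}: negative count at feature {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )


def write_feature_table(table: FeatureTable, path, dialect: str = "dense-tsv") -> None:
    if dialect == "dense-tsv":
        df = table.counts.copy()
        if table.taxonomy is not None:
            df = df.assign(taxonomy=table.taxonomy)
        df.to_csv(path, sep="\t", index_label="feature_id")
    elif dialect == "sparse-triplet":
        stacked = table.counts.stack()
        stacked = stacked[stacked > 0]
        with open(path, "w", encoding="utf-8") as fh:
            for (feat, samp), count in stacked.items():
                fh.write(f"{feat}\t{samp}\t{int(count)}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "sampleid": "sample_id",
    "#sampleid": "sample_id",
    "sample-id": "sample_id",
}


def read_metadata(path) -> SampleMetadata:
    """Read the sample metadata TSV.

    A QIIME2-style secondary header line (``#q2:types``) is tolerated and
    dropped without interpretation. Unknown columns are preserved.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    lines = [ln for i, ln in enumerate(lines)
             if not (i > 0 and ln.startswith("#"))]
    df = pd.read_csv(StringIO("\n".join(lines)), sep="\t", dtype=str)
    df.columns = [_COLUMN_ALIASES.get(c.strip().lower(), c.strip()) for c in df.columns]
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: no sample_id column")
    df = df.set_index("sample_id")
    for col in ("location_id", "session_index"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    if "radius" in df.columns:
        df["radius"] = pd.to_numeric(df["radius"], errors="coerce")
    if "pma_treated" in df.columns:
        df["pma_treated"] = (
            df["pma_treated"].str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False,
                 "yes": True, "no": False}
            )
        )
        if df["pma_treated"].isna().any():
            raise FormatError(f"{path}: unparseable pma_treated values")
        df["pma_treated"] = df["pma_treated"].astype(bool)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick(source) -> skbio.TreeNode:
    """Parse a rooted Newick tree with validation.

    Quoted labels and absent branch lengths are accepted; missing lengths
    become 0.0 (with a logged warning) so path-distance arithmetic stays
    total. Duplicate tip labels are an error.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        data = Path(source).read_text(encoding="utf-8")
    else:
        data = str(source)
    try:
        tree = skbio.TreeNode.read(StringIO(data), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"invalid newick: {exc}") from exc
    labels = [t.name for t in tree.tips()]
    if any(lbl is None for lbl in labels):
        raise FormatError("invalid newick: unlabeled tip")
    seen: set[str] = set()
    for lbl in labels:
        if lbl in seen:
            raise FormatError(f"invalid newick: duplicate tip label {lbl!r}")
        seen.add(lbl)
    n_missing = 0
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
            if not node.is_root():
                n_missing += 1
    if n_missing:
        log.warning("newick: %d missing branch lengths set to 0.0", n_missing)
    return tree


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# sequences and trait records
# ---------------------------------------------------------------------------

def normalize_sequence(seq: str) -> str:
    """Uppercase and strip gap characters; validate the IUPAC alphabet."""
    cleaned = str(seq).upper().replace("-", "").replace(".", "")
    bad = set(cleaned) - _IUPAC
    if bad:
        raise FormatError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return cleaned


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an id → sequence dict (ids must be unique)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise FormatError(f"{path}: no sequences")
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_trait_records(path) -> pd.DataFrame:
    """Read trait records TSV: record_id, sequence (or tip_label), spore_former."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "record_id" not in df.columns:
        raise FormatError(f"{path}: no record_id column")
    if "spore_former" not in df.columns and "state" not in df.columns:
        raise FormatError(f"{path}: no spore_former/state column")
    col = "spore_former" if "spore_former" in df.columns else "state"
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False, "spore_former": True,
               "non_spore_former": False, "spore": True, "non_spore": False}
    df["spore_former"] = df[col].str.strip().str.lower().map(mapping)
    if df["spore_former"].isna().any():
        raise FormatError(f"{path}: unparseable spore_former values")
    return df.set_index("record_id")
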