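"""Readers and writers for bioBakery/HUMAnN-style TSV tables.

Feature tables are tab-separated with the feature id in the first column and
one column per sample; feature ids follow the stratified
``PATHWAY|g__Genus.s__species`` convention, and the taxon part is matched
verbatim against the taxa-table row names. Lines starting with ``#`` are
comments. ``UNMAPPED``/``UNINTEGRATED`` pathway rows and unknown taxa are
dropped on load.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .containers import PairedDataset

__all__ = [
    "read_feature_table",
    "read_taxa_table",
    "read_metadata",
    "write_table",
    "write_metadata",
    "load_paired_dataset",
    "split_feature_id",
]

log = logging.getLogger(__name__)

UNMAPPED_PREFIXES = ("UNMAPPED", "UNINTEGRATED")
UNKNOWN_TAXA = ("unclassified", "UNKNOWN", "UNCLASSIFIED")


def split_feature_id(feature: str) -> tuple[str, str]:
    """Split ``'PATHWAY|g__Genus.s__species'`` into (pathway, taxon)."""
    if "|" not in feature:
        raise ValueError(f"feature id {feature!r} has no '|' pathway/taxon separator")
    pathway, taxon = feature.split("|", 1)
    return pathway, taxon


def _read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV whose header line may start with '#' (bioBakery style).

    Lines starting with '#' are comments, except that the last line of the
    leading comment block is taken as the header when it is tab-separated.
    """
    import io as _io

    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        i += 1
    if i > 0 and "\t" in lines[i - 1]:
        header = lines[i - 1].lstrip("#")
    elif i < len(lines):
        header = lines[i]
        i += 1
    else:
        raise ValueError(f"{path}: no header line found")
    body = [ln for ln in lines[i:] if ln and not ln.startswith("#")]
    df = pd.read_csv(_io.StringIO("\n".join([header] + body)), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def read_feature_table(
    path: str | Path, drop_unmapped: bool = True, renormalize: bool = False
) -> pd.DataFrame:
    """Read an RNA or DNA pathway-per-species abundance table.

    With ``renormalize`` the columns are rescaled to CPM after dropping
    unmapped rows (useful when the source totals included them).
    """
    df = _read_tsv(path)
    if drop_unmapped:
        keep = ~df.index.str.upper().str.startswith(UNMAPPED_PREFIXES)
        df = df.loc[keep]
    if renormalize:
        from .transforms import to_cpm

        df = to_cpm(df)
    return df


def read_taxa_table(path: str | Path, drop_unknown: bool = True) -> pd.DataFrame:
    """Read a MetaPhlAn-style species-by-sample relative-abundance table."""
    df = _read_tsv(path)
    if drop_unknown:
        low = df.index.str.lower()
        df = df.loc[~low.str.contains("unclassified") & ~low.str.contains("unknown")]
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    meta.index = meta.index.astype(str)
    return meta


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "#FEATURE") -> None:
    """Write a numeric table as TSV with fixed decimal precision (6 places)."""
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.6f")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def load_paired_dataset(
    rna_path: str | Path,
    dna_path: str | Path,
    taxa_path: str | Path,
    meta_path: str | Path,
    renormalize: bool = False,
) -> PairedDataset:
    """Assemble a :class:`PairedDataset` from four TSV files.

    Samples are intersected across the four inputs (ordered as in the RNA
    table); features present in only one of RNA/DNA, or whose taxon is
    absent from the taxa table, are dropped with a logged count.
    """
    rna = read_feature_table(rna_path, renormalize=renormalize)
    dna = read_feature_table(dna_path, renormalize=renormalize)
    taxa = read_taxa_table(taxa_path)
    meta = read_metadata(meta_path)

    samples = [s for s in rna.columns if s in dna.columns and s in taxa.columns and s in meta.index]
    if not samples:
        raise ValueError("no samples shared by all four input tables")

    features = rna.index.intersection(dna.index)
    n_dropped_pairing = len(rna.index.union(dna.index)) - len(features)
    taxon_of = {}
    kept = []
    for f in features:
        _, taxon = split_feature_id(f)
        if taxon in taxa.index:
            taxon_of[f] = taxon
            kept.append(f)
    if n_dropped_pairing or len(kept) < len(features):
        log.warning(
            "dropped %d unpaired features and %d features with unknown taxa",
            n_dropped_pairing,
            len(features) - len(kept),
        )
    if not kept:
        raise ValueError("no features with RNA, DNA and a matching taxon")

    return PairedDataset(
        rna=rna.loc[kept, samples],
        dna=dna.loc[kept, samples],
        taxa=taxa.loc[:, samples],
        feature_taxon=pd.Series(taxon_of, name="taxon").loc[kept],
        meta=meta.loc[samples],
    )


def write_paired_dataset(data: PairedDataset, outdir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write the four tables of a dataset; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rna": outdir / f"{prefix}rna.tsv",
        "dna": outdir / f"{prefix}dna.tsv",
        "taxa": outdir / f"{prefix}taxa.tsv",
        "meta": outdir / f"{prefix}metadata.tsv",
    }
    write_table(data.rna, paths["rna"])
    write_table(data.dna, paths["dna"])
    write_table(data.taxa, paths["taxa"], index_label="#SPECIES")
    write_metadata(data.meta, paths["meta"])
    return paths
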