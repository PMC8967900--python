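"""Readers, writers, and alignment for the cohort's standard inputs.

All matrices are gene-symbol-centric TSV files: a header row of sample (or
cell-line) identifiers, a first column named ``gene`` (or ``drug``), tab
separation, and missing values written as ``NA`` (empty cells accepted on
read).  Gene symbols are uppercased and whitespace-stripped so joins across
layers are deterministic; no alias mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROTEIN_KIND = "protein_log2ratio"
MRNA_KIND = "mrna_log2tpm"


def _normalize_symbols(ids: Iterable[str]) -> list[str]:
    return [str(s).strip().upper() for s in ids]


def _check_unique(labels, what: str) -> None:
    seen, dups = set(), []
    for x in labels:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class OmicsMatrix:
    """A features x samples abundance matrix with missing-value support.

    ``kind`` tags the layer: ``protein_log2ratio`` (relative log2 protein
    levels, missing allowed) or ``mrna_log2tpm`` (log2 TPM, complete).
    """

    values: pd.DataFrame
    kind: str = PROTEIN_KIND

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        if not all(np.issubdtype(dt, np.number) for dt in self.values.dtypes):
            bad = [c for c, dt in self.values.dtypes.items()
                   if not np.issubdtype(dt, np.number)]
            raise ValueError(f"non-numeric columns: {bad}")
        self.values.index = pd.Index(_normalize_symbols(self.values.index),
                                     name=self.values.index.name or "gene")
        _check_unique(self.values.index, "feature ids (after normalization)")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_complete_features(self) -> int:
        """Features quantified (non-missing) in every sample."""
        return int(self.values.notna().all(axis=1).sum())

    def subset_samples(self, samples: list[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values[list(samples)].copy(), kind=self.kind)

    def subset_features(self, features: list[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[list(features)].copy(), kind=self.kind)


@dataclass
class DrugResponseMatrix:
    """Drugs x cell lines matrix of sDSS (bone-marrow-normalized sensitivity)."""

    sdss: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.sdss.index, "drug ids")
        _check_unique(self.sdss.columns, "sample ids")
        vals = self.sdss.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("sDSS matrix contains infinite values")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.sdss.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sdss.columns)

    def subset_samples(self, samples: list[str]) -> "DrugResponseMatrix":
        return DrugResponseMatrix(self.sdss[list(samples)].copy())


@dataclass
class SampleMetadata:
    """Per-sample lineage (B/T/other), subtype, and replicate parentage."""

    table: pd.DataFrame  # index sample_id; columns lineage, subtype, replicate_of

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        for col in ("lineage", "subtype", "replicate_of"):
            if col not in self.table.columns:
                raise ValueError(f"metadata missing column {col!r}")
        known = set(self.table.index)
        parents = self.table["replicate_of"].dropna()
        missing = set(parents) - known
        if missing:
            raise ValueError(f"replicate_of points to unknown samples: {sorted(missing)}")
        # no replicate chains: a parent must itself have no parent
        chained = [s for s, p in parents.items()
                   if pd.notna(self.table.loc[p, "replicate_of"])]
        if chained:
            raise ValueError(f"replicate chains not allowed (samples {chained})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def lineage_of(self, sample: str) -> str:
        return str(self.table.loc[sample, "lineage"])

    def replicate_groups(self) -> dict[str, list[str]]:
        """parent -> [parent, replicates...]; only parents that have replicates."""
        groups: dict[str, list[str]] = {}
        for s, p in self.table["replicate_of"].items():
            if pd.notna(p):
                groups.setdefault(p, [p]).append(s)
        return groups

    def non_replicate_samples(self) -> list[str]:
        return [s for s in self.table.index
                if pd.isna(self.table.loc[s, "replicate_of"])]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. hallmark or KEGG pathways) from a GMT file."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = set(_normalize_symbols(members))

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ComplexCatalog:
    """Protein-complex membership catalog (CORUM-style)."""

    complexes: dict[str, set[str]]  # complex_id -> members
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if not members:
                raise ValueError(f"complex {cid!r} has no members")
            self.complexes[cid] = set(_normalize_symbols(members))

    def complexes_of(self, gene: str) -> list[str]:
        g = gene.strip().upper()
        return [cid for cid, members in self.complexes.items() if g in members]

    def __len__(self) -> int:
        return len(self.complexes)


@dataclass
class DrugAnnotation:
    """Per-drug class, putative target gene symbols, and free-text mechanism."""

    table: pd.DataFrame  # index drug_id; columns drug_class, targets (list), mechanism

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "drug ids")

    def targets_of(self, drug: str) -> list[str]:
        t = self.table.loc[drug, "targets"]
        return list(t) if isinstance(t, (list, tuple, set)) else []


# ---------------------------------------------------------------------------
# matrix TSV round trip
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, kind: str = PROTEIN_KIND) -> OmicsMatrix:
    df = _read_tsv_matrix(path)
    return OmicsMatrix(df, kind=kind)


def read_drug_matrix(path: str | Path) -> DrugResponseMatrix:
    return DrugResponseMatrix(_read_tsv_matrix(path))


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""],
                     keep_default_na=False)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path}")
            df[col] = coerced
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(matrix: OmicsMatrix | DrugResponseMatrix, path: str | Path) -> None:
    df = matrix.values if isinstance(matrix, OmicsMatrix) else matrix.sdss
    label = "gene" if isinstance(matrix, OmicsMatrix) else "drug"
    out = df.copy()
    out.index.name = label
    out.to_csv(path, sep="\t", na_rep="NA")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     na_values=["NA", ""], keep_default_na=False)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# cohort loading
# ---------------------------------------------------------------------------

def load_cohort(protein_path: str | Path, mrna_path: str | Path,
                metadata_path: str | Path) -> tuple[OmicsMatrix, OmicsMatrix,
                                                    SampleMetadata, dict]:
    """Load the protein and mRNA layers plus metadata, with a summary report."""
    protein = read_matrix(protein_path, kind=PROTEIN_KIND)
    mrna = read_matrix(mrna_path, kind=MRNA_KIND)
    meta = read_metadata(metadata_path)
    report = {
        "n_protein_features": len(protein.feature_ids),
        "n_mrna_features": len(mrna.feature_ids),
        "n_protein_samples": len(protein.sample_ids),
        "n_mrna_samples": len(mrna.sample_ids),
        "n_protein_complete_features": protein.n_complete_features(),
        "n_shared_features": len(set(protein.feature_ids) & set(mrna.feature_ids)),
    }
    logger.info("cohort loaded: %s", report)
    return protein, mrna, meta, report


def collapse_replicates(matrix: OmicsMatrix, metadata: SampleMetadata,
                        mode: str = "median") -> OmicsMatrix:
    """Collapse replicate columns onto their parent by protein-wise median.

    Missing values are ignored within each group; a group that is entirely
    missing for a feature yields a missing output value.
    """
    if mode != "median":
        raise ValueError("only median replicate collapse is supported")
    groups = metadata.replicate_groups()
    present = set(matrix.sample_ids)
    out = {}
    for s in matrix.sample_ids:
        parent = metadata.table.loc[s, "replicate_of"] if s in metadata.table.index else np.nan
        if pd.notna(parent):
            continue  # replicate columns are folded into their parent
        members = [m for m in groups.get(s, [s]) if m in present]
        if not members:
            continue
        col = matrix.values[members].median(axis=1, skipna=True)
        if len(members) > 1 and col.isna().any():
            logger.warning("collapse_replicates: %d features with no value in group %r",
                           int(col.isna().sum()), s)
        out[s] = col
    return OmicsMatrix(pd.DataFrame(out), kind=matrix.kind)


def align_samples(a, b):
    """Reorder two matrices to their sorted shared sample set.

    Accepts any mix of OmicsMatrix / DrugResponseMatrix.  Returns
    (a_aligned, b_aligned, shared_samples).
    """
    shared = sorted(set(a.sample_ids) & set(b.sample_ids))
    if not shared:
        raise ValueError("no shared samples between the two matrices")
    logger.info("align_samples: %d shared samples", len(shared))
    return a.subset_samples(shared), b.subset_samples(shared), shared


# ---------------------------------------------------------------------------
# annotation formats
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {i}: expected >= 3 fields, got {len(fields)}")
            name, desc, *members = fields
            members = [m for m in members if m]
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def read_complex_catalog(path: str | Path) -> ComplexCatalog:
    """TSV with columns complex_id, name, members (';'-joined gene symbols)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    complexes, names = {}, {}
    for _, row in df.iterrows():
        cid = str(row.iloc[0])
        names[cid] = str(row.iloc[1])
        members = [m for m in str(row.iloc[2]).split(";") if m]
        complexes[cid] = set(members)
    return ComplexCatalog(complexes, names)


def read_drug_annotations(path: str | Path) -> DrugAnnotation:
    """TSV with columns drug_id, drug_class, targets (';'-joined), mechanism."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                     keep_default_na=False)
    df = df.set_index(df.columns[0])
    cols = list(df.columns)
    out = pd.DataFrame(index=df.index)
    out["drug_class"] = df[cols[0]] if cols else ""
    raw_targets = df[cols[1]] if len(cols) >= 2 else pd.Series("", index=df.index)
    out["targets"] = [
        _normalize_symbols([x for x in str(t).split(";") if x]) if pd.notna(t) else []
        for t in raw_targets
    ]
    out["mechanism"] = df[cols[2]] if len(cols) >= 3 else ""
    return DrugAnnotation(out)


def load_annotations(gmt_path, complex_path, drug_annotation_path):
    gene_sets = read_gmt(gmt_path)
    catalog = read_complex_catalog(complex_path)
    drugs = read_drug_annotations(drug_annotation_path)
    logger.info("annotations: %d gene sets, %d complexes, %d drugs",
                len(gene_sets), len(catalog), len(drugs.table))
    return gene_sets, catalog, drugs
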