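"""Data containers and on-disk formats for genotype/trait datasets.

The two core containers mirror what a small GWAS cohort analysis needs:

``GenotypeMatrix``
    individuals x markers, either as allele dosages (0/1/2 copies of the
    minor allele) or dominant-coded presence/absence (0/1), with per-marker
    metadata (id, chromosome, position).

``TraitTable``
    individuals x traits, a mixture of binary (0/1) and quantitative
    columns, plus named covariates such as sex.

On disk a dataset is a directory of plain-text files: a TSV genotype
matrix, a CSV trait table, a TSV marker-metadata table and a JSON sidecar
declaring the genotype coding and per-trait kind.  A reader for the PLINK
``.raw`` dialect (``FID IID PAT MAT SEX PHENOTYPE`` followed by
``SNP_allele`` dosage columns) is provided for import.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DOSAGE = "dosage"
DOMINANT = "dominant"
CODINGS = (DOSAGE, DOMINANT)

BINARY = "binary"
QUANTITATIVE = "quantitative"
TRAIT_KINDS = (BINARY, QUANTITATIVE)

GENOTYPE_FILE = "genotypes.tsv"
TRAIT_FILE = "traits.csv"
MARKER_FILE = "markers.tsv"
METADATA_FILE = "metadata.json"


def _default_marker_meta(marker_ids: pd.Index) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": np.zeros(len(marker_ids), dtype=int),
         "pos": np.arange(len(marker_ids), dtype=int)},
        index=marker_ids,
    )


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype matrix with marker metadata.

    Parameters
    ----------
    values
        Numeric matrix, one row per individual and one column per marker.
        Entries must lie in {0, 1, 2} for ``coding='dosage'`` or {0, 1}
        for ``coding='dominant'``; NaN marks a missing call.
    coding
        Either ``'dosage'`` or ``'dominant'``.
    marker_ids, individual_ids
        Unique identifiers for columns and rows.
    marker_meta
        Optional per-marker table (indexed by marker id) with at least
        ``chrom`` and ``pos`` columns; generated if omitted.
    """

    values: np.ndarray
    coding: str = DOSAGE
    marker_ids: pd.Index = None
    individual_ids: pd.Index = None
    marker_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        n, m = self.values.shape
        if self.coding not in CODINGS:
            raise ValueError(f"unknown genotype coding {self.coding!r}")
        if self.marker_ids is None:
            self.marker_ids = pd.Index([f"snp{i:05d}" for i in range(m)])
        else:
            self.marker_ids = pd.Index(self.marker_ids)
        if self.individual_ids is None:
            self.individual_ids = pd.Index([f"ind{i:05d}" for i in range(n)])
        else:
            self.individual_ids = pd.Index(self.individual_ids)
        if len(self.marker_ids) != m:
            raise ValueError("marker_ids length does not match matrix width")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match matrix height")
        if self.marker_ids.has_duplicates:
            raise ValueError("marker IDs must be unique")
        if self.individual_ids.has_duplicates:
            raise ValueError("individual IDs must be unique")
        finite = self.values[np.isfinite(self.values)]
        allowed = {DOSAGE: (0, 1, 2), DOMINANT: (0, 1)}[self.coding]
        if finite.size and not np.isin(finite, allowed).all():
            raise ValueError(
                f"{self.coding}-coded genotypes must take values in {allowed}"
            )
        if self.marker_meta is None:
            self.marker_meta = _default_marker_meta(self.marker_ids)
        else:
            self.marker_meta = self.marker_meta.loc[self.marker_ids]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individual_ids,
                            columns=self.marker_ids)

    def select_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the given marker positions (order kept)."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            values=self.values[:, keep],
            coding=self.coding,
            marker_ids=self.marker_ids[keep],
            individual_ids=self.individual_ids,
            marker_meta=self.marker_meta.iloc[keep],
        )


@dataclass
class TraitTable:
    """Individuals x traits table with per-trait kind and covariates."""

    values: pd.DataFrame
    kinds: dict = field(default_factory=dict)
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        missing = [c for c in self.values.columns if c not in self.kinds]
        if missing:
            raise ValueError(f"trait kind not declared for: {missing}")
        for name, kind in self.kinds.items():
            if kind not in TRAIT_KINDS:
                raise ValueError(f"unknown trait kind {kind!r} for {name!r}")
            if kind == BINARY:
                col = self.values[name].dropna()
                if not col.isin([0, 1]).all():
                    raise ValueError(f"binary trait {name!r} must take values 0/1")
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=self.values.index)
        else:
            self.covariates = pd.DataFrame(self.covariates)
            if not self.covariates.index.equals(self.values.index):
                raise ValueError("covariate index must match trait index")

    @property
    def trait_names(self) -> list:
        return list(self.values.columns)

    @property
    def individual_ids(self) -> pd.Index:
        return self.values.index

    def binary_traits(self) -> list:
        return [t for t in self.trait_names if self.kinds[t] == BINARY]

    def quantitative_traits(self) -> list:
        return [t for t in self.trait_names if self.kinds[t] == QUANTITATIVE]


def write_dataset(genotypes: GenotypeMatrix, traits: TraitTable,
                  directory: str | Path) -> Path:
    """Write a genotype/trait dataset to ``directory`` as plain-text files.

    The round trip through :func:`read_dataset` is lossless for values,
    IDs, the genotype coding flag and the per-trait kinds.
    """
    if not genotypes.individual_ids.equals(traits.individual_ids):
        raise ValueError("genotype and trait individual IDs do not match")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gdf = genotypes.to_frame()
    gdf.index.name = "individual_id"
    gdf.to_csv(directory / GENOTYPE_FILE, sep="\t")
    tdf = pd.concat([traits.values, traits.covariates], axis=1)
    tdf.index.name = "individual_id"
    tdf.to_csv(directory / TRAIT_FILE)
    meta = genotypes.marker_meta.copy()
    meta.index.name = "marker_id"
    meta.to_csv(directory / MARKER_FILE, sep="\t")
    sidecar = {
        "coding": genotypes.coding,
        "trait_kinds": dict(traits.kinds),
        "covariates": list(traits.covariates.columns),
    }
    (directory / METADATA_FILE).write_text(json.dumps(sidecar, indent=2))
    return directory


def read_dataset(directory: str | Path) -> tuple[GenotypeMatrix, TraitTable]:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    for fname in (GENOTYPE_FILE, TRAIT_FILE, MARKER_FILE, METADATA_FILE):
        if not (directory / fname).exists():
            raise FileNotFoundError(f"missing dataset file: {directory / fname}")
    sidecar = json.loads((directory / METADATA_FILE).read_text())
    gdf = pd.read_csv(directory / GENOTYPE_FILE, sep="\t", index_col=0)
    gdf.index = gdf.index.astype(str)
    meta = pd.read_csv(directory / MARKER_FILE, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    tdf = pd.read_csv(directory / TRAIT_FILE, index_col=0)
    tdf.index = tdf.index.astype(str)
    if not gdf.index.equals(tdf.index):
        raise ValueError("individual IDs differ between genotype and trait files")
    covars = sidecar.get("covariates", [])
    kinds = sidecar["trait_kinds"]
    genotypes = GenotypeMatrix(
        values=gdf.to_numpy(dtype=float),
        coding=sidecar["coding"],
        marker_ids=gdf.columns.astype(str),
        individual_ids=gdf.index,
        marker_meta=meta if len(meta) else _default_marker_meta(gdf.columns.astype(str)),
    )
    traits = TraitTable(
        values=tdf[list(kinds)],
        kinds=kinds,
        covariates=tdf[covars],
    )
    return genotypes, traits


def read_plink_raw(path: str | Path, missing_code: str = "NA") -> tuple[GenotypeMatrix, pd.Series]:
    """Import genotypes from a PLINK ``.raw`` (``--recode A``) file.

    Returns the dosage-coded genotype matrix and a 0/1 sex covariate
    (1 = male, from PLINK's SEX column where 1 = male, 2 = female).
    Marker IDs are taken from the ``SNP_allele`` column headers with the
    counted-allele suffix stripped.
    """
    df = pd.read_csv(path, sep=r"\s+", na_values=[missing_code])
    fixed = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[: len(fixed)]) != fixed:
        raise ValueError("not a PLINK .raw file: expected header "
                         "FID IID PAT MAT SEX PHENOTYPE ...")
    snp_cols = df.columns[len(fixed):]
    marker_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    genotypes = GenotypeMatrix(
        values=df[snp_cols].to_numpy(dtype=float),
        coding=DOSAGE,
        marker_ids=marker_ids,
        individual_ids=df["IID"].astype(str),
    )
    sex = pd.Series(np.where(df["SEX"] == 1, 1, 0), index=genotypes.individual_ids,
                    name="sex")
    return genotypes, sex
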