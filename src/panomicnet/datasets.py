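"""Typed container and I/O for the integrated multi-modal patient data frame.

The network analysis operates on a single complete patients x variables
matrix in which every variable carries a *class* label (the measurement
modality it came from: genetics, expression, proteomics, metabolomics,
lipidomics, conventional biomarker, clinical, phenotype) and a *kind*
(continuous, binary, or additive genotype dosage).  Class labels drive the
class-aware complexity penalty in :mod:`panomicnet.scoring`; kinds select
the local regression family.

Missingness is rejected outright: the integrated frame is required to be
complete, and imputation belongs to the upstream omics preprocessing stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VAR_CLASSES = frozenset(
    {
        "genetics",
        "expression",
        "proteomics",
        "metabolomics",
        "lipidomics",
        "biomarker",
        "clinical",
        "phenotype",
    }
)

VAR_KINDS = frozenset({"continuous", "binary", "genotype_additive"})


class CompletenessError(ValueError):
    """A cell of the integrated data frame is missing."""


class MetadataError(ValueError):
    """Variable metadata is malformed or inconsistent with the matrix."""


class DomainError(ValueError):
    """A value violates its declared measurement kind."""


@dataclass(frozen=True)
class VariableMeta:
    """Name, modality class, and measurement kind of one variable."""

    name: str
    var_class: str
    kind: str

    def __post_init__(self) -> None:
        if self.var_class not in VAR_CLASSES:
            raise MetadataError(
                f"unknown var_class {self.var_class!r} for {self.name!r}; "
                f"expected one of {sorted(VAR_CLASSES)}"
            )
        if self.kind not in VAR_KINDS:
            raise MetadataError(
                f"unknown kind {self.kind!r} for {self.name!r}; "
                f"expected one of {sorted(VAR_KINDS)}"
            )


@dataclass(frozen=True)
class ClassMap:
    """Distinct variable classes present in a dataset and their sizes |S_c|."""

    classes: tuple[str, ...]
    sizes: dict[str, int] = field(hash=False)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def size_of(self, var_class: str) -> int:
        if var_class not in self.sizes:
            raise MetadataError(f"class {var_class!r} not present in dataset")
        return self.sizes[var_class]


class PanomicDataset:
    """Complete patients x variables matrix with per-variable metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix, one row per patient, columns ordered as ``meta``.
    meta : sequence of VariableMeta
        One entry per column, same order.
    patient_ids : sequence of str, optional
        Defaults to the values index.
    """

    def __init__(self, values: pd.DataFrame, meta: list[VariableMeta], patient_ids=None):
        meta = list(meta)
        if values.shape[1] != len(meta):
            raise MetadataError(
                f"matrix has {values.shape[1]} columns but metadata describes {len(meta)}"
            )
        names = [m.name for m in meta]
        if len(set(names)) != len(names):
            raise MetadataError("duplicate variable names in metadata")
        if list(values.columns) != names:
            # allow same set in different order; realign to meta order
            if set(values.columns) != set(names):
                raise MetadataError("matrix columns do not match metadata names")
            values = values[names]
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise MetadataError("dataset requires n >= 1 patients and p >= 1 variables")

        arr = values.to_numpy(dtype=float, copy=True)
        nan_rows, nan_cols = np.nonzero(np.isnan(arr))
        if nan_rows.size:
            r, c = int(nan_rows[0]), int(nan_cols[0])
            raise CompletenessError(
                f"missing value at patient {values.index[r]!r}, variable {names[c]!r}; "
                "the integrated frame must be complete"
            )

        for j, m in enumerate(meta):
            col = arr[:, j]
            if m.kind == "genotype_additive" and not np.isin(col, (0.0, 1.0, 2.0)).all():
                bad = col[~np.isin(col, (0.0, 1.0, 2.0))][0]
                raise DomainError(
                    f"genotype variable {m.name!r} contains {bad!r}; values must be 0/1/2"
                )
            if m.kind == "binary" and not np.isin(col, (0.0, 1.0)).all():
                bad = col[~np.isin(col, (0.0, 1.0))][0]
                raise DomainError(
                    f"binary variable {m.name!r} contains {bad!r}; values must be 0/1"
                )

        if patient_ids is None:
            patient_ids = [str(i) for i in values.index]
        else:
            patient_ids = [str(p) for p in patient_ids]
        if len(patient_ids) != arr.shape[0]:
            raise MetadataError("patient_ids length does not match matrix rows")
        if len(set(patient_ids)) != len(patient_ids):
            raise MetadataError("patient IDs must be unique")
        self.values = pd.DataFrame(
            arr, columns=names, index=pd.Index(patient_ids, name="patient_id")
        )
        self.meta = meta

    # -- basic introspection -------------------------------------------------

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def patient_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def meta_of(self, name: str) -> VariableMeta:
        for m in self.meta:
            if m.name == name:
                return m
        raise MetadataError(f"unknown variable {name!r}")

    def kind_of(self, name: str) -> str:
        return self.meta_of(name).kind

    def class_of(self, name: str) -> str:
        return self.meta_of(name).var_class

    def column(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy()

    # -- I/O -----------------------------------------------------------------

    def save(self, matrix_path, meta_path) -> None:
        """Write the matrix and metadata back out as delimited text."""
        sep_m = _sep_for(matrix_path)
        self.values.to_csv(matrix_path, sep=sep_m, index_label="patient_id")
        meta_df = pd.DataFrame(
            {
                "name": [m.name for m in self.meta],
                "var_class": [m.var_class for m in self.meta],
                "kind": [m.kind for m in self.meta],
            }
        )
        meta_df.to_csv(meta_path, sep=_sep_for(meta_path), index=False)


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def load_dataset(matrix_path, meta_path) -> PanomicDataset:
    """Load and validate an integrated matrix + variable metadata pair.

    Matrix files carry a header row of variable names and a leading
    ``patient_id`` column; metadata files carry columns name, var_class, kind.
    Tab or comma delimiting is sniffed from the file extension (.csv = comma).
    """
    matrix_path, meta_path = Path(matrix_path), Path(meta_path)
    mat = pd.read_csv(matrix_path, sep=_sep_for(matrix_path))
    meta_df = pd.read_csv(meta_path, sep=_sep_for(meta_path))

    for col in ("name", "var_class", "kind"):
        if col not in meta_df.columns:
            raise MetadataError(f"metadata file lacks required column {col!r}")
    meta = [
        VariableMeta(str(r.name), str(r.var_class), str(r.kind))
        for r in meta_df.itertuples(index=False)
    ]

    if mat.columns[0] in ("patient_id", "id", "sample_id"):
        mat = mat.set_index(mat.columns[0])
    names = [m.name for m in meta]
    missing = set(names) - set(mat.columns)
    if missing:
        raise MetadataError(f"matrix lacks columns described in metadata: {sorted(missing)}")

    try:
        vals = mat[names].apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise DomainError(f"non-numeric cell in matrix: {exc}") from exc
    return PanomicDataset(vals, meta, patient_ids=list(mat.index))


def class_map(dataset: PanomicDataset) -> ClassMap:
    """Count the classes actually present: |C| and each |S_c|."""
    sizes: dict[str, int] = {}
    for m in dataset.meta:
        sizes[m.var_class] = sizes.get(m.var_class, 0) + 1
    return ClassMap(classes=tuple(sorted(sizes)), sizes=sizes)


def standardize(dataset: PanomicDataset) -> PanomicDataset:
    """Rescale continuous columns to mean 0, unit (MLE) variance.

    Binary and genotype columns pass through untouched.  A zero-variance
    continuous column becomes all zeros with a logged warning.
    """
    vals = dataset.values.copy()
    for m in dataset.meta:
        if m.kind != "continuous":
            continue
        col = vals[m.name].to_numpy()
        sd = col.std()
        if sd == 0.0:
            logger.warning("variable %r is constant; standardized to zeros", m.name)
            vals[m.name] = 0.0
        else:
            vals[m.name] = (col - col.mean()) / sd
    return PanomicDataset(vals, dataset.meta, patient_ids=dataset.patient_ids)


def load_genotypes_vcf(vcf_path, variant_ids: list[str]) -> pd.DataFrame:
    """Extract additive-coded genotype columns (0/1/2 alt-allele counts) from a VCF.

    Phase is ignored; a half-missing or missing GT raises, since the
    integrated frame admits no missing cells and imputation is not done here.
    """
    from cyvcf2 import VCF

    wanted = list(variant_ids)
    found: dict[str, np.ndarray] = {}
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    try:
        for rec in vcf:
            vid = rec.ID
            if vid not in wanted:
                continue
            gts = rec.genotypes  # [[a0, a1, phased], ...]
            dosages = np.empty(len(gts), dtype=float)
            for i, g in enumerate(gts):
                alleles = [a for a in g[:-1] if a is not None and a >= 0]
                if len(alleles) != len(g) - 1:
                    raise CompletenessError(
                        f"variant {vid!r} has a missing genotype call for sample "
                        f"{samples[i]!r}; no imputation is performed here"
                    )
                dosages[i] = float(sum(1 for a in alleles if a > 0))
            found[vid] = dosages
    finally:
        vcf.close()

    absent = [v for v in wanted if v not in found]
    if absent:
        raise LookupError(f"variant IDs not found in {vcf_path}: {absent}")
    return pd.DataFrame({v: found[v] for v in wanted}, index=samples)
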