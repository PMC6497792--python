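"""Reading, validating and writing long-format phenotype and qPCR tables.

The universal input is a tidy long table: one row per measurement with
columns ``genotype, environment, replicate, trait, value`` and an optional
``day`` column for time-course data.  qPCR tables carry raw cycle-threshold
(Ct) values with columns
``genotype, treatment, day, gene, biological_rep, technical_rep, ct``.

Environment / treatment labels are normalized case-insensitively to the
two-level factor ``{non_stressed, stressed}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRecordError,
    EmptyTableError,
    SchemaError,
)

NON_STRESSED = "non_stressed"
STRESSED = "stressed"
ENVIRONMENTS = (NON_STRESSED, STRESSED)

PHENOTYPE_COLUMNS = ["genotype", "environment", "replicate", "trait", "value"]
QPCR_COLUMNS = [
    "genotype",
    "treatment",
    "day",
    "gene",
    "biological_rep",
    "technical_rep",
    "ct",
]

_KEY_COLUMNS = ["genotype", "environment", "replicate", "trait", "day"]


def normalize_environment(label: object) -> str:
    """Map an environment/treatment label onto the canonical two-level factor.

    Accepts any case and any of space, hyphen or underscore as the word
    separator (``"Non-stressed"`` -> ``"non_stressed"``).
    """
    text = str(label).strip().lower().replace("-", "_").replace(" ", "_")
    if text in {"non_stressed", "nonstressed", "ns", "control", "non_stress"}:
        return NON_STRESSED
    if text in {"stressed", "s", "stress", "drought"}:
        return STRESSED
    raise SchemaError(
        f"unrecognized environment label {label!r}; expected one of "
        f"{ENVIRONMENTS} (case-insensitive)"
    )


@dataclass(frozen=True)
class DesignSummary:
    """Design constants of a phenotype table.

    ``n_replicates`` is the modal number of observations per
    genotype x environment x trait cell; ``balanced`` is true iff every
    cell of the full cross holds exactly that many non-missing values.
    """

    n_genotypes: int
    n_environments: int
    n_replicates: int
    balanced: bool
    missing_cells: tuple = field(default_factory=tuple)

    # Short aliases matching the field's conventional symbols.
    @property
    def g(self) -> int:
        return self.n_genotypes

    @property
    def s(self) -> int:
        return self.n_environments

    @property
    def r(self) -> int:
        return self.n_replicates


@dataclass
class PhenotypeTable:
    """A validated long-format phenotype table.

    ``data`` always carries the canonical columns in canonical order; the
    ``day`` column is present only for time-course tables.  ``design`` is
    computed once at construction.
    """

    data: pd.DataFrame
    design: DesignSummary = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.design is None:
            self.design = design_summary(self)

    @property
    def traits(self) -> list:
        return sorted(self.data["trait"].unique())

    @property
    def genotypes(self) -> list:
        return sorted(self.data["genotype"].unique())

    def trait_values(self, trait: str, environment: str | None = None) -> pd.DataFrame:
        """Rows for one trait (optionally one environment), missing values dropped."""
        sub = self.data[self.data["trait"] == trait]
        if environment is not None:
            sub = sub[sub["environment"] == normalize_environment(environment)]
        return sub.dropna(subset=["value"])

    def __len__(self) -> int:
        return len(self.data)


def _validate_phenotype_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"phenotype table is missing required columns: {missing}")
    df = df.copy()
    df["environment"] = df["environment"].map(normalize_environment)
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    if (df["replicate"] < 1).any():
        raise SchemaError("replicate numbers must be positive integers")
    # Unparseable values become missing but the record is kept, never dropped.
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df.loc[~np.isfinite(df["value"].to_numpy(dtype=float)), "value"] = np.nan
    if "day" in df.columns:
        df["day"] = pd.to_numeric(df["day"], errors="coerce")
        cols = PHENOTYPE_COLUMNS + ["day"]
    else:
        cols = PHENOTYPE_COLUMNS
    df = df[cols].reset_index(drop=True)

    key_cols = [c for c in _KEY_COLUMNS if c in df.columns]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        first = df.loc[dup, key_cols].iloc[0].to_dict()
        raise DuplicateRecordError(f"duplicate record key: {first}")
    return df


def phenotype_table_from_frame(df: pd.DataFrame) -> PhenotypeTable:
    """Validate an in-memory data frame into a :class:`PhenotypeTable`."""
    return PhenotypeTable(_validate_phenotype_frame(df))


def read_phenotype_table(path, sep: str = ",") -> PhenotypeTable:
    """Read and validate a long-format phenotype CSV.

    Empty fields and ``NA`` encode missing values.  Records with
    unparseable values are kept with value marked missing.
    """
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""], keep_default_na=True)
    return phenotype_table_from_frame(df)


def write_phenotype_table(table: PhenotypeTable, path, sep: str = ",") -> None:
    """Write a phenotype table as CSV with deterministic column order."""
    cols = PHENOTYPE_COLUMNS + (["day"] if "day" in table.data.columns else [])
    table.data[cols].to_csv(path, sep=sep, index=False, na_rep="NA")


def design_summary(table: PhenotypeTable | pd.DataFrame) -> DesignSummary:
    """Compute g, s, r and the balance flag for a phenotype table.

    The replicate count r is the modal cell count over the complete
    genotype x environment x trait cross (per day for time-course data);
    any cell with fewer than r non-missing values is listed in
    ``missing_cells`` and flips ``balanced`` to False.
    """
    df = table.data if isinstance(table, PhenotypeTable) else table
    if len(df) == 0:
        raise EmptyTableError("cannot summarize an empty phenotype table")

    cell_cols = ["genotype", "environment", "trait"]
    if "day" in df.columns and df["day"].notna().any():
        cell_cols = cell_cols + ["day"]
    observed = df.dropna(subset=["value"])
    counts = (
        observed.groupby(cell_cols, observed=True)
        .size()
        .unstack("trait", fill_value=0)  # type: ignore[arg-type]
    )
    # Reindex over the full genotype x environment (x day) cross so absent
    # cells count as zero observations.
    full_index = pd.MultiIndex.from_product(
        [sorted(df[c].dropna().unique()) for c in cell_cols if c != "trait"],
        names=[c for c in cell_cols if c != "trait"],
    )
    counts = counts.reindex(full_index, fill_value=0)

    flat = counts.to_numpy().ravel()
    if flat.size == 0 or flat.max() == 0:
        raise EmptyTableError("phenotype table has no non-missing values")
    values, freqs = np.unique(flat[flat > 0], return_counts=True)
    # modal cell count; ties resolved toward the larger count so that
    # genuinely short cells are the ones flagged as missing
    r = int(values[freqs == freqs.max()].max())

    missing = []
    short = counts < r
    for idx, row in short.iterrows():
        for trait in counts.columns[row.to_numpy()]:
            key = idx if isinstance(idx, tuple) else (idx,)
            missing.append((*key[:2], trait))
    balanced = not missing and bool((counts.to_numpy() == r).all())

    return DesignSummary(
        n_genotypes=int(df["genotype"].nunique()),
        n_environments=int(df["environment"].nunique()),
        n_replicates=r,
        balanced=balanced,
        missing_cells=tuple(missing),
    )


def _validate_qpcr_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"qPCR table is missing required columns: {missing}")
    df = df.copy()
    df["treatment"] = df["treatment"].map(normalize_environment)
    for col in ("day", "biological_rep", "technical_rep"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    if (df["ct"] <= 0).any():
        bad = df.loc[df["ct"] <= 0].iloc[0]
        raise SchemaError(
            f"non-positive Ct value {bad['ct']} for gene {bad['gene']!r}"
        )
    df = df[QPCR_COLUMNS].reset_index(drop=True)
    key = ["genotype", "treatment", "day", "gene", "biological_rep", "technical_rep"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0].to_dict()
        raise DuplicateRecordError(f"duplicate qPCR record key: {first}")
    return df


def read_qpcr_table(path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a long-format qPCR Ct table."""
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""], keep_default_na=True)
    return _validate_qpcr_frame(df)


def qpcr_table_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory qPCR data frame."""
    return _validate_qpcr_frame(df)


def write_qpcr_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    df[QPCR_COLUMNS].to_csv(path, sep=sep, index=False, na_rep="NA")
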