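"""Domain containers and file I/O shared by every pipeline stage.

The pipeline moves four kinds of objects between stages: a genes-by-samples
expression matrix on a positive linear (PLIER-like) intensity scale, a
per-sample phenotype table, a many-to-one cross-platform probeset map, and a
collection of named gene sets over a stated background.  All readers validate
hard and reject malformed input with messages that name the offending row or
identifier; silent coercion is the classic source of irreproducible microarray
analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("bloodsig")

DIAGNOSES = ("case", "control")
SUBTYPES = ("AUT", "PDDNOS", "ASP", "none")
SEXES = ("male", "female")
COHORTS = ("P1like", "P2like")

PHENOTYPE_COLUMNS = (
    "sample_id",
    "diagnosis",
    "subtype",
    "sex",
    "age_years",
    "batch",
    "cohort",
)


class ValidationError(ValueError):
    """Raised when an input file or container violates a pipeline invariant."""


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind} ID: {i!r}")
        seen.add(i)


class ExpressionMatrix:
    """Genes-by-samples expression values on a positive linear scale.

    Parameters
    ----------
    values
        DataFrame with feature IDs as the index and sample IDs as columns.
        All entries must be finite, positive floats.
    """

    def __init__(self, values: pd.DataFrame):
        _check_unique(values.index, "feature")
        _check_unique(values.columns, "sample")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = values.columns[
                [not np.issubdtype(d, np.number) for d in values.dtypes]
            ]
            raise ValidationError(f"non-numeric expression values in columns {list(bad)}")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing expression value at feature {values.index[r]!r}, "
                f"sample {values.columns[c]!r}"
            )
        if (arr <= 0).any():
            r, c = np.argwhere(arr <= 0)[0]
            raise ValidationError(
                f"non-positive intensity {arr[r, c]!r} at feature "
                f"{values.index[r]!r}, sample {values.columns[c]!r}; "
                "expression must be on the positive linear scale"
            )
        self._df = values.astype(float)
        self._df.index = self._df.index.astype(str)
        self._df.columns = self._df.columns.astype(str)

    @property
    def feature_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        """Features-by-samples float array (a view of the backing frame)."""
        return self._df.to_numpy()

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def log2(self) -> np.ndarray:
        return np.log2(self._df.to_numpy())

    def subset_features(self, features) -> "ExpressionMatrix":
        missing = [f for f in features if f not in self._df.index]
        if missing:
            raise ValidationError(f"unknown feature IDs: {missing[:5]}")
        return ExpressionMatrix(self._df.loc[list(features)])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self._df.columns]
        if missing:
            raise ValidationError(f"unknown sample IDs: {missing[:5]}")
        return ExpressionMatrix(self._df[list(samples)])

    @classmethod
    def from_log2(cls, log2_values: np.ndarray, feature_ids, sample_ids) -> "ExpressionMatrix":
        """Build a matrix from log2-scale values (exponentiated on the way in)."""
        return cls(
            pd.DataFrame(
                np.exp2(np.asarray(log2_values, dtype=float)),
                index=list(feature_ids),
                columns=list(sample_ids),
            )
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self._df.equals(other._df)


class SampleTable:
    """Per-sample phenotype annotations: diagnosis, subtype, sex, age, batch, cohort."""

    def __init__(self, table: pd.DataFrame):
        missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
        if missing_cols:
            raise ValidationError(f"phenotype table missing columns {missing_cols}")
        table = table.loc[:, list(PHENOTYPE_COLUMNS)].copy()
        table["sample_id"] = table["sample_id"].astype(str)
        _check_unique(table["sample_id"], "sample")
        for col, levels in (
            ("diagnosis", DIAGNOSES),
            ("subtype", SUBTYPES),
            ("sex", SEXES),
            ("cohort", COHORTS),
        ):
            bad = table.loc[~table[col].isin(levels), "sample_id"]
            if len(bad):
                raise ValidationError(
                    f"unknown {col} level for sample {bad.iloc[0]!r}: "
                    f"{table.set_index('sample_id')[col][bad.iloc[0]]!r} "
                    f"(allowed: {levels})"
                )
        ctrl_with_subtype = table[
            (table["diagnosis"] == "control") & (table["subtype"] != "none")
        ]
        if len(ctrl_with_subtype):
            raise ValidationError(
                "control sample with an ASD subtype: "
                f"{ctrl_with_subtype['sample_id'].iloc[0]!r}"
            )
        case_without = table[(table["diagnosis"] == "case") & (table["subtype"] == "none")]
        if len(case_without):
            raise ValidationError(
                f"case sample without a subtype: {case_without['sample_id'].iloc[0]!r}"
            )
        table["age_years"] = pd.to_numeric(table["age_years"], errors="raise")
        if (table["age_years"] < 0).any():
            sid = table.loc[table["age_years"] < 0, "sample_id"].iloc[0]
            raise ValidationError(f"negative age for sample {sid!r}")
        table["batch"] = table["batch"].astype(str)
        self._df = table.set_index("sample_id", drop=False)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    def aligned_to(self, sample_ids) -> "SampleTable":
        missing = [s for s in sample_ids if s not in self._df.index]
        if missing:
            raise ValidationError(f"phenotype table missing samples {missing[:5]}")
        return SampleTable(self._df.loc[list(sample_ids)].reset_index(drop=True))

    def column(self, name: str, sample_ids=None) -> np.ndarray:
        df = self._df if sample_ids is None else self._df.loc[list(sample_ids)]
        return df[name].to_numpy()

    def is_case(self, sample_ids=None) -> np.ndarray:
        return self.column("diagnosis", sample_ids) == "case"

    def __len__(self) -> int:
        return len(self._df)


@dataclass(frozen=True)
class PlatformMap:
    """Many-to-one links from source probesets to target probesets/genes.

    A source probeset maps to exactly one target; a target may collect
    several sources (the best-match situation between an older and a newer
    array design).
    """

    records: pd.DataFrame  # columns: source_probeset, target_probeset, gene_symbol

    def __post_init__(self):
        req = ["source_probeset", "target_probeset", "gene_symbol"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValidationError(f"platform map missing columns {missing}")
        dup = self.records["source_probeset"][self.records["source_probeset"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"source probeset mapped more than once: {dup.iloc[0]!r}"
            )

    @property
    def source_ids(self) -> list[str]:
        return list(self.records["source_probeset"])

    @property
    def target_ids(self) -> list[str]:
        return list(pd.unique(self.records["target_probeset"]))

    def sources_for_target(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for src, tgt in zip(
            self.records["source_probeset"], self.records["target_probeset"]
        ):
            out.setdefault(tgt, []).append(src)
        return out


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (pathways) over an explicit background universe."""

    background: frozenset
    sets: dict  # name -> frozenset of gene symbols
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if len(members) < 1:
                raise ValidationError(f"gene set {name!r} is empty")
            stray = members - self.background
            if stray:
                raise ValidationError(
                    f"gene set {name!r} has members outside the background: "
                    f"{sorted(stray)[:5]}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, *, phenotype: SampleTable | None = None,
                    impute_missing: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix (genes in rows, header of sample IDs).

    The transposed (samples-in-rows) orientation is auto-detected only when a
    phenotype table is supplied and the header matches its sample IDs;
    otherwise the file is taken at face value.  Missing cells are a hard
    error unless ``impute_missing`` asks for per-gene median imputation.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ValidationError(f"{path}: missing header row with sample IDs")
    _check_unique(header[1:], "sample")  # pandas would silently mangle these
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.columns.size == 0 or df.index.name is None:
        raise ValidationError(f"{path}: missing header row with sample IDs")
    try:
        num = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric expression cell ({exc})") from exc
    if phenotype is not None:
        known = set(phenotype.sample_ids)
        cols_known = sum(c in known for c in num.columns)
        rows_known = sum(r in known for r in num.index)
        if rows_known > cols_known and rows_known == len(num.index):
            logger.info("expression file %s is samples-in-rows; transposing", path)
            num = num.T
    if num.isna().any().any():
        if impute_missing:
            med = num.median(axis=1)
            num = num.apply(lambda row: row.fillna(med[row.name]), axis=1)
        else:
            r = num.index[num.isna().any(axis=1)][0]
            raise ValidationError(
                f"{path}: missing value in feature {r!r} "
                "(pass impute_missing=True for per-gene median imputation)"
            )
    x = ExpressionMatrix(num)
    logger.info("read expression matrix %s: %d features x %d samples",
                path, *x.shape)
    return x


def write_expression(x: ExpressionMatrix, path) -> None:
    """Write the matrix as TSV with 6 significant digits per value."""
    df = x.frame.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_phenotype(path) -> SampleTable:
    """Read the per-sample phenotype CSV (see :data:`PHENOTYPE_COLUMNS`)."""
    df = pd.read_csv(path, dtype=str)
    return SampleTable(df)


def write_phenotype(t: SampleTable, path) -> None:
    t.frame.to_csv(path, index=False)


def read_platform_map(path) -> PlatformMap:
    """Read the TSV source→target probeset map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return PlatformMap(df)


def write_platform_map(m: PlatformMap, path) -> None:
    m.records.to_csv(path, sep="\t", index=False)


def read_gmt(path, background=None) -> GeneSetCollection:
    """Read a GMT gene-set file.

    Each line: name, description, then tab-separated members.  The background
    defaults to the union of all members unless supplied explicitly, in which
    case every member must belong to it.
    """
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: gene set {parts[0]!r} has no members"
                )
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValidationError(
                    f"{path}:{lineno}: gene set {name!r} has no members"
                )
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    if background is None:
        background = frozenset().union(*sets.values()) if sets else frozenset()
    else:
        background = frozenset(background)
        for name, members in sets.items():
            stray = sorted(members - background)
            if stray:
                raise ValidationError(
                    f"gene set {name!r} has members outside the supplied "
                    f"background: {stray[:5]}"
                )
    return GeneSetCollection(background=background, sets=sets, descriptions=descriptions)


def write_gmt(c: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in c.sets.items():
            desc = c.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
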