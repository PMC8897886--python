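"""Input readers, validation, and the shared data model.

The analysis pipeline operates on three inputs: an expression matrix
(genes x samples), a per-sample clinical table (optionally carrying
survival time/event columns), and a plain-text list of driver genes.
Gene-set collections in GMT format feed the enrichment stage.

All tabular IO goes through pandas; files are TSV by default with CSV
auto-detected from the ``.csv`` extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: Numeric clinical columns with at most this many distinct non-missing
#: values are auto-typed categorical (ordinal stage-like codes); overrides
#: always win.
MAX_CATEGORICAL_LEVELS = 5


class InputError(ValueError):
    """Raised for malformed or inconsistent input data."""


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise InputError(f"duplicate {what} identifier(s): {', '.join(map(str, dups.index[:10]))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric expression matrix.

    ``data`` is indexed by gene id with sample ids as columns. Missing
    values are permitted; downstream statistics use pairwise-complete
    observations. Genes with fewer than two distinct finite values are
    flagged in ``constant_genes`` (they cannot enter correlation-based
    analyses).
    """

    data: pd.DataFrame
    constant_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "gene")
        _check_unique(list(self.data.columns), "sample")
        if self.data.shape[1] < 3:
            raise InputError(f"need at least 3 samples, got {self.data.shape[1]}")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = None
        self.data.columns.name = None
        vals = self.data.to_numpy(dtype=float)
        n_distinct = [len(np.unique(row[np.isfinite(row)])) for row in vals]
        self.constant_genes = [g for g, k in zip(self.data.index, n_distinct) if k < 2]
        if self.constant_genes:
            logger.warning(
                "%d gene(s) are constant (or all-missing) and will be excluded from "
                "correlation-based analyses: %s",
                len(self.constant_genes),
                ", ".join(self.constant_genes[:10]),
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise InputError(f"gene(s) not in matrix: {', '.join(missing[:10])}")
        return ExpressionMatrix(self.data.loc[list(genes)].copy())

    def drop_constant(self) -> "ExpressionMatrix":
        if not self.constant_genes:
            return self
        keep = [g for g in self.gene_ids if g not in set(self.constant_genes)]
        return ExpressionMatrix(self.data.loc[keep].copy())


@dataclass
class ClinicalTable:
    """Per-sample clinical features with declared types and optional survival.

    ``feature_types`` maps each feature column to ``"continuous"`` or
    ``"categorical"``. ``survival_time``/``survival_event`` are parallel
    Series (or ``None`` when absent); event is 1 for an observed event,
    0 for censoring. Samples with missing survival are retained here and
    excluded only inside survival analyses.
    """

    data: pd.DataFrame
    feature_types: dict[str, str]
    survival_time: pd.Series | None = None
    survival_event: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "sample")
        self.data.index = self.data.index.astype(str)
        self.data.index.name = None
        if (self.survival_time is None) != (self.survival_event is None):
            raise InputError("survival_time and survival_event must be supplied together")
        if self.survival_time is not None:
            t = pd.to_numeric(self.survival_time, errors="coerce")
            if (t.dropna() < 0).any():
                raise InputError("negative survival times")
            e = self.survival_event
            bad = e.dropna()[~e.dropna().isin([0, 1])]
            if len(bad):
                raise InputError(f"survival event values outside {{0,1}}: {sorted(set(bad))}")
            self.survival_time = t
            self.survival_event = pd.to_numeric(e, errors="coerce")
        for name, ftype in self.feature_types.items():
            if ftype not in (CONTINUOUS, CATEGORICAL):
                raise InputError(f"unknown feature type {ftype!r} for {name!r}")
            if ftype == CATEGORICAL and self.data[name].dropna().nunique() < 2:
                logger.warning("categorical feature %r has < 2 observed levels", name)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.feature_types)

    def has_survival(self) -> bool:
        return self.survival_time is not None

    def subset_samples(self, samples: Sequence[str]) -> "ClinicalTable":
        samples = list(samples)
        return ClinicalTable(
            self.data.loc[samples].copy(),
            dict(self.feature_types),
            None if self.survival_time is None else self.survival_time.loc[samples].copy(),
            None if self.survival_event is None else self.survival_event.loc[samples].copy(),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (id -> description + members) for over-representation.

    Stand-in for annotation databases: any GMT file (GO, KEGG, custom)
    can be supplied. Duplicate members within a set are collapsed.
    """

    sets: dict[str, tuple[str, tuple[str, ...]]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for sid, (_desc, members) in self.sets.items():
            if not members:
                raise InputError(f"gene set {sid!r} is empty")

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class AlignedDataset:
    """Expression + clinical on an identical sample order, plus the driver list."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    driver_genes: list[str]

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.clinical.sample_ids:
            raise InputError("expression and clinical sample order differ")
        missing = set(self.driver_genes) - set(self.expression.gene_ids)
        if missing:
            raise InputError(f"driver gene(s) absent from expression: {sorted(missing)[:10]}")

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    def driver_expression(self) -> ExpressionMatrix:
        return self.expression.subset_genes(self.driver_genes)


# ---------------------------------------------------------------------------
# loaders


def load_expression(
    path: str | Path, genes_in_rows: bool = True, sep: str | None = None
) -> ExpressionMatrix:
    """Read a delimited expression table; orient to genes x samples.

    Non-numeric cells become missing. The first column (or row, when
    ``genes_in_rows`` is false) holds identifiers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path, sep), index_col=0)
    if not genes_in_rows:
        df = df.T
    df = df.apply(pd.to_numeric, errors="coerce")
    return ExpressionMatrix(df)


def load_clinical(
    path: str | Path,
    type_overrides: Mapping[str, str] | None = None,
    time_col: str | None = None,
    event_col: str | None = None,
    sep: str | None = None,
) -> ClinicalTable:
    """Read a per-sample clinical table; auto-type each feature.

    Auto-typing rule: a numeric column with at most
    ``MAX_CATEGORICAL_LEVELS`` distinct non-missing values is
    categorical (ordinal codes such as tumour stage), any other numeric
    column is continuous, and non-numeric columns are categorical.
    ``type_overrides`` wins over the heuristic.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path, sep), index_col=0)
    df.index = df.index.astype(str)
    overrides = dict(type_overrides or {})

    time = event = None
    if (time_col is None) != (event_col is None):
        raise InputError("time_col and event_col must be supplied together")
    if time_col is not None:
        for col in (time_col, event_col):
            if col not in df.columns:
                raise InputError(f"survival column {col!r} not in table")
        time = pd.to_numeric(df[time_col], errors="coerce")
        event = pd.to_numeric(df[event_col], errors="coerce")
        df = df.drop(columns=[time_col, event_col])

    types: dict[str, str] = {}
    for col in df.columns:
        if col in overrides:
            types[col] = overrides[col]
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.notna().sum() == 0 and df[col].notna().sum() > 0:
            types[col] = CATEGORICAL
        elif numeric.dropna().nunique() <= MAX_CATEGORICAL_LEVELS:
            types[col] = CATEGORICAL
        else:
            types[col] = CONTINUOUS
            df[col] = numeric
    for col, t in types.items():
        if t == CONTINUOUS:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return ClinicalTable(df, types, time, event)


def load_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``id TAB description TAB gene...``."""
    path = Path(path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path.name}:{lineno}: GMT line has < 3 tab-fields")
            sid, desc, *genes = fields
            members = tuple(dict.fromkeys(g for g in genes if g))
            if sid in sets:
                raise InputError(f"{path.name}:{lineno}: duplicate set id {sid!r}")
            sets[sid] = (desc, members)
    if not sets:
        raise InputError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


def load_driver_list(path: str | Path) -> list[str]:
    """Read a plain-text driver-gene list, one symbol per line."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if not genes:
        raise InputError(f"{path}: empty driver list")
    return list(dict.fromkeys(genes))


def align(
    expression: ExpressionMatrix, clinical: ClinicalTable, drivers: Sequence[str]
) -> AlignedDataset:
    """Intersect samples, order clinical like expression, drop unknown drivers."""
    common = [s for s in expression.sample_ids if s in set(clinical.sample_ids)]
    if not common:
        raise InputError("expression and clinical tables share no samples")
    dropped_expr = len(expression.sample_ids) - len(common)
    dropped_clin = len(clinical.sample_ids) - len(common)
    if dropped_expr or dropped_clin:
        logger.warning(
            "sample alignment dropped %d expression-only and %d clinical-only samples; "
            "%d remain",
            dropped_expr,
            dropped_clin,
            len(common),
        )
    known = set(expression.gene_ids)
    kept = [g for g in dict.fromkeys(drivers) if g in known]
    missing = [g for g in dict.fromkeys(drivers) if g not in known]
    if missing:
        logger.warning(
            "%d driver gene(s) absent from the expression matrix were dropped: %s",
            len(missing),
            ", ".join(missing[:10]),
        )
    if not kept:
        raise InputError("no driver genes present in the expression matrix")
    expr = ExpressionMatrix(expression.data.loc[:, common].copy())
    clin = clinical.subset_samples(common)
    return AlignedDataset(expr, clin, kept)


# ---------------------------------------------------------------------------
# writers (round-trip partners of the loaders)


def write_expression(expr: ExpressionMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    expr.data.to_csv(path, sep=_infer_sep(path, sep), index_label="gene")


def write_clinical(clin: ClinicalTable, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    out = clin.data.copy()
    if clin.has_survival():
        out["time"] = clin.survival_time
        out["event"] = clin.survival_event
    out.to_csv(path, sep=_infer_sep(path, sep), index_label="sample")
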