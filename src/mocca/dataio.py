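"""Reading, writing and aligning assay matrices, phenotypes, weights and configs.

An *assay matrix* is a samples-by-features table of one omics data type
(protein abundances, methylation beta values, genotype dosages coded 0/1/2).
In memory it is a :class:`pandas.DataFrame` whose index holds sample
identifiers and whose columns hold feature identifiers.  Canonical *weight
matrices* are features-by-components DataFrames with columns ``CV1..CVK``.

All identifier matching is by exact string equality: silent fuzzy matches
are worse than loud errors.  Missing values are rejected outright — the CCA
machinery cannot accommodate them and imputation belongs upstream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_assay",
    "write_assay",
    "validate_assay",
    "align_samples",
    "intersect_features",
    "drop_features",
    "read_weights",
    "write_weights",
    "read_phenotypes",
    "read_config",
]


@dataclasses.dataclass
class RunConfig:
    """Run configuration for a fit.

    Parameters mirror the solver knobs: ``penalties`` is either the string
    ``"default"`` (0.5 * sqrt(p_i) per assay) or a per-assay list of L1
    bounds in [1, sqrt(p_i)]; ``deflation_mode`` selects projection
    residualization (default, guarantees orthogonal CVs) or the literal
    cumulative rank-one subtraction; ``selection_quantile`` is the fraction
    of features the supervised variant retains per assay.
    """

    n_components: int = 1
    penalties: object = "default"
    deflation_mode: str = "projection"
    selection_quantile: float = 0.8
    seed: int = 0
    convergence_tol: float = 1e-6
    max_iter: int = 100
    init: str = "svd"

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be a positive integer")
        if self.deflation_mode not in ("projection", "rank_one"):
            raise ValueError(f"unknown deflation_mode {self.deflation_mode!r}")
        if not 0 < self.selection_quantile <= 1:
            raise ValueError("selection_quantile must be in (0, 1]")
        if self.convergence_tol <= 0 or self.max_iter < 1:
            raise ValueError("convergence_tol must be > 0 and max_iter >= 1")
        if self.init not in ("svd", "random"):
            raise ValueError(f"unknown init {self.init!r}")


def _check_unique(ids: Iterable[str], what: str, path: object = None) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()[:5]
        where = f" in {path}" if path is not None else ""
        raise ValueError(f"duplicate {what} identifiers{where}: {dups}")


def validate_assay(assay: pd.DataFrame, name: str = "assay") -> pd.DataFrame:
    """Validate an assay matrix: unique ids, numeric dtype, no missing cells.

    Returns the validated frame (values coerced to float64).  On the first
    missing cell the error names the offending sample/feature pair.
    """
    _check_unique(assay.index, "sample")
    _check_unique(assay.columns, "feature")
    try:
        values = assay.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{name}: non-numeric cell(s): {exc}") from exc
    if values.isna().any().any():
        mask = values.isna()
        col = mask.any(axis=0).idxmax()
        row = mask[col].idxmax()
        raise ValueError(
            f"{name}: missing value at sample {row!r}, feature {col!r}; "
            "the method cannot accommodate missing data"
        )
    return values


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_assay(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a samples x features assay table (header = feature ids, first
    column = sample ids)."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    _check_unique(header, "feature", path)  # pandas would silently mangle these
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = header
    return validate_assay(df, name=str(path))


def write_assay(assay: pd.DataFrame, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    assay.to_csv(path, sep=_sep_for(path, dialect), float_format="%.17g")


def align_samples(
    assays: Sequence[pd.DataFrame], phenotypes: pd.DataFrame | None = None
) -> tuple[list[pd.DataFrame], pd.DataFrame | None, dict]:
    """Restrict all inputs to their common samples, in a single shared order.

    The common order is the sample order of the first assay restricted to the
    intersection.  Returns the aligned assays, the aligned phenotype table
    (or None), and a report of per-input dropped counts.
    """
    if not assays:
        raise ValueError("no assays given")
    tables: list[pd.DataFrame] = list(assays)
    if phenotypes is not None:
        tables = tables + [phenotypes]
    common = tables[0].index
    for t in tables[1:]:
        common = common.intersection(t.index)
    if len(common) == 0:
        raise ValueError("no samples are shared across all inputs")
    order = [s for s in assays[0].index if s in set(common)]
    report = {
        "n_common": len(order),
        "dropped": [int(t.shape[0] - len(order)) for t in tables],
    }
    for i, n_drop in enumerate(report["dropped"]):
        if n_drop:
            logger.info("align_samples: input %d drops %d sample(s)", i, n_drop)
    out_assays = [a.loc[order] for a in assays]
    out_pheno = phenotypes.loc[order] if phenotypes is not None else None
    return out_assays, out_pheno, report


def intersect_features(
    weights: pd.DataFrame,
    assay: pd.DataFrame,
    max_missing_fraction: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict a weight matrix and a target assay to their shared features.

    Used for cross-cohort transfer, where the target cohort may lack some
    features the weights were trained on.  The tolerated loss is measured as
    the fraction of total absolute weight mass per component carried by the
    missing features; exceeding ``max_missing_fraction`` on any component is
    an error (too much of the canonical variable would be silently dropped).
    """
    shared = [f for f in weights.index if f in set(assay.columns)]
    if not shared:
        raise ValueError("weight matrix and assay share no features")
    missing = weights.index.difference(shared)
    if len(missing):
        total = weights.abs().sum(axis=0)
        lost = weights.loc[missing].abs().sum(axis=0)
        frac = (lost / total.replace(0.0, np.nan)).fillna(0.0)
        worst = float(frac.max())
        if worst > max_missing_fraction:
            raise ValueError(
                f"{len(missing)} weight-bearing feature(s) absent from assay; "
                f"up to {worst:.3g} of absolute weight mass lost on component "
                f"{frac.idxmax()!r} (max allowed {max_missing_fraction})"
            )
        logger.warning(
            "intersect_features: dropping %d feature(s) absent from assay "
            "(max weight-mass loss %.3g)", len(missing), worst,
        )
    return weights.loc[shared], assay[shared]


def drop_features(assay: pd.DataFrame, exclusion_ids: Iterable[str]) -> pd.DataFrame:
    """Remove features on an exclusion list (e.g. sex-chromosome probes).

    Ids absent from the assay are ignored (logged); removing every feature
    is an error.
    """
    excl = set(exclusion_ids)
    present = [c for c in assay.columns if c in excl]
    absent = excl.difference(present)
    if absent:
        logger.info("drop_features: %d exclusion id(s) not in assay", len(absent))
    keep = [c for c in assay.columns if c not in excl]
    if not keep:
        raise ValueError("exclusion list covers all features: empty assay")
    return assay[keep]


def write_weights(
    weights: pd.DataFrame,
    path: str | Path,
    assay_name: str = "",
    penalties: Sequence[float] | None = None,
    standardization: Mapping[str, Mapping[str, float]] | None = None,
) -> None:
    """Write a features x components weight matrix as TSV plus a JSON sidecar
    (assay name, per-component penalties, training standardization constants)."""
    path = Path(path)
    weights.to_csv(path, sep="\t", index_label="feature_id", float_format="%.17g")
    meta = {
        "assay_name": assay_name,
        "penalties": None if penalties is None else [float(c) for c in penalties],
        "standardization": None
        if standardization is None
        else {k: {f: float(v) for f, v in m.items()} for k, m in standardization.items()},
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True)
    )


def read_weights(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    weights = pd.read_csv(path, sep="\t", index_col=0)
    weights.index = weights.index.astype(str)
    _check_unique(weights.index, "feature", path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return weights, meta


def read_phenotypes(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a phenotype/covariate table (first column = sample ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    df.index = df.index.astype(str)
    _check_unique(df.index, "sample", path)
    return df


def check_binary(outcome: pd.Series | np.ndarray, name: str = "outcome") -> np.ndarray:
    """Validate a binary outcome (exactly two distinct values) and code it 0/1."""
    y = np.asarray(outcome)
    levels = np.unique(y)
    if len(levels) != 2:
        raise ValueError(f"{name} is not binary: {len(levels)} distinct value(s)")
    return (y == levels[1]).astype(float)


def read_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file; unknown keys are errors."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**data)


def validate_penalty(c: float, p: int) -> float:
    c = float(c)
    if not (1.0 <= c <= math.sqrt(p) + 1e-12):
        raise ValueError(f"penalty {c} outside [1, sqrt(p)=" f"{math.sqrt(p):.4g}]")
    return c
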