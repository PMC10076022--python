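"""Readers, writers and validated domain containers.

Orientation convention used throughout the package: expression matrices are
genes x samples (genes are rows, samples are columns). Enrichment matrices
are pathways x samples. All on-disk tables are plain TSV/CSV with a header
row of sample identifiers and an identifier first column; gene sets travel
as GMT; structured results as key-ordered JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ParseError",
    "ExpressionMatrix",
    "StageDesign",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_annotations",
    "write_annotations",
    "prepare_expression",
    "write_report",
    "read_report",
]

#: significant digits used for all floating-point round trips
FLOAT_FMT = "%.12g"

ANNOTATION_COLUMNS = ("cohort", "group", "stage", "cluster", "surv_time", "surv_event")


class FormatError(ValueError):
    """A file violates the structural contract of its format."""


class ParseError(ValueError):
    """A cell or line could not be interpreted; the message names the location."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, genes x samples.

    ``data`` is a pandas DataFrame whose index holds unique gene ids and whose
    columns hold unique sample ids. Missing entries are NaN; infinities are
    rejected at validation.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- attribute surface -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if np.isinf(vals).any():
            g, s = np.argwhere(np.isinf(vals))[0]
            raise FormatError(
                f"non-finite value at gene {idx[g]!r}, sample {cols[s]!r}"
            )

    def subset(
        self,
        genes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        df = self.data
        if genes is not None:
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise KeyError(f"genes not in matrix: {missing[:5]}")
            df = df.loc[list(genes)]
        if samples is not None:
            missing = [s for s in samples if s not in df.columns]
            if missing:
                raise KeyError(f"samples not in matrix: {missing[:5]}")
            df = df[list(samples)]
        return ExpressionMatrix(df.copy())


@dataclass
class StageDesign:
    """Maps samples to ordered stage labels with one reference (normal) stage."""

    sample_to_stage: dict[str, str]
    stage_order: tuple[str, ...]
    reference_stage: str

    def __post_init__(self) -> None:
        self.stage_order = tuple(self.stage_order)
        used = set(self.sample_to_stage.values())
        unknown = used - set(self.stage_order)
        if unknown:
            raise FormatError(f"stages not in stage_order: {sorted(unknown)}")
        if self.reference_stage not in self.stage_order:
            raise FormatError(
                f"reference stage {self.reference_stage!r} not in stage_order"
            )

    @property
    def stages(self) -> tuple[str, ...]:
        return self.stage_order

    @property
    def non_reference_stages(self) -> tuple[str, ...]:
        return tuple(s for s in self.stage_order if s != self.reference_stage)

    def samples_for(self, stage: str) -> list[str]:
        if stage not in self.stage_order:
            raise KeyError(f"unknown stage {stage!r}")
        return [s for s, st in self.sample_to_stage.items() if st == stage]

    def require_min_samples(self, stage: str, n: int) -> list[str]:
        samples = self.samples_for(stage)
        if len(samples) < n:
            raise ValueError(
                f"stage {stage!r} has {len(samples)} samples; at least {n} required"
            )
        return samples

    @classmethod
    def from_annotations(
        cls,
        annotations: pd.DataFrame,
        reference_stage: str,
        stage_order: Sequence[str] | None = None,
    ) -> "StageDesign":
        if "stage" not in annotations.columns:
            raise FormatError("annotation table lacks a 'stage' column")
        mapping = {
            str(s): str(st)
            for s, st in annotations["stage"].dropna().items()
        }
        if stage_order is None:
            seen: list[str] = []
            for st in mapping.values():
                if st not in seen:
                    seen.append(st)
            if reference_stage in seen:  # reference first, rest in file order
                seen.remove(reference_stage)
            stage_order = [reference_stage] + seen
        return cls(mapping, tuple(stage_order), reference_stage)

    def to_dict(self) -> dict[str, Any]:
        return {
            "sample_to_stage": dict(self.sample_to_stage),
            "stage_order": list(self.stage_order),
            "reference_stage": self.reference_stage,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "StageDesign":
        return cls(dict(d["sample_to_stage"]), tuple(d["stage_order"]), d["reference_stage"])


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways), GMT-backed.

    ``sets`` maps set name -> (description, gene list); gene lists are
    deduplicated preserving first occurrence. ``category`` optionally labels
    each set (e.g. a KEGG metabolic category).
    """

    sets: dict[str, tuple[str, list[str]]]
    category: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, tuple[str, list[str]]] = {}
        for name, (desc, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(g, None)
            cleaned[name] = (desc, list(seen))
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return list(self.sets[name][1])

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def all_genes(self) -> list[str]:
        out: dict[str, None] = {}
        for _, genes in self.sets.values():
            for g in genes:
                out.setdefault(g, None)
        return list(out)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        names = list(names)
        return GeneSetCollection(
            {n: self.sets[n] for n in names},
            {n: self.category[n] for n in names if n in self.category},
        )


# ---------------------------------------------------------------------------
# expression I/O
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: str | Path,
    delimiter: str = "\t",
    missing_token: str = "NA",
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples table: first column gene ids, header sample ids.

    Duplicated gene rows are collapsed by their mean with a warning. Cells
    equal to ``missing_token`` become missing; any other non-numeric cell is a
    :class:`ParseError` naming the row and column. ``log2_transform`` applies
    log2(x + 1) for matrices that arrive on linear scale.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False,
        skip_blank_lines=True,
    )
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"{path}: empty expression table")
    stripped = raw.apply(lambda c: c.str.strip())
    is_missing = stripped.eq(missing_token) | stripped.eq("")
    numeric = stripped.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~is_missing
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {stripped.iat[g, s]!r} at "
            f"gene {raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    numeric = numeric.where(~is_missing)
    if numeric.index.has_duplicates:
        dups = sorted(set(numeric.index[numeric.index.duplicated()]))
        warnings.warn(
            f"{path}: collapsing duplicated gene ids by mean: {dups[:10]}",
            UserWarning,
            stacklevel=2,
        )
        numeric = numeric.groupby(level=0, sort=False).mean()
    if log2_transform:
        if (numeric < 0).any().any():
            raise FormatError(f"{path}: negative values cannot be log2(x+1)-transformed")
        numeric = np.log2(numeric + 1.0)
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric)


def write_expression_matrix(
    expr: ExpressionMatrix, path: str | Path, delimiter: str = "\t",
    missing_token: str = "NA",
) -> None:
    expr.data.to_csv(
        Path(path), sep=delimiter, float_format=FLOAT_FMT, na_rep=missing_token,
        index_label="gene_id",
    )


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB gene TAB gene ..."""
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, genes)
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# sample annotations
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read per-sample annotations (sample_id, cohort, group, stage, cluster,
    surv_time, surv_event); unknown columns are preserved."""
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: annotation table lacks 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    df = df.set_index("sample_id")
    if "surv_time" in df.columns:
        t = pd.to_numeric(df["surv_time"], errors="coerce")
        if (t.dropna() < 0).any():
            raise FormatError(f"{path}: negative survival time")
        df["surv_time"] = t
    if "surv_event" in df.columns:
        e = pd.to_numeric(df["surv_event"], errors="coerce")
        if not e.dropna().isin([0, 1]).all():
            raise FormatError(f"{path}: surv_event must be 0 or 1")
        df["surv_event"] = e
    return df


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(Path(path), sep="\t", index_label="sample_id",
                       float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# missing-value policy
# ---------------------------------------------------------------------------


def prepare_expression(
    expr: ExpressionMatrix,
    design: StageDesign,
    max_missing_per_stage: float = 0.2,
) -> ExpressionMatrix:
    """Apply the package's missing-value policy ahead of correlation work.

    Genes with more than ``max_missing_per_stage`` missing entries in any
    stage are dropped (warning); remaining missing entries are imputed by the
    gene's stage median. Correlation and SD estimates downstream require
    complete vectors.
    """
    df = expr.data.copy()
    drop = pd.Series(False, index=df.index)
    for stage in design.stage_order:
        samples = [s for s in design.samples_for(stage) if s in df.columns]
        if not samples:
            continue
        frac = df[samples].isna().mean(axis=1)
        drop |= frac > max_missing_per_stage
    if drop.any():
        warnings.warn(
            f"dropping {int(drop.sum())} genes with > "
            f"{max_missing_per_stage:.0%} missing entries in some stage",
            UserWarning,
            stacklevel=2,
        )
        df = df.loc[~drop]
    if df.isna().to_numpy().any():
        for stage in design.stage_order:
            samples = [s for s in design.samples_for(stage) if s in df.columns]
            if not samples:
                continue
            block = df[samples]
            med = block.median(axis=1)
            df[samples] = block.apply(lambda col: col.fillna(med))
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)!r}")


def write_report(report: Any, path: str | Path) -> None:
    """Serialize a pipeline result deterministically.

    Objects exposing ``to_dict`` (reports, models) become key-ordered JSON;
    :class:`ExpressionMatrix` and enrichment-style DataFrame payloads become
    TSV. The matching reader round-trips the object.
    """
    path = Path(path)
    if isinstance(report, ExpressionMatrix):
        write_expression_matrix(report, path)
        return
    if hasattr(report, "to_frame") and not isinstance(report, pd.DataFrame):
        report.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FMT)
        return
    if isinstance(report, pd.DataFrame):
        report.to_csv(path, sep="\t", float_format=FLOAT_FMT)
        return
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    try:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: str | Path, cls: type | None = None) -> Any:
    """Read a JSON report written by :func:`write_report`; ``cls`` with a
    ``from_dict`` classmethod reconstructs the typed object."""
    with open(Path(path)) as fh:
        payload = json.load(fh)
    if cls is not None and hasattr(cls, "from_dict"):
        return cls.from_dict(payload)
    return payload
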