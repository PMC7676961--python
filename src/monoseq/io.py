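"""Tab-delimited readers and writers for expression matrices, stage files
and result tables.

All formats are plain text: an expression matrix has sample identifiers in
the first row and gene identifiers in the first column; a stage file has
two (optionally three) columns ``sample<TAB>stage[<TAB>label]`` with
integer stage codes where 0 marks a normal control; result tables are the
DataFrames produced by the detection modules, written with a fixed column
order so runs diff cleanly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .megdetect import StageDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_stages",
    "write_stages",
    "write_table",
]


@dataclass
class ExpressionMatrix:
    """Genes-by-samples real matrix with identifier axes.

    ``scale_note`` is a free-text provenance tag (e.g. "log2(FPKM+1)");
    it is carried along but never interpreted.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    scale_note: str = ""

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match gene/sample axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return ExpressionMatrix(
            self.genes, sample_ids, self.values[:, idx], self.scale_note
        )

    def reorder_genes(self, genes: list[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = [pos[g] for g in genes]
        return ExpressionMatrix(genes, self.samples, self.values[idx], self.scale_note)


def read_expression(path, log2_shift: bool = False) -> ExpressionMatrix:
    """Read a tab-delimited genes-by-samples matrix.

    First row: sample identifiers; first column: gene identifiers.  With
    ``log2_shift`` each value x becomes log2(x + 1), the usual transform
    for FPKM-like nonnegative input.

    Raises on duplicate gene identifiers, non-numeric cells, ragged rows
    and missing values, naming the offending gene/position.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = df.index.astype(str)
    dup = genes[genes.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene identifier(s): {sorted(set(dup))[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for g, row in df.iterrows():
            for s, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {cell!r} at gene {g!r}, sample {s!r}"
                    ) from None
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing value at gene {genes[i]!r}, sample {df.columns[j]!r}"
        )
    note = ""
    if log2_shift:
        if (values < 0).any():
            raise ValueError("log2_shift requires nonnegative input values")
        values = np.log2(values + 1.0)
        note = "log2(x+1)"
    return ExpressionMatrix(
        list(genes), [str(c) for c in df.columns], values, scale_note=note
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.genes, columns=expr.samples)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_stages(path, expected_samples: list[str] | None = None) -> StageDesign:
    """Read a ``sample<TAB>stage[<TAB>label]`` file into a StageDesign.

    Stage codes must be nonnegative integers (0 = normal control).  When
    ``expected_samples`` is given, the design is returned in that order;
    samples present in the file but absent from the expression matrix are
    dropped with a logged count, while expression samples missing from the
    file raise an error listing them.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] not in (2, 3):
        raise ValueError(
            f"stage file must have 2 or 3 columns, found {df.shape[1]}"
        )
    samples = df[0].astype(str).tolist()
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample identifier in stage file")
    try:
        stage = df[1].astype(int).to_numpy()
    except ValueError:
        bad = df[1][~df[1].str.fullmatch(r"\d+")].iloc[0]
        raise ValueError(f"non-integer stage code {bad!r}") from None

    labels = None
    if df.shape[1] == 3:
        labels = {}
        for code, lab in zip(stage, df[2].astype(str)):
            prev = labels.setdefault(int(code), lab)
            if prev != lab:
                raise ValueError(
                    f"stage {code} mapped to both labels {prev!r} and {lab!r}"
                )

    if expected_samples is not None:
        have = dict(zip(samples, stage))
        missing = [s for s in expected_samples if s not in have]
        if missing:
            raise ValueError(
                f"{len(missing)} expression sample(s) missing from stage file: "
                f"{missing[:5]}"
            )
        n_extra = len(set(samples) - set(expected_samples))
        if n_extra:
            logger.warning(
                "dropped %d stage-file sample(s) absent from expression matrix",
                n_extra,
            )
        samples = list(expected_samples)
        stage = np.array([have[s] for s in samples])
    return StageDesign(samples, stage, labels)


def write_stages(design: StageDesign, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for s, k in zip(design.samples, design.stage):
            if design.stage_labels and int(k) in design.stage_labels:
                fh.write(f"{s}\t{k}\t{design.stage_labels[int(k)]}\n")
            else:
                fh.write(f"{s}\t{k}\n")


def write_table(table: pd.DataFrame, path, sort_by_p: bool = False) -> None:
    """Write a result table (MEG or MFSelector) as TSV.

    Row order is input gene order by default for diffability; with
    ``sort_by_p`` rows are ordered by adjusted p (stable on ties).
    """
    out = table
    if sort_by_p and "p_adjusted" in table.columns:
        out = table.sort_values("p_adjusted", kind="stable")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
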