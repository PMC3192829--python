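"""Data model and TSV readers/writers for expression matrices, sample designs
and gene annotations.

The central container is :class:`ExpressionMatrix`: a gene x sample table of
normalized log2(Cy5 sample / Cy3 common-reference) ratios with an optional
matched signal-to-noise (SNR) table.  Spots with SNR below ``snr_min``
(default 2) are considered unquantifiable and masked; all downstream
operations (replicate summaries, correlations) honour that mask.

File dialect: tab-separated UTF-8, ``NA`` for masked/missing cells, first
header cell of a matrix file is the literal ``gene_id``.  Matrix files carry
gene order; design files carry sample order.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SUBSTRATES = ("glucose", "xylose", "fructose", "cellobiose", "glucose_xylose")
PHASES = ("early", "mid", "late")

#: Standard single-letter COG functional categories.
COG_LETTERS = "JAKLBDYVTMNZWUOCGEFHIPQRS"

DEFAULT_SNR_MIN = 2.0


class ValidationError(ValueError):
    """Raised when an input table violates the data-model contract."""


@dataclass(frozen=True)
class Sample:
    sample_id: str
    substrate: str
    phase: str
    replicate: int

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES:
            raise ValidationError(
                f"unknown substrate {self.substrate!r} for sample {self.sample_id!r};"
                f" expected one of {SUBSTRATES}"
            )
        if self.phase not in PHASES:
            raise ValidationError(
                f"unknown phase {self.phase!r} for sample {self.sample_id!r};"
                f" expected one of {PHASES}"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"replicate index must be >= 1, got {self.replicate} for {self.sample_id!r}"
            )

    @property
    def condition(self) -> tuple[str, str]:
        return (self.substrate, self.phase)


@dataclass(frozen=True)
class SampleDesign:
    """Ordered collection of samples in a substrate x growth-phase design."""

    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate sample ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def conditions(self) -> list[tuple[str, str]]:
        """Distinct (substrate, phase) pairs in first-appearance order."""
        seen: dict[tuple[str, str], None] = {}
        for s in self.samples:
            seen.setdefault(s.condition, None)
        return list(seen)

    def columns_for(self, condition: tuple[str, str]) -> list[int]:
        """Column indices of the replicates of one condition."""
        return [i for i, s in enumerate(self.samples) if s.condition == condition]

    def phases_for(self, substrate: str) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            if s.substrate == substrate:
                seen.setdefault(s.phase, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "substrate": [s.substrate for s in self.samples],
                "phase": [s.phase for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2 ratios with quantifiability mask.

    ``mask[g, s]`` is True where the spot is quantifiable.  When an SNR table
    is present the mask is exactly ``snr >= snr_min``; without one, cells that
    were read as ``NA`` stay masked and everything else is quantifiable.
    """

    genes: list[str]
    design: SampleDesign
    values: np.ndarray
    snr: np.ndarray | None = None
    snr_min: float = DEFAULT_SNR_MIN
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_genes, n_samples = len(self.genes), len(self.design)
        if self.values.shape != (n_genes, n_samples):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{n_genes} genes x {n_samples} samples"
            )
        dupes = {g for g in self.genes if self.genes.count(g) > 1} if len(set(self.genes)) != n_genes else set()
        if dupes:
            raise ValidationError(f"duplicate gene ids: {sorted(dupes)}")
        if self.snr is not None:
            self.snr = np.asarray(self.snr, dtype=float)
            if self.snr.shape != self.values.shape:
                raise ValidationError(
                    f"SNR shape {self.snr.shape} does not match matrix {self.values.shape}"
                )
            if np.nanmin(self.snr) < 0:
                raise ValidationError("SNR values must be nonnegative")
        if self.mask is None:
            self.mask = self._default_mask()
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValidationError("mask shape does not match matrix shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            bad = np.argwhere(self.mask & ~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at quantifiable cell "
                f"(gene {self.genes[bad[0]]!r}, sample {self.design.sample_ids[bad[1]]!r})"
            )

    def _default_mask(self) -> np.ndarray:
        if self.snr is not None:
            return self.snr >= self.snr_min
        return np.isfinite(self.values)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.design)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def with_snr_min(self, snr_min: float) -> "ExpressionMatrix":
        """Same data, recomputed mask at a different SNR cutoff."""
        return ExpressionMatrix(
            genes=list(self.genes),
            design=self.design,
            values=self.values.copy(),
            snr=None if self.snr is None else self.snr.copy(),
            snr_min=snr_min,
            mask=None,
        )


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    cog: str | None = None
    operon_id: str | None = None
    is_negative_control: bool = False

    def __post_init__(self) -> None:
        if self.cog is not None and (len(self.cog) != 1 or self.cog not in COG_LETTERS):
            raise ValidationError(
                f"COG category {self.cog!r} for {self.gene_id!r} is not a standard letter"
            )


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[], encoding="utf-8"
    )


def read_design(path: str | Path) -> SampleDesign:
    df = _read_tsv(path)
    required = {"sample_id", "substrate", "phase", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"design file {path} missing columns: {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        try:
            rep = int(row.replicate)
        except ValueError:
            raise ValidationError(
                f"non-integer replicate {row.replicate!r} for sample {row.sample_id!r}"
            ) from None
        samples.append(Sample(row.sample_id, row.substrate, row.phase, rep))
    return SampleDesign(tuple(samples))


def _parse_matrix(path: str | Path, what: str) -> tuple[list[str], list[str], np.ndarray]:
    df = _read_tsv(path)
    if df.columns[0] != "gene_id":
        raise ValidationError(
            f"{what} file {path}: first header cell must be 'gene_id', got {df.columns[0]!r}"
        )
    genes = df["gene_id"].tolist()
    dupes = df["gene_id"][df["gene_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"{what} file {path}: duplicate gene ids {dupes}")
    sample_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            if cell == "NA":
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{what} file {path}: non-numeric cell {cell!r} at "
                    f"gene {genes[i]!r}, sample {sample_ids[j]!r}"
                ) from None
    return genes, sample_ids, values


def read_expression(
    matrix_path: str | Path,
    design_path: str | Path,
    snr_path: str | Path | None = None,
    snr_min: float = DEFAULT_SNR_MIN,
) -> ExpressionMatrix:
    """Read an expression matrix, its design and an optional SNR table.

    Gene order follows the matrix file; sample order follows the design file
    (matrix columns are reordered to match).  The mask is ``snr >= snr_min``
    when an SNR table is given, otherwise all cells read as numbers are
    quantifiable and ``NA`` cells are masked.
    """
    genes, sample_ids, values = _parse_matrix(matrix_path, "matrix")
    design = read_design(design_path)
    if set(sample_ids) != set(design.sample_ids):
        only_matrix = sorted(set(sample_ids) - set(design.sample_ids))
        only_design = sorted(set(design.sample_ids) - set(sample_ids))
        raise ValidationError(
            f"matrix/design sample mismatch: only in matrix {only_matrix}, "
            f"only in design {only_design}"
        )
    order = [sample_ids.index(s) for s in design.sample_ids]
    values = values[:, order]
    snr = None
    if snr_path is not None:
        snr_genes, snr_samples, snr_vals = _parse_matrix(snr_path, "SNR")
        if snr_genes != genes:
            raise ValidationError("SNR table gene list differs from matrix gene list")
        if set(snr_samples) != set(sample_ids):
            raise ValidationError("SNR table sample set differs from matrix sample set")
        snr = snr_vals[:, [snr_samples.index(s) for s in design.sample_ids]]
    return ExpressionMatrix(genes=genes, design=design, values=values, snr=snr, snr_min=snr_min)


def _format_cell(v: float) -> str:
    return "NA" if not np.isfinite(v) else repr(float(v))


def write_matrix_tsv(
    genes: Sequence[str],
    sample_ids: Sequence[str],
    values: np.ndarray,
    path: str | Path,
    mask: np.ndarray | None = None,
) -> None:
    """Write any gene x sample table; masked cells become ``NA``."""
    values = np.asarray(values, dtype=float)
    buf = _io.StringIO()
    buf.write("gene_id\t" + "\t".join(sample_ids) + "\n")
    for i, g in enumerate(genes):
        row = [
            "NA" if (mask is not None and not mask[i, j]) else _format_cell(values[i, j])
            for j in range(values.shape[1])
        ]
        buf.write(g + "\t" + "\t".join(row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_expression(
    x: ExpressionMatrix,
    matrix_path: str | Path,
    snr_path: str | Path | None = None,
    design_path: str | Path | None = None,
) -> None:
    """Serialize an ExpressionMatrix; masked cells are written as ``NA``.

    Values survive a write/read round trip bit-equal (full ``repr``
    precision).  SNR and design files are written when paths are given.
    """
    if x.n_genes == 0:
        raise ValidationError("refusing to write an expression matrix with no genes")
    write_matrix_tsv(x.genes, x.design.sample_ids, x.values, matrix_path, mask=x.mask)
    if snr_path is not None:
        if x.snr is None:
            raise ValidationError("no SNR table to write")
        write_matrix_tsv(x.genes, x.design.sample_ids, x.snr, snr_path)
    if design_path is not None:
        write_design(x.design, design_path)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    df = _read_tsv(path)
    required = {"gene_id", "cog", "operon_id", "is_negative_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"annotation file {path} missing columns: {sorted(missing)}")
    out = []
    ids = set()
    for row in df.itertuples(index=False):
        if row.gene_id in ids:
            raise ValidationError(f"duplicate gene id in annotations: {row.gene_id!r}")
        ids.add(row.gene_id)
        out.append(
            GeneAnnotation(
                gene_id=row.gene_id,
                cog=None if row.cog in ("", "NA") else row.cog,
                operon_id=None if row.operon_id in ("", "NA") else row.operon_id,
                is_negative_control=row.is_negative_control in ("1", "True", "true"),
            )
        )
    return out


def write_annotations(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    anns = list(annotations)
    df = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in anns],
            "cog": [a.cog if a.cog is not None else "NA" for a in anns],
            "operon_id": [a.operon_id if a.operon_id is not None else "NA" for a in anns],
            "is_negative_control": [int(a.is_negative_control) for a in anns],
        }
    )
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
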