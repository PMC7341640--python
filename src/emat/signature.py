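"""Derivation of motility-program gene signatures from perturbation experiments.

The EMAT signature is the union of two component gene lists: an
epithelial-to-mesenchymal transition (EMT) list and a
mesenchymal-to-amoeboid transition (MAT) list.  Each component list is
derived from cell-perturbation experiments by a threshold-and-count rule:
a gene enters the list when its treated-vs-control expression ratio is at
least ``fold_threshold``-fold up or down in at least ``min_experiments``
independent experiments.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCES = ("EMT", "MAT", "both")
DIRECTIONS = ("up", "down", "mixed", "unknown")


@dataclass(frozen=True)
class SignatureEntry:
    """One gene in a signature with its provenance and regulation direction."""

    gene_id: str
    source: str = "EMT"
    direction: str = "unknown"

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"unknown direction {self.direction!r}; expected one of {DIRECTIONS}"
            )


@dataclass
class GeneSignature:
    """A named gene set with per-gene source and regulation direction."""

    entries: list[SignatureEntry] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [e.gene_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dups = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids in signature: {dups}")

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)

    def direction_of(self, gene_id: str) -> str:
        for e in self.entries:
            if e.gene_id == gene_id:
                return e.direction
        raise KeyError(gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [e.gene_id for e in self.entries],
                "source": [e.source for e in self.entries],
                "direction": [e.direction for e in self.entries],
            }
        )


@dataclass
class FoldChangeTable:
    """Genes x experiments table of treated-vs-control expression ratios.

    Ratios are on the linear scale and must be strictly positive; a ratio
    of 1 means no change relative to control.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError(
                f"duplicate gene ids: {sorted(v.index[v.index.duplicated()].unique())}"
            )
        if v.columns.has_duplicates:
            raise ValueError(
                f"duplicate experiment ids: "
                f"{sorted(v.columns[v.columns.duplicated()].unique())}"
            )
        bad = ~(v.to_numpy() > 0) | ~np.isfinite(v.to_numpy())
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "fold-change ratios must be finite and strictly positive; "
                f"offending entry gene={v.index[i]!r} experiment={v.columns[j]!r} "
                f"value={v.iat[i, j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def experiment_ids(self) -> list[str]:
        return list(self.values.columns)


def derive_signature(
    folds: FoldChangeTable,
    fold_threshold: float = 1.5,
    min_experiments: int = 2,
    source: str = "MAT",
    name: str = "",
) -> GeneSignature:
    """Apply the threshold-and-count rule to a fold-change table.

    A gene qualifies in an experiment when its ratio is >= ``fold_threshold``
    (up) or <= ``1/fold_threshold`` (down), both inclusive.  Genes with at
    least ``min_experiments`` qualifying experiments (up and down calls
    pooled) enter the signature.  Direction is ``up`` if every qualifying
    call is up, ``down`` if every call is down, and ``mixed`` otherwise.
    """
    if folds.values.empty:
        raise ValueError("fold-change table is empty")
    if fold_threshold < 1:
        raise ValueError(f"fold_threshold must be >= 1, got {fold_threshold}")
    n_exp = folds.values.shape[1]
    if not 1 <= min_experiments <= n_exp:
        raise ValueError(
            f"min_experiments must be in [1, {n_exp}], got {min_experiments}"
        )

    v = folds.values.to_numpy(dtype=float)
    up = v >= fold_threshold
    down = v <= 1.0 / fold_threshold
    n_calls = (up | down).sum(axis=1)
    keep = n_calls >= min_experiments

    entries = []
    for i in np.flatnonzero(keep):
        has_up = up[i].any()
        has_down = down[i].any()
        direction = "up" if not has_down else ("down" if not has_up else "mixed")
        entries.append(
            SignatureEntry(folds.values.index[i], source=source, direction=direction)
        )
    logger.info(
        "derived signature %s: %d/%d genes at fold>=%.3g in >=%d experiments",
        name or "<unnamed>", len(entries), len(folds.values), fold_threshold,
        min_experiments,
    )
    return GeneSignature(entries, name=name)


def combine_signatures(a: GeneSignature, b: GeneSignature, name: str = "") -> GeneSignature:
    """Union of two signatures; genes present in both are labelled ``both``.

    When the two inputs disagree on a shared gene's direction it becomes
    ``mixed``.  The result keeps the order of ``a`` followed by genes unique
    to ``b``.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both signatures must be non-empty")
    b_by_id = {e.gene_id: e for e in b.entries}
    a_ids = set(a.gene_ids)
    entries: list[SignatureEntry] = []
    for e in a.entries:
        if e.gene_id in b_by_id:
            other = b_by_id[e.gene_id]
            direction = e.direction if e.direction == other.direction else "mixed"
            entries.append(SignatureEntry(e.gene_id, source="both", direction=direction))
        else:
            entries.append(e)
    entries.extend(e for e in b.entries if e.gene_id not in a_ids)
    return GeneSignature(entries, name=name)


def fold_changes_from_groups(
    treated: pd.DataFrame, control: pd.DataFrame
) -> FoldChangeTable:
    """Compute per-experiment ratio tables from paired group-mean matrices.

    Both inputs are genes x experiments matrices of linear-scale group mean
    expression; the ratio is treated / control, elementwise.
    """
    if not treated.index.equals(control.index) or not treated.columns.equals(
        control.columns
    ):
        raise ValueError("treated and control matrices must share genes and experiments")
    return FoldChangeTable(treated / control)


# ---------------------------------------------------------------------------
# gene-list I/O and packaged component lists


def read_gene_list(path: str | Path, source: str = "EMT", name: str = "") -> GeneSignature:
    """Read a two-column (gene_id, direction) TSV; a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] == 1:
        df[1] = "unknown"
    if str(df.iat[0, 0]).lower() in {"gene_id", "gene", "symbol"}:
        df = df.iloc[1:]
    entries = [
        SignatureEntry(str(g), source=source, direction=str(d))
        for g, d in zip(df.iloc[:, 0], df.iloc[:, 1])
    ]
    return GeneSignature(entries, name=name or Path(path).stem)


def write_gene_list(sig: GeneSignature, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdirection\n")
        for e in sig.entries:
            fh.write(f"{e.gene_id}\t{e.direction}\n")


def _data_path(filename: str):
    return importlib.resources.files("emat.data").joinpath(filename)


def load_emt_signature() -> GeneSignature:
    """Packaged synthetic stand-in for the 253-gene EMT component list."""
    with importlib.resources.as_file(_data_path("emt_genes_synthetic.tsv")) as p:
        return read_gene_list(p, source="EMT", name="EMT")


def load_mat_signature() -> GeneSignature:
    """Packaged synthetic stand-in for the 138-gene MAT component list."""
    with importlib.resources.as_file(_data_path("mat_genes_synthetic.tsv")) as p:
        return read_gene_list(p, source="MAT", name="MAT")


def load_emat_signature() -> GeneSignature:
    """The combined EMAT signature (union of the packaged EMT and MAT lists)."""
    return combine_signatures(load_emt_signature(), load_mat_signature(), name="EMAT")


def load_tf_list() -> list[str]:
    """Packaged synthetic stand-in transcription-factor symbol list."""
    with importlib.resources.as_file(_data_path("tf_list_synthetic.txt")) as p:
        return [line.strip() for line in Path(p).read_text().splitlines() if line.strip()]
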