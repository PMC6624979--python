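"""Screen representation: construct annotations, count matrices and log-fold changes.

A combinatorial CRISPR screen is a library of *constructs*, each expressing two
guides targeting two genes (possibly the same gene, possibly a negative
control).  The library is sequenced at an early reference time point (typically
the plasmid pool) and at one or more late time points per sample, usually with
replicates.  This module parses the three input tables (counts, construct
annotation, sample sheet), validates them into a :class:`ScreenDesign` +
:class:`CountMatrix`, and computes per-replicate log2 fold changes
(:class:`LFCTensor`), the observation the downstream model works on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScreenError",
    "ReplicateBinding",
    "SampleLayout",
    "ScreenDesign",
    "CountMatrix",
    "LFCTensor",
    "pair_key",
    "load_screen",
    "compute_lfc",
    "accept_external_lfc",
]

ANNOTATION_COLUMNS = ["construct_id", "guide_i", "guide_j", "gene_g", "gene_h"]


class ScreenError(ValueError):
    """Raised for malformed or inconsistent screen inputs."""


def pair_key(gene_g: str, gene_h: str) -> tuple[str, str]:
    """Canonical, orientation-free key for a gene pair: (g, h) == (h, g)."""
    return (gene_g, gene_h) if gene_g <= gene_h else (gene_h, gene_g)


@dataclass(frozen=True)
class ReplicateBinding:
    """Binds one replicate of one sample to a late count column (and its early reference)."""

    replicate_id: str
    late_column: str
    early_columns: tuple[str, ...]


@dataclass(frozen=True)
class SampleLayout:
    sample_id: str
    replicates: tuple[ReplicateBinding, ...]

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


@dataclass(frozen=True)
class ScreenDesign:
    """Validated construct annotation and sample/replicate layout.

    ``constructs`` is indexed by ``construct_id`` with columns
    ``guide_i, guide_j, gene_g, gene_h, same_gene``.  Gene-pair identity is
    orientation-free; construct orientation is retained in the table but all
    pair-level grouping goes through :meth:`pair_keys`.
    """

    constructs: pd.DataFrame
    samples: tuple[SampleLayout, ...]
    negative_control_genes: frozenset[str] = frozenset()
    nonint_pairs: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS[1:] if c not in self.constructs.columns]
        if missing:
            raise ScreenError(f"construct table missing columns: {missing}")
        if self.constructs.index.duplicated().any():
            dups = self.constructs.index[self.constructs.index.duplicated()].unique().tolist()
            raise ScreenError(f"duplicate construct IDs: {dups}")
        same_guide = self.constructs["guide_i"] == self.constructs["guide_j"]
        if same_guide.any():
            bad = self.constructs.index[same_guide].tolist()
            raise ScreenError(f"constructs pairing a guide with itself are not supported: {bad}")
        if "same_gene" not in self.constructs.columns:
            object.__setattr__(
                self,
                "constructs",
                self.constructs.assign(
                    same_gene=self.constructs["gene_g"] == self.constructs["gene_h"]
                ),
            )
        for s in self.samples:
            if s.n_replicates < 1:
                raise ScreenError(f"sample {s.sample_id!r} has no replicates")
            for rep in s.replicates:
                if not rep.early_columns:
                    raise ScreenError(
                        f"sample {s.sample_id!r} replicate {rep.replicate_id!r} "
                        "has no early reference column"
                    )

    @property
    def construct_ids(self) -> pd.Index:
        return self.constructs.index

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.constructs["gene_g"]) | set(self.constructs["gene_h"]))

    @property
    def guides(self) -> list[str]:
        return sorted(set(self.constructs["guide_i"]) | set(self.constructs["guide_j"]))

    def pair_keys(self) -> pd.Series:
        """Canonical gene-pair key per construct (aligned with ``constructs``)."""
        return pd.Series(
            [pair_key(g, h) for g, h in zip(self.constructs["gene_g"], self.constructs["gene_h"])],
            index=self.constructs.index,
            name="pair",
        )

    def is_control_pair(self, g: str, h: str) -> bool:
        return g in self.negative_control_genes or h in self.negative_control_genes


@dataclass(frozen=True)
class CountMatrix:
    """Raw construct read counts, constructs x sequencing columns."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values
        if (vals.to_numpy() < 0).any():
            raise ScreenError("count matrix contains negative entries")
        zero_cols = vals.columns[vals.sum(axis=0) == 0].tolist()
        if zero_cols:
            raise ScreenError(f"count columns with zero total reads: {zero_cols}")


@dataclass
class LFCTensor:
    """Observed log2 fold changes.

    ``D`` (constructs x samples) is the replicate-mean LFC — the model's
    observation.  ``D_rep`` keeps the per-replicate values (NaN-padded to the
    widest sample) and ``rep_var`` the unbiased across-replicate variance,
    NaN where a sample has fewer than two replicates.
    """

    D: pd.DataFrame
    D_rep: np.ndarray  # (n_constructs, n_samples, max_replicates), NaN padded
    rep_var: pd.DataFrame

    def __post_init__(self) -> None:
        means = np.nanmean(self.D_rep, axis=2)
        if not np.allclose(means, self.D.to_numpy(), atol=1e-8, equal_nan=True):
            raise ScreenError("D is not the replicate mean of D_rep")
        rv = self.rep_var.to_numpy()
        if np.nanmin(rv, initial=0.0) < 0:
            raise ScreenError("negative replicate variance")

    @property
    def construct_ids(self) -> pd.Index:
        return self.D.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.D.columns)

    def n_replicates(self) -> np.ndarray:
        """Replicate count per (construct, sample)."""
        return np.sum(~np.isnan(self.D_rep), axis=2)

    def to_tsv(self, path: str | Path) -> None:
        """Write replicate-level LFCs wide, columns named ``<sample>.<replicate index>``."""
        cols: dict[str, np.ndarray] = {}
        for li, sample in enumerate(self.sample_ids):
            for r in range(self.D_rep.shape[2]):
                col = self.D_rep[:, li, r]
                if np.isnan(col).all():
                    continue
                cols[f"{sample}.{r + 1}"] = col
        out = pd.DataFrame(cols, index=self.construct_ids)
        out.index.name = "construct_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ScreenError(f"input file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def _parse_sample_sheet(path: str | Path) -> list[dict]:
    """Return records with keys column, sample, replicate, timepoint."""
    path = Path(path)
    if not path.exists():
        raise ScreenError(f"sample sheet not found: {path}")
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        records = doc["columns"] if isinstance(doc, dict) else doc
    else:
        records = _read_table(path).to_dict("records")
    required = {"column", "sample", "replicate", "timepoint"}
    for rec in records:
        missing = required - set(rec)
        if missing:
            raise ScreenError(f"sample sheet record {rec!r} missing keys {sorted(missing)}")
        if rec["timepoint"] not in ("early", "late"):
            raise ScreenError(
                f"sample sheet timepoint must be 'early' or 'late', got {rec['timepoint']!r}"
            )
    return records


def _build_samples(records: Sequence[Mapping], count_columns: Iterable[str]) -> tuple[SampleLayout, ...]:
    count_columns = set(count_columns)
    for rec in records:
        if rec["column"] not in count_columns:
            raise ScreenError(f"sample sheet column {rec['column']!r} not present in counts")

    by_sample: dict[str, list[Mapping]] = {}
    shared_early: list[str] = []
    for rec in records:
        sample = str(rec["sample"])
        if rec["timepoint"] == "early" and sample in ("", "*", "shared", "None", "nan"):
            shared_early.append(rec["column"])
        else:
            by_sample.setdefault(sample, []).append(rec)

    # An early-only "sample" (e.g. the plasmid pool, sample=pDNA) is a shared
    # reference for every sample that declares no early column of its own.
    for s in [s for s, recs in by_sample.items() if all(r["timepoint"] == "early" for r in recs)]:
        shared_early.extend(r["column"] for r in by_sample.pop(s))

    layouts = []
    for sample in sorted(by_sample):
        recs = by_sample[sample]
        early_by_rep = {
            str(r["replicate"]): r["column"] for r in recs if r["timepoint"] == "early"
        }
        late = [r for r in recs if r["timepoint"] == "late"]
        if not late:
            raise ScreenError(f"sample {sample!r} has no late timepoint column")
        reps = []
        for r in sorted(late, key=lambda r: str(r["replicate"])):
            rep_id = str(r["replicate"])
            if rep_id in early_by_rep:
                early = (early_by_rep[rep_id],)
            elif early_by_rep:  # per-sample early shared across its replicates
                early = tuple(early_by_rep.values())
            elif shared_early:
                early = tuple(shared_early)
            else:
                raise ScreenError(
                    f"sample {sample!r} has no early reference (none shared, none per-sample)"
                )
            reps.append(ReplicateBinding(rep_id, r["column"], early))
        layouts.append(SampleLayout(sample, tuple(reps)))
    if not layouts:
        raise ScreenError("sample sheet defines no samples with late timepoints")
    return tuple(layouts)


def load_screen(
    counts_path: str | Path,
    annotation_path: str | Path,
    sample_sheet_path: str | Path,
    negative_control_genes: Iterable[str] = (),
    nonint_pairs: Iterable[tuple[str, str]] = (),
) -> tuple[ScreenDesign, CountMatrix]:
    """Parse and cross-validate counts, construct annotation and sample sheet.

    Every construct row in the counts table must be covered by the annotation;
    unannotated constructs are an error, never silently dropped.
    """
    counts_df = _read_table(counts_path)
    ann = _read_table(annotation_path)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise ScreenError(f"annotation missing columns: {missing_cols}")
    if "construct_id" not in counts_df.columns:
        raise ScreenError("counts table must have a construct_id first column")

    ann = ann.set_index("construct_id")
    counts_df = counts_df.set_index("construct_id")
    unannotated = counts_df.index.difference(ann.index)
    if len(unannotated):
        raise ScreenError(
            f"constructs present in counts but missing from annotation: {unannotated.tolist()}"
        )
    ann = ann.loc[counts_df.index]

    records = _parse_sample_sheet(sample_sheet_path)
    samples = _build_samples(records, counts_df.columns)

    design = ScreenDesign(
        constructs=ann,
        samples=samples,
        negative_control_genes=frozenset(negative_control_genes),
        nonint_pairs=frozenset(pair_key(*p) for p in nonint_pairs),
    )
    counts = CountMatrix(values=counts_df.astype(np.int64, errors="ignore"))
    return design, counts


# ---------------------------------------------------------------------------
# log-fold change
# ---------------------------------------------------------------------------

def _log2_frequency(col: np.ndarray, pseudocount: float) -> np.ndarray:
    shifted = col.astype(float) + pseudocount
    total = shifted.sum()
    if total <= 0:
        raise ScreenError("zero total counts in a column (after pseudocount)")
    return np.log2(shifted / total)


def compute_lfc(
    counts: CountMatrix, design: ScreenDesign, pseudocount: float = 1.0
) -> LFCTensor:
    """Per-replicate log2 fold change of construct frequency, late vs early.

    For replicate r of sample l:
    ``D_rep = log2((late + pc) / sum(late + pc)) - log2((early + pc) / sum(early + pc))``
    where a replicate's early reference is the sum of its bound early columns.
    ``D`` is the replicate mean and ``rep_var`` the unbiased replicate variance.
    """
    vals = counts.values.loc[design.construct_ids]
    n_constructs = len(vals)
    max_reps = max(s.n_replicates for s in design.samples)
    D_rep = np.full((n_constructs, len(design.samples), max_reps), np.nan)

    for li, sample in enumerate(design.samples):
        for ri, rep in enumerate(sample.replicates):
            early_counts = vals[list(rep.early_columns)].sum(axis=1).to_numpy()
            late_counts = vals[rep.late_column].to_numpy()
            D_rep[:, li, ri] = _log2_frequency(late_counts, pseudocount) - _log2_frequency(
                early_counts, pseudocount
            )

    return _tensor_from_reps(D_rep, design)


def _tensor_from_reps(D_rep: np.ndarray, design: ScreenDesign) -> LFCTensor:
    sample_ids = design.sample_ids
    D = pd.DataFrame(
        np.nanmean(D_rep, axis=2), index=design.construct_ids, columns=sample_ids
    )
    n_rep = np.sum(~np.isnan(D_rep), axis=2)
    with np.errstate(invalid="ignore"):
        var = np.nanvar(D_rep, axis=2, ddof=1)
    var = np.where(n_rep >= 2, var, np.nan)  # undefined below 2 replicates
    rep_var = pd.DataFrame(var, index=design.construct_ids, columns=sample_ids)
    return LFCTensor(D=D, D_rep=D_rep, rep_var=rep_var)


def accept_external_lfc(lfc_path: str | Path, design: ScreenDesign) -> LFCTensor:
    """Read a pre-computed LFC table (e.g. copy-number corrected), bypassing counts.

    The table is wide with a ``construct_id`` column.  Remaining columns are
    either sample IDs (replicate-mean LFCs; replicate variance unavailable) or
    ``<sample>.<replicate>`` replicate-level columns, from which the mean and
    variance are recomputed.
    """
    table = _read_table(lfc_path)
    if "construct_id" not in table.columns:
        raise ScreenError("external LFC table must have a construct_id column")
    table = table.set_index("construct_id")

    missing = design.construct_ids.difference(table.index)
    if len(missing):
        raise ScreenError(f"external LFC table missing constructs: {missing.tolist()}")
    table = table.loc[design.construct_ids]

    sample_ids = design.sample_ids
    if set(table.columns) == set(sample_ids):
        D_rep = table[sample_ids].to_numpy()[:, :, None]
        return _tensor_from_reps(D_rep, design)

    by_sample: dict[str, list[str]] = {s: [] for s in sample_ids}
    unmatched = []
    for col in table.columns:
        sample, _, rep = col.rpartition(".")
        if sample in by_sample and rep:
            by_sample[sample].append(col)
        else:
            unmatched.append(col)
    if unmatched:
        raise ScreenError(
            f"external LFC columns do not match design samples: {unmatched}"
        )
    empty = [s for s, cols in by_sample.items() if not cols]
    if empty:
        raise ScreenError(f"external LFC table missing samples: {empty}")

    max_reps = max(len(cols) for cols in by_sample.values())
    D_rep = np.full((len(table), len(sample_ids), max_reps), np.nan)
    for li, s in enumerate(sample_ids):
        for ri, col in enumerate(sorted(by_sample[s])):
            D_rep[:, li, ri] = table[col].to_numpy(dtype=float)
    return _tensor_from_reps(D_rep, design)
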