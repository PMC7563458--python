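"""Cross-sample aggregation: the presence/absence TIP matrix and summaries.

The matrix has one row per sample and one column per TIP window (the sorted
union of windows called in any sample); entries are 1 when that sample has a
call at that window. Each sample carries a binary condition label
(1 = case, 0 = control).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import LabelingError, ParseError, ValidationError
from .io_formats import BedRecord, natural_key

Window = tuple[str, int, int]


def window_key_str(window: Window) -> str:
    return f"{window[0]}:{window[1]}-{window[2]}"


def parse_window_key(key: str) -> Window:
    try:
        chrom, span = key.rsplit(":", 1)
        start, end = span.split("-")
        return (chrom, int(start), int(end))
    except ValueError as exc:
        raise ParseError(f"malformed window key {key!r}") from exc


@dataclass
class TipMatrix:
    """Samples x TIP-windows binary presence/absence matrix with labels."""

    samples: list[str]
    windows: list[Window]
    data: np.ndarray  # shape (n, m), entries in {0, 1}
    labels: dict[str, int]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.samples), len(self.windows)):
            raise ValidationError(
                f"matrix shape {self.data.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.windows)} windows"
            )
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            raise ValidationError("matrix entries must be 0 or 1")
        missing = [s for s in self.samples if s not in self.labels]
        if missing:
            raise LabelingError(f"samples without a condition label: {missing}")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def m(self) -> int:
        return len(self.windows)

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[s] for s in self.samples], dtype=np.int8)

    def column(self, window: Window) -> np.ndarray:
        try:
            j = self.windows.index(window)
        except ValueError:
            raise LookupError(f"window {window} not in matrix") from None
        return self.data[:, j]

    def row_totals(self) -> np.ndarray:
        return self.data.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.data,
            index=pd.Index(self.samples, name="sample_id"),
            columns=[window_key_str(w) for w in self.windows],
        )
        frame.insert(0, "label", self.label_array())
        return frame

    def to_tsv(self, dest: Union[str, Path, IO[str]]) -> None:
        self.to_frame().to_csv(dest, sep="\t")

    @classmethod
    def from_tsv(cls, source: Union[str, Path, IO[str]]) -> "TipMatrix":
        frame = pd.read_csv(source, sep="\t", index_col=0)
        if "label" not in frame.columns:
            raise ParseError("matrix TSV missing the 'label' column")
        labels = {str(s): int(v) for s, v in frame["label"].items()}
        windows = [parse_window_key(c) for c in frame.columns if c != "label"]
        data = frame.drop(columns="label").to_numpy(dtype=np.int8)
        return cls(
            samples=[str(s) for s in frame.index],
            windows=windows,
            data=data,
            labels=labels,
        )


def build_matrix(
    per_sample_beds: Mapping[str, Sequence[BedRecord]],
    labels: Mapping[str, int],
) -> TipMatrix:
    """Build the presence/absence matrix from per-sample BED calls.

    The window axis is the sorted union of windows called in any sample;
    samples are ordered canonically, so input ordering never changes the
    result. A sample calling the same window twice is a validation error.
    """
    for sample in per_sample_beds:
        if sample not in labels:
            raise LabelingError(f"sample {sample!r} has no condition label")
        if labels[sample] not in (0, 1):
            raise LabelingError(f"sample {sample!r} label must be 0 or 1")

    window_set: set[Window] = set()
    per_sample_windows: dict[str, set[Window]] = {}
    for sample, records in per_sample_beds.items():
        seen: set[Window] = set()
        for rec in records:
            key: Window = (rec.chrom, rec.start, rec.end)
            if key in seen:
                raise ValidationError(
                    f"sample {sample!r} calls window {window_key_str(key)} twice"
                )
            seen.add(key)
        per_sample_windows[sample] = seen
        window_set |= seen

    windows = sorted(window_set, key=lambda w: (natural_key(w[0]), w[1], w[2]))
    samples = sorted(per_sample_beds, key=natural_key)
    col_of = {w: j for j, w in enumerate(windows)}
    data = np.zeros((len(samples), len(windows)), dtype=np.int8)
    for i, sample in enumerate(samples):
        for w in per_sample_windows[sample]:
            data[i, col_of[w]] = 1
    return TipMatrix(
        samples=samples,
        windows=windows,
        data=data,
        labels={s: int(labels[s]) for s in samples},
    )


def tip_count_histogram(matrix: TipMatrix, bin_width: int = 500) -> pd.DataFrame:
    """Bin per-sample TIP totals (row sums) per label group.

    Bins are [0, w), [w, 2w), ...; the index holds bin starts and the
    ``case``/``control`` columns hold sample counts per bin. Column sums
    equal group sizes.
    """
    if bin_width < 1:
        raise ValidationError(f"bin_width must be >= 1, got {bin_width}")
    totals = matrix.row_totals()
    labels = matrix.label_array()
    n_bins = int(totals.max() // bin_width) + 1 if matrix.n else 1
    starts = np.arange(n_bins) * bin_width
    out = pd.DataFrame(0, index=pd.Index(starts, name="bin_start"), columns=["control", "case"])
    for total, label in zip(totals, labels):
        out.iloc[int(total // bin_width), label] = out.iloc[int(total // bin_width), label] + 1
    return out


def peak_profile(
    matrix: TipMatrix,
    chrom: str,
    bin_windows: int = 300,
    window_size: int | None = None,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Pool TIP presence along one chromosome into runs of ``bin_windows``.

    Bins are anchored to the genome window grid (window indices 0, 300, ...),
    not to the observed data, so case and control profiles are directly
    comparable. The value for a bin and group is the sum of matrix entries
    over the bin's window columns and the group's sample rows. The index
    holds the genomic start of each bin.
    """
    if bin_windows < 1:
        raise ValidationError(f"bin_windows must be >= 1, got {bin_windows}")
    cols = [(j, w) for j, w in enumerate(matrix.windows) if w[0] == chrom]
    if not cols and chrom_length is None:
        raise LookupError(f"chromosome {chrom!r} has no windows in the matrix")
    if window_size is None:
        if not cols:
            raise ValidationError("window_size required when chrom has no columns")
        window_size = max(w[2] - w[1] for _, w in cols)
    if chrom_length is not None:
        n_windows = -(-chrom_length // window_size)
    else:
        n_windows = max(w[1] // window_size for _, w in cols) + 1
    n_bins = -(-n_windows // bin_windows)

    labels = matrix.label_array()
    values = np.zeros((n_bins, 2), dtype=np.int64)
    for j, w in cols:
        b = (w[1] // window_size) // bin_windows
        col = matrix.data[:, j]
        values[b, 0] += int(col[labels == 0].sum())
        values[b, 1] += int(col[labels == 1].sum())
    starts = np.arange(n_bins) * bin_windows * window_size
    return pd.DataFrame(
        values,
        index=pd.Index(starts, name="bin_start"),
        columns=["control", "case"],
    )
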