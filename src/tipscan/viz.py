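"""Figure rendering for cohort summaries.

Three chart types: per-group TIP-count histograms, per-chromosome peak
profiles, and the per-chromosome associated-TIP bar chart. All numbers are
computed upstream (:mod:`tipscan.cohort`, :mod:`tipscan.assoc`) and consumed
verbatim; every plot also dumps its input table as a sibling TSV so the
rendered values stay testable headlessly.

Convention: cases blue, controls red.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_COLORS = {"case": "tab:blue", "control": "tab:red"}


def _dump_tsv(frame: pd.DataFrame, output_path: str | Path) -> None:
    frame.to_csv(Path(output_path).with_suffix(".tsv"), sep="\t")


def plot_histogram(
    binned: pd.DataFrame,
    output_path: str | Path,
    log2_counts: bool = False,
) -> Path:
    """Bar chart of binned per-sample TIP totals, one series per group.

    ``binned`` is the frame from :func:`tipscan.cohort.tip_count_histogram`
    (index = bin start, columns control/case). ``log2_counts`` puts the
    sample-count axis on a log2 scale.
    """
    output_path = Path(output_path)
    if binned.to_numpy().sum() == 0:
        logger.warning("histogram input has no samples in any bin; rendering empty axes")
    fig, ax = plt.subplots(figsize=(8, 4))
    width = (binned.index[1] - binned.index[0]) * 0.4 if len(binned) > 1 else 0.4 * max(
        binned.index.max(), 1
    )
    for i, group in enumerate(c for c in ("control", "case") if c in binned.columns):
        ax.bar(
            binned.index + i * width,
            binned[group],
            width=width,
            align="edge",
            label=group,
            color=GROUP_COLORS[group],
        )
    if log2_counts:
        ax.set_yscale("log", base=2)
    ax.set_xlabel("TIPs per sample (bin start)")
    ax.set_ylabel("number of samples")
    ax.legend()
    fig.tight_layout()
    fig.savefig(output_path)
    plt.close(fig)
    _dump_tsv(binned, output_path)
    return output_path


def plot_peaks(profile: pd.DataFrame, output_path: str | Path, chrom: str = "") -> Path:
    """Line chart of TIP frequency along a chromosome, one line per group.

    ``profile`` is the frame from :func:`tipscan.cohort.peak_profile`
    (index = genomic bin start, columns control/case).
    """
    output_path = Path(output_path)
    fig, ax = plt.subplots(figsize=(8, 4))
    for group in (c for c in ("control", "case") if c in profile.columns):
        ax.plot(profile.index, profile[group], label=group, color=GROUP_COLORS[group])
    ax.set_xlabel(f"position along {chrom}" if chrom else "genomic bin start")
    ax.set_ylabel("TIP frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(output_path)
    plt.close(fig)
    _dump_tsv(profile, output_path)
    return output_path


def plot_association(counts: Mapping[str, int], output_path: str | Path) -> Path:
    """Bar chart of significant-TIP counts per chromosome (natural order).

    ``counts`` is the mapping from :func:`tipscan.assoc.per_chromosome_counts`;
    insertion order is preserved (it is already naturally sorted).
    """
    output_path = Path(output_path)
    chroms = list(counts)
    values = [counts[c] for c in chroms]
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(chroms)), 4))
    ax.bar(np.arange(len(chroms)), values, color="tab:blue")
    ax.set_xticks(np.arange(len(chroms)))
    ax.set_xticklabels(chroms, rotation=45, ha="right")
    ax.set_xlabel("chromosome")
    ax.set_ylabel("associated TIPs")
    fig.tight_layout()
    fig.savefig(output_path)
    plt.close(fig)
    _dump_tsv(pd.DataFrame({"chrom": chroms, "significant": values}).set_index("chrom"), output_path)
    return output_path
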