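"""Taxon-annotated GC-coverage scatter plots ("blob plots").

Each contig of a mixed-sample assembly is one point, placed by its GC fraction
(x) and mean read depth (y, log scale) and coloured by its best-hit taxon.
Distinct genomes in the sample show up as distinct blobs, letting the analyst
choose separation filters. To reduce clutter, only taxa annotating at least a
fraction (default 10%) of the hit-bearing contigs get their own colour; the
rest collapse to "other". Contigs outside the annotated subsample are
"not-annotated" and contigs whose hits all failed the filter are "no-hit".
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .errors import ConsistencyError
from .taxonomy_annotation import NO_HIT

__all__ = ["NOT_ANNOTATED", "OTHER", "build_blob_table", "render_blob_plot"]

NOT_ANNOTATED = "not-annotated"
OTHER = "other"

_MUTED = {NO_HIT: "#bbbbbb", OTHER: "#888888", NOT_ANNOTATED: "#e0e0e0"}
# colour-blind-safe palette (Okabe-Ito), assigned to displayed taxa in sorted order
_PALETTE = ["#E69F00", "#56B4E9", "#009E73", "#D55E00",
            "#CC79A7", "#0072B2", "#F0E442", "#000000"]


def build_blob_table(
    stats: pd.DataFrame,
    annotations: pd.DataFrame,
    display_fraction: float = 0.10,
) -> pd.DataFrame:
    """Join per-contig stats with annotations and apply the display rule.

    *stats* needs columns ``contig_id``, ``gc_fraction``, ``mean_depth``,
    ``length``; *annotations* needs ``contig_id``, ``taxon_label``. A taxon is
    displayed iff it annotates at least ``display_fraction`` of the contigs
    carrying a real (non-``no-hit``) annotation — the inclusive "at least"
    reading. Returns one row per stats contig with a ``displayed_taxon``
    column.
    """
    unknown = set(annotations["contig_id"]) - set(stats["contig_id"])
    if unknown:
        raise ConsistencyError(
            f"annotations reference contigs absent from stats: {sorted(unknown)[:5]}"
        )
    table = stats.merge(
        annotations[["contig_id", "taxon_label"]], on="contig_id", how="left"
    )
    table["taxon_label"] = table["taxon_label"].fillna(NOT_ANNOTATED)

    real = table.loc[~table["taxon_label"].isin([NO_HIT, NOT_ANNOTATED]), "taxon_label"]
    counts = real.value_counts()
    threshold = display_fraction * len(real)
    displayed = set(counts[counts >= threshold].index)

    def _display(label: str) -> str:
        if label in (NO_HIT, NOT_ANNOTATED):
            return label
        return label if label in displayed else OTHER

    table["displayed_taxon"] = table["taxon_label"].map(_display)
    return table


def render_blob_plot(
    table: pd.DataFrame,
    out,
    *,
    log_coverage: bool = True,
    cov_floor: float = 0.01,
    scale_by_length: bool = False,
    title: str = "GC-coverage plot",
) -> Path:
    """Render a blob table to an image and write the companion TSV.

    Zero-depth contigs are plotted at ``cov_floor`` so they stay visible on
    the log axis. The companion TSV (same path, ``.tsv`` suffix) is exactly
    the plotted table, so any plot can be regenerated from it. Returns the
    companion TSV path.
    """
    if table.empty:
        raise ValueError("cannot render an empty blob table")
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)

    plotted = table.copy()
    plotted["plot_depth"] = plotted["mean_depth"].clip(lower=cov_floor)

    muted_order = [NOT_ANNOTATED, NO_HIT, OTHER]
    taxa = sorted(t for t in plotted["displayed_taxon"].unique() if t not in _MUTED)
    colours = {t: _PALETTE[i % len(_PALETTE)] for i, t in enumerate(taxa)}
    colours.update(_MUTED)

    fig, ax = plt.subplots(figsize=(7, 5.5))
    for taxon in muted_order + taxa:
        sub = plotted[plotted["displayed_taxon"] == taxon]
        if sub.empty:
            continue
        size = sub["length"] / 200.0 if scale_by_length else 12
        ax.scatter(
            sub["gc_fraction"], sub["plot_depth"],
            s=size, c=colours[taxon], alpha=0.6, linewidths=0,
            label=f"{taxon} ({len(sub)})",
        )
    if log_coverage:
        ax.set_yscale("log")
    ax.set_xlim(0, 1)
    ax.set_xlabel("GC fraction")
    ax.set_ylabel("mean read depth")
    ax.set_title(title)
    ax.legend(fontsize=8, markerscale=1.5, loc="best")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)

    companion = out.with_suffix(".tsv")
    plotted.drop(columns=["plot_depth"]).to_csv(companion, sep="\t", index=False)
    return companion
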