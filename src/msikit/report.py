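"""Publication-style outputs: frequency tables and trace overlays."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .msi import Electropherogram

FOOTNOTE = "-1: deletion of one nucleotide in MNR region."


def render_frequency_table(
    frequency_table: pd.DataFrame,
    group_order: Sequence[str] | None = None,
    group_sizes: Mapping[str, int] | None = None,
) -> str:
    """Format a mutation-frequency table as rows of ``Gene(offset)`` against
    group columns with percentages to one decimal, footnoted for the -1
    mononucleotide-repeat deletions."""
    if frequency_table.empty:
        raise ValueError("frequency table is empty")
    df = frequency_table.copy()
    df["row"] = [
        f"{r.locus_id}({r.offset:+d})".replace("+", "") if r.offset < 0
        else f"{r.locus_id}(+{r.offset})"
        for r in df.itertuples(index=False)
    ]
    df["pct"] = [f"{100 * f:.1f}%" for f in df["frequency"]]
    pivot = df.pivot_table(index="row", columns="group", values="pct",
                           aggfunc="first", sort=False)
    groups = [g for g in (group_order or pivot.columns) if g in pivot.columns]
    pivot = pivot[groups]

    def header(g: str) -> str:
        n = (group_sizes or {}).get(g)
        return f"{g} (n = {n})" if n else str(g)

    widths = [max(len("Gene"), *(len(i) for i in pivot.index))] + [
        max(len(header(g)), 8) for g in groups
    ]
    lines = [
        "\t".join(["Gene".ljust(widths[0])] + [header(g).ljust(w)
                                               for g, w in zip(groups, widths[1:])])
    ]
    for row_name, row in pivot.iterrows():
        cells = [str(row_name).ljust(widths[0])]
        cells += [str(row[g] if pd.notna(row[g]) else "-").ljust(w)
                  for g, w in zip(groups, widths[1:])]
        lines.append("\t".join(cells))
    lines.append("")
    lines.append(FOOTNOTE)
    return "\n".join(lines)


def plot_trace_overlay(sample_trace: Electropherogram,
                       control_trace: Electropherogram, ax=None):
    """Overlay a sample trace on its matched wild-type control, the usual
    way fragment-analysis software displays MSI marker shifts."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 2.5))
    ax.fill_between(control_trace.sizes_bp, control_trace.intensities,
                    alpha=0.4, color="tab:pink", label="control")
    ax.plot(sample_trace.sizes_bp, sample_trace.intensities,
            color="tab:blue", label=sample_trace.sample_id or "sample")
    ax.set_xlabel("fragment size (bp)")
    ax.set_ylabel("intensity")
    ax.set_title(sample_trace.marker_id)
    ax.legend(frameon=False, fontsize=8)
    return ax
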