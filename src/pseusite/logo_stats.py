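"""Two-sample logo statistics: per-position nucleotide enrichment.

For each (position, nucleotide) cell, every sequence in the positive
and negative sets contributes a 0/1 indicator (does it carry that
nucleotide at that position?), and a two-sided two-sample t-test
compares the indicator means.  A nucleotide significantly more
frequent among Ψ-site fragments than among non-sites is *enriched*;
significantly less frequent, *depleted*.  This is the convention of
two-sample logo tools; the default is the pooled-variance Student test
with per-cell α = 0.05 and no multiple-testing correction, which is
deliberately liberal — one cell in twenty is expected to reach
significance under the null.

The central position always holds U in both sets, so its cells have
zero variance and yield no call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import FragmentDataset, UCenteredFragment

NUCLEOTIDES = ("A", "C", "G", "U")

LOGO_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728"}


@dataclass(frozen=True)
class PositionStat:
    """Test outcome for one (position, nucleotide) cell.

    ``position`` is the 0-based fragment-internal index; display
    formats add 1.  ``call`` is ``"enriched"`` when p < α with the
    positive frequency higher, ``"depleted"`` when lower, else
    ``"none"``.
    """

    position: int
    nucleotide: str
    freq_positive: float
    freq_negative: float
    t_statistic: float
    p_value: float
    call: str


def _residue_array(fragments: Sequence[UCenteredFragment]) -> np.ndarray:
    return np.array([list(f.residues) for f in fragments])


def two_sample_logo(
    positives: Union[FragmentDataset, Sequence[UCenteredFragment]],
    negatives: Union[FragmentDataset, Sequence[UCenteredFragment]],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> list[PositionStat]:
    """Per-position, per-nucleotide enrichment tests (positives vs negatives).

    ``equal_var=True`` gives the pooled-variance Student test; set
    False for the Welch variant.  Cells with zero variance in both
    groups report NaN statistics and ``call="none"``.
    """
    pos_list = list(positives)
    neg_list = list(negatives)
    if not pos_list or not neg_list:
        raise ValueError("both fragment sets must be non-empty")
    if len(pos_list[0]) != len(neg_list[0]):
        raise ValueError(
            f"fragment length mismatch: {len(pos_list[0])} vs {len(neg_list[0])}"
        )
    pos_arr = _residue_array(pos_list)
    neg_arr = _residue_array(neg_list)

    out: list[PositionStat] = []
    for position in range(pos_arr.shape[1]):
        for nuc in NUCLEOTIDES:
            ind_pos = (pos_arr[:, position] == nuc).astype(float)
            ind_neg = (neg_arr[:, position] == nuc).astype(float)
            fp, fn_ = float(ind_pos.mean()), float(ind_neg.mean())
            if ind_pos.std() == 0 and ind_neg.std() == 0:
                t, p = float("nan"), float("nan")
            else:
                t, p = stats.ttest_ind(ind_pos, ind_neg, equal_var=equal_var)
                t, p = float(t), float(p)
            if np.isfinite(p) and p < alpha and fp > fn_:
                call = "enriched"
            elif np.isfinite(p) and p < alpha and fp < fn_:
                call = "depleted"
            else:
                call = "none"
            out.append(PositionStat(position=position, nucleotide=nuc,
                                    freq_positive=fp, freq_negative=fn_,
                                    t_statistic=t, p_value=p, call=call))
    return out


def stats_to_frame(statistics: Sequence[PositionStat]) -> pd.DataFrame:
    """Tabulate stats with 1-based display positions."""
    return pd.DataFrame(
        {
            "position": s.position + 1,
            "nucleotide": s.nucleotide,
            "freq_pos": s.freq_positive,
            "freq_neg": s.freq_negative,
            "t": s.t_statistic,
            "p": s.p_value,
            "call": s.call,
        }
        for s in statistics
    )


def write_stats_tsv(statistics: Sequence[PositionStat], path) -> None:
    stats_to_frame(statistics).to_csv(path, sep="\t", index=False,
                                      float_format="%.6g")


def _draw_letter(ax, letter: str, x: float, y0: float, height: float,
                 color: str, width: float = 0.85) -> None:
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    tp = TextPath((0, 0), letter, size=1,
                  prop=FontProperties(family="DejaVu Sans", weight="bold"))
    bbox = tp.get_extents()
    tf = (Affine2D()
          .translate(-bbox.x0, -bbox.y0)
          .scale(width / bbox.width, height / bbox.height)
          .translate(x - width / 2, y0))
    ax.add_patch(PathPatch(tp, transform=tf + ax.transData,
                           facecolor=color, edgecolor="none"))


def render_logo(
    statistics: Sequence[PositionStat],
    image_path,
    tsv_path=None,
    title: Optional[str] = None,
) -> None:
    """Render significant cells as a stacked-letter difference logo.

    Letter heights are proportional to |freq_positive − freq_negative|;
    enriched letters stack above the axis, depleted below.  The full
    cell table is always written as TSV (default: ``image_path`` with a
    ``.tsv`` suffix), so an all-``none`` result still produces output.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    image_path = Path(image_path)
    tsv_path = Path(tsv_path) if tsv_path else image_path.with_suffix(".tsv")
    write_stats_tsv(statistics, tsv_path)

    positions = sorted({s.position for s in statistics})
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(positions)), 3.2))
    max_stack = 0.0
    for position in positions:
        cells = [s for s in statistics if s.position == position]
        up = sorted((s for s in cells if s.call == "enriched"),
                    key=lambda s: abs(s.freq_positive - s.freq_negative))
        down = sorted((s for s in cells if s.call == "depleted"),
                      key=lambda s: abs(s.freq_positive - s.freq_negative))
        y = 0.0
        for s in up:
            h = abs(s.freq_positive - s.freq_negative)
            _draw_letter(ax, s.nucleotide, position + 1, y, h,
                         LOGO_COLORS[s.nucleotide])
            y += h
        max_stack = max(max_stack, y)
        y = 0.0
        for s in down:
            h = abs(s.freq_positive - s.freq_negative)
            _draw_letter(ax, s.nucleotide, position + 1, -(y + h), h,
                         LOGO_COLORS[s.nucleotide])
            y += h
        max_stack = max(max_stack, y)

    lim = max(max_stack * 1.1, 0.05)
    ax.set_xlim(0.3, len(positions) + 0.7)
    ax.set_ylim(-lim, lim)
    ax.axhline(0.0, color="black", linewidth=0.8)
    shown = positions[::2] if len(positions) > 25 else positions
    ax.set_xticks([p + 1 for p in shown], [str(p + 1) for p in shown])
    ax.set_xlabel("position (1-based)")
    ax.set_ylabel("frequency difference")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    image_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(image_path, dpi=150)
    plt.close(fig)
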