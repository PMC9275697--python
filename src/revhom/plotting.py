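"""Matplotlib rendering of sequence logos and letter maps.

Letters are drawn as stretched glyph outlines (TextPath), stacked per
column; heights are information content in bits for logos and summed
mutation-effect magnitudes for letter maps.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from .encoding import ALPHABET
from .interpretation import LetterMap, PositionFrequencyMatrix, feature_name

# chemistry-flavored letter colors
_COLORS = {}
for aa in "RKH":
    _COLORS[aa] = "#145AFF"   # basic
for aa in "DE":
    _COLORS[aa] = "#E60A0A"   # acidic
for aa in "STNQ":
    _COLORS[aa] = "#00B050"   # polar
for aa in "AVLIMFWYC":
    _COLORS[aa] = "#333333"   # hydrophobic
for aa in "GP":
    _COLORS[aa] = "#FF8C00"   # special

_FONT = FontProperties(family="DejaVu Sans", weight="bold")


def _draw_letter(ax, letter, x, y, width, height, color):
    if height <= 0:
        return
    tp = TextPath((0, 0), letter, size=1.0, prop=_FONT)
    bb = tp.get_extents()
    sx = width / bb.width
    sy = height / bb.height
    tr = (Affine2D().translate(-bb.x0, -bb.y0).scale(sx, sy).translate(x, y))
    ax.add_patch(PathPatch(tp.transformed(tr), facecolor=color, edgecolor="none"))


def render_logo(pfm: PositionFrequencyMatrix, path, cap: float = 4.0) -> None:
    """Information-content sequence logo for one feature's PFM."""
    probs = pfm.probabilities()
    ic = pfm.information_content(cap=cap)
    fig, ax = plt.subplots(figsize=(max(4, pfm.width * 0.5), 2.5))
    for j in range(pfm.width):
        p = probs[j]
        if np.any(np.isnan(p)) or ic[j] <= 0:
            continue
        heights = p * ic[j]
        order = np.argsort(heights)
        y = 0.0
        for a in order:
            h = heights[a]
            if h <= 1e-6:
                continue
            aa = ALPHABET[a]
            _draw_letter(ax, aa, j + 0.05, y, 0.9, h, _COLORS[aa])
            y += h
    ax.set_xlim(0, pfm.width)
    ax.set_ylim(0, cap)
    ax.set_xlabel("position in receptive field")
    ax.set_ylabel("bits")
    ax.set_title(feature_name(pfm.feature_id))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_letter_map(lmap: LetterMap, path, max_letters: int = 3) -> None:
    """Signed letter map: favored residues above the axis, disfavored below."""
    from .interpretation import letter_map_summary
    summary = letter_map_summary(lmap, max_letters=max_letters)
    L = len(summary)
    fig, ax = plt.subplots(figsize=(max(6, L * 0.12), 3))
    for _, row in summary.iterrows():
        i, sign, height = int(row["position"]), int(row["sign"]), row["height"]
        if sign == 0 or height <= 0:
            continue
        d = lmap.deltas[i]
        letters = row["letters"]
        mags = np.abs([d[ALPHABET.index(c)] if c != lmap.wild_type[i] else
                       max(abs(d).max(), 1e-12) for c in letters])
        if mags.sum() <= 0:
            continue
        mags = mags / mags.sum() * height
        y = 0.0
        for c, h in zip(letters, mags):
            y0 = y if sign > 0 else -(y + h)
            _draw_letter(ax, c, i + 0.05, y0, 0.9, h, _COLORS[c])
            y += h
    ymax = max(summary["height"].max(), 1e-6)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlim(0, L)
    ax.set_ylim(-ymax * 1.05, ymax * 1.05)
    ax.set_xlabel("position")
    ax.set_ylabel("favourability")
    ax.set_title(feature_name(lmap.feature_id))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
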