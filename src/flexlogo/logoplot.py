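"""Rendering of flexibility-annotated sequence logos.

The plot is a conventional stacked-letter logo (letter heights sum to
the column's base IC on a 0-2.0 bit axis) with an extra gray bar at
every intervening phosphate linkage: bar height is the linkage IC on
the 2.0-bit display scale and bar fill encodes the mean TRX score,
from black (TRX 0, stiff) to white (TRX 43, flexible).  Bars carry a
thin outline and are drawn behind the letters so near-white bars stay
visible and never occlude glyphs.

Vector output (SVG default, PDF selectable) is deterministic: the same
profile and style produce byte-identical files, with timestamps and
hash salts pinned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch, Rectangle
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from .errors import ValidationError
from .infocontent import LogoProfile
from .trx_scale import TRXScale

__all__ = ["LogoStyle", "letter_stack", "render_logo"]

# conventional logo palette
_PALETTE = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}

_FONT = FontProperties(family="DejaVu Sans", weight="bold")


@dataclass(frozen=True)
class LogoStyle:
    """Graphical parameters of the logo.

    ``bar_start`` is the x coordinate of the first linkage bar (letters
    sit at integer x = 1..L), ``bar_increment`` the spacing between
    bars; the defaults put every bar midway between adjacent letter
    columns and suit sequences around 20 bp.  The former interactive
    adjustment console is replaced by these config values.
    """

    bar_start: float = 1.5
    bar_increment: float = 1.0
    bar_width: float = 0.30
    y_max: float = 2.0
    letter_width: float = 0.9
    palette: dict = field(default_factory=lambda: dict(_PALETTE))
    fmt: str = "svg"
    fig_width_per_position: float = 0.45
    fig_height: float = 2.6

    def __post_init__(self) -> None:
        if self.bar_increment <= 0:
            raise ValidationError("bar_increment must be positive")
        if self.fmt not in {"svg", "pdf", "png"}:
            raise ValidationError(f"unsupported output format {self.fmt!r}")


def letter_stack(freqs, ic: float) -> list[tuple[str, float]]:
    """Stacked-letter geometry for one column.

    Returns (letter, height) pairs sorted ascending by frequency, the
    most frequent letter on top; ``height = p * IC`` so the heights sum
    to the column IC.  Zero-frequency letters are omitted.
    """
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValidationError("column frequencies must sum to 1")
    order = np.argsort(freqs, kind="stable")
    bases = ("A", "C", "G", "T")
    return [
        (bases[i], float(freqs[i] * ic)) for i in order if freqs[i] > 0 and ic > 0
    ]


def _draw_letter(ax, letter: str, x: float, y: float, width: float, height: float,
                 color: str) -> None:
    """One glyph stretched to fill the (width x height) box at (x, y)."""
    tp = TextPath((0, 0), letter, size=1.0, prop=_FONT)
    bb = tp.get_extents()
    transform = (
        Affine2D()
        .translate(-bb.x0, -bb.y0)
        .scale(width / bb.width, height / bb.height)
        .translate(x - width / 2, y)
    )
    ax.add_patch(
        PathPatch(transform.transform_path(tp), facecolor=color, edgecolor="none",
                  zorder=3)
    )


def render_logo(
    profile: LogoProfile,
    style: LogoStyle | None = None,
    out_path: str | Path = "logo.svg",
    scale: TRXScale | None = None,
) -> Path:
    """Render a profile to ``out_path``; format from style (or suffix).

    Bars sit at ``bar_start + (j-1) * bar_increment`` for linkage j,
    with height ``ic_link_norm[j]`` and gray fill ``shade(mean_trx[j])``.
    Unobserved columns and linkages render at zero height.
    """
    style = style or LogoStyle()
    out_path = Path(out_path)
    suffix = out_path.suffix.lstrip(".").lower()
    if suffix in {"svg", "pdf", "png"} and suffix != style.fmt:
        style = replace(style, fmt=suffix)
    L = profile.L
    n_bars = L - 1
    last_bar = style.bar_start + (n_bars - 1) * style.bar_increment
    if n_bars and not (1.0 < style.bar_start and last_bar < L):
        raise ValidationError(
            "bar positions fall outside the letter columns; adjust bar_start "
            "or bar_increment to the sequence length"
        )

    with plt.rc_context({"svg.hashsalt": "flexlogo", "svg.fonttype": "path"}):
        fig, ax = plt.subplots(
            figsize=(max(2.5, style.fig_width_per_position * L), style.fig_height)
        )
        shade = (scale or TRXScale).shade
        for j in range(n_bars):
            mean_trx = profile.mean_trx[j]
            height = float(profile.ic_link_norm[j])
            if not profile.link_observed[j] or height <= 0:
                continue
            x = style.bar_start + j * style.bar_increment
            gray = shade(float(mean_trx))
            ax.add_patch(
                Rectangle(
                    (x - style.bar_width / 2, 0),
                    style.bar_width,
                    height,
                    facecolor=(gray, gray, gray),
                    edgecolor="black",
                    linewidth=0.7,
                    zorder=2,
                )
            )
        for i in range(L):
            y = 0.0
            for letter, h in letter_stack(
                profile.base_freqs[:, i] if profile.base_observed[i] else
                np.array([0.25, 0.25, 0.25, 0.25]),
                float(profile.ic_base[i]) if profile.base_observed[i] else 0.0,
            ):
                _draw_letter(ax, letter, i + 1, y, style.letter_width, h,
                             style.palette[letter])
                y += h
        ax.set_xlim(0.4, L + 0.6)
        ax.set_ylim(0, style.y_max)
        ax.set_xticks(range(1, L + 1))
        ax.tick_params(axis="x", labelsize=7)
        ax.set_xlabel("position")
        ax.set_ylabel("information (bits)")
        ax.spines[["top", "right"]].set_visible(False)
        fig.tight_layout()
        metadata = {"Date": None} if style.fmt == "svg" else (
            {"CreationDate": None} if style.fmt == "pdf" else None
        )
        try:
            fig.savefig(out_path, format=style.fmt, metadata=metadata)
        except OSError:
            raise
        finally:
            plt.close(fig)
    return out_path
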