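"""Logo-like visualisation of a linear classifier's positional features.

Only position-specific binary features (``bin_<scheme>:pos<i>:<symbol>``)
are drawn; composition-type features (k-mers, cPseAAC, folding components)
are listed in a side table instead.

Normalisation, for coefficients c_k of the linear model and the stored
per-feature standard deviations sd_k:

* per-feature weight       w_ik = c_k / sd_k, at position i;
* per-position, per-sign sums   s_i+ = sum of positive w_ik,
                                s_i- = sum of negative w_ik;
* rescaled stack totals    S_i+ = s_i+ / max_i |s_i+|  in [0, 1],
                           S_i- = s_i- / max_i |s_i-|  in [-1, 0];
* per-entry heights        H_ik = (w_ik / sum of same-sign w at i) |S_i|,

so within a stack the positive heights sum to S_i+ and the negative heights
to |S_i-|, and the tallest positive (negative) stack has total exactly
1 (-1).  All quantities are invariant to positive rescaling of the
coefficients.  Rendering order is negative entries below the axis,
positive above.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .models import TrainedModel

_POSITIONAL = re.compile(r"^bin_([a-z_]+):pos(\d+):(.+)$")


@dataclass
class LogoEntry:
    symbol: str
    height: float  # |H_ik|, always >= 0
    sign: int  # +1 or -1


@dataclass
class LogoStack:
    position: int
    entries: list = field(default_factory=list)
    stack_positive: float = 0.0  # S_i+ in [0, 1]
    stack_negative: float = 0.0  # S_i- in [-1, 0]


def positional_weights(model: TrainedModel):
    """(position, symbol, w=c/sd) triples for positional features, plus the
    names of non-positional selected features."""
    if not model.is_linear or model.coefficients is None:
        raise ValueError("logo representation requires a linear model")
    positional, other = [], []
    for name, c, sd in zip(model.selected_features, model.coefficients, model.sds):
        m = _POSITIONAL.match(name)
        if m is None:
            other.append(name)
            continue
        sd = sd if sd > 0 else 1.0
        positional.append((int(m.group(2)), m.group(3), c / sd))
    return positional, other


def normalize_weights(model: TrainedModel) -> list[LogoStack]:
    """Build per-position logo stacks from a linear model's coefficients."""
    positional, _ = positional_weights(model)
    if not positional:
        return []
    by_pos: dict[int, list] = {}
    for pos, sym, w in positional:
        by_pos.setdefault(pos, []).append((sym, w))

    s_pos = {i: sum(w for _, w in ws if w > 0) for i, ws in by_pos.items()}
    s_neg = {i: sum(w for _, w in ws if w < 0) for i, ws in by_pos.items()}
    max_pos = max((v for v in s_pos.values()), default=0.0)
    max_neg = max((abs(v) for v in s_neg.values()), default=0.0)

    stacks = []
    for i in sorted(by_pos):
        S_plus = s_pos[i] / max_pos if max_pos > 0 else 0.0
        S_minus = s_neg[i] / max_neg if max_neg > 0 else 0.0
        stack = LogoStack(position=i, stack_positive=S_plus, stack_negative=S_minus)
        for sym, w in by_pos[i]:
            if w > 0 and s_pos[i] > 0:
                stack.entries.append(LogoEntry(sym, (w / s_pos[i]) * abs(S_plus), +1))
            elif w < 0 and s_neg[i] < 0:
                stack.entries.append(LogoEntry(sym, (w / s_neg[i]) * abs(S_minus), -1))
        stacks.append(stack)
    return stacks


def render_logo_tsv(stacks: Sequence[LogoStack], path) -> None:
    """Schema: position, symbol, sign, height, stack_total (per sign)."""
    with open(path, "w") as fh:
        fh.write("position\tsymbol\tsign\theight\tstack_total\n")
        for stack in stacks:
            for entry in sorted(
                stack.entries, key=lambda e: (e.sign, -e.height, e.symbol)
            ):
                total = stack.stack_positive if entry.sign > 0 else stack.stack_negative
                fh.write(
                    f"{stack.position}\t{entry.symbol}\t{entry.sign:+d}\t"
                    f"{entry.height:.12g}\t{total:.12g}\n"
                )


def render_logo_svg(
    stacks: Sequence[LogoStack],
    path,
    col_width: float = 18.0,
    half_height: float = 120.0,
) -> None:
    """Minimal SVG: stacked symbols above/below a zero axis, heights
    proportional to H_ik.  The TSV is the authoritative numeric output."""
    if not stacks:
        raise ValueError("no stacks to render")
    width = (max(s.position for s in stacks) + 1) * col_width + 40
    height = 2 * half_height + 40
    y0 = 20 + half_height
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" font-family="monospace">',
        f'<line x1="20" y1="{y0}" x2="{width - 20:.0f}" y2="{y0}" stroke="black"/>',
    ]
    for stack in stacks:
        x = 20 + stack.position * col_width
        up = y0
        for e in sorted((e for e in stack.entries if e.sign > 0), key=lambda e: e.height):
            h = e.height * half_height
            up -= h
            size = max(h, 4.0)
            parts.append(
                f'<text x="{x:.1f}" y="{up + h:.1f}" font-size="{size:.1f}" '
                f'fill="#1a6b2a">{_esc(e.symbol)}</text>'
            )
        down = y0
        for e in sorted((e for e in stack.entries if e.sign < 0), key=lambda e: e.height):
            h = e.height * half_height
            down += h
            size = max(h, 4.0)
            parts.append(
                f'<text x="{x:.1f}" y="{down:.1f}" font-size="{size:.1f}" '
                f'fill="#1b4f9c">{_esc(e.symbol)}</text>'
            )
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")


def _esc(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
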