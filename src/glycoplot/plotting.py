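"""Annotated-spectrum rendering: single, mirrored and aligned modes.

Figures are built on matplotlib's object-oriented API (no pyplot state) so
repeated renders of identical inputs are byte-identical in svg and pdf once
embedded timestamps are suppressed. Text in svg output stays text
(``svg.fonttype = none``), which makes labels searchable in the file and
keeps published figures editable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from matplotlib.ticker import FuncFormatter

from .errors import ValidationError
from .glycan import format_composition
from .matching import AnnotatedSpectrum, PeakMatch

#: Default per-series peak/label colors; unmatched peaks are grey.
SERIES_COLORS: dict[str, str] = {
    "b": "#d62728",      # red
    "y": "#1f77b4",      # blue
    "c": "#17becf",      # teal
    "z": "#ff7f0e",      # orange
    "Y": "#1a6b1a",      # dark green
    "B": "#9467bd",      # purple
    "oxonium": "#e377c2",  # magenta
    "precursor": "#8c564b",
}
UNMATCHED_COLOR = "#9e9e9e"

VECTOR_FORMATS = ("svg", "pdf", "eps")
RASTER_FORMATS = ("png",)


@dataclass
class RenderSpec:
    """Rendering parameters (image size, axis range, labelled ion info)."""

    mode: str = "single"  # single | mirrored | aligned
    width: float = 10.0   # inches
    height: float = 6.0   # inches (per pane in aligned mode)
    mz_range: tuple[float, float] | None = None
    relative_intensity: bool = True  # scale max peak to 100% per pane
    label_series: frozenset[str] | None = None  # None: label everything matched
    label_ion_name: bool = True
    label_mz: bool = False
    label_charge: bool = True  # charge is part of the ion name suffix
    colors: dict[str, str] = field(default_factory=dict)
    fmt: str | None = None  # inferred from the path when None
    dpi: int = 100

    def __post_init__(self) -> None:
        if self.mode not in ("single", "mirrored", "aligned"):
            raise ValidationError(f"unknown render mode {self.mode!r}")
        if self.mz_range is not None and not self.mz_range[0] < self.mz_range[1]:
            raise ValidationError("mz_range must satisfy min < max")
        if self.fmt is not None and self.fmt not in VECTOR_FORMATS + RASTER_FORMATS:
            raise ValidationError(
                f"unsupported format {self.fmt!r}; choose from "
                f"{VECTOR_FORMATS + RASTER_FORMATS}"
            )

    def color_for(self, series: str) -> str:
        return self.colors.get(series, SERIES_COLORS.get(series, UNMATCHED_COLOR))


def _format_for(path: Path, spec: RenderSpec) -> str:
    fmt = spec.fmt or path.suffix.lstrip(".").lower()
    if fmt not in VECTOR_FORMATS + RASTER_FORMATS:
        raise ValidationError(
            f"unsupported output format {fmt!r}; choose from "
            f"{VECTOR_FORMATS + RASTER_FORMATS}"
        )
    return fmt


def _new_figure(spec: RenderSpec, n_panes: int = 1) -> Figure:
    fig = Figure(figsize=(spec.width, spec.height * n_panes), dpi=spec.dpi)
    FigureCanvasAgg(fig)
    return fig


def _label_text(match: PeakMatch, spec: RenderSpec) -> str:
    parts: list[str] = []
    if spec.label_ion_name:
        label = match.ion.label
        if not spec.label_charge:
            label = label.split("^")[0]
        parts.append(label)
    if spec.label_mz:
        parts.append(f"{match.ion.mz:.3f}")
    return " ".join(parts)


def _pane_title(a: AnnotatedSpectrum) -> str:
    ident = a.identification
    title = str(ident.peptide)
    comp = ident.glycan_composition
    if ident.glycan_tree is not None:
        comp = ident.glycan_tree.composition()
    if comp:
        title += f" + {format_composition(comp)}"
    title += f"  (scan {a.spectrum.scan_number}, {a.spectrum.activation.value})"
    return title


def _draw_pane(
    ax,
    a: AnnotatedSpectrum,
    spec: RenderSpec,
    sign: float = 1.0,
    mz_range: tuple[float, float] | None = None,
) -> None:
    """Draw one spectrum into ``ax``; ``sign=-1`` mirrors it downward."""
    mz = a.spectrum.mz
    intensity = a.spectrum.intensity.astype(float)
    rng = mz_range or spec.mz_range
    scale = 1.0
    if spec.relative_intensity and intensity.size and intensity.max() > 0:
        scale = 100.0 / intensity.max()
    heights = intensity * scale * sign

    labels = a.peak_labels()
    if spec.label_series is not None:
        labels = {i: m for i, m in labels.items() if m.ion.series in spec.label_series}
    matched_idx = set(labels)
    all_matched = {m.peak_index for m in a.matches}

    unmatched = [i for i in range(mz.size) if i not in all_matched]
    if unmatched:
        ax.vlines(mz[unmatched], 0, heights[unmatched], color=UNMATCHED_COLOR,
                  linewidth=0.8, zorder=1)
    by_series: dict[str, list[int]] = {}
    for i in sorted(all_matched):
        series = labels[i].ion.series if i in labels else next(
            m.ion.series for m in a.matches if m.peak_index == i
        )
        by_series.setdefault(series, []).append(i)
    for series in sorted(by_series):
        idx = by_series[series]
        ax.vlines(mz[idx], 0, heights[idx], color=spec.color_for(series),
                  linewidth=1.4, zorder=2)

    # greedy label placement: intensity-descending, nudge upward on x-overlap
    if rng is None and mz.size:
        span = float(mz.max() - mz.min()) or 1.0
    else:
        span = (rng[1] - rng[0]) if rng else 1.0
    min_dx = span * 0.02
    placed: list[tuple[float, float]] = []  # (x, tier)
    ymax = 100.0 if spec.relative_intensity else (float(intensity.max()) if intensity.size else 1.0)
    for i in sorted(matched_idx, key=lambda j: -intensity[j]):
        if rng is not None and not rng[0] <= mz[i] <= rng[1]:
            continue
        tier = 0
        for x, t in placed:
            if abs(x - mz[i]) < min_dx and t == tier:
                tier += 1
        placed.append((float(mz[i]), tier))
        text = _label_text(labels[i], spec)
        if not text:
            continue
        offset = ymax * 0.03 * (1 + tier)
        ax.text(
            mz[i], heights[i] + sign * offset, text,
            rotation=90, ha="center",
            va="bottom" if sign > 0 else "top",
            fontsize=7, color=spec.color_for(labels[i].ion.series),
            clip_on=True,
        )

    if rng is not None:
        ax.set_xlim(*rng)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.spines["top"].set_visible(False)
    ax.spines["right"].set_visible(False)


def _finish_axes(ax, spec: RenderSpec, mirrored: bool = False) -> None:
    ax.set_xlabel("m/z")
    ax.set_ylabel("Relative intensity (%)" if spec.relative_intensity else "Intensity")
    if mirrored:
        ax.yaxis.set_major_formatter(FuncFormatter(lambda v, _pos: f"{abs(v):g}"))


def _save(fig: Figure, path: str | Path, spec: RenderSpec) -> Path:
    path = Path(path)
    fmt = _format_for(path, spec)
    with _deterministic_rc():
        if fmt == "svg":
            fig.savefig(path, format="svg", metadata={"Date": None})
        elif fmt == "pdf":
            fig.savefig(
                path, format="pdf",
                metadata={"CreationDate": None, "Producer": "glycoplot", "Creator": "glycoplot"},
            )
        elif fmt == "eps":
            fig.savefig(path, format="eps")
        else:
            fig.savefig(path, format=fmt, dpi=spec.dpi)
    return path


class _deterministic_rc:
    """Pin rc settings that affect vector-output reproducibility."""

    def __enter__(self):
        import matplotlib

        self._old = {
            k: matplotlib.rcParams[k]
            for k in ("svg.hashsalt", "svg.fonttype", "pdf.fonttype", "ps.fonttype")
        }
        matplotlib.rcParams["svg.hashsalt"] = "glycoplot"
        matplotlib.rcParams["svg.fonttype"] = "none"
        matplotlib.rcParams["pdf.fonttype"] = 42
        matplotlib.rcParams["ps.fonttype"] = 42
        return self

    def __exit__(self, *exc):
        import matplotlib

        matplotlib.rcParams.update(self._old)
        return False


def render_single(a: AnnotatedSpectrum, spec: RenderSpec, path: str | Path) -> Path:
    """Render one annotated spectrum to ``path``."""
    if spec.mode != "single":
        raise ValidationError(f"render_single requires mode 'single', got {spec.mode!r}")
    fig = _new_figure(spec)
    ax = fig.add_subplot(1, 1, 1)
    _draw_pane(ax, a, spec)
    if spec.relative_intensity:
        ax.set_ylim(0, 115)
    ax.set_title(_pane_title(a), fontsize=9)
    _finish_axes(ax, spec)
    fig.tight_layout()
    return _save(fig, path, spec)


def _union_range(
    annotated: Sequence[AnnotatedSpectrum], spec: RenderSpec
) -> tuple[float, float] | None:
    if spec.mz_range is not None:
        return spec.mz_range
    los = [float(a.spectrum.mz.min()) for a in annotated if len(a.spectrum)]
    his = [float(a.spectrum.mz.max()) for a in annotated if len(a.spectrum)]
    if not los:
        return None
    pad = (max(his) - min(los)) * 0.02 or 1.0
    return (min(los) - pad, max(his) + pad)


def render_mirrored(
    a1: AnnotatedSpectrum, a2: AnnotatedSpectrum, spec: RenderSpec, path: str | Path
) -> Path:
    """Render two spectra sharing the x-axis, the second mirrored downward."""
    if spec.mode != "mirrored":
        raise ValidationError(f"render_mirrored requires mode 'mirrored', got {spec.mode!r}")
    fig = _new_figure(spec)
    ax = fig.add_subplot(1, 1, 1)
    rng = _union_range((a1, a2), spec)
    _draw_pane(ax, a1, spec, sign=1.0, mz_range=rng)
    _draw_pane(ax, a2, spec, sign=-1.0, mz_range=rng)
    if spec.relative_intensity:
        ax.set_ylim(-115, 115)
    ax.set_title(f"{_pane_title(a1)}\nvs {_pane_title(a2)}", fontsize=9)
    _finish_axes(ax, spec, mirrored=True)
    fig.tight_layout()
    return _save(fig, path, spec)


def render_aligned(
    annotated: Sequence[AnnotatedSpectrum], spec: RenderSpec, path: str | Path
) -> Path:
    """Render >= 2 spectra stacked vertically with identical x-limits."""
    if spec.mode != "aligned":
        raise ValidationError(f"render_aligned requires mode 'aligned', got {spec.mode!r}")
    if len(annotated) < 2:
        raise ValidationError("aligned mode needs at least 2 spectra")
    fig = _new_figure(spec, n_panes=len(annotated))
    rng = _union_range(annotated, spec)
    axes = fig.subplots(len(annotated), 1, sharex=True)
    for ax, a in zip(axes, annotated):
        _draw_pane(ax, a, spec, mz_range=rng)
        if spec.relative_intensity:
            ax.set_ylim(0, 115)
        ax.set_title(_pane_title(a), fontsize=9)
        ax.set_ylabel("Relative intensity (%)" if spec.relative_intensity else "Intensity")
    axes[-1].set_xlabel("m/z")
    fig.tight_layout()
    return _save(fig, path, spec)
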