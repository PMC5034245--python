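"""Spiral (wenxiang) diagrams of helical phase positions.

Each residue is represented by the average position of its N, Cα, C and
O atoms.  Observed and model phases are measured in the fitted helix's
basis frame and offset so the first residue of the fitted model lies on
the horizontal axis (phase 0).  Residues are placed on an expanding
spiral (radius grows linearly with residue index) and colored in cycles
of black, red, green and blue; observed positions are solid dots, fitted
positions open circles — their superposition shows the goodness of fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from helixforge.model import FitResult, build_basis, generate_helix_coordinates

__all__ = ["SpiralDiagram", "make_spiral", "render_spiral", "write_spiral_table"]

#: inner radius and per-residue radial growth of the spiral (unitless
#: plotting constants)
SPIRAL_INNER_RADIUS = 1.0
SPIRAL_GROWTH_PER_RESIDUE = 0.18

COLOR_CYCLE = ("black", "red", "green", "blue")


@dataclass(frozen=True)
class SpiralDiagram:
    """Per-residue observed and fitted phases of one helical segment.

    Phases are degrees in [0, 360); the first residue's fitted phase is
    0 by construction.  ``spiral_arm_radius`` is the unitless plotting
    radius, increasing with residue index; ``color_cycle_index`` cycles
    0-3 through black/red/green/blue.
    """

    residue_ids: tuple[str, ...]
    observed_phase: np.ndarray
    fitted_phase: np.ndarray
    spiral_arm_radius: np.ndarray
    color_cycle_index: np.ndarray
    label: str = ""


def make_spiral(segment, fit: FitResult) -> SpiralDiagram:
    """Build spiral-diagram data from a segment and its converged fit.

    The observed phase of residue i is the azimuth, in the fit's basis
    frame, of the projection of the residue's four-atom average position
    onto the plane normal to the axis; the fitted phase advances by
    exactly Ω per residue index.  Both are offset so the fitted model's
    first residue sits at 0°.
    """
    if not fit.converged:
        raise ValueError("spiral diagram requires a converged fit")
    coords = np.asarray(segment.coords, dtype=float)
    idx = np.asarray(fit.residue_indices, dtype=float)
    if len(coords) != len(idx):
        raise ValueError("segment and fit size mismatch")
    p = fit.params
    frame = build_basis(p.n)
    model = generate_helix_coordinates(p, frame, idx)

    def azimuth(points: np.ndarray) -> np.ndarray:
        rel = points - p.P[None, :]
        perp = rel - (rel @ p.n)[:, None] * p.n[None, :]
        return np.degrees(np.arctan2(perp @ frame.b, perp @ frame.a))

    obs_mean = coords.mean(axis=1)
    fit_mean = model.mean(axis=1)
    ref = azimuth(fit_mean[:1])[0]  # fitted first residue defines phase 0
    observed = (azimuth(obs_mean) - ref) % 360.0
    fitted = (azimuth(fit_mean) - ref) % 360.0
    pos = np.arange(len(idx))
    return SpiralDiagram(
        residue_ids=tuple(getattr(segment, "residue_ids", map(str, pos))),
        observed_phase=observed,
        fitted_phase=fitted,
        spiral_arm_radius=SPIRAL_INNER_RADIUS + SPIRAL_GROWTH_PER_RESIDUE * pos,
        color_cycle_index=pos % 4,
        label=fit.label or getattr(segment, "label", ""),
    )


def render_spiral(diagram: SpiralDiagram, path) -> None:
    """Render a spiral diagram to a deterministic SVG file.

    Solid dots mark observed phases, open circles the fitted ones; the
    first residue lies on the +x axis.  Identical inputs produce
    byte-identical files.
    """
    if len(diagram.residue_ids) == 0:
        raise ValueError("cannot render an empty spiral diagram")
    with matplotlib.rc_context({"svg.hashsalt": "helixforge"}):
        fig, ax = plt.subplots(figsize=(5, 5))
        theta = np.linspace(
            0, 2 * np.pi * (len(diagram.residue_ids) + 4) / 4, 400
        )
        guide_r = SPIRAL_INNER_RADIUS + SPIRAL_GROWTH_PER_RESIDUE * theta * 4 / (2 * np.pi)
        ax.plot(guide_r * np.cos(theta), guide_r * np.sin(theta),
                color="0.85", lw=0.6, zorder=0)
        for k, (rid, obs, fitp, radius, ci) in enumerate(zip(
            diagram.residue_ids,
            diagram.observed_phase,
            diagram.fitted_phase,
            diagram.spiral_arm_radius,
            diagram.color_cycle_index,
        )):
            color = COLOR_CYCLE[int(ci)]
            (dot,) = ax.plot(
                radius * np.cos(np.radians(obs)),
                radius * np.sin(np.radians(obs)),
                marker="o", ms=6, color=color, ls="none", zorder=2,
            )
            dot.set_gid(f"observed-{k}")
            (circle,) = ax.plot(
                radius * np.cos(np.radians(fitp)),
                radius * np.sin(np.radians(fitp)),
                marker="o", ms=9, mfc="none", mec=color, ls="none", zorder=1,
            )
            circle.set_gid(f"fitted-{k}")
        ax.axhline(0, color="0.7", lw=0.5, zorder=0)
        ax.set_aspect("equal")
        ax.set_axis_off()
        ax.set_title(diagram.label or "spiral diagram")
        fig.savefig(path, format="svg", metadata={"Date": None})
        plt.close(fig)


def write_spiral_table(diagram: SpiralDiagram, path) -> None:
    """Dump spiral-diagram entries as TSV."""
    lines = ["residue_id\tobserved_phase\tfitted_phase\tradius\tcolor_index"]
    for rid, obs, fitp, radius, ci in zip(
        diagram.residue_ids,
        diagram.observed_phase,
        diagram.fitted_phase,
        diagram.spiral_arm_radius,
        diagram.color_cycle_index,
    ):
        lines.append(f"{rid}\t{obs:.6g}\t{fitp:.6g}\t{radius:.6g}\t{int(ci)}")
    Path(path).write_text("\n".join(lines) + "\n")
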