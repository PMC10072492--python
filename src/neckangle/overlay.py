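"""Debug/documentation overlay: the geometric construction on a slab."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .measurement import Slice2D, TorsionMeasurement


def plot_construction(slab: Slice2D, measurement: TorsionMeasurement,
                      path=None, *, dpi: int = 150):
    """Render the slab with tangent, parallel line, circles and axes.

    Saves to ``path`` (PNG/SVG by extension) if given, else returns the
    matplotlib figure.
    """
    ny, nx = slab.values.shape
    x0, y0 = slab.origin2d
    extent = [x0, x0 + (nx - 1) * slab.spacing[0],
              y0, y0 + (ny - 1) * slab.spacing[1]]
    fig, ax = plt.subplots(figsize=(8, 6))
    ax.imshow(slab.values, origin="lower", extent=extent, cmap="gray")

    def draw_line(line, color, label):
        t = np.linspace(-120, 120, 2)
        seg = line.point[None, :] + t[:, None] * line.direction[None, :]
        ax.plot(seg[:, 0], seg[:, 1], color=color, lw=1.2, label=label)

    draw_line(measurement.tangent, "tab:orange", "tangent (GT ventral cortex)")
    draw_line(measurement.parallel, "tab:red", "parallel (dorsal border)")
    draw_line(measurement.axes.medial_axis, "tab:cyan", "medial axis")
    draw_line(measurement.axes.lateral_axis, "tab:green", "lateral axis")
    names = ["head", "lateral opening", "neck 1", "neck 2"]
    for circ, name in zip(measurement.circles, names):
        ax.add_patch(plt.Circle(circ.center, circ.radius, fill=False,
                                ec="yellow", lw=1.0))
        ax.annotate(name, circ.center, color="yellow", fontsize=7,
                    ha="center")
    ax.set_xlim(extent[0], extent[1])
    ax.set_ylim(extent[2], extent[3])
    ax.set_xlabel("along neck axis (mm, medial →)")
    ax.set_ylabel("ventral (mm)")
    ax.set_title(f"direct torsion measurement: {measurement.angle_deg:+.2f}°")
    ax.legend(loc="lower left", fontsize=7)
    if path is not None:
        fig.savefig(path, dpi=dpi, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
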