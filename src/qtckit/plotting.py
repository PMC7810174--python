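"""Optional static plots (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .agreement import BlandAltmanResult


def bland_altman_plot(values_a, values_b, result: BlandAltmanResult, path: str | Path) -> Path:
    """Save a Bland-Altman scatter (mean vs difference) with bias and LOA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((a + b) / 2.0, a - b, s=12, alpha=0.6)
    for y, style, label in (
        (result.bias, "-", f"bias {result.bias:.2f}"),
        (result.loa_lower, "--", f"LOA {result.loa_lower:.2f}"),
        (result.loa_upper, "--", f"LOA {result.loa_upper:.2f}"),
    ):
        ax.axhline(y, linestyle=style, color="crimson", linewidth=1)
        ax.annotate(label, (ax.get_xlim()[1], y), fontsize=8, ha="right", va="bottom")
    ax.set_xlabel(f"mean of {result.method_a} and {result.method_b} (ms)")
    ax.set_ylabel(f"{result.method_a} - {result.method_b} (ms)")
    ax.set_title(f"Bland-Altman: {result.pair}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
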